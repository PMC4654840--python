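"""Two-species synthetic worlds with tunable co-expression conservation.

Species-A genes are partitioned into co-expression modules plus background.
Each homologous gene's species-B copy keeps its module with probability
``1 - z`` (z = the module's divergence) and is otherwise reassigned, so low-z
modules stay conserved across species and high-z modules scatter.  Per-pair
dN/dS is drawn from a Gamma whose mean increases linearly in z and by
relationship class (one2one < one2many < many2many), which plants a negative
association between co-expression conservation and molecular evolution rate.
Expression follows a module-latent Gaussian model so the vote-counting map
builder is exercised on realistic input.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from coexcons.coexpr import CoexpressionMap, ExpressionDataset
from coexcons.genesets import GeneSetCollection
from coexcons.homology import HomologyTable, classify_relationships

logger = logging.getLogger(__name__)

_CLASS_CODES = ("one2one", "one2many", "many2many", "nonhomolog")


@dataclass
class GeneratorConfig:
    """Knobs for :func:`generate_world`; defaults give a small, fast world."""

    n_genes_a: int = 500
    n_genes_b: int = 500
    n_datasets: int = 10
    n_conditions: int = 8
    n_modules: int = 10
    module_size: int = 20
    #: per-module divergence in [0, 1]; default: linspace(0, 1, n_modules)
    divergence: Sequence[float] | None = None
    p_one2one: float = 0.55
    p_one2many: float = 0.08
    p_many2many: float = 0.07
    p_nonhomolog: float = 0.30
    duplication_count: int = 2
    dnds_shape: float = 3.0
    dnds_base: float = 0.05
    dnds_slope: float = 0.25
    class_offsets: dict = field(
        default_factory=lambda: {"one2one": 0.0, "one2many": 0.05, "many2many": 0.10}
    )
    noise_sigma: float = 1.0
    background_z: float = 0.5
    n_planted_per_type: int = 3
    planted_set_size: int = 15
    n_null_sets: int = 20

    def __post_init__(self) -> None:
        for name in ("n_genes_a", "n_genes_b", "n_datasets", "n_conditions",
                     "n_modules", "module_size", "duplication_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        mix = (self.p_one2one, self.p_one2many, self.p_many2many, self.p_nonhomolog)
        if any(p < 0 or p > 1 for p in mix):
            raise ValueError("homology mix probabilities must be in [0, 1]")
        if sum(mix) > 1 + 1e-9:
            raise ValueError("homology mix probabilities must sum to <= 1")
        if self.n_modules * self.module_size > self.n_genes_a:
            raise ValueError("module sizes exceed the species-A universe")
        if self.divergence is None:
            self.divergence = np.linspace(0.0, 1.0, self.n_modules).tolist()
        self.divergence = [float(z) for z in self.divergence]
        if len(self.divergence) != self.n_modules:
            raise ValueError("divergence must have one entry per module")
        if any(z < 0 or z > 1 for z in self.divergence):
            raise ValueError("divergence values must lie in [0, 1]")

    @classmethod
    def standard(cls) -> "GeneratorConfig":
        """The full-size benchmark world (2,000 genes/species, 40x25 modules)."""
        return cls(
            n_genes_a=2000,
            n_genes_b=2000,
            n_datasets=50,
            n_conditions=10,
            n_modules=40,
            module_size=25,
            p_one2one=0.70,
            p_one2many=0.06,
            p_many2many=0.06,
            p_nonhomolog=0.18,
            noise_sigma=1.0,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class SyntheticTruth:
    """Ground truth of a generated world (module labels, divergence, set roles)."""

    module_a: dict[str, int]
    module_b: dict[str, int]
    z_module: list[float]
    gene_z_a: dict[str, float]
    set_labels: dict[str, str]  # set name -> conserved | diverged | duplication | null

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class SyntheticWorld:
    """Everything :func:`generate_world` produces, plus file-format writers."""

    datasets_a: list[ExpressionDataset]
    datasets_b: list[ExpressionDataset]
    homology: HomologyTable
    genesets: GeneSetCollection
    truth: SyntheticTruth
    config: GeneratorConfig
    seed: int

    def write(self, outdir) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for side, datasets in (("a", self.datasets_a), ("b", self.datasets_b)):
            for i, ds in enumerate(datasets):
                path = outdir / f"expression_{side}_{i:03d}.tsv"
                ds.to_tsv(path)
                written.append(path)
        self.homology.to_tsv(outdir / "homology.tsv")
        self.genesets.to_gmt(outdir / "genesets.gmt")
        self.truth.to_json(outdir / "truth.json")
        self.config.to_yaml(outdir / "generator_config.yaml")
        written += [
            outdir / "homology.tsv",
            outdir / "genesets.gmt",
            outdir / "truth.json",
            outdir / "generator_config.yaml",
        ]
        return written


def _inherit_module(module: int, z: Sequence[float], n_modules: int, rng) -> int:
    """Species-B module of a homolog: retained with prob 1-z, else reassigned."""
    if module < 0:
        return -1
    if rng.random() >= z[module]:
        return module
    # uniform over the other modules plus background
    choices = [m for m in range(-1, n_modules) if m != module]
    return int(choices[rng.integers(len(choices))])


def generate_world(config: GeneratorConfig, seed: int = 0) -> SyntheticWorld:
    """Generate expression data, homology, dN/dS and planted gene sets.

    Deterministic for a fixed ``(config, seed)``: identical calls produce
    byte-identical outputs when written to disk.
    """
    rng = np.random.default_rng(seed)
    cfg = config
    n_modules = cfg.n_modules
    z = list(cfg.divergence)

    genes_a = [f"hA{i:05d}" for i in range(cfg.n_genes_a)]
    perm = rng.permutation(cfg.n_genes_a)
    module_a = {g: -1 for g in genes_a}
    for slot, gi in enumerate(perm[: n_modules * cfg.module_size]):
        module_a[genes_a[gi]] = slot // cfg.module_size

    # homology classes per species-A gene
    probs = [cfg.p_one2one, cfg.p_one2many, cfg.p_many2many]
    probs.append(max(0.0, 1.0 - sum(probs)))
    class_draw = rng.choice(4, size=cfg.n_genes_a, p=np.array(probs) / sum(probs))

    pairs: list[tuple[str, str]] = []
    module_b: dict[str, int] = {}
    b_counter = 0

    def new_b_gene(source_module: int) -> str:
        nonlocal b_counter
        g = f"mB{b_counter:05d}"
        b_counter += 1
        module_b[g] = _inherit_module(source_module, z, n_modules, rng)
        return g

    m2m_buffer: list[str] = []
    for gi, g in enumerate(genes_a):
        code = _CLASS_CODES[class_draw[gi]]
        if code == "one2one":
            pairs.append((g, new_b_gene(module_a[g])))
        elif code == "one2many":
            for _ in range(cfg.duplication_count):
                pairs.append((g, new_b_gene(module_a[g])))
        elif code == "many2many":
            m2m_buffer.append(g)
            if len(m2m_buffer) == 2:
                block_b = [new_b_gene(module_a[a]) for a in m2m_buffer]
                for a in m2m_buffer:
                    for b in block_b:
                        pairs.append((a, b))
                m2m_buffer = []
    if m2m_buffer:  # odd leftover becomes a plain duplication
        a = m2m_buffer[0]
        for _ in range(2):
            pairs.append((a, new_b_gene(module_a[a])))

    while b_counter < cfg.n_genes_b:  # non-homologous species-B background
        g = f"mB{b_counter:05d}"
        b_counter += 1
        module_b[g] = -1
    genes_b = sorted(module_b)

    relationship = classify_relationships(pairs)

    # dN/dS coupled to the divergence of the species-A gene's module
    gene_z_a = {
        g: (z[m] if (m := module_a[g]) >= 0 else cfg.background_z) for g in genes_a
    }
    dn = np.empty(len(pairs))
    ds = np.empty(len(pairs))
    for i, ((a, _), rel) in enumerate(zip(pairs, relationship)):
        mean = cfg.dnds_base + cfg.dnds_slope * gene_z_a[a] + cfg.class_offsets[rel]
        ratio = rng.gamma(cfg.dnds_shape, mean / cfg.dnds_shape)
        ds[i] = rng.uniform(0.5, 2.0)
        dn[i] = ratio * ds[i]

    homology = HomologyTable(
        pairs=pairs,
        relationship=relationship,
        dn=dn,
        ds=ds,
        universe_a=set(genes_a),
        universe_b=set(genes_b),
    )

    datasets_a = _expression_datasets(
        genes_a, module_a, cfg, rng, prefix="dsA"
    )
    datasets_b = _expression_datasets(
        genes_b, module_b, cfg, rng, prefix="dsB"
    )

    genesets, set_labels = _planted_sets(
        genes_a, module_a, z, homology, cfg, rng
    )
    truth = SyntheticTruth(
        module_a=module_a,
        module_b=module_b,
        z_module=z,
        gene_z_a=gene_z_a,
        set_labels=set_labels,
    )
    return SyntheticWorld(
        datasets_a=datasets_a,
        datasets_b=datasets_b,
        homology=homology,
        genesets=genesets,
        truth=truth,
        config=cfg,
        seed=seed,
    )


def _expression_datasets(genes, module_of, cfg, rng, prefix):
    mod_idx = np.array([module_of[g] for g in genes])
    in_mod = mod_idx >= 0
    datasets = []
    for d in range(cfg.n_datasets):
        latent = rng.standard_normal((cfg.n_modules, cfg.n_conditions))
        values = rng.standard_normal((len(genes), cfg.n_conditions)) * cfg.noise_sigma
        values[in_mod] += latent[mod_idx[in_mod]]
        datasets.append(
            ExpressionDataset(
                genes=list(genes),
                conditions=[f"{prefix}{d:03d}_c{j}" for j in range(cfg.n_conditions)],
                values=values,
                name=f"{prefix}{d:03d}",
            )
        )
    return datasets


def _planted_sets(genes_a, module_a, z, homology, cfg, rng):
    order = np.argsort(z, kind="stable")
    low_modules = set(order[: max(1, cfg.n_planted_per_type)].tolist())
    high_modules = set(order[::-1][: max(1, cfg.n_planted_per_type)].tolist())
    homolog_a = homology.homolog_genes_a
    pools = {
        "conserved": [g for g in genes_a if module_a[g] in low_modules and g in homolog_a],
        "diverged": [g for g in genes_a if module_a[g] in high_modules and g in homolog_a],
        "duplication": sorted(homology.duplicated_genes_a),
    }
    sets: dict[str, list[str]] = {}
    labels: dict[str, str] = {}
    for kind in ("conserved", "diverged", "duplication"):
        pool = pools[kind]
        for i in range(cfg.n_planted_per_type):
            size = min(cfg.planted_set_size, len(pool))
            if size < 2:
                logger.warning("pool for %s sets too small; skipping", kind)
                break
            name = f"{kind}_{i:02d}"
            sets[name] = sorted(rng.choice(pool, size=size, replace=False).tolist())
            labels[name] = kind
    for i in range(cfg.n_null_sets):
        name = f"null_{i:02d}"
        size = min(cfg.planted_set_size, len(genes_a))
        sets[name] = sorted(rng.choice(genes_a, size=size, replace=False).tolist())
        labels[name] = "null"
    return GeneSetCollection(sets=sets, source="synthetic"), labels


# -- direct-map shortcut generators (fast unit-test substrate) ----------


def random_map(n_genes: int, seed: int = 0, species: str = "toy") -> CoexpressionMap:
    """A structureless symmetric map with uniform scores (for property tests)."""
    rng = np.random.default_rng(seed)
    genes = [f"{species}{i:04d}" for i in range(n_genes)]
    upper = rng.uniform(0.0, 1.0, size=(n_genes, n_genes))
    values = np.triu(upper, k=1)
    values = values + values.T
    return CoexpressionMap(species=species, genes=genes, values=values)


def generate_map_pair(
    n_genes: int = 60,
    n_modules: int = 4,
    z: float = 0.0,
    seed: int = 0,
    within: tuple[float, float] = (0.6, 1.0),
    between: tuple[float, float] = (0.0, 0.4),
) -> tuple[CoexpressionMap, CoexpressionMap, HomologyTable]:
    """Directly synthesize two module-structured maps linked by one2one homology.

    Gene ``hA_i`` is the one2one homolog of ``mB_i``; species-B genes keep
    their module with probability ``1 - z``.  Skips the expression layer, so
    unit tests of CCG / network logic stay fast.
    """
    rng = np.random.default_rng(seed)
    genes_a = [f"hA{i:04d}" for i in range(n_genes)]
    genes_b = [f"mB{i:04d}" for i in range(n_genes)]
    size = n_genes // n_modules
    module_a = np.array([min(i // size, n_modules - 1) for i in range(n_genes)])
    reassign = rng.random(n_genes) < z
    module_b = module_a.copy()
    module_b[reassign] = rng.integers(0, n_modules, size=int(reassign.sum()))

    def module_map(modules):
        upper = rng.uniform(*between, size=(n_genes, n_genes))
        same = modules[:, None] == modules[None, :]
        upper[same] = rng.uniform(*within, size=int(same.sum()))
        values = np.triu(upper, k=1)
        return values + values.T

    map_a = CoexpressionMap(species="A", genes=genes_a, values=module_map(module_a))
    map_b = CoexpressionMap(species="B", genes=genes_b, values=module_map(module_b))
    pairs = list(zip(genes_a, genes_b))
    mean = 0.05 + 0.25 * z
    ratio = rng.gamma(3.0, mean / 3.0, size=n_genes)
    ds = rng.uniform(0.5, 2.0, size=n_genes)
    table = HomologyTable(
        pairs=pairs,
        relationship=["one2one"] * n_genes,
        dn=ratio * ds,
        ds=ds,
        universe_a=set(genes_a),
        universe_b=set(genes_b),
    )
    return map_a, map_b, table
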