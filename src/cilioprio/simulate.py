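"""Seeded synthetic data with planted ground truth for every pipeline stage.

Three generators:

* :func:`gen_variant_table` — annotated variant tables in which every
  background variant is constructed to fail exactly one cascade rule
  (frequency, conservation or pathogenicity) or to pass without forming a
  recessive genotype, while planted variants pass all rules and form the
  configured compound-heterozygous or homozygous genotype.
* :func:`gen_scrna_counts` — negative-binomial gene-by-cell UMI counts with
  type-specific marker genes, a seed disease gene expressed in a chosen set of
  cell types, planted co-expressed partner genes sharing that set, planted
  null genes on the complementary set, mitochondrial genes (``MT-`` prefix)
  and injected QC-outlier cells.
* :func:`gen_cohort` — patient-level tables with per-group binary events and
  continuous variables.

Each generator returns its output together with a ground-truth ledger, and is
a pure function of its config (identical seeds give identical outputs).  The
simulations deliberately omit LD structure, sequencing error, batch effects
and ambient RNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .variants import (
    AF_FIELDS,
    PREDICTION_TOOLS,
    AnnotatedVariant,
    Consequence,
    Genotype,
    ToolCall,
)

__all__ = [
    "PlantedVariant",
    "VariantSimConfig",
    "ScrnaSimConfig",
    "CohortSimConfig",
    "gen_variant_table",
    "gen_scrna_counts",
    "gen_cohort",
]


# ---------------------------------------------------------------------------
# Variant tables


@dataclass(frozen=True)
class PlantedVariant:
    gene: str
    mechanism: str  # "compound_het" | "homozygous"
    sample_index: int

    def __post_init__(self) -> None:
        if self.mechanism not in ("compound_het", "homozygous"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.sample_index < 0:
            raise ValueError("sample_index must be >= 0")


@dataclass(frozen=True)
class VariantSimConfig:
    """Background variants fail one rule each; planted ones pass and pair up.

    ``rule_fail_fractions`` gives the multinomial probabilities of the four
    background categories (frequency-fail, conservation-fail,
    pathogenicity-fail, benign-pass); each background variant lands in its own
    gene so passes never combine into a recessive genotype by accident.
    """

    n_background_variants: int = 500
    n_samples: int = 9
    planted: tuple[PlantedVariant, ...] = (
        PlantedVariant("PKHD1", "compound_het", 0),
        PlantedVariant("CRB3", "homozygous", 4),
    )
    rule_fail_fractions: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background_variants < 0 or self.n_samples <= 0:
            raise ValueError("counts must be positive")
        if abs(sum(self.rule_fail_fractions) - 1.0) > 1e-9 or any(
            f < 0 for f in self.rule_fail_fractions
        ):
            raise ValueError("rule_fail_fractions must be nonnegative and sum to 1")
        for p in self.planted:
            if p.sample_index >= self.n_samples:
                raise ValueError("planted sample_index out of range")
        if any(p.gene.startswith("BGGENE") for p in self.planted):
            raise ValueError("planted genes must not collide with background gene names")


_BASES = np.array(list("ACGT"))


def _rare_afs(rng: np.random.Generator) -> dict[str, float | None]:
    """Frequencies all either absent or strictly below 0.01."""
    out: dict[str, float | None] = {}
    for name in AF_FIELDS:
        out[name] = None if rng.random() < 0.5 else float(rng.uniform(0, 0.009))
    return out


def _tool_votes(rng: np.random.Generator, n_damaging: int) -> dict[str, ToolCall]:
    tools = list(PREDICTION_TOOLS)
    rng.shuffle(tools)
    calls = {}
    for i, t in enumerate(tools):
        if i < n_damaging:
            calls[t] = (ToolCall.deleterious, ToolCall.highly_pathogenic)[int(rng.integers(2))]
        else:
            calls[t] = (ToolCall.tolerated, ToolCall.unknown)[int(rng.integers(2))]
    return calls


def _mk_variant(rng, gene, sample, genotype, consequence, afs, gerp, mcap, votes):
    ref, alt = rng.choice(_BASES, size=2, replace=False)
    return AnnotatedVariant(
        chrom=f"chr{int(rng.integers(1, 23))}",
        pos=int(rng.integers(1, 200_000_000)),
        ref=str(ref),
        alt=str(alt),
        gene=gene,
        consequence=consequence,
        sample_id=sample,
        genotype=genotype,
        gerp=gerp,
        mcap=mcap,
        tool_calls=_tool_votes(rng, votes),
        **afs,
    )


def gen_variant_table(cfg: VariantSimConfig) -> tuple[list[AnnotatedVariant], pd.DataFrame]:
    """Generate an annotated variant table plus a per-variant truth ledger.

    Ledger columns: variant key fields, gene, sample_id, ``category`` (the
    rule the variant was built to fail, ``benign_pass``, or ``planted``),
    ``is_candidate`` and ``mechanism`` for planted candidate variants.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = [f"P{i + 1}" for i in range(cfg.n_samples)]
    variants: list[AnnotatedVariant] = []
    ledger_rows: list[dict] = []
    categories = ["frequency", "conservation", "pathogenicity", "benign_pass"]
    draws = rng.choice(4, size=cfg.n_background_variants, p=cfg.rule_fail_fractions)

    for i, cat_idx in enumerate(draws):
        cat = categories[cat_idx]
        gene = f"BGGENE{i:05d}"
        sample = samples[int(rng.integers(len(samples)))]
        if cat == "frequency":
            afs = _rare_afs(rng)
            hot = rng.choice(AF_FIELDS)
            afs[hot] = float(rng.uniform(0.01, 0.5))
            v = _mk_variant(rng, gene, sample, Genotype.het, Consequence.missense,
                            afs, float(rng.uniform(3, 6)), float(rng.uniform(0.61, 1.0)), 3)
        elif cat == "conservation":
            v = _mk_variant(rng, gene, sample, Genotype.het, Consequence.missense,
                            _rare_afs(rng), float(rng.uniform(-3, 1.9)),
                            float(rng.uniform(0.61, 1.0)), 3)
        elif cat == "pathogenicity":
            if rng.random() < 0.5:  # sub-gray M-CAP
                mcap, votes = float(rng.uniform(0.0, 0.024)), 3
            else:  # gray zone, insufficient damaging votes
                mcap, votes = float(rng.uniform(0.025, 0.6)), int(rng.integers(0, 2))
            v = _mk_variant(rng, gene, sample, Genotype.het, Consequence.missense,
                            _rare_afs(rng), float(rng.uniform(2.5, 6)), mcap, votes)
        else:  # benign_pass: survives the cascade, single het -> no candidate
            if rng.random() < 0.3:
                v = _mk_variant(rng, gene, sample, Genotype.het, Consequence.stopgain,
                                {n: None for n in AF_FIELDS}, None, None, 0)
            else:
                v = _mk_variant(rng, gene, sample, Genotype.het, Consequence.missense,
                                _rare_afs(rng), float(rng.uniform(2.5, 6)),
                                float(rng.uniform(0.61, 1.0)), 3)
        variants.append(v)
        ledger_rows.append(
            {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt, "gene": gene,
             "sample_id": sample, "category": cat, "is_candidate": False, "mechanism": ""}
        )

    for p in cfg.planted:
        sample = samples[p.sample_index]
        if p.mechanism == "compound_het":
            # one conserved damaging missense + one truncating variant absent
            # from every database, both heterozygous
            pair = [
                _mk_variant(rng, p.gene, sample, Genotype.het, Consequence.missense,
                            _rare_afs(rng), float(rng.uniform(5.4, 6.2)),
                            float(rng.uniform(0.61, 1.0)), 3),
                _mk_variant(rng, p.gene, sample, Genotype.het, Consequence.stopgain,
                            {n: None for n in AF_FIELDS}, None, None, 0),
            ]
        else:
            pair = [
                _mk_variant(rng, p.gene, sample, Genotype.hom_alt, Consequence.missense,
                            _rare_afs(rng), float(rng.uniform(4, 6)),
                            float(rng.uniform(0.61, 1.0)), 3),
            ]
        for v in pair:
            variants.append(v)
            ledger_rows.append(
                {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                 "gene": p.gene, "sample_id": sample, "category": "planted",
                 "is_candidate": True, "mechanism": p.mechanism}
            )

    return variants, pd.DataFrame(ledger_rows)


# ---------------------------------------------------------------------------
# Single-cell count matrices


@dataclass(frozen=True)
class ScrnaSimConfig:
    """Negative-binomial counts over distinct cell types with planted structure.

    Each cell type gets ``n_markers_per_type`` exclusive marker genes at
    ``marker_mean``; the seed gene and every ``planted_coexpressed`` gene are
    expressed (mean ``expressed_mean``) exactly in ``seed_gene_types``;
    ``planted_null`` genes are expressed in the complementary types.  QC
    outlier cells (low-gene, low-UMI, high-UMI, high-mito) are appended on top
    of the clean cells at the configured fractions.
    """

    cell_types: tuple[str, ...] = (
        "ureteric_bud", "stromal", "hepatoblast", "immune", "endothelial"
    )
    cells_per_type: int = 300
    n_genes: int = 2000
    n_mito_genes: int = 13
    seed_gene: str = "PKHD1"
    seed_gene_types: tuple[str, ...] = ("ureteric_bud", "stromal", "hepatoblast")
    planted_coexpressed: tuple[str, ...] = ("CRB3",)
    planted_null: tuple[str, ...] = ("NULLG1",)
    n_markers_per_type: int = 40
    baseline_mean_range: tuple[float, float] = (0.5, 2.0)
    marker_mean: float = 6.0
    off_mean: float = 0.02
    expressed_mean: float = 5.0
    mito_frac: float = 0.05
    nb_dispersion: float = 10.0
    qc_outlier_fractions: tuple[float, float, float, float] = (0.02, 0.02, 0.02, 0.05)
    doublet_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cells_per_type <= 0 or self.n_genes <= 0:
            raise ValueError("counts must be positive")
        if not set(self.seed_gene_types) <= set(self.cell_types):
            raise ValueError("seed_gene_types must be a subset of cell_types")
        if any(not (0.0 <= f <= 1.0) for f in self.qc_outlier_fractions):
            raise ValueError("qc_outlier_fractions must lie in [0, 1]")
        if not (0.0 <= self.doublet_fraction <= 1.0):
            raise ValueError("doublet_fraction must lie in [0, 1]")
        if not (0.0 < self.mito_frac < 1.0):
            raise ValueError("mito_frac must lie in (0, 1)")
        needed = (
            self.n_mito_genes
            + self.n_markers_per_type * len(self.cell_types)
            + 1 + len(self.planted_coexpressed) + len(self.planted_null)
        )
        if needed > self.n_genes:
            raise ValueError("n_genes too small for the configured structure")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """NB(mean=mu, dispersion theta): var = mu + mu^2/theta."""
    out = np.zeros_like(mu, dtype=np.int64)
    pos = mu > 0
    p = theta / (theta + mu[pos])
    out[pos] = rng.negative_binomial(theta, p)
    return out


def gen_scrna_counts(cfg: ScrnaSimConfig) -> tuple[ad.AnnData, pd.DataFrame]:
    """Generate a counts AnnData (cells x genes) plus a per-cell truth table.

    Truth columns: ``true_type``, ``is_qc_outlier``, ``outlier_kind``,
    ``is_doublet``.  The AnnData carries the same columns in ``obs``, the
    gene-by-type mean design in ``uns['type_means']`` and the planted gene
    sets in ``uns['planted']``; marker genes are named ``<TYPE>_MK###``.
    """
    rng = np.random.default_rng(cfg.seed)
    types = list(cfg.cell_types)

    genes: list[str] = [f"MT-{i + 1}" for i in range(cfg.n_mito_genes)]
    marker_genes: dict[str, list[str]] = {}
    for t in types:
        marker_genes[t] = [f"{t.upper()}_MK{j + 1:03d}" for j in range(cfg.n_markers_per_type)]
        genes += marker_genes[t]
    genes.append(cfg.seed_gene)
    genes += list(cfg.planted_coexpressed) + list(cfg.planted_null)
    n_bg = cfg.n_genes - len(genes)
    genes += [f"BG{i + 1:05d}" for i in range(n_bg)]
    gene_idx = {g: i for i, g in enumerate(genes)}

    # gene x type mean design
    mu = np.empty((cfg.n_genes, len(types)))
    base = rng.uniform(*cfg.baseline_mean_range, size=cfg.n_genes)
    mu[:] = base[:, None]
    for t_i, t in enumerate(types):
        for g in marker_genes[t]:
            mu[gene_idx[g], :] = cfg.off_mean
            mu[gene_idx[g], t_i] = cfg.marker_mean
    on = np.array([t in cfg.seed_gene_types for t in types])
    for g in (cfg.seed_gene, *cfg.planted_coexpressed):
        mu[gene_idx[g], :] = np.where(on, cfg.expressed_mean, cfg.off_mean)
    for g in cfg.planted_null:
        mu[gene_idx[g], :] = np.where(on, cfg.off_mean, cfg.expressed_mean)
    # mitochondrial means set per type so clean cells land near mito_frac
    mito_idx = [gene_idx[f"MT-{i + 1}"] for i in range(cfg.n_mito_genes)]
    nonmito = np.ones(cfg.n_genes, dtype=bool)
    nonmito[mito_idx] = False
    for t_i in range(len(types)):
        target = cfg.mito_frac / (1.0 - cfg.mito_frac)
        mu[mito_idx, t_i] = target * mu[nonmito, t_i].sum() / cfg.n_mito_genes

    rows, truth = [], []

    def add_cell(mu_vec, true_type, kind=None, doublet=False):
        rows.append(_nb_draw(rng, mu_vec, cfg.nb_dispersion))
        truth.append(
            {"true_type": true_type, "is_qc_outlier": kind is not None,
             "outlier_kind": kind or "", "is_doublet": doublet}
        )

    for t_i, t in enumerate(types):
        for _ in range(cfg.cells_per_type):
            add_cell(mu[:, t_i], t)

    n_clean = len(types) * cfg.cells_per_type
    n_low_gene, n_low_umi, n_high_umi, n_high_mito = (
        int(round(f * n_clean)) for f in cfg.qc_outlier_fractions
    )
    mito_rows = np.array([g.startswith("MT-") for g in genes])

    n_pick = min(200, int((~mito_rows).sum()) // 3)
    for _ in range(n_low_gene):
        # expression concentrated on few genes: plenty of UMI, <400 detected
        v = np.zeros(cfg.n_genes)
        picked = rng.choice(np.where(~mito_rows)[0], size=n_pick, replace=False)
        v[picked] = 8.0
        add_cell(v, rng.choice(types), kind="low_gene")
    for _ in range(n_low_umi):
        t_i = int(rng.integers(len(types)))
        scale = 200.0 / mu[:, t_i].sum()
        add_cell(mu[:, t_i] * scale, types[t_i], kind="low_umi")
    for _ in range(n_high_umi):
        t_i = int(rng.integers(len(types)))
        scale = 16_000.0 / mu[:, t_i].sum()
        add_cell(mu[:, t_i] * scale, types[t_i], kind="high_umi")
    for _ in range(n_high_mito):
        t_i = int(rng.integers(len(types)))
        v = mu[:, t_i].copy()
        nonmito_total = v[~mito_rows].sum()
        v[mito_rows] = (0.4 / 0.6) * nonmito_total / mito_rows.sum()
        add_cell(v, types[t_i], kind="high_mito")

    # all doublets combine one (randomly drawn) pair of types, so they are
    # numerous enough to form their own cluster carrying both marker sets
    n_doublets = int(round(cfg.doublet_fraction * n_clean))
    if n_doublets:
        a, b = rng.choice(len(types), size=2, replace=False)
        for _ in range(n_doublets):
            add_cell(mu[:, a] + mu[:, b], f"{types[a]}+{types[b]}", doublet=True)

    X = np.vstack(rows)
    obs = pd.DataFrame(truth, index=[f"CELL{i + 1:05d}" for i in range(len(rows))])
    adata = ad.AnnData(
        X=X, obs=obs.copy(), var=pd.DataFrame(index=pd.Index(genes, name="gene"))
    )
    adata.uns["type_means"] = pd.DataFrame(mu, index=genes, columns=types)
    adata.uns["planted"] = {
        "seed_gene": cfg.seed_gene,
        "coexpressed": list(cfg.planted_coexpressed),
        "null": list(cfg.planted_null),
        "markers": {t: marker_genes[t] for t in types},
        "seed_gene_types": list(cfg.seed_gene_types),
    }
    return adata, obs


# ---------------------------------------------------------------------------
# Cohort tables


@dataclass(frozen=True)
class CohortSimConfig:
    """Patient-level cohort with per-group binary events and continuous traits."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"ncph": 267, "cirrhosis": 8295}
    )
    event_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"MRC": {"ncph": 0.195, "cirrhosis": 0.062}}
    )
    continuous: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        for probs in self.event_probs.values():
            if any(not (0.0 <= p <= 1.0) for p in probs.values()):
                raise ValueError("event probabilities must lie in [0, 1]")


def gen_cohort(cfg: CohortSimConfig) -> pd.DataFrame:
    """One row per patient: group label, binary events, continuous variables."""
    rng = np.random.default_rng(cfg.seed)
    frames = []
    for group, n in cfg.group_sizes.items():
        df = pd.DataFrame({"group": group}, index=range(n))
        for event, probs in cfg.event_probs.items():
            df[event] = rng.random(n) < probs.get(group, 0.0)
        for var, per_group in cfg.continuous.items():
            mean, sd = per_group.get(group, (np.nan, np.nan))
            df[var] = rng.normal(mean, sd, size=n)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.index.name = "patient"
    return out.reset_index()
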