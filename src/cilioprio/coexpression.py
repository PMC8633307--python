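"""Co-expression prioritization of a gene panel against a seed disease gene.

A candidate gene is "co-expressed" with the seed gene when the two share a
cell-type expression pattern.  Per dataset this is scored from the cell-type
profile (the dot-plot statistics) with two components:

* ``profile_correlation`` — Spearman rank correlation of the two genes'
  mean-expression vectors over cell types (robust to absolute scale);
* ``pct_overlap`` — Jaccard index of the cell-type sets in which each gene is
  "on" (pct_expressing >= ``pct_on_threshold``).

The combined score is ``w * (correlation + 1)/2 + (1 - w) * overlap`` in
[0, 1].  Rankings from several datasets are aggregated by mean rank, with a
gene missing from a dataset charged that dataset's worst rank + 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .variants import GenePanel

__all__ = [
    "CoexpressionParams",
    "CoexpressionScore",
    "CoexpressionRanking",
    "coexpression_score",
    "rank_panel",
    "aggregate_datasets",
]


@dataclass(frozen=True)
class CoexpressionParams:
    weight: float = 0.5
    pct_on_threshold: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError("weight must be in [0, 1]")
        if not (0.0 <= self.pct_on_threshold <= 1.0):
            raise ValueError("pct_on_threshold must be in [0, 1]")


@dataclass(frozen=True)
class CoexpressionScore:
    gene: str
    seed_gene: str
    profile_correlation: float
    pct_overlap: float
    combined: float
    missing: bool = False

    @classmethod
    def missing_gene(cls, gene: str, seed_gene: str) -> "CoexpressionScore":
        return cls(gene, seed_gene, float("nan"), float("nan"), float("nan"), missing=True)


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        # degenerate profile: no rank signal; score as uncorrelated
        return 0.0
    rho = stats.spearmanr(a, b).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def coexpression_score(
    profile, seed: str, gene: str, params: CoexpressionParams | None = None
) -> CoexpressionScore:
    """Score one panel gene against the seed gene on a cell-type profile.

    Needs at least 3 cell types (rank correlation over fewer is meaningless).
    A gene absent from the profile yields a ``missing`` result, not an error;
    an absent seed gene is an error.
    """
    params = params or CoexpressionParams()
    if len(profile.cell_types) < 3:
        raise ValueError("co-expression scoring needs >= 3 cell types")
    genes_upper = {g.upper(): g for g in profile.genes}
    if seed.upper() not in genes_upper:
        raise KeyError(f"seed gene {seed!r} absent from profile")
    if gene.upper() not in genes_upper:
        return CoexpressionScore.missing_gene(gene, seed)
    s_row, g_row = genes_upper[seed.upper()], genes_upper[gene.upper()]
    mean_s = profile.mean_expr.loc[s_row].to_numpy(dtype=float)
    mean_g = profile.mean_expr.loc[g_row].to_numpy(dtype=float)
    rho = _spearman(mean_s, mean_g)
    on_s = profile.pct.loc[s_row].to_numpy(dtype=float) >= params.pct_on_threshold
    on_g = profile.pct.loc[g_row].to_numpy(dtype=float) >= params.pct_on_threshold
    union = np.logical_or(on_s, on_g).sum()
    overlap = float(np.logical_and(on_s, on_g).sum() / union) if union else 0.0
    combined = params.weight * (rho + 1.0) / 2.0 + (1.0 - params.weight) * overlap
    return CoexpressionScore(gene, seed, rho, overlap, combined)


@dataclass
class CoexpressionRanking:
    """Ordered panel genes for one dataset, best (highest combined) first."""

    dataset: str
    seed_gene: str
    scores: list[CoexpressionScore]
    missing: list[str]

    def rank_of(self, gene: str) -> int | None:
        for i, s in enumerate(self.scores, start=1):
            if s.gene.upper() == gene.upper():
                return i
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": range(1, len(self.scores) + 1),
                "gene": [s.gene for s in self.scores],
                "combined": [s.combined for s in self.scores],
                "correlation": [s.profile_correlation for s in self.scores],
                "overlap": [s.pct_overlap for s in self.scores],
                "dataset": self.dataset,
                "seed_gene": self.seed_gene,
            }
        )


def rank_panel(
    profile,
    seed: str,
    panel: GenePanel,
    params: CoexpressionParams | None = None,
    dataset: str = "dataset",
) -> CoexpressionRanking:
    """Rank every panel gene by combined co-expression score, descending.

    Ties break lexicographically on the gene symbol; the seed gene itself is
    not ranked.  Panel genes absent from the profile are listed separately.
    """
    params = params or CoexpressionParams()
    scores, absent = [], []
    for gene in sorted(panel.genes):
        if gene.upper() == seed.upper():
            continue
        sc = coexpression_score(profile, seed, gene, params)
        (absent if sc.missing else scores).append(sc.gene if sc.missing else sc)
    scores.sort(key=lambda s: (-s.combined, s.gene.upper()))
    return CoexpressionRanking(dataset, seed, scores, sorted(absent))


def aggregate_datasets(rankings: list[CoexpressionRanking]) -> pd.DataFrame:
    """Consensus ranking across datasets by mean per-dataset rank.

    A gene missing from a dataset is charged (worst rank in that dataset) + 1,
    penalizing absence without discarding the gene.  Returns a table sorted by
    mean rank ascending (consensus rank 1 = best), with per-dataset ranks for
    transparency; ties break lexicographically.
    """
    if not rankings:
        raise ValueError("need at least one ranking")
    seeds = {r.seed_gene.upper() for r in rankings}
    if len(seeds) != 1:
        raise ValueError("rankings must share the seed gene")
    all_genes = sorted(
        {s.gene.upper() for r in rankings for s in r.scores}
        | {g.upper() for r in rankings for g in r.missing}
    )
    if not all_genes:
        raise ValueError("no genes present in any dataset")
    rows = []
    for gene in all_genes:
        per_ds = {}
        for r in rankings:
            rank = r.rank_of(gene)
            per_ds[r.dataset] = rank if rank is not None else len(r.scores) + 1
        rows.append({"gene": gene, "mean_rank": float(np.mean(list(per_ds.values()))), **{
            f"rank_{d}": v for d, v in per_ds.items()
        }})
    out = pd.DataFrame(rows).sort_values(["mean_rank", "gene"]).reset_index(drop=True)
    out.insert(0, "consensus_rank", range(1, len(out) + 1))
    return out
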