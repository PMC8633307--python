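"""Co-expression prioritization of a cilia panel against a seed disease gene.

Builds cell-type profiles from four synthetic datasets in which one panel
gene (CRB3) shares the seed gene's (PKHD1) cell-type pattern and 20 panel
genes do not, ranks the panel per dataset, and aggregates to a consensus.
"""

from cilioprio import (
    GenePanel,
    ScrnaSimConfig,
    aggregate_datasets,
    aggregate_profiles,
    gen_scrna_counts,
    log_normalize,
    rank_panel,
)

null_genes = tuple(f"NULLG{i + 1}" for i in range(20))
panel = GenePanel("cilia", frozenset(("CRB3",) + null_genes))

rankings = []
for d in range(4):
    cfg = ScrnaSimConfig(
        cells_per_type=40, n_genes=300, n_markers_per_type=10,
        planted_null=null_genes, qc_outlier_fractions=(0, 0, 0, 0), seed=100 + d,
    )
    adata, truth = gen_scrna_counts(cfg)
    adata = log_normalize(adata)
    profile = aggregate_profiles(adata, truth["true_type"])
    r = rank_panel(profile, "PKHD1", panel, dataset=f"ds{d + 1}")
    top = r.scores[0]
    print(f"ds{d + 1}: top gene {top.gene} "
          f"(combined {top.combined:.3f}, rank-corr {top.profile_correlation:.2f}, "
          f"overlap {top.pct_overlap:.2f})")
    rankings.append(r)

consensus = aggregate_datasets(rankings)
print("\nconsensus ranking (mean rank across the 4 datasets):")
print(consensus.head(5).to_string(index=False))
# The planted co-expressed gene wins consensus rank 1: its mean expression
# tracks the seed gene's across cell types (rank correlation ~1) and both are
# "on" in the same cell types (overlap 1), while null genes share neither.
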