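"""Single-cell stage: QC, normalization, HVGs, scaling, PCA, clustering,
markers, cell-type assignment, profile aggregation."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from cilioprio.scrna import (
    CellTypeProfile,
    PipelineConfig,
    QCConfig,
    aggregate_profiles,
    assign_cell_types,
    build_snn_and_cluster,
    compute_umap,
    find_markers,
    log_normalize,
    qc_filter_cells,
    run_pca,
    run_scrna_pipeline,
    scale_and_regress,
    select_hvgs,
)


def adata_from_counts(X, genes=None, barcodes=None):
    X = np.asarray(X)
    genes = genes or [f"G{i}" for i in range(X.shape[1])]
    barcodes = barcodes or [f"C{i}" for i in range(X.shape[0])]
    return ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=barcodes),
        var=pd.DataFrame(index=genes),
    )


class TestQC:
    def make_cell(self, n_genes_on, total, mito_share=0.0, n_genes=800):
        """Single-cell count vector hitting the requested QC metrics exactly."""
        x = np.zeros(n_genes)
        mito_umi = int(round(total * mito_share))
        body = total - mito_umi
        per = body // (n_genes_on - (mito_umi > 0))
        rem = body - per * (n_genes_on - (mito_umi > 0))
        x[10 : 10 + n_genes_on - (mito_umi > 0)] = per
        x[10] += rem
        x[0] = mito_umi  # gene 0 is MT-1
        return x

    def qc_run(self, cells):
        genes = ["MT-1"] + [f"G{i}" for i in range(len(cells[0]) - 1)]
        adata = adata_from_counts(np.array(cells), genes=genes)
        return qc_filter_cells(adata, QCConfig())

    def test_low_gene_cell_discarded(self):
        good = self.make_cell(500, 5000)
        bad = self.make_cell(350, 5000)
        kept, verdict = self.qc_run([good, bad])
        assert kept.n_obs == 1
        assert verdict.loc["C1", "reasons"] == "genes_low"

    def test_umi_bounds(self):
        high = self.make_cell(500, 12_000)
        low = self.make_cell(500, 550)
        ok = self.make_cell(500, 5000)
        kept, verdict = self.qc_run([high, low, ok])
        assert kept.n_obs == 1
        assert verdict.loc["C0", "reasons"] == "umi_high"
        assert verdict.loc["C1", "reasons"] == "umi_low"

    def test_boundaries_are_retained(self):
        """Exactly 400 genes, exactly 600/10,000 UMI, exactly 15% mito: kept."""
        cells = [
            self.make_cell(400, 5000),
            self.make_cell(500, 600),
            self.make_cell(500, 10_000),
            self.make_cell(500, 5000, mito_share=0.15),
        ]
        kept, verdict = self.qc_run(cells)
        assert kept.n_obs == 4
        assert not verdict.discarded.any()

    def test_mito_over_threshold_discarded(self):
        kept, verdict = self.qc_run([self.make_cell(500, 5000, mito_share=0.16)])
        assert kept.n_obs == 0
        assert verdict.loc["C0", "reasons"] == "mito_high"

    def test_retained_plus_discarded_partition_input(self, small_scrna):
        adata, _ = small_scrna
        kept, verdict = qc_filter_cells(adata, QCConfig(min_genes=50, min_umi=50))
        assert kept.n_obs + verdict.discarded.sum() == adata.n_obs
        assert (verdict.loc[verdict.discarded, "reasons"] != "").all()

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            qc_filter_cells(adata_from_counts(np.empty((0, 5))))


class TestLogNormalize:
    def test_single_gene_closed_form(self):
        adata = adata_from_counts([[7, 0, 0]])
        out = log_normalize(adata, scale_factor=10_000.0)
        assert out.layers["lognorm"][0, 0] == pytest.approx(np.log(1 + 10_000.0))
        assert (out.layers["lognorm"][0, 1:] == 0).all()

    def test_per_cell_conservation_identity(self, small_scrna):
        adata, _ = small_scrna
        out = log_normalize(adata.copy(), scale_factor=10_000.0)
        sums = np.expm1(out.layers["lognorm"]).sum(axis=1)
        assert np.allclose(sums, 10_000.0, atol=1e-6)

    def test_zero_total_cell_rejected(self):
        with pytest.raises(ValueError):
            log_normalize(adata_from_counts([[0, 0], [1, 2]]))


class TestHVGs:
    def test_planted_overdispersed_genes_recovered(self):
        rng = np.random.default_rng(0)
        n_cells, n_genes = 300, 200
        X = rng.poisson(2.0, size=(n_cells, n_genes)).astype(float)
        hot = [3, 50, 120, 199]
        for g in hot:  # dispersion gap >= 10x at matched mean
            X[:, g] = rng.negative_binomial(0.2, 0.2 / 2.2, size=n_cells)
        adata = adata_from_counts(X)
        top = select_hvgs(adata, 10)
        assert {f"G{g}" for g in hot} <= set(top)

    def test_constant_gene_never_beats_variable_gene(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(3.0, size=(100, 50)).astype(float)
        X[:, 7] = 4.0  # constant
        adata = adata_from_counts(X)
        ranked = select_hvgs(adata, 50)
        assert ranked[-1] == "G7" or adata.var.loc["G7", "hvg_score"] == 0.0

    def test_all_genes_returned_when_n_equals_genes(self):
        rng = np.random.default_rng(2)
        adata = adata_from_counts(rng.poisson(2.0, size=(50, 30)))
        assert set(select_hvgs(adata, 30)) == set(adata.var_names)

    def test_too_many_requested(self):
        adata = adata_from_counts(np.ones((10, 5)))
        with pytest.raises(ValueError):
            select_hvgs(adata, 6)


class TestScaleRegress:
    def _normalized(self, X):
        adata = adata_from_counts(X)
        adata = log_normalize(adata, 1000.0)
        from cilioprio.scrna import qc_metrics

        return qc_metrics(adata)

    def test_gene_linear_in_covariate_has_zero_residual_signal(self):
        rng = np.random.default_rng(3)
        n = 200
        X = rng.poisson(5.0, size=(n, 20)).astype(float) + 1
        adata = self._normalized(X)
        # overwrite one gene's normalized values as linear in mito_fraction
        # plus small noise: the covariate signal must be fully absorbed
        covar = rng.uniform(0.0, 0.2, n)
        noise = rng.normal(0.0, 0.01, n)
        adata.obs["mito_fraction"] = covar
        adata.layers["lognorm"][:, 0] = 2.0 + 3.0 * covar + noise
        scaled = scale_and_regress(adata, covariates=("mito_fraction",))
        # OLS residuals are exactly orthogonal to the covariate
        assert abs(np.corrcoef(scaled[:, 0], covar)[0, 1]) < 1e-8
        # and what remains is the noise, not the 3*covar trend
        raw = adata.layers["lognorm"][:, 0]
        assert abs(np.corrcoef(raw, covar)[0, 1]) > 0.9

    def test_constant_covariates_degrade_to_z_scoring(self):
        rng = np.random.default_rng(4)
        X = rng.poisson(5.0, size=(100, 10)).astype(float) + 1
        adata = self._normalized(X)
        adata.obs["mito_fraction"] = 0.0
        adata.obs["total_umi"] = 1.0
        with pytest.warns(UserWarning):
            scaled = scale_and_regress(adata)
        L = adata.layers["lognorm"]
        z = (L - L.mean(axis=0)) / L.std(axis=0, ddof=1)
        assert np.allclose(scaled, z, atol=1e-10)

    def test_output_centered_and_unit_variance(self, small_scrna):
        adata, _ = small_scrna
        adata = log_normalize(adata.copy())
        from cilioprio.scrna import qc_metrics

        adata = qc_metrics(adata)
        scaled = scale_and_regress(adata, clip_max=1e9)
        assert np.allclose(scaled.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(scaled.std(axis=0, ddof=1), 1.0, atol=1e-6)


class TestPCA:
    def test_rank2_data_has_no_variance_beyond_pc2(self):
        rng = np.random.default_rng(5)
        basis = rng.normal(size=(2, 40))
        coords = rng.normal(size=(100, 2))
        X = coords @ basis
        emb = run_pca(X, 5)
        assert emb[:, 2:].var(axis=0).max() < 1e-20

    def test_explained_variance_nonincreasing_and_sign_fixed(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(80, 30)) * np.linspace(5, 0.1, 30)
        e1 = run_pca(X, 10, seed=1)
        e2 = run_pca(X, 10, seed=2)
        variances = e1.var(axis=0)
        assert (np.diff(variances) <= 1e-10).all()
        # deterministic regardless of seed (full SVD + sign convention)
        assert np.allclose(e1, e2)

    def test_reconstruction_error_monotone_in_components(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 50))
        Xc = X - X.mean(axis=0)

        def recon_err(k):
            from sklearn.decomposition import PCA

            p = PCA(n_components=k, svd_solver="full").fit(Xc)
            return ((Xc - p.inverse_transform(p.transform(Xc))) ** 2).sum()

        assert recon_err(40) <= recon_err(10) + 1e-9

    def test_too_many_pcs_rejected(self):
        with pytest.raises(ValueError):
            run_pca(np.ones((10, 5)), 6)


class TestClustering:
    def test_two_separated_blobs_two_clusters(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, size=(100, 10))
        b = rng.normal(0, 1, size=(100, 10))
        b[:, 0] += 20  # >= 10 SD separation
        emb = np.vstack([a, b])
        labels = build_snn_and_cluster(emb, snn_k=20, resolution=0.5, seed=0)
        truth = np.array([0] * 100 + [1] * 100)
        assert len(set(labels)) == 2
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_seeded_determinism(self):
        rng = np.random.default_rng(9)
        emb = rng.normal(size=(150, 8))
        l1 = build_snn_and_cluster(emb, snn_k=10, seed=3)
        l2 = build_snn_and_cluster(emb, snn_k=10, seed=3)
        assert np.array_equal(l1, l2)

    def test_fewer_cells_than_k_rejected(self):
        with pytest.raises(ValueError):
            build_snn_and_cluster(np.ones((5, 3)), snn_k=10)


class TestUMAP:
    def test_shape_determinism_and_type_separation(self):
        rng = np.random.default_rng(10)
        emb = np.vstack(
            [rng.normal(0, 1, size=(60, 6)), rng.normal(12, 1, size=(60, 6))]
        )
        c1 = compute_umap(emb, n_neighbors=15, seed=4)
        c2 = compute_umap(emb, n_neighbors=15, seed=4)
        assert c1.shape == (120, 2)
        assert np.allclose(c1, c2)
        truth = [0] * 60 + [1] * 60
        assert silhouette_score(c1, truth) > 0


class TestMarkers:
    def make_labeled(self):
        rng = np.random.default_rng(11)
        n_a, n_b = 60, 60
        X = rng.poisson(1.0, size=(n_a + n_b, 30)).astype(float) + 1
        X[:n_a, 0] = rng.poisson(30.0, n_a)  # exclusive high marker of A
        X[n_a:, 0] = 0.0
        X[:n_a, 1] = 0.0
        X[: int(0.2 * n_a), 1] = 50.0  # pct_in = 0.2 in A: below the gate
        adata = adata_from_counts(X)
        adata = log_normalize(adata, 1000.0)
        return adata, np.array(["A"] * n_a + ["B"] * n_b)

    def test_exclusive_gene_is_top_marker(self):
        adata, labels = self.make_labeled()
        table = find_markers(adata, labels, min_pct=0.3, logfc_threshold=0.6)
        top_a = table[table.cluster == "A"].iloc[0]
        assert top_a.gene == "G0"
        assert top_a.pct_in > 0.9 and top_a.log_fc > 0.6

    def test_low_pct_gene_excluded_despite_fold_change(self):
        adata, labels = self.make_labeled()
        table = find_markers(adata, labels, min_pct=0.3, logfc_threshold=0.6)
        assert "G1" not in set(table[table.cluster == "A"].gene)

    def test_single_cluster_rejected(self):
        adata, _ = self.make_labeled()
        with pytest.raises(ValueError):
            find_markers(adata, np.zeros(adata.n_obs))


class TestAssignTypes:
    REF = {"X": {"M1", "M2", "M3"}, "Y": {"N1", "N2", "N3"}}

    @staticmethod
    def marker_table(rows):
        return pd.DataFrame(rows, columns=["cluster", "gene"]).assign(
            pct_in=0.9, pct_out=0.05, log_fc=2.0, p_value=1e-8
        )

    def test_unambiguous_assignment(self):
        t = self.marker_table([(0, "M1"), (0, "M2"), (0, "M3")])
        types, doublets = assign_cell_types(t, self.REF)
        assert types[0] == "X" and not doublets[0]

    def test_two_type_marker_cluster_is_doublet(self):
        t = self.marker_table([(0, "M1"), (0, "M2"), (0, "N1"), (0, "N2")])
        _, doublets = assign_cell_types(t, self.REF)
        assert doublets[0]

    def test_no_match_labeled_unknown(self):
        t = self.marker_table([(0, "Q1"), (0, "Q2")])
        with pytest.warns(UserWarning):
            types, _ = assign_cell_types(t, self.REF)
        assert types[0] == "unknown"

    def test_override_bypasses_scoring(self):
        t = self.marker_table([(0, "M1"), (0, "M2"), (0, "N1"), (0, "N2")])
        types, doublets = assign_cell_types(t, self.REF, overrides={0: "X"})
        assert types[0] == "X" and not doublets[0]

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            assign_cell_types(self.marker_table([(0, "M1")]), {})


class TestAggregateProfiles:
    def test_matches_brute_force_recomputation(self, small_scrna):
        adata, truth = small_scrna
        adata = log_normalize(adata.copy())
        profile = aggregate_profiles(adata, truth["true_type"])
        L = adata.layers["lognorm"]
        X = np.asarray(adata.X)
        for t in profile.cell_types:
            idx = np.where(truth["true_type"].values == t)[0]
            for gi, g in enumerate(adata.var_names[:25]):
                mean = np.mean([L[i, gi] for i in idx])
                pct = np.mean([X[i, gi] > 0 for i in idx])
                assert profile.mean_expr.loc[g, t] == pytest.approx(mean)
                assert profile.pct.loc[g, t] == pytest.approx(pct)

    def test_pct_one_and_zero_extremes(self):
        X = np.array([[5, 0], [3, 0], [1, 0]])
        adata = adata_from_counts(X)
        adata = log_normalize(adata, 100.0)
        profile = aggregate_profiles(adata, ["T"] * 3)
        assert profile.pct.loc["G0", "T"] == 1.0
        assert profile.pct.loc["G1", "T"] == 0.0
        assert profile.mean_expr.loc["G1", "T"] == 0.0

    def test_unlabeled_cells_excluded(self):
        X = np.array([[10, 1], [1, 10], [100, 100]])
        adata = adata_from_counts(X)
        adata = log_normalize(adata, 100.0)
        profile = aggregate_profiles(adata, ["T", "T", None])
        assert profile.mean_expr.shape[1] == 1

    def test_tsv_round_trip(self, small_scrna, tmp_path):
        adata, truth = small_scrna
        adata = log_normalize(adata.copy())
        profile = aggregate_profiles(adata, truth["true_type"])
        profile.write(tmp_path / "p.tsv")
        back = CellTypeProfile.read(tmp_path / "p.tsv")
        pd.testing.assert_frame_equal(
            back.mean_expr.sort_index(), profile.mean_expr.sort_index(), check_names=False
        )


class TestEndToEnd:
    def test_pipeline_recovers_planted_types(self, small_scrna):
        adata, truth = small_scrna
        marker_ref = {
            t: set(ms[:3]) for t, ms in adata.uns["planted"]["markers"].items()
        }
        cfg = PipelineConfig(n_hvgs=200, n_pcs=20, snn_k=15, random_seed=0)
        res = run_scrna_pipeline(
            adata, marker_ref, qc=QCConfig(min_genes=50, min_umi=50), cfg=cfg
        )
        truth_kept = truth.loc[res.adata.obs_names, "true_type"]
        assert adjusted_rand_score(truth_kept, res.clusters) >= 0.9
        assert set(res.cluster_types.values()) == set(adata.uns["planted"]["markers"])

    def test_injected_doublet_cluster_flagged(self):
        from cilioprio.simulate import ScrnaSimConfig, gen_scrna_counts

        cfg = ScrnaSimConfig(
            cells_per_type=60, n_genes=400, n_markers_per_type=15,
            qc_outlier_fractions=(0.0, 0.0, 0.0, 0.0), doublet_fraction=0.1, seed=21,
        )
        adata, truth = gen_scrna_counts(cfg)
        marker_ref = {
            t: set(ms[:3]) for t, ms in adata.uns["planted"]["markers"].items()
        }
        pcfg = PipelineConfig(n_hvgs=200, n_pcs=20, snn_k=15, random_seed=0)
        res = run_scrna_pipeline(
            adata, marker_ref, qc=QCConfig(min_genes=50, min_umi=50), cfg=pcfg
        )
        doublet_cells = truth.loc[res.adata.obs_names, "is_doublet"].values
        flagged = np.array([res.doublet_clusters.get(c, False) for c in res.clusters])
        # most injected doublets sit in flagged clusters
        assert flagged[doublet_cells].mean() > 0.8
        # discarded clusters contribute nothing to the profile
        assert res.adata.obs.loc[doublet_cells, "cell_type"].isna().mean() > 0.8
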