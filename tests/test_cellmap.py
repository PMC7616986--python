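"""Single-cell QC, diffusion imputation, classification and markers."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from hrcmap.cellmap import (QCThresholds, classify_cells, composition,
                            derive_core_signature, diffusion_impute,
                            find_markers, identify_epithelial,
                            preprocess_cells, score_cells,
                            signature_gene_correlations, SmoothedCellMatrix)
from hrcmap.scoring import GeneSignature


def _adata(counts, genes=None, sample="S1"):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[1])]
    obs = pd.DataFrame({"sample": sample},
                       index=[f"c{i}" for i in range(counts.shape[0])])
    return ad.AnnData(X=sp.csr_matrix(counts.astype(np.int32)), obs=obs,
                      var=pd.DataFrame(index=genes))


class TestPreprocess:
    def test_high_mito_cell_removed(self):
        genes = ["MT-01", "gA", "gB"]
        counts = np.array([[300, 400, 500],    # 25% mito -> dropped
                           [100, 700, 700],    # ~6.7% mito -> kept
                           [50, 800, 800]])
        thr = QCThresholds(min_counts=0, min_genes=0, min_cells_per_sample=0,
                           drop_ribo=False)
        out = preprocess_cells(_adata(counts, genes), thr)
        assert out.n_obs == 2
        assert "c0" not in out.obs_names

    def test_small_sample_dropped(self):
        counts = np.full((10, 4), 500)
        a = _adata(counts)
        thr = QCThresholds(max_mito=1.0, min_counts=0, min_genes=0,
                           min_cells_per_sample=11, drop_ribo=False)
        with pytest.raises(ValueError, match="min_cells_per_sample"):
            preprocess_cells(a, thr)

    def test_permissive_thresholds_keep_all_cells(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5, size=(20, 10))
        out = preprocess_cells(_adata(counts), QCThresholds.permissive())
        assert out.n_obs == 20

    def test_ribosomal_genes_removed_and_counts_kept(self):
        counts = np.full((8, 3), 400)
        out = preprocess_cells(_adata(counts, ["RPL01", "RPS02", "gA"]),
                               QCThresholds(min_counts=0, min_genes=0,
                                            min_cells_per_sample=0))
        assert list(out.var_names) == ["gA"]
        assert "counts" in out.layers


class TestDiffusion:
    def test_zero_steps_is_identity(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 5)))
        sm = diffusion_impute(X, k=5, ka=2, t=0, n_pcs=3)
        np.testing.assert_array_equal(sm.values.to_numpy(), X.to_numpy())

    def test_identical_cells_unchanged(self):
        X = pd.DataFrame(np.ones((20, 4)) * 3.0)
        sm = diffusion_impute(X, k=4, ka=2, t=3, n_pcs=2)
        np.testing.assert_allclose(sm.values.to_numpy(), 3.0, atol=1e-12)

    def test_three_cell_chain_matches_hand_markov(self):
        X = pd.DataFrame([[0.0, 1.0], [1.0, 0.0], [2.0, 1.0]],
                         index=["c1", "c2", "c3"], columns=["gA", "gB"])
        sm = diffusion_impute(X, k=2, ka=1, alpha=2.0, t=2, n_pcs=0)
        # hand-built adaptive kernel: sigma_i = distance to nearest neighbor
        D = np.array([[np.linalg.norm(X.iloc[i] - X.iloc[j]) for j in range(3)]
                      for i in range(3)])
        A = np.zeros((3, 3))
        for i in range(3):
            sigma = np.sort(D[i])[1]
            for j in range(3):
                A[i, j] = np.exp(-((D[i, j] / sigma) ** 2))
        A = (A + A.T) / 2
        M = A / A.sum(axis=1, keepdims=True)
        expected = M @ M @ X.to_numpy()
        np.testing.assert_allclose(sm.values.to_numpy(), expected, atol=1e-12)

    def test_imputed_values_stay_in_observed_range(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 6)))
        sm = diffusion_impute(X, k=6, ka=3, t=4, n_pcs=4)
        lo, hi = X.min(axis=0), X.max(axis=0)
        assert (sm.values.ge(lo - 1e-12, axis=1)
                & sm.values.le(hi + 1e-12, axis=1)).all().all()


class TestEpithelialCalling:
    def _two_blobs(self, rng, epcam_high=5.0):
        a = rng.normal(0, 0.2, size=(25, 4)) + np.array([10, 0, 0, epcam_high])
        b = rng.normal(0, 0.2, size=(25, 4)) + np.array([0, 10, 0, 0.0])
        X = pd.DataFrame(np.vstack([a, b]),
                         columns=["m1", "m2", "m3", "EPCAM"])
        return diffusion_impute(X, k=5, ka=2, t=2, n_pcs=3)

    def test_high_epcam_component_flagged(self, rng):
        sm = self._two_blobs(rng)
        mask = identify_epithelial(sm)
        assert mask.iloc[:25].all()
        assert not mask.iloc[25:].any()

    def test_missing_epcam_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=["a", "b", "c"])
        sm = diffusion_impute(X, k=4, ka=2, t=1, n_pcs=2)
        with pytest.raises(ValueError, match="EPCAM"):
            identify_epithelial(sm)


class TestScoreAndClassify:
    def _smoothed(self, values, genes):
        df = pd.DataFrame(values, columns=genes,
                          index=[f"c{i}" for i in range(len(values))])
        return SmoothedCellMatrix(values=df, params={}, kernel=sp.eye(len(df)))

    def test_score_is_mean_of_imputed_values(self):
        sm = self._smoothed([[1.0, 3.0], [0.0, 0.0]], ["gA", "gB"])
        sc = score_cells(sm, GeneSignature("s", ["gA", "gB"]))
        np.testing.assert_allclose(sc.to_numpy(), [2.0, 0.0])
        one = score_cells(sm, GeneSignature("s1", ["gB"]))
        np.testing.assert_allclose(one.to_numpy(), [3.0, 0.0])

    def test_percentile_worked_example(self):
        idx = [f"c{i}" for i in range(8)]
        e = pd.Series(np.arange(1.0, 9.0), index=idx)
        l = pd.Series(np.arange(8.0, 0.0, -1.0), index=idx)
        res = classify_cells(e, l, percentile=75)
        assert res.thresholds == {"EpiHR": 6.25, "Lgr5": 6.25}
        assert list(res.labels[e > 6.25]) == ["HRC", "HRC"]
        assert list(res.labels[l > 6.25]) == ["LGR5pos", "LGR5pos"]
        assert (res.labels[(e <= 6.25) & (l <= 6.25)] == "other").all()

    def test_constant_scores_flag_nothing(self):
        idx = [f"c{i}" for i in range(6)]
        e = pd.Series(1.0, index=idx)
        res = classify_cells(e, e.copy())
        assert (res.labels == "other").all()

    def test_cell_above_both_thresholds_is_double_positive(self):
        idx = [f"c{i}" for i in range(5)]
        e = pd.Series([0.0, 0.1, 0.2, 0.3, 9.0], index=idx)
        l = pd.Series([0.0, 0.1, 0.2, 0.3, 9.0], index=idx)
        res = classify_cells(e, l)
        assert res.labels.iloc[-1] == "double_positive"

    def test_at_most_quarter_flagged_with_continuous_scores(self, rng):
        idx = [f"c{i}" for i in range(1000)]
        e = pd.Series(rng.normal(size=1000), index=idx)
        l = pd.Series(rng.normal(size=1000), index=idx)
        res = classify_cells(e, l)
        epihr = res.labels.isin(["HRC", "double_positive"]).mean()
        lgr5 = res.labels.isin(["LGR5pos", "double_positive"]).mean()
        assert epihr <= 0.25 and lgr5 <= 0.25


class TestComposition:
    def test_fractions_partition_and_zero_patient(self):
        labels = pd.Series(["HRC", "other", "other", "LGR5pos",
                            "other", "other"],
                           index=[f"c{i}" for i in range(6)])
        patients = pd.Series(["P1"] * 4 + ["P2"] * 2, index=labels.index)
        from hrcmap.cellmap import CellClassLabels
        frac, kw = composition(CellClassLabels(labels=labels, thresholds={}),
                               patients)
        np.testing.assert_allclose(frac.sum(axis=1), 1.0)
        assert frac.loc["P2", "HRC"] == 0.0

    def test_kruskal_detects_monotone_stage_effect(self, rng):
        rows = []
        stages = {}
        for i, (stage, p_hrc) in enumerate(
                [("II", 0.05)] * 8 + [("III", 0.15)] * 8 + [("IV", 0.30)] * 8):
            pid = f"P{i}"
            n = 200
            hrc = rng.random(n) < p_hrc
            labels = np.where(hrc, "HRC", "other")
            rows.append(pd.DataFrame({"label": labels, "patient": pid}))
            stages[pid] = stage
        df = pd.concat(rows, ignore_index=True)
        df.index = [f"c{i}" for i in range(len(df))]
        from hrcmap.cellmap import CellClassLabels
        frac, kw = composition(
            CellClassLabels(labels=df["label"], thresholds={}),
            df["patient"], stages=pd.Series(stages))
        assert kw["p"] < 0.05


class TestMarkers:
    def _data(self, rng, n_cells=200, n_genes=60, n_planted=10, fold=2.0):
        target = np.zeros(n_cells, dtype=bool)
        target[:n_cells // 4] = True
        base = rng.gamma(2.0, 1.0, size=n_genes)
        base[:n_planted] += 1.5  # planted markers are clearly expressed
        mu = np.tile(base, (n_cells, 1))
        mu[target, :n_planted] *= fold
        X = rng.poisson(mu)
        norm = pd.DataFrame(np.log1p(X),
                            columns=[f"g{i}" for i in range(n_genes)])
        labels = np.where(target, "HRC", "rest")
        return norm, labels

    def test_low_detection_gene_not_tested(self, rng):
        norm, labels = self._data(rng)
        norm["grare"] = 0.0
        norm.loc[norm.index[:3], "grare"] = 5.0   # ~6% of target cells
        res = find_markers(norm, labels, "HRC")
        assert "grare" not in res.index

    def test_planted_markers_recovered(self, rng):
        norm, labels = self._data(rng, fold=2.5)
        res = find_markers(norm, labels, "HRC")
        planted = [f"g{i}" for i in range(10)]
        hits = res.index.intersection(planted)
        recovered = res.loc[hits, "significant"].sum()
        assert recovered >= 9

    def test_permuted_labels_control_fdr(self, rng):
        norm, labels = self._data(rng, fold=1.0, n_genes=500)
        false_hits = []
        for _ in range(20):
            perm = rng.permutation(labels)
            res = find_markers(norm, perm, "HRC")
            false_hits.append(res["significant"].sum())
        assert np.mean(false_hits) <= 0.075 * 500


class TestCoreProgram:
    def _smoothed(self, values, genes, idx):
        df = pd.DataFrame(values, columns=genes, index=idx)
        return SmoothedCellMatrix(values=df, params={}, kernel=sp.eye(len(df)))

    def test_self_signature_correlates_perfectly(self, rng):
        genes = ["gsig", "gnoise", "gconst"]
        vals = np.column_stack([np.arange(20.0),
                                rng.normal(size=20),
                                np.ones(20)])
        sm = self._smoothed(vals, genes, [f"c{i}" for i in range(20)])
        scores = score_cells(sm, GeneSignature("s", ["gsig"]))
        avg = signature_gene_correlations([sm], [scores])
        assert abs(avg["gsig"] - 1.0) < 1e-12
        assert "gconst" not in avg.index

    def test_average_over_samples(self, rng):
        idx1 = [f"a{i}" for i in range(15)]
        idx2 = [f"b{i}" for i in range(15)]
        x = np.arange(15.0)
        sm1 = self._smoothed(np.column_stack([x, x]), ["s", "g"], idx1)
        noisy = 0.5 * x + rng.normal(size=15)
        sm2 = self._smoothed(np.column_stack([x, noisy]), ["s", "g"], idx2)
        sc1 = score_cells(sm1, GeneSignature("s", ["s"]))
        sc2 = score_cells(sm2, GeneSignature("s", ["s"]))
        avg = signature_gene_correlations([sm1, sm2], [sc1, sc2])
        r2 = np.corrcoef(x, noisy)[0, 1]
        assert abs(avg["g"] - (1.0 + r2) / 2) < 1e-9

    def test_top_k_selection(self):
        avg = pd.Series({"g1": 0.9, "g2": 0.8, "g3": 0.1})
        sig = derive_core_signature(avg, k=1)
        assert sig.genes == ["g1"]
        sig_all = derive_core_signature(avg, k=10)
        assert len(sig_all.genes) == 3
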