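"""Harmonization steps against hand-computed and residualization oracles."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_clinical
from hrcmap.metacohort import (GeneMatrix, ProbesetMatrix, correct_technical,
                               impute_msi, merge_cohort,
                               standardize_to_reference, summarize_probesets)
from hrcmap.scoring import GeneSignature


def _pm(values, mapping, technical=None, dataset_id="DS1"):
    tech = technical if technical is not None else pd.DataFrame(
        {"quality": 0.0, "scan_batch": "A", "center": "c1"},
        index=values.columns)
    return ProbesetMatrix(values=values, probeset_to_gene=pd.Series(mapping),
                          dataset_id=dataset_id, technical=tech)


class TestSummarizeProbesets:
    def test_single_probeset_passes_through(self):
        vals = pd.DataFrame([[1.0, 2.0, 4.0, 3.0]], index=["gA_ps1"],
                            columns=list("wxyz"))
        gm = summarize_probesets(_pm(vals, {"gA_ps1": "gA"}))
        np.testing.assert_allclose(gm.values.loc["gA"], vals.iloc[0], rtol=1e-12)

    def test_duplicate_probesets_keep_shared_moments(self):
        row = np.array([1.0, 3.0, 2.0, 6.0])
        vals = pd.DataFrame([row, row], index=["gA_ps1", "gA_ps2"],
                            columns=list("wxyz"))
        gm = summarize_probesets(_pm(vals, {"gA_ps1": "gA", "gA_ps2": "gA"}))
        out = gm.values.loc["gA"]
        assert abs(np.corrcoef(out, row)[0, 1] - 1.0) < 1e-12
        assert abs(out.mean() - row.mean()) < 1e-9
        assert abs(out.std(ddof=1) - row.std(ddof=1)) < 1e-9

    def test_sign_follows_dominant_probeset(self):
        # A (larger loading, higher variance) anti-correlated with B
        a = np.array([0.0, 2.0, 4.0, 6.0])
        b = -0.5 * a
        vals = pd.DataFrame([a, b], index=["gA_ps1", "gA_ps2"],
                            columns=list("wxyz"))
        gm = summarize_probesets(_pm(vals, {"gA_ps1": "gA", "gA_ps2": "gA"}))
        assert np.corrcoef(gm.values.loc["gA"], a)[0, 1] > 0.99

    def test_constant_gene_flagged(self):
        vals = pd.DataFrame([[5.0] * 4, [5.0] * 4],
                            index=["gA_ps1", "gA_ps2"], columns=list("wxyz"))
        gm = summarize_probesets(_pm(vals, {"gA_ps1": "gA", "gA_ps2": "gA"}))
        assert "gA" in gm.flags
        assert (gm.values.loc["gA"] == 5.0).all()


class TestCorrectTechnical:
    def test_constant_technical_is_identity(self):
        rng = np.random.default_rng(1)
        clin = make_clinical(30)
        vals = pd.DataFrame(rng.normal(size=(5, 30)),
                            index=[f"g{i}" for i in range(5)],
                            columns=clin.index)
        tech = pd.DataFrame({"quality": 1.0, "scan_batch": "A"},
                            index=clin.index)
        gm = GeneMatrix(values=vals, dataset_id="DS1")
        out = correct_technical(gm, tech, clin)
        np.testing.assert_allclose(out.values, vals, atol=1e-12)

    def test_planted_batch_shift_removed(self):
        rng = np.random.default_rng(2)
        clin = make_clinical(200)
        batch = np.array(["A"] * 100 + ["B"] * 100)
        vals = pd.DataFrame(rng.normal(size=(10, 200)) + 0.5 * (batch == "B"),
                            index=[f"g{i}" for i in range(10)],
                            columns=clin.index)
        tech = pd.DataFrame({"quality": rng.normal(size=200),
                             "scan_batch": batch}, index=clin.index)
        out = correct_technical(GeneMatrix(values=vals, dataset_id="D"),
                                tech, clin)
        diff = (out.values.loc[:, batch == "B"].mean(axis=1)
                - out.values.loc[:, batch == "A"].mean(axis=1))
        assert diff.abs().max() < 0.05

    def test_clinical_effect_preserved(self):
        rng = np.random.default_rng(3)
        clin = make_clinical(200)
        shift = 0.8 * (clin["stage"] == "III").to_numpy()
        vals = pd.DataFrame(rng.normal(size=(5, 200)) + shift,
                            index=[f"g{i}" for i in range(5)],
                            columns=clin.index)
        tech = pd.DataFrame({"quality": rng.normal(size=200),
                             "scan_batch": rng.choice(["A", "B"], 200)},
                            index=clin.index)
        out = correct_technical(GeneMatrix(values=vals, dataset_id="D"),
                                tech, clin)
        g = out.values.T.groupby((clin["stage"] == "III").to_numpy()).mean()
        assert (g.loc[True] - g.loc[False]).mean() > 0.6


class TestImputeMsi:
    def test_complete_labels_untouched(self):
        rng = np.random.default_rng(4)
        clin = make_clinical(30)
        vals = pd.DataFrame(rng.normal(size=(12, 30)),
                            index=[f"g{i}" for i in range(12)],
                            columns=clin.index)
        sig = GeneSignature("MSI", ["g0", "g1", "g2"], direction="high=MSI")
        out = impute_msi(GeneMatrix(values=vals, dataset_id="D"), sig, clin)
        assert out["msi"].equals(clin["msi"])

    def test_well_separated_modes_recovered(self):
        rng = np.random.default_rng(5)
        n = 300
        clin = make_clinical(n)
        truth = rng.random(n) < 0.3
        sig_genes = [f"g{i}" for i in range(16)]
        vals = pd.DataFrame(rng.normal(size=(16, n)) + truth * 1.0,
                            index=sig_genes, columns=clin.index)
        clin = clin.copy()
        clin["msi"] = pd.array([None] * n, dtype="object")
        sig = GeneSignature("MSI", sig_genes, direction="high=MSI")
        out = impute_msi(GeneMatrix(values=vals, dataset_id="D"), sig, clin)
        acc = ((out["msi"] == "MSI") == truth).mean()
        assert acc >= 0.95

    def test_unimodal_scores_trigger_mixture_fallback(self):
        rng = np.random.default_rng(6)
        clin = make_clinical(60)
        clin.loc[clin.index[:20], "msi"] = None
        vals = pd.DataFrame(rng.normal(size=(6, 60)),
                            index=[f"g{i}" for i in range(6)],
                            columns=clin.index)
        sig = GeneSignature("MSI", ["g0", "g1"], direction="high=MSI")
        out = impute_msi(GeneMatrix(values=vals, dataset_id="D"), sig, clin)
        assert out["msi"].notna().all()
        assert out.attrs["msi_imputation"]["method"] in ("gmm", "gap")


class TestStandardize:
    def test_reference_is_fixed_point(self):
        rng = np.random.default_rng(7)
        clin = make_clinical(60)
        vals = pd.DataFrame(rng.normal(7, 1, size=(8, 60)),
                            index=[f"g{i}" for i in range(8)],
                            columns=clin.index)
        gm = GeneMatrix(values=vals, dataset_id="REF")
        out = standardize_to_reference(gm, gm, clin, clin, seed=0)
        np.testing.assert_allclose(out.values, vals, atol=1e-9)

    def test_closed_form_z_map(self):
        cols_t = ["t1", "t2", "t3"]
        cols_r = ["r1", "r2", "r3"]
        clin_t = make_clinical(3).set_axis(cols_t)
        # identical single stratum on both sides
        for c in ("gender", "stage", "site", "msi"):
            clin_t[c] = clin_t[c].iloc[0]
        clin_t["age"] = 55.0
        clin_r = clin_t.set_axis(cols_r)
        tgt = GeneMatrix(values=pd.DataFrame([[8.0, 10.0, 12.0]],
                                             index=["g"], columns=cols_t),
                         dataset_id="T")
        ref = GeneMatrix(values=pd.DataFrame([[-1.0, 0.0, 1.0]],
                                             index=["g"], columns=cols_r),
                         dataset_id="R")
        out = standardize_to_reference(tgt, ref, clin_t, clin_r, seed=0)
        # target mean 10, sd 2; refsub mean 0, sd 1: 12 -> +1
        np.testing.assert_allclose(out.values.loc["g"].to_numpy(),
                                   [-1.0, 0.0, 1.0], atol=1e-12)

    def test_output_respects_reference_bounds(self):
        rng = np.random.default_rng(8)
        clin_t = make_clinical(50, seed=1)
        clin_r = make_clinical(80, dataset_id="REF", seed=2)
        tgt = GeneMatrix(values=pd.DataFrame(
            rng.normal(10, 3, size=(6, 50)),
            index=[f"g{i}" for i in range(6)], columns=clin_t.index),
            dataset_id="T")
        ref = GeneMatrix(values=pd.DataFrame(
            rng.normal(0, 1, size=(6, 80)),
            index=[f"g{i}" for i in range(6)], columns=clin_r.index),
            dataset_id="REF")
        out = standardize_to_reference(tgt, ref, clin_t, clin_r, seed=0)
        lo = ref.values.min(axis=1)
        hi = ref.values.max(axis=1)
        assert (out.values.ge(lo, axis=0) & out.values.le(hi, axis=0)).all().all()

    def test_idempotence_with_same_seed(self):
        # target narrower than the reference range, so truncation stays
        # inactive and the z-map is an exact fixed point
        rng = np.random.default_rng(9)
        clin_t = make_clinical(40, seed=3)
        clin_r = make_clinical(200, dataset_id="REF", seed=4)
        tgt = GeneMatrix(values=pd.DataFrame(
            np.clip(rng.normal(7, 0.8, size=(5, 40)), 6.0, 8.0),
            index=[f"g{i}" for i in range(5)], columns=clin_t.index),
            dataset_id="T")
        ref = GeneMatrix(values=pd.DataFrame(
            rng.normal(7, 1, size=(5, 200)),
            index=[f"g{i}" for i in range(5)], columns=clin_r.index),
            dataset_id="REF")
        once = standardize_to_reference(tgt, ref, clin_t, clin_r, seed=5)
        twice = standardize_to_reference(once, ref, clin_t, clin_r, seed=5)
        assert np.abs(twice.values - once.values).to_numpy().mean() < 1e-6


class TestMerge:
    def test_duplicate_sample_ids_rejected(self):
        vals = pd.DataFrame(np.ones((2, 3)), index=["g1", "g2"],
                            columns=["s1", "s2", "s3"])
        gms = [GeneMatrix(values=vals, dataset_id="A"),
               GeneMatrix(values=vals, dataset_id="B")]
        clin = make_clinical(3).set_axis(["s1", "s2", "s3"])
        with pytest.raises(ValueError, match="duplicated sample ids"):
            merge_cohort(gms, [clin, clin], reference_id="A")

    def test_gene_intersection(self):
        rng = np.random.default_rng(10)
        c1 = make_clinical(4, "A")
        c2 = make_clinical(4, "B")
        g1 = GeneMatrix(values=pd.DataFrame(
            rng.normal(size=(5, 4)), index=list("abcde"), columns=c1.index),
            dataset_id="A")
        g2 = GeneMatrix(values=pd.DataFrame(
            rng.normal(size=(4, 4)), index=list("abcf"), columns=c2.index),
            dataset_id="B")
        cohort = merge_cohort([g1, g2], [c1, c2], reference_id="A")
        assert sorted(cohort.values.index) == ["a", "b", "c"]
        assert cohort.values.shape == (3, 8)
        assert cohort.gene_bounds.shape[0] == 3
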