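"""Signature scoring, the relapse screen and the epithelial split."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_clinical
from hrcmap.metacohort import HarmonizedCohort
from hrcmap.scoring import (GeneSignature, score_signature,
                            zscore_signature_replicates)
from hrcmap.screen import (SortedPopulationSet, associate_clinical,
                           evaluate_signature_survival, screen_relapse_genes,
                           split_epithelial)
from hrcmap.pipeline import derive_signatures


class TestScoreSignature:
    def test_worked_example(self):
        mat = pd.DataFrame({"s1": [1.0, 2.0], "s2": [2.0, 4.0],
                            "s3": [3.0, 6.0]}, index=["g1", "g2"])
        sc = score_signature(mat, GeneSignature("sig", ["g1", "g2"]))
        np.testing.assert_allclose(sc.scores.to_numpy(), [-1.0, 0.0, 1.0],
                                   atol=1e-12)

    def test_constant_signature_rejected(self):
        mat = pd.DataFrame({"s1": [1.0], "s2": [1.0], "s3": [1.0]},
                           index=["g1"])
        with pytest.raises(ValueError, match="constant"):
            score_signature(mat, GeneSignature("sig", ["g1"]))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_affine_invariance_and_normalization(self, seed):
        rng = np.random.default_rng(seed)
        mat = pd.DataFrame(rng.normal(size=(6, 8)),
                           index=[f"g{i}" for i in range(6)],
                           columns=[f"s{i}" for i in range(8)])
        sig = GeneSignature("sig", ["g0", "g2", "g4"])
        base = score_signature(mat, sig).scores
        a = rng.uniform(0.5, 3.0, size=6)
        b = rng.normal(size=6)
        transformed = mat.mul(a, axis=0).add(b, axis=0)
        again = score_signature(transformed, sig).scores
        np.testing.assert_allclose(base, again, atol=1e-9)
        assert abs(base.mean()) < 1e-9
        assert abs(base.std(ddof=1) - 1.0) < 1e-9


class TestZscoreReplicates:
    def test_all_gene_signature_centers_to_zero(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.normal(size=(5, 6)),
                           index=[f"g{i}" for i in range(5)],
                           columns=[f"s{i}" for i in range(6)])
        sig = GeneSignature("all", list(mat.index))
        sc = zscore_signature_replicates(mat, sig, ["r1"] * 3 + ["r2"] * 3)
        np.testing.assert_allclose(sc.scores, 0.0, atol=1e-12)

    def test_replicate_shift_removed(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(rng.normal(size=(5, 6)),
                           index=[f"g{i}" for i in range(5)],
                           columns=[f"s{i}" for i in range(6)])
        reps = ["r1"] * 3 + ["r2"] * 3
        sig = GeneSignature("sig", ["g0", "g1"])
        base = zscore_signature_replicates(mat, sig, reps).scores
        shifted = mat.copy()
        shifted.iloc[:, 3:] += 1.0
        again = zscore_signature_replicates(shifted, sig, reps).scores
        np.testing.assert_allclose(base, again, atol=1e-9)

    def test_opposed_programs_score_with_opposite_signs(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.normal(size=(10, 8)) * 0.1,
                           index=[f"g{i}" for i in range(10)],
                           columns=[f"s{i}" for i in range(8)])
        mat.loc[["g0", "g1"], ["s0", "s1"]] += 3.0   # up program
        mat.loc[["g2", "g3"], ["s0", "s1"]] -= 3.0   # down program
        reps = ["r"] * 8
        up = zscore_signature_replicates(mat, GeneSignature("up", ["g0", "g1"]),
                                         reps).scores
        dn = zscore_signature_replicates(mat, GeneSignature("dn", ["g2", "g3"]),
                                         reps).scores
        assert up["s0"] > 0 > dn["s0"]


def _toy_cohort(seed=0, n=300, beta=0.0):
    rng = np.random.default_rng(seed)
    clin = pd.concat([make_clinical(n // 2, "D1", seed=seed),
                      make_clinical(n // 2, "D2", seed=seed + 1)])
    genes = [f"g{i}" for i in range(6)]
    vals = pd.DataFrame(rng.normal(size=(6, n)), index=genes,
                        columns=clin.index)
    vals.loc["gconst"] = 1.0
    base = rng.exponential(scale=np.exp(-beta * vals.loc["g0"].to_numpy()))
    cens = rng.exponential(scale=np.median(base) * 2, size=n)
    surv = pd.DataFrame({"time": np.minimum(base, cens),
                         "event": (base <= cens).astype(int),
                         "dataset_id": clin["dataset_id"]}, index=clin.index)
    bounds = pd.DataFrame({"min": vals.min(axis=1), "max": vals.max(axis=1)})
    cohort = HarmonizedCohort(values=vals, clinical=clin,
                              reference_dataset_id="D1", gene_bounds=bounds)
    return cohort, surv


class TestScreen:
    def test_constant_gene_excluded_and_rule_applied(self):
        cohort, surv = _toy_cohort(seed=4, beta=0.6)
        res = screen_relapse_genes(cohort, surv)
        assert res.loc["gconst", "excluded_reason"] == "zero variance"
        assert not res.loc["gconst", "in_allhr"]
        ok = res["p"].notna()
        np.testing.assert_array_equal(
            res.loc[ok, "in_allhr"],
            (res.loc[ok, "hr"] > 1) & (res.loc[ok, "p"] < 0.05))
        assert res.loc["g0", "in_allhr"]

    def test_single_dataset_matches_plain_cox(self):
        # with one dataset the stratified screen is an ordinary Cox fit
        from lifelines import CoxPHFitter
        cohort, surv = _toy_cohort(seed=5, beta=0.4)
        surv1 = surv.copy()
        surv1["dataset_id"] = "D1"
        res = screen_relapse_genes(cohort, surv1)
        x = cohort.values.loc["g0"]
        df = pd.DataFrame({"x": (x - x.mean()) / x.std(ddof=1),
                           "t": surv1["time"], "e": surv1["event"]})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        beta_hat = np.log(res.loc["g0", "hr"])
        se = cph.summary.loc["x", "se(coef)"]
        assert abs(beta_hat - cph.summary.loc["x", "coef"]) < 2 * se


def _sorted_set(values: dict, n_tumors=6):
    """Build a SortedPopulationSet from {pop: gene x tumor array}."""
    genes = list(next(iter(values.values())).index)
    cols, pops, tids, blocks = [], [], [], []
    for pop, mat in values.items():
        for t in mat.columns:
            cols.append(f"{t}_{pop.rstrip('+')}")
            pops.append(pop)
            tids.append(t)
            blocks.append(mat[t].to_numpy())
    vals = pd.DataFrame(np.column_stack(blocks), index=genes, columns=cols)
    return SortedPopulationSet(values=vals,
                               population=pd.Series(pops, index=cols),
                               tumor_id=pd.Series(tids, index=cols))


class TestSplitEpithelial:
    def _base(self, rng, genes, tumors, shift_gene=None, pops_up=()):
        out = {}
        for pop in ("EPCAM+", "FAP+", "CD45+", "CD31+"):
            m = pd.DataFrame(rng.normal(5, 0.3, size=(len(genes), len(tumors))),
                             index=genes, columns=tumors)
            if shift_gene and pop == "EPCAM+":
                m.loc[shift_gene] += 2.0
            if shift_gene and pop in pops_up:
                m.loc[shift_gene] += 2.0
            out[pop] = m
        return out

    def test_flat_gene_goes_to_tme(self):
        rng = np.random.default_rng(6)
        tumors = [f"T{i}" for i in range(8)]
        sset = _sorted_set(self._base(rng, ["gflat", "gepi"], tumors,
                                      shift_gene="gepi"))
        allhr = GeneSignature("allHR", ["gflat", "gepi"])
        epi, tme, detail = split_epithelial(allhr, sset)
        assert epi.genes == ["gepi"]
        assert tme.genes == ["gflat"]

    def test_all_three_rule(self):
        # higher than two compartments but equal to the third -> TME-HR
        rng = np.random.default_rng(7)
        tumors = [f"T{i}" for i in range(8)]
        base = self._base(rng, ["gpart", "gepi"], tumors, shift_gene="gepi")
        base["FAP+"].loc["gpart"] -= 2.0
        base["CD45+"].loc["gpart"] -= 2.0   # CD31+ stays equal
        sset = _sorted_set(base)
        allhr = GeneSignature("allHR", ["gpart", "gepi"])
        epi, tme, _ = split_epithelial(allhr, sset)
        assert "gpart" in tme.genes
        assert "gepi" in epi.genes

    def test_too_few_tumors_rejected(self):
        rng = np.random.default_rng(8)
        sset = _sorted_set(self._base(rng, ["g"], ["T0", "T1"]))
        with pytest.raises(ValueError, match="<3"):
            split_epithelial(GeneSignature("allHR", ["g"]), sset)


class TestEvaluate:
    def test_null_score_ci_covers_one(self):
        cohort, surv = _toy_cohort(seed=9, beta=0.0)
        sc = score_signature(cohort.values, GeneSignature("s", ["g1", "g2"]))
        ev = evaluate_signature_survival({"s": sc}, surv)
        row = ev.univariate.loc["s"]
        assert row["ci_low"] < 1.0 < row["ci_high"]
        assert "s" in ev.km and 0 <= ev.km["s"]["logrank_p"] <= 1

    def test_collinear_signatures_refused(self):
        cohort, surv = _toy_cohort(seed=10)
        sc = score_signature(cohort.values, GeneSignature("s", ["g1", "g2"]))
        sc2 = type(sc)(scores=sc.scores.copy(), signature="s2")
        with pytest.raises(ValueError, match="collinear"):
            evaluate_signature_survival({"a": sc, "b": sc2}, surv)

    def test_lrt_detects_planted_signal(self):
        cohort, surv = _toy_cohort(seed=11, beta=0.8)
        sc = score_signature(cohort.values, GeneSignature("s", ["g0"]))
        ev = evaluate_signature_survival({"s": sc}, surv)
        assert ev.lrt.loc["s", "p"] < 0.01


class TestAssociateClinical:
    def test_planted_stage_shift_recovered(self):
        rng = np.random.default_rng(12)
        clin = make_clinical(400)
        score = pd.Series(rng.normal(size=400), index=clin.index)
        score[clin["stage"] == "III"] += 0.5
        from hrcmap.scoring import SignatureScores
        res = associate_clinical(SignatureScores(scores=score, signature="s"),
                                 clin, variables=("stage", "gender"))
        row = res[(res["variable"] == "stage") & (res["level"] == "III")].iloc[0]
        assert row["ci_low"] < 0.5 < row["ci_high"]
        g = res[res["variable"] == "gender"].iloc[0]
        assert g["ci_low"] < 0.0 < g["ci_high"]

    def test_single_level_variable_skipped(self):
        rng = np.random.default_rng(13)
        clin = make_clinical(50)
        clin["site"] = "left"
        from hrcmap.scoring import SignatureScores
        res = associate_clinical(
            SignatureScores(scores=pd.Series(rng.normal(size=50),
                                             index=clin.index),
                            signature="s"), clin, variables=("site",))
        assert res.empty
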