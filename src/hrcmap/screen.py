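"""Relapse-gene screening and prognostic-signature evaluation.

Every gene of the harmonized cohort is tested for association with
relapse-free survival in a Cox proportional-hazards model with a
dataset-level shared effect (implemented by stratification on the dataset:
each series keeps its own baseline hazard).  Genes with HR > 1 and Wald
p < 0.05 (raw, no multiplicity correction at this stage; a BH column is
reported for transparency) form the **allHR** signature.  Genes of allHR
that are upregulated in FACS-sorted EPCAM+ epithelial cells versus all
three microenvironment compartments (FAP+, CD45+, CD31+; paired t-tests)
form **EpiHR**; the remainder form **TME-HR**.

Signature scores (scaled mean, SD units) are then evaluated with
univariate/multivariate Cox fits, drop-one likelihood-ratio tests and
Kaplan-Meier splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .cox import fit_cox, prepare_strata
from .metacohort import HarmonizedCohort
from .scoring import GeneSignature, SignatureScores, score_signature  # noqa: F401

logger = logging.getLogger("hrcmap")

POPULATIONS = ("EPCAM+", "FAP+", "CD45+", "CD31+")
TME_POPULATIONS = ("FAP+", "CD45+", "CD31+")


@dataclass
class SortedPopulationSet:
    """FACS-sorted compartment expression, paired by tumor."""

    values: pd.DataFrame          # gene x sample (log2 expression)
    population: pd.Series         # per sample, one of POPULATIONS
    tumor_id: pd.Series           # per sample

    def __post_init__(self) -> None:
        bad = set(self.population.unique()) - set(POPULATIONS)
        if bad:
            raise ValueError(f"unknown populations: {bad}")
        counts = pd.crosstab(self.tumor_id, self.population)
        if (counts > 1).any().any():
            raise ValueError("a tumor contributes >1 sample to a population")

    def wide(self, population: str) -> pd.DataFrame:
        """Gene x tumor matrix for one population (columns = tumor ids)."""
        cols = self.population.index[self.population == population]
        sub = self.values[cols]
        sub.columns = self.tumor_id.loc[cols].to_numpy()
        return sub


def screen_relapse_genes(cohort: HarmonizedCohort, surv: pd.DataFrame,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene Cox screen of standardized expression vs relapse.

    ``surv`` is indexed by sample id with columns ``time`` (years, > 0),
    ``event`` (1 = relapse) and ``dataset_id``.  Returns one row per gene:
    hr, ci_low, ci_high, p, p_bh, n, n_events, in_allhr, excluded_reason.
    Zero-variance or non-convergent genes are excluded with a reason.
    """
    samples = cohort.values.columns.intersection(surv.index)
    if len(samples) < len(cohort.values.columns):
        logger.warning("screen_relapse_genes: %d cohort samples lack survival",
                       len(cohort.values.columns) - len(samples))
    surv = surv.loc[samples]
    if (surv["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    X = cohort.values[samples]
    prepared = prepare_strata(surv["time"].to_numpy(),
                              surv["event"].to_numpy(),
                              surv["dataset_id"].to_numpy())
    records = []
    arr = X.to_numpy()
    sd = arr.std(axis=1, ddof=1)
    mean = arr.mean(axis=1)
    for i, gene in enumerate(X.index):
        if sd[i] == 0:
            records.append((gene, np.nan, np.nan, np.nan, np.nan, len(samples),
                            np.nan, False, "zero variance"))
            continue
        x = (arr[i] - mean[i]) / sd[i]
        fit = fit_cox(x, None, None, prepared=prepared)
        if not fit.converged or not np.isfinite(fit.beta):
            records.append((gene, np.nan, np.nan, np.nan, np.nan, fit.n,
                            fit.n_events, False, "non-convergent"))
            continue
        lo, hi = fit.ci()
        records.append((gene, fit.hr, lo, hi, fit.p, fit.n, fit.n_events,
                        bool(fit.hr > 1 and fit.p < alpha), ""))
    res = pd.DataFrame(records, columns=[
        "gene", "hr", "ci_low", "ci_high", "p", "n", "n_events",
        "in_allhr", "excluded_reason"]).set_index("gene")
    ok = res["p"].notna()
    from statsmodels.stats.multitest import multipletests
    res["p_bh"] = np.nan
    if ok.any():
        res.loc[ok, "p_bh"] = multipletests(res.loc[ok, "p"], method="fdr_bh")[1]
    return res


def allhr_signature(screen_result: pd.DataFrame,
                    name: str = "allHR") -> GeneSignature:
    """Signature of all screened genes with HR>1 and p<0.05."""
    genes = list(screen_result.index[screen_result["in_allhr"]])
    return GeneSignature(name=name, genes=genes,
                         derivation="Cox screen: HR>1 and Wald p<0.05")


def split_epithelial(allhr: GeneSignature, sorted_set: SortedPopulationSet,
                     alpha: float = 0.05,
                     ) -> Tuple[GeneSignature, GeneSignature, pd.DataFrame]:
    """Split allHR into epithelial (EpiHR) and microenvironment (TME-HR).

    Per gene, paired t-tests compare EPCAM+ against each of the three TME
    compartments on log expression across tumors.  A gene is epithelial iff
    the paired mean log-difference is positive (fold change > 1) AND
    p < alpha against *all three* populations.  Genes missing from the
    sorted set fall to TME-HR with a warning.  Returns (EpiHR, TMEHR,
    per-gene detail table).
    """
    epi = sorted_set.wide("EPCAM+")
    tme = {p: sorted_set.wide(p) for p in TME_POPULATIONS}
    tumors = epi.columns
    for p, m in tme.items():
        tumors = tumors.intersection(m.columns)
    if len(tumors) < 3:
        raise ValueError("paired test undefined with <3 complete tumors")

    present = [g for g in allhr.genes if g in sorted_set.values.index]
    absent = [g for g in allhr.genes if g not in sorted_set.values.index]
    if absent:
        logger.warning("split_epithelial: %d allHR genes absent from the "
                       "sorted set; assigned to TME-HR", len(absent))

    detail = []
    epi_genes = []
    e = epi.loc[present, tumors]
    for pop in TME_POPULATIONS:
        m = tme[pop].loc[present, tumors]
        diff = e - m
        md = diff.mean(axis=1)
        t, p = stats.ttest_rel(e, m, axis=1)
        detail.append(pd.DataFrame({f"logfc_{pop}": md, f"p_{pop}": p},
                                   index=present))
    detail = pd.concat(detail, axis=1)
    is_epi = np.ones(len(present), dtype=bool)
    for pop in TME_POPULATIONS:
        is_epi &= (detail[f"logfc_{pop}"] > 0).to_numpy()
        is_epi &= (detail[f"p_{pop}"] < alpha).to_numpy()
    detail["epithelial"] = is_epi
    epi_genes = [g for g, ok in zip(present, is_epi) if ok]
    tme_genes = [g for g in allhr.genes if g not in set(epi_genes)]
    if not epi_genes:
        raise ValueError("no epithelial genes passed the all-three rule")
    epihr = GeneSignature("EpiHR", epi_genes,
                          derivation="allHR & up in EPCAM+ vs all three TME "
                                     f"compartments (paired t, p<{alpha})")
    tmehr = GeneSignature("TME-HR", tme_genes,
                          derivation="allHR minus EpiHR")
    return epihr, tmehr, detail


@dataclass
class SurvivalEvaluation:
    """Results of evaluating one or more signature scores against relapse."""

    univariate: pd.DataFrame          # per signature: hr, ci, p
    multivariate: Optional[pd.DataFrame]   # per model term
    lrt: Optional[pd.DataFrame]       # drop-one likelihood-ratio tests
    km: Dict[str, dict] = field(default_factory=dict)


def _survival_frame(scores: Dict[str, SignatureScores], surv: pd.DataFrame,
                    clinical: Optional[pd.DataFrame]) -> pd.DataFrame:
    idx = surv.index
    df = pd.DataFrame({"time": surv["time"], "event": surv["event"],
                       "dataset_id": surv["dataset_id"]}, index=idx)
    for name, s in scores.items():
        df[name] = s.scores.reindex(idx)
    if clinical is not None:
        cl = clinical.loc[idx]
        df["age"] = (cl["age"] - cl["age"].mean()) / cl["age"].std(ddof=1)
        for col in ("gender", "stage", "site"):
            if col in cl.columns and cl[col].nunique() > 1:
                dummies = pd.get_dummies(cl[col].astype(str), prefix=col,
                                         drop_first=True, dtype=float)
                df = pd.concat([df, dummies], axis=1)
    return df.dropna()


def evaluate_signature_survival(scores: Dict[str, SignatureScores],
                                surv: pd.DataFrame,
                                clinical: Optional[pd.DataFrame] = None,
                                group_rule: str = "median",
                                ) -> SurvivalEvaluation:
    """Cox and Kaplan-Meier evaluation of signature scores.

    (i) univariate Cox per signature (dataset-stratified) -> HR per +1 SD;
    (ii) multivariate Cox with all signatures + clinical covariates;
    (iii) drop-one likelihood-ratio test per signature;
    (iv) Kaplan-Meier split of each score at the median (or tertiles) with
    a log-rank test.  Signatures correlated at |r| > 0.999 make the joint
    model unidentifiable and are refused.
    """
    from lifelines import CoxPHFitter, KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    names = list(scores)
    mat = pd.DataFrame({n: scores[n].scores for n in names}).dropna()
    if len(names) > 1:
        corr = mat.corr().to_numpy()
        iu = np.triu_indices(len(names), k=1)
        if np.any(np.abs(corr[iu]) > 0.999):
            raise ValueError("signatures are collinear (|r|>0.999); "
                             "multivariate fit refused")

    df = _survival_frame(scores, surv, clinical)
    strata = ["dataset_id"] if df["dataset_id"].nunique() > 1 else None

    uni_rows = []
    for name in names:
        cph = CoxPHFitter()
        cols = ["time", "event", name] + (["dataset_id"] if strata else [])
        cph.fit(df[cols], duration_col="time", event_col="event",
                strata=strata)
        s = cph.summary.loc[name]
        uni_rows.append({"signature": name, "hr": s["exp(coef)"],
                         "ci_low": s["exp(coef) lower 95%"],
                         "ci_high": s["exp(coef) upper 95%"],
                         "p": s["p"]})
    univariate = pd.DataFrame(uni_rows).set_index("signature")

    covar_cols = [c for c in df.columns
                  if c not in {"time", "event", "dataset_id"}]
    multivariate = None
    lrt = None
    if len(covar_cols) >= 1:
        full = CoxPHFitter()
        full.fit(df[["time", "event", "dataset_id"] + covar_cols]
                 if strata else df[["time", "event"] + covar_cols],
                 duration_col="time", event_col="event", strata=strata)
        multivariate = full.summary[["exp(coef)", "exp(coef) lower 95%",
                                     "exp(coef) upper 95%", "p"]].rename(
            columns={"exp(coef)": "hr", "exp(coef) lower 95%": "ci_low",
                     "exp(coef) upper 95%": "ci_high"})
        lrt_rows = []
        for name in names:
            reduced_cols = [c for c in covar_cols if c != name]
            red = CoxPHFitter()
            cols = (["time", "event", "dataset_id"] if strata
                    else ["time", "event"]) + reduced_cols
            if reduced_cols:
                red.fit(df[cols], duration_col="time", event_col="event",
                        strata=strata)
                ll0 = red.log_likelihood_
            else:
                ll0 = _null_loglik(df, strata)
            stat = 2.0 * (full.log_likelihood_ - ll0)
            lrt_rows.append({"signature": name, "lr_stat": stat,
                             "p": stats.chi2.sf(max(stat, 0.0), df=1)})
        lrt = pd.DataFrame(lrt_rows).set_index("signature")

    km: Dict[str, dict] = {}
    for name in names:
        s = df[name]
        if group_rule == "median":
            groups = np.where(s > s.median(), "high", "low")
        elif group_rule == "tertiles":
            groups = pd.qcut(s, 3, labels=["low", "mid", "high"]).astype(str)
        else:
            raise ValueError(f"unknown group_rule {group_rule!r}")
        lr = multivariate_logrank_test(df["time"], groups, df["event"])
        curves = {}
        for g in pd.unique(groups):
            kmf = KaplanMeierFitter()
            m = groups == g
            kmf.fit(df.loc[m, "time"], df.loc[m, "event"], label=str(g))
            curves[str(g)] = kmf.survival_function_
        km[name] = {"logrank_p": float(lr.p_value), "groups": groups,
                    "curves": curves}
    return SurvivalEvaluation(univariate=univariate, multivariate=multivariate,
                              lrt=lrt, km=km)


def _null_loglik(df: pd.DataFrame, strata) -> float:
    """Log partial likelihood of the covariate-free (null) Cox model."""
    total = 0.0
    groups = df.groupby("dataset_id") if strata else [(None, df)]
    for _, g in groups:
        t = g["time"].to_numpy()
        e = g["event"].to_numpy().astype(bool)
        order = np.argsort(t, kind="stable")
        ts, es = t[order], e[order]
        nrisk = np.arange(len(ts), 0, -1, dtype=float)
        first = np.searchsorted(ts, ts, side="left")
        total += float(-np.sum(np.log(nrisk[first[es]])))
    return total


def associate_clinical(scores: SignatureScores, clinical: pd.DataFrame,
                       variables: Sequence[str] = ("gender", "age", "stage",
                                                   "site", "msi"),
                       ) -> pd.DataFrame:
    """Linear-model association of a signature score with clinical variables.

    One model per variable: ``score ~ variable + C(dataset_id)``.  For
    categorical variables, effects are reported per level versus the
    reference level, with 95% CIs.  Single-level variables are skipped.
    """
    import statsmodels.formula.api as smf

    idx = scores.scores.index.intersection(clinical.index)
    base = pd.DataFrame({"score": scores.scores.loc[idx]})
    base["dataset_id"] = clinical.loc[idx, "dataset_id"].astype(str)
    rows: List[dict] = []
    for var in variables:
        if var not in clinical.columns:
            continue
        v = clinical.loc[idx, var]
        if v.nunique(dropna=True) < 2:
            logger.info("associate_clinical: %s has a single level; skipped", var)
            continue
        df = base.copy()
        numeric = v.dtype.kind in "fi"
        df["x"] = v if numeric else v.astype("object").where(v.notna(), "missing").astype(str)
        df = df.dropna()
        adj = " + C(dataset_id)" if df["dataset_id"].nunique() > 1 else ""
        term = "x" if numeric else "C(x)"
        fit = smf.ols(f"score ~ {term}{adj}", data=df).fit()
        ci = fit.conf_int()
        for pname in fit.params.index:
            if pname == "Intercept" or "dataset_id" in pname:
                continue
            level = pname.split("T.")[-1].rstrip("]") if not numeric else ""
            rows.append({"variable": var, "level": level,
                         "effect": fit.params[pname],
                         "ci_low": ci.loc[pname, 0], "ci_high": ci.loc[pname, 1],
                         "p": fit.pvalues[pname], "n": int(fit.nobs)})
    return pd.DataFrame(rows)
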