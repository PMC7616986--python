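"""Recovery and calibration benchmarks on synthetic ground truth.

Each function simulates data under the study conditions, runs the relevant
pipeline stage from scratch, and returns the measured quantities as a flat
dict.  They are shared by the test suite and by ``scripts/acceptance.py``.
All randomness descends from the ``seed`` argument.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import assoc, cellmap, synthetic
from .config import SimulationConfig
from .pipeline import (build_metacohort, core_program, derive_signatures,
                       map_single_cells)
from .scoring import GeneSignature, score_signature
from .screen import evaluate_signature_survival, screen_relapse_genes


def cox_screen_calibration(seed: int, n_genes: int = 2000,
                           samples_per_dataset: int = 200,
                           n_datasets: int = 4) -> Dict[str, float]:
    """Type-I error of the per-gene Cox screen on a null cohort.

    With the planted hazard effect switched off every gene is null; the
    fraction of Wald p < 0.05 should sit near the nominal level.
    """
    config = SimulationConfig(
        n_genes=n_genes, n_datasets=n_datasets,
        samples_per_dataset=samples_per_dataset,
        log_hr_per_sd=0.0, n_epi_prognostic=1, n_tme_prognostic=1,
        seed=seed)
    pms, clinical, surv, _ = synthetic.simulate_metacohort(config)
    cohort, _ = build_metacohort(pms, clinical,
                                 msi_sig=synthetic.msi_signature(config),
                                 seed=seed)
    screen = screen_relapse_genes(cohort, surv)
    ok = screen["p"].notna()
    frac = float((screen.loc[ok, "p"] < 0.05).mean())
    return {"null_fraction_p_lt_005": frac, "n_genes_tested": int(ok.sum())}


def signature_recovery(seed: int, n_genes: int = 1200,
                       samples_per_dataset: int = 375) -> Dict[str, float]:
    """allHR sensitivity and EpiHR precision/recall against planted truth."""
    config = SimulationConfig(
        n_genes=n_genes, samples_per_dataset=samples_per_dataset,
        n_epi_prognostic=100, n_tme_prognostic=100, log_hr_per_sd=0.2,
        seed=seed)
    pms, clinical, surv, truth = synthetic.simulate_metacohort(config)
    cohort, _ = build_metacohort(pms, clinical,
                                 msi_sig=synthetic.msi_signature(config),
                                 seed=seed)
    sorted_set, _ = synthetic.simulate_sorted_populations(config)
    der = derive_signatures(cohort, surv, sorted_set)

    planted = set(truth.epi_prognostic_genes) | set(truth.tme_prognostic_genes)
    allhr = set(der.allhr.genes)
    sensitivity = len(allhr & planted) / len(planted)
    epihr = set(der.epihr.genes)
    epi_true = set(truth.epi_prognostic_genes)
    precision = len(epihr & epi_true) / len(epihr) if epihr else 0.0
    recall = len(epihr & epi_true) / len(epi_true)
    return {"allhr_sensitivity": float(sensitivity),
            "epihr_precision": float(precision),
            "epihr_recall": float(recall),
            "allhr_size": len(allhr), "epihr_size": len(epihr)}


def survival_evaluation(seed: int, n_reps: int = 50,
                        target_score_loghr: float = 0.5) -> Dict[str, float]:
    """Recovery of the planted score hazard ratio over replicates.

    Each replicate simulates a ~1500-sample cohort whose linear predictor
    gives the planted-gene signature score a per-SD log hazard ratio of
    0.5, harmonizes it, scores the planted signature and fits the
    dataset-stratified Cox model.  Reports the fraction of replicates with
    the estimate inside [0.35, 0.65] on the log scale.
    """
    # choose the per-gene marginal log-HR b so the standardized mean-z score
    # over the k_e + k_t planted genes has per-SD log-HR 0.5: with gene
    # loading rho, cov(score, eta) = b and
    # var(score) = rho^2 (k_e^2 + k_t^2)/k^2 + (1 - rho^2)/k.
    # balanced programs so the score spans both hazard factors (otherwise
    # the omitted factor acts as a frailty and attenuates the marginal HR)
    k_e, k_t, rho = 13, 13, 0.5
    k = k_e + k_t
    score_sd = np.sqrt(rho ** 2 * (k_e ** 2 + k_t ** 2) / k ** 2
                       + (1 - rho ** 2) / k)
    b = target_score_loghr * score_sd
    betas = []
    ss = np.random.SeedSequence(seed, spawn_key=(11,))
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_reps)]
    for rep_seed in seeds:
        config = SimulationConfig(
            n_genes=80, n_epi_prognostic=k_e, n_tme_prognostic=k_t,
            n_msi_genes=10, samples_per_dataset=375,
            planted_gene_loading=rho, log_hr_per_sd=b, seed=rep_seed)
        pms, clinical, surv, truth = synthetic.simulate_metacohort(config)
        cohort, _ = build_metacohort(pms, clinical, seed=rep_seed)
        sig = GeneSignature("planted", truth.epi_prognostic_genes
                            + truth.tme_prognostic_genes)
        scores = score_signature(cohort.values, sig)
        ev = evaluate_signature_survival({"planted": scores}, surv)
        betas.append(float(np.log(ev.univariate.loc["planted", "hr"])))
    betas = np.asarray(betas)
    inside = float(np.mean((betas >= 0.35) & (betas <= 0.65)))
    return {"hr_recovery_coverage": inside,
            "median_hr_per_sd": float(np.exp(np.median(betas))),
            "n_reps": n_reps}


def harmonization_benchmark(seed: int) -> Dict[str, float]:
    """Batch-effect reduction and truncation-bound compliance."""
    config = SimulationConfig(n_genes=400, samples_per_dataset=150,
                              n_epi_prognostic=20, n_tme_prognostic=20,
                              seed=seed)
    pms, clinical, surv, _ = synthetic.simulate_metacohort(config)
    cohort, info = build_metacohort(pms, clinical,
                                    msi_sig=synthetic.msi_signature(config),
                                    seed=seed)

    def discrepancy(mats):
        """Mean over genes of the SD of per-dataset gene means."""
        means = pd.DataFrame({gm.dataset_id: gm.values.mean(axis=1)
                              for gm in mats})
        shared = means.dropna().index
        return float(means.loc[shared].std(axis=1, ddof=1).mean())

    before = discrepancy(info["pre_standardization"])
    after_mats = []
    for ds, cl in cohort.clinical.groupby("dataset_id"):
        from .metacohort import GeneMatrix
        after_mats.append(GeneMatrix(values=cohort.values[cl.index],
                                     dataset_id=str(ds)))
    after = discrepancy(after_mats)
    reduction = 1.0 - after / before if before > 0 else np.nan

    vals = cohort.values
    viol = ((vals.lt(cohort.gene_bounds["min"] - 1e-12, axis=0))
            | (vals.gt(cohort.gene_bounds["max"] + 1e-12, axis=0))).sum().sum()
    return {"discrepancy_before": before, "discrepancy_after": after,
            "discrepancy_reduction": float(reduction),
            "truncation_violations": int(viol)}


def msi_imputation_benchmark(seed: int) -> Dict[str, float]:
    """Accuracy of MSI imputation at the configured mode separation."""
    config = SimulationConfig(n_genes=300, samples_per_dataset=250,
                              n_epi_prognostic=10, n_tme_prognostic=10,
                              msi_separation_sd=4.0, msi_missing_rate=0.3,
                              seed=seed)
    pms, clinical, surv, truth = synthetic.simulate_metacohort(config)
    _, info = build_metacohort(pms, clinical,
                               msi_sig=synthetic.msi_signature(config),
                               seed=seed)
    completed = info["clinical_completed"]
    filled_mask = clinical["msi"].isna() & completed["msi"].notna()
    imputed = completed.loc[filled_mask, "msi"]
    correct = (imputed == truth.true_msi.loc[imputed.index]).mean()
    return {"msi_imputation_accuracy": float(correct),
            "n_filled": int(filled_mask.sum())}


def single_cell_mapping_benchmark(seed: int, n_patients: int = 20,
                                  corehrc_k: int = 100) -> Dict[str, float]:
    """HRC-fraction recovery and coreHRC-program recovery on synthetic cells.

    Simulates patients with true HRC fractions spanning 0-60% (some exact
    zeros), runs QC -> imputation -> epithelial calling -> signature
    scoring -> 75th-percentile classification, and compares the estimated
    per-patient HRC fraction (among epithelial cells) with the planted
    one.  The correlation-ranked core program is derived from the same
    mapping and scored against the planted program.
    """
    config = SimulationConfig(n_patients_sc=n_patients, seed=seed)
    adatas, truth = synthetic.simulate_scrna(config)
    epihr = GeneSignature("EpiHR", truth.epi_prognostic_genes)
    lgr5 = GeneSignature("Lgr5", truth.stem_program_genes + ["LGR5"])
    mapping = map_single_cells(adatas, epihr, lgr5)

    est = mapping.fractions["HRC"] + mapping.fractions["double_positive"]
    true = truth.true_hrc_fraction.loc[est.index]
    pearson = float(np.corrcoef(est, true)[0, 1])
    zero_pat = true.index[true == 0]
    zero_max = float(est.loc[zero_pat].max()) if len(zero_pat) else np.nan

    lab = mapping.labels.labels
    epihr_flag = float(lab.isin(["HRC", "double_positive"]).mean())
    lgr5_flag = float(lab.isin(["LGR5pos", "double_positive"]).mean())
    n_cells = int(len(lab))

    core, avg = core_program(mapping, epihr, k=corehrc_k)
    overlap = len(set(core.genes) & set(truth.hrc_program_genes))
    return {"hrc_fraction_pearson": pearson,
            "zero_patient_max_flagged": zero_max,
            "n_zero_patients": int(len(zero_pat)),
            "epihr_flagged_fraction": epihr_flag,
            "lgr5_flagged_fraction": lgr5_flag,
            "n_cells_analysis": n_cells,
            "corehrc_program_overlap": int(overlap),
            "corehrc_k": int(corehrc_k)}


def oracle_equivalence(seed: int = 0) -> Dict[str, float]:
    """Agreement of the statistical primitives with independent oracles.

    Brute-force enumerations (Spearman permutations, Wilcoxon assignments,
    maxmean subsets), the hand-computed 3-cell Markov diffusion, and the
    worked signature-score example, all recomputed here from first
    principles and compared against the package implementations.
    """
    out: Dict[str, float] = {}

    # Spearman: n=6 toy vs full 720-permutation enumeration
    import itertools
    x = np.array([1, 2, 3, 4, 5, 6], dtype=float)
    y = np.array([2, 1, 4, 3, 6, 5], dtype=float)
    res = assoc.spearman_association(x, y)
    rhos = []
    ry = stats.rankdata(y)
    for perm in itertools.permutations(range(6)):
        rhos.append(stats.spearmanr(x, ry[list(perm)]).statistic)
    rhos = np.array(rhos)
    p_oracle = float(np.mean(np.abs(rhos) >= abs(res["rho"]) - 1e-12))
    out["spearman_exact_p_abs_error"] = abs(res["p"] - p_oracle)

    # Wilcoxon 3v3: enumeration of all 20 assignments
    scores = pd.Series([1, 2, 3, 4, 5, 6], index=list("abcdef"), dtype=float)
    geno = pd.DataFrame({"ALT": [0, 0, 0, 1, 1, 1]}, index=list("abcdef"))
    wres = assoc.associate_mutations(scores, geno)
    vals = scores.to_numpy()
    obs_u = stats.mannwhitneyu(vals[3:], vals[:3],
                               alternative="two-sided").statistic
    us = []
    for combo in itertools.combinations(range(6), 3):
        mut = vals[list(combo)]
        wt = vals[[i for i in range(6) if i not in combo]]
        us.append(stats.mannwhitneyu(mut, wt, alternative="two-sided").statistic)
    us = np.asarray(us)
    mu_u = us.mean()
    p_oracle = float(np.mean(np.abs(us - mu_u) >= abs(obs_u - mu_u) - 1e-12))
    out["wilcoxon_exact_p_abs_error"] = abs(wres.loc["ALT", "p"] - p_oracle)

    # maxmean: z=(2,1,0,-1,-2), S = top two, against all 10 size-2 subsets
    z = pd.Series([2.0, 1.0, 0.0, -1.0, -2.0],
                  index=["g1", "g2", "g3", "g4", "g5"])
    mres = assoc.maxmean_enrichment(z, {"S": ["g1", "g2"]}, n_perm=1000,
                                    seed=seed, min_size=2)
    null = []
    for combo in itertools.combinations(range(5), 2):
        zz = z.to_numpy()[list(combo)]
        sp_, sn_ = np.maximum(zz, 0).mean(), np.maximum(-zz, 0).mean()
        null.append(sp_ if sp_ >= sn_ else -sn_)
    null = np.asarray(null)
    raw_oracle = 1.5
    p_oracle = float(np.mean(null >= raw_oracle - 1e-12))
    out["maxmean_raw_abs_error"] = abs(mres.loc["S", "maxmean"] - raw_oracle)
    out["maxmean_exact_p_abs_error"] = abs(mres.loc["S", "p"] - p_oracle)

    # diffusion on a 3-cell chain vs the hand-built Markov matrix
    X = pd.DataFrame([[0.0, 1.0], [1.0, 0.0], [2.0, 1.0]],
                     index=["c1", "c2", "c3"], columns=["gA", "gB"])
    sm = cellmap.diffusion_impute(X, k=2, ka=1, alpha=2.0, t=2, n_pcs=0)
    M_oracle = _chain_markov(X.to_numpy())
    expected = M_oracle @ M_oracle @ X.to_numpy()
    out["diffusion_markov_max_abs_error"] = float(
        np.max(np.abs(sm.values.to_numpy() - expected)))

    # signature score worked example
    mat = pd.DataFrame({"s1": [1.0, 2.0], "s2": [2.0, 4.0], "s3": [3.0, 6.0]},
                       index=["g1", "g2"])
    sc = score_signature(mat, GeneSignature("toy", ["g1", "g2"]))
    out["score_signature_example_max_abs_error"] = float(
        np.max(np.abs(sc.scores.to_numpy() - np.array([-1.0, 0.0, 1.0]))))
    return out


def _chain_markov(X: np.ndarray) -> np.ndarray:
    """Hand-built adaptive-kernel Markov operator for 3 cells, k=2, ka=1."""
    n = X.shape[0]
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    A = np.zeros((n, n))
    for i in range(n):
        order = np.argsort(D[i])
        neigh = order[:3]  # self + k=2 neighbors
        sigma = D[i][order[1]]  # ka-th (1st) non-self neighbor
        for j in neigh:
            A[i, j] = np.exp(-((D[i, j] / sigma) ** 2))
    A = (A + A.T) / 2.0
    return A / A.sum(axis=1, keepdims=True)


def enrichment_calibration(seed: int, n_sets: int = 1000,
                           n_genes: int = 500, set_size: int = 20,
                           n_perm: int = 200,
                           n_batches: int = 1000) -> Dict[str, float]:
    """Empirical type-I error of maxmean and preranked on null statistics.

    The random sets are spread over independent null statistic vectors
    (by default one per set); sets tested on one shared vector have
    positively correlated outcomes, which would inflate the variance of
    the empirical rate far beyond binomial.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(21,)))
    genes = [f"g{i}" for i in range(n_genes)]
    per_batch = max(n_sets // n_batches, 1)
    n_batches = n_sets // per_batch
    mm_p, pr_p = [], []
    for b in range(n_batches):
        z = pd.Series(rng.normal(size=n_genes), index=genes)
        sets = {f"set{b}_{i}": list(rng.choice(genes, size=set_size,
                                               replace=False))
                for i in range(per_batch)}
        mm = assoc.maxmean_enrichment(z, sets, n_perm=n_perm, seed=seed + b)
        pr = assoc.preranked_enrichment(z, sets, weight=1.0, n_perm=n_perm,
                                        seed=seed + b)
        mm_p.append(mm["p"])
        pr_p.append(pr["p"])
    mm_p = pd.concat(mm_p)
    pr_p = pd.concat(pr_p)
    return {"maxmean_type1_at_005": float((mm_p < 0.05).mean()),
            "preranked_type1_at_005": float((pr_p < 0.05).mean()),
            "n_sets": int(len(mm_p))}


def simulate_metastasis_counts(seed: int, n_tumors: int = 20,
                               mets_per_tumor: int = 3,
                               tcell_slope: float = -0.4):
    """Synthetic multiplex-imaging counts with a planted T-cell decline.

    Composition over five populations follows a logistic-normal model in
    which the T-cell log-ratio falls linearly with log2 metastasis size;
    tumors contribute correlated metastases via a shared intercept.  The
    default slope is a moderate compositional effect sized for ~90%
    planned power at 60 metastases once the burden class (itself a
    function of size) is adjusted for.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(22,)))
    pops = ["CD4", "CD8", "FOXP3", "LY6G", "CD68"]
    tcell_pops = {"CD8"}
    rows, sizes, burdens, tumors = [], [], [], []
    base = np.log(np.array([0.25, 0.25, 0.1, 0.15, 0.25]))
    for t in range(n_tumors):
        intercept = rng.normal(0.0, 0.3, size=len(pops))
        for m in range(mets_per_tumor):
            log2size = rng.uniform(8, 14)
            burden = ("micro" if log2size < 10
                      else "small" if log2size < 12 else "big")
            eta = base + intercept + rng.normal(0.0, 0.25, size=len(pops))
            for i, p in enumerate(pops):
                if p in tcell_pops:
                    eta[i] += tcell_slope * (log2size - 11.0)
            props = np.exp(eta) / np.exp(eta).sum()
            total = int(2 ** log2size / 16)
            rows.append(rng.multinomial(total, props))
            sizes.append(2.0 ** log2size)
            burdens.append(burden)
            tumors.append(f"tumor{t}")
    idx = [f"met{i}" for i in range(len(rows))]
    counts = pd.DataFrame(rows, index=idx, columns=pops)
    return (counts, pd.Series(sizes, index=idx), pd.Series(burdens, index=idx),
            pd.Series(tumors, index=idx))


def clr_trend_power(seed: int, n_reps: int = 50) -> Dict[str, float]:
    """Power to recover the planted T-cell decline with metastasis size."""
    ss = np.random.SeedSequence(seed, spawn_key=(23,))
    hits = 0
    for child in ss.spawn(n_reps):
        rep_seed = int(child.generate_state(1)[0] % (2 ** 31))
        counts, size, burden, tumor = simulate_metastasis_counts(rep_seed)
        res = assoc.clr_composition_trend(counts, size, burden, tumor)
        row = res["trend"].loc["CD8"]
        if row["size_coef"] < 0 and row["size_p"] < 0.05:
            hits += 1
    return {"clr_trend_power": hits / n_reps, "n_reps": n_reps}
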