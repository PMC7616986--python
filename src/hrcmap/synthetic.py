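"""Seeded synthetic cohorts with ground truth.

Three generators emulate the statistical structure the analysis assumes:

* :func:`simulate_metacohort` — several probeset-level expression series
  with dataset batch structure, clinical covariates, an MSI gene block,
  driver genotypes, and relapse-free survival drawn from a Cox-Weibull
  model whose linear predictor sums the planted prognostic genes.
* :func:`simulate_sorted_populations` — paired FACS-compartment profiles
  (EPCAM+/FAP+/CD45+/CD31+) per tumor, with the epithelial prognostic
  genes up-shifted in EPCAM+ and the TME prognostic genes in FAP+.
* :func:`simulate_scrna` — per-patient negative-binomial count matrices
  with an HRC subpopulation up-shifting the HRC program, an LGR5+ stem
  population, lineage markers, mitochondrial/ribosomal gene groups, and a
  per-patient HRC fraction coupled to the CAF fraction via a Gaussian
  copula.

Every generator is a pure function of the :class:`SimulationConfig`: the
global seed is split into fixed substreams, so identical configs produce
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import beta as beta_dist

from .config import (CELL_TYPES, EPITHELIAL_TYPES, TME_TYPES,
                     SimulationConfig)
from .metacohort import ProbesetMatrix
from .screen import POPULATIONS, SortedPopulationSet

MARKER_GENES = ("EPCAM", "LGR5", "FAP", "PECAM1", "PTPRC", "CD3D", "LYZ")


@dataclass
class GroundTruth:
    """Planted truth for recovery tests."""

    epi_prognostic_genes: List[str] = field(default_factory=list)
    tme_prognostic_genes: List[str] = field(default_factory=list)
    msi_genes: List[str] = field(default_factory=list)
    hrc_program_genes: List[str] = field(default_factory=list)
    stem_program_genes: List[str] = field(default_factory=list)
    per_gene_true_loghr: Optional[pd.Series] = None
    true_msi: Optional[pd.Series] = None
    genotypes: Optional[pd.DataFrame] = None
    true_cell_type: Optional[pd.Series] = None
    true_hrc_fraction: Optional[pd.Series] = None   # among epithelial cells
    latent_hrc_fraction: Optional[pd.Series] = None
    true_caf_fraction: Optional[pd.Series] = None   # among all cells


def gene_universe(config: SimulationConfig) -> Dict[str, List[str]]:
    """Deterministic bulk gene ids and planted-set assignment."""
    width = max(4, len(str(config.n_genes)))
    genes = [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]
    a = config.n_epi_prognostic
    b = a + config.n_tme_prognostic
    c = b + config.n_msi_genes
    return {
        "genes": genes,
        "epi": genes[:a],
        "tme": genes[a:b],
        "msi": genes[b:c],
        "null": genes[c:],
    }


def sc_gene_universe(config: SimulationConfig) -> Dict[str, List[str]]:
    """Single-cell gene universe: bulk genes plus sc-only groups.

    Besides the planted programs, each microenvironment lineage carries a
    transcriptional program of its own (drawn from the null bulk genes) and
    the epithelial lineages share a common epithelial program, so that
    lineages are transcriptionally distant the way real cell types are and
    graph components separate by lineage.
    """
    uni = gene_universe(config)
    n_extra = config.n_hrc_program - config.n_epi_prognostic
    sc_only = [f"SCP{i + 1:03d}" for i in range(n_extra)]
    stem = [f"STM{i + 1:03d}" for i in range(config.n_stem_program)]
    mito = [f"MT-{i + 1:02d}" for i in range(10)]
    ribo = ([f"RPL{i + 1:02d}" for i in range(15)]
            + [f"RPS{i + 1:02d}" for i in range(15)])
    null = uni["null"]
    m = min(30, len(null) // 5)
    lineage = {}
    for i, name in enumerate(("epithelial_common", "CAF_program",
                              "endothelial_program", "myeloid_program",
                              "Tcell_program")):
        lineage[name] = null[i * m:(i + 1) * m]
    uni.update(lineage)
    uni.update({
        "hrc_program": uni["epi"] + sc_only,
        "sc_only": sc_only,
        "stem": stem,
        "markers": list(MARKER_GENES),
        "mito": mito,
        "ribo": ribo,
        "sc_genes": (uni["genes"] + sc_only + stem + list(MARKER_GENES)
                     + mito + ribo),
    })
    return uni


# ---------------------------------------------------------------------------
# bulk meta-cohort
# ---------------------------------------------------------------------------

def _calibrated_survival(eta: np.ndarray, config: SimulationConfig,
                         rng: np.random.Generator
                         ) -> Tuple[np.ndarray, np.ndarray, float]:
    """Draw (time, event) hitting the target censoring rate.

    Event times are inverse-transform Weibull draws accelerated by exp(eta);
    censoring is uniform on the follow-up window.  When the Weibull scale is
    not fixed in the config it is calibrated by bisection on the realized
    draws so the event fraction equals 1 - censoring_rate.
    """
    n = eta.size
    shape = config.weibull_shape
    u_t = rng.uniform(1e-12, 1.0, size=n)
    u_c = rng.uniform(0.0, 1.0, size=n)
    base = (-np.log(u_t) / np.exp(eta)) ** (1.0 / shape)
    cens = config.followup_years * u_c
    target_event = 1.0 - config.censoring_rate

    if config.weibull_scale is not None:
        scale = config.weibull_scale
    elif config.censoring_rate <= 0:
        scale = 3.0
    else:
        lo, hi = 1e-4, 1e4
        for _ in range(80):
            mid = np.sqrt(lo * hi)
            frac = np.mean(mid * base <= cens)
            if frac > target_event:
                lo = mid  # too many events -> times too short -> raise scale
            else:
                hi = mid
        scale = np.sqrt(lo * hi)

    t_event = scale * base
    if config.censoring_rate <= 0:
        return np.maximum(t_event, 1e-6), np.ones(n, dtype=int), scale
    event = (t_event <= cens).astype(int)
    time = np.maximum(np.minimum(t_event, cens), 1e-6)
    return time, event, scale


def simulate_metacohort(config: SimulationConfig
                        ) -> Tuple[List[ProbesetMatrix], pd.DataFrame,
                                   pd.DataFrame, GroundTruth]:
    """Simulate the multi-dataset probeset-level meta-cohort.

    Returns (probeset matrices, clinical table, survival table, truth).
    Gene-level latent expression is standard normal with dataset-specific
    additive shifts and multiplicative scales; MSI samples shift the MSI
    block by ``msi_separation_sd / sqrt(n_msi_genes)`` per gene (so the
    signature-score modes sit ~``msi_separation_sd`` score-SDs apart);
    KRAS-mutant samples shift the epithelial prognostic genes.  Each gene
    expands into 1-4 probesets sharing the gene signal plus independent
    noise.
    """
    uni = gene_universe(config)
    genes = uni["genes"]
    g_index = {g: i for i, g in enumerate(genes)}
    epi_idx = np.array([g_index[g] for g in uni["epi"]])
    tme_idx = np.array([g_index[g] for g in uni["tme"]])
    msi_idx = np.array([g_index[g] for g in uni["msi"]])

    root = np.random.SeedSequence(config.seed, spawn_key=(1,))
    n_children = 2 + config.n_datasets
    children = root.spawn(n_children)
    rng_global = np.random.default_rng(children[0])
    rng_surv = np.random.default_rng(children[1])

    # shared platform structure
    mu = rng_global.normal(7.0, 1.0, size=config.n_genes)
    n_ps = rng_global.choice(np.arange(1, len(config.probesets_per_gene_probs) + 1),
                             size=config.n_genes,
                             p=config.probesets_per_gene_probs)
    lo, hi = config.probeset_loading_range
    loadings = [rng_global.uniform(lo, hi, size=m) for m in n_ps]

    msi_delta = config.msi_separation_sd / np.sqrt(config.n_msi_genes)
    drivers = list(config.mutation_rates)

    pms: List[ProbesetMatrix] = []
    clin_parts, lat_parts, truth_msi, truth_geno = [], [], [], []
    for d in range(config.n_datasets):
        rng = np.random.default_rng(children[2 + d])
        ds = f"DS{d + 1}"
        n_s = config.samples_per_dataset
        sids = [f"{ds}_S{i + 1:04d}" for i in range(n_s)]

        # clinical covariates with per-dataset frequency differences
        p_female = rng.uniform(0.40, 0.60)
        gender = np.where(rng.random(n_s) < p_female, "F", "M")
        age = np.clip(rng.normal(rng.uniform(62, 68), 10, n_s), 30, 89)
        stage_p = rng.dirichlet(np.array([0.15, 0.35, 0.35, 0.15]) * 40)
        stage = rng.choice(["I", "II", "III", "IV"], size=n_s, p=stage_p)
        site_p = rng.dirichlet(np.array([0.45, 0.35, 0.20]) * 40)
        site = rng.choice(["left", "right", "rectum"], size=n_s, p=site_p)
        msi_true = np.where(rng.random(n_s) < config.msi_fraction, "MSI", "MSS")
        msi_obs = pd.array(msi_true, dtype="object")
        hide = rng.random(n_s) < config.msi_missing_rate
        msi_obs[hide] = None
        geno = pd.DataFrame(
            {drv: (rng.random(n_s) < config.mutation_rates[drv]).astype(int)
             for drv in drivers}, index=sids)

        # latent biology: the planted prognostic genes form two co-expressed
        # programs (epithelial, TME) loading on per-sample program factors,
        # which also drive the relapse hazard
        rho = config.planted_gene_loading
        f_epi = rng.normal(size=n_s)
        f_tme = rng.normal(size=n_s)
        z = rng.normal(size=(config.n_genes, n_s))
        z[epi_idx] = rho * f_epi + np.sqrt(1 - rho ** 2) * z[epi_idx]
        z[tme_idx] = rho * f_tme + np.sqrt(1 - rho ** 2) * z[tme_idx]
        z[np.ix_(msi_idx, np.nonzero(msi_true == "MSI")[0])] += msi_delta
        if "KRAS" in geno:
            kras = geno["KRAS"].to_numpy().astype(bool)
            z[np.ix_(epi_idx, np.nonzero(kras)[0])] += config.kras_effect

        # technical covariates and their planted effects
        quality = rng.normal(0.0, 1.0, n_s)
        scan_batch = rng.choice(["A", "B"], size=n_s)
        center = rng.choice([f"{ds}_c1", f"{ds}_c2"], size=n_s)
        tech = (config.tech_quality_effect * quality
                + config.tech_batch_effect * (scan_batch == "B")
                + config.tech_batch_effect * 0.75 * (center == f"{ds}_c2"))

        scale_d = rng.uniform(*config.batch_scale_range)
        shift_dg = rng.normal(0.0, config.batch_shift_sd, size=config.n_genes)
        X = (mu[:, None] + shift_dg[:, None] + scale_d * z + tech[None, :])

        # probeset expansion
        ps_rows, ps_ids, ps_gene = [], [], []
        for gi, g in enumerate(genes):
            for j in range(n_ps[gi]):
                noise = rng.normal(0.0, config.probeset_noise_sd, n_s)
                ps_rows.append(loadings[gi][j] * X[gi] + noise)
                ps_ids.append(f"{g}_ps{j + 1}")
                ps_gene.append(g)
        values = pd.DataFrame(np.vstack(ps_rows), index=ps_ids, columns=sids)
        technical = pd.DataFrame({"quality": quality, "scan_batch": scan_batch,
                                  "center": center}, index=sids)
        pms.append(ProbesetMatrix(values=values,
                                  probeset_to_gene=pd.Series(ps_gene, index=ps_ids),
                                  dataset_id=ds, technical=technical))
        clin_parts.append(pd.DataFrame(
            {"gender": gender, "age": age, "stage": stage, "site": site,
             "msi": msi_obs, "dataset_id": ds}, index=sids))
        lat_parts.append(np.stack([f_epi, f_tme]))
        truth_msi.append(pd.Series(msi_true, index=sids))
        truth_geno.append(geno)

    clinical = pd.concat(clin_parts)
    factors = np.concatenate(lat_parts, axis=1)  # 2 x n_total

    # Cox-Weibull relapse hazard driven by the program factors; with gene
    # loading rho, each planted gene's marginal per-SD log-HR is
    # log_hr_per_sd (the factor coefficient is log_hr_per_sd / rho)
    gamma = config.log_hr_per_sd / config.planted_gene_loading
    eta = gamma * (factors[0] + factors[1])
    time, event, scale = _calibrated_survival(eta, config, rng_surv)
    survival = pd.DataFrame({"time": time, "event": event,
                             "dataset_id": clinical["dataset_id"]},
                            index=clinical.index)
    survival.attrs["weibull_scale"] = float(scale)

    loghr = pd.Series(0.0, index=genes)
    loghr.loc[uni["epi"] + uni["tme"]] = config.log_hr_per_sd
    truth = GroundTruth(
        epi_prognostic_genes=uni["epi"],
        tme_prognostic_genes=uni["tme"],
        msi_genes=uni["msi"],
        hrc_program_genes=sc_gene_universe(config)["hrc_program"],
        per_gene_true_loghr=loghr,
        true_msi=pd.concat(truth_msi),
        genotypes=pd.concat(truth_geno),
    )
    return pms, clinical, survival, truth


def msi_signature(config: SimulationConfig) -> "GeneSignature":
    """The planted MSI transcriptomic signature (high score = MSI)."""
    from .scoring import GeneSignature
    return GeneSignature("MSI", gene_universe(config)["msi"],
                         derivation="planted MSI block", direction="high=MSI")


# ---------------------------------------------------------------------------
# sorted compartments
# ---------------------------------------------------------------------------

def simulate_sorted_populations(config: SimulationConfig
                                ) -> Tuple[SortedPopulationSet, GroundTruth]:
    """Paired compartment profiles for n_tumors (default 14) tumors.

    Epithelial prognostic genes are shifted up by ``sorted_epi_shift`` log2
    units in EPCAM+ relative to all three TME populations; TME prognostic
    genes are shifted up in FAP+.  A gene-by-tumor random intercept makes
    the design genuinely paired.
    """
    uni = gene_universe(config)
    genes = uni["genes"]
    g_index = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(np.random.SeedSequence(config.seed,
                                                       spawn_key=(2,)))
    n_t = config.n_tumors_sorted
    tumors = [f"T{i + 1:02d}" for i in range(n_t)]
    mu = rng.normal(7.0, 1.0, size=config.n_genes)
    tumor_eff = rng.normal(0.0, config.sorted_tumor_sd,
                           size=(config.n_genes, n_t))

    shift = np.zeros((config.n_genes, len(POPULATIONS)))
    p_index = {p: i for i, p in enumerate(POPULATIONS)}
    for g in uni["epi"]:
        shift[g_index[g], p_index["EPCAM+"]] = config.sorted_epi_shift
    for g in uni["tme"]:
        shift[g_index[g], p_index["FAP+"]] = config.sorted_tme_shift

    cols, pops, tids = [], [], []
    blocks = []
    for t_i, t in enumerate(tumors):
        for p in POPULATIONS:
            noise = rng.normal(0.0, config.sorted_noise_sd, config.n_genes)
            blocks.append(mu + tumor_eff[:, t_i] + shift[:, p_index[p]] + noise)
            cols.append(f"{t}_{p.rstrip('+')}")
            pops.append(p)
            tids.append(t)
    values = pd.DataFrame(np.column_stack(blocks), index=genes, columns=cols)
    sset = SortedPopulationSet(values=values,
                               population=pd.Series(pops, index=cols),
                               tumor_id=pd.Series(tids, index=cols))
    truth = GroundTruth(epi_prognostic_genes=uni["epi"],
                        tme_prognostic_genes=uni["tme"])
    return sset, truth


# ---------------------------------------------------------------------------
# patient single-cell data
# ---------------------------------------------------------------------------

def _copula_fractions(config: SimulationConfig, rng: np.random.Generator
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Per-patient (HRC fraction among epithelium, CAF fraction).

    A Gaussian copula with the Pearson parameter matched to the target
    Spearman coupling drives both margins; the HRC margin puts
    ``hrc_zero_patient_rate`` mass at exactly zero and is otherwise uniform
    on [hrc_fraction_min, hrc_fraction_max] (patients either lack the HRC
    state or harbor it at a substantial fraction; the cohort-mean fraction
    then exceeds the 25% flagged by a pooled 75th-percentile threshold, a
    consistency requirement of the percentile classifier).  The CAF margin
    is Beta(3, 22) (mean ~0.12).
    """
    rho_s = config.hrc_caf_coupling
    rho = 2.0 * np.sin(np.pi * rho_s / 6.0)
    n = config.n_patients_sc
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=n,
                                method="cholesky")
    from scipy.stats import norm
    u = norm.cdf(z)
    p0 = config.hrc_zero_patient_rate
    span = config.hrc_fraction_max - config.hrc_fraction_min
    h = np.where(u[:, 0] < p0, 0.0,
                 config.hrc_fraction_min
                 + span * (u[:, 0] - p0) / max(1.0 - p0, 1e-12))
    caf = beta_dist.ppf(u[:, 1], 3.0, 22.0)
    return h, caf


def simulate_scrna(config: SimulationConfig
                   ) -> Tuple[List[ad.AnnData], GroundTruth]:
    """Per-patient 10X-style negative-binomial count matrices.

    Cell types follow per-patient proportions; HRC cells up-shift the HRC
    program by ``exp(hrc_effect_log)``, LGR5+ stem cells a disjoint stem
    program (plus LGR5), epithelial cells EPCAM; each TME lineage carries a
    canonical marker.  Mitochondrial and ribosomal gene groups occupy
    per-cell Beta-distributed library fractions so QC filters have
    something to remove.  Counts are NB with var = mu + mu^2/theta.
    """
    uni = sc_gene_universe(config)
    genes = uni["sc_genes"]
    n_g = len(genes)
    gi = {g: i for i, g in enumerate(genes)}
    idx = {k: np.array([gi[g] for g in uni[k]], dtype=int)
           for k in ("hrc_program", "stem", "mito", "ribo", "tme",
                     "epithelial_common", "CAF_program",
                     "endothelial_program", "myeloid_program",
                     "Tcell_program")}

    root = np.random.SeedSequence(config.seed, spawn_key=(3,))
    children = root.spawn(1 + config.n_patients_sc)
    rng0 = np.random.default_rng(children[0])

    # relative abundances: moderate, narrow spread for program genes so the
    # planted effects are detectable at 10X-like depth
    rel = rng0.lognormal(0.0, 1.0, size=n_g)
    prog_all = np.concatenate([idx["hrc_program"], idx["stem"]])
    rel[prog_all] = 2.0 * rng0.lognormal(0.0, 0.5, size=prog_all.size)
    for m in MARKER_GENES:
        rel[gi[m]] = 5.0
    mito_rel = rng0.dirichlet(np.full(len(uni["mito"]), 5.0))
    ribo_rel = rng0.dirichlet(np.full(len(uni["ribo"]), 5.0))

    # cell-type effect multipliers
    t_index = {t: i for i, t in enumerate(CELL_TYPES)}
    E = np.ones((len(CELL_TYPES), n_g))
    E[t_index["HRC"], idx["hrc_program"]] = np.exp(config.hrc_effect_log)
    E[t_index["LGR5_stem"], idx["stem"]] = np.exp(1.2)
    E[t_index["LGR5_stem"], gi["LGR5"]] = np.exp(1.2)
    for t in EPITHELIAL_TYPES:
        E[t_index[t], gi["EPCAM"]] = np.exp(2.5)
    for t in TME_TYPES:
        E[t_index[t], gi["EPCAM"]] = np.exp(-2.0)
    E[t_index["CAF"], gi["FAP"]] = np.exp(3.0)
    E[t_index["CAF"], idx["tme"]] = np.exp(1.0)
    E[t_index["endothelial"], gi["PECAM1"]] = np.exp(3.0)
    E[t_index["myeloid"], gi["LYZ"]] = np.exp(3.0)
    E[t_index["myeloid"], gi["PTPRC"]] = np.exp(2.0)
    E[t_index["Tcell"], gi["PTPRC"]] = np.exp(2.0)
    E[t_index["Tcell"], gi["CD3D"]] = np.exp(3.0)
    # lineage programs: each TME lineage is transcriptionally distant
    for t in EPITHELIAL_TYPES:
        E[t_index[t], idx["epithelial_common"]] = np.exp(1.5)
    for t, key in (("CAF", "CAF_program"), ("endothelial", "endothelial_program"),
                   ("myeloid", "myeloid_program"), ("Tcell", "Tcell_program")):
        E[t_index[t], idx[key]] = np.exp(2.0)

    h_frac, caf_frac = _copula_fractions(config, rng0)

    main_mask = np.ones(n_g, dtype=bool)
    main_mask[idx["mito"]] = False
    main_mask[idx["ribo"]] = False
    base_props = config.celltype_base_props
    other_tme = sum(base_props[t] for t in TME_TYPES if t != "CAF")
    epi_rest = {t: base_props[t] for t in EPITHELIAL_TYPES if t != "HRC"}
    epi_rest_total = sum(epi_rest.values())

    adatas: List[ad.AnnData] = []
    truth_type, truth_h, truth_lat_h, truth_caf = {}, {}, {}, {}
    theta = config.nb_dispersion
    for p in range(config.n_patients_sc):
        rng = np.random.default_rng(children[1 + p])
        pid = f"P{p + 1:02d}"
        n_c = config.cells_per_patient

        probs = np.zeros(len(CELL_TYPES))
        probs[t_index["CAF"]] = caf_frac[p]
        for t in TME_TYPES:
            if t != "CAF":
                probs[t_index[t]] = base_props[t]
        epi_total = max(1.0 - probs.sum(), 0.0)
        probs[t_index["HRC"]] = h_frac[p] * epi_total
        for t, w in epi_rest.items():
            probs[t_index[t]] = (1.0 - h_frac[p]) * epi_total * w / epi_rest_total
        probs = probs / probs.sum()

        types = rng.choice(len(CELL_TYPES), size=n_c, p=probs)
        lib = config.mean_counts_per_cell * np.exp(
            rng.normal(0.0, 0.3, n_c) - 0.045)
        f_mito = rng.beta(2.0, 23.0, n_c)
        f_ribo = rng.beta(30.0, 170.0, n_c)

        frac = rel[None, :] * E[types]
        frac[:, ~main_mask] = 0.0
        frac /= frac.sum(axis=1, keepdims=True)
        mu = frac * (lib * (1.0 - f_mito - f_ribo))[:, None]
        mu[:, idx["mito"]] = np.outer(lib * f_mito, mito_rel)
        mu[:, idx["ribo"]] = np.outer(lib * f_ribo, ribo_rel)

        pnb = theta / (theta + mu)
        counts = rng.negative_binomial(theta, pnb)
        barcodes = [f"{pid}_c{i + 1:04d}" for i in range(n_c)]
        tnames = np.array(CELL_TYPES)[types]
        obs = pd.DataFrame({"patient": pid, "sample": pid,
                            "true_cell_type": tnames}, index=barcodes)
        adata = ad.AnnData(X=sp.csr_matrix(counts.astype(np.int32)), obs=obs,
                           var=pd.DataFrame(index=genes))
        adatas.append(adata)

        truth_type.update(dict(zip(barcodes, tnames)))
        epi_cells = np.isin(tnames, EPITHELIAL_TYPES)
        truth_h[pid] = float((tnames == "HRC").sum() / max(epi_cells.sum(), 1))
        truth_lat_h[pid] = float(h_frac[p])
        truth_caf[pid] = float((tnames == "CAF").mean())

    truth = GroundTruth(
        epi_prognostic_genes=uni["epi"],
        tme_prognostic_genes=uni["tme"],
        hrc_program_genes=uni["hrc_program"],
        stem_program_genes=uni["stem"],
        true_cell_type=pd.Series(truth_type),
        true_hrc_fraction=pd.Series(truth_h),
        latent_hrc_fraction=pd.Series(truth_lat_h),
        true_caf_fraction=pd.Series(truth_caf),
    )
    return adatas, truth
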