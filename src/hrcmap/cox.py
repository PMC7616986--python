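"""Single-covariate Cox proportional-hazards fits stratified by dataset.

The genome-wide relapse screen fits one Cox model per gene with the dataset
as a stratification factor (each dataset keeps its own baseline hazard —
the same inferential target as a shared dataset-level frailty, and robust
with a handful of datasets).  Screening thousands of genes makes a dedicated
Newton solver for the one-covariate stratified partial likelihood worthwhile;
`lifelines` serves as the independent reference implementation in the test
suite and is used for the multivariate evaluation fits elsewhere.

Breslow's approximation handles ties (simulated relapse times are
continuous, so event-time ties are rare).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm


@dataclass
class CoxFit:
    """Result of a single-covariate Cox fit."""

    beta: float
    se: float
    p: float
    n: int
    n_events: int
    converged: bool

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta))

    def ci(self, level: float = 0.95) -> tuple:
        z = norm.ppf(0.5 + level / 2)
        return (float(np.exp(self.beta - z * self.se)),
                float(np.exp(self.beta + z * self.se)))


class _StratumData:
    """Pre-sorted survival data for one stratum."""

    __slots__ = ("order", "event_idx", "first_idx")

    def __init__(self, time: np.ndarray, event: np.ndarray):
        self.order = np.argsort(time, kind="stable")
        t = time[self.order]
        e = event[self.order].astype(bool)
        # Breslow risk set at a tied time = everything from the first
        # occurrence of that time onward (times sorted ascending, risk sums
        # accumulated from the end).
        self.first_idx = np.searchsorted(t, t, side="left")
        self.event_idx = np.nonzero(e)[0]


def prepare_strata(time: np.ndarray, event: np.ndarray,
                   strata: np.ndarray) -> list:
    """Pre-sort survival data per stratum for repeated fits over genes."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    strata = np.asarray(strata)
    out = []
    for s in np.unique(strata):
        mask = strata == s
        out.append((np.nonzero(mask)[0], _StratumData(time[mask], event[mask])))
    return out


def _score_info(beta: float, xs: Sequence[np.ndarray],
                prep: Sequence[_StratumData]) -> tuple:
    """Score, information and log partial likelihood at ``beta``."""
    U = 0.0
    I = 0.0
    ll = 0.0
    for x, sd in zip(xs, prep):
        if sd.event_idx.size == 0:
            continue
        xo = x[sd.order]
        eta = beta * xo
        eta = eta - eta.max()  # guard overflow; cancels in the ratios
        w = np.exp(eta)
        r0 = np.cumsum(w[::-1])[::-1]
        r1 = np.cumsum((xo * w)[::-1])[::-1]
        r2 = np.cumsum((xo * xo * w)[::-1])[::-1]
        fi = sd.first_idx[sd.event_idx]
        s0 = r0[fi]
        m1 = r1[fi] / s0
        U += float(np.sum(xo[sd.event_idx] - m1))
        I += float(np.sum(r2[fi] / s0 - m1 * m1))
        ll += float(np.sum(eta[sd.event_idx] - np.log(s0)))
    return U, I, ll


def fit_cox(x: np.ndarray, time: np.ndarray, event: np.ndarray,
            strata: np.ndarray | None = None,
            prepared: list | None = None,
            max_iter: int = 30, tol: float = 1e-9) -> CoxFit:
    """Newton fit of a one-covariate Cox model, optionally stratified.

    ``prepared`` (from :func:`prepare_strata`) amortizes the per-stratum
    sorting across many genes screened on the same survival data.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if prepared is None:
        if strata is None:
            strata = np.zeros(n, dtype=int)
        prepared = prepare_strata(time, event, strata)
    if np.ptp(x) == 0:
        raise ValueError("covariate has zero variance")

    xs = [x[idx] for idx, _ in prepared]
    prep = [sd for _, sd in prepared]
    n_events = int(sum(sd.event_idx.size for sd in prep))

    beta = 0.0
    converged = False
    _, _, ll = _score_info(beta, xs, prep)
    for _ in range(max_iter):
        U, I, _ = _score_info(beta, xs, prep)
        if I <= 0:
            break
        step = U / I
        # step-halving on the log partial likelihood
        new_beta = beta + step
        for _ in range(20):
            _, _, new_ll = _score_info(new_beta, xs, prep)
            if new_ll >= ll - 1e-12:
                break
            new_beta = beta + (new_beta - beta) / 2.0
        if abs(new_beta - beta) < tol:
            beta = new_beta
            converged = True
            break
        beta, ll = new_beta, new_ll

    _, I, _ = _score_info(beta, xs, prep)
    if I <= 0 or not np.isfinite(beta):
        return CoxFit(beta=float("nan"), se=float("nan"), p=float("nan"),
                      n=n, n_events=n_events, converged=False)
    se = 1.0 / np.sqrt(I)
    z = beta / se
    p = 2.0 * norm.sf(abs(z))
    return CoxFit(beta=float(beta), se=float(se), p=float(p),
                  n=n, n_events=n_events, converged=converged)
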