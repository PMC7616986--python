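"""Small shared numerical helpers."""

from __future__ import annotations

import logging
from typing import Tuple

import numpy as np
from scipy.stats import gaussian_kde

logger = logging.getLogger("hrcmap")


def bimodal_threshold(values: np.ndarray) -> Tuple[float, str]:
    """Split a 1-d sample at the density valley between its two largest modes.

    A Gaussian KDE (Silverman bandwidth) is evaluated on a fine grid; local
    maxima are located and the threshold is placed at the minimum-density
    point between the two highest modes.  When the density is unimodal (or
    the sample is too small for a stable KDE) the split falls back to a
    two-component Gaussian mixture; with fewer than five points the midpoint
    of the largest gap is used.

    Returns
    -------
    threshold, method
        ``method`` is one of ``"kde_valley"``, ``"gmm"`` or ``"gap"``.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2 or np.ptp(values) == 0:
        raise ValueError("bimodal_threshold needs >=2 distinct finite values")

    if values.size < 5:
        return _largest_gap_midpoint(values), "gap"

    try:
        kde = gaussian_kde(values, bw_method="silverman")
    except np.linalg.LinAlgError:  # singular covariance (near-constant data)
        return _largest_gap_midpoint(values), "gap"
    lo, hi = values.min(), values.max()
    pad = 0.05 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, 512)
    dens = kde(grid)
    # interior local maxima
    peaks = np.where((dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:]))[0] + 1
    if peaks.size >= 2:
        top2 = peaks[np.argsort(dens[peaks])[-2:]]
        left, right = sorted(top2)
        valley = left + int(np.argmin(dens[left:right + 1]))
        return float(grid[valley]), "kde_valley"

    logger.info("bimodal_threshold: unimodal density, falling back to a "
                "two-component Gaussian mixture")
    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(n_components=2, random_state=0, n_init=3)
    gm.fit(values.reshape(-1, 1))
    means = np.sort(gm.means_.ravel())
    # decision boundary approximated on a grid between the component means
    grid = np.linspace(means[0], means[1], 256)
    post = gm.predict_proba(grid.reshape(-1, 1))
    hi_comp = int(np.argmax(gm.means_.ravel()))
    crossing = np.where(post[:, hi_comp] >= 0.5)[0]
    thr = float(grid[crossing[0]]) if crossing.size else float(means.mean())
    return thr, "gmm"


def _largest_gap_midpoint(values: np.ndarray) -> float:
    s = np.sort(values)
    gaps = np.diff(s)
    i = int(np.argmax(gaps))
    return float(0.5 * (s[i] + s[i + 1]))


def spawn_rngs(seed: int, n: int) -> list:
    """Derive ``n`` independent deterministic Generators from one seed."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]
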