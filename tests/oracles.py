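"""Independent brute-force references used to validate the fast paths.

The decoder oracle maximizes the same Poisson mixture likelihood as the
package decoder, but by exhaustive grid search over component means, a
small grid of concentrations and mixing weights, and an inner 1D Newton
solve for the gain.  It shares no code with the L-BFGS decoder beyond the
tuning-bank matrices it is given.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import special


def _gain_profile_loglik(counts, A, B, g_init):
    """Maximize sum c*log(B + G*A) - (B + G*A) over G >= 0 (concave in G)."""
    G = max(g_init, 1e-6)
    for _ in range(60):
        mu = B + G * A
        d1 = float(np.sum((counts / mu - 1.0) * A))
        d2 = float(-np.sum(counts * (A / mu) ** 2))
        step = d1 / d2
        G_new = G - step
        if not np.isfinite(G_new) or G_new <= 0:
            G_new = G / 2.0
        if abs(G_new - G) < 1e-10 * max(G, 1.0):
            G = G_new
            break
        G = G_new
    mu = B + G * A
    return float(np.sum(counts * np.log(mu) - mu)), G


def grid_decode(
    counts,
    tuning_hist,
    bin_centers_rad,
    baseline,
    k,
    mean_step_deg=4.0,
    kappa_grid=(2.0, 6.0, 18.0, 54.0),
    weight_grid=(0.2, 0.35, 0.5, 0.65, 0.8),
):
    """Exhaustive grid-search ML fit of a k-component von Mises mixture.

    Returns (log_likelihood, means_deg, best_params).  The log-likelihood
    includes the gammaln normalization so it is directly comparable with
    the package decoder's reported value.
    """
    counts = np.asarray(counts, dtype=float)
    H = bin_centers_rad.size
    means_rad = np.arange(-math.pi, math.pi, mean_step_deg * math.pi / 90.0)

    # precompute normalized component profiles for every (mean, kappa)
    profiles = {}
    for kap in kappa_grid:
        u = np.exp(kap * (np.cos(bin_centers_rad[None, :] - means_rad[:, None]) - 1))
        profiles[kap] = u / u.sum(axis=1, keepdims=True)

    colsum = float(tuning_hist.sum(axis=0).mean())
    g0 = max(float(counts.sum()) - counts.size * baseline, 1.0) / colsum

    best = (-np.inf, None, None)
    if k == 1:
        combos = [((i,), (kap,), (1.0,))
                  for i in range(means_rad.size) for kap in kappa_grid]
    elif k == 2:
        combos = [
            ((i, j), (k1, k2), (w, 1 - w))
            for i, j in itertools.combinations(range(means_rad.size), 2)
            for k1 in kappa_grid
            for k2 in kappa_grid
            for w in weight_grid
        ]
    else:
        raise ValueError("oracle supports k in {1, 2}")

    for idxs, kaps, ws in combos:
        q = np.zeros(H)
        for i, kap, w in zip(idxs, kaps, ws):
            q += w * profiles[kap][i]
        A = tuning_hist @ q
        ll, G = _gain_profile_loglik(counts, A, baseline, g0)
        if ll > best[0]:
            best = (ll, idxs, (kaps, ws, G))

    ll, idxs, params = best
    ll -= float(special.gammaln(counts + 1.0).sum())
    means_deg = [((means_rad[i] / (math.pi / 90.0)) + 90.0) % 180.0 - 90.0 for i in idxs]
    return ll, np.array(means_deg), params
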