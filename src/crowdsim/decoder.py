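"""Maximum-likelihood mixture decoding of post-integration population codes.

The decoder inverts the encoding model: it finds the mixture q(s) of 1-3
von Mises components (on the circular orientation domain) that maximizes
the Poisson likelihood of the observed spike counts,

    L = prod_i Poisson(count_i ; B + G * sum_h q_h f_hi),

where f_hi are the bank's tuning histograms, B is the expected spontaneous
contribution (the bank's base rate times the summed integration-weight
mass), and G is a free global gain that absorbs the arbitrary total mass of
a weighted-sum code.  Components are von Mises rather than linear Gaussians
so that the fit is exact on the circular domain; at the widths in play the
two are indistinguishable.

The number of components is selected with the Bayesian Information
Criterion, BIC_k = -2 log L_k + p_k ln J with p_k = 3k free parameters
(k means, k concentrations, k-1 mixing weights, one gain), treating the J
cells as the observations.  Ties within 1e-9 go to the smaller k.

Optimization is quasi-Newton (L-BFGS-B) with analytic gradients and seeded
multi-starts whose component means are initialized at the largest local
maxima of the smoothed count profile.  The fit is deterministic given a
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .config import DecoderConfig
from .encoder import (
    DEG_TO_RAD,
    PopulationCode,
    TuningBank,
    circ_to_deg,
    circular_sd_from_kappa,
    deg_to_circ,
)

__all__ = [
    "MixtureComponent",
    "DecodedPercept",
    "UninformativeCodeError",
    "decode",
    "decode_select",
    "peak_orientation",
    "mixture_density_deg",
]

_LOGKAP_BOUNDS = (math.log(0.05), math.log(2000.0))
_LOGIT_BOUNDS = (-9.0, 9.0)
_LOGG_BOUNDS = (math.log(1e-4), math.log(1e8))


class UninformativeCodeError(ValueError):
    """Raised when a population code carries no spikes to decode."""


@dataclass(frozen=True)
class MixtureComponent:
    weight: float
    mean_deg: float
    width_deg: float
    kappa: float


@dataclass
class DecodedPercept:
    """Mixture of 1-3 circular components decoded from a population code.

    Components are sorted by decreasing mixing proportion; proportions are
    positive and sum to 1, means lie in [-90, 90).
    """

    components: list[MixtureComponent]
    n_components: int
    bic_scores: dict[int, float]
    log_likelihood: float

    def __post_init__(self) -> None:
        total = sum(c.weight for c in self.components)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"mixing proportions must sum to 1, got {total}")
        if any(c.weight <= 0 for c in self.components):
            raise ValueError("mixing proportions must be > 0")


def _component_profiles(means: np.ndarray, kappas: np.ndarray, bins: np.ndarray):
    """Discretized, sum-1 von Mises profiles and their raw ingredients."""
    diff = bins[None, :] - means[:, None]
    u = np.exp(kappas[:, None] * (np.cos(diff) - 1.0))  # scale-safe, peak 1
    s = u.sum(axis=1)
    v = u / s[:, None]
    return u, s, v, diff


def _neg_loglik(x, counts, F, bins, B, k):
    """Negative Poisson log-likelihood and gradient w.r.t. packed params.

    x = [means (k, rad), log kappas (k), weight logits (k-1), log gain].
    The gammaln(count+1) constant is omitted; it cancels in optimization
    and BIC comparisons and is restored when the final value is reported.
    """
    m = x[:k]
    kap = np.exp(x[k : 2 * k])
    logits = np.append(x[2 * k : 3 * k - 1], 0.0)
    logits = logits - logits.max()
    w = np.exp(logits)
    w /= w.sum()
    G = math.exp(x[-1])

    u, s, v, diff = _component_profiles(m, kap, bins)
    q = w @ v
    A = F @ q
    mu = np.maximum(B + G * A, 1e-12)
    L = float(np.sum(counts * np.log(mu) - mu))

    e = counts / mu - 1.0
    g_h = G * (F.T @ e)  # dL/dq_h

    s_j = v @ g_h  # dL/dw_j
    grad_logits = w * (s_j - float(w @ s_j))
    # means
    du = kap[:, None] * np.sin(diff) * u
    grad_m = w * ((du @ g_h) - s_j * du.sum(axis=1)) / s
    # kappas (via log)
    dk = (np.cos(diff) - 1.0) * u
    grad_logkap = kap * w * ((dk @ g_h) - s_j * dk.sum(axis=1)) / s
    grad_logG = G * float(e @ A)

    grad = np.concatenate([grad_m, grad_logkap, grad_logits[:-1], [grad_logG]])
    return -L, -grad


def _profile_maxima(counts: np.ndarray, bank: TuningBank, B: float) -> np.ndarray:
    """Preferred orientations (rad) of circular local maxima of the smoothed
    baseline-subtracted count profile, ordered by decreasing height."""
    p = np.maximum(counts - B, 0.0)
    kernel = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
    kernel /= kernel.sum()
    n = len(p)
    sm = np.zeros(n)
    for o, kv in zip(range(-2, 3), kernel):
        sm += kv * np.roll(p, o)
    left, right = np.roll(sm, 1), np.roll(sm, -1)
    is_max = (sm >= left) & (sm >= right) & (sm > 0)
    idx = np.nonzero(is_max)[0]
    if idx.size == 0:
        idx = np.array([int(np.argmax(sm))])
    order = np.argsort(-sm[idx], kind="stable")
    # suppress maxima closer than 3 cells to a stronger one (plateau ties)
    chosen: list[int] = []
    for i in idx[order]:
        if all(min((i - j) % n, (j - i) % n) > 2 for j in chosen):
            chosen.append(int(i))
    return deg_to_circ(bank.preferred_deg[np.array(chosen)])


def decode(
    code: PopulationCode,
    bank: TuningBank | None = None,
    k: int = 1,
    cfg: DecoderConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[MixtureComponent], float]:
    """ML fit of a k-component circular mixture to one population code.

    Returns the fitted components (weights summing to 1, means in degrees)
    and the full Poisson log-likelihood of the winning fit.
    """
    bank = bank if bank is not None else code.bank
    cfg = cfg if cfg is not None else DecoderConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2, or 3")
    counts = np.asarray(code.counts, dtype=float)
    if np.all(counts == 0):
        raise UninformativeCodeError("uninformative code: all spike counts zero")

    F = bank.tuning_hist
    bins = bank.bin_centers_rad
    B = bank.config.r_base * code.weight_mass
    colsum = float(F.sum(axis=0).mean())
    G0 = max(float(counts.sum()) - bank.J * B, 1.0) / colsum

    peaks = _profile_maxima(counts, bank, B)
    base_means = np.array(
        [peaks[i % len(peaks)] for i in range(k)], dtype=float
    )
    if len(peaks) < k:  # spread duplicated inits so components can separate
        base_means += np.linspace(0, 0.5, k)

    kappa0 = 1.0 / (15.0 * DEG_TO_RAD) ** 2  # ~15 deg circular s.d.
    best: tuple[float, np.ndarray] | None = None
    n_at_best = 0
    for start in range(cfg.n_multistarts):
        m0 = base_means.copy()
        logkap0 = np.full(k, math.log(kappa0))
        if start > 0:
            m0 = m0 + rng.normal(0.0, 10.0 * DEG_TO_RAD, size=k)
            logkap0 = logkap0 + rng.normal(0.0, 0.5, size=k)
        x0 = np.concatenate(
            [m0, logkap0, np.zeros(k - 1), [math.log(max(G0, 1e-3))]]
        )
        bounds = (
            [(None, None)] * k
            + [_LOGKAP_BOUNDS] * k
            + [_LOGIT_BOUNDS] * (k - 1)
            + [_LOGG_BOUNDS]
        )
        res = optimize.minimize(
            _neg_loglik,
            x0,
            args=(counts, F, bins, B, k),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": cfg.em_max_iter, "ftol": cfg.em_tol, "gtol": 1e-7},
        )
        if best is None or res.fun < best[0] - 1e-4:
            best = (float(res.fun), res.x)
            n_at_best = 1
        elif res.fun <= best[0] + 1e-4:
            if res.fun < best[0]:
                best = (float(res.fun), res.x)
            n_at_best += 1
        # stop early once two starts confirm the same optimum
        if n_at_best >= 2:
            break

    _, x = best
    m = x[:k]
    kap = np.exp(x[k : 2 * k])
    logits = np.append(x[2 * k : 3 * k - 1], 0.0)
    w = np.exp(logits - logits.max())
    w /= w.sum()

    logL = -best[0] - float(special.gammaln(counts + 1.0).sum())
    comps = [
        MixtureComponent(
            weight=float(w[j]),
            mean_deg=float(circ_to_deg(m[j])),
            width_deg=float(circular_sd_from_kappa(kap[j]) / DEG_TO_RAD),
            kappa=float(kap[j]),
        )
        for j in range(k)
    ]
    comps.sort(key=lambda c: -c.weight)
    return comps, logL


def decode_select(
    code: PopulationCode,
    bank: TuningBank | None = None,
    cfg: DecoderConfig | None = None,
    rng: np.random.Generator | None = None,
) -> DecodedPercept:
    """Decode with the component count chosen by BIC over k = 1..3.

    After selection, components with mixing proportion below the configured
    floor are pruned and the remaining proportions renormalized.
    """
    bank = bank if bank is not None else code.bank
    cfg = cfg if cfg is not None else DecoderConfig()
    rng = rng if rng is not None else np.random.default_rng(0)

    fits: dict[int, tuple[list[MixtureComponent], float]] = {}
    bic: dict[int, float] = {}
    for k in range(1, cfg.max_components + 1):
        comps, logL = decode(code, bank, k, cfg, rng)
        fits[k] = (comps, logL)
        bic[k] = -2.0 * logL + 3 * k * math.log(bank.J)

    # parsimony tie-break: smallest k within 1e-9 of the minimum BIC
    bic_min = min(bic.values())
    best_k = min(k for k in bic if bic[k] <= bic_min + 1e-9)

    comps, logL = fits[best_k]
    kept = [c for c in comps if c.weight >= cfg.prune_floor]
    if not kept:
        kept = [comps[0]]
    total = sum(c.weight for c in kept)
    kept = [
        MixtureComponent(c.weight / total, c.mean_deg, c.width_deg, c.kappa)
        for c in kept
    ]
    return DecodedPercept(
        components=kept,
        n_components=len(kept),
        bic_scores=bic,
        log_likelihood=logL,
    )


def mixture_density_deg(percept: DecodedPercept, theta_deg: np.ndarray) -> np.ndarray:
    """Mixture density (per mapped radian) evaluated at orientations in degrees."""
    phi = deg_to_circ(theta_deg)
    dens = np.zeros_like(np.asarray(phi, dtype=float))
    for c in percept.components:
        # von Mises normalized on the circle; i0e keeps large kappa stable
        dens += (
            c.weight
            * np.exp(c.kappa * (np.cos(phi - deg_to_circ(c.mean_deg)) - 1.0))
            / (2 * math.pi * special.i0e(c.kappa))
        )
    return dens


def peak_orientation(
    percept: DecodedPercept, grid_deg: float = 0.1
) -> float:
    """Mode of the full mixture density, in degrees, on a uniform grid.

    This is the orientation reported by the simulated observer: the mode of
    the decoded density, not merely the mean of the heaviest component (the
    two differ when overlapping components merge into one hill).
    """
    grid = np.arange(-90.0, 90.0, grid_deg)
    dens = mixture_density_deg(percept, grid)
    return float(grid[int(np.argmax(dens))])
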