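"""Simulated-observer harness: trials, psychometric fits, critical spacing.

A single identification trial runs the full model: every stimulus is
encoded to a Poisson population code, the codes are integrated at the
target's location, the integrated code is decoded, and the sign of the mode
of the decoded density is compared with the sign of the target tilt.  The
target's tilt sign is randomized on each trial so that chance performance
is exactly 50%.

Thresholds come from the standard simulated-psychophysics pipeline:
proportion correct is measured at several stimulus levels (contrast, or
tilt for averaging tasks), a logistic between 0.5 and 1,

    P(c) = 0.5 + 0.5 / (1 + exp(-(c - a) / b)),

is least-squares fit, and its midpoint ``a`` is the 75%-correct threshold.
Critical spacing is the breakpoint of a clipped line — a declining segment
that plateaus at a floor — fit to thresholds versus target-flanker spacing.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize
from scipy.special import expit

from .config import ModelConfig, EncoderConfig
from .cortex import IntegrationField, integrate
from .decoder import (
    UninformativeCodeError,
    decode,
    decode_select,
    peak_orientation,
    DecodedPercept,
    MixtureComponent,
)
from .encoder import TuningBank, encode_stimulus
from .stimuli import StimulusSet

logger = logging.getLogger(__name__)

__all__ = [
    "PsychometricFit",
    "ThresholdCurve",
    "ThresholdNotBracketedError",
    "get_bank",
    "run_identification_trial",
    "decode_stimset",
    "fit_psychometric",
    "estimate_threshold",
    "fit_clipped_line",
    "threshold_elevation",
]


class ThresholdNotBracketedError(RuntimeError):
    """Raised when observed performance never crosses the 75% criterion."""


_BANK_CACHE: dict[tuple, TuningBank] = {}


def get_bank(cfg: EncoderConfig) -> TuningBank:
    """Memoized tuning bank for a given encoder configuration."""
    key = dataclasses.astuple(cfg)
    if key not in _BANK_CACHE:
        _BANK_CACHE[key] = TuningBank(cfg)
    return _BANK_CACHE[key]


def decode_stimset(
    stimset: StimulusSet,
    config: ModelConfig,
    rng: np.random.Generator,
    decode_at: tuple[float, float] | None = None,
    fixed_components: int | None = None,
) -> DecodedPercept:
    """Encode, integrate at one location, and decode a stimulus set."""
    bank = get_bank(config.encoder)
    codes = [encode_stimulus(s, bank, rng) for s in stimset]
    if decode_at is None:
        decode_at = stimset.target.location
    fld = IntegrationField.at(decode_at, config.cortex)
    merged = integrate(codes, fld, config.cortex)
    if fixed_components is None:
        return decode_select(merged, bank, config.decoder, rng)
    comps, logL = decode(merged, bank, fixed_components, config.decoder, rng)
    return DecodedPercept(
        components=comps,
        n_components=len(comps),
        bic_scores={},
        log_likelihood=logL,
    )


def run_identification_trial(
    stimset: StimulusSet,
    config: ModelConfig,
    rng: np.random.Generator,
    decode_at: tuple[float, float] | None = None,
    fixed_components: int | None = None,
    randomize_sign: bool = True,
) -> bool:
    """One 2AFC tilt-sign identification trial; returns correctness.

    The target tilt sign is flipped with probability 1/2 (seeded) so chance
    is 50%.  Decoder failures on degenerate codes are redrawn up to the
    configured cap, then scored incorrect.
    """
    if stimset.target_index is None or stimset.target.orientation == 0:
        raise ValueError("trial needs a designated target with nonzero tilt")
    if randomize_sign and rng.random() < 0.5:
        stimset = stimset.with_target_orientation(-stimset.target.orientation)
    target_sign = math.copysign(1.0, stimset.target.orientation)

    for attempt in range(config.psychophysics.max_redraws + 1):
        try:
            percept = decode_stimset(
                stimset, config, rng, decode_at, fixed_components
            )
            break
        except UninformativeCodeError:
            logger.debug("uninformative code on attempt %d; redrawing", attempt + 1)
    else:
        return False

    peak = peak_orientation(percept, config.decoder.mode_grid_deg)
    if peak == 0.0:
        return bool(rng.random() < 0.5)
    return math.copysign(1.0, peak) == target_sign


@dataclass
class PsychometricFit:
    """Logistic psychometric fit between chance (0.5) and 1.

    ``a`` is the sigmoid midpoint — exactly the 75%-correct level — and
    ``b`` its width.  ``censored`` marks fits where performance never
    crossed 75% within the probed ladder and the threshold was clamped to
    the ladder edge.
    """

    a: float
    b: float
    threshold_75: float
    trials_per_level: int
    levels: np.ndarray
    proportions: np.ndarray
    censored: bool = False

    def predict(self, level) -> np.ndarray:
        x = np.asarray(level, dtype=float)
        return 0.5 + 0.5 * expit((x - self.a) / self.b)


def _sigmoid(c, a, b):
    return 0.5 + 0.5 * expit((c - a) / b)


def fit_psychometric(
    levels: Sequence[float],
    proportions: Sequence[float],
    trials_per_level: int,
) -> PsychometricFit:
    """Least-squares logistic fit; the midpoint ``a`` is the 75% threshold."""
    levels = np.asarray(levels, dtype=float)
    proportions = np.asarray(proportions, dtype=float)
    if levels.size < 4:
        raise ValueError("need at least 4 levels")
    if np.any((proportions < 0) | (proportions > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    if proportions.max() < 0.75 or proportions.min() >= 0.75:
        raise ThresholdNotBracketedError(
            "threshold not bracketed: observed proportions do not cross 0.75"
        )
    span = levels.max() - levels.min()
    # initial midpoint: first ladder crossing of 0.75
    above = np.nonzero(proportions >= 0.75)[0]
    a0 = levels[above[0]]
    b0 = max(span / 8.0, 1e-6)
    try:
        popt, _ = optimize.curve_fit(
            _sigmoid,
            levels,
            proportions,
            p0=[a0, b0],
            bounds=([levels.min() - span, 1e-9], [levels.max() + span, 10 * span]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise ThresholdNotBracketedError(f"psychometric fit failed: {exc}") from exc
    a, b = float(popt[0]), float(popt[1])
    return PsychometricFit(a, b, a, trials_per_level, levels, proportions)


def estimate_threshold(
    stimset_factory: Callable[[float], StimulusSet],
    levels: Sequence[float],
    trials_per_level: int,
    config: ModelConfig,
    rng: np.random.Generator,
    decode_at: tuple[float, float] | None = None,
    fixed_components: int | None = None,
    on_unbracketed: str = "raise",
    randomize_sign: bool = True,
    rng_factory: Callable[[float, int], np.random.Generator] | None = None,
) -> PsychometricFit:
    """Measure proportion correct per level and fit the psychometric curve.

    ``stimset_factory`` maps a stimulus level (contrast, or tilt magnitude
    for averaging tasks) to a stimulus set.  With ``on_unbracketed='censor'``
    a ladder that never reaches (or never falls below) 75% yields a fit
    clamped to the ladder edge and flagged ``censored`` instead of raising.
    Tasks where the factory already randomizes the sign of every target
    (e.g. multi-target averaging arrays) pass ``randomize_sign=False``.

    ``rng_factory(level, trial)``, when given, supplies one generator per
    (level, trial) instead of drawing everything from ``rng``.  Conditions
    measured with the same factory share their trial noise (common random
    numbers), which leaves each threshold unbiased but strongly reduces the
    variance of threshold differences and ratios across conditions.
    """
    levels = np.asarray(levels, dtype=float)
    props = np.empty(levels.size)
    for i, level in enumerate(levels):
        n_correct = 0
        for t in range(trials_per_level):
            stimset = stimset_factory(float(level))
            trial_rng = rng if rng_factory is None else rng_factory(float(level), t)
            n_correct += run_identification_trial(
                stimset, config, trial_rng, decode_at, fixed_components,
                randomize_sign=randomize_sign,
            )
        props[i] = n_correct / trials_per_level
    try:
        return fit_psychometric(levels, props, trials_per_level)
    except ThresholdNotBracketedError:
        if on_unbracketed != "censor":
            raise
        edge = float(levels.max() if props.max() < 0.75 else levels.min())
        span = float(levels.max() - levels.min())
        logger.info("threshold censored at ladder edge %.4g", edge)
        return PsychometricFit(
            edge, span / 8.0, edge, trials_per_level, levels, props, censored=True
        )


@dataclass
class ThresholdCurve:
    """Thresholds vs spacing plus the clipped-line fit.

    T(s) = floor + max(0, slope * (s_c - s)) with slope >= 0; the breakpoint
    ``critical_spacing`` (s_c) estimates the largest spacing at which
    flankers still elevate thresholds.
    """

    spacings: np.ndarray
    thresholds: np.ndarray
    floor_threshold: float
    slope: float
    critical_spacing: float
    fit_residual: float
    no_crowding: bool = False
    unbounded: bool = False
    fits: list[PsychometricFit] = field(default_factory=list)

    def predict(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return self.floor_threshold + np.maximum(
            0.0, self.slope * (self.critical_spacing - s)
        )


def fit_clipped_line(
    spacings: Sequence[float],
    thresholds: Sequence[float],
    grid_deg: float = 0.05,
) -> ThresholdCurve:
    """Fit T(s) = floor + max(0, slope*(s_c - s)) by breakpoint grid search.

    For each candidate breakpoint on a ``grid_deg`` grid spanning the probed
    spacings, (floor, slope) has a closed-form least-squares solution; the
    candidate with minimal residual wins, ties (within 1e-6) going to the
    smallest breakpoint.  Thresholds that only rise with spacing are flagged
    ``no_crowding`` with s_c = 0.
    """
    s = np.asarray(spacings, dtype=float)
    t = np.asarray(thresholds, dtype=float)
    if s.size < 5:
        raise ValueError("need at least 5 spacings")
    if s.size != t.size:
        raise ValueError("spacings and thresholds must have equal length")
    order = np.argsort(s)
    s, t = s[order], t[order]

    lo = math.floor(s.min() / grid_deg)
    hi = math.ceil(s.max() / grid_deg)
    candidates = np.arange(lo, hi + 1) * grid_deg

    best: tuple[float, float, float, float] | None = None  # sse, sc, floor, slope
    for sc in candidates:
        x = np.maximum(0.0, sc - s)
        X = np.column_stack([np.ones_like(s), x])
        coef, *_ = np.linalg.lstsq(X, t, rcond=None)
        floor, slope = float(coef[0]), float(coef[1])
        if slope < 0:
            slope = 0.0
            floor = float(t.mean())
        elif floor < 0:  # thresholds are positive; pin the floor at zero
            floor = 0.0
            slope = max(0.0, float(x @ t / max(x @ x, 1e-12)))
        sse = float(np.sum((floor + slope * x - t) ** 2))
        if best is None or sse < best[0] - 1e-6 or (
            abs(sse - best[0]) <= 1e-6 and sc < best[1]
        ):
            best = (sse, float(sc), floor, slope)

    sse, sc, floor, slope = best
    no_crowding = slope <= 0
    if no_crowding:
        sc = 0.0
        slope = 0.0
        floor = float(t.mean())
        sse = float(np.sum((t - floor) ** 2))
    unbounded = (not no_crowding) and sc >= s.max() - grid_deg / 2
    return ThresholdCurve(
        spacings=s,
        thresholds=t,
        floor_threshold=floor,
        slope=slope,
        critical_spacing=sc,
        fit_residual=sse,
        no_crowding=no_crowding,
        unbounded=unbounded,
    )


def threshold_elevation(
    flanked: PsychometricFit, unflanked: PsychometricFit
) -> float:
    """Flanked 75%-correct threshold divided by the unflanked threshold."""
    return flanked.threshold_75 / unflanked.threshold_75
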