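"""Layer 2: retinotopic mapping and cortical-distance-weighted integration.

Visual-field locations are mapped to cortical coordinates with a monopole
log map: areal magnification M(E) = M0 / (1 + E/E2) gives a radial cortical
coordinate lambda * ln(1 + E/E2) with lambda = M0 * E2 (defaults M0 = 17.3
mm/deg, E2 = 0.75 deg — standard human V1 values).  The map is strictly
increasing and concave in eccentricity, so equal visual-field steps span
less cortex in the periphery.  That compression is the geometric source of
the foveal/peripheral crowding asymmetry: integration weights are isotropic
functions of cortical distance only, yet a peripheral flanker lies
cortically closer to the target than a foveal flanker at the same visual
spacing.

An integration field is a 2D Gaussian in cortical coordinates with separate
radial (along the eccentricity axis) and tangential (iso-eccentricity)
widths.  Integration is a plain weighted sum of layer-1 population codes —
no renormalization; the decoder's fitted gain absorbs total-mass scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import CortexConfig
from .encoder import PopulationCode

__all__ = [
    "CorticalPoint",
    "visual_to_cortex",
    "IntegrationField",
    "integration_weight",
    "integrate",
]


@dataclass(frozen=True)
class CorticalPoint:
    """Cortical coordinates: mm along the eccentricity axis and orthogonal."""

    radial_mm: float
    tangential_mm: float


def visual_to_cortex(
    location: tuple[float, float], cfg: CortexConfig
) -> CorticalPoint:
    """Map a visual-field location (degrees) to cortical coordinates (mm).

    radial = lambda * ln(1 + E/E2); tangential = polar angle (radians) *
    lambda * E / (E + E2) (arc length at the local magnification).  The
    fovea maps to (0, 0).
    """
    x, y = location
    ecc = math.hypot(x, y)
    lam = cfg.M0_mm_per_deg * cfg.E2_deg
    radial = lam * math.log1p(ecc / cfg.E2_deg)
    if ecc == 0.0:
        tangential = 0.0
    else:
        polar = math.atan2(y, x)
        tangential = polar * lam * ecc / (ecc + cfg.E2_deg)
    return CorticalPoint(radial, tangential)


@dataclass(frozen=True)
class IntegrationField:
    """2D Gaussian cortical weight profile centered on a visual location."""

    center: tuple[float, float]
    sigma_rad_mm: float
    sigma_tan_mm: float

    def __post_init__(self) -> None:
        if self.sigma_rad_mm <= 0 or self.sigma_tan_mm <= 0:
            raise ValueError("integration-field sigmas must be > 0")

    @classmethod
    def at(cls, center: tuple[float, float], cfg: CortexConfig) -> "IntegrationField":
        return cls(center, cfg.sigma_rad_mm, cfg.sigma_tan_mm)


def integration_weight(
    field: IntegrationField,
    stimulus_location: tuple[float, float],
    cfg: CortexConfig,
) -> float:
    """Gaussian weight of a stimulus within an integration field.

    w = exp(-d_rad^2 / (2 sigma_rad^2) - d_tan^2 / (2 sigma_tan^2)), where
    d_rad and d_tan are the cortical-coordinate differences between the
    field center and the stimulus.  Equals 1 at zero distance and depends on
    visual-field direction only through the retinotopic map.
    """
    a = visual_to_cortex(field.center, cfg)
    b = visual_to_cortex(stimulus_location, cfg)
    d_rad = a.radial_mm - b.radial_mm
    d_tan = a.tangential_mm - b.tangential_mm
    return math.exp(
        -(d_rad**2) / (2 * field.sigma_rad_mm**2)
        - (d_tan**2) / (2 * field.sigma_tan_mm**2)
    )


def integrate(
    codes: Sequence[PopulationCode],
    field: IntegrationField,
    cfg: CortexConfig,
) -> PopulationCode:
    """Weighted sum of population codes under an integration field.

    Output counts are sum_n w_n * counts_n (non-negative reals), located at
    the field center; ``weight_mass`` records sum_n w_n so the decoder can
    scale the expected spontaneous-rate contribution.
    """
    if not codes:
        raise ValueError("integrate needs at least one population code")
    bank = codes[0].bank
    for c in codes[1:]:
        if c.bank is not bank and c.bank != bank:
            raise ValueError("all codes must come from the same TuningBank")
    weights = np.array(
        [integration_weight(field, c.location, cfg) for c in codes]
    )
    counts = np.zeros(bank.J)
    for w, c in zip(weights, codes):
        counts += w * c.counts
    return PopulationCode(
        counts,
        field.center,
        bank,
        is_integrated=True,
        weight_mass=float(weights.sum()),
    )
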