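"""Stimulus types, generators for the standard crowding configurations, and I/O.

A stimulus is a parametric oriented element: orientation (0 deg = vertical,
positive = clockwise, reduced modulo 180 into [-90, 90)), a dimensionless
relative size, a 2D visual-field location in degrees with fixation at the
origin, and a relative contrast in (0, 1].  Stimuli are never rendered to
pixels; the model consumes them parametrically.

Generators cover the stimulus configurations used throughout the simulated
experiments: a target with radial or tangential flankers, the N-target /
(9-N)-flanker ring array used for orientation-averaging tasks, and a field
of contours embedded in orientation noise.  All generators are pure
functions of their arguments plus an explicit seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Stimulus",
    "StimulusSet",
    "normalize_orientation",
    "make_flanked_target",
    "make_parkes_array",
    "make_contour_field",
    "read_stimuli",
    "write_stimuli",
]


def normalize_orientation(theta_deg: float) -> float:
    """Reduce an orientation modulo 180 deg into [-90, 90)."""
    return float((theta_deg + 90.0) % 180.0 - 90.0)


@dataclass(frozen=True)
class Stimulus:
    """One oriented element of the visual input.

    Attributes
    ----------
    orientation : float
        Degrees in [-90, 90); 0 = vertical, positive = clockwise tilt.
    size : float
        Dimensionless relative size, > 0.
    location : tuple of float
        (x, y) visual-field position in degrees; fixation at the origin.
    contrast : float
        Relative contrast in (0, 1].
    """

    orientation: float
    size: float
    location: tuple[float, float]
    contrast: float

    def __post_init__(self) -> None:
        if not self.size > 0:
            raise ValueError(f"stimulus size must be > 0, got {self.size}")
        if not 0 < self.contrast <= 1:
            raise ValueError(f"stimulus contrast must be in (0, 1], got {self.contrast}")
        object.__setattr__(self, "orientation", normalize_orientation(self.orientation))
        object.__setattr__(self, "location",
                           (float(self.location[0]), float(self.location[1])))

    @property
    def eccentricity(self) -> float:
        """Angular distance from fixation, degrees."""
        x, y = self.location
        return math.hypot(x, y)


@dataclass
class StimulusSet:
    """Ordered collection of stimuli with an optional designated target."""

    stimuli: list[Stimulus] = field(default_factory=list)
    target_index: int | None = None

    def __post_init__(self) -> None:
        if self.target_index is not None and not (
            0 <= self.target_index < len(self.stimuli)
        ):
            raise ValueError(
                f"target_index {self.target_index} out of range for "
                f"{len(self.stimuli)} stimuli"
            )
        locs = [s.location for s in self.stimuli]
        if len(set(locs)) < len(locs):
            logger.debug("StimulusSet contains duplicate locations")

    def __len__(self) -> int:
        return len(self.stimuli)

    def __iter__(self) -> Iterator[Stimulus]:
        return iter(self.stimuli)

    def __getitem__(self, i: int) -> Stimulus:
        return self.stimuli[i]

    @property
    def target(self) -> Stimulus:
        if self.target_index is None:
            raise ValueError("StimulusSet has no designated target")
        return self.stimuli[self.target_index]

    def with_target_orientation(self, theta_deg: float) -> "StimulusSet":
        """Copy of the set with the target's orientation replaced."""
        t = self.target
        new = replace(t, orientation=theta_deg)
        stimuli = list(self.stimuli)
        stimuli[self.target_index] = new
        return StimulusSet(stimuli, self.target_index)

    def to_json(self) -> str:
        """JSON export for experiment provenance."""
        return json.dumps(
            {
                "target_index": self.target_index,
                "stimuli": [
                    {
                        "orientation_deg": s.orientation,
                        "size": s.size,
                        "x_deg": s.location[0],
                        "y_deg": s.location[1],
                        "contrast": s.contrast,
                    }
                    for s in self.stimuli
                ],
            },
            indent=2,
        )


def make_flanked_target(
    target_tilt: float,
    target_ecc: float,
    flanker_tilts: Sequence[float],
    spacing: float,
    axis: Literal["radial", "tangential"] = "radial",
    sides: Literal["both", "foveal", "peripheral"] = "both",
    target_contrast: float = 1.0,
    flanker_contrast: float = 1.0,
    size: float = 1.0,
) -> StimulusSet:
    """Target on the positive x-axis with flankers at the given spacing.

    Radial flankers sit on the fixation-target axis at eccentricities
    ``target_ecc - spacing`` (foveal) and ``target_ecc + spacing``
    (peripheral); tangential flankers are displaced perpendicular to that
    axis.  ``sides`` selects which flankers are emitted; with ``both``, the
    first flanker tilt is used on the foveal (or -y) side and the second on
    the peripheral (or +y) side.
    """
    if target_ecc <= 0:
        raise ValueError("target_ecc must be > 0")
    if spacing < 0:
        raise ValueError("spacing must be >= 0")

    if sides == "both":
        n_flank = 2
    else:
        n_flank = 1
    if len(flanker_tilts) < n_flank:
        raise ValueError(f"need {n_flank} flanker tilts for sides='{sides}'")

    if axis == "radial":
        offsets = {"foveal": (-spacing, 0.0), "peripheral": (spacing, 0.0)}
    elif axis == "tangential":
        offsets = {"foveal": (0.0, -spacing), "peripheral": (0.0, spacing)}
    else:
        raise ValueError(f"unknown axis '{axis}'")

    side_order = ["foveal", "peripheral"] if sides == "both" else [sides]
    stimuli = [
        Stimulus(target_tilt, size, (target_ecc, 0.0), target_contrast)
    ]
    for tilt, side in zip(flanker_tilts, side_order):
        dx, dy = offsets[side]
        x, y = target_ecc + dx, dy
        if axis == "radial" and side == "foveal" and x < 0:
            raise ValueError(
                f"spacing {spacing} places the foveal flanker at negative "
                f"eccentricity (target_ecc={target_ecc})"
            )
        stimuli.append(Stimulus(tilt, size, (x, y), flanker_contrast))
    return StimulusSet(stimuli, target_index=0)


def make_parkes_array(
    n_targets: int,
    n_total: int = 9,
    target_tilt: float = 4.0,
    flanker_tilt: float = 0.0,
    center_ecc: float = 2.5,
    spacing: float = 0.5,
    contrast: float = 0.5,
    size: float = 0.5,
    with_flankers: bool = True,
    rng: np.random.Generator | None = None,
) -> StimulusSet:
    """N-target / (n_total - N)-flanker ring array for averaging tasks.

    One element sits at ``(center_ecc, 0)`` and the remaining ``n_total - 1``
    are equally spaced on a circle of radius ``spacing`` around it.  The
    central element always carries ``target_tilt`` (the observer's decoded
    location is guaranteed to hold a target); the remaining ``n_targets - 1``
    target positions are drawn at random from the ring.  With
    ``with_flankers=False`` only the tilted target elements are emitted.

    The degenerate ``spacing=0`` collapses all elements onto the central
    location, which makes every integration weight exactly 1 (the ideal
    pooling regime).
    """
    if not 1 <= n_targets <= n_total:
        raise ValueError(f"need 1 <= n_targets <= n_total, got {n_targets}/{n_total}")
    if rng is None:
        rng = np.random.default_rng(0)

    center = (center_ecc, 0.0)
    ring_angles = 2 * np.pi * np.arange(n_total - 1) / max(n_total - 1, 1)
    locations = [center] + [
        (center_ecc + spacing * math.cos(a), spacing * math.sin(a))
        for a in ring_angles
    ]
    ring_target_idx = rng.choice(n_total - 1, size=n_targets - 1, replace=False)
    is_target = np.zeros(n_total, dtype=bool)
    is_target[0] = True
    is_target[1 + ring_target_idx] = True

    stimuli = []
    target_index = None
    for i, loc in enumerate(locations):
        if not is_target[i] and not with_flankers:
            continue
        tilt = target_tilt if is_target[i] else flanker_tilt
        if i == 0:
            target_index = len(stimuli)
        stimuli.append(Stimulus(tilt, size, loc, contrast))
    return StimulusSet(stimuli, target_index=target_index)


def _arc_points(
    start: np.ndarray, heading: float, curvature: float, n: int, step: float
) -> tuple[list[tuple[float, float]], list[float]]:
    """March n points along a constant-curvature arc; return points and tangents."""
    pts, tangents = [], []
    p = np.asarray(start, dtype=float)
    h = heading
    for _ in range(n):
        pts.append((float(p[0]), float(p[1])))
        tangents.append(h)
        p = p + step * np.array([math.cos(h), math.sin(h)])
        h += curvature * step
    return pts, tangents


def _tangent_to_orientation(heading_rad: float) -> float:
    """Convert a 2D direction to the element orientation convention.

    0 deg = vertical, positive = clockwise: a direction at angle ``h`` from
    the +x axis corresponds to orientation 90 - h (degrees), mod 180.
    """
    return normalize_orientation(90.0 - math.degrees(heading_rad))


def make_contour_field(
    seed: int = 0,
    contrast: float = 0.8,
    size: float = 0.8,
) -> StimulusSet:
    """Contours embedded in an orientation-noise background.

    The field contains a circle of 35 tangentially oriented segments
    (center (0, 10) deg, radius 4 deg), four open smooth-arc contours of 23
    segments each with 0.7 deg inter-segment spacing, and background
    segments with uniformly random orientations placed on a square grid of
    2.0 deg spacing out to 18 deg eccentricity.  Grid points closer than
    1 deg to any contour segment are left empty so background noise does not
    overdraw the contours.  Contrast and size of every element are 0.8.
    """
    rng = np.random.default_rng(seed)
    stimuli: list[Stimulus] = []

    # circle contour: 35 segments, tangential orientation
    cx, cy, radius = 0.0, 10.0, 4.0
    angles = 2 * np.pi * np.arange(35) / 35
    for a in angles:
        loc = (cx + radius * math.cos(a), cy + radius * math.sin(a))
        heading = a + math.pi / 2  # tangent of a CCW circle
        stimuli.append(Stimulus(_tangent_to_orientation(heading), size, loc, contrast))

    # four open contours: smooth constant-curvature arcs, seeded start/heading
    starts = [(-9.0, 2.0), (5.0, -4.0), (-4.0, -10.0), (8.0, 8.0)]
    for s0 in starts:
        heading = rng.uniform(0, 2 * math.pi)
        curvature = rng.uniform(-0.12, 0.12)  # 1/deg; gentle arcs
        pts, tangents = _arc_points(np.array(s0), heading, curvature, 23, 0.7)
        for p, h in zip(pts, tangents):
            stimuli.append(Stimulus(_tangent_to_orientation(h), size, p, contrast))

    contour_locs = np.array([s.location for s in stimuli])

    # background: random orientations on a square grid within 18 deg
    grid_r, grid_step = 18.0, 2.0
    coords = np.arange(-grid_r, grid_r + 1e-9, grid_step)
    for gx in coords:
        for gy in coords:
            if math.hypot(gx, gy) > grid_r:
                continue
            d = np.min(np.hypot(contour_locs[:, 0] - gx, contour_locs[:, 1] - gy))
            if d < 1.0:
                continue
            theta = rng.uniform(-90.0, 90.0)
            stimuli.append(Stimulus(theta, size, (gx, gy), contrast))

    return StimulusSet(stimuli, target_index=None)


_COLUMNS = ["orientation_deg", "size", "x_deg", "y_deg", "contrast"]


def write_stimuli(stimset: StimulusSet, path: str | Path) -> None:
    """Write a stimulus set to a tab-separated file."""
    lines = ["\t".join(_COLUMNS + ["is_target"])]
    for i, s in enumerate(stimset):
        flag = 1 if i == stimset.target_index else 0
        lines.append(
            f"{s.orientation:.10g}\t{s.size:.10g}\t{s.location[0]:.10g}"
            f"\t{s.location[1]:.10g}\t{s.contrast:.10g}\t{flag}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_stimuli(path: str | Path) -> StimulusSet:
    """Read a tab-separated stimulus file.

    Required columns: orientation_deg, size, x_deg, y_deg, contrast; the
    is_target flag column is optional, but at most one row may set it.
    Errors name the offending row and column.
    """
    lines = Path(path).read_text().strip().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty stimulus file")
    header = lines[0].rstrip("\n").split("\t")
    for col in _COLUMNS:
        if col not in header:
            raise ValueError(f"{path}: missing column '{col}'")
    idx = {c: header.index(c) for c in header}
    has_flag = "is_target" in header

    stimuli: list[Stimulus] = []
    target_index: int | None = None
    for row_no, line in enumerate(lines[1:], start=2):
        cells = line.rstrip("\n").split("\t")
        vals = {}
        for col in _COLUMNS:
            cell = cells[idx[col]]
            try:
                vals[col] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: row {row_no}, column '{col}': non-numeric value {cell!r}"
                ) from None
        if vals["contrast"] <= 0:
            raise ValueError(
                f"{path}: row {row_no}, column 'contrast': must be > 0, "
                f"got {vals['contrast']}"
            )
        if vals["size"] <= 0:
            raise ValueError(
                f"{path}: row {row_no}, column 'size': must be > 0, got {vals['size']}"
            )
        if has_flag:
            flag_cell = cells[idx["is_target"]]
            try:
                flag = int(float(flag_cell))
            except ValueError:
                raise ValueError(
                    f"{path}: row {row_no}, column 'is_target': non-numeric value "
                    f"{flag_cell!r}"
                ) from None
            if flag:
                if target_index is not None:
                    raise ValueError(
                        f"{path}: row {row_no}: multiple rows flagged is_target"
                    )
                target_index = len(stimuli)
        stimuli.append(
            Stimulus(
                vals["orientation_deg"],
                vals["size"],
                (vals["x_deg"], vals["y_deg"]),
                vals["contrast"],
            )
        )
    return StimulusSet(stimuli, target_index=target_index)
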