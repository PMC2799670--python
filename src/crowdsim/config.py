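"""Model configuration, validation, and seeded random-number streams.

All tunable parameters of the simulation live in one :class:`ModelConfig`
object with module-scoped sections (``encoder``, ``cortex``, ``decoder``,
``psychophysics``).  Configuration files are YAML; keys may be given either
nested under their section or flat with a dotted prefix
(``cortex.sigma_rad_mm: 1.6``).  Unknown keys are rejected so that typos
cannot silently fall back to defaults.

Randomness is never drawn from global state.  Every stochastic operation
receives a :class:`numpy.random.Generator`, and :func:`rng_stream` derives
independent, reproducible sub-streams from a master seed and a stable label.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

__all__ = [
    "EncoderConfig",
    "CortexConfig",
    "DecoderConfig",
    "PsychophysicsConfig",
    "ModelConfig",
    "ConfigError",
    "load_config",
    "rng_stream",
]


class ConfigError(ValueError):
    """Raised when a configuration file or override is invalid."""


@dataclass
class EncoderConfig:
    """Layer-1 parameters: tuning bank and input-distribution width.

    ``J`` cells with von Mises tuning of width ``sigma_tc_deg`` tile the
    orientation domain.  The input-distribution width sigma(E, alpha, c) =
    sigma0 * (1 + k_E*E) * (1 + k_c*(1/c - 1)) * (1 + k_alpha*(1/alpha - 1))
    grows with eccentricity and shrinks with contrast and size.  Gain follows
    a Naka-Rushton saturating function of the contrast-size product.
    """

    J: int = 90
    r_base: float = 5.0
    r_max: float = 90.0
    sigma_tc_deg: float = 20.0
    sigma0_deg: float = 3.0
    k_E: float = 0.12
    k_c: float = 0.3
    k_alpha: float = 0.3
    gain_n: float = 2.0
    gain_c50: float = 0.3
    n_bins: int = 180
    jitter: bool = True


@dataclass
class CortexConfig:
    """Retinotopic map and integration-field geometry.

    The visual field maps to cortex with a monopole log map of areal
    magnification M(E) = M0 / (1 + E/E2); integration fields are 2D Gaussians
    in cortical coordinates with radial/tangential widths in millimetres.
    """

    sigma_rad_mm: float = 2.5
    sigma_tan_mm: float = 1.0
    M0_mm_per_deg: float = 17.3
    E2_deg: float = 0.75


@dataclass
class DecoderConfig:
    """Maximum-likelihood mixture decoder settings."""

    max_components: int = 3
    prune_floor: float = 0.05
    em_tol: float = 1e-6
    em_max_iter: int = 500
    n_multistarts: int = 5
    mode_grid_deg: float = 0.1


@dataclass
class PsychophysicsConfig:
    """Simulated-observer defaults: trial counts and ladder/fit settings."""

    trials_per_level: int = 50
    n_levels: int = 8
    contrast_min: float = 0.02
    contrast_max: float = 1.0
    sc_grid_deg: float = 0.05
    max_redraws: int = 3


_SECTIONS = {
    "encoder": EncoderConfig,
    "cortex": CortexConfig,
    "decoder": DecoderConfig,
    "psychophysics": PsychophysicsConfig,
}


@dataclass
class ModelConfig:
    """Full parameter set for one simulation run."""

    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    cortex: CortexConfig = field(default_factory=CortexConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    psychophysics: PsychophysicsConfig = field(default_factory=PsychophysicsConfig)
    seed: int = 0
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        enc, ctx, dec, psy = self.encoder, self.cortex, self.decoder, self.psychophysics
        checks = [
            (enc.J >= 2, "encoder.J", "must be >= 2"),
            (enc.r_base >= 0, "encoder.r_base", "must be >= 0"),
            (enc.r_base < enc.r_max, "encoder.r_max", "must exceed r_base"),
            (enc.sigma_tc_deg > 0, "encoder.sigma_tc_deg", "must be > 0"),
            (enc.sigma0_deg > 0, "encoder.sigma0_deg", "must be > 0"),
            (enc.k_E >= 0, "encoder.k_E", "must be >= 0"),
            (enc.k_c >= 0, "encoder.k_c", "must be >= 0"),
            (enc.k_alpha >= 0, "encoder.k_alpha", "must be >= 0"),
            (enc.gain_n > 0, "encoder.gain_n", "must be > 0"),
            (enc.gain_c50 > 0, "encoder.gain_c50", "must be > 0"),
            (enc.n_bins >= 8, "encoder.n_bins", "must be >= 8"),
            (ctx.sigma_rad_mm > 0, "cortex.sigma_rad_mm", "must be > 0"),
            (ctx.sigma_tan_mm > 0, "cortex.sigma_tan_mm", "must be > 0"),
            (ctx.M0_mm_per_deg > 0, "cortex.M0_mm_per_deg", "must be > 0"),
            (ctx.E2_deg > 0, "cortex.E2_deg", "must be > 0"),
            (1 <= dec.max_components <= 3, "decoder.max_components", "must be in {1,2,3}"),
            (0 <= dec.prune_floor < 0.5, "decoder.prune_floor", "must be in [0, 0.5)"),
            (dec.em_tol > 0, "decoder.em_tol", "must be > 0"),
            (dec.em_max_iter >= 1, "decoder.em_max_iter", "must be >= 1"),
            (dec.n_multistarts >= 1, "decoder.n_multistarts", "must be >= 1"),
            (dec.mode_grid_deg > 0, "decoder.mode_grid_deg", "must be > 0"),
            (psy.trials_per_level >= 1, "psychophysics.trials_per_level", "must be >= 1"),
            (psy.n_levels >= 4, "psychophysics.n_levels", "must be >= 4"),
            (0 < psy.contrast_min < psy.contrast_max <= 1,
             "psychophysics.contrast_min", "need 0 < min < max <= 1"),
            (psy.sc_grid_deg > 0, "psychophysics.sc_grid_deg", "must be > 0"),
            (self.scale > 0, "scale", "must be > 0"),
        ]
        for ok, key, msg in checks:
            if not ok:
                raise ConfigError(f"config key '{key}': {msg}")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    def hash(self) -> str:
        """Stable hash of the full parameter snapshot (for run manifests)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def replace(self, **flat_overrides: Any) -> "ModelConfig":
        """Return a copy with dotted-key overrides applied.

        >>> cfg = ModelConfig().replace(**{"cortex.sigma_rad_mm": 1.6})
        >>> cfg.cortex.sigma_rad_mm
        1.6
        """
        d = self.to_dict()
        for key, value in flat_overrides.items():
            _set_key(d, key, value)
        return _from_dict(d)


def _set_key(d: dict[str, Any], key: str, value: Any) -> None:
    if "." in key:
        section, name = key.split(".", 1)
        if section not in _SECTIONS:
            raise ConfigError(f"unknown config section '{section}'")
        if name not in {f.name for f in dataclasses.fields(_SECTIONS[section])}:
            raise ConfigError(f"unknown config key '{key}'")
        d[section][name] = value
    elif key in ("seed", "scale"):
        d[key] = value
    elif key in _SECTIONS:
        if not isinstance(value, Mapping):
            raise ConfigError(f"config section '{key}' must map keys to values")
        for name, v in value.items():
            _set_key(d, f"{key}.{name}", v)
    else:
        raise ConfigError(f"unknown config key '{key}'")


def _from_dict(d: dict[str, Any]) -> ModelConfig:
    kwargs: dict[str, Any] = {}
    for section, cls in _SECTIONS.items():
        kwargs[section] = cls(**d.get(section, {}))
    return ModelConfig(seed=d.get("seed", 0), scale=d.get("scale", 1.0), **kwargs)


def load_config(path: str | Path | None = None, **overrides: Any) -> ModelConfig:
    """Load a :class:`ModelConfig` from a YAML file, merged over defaults.

    Parameters
    ----------
    path
        YAML file with nested sections and/or dotted keys.  ``None`` or an
        empty file yields the full defaults.
    overrides
        Dotted-key overrides applied after the file (CLI flags).
    """
    cfg = ModelConfig()
    data: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, Mapping):
            raise ConfigError(f"config file {path} must contain a mapping")
        data.update(loaded)
    flat = dict(data)
    flat.update(overrides)
    if flat:
        cfg = cfg.replace(**flat)
    return cfg


def rng_stream(seed: int, label: str) -> np.random.Generator:
    """Independent, reproducible generator for (seed, label).

    Sub-stream seeds are derived by hashing the label, so streams for
    different experiments/conditions/trials are statistically independent
    and insensitive to the order in which they are created.
    """
    h = hashlib.sha256(f"{int(seed)}:{label}".encode()).digest()
    child = int.from_bytes(h[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, child]))
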