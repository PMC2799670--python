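# crowdsim

Simulation of **visual crowding** — the impaired recognition of a
peripheral target when neighbors are nearby — as a by-product of spatial
feature integration in a two-layer neural population-code model.

The package is for computational-neuroscience and psychophysics
researchers who want to run simulated crowding experiments: it encodes
oriented stimuli as distributional population codes, integrates them with
cortical-distance-weighted summation, decodes percepts as circular mixture
models, and measures identification thresholds and critical spacing with a
simulated observer.

## Model in brief

Each oriented element (orientation θ, size α, location, contrast c) is
first represented as a von Mises probability distribution over orientation
whose width σ(E, α, c) grows with eccentricity and shrinks with contrast
and size. A bank of J = 90 von Mises-tuned cells (width 20°) encodes the
distribution; cell means follow

    ⟨r_i⟩ = r_base + g(c, α) · Σ_h P_h f_hi ,

with Naka–Rushton gain g and Poisson spiking. A second layer sums these
population codes with 2D Gaussian weights defined on **cortical** distance
under a monopole log retinotopic map (radial coordinate λ·ln(1 + E/E₂)).
Because the map compresses the periphery, a peripheral flanker lies
cortically closer to the target than a foveal flanker at the same visual
spacing — the geometric source of crowding's foveal-peripheral asymmetry.
A maximum-likelihood decoder fits a mixture of 1–3 von Mises components to
the integrated code (Poisson likelihood, BIC model selection); the mode of
the decoded density is the reported orientation.

With these ingredients the model reproduces the signature crowding
phenomena: critical spacing proportional to eccentricity (Bouma's law) and
invariant to stimulus manipulations, radially elongated critical regions,
compulsory averaging of similar crowded orientations, stronger crowding by
peripheral than foveal flankers, and enhancement of contour elements in
the post-integration representation.

## Worked example

Measure thresholds for a ±10°-tilted target at 6° eccentricity with two
30° flankers on the radial axis, then estimate the critical spacing:

```python
import numpy as np
from crowdsim import ModelConfig
from crowdsim.experiments import estimate_critical_spacing

config = ModelConfig(scale=0.5)          # 25 trials per contrast level
curve = estimate_critical_spacing(
    config, seed=1, label="demo", target_ecc=6.0,
)
print("thresholds:", np.round(curve.thresholds, 3))
print("critical spacing: %.2f deg  (%.2f x eccentricity)"
      % (curve.critical_spacing, curve.critical_spacing / 6.0))
```

Output:

```
thresholds: [0.905 0.485 0.239 0.169 0.106 0.105]
critical spacing: 2.90 deg  (0.48 x eccentricity)
```

Contrast thresholds fall from 0.9 at 0.9° spacing to a floor of ~0.1 by
3–4° spacing; the clipped-line breakpoint estimates the critical spacing,
here 0.48× the target eccentricity — inside the 0.3–0.6 range reported
across the crowding literature. With the narrow integration-field variant
(`cortex.sigma_rad_mm: 1.6`, `cortex.sigma_tan_mm: 1.1`) the ratio drops
to ≈ 0.3× eccentricity.

The same machinery is exposed from the shell:

```bash
crowdsim run anisotropy --seed 1 --scale 0.5 --out results/ --plot
crowdsim validate-config myconfig.yaml
```

Experiments: `critical_region`, `manipulations`, `compulsory_averaging`,
`averaging_thresholds`, `anisotropy`, `contours`, `param_robustness`.
Each run writes a manifest (full config snapshot + hash + seed) and tidy
CSV tables; everything is reproducible bit-for-bit from (config, seed).

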