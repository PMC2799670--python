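# Methods

`crowdsim` simulates visual crowding as a by-product of spatial feature
integration in a two-layer population-code model of orientation processing.
This note records the model, its parameters and defaults, the numerical
choices, and what the simulated experiments do and do not establish.

## Model

### Stimuli

A stimulus is a parametric oriented element: orientation θ ∈ [−90°, 90°)
(0° = vertical, positive = clockwise), relative size α > 0, visual-field
location (x, y) in degrees with fixation at the origin, and relative
contrast c ∈ (0, 1]. Eccentricity E = √(x²+y²) is always derived, never
stored. Stimuli are never rendered; contrast and size enter the model only
through the input-distribution width and the response gain.

### Layer 1 — distributional encoding

Each stimulus is represented as a probability distribution over
orientation, capturing the uncertainty contributed by processing before
this stage. The distribution is von Mises (circular normal) on the mapped
domain [−90°, 90°) → [−π, π). Its width is

    σ(E, α, c) = σ₀ · (1 + k_E·E) · (1 + k_c·(1/c − 1)) · (1 + k_α·(1/α − 1)),

strictly increasing in eccentricity and decreasing in contrast and size.
Defaults: σ₀ = 3°, k_E = 0.12 /deg, k_c = k_α = 0.3. The eccentricity gain
k_E was set so that an isolated ±10°-tilted target at 6° eccentricity and
full contrast is identified nearly perfectly (jittered-mean sign-flip rate
Φ(−10/σ) ≈ 2.6% at σ = 5.16°); larger values make ceiling performance
impossible regardless of the downstream model. On each simulated trial the
distribution's mean is the stimulus orientation plus Gaussian jitter of
s.d. σ (switchable off for deterministic unit checks), and the von Mises
concentration κ is set so the circular s.d. on the mapped domain equals σ
(κ inverted from a dense precomputed table of the I₁/I₀ ratio).

A bank of J = 90 cells with von Mises tuning curves (width σ_tc = 20°,
V1-simple-cell-like; preferred orientations exactly evenly spaced) encodes
the distribution. The mean response of cell i is

    ⟨r_i⟩ = r_base + g(c, α) · Σ_h P_h f_hi ,

the inner product of the input histogram P (H = 180 bins of 1°) with the
cell's discretized tuning curve f_hi (peak normalized to 1), scaled by a
Naka–Rushton gain

    g(c, α) = (r_max − r_base) · (cα)^n / ((cα)^n + c50^n),

with n = 2, c50 = 0.3, r_base = 5 spikes/s, r_max = 90 spikes/s. Spike
counts are independent Poisson draws per cell.

### Layer 2 — cortical integration

Visual locations map to cortical coordinates with a monopole log map:
areal magnification M(E) = M₀/(1 + E/E₂) with M₀ = 17.3 mm/deg and
E₂ = 0.75° (standard human V1 values) gives a radial coordinate
λ·ln(1 + E/E₂), λ = M₀·E₂ = 12.975 mm, and a tangential coordinate equal
to polar angle × λ·E/(E+E₂) (local arc length). The map is concave in E:
equal visual steps span less cortex in the periphery, which is the sole
source of every foveal/peripheral asymmetry in the model.

An integration field is a 2D Gaussian in cortical coordinates with radial
and tangential widths σ_rad and σ_tan (defaults 2.5 and 1.0 mm; the
critical-region experiment uses 1.6 and 1.1 mm, matching a subject with an
unusually small critical region ≈ 0.3× eccentricity). Integration is a
plain weighted sum of layer-1 spike counts — no renormalization — with the
summed weight mass recorded so the decoder can scale the expected
spontaneous contribution.

### Decoder

The percept at a location is the mixture q(s) of 1–3 von Mises components
maximizing the Poisson likelihood of the integrated counts,

    L = Π_i Poisson(count_i ; B + G · Σ_h q_h f_hi),

where B = r_base × (summed weight mass) and G is a free global gain
absorbing the arbitrary total mass of a weighted-sum code. Components are
von Mises rather than linear Gaussians so the fit is exact on the circular
domain (indistinguishable at the widths in play). The component count is
chosen by BIC with p_k = 3k free parameters and n = J cells as
observations; ties within 1e-9 go to the smaller k; components below a
0.05 mixing floor are pruned and weights renormalized. The reported
orientation is the mode of the full mixture density on a 0.1° grid — not
the largest component's mean — so overlapping components that merge into
one hill report an intermediate orientation (compulsory averaging).

Optimization: L-BFGS-B on (means, log κ, weight logits, log G) with
analytic gradients, 5 seeded multi-starts initialized at the largest local
maxima of the smoothed count profile, stopping early once two starts agree
within 1e-4 log-likelihood; κ is bounded to [0.05, 2000] and convergence
tolerance is 1e-6. A brute-force grid-search oracle in the test suite
confirms the optimizer attains the global optimum to better than 1e-3
log-likelihood on random one- and two-component codes.

### Simulated observer

A tilt-identification trial encodes all stimuli, integrates at the
target's location, decodes, and compares the sign of the decoded mode with
the sign of the target tilt; the tilt sign is randomized per trial so
chance is exactly 50% (in multi-target averaging arrays the shared sign of
all targets is randomized instead). Proportion correct is measured at
several stimulus levels and fit by least squares with a logistic between
chance and 1,

    P(c) = 0.5 + 0.5/(1 + exp(−(c − a)/b)),

whose midpoint a is exactly the 75% threshold. Ladders that never cross
75% are flagged censored and clamped to the ladder edge (this happens in
deeply crowded conditions where performance at full contrast plateaus near
the criterion). Critical spacing is the breakpoint of a clipped line
T(s) = floor + max(0, slope·(s_c − s)) fit to thresholds versus spacing by
grid search over the breakpoint (0.05° grid, closed-form line fit per
candidate, ties to the smaller breakpoint); thresholds that only rise with
spacing are flagged "no crowding" with s_c = 0.

## Experiment designs and problem sizes

Trial counts follow the simulated-psychophysics conventions (50 trials per
contrast level, 100 per tilt level, 1000 decode trials for the
percept-statistics experiment) and scale uniformly with the `scale`
config field; the packaged checks run at 20–100 trials per level, which
keeps every qualitative ordering stable and the headline ratios within
their Monte-Carlo tolerances.

Spacing grids are design choices (no canonical grid exists): critical-
spacing runs probe 6 spacings between 0.15× and 0.9× eccentricity; the
eccentricity-scaling runs probe 0.33×–1.0× eccentricity because thresholds
at tighter spacings are ill-conditioned — performance at full contrast
plateaus near the 75% criterion, making the fitted threshold bistable —
which adds variance without information about the breakpoint. Contrast
ladders are 6–8 log-spaced levels in [0.02, 1].

Threshold-vs-spacing curves use paired trial noise (common random
numbers): every spacing in a sweep reuses the same per-(contrast, trial)
random streams, and the eccentricity-scaling sweep additionally pairs
streams across eccentricities at matched relative designs. Pairing leaves
each threshold unbiased while sharply reducing the variance of threshold
differences, which is what the clipped-line breakpoint and the scaling law
depend on. The foveal/peripheral anisotropy sweep deliberately runs each
condition with independent streams, since its summary (the maximum
threshold-elevation ratio over a spacing sweep) is defined by
condition-by-condition measurement.

The ideal-pooling check (all integration weights 1) runs at element
contrast and size 1.0 so that tilt thresholds stay in the small-angle
regime where the 1/N prediction holds; at lower contrast the single-target
threshold leaves the linear range and circular shrinkage of the decoded
mean steepens the log-log slope. The Parkes-style replication itself keeps
the original contrast and size of 0.5.

The averaging-array geometry places one element at the central location
and the rest equally spaced on a ring of radius equal to the spacing; the
central element always carries the target tilt (the decoded location must
hold a target for the task to be defined at every N), with the remaining
target positions drawn at random. At spacing 0 all elements coincide and
every integration weight is exactly 1, the ideal pooling regime, where
tilt thresholds fall as 1/N; beyond the critical spacing only the central
element contributes and thresholds are independent of N.

The contour field embeds a 35-segment circle (center (0, 10)°, radius 4°,
tangential orientations) and four 23-segment open contours (0.7°
inter-segment spacing, constant-curvature arcs with seeded geometry) in a
background of randomly oriented elements on a 2°-spaced grid out to 18°;
background cells within 1° of a contour are left empty so noise does not
overdraw the contours. All contrasts and sizes are 0.8.

## Known limitations

- The integration-field constants and retinotopic-map constants are not
  jointly identified by any single phenomenon here; with the defaults the
  model's critical spacing is ≈ 0.5× eccentricity, at the upper half of the
  0.3–0.6 range reported across the literature. Consequently the
  foveal/peripheral threshold-elevation ratio peaks near 0.45×
  eccentricity (≈ 3° at 6.7° eccentricity) rather than at 0.3×; the peak
  value (~2.2–2.5) is in the reported range.
- Purely excitatory integration: no inhibitory or feedback connections, so
  target-flanker similarity and flanker-configuration effects are outside
  the model's reach.
- Orientation is the only feature domain; size/contrast enter only through
  the input width and gain, and no spatial receptive-field structure
  (image filtering) is modeled.
- The simulated observer has no lapse rate, bias terms, or adaptive
  staircases; thresholds in deeply crowded conditions are censored at the
  maximum physical contrast rather than extrapolated.
- Synthetic stimuli are parametric idealizations; nothing here constrains
  real V1/V4 physiology beyond the qualitative geometry of the
  retinotopic map.
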