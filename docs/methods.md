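# Methods

## Coordinate and angle conventions

Screen coordinates are x-rightward, y-upward; directions are measured
in degrees **clockwise from vertical-up**, so direction θ maps to the
unit vector (sin θ, cos θ). Stripe orientations live on [0, 180). The
drift axis of a carrier is orthogonal to its stripes (orientation
+ 90°) and is canonicalized to the half-plane with positive x (ties
toward positive y): a grating drifting at +r along n̂ is physically
identical to one drifting at −r along −n̂, and fixing n̂ makes signed
rates reproducible and manifests comparable across runs.

## Stimulus synthesis

Every element is a stationary Gaussian envelope over one (grating) or
two orthogonal (plaid) drifting sinusoidal carriers. The signed drift
rate of each carrier is the dot product n̂·v of its canonical drift
axis with the parent object's velocity v. This makes the element array
exactly consistent with a single rigid translation: the IOC solution
of the constraint set {v·n̂ᵢ = rᵢ} is v itself, to machine precision.
Plaids split the element contrast equally between their two
components, so a 0.40-contrast plaid has two 0.20 components.

Defaults (units as noted): target ring of 28 elements at radius 4°;
backgrounds of 40 elements scattered uniformly over 20° × 20° (no
minimum separation, and elements may fall inside the target ring), or
rings of 40 at 5.6° / 16 at 2.4°; envelope SD 8 arcmin; carrier 3 c/°
("high" regime 6 c/°); Michelson contrast 0.40; object speeds 6 deg/s;
500 ms at 100 Hz (50 frames). Element orientations are redrawn
uniformly on [0, 180) per element per trial; in the
cardinal/intercardinal regime background orientations are drawn from
{0°, 90°} and target orientations from {45°, 135°}, giving a fixed 45°
minimum orientation difference between the two objects.

Rendering: luminance = 0.5·(1 + Σ contrast·envelope·carrier), with
envelopes truncated at ±3 SD and carrier phase advancing by
2π·sf·rate·Δt per frame. Overlapping elements sum; excursions outside
[0, 1] are clipped with a warning (overlap handling is a pragmatic
choice — the layouts of interest rarely overlap). Initial carrier
phases are randomized per element by default. No gamma correction or
display calibration is modelled. Contrast equality across elements is
exact by construction; the perceptual contrast-matching that a human
study needs at different eccentricities has no counterpart for a
synthetic observer.

Measurement helpers used for verification: Michelson contrast is taken
over the full rendered movie — a drifting carrier sweeps every phase
through the envelope peak, so (Lmax−Lmin)/(Lmax+Lmin) over the
spatiotemporal stack recovers the nominal element contrast exactly
(a single static frame cannot: the nearest carrier trough is
attenuated by the envelope, which at 8′ SD and 3 c/° caps a one-frame
measurement near 0.26). Carrier frequency is the radial location of
the non-DC 2-D spectrum peak, refined by zero-padding plus parabolic
log-amplitude interpolation (exact for a Gaussian-shaped spectrum;
residual error ≈ 1% from envelope truncation ripple). Envelope SD is
recovered from a quadrature pair of renders, whose analytic amplitude
equals contrast·envelope, by regressing log-amplitude on squared
radius over well-supported pixels.

## Integration

`ioc_solve` computes the least-squares velocity minimizing
Σ(v·n̂ᵢ − rᵢ)², solved via SVD-checked least squares rather than
pairwise line intersections so that overdetermined and noisy sets are
handled uniformly. Fewer than two linearly independent axes raises an
underdetermined error; a reciprocal condition number below 1e−8 warns
of ill-conditioning. Elements are weighted uniformly — how the visual
system weights elements during integration is unknown, and uniform
weighting is the natural default. `vector_average` is the plain mean,
the integration rule appropriate to unambiguous 2-D signals.

## Observer

The synthetic observer applies p = t − βb to the integrated global
motions and judges clockwise/anticlockwise of vertical. Three nuisance
processes:

- **bias** (deg): a constant error in perceived vertical. It rotates
  the judged target direction *upstream* of the background
  subtraction, i.e. the decision variable is
  direction(t(θ_t + bias) − βb) + noise. With this placement the
  psychometric function crosses 0.5 exactly at the closed-form PSE
  arcsin(β·(s_b/s_t)·sin θ_b) − bias for every bias, which is also the
  curve the model fit assumes; placing the bias downstream of the
  subtraction instead would rescale it by the local angular
  sensitivity (≈ 1 − β at θ_b = 0) and make "offset" in the fit
  systematically under-recover the generating bias.
- **noise_sd** (deg): Gaussian angular noise on the perceived
  direction. Placing noise on direction (rather than on the velocity
  vector) matches the task — a direction judgment — and yields an
  approximately cumulative-Gaussian psychometric function. Human noise
  magnitude is unknown; 5° is the synthetic default and produces
  session-to-session PSE scatter of roughly ±1°.
- **lapse**: probability of a stimulus-independent coin flip
  (default 0.02 in simulations).

A fully cancelled percept (p = 0, e.g. t = b with β = 1) has no
direction and triggers a random response.

The observer deliberately ignores element-level detail — spatial
frequency, orientation content, 1D vs 2D elements, layout — encoding
the conclusion that induced motion operates on the integrated global
motions. Condition manipulations in the simulated designs therefore
differ only by sampling noise, *by construction*: the pipeline-level
null results are a consistency check on the machinery, not evidence
about vision.

## Psi adaptive procedure

Psychometric model: P(clockwise | θ) = λ/2 + (1 − λ)·Φ((θ − μ)/σ) with
fixed lapse λ = 0.02 split across both responses. Grids: μ ∈ [−40°,
40°] in 1° steps (81 levels — spans the largest plausible repulsions
with margin), σ ∈ [0.5°, 20°] log-spaced (20 levels); the candidate
stimulus set equals the μ grid; uniform prior.

Each trial presents the candidate minimizing the expected posterior
entropy over the two possible responses. This is computed as mutual-
information maximization — H(marginal response probability) minus the
posterior-weighted conditional response entropy — which is
algebraically identical but lets the conditional-entropy table be
precomputed once, reducing each selection to two matrix-vector
products (~0.5 ms at the default grid sizes). Ties resolve to the
lowest candidate index so that identical seeds replay identical
sessions. The posterior is accumulated in log space and renormalized
every trial; a zero-total-likelihood update raises rather than
silently degenerating. Estimates are posterior means of μ and σ.

Sessions run 75 trials; each condition is run twice, with sessions
randomly interleaved at the session (not trial) level. Over 100
replications at the default observer (β = 0.5, noise 5°, lapse 0.02,
θ_b = 90°), the median |μ̂ − PSE| is well under 1.5°.

## Experiment simulation

`run_session` couples Psi to the observer; per trial the full stimulus
spec for the session's named condition is generated (and its element
counts logged), exercising the synthesis path end to end, while the
judgment itself consumes only (θ_t, θ_b, speeds). Design 1 crosses
field/ring layouts with background directions {0, 15, 30, 60, 90}°;
designs 1-part-2, 2 and 4 fix the background at 30° (far enough from
vertical for a reliable deviation) and cross ring position with
spatial frequency or element kind; design 3 compares uniform-random
with cardinal/intercardinal orientation regimes. Additive
between-observer normalization (new = group baseline mean +
[old − individual baseline]) is provided for multi-observer tables; it
leaves baseline group means unchanged and removes between-observer
variance from them. Inferential statistics on simulated groups are out
of scope; the runners return tidy DataFrames for external analysis.

## Model fitting

`FlowParsingRegression` fits PSE(θ_b) = arcsin(β·r·sin θ_b) − offset
(r = s_b/s_t) by bounded nonlinear least squares (trust-region
reflective), multi-started over β ∈ {0.05, 0.15, …, 0.95} with β
constrained to [0, 1/r] so the arcsine stays in domain for all
directions. The scalar reduction of the vector model is fitted because
the experiments measure only perceived-vertical crossings. R² is
1 − SS_res/SS_tot, reported as NaN with a degeneracy flag for
zero-variance curves rather than 0. A constant added to every PSE is
absorbed entirely by the offset. Noiseless synthetic curves are
recovered to ~1e−7 in β; closed-loop curves (5 directions × 2
sessions, noise 5°) recover β with median error well below 0.05 and
offset within 1° across 50 replicates for β ∈ {0.1, 0.3, 0.5}.

## Problem sizes and determinism

All randomness flows through one explicitly passed
`numpy.random.Generator`; identical seeds give bit-identical trial
logs, PSE tables and stimuli. The test suite runs the simulation
checks at the study's native sizes (75-trial sessions, two sessions
per condition, 5 background directions; 100 convergence replications;
50 fit-recovery replicates per gain, run without per-trial stimulus
construction since the judgment path does not consume it). Rendering
checks use single elements on windows of a few envelope SDs at 64–128
px/deg rather than full 20° scenes.

## Known limitations

- The synthetic observer has a single, condition-independent gain; it
  cannot exhibit (and is not meant to test for) low-level interactions
  that a condition-dependent mechanism would produce.
- Noise locus and magnitude are free synthetic parameters, not
  measurements; quantitative session dynamics (stimulus sequences,
  posterior trajectories) are internal to this package's Psi defaults.
- 3-D flow parsing with depth cues, speed misperception at low
  contrast, and biologically detailed motion-energy front ends are out
  of scope; integration operates on symbolic constraints, not on the
  rendered frames.
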