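# flowparse

Simulation toolkit for **induced motion** (the Duncker illusion) in
*global-Gabor* displays, built around the flow-parsing account of the
effect.

When a target moves over a moving background, its perceived direction
is repelled away from the background direction. The flow-parsing
hypothesis explains this as partial subtraction of the background
motion — treated as optic flow due to self-motion — before the target
is judged:

```
p = t − β·b
```

where **t** and **b** are the target and background velocity vectors,
**p** is the perceived target velocity, and β ∈ [0, 1] is the
flow-parsing gain (1 = complete subtraction). For a direction-judgment
task the model predicts that the target direction judged *vertical*
(the point of subjective equality, PSE) deviates from true vertical by

```
PSE(θ_b) = arcsin(β · (s_b/s_t) · sin θ_b) − offset
```

with the repulsion maximal when the background moves orthogonally to
the perceived target direction (θ_b = 90°).

The package provides, end to end:

- **`flowparse.stimulus`** — global-Gabor / global-plaid synthesis.
  Stationary Gaussian envelopes (SD 8′) with drifting sinusoidal
  carriers (3 or 6 c/°, Michelson contrast 0.40); each carrier's signed
  drift rate is the projection of its object's velocity onto the
  carrier's drift axis, so the array is exactly consistent with one
  rigid global motion. Ring and random-field layouts, rendering to
  luminance movies, element-manifest export.
- **`flowparse.integration`** — local-to-global integration: a
  least-squares intersection-of-constraints (IOC) solver for 1-D
  (grating) signals and vector averaging for 2-D (plaid) signals.
- **`flowparse.observer`** — a synthetic observer implementing
  `p = t − βb` with angular decision noise, a constant
  perceived-vertical bias, and lapses, emitting binary
  clockwise/anticlockwise judgments.
- **`flowparse.psi`** — the Psi adaptive Bayesian procedure: a
  posterior over psychometric (PSE, slope) parameters, with each
  trial's target direction chosen to minimize expected posterior
  entropy.
- **`flowparse.experiment`** — closed-loop simulation of four designs
  (field vs. ring backgrounds over five background directions;
  spatial-frequency, orientation-content, and 1D/2D element-type
  manipulations), 75 trials per session, two sessions per condition.
- **`flowparse.modelfit`** — `FlowParsingRegression`, a scikit-learn
  style estimator fitting (β, offset) to PSE-versus-background-direction
  curves by bounded multi-start nonlinear least squares.

## Worked example

Simulate the field/ring design for a synthetic observer with gain
β = 0.5 and 5° decision noise, then fit the model to the resulting PSE
curve:

```bash
simulate --experiment 1 --seed 11 --out results/exp1
fitmodel results/exp1/pse_sessions.csv
```

```
beta = 0.495  offset = 0.10 deg  R^2 = 0.9985  (n = 20)
```

The fitted gain recovers the observer's generating β = 0.5 to within
0.005 and the offset its zero vertical bias; R² ≈ 1 because, with only
sampling noise from 75-trial adaptive sessions, the arcsin curve
explains nearly all variance across the 2 layouts × 5 background
directions × 2 sessions. The same pipeline is available in Python:

```python
import numpy as np
from flowparse import ObserverParams, run_experiment1, fit_flow_parsing

observer = ObserverParams(beta=0.5, noise_sd=5.0, lapse=0.02)
curve = run_experiment1(observer, np.random.default_rng(11))
print(fit_flow_parsing(curve[curve.condition == "exp1-field"]))
```

Single stimuli can be generated (and rendered to a GIF) with
`stimgen --condition exp1-field --background-direction 30 --seed 7
--out stim/ --render`.

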