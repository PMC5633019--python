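# avinet — developmental audio-visual integration

`avinet` simulates how a Bayesian-like audio-visual localiser can
*develop* from the statistics of sensory experience, for computational
neuroscientists studying multisensory integration and cue combination.
Two recurrent firing-rate layers of 180 neurons each (auditory and
visual) code azimuth on a circular 180-deg axis.  Neurons receive the
inner product of the stimulus with their receptive-field (RF)
synapses, Mexican-hat lateral input, and cross-modal input from the
other layer; rates follow first-order dynamics toward a sigmoid of the
summed drive.  Both RF and cross-modal synapses are trained by Hebbian
potentiation with an activity-gated forgetting term, whose fixed point
is the average presented input:

- RF widths shrink to the width of the stimuli (σ_V grows from 4 deg
  at the fovea to ~12 deg at the periphery following retinal acuity;
  σ_A = 20 deg everywhere) — the **likelihood** becomes encoded in the
  RFs;
- visual preferred positions ρ_k (0.2-thresholded circular RF
  barycenters) crowd toward the fovea, mirroring the Gaussian
  position prior p(θ_V) ~ N(90°, 30°) — the **unisensory prior**
  becomes encoded in the map density;
- cross-modal synapses grow only where the two layers fire together,
  under a pairing prior p(θ_A | θ_V) concentrated within λ_AV = 1 deg
  — the **co-occurrence prior** becomes encoded in a diagonal synaptic
  band.

Decoded positions are activity-weighted circular barycenters of the
preferred positions (a population-vector readout).  A reference
estimator computes the exact maximum a posteriori solution,

θ̂ = argmax_{θ_A, θ_V} [ log p(I_A | θ_A) + log p(I_V | θ_V)
                         + log p(θ_A, θ_V) ],

by exhaustive search on the 1-deg grid, with Gaussian likelihoods over
the 180 noisy samples of each stimulus profile.  After training the
network reproduces unisensory foveal precision, the foveal pull of
visual estimates, cross-modal variance reduction, and the
ventriloquism effect (auditory capture by vision that grows with
disparity up to ~20-25 deg, vanishes at large disparity, and weakens
with eccentricity).

## Worked example

```python
import numpy as np
from avinet import (EnvironmentParams, NetworkParams, LearningParams,
                    TrainingSchedule, init_weights, train_network,
                    reduced_schedule, make_stimulus, steady_state_response,
                    preferred_positions, population_estimate)

env, net, learn = EnvironmentParams(), NetworkParams(), LearningParams()
schedule, learn = reduced_schedule(TrainingSchedule(), learn, factor=5)
rng = np.random.default_rng(1)

trained = train_network(init_weights(), schedule, env, net, learn, rng).weights
prefs = preferred_positions(trained)
print(f"visual neuron 50 now prefers {prefs.rho_v[49]:.1f} deg")

# decode one noisy visual stimulus at 20 deg left of the fovea
stim = make_stimulus("V", 70.0, env, noise_frac=0.5, rng=rng)
state = steady_state_response(None, stim, trained, net)
est = population_estimate(state, prefs)
print(f"true 70.0 deg -> decoded {est.theta_hat_v:.1f} deg")
```

```
visual neuron 50 now prefers 64.5 deg
true 70.0 deg -> decoded 70.9 deg
```

The first line shows the prior-driven re-mapping: a neuron that
started with its RF at 50 deg has migrated ~15 deg toward the fovea
because visual stimuli are denser there.  The second shows the decoder
recovering a noisy stimulus position to within a degree at moderate
eccentricity.

A command-line interface wraps the same library:

```
avinet train --seed 1 --reduce 5 --out weights.npz --log train_log.csv
avinet sweep unisensory --weights weights.npz --seed 2 --out uni.csv
avinet sweep ventriloquism --weights weights.npz --seed 3 \
       --estimators network --out vent.csv
avinet decode --weights weights.npz --seed 4 --condition uniV \
       --positions 70,90,110 --out estimates.csv
```

`sweep` tables report, per (condition, position, disparity, noise)
cell, the circular mean signed error (bias), its SD, and the number of
valid trials, for the network and/or the MAP estimator.

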