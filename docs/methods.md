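# Methods

## The model in brief

`avinet` implements a developmental model of audio-visual spatial
integration.  Two chains of 180 firing-rate neurons (auditory, visual)
code azimuth on a circular 180-deg axis (positions 1 and 180 are
neighbours, so all positions are statistically equivalent before
learning and every asymmetry that emerges is attributable to the
stimulus statistics).  Each neuron receives

1. a feedforward drive — the inner product of the external stimulus
   profile with its receptive-field (RF) synapses,
2. lateral drive through a fixed Mexican-hat kernel (short-range
   excitation, long-range inhibition) within its layer, and
3. cross-modal drive from the other layer through learned synapses.

Rates follow first-order leaky dynamics toward a logistic function of
the summed drive, with saturation normalised to 1.  Only steady states
are used: for decoding, and as the activity on which plasticity acts.

Both synapse families learn by Hebbian potentiation with an
activity-gated forgetting term.  The fixed point of the RF rule is the
*average stimulus seen while the neuron fires*, so RFs come to encode
the likelihood of the input (their width tracks stimulus width, hence
visual acuity at each eccentricity); the *position* of each RF
barycenter tracks where stimuli occur, so the density of preferred
positions encodes the unisensory prior (visual preferred positions
crowd toward the fovea).  Cross-modal synapses grow only under
co-activation and decay when the target fires alone, so they encode
the audio-visual co-occurrence prior: a diagonal band linking neurons
with matching preferred positions, stronger onto foveal auditory
neurons (where visual stimuli are dense) and onto peripheral visual
neurons (where isolated visual stimuli are rare).

The reference estimator is an exhaustive maximum-a-posteriori search
on the 1-deg grid: Gaussian log-likelihoods of the 180 observed
samples under the known generative model, plus the exact log-priors,
maximised over the 180 (unisensory) or 180x180 (cross-modal) candidate
positions.

## Generative model of the environment

A stimulus of modality S centred at theta is a circular Gaussian
activity profile with area `strength` and width `sigma`, plus i.i.d.
Gaussian white noise whose SD is a stated fraction of the noiseless
peak (50% during training; 33/50/66% in testing).  The noise is drawn
once per trial (the stimulus, not the dynamics, is noisy) and negative
excursions are kept: the Gaussian-likelihood decoder assumes unbounded
noise.

Auditory inputs have constant width sigma_A = 20 deg.  Visual width
follows acuity: sigma_V(e) = 4 + (epsilon/360) (D(e) - D(0)) where
D(e) is the printed cubic for the dendritic-field diameter of
parvocellular cells (arcmin) and e is eccentricity from the fovea at
90 deg.  Two calibrations of epsilon are provided, since only the
endpoints (4 deg at the fovea, "about 12 deg" at maximum eccentricity)
are pinned: the default pins sigma_V(90) = 12 (epsilon = 125); an
alternative pins the *maximum* of sigma_V at 12 (epsilon = 79).  The
cubic is non-monotone (it peaks near e = 68 deg, where the default
calibration yields sigma_V of about 16.7 deg); we evaluate it as
printed over the whole range and take |e| for positions left of the
fovea.  Visual strength grows sub-proportionally with sigma_V
(attenuation alpha = 0.3 in (0,1), a design choice).

Positions are drawn from: a Gaussian prior at the fovea (SD 30 deg,
truncated to the axis by rejection; about 0.3% of draws are redrawn)
for unisensory visual trials; a uniform distribution over the 180 grid
positions for unisensory auditory trials; and, for cross-modal pairs,
an even mixture of visual-led and auditory-led factorisations whose
conditional is a circular Gaussian of SD lambda_AV = 1 deg mixed with
a small uniform component beta = 0.01 (the pair is almost always
caused by one source).

Absolute stimulus strengths are not identifiable from the published
description beyond two constraints — each unisensory input must drive
its layer close to saturation, and the wide auditory input needs more
area than the foveal visual one to survive lateral competition.  The
defaults strength_v0 = 10, strength_a = 22 were calibrated to those
constraints against the untrained network and the mature
(template-RF) network.

## Numerical and architectural choices

*Dynamics constants.*  tau = 3 ms, explicit Euler with dt = 0.5 ms,
steady state declared when the largest per-step rate change falls
below 1e-4 (horizon 200 ms; non-converged trials are counted and
reported, never silently dropped).  Halving dt changes steady-state
rates by < 1e-3.  Euler is sufficient because the dynamics are
contractive near the fixed point and only the fixed point is consumed.

*Sigmoid.*  Center 5.5, slope 1.4: the rest state (zero drive) sits at
4e-4 (well under the 0.01 silence criterion) and calibrated stimuli
saturate the bubble above 0.9.

*Lateral kernel.*  Difference of circular Gaussians with excitation
(strength 1.2, SD 2.5 deg) and broad, near-global inhibition
(strength 0.4, SD 60 deg), self-connection included.  The broad inhibitory pool
is a deliberate choice: with a surround of only 8-12 deg the wide
auditory activity profile can sustain several simultaneous bubbles,
and at 50% noise spurious remote bubbles occasionally ignite, which
multiplies decoder variance several-fold.  A near-global pool makes
the competition winner-take-all at the scale of the whole axis — one
contiguous bubble, anchored at the stimulus, at every width we use —
while keeping the kernel a genuine Mexican hat (excitatory at zero
distance, net-inhibitory surround, zero crossing near 4 deg).

*Learning.*  The schedule is 100 epochs of a 2:2:1 mix (360 visual,
360 auditory, 180 cross-modal trials per epoch; 90,000 trials; seeded
shuffle within each epoch).  gamma_rf = gamma_cm = 0.01 per trial:
large enough that every receptive field stabilises within the
schedule, small enough to keep the residual fixed-point noise of the
maps (which grows as sqrt(gamma)) from dominating decoder statistics.
Plasticity acts once per trial at the steady state.
Both rules gate on a minimum post-synaptic rate of 0.1; the
cross-modal rule gates its presynaptic factor by the same threshold so
that sub-threshold echoes (rates of order 1e-4 leaking through the
sigmoid) neither build synapses in purely unisensory epochs nor erode
trained ones.  The cross-modal cap w_max = 0.35 is calibrated so that
cross-modal drive alone stays below the ignition threshold of the
receiving layer (no bubble without a matching stimulus) yet biases a
concurrent noisy stimulus — the regime in which the ventriloquism
effect is graded and vanishes at large disparity.  Raising the cap
much beyond this lets the early, still-broad bubbles co-activate both
layers, which saturates the cross-modal matrix and destroys the
receptive-field maps (we verified this failure mode directly).

*Reduced training.*  Desk-scale runs divide the number of epochs by a
factor and multiply both learning rates by the same factor, keeping
the per-epoch mix and the total learning drive.  The acceptance script
uses factor 2 (50 epochs) for the main network and factor 5 for the
enriched-mix retraining; the test suite uses factors 5 and 10.  The price of
reduction is map roughness: each RF averages fewer noisy trials, so
preferred-position maps acquire degree-scale waviness that adds to
decoder variance and local bias.  Numbers quoted at desk scale are
therefore expected to sit slightly above the full-schedule variance.

*Decoders.*  Preferred positions are the circular barycenter of the
RF row above the 0.2 threshold (neurons never exceeding it have no
defined preference and are excluded).  Population estimates are the
circular barycenter of the layer's rates located at the neurons'
preferred positions; a layer with total usable activity below 0.05 is
flagged invalid and the trial excluded from summaries.  The circular
barycenter computes the doubling-angle resultant to find a wrap-safe
reference, unwraps positions around it, and takes the plain weighted
mean — exactly the arithmetic barycenter whenever the mass lies within
a 90-deg arc, and well-defined across the border.

*MAP estimator.*  Grid resolution 1 deg (the neuron spacing); the
180x180 joint search is exact, so no optimiser is involved.  Exact
ties (which essentially never occur with noisy inputs) are broken
toward the grid centre, then the lowest index.  Likelihood templates
use the same epsilon/alpha calibration as the simulator, so network
and estimator face the identical generative model.  For unisensory
trials the other modality's likelihood is dropped and the
corresponding marginal prior used.  Priors are normalised on the grid
(the joint cross-modal prior sums to 1 within 1e-6).

## Experiment conventions

Summaries report circular-aware signed errors (estimate minus true
position, mapped to (-90, 90]) per cell, their mean (bias) and SD over
100 trials per cell, and the number of valid trials.  Auditory and
cross-modal cells are summarised over the 40-140 deg window and visual
unisensory cells over 30-150 deg; outside those windows the visual
estimate variance grows too large to be informative, mirroring how the
periphery is excluded from the published summaries.  In the
ventriloquism sweep a positive disparity places the auditory stimulus
to the left of the visual one (theta_a = theta_v - disparity), and the
attraction of the auditory estimate toward the visual stimulus then
appears as a positive auditory bias.

The acceptance script (`scripts/acceptance.py`) runs, at desk scale:
the reduced training; 100-trial unisensory foveal cells at 33/50/66%
noise; a unisensory visual bias sweep and a coincident cross-modal
sweep at 50% noise; the ventriloquism sweep (visual positions 40-140
deg in steps of 10, disparities -40..+40 in steps of 5); and a
retraining with the cross-modal share raised to 35% of trials followed
by the same ventriloquism sweep.  Every random stream derives from the
single `--seed` argument.

## What the synthetic environment does and does not capture

The generator *is* the study's environment — there is no external
data.  It reproduces: eccentricity-dependent visual acuity and
strength, the foveal concentration of visual experience, uniform
auditory experience, near-coincident audio-visual pairing, and
stationary white stimulus noise.  It does not model interaural cues or
any auditory periphery (the auditory "layer" is an abstract spatial
map, which real primary auditory cortex is not), non-Gaussian or
rate-dependent noise, 2-D retinotopy, eye movements, or the peripheral
auditory localisation bias reported in some behavioural studies — the
model is known not to reproduce that finding.  Passing tests therefore
certify the internal consistency of the model and its agreement with
the published simulation outcomes, not fidelity to any behavioural
dataset.

## Known limitations

- The sigmoid, Mexican-hat, and learning constants have no canonical
  values: they are calibrated to the functional constraints described
  above (silence at rest, saturation under calibrated stimuli, single
  anchored bubbles, subthreshold-but-biasing cross-modal drive) and
  every one is exposed in the config.
- Reduced-epoch training trades map smoothness for time (see above);
  sign patterns of small biases at single positions can fluctuate at
  desk scale even when pooled statistics are stable.
- With the exact coincidence prior (beta near 0, lambda_AV = 1 deg) the
  MAP estimator abandons coincidence abruptly once the likelihood cost
  exceeds the prior penalty, so its ventriloquism curve rises and
  collapses over a narrower disparity range than the network's; the
  network-vs-MAP comparison flags the visual cells at large disparity
  or eccentricity where the two are known to disagree.
- The cubic acuity polynomial is used outside its comfortable range
  (beyond ~70 deg eccentricity it turns over); both epsilon
  calibrations are provided for exactly this reason.
- The published maxima of the *visual* bias profiles (a few degrees in
  unisensory and coincident conditions, sub-degree pooled visual
  attraction during ventriloquism) are not reproduced quantitatively.
  Two effects conspire: under this generative calibration the
  positional Fisher information at moderate eccentricity caps the
  systematic prior-induced pull near one degree, while desk-scale map
  waviness lets the coupled layers settle a few degrees off at one or
  two azimuths, inflating any maximum-over-positions summary.  The
  pooled auditory ventriloquism curve — rise to a peak near 15-25 deg
  of disparity, decay to zero at 40 deg, stronger effect under
  cross-modal-enriched rearing — is reproduced robustly.
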