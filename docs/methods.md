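# Methods

`multisense` implements a latent-variable density-estimation account of
multisensory integration: noisy population codes for hand position are fed
to a two-layer energy-based model whose hidden layer, trained only to model
the joint distribution of its inputs, ends up encoding the full Bayesian
posterior over the stimulus.  This note records the model, the choices made
where the design was open, and what the bundled experiments do and do not
show.

## World model: probabilistic population codes

A trial draws a stimulus and per-population gains, then emits spikes.

* **Arm geometry.** A planar two-link arm with link lengths 12 cm (upper
  arm) and 20 cm (forearm); shoulder angle in [0, π/2], elbow in
  [π/3, 5π/6] rad.  Joint angles θ and fingertip position x = f(θ) are two
  coordinate systems for the same stimulus; f is injective on the joint box
  (elbow bounded away from full extension) and its Jacobian J is available
  in closed form.  The joint ranges are package defaults chosen so that the
  single-population posterior variances land in the low-mm² range expected
  of visual/proprioceptive localization (see *Population geometry* below);
  they are fully configurable.
* **Populations.** Each modality is a regular grid of neurons with
  isotropic Gaussian tuning curves and independent Poisson spike counts:
  rate_i = g · exp(−‖s − s_i‖²/2σ_tc²).  The standard network uses two
  30×30 grids: proprioception tuned to θ, vision tuned to x over the
  bounding box of the reachable workspace.  Tuning width: the full width at
  half maximum spans 1/6 of the (geometric-mean) response-area extent, so
  σ_tc = extent/(6·2√(2 ln 2)).  A margin of 4σ_tc of extra preferred
  locations surrounds the response area so stimuli at its edge still evoke
  an untruncated profile.
* **Gains.** The per-trial gain g (maximum mean spike count) is uniform on
  [12, 18] spikes independently per population.  The gain sets the cue's
  reliability: a single population's posterior over the stimulus is
  approximately Gaussian with covariance σ_tc²/n per dimension, where n is
  the realized total spike count (∝ g).
* **Population geometry.** With the defaults above, the per-dimension
  posterior variances of the two populations, expressed in Cartesian mm²,
  average roughly 2–6 mm² across the gain range (variance ≈ Δ²/(2πg) with
  Δ the grid spacing), comparable to psychophysical localization variances.
  The acceptance suite asserts the 9 mm² upper bound by simulation.

## Optimal posterior

With a flat (or Gaussian) prior over θ, the posterior given both spike
vectors is approximately Gaussian with additive precision

    P = Σ_prior⁻¹ + (n_p/σ_p²) I + n_v Jᵀ J / σ_v²,

J evaluated at the proprioceptive center of mass (if prop is silent, at the
back-transformed visual estimate), and mean P⁻¹-weighted combination of the
prior mean, the prop center of mass, and the inverse-kinematics image of
the vis center of mass.  The test suite validates this closed form against
brute-force grid integration of the exact Poisson likelihoods: at 20×20
populations and above, means agree to well under a tenth of a grid spacing
and covariances to <1% Frobenius; at very sparse codes (12×12, ~20 spikes
per population) the Gaussian/linearization error grows to several percent,
which is why the oracle comparison is performed at 20×20.

For the 1D coordinate-transformation model (X_b = L cos θ, X_r = X_b − E),
the exact flat-prior Gaussian marginal over X_b reduces to the
precision-weighted combination of the prop cue (mapped through the local
slope −L sin θ) with the chained vis+eye cue (mean X̂_r + Ê, variance
σ_v²/n_v + σ_e²/n_e); this is verified against a dense 2D grid posterior.

## The harmonium and its training

The association network is an exponential-family harmonium: visible units
Poisson with exponential inverse link, hidden units Bernoulli with logistic
link, full interlayer and no intralayer connections.  The hidden layer has
half as many units as the visible layer (one input population's worth),
forcing a compressed representation.

Training is one-step contrastive divergence on minibatches of 40 vectors:
up (sample hidden), down (sample visible), up again; ΔW ∝ difference of
data-phase and reconstruction-phase correlations, with matching bias
updates.  Schedule: 15-epoch stages with learning rates annealed by 0.8
between stages; 6 stages (90 epochs) at the standard scale.  Choices the
source account leaves open, fixed here:

* **Learning rates.** 5·10⁻³ for weights and biases (annealed).  This was
  set by monitoring convergence (reconstruction deviance and the error
  covariance of the decoded estimate): an order of magnitude lower leaves
  the model visibly undertrained after 90 epochs.
* **Correlation statistics.** The Gibbs chain always descends from sampled
  hidden states; the correlation statistics default to conditional means in
  both phases (identical expectation to the fully sampled rule — the test
  suite checks the sampled update is unbiased for the enumerated exact
  correlation difference — with lower variance).  Both phases can be
  switched to fully sampled via configuration.
* **Initialization.** Weights N(0, 0.01²); visible biases at the log mean
  training rate per unit (so reconstruction starts near the data
  marginals); hidden biases 0.
* **Rate cap.** The exponential link can explode early in training; visible
  means are capped at 3× the maximum gain.  The cap is a numerical guard:
  the training trace records how often it binds (zero after the first
  stage on default configurations).
* **Arithmetic.** Training runs in float32 by default (the matrix products
  dominate the cost); float64 is available via configuration and changes
  results only within sampling noise.

## Decoding

Testing draws a fresh batch, computes the hidden conditional means for each
trial, and averages 15 Bernoulli samples (equivalently Binomial(15, p)/15).
Because the model is generative, the hidden vector is pushed back through
the same weights to expected input spike counts, which are decoded exactly
like real inputs: the posterior-mean estimate is the center of mass of the
decoded population for the reporting space (prop for joint space — the
weighted combination across decoded cues is also available), and the
posterior covariance is the additive-precision formula with the decoded
per-population total counts as weights.  Decoding touches only the model
parameters, the hidden activity, and static configuration — never the true
stimuli or gains.

Total-count recovery is improved by a calibration regressor (one hidden
layer of 32 logistic units, standardized inputs/targets, early stopping)
mapping hidden-derived features — the decoded per-population sums together
with the hidden vector itself — to the true totals, fit on trials disjoint
from those evaluated.  The posterior-covariance pathway never uses this
regressor.

## Evaluation metrics

* **Error statistics.** Conditional (per stimulus) and marginal error mean
  and covariance for four estimators: vis-only, prop-only, optimal (both
  populations), and the network estimate.
* **Covariance-only KL.** The Gaussian KL divergence with the mean term
  dropped isolates the divergence due to covariance mismatch; the baseline
  comparison replaces per-trial total counts by their batch averages (a
  model that learned the gain prior but transmits no trial-by-trial
  reliability information).
* **Fractional information loss.**  KL(opt‖model)/KL(opt‖prior): 0 when
  the decoded posterior matches the optimal one, 1 when it has degraded to
  the prior.  A flat prior has no finite KL from a Gaussian, so the
  denominator uses the moment-matched Gaussian over the joint box
  (configurable).  Losses are averaged within bins of the (g_p, g_v) gain
  plane (3×3 by default) and summarized by the worst bin.

### Problem sizes and what the numbers mean

Training cost scales with (visible × hidden) × minibatches.  Three scales
are used:

* **Scaled** (tests): two 12×12 inputs, 144 hidden, 10k vectors, 90
  epochs.  All qualitative properties (near-optimal covariance, prior
  learning, hierarchy, coordinate transformation, sharpening) are asserted
  here.
* **Desk** (tests and `scripts/acceptance.py`): two 20×20 inputs, 400
  hidden, 20k–40k vectors, 90 epochs — minutes on one CPU.  Information
  loss per gain bin lands near 2–2.5% and calibrated total-count R² near
  0.75–0.8.
* **Standard**: two 30×30 inputs, 900 hidden, 40k vectors, 90 epochs —
  about 1.5 h on one CPU.  This is the configuration under which the
  percent-level information losses and R² > 0.82 are attainable; the
  information loss decreases systematically with network size and training
  budget (the capacity sweep in `run_capacity_sweep` shows the error
  covariance shrinking toward the optimum with more hidden units and more
  hidden samples).

The acceptance script runs the desk scale to stay within a practical time
budget and reports the honestly computed value at that scale.

## Experiment protocols

All experiments are pure functions of (configuration, seed): data come
from purpose-keyed seed streams (`train-data`, `test-data`, `init`,
`gibbs`, `decode`, `calibrator`), so training and test batches are always
disjoint and any stage can be changed without perturbing the others.

* **Integration** (`run_integration`): the headline protocol above.
* **Capacity/noise sweep** (`run_capacity_sweep`): one model per hidden
  size, decoded with each sample count and with means (infinite samples).
* **Generalization** (`run_generalization`): a single trained model tested
  on shifted data — the prop report displaced by k standard deviations of
  the summed input covariance (k ∈ {2.5, 5, 7.5}) along a configurable
  direction — and on gain ranges outside the training regime.  Shifted
  trials whose angles leave the joint box are resampled, keeping the prior
  over θ unchanged; the resample count is recorded.
* **Gaussian prior** (`run_prior_experiment`): training stimuli drawn from
  a tight Gaussian whose per-dimension extreme angles are 150 prior
  standard deviations apart.  The decoder is unchanged, so any conditional
  bias toward the prior mean and any marginal-covariance shrinkage must
  have been learned into the weights.
* **Sometimes-decoupled inputs** (`run_decoupled`): with probability
  1 − p_couple the visual population reports an independently drawn "left
  hand" and a dedicated toggle unit fires at the trial's visual gain
  (silent otherwise; appended as the last visible unit).  The benchmark is
  the condition-aware optimal estimator's error covariance, the
  p-weighted average of the coupled (integrated) and decoupled (prop-only)
  covariances.  p_couple defaults to 0.5.
* **Hierarchical integration** (`run_hierarchical`): a second harmonium is
  trained on [stage-1 hidden activity, a third population encoding θ].
  The stage-1 channel defaults to the hidden means scaled by the sample
  count (a per-unit expected spike count in 0..15; sampled Binomial counts
  are available via configuration but their extra noise swamps the third
  cue's benefit at reduced network sizes).  The channel is treated as
  Poisson with rate cap 15; stage-2 activity is decoded down both
  generative maps, and the reported estimate combines all three decoded
  cues by their decoded precisions.  Feeding exact stage-1 means and raw
  third-population counts through this decode path reproduces the
  three-cue optimum, so any stage-2 shortfall measures the second
  harmonium's learning quality, not the decoding scheme.
* **Coordinate transformation** (`run_coordtrans`): 60 units each for
  prop(θ), vis(X_r), eye(E) (180 visible), 160 hidden.  The retinal
  position X_r and gaze angle E are sampled independently and uniformly on
  [−13.5, 13.5] cm, and X_b = X_r + E — so the sampled (X_b, E) region is
  a parallelogram, X_b stays strictly inside the joint range's image
  (±32 cos π/6 ≈ ±27.7 cm), and the proprioceptive population, which tiles
  the whole joint range, is responsible for a larger space than either
  other population.  That dilution is why the prop gain is raised to
  U[36, 54]: with it the prop cue and the chained vis+eye cue contribute
  comparable precision, so integration visibly improves on every single
  cue.  Because the raised gain roughly triples the visible spike counts
  (and hence the CD-1 correlation gradients), this network trains with a
  proportionally smaller learning rate (2·10⁻³) over a longer schedule
  (9 stages).  The score is the MSE of the decoded X_b estimate against
  the three-cue optimal MSE and the single-cue (prop-only, vis+eye) MSEs.

## Hidden-unit analyses

Tuning curves are computed noiselessly (means in both layers) at fixed
gain 15.  A unit is "tuned" if its firing probability varies by more than
0.1 over the stated stimulus domain (full plane or a 1D arc — the mask is
domain-specific by contract).  "Sharpening" is quantified by the fraction
of hidden units emitting at least one spike in 15 samples, which falls
with gain while the input-layer active fraction rises.

Reference-frame analysis builds each tuned unit's response over an
(H_b, E) rectangle and computes (1) a separability index — the first
singular value's share of squared singular values of the raw response
matrix, exactly 1 for any product-form (pure gain field) map — with
threshold 0.95, and (2) the unit's reference frame as the axial circular
mean of the response-gradient direction (0° ≡ body-centered H_b, ±90° ≡
eye E, −45° ≡ retinal H_r = H_b − E, +45° ≡ H_b + E), binned at 15° for the
histogram.  Because X_b and E are sampled independently here, the sampled
region is already a rectangle; the analysis subregion remains configurable
since the histogram is known to depend on it.

## Limitations

* The synthetic world uses homogeneous, isotropic tuning, independent
  Poisson noise, and uniform tiling; passing tests demonstrates the
  learning and decoding machinery under those assumptions, not robustness
  to heterogeneous tuning or correlated noise in real recordings.
* The Gaussian "optimal posterior" is itself an approximation that
  requires enough spikes for errors to stay in the kinematics' linear
  regime; the package treats the 20×20-and-up regime as its operating
  range and quantifies the approximation error by grid integration.
* The unsignaled decoupling case (mixture posterior without a toggle) and
  decoding of individual gains beyond totals are out of scope.
* Quantitative matching of empirical reference-frame histograms is not
  attempted; the histogram depends strongly on the sampled subregion.
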