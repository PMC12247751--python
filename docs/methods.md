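# Methods

## Model

`modmindy` models mesoscale brain activity as `n = n_exc + n_inh` neural
populations — excitatory populations stacked first, each optionally paired
with a local inhibitory population — evolving in discrete time:

    x[t+1] − x[t] = (W ∘ Γ_i) tanh(S x[t] + V) − D x[t] + C + ε[t]
    y[t] = H x[t] + ν[t]

* `W` is the baseline effective connectivity, block structured by source
  type: `Wee` (E→E) and `Wei` (E→I) are nonnegative and carry a fixed
  binary mask zeroing 75% of their off-diagonal entries; `Wie` (I→E) and
  `Wii` (I→I) are nonpositive and diagonal, reflecting the local-only
  reach of inhibitory populations.
* `Γ_i = u_i v_iᵀ` is a nonnegative rank-1 modulation attached to regime
  `i ∈ {1..m}`; the Hadamard product `W ∘ Γ_i` rescales connections
  without changing their sign structure.  Rank 1 encodes the assumption
  that neuromodulation acts in a spatially diffuse, factorizable way.
  Regime labels are part of the input; inferring *when* regimes switch is
  out of scope.
* `D` holds positive per-population decay (leak) rates and enters the
  update with a minus sign.  The printed decay values (≈0.65 excitatory,
  ≈0.8 inhibitory) make the linear part of the one-step map `1 − D`,
  i.e. contractive; the opposite sign convention produces a `1 + D`
  multiplier that diverges within a handful of steps, so it cannot be the
  intended reading.  The convention is fixed in `model.DECAY_SIGN`.
* `S` is one slope per population group (default 2.5 excitatory, 1
  inhibitory), `V` an offset (default 0), `C` a per-population bias
  (default 0).
* `H = [H_exc | 0]` maps excitatory activity to channels; inhibitory
  populations do not contribute to recorded potentials.  For real
  recordings `H_exc = I − 0.05·11ᵀ` (a dominant own-population pickup
  with a small common-reference subtraction); the synthetic generator
  draws `H_exc` with standard normal entries.
* `ε ~ N(0, Q)` is process noise, `ν ~ N(0, R)` measurement noise.

## Synthetic ground truth

The generator (`synthgen`) draws models whose excitatory-source blocks
are sparse + low-rank + diagonal, `Wee = Ws + Wl1 Wl2ᵀ + diag(w_d)`:
`Ws` entries are cubes of uniforms scaled by 16/20 (cubing skews weights
toward small values with a heavy right tail), the low-rank factors are
`n × n/4` (floored at width 1 for small n) with entries `U(0,1)³ +
0.2·U(0,1)`, and the self-connection vector `w_d` uses the same entry
family.  The magnitudes of the inhibitory diagonals are drawn from that
family and negated; their distribution is not otherwise constrained and
is exposed in the config.  Modulations are symmetric self outer products
`Γ_i = γ_i γ_iᵀ` with a hierarchical draw (level `μ_i ~ N(1, 0.1)`, a
fair coin choosing a uniform or normal shape, spread `σ_i ~ N(0.4, 0.1)`
or `N(0.05, 0.01)`), clipped at zero — values concentrate near 1 so that
modulation rescales rather than overwhelms `W`.  Regimes follow a sticky
Markov chain `A = 0.999·I + (0.001/m)(11ᵀ − I)`; the rows of that matrix
do not sum to exactly one as written, so they are renormalized (with a
warning).  Defaults: 20 paired populations, 3 regimes, 20,000 steps at
250 Hz (80 s), process noise `Q = 0.25·I`, a single uniform measurement
variance on (0.2, 0.3).

The generator reproduces the regime-switching, the E/I structure, and
the observation bottleneck of labeled EEG; it does not emulate realistic
EEG spectra, volume conduction, or artifacts.  Passing recovery tests
therefore demonstrate identifiability of the model's own parameters from
its own dynamics, not robustness to real-data model mismatch.

A note on the dynamical regime these defaults produce: the excitatory
row sums are large relative to the decay, so trajectories saturate the
tanh and hop (noise-driven) between a small number of sign-pattern
attractors.  Connectivity is then identified chiefly through attractor
positions across visited pattern × regime combinations, which makes the
inhibitory pathway — observed only through the diagonal I→E feedback —
the hardest part of the problem at short data lengths (see Limitations).

## Dual estimation

`fit` alternates, on windows of the recording:

1. **Extended Kalman filter** over a window (default desk-scale length
   500 steps): predict with the regime-appropriate dynamics, linearize
   the Jacobian `I − diag(D) + (W∘Γ_i) diag(S sech²(Sx+V))` at the
   current estimate, update with the observation.  The filter starts
   each window at zero state with unit covariance; the first
   `kalman_burn_in = 10` innovations are excluded from the loss.
2. **Free simulation**: a noiseless rollout from the last filtered state
   over a short horizon (default 25 steps), scored against the held
   observations.
3. **Backpropagation** of the summed innovation and prediction errors
   into all learnable parameters.  Gradients are hand-derived
   reverse-mode accumulation, compiled with numba: exact BPTT through
   the rollout, and — in the default `covariance_backprop=True` mode —
   through the entire filter recursion including the covariance
   propagation, gain computation, and innovation covariance, so that
   parameters receive gradient both for how states *evolve* and for how
   they are *estimated*.  The noise covariances are learned as diagonals
   through a log parameterization floored at 1e-6.  Every gradient path
   is validated against central finite differences to ~1e-9 relative
   error in the test suite.
4. **NADAM step + projection** onto the constraint set: clamp
   `Wee, Wei ≥ 0` (masked entries reset to exact zero), `Wie, Wii ≤ 0`
   and diagonal, modulation factors ≥ 0, baseline factors reset to exact
   ones when pinned.

Two further ingredients proved necessary at desk scale:

* **Gauge fixing.**  `W` and `{Γ_i}` are only identified up to a shared
  elementwise rank-1 factor (`W → W ∘ abᵀ`, `u_i → u_i/a`, `v_i → v_i/b`).
  Left free, this gauge drifts slowly during stochastic optimization and
  decorrelates both factors from any reference.  The projection
  normalizes the geometric mean of the factors across regimes to 1 and
  absorbs it into `W` — the analogue, for unpinned fits, of pinning the
  baseline regime's modulation at `11ᵀ` in real-data fits.
* **Early stopping on a temporal holdout.**  With a finite recording the
  loss keeps creeping down long after parameter recovery has peaked, as
  near-flat directions absorb noise idiosyncrasies.  By default at desk
  scale the trailing 15% of the recording is held out, scored
  (forward-only) every 25 iterations, and the best-scoring parameters
  are returned; the exponential-moving-average convergence rule on the
  training error remains available (and is the default when
  `holdout_frac = 0`).

Desk-scale experiment schedule (`experiments.desk_fit_config`): the whole
training segment is tiled into fixed windows and every iteration
processes all of them (a deterministic full-data gradient; removing
window-sampling noise lets the weakly determined inhibitory pathway
accumulate a coherent gradient), NADAM at 0.035 with cosine annealing,
at most 200 iterations, and a mild ridge (`weight_decay = 0.03`) on the
connectivity blocks that controls variance inflation of weakly
determined entries.  Each synthetic-recovery fit is run from two random
initializations and the fitted parameters are averaged entrywise — the
gauge anchoring keeps the two solutions aligned, and the average is
better centered than either run.  Random initialization: small correctly
signed uniforms for the connectivity blocks, modulation factors
`N(1, 0.05)` clipped at zero, decay/slopes/offset/bias at the standard
defaults.

## Recovery metrics

`masked_correlation` vectorizes each block over the entries surviving
the true sparsity mask (shared zeros would otherwise inflate the
correlation), plus diagonals; the full-W correlation pools the surviving
`Wee`/`Wei` entries with the `Wie`/`Wii` diagonals.  Γ correlations are
taken per regime over the effective EE and EI sub-blocks.  Pearson r is
invariant to uniform rescaling, matching the scale indeterminacy of the
factorization.  `split_half_reliability` compares within-subject to
across-subject correlations of split-half fits with a Wilcoxon rank-sum
test (the distributions' medians and IQRs are what the numbers mean;
the rank-sum test is the package's choice of nonparametric
comparison).  `modulation_impact` is `W ∘ (Γ_b − Γ_a)`, antisymmetric by
construction; `gamma_value_summary` counts entries strictly greater
than 1 (a value of exactly 1 is "not greater").

## EEG preprocessing

4th-order Butterworth bandpass (0.5–15 Hz default) applied
forward-backward (zero phase; the two-pass attenuation at 20 Hz is
~19.6 dB), per-channel median subtraction and division by the mean
absolute deviation about the median (constant channels are detected on
the raw signal and passed through as zeros with a warning, since the
bandpass would otherwise turn them into amplified numerical noise),
channel-subset selection, and concatenation of per-regime sessions with
1-based labels.  Session boundaries are recorded and fitting windows do
not straddle them.

## Numerical choices

* Innovation covariance inverses get a 1e-8 jitter retry if singular.
* Covariance matrices are symmetrized each step; `apply_constraints`
  floors `Q`/`R` eigenvalues at 1e-6.
* Slopes are floored at 1e-3 (the sign symmetry `s → −s` is excluded by
  the sign constraints on `W`).
* Divergent windows (non-finite states) raise; the fit loop skips the
  window and aborts with the last stable parameters after 50 consecutive
  failures.
* With both noise covariances zero, simulation is bit-for-bit
  reproducible and seed-independent.
* Sticky regime chains can miss a regime in a short run; experiment
  drivers redraw with an offset seed until every regime is present.

## Desk-scale problem sizes

The recovery suites use 10 paired E/I populations, 3 regimes (or 1 for
the stationary baseline), 5,000 timesteps, 8 models per suite, 2
restarts per model.  At these sizes the EE block recovers at a median
r around 0.8 and the full-W median around 0.7, with wide per-model
spread (individual recordings differ greatly in how many attractor
patterns and regime transitions they happen to visit); the EI block is
substantially lower.  `scripts/acceptance.py` recomputes these medians
from scratch for a given seed.

## Limitations

* At 5,000 timesteps the saturated-attractor dynamics visit only a few
  sign patterns and regime transitions are rare, so the E→I block and
  the inhibitory diagonals — which influence the observations only
  through the diagonal I→E feedback — are weakly determined.  A
  least-squares oracle given the *true* latent states recovers `Wei` at
  r ≈ 0.8–1.0 at this length, so the limit is the filtering-only state
  estimate (filtering only; no retrospective smoothing pass, so the
  estimate at time t never uses future observations), not
  the data per se.  Longer recordings and more populations close this
  gap.
* The ridge and the restart averaging are desk-scale conditioning
  devices; with longer recordings they can be disabled
  (`weight_decay=0`, `n_restarts=1`) to regularize structure only.
* The EKF linearization is first order; strongly saturated steps are
  handled but the filter's inhibitory-state estimates are prior-driven
  when the I→E feedback is small.
* Modulation recovery inherits the `W` estimate's entrywise error;
  because modulation values concentrate near 1, their correlation with
  the truth degrades faster than `W`'s.
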