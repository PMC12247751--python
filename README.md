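# modmindy

Regime-modulated excitatory/inhibitory network models of mesoscale brain
activity, fitted directly to multichannel recordings.

Brain dynamics are individualized *and* nonstationary: the circuit
parameters that generate a person's EEG change with physiological state
(sedation level, sleep stage, task).  Fitting one stationary model to
such data averages over regimes; fitting a separate model per regime
discards what the regimes share.  `modmindy` takes a middle path
grounded in neuromodulation: a single baseline connectivity matrix `W`,
common to all regimes, is rescaled element-wise by a nonnegative rank-1
modulation matrix `Γ_i` specific to the labeled regime `i` active at
each moment:

    x[t+1] − x[t] = (W ∘ Γ_i) tanh(S x + V) − D x + C + ε
    y[t] = H x[t] + ν

The state `x` holds excitatory and inhibitory population activities.
`W` is biologically structured: excitatory-source blocks are nonnegative
with 75% sparsity, inhibitory-source blocks are nonpositive and diagonal
(inhibition is local), and the lead field `H` is zero over inhibitory
populations (they do not generate scalp potentials).  Because the latent
states are never observed directly, fitting is a dual-estimation
problem: an extended Kalman filter estimates the states on random data
windows, a free simulation scores multi-step predictions, and both
errors are backpropagated into every parameter — including the noise
covariances — under the structural constraints (NADAM with projection).
The package includes the synthetic ground-truth generator used to
validate recovery, the recovery/reliability/modulation-impact metrics,
and an EEG preprocessing front end.

Intended users: researchers fitting interpretable whole-brain dynamical
models to regime-labeled electrophysiology (anesthesia levels, sleep
stages, task blocks), and anyone studying identifiability of Hadamard-
factorized effective connectivity.

## Worked example

Draw a known ground-truth network, simulate a labeled recording, fit a
modulated model from random initialization, and compare to the truth:

```python
import modmindy as mm

# draw a ground-truth network: 8 paired E/I populations, 2 regimes, 12 s
cfg = mm.SynthConfig(n_exc=8, n_inh=8, m=2, T=3000, hmm_leak=0.01)
bundle = mm.generate_dataset(cfg, seed=7)
rec = bundle.recording
print(f"recording: {rec.n_channels} channels x {rec.T} steps "
      f"({rec.duration:.0f} s at {rec.fs:.0f} Hz), "
      f"regimes visited: {sorted(set(map(int, rec.labels)))}")

# fit from random init; true lead field, noise covariances and mask given
truth = bundle.params
init = mm.random_init(8, 8, 2, truth.H, truth.Q, truth.R,
                      mask_ee=truth.W.mask_ee, mask_ei=truth.W.mask_ei,
                      seed=1)
config = mm.FitConfig(kalman_window_len=500, free_sim_horizon=25,
                      learning_rate=0.035, max_iterations=200,
                      full_batch_frac=1.0, weight_decay=0.03,
                      holdout_frac=0.15, holdout_patience=4,
                      n_windows_per_epoch=25, tail_average_frac=0.0,
                      convergence_tol=1e-9, seed=2)
result = mm.fit(rec, config, init=init)
print(f"fit: {result.n_iterations} iterations, converged={result.converged}")

report = mm.masked_correlation(truth, result.params)
print(f"recovery r: full W {report.r_full_W:.3f} | "
      f"EE {report.r_Wee:.3f} | EI {report.r_Wei:.3f}")

impact = mm.modulation_impact(result.params.W, result.params.gammas[0],
                              result.params.gammas[1])
print(f"regime 1 -> 2 modulation impact: mean {impact.value.mean():+.4f}, "
      f"{(impact.value < 0).mean():.0%} of connections weakened")
```

Output:

```
recording: 8 channels x 3000 steps (12 s at 250 Hz), regimes visited: [1, 2]
fit: 200 iterations, converged=False
recovery r: full W 0.805 | EE 0.903 | EI 0.440
regime 1 -> 2 modulation impact: mean -0.0097, 13% of connections weakened
```

The correlations measure how well the fitted connectivity matches the
generating truth over the structurally free entries (Pearson r, so a
common scale factor is forgiven).  The excitatory-to-excitatory block is
recovered well; the excitatory-to-inhibitory block is harder because
inhibitory populations are observed only through their feedback onto
excitatory ones.  The modulation impact `W ∘ (Γ₂ − Γ₁)` gives the signed
change of each connection between regimes: negative entries are
connections weakened by the regime switch.

A thin CLI mirrors the library: `modmindy simulate`, `modmindy fit`,
`modmindy evaluate`, `modmindy preprocess` (see `--help` on each).
Recordings, parameter bundles, and fit results serialize to HDF5.

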