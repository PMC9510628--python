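# fada — unified identification of motor primitives

Movement data — EMG envelopes, joint-angle trajectories, forces — are
routinely decomposed into a small number of **motor primitives**: fixed
spatial patterns, temporal waveforms, or spatiotemporal modules whose
weighted (and possibly delayed) combination reconstructs the recorded
signals. Different communities use different generative models for this
(spatial/NMF-style, temporal/ICA-style, delayed-temporal, time-varying
synergies, space-by-time trifactorization), each traditionally fitted with
its own specialized algorithm.

`fada` implements all five classical decompositions as constrained special
cases of a single **anechoic mixture model**

```
y_r(t) = Σ_u  a_ru · f_u(t − τ_ru),        r = 1 … M·L
```

where the row index `r` enumerates (DOF, trial) pairs, `f_u` are latent
band-limited source functions, `a_ru` mixing weights, and `τ_ru` time
delays. Each classical model corresponds to a set of equality constraints
(weight/delay tying, structural zeros, zero delays, non-negativity, or a
bilinear weight factorization), and a single **Fourier-domain anechoic
demixing engine** identifies them all: signals are represented by truncated
Fourier series `y_r(t) ≈ Σ_{|k|≤K} c_rk e^{2πikt/T_s}`, delays become phase
ramps `e^{−2πikτ/T_s}`, source magnitude spectra are initialized from the
delay-blind identity `|c_rk|² ≈ Σ_u |a_ru|²|ν_uk|²` (non-negative
factorization), and sources, weights and delays are then refined by
alternating least squares with a multistart cross-correlation delay search.

The package ships a seeded generator of EMG-like (non-negative) and
kinematic-like (unconstrained) benchmark datasets with signal-dependent
noise, recovery metrics (explained variance `R²`, chance-normalized
similarity `S_N` after optimal component matching), model-order selection
by the elbow rule, library ICA/NMF baseline adapters, and a CLI.

## Worked example

```python
from fada import api, FitOptions, evaluate
from fada.simulate import SimulationSpec, generate_benchmark

# EMG-like ground truth: 3 delayed temporal primitives, 10 muscles, 20 trials
spec = SimulationSpec(model_kind="temporal_delays", nonneg=True, seed=1)
bundle = generate_benchmark(spec)[0]

fit = api.fit(bundle.dataset, "temporal_delays", P=3, nonneg=True,
              opts=FitOptions(seed=0))
report = evaluate(fit, bundle)
print(f"R2 = {fit.r2:.4f}")
print(f"S_N primitives = {report.sn_primitives:.3f}, "
      f"weights = {report.sn_weights:.3f}, "
      f"delay RMS = {report.delay_rms_samples:.2f} samples")
```

prints

```
R2 = 1.0000
S_N primitives = 0.998, weights = 1.000, delay RMS = 0.00 samples
```

i.e. the engine reconstructs this noiseless dataset essentially exactly,
the three recovered waveforms match the generating primitives at the
chance-corrected similarity 0.998, and the 600 trial-and-muscle-specific
activation delays are recovered to a small fraction of a sample.

The same interface fits the other models (`"spatial"`, `"temporal"`,
`"spatiotemporal"`, `"space_by_time"`); `api.r2_curve` and
`api.elbow_select` choose the number of primitives. From a shell:

```bash
fada simulate --model temporal-delays --nonneg --noise 0.15 --n 20 --seed 7 -o out/
fada fit out/temporal_delays_r000.csv --model temporal-delays -p 3 -o fit.json
fada select out/temporal_delays_r000.csv --model temporal-delays --max-p 6
fada evaluate fit.json out/temporal_delays_r000.truth.json -o report.json
fada bench -o bench.csv --models temporal --noise 0,0.15 --n 5
```

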