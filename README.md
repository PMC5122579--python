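# synquant

Bayesian inference of synaptic quantal and short-term-plasticity parameters
from trains of postsynaptic-potential (EPSP) amplitudes.

A synapse is modeled as `n` independent vesicle release sites with
spike-triggered Bernoulli release (probability `u_m`, with depression via
vesicle depletion and optional facilitation), Poissonian restock between
spikes (probability `g_m`), gamma-distributed quantal amplitudes (mean
`mu_a`, s.d. `sigma_a`) and Gaussian background noise (`sigma_b`).  The
exact likelihood of an amplitude train — retaining the serial correlations
induced by shared vesicle depletion — is computed as a scaled matrix product
over the hidden release-site occupancy (a forward algorithm), at cost linear
in the number of spikes instead of the naive `(n+1)^M` enumeration.  A
factorized "uncorrelated" baseline likelihood, a stochastic synapse
simulator and a grid Metropolis-Hastings sampler with flat priors complete
the pipeline.

## Layout

| module                | contents |
|-----------------------|----------|
| `synquant.dynamics`   | model parameters, spike trains, per-spike release/restock schedules, analytic mean occupancy |
| `synquant.amplitude`  | gamma ⊗ Gaussian observation density `P[A|k]` |
| `synquant.likelihood` | matrix-product likelihood, uncorrelated baseline, joint release-count law, brute-force enumeration oracle |
| `synquant.inference`  | parameter grids, Metropolis-Hastings, exhaustive grid posterior, marginals / MAP / credible intervals / convergence checks |
| `synquant.simulate`   | stochastic sweep simulator (per-site histories, seeded and reproducible) |
| `synquant.io` / `synquant.cli` | sweep CSV and posterior/summary formats, YAML/JSON run configs, `synquant` command |

## Command line

```sh
# simulate 5 sweeps of 30 regular spikes at 30 Hz
synquant simulate --params params.yaml \
    --protocol "regular:rate=30,count=30,sweeps=5" --seed 1 \
    --out sweeps.csv --truth-out truth.csv

# posterior sampling (grid + sampler settings in config.yaml)
synquant infer --data sweeps.csv --config config.yaml \
    --mode correlated --out posterior.csv --summary-out summary.json

# correlated vs uncorrelated interval widths
synquant compare --data sweeps.csv --config config.yaml --out widths.json

# summarize an existing posterior table
synquant summarize --posterior posterior.csv --out report.json
```

`params.yaml` is a mapping of the eight parameters (`n, tau_D, tau_F, p0,
p1, mu_a, sigma_a, sigma_b`, plus optional `variant`); `config.yaml` holds
the model variant, a per-parameter grid specification (ranges with
`step`/`points`, `scale: log`, or a single `value` to clamp) and sampler
settings.  Sweep data is a CSV with columns
`sweep_id, spike_time_s, amplitude_mV`, grouped by sweep with strictly
increasing times.  Units are fixed: seconds and millivolts.

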