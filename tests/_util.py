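"""Shared helpers for randomized test instances."""

from __future__ import annotations

import numpy as np

from synquant import ModelParams, SpikeTrain, Sweep

FIG1 = dict(n=7, tau_D=0.25, tau_F=0.2, p0=0.6, p1=0.8, mu_a=0.25, sigma_a=0.1, sigma_b=0.05)


def random_params(rng: np.random.Generator, n_max: int = 4, n_min: int = 1) -> ModelParams:
    """A random valid parameter set, broad but away from degenerate edges."""
    n = int(rng.integers(n_min, n_max + 1))
    p0 = float(rng.uniform(0.1, 0.8))
    p1 = float(rng.uniform(p0 + 0.02, 0.95))
    mu_a = float(rng.uniform(0.1, 0.6))
    sigma_a = float(rng.uniform(0.3, 0.9) * mu_a)
    return ModelParams(
        n=n,
        tau_D=float(rng.uniform(0.05, 1.0)),
        tau_F=float(rng.uniform(0.05, 1.0)),
        p0=p0,
        p1=p1,
        mu_a=mu_a,
        sigma_a=sigma_a,
        sigma_b=float(rng.uniform(0.02, 0.2)),
    )


def random_spikes(rng: np.random.Generator, M: int) -> SpikeTrain:
    """Regular or Poisson spike pattern at a random rate in 10-60 Hz."""
    rate = float(rng.uniform(10.0, 60.0))
    if rng.random() < 0.5:
        times = np.arange(M) / rate
    else:
        gaps = rng.exponential(1.0 / rate, size=M)
        times = np.cumsum(gaps) - gaps[0]
    return SpikeTrain(times)


def random_instance(rng: np.random.Generator, n_max: int = 4, M_max: int = 5):
    """(params, sweep) with amplitudes simulated from the model itself."""
    from synquant import simulate_sweep

    params = random_params(rng, n_max=n_max)
    M = int(rng.integers(1, M_max + 1))
    spikes = random_spikes(rng, M)
    sweep = simulate_sweep(params, spikes, rng)
    return params, sweep
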