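"""Stochastic synapse simulator.

Generates synthetic sweeps with exactly the statistical structure the
likelihood assumes: n independent release sites, per-spike Bernoulli release
with probability ``u_m`` (from :mod:`synquant.dynamics`), per-interval
Bernoulli restock with probability ``g_m``, gamma-distributed quantal sums
and additive Gaussian background noise.  Restock is sampled per interval —
exactly equivalent to drawing exponential waiting times for the
constant-rate model (a waiting-time sampler is kept behind a flag for
future activity-dependent-recovery variants).

Reproducibility: one root seed, per-sweep child streams spawned from a
``SeedSequence``, so sweep i is invariant to the total sweep count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .dynamics import ModelParams, SpikeTrain, schedule
from .likelihood import Dataset, Sweep

__all__ = [
    "Protocol",
    "SweepTruth",
    "simulate_sweep",
    "simulate_dataset",
    "simulate_release_counts",
    "empirical_release_marginals",
]


@dataclass(frozen=True)
class Protocol:
    """Stimulation protocol: how many sweeps of which spike pattern."""

    sweep_count: int
    kind: Literal["regular", "poisson", "explicit"]
    rate_hz: float | None = None
    spike_count: int | None = None
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.sweep_count < 1:
            raise ValueError("sweep_count must be >= 1")
        if self.kind in ("regular", "poisson"):
            if self.rate_hz is None or self.rate_hz <= 0:
                raise ValueError("rate_hz must be > 0")
            if self.spike_count is None or self.spike_count < 1:
                raise ValueError("spike_count must be >= 1")
        elif self.kind == "explicit":
            if self.times is None:
                raise ValueError("explicit protocol requires times")
            object.__setattr__(self, "times", SpikeTrain(self.times).times)
        else:
            raise ValueError(f"unknown protocol kind {self.kind!r}")

    @classmethod
    def regular(cls, rate_hz: float, spike_count: int, sweep_count: int) -> "Protocol":
        return cls(sweep_count=sweep_count, kind="regular", rate_hz=rate_hz, spike_count=spike_count)

    @classmethod
    def poisson(cls, rate_hz: float, spike_count: int, sweep_count: int) -> "Protocol":
        return cls(sweep_count=sweep_count, kind="poisson", rate_hz=rate_hz, spike_count=spike_count)

    @classmethod
    def explicit(cls, times, sweep_count: int = 1) -> "Protocol":
        return cls(sweep_count=sweep_count, kind="explicit", times=np.asarray(times, float))

    def spike_train(self, rng: np.random.Generator | None = None) -> SpikeTrain:
        """Draw (or return) the spike train for one sweep."""
        if self.kind == "regular":
            return SpikeTrain(np.arange(self.spike_count) / self.rate_hz)
        if self.kind == "explicit":
            return SpikeTrain(self.times)
        if rng is None:
            raise ValueError("poisson protocol needs an rng")
        gaps = rng.exponential(1.0 / self.rate_hz, size=self.spike_count)
        return SpikeTrain(np.cumsum(gaps) - gaps[0])


@dataclass(frozen=True)
class SweepTruth:
    """Ground-truth hidden trajectories for one simulated sweep."""

    k: np.ndarray  # released vesicles per spike
    y_before: np.ndarray  # stocked sites just before each spike


def _draw_restock(
    empty: np.ndarray, g_m: float, T_m: float, tau_D: float, rng, waiting_time: bool
) -> np.ndarray:
    if waiting_time:
        # exponential waiting-time draw; equivalent Bernoulli for constant rate
        return empty & (rng.exponential(tau_D, size=empty.shape) < T_m)
    return empty & (rng.random(empty.shape) < g_m)


def simulate_sweep(
    params: ModelParams,
    spikes: SpikeTrain,
    rng: np.random.Generator,
    return_truth: bool = False,
    waiting_time_restock: bool = False,
):
    """Simulate one sweep; sites start fully stocked.

    Returns a :class:`Sweep`, or ``(Sweep, SweepTruth)`` when
    ``return_truth`` is set.
    """
    sched = schedule(params, spikes)
    n, M = params.n, len(spikes)
    intervals = spikes.intervals
    occupied = np.ones(n, dtype=bool)
    ks = np.empty(M, dtype=np.int64)
    ys = np.empty(M, dtype=np.int64)
    amps = np.empty(M)
    lam = params.mu_a / params.sigma_a**2
    shape1 = params.mu_a**2 / params.sigma_a**2
    for m in range(M):
        ys[m] = occupied.sum()
        released = occupied & (rng.random(n) < sched.u_pre[m])
        k = int(released.sum())
        ks[m] = k
        occupied &= ~released
        amp = rng.normal(0.0, params.sigma_b)
        if k > 0:
            # single gamma draw with shape k*mu^2/sigma^2: exact for the iid sum
            amp += rng.gamma(k * shape1, 1.0 / lam)
        amps[m] = amp
        if m < M - 1:
            occupied |= _draw_restock(
                ~occupied, sched.g[m], intervals[m], params.tau_D, rng, waiting_time_restock
            )
    sweep = Sweep(spikes=spikes, amplitudes=amps)
    if return_truth:
        return sweep, SweepTruth(k=ks, y_before=ys)
    return sweep


def simulate_dataset(
    params: ModelParams,
    protocol: Protocol,
    seed: int,
    return_truth: bool = False,
    waiting_time_restock: bool = False,
):
    """Simulate ``protocol.sweep_count`` independent sweeps, reproducibly.

    Returns a :class:`Dataset`, or ``(Dataset, list[SweepTruth])``.
    """
    children = np.random.SeedSequence(seed).spawn(protocol.sweep_count)
    sweeps = []
    truths = []
    for child in children:
        rng = np.random.default_rng(child)
        spikes = protocol.spike_train(rng)
        res = simulate_sweep(
            params, spikes, rng, return_truth=True, waiting_time_restock=waiting_time_restock
        )
        sweeps.append(res[0])
        truths.append(res[1])
    dataset = Dataset(sweeps=tuple(sweeps))
    if return_truth:
        return dataset, truths
    return dataset


def simulate_release_counts(
    params: ModelParams, spikes: SpikeTrain, n_rep: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized release-count simulation: (n_rep, M) matrix of k_m draws."""
    sched = schedule(params, spikes)
    n, M = params.n, len(spikes)
    occ = np.ones((n_rep, n), dtype=bool)
    ks = np.empty((n_rep, M), dtype=np.int64)
    for m in range(M):
        released = occ & (rng.random((n_rep, n)) < sched.u_pre[m])
        ks[:, m] = released.sum(axis=1)
        occ &= ~released
        if m < M - 1:
            occ |= ~occ & (rng.random((n_rep, n)) < sched.g[m])
    return ks


@dataclass(frozen=True)
class ReleaseMarginals:
    """Empirical per-spike and pairwise release-count frequencies."""

    n_rep: int
    per_spike: np.ndarray  # (M, n+1) frequencies
    per_spike_se: np.ndarray  # matching Monte-Carlo standard errors
    pairwise: dict  # (m1, m2) -> (n+1, n+1) joint frequencies


def empirical_release_marginals(
    params: ModelParams, spikes: SpikeTrain, n_rep: int, seed: int
) -> ReleaseMarginals:
    """Monte-Carlo release-count marginals (oracle for the matrix form)."""
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    ks = simulate_release_counts(params, spikes, n_rep, rng)
    n, M = params.n, len(spikes)
    per = np.empty((M, n + 1))
    for m in range(M):
        per[m] = np.bincount(ks[:, m], minlength=n + 1) / n_rep
    se = np.sqrt(per * (1.0 - per) / n_rep)
    pairwise = {}
    for m1 in range(M):
        for m2 in range(m1 + 1, M):
            joint = np.zeros((n + 1, n + 1))
            np.add.at(joint, (ks[:, m1], ks[:, m2]), 1.0)
            pairwise[(m1, m2)] = joint / n_rep
    return ReleaseMarginals(n_rep=n_rep, per_spike=per, per_spike_se=se, pairwise=pairwise)
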