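"""Deterministic short-term-plasticity state.

Per-spike release probabilities, inter-spike restock probabilities and the
analytic mean site occupancy for a stochastic vesicle-release synapse with
depression (vesicle depletion, Poissonian restock at rate ``1/tau_D``) and
optional facilitation (release probability jumps after each spike and decays
back to baseline with timescale ``tau_F``).

All dynamics are event-driven: interspike intervals enter through exact
exponential factors, no time discretization is performed anywhere.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Variant",
    "ModelParams",
    "SpikeTrain",
    "ReleaseSchedule",
    "release_probabilities",
    "restock_probabilities",
    "schedule",
    "mean_occupancy",
    "expected_amplitudes",
]

_P1_TOL = 1e-9


class Variant(str, enum.Enum):
    """Model variants supported by the built-in release-probability dynamics.

    ``DEPRESSION_ONLY``
        No facilitation: ``p1 == p0`` and the release probability is constant.
    ``DEPRESSION_FACILITATION``
        Full model: release probability jumps from ``u`` to
        ``u + (1-u)(p1-p0)/(1-p0)`` at each spike and relaxes to ``p0``.
    ``FACILITATION_DOUBLING``
        Reduced facilitation model with ``p1 = 2 p0`` tied at construction,
        removing ``p1`` from the free-parameter set.
    """

    DEPRESSION_ONLY = "depression_only"
    DEPRESSION_FACILITATION = "depression_facilitation"
    FACILITATION_DOUBLING = "facilitation_doubling"


@dataclass(frozen=True)
class ModelParams:
    """The eight synapse parameters.

    Parameters
    ----------
    n : int
        Number of statistically independent release sites (>= 1).
    tau_D : float
        Timescale of recovery from depression, seconds.
    tau_F : float
        Timescale on which facilitation decays, seconds.
    p0 : float
        Baseline single-site release probability.
    p1 : float, optional
        Facilitated release probability immediately after one isolated
        spike. Derived automatically for the tied variants
        (``p1 = p0`` for depression-only, ``p1 = 2 p0`` for the doubling
        variant); required for ``DEPRESSION_FACILITATION``.
    mu_a : float
        Mean quantal (single-vesicle) amplitude, mV.
    sigma_a : float
        Standard deviation of the quantal amplitude, mV (must be < ``mu_a``).
    sigma_b : float
        Standard deviation of the Gaussian background noise, mV.
    variant : Variant or str
        Release-dynamics variant.
    """

    n: int
    tau_D: float
    tau_F: float
    p0: float
    mu_a: float
    sigma_a: float
    sigma_b: float
    p1: float | None = None
    variant: Variant = Variant.DEPRESSION_FACILITATION

    def __post_init__(self) -> None:
        variant = Variant(self.variant)
        object.__setattr__(self, "variant", variant)
        if not (isinstance(self.n, (int, np.integer)) and not isinstance(self.n, bool)):
            raise ValueError(f"n must be an integer, got {self.n!r}")
        object.__setattr__(self, "n", int(self.n))
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        for name in ("tau_D", "tau_F", "p0", "mu_a", "sigma_a", "sigma_b"):
            val = float(getattr(self, name))
            if not np.isfinite(val):
                raise ValueError(f"{name} must be finite, got {val}")
            object.__setattr__(self, name, val)
        if self.tau_D <= 0:
            raise ValueError(f"tau_D must be > 0, got {self.tau_D}")
        if self.tau_F <= 0:
            raise ValueError(f"tau_F must be > 0, got {self.tau_F}")
        if not 0.0 < self.p0 < 1.0:
            raise ValueError(f"p0 must be in (0, 1), got {self.p0}")

        p1 = self.p1
        if variant is Variant.DEPRESSION_ONLY:
            implied = self.p0
        elif variant is Variant.FACILITATION_DOUBLING:
            implied = 2.0 * self.p0
        else:
            implied = None
        if implied is not None:
            if p1 is not None and abs(float(p1) - implied) > _P1_TOL:
                raise ValueError(
                    f"variant {variant.value} ties p1 to {implied}, got p1={p1}"
                )
            p1 = implied
        elif p1 is None:
            raise ValueError("p1 is required for the depression_facilitation variant")
        p1 = float(p1)
        object.__setattr__(self, "p1", p1)

        if not self.p0 <= p1 < 1.0:
            raise ValueError(f"require p0 <= p1 < 1, got p0={self.p0}, p1={p1}")
        if variant is Variant.DEPRESSION_FACILITATION and not self.p0 < p1:
            raise ValueError(
                f"depression_facilitation requires p0 < p1, got p0={self.p0}, p1={p1}"
            )
        if not self.mu_a > self.sigma_a > 0.0:
            raise ValueError(
                f"require mu_a > sigma_a > 0, got mu_a={self.mu_a}, sigma_a={self.sigma_a}"
            )
        if self.sigma_b <= 0.0:
            raise ValueError(f"sigma_b must be > 0, got {self.sigma_b}")

    @property
    def free_names(self) -> tuple[str, ...]:
        """Names of the free parameters under this variant."""
        base = ["n", "tau_D", "tau_F", "p0", "p1", "mu_a", "sigma_a", "sigma_b"]
        if self.variant is not Variant.DEPRESSION_FACILITATION:
            base.remove("p1")
        return tuple(base)

    def replace(self, **kwargs) -> "ModelParams":
        d = {
            "n": self.n,
            "tau_D": self.tau_D,
            "tau_F": self.tau_F,
            "p0": self.p0,
            "p1": self.p1,
            "mu_a": self.mu_a,
            "sigma_a": self.sigma_a,
            "sigma_b": self.sigma_b,
            "variant": self.variant,
        }
        d.update(kwargs)
        if Variant(d["variant"]) is not Variant.DEPRESSION_FACILITATION and "p1" not in kwargs:
            d["p1"] = None
        return ModelParams(**d)


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered presynaptic action-potential times ``t_1 < ... < t_M`` (s)."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("spike train must be a non-empty 1-D sequence of times")
        if not np.all(np.isfinite(t)):
            raise ValueError("spike times must be finite")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("spike times must be strictly increasing")
        t = t.copy()
        t.setflags(write=False)
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return self.times.size

    @property
    def intervals(self) -> np.ndarray:
        """Interspike intervals ``T_m = t_{m+1} - t_m`` (length M-1)."""
        return np.diff(self.times)


@dataclass(frozen=True)
class ReleaseSchedule:
    """Deterministic per-spike probabilities for a given (params, spikes).

    ``u_pre[m]`` is the release probability just before spike ``m+1``,
    ``u_post[m]`` just after, and ``g[m]`` the probability that an empty
    site is restocked during the interval following spike ``m+1``.
    Fields not produced by a partial computation are ``None``.
    """

    u_pre: np.ndarray | None = None
    u_post: np.ndarray | None = None
    g: np.ndarray | None = None


def release_probabilities(params: ModelParams, spikes: SpikeTrain) -> ReleaseSchedule:
    """Pre- and post-spike release probabilities ``u_m``, ``u_m^+``.

    The recursion is ``u_1 = p0``,
    ``u_m^+ = u_m + (1 - u_m) (p1 - p0) / (1 - p0)`` and
    ``u_{m+1} = p0 + (u_m^+ - p0) exp(-T_m / tau_F)``.
    """
    M = len(spikes)
    p0, p1, tau_F = params.p0, params.p1, params.tau_F
    jump = (p1 - p0) / (1.0 - p0)
    decay = np.exp(-spikes.intervals / tau_F) if M > 1 else np.empty(0)
    u_pre = np.empty(M)
    u_post = np.empty(M)
    u = p0
    for m in range(M):
        u_pre[m] = u
        up = u + (1.0 - u) * jump
        u_post[m] = up
        if m < M - 1:
            u = p0 + (up - p0) * decay[m]
    np.clip(u_pre, 0.0, 1.0, out=u_pre)
    np.clip(u_post, 0.0, 1.0, out=u_post)
    return ReleaseSchedule(u_pre=u_pre, u_post=u_post)


def restock_probabilities(params: ModelParams, spikes: SpikeTrain) -> ReleaseSchedule:
    """Per-interval restock probabilities ``g_m = 1 - exp(-T_m / tau_D)``."""
    g = -np.expm1(-spikes.intervals / params.tau_D)
    return ReleaseSchedule(g=g)


def schedule(params: ModelParams, spikes: SpikeTrain) -> ReleaseSchedule:
    """Full release/restock schedule (u_pre, u_post and g together)."""
    rel = release_probabilities(params, spikes)
    res = restock_probabilities(params, spikes)
    return ReleaseSchedule(u_pre=rel.u_pre, u_post=rel.u_post, g=res.g)


def mean_occupancy(params: ModelParams, spikes: SpikeTrain) -> tuple[np.ndarray, np.ndarray]:
    """Analytic mean single-site occupancy before and after each spike.

    Starts fully stocked (``<x>_1^- = 1``) and follows
    ``<x>_m^+ = <x>_m^- (1 - u_m)`` and
    ``<x>_{m+1}^- = 1 - (1 - <x>_m^+)(1 - g_m)``.

    Returns
    -------
    (before, after) : pair of arrays of length M
    """
    sched = schedule(params, spikes)
    M = len(spikes)
    before = np.empty(M)
    after = np.empty(M)
    x = 1.0
    for m in range(M):
        before[m] = x
        x = x * (1.0 - sched.u_pre[m])
        after[m] = x
        if m < M - 1:
            x = 1.0 - (1.0 - x) * (1.0 - sched.g[m])
    return before, after


def expected_amplitudes(params: ModelParams, spikes: SpikeTrain) -> np.ndarray:
    """Mean EPSP amplitude per spike: ``n * <x>_m^- * u_m * mu_a`` (mV)."""
    before, _ = mean_occupancy(params, spikes)
    u_pre = release_probabilities(params, spikes).u_pre
    return params.n * before * u_pre * params.mu_a
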