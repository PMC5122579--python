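"""Grid-discretized Metropolis-Hastings posterior sampling with flat priors.

Parameter space is a per-parameter grid (integer grid for ``n``, uniform or
log-spaced grids for continuous parameters); constraint predicates
(``p0 < p1``, ``mu_a > sigma_a``, ...) are enforced by rejecting invalid
grid points.  At each step one of the 2d axis-neighbor moves is proposed
with equal probability; off-grid or invalid proposals are rejected (the
chain stays put), otherwise the move is accepted with probability
``min(1, exp(delta log-likelihood))`` — flat priors make the prior ratio 1.

Log-likelihoods are cached per grid point (and the per-sweep schedule and
amplitude-density tables per relevant sub-tuple), which makes long chains
on modest grids cheap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Iterable, Literal, Mapping, Sequence

import numpy as np

from . import _kernels
from .amplitude import amplitude_density_table
from .dynamics import ModelParams, Variant, schedule
from .likelihood import Dataset

__all__ = [
    "PARAM_ORDER",
    "ParameterGrid",
    "Chain",
    "PosteriorSummary",
    "ConvergenceReport",
    "metropolis_hastings",
    "marginal_posterior",
    "pairwise_posterior",
    "map_estimate",
    "credible_interval",
    "convergence_check",
    "exhaustive_posterior",
    "summarize",
]

PARAM_ORDER = ("n", "tau_D", "tau_F", "p0", "p1", "mu_a", "sigma_a", "sigma_b")

_EXHAUSTIVE_GUARD = 10**6


class ParameterGrid:
    """Discretized parameter space for the grid sampler.

    Parameters
    ----------
    axes : mapping of parameter name to 1-D array of grid values.
        Parameters absent from ``axes`` must appear in ``clamps``.
        Single-value axes behave as clamps.
    clamps : mapping of parameter name to a fixed value.
    variant : model variant; tied variants (``depression_only``,
        ``facilitation_doubling``) derive ``p1`` and must not list it.
    """

    def __init__(
        self,
        axes: Mapping[str, Sequence[float]],
        clamps: Mapping[str, float] | None = None,
        variant: Variant | str = Variant.DEPRESSION_FACILITATION,
    ) -> None:
        self.variant = Variant(variant)
        clamps = dict(clamps or {})
        tied_p1 = self.variant is not Variant.DEPRESSION_FACILITATION
        expected = [p for p in PARAM_ORDER if not (p == "p1" and tied_p1)]
        unknown = (set(axes) | set(clamps)) - set(expected)
        if unknown:
            raise ValueError(f"unknown or tied parameter(s) in grid: {sorted(unknown)}")
        self.axes: dict[str, np.ndarray] = {}
        for name in expected:
            if name in axes:
                vals = np.asarray(axes[name], dtype=float)
                if name in clamps:
                    raise ValueError(f"parameter {name!r} both gridded and clamped")
            elif name in clamps:
                vals = np.asarray([clamps[name]], dtype=float)
            else:
                raise ValueError(f"parameter {name!r} missing from grid")
            if vals.ndim != 1 or vals.size == 0:
                raise ValueError(f"axis {name!r} must be a non-empty 1-D array")
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"axis {name!r} has non-finite values")
            if vals.size > 1 and not np.all(np.diff(vals) > 0):
                raise ValueError(f"axis {name!r} must be strictly increasing")
            self.axes[name] = vals
        self.names = tuple(self.axes)
        self.shape = tuple(len(self.axes[p]) for p in self.names)
        self.free_names = tuple(p for p in self.names if len(self.axes[p]) > 1)
        self._free_idx = tuple(self.names.index(p) for p in self.free_names)

    @classmethod
    def default(cls, variant: Variant | str = Variant.DEPRESSION_FACILITATION) -> "ParameterGrid":
        """Broad default grid spanning physiologically plausible values."""
        axes = {
            "n": np.arange(1, 51, dtype=float),
            "tau_D": np.geomspace(0.02, 2.0, 40),
            "tau_F": np.geomspace(0.02, 2.0, 40),
            "p0": np.arange(0.05, 0.951, 0.05),
            "mu_a": np.linspace(0.02, 1.0, 30),
            "sigma_a": np.linspace(0.01, 0.5, 30),
            "sigma_b": np.linspace(0.005, 0.3, 30),
        }
        if Variant(variant) is Variant.DEPRESSION_FACILITATION:
            axes["p1"] = np.arange(0.05, 0.951, 0.05)
        return cls(axes=axes, variant=variant)

    @property
    def size(self) -> int:
        return int(np.prod(self.shape))

    def values(self, name: str) -> np.ndarray:
        if name not in self.axes:
            raise KeyError(f"unknown parameter {name!r}")
        return self.axes[name]

    def point(self, idx: Sequence[int]) -> dict[str, float]:
        if len(idx) != len(self.names):
            raise ValueError(f"index must have {len(self.names)} entries, got {len(idx)}")
        return {p: float(self.axes[p][i]) for p, i in zip(self.names, idx)}

    def params_at(self, idx: Sequence[int]) -> ModelParams:
        """Build ModelParams at a grid index; raises ValueError if invalid."""
        pt = self.point(idx)
        pt["n"] = int(round(pt["n"]))
        return ModelParams(variant=self.variant, **pt)

    def is_valid(self, idx: Sequence[int]) -> bool:
        try:
            self.params_at(idx)
            return True
        except (ValueError, IndexError):
            return False

    def random_valid_index(self, rng: np.random.Generator, max_tries: int = 10_000) -> tuple[int, ...]:
        for _ in range(max_tries):
            idx = tuple(int(rng.integers(s)) for s in self.shape)
            if self.is_valid(idx):
                return idx
        # rejection sampling failed; fall back to explicit enumeration
        valid = [idx for idx in self.iter_indices() if self.is_valid(idx)]
        if not valid:
            raise ValueError("grid contains no valid parameter combination")
        return valid[int(rng.integers(len(valid)))]

    def iter_indices(self) -> Iterable[tuple[int, ...]]:
        return itertools.product(*(range(s) for s in self.shape))


@dataclass
class Chain:
    """Post-burn-in MCMC sample path over the grid."""

    grid: ParameterGrid
    indices: np.ndarray  # (kept, n_params) int
    logliks: np.ndarray  # (kept,)
    seed: int
    acceptance_count: int
    n_samples: int
    burn_in: int
    mode: str = "correlated"

    def __len__(self) -> int:
        return self.indices.shape[0]

    def values(self, name: str) -> np.ndarray:
        j = self.grid.names.index(name)
        return self.grid.axes[name][self.indices[:, j]]


class _CachedLoglik:
    """Per-grid-point dataset log-likelihood with sub-tuple caching.

    Caches (i) the release/restock schedules per dynamics sub-tuple,
    (ii) amplitude-density tables per quantal sub-tuple (computed once up
    to the grid's largest n and sliced), and (iii) the final log-likelihood
    per full index tuple.
    """

    def __init__(self, dataset: Dataset, grid: ParameterGrid, mode: str) -> None:
        if mode not in ("correlated", "uncorrelated"):
            raise ValueError(f"unknown mode {mode!r}")
        self.dataset = dataset
        self.grid = grid
        self.mode = mode
        self.n_max = int(round(grid.axes["n"].max()))
        self.pascal = _kernels.pascal_table(self.n_max)
        self._dyn_names = tuple(
            p for p in ("tau_D", "tau_F", "p0", "p1") if p in grid.names
        )
        self._quant_names = ("mu_a", "sigma_a", "sigma_b")
        self._dyn_pos = tuple(grid.names.index(p) for p in self._dyn_names)
        self._quant_pos = tuple(grid.names.index(p) for p in self._quant_names)
        self._sched_cache: dict[tuple, list] = {}
        self._dens_cache: dict[tuple, list] = {}
        self._ll_cache: dict[tuple, float] = {}
        self.n_evals = 0

    def _schedules(self, key: tuple, params: ModelParams) -> list:
        out = self._sched_cache.get(key)
        if out is None:
            out = [schedule(params, sw.spikes) for sw in self.dataset]
            self._sched_cache[key] = out
        return out

    def _densities(self, key: tuple, params: ModelParams) -> list:
        out = self._dens_cache.get(key)
        if out is None:
            out = [
                amplitude_density_table(sw.amplitudes, self.n_max, params)
                for sw in self.dataset
            ]
            self._dens_cache[key] = out
        return out

    def __call__(self, idx: tuple[int, ...]) -> float:
        ll = self._ll_cache.get(idx)
        if ll is not None:
            return ll
        params = self.grid.params_at(idx)
        dyn_key = tuple(idx[p] for p in self._dyn_pos)
        quant_key = tuple(idx[p] for p in self._quant_pos)
        scheds = self._schedules(dyn_key, params)
        denss = self._densities(quant_key, params)
        n = params.n
        kernel = (
            _kernels.forward_loglik
            if self.mode == "correlated"
            else _kernels.forward_loglik_uncorrelated
        )
        ll = 0.0
        for sched, dens in zip(scheds, denss):
            ll += kernel(dens[:, : n + 1], sched.u_pre, sched.g, n, self.pascal)
            if ll == -np.inf:
                break
        ll = float(ll)
        self._ll_cache[idx] = ll
        self.n_evals += 1
        return ll


def metropolis_hastings(
    dataset: Dataset | None,
    grid: ParameterGrid,
    mode: Literal["correlated", "uncorrelated"] = "correlated",
    n_samples: int = 100_000,
    burn_in: int | None = None,
    seed: int = 0,
    init_index: Sequence[int] | None = None,
    loglik_fn: Callable[[tuple[int, ...]], float] | None = None,
) -> Chain:
    """Sample the grid posterior by axis-neighbor Metropolis-Hastings.

    ``loglik_fn`` (index tuple -> float) may be supplied instead of a
    dataset, e.g. for synthetic likelihood surfaces in tests.
    ``burn_in`` defaults to 10% of ``n_samples``.  Identical seeds produce
    identical chains.
    """
    if burn_in is None:
        burn_in = n_samples // 10
    if not (n_samples > burn_in >= 0):
        raise ValueError("need n_samples > burn_in >= 0")
    if loglik_fn is None:
        if dataset is None:
            raise ValueError("need a dataset or a loglik_fn")
        loglik_fn = _CachedLoglik(dataset, grid, mode)
    d = len(grid.free_names)
    rng = np.random.default_rng(seed)
    if init_index is None:
        idx = list(grid.random_valid_index(rng))
    else:
        idx = list(init_index)
        if len(idx) != len(grid.names) or not grid.is_valid(idx):
            raise ValueError("init_index is not a valid grid point")
    cur_ll = loglik_fn(tuple(idx))
    free_axes = grid._free_idx
    kept = n_samples - burn_in
    out_idx = np.empty((kept, len(grid.names)), dtype=np.int64)
    out_ll = np.empty(kept)
    accepted = 0

    if d == 0:  # fully clamped grid: the chain is constant
        out_idx[:] = idx
        out_ll[:] = cur_ll
        return Chain(
            grid=grid,
            indices=out_idx,
            logliks=out_ll,
            seed=seed,
            acceptance_count=0,
            n_samples=n_samples,
            burn_in=burn_in,
            mode=mode,
        )

    block = 65536
    step = 0
    while step < n_samples:
        nb = min(block, n_samples - step)
        ax_draw = rng.integers(0, d, size=nb)
        dir_draw = rng.integers(0, 2, size=nb) * 2 - 1
        log_u = np.log(rng.random(size=nb))
        for b in range(nb):
            a = free_axes[ax_draw[b]]
            j = idx[a] + dir_draw[b]
            if 0 <= j < grid.shape[a]:
                old = idx[a]
                idx[a] = j
                t = tuple(idx)
                if grid.is_valid(t):
                    new_ll = loglik_fn(t)
                    if new_ll - cur_ll > log_u[b]:
                        cur_ll = new_ll
                        accepted += 1
                    else:
                        idx[a] = old
                else:
                    idx[a] = old
            if step >= burn_in:
                out_idx[step - burn_in] = idx
                out_ll[step - burn_in] = cur_ll
            step += 1
    return Chain(
        grid=grid,
        indices=out_idx,
        logliks=out_ll,
        seed=seed,
        acceptance_count=accepted,
        n_samples=n_samples,
        burn_in=burn_in,
        mode=mode,
    )


def marginal_posterior(chain: Chain, param: str) -> tuple[np.ndarray, np.ndarray]:
    """Normalized visit frequencies over one parameter's grid values."""
    if len(chain) == 0:
        raise ValueError("empty chain")
    grid = chain.grid
    if param not in grid.names:
        raise KeyError(f"unknown parameter {param!r}")
    j = grid.names.index(param)
    counts = np.bincount(chain.indices[:, j], minlength=grid.shape[j]).astype(float)
    return grid.axes[param], counts / counts.sum()


def pairwise_posterior(chain: Chain, param_a: str, param_b: str) -> np.ndarray:
    """Normalized 2-D visit-frequency histogram over two parameter grids."""
    if len(chain) == 0:
        raise ValueError("empty chain")
    grid = chain.grid
    ja = grid.names.index(param_a)
    jb = grid.names.index(param_b)
    hist = np.zeros((grid.shape[ja], grid.shape[jb]))
    np.add.at(hist, (chain.indices[:, ja], chain.indices[:, jb]), 1.0)
    return hist / hist.sum()


def map_estimate(chain: Chain) -> dict[str, float]:
    """Visited grid point with the highest log-likelihood (first occurrence)."""
    if len(chain) == 0:
        raise ValueError("empty chain")
    best = int(np.argmax(chain.logliks))
    return chain.grid.point(chain.indices[best])


def credible_interval(chain: Chain, param: str, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed credible interval of the marginal grid histogram.

    Smallest grid span holding >= ``level`` mass with at most
    ``(1-level)/2`` strictly outside on each side (tails rounded outward).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    values, probs = marginal_posterior(chain, param)
    return _interval_from_hist(values, probs, level)


def _interval_from_hist(values: np.ndarray, probs: np.ndarray, level: float) -> tuple[float, float]:
    tail = (1.0 - level) / 2.0
    cum = np.cumsum(probs)
    below = cum - probs  # mass strictly before each point
    above = 1.0 - cum  # mass strictly after each point
    eps = 1e-12
    lo_candidates = np.nonzero(below <= tail + eps)[0]
    hi_candidates = np.nonzero(above <= tail + eps)[0]
    lo = int(lo_candidates[-1])
    hi = int(hi_candidates[0])
    if hi < lo:
        lo = hi = int(np.argmax(probs))
    return float(values[lo]), float(values[hi])


@dataclass
class ConvergenceReport:
    """Pairwise total-variation distances between chain marginals."""

    tv_distance: dict[str, float]
    threshold: float
    passed: bool


def convergence_check(chains: Sequence[Chain], threshold: float = 0.1) -> ConvergenceReport:
    """Max pairwise TV distance per free parameter, with a pass/fail flag."""
    if len(chains) < 2:
        raise ValueError("convergence check needs at least 2 chains")
    grid = chains[0].grid
    tv: dict[str, float] = {}
    for p in grid.free_names:
        hists = [marginal_posterior(c, p)[1] for c in chains]
        worst = 0.0
        for i in range(len(hists)):
            for j in range(i + 1, len(hists)):
                worst = max(worst, 0.5 * float(np.abs(hists[i] - hists[j]).sum()))
        tv[p] = worst
    passed = all(v < threshold for v in tv.values())
    return ConvergenceReport(tv_distance=tv, threshold=threshold, passed=passed)


@dataclass
class ExhaustivePosterior:
    """Fully normalized posterior over every valid grid point."""

    grid: ParameterGrid
    log_post: np.ndarray  # full grid shape; -inf at invalid points
    post: np.ndarray  # normalized probabilities, same shape

    def marginal(self, param: str) -> tuple[np.ndarray, np.ndarray]:
        j = self.grid.names.index(param)
        axes = tuple(i for i in range(len(self.grid.names)) if i != j)
        return self.grid.axes[param], self.post.sum(axis=axes)

    def map_point(self) -> dict[str, float]:
        idx = np.unravel_index(int(np.argmax(self.post)), self.post.shape)
        return self.grid.point(idx)

    def interval(self, param: str, level: float = 0.95) -> tuple[float, float]:
        values, probs = self.marginal(param)
        return _interval_from_hist(values, probs, level)


def exhaustive_posterior(
    dataset: Dataset | None,
    grid: ParameterGrid,
    mode: Literal["correlated", "uncorrelated"] = "correlated",
    loglik_fn: Callable[[tuple[int, ...]], float] | None = None,
) -> ExhaustivePosterior:
    """Normalized posterior over the whole grid (guard: <= 10^6 points)."""
    if grid.size > _EXHAUSTIVE_GUARD:
        raise ValueError(f"grid size {grid.size} exceeds exhaustive guard {_EXHAUSTIVE_GUARD}")
    if loglik_fn is None:
        if dataset is None:
            raise ValueError("need a dataset or a loglik_fn")
        loglik_fn = _CachedLoglik(dataset, grid, mode)
    log_post = np.full(grid.shape, -np.inf)
    for idx in grid.iter_indices():
        if grid.is_valid(idx):
            log_post[idx] = loglik_fn(tuple(idx))
    m = log_post.max()
    if not np.isfinite(m):
        raise ValueError("no valid grid point has finite likelihood")
    post = np.exp(log_post - m)
    post /= post.sum()
    return ExhaustivePosterior(grid=grid, log_post=log_post, post=post)


@dataclass
class PosteriorSummary:
    """Marginals, MAP estimates and credible intervals from a chain."""

    level: float
    marginals: dict[str, tuple[list[float], list[float]]]
    map_joint: dict[str, float]
    map_marginal: dict[str, float]
    intervals: dict[str, tuple[float, float]]
    acceptance_rate: float
    n_kept: int

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "marginals": {k: [list(v[0]), list(v[1])] for k, v in self.marginals.items()},
            "map_joint": self.map_joint,
            "map_marginal": self.map_marginal,
            "intervals": {k: list(v) for k, v in self.intervals.items()},
            "acceptance_rate": self.acceptance_rate,
            "n_kept": self.n_kept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PosteriorSummary":
        return cls(
            level=d["level"],
            marginals={k: (list(v[0]), list(v[1])) for k, v in d["marginals"].items()},
            map_joint={k: float(v) for k, v in d["map_joint"].items()},
            map_marginal={k: float(v) for k, v in d["map_marginal"].items()},
            intervals={k: (float(v[0]), float(v[1])) for k, v in d["intervals"].items()},
            acceptance_rate=d["acceptance_rate"],
            n_kept=d["n_kept"],
        )


def summarize(chain: Chain, level: float = 0.95) -> PosteriorSummary:
    """Posterior summary: marginals, joint and per-marginal MAP, intervals."""
    marginals = {}
    map_marginal = {}
    intervals = {}
    for p in chain.grid.free_names:
        values, probs = marginal_posterior(chain, p)
        marginals[p] = (list(map(float, values)), list(map(float, probs)))
        map_marginal[p] = float(values[int(np.argmax(probs))])
        intervals[p] = _interval_from_hist(values, probs, level)
    return PosteriorSummary(
        level=level,
        marginals=marginals,
        map_joint=map_estimate(chain),
        map_marginal=map_marginal,
        intervals=intervals,
        acceptance_rate=chain.acceptance_count / chain.n_samples,
        n_kept=len(chain),
    )
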