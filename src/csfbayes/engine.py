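"""Gridded 5-D Bayesian posterior over CSF parameters.

The parameter vector theta = (M, A, F, beta, delta) is discretized on a
tensor-product grid in log10 space (default [32, 32, 32, 8, 8] nodes; the
guess rate gamma is a fixed design constant, 1/2 for 2AFC).  The prior is a
diagonal-covariance normal in log10 space, evaluated on the nodes and
renormalized.  Each binary trial multiplies the mass by the Bernoulli
likelihood P^r (1-P)^(1-r), with P the 2-D psychometric probability at the
trial stimulus for every node's theta, followed by renormalization.  The
point estimate is the vector of marginal posterior means in log10 space,
exponentiated back to linear scale.

Sequential updates renormalize after every trial, so per-node underflow can
only occur at nodes whose posterior mass is already negligible; a zero total
mass (all nodes impossible) raises :class:`DegenerateposteriorError`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .model import GAMMA_2AFC, ObserverParams, Stimulus, csf_sensitivity

__all__ = [
    "EngineConfig",
    "ParameterGrid",
    "Posterior",
    "TrialRecord",
    "PointEstimate",
    "DegeneratePosteriorError",
    "build_prior",
    "update",
    "infer",
    "point_estimate",
    "estimated_csf",
    "entropy",
    "likelihood_surface",
]

PARAM_NAMES = ("M", "A", "F", "beta", "delta")

DEFAULT_PRIOR_MEAN = (2.00, -0.30, 0.78, 0.62, -1.70)
#: The printed lapse-rate prior mean (-0.30 in log10, i.e. delta ~ 0.5) makes a
#: 2AFC observer uninformative at the prior center; the default above centers
#: the narrow nuisance prior near delta = 0.02 instead.  The alternative
#: remains available through ``EngineConfig(prior_mean=...)``.
PRINTED_DELTA_LOG10_MEAN = -0.30
DEFAULT_PRIOR_DIAG = (0.50, 0.50, 0.50, 0.11, 0.02)
DEFAULT_GRID_SIZES = (32, 32, 32, 8, 8)


class DegeneratePosteriorError(RuntimeError):
    """Raised when an update leaves zero total posterior mass."""


@dataclass(frozen=True)
class TrialRecord:
    """One trial: index, stimulus, and binary response (1 = detected)."""

    index: int
    stim: Stimulus
    response: int

    def __post_init__(self) -> None:
        if self.response not in (0, 1):
            raise ValueError("response must be 0 or 1")


@dataclass(frozen=True)
class EngineConfig:
    """Prior and discretization settings for the 5-D Bayes engine.

    ``prior_diag`` is read as per-axis standard deviations by default, which
    keeps the nuisance (beta, delta) priors narrow; set
    ``diag_is_variance=True`` to interpret the entries as variances instead.
    Each grid axis spans the prior mean +/- ``span_sd`` prior standard
    deviations, linearly spaced in log10, endpoints included.
    """

    prior_mean: tuple = DEFAULT_PRIOR_MEAN
    prior_diag: tuple = DEFAULT_PRIOR_DIAG
    diag_is_variance: bool = False
    grid_sizes: tuple = DEFAULT_GRID_SIZES
    span_sd: float = 2.5
    gamma: float = GAMMA_2AFC

    @property
    def prior_sd(self) -> np.ndarray:
        d = np.asarray(self.prior_diag, dtype=float)
        return np.sqrt(d) if self.diag_is_variance else d


class ParameterGrid:
    """Tensor-product log10 grid over (M, A, F, beta, delta).

    Caches, per spatial frequency, the log-sensitivity ln S(f) evaluated on
    the flattened (M, A, F) sub-grid — the only stimulus-dependent part of
    the likelihood exponent shared across beta and delta nodes.
    """

    def __init__(self, axes: Sequence[np.ndarray], gamma: float = GAMMA_2AFC):
        if len(axes) != 5:
            raise ValueError("expected 5 axes (log10 M, A, F, beta, delta)")
        self.axes = [np.asarray(a, dtype=float) for a in axes]
        for a in self.axes:
            if a.ndim != 1 or (a.size > 1 and np.any(np.diff(a) <= 0)):
                raise ValueError("axes must be strictly increasing 1-D arrays")
        self.sizes = tuple(a.size for a in self.axes)
        self.gamma = float(gamma)
        self.linear_axes = [10.0 ** a for a in self.axes]
        self._ln_s_cache: dict[float, np.ndarray] = {}
        # beta (linear) and per-delta dynamic range 1 - gamma - delta
        self.beta_lin = self.linear_axes[3]
        self.delta_lin = self.linear_axes[4]
        self.range_coef = 1.0 - self.gamma - self.delta_lin

    @classmethod
    def from_config(cls, config: EngineConfig) -> "ParameterGrid":
        mean = np.asarray(config.prior_mean, dtype=float)
        sd = config.prior_sd
        if mean.size != 5 or sd.size != 5 or len(config.grid_sizes) != 5:
            raise ValueError("prior mean/diag and grid sizes must have 5 entries")
        axes = [
            np.linspace(m - config.span_sd * s, m + config.span_sd * s, n)
            for m, s, n in zip(mean, sd, config.grid_sizes)
        ]
        return cls(axes, gamma=config.gamma)

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.sizes))

    def ln_sensitivity_maf(self, sf: float) -> np.ndarray:
        """ln S(f) = ln M + A ln f - f/F on the flattened (M, A, F) sub-grid."""
        key = float(sf)
        out = self._ln_s_cache.get(key)
        if out is None:
            lnM = np.log(self.linear_axes[0])[:, None, None]
            A = self.linear_axes[1][None, :, None]
            invF = 1.0 / self.linear_axes[2][None, None, :]
            out = np.ascontiguousarray(
                (lnM + A * math.log(key) - key * invF).ravel()
            )
            self._ln_s_cache[key] = out
        return out


@dataclass
class Posterior:
    """Probability mass on a :class:`ParameterGrid`; sums to 1."""

    grid: ParameterGrid
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.mass = np.ascontiguousarray(self.mass, dtype=float)
        if self.mass.shape != self.grid.sizes:
            raise ValueError("mass shape does not match grid sizes")

    def copy(self) -> "Posterior":
        return Posterior(self.grid, self.mass.copy())

    def normalize(self) -> None:
        total = self.mass.sum()
        if not total > 0 or not np.isfinite(total):
            raise DegeneratePosteriorError("posterior mass is zero or non-finite")
        self.mass /= total

    def marginal(self, axis: int) -> np.ndarray:
        other = tuple(i for i in range(5) if i != axis)
        return self.mass.sum(axis=other)


@njit(cache=True, fastmath=True)
def _bernoulli_update(mass, ln_s_maf, beta, coef, gamma, lnc, response):
    """In-place multiply of mass (nMAF, nb, nd) by P^r (1-P)^(1-r); returns total."""
    total = 0.0
    for i in range(mass.shape[0]):
        y = lnc + ln_s_maf[i]  # ln c - ln alpha
        for j in range(beta.shape[0]):
            z = beta[j] * y
            if z < -700.0:
                L = 0.0
            elif z > 700.0:
                L = 1.0
            else:
                L = 1.0 / (1.0 + math.exp(-z))
            for d in range(coef.shape[0]):
                P = gamma + coef[d] * L
                if response == 0:
                    P = 1.0 - P
                m = mass[i, j, d] * P
                mass[i, j, d] = m
                total += m
    return total


def build_prior(config: EngineConfig | None = None, *, grid: ParameterGrid | None = None,
                uniform: bool = False) -> Posterior:
    """Evaluate the diagonal log10-normal prior on the grid and normalize.

    With ``uniform=True`` every node receives equal mass instead (useful for
    sensitivity checks).  The diagonal covariance makes the density separable,
    so it is built as an outer product of 1-D normal densities.
    """
    config = config or EngineConfig()
    if grid is None:
        grid = ParameterGrid.from_config(config)
    if uniform:
        mass = np.full(grid.sizes, 1.0 / grid.n_nodes)
        return Posterior(grid, mass)
    mean = np.asarray(config.prior_mean, dtype=float)
    sd = config.prior_sd
    dens = [
        np.exp(-0.5 * ((ax - m) / s) ** 2)
        for ax, m, s in zip(grid.axes, mean, sd)
    ]
    mass = np.einsum("i,j,k,l,m->ijklm", *dens)
    post = Posterior(grid, mass)
    post.normalize()
    return post


def update(post: Posterior, trial: TrialRecord, *, in_place: bool = False) -> Posterior:
    """One Bayes step: multiply by the Bernoulli likelihood and renormalize."""
    out = post if in_place else post.copy()
    grid = out.grid
    flat = out.mass.reshape(-1, grid.sizes[3], grid.sizes[4])
    total = _bernoulli_update(
        flat,
        grid.ln_sensitivity_maf(trial.stim.sf),
        grid.beta_lin,
        grid.range_coef,
        grid.gamma,
        math.log(trial.stim.contrast),
        int(trial.response),
    )
    if not total > 0 or not np.isfinite(total):
        raise DegeneratePosteriorError("zero total mass after likelihood update")
    out.mass /= total
    return out


def infer(trials: Iterable[TrialRecord], config: EngineConfig | None = None, *,
          grid: ParameterGrid | None = None, prior: Posterior | None = None) -> Posterior:
    """Fold :func:`update` over a trial log, starting from the prior.

    The likelihood factorizes over trials, so the result is invariant to
    trial order; an empty log returns the prior itself.
    """
    post = (prior.copy() if prior is not None
            else build_prior(config, grid=grid))
    for trial in trials:
        update(post, trial, in_place=True)
    return post


@dataclass(frozen=True)
class PointEstimate:
    """Posterior-MEAN estimate: log10 marginal means and linear parameters."""

    log10_means: np.ndarray
    params: ObserverParams

    def as_dict(self) -> dict:
        return {
            "log10_means": {n: float(v) for n, v in zip(PARAM_NAMES, self.log10_means)},
            "params": {
                "M": self.params.M, "A": self.params.A, "F": self.params.F,
                "beta": self.params.beta, "gamma": self.params.gamma,
                "delta": self.params.delta,
            },
        }


def point_estimate(post: Posterior) -> PointEstimate:
    """Marginal posterior means per log10 axis, exponentiated to linear scale."""
    # staged reductions: two full-grid passes instead of five
    m = post.mass
    s4 = m.sum(axis=4)                      # (nM, nA, nF, nb)
    marg_delta = m.reshape(-1, m.shape[4]).sum(axis=0)
    marg_beta = s4.sum(axis=(0, 1, 2))
    s34 = s4.sum(axis=3)                    # (nM, nA, nF)
    marginals = [s34.sum(axis=(1, 2)), s34.sum(axis=(0, 2)),
                 s34.sum(axis=(0, 1)), marg_beta, marg_delta]
    means = np.array([
        float(marg @ ax) for marg, ax in zip(marginals, post.grid.axes)
    ])
    lin = 10.0 ** means
    params = ObserverParams(M=lin[0], A=lin[1], F=lin[2], beta=lin[3],
                            gamma=post.grid.gamma, delta=lin[4])
    return PointEstimate(log10_means=means, params=params)


def estimated_csf(post: Posterior, sfs: Sequence[float]) -> np.ndarray:
    """CSF sensitivity S(f) at the posterior point estimate, per requested sf."""
    p = point_estimate(post).params
    return np.asarray(csf_sensitivity(np.asarray(sfs, dtype=float), p.M, p.A, p.F))


def entropy(post: Posterior) -> float:
    """Shannon entropy (nats) of the posterior mass."""
    m = post.mass[post.mass > 0]
    return float(-(m * np.log(m)).sum())


def likelihood_surface(grid: ParameterGrid, stim: Stimulus) -> np.ndarray:
    """P(stim | theta) for every grid node, shaped like the posterior mass.

    Pure-numpy companion to the sequential update kernel; used for batch
    (joint-likelihood) computations and by entropy-based stimulus scoring.
    """
    y = math.log(stim.contrast) + grid.ln_sensitivity_maf(stim.sf)  # (nMAF,)
    z = y[:, None] * grid.beta_lin[None, :]
    with np.errstate(over="ignore"):
        L = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.clip(z, 0, None))),
                     np.exp(np.clip(z, None, 0)) / (1.0 + np.exp(np.clip(z, None, 0))))
    P = grid.gamma + L[:, :, None] * grid.range_coef[None, None, :]
    return P.reshape(grid.sizes)
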