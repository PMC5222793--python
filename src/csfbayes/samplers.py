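"""Adaptive stimulus-selection strategies over the shared stimulus grid.

Four methods share one propose/observe contract:

* ``StaircaseSampler`` — 12 randomly interleaved weighted up-down staircases
  (one per spatial frequency); contrast steps up ~33% (x4/3) after a miss
  and down 10% (x0.9) after a hit, with cubed factors on each staircase's
  first four trials.  The step ratio places the convergence point near the
  p* = ln(4/3)/(ln(4/3)+ln(10/9)) ~ 0.73 detection probability.
* ``PsiSampler`` — 12 interleaved independent Bayesian runs, each holding a
  2-D (log10 threshold, log10 slope) posterior and picking the contrast that
  minimizes the expected posterior entropy.
* ``QcsfSampler`` — one 5-D CSF-parameter posterior; picks the (sf, contrast)
  pair over the whole 2-D stimulus grid that minimizes expected entropy.
* ``FigSampler`` — D-optimal one-step-ahead search: scores every candidate by
  the determinant of the accumulated Fisher information matrix plus the
  candidate's rank-one information at the current posterior-mean parameters,
  then draws uniformly among the top 10%.

Expected-entropy scores for Psi and qCSF use the exact identity
E[H(posterior | r)] = H(posterior) - I(r; theta), where the mutual
information is I = h(p1) - sum_theta p(theta) h(P(x, theta)) with h the
binary entropy and p1 the predictive probability of a positive response —
so minimizing expected entropy is maximizing I.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from . import engine as _eng
from .engine import (EngineConfig, Posterior, TrialRecord, build_prior,
                     likelihood_surface, point_estimate, update)
from .model import (GAMMA_2AFC, LN10, ObserverParams, Stimulus, StimulusGrid,
                    csf_sensitivity)

__all__ = [
    "StaircaseSampler",
    "PsiSampler",
    "QcsfSampler",
    "FigSampler",
    "make_sampler",
    "psi_threshold",
    "staircase_threshold",
    "prior_mean_params",
    "STAIRCASE_CONVERGENCE_P",
]

#: Detection probability at the weighted up-down equilibrium for the default
#: x4/3 up / x0.9 down steps.
STAIRCASE_CONVERGENCE_P = math.log(4 / 3) / (math.log(4 / 3) + math.log(10 / 9))

SAMPLER_NAMES = ("staircase", "psi", "qcsf", "fig")


def prior_mean_params(config: EngineConfig | None = None) -> ObserverParams:
    """Observer parameters at the prior mean (linear scale)."""
    config = config or EngineConfig()
    m = 10.0 ** np.asarray(config.prior_mean, dtype=float)
    return ObserverParams(M=m[0], A=m[1], F=m[2], beta=m[3],
                          gamma=config.gamma, delta=m[4])


def _interleave_schedule(n_sfs: int, budget: int, rng: np.random.Generator) -> np.ndarray:
    """Random interleaving with budget//n_sfs trials per sf; remainders are
    assigned to distinct spatial frequencies chosen uniformly at random."""
    counts = np.full(n_sfs, budget // n_sfs, dtype=int)
    rem = budget - counts.sum()
    if rem:
        counts[rng.choice(n_sfs, size=rem, replace=False)] += 1
    sched = np.repeat(np.arange(n_sfs), counts)
    rng.shuffle(sched)
    return sched


def _binary_entropy(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    ok = (p > 0) & (p < 1)
    q = p[ok]
    out[ok] = -q * np.log(q) - (1 - q) * np.log(1 - q)
    return out


def _choose_argmax(scores: np.ndarray, rng: np.random.Generator,
                   rtol: float = 1e-12) -> int:
    """Index of the maximum score; exact-precision ties broken uniformly."""
    top = scores.max()
    ties = np.flatnonzero(scores >= top - rtol * max(1.0, abs(top)))
    return int(ties[0]) if ties.size == 1 else int(rng.choice(ties))


class StaircaseSampler:
    """Randomly interleaved per-frequency weighted up-down staircases."""

    name = "staircase"

    def __init__(self, stim_grid: StimulusGrid, budget: int,
                 rng: np.random.Generator, *,
                 prior_params: ObserverParams | None = None,
                 up_factor: float = 4 / 3, down_factor: float = 0.9,
                 warmup_trials: int = 4):
        self.stim_grid = stim_grid
        self.budget = int(budget)
        self.rng = rng
        self.up = float(up_factor)
        self.down = float(down_factor)
        self.warmup = int(warmup_trials)
        prior_params = prior_params or prior_mean_params()
        s_prior = csf_sensitivity(stim_grid.sfs, prior_params.M, prior_params.A,
                                  prior_params.F)
        lo, hi = stim_grid.contrasts[0], stim_grid.contrasts[-1]
        # each staircase starts at the prior-estimated threshold 1/S_prior(f)
        self.level = np.clip(1.0 / s_prior, lo, hi)
        self.counts = np.zeros(stim_grid.n_sfs, dtype=int)
        self.log_history: list[list[float]] = [[] for _ in range(stim_grid.n_sfs)]
        self.schedule = _interleave_schedule(stim_grid.n_sfs, self.budget, rng)
        self._t = 0

    def propose(self) -> Stimulus:
        i = int(self.schedule[self._t])
        c = self.stim_grid.snap_contrast(self.level[i])
        return Stimulus(float(self.stim_grid.sfs[i]), c)

    def observe(self, trial: TrialRecord) -> None:
        i = self.stim_grid.sf_index(trial.stim.sf)
        self.counts[i] += 1
        self.log_history[i].append(math.log(trial.stim.contrast))
        factor = self.down if trial.response else self.up
        if self.counts[i] <= self.warmup:
            factor = factor ** 3
        lo, hi = self.stim_grid.contrasts[0], self.stim_grid.contrasts[-1]
        self.level[i] = min(max(self.level[i] * factor, lo), hi)
        self._t += 1

    def threshold(self, sf: float, *, strict: bool = True) -> float:
        """Sensitivity 1/exp(mean ln contrast), excluding the warmup trials.

        With ``strict=False`` a staircase shorter than ``warmup + 1`` trials
        excludes only its first ``n - 1`` trials instead of erroring, so
        budgets below 5 trials per frequency still yield an estimate (the
        last, most-converged level).
        """
        i = self.stim_grid.sf_index(sf)
        hist = self.log_history[i]
        tail = hist[self.warmup:]
        if not tail:
            if strict or not hist:
                raise ValueError(
                    f"staircase at sf={sf} needs more than {self.warmup} trials"
                )
            tail = hist[-1:]
        return 1.0 / math.exp(float(np.mean(tail)))

    def thresholds(self) -> np.ndarray:
        return np.array([self.threshold(f, strict=False)
                         for f in self.stim_grid.sfs])


class _PsiRun:
    """One spatial frequency's 2-D (log10 alpha, log10 beta) posterior."""

    def __init__(self, contrasts: np.ndarray, prior_alpha_mean: float, *,
                 alpha_var: float = 5.0, beta_mean: float = 0.62,
                 beta_var: float = 0.11, n_alpha: int = 64, n_beta: int = 8,
                 gamma: float = GAMMA_2AFC, delta: float = 0.02,
                 span_sd: float = 2.5):
        a_sd, b_sd = math.sqrt(alpha_var), math.sqrt(beta_var)
        lo = max(-3.0, prior_alpha_mean - span_sd * a_sd)
        hi = min(0.0, prior_alpha_mean + span_sd * a_sd)
        self.alpha_axis = np.linspace(lo, hi, n_alpha)
        self.beta_axis = np.linspace(beta_mean - span_sd * b_sd,
                                     beta_mean + span_sd * b_sd, n_beta)
        pa = np.exp(-0.5 * ((self.alpha_axis - prior_alpha_mean) / a_sd) ** 2)
        pb = np.exp(-0.5 * ((self.beta_axis - beta_mean) / b_sd) ** 2)
        w = np.outer(pa, pb).ravel()
        self.w = w / w.sum()
        # P(detect | c, alpha, beta) for every contrast x node, plus its
        # binary entropy — both fixed for the whole run
        lnc = np.log(contrasts)[:, None, None]
        lna = (LN10 * self.alpha_axis)[None, :, None]
        b = (10.0 ** self.beta_axis)[None, None, :]
        z = b * (lnc - lna)
        with np.errstate(over="ignore"):
            L = np.where(z >= 0, 1 / (1 + np.exp(-np.clip(z, 0, None))),
                         np.exp(np.clip(z, None, 0)) / (1 + np.exp(np.clip(z, None, 0))))
        n = contrasts.size
        self.P = (gamma + (1 - gamma - delta) * L).reshape(n, -1)
        self.HP = _binary_entropy(self.P)
        self.n_trials = 0

    def info_gain(self) -> np.ndarray:
        """Mutual information I(r; alpha, beta) per candidate contrast."""
        p1 = self.P @ self.w
        return _binary_entropy(p1) - self.HP @ self.w

    def propose_index(self, rng: np.random.Generator) -> int:
        return _choose_argmax(self.info_gain(), rng)

    def observe(self, c_index: int, response: int) -> None:
        lik = self.P[c_index] if response else 1.0 - self.P[c_index]
        self.w = self.w * lik
        self.w /= self.w.sum()
        self.n_trials += 1

    def threshold_sensitivity(self) -> float:
        """Reciprocal of the posterior-mean threshold: 10**(-mean log10 alpha)."""
        marg = self.w.reshape(self.alpha_axis.size, -1).sum(axis=1)
        return 10.0 ** (-float(marg @ self.alpha_axis))


class PsiSampler:
    """Interleaved per-frequency Bayesian threshold/slope (Psi) runs."""

    name = "psi"

    def __init__(self, stim_grid: StimulusGrid, budget: int,
                 rng: np.random.Generator, *,
                 prior_params: ObserverParams | None = None,
                 alpha_var: float = 5.0, beta_mean: float = 0.62,
                 beta_var: float = 0.11, n_alpha: int = 64, n_beta: int = 8,
                 delta: float = 0.02):
        self.stim_grid = stim_grid
        self.budget = int(budget)
        self.rng = rng
        prior_params = prior_params or prior_mean_params()
        s_prior = csf_sensitivity(stim_grid.sfs, prior_params.M, prior_params.A,
                                  prior_params.F)
        self.runs = [
            _PsiRun(stim_grid.contrasts, -math.log10(s), alpha_var=alpha_var,
                    beta_mean=beta_mean, beta_var=beta_var, n_alpha=n_alpha,
                    n_beta=n_beta, gamma=prior_params.gamma, delta=delta)
            for s in s_prior
        ]
        self.schedule = _interleave_schedule(stim_grid.n_sfs, self.budget, rng)
        self._t = 0

    def propose(self) -> Stimulus:
        i = int(self.schedule[self._t])
        ci = self.runs[i].propose_index(self.rng)
        return Stimulus(float(self.stim_grid.sfs[i]),
                        float(self.stim_grid.contrasts[ci]))

    def observe(self, trial: TrialRecord) -> None:
        i = self.stim_grid.sf_index(trial.stim.sf)
        ci = int(np.argmin(np.abs(np.log10(self.stim_grid.contrasts)
                                  - math.log10(trial.stim.contrast))))
        self.runs[i].observe(ci, trial.response)
        self._t += 1

    def threshold(self, sf: float) -> float:
        run = self.runs[self.stim_grid.sf_index(sf)]
        if run.n_trials < 1:
            raise ValueError(f"psi run at sf={sf} has no trials")
        return run.threshold_sensitivity()

    def thresholds(self) -> np.ndarray:
        return np.array([self.threshold(f) for f in self.stim_grid.sfs])


@njit(cache=True, fastmath=True)
def _qcsf_predictives(mass, ln_s_table, sf_idx, lnc, beta, coef, gamma):
    """Per-candidate predictive p1 and posterior-averaged binary entropy.

    mass: (nMAF, nb, nd) posterior; ln_s_table: (n_sfs, nMAF) cached ln S(f);
    candidates given by (sf_idx, lnc).  Returns (p1, sum_theta p*h(P)).
    """
    k = lnc.shape[0]
    p1 = np.zeros(k)
    hterm = np.zeros(k)
    for c in range(k):
        ln_s = ln_s_table[sf_idx[c]]
        acc_p = 0.0
        acc_h = 0.0
        for i in range(mass.shape[0]):
            y = lnc[c] + ln_s[i]
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
                    m = mass[i, j, d]
                    acc_p += m * P
                    if 0.0 < P < 1.0:
                        acc_h -= m * (P * math.log(P)
                                      + (1.0 - P) * math.log(1.0 - P))
        p1[c] = acc_p
        hterm[c] = acc_h
    return p1, hterm


class QcsfSampler:
    """Expected-entropy-minimizing 2-D sampler over the 5-D CSF posterior.

    Stimulus selection runs on its own (by default coarser) parameter grid to
    keep the per-trial candidate sweep affordable; the reported CSF estimate
    is always a full-resolution Bayesian re-fit of the collected log, matching
    the study workflow.  ``selection_grid_sizes=None`` selects on the full
    inference grid; ``candidate_subsample`` restricts each trial's sweep to a
    random subset of the stimulus grid (0 or None sweeps every candidate).
    """

    name = "qcsf"

    DEFAULT_SELECTION_GRID = (12, 12, 12, 4, 4)

    def __init__(self, stim_grid: StimulusGrid, budget: int,
                 rng: np.random.Generator, *,
                 engine_config: EngineConfig | None = None,
                 selection_grid_sizes: tuple | None = DEFAULT_SELECTION_GRID,
                 candidate_subsample: int | None = 40):
        self.stim_grid = stim_grid
        self.budget = int(budget)
        self.rng = rng
        base = engine_config or EngineConfig()
        if selection_grid_sizes is not None:
            base = EngineConfig(prior_mean=base.prior_mean, prior_diag=base.prior_diag,
                                diag_is_variance=base.diag_is_variance,
                                grid_sizes=tuple(selection_grid_sizes),
                                span_sd=base.span_sd, gamma=base.gamma)
        self.posterior: Posterior = build_prior(base)
        self.candidate_subsample = candidate_subsample
        self._stimuli = stim_grid.all_stimuli()
        # flat candidate arrays + cached ln S(f) rows for the scoring kernel
        self._cand_sf_idx = np.repeat(np.arange(stim_grid.n_sfs),
                                      stim_grid.n_contrasts)
        self._cand_lnc = np.tile(np.log(stim_grid.contrasts), stim_grid.n_sfs)
        grid = self.posterior.grid
        self._ln_s_table = np.stack(
            [grid.ln_sensitivity_maf(float(f)) for f in stim_grid.sfs])

    def info_gain(self, stim: Stimulus) -> float:
        """Mutual information between the response at ``stim`` and theta."""
        P = likelihood_surface(self.posterior.grid, stim).ravel()
        w = self.posterior.mass.ravel()
        p1 = float(w @ P)
        return float(_binary_entropy(np.array(p1))
                     - w @ _binary_entropy(P))

    def expected_posterior_entropy(self, stim: Stimulus) -> float:
        """E over the response of the updated posterior's Shannon entropy."""
        return _eng.entropy(self.posterior) - self.info_gain(stim)

    def propose(self) -> Stimulus:
        n = len(self._stimuli)
        k = self.candidate_subsample
        idx = (self.rng.choice(n, size=k, replace=False)
               if k and k < n else np.arange(n))
        grid = self.posterior.grid
        mass = self.posterior.mass.reshape(-1, grid.sizes[3], grid.sizes[4])
        p1, hterm = _qcsf_predictives(
            mass, self._ln_s_table, self._cand_sf_idx[idx],
            self._cand_lnc[idx], grid.beta_lin, grid.range_coef, grid.gamma)
        scores = _binary_entropy(p1) - hterm
        return self._stimuli[int(idx[_choose_argmax(scores, self.rng)])]

    def observe(self, trial: TrialRecord) -> None:
        update(self.posterior, trial, in_place=True)


class FigSampler:
    """One-step-ahead D-optimal (max det Fisher information) sampler.

    The Fisher information of a Bernoulli trial at stimulus x is the rank-one
    matrix g g^T / (P (1 - P)) with g the gradient of P with respect to the
    four shape parameters (log10 M, A, F, beta) at the current posterior-mean
    theta; the lapse rate is treated as a nuisance and excluded.  A ridge of
    1e-8 I keeps the accumulated matrix invertible before any data arrive.
    """

    name = "fig"

    def __init__(self, stim_grid: StimulusGrid, budget: int,
                 rng: np.random.Generator, *,
                 engine_config: EngineConfig | None = None,
                 top_fraction: float = 0.10, ridge: float = 1e-8):
        self.stim_grid = stim_grid
        self.budget = int(budget)
        self.rng = rng
        self.config = engine_config or EngineConfig()
        self.posterior: Posterior = build_prior(self.config)
        self.top_fraction = float(top_fraction)
        self.J = ridge * np.eye(4)
        sfs = np.repeat(stim_grid.sfs, stim_grid.n_contrasts)
        cons = np.tile(stim_grid.contrasts, stim_grid.n_sfs)
        self._cand_sf = sfs
        self._cand_c = cons
        self._pending: dict[tuple[float, float], np.ndarray] = {}

    def _grad_and_p(self, theta: ObserverParams):
        """P and d P / d log10(M, A, F, beta) for every candidate stimulus."""
        f, c = self._cand_sf, self._cand_c
        u = np.log(c) + math.log(theta.M) + theta.A * np.log(f) - f / theta.F
        z = theta.beta * u
        with np.errstate(over="ignore"):
            L = np.where(z >= 0, 1 / (1 + np.exp(-np.clip(z, 0, None))),
                         np.exp(np.clip(z, None, 0)) / (1 + np.exp(np.clip(z, None, 0))))
        P = theta.gamma + (1 - theta.gamma - theta.delta) * L
        core = (1 - theta.gamma - theta.delta) * L * (1 - L) * LN10
        g = np.stack([
            np.full_like(z, theta.beta),
            theta.beta * theta.A * np.log(f),
            theta.beta * f / theta.F,
            z,
        ], axis=1) * core[:, None]
        return P, g

    def candidate_info(self, P: np.ndarray, g: np.ndarray) -> np.ndarray:
        """Per-candidate rank-one Fisher information matrices (n, 4, 4)."""
        w = 1.0 / np.maximum(P * (1.0 - P), 1e-300)
        return g[:, :, None] * g[:, None, :] * w[:, None, None]

    def propose(self) -> Stimulus:
        theta = point_estimate(self.posterior).params
        P, g = self._grad_and_p(theta)
        info = self.candidate_info(P, g)
        scores = np.linalg.det(self.J[None, :, :] + info)
        n = scores.size
        k = max(1, int(math.ceil(self.top_fraction * n)))
        top = np.argpartition(scores, n - k)[n - k:]
        pick = int(self.rng.choice(top))
        stim = Stimulus(float(self._cand_sf[pick]), float(self._cand_c[pick]))
        self._pending = {(stim.sf, stim.contrast): info[pick]}
        return stim

    def observe(self, trial: TrialRecord) -> None:
        key = (trial.stim.sf, trial.stim.contrast)
        info = self._pending.pop(key, None)
        if info is None:
            theta = point_estimate(self.posterior).params
            P, g = self._grad_and_p(theta)
            mask = (self._cand_sf == trial.stim.sf) & (self._cand_c == trial.stim.contrast)
            i = int(np.flatnonzero(mask)[0])
            info = self.candidate_info(P[i:i + 1], g[i:i + 1])[0]
        self.J = self.J + info
        update(self.posterior, trial, in_place=True)


def make_sampler(name: str, stim_grid: StimulusGrid, budget: int,
                 rng: np.random.Generator, **kwargs):
    """Factory over the four strategies; ``name`` in {staircase, psi, qcsf, fig}."""
    classes = {"staircase": StaircaseSampler, "psi": PsiSampler,
               "qcsf": QcsfSampler, "fig": FigSampler}
    try:
        cls = classes[name]
    except KeyError:
        raise ValueError(
            f"unknown sampler {name!r}; choose from {sorted(classes)}"
        ) from None
    return cls(stim_grid, budget, rng, **kwargs)


def psi_threshold(sampler: PsiSampler, sf: float) -> float:
    """Sensitivity estimate from a Psi run: 10**(-posterior-mean log10 alpha)."""
    return sampler.threshold(sf)


def staircase_threshold(sampler: StaircaseSampler, sf: float) -> float:
    """Sensitivity from the mean log contrast after the warmup trials."""
    return sampler.threshold(sf)
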