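"""Monte-Carlo harness and error metrics for the sampling/inference methods.

A single simulated session alternates sampler propose -> observer respond ->
sampler observe for a fixed trial budget, then summarizes the session as a
vector of per-spatial-frequency sensitivity estimates.  Six reported methods
arise from four sampling strategies:

===========  ==========  =====================================================
label        sampler     estimate
===========  ==========  =====================================================
fig          fig         5-D posterior mean (updated online during sampling)
qcsf         qcsf        full-grid 5-D Bayesian re-fit of the trial log
bayes-psi    psi         full-grid 5-D Bayesian re-fit of the same Psi log
psi          psi         per-frequency reciprocal posterior-mean threshold
bayes-stc    staircase   full-grid 5-D Bayesian re-fit of the same log
stc          staircase   per-frequency mean-log-contrast convergence estimate
===========  ==========  =====================================================

``bayes-psi``/``psi`` (and ``bayes-stc``/``stc``) are computed from the SAME
sampled trial logs, isolating the effect of the inference step.  Errors are
reported in sensitivity decibels, dB = 20 log10 S (a factor of 10 is
available for sensitivity analysis), pooled jointly across runs and spatial
frequencies: RMSE is the square root of one grand mean of squared dB errors,
bias the grand mean of signed dB errors (estimate minus truth).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .engine import EngineConfig, TrialRecord, estimated_csf, infer
from .model import ObserverParams, StimulusGrid, csf_sensitivities
from .observer import SimulatedObserver
from .samplers import make_sampler

__all__ = [
    "RunResult",
    "MetricsReport",
    "METHOD_LABELS",
    "run_experiment",
    "rmse_db",
    "bias_db",
    "aulcsf",
    "monte_carlo",
    "DB_FACTOR",
]

DB_FACTOR = 20.0

#: reported method label -> (sampling strategy, estimate key)
METHOD_LABELS = {
    "fig": ("fig", "bayes"),
    "qcsf": ("qcsf", "bayes"),
    "bayes-psi": ("psi", "bayes"),
    "psi": ("psi", "native"),
    "bayes-stc": ("staircase", "bayes"),
    "stc": ("staircase", "native"),
}


@dataclass
class RunResult:
    """One simulated session: trial log plus per-method sensitivity estimates."""

    method: str
    budget: int
    seed: int
    trials: list[TrialRecord]
    estimates: dict[str, np.ndarray]
    true_sens: np.ndarray
    sfs: np.ndarray

    def __post_init__(self) -> None:
        for key, est in self.estimates.items():
            est = np.asarray(est, dtype=float)
            if est.shape != self.sfs.shape or np.any(est <= 0):
                raise ValueError(f"estimate {key!r} must be positive per sf")
            self.estimates[key] = est

    def estimate(self, key: str | None = None) -> np.ndarray:
        if key is None:
            if len(self.estimates) != 1:
                raise ValueError(
                    f"multiple estimates {sorted(self.estimates)}; specify key")
            key = next(iter(self.estimates))
        return self.estimates[key]


def run_experiment(method: str, budget: int, observer: ObserverParams,
                   seed: int, *, stim_grid: StimulusGrid | None = None,
                   engine_config: EngineConfig | None = None,
                   bayes: bool = True,
                   sampler_kwargs: dict | None = None) -> RunResult:
    """Simulate one seeded session of ``budget`` trials with one sampler.

    The sampler and the observer draw from independent substreams spawned
    from ``seed``, so the response sequence at a given stimulus sequence does
    not depend on sampler-internal randomness.  With ``bayes=True`` the
    result includes the full-grid Bayesian estimate; Psi and staircase
    results additionally carry their native 1-D estimates.
    """
    stim_grid = stim_grid or StimulusGrid()
    ss = np.random.SeedSequence(seed)
    sampler_rng, observer_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    kwargs = dict(sampler_kwargs or {})
    if method in ("qcsf", "fig"):
        kwargs.setdefault("engine_config", engine_config)
    sampler = make_sampler(method, stim_grid, budget, sampler_rng, **kwargs)
    obs = SimulatedObserver(observer, observer_rng)
    trials: list[TrialRecord] = []
    for t in range(budget):
        stim = sampler.propose()
        trial = TrialRecord(index=t, stim=stim, response=obs.respond(stim))
        sampler.observe(trial)
        trials.append(trial)

    estimates: dict[str, np.ndarray] = {}
    if method in ("psi", "staircase"):
        estimates["native"] = sampler.thresholds()
    if bayes:
        if method == "fig":
            # the FIG posterior is already the full-grid fit of this log
            estimates["bayes"] = estimated_csf(sampler.posterior, stim_grid.sfs)
        else:
            post = infer(trials, engine_config)
            estimates["bayes"] = estimated_csf(post, stim_grid.sfs)
    return RunResult(method=method, budget=budget, seed=seed, trials=trials,
                     estimates=estimates,
                     true_sens=csf_sensitivities(stim_grid.sfs, observer),
                     sfs=stim_grid.sfs.copy())


def _errors_db(results: Sequence[RunResult], key: str | None,
               db_factor: float) -> np.ndarray:
    """Signed dB errors, shape (n_runs, n_sfs)."""
    rows = []
    for r in results:
        est = r.estimate(key)
        if np.any(est <= 0) or np.any(r.true_sens <= 0):
            raise ValueError("sensitivities must be positive for dB errors")
        rows.append(db_factor * (np.log10(est) - np.log10(r.true_sens)))
    return np.asarray(rows)


def rmse_db(results: Sequence[RunResult], key: str | None = None, *,
            db_factor: float = DB_FACTOR) -> float:
    """Pooled RMSE: sqrt of the grand mean squared dB error over (run, sf)."""
    err = _errors_db(results, key, db_factor)
    return float(np.sqrt(np.mean(err ** 2)))


def bias_db(results: Sequence[RunResult], key: str | None = None, *,
            db_factor: float = DB_FACTOR) -> float:
    """Pooled signed bias: grand mean dB error (estimate minus truth)."""
    return float(np.mean(_errors_db(results, key, db_factor)))


def aulcsf(result: RunResult, key: str | None = None) -> float:
    """Area under the log10 CSF over log2 spatial frequency (trapezoid)."""
    est = result.estimate(key)
    return float(np.trapezoid(np.log10(est), np.log2(result.sfs)))


def _bootstrap_se(err: np.ndarray, stat: str, n_boot: int,
                  rng: np.random.Generator) -> float:
    """Run-level bootstrap standard error of the pooled RMSE or bias."""
    n = err.shape[0]
    if n < 2:
        return float("nan")
    per_run = np.mean(err ** 2, axis=1) if stat == "rmse" else np.mean(err, axis=1)
    idx = rng.integers(0, n, size=(n_boot, n))
    means = per_run[idx].mean(axis=1)
    vals = np.sqrt(means) if stat == "rmse" else means
    return float(np.std(vals, ddof=1))


@dataclass
class MetricsReport:
    """Tidy per-(method, budget) metrics with bootstrap Monte-Carlo errors."""

    rows: list[dict] = field(default_factory=list)

    def as_records(self) -> list[dict]:
        return [dict(r) for r in self.rows]

    def get(self, method: str, budget: int) -> dict:
        for r in self.rows:
            if r["method"] == method and r["budget"] == budget:
                return r
        raise KeyError((method, budget))


def monte_carlo(methods: Sequence[str], budgets: Sequence[int],
                observer: ObserverParams, N: int, base_seed: int, *,
                stim_grid: StimulusGrid | None = None,
                engine_config: EngineConfig | None = None,
                sampler_kwargs: dict | None = None,
                n_boot: int = 1000, db_factor: float = DB_FACTOR,
                with_aulcsf: bool = False,
                progress: bool = False) -> MetricsReport:
    """Monte-Carlo evaluation of the requested method labels.

    ``methods`` are reported labels (see ``METHOD_LABELS``).  Labels that
    share a sampling strategy (e.g. ``psi`` and ``bayes-psi``) reuse the same
    N simulated trial logs.  Per-run seeds are drawn once from ``base_seed``,
    so adding or removing methods never changes another method's runs.
    """
    stim_grid = stim_grid or StimulusGrid()
    for m in methods:
        if m not in METHOD_LABELS:
            raise ValueError(f"unknown method label {m!r}; choose from "
                             f"{sorted(METHOD_LABELS)}")
    report = MetricsReport()
    boot_rng = np.random.default_rng(np.random.SeedSequence(base_seed).spawn(1)[0])
    for budget in budgets:
        by_sampler: dict[str, list[str]] = {}
        for m in methods:
            samp, _ = METHOD_LABELS[m]
            by_sampler.setdefault(samp, []).append(m)
        for samp, labels in by_sampler.items():
            need_bayes = any(METHOD_LABELS[m][1] == "bayes" for m in labels)
            seed_rng = np.random.default_rng(
                np.random.SeedSequence((base_seed, budget, _samp_tag(samp))))
            seeds = seed_rng.integers(0, 2 ** 31 - 1, size=N)
            results = []
            for i, s in enumerate(seeds):
                results.append(run_experiment(
                    samp, budget, observer, int(s), stim_grid=stim_grid,
                    engine_config=engine_config, bayes=need_bayes,
                    sampler_kwargs=(sampler_kwargs or {}).get(samp)))
                if progress and (i + 1) % 25 == 0:
                    print(f"  {samp} budget={budget}: {i + 1}/{N} runs")
            for m in labels:
                key = METHOD_LABELS[m][1]
                err = _errors_db(results, key, db_factor)
                row = {
                    "method": m, "budget": int(budget), "n_runs": int(N),
                    "rmse_db": float(np.sqrt(np.mean(err ** 2))),
                    "bias_db": float(np.mean(err)),
                    "rmse_se": _bootstrap_se(err, "rmse", n_boot, boot_rng),
                    "bias_se": _bootstrap_se(err, "bias", n_boot, boot_rng),
                }
                if with_aulcsf:
                    areas = [aulcsf(r, key) for r in results]
                    row["aulcsf_mean"] = float(np.mean(areas))
                    row["aulcsf_sd"] = float(np.std(areas, ddof=1)) if N > 1 else 0.0
                report.rows.append(row)
    return report


def _samp_tag(name: str) -> int:
    return {"staircase": 1, "psi": 2, "qcsf": 3, "fig": 4}[name]
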