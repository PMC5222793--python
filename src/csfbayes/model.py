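"""Parametric 2-D psychometric model of contrast detection.

The observer's probability of detecting a grating of spatial frequency ``f``
(cycles/degree) at Michelson contrast ``c`` is a logistic function of log
contrast whose midpoint tracks the contrast sensitivity function (CSF)

    S(f) = M * f**A * exp(-f / F),

the double-exponential CSF shape.  ``M`` scales overall sensitivity, ``A``
sets the steepness of the low-frequency limb, ``F`` the high-frequency
cut-off; the peak sits at ``f = A*F`` with amplitude ``M*(F*A)**A*exp(-A)``.
Detection threshold is the reciprocal of sensitivity, so the full 2-D
psychometric surface is

    P(f, c) = gamma + (1 - gamma - delta) /
              (1 + exp(-beta * (ln c + ln M + A*ln f - f/F))),

with guess rate ``gamma`` (1/2 for a 2AFC task) and lapse rate ``delta``
bounding the asymptotes.  All internal math is in natural logs; base-10
logs appear only in parameter grids and priors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ObserverParams",
    "Stimulus",
    "StimulusGrid",
    "logistic_p",
    "csf_sensitivity",
    "csf_peak_sf",
    "csf_peak_sensitivity",
    "detect_prob",
    "detect_prob_grad",
    "GAMMA_2AFC",
]

GAMMA_2AFC = 0.5

LN10 = math.log(10.0)


@dataclass(frozen=True)
class ObserverParams:
    """True (or estimated) parameter vector of the 2-D psychometric model.

    Parameters
    ----------
    M, A, F : float
        CSF shape parameters (all strictly positive); ``F`` in c/d.
    beta : float
        Logistic slope on the natural-log contrast axis (> 0).
    gamma : float
        Guess rate; 0.5 for the standard 2AFC configuration.
    delta : float
        Lapse rate; the upper asymptote is ``1 - delta``.
    """

    M: float
    A: float
    F: float
    beta: float
    gamma: float = GAMMA_2AFC
    delta: float = 0.02

    def __post_init__(self) -> None:
        for name in ("M", "A", "F", "beta"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0 <= self.gamma < 1 and 0 <= self.delta < 1):
            raise ValueError("gamma and delta must lie in [0, 1)")
        if not self.gamma + self.delta < 1:
            raise ValueError("gamma + delta must be < 1")

    def with_(self, **kw) -> "ObserverParams":
        return replace(self, **kw)

    def as_array(self) -> np.ndarray:
        """(M, A, F, beta, delta) as a linear-scale vector (gamma is fixed)."""
        return np.array([self.M, self.A, self.F, self.beta, self.delta])


@dataclass(frozen=True)
class Stimulus:
    """A (spatial frequency, contrast) pair; sf in c/d, contrast in (0, 1]."""

    sf: float
    contrast: float

    def __post_init__(self) -> None:
        if not self.sf > 0:
            raise ValueError("sf must be strictly positive")
        if not 0 < self.contrast <= 1:
            raise ValueError("contrast must lie in (0, 1]")


def _default_sfs() -> np.ndarray:
    # 0.5 to 22.6 c/d in 0.5 log2 steps (12 values)
    return 0.5 * 2.0 ** (0.5 * np.arange(12))


def _default_contrasts() -> np.ndarray:
    # 0.001 to 1 in 0.02 log10 steps (151 values)
    return 10.0 ** (-3.0 + 0.02 * np.arange(151))


@dataclass(frozen=True)
class StimulusGrid:
    """Discrete stimulus space shared by every sampling strategy.

    Defaults: 12 spatial frequencies from 0.5 to 22.6 c/d in 0.5 log2 steps
    and 151 contrasts from 0.001 to 1 in 0.02 log10 steps.
    """

    sfs: np.ndarray = field(default_factory=_default_sfs)
    contrasts: np.ndarray = field(default_factory=_default_contrasts)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sfs", np.asarray(self.sfs, dtype=float))
        object.__setattr__(self, "contrasts", np.asarray(self.contrasts, dtype=float))
        for name in ("sfs", "contrasts"):
            ax = getattr(self, name)
            if ax.ndim != 1 or ax.size == 0 or np.any(np.diff(ax) <= 0):
                raise ValueError(f"{name} must be a strictly increasing 1-D array")
        if np.any(self.sfs <= 0) or np.any(self.contrasts <= 0) or np.any(self.contrasts > 1):
            raise ValueError("sfs must be > 0 and contrasts in (0, 1]")

    @property
    def n_sfs(self) -> int:
        return self.sfs.size

    @property
    def n_contrasts(self) -> int:
        return self.contrasts.size

    def snap_contrast(self, contrast: float) -> float:
        """Clamp to grid bounds and snap to the nearest log10-contrast node.

        Ties between two equidistant nodes resolve toward the lower contrast.
        """
        logc = np.log10(np.clip(contrast, self.contrasts[0], self.contrasts[-1]))
        lognodes = np.log10(self.contrasts)
        dist = np.abs(lognodes - logc)
        # ties toward the lower contrast: argmin picks the first (lower) node
        return float(self.contrasts[int(np.argmin(dist + 1e-15 * lognodes))])

    def sf_index(self, sf: float) -> int:
        i = int(np.argmin(np.abs(np.log2(self.sfs) - np.log2(sf))))
        if not np.isclose(self.sfs[i], sf, rtol=1e-9):
            raise ValueError(f"sf {sf} not on the stimulus grid")
        return i

    def all_stimuli(self) -> list[Stimulus]:
        return [Stimulus(float(f), float(c)) for f in self.sfs for c in self.contrasts]


def logistic_p(contrast, alpha, beta, gamma, delta):
    """Logistic psychometric function of log contrast.

    ``gamma + (1 - gamma - delta) / (1 + exp(-beta * (ln c - ln alpha)))``;
    strictly increasing in ``contrast`` and bounded in (gamma, 1 - delta).
    Accepts scalars or broadcastable arrays.
    """
    contrast = np.asarray(contrast, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(contrast <= 0) or np.any(alpha <= 0):
        raise ValueError("contrast and alpha must be strictly positive")
    if np.any(np.asarray(gamma) + np.asarray(delta) >= 1):
        raise ValueError("gamma + delta must be < 1")
    z = np.asarray(beta, dtype=float) * (np.log(contrast) - np.log(alpha))
    out = gamma + (1.0 - gamma - delta) * _expit(z)
    return out if out.ndim else float(out)


def _expit(z):
    # overflow-safe logistic
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def csf_sensitivity(sf, M, A, F):
    """Double-exponential CSF: ``S(f) = M * f**A * exp(-f/F)``.

    Unimodal in ``f`` with peak at ``f = A*F``.
    """
    sf = np.asarray(sf, dtype=float)
    if np.any(sf <= 0) or np.any(np.asarray(M) <= 0) or np.any(np.asarray(A) <= 0) \
            or np.any(np.asarray(F) <= 0):
        raise ValueError("sf, M, A, F must all be strictly positive")
    out = M * sf ** A * np.exp(-sf / F)
    return out if out.ndim else float(out)


def csf_peak_sf(A: float, F: float) -> float:
    """Spatial frequency of the CSF peak, ``A*F``."""
    return A * F


def csf_peak_sensitivity(M: float, A: float, F: float) -> float:
    """Closed-form peak amplitude ``M * (F*A)**A * exp(-A)``."""
    return M * (F * A) ** A * math.exp(-A)


def detect_prob(stim, theta: ObserverParams):
    """Probability of a positive response to ``stim`` under ``theta``.

    Equals ``logistic_p(c, 1/S(f), beta, gamma, delta)`` with the threshold
    set by the reciprocal CSF; evaluated through the shared exponent
    ``beta * (ln c + ln M + A*ln f - f/F)``.
    """
    sf, c = np.asarray(stim.sf, float), np.asarray(stim.contrast, float)
    z = theta.beta * (np.log(c) + math.log(theta.M) + theta.A * np.log(sf) - sf / theta.F)
    out = theta.gamma + (1.0 - theta.gamma - theta.delta) * _expit(z)
    return out if out.ndim else float(out)


def detect_prob_grad(stim, theta: ObserverParams) -> np.ndarray:
    """Analytic gradient of ``detect_prob`` w.r.t. (log10 M, log10 A, log10 F, log10 beta).

    Needed by Fisher-information stimulus scoring.  The chain rule runs
    through the natural-log exponent ``u = ln c + ln M + A ln f - f/F``:
    d/dlog10(x) = ln(10) * x * d/dx for each positive parameter x.
    """
    sf, c = float(stim.sf), float(stim.contrast)
    u = math.log(c) + math.log(theta.M) + theta.A * math.log(sf) - sf / theta.F
    z = theta.beta * u
    L = float(_expit(z))
    core = (1.0 - theta.gamma - theta.delta) * L * (1.0 - L)
    # du/dlnM = 1; du/dlnA = A*ln f; du/dlnF = f/F; dz/dlnbeta = z
    dz = np.array([
        theta.beta * 1.0,
        theta.beta * theta.A * math.log(sf),
        theta.beta * sf / theta.F,
        z,
    ])
    return core * dz * LN10


def csf_sensitivities(sfs: Sequence[float], theta: ObserverParams) -> np.ndarray:
    """Vector of S(f) over ``sfs`` for an observer."""
    return np.asarray(csf_sensitivity(np.asarray(sfs, float), theta.M, theta.A, theta.F))
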