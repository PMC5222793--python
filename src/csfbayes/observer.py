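"""Simulated 2AFC observers emitting Bernoulli responses from the 2-D model.

Two presets bracket the study conditions: a normal observer
{M, A, F, beta, delta} = {100, 0.8, 4, 4, 0.02} (CSF peak at 3.2 c/d) and an
amblyopic observer {40, 1.2, 6, 4, 0.02} (peak at 7.2 c/d) whose CSF poorly
matches the normal-vision prior.  Each observer owns its RNG stream so that
sampler-side randomness never perturbs the response draws.
"""

from __future__ import annotations

import numpy as np

from .model import GAMMA_2AFC, ObserverParams, Stimulus, detect_prob

__all__ = ["SimulatedObserver", "preset", "PRESETS"]

PRESETS = {
    "normal": ObserverParams(M=100.0, A=0.8, F=4.0, beta=4.0, gamma=GAMMA_2AFC, delta=0.02),
    "amblyope": ObserverParams(M=40.0, A=1.2, F=6.0, beta=4.0, gamma=GAMMA_2AFC, delta=0.02),
}


def preset(name: str) -> ObserverParams:
    """Named observer parameter sets: ``normal`` or ``amblyope``."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown observer preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None


class SimulatedObserver:
    """Bernoulli responder driven by ``detect_prob`` and a private RNG."""

    def __init__(self, params: ObserverParams, rng: np.random.Generator | int | None = None):
        self.params = params
        self.rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    def respond(self, stim: Stimulus) -> int:
        """Draw one binary response (1 = detected) to ``stim``."""
        return int(self.rng.random() < detect_prob(stim, self.params))
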