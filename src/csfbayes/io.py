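"""Configuration parsing and trial-log round-tripping.

Trial logs are plain CSV with the header ``trial,sf_cpd,contrast,response``
(contrast as linear Michelson contrast with at least six significant digits,
spatial frequency in c/d, response 0/1); extra columns are tolerated on
read, so logs from other lab software can be fed straight to inference.
Configurations are JSON or YAML mappings.  All final files are written via
write-then-rename so an interrupted run never leaves a partial file.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd
import yaml

from .engine import EngineConfig, TrialRecord
from .model import ObserverParams, Stimulus, StimulusGrid
from .observer import preset

__all__ = [
    "ConfigError",
    "read_trial_log",
    "write_trial_log",
    "load_config",
    "atomic_write_text",
    "observer_from_config",
    "engine_config_from_config",
    "stimulus_grid_from_config",
    "sampler_spec_from_config",
]

LOG_COLUMNS = ["trial", "sf_cpd", "contrast", "response"]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending key path."""


def atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_trial_log(path: str | Path, trials: Iterable[TrialRecord]) -> None:
    df = pd.DataFrame(
        [{"trial": t.index, "sf_cpd": t.stim.sf, "contrast": t.stim.contrast,
          "response": t.response} for t in trials],
        columns=LOG_COLUMNS,
    )
    atomic_write_text(path, df.to_csv(index=False, float_format="%.8g"))


def read_trial_log(path: str | Path) -> list[TrialRecord]:
    df = pd.read_csv(path)
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"trial log {path}: missing columns {missing}")
    if len(df) == 0:
        raise ConfigError(f"trial log {path}: no trials")
    bad = ~df["response"].isin([0, 1])
    if bad.any():
        raise ConfigError(
            f"trial log {path}: responses outside {{0, 1}} at rows "
            f"{df.index[bad].tolist()[:5]}")
    return [
        TrialRecord(index=int(r.trial),
                    stim=Stimulus(float(r.sf_cpd), float(r.contrast)),
                    response=int(r.response))
        for r in df.itertuples()
    ]


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        data = yaml.safe_load(text)
    else:
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"config {path}: expected a mapping at the top level")
    return data


def observer_from_config(config: dict) -> ObserverParams:
    spec = config.get("observer", {"preset": "normal"})
    if not isinstance(spec, dict):
        raise ConfigError("observer: expected a mapping")
    if "preset" in spec:
        try:
            return preset(spec["preset"])
        except ValueError as e:
            raise ConfigError(f"observer.preset: {e}") from None
    try:
        return ObserverParams(
            M=float(spec["M"]), A=float(spec["A"]), F=float(spec["F"]),
            beta=float(spec["beta"]), gamma=float(spec.get("gamma", 0.5)),
            delta=float(spec.get("delta", 0.02)))
    except KeyError as e:
        raise ConfigError(f"observer.{e.args[0]}: required") from None
    except ValueError as e:
        raise ConfigError(f"observer: {e}") from None


def engine_config_from_config(config: dict) -> EngineConfig:
    prior = config.get("prior", {})
    grid = config.get("grid", {})
    kw: dict[str, Any] = {}
    if "mean" in prior:
        kw["prior_mean"] = tuple(float(v) for v in prior["mean"])
    if "diag" in prior:
        kw["prior_diag"] = tuple(float(v) for v in prior["diag"])
    if "diag_is_variance" in prior:
        kw["diag_is_variance"] = bool(prior["diag_is_variance"])
    if "sizes" in grid:
        kw["grid_sizes"] = tuple(int(v) for v in grid["sizes"])
    if "span_sd" in grid:
        kw["span_sd"] = float(grid["span_sd"])
    if "gamma" in config:
        kw["gamma"] = float(config["gamma"])
    try:
        return EngineConfig(**kw)
    except ValueError as e:
        raise ConfigError(f"prior/grid: {e}") from None


def stimulus_grid_from_config(config: dict) -> StimulusGrid:
    spec = config.get("stimuli", {})
    kw = {}
    if "sfs" in spec:
        kw["sfs"] = np.asarray(spec["sfs"], dtype=float)
    if "contrasts" in spec:
        kw["contrasts"] = np.asarray(spec["contrasts"], dtype=float)
    try:
        return StimulusGrid(**kw)
    except ValueError as e:
        raise ConfigError(f"stimuli: {e}") from None


def sampler_spec_from_config(config: dict) -> tuple[str, dict]:
    """Sampler name plus keyword options from the ``sampler`` entry.

    Accepts ``sampler: staircase`` or a mapping with a ``name`` key; dotted
    config keys from the flat form (``fig.top_fraction``,
    ``staircase.up_factor`` ...) are merged in.
    """
    spec = config.get("sampler", "staircase")
    if isinstance(spec, str):
        name, opts = spec, {}
    elif isinstance(spec, dict):
        spec = dict(spec)
        try:
            name = spec.pop("name")
        except KeyError:
            raise ConfigError("sampler.name: required") from None
        opts = spec
    else:
        raise ConfigError("sampler: expected a name or a mapping")
    allowed = {"staircase", "psi", "qcsf", "fig"}
    if name not in allowed:
        raise ConfigError(f"sampler: unknown name {name!r}; "
                          f"allowed: {sorted(allowed)}")
    for key, val in config.items():
        if isinstance(key, str) and key.startswith(name + "."):
            opts[key[len(name) + 1:]] = val
    renames = {"top_fraction": "top_fraction", "up_factor": "up_factor",
               "down_factor": "down_factor", "warmup_trials": "warmup_trials",
               "candidate_subsample": "candidate_subsample",
               "selection_grid_sizes": "selection_grid_sizes",
               "ridge": "ridge"}
    kwargs = {}
    for k, v in opts.items():
        if k not in renames:
            raise ConfigError(f"sampler.{k}: unknown option")
        kwargs[renames[k]] = tuple(v) if k == "selection_grid_sizes" else v
    return name, kwargs
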