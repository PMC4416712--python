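"""YAML analysis configuration.

One documented key-value format, no format guessing::

    horizon: 10.0                    # or [t0, t1]
    functionalities:                 # ordered mapping name -> reaction ids
      F1: [R1, R2, R3]
      F2: [R4, R5]
    solver:                          # optional; SolverOptions fields
      rtol: 1.0e-8
      atol: 1.0e-10
      n_grid: 1001
    inputs:                          # optional piecewise-constant schedules
      k:
        segments: [[0, 50, 3.0], [50, null, 10.0]]
    weights:                         # optional per-species metric weights
      X1: 1.0
      X2: 0.0
"""

from __future__ import annotations

from dataclasses import fields as dc_fields
from pathlib import Path

import yaml

from .errors import ConfigError
from .layers import SolverOptions
from .network import FunctionalitySet, InputSignal, ReactionNetwork

__all__ = ["load_config", "apply_config"]


def load_config(path) -> dict:
    """Parse and structurally validate a configuration file."""
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError("configuration must be a mapping")
    known = {"horizon", "functionalities", "solver", "inputs", "weights"}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    if "functionalities" in doc and not isinstance(doc["functionalities"], dict):
        raise ConfigError("functionalities must map names to reaction-id lists")
    return doc


def apply_config(
    network: ReactionNetwork, doc: dict
) -> tuple[FunctionalitySet | None, float | tuple | None, SolverOptions]:
    """Materialise a parsed configuration against a network.

    Returns ``(functionality_set, horizon, solver_options)``; input schedules
    in the configuration are attached to the network (overriding same-named
    signals).
    """
    fs = None
    if "functionalities" in doc:
        try:
            fs = FunctionalitySet.from_dict(network, doc["functionalities"])
        except Exception as exc:
            raise ConfigError(f"bad functionality definition: {exc}") from exc
    horizon = doc.get("horizon")
    if isinstance(horizon, list):
        horizon = tuple(horizon)
    opt_kwargs = doc.get("solver", {})
    valid = {f.name for f in dc_fields(SolverOptions)}
    bad = set(opt_kwargs) - valid
    if bad:
        raise ConfigError(f"unknown solver options: {sorted(bad)}")
    opts = SolverOptions(**opt_kwargs)
    for name, spec in (doc.get("inputs") or {}).items():
        if not isinstance(spec, dict) or "segments" not in spec:
            raise ConfigError(f"input {name!r} needs a 'segments' list")
        network.inputs[name] = InputSignal(name, schedule=[tuple(s) for s in spec["segments"]])
        network._compiled = None
    return fs, horizon, opts
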