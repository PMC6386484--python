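"""YAML configuration for the simulation environment.

A config file holds plain scalar overrides grouped by section; any omitted
key falls back to the study default.  Example::

    geometry:
      finger_diameter: 0.02
      skin_thickness: 0.0009
    conductivities:
      sigma_skin: 0.0552
    array:
      longitudinal_offset: 0.007
    nail:
      x_start: 0.002
    fiber:
      grouping: 4
    membrane:
      temperature: 20.0
      correct_v_r: true
      correct_rho_i: true
    pulse:
      onset: 0.01
      width: 0.00045
    solver:
      resolution: 0.0003
      method: direct
      tolerance: 1.0e-12
"""

from __future__ import annotations

from dataclasses import replace

import yaml

from .fibers import FiberGeometry
from .geometry import ElectrodeArray, FingerGeometry, TissueConductivities
from .kinetics import HHParams
from .stimulation import StimulusPulse
from .volume_conductor import NailPatch

__all__ = ["load_config", "environment_kwargs"]

_SECTIONS = {
    "geometry": FingerGeometry,
    "conductivities": TissueConductivities,
    "array": ElectrodeArray,
    "nail": NailPatch,
    "fiber": FiberGeometry,
    "membrane": HHParams,
    "pulse": StimulusPulse,
}


def load_config(path) -> dict:
    """Parse a YAML config file into constructed component objects.

    Returns a dict with keys matching the sections above plus ``solver``
    (a plain dict of resolution/method/tolerance).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(_SECTIONS) - {"solver", "screen"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    out = {}
    for section, cls in _SECTIONS.items():
        overrides = raw.get(section) or {}
        if not isinstance(overrides, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        try:
            out[section] = replace(cls(), **overrides)
        except TypeError as exc:
            raise ValueError(f"bad key in config section {section!r}: {exc}") from exc
    out["solver"] = dict(raw.get("solver") or {})
    out["screen"] = dict(raw.get("screen") or {})
    return out


def environment_kwargs(cfg: dict) -> dict:
    """Map a parsed config onto SimulationEnvironment keyword arguments."""
    solver = cfg.get("solver", {})
    kwargs = {
        "geometry": cfg["geometry"],
        "conductivities": cfg["conductivities"],
        "array": cfg["array"],
        "nail": cfg["nail"],
        "fiber": cfg["fiber"],
        "params": cfg["membrane"],
        "pulse": cfg["pulse"],
    }
    if "resolution" in solver:
        kwargs["resolution"] = float(solver["resolution"])
    if "method" in solver:
        kwargs["solver_method"] = solver["method"]
    if "tolerance" in solver:
        kwargs["solver_tolerance"] = float(solver["tolerance"])
    return kwargs
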