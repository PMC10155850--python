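"""Run configuration: a serializable description of a whole study.

The config is a human-readable YAML document with sections
``geometry``, ``materials.hps``, ``materials.normal``, ``closure``,
``grid``, ``solver``, ``source``, ``damage``, ``dose_grid`` and
``selection``.  Loading a saved config reproduces a run exactly; all
simulation paths are deterministic (seeds exist only for fixture
generation).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .bioheat import SolverSpec
from .damage import DamageParams
from .laser import SourceOptions
from .tissue import DEFAULT_CLOSURE, PRESETS, ConfigurationError, GridSpec

__all__ = ["RunConfig", "default_config_dict"]


def default_config_dict() -> dict:
    """The study's default configuration as a plain dict."""
    shared = {"rho_b": 1000.0, "c_b": 4180.0, "w_b": 6.4e-3,
              "T0": 37.0, "T_art": 37.0, "T1": 25.0}
    return {
        "geometry": {
            "radius_mm": 10.0,
            "depth_mm": 4.0,
            "vessel_depth_mm": 2.0,
            "vessel_top_offset_mm": 0.0,
            "vessel_radius_mm": {"hps": 0.5, "normal_skin": 0.3},
        },
        "materials": {
            "hps": {**PRESETS["hps"]["optics"], **shared},
            "normal": {**PRESETS["normal_skin"]["optics"], **shared},
        },
        "closure": dict(DEFAULT_CLOSURE),
        "grid": {"dr_mm": 0.1, "nz": 120, "dz0_mm": 5.0e-3},
        "solver": {
            "scheme": "implicit",
            "t_end_s": 1.0,
            "pulse_steps": 250,
            "cooling_growth": 1.3,
            "dt_max_s": 0.05,
            "h_W_per_m2K": 10.0,
        },
        "source": {
            "radial": "gaussian",
            "axial": "beer-lambert",
            "envelope": "gaussian-normalized",
            "beam_size_is_diameter": True,
        },
        "damage": {
            "A": 4.575e72,
            "Ea": 4.71e5,
            "R_gas": 8.314,
            "burn_thresholds": [0.58, 1.0, 1.0e4],
            "damage_threshold": 1.0,
        },
        "dose_grid": {"q": [4.0, 7.5, 10.0], "tau_ms": [0.5, 4.0, 10.0],
                      "spot_mm": [5.0, 6.0, 7.0]},
        "selection": {"threshold_C": 50.0, "objective": "final_damage_extent"},
    }


@dataclass
class RunConfig:
    """Structured study configuration with object builders."""

    data: dict = field(default_factory=default_config_dict)

    # -- serialization ----------------------------------------------------
    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict) or "materials" not in data:
            raise ConfigurationError(f"{path}: not a scartherm config file")
        merged = default_config_dict()
        _deep_update(merged, data)
        return cls(merged)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=False)

    def copy(self) -> "RunConfig":
        return RunConfig(copy.deepcopy(self.data))

    # -- builders ---------------------------------------------------------
    def grid_spec(self) -> GridSpec:
        g = self.data["grid"]
        if "dz_mm" in g and g["dz_mm"]:
            return GridSpec(dr_mm=g["dr_mm"], dz_mm=g["dz_mm"])
        return GridSpec(dr_mm=g["dr_mm"], nz=g["nz"], dz0_mm=g["dz0_mm"])

    def solver_spec(self) -> SolverSpec:
        s = self.data["solver"]
        return SolverSpec(
            scheme=s.get("scheme", "implicit"),
            t_end=s.get("t_end_s", 1.0),
            pulse_steps=s.get("pulse_steps", 250),
            cooling_growth=s.get("cooling_growth", 1.3),
            dt_max=s.get("dt_max_s", 0.05),
            dt=s.get("dt_s"),
            h=s.get("h_W_per_m2K", 10.0),
        )

    def source_options(self) -> SourceOptions:
        s = self.data["source"]
        return SourceOptions(radial=s["radial"], axial=s["axial"], envelope=s["envelope"])

    def damage_params(self) -> DamageParams:
        d = self.data["damage"]
        return DamageParams(
            A=d["A"], Ea=d["Ea"], R_gas=d["R_gas"],
            thresholds=tuple(d["burn_thresholds"]),
            damage_threshold=d["damage_threshold"],
        )

    def closure(self) -> dict:
        return dict(self.data["closure"])

    def dose_grid(self) -> dict:
        return {k: tuple(v) for k, v in self.data["dose_grid"].items()}

    @property
    def selection_threshold(self) -> float:
        return float(self.data["selection"]["threshold_C"])

    @property
    def selection_objective(self) -> str:
        return str(self.data["selection"]["objective"])

    def beam_size_is_diameter(self) -> bool:
        return bool(self.data["source"].get("beam_size_is_diameter", True))


def _deep_update(base: dict, other: dict) -> None:
    for key, val in other.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], val)
        else:
            base[key] = val
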