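"""Dose sweeps and constrained selection of laser treatment parameters.

The study design sweeps laser energy density q, pulse width tau, and
spot diameter omega_0 over the clinical grids (q in {4, 7.5, 10},
tau in {0.5, 4, 10} ms, omega_0 in {5, 6, 7} mm), either one factor at a
time around the reference dose (q = 7.5, tau = 4 ms, omega_0 = 7 mm) or
as the full factorial.  Every run records the center-temperature trace
and the damage traces; the selection rule then maximizes the final scar
damage among candidates whose peak center temperature stays at or below
the 50 degC protein-denaturation threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .bioheat import SolverSpec, solve_transient
from .damage import DamageAccumulator, DamageParams, classify_burn
from .laser import DoseParams, SourceOptions
from .tissue import GridSpec, build_domain

__all__ = [
    "REFERENCE_DOSE",
    "DEFAULT_DOSE_GRID",
    "SweepResult",
    "SelectionVerdict",
    "run_single",
    "run_sweep",
    "select_optimal",
    "summarize",
]

REFERENCE_DOSE = (7.5, 4.0, 7.0)  # (q, tau_ms, spot_mm)

# Device-consistent pulse grid (the 0.4 ms variant of the shortest pulse
# is available through the config layer).
DEFAULT_DOSE_GRID = {
    "q": (4.0, 7.5, 10.0),
    "tau_ms": (0.5, 4.0, 10.0),
    "spot_mm": (5.0, 6.0, 7.0),
}


@dataclass(frozen=True)
class SweepResult:
    """Outcome of one (preset, dose) simulation."""

    preset: str
    q: float
    tau_ms: float
    spot_mm: float
    peak_T_C: float
    t_peak_s: float
    T_at_end_C: float
    final_damaged_fraction: float  # thresholded coagulated-volume fraction
    final_damage_extent: float  # mean denatured fraction of the scar region
    final_damage_extent_domain: float
    max_omega: float
    burn_class: str
    threshold_pass: bool
    times: np.ndarray = field(repr=False)
    center_trace: np.ndarray = field(repr=False)
    damage_times: np.ndarray = field(repr=False)
    damage_extent_trace: np.ndarray = field(repr=False)
    damaged_fraction_trace: np.ndarray = field(repr=False)

    @property
    def dose(self) -> tuple:
        return (self.q, self.tau_ms, self.spot_mm)


@dataclass(frozen=True)
class SelectionVerdict:
    """Result of the constrained dose selection."""

    admissible: bool
    chosen: tuple | None  # (q, tau_ms, spot_mm)
    objective_value: float | None
    objective: str
    threshold_C: float
    candidate_status: pd.DataFrame = field(repr=False)
    tie_break_note: str = ""


def run_single(
    preset: str,
    dose: DoseParams,
    resolution: GridSpec | None = None,
    spec: SolverSpec = SolverSpec(),
    options: SourceOptions = SourceOptions(),
    damage_params: DamageParams = DamageParams(),
    threshold_C: float = 50.0,
    closure: dict | None = None,
) -> SweepResult:
    """Simulate one laser exposure and summarize temperature and damage."""
    _, grid = build_domain(preset, resolution, closure)
    acc = DamageAccumulator(grid, damage_params)
    result = solve_transient(grid, dose, spec, options, hooks=(acc,))
    f = acc.field
    peak = result.peak_T
    return SweepResult(
        preset=preset,
        q=dose.q,
        tau_ms=dose.tau_ms,
        spot_mm=dose.spot_mm,
        peak_T_C=peak,
        t_peak_s=result.t_peak,
        T_at_end_C=float(result.probe_trace[-1]),
        final_damaged_fraction=f.fraction_scar[-1],
        final_damage_extent=f.extent_scar[-1],
        final_damage_extent_domain=f.extent_domain[-1],
        max_omega=f.max_omega,
        burn_class=classify_burn(f.max_omega, damage_params),
        threshold_pass=bool(peak <= threshold_C),
        times=result.times,
        center_trace=result.probe_trace,
        damage_times=np.array(f.times),
        damage_extent_trace=np.array(f.extent_scar),
        damaged_fraction_trace=np.array(f.fraction_scar),
    )


def _grid_doses(dose_grid: dict, mode: str) -> list[tuple]:
    qs, taus, spots = dose_grid["q"], dose_grid["tau_ms"], dose_grid["spot_mm"]
    if not (len(qs) and len(taus) and len(spots)):
        raise ValueError("empty dose grid")
    if mode == "factorial":
        return sorted(product(qs, taus, spots))
    if mode == "oat":
        q0, t0, s0 = REFERENCE_DOSE
        doses = {(q, t0, s0) for q in qs} | {(q0, t, s0) for t in taus} | {(q0, t0, s) for s in spots}
        return sorted(doses)
    raise ValueError(f"unknown sweep mode {mode!r}")


def run_sweep(
    presets=("hps",),
    dose_grid: dict | None = None,
    mode: str = "factorial",
    resolution: GridSpec | None = None,
    spec: SolverSpec = SolverSpec(),
    options: SourceOptions = SourceOptions(),
    damage_params: DamageParams = DamageParams(),
    threshold_C: float = 50.0,
    closure: dict | None = None,
    progress=None,
) -> list[SweepResult]:
    """Run the dose study.  Deterministic: identical inputs, identical results.

    mode : {"factorial", "oat"}
        Full factorial (selection), or one factor at a time around the
        reference dose (mirrors the per-parameter trend figures).
    """
    dose_grid = dose_grid or DEFAULT_DOSE_GRID
    doses = _grid_doses(dose_grid, mode)
    results = []
    for preset in presets:
        for q, tau_ms, spot_mm in doses:
            try:
                res = run_single(
                    preset, DoseParams(q, tau_ms, spot_mm), resolution, spec,
                    options, damage_params, threshold_C, closure,
                )
            except Exception as exc:  # abort with the offending dose identified
                raise RuntimeError(
                    f"sweep failed at preset={preset}, q={q}, tau={tau_ms} ms, "
                    f"spot={spot_mm} mm: {exc}"
                ) from exc
            results.append(res)
            if progress is not None:
                progress(res)
    return results


def summarize(results) -> pd.DataFrame:
    """One row per candidate, lexicographically ordered and deterministic."""
    results = list(results)
    if not results:
        raise ValueError("no sweep results to summarize")
    rows = [
        {
            "preset": r.preset,
            "q": r.q,
            "tau_ms": r.tau_ms,
            "spot_mm": r.spot_mm,
            "peak_T_C": r.peak_T_C,
            "t_peak_s": r.t_peak_s,
            "T_at_end_C": r.T_at_end_C,
            "final_damage_extent": r.final_damage_extent,
            "final_damaged_fraction": r.final_damaged_fraction,
            "max_omega": r.max_omega,
            "burn_class": r.burn_class,
            "threshold_pass": r.threshold_pass,
        }
        for r in results
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["preset", "q", "tau_ms", "spot_mm"], kind="mergesort")
        .reset_index(drop=True)
    )


def select_optimal(
    results,
    threshold_C: float = 50.0,
    objective: str = "final_damage_extent",
    preset: str = "hps",
) -> SelectionVerdict:
    """Constrained argmax over the sweep: maximal scar damage at <= 50 degC.

    Among the ``preset`` candidates whose peak center temperature does
    not exceed ``threshold_C``, returns the maximizer of ``objective``
    (default: the final mean denatured fraction of the scar).  Ties are
    broken toward lower q, then lower tau, then smaller spot; if no
    candidate is admissible the verdict says so rather than raising.

    ``results`` is either a list of SweepResult or an already summarized
    DataFrame (e.g. a re-read summary.csv).
    """
    if isinstance(results, pd.DataFrame):
        table = results[results["preset"] == preset].reset_index(drop=True)
        if table.empty:
            raise ValueError(f"summary holds no rows for preset {preset!r}")
    else:
        table = summarize(r for r in results if r.preset == preset)
    if objective not in table.columns:
        raise ValueError(f"unknown objective {objective!r}")
    table = table.assign(admissible=table["peak_T_C"] <= threshold_C)
    ok = table[table["admissible"]]
    if ok.empty:
        return SelectionVerdict(False, None, None, objective, threshold_C, table,
                                "no admissible dose: every candidate exceeds the threshold")
    best_val = ok[objective].max()
    winners = ok[ok[objective] == best_val].sort_values(["q", "tau_ms", "spot_mm"])
    row = winners.iloc[0]
    note = ""
    if len(winners) > 1:
        note = (f"{len(winners)} candidates tied at {objective}={best_val:.6g}; "
                "broke the tie toward lower q, then lower tau, then smaller spot")
    return SelectionVerdict(
        True,
        (float(row["q"]), float(row["tau_ms"]), float(row["spot_mm"])),
        float(best_val),
        objective,
        threshold_C,
        table,
        note,
    )
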