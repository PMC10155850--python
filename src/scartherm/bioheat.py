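"""Transient Pennes bioheat solver on the axisymmetric (r, z) grid.

The temperature field obeys

    rho c dT/dt = (1/r) d/dr(k r dT/dr) + d/dz(k dT/dz)
                  + rho_b c_b w_b (T_art - T) + Q(r, z, t)

discretized by a cell-centered finite-volume scheme (annular cells,
harmonic-mean face conductivities, exact on nonuniform axial meshes).
The irradiated top surface exchanges heat with ambient air through a
convective film coefficient h; the bottom and outer-radius surfaces are
held at body temperature, and the axis is a symmetry (zero-flux) line.

Time integration is backward Euler (unconditionally stable) with a
uniform fine step through the pulse window and geometrically coarsening
steps through the cooling phase; the pulse envelope is averaged exactly
over each step so the deposited energy is independent of step size.  An
explicit forward-Euler scheme is available and refuses steps beyond its
stability bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .laser import DoseParams, HeatSourceField, SourceOptions
from .tissue import MaterialGrid

__all__ = [
    "SolverSpec",
    "SolverError",
    "TemperatureField",
    "TransientResult",
    "BioheatSolver",
    "solve_transient",
    "grid_convergence_report",
]


class SolverError(RuntimeError):
    """Stability violation, diverged solve, or unphysical temperatures."""


@dataclass(frozen=True)
class SolverSpec:
    """Numerical controls for the transient solve.

    Attributes
    ----------
    scheme : {"implicit", "explicit"}
    t_end : float
        Simulation horizon in seconds (>= 1 s covers the full cooling
        transient the study reports).
    pulse_steps : int
        Uniform backward-Euler steps across the pulse window.
    cooling_growth, dt_max : float
        After the pulse the step grows geometrically by
        ``cooling_growth`` per step up to ``dt_max`` seconds.
    dt : float, optional
        Fixed step override (required for the explicit scheme).
    h : float
        Convective film coefficient of the top surface, W/(m^2 K).
    bc_top, bc_bottom, bc_outer : {"convective", "dirichlet", "insulated"}
    T_boundary : float
        Temperature of Dirichlet boundaries (degC).
    """

    scheme: str = "implicit"
    t_end: float = 1.0
    pulse_steps: int = 250
    cooling_growth: float = 1.3
    dt_max: float = 0.05
    dt: float | None = None
    h: float = 10.0
    bc_top: str = "convective"
    bc_bottom: str = "dirichlet"
    bc_outer: str = "dirichlet"
    T_boundary: float = 37.0
    snapshot_times: tuple = ()
    sanity_max_C: float = 120.0

    def __post_init__(self) -> None:
        if self.scheme not in ("implicit", "explicit"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        for name in ("bc_top", "bc_bottom", "bc_outer"):
            if getattr(self, name) not in ("convective", "dirichlet", "insulated"):
                raise ValueError(f"unknown boundary kind for {name}")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.scheme == "explicit" and self.dt is None:
            raise ValueError("explicit scheme requires an explicit dt")


@dataclass
class TemperatureField:
    """Temperature (degC) on the grid plus its timestamp."""

    T: np.ndarray
    time: float = 0.0


@dataclass
class TransientResult:
    """History of a transient solve.

    ``axis_history`` holds the r = 0 column at every accepted step;
    the probe cell is the axis cell hottest at the end of the pulse
    (a reproducible stand-in for the study's "central temperature").
    """

    times: np.ndarray
    axis_history: np.ndarray  # (n_times, nz)
    probe_index: int
    T_final: np.ndarray
    snapshots: dict = field(default_factory=dict)

    @property
    def probe_trace(self) -> np.ndarray:
        return self.axis_history[:, self.probe_index]

    @property
    def peak_T(self) -> float:
        return float(self.probe_trace.max())

    @property
    def t_peak(self) -> float:
        return float(self.times[int(self.probe_trace.argmax())])

    def probe_at(self, t: float) -> float:
        """Probe temperature at time t (linear interpolation)."""
        return float(np.interp(t, self.times, self.probe_trace))


class BioheatSolver:
    """Finite-volume Pennes operator bound to one material grid."""

    def __init__(self, grid: MaterialGrid, spec: SolverSpec = SolverSpec()):
        self.grid = grid
        self.spec = spec
        self._assemble()
        self._lu = None
        self._lu_dt = None

    # -- discrete operator -------------------------------------------------
    def _assemble(self) -> None:
        g, spec = self.grid, self.spec
        nr, nz = g.nr, g.nz
        n = nr * nz
        k = g.k
        dr = g.dr_m
        dz = g.dz_m
        idx = np.arange(n).reshape(nz, nr)

        rows, cols, vals = [], [], []

        def add_pair(a, b, G):
            rows.extend([a, b, a, b])
            cols.extend([a, b, b, a])
            vals.extend([G, G, -G, -G])

        # radial faces between (j, i) and (j, i+1)
        r_edge = (np.arange(1, nr)) * dr
        for i in range(nr - 1):
            kbar = 2.0 * k[:, i] * k[:, i + 1] / (k[:, i] + k[:, i + 1])
            G = kbar * (2.0 * np.pi * r_edge[i] * dz) / dr
            for j in range(nz):
                add_pair(idx[j, i], idx[j, i + 1], G[j])

        # axial faces between (j, i) and (j+1, i)
        face_area = 2.0 * np.pi * g.r_m * dr
        for j in range(nz - 1):
            resist = dz[j] / (2.0 * k[j, :]) + dz[j + 1] / (2.0 * k[j + 1, :])
            G = face_area / resist
            for i in range(nr):
                add_pair(idx[j, i], idx[j + 1, i], G[i])

        K = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

        # boundary conductances (diagonal) and their fixed RHS drive
        Ub = np.zeros(n)
        bb = np.zeros(n)
        T1 = g.tissue.T1

        def side(cells, area, half_thick, kcell, kind, T_ext):
            if kind == "insulated":
                return
            if kind == "convective":
                U = area / (1.0 / spec.h + half_thick / kcell)
                T_ext = T1
            else:  # dirichlet
                U = area * kcell / half_thick
            Ub[cells] += U
            bb[cells] += U * T_ext

        side(idx[0, :], face_area, dz[0] / 2.0, k[0, :], spec.bc_top, spec.T_boundary)
        side(idx[-1, :], face_area, dz[-1] / 2.0, k[-1, :], spec.bc_bottom, spec.T_boundary)
        outer_area = 2.0 * np.pi * (g.domain.radius * 1e-3) * dz
        side(idx[:, -1], outer_area, dr / 2.0, k[:, -1], spec.bc_outer, spec.T_boundary)

        V = g.volumes.ravel()
        self._K = K
        self._C = Ub + g.perfusion.ravel() * V  # W/K, diagonal
        self._b0 = bb + g.perfusion.ravel() * V * g.tissue.T_art
        self._heat_capacity = g.rho_c.ravel() * V  # J/K
        self._V = V

    # -- stepping ----------------------------------------------------------
    def explicit_stable_dt(self) -> float:
        """Largest stable forward-Euler step (positivity bound)."""
        # off-diagonal row sum equals the diagonal (conservation), so the
        # total outflow coefficient per cell is diagonal + C
        total = self._K.diagonal() + self._C
        return float((self._heat_capacity / total).min())

    def step(self, state: TemperatureField, dt: float, Q: np.ndarray | None = None) -> TemperatureField:
        """Advance one time step of length ``dt``.

        ``Q`` is the step-averaged volumetric source (W/m^3) on the
        grid, already including the pulse envelope.
        """
        T = state.T.ravel()
        rhs_src = np.zeros_like(T) if Q is None else Q.ravel() * self._V
        if self.spec.scheme == "explicit":
            bound = self.explicit_stable_dt()
            if dt > bound:
                raise SolverError(
                    f"explicit step dt={dt:.3e} s violates the stability bound; "
                    f"require dt <= {bound:.3e} s"
                )
            flux = -(self._K @ T) - self._C * T + self._b0 + rhs_src
            Tn = T + dt * flux / self._heat_capacity
        else:
            if self._lu is None or self._lu_dt != dt:
                M = self._K + sparse.diags(self._C + self._heat_capacity / dt)
                self._lu = splu(M.tocsc())
                self._lu_dt = dt
            Tn = self._lu.solve(self._heat_capacity / dt * T + self._b0 + rhs_src)
        Tn = Tn.reshape(self.grid.nz, self.grid.nr)
        self._check(Tn)
        return TemperatureField(Tn, state.time + dt)

    def _check(self, T: np.ndarray) -> None:
        g = self.grid
        lo = min(g.tissue.T0, g.tissue.T1) - 1.0
        if not np.isfinite(T).all():
            raise SolverError("temperature field is not finite")
        if T.min() < lo or T.max() > self.spec.sanity_max_C:
            raise SolverError(
                f"temperature left the sanity bounds [{lo}, {self.spec.sanity_max_C}] degC: "
                f"range [{T.min():.2f}, {T.max():.2f}]"
            )

    # -- time grid ---------------------------------------------------------
    def time_grid(self, source: HeatSourceField | None) -> np.ndarray:
        spec = self.spec
        if spec.dt is not None:
            n = int(np.ceil(spec.t_end / spec.dt))
            return np.linspace(0.0, spec.t_end, n + 1)
        if source is not None:
            t_pulse = min(source.pulse_window()[1], spec.t_end)
            times = list(np.linspace(0.0, t_pulse, spec.pulse_steps + 1))
            dt = t_pulse / spec.pulse_steps * 4.0
        else:
            times = [0.0]
            dt = spec.t_end / 200.0
        t = times[-1]
        while t < spec.t_end:
            t = min(t + dt, spec.t_end)
            times.append(t)
            dt = min(dt * spec.cooling_growth, spec.dt_max)
        return np.array(times)

    def run(
        self,
        source: HeatSourceField | None = None,
        T_init: np.ndarray | None = None,
        extra_source=None,
        hooks: tuple = (),
    ) -> TransientResult:
        """Integrate from t = 0 to ``spec.t_end``.

        extra_source : callable (t0, t1) -> (nz, nr) array, optional
            Additional step-averaged volumetric source in W/m^3 (used by
            manufactured-solution verification).
        hooks : iterable of callables
            Called as hook(T_prev, T_new, t0, t1) after every step
            (damage accumulation couples through this).
        """
        g = self.grid
        if T_init is None:
            T_init = np.full((g.nz, g.nr), g.tissue.T0)
        state = TemperatureField(np.array(T_init, dtype=float), 0.0)
        times = self.time_grid(source)
        axis = np.empty((len(times), g.nz))
        axis[0] = state.T[:, 0]
        snap_times = sorted(self.spec.snapshot_times)
        snapshots = {}
        pulse_end = source.pulse_window()[1] if source is not None else 0.0
        probe_idx = 0
        for n in range(len(times) - 1):
            t0, t1 = times[n], times[n + 1]
            Q = None
            if source is not None:
                Q = source.step_average(t0, t1)
            if extra_source is not None:
                Qe = extra_source(t0, t1)
                Q = Qe if Q is None else Q + Qe
            prev = state.T
            state = self.step(state, t1 - t0, Q)
            axis[n + 1] = state.T[:, 0]
            for hook in hooks:
                hook(prev, state.T, t0, t1)
            while snap_times and t1 >= snap_times[0] - 1e-12:
                snapshots[snap_times.pop(0)] = state.T.copy()
            if t0 < pulse_end <= t1 or (pulse_end == 0.0 and n == 0):
                probe_idx = int(axis[n + 1].argmax())
        return TransientResult(times, axis, probe_idx, state.T, snapshots)


def solve_transient(
    grid: MaterialGrid,
    dose: DoseParams,
    spec: SolverSpec = SolverSpec(),
    options: SourceOptions = SourceOptions(),
    hooks: tuple = (),
) -> TransientResult:
    """Run one laser exposure on a prepared domain grid."""
    solver = BioheatSolver(grid, spec)
    return solver.run(HeatSourceField(dose, grid, options), hooks=hooks)


def grid_convergence_report(preset: str, dose: DoseParams, resolutions, spec: SolverSpec = SolverSpec()):
    """Peak probe temperature across grid resolutions (verification aid).

    ``resolutions`` is an iterable of GridSpec.  Returns a DataFrame
    with one row per resolution and the successive peak differences;
    a convergent sequence shows shrinking differences.
    """
    import pandas as pd

    from .tissue import build_domain

    resolutions = list(resolutions)
    if len(resolutions) < 3:
        raise ValueError("need at least 3 resolutions for a convergence report")
    rows = []
    for res in resolutions:
        _, grid = build_domain(preset, res)
        result = solve_transient(grid, dose, spec)
        rows.append({
            "dr_mm": res.dr_mm,
            "nz": grid.nz,
            "n_cells": grid.nr * grid.nz,
            "peak_T_C": result.peak_T,
        })
    df = pd.DataFrame(rows)
    df["delta_peak"] = df["peak_T_C"].diff().abs()
    ratios = df["delta_peak"].iloc[1:-1].values / df["delta_peak"].iloc[2:].values
    df["richardson_ratio"] = [np.nan, np.nan, *ratios]
    return df
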