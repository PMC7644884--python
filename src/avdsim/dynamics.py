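"""Time-dependent water/osmolyte flux dynamics.

State variables are the cell volume ``V`` (cm^3) and the total molar
amount of intracellular osmolyte ``N`` (mol); the internal concentration
``Ci = N/V`` and gradient ``dC = Ci - C0`` are derived.  The coupled
fluxes are

    dV/dt = -rho * (S - dC) * A * Pw        (water, reverse osmosis)
    dN/dt = -(S + dC) * A * Pi              (osmolyte, channel efflux)

with the osmolyte efflux driven by the concentration gradient *and*
aided by the excess hydrostatic pressure.  The (V, N) formulation is the
workhorse because it conserves N exactly when channels are blocked
(Pi = 0); the equivalent (V, dC) formulation

    d(dC)/dt = -(S + dC) A Pi / V + (C0 + dC)(S - dC) rho A Pw / V

is provided as a cross-check.

The system is two-timescale: dC relaxes in seconds (tau ~ (r/3)/(Pi +
C0 rho Pw), ~12 s at default parameters) while the volume drains over
hours, so the default integrator is stiffness-capable (LSODA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model_core import (
    ModelParameters,
    SECONDS_PER_HOUR,
    qss_relative_rate,
)

__all__ = [
    "CellState",
    "Schedule",
    "Trajectory",
    "IntegrationOptions",
    "IntegrationError",
    "QssNotReachedError",
    "equilibrium_state",
    "membrane_area",
    "rhs_volume_osmolyte",
    "rhs_delta_c",
    "integrate",
    "integrate_delta_c",
    "equilibrium_blocked",
    "detect_qss",
    "qss_relaxation_time",
    "sweep",
]


class IntegrationError(RuntimeError):
    """The ODE solver failed; carries the time at which it gave up."""

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


class QssNotReachedError(RuntimeError):
    """No quasi-steady plateau was found within the trajectory horizon."""


@dataclass(frozen=True)
class CellState:
    """Instantaneous cell state: volume (cm³) and osmolyte amount (mol)."""

    volume: float
    osmolyte_amount: float

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError(f"volume must be positive, got {self.volume}")
        if self.osmolyte_amount < 0:
            raise ValueError(
                f"osmolyte_amount must be non-negative, got {self.osmolyte_amount}"
            )

    @property
    def internal_concentration(self) -> float:
        """Ci = N/V in mol/cm³ (derived, never stored independently)."""
        return self.osmolyte_amount / self.volume

    def delta_c(self, external_osmolarity: float) -> float:
        """Osmotic gradient dC = Ci − C0 in mol/cm³."""
        return self.internal_concentration - external_osmolarity


def equilibrium_state(params: ModelParameters, delta_c0: float = 0.0) -> CellState:
    """State of a cell osmotically equilibrated before pressure onset.

    ``delta_c0`` sets a pre-existing gradient; the default 0 means
    Ci(0) = C0 (no excess before the pressure step).
    """
    v0 = params.initial_volume
    return CellState(
        volume=v0, osmolyte_amount=(params.external_osmolarity + delta_c0) * v0
    )


def membrane_area(params: ModelParameters, volume: float) -> float:
    """Membrane area at the given volume under the parameter's area_mode."""
    if params.area_mode == "constant":
        return params.initial_area
    # sphere_coupled: A = (36 pi)^(1/3) V^(2/3), beyond the constant-A model
    return (36.0 * math.pi) ** (1.0 / 3.0) * volume ** (2.0 / 3.0)


def rhs_volume_osmolyte(
    state: CellState, params: ModelParameters
) -> tuple[float, float]:
    """Right-hand sides (dV/dt, dN/dt) in (cm³/s, mol/s)."""
    rho = params.constants.water_molar_volume
    s = params.pressure_equivalent
    dc = state.delta_c(params.external_osmolarity)
    area = membrane_area(params, state.volume)
    dv_dt = -rho * (s - dc) * area * params.water_permeability
    dn_dt = -(s + dc) * area * params.ion_permeability
    return dv_dt, dn_dt


def rhs_delta_c(state: CellState, params: ModelParameters) -> float:
    """d(dC)/dt in mol·cm⁻³·s⁻¹, evaluated from the dC-form equation.

    Exactly equals the chain-rule combination d(N/V)/dt of the (V, N)
    right-hand sides; kept separate as a consistency cross-check.
    """
    rho = params.constants.water_molar_volume
    s = params.pressure_equivalent
    c0 = params.external_osmolarity
    dc = state.delta_c(c0)
    v = state.volume
    area = membrane_area(params, v)
    return (
        -(s + dc) / v * area * params.ion_permeability
        + (c0 + dc) / v * (s - dc) * rho * area * params.water_permeability
    )


@dataclass(frozen=True)
class Schedule:
    """Piecewise-constant-in-time parameter overrides.

    ``segments`` is an ordered list of ``(time_start_s, overrides)`` where
    ``overrides`` maps :class:`ModelParameters` field names to new values.
    The first segment must start at t = 0 and times must strictly
    increase.  Integration restarts at each breakpoint, so steps (pressure
    onset, channel blockade) are handled exactly.
    """

    segments: tuple[tuple[float, Mapping[str, float]], ...] = ((0.0, {}),)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule needs at least one segment")
        times = [t for t, _ in self.segments]
        if times[0] != 0.0:
            raise ValueError(f"first segment must start at t=0, got t={times[0]}")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"segment start times must strictly increase: {times}")
        object.__setattr__(
            self,
            "segments",
            tuple((float(t), dict(ov)) for t, ov in self.segments),
        )

    @classmethod
    def constant(cls) -> "Schedule":
        return cls()

    @classmethod
    def step(cls, time_s: float, **overrides: float) -> "Schedule":
        """Single parameter step at ``time_s`` (e.g. channel blockade)."""
        return cls(segments=((0.0, {}), (time_s, overrides)))

    def params_at(self, t: float, base: ModelParameters) -> ModelParameters:
        """Effective parameters at time t (piecewise-constant semantics)."""
        current: dict[str, float] = {}
        for start, overrides in self.segments:
            if t < start:
                break
            current = dict(overrides)
        return base.with_(**current) if current else base

    @property
    def is_trivial(self) -> bool:
        return all(not ov for _, ov in self.segments)


@dataclass(frozen=True)
class IntegrationOptions:
    """Solver settings.

    ``atol_scale`` scales the absolute tolerance per state variable to its
    initial magnitude (atol = atol_scale * (V0, N0)); the default pairing
    rtol 1e-8 / atol_scale 1e-12 resolves both the seconds-scale dC
    transient and the hours-scale drainage.  ``min_volume_fraction`` is a
    terminal stop (default half the initial volume — deliberately more
    permissive than the ~10–20 % losses the constant-area model is meant
    for, and flagged in the trajectory metadata when it triggers).
    """

    rtol: float = 1.0e-8
    atol_scale: float = 1.0e-12
    max_step: float = math.inf
    method: str = "LSODA"
    min_volume_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol_scale <= 0:
            raise ValueError("tolerances must be positive")
        if not (0.0 <= self.min_volume_fraction < 1.0):
            raise ValueError(
                f"min_volume_fraction must be in [0, 1), got {self.min_volume_fraction}"
            )


@dataclass
class Trajectory:
    """A simulated time course.

    Arrays share one length; ``times`` strictly increases and volumes stay
    positive.  Fluxes are recomputed on demand from the stored states and
    the (possibly scheduled) parameters rather than stored.
    """

    times: np.ndarray
    volume: np.ndarray
    osmolyte: np.ndarray
    params: ModelParameters
    schedule: Schedule = field(default_factory=Schedule)
    options: IntegrationOptions = field(default_factory=IntegrationOptions)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        self.osmolyte = np.asarray(self.osmolyte, dtype=float)
        n = len(self.times)
        if len(self.volume) != n or len(self.osmolyte) != n:
            raise ValueError("times, volume and osmolyte must share one length")
        if n and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must strictly increase")
        if n and np.any(self.volume <= 0):
            raise ValueError("volumes must stay positive")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def internal_concentration(self) -> np.ndarray:
        return self.osmolyte / self.volume

    @property
    def delta_c(self) -> np.ndarray:
        c0 = np.array(
            [
                self.schedule.params_at(t, self.params).external_osmolarity
                for t in self.times
            ]
        )
        return self.internal_concentration - c0

    def _fluxes(self) -> tuple[np.ndarray, np.ndarray]:
        water = np.empty(len(self))
        osmolyte = np.empty(len(self))
        for i, t in enumerate(self.times):
            p = self.schedule.params_at(t, self.params)
            state = CellState(self.volume[i], self.osmolyte[i])
            water[i], osmolyte[i] = rhs_volume_osmolyte(state, p)
        return water, osmolyte

    @property
    def water_flux(self) -> np.ndarray:
        """dV/dt at each sample, cm³/s."""
        return self._fluxes()[0]

    @property
    def osmolyte_flux(self) -> np.ndarray:
        """dN/dt at each sample, mol/s."""
        return self._fluxes()[1]

    def volume_at(self, t: float) -> float:
        """Linearly interpolated volume; t must be inside the horizon."""
        if not (self.times[0] <= t <= self.times[-1]):
            raise ValueError(
                f"t={t} s outside trajectory horizon "
                f"[{self.times[0]}, {self.times[-1]}] s"
            )
        return float(np.interp(t, self.times, self.volume))

    def fractional_water_loss(self, t: float) -> float:
        """1 − V(t)/V(0), the fraction of initial water lost by time t."""
        return 1.0 - self.volume_at(t) / self.volume[0]

    def to_frame(self) -> pd.DataFrame:
        """Numeric columns in the documented order."""
        return pd.DataFrame(
            {
                "time_s": self.times,
                "V_cm3": self.volume,
                "N_mol": self.osmolyte,
                "Ci_mol_cm3": self.internal_concentration,
                "dC_mol_cm3": self.delta_c,
            }
        )


def _segment_t_eval(t0: float, t1: float, n: int) -> np.ndarray:
    """Sample points biased toward the segment start to resolve the fast
    dC transient, merged with uniform coverage of the slow drainage."""
    span = t1 - t0
    early = t0 + np.geomspace(min(1e-3, span / 10.0), span, n // 2)
    late = np.linspace(t0, t1, n - n // 2)
    pts = np.unique(np.concatenate(([t0, t1], early, late)))
    return pts[(pts >= t0) & (pts <= t1)]


def integrate(
    params: ModelParameters,
    t_max: float,
    *,
    init: CellState | None = None,
    schedule: Schedule | None = None,
    options: IntegrationOptions | None = None,
    t_eval: Sequence[float] | None = None,
    n_points: int = 400,
) -> Trajectory:
    """Integrate the (V, N) system from 0 to ``t_max`` seconds.

    Deterministic: no randomness anywhere.  The schedule's overrides are
    applied piecewise-constantly with the solver restarted at each
    breakpoint.  Integration stops early (with a metadata flag) if the
    volume falls below ``options.min_volume_fraction`` of V0.

    Parameters
    ----------
    t_eval : sequence of float, optional
        Explicit output times (e.g. observation times of a measured
        trajectory); defaults to a transient-resolving grid of
        ``n_points`` samples.
    """
    if t_max <= 0:
        raise ValueError(f"t_max must be positive, got {t_max}")
    schedule = schedule or Schedule()
    options = options or IntegrationOptions()
    init = init or equilibrium_state(params)

    breakpoints = [t for t, _ in schedule.segments if 0.0 < t < t_max]
    edges = [0.0, *breakpoints, t_max]

    if t_eval is not None:
        t_eval = np.unique(np.asarray(t_eval, dtype=float))
        if len(t_eval) == 0 or t_eval[0] < 0 or t_eval[-1] > t_max:
            raise ValueError("t_eval must lie within [0, t_max]")

    v0, n0 = init.volume, init.osmolyte_amount
    atol = [options.atol_scale * v0, options.atol_scale * max(n0, v0)]
    v_min = options.min_volume_fraction * v0

    times_out: list[np.ndarray] = []
    v_out: list[np.ndarray] = []
    n_out: list[np.ndarray] = []
    y = np.array([v0, n0])
    stopped_early = False
    seg_points = max(n_points // max(len(edges) - 1, 1), 16)

    for t0, t1 in zip(edges, edges[1:]):
        p = schedule.params_at(t0, params)

        def rhs(t: float, y: np.ndarray) -> list[float]:
            state = CellState(max(y[0], 1e-300), max(y[1], 0.0))
            dv, dn = rhs_volume_osmolyte(state, p)
            return [dv, dn]

        def hit_min_volume(t: float, y: np.ndarray) -> float:
            return y[0] - v_min

        hit_min_volume.terminal = True  # type: ignore[attr-defined]
        hit_min_volume.direction = -1  # type: ignore[attr-defined]

        if t_eval is not None:
            seg_eval = t_eval[(t_eval >= t0) & (t_eval <= t1)]
            if len(seg_eval) == 0 or seg_eval[-1] < t1:
                seg_eval = np.unique(np.append(seg_eval, t1))
            if t0 == 0.0 and (len(seg_eval) == 0 or seg_eval[0] > 0.0):
                seg_eval = np.unique(np.append(seg_eval, 0.0))
        else:
            seg_eval = _segment_t_eval(t0, t1, seg_points)

        sol = solve_ivp(
            rhs,
            (t0, t1),
            y,
            method=options.method,
            rtol=options.rtol,
            atol=atol,
            max_step=options.max_step,
            t_eval=seg_eval,
            events=hit_min_volume,
        )
        if sol.status == -1:
            raise IntegrationError(
                f"integration failed at t = {sol.t[-1] if len(sol.t) else t0:.6g} s: "
                f"{sol.message}",
                time=float(sol.t[-1]) if len(sol.t) else t0,
            )
        times_out.append(sol.t)
        v_out.append(sol.y[0])
        n_out.append(sol.y[1])
        if sol.status == 1:  # min-volume event fired: record the exact stop state
            times_out.append(sol.t_events[0][-1:])
            v_out.append(sol.y_events[0][-1:, 0])
            n_out.append(sol.y_events[0][-1:, 1])
            stopped_early = True
            break
        y = sol.y[:, -1] if sol.y.size else y
        # re-seed next segment from the exact segment end
        y = np.array([v_out[-1][-1], n_out[-1][-1]])

    times = np.concatenate(times_out)
    volume = np.concatenate(v_out)
    osmolyte = np.concatenate(n_out)
    times, idx = np.unique(times, return_index=True)
    traj = Trajectory(
        times=times,
        volume=volume[idx],
        osmolyte=np.clip(osmolyte[idx], 0.0, None),
        params=params,
        schedule=schedule,
        options=options,
        metadata={
            "t_max": t_max,
            "stopped_at_min_volume": stopped_early,
            "initial_volume": v0,
            "initial_osmolyte": n0,
        },
    )
    return traj


def integrate_delta_c(
    params: ModelParameters,
    t_max: float,
    *,
    delta_c0: float = 0.0,
    options: IntegrationOptions | None = None,
    n_points: int = 400,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate the alternative (V, dC) formulation; cross-check only.

    Returns (times, V, dC).  Agreement with :func:`integrate` verifies
    that the dC-form right-hand side is the exact chain-rule consequence
    of the (V, N) fluxes.
    """
    options = options or IntegrationOptions()
    v0 = params.initial_volume
    c0 = params.external_osmolarity

    def rhs(t: float, y: np.ndarray) -> list[float]:
        v, dc = y
        n = (c0 + dc) * max(v, 1e-300)
        state = CellState(max(v, 1e-300), max(n, 0.0))
        dv, _ = rhs_volume_osmolyte(state, params)
        ddc = rhs_delta_c(state, params)
        return [dv, ddc]

    t_eval = _segment_t_eval(0.0, t_max, n_points)
    sol = solve_ivp(
        rhs,
        (0.0, t_max),
        [v0, delta_c0],
        method=options.method,
        rtol=options.rtol,
        atol=[options.atol_scale * v0, options.atol_scale * c0],
        t_eval=t_eval,
    )
    if sol.status != 0:
        raise IntegrationError(f"dC-form integration failed: {sol.message}")
    return sol.t, sol.y[0], sol.y[1]


def equilibrium_blocked(
    params: ModelParameters, init: CellState | None = None
) -> float:
    """Final volume fraction V∞/V0 when osmolyte channels are blocked.

    With Pi = 0 the osmolyte amount is conserved, and water efflux stops
    once the gradient has grown to match the pressure (dC = S):
    V∞/V0 = (C0 + dC(0)) / (C0 + S).  For the default equilibrium start,
    V∞/V0 = C0/(C0 + S) — a sub-percent loss at default parameters, which
    is why blocked channels abolish apoptotic shrinkage in this model.
    The value ignores ``params.ion_permeability``.
    """
    c0 = params.external_osmolarity
    s = params.pressure_equivalent
    dc0 = 0.0 if init is None else init.delta_c(c0)
    return (c0 + dc0) / (c0 + s)


def qss_relaxation_time(params: ModelParameters) -> float:
    """Linearized dC relaxation time tau = (V0/A0)/(Pi + C0 ρ Pw), s.

    For a sphere V0/A0 = r/3 (~12 s at default parameters); the volume
    half-time is hours, giving the two-timescale structure.
    """
    rho = params.constants.water_molar_volume
    rate = params.ion_permeability + (
        params.external_osmolarity * rho * params.water_permeability
    )
    if rate <= 0:
        raise ValueError("relaxation undefined: Pi + C0*rho*Pw must be positive")
    return (params.initial_volume / params.initial_area) / rate


def detect_qss(traj: Trajectory, tol: float = 0.01) -> tuple[float, float]:
    """Locate the quasi-steady plateau of dC in a constant-parameter run.

    Returns ``(onset_time_s, plateau_delta_c)``.  The onset is the first
    sample from which ``|d(dC)/dt|`` stays below ``tol * |dC_ref| / tau``
    (tau the linearized relaxation time, dC_ref the final gradient); the
    plateau value is the median dC from onset onward.

    Raises :class:`QssNotReachedError` when no plateau exists within the
    horizon rather than silently defaulting.
    """
    if not traj.schedule.is_trivial:
        raise ValueError("detect_qss requires a constant-parameter trajectory")
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol}")
    params = traj.params
    tau = qss_relaxation_time(params)
    dc = traj.delta_c
    ref = abs(dc[-1])
    if ref == 0.0:
        if params.pressure == 0.0:  # no forcing: already at steady state
            return float(traj.times[0]), 0.0
        raise QssNotReachedError("dC never moved away from zero under forcing")
    rates = np.array(
        [
            abs(
                rhs_delta_c(
                    CellState(traj.volume[i], traj.osmolyte[i]), params
                )
            )
            for i in range(len(traj))
        ]
    )
    threshold = tol * ref / tau
    below = rates <= threshold
    # first index from which the criterion holds for the rest of the run
    holds_from = len(traj)
    for i in range(len(traj) - 1, -1, -1):
        if below[i]:
            holds_from = i
        else:
            break
    if holds_from >= len(traj):
        raise QssNotReachedError(
            f"no quasi-steady plateau within {traj.times[-1]:.6g} s at tol={tol}"
        )
    onset = float(traj.times[holds_from])
    plateau = float(np.median(dc[holds_from:]))
    return onset, plateau


_SWEEPABLE = (
    "pressure",
    "ion_permeability",
    "water_permeability",
    "external_osmolarity",
    "radius",
)


def sweep(
    base: ModelParameters,
    parameter: str,
    values: Iterable[float],
    *,
    t_max: float = 1800.0,
    options: IntegrationOptions | None = None,
) -> pd.DataFrame:
    """One-parameter sweep comparing closed-form and ODE shrinkage rates.

    Returns a DataFrame with one row per grid value: the quasi-steady
    closed-form relative rate and the ODE plateau rate (instantaneous
    relative rate at the first post-onset sample with V ≥ 0.95 V0), both
    in h⁻¹ (signed).  Failures at individual grid points are recorded in
    the ``error`` column, not raised.
    """
    if parameter not in _SWEEPABLE:
        raise ValueError(f"parameter must be one of {_SWEEPABLE}, got {parameter!r}")
    rows = []
    for value in values:
        row: dict[str, object] = {"parameter": parameter, "value": value}
        try:
            p = base.with_(**{parameter: value})
            row["qss_rate_per_h"] = qss_relative_rate(p)
            traj = integrate(p, t_max, options=options)
            onset, plateau_dc = detect_qss(traj)
            v0 = traj.volume[0]
            mask = (traj.times >= onset) & (traj.volume >= 0.95 * v0)
            if not mask.any():
                raise QssNotReachedError(
                    "no sample with V >= 0.95 V0 after the plateau onset"
                )
            i = int(np.argmax(mask))
            state = CellState(traj.volume[i], traj.osmolyte[i])
            dv, _ = rhs_volume_osmolyte(state, p)
            row["ode_rate_per_h"] = dv / v0 * SECONDS_PER_HOUR
            row["plateau_delta_c"] = plateau_dc
            row["error"] = ""
        except Exception as exc:  # per-row failure is data, not fatal
            row.setdefault("qss_rate_per_h", np.nan)
            row["ode_rate_per_h"] = np.nan
            row["plateau_delta_c"] = np.nan
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "parameter",
            "value",
            "qss_rate_per_h",
            "ode_rate_per_h",
            "plateau_delta_c",
            "error",
        ],
    )
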