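"""Hybrid colony dynamics: growth-phase ODEs plus the annual reproductive jump.

Within a season the reserves (N, P) and structure (V) follow forward-Euler
updates of the budget ODEs while the colony count R is frozen; at season end a
discrete impulse converts structure into next year's colonies and resets the
reserves.  Everything is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fluxes import FluxSet, compute_fluxes, reproduction_flux
from .foraging import ForagerAllocation, compute_distribution
from .landscape import LandscapeGrid, ProductionSchedule, reset_for_season, step_resources
from .params import DebParams


@dataclass
class ColonyState:
    """The continuous state: time, reserves, structure, colonies, peak size."""

    t: float = 0.0
    N: float = 0.0
    P: float = 0.0
    V: float = 0.0
    R: float = 1.0
    n_max: float = 0.0

    def copy(self) -> "ColonyState":
        return replace(self)


@dataclass
class SeasonEvent:
    """A discrete landscape intervention at a season-local time.

    ``action`` is one of ``"clear_nectar"`` / ``"clear_pollen"`` (remove the
    corresponding stocks from every node).  Used to induce sudden shortages.
    """

    time: float
    action: str

    def apply(self, grid: LandscapeGrid) -> None:
        if self.action == "clear_nectar":
            grid.nectar[:] = 0.0
        elif self.action == "clear_pollen":
            grid.pollen[:] = 0.0
        else:
            raise ValueError(f"unknown event action {self.action!r}")


@dataclass
class Trajectory:
    """Recorded time series of one growth phase (or several, concatenated)."""

    times: list[float] = field(default_factory=list)
    records: list[dict] = field(default_factory=list)
    node_snapshots: list[dict] = field(default_factory=list)

    def append(self, record: dict) -> None:
        if self.times and record["t"] <= self.times[-1]:
            raise ValueError("sample times must be strictly increasing")
        self.times.append(record["t"])
        self.records.append(record)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def node_snapshot_frame(self, grid: LandscapeGrid) -> pd.DataFrame:
        """Long-format per-node snapshots: one row per (t, node).

        Columns: t, node_x, node_y, rho_N, rho_P, F_N, F_P — suitable for
        rendering forager-density and resource heat maps.
        """
        frames = []
        for snap in self.node_snapshots:
            frames.append(pd.DataFrame({
                "t": snap["t"],
                "node_x": grid.coords[:, 0],
                "node_y": grid.coords[:, 1],
                "rho_N": snap["rho_N"],
                "rho_P": snap["rho_P"],
                "F_N": snap["F_N"],
                "F_P": snap["F_P"],
            }))
        if not frames:
            return pd.DataFrame(
                columns=["t", "node_x", "node_y", "rho_N", "rho_P",
                         "F_N", "F_P"]
            )
        return pd.concat(frames, ignore_index=True)

    def __len__(self) -> int:
        return len(self.records)


def derivatives(
    state: ColonyState, fluxes: FluxSet, params: DebParams
) -> tuple[float, float, float]:
    """Right-hand sides for (dN/dt, dP/dt, dV/dt).

    Nectar pays maintenance, heating, travel, and evaporates at rate theta;
    pollen pays maintenance and growth; structure grows with the growth flux
    scaled by R / E_G and dies at a baseline rate boosted exponentially as the
    nectar reserve empties.
    """
    dN = (
        fluxes.assimilation_nectar
        - fluxes.maintenance_nectar
        - fluxes.heating
        - fluxes.travel
        - params.theta * state.N
    )
    dP = fluxes.assimilation_pollen - fluxes.maintenance_pollen - fluxes.growth
    death_rate = params.delta_0 + params.delta_n * math.exp(
        -state.N / params.eps_n
    )
    dV = (state.R / params.e_g) * fluxes.growth - death_rate * state.V
    return dN, dP, dV


def euler_step(
    state: ColonyState,
    grid: LandscapeGrid,
    schedule: ProductionSchedule,
    params: DebParams,
    dt: float,
    t_local: float | None = None,
) -> tuple[ColonyState, ForagerAllocation, FluxSet]:
    """One forward-Euler step of colony and landscape, returning the new state.

    ``t_local`` is the season-local time used to query the production
    schedule (defaults to ``state.t``).  The grid is advanced in place.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not all(map(math.isfinite, (state.N, state.P, state.V, state.R))):
        raise FloatingPointError(
            f"non-finite state at t={state.t}: N={state.N} P={state.P} "
            f"V={state.V} R={state.R}"
        )
    if t_local is None:
        t_local = state.t

    alloc = compute_distribution(state.N, state.P, state.V, grid, params)
    fluxes = compute_fluxes(
        state.N, state.P, state.V, state.n_max, alloc, grid, params
    )
    dN, dP, dV = derivatives(state, fluxes, params)

    new_state = ColonyState(
        t=state.t + dt,
        N=max(0.0, state.N + dt * dN),
        P=max(0.0, state.P + dt * dP),
        V=max(0.0, state.V + dt * dV),
        R=state.R,
        n_max=state.n_max,
    )
    new_state.n_max = max(new_state.n_max, params.alpha * new_state.V)

    prod_n, prod_p = schedule.production_at(t_local)
    step_resources(
        grid,
        prod_n,
        prod_p,
        fluxes.ingestion_nectar_per_node,
        fluxes.ingestion_pollen_per_node,
        params.gamma_n,
        params.gamma_p,
        dt,
    )
    return new_state, alloc, fluxes


def _record(
    state: ColonyState,
    alloc: ForagerAllocation,
    fluxes: FluxSet,
    grid: LandscapeGrid,
    crop_nodes: tuple[int, ...] | None,
) -> dict:
    rec = {
        "t": state.t,
        "N": state.N,
        "P": state.P,
        "V": state.V,
        "R": state.R,
        "n_N": alloc.n_nectar,
        "n_P": alloc.n_pollen,
        "n_max": state.n_max,
        "sum_F_N": float(grid.nectar.sum()),
        "sum_F_P": float(grid.pollen.sum()),
        "p_X_N": fluxes.ingestion_nectar,
        "p_X_P": fluxes.ingestion_pollen,
        "p_A_N": fluxes.assimilation_nectar,
        "p_A_P": fluxes.assimilation_pollen,
        "p_M_N": fluxes.maintenance_nectar,
        "p_M_P": fluxes.maintenance_pollen,
        "p_H": fluxes.heating,
        "p_C": fluxes.travel,
        "p_G": fluxes.growth,
    }
    if crop_nodes is not None:
        idx = list(crop_nodes)
        rec["crop_foragers"] = float(
            np.sum(
                alloc.n_nectar * alloc.rho_nectar[idx]
                + alloc.n_pollen * alloc.rho_pollen[idx]
            )
        )
    return rec


def run_growth_phase(
    state: ColonyState,
    grid: LandscapeGrid,
    schedule: ProductionSchedule,
    params: DebParams,
    season_length: float | None = None,
    dt: float | None = None,
    record_stride: int = 1,
    events: tuple[SeasonEvent, ...] = (),
    crop_nodes: tuple[int, ...] | None = None,
    record_nodes: bool = False,
) -> tuple[ColonyState, Trajectory]:
    """Integrate one growth phase of ``season_length`` days.

    The peak colony size ``n_max`` is reset to ``alpha V`` at phase start.
    Samples are recorded every ``record_stride`` steps plus the final state;
    with ``record_nodes`` the per-node densities and stocks are kept too.
    Returns the end-of-season state (the reproduction-flux input) and the
    trajectory.
    """
    if season_length is None:
        season_length = params.season_length
    if dt is None:
        dt = params.dt
    if season_length <= 0:
        raise ValueError("season_length must be positive")

    state = state.copy()
    state.n_max = params.alpha * state.V
    t0 = state.t
    n_steps = int(round(season_length / dt))
    pending = sorted(events, key=lambda e: e.time)
    traj = Trajectory()

    for step in range(n_steps):
        t_local = step * dt
        while pending and pending[0].time <= t_local + 1e-12:
            pending.pop(0).apply(grid)
        record_now = step % record_stride == 0
        if record_now:
            alloc = compute_distribution(state.N, state.P, state.V, grid, params)
            fluxes = compute_fluxes(
                state.N, state.P, state.V, state.n_max, alloc, grid, params
            )
            traj.append(_record(state, alloc, fluxes, grid, crop_nodes))
            if record_nodes:
                _snapshot_nodes(traj, state.t, alloc, grid)
        state, _, _ = euler_step(state, grid, schedule, params, dt, t_local)

    state.t = t0 + season_length  # avoid accumulated rounding in t
    alloc = compute_distribution(state.N, state.P, state.V, grid, params)
    fluxes = compute_fluxes(
        state.N, state.P, state.V, state.n_max, alloc, grid, params
    )
    traj.append(_record(state, alloc, fluxes, grid, crop_nodes))
    if record_nodes:
        _snapshot_nodes(traj, state.t, alloc, grid)
    return state, traj


def _snapshot_nodes(traj, t, alloc, grid) -> None:
    traj.node_snapshots.append({
        "t": t,
        "rho_N": alloc.rho_nectar.copy(),
        "rho_P": alloc.rho_pollen.copy(),
        "F_N": grid.nectar.copy(),
        "F_P": grid.pollen.copy(),
    })


def reproductive_jump(state: ColonyState, params: DebParams) -> ColonyState:
    """Season-end impulse: queens are produced, overwinter, and refound.

    R' = max(0, R + p_R - delta_R R); reserves reset to zero; V' = eps_V R'.
    """
    if state.R < 0:
        raise ValueError("R must be nonnegative at the jump")
    if state.R == 0.0:
        new_r = 0.0
    else:
        p_r = reproduction_flux(
            state.V,
            state.R,
            params.c_r,
            params.eps_r,
            params.psi,
            params.reproduction_normalized,
        )
        new_r = max(0.0, state.R + p_r - params.delta_r * state.R)
    new_v = params.eps_v * new_r
    return ColonyState(
        t=state.t, N=0.0, P=0.0, V=new_v, R=new_r,
        n_max=params.alpha * new_v,
    )


def run_multi_year(
    grid: LandscapeGrid,
    schedule: ProductionSchedule,
    params: DebParams,
    years: int,
    initial_r: float = 1.0,
    record_stride: int = 1,
    events: tuple[SeasonEvent, ...] = (),
    crop_nodes: tuple[int, ...] | None = None,
    initial_nectar: float | np.ndarray = 0.0,
    initial_pollen: float | np.ndarray = 0.0,
    record_nodes: bool = False,
) -> tuple[list[Trajectory], pd.DataFrame]:
    """Alternate growth phases and reproductive jumps for ``years`` seasons.

    The landscape is reset to the scenario's initial stocks at every season
    start.  The annual summary samples V and R immediately before each
    reproductive impulse.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    state = ColonyState(
        t=0.0, N=0.0, P=0.0, V=params.eps_v * initial_r, R=initial_r,
    )
    trajectories: list[Trajectory] = []
    summary_rows = []
    for year in range(1, years + 1):
        reset_for_season(grid, initial_nectar, initial_pollen)
        state, traj = run_growth_phase(
            state,
            grid,
            schedule,
            params,
            record_stride=record_stride,
            events=events,
            crop_nodes=crop_nodes,
            record_nodes=record_nodes,
        )
        trajectories.append(traj)
        summary_rows.append(
            {"year": year, "V_pre_impulse": state.V, "R_pre_impulse": state.R}
        )
        state = reproductive_jump(state, params)
    return trajectories, pd.DataFrame(summary_rows)


def extinction_time(
    trajectory: Trajectory,
    threshold: float = 1.0,
    alpha: float = 1.0,
) -> float | None:
    """First sampled time with ``alpha V`` below the threshold, if any."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    for rec in trajectory.records:
        if alpha * rec["V"] < threshold:
            return rec["t"]
    return None
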