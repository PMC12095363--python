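"""Energy fluxes of the colony-level dynamic energy budget.

All fluxes are nonnegative rates: nectar fluxes in ml/day, pollen fluxes in
g/day.  Ingestion couples the colony to the landscape through the forager
distribution; maintenance, heating, and travel drain the reserves; growth
converts reserves into structure; reproduction converts end-of-season
structure into next year's colonies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .foraging import ForagerAllocation
from .landscape import LandscapeGrid
from .params import DebParams


@dataclass
class FluxSet:
    """All in-season fluxes evaluated at one instant."""

    ingestion_nectar: float
    ingestion_pollen: float
    ingestion_nectar_per_node: np.ndarray
    ingestion_pollen_per_node: np.ndarray
    faeces_nectar: float
    faeces_pollen: float
    assimilation_nectar: float
    assimilation_pollen: float
    maintenance_nectar: float
    maintenance_pollen: float
    heating: float
    travel: float
    growth: float


def ingestion(
    stocks: np.ndarray,
    rho: np.ndarray,
    n_foragers: float,
    c_x: float,
    form: str = "smooth",
) -> tuple[float, np.ndarray]:
    """Collection rate per node and in total for one forager guild.

    The per-node demand is ``a_i = c_x * n * rho_i`` (resource/day).  The
    smooth form ``u_i = a_i F_i / (F_i + a_i)`` saturates at the demand when
    stocks are ample and at ``F_i`` per day when stocks are scarce; the
    hard-min form takes ``min(F_i, a_i)`` directly.  Both limits carry an
    implicit unit rate constant of 1/day in the scarce regime.
    """
    stocks = np.asarray(stocks, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if n_foragers < 0 or c_x < 0:
        raise ValueError("forager count and collection rate must be >= 0")
    demand = c_x * n_foragers * rho
    if form == "smooth":
        denom = stocks + demand
        per_node = np.divide(
            demand * stocks, denom, out=np.zeros_like(stocks), where=denom > 0
        )
    elif form == "hardmin":
        per_node = np.minimum(stocks, demand)
    else:
        raise ValueError(f"unknown ingestion form {form!r}")
    return float(per_node.sum()), per_node


def assimilation_and_faeces(
    ingested: float, c_p: float, c_a: float
) -> tuple[float, float]:
    """Split an ingestion rate into faeces and assimilated reserve intake."""
    faeces = c_p * ingested
    assimilated = c_a * (ingested - faeces)
    return faeces, assimilated


def somatic_maintenance(V: float, params: DebParams) -> tuple[float, float]:
    """Nectar and pollen maintenance of ``alpha V`` foragers + ``beta V`` brood."""
    if V < 0:
        raise ValueError("V must be nonnegative")
    foragers = params.alpha * V
    brood = params.beta * V
    nectar = params.c_m1_n * foragers + params.c_m2_n * brood
    pollen = params.c_m1_p * foragers + params.c_m2_p * brood
    return nectar, pollen


def heating(n_max: float, c_h: float) -> float:
    """Nest-heating cost, proportional to the season's peak colony size."""
    if n_max < 0:
        raise ValueError("n_max must be nonnegative")
    return c_h * n_max


def travel_cost(
    alloc: ForagerAllocation, distances: np.ndarray, c_c: float
) -> float:
    """Energy spent flying: c_c * sum_i (n^N rho^N_i + n^P rho^P_i) d_i."""
    load = alloc.n_nectar * alloc.rho_nectar + alloc.n_pollen * alloc.rho_pollen
    return float(c_c * np.sum(load * np.asarray(distances)))


def growth_flux(
    N: float, P: float, V: float, kappa: float, eps_n: float, eps_p: float
) -> float:
    """Reserve-limited structural growth, 0 <= flux <= kappa.

    Each reserve saturates against a demand that scales with sqrt(V): larger
    colonies need more on hand before the brood can grow at full rate.
    """
    if min(N, P, V) < 0:
        raise ValueError("N, P, V must be nonnegative")
    if N == 0.0 or P == 0.0:
        return 0.0
    root_v = math.sqrt(V)
    return (
        kappa * (P / (P + root_v * eps_p)) * (N / (N + root_v * eps_n))
    )


def reproduction_flux(
    V: float,
    R: float,
    c_r: float,
    eps_r: float,
    psi: float,
    normalized: bool = False,
) -> float:
    """Queens produced at the season-end impulse.

    An arctangent of the per-colony size ``V/R`` relative to the threshold
    ``eps_r``; negative values (undersized colonies) are clamped to zero.
    With ``normalized`` the saturation value is ``c_r * R`` exactly instead of
    ``c_r * R * pi/2``.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    if V < 0:
        raise ValueError("V must be nonnegative")
    raw = c_r * R * math.atan((V / R - eps_r) * psi)
    if normalized:
        raw *= 2.0 / math.pi
    return max(0.0, raw)


def compute_fluxes(
    N: float,
    P: float,
    V: float,
    n_max: float,
    alloc: ForagerAllocation,
    grid: LandscapeGrid,
    params: DebParams,
) -> FluxSet:
    """Evaluate every in-season flux from state, allocation, and landscape."""
    ing_n, ing_n_nodes = ingestion(
        grid.nectar, alloc.rho_nectar, alloc.n_nectar, params.c_x_n,
        params.ingestion_form,
    )
    ing_p, ing_p_nodes = ingestion(
        grid.pollen, alloc.rho_pollen, alloc.n_pollen, params.c_x_p,
        params.ingestion_form,
    )
    faeces_n, assim_n = assimilation_and_faeces(ing_n, params.c_p_n, params.c_a_n)
    faeces_p, assim_p = assimilation_and_faeces(ing_p, params.c_p_p, params.c_a_p)
    maint_n, maint_p = somatic_maintenance(V, params)
    # An extinct colony (V = 0) has no brood: no growth, so extinction is
    # absorbing within a season even if reserves remain.
    growth = (
        0.0 if V == 0.0
        else growth_flux(N, P, V, params.kappa, params.eps_n, params.eps_p)
    )
    return FluxSet(
        ingestion_nectar=ing_n,
        ingestion_pollen=ing_p,
        ingestion_nectar_per_node=ing_n_nodes,
        ingestion_pollen_per_node=ing_p_nodes,
        faeces_nectar=faeces_n,
        faeces_pollen=faeces_p,
        assimilation_nectar=assim_n,
        assimilation_pollen=assim_p,
        maintenance_nectar=maint_n,
        maintenance_pollen=maint_p,
        heating=heating(n_max, params.c_h),
        travel=travel_cost(alloc, grid.distances, params.c_c),
        growth=growth,
    )
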