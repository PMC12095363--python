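"""MaxEnt (Boltzmann) spatial allocation of nectar and pollen foragers.

The colony fields ``n_T = alpha V`` foragers, split between nectar and pollen
collection by the state of the reserves, and each guild distributes over
landscape nodes with probability proportional to ``exp(gain_i / T)``.  The
gain of a node is the saturating per-bee collection rate minus a travel cost;
``T`` interpolates between the ideal free distribution (T -> 0) and a uniform
random distribution (T -> infinity).
"""

from __future__ import annotations

import math

from dataclasses import dataclass

import numpy as np

from .landscape import LandscapeGrid
from .params import DebParams

__all__ = [
    "ForagerAllocation",
    "allocate_forager_numbers",
    "patch_gain",
    "boltzmann_distribution",
    "compute_distribution",
]


@dataclass
class ForagerAllocation:
    """Forager counts per guild and their probability densities over nodes."""

    n_nectar: float
    n_pollen: float
    rho_nectar: np.ndarray
    rho_pollen: np.ndarray

    @property
    def n_total(self) -> float:
        return self.n_nectar + self.n_pollen


def allocate_forager_numbers(
    N: float, P: float, V: float, params: DebParams
) -> tuple[float, float]:
    """Split the ``alpha V`` foragers into nectar and pollen guilds.

    The ratio n^N / n^P = lam (P + eps_P) / (N + eps_N) sends more foragers
    after whichever reserve is scarce; ``lam`` biases towards nectar when the
    reserves are comparable, and the eps terms decide the split when both
    reserves are empty.
    """
    if N < 0 or P < 0 or V < 0:
        raise ValueError("reserves and structure must be nonnegative")
    n_total = params.alpha * V
    weight_nectar = params.lam * (P + params.eps_p)
    weight_pollen = N + params.eps_n
    denom = weight_nectar + weight_pollen
    if denom == 0.0:
        return 0.5 * n_total, 0.5 * n_total
    n_nectar = float(n_total * weight_nectar / denom)
    n_pollen = float(n_total - n_nectar)
    # nudge the smaller guild by ulps (finest control over the rounded sum)
    # so that n_nectar + n_pollen reproduces alpha*V bit-exactly
    for _ in range(64):
        total = n_nectar + n_pollen
        if total == n_total:
            break
        direction = math.inf if total < n_total else -math.inf
        if abs(n_nectar) < abs(n_pollen):
            n_nectar = math.nextafter(n_nectar, direction)
        else:
            n_pollen = math.nextafter(n_pollen, direction)
    if n_pollen < 0.0:
        n_nectar, n_pollen = float(n_total), 0.0
    if n_nectar < 0.0:
        n_nectar, n_pollen = 0.0, float(n_total)
    return n_nectar, n_pollen


def patch_gain(
    stocks: np.ndarray,
    n_foragers: float,
    distances: np.ndarray,
    forager_type: str,
    params: DebParams,
    d_max: float | None = None,
) -> np.ndarray:
    """Per-bee daily gain of each node for one forager guild.

    Nectar foragers pay a travel cost in energy units (``c_c * d``), so their
    gain turns negative beyond ~c_x_n/c_c km at saturation (about 3 km with
    defaults).  Pollen foragers pay a cost scaled against the largest
    nest-to-node distance ``d_max``, so distance alone never forbids a node.
    Gains may be negative.
    """
    stocks = np.asarray(stocks, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if np.any(stocks < 0) or np.any(distances < 0) or n_foragers < 0:
        raise ValueError("stocks, distances and forager count must be >= 0")
    if forager_type == "nectar":
        c_x = params.c_x_n
        cost = params.c_c * distances
    elif forager_type == "pollen":
        c_x = params.c_x_p
        if d_max is None:
            d_max = params.d_max if params.d_max is not None else float(
                distances.max()
            )
        cost = np.zeros_like(distances) if d_max == 0 else c_x * distances / d_max
    else:
        raise ValueError(f"unknown forager_type {forager_type!r}")

    denom = stocks + c_x * n_foragers
    collection = np.divide(
        stocks * c_x, denom, out=np.zeros_like(stocks), where=denom > 0
    )
    return collection - cost


def boltzmann_distribution(gains: np.ndarray, temperature: float) -> np.ndarray:
    """Probability vector rho_i = exp(g_i / T) / Z, max-shifted for safety."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    gains = np.asarray(gains, dtype=float)
    finite = np.isfinite(gains)
    if not finite.any():
        raise ValueError("all gains are -inf; distribution undefined")
    shifted = np.where(finite, gains - gains[finite].max(), -np.inf)
    weights = np.exp(shifted / temperature)
    return weights / weights.sum()


def compute_distribution(
    N: float,
    P: float,
    V: float,
    grid: LandscapeGrid,
    params: DebParams,
) -> ForagerAllocation:
    """Full allocation: guild sizes plus Boltzmann densities over nodes.

    Gains use the guild's *total* forager count in the competition term
    (mean-field crowding), matching the partition-function form.  A ``V = 0``
    colony yields zero foragers with uniform densities.
    """
    n_nodes = grid.n_nodes
    uniform = np.full(n_nodes, 1.0 / n_nodes)
    n_nectar, n_pollen = allocate_forager_numbers(N, P, V, params)
    if V == 0.0:
        return ForagerAllocation(0.0, 0.0, uniform.copy(), uniform.copy())

    d_max = params.d_max if params.d_max is not None else grid.max_distance

    gains_n = patch_gain(grid.nectar, n_nectar, grid.distances, "nectar", params)
    if params.nectar_range_cutoff is not None:
        gains_n = np.where(
            grid.distances <= params.nectar_range_cutoff, gains_n, -np.inf
        )
    rho_n = boltzmann_distribution(gains_n, params.temperature)

    gains_p = patch_gain(
        grid.pollen, n_pollen, grid.distances, "pollen", params, d_max=d_max
    )
    rho_p = boltzmann_distribution(gains_p, params.temperature)

    return ForagerAllocation(n_nectar, n_pollen, rho_n, rho_p)
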