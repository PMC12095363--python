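"""Square-lattice landscapes: geometry, floral production, and stock dynamics.

Each node of a regular square lattice carries a nectar stock ``F_i^N`` (ml)
and a pollen stock ``F_i^P`` (g).  Stocks accrue from a time-dependent
production schedule, are drawn down by forager ingestion, and self-limit
through a quadratic saturation term, so that an unexploited node equilibrates
at ``sqrt(F0 / gamma)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class LandscapeGrid:
    """Node geometry plus the current per-node nectar and pollen stocks.

    ``coords`` holds (x, y) positions in km, ``distances`` the Euclidean
    nest-to-node distances, and ``nest_index`` identifies the nest node
    (distance zero).
    """

    coords: np.ndarray
    nest_index: int
    distances: np.ndarray
    nectar: np.ndarray
    pollen: np.ndarray
    spacing: float

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def max_distance(self) -> float:
        return float(self.distances.max())

    def copy(self) -> "LandscapeGrid":
        return LandscapeGrid(
            coords=self.coords,  # geometry is immutable, share it
            nest_index=self.nest_index,
            distances=self.distances,
            nectar=self.nectar.copy(),
            pollen=self.pollen.copy(),
            spacing=self.spacing,
        )

    def node_at_offset(self, dx_nodes: int, dy_nodes: int) -> int:
        """Index of the node offset from the nest by whole lattice steps."""
        target = self.coords[self.nest_index] + np.array(
            [dx_nodes * self.spacing, dy_nodes * self.spacing]
        )
        dist2 = np.sum((self.coords - target) ** 2, axis=1)
        idx = int(np.argmin(dist2))
        if dist2[idx] > (0.25 * self.spacing) ** 2:
            raise ValueError(
                f"offset ({dx_nodes}, {dy_nodes}) falls outside the grid"
            )
        return idx


def build_grid(
    n_nodes_per_side: int,
    spacing: float,
    nest_at_center: bool = True,
) -> LandscapeGrid:
    """Build an ``n x n`` lattice with zeroed stocks and the nest placed.

    With ``nest_at_center`` the side length must be odd so a central node
    exists.  Otherwise the nest goes to the node nearest the geometric centre,
    ties broken by lowest node index.
    """
    if n_nodes_per_side < 1:
        raise ValueError("n_nodes_per_side must be a positive integer")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if nest_at_center and n_nodes_per_side % 2 == 0:
        raise ValueError(
            "nest_at_center requires an odd n_nodes_per_side "
            f"(got {n_nodes_per_side}); use nest_at_center=False"
        )

    half = (n_nodes_per_side - 1) / 2.0
    axis = (np.arange(n_nodes_per_side) - half) * spacing
    xx, yy = np.meshgrid(axis, axis, indexing="xy")
    coords = np.column_stack([xx.ravel(), yy.ravel()])

    # Geometric centre is the origin by construction; argmin returns the
    # lowest index among ties.
    dist2_to_center = np.sum(coords**2, axis=1)
    nest_index = int(np.argmin(dist2_to_center))

    distances = np.sqrt(np.sum((coords - coords[nest_index]) ** 2, axis=1))
    n = coords.shape[0]
    return LandscapeGrid(
        coords=coords,
        nest_index=nest_index,
        distances=distances,
        nectar=np.zeros(n),
        pollen=np.zeros(n),
        spacing=float(spacing),
    )


@dataclass
class Patch:
    """A set of nodes producing at fixed rates inside a bloom window.

    ``window`` is the half-open interval [t_on, t_off) in days; production is
    zero outside it.  Rates are per node in the set.
    """

    nodes: tuple[int, ...]
    nectar_rate: float = 0.0
    pollen_rate: float = 0.0
    window: tuple[float, float] = (0.0, np.inf)
    label: str = ""

    def __post_init__(self) -> None:
        if self.nectar_rate < 0 or self.pollen_rate < 0:
            raise ValueError("patch production rates must be nonnegative")
        if self.window[1] < self.window[0]:
            raise ValueError("bloom window must satisfy t_off >= t_on")

    def active(self, t: float) -> bool:
        return self.window[0] <= t < self.window[1]


@dataclass
class ProductionSchedule:
    """Per-node production rates: a constant background plus bloom patches."""

    n_nodes: int
    background_nectar: float = 0.0
    background_pollen: float = 0.0
    background_window: tuple[float, float] = (0.0, np.inf)
    patches: list[Patch] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.background_nectar < 0 or self.background_pollen < 0:
            raise ValueError("background rates must be nonnegative")

    def production_at(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Nectar and pollen production rate vectors at time ``t`` (days)."""
        if t < 0:
            raise ValueError("t must be nonnegative")
        nectar = np.zeros(self.n_nodes)
        pollen = np.zeros(self.n_nodes)
        if self.background_window[0] <= t < self.background_window[1]:
            nectar += self.background_nectar
            pollen += self.background_pollen
        for patch in self.patches:
            if patch.active(t):
                idx = list(patch.nodes)
                nectar[idx] += patch.nectar_rate
                pollen[idx] += patch.pollen_rate
        return nectar, pollen


def step_resources(
    grid: LandscapeGrid,
    production_nectar: np.ndarray,
    production_pollen: np.ndarray,
    ingestion_nectar: np.ndarray,
    ingestion_pollen: np.ndarray,
    gamma_n: float,
    gamma_p: float,
    dt: float,
) -> None:
    """Advance per-node stocks by one forward-Euler step, in place.

    dF/dt = production - ingestion - gamma * F^2, clamped at zero afterwards.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    for arr, name in (
        (production_nectar, "production"),
        (production_pollen, "production"),
        (ingestion_nectar, "ingestion"),
        (ingestion_pollen, "ingestion"),
    ):
        if np.any(np.asarray(arr) < 0):
            raise ValueError(f"negative {name} rates are not allowed")
    if gamma_n < 0 or gamma_p < 0:
        raise ValueError("saturation coefficients must be nonnegative")

    grid.nectar += dt * (
        production_nectar - ingestion_nectar - gamma_n * grid.nectar**2
    )
    grid.pollen += dt * (
        production_pollen - ingestion_pollen - gamma_p * grid.pollen**2
    )
    np.maximum(grid.nectar, 0.0, out=grid.nectar)
    np.maximum(grid.pollen, 0.0, out=grid.pollen)


def reset_for_season(
    grid: LandscapeGrid,
    initial_nectar: np.ndarray | float = 0.0,
    initial_pollen: np.ndarray | float = 0.0,
) -> None:
    """Set stocks to the scenario's season-start values (default: empty)."""
    grid.nectar = np.broadcast_to(
        np.asarray(initial_nectar, dtype=float), (grid.n_nodes,)
    ).copy()
    grid.pollen = np.broadcast_to(
        np.asarray(initial_pollen, dtype=float), (grid.n_nodes,)
    ).copy()
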