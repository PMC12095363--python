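"""Named experiment scenarios and the wildflower-enhancement metrics.

Scenarios are small declarative configs (grid, background production, bloom
patches, shortage events) that realise into a landscape + schedule and run
through the colony dynamics.  The metrics quantify how a wildflower patch,
described by its relative composition (nectar-vs-pollen contrast) and its
relative quantity, changes the pollination services the colony delivers to a
crop during its bloom.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dynamics import SeasonEvent, Trajectory, run_multi_year
from .landscape import LandscapeGrid, Patch, ProductionSchedule, build_grid
from .params import DebParams

__all__ = [
    "PatchSpec",
    "ScenarioConfig",
    "EnhancementSpec",
    "relative_composition",
    "composition_shares",
    "mirrored_wildflower_rates",
    "relative_quantity_wf",
    "relative_background_flowers",
    "pollination_services",
    "relative_change_services",
    "build_scenario",
    "run_scenario",
    "SCENARIO_IDS",
]


@dataclass
class PatchSpec:
    """A bloom patch placed by lattice offset from the nest node."""

    offset: tuple[int, int]
    nectar_rate: float = 0.0
    pollen_rate: float = 0.0
    window: tuple[float, float] = (0.0, np.inf)
    label: str = ""


@dataclass
class ScenarioConfig:
    """Declarative description of one experiment."""

    name: str
    n_nodes_per_side: int = 5
    spacing: float = 1.2
    background_nectar: float = 0.0
    background_pollen: float = 0.0
    background_window: tuple[float, float] = (0.0, np.inf)
    patches: list[PatchSpec] = field(default_factory=list)
    events: list[SeasonEvent] = field(default_factory=list)
    years: int = 1
    initial_r: float = 1.0
    season_length: float | None = None
    dt: float | None = None
    crop_label: str = "crop"
    initial_stocks: str = "zero"
    description: str = ""

    def initial_stock_arrays(
        self, grid: LandscapeGrid, schedule: ProductionSchedule,
        gamma_n: float, gamma_p: float,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Season-start stocks: empty, or the unexploited equilibrium.

        The equilibrium option seeds each node at sqrt(F0 / gamma) of its
        day-0 production — the standing stock an unvisited landscape relaxes
        to — so early-spring foragers find flowers already in bloom.
        """
        if self.initial_stocks == "zero":
            zeros = np.zeros(grid.n_nodes)
            return zeros, zeros.copy()
        if self.initial_stocks == "equilibrium":
            prod_n, prod_p = schedule.production_at(0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                eq_n = np.sqrt(prod_n / gamma_n) if gamma_n > 0 else prod_n * 0
                eq_p = np.sqrt(prod_p / gamma_p) if gamma_p > 0 else prod_p * 0
            return np.nan_to_num(eq_n), np.nan_to_num(eq_p)
        raise ValueError(
            f"unknown initial_stocks policy {self.initial_stocks!r}"
        )

    def realize(
        self,
    ) -> tuple[LandscapeGrid, ProductionSchedule, tuple[SeasonEvent, ...],
               tuple[int, ...] | None]:
        """Build the grid, schedule, events, and crop node indices."""
        grid = build_grid(
            self.n_nodes_per_side,
            self.spacing,
            nest_at_center=self.n_nodes_per_side % 2 == 1,
        )
        patches = []
        crop_nodes: list[int] = []
        for spec in self.patches:
            node = grid.node_at_offset(*spec.offset)
            patches.append(
                Patch(
                    nodes=(node,),
                    nectar_rate=spec.nectar_rate,
                    pollen_rate=spec.pollen_rate,
                    window=spec.window,
                    label=spec.label,
                )
            )
            if spec.label == self.crop_label:
                crop_nodes.append(node)
        schedule = ProductionSchedule(
            n_nodes=grid.n_nodes,
            background_nectar=self.background_nectar,
            background_pollen=self.background_pollen,
            background_window=self.background_window,
            patches=patches,
        )
        crop = tuple(sorted(set(crop_nodes))) if crop_nodes else None
        return grid, schedule, tuple(self.events), crop

    def crop_bloom_window(self) -> tuple[float, float] | None:
        for spec in self.patches:
            if spec.label == self.crop_label:
                return spec.window
        return None


@dataclass
class EnhancementSpec:
    """How a wildflower enhancement is configured relative to the crop."""

    rc: float = 90.0
    rwf: float = 0.5
    location: str = "close"
    bloom_label: str = "during"

    def __post_init__(self) -> None:
        if not -100.0 <= self.rc <= 100.0:
            raise ValueError("relative composition must lie in [-100, 100]")
        if self.rwf < 0:
            raise ValueError("relative wildflower quantity must be >= 0")
        if self.location not in ("close", "far"):
            raise ValueError("location must be 'close' or 'far'")
        if self.bloom_label not in (
            "before", "during", "after", "before+after", "all"
        ):
            raise ValueError(f"unknown bloom label {self.bloom_label!r}")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def relative_composition(crop_nectar: float, crop_pollen: float) -> float:
    """Signed percent contrast 100 (F_N - F_P) / (F_N + F_P) of a producer."""
    if crop_nectar < 0 or crop_pollen < 0:
        raise ValueError("production rates must be nonnegative")
    total = crop_nectar + crop_pollen
    if total == 0:
        raise ValueError("relative composition undefined for zero production")
    # single-resource extremes are exactly +/-100 regardless of rounding
    if crop_nectar == 0:
        return -100.0
    if crop_pollen == 0:
        return 100.0
    if crop_nectar == crop_pollen:
        return 0.0
    return 100.0 * (crop_nectar - crop_pollen) / total


def composition_shares(rc: float) -> tuple[float, float]:
    """Nectar and pollen shares (summing to 1) realising a composition."""
    r = rc / 100.0
    return (1.0 + r) / 2.0, (1.0 - r) / 2.0


def mirrored_wildflower_rates(
    rc: float,
    rwf: float,
    ref_nectar: float = 500.0,
    ref_pollen: float = 100.0,
) -> dict[str, float]:
    """Crop and wildflower production rates for a mirrored enhancement.

    The crop realises composition ``rc`` and the wildflowers the mirror
    ``-rc``, each expressed as shares of the reference rates, with the
    wildflower side scaled by the relative quantity ``rwf``.  The mirror
    identity holds exactly on the shares: the crop's share contrast is ``rc``
    and the wildflowers' pollen-minus-nectar share contrast is also ``rc``.
    """
    if not -100.0 <= rc <= 100.0:
        raise ValueError("rc must lie in [-100, 100]")
    if rwf < 0:
        raise ValueError("rwf must be >= 0")
    share_n, share_p = composition_shares(rc)
    return {
        "crop_nectar": ref_nectar * share_n,
        "crop_pollen": ref_pollen * share_p,
        "wf_nectar": rwf * ref_nectar * share_p,
        "wf_pollen": rwf * ref_pollen * share_n,
        "crop_share_nectar": share_n,
        "crop_share_pollen": share_p,
        "wf_share_nectar": rwf * share_p,
        "wf_share_pollen": rwf * share_n,
    }


def relative_quantity_wf(crop_quantity: float, wf_quantity: float) -> float:
    """Wildflower quantity as a fraction of the crop quantity."""
    if crop_quantity <= 0:
        raise ValueError("crop quantity must be positive")
    return wf_quantity / crop_quantity


def relative_background_flowers(
    total_flowers: float, crop_plus_wf: float
) -> float:
    """Percent of floral resources outside the crop and wildflower patches."""
    if total_flowers <= 0:
        raise ValueError("total flowers must be positive")
    if crop_plus_wf > total_flowers:
        raise ValueError("crop + wildflowers cannot exceed the total")
    return 100.0 * (total_flowers - crop_plus_wf) / total_flowers


def pollination_services(
    trajectory: Trajectory, window: tuple[float, float]
) -> float:
    """Bee-days of forager presence on the crop during its bloom window.

    Integrates the recorded crop forager density (nectar plus pollen guilds)
    over sampled times inside the window.  The trajectory must have been run
    with crop nodes declared.  Extinct colonies contribute zero.
    """
    df = trajectory.to_dataframe()
    if "crop_foragers" not in df.columns:
        raise ValueError("trajectory was recorded without crop nodes")
    t0, t1 = window
    mask = (df["t"] >= t0) & (df["t"] <= t1)
    if mask.sum() < 2:
        return 0.0
    t = df.loc[mask, "t"].to_numpy()
    y = df.loc[mask, "crop_foragers"].to_numpy()
    return float(np.trapezoid(y, t))


def relative_change_services(
    ps_with_wf: float, ps_without_wf: float
) -> float | None:
    """Percent change in pollination services; None if the baseline is zero."""
    if ps_without_wf < 0 or ps_with_wf < 0:
        raise ValueError("pollination services must be nonnegative")
    if ps_without_wf == 0:
        return None
    return 100.0 * (ps_with_wf - ps_without_wf) / ps_without_wf


# ---------------------------------------------------------------------------
# Figure scenario builders
# ---------------------------------------------------------------------------

_CROP_BLOOM = (65.0, 85.0)
_WF_WINDOWS = {
    "before": [(45.0, 65.0)],
    "during": [(65.0, 85.0)],
    "after": [(85.0, 105.0)],
    "before+after": [(45.0, 65.0), (85.0, 105.0)],
    "all": [(0.0, 150.0)],
}

FIG8_LEVELS = {
    "low": (250.0, 10.0),
    "mid": (2500.0, 100.0),
    "high": (25000.0, 1000.0),
}


def _fig4_like(name: str, nectar: float, pollen: float) -> ScenarioConfig:
    return ScenarioConfig(
        name=name,
        background_nectar=0.1,
        background_pollen=0.1,
        patches=[
            PatchSpec((0, 0), nectar_rate=nectar, pollen_rate=pollen,
                      label="crop")
        ],
        description=(
            "Uniform 0.1/0.1 background with a central patch producing "
            f"{nectar} ml/day nectar and {pollen} g/day pollen all season."
        ),
    )


def _fig5(name: str, shortage: str) -> ScenarioConfig:
    """Central rich patch for 25 days, then a total shortage of one resource."""
    if shortage == "nectar":
        bg_n_window, bg_p_window = (0.0, 25.0), (0.0, np.inf)
        patch_n_window, patch_p_window = (0.0, 25.0), (0.0, np.inf)
        event = SeasonEvent(25.0, "clear_nectar")
    else:
        bg_n_window, bg_p_window = (0.0, np.inf), (0.0, 25.0)
        patch_n_window, patch_p_window = (0.0, np.inf), (0.0, 25.0)
        event = SeasonEvent(25.0, "clear_pollen")
    # Background nectar and pollen can be cut independently, so express the
    # background as two all-node single-resource patches.
    return ScenarioConfig(
        name=name,
        background_nectar=0.0,
        background_pollen=0.0,
        patches=[
            PatchSpec((0, 0), nectar_rate=500.0, window=patch_n_window,
                      label="crop"),
            PatchSpec((0, 0), pollen_rate=100.0, window=patch_p_window,
                      label="crop"),
            *[
                PatchSpec(off, nectar_rate=0.1, window=bg_n_window,
                          label="background")
                for off in _all_offsets(5)
            ],
            *[
                PatchSpec(off, pollen_rate=0.1, window=bg_p_window,
                          label="background")
                for off in _all_offsets(5)
            ],
        ],
        events=[event],
        description=(
            f"Total {shortage} shortage at day 25: production zeroed and "
            "remaining stocks removed."
        ),
    )


def _all_offsets(n_per_side: int) -> list[tuple[int, int]]:
    half = n_per_side // 2
    return [
        (dx, dy)
        for dy in range(-half, half + 1)
        for dx in range(-half, half + 1)
    ]


def _fig6(name: str, nectar_bg: float, pollen_bg: float) -> ScenarioConfig:
    return ScenarioConfig(
        name=name,
        background_nectar=nectar_bg,
        background_pollen=pollen_bg,
        patches=[
            PatchSpec((0, 0), nectar_rate=500.0, pollen_rate=100.0,
                      window=_CROP_BLOOM, label="crop")
        ],
        description=(
            "Mass-flowering crop blooming days 65-85 over a uniform "
            f"{nectar_bg} ml/day + {pollen_bg} g/day background."
        ),
    )


def _fig7(nectar_offset=(1, 0), pollen_offset=(-1, 0)) -> ScenarioConfig:
    return ScenarioConfig(
        name="fig7",
        n_nodes_per_side=10,
        spacing=0.67,
        background_nectar=0.025,
        background_pollen=0.025,
        patches=[
            PatchSpec(tuple(nectar_offset), nectar_rate=500.0, label="nectar"),
            PatchSpec(tuple(pollen_offset), pollen_rate=100.0, label="pollen"),
        ],
        description=(
            "10x10 grid at 0.67 km: separate nectar and pollen patches at "
            "configurable offsets from a near-centre nest."
        ),
    )


def _fig8(level: str = "low", years: int = 10) -> ScenarioConfig:
    try:
        nectar, pollen = FIG8_LEVELS[level]
    except KeyError:
        raise ValueError(
            f"unknown fig8 level {level!r}; choose from {sorted(FIG8_LEVELS)}"
        ) from None
    return ScenarioConfig(
        name=f"fig8-{level}",
        background_nectar=nectar,
        background_pollen=pollen,
        years=years,
        description=(
            f"Uniform constant production ({nectar} ml/day, {pollen} g/day "
            f"per node) over {years} years."
        ),
    )


def _enhancement_patches(
    spec: EnhancementSpec,
    ref_nectar: float,
    ref_pollen: float,
    crop_offset: tuple[int, int],
    wf_offset: tuple[int, int],
    include_wildflowers: bool,
    season_length: float,
) -> list[PatchSpec]:
    rates = mirrored_wildflower_rates(spec.rc, spec.rwf, ref_nectar, ref_pollen)
    patches = [
        PatchSpec(
            crop_offset,
            nectar_rate=rates["crop_nectar"],
            pollen_rate=rates["crop_pollen"],
            window=_CROP_BLOOM,
            label="crop",
        )
    ]
    if include_wildflowers and spec.rwf > 0:
        windows = _WF_WINDOWS[spec.bloom_label]
        if spec.bloom_label == "all":
            windows = [(0.0, season_length)]
        for window in windows:
            patches.append(
                PatchSpec(
                    wf_offset,
                    nectar_rate=rates["wf_nectar"],
                    pollen_rate=rates["wf_pollen"],
                    window=window,
                    label="wildflower",
                )
            )
    return patches


def _fig9_10(
    name: str,
    spec: EnhancementSpec,
    background: float,
    include_wildflowers: bool,
) -> ScenarioConfig:
    wf_offset = (-1, 0) if spec.location == "close" else (-2, 0)
    return ScenarioConfig(
        name=name,
        background_nectar=background,
        background_pollen=background,
        patches=_enhancement_patches(
            spec, 500.0, 100.0, (1, 0), wf_offset, include_wildflowers, 150.0
        ),
        initial_stocks="equilibrium",
        description=(
            "Crop one node right of centre blooming days 65-85, mirrored "
            "wildflower patch on the left."
        ),
    )


def _fig11(
    spec: EnhancementSpec, include_wildflowers: bool, years: int
) -> ScenarioConfig:
    wf_offset = (0, 0) if spec.location == "close" else (-1, -1)
    return ScenarioConfig(
        name="fig11",
        n_nodes_per_side=11,
        spacing=0.6,
        background_nectar=25.0,
        background_pollen=10.0,
        years=years,
        patches=_enhancement_patches(
            spec, 5000.0, 1000.0, (1, 0), wf_offset, include_wildflowers, 150.0
        ),
        initial_stocks="equilibrium",
        description=(
            "Multi-year enhancement run: crop 0.6 km from the nest, "
            "wildflowers at the nest (close) or 0.85 km opposite (far)."
        ),
    )


SCENARIO_IDS = (
    "fig3", "fig4a", "fig4b", "fig4c", "fig5a", "fig5b",
    "fig6a", "fig6b", "fig6c", "fig7", "fig8", "fig9", "fig10", "fig11",
)


def build_scenario(figure_id: str, **overrides) -> ScenarioConfig:
    """Build a named experiment configuration.

    Supported overrides depend on the figure: ``level``/``years`` for fig8;
    ``rc``, ``rwf``, ``location``, ``bloom_label``, ``background``,
    ``include_wildflowers``, ``years`` for fig9-11; ``nectar_offset`` /
    ``pollen_offset`` for fig7; ``years`` anywhere.
    """
    years = overrides.pop("years", None)

    if figure_id in ("fig3", "fig4a"):
        config = _fig4_like(figure_id, 500.0, 100.0)
    elif figure_id == "fig4b":
        config = _fig4_like(figure_id, 50.0, 100.0)
    elif figure_id == "fig4c":
        config = _fig4_like(figure_id, 500.0, 10.0)
    elif figure_id == "fig5a":
        config = _fig5(figure_id, "nectar")
    elif figure_id == "fig5b":
        config = _fig5(figure_id, "pollen")
    elif figure_id == "fig6a":
        config = _fig6(figure_id, 10.0, 0.4)
    elif figure_id == "fig6b":
        config = _fig6(figure_id, 20.0, 0.8)
    elif figure_id == "fig6c":
        config = _fig6(figure_id, 50.0, 2.0)
    elif figure_id == "fig7":
        config = _fig7(
            overrides.pop("nectar_offset", (1, 0)),
            overrides.pop("pollen_offset", (-1, 0)),
        )
    elif figure_id == "fig8":
        config = _fig8(overrides.pop("level", "low"), years or 10)
        years = None
    elif figure_id in ("fig9", "fig10"):
        spec = EnhancementSpec(
            rc=overrides.pop("rc", 90.0),
            rwf=overrides.pop("rwf", 0.5),
            location=overrides.pop("location", "close"),
            bloom_label=overrides.pop("bloom_label", "during"),
        )
        background = overrides.pop(
            "background", 0.1 if figure_id == "fig9" else 0.1
        )
        config = _fig9_10(
            figure_id, spec, background,
            overrides.pop("include_wildflowers", True),
        )
    elif figure_id == "fig11":
        spec = EnhancementSpec(
            rc=overrides.pop("rc", 90.0),
            rwf=overrides.pop("rwf", 0.5),
            location=overrides.pop("location", "close"),
            bloom_label=overrides.pop("bloom_label", "before+after"),
        )
        config = _fig11(
            spec,
            overrides.pop("include_wildflowers", True),
            years or 5,
        )
        years = None
    else:
        raise ValueError(
            f"unknown figure id {figure_id!r}; valid ids: "
            + ", ".join(SCENARIO_IDS)
        )

    if years is not None:
        config = replace(config, years=years)
    if overrides:
        raise TypeError(
            f"unsupported overrides for {figure_id}: {sorted(overrides)}"
        )
    return config


def run_scenario(
    config: ScenarioConfig,
    params: DebParams | None = None,
    record_stride: int = 1,
    record_nodes: bool = False,
):
    """Realize and run a scenario; returns (trajectories, annual summary)."""
    if params is None:
        params = DebParams()
    if config.season_length is not None:
        params = params.replace(season_length=config.season_length)
    if config.dt is not None:
        params = params.replace(dt=config.dt)
    grid, schedule, events, crop_nodes = config.realize()
    init_n, init_p = config.initial_stock_arrays(
        grid, schedule, params.gamma_n, params.gamma_p
    )
    return run_multi_year(
        grid,
        schedule,
        params,
        years=config.years,
        initial_r=config.initial_r,
        record_stride=record_stride,
        events=events,
        crop_nodes=crop_nodes,
        initial_nectar=init_n,
        initial_pollen=init_p,
        record_nodes=record_nodes,
    )
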