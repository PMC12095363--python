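"""Colony and landscape parameters with their default values.

The defaults describe a generic bumble bee (*Bombus*) colony foraging on a
gridded agricultural landscape.  Nectar is tracked in ml (energy currency),
pollen in g (protein currency), and colony structure ``V`` in bee-equivalents:
``alpha * V`` is the number of foragers and ``beta * V`` the brood count.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


@dataclass
class DebParams:
    """Parameter set for the colony energy budget and forager distribution.

    Attributes
    ----------
    c_x_n, c_x_p :
        Per-forager collection rates: nectar in ml/(bee day), pollen in
        g/(bee day).
    c_p_n, c_p_p :
        Fraction of ingested resource lost as faeces (dimensionless, in [0,1]).
    c_a_n, c_a_p :
        Fraction of non-faeces intake assimilated into reserves (in [0,1]).
    c_m1_n, c_m1_p :
        Per-forager somatic maintenance rates (ml/(bee day), g/(bee day)).
    c_m2_n, c_m2_p :
        Per-brood somatic maintenance rates.
    c_h :
        Nest-heating cost per unit of peak colony size, ml/(bee day).
    c_c :
        Travel cost per forager per km, ml/(bee day km).
    theta :
        Nectar evaporation rate, 1/day.
    kappa :
        Maximum conversion rate of reserves into structure, g/day.
    eps_n, eps_p :
        Half-saturation reserve levels for growth (ml, g); also set the
        forager-allocation correction near empty reserves, and ``eps_n``
        additionally scales the starvation death term.
    delta_0 :
        Baseline per-capita death rate of structure, 1/day.
    delta_n :
        Extra death rate when nectar reserves are empty, 1/day.
    e_g :
        Pollen required per unit of new structure, g/bee.
    lam :
        Nectar-to-pollen forager bias under ample reserves (dimensionless).
    alpha, beta :
        Foragers and brood per unit structural energy.
    temperature :
        MaxEnt "temperature" T (inverse foraging efficiency); T -> 0 gives the
        ideal free distribution, T -> infinity a uniform one.
    gamma_n, gamma_p :
        Landscape stock saturation coefficients (1/ml, 1/g).
    c_r :
        Queen production scale per colony per reproductive impulse.
    delta_r :
        Overwinter queen mortality per impulse (dimensionless fraction).
    eps_v :
        Structural energy per surviving queen at season start
        (bee-equivalents).  The default of one bee-equivalent per queen is
        required for a founding queen to outpace the starvation death term
        while the first reserves accumulate; see the methods note.
    eps_r :
        Per-colony size threshold for reproduction (bee-equivalents).
    psi :
        Slope of the arctangent reproduction response.
    d_max :
        Pollen-forager distance scale in km; ``None`` means "use the largest
        nest-to-node distance of the grid".
    nectar_range_cutoff :
        Optional hard cutoff radius (km) beyond which nectar foragers are
        excluded.  ``None`` (default) disables it; with default parameters the
        ~3 km range is already emergent from the travel-cost term.
    ingestion_form :
        ``"smooth"`` for the saturating Michaelis-Menten-like form, or
        ``"hardmin"`` for the piecewise min of the two limiting regimes.
    reproduction_normalized :
        If True, scale the arctangent reproduction flux by 2/pi so its
        saturation value is exactly ``c_r * R``.
    season_length :
        Length of the growth phase L, days.
    dt :
        Forward-Euler time step, days.
    """

    c_x_n: float = 1.2
    c_x_p: float = 0.8
    c_p_n: float = 0.0
    c_p_p: float = 0.0
    c_a_n: float = 1.0
    c_a_p: float = 1.0
    c_m1_n: float = 0.025
    c_m1_p: float = 0.04
    c_m2_n: float = 0.0
    c_m2_p: float = 0.01
    c_h: float = 0.03
    c_c: float = 0.4
    theta: float = 0.01
    kappa: float = 1.0
    eps_n: float = 0.1
    eps_p: float = 0.5
    delta_0: float = 0.05
    delta_n: float = 1.0
    e_g: float = 1.0 / 8.5
    lam: float = 5.0
    alpha: float = 1.0
    beta: float = 4.0
    temperature: float = 0.1
    gamma_n: float = 0.001
    gamma_p: float = 0.001
    c_r: float = 5.0
    delta_r: float = 0.12
    eps_v: float = 1.0
    eps_r: float = 100.0
    psi: float = 0.2
    d_max: float | None = None
    nectar_range_cutoff: float | None = None
    ingestion_form: str = "smooth"
    reproduction_normalized: bool = False
    season_length: float = 150.0
    dt: float = 0.1

    def __post_init__(self) -> None:
        for name in ("c_p_n", "c_p_p", "c_a_n", "c_a_p"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.temperature <= 0:
            raise ValueError("temperature (T) must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.ingestion_form not in ("smooth", "hardmin"):
            raise ValueError(
                f"ingestion_form must be 'smooth' or 'hardmin', got "
                f"{self.ingestion_form!r}"
            )
        nonneg = [
            f.name
            for f in dataclasses.fields(self)
            if f.name not in ("d_max", "nectar_range_cutoff",
                              "ingestion_form", "reproduction_normalized")
        ]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def replace(self, **overrides) -> "DebParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **overrides)


#: Aliases accepted in configuration files, keyed by the symbols conventional
#: in the energy-budget literature.
PARAM_ALIASES: dict[str, str] = {
    "C_X_N": "c_x_n",
    "C_X_P": "c_x_p",
    "C_P_N": "c_p_n",
    "C_P_P": "c_p_p",
    "C_A_N": "c_a_n",
    "C_A_P": "c_a_p",
    "C_M1_N": "c_m1_n",
    "C_M1_P": "c_m1_p",
    "C_M2_N": "c_m2_n",
    "C_M2_P": "c_m2_p",
    "C_H": "c_h",
    "C_C": "c_c",
    "theta": "theta",
    "kappa": "kappa",
    "eps_N": "eps_n",
    "eps_P": "eps_p",
    "delta_0": "delta_0",
    "delta_N": "delta_n",
    "E_G": "e_g",
    "lambda": "lam",
    "alpha": "alpha",
    "beta": "beta",
    "T": "temperature",
    "gamma_N": "gamma_n",
    "gamma_P": "gamma_p",
    "C_R": "c_r",
    "delta_R": "delta_r",
    "eps_V": "eps_v",
    "eps_R": "eps_r",
    "psi": "psi",
    "d_max": "d_max",
    "L": "season_length",
    "dt": "dt",
}


def resolve_param_name(name: str) -> str:
    """Map a configuration key (symbol alias or field name) to a field name.

    Raises ``KeyError`` with the offending name if it is unknown.
    """
    if name in PARAM_ALIASES:
        return PARAM_ALIASES[name]
    field_names = {f.name for f in dataclasses.fields(DebParams)}
    if name in field_names:
        return name
    raise KeyError(name)
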