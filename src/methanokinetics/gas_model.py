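"""Stoichiometric and ideal-gas bookkeeping for CO2-based biological methanation.

Hydrogenotrophic methanogens convert a pressurized H2/CO2 headspace to
methane via

    4 H2 + CO2 -> CH4 + 2 H2O

In a sealed vessel at cultivation temperature the product water condenses,
so each mole of CH4 formed removes a net 4 moles of gas from the headspace
(5 moles consumed, 1 mole produced).  The headspace pressure trace is
therefore a direct, online readout of the reaction extent, and for the
standard 4:1 H2:CO2 mixture complete conversion leaves exactly one fifth of
the initial pressure.

All pressures are in bar, volumes in litres, temperatures in kelvin and
amounts in mol.  Pressures follow the gauge convention used on lab pressure
transducers by default (``paper_gauge``: the recorded relative value is used
as-is in the gas law); ``absolute_corrected`` adds one standard atmosphere
for physically exact work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "R_GAS",
    "BAR_PER_PA",
    "ATM_BAR",
    "GasComposition",
    "VesselSpec",
    "ConversionState",
    "moles_from_pressure",
    "pressure_from_moles",
    "extent_from_pressure_drop",
    "max_extent_per_mole",
    "turnover_fraction",
    "residual_pressure_full_conversion",
    "dissolved_h2_ratio",
]

#: Universal gas constant, J mol^-1 K^-1.
R_GAS = 8.314
#: 1 bar in Pa is 1e5; its inverse converts Pa to bar.
BAR_PER_PA = 1e-5
#: One standard atmosphere in bar, added under the absolute_corrected convention.
ATM_BAR = 1.013

_COMPOSITION_TOL = 1e-9


@dataclass(frozen=True)
class GasComposition:
    """Headspace mole fractions.

    The default is the 4:1 H2:CO2 substrate mixture (80 vol-% H2 in CO2)
    used throughout closed-batch methanogen cultivation.
    """

    x_h2: float = 0.8
    x_co2: float = 0.2
    x_ch4: float = 0.0
    x_other: float = 0.0

    def __post_init__(self) -> None:
        fractions = (self.x_h2, self.x_co2, self.x_ch4, self.x_other)
        for name, x in zip(("x_h2", "x_co2", "x_ch4", "x_other"), fractions):
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"mole fraction {name}={x} outside [0, 1]")
        total = sum(fractions)
        if abs(total - 1.0) > _COMPOSITION_TOL:
            raise ValueError(f"mole fractions sum to {total}, expected 1 within {_COMPOSITION_TOL}")


@dataclass(frozen=True)
class VesselSpec:
    """Geometry and temperatures of a sealed cultivation vessel.

    Parameters
    ----------
    v_total, v_liquid:
        Total and liquid-phase volumes in litres; the headspace is their
        difference.
    t_incubation:
        Cultivation temperature in kelvin, used for online pressure traces.
    t_measurement:
        Temperature at which point pressure measurements are taken (bottles
        are equilibrated to room temperature before offline readings).
    pressure_convention:
        ``"paper_gauge"`` (default) feeds recorded gauge values straight
        into the gas law; ``"absolute_corrected"`` adds 1.013 bar first.
    """

    v_total: float
    v_liquid: float
    t_incubation: float
    t_measurement: float = 298.15
    pressure_convention: str = "paper_gauge"

    def __post_init__(self) -> None:
        if not 0.0 < self.v_liquid < self.v_total:
            raise ValueError(
                f"need 0 < v_liquid < v_total, got v_liquid={self.v_liquid}, v_total={self.v_total}"
            )
        for name in ("t_incubation", "t_measurement"):
            t = getattr(self, name)
            if t <= 273.0:
                raise ValueError(f"{name}={t} K must exceed 273 K")
        if self.pressure_convention not in ("paper_gauge", "absolute_corrected"):
            raise ValueError(
                f"unknown pressure_convention {self.pressure_convention!r}; "
                "expected 'paper_gauge' or 'absolute_corrected'"
            )

    @property
    def v_gas(self) -> float:
        """Headspace volume in litres."""
        return self.v_total - self.v_liquid


@dataclass
class ConversionState:
    """Snapshot of one conversion run: pressures, extent and turnover."""

    p0: float
    p: float
    xi: float = 0.0
    turnover: float = 0.0
    composition: GasComposition = field(default_factory=GasComposition)


def _effective_pressure(p: float, vessel: VesselSpec) -> float:
    if vessel.pressure_convention == "absolute_corrected":
        p = p + ATM_BAR
    if p < 0:
        raise ValueError(
            f"pressure {p} bar is negative after applying the "
            f"{vessel.pressure_convention!r} convention"
        )
    return p


def moles_from_pressure(p: float, vessel: VesselSpec, temperature: float) -> float:
    """Total gas amount n = P V_gas / (R T) in the vessel headspace.

    ``p`` is interpreted per ``vessel.pressure_convention``.
    """
    if temperature <= 0:
        raise ValueError(f"temperature {temperature} K must be positive")
    p_eff = _effective_pressure(p, vessel)
    return (p_eff / BAR_PER_PA) * (vessel.v_gas * 1e-3) / (R_GAS * temperature)


def pressure_from_moles(n: float, vessel: VesselSpec, temperature: float) -> float:
    """Inverse of :func:`moles_from_pressure` (same convention handling)."""
    if temperature <= 0:
        raise ValueError(f"temperature {temperature} K must be positive")
    if n < 0:
        raise ValueError(f"amount {n} mol must be non-negative")
    p = n * R_GAS * temperature / (vessel.v_gas * 1e-3) * BAR_PER_PA
    if vessel.pressure_convention == "absolute_corrected":
        p = p - ATM_BAR
    return p


def extent_from_pressure_drop(
    p0: float,
    p: float,
    vessel: VesselSpec,
    temperature: float,
    noise_tol: float = 0.05,
) -> float:
    """Moles of CH4 formed, from the headspace pressure drop p0 -> p.

    Five moles of gas become one per mole of CH4 (water condenses), so the
    extent is one quarter of the lost gas amount.  A pressure *rise* beyond
    ``noise_tol`` bar is rejected: it signals a repressurization event that
    belongs to RCB segmentation, not to a single conversion segment.
    """
    if p > p0 + noise_tol:
        raise ValueError(
            f"pressure increase inside a conversion segment (p={p} > p0={p0} bar); "
            "use RCB segmentation for multi-cycle traces"
        )
    n0 = moles_from_pressure(p0, vessel, temperature)
    n = moles_from_pressure(min(p, p0), vessel, temperature)
    return (n0 - n) / 4.0


def max_extent_per_mole(composition: GasComposition) -> float:
    """Maximum CH4 extent per mole of initial headspace gas.

    Limiting-reagent logic: each mole of CH4 needs 4 mol H2 and 1 mol CO2,
    so the cap is min(x_H2/4, x_CO2).  Exactly 0.2 for the 4:1 mixture.
    """
    return min(composition.x_h2 / 4.0, composition.x_co2)


def turnover_fraction(
    p0: float, p: float, composition: GasComposition | None = None
) -> float:
    """Fraction of the supplied substrate converted, from pressures alone.

    Since the gas amount falls by 4 mol per mol CH4 at fixed V and T, the
    relative pressure drop maps linearly onto the extent:
    X = (p0 - p) / (4 * xi_max_per_mole * p0), clipped to [0, 1].
    For the 4:1 mixture this is (p0 - p) / (0.8 p0): full conversion at
    one fifth of the initial pressure.
    """
    if composition is None:
        composition = GasComposition()
    if p0 <= 0:
        raise ValueError(f"turnover is undefined for initial pressure p0={p0} bar")
    per_mole = max_extent_per_mole(composition)
    if per_mole <= 0:
        raise ValueError("composition contains no convertible substrate")
    x = (p0 - p) / (4.0 * per_mole * p0)
    return min(max(x, 0.0), 1.0)


def residual_pressure_full_conversion(
    p0: float, composition: GasComposition | None = None
) -> float:
    """Headspace pressure left after complete conversion of the substrate.

    For the stoichiometric 4:1 H2:CO2 mixture this is p0/5 (2 bar from
    10 bar, 10 bar from 50 bar); other mixtures follow the limiting
    reagent.
    """
    if composition is None:
        composition = GasComposition()
    if p0 < 0:
        raise ValueError(f"initial pressure p0={p0} bar must be non-negative")
    return p0 * (1.0 - 4.0 * max_extent_per_mole(composition))


def dissolved_h2_ratio(p_a: float, p_b: float) -> float:
    """Fold change of equilibrium dissolved H2 between two total pressures.

    By Henry's law the dissolved concentration is proportional to the H2
    partial pressure, so at identical composition and temperature the fold
    change is simply p_a / p_b — e.g. 5x for 10 vs 2 bar, 25x for 50 vs 2.
    """
    if p_b <= 0:
        raise ValueError(f"reference pressure p_b={p_b} bar must be positive")
    return p_a / p_b
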