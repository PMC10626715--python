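"""Reactor geometry arithmetic for transit-time-controlled colon compartments.

A two-stage semi-continuous colon simulator imposes a chosen colonic transit
time by sizing each compartment so that its working volume equals the influent
dosage rate multiplied by the desired residence time.  With a fixed dose of
200 mL every 8 h (25 mL/h), a proximal compartment held at 8 h transit has a
200 mL working volume and a dilution rate of 1/8 h^-1; scaling the volume
scales the transit linearly.

Three arms are supported: *short* (proximal 8 h + distal 13 h = 21 h total),
*medium* (16 h + 26 h) and *long* (24 h + 39 h = 63 h).  To prevent nutrient
concentration from confounding transit time, the influent is concentrated per
arm so that every configuration receives the same volumetric nutrient loading
(default 16.38 g per litre of reactor per day).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "CompartmentSpec",
    "ReactorConfig",
    "DEFAULT_TRANSITS_H",
    "DEFAULT_LOADING_G_PER_L_DAY",
    "daily_flow",
    "compartment_volume",
    "total_transit",
    "stabilisation_days",
    "influent_concentration_for_loading",
]

#: Proximal/distal residence times (hours) per arm.  The medium arm uses the
#: compartment-level values 16 + 26 h; the alternative 32 h total sometimes
#: quoted for this design is inconsistent with the compartment split and with
#: the 11-day stabilisation rule, and is not used.
DEFAULT_TRANSITS_H: dict[str, tuple[float, float]] = {
    "short": (8.0, 13.0),
    "medium": (16.0, 26.0),
    "long": (24.0, 39.0),
}

DEFAULT_LOADING_G_PER_L_DAY = 16.38
DEFAULT_CYCLE_VOLUME_ML = 200.0
DEFAULT_CYCLE_PERIOD_H = 8.0


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0) or not math.isfinite(value):
            raise ValueError(f"{name} must be positive and finite, got {value!r}")


def daily_flow(cycle_volume_mL: float, cycle_period_h: float) -> float:
    """Daily throughput (mL/day) of a semi-continuous feed schedule.

    200 mL dosed every 8 h gives the canonical 600 mL/day.
    """
    _require_positive(cycle_volume_mL=cycle_volume_mL, cycle_period_h=cycle_period_h)
    return cycle_volume_mL * 24.0 / cycle_period_h


def compartment_volume(dosage_rate_mL_per_h: float, transit_h: float) -> float:
    """Working volume (mL) imposing ``transit_h`` at a given dosage rate."""
    _require_positive(
        dosage_rate_mL_per_h=dosage_rate_mL_per_h, transit_h=transit_h
    )
    return dosage_rate_mL_per_h * transit_h


def stabilisation_days(
    pc_transit_h: float,
    dc_transit_h: float,
    n_distal_transits: float = 9,
    n_total_transits: float = 6,
) -> int:
    """Days until the community is considered stabilised.

    Stabilisation requires at least ``n_distal_transits`` distal-compartment
    residence times and ``n_total_transits`` whole-colon residence times to
    have elapsed; the day count is the ceiling of the larger requirement in
    hours divided by 24.  For the three default arms this yields 6, 11 and
    16 days.
    """
    _require_positive(
        pc_transit_h=pc_transit_h,
        dc_transit_h=dc_transit_h,
        n_distal_transits=n_distal_transits,
        n_total_transits=n_total_transits,
    )
    hours = max(
        n_distal_transits * dc_transit_h,
        n_total_transits * (pc_transit_h + dc_transit_h),
    )
    return math.ceil(hours / 24.0)


def influent_concentration_for_loading(
    target_loading_g_per_L_day: float, volume_mL: float, daily_flow_mL: float
) -> float:
    """Influent concentration (g/L) delivering a target volumetric loading.

    The loading is expressed per litre of reactor per day, so
    ``C_in = loading * V / Q``; recomputing ``C_in * Q / V`` returns the
    target for every arm, which is how equal nutrient loading is enforced
    across transit configurations.
    """
    _require_positive(
        target_loading_g_per_L_day=target_loading_g_per_L_day,
        volume_mL=volume_mL,
        daily_flow_mL=daily_flow_mL,
    )
    return target_loading_g_per_L_day * volume_mL / daily_flow_mL


@dataclass(frozen=True)
class CompartmentSpec:
    """One colon compartment: residence time, volume and dilution rate."""

    name: str  # "proximal" or "distal"
    transit_h: float
    volume_mL: float
    dilution_per_h: float

    def __post_init__(self) -> None:
        if self.name not in ("proximal", "distal"):
            raise ValueError(f"compartment name must be proximal/distal, got {self.name!r}")
        _require_positive(transit_h=self.transit_h, volume_mL=self.volume_mL)

    @classmethod
    def from_transit(
        cls, name: str, transit_h: float, dosage_rate_mL_per_h: float
    ) -> "CompartmentSpec":
        volume = compartment_volume(dosage_rate_mL_per_h, transit_h)
        return cls(
            name=name,
            transit_h=transit_h,
            volume_mL=volume,
            dilution_per_h=1.0 / transit_h,
        )


@dataclass(frozen=True)
class ReactorConfig:
    """Full two-compartment arm configuration.

    ``influent_carb_g_per_L`` is derived so that the volumetric nutrient
    loading (g per L of total colon volume per day) is identical across arms.
    """

    arm: str
    cycle_volume_mL: float
    cycle_period_h: float
    compartments: tuple[CompartmentSpec, CompartmentSpec]
    target_loading_g_per_L_day: float
    influent_carb_g_per_L: float = field(default=0.0)

    def __post_init__(self) -> None:
        names = [c.name for c in self.compartments]
        if names != ["proximal", "distal"]:
            raise ValueError("compartments must be (proximal, distal) in order")
        if self.cycle_volume_mL > min(c.volume_mL for c in self.compartments):
            raise ValueError("cycle volume exceeds a compartment working volume")

    @property
    def proximal(self) -> CompartmentSpec:
        return self.compartments[0]

    @property
    def distal(self) -> CompartmentSpec:
        return self.compartments[1]

    @property
    def dosage_rate_mL_per_h(self) -> float:
        return self.cycle_volume_mL / self.cycle_period_h

    @property
    def daily_flow_mL(self) -> float:
        return daily_flow(self.cycle_volume_mL, self.cycle_period_h)

    @property
    def total_volume_mL(self) -> float:
        return sum(c.volume_mL for c in self.compartments)

    @property
    def stabilisation_days(self) -> int:
        return stabilisation_days(self.proximal.transit_h, self.distal.transit_h)

    @classmethod
    def for_arm(
        cls,
        arm: str,
        cycle_volume_mL: float = DEFAULT_CYCLE_VOLUME_ML,
        cycle_period_h: float = DEFAULT_CYCLE_PERIOD_H,
        target_loading_g_per_L_day: float = DEFAULT_LOADING_G_PER_L_DAY,
        transits_h: tuple[float, float] | None = None,
    ) -> "ReactorConfig":
        """Build the standard configuration for one arm (short/medium/long)."""
        if transits_h is None:
            try:
                transits_h = DEFAULT_TRANSITS_H[arm]
            except KeyError:
                raise ValueError(
                    f"unknown arm {arm!r}; expected one of {sorted(DEFAULT_TRANSITS_H)}"
                ) from None
        rate = cycle_volume_mL / cycle_period_h
        pc = CompartmentSpec.from_transit("proximal", transits_h[0], rate)
        dc = CompartmentSpec.from_transit("distal", transits_h[1], rate)
        q = daily_flow(cycle_volume_mL, cycle_period_h)
        c_in = influent_concentration_for_loading(
            target_loading_g_per_L_day, pc.volume_mL + dc.volume_mL, q
        )
        return cls(
            arm=arm,
            cycle_volume_mL=cycle_volume_mL,
            cycle_period_h=cycle_period_h,
            compartments=(pc, dc),
            target_loading_g_per_L_day=target_loading_g_per_L_day,
            influent_carb_g_per_L=c_in,
        )


def total_transit(config: ReactorConfig) -> float:
    """Total colonic transit time (h): sum of compartment residence times."""
    return sum(c.transit_h for c in config.compartments)
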