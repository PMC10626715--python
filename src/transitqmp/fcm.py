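"""Flow-cytometric cell enumeration from two-channel stained event tables.

Events carry green (530/30 nm, nucleic-acid stain) and red (>670 nm,
membrane-integrity stain) log10 fluorescence.  Rectangular threshold gates —
a noise floor on the green channel derived from filtered negative controls
and a damaged-cell threshold on the red channel derived from heat-killed
controls — partition events into noise, intact and damaged.  Cell counts
divided by the acquisition volume and multiplied by the pre-stain dilution
give concentrations in cells/mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GateSet",
    "build_gates",
    "gate_counts",
    "cell_concentration",
    "intact_fraction",
    "load_event_table",
    "merge_duplicates",
]


@dataclass(frozen=True)
class GateSet:
    """Log10 thresholds: events below ``noise_green_threshold`` are noise;
    remaining events at or above ``damaged_red_threshold`` are damaged; the
    rest are intact.  The partition is exhaustive and disjoint."""

    noise_green_threshold: float
    damaged_red_threshold: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.noise_green_threshold)
                and math.isfinite(self.damaged_red_threshold)):
            raise ValueError("gate thresholds must be finite")


def _as_log10(events: pd.DataFrame, assume_log10: bool = True) -> pd.DataFrame:
    if not {"green", "red"}.issubset(events.columns):
        raise ValueError("event table needs 'green' and 'red' columns")
    ev = events[["green", "red"]].astype(float)
    if not assume_log10:
        ev = np.log10(ev.clip(lower=1.0))
    if not np.isfinite(ev.to_numpy()).all():
        raise ValueError("event table contains non-finite fluorescence values")
    return ev


def build_gates(
    negative_control_events: pd.DataFrame,
    heat_killed_events: pd.DataFrame,
    q_noise: float = 0.999,
    q_damaged: float = 0.01,
) -> GateSet:
    """Derive thresholds from control acquisitions.

    The noise gate is the ``q_noise`` quantile of negative-control green
    fluorescence (so <=0.1% of pure-noise events pass by default); the
    damaged gate is the ``q_damaged`` quantile of red fluorescence over the
    heat-killed events that pass the noise gate (so >=99% of gated
    heat-killed cells classify damaged, by construction).
    """
    for name, tbl in (("negative control", negative_control_events),
                      ("heat-killed", heat_killed_events)):
        if tbl is None or len(tbl) == 0:
            raise ValueError(f"{name} event table is empty")
    neg = _as_log10(negative_control_events)
    hk = _as_log10(heat_killed_events)
    # order-statistic quantiles so the classification guarantees are exact
    noise_thr = float(neg["green"].quantile(q_noise, interpolation="higher"))
    hk_gated = hk[hk["green"] >= noise_thr]
    if hk_gated.empty:
        raise ValueError("no heat-killed events pass the noise gate")
    return GateSet(
        noise_green_threshold=noise_thr,
        damaged_red_threshold=float(
            hk_gated["red"].quantile(q_damaged, interpolation="lower")
        ),
    )


def gate_counts(events: pd.DataFrame, gates: GateSet) -> dict[str, int]:
    """Classify events; returns total/intact/damaged/noise counts."""
    if len(events) == 0:
        return {"total": 0, "intact": 0, "damaged": 0, "noise": 0}
    ev = _as_log10(events)
    is_noise = ev["green"].to_numpy() < gates.noise_green_threshold
    is_damaged = ~is_noise & (ev["red"].to_numpy() >= gates.damaged_red_threshold)
    n_noise = int(is_noise.sum())
    n_damaged = int(is_damaged.sum())
    n_intact = len(ev) - n_noise - n_damaged
    return {
        "total": n_intact + n_damaged,
        "intact": n_intact,
        "damaged": n_damaged,
        "noise": n_noise,
    }


def cell_concentration(
    count: int, acquisition_volume_uL: float, dilution_factor: float = 1e4
) -> float:
    """Cells/mL of the undiluted sample from a gated event count."""
    if not acquisition_volume_uL > 0:
        raise ValueError("acquisition volume must be positive")
    if dilution_factor < 1:
        raise ValueError("dilution factor must be >= 1")
    return count / (acquisition_volume_uL / 1000.0) * dilution_factor


def intact_fraction(counts: dict[str, int]) -> float:
    """Fraction of cell events classified intact; NaN when no cells gated."""
    if counts["total"] <= 0:
        return float("nan")
    return counts["intact"] / counts["total"]


def merge_duplicates(concentrations: list[float]) -> float:
    """Mean of technical duplicate concentrations (order-invariant)."""
    if not concentrations:
        raise ValueError("no measurements to merge")
    return float(np.mean(concentrations))


def load_event_table(path) -> pd.DataFrame:
    """Read a CSV event table with 'green,red' header columns."""
    return pd.read_csv(path)[["green", "red"]]
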