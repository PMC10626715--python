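"""Compartment mass-balance rates and conversion efficiencies.

Net daily rates follow the flow-through bookkeeping of a semi-continuous
reactor sampled at (pseudo) steady state: a concentration difference between
a vessel and its feed, multiplied by the daily flow.  For the proximal
vessel the feed is fresh influent (no cells, no fermentation metabolites);
for the distal vessel the feed is proximal effluent, so proximal
concentrations are subtracted.  Rates telescope: proximal + distal rates
equal the whole-system rate exactly.

Efficiency ratios divide net production by net carbohydrate utilisation
(mmol/g or cells/g) or by net biomass production (mmol/cell).  They are
reported only where the denominator is positive; otherwise the value is NaN
with an ``undefined`` flag, never an infinity or a negative ratio.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .simulate import METABOLITES, SCFA

__all__ = [
    "net_production_rate",
    "distal_net_production",
    "net_carb_utilisation",
    "net_biomass_production",
    "conversion_efficiency",
    "biomass_normalised_production",
    "total_scfa",
    "mass_balance_table",
]


def net_production_rate(c_out_mM: float, c_in_mM: float, daily_flow_mL: float) -> float:
    """Net metabolite production (mmol/day) = (c_out - c_in) x Q[L/day]."""
    return (c_out_mM - c_in_mM) * daily_flow_mL / 1000.0


def distal_net_production(
    c_distal_mM: float, c_proximal_mM: float, daily_flow_mL: float
) -> float:
    """Distal rate with proximal effluent as the incoming stream."""
    return net_production_rate(c_distal_mM, c_proximal_mM, daily_flow_mL)


def net_carb_utilisation(
    c_in_g_per_L: float, c_out_g_per_L: float, daily_flow_mL: float
) -> float:
    """Net carbohydrate utilisation (g/day); positive = consumed."""
    return (c_in_g_per_L - c_out_g_per_L) * daily_flow_mL / 1000.0


def net_biomass_production(
    x_out_cells_per_mL: float, x_in_cells_per_mL: float, daily_flow_mL: float
) -> float:
    """Net biomass production (cells/day) = (x_out - x_in) x Q[mL/day]."""
    return (x_out_cells_per_mL - x_in_cells_per_mL) * daily_flow_mL


def conversion_efficiency(P_mmol_per_day: float, U_g_per_day: float) -> float:
    """P/U (mmol per g carbohydrate); NaN when U <= 0."""
    if not U_g_per_day > 0:
        return float("nan")
    return P_mmol_per_day / U_g_per_day


def biomass_normalised_production(
    P_mmol_per_day: float, B_cells_per_day: float
) -> float:
    """P/B (mmol per cell produced); NaN when B <= 0."""
    if not B_cells_per_day > 0:
        return float("nan")
    return P_mmol_per_day / B_cells_per_day


def total_scfa(
    per_metabolite_rates: dict[str, float], members: tuple[str, ...] = SCFA
) -> float:
    """Sum the configured SCFA members (default: acetate, propionate,
    butyrate, isobutyrate, isovalerate)."""
    missing = [m for m in members if m not in per_metabolite_rates]
    if missing:
        raise KeyError(f"missing SCFA members: {missing}")
    return float(sum(per_metabolite_rates[m] for m in members))


def mass_balance_table(
    samples: pd.DataFrame,
    influent_carb_g_per_L: float | dict[str, float],
    daily_flow_mL: float = 600.0,
    metabolites: tuple[str, ...] = METABOLITES,
    scfa_members: tuple[str, ...] = SCFA,
    influent_metabolite_mM: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-sample mass-balance records from paired compartment measurements.

    ``samples`` must have one row per (donor, arm, day, compartment) with
    columns: the metabolite concentrations (mM), ``carb_g_per_L`` and
    ``total_cells_per_mL``.  Proximal and distal rows of the same
    (donor, arm, day) are paired; an unpaired distal sample raises.
    ``influent_carb_g_per_L`` may be a single value or a per-arm dict.

    Returns a tidy frame with net production P per metabolite plus
    ``total_scfa`` (mmol/day), carbohydrate utilisation U (g/day), biomass
    production B (cells/day), and the efficiency ratios P/U, B/U and P/B
    (NaN + ``*_undefined`` flag where the denominator is not positive).
    """
    req = {"donor", "arm", "day", "compartment", "carb_g_per_L", "total_cells_per_mL"}
    missing = req - set(samples.columns)
    if missing:
        raise ValueError(f"samples missing columns: {sorted(missing)}")
    inf_met = influent_metabolite_mM or {}
    records = []
    for (donor, arm, day), grp in samples.groupby(["donor", "arm", "day"]):
        by_comp = {r["compartment"]: r for _, r in grp.iterrows()}
        if "distal" in by_comp and "proximal" not in by_comp:
            raise ValueError(
                f"distal sample without proximal pair: {donor}/{arm}/day {day}"
            )
        c_in_carb = (
            influent_carb_g_per_L[arm]
            if isinstance(influent_carb_g_per_L, dict)
            else influent_carb_g_per_L
        )
        for comp in ("proximal", "distal"):
            if comp not in by_comp:
                continue
            row = by_comp[comp]
            if comp == "proximal":
                met_in = {m: inf_met.get(m, 0.0) for m in metabolites}
                carb_in = c_in_carb
                cells_in = 0.0
            else:
                prox = by_comp["proximal"]
                met_in = {m: prox[m] for m in metabolites}
                carb_in = prox["carb_g_per_L"]
                cells_in = prox["total_cells_per_mL"]
            P = {
                m: net_production_rate(row[m], met_in[m], daily_flow_mL)
                for m in metabolites
            }
            U = net_carb_utilisation(carb_in, row["carb_g_per_L"], daily_flow_mL)
            B = net_biomass_production(
                row["total_cells_per_mL"], cells_in, daily_flow_mL
            )
            rec = {
                "donor": donor, "arm": arm, "day": day, "compartment": comp,
                **{f"P_{m}": P[m] for m in metabolites},
                "P_total_scfa": total_scfa(P, scfa_members),
                "U_carb_g_per_day": U,
                "B_cells_per_day": B,
                "U_undefined": not U > 0,
                "B_undefined": not B > 0,
            }
            for m in metabolites:
                rec[f"E_{m}_mmol_per_g"] = conversion_efficiency(P[m], U)
                rec[f"PB_{m}_mmol_per_cell"] = biomass_normalised_production(P[m], B)
            rec["E_total_scfa_mmol_per_g"] = conversion_efficiency(
                rec["P_total_scfa"], U
            )
            rec["E_biomass_cells_per_g"] = (
                B / U if U > 0 else float("nan")
            )
            rec["PB_total_scfa_mmol_per_cell"] = biomass_normalised_production(
                rec["P_total_scfa"], B
            )
            records.append(rec)
    return pd.DataFrame(records)
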