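"""Synthetic two-compartment semi-continuous reactor community simulator.

Generates everything the downstream analysis stages consume — ground-truth
community trajectories, amplicon read counts, flow-cytometry event tables and
noisy chemistry — without any external data.

Mechanism
---------
Each arm is a proximal and a distal vessel.  Growth follows multi-substrate
Monod kinetics: species ``s`` grows at ``mu_s = mu_max_s * sum_p w_sp *
S_p/(K_sp + S_p)`` over its preferred substrate pools (simple carbohydrates,
complex fibre, mucin/protein, and lactate as a cross-feeding pool).  Within a
feed cycle the state is integrated with fixed exponential-Euler steps; cell
production is tied to substrate consumption through a fixed cell yield, and
metabolite release through per-gram stoichiometries, so mass balance holds by
construction.  At sub-cycle boundaries a transfer event moves a dose of
volume ``v`` through the train (fresh influent -> proximal -> distal ->
waste) as an instantaneous volume-weighted mix, the discrete analogue of
dilution: a non-growing population decays by ``ln(V/(V-v))`` per transfer
period, so species persist only when their realised growth rate beats that
threshold — the washout criterion that drives the transit-time response.

The 8-h cycle dose is split into hourly sub-doses by default.  A single
8-h event would equal the proximal working volume at the short arm (200 mL)
and sterilise the compartment each cycle; hourly sub-dosing keeps the
semi-continuous character with a finite washout threshold.

The default 12-species panel spans the anaerobic growth-rate range predicted
for gut taxa in silico (0.084-0.520 h^-1): fast simple-sugar fermenters and
lactate consumers at the short-transit end, slow fibre/mucin/amino-acid
specialists that only persist at long transit, and intermediate butyrate and
propionate producers.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reactor import ReactorConfig

__all__ = [
    "SUBSTRATE_POOLS",
    "METABOLITES",
    "SCFA",
    "LACTATE_G_PER_MMOL",
    "SpeciesParams",
    "SpeciesSet",
    "default_panel",
    "Influent",
    "standard_influent",
    "ReactorState",
    "SimOutput",
    "step_growth",
    "transfer_event",
    "simulate_experiment",
    "observe_reads",
    "observe_fcm",
    "synthetic_control_events",
    "observe_chemistry",
    "planted_regression",
    "child_rng",
]

SUBSTRATE_POOLS = ("simple_carb", "complex_fibre", "mucin_protein")
METABOLITES = (
    "acetate",
    "propionate",
    "butyrate",
    "isobutyrate",
    "isovalerate",
    "lactate",
    "ammonium",
)
#: Acids summed into "total SCFA" by default.
SCFA = ("acetate", "propionate", "butyrate", "isobutyrate", "isovalerate")

LACTATE_G_PER_MMOL = 0.09008  # lactic acid molar mass, g/mmol
_LACTATE_IDX = METABOLITES.index("lactate")
_N_POOLS = len(SUBSTRATE_POOLS) + 1  # + lactate cross-feeding pool
_TINY = 1e-300

# Log10-fluorescence mixture locations used by the synthetic cytometer
# (green 530/30 nm, red >670 nm channels).  Intact cells: bright green, dim
# red; membrane-damaged cells: red-shifted; instrument noise: dim in both.
FCM_INTACT_MEAN = (2.8, 1.2)
FCM_DAMAGED_MEAN = (2.3, 2.6)
FCM_NOISE_MEAN = (0.8, 0.8)
FCM_INTACT_SD = (0.15, 0.20)
FCM_DAMAGED_SD = (0.20, 0.20)
FCM_NOISE_SD = (0.30, 0.30)


def child_rng(seed: int, *keys: str) -> np.random.Generator:
    """Named child stream derived from a root seed.

    Stream identity depends only on (seed, keys), so any stage can be re-run
    in isolation with the stream it saw inside the full pipeline.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy.extend(zlib.crc32(k.encode()) & 0x7FFFFFFF for k in keys)
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# species parameters


@dataclass(frozen=True)
class SpeciesParams:
    """Growth, yield and fermentation parameters of one archetype.

    ``substrate_prefs`` maps pool name -> (K_s in g/L, uptake weight); the
    weights of a species should sum to <= 1.  ``scfa_stoich`` maps metabolite
    -> mmol produced per gram of substrate consumed.  Lactate consumption is
    expressed by listing ``"lactate"`` among the substrate preferences, not
    by a negative stoichiometry.
    """

    species_id: str
    mu_max_per_h: float
    substrate_prefs: dict[str, tuple[float, float]]
    yield_cells_per_g: float
    scfa_stoich: dict[str, float] = field(default_factory=dict)
    copy_number: int = 4
    death_rate_per_h: float = 0.0

    def __post_init__(self) -> None:
        if not self.mu_max_per_h > 0:
            raise ValueError("mu_max_per_h must be positive")
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")
        if self.yield_cells_per_g < 0:
            raise ValueError("yield must be >= 0")
        valid = set(SUBSTRATE_POOLS) | {"lactate"}
        unknown = set(self.substrate_prefs) - valid
        if unknown:
            raise ValueError(f"unknown substrate pools: {sorted(unknown)}")
        if set(self.scfa_stoich) - set(METABOLITES):
            raise ValueError("unknown metabolites in scfa_stoich")


class SpeciesSet:
    """A species panel compiled to dense arrays for fast stepping."""

    def __init__(self, species: list[SpeciesParams]):
        if not species:
            raise ValueError("species list is empty")
        self.species = list(species)
        self.ids = [s.species_id for s in species]
        n = len(species)
        pools = list(SUBSTRATE_POOLS) + ["lactate"]
        self.mu_max = np.array([s.mu_max_per_h for s in species])
        self.K = np.ones((n, _N_POOLS))
        self.W = np.zeros((n, _N_POOLS))
        for i, s in enumerate(species):
            for pool, (ks, w) in s.substrate_prefs.items():
                j = pools.index(pool)
                self.K[i, j] = ks
                self.W[i, j] = w
        self.yield_ = np.array([s.yield_cells_per_g for s in species])
        self.stoich = np.zeros((n, len(METABOLITES)))
        for i, s in enumerate(species):
            for met, v in s.scfa_stoich.items():
                self.stoich[i, METABOLITES.index(met)] = v
        self.death = np.array([s.death_rate_per_h for s in species])
        self.copy_numbers = np.array([s.copy_number for s in species], dtype=int)

    def __len__(self) -> int:
        return len(self.species)

    def saturated_mu(self) -> np.ndarray:
        """Growth rate with every preferred pool saturated (h^-1)."""
        return self.mu_max * self.W.sum(axis=1)

    def with_mu_factors(self, factors: np.ndarray) -> "SpeciesSet":
        """Copy of the panel with per-species growth rates rescaled.

        Used to express donor-to-donor strain variation: the archetype is
        shared, the realised maximal growth rate differs per donor.
        """
        factors = np.asarray(factors, dtype=float)
        if factors.shape != self.mu_max.shape or np.any(factors <= 0):
            raise ValueError("need one positive factor per species")
        out = SpeciesSet(self.species)
        out.mu_max = self.mu_max * factors
        return out


def default_panel() -> SpeciesSet:
    """Twelve gut-community archetypes spanning 0.084-0.520 h^-1.

    Maximal growth rates are anchored to in-silico predicted anaerobic rates
    for the corresponding guilds; yields are of order 2-3.5e11 cells per gram
    of substrate (~0.3 g biomass/g at ~1 pg per cell).
    """
    sp = SpeciesParams
    return SpeciesSet(
        [
            sp("bifidobacterium_like", 0.170,
               {"simple_carb": (0.3, 0.8), "complex_fibre": (1.5, 0.2)},
               2.5e11, {"acetate": 5.0, "lactate": 3.0}, copy_number=3),
            sp("veillonella_like", 0.170, {"lactate": (0.05, 1.0)},
               1.5e11, {"acetate": 2.0, "propionate": 6.0}, copy_number=4),
            sp("bacteroides_like", 0.419,
               {"complex_fibre": (0.8, 0.7), "simple_carb": (0.4, 0.3)},
               3.0e11, {"acetate": 4.0, "propionate": 3.5}, copy_number=6),
            sp("phocaeicola_like", 0.520,
               {"complex_fibre": (1.0, 0.6), "simple_carb": (0.3, 0.4)},
               3.0e11, {"acetate": 3.5, "propionate": 4.5}, copy_number=7),
            sp("prevotella_like", 0.084, {"complex_fibre": (0.25, 1.0)},
               3.5e11, {"acetate": 4.0, "propionate": 4.0}, copy_number=3),
            sp("ruminococcus_like", 0.200,
               {"complex_fibre": (0.6, 0.6), "simple_carb": (0.5, 0.4)},
               2.5e11, {"acetate": 6.0}, copy_number=4),
            sp("akkermansia_like", 0.084, {"mucin_protein": (0.15, 1.0)},
               2.5e11, {"acetate": 3.0, "propionate": 2.0, "ammonium": 1.5},
               copy_number=3),
            sp("bilophila_like", 0.088, {"mucin_protein": (0.4, 1.0)},
               2.0e11, {"acetate": 1.5, "ammonium": 2.5}, copy_number=2),
            sp("faecalibacterium_like", 0.239,
               {"simple_carb": (0.4, 0.5), "complex_fibre": (0.8, 0.5)},
               2.5e11, {"butyrate": 4.5, "acetate": 1.0}, copy_number=6),
            sp("blautia_like", 0.239, {"simple_carb": (0.3, 1.0)},
               2.5e11, {"butyrate": 3.0, "acetate": 2.5}, copy_number=5),
            sp("enterobacteriaceae_like", 0.520, {"simple_carb": (0.1, 1.0)},
               2.0e11, {"acetate": 2.5, "lactate": 2.0, "ammonium": 1.0},
               copy_number=7),
            sp("acidaminococcus_like", 0.088, {"mucin_protein": (0.5, 1.0)},
               2.0e11,
               {"acetate": 2.0, "isobutyrate": 1.2, "isovalerate": 1.2,
                "ammonium": 3.0}, copy_number=4),
        ]
    )


# ---------------------------------------------------------------------------
# state containers


@dataclass(frozen=True)
class Influent:
    """Feed composition: sterile medium with substrate pools (g/L)."""

    substrate_g_per_L: np.ndarray
    metabolite_mM: np.ndarray

    @property
    def cells(self) -> float:
        return 0.0


def standard_influent(
    config: ReactorConfig,
    fractions: tuple[float, float, float] = (0.40, 0.50, 0.10),
) -> Influent:
    """Influent for an arm: total carbohydrate split over the three pools.

    Default split 40% simple carbohydrates / 50% complex fibre / 10%
    mucin+protein mimics a starch-supplemented standard gut medium.
    """
    total = config.influent_carb_g_per_L
    subs = np.asarray(fractions, dtype=float) * total
    return Influent(subs, np.zeros(len(METABOLITES)))


@dataclass
class ReactorState:
    """Instantaneous state of both compartments (row 0 proximal, 1 distal)."""

    time_h: float
    cells_per_mL: np.ndarray  # (2, n_species)
    substrate_g_per_L: np.ndarray  # (2, 3)
    metabolite_mM: np.ndarray  # (2, n_metabolites)

    def validate(self) -> None:
        for name in ("cells_per_mL", "substrate_g_per_L", "metabolite_mM"):
            a = getattr(self, name)
            if not np.all(np.isfinite(a)) or np.any(a < 0):
                raise ValueError(f"invalid state: {name} has negative/non-finite entries")

    def copy(self) -> "ReactorState":
        return ReactorState(
            self.time_h,
            self.cells_per_mL.copy(),
            self.substrate_g_per_L.copy(),
            self.metabolite_mM.copy(),
        )


# ---------------------------------------------------------------------------
# dynamics


def _growth_substep(cells, subs, mets, ss: SpeciesSet, dt_h: float):
    """One exponential-Euler growth step for a single compartment.

    Returns updated (cells, subs, mets) plus the net biochemical metabolite
    change (mM), grams of substrate consumed per litre, and cells produced
    per mL, for the conservation ledgers.
    """
    s_pool = np.concatenate([subs, [mets[_LACTATE_IDX] * LACTATE_G_PER_MMOL]])
    denom = ss.K + s_pool[None, :]
    monod = np.where(
        (ss.W > 0) & (s_pool[None, :] > 0),
        s_pool[None, :] / np.where(denom > 0, denom, 1.0),
        0.0,
    )
    frac = ss.W * monod
    frac_sum = frac.sum(axis=1)
    mu = ss.mu_max * frac_sum
    share = np.where(
        frac_sum[:, None] > 0, frac / np.maximum(frac_sum[:, None], _TINY), 0.0
    )
    gross = cells * np.expm1(mu * dt_h)  # cells/mL that full growth would add
    demand = (gross[:, None] * 1000.0 / ss.yield_[:, None]) * share  # g/L
    pool_demand = demand.sum(axis=0)
    scale = np.where(
        pool_demand > s_pool, s_pool / np.maximum(pool_demand, _TINY), 1.0
    )
    taken = demand * scale[None, :]
    grams = taken.sum(axis=1)  # g/L consumed per species
    produced = grams * ss.yield_ / 1000.0  # cells/mL, exact conservation
    cells = (cells + produced) * np.exp(-ss.death * dt_h)
    subs = np.maximum(subs - taken[:, :3].sum(axis=0), 0.0)
    d_met = ss.stoich.T @ grams
    d_met[_LACTATE_IDX] -= taken[:, 3].sum() / LACTATE_G_PER_MMOL
    mets = np.maximum(mets + d_met, 0.0)
    return cells, subs, mets, d_met, taken[:, :3].sum(), produced.sum()


def step_growth(state: ReactorState, species: SpeciesSet, dt_h: float) -> ReactorState:
    """Advance growth in both compartments by ``dt_h`` (no transfer).

    Substrate uptake is rescaled pool-wise when demand exceeds availability,
    so concentrations never go negative and grams consumed x yield always
    equals cells produced.
    """
    state.validate()
    out = state.copy()
    for c in range(state.cells_per_mL.shape[0]):
        cells, subs, mets, *_ = _growth_substep(
            out.cells_per_mL[c], out.substrate_g_per_L[c], out.metabolite_mM[c],
            species, dt_h,
        )
        out.cells_per_mL[c] = cells
        out.substrate_g_per_L[c] = subs
        out.metabolite_mM[c] = mets
    out.time_h = state.time_h + dt_h
    return out


def transfer_event(
    state: ReactorState,
    config: ReactorConfig,
    influent: Influent,
    volume_mL: float | None = None,
) -> ReactorState:
    """One feed/transfer event moving ``volume_mL`` through the train.

    Order: waste ``v`` from the distal vessel, move ``v`` of (pre-event)
    proximal content to the distal vessel, dose ``v`` of fresh influent into
    the proximal vessel.  Each vessel ends as a volume-weighted mix at
    unchanged working volume.
    """
    v = config.cycle_volume_mL if volume_mL is None else volume_mL
    vp = config.proximal.volume_mL
    vd = config.distal.volume_mL
    if v > min(vp, vd):
        raise ValueError(
            f"transfer volume {v} mL exceeds a compartment volume ({vp}, {vd})"
        )
    out = state.copy()

    def mix(conc_self, conc_in, vol):
        return (conc_self * (vol - v) + conc_in * v) / vol

    prox_cells = state.cells_per_mL[0]
    prox_subs = state.substrate_g_per_L[0]
    prox_mets = state.metabolite_mM[0]
    out.cells_per_mL[1] = mix(state.cells_per_mL[1], prox_cells, vd)
    out.substrate_g_per_L[1] = mix(state.substrate_g_per_L[1], prox_subs, vd)
    out.metabolite_mM[1] = mix(state.metabolite_mM[1], prox_mets, vd)
    out.cells_per_mL[0] = mix(prox_cells, 0.0, vp)
    out.substrate_g_per_L[0] = mix(prox_subs, influent.substrate_g_per_L, vp)
    out.metabolite_mM[0] = mix(prox_mets, influent.metabolite_mM, vp)
    return out


@dataclass
class SimOutput:
    """Simulation result: sampled truth plus conservation ledgers.

    ``samples`` holds pre-transfer end-of-day states (one row per day and
    compartment); ``cum_production_mmol`` holds the cumulative net
    biochemical production (mmol, per compartment) at the same instants, so
    day-over-day differences give true daily production rates.
    """

    config: ReactorConfig
    species_ids: list[str]
    donor: str
    samples: pd.DataFrame
    cum_production_mmol: pd.DataFrame
    cum_substrate_consumed_g: pd.DataFrame
    trajectory: pd.DataFrame

    def daily_production_mmol(self, day: int) -> pd.DataFrame:
        """Net mmol produced biochemically during ``day`` per compartment."""
        cur = self.cum_production_mmol.xs(day, level="day")
        prev = self.cum_production_mmol.xs(day - 1, level="day")
        return cur - prev


_OVERFLOW_GUARD = 1e15


def simulate_experiment(
    config: ReactorConfig,
    species: SpeciesSet,
    n_days: int,
    sample_days: list[int],
    seed: int = 0,
    dt_h: float = 0.05,
    subdoses_per_cycle: int = 8,
    donor: str = "donor1",
    influent: Influent | None = None,
    initial_cells_per_mL: np.ndarray | None = None,
    inoculum_sigma: float = 0.7,
    donor_mu_sigma: float = 0.0,
) -> SimOutput:
    """Run one arm for ``n_days`` and sample the listed days.

    The inoculum is 1e7 cells/mL per species, jittered lognormally per
    (seed, donor), and each donor carries lognormal per-species growth-rate
    factors (sd ``donor_mu_sigma`` on the log scale) representing strain
    variation — the source of persistent inter-individual differences.
    Dynamics themselves are deterministic; identical arguments give
    identical output.
    """
    if any(d < 1 or d > n_days for d in sample_days):
        raise ValueError("sample_days must lie within the simulated horizon")
    if subdoses_per_cycle < 1:
        raise ValueError("subdoses_per_cycle must be >= 1")
    stab = config.stabilisation_days
    if sample_days and min(sample_days) < stab:
        import warnings

        warnings.warn(
            f"sampling before stabilisation day {stab} of arm {config.arm}",
            stacklevel=2,
        )
    if influent is None:
        influent = standard_influent(config)
    if initial_cells_per_mL is None:
        rng = child_rng(seed, "inoculum", donor)
        initial_cells_per_mL = 1e7 * rng.lognormal(
            -0.5 * inoculum_sigma**2, inoculum_sigma, size=len(species)
        )
    if donor_mu_sigma > 0:
        mu_rng = child_rng(seed, "donor_mu", donor)
        species = species.with_mu_factors(
            mu_rng.lognormal(-0.5 * donor_mu_sigma**2, donor_mu_sigma,
                             size=len(species))
        )

    n_met = len(METABOLITES)
    state = ReactorState(
        0.0,
        np.tile(np.asarray(initial_cells_per_mL, dtype=float), (2, 1)),
        np.tile(influent.substrate_g_per_L * 0.25, (2, 1)),
        np.zeros((2, n_met)),
    )
    state.validate()

    sub_period_h = config.cycle_period_h / subdoses_per_cycle
    v_sub = config.cycle_volume_mL / subdoses_per_cycle
    steps_per_sub = max(1, round(sub_period_h / dt_h))
    dt = sub_period_h / steps_per_sub
    vols = np.array([config.proximal.volume_mL, config.distal.volume_mL])

    cum_prod = np.zeros((2, n_met))  # mmol
    cum_subs = np.zeros(2)  # g consumed
    sample_set = set(sample_days)
    sample_rows, prod_rows, subs_rows, traj_rows = [], [], [], []
    n_sub_total = round(n_days * 24.0 / sub_period_h)

    for k in range(1, n_sub_total + 1):
        for _ in range(steps_per_sub):
            for c in range(2):
                res = _growth_substep(
                    state.cells_per_mL[c],
                    state.substrate_g_per_L[c],
                    state.metabolite_mM[c],
                    species,
                    dt,
                )
                state.cells_per_mL[c] = res[0]
                state.substrate_g_per_L[c] = res[1]
                state.metabolite_mM[c] = res[2]
                cum_prod[c] += res[3] * vols[c] / 1000.0
                cum_subs[c] += res[4] * vols[c] / 1000.0
        state.time_h = k * sub_period_h
        if np.any(state.cells_per_mL > _OVERFLOW_GUARD):
            raise FloatingPointError(
                f"simulation diverged at t={state.time_h} h (cells > {_OVERFLOW_GUARD:g})"
            )
        t = state.time_h
        day = t / 24.0
        if abs(day - round(day)) < 1e-9:
            d = round(day)
            for c, comp in enumerate(("proximal", "distal")):
                traj_rows.append(
                    {"time_h": t, "compartment": comp,
                     "total_cells_per_mL": state.cells_per_mL[c].sum(),
                     "carb_g_per_L": state.substrate_g_per_L[c].sum()}
                )
            if d in sample_set or (d - 1) in sample_set or (d + 1) in sample_set:
                for c, comp in enumerate(("proximal", "distal")):
                    row = {"day": d, "compartment": comp}
                    row.update(dict(zip(species.ids, state.cells_per_mL[c])))
                    row.update(
                        {f"sub_{p}": v for p, v in
                         zip(SUBSTRATE_POOLS, state.substrate_g_per_L[c])}
                    )
                    row.update(dict(zip(METABOLITES, state.metabolite_mM[c])))
                    if d in sample_set:
                        sample_rows.append(row)
                    prod_rows.append(
                        {"day": d, "compartment": comp,
                         **dict(zip(METABOLITES, cum_prod[c]))}
                    )
                    subs_rows.append(
                        {"day": d, "compartment": comp, "consumed_g": cum_subs[c]}
                    )
        state_pre = state  # sampled state is pre-transfer
        state = transfer_event(state_pre, config, influent, volume_mL=v_sub)

    samples = pd.DataFrame(sample_rows)
    if not samples.empty:
        samples.insert(0, "arm", config.arm)
        samples.insert(0, "donor", donor)
        samples = samples.set_index(["day", "compartment"]).sort_index()
    cum_production = (
        pd.DataFrame(prod_rows).drop_duplicates(["day", "compartment"])
        .set_index(["day", "compartment"]).sort_index()
    )
    cum_substrate = (
        pd.DataFrame(subs_rows).drop_duplicates(["day", "compartment"])
        .set_index(["day", "compartment"]).sort_index()
    )
    return SimOutput(
        config=config,
        species_ids=list(species.ids),
        donor=donor,
        samples=samples,
        cum_production_mmol=cum_production,
        cum_substrate_consumed_g=cum_substrate,
        trajectory=pd.DataFrame(traj_rows),
    )


# ---------------------------------------------------------------------------
# observation layer


def observe_reads(
    composition_cells_per_mL: np.ndarray,
    copy_numbers: np.ndarray,
    depth: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Multinomial amplicon read counts with 16S copy-number bias.

    Read probabilities are proportional to cells x copy number — the forward
    model whose inverse is the copy-number correction applied downstream.
    """
    comp = np.asarray(composition_cells_per_mL, dtype=float)
    cn = np.asarray(copy_numbers, dtype=float)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if np.any(comp < 0):
        raise ValueError("composition must be non-negative")
    w = comp * cn
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero composition cannot be sequenced")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multinomial(depth, w / total)


def _mixture_events(rng, n, mean, sd):
    g = rng.normal(mean[0], sd[0], size=n)
    r = rng.normal(mean[1], sd[1], size=n)
    return np.column_stack([g, r])


def observe_fcm(
    total_cells_per_mL: float,
    cv: float,
    intact_fraction_true: float,
    n_events_target: int,
    seed: int | np.random.Generator = 0,
    dilution_factor: float = 1e4,
    noise_fraction: float = 0.10,
) -> tuple[pd.DataFrame, float, float]:
    """Synthesise one stained-sample event table.

    The measured concentration is drawn lognormally around the truth with the
    given CV (mean-unbiased parameterisation); cell events are emitted from
    the intact/damaged/noise fluorescence mixture and the acquisition volume
    is set so that gated counts divided by volume recover the measured
    concentration.  Returns (events, acquisition_volume_uL, dilution_factor).
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if not 0 <= intact_fraction_true <= 1:
        raise ValueError("intact_fraction_true must be in [0, 1]")
    if total_cells_per_mL <= 0:
        raise ValueError("total_cells_per_mL must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(cv**2))
    measured = total_cells_per_mL * rng.lognormal(-0.5 * sigma**2, sigma)
    n_cells = max(1, round(n_events_target * (1.0 - noise_fraction)))
    n_intact = rng.binomial(n_cells, intact_fraction_true)
    n_damaged = n_cells - n_intact
    n_noise = n_events_target - n_cells
    cells_per_uL = measured / dilution_factor / 1000.0
    acquisition_volume_uL = n_cells / cells_per_uL
    parts = [
        _mixture_events(rng, n_intact, FCM_INTACT_MEAN, FCM_INTACT_SD),
        _mixture_events(rng, n_damaged, FCM_DAMAGED_MEAN, FCM_DAMAGED_SD),
        _mixture_events(rng, n_noise, FCM_NOISE_MEAN, FCM_NOISE_SD),
    ]
    ev = np.vstack([p for p in parts if len(p)])
    ev = ev[rng.permutation(len(ev))]
    events = pd.DataFrame(ev, columns=["green", "red"])
    return events, acquisition_volume_uL, dilution_factor


def synthetic_control_events(
    n_events: int, kind: str, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Synthetic control acquisitions for gate construction.

    ``kind='negative'`` emits pure instrument noise (0.22 um filtered
    sample); ``kind='heat_killed'`` emits membrane-damaged cells only.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if kind == "negative":
        ev = _mixture_events(rng, n_events, FCM_NOISE_MEAN, FCM_NOISE_SD)
    elif kind == "heat_killed":
        ev = _mixture_events(rng, n_events, FCM_DAMAGED_MEAN, FCM_DAMAGED_SD)
    else:
        raise ValueError("kind must be 'negative' or 'heat_killed'")
    return pd.DataFrame(ev, columns=["green", "red"])


def observe_chemistry(
    values: np.ndarray, sd_abs: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Additive Gaussian measurement noise, truncated at zero."""
    v = np.asarray(values, dtype=float)
    if sd_abs < 0:
        raise ValueError("sd_abs must be >= 0")
    if np.any(v < 0):
        raise ValueError("true concentrations must be non-negative")
    if sd_abs == 0:
        return v.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return np.clip(v + rng.normal(0.0, sd_abs, size=v.shape), 0.0, None)


def planted_regression(
    n: int = 60,
    n_taxa: int = 20,
    n_active: int = 3,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Sparse planted taxon->metabolite dataset for integration benchmarks.

    The first ``n_active`` taxa drive a single response ("acetate") with unit
    coefficients; the rest are noise.  Returns (X, Y, active_taxon_ids).
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_taxa))
    y = X[:, :n_active].sum(axis=1) + rng.normal(0.0, noise_sd, size=n)
    taxa = [f"taxon_{i:02d}" for i in range(n_taxa)]
    Xdf = pd.DataFrame(X, columns=taxa)
    Ydf = pd.DataFrame({"acetate": y})
    return Xdf, Ydf, taxa[:n_active]
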