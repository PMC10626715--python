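"""End-to-end pipeline: simulate -> observe -> profile -> mass balance ->
statistics -> ordination -> integration.

Each stage is a plain function reading/writing tidy TSV files in a run
directory, so stages can be re-run in isolation; ``run_pipeline`` wires them
together under a single root seed and records a machine-readable manifest
(config hash, per-stage child seed keys, file checksums, timings).
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fcm import build_gates, cell_concentration, gate_counts, intact_fraction, merge_duplicates
from .massbalance import mass_balance_table
from .ordination import bray_curtis, variance_partition
from .qmp import CountTable, build_qmp, copy_number_correct, filter_otus, flag_low_depth_samples, rarefy
from .reactor import ReactorConfig
from .simulate import (
    METABOLITES,
    child_rng,
    default_panel,
    observe_chemistry,
    observe_fcm,
    observe_reads,
    simulate_experiment,
    synthetic_control_events,
)
from .spls import SPLS, relevance_network
from .stats import bh_adjust, kruskal_wallis, pairwise_rank_sum, signed_rank_paired

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "report"]

DEFAULT_CONFIG: dict = {
    "n_donors": 6,
    "arms": ["short", "medium", "long"],
    "n_sample_days": 5,
    "dt_h": 0.05,
    "subdoses_per_cycle": 8,
    "donor_mu_sigma": 0.05,
    "read_depth": 10000,
    "fcm": {"cv": 0.05, "n_events": 20000, "dilution_factor": 1e4,
            "n_control_events": 20000},
    "chemistry": {"metabolite_sd_mM": 1.0, "carb_sd_g_per_L": 0.3},
    "ordination": {"n_perm": 199},
    "spls": {"n_components": 2, "keep_x": 8, "network_threshold": 0.55},
}

#: Donor labels -> in vivo transit class (two donors per class, mirroring a
#: short/medium/long donor panel).
DONOR_INVIVO = {
    "donor1": "short", "donor2": "short",
    "donor3": "medium", "donor4": "medium",
    "donor5": "long", "donor6": "long",
}

_INTACT_BASE = {"short": 0.92, "medium": 0.88, "long": 0.84}


def load_config(path: str | Path | None) -> dict:
    """Load a YAML run configuration, filling defaults for absent keys."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError("config file must contain a mapping")
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k, v in user.items():
            if isinstance(cfg.get(k), dict) and isinstance(v, dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: dict, seed: int, out_dir: Path) -> pd.DataFrame:
    """Simulate every donor x arm and write ground-truth sample tables."""
    panel = default_panel()
    donors = [f"donor{i + 1}" for i in range(cfg["n_donors"])]
    truth_rows = []
    prod_rows = []
    for arm in cfg["arms"]:
        rconf = ReactorConfig.for_arm(arm)
        stab = rconf.stabilisation_days
        days = list(range(stab + 1, stab + 1 + cfg["n_sample_days"]))
        for donor in donors:
            sim = simulate_experiment(
                rconf, panel, n_days=days[-1], sample_days=days,
                seed=seed, dt_h=cfg["dt_h"],
                subdoses_per_cycle=cfg["subdoses_per_cycle"], donor=donor,
                donor_mu_sigma=cfg["donor_mu_sigma"],
            )
            truth = sim.samples.reset_index()
            truth["influent_carb_g_per_L"] = rconf.influent_carb_g_per_L
            truth_rows.append(truth)
            for day in days:
                prod = sim.daily_production_mmol(day).reset_index()
                prod.insert(0, "arm", arm)
                prod.insert(0, "donor", donor)
                prod.insert(3, "day", day)
                prod_rows.append(prod)
    truth_df = pd.concat(truth_rows, ignore_index=True)
    prod_df = pd.concat(prod_rows, ignore_index=True)
    _write_tsv(truth_df, out_dir / "truth_samples.tsv")
    _write_tsv(prod_df, out_dir / "truth_daily_production.tsv")
    return truth_df


def stage_observe(cfg: dict, seed: int, out_dir: Path) -> None:
    """Amplicon reads, cytometry and chemistry measurements from the truth."""
    truth = pd.read_csv(out_dir / "truth_samples.tsv", sep="\t")
    panel = default_panel()
    taxa = panel.ids
    cns = panel.copy_numbers
    fcm_cfg, chem_cfg = cfg["fcm"], cfg["chemistry"]

    gates_rng = child_rng(seed, "fcm_controls")
    neg = synthetic_control_events(fcm_cfg["n_control_events"], "negative", gates_rng)
    hk = synthetic_control_events(fcm_cfg["n_control_events"], "heat_killed", gates_rng)
    gates = build_gates(neg, hk)

    counts = {}
    meas_rows = []
    for _, row in truth.iterrows():
        sid = f"{row['donor']}_{row['arm']}_{row['compartment']}_d{int(row['day'])}"
        comp = row[taxa].to_numpy(dtype=float)
        reads_rng = child_rng(seed, "reads", sid)
        counts[sid] = observe_reads(comp, cns, cfg["read_depth"], reads_rng)

        total_true = comp.sum()
        intact_true = float(np.clip(
            _INTACT_BASE[row["arm"]]
            - (0.02 if row["compartment"] == "distal" else 0.0)
            + child_rng(seed, "intact", row["donor"]).normal(0.0, 0.02),
            0.0, 1.0,
        ))
        reps = []
        ifracs = []
        for rep in range(2):  # technical duplicates
            ev, vol, dil = observe_fcm(
                total_true, fcm_cfg["cv"], intact_true, fcm_cfg["n_events"],
                child_rng(seed, "fcm", sid, str(rep)),
                dilution_factor=fcm_cfg["dilution_factor"],
            )
            gc = gate_counts(ev, gates)
            reps.append(cell_concentration(gc["total"], vol, dil))
            ifracs.append(intact_fraction(gc))
        chem_rng = child_rng(seed, "chem", sid)
        mets = observe_chemistry(
            row[list(METABOLITES)].to_numpy(dtype=float),
            chem_cfg["metabolite_sd_mM"], chem_rng,
        )
        carb_true = sum(row[f"sub_{p}"] for p in
                        ("simple_carb", "complex_fibre", "mucin_protein"))
        carb = float(observe_chemistry(
            np.array([carb_true]), chem_cfg["carb_sd_g_per_L"], chem_rng
        )[0])
        meas = {
            "sample_id": sid, "donor": row["donor"], "arm": row["arm"],
            "compartment": row["compartment"], "day": int(row["day"]),
            "in_vivo": DONOR_INVIVO.get(row["donor"], "unknown"),
            "total_cells_per_mL": merge_duplicates(reps),
            "intact_fraction": float(np.nanmean(ifracs)),
            "carb_g_per_L": carb,
            "influent_carb_g_per_L": row["influent_carb_g_per_L"],
        }
        meas.update(dict(zip(METABOLITES, mets)))
        meas_rows.append(meas)

    # two blank controls with sparse low-depth counts
    blank_rng = child_rng(seed, "blanks")
    for b in range(2):
        depth = int(blank_rng.integers(200, 700))
        counts[f"blank{b + 1}"] = blank_rng.multinomial(
            depth, np.full(len(taxa), 1.0 / len(taxa))
        )
    count_df = pd.DataFrame(counts, index=taxa)
    _write_tsv(count_df, out_dir / "counts.tsv", index=True)
    _write_tsv(
        pd.DataFrame({"otu_id": taxa, "copy_number": cns}),
        out_dir / "copy_numbers.tsv",
    )
    _write_tsv(pd.DataFrame(meas_rows), out_dir / "measured_samples.tsv")


def stage_qmp(cfg: dict, seed: int, out_dir: Path) -> None:
    """QC, rarefaction, copy-number correction and QMP construction."""
    counts = pd.read_csv(out_dir / "counts.tsv", sep="\t", index_col=0)
    cns = pd.read_csv(out_dir / "copy_numbers.tsv", sep="\t").set_index("otu_id")[
        "copy_number"
    ]
    meas = pd.read_csv(out_dir / "measured_samples.tsv", sep="\t")
    sample_meta = pd.DataFrame(
        {"sample_type": ["blank" if s.startswith("blank") else "experimental"
                         for s in counts.columns]},
        index=counts.columns,
    )
    table = CountTable(counts, sample_meta=sample_meta)
    table = filter_otus(table)
    table, removed = flag_low_depth_samples(table)
    exp_samples = [s for s in table.counts.columns if not s.startswith("blank")]
    table = table.subset_samples(exp_samples)
    rarefied = rarefy(table, seed=int(child_rng(seed, "rarefy").integers(2**31)))
    props = copy_number_correct(rarefied.counts, cns)
    totals = meas.set_index("sample_id")["total_cells_per_mL"]
    qmp = build_qmp(props, totals.loc[props.columns],
                    rarefaction_depth=int(rarefied.sample_totals().iloc[0]))
    _write_tsv(props, out_dir / "pmp.tsv", index=True)
    _write_tsv(qmp.abundance, out_dir / "qmp.tsv", index=True)
    if removed:
        (out_dir / "removed_samples.txt").write_text("\n".join(removed) + "\n")


def stage_massbalance(cfg: dict, seed: int, out_dir: Path) -> None:
    meas = pd.read_csv(out_dir / "measured_samples.tsv", sep="\t")
    influent = meas.groupby("arm")["influent_carb_g_per_L"].first().to_dict()
    mb = mass_balance_table(meas, influent_carb_g_per_L=influent)
    mb = mb.merge(
        meas[["donor", "arm", "day", "compartment", "in_vivo"]],
        on=["donor", "arm", "day", "compartment"],
    )
    _write_tsv(mb, out_dir / "massbalance.tsv")


def stage_stats(cfg: dict, seed: int, out_dir: Path) -> None:
    """Univariate battery on cell concentrations and taxon abundances."""
    meas = pd.read_csv(out_dir / "measured_samples.tsv", sep="\t")
    rows = []
    for comp, grp in meas.groupby("compartment"):
        groups = [g["total_cells_per_mL"].to_numpy() for _, g in grp.groupby("arm")]
        kw = kruskal_wallis(groups)
        pw, letters = pairwise_rank_sum(
            grp["total_cells_per_mL"].to_numpy(), grp["arm"].to_numpy()
        )
        rows.append({
            "variable": "total_cells_per_mL", "compartment": comp,
            "test": "kruskal-wallis", "statistic": kw.statistic,
            "p_raw": kw.p_raw,
            "letters": ";".join(f"{k}={v}" for k, v in letters.items()),
        })
        for _, r in pw.iterrows():
            rows.append({
                "variable": "total_cells_per_mL", "compartment": comp,
                "test": f"rank-sum {r['group1']} vs {r['group2']}",
                "statistic": r["statistic"], "p_raw": r["p_raw"],
                "p_adjusted": r["p_adjusted"],
            })
    for arm, grp in meas.groupby("arm"):
        wide = grp.pivot_table(index=["donor", "day"], columns="compartment",
                               values="total_cells_per_mL")
        if {"proximal", "distal"}.issubset(wide.columns):
            sr = signed_rank_paired(
                wide["proximal"].to_numpy(), wide["distal"].to_numpy()
            )
            rows.append({
                "variable": "total_cells_per_mL", "compartment": "paired",
                "test": f"signed-rank proximal vs distal ({arm})",
                "statistic": sr.statistic, "p_raw": sr.p_raw,
            })
    _write_tsv(pd.DataFrame(rows), out_dir / "stats_cells.tsv")

    qmp = pd.read_csv(out_dir / "qmp.tsv", sep="\t", index_col=0)
    meta = meas.set_index("sample_id").loc[qmp.columns]
    taxa_rows = []
    for taxon in qmp.index:
        for comp, grp in meta.groupby("compartment"):
            vals = qmp.loc[taxon, grp.index].to_numpy(dtype=float)
            arms = grp["arm"].to_numpy()
            if len(np.unique(arms)) < 2:
                continue
            kw = kruskal_wallis([vals[arms == a] for a in np.unique(arms)])
            taxa_rows.append({"taxon": taxon, "compartment": comp,
                              "statistic": kw.statistic, "p_raw": kw.p_raw})
    taxa_df = pd.DataFrame(taxa_rows)
    taxa_df["p_fdr"] = bh_adjust(taxa_df["p_raw"].to_numpy())
    _write_tsv(taxa_df, out_dir / "stats_taxa.tsv")


def stage_ordination(cfg: dict, seed: int, out_dir: Path) -> None:
    """Variance partitioning of QMP and PMP composition."""
    meas = pd.read_csv(out_dir / "measured_samples.tsv", sep="\t").set_index(
        "sample_id"
    )
    n_perm = cfg["ordination"]["n_perm"]
    frames = []
    for name in ("qmp", "pmp"):
        prof = pd.read_csv(out_dir / f"{name}.tsv", sep="\t", index_col=0).T
        design = meas.loc[prof.index, ["arm", "compartment", "donor", "in_vivo"]]
        D = bray_curtis(prof)
        vp = variance_partition(
            D, design,
            models={
                "donor_model": ["arm", "compartment", "donor"],
                "invivo_model": ["arm", "compartment", "in_vivo"],
            },
            n_perm=n_perm,
            seed=int(child_rng(seed, "ordination", name).integers(2**31)),
        )
        vp.insert(0, "profile", name.upper())
        frames.append(vp)
    _write_tsv(pd.concat(frames, ignore_index=True), out_dir / "varpart.tsv")


def stage_integrate(cfg: dict, seed: int, out_dir: Path) -> None:
    """sPLS linking QMP taxon abundances to net SCFA production."""
    qmp = pd.read_csv(out_dir / "qmp.tsv", sep="\t", index_col=0).T
    mb = pd.read_csv(out_dir / "massbalance.tsv", sep="\t")
    mb["sample_id"] = (
        mb["donor"] + "_" + mb["arm"] + "_" + mb["compartment"]
        + "_d" + mb["day"].astype(str)
    )
    mb = mb.set_index("sample_id")
    common = qmp.index.intersection(mb.index)
    ycols = ["P_acetate", "P_propionate", "P_butyrate", "P_total_scfa"]
    X = qmp.loc[common]
    Y = mb.loc[common, ycols]
    scfg = cfg["spls"]
    model = SPLS(X, Y, n_components=scfg["n_components"],
                 keep_x=scfg["keep_x"], log10_x=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit()
    net = relevance_network(res, threshold=scfg["network_threshold"])
    _write_tsv(net.edges, out_dir / "spls_edges.tsv")
    _write_tsv(res.x_weights, out_dir / "spls_x_weights.tsv", index=True)
    (out_dir / "spls_summary.txt").write_text(res.summary() + "\n")


STAGES = [
    ("simulate", stage_simulate),
    ("observe", stage_observe),
    ("qmp", stage_qmp),
    ("massbalance", stage_massbalance),
    ("stats", stage_stats),
    ("ordination", stage_ordination),
    ("integrate", stage_integrate),
]


def run_pipeline(
    config: dict | str | Path | None, seed: int, out_dir: str | Path
) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    cfg = config if isinstance(config, dict) else load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "root_seed": int(seed),
        "stages": {},
    }
    for name, fn in STAGES:
        t0 = time.time()
        try:
            fn(cfg, seed, out)
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {
            "status": "ok",
            "seconds": round(time.time() - t0, 2),
            "seed_keys": [int(seed), name],
        }
    manifest["files"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def report(out_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Per-arm summary tables from a completed (or partial) run directory."""
    out = Path(out_dir)
    tables: dict[str, pd.DataFrame] = {}
    if (out / "measured_samples.tsv").exists():
        meas = pd.read_csv(out / "measured_samples.tsv", sep="\t")
        tables["cell_concentrations"] = (
            meas.groupby(["arm", "compartment"])
            .agg(total_cells_per_mL=("total_cells_per_mL", "mean"),
                 intact_fraction=("intact_fraction", "mean"))
            .reset_index()
        )
    if (out / "massbalance.tsv").exists():
        mb = pd.read_csv(out / "massbalance.tsv", sep="\t")
        keys = ["P_acetate", "P_propionate", "P_butyrate", "P_total_scfa",
                "U_carb_g_per_day", "E_total_scfa_mmol_per_g"]
        tables["production"] = (
            mb.groupby(["arm", "compartment"])[keys].mean().reset_index()
        )
    if (out / "varpart.tsv").exists():
        tables["variance_partition"] = pd.read_csv(out / "varpart.tsv", sep="\t")
    if (out / "spls_edges.tsv").exists():
        tables["network_edges"] = pd.read_csv(out / "spls_edges.tsv", sep="\t")
    if (out / "stats_cells.tsv").exists():
        tables["stats_cells"] = pd.read_csv(out / "stats_cells.tsv", sep="\t")
    if (out / "qmp.tsv").exists():
        qmp = pd.read_csv(out / "qmp.tsv", sep="\t", index_col=0)
        tables["qmp_taxon_means"] = (
            qmp.mean(axis=1).rename("mean_cells_per_mL").reset_index()
            .rename(columns={"index": "taxon"})
        )
    missing = [n for n in
               ("cell_concentrations", "production", "variance_partition")
               if n not in tables]
    if missing:
        warnings.warn(f"partial report; missing tables: {missing}", stacklevel=2)
    for name, df in tables.items():
        _write_tsv(df, out / "report" / f"{name}.tsv")
    return tables
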