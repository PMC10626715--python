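"""OTU-table QC and quantitative microbiome profile (QMP) construction.

A proportional 16S profile only reports fractions; multiplying
copy-number-corrected proportions by the flow-cytometric total cell
concentration converts them to absolute abundances (cells/mL), the
quantitative profile.  The stages here mirror the standard QMP recipe:

1. OTU quality control (singletons, low prevalence, low total reads),
2. removal of experimental samples whose depth is in the blank range,
3. rarefaction to even depth (single seeded draw, integers throughout),
4. 16S copy-number correction to cell proportions,
5. scaling by total cell concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "CountTable",
    "QMPTable",
    "filter_otus",
    "flag_low_depth_samples",
    "rarefy",
    "rarefaction_curve",
    "copy_number_correct",
    "build_qmp",
]

SAMPLE_TYPES = ("experimental", "blank", "negative", "positive", "mock")


@dataclass
class CountTable:
    """OTU x sample integer read counts with OTU and sample metadata.

    ``counts``: DataFrame, rows = OTU ids, columns = sample ids.
    ``otu_meta``: indexed by OTU id; must carry ``copy_number`` for QMP.
    ``sample_meta``: indexed by sample id; ``sample_type`` distinguishes
    experimental samples from blanks/controls.
    """

    counts: pd.DataFrame
    otu_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        c = self.counts
        if (c.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")
        if not np.array_equal(c.to_numpy(), np.asarray(c, dtype=float).round()):
            raise ValueError("read counts must be integers")
        self.counts = c.astype(int)
        if self.otu_meta.empty:
            self.otu_meta = pd.DataFrame(index=c.index)
        if self.sample_meta.empty:
            self.sample_meta = pd.DataFrame(
                {"sample_type": "experimental"}, index=c.columns
            )

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_otus(self, otus) -> "CountTable":
        return replace(
            self, counts=self.counts.loc[otus], otu_meta=self.otu_meta.loc[otus]
        )

    def subset_samples(self, samples) -> "CountTable":
        return replace(
            self,
            counts=self.counts[samples],
            sample_meta=self.sample_meta.loc[samples],
        )


@dataclass
class QMPTable:
    """OTU x sample absolute abundances (cells/mL) with provenance."""

    abundance: pd.DataFrame
    rarefaction_depth: int | None = None
    seed: int | None = None
    copy_number_source: str = "metadata"

    def column_totals(self) -> pd.Series:
        return self.abundance.sum(axis=0)


def filter_otus(table: CountTable) -> CountTable:
    """Standard OTU quality-control filters, applied in order:

    1. singletons (one read in the whole table),
    2. prevalence < 5% of samples,
    3. total reads <= 0.5 x number of samples.

    Idempotent; never removes samples or alters retained counts.
    """
    if table.n_samples < 1:
        raise ValueError("table has no samples")
    c = table.counts
    n = table.n_samples
    keep = c.sum(axis=1) != 1
    c = c.loc[keep]
    keep = (c > 0).sum(axis=1) >= 0.05 * n
    c = c.loc[keep]
    keep = c.sum(axis=1) > 0.5 * n
    c = c.loc[keep]
    return table.subset_otus(c.index)


def flag_low_depth_samples(
    table: CountTable, blank_max_reads: int | None = None
) -> tuple[CountTable, list[str]]:
    """Drop experimental samples whose total reads fall in the blank range.

    The threshold defaults to the maximum total read count over blank and
    negative-control samples; an experimental sample at or below it is
    removed and reported.
    """
    totals = table.sample_totals()
    types = table.sample_meta["sample_type"]
    if blank_max_reads is None:
        blanks = types[types.isin(["blank", "negative"])].index
        if len(blanks) == 0:
            raise ValueError(
                "no blank/negative samples present and no explicit threshold given"
            )
        blank_max_reads = int(totals[blanks].max())
    is_exp = types == "experimental"
    removed = totals.index[(totals <= blank_max_reads) & is_exp].tolist()
    kept = [s for s in table.counts.columns if s not in removed]
    return table.subset_samples(kept), removed


def rarefy(table: CountTable, depth: int | None = None, seed: int = 0) -> CountTable:
    """Subsample each sample to even ``depth`` reads without replacement.

    Default depth is the minimum sample total.  Uses a multivariate
    hypergeometric draw per sample (exact without-replacement sampling) from
    a generator seeded by ``seed``; the result is deterministic per seed.
    """
    totals = table.sample_totals()
    if depth is None:
        depth = int(totals.min())
    too_shallow = totals.index[totals < depth].tolist()
    if too_shallow:
        raise ValueError(
            f"samples shallower than rarefaction depth {depth}: {too_shallow}"
        )
    rng = np.random.default_rng(seed)
    out = {}
    for s in table.counts.columns:
        out[s] = rng.multivariate_hypergeometric(
            table.counts[s].to_numpy(), depth
        )
    rarefied = pd.DataFrame(out, index=table.counts.index)
    return replace(table, counts=rarefied)


def rarefaction_curve(
    sample_counts: np.ndarray, depths: list[int]
) -> np.ndarray:
    """Analytic expected OTU richness at each subsampling depth.

    ``E[S(d)] = sum_i (1 - C(N-N_i, d)/C(N, d))`` for a sample with counts
    ``N_i`` totalling ``N`` — the mean over all without-replacement
    subsamples of size ``d``.
    """
    counts = np.asarray(sample_counts, dtype=float)
    counts = counts[counts > 0]
    n_total = counts.sum()
    out = []
    for d in depths:
        if d > n_total:
            raise ValueError(f"depth {d} exceeds sample total {int(n_total)}")
        # log C(N-Ni, d) - log C(N, d); impossible draws contribute 0 prob
        rem = n_total - counts
        ok = rem >= d
        logp = np.full(counts.shape, -np.inf)
        logp[ok] = (
            gammaln(rem[ok] + 1) - gammaln(d + 1) - gammaln(rem[ok] - d + 1)
            - (gammaln(n_total + 1) - gammaln(d + 1) - gammaln(n_total - d + 1))
        )
        out.append(float(np.sum(1.0 - np.exp(logp))))
    return np.asarray(out)


def copy_number_correct(
    counts: pd.DataFrame, copy_numbers: pd.Series
) -> pd.DataFrame:
    """Convert reads to cell proportions by dividing out 16S copy numbers.

    ``weight_i = reads_i / copy_number_i`` per sample, renormalised to 1.
    Missing or sub-unit copy numbers raise — no silent default.
    """
    missing = counts.index.difference(copy_numbers.index)
    if len(missing):
        raise ValueError(f"missing copy numbers for OTUs: {missing.tolist()}")
    cn = copy_numbers.loc[counts.index].astype(float)
    if (cn < 1).any():
        raise ValueError("copy numbers must be >= 1")
    w = counts.div(cn, axis=0)
    colsum = w.sum(axis=0)
    if (colsum <= 0).any():
        empty = colsum.index[colsum <= 0].tolist()
        raise ValueError(f"samples with zero corrected weight: {empty}")
    return w.div(colsum, axis=1)


def build_qmp(
    proportions: pd.DataFrame,
    total_cells_per_mL: pd.Series,
    rarefaction_depth: int | None = None,
    seed: int | None = None,
) -> QMPTable:
    """Scale per-sample cell proportions by total cell concentrations.

    Column sums of the result equal the cytometry totals by construction
    (asserted to 1e-9 relative).
    """
    missing = proportions.columns.difference(total_cells_per_mL.index)
    extra = total_cells_per_mL.index.difference(proportions.columns)
    if len(missing) or len(extra):
        raise ValueError(
            "sample sets differ between proportions and cell totals: "
            f"missing totals for {missing.tolist()}, unmatched totals {extra.tolist()}"
        )
    colsum = proportions.sum(axis=0)
    if not np.allclose(colsum, 1.0, rtol=1e-6):
        raise ValueError("proportions must sum to 1 per sample")
    totals = total_cells_per_mL.loc[proportions.columns].astype(float)
    qmp = proportions.mul(totals, axis=1)
    assert np.allclose(qmp.sum(axis=0), totals, rtol=1e-9)
    return QMPTable(qmp, rarefaction_depth=rarefaction_depth, seed=seed)
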