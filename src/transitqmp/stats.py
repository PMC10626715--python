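"""Non-parametric statistical battery with the study's correction conventions.

Group comparisons across transit arms use Kruskal-Wallis followed by
pairwise two-sided Mann-Whitney rank-sum tests with Holm correction and a
compact letter display; proximal-vs-distal contrasts use paired two-sided
Wilcoxon signed-rank tests.  Feature-wise families are corrected with
Benjamini-Hochberg.  Exact small-sample enumeration is used where feasible
(rank tests at small n without ties; Spearman for n <= 9), otherwise the
tie-corrected large-sample approximations.

Note on naming: an "unpaired Wilcoxon signed rank test" is a contradiction
in terms; the unpaired member of the Wilcoxon family is the rank-sum
(Mann-Whitney) test, which is what ``rank_sum_unpaired`` computes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "kruskal_wallis",
    "rank_sum_unpaired",
    "signed_rank_paired",
    "holm_adjust",
    "bh_adjust",
    "spearman",
    "exclude_absent_donors",
    "compact_letters",
    "pairwise_rank_sum",
]


@dataclass
class TestResult:
    statistic: float
    p_raw: float
    method: str
    n_per_group: tuple[int, ...]
    p_adjusted: float | None = None
    undefined: bool = False
    letters: dict[str, str] | None = field(default=None, repr=False)


def kruskal_wallis(groups: list[np.ndarray]) -> TestResult:
    """Kruskal-Wallis H test (tie-corrected, chi-square p with k-1 df)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group needs at least one observation")
    if np.ptp(np.concatenate(arrays)) == 0:
        # all observations identical: H = 0 by convention
        return TestResult(0.0, 1.0, "kruskal-wallis",
                          tuple(len(a) for a in arrays))
    h, p = sps.kruskal(*arrays)
    return TestResult(float(h), float(p), "kruskal-wallis",
                      tuple(len(a) for a in arrays))


def rank_sum_unpaired(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Two-sided Mann-Whitney rank-sum test.

    Exact enumeration when n_x + n_y <= 12 and there are no ties; otherwise
    the tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 12 and no_ties) else "asymptotic"
    u, p = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(float(u), float(min(p, 1.0)), f"rank-sum ({method})",
                      (len(x), len(y)))


def signed_rank_paired(
    x: np.ndarray, y: np.ndarray, zero_method: str = "wilcox"
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped by default (``zero_method='wilcox'``;
    Pratt's treatment available).  Exact when n <= 15 after zero removal and
    the absolute differences are untied.  If every difference is zero the
    test is undefined and flagged rather than given a p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    d = x - y
    nz = d[d != 0]
    if len(nz) == 0:
        return TestResult(float("nan"), float("nan"),
                          "signed-rank (all differences zero)",
                          (len(x), len(y)), undefined=True)
    no_ties = len(np.unique(np.abs(nz))) == len(nz)
    method = "exact" if (len(nz) <= 15 and no_ties) else "approx"
    w, p = sps.wilcoxon(
        x, y, zero_method=zero_method, alternative="two-sided", method=method
    )
    return TestResult(float(w), float(p), f"signed-rank ({method})",
                      (len(x), len(y)))


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment, monotone and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, monotone, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p for Spearman's rho by full enumeration."""
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rxc = rx - rx.mean()
    ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum(axis=1))
    rhos = (ryc @ rxc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Spearman rank correlation on average ranks.

    p by exhaustive permutation enumeration for n <= 9, else the
    t-approximation.  Constant input yields an undefined flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(float("nan"), float("nan"), "spearman (constant input)",
                          (len(x),), undefined=True)
    rho, p_approx = sps.spearmanr(x, y)
    if len(x) <= 9:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        p = _exact_spearman_p(rx, ry, float(rho))
        return TestResult(float(rho), p, "spearman (exact)", (len(x),))
    return TestResult(float(rho), float(p_approx), "spearman (t-approx)", (len(x),))


def exclude_absent_donors(
    abundance: pd.Series,
    metadata: pd.DataFrame,
    mode: str = "strict",
) -> list[str]:
    """Donors retained for a taxon-specific transit comparison.

    ``abundance`` is the taxon's abundance per sample (index = sample ids);
    ``metadata`` carries ``donor`` and ``arm`` per sample.  Under the strict
    rule (default) a donor is kept only if the taxon is detected (> 0) in at
    least one sample of *every* arm; ``mode='lenient'`` keeps a donor with
    detection in at least one arm.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError("mode must be 'strict' or 'lenient'")
    df = metadata[["donor", "arm"]].copy()
    df["present"] = abundance.reindex(df.index).to_numpy() > 0
    arms = df["arm"].unique()
    kept = []
    for donor, grp in df.groupby("donor"):
        by_arm = grp.groupby("arm")["present"].any()
        present_arms = int(by_arm.reindex(arms, fill_value=False).sum())
        if mode == "strict" and present_arms == len(arms):
            kept.append(donor)
        elif mode == "lenient" and present_arms >= 1:
            kept.append(donor)
    return kept


def compact_letters(
    pairwise_adjusted_p: dict[tuple[str, str], float],
    groups: list[str],
    alpha: float = 0.05,
) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Two groups share a letter iff their (adjusted) comparison is
    non-significant at ``alpha``.  Inconsistent closures (A=B, B=C, A!=C)
    yield multi-letter labels.
    """
    pmap = {}
    for (a, b), p in pairwise_adjusted_p.items():
        pmap[frozenset((a, b))] = p
    for a, b in itertools.combinations(groups, 2):
        if frozenset((a, b)) not in pmap:
            raise ValueError(f"missing pairwise comparison ({a}, {b})")
    sets: list[set[str]] = [set(groups)]
    for a, b in itertools.combinations(groups, 2):
        if pmap[frozenset((a, b))] < alpha:
            for s in [s for s in sets if a in s and b in s]:
                sets.remove(s)
                for reduced in (s - {a}, s - {b}):
                    if reduced and not any(reduced <= t for t in sets):
                        sets.append(reduced)
    # absorb subsets, then order letters by first member appearance
    sets = [s for s in sets if not any(s < t for t in sets)]
    order = {g: i for i, g in enumerate(groups)}
    sets.sort(key=lambda s: min(order[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, sets):
        for g in s:
            out[g] += letter
    return {g: "".join(sorted(v)) for g, v in out.items()}


def pairwise_rank_sum(
    values: np.ndarray,
    labels: np.ndarray,
    adjust: str = "holm",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """All pairwise rank-sum tests between factor levels, adjusted, with CLD.

    Returns (one row per pair with statistic/p_raw/p_adjusted, letter map).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    levels = list(pd.unique(labels))
    rows = []
    for a, b in itertools.combinations(levels, 2):
        res = rank_sum_unpaired(values[labels == a], values[labels == b])
        rows.append({"group1": a, "group2": b,
                     "statistic": res.statistic, "p_raw": res.p_raw,
                     "method": res.method})
    df = pd.DataFrame(rows)
    adjuster = holm_adjust if adjust == "holm" else bh_adjust
    df["p_adjusted"] = adjuster(df["p_raw"].to_numpy())
    letters = compact_letters(
        {(r["group1"], r["group2"]): r["p_adjusted"] for _, r in df.iterrows()},
        levels, alpha=alpha,
    )
    return df, letters
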