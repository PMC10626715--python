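"""Bray-Curtis ordination and distance-based variance partitioning.

``bray_curtis`` and ``pcoa`` provide the unconstrained view of community
dissimilarity.  ``DBRDA`` is a statsmodels-style model object: constrained
ordination of a dissimilarity matrix obtained by regressing its principal
coordinates on a dummy-coded explanatory factor, optionally partialling out
covariate factors.  Explained fractions are reported raw (constrained
inertia / total positive inertia) and bias-corrected with Ezekiel's
adjustment; for partial models the covariate-adjusted fraction is obtained
subtractively, ``adjR2(X|Z) = adjR2(X+Z) - adjR2(Z)``.  Significance comes
from label permutation (free, or restricted within covariate strata).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .stats import holm_adjust

__all__ = [
    "bray_curtis",
    "PCoAResult",
    "pcoa",
    "adjusted_r2",
    "DBRDA",
    "DBRDAResults",
    "variance_partition",
]


def bray_curtis(abundance: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples (rows).

    ``d(x, y) = sum|x_i - y_i| / sum(x_i + y_i)``; abundances must be
    non-negative and no sample may be all-zero.
    """
    a = abundance.to_numpy(dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    zero = abundance.index[a.sum(axis=1) == 0].tolist()
    if zero:
        raise ValueError(f"all-zero samples cannot be compared: {zero}")
    d = squareform(pdist(a, metric="braycurtis"))
    return pd.DataFrame(d, index=abundance.index, columns=abundance.index)


@dataclass
class PCoAResult:
    """Principal coordinates: samples x positive axes, plus all eigenvalues
    (negative ones reported but excluded from the coordinates)."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    @property
    def total_inertia(self) -> float:
        return float(self.eigenvalues[self.eigenvalues > 0].sum())


def _gower_center(D: np.ndarray) -> np.ndarray:
    a = -0.5 * D**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _check_distance(D: pd.DataFrame) -> np.ndarray:
    arr = D.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    return arr


def pcoa(D: pd.DataFrame, correction: str | None = None) -> PCoAResult:
    """Classical (Gower) principal coordinates analysis.

    Eigendecomposes the double-centred ``-D^2/2``; coordinates are
    eigenvectors scaled by sqrt(eigenvalue) for positive eigenvalues only.
    ``correction='lingoes'`` adds the constant making all eigenvalues
    non-negative before decomposition (off by default; negative eigenvalues
    are simply reported).
    """
    arr = _check_distance(D)
    G = _gower_center(arr)
    eigvals, eigvecs = np.linalg.eigh(G)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    if correction == "lingoes" and eigvals[-1] < 0:
        c = -eigvals[-1]
        d2 = arr**2 + 2 * c
        np.fill_diagonal(d2, 0.0)
        G = _gower_center(np.sqrt(d2))
        eigvals, eigvecs = np.linalg.eigh(G)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals).max(), 1.0) * 1e-10
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    total = eigvals[pos].sum()
    return PCoAResult(
        coordinates=pd.DataFrame(
            coords, index=D.index,
            columns=[f"PCo{i + 1}" for i in range(pos.sum())],
        ),
        eigenvalues=eigvals,
        proportion_explained=np.where(pos, eigvals / total, 0.0)[pos],
    )


def adjusted_r2(r2_raw: float, n_samples: int, n_constraint_df: int) -> float:
    """Ezekiel's adjustment: ``1 - (1 - R2)(n-1)/(n-m-1)``.

    NaN when the residual degrees of freedom vanish.
    """
    if n_samples <= n_constraint_df + 1:
        return float("nan")
    if n_constraint_df == 0:
        return 0.0
    return 1.0 - (1.0 - r2_raw) * (n_samples - 1) / (n_samples - n_constraint_df - 1)


def _design_matrix(design: pd.DataFrame, factors: list[str]) -> np.ndarray:
    """Centred treatment-contrast dummy matrix for the listed factors."""
    if not factors:
        return np.empty((len(design), 0))
    blocks = []
    for f in factors:
        col = design[f]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 8:
            m = col.to_numpy(dtype=float)[:, None]
        else:
            m = pd.get_dummies(col.astype("category"), drop_first=True).to_numpy(
                dtype=float
            )
        blocks.append(m)
    X = np.hstack(blocks)
    return X - X.mean(axis=0, keepdims=True)


def _fit_r2(Y: np.ndarray, X: np.ndarray, total: float) -> tuple[float, np.ndarray]:
    """R2 of the projection of Y onto span(X) plus the fitted matrix."""
    if X.shape[1] == 0:
        return 0.0, np.zeros_like(Y)
    Q, R = np.linalg.qr(X)
    keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(np.diag(R)).max())
    Q = Q[:, keep]
    fitted = Q @ (Q.T @ Y)
    return float((fitted**2).sum() / total), fitted


@dataclass
class DBRDAResults:
    """Fit results of a (partial) distance-based redundancy analysis."""

    constraint: str
    covariates: tuple[str, ...]
    r2_raw: float
    r2_adjusted: float
    p_perm: float
    canonical_proportions: tuple[float, ...]
    n_samples: int
    df_constraint: int
    df_covariates: int
    n_perm: int
    seed: int
    p_holm: float | None = None

    def summary(self) -> str:
        lines = [
            "db-RDA (Bray-Curtis principal coordinates response)",
            f"  constraint:  {self.constraint} (df={self.df_constraint})",
            f"  covariates:  {', '.join(self.covariates) or 'none'} "
            f"(df={self.df_covariates})",
            f"  n samples:   {self.n_samples}",
            f"  R2 (raw):    {self.r2_raw:.4f}",
            f"  R2 (adj):    {self.r2_adjusted:.4f}",
            f"  perm p:      {self.p_perm:.4g}  ({self.n_perm} permutations, "
            f"seed {self.seed})",
            "  canonical axis fractions: "
            + ", ".join(f"{v:.3f}" for v in self.canonical_proportions[:2]),
        ]
        return "\n".join(lines)


class DBRDA:
    """Distance-based redundancy analysis model.

    Parameters
    ----------
    distance : square symmetric DataFrame of dissimilarities.
    design : per-sample factor table aligned with ``distance``.
    constraint : name of the explanatory factor.
    covariates : factors to partial out before testing the constraint.
    """

    def __init__(
        self,
        distance: pd.DataFrame,
        design: pd.DataFrame,
        constraint: str,
        covariates: tuple[str, ...] | list[str] = (),
    ):
        _check_distance(distance)
        if not distance.index.equals(design.index):
            design = design.loc[distance.index]
        for f in [constraint, *covariates]:
            if f not in design.columns:
                raise ValueError(f"factor {f!r} not in design")
            if design[f].isna().any():
                raise ValueError(f"factor {f!r} has missing values")
        self.distance = distance
        self.design = design
        self.constraint = constraint
        self.covariates = tuple(covariates)
        self._pcoa = pcoa(distance)
        X = _design_matrix(design, [constraint])
        Z = _design_matrix(design, list(self.covariates))
        both = np.hstack([Z, X])
        rank = np.linalg.matrix_rank
        if Z.shape[1] and rank(both) < rank(Z) + rank(X):
            raise ValueError(
                f"constraint {constraint!r} is collinear with covariates "
                f"{self.covariates}; fit separate models instead"
            )
        self._X, self._Z = X, Z

    def fit(self, n_perm: int = 999, seed: int = 0) -> DBRDAResults:
        if n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        Y = self._pcoa.coordinates.to_numpy()
        total = self._pcoa.total_inertia
        X, Z = self._X, self._Z
        r2_z, fitted_z = _fit_r2(Y, Z, total)
        r2_full, _ = _fit_r2(Y, np.hstack([Z, X]), total)
        r2_sp = r2_full - r2_z
        n = Y.shape[0]
        m_x = np.linalg.matrix_rank(X) if X.shape[1] else 0
        m_z = np.linalg.matrix_rank(Z) if Z.shape[1] else 0
        r2_adj = adjusted_r2(r2_full, n, m_x + m_z) - adjusted_r2(r2_z, n, m_z)
        # a covariate set fitting worse than chance has a negative adjusted
        # fraction; keep the semipartial fraction within its raw ceiling
        r2_adj = min(r2_adj, r2_sp)
        # canonical axes of the constrained (covariate-residualised) fit
        Yr = Y - fitted_z
        Xr = X
        if Z.shape[1]:
            _, fz = _fit_r2(X, Z, max((X**2).sum(), 1e-300))
            Xr = X - fz
        _, fitted_c = _fit_r2(Yr, Xr, total)
        sv = np.linalg.svd(fitted_c, compute_uv=False)
        can = (sv**2) / total
        # permutation test on the semipartial fraction
        rng = np.random.default_rng(seed)
        strata = (
            self.design[list(self.covariates)].astype(str).agg("|".join, axis=1)
            if self.covariates
            else pd.Series("all", index=self.design.index)
        )
        groups = [np.flatnonzero(strata.to_numpy() == g) for g in strata.unique()]
        count = 0
        for _ in range(n_perm):
            perm = np.arange(n)
            for g in groups:
                perm[g] = g[rng.permutation(len(g))]
            Xp = X[perm]
            r2_full_p, _ = _fit_r2(Y, np.hstack([Z, Xp]), total)
            if r2_full_p - r2_z >= r2_sp - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
        return DBRDAResults(
            constraint=self.constraint,
            covariates=self.covariates,
            r2_raw=r2_sp,
            r2_adjusted=r2_adj,
            p_perm=p,
            canonical_proportions=tuple(can[:2]),
            n_samples=n,
            df_constraint=m_x,
            df_covariates=m_z,
            n_perm=n_perm,
            seed=seed,
        )


def variance_partition(
    distance: pd.DataFrame,
    design: pd.DataFrame,
    models: dict[str, list[str]],
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-factor db-RDA fractions across one or more model families.

    ``models`` maps a model name to its factor list; each factor is tested
    as the constraint with the remaining factors of its model as covariates.
    Holm correction is applied across the whole family of permutation
    p-values.  Collinear factor pairs (e.g. donor and a donor-level trait)
    must be placed in separate models.
    """
    rows = []
    for k, (model_name, factors) in enumerate(models.items()):
        for j, factor in enumerate(factors):
            covs = [f for f in factors if f != factor]
            res = DBRDA(distance, design, factor, covs).fit(
                n_perm=n_perm, seed=seed + 1000 * k + j
            )
            rows.append(
                {"model": model_name, "factor": factor,
                 "covariates": "+".join(covs),
                 "R2_raw": res.r2_raw, "R2_adjusted": res.r2_adjusted,
                 "p_perm": res.p_perm, "df": res.df_constraint,
                 "n_perm": n_perm}
            )
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_perm"].to_numpy())
    return out
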