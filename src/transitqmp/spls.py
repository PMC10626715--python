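"""Sparse partial least squares (sPLS) microbe-metabolite integration.

Links absolute taxon abundances (X) to net metabolite production rates (Y)
in regression mode.  Each component extracts a pair of weight vectors
maximising the X'Y cross-covariance by NIPALS power iteration, with sparsity
imposed by soft-thresholding that retains the ``keep_x`` (``keep_y``)
largest-magnitude entries; both matrices are then deflated on the X-scores.
With all variables kept the model coincides with dense PLS regression.

``tune_spls`` selects the number of components and per-component sparsity by
cross-validated correlation with a one-standard-error rule, and
``relevance_network`` extracts the taxon-metabolite association graph from
the bilinear reconstruction of the fitted components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SPLS", "SPLSResults", "RelevanceNetwork", "tune_spls", "relevance_network"]


def _soft_threshold_topk(w: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold keeping the ``keep`` largest |entries|."""
    if keep >= len(w):
        return w.copy()
    cut = np.sort(np.abs(w))[::-1][keep]
    out = np.sign(w) * np.maximum(np.abs(w) - cut, 0.0)
    return out


@dataclass
class SPLSResults:
    """Fitted sPLS model: weights, scores and regression coefficients.

    Weight vectors (``x_weights``, ``y_weights``) are unit-norm with at most
    ``keep_x[h]`` / ``keep_y[h]`` nonzero entries per component.
    ``coefficients`` maps standardised X to standardised Y.
    """

    x_names: list[str]
    y_names: list[str]
    n_components: int
    keep_x: tuple[int, ...]
    keep_y: tuple[int, ...]
    x_weights: pd.DataFrame
    y_weights: pd.DataFrame
    x_loadings: pd.DataFrame
    x_scores: np.ndarray
    y_scores: np.ndarray
    coefficients: pd.DataFrame
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray
    n_iter: tuple[int, ...]
    x_std: np.ndarray = None  # standardised (undeflated) data, for networks
    y_std: np.ndarray = None

    def selected_x(self, component: int | None = None) -> list[str]:
        """X variables with a nonzero weight (in one or any component)."""
        w = self.x_weights
        if component is None:
            mask = (w != 0).any(axis=1)
        else:
            mask = w.iloc[:, component] != 0
        return w.index[mask].tolist()

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        Xs = (X[self.x_names].to_numpy(dtype=float) - self.x_mean) / self.x_scale
        Ys = Xs @ self.coefficients.to_numpy()
        return pd.DataFrame(
            Ys * self.y_scale + self.y_mean, index=X.index, columns=self.y_names
        )

    def summary(self) -> str:
        lines = [
            f"sPLS regression: {len(self.x_names)} X vars -> "
            f"{len(self.y_names)} Y vars, {self.n_components} components",
            f"  keepX per component: {self.keep_x}",
            f"  keepY per component: {self.keep_y}",
        ]
        for h in range(self.n_components):
            sel = self.selected_x(h)
            shown = ", ".join(sel[:6]) + ("..." if len(sel) > 6 else "")
            lines.append(f"  comp {h + 1}: {len(sel)} X selected ({shown})")
        return "\n".join(lines)


class SPLS:
    """Sparse PLS model in regression mode.

    Parameters
    ----------
    X, Y : DataFrames (samples x variables).  Columns are centred and
        scaled to unit variance internally; ``log10_x=True`` additionally
        applies log10(x+1) first (appropriate for cell concentrations
        spanning orders of magnitude).
    n_components : number of latent components.
    keep_x, keep_y : ints or per-component sequences of retained variable
        counts (defaults: all).
    """

    def __init__(
        self,
        X: pd.DataFrame,
        Y: pd.DataFrame,
        n_components: int = 2,
        keep_x: int | list[int] | None = None,
        keep_y: int | list[int] | None = None,
        log10_x: bool = False,
        max_iter: int = 500,
        tol: float = 1e-9,
    ):
        if len(X) != len(Y):
            raise ValueError("X and Y must have the same number of samples")
        if len(X) < n_components + 2:
            raise ValueError("need at least n_components + 2 samples")
        Xv = X.astype(float)
        if log10_x:
            Xv = np.log10(Xv + 1.0)
        # drop zero-variance features with a warning
        keep_cols = Xv.std(axis=0, ddof=1) > 0
        if not keep_cols.all():
            dropped = Xv.columns[~keep_cols].tolist()
            warnings.warn(f"dropping zero-variance X columns: {dropped}",
                          stacklevel=2)
            Xv = Xv.loc[:, keep_cols]
        self.X = Xv
        self.Y = Y.astype(float)
        self.n_components = n_components
        p, q = Xv.shape[1], Y.shape[1]

        def _expand(k, limit, name):
            if k is None:
                return (limit,) * n_components
            ks = [k] * n_components if np.isscalar(k) else list(k)
            if len(ks) != n_components:
                raise ValueError(f"{name} must have one entry per component")
            out = []
            for v in ks:
                if v > limit:
                    warnings.warn(
                        f"{name}={v} exceeds available variables ({limit}); clipped",
                        stacklevel=3,
                    )
                out.append(min(int(v), limit))
            return tuple(out)

        self.keep_x = _expand(keep_x, p, "keep_x")
        self.keep_y = _expand(keep_y, q, "keep_y")
        self.max_iter = max_iter
        self.tol = tol

    def fit(self) -> SPLSResults:
        X = self.X.to_numpy(dtype=float)
        Y = self.Y.to_numpy(dtype=float)
        x_mean, x_scale = X.mean(axis=0), X.std(axis=0, ddof=1)
        y_mean, y_scale = Y.mean(axis=0), Y.std(axis=0, ddof=1)
        y_scale = np.where(y_scale > 0, y_scale, 1.0)
        Xd = (X - x_mean) / x_scale
        Yd = (Y - y_mean) / y_scale
        n, p = Xd.shape
        q = Yd.shape[1]
        H = self.n_components
        U = np.zeros((p, H))
        V = np.zeros((q, H))
        P = np.zeros((p, H))
        C = np.zeros((q, H))
        T = np.zeros((n, H))
        S = np.zeros((n, H))
        iters = []
        for h in range(H):
            M = Xd.T @ Yd
            if not np.any(M):
                warnings.warn(f"no remaining covariance at component {h + 1}",
                              stacklevel=2)
                iters.append(0)
                continue
            # initialise from the dominant singular pair
            _, _, vt = np.linalg.svd(M, full_matrices=False)
            v = vt[0]
            u = np.zeros(p)
            it = 0
            for it in range(1, self.max_iter + 1):
                u_new = _soft_threshold_topk(M @ v, self.keep_x[h])
                nrm = np.linalg.norm(u_new)
                if nrm == 0:  # threshold removed everything; keep top-1
                    u_new = _soft_threshold_topk(M @ v, 1)
                    nrm = np.linalg.norm(u_new)
                u_new /= nrm
                v_new = _soft_threshold_topk(M.T @ u_new, self.keep_y[h])
                v_new /= np.linalg.norm(v_new)
                if np.linalg.norm(u_new - u) < self.tol:
                    u, v = u_new, v_new
                    break
                u, v = u_new, v_new
            iters.append(it)
            t = Xd @ u
            tt = t @ t
            s = Yd @ v
            pl = Xd.T @ t / tt
            c = Yd.T @ t / tt
            Xd = Xd - np.outer(t, pl)
            Yd = Yd - np.outer(t, c)
            U[:, h], V[:, h], P[:, h], C[:, h], T[:, h], S[:, h] = u, v, pl, c, t, s
        # regression coefficients on the standardised scale
        PW = P.T @ U
        B = U @ np.linalg.pinv(PW) @ C.T
        comps = [f"comp{h + 1}" for h in range(H)]
        xn, yn = list(self.X.columns), list(self.Y.columns)
        return SPLSResults(
            x_names=xn, y_names=yn, n_components=H,
            keep_x=self.keep_x, keep_y=self.keep_y,
            x_weights=pd.DataFrame(U, index=xn, columns=comps),
            y_weights=pd.DataFrame(V, index=yn, columns=comps),
            x_loadings=pd.DataFrame(P, index=xn, columns=comps),
            x_scores=T, y_scores=S,
            coefficients=pd.DataFrame(B, index=xn, columns=yn),
            x_mean=x_mean, x_scale=x_scale, y_mean=y_mean, y_scale=y_scale,
            n_iter=tuple(iters),
            x_std=(X - x_mean) / x_scale,
            y_std=(Y - y_mean) / y_scale,
        )


def tune_spls(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    keepX_grid: list[int],
    ncomp_max: int = 3,
    n_folds: int = 5,
    seed: int = 0,
    log10_x: bool = False,
) -> tuple[int, tuple[int, ...], pd.DataFrame]:
    """Choose (n_components, keepX) by cross-validated correlation.

    For each grid point the mean correlation between predicted and held-out
    Y is estimated by k-fold CV; the smallest keepX (then fewest components)
    whose mean lies within one standard error of the best is selected.
    Returns (n_components, keepX per component, full CV table).
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    n = len(X)
    rng = np.random.default_rng(seed)
    for attempt in range(10):
        idx = rng.permutation(n)
        folds = np.array_split(idx, n_folds)
        ok = all(
            Y.iloc[np.concatenate([f for j, f in enumerate(folds) if j != i])]
            .std(axis=0).gt(0).all()
            for i in range(n_folds)
        )
        if ok:
            break
        warnings.warn("zero-variance training fold; reshuffling", stacklevel=2)
    rows = []
    for ncomp in range(1, ncomp_max + 1):
        for keepx in keepX_grid:
            cors = []
            for i in range(n_folds):
                test = folds[i]
                train = np.concatenate([f for j, f in enumerate(folds) if j != i])
                model = SPLS(
                    X.iloc[train], Y.iloc[train], n_components=ncomp,
                    keep_x=keepx, log10_x=log10_x,
                )
                res = model.fit()
                pred = res.predict(X.iloc[test])
                fold_cors = []
                for col in Y.columns:
                    yt = Y[col].iloc[test].to_numpy()
                    yp = pred[col].to_numpy()
                    if np.std(yt) > 0 and np.std(yp) > 0:
                        fold_cors.append(np.corrcoef(yt, yp)[0, 1])
                if fold_cors:
                    cors.append(float(np.mean(fold_cors)))
            mean = float(np.mean(cors))
            se = float(np.std(cors, ddof=1) / np.sqrt(len(cors)))
            rows.append({"ncomp": ncomp, "keepX": keepx, "cv_cor": mean, "se": se})
    table = pd.DataFrame(rows)
    best = table.loc[table["cv_cor"].idxmax()]
    threshold = best["cv_cor"] - best["se"]
    candidates = table[table["cv_cor"] >= threshold]
    chosen = candidates.sort_values(["keepX", "ncomp"]).iloc[0]
    ncomp = int(chosen["ncomp"])
    return ncomp, (int(chosen["keepX"]),) * ncomp, table


@dataclass
class RelevanceNetwork:
    """Bipartite taxon-metabolite association graph."""

    edges: pd.DataFrame  # columns: taxon, metabolite, weight
    threshold: float


def relevance_network(
    results: SPLSResults, threshold: float = 0.55
) -> RelevanceNetwork:
    """Taxon-metabolite similarities from the bilinear reconstruction.

    ``sim(i, j) = sum_h cor(x_i, t_h) * cor(y_j, t_h)`` over the fitted
    components, clipped to [-1, 1]; edges with |sim| >= ``threshold`` among
    the selected X variables are retained.  Raising the threshold never adds
    edges.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    T = results.x_scores
    H = T.shape[1]

    def _cors(mat: np.ndarray) -> np.ndarray:
        out = np.zeros((mat.shape[1], H))
        for h in range(H):
            t = T[:, h]
            sd_t = np.std(t)
            if sd_t == 0:
                continue
            tc = (t - t.mean()) / sd_t
            sd_m = mat.std(axis=0)
            mc = (mat - mat.mean(axis=0)) / np.where(sd_m > 0, sd_m, 1.0)
            out[:, h] = mc.T @ tc / len(t)
        return out

    cx = _cors(results.x_std)
    cy = _cors(results.y_std)
    sim = np.clip(cx @ cy.T, -1.0, 1.0)
    selected = set(results.selected_x())
    rows = []
    for i, taxon in enumerate(results.x_names):
        if taxon not in selected:
            continue
        for j, met in enumerate(results.y_names):
            if abs(sim[i, j]) >= threshold:
                rows.append({"taxon": taxon, "metabolite": met,
                             "weight": float(sim[i, j])})
    edges = pd.DataFrame(rows, columns=["taxon", "metabolite", "weight"])
    return RelevanceNetwork(edges=edges, threshold=threshold)
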