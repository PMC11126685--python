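"""Sparse partial least squares discriminant analysis (sPLS-DA) from scratch.

X is the column-centered, unit-variance-scaled species x family count matrix;
Y is a centered/scaled two-column class indicator (one column per group).
Each component is the dominant singular pair of X_h^T Y_h obtained by power
iteration, with the X weight soft-thresholded so that exactly ``keepX``
features keep a non-zero loading (order-statistic lambda; ties broken by
ascending feature order), then re-normalized.  X is deflated by regressing it
on the component score (regression mode); Y is not deflated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SplsdaParams", "SplsdaModel", "fit_splsda", "explained_variance", "top_contributors"]


@dataclass
class SplsdaParams:
    n_components: int = 2
    keepX: int | list[int] = 100
    max_iter: int = 500
    tol: float = 1e-9
    log1p: bool = False
    y_coding: str = "indicator"  # or "pm_one" (single +/-1 column; K=2 only)

    def keepx_for(self, h: int) -> int:
        if isinstance(self.keepX, int):
            return self.keepX
        return self.keepX[h]


@dataclass
class SplsdaModel:
    params: SplsdaParams
    features: list[str]
    species: list[str]
    loadings: np.ndarray  # (n_features, n_components), unit-norm sparse columns
    scores: np.ndarray  # (n_species, n_components)
    selected: list[list[str]]  # per component
    x_mean: np.ndarray
    x_scale: np.ndarray
    explained_variance_x: np.ndarray = field(default=None)
    explained_variance_y: np.ndarray = field(default=None)
    group_of: dict = field(default_factory=dict)

    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.loadings,
            index=self.features,
            columns=[f"comp{h + 1}" for h in range(self.loadings.shape[1])],
        )

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores,
            index=self.species,
            columns=[f"comp{h + 1}" for h in range(self.scores.shape[1])],
        )


def _scale_columns(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    scale = np.where(sd > 0, sd, 1.0)  # zero-variance columns stay (centered) zero
    return (M - mean) / scale, mean, scale


def _soft_threshold_keepx(w: np.ndarray, keepx: int) -> np.ndarray:
    """Keep exactly ``keepx`` entries of largest |w| (ties -> lowest index),
    soft-thresholded by the (keepx+1)-th largest absolute value."""
    p = len(w)
    if keepx >= p:
        return w.copy()
    order = np.lexsort((np.arange(p), -np.abs(w)))  # |w| desc, index asc
    kept = order[:keepx]
    lam = np.abs(w[order[keepx]])
    out = np.zeros_like(w)
    out[kept] = np.sign(w[kept]) * np.maximum(np.abs(w[kept]) - lam, 0.0)
    # entries tied with lambda would vanish; keep them at a small magnitude so
    # the support stays exactly keepx (tie-break already fixed by the lexsort)
    zeroed = kept[(out[kept] == 0.0) & (np.abs(w[kept]) > 0.0)]
    if zeroed.size:
        nz = np.abs(out[out != 0.0])
        fill = float(nz.min()) / 2.0 if nz.size else 1.0
        out[zeroed] = np.sign(w[zeroed]) * fill
    return out


def fit_splsda(
    matrix: pd.DataFrame,
    groups: pd.Series,
    params: SplsdaParams | None = None,
) -> SplsdaModel:
    """Fit sPLS-DA of the (filtered) count matrix against focal/other labels."""
    params = params or SplsdaParams()
    groups = groups.reindex(matrix.index).dropna()
    matrix = matrix.loc[groups.index]
    classes = sorted(groups.unique())
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    if min((groups == c).sum() for c in classes) < 2:
        raise ValueError("each class needs at least two species")
    X0 = matrix.to_numpy(dtype=float)
    if params.log1p:
        X0 = np.log1p(X0)
    X, x_mean, x_scale = _scale_columns(X0)
    nonconstant = X0.std(axis=0, ddof=1) > 0
    if params.y_coding == "indicator":
        Y0 = np.column_stack([(groups == c).to_numpy(dtype=float) for c in classes])
    elif params.y_coding == "pm_one":
        Y0 = ((groups == classes[0]).to_numpy(dtype=float) * 2.0 - 1.0)[:, None]
    else:
        raise ValueError(f"unknown y_coding {params.y_coding!r}")
    Y, _, _ = _scale_columns(Y0)

    n, p = X.shape
    ncomp = params.n_components
    loadings = np.zeros((p, ncomp))
    scores = np.zeros((n, ncomp))
    selected: list[list[str]] = []
    Xh = X.copy()
    for h in range(ncomp):
        keepx = params.keepx_for(h)
        if keepx > p:
            warnings.warn(f"keepX={keepx} exceeds feature count {p}; clipped")
            keepx = p
        if keepx < 1:
            raise ValueError("keepX must be >= 1")
        M = Xh.T @ Y  # p x q
        v = M.sum(axis=0)
        nv = np.linalg.norm(v)
        if nv == 0:
            v = np.ones(M.shape[1])
            nv = np.linalg.norm(v)
        v = v / nv
        w = np.zeros(p)
        converged = False
        for it in range(params.max_iter):
            w_new = M @ v
            w_new[~nonconstant] = 0.0  # zero-variance features keep zero loading
            w_new = _soft_threshold_keepx(w_new, keepx)
            nw = np.linalg.norm(w_new)
            if nw == 0:
                raise ValueError("all X weights vanished; is X constant?")
            w_new /= nw
            v_new = M.T @ w_new
            nv = np.linalg.norm(v_new)
            if nv == 0:
                raise ValueError("Y weight vanished during power iteration")
            v_new /= nv
            if np.linalg.norm(w_new - w) < params.tol:
                w, v = w_new, v_new
                converged = True
                break
            w, v = w_new, v_new
        if not converged:
            raise RuntimeError(
                f"power iteration did not converge in {params.max_iter} iterations "
                f"on component {h + 1}"
            )
        t = Xh @ w
        tt = float(t @ t)
        if tt == 0:
            raise ValueError("zero score vector; X has no variance left")
        loadings[:, h] = w
        scores[:, h] = t
        sel = np.flatnonzero(w != 0)
        selected.append([matrix.columns[j] for j in sel])
        Xh = Xh - np.outer(t, (t @ Xh) / tt)

    model = SplsdaModel(
        params=params,
        features=list(matrix.columns),
        species=list(matrix.index),
        loadings=loadings,
        scores=scores,
        selected=selected,
        x_mean=x_mean,
        x_scale=x_scale,
        group_of=dict(groups),
    )
    model.explained_variance_x = explained_variance(model, X)
    model.explained_variance_y = explained_variance(model, Y)
    return model


def explained_variance(model: SplsdaModel, X: np.ndarray) -> np.ndarray:
    """Per-component fractions of ||X||_F^2 captured by the component scores.

    Scores are Gram-Schmidt-orthogonalized in fit order and X (the undeflated
    scaled matrix) is projected on each in turn.
    """
    X = np.asarray(X, dtype=float)
    total = float((X**2).sum())
    if total == 0:
        raise ValueError("X is identically zero")
    fracs = []
    basis: list[np.ndarray] = []
    for h in range(model.scores.shape[1]):
        t = model.scores[:, h].copy()
        for b in basis:
            t -= (t @ b) * b
        norm = np.linalg.norm(t)
        if norm < 1e-12:
            fracs.append(0.0)
            continue
        t /= norm
        basis.append(t)
        proj = t @ X  # row vector of projection coefficients
        fracs.append(float((proj**2).sum()) / total)
    return np.asarray(fracs)


def top_contributors(model: SplsdaModel, component: int = 0, k: int = 100) -> list[str]:
    """Families ranked by |loading| (descending) on a component; ties by id."""
    if k <= 0:
        raise ValueError("k must be positive")
    w = model.loadings[:, component]
    nz = np.flatnonzero(w != 0)
    if k > len(nz):
        raise ValueError(f"k={k} exceeds the {len(nz)} selected features")
    feats = sorted(
        ((model.features[j], abs(w[j])) for j in nz),
        key=lambda fa: (-fa[1], fa[0]),
    )
    return [f for f, _ in feats[:k]]
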