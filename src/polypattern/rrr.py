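"""Reduced rank regression (RRR) and variable importance in projection (VIP).

RRR finds linear combinations of predictors that maximize the explained
variance of the responses.  After columnwise standardization of X (n x p)
and Y (n x q), the rank-K solution is ``B_K = B_OLS V_K V_K'`` where the
columns of ``V_K`` are the top-K eigenvectors of ``Yhat' Yhat`` with
``Yhat = X B_OLS``.  The factor weights ``w_k`` are the unit-normalized
columns of ``B_OLS V_K``; pattern scores are projections of standardized
predictors on the weights.  With a single response (q = 1) the rank-1
direction is proportional to the OLS coefficient vector, so RRR scores are
perfectly correlated with OLS fitted values.

The per-predictor VIP is

    VIP_j = sqrt( p * sum_k R2_k w_jk^2 / sum_k R2_k ),

with ``R2_k`` the fraction of (standardized) response variance explained by
factor k and ``||w_k|| = 1``; consequently ``sum_j VIP_j^2 = p``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd


class RRRError(ValueError):
    pass


@dataclass
class RRRModel:
    """Fitted reduced-rank-regression model (weights are p x K, unit-norm
    columns; x/y standardization parameters are stored for out-of-sample
    scoring)."""

    weights: np.ndarray
    response_loadings: np.ndarray
    explained_share: np.ndarray
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: np.ndarray
    y_scale: np.ndarray
    rank: int
    predictor_names: list[str]
    response_names: list[str]

    def coefficients(self) -> np.ndarray:
        """Rank-K coefficient matrix B_K (standardized scale), p x q."""
        return self.weights @ self.response_loadings

    def to_json(self, path) -> None:
        payload = {
            "weights": self.weights.tolist(),
            "response_loadings": self.response_loadings.tolist(),
            "explained_share": self.explained_share.tolist(),
            "x_center": self.x_center.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_center": self.y_center.tolist(),
            "y_scale": self.y_scale.tolist(),
            "rank": self.rank,
            "predictor_names": self.predictor_names,
            "response_names": self.response_names,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RRRModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            response_loadings=np.asarray(d["response_loadings"], dtype=float),
            explained_share=np.asarray(d["explained_share"], dtype=float),
            x_center=np.asarray(d["x_center"], dtype=float),
            x_scale=np.asarray(d["x_scale"], dtype=float),
            y_center=np.asarray(d["y_center"], dtype=float),
            y_scale=np.asarray(d["y_scale"], dtype=float),
            rank=int(d["rank"]),
            predictor_names=list(d["predictor_names"]),
            response_names=list(d["response_names"]),
        )


@dataclass
class VIPTable:
    """Per-predictor VIP scores; mean(VIP^2) = 1 by construction."""

    vip: pd.Series
    model_rank: int


def _as_matrix(A, what: str) -> tuple[np.ndarray, list[str]]:
    if isinstance(A, pd.DataFrame):
        return A.to_numpy(dtype=float), list(A.columns)
    if isinstance(A, pd.Series):
        return A.to_numpy(dtype=float)[:, None], [A.name or what]
    arr = np.asarray(A, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"{what}{j + 1}" for j in range(arr.shape[1])]


def _standardize(A: np.ndarray, what: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = A.mean(axis=0)
    scale = A.std(axis=0, ddof=1)
    if (scale == 0).any():
        bad = list(np.flatnonzero(scale == 0))
        raise RRRError(f"zero-variance {what} columns at positions {bad}")
    return (A - center) / scale, center, scale


def fit_rrr(X, Y, rank: int | None = None) -> RRRModel:
    """Fit reduced rank regression of Y on X at the requested rank.

    Both sides are standardized to zero mean and unit variance first, so
    weights and VIP are scale-free.  Each weight vector is oriented so its
    largest-magnitude entry is positive; eigenvalue ties are broken by
    column index order.
    """
    Xa, x_names = _as_matrix(X, "x")
    Ya, y_names = _as_matrix(Y, "y")
    n, p = Xa.shape
    q = Ya.shape[1]
    if Ya.shape[0] != n:
        raise RRRError(f"X has {n} rows but Y has {Ya.shape[0]}")
    if rank is None:
        rank = min(p, q)
    if rank < 1 or rank > min(p, q):
        raise RRRError(f"rank must be in [1, {min(p, q)}], got {rank}")
    if np.isnan(Xa).any() or np.isnan(Ya).any():
        raise RRRError("X and Y must be complete (no NaN)")
    Xs, x_center, x_scale = _standardize(Xa, "predictor")
    Ys, y_center, y_scale = _standardize(Ya, "response")
    if n <= p:
        raise RRRError(f"need n > p for the OLS step (n={n}, p={p})")
    XtX = Xs.T @ Xs
    cond = np.linalg.cond(XtX)
    if not np.isfinite(cond) or cond > 1e12:
        raise RRRError(
            "X'X is singular or near-singular; drop collinear predictors or "
            "add a ridge upstream"
        )
    B_ols = np.linalg.solve(XtX, Xs.T @ Ys)  # p x q
    Yhat = Xs @ B_ols
    M = Yhat.T @ Yhat  # q x q
    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(-evals, kind="stable")
    evals = np.maximum(evals[order], 0.0)
    V = evecs[:, order][:, :rank]  # q x K
    lam = evals[:rank]

    A = B_ols @ V  # p x K, X-side directions
    norms = np.linalg.norm(A, axis=0)
    if (norms == 0).any():
        # a factor with zero X-side direction explains nothing; keep the
        # direction as e_1 with zero loading so shapes stay consistent
        for k in np.flatnonzero(norms == 0):
            A[0, k] = 1.0
        norms = np.linalg.norm(A, axis=0)
    W = A / norms
    # response loadings such that B_K = W @ L
    L = norms[:, None] * V.T  # K x q
    # deterministic sign: largest-|w| entry positive
    for k in range(rank):
        j = int(np.argmax(np.abs(W[:, k])))
        if W[j, k] < 0:
            W[:, k] = -W[:, k]
            L[k, :] = -L[k, :]
    total_yss = float(np.sum(Ys**2))
    share = lam / total_yss if total_yss > 0 else np.zeros(rank)
    return RRRModel(
        weights=W,
        response_loadings=L,
        explained_share=share,
        x_center=x_center,
        x_scale=x_scale,
        y_center=y_center,
        y_scale=y_scale,
        rank=rank,
        predictor_names=x_names,
        response_names=y_names,
    )


def score(model: RRRModel, X_new) -> np.ndarray:
    """Pattern scores for new subjects using the model's stored
    standardization and weights; nothing is re-estimated from ``X_new``."""
    Xa, names = _as_matrix(X_new, "x")
    if isinstance(X_new, pd.DataFrame):
        if list(X_new.columns) != model.predictor_names:
            missing = [c for c in model.predictor_names if c not in X_new.columns]
            extra = [c for c in X_new.columns if c not in model.predictor_names]
            raise RRRError(
                f"predictor columns mismatch (missing {missing}, unexpected {extra})"
            )
    elif Xa.shape[1] != len(model.predictor_names):
        raise RRRError(
            f"expected {len(model.predictor_names)} predictor columns, got {Xa.shape[1]}"
        )
    Xs = (Xa - model.x_center) / model.x_scale
    return Xs @ model.weights


def vip_scores(model: RRRModel) -> VIPTable:
    """Variable importance in projection for every predictor."""
    r2 = model.explained_share
    total = float(r2.sum())
    if total <= 0:
        raise RRRError("zero explained variance: VIP undefined")
    p = model.weights.shape[0]
    vip = np.sqrt(p * (model.weights**2 @ r2) / total)
    return VIPTable(
        vip=pd.Series(vip, index=model.predictor_names, name="vip"),
        model_rank=model.rank,
    )
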