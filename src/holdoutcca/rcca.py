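"""Regularized canonical correlation analysis.

The solver finds weight vectors u, v maximizing the correlation between
the paired scores Xu and Yv under ridge-type shrinkage of the within-set
covariances: each C is replaced by (1 - c) C + c I with c in [0, 1]. At
c -> 0 this is classical CCA; at c = 1 the within-set metric is the
identity and the solution reduces to the singular vectors of the
cross-covariance (the PLS limit). Weights are normalized so that
u' ((1-c) C_xx + c I) u = 1 on the training covariance.

The solve goes through the whitened cross-covariance
W_x C_xy W_y with W = ((1-c) C + c I)^(-1/2), computed by symmetric
eigendecomposition with an eigenvalue floor. The problem sizes this
package targets (p ~ 148, q ~ 68) make this primal formulation cheap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "RCCAModel",
    "Scores",
    "fit_rcca",
    "project",
    "canonical_correlation",
    "compute_loadings",
    "deflate",
    "fit_deflation",
    "apply_deflation",
    "save_model",
    "load_model",
]

_EIG_FLOOR = 1e-12


@dataclass
class Scores:
    x_scores: np.ndarray  # (n, K)
    y_scores: np.ndarray  # (n, K)


@dataclass
class RCCAModel:
    c_x: float
    c_y: float
    u: np.ndarray                 # (p, K)
    v: np.ndarray                 # (q, K)
    train_cancorrs: np.ndarray    # (K,) Pearson correlations of training scores
    n_train: int
    x_names: list[str] | None = None
    y_names: list[str] | None = None


def _check_matrix(A: np.ndarray, name: str) -> np.ndarray:
    A = np.asarray(A, float)
    if A.ndim != 2:
        raise ValueError(f"{name} must be 2-D")
    if not np.all(np.isfinite(A)):
        raise ValueError(f"non-finite values in {name}")
    return A


def _inv_sqrt(M: np.ndarray) -> np.ndarray:
    """Symmetric inverse square root with eigenvalue floor."""
    w, Q = np.linalg.eigh(M)
    w = np.maximum(w, _EIG_FLOOR)
    return (Q / np.sqrt(w)) @ Q.T


def regularized_whitener(C: np.ndarray, c: float) -> np.ndarray:
    """W = ((1 - c) C + c I)^(-1/2)."""
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"regularization level {c} outside [0, 1]")
    R = (1.0 - c) * C + c * np.eye(len(C))
    return _inv_sqrt(R)


def _solve_from_cross_cov(
    W_x: np.ndarray, W_y: np.ndarray, C_xy: np.ndarray, K: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD of the whitened cross-covariance; shared by fit and permutation refits."""
    M = W_x @ C_xy @ W_y
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    u = W_x @ U[:, :K]
    v = W_y @ Vt[:K].T
    return u, v, s[:K]


def fit_rcca(
    X_train: np.ndarray,
    Y_train: np.ndarray,
    c_x: float,
    c_y: float,
    K: int = 1,
    x_names: list[str] | None = None,
    y_names: list[str] | None = None,
) -> RCCAModel:
    """Fit regularized CCA on (standardized) training rows.

    Sample covariances use denominator n - 1; on standardized inputs they
    are correlation matrices. Components are ordered by nonincreasing
    training canonical correlation (Pearson correlation of score pairs).
    """
    X = _check_matrix(X_train, "X_train")
    Y = _check_matrix(Y_train, "Y_train")
    if len(X) != len(Y):
        raise ValueError("X and Y row counts differ")
    n, p = X.shape
    q = Y.shape[1]
    if not 1 <= K <= min(p, q):
        raise ValueError(f"K={K} must lie in [1, min(p, q)={min(p, q)}]")
    if n < 3:
        raise ValueError("need at least 3 training rows")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    C_xx = (Xc.T @ Xc) / (n - 1)
    C_yy = (Yc.T @ Yc) / (n - 1)
    C_xy = (Xc.T @ Yc) / (n - 1)
    W_x = regularized_whitener(C_xx, c_x)
    W_y = regularized_whitener(C_yy, c_y)
    u, v, _ = _solve_from_cross_cov(W_x, W_y, C_xy, K)
    # training canonical correlations and ordering by them
    sx, sy = Xc @ u, Yc @ v
    corrs = np.array(
        [_pearson(sx[:, k], sy[:, k]) for k in range(K)]
    )
    order = np.argsort(-corrs, kind="stable")
    return RCCAModel(
        c_x=c_x,
        c_y=c_y,
        u=u[:, order],
        v=v[:, order],
        train_cancorrs=corrs[order],
        n_train=n,
        x_names=x_names,
        y_names=y_names,
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("undefined correlation: constant score vector")
    return float(((a - a.mean()) @ (b - b.mean())) / (len(a) * sa * sb))


def project(model: RCCAModel, X: np.ndarray, Y: np.ndarray) -> Scores:
    """Project new data onto fitted weights (Xu, Yv); no refitting."""
    X = _check_matrix(X, "X")
    Y = _check_matrix(Y, "Y")
    problems = []
    if X.shape[1] != model.u.shape[0]:
        problems.append(
            f"X has {X.shape[1]} columns, model expects {model.u.shape[0]}"
            + (f" ({model.x_names})" if model.x_names else "")
        )
    if Y.shape[1] != model.v.shape[0]:
        problems.append(
            f"Y has {Y.shape[1]} columns, model expects {model.v.shape[0]}"
            + (f" ({model.y_names})" if model.y_names else "")
        )
    if problems:
        raise ValueError("; ".join(problems))
    return Scores(X @ model.u, Y @ model.v)


def canonical_correlation(scores: Scores, k: int = 0) -> float:
    """Pearson correlation of the k-th score pair."""
    if len(scores.x_scores) < 3:
        raise ValueError("need at least 3 rows")
    return _pearson(scores.x_scores[:, k], scores.y_scores[:, k])


def compute_loadings(original_data: np.ndarray, score: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation of the original variables with a score.

    Zero-variance columns yield NaN (flagged as undefined) rather than an
    error, since a single degenerate variable should not abort a run.
    """
    Xd = _check_matrix(np.atleast_2d(np.asarray(original_data, float).T).T, "data")
    s = np.asarray(score, float).ravel()
    if len(Xd) != len(s):
        raise ValueError("row counts differ")
    sc = s - s.mean()
    ss = np.linalg.norm(sc)
    if ss == 0:
        raise ValueError("undefined loadings: constant score vector")
    Xc = Xd - Xd.mean(axis=0)
    norms = np.linalg.norm(Xc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (Xc.T @ sc) / (norms * ss)
    out[norms == 0] = np.nan
    return out


def fit_deflation(data: np.ndarray, score: np.ndarray) -> tuple[np.ndarray, float]:
    """Regression slopes of each column on a score (for projection deflation).

    Returns ``(beta, score_mean)``; both are training-estimated and must be
    reused unchanged when deflating out-of-sample rows.
    """
    s = np.asarray(score, float).ravel()
    s_mean = float(s.mean())
    sc = s - s_mean
    denom = sc @ sc
    if denom == 0:
        raise ValueError("zero-norm score; cannot deflate")
    Xd = _check_matrix(data, "data")
    return (Xd.T @ sc) / denom, s_mean


def apply_deflation(
    data: np.ndarray, score: np.ndarray, beta: np.ndarray, score_mean: float
) -> np.ndarray:
    """Remove the score's fitted contribution from every column."""
    Xd = _check_matrix(data, "data")
    s = np.asarray(score, float).ravel()
    return Xd - np.outer(s - score_mean, beta)


def deflate(
    X: np.ndarray, Y: np.ndarray, scores: Scores, k: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Projection deflation: residualize X on x_scores[:, k] and Y on y_scores[:, k].

    Slopes are estimated on the given rows; for out-of-sample rows use
    :func:`fit_deflation` on training rows followed by
    :func:`apply_deflation`.
    """
    bx, mx = fit_deflation(X, scores.x_scores[:, k])
    by, my = fit_deflation(Y, scores.y_scores[:, k])
    return (
        apply_deflation(X, scores.x_scores[:, k], bx, mx),
        apply_deflation(Y, scores.y_scores[:, k], by, my),
    )


def save_model(model: RCCAModel, path: str | Path) -> None:
    """Serialize a fitted model to a structured text (JSON) file."""
    payload = {
        "c_x": model.c_x,
        "c_y": model.c_y,
        "u": model.u.tolist(),
        "v": model.v.tolist(),
        "train_cancorrs": model.train_cancorrs.tolist(),
        "n_train": model.n_train,
        "x_names": model.x_names,
        "y_names": model.y_names,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> RCCAModel:
    d = json.loads(Path(path).read_text())
    return RCCAModel(
        c_x=d["c_x"],
        c_y=d["c_y"],
        u=np.asarray(d["u"], float),
        v=np.asarray(d["v"], float),
        train_cancorrs=np.asarray(d["train_cancorrs"], float),
        n_train=d["n_train"],
        x_names=d["x_names"],
        y_names=d["y_names"],
    )
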