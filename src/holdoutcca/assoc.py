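"""Subject-wise latent scores and rank-based external associations.

After the holdout framework has fitted one RCCA model per outer split,
every subject can be projected through each split's model (with that
split's training-estimated preprocessing). Averaging the sign-aligned
per-split scores gives a single composite score per subject and
dimension, which is then related to external variables — an inflammation
marker such as C-reactive protein, or demographics — with Spearman rank
correlation and Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .framework import LatentDimensionResult

__all__ = [
    "SubjectScores",
    "compute_subject_scores",
    "spearman_association",
    "risk_factor_correlation_matrix",
    "waist_to_hip_ratio",
]


@dataclass
class SubjectScores:
    """Per-subject composite scores for one latent dimension."""

    x_scores: np.ndarray  # (n,) brain-side, averaged across outer splits
    y_scores: np.ndarray  # (n,) risk-factor-side
    n_splits: int
    flips: np.ndarray


def compute_subject_scores(
    x_scores_per_split: list[np.ndarray],
    y_scores_per_split: list[np.ndarray],
    flips: np.ndarray,
) -> SubjectScores:
    """Average all-subject scores across outer splits after sign alignment.

    ``x_scores_per_split[s]`` holds every subject's brain-side score under
    split s's model (rows in original cohort order, preprocessing
    re-applied with that split's training-estimated parameters, as
    assembled by the sequential framework). The flips are the ones used
    for loading aggregation, so scores and loadings share an orientation.
    """
    if len(x_scores_per_split) != len(y_scores_per_split) or not x_scores_per_split:
        raise ValueError("need matched, nonempty per-split score lists")
    if len(flips) != len(x_scores_per_split):
        raise ValueError("missing alignment flip for a split")
    lengths = {len(v) for v in x_scores_per_split} | {len(v) for v in y_scores_per_split}
    if len(lengths) != 1:
        raise ValueError("per-split score vectors differ in length")
    Xs = np.vstack([f * np.asarray(v, float) for f, v in zip(flips, x_scores_per_split)])
    Ys = np.vstack([f * np.asarray(v, float) for f, v in zip(flips, y_scores_per_split)])
    return SubjectScores(Xs.mean(axis=0), Ys.mean(axis=0), len(flips), np.asarray(flips))


def scores_from_dimension(dim: LatentDimensionResult) -> SubjectScores:
    """Composite subject scores for a fitted dimension result."""
    flips = dim.flips if dim.flips is not None else np.ones(len(dim.models))
    return compute_subject_scores(
        dim.per_split_x_scores, dim.per_split_y_scores, flips
    )


def spearman_association(
    scores: np.ndarray,
    external: np.ndarray,
    n_comparisons: int = 1,
) -> tuple[float, float, float]:
    """Spearman rank correlation with Bonferroni-corrected analytic p.

    Ties are handled by midranks; the corrected p is
    ``min(1, n_comparisons * raw_p)``.
    """
    s = np.asarray(scores, float).ravel()
    e = np.asarray(external, float).ravel()
    if len(s) != len(e):
        raise ValueError("scores and external variable differ in length")
    if len(s) < 10:
        raise ValueError("need at least 10 pairs")
    if np.std(s) == 0 or np.std(e) == 0:
        raise ValueError("constant vector; Spearman correlation undefined")
    rho, p = spearmanr(s, e)
    return float(rho), float(p), min(1.0, n_comparisons * float(p))


def risk_factor_correlation_matrix(Y: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Symmetric Pearson intercorrelation matrix of the risk factors.

    Zero-variance columns get NaN rows/columns (flagged as undefined)
    rather than aborting; the diagonal is exactly 1 elsewhere.
    """
    if isinstance(Y, pd.DataFrame):
        names = list(Y.columns)
        A = Y.to_numpy(float)
    else:
        A = np.asarray(Y, float)
        names = [f"rf_{j:02d}" for j in range(A.shape[1])]
    if np.isnan(A).any():
        raise ValueError("missing values in risk-factor matrix")
    sd = A.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(A, rowvar=False)
    C[sd == 0, :] = np.nan
    C[:, sd == 0] = np.nan
    ok = sd > 0
    np.fill_diagonal(C, np.where(ok, 1.0, np.nan))
    return pd.DataFrame(C, index=names, columns=names)


def waist_to_hip_ratio(
    table: pd.DataFrame, waist_col: str = "waist", hip_col: str = "hip",
    out_col: str = "waist_to_hip_ratio",
) -> pd.DataFrame:
    """Derived variable: waist circumference divided by hip circumference."""
    for c in (waist_col, hip_col):
        if c not in table.columns:
            raise KeyError(f"column {c!r} not found")
    if (table[hip_col] <= 0).any():
        raise ValueError("nonpositive hip circumference")
    out = table.copy()
    out[out_col] = out[waist_col] / out[hip_col]
    return out
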