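"""Cross-validation-consistent preprocessing.

All transforms here follow the same contract: parameters are estimated on
training rows only and then applied unchanged to any partition (training,
test, or holdout), so no information leaks from evaluation rows into the
fitted model. The composition order used by the pipeline is fixed:
brain-size scaling -> confound removal -> standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Residualizer",
    "Standardizer",
    "brain_scaling",
    "fit_residualizer",
    "apply_residualizer",
    "standardize",
    "Preprocessor",
    "SingularDesignError",
]

SCALING_MODES = ("raw", "proportional", "corrected")


class SingularDesignError(ValueError):
    """Confound design matrix is rank deficient."""


def _build_design(
    confounds: pd.DataFrame, levels: dict[str, list] | None = None
) -> tuple[np.ndarray, list[str], dict[str, list]]:
    """Intercept + numeric columns + k-1 dummy columns per categorical.

    When ``levels`` is given (apply time) the categorical encoding of fit
    time is reused and unseen levels raise instead of extrapolating.
    """
    cols: list[np.ndarray] = [np.ones(len(confounds))]
    names = ["intercept"]
    fitted_levels: dict[str, list] = {}
    for name in confounds.columns:
        col = confounds[name]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            cols.append(col.to_numpy(float))
            names.append(name)
        elif pd.api.types.is_numeric_dtype(col):
            # binary numeric (e.g., sex coded 0/1): use as-is
            cols.append(col.to_numpy(float))
            names.append(name)
        else:
            if levels is not None:
                lv = levels[name]
                unseen = set(col.astype(str)) - set(lv)
                if unseen:
                    raise ValueError(
                        f"unseen level(s) {sorted(unseen)} in confound '{name}'"
                    )
            else:
                lv = sorted(col.astype(str).unique())
            fitted_levels[name] = lv
            for level in lv[1:]:  # drop first level
                cols.append((col.astype(str) == level).to_numpy(float))
                names.append(f"{name}[{level}]")
    return np.column_stack(cols), names, fitted_levels


@dataclass
class Residualizer:
    """Per-column OLS fit of the data on the confound design."""

    design_columns: list[str]
    coefficients: np.ndarray  # (n_design, n_targets)
    levels: dict[str, list]
    confound_names: list[str]


def fit_residualizer(
    train_data: np.ndarray | pd.DataFrame, train_confounds: pd.DataFrame
) -> Residualizer:
    """Estimate confound regression coefficients on training rows only."""
    Xd = np.asarray(train_data, float)
    if Xd.ndim == 1:
        Xd = Xd[:, None]
    D, names, levels = _build_design(train_confounds)
    if len(Xd) != len(D):
        raise ValueError("data and confounds row counts differ")
    if len(Xd) < D.shape[1] + 2:
        raise ValueError(
            f"need at least {D.shape[1] + 2} training rows for {D.shape[1]} design columns"
        )
    # scale-invariant rank check: unit-normalize columns first so a large-mean
    # covariate next to the intercept is not falsely flagged collinear
    Dn = D / np.linalg.norm(D, axis=0)
    rank = np.linalg.matrix_rank(Dn)
    if rank < D.shape[1]:
        # identify offending columns via pivoted QR on the design
        from scipy.linalg import qr

        _, r, piv = qr(Dn, mode="economic", pivoting=True)
        bad = [names[piv[j]] for j in range(rank, D.shape[1])]
        raise SingularDesignError(f"collinear confound design columns: {bad}")
    beta, *_ = np.linalg.lstsq(D, Xd, rcond=None)
    return Residualizer(names, beta, levels, list(train_confounds.columns))


def apply_residualizer(
    model: Residualizer, data: np.ndarray | pd.DataFrame, confounds: pd.DataFrame
) -> np.ndarray:
    """Return data minus the fitted confound contribution (row count preserved)."""
    Xd = np.asarray(data, float)
    if Xd.ndim == 1:
        Xd = Xd[:, None]
    if list(confounds.columns) != model.confound_names:
        raise ValueError(
            f"confound columns {list(confounds.columns)} do not match fitted "
            f"{model.confound_names}"
        )
    if Xd.shape[1] != model.coefficients.shape[1]:
        raise ValueError("data column count does not match the fitted model")
    D, _, _ = _build_design(confounds, levels=model.levels)
    return Xd - D @ model.coefficients


@dataclass
class Standardizer:
    mean: np.ndarray
    sd: np.ndarray
    columns: list[str] | None = None

    def transform(self, data: np.ndarray | pd.DataFrame) -> np.ndarray:
        Xd = np.asarray(data, float)
        if Xd.shape[-1] != len(self.mean):
            raise ValueError("column count does not match the fitted standardizer")
        return (Xd - self.mean) / self.sd


def standardize(
    train_data: np.ndarray | pd.DataFrame, *other_partitions
) -> tuple:
    """Z-score partitions with training-row means and SDs.

    Returns ``(train_z, *others_z, Standardizer)``. A zero-variance training
    column is an error naming the column.
    """
    cols = list(train_data.columns) if isinstance(train_data, pd.DataFrame) else None
    Xd = np.asarray(train_data, float)
    mu = Xd.mean(axis=0)
    sd = Xd.std(axis=0, ddof=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [cols[j] if cols else f"column {j}" for j in zero]
        raise ValueError(f"zero-variance training column(s): {names}")
    model = Standardizer(mu, sd, cols)
    out = [model.transform(Xd)]
    out.extend(model.transform(part) for part in other_partitions)
    return (*out, model)


def brain_scaling(
    brain: np.ndarray | pd.DataFrame,
    mode: str,
    global_reference: np.ndarray | None = None,
    residualizer: Residualizer | None = None,
) -> np.ndarray:
    """Raw / proportional / brain-size-corrected parcel measures.

    raw
        identity.
    proportional
        each subject's parcels divided by that subject's global reference
        (mean cortical thickness or total intracranial volume).
    corrected
        residual of each parcel on the global reference, using a
        residualizer fitted on training rows with the reference as the sole
        covariate (cross-validation-consistent brain-size correction).
    """
    Xd = np.asarray(brain, float)
    if mode not in SCALING_MODES:
        raise ValueError(f"unknown scaling mode {mode!r}; expected one of {SCALING_MODES}")
    if mode == "raw":
        return Xd
    if global_reference is None:
        raise ValueError(f"{mode} scaling requires a global reference vector")
    ref = np.asarray(global_reference, float).ravel()
    if len(ref) != len(Xd):
        raise ValueError("global reference length must equal the number of subjects")
    if mode == "proportional":
        if np.any(ref <= 0):
            raise ValueError("nonpositive global reference value")
        return Xd / ref[:, None]
    if residualizer is None:
        raise ValueError("corrected scaling requires a residualizer fitted on training rows")
    return apply_residualizer(model=residualizer, data=Xd, confounds=pd.DataFrame({"global_reference": ref}))


@dataclass
class Preprocessor:
    """Confound removal + standardization bundle, fitted on training rows.

    A thin convenience over :func:`fit_residualizer` and
    :func:`standardize` used by the holdout framework; ``transform`` can be
    applied to any partition with the training-estimated parameters.
    """

    confound_names: list[str] | None = None
    residualizer: Residualizer | None = field(default=None, init=False)
    standardizer: Standardizer | None = field(default=None, init=False)

    def fit(self, train_data, train_confounds: pd.DataFrame | None = None) -> "Preprocessor":
        Xd = np.asarray(train_data, float)
        if train_confounds is not None:
            self.residualizer = fit_residualizer(Xd, train_confounds)
            Xd = apply_residualizer(self.residualizer, Xd, train_confounds)
        *_, self.standardizer = standardize(Xd)
        return self

    def transform(self, data, confounds: pd.DataFrame | None = None) -> np.ndarray:
        Xd = np.asarray(data, float)
        if self.residualizer is not None:
            if confounds is None:
                raise ValueError("fitted with confounds; confounds required at transform time")
            Xd = apply_residualizer(self.residualizer, Xd, confounds)
        assert self.standardizer is not None, "fit() must be called first"
        return self.standardizer.transform(Xd)

    def fit_transform(self, train_data, train_confounds: pd.DataFrame | None = None) -> np.ndarray:
        self.fit(train_data, train_confounds)
        return self.transform(train_data, train_confounds)
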