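"""Multiple-holdout machine-learning framework around the RCCA solver.

Two nested levels of data splitting drive everything:

* the *outer* split separates the cohort into an optimization set and a
  holdout set; the holdout is touched only for statistical evaluation;
* the *inner* split divides the optimization set into training and test
  sets and drives hyperparameter selection.

Defaults follow the emulated design: 5 outer and 5 inner splits, each an
independent random 80/20 partition. A latent dimension is evaluated by
refitting on the full optimization set with the selected regularization,
projecting the holdout, and comparing the holdout canonical correlation
against 1,000 refits on row-shuffled Y (raw p = (1 + #{null >= observed})
/ n_perm, Bonferroni-corrected over the five outer splits). The omnibus
null — no effect in any split — is rejected as soon as one corrected p
falls below alpha; a significant dimension's variance is removed by
projection deflation and the next dimension is sought.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .preprocess import Preprocessor
from .rcca import (
    RCCAModel,
    Scores,
    _pearson,
    _solve_from_cross_cov,
    apply_deflation,
    canonical_correlation,
    compute_loadings,
    fit_deflation,
    fit_rcca,
    project,
    regularized_whitener,
)

__all__ = [
    "SplitScheme",
    "SelectionResult",
    "EvaluationResult",
    "AggregatedLoadings",
    "LatentDimensionResult",
    "SequentialResult",
    "make_splits",
    "weight_stability",
    "select_hyperparameters",
    "evaluate_dimension",
    "aggregate_loadings",
    "run_sequential_dimensions",
]


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


@dataclass
class SplitScheme:
    """Outer optimization/holdout and inner training/test assignments.

    ``outer[s]`` is ``(opt_idx, hold_idx)`` over all subjects;
    ``inner[s][i]`` is ``(train_pos, test_pos)`` given as positions within
    ``opt_idx`` of outer split ``s``.
    """

    outer: list[tuple[np.ndarray, np.ndarray]]
    inner: list[list[tuple[np.ndarray, np.ndarray]]]
    holdout_frac: float
    test_frac: float
    seed: int

    @property
    def n_outer(self) -> int:
        return len(self.outer)

    @property
    def n_inner(self) -> int:
        return len(self.inner[0]) if self.inner else 0


def _stratified_partition(
    n: int,
    frac_second: float,
    labels: np.ndarray | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Random two-way partition; with labels, proportions held within +-1."""
    if labels is None:
        perm = rng.permutation(n)
        n_second = int(round(n * frac_second))
        if n_second == 0 or n_second == n:
            raise ValueError("partition fractions leave an empty set")
        return np.sort(perm[n_second:]), np.sort(perm[:n_second])
    labels = np.asarray(labels)
    first, second = [], []
    strata = [np.flatnonzero(labels == lv) for lv in pd.unique(labels)]
    if any(len(s) < 2 for s in strata):
        raise ValueError("stratification infeasible: a stratum has fewer than 2 subjects")
    targets = [len(s) * frac_second for s in strata]
    base = [int(np.floor(t)) for t in targets]
    deficit = int(round(n * frac_second)) - sum(base)
    order = np.argsort([-(t - b) for t, b in zip(targets, base)], kind="stable")
    take = list(base)
    for j in order[:deficit]:
        take[j] += 1
    for s_idx, k in zip(strata, take):
        perm = rng.permutation(s_idx)
        second.append(perm[:k])
        first.append(perm[k:])
    first_idx = np.sort(np.concatenate(first))
    second_idx = np.sort(np.concatenate(second))
    if len(first_idx) == 0 or len(second_idx) == 0:
        raise ValueError("partition fractions leave an empty set")
    return first_idx, second_idx


def make_splits(
    n_subjects: int,
    n_outer: int = 5,
    n_inner: int = 5,
    holdout_frac: float = 0.2,
    test_frac: float = 0.2,
    stratify_by: np.ndarray | None = None,
    seed: int = 0,
) -> SplitScheme:
    """Seeded random outer/inner splits (independent repetitions, not folds)."""
    if not (0 < holdout_frac < 1 and 0 < test_frac < 1):
        raise ValueError("fractions must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = None if stratify_by is None else np.asarray(stratify_by)
    if labels is not None and len(labels) != n_subjects:
        raise ValueError("stratify_by length must equal n_subjects")
    outer, inner = [], []
    for _ in range(n_outer):
        opt_idx, hold_idx = _stratified_partition(n_subjects, holdout_frac, labels, rng)
        outer.append((opt_idx, hold_idx))
        opt_labels = None if labels is None else labels[opt_idx]
        splits_s = []
        for _ in range(n_inner):
            train_pos, test_pos = _stratified_partition(
                len(opt_idx), test_frac, opt_labels, rng
            )
            splits_s.append((train_pos, test_pos))
        inner.append(splits_s)
    return SplitScheme(outer, inner, holdout_frac, test_frac, seed)


# ---------------------------------------------------------------------------
# stability and selection
# ---------------------------------------------------------------------------


def weight_stability(weight_vectors: list[np.ndarray]) -> float:
    """Mean absolute pairwise Pearson correlation of weight vectors.

    The absolute value absorbs the sign indeterminacy of CCA solutions.
    """
    vecs = [np.asarray(w, float).ravel() for w in weight_vectors]
    if len(vecs) < 2:
        raise ValueError("need at least 2 weight vectors")
    if len({len(v) for v in vecs}) != 1:
        raise ValueError("weight vectors must have equal length")
    vals = [abs(_pearson(a, b)) for a, b in combinations(vecs, 2)]
    return float(np.mean(vals))


@dataclass
class SelectionResult:
    grid: list
    mean_test_corr: np.ndarray   # per candidate
    stability: np.ndarray        # per candidate
    rank_sum: np.ndarray
    chosen: float | tuple[float, float]
    chosen_index: int


def _candidate_cs(candidate) -> tuple[float, float]:
    if np.isscalar(candidate):
        return float(candidate), float(candidate)
    cx, cy = candidate
    return float(cx), float(cy)


def select_hyperparameters(
    X_opt: np.ndarray,
    Y_opt: np.ndarray,
    grid: list,
    inner_splits: list[tuple[np.ndarray, np.ndarray]],
    confounds: pd.DataFrame | None = None,
    K: int = 1,
) -> SelectionResult:
    """Pick the regularization level by test correlation plus weight stability.

    For every candidate, an RCCA is fitted on each inner training set
    (preprocessing — standardization and, when confounds are supplied,
    confound regression — refitted on those rows only) and scored by the
    inner-test canonical correlation of the first component. Stability is
    the mean absolute pairwise correlation of the fitted weights across
    inner splits, averaged over the two sides. Candidates are ranked on
    both criteria (descending) and the minimal rank sum wins; ties go to
    the more regularized candidate.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    X_opt = np.asarray(X_opt, float)
    Y_opt = np.asarray(Y_opt, float)
    conf = confounds.reset_index(drop=True) if confounds is not None else None
    mean_corr = np.full(len(grid), -np.inf)
    stab = np.full(len(grid), -np.inf)
    any_ok = False
    for ci, cand in enumerate(grid):
        cx, cy = _candidate_cs(cand)
        corrs, us, vs = [], [], []
        try:
            for train_pos, test_pos in inner_splits:
                if conf is not None:
                    px = Preprocessor().fit(X_opt[train_pos], conf.iloc[train_pos])
                    py = Preprocessor().fit(Y_opt[train_pos], conf.iloc[train_pos])
                    Xtr = px.transform(X_opt[train_pos], conf.iloc[train_pos])
                    Xte = px.transform(X_opt[test_pos], conf.iloc[test_pos])
                    Ytr = py.transform(Y_opt[train_pos], conf.iloc[train_pos])
                    Yte = py.transform(Y_opt[test_pos], conf.iloc[test_pos])
                else:
                    px = Preprocessor().fit(X_opt[train_pos])
                    py = Preprocessor().fit(Y_opt[train_pos])
                    Xtr, Xte = px.transform(X_opt[train_pos]), px.transform(X_opt[test_pos])
                    Ytr, Yte = py.transform(Y_opt[train_pos]), py.transform(Y_opt[test_pos])
                model = fit_rcca(Xtr, Ytr, cx, cy, K=K)
                corrs.append(canonical_correlation(project(model, Xte, Yte), 0))
                us.append(model.u[:, 0])
                vs.append(model.v[:, 0])
        except (ValueError, np.linalg.LinAlgError):
            continue
        mean_corr[ci] = np.mean(corrs)
        stab[ci] = 0.5 * (weight_stability(us) + weight_stability(vs))
        any_ok = True
    if not any_ok:
        raise RuntimeError("all hyperparameter candidates failed to fit")
    rank_corr = rankdata(-mean_corr, method="min")
    rank_stab = rankdata(-stab, method="min")
    rank_sum = rank_corr + rank_stab
    best = np.flatnonzero(rank_sum == rank_sum.min())
    # ties broken toward the larger (more regularized) candidate
    key = [sum(_candidate_cs(grid[i])) for i in best]
    chosen_index = int(best[int(np.argmax(key))])
    return SelectionResult(
        grid=list(grid),
        mean_test_corr=mean_corr,
        stability=stab,
        rank_sum=rank_sum.astype(float),
        chosen=grid[chosen_index],
        chosen_index=chosen_index,
    )


# ---------------------------------------------------------------------------
# permutation evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvaluationResult:
    holdout_corr: float
    raw_p: float
    corrected_p: float
    model: RCCAModel
    n_perm: int
    n_null_ge: int


def evaluate_dimension(
    X_opt: np.ndarray,
    Y_opt: np.ndarray,
    X_hold: np.ndarray,
    Y_hold: np.ndarray,
    c_x: float,
    c_y: float,
    n_perm: int = 1000,
    seed: int = 0,
    n_bonferroni: int = 5,
) -> EvaluationResult:
    """Permutation test of the first holdout canonical correlation.

    Refits RCCA with the given regularization on the optimization set and
    projects the holdout; the observed statistic is the (signed) first
    holdout canonical correlation. Each permutation shuffles the rows of Y
    independently within the optimization and holdout sets, refits on the
    permuted optimization set and projects the permuted holdout. Row
    shuffling leaves the within-set covariances (and any row-wise
    preprocessing) unchanged, so the refit reuses the whitening transforms
    and recomputes only the cross-covariance — algebraically identical to
    a full refit. raw p = (1 + #{null >= observed}) / n_perm, then
    Bonferroni over the outer splits. Inputs are expected preprocessed
    with optimization-set-estimated parameters.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-value resolution is 1/{n_perm}")
    X_opt = np.asarray(X_opt, float)
    Y_opt = np.asarray(Y_opt, float)
    X_hold = np.asarray(X_hold, float)
    Y_hold = np.asarray(Y_hold, float)
    model = fit_rcca(X_opt, Y_opt, c_x, c_y, K=1)
    observed = canonical_correlation(project(model, X_hold, Y_hold), 0)

    n = len(X_opt)
    Xc = X_opt - X_opt.mean(axis=0)
    Yc = Y_opt - Y_opt.mean(axis=0)
    W_x = regularized_whitener((Xc.T @ Xc) / (n - 1), c_x)
    W_y = regularized_whitener((Yc.T @ Yc) / (n - 1), c_y)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm_opt = rng.permutation(n)
        perm_hold = rng.permutation(len(Y_hold))
        try:
            C_xy = (Xc.T @ Yc[perm_opt]) / (n - 1)
            u, v, _ = _solve_from_cross_cov(W_x, W_y, C_xy, 1)
            null_scores = Scores(X_hold @ u, Y_hold[perm_hold] @ v)
            null_corr = canonical_correlation(null_scores, 0)
        except (ValueError, np.linalg.LinAlgError):
            n_ge += 1  # conservative: failed refit counted against the alternative
            continue
        if null_corr >= observed:
            n_ge += 1
    raw_p = (1 + n_ge) / n_perm
    corrected_p = min(1.0, n_bonferroni * raw_p)
    return EvaluationResult(observed, raw_p, corrected_p, model, n_perm, n_ge)


# ---------------------------------------------------------------------------
# loading aggregation
# ---------------------------------------------------------------------------


@dataclass
class AggregatedLoadings:
    mean: np.ndarray
    sd: np.ndarray
    stable: np.ndarray  # bool, |mean| > sd


def aggregate_loadings(
    x_loadings_per_split: list[np.ndarray],
    y_loadings_per_split: list[np.ndarray],
) -> tuple[AggregatedLoadings, AggregatedLoadings, np.ndarray]:
    """Sign-align splits to the first and summarize loadings.

    A split is flipped when the Pearson correlation of its risk-factor
    loading vector with the first split's is negative; the flip applies to
    both sides of that split. Returns (brain, risk-factor) aggregates with
    per-variable mean, sample SD (ddof=1, the error bar), and the
    stability flag |mean| > SD, plus the per-split sign flips.
    """
    ys = [np.asarray(v, float).ravel() for v in y_loadings_per_split]
    xs = [np.asarray(v, float).ravel() for v in x_loadings_per_split]
    if len(xs) != len(ys) or len(ys) < 2:
        raise ValueError("need matched per-split loading lists (>= 2 splits)")
    flips = np.ones(len(ys))
    for s in range(1, len(ys)):
        r = _pearson(ys[s], ys[0])
        if abs(r) < 0.1:
            warnings.warn(
                f"loading alignment correlation {r:.3f} for split {s} is near zero; "
                "dimension matching across splits may be unreliable"
            )
        if r < 0:
            flips[s] = -1.0
    Yl = np.vstack([f * v for f, v in zip(flips, ys)])
    Xl = np.vstack([f * v for f, v in zip(flips, xs)])

    def _agg(mat: np.ndarray) -> AggregatedLoadings:
        mean = mat.mean(axis=0)
        sd = mat.std(axis=0, ddof=1)
        return AggregatedLoadings(mean, sd, np.abs(mean) > sd)

    return _agg(Xl), _agg(Yl), flips


# ---------------------------------------------------------------------------
# sequential dimension extraction
# ---------------------------------------------------------------------------


@dataclass
class LatentDimensionResult:
    dimension: int
    chosen_c: list
    holdout_corrs: np.ndarray     # per outer split
    raw_p: np.ndarray
    corrected_p: np.ndarray
    omnibus: bool
    x_loadings: AggregatedLoadings | None
    y_loadings: AggregatedLoadings | None
    flips: np.ndarray | None
    per_split_x_loadings: list[np.ndarray]
    per_split_y_loadings: list[np.ndarray]
    models: list[RCCAModel]
    # all-subject scores under each split's model (original row order)
    per_split_x_scores: list[np.ndarray]
    per_split_y_scores: list[np.ndarray]

    def table_row(self) -> dict:
        return {
            "dimension": self.dimension,
            "omnibus_significant": self.omnibus,
            **{f"holdout_r_split{s}": float(r) for s, r in enumerate(self.holdout_corrs)},
            **{f"p_corrected_split{s}": float(p) for s, p in enumerate(self.corrected_p)},
            **{f"chosen_c_split{s}": self.chosen_c[s] for s in range(len(self.chosen_c))},
        }


@dataclass
class SequentialResult:
    dimensions: list[LatentDimensionResult]
    scheme: SplitScheme
    x_names: list[str]
    y_names: list[str]
    seeds: dict = field(default_factory=dict)

    @property
    def n_significant(self) -> int:
        return sum(d.omnibus for d in self.dimensions)


def run_sequential_dimensions(
    X,
    Y,
    confounds: pd.DataFrame | None = None,
    *,
    grid: list | None = None,
    n_outer: int = 5,
    n_inner: int = 5,
    holdout_frac: float = 0.2,
    test_frac: float = 0.2,
    n_perm: int = 1000,
    alpha: float = 0.05,
    max_dimensions: int = 5,
    stratify_by: np.ndarray | None = None,
    seed: int = 0,
) -> SequentialResult:
    """Select -> evaluate -> deflate loop over successive latent dimensions.

    Per outer split, confound regression and standardization are fitted on
    the optimization rows and applied to the holdout; hyperparameter
    selection re-standardizes within every inner training set. After an
    omnibus-significant dimension, its variance is removed from each
    split's optimization and holdout matrices by projection deflation
    (slopes estimated on the optimization rows). The loop records every
    evaluated dimension, including the first non-significant one at which
    it stops.
    """
    if grid is None:
        grid = [0.0, 0.1, 0.3, 0.5, 0.7, 0.9, 0.99, 1 - 1e-4]
    x_names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{j}" for j in range(np.shape(X)[1])]
    y_names = list(Y.columns) if isinstance(Y, pd.DataFrame) else [f"y{j}" for j in range(np.shape(Y)[1])]
    Xa = np.asarray(X, float)
    Ya = np.asarray(Y, float)
    n = len(Xa)
    conf = confounds.reset_index(drop=True) if confounds is not None else None

    ss = np.random.SeedSequence(seed)
    split_seed, perm_root = ss.spawn(2)
    scheme = make_splits(
        n, n_outer, n_inner, holdout_frac, test_frac, stratify_by,
        seed=int(split_seed.generate_state(1)[0] % (2**31)),
    )
    perm_seeds = perm_root.spawn(max(max_dimensions, 1) * n_outer)
    seeds_log = {"master": seed, "splits": scheme.seed}

    # per-split preprocessed matrices, deflated in place as dimensions are found
    state = []
    for opt_idx, hold_idx in scheme.outer:
        cs = conf.iloc[opt_idx] if conf is not None else None
        ch = conf.iloc[hold_idx] if conf is not None else None
        px = Preprocessor().fit(Xa[opt_idx], cs)
        py = Preprocessor().fit(Ya[opt_idx], cs)
        state.append(
            {
                "Xo": px.transform(Xa[opt_idx], cs),
                "Yo": py.transform(Ya[opt_idx], cs),
                "Xh": px.transform(Xa[hold_idx], ch),
                "Yh": py.transform(Ya[hold_idx], ch),
                "opt_idx": opt_idx,
                "hold_idx": hold_idx,
            }
        )

    results: list[LatentDimensionResult] = []
    for d in range(max_dimensions):
        chosen, corrs, raws, cors, models = [], [], [], [], []
        xl_split, yl_split, sx_all, sy_all = [], [], [], []
        opt_scores = []
        for s, st in enumerate(state):
            sel = select_hyperparameters(
                st["Xo"], st["Yo"], grid, scheme.inner[s], confounds=None, K=1
            )
            cx, cy = _candidate_cs(sel.chosen)
            pseed = int(perm_seeds[d * n_outer + s].generate_state(1)[0] % (2**31))
            seeds_log[f"perm_dim{d}_split{s}"] = pseed
            ev = evaluate_dimension(
                st["Xo"], st["Yo"], st["Xh"], st["Yh"], cx, cy,
                n_perm=n_perm, seed=pseed, n_bonferroni=n_outer,
            )
            chosen.append(sel.chosen)
            corrs.append(ev.holdout_corr)
            raws.append(ev.raw_p)
            cors.append(ev.corrected_p)
            models.append(ev.model)
            sc_opt = project(ev.model, st["Xo"], st["Yo"])
            opt_scores.append(sc_opt)
            xl_split.append(compute_loadings(st["Xo"], sc_opt.x_scores[:, 0]))
            yl_split.append(compute_loadings(st["Yo"], sc_opt.y_scores[:, 0]))
            sc_hold = project(ev.model, st["Xh"], st["Yh"])
            fx = np.empty(n)
            fy = np.empty(n)
            fx[st["opt_idx"]] = sc_opt.x_scores[:, 0]
            fx[st["hold_idx"]] = sc_hold.x_scores[:, 0]
            fy[st["opt_idx"]] = sc_opt.y_scores[:, 0]
            fy[st["hold_idx"]] = sc_hold.y_scores[:, 0]
            sx_all.append(fx)
            sy_all.append(fy)

        omnibus = bool(np.any(np.asarray(cors) < alpha))
        if omnibus:
            xagg, yagg, flips = aggregate_loadings(xl_split, yl_split)
        else:
            xagg = yagg = flips = None
        results.append(
            LatentDimensionResult(
                dimension=d,
                chosen_c=chosen,
                holdout_corrs=np.asarray(corrs),
                raw_p=np.asarray(raws),
                corrected_p=np.asarray(cors),
                omnibus=omnibus,
                x_loadings=xagg,
                y_loadings=yagg,
                flips=flips,
                per_split_x_loadings=xl_split,
                per_split_y_loadings=yl_split,
                models=models,
                per_split_x_scores=sx_all,
                per_split_y_scores=sy_all,
            )
        )
        if not omnibus:
            break
        # projection deflation: slopes from optimization rows, applied to holdout
        for s, st in enumerate(state):
            sc_opt = opt_scores[s]
            model = models[s]
            sc_hold = project(model, st["Xh"], st["Yh"])
            bx, mx = fit_deflation(st["Xo"], sc_opt.x_scores[:, 0])
            by, my = fit_deflation(st["Yo"], sc_opt.y_scores[:, 0])
            st["Xo"] = apply_deflation(st["Xo"], sc_opt.x_scores[:, 0], bx, mx)
            st["Yo"] = apply_deflation(st["Yo"], sc_opt.y_scores[:, 0], by, my)
            st["Xh"] = apply_deflation(st["Xh"], sc_hold.x_scores[:, 0], bx, mx)
            st["Yh"] = apply_deflation(st["Yh"], sc_hold.y_scores[:, 0], by, my)

    return SequentialResult(results, scheme, x_names, y_names, seeds_log)
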