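"""Spatial-null (spin) comparison of parcel-wise cortical maps.

Parcel-wise brain maps are spatially autocorrelated, so a naive
permutation null for the correlation between two maps is far too narrow.
The spin test builds a null that preserves spatial structure: the parcel
centroids of one hemisphere are randomly rotated on the sphere, the
mirrored rotation is applied to the other hemisphere, and each parcel is
reassigned the value of the nearest original centroid within its own
hemisphere (duplicates permitted). Correlations between spun copies of
one map and the fixed second map form the null distribution.

Also provided: batteries of spin tests against annotation maps with
Bonferroni correction, and Pearson comparison of risk-factor loading
profiles across models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr, rankdata

from .synthio import ParcelGeometry

__all__ = [
    "SpinNull",
    "MapComparison",
    "generate_spin_permutations",
    "spin_correlation_test",
    "characterize_against_annotations",
    "compare_loading_profiles",
]


@dataclass
class SpinNull:
    """Parcel reassignment indices from random sphere rotations.

    ``perms`` has shape (n_perm + 1, n_parcels); row 0 is the identity,
    kept for self-tests and excluded from the null count. Every row maps
    each parcel to a source parcel of the same hemisphere.
    """

    perms: np.ndarray
    n_perm: int
    seed: int
    geometry: ParcelGeometry


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation: QR of a Gaussian matrix, det forced to +1."""
    G = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(G)
    Q = Q @ np.diag(np.sign(np.diag(R)))  # unique QR -> Haar measure
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


_MIRROR = np.diag([-1.0, 1.0, 1.0])


def generate_spin_permutations(
    geometry: ParcelGeometry, n_perm: int = 10000, seed: int = 0
) -> SpinNull:
    """Draw rotation-based parcel reassignments for the spin null.

    The left-hemisphere centroids are rotated by a Haar-uniform rotation R
    and the right-hemisphere centroids by its x-mirror M R M, preserving
    the hemispheric mirror symmetry. Each rotated centroid takes the value
    of its nearest original same-hemisphere centroid (Euclidean metric,
    duplicates permitted).
    """
    left = geometry.indices("L")
    right = geometry.indices("R")
    if len(left) != len(right) or len(left) + len(right) != geometry.n_parcels:
        raise ValueError("geometry must have equal parcel counts in hemispheres L and R")
    cl = geometry.centroid[left]
    cr = geometry.centroid[right]
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm + 1, geometry.n_parcels), dtype=np.intp)
    perms[0] = np.arange(geometry.n_parcels)
    for i in range(1, n_perm + 1):
        R = _random_rotation(rng)
        Rm = _MIRROR @ R @ _MIRROR
        rot_l = cl @ R.T
        rot_r = cr @ Rm.T
        perms[i, left] = left[np.argmin(cdist(rot_l, cl), axis=1)]
        perms[i, right] = right[np.argmin(cdist(rot_r, cr), axis=1)]
    return SpinNull(perms, n_perm, seed, geometry)


@dataclass
class MapComparison:
    name_a: str
    name_b: str
    corr_type: str
    observed: float
    raw_p: float
    corrected_p: float
    significant: bool
    null_corrs: np.ndarray | None = None


def _validate_map(m: np.ndarray, geometry: ParcelGeometry, name: str) -> np.ndarray:
    m = np.asarray(m, float).ravel()
    if m.shape != (geometry.n_parcels,):
        raise ValueError(f"{name} length {len(m)} does not match geometry ({geometry.n_parcels})")
    if not np.all(np.isfinite(m)):
        raise ValueError(f"undefined values in {name} (hemisphere-incomplete maps are rejected)")
    if m.std() == 0:
        raise ValueError(f"{name} is constant")
    return m


def _corr_many(A: np.ndarray, b: np.ndarray, corr_type: str) -> np.ndarray:
    """Row-wise correlation of a matrix of maps with one fixed map."""
    if corr_type == "spearman":
        A = rankdata(A, axis=1)
        b = rankdata(b)
    elif corr_type != "pearson":
        raise ValueError("corr_type must be 'spearman' or 'pearson'")
    Ac = A - A.mean(axis=1, keepdims=True)
    bc = b - b.mean()
    denom = np.linalg.norm(Ac, axis=1) * np.linalg.norm(bc)
    return (Ac @ bc) / denom


def spin_correlation_test(
    map_a: np.ndarray,
    map_b: np.ndarray,
    null: SpinNull,
    corr_type: str = "spearman",
    name_a: str = "map_a",
    name_b: str = "map_b",
    n_comparisons: int = 1,
    alpha: float = 0.05,
    keep_null: bool = False,
) -> MapComparison:
    """Two-sided spin test of the correlation between two parcel maps.

    The null distribution is the correlation of spun copies of ``map_a``
    with the fixed ``map_b``; raw p = (1 + #{|null| >= |observed|}) /
    (n_perm + 1). The two-sided statistic makes the test invariant to a
    global sign flip of either map.
    """
    a = _validate_map(map_a, null.geometry, name_a)
    b = _validate_map(map_b, null.geometry, name_b)
    spun = a[null.perms[1:]]
    nulls = _corr_many(spun, b, corr_type)
    observed = float(_corr_many(a[None, :], b, corr_type)[0])
    raw_p = (1 + int(np.sum(np.abs(nulls) >= abs(observed)))) / (null.n_perm + 1)
    corrected = min(1.0, n_comparisons * raw_p)
    return MapComparison(
        name_a,
        name_b,
        corr_type,
        observed,
        raw_p,
        corrected,
        corrected < alpha,
        nulls if keep_null else None,
    )


def characterize_against_annotations(
    loading_map: np.ndarray,
    annotation_set: dict[str, np.ndarray],
    null: SpinNull,
    alpha: float = 0.05,
) -> list[MapComparison]:
    """Spin-test battery (Spearman) of a loading map against annotations.

    Bonferroni correction uses the battery size; results are sorted by
    absolute observed correlation, descending.
    """
    names = list(annotation_set)
    if len(set(names)) != len(names):
        raise ValueError("duplicate annotation names")
    m = len(names)
    out = [
        spin_correlation_test(
            loading_map,
            annotation_set[name],
            null,
            corr_type="spearman",
            name_a="loadings",
            name_b=name,
            n_comparisons=m,
            alpha=alpha,
        )
        for name in names
    ]
    return sorted(out, key=lambda c: -abs(c.observed))


def compare_loading_profiles(
    loadings_a: np.ndarray,
    loadings_b: np.ndarray,
    side: str,
    null: SpinNull | None = None,
    n_comparisons: int = 1,
    alpha: float = 0.05,
) -> MapComparison:
    """Compare two loading profiles across models.

    Risk-factor profiles use Pearson correlation with its analytic p-value;
    brain profiles delegate to the spin test (spatial null required).
    Correlations are reported signed — sign alignment is the caller's duty.
    """
    a = np.asarray(loadings_a, float).ravel()
    b = np.asarray(loadings_b, float).ravel()
    if a.shape != b.shape:
        raise ValueError("loading profiles differ in length")
    if side == "brain":
        if null is None:
            raise ValueError("brain-side comparison requires a SpinNull")
        return spin_correlation_test(
            a, b, null, corr_type="pearson",
            name_a="loadings_a", name_b="loadings_b",
            n_comparisons=n_comparisons, alpha=alpha,
        )
    if side != "risk_factor":
        raise ValueError("side must be 'risk_factor' or 'brain'")
    r, p = pearsonr(a, b)
    corrected = min(1.0, n_comparisons * float(p))
    return MapComparison(
        "loadings_a", "loadings_b", "pearson", float(r), float(p), corrected,
        corrected < alpha,
    )
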