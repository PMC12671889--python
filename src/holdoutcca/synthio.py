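"""Synthetic cohorts and parcel geometries with planted latent structure.

Real cohort data linking risk-factor panels to parcel-wise cortical
structure is access-restricted, so this module generates surrogates that
carry the statistical features the analysis machinery assumes:

* one or more planted latent dimensions, each a pair of subject-level
  factors with a prescribed correlation, entering the brain block through
  a spatially smooth weight map over parcel centroids and the risk-factor
  block through block-patterned weights;
* blocks of intercorrelated risk factors (mimicking body-composition and
  air-pollution clusters seen in population panels);
* linear confound effects (age, sex, acquisition site);
* a right-skewed, CRP-like inflammation marker rank-linked to one latent
  dimension's subject scores.

The planted ground truth (weights, latent scores, correlations) is
recorded so parameter-recovery tests can score the estimation pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PlantedDimension",
    "RiskFactorBlock",
    "SynthConfig",
    "ParcelGeometry",
    "SynthCohort",
    "generate_parcel_geometry",
    "generate_cohort",
    "generate_annotation_maps",
    "write_cohort",
    "read_cohort",
    "read_geometry",
]

_GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0


class ConfigurationError(ValueError):
    """Raised when a synthetic-cohort configuration is internally inconsistent."""


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedDimension:
    """One planted latent dimension.

    Parameters
    ----------
    canonical_correlation
        Correlation imposed on the pair of latent subject factors
        (brain-side, risk-factor-side). Must lie in [0, 1).
    x_weight_smoothness
        Length-scale (chord distance on the unit sphere) of the Gaussian
        kernel used to smooth the brain-side weight map.
    y_block_pattern
        Signed weight magnitude per risk-factor block; columns outside all
        blocks carry weight zero.
    """

    canonical_correlation: float
    x_weight_smoothness: float = 0.5
    y_block_pattern: tuple[float, ...] = (3.0, 0.0)


@dataclass(frozen=True)
class RiskFactorBlock:
    """A block of risk-factor columns sharing a latent noise factor."""

    size: int
    within_correlation: float = 0.6


@dataclass(frozen=True)
class SynthConfig:
    """Full recipe for one synthetic cohort.

    Defaults mirror the emulated study: 7,370 subjects, 68 risk factors,
    148 cortical parcels, two planted dimensions with correlations in the
    ranges reported for the cardiometabolic (~0.32) and physical-robustness
    (~0.10) dimensions, and a marker rank-linked at -0.39 to the first
    dimension's risk-factor scores.
    """

    n_subjects: int = 7370
    n_risk_factors: int = 68
    n_parcels: int = 148
    planted_dims: tuple[PlantedDimension, ...] = (
        PlantedDimension(0.32, 0.5, (3.0, 0.0)),
        PlantedDimension(0.10, 0.5, (0.0, 3.0)),
    )
    rf_blocks: tuple[RiskFactorBlock, ...] = (
        RiskFactorBlock(10, 0.6),  # body-composition-like block
        RiskFactorBlock(8, 0.6),   # air-pollution-like block
    )
    # per-confound linear effect sizes on (X columns, Y columns), applied to
    # the standardized confound
    confound_effects: dict = field(
        default_factory=lambda: {"age": (0.2, 0.1), "sex": (0.1, 0.1), "site": (0.05, 0.05)}
    )
    marker_dim_index: int = 0
    marker_spearman_target: float = -0.39
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        rs = [d.canonical_correlation for d in self.planted_dims]
        if any(not (0.0 <= r < 1.0) for r in rs):
            raise ConfigurationError(
                "canonical correlations must lie in [0, 1); got %r" % (rs,)
            )
        if sorted(rs, reverse=True) != rs:
            raise ConfigurationError("planted canonical correlations must be sorted descending")
        if sum(b.size for b in self.rf_blocks) > self.n_risk_factors:
            raise ConfigurationError("risk-factor block sizes exceed n_risk_factors")
        if self.n_parcels % 2 != 0:
            raise ConfigurationError("n_parcels must be even (two hemispheres)")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        for d in self.planted_dims:
            if len(d.y_block_pattern) != len(self.rf_blocks):
                raise ConfigurationError(
                    "y_block_pattern length must equal the number of rf_blocks"
                )
        if self.planted_dims and not (
            0 <= self.marker_dim_index < len(self.planted_dims)
        ):
            raise ConfigurationError("marker_dim_index out of range")
        if abs(self.marker_spearman_target) > 1:
            raise ConfigurationError("marker spearman target must lie in [-1, 1]")


# ---------------------------------------------------------------------------
# parcel geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParcelGeometry:
    """Unit-sphere parcel centroids, mirrored across hemispheres.

    ``hemisphere`` holds 'L'/'R' labels; right-hemisphere centroids are the
    left ones reflected through the x = 0 plane, which is the symmetry the
    spin-permutation null relies on.
    """

    parcel_id: tuple[str, ...]
    hemisphere: np.ndarray  # (n,) of 'L'/'R'
    centroid: np.ndarray    # (n, 3) unit vectors

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_id)

    def indices(self, hemi: str) -> np.ndarray:
        return np.flatnonzero(self.hemisphere == hemi)


def generate_parcel_geometry(n_parcels: int, seed: int = 0) -> ParcelGeometry:
    """Quasi-uniform centroids on the unit sphere, split across hemispheres.

    Left-hemisphere centroids are placed on a Fibonacci lattice covering the
    x < 0 half-sphere; the right hemisphere is their mirror image through
    the x = 0 plane. The seed rotates the lattice azimuthally, so different
    seeds give rotational offsets of the same quasi-uniform layout.
    """
    if n_parcels < 4 or n_parcels % 2 != 0:
        raise ValueError("n_parcels must be an even integer >= 4")
    m = n_parcels // 2
    rng = np.random.default_rng(seed)
    offset = rng.uniform(0.0, 2.0 * np.pi)
    k = np.arange(m)
    # uniform-in-area polar angle on the half-sphere about the -x axis
    cos_phi = 1.0 - (k + 0.5) / m
    sin_phi = np.sqrt(1.0 - cos_phi**2)
    psi = 2.0 * np.pi * ((k / _GOLDEN) % 1.0) + offset
    left = np.column_stack(
        [-cos_phi, sin_phi * np.cos(psi), sin_phi * np.sin(psi)]
    )
    left /= np.linalg.norm(left, axis=1, keepdims=True)
    right = left * np.array([-1.0, 1.0, 1.0])
    ids = tuple(f"L_{i:03d}" for i in range(m)) + tuple(f"R_{i:03d}" for i in range(m))
    hemi = np.array(["L"] * m + ["R"] * m)
    return ParcelGeometry(ids, hemi, np.vstack([left, right]))


def _smooth_kernel(centroids: np.ndarray, length_scale: float) -> np.ndarray:
    """Gaussian kernel exp(-d^2 / 2 sigma^2) on chord distance."""
    d2 = np.sum((centroids[:, None, :] - centroids[None, :, :]) ** 2, axis=-1)
    return np.exp(-d2 / (2.0 * length_scale**2))


def _smooth_map(
    geometry: ParcelGeometry, length_scale: float, rng: np.random.Generator
) -> np.ndarray:
    """One spatially autocorrelated map: kernel-smoothed white noise, z-scored."""
    kern = _smooth_kernel(geometry.centroid, length_scale)
    m = kern @ rng.standard_normal(geometry.n_parcels)
    m -= m.mean()
    sd = m.std()
    if sd == 0:  # pragma: no cover - degenerate kernel
        raise RuntimeError("degenerate smooth map")
    return m / sd


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass
class CohortTruth:
    """Planted ground truth recorded before noise addition."""

    true_u: np.ndarray                    # (p, K) brain-side weight maps
    true_v: np.ndarray                    # (q, K) risk-factor-side weights
    true_canonical_correlations: np.ndarray  # (K,)
    true_x_scores: np.ndarray             # (n, K) latent brain-side factors
    true_y_scores: np.ndarray             # (n, K) latent risk-factor-side factors


@dataclass
class SynthCohort:
    X: pd.DataFrame           # n x p brain matrix
    Y: pd.DataFrame           # n x q risk-factor matrix
    confounds: pd.DataFrame   # age, sex, site
    marker: pd.Series         # CRP-like, nonnegative, right-skewed
    geometry: ParcelGeometry
    truth: CohortTruth
    config: SynthConfig


def _block_slices(config: SynthConfig) -> list[slice]:
    out, start = [], 0
    for b in config.rf_blocks:
        out.append(slice(start, start + b.size))
        start += b.size
    return out


def generate_cohort(config: SynthConfig) -> SynthCohort:
    """Draw one cohort from the configured generative model.

    For each planted dimension k a standard-normal brain-side factor t_k is
    drawn and the risk-factor-side factor is set to
    ``r_k * t_k + sqrt(1 - r_k^2) * eps`` so the latent pair has population
    correlation exactly r_k. The factors enter X through mutually
    orthogonalized smooth weight maps and Y through per-block weight
    patterns; block noise factors induce within-block correlation, confound
    effects are added linearly, and isotropic Gaussian noise is added last.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p, q = config.n_subjects, config.n_parcels, config.n_risk_factors
    K = len(config.planted_dims)
    geometry = generate_parcel_geometry(p, seed=config.seed)

    # --- brain-side weight maps (smooth, orthogonalized across dims) --------
    amp_x = 1.0  # per-parcel RMS signal amplitude
    U = np.empty((p, K))
    for k, dim in enumerate(config.planted_dims):
        w = _smooth_map(geometry, dim.x_weight_smoothness, rng)
        for j in range(k):  # keep planted brain directions orthogonal
            w = w - (U[:, j] @ w) / (U[:, j] @ U[:, j]) * U[:, j]
        nrm = np.linalg.norm(w)
        if nrm < 1e-8:
            raise ConfigurationError("degenerate brain weight map after orthogonalization")
        U[:, k] = w / nrm * amp_x * np.sqrt(p)

    # --- risk-factor-side weights -------------------------------------------
    V = np.zeros((q, K))
    slices = _block_slices(config)
    for k, dim in enumerate(config.planted_dims):
        for mag, sl in zip(dim.y_block_pattern, slices):
            V[sl, k] = mag

    # --- calibration: scale latent-pair correlation for measurement noise ---
    # Projecting noisy X (or Y) onto the planted direction attenuates the
    # latent factor by alpha = signal_sd / sqrt(signal_var + noise_var); the
    # latent pair correlation is raised to r / (alpha_x * alpha_y) so the
    # population canonical correlation of the observed matrices equals the
    # configured value. Unreachable targets (>= 1 after noise) are an error.
    sd = config.noise_sd
    latent_r = np.empty(K)
    for k, dim in enumerate(config.planted_dims):
        ax = np.linalg.norm(U[:, k])
        alpha_x = ax / np.hypot(ax, sd)
        noise_var_y = 0.0
        vk = V[:, k]
        for b, sl in zip(config.rf_blocks, slices):
            vb = vk[sl]
            rho = b.within_correlation
            noise_var_y += sd**2 * ((1 - rho) * vb @ vb + rho * vb.sum() ** 2)
        free = np.ones(q, bool)
        for sl in slices:
            free[sl] = False
        noise_var_y += sd**2 * (vk[free] @ vk[free])
        # signal variance along the planted direction is |vk|^4 (score |vk|^2 t);
        # noise_var_y above is vk' Sigma_noise vk
        ay2 = vk @ vk
        alpha_y = np.sqrt(ay2**2 / (ay2**2 + noise_var_y)) if ay2 > 0 else 0.0
        r = dim.canonical_correlation
        if r == 0.0:
            latent_r[k] = 0.0
            continue
        if alpha_x * alpha_y == 0 or r / (alpha_x * alpha_y) >= 1.0:
            raise ConfigurationError(
                f"planted canonical correlation {r} unreachable after noise "
                f"(attenuation factor {alpha_x * alpha_y:.3f})"
            )
        latent_r[k] = r / (alpha_x * alpha_y)

    # --- latent factors -----------------------------------------------------
    t_x = rng.standard_normal((n, K))
    t_y = np.empty_like(t_x)
    for k in range(K):
        t_y[:, k] = latent_r[k] * t_x[:, k] + np.sqrt(
            1.0 - latent_r[k] ** 2
        ) * rng.standard_normal(n)

    # --- assemble signal ----------------------------------------------------
    X = t_x @ U.T
    Y = t_y @ V.T

    # within-block shared noise factors
    for b, sl in zip(config.rf_blocks, slices):
        rho = b.within_correlation
        g = rng.standard_normal(n)
        e = rng.standard_normal((n, b.size))
        Y[:, sl] += sd * (np.sqrt(rho) * g[:, None] + np.sqrt(1.0 - rho) * e)
    free = np.ones(q, bool)
    for sl in slices:
        free[sl] = False
    Y[:, free] += sd * rng.standard_normal((n, int(free.sum())))

    # --- confounds -----------------------------------------------------------
    age = rng.uniform(46.0, 81.0, size=n)
    sex = rng.permutation(np.arange(n) % 2).astype(int)
    site = rng.integers(0, 4, size=n)
    confounds = pd.DataFrame({"age": age, "sex": sex, "site": site.astype(str)})

    z_age = (age - age.mean()) / age.std()
    z_sex = sex - sex.mean()
    site_offsets = rng.standard_normal(4)
    z_site = site_offsets[site]
    z_site = (z_site - z_site.mean()) / (z_site.std() or 1.0)
    for name, z in [("age", z_age), ("sex", z_sex), ("site", z_site)]:
        ex, ey = config.confound_effects.get(name, (0.0, 0.0))
        X += ex * z[:, None]
        Y += ey * z[:, None]

    # --- measurement noise on X ----------------------------------------------
    X += sd * rng.standard_normal((n, p))

    # --- marker ---------------------------------------------------------------
    if config.planted_dims:
        rho_s = config.marker_spearman_target
        # bivariate-normal inversion: Pearson rho giving Spearman rho_s
        rho_p = 2.0 * np.sin(np.pi * rho_s / 6.0)
        t = t_y[:, config.marker_dim_index]
        lin = rho_p * t + np.sqrt(1.0 - rho_p**2) * rng.standard_normal(n)
    else:
        lin = rng.standard_normal(n)
    marker = pd.Series(np.exp(lin), name="marker")  # lognormal, right-skewed

    truth = CohortTruth(
        true_u=U,
        true_v=V,
        true_canonical_correlations=np.array(
            [d.canonical_correlation for d in config.planted_dims]
        ),
        true_x_scores=t_x,
        true_y_scores=t_y,
    )
    Xdf = pd.DataFrame(X, columns=list(geometry.parcel_id))
    Ydf = pd.DataFrame(Y, columns=[f"rf_{j:02d}" for j in range(q)])
    return SynthCohort(Xdf, Ydf, confounds, marker, geometry, truth, config)


# ---------------------------------------------------------------------------
# annotation surrogates
# ---------------------------------------------------------------------------


def generate_annotation_maps(
    geometry: ParcelGeometry,
    reference_map: np.ndarray,
    target_correlations: Sequence[float],
    smoothness: float = 0.5,
    seed: int = 0,
) -> list[np.ndarray]:
    """Smooth parcel maps with prescribed sample correlation to a reference.

    Each map is ``rho * z(ref) + sqrt(1 - rho^2) * z(g_perp)`` where g is an
    independent kernel-smoothed field orthogonalized against the reference,
    so the achieved sample correlation equals the target exactly while the
    map stays spatially smooth. ``|target| > 1`` is rejected; ``|target| = 1``
    degenerates to a (sign-flipped) rescaled copy of the reference.
    """
    ref = np.asarray(reference_map, float)
    if ref.shape != (geometry.n_parcels,):
        raise ValueError("reference_map length does not match geometry")
    if ref.std() == 0:
        raise ValueError("reference_map is constant")
    rng = np.random.default_rng(seed)
    ref_z = (ref - ref.mean()) / ref.std()
    out = []
    for rho in target_correlations:
        if abs(rho) > 1:
            raise ValueError(f"target correlation {rho} outside [-1, 1]")
        if abs(rho) == 1:
            out.append(rho * ref_z)
            continue
        g = _smooth_map(geometry, smoothness, rng)
        g = g - (ref_z @ g) / (ref_z @ ref_z) * ref_z
        sdg = g.std()
        if sdg == 0:  # pragma: no cover
            raise RuntimeError("degenerate orthogonalized map")
        g = (g - g.mean()) / sdg
        out.append(rho * ref_z + np.sqrt(1.0 - rho**2) * g)
    return out


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------


def write_cohort(cohort: SynthCohort, outdir: str | Path) -> None:
    """Write X/Y/confounds+marker/geometry CSVs plus a truth sidecar (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sid = pd.Index([f"sub_{i:05d}" for i in range(len(cohort.X))], name="subject_id")
    cohort.X.set_axis(sid).to_csv(outdir / "X.csv")
    cohort.Y.set_axis(sid).to_csv(outdir / "Y.csv")
    cm = cohort.confounds.copy()
    cm["marker"] = cohort.marker.values
    cm.set_axis(sid).to_csv(outdir / "confounds.csv")
    geo = pd.DataFrame(
        {
            "parcel_id": cohort.geometry.parcel_id,
            "hemisphere": cohort.geometry.hemisphere,
            "x": cohort.geometry.centroid[:, 0],
            "y": cohort.geometry.centroid[:, 1],
            "z": cohort.geometry.centroid[:, 2],
        }
    )
    geo.to_csv(outdir / "geometry.csv", index=False)
    truth = {
        "true_u": cohort.truth.true_u.tolist(),
        "true_v": cohort.truth.true_v.tolist(),
        "true_canonical_correlations": cohort.truth.true_canonical_correlations.tolist(),
        "true_x_scores": cohort.truth.true_x_scores.tolist(),
        "true_y_scores": cohort.truth.true_y_scores.tolist(),
    }
    (outdir / "truth.json").write_text(json.dumps(truth))


def read_geometry(path: str | Path) -> ParcelGeometry:
    geo = pd.read_csv(path)
    required = {"parcel_id", "hemisphere", "x", "y", "z"}
    if not required.issubset(geo.columns):
        raise ValueError(f"geometry CSV must contain columns {sorted(required)}")
    return ParcelGeometry(
        tuple(geo["parcel_id"].astype(str)),
        geo["hemisphere"].to_numpy(dtype=object).astype(str),
        geo[["x", "y", "z"]].to_numpy(float),
    )


def read_cohort(indir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, ParcelGeometry | None]:
    """Read X, Y, confounds(+marker) and, if present, the geometry."""
    indir = Path(indir)
    X = pd.read_csv(indir / "X.csv", index_col=0)
    Y = pd.read_csv(indir / "Y.csv", index_col=0)
    conf = pd.read_csv(indir / "confounds.csv", index_col=0)
    for df, name in [(X, "X"), (Y, "Y"), (conf, "confounds")]:
        if df.isna().any().any():
            raise ValueError(f"missing values in {name}; incomplete records are rejected")
    geom_path = indir / "geometry.csv"
    geometry = read_geometry(geom_path) if geom_path.exists() else None
    return X, Y, conf, geometry
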