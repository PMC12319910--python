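"""Synthetic parcellated resting-state cohorts with planted network effects.

This module generates everything the downstream gradient pipeline consumes,
without any imaging data: a spherical parcel scheme with spatially clustered
Yeo-7 networks, multi-subject two-condition (medication ON / OFF) BOLD-like
timeseries with a block-structured network covariance, a daily dopamine dose
(DDE) table, and spatially autocorrelated annotation maps standing in for
regional gene-expression or meta-analytic maps.

The planted effect mirrors the phenomenon of interest: in the ON condition
the correlation between selected network pairs (by default visual–dorsal
attention and visual–ventral attention) is *reduced* — i.e. those networks
segregate — by an amount that scales with the subject's standardized dose.
Greater segregation in connectivity translates into greater between-network
dispersion in the 3-D gradient manifold downstream.

Timeseries are draws from a multivariate normal with the subject/condition
target correlation matrix; no temporal autocorrelation is simulated (inputs
to the real pipeline are band-passed and denoised, and every downstream
statistic is a function of the Pearson correlation matrix only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parcellation import SCHAEFER400_SIZES, YEO7_NETWORKS, ParcelScheme, SchemeError

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "ScanTimeseries",
    "generate_parcel_scheme",
    "build_target_covariance",
    "generate_cohort",
    "generate_autocorrelated_map",
    "nearest_psd_correlation",
]

#: eigenvalue clipping tolerance for positive-semidefinite repair
PSD_TOL = 1e-10


class GenerationError(RuntimeError):
    """Raised when a requested cohort cannot be generated."""


@dataclass(frozen=True)
class ScanTimeseries:
    """One scan's time × parcel matrix with subject/condition metadata."""

    scan_id: str
    subject: str
    condition: str  # "ON" | "OFF" | "control"
    data: np.ndarray  # (T, P)
    parcel_ids: tuple

    def __post_init__(self):
        data = np.asarray(self.data, float)
        if data.ndim != 2 or data.shape[0] < 2:
            raise ValueError("timeseries must be a 2-D matrix with >= 2 timepoints")
        if data.shape[1] != len(self.parcel_ids):
            raise ValueError("column count does not match parcel ids")
        if not np.isfinite(data).all():
            raise ValueError(f"scan {self.scan_id}: non-finite values present")
        object.__setattr__(self, "data", data)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic ON/OFF cohort.

    Defaults describe the study conditions emulated throughout: 27 patients
    scanned ON and OFF medication, 19 single-scan controls, 140 timepoints
    over 400 parcels assigned to the Yeo-7 networks in Schaefer-400
    proportions, and an ON-state segregation (correlation reduction) of the
    visual–dorsal-attention and visual–ventral-attention pairs whose size
    scales with the subject's standardized daily dose.

    ``within_r``/``between_r`` are the baseline within-/between-network
    correlations of the block-structured target matrix. ``effect_size`` is
    the ON-state reduction of the between-network correlation for each pair
    in ``effect_networks`` at the cohort-mean dose; a subject one dose SD
    above the mean receives ``effect_size * (1 + dose_interaction)``.
    ``subject_sd`` is the SD of a subject-level additive perturbation of
    between-network correlations, shared between a subject's ON and OFF
    scans (this is what makes the paired design informative).

    ``spatial_strength``/``spatial_scale`` add a spatially decaying
    component (``exp(-d / spatial_scale)`` over great-circle centroid
    distance, centered within every network-block pair so block means are
    untouched). Real cortical connectivity falls off smoothly with
    distance; without this heterogeneity a thresholded block matrix has
    disjoint connectivity profiles across networks and no connected
    affinity graph.
    """

    n_pairs: int = 27
    n_controls: int = 19
    n_timepoints: int = 140
    n_parcels: int = 400
    network_sizes: tuple = SCHAEFER400_SIZES
    within_r: float = 0.30
    between_r: float = 0.10
    effect_networks: tuple = (("VIS", "DAN"), ("VIS", "VAN"))
    effect_size: float = 0.19
    dose_mean: float = 680.28
    dose_sd: float = 404.79
    dose_interaction: float = 0.2
    subject_sd: float = 0.02
    spatial_strength: float = 0.5
    spatial_scale: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if sum(self.network_sizes) != self.n_parcels:
            raise GenerationError(
                f"network_sizes sum to {sum(self.network_sizes)}, "
                f"expected n_parcels={self.n_parcels}"
            )
        if len(self.network_sizes) != len(YEO7_NETWORKS):
            raise GenerationError("network_sizes must list all 7 networks")
        if not (0 < self.within_r <= 1) or not (0 <= self.between_r < 1):
            raise GenerationError("correlation parameters must lie in [0, 1]")
        if self.between_r >= self.within_r:
            raise GenerationError("between_r must be below within_r")
        if self.n_timepoints < 20:
            raise GenerationError(
                "n_timepoints must be >= 20 (twice the default component count)"
            )
        for pair in self.effect_networks:
            if len(pair) != 2 or any(n not in YEO7_NETWORKS for n in pair):
                raise GenerationError(f"invalid effect network pair: {pair}")
        # the noise-free target matrices must themselves be PSD
        for cond in ("OFF", "ON"):
            block = self._network_block(cond, dose_z=0.0)
            full = _expand_blocks(block, self.network_sizes)
            if np.linalg.eigvalsh(full).min() < -1e-8:
                raise GenerationError(
                    "correlation parameters yield a non-PSD target covariance"
                )

    def _network_block(self, condition: str, dose_z: float, noise: np.ndarray | None = None):
        """7×7 matrix of within-(diagonal) / between-network correlations."""
        k = len(YEO7_NETWORKS)
        block = np.full((k, k), self.between_r, float)
        np.fill_diagonal(block, self.within_r)
        if noise is not None:
            block = block + noise
            np.fill_diagonal(block, self.within_r)
        if condition == "ON":
            eff = self.effect_size * (1.0 + self.dose_interaction * dose_z)
            for a, b in self.effect_networks:
                ia, ib = YEO7_NETWORKS.index(a), YEO7_NETWORKS.index(b)
                block[ia, ib] -= eff
                block[ib, ia] -= eff
        elif condition not in ("OFF", "control"):
            raise GenerationError(f"unknown condition {condition!r}")
        return block


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated dataset: scheme, scans, dose table and the generating spec."""

    scheme: ParcelScheme
    scans: tuple
    doses: pd.DataFrame  # columns: subject, DDE
    spec: CohortSpec

    def scans_for(self, condition: str) -> list:
        return [s for s in self.scans if s.condition == condition]


# ---------------------------------------------------------------------------
# parcel scheme
# ---------------------------------------------------------------------------

def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """n well-spread unit vectors with x > 0 (golden-spiral construction)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - i / n)  # polar angle over a hemisphere of directions
    theta = np.pi * (1 + 5**0.5) * i
    pts = np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )
    # rotate so the hemisphere opens along +x, then fold stragglers across
    pts = pts[:, [2, 0, 1]]
    pts[:, 0] = np.abs(pts[:, 0]) + 0.05
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


_PATCH_CENTERS = _fibonacci_hemisphere(len(YEO7_NETWORKS))
_PATCH_ANGLE = 0.25  # rad; angular jitter of parcels around their patch center


def generate_parcel_scheme(
    n_parcels: int = 400,
    network_sizes: tuple | None = None,
    seed: int = 0,
) -> ParcelScheme:
    """Build a two-hemisphere spherical parcel scheme with clustered networks.

    Each network occupies a patch around a fixed direction on the right
    hemisphere and its mirror image (x → −x) on the left, so that parcels of
    one network are spatially contiguous and spin nulls preserve the spatial
    autocorrelation of network-structured maps.

    Parameters
    ----------
    n_parcels
        Total parcel count; must be even (split across two hemispheres).
    network_sizes
        Seven counts summing to ``n_parcels``; defaults to Schaefer-400
        proportions rescaled to ``n_parcels``.
    """
    if n_parcels % 2:
        raise SchemeError("n_parcels must be even (two hemispheres)")
    if network_sizes is None:
        network_sizes = _proportional_sizes(n_parcels)
    network_sizes = tuple(int(s) for s in network_sizes)
    if sum(network_sizes) != n_parcels:
        raise SchemeError(
            f"network_sizes sum to {sum(network_sizes)}, expected {n_parcels}"
        )
    if len(network_sizes) != len(YEO7_NETWORKS):
        raise SchemeError("network_sizes must list all 7 networks")
    if any(s < 1 for s in network_sizes):
        raise SchemeError("every network needs at least one parcel")

    # split each network across hemispheres; odd remainders alternate sides
    rng = np.random.default_rng(seed)
    right_counts, extra_side = [], 0
    for size in network_sizes:
        nr = size // 2
        if size % 2:
            nr += extra_side
            extra_side = 1 - extra_side
        right_counts.append(nr)
    if sum(right_counts) != n_parcels // 2:
        raise SchemeError("network_sizes cannot be balanced across hemispheres")

    rows = []
    pid = 0
    for hemi in ("L", "R"):
        for net, size, nr in zip(YEO7_NETWORKS, network_sizes, right_counts):
            count = nr if hemi == "R" else size - nr
            center = _PATCH_CENTERS[YEO7_NETWORKS.index(net)].copy()
            if hemi == "L":
                center[0] = -center[0]
            g = rng.standard_normal((count, 3))
            tangential = g - np.outer(g @ center, center)
            pts = center + _PATCH_ANGLE * tangential
            pts /= np.linalg.norm(pts, axis=1, keepdims=True)
            for p in pts:
                rows.append((f"parcel_{pid:03d}", net, hemi, p[0], p[1], p[2]))
                pid += 1
    table = pd.DataFrame(rows, columns=["parcel_id", "network", "hemisphere", "x", "y", "z"])
    # canonical ordering: network-major (as in the block covariance), then hemi
    order = {n: i for i, n in enumerate(YEO7_NETWORKS)}
    table = (
        table.assign(_net=table["network"].map(order))
        .sort_values(["_net", "hemisphere", "parcel_id"], kind="stable")
        .drop(columns="_net")
        .reset_index(drop=True)
    )
    return ParcelScheme(table)


def _proportional_sizes(n_parcels: int) -> tuple:
    """Scale the Schaefer-400 network proportions to ``n_parcels``."""
    raw = np.array(SCHAEFER400_SIZES, float) * n_parcels / sum(SCHAEFER400_SIZES)
    sizes = np.floor(raw).astype(int)
    frac_order = np.argsort(-(raw - sizes), kind="stable")
    for i in frac_order[: n_parcels - sizes.sum()]:
        sizes[i] += 1
    return tuple(int(s) for s in sizes)


# ---------------------------------------------------------------------------
# target covariance
# ---------------------------------------------------------------------------

def nearest_psd_correlation(mat: np.ndarray, tol: float = PSD_TOL) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD matrix, re-standardized.

    Negative eigenvalues are clipped at zero and the result is rescaled to a
    unit diagonal. Raises :class:`GenerationError` if the diagonal collapses.
    """
    mat = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(mat)
    if vals.min() >= -tol:
        return mat
    vals = np.clip(vals, 0.0, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.diag(repaired).copy()
    if (d <= tol).any():
        raise GenerationError("PSD repair collapsed a diagonal entry to zero")
    repaired = repaired / np.sqrt(np.outer(d, d))
    np.fill_diagonal(repaired, 1.0)
    return (repaired + repaired.T) / 2.0


def _expand_blocks(block: np.ndarray, sizes) -> np.ndarray:
    """Expand a 7×7 network-block matrix to a full parcel correlation matrix."""
    labels = np.repeat(np.arange(len(sizes)), sizes)
    full = block[np.ix_(labels, labels)].copy()
    np.fill_diagonal(full, 1.0)
    return full


def spatial_anomaly(scheme: ParcelScheme, scale: float) -> np.ndarray:
    """Distance-decaying correlation component, centered per block pair.

    ``exp(-d / scale)`` over great-circle centroid distance, with the mean
    removed separately within every network-block pair (and within each
    diagonal block) so that adding the anomaly leaves all block-mean
    correlations unchanged. Diagonal is zero.
    """
    xyz = scheme.centroids()
    d = np.arccos(np.clip(xyz @ xyz.T, -1.0, 1.0))
    s = np.exp(-d / scale)
    np.fill_diagonal(s, np.nan)
    labels = scheme.network_labels
    out = np.zeros_like(s)
    for a in YEO7_NETWORKS:
        ia = np.flatnonzero(labels == a)
        for b in YEO7_NETWORKS:
            ib = np.flatnonzero(labels == b)
            block = s[np.ix_(ia, ib)]
            mean = np.nanmean(block)
            out[np.ix_(ia, ib)] = block - mean
    np.fill_diagonal(out, 0.0)
    return out


def build_target_covariance(
    spec: CohortSpec,
    condition: str,
    dose_z: float = 0.0,
    subject_noise: np.ndarray | None = None,
    spatial: np.ndarray | None = None,
) -> np.ndarray:
    """Target parcel correlation matrix for one scan.

    ``subject_noise`` is a symmetric zero-diagonal 7×7 matrix of additive
    between-network correlation perturbations (a subject random effect).
    For ``condition='ON'`` the between-network correlation of every effect
    pair is reduced by ``effect_size * (1 + dose_interaction * dose_z)``;
    because ``spatial`` (a pre-computed :func:`spatial_anomaly`, scaled by
    ``spec.spatial_strength``) is centered per block pair, the mean
    between-block correlation read back from the matrix still equals the
    block value. The result is projected to the nearest PSD correlation
    matrix.
    """
    if subject_noise is not None:
        subject_noise = np.asarray(subject_noise, float)
        if subject_noise.shape != (7, 7) or not np.allclose(subject_noise, subject_noise.T):
            raise GenerationError("subject_noise must be a symmetric 7x7 matrix")
    block = spec._network_block(condition, dose_z, subject_noise)
    full = _expand_blocks(block, spec.network_sizes)
    if spatial is not None:
        full = full + spec.spatial_strength * spatial
        np.fill_diagonal(full, 1.0)
    full = nearest_psd_correlation(full)
    if np.abs(np.diag(full) - 1.0).max() > 1e-8:
        raise GenerationError("covariance diagonal not unit after PSD projection")
    return full


def _symmetric_noise(rng: np.random.Generator, sd: float) -> np.ndarray:
    k = len(YEO7_NETWORKS)
    noise = np.zeros((k, k))
    iu = np.triu_indices(k, 1)
    noise[iu] = rng.normal(0.0, sd, len(iu[0]))
    return noise + noise.T


def _sample_mvn(rng: np.random.Generator, cov: np.ndarray, n: int) -> np.ndarray:
    """Draw n rows from N(0, cov) via eigendecomposition (tolerant of PSD edge)."""
    vals, vecs = np.linalg.eigh(cov)
    if vals.min() < -1e-8:
        raise GenerationError("non-PSD covariance passed to sampler")
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    return rng.standard_normal((n, cov.shape[0])) @ root.T


def generate_cohort(spec: CohortSpec, scheme: ParcelScheme | None = None) -> SyntheticCohort:
    """Generate the full synthetic cohort described by ``spec``.

    Returns a :class:`SyntheticCohort` holding ``n_pairs`` ON/OFF scan pairs
    plus ``n_controls`` single scans, the dose table, and the parcel scheme
    (built from the spec if not supplied). Fully reproducible from
    ``spec.seed``.
    """
    if scheme is None:
        scheme = generate_parcel_scheme(spec.n_parcels, spec.network_sizes, seed=spec.seed)
    if scheme.n_parcels != spec.n_parcels:
        raise GenerationError("scheme size does not match spec.n_parcels")
    expected_labels = np.repeat(list(YEO7_NETWORKS), spec.network_sizes)
    if not np.array_equal(scheme.network_labels, expected_labels):
        raise GenerationError(
            "scheme parcels must be ordered network-major (as generate_parcel_scheme emits)"
        )
    parcel_ids = tuple(scheme.parcel_ids)
    spatial = (
        spatial_anomaly(scheme, spec.spatial_scale) if spec.spatial_strength > 0 else None
    )
    rng = np.random.default_rng(spec.seed)

    doses = np.clip(rng.normal(spec.dose_mean, spec.dose_sd, spec.n_pairs), 0.0, None)
    dose_sd = doses.std(ddof=0)
    dose_z = (doses - doses.mean()) / dose_sd if dose_sd > 0 else np.zeros_like(doses)

    scans = []
    subjects = [f"sub-{i + 1:02d}" for i in range(spec.n_pairs)]
    for i, sub in enumerate(subjects):
        noise = _symmetric_noise(rng, spec.subject_sd) if spec.subject_sd > 0 else None
        for cond in ("OFF", "ON"):
            cov = build_target_covariance(spec, cond, dose_z[i], noise, spatial)
            data = _sample_mvn(rng, cov, spec.n_timepoints)
            scans.append(
                ScanTimeseries(f"{sub}_{cond}", sub, cond, data, parcel_ids)
            )
    for j in range(spec.n_controls):
        sub = f"con-{j + 1:02d}"
        noise = _symmetric_noise(rng, spec.subject_sd) if spec.subject_sd > 0 else None
        cov = build_target_covariance(spec, "control", 0.0, noise, spatial)
        data = _sample_mvn(rng, cov, spec.n_timepoints)
        scans.append(ScanTimeseries(f"{sub}_rest", sub, "control", data, parcel_ids))

    dose_table = pd.DataFrame({"subject": subjects, "DDE": doses})
    return SyntheticCohort(scheme, tuple(scans), dose_table, spec)


# ---------------------------------------------------------------------------
# spatially autocorrelated annotation maps
# ---------------------------------------------------------------------------

def generate_autocorrelated_map(
    scheme: ParcelScheme,
    smoothness: float,
    seed: int = 0,
    n_maps: int = 1,
) -> np.ndarray:
    """Zero-mean unit-SD map(s) whose spatial correlation decays with distance.

    A Gaussian process with covariance ``exp(-d / smoothness)`` over
    great-circle centroid distances ``d`` (radians). Small ``smoothness``
    approaches i.i.d. values; large ``smoothness`` yields smooth maps such
    as regional gene-expression profiles. Returns a (P,) vector when
    ``n_maps == 1``, else an (n_maps, P) array.
    """
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    xyz = scheme.centroids()
    d = np.arccos(np.clip(xyz @ xyz.T, -1.0, 1.0))
    cov = np.exp(-d / smoothness)
    root = np.linalg.cholesky(cov + 1e-8 * np.eye(len(d)))
    rng = np.random.default_rng(seed)
    maps = rng.standard_normal((n_maps, len(d))) @ root.T
    maps = (maps - maps.mean(axis=1, keepdims=True)) / maps.std(axis=1, keepdims=True)
    return maps[0] if n_maps == 1 else maps
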