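"""Statistical inference for paired ON/OFF gradient analyses.

Implements the paired sign-flip permutation test (with exhaustive
enumeration when feasible), family-wise error control via the permutation
distribution of the maximum statistic, two-sample Kolmogorov-Smirnov
comparisons, Benjamini-Hochberg FDR, the state × dose linear mixed model,
and spatially constrained ("spin") association tests between regional maps.

All resampling draws flow from a counter-based Philox generator keyed by the
caller's seed, and the full draw matrix for a test is generated in one pass
in permutation-index order, so results are reproducible and independent of
any parallel execution layout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import mixedlm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .parcellation import ParcelScheme

__all__ = [
    "PermutationResult",
    "InteractionResult",
    "SpinResult",
    "KSResult",
    "paired_permutation",
    "maxstat_family",
    "ks_compare",
    "bh_fdr",
    "fit_state_dose_interaction",
    "delta_map",
    "spin_rotations",
    "spin_correlate",
    "rank_term_maps",
]


class InferenceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermutationResult:
    metric: str
    t: float
    p_uncorrected: float
    p_fwe: float
    n_permutations: int
    seed: int | None
    exhaustive: bool = False

    def __post_init__(self):
        if not (0 < self.p_uncorrected <= 1) or not (0 < self.p_fwe <= 1):
            raise InferenceError("permutation p-values must lie in (0, 1]")
        if self.p_fwe < self.p_uncorrected - 1e-12:
            raise InferenceError("p_fwe cannot be below p_uncorrected")


@dataclass(frozen=True)
class InteractionResult:
    metric: str
    estimates: dict  # fixed effects: state, dose_z, state_x_dose_z (+ raw scale)
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    p_fdr: float | None = None

    def __post_init__(self):
        if self.f_statistic < 0 or self.df_num <= 0 or self.df_den <= 0:
            raise InferenceError("invalid F statistic or degrees of freedom")


@dataclass(frozen=True)
class SpinResult:
    map_name: str
    rho: float
    p_spin: float
    n_rotations: int
    seed: int | None
    p_fdr: float | None = None

    def __post_init__(self):
        if not -1 <= self.rho <= 1:
            raise InferenceError("rho must lie in [-1, 1]")
        if not 0 < self.p_spin <= 1:
            raise InferenceError("p_spin must lie in (0, 1]")


@dataclass(frozen=True)
class KSResult:
    gradient: str
    d_statistic: float
    p_value: float
    p_fdr: float | None = None

    def __post_init__(self):
        if not 0 <= self.d_statistic <= 1:
            raise InferenceError("KS D must lie in [0, 1]")


# ---------------------------------------------------------------------------
# sign-flip permutation machinery
# ---------------------------------------------------------------------------

def _philox(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=seed))


def _sign_matrix(n: int, n_perm: int, seed: int) -> tuple[np.ndarray, bool]:
    """(B, n) matrix of ±1 sign flips; exhaustive when 2^n <= n_perm."""
    if n <= 62 and 2**n <= n_perm:
        codes = np.arange(2**n, dtype=np.uint64)
        bits = (codes[:, None] >> np.arange(n, dtype=np.uint64)) & 1
        return bits.astype(np.int8) * 2 - 1, True
    rng = _philox(seed)
    return rng.integers(0, 2, size=(n_perm, n), dtype=np.int8) * 2 - 1, False


def _flip_t_stats(diffs: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Paired t statistics for every sign-flipped copy of ``diffs``.

    Sign flips leave each squared difference unchanged, so only the mean
    varies across flips and the t statistics vectorize. A zero-variance
    flipped sample yields t = ±inf (or 0 when the mean is also zero).
    """
    n, _ = diffs.shape
    sumsq = np.sum(diffs * diffs, axis=0)
    means = signs.astype(float) @ diffs / n
    var = (sumsq - n * means**2) / (n - 1)
    var = np.clip(var, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / n)
    degenerate = var <= 1e-300
    if np.any(degenerate):
        t = np.where(
            degenerate, np.where(means == 0, 0.0, np.sign(means) * np.inf), t
        )
    return t


def _exceeds(null_abs: np.ndarray, obs_abs: float) -> np.ndarray:
    """|null| >= |obs| with a tolerance for exact ties along identical paths."""
    with np.errstate(invalid="ignore"):
        return (null_abs >= obs_abs) | np.isclose(null_abs, obs_abs, rtol=1e-10, atol=1e-12)


def maxstat_family(
    values_on: np.ndarray,
    values_off: np.ndarray,
    metrics: list[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[PermutationResult]:
    """Paired sign-flip tests over a family of metrics with max-stat FWE.

    ``values_on`` / ``values_off`` are subject × metric matrices with the
    same subjects (rows) and metrics (columns). A single set of per-subject
    sign flips is shared across metrics; each metric's ``p_fwe`` is the
    (add-one) proportion of permutations whose maximum |t| over the family
    reaches that metric's observed |t|. When ``2^n_subjects <= n_perm`` the
    flips are enumerated exhaustively and plain proportions are reported.
    """
    on = np.atleast_2d(np.asarray(values_on, float))
    off = np.atleast_2d(np.asarray(values_off, float))
    if on.shape != off.shape:
        raise InferenceError("ON and OFF matrices must have identical shape")
    n, m = on.shape
    if n < 3:
        raise InferenceError("need at least 3 paired subjects")
    if metrics is None:
        metrics = [f"metric_{j}" for j in range(m)]
    if len(metrics) != m:
        raise InferenceError("metric names do not match the number of columns")

    diffs = on - off
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero", RuntimeWarning, stacklevel=2)
    t_obs = _flip_t_stats(diffs, np.ones((1, n), dtype=np.int8))[0]

    signs, exhaustive = _sign_matrix(n, n_perm, seed)
    t_null = np.abs(_flip_t_stats(diffs, signs))
    max_null = t_null.max(axis=1)

    results = []
    b = signs.shape[0]
    for j, name in enumerate(metrics):
        obs = abs(t_obs[j])
        hits_unc = int(_exceeds(t_null[:, j], obs).sum())
        hits_fwe = int(_exceeds(max_null, obs).sum())
        if exhaustive:
            p_unc, p_fwe = hits_unc / b, hits_fwe / b
        else:
            p_unc = (1 + hits_unc) / (b + 1)
            p_fwe = (1 + hits_fwe) / (b + 1)
        results.append(
            PermutationResult(
                metric=name,
                t=float(t_obs[j]),
                p_uncorrected=min(p_unc, 1.0),
                p_fwe=min(max(p_fwe, p_unc), 1.0),
                n_permutations=b,
                seed=seed,
                exhaustive=exhaustive,
            )
        )
    return results


def paired_permutation(
    values_on,
    values_off,
    n_perm: int = 1000,
    seed: int = 0,
    metric: str = "metric",
) -> PermutationResult:
    """Two-sided paired sign-flip permutation test for one metric.

    The observed statistic is the paired t on the ON−OFF differences; the
    null is built by independent per-subject sign flips. Exhaustive
    enumeration replaces Monte Carlo sampling whenever ``2^n <= n_perm``.
    """
    on = np.asarray(values_on, float).reshape(-1, 1)
    off = np.asarray(values_off, float).reshape(-1, 1)
    if on.shape[0] != off.shape[0]:
        raise InferenceError("paired samples must have equal length")
    return maxstat_family(on, off, [metric], n_perm=n_perm, seed=seed)[0]


# ---------------------------------------------------------------------------
# KS / FDR
# ---------------------------------------------------------------------------

def ks_compare(sample_a, sample_b, gradient: str = "G1") -> KSResult:
    """Two-sample Kolmogorov-Smirnov comparison with asymptotic p-value."""
    a = np.asarray(sample_a, float).ravel()
    b = np.asarray(sample_b, float).ravel()
    if a.size == 0 or b.size == 0:
        raise InferenceError("KS comparison needs nonempty samples")
    res = stats.ks_2samp(a, b, method="asymp")
    return KSResult(gradient, float(res.statistic), float(res.pvalue))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise InferenceError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# state × dose mixed model
# ---------------------------------------------------------------------------

def fit_state_dose_interaction(
    data: pd.DataFrame,
    doses: pd.DataFrame,
    metric: str = "metric",
) -> InteractionResult:
    """Linear mixed model ``value ~ state * dose + (1 | subject)``.

    ``data`` is a long table with columns ``subject``, ``state`` ("ON"/"OFF")
    and ``value``; ``doses`` has ``subject`` and ``DDE`` (mg/day). Dose is
    z-scored across subjects before entering the interaction, so the
    interaction coefficient is per dose-SD; the raw per-mg/day coefficient
    is also reported. Fixed effects come from the REML fit (statsmodels
    MixedLM, random intercept per subject). Because the design is balanced
    (each subject contributes exactly one ON and one OFF value), the
    interaction F test is computed exactly from the regression of the
    within-subject difference on dose, with denominator df = n_subjects − 2
    (the Satterthwaite value for this design).
    """
    required = {"subject", "state", "value"}
    if not required <= set(data.columns):
        raise InferenceError(f"data must have columns {sorted(required)}")
    merged = data.merge(doses[["subject", "DDE"]], on="subject", how="left")
    if merged["DDE"].isna().any():
        missing = merged.loc[merged["DDE"].isna(), "subject"].unique().tolist()
        raise InferenceError(f"missing dose for subjects {missing[:5]}")
    counts = merged.pivot_table(index="subject", columns="state", values="value", aggfunc="count")
    if not (set(counts.columns) == {"ON", "OFF"} and (counts == 1).all().all()):
        raise InferenceError("every subject needs exactly one ON and one OFF value")
    n = counts.shape[0]
    if n < 6:
        raise InferenceError("need at least 6 subjects")
    dose_by_subject = doses.set_index("subject")["DDE"]
    dose_sd = dose_by_subject.loc[counts.index].std(ddof=1)
    if dose_sd == 0 or not np.isfinite(dose_sd):
        raise InferenceError("all doses identical: interaction is inestimable")

    merged["dose_z"] = (merged["DDE"] - dose_by_subject.loc[counts.index].mean()) / dose_sd
    merged["state_on"] = (merged["state"] == "ON").astype(float)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        fit = mixedlm(
            "value ~ state_on * dose_z", merged, groups=merged["subject"]
        ).fit(reml=True)
    params = fit.fe_params
    estimates = {
        "intercept": float(params["Intercept"]),
        "state": float(params["state_on"]),
        "dose_z": float(params["dose_z"]),
        "state_x_dose_z": float(params["state_on:dose_z"]),
        "state_x_dose_raw": float(params["state_on:dose_z"]) / float(dose_sd),
    }

    # exact interaction test in the balanced paired design
    wide = merged.pivot_table(index="subject", columns="state", values="value")
    diff = (wide["ON"] - wide["OFF"]).to_numpy()
    z = ((dose_by_subject.loc[wide.index] - dose_by_subject.loc[wide.index].mean()) / dose_sd).to_numpy()
    zc = z - z.mean()
    slope = float(zc @ diff / (zc @ zc))
    resid = diff - diff.mean() - slope * zc
    df_den = n - 2
    sigma2 = float(resid @ resid) / df_den
    se = np.sqrt(sigma2 / float(zc @ zc))
    f_stat = (slope / se) ** 2 if se > 0 else np.inf
    p = float(stats.f.sf(f_stat, 1, df_den))
    return InteractionResult(metric, estimates, float(f_stat), 1, df_den, p)


def interaction_family(
    tables: dict[str, pd.DataFrame], doses: pd.DataFrame
) -> list[InteractionResult]:
    """Fit the state × dose model per metric and FDR-adjust across metrics."""
    results = [fit_state_dose_interaction(tab, doses, metric=m) for m, tab in tables.items()]
    adj = bh_fdr([r.p_value for r in results])
    return [replace(r, p_fdr=float(a)) for r, a in zip(results, adj)]


# ---------------------------------------------------------------------------
# Δ maps and spin tests
# ---------------------------------------------------------------------------

def delta_map(gradients_on: dict, gradients_off: dict, gradient: str = "G2") -> np.ndarray:
    """Mean ON-minus-OFF change in a labeled gradient's regional scores.

    ``gradients_on`` / ``gradients_off`` map subject id → labeled
    :class:`~funcgrad.embedding.GradientSet`; subjects must pair exactly.
    """
    if set(gradients_on) != set(gradients_off):
        unpaired = set(gradients_on) ^ set(gradients_off)
        raise InferenceError(f"unpaired subjects: {sorted(unpaired)[:5]}")
    if not gradients_on:
        raise InferenceError("no subjects supplied")
    deltas = [
        gradients_on[s].axis_scores(gradient) - gradients_off[s].axis_scores(gradient)
        for s in sorted(gradients_on)
    ]
    return np.mean(deltas, axis=0)


def _random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 3, 3) Haar-uniform rotation matrices (det = +1)."""
    a = rng.standard_normal((n, 3, 3))
    q, r = np.linalg.qr(a)
    d = np.sign(np.einsum("nii->ni", r))
    d[d == 0] = 1.0
    q = q * d[:, None, :]
    neg = np.linalg.det(q) < 0
    q[neg, :, 2] *= -1
    return q


def spin_rotations(
    scheme: ParcelScheme,
    n_rotations: int = 1000,
    seed: int = 0,
    _chunk: int = 200,
) -> np.ndarray:
    """Parcel permutations from random sphere rotations (the "spin" null).

    Each rotation applies a Haar-uniform 3-D rotation to the left
    hemisphere's centroids and its x-mirrored counterpart to the right, then
    maps every original parcel to the nearest rotated parcel within its
    hemisphere (duplicates permitted). The identity permutation is excluded.
    Returns an (n_rotations, P) integer array of source indices: a null map
    is ``map[perm]``.
    """
    xyz = scheme.centroids()
    if not np.isfinite(xyz).all():
        raise InferenceError("scheme centroids contain non-finite coordinates")
    left = scheme.hemisphere_indices("L")
    right = scheme.hemisphere_indices("R")
    mirror = np.diag([-1.0, 1.0, 1.0])
    rng = _philox(seed)
    perms = np.empty((n_rotations, scheme.n_parcels), dtype=np.intp)
    filled = 0
    while filled < n_rotations:
        want = min(_chunk, n_rotations - filled)
        rot_l = _random_rotations(want, rng)
        rot_r = mirror[None] @ rot_l @ mirror[None]
        for hemi_idx, rot in ((left, rot_l), (right, rot_r)):
            coords = xyz[hemi_idx]
            rotated = np.einsum("bij,nj->bni", rot, coords)
            # nearest rotated parcel = max cosine similarity on the sphere
            sim = np.einsum("ni,bmi->bnm", coords, rotated)
            nearest = sim.argmax(axis=2)
            perms[filled : filled + want, hemi_idx] = hemi_idx[nearest]
        filled += want
    identity = np.arange(scheme.n_parcels)
    is_identity = (perms == identity).all(axis=1)
    if is_identity.any():  # vanishingly rare; redraw those rows
        redo = np.flatnonzero(is_identity)
        extra = spin_rotations(scheme, len(redo), seed=seed + 1, _chunk=_chunk)
        perms[redo] = extra
    return perms


def spin_correlate(
    map_a,
    map_b,
    rotations: np.ndarray,
    method: str = "spearman",
    map_name: str = "map",
    seed: int | None = None,
) -> SpinResult:
    """Spearman association between two maps with a spin-permutation null.

    ``map_a`` (the annotation map) is rotated; ``map_b`` (the data map)
    stays fixed. Two-sided add-one p-value.
    """
    if method != "spearman":
        raise InferenceError("only Spearman correlation is supported")
    a = np.asarray(map_a, float).ravel()
    b = np.asarray(map_b, float).ravel()
    if a.size != b.size:
        raise InferenceError("maps must cover the same parcels")
    if a.std() == 0 or b.std() == 0:
        raise InferenceError("correlation undefined for a constant map")
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)

    def _standardize(x, axis=-1):
        mu = x.mean(axis=axis, keepdims=True)
        sd = x.std(axis=axis, keepdims=True)
        return (x - mu) / sd

    za, zb = _standardize(ra), _standardize(rb)
    rho_obs = float(za @ zb / a.size)
    # permuting a map permutes its ranks (the value multiset is unchanged)
    null = _standardize(ra[rotations], axis=1) @ zb / a.size
    hits = int(_exceeds(np.abs(null), abs(rho_obs)).sum())
    p = (1 + hits) / (rotations.shape[0] + 1)
    return SpinResult(map_name, rho_obs, p, rotations.shape[0], seed)


def rank_term_maps(
    gradient_map,
    term_maps: pd.DataFrame,
    top_k: int = 5,
) -> pd.DataFrame:
    """Rank meta-analytic term maps by Spearman correlation with a gradient.

    Constant term columns are dropped with a warning. Returns the ``top_k``
    most positive and most negative terms (columns ``term``, ``rho``,
    ``direction``); no significance is claimed.
    """
    g = np.asarray(gradient_map, float).ravel()
    constant = [c for c in term_maps.columns if term_maps[c].std() == 0]
    if constant:
        warnings.warn(f"dropping constant term maps: {constant[:5]}", RuntimeWarning, stacklevel=2)
        term_maps = term_maps.drop(columns=constant)
    if term_maps.shape[1] < top_k:
        raise InferenceError("fewer usable term maps than top_k")
    rhos = {
        c: float(stats.spearmanr(g, term_maps[c].to_numpy()).statistic)
        for c in term_maps.columns
    }
    ordered = sorted(rhos.items(), key=lambda kv: kv[1], reverse=True)
    pos = [(t, r, "positive") for t, r in ordered[:top_k]]
    neg = [(t, r, "negative") for t, r in sorted(ordered[-top_k:], key=lambda kv: kv[1])]
    return pd.DataFrame(pos + neg, columns=["term", "rho", "direction"])
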