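"""Network summaries in the 3-D gradient manifold.

Each scan's first three labeled gradients span a manifold in which every
parcel is a point. Functional differentiation is quantified per network:
*within-network dispersion* is the sum of squared Euclidean distances of a
network's parcels to the network centre (the coordinate-wise median), and
*between-network dispersion* is the Euclidean distance between two network
centres. Higher between-network dispersion means the two networks occupy
more segregated territory in gradient space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .embedding import GRADIENT_AXES, GradientSet
from .parcellation import YEO7_NETWORKS, ParcelScheme

__all__ = [
    "ManifoldEmbedding",
    "DispersionSummary",
    "network_centroid",
    "within_dispersion",
    "between_dispersion",
    "dispersion_summary",
    "network_mean_scores",
    "distribution_summary",
]


class ManifoldError(ValueError):
    pass


@dataclass(frozen=True)
class ManifoldEmbedding:
    """One scan's parcels in the 3-D space of the labeled gradients."""

    scan_id: str
    coords: np.ndarray  # (P, 3), columns G1, G2, G3
    scheme: ParcelScheme

    def __post_init__(self):
        c = np.asarray(self.coords, float)
        if c.ndim != 2 or c.shape[1] != 3:
            raise ManifoldError("manifold coordinates must be a parcel × 3 matrix")
        if c.shape[0] != self.scheme.n_parcels:
            raise ManifoldError("coordinate rows do not match the parcel scheme")
        if not np.isfinite(c).all():
            raise ManifoldError("non-finite manifold coordinates")
        object.__setattr__(self, "coords", c)

    @classmethod
    def from_gradients(cls, gradients: GradientSet, scheme: ParcelScheme, scan_id: str):
        return cls(scan_id, gradients.manifold_coordinates(), scheme)


@dataclass(frozen=True)
class DispersionSummary:
    """Per-scan dispersion values: 7 within-network, 21 between-network-pair."""

    scan_id: str
    within: dict  # network -> sum of squared distances
    between: dict  # (net_a, net_b) canonical-order tuple -> distance

    def between_value(self, net_a: str, net_b: str) -> float:
        key = _canonical_pair(net_a, net_b)
        return self.between[key]

    def to_long(self) -> pd.DataFrame:
        rows = [
            {"scan_id": self.scan_id, "metric": f"within_{n}", "value": v}
            for n, v in self.within.items()
        ] + [
            {"scan_id": self.scan_id, "metric": f"between_{a}_{b}", "value": v}
            for (a, b), v in self.between.items()
        ]
        return pd.DataFrame(rows)


def _canonical_pair(net_a: str, net_b: str) -> tuple:
    order = {n: i for i, n in enumerate(YEO7_NETWORKS)}
    if net_a not in order or net_b not in order:
        raise ManifoldError(f"unknown network label in pair ({net_a}, {net_b})")
    return (net_a, net_b) if order[net_a] < order[net_b] else (net_b, net_a)


def network_centroid(embedding: ManifoldEmbedding, network: str) -> np.ndarray:
    """Coordinate-wise median of a network's parcels in manifold space.

    For an even parcel count the median is the mean of the two middle values
    (numpy convention).
    """
    try:
        idx = embedding.scheme.indices(network)
    except Exception as exc:
        raise ManifoldError(f"unknown network label: {network!r}") from exc
    if idx.size == 0:
        raise ManifoldError(f"network {network!r} has no parcels")
    return np.median(embedding.coords[idx], axis=0)


def within_dispersion(embedding: ManifoldEmbedding, network: str) -> float:
    """Sum of squared distances of the network's parcels to its centre."""
    idx = embedding.scheme.indices(network)
    centre = network_centroid(embedding, network)
    diffs = embedding.coords[idx] - centre
    return float(np.sum(diffs * diffs))


def between_dispersion(embedding: ManifoldEmbedding, net_a: str, net_b: str) -> float:
    """Euclidean distance between two networks' centres."""
    if net_a == net_b:
        raise ManifoldError("between-network dispersion needs two distinct networks")
    ca = network_centroid(embedding, net_a)
    cb = network_centroid(embedding, net_b)
    return float(np.linalg.norm(ca - cb))


def dispersion_summary(embedding: ManifoldEmbedding) -> DispersionSummary:
    """All 7 within-network and 21 between-pair dispersion values for a scan."""
    within = {n: within_dispersion(embedding, n) for n in YEO7_NETWORKS}
    between = {
        (a, b): between_dispersion(embedding, a, b)
        for a, b in ParcelScheme.network_pairs()
    }
    return DispersionSummary(embedding.scan_id, within, between)


def network_mean_scores(gradients: GradientSet, scheme: ParcelScheme) -> pd.DataFrame:
    """Mean gradient score per network per labeled gradient (network × G1..G3)."""
    coords = gradients.manifold_coordinates()
    rows = {}
    for n in YEO7_NETWORKS:
        idx = scheme.indices(n)
        rows[n] = coords[idx].mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(GRADIENT_AXES))


@dataclass(frozen=True)
class DistributionSummary:
    """Range and bimodality of a score distribution.

    Bimodality is Sarle's coefficient
    ``(skew^2 + 1) / (kurtosis + 3 (n-1)^2 / ((n-2)(n-3)))`` with excess
    kurtosis; it approaches 1/3 for a normal sample and 1 for a balanced
    two-point distribution. ``defined`` is False for a constant vector.
    """

    value_range: float
    bimodality: float
    defined: bool = True


def distribution_summary(scores) -> DistributionSummary:
    x = np.asarray(scores, float)
    n = x.size
    if n < 4:
        raise ManifoldError("distribution summary needs at least 4 values")
    rng = float(x.max() - x.min())
    if rng == 0:
        return DistributionSummary(0.0, float("nan"), defined=False)
    g1 = stats.skew(x, bias=False)
    g2 = stats.kurtosis(x, fisher=True, bias=False)
    bim = (g1**2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3)))
    return DistributionSummary(rng, float(bim))
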