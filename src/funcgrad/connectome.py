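"""From parcellated timeseries to the affinity matrix that feeds the embedding.

The recipe: Pearson correlation over z-scored parcel timeseries (the
functional connectivity matrix), row-wise retention of the top fraction of
off-diagonal entries by signed value, then cosine similarity between the
sparsified connectivity rows, with negative similarities clipped to zero so
the result is a valid affinity for the diffusion operator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .synthetic import ScanTimeseries

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectivityMatrix",
    "AffinityMatrix",
    "compute_fc",
    "threshold_rows",
    "cosine_affinity",
]


class ConnectomeError(ValueError):
    pass


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Parcel × parcel Pearson correlation matrix (symmetric, unit diagonal)."""

    values: np.ndarray
    parcel_ids: tuple

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ConnectomeError("connectivity matrix must be square")
        if not np.isfinite(v).all():
            raise ConnectomeError("connectivity matrix contains non-finite values")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ConnectomeError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ConnectomeError("connectivity matrix must have unit diagonal")
        object.__setattr__(self, "values", v)

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class AffinityMatrix:
    """Nonnegative parcel × parcel similarity matrix with provenance.

    The diagonal holds each row's self-similarity (1 for nonzero rows); it is
    not zeroed, matching the convention of cosine-affinity gradient pipelines.
    """

    values: np.ndarray
    parcel_ids: tuple
    threshold_fraction: float | None = None
    kernel: str = "cosine"

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if not np.allclose(v, v.T, atol=1e-10):
            raise ConnectomeError("affinity must be symmetric")
        if v.min() < 0 or v.max() > 1 + 1e-10:
            raise ConnectomeError("affinity values must lie in [0, 1]")
        object.__setattr__(self, "values", v)


def compute_fc(scan: ScanTimeseries) -> ConnectivityMatrix:
    """Pearson correlation matrix over z-scored parcel timeseries.

    Raises :class:`ConnectomeError` naming the parcel if any column is
    constant (zero variance).
    """
    data = scan.data
    sd = data.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [scan.parcel_ids[i] for i in bad[:5]]
        raise ConnectomeError(
            f"scan {scan.scan_id}: constant timeseries for parcel(s) {names}"
        )
    z = (data - data.mean(axis=0)) / sd
    r = np.corrcoef(z, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, tuple(scan.parcel_ids))


def mean_fc(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of connectivity matrices over a common parcel set."""
    if not matrices:
        raise ConnectomeError("need at least one connectivity matrix")
    ids = matrices[0].parcel_ids
    for m in matrices[1:]:
        if m.parcel_ids != ids:
            raise ConnectomeError("parcel schemes differ across matrices")
    avg = np.mean([m.values for m in matrices], axis=0)
    np.fill_diagonal(avg, 1.0)
    return ConnectivityMatrix(avg, ids)


def threshold_rows(fc: ConnectivityMatrix | np.ndarray, fraction: float = 0.10) -> np.ndarray:
    """Keep the top ``fraction`` of off-diagonal entries per row, zero the rest.

    Exactly ``k = round(fraction * (P - 1))`` entries survive in each row,
    selected by signed value (strong negative correlations are discarded);
    the diagonal never survives. Ties at the cutoff are broken in favour of
    the lower parcel index. The result is generally asymmetric.
    """
    values = fc.values if isinstance(fc, ConnectivityMatrix) else np.asarray(fc, float)
    p = values.shape[0]
    if not 0 < fraction < 1:
        raise ConnectomeError("fraction must lie in (0, 1)")
    k = int(round(fraction * (p - 1)))
    if k < 1:
        raise ConnectomeError(
            f"fraction {fraction} retains zero entries per row at P={p}"
        )
    work = values.copy()
    np.fill_diagonal(work, -np.inf)
    # stable argsort of the negated row -> descending values, ties by low index
    order = np.argsort(-work, axis=1, kind="stable")
    out = np.zeros_like(values)
    rows = np.repeat(np.arange(p), k)
    cols = order[:, :k].ravel()
    out[rows, cols] = values[rows, cols]
    return out


def cosine_affinity(thresholded: np.ndarray, parcel_ids=None, threshold_fraction=None) -> AffinityMatrix:
    """Cosine similarity between rows of the sparsified connectivity matrix.

    Entry (i, j) is the cosine of the angle between rows i and j; negative
    similarities are clipped to zero (the count is logged) so the output is a
    valid nonnegative affinity.
    """
    mat = np.asarray(thresholded, float)
    norms = np.linalg.norm(mat, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        names = (
            [parcel_ids[i] for i in bad[:5]] if parcel_ids is not None else bad[:5].tolist()
        )
        raise ConnectomeError(f"all-zero connectivity row(s) for parcel(s) {names}")
    unit = mat / norms[:, None]
    sim = unit @ unit.T
    n_neg = int((sim < 0).sum())
    if n_neg:
        logger.info("cosine affinity: clipped %d negative entries to 0", n_neg)
    sim = np.clip(sim, 0.0, 1.0)
    sim = (sim + sim.T) / 2.0
    if parcel_ids is None:
        parcel_ids = tuple(range(mat.shape[0]))
    return AffinityMatrix(sim, tuple(parcel_ids), threshold_fraction=threshold_fraction)
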