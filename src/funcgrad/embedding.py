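"""Diffusion-map embedding of affinity matrices and gradient alignment.

The embedding follows the standard anisotropic-diffusion construction: the
affinity W is density-normalized as W' = D^-alpha W D^-alpha (alpha controls
how strongly the sampling density shapes the operator; alpha = 0.5
approximates the Fokker-Planck/geometry-preserving normalization), turned
into a Markov transition operator by row normalization, and
eigendecomposed. The trivial constant eigenvector (eigenvalue 1) is
dropped; the i-th gradient is the i-th non-trivial right eigenvector scaled
by lambda_i / (1 - lambda_i) (the diffusion-time-0 convention of the
gradient toolboxes this pipeline emulates). Individual embeddings are made
comparable via orthogonal Procrustes alignment to a group template, and the
first three aligned components are labeled G1/G2/G3 against reference axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from scipy.linalg import orthogonal_procrustes
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh

from .connectome import AffinityMatrix, compute_fc, cosine_affinity, mean_fc, threshold_rows

__all__ = [
    "GradientSet",
    "GradientTemplate",
    "diffusion_map_embed",
    "variance_explained",
    "gradients_from_scan",
    "build_group_template",
    "procrustes_align",
    "label_gradients",
]

GRADIENT_AXES = ("G1", "G2", "G3")

#: dense eigensolver used up to this many parcels, iterative beyond
DENSE_EIG_LIMIT = 512
_EIG_TOL = 1e-10


class EmbeddingError(RuntimeError):
    pass


@dataclass(frozen=True)
class GradientSet:
    """Parcel × component embedding scores with spectral bookkeeping.

    ``labels`` maps component index → axis name ("G1" sensorimotor-to-
    association, "G2" visual-to-somatomotor, "G3" somatomotor-to-insula) once
    :func:`label_gradients` has run; ``label_rho`` stores the Spearman
    correlations with the reference axes that justified the assignment.
    """

    scores: np.ndarray  # (P, k)
    eigenvalues: np.ndarray  # (k,), descending
    variance_explained: np.ndarray  # (k,), sums to 1
    alpha: float
    parcel_ids: tuple
    aligned_to: str | None = None
    labels: dict | None = None
    label_rho: dict | None = None
    alignment_residuals: tuple | None = None  # (before, after)

    def __post_init__(self):
        s = np.asarray(self.scores, float)
        lam = np.asarray(self.eigenvalues, float)
        if s.ndim != 2 or s.shape[1] != lam.size:
            raise EmbeddingError("scores and eigenvalues are inconsistent")
        # labeling may permute components; the spectrum is descending before then
        if self.labels is None and np.any(np.diff(lam) > _EIG_TOL):
            raise EmbeddingError("eigenvalues must be descending")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "eigenvalues", lam)
        object.__setattr__(self, "variance_explained", np.asarray(self.variance_explained, float))

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def axis_scores(self, axis: str) -> np.ndarray:
        """Scores of a labeled axis ("G1"/"G2"/"G3")."""
        if not self.labels:
            raise EmbeddingError("gradients are not labeled yet")
        for idx, name in self.labels.items():
            if name == axis:
                return self.scores[:, idx]
        raise EmbeddingError(f"no component labeled {axis!r}")

    def manifold_coordinates(self) -> np.ndarray:
        """(P, 3) coordinates of the labeled G1/G2/G3 axes, in that order."""
        return np.column_stack([self.axis_scores(a) for a in GRADIENT_AXES])


@dataclass(frozen=True)
class GradientTemplate:
    """Group-level gradients plus provenance of the scans that built them."""

    gradients: GradientSet
    scan_ids: tuple
    template_id: str = "group-template"


def variance_explained(eigenvalues) -> np.ndarray:
    """Fraction of variance per component: lambda_i over the eigenvalue sum."""
    lam = np.asarray(eigenvalues, float)
    if lam.size == 0 or np.any(lam < 0):
        raise EmbeddingError("eigenvalues must be nonnegative and nonempty")
    total = lam.sum()
    if total == 0:
        raise EmbeddingError("all eigenvalues are zero")
    return lam / total


def diffusion_map_embed(
    affinity: AffinityMatrix | np.ndarray,
    alpha: float = 0.5,
    n_components: int = 10,
) -> GradientSet:
    """Diffusion-map embedding of a symmetric nonnegative affinity matrix.

    Raises :class:`EmbeddingError` if the affinity graph is disconnected
    (the component sizes are reported) or if fewer than ``n_components``
    strictly positive non-trivial eigenvalues exist.
    """
    if isinstance(affinity, AffinityMatrix):
        w = affinity.values
        parcel_ids = affinity.parcel_ids
    else:
        w = np.asarray(affinity, float)
        parcel_ids = tuple(range(w.shape[0]))
    p = w.shape[0]
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise EmbeddingError("affinity must be square")
    if not np.allclose(w, w.T, atol=1e-10):
        raise EmbeddingError("affinity must be symmetric")
    if w.min() < 0:
        raise EmbeddingError("affinity must be nonnegative")
    if not 1 <= n_components < p:
        raise EmbeddingError("need 1 <= n_components < n_parcels")

    n_comp_graph, graph_labels = connected_components(csr_matrix(w > 0), directed=False)
    if n_comp_graph > 1:
        sizes = np.bincount(graph_labels).tolist()
        raise EmbeddingError(
            f"affinity graph is disconnected ({n_comp_graph} components, sizes {sizes})"
        )

    d = w.sum(axis=1)
    w_alpha = w / np.outer(d**alpha, d**alpha)
    d_alpha = w_alpha.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d_alpha)
    # symmetric conjugate of the Markov operator P = D'^-1 W'
    sym = w_alpha * np.outer(inv_sqrt, inv_sqrt)
    sym = (sym + sym.T) / 2.0

    k = n_components + 1  # include the trivial eigenpair
    if p <= DENSE_EIG_LIMIT:
        vals, vecs = np.linalg.eigh(sym)
        vals, vecs = vals[::-1][:k], vecs[:, ::-1][:, :k]
    else:
        vals, vecs = eigsh(sym, k=k, which="LA", tol=_EIG_TOL)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]

    if abs(vals[0] - 1.0) > 1e-6:
        raise EmbeddingError("leading eigenvalue is not 1; invalid Markov operator")
    lam = vals[1:]
    if np.any(lam >= 1.0 - _EIG_TOL):
        raise EmbeddingError("repeated unit eigenvalue; affinity graph effectively disconnected")
    if np.any(lam <= 0):
        raise EmbeddingError(
            f"only {int((lam > 0).sum())} positive non-trivial eigenvalues; "
            f"reduce n_components"
        )

    # right eigenvectors of the Markov operator, unit-normalized
    phi = vecs[:, 1:] * inv_sqrt[:, None]
    phi /= np.linalg.norm(phi, axis=0, keepdims=True)
    scores = phi * (lam / (1.0 - lam))
    return GradientSet(
        scores=scores,
        eigenvalues=lam,
        variance_explained=variance_explained(lam),
        alpha=alpha,
        parcel_ids=tuple(parcel_ids),
    )


def gradients_from_scan(
    scan,
    threshold_fraction: float = 0.10,
    alpha: float = 0.5,
    n_components: int = 10,
) -> GradientSet:
    """Full single-scan recipe: FC → row threshold → cosine affinity → embed."""
    fc = compute_fc(scan)
    sparse = threshold_rows(fc, threshold_fraction)
    aff = cosine_affinity(sparse, fc.parcel_ids, threshold_fraction)
    return diffusion_map_embed(aff, alpha=alpha, n_components=n_components)


def build_group_template(
    scans,
    threshold_fraction: float = 0.10,
    alpha: float = 0.5,
    n_components: int = 10,
) -> GradientTemplate:
    """Embed the element-wise mean connectivity matrix of all scans.

    The same threshold/affinity recipe used for individual scans is applied
    to the averaged matrix, and the scans entering the average are recorded.
    """
    if len(scans) < 2:
        raise EmbeddingError("a group template needs at least 2 scans")
    fcs = [compute_fc(s) for s in scans]
    avg = mean_fc(fcs)
    sparse = threshold_rows(avg, threshold_fraction)
    aff = cosine_affinity(sparse, avg.parcel_ids, threshold_fraction)
    grads = diffusion_map_embed(aff, alpha=alpha, n_components=n_components)
    return GradientTemplate(grads, tuple(s.scan_id for s in scans))


def procrustes_align(
    individual: GradientSet,
    template: GradientTemplate | GradientSet,
    n_components: int = 10,
) -> GradientSet:
    """Orthogonally rotate/reflect individual gradients onto the template.

    No scaling and no translation are applied — only the orthogonal
    transform minimizing the Frobenius distance between the first
    ``n_components`` columns. Residuals before and after are recorded on the
    returned set.
    """
    tmpl = template.gradients if isinstance(template, GradientTemplate) else template
    tmpl_id = getattr(template, "template_id", "template")
    if individual.n_components < n_components or tmpl.n_components < n_components:
        raise EmbeddingError("both gradient sets need >= n_components components")
    if individual.parcel_ids != tmpl.parcel_ids:
        raise EmbeddingError("parcel sets differ between individual and template")
    a = individual.scores[:, :n_components]
    b = tmpl.scores[:, :n_components]
    if np.linalg.matrix_rank(a) < n_components:
        warnings.warn(
            "rank-deficient gradient scores; Procrustes alignment is best-effort",
            RuntimeWarning,
            stacklevel=2,
        )
    rot, _ = orthogonal_procrustes(a, b)
    aligned = a @ rot
    before = float(np.linalg.norm(a - b))
    after = float(np.linalg.norm(aligned - b))
    return replace(
        individual,
        scores=aligned,
        eigenvalues=individual.eigenvalues[:n_components],
        variance_explained=variance_explained(individual.eigenvalues[:n_components]),
        aligned_to=tmpl_id,
        alignment_residuals=(before, after),
    )


def label_gradients(
    aligned: GradientSet,
    reference_axes: np.ndarray,
    tie_tol: float = 1e-6,
) -> GradientSet:
    """Assign G1/G2/G3 labels to the first three components.

    Each reference axis (columns of ``reference_axes``, ordered G1, G2, G3)
    is matched greedily, without replacement, to the component with maximal
    absolute Spearman correlation; the component's sign is flipped so the
    correlation is positive. An ambiguous assignment — two candidates within
    ``tie_tol`` of the running maximum — raises :class:`EmbeddingError`.
    """
    ref = np.asarray(reference_axes, float)
    if ref.ndim != 2 or ref.shape[1] != 3 or ref.shape[0] != aligned.scores.shape[0]:
        raise EmbeddingError("reference_axes must be a parcel × 3 matrix")
    if aligned.n_components < 3:
        raise EmbeddingError("need at least 3 components to label")

    rho = np.zeros((aligned.n_components, 3))
    for i in range(aligned.n_components):
        for j in range(3):
            rho[i, j] = stats.spearmanr(aligned.scores[:, i], ref[:, j]).statistic

    assignment: dict[int, int] = {}  # component -> axis
    free_comp = set(range(aligned.n_components))
    free_axis = set(range(3))
    work = np.abs(rho)
    while free_axis:
        candidates = [(work[i, j], i, j) for i in free_comp for j in free_axis]
        candidates.sort(reverse=True)
        best, besti, bestj = candidates[0]
        # only ties competing for the same component or the same axis are
        # ambiguous; equal-strength matches on disjoint rows/columns are not
        ties = [
            (i, j)
            for v, i, j in candidates
            if best - v <= tie_tol
            and (i, j) != (besti, bestj)
            and (i == besti or j == bestj)
        ]
        if ties:
            raise EmbeddingError(
                f"ambiguous gradient labeling: component {besti}/axis {bestj} "
                f"ties with candidates {ties} at |rho|={best:.6f}"
            )
        assignment[besti] = bestj
        free_comp.discard(besti)
        free_axis.discard(bestj)

    # reorder so columns 0..2 are G1..G3; flip signs to positive correlation
    axis_to_comp = {j: i for i, j in assignment.items()}
    order = [axis_to_comp[j] for j in range(3)]
    rest = [i for i in range(aligned.n_components) if i not in order]
    new_order = order + rest
    scores = aligned.scores[:, new_order].copy()
    rho_vals = {}
    for newpos, j in enumerate(range(3)):
        r = rho[axis_to_comp[j], j]
        if r < 0:
            scores[:, newpos] *= -1
            r = -r
        rho_vals[GRADIENT_AXES[j]] = float(r)
    labels = {j: GRADIENT_AXES[j] for j in range(3)}
    return replace(
        aligned,
        scores=scores,
        eigenvalues=aligned.eigenvalues[new_order],
        variance_explained=aligned.variance_explained[new_order],
        labels=labels,
        label_rho=rho_vals,
    )
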