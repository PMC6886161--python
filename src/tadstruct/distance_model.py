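"""Contact-to-distance conversion and the R values for zero-contact pairs.

A Hi-C contact matrix splits its off-diagonal bead pairs into C1 (nonzero
contact) and C2 (zero contact).  C1 contacts are converted into target
spatial distances by the decreasing power law ``delta_ij = beta * (1/c_ij)**alpha``
(alpha defaults to 1/3, beta to 1).  C2 pairs carry no target distance; the
eq4 objective pushes them toward a reference distance R, computed either as
the graph shortest path over C1 edges (per pair) or as the maximum target
distance (one scalar).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .hic_io import ContactMatrix

__all__ = [
    "TargetDistanceModel",
    "partition_contacts",
    "contacts_to_distances",
    "shortest_path_R",
    "max_distance_R",
    "largest_connected_component",
]


@dataclass
class TargetDistanceModel:
    """Target distances on C1 plus the optional R fields used for C2."""

    delta: np.ndarray  # NaN where undefined (C2 and the diagonal)
    c1_mask: np.ndarray  # boolean, True where c_ij != 0, i != j
    alpha: float
    beta: float
    r_scalar: float | None = None
    r_matrix: np.ndarray | None = None

    @property
    def n_beads(self) -> int:
        return self.delta.shape[0]

    @property
    def c2_mask(self) -> np.ndarray:
        n = self.n_beads
        return ~self.c1_mask & ~np.eye(n, dtype=bool)


def partition_contacts(matrix: ContactMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks (c1, c2) over off-diagonal pairs; diagonal in neither."""
    c = matrix.counts
    off = ~np.eye(c.shape[0], dtype=bool)
    c1 = (c != 0) & off
    c2 = (c == 0) & off
    return c1, c2


def contacts_to_distances(
    matrix: ContactMatrix, alpha: float = 1.0 / 3.0, beta: float = 1.0
) -> TargetDistanceModel:
    """Convert contacts into target distances delta = beta*(1/c)**alpha on C1."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    c1, _ = partition_contacts(matrix)
    delta = np.full(matrix.counts.shape, np.nan)
    with np.errstate(divide="ignore"):
        delta[c1] = beta * (1.0 / matrix.counts[c1]) ** alpha
    return TargetDistanceModel(delta=delta, c1_mask=c1, alpha=alpha, beta=beta)


def _c1_graph(model: TargetDistanceModel) -> csr_matrix:
    w = np.where(model.c1_mask, np.nan_to_num(model.delta, nan=0.0), 0.0)
    return csr_matrix(w)


def shortest_path_R(model: TargetDistanceModel) -> TargetDistanceModel:
    """Set ``r_matrix`` to all-pairs shortest-path distances over C1 edges.

    Edge weights are the target distances; a disconnected contact graph is an
    error (R would be undefined across components).
    """
    graph = _c1_graph(model)
    n_comp, labels = connected_components(graph, directed=False)
    if n_comp > 1:
        groups = [list(np.flatnonzero(labels == k)) for k in range(n_comp)]
        raise ValueError(
            f"contact graph is disconnected into {n_comp} components: "
            + "; ".join(str(g[:8]) + ("..." if len(g) > 8 else "") for g in groups)
        )
    r = shortest_path(graph, method="auto", directed=False)
    return replace(model, r_matrix=r)


def max_distance_R(model: TargetDistanceModel) -> TargetDistanceModel:
    """Set ``r_scalar`` to the maximum target distance over C1."""
    if not model.c1_mask.any():
        raise ValueError("C1 is empty: no contacts, R undefined")
    return replace(model, r_scalar=float(np.nanmax(model.delta[model.c1_mask])))


def largest_connected_component(matrix: ContactMatrix) -> tuple[ContactMatrix, np.ndarray]:
    """Restrict a matrix to its largest contact-connected bead set.

    Returns the submatrix and the original bead indices kept.  Helper for
    callers whose contact graphs are disconnected (shortest_path_R and the
    eq3 objective both reject such inputs).
    """
    c1, _ = partition_contacts(matrix)
    n_comp, labels = connected_components(csr_matrix(c1.astype(float)), directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    keep = np.flatnonzero(labels == np.argmax(sizes))
    sub = matrix.counts[np.ix_(keep, keep)]
    return ContactMatrix(sub, matrix.bin_index), keep
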