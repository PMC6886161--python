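"""Structural metrics for TAD 3D structures and contact matrices.

Three metrics quantify how a TAD folds:

* **radius of gyration** — mass-weighted RMS distance of beads from their
  center of mass.  The per-bead mass can encode feature density (TSS,
  H3K4me3 peaks, RNA polII peaks) under four named schemes, so compactness
  can be measured with respect to where the features sit, not just the
  nucleotide backbone.
* **folding degree** — an Estrada-index style statistic: the chain of beads
  is lifted through three iterated line graphs so that each node of the
  third line graph indexes one dihedral angle between consecutive bead
  planes; the mean of exp(eigenvalues) of adjacency + diag(dihedrals)
  summarizes how strongly the chain is folded.
* **exponent parameter** — the magnitude of the power-law decay of mean
  contact count with genomic separation, fit on the 2D contact matrix alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .hic_io import ContactMatrix, Structure3D

__all__ = [
    "MassVector",
    "LineGraphChain",
    "MASS_SCHEMES",
    "assign_masses",
    "center_of_mass",
    "radius_of_gyration",
    "chain_graph",
    "line_graph",
    "dihedral_angles",
    "folding_degree",
    "exponent_parameter",
]

MASS_SCHEMES = ("mass_unit", "mass_TSS", "mass_or", "mass_and")


@dataclass
class MassVector:
    """Per-bead masses under a named feature scheme."""

    masses: np.ndarray
    scheme: str

    def __post_init__(self) -> None:
        m = np.asarray(self.masses, dtype=float)
        if np.any(m < 1):
            raise ValueError("all masses must be >= 1 (unit nucleotide mass included)")
        self.masses = m

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())


def assign_masses(
    n_beads: int,
    scheme: str = "mass_unit",
    tss_counts: np.ndarray | None = None,
    h3k4me3_counts: np.ndarray | None = None,
    polii_counts: np.ndarray | None = None,
) -> MassVector:
    """Build per-bead masses from feature counts.

    ``mass_unit``: 1 everywhere.  ``mass_TSS``: 1 + #TSS in the bead.
    ``mass_or``: 2 if any of TSS/H3K4me3/polII present, else 1.
    ``mass_and``: 1 + #TSS + #H3K4me3 peaks + #polII peaks.
    """
    if scheme not in MASS_SCHEMES:
        raise ValueError(f"scheme must be one of {MASS_SCHEMES}, got {scheme!r}")

    def need(vec, label):
        if vec is None:
            raise ValueError(f"scheme {scheme!r} requires {label}")
        v = np.asarray(vec, dtype=float)
        if v.shape != (n_beads,):
            raise ValueError(f"{label} must have length {n_beads}, got {v.shape}")
        if np.any(v < 0) or np.any(v != np.round(v)):
            raise ValueError(f"{label} must be nonnegative integer counts")
        return v

    if scheme == "mass_unit":
        m = np.ones(n_beads)
    elif scheme == "mass_TSS":
        m = 1.0 + need(tss_counts, "tss_counts")
    else:
        tss = need(tss_counts, "tss_counts")
        h3 = need(h3k4me3_counts, "h3k4me3_counts")
        pol = need(polii_counts, "polii_counts")
        if scheme == "mass_or":
            m = np.where(tss + h3 + pol > 0, 2.0, 1.0)
        else:  # mass_and
            m = 1.0 + tss + h3 + pol
    return MassVector(m, scheme)


def _coords(structure) -> np.ndarray:
    return structure.coords if isinstance(structure, Structure3D) else np.asarray(structure, float)


def center_of_mass(structure, masses: MassVector | np.ndarray | None = None) -> np.ndarray:
    """Mass-weighted centroid R_C, satisfying sum m_i (x_i - R_C) = 0."""
    x = _coords(structure)
    m = _mass_array(masses, x.shape[0])
    return (m[:, None] * x).sum(axis=0) / m.sum()


def _mass_array(masses, n: int) -> np.ndarray:
    if masses is None:
        return np.ones(n)
    m = masses.masses if isinstance(masses, MassVector) else np.asarray(masses, float)
    if m.shape != (n,):
        raise ValueError(f"mass vector length {m.shape} does not match {n} beads")
    if np.any(m <= 0):
        raise ValueError("masses must be positive")
    return m


def radius_of_gyration(
    structure,
    masses: MassVector | np.ndarray | None = None,
    length_normalized: bool = False,
) -> float:
    """R_g = sqrt( sum_i m_i |x_i - R_C|^2 / M ).

    By default M is the total mass.  With ``length_normalized`` the
    denominator uses total mass divided by the chain length in beads, a
    variant that rescales compactness by TAD size.
    """
    x = _coords(structure)
    n = x.shape[0]
    if n < 2:
        raise ValueError("radius of gyration needs at least 2 beads")
    m = _mass_array(masses, n)
    rc = (m[:, None] * x).sum(axis=0) / m.sum()
    moment = float((m * ((x - rc) ** 2).sum(axis=1)).sum())
    big_m = m.sum() / n if length_normalized else m.sum()
    return float(np.sqrt(moment / big_m))


# ---------------------------------------------------------------------------
# line graphs and the folding degree


@dataclass
class LineGraphChain:
    """A graph in the iterated line-graph tower, nodes labeled by bead tuples."""

    level: int
    adjacency: np.ndarray
    node_labels: list[tuple[int, ...]]

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def chain_graph(n_beads: int) -> LineGraphChain:
    """The level-0 chain: a path graph with one node per bead."""
    if n_beads < 1:
        raise ValueError("need at least 1 bead")
    adj = np.zeros((n_beads, n_beads))
    for k in range(n_beads - 1):
        adj[k, k + 1] = adj[k + 1, k] = 1.0
    return LineGraphChain(0, adj, [(k,) for k in range(n_beads)])


def line_graph(chain: LineGraphChain) -> LineGraphChain:
    """One line-graph step: nodes become edges, adjacent when they share an endpoint."""
    if chain.level >= 3:
        raise ValueError("only the first three line graphs are used")
    if chain.n_nodes < 2:
        raise ValueError("graph has fewer than 2 nodes: no edges, line graph empty")
    g = nx.from_numpy_array(chain.adjacency)
    if g.number_of_edges() == 0:
        raise ValueError("graph has no edges; line graph is empty")
    lg = nx.line_graph(g)
    edges = sorted(lg.nodes())  # edges of g as sorted (u, v) node pairs
    index = {e: k for k, e in enumerate(edges)}
    m = len(edges)
    adj = np.zeros((m, m))
    for a, b in lg.edges():
        adj[index[a], index[b]] = adj[index[b], index[a]] = 1.0
    labels = [
        tuple(sorted(set(chain.node_labels[u] + chain.node_labels[v]))) for u, v in edges
    ]
    return LineGraphChain(chain.level + 1, adj, labels)


def dihedral_angles(structure) -> np.ndarray:
    """Unsigned dihedral angles (radians, in [0, pi]) along the bead chain.

    Angle k is between the plane of beads (k, k+1, k+2) and the plane of
    (k+1, k+2, k+3); chirality is discarded.  An all-planar (trans) chain
    gives the extremal value pi.
    """
    x = _coords(structure)
    n = x.shape[0]
    if n < 4:
        raise ValueError("dihedral angles need at least 4 beads")
    b = np.diff(x, axis=0)  # bond vectors, n-1 of them
    n1 = np.cross(b[:-1], b[1:])  # plane normals, n-2 of them
    norms = np.linalg.norm(n1, axis=1)
    bad = np.flatnonzero(norms <= 1e-12)
    if bad.size:
        raise ValueError(
            f"beads {bad[0]},{bad[0] + 1},{bad[0] + 2} are collinear; dihedral undefined"
        )
    u = n1 / norms[:, None]
    cosang = np.clip((u[:-1] * u[1:]).sum(axis=1), -1.0, 1.0)
    return np.arccos(cosang)


def folding_degree(structure, normalized: bool = True) -> float:
    """Estrada-style folding degree of a bead chain.

    The third line graph of the chain has one node per dihedral angle; the
    statistic is sum_j exp(lambda_j) over the eigenvalues of
    ``S = A(L3) + diag(dihedrals)``, divided by the node count when
    ``normalized`` (default).  Larger values indicate a more folded chain.
    """
    x = _coords(structure)
    n = x.shape[0]
    if n < 4:
        raise ValueError("folding degree needs at least 4 beads")
    phi = dihedral_angles(structure)  # length n-3
    l3 = chain_graph(n)
    for _ in range(3):
        l3 = line_graph(l3)
    if l3.n_nodes != phi.size:
        raise AssertionError("third line graph node count != dihedral count")
    s = l3.adjacency + np.diag(phi)
    lam = np.linalg.eigvalsh(s)
    total = float(np.exp(lam).sum())
    return total / l3.n_nodes if normalized else total


# ---------------------------------------------------------------------------
# contact-decay exponent


def exponent_parameter(matrix: ContactMatrix, max_s: int | None = None) -> float:
    """Power-law decay exponent of mean contact count with genomic distance.

    For each separation s the mean contact over all |i-j| = s pairs is taken
    (zeros count as data); separations with mean exactly 0 are dropped, and
    the negative slope of the log10-log10 least-squares fit is returned
    (positive for decaying contacts).
    """
    c = matrix.counts
    n = c.shape[0]
    if n < 4:
        raise ValueError("exponent parameter needs at least 4 beads")
    s_max = n - 1 if max_s is None else min(max_s, n - 1)
    seps = np.arange(1, s_max + 1)
    p = np.array([np.mean(np.diagonal(c, offset=int(s))) for s in seps])
    keep = p > 0
    if keep.sum() < 3:
        raise ValueError("insufficient decay range: fewer than 3 separations with mean contact > 0")
    slope = np.polyfit(np.log10(seps[keep]), np.log10(p[keep]), 1)[0]
    return float(-slope)
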