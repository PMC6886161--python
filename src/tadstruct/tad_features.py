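"""Per-TAD feature enrichment, chromatin-state analyses and inter-TAD O/E.

Feature enrichment follows two conventions: peak-like tracks are counted
(number of peaks whose midpoint falls inside the TAD), signal tracks are
averaged on log2 scale; both are then normalized by TAD length in base
pairs.  Chromatin-state fold enrichment, |Pearson| affinities between TAD
state profiles, and spectral clustering of those affinities reproduce the
state-cluster analysis; observed/expected inter-TAD contacts use
``E_ij = R_i * R_j * N_inter`` with R_i the fraction of inter-TAD reads
associated with TAD i (each inter-TAD contact is associated with both of
its TADs, so sum_i R_i = 2 — the convention that makes the two-TAD case
give O/E = 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import SpectralClustering

from .hic_io import ContactMatrix, GenomicInterval, Structure3D

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterAssignment",
    "InterTadExpectation",
    "TADStateClustering",
    "feature_enrichment",
    "correlate_metric_feature",
    "state_fold_enrichment",
    "state_affinity",
    "spectral_cluster",
    "observed_expected_inter_tad",
    "locus_distance_profile",
]


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    k: int
    seed: int


@dataclass
class InterTadExpectation:
    """Observed, expected and O/E inter-TAD contact totals."""

    observed: np.ndarray  # T x T, diagonal unused
    r_frac: np.ndarray  # R_i, sums to 2 under the both-ends convention
    n_inter: float
    expected: np.ndarray
    oe: np.ndarray  # observed / expected, NaN where expected = 0 or on diagonal


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def feature_enrichment(
    tad: GenomicInterval, track: Sequence[GenomicInterval], mode: str = "count"
) -> float:
    """Enrichment of a feature track in one TAD, normalized by TAD length (bp).

    ``count``: peaks with midpoint inside the TAD, / length.  ``log2mean``:
    mean log2(value) over intervals overlapping the TAD (non-positive values
    excluded with a warning), / length.  Returns NaN for log2mean with no
    overlapping data.
    """
    if mode not in ("count", "log2mean"):
        raise ValueError(f"mode must be 'count' or 'log2mean', got {mode!r}")
    length = tad.length
    if mode == "count":
        k = sum(
            1
            for iv in track
            if iv.chrom == tad.chrom and tad.start <= iv.midpoint < tad.end
        )
        return k / length
    vals = []
    skipped = 0
    for iv in track:
        if iv.chrom != tad.chrom or _overlap(tad.start, tad.end, iv.start, iv.end) == 0:
            continue
        if iv.value is None or iv.value <= 0:
            skipped += 1
            continue
        vals.append(np.log2(iv.value))
    if skipped:
        warnings.warn(f"excluded {skipped} non-positive signal value(s) from log2 mean")
    if not vals:
        return float("nan")
    return float(np.mean(vals)) / length


def correlate_metric_feature(
    metric_values: Sequence[float], feature_values: Sequence[float]
) -> tuple[float, float]:
    """Pearson r and two-sided p-value (t-distribution, n-2 df); NaN pairs dropped."""
    x = np.asarray(metric_values, dtype=float)
    y = np.asarray(feature_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("metric and feature vectors must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = pearsonr(x, y)
    return float(r), float(p)


def _tad_id(tad: GenomicInterval) -> str:
    return tad.name or f"{tad.chrom}:{tad.start}-{tad.end}"


def state_fold_enrichment(
    tads: Sequence[GenomicInterval],
    segmentation: Sequence[GenomicInterval],
    states: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Fold enrichment of each chromatin state in each TAD.

    fold(t, s) = (fraction of t's bp covered by s) /
                 (fraction of all segmented bp covered by s).
    A value of 1 means the TAD matches the genome-wide state composition.
    States absent genome-wide give NaN columns.
    """
    seg_states = [iv.name for iv in segmentation]
    if any(s is None for s in seg_states):
        raise ValueError("segmentation intervals must carry state names (BED4)")
    if states is None:
        states = sorted(set(seg_states))
    genome_bp = {s: 0 for s in states}
    for iv in segmentation:
        if iv.name in genome_bp:
            genome_bp[iv.name] += iv.length
    total_bp = sum(genome_bp.values())
    if total_bp == 0:
        raise ValueError("empty segmentation")
    rows = []
    for tad in tads:
        covered = {s: 0 for s in states}
        for iv in segmentation:
            if iv.chrom != tad.chrom or iv.name not in covered:
                continue
            covered[iv.name] += _overlap(tad.start, tad.end, iv.start, iv.end)
        row = {}
        for s in states:
            if genome_bp[s] == 0:
                row[s] = float("nan")
            else:
                row[s] = (covered[s] / tad.length) / (genome_bp[s] / total_bp)
        rows.append(row)
    return pd.DataFrame(rows, index=[_tad_id(t) for t in tads], columns=list(states))


def state_affinity(profiles: pd.DataFrame | np.ndarray) -> np.ndarray:
    """T x T affinity: absolute Pearson correlation between state profiles."""
    p = profiles.to_numpy(dtype=float) if isinstance(profiles, pd.DataFrame) else np.asarray(profiles, float)
    if p.shape[0] < 2:
        raise ValueError("need at least 2 profiles")
    if p.shape[1] < 3:
        raise ValueError("profiles need at least 3 states")
    sd = p.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(p)
    a = np.abs(corr)
    if flat.size:
        warnings.warn(f"{flat.size} zero-variance profile(s); affinity rows zeroed")
        a[flat, :] = 0.0
        a[:, flat] = 0.0
    np.fill_diagonal(a, 1.0)
    a = np.nan_to_num(a, nan=0.0)
    np.fill_diagonal(a, 1.0)
    return 0.5 * (a + a.T)


def spectral_cluster(affinity: np.ndarray, k: int, seed: int = 0) -> ClusterAssignment:
    """Normalized-Laplacian spectral clustering of a precomputed affinity.

    Top-k spectral embedding followed by seeded k-means (10 restarts);
    deterministic for a fixed seed.
    """
    a = np.asarray(affinity, dtype=float)
    t = a.shape[0]
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("affinity must be square")
    if not np.allclose(a, a.T, atol=1e-9):
        raise ValueError("affinity must be symmetric")
    if np.any(a < 0):
        raise ValueError("affinity must be nonnegative")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > t:
        raise ValueError(f"k={k} exceeds number of profiles T={t}")
    sc = SpectralClustering(
        n_clusters=k,
        affinity="precomputed",
        assign_labels="kmeans",
        n_init=10,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # perfectly block-diagonal affinities are legitimately disconnected
        warnings.filterwarnings("ignore", message="Graph is not fully connected")
        labels = sc.fit_predict(a)
    return ClusterAssignment(labels=np.asarray(labels), k=k, seed=seed)


class TADStateClustering(ClusterMixin, BaseEstimator):
    """Cluster TADs by chromatin-state profile similarity (|Pearson| affinity).

    ``fit(X)`` takes a T x S matrix (or DataFrame) of per-TAD state fold
    enrichments, builds the absolute-correlation affinity and runs seeded
    spectral clustering into ``n_clusters`` groups (default 20).
    """

    def __init__(self, n_clusters: int = 20, random_state: int = 0) -> None:
        self.n_clusters = n_clusters
        self.random_state = random_state

    def fit(self, X, y=None) -> "TADStateClustering":
        self.affinity_matrix_ = state_affinity(X)
        assignment = spectral_cluster(
            self.affinity_matrix_, self.n_clusters, seed=self.random_state
        )
        self.labels_ = assignment.labels
        return self


def observed_expected_inter_tad(
    matrix: ContactMatrix, tad_of_bead: Sequence[int]
) -> InterTadExpectation:
    """Observed vs expected inter-TAD contact totals, E_ij = R_i * R_j * N_inter.

    ``tad_of_bead`` assigns every bead to a TAD (labels 0..T-1 or arbitrary
    hashables).  O_ij sums all bead-pair contacts crossing the i/j TAD
    boundary; R_i is TAD i's share of inter-TAD reads (both TADs of a
    contact are credited, so sum R_i = 2).
    """
    labels = np.asarray(tad_of_bead)
    n = matrix.n_beads
    if labels.shape != (n,):
        raise ValueError(f"tad_of_bead must have length {n}")
    uniq = np.unique(labels)
    t = uniq.size
    if t < 2:
        raise ValueError("need at least 2 TADs")
    lab_idx = np.searchsorted(uniq, labels)
    iu, ju = np.triu_indices(n, 1)
    inter = lab_idx[iu] != lab_idx[ju]
    obs = np.zeros((t, t))
    np.add.at(obs, (lab_idx[iu[inter]], lab_idx[ju[inter]]), matrix.counts[iu[inter], ju[inter]])
    obs = obs + obs.T
    n_inter = float(np.triu(obs, 1).sum())
    if n_inter == 0:
        raise ValueError("no inter-TAD reads: all contacts are intra-TAD")
    r = obs.sum(axis=1) / n_inter
    assert abs(r.sum() - 2.0) < 1e-9, "R_i convention violated"
    expected = np.outer(r, r) * n_inter
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = np.where(expected > 0, obs / expected, np.nan)
    np.fill_diagonal(oe, np.nan)
    np.fill_diagonal(expected, np.nan)
    return InterTadExpectation(obs, r, n_inter, expected, oe)


def locus_distance_profile(structure: Structure3D, focus_bead: int) -> np.ndarray:
    """Euclidean distances from one bead to every bead (0 at the focus)."""
    coords = structure.coords if isinstance(structure, Structure3D) else np.asarray(structure, float)
    n = coords.shape[0]
    if not 0 <= focus_bead < n:
        raise IndexError(f"focus bead {focus_bead} out of range for n={n}")
    return np.linalg.norm(coords - coords[focus_bead], axis=1)
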