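"""Readers/writers for Hi-C matrices, genomic intervals and 3D structures.

All genomic coordinates are 0-based half-open (UCSC BED convention); bead
``b`` of a :class:`BinIndex` covers ``[start_offset + b*resolution,
start_offset + (b+1)*resolution)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "BinIndex",
    "GenomicInterval",
    "ContactMatrix",
    "Structure3D",
    "read_dense_matrix",
    "read_coo_matrix",
    "write_dense_matrix",
    "read_bed",
    "intervals_to_bins",
    "ice_normalize",
    "write_structure",
    "read_structure",
]


class FormatError(ValueError):
    """Malformed input file (wrong shape, wrong column count, bad token)."""


@dataclass(frozen=True)
class BinIndex:
    """Fixed-resolution binning of one chromosome into beads."""

    resolution: int
    chrom: str = "chr?"
    start_offset: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")

    def bin_of(self, position: float) -> int:
        """Bin index containing a base-pair position (may be out of range)."""
        return int(np.floor((position - self.start_offset) / self.resolution))

    def bin_span(self, bead: int) -> tuple[int, int]:
        start = self.start_offset + bead * self.resolution
        return start, start + self.resolution


@dataclass
class GenomicInterval:
    """0-based half-open genomic interval with optional signal value / name."""

    chrom: str
    start: int
    end: int
    value: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative coordinate: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"start >= end: {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class ContactMatrix:
    """Symmetric nonnegative bead-pair contact counts for one chromosome/TAD.

    The diagonal is ignored by downstream modeling.  Off-diagonal zeros define
    the C2 set of bead pairs (no observed contact); nonzeros define C1.
    """

    counts: np.ndarray
    bin_index: BinIndex = field(default_factory=lambda: BinIndex(40_000))

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise FormatError(f"contact matrix must be square, got shape {c.shape}")
        if c.shape[0] < 2:
            raise ValueError("contact matrix needs at least 2 beads")
        if np.any(c < 0):
            i, j = np.unravel_index(np.argmin(c), c.shape)
            raise ValueError(f"negative contact count at ({i},{j}): {c[i, j]}")
        if not np.allclose(c, c.T, atol=1e-9, rtol=0.0):
            raise ValueError("contact matrix is not symmetric within 1e-9")
        self.counts = c

    @property
    def n_beads(self) -> int:
        return self.counts.shape[0]

    @property
    def resolution(self) -> int:
        return self.bin_index.resolution

    @property
    def chrom(self) -> str:
        return self.bin_index.chrom

    @property
    def start_offset(self) -> int:
        return self.bin_index.start_offset


@dataclass
class Structure3D:
    """A reconstructed chain of beads: n x 3 coordinates plus bin mapping."""

    coords: np.ndarray
    bin_index: BinIndex | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        x = np.asarray(self.coords, dtype=float)
        if x.ndim != 2 or x.shape[1] != 3:
            raise ValueError(f"coordinates must be n x 3, got shape {x.shape}")
        if not np.all(np.isfinite(x)):
            raise ValueError("coordinates contain non-finite values")
        self.coords = x

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    def distances(self) -> np.ndarray:
        """Full n x n matrix of pairwise Euclidean distances."""
        from scipy.spatial.distance import pdist, squareform

        return squareform(pdist(self.coords))


# ---------------------------------------------------------------------------
# contact-matrix I/O


def read_dense_matrix(
    path: str | Path,
    resolution: int = 40_000,
    chrom: str = "chr?",
    start_offset: int = 0,
) -> ContactMatrix:
    """Read a whitespace-delimited square matrix of contact counts.

    Small asymmetries (relative magnitude <= 1e-6) are repaired by averaging
    ``(M + M.T)/2``; anything larger is an error naming the worst cell.
    """
    try:
        m = np.loadtxt(path, dtype=float, ndmin=2)
    except ValueError as exc:  # ragged rows, bad tokens
        raise FormatError(f"{path}: {exc}") from exc
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise FormatError(f"{path}: matrix is not square (shape {m.shape})")
    if np.any(m < 0):
        i, j = np.unravel_index(int(np.argmin(m)), m.shape)
        raise ValueError(f"{path}: negative entry {m[i, j]} at ({i},{j})")
    asym = np.abs(m - m.T)
    scale = max(float(np.abs(m).max()), 1e-300)
    if asym.max() / scale > 1e-6:
        i, j = np.unravel_index(int(np.argmax(asym)), m.shape)
        raise ValueError(
            f"{path}: asymmetry beyond tolerance at ({i},{j}): "
            f"{m[i, j]} vs {m[j, i]}"
        )
    m = 0.5 * (m + m.T)
    return ContactMatrix(m, BinIndex(resolution, chrom, start_offset))


def read_coo_matrix(
    path: str | Path,
    n_beads: int,
    resolution: int = 40_000,
    chrom: str = "chr?",
    start_offset: int = 0,
) -> ContactMatrix:
    """Read 3-column ``i j count`` triples (0-based) into a dense symmetric matrix.

    Duplicate records for a pair are summed, and each record fills both
    triangles.
    """
    m = np.zeros((n_beads, n_beads))
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                i, j, c = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if i < 0 or j < 0 or i >= n_beads or j >= n_beads:
                raise IndexError(
                    f"{path}:{lineno}: bead index ({i},{j}) out of range for n={n_beads}"
                )
            if c < 0:
                raise ValueError(f"{path}:{lineno}: negative count {c}")
            m[i, j] += c
            if i != j:
                m[j, i] += c
    return ContactMatrix(m, BinIndex(resolution, chrom, start_offset))


def write_dense_matrix(matrix: ContactMatrix, path: str | Path) -> None:
    np.savetxt(path, matrix.counts, fmt="%.10g")


# ---------------------------------------------------------------------------
# BED-family readers

_BED_KINDS = ("bed3", "bed4-name", "bedgraph")


def read_bed(path: str | Path, kind: str = "bed3") -> list[GenomicInterval]:
    """Read BED3 / BED4-with-name / bedGraph intervals, sorted by (chrom, start)."""
    if kind not in _BED_KINDS:
        raise ValueError(f"kind must be one of {_BED_KINDS}, got {kind!r}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith(("#", "track", "browser")):
                continue
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            value = None
            name = None
            if kind == "bedgraph":
                if len(parts) < 4:
                    raise FormatError(f"{path}:{lineno}: bedGraph needs a 4th column")
                try:
                    value = float(parts[3])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric bedGraph score {parts[3]!r}"
                    ) from exc
            elif kind == "bed4-name":
                if len(parts) < 4:
                    raise FormatError(f"{path}:{lineno}: bed4-name needs a 4th column")
                name = parts[3]
            out.append(GenomicInterval(chrom, start, end, value=value, name=name))
    out.sort(key=lambda iv: (iv.chrom, iv.start))
    return out


_BIN_MODES = ("count", "sum_value", "mean_value", "any")


def intervals_to_bins(
    intervals: Sequence[GenomicInterval],
    bin_index: BinIndex,
    n_beads: int,
    mode: str = "count",
) -> np.ndarray:
    """Aggregate intervals into a length-n per-bead vector.

    ``count`` assigns each interval to the single bin containing its midpoint
    (so a peak spanning two beads is counted once); ``sum_value``/``mean_value``
    /``any`` use overlap with every bin the interval touches.  ``mean_value``
    flags data-free bins as NaN; the other modes leave them 0.
    """
    if mode not in _BIN_MODES:
        raise ValueError(f"mode must be one of {_BIN_MODES}, got {mode!r}")
    out = np.zeros(n_beads)
    cnt = np.zeros(n_beads)
    for iv in intervals:
        if iv.chrom != bin_index.chrom:
            raise ValueError(
                f"interval chrom {iv.chrom!r} does not match bin chrom {bin_index.chrom!r}"
            )
        if mode == "count":
            b = bin_index.bin_of(iv.midpoint)
            if 0 <= b < n_beads:
                out[b] += 1
            continue
        b0 = max(0, bin_index.bin_of(iv.start))
        b1 = min(n_beads - 1, bin_index.bin_of(iv.end - 1))
        for b in range(b0, b1 + 1):
            if mode == "any":
                out[b] = 1.0
            elif mode == "sum_value":
                out[b] += iv.value if iv.value is not None else 1.0
            else:  # mean_value
                out[b] += iv.value if iv.value is not None else 0.0
                cnt[b] += 1
    if mode == "mean_value":
        with np.errstate(invalid="ignore"):
            out = np.where(cnt > 0, out / np.maximum(cnt, 1), np.nan)
    return out


# ---------------------------------------------------------------------------
# ICE matrix balancing


def ice_normalize(
    matrix: ContactMatrix, max_iter: int = 200, tol: float = 1e-5
) -> ContactMatrix:
    """Iterative correction: equalize row/column marginals by repeated rescaling.

    Rows that are entirely zero in the input are left zero and excluded from
    the convergence check.  The result is scaled so the mean marginal over
    nonzero rows is 1.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be positive")
    w = matrix.counts.astype(float).copy()
    n = w.shape[0]
    nonzero = w.sum(axis=1) > 0
    converged = False
    if nonzero.any():
        for _ in range(max_iter):
            s = w.sum(axis=1)
            mean = s[nonzero].mean()
            if mean == 0:
                break
            cv = s[nonzero].std() / mean
            if cv < tol:
                converged = True
                break
            bias = np.ones(n)
            bias[nonzero] = s[nonzero] / mean
            w /= np.outer(bias, bias)
        s = w.sum(axis=1)
        mean = s[nonzero].mean()
        if mean > 0:
            w /= mean
    if not converged:
        logger.warning("ICE did not converge in %d iterations (tol=%g)", max_iter, tol)
    w = 0.5 * (w + w.T)  # guard against floating-point drift
    return ContactMatrix(w, matrix.bin_index)


# ---------------------------------------------------------------------------
# structure I/O

_STRUCT_FORMATS = ("xyz", "csv", "pdb-catrace")


def write_structure(structure: Structure3D, path: str | Path, format: str = "xyz") -> None:
    """Write bead coordinates as XYZ, CSV or a PDB CA-trace."""
    if format not in _STRUCT_FORMATS:
        raise ValueError(f"format must be one of {_STRUCT_FORMATS}, got {format!r}")
    x = structure.coords
    if not np.all(np.isfinite(x)):
        raise ValueError("structure has non-finite coordinates")
    n = structure.n_beads
    bi = structure.bin_index or BinIndex(1)
    lines: list[str] = []
    if format == "xyz":
        lines.append(str(n))
        lines.append(f"tadstruct structure {bi.chrom}")
        for k in range(n):
            lines.append(f"C {x[k, 0]:.8f} {x[k, 1]:.8f} {x[k, 2]:.8f}")
    elif format == "csv":
        lines.append("bead,chrom,start,end,x,y,z")
        for k in range(n):
            s, e = bi.bin_span(k)
            lines.append(
                f"{k},{bi.chrom},{s},{e},{x[k, 0]:.8f},{x[k, 1]:.8f},{x[k, 2]:.8f}"
            )
    else:  # pdb-catrace; coordinates must fit the 8.3 fixed-width field
        scale = 1.0
        biggest = float(np.abs(x).max()) if n else 0.0
        if biggest > 9999.0:
            scale = 9999.0 / biggest
        for k in range(n):
            lines.append(
                f"ATOM  {k + 1:5d}  CA  GLY A{k + 1:4d}    "
                f"{x[k, 0] * scale:8.3f}{x[k, 1] * scale:8.3f}{x[k, 2] * scale:8.3f}"
                f"  1.00  0.00           C"
            )
        lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_structure(path: str | Path, format: str | None = None) -> Structure3D:
    """Read a structure written by :func:`write_structure` (xyz or csv)."""
    p = Path(path)
    if format is None:
        format = "csv" if p.suffix.lower() == ".csv" else "xyz"
    text = p.read_text().strip().splitlines()
    if format == "xyz":
        n = int(text[0].split()[0])
        coords = np.array(
            [[float(v) for v in line.split()[1:4]] for line in text[2 : 2 + n]]
        )
        return Structure3D(coords)
    if format == "csv":
        rows = [line.split(",") for line in text[1:]]
        coords = np.array([[float(r[4]), float(r[5]), float(r[6])] for r in rows])
        chrom = rows[0][1]
        res = int(rows[0][3]) - int(rows[0][2])
        offset = int(rows[0][2])
        return Structure3D(coords, BinIndex(res, chrom, offset))
    raise ValueError(f"cannot read structure format {format!r}")
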