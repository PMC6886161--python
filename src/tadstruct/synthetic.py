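"""Synthetic ground-truth generators for testing every other module.

The generators produce 3D structures with known geometry, contact matrices
that are the exact inverse of the power-law contact-to-distance conversion
(so structure -> contacts -> target distances is an identity when noiseless),
feature tracks with Poisson peak counts, and planted-block chromatin-state
profiles with known cluster labels.  Everything is bit-reproducible given a
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hic_io import BinIndex, ContactMatrix, GenomicInterval, Structure3D

__all__ = [
    "SyntheticSpec",
    "make_structure",
    "structure_to_contacts",
    "make_power_law_matrix",
    "make_feature_tracks",
    "make_signal_track",
    "make_planted_state_profiles",
]

_DEFAULT_BIN = BinIndex(40_000, "chrS", 0)


@dataclass
class SyntheticSpec:
    """Declarative description of a synthetic fixture."""

    kind: str  # helix | random_walk | power_law_matrix | planted_blocks
    n_beads: int
    seed: int = 0
    params: dict = field(default_factory=dict)


def make_structure(spec: SyntheticSpec) -> Structure3D:
    """Generate a helix or self-avoiding-ish random-walk bead chain.

    Helix bead k sits at (r cos(k*twist), r sin(k*twist), k*pitch); the random
    walk takes unit steps in seeded uniform directions, resampling any step
    that would make three consecutive beads collinear.
    """
    n = spec.n_beads
    if n < 2:
        raise ValueError("need at least 2 beads")
    p = spec.params
    if spec.kind == "helix":
        radius = p.get("radius", 1.0)
        twist = p.get("twist", np.pi / 4)
        pitch = p.get("pitch", 0.3)
        k = np.arange(n)
        coords = np.column_stack(
            (radius * np.cos(k * twist), radius * np.sin(k * twist), k * pitch)
        )
        return Structure3D(coords, _DEFAULT_BIN, {"kind": "helix"})
    if spec.kind == "random_walk":
        step = p.get("step", 1.0)
        rng = np.random.default_rng(spec.seed)
        coords = np.zeros((n, 3))
        prev = None
        for k in range(1, n):
            while True:
                v = rng.normal(size=3)
                v *= step / np.linalg.norm(v)
                if prev is None or np.linalg.norm(np.cross(prev, v)) > 1e-6:
                    break
            coords[k] = coords[k - 1] + v
            prev = v
        return Structure3D(coords, _DEFAULT_BIN, {"kind": "random_walk", "seed": spec.seed})
    raise ValueError(f"unknown structure kind {spec.kind!r}")


def structure_to_contacts(
    structure: Structure3D,
    alpha: float = 1.0 / 3.0,
    beta: float = 1.0,
    noise_sd: float = 0.0,
    dropout_rate: float = 0.0,
    seed: int | None = None,
) -> ContactMatrix:
    """Contacts consistent with the distance power law: c_ij = (beta/d_ij)^(1/alpha).

    Optional multiplicative lognormal noise (sigma = noise_sd, natural-log
    scale) and symmetric pair dropout (zeroed with probability dropout_rate)
    create noisy matrices with a nonempty C2 set.  A seed is mandatory for
    any stochastic setting.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    if noise_sd < 0 or dropout_rate < 0 or dropout_rate > 1:
        raise ValueError("noise_sd >= 0 and 0 <= dropout_rate <= 1 required")
    d = structure.distances()
    n = d.shape[0]
    iu, ju = np.triu_indices(n, 1)
    if np.any(d[iu, ju] == 0):
        raise ValueError("coincident beads: zero pairwise distance")
    c = np.zeros((n, n))
    c[iu, ju] = (beta / d[iu, ju]) ** (1.0 / alpha)
    stochastic = noise_sd > 0 or dropout_rate > 0
    if stochastic:
        if seed is None:
            raise ValueError("seed is required when noise_sd or dropout_rate is nonzero")
        rng = np.random.default_rng(seed)
        if noise_sd > 0:
            c[iu, ju] *= rng.lognormal(mean=0.0, sigma=noise_sd, size=iu.size)
        if dropout_rate > 0:
            drop = rng.random(iu.size) < dropout_rate
            c[iu[drop], ju[drop]] = 0.0
    c = c + c.T
    return ContactMatrix(c, structure.bin_index or _DEFAULT_BIN)


def make_power_law_matrix(
    n: int, exponent: float, prefactor: float = 1.0
) -> ContactMatrix:
    """Contacts decaying as prefactor * |i-j|^(-exponent); diagonal 0."""
    if n < 4:
        raise ValueError("need n >= 4")
    if prefactor <= 0:
        raise ValueError("prefactor must be positive")
    idx = np.arange(n)
    s = np.abs(idx[:, None] - idx[None, :]).astype(float)
    with np.errstate(divide="ignore"):
        c = np.where(s > 0, prefactor * s ** (-exponent), 0.0)
    return ContactMatrix(c, _DEFAULT_BIN)


def make_feature_tracks(
    n_beads: int,
    bin_index: BinIndex = _DEFAULT_BIN,
    rates: dict[str, float] | None = None,
    seed: int = 0,
) -> dict[str, list[GenomicInterval]]:
    """Point-interval peak tracks with seeded Poisson counts per bead.

    ``rates`` maps feature name -> expected events per bead; each event
    becomes a 1-bp interval placed uniformly within its bead.
    """
    rates = rates if rates is not None else {"tss": 1.0, "h3k4me3": 0.5, "polii": 0.5}
    rng = np.random.default_rng(seed)
    out: dict[str, list[GenomicInterval]] = {}
    res = bin_index.resolution
    for name, rate in rates.items():
        if rate < 0:
            raise ValueError(f"rate for {name!r} must be >= 0")
        intervals: list[GenomicInterval] = []
        counts = rng.poisson(rate, size=n_beads)
        for b in range(n_beads):
            start0 = bin_index.start_offset + b * res
            for pos in np.sort(rng.integers(0, res - 1, size=counts[b])):
                intervals.append(
                    GenomicInterval(bin_index.chrom, start0 + int(pos), start0 + int(pos) + 1)
                )
        out[name] = intervals
    return out


def make_signal_track(
    n_beads: int,
    bin_index: BinIndex = _DEFAULT_BIN,
    seed: int = 0,
    mean_log2: float = 2.0,
    sd_log2: float = 1.0,
) -> list[GenomicInterval]:
    """bedGraph-style per-bead signal values drawn lognormal (base-2 parameters)."""
    rng = np.random.default_rng(seed)
    vals = 2.0 ** rng.normal(mean_log2, sd_log2, size=n_beads)
    out = []
    for b in range(n_beads):
        s, e = bin_index.bin_span(b)
        out.append(GenomicInterval(bin_index.chrom, s, e, value=float(vals[b])))
    return out


def make_planted_state_profiles(
    T: int,
    S: int = 14,
    k_blocks: int = 3,
    seed: int = 0,
    noise_sd: float = 0.05,
    max_block_corr: float = 0.4,
) -> tuple[np.ndarray, np.ndarray]:
    """Planted-block state-enrichment profiles plus their true block labels.

    Each block has its own mean enrichment vector; TAD profiles are the block
    mean plus seeded Gaussian noise.  Block means are rejection-sampled so no
    two have |Pearson r| above ``max_block_corr``, keeping the planted
    partition identifiable under the absolute-correlation affinity.
    """
    if not (2 <= k_blocks <= T):
        raise ValueError("need T >= k_blocks >= 2")
    rng = np.random.default_rng(seed)
    means: list[np.ndarray] = []
    attempts = 0
    while len(means) < k_blocks:
        cand = rng.uniform(0.2, 4.0, size=S)
        ok = True
        cc = cand - cand.mean()
        for m in means:
            mc = m - m.mean()
            r = float(cc @ mc / (np.linalg.norm(cc) * np.linalg.norm(mc)))
            if abs(r) > max_block_corr:
                ok = False
                break
        if ok:
            means.append(cand)
        attempts += 1
        if attempts > 10_000:
            raise RuntimeError("could not sample sufficiently distinct block means")
    labels = np.sort(np.arange(T) % k_blocks)
    profiles = np.stack([means[b] for b in labels]) + rng.normal(0, noise_sd, size=(T, S))
    profiles = np.clip(profiles, 1e-6, None)
    return profiles, labels
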