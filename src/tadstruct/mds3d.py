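"""Metric-MDS reconstruction of 3D bead structures from Hi-C contacts.

Three stress objectives over unordered bead pairs i<j are supported, all
functions of the inferred Euclidean distances d_ij and the target distances
delta_ij on C1 (pairs with nonzero contact):

``eq2``           sum_C1 (d - delta)^2 / delta^2
``eq3``           sum_C1 (d - delta)^2 / delta  -  gamma * sum_C2 d^2
``eq4-shortest``  eq2 term  +  sum_C2 (d - R_ij)^2 / R_ij^2   (graph shortest path)
``eq4-max``       eq2 term  +  sum_C2 (d - R)^2 / R^2         (scalar max target distance)

The eq3 regularizer pushes zero-contact (C2) pairs apart; the eq4 variants
instead pull them toward a finite reference distance R, which keeps the
objective bounded and gives C2 pairs an explicit geometry.

The optimizer is quasi-Newton (L-BFGS-B) with analytic gradients, run from
several starts: a classical-MDS (Torgerson) warm start on the shortest-path
completed target distances, then seeded random cube initializations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.sparse.csgraph import connected_components
from scipy.stats import pearsonr, spearmanr
from sklearn.base import BaseEstimator

from .distance_model import (
    TargetDistanceModel,
    contacts_to_distances,
    max_distance_R,
    shortest_path_R,
    _c1_graph,
)
from .hic_io import BinIndex, ContactMatrix, Structure3D

logger = logging.getLogger(__name__)

__all__ = [
    "MDSConfig",
    "ChromatinMDS",
    "objective_value",
    "objective_gradient",
    "reconstruct",
    "evaluate_reconstruction",
    "ReconstructionReport",
    "OBJECTIVES",
]

OBJECTIVES = ("eq2", "eq3", "eq4-shortest", "eq4-max")


@dataclass
class MDSConfig:
    """Knobs of the reconstruction: objective choice, optimizer, seeding."""

    objective: str = "eq2"
    gamma: float = 0.01
    n_restarts: int = 5
    max_iterations: int = 3000
    gradient_tolerance: float = 1e-7
    seed: int = 0
    init_scale: float | None = None  # None: mean target distance over C1

    def __post_init__(self) -> None:
        if self.objective not in OBJECTIVES:
            raise ValueError(f"objective must be one of {OBJECTIVES}, got {self.objective!r}")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class _PairTerms:
    """Flattened i<j pair data for one objective."""

    i1: np.ndarray
    j1: np.ndarray
    delta1: np.ndarray
    i2: np.ndarray
    j2: np.ndarray
    r2: np.ndarray | None  # per-C2-pair R (eq4), else None
    gamma: float
    objective: str


def _pair_terms(model: TargetDistanceModel, config: MDSConfig) -> _PairTerms:
    n = model.n_beads
    iu, ju = np.triu_indices(n, 1)
    in_c1 = model.c1_mask[iu, ju]
    i1, j1 = iu[in_c1], ju[in_c1]
    i2, j2 = iu[~in_c1], ju[~in_c1]
    delta1 = model.delta[i1, j1]
    obj = config.objective
    r2 = None
    if obj == "eq4-shortest":
        if model.r_matrix is None:
            raise ValueError("eq4-shortest requires r_matrix (run shortest_path_R)")
        r2 = model.r_matrix[i2, j2]
    elif obj == "eq4-max":
        if model.r_scalar is None:
            raise ValueError("eq4-max requires r_scalar (run max_distance_R)")
        r2 = np.full(i2.shape, model.r_scalar)
    elif obj == "eq3":
        degree = np.zeros(n, dtype=int)
        np.add.at(degree, i1, 1)
        np.add.at(degree, j1, 1)
        if np.any(degree == 0):
            bad = np.flatnonzero(degree == 0)
            raise ValueError(
                f"eq3 is unbounded below: bead(s) {bad.tolist()} have no nonzero "
                "contact; pre-filter to the largest connected component"
            )
    return _PairTerms(i1, j1, delta1, i2, j2, r2, config.gamma, obj)


def _dist(coords: np.ndarray, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    diff = coords[i] - coords[j]
    return np.sqrt((diff * diff).sum(axis=1))


def _value(coords: np.ndarray, t: _PairTerms) -> float:
    d1 = _dist(coords, t.i1, t.j1)
    if t.objective == "eq2":
        return float((((d1 - t.delta1) / t.delta1) ** 2).sum())
    if t.objective == "eq3":
        f = float(((d1 - t.delta1) ** 2 / t.delta1).sum())
        if t.i2.size:
            d2 = _dist(coords, t.i2, t.j2)
            f -= t.gamma * float((d2**2).sum())
        return f
    f = float((((d1 - t.delta1) / t.delta1) ** 2).sum())
    if t.objective.startswith("eq4") and t.i2.size:
        d2 = _dist(coords, t.i2, t.j2)
        f += float((((d2 - t.r2) / t.r2) ** 2).sum())
    return f


def _value_grad(
    coords: np.ndarray, t: _PairTerms, rng: np.random.Generator | None = None
) -> tuple[float, np.ndarray]:
    n = coords.shape[0]
    diff1 = coords[t.i1] - coords[t.j1]
    d1 = np.sqrt((diff1 * diff1).sum(axis=1))
    if np.any(d1 == 0):
        # coincident beads in an active pair: symmetric jitter, logged
        scale = float(np.mean(t.delta1)) if t.delta1.size else 1.0
        rng = rng or np.random.default_rng(0)
        coords = coords + rng.normal(scale=1e-9 * scale, size=coords.shape)
        logger.warning("coincident beads perturbed by 1e-9 * init_scale jitter")
        diff1 = coords[t.i1] - coords[t.j1]
        d1 = np.sqrt((diff1 * diff1).sum(axis=1))
    grad = np.zeros_like(coords)
    if t.objective == "eq2" or t.objective.startswith("eq4"):
        f = float((((d1 - t.delta1) / t.delta1) ** 2).sum())
        coef = 2.0 * (d1 - t.delta1) / (t.delta1**2 * d1)
    else:  # eq3
        f = float(((d1 - t.delta1) ** 2 / t.delta1).sum())
        coef = 2.0 * (d1 - t.delta1) / (t.delta1 * d1)
    contrib = coef[:, None] * diff1
    np.add.at(grad, t.i1, contrib)
    np.add.at(grad, t.j1, -contrib)
    if t.i2.size and t.objective != "eq2":
        diff2 = coords[t.i2] - coords[t.j2]
        d2 = np.sqrt((diff2 * diff2).sum(axis=1))
        if t.objective == "eq3":
            f -= t.gamma * float((d2**2).sum())
            contrib2 = -2.0 * t.gamma * diff2
        else:
            if np.any(d2 == 0):
                d2 = np.maximum(d2, 1e-300)
            f += float((((d2 - t.r2) / t.r2) ** 2).sum())
            coef2 = 2.0 * (d2 - t.r2) / (t.r2**2 * d2)
            contrib2 = coef2[:, None] * diff2
        np.add.at(grad, t.i2, contrib2)
        np.add.at(grad, t.j2, -contrib2)
    return f, grad


def objective_value(
    coords: np.ndarray, model: TargetDistanceModel, config: MDSConfig
) -> float:
    """Evaluate the configured stress objective at given n x 3 coordinates."""
    return _value(np.asarray(coords, dtype=float), _pair_terms(model, config))


def objective_gradient(
    coords: np.ndarray, model: TargetDistanceModel, config: MDSConfig
) -> np.ndarray:
    """Analytic gradient of the configured objective w.r.t. every coordinate."""
    _, g = _value_grad(np.asarray(coords, dtype=float), _pair_terms(model, config))
    return g


def _classical_mds_init(model: TargetDistanceModel) -> np.ndarray | None:
    """Torgerson embedding of the shortest-path completed target distances."""
    graph = _c1_graph(model)
    n_comp, _ = connected_components(graph, directed=False)
    if n_comp > 1:
        return None
    if model.r_matrix is not None:
        full = model.r_matrix.copy()
        full[model.c1_mask] = model.delta[model.c1_mask]
    else:
        from scipy.sparse.csgraph import shortest_path as _sp

        full = _sp(graph, directed=False)
        full[model.c1_mask] = model.delta[model.c1_mask]
    np.fill_diagonal(full, 0.0)
    n = full.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (full**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:3]
    lam = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(lam)
    if coords.shape[1] < 3:
        coords = np.pad(coords, ((0, 0), (0, 3 - coords.shape[1])))
    return coords


def _prepare_model(
    matrix: ContactMatrix, config: MDSConfig, alpha: float, beta: float
) -> TargetDistanceModel:
    model = contacts_to_distances(matrix, alpha=alpha, beta=beta)
    if not model.c1_mask.any():
        raise ValueError("no contacts: C1 is empty, nothing to reconstruct")
    if config.objective == "eq4-shortest":
        model = shortest_path_R(model)
    elif config.objective == "eq4-max":
        model = max_distance_R(model)
    return model


def reconstruct(
    matrix: ContactMatrix,
    config: MDSConfig | None = None,
    alpha: float = 1.0 / 3.0,
    beta: float = 1.0,
) -> Structure3D:
    """Reconstruct a 3D structure by minimizing the configured objective.

    Runs ``n_restarts`` local minimizations (one classical-MDS warm start when
    the contact graph is connected, the rest from seeded random cubes) and
    returns the structure with the lowest final objective.  Deterministic for
    a fixed seed.
    """
    config = config or MDSConfig()
    model = _prepare_model(matrix, config, alpha, beta)
    terms = _pair_terms(model, config)
    n = matrix.n_beads
    rng = np.random.default_rng(config.seed)
    init_scale = config.init_scale or float(np.mean(terms.delta1))

    def fun(x: np.ndarray) -> tuple[float, np.ndarray]:
        f, g = _value_grad(x.reshape(n, 3), terms, rng=rng)
        return f, g.ravel()

    warm = _classical_mds_init(model)
    best: tuple[float, np.ndarray, int] | None = None
    for restart in range(config.n_restarts):
        if restart == 0 and warm is not None:
            x0 = warm
        else:
            x0 = rng.uniform(-init_scale / 2, init_scale / 2, size=(n, 3))
        res = minimize(
            fun,
            x0.ravel(),
            jac=True,
            method="L-BFGS-B",
            options={
                "maxiter": config.max_iterations,
                "maxfun": 10 * config.max_iterations,
                "gtol": config.gradient_tolerance,
                "ftol": 1e-15,
            },
        )
        if not np.isfinite(res.fun) or not np.all(np.isfinite(res.x)):
            logger.warning("restart %d produced non-finite objective; discarded", restart)
            continue
        if best is None or res.fun < best[0]:
            best = (float(res.fun), res.x.reshape(n, 3).copy(), restart)
    if best is None:
        raise RuntimeError("all restarts failed (non-finite objectives)")
    value, coords, restart = best
    return Structure3D(
        coords,
        bin_index=matrix.bin_index,
        provenance={
            "objective": config.objective,
            "seed": config.seed,
            "restart": restart,
            "objective_value": value,
            "alpha": alpha,
            "beta": beta,
        },
    )


class ChromatinMDS(BaseEstimator):
    """Scikit-learn style estimator for Hi-C metric-MDS reconstruction.

    Parameters mirror :class:`MDSConfig`; ``fit`` accepts a
    :class:`~tadstruct.hic_io.ContactMatrix` or a square symmetric array of
    contact counts, and exposes the 3D embedding as ``embedding_``.

    Attributes
    ----------
    embedding_ : (n, 3) array of bead coordinates.
    structure_ : the fitted :class:`~tadstruct.hic_io.Structure3D`.
    model_ : the :class:`~tadstruct.distance_model.TargetDistanceModel` used.
    stress_ : final objective value.
    """

    def __init__(
        self,
        objective: str = "eq2",
        alpha: float = 1.0 / 3.0,
        beta: float = 1.0,
        gamma: float = 0.01,
        n_restarts: int = 5,
        max_iterations: int = 3000,
        gradient_tolerance: float = 1e-7,
        init_scale: float | None = None,
        random_state: int = 0,
    ) -> None:
        self.objective = objective
        self.alpha = alpha
        self.beta = beta
        self.gamma = gamma
        self.n_restarts = n_restarts
        self.max_iterations = max_iterations
        self.gradient_tolerance = gradient_tolerance
        self.init_scale = init_scale
        self.random_state = random_state

    def _config(self) -> MDSConfig:
        return MDSConfig(
            objective=self.objective,
            gamma=self.gamma,
            n_restarts=self.n_restarts,
            max_iterations=self.max_iterations,
            gradient_tolerance=self.gradient_tolerance,
            seed=self.random_state,
            init_scale=self.init_scale,
        )

    def fit(self, X, y=None) -> "ChromatinMDS":
        cm = X if isinstance(X, ContactMatrix) else ContactMatrix(np.asarray(X, float))
        config = self._config()
        st = reconstruct(cm, config, alpha=self.alpha, beta=self.beta)
        self.structure_ = st
        self.embedding_ = st.coords
        self.model_ = _prepare_model(cm, config, self.alpha, self.beta)
        self.stress_ = st.provenance["objective_value"]
        self.n_features_in_ = cm.n_beads
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).embedding_


@dataclass
class ReconstructionReport:
    """Fit statistics between a structure and its source contact matrix."""

    pearson_c1: float  # Pearson r between inferred d and target delta on C1
    rmse_c1: float  # RMSE between inferred d and target delta on C1
    spearman_c1: float  # Spearman rho between inferred d and contacts, C1 only
    spearman_all: float  # same over all off-diagonal pairs (zeros included)
    c2_min: float = float("nan")
    c2_median: float = float("nan")
    c2_max: float = float("nan")
    n_c1: int = 0
    n_c2: int = 0

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def evaluate_reconstruction(
    structure: Structure3D, model: TargetDistanceModel, matrix: ContactMatrix
) -> ReconstructionReport:
    """Distance-vs-target and distance-vs-contact agreement statistics."""
    if structure.n_beads != matrix.n_beads:
        raise ValueError("structure and matrix bead counts differ")
    d = structure.distances()
    n = matrix.n_beads
    iu, ju = np.triu_indices(n, 1)
    in_c1 = model.c1_mask[iu, ju]
    d_c1 = d[iu[in_c1], ju[in_c1]]
    delta_c1 = model.delta[iu[in_c1], ju[in_c1]]
    c_c1 = matrix.counts[iu[in_c1], ju[in_c1]]
    d_all = d[iu, ju]
    c_all = matrix.counts[iu, ju]
    if d_c1.size >= 3:
        pear = float(pearsonr(d_c1, delta_c1)[0])
        spear_c1 = float(spearmanr(d_c1, c_c1)[0])
    else:
        pear = float("nan")
        spear_c1 = float("nan")
    rmse = float(np.sqrt(np.mean((d_c1 - delta_c1) ** 2))) if d_c1.size else float("nan")
    spear_all = float(spearmanr(d_all, c_all)[0]) if d_all.size >= 3 else float("nan")
    d_c2 = d[iu[~in_c1], ju[~in_c1]]
    return ReconstructionReport(
        pearson_c1=pear,
        rmse_c1=rmse,
        spearman_c1=spear_c1,
        spearman_all=spear_all,
        c2_min=float(np.min(d_c2)) if d_c2.size else float("nan"),
        c2_median=float(np.median(d_c2)) if d_c2.size else float("nan"),
        c2_max=float(np.max(d_c2)) if d_c2.size else float("nan"),
        n_c1=int(d_c1.size),
        n_c2=int(d_c2.size),
    )
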