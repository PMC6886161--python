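import numpy as np
import pytest

from tadstruct.distance_model import (
    contacts_to_distances,
    max_distance_R,
    shortest_path_R,
)
from tadstruct.evaluation import recovery_rmsd
from tadstruct.hic_io import ContactMatrix
from tadstruct.mds3d import (
    ChromatinMDS,
    MDSConfig,
    evaluate_reconstruction,
    objective_gradient,
    objective_value,
    reconstruct,
)
from tadstruct.synthetic import SyntheticSpec, make_structure, structure_to_contacts

ALL_OBJECTIVES = ["eq2", "eq3", "eq4-shortest", "eq4-max"]


def _model_for(cm, objective):
    model = contacts_to_distances(cm)
    if objective == "eq4-shortest":
        model = shortest_path_R(model)
    elif objective == "eq4-max":
        model = max_distance_R(model)
    return model


def _random_instance(rng, n=5, dropout=0.3):
    st = make_structure(SyntheticSpec("random_walk", n, seed=int(rng.integers(2**31))))
    return structure_to_contacts(
        st, noise_sd=0.1, dropout_rate=dropout, seed=int(rng.integers(2**31))
    )


class TestObjectiveValue:
    def test_perfect_fit_eq2_is_zero(self, helix10, helix10_contacts):
        model = _model_for(helix10_contacts, "eq2")
        val = objective_value(helix10.coords, model, MDSConfig(objective="eq2"))
        assert val == pytest.approx(0.0, abs=1e-18)

    def test_single_pair_hand_value(self):
        cm = ContactMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]))  # delta = 1
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        model = _model_for(cm, "eq2")
        assert objective_value(coords, model, MDSConfig()) == pytest.approx(1.0)

    def test_eq4_hand_value_three_beads_on_line(self):
        # C1 = {(0,1),(1,2)} with delta = 1 (contacts 1); C2 = {(0,2)}, R scalar = 1
        cm = ContactMatrix(np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0.0]]))
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        model = max_distance_R(contacts_to_distances(cm))
        assert model.r_scalar == pytest.approx(1.0)
        val = objective_value(coords, model, MDSConfig(objective="eq4-max"))
        assert val == pytest.approx(1.0)  # 0 + (2-1)^2/1^2

    def test_eq3_hand_value(self):
        cm = ContactMatrix(np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0.0]]))
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        model = contacts_to_distances(cm)
        cfg = MDSConfig(objective="eq3", gamma=0.01)
        # C1 terms vanish (d = delta = 1); regularizer: -gamma * d_02^2 = -0.04
        assert objective_value(coords, model, cfg) == pytest.approx(-0.04)

    def test_eq4_without_r_field_is_error(self, small_matrix):
        model = contacts_to_distances(small_matrix)
        coords = np.zeros((3, 3))
        with pytest.raises(ValueError, match="r_scalar"):
            objective_value(coords, model, MDSConfig(objective="eq4-max"))

    def test_eq3_rejects_contactless_bead(self):
        cm = ContactMatrix(np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0.0]]))
        model = contacts_to_distances(cm)
        with pytest.raises(ValueError, match="unbounded"):
            objective_value(np.eye(3), model, MDSConfig(objective="eq3"))

    @pytest.mark.parametrize("objective", ALL_OBJECTIVES)
    def test_rigid_motion_invariance(self, rng, objective):
        cm = _random_instance(rng)
        model = _model_for(cm, objective)
        cfg = MDSConfig(objective=objective)
        coords = rng.normal(size=(cm.n_beads, 3))
        v0 = objective_value(coords, model, cfg)
        shifted = coords + np.array([3.0, -2.0, 11.0])
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1.0],
            ]
        )
        assert objective_value(shifted, model, cfg) == pytest.approx(v0, rel=1e-12)
        assert objective_value(coords @ rot.T, model, cfg) == pytest.approx(v0, rel=1e-10)

    def test_eq2_is_scale_variant(self, rng):
        cm = _random_instance(rng, dropout=0.0)
        model = _model_for(cm, "eq2")
        cfg = MDSConfig()
        coords = rng.normal(size=(cm.n_beads, 3))
        assert objective_value(2 * coords, model, cfg) != pytest.approx(
            objective_value(coords, model, cfg)
        )


class TestObjectiveGradient:
    @pytest.mark.parametrize("objective", ALL_OBJECTIVES)
    def test_matches_central_finite_differences(self, rng, objective):
        cm = _random_instance(rng, n=5)
        model = _model_for(cm, objective)
        cfg = MDSConfig(objective=objective)
        coords = rng.normal(size=(5, 3))
        g = objective_gradient(coords, model, cfg)
        h = 1e-6
        num = np.zeros_like(g)
        for i in range(5):
            for k in range(3):
                up = coords.copy()
                dn = coords.copy()
                up[i, k] += h
                dn[i, k] -= h
                num[i, k] = (
                    objective_value(up, model, cfg) - objective_value(dn, model, cfg)
                ) / (2 * h)
        scale = max(np.abs(num).max(), 1.0)
        assert np.abs(g - num).max() / scale < 1e-5

    def test_zero_gradient_at_perfect_fit(self, helix10, helix10_contacts):
        model = _model_for(helix10_contacts, "eq2")
        g = objective_gradient(helix10.coords, model, MDSConfig())
        assert np.abs(g).max() < 1e-9

    def test_translation_leaves_gradient_unchanged(self, rng):
        cm = _random_instance(rng)
        model = _model_for(cm, "eq2")
        coords = rng.normal(size=(cm.n_beads, 3))
        g0 = objective_gradient(coords, model, MDSConfig())
        g1 = objective_gradient(coords + 5.0, model, MDSConfig())
        assert np.allclose(g0, g1, atol=1e-9)


class TestReconstruct:
    def test_recovers_noiseless_helix(self, helix10, helix10_contacts):
        cfg = MDSConfig(objective="eq2", seed=11, n_restarts=3)
        rec = reconstruct(helix10_contacts, cfg)
        assert rec.provenance["objective_value"] < 1e-10
        assert recovery_rmsd(rec, helix10) < 1e-2
        model = contacts_to_distances(helix10_contacts)
        rep = evaluate_reconstruction(rec, model, helix10_contacts)
        assert rep.pearson_c1 > 0.999

    def test_deterministic_given_seed(self, helix10_contacts):
        cfg = MDSConfig(objective="eq2", seed=5, n_restarts=2)
        a = reconstruct(helix10_contacts, cfg)
        b = reconstruct(helix10_contacts, cfg)
        assert np.allclose(a.coords, b.coords, atol=1e-12)

    def test_two_bead_closed_form(self):
        cm = ContactMatrix(np.array([[0.0, 8.0], [8.0, 0.0]]))
        rec = reconstruct(cm, MDSConfig(seed=1, n_restarts=2))
        d = np.linalg.norm(rec.coords[0] - rec.coords[1])
        assert d == pytest.approx(0.5, abs=1e-6)

    def test_all_zero_matrix_is_error(self):
        cm = ContactMatrix(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="no contacts"):
            reconstruct(cm, MDSConfig())

    def test_eq4_max_c2_distances_exceed_shortest_path(self):
        st = make_structure(SyntheticSpec("random_walk", 40, seed=3))
        cm = structure_to_contacts(st, dropout_rate=0.2, seed=5)
        medians = {}
        for objective in ("eq4-max", "eq4-shortest"):
            cfg = MDSConfig(objective=objective, seed=2, n_restarts=2)
            rec = reconstruct(cm, cfg)
            rep = evaluate_reconstruction(rec, _model_for(cm, objective), cm)
            medians[objective] = rep.c2_median
        assert medians["eq4-max"] >= medians["eq4-shortest"]


class TestEstimator:
    def test_fit_exposes_sklearn_attributes(self, helix10_contacts):
        est = ChromatinMDS(objective="eq2", n_restarts=2, random_state=3)
        emb = est.fit_transform(helix10_contacts)
        assert emb.shape == (10, 3)
        assert est.embedding_ is emb
        assert est.stress_ < 1e-8
        params = est.get_params()
        assert params["objective"] == "eq2"
        est.set_params(objective="eq3")
        assert est.objective == "eq3"

    def test_accepts_raw_array(self, helix10_contacts):
        est = ChromatinMDS(n_restarts=1, random_state=0)
        est.fit(helix10_contacts.counts)
        assert est.embedding_.shape == (10, 3)


class TestEvaluateReconstruction:
    def test_perfect_fit_statistics(self, helix10, helix10_contacts):
        model = contacts_to_distances(helix10_contacts)
        rep = evaluate_reconstruction(helix10, model, helix10_contacts)
        assert rep.pearson_c1 == pytest.approx(1.0)
        assert rep.rmse_c1 == pytest.approx(0.0, abs=1e-12)
        # distances decrease in contacts, so the rank correlation is negative
        assert rep.spearman_c1 < 0

    def test_four_bead_hand_report(self):
        coords = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [2, 1, 0]])
        c = np.array(
            [
                [0, 8.0, 1.0, 0.0],
                [8.0, 0, 8.0, 1.0],
                [1.0, 8.0, 0, 8.0],
                [0.0, 1.0, 8.0, 0],
            ]
        )
        cm = ContactMatrix(c)
        model = contacts_to_distances(cm)
        rep = evaluate_reconstruction(
            __import__("tadstruct").Structure3D(coords), model, cm
        )
        # C1 pairs in i<j order: (0,1), (0,2), (1,2), (1,3), (2,3)
        d = [1.0, np.sqrt(2), 1.0, np.sqrt(2), 1.0]
        delta = [0.5, 1.0, 0.5, 1.0, 0.5]
        # independent oracle: covariance formula for Pearson r
        dx = np.array(d) - np.mean(d)
        dy = np.array(delta) - np.mean(delta)
        r_hand = (dx @ dy) / np.sqrt((dx @ dx) * (dy @ dy))
        assert rep.pearson_c1 == pytest.approx(r_hand)
        assert rep.rmse_c1 == pytest.approx(
            np.sqrt(np.mean((np.array(d) - np.array(delta)) ** 2))
        )
        assert rep.n_c1 == 5 and rep.n_c2 == 1
        assert rep.c2_median == pytest.approx(np.sqrt(5))  # beads 0 and 3

    def test_too_few_c1_pairs_reported_missing(self):
        cm = ContactMatrix(np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0.0]]))
        model = contacts_to_distances(cm)
        rep = evaluate_reconstruction(
            __import__("tadstruct").Structure3D(np.eye(3)), model, cm
        )
        assert np.isnan(rep.pearson_c1)
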