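"""Objective template, priority application, penalties and the optimizer."""

import numpy as np
import pytest
from scipy import sparse

from rtautoplan.geometry import StructureSet, VoxelGrid
from rtautoplan.objectives import (
    ObjectiveSet,
    PlanObjective,
    PriorityVector,
    apply_priorities,
    initial_priority_vector,
    load_objective_template,
    objective_value,
    template_summary,
)
from rtautoplan.optimizer import optimize_fluence


@pytest.fixture(scope="module")
def template():
    return load_objective_template()


def line_structures(n, names_masks):
    """1-D helper structure set over n voxels."""
    g = VoxelGrid((n, 1, 1), (1.0, 1.0, 1.0))
    ss = StructureSet(grid=g)
    ss.add("BODY", np.ones(g.shape, dtype=bool), "body")
    for name, idx in names_masks.items():
        m = np.zeros(g.shape, dtype=bool)
        m[idx, 0, 0] = True
        ss.add(name, m, "organ")
    return ss


class TestTemplate:
    def test_first_objective_is_ptv63_boost_coverage(self, template):
        first = template.objectives[0]
        assert (first.structure, first.dose_cGy, first.volume_pct,
                first.priority, first.objective_type) == ("PTV63", 6330.0, 99.9, 90.0, "lower")

    def test_census_counts(self, template):
        s = template_summary(template)
        assert s["n_structures"] == 26
        assert s["n_objectives"] == 47
        assert (s["n_lower"], s["n_upper"], s["n_mean"]) == (20, 18, 9)
        assert s["n_parameter_slots"] == 141
        assert (s["n_fixed"], s["n_adjustable"]) == (36, 11)
        assert s["n_shared_priority_aux"] == 3
        assert s["n_priority_slots"] == 8

    def test_every_slot_has_an_objective(self, template):
        amap = template.adjustable_map
        assert sorted(amap) == [f"P{k}" for k in range(1, 9)]
        assert all(len(v) >= 1 for v in amap.values())

    def test_unknown_structure_binds_late(self, template, mini_structures):
        # loading tolerates any structure name; binding to a phantom that
        # lacks it fails with a named error
        objs = list(template.objectives) + [
            PlanObjective(structure="Larynx", dose_cGy=100, objective_type="mean", priority=10)
        ]
        oset = ObjectiveSet(objs, template.priority_bounds, template.initial_priorities)
        bound = apply_priorities(oset, initial_priority_vector(oset))
        with pytest.raises(KeyError, match="Larynx"):
            objective_value(np.zeros(mini_structures.grid.n_voxels), bound, mini_structures)

    def test_invalid_objective_rejected(self):
        with pytest.raises(ValueError):
            PlanObjective(structure="X", dose_cGy=100, objective_type="upper", priority=10)
        with pytest.raises(ValueError):
            PlanObjective(structure="X", dose_cGy=100, objective_type="sideways",
                          priority=10, volume_pct=0)


class TestApplyPriorities:
    def test_shared_slot_updates_both_parotid_objectives(self, template):
        pv = initial_priority_vector(template).replace_slot(1, 50.0)  # P2
        out = apply_priorities(template, pv)
        hits = [o for o in out.objectives if o.placeholder == "P2"]
        assert {o.structure for o in hits} == {"L Parotid", "L Parotid_opti"}
        assert all(o.priority == 50.0 for o in hits)

    def test_idempotent(self, template):
        pv = initial_priority_vector(template)
        once = apply_priorities(template, pv)
        twice = apply_priorities(once, pv)
        assert once.objectives == twice.objectives

    def test_fixed_objectives_untouched(self, template):
        pv = initial_priority_vector(template)
        out = apply_priorities(template, pv)
        for before, after in zip(template.objectives, out.objectives):
            if before.placeholder is None:
                assert before == after

    def test_out_of_bounds_priority_rejected(self, template):
        with pytest.raises(ValueError):
            PriorityVector((0.5,) + (30.0,) * 7)
        with pytest.raises(ValueError):
            PriorityVector((101.0,) + (30.0,) * 7)


class TestObjectiveValue:
    def test_satisfying_dose_scores_zero(self):
        ss = line_structures(4, {"O": [0, 1]})
        oset = ObjectiveSet([
            PlanObjective("O", 50.0, "mean", priority=2.0),
            PlanObjective("O", 60.0, "upper", volume_pct=0, priority=3.0),
        ])
        total, per = objective_value(np.array([40.0, 50.0, 0, 0]), oset, ss)
        assert total == 0.0
        assert np.all(per == 0.0)

    def test_mean_upper_hand_arithmetic(self):
        # doses (10, 20, 30), tau = 15, lambda = 2 -> 2 * (20 - 15)^2 = 50
        ss = line_structures(3, {"O": [0, 1, 2]})
        oset = ObjectiveSet([PlanObjective("O", 15.0, "mean", priority=2.0)])
        total, per = objective_value(np.array([10.0, 20.0, 30.0]), oset, ss)
        assert total == pytest.approx(50.0)
        assert per[0] == pytest.approx(25.0)

    def test_upper_dvc_matches_voxel_loop_oracle(self):
        # upper DVC (tau, V): allowed to have V% above tau; penalize only the
        # voxels between tau and the current dose-at-volume-V
        rng = np.random.default_rng(42)
        n = 10
        ss = line_structures(n, {"O": list(range(n))})
        tau, v_pct, lam = 50.0, 30.0, 4.0
        for _ in range(20):
            d = rng.uniform(0, 100, size=n)
            oset = ObjectiveSet([PlanObjective("O", tau, "upper", volume_pct=v_pct, priority=lam)])
            total, _ = objective_value(d, oset, ss)
            k = int(np.ceil(v_pct / 100 * n))
            d_v = np.sort(d)[::-1][k - 1]
            pen = sum((x - tau) ** 2 for x in d if tau < x <= d_v) / n
            assert total == pytest.approx(lam * pen)

    def test_lower_dvc_matches_voxel_loop_oracle(self):
        rng = np.random.default_rng(7)
        n = 12
        ss = line_structures(n, {"O": list(range(n))})
        tau, v_pct, lam = 60.0, 99.0, 2.5
        for _ in range(20):
            d = rng.uniform(0, 100, size=n)
            oset = ObjectiveSet([PlanObjective("O", tau, "lower", volume_pct=v_pct, priority=lam)])
            total, _ = objective_value(d, oset, ss)
            k = min(max(int(np.ceil(v_pct / 100 * n)), 1), n)
            d_v = np.sort(d)[::-1][k - 1]
            pen = sum((x - tau) ** 2 for x in d if d_v <= x < tau) / n
            assert total == pytest.approx(lam * pen)

    def test_unresolved_placeholder_raises(self, template, mini_structures):
        with pytest.raises(ValueError, match="placeholder"):
            objective_value(np.zeros(mini_structures.grid.n_voxels), template, mini_structures)


class TestOptimizeFluence:
    def test_empty_objective_set_returns_x0(self):
        A = sparse.csr_matrix(np.eye(3))
        ss = line_structures(3, {})
        x0 = np.array([1.0, 2.0, 3.0])
        res = optimize_fluence(A, ObjectiveSet([]), ss, x0)
        np.testing.assert_array_equal(res.x, x0)

    def test_zero_mean_target_drives_dose_to_zero(self):
        rng = np.random.default_rng(0)
        A = sparse.csr_matrix(rng.random((6, 4)))
        ss = line_structures(6, {"O": list(range(6))})
        oset = ObjectiveSet([PlanObjective("O", 0.0, "mean", priority=5.0)])
        res = optimize_fluence(A, oset, ss, np.ones(4), max_iters=500, tol=1e-14)
        d = A @ res.x
        assert np.linalg.norm(d) < 1e-3

    def test_matches_closed_form_least_squares(self):
        # two beamlets, two voxels, paired lower/upper objectives pinning
        # each voxel at tau: the objective is ||A x - tau||^2-like with the
        # unique nonnegative minimizer solving A x = tau exactly
        A_dense = np.array([[1.0, 0.2], [0.3, 1.0]])
        tau = np.array([10.0, 8.0])
        x_star = np.linalg.solve(A_dense, tau)
        assert np.all(x_star >= 0)
        ss = line_structures(2, {"V0": [0], "V1": [1]})
        oset = ObjectiveSet([
            PlanObjective("V0", tau[0], "lower", volume_pct=100, priority=1.0),
            PlanObjective("V1", tau[1], "lower", volume_pct=100, priority=1.0),
            PlanObjective("V0", tau[0], "upper", volume_pct=0, priority=1.0),
            PlanObjective("V1", tau[1], "upper", volume_pct=0, priority=1.0),
        ])
        res = optimize_fluence(sparse.csr_matrix(A_dense), oset, ss,
                               np.zeros(2), max_iters=5000, tol=1e-16)
        np.testing.assert_allclose(res.x, x_star, atol=1e-4)
        np.testing.assert_allclose(A_dense @ res.x, tau, atol=1e-4)

    def test_objective_trace_is_monotone(self, mini_state):
        trace = optimize_fluence(
            mini_state.influence,
            apply_priorities(mini_state.template, mini_state.priorities),
            mini_state.structures,
            mini_state.x0,
            max_iters=50,
        ).objective_trace
        assert np.all(np.diff(trace) <= 1e-9)

    def test_negative_x0_rejected(self):
        A = sparse.csr_matrix(np.eye(2))
        ss = line_structures(2, {"O": [0]})
        oset = ObjectiveSet([PlanObjective("O", 1.0, "mean", priority=1.0)])
        with pytest.raises(ValueError):
            optimize_fluence(A, oset, ss, np.array([-1.0, 0.0]))

    def test_raising_a_priority_does_not_worsen_its_penalty(self, mini_state):
        # fixture-level monotonicity: multiply one adjustable priority by 10
        # and re-optimize; that objective's own penalty must not increase
        ss, infl, x0 = mini_state.structures, mini_state.influence, mini_state.x0
        pv = mini_state.priorities
        base_oset = apply_priorities(mini_state.template, pv)
        base = optimize_fluence(infl, base_oset, ss, x0, max_iters=120)
        slot = 1  # P2: parotid mean doses
        pv_hi = pv.replace_slot(slot, min(pv[slot] * 10, 100.0))
        hi_oset = apply_priorities(mini_state.template, pv_hi)
        hi = optimize_fluence(infl, hi_oset, ss, x0, max_iters=120)
        idxs = base_oset.adjustable_map["P2"]
        _, per_base = objective_value(infl.entries @ base.x, base_oset, ss)
        _, per_hi = objective_value(infl.entries @ hi.x, hi_oset, ss)
        assert per_hi[idxs].sum() <= per_base[idxs].sum() + 1e-9
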