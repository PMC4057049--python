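import math

import numpy as np
import pytest

from kneescrew import (
    ConstraintSet,
    Twist,
    Wrench,
    decompose_wrench,
    gen_constraint_geometry,
    grf_wrench,
    reciprocal_system,
    replace_wrench,
    screw_from_axis,
    special_config_ratios,
    transform_screw,
    virtual_coefficient,
)
from kneescrew.constraint_equilibrium import (
    CONSTRAINT_NAMES,
    InconsistentWrenchError,
    NoLeverageError,
)
from kneescrew.screw_core import ScrewError

from conftest import random_pose, random_screw


class TestReciprocalSystem:
    def test_generic_screw_leaves_fifth_order_system(self):
        s = screw_from_axis([0.1, 0.2, 0.3], [1, 2, 3], 0.01)
        basis = reciprocal_system([s])
        assert len(basis) == 5
        assert all(abs(virtual_coefficient(s, r)) < 1e-9 for r in basis)

    def test_five_lines_meeting_an_axis_return_it(self):
        # five independent lines all intersecting a chosen axis: the
        # reciprocal system is one-dimensional and is that axis
        axis = screw_from_axis([0.05, -0.1, 0.2], [0.2, 1.0, 0.4], 0.0)
        rng = np.random.default_rng(41)
        lines = [
            screw_from_axis(axis.axis_point + t * axis.d, rng.normal(size=3), 0.0)
            for t in (-0.2, -0.05, 0.0, 0.1, 0.25)
        ]
        S = np.stack([l.coords() for l in lines])
        assert np.linalg.matrix_rank(S, tol=1e-9) == 5
        basis = reciprocal_system(lines)
        assert len(basis) == 1
        found = basis[0]
        assert abs(found.d @ axis.d) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(found.axis_point, axis.axis_point, atol=1e-9)
        assert abs(found.pitch) < 1e-9

    def test_full_rank_inputs_leave_nothing(self):
        screws = [
            screw_from_axis([0, 0, 0], e, 0.0)
            for e in ([1, 0, 0], [0, 1, 0], [0, 0, 1])
        ] + [
            screw_from_axis([0, 0, 0], e, math.inf)
            for e in ([1, 0, 0], [0, 1, 0], [0, 0, 1])
        ]
        assert reciprocal_system(screws) == []

    def test_dimension_is_six_minus_rank(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            k = int(rng.integers(1, 7))
            screws = [random_screw(rng) for _ in range(k)]
            S = np.stack([s.coords() for s in screws])
            rank = np.linalg.matrix_rank(S, tol=1e-9)
            basis = reciprocal_system(screws)
            assert len(basis) == 6 - rank
            for r in basis:
                assert all(abs(virtual_coefficient(s, r)) < 1e-9 for s in screws)

    def test_invalid_tolerance_rejected(self):
        with pytest.raises(ScrewError):
            reciprocal_system([random_screw(np.random.default_rng(0))], tol=0.0)


class TestGrfWrench:
    def test_vertical_force_at_origin(self):
        w = grf_wrench([0, 0, 700.0], [0, 0, 0])
        assert w.intensity == pytest.approx(700.0)
        assert np.allclose(w.screw.d, [0, 0, 1])
        assert w.screw.pitch == pytest.approx(0.0, abs=1e-15)

    def test_offset_cop_moment_is_cop_cross_force(self):
        F, cop = np.array([0, 0, 700.0]), np.array([0.1, 0, 0])
        w = grf_wrench(F, cop)
        assert np.allclose(w.intensity * w.screw.m, np.cross(cop, F), atol=1e-9)

    def test_pure_free_moment_is_couple(self):
        w = grf_wrench([0, 0, 0], [0.2, 0.1, 0], [0, 0, 12.0])
        assert w.screw.is_infinite_pitch
        assert w.intensity == pytest.approx(12.0)

    def test_null_input_flagged(self):
        w = grf_wrench([0, 0, 0], [0, 0, 0])
        assert w.is_null and w.flagged


class TestReplaceWrench:
    def test_reciprocal_applied_wrench_needs_no_replacement(self):
        iak = screw_from_axis([0, 0, 0], [1, 0, 0], 0.0)
        phi = Wrench(screw_from_axis([0, 0.3, 0], [1, 2, 0], 0.0), 500.0)
        # phi's line meets the IAK axis -> reciprocal -> zero intensity
        assert abs(virtual_coefficient(phi.screw, iak)) < 1e-12
        eta = screw_from_axis([0, 0.1, 0.2], [0, 1, 0], 0.0)
        assert replace_wrench(phi, eta, iak) == pytest.approx(0.0, abs=1e-12)

    def test_self_replacement_negates_intensity(self):
        rng = np.random.default_rng(43)
        iak, s = random_screw(rng), random_screw(rng)
        phi = Wrench(s, 321.0)
        assert replace_wrench(phi, s, iak) == pytest.approx(-321.0, rel=1e-12)

    def test_zero_combined_virtual_work(self):
        rng = np.random.default_rng(44)
        for _ in range(100):
            iak = random_screw(rng)
            phi = Wrench(random_screw(rng), 100.0 * rng.normal())
            eta = random_screw(rng)
            if abs(virtual_coefficient(eta, iak)) < 1e-6:
                continue
            eta_int = replace_wrench(phi, eta, iak)
            work = eta_int * virtual_coefficient(eta, iak) \
                + phi.intensity * virtual_coefficient(phi.screw, iak)
            assert abs(work) < 1e-10

    def test_no_leverage_error(self):
        iak = screw_from_axis([0, 0, 0], [1, 0, 0], 0.0)
        eta = screw_from_axis([0.5, 0, 0], [0, 1, 1], 0.0)  # meets the axis
        phi = Wrench(screw_from_axis([0, 0.3, 0.1], [0, 0, 1], 0.0), 100.0)
        with pytest.raises(NoLeverageError):
            replace_wrench(phi, eta, iak)


@pytest.fixture(scope="module")
def geometry():
    return gen_constraint_geometry(3)


@pytest.fixture(scope="module")
def knee_axis(geometry):
    basis = reciprocal_system([geometry[n] for n in CONSTRAINT_NAMES])
    assert len(basis) == 1
    return basis[0]


class TestDecomposeWrench:
    def test_zero_wrench_gives_zero_intensities(self, geometry, knee_axis):
        w = Wrench(geometry["P1"], 0.0)
        sol = decompose_wrench(w, geometry, knee_axis)
        assert np.allclose(sol.as_array(), 0.0, atol=1e-12)
        assert sol.rank == 5

    def test_forward_constructed_recovery(self, geometry, knee_axis):
        # wrench built from known intensities; the minimum-norm least-squares
        # answer must match the pseudoinverse oracle and re-synthesize exactly
        A = geometry.matrix()
        x_true = np.array([20.0, 35.0, 15.0, 10.0, 420.0, 310.0])
        w6 = -(A @ x_true)
        from kneescrew import screw_from_coords
        w = Wrench(screw_from_coords(w6), float(np.linalg.norm(w6[:3])))
        sol = decompose_wrench(w, geometry, knee_axis)
        x_oracle = np.linalg.pinv(A) @ (-w.coords())
        assert np.allclose(sol.as_array(), x_oracle, atol=1e-9)
        resynth = A @ sol.as_array() + w.coords()
        assert np.linalg.norm(resynth) < 1e-9
        assert sol.medial_force == pytest.approx(sol.intensities["P1"])
        assert sol.lateral_force == pytest.approx(sol.intensities["P2"])

    def test_single_line_wrench_minimum_norm(self, geometry, knee_axis):
        # a 300 N wrench on the P1 line itself: the minimum-norm solution is
        # −300 on P1 minus the nullspace shadow (pseudoinverse oracle)
        w = Wrench(geometry["P1"], 300.0)
        sol = decompose_wrench(w, geometry, knee_axis)
        x_oracle = np.linalg.pinv(geometry.matrix()) @ (-w.coords())
        assert np.allclose(sol.as_array(), x_oracle, atol=1e-9)
        assert np.linalg.norm(geometry.matrix() @ sol.as_array() + w.coords()) < 1e-9

    def test_scaling_equivariance(self, geometry, knee_axis):
        A = geometry.matrix()
        x = np.array([5.0, 8.0, 3.0, 2.0, 100.0, 90.0])
        from kneescrew import screw_from_coords
        w6 = -(A @ x)
        w1 = Wrench(screw_from_coords(w6), float(np.linalg.norm(w6[:3])))
        w2 = Wrench(w1.screw, 2 * w1.intensity)
        s1 = decompose_wrench(w1, geometry, knee_axis)
        s2 = decompose_wrench(w2, geometry, knee_axis)
        assert np.allclose(s2.as_array(), 2 * s1.as_array(), atol=1e-9)

    def test_wrench_outside_span_rejected(self, geometry, knee_axis):
        # a couple about the flexion axis would twist the knee; no set of
        # pure-line reactions reciprocal to the axis can balance it
        couple = screw_from_axis([0, 0, 0], knee_axis.d, math.inf)
        w = Wrench(couple, 10.0)
        with pytest.raises(InconsistentWrenchError):
            decompose_wrench(w, geometry, knee_axis)

    def test_non_reciprocal_constraints_rejected(self, geometry):
        bogus_axis = screw_from_axis([0.3, 0.4, 0.1], [0, 1, 1], 0.0)
        w = Wrench(geometry["P1"], 10.0)
        with pytest.raises(ScrewError, match="not reciprocal"):
            decompose_wrench(w, geometry, bogus_axis)

    def test_zero_virtual_work_on_iak(self, geometry, knee_axis):
        # applied wrench plus reactions exchange no work with the free twist
        rng = np.random.default_rng(45)
        A = geometry.matrix()
        for _ in range(20):
            x = rng.uniform(0, 300, 6)
            from kneescrew import screw_from_coords
            w6 = -(A @ x)
            w = Wrench(screw_from_coords(w6), float(np.linalg.norm(w6[:3])))
            sol = decompose_wrench(w, geometry, knee_axis)
            total = w.coords() + A @ sol.as_array()
            vw = total[:3] @ knee_axis.m + total[3:] @ knee_axis.d
            assert abs(vw) < 1e-9

    def test_tension_at_contact_flagged(self, geometry, knee_axis):
        A = geometry.matrix()
        x = np.array([10.0, 10.0, 5.0, 5.0, -200.0, 150.0])
        x = np.linalg.pinv(A) @ (A @ x)  # row-space representative
        from kneescrew import screw_from_coords
        w6 = -(A @ x)
        w = Wrench(screw_from_coords(w6), float(np.linalg.norm(w6[:3])))
        sol = decompose_wrench(w, geometry, knee_axis)
        assert sol.inconsistent_contact

    def test_rigid_transform_carries_solution(self, geometry, knee_axis):
        # decomposition in a transformed lab frame gives identical intensities
        rng = np.random.default_rng(46)
        R, t = random_pose(rng)
        lab_geom = geometry.transformed(R, t)
        lab_axis = transform_screw(knee_axis, R, t)
        A = geometry.matrix()
        x = np.array([12.0, 22.0, 9.0, 14.0, 350.0, 260.0])
        from kneescrew import screw_from_coords
        w6 = -(A @ x)
        w = Wrench(screw_from_coords(w6), float(np.linalg.norm(w6[:3])))
        w6_lab = -(lab_geom.matrix() @ x)
        w_lab = Wrench(screw_from_coords(w6_lab), float(np.linalg.norm(w6_lab[:3])))
        s0 = decompose_wrench(w, geometry, knee_axis)
        s1 = decompose_wrench(w_lab, lab_geom, lab_axis)
        assert np.allclose(s0.as_array(), s1.as_array(), atol=1e-8)


class TestSpecialConfigRatios:
    def _twist(self, amp):
        return Twist(screw_from_axis([0, 0, 0], [0, 0, 1], 0.0), amp)

    def _wrench(self, inten):
        return Wrench(screw_from_axis([0, 0, 0], [0, 0, 1], 0.0), inten)

    def test_zero_actuator_amplitudes(self):
        rep = special_config_ratios(
            [self._twist(0.0)] * 3, self._twist(1.0),
            [self._wrench(10.0)] * 3, self._wrench(5.0))
        assert rep.ratio1 == 0.0
        assert not rep.is_special

    def test_vanishing_end_intensity_diverges(self):
        rep = special_config_ratios(
            [self._twist(0.0)] * 2, self._twist(1.0),
            [self._wrench(10.0)] * 2, self._wrench(0.0))
        assert math.isinf(rep.ratio2)
        assert rep.is_special

    def test_generic_state_finite_ratios(self):
        rep = special_config_ratios(
            [self._twist(0.5), self._twist(-0.3)], self._twist(1.2),
            [self._wrench(40.0)], self._wrench(90.0))
        assert 0 < rep.ratio1 < math.inf
        assert 0 < rep.ratio2 < math.inf
        assert not rep.is_special


class TestConstraintSet:
    def test_requires_all_named_lines(self):
        with pytest.raises(ScrewError, match="missing"):
            ConstraintSet({"ACL": screw_from_axis([0, 0, 0], [1, 0, 0], 0.0)})

    def test_rejects_nonzero_pitch_members(self, geometry):
        screws = {n: geometry[n] for n in CONSTRAINT_NAMES}
        screws["ACL"] = screw_from_axis([0, 0, 0], [1, 0, 0], 0.01)
        with pytest.raises(ScrewError, match="zero pitch"):
            ConstraintSet(screws)
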