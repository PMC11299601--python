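"""CRISP: subgradient projection, step clipping, xi auto-tuning, toy harness."""

import numpy as np
import pytest

import ptycrisp as pc
from ptycrisp.crisp import (
    DegenerateDirectionError,
    clip_G,
    crisp_direction,
    initialize_xi,
    sample_cost,
    step_size_G,
    subgradient_step,
    update_xi,
)
from ptycrisp.forward import clean_intensity, revised_exit_wave
from ptycrisp.toy import ToyProblem, run_toy_subgradient

from test_pie import random_complex, tiny_problem


class TestSampleCost:
    def test_zero_for_identical_fields(self, rng):
        psi = random_complex(rng, (4, 4))
        assert sample_cost(psi, psi) == 0.0

    def test_scalar_case(self):
        assert sample_cost(np.array([[2.0 + 0j]]), np.array([[3.0 + 0j]])) == 1.0

    def test_quadratic_homogeneity(self, rng):
        psi = random_complex(rng, (4, 4))
        psi_p = random_complex(rng, (4, 4))
        assert sample_cost(3 * psi, 3 * psi_p) == pytest.approx(
            9 * sample_cost(psi, psi_p))


class TestSubgradientStep:
    def test_below_threshold_is_identity(self):
        x = np.array([2.0, 1.0])
        out = subgradient_step(x, np.array([1.0, 0.0]), g_value=3.0, xi=4.0, lam=1.0)
        np.testing.assert_array_equal(out, x)

    def test_1d_quadratic_iteration_oracle(self):
        # g(x) = x^2, xi = 0, lam = 1: x' = x - (x^2 / (2x)^2) * 2x = x/2
        x = np.array([2.0])
        x = subgradient_step(x, np.array([4.0]), 4.0, 0.0, 1.0)
        assert x[0] == pytest.approx(1.0)
        x = subgradient_step(x, np.array([2.0]), 1.0, 0.0, 1.0)
        assert x[0] == pytest.approx(0.5)

    def test_threshold_met_at_start_is_fixed_point(self):
        x = np.array([2.0])
        out = subgradient_step(x, np.array([4.0]), g_value=4.0, xi=4.0, lam=1.0)
        np.testing.assert_array_equal(out, x)

    def test_zero_gradient_with_positive_cost_raises(self):
        with pytest.raises(DegenerateDirectionError):
            subgradient_step(np.array([1.0]), np.array([0.0]), 2.0, 0.0, 1.0)

    def test_lambda_range_enforced(self):
        with pytest.raises(ValueError):
            subgradient_step(np.array([1.0]), np.array([1.0]), 1.0, 0.0, 2.0)


class TestStepSizeG:
    def test_zero_when_cost_below_threshold(self, rng):
        Q = random_complex(rng, (3, 3))
        assert step_size_G(Q, random_complex(rng, (3, 3)), e=0.5, xi=0.5) == 0.0

    def test_scalar_oracle(self):
        # Q=2, delta=1, e=1, xi=0: G = 1 / |2*1|^2 = 1/4
        G = step_size_G(np.array([[2.0 + 0j]]), np.array([[1.0 + 0j]]), 1.0, 0.0)
        assert G == pytest.approx(0.25)

    def test_invariant_to_global_phase_of_Q(self, rng):
        Q = random_complex(rng, (4, 4))
        delta = random_complex(rng, (4, 4))
        g1 = step_size_G(Q, delta, 2.0, 0.0)
        g2 = step_size_G(Q * np.exp(0.7j), delta, 2.0, 0.0)
        assert g1 == pytest.approx(g2, rel=1e-12)

    def test_zero_denominator_with_positive_cost_raises(self):
        with pytest.raises(DegenerateDirectionError):
            step_size_G(np.zeros((2, 2), complex), np.ones((2, 2), complex), 1.0, 0.0)


class TestClipG:
    def test_below_cap_unchanged(self):
        assert clip_G(0.1, np.array([[2.0 + 0j]]), nu=1.0) == pytest.approx(0.1)

    def test_scalar_cap(self):
        # cap = nu/|Q|^2_max = 1/4
        assert clip_G(10.0, np.array([[2.0 + 0j]]), nu=1.0) == pytest.approx(0.25)

    def test_scale_adaptive_cap_is_reciprocal_max(self, rng):
        Q = random_complex(rng, (4, 4))
        qmax = np.abs(Q).max()
        assert clip_G(np.inf, Q, nu="scale_adaptive") == pytest.approx(1 / qmax)

    def test_zero_field_rejected(self):
        with pytest.raises(DegenerateDirectionError):
            clip_G(1.0, np.zeros((2, 2), complex), nu=1.0)


class TestCrispDirection:
    def test_zero_residual_gives_zero_directions(self, rng):
        O_n = random_complex(rng, (4, 4))
        P_n = random_complex(rng, (4, 4))
        D_o, D_p, e = crisp_direction(O_n, P_n, P_n * O_n, 0.0, 1.0, 1.0)
        assert e == 0.0
        assert not np.any(D_o) and not np.any(D_p)

    def test_scalar_oracle_matches_epie(self):
        # 1x1, O=1, P=2, psi'=3, xi=0, nu=1: e=1, G=1/4=cap,
        # D_o = (1/4)*2*1 = 0.5 -> O + 1*D_o = 1.5, exactly the ePIE update
        O = np.array([[1.0 + 0j]])
        P = np.array([[2.0 + 0j]])
        D_o, D_p, e = crisp_direction(O, P, np.array([[3.0 + 0j]]), 0.0, 1.0, 1.0)
        assert e == pytest.approx(1.0)
        assert D_o[0, 0] == pytest.approx(0.5)
        assert (O + 1.0 * D_o)[0, 0] == pytest.approx(1.5)
        # probe direction: G = 1/|1*1|^2 = 1, cap = 1 -> D_p = conj(O)*delta = 1
        assert D_p[0, 0] == pytest.approx(1.0)

    def test_threshold_above_cost_freezes_both(self, rng):
        O_n = random_complex(rng, (4, 4))
        P_n = random_complex(rng, (4, 4))
        psi_p = random_complex(rng, (4, 4))
        e = sample_cost(P_n * O_n, psi_p)
        D_o, D_p, _ = crisp_direction(O_n, P_n, psi_p, e + 1.0, 1.0, 1.0)
        assert not np.any(D_o) and not np.any(D_p)

    def test_clipping_dominance(self, rng):
        # applied coefficient never exceeds nu/|Q|^2_max
        for _ in range(25):
            O_n = random_complex(rng, (6, 6))
            P_n = random_complex(rng, (6, 6))
            psi_p = random_complex(rng, (6, 6)) * rng.uniform(0.1, 5)
            nu = rng.uniform(0.2, 2.0)
            D_o, D_p, e = crisp_direction(O_n, P_n, psi_p, 0.0, nu, nu)
            delta = psi_p - P_n * O_n
            coeff_o = np.abs(D_o) / np.maximum(np.abs(np.conj(P_n) * delta), 1e-300)
            cap_o = nu / np.abs(P_n).max() ** 2
            assert np.all(coeff_o <= cap_o * (1 + 1e-9))
            coeff_p = np.abs(D_p) / np.maximum(np.abs(np.conj(O_n) * delta), 1e-300)
            cap_p = nu / np.abs(O_n).max() ** 2
            assert np.all(coeff_p <= cap_p * (1 + 1e-9))


class TestXiTuning:
    def test_update_xi_is_scaled_mean(self):
        assert update_xi(np.array([1.0, 3.0]), 0.5) == 1.0
        assert update_xi(np.full(7, 2.0), 0.25) == pytest.approx(0.5)

    def test_update_xi_vanishes_with_c(self):
        e = np.array([4.0, 2.0])
        assert update_xi(e, 1e-9) == pytest.approx(0.0, abs=1e-8)

    def test_empty_errors_rejected(self):
        with pytest.raises(ValueError):
            update_xi(np.array([]), 0.5)

    def test_initialize_xi_zero_at_truth_on_clean_data(self, rng):
        ds, scan, O, P = tiny_problem(rng)
        assert initialize_xi(ds, scan, O, P, 0.5) == pytest.approx(0.0, abs=1e-20)

    def test_initialize_xi_scalar_worked_case(self):
        # single 1x1 sample: O=1, P=2 -> psi=2, I=9 -> psi'=3, e=1, xi0 = c*1
        ds = pc.DiffractionSet(np.array([[[9.0]]]))
        scan = pc.ScanPlan(np.array([[0.0, 0.0]]))
        O = pc.ObjectField(np.array([[1.0 + 0j]]))
        P = pc.ProbeField(np.array([[2.0 + 0j]]))
        assert initialize_xi(ds, scan, O, P, 0.5) == pytest.approx(0.5)
        assert initialize_xi(ds, scan, O, P, 0.1) == pytest.approx(0.1)


class TestRunCrisp:
    def test_seeded_determinism(self, rng):
        ds, scan, O, P = tiny_problem(rng)
        noisy = pc.DiffractionSet(ds.intensities * rng.uniform(0.9, 1.1, ds.intensities.shape))
        r1, _ = pc.run_crisp(noisy, scan, O, P, pc.CrispParams(K=3, seed=5, c=0.3))
        r2, _ = pc.run_crisp(noisy, scan, O, P, pc.CrispParams(K=3, seed=5, c=0.3))
        np.testing.assert_array_equal(r1.object.values, r2.object.values)
        np.testing.assert_array_equal(r1.xi_trace, r2.xi_trace)

    def test_xi_trace_is_scaled_mean_cost_exactly(self, rng):
        ds, scan, O, P = tiny_problem(rng)
        noisy = pc.DiffractionSet(ds.intensities * rng.uniform(0.8, 1.2, ds.intensities.shape))
        c = 0.3
        res, _ = pc.run_crisp(noisy, scan, O, P, pc.CrispParams(K=6, seed=2, c=c))
        np.testing.assert_array_equal(res.xi_trace, c * res.cost_trace)

    def test_fixed_point_when_threshold_exceeds_all_costs(self, rng):
        ds, scan, O, P = tiny_problem(rng)
        noisy = pc.DiffractionSet(ds.intensities * rng.uniform(0.9, 1.1, ds.intensities.shape))
        res, _ = pc.run_crisp(noisy, scan, O, P,
                              pc.CrispParams(K=2, seed=0, fixed_xi=1e12))
        np.testing.assert_array_equal(res.object.values, O.values)
        np.testing.assert_array_equal(res.probe.values, P.values)

    def test_forced_cap_with_nu_one_reproduces_epie(self, clean_sim):
        O0, P0 = pc.default_initializers(clean_sim.dataset)
        epie = pc.run_pie(clean_sim.dataset, clean_sim.scan, O0, P0,
                          pc.PieParams(alpha_o=1.0, alpha_p=0.4, K=8, seed=7), "epie")
        crisp, _ = pc.run_crisp(
            clean_sim.dataset, clean_sim.scan, O0, P0,
            pc.CrispParams(lambda_o=1.0, lambda_p=0.4, nu_o=1.0, nu_p=1.0,
                           fixed_xi=0.0, force_cap=True, K=8, seed=7))
        np.testing.assert_allclose(crisp.object.values, epie.object.values,
                                   atol=1e-10 * np.abs(epie.object.values).max())
        np.testing.assert_allclose(crisp.probe.values, epie.probe.values,
                                   atol=1e-10 * np.abs(epie.probe.values).max())


class TestToyHarness:
    def test_zero_offset_zero_threshold_converges_to_minimizer(self):
        prob = ToyProblem.quadratic_bowl(offset=0.0, start=(3.0, 2.0))
        traj = run_toy_subgradient(prob, K=200)
        assert not traj.diverged
        assert np.linalg.norm(traj.points[-1]) < 1e-6

    def test_positive_offset_zero_threshold_diverges(self):
        # flattening tails: once the step overshoots, the gradient shrinks
        # faster than the cost and the iterates run away
        prob = ToyProblem.gaussian_well(offset=1.0, xi=0.0)
        traj = run_toy_subgradient(prob, K=200)
        assert traj.diverged

    def test_bowl_with_positive_offset_never_settles(self):
        # quadratic bowl, E > 0, xi = 0: the step coefficient blows up near
        # the minimizer, so the iteration cannot converge to it
        prob = ToyProblem.quadratic_bowl(offset=1.0, xi=0.0, start=(3.0, 2.0))
        traj = run_toy_subgradient(prob, K=300)
        assert not traj.stopped_in_sublevel
        assert np.linalg.norm(traj.points[-1]) > 1e-3  # never at the minimizer
        # and the cost never drops to the offset floor
        assert traj.values[-1] > prob.offset + 1e-6

    def test_threshold_above_offset_stops_in_sublevel_set(self):
        prob = ToyProblem.quadratic_bowl(offset=1.0, xi=1.5, start=(3.0, 2.0))
        traj = run_toy_subgradient(prob, K=500)
        assert not traj.diverged
        assert traj.stopped_in_sublevel
        assert prob.g(traj.points[-1]) <= prob.xi

    def test_clipping_tames_the_divergent_case(self):
        prob = ToyProblem.gaussian_well(offset=1.0, xi=0.0)
        traj = run_toy_subgradient(prob, clip=1.0, K=200)
        assert not traj.diverged
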