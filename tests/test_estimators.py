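"""Free-energy estimators against analytic and cross-estimator oracles."""

import numpy as np
import pytest

import fepensemble as fe
from fepensemble.estimators import ReducedPotentialSet, mbar_uncertainty


def _works(data, i=0, j=1):
    """Forward/reverse reduced works between two sampled states."""
    ci, cj = data.sample_slice(i), data.sample_slice(j)
    wf = data.u_kn[j, ci] - data.u_kn[i, ci]
    wr = data.u_kn[i, cj] - data.u_kn[j, cj]
    return wf, wr


class TestMBAR:
    def test_identical_states_give_zero(self):
        rng = np.random.default_rng(0)
        u = np.tile(rng.normal(size=300), (3, 1))
        data = ReducedPotentialSet(u, n_k=[100, 100, 100])
        f = fe.mbar_solve(data)
        assert np.allclose(f.f_k, 0.0, atol=1e-8)

    def test_harmonic_pair_recovers_analytic(self, harmonic_pair):
        data, exact, f = harmonic_pair
        assert f.delta_f() == pytest.approx(
            exact.delta_f(), abs=3 * f.delta_f_sigma()
        )

    def test_translation_invariance_of_harmonic_free_energy(self):
        # equal stiffness, centers 0 and 5: exact Δf = 0 despite tiny overlap
        spec = fe.HarmonicSchedule(
            stiffness=[1.0, 1.0, 1.0], offsets=[0.0, 2.5, 5.0],
            samples_per_state=5_000, seed=9,
        )
        data, exact = fe.gen_harmonic_alchemy(spec)
        assert exact.delta_f() == 0.0
        f = fe.mbar_solve(data)
        assert abs(f.delta_f()) <= 3 * f.delta_f_sigma()

    def test_matches_bar_at_two_states(self, harmonic_pair):
        data, _, f = harmonic_pair
        wf, wr = _works(data)
        assert f.delta_f() == pytest.approx(
            fe.bar_estimate(wf, wr), abs=1e-7
        )

    def test_path_additivity_and_antisymmetry(self):
        spec = fe.HarmonicSchedule(
            stiffness=[1.0, 2.0, 4.0], offsets=[0.0, 0.0, 0.0],
            samples_per_state=2_000, seed=3,
        )
        data, _ = fe.gen_harmonic_alchemy(spec)
        f = fe.mbar_solve(data)
        assert f.delta_f(0, 2) == pytest.approx(
            f.delta_f(0, 1) + f.delta_f(1, 2), abs=1e-12
        )
        assert f.delta_f(2, 0) == pytest.approx(-f.delta_f(0, 2), abs=1e-12)

    def test_sample_order_permutation_invariance(self):
        spec = fe.HarmonicSchedule(
            stiffness=[1.0, 3.0], offsets=[0.0, 0.5], samples_per_state=1_000, seed=5
        )
        data, _ = fe.gen_harmonic_alchemy(spec)
        rng = np.random.default_rng(1)
        # permute within each state block so n_k attribution stays valid
        perm = np.concatenate(
            [rng.permutation(1000), 1000 + rng.permutation(1000)]
        )
        shuffled = ReducedPotentialSet(data.u_kn[:, perm], n_k=data.n_k)
        f1 = fe.mbar_solve(data)
        f2 = fe.mbar_solve(shuffled)
        assert f1.delta_f() == pytest.approx(f2.delta_f(), abs=1e-7)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            ReducedPotentialSet(np.array([[0.0, np.inf], [0.0, 0.0]]), n_k=[1, 1])

    def test_nonconvergence_raises_with_residual(self, harmonic_pair):
        data, _, _ = harmonic_pair
        with pytest.raises(fe.ConvergenceError) as exc:
            fe.mbar_solve(data, tolerance=0.0, max_iterations=2)
        assert exc.value.residual is not None


class TestUncertainty:
    def test_identical_states_sigma_vanishes(self):
        # perfectly correlated states carry no uncertainty on their Δf
        rng = np.random.default_rng(2)
        n = 5_000
        u = np.tile(rng.normal(size=2 * n), (2, 1))
        f = fe.mbar_solve(ReducedPotentialSet(u, n_k=[n, n]))
        assert f.delta_f_sigma() <= 1e-4

    def test_sigma_calibrated_against_seed_scatter(self):
        """Empirical sd of Δf over repeated draws within 30% of reported σ."""
        estimates, sigmas = [], []
        for seed in range(150):
            spec = fe.HarmonicSchedule(
                stiffness=[1.0, 4.0], offsets=[0.0, 0.0],
                samples_per_state=400, seed=1_000 + seed,
            )
            data, _ = fe.gen_harmonic_alchemy(spec)
            f = fe.mbar_solve(data, tolerance=1e-10)
            estimates.append(f.delta_f())
            sigmas.append(f.delta_f_sigma())
        empirical = np.std(estimates, ddof=1)
        assert empirical == pytest.approx(np.mean(sigmas), rel=0.30)

    def test_sigma_positive_on_fixture_scale_input(self, harmonic_pair):
        _, _, f = harmonic_pair
        assert f.delta_f_sigma() > 0

    def test_zero_effective_samples_named(self, harmonic_pair):
        data, _, f = harmonic_pair
        # an absurd free energy starves state 1 of weight
        bad_f = np.array([0.0, -500.0])
        with pytest.raises(ValueError, match="state 1"):
            mbar_uncertainty(data, bad_f)


class TestExpAndBar:
    def test_exp_trivial_cases(self):
        assert fe.exp_estimate(np.zeros(10)) == 0.0
        assert fe.exp_estimate([3.0]) == pytest.approx(3.0)
        with pytest.raises(ValueError):
            fe.exp_estimate([])

    def test_exp_overflow_safe(self):
        # naive mean(exp(-w)) underflows; log-sum-exp must not
        assert np.isfinite(fe.exp_estimate(np.full(5, 2000.0)))
        assert fe.exp_estimate(np.full(5, 2000.0)) == pytest.approx(2000.0)

    def test_exp_gaussian_work_limit(self):
        # for w ~ N(mu, s^2): Δf -> mu - s^2/2
        rng = np.random.default_rng(7)
        mu, s = 2.0, 0.8
        w = rng.normal(mu, s, size=400_000)
        assert fe.exp_estimate(w) == pytest.approx(mu - s * s / 2, abs=0.02)

    def test_bar_symmetric_case(self):
        assert fe.bar_estimate(np.zeros(50), np.zeros(50)) == pytest.approx(0.0, abs=1e-9)

    def test_bar_crooks_gaussian_pair(self):
        # forward N(mu, s^2) and reverse N(-mu + s^2, s^2) satisfy Crooks
        # with Δf = mu - s^2/2
        rng = np.random.default_rng(11)
        mu, s = 1.5, 1.0
        wf = rng.normal(mu, s, size=200_000)
        wr = rng.normal(-mu + s * s, s, size=200_000)
        assert fe.bar_estimate(wf, wr) == pytest.approx(mu - s * s / 2, abs=0.02)

    def test_bar_empty_direction_rejected(self):
        with pytest.raises(ValueError):
            fe.bar_estimate([], [0.0])

    def test_estimator_consistency_on_overlapping_pair(self, harmonic_pair):
        data, _, f = harmonic_pair
        wf, wr = _works(data)
        sigma = f.delta_f_sigma()
        assert fe.exp_estimate(wf) == pytest.approx(f.delta_f(), abs=3 * sigma + 0.01)
        assert fe.bar_estimate(wf, wr) == pytest.approx(f.delta_f(), abs=3 * sigma)


class TestOverlap:
    def test_identical_states_uniform_matrix(self):
        rng = np.random.default_rng(4)
        u = np.tile(rng.normal(size=400), (4, 1))
        data = ReducedPotentialSet(u, n_k=[100] * 4)
        f = fe.mbar_solve(data)
        mat = fe.overlap_matrix(data, f)
        assert np.allclose(mat, 0.25, atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rows_sum_to_one(self, seed):
        spec = fe.HarmonicSchedule(
            stiffness=[1.0, 2.0, 8.0], offsets=[0.0, 1.0, -1.0],
            samples_per_state=500, seed=seed,
        )
        data, _ = fe.gen_harmonic_alchemy(spec)
        mat = fe.overlap_matrix(data, fe.mbar_solve(data))
        assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-8)
        assert mat.min() >= 0.0

    def test_disjoint_states_vanishing_off_diagonal(self):
        spec = fe.HarmonicSchedule(
            stiffness=[1.0, 1.0], offsets=[0.0, 25.0], samples_per_state=500, seed=6
        )
        data, _ = fe.gen_harmonic_alchemy(spec)
        mat = fe.overlap_matrix(data, fe.mbar_solve(data, max_iterations=100_000))
        assert mat[0, 1] < 1e-6 and mat[1, 0] < 1e-6


class TestPiBiasMeasure:
    def test_near_identical_states_pass(self):
        spec = fe.HarmonicSchedule(
            stiffness=[1.0, 1.01], offsets=[0.0, 0.0],
            samples_per_state=10_000, seed=8,
        )
        data, _ = fe.gen_harmonic_alchemy(spec)
        pi, ok = fe.pi_bias_measure(data, (0, 1))
        assert ok and pi > 0.5

    def test_disjoint_states_fail_with_midpoint_recommendation(self):
        spec = fe.HarmonicSchedule(
            stiffness=[1.0, 1.0], offsets=[0.0, 20.0], samples_per_state=500, seed=10
        )
        data, _ = fe.gen_harmonic_alchemy(spec)
        f = fe.mbar_solve(data, max_iterations=100_000)
        pi, ok = fe.pi_bias_measure(data, (0, 1), f)
        assert not ok and pi < 0.5
        report = fe.overlap_report(data, f)
        assert any("insert" in r for r in report.recommendations)

    def test_boundary_is_closed_at_half(self, harmonic_pair):
        # the rule adds lambdas strictly below 0.5, so Π == 0.5 passes
        data, _, f = harmonic_pair
        pi, _ = fe.pi_bias_measure(data, (0, 1), f)
        _, ok = fe.pi_bias_measure(data, (0, 1), f, threshold=pi)
        assert ok

    def test_too_few_samples_rejected(self):
        spec = fe.HarmonicSchedule(
            stiffness=[1.0, 2.0], offsets=[0.0, 0.0], samples_per_state=5, seed=0
        )
        data, _ = fe.gen_harmonic_alchemy(spec)
        with pytest.raises(ValueError, match="10 samples"):
            fe.pi_bias_measure(data, (0, 1), np.zeros(2))


def test_unit_conversion_uses_configured_temperature(harmonic_pair):
    data, _, _ = harmonic_pair
    f300 = fe.mbar_solve(data, temperature=300.0)
    dkj, _ = f300.to_kjmol()
    assert dkj == pytest.approx(f300.delta_f() * 8.31446e-3 * 300.0, rel=1e-6)
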