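import itertools
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from _oracles import simplex_least_squares
from confenum.ensemble_fitting import (
    ObservableProfile,
    debye_curve,
    ensemble_profile,
    fit_metrics,
    greedy_select,
    maxent_reweight,
    pre_profile,
    read_profile,
    two_round_populations,
    weighted_scalar,
    write_profile,
)
from confenum.geometry_core import Conformation, build_backbone
from confenum.synth import make_recovery_ensemble


def _profile(values, kind="RDC", absc=None):
    values = np.asarray(values, dtype=float)
    absc = np.arange(len(values)) if absc is None else absc
    return ObservableProfile(kind, absc, values)


class TestFitMetrics:
    def test_perfect_agreement(self):
        obs = _profile([1, 2, 3, 4])
        m = fit_metrics(obs, obs)
        assert (m.rms, m.r, m.q) == (0.0, pytest.approx(1.0), 0.0)

    def test_constant_offset(self):
        obs = _profile([1, 2, 3, 4])
        calc = _profile([3, 4, 5, 6])
        m = fit_metrics(calc, obs)
        assert m.rms == pytest.approx(2.0)
        assert m.r == pytest.approx(1.0)

    def test_anticorrelated_hand_values(self):
        m = fit_metrics(_profile([1, 2, 3]), _profile([3, 2, 1]))
        assert m.r == pytest.approx(-1.0)
        assert m.rms == pytest.approx(math.sqrt(8.0 / 3.0))
        # Q = rms(diff) / rms(obs)
        assert m.q == pytest.approx(math.sqrt(8.0 / 3.0) / math.sqrt(14.0 / 3.0))

    def test_zero_variance_observation_is_an_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            fit_metrics(_profile([1, 2, 3]), _profile([5, 5, 5]))


class TestEnsembleProfile:
    def test_degenerate_weight_selects_single_member(self):
        a, b = _profile([1, 2]), _profile([5, 6])
        out = ensemble_profile([a, b], [1.0, 0.0])
        assert np.allclose(out.values, a.values)

    def test_equal_weights_on_identical_profiles(self):
        a = _profile([2, 4, 6])
        out = ensemble_profile([a, a, a], np.full(3, 1 / 3))
        assert np.allclose(out.values, a.values)

    def test_weighted_mean_arithmetic(self):
        a, b = _profile([0, 0]), _profile([4, 4])
        out = ensemble_profile([a, b], [0.25, 0.75])
        assert np.allclose(out.values, 3.0)

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            ensemble_profile([_profile([1, 2])], [0.5, 0.5])


class TestGreedySelect:
    def test_exact_candidate_selected_first(self):
        obs = _profile([1.0, 3.0, 2.0, 5.0])
        cands = [_profile([2.0, 2.0, 2.0, 2.1]), obs, _profile([5, 3, 2, 1])]
        chosen, traj = greedy_select(cands, obs)
        assert chosen[0] == 1
        assert traj[0].r == pytest.approx(1.0)
        assert traj[0].rms == pytest.approx(0.0)

    def test_complementary_pair_improves_r_at_size_two(self):
        obs = _profile([1.0, 2.0, 3.0, 4.0])
        a = _profile([1.0, 3.0, 2.0, 4.0])      # R = 0.8 alone
        b = _profile([1.0, 1.0, 4.0, 4.0])      # imperfect alone
        chosen, traj = greedy_select([a, b], obs)
        assert set(chosen) == {0, 1}
        assert traj[1].r == pytest.approx(1.0)
        assert traj[1].r > traj[0].r

    def test_planted_triplet_recovered_and_matches_subset_oracle(self):
        rng = np.random.default_rng(8)
        x = np.linspace(0, 1, 30)
        curves = [np.sin(2 * np.pi * (k + 1) * x) + rng.normal(0, 0.3, 30) for k in range(10)]
        planted = {1, 4, 7}
        obs_values = np.mean([curves[i] for i in planted], axis=0)
        cands = [_profile(c, absc=x) for c in curves]
        obs = _profile(obs_values, absc=x)
        chosen, traj = greedy_select(cands, obs, max_size=3)
        assert set(chosen) == planted
        # exhaustive 3-subset oracle: the planted set has the best R
        best = max(
            itertools.combinations(range(10), 3),
            key=lambda s: fit_metrics(
                ensemble_profile([cands[i] for i in s], np.full(3, 1 / 3)), obs
            ).r,
        )
        assert set(best) == planted


class TestMaxEnt:
    def test_single_conformer_is_fixed(self):
        obs = _profile([1.0, 2.0], kind="SAXS")
        res = maxent_reweight([_profile([1.5, 2.5], kind="SAXS")], obs)
        assert res.weights.weights == pytest.approx([1.0])
        assert res.entropy == 0.0

    def test_large_theta_returns_reference_weights(self):
        x = np.linspace(0.1, 3, 20)
        curves = np.stack([np.exp(-x * t) for t in (0.5, 1.5, 3.0)])
        obs = ObservableProfile("SAXS", x, curves[0], np.full(20, 0.01))
        res = maxent_reweight(curves, obs, theta=1e8)
        assert np.allclose(res.weights.weights, 1 / 3, atol=1e-3)

    def test_recovers_exact_mixture_within_oracle_tolerance(self):
        x = np.linspace(0.05, 5, 50)
        curves = np.stack([np.exp(-x * t) + 0.1 * t for t in (0.5, 1.5, 3.0)])
        w_true = np.array([0.6, 0.3, 0.1])
        mix = w_true @ curves
        obs = ObservableProfile("SAXS", x, mix, np.maximum(0.01 * mix, 1e-9))
        res = maxent_reweight(curves, obs, theta=0.001)
        assert np.allclose(res.weights.weights, w_true, atol=0.02)
        oracle = simplex_least_squares(curves, obs)
        assert np.allclose(res.weights.weights, oracle, atol=0.02)

    def test_chi2_never_worse_than_reference(self):
        rng = np.random.default_rng(9)
        x = np.linspace(0.05, 5, 30)
        curves = rng.random((6, 30)) + 0.5
        obs = ObservableProfile("SAXS", x, curves[2] * 0.7 + curves[4] * 0.3,
                                np.full(30, 0.02))
        w0 = np.full(6, 1 / 6)
        res = maxent_reweight(curves, obs, w0=w0, theta=1.0)
        chi2_ref = float(np.sum(((w0 @ curves - obs.values) / 0.02) ** 2))
        assert res.chi2 <= chi2_ref + 1e-9
        assert res.entropy <= 1e-12

    def test_weights_stay_on_simplex(self):
        rng = np.random.default_rng(10)
        curves = rng.random((5, 20))
        obs = ObservableProfile("SAXS", np.arange(20), curves[0], np.full(20, 0.05))
        res = maxent_reweight(curves, obs, theta=0.5)
        w = res.weights.weights
        assert (w >= 0).all()
        assert w.sum() == pytest.approx(1.0, abs=1e-9)


class TestTwoRound:
    def test_dominant_conformer_recovered_with_tiny_spread(self):
        x = np.linspace(0.05, 5, 40)
        curves = np.stack([np.exp(-x * t) + 0.05 * t for t in (0.4, 1.2, 2.5, 5.0)])
        obs = ObservableProfile("SAXS", x, curves[1], np.maximum(0.002 * curves[1], 1e-9))
        res = two_round_populations(curves, obs, seed=3, theta=0.001)
        i = res["kept"].index(1)
        assert res["mean"][i] > 0.98
        assert res["sd"][i] < 1e-2
        assert res["mean"].sum() == pytest.approx(1.0, abs=1e-6)

    def test_identical_profiles_share_identifiable_total(self):
        x = np.linspace(0.05, 5, 40)
        base = np.exp(-x * 1.5)
        other = np.exp(-x * 0.3)
        curves = np.stack([base, base, other])
        mix = 0.6 * base + 0.4 * other
        obs = ObservableProfile("SAXS", x, mix, np.maximum(0.005 * mix, 1e-9))
        res = two_round_populations(curves, obs, seed=4, theta=0.001)
        w = np.zeros(3)
        for k, i in enumerate(res["kept"]):
            w[i] = res["mean"][k]
        assert w[0] + w[1] == pytest.approx(0.6, abs=0.02)
        assert w[2] == pytest.approx(0.4, abs=0.02)

    def test_single_seed_recovery_from_benchmark_condition(self):
        curves, w_true, obs = make_recovery_ensemble(seed=11)
        res = two_round_populations(curves, obs, seed=11, theta=0.05)
        w_est = np.zeros(len(w_true))
        for k, i in enumerate(res["kept"]):
            w_est[i] = res["mean"][k]
        assert np.mean(np.abs(w_est - w_true)) < 0.1


class TestPredictors:
    @staticmethod
    def _ca(positions):
        n = len(positions)
        return Conformation(
            np.arange(1, n + 1), ["ALA"] * n, ["CA"] * n, ["C"] * n,
            np.asarray(positions, dtype=float),
        )

    def test_debye_low_q_limit_is_n_squared(self):
        conf = self._ca([[0, 0, 0], [8.0, 0, 0]])
        prof = debye_curve(conf, [1e-9])
        assert prof.values[0] == pytest.approx(4.0)

    def test_debye_rotation_invariant(self, params):
        conf = build_backbone("AVLKEQ", [(-120, 130)] * 6, params)
        rot = Rotation.from_rotvec([1.0, 0.2, -0.4]).as_matrix()
        q = np.linspace(0.05, 5, 20)
        a = debye_curve(conf, q).values
        b = debye_curve(conf.transformed(rot, np.zeros(3)), q).values
        assert np.allclose(a, b, atol=1e-9)

    def test_debye_three_collinear_points_hand_sum(self):
        conf = self._ca([[0, 0, 0], [10.0, 0, 0], [20.0, 0, 0]])
        q = 1.0  # nm^-1; pair distances 1, 1, 2 nm
        expected = 3 + 4 * math.sin(1.0) / 1.0 + 2 * math.sin(2.0) / 2.0
        prof = debye_curve(conf, [q])
        assert prof.values[0] == pytest.approx(expected, abs=1e-9)

    def test_pre_limits_and_monotonicity(self, params):
        conf = self._ca([[0, 0, 0]] + [[r, 0, 0] for r in (5, 10, 20, 40, 60)])
        conf.names = ["CB"] + ["N"] * 5  # probe site + amides
        conf.resids = np.arange(1, 7)
        prof = pre_profile(conf, probe_residue=1)
        ratios = dict(zip(prof.abscissa.astype(int), prof.values))
        assert ratios[6] > 0.99                    # far residue unaffected
        vals = [ratios[r] for r in (2, 3, 4, 5, 6)]
        assert all(x <= y + 1e-12 for x, y in zip(vals, vals[1:]))
        assert (prof.values >= 0).all() and (prof.values <= 1).all()

    def test_pre_probe_residue_is_bleached(self, params):
        conf = build_backbone("AVLKEQ", [(-120, 130)] * 6, params)
        prof = pre_profile(conf, probe_residue=3)
        i = list(prof.abscissa.astype(int)).index(3)
        assert prof.values[i] < 0.05


class TestWeightedScalarAndIO:
    def test_degenerate_and_uniform_weights(self):
        assert weighted_scalar([24, 26, 28], [1, 0, 0]) == 24
        assert weighted_scalar([24, 26, 28], np.full(3, 1 / 3)) == pytest.approx(26)

    def test_matches_dot_product(self):
        v = [31.0, 24.5, 28.0, 26.1]
        w = [0.6, 0.1, 0.15, 0.15]
        assert weighted_scalar(v, w) == pytest.approx(float(np.dot(v, w)))

    def test_profile_file_round_trip(self, tmp_path):
        prof = ObservableProfile(
            "SAXS", np.linspace(0.1, 3, 7), np.arange(7) + 1.0, np.full(7, 0.1)
        )
        path = tmp_path / "p.dat"
        write_profile(prof, path)
        back = read_profile(path, kind="SAXS")
        assert np.allclose(back.abscissa, prof.abscissa)
        assert np.allclose(back.values, prof.values)
        assert np.allclose(back.uncertainties, prof.uncertainties)

    def test_angstrom_q_unit_conversion(self, tmp_path):
        path = tmp_path / "p.dat"
        path.write_text("0.1 5.0\n0.2 4.0\n")
        prof = read_profile(path, kind="SAXS", q_unit="angstrom")
        assert np.allclose(prof.abscissa, [1.0, 2.0])  # A^-1 -> nm^-1
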