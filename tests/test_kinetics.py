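"""Diffusion estimation, rate-model construction, KMC, MFPTs, rate fits."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import felscape as fs
from felscape.errors import ConfigError, FelscapeError
from felscape.frames import KB

KT = KB * 300.0


class TestEstimateDiffusion:
    def test_ideal_random_walk(self, rng):
        delta = 0.05
        s = np.cumsum(rng.choice([-delta, delta], size=100_000))
        series = fs.CVSeries.from_columns(np.arange(100_000, dtype=float), s=s)
        result = fs.estimate_diffusion(series, [1, 2, 5, 10, 20])
        expected = delta**2 / 2.0  # per ps, unit time step
        for d in result.table["D_s"]:
            assert d == pytest.approx(expected, rel=0.05)
        assert result.plateau["s"] == pytest.approx(expected, rel=0.05)
        assert result.plateau_ok["s"]

    def test_linear_drift_grows_and_flags_no_plateau(self):
        v = 0.01
        t = np.arange(50_000, dtype=float)
        series = fs.CVSeries.from_columns(t, s=v * t)
        lags = [1, 5, 10, 50, 100]
        result = fs.estimate_diffusion(series, lags)
        for lag, d in zip(lags, result.table["D_s"]):
            assert d == pytest.approx(v**2 * lag / 2.0, rel=1e-9)
        assert not result.plateau_ok["s"]

    def test_constant_series_zero(self):
        series = fs.CVSeries.from_columns(np.arange(100.0), s=np.ones(100))
        result = fs.estimate_diffusion(series, [1, 5])
        assert (result.table["D_s"] == 0).all()

    def test_lag_beyond_length_errors(self):
        series = fs.CVSeries.from_columns(np.arange(10.0), s=np.ones(10))
        with pytest.raises(ConfigError):
            fs.estimate_diffusion(series, [10])


def _surface_from(F_values, width=0.1):
    F = np.asarray(F_values, dtype=float)
    edges = [np.arange(0, width * (len(F) + 0.5), width)]
    return fs.FreeEnergySurface(
        ["s1"], edges, F, 300.0, counts=np.ones(len(F), dtype=int)
    )


class TestBuildRateModel:
    def test_flat_surface_uniform_rates(self):
        model = fs.build_rate_model(_surface_from(np.zeros(5)), D=0.02)
        base = 0.02 / 0.1**2
        assert model.rates.nnz == 8
        np.testing.assert_allclose(model.rates.data, base)

    def test_two_bin_detailed_balance_ratio(self):
        model = fs.build_rate_model(_surface_from([0.0, KT]), D=0.01)
        k01 = model.rates[0, 1]
        k10 = model.rates[1, 0]
        assert k01 / k10 == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_stationary_matches_boltzmann_eigenvector(self, double_well):
        surface = fs.FreeEnergySurface.from_potential(
            double_well, [np.linspace(-1.5, 1.5, 51)], 300.0
        )
        model = fs.build_rate_model(surface, D=0.01)
        # independent oracle: null space of the dense generator
        q = model.generator().toarray()
        w, v = np.linalg.eig(q.T)
        pi = np.real(v[:, np.argmin(np.abs(w))])
        pi = np.abs(pi) / np.abs(pi).sum()
        boltz = np.exp(-model.free_energies / KT)
        boltz /= boltz.sum()
        np.testing.assert_allclose(pi, boltz, atol=1e-10)

    @given(seed=st.integers(0, 2**31 - 1),
           convention=st.sampled_from(["half", "metropolis"]))
    def test_detailed_balance_exact_for_random_surfaces(self, seed, convention):
        rng = np.random.default_rng(seed)
        F = rng.uniform(0, 12, size=(5, 4))
        surface = fs.FreeEnergySurface(
            ["a", "b"], [np.arange(6.0), np.arange(5.0)], F, 300.0,
            counts=np.ones((5, 4), dtype=int),
        )
        model = fs.build_rate_model(surface, D={"a": 0.5, "b": 0.2},
                                    convention=convention)
        assert model.detailed_balance_violation() < 1e-12

    def test_disconnected_bins_reported(self):
        F = np.array([0.0, 1.0, np.inf, 0.5, 0.2])
        counts = np.array([5, 5, 0, 5, 5])
        surface = fs.FreeEnergySurface(
            ["s1"], [np.arange(6.0)], F, 300.0, counts=counts
        )
        with pytest.warns(UserWarning, match="disconnected"):
            model = fs.build_rate_model(surface, D=0.1)
        with pytest.warns(UserWarning), pytest.raises(FelscapeError, match="disconnected"):
            fs.build_rate_model(
                surface, D=0.1,
                folded_states=np.array([0]), unfolded_states=np.array([3]),
            )
        assert model.n_states == 4


class TestKMC:
    def test_absorbing_state_dwells_to_t_max(self):
        model = fs.generate_known_rate_model(2, {(1, 0): 1.0})
        (traj,) = fs.kmc_simulate(model, [0], n_traj=1, t_max=5.0, seed=1)
        assert list(traj.states) == [0]
        assert traj.t_max == 5.0

    def test_exponential_dwell_mean(self):
        model = fs.generate_known_rate_model(2, {(0, 1): 1.0, (1, 0): 1.0})
        (traj,) = fs.kmc_simulate(model, [0], n_traj=1, t_max=30_000.0, seed=2)
        dwells = np.diff(traj.times)
        assert len(dwells) > 10_000
        assert dwells.mean() == pytest.approx(1.0, rel=0.02)

    def test_two_state_occupancy(self):
        model = fs.generate_known_rate_model(2, {(0, 1): 3.0, (1, 0): 1.0})
        occ = fs.kmc_occupancy(model, 0, n_jumps=50_000, seed=3)
        np.testing.assert_allclose(occ, [0.25, 0.75], atol=0.02)

    def test_per_trajectory_substreams_are_stable(self):
        model = fs.generate_known_rate_model(2, {(0, 1): 1.0, (1, 0): 2.0})
        short = fs.kmc_simulate(model, [0], n_traj=2, t_max=50.0, seed=7)
        longer = fs.kmc_simulate(model, [0], n_traj=5, t_max=50.0, seed=7)
        for a, b in zip(short, longer[:2]):
            np.testing.assert_array_equal(a.states, b.states)
            np.testing.assert_array_equal(a.times, b.times)

    def test_vectorized_first_passage_agrees_with_gillespie(self):
        model = fs.generate_known_rate_model(
            3, {(0, 1): 1.0, (1, 0): 0.5, (1, 2): 0.8}
        )
        trajs = fs.kmc_simulate(model, [0], n_traj=400, t_max=1e4, seed=11)
        gillespie = np.array(
            [fs.kinetics.first_passage_time(t, [2]) for t in trajs]
        )
        vec = fs.kmc_first_passage_times(model, [0], [2], 2000, seed=12)
        assert np.isfinite(vec).all()
        assert vec.mean() == pytest.approx(gillespie.mean(), rel=0.15)


class TestFoldingKinetics:
    def test_exact_curve_self_fit(self):
        t = np.linspace(0.01, 3.0, 100)
        k, resid = fs.fit_single_exponential(t, 1.0 - np.exp(-2.0 * t))
        assert k == pytest.approx(2.0, abs=1e-6)
        assert resid < 1e-10

    @pytest.mark.parametrize("k_true", [1e-3, 0.5, 1e3])
    def test_two_state_rate_recovered(self, k_true):
        model = fs.generate_known_rate_model(2, {(0, 1): k_true})
        fpts = fs.kmc_first_passage_times(model, [0], [1], 10_000, seed=21)
        kin = fs.folding_kinetics(fpts)
        assert kin.rate == pytest.approx(k_true, rel=0.05)
        assert kin.n_folded == 10_000

    def test_deep_intermediate_breaks_single_exponential(self):
        # two sequential unit-rate steps: first passage is Gamma(2), whose
        # best single-exponential fit leaves a visible residual
        two_state = fs.generate_known_rate_model(2, {(0, 1): 0.5})
        three_state = fs.generate_known_rate_model(
            3, {(0, 1): 1.0, (1, 2): 1.0}
        )
        f2 = fs.kmc_first_passage_times(two_state, [0], [1], 4000, seed=31)
        f3 = fs.kmc_first_passage_times(three_state, [0], [2], 4000, seed=32)
        r2 = fs.folding_kinetics(f2).residual
        r3 = fs.folding_kinetics(f3).residual
        assert r3 > r2  # multi-exponential signature reported, not hidden

    def test_never_folding_flagged(self):
        model = fs.generate_known_rate_model(2, {(1, 0): 1.0})
        trajs = fs.kmc_simulate(model, [0], n_traj=3, t_max=10.0, seed=4)
        with pytest.warns(UserWarning, match="ever folded"):
            kin = fs.folding_kinetics(trajs, folded_states=[1])
        assert kin.rate is None


class TestTransitionTimes:
    def test_self_time_is_zero(self):
        model = fs.generate_known_rate_model(2, {(0, 1): 1.0, (1, 0): 1.0})
        out = fs.transition_times(model, np.array(["a", "b"], dtype=object))
        assert out.loc["a", "a"] == 0.0
        assert out.loc["b", "b"] == 0.0

    def test_matches_birth_death_closed_form(self, rng):
        """Linear-system MFPT vs the nested-sum formula on a random chain."""
        n = 12
        k_up = rng.uniform(0.2, 2.0, size=n - 1)
        k_down = rng.uniform(0.2, 2.0, size=n - 1)
        rates = {}
        for i in range(n - 1):
            rates[(i, i + 1)] = k_up[i]
            rates[(i + 1, i)] = k_down[i]
        model = fs.generate_known_rate_model(n, rates)
        labels = np.array(["mid"] * n, dtype=object)
        labels[0], labels[-1] = "A", "B"
        out = fs.transition_times(model, labels)
        expected = fs.birth_death_mfpt(k_up, k_down, 0, n - 1)
        assert out.loc["A", "B"] == pytest.approx(expected, rel=1e-8)
        back = fs.birth_death_mfpt(k_up, k_down, n - 1, 0)
        assert out.loc["B", "A"] == pytest.approx(back, rel=1e-8)

    def test_unreachable_target_is_infinite(self):
        model = fs.generate_known_rate_model(2, {(1, 0): 1.0})
        with pytest.warns(UserWarning, match="cannot reach"):
            out = fs.transition_times(model, np.array(["a", "b"], dtype=object))
        assert np.isinf(out.loc["a", "b"])

    def test_kmc_cross_check_on_double_well(self, double_well):
        surface = fs.FreeEnergySurface.from_potential(
            double_well, [np.linspace(-1.6, 1.6, 17)], 300.0
        )
        model = fs.build_rate_model(surface, D=0.02)
        labels = np.array(["mid"] * model.n_states, dtype=object)
        x = model.state_coords[:, 0]
        left, right = np.nonzero(x < 0)[0], np.nonzero(x > 0)[0]
        labels[left[np.argmin(model.free_energies[left])]] = "L"
        labels[right[np.argmin(model.free_energies[right])]] = "R"
        out = fs.transition_times(model, labels, kmc_check=2000, seed=5)
        assert out.loc["L", "R_kmc"] == pytest.approx(out.loc["L", "R"], rel=0.05)
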