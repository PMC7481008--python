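"""Free-energy estimators, ACF diagnostics, replicate statistics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mdinfer as m
from mdinfer._units import kt_kj_per_mol
from mdinfer.free_energy import UmbrellaWindow, neighbor_overlap, profile_convergence

KT298 = kt_kj_per_mol(298.0)


def brute_force_bar(wf, wr, beta):
    """Independent oracle: dense scan + bisection of the acceptance-ratio
    equation, coded without the package's solver."""
    wf, wr = np.asarray(wf), np.asarray(wr)
    m_const = math.log(len(wf) / len(wr))

    def fn(dg):
        lhs = np.sum(1.0 / (1.0 + np.exp(m_const + beta * (wf - dg))))
        rhs = np.sum(1.0 / (1.0 + np.exp(-m_const + beta * (wr + dg))))
        return lhs - rhs

    lo, hi = -100.0, 100.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if fn(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestCrooksMle:
    def test_consistent_deltas(self):
        ws = m.WorkSet([2.0, 2.0, 2.0], [-2.0, -2.0, -2.0])
        est = m.crooks_mle_dg(ws, n_boot=0)
        assert est.dg == pytest.approx(2.0, abs=1e-9)

    def test_gaussian_parameter_recovery(self):
        ws = m.gen_gaussian_work(5.0, 2.0, 500, 500, seed=1)
        est = m.crooks_mle_dg(ws, n_boot=300, seed=2)
        assert abs(est.dg - 5.0) < 3 * est.se
        assert not est.low_overlap

    def test_antisymmetric_under_direction_swap(self):
        ws = m.gen_gaussian_work(5.0, 2.0, 300, 200, seed=3)
        a = m.crooks_mle_dg(ws, n_boot=0).dg
        b = m.crooks_mle_dg(ws.swapped(), n_boot=0).dg
        assert a == pytest.approx(-b, abs=1e-8)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        wf = rng.normal(6.0, 2.0, 150)
        wr = rng.normal(-4.0, 2.0, 150)
        ws = m.WorkSet(wf, wr)
        beta = 1.0 / KT298
        assert m.crooks_mle_dg(ws, n_boot=0).dg == pytest.approx(
            brute_force_bar(wf, wr, beta), abs=1e-6
        )

    def test_equal_width_gaussians_cross_at_midpoint(self):
        # symmetric samples make the midpoint exact, not just asymptotic
        d = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
        ws = m.WorkSet(6.0 + d, -4.0 + d)
        est = m.crooks_mle_dg(ws, n_boot=0)
        assert est.dg == pytest.approx(5.0, abs=1e-9)

    def test_low_overlap_flagged(self):
        ws = m.WorkSet([300.0, 301.0], [-10.0, -11.0])
        assert m.crooks_mle_dg(ws, n_boot=0).low_overlap

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            m.WorkSet([], [1.0])


class TestMbarPmf:
    def test_double_well_shape_recovered(self, double_well_windows):
        model, windows = double_well_windows
        prof = m.mbar_pmf(windows, temperature=298.0, bins=40)
        true = model.potential_kj_per_mol(prof.bin_centers)
        true -= true.min()
        rmsd = np.sqrt(np.mean((prof.dg - true) ** 2)) / KT298
        assert rmsd < 0.35
        # wells near +-1, substantial barrier at 0
        assert prof.dg[np.argmin(np.abs(prof.bin_centers))] > 3 * KT298

    def test_alignment_and_residual_invariants(self, double_well_windows):
        _, windows = double_well_windows
        prof = m.mbar_pmf(windows, temperature=298.0, bins=40)
        assert prof.dg.min() == 0.0
        assert np.all(prof.se >= 0)
        assert prof.residual < 1e-8
        assert np.all(np.diff(prof.bin_centers) > 0)

    def test_single_nearly_unrestrained_window_reduces_to_histogram(self):
        model = m.DoubleWellModel(2.0)
        wins = m.gen_umbrella_samples(model, [0.0], 1e-9, 30_000, seed=5)
        prof = m.mbar_pmf(wins, temperature=298.0, bins=25, min_bin_count=1)
        x = wins[0].samples
        hist, edges = np.histogram(x, bins=25, range=(x.min(), x.max()))
        ref = -KT298 * np.log(hist[hist > 0])
        ref -= ref.min()
        occupied = hist > 0
        np.testing.assert_allclose(prof.dg, ref[: occupied.sum()], atol=1e-6)

    def test_flat_potential_statistically_flat(self):
        model = m.DoubleWellModel(0.0)
        wins = m.gen_umbrella_samples(
            model, np.linspace(-1.0, 1.0, 9), 16 * KT298, 6000, seed=6
        )
        prof = m.mbar_pmf(wins, temperature=298.0, bins=30)
        dev = np.abs(prof.dg - prof.dg.mean()).max()
        assert dev < 2 * prof.se.max()

    def test_gap_between_windows_detected(self):
        rng = np.random.default_rng(7)
        wins = [
            UmbrellaWindow(0.0, 100.0, rng.normal(0.0, 0.05, 500)),
            UmbrellaWindow(5.0, 100.0, rng.normal(5.0, 0.05, 500)),
        ]
        with pytest.raises(ValueError, match="overlap"):
            m.mbar_pmf(wins, temperature=298.0)

    def test_neighbor_overlap_metric(self, double_well_windows):
        _, windows = double_well_windows
        ov = neighbor_overlap(windows)
        assert len(ov) == len(windows) - 1
        assert np.all(ov > 0.3)


@pytest.fixture(scope="module")
def windows():
    model = m.DoubleWellModel(3.0)
    return m.gen_umbrella_samples(
        model, np.linspace(-1.3, 1.3, 9), 16 * KT298, 10_000, seed=8
    )


class TestProfileConvergence:
    def test_full_fraction_reproduces_pmf(self, windows):
        profs = profile_convergence(windows, [1.0], n_rep=4, temperature=298.0, bins=30)
        full = m.mbar_pmf(
            windows,
            temperature=298.0,
            bins=30,
            coord_range=(
                min(w.samples.min() for w in windows),
                max(w.samples.max() for w in windows),
            ),
        )
        np.testing.assert_allclose(profs[0].dg, full.dg, atol=1e-9)

    def test_uncertainty_shrinks_with_data(self, windows):
        profs = profile_convergence(
            windows, [0.05, 1.0], n_rep=4, temperature=298.0, bins=30
        )
        assert np.nanmean(profs[0].se) > np.nanmean(profs[1].se)

    def test_empty_fraction_rejected(self, windows):
        with pytest.raises(ValueError):
            profile_convergence(windows, [1e-6], n_rep=4)


class TestAcf:
    def test_white_noise_flat(self):
        x = np.random.default_rng(9).normal(size=100_000)
        res = m.acf(x, max_lag=50)
        assert res.acf[0] == pytest.approx(1.0)
        assert np.all(np.abs(res.acf[1:]) < 3 / math.sqrt(100_000))
        assert res.inefficiency == pytest.approx(1.0, abs=0.05)

    def test_ar1_analytic_forms(self):
        x = m.gen_ar1(0.9, 1.0, 100_000, seed=10)
        res = m.acf(x, max_lag=100)
        for lag in (1, 5, 10, 20):
            assert res.acf[lag] == pytest.approx(0.9**lag, abs=0.05)
        assert res.inefficiency == pytest.approx(19.0, rel=0.10)
        assert res.integrated_time == pytest.approx(res.inefficiency / 2)

    def test_subsampling_at_g_decorrelates(self):
        x = m.gen_ar1(0.9, 1.0, 200_000, seed=11)
        g = int(round(m.acf(x, max_lag=200).inefficiency))
        sub = x[::g]
        rho1 = np.corrcoef(sub[:-1], sub[1:])[0, 1]
        # residual correlation at spacing g is phi^g (~0.14 for phi=0.9)
        assert rho1 == pytest.approx(0.9**g, abs=0.05)
        assert abs(rho1) < 0.2

    @given(st.integers(0, 1000))
    def test_bounds_invariant(self, seed):
        x = np.random.default_rng(seed).normal(size=500)
        res = m.acf(x, max_lag=20)
        assert res.acf[0] == pytest.approx(1.0)
        assert np.all(np.abs(res.acf) <= 1.0 + 1e-12)
        assert res.inefficiency >= 1.0

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            m.acf(np.ones(1000), max_lag=10)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            m.acf(np.arange(10.0), max_lag=10)


class TestReplicateStatistics:
    def test_degenerate_replicates(self):
        s = m.replicate_statistics([1.0, 1.0, 1.0, 1.0])
        assert (s.mean, s.se) == (1.0, 0.0)
        assert s.ci == (1.0, 1.0)

    def test_ci_coverage_near_nominal(self):
        hits = 0
        trials = 1000
        rng = np.random.default_rng(12)
        for _ in range(trials):
            s = m.replicate_statistics(rng.normal(-10.0, 1.0, 20), level=0.95)
            hits += s.ci[0] <= -10.0 <= s.ci[1]
        assert hits / trials == pytest.approx(0.95, abs=0.025)

    def test_ci_width_scales_inverse_sqrt(self):
        rng = np.random.default_rng(13)
        vals = rng.normal(0.0, 1.0, 400)
        w_full = np.diff(m.replicate_statistics(vals).ci)[0]
        w_half = np.diff(m.replicate_statistics(vals[:200]).ci)[0]
        assert w_half / w_full == pytest.approx(math.sqrt(2), rel=0.25)

    def test_normal_vs_t_quantile(self):
        vals = [1.0, 2.0, 3.0]
        t_ci = m.replicate_statistics(vals, method="t").ci
        n_ci = m.replicate_statistics(vals, method="normal").ci
        assert (n_ci[1] - n_ci[0]) < (t_ci[1] - t_ci[0])

    def test_single_value_refused_with_n1_warning(self):
        with pytest.raises(ValueError, match="N = 1"):
            m.replicate_statistics([1.0])


class TestTrendSignificance:
    def test_null_type_i_error_controlled(self):
        rng = np.random.default_rng(14)
        false_hits = 0
        trials = 300
        for _ in range(trials):
            groups = {f"c{i}": rng.normal(0, 1, 20) for i in range(6)}
            if m.trend_significance(groups).trend_significant:
                false_hits += 1
        assert false_hits / trials < 0.10

    def test_injected_slope_detected(self):
        rng = np.random.default_rng(15)
        se = 1.0 / math.sqrt(20)
        detected = 0
        trials = 100
        for _ in range(trials):
            groups = {
                f"c{i}": rng.normal(3 * se * i, 1.0, 20) for i in range(6)
            }
            detected += m.trend_significance(groups).trend_significant
        assert detected / trials > 0.80

    def test_single_replicate_refused(self):
        with pytest.raises(ValueError, match="N = 1"):
            m.trend_significance({"a": [1.0], "b": [1.0, 2.0]})
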