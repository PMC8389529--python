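import math

import numpy as np
import pytest

from pathmetad.fixtures import (featureless_pmf, logistic_dg_curve,
                                matching_pmf, two_plateau_dg_curve)
from pathmetad.free_energy import (ConvergenceWindow, DividingFrame,
                                   FreeEnergySurface, NoDividerError,
                                   V_STANDARD, convergence_window,
                                   dg_bound_unbound, dg_time_series,
                                   dg_time_stats, dg_vs_divider_curve,
                                   fes_from_hills, find_x_star, pmf_along_s,
                                   volume_correction)
from pathmetad.metad_engine import ColvarSeries, HillsLedger
from pathmetad.units import kt


def one_hill_ledger(center=0.5, width=0.1, height=0.3, gamma=10.0):
    return HillsLedger(times=np.array([1.0]),
                       centers=np.array([[center]]),
                       widths=np.array([[width]]),
                       heights=np.array([height]),
                       bias_factor=gamma, initial_height=height)


def flat_fes(n=201):
    s = np.linspace(0.0, 1.0, n)
    return FreeEnergySurface(s_axis=s, values=np.zeros(n))


class TestFesFromHills:
    def test_single_hill_closed_form(self):
        gamma = 10.0
        hills = one_hill_ledger(gamma=gamma)
        fes = fes_from_hills(hills, ((0.0, 1.0, 101),))
        # F = -(gamma/(gamma-1)) V, gauged so the minimum is zero
        factor = gamma / (gamma - 1.0)
        raw = -factor * 0.3 * np.exp(-((fes.s_axis - 0.5) ** 2) / (2 * 0.01))
        expected = raw - raw.min()
        assert np.allclose(fes.values, expected, atol=1e-10)
        assert fes.values.min() == pytest.approx(0.0)

    def test_rescale_s_maps_frame_units_to_unit_interval(self):
        hills = one_hill_ledger(center=8.0, width=1.0)
        fes = fes_from_hills(hills, ((1.0, 15.0, 141),), rescale_s=15)
        assert fes.s_axis[0] == pytest.approx(0.0)
        assert fes.s_axis[-1] == pytest.approx(1.0)
        assert fes.s_axis[np.argmax(fes.values == 0.0)] is not None
        # the deepest point sits at the hill center, (8-1)/14 = 0.5
        assert fes.s_axis[int(np.argmin(fes.values))] == pytest.approx(0.5)

    def test_explicit_gamma_overrides_ledger(self):
        hills = one_hill_ledger(gamma=10.0)
        a = fes_from_hills(hills, ((0.0, 1.0, 101),))
        b = fes_from_hills(hills, ((0.0, 1.0, 101),), gamma=2.0)
        assert b.values.max() == pytest.approx(
            a.values.max() * (2.0 / 1.0) / (10.0 / 9.0))

    def test_empty_ledger_rejected(self):
        empty = HillsLedger(times=np.array([]), centers=np.zeros((0, 1)),
                            widths=np.zeros((0, 1)), heights=np.array([]),
                            bias_factor=10.0, initial_height=0.3)
        with pytest.raises(ValueError):
            fes_from_hills(empty, ((0.0, 1.0, 101),))


class TestPartitionSplit:
    def test_flat_surface_counts_lengths(self):
        # with F = 0 everywhere, dG_b = -kT ln(0.25/0.75)
        dg = dg_bound_unbound(flat_fes(), 0.25, temperature=300.0)
        expected = -kt(300.0) * math.log(0.25 / 0.75)
        assert dg == pytest.approx(expected, abs=1e-6)
        assert dg == pytest.approx(0.655, abs=5e-3)

    def test_deep_well_binds(self):
        s = np.linspace(0.0, 1.0, 401)
        values = 6.0 - 6.0 * np.exp(-(s ** 2) / (2 * 0.05 ** 2))
        fes = FreeEnergySurface(s_axis=s, values=values)
        dg = dg_bound_unbound(fes, 0.4, temperature=300.0)
        assert dg < -1.0

    def test_accepts_dividing_frame_object(self):
        d = DividingFrame(0.25, 50, "manual")
        assert dg_bound_unbound(flat_fes(), d) == pytest.approx(
            dg_bound_unbound(flat_fes(), 0.25))

    def test_divider_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            dg_bound_unbound(flat_fes(), 1.5)

    def test_2d_z_integration_and_cap(self):
        s = np.linspace(0.0, 1.0, 101)
        z = np.linspace(0.0, 0.1, 21)
        # separable surface: F(s,z) = f(s) + 20*z -> z factor cancels in ratio
        fs = 3.0 * s
        values = fs[:, None] + 20.0 * z[None, :]
        fes = FreeEnergySurface(s_axis=s, values=values, z_axis=z)
        fes1 = FreeEnergySurface(s_axis=s, values=fs)
        a = dg_bound_unbound(fes, 0.3)
        b = dg_bound_unbound(fes1, 0.3)
        assert a == pytest.approx(b, abs=1e-9)
        capped = dg_bound_unbound(fes, 0.3, z_max=0.05)
        assert capped == pytest.approx(b, abs=1e-9)

    def test_pmf_along_s_gauge(self):
        s = np.linspace(0.0, 1.0, 101)
        z = np.linspace(0.0, 0.1, 11)
        values = (2.0 * s)[:, None] + 0.0 * z[None, :]
        fes = FreeEnergySurface(s_axis=s, values=values, z_axis=z)
        f = pmf_along_s(fes, 300.0)
        assert f.min() == pytest.approx(0.0)
        assert np.allclose(f, 2.0 * s, atol=1e-9)

    def test_dg_vs_divider_curve_monotone_for_deep_well(self):
        s = np.linspace(0.0, 1.0, 401)
        values = 6.0 - 6.0 * np.exp(-(s ** 2) / (2 * 0.05 ** 2))
        fes = FreeEnergySurface(s_axis=s, values=values)
        cands = np.linspace(0.2, 0.8, 25)
        curve = dg_vs_divider_curve(fes, 300.0, cands)
        assert curve.shape == (25,)
        # moving the divider outward only grows the site integral
        assert np.all(np.diff(curve) < 0)
        with pytest.raises(ValueError):
            dg_vs_divider_curve(fes, 300.0, cands[:5])


class TestFindXStar:
    def test_logistic_curve_inflection_recovered(self):
        s, dg = logistic_dg_curve()
        ps, pf = matching_pmf()
        d = find_x_star(s, dg, ps, pf, n_frames=15)
        assert d.method == "first-inflection"
        assert d.s_star == pytest.approx(0.4, abs=0.02)
        assert d.frame_index == round(d.s_star * 14)

    def test_two_plateau_midpoint_fallback(self):
        s, dg = two_plateau_dg_curve()
        ps, pf = featureless_pmf()
        d = find_x_star(s, dg, ps, pf)
        assert d.method == "midpoint-fallback"
        assert d.s_star == pytest.approx(0.5, abs=0.05)

    def test_linear_curve_raises_with_guidance(self):
        s = np.linspace(0.01, 0.99, 101)
        with pytest.raises(NoDividerError, match="human"):
            find_x_star(s, -3.0 * s)

    def test_flat_curve_raises(self):
        s = np.linspace(0.01, 0.99, 101)
        with pytest.raises(NoDividerError):
            find_x_star(s, np.zeros_like(s))

    def test_sparse_curve_rejected(self):
        with pytest.raises(ValueError):
            find_x_star(np.linspace(0, 1, 5), np.zeros(5))

    def test_divider_frame_validation(self):
        with pytest.raises(ValueError):
            DividingFrame(0.0, 0, "manual")
        with pytest.raises(ValueError):
            DividingFrame(1.0, 0, "manual")


class TestVolumeCorrection:
    def test_standard_volume_is_identity(self):
        assert volume_correction(V_STANDARD) == 0.0

    def test_doubled_volume_worked_example(self):
        assert volume_correction(3322.0, 300.0) == pytest.approx(0.413,
                                                                 abs=2e-3)

    def test_sub_standard_volume_negative(self):
        assert volume_correction(800.0) < 0

    def test_invalid_volume(self):
        with pytest.raises(ValueError):
            volume_correction(0.0)


def synthetic_run(converged=True, n_hills=400, seed=0):
    rng = np.random.default_rng(seed)
    times = np.arange(1, n_hills + 1, dtype=float)
    if converged:
        heights = 0.3 * np.exp(-times / 40.0) + 0.005 * rng.random(n_hills)
    else:
        heights = 0.3 * np.ones(n_hills) + 0.01 * rng.random(n_hills)
    hills = HillsLedger(times=times,
                        centers=np.zeros((n_hills, 1)),
                        widths=0.1 * np.ones((n_hills, 1)),
                        heights=heights, bias_factor=10.0, initial_height=0.3)
    ct = np.linspace(0.0, float(n_hills), 4000)
    s = 0.5 + 0.5 * np.sin(ct * 2.1) + 0.02 * rng.standard_normal(ct.size)
    colvar = ColvarSeries(times=ct, values=s[:, None], bias=np.zeros(ct.size))
    return hills, colvar


class TestConvergenceWindow:
    def test_decaying_heights_and_diffusive_s(self):
        hills, colvar = synthetic_run(converged=True)
        w = convergence_window(hills, colvar)
        assert w.converged and w.diffusive
        assert w.t_start < w.t_end
        assert w.residual_fraction < 0.1
        # decay time 40, threshold 0.1 -> earliest possible start ~ 92
        assert w.t_start < 0.6 * w.t_end

    def test_constant_heights_not_converged(self):
        hills, colvar = synthetic_run(converged=False)
        w = convergence_window(hills, colvar)
        assert not w.converged
        assert w.t_start == w.t_end
        assert w.residual_fraction > 0.9

    def test_stuck_walker_not_diffusive(self):
        hills, colvar = synthetic_run(converged=True)
        stuck = ColvarSeries(times=colvar.times,
                             values=np.where(colvar.times[:, None] < 300.0,
                                             colvar.values,
                                             0.95 + 0.001 * colvar.values),
                             bias=colvar.bias)
        w = convergence_window(hills, stuck)
        assert not w.converged

    def test_empty_inputs_rejected(self):
        hills, colvar = synthetic_run()
        empty_hills = HillsLedger(times=np.array([]), centers=np.zeros((0, 1)),
                                  widths=np.zeros((0, 1)),
                                  heights=np.array([]), bias_factor=10.0,
                                  initial_height=0.3)
        with pytest.raises(ValueError):
            convergence_window(empty_hills, colvar)


class TestTimeStatistics:
    def test_mean_and_stderr_hand_value(self):
        mean, err = dg_time_stats([-9.0, -8.8, -9.2, -9.0])
        assert mean == pytest.approx(-9.0)
        assert err == pytest.approx(np.std([-9.0, -8.8, -9.2, -9.0], ddof=1)
                                    / 2.0)
        assert err == pytest.approx(0.0816, abs=1e-3)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            dg_time_stats([-9.0])

    def test_time_series_nan_before_first_hill(self):
        hills = one_hill_ledger(center=0.5, gamma=10.0)
        series = dg_time_series(hills, ((0.0, 1.0, 101),), 0.3, 300.0,
                                checkpoint_times=[0.5, 2.0])
        assert np.isnan(series[0])
        assert np.isfinite(series[1])

    def test_time_series_converges_to_full_ledger_value(self):
        rng = np.random.default_rng(1)
        n = 50
        hills = HillsLedger(times=np.arange(1.0, n + 1),
                            centers=rng.uniform(0.2, 0.8, (n, 1)),
                            widths=0.1 * np.ones((n, 1)),
                            heights=0.1 * np.ones(n),
                            bias_factor=10.0, initial_height=0.1)
        series = dg_time_series(hills, ((0.0, 1.0, 101),), 0.4, 300.0,
                                checkpoint_times=[n + 1.0])
        fes = fes_from_hills(hills, ((0.0, 1.0, 101),))
        assert series[-1] == pytest.approx(dg_bound_unbound(fes, 0.4))
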