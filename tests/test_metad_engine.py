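import math

import numpy as np
import pytest

from pathmetad.fixtures import (DoubleWellSpec, double_well_profile,
                                double_well_system, funnel_system)
from pathmetad.free_energy import fes_from_hills
from pathmetad.metad_engine import (ColvarSeries, GridBias, Hill, HillsLedger,
                                    IdentityCV, PathCV, ToySystem,
                                    WTMetaDParams, bias_energy, bias_force,
                                    langevin_coefficients, langevin_step,
                                    next_height, read_colvar, read_hills,
                                    run_wtmetad, wall_energy, write_colvar,
                                    write_hills)
from pathmetad.units import KCAL_TO_MD, kt


def small_ledger():
    return HillsLedger(times=np.array([1.0, 2.0]),
                       centers=np.array([[0.0, 0.01], [0.5, 0.02]]),
                       widths=np.tile([0.2, 0.01], (2, 1)),
                       heights=np.array([0.2, 0.15]),
                       bias_factor=15.0, initial_height=0.2)


class TestTempering:
    def test_zero_bias_gives_initial_height(self):
        assert next_height(0.2, 15.0, 0.0, 300.0) == pytest.approx(0.2)

    def test_halving_bias_value(self):
        gamma, t = 15.0, 300.0
        v = (gamma - 1.0) * kt(t) * math.log(2.0)
        assert next_height(0.2, gamma, v, t) == pytest.approx(0.1)

    def test_invalid_bias_factor(self):
        with pytest.raises(ValueError):
            next_height(0.2, 1.0, 0.0, 300.0)
        with pytest.raises(ValueError):
            WTMetaDParams(bias_factor=0.5)


class TestBiasSums:
    def test_single_hill_closed_form(self):
        h = Hill(time=0.0, center=np.array([1.0]), widths=np.array([0.2]),
                 height=0.3)
        assert bias_energy([1.0], [h]) == pytest.approx(0.3)
        expected = 0.3 * math.exp(-0.5)
        assert bias_energy([1.2], [h]) == pytest.approx(expected)

    def test_force_is_minus_numeric_gradient(self):
        hills = small_ledger()
        point = np.array([0.3, 0.015])
        f = bias_force(point, hills)
        eps = 1e-7
        for k in range(2):
            pp, pm = point.copy(), point.copy()
            pp[k] += eps
            pm[k] -= eps
            num = -(bias_energy(pp, hills) - bias_energy(pm, hills)) / (2 * eps)
            assert f[k] == pytest.approx(num, abs=1e-6)

    def test_grid_bias_matches_exact_sums(self):
        hills = small_ledger()
        gb = GridBias(((-1.0, 2.0, 601), (-0.05, 0.1, 151)))
        for i in range(len(hills)):
            gb.deposit(hills.centers[i], hills.widths[i], hills.heights[i])
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = np.array([rng.uniform(-0.5, 1.5), rng.uniform(-0.02, 0.06)])
            v, g = gb.value_and_grad(p)
            assert v == pytest.approx(bias_energy(p, hills), abs=2e-4)
            # bilinear interpolation: ~(h/sigma)^2 relative gradient error
            assert np.allclose(g, -bias_force(p, hills), rtol=1e-2, atol=1e-3)

    def test_grid_bias_1d(self):
        gb = GridBias(((-2.0, 2.0, 801),))
        gb.deposit(np.array([0.0]), np.array([0.3]), 0.25)
        v, g = gb.value_and_grad(np.array([0.3]))
        assert v == pytest.approx(0.25 * math.exp(-0.5), abs=1e-4)
        assert g[0] == pytest.approx(-0.25 * math.exp(-0.5) * 0.3 / 0.09,
                                     abs=1e-3)


def test_wall_energy_one_sided():
    assert wall_energy(0.03, 0.05, 2000.0) == 0.0
    assert wall_energy(0.07, 0.05, 2000.0) == pytest.approx(2000.0 * 0.02 ** 2)


class TestLangevin:
    def test_equipartition_in_harmonic_well(self):
        k_spring = 50.0  # kcal/mol/nm^2
        mass, temp, dt, friction = 1.0, 300.0, 0.002, 5.0

        def force(x):
            return -k_spring * x

        c1, c2 = langevin_coefficients(mass, dt, friction, temp)
        rng = np.random.default_rng(4)
        x = np.zeros(1)
        v = np.zeros(1)
        accel = force(x) * (KCAL_TO_MD / mass)
        xs, vs = [], []
        n_steps, burn = 400_000, 40_000
        noise = rng.standard_normal((n_steps, 1))
        for i in range(n_steps):
            x, v, accel = langevin_step(x, v, accel, force, mass, dt, c1, c2,
                                        noise[i])
            if i >= burn:
                xs.append(x[0])
                vs.append(v[0])
        xs = np.array(xs)
        vs = np.array(vs)
        assert xs.var() == pytest.approx(kt(temp) / k_spring, rel=0.1)
        assert vs.var() == pytest.approx(kt(temp) * KCAL_TO_MD / mass,
                                         rel=0.1)

    def test_nonfinite_force_detected(self):
        def bad_force(x):
            return np.array([np.nan])

        c1, c2 = langevin_coefficients(1.0, 0.002, 5.0, 300.0)
        with pytest.raises(FloatingPointError):
            langevin_step(np.zeros(1), np.zeros(1), np.zeros(1), bad_force,
                          1.0, 0.002, c1, c2, np.zeros(1))


class TestRunWTMetaD:
    def test_deterministic_given_seed(self):
        system = double_well_system()
        params = WTMetaDParams(sigma=(0.1,), pace=100, wall_position=None)
        a1, c1_ = run_wtmetad(system, IdentityCV((0,)), params, 5_000, seed=3,
                              x0=np.array([-0.7]))
        a2, c2_ = run_wtmetad(system, IdentityCV((0,)), params, 5_000, seed=3,
                              x0=np.array([-0.7]))
        assert np.array_equal(a1.centers, a2.centers)
        assert np.array_equal(a1.heights, a2.heights)
        assert np.array_equal(c1_.values, c2_.values)
        b1, _ = run_wtmetad(system, IdentityCV((0,)), params, 5_000, seed=4,
                            x0=np.array([-0.7]))
        assert not np.array_equal(a1.centers, b1.centers)

    def test_no_hills_when_run_shorter_than_pace(self):
        system = double_well_system()
        params = WTMetaDParams(sigma=(0.1,), pace=1_000, wall_position=None)
        hills, colvar = run_wtmetad(system, IdentityCV((0,)), params, 300,
                                    seed=0, x0=np.array([-0.7]), stride=50)
        assert len(hills) == 0
        assert len(colvar) == 6

    def test_heights_temper_downwards(self):
        system = double_well_system()
        params = WTMetaDParams(sigma=(0.1,), pace=200, wall_position=None,
                               bias_factor=5.0)
        hills, _ = run_wtmetad(system, IdentityCV((0,)), params, 100_000,
                               seed=5, x0=np.array([-0.7]), dt=0.005)
        n = len(hills)
        assert hills.heights[0] == pytest.approx(params.initial_height)
        assert hills.heights[-n // 4:].mean() < 0.5 * params.initial_height

    def test_path_cv_run_requires_grid(self):
        system = funnel_system()
        refs = np.column_stack([np.linspace(0.0, 0.8, 9),
                                np.zeros(9), np.zeros(9)])
        cv = PathCV(refs, 230.0)
        with pytest.raises(ValueError):
            run_wtmetad(system, cv, WTMetaDParams(), 1_000, seed=0)


class TestDoubleWellRecovery:
    def test_free_energy_profile_within_tolerance(self, double_well_run):
        spec, params, hills, _ = double_well_run
        grid = ((-1.3, 1.3, 261),)
        fes = fes_from_hills(hills, grid)
        x = fes.s_axis
        exact = double_well_profile(spec, x)
        mask = np.abs(x) <= spec.half_separation + 0.25
        est = fes.values[mask] - fes.values[mask].mean()
        ref = exact[mask] - exact[mask].mean()
        rmsd = float(np.sqrt(np.mean((est - ref) ** 2)))
        assert rmsd <= 0.3

    def test_both_wells_visited(self, double_well_run):
        _, _, _, colvar = double_well_run
        x = colvar.values[:, 0]
        assert x.min() < -0.5 and x.max() > 0.5


class TestFileDialect:
    def test_hills_round_trip(self, tmp_path):
        ledger = small_ledger()
        f = tmp_path / "HILLS"
        write_hills(ledger, f)
        back = read_hills(f)
        assert np.allclose(back.times, ledger.times)
        assert np.allclose(back.centers, ledger.centers)
        assert np.allclose(back.widths, ledger.widths)
        assert np.allclose(back.heights, ledger.heights)
        assert back.bias_factor == ledger.bias_factor
        assert back.cv_names == ("s", "z")

    def test_colvar_round_trip(self, tmp_path):
        series = ColvarSeries(times=np.array([0.1, 0.2, 0.3]),
                              values=np.array([[1.0, 0.01], [2.0, 0.02],
                                               [1.5, 0.015]]),
                              bias=np.array([0.0, 0.1, 0.2]))
        f = tmp_path / "COLVAR"
        write_colvar(series, f)
        back = read_colvar(f)
        assert np.allclose(back.times, series.times)
        assert np.allclose(back.values, series.values)
        assert np.allclose(back.bias, series.bias)

    def test_reader_tolerates_comments(self, tmp_path):
        f = tmp_path / "HILLS"
        f.write_text("#! FIELDS time s sigma_s height biasf\n"
                     "# a stray comment\n"
                     "1.0 0.5 0.2 0.2 15\n"
                     "\n"
                     "2.0 0.6 0.2 0.18 15\n")
        hills = read_hills(f)
        assert len(hills) == 2
        assert hills.centers.shape == (2, 1)
        assert hills.cv_names == ("s",)

    def test_reader_rejects_non_hills_text(self, tmp_path):
        f = tmp_path / "junk.txt"
        f.write_text("hello world\n")
        with pytest.raises(ValueError):
            read_hills(f)
        with pytest.raises(ValueError):
            read_colvar(f)
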