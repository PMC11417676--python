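"""Collective variables, umbrella sampling, WHAM and free-energy corrections."""

import numpy as np
import pytest

from solvshell.cv import CoordinationCV, DistanceCV, coordination_number, switching_function
from solvshell.sampling import (
    PmfProfile,
    WindowSpec,
    barrier_and_uncertainty,
    boltzmann_inversion,
    histogram_overlap,
    jacobian_correction,
    wham,
)
from solvshell.units import KB


class _Dummy1DCV:
    kind = "interatomic-distance"


class TestCoordinationCV:
    def test_saturation_at_short_distances(self):
        pos = np.zeros((5, 3))
        pos[1:] = np.array([[0.1, 0, 0], [0, 0.1, 0], [0, 0, 0.1], [0.1, 0.1, 0]])
        val, _ = coordination_number(pos, (0, [1, 2, 3, 4]), r0=2.5)
        assert val == pytest.approx(4.0, abs=1e-3)

    def test_limit_value_at_r0_is_p_over_q(self):
        pos = np.array([[0.0, 0, 0], [2.5, 0, 0]])
        val, _ = coordination_number(pos, (0, [1]), r0=2.5, p=6, q=12)
        assert val == pytest.approx(0.5, abs=1e-6)

    def test_closed_form_sum(self):
        """4 ligands at 0.5 r0 + 2 at 2 r0 matches term-by-term evaluation."""
        r0 = 3.0
        rs = [0.5 * r0] * 4 + [2.0 * r0] * 2
        pos = np.zeros((7, 3))
        for i, r in enumerate(rs):
            d = np.zeros(3)
            d[i % 3] = r
            pos[i + 1] = d
        val, _ = coordination_number(pos, (0, list(range(1, 7))), r0=r0, p=6, q=12)
        s = lambda x: (1 - x**6) / (1 - x**12)
        expected = 4 * s(0.5) + 2 * s(2.0)
        assert val == pytest.approx(expected, rel=1e-10)

    def test_gradient_finite_difference_including_r0(self):
        rng = np.random.default_rng(5)
        pos = rng.uniform(-2, 2, (6, 3))
        pos[3] = [2.5, 0.0, 0.0]  # exactly at r0 from center 0 at origin
        pos[0] = 0.0
        cv = CoordinationCV(center=0, ligands=np.arange(1, 6), r0=2.5)
        _, grad = cv.value_and_gradient(pos)
        h = 1e-6
        for a in range(6):
            for alpha in range(3):
                pos[a, alpha] += h
                vp = cv.value(pos)
                pos[a, alpha] -= 2 * h
                vm = cv.value(pos)
                pos[a, alpha] += h
                assert grad[a, alpha] == pytest.approx((vp - vm) / (2 * h), abs=1e-6)

    def test_switching_function_continuous_through_r0(self):
        r = np.linspace(2.4999, 2.5001, 101)
        s, ds = switching_function(r, 2.5, 6, 12)
        assert np.all(np.diff(s) < 0)
        assert np.abs(np.diff(ds)).max() < 1e-3

    def test_exponent_validation(self):
        with pytest.raises(ValueError):
            CoordinationCV(0, [1], r0=2.5, p=12, q=6)
        with pytest.raises(ValueError):
            CoordinationCV(0, [1], r0=2.5, p=5, q=12)


class TestDistanceCV:
    def test_value_and_gradient(self):
        pos = np.array([[0.0, 0, 0], [3.0, 4.0, 0.0]])
        cv = DistanceCV(0, 1)
        val, grad = cv.value_and_gradient(pos)
        assert val == pytest.approx(5.0)
        np.testing.assert_allclose(grad[0], [-0.6, -0.8, 0.0])
        np.testing.assert_allclose(grad[1], [0.6, 0.8, 0.0])


def _mc_window_series(U, centers, k, T, rng, n=20_000, lo=-1.6, hi=1.6):
    """Exact Monte-Carlo draws from each biased Boltzmann density."""
    beta = 1.0 / (KB * T)
    grid = np.linspace(lo, hi, 4001)
    series, windows = [], []
    for c in centers:
        w = np.exp(-beta * (U(grid) + k * (grid - c) ** 2))
        w /= w.sum()
        cdf = np.cumsum(w)
        series.append(np.interp(rng.random(n), cdf, grid))
        windows.append(WindowSpec(cv=_Dummy1DCV(), center=c, k_umb=k))
    return series, windows


class TestWham:
    def test_double_well_barrier_recovery(self):
        """Analytic double-well (5 kcal/mol barrier), 12 harmonic windows,
        exact MC sampling: WHAM recovers the barrier within 0.2 kcal/mol."""
        rng = np.random.default_rng(0)
        U = lambda x: 5.0 * (x**2 - 1.0) ** 2
        series, windows = _mc_window_series(U, np.linspace(-1.1, 1.1, 12), 20.0,
                                            300.0, rng)
        pmf = wham(series, windows, 300.0, n_bins=120)
        assert pmf.wham_residual < 1e-7
        _, barrier, _, _ = barrier_and_uncertainty([pmf], ts_location=0.0)
        assert barrier == pytest.approx(5.0, abs=0.2)

    def test_pointwise_profile_recovery(self):
        """Reconstructed profile matches the analytic PES wherever sampled."""
        rng = np.random.default_rng(1)
        U = lambda x: 3.0 * (x**2 - 1.0) ** 2
        series, windows = _mc_window_series(U, np.linspace(-1.2, 1.2, 14), 15.0,
                                            300.0, rng)
        pmf = wham(series, windows, 300.0, n_bins=100)
        ref = U(pmf.grid)
        mask = ~np.isnan(pmf.free_energy) & (np.abs(pmf.grid) < 1.25)
        diff = pmf.free_energy[mask] - ref[mask]
        diff -= diff.mean()
        assert np.abs(diff).max() < 0.35

    def test_gauge_invariance_under_constant_shift(self):
        rng = np.random.default_rng(2)
        U = lambda x: 4.0 * (x**2 - 1.0) ** 2
        series, windows = _mc_window_series(U, np.linspace(-1.1, 1.1, 10), 15.0,
                                            300.0, rng)
        pmf1 = wham(series, windows, 300.0, n_bins=80)
        shifted = [s + 5.0 for s in series]
        windows2 = [WindowSpec(cv=_Dummy1DCV(), center=w.center + 5.0, k_umb=w.k_umb)
                    for w in windows]
        pmf2 = wham(shifted, windows2, 300.0, n_bins=80)
        a = pmf1.free_energy
        b = pmf2.free_energy
        mask = ~np.isnan(a) & ~np.isnan(b)
        np.testing.assert_allclose(a[mask], b[mask], atol=0.2)

    def test_temperature_scaling_consistency(self):
        """Same samples at doubled temperature rescale A through kB T."""
        rng = np.random.default_rng(3)
        samples = rng.normal(0.0, 0.2, 50_000)
        w = [WindowSpec(cv=_Dummy1DCV(), center=0.0, k_umb=1e-12)]
        a1 = wham([samples], w, 300.0, n_bins=60)
        a2 = wham([samples], w, 600.0, n_bins=60)
        mask = ~np.isnan(a1.free_energy)
        np.testing.assert_allclose(a2.free_energy[mask], 2.0 * a1.free_energy[mask],
                                   atol=1e-6)

    def test_single_unbiased_window_is_boltzmann_inversion(self):
        rng = np.random.default_rng(4)
        samples = rng.normal(0.0, 0.3, 30_000)
        w = [WindowSpec(cv=_Dummy1DCV(), center=0.0, k_umb=1e-12)]
        pmf = wham([samples], w, 300.0, n_bins=50)
        direct = boltzmann_inversion(samples, 300.0, n_bins=50)
        mask = ~np.isnan(pmf.free_energy)
        np.testing.assert_allclose(pmf.free_energy[mask], direct.free_energy[mask],
                                   atol=1e-6)

    def test_non_overlapping_windows_error_names_gap(self):
        rng = np.random.default_rng(5)
        s1 = rng.normal(0.0, 0.01, 1000)
        s2 = rng.normal(5.0, 0.01, 1000)
        windows = [WindowSpec(cv=_Dummy1DCV(), center=0.0, k_umb=100.0),
                   WindowSpec(cv=_Dummy1DCV(), center=5.0, k_umb=100.0)]
        with pytest.raises(ValueError, match="overlap"):
            wham([s1, s2], windows, 300.0)

    def test_histogram_overlap_reporting(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.0, 0.5, 5000)
        b = rng.normal(0.5, 0.5, 5000)
        c = rng.normal(9.0, 0.1, 5000)
        ov = histogram_overlap([a, b, c])
        assert ov[0] > 0.3
        assert ov[1] == 0.0


class TestJacobianCorrection:
    def _flat_pmf(self):
        grid = np.linspace(1.0, 6.0, 101)
        return PmfProfile(grid=grid, free_energy=np.zeros_like(grid),
                          cv_kind="interatomic-distance")

    def test_zero_at_reference(self):
        """The correction term vanishes at r = r_ref (profile unchanged there,
        up to the overall min = 0 gauge)."""
        raw = self._flat_pmf()
        pmf = jacobian_correction(raw, 300.0, r_ref=2.0)
        i = np.argmin(np.abs(pmf.grid - 2.0))
        added = pmf.free_energy - 2 * KB * 300.0 * np.log(pmf.grid / 2.0)
        # the added term is a constant (the re-gauge); at r_ref the correction is 0
        assert np.ptp(added) == pytest.approx(0.0, abs=1e-9)

    def test_value_at_twice_reference(self):
        """2 kB T ln 2 between r_ref and 2 r_ref at 300 K is 0.8265 kcal/mol."""
        pmf = jacobian_correction(self._flat_pmf(), 300.0, r_ref=2.0)
        i2 = np.argmin(np.abs(pmf.grid - 4.0))
        i1 = np.argmin(np.abs(pmf.grid - 2.0))
        delta = pmf.free_energy[i2] - pmf.free_energy[i1]
        assert delta == pytest.approx(0.8265, abs=2e-3)
        assert delta == pytest.approx(2 * KB * 300.0 * np.log(2.0), abs=1e-6)

    def test_flat_input_becomes_pure_log_term(self):
        """Flat A(r) in, exactly the log term out, with its minimum at r_ref
        (the left edge of the grid here, so the gauge is untouched)."""
        pmf = jacobian_correction(self._flat_pmf(), 300.0, r_ref=1.0)
        expected = 2 * KB * 300.0 * np.log(pmf.grid / 1.0)
        np.testing.assert_allclose(pmf.free_energy, expected, atol=1e-9)
        assert pmf.grid[np.argmin(pmf.free_energy)] == pmf.grid[0]
        assert pmf.jacobian_corrected

    def test_rejects_coordination_cv(self):
        grid = np.linspace(3.5, 5.5, 50)
        pmf = PmfProfile(grid=grid, free_energy=np.zeros(50),
                         cv_kind="coordination-number")
        with pytest.raises(ValueError):
            jacobian_correction(pmf, 300.0, r_ref=4.0)


class TestBarrier:
    def _profile(self, shift=0.0):
        grid = np.linspace(1.5, 6.0, 200)
        A = 8.0 * np.exp(-((grid - 2.1) ** 2) / 0.05)
        A = -A
        A += 6.0 * np.exp(-((grid - 3.1) ** 2) / 0.3)
        return PmfProfile(grid=grid, free_energy=A - A.min() + shift)

    def test_identical_repeats_zero_std(self):
        p = self._profile()
        _, barrier, std, loc = barrier_and_uncertainty([p, p])
        assert std == 0.0
        assert loc == pytest.approx(3.1, abs=0.1)

    def test_single_repeat_warns_and_reports_zero(self, caplog):
        with caplog.at_level("WARNING"):
            _, _, std, _ = barrier_and_uncertainty([self._profile()])
        assert std == 0.0
        assert any("single" in r.message for r in caplog.records)

    def test_supplied_ts_location(self):
        p = self._profile()
        _, barrier, _, loc = barrier_and_uncertainty([p], ts_location=3.5)
        i_ts = np.argmin(np.abs(p.grid - 3.5))
        assert loc == pytest.approx(p.grid[i_ts])

    def test_mismatched_grids_rejected(self):
        p1 = self._profile()
        grid = np.linspace(0, 1, 10)
        p2 = PmfProfile(grid=grid, free_energy=np.zeros(10))
        with pytest.raises(ValueError):
            barrier_and_uncertainty([p1, p2])

    def test_uncertainty_nonnegative_enforced(self):
        with pytest.raises(ValueError):
            PmfProfile(grid=np.arange(3.0), free_energy=np.zeros(3),
                       uncertainty=np.array([0.1, -0.2, 0.0]))


class _XCalc:
    """Toy calculator: harmonic well in the 0-1 interatomic distance."""

    elements = ["Mg", "O"]
    cutoff = np.inf

    def __init__(self, k=5.0, x0=3.0):
        self.k = k
        self.x0 = x0
        self._cv = DistanceCV(0, 1)

    def bind(self, config):
        def _ef(pos):
            d, grad = self._cv.value_and_gradient(pos)
            e = self.k * (d - self.x0) ** 2 + 0.05 * float((pos[0] ** 2).sum())
            f = -2.0 * self.k * (d - self.x0) * grad
            f[0] -= 0.1 * pos[0]
            return e, f
        return _ef

    def energy_forces(self, config):
        return self.bind(config)(config.positions)


class TestUmbrellaMD:
    def _start(self, x=3.0):
        from solvshell.structures import Configuration

        return Configuration(["Mg", "O"], np.array([[0.0, 0, 0], [x, 0.0, 0.0]]),
                             molecule_ids=np.array([0, 1]))

    def test_window_mean_is_bias_pes_compromise(self):
        """Harmonic PES (min x0, stiffness k_t) + harmonic bias (center c,
        k_u) on the same coordinate: stationary mean = weighted average
        (k_t x0 + k_u c)/(k_t + k_u)."""
        from solvshell.sampling import WindowSpec, run_umbrella

        k_t, x0 = 5.0, 3.0
        calc = _XCalc(k=k_t, x0=x0)
        cv = DistanceCV(0, 1)
        k_u, c = 20.0, 3.5
        windows = [WindowSpec(cv=cv, center=c, k_umb=k_u, n_steps=30_000,
                              n_equil=4_000, seed=3, temperature=300.0,
                              start=self._start())]
        (series,) = run_umbrella(windows, calc)
        expected = (k_t * x0 + k_u * c) / (k_t + k_u)
        assert series.mean() == pytest.approx(expected, abs=0.05)

    def test_identical_seeds_identical_series(self):
        from solvshell.sampling import WindowSpec, run_umbrella

        calc = _XCalc()
        cv = DistanceCV(0, 1)
        w = WindowSpec(cv=cv, center=3.0, k_umb=30.0, n_steps=3000, n_equil=500,
                       seed=9, start=self._start())
        (a,) = run_umbrella([w], calc)
        (b,) = run_umbrella([w], calc)
        np.testing.assert_array_equal(a, b)

    def test_too_few_samples_flagged(self):
        from solvshell.sampling import WindowSpec, run_umbrella

        calc = _XCalc()
        w = WindowSpec(cv=DistanceCV(0, 1), center=3.0, k_umb=30.0, n_steps=300,
                       n_equil=290, seed=1, start=self._start())
        with pytest.raises(ValueError, match="samples"):
            run_umbrella([w], calc)

    def test_unordered_windows_rejected(self):
        from solvshell.sampling import WindowSpec, run_umbrella

        calc = _XCalc()
        ws = [WindowSpec(cv=DistanceCV(0, 1), center=c, k_umb=30.0,
                         start=self._start()) for c in (4.0, 3.0)]
        with pytest.raises(ValueError, match="ordered"):
            run_umbrella(ws, calc)


class TestSteeredMD:
    def test_stationary_schedule_is_restrained_equilibrium(self):
        from solvshell.md import initialize_state
        from solvshell.sampling import steered_md

        calc = _XCalc(k=5.0, x0=3.0)
        cv = DistanceCV(0, 1)
        state = initialize_state(
            __import__("solvshell").structures.Configuration(
                ["Mg", "O"], np.array([[0.0, 0, 0], [3.0, 0, 0]]),
                molecule_ids=np.array([0, 1])), 300.0, seed=2)
        traj, cvs = steered_md(state, calc, cv, 3.0, 3.0, k_pull=50.0,
                               n_steps=4000)
        assert abs(cvs[len(cvs) // 2:].mean() - 3.0) < 0.1

    def test_zero_pull_constant_is_plain_md(self):
        from solvshell.md import initialize_state
        from solvshell.sampling import steered_md
        from solvshell.structures import Configuration

        calc = _XCalc(k=0.5, x0=3.0)
        state = initialize_state(
            Configuration(["Mg", "O"], np.array([[0.0, 0, 0], [3.0, 0, 0]]),
                          molecule_ids=np.array([0, 1])), 300.0, seed=4)
        traj, cvs = steered_md(state, calc, DistanceCV(0, 1), 2.0, 6.0,
                               k_pull=0.0, n_steps=2000)
        # CV ignores the (zero-strength) moving restraint
        assert cvs.std() > 0.0

    def test_ion_water_pull_reaches_target(self, water_calc, hexaaqua):
        """Pulling one first-shell solvent molecule from 2 to 6 Å: the CV
        tracks the moving center to the end."""
        import solvshell as ss
        from solvshell.md import initialize_state
        from solvshell.sampling import steered_md

        # CV: metal (0) to the O of the first ligand (1)
        cv = DistanceCV(1, 0)
        state = initialize_state(hexaaqua, 300.0, seed=5)
        fb = ss.RestraintSpec(center=0, r_fb=8.0, k=500.0)
        from solvshell.md import FlatBottomRestraint
        traj, cvs = steered_md(
            state, water_calc, cv, 2.05, 6.0, k_pull=500.0, n_steps=8000,
            extra_restraints=[FlatBottomRestraint(fb, hexaaqua.n_atoms)],
        )
        assert abs(cvs[-1] - 6.0) < 0.2


class TestDissociationPmfShape:
    def test_scaled_ligand_exchange_profile(self, water_calc):
        """Scaled umbrella run (12 windows, 20 ps each) on the classical
        ion-water cluster: the dissociation PMF has a first-shell minimum,
        a single barrier, and a plateau beyond it (shape property only)."""
        import solvshell as ss
        from solvshell.fixtures import build_complex, solvate_complex, minimize
        from solvshell.md import FlatBottomRestraint, initialize_state
        from solvshell.sampling import (
            WindowSpec, barrier_and_uncertainty, jacobian_correction,
            pick_window_starts, run_umbrella, steered_md, wham,
        )

        comp = build_complex("octahedral", bond_length=2.05)
        cluster = minimize(solvate_complex(comp, 14, 5.5, seed=8), water_calc, 300)
        fbr = FlatBottomRestraint(ss.RestraintSpec(center=0, r_fb=6.5, k=500.0),
                                  cluster.n_atoms)
        cv = DistanceCV(1, 0)
        state = initialize_state(cluster, 300.0, seed=9)
        traj, cvs = steered_md(state, water_calc, cv, 2.05, 5.0, k_pull=200.0,
                               n_steps=12_000, extra_restraints=[fbr])
        centers = np.linspace(2.0, 5.0, 12)
        windows = [
            WindowSpec(cv=cv, center=c, k_umb=25.0, n_steps=40_000, n_equil=8_000,
                       seed=100 + i, temperature=300.0, start=s, restraints=(fbr,))
            for i, (c, s) in enumerate(zip(centers, pick_window_starts(traj, cvs, centers)))
        ]
        series = run_umbrella(windows, water_calc)
        pmf = wham(series, windows, 300.0, n_bins=120)
        pmf = jacobian_correction(pmf, 300.0,
                                  r_ref=pmf.grid[np.nanargmin(pmf.free_energy)])
        _, barrier, _, loc = barrier_and_uncertainty([pmf])
        g, A = pmf.grid, pmf.free_energy
        r_min = g[np.nanargmin(A)]
        # first-shell minimum where the metal-oxygen bond sits
        assert 1.9 < r_min < 2.3
        # one barrier between the minimum and the dissociated plateau
        assert barrier > 2.0
        assert r_min < loc < 4.0
        plateau = A[(g > loc + 0.7) & ~np.isnan(A)]
        assert plateau.size > 0
        assert plateau.max() < barrier + 1.0
        assert plateau.mean() < barrier
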