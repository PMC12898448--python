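"""Density profiles, dG = -kT ln rho, replica averaging, double-Gaussian fits."""
import numpy as np
import pytest
from scipy import integrate

import memperm as mp
from memperm.models import double_gaussian


def quadrature_bin_density(pmf, temperature, edges):
    grid, dens = mp.boltzmann_density(pmf, temperature, grid_points=20001)
    cdf = integrate.cumulative_trapezoid(dens, grid, initial=0.0)
    mass = np.diff(np.interp(edges, grid, cdf))
    return mass / np.diff(edges)


def true_barrier_height(pmf, lo=-3.0, hi=3.0):
    """Fine-grid oracle: interior extremum vs mean of the flanking extrema."""
    grid = np.linspace(lo, hi, 60001)
    v = pmf.energy(grid)
    half = grid.size // 2
    left = v[:half].max()
    right = v[half:].max()
    centre = v[(grid > grid[:half][np.argmax(v[:half])]) &
               (grid < grid[half:][np.argmax(v[half:])])].min()
    return 0.5 * (left + right) - centre


class TestDensityProfile:
    def test_uniform_samples_fill_bins_evenly(self):
        rng = np.random.default_rng(1)
        s = rng.uniform(-6, 6, 120_000)
        prof = mp.density_profile(s, 0.1, bounds=(-6, 6))
        p = 1 / prof.bin_centers.size
        se = np.sqrt(p * (1 - p) / s.size)
        assert np.all(np.abs(prof.counts / s.size - p) < 5 * se)
        assert prof.density.sum() * prof.bin_width == pytest.approx(1.0)

    def test_delta_like_profile_still_normalizes(self):
        prof = mp.density_profile(np.zeros(100), 0.1, bounds=(-1, 1))
        assert prof.density.sum() * prof.bin_width == pytest.approx(1.0)
        assert np.count_nonzero(prof.counts) == 1

    def test_boltzmann_samples_match_quadrature_density(self):
        pmf = mp.PMFSpec.symmetric_barrier(1.0, 0.8, 0.5, domain=(-4, 4))
        n = 200_000
        s = mp.sample_boltzmann(pmf, 440.0, n, seed=9)
        prof = mp.density_profile(s, 0.1, bounds=(-4, 4))
        edges = np.arange(-4, 4.05, 0.1)
        want = quadrature_bin_density(pmf, 440.0, edges)
        se = np.sqrt(want * prof.bin_width * (1 - want * prof.bin_width) / n) \
            / prof.bin_width
        assert np.max(np.abs(prof.density - want) / np.maximum(se, 1e-12)) < 5

    def test_no_samples_fails(self):
        with pytest.raises(ValueError):
            mp.density_profile(np.array([]), 0.1, bounds=(0, 1))


class TestFreeEnergyProfile:
    def test_two_to_one_density_ratio_gives_kt_ln2(self):
        prof = mp.DensityProfile(np.array([0.0, 0.1]), np.array([200, 100]), 0.1)
        fep = mp.free_energy_profile(prof, 440.0)
        expected = mp.KB_KCAL_PER_MOL_K * 440.0 * np.log(2)
        assert fep.dg[1] - fep.dg[0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.606, abs=1e-3)

    def test_uniform_density_gives_flat_zero_profile(self):
        prof = mp.DensityProfile(np.arange(10) * 0.1, np.full(10, 50), 0.1)
        fep = mp.free_energy_profile(prof, 440.0)
        assert np.allclose(fep.dg, 0.0)

    def test_empty_bins_are_masked_not_imputed(self):
        prof = mp.DensityProfile(np.arange(4) * 0.1, np.array([10, 0, 5, 0]), 0.1)
        fep = mp.free_energy_profile(prof, 300.0)
        assert list(fep.mask) == [True, False, True, False]

    def test_round_trip_reproduces_density_on_unmasked_bins(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 500, size=40)
        prof = mp.DensityProfile(np.arange(40) * 0.1, counts, 0.1)
        fep = mp.free_energy_profile(prof, 440.0)
        kt = mp.thermal_energy(440.0)
        w = np.exp(-fep.dg[fep.mask] / kt)
        w = w / (w.sum() * 0.1)
        rho = prof.density[fep.mask]
        rho = rho / (rho.sum() * 0.1)
        assert np.allclose(w, rho, rtol=1e-12)

    def test_profile_recovered_from_generator_ground_truth(self):
        pmf = mp.PMFSpec.symmetric_barrier(1.0, 0.8, 0.5, domain=(-6, 6))
        s = mp.sample_boltzmann(pmf, 440.0, 1_000_000, seed=17)
        prof = mp.density_profile(s, 0.1, bounds=(-6, 6))
        fep = mp.free_energy_profile(prof, 440.0)
        truth = pmf.energy(fep.eta)
        well = fep.counts >= 100
        err = np.abs((fep.dg - fep.dg[well].min()) - (truth - truth[well].min()))
        assert np.nanmax(err[well]) < 0.1


class TestAverageProfiles:
    def _profile(self, dg, t=440.0):
        eta = np.arange(len(dg)) * 0.1
        return mp.FreeEnergyProfile(eta, np.asarray(dg, float), t)

    def test_identical_replicas_average_to_themselves(self):
        p = self._profile([0.0, 0.5, 1.0])
        avg = mp.average_profiles([p, p, p])
        assert np.allclose(avg.dg, p.dg)
        assert np.allclose(avg.sd, 0.0)

    def test_constant_offset_pair_has_sd_shift_over_sqrt2(self):
        a = self._profile([0.0, 0.5, 1.0])
        b = self._profile([0.4, 0.9, 1.4])
        avg = mp.average_profiles([a, b])
        assert np.allclose(avg.dg, a.dg + 0.2)
        assert np.allclose(avg.sd, 0.4 / np.sqrt(2))

    def test_masked_bin_in_any_replica_masks_the_mean(self):
        a = self._profile([0.0, np.nan, 1.0])
        b = self._profile([0.2, 0.5, 0.8])
        avg = mp.average_profiles([a, b])
        assert not np.isfinite(avg.dg[1])

    def test_five_noisy_replicas_match_brute_force_statistics(self):
        rng = np.random.default_rng(5)
        reps = [self._profile(rng.normal(1.0, 0.1, size=20)) for _ in range(5)]
        avg = mp.average_profiles(reps)
        stack = np.vstack([r.dg for r in reps])
        assert np.allclose(avg.dg, stack.mean(axis=0))
        assert np.allclose(avg.sd, stack.std(axis=0, ddof=1))

    def test_binning_mismatch_fails(self):
        a = self._profile([0.0, 1.0, 2.0])
        b = mp.FreeEnergyProfile(np.array([0.0, 0.2, 0.4]),
                                 np.array([0.0, 1.0, 2.0]), 440.0)
        with pytest.raises(ValueError, match="binning"):
            mp.average_profiles([a, b])


class TestDoubleGaussianFit:
    TRUE = (1.0, -1.0, 0.5, 1.0, 1.0, 0.5)

    def _noiseless_profile(self):
        eta = np.linspace(-3, 3, 121)
        return eta, double_gaussian(eta, *self.TRUE)

    def test_noiseless_curve_recovered_to_four_significant_figures(self):
        eta, y = self._noiseless_profile()
        fit = mp.fit_double_gaussian((eta, y))
        assert np.allclose(fit.params, self.TRUE, rtol=1e-4)

    def test_mirror_symmetry_swaps_centers_only(self):
        eta, y = self._noiseless_profile()
        fit = mp.fit_double_gaussian((eta, y))
        mirror = mp.fit_double_gaussian((eta, y[::-1]))
        assert mirror.params[1] == pytest.approx(-fit.params[4], abs=1e-6)
        assert mirror.width == pytest.approx(fit.width, abs=1e-8)
        assert mirror.barrier_height == pytest.approx(fit.barrier_height, abs=1e-8)

    def test_barrier_height_matches_fine_grid_evaluation(self):
        eta, y = self._noiseless_profile()
        fit = mp.fit_double_gaussian((eta, y))
        # analytic: centre 2 e^-2, flanks ~ 1.0
        assert fit.barrier_height == pytest.approx(0.730, abs=2e-3)
        assert fit.orientation == "maxima_flanking_minimum"

    def test_amplitude_scaling_scales_the_barrier(self):
        eta = np.linspace(-3, 3, 121)
        y1 = double_gaussian(eta, *self.TRUE)
        fit1 = mp.fit_double_gaussian((eta, y1))
        fit2 = mp.fit_double_gaussian((eta, 2 * y1))
        assert fit2.barrier_height == pytest.approx(2 * fit1.barrier_height, rel=1e-6)

    def test_flat_profile_has_no_extremum(self):
        prof = mp.FreeEnergyProfile(np.arange(30) * 0.1, np.zeros(30), 440.0)
        with pytest.raises((mp.FitError, ValueError)):
            mp.barrier_metrics(prof)

    def test_raw_profile_fallback_is_max_minus_min(self):
        eta = np.linspace(-3, 3, 61)
        pmf = mp.PMFSpec.symmetric_barrier(1.0, 0.8, 0.5)
        prof = mp.FreeEnergyProfile(eta, pmf.energy(eta), 440.0)
        got = mp.barrier_metrics(prof, membrane_bounds=(-3, 3))
        assert got == pytest.approx(pmf.energy(eta).max() - pmf.energy(eta).min())


class TestBootstrap:
    def test_zero_residuals_degenerate_ci(self):
        eta = np.linspace(-3, 3, 121)
        y = double_gaussian(eta, 1.0, -1.0, 0.5, 1.0, 1.0, 0.5)
        fit = mp.fit_double_gaussian((eta, y))
        out = mp.bootstrap_width_ci(fit, n_boot=200, seed=0)
        assert out.ci == (out.width, out.width)

    def test_same_seed_reproduces_the_interval(self):
        rng = np.random.default_rng(11)
        eta = np.linspace(-3, 3, 121)
        y = double_gaussian(eta, 1.0, -1.0, 0.5, 1.0, 1.0, 0.5) + \
            rng.normal(0, 0.05, eta.size)
        fit = mp.fit_double_gaussian((eta, y))
        a = mp.bootstrap_width_ci(fit, n_boot=200, seed=4)
        b = mp.bootstrap_width_ci(fit, n_boot=200, seed=4)
        assert a.ci == b.ci
        assert a.ci[0] < a.width < a.ci[1]

    def test_ci_width_shrinks_with_bin_count(self):
        rng = np.random.default_rng(12)
        widths = []
        for n_bins in (80, 320):
            eta = np.linspace(-3, 3, n_bins)
            y = double_gaussian(eta, 1.0, -1.0, 0.5, 1.0, 1.0, 0.5) + \
                rng.normal(0, 0.05, eta.size)
            fit = mp.fit_double_gaussian((eta, y))
            out = mp.bootstrap_width_ci(fit, n_boot=300, seed=5)
            widths.append(out.ci[1] - out.ci[0])
        # quadrupling the bins should roughly halve the CI width
        assert widths[1] < 0.75 * widths[0]

    def test_coverage_of_the_true_width(self):
        """Residual bootstrap CI covers the true sigma in >=90% of repetitions."""
        true = (1.0, -1.0, 0.5, 1.0, 1.0, 0.5)
        eta = np.linspace(-3, 3, 121)
        base = double_gaussian(eta, *true)
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            y = base + rng.normal(0, 0.05, eta.size)
            fit = mp.fit_double_gaussian((eta, y))
            out = mp.bootstrap_width_ci(fit, n_boot=200, seed=rep)
            if out.ci[0] <= 0.5 <= out.ci[1]:
                hits += 1
        assert hits >= 0.9 * n_rep
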