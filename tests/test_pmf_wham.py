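import numpy as np
import pytest

from rigidpmf import pmf_wham as pw
from rigidpmf import synthetic_data as sd

KT300 = pw.KB * 300.0


def harmonic_fixture(n=2000, seed=0):
    pot = sd.PotentialSpec("harmonic", {"a": 2.0, "r_min": 34.0})
    specs = pw.plan_umbrella_windows(26, 42, 1.0, k=1.0)
    return pot, sd.umbrella_sampler(pot, specs, n, seed=seed, method="exact")


class TestWindowPlanning:
    @pytest.mark.parametrize(
        "rmin,rmax,spacing,count", [(26, 42, 1, 17), (0, 10, 5, 3), (26, 42, 2, 9)]
    )
    def test_counts(self, rmin, rmax, spacing, count):
        wins = pw.plan_umbrella_windows(rmin, rmax, spacing)
        assert len(wins) == count
        assert wins[0]["r0"] == rmin
        assert wins[-1]["r0"] == pytest.approx(rmin + (count - 1) * spacing)

    def test_oversized_spacing_warns_single_window(self):
        with pytest.warns(UserWarning, match="single window"):
            wins = pw.plan_umbrella_windows(0, 10, 20)
        assert len(wins) == 1

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            pw.plan_umbrella_windows(42, 26, 1)
        with pytest.raises(ValueError):
            pw.plan_umbrella_windows(26, 42, 0)


class TestWham:
    def test_single_unbiased_window_is_boltzmann_inversion(self, rng):
        # samples from N(34, sigma^2) => G(r) = kT (r-34)^2 / (2 sigma^2) + const
        sigma = 0.6
        samples = rng.normal(34.0, sigma, 200_000)
        w = pw.UmbrellaWindow(34.0, 0.0, np.arange(samples.size, dtype=float), samples,
                              equilibration_cut=0.0)
        prof = pw.wham_pmf([w], bin_width=0.1)
        expect = KT300 * (prof.bin_centers - 34.0) ** 2 / (2 * sigma**2)
        core = np.abs(prof.bin_centers - 34.0) < 1.5 * sigma
        assert np.max(np.abs(prof.free_energy[core] - (expect - expect[core].min())[core])) < 0.03

    def test_half_k_bias_convention_recovers_planted_potential(self):
        pot, wins = harmonic_fixture(n=4000, seed=3)
        prof = pw.wham_pmf(wins, bin_width=0.1)
        ref = sd.analytic_pmf(pot, prof.bin_centers)
        core = np.abs(prof.bin_centers - 34.0) < 2.0
        rms = np.sqrt(np.mean((prof.free_energy[core] - ref[core]) ** 2))
        assert rms < 0.1

    def test_error_decreases_with_sample_size(self):
        pot, w_small = harmonic_fixture(n=1000, seed=11)
        _, w_large = harmonic_fixture(n=10_000, seed=11)
        rmss = []
        for wins in (w_small, w_large):
            prof = pw.wham_pmf(wins, bin_width=0.1)
            ref = sd.analytic_pmf(pot, prof.bin_centers)
            core = np.abs(prof.bin_centers - 34.0) < 2.0
            rmss.append(np.sqrt(np.mean((prof.free_energy[core] - ref[core]) ** 2)))
        assert rmss[1] < rmss[0]

    def test_merging_duplicate_windows_equals_pooling(self, rng):
        s1 = rng.normal(34.0, 0.5, 4000)
        s2 = rng.normal(34.0, 0.5, 4000)
        t = np.arange(4000, dtype=float)
        w1 = pw.UmbrellaWindow(34.0, 1.0, t, s1, 0.0)
        w2 = pw.UmbrellaWindow(34.0, 1.0, t, s2, 0.0)
        pooled = pw.UmbrellaWindow(34.0, 1.0, np.arange(8000, dtype=float),
                                   np.concatenate([s1, s2]), 0.0)
        g_split = pw.wham_pmf([w1, w2], bin_width=0.2)
        g_pool = pw.wham_pmf([pooled], bin_width=0.2)
        assert np.allclose(g_split.free_energy, g_pool.free_energy, atol=1e-4)

    def test_flat_potential_recovered_flat(self):
        pot = sd.PotentialSpec("flat")
        specs = pw.plan_umbrella_windows(30, 38, 1.0, k=1.0)
        wins = sd.umbrella_sampler(pot, specs, 5000, seed=9, method="exact")
        prof = pw.bootstrap_pmf_errors(wins, n_trials=50, seed=1, bin_width=0.2)
        core = (prof.bin_centers > 30) & (prof.bin_centers < 38)
        sd_floor = np.maximum(prof.bootstrap_sd[core], 1e-3)
        assert np.all(prof.free_energy[core] <= 3 * sd_floor + 0.1)

    def test_disconnected_support_names_the_gap(self, rng):
        t = np.arange(1000, dtype=float)
        w1 = pw.UmbrellaWindow(10.0, 50.0, t, rng.normal(10, 0.1, 1000), 0.0)
        w2 = pw.UmbrellaWindow(20.0, 50.0, t, rng.normal(20, 0.1, 1000), 0.0)
        with pytest.raises(pw.WhamError, match="no samples between"):
            pw.wham_pmf([w1, w2])


class TestBootstrap:
    def test_constant_samples_have_zero_sd(self):
        t = np.arange(100, dtype=float)
        w = pw.UmbrellaWindow(34.0, 1.0, t, np.full(100, 34.0), 0.0)
        prof = pw.bootstrap_pmf_errors([w], n_trials=10, seed=0)
        assert np.allclose(prof.bootstrap_sd, 0.0)

    def test_seed_determinism(self):
        _, wins = harmonic_fixture(n=800, seed=5)
        a = pw.bootstrap_pmf_errors(wins, n_trials=25, seed=7, bin_width=0.2)
        b = pw.bootstrap_pmf_errors(wins, n_trials=25, seed=7, bin_width=0.2)
        assert np.array_equal(a.bootstrap_sd, b.bootstrap_sd)

    def test_more_samples_shrink_mean_sd(self):
        _, w_small = harmonic_fixture(n=1000, seed=13)
        _, w_large = harmonic_fixture(n=4000, seed=13)
        sd_small = pw.bootstrap_pmf_errors(w_small, n_trials=50, seed=2, bin_width=0.2)
        sd_large = pw.bootstrap_pmf_errors(w_large, n_trials=50, seed=2, bin_width=0.2)
        common = np.intersect1d(np.round(sd_small.bin_centers, 6), np.round(sd_large.bin_centers, 6))
        ia = np.isin(np.round(sd_small.bin_centers, 6), common)
        ib = np.isin(np.round(sd_large.bin_centers, 6), common)
        assert sd_large.bootstrap_sd[ib].mean() < sd_small.bootstrap_sd[ia].mean()

    def test_too_few_trials_rejected(self):
        _, wins = harmonic_fixture(n=100, seed=1)
        with pytest.raises(ValueError):
            pw.bootstrap_pmf_errors(wins, n_trials=1)


class TestOverlap:
    def test_identical_distributions_overlap_fully(self, rng):
        s = rng.normal(34, 0.5, 50_000)
        t = np.arange(s.size, dtype=float)
        w1 = pw.UmbrellaWindow(34.0, 1.0, t, s, 0.0)
        w2 = pw.UmbrellaWindow(34.1, 1.0, t, s.copy(), 0.0)
        assert pw.histogram_overlap([w1, w2])[0] == pytest.approx(1.0)

    def test_disjoint_supports_overlap_zero(self, rng):
        t = np.arange(1000, dtype=float)
        w1 = pw.UmbrellaWindow(10.0, 1.0, t, rng.uniform(9, 10, 1000), 0.0)
        w2 = pw.UmbrellaWindow(20.0, 1.0, t, rng.uniform(19, 20, 1000), 0.0)
        assert pw.histogram_overlap([w1, w2])[0] == 0.0

    def test_gaussians_one_angstrom_apart_match_closed_form(self, rng):
        # overlap of two unit Gaussians sd 0.5 at distance 1: 2*Phi(-1) = 0.3173
        t = np.arange(200_000, dtype=float)
        w1 = pw.UmbrellaWindow(33.0, 1.0, t, rng.normal(33.0, 0.5, t.size), 0.0)
        w2 = pw.UmbrellaWindow(34.0, 1.0, t, rng.normal(34.0, 0.5, t.size), 0.0)
        assert pw.histogram_overlap([w1, w2])[0] == pytest.approx(0.3173, abs=0.02)


class TestConvergenceSplit:
    def test_duplicated_data_differs_exactly_zero(self):
        _, wins = harmonic_fixture(n=1500, seed=21)
        doubled = [
            pw.UmbrellaWindow(w.r0, w.k, np.arange(2 * w.samples.size, dtype=float),
                              np.tile(w.samples, 2), 0.0)
            for w in wins
        ]
        assert pw.convergence_split(doubled, bin_width=0.1) < 1e-6

    def test_planted_drift_exceeds_stationary_case(self):
        _, wins = harmonic_fixture(n=4000, seed=22)
        stationary = pw.convergence_split(wins, bin_width=0.1)
        drifted = [
            pw.UmbrellaWindow(w.r0, w.k, w.times,
                              w.samples + np.linspace(0.6, 0.0, w.samples.size), 0.0)
            for w in wins
        ]
        assert pw.convergence_split(drifted, bin_width=0.1) > stationary


def test_sd_at_references_interpolates_within_support():
    _, wins = harmonic_fixture(n=1500, seed=30)
    prof = pw.bootstrap_pmf_errors(wins, n_trials=25, seed=3, bin_width=0.2)
    vals = pw.sd_at_references(prof, wins)
    assert vals.size > 0
    assert np.all(vals >= 0)


def test_autocorrelation_time_of_iid_near_one(rng):
    tau = pw.integrated_autocorrelation_time(rng.normal(size=5000))
    assert tau == pytest.approx(1.0, abs=0.25)
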