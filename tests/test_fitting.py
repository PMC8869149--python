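import numpy as np
import pytest

from smlsize import (
    BoundaryPeakError,
    DegenerateInputError,
    GaussianKernel,
    LineProfile,
    NoPeakError,
    Shape,
    UnderdeterminedFitError,
    compare_estimators,
    fit_sba,
    initial_guess,
    measure_fwhm,
)
from smlsize.profiles import extract_profile, find_clusters
from smlsize.simulate import EmitterSpec, SimConfig, simulate_localizations

from conftest import make_noiseless_profile

ALL_SHAPES = list(Shape)


def gaussian_profile(sigma=20.0, bin_width=1.0, amplitude=1000.0, half_span=150.0):
    x = np.arange(-half_span, half_span, bin_width) + bin_width / 2
    counts = amplitude * np.exp(-0.5 * (x / sigma) ** 2)
    return LineProfile(bin_centers=x, counts=counts, bin_width=bin_width)


class TestMeasureFWHM:
    def test_pure_gaussian_matches_analytic(self):
        prof = gaussian_profile(sigma=20.0, bin_width=1.0)
        res = measure_fwhm(prof, baseline_mode="zero")
        expected = 2.0 * np.sqrt(2.0 * np.log(2.0)) * 20.0  # 47.10 nm
        assert res.fwhm == pytest.approx(expected, abs=1.0)
        assert res.fwhm == pytest.approx(res.right_cross - res.left_cross)
        peak = prof.counts.max()  # max bin count, not the continuous peak
        assert res.half_level == pytest.approx(res.baseline + (peak - res.baseline) / 2)

    def test_uniform_plateau_width(self):
        bw = 2.0
        x = np.arange(-100, 100, bw) + bw / 2
        counts = np.where(np.abs(x) <= 50.0, 40.0, 0.0)
        res = measure_fwhm(
            LineProfile(bin_centers=x, counts=counts, bin_width=bw),
            baseline_mode="zero",
        )
        assert res.fwhm == pytest.approx(100.0, abs=bw)

    def test_convolved_sphere_derived_value(self):
        # root-finding on the erf closed form gives 100.6226 for R=50, sigma=20
        prof = make_noiseless_profile(
            radius=50.0, sigma=20.0, background=0.0, center=0.0, bin_width=1.0,
            half_span=200.0,
        )
        res = measure_fwhm(prof, baseline_mode="zero")
        assert res.fwhm == pytest.approx(100.6226, abs=1.0)

    def test_no_peak_error(self):
        bw = 1.0
        x = np.arange(-50, 50, bw) + bw / 2
        prof = LineProfile(bin_centers=x, counts=np.full_like(x, 5.0), bin_width=bw)
        with pytest.raises(NoPeakError):
            measure_fwhm(prof, baseline_mode="edge_mean")

    def test_boundary_peak_error(self):
        bw = 1.0
        x = np.arange(0, 50, bw) + bw / 2
        counts = np.linspace(100, 1, x.size)  # peak at left boundary
        prof = LineProfile(bin_centers=x, counts=counts, bin_width=bw)
        with pytest.raises(BoundaryPeakError):
            measure_fwhm(prof, baseline_mode="zero")

    def test_outermost_crossings_for_edge_peaked_profile(self):
        # ring-like double-peaked profile: total width spans both peaks
        prof = make_noiseless_profile(
            shape="disc_ring", radius=50.0, sigma=10.0, background=0.0,
            center=0.0, bin_width=2.0, half_span=150.0,
        )
        res = measure_fwhm(prof, baseline_mode="zero")
        assert res.left_cross < -50.0
        assert res.right_cross > 50.0

    def test_fitted_constant_baseline_mode(self):
        prof = gaussian_profile()
        res = measure_fwhm(prof, baseline_mode="fitted_constant")
        # outer 20% of bins carry faint Gaussian tails, not exactly zero
        assert res.baseline == pytest.approx(0.0, abs=0.05)


class TestInitialGuess:
    def test_center_within_one_bin_of_truth(self, noiseless_profile):
        guess = initial_guess(noiseless_profile, "sphere_surface")
        assert abs(guess.center - 13.0) <= noiseless_profile.bin_width

    def test_uniform_counts_falls_back_without_exception(self):
        bw = 5.0
        x = np.arange(-100, 100, bw) + bw / 2
        prof = LineProfile(bin_centers=x, counts=np.full_like(x, 7.0), bin_width=bw)
        guess = initial_guess(prof, "sphere_surface")
        assert guess.model.radius == pytest.approx(prof.span / 2.0)

    def test_all_zero_profile_is_degenerate(self):
        bw = 5.0
        x = np.arange(-100, 100, bw) + bw / 2
        prof = LineProfile(bin_centers=x, counts=np.zeros_like(x), bin_width=bw)
        with pytest.raises(DegenerateInputError):
            initial_guess(prof, "sphere_surface")

    def test_simulated_sphere_radius_within_factor_two(self):
        # Monte-Carlo: initial radius within a factor 2 of truth (R=50)
        spec = EmitterSpec(geometry="sphere_surface", diameter=100.0, n_fluorophores=667)
        ok = 0
        n_seeds = 30
        for seed in range(n_seeds):
            cfg = SimConfig(sigma_loc=20.0, blinks_per_fluorophore=3.0, seed=seed)
            table = simulate_localizations(spec, cfg)
            clusters = find_clusters(table)
            prof = extract_profile(clusters[0], table, bin_width=10.0)
            r = initial_guess(prof, "sphere_surface").model.radius
            if 25.0 <= r <= 100.0:
                ok += 1
        assert ok >= n_seeds - 1


class TestFitSBA:
    def test_noiseless_recovery_example(self):
        prof = make_noiseless_profile(
            radius=100.0, sigma=20.0, amplitude=5000.0, background=2.0,
            center=13.0, bin_width=5.0,
        )
        res = fit_sba(prof, "sphere_surface")
        assert res.diameter_hat == pytest.approx(200.0, rel=1e-6)
        assert res.sigma_hat == pytest.approx(20.0, rel=1e-6)
        assert res.amplitude_hat == pytest.approx(5000.0, rel=1e-6)
        assert res.background_hat == pytest.approx(2.0, rel=1e-6)
        assert res.center_hat == pytest.approx(13.0, rel=1e-6)
        assert res.converged

    @pytest.mark.parametrize("shape", ALL_SHAPES)
    def test_self_consistency_every_shape(self, shape):
        prof = make_noiseless_profile(shape=shape)
        res = fit_sba(prof, shape)
        assert res.diameter_hat == pytest.approx(200.0, rel=1e-6)
        assert res.sigma_hat == pytest.approx(20.0, rel=1e-6)

    def test_rss_not_worse_than_initial_guess(self, bead_spec, bead_cfg):
        table = simulate_localizations(bead_spec, bead_cfg)
        prof = extract_profile(find_clusters(table)[0], table, bin_width=10.0)
        res = fit_sba(prof, "sphere_surface")
        guess = initial_guess(prof, "sphere_surface")
        rss0 = float(np.sum((prof.counts - guess.predict(prof.bin_centers, prof.bin_width)) ** 2))
        assert res.rss <= rss0 + 1e-9

    def test_fix_sigma(self, noiseless_profile):
        res = fit_sba(noiseless_profile, "sphere_surface", fix_sigma=20.0)
        assert res.sigma_hat == 20.0
        assert res.sigma_fixed
        assert res.diameter_hat == pytest.approx(200.0, rel=1e-6)

    def test_poisson_weights(self, noiseless_profile):
        res = fit_sba(noiseless_profile, "sphere_surface", weights="poisson")
        assert res.diameter_hat == pytest.approx(200.0, rel=1e-4)

    def test_translation_equivariance(self):
        prof = make_noiseless_profile(center=0.0)
        shifted = LineProfile(
            bin_centers=prof.bin_centers + 37.0,
            counts=prof.counts,
            bin_width=prof.bin_width,
        )
        a = fit_sba(prof, "sphere_surface")
        b = fit_sba(shifted, "sphere_surface")
        assert b.center_hat - a.center_hat == pytest.approx(37.0, abs=1e-6)
        assert b.diameter_hat == pytest.approx(a.diameter_hat, abs=1e-6)

    def test_scale_equivariance(self):
        c = 2.5
        prof = make_noiseless_profile(center=0.0)
        scaled = make_noiseless_profile(
            radius=100.0 * c, sigma=20.0 * c, center=0.0,
            bin_width=5.0 * c, half_span=300.0 * c,
        )
        a = fit_sba(prof, "sphere_surface")
        b = fit_sba(scaled, "sphere_surface")
        assert b.diameter_hat == pytest.approx(c * a.diameter_hat, rel=1e-6)

    def test_underdetermined_error(self):
        bw = 10.0
        x = np.arange(0, 40, bw) + bw / 2
        prof = LineProfile(bin_centers=x, counts=np.array([1.0, 5, 5, 1]), bin_width=bw)
        with pytest.raises(UnderdeterminedFitError):
            fit_sba(prof, "sphere_surface")

    def test_stderr_reported(self, bead_spec, bead_cfg):
        table = simulate_localizations(bead_spec, bead_cfg)
        prof = extract_profile(find_clusters(table)[0], table, bin_width=10.0)
        res = fit_sba(prof, "sphere_surface")
        assert "diameter" in res.stderr
        assert res.stderr["diameter"] > 0
        assert res.dof == prof.n_bins - 5

    def test_gaussian_limit_fwhm(self):
        # small structure: fitted model's FWHM approaches 2.3548 sigma
        prof = make_noiseless_profile(
            radius=1.0, sigma=30.0, background=0.0, center=0.0,
            bin_width=2.0, half_span=200.0,
        )
        w = measure_fwhm(prof, baseline_mode="zero")
        assert w.fwhm == pytest.approx(2.3548 * 30.0, abs=prof.bin_width)

    def test_report_serialization(self, noiseless_profile):
        res = fit_sba(noiseless_profile, "sphere_surface")
        d = res.to_dict()
        assert d["shape"] == "sphere_surface"
        table = res.to_table()
        assert list(table.columns) == ["name", "estimate", "stderr"]
        assert "diameter" in set(table["name"])
        assert isinstance(res.to_json(), str)


class TestParameterRecovery:
    def test_monte_carlo_bead_recovery(self):
        # 100 replicates, d=100 nm, sigma 20, ~1000 localizations
        spec = EmitterSpec(geometry="sphere_surface", diameter=100.0, n_fluorophores=334)
        diam, fwhm = [], []
        for seed in range(100):
            cfg = SimConfig(sigma_loc=20.0, blinks_per_fluorophore=3.0, seed=seed)
            table = simulate_localizations(spec, cfg)
            prof = extract_profile(find_clusters(table)[0], table, bin_width=10.0)
            diam.append(fit_sba(prof, "sphere_surface", fix_sigma=20.0).diameter_hat)
            fwhm.append(measure_fwhm(prof).fwhm)
        diam = np.asarray(diam)
        fwhm = np.asarray(fwhm)
        assert abs(diam.mean() - 100.0) / 100.0 < 0.05
        assert diam.std(ddof=1) < fwhm.std(ddof=1)


class TestCompareEstimators:
    def test_identical_noiseless_profiles_have_zero_sd(self, noiseless_profile):
        out = compare_estimators([noiseless_profile, noiseless_profile], "sphere_surface")
        assert out["summary"].loc["sba", "sd"] == pytest.approx(0.0, abs=1e-6)
        assert out["summary"].loc["fwhm", "sd"] == pytest.approx(0.0, abs=1e-9)

    def test_true_size_adds_bias_and_rmse(self, noiseless_profile):
        out = compare_estimators(
            [noiseless_profile, noiseless_profile], "sphere_surface", true_size=200.0
        )
        assert "bias" in out["summary"].columns
        assert out["summary"].loc["sba", "bias"] == pytest.approx(0.0, abs=1e-4)

    def test_no_true_size_omits_bias(self, noiseless_profile):
        out = compare_estimators([noiseless_profile, noiseless_profile], "sphere_surface")
        assert "bias" not in out["summary"].columns
        assert "mean" in out["summary"].columns

    def test_per_row_failure_not_fatal(self, noiseless_profile):
        bw = 5.0
        x = np.arange(-100, 100, bw) + bw / 2
        flat = LineProfile(bin_centers=x, counts=np.full_like(x, 4.0), bin_width=bw)
        out = compare_estimators([noiseless_profile, flat], "sphere_surface")
        assert out["table"]["error"].iloc[1] != ""
        assert np.isfinite(out["summary"].loc["sba", "mean"])

    def test_requires_two_profiles(self, noiseless_profile):
        with pytest.raises(DegenerateInputError):
            compare_estimators([noiseless_profile], "sphere_surface")
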