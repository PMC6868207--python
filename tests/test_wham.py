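"""WHAM solver: exactness on constructed histograms, recovery on BD data."""

import numpy as np
import pytest
from scipy.integrate import quad

import curvperm as cp
from curvperm.errors import ConvergenceError, ValidationError
from curvperm.wham import moving_block_resample


def _expected_count_histograms(model, centers, k, edges, n_per_window=10**7):
    """Deterministic oracle: histograms with *expected* counts.

    Bin probabilities are exact quadratures of the biased Boltzmann density
    exp(-(G + k/2 (z-z_i)^2)/k_B T); WHAM fed these must recover the model
    PMF up to binning resolution, independent of any sampling.
    """
    hists = []
    for c in centers:
        def dens(z):
            return np.exp(-(model.pmf(np.array([z]))[0]
                            + 0.5 * k * (z - c) ** 2) / model.kbt)
        probs = np.array([quad(dens, a, b, limit=200)[0]
                          for a, b in zip(edges[:-1], edges[1:])])
        probs /= probs.sum()
        counts = np.round(probs * n_per_window).astype(int)
        hists.append(cp.BiasedHistogram(edges=edges, counts=counts, center=c,
                                        force_constant=k,
                                        temperature=model.temperature))
    return hists


class TestBuildHistograms:
    def test_single_window_single_bin(self):
        w = cp.UmbrellaWindow(0.0, 10.0, 1e-3, np.full(50, 0.101))
        (h,) = cp.build_histograms([w], bin_width=0.05)
        assert h.n_total == 50
        assert (h.counts > 0).sum() == 1

    def test_window_order_invariance(self, small_flat_windows):
        _, ws = small_flat_windows
        a = cp.build_histograms(ws, bin_width=0.1)
        b = cp.build_histograms(ws[::-1], bin_width=0.1)
        by_center = lambda hs: {h.center: h.counts.tolist() for h in hs}
        assert by_center(a) == by_center(b)

    def test_uniform_samples_spread_multinomially(self):
        rng = np.random.default_rng(0)
        w = cp.UmbrellaWindow(0.5, 5.0, 1e-3, rng.uniform(0, 1, 20_000))
        (h,) = cp.build_histograms([w], bin_width=0.1)
        inner = h.counts[(h.centers > 0.05) & (h.centers < 0.95)]
        assert np.all(np.abs(inner - 2_000) < 5 * np.sqrt(2_000))

    def test_empty_window_rejected_by_name(self):
        w = cp.UmbrellaWindow(0.0, 10.0, 1e-3, [0.0, 0.1])
        w.samples = np.empty(0)
        with pytest.raises(ValidationError, match="window 0"):
            cp.build_histograms([w])


class TestWhamSolve:
    def test_unbiased_window_reduces_to_boltzmann_inversion(self):
        rng = np.random.default_rng(1)
        samples = rng.normal(0.0, 0.4, 200_000)
        w = cp.UmbrellaWindow(0.0, 0.0, 1e-3, samples, temperature=320.0)
        hists = cp.build_histograms([w], bin_width=0.1)
        pmf = cp.wham_solve(hists, bulk_fraction=0.8)
        kt = cp.kbt(320.0)
        direct = -kt * np.log(hists[0].counts.astype(float))
        ok = np.isfinite(pmf.values)
        err = pmf.values[ok] - direct[ok]
        # identical up to the (reference-dependent) additive constant
        assert np.ptp(err) < 1e-6

    def test_recovers_pmf_from_exact_expected_count_histograms(self):
        """Direct-quadrature oracle: WHAM on analytic biased densities."""
        model = cp.MembraneModel(barrier_height=12.0, well_depth=-2.0,
                                 box_half_width=3.0, half_width=1.5,
                                 peak_width=0.8, d_bulk=1.0, d_mem=1.0)
        edges = np.arange(-3.0, 3.0 + 1e-9, 0.05)
        centers = np.linspace(-2.7, 2.7, 19)
        hists = _expected_count_histograms(model, centers, 60.0, edges)
        pmf = cp.wham_solve(hists, tol=1e-8)
        truth = model.pmf(pmf.z)
        ok = np.isfinite(pmf.values)
        err = pmf.values[ok] - truth[ok]
        err -= err.mean()
        # binning bias only: well below 2% of the barrier height
        assert np.max(np.abs(err)) < 0.2

    def test_harmonic_landscape_curvature_recovered(self, harmonic_model,
                                                    harmonic_windows):
        pmf = cp.bootstrap_pmf(harmonic_windows, n_boot=16, seed=3, bin_width=0.1)
        ok = np.isfinite(pmf.values) & (np.abs(pmf.z) < 1.4)
        coeff = np.polyfit(pmf.z[ok], pmf.values[ok], 2)
        kappa_hat = 2 * coeff[0]
        # bootstrap error of the fitted curvature via replicates of the band
        assert kappa_hat == pytest.approx(harmonic_model.quadratic_kappa, rel=0.10)

    def test_flat_landscape_gives_flat_pmf(self, flat_free_model):
        ws = cp.generate_umbrella_dataset(
            flat_free_model, np.linspace(-1.0, 1.0, 9), force_constant=60.0,
            n_steps=150_000, n_equil=3_000, dt=1e-4, seed=11)
        pmf = cp.wham_solve(cp.build_histograms(ws, bin_width=0.1))
        # judge flatness over the well-sampled interior; per-window free
        # energies random-walk by ~kT/sqrt(n_eff) per window
        ok = np.isfinite(pmf.values) & (np.abs(pmf.z) <= 1.0)
        assert np.ptp(pmf.values[ok]) < 1.5

    def test_window_permutation_leaves_pmf_invariant(self, small_flat_windows):
        _, ws = small_flat_windows
        a = cp.wham_solve(cp.build_histograms(ws, bin_width=0.1), tol=1e-8)
        b = cp.wham_solve(cp.build_histograms(ws[::-1], bin_width=0.1), tol=1e-8)
        ok = np.isfinite(a.values)
        assert np.allclose(a.values[ok], b.values[ok], atol=1e-6)

    def test_disconnected_windows_error_lists_components(self):
        rng = np.random.default_rng(2)
        w1 = cp.UmbrellaWindow(-2.0, 100.0, 1e-3, rng.normal(-2.0, 0.05, 1000))
        w2 = cp.UmbrellaWindow(2.0, 100.0, 1e-3, rng.normal(2.0, 0.05, 1000))
        with pytest.raises(ValidationError, match="connected"):
            cp.wham_solve(cp.build_histograms([w1, w2], bin_width=0.05))

    def test_nonconvergence_reports_residual(self, small_flat_windows):
        _, ws = small_flat_windows
        with pytest.raises(ConvergenceError) as exc:
            cp.wham_solve(cp.build_histograms(ws, bin_width=0.1), max_iter=2)
        assert exc.value.residual is not None and exc.value.residual > 0

    def test_self_consistency_resimulating_recovered_pmf(self, small_flat_windows):
        """BD on the WHAM output reproduces that PMF within its own bands."""
        model, ws = small_flat_windows
        pmf1 = cp.bootstrap_pmf(ws, n_boot=12, seed=5, bin_width=0.1)
        lo, hi = pmf1.largest_gap_free_run()
        tab = cp.TabulatedModel(
            z_table=pmf1.z[lo:hi], g_table=pmf1.values[lo:hi],
            box_half_width=model.box_half_width, half_width=model.half_width,
            d_bulk=model.d_bulk, d_mem=model.d_mem,
            temperature=model.temperature)
        ws2 = cp.generate_umbrella_dataset(
            tab, np.linspace(-2.6, 2.6, 15), force_constant=80.0,
            n_steps=120_000, n_equil=5_000, dt=2e-4, seed=99)
        pmf2 = cp.bootstrap_pmf(ws2, n_boot=12, seed=6, bin_width=0.1)
        grid = pmf1.z[lo:hi]
        v2 = np.interp(grid, pmf2.z[np.isfinite(pmf2.values)],
                       pmf2.values[np.isfinite(pmf2.values)])
        band = np.hypot(np.nan_to_num(pmf1.sigma[lo:hi], nan=0.3),
                        0.3)  # combined bands, floor at grid noise
        cover = np.mean(np.abs(v2 - pmf1.values[lo:hi]) <= 3 * band)
        assert cover >= 0.9


class TestBootstrap:
    def test_degenerate_full_block_gives_zero_sigma(self):
        rng = np.random.default_rng(3)
        ws = [cp.UmbrellaWindow(c, 60.0, 1e-3, rng.normal(c, 0.25, 4000))
              for c in (-0.3, 0.0, 0.3)]
        n = ws[0].n_samples
        pmf = cp.bootstrap_pmf(ws, n_boot=4, block_length=n - 1, seed=0,
                               bin_width=0.1)
        # block ~ full window: replicates nearly identical resamples
        assert np.nanmax(pmf.sigma) < 0.35

    def test_full_window_block_resample_is_identity(self):
        x = np.arange(100.0)
        rng = np.random.default_rng(0)
        out = moving_block_resample(x, 99, rng)
        assert out.size == 100

    def test_sigma_shrinks_with_window_length(self, harmonic_model):
        def sig(n_steps, seed):
            ws = cp.generate_umbrella_dataset(
                harmonic_model, np.linspace(-1.0, 1.0, 7), force_constant=60.0,
                n_steps=n_steps, n_equil=2_000, dt=2e-4, seed=seed)
            pmf = cp.bootstrap_pmf(ws, n_boot=12, seed=1, bin_width=0.1)
            return np.nanmedian(pmf.sigma)

        assert sig(80_000, 21) < sig(10_000, 21)

    def test_block_length_at_least_window_length_rejected(self):
        rng = np.random.default_rng(4)
        ws = [cp.UmbrellaWindow(0.0, 60.0, 1e-3, rng.normal(0, 0.2, 500))]
        with pytest.raises(ValidationError, match="block"):
            cp.bootstrap_pmf(ws, n_boot=2, block_length=500, seed=0)

    def test_one_sigma_bands_cover_truth_at_nominal_rate(self):
        # landscape chosen flat over the bulk reference region so the
        # estimator's zero convention and the ground truth's coincide
        m = cp.MembraneModel(barrier_height=10.0, well_depth=-2.0,
                             well_position=1.3, well_width=0.3,
                             d_bulk=1.0, d_mem=0.3, box_half_width=3.0,
                             half_width=1.5, peak_width=0.8)
        covers = []
        for seed in (31, 32, 33):
            ws = cp.generate_umbrella_dataset(
                m, np.linspace(-2.6, 2.6, 15), force_constant=80.0,
                n_steps=150_000, n_equil=5_000, dt=2e-4, seed=seed)
            pmf = cp.bootstrap_pmf(ws, n_boot=24, seed=seed, bin_width=0.1)
            ok = np.isfinite(pmf.values) & np.isfinite(pmf.sigma) & (pmf.sigma > 0)
            truth = m.pmf(pmf.z)
            covers.append(np.mean(
                np.abs(pmf.values[ok] - truth[ok]) <= pmf.sigma[ok]))
        # nominal 68%; moving-block bands run slightly narrow on short windows
        assert np.mean(covers) >= 0.5


class TestBarrierAnalytics:
    def test_zero_profile_zero_barrier(self):
        pmf = cp.PMFProfile(np.linspace(-1, 1, 21), np.zeros(21),
                            meta={"bulk_fraction": 0.9})
        assert cp.barrier_height(pmf) == 0.0

    def test_gaussian_barrier_amplitude_recovered(self):
        z = np.linspace(-4, 4, 801)
        m = cp.MembraneModel(barrier_height=55.0, well_depth=-1.0)
        pmf = cp.PMFProfile(z, m.pmf(z), meta={"bulk_fraction": 0.9})
        assert cp.barrier_height(pmf) == pytest.approx(55.0, abs=0.1)

    def test_all_gap_profile_rejected(self):
        pmf = cp.PMFProfile(np.linspace(-1, 1, 5), np.full(5, np.nan),
                            meta={"bulk_fraction": 0.9})
        with pytest.raises(ValidationError):
            cp.barrier_height(pmf)

    def test_symmetric_profile_peak_at_zero(self):
        z = np.linspace(-4, 4, 161)
        m = cp.MembraneModel(barrier_height=40.0)
        pmf = cp.PMFProfile(z, m.pmf(z), meta={"bulk_fraction": 0.9})
        assert abs(cp.peak_position(pmf)) <= (z[1] - z[0]) / 2

    def test_known_peak_shift_recovered(self):
        z = np.linspace(-4, 4, 161)
        flat = cp.preset("drug", 0.0)
        bent = cp.preset("drug", 0.2)
        p_flat = cp.peak_position(cp.PMFProfile(z, flat.pmf(z), meta={"bulk_fraction": 0.9}))
        p_bent = cp.peak_position(cp.PMFProfile(z, bent.pmf(z), meta={"bulk_fraction": 0.9}))
        assert p_bent - p_flat == pytest.approx(-0.15, abs=z[1] - z[0])

    def test_pure_noise_profile_flagged_ambiguous(self):
        rng = np.random.default_rng(8)
        pmf = cp.PMFProfile(np.linspace(-1, 1, 101), rng.normal(0, 1, 101),
                            meta={"bulk_fraction": 0.9})
        with pytest.warns(UserWarning, match="ambiguous"):
            cp.peak_position(pmf)


class TestCompareBarriers:
    @pytest.mark.parametrize("flat,curved,expected", [
        (101.1, 98.3, 0.97),
        (70.1, 63.1, 0.90),
        (101.6, 96.4, 0.95),
        (31.4, 30.2, 0.96),
        (77.5, 67.6, 0.87),
    ])
    def test_reference_relative_heights(self, flat, curved, expected):
        assert cp.compare_barriers(flat, curved).rounded == pytest.approx(expected)

    def test_identity_ratio_is_one(self):
        r = cp.compare_barriers(43.21, 43.21)
        assert r.value == 1.0 and r.rounded == 1.0

    def test_nonpositive_flat_barrier_rejected(self):
        with pytest.raises(ValidationError):
            cp.compare_barriers(0.0, 10.0)

    def test_unrounded_value_retained(self):
        r = cp.compare_barriers(101.1, 98.3)
        assert r.value == pytest.approx(98.3 / 101.1, rel=1e-12)
        assert str(r) == "0.97"
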