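"""Resistance profiles, ISD integration, error propagation and tables."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import curvperm as cp
from curvperm.errors import GapError, ValidationError


def _flat_resistance(d=0.5, l=4.0, n=81, temperature=320.0):
    z = np.linspace(-l / 2, l / 2, n)
    pmf = cp.PMFProfile(z, np.zeros(n), meta={"temperature_K": temperature,
                                              "bulk_fraction": 0.9})
    dprof = cp.Profile(z, np.full(n, d))
    return cp.resistance(pmf, dprof)


class TestResistance:
    def test_zero_pmf_constant_d_gives_one_over_d(self):
        r = _flat_resistance(d=0.5)
        assert np.allclose(r.values, 2.0)
        assert np.all(np.diff(r.cumulative) >= 0)

    @given(st.floats(min_value=-5.0, max_value=5.0))
    def test_constant_pmf_offset_scales_r_exactly(self, c):
        z = np.linspace(-1, 1, 21)
        dprof = cp.Profile(z, np.full(21, 0.7))
        base = cp.resistance(cp.PMFProfile(z, np.zeros(21),
                                           meta={"temperature_K": 320.0,
                                                 "bulk_fraction": 0.9}), dprof)
        shifted = cp.resistance(cp.PMFProfile(z, np.full(21, c),
                                              meta={"temperature_K": 320.0,
                                                    "bulk_fraction": 0.9}), dprof)
        assert np.allclose(shifted.values, base.values * np.exp(c / cp.kbt(320.0)),
                           rtol=1e-12)

    def test_gap_bins_propagate_with_warning(self):
        z = np.linspace(-1, 1, 21)
        vals = np.zeros(21)
        vals[10] = np.nan
        pmf = cp.PMFProfile(z, vals, meta={"temperature_K": 320.0,
                                           "bulk_fraction": 0.9})
        with pytest.warns(UserWarning, match="gap"):
            r = cp.resistance(pmf, cp.Profile(z, np.ones(21)))
        assert np.isnan(r.values[10])

    def test_disjoint_grids_rejected(self):
        pmf = cp.PMFProfile(np.linspace(-1, 0, 11), np.zeros(11),
                            meta={"temperature_K": 320.0, "bulk_fraction": 0.9})
        dprof = cp.Profile(np.linspace(2, 3, 11), np.ones(11))
        with pytest.raises(ValidationError):
            cp.resistance(pmf, dprof)

    def test_barrier_dominated_profile_concentrates_resistance_centrally(self):
        m = cp.preset("ion", 0.0)
        z = np.linspace(-4, 4, 801)
        pmf = cp.PMFProfile(z, m.pmf(z), meta={"temperature_K": 320.0,
                                               "bulk_fraction": 0.9})
        r = cp.resistance(pmf, cp.model_diffusivity(m, z))
        total = np.trapezoid(r.values, z)
        inner = (z >= -1.0) & (z <= 1.0)
        inner_part = np.trapezoid(r.values[inner], z[inner])
        assert inner_part / total > 0.99


class TestPermeability:
    def test_constant_resistance_closed_form(self):
        r = _flat_resistance(d=0.5, l=4.0)
        res = cp.permeability(r)
        assert res.p == pytest.approx(0.5 / 4.0, rel=1e-12)
        assert res.units == "m/s"

    def test_matches_analytic_oracle_on_exact_profiles(self):
        m = cp.preset("drug", -0.2)
        z = np.linspace(-4, 4, 1601)
        pmf = cp.PMFProfile(z, m.pmf(z), meta={"temperature_K": m.temperature,
                                               "bulk_fraction": 0.9})
        r = cp.resistance(pmf, cp.model_diffusivity(m, z))
        p = cp.permeability(r).p
        assert p == pytest.approx(cp.analytic_permeability(m), rel=1e-3)

    def test_halving_window_on_barrier_dominated_profile_changes_p_little(self):
        m = cp.preset("ion", 0.0)
        z = np.linspace(-4, 4, 1601)
        pmf = cp.PMFProfile(z, m.pmf(z), meta={"temperature_K": m.temperature,
                                               "bulk_fraction": 0.9})
        r = cp.resistance(pmf, cp.model_diffusivity(m, z))
        p_full = cp.permeability(r, -4.0, 4.0).p
        p_half = cp.permeability(r, -2.0, 2.0).p
        assert abs(p_half - p_full) / p_full < 0.05

    def test_gap_inside_limits_rejected_listing_bins(self):
        z = np.linspace(-1, 1, 21)
        vals = np.ones(21)
        vals[8] = np.nan
        r = cp.ResistanceProfile(z, vals, np.zeros(21),
                                 meta={"temperature_K": 320.0})
        with pytest.raises(GapError, match="gap"):
            cp.permeability(r, -1.0, 1.0)
        # default limits skip to the largest gap-free run
        res = cp.permeability(r)
        assert res.z1 >= z[9] - 1e-9

    def test_lowering_barrier_raises_p_exponentially(self):
        m = cp.preset("ion", 0.0)
        z = np.linspace(-4, 4, 1601)
        d = cp.model_diffusivity(m, z)
        kt = m.kbt
        dg = 5.0
        pmf_hi = cp.PMFProfile(z, m.pmf(z), meta={"temperature_K": m.temperature,
                                                  "bulk_fraction": 0.9})
        lower = m.with_(barrier_height=m.barrier_height - dg)
        pmf_lo = cp.PMFProfile(z, lower.pmf(z), meta={"temperature_K": m.temperature,
                                                      "bulk_fraction": 0.9})
        p_hi = cp.permeability(cp.resistance(pmf_hi, d)).p
        p_lo = cp.permeability(cp.resistance(pmf_lo, d)).p
        assert p_lo / p_hi == pytest.approx(np.exp(dg / kt), rel=0.1)


def test_attribution_choice_moves_p_by_less_than_5_percent():
    """Attributing D to the window sample mean vs the bias centre barely
    changes P at the default window spacing."""
    import warnings
    model = cp.preset("water", 0.0)
    windows = cp.generate_umbrella_dataset(
        model, cp.default_window_centers(model), n_steps=300_000, seed=55)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p_mean = cp.run_pipeline(windows, attribute="mean").permeability.p
        p_center = cp.run_pipeline(windows, attribute="center").permeability.p
    assert abs(p_mean - p_center) / p_mean < 0.05


class TestPropagateErrors:
    def test_degenerate_full_block_bootstrap_gives_zero_sigma(self, small_flat_windows):
        _, ws = small_flat_windows
        short = [cp.UmbrellaWindow(w.center, w.force_constant, w.dt,
                                   w.samples[:20_000], w.temperature) for w in ws]
        res = cp.propagate_errors(short, n_boot=4, seed=0,
                                  block_length=19_999, bin_width=0.1)
        assert res.sigma_p == pytest.approx(0.0, abs=0.05 * res.p)

    def test_sigma_positive_and_relative_error_shrinks_with_sampling(self, small_flat_windows):
        _, ws = small_flat_windows
        def rel_sigma(n):
            cut = [cp.UmbrellaWindow(w.center, w.force_constant, w.dt,
                                     w.samples[:n], w.temperature) for w in ws]
            r = cp.propagate_errors(cut, n_boot=12, seed=1, bin_width=0.1)
            return r.sigma_p / r.p, r
        rel_small, _ = rel_sigma(12_000)
        rel_big, res = rel_sigma(120_000)
        assert res.sigma_p > 0
        assert rel_big < rel_small

    def test_deterministic_given_seed(self, small_flat_windows):
        _, ws = small_flat_windows
        a = cp.propagate_errors(ws, n_boot=6, seed=9, bin_width=0.1)
        b = cp.propagate_errors(ws, n_boot=6, seed=9, bin_width=0.1)
        assert a.p == b.p and a.sigma_p == b.sigma_p


class TestRatiosAndTables:
    @pytest.mark.parametrize("flat,curved,expected", [
        (2.5e-6, 3.7e-6, 1.5),
        (2.3e-12, 7.0e-12, 3.0),
    ])
    def test_reference_permeability_ratios(self, flat, curved, expected):
        assert cp.permeability_ratio(flat, curved).rounded == pytest.approx(expected)

    def test_identity_ratio(self):
        assert cp.permeability_ratio(1.2e-7, 1.2e-7).value == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            cp.permeability_ratio(0.0, 1e-6)

    def test_single_flat_entry_table_has_unit_ratio(self):
        t = cp.curvature_table([{"ligand": "water", "curvature": 0.0,
                                 "value": 2.5e-6}])
        assert t.data.relative.tolist() == [1.0]

    def test_duplicate_keys_and_missing_flat_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            cp.curvature_table([
                {"ligand": "w", "curvature": 0.0, "value": 1.0},
                {"ligand": "w", "curvature": 0.0, "value": 2.0}])
        with pytest.raises(ValidationError, match="flat"):
            cp.curvature_table([{"ligand": "w", "curvature": 0.2, "value": 1.0}])

    def test_layout_independent_of_insertion_order(self):
        recs = [
            {"ligand": "b", "curvature": 0.2, "value": 2.0},
            {"ligand": "a", "curvature": 0.0, "value": 1.0},
            {"ligand": "b", "curvature": 0.0, "value": 1.0},
            {"ligand": "a", "curvature": 0.2, "value": 3.0},
        ]
        t1 = cp.curvature_table(recs)
        t2 = cp.curvature_table(recs[::-1])
        assert t1.to_wide().equals(t2.to_wide())
        assert list(t1.to_wide().columns) == ["a", "b"]

    def test_barrier_table_rounds_to_two_decimals(self):
        t = cp.curvature_table([
            {"ligand": "CPT", "curvature": 0.0, "value": 70.1},
            {"ligand": "CPT", "curvature": 0.2, "value": 63.1},
        ], quantity="barrier")
        row = t.data[t.data.curvature == 0.2].iloc[0]
        assert row.rel_rounded == pytest.approx(0.90)
        assert "(0.90)" in t.render()
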