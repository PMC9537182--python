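"""Competitive-import ODE model: occupancy, trajectories, half-times, profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from nucimport import InvalidInput
from nucimport.model import (
    DropletVolumeCurve,
    ImportModelConfig,
    default_embryo_config,
    droplet_flux_variant,
    entry_half_time,
    euler_oracle,
    importin_occupancy,
    nuclear_concentration_profiles,
    sample_kd,
    simulate_import,
    SimulationResult,
)
from nucimport.volume import MonotoneTimeMap


class TestSampleKd:
    def test_zero_sigma_is_point_mass(self):
        kd = sample_kd(50, mu_ln=-18.0, sigma_ln=0.0, seed=0)
        np.testing.assert_allclose(kd, np.exp(-18.0))

    def test_sample_median_matches_lognormal_median(self):
        kd = sample_kd(100_000, mu_ln=-18.0, sigma_ln=2.0, seed=1)
        assert np.median(kd) == pytest.approx(np.exp(-18.0), rel=0.03)

    def test_seed_determinism(self):
        np.testing.assert_array_equal(sample_kd(100, seed=7), sample_kd(100, seed=7))


class TestImportinOccupancy:
    def test_single_substrate_at_kd_is_half(self):
        assert importin_occupancy([1e-8], [1e-8])[0] == pytest.approx(0.5)

    def test_two_identical_substrates_share_a_third(self):
        theta = importin_occupancy([1e-8, 1e-8], [1e-8, 1e-8])
        np.testing.assert_allclose(theta, [1 / 3, 1 / 3])

    def test_inert_species_is_zero(self):
        theta = importin_occupancy([1e-3, 1e-8], [np.inf, 1e-8])
        assert theta[0] == 0.0

    @settings(deadline=None, max_examples=50)
    @given(
        conc=hnp.arrays(np.float64, 5, elements=st.floats(0, 1e-2)),
        kd=hnp.arrays(np.float64, 5, elements=st.floats(1e-12, 1e-3)),
    )
    def test_occupancy_invariants(self, conc, kd):
        theta = importin_occupancy(conc, kd)
        assert np.all(theta >= 0) and np.all(theta <= 1)
        assert theta.sum() <= 1 + 1e-12

    def test_saturation_when_substrate_dominates_kd(self):
        theta = importin_occupancy([1e-3], [1e-9])
        assert theta.sum() == pytest.approx(1.0, abs=1e-5)


def _linear_flux_map(rate_l_per_h=1e-9, t_end=50.0):
    t = np.linspace(0.0, t_end, 11)
    return MonotoneTimeMap(t, 1e-4 * (1 + t), rate_l_per_h * (1 + t))


class TestSimulateImport:
    def test_zero_flux_keeps_initial_state(self):
        t = np.linspace(0.0, 10.0, 6)
        vm = MonotoneTimeMap(t, 0.01 * (1 + t), np.full_like(t, 1e-9))
        cfg = ImportModelConfig([1e-8, 1e-7], [1e-6, 1e-6], vm)
        res = simulate_import(cfg)
        assert np.all(res.nuclear_amounts_mol == 0.0)

    def test_saturated_single_substrate_matches_linear_intake(self):
        # K_D so small that theta ~ 1: P_nuc(t) = F * t until depletion
        vm = _linear_flux_map(rate_l_per_h=1e-9, t_end=20.0)
        cfg = ImportModelConfig([1e-18], [1e-4], vm, embryo_volume_l=1e-6)
        res = simulate_import(cfg, output_grid=np.linspace(0, 20, 50))
        flux_rate = 1e-9 * 1e-4  # dV/dt * total concentration, mol/h
        expected = np.minimum(flux_rate * res.times, 1e-4 * 1e-6)
        np.testing.assert_allclose(res.nuclear_amounts_mol[:, 0], expected, rtol=1e-3)

    def test_high_affinity_substrate_enters_first(self):
        # the pair of representative substrates: 10 nM vs 1 uM at equal abundance
        cfg = default_embryo_config(n_nuclear=2, seed=0)
        cfg.kd_m[:2] = [10e-9, 1e-6]
        cfg.total_concentrations_m[:2] = 1e-4
        res = simulate_import(cfg)
        t_half = entry_half_time(res)
        # a never-crossing substrate counts as entering later than any crosser
        assert np.isfinite(t_half[0])
        assert t_half[0] < np.nan_to_num(t_half[1], nan=np.inf)
        frac = res.nuclear_fraction[-1]
        assert frac[0] > frac[1]

    def test_adaptive_solver_matches_euler_oracle(self, volmap):
        cfg = ImportModelConfig(
            kd_m=[1e-9, 1e-8, 3e-8, 1e-6, np.inf],
            total_concentrations_m=[5e-5, 5e-5, 5e-5, 5e-5, 1.8e-3],
            flux_source=volmap,
        )
        grid = np.linspace(*volmap.support, 25)
        res = simulate_import(cfg, output_grid=grid)
        ref = euler_oracle(cfg, volmap.support, grid, dt=1e-3)
        scale = cfg.total_concentrations_m * cfg.embryo_volume_l
        err = np.abs(res.nuclear_amounts_mol - ref.nuclear_amounts_mol) / scale
        assert err.max() < 0.005

    def test_mass_conservation_and_monotone_fractions(self, volmap):
        cfg = default_embryo_config(n_nuclear=20, seed=3, volmap=volmap)
        res = simulate_import(cfg)
        tot = res.total_amounts_mol
        for idx in (0, len(res.times) // 2, -1):
            st_ = res.state_at(idx)
            np.testing.assert_allclose(
                st_.nuclear_amounts_mol + st_.cytoplasmic_amounts_mol, tot, rtol=1e-9
            )
        frac = res.nuclear_fraction
        assert np.all(np.diff(frac, axis=0) >= -1e-9)
        assert np.nanmin(frac) >= 0 and np.nanmax(frac) <= 1 + 1e-12

    def test_importin_conserved_by_construction(self, volmap):
        cfg = default_embryo_config(n_nuclear=10, seed=4, volmap=volmap)
        res = simulate_import(cfg)
        st_ = res.state_at(-1)
        total = st_.free_importin_m + st_.bound_importin_m.sum()
        assert total == pytest.approx(cfg.importin_total_m, rel=1e-12)

    def test_t_span_outside_flux_support_rejected(self, volmap):
        cfg = default_embryo_config(n_nuclear=2, seed=0, volmap=volmap)
        with pytest.raises(InvalidInput):
            simulate_import(cfg, t_span=(-10.0, 5.0))


class TestEntryHalfTime:
    def _result(self, times, fracs, volmap):
        cfg = ImportModelConfig([1e-8], [1e-6], volmap, embryo_volume_l=1.0)
        amounts = np.asarray(fracs)[:, None] * 1e-6
        return SimulationResult(cfg, np.asarray(times), amounts)

    def test_linear_interpolation_between_grid_points(self, volmap):
        res = self._result([10.0, 12.0], [0.4, 0.6], volmap)
        assert entry_half_time(res)[0] == pytest.approx(11.0)

    def test_never_crossing_is_undefined(self, volmap):
        res = self._result([10.0, 12.0, 14.0], [0.1, 0.2, 0.3], volmap)
        assert np.isnan(entry_half_time(res)[0])

    def test_entry_order_tracks_affinity_order(self, volmap):
        cfg = default_embryo_config(n_nuclear=60, seed=5, volmap=volmap)
        res = simulate_import(cfg)
        t_half = entry_half_time(res)[:-1]
        kd = cfg.kd_m[:-1]
        ok = np.isfinite(t_half)
        from scipy.stats import spearmanr

        assert spearmanr(kd[ok], t_half[ok]).statistic > 0.95


class TestNuclearConcentrationProfiles:
    def test_constant_amount_dilutes_in_growing_volume(self, volmap):
        t = np.linspace(5.0, 40.0, 20)
        cfg = ImportModelConfig([1e-8], [1e-6], volmap)
        res = SimulationResult(cfg, t, np.full((20, 1), 1e-15))
        conc, _ = nuclear_concentration_profiles(res)
        assert np.all(np.diff(conc[:, 0]) < 0)

    def test_zero_import_substrate_has_zero_concentration(self, volmap):
        t = np.linspace(5.0, 40.0, 10)
        cfg = ImportModelConfig([np.inf], [1e-6], volmap)
        res = SimulationResult(cfg, t, np.zeros((10, 1)))
        conc, _ = nuclear_concentration_profiles(res)
        assert np.all(conc == 0)

    @staticmethod
    def _three_kd_config(flux_source, **kwargs):
        kd = np.array([1e-9, 30e-9, 1e-6, np.inf])
        conc = np.array([44e-9, 44e-9, 44e-9, 1.8e-3])
        return ImportModelConfig(kd, conc, flux_source, **kwargs)

    def test_peak_times_ordered_by_affinity_embryo(self, volmap):
        cfg = self._three_kd_config(volmap)
        res = simulate_import(cfg, output_grid=np.linspace(5.0, volmap.support[1], 300))
        _, peaks = nuclear_concentration_profiles(res)
        assert peaks[0] < peaks[1] < peaks[2]

    def test_peak_times_ordered_by_affinity_droplet(self):
        # logistic droplet nuclear volume over a 2 h window (minutes axis);
        # droplet-scale container volume (~50 um diameter, 6.5e-11 L)
        t = np.linspace(0.0, 120.0, 61)
        v = 4.2e-12 / (1 + np.exp(-0.1 * (t - 40.0)))
        curve = DropletVolumeCurve(t, v)
        cfg = self._three_kd_config(curve, embryo_volume_l=6.5e-11)
        cfg.total_concentrations_m[:3] = 2e-5  # substrates deplete within the window
        res = simulate_import(cfg, output_grid=np.linspace(1.0, 120.0, 240))
        _, peaks = nuclear_concentration_profiles(res)
        assert peaks[0] < peaks[1] < peaks[2]


class TestDropletFlux:
    def test_logistic_volume_flux_peaks_at_inflection(self):
        t = np.linspace(0.0, 120.0, 121)
        v = 4.2e-12 / (1 + np.exp(-0.1 * (t - 40.0)))
        curve = DropletVolumeCurve(t, v)
        flux = droplet_flux_variant(curve, 2e-3)
        tt = np.linspace(5, 115, 500)
        assert tt[np.argmax(flux(tt))] == pytest.approx(40.0, abs=2.0)

    def test_constant_volume_gives_zero_flux(self):
        t = np.linspace(0.0, 10.0, 11)
        curve = DropletVolumeCurve(t, np.full_like(t, 1e-12))
        flux = droplet_flux_variant(curve, 2e-3)
        assert flux(5.0) == 0.0

    def test_decreasing_volume_rejected(self):
        with pytest.raises(InvalidInput):
            DropletVolumeCurve([0.0, 1.0, 2.0], [2e-12, 1e-12, 3e-12])
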