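"""Importin-affinity: bound fractions, normalization, slopes, CV-CCA, calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucimport import ConfigurationError, FitFailure, InvalidInput
from nucimport.affinity import (
    TitrationTable,
    bound_fraction,
    bound_fraction_table,
    calibrate_abundance,
    fit_affinity_slope,
    integrate_replicates_cca,
    normalize_pulldown,
    replicate_slopes,
    variance_explained,
)


class TestBoundFraction:
    @pytest.mark.parametrize(
        "s_ran, s_noran, expected",
        [(0.3, 0.3, 0.5), (0.0, 0.7, 0.0), (0.7, 0.0, 1.0)],
    )
    def test_definition(self, s_ran, s_noran, expected):
        assert bound_fraction(s_ran, s_noran) == pytest.approx(expected)

    def test_both_zero_is_missing(self):
        assert np.isnan(bound_fraction(0.0, 0.0))

    @settings(deadline=None, max_examples=30)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_invariant_under_common_scaling(self, scale):
        assert bound_fraction(0.2 * scale, 0.6 * scale) == pytest.approx(0.25, rel=1e-9)


def _long_table(frac_by_protein, levels=(0.0, 2.0, 5.0), background=(), s0=1.0):
    """Build a titration table from per-protein fraction functions f(x)."""
    rows = []
    for pid, f in frac_by_protein.items():
        for x in levels:
            sig = s0 if x == 0 else s0 * f(x) / (1.0 - f(x))
            rows.append((pid, "r1", x, sig))
    df = pd.DataFrame(rows, columns=["protein_id", "replicate", "ran_level", "signal"])
    return TitrationTable(df, background_ids=set(background))


class TestNormalizePulldown:
    def test_background_median_rescaled_to_half(self):
        # background proteins drift to fraction 0.55 at every level
        bgs = {f"bg{i}": (lambda x: 0.55) for i in range(6)}
        table = _long_table({**bgs, "p": lambda x: 0.3}, background=bgs)
        out = normalize_pulldown(table)
        fr = bound_fraction_table(out)
        for x in (2.0, 5.0):
            med = fr[(fr["protein_id"].str.startswith("bg")) & (fr["ran_level"] == x)]["fraction"].median()
            assert med == pytest.approx(0.5, abs=1e-9)

    def test_idempotent_on_normalized_table(self):
        bgs = {f"bg{i}": (lambda x: 0.5) for i in range(6)}
        table = _long_table({**bgs, "p": lambda x: 0.5 - 0.03 * x}, background=bgs)
        once = normalize_pulldown(table)
        twice = normalize_pulldown(once)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_planted_bait_loading_artifact_removed(self):
        bgs = {f"bg{i}": (lambda x: 0.5) for i in range(6)}
        clean = _long_table({**bgs, "p": lambda x: 0.5 - 0.02 * x}, background=bgs)
        spoiled = TitrationTable(clean.data.copy(), set(bgs))
        mask = spoiled.data["ran_level"] == 2.0
        spoiled.data.loc[mask, "signal"] *= 2.0  # 2x loading in one condition
        fr_clean = bound_fraction_table(normalize_pulldown(clean))
        fr_spoiled = bound_fraction_table(normalize_pulldown(spoiled))
        merged = fr_clean.merge(fr_spoiled, on=["protein_id", "replicate", "ran_level"])
        np.testing.assert_allclose(merged["fraction_x"], merged["fraction_y"], atol=1e-9)

    def test_no_background_proteins_rejected(self):
        table = _long_table({"p": lambda x: 0.4})
        with pytest.raises(ConfigurationError):
            normalize_pulldown(table)


class TestFitAffinitySlope:
    def test_exact_line_through_fixed_intercept(self):
        pts = [(x, 0.5 - 0.04 * x) for x in (0.0, 2.0, 5.0, 10.0)]
        assert fit_affinity_slope(pts) == pytest.approx(-0.04, rel=1e-12)

    def test_background_protein_slope_zero(self):
        pts = [(x, 0.5) for x in (0.0, 2.0, 5.0, 10.0)]
        assert fit_affinity_slope(pts) == pytest.approx(0.0, abs=1e-15)

    def test_single_level_undefined(self):
        with pytest.raises(FitFailure):
            fit_affinity_slope([(2.0, 0.4), (2.0, 0.45)])

    def test_fit_passes_through_half_at_zero(self):
        # intercept is structurally 0.5: residual at x=0 never moves the fit
        pts = [(0.0, 0.9), (1.0, 0.48), (2.0, 0.46)]
        m = fit_affinity_slope(pts)
        assert 0.5 + m * 0.0 == 0.5

    def test_noisy_simulation_unbiased(self):
        rng = np.random.default_rng(0)
        levels = np.array([0.0, 1.0, 2.0, 4.0, 7.0, 10.0])
        est = []
        for _ in range(1000):
            f = 0.5 - 0.02 * levels + rng.normal(0, 0.03, levels.size)
            est.append(fit_affinity_slope(list(zip(levels, f))))
        assert np.mean(est) == pytest.approx(-0.02, rel=0.10)


class TestIntegrateReplicatesCca:
    def test_perfect_latent_gives_unit_correlation(self):
        rng = np.random.default_rng(1)
        t = pd.Series(rng.uniform(10, 40, 60), index=[f"p{i}" for i in range(60)])
        slopes = pd.DataFrame({"r1": t, "r2": t, "r3": t})
        out = integrate_replicates_cca(slopes, t, folds=5, seed=0)
        r = np.corrcoef(out["integrated_proxy"], t.loc[out.index])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-6)

    def test_pure_noise_gives_no_correlation(self):
        # the null corr of out-of-fold projections has spread ~ sqrt(p/n) per
        # dataset, so the property is asserted on the mean over datasets
        n = 1000
        idx = [f"p{i}" for i in range(n)]
        corrs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            t = pd.Series(rng.uniform(10, 40, n), index=idx)
            slopes = pd.DataFrame(rng.normal(size=(n, 3)), index=idx, columns=["r1", "r2", "r3"])
            out = integrate_replicates_cca(slopes, t, folds=10, seed=seed)
            corrs.append(abs(np.corrcoef(out["integrated_proxy"], t.loc[out.index])[0, 1]))
        assert np.mean(corrs) < 0.1

    def test_known_latent_r2_recovered(self):
        rng = np.random.default_rng(4)
        n = 500
        idx = [f"p{i}" for i in range(n)]
        latent = rng.standard_normal(n)
        t = pd.Series(latent, index=idx)
        # replicate noise sd sqrt(3): the optimal 3-replicate average has R^2 = 0.5
        slopes = pd.DataFrame(
            latent[:, None] + np.sqrt(3.0) * rng.standard_normal((n, 3)),
            index=idx, columns=["r1", "r2", "r3"],
        )
        out = integrate_replicates_cca(slopes, t, folds=10, seed=5)
        r2, _ = variance_explained(out["integrated_proxy"], t.loc[out.index])
        assert 0.4 <= r2 <= 0.6

    def test_permuted_labels_destroy_correlation(self):
        """Out-of-fold projections carry no leakage from the held-out labels."""
        rng = np.random.default_rng(6)
        n = 500
        idx = [f"p{i}" for i in range(n)]
        latent = rng.standard_normal(n)
        slopes = pd.DataFrame(
            latent[:, None] + rng.standard_normal((n, 3)),
            index=idx, columns=["r1", "r2", "r3"],
        )
        corrs = []
        for seed in range(20):
            t_perm = pd.Series(np.random.default_rng(100 + seed).permutation(latent), index=idx)
            out = integrate_replicates_cca(slopes, t_perm, folds=10, seed=seed)
            corrs.append(abs(np.corrcoef(out["integrated_proxy"], t_perm.loc[out.index])[0, 1]))
        assert np.mean(corrs) < 2.0 / np.sqrt(n)

    def test_missing_replicates_imputed_and_counted(self):
        rng = np.random.default_rng(7)
        n = 40
        idx = [f"p{i}" for i in range(n)]
        t = pd.Series(rng.uniform(10, 40, n), index=idx)
        slopes = pd.DataFrame(rng.normal(size=(n, 3)), index=idx, columns=["r1", "r2", "r3"])
        slopes.iloc[0, 0] = np.nan  # 2 replicates -> kept
        slopes.iloc[1, :2] = np.nan  # 1 replicate -> dropped
        out = integrate_replicates_cca(slopes, t, folds=4, seed=8)
        assert idx[0] in out.index and idx[1] not in out.index
        assert out.loc[idx[0], "n_replicates_observed"] == 2


class TestVarianceExplained:
    def test_identical_vectors(self):
        r2, _ = variance_explained([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert r2 == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        r2, _ = variance_explained([1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0])
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_planted_correlation(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(2000)
        y = 0.6 * x + np.sqrt(1 - 0.36) * rng.standard_normal(2000)
        r2, p = variance_explained(x, y)
        assert r2 == pytest.approx(0.36, abs=0.05)
        assert p < 1e-10

    def test_zero_variance_rejected(self):
        with pytest.raises(InvalidInput):
            variance_explained([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCalibrateAbundance:
    def test_exact_power_law_recovered(self):
        rng = np.random.default_rng(10)
        log_s = rng.uniform(0, 5, 200)
        log_c = -9.0 + 0.8 * log_s
        cal = calibrate_abundance(log_s, log_c)
        assert cal.slope == pytest.approx(0.8, abs=1e-6)
        assert cal.intercept == pytest.approx(-9.0, abs=1e-6)
        np.testing.assert_allclose(cal.predict_conc_m([2.5]), 10 ** (-9.0 + 2.0), rtol=1e-6)

    def test_gross_outliers_tolerated_where_ols_fails(self):
        rng = np.random.default_rng(11)
        log_s = rng.uniform(0, 5, 300)
        log_c = -9.0 + 0.8 * log_s + rng.normal(0, 0.05, 300)
        out = rng.random(300) < 0.10
        log_c[out] += 2.0  # x100 concentration errors
        cal = calibrate_abundance(log_s, log_c)
        assert cal.slope == pytest.approx(0.8, rel=0.05)
        ols = np.polyfit(log_s, log_c, 1)[0]
        assert abs(ols - 0.8) > abs(cal.slope - 0.8)

    def test_single_populated_bin_rejected(self):
        with pytest.raises(FitFailure):
            calibrate_abundance([1.0, 1.1, 1.05], [-8.0, -8.1, -8.05])


def test_end_to_end_latent_kd_drives_proxy_and_entry_time():
    """Planted ln K_D couples slopes and T1/2; CV-CCA R^2 tracks the generative R^2."""
    from nucimport import synth

    table, truth = synth.generate_titration(n_proteins=300, seed=12)
    table = normalize_pulldown(table)
    slopes = replicate_slopes(table).loc[truth.values["protein_id"]]
    t_half = pd.Series(truth.values["t_half_h"], index=truth.values["protein_id"])
    out = integrate_replicates_cca(slopes, t_half, folds=10, seed=13)
    r2, _ = variance_explained(out["integrated_proxy"], t_half.loc[out.index])
    # generative R^2: planted slope (noise-free latent) against planted t_half
    gen_r2, _ = variance_explained(truth.values["slope"], t_half.to_numpy())
    assert abs(r2 - gen_r2) <= 0.1
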