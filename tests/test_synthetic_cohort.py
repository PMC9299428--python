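"""Generator calibration: LD structure, summary-stat noise, prevalences,
disease model, determinism."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from prsjoint import (
    ConfigurationError,
    LifestyleConfig,
    SimulationConfig,
    derive_profile,
    make_ground_truth,
    simulate_disease,
    simulate_lifestyle,
    simulate_panel,
    simulate_summary_stats,
    variant_map,
)
from prsjoint.synthetic_cohort import summary_stat_se


def test_seeded_determinism_across_all_generators(small_config):
    p1, p2 = simulate_panel(small_config), simulate_panel(small_config)
    np.testing.assert_array_equal(p1.dosages, p2.dosages)
    t1, t2 = make_ground_truth(small_config), make_ground_truth(small_config)
    np.testing.assert_array_equal(t1.true_betas, t2.true_betas)
    s1 = simulate_summary_stats(small_config, t1)
    s2 = simulate_summary_stats(small_config, t2)
    assert s1.equals(s2)
    l1 = simulate_lifestyle(small_config, 500)
    l2 = simulate_lifestyle(small_config, 500)
    assert l1.equals(l2)
    c1 = simulate_disease(p1, simulate_lifestyle(small_config), t1, small_config)
    c2 = simulate_disease(p2, simulate_lifestyle(small_config), t2, small_config)
    assert c1.equals(c2)


def test_dosages_are_legal_hard_calls(small_bundle):
    d = small_bundle.panel.dosages
    assert not np.isnan(d).any()
    assert set(np.unique(d)) <= {0.0, 1.0, 2.0}


def test_missingness_only_when_configured(small_config):
    cfg = SimulationConfig(
        **{**small_config.__dict__, "missing_rate": 0.05, "seed": 99}
    )
    panel = simulate_panel(cfg)
    frac = np.isnan(panel.dosages).mean()
    assert 0.03 < frac < 0.07


def test_invalid_dimensions_rejected():
    with pytest.raises(ConfigurationError):
        SimulationConfig(n_individuals=0).validate()
    with pytest.raises(ConfigurationError):
        SimulationConfig(ld_rho=1.0).validate()
    with pytest.raises(ConfigurationError):
        SimulationConfig(n_causal=10, n_variants=5).validate()


def test_variant_map_geometry(small_config):
    vm = variant_map(small_config)
    # blocks never straddle chromosomes and stay under 1 Mb wide
    for _, blk in vm.groupby("block"):
        assert blk["chrom"].nunique() == 1
        assert blk["pos"].max() - blk["pos"].min() < 1_000_000
    # some chr6 variants fall inside the MHC window for exclusion tests
    chr6 = vm[vm["chrom"] == "6"]
    inside = (chr6["pos"] >= 28_477_797) & (chr6["pos"] <= 33_448_354)
    assert inside.any()


def test_empirical_maf_matches_drawn_maf():
    cfg = SimulationConfig(n_individuals=20_000, n_variants=40, block_size=5, seed=31)
    panel = simulate_panel(cfg)
    # binomial sampling error at n=20,000 is ~0.005 at two allele draws
    np.testing.assert_allclose(
        panel.allele_frequency(), panel.variants["maf"], atol=0.012
    )


def test_ld_free_panel_has_no_residual_correlation():
    cfg = SimulationConfig(
        n_individuals=20_000,
        n_variants=20,
        block_size=5,
        ld_rho=0.0,
        n_causal=2,
        maf_range=(0.3, 0.3001),
        seed=32,
    )
    panel = simulate_panel(cfg)
    corr = np.corrcoef(panel.dosages.T)
    off = np.abs(corr[np.triu_indices(20, k=1)])
    assert off.mean() < 0.02  # sampling bound ~ 1/sqrt(n)


def _copula_dosage_corr(p: float, rho: float) -> float:
    """Oracle: dosage correlation implied by the Gaussian copula.

    Haplotypes are thresholded latents, so their correlation is the
    standardised bivariate-normal orthant probability; summing two
    independent haplotypes preserves the correlation.
    """
    t = sps.norm.ppf(p)
    p11 = sps.multivariate_normal.cdf([t, t], mean=[0, 0], cov=[[1, rho], [rho, 1]])
    return (p11 - p * p) / (p * (1 - p))


def test_high_ld_adjacent_r2_matches_copula_oracle():
    cfg = SimulationConfig(
        n_individuals=20_000, n_variants=10, block_size=10, ld_rho=0.9,
        n_causal=2, maf_range=(0.45, 0.5), seed=33,
    )
    panel = simulate_panel(cfg)
    maf = panel.variants["maf"].to_numpy()
    r2 = np.array([
        np.corrcoef(panel.dosages[:, j], panel.dosages[:, j + 1])[0, 1] ** 2
        for j in range(9)
    ])
    expected = np.array([
        _copula_dosage_corr(0.5 * (maf[j] + maf[j + 1]), 0.9) ** 2 for j in range(9)
    ])
    np.testing.assert_allclose(r2, expected, atol=0.04)
    assert r2.mean() > 0.5  # near-balanced alleles keep dosage r^2 above half
    # and LD decays with distance
    r2_far = np.corrcoef(panel.dosages[:, 0], panel.dosages[:, 9])[0, 1] ** 2
    assert r2_far < r2.mean()


def test_summary_stat_se_closed_form():
    se = summary_stat_se(0.3, 50_000, 0.25)
    expected = 1.0 / math.sqrt(2 * 50_000 * 0.3 * 0.7 * 0.25 * 0.75)
    assert se == pytest.approx(expected, abs=1e-12)


def test_infinite_discovery_is_noise_free():
    # LD-free so the marginal beta of a causal variant is its own effect
    cfg = SimulationConfig(
        n_individuals=100, n_variants=100, block_size=1, ld_rho=0.0,
        n_causal=20, discovery_n=math.inf, seed=30,
    )
    truth = make_ground_truth(cfg)
    stats = simulate_summary_stats(cfg, truth)
    causal = stats["SNP"].isin(truth.causal_variant_ids).to_numpy()
    np.testing.assert_allclose(
        stats["BETA"][causal],
        truth.true_betas[truth.true_betas != 0],
        rtol=1e-12,
    )
    assert (stats.loc[causal, "P"] < 1e-290).all()
    assert (stats.loc[~causal, "P"] == 1.0).all()


def test_null_variant_pvalues_are_uniform():
    # LD-free, no causal signal: two-sided Wald p uniform on (0,1)
    cfg = SimulationConfig(
        n_individuals=100, n_variants=2_000, block_size=1, ld_rho=0.0,
        n_causal=0, seed=34,
    )
    truth = make_ground_truth(cfg)
    stats = simulate_summary_stats(cfg, truth)
    ks = sps.kstest(stats["P"], "uniform")
    assert ks.pvalue > 0.01


def test_tagged_variant_marginal_beta_projection():
    cfg = SimulationConfig(
        n_individuals=100, n_variants=4, block_size=4, ld_rho=0.8,
        n_causal=1, discovery_n=math.inf, or_per_sd=None, causal_log_or=0.3,
        seed=35,
    )
    truth = make_ground_truth(cfg)
    stats = simulate_summary_stats(cfg, truth)
    j = int(np.flatnonzero(truth.true_betas != 0)[0])
    beta = truth.true_betas[j]
    for k in range(4):
        assert stats["BETA"].iloc[k] == pytest.approx(beta * 0.8 ** abs(k - j), rel=1e-9)


def test_lifestyle_prevalences_recovered():
    cfg = SimulationConfig(seed=36)
    raw = simulate_lifestyle(cfg, 100_000)
    prof = derive_profile(raw, LifestyleConfig())
    assert 0.70 <= prof["regular_activity"].mean() <= 0.72
    assert 0.60 <= prof["no_smoking"].mean() <= 0.62
    assert abs(prof["moderate_bmi"].mean() - 0.781) <= 0.01
    assert abs(prof["no_alcohol"].mean() - 0.06) <= 0.005


def test_bmi_quantile_calibration():
    # the log-normal parameters must put the configured mass in [18.5, 24)
    cfg = SimulationConfig(seed=37)
    raw = simulate_lifestyle(cfg, 100_000)
    frac = ((raw["bmi"] >= 18.5) & (raw["bmi"] < 24.0)).mean()
    assert abs(frac - 0.781) <= 0.01


def test_null_cohort_matches_baseline_rates():
    cfg = SimulationConfig(
        n_individuals=50_000, n_variants=20, block_size=1, n_causal=1,
        or_per_sd=None, causal_log_or=0.0,
        lifestyle_log_or={}, covariate_log_or={},
        baseline_prevalence=0.02, baseline_hazard=2e-3, seed=38,
    )
    panel = simulate_panel(cfg)
    truth = make_ground_truth(cfg)
    truth.true_betas[:] = 0.0
    life = simulate_lifestyle(cfg)
    cohort = simulate_disease(panel, life, truth, cfg)
    prev = (cohort["onset_period"] == "baseline").mean()
    assert prev == pytest.approx(0.02, abs=3 * math.sqrt(0.02 * 0.98 / 50_000))


def test_zero_hazard_means_no_events(small_bundle, small_config):
    cfg = SimulationConfig(**{**small_config.__dict__, "baseline_hazard": 0.0})
    truth = make_ground_truth(cfg)
    life = simulate_lifestyle(cfg)
    cohort = simulate_disease(small_bundle.panel, life, truth, cfg)
    assert cohort["event"].sum() == 0
    censored = cohort["onset_period"] != "baseline"
    lo, hi = cfg.censor_year_range
    assert ((cohort.loc[censored, "time"] >= lo) & (cohort.loc[censored, "time"] <= hi)).all()


def test_km_on_null_cohort_tracks_exponential_survival():
    from lifelines import KaplanMeierFitter

    h0 = 3e-3
    cfg = SimulationConfig(
        n_individuals=40_000, n_variants=10, block_size=1, n_causal=1,
        or_per_sd=None, causal_log_or=0.0,
        lifestyle_log_or={}, covariate_log_or={},
        baseline_prevalence=0.001, baseline_hazard=h0,
        censor_year_range=(10.0, 14.0), seed=39,
    )
    panel = simulate_panel(cfg)
    truth = make_ground_truth(cfg)
    truth.true_betas[:] = 0.0
    cohort = simulate_disease(panel, simulate_lifestyle(cfg), truth, cfg)
    sub = cohort[cohort["onset_period"] != "baseline"]
    km = KaplanMeierFitter().fit(sub["time"], sub["event"])
    for t in (2.0, 5.0, 8.0):
        est = float(km.survival_function_at_times(t).iloc[0])
        # 99% band: Greenwood-scale error ~ sqrt(S(1-S)/n)
        band = 2.58 * math.sqrt(max(est * (1 - est), 1e-6) / len(sub)) + 1e-4
        assert abs(est - math.exp(-h0 * t)) < band


def test_or_per_sd_recovered_by_true_score_refit():
    # logistic refit of the standardized true score recovers the configured
    # odds ratio per SD (the generator's headline calibration)
    import pandas as pd

    from prsjoint import fit_logistic

    cfg = SimulationConfig(
        n_individuals=150_000, n_variants=60, block_size=1, n_causal=30,
        or_per_sd=1.4, baseline_prevalence=0.02, baseline_hazard=2e-3,
        seed=40,
    )
    panel = simulate_panel(cfg)
    truth = make_ground_truth(cfg)
    cohort = simulate_disease(panel, simulate_lifestyle(cfg), truth, cfg)
    g = panel.dosages.astype(float) @ truth.true_betas
    z = (g - g.mean()) / g.std(ddof=1)
    X = pd.DataFrame(
        {
            "prs": z,
            "age": cohort["age"],
            "sex_female": (cohort["sex"] == "female").astype(float),
        }
    )
    fit = fit_logistic(X, cohort["status"].to_numpy(float))
    assert 1.33 <= math.exp(fit["prs"]) <= 1.47
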