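"""Synthetic biobank-style cohort generator with known ground truth.

Generates everything the PRS/lifestyle pipeline consumes:

* LD-blocked genotype dosages (Gaussian-copula haplotypes, AR(1) latent
  correlation within blocks, Hardy–Weinberg marginals at a drawn MAF);
* discovery GWAS summary statistics sampled analytically around the true
  marginal effects, with the binary-trait standard-error approximation
  ``se = 1 / sqrt(2 N maf (1-maf) phi (1-phi))``;
* raw lifestyle questionnaire fields whose derived indicators hit
  configured prevalences (defaults follow a large population biobank: ~71%
  regularly active, ~61% non-smokers, ~78% moderate BMI, ~6% non-drinkers);
* prevalent (baseline) and incident (follow-up) rheumatoid-arthritis-like
  disease from a logistic and a proportional-hazards model sharing one
  linear predictor, with administrative censoring.

Every operation is deterministic given ``SimulationConfig.seed``; each
stage draws from its own spawned stream so that, e.g., regenerating the
panel does not perturb the lifestyle table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import AlignmentError, ConfigurationError
from .lifestyle import LifestyleConfig, derive_profile
from .panel import GenotypePanel

# stream ids for per-stage RNG substreams
_STREAM_VARIANTS = 0
_STREAM_PANEL = 1
_STREAM_SUMSTATS = 2
_STREAM_LIFESTYLE = 3
_STREAM_DISEASE = 4
_STREAM_TRUTH = 5

_ALLELES = np.array(list("ACGT"))

#: within-block spacing between adjacent variants (bp)
_POS_STEP = 5_000
#: gap between successive blocks on the same chromosome (bp); larger than
#: the 1 Mb clumping window so blocks are independent for clumping purposes
_BLOCK_GAP = 3_000_000
#: chr6 blocks start here so early chr6 variants fall inside the MHC window
_CHR6_BASE = 28_450_000
_OTHER_BASE = 10_000_000


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults are calibrated to the published epidemiology this package
    models: OR per PRS standard deviation 1.4, protective lifestyle ORs
    0.70-0.75, ~0.35% prevalent and ~0.9% incident disease, lifestyle
    prevalences from the cohort's descriptive table.
    """

    n_individuals: int = 20_000
    n_variants: int = 2_000
    block_size: int = 10
    ld_rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 30
    causal_log_or: float = 0.1
    #: if set, causal effects are rescaled so the true genetic score has
    #: this odds ratio per standard deviation
    or_per_sd: float | None = 1.4
    discovery_n: float = 100_000
    discovery_case_fraction: float = 0.25
    lifestyle_prevalences: Mapping[str, float] = field(
        default_factory=lambda: {
            "no_smoking": 0.61,
            "regular_activity": 0.71,
            "moderate_bmi": 0.781,
            "no_alcohol": 0.06,
        }
    )
    lifestyle_log_or: Mapping[str, float] = field(
        default_factory=lambda: {
            "no_smoking": math.log(0.70),
            "regular_activity": math.log(0.75),
            "moderate_bmi": math.log(0.72),
        }
    )
    covariate_log_or: Mapping[str, float] = field(
        default_factory=lambda: {"age_per_sd": 0.38, "female": 0.56}
    )
    # calibrated to the emulated cohort: ~0.35% prevalent at baseline and
    # ~0.9% incident over a median ~11-year follow-up (the population-mean
    # relative hazard exp(eta) is ~0.74 under the default lifestyle mix)
    baseline_prevalence: float = 0.0035
    baseline_hazard: float = 1.1e-3
    censor_year_range: tuple[float, float] = (8.0, 14.0)
    interaction_log_or: float = 0.0
    missing_rate: float = 0.0
    seed: int = 20220706

    def validate(self) -> None:
        if self.n_individuals <= 0 or self.n_variants <= 0 or self.block_size <= 0:
            raise ConfigurationError("dimensions must be positive")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ConfigurationError("ld_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.02 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie in (0.02, 0.5]")
        if self.n_causal > self.n_variants:
            raise ConfigurationError("n_causal exceeds n_variants")
        if self.block_size > 200:
            raise ConfigurationError("block_size > 200 would exceed 1 Mb block width")
        for name, p in {
            "baseline_prevalence": self.baseline_prevalence,
            "discovery_case_fraction": self.discovery_case_fraction,
            **dict(self.lifestyle_prevalences),
        }.items():
            if not (0.0 < p < 1.0):
                raise ConfigurationError(f"probability {name}={p} outside (0,1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate outside [0,1)")
        if self.censor_year_range[0] > self.censor_year_range[1]:
            raise ConfigurationError("censor_year_range reversed")
        if self.discovery_n <= 0:
            raise ConfigurationError("discovery_n must be positive")


@dataclass
class GroundTruth:
    """Generative parameters recorded for recovery testing."""

    causal_variant_ids: list[str]
    true_betas: np.ndarray
    true_lifestyle_effects: dict[str, float]
    true_or_per_sd: float
    true_covariate_effects: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "causal_variant_ids": list(self.causal_variant_ids),
            "true_betas": np.asarray(self.true_betas).tolist(),
            "true_lifestyle_effects": dict(self.true_lifestyle_effects),
            "true_or_per_sd": float(self.true_or_per_sd),
            "true_covariate_effects": dict(self.true_covariate_effects),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            causal_variant_ids=list(d["causal_variant_ids"]),
            true_betas=np.asarray(d["true_betas"], dtype=float),
            true_lifestyle_effects=dict(d["true_lifestyle_effects"]),
            true_or_per_sd=float(d["true_or_per_sd"]),
            true_covariate_effects=dict(d.get("true_covariate_effects", {})),
        )


# ----------------------------------------------------------------------
# variant map: shared, deterministic metadata for panel and summary stats
# ----------------------------------------------------------------------

def variant_map(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic variant metadata (id, chrom, pos, block, alleles, maf).

    Blocks are assigned to chromosomes 1..22 cyclically; positions are spaced
    so a block spans < 1 Mb and successive blocks on a chromosome sit 3 Mb
    apart.  Chromosome 6 blocks start just below the MHC window so some
    variants land inside it, which exercises the MHC-exclusion path.
    """
    config.validate()
    m = config.n_variants
    bs = config.block_size
    n_blocks = math.ceil(m / bs)

    block_of = np.repeat(np.arange(n_blocks), bs)[:m]
    chrom_of_block = (np.arange(n_blocks) % 22) + 1
    round_of_block = np.arange(n_blocks) // 22

    chrom = chrom_of_block[block_of]
    base = np.where(chrom == 6, _CHR6_BASE, _OTHER_BASE)
    offset_in_block = np.arange(m) - block_of * bs
    pos = base + round_of_block[block_of] * _BLOCK_GAP + offset_in_block * _POS_STEP

    rng = _rng(config.seed, _STREAM_VARIANTS)
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    a1_idx = rng.integers(0, 4, size=m)
    a2_idx = (a1_idx + rng.integers(1, 4, size=m)) % 4

    return pd.DataFrame(
        {
            "id": [f"snp{i:06d}" for i in range(m)],
            "chrom": chrom.astype(str),
            "pos": pos.astype(np.int64),
            "block": block_of,
            "a1": _ALLELES[a1_idx],
            "a2": _ALLELES[a2_idx],
            "maf": maf,
        }
    )


# ----------------------------------------------------------------------
# genotype panel
# ----------------------------------------------------------------------

def _ar1_latents(rng: np.random.Generator, n: int, width: int, rho: float) -> np.ndarray:
    """Stationary AR(1) Gaussian latents, one row per haplotype."""
    eps = rng.standard_normal((n, width))
    if rho == 0.0 or width == 1:
        return eps
    z = np.empty_like(eps)
    z[:, 0] = eps[:, 0]
    c = math.sqrt(1.0 - rho * rho)
    for j in range(1, width):
        z[:, j] = rho * z[:, j - 1] + c * eps[:, j]
    return z


def simulate_panel(config: SimulationConfig) -> GenotypePanel:
    """Draw an LD-blocked dosage panel via a Gaussian copula.

    Each individual carries two independent haplotype latents per block;
    a haplotype carries the counted allele when its latent falls below the
    MAF quantile, so marginal genotypes are Binomial(2, maf) — exact
    Hardy–Weinberg — while adjacent-variant correlation decays like
    ``ld_rho ** distance`` on the latent scale.
    """
    config.validate()
    vm = variant_map(config)
    rng = _rng(config.seed, _STREAM_PANEL)
    n = config.n_individuals

    thresholds = stats.norm.ppf(vm["maf"].to_numpy())
    dosages = np.empty((n, config.n_variants), dtype=np.float32)
    for b, idx in vm.groupby("block").groups.items():
        cols = np.asarray(idx)
        t = thresholds[cols]
        hap1 = _ar1_latents(rng, n, len(cols), config.ld_rho) < t
        hap2 = _ar1_latents(rng, n, len(cols), config.ld_rho) < t
        dosages[:, cols] = hap1.astype(np.float32) + hap2.astype(np.float32)

    if config.missing_rate > 0:
        miss = rng.random(dosages.shape) < config.missing_rate
        dosages[miss] = np.nan

    ids = np.array([f"id{i:07d}" for i in range(n)])
    return GenotypePanel(individual_ids=ids, variants=vm.drop(columns="block"), dosages=dosages)


# ----------------------------------------------------------------------
# ground truth
# ----------------------------------------------------------------------

def _expected_score_variance(vm: pd.DataFrame, betas: np.ndarray, rho: float) -> float:
    """Variance of the true genetic score under the copula's latent LD.

    Diagonal terms 2 p q beta^2 are exact (binomial dosages); cross terms
    use the latent AR(1) correlation as the dosage correlation, a documented
    approximation that slightly overstates dosage-scale LD.
    """
    maf = vm["maf"].to_numpy()
    sd = np.sqrt(2.0 * maf * (1.0 - maf))
    var = 0.0
    for _, idx in vm.groupby("block").groups.items():
        cols = np.asarray(idx)
        b = betas[cols]
        if not np.any(b):
            continue
        d = np.abs(np.subtract.outer(np.arange(len(cols)), np.arange(len(cols))))
        r = rho ** d if rho > 0 else np.eye(len(cols))
        s = sd[cols] * b
        var += float(s @ r @ s)
    return var


def make_ground_truth(
    config: SimulationConfig,
    *,
    causal_ids: list[str] | None = None,
    betas: Mapping[str, float] | None = None,
) -> GroundTruth:
    """Choose causal variants and per-allele effects.

    By default ``n_causal`` variants are drawn at random with effects
    N(0, causal_log_or^2); when ``config.or_per_sd`` is set the effects are
    rescaled so the true genetic score has that odds ratio per SD.  Explicit
    ``causal_ids``/``betas`` override the random draw (used by the designed
    validation scenarios).
    """
    config.validate()
    vm = variant_map(config)
    true_betas = np.zeros(config.n_variants)

    if betas is not None:
        lookup = pd.Index(vm["id"])
        for vid, b in betas.items():
            j = lookup.get_loc(vid)
            true_betas[j] = b
        causal = [v for v in vm["id"] if betas.get(v, 0.0) != 0.0]
    else:
        rng = _rng(config.seed, _STREAM_TRUTH)
        pick = rng.choice(config.n_variants, size=config.n_causal, replace=False)
        if causal_ids is not None:
            pick = vm.set_index("id").index.get_indexer(causal_ids)
        draws = rng.normal(0.0, config.causal_log_or, size=len(pick))
        draws[draws == 0.0] = config.causal_log_or
        true_betas[pick] = draws
        causal = vm["id"].to_numpy()[np.sort(pick)].tolist()

    var = _expected_score_variance(vm, true_betas, config.ld_rho)
    if config.or_per_sd is not None and betas is None and var > 0:
        true_betas *= math.log(config.or_per_sd) / math.sqrt(var)
        or_per_sd = float(config.or_per_sd)
    else:
        or_per_sd = float(math.exp(math.sqrt(var))) if var > 0 else 1.0

    return GroundTruth(
        causal_variant_ids=causal,
        true_betas=true_betas,
        true_lifestyle_effects=dict(config.lifestyle_log_or),
        true_or_per_sd=or_per_sd,
        true_covariate_effects=dict(config.covariate_log_or),
    )


# ----------------------------------------------------------------------
# discovery summary statistics
# ----------------------------------------------------------------------

def summary_stat_se(maf, discovery_n, case_fraction) -> np.ndarray:
    """Binary-trait GWAS standard error approximation."""
    maf = np.asarray(maf, dtype=float)
    phi = case_fraction
    with np.errstate(divide="ignore"):
        return 1.0 / np.sqrt(2.0 * discovery_n * maf * (1.0 - maf) * phi * (1.0 - phi))


def simulate_summary_stats(config: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    """Sample discovery summary statistics analytically.

    Marginal effects: causal variants keep their true beta; LD partners pick
    up ``sum_j r_ij beta_j`` with r the latent AR(1) correlation.  Estimates
    are ``N(beta_marginal, se^2)`` with the binary-trait se; two-sided Wald
    p-values follow.  ``discovery_n = inf`` gives the noise-free limit.
    """
    config.validate()
    vm = variant_map(config)
    if len(truth.true_betas) != config.n_variants:
        raise AlignmentError("truth.true_betas length does not match n_variants")

    beta_marg = np.zeros(config.n_variants)
    for _, idx in vm.groupby("block").groups.items():
        cols = np.asarray(idx)
        b = truth.true_betas[cols]
        if not np.any(b):
            continue
        if config.ld_rho > 0:
            d = np.abs(np.subtract.outer(np.arange(len(cols)), np.arange(len(cols))))
            beta_marg[cols] = (config.ld_rho ** d) @ b
        else:
            beta_marg[cols] = b

    infinite = math.isinf(config.discovery_n)
    se = (
        np.zeros(config.n_variants)
        if infinite
        else summary_stat_se(vm["maf"], config.discovery_n, config.discovery_case_fraction)
    )
    rng = _rng(config.seed, _STREAM_SUMSTATS)
    beta_hat = beta_marg if infinite else rng.normal(beta_marg, se)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta_hat / np.where(se > 0, se, 1.0), np.inf * np.sign(beta_hat))
    z = np.where((se == 0) & (beta_hat == 0), 0.0, z)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals = np.clip(pvals, np.nextafter(0, 1), 1.0)

    out = pd.DataFrame(
        {
            "SNP": vm["id"],
            "CHR": vm["chrom"],
            "BP": vm["pos"],
            "A1": vm["a1"],
            "A2": vm["a2"],
            "BETA": beta_hat,
            "SE": se,
            "P": pvals,
        }
    )
    out.attrs["discovery_n"] = config.discovery_n
    out.attrs["case_fraction"] = config.discovery_case_fraction
    out.attrs["seed"] = config.seed
    return out


# ----------------------------------------------------------------------
# lifestyle fields
# ----------------------------------------------------------------------

_FREQ_EXCEEDS_MONTHLY = "more than monthly"
_FREQ_MONTHLY_OR_LESS = "monthly or less"
_FREQ_NEVER = "never"

_DIET_COLUMNS = ("fruit", "vegetables", "whole_grains", "fish", "red_meat", "processed_meat")


def _solve_bmi_mu(low: float, high: float, target: float, sigma: float) -> float:
    """Log-normal location giving P(low <= BMI < high) = target."""
    def window(mu: float) -> float:
        return (
            stats.norm.cdf((math.log(high) - mu) / sigma)
            - stats.norm.cdf((math.log(low) - mu) / sigma)
            - target
        )

    center = 0.5 * (math.log(low) + math.log(high))
    if window(center) < 0:
        raise ConfigurationError(
            f"moderate-BMI prevalence {target} unattainable with sigma={sigma}"
        )
    # take the upper root: population mean BMI above the window midpoint
    return optimize.brentq(window, center, center + 2.0, xtol=1e-12)


def simulate_lifestyle(config: SimulationConfig, n: int | None = None) -> pd.DataFrame:
    """Emit raw questionnaire-style lifestyle fields for ``n`` individuals.

    The raw fields are constructed so that the lifestyle module's derivation
    rules recover the configured indicator prevalences (diet is the
    exception: the k-of-6 median rule pins its prevalence near 0.34
    regardless, which matches the cohort table this generator emulates).
    """
    config.validate()
    n = config.n_individuals if n is None else int(n)
    if n <= 0:
        raise ConfigurationError("n must be positive")
    rng = _rng(config.seed, _STREAM_LIFESTYLE)
    prev = dict(config.lifestyle_prevalences)

    # --- smoking: never / former (uniform quit years on (0, 40]) / current
    pi_s = prev["no_smoking"]
    former = 0.30
    never = pi_s - former * 0.25
    current = 1.0 - former - never
    if never <= 0 or current <= 0:
        raise ConfigurationError("no_smoking prevalence outside attainable range")
    status = rng.choice(["never", "former", "current"], size=n, p=[never, former, current])
    quit_years = np.where(status == "former", rng.uniform(0.0, 40.0, size=n), np.nan)

    # --- alcohol: non-drinking = not (current AND more than monthly)
    pi_a = prev["no_alcohol"]
    p_current = 1.0 - 0.6 * pi_a
    is_current = rng.random(n) < p_current
    p_freq_high = (1.0 - pi_a) / p_current
    freq = np.where(
        is_current,
        np.where(rng.random(n) < p_freq_high, _FREQ_EXCEEDS_MONTHLY, _FREQ_MONTHLY_OR_LESS),
        _FREQ_NEVER,
    )
    drinker_status = np.where(
        is_current, "current", np.where(rng.random(n) < 0.5, "never", "former")
    )

    # --- physical activity
    pi_p = prev["regular_activity"]
    active = rng.random(n) < pi_p
    vig = np.empty(n)
    mod = np.empty(n)
    days = np.empty(n, dtype=int)
    hi = rng.random(n) < 0.5  # active subtype: vigorous-led vs combination
    vig[active & hi] = rng.uniform(80.0, 300.0, size=int(np.sum(active & hi)))
    mod[active & hi] = rng.uniform(0.0, 150.0, size=int(np.sum(active & hi)))
    k = int(np.sum(active & ~hi))
    v = rng.uniform(0.0, 60.0, size=k)
    vig[active & ~hi] = v
    mod[active & ~hi] = 150.0 - 2.0 * v + rng.uniform(0.0, 250.0, size=k)
    days[active] = rng.integers(3, 8, size=int(np.sum(active)))
    k = int(np.sum(~active))
    v = rng.uniform(0.0, 40.0, size=k)
    vig[~active] = v
    mod[~active] = rng.uniform(0.0, np.maximum(149.0 - 2.0 * v, 1.0), size=k)
    days[~active] = rng.integers(0, 5, size=k)

    # --- diet component frequencies (servings/week, independent)
    diet = {c: rng.lognormal(mean=1.0, sigma=0.5, size=n) for c in _DIET_COLUMNS}

    # --- BMI: log-normal calibrated to the moderate-BMI window
    sigma = 0.09
    mu = _solve_bmi_mu(18.5, 24.0, prev["moderate_bmi"], sigma)
    bmi = rng.lognormal(mean=mu, sigma=sigma, size=n)

    return pd.DataFrame(
        {
            "smoking_status": status,
            "years_since_quit": quit_years,
            "drinker_status": drinker_status,
            "drink_frequency": freq,
            "vigorous_min_wk": vig,
            "moderate_min_wk": mod,
            "active_days_wk": days,
            **diet,
            "bmi": bmi,
        }
    )


# ----------------------------------------------------------------------
# disease outcomes and covariates
# ----------------------------------------------------------------------

def _solve_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept alpha with mean(expit(alpha + eta)) = target."""
    def f(a: float) -> float:
        return float(np.mean(special.expit(a + eta))) - target

    return optimize.brentq(f, -30.0, 10.0, xtol=1e-12)


def simulate_disease(
    panel: GenotypePanel,
    lifestyle: pd.DataFrame,
    truth: GroundTruth,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Generate outcomes, covariates and merge in the raw lifestyle fields.

    One linear predictor (genetics + lifestyle + age/sex) drives both the
    prevalent-at-baseline logistic draw and the incident exponential hazard,
    mirroring parallel case-control and prospective designs.  Administrative
    censoring is uniform over ``censor_year_range``.
    """
    config.validate()
    n = panel.n_individuals
    if len(lifestyle) != n:
        raise AlignmentError(
            f"lifestyle table has {len(lifestyle)} rows for {n} individuals"
        )
    rng = _rng(config.seed, _STREAM_DISEASE)

    dos = panel.dosages
    if np.isnan(dos).any():
        col_mean = np.nanmean(dos, axis=0)
        dos = np.where(np.isnan(dos), col_mean, dos)
    g_score = dos @ truth.true_betas
    g_centered = g_score - g_score.mean()

    profile = derive_profile(lifestyle, LifestyleConfig())
    life_term = np.zeros(n)
    for factor, gamma in truth.true_lifestyle_effects.items():
        flag = profile[factor].to_numpy(dtype=float)
        life_term += gamma * np.nan_to_num(flag, nan=0.0)

    age = np.clip(rng.normal(56.5, 8.0, size=n), 40.0, 70.0)
    female = rng.random(n) < 0.534
    tdi = rng.normal(-1.65, 2.89, size=n)
    batch = rng.choice(["batch1", "batch2", "batch3"], size=n)
    center = rng.choice([f"center{i}" for i in range(1, 7)], size=n)
    pcs = rng.standard_normal((n, 10))

    cov_eff = truth.true_covariate_effects
    eta = (
        g_centered
        + life_term
        + cov_eff.get("age_per_sd", 0.0) * (age - 56.5) / 8.0
        + cov_eff.get("female", 0.0) * female
    )
    if config.interaction_log_or != 0.0:
        sd = g_centered.std()
        z_g = g_centered / sd if sd > 0 else g_centered
        idx3 = profile["index_3"].to_numpy(dtype=float)
        unfavorable = np.nan_to_num((idx3 <= 1).astype(float), nan=0.0)
        eta = eta + config.interaction_log_or * z_g * unfavorable

    # prevalent at baseline
    alpha_prev = _solve_intercept(eta, config.baseline_prevalence)
    prevalent = rng.random(n) < special.expit(alpha_prev + eta)

    # incident during follow-up (drawn for everyone; prevalent individuals
    # are excluded from prospective analyses downstream)
    censor = rng.uniform(*config.censor_year_range, size=n)
    if config.baseline_hazard > 0:
        rate = config.baseline_hazard * np.exp(eta)
        onset = rng.exponential(1.0, size=n) / rate
    else:
        onset = np.full(n, np.inf)
    event = (~prevalent) & (onset <= censor)
    time = np.where(prevalent, 0.0, np.minimum(onset, censor))

    status = prevalent | event
    onset_period = np.where(prevalent, "baseline", np.where(event, "follow-up", ""))

    cohort = pd.DataFrame(
        {
            "iid": panel.individual_ids,
            "status": status.astype(int),
            "onset_period": onset_period,
            "time": time,
            "event": event.astype(int),
            "age": age,
            "sex": np.where(female, "female", "male"),
            "tdi": tdi,
            "batch": batch,
            "center": center,
            **{f"pc{i+1}": pcs[:, i] for i in range(10)},
        }
    )
    cohort = pd.concat([cohort, lifestyle.reset_index(drop=True)], axis=1)
    cohort.attrs["seed"] = config.seed
    cohort.attrs["alpha_prevalent"] = alpha_prev
    return cohort


@dataclass
class SimBundle:
    """All simulated inputs for one pipeline run."""

    config: SimulationConfig
    panel: GenotypePanel
    truth: GroundTruth
    summary_stats: pd.DataFrame
    cohort: pd.DataFrame


def simulate_all(config: SimulationConfig) -> SimBundle:
    """Run all four generators in order with one master seed."""
    panel = simulate_panel(config)
    truth = make_ground_truth(config)
    stats_df = simulate_summary_stats(config, truth)
    lifestyle = simulate_lifestyle(config, config.n_individuals)
    cohort = simulate_disease(panel, lifestyle, truth, config)
    return SimBundle(config, panel, truth, stats_df, cohort)
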