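"""End-to-end study orchestration: split, PRS selection, joint analyses.

Mirrors the published study design: a random 20% training set is used only
to pick the best-performing PRS p-value threshold (strongest covariate-
adjusted association, AUC as tie-break); every substantive analysis runs
on the held-out 80%: per-SD and risk-group associations (logistic OR for
the case-control design, Cox HR for the prospective design with baseline
cases excluded), lifestyle associations, the 3x3 genetic-risk x lifestyle
joint grid, additive interaction (RERI/AP), trend tests, a restricted
cubic spline dose-response fit, and the SNP-by-lifestyle interaction scan.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyCellError, InputError
from .lifestyle import CATEGORY_ORDER, INDEX_FACTORS, LifestyleConfig, derive_profile
from .panel import GenotypePanel, PRSVector
from .prs_scoring import assign_deciles, assign_risk_groups, score, standardize
from .risk_models import (
    RegressionFit,
    auc,
    cochran_armitage_trend,
    fit_cox,
    fit_logistic,
    rcs_basis,
    reri_ap,
    snp_lifestyle_scan,
)
from .synthetic_cohort import SimulationConfig, simulate_all
from .variant_selection import (
    ClumpConfig,
    apply_thresholds,
    clump,
    harmonize_weights,
    maf_hwe_missingness_filter,
    mhc_mask,
)

logger = logging.getLogger(__name__)

RISK_ORDER = ("low", "intermediate", "high")


# ----------------------------------------------------------------------
# cohort splitting
# ----------------------------------------------------------------------

@dataclass
class SplitAssignment:
    """Train/test membership; train size is floor(fraction x N)."""

    train_ids: np.ndarray
    test_ids: np.ndarray
    fraction: float
    seed: int


def split_cohort(ids, fraction: float = 0.2, seed: int = 1234) -> SplitAssignment:
    """Simple random sample without replacement into train/test.

    Uses numpy's PCG64 generator seeded with ``seed``; the training set has
    exactly ``floor(fraction * N)`` members and the two sets partition the
    input ids.
    """
    if not (0.0 < fraction < 1.0):
        raise ConfigurationError("fraction must be in (0,1)")
    ids = np.asarray(ids)
    n_train = math.floor(fraction * len(ids))
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(ids), size=n_train, replace=False)
    mask = np.zeros(len(ids), dtype=bool)
    mask[pick] = True
    return SplitAssignment(
        train_ids=ids[mask], test_ids=ids[~mask], fraction=fraction, seed=seed
    )


# ----------------------------------------------------------------------
# covariate design
# ----------------------------------------------------------------------

def build_covariates(cohort: pd.DataFrame, n_pcs: int = 10) -> pd.DataFrame:
    """Numeric design block: age, sex, deprivation, batch/center dummies, PCs."""
    out = pd.DataFrame(index=cohort.index)
    out["age"] = cohort["age"].astype(float)
    out["sex_female"] = (cohort["sex"] == "female").astype(float)
    out["tdi"] = cohort["tdi"].astype(float)
    for col in ("batch", "center"):
        if col in cohort.columns:
            dummies = pd.get_dummies(cohort[col], prefix=col, drop_first=True, dtype=float)
            out = pd.concat([out, dummies], axis=1)
    for i in range(1, n_pcs + 1):
        c = f"pc{i}"
        if c in cohort.columns:
            out[c] = cohort[c].astype(float)
    return out


# ----------------------------------------------------------------------
# PRS threshold selection
# ----------------------------------------------------------------------

def select_best_prs(
    outcome,
    candidates: dict[str, np.ndarray],
    covariates: pd.DataFrame | None = None,
) -> tuple[str, pd.DataFrame]:
    """Pick the best threshold on the training set.

    Each candidate's standardized score is fitted in a covariate-adjusted
    logistic model; the primary criterion is the smallest score-term
    p-value, ties broken by the larger AUC of the score+covariates model,
    remaining ties by candidate order.  The full per-threshold table is
    returned so the choice is auditable; if no candidate is significant the
    best one is still selected, with a warning.
    """
    if len(candidates) < 2:
        raise InputError("threshold selection needs at least 2 candidates")
    y = np.asarray(outcome, dtype=float)
    rows = []
    best_label = None
    best_key: tuple[float, float] | None = None
    for label, z in candidates.items():
        X = covariates.copy() if covariates is not None else pd.DataFrame(index=range(len(y)))
        X = X.reset_index(drop=True)
        X["prs"] = np.asarray(z, dtype=float)
        fit = fit_logistic(X, y)
        tab = fit.table().set_index("term")
        p = float(tab.at["prs", "p"])
        from scipy.special import expit

        design = np.column_stack([np.ones(len(y)), X.to_numpy(float)])
        # predicted probabilities of the score+covariates model
        prob = expit(design @ fit.coef) if len(fit.coef) == design.shape[1] else None
        if prob is None:  # aliased columns were dropped; recompute via terms
            cols = [c for c in fit.terms if c != "const"]
            prob = expit(fit.coef[0] + X[cols].to_numpy(float) @ fit.coef[1:])
        a = auc(prob, y)
        rows.append(
            {
                "threshold": label,
                "n_variants": np.nan,
                "or_per_sd": float(tab.at["prs", "estimate"]),
                "ci_low": float(tab.at["prs", "ci_low"]),
                "ci_high": float(tab.at["prs", "ci_high"]),
                "p": p,
                "auc": a,
            }
        )
        key = (p, -a)
        if best_key is None or key < best_key:
            best_key = key
            best_label = label
    table = pd.DataFrame(rows)
    if (table["p"] >= 0.05).all():
        warnings.warn("no candidate PRS reached nominal significance", stacklevel=2)
    return best_label, table


# ----------------------------------------------------------------------
# joint genetic-risk x lifestyle grid
# ----------------------------------------------------------------------

@dataclass
class JointRiskGrid:
    """3x3 joint-risk estimates vs the low-genetic/favorable reference cell."""

    table: pd.DataFrame
    trend: pd.DataFrame
    logistic_fit: RegressionFit
    cox_fit: RegressionFit | None


def joint_analysis(
    cohort: pd.DataFrame,
    genetic_group,
    lifestyle_category,
    covariates: pd.DataFrame,
    include_cox: bool = True,
    reri_high_unfavorable: bool = False,
) -> JointRiskGrid:
    """Joint 9-cell analysis with indicator coding against the reference.

    Logistic ORs use the whole (case-control) sample; Cox HRs use the
    prospective subset with baseline-prevalent cases excluded.  Also emits
    Cochran-Armitage trend tests across lifestyle categories within each
    genetic stratum.
    """
    g = pd.Categorical(genetic_group, categories=RISK_ORDER, ordered=True)
    l = pd.Categorical(lifestyle_category, categories=CATEGORY_ORDER, ordered=True)
    ok = ~(pd.isna(g) | pd.isna(l))
    df = cohort.loc[np.asarray(ok)].reset_index(drop=True)
    g = g[np.asarray(ok)]
    l = l[np.asarray(ok)]
    cov = covariates.loc[np.asarray(ok)].reset_index(drop=True)

    cells = [(gg, ll) for gg in RISK_ORDER for ll in reversed(CATEGORY_ORDER)]
    cell_of = pd.Series(list(zip(g, l)))
    dummies = pd.DataFrame(index=df.index)
    for gg, ll in cells:
        if (gg, ll) == ("low", "favorable"):
            continue
        dummies[f"{gg}|{ll}"] = (cell_of == (gg, ll)).astype(float)

    counts = cell_of.value_counts()
    for cell in cells:
        if counts.get(cell, 0) == 0:
            raise EmptyCellError(f"joint grid cell {cell[0]}/{cell[1]} is empty")

    y = df["status"].to_numpy(float)
    X = pd.concat([dummies, cov], axis=1)
    logit_fit = fit_logistic(X, y)
    logit_tab = logit_fit.table().set_index("term")

    cox_fit = None
    cox_tab = None
    if include_cox:
        prosp = (df["onset_period"] != "baseline") & (df["time"] > 0)
        assert not (
            (df.loc[prosp, "onset_period"] == "baseline").any()
        ), "prospective subset contains baseline-prevalent cases"
        cox_fit = fit_cox(
            df.loc[prosp, "time"],
            df.loc[prosp, "event"],
            X.loc[np.asarray(prosp)],
        )
        cox_tab = cox_fit.table().set_index("term")

    rows = []
    for gg, ll in cells:
        name = f"{gg}|{ll}"
        sel = cell_of == (gg, ll)
        row = {
            "genetic_risk": gg,
            "lifestyle": ll,
            "n": int(sel.sum()),
            "cases": int(df.loc[np.asarray(sel), "status"].sum()),
        }
        if (gg, ll) == ("low", "favorable"):
            row.update({"or": 1.0, "or_low": np.nan, "or_high": np.nan, "or_p": np.nan})
            if cox_tab is not None:
                row.update({"hr": 1.0, "hr_low": np.nan, "hr_high": np.nan, "hr_p": np.nan})
        else:
            row.update(
                {
                    "or": float(logit_tab.at[name, "estimate"]),
                    "or_low": float(logit_tab.at[name, "ci_low"]),
                    "or_high": float(logit_tab.at[name, "ci_high"]),
                    "or_p": float(logit_tab.at[name, "p"]),
                }
            )
            if cox_tab is not None:
                row.update(
                    {
                        "hr": float(cox_tab.at[name, "estimate"]),
                        "hr_low": float(cox_tab.at[name, "ci_low"]),
                        "hr_high": float(cox_tab.at[name, "ci_high"]),
                        "hr_p": float(cox_tab.at[name, "p"]),
                    }
                )
        rows.append(row)
    table = pd.DataFrame(rows)

    trend_rows = []
    for gg in RISK_ORDER:
        cases, controls = [], []
        for ll in reversed(CATEGORY_ORDER):  # favorable -> unfavorable
            sel = np.asarray(cell_of == (gg, ll))
            cases.append(df.loc[sel, "status"].sum())
            controls.append((1 - df.loc[sel, "status"]).sum())
        z, p = cochran_armitage_trend(cases, controls)
        trend_rows.append({"genetic_risk": gg, "trend_z": z, "trend_p": p})
    trend = pd.DataFrame(trend_rows)

    return JointRiskGrid(table=table, trend=trend, logistic_fit=logit_fit, cox_fit=cox_fit)


# ----------------------------------------------------------------------
# Table-1-style summary
# ----------------------------------------------------------------------

#: summary rows as (name, numerator key, denominator key)
_SUMMARY_ROWS = (
    ("case_percent", "cases", "total"),
    ("incident_case_percent", "followup_onset", "total"),
    ("baseline_onset_share", "baseline_onset", "cases"),
    ("followup_onset_share", "followup_onset", "cases"),
    ("female_case_share", "female_cases", "cases"),
)


@dataclass
class CohortSummary:
    """Counts with percentages recomputed (never stored) from them."""

    counts: dict[str, int] = field(default_factory=dict)

    @staticmethod
    def _pct(num: int, den: int) -> float:
        if den == 0:
            warnings.warn("degenerate summary: zero denominator", stacklevel=3)
            return 0.0
        return round(100.0 * num / den, 1)

    def percent(self, name: str) -> float:
        for row, num, den in _SUMMARY_ROWS:
            if row == name:
                if self.counts.get(den, 0) == 0 and den == "cases":
                    warnings.warn("degenerate summary: zero cases", stacklevel=2)
                    return 0.0
                return self._pct(self.counts.get(num, 0), self.counts.get(den, 0))
        raise KeyError(name)

    def table(self) -> pd.DataFrame:
        rows = []
        for row, num, den in _SUMMARY_ROWS:
            rows.append(
                {
                    "row": row,
                    "count": self.counts.get(num, 0),
                    "denominator": self.counts.get(den, 0),
                    "percent": self.percent(row),
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_counts(cls, **counts: int) -> "CohortSummary":
        return cls(counts=dict(counts))


def cohort_summary(cohort: pd.DataFrame) -> CohortSummary:
    """Table-1-style counts from a cohort table.

    Denominators follow the published layout: case percentage over the whole
    cohort, onset-period and sex shares within cases.
    """
    if len(cohort) == 0:
        raise InputError("empty cohort")
    cases = cohort["status"] == 1
    counts = {
        "total": int(len(cohort)),
        "cases": int(cases.sum()),
        "controls": int((~cases).sum()),
        "baseline_onset": int((cohort["onset_period"] == "baseline").sum()),
        "followup_onset": int((cohort["onset_period"] == "follow-up").sum()),
        "female_cases": int((cases & (cohort["sex"] == "female")).sum()),
    }
    return CohortSummary(counts=counts)


# ----------------------------------------------------------------------
# full pipeline
# ----------------------------------------------------------------------

@dataclass
class PipelineConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    clump: ClumpConfig = field(default_factory=ClumpConfig)
    lifestyle: LifestyleConfig = field(default_factory=LifestyleConfig)
    train_fraction: float = 0.2
    split_seed: int = 1234
    maf_min: float = 0.02
    hwe_p_min: float = 1e-7
    call_rate_min: float = 0.95
    rcs_knots: int = 4
    n_pcs: int = 10
    #: population used for quartile/decile cuts: "all" (default, matching the
    #: standardisation convention) or "test"
    group_population: str = "all"

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "sim": {**self.sim.__dict__, "maf_range": list(self.sim.maf_range),
                        "censor_year_range": list(self.sim.censor_year_range),
                        "lifestyle_prevalences": dict(self.sim.lifestyle_prevalences),
                        "lifestyle_log_or": dict(self.sim.lifestyle_log_or),
                        "covariate_log_or": dict(self.sim.covariate_log_or)},
                "clump": {**self.clump.__dict__, "p_cutoffs": list(self.clump.p_cutoffs)},
                "train_fraction": self.train_fraction,
                "split_seed": self.split_seed,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    summary: CohortSummary
    selection_table: pd.DataFrame
    selected_threshold: str
    prs_assoc: pd.DataFrame
    lifestyle_assoc: pd.DataFrame
    joint: JointRiskGrid
    interaction: pd.DataFrame
    decile_table: pd.DataFrame
    spline_table: pd.DataFrame
    scan: pd.DataFrame
    log_lines: list[str]
    scores: pd.DataFrame


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Simulate -> QC -> clump -> threshold -> score -> select -> analyse."""
    cfg = config or PipelineConfig()
    log: list[str] = []

    def note(msg: str) -> None:
        log.append(msg)
        logger.info(msg)

    note(f"seed={cfg.sim.seed} config_hash={cfg.config_hash()}")

    bundle = simulate_all(cfg.sim)
    cohort = bundle.cohort
    note(f"simulated n={len(cohort)} individuals, m={bundle.panel.n_variants} variants")

    panel = maf_hwe_missingness_filter(
        bundle.panel, cfg.maf_min, cfg.hwe_p_min, cfg.call_rate_min
    )
    note(f"QC retained {panel.n_variants}/{bundle.panel.n_variants} variants")

    stats = harmonize_weights(bundle.summary_stats, panel)
    index_ids = clump(stats, panel, cfg.clump)
    clumped = stats[stats["SNP"].isin(index_ids)].reset_index(drop=True)
    note(f"clumping kept {len(clumped)} index variants")

    grids = apply_thresholds(clumped, cfg.clump)

    candidates: dict[str, PRSVector] = {}
    weights_by_label: dict[str, pd.DataFrame] = {}
    for cutoff, label in zip(cfg.clump.p_cutoffs, cfg.clump.labels()):
        ids = grids[cutoff]
        if not ids:
            note(f"threshold {label}: empty grid, skipped")
            continue
        w = clumped[clumped["SNP"].isin(ids)]
        prs = standardize(score(panel, w, threshold_label=label))
        candidates[label] = prs
        weights_by_label[label] = w
        note(f"threshold {label}: {len(w)} variants")
    if len(candidates) < 2:
        raise InputError("fewer than 2 non-empty PRS candidates")

    split = split_cohort(cohort["iid"].to_numpy(), cfg.train_fraction, cfg.split_seed)
    in_train = np.isin(cohort["iid"].to_numpy(), split.train_ids)
    note(f"split: train={int(in_train.sum())} test={int((~in_train).sum())}")

    covs = build_covariates(cohort, cfg.n_pcs)
    y = cohort["status"].to_numpy(float)

    train_candidates = {
        lab: prs.standardized[in_train] for lab, prs in candidates.items()
    }
    best_label, sel_table = select_best_prs(
        y[in_train], train_candidates, covs.loc[in_train]
    )
    sel_table["n_variants"] = [
        len(weights_by_label[lab]) for lab in sel_table["threshold"]
    ]
    note(f"selected threshold {best_label}")
    best = candidates[best_label]
    best_w = weights_by_label[best_label]

    # genetic risk groups / deciles (population per config)
    pop_mask = np.ones(len(cohort), bool) if cfg.group_population == "all" else ~in_train
    groups = np.full(len(cohort), None, dtype=object)
    groups_pop = assign_risk_groups(best.standardized[pop_mask])
    groups[pop_mask] = groups_pop
    if not pop_mask.all():
        # assign remaining individuals against the same cuts
        q25, q75 = np.quantile(best.standardized[pop_mask], [0.25, 0.75])
        rest = ~pop_mask
        rg = np.full(int(rest.sum()), "intermediate", dtype=object)
        rg[best.standardized[rest] <= q25] = "low"
        rg[best.standardized[rest] > q75] = "high"
        groups[rest] = rg
    deciles = assign_deciles(best.standardized)

    profile = derive_profile(cohort, cfg.lifestyle)

    test = ~in_train
    test_df = cohort.loc[test].reset_index(drop=True)
    test_cov = covs.loc[test].reset_index(drop=True)
    y_test = y[test]

    # per-SD association, full PRS and non-MHC PRS
    prs_rows = []
    nonmhc_w = best_w.loc[~mhc_mask(best_w)].reset_index(drop=True)
    for name, w in (("PRS", best_w), ("PRS_non-MHC", nonmhc_w)):
        if len(w) == 0:
            continue
        z_all = standardize(score(panel, w, threshold_label=name)).standardized
        X = test_cov.copy()
        X["prs"] = z_all[test]
        fit = fit_logistic(X, y_test)
        t = fit.table().set_index("term")
        prosp = (test_df["onset_period"] != "baseline") & (test_df["time"] > 0)
        coxf = fit_cox(
            test_df.loc[prosp, "time"], test_df.loc[prosp, "event"], X.loc[np.asarray(prosp)]
        )
        ct = coxf.table().set_index("term")
        pred = t.loc["prs"]
        prs_rows.append(
            {
                "score": name,
                "n_variants": len(w),
                "or_per_sd": pred["estimate"],
                "or_low": pred["ci_low"],
                "or_high": pred["ci_high"],
                "or_p": pred["p"],
                "hr_per_sd": ct.at["prs", "estimate"],
                "hr_low": ct.at["prs", "ci_low"],
                "hr_high": ct.at["prs", "ci_high"],
                "hr_p": ct.at["prs", "p"],
                "auc": auc(z_all[test], y_test),
            }
        )
    prs_assoc = pd.DataFrame(prs_rows)

    # lifestyle factor associations on the test set
    lf_rows = []
    for factor in profile.columns[:5]:
        flag = profile[factor].to_numpy(float)[test]
        X = test_cov.copy()
        X["factor"] = flag
        fit = fit_logistic(X, y_test)
        t = fit.table().set_index("term").loc["factor"]
        lf_rows.append(
            {
                "factor": factor,
                "or": t["estimate"],
                "ci_low": t["ci_low"],
                "ci_high": t["ci_high"],
                "p": t["p"],
            }
        )
    lifestyle_assoc = pd.DataFrame(lf_rows)

    # joint 3x3 grid on the test set
    joint = joint_analysis(
        test_df,
        groups[test],
        profile["category"].to_numpy()[test],
        test_cov,
    )

    # additive interaction: high genetic risk x unfavorable lifestyle
    high = (groups[test] == "high").astype(float)
    idx3 = profile["index_3"].to_numpy(float)[test]
    unfav = np.where(np.isnan(idx3), np.nan, (idx3 <= 1).astype(float))
    ok = ~np.isnan(unfav)
    Xi = test_cov.loc[ok].reset_index(drop=True)
    gi, li = high[ok], unfav[ok]
    Xi["g_only"] = gi * (1 - li)
    Xi["l_only"] = li * (1 - gi)
    Xi["g_and_l"] = gi * li
    int_fit = fit_logistic(Xi, y_test[ok])
    est = reri_ap(int_fit, "g_only", "l_only", "g_and_l")
    interaction = pd.DataFrame(
        [
            {
                "exposure": "high_genetic_x_unfavorable",
                "scale": "odds-ratio",
                "reri": est.reri,
                "reri_low": est.reri_ci[0],
                "reri_high": est.reri_ci[1],
                "ap": est.ap,
                "ap_low": est.ap_ci[0],
                "ap_high": est.ap_ci[1],
                "method": est.method,
            }
        ]
    )

    # decile gradient + trend
    dec_test = deciles[test]
    dec_rows = []
    cases_per, ctrls_per = [], []
    for d in range(1, 11):
        sel = dec_test == d
        dec_rows.append(
            {"decile": d, "n": int(sel.sum()), "cases": int(y_test[sel].sum())}
        )
        cases_per.append(int(y_test[sel].sum()))
        ctrls_per.append(int((1 - y_test[sel]).sum()))
    z, p = cochran_armitage_trend(cases_per, ctrls_per)
    decile_table = pd.DataFrame(dec_rows)
    decile_table.attrs["trend_z"] = z
    decile_table.attrs["trend_p"] = p

    # restricted cubic spline dose-response on the test set
    basis = rcs_basis(best.standardized[test], n_knots=cfg.rcs_knots)
    Xs = test_cov.copy()
    for i in range(basis.basis.shape[1]):
        Xs[f"rcs{i+1}"] = basis.basis[:, i]
    sp_fit = fit_logistic(Xs, y_test)
    spt = sp_fit.table()
    spline_table = spt[spt["term"].str.startswith("rcs")].reset_index(drop=True)
    spline_table.attrs["knots"] = basis.knots.tolist()

    # SNP x lifestyle scan over the selected PRS variants
    scan = _scan_on_test(panel, best_w, test, unfav, y_test, test_cov)

    summary = cohort_summary(cohort)
    note(
        f"cases={summary.counts['cases']} "
        f"({summary.percent('case_percent')}%), "
        f"incident={summary.counts['followup_onset']}"
    )

    scores_frame = pd.DataFrame(
        {
            "IID": cohort["iid"],
            "RAW": best.raw,
            "Z": best.standardized,
            "GROUP": groups,
            "DECILE": deciles,
            "SET": np.where(in_train, "train", "test"),
        }
    )

    return PipelineResult(
        config=cfg,
        summary=summary,
        selection_table=sel_table,
        selected_threshold=best_label,
        prs_assoc=prs_assoc,
        lifestyle_assoc=lifestyle_assoc,
        joint=joint,
        interaction=interaction,
        decile_table=decile_table,
        spline_table=spline_table,
        scan=scan,
        log_lines=log,
        scores=scores_frame,
    )


def _scan_on_test(panel, weights, test_mask, unfav, y_test, test_cov):
    """Interaction scan restricted to test-set rows with a resolved lifestyle."""
    sub = panel.subset_variants(weights["SNP"])
    sub_test = GenotypePanel(
        individual_ids=sub.individual_ids[test_mask],
        variants=sub.variants,
        dosages=sub.dosages[test_mask],
    )
    ok = ~np.isnan(unfav)
    sub_ok = GenotypePanel(
        individual_ids=sub_test.individual_ids[ok],
        variants=sub_test.variants,
        dosages=sub_test.dosages[ok],
    )
    return snp_lifestyle_scan(
        sub_ok, unfav[ok], y_test[ok], test_cov.loc[ok].reset_index(drop=True)
    )


def write_report(result: PipelineResult, outdir) -> dict[str, Path]:
    """Write every result table plus the run log; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = result.config.sim.seed
    paths: dict[str, Path] = {}

    def w(name: str, df: pd.DataFrame) -> None:
        p = outdir / f"{name}.tsv"
        with open(p, "w") as fh:
            fh.write(f"# prsjoint report seed={seed} hash={result.config.config_hash()}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        paths[name] = p

    w("cohort_summary", result.summary.table())
    w("prs_selection", result.selection_table)
    w("prs_assoc", result.prs_assoc)
    w("lifestyle_assoc", result.lifestyle_assoc)
    w("joint_grid", result.joint.table)
    w("joint_trend", result.joint.trend)
    w("additive_interaction", result.interaction)
    w("decile_gradient", result.decile_table)
    w("spline_fit", result.spline_table)
    w("snp_lifestyle_scan", result.scan)
    w("scores", result.scores)
    logp = outdir / "run_log.txt"
    logp.write_text("\n".join(result.log_lines) + "\n")
    paths["run_log"] = logp
    return paths
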