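"""Healthy-lifestyle indicators and the three-factor lifestyle index.

Five binary indicators are derived from raw questionnaire fields:

* **no smoking** — never-smokers, or former smokers who quit >= 30 years ago
  (the published definition's wording is garbled; this is the reading used
  throughout, with a "no current smoking" variant available for sensitivity
  analysis);
* **regular physical activity** — >= 75 min/week vigorous, or >= 150 min/week
  moderate, or an equivalent combination (2 x vigorous + moderate >= 150, the
  WHO convention), or both intensities practised on >= 5 days/week;
* **moderate BMI** — BMI in [18.5, 24) by default (half-open; a closed upper
  bound and the 18.5-25 sensitivity window are configurable);
* **no alcohol consumption** — everyone except current drinkers who drink
  more often than once per month;
* **healthy diet** — at least k of 6 food groups on the healthy side of the
  cohort median (more fruit/vegetables/whole grains/fish, less red and
  processed meat); k = 4 by default.

The lifestyle *index* counts the three indicators found protective in the
cohort this package models (no smoking, regular activity, moderate BMI):
0-1 of them = unfavorable, 2 = moderate, 3 = favorable.

Missing raw fields propagate to missing flags (NaN); individuals with any
missing index component are excluded from index-based analyses by callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: index factors, in reporting order
INDEX_FACTORS = ("no_smoking", "regular_activity", "moderate_bmi")
ALL_FACTORS = INDEX_FACTORS + ("no_alcohol", "healthy_diet")

CATEGORY_ORDER = ("unfavorable", "moderate", "favorable")

DIET_HEALTHY_HIGH = ("fruit", "vegetables", "whole_grains", "fish")
DIET_HEALTHY_LOW = ("red_meat", "processed_meat")


@dataclass
class LifestyleConfig:
    """Conventions for deriving the indicators (all documented defaults)."""

    bmi_low: float = 18.5
    bmi_high: float = 24.0
    bmi_closed_upper: bool = False
    quit_years_nonsmoker: float = 30.0
    #: "nonsmoker" = never or long-quit former; "no_current" = never or former
    smoking_definition: str = "nonsmoker"
    diet_k_of_6: int = 4
    #: drink_frequency labels that exceed once per month
    alcohol_exceeds_monthly: tuple[str, ...] = ("more than monthly", "weekly", "daily")
    activity_vigorous_min: float = 75.0
    activity_moderate_min: float = 150.0
    activity_days_min: int = 5
    diet_medians: dict | None = field(default=None)


def _as_array(x) -> np.ndarray:
    return np.asarray(pd.Series(x))


def derive_no_smoking(
    smoking_status, years_since_quit, config: LifestyleConfig | None = None
) -> np.ndarray:
    """1.0 for non-smokers, 0.0 for smokers, NaN when undeterminable.

    Never-smokers qualify; former smokers qualify once quit for at least 30
    years (missing quit years -> NaN); current smokers never qualify.  Under
    the "no_current" sensitivity definition all former smokers qualify.
    """
    cfg = config or LifestyleConfig()
    status = _as_array(smoking_status).astype(object)
    quit = np.asarray(pd.to_numeric(pd.Series(years_since_quit)), dtype=float)
    out = np.full(status.shape, np.nan)
    out[status == "never"] = 1.0
    out[status == "current"] = 0.0
    former = status == "former"
    if cfg.smoking_definition == "no_current":
        out[former] = 1.0
    else:
        known = former & ~np.isnan(quit)
        out[known] = (quit[known] >= cfg.quit_years_nonsmoker).astype(float)
    return out


def derive_regular_activity(
    vigorous_min_wk, moderate_min_wk, active_days_wk, config: LifestyleConfig | None = None
) -> np.ndarray:
    """Weekly-activity indicator per the 75/150-minute rule.

    True if vigorous >= 75 min/wk, or moderate >= 150 min/wk, or the
    equivalent combination 2*vigorous + moderate >= 150, or both intensities
    reported on at least 5 active days per week.
    """
    cfg = config or LifestyleConfig()
    vig = np.asarray(vigorous_min_wk, dtype=float)
    mod = np.asarray(moderate_min_wk, dtype=float)
    days = np.asarray(active_days_wk, dtype=float)
    ok = (
        (vig >= cfg.activity_vigorous_min)
        | (mod >= cfg.activity_moderate_min)
        | (2.0 * vig + mod >= cfg.activity_moderate_min)
        | ((vig > 0) & (mod > 0) & (days >= cfg.activity_days_min))
    )
    out = ok.astype(float)
    out[np.isnan(vig) & np.isnan(mod)] = np.nan
    return out


def derive_moderate_bmi(bmi, config: LifestyleConfig | None = None) -> np.ndarray:
    """BMI-in-window indicator; half-open [low, high) unless configured closed."""
    cfg = config or LifestyleConfig()
    b = np.asarray(bmi, dtype=float)
    upper = b <= cfg.bmi_high if cfg.bmi_closed_upper else b < cfg.bmi_high
    out = ((b >= cfg.bmi_low) & upper).astype(float)
    out[np.isnan(b)] = np.nan
    return out


def derive_no_alcohol(
    drink_frequency, drinker_status, config: LifestyleConfig | None = None
) -> np.ndarray:
    """True unless a current drinker drinking more often than once a month."""
    cfg = config or LifestyleConfig()
    freq = _as_array(drink_frequency).astype(object)
    status = _as_array(drinker_status).astype(object)
    drinks = np.isin(freq.astype(str), cfg.alcohol_exceeds_monthly) & (status == "current")
    out = (~drinks).astype(float)
    out[pd.isna(freq) | pd.isna(status)] = np.nan
    return out


def derive_healthy_diet(
    diet_components: pd.DataFrame, config: LifestyleConfig | None = None
) -> np.ndarray:
    """k-of-6 rule against cohort medians (configurable reference medians).

    A component counts as healthy when at or beyond the median in its
    beneficial direction; missing components count as unhealthy, and rows
    with every component missing yield NaN.
    """
    cfg = config or LifestyleConfig()
    cols = list(DIET_HEALTHY_HIGH + DIET_HEALTHY_LOW)
    df = diet_components[cols]
    medians = cfg.diet_medians or {c: float(df[c].median()) for c in cols}
    healthy = np.zeros((len(df), len(cols)))
    for j, c in enumerate(cols):
        v = df[c].to_numpy(dtype=float)
        if c in DIET_HEALTHY_HIGH:
            healthy[:, j] = v >= medians[c]
        else:
            healthy[:, j] = v <= medians[c]
        healthy[np.isnan(v), j] = 0.0
    out = (healthy.sum(axis=1) >= cfg.diet_k_of_6).astype(float)
    out[df.isna().all(axis=1).to_numpy()] = np.nan
    return out


def lifestyle_index(no_smoking, regular_activity, moderate_bmi):
    """Three-factor index and category.

    Returns ``(index_3, category)`` arrays; the index is the number of
    healthy indicators (0-3, NaN if any flag is missing) and the category is
    unfavorable (0-1), moderate (2) or favorable (3).
    """
    flags = np.column_stack(
        [
            np.asarray(no_smoking, dtype=float),
            np.asarray(regular_activity, dtype=float),
            np.asarray(moderate_bmi, dtype=float),
        ]
    )
    idx = flags.sum(axis=1)
    idx[np.isnan(flags).any(axis=1)] = np.nan
    category = np.full(idx.shape, None, dtype=object)
    category[idx <= 1] = "unfavorable"
    category[idx == 2] = "moderate"
    category[idx == 3] = "favorable"
    return idx, category


def derive_profile(raw: pd.DataFrame, config: LifestyleConfig | None = None) -> pd.DataFrame:
    """Derive all five indicators plus the 3-factor index from raw fields."""
    cfg = config or LifestyleConfig()
    out = pd.DataFrame(index=raw.index)
    out["no_smoking"] = derive_no_smoking(
        raw["smoking_status"], raw["years_since_quit"], cfg
    )
    out["regular_activity"] = derive_regular_activity(
        raw["vigorous_min_wk"], raw["moderate_min_wk"], raw["active_days_wk"], cfg
    )
    out["moderate_bmi"] = derive_moderate_bmi(raw["bmi"], cfg)
    out["no_alcohol"] = derive_no_alcohol(
        raw["drink_frequency"], raw["drinker_status"], cfg
    )
    diet_cols = list(DIET_HEALTHY_HIGH + DIET_HEALTHY_LOW)
    if set(diet_cols).issubset(raw.columns):
        out["healthy_diet"] = derive_healthy_diet(raw[diet_cols], cfg)
    else:
        out["healthy_diet"] = np.nan
    idx, cat = lifestyle_index(
        out["no_smoking"], out["regular_activity"], out["moderate_bmi"]
    )
    out["index_3"] = idx
    out["category"] = cat
    return out
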