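"""Regression models and epidemiological statistics for joint-risk analysis.

Wraps maximum-likelihood logistic regression (statsmodels, Newton/IRLS) and
Cox proportional hazards with Efron tie handling (lifelines) behind one
:class:`RegressionFit` surface, and implements the statistics consumed by
the analysis: Mann-Whitney AUC, restricted cubic spline bases, the
Cochran-Armitage trend test, additive interaction (RERI and AP with
delta-method or parametric-bootstrap CIs), and the per-SNP
lifestyle-interaction scan.

All confidence intervals are two-sided 95% Wald intervals on the log
scale, reported as exponentiated OR/HR bounds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    AliasedColumnWarning,
    DivergenceError,
    InputError,
    NoEventsError,
    SeparationError,
)
from .panel import GenotypePanel

logger = logging.getLogger(__name__)

Z975 = float(sps.norm.ppf(0.975))


@dataclass
class RegressionFit:
    """Coefficients, covariance and an exponentiated effect table."""

    terms: list[str]
    coef: np.ndarray
    cov: np.ndarray
    effect_scale: str  # "odds-ratio" or "hazard-ratio"
    n_used: int
    converged: bool
    llf: float | None = None

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def __getitem__(self, term: str) -> float:
        return float(self.coef[self.terms.index(term)])

    def se_of(self, term: str) -> float:
        return float(self.se[self.terms.index(term)])

    def p_of(self, term: str) -> float:
        i = self.terms.index(term)
        z = self.coef[i] / self.se[i]
        return float(2.0 * sps.norm.sf(abs(z)))

    def cov_block(self, names: list[str]) -> np.ndarray:
        idx = [self.terms.index(t) for t in names]
        return self.cov[np.ix_(idx, idx)]

    def table(self) -> pd.DataFrame:
        se = self.se
        est = np.exp(self.coef)
        lo = np.exp(self.coef - Z975 * se)
        hi = np.exp(self.coef + Z975 * se)
        z = np.divide(self.coef, se, out=np.zeros_like(se), where=se > 0)
        p = 2.0 * sps.norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "term": self.terms,
                "beta": self.coef,
                "se": se,
                "estimate": est,
                "ci_low": lo,
                "ci_high": hi,
                "p": p,
            }
        )


def _drop_aliased(X: pd.DataFrame) -> pd.DataFrame:
    """Drop rank-deficient columns (QR pivot test) with a warning."""
    arr = np.asarray(X, dtype=float)
    if arr.shape[1] == 0:
        return X
    r = np.linalg.qr(arr, mode="r")
    diag = np.abs(np.diag(r))
    scale = diag.max() if diag.max() > 0 else 1.0
    # QR without pivoting flags a dependent column by a tiny diagonal entry
    bad = [c for c, d in zip(X.columns, diag) if d < 1e-10 * scale]
    zerovar = [c for c in X.columns if c != "const" and np.nanstd(X[c].to_numpy(float)) == 0]
    bad = list(dict.fromkeys(bad + zerovar))
    if bad:
        warnings.warn(
            f"dropping aliased design columns: {bad}", AliasedColumnWarning, stacklevel=3
        )
        X = X.drop(columns=bad)
    return X


def _as_design(X, add_intercept: bool) -> pd.DataFrame:
    X = pd.DataFrame(X).copy()
    X = X.astype(float)
    if add_intercept and "const" not in X.columns:
        X.insert(0, "const", 1.0)
    return X


def fit_logistic(X, y, add_intercept: bool = True) -> RegressionFit:
    """Maximum-likelihood logistic regression (Newton iterations).

    Rows with missing values are dropped (complete-case); aliased columns
    are removed with a warning; perfect separation raises
    :class:`SeparationError`.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import (
        PerfectSeparationError,
        PerfectSeparationWarning,
    )

    X = _as_design(X, add_intercept)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(np.asarray(X)).any(axis=1) | np.isnan(y))
    dropped = int((~ok).sum())
    if dropped:
        logger.info("fit_logistic: %d incomplete rows excluded", dropped)
    X = X.loc[ok]
    y = y[ok]
    if len(np.unique(y)) < 2:
        raise InputError("outcome is constant")
    X = _drop_aliased(X)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            warnings.simplefilter("error", PerfectSeparationWarning)
            try:
                res = sm.Logit(y, X).fit(method="newton", maxiter=50, tol=1e-10, disp=0)
            except np.linalg.LinAlgError:
                # singular Hessian mid-iteration (sparse outcomes); quasi-Newton
                # is slower but tolerates it — separation is re-checked below
                res = sm.Logit(y, X).fit(method="lbfgs", maxiter=500, disp=0)
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    eta = np.asarray(X) @ res.params.to_numpy()
    if np.max(np.abs(eta)) > 30.0:
        raise SeparationError("fitted linear predictor diverged: perfect separation")

    return RegressionFit(
        terms=list(X.columns),
        coef=res.params.to_numpy(),
        cov=np.asarray(res.cov_params()),
        effect_scale="odds-ratio",
        n_used=int(len(y)),
        converged=bool(res.mle_retvals.get("converged", True)),
        llf=float(res.llf),
    )


def fit_cox(time, event, X, add_intercept: bool = False) -> RegressionFit:
    """Cox proportional-hazards fit (partial likelihood, Efron ties).

    ``time`` is follow-up from baseline to event/censoring; rows with
    missing values are dropped.  Zero-variance covariates raise an
    aliased/zero-information error; monotone-likelihood divergence raises
    :class:`DivergenceError`.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    X = pd.DataFrame(X).astype(float).reset_index(drop=True)
    if "const" in X.columns:
        X = X.drop(columns="const")  # absorbed by the baseline hazard
    df = X.copy()
    df["_T"] = np.asarray(time, dtype=float)
    df["_E"] = np.asarray(event, dtype=float)
    df = df.dropna()
    if (df["_T"] <= 0).any():
        raise InputError("event/censoring times must be positive")
    if df["_E"].sum() == 0:
        raise NoEventsError("no events observed")
    const_cols = [c for c in X.columns if df[c].nunique() <= 1]
    if const_cols:
        raise InputError(f"zero-information (constant) covariates: {const_cols}")

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df,
                duration_col="_T",
                event_col="_E",
                fit_options={"precision": 1e-10, "max_steps": 500},
            )
    except ConvergenceError as exc:
        raise DivergenceError(f"Cox partial likelihood diverged: {exc}") from exc

    return RegressionFit(
        terms=list(cph.params_.index),
        coef=cph.params_.to_numpy(),
        cov=cph.variance_matrix_.to_numpy(),
        effect_scale="hazard-ratio",
        n_used=int(df.shape[0]),
        converged=True,
        llf=float(cph.log_likelihood_),
    )


# ----------------------------------------------------------------------
# AUC
# ----------------------------------------------------------------------

def auc(scores, labels) -> float:
    """Mann-Whitney concordance: P(score_case > score_control) + 0.5 P(tie)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise InputError("AUC requires both cases and controls")
    ranks = sps.rankdata(s, method="average")
    rank_sum = float(ranks[y == 1].sum())
    return (rank_sum - n1 * (n1 + 1) / 2.0) / (n1 * n0)


# ----------------------------------------------------------------------
# restricted cubic splines
# ----------------------------------------------------------------------

#: default knot placement percentiles per knot count (Harrell convention)
RCS_PERCENTILES = {
    3: (10.0, 50.0, 90.0),
    4: (5.0, 35.0, 65.0, 95.0),
    5: (5.0, 27.5, 50.0, 72.5, 95.0),
}


@dataclass
class SplineBasis:
    """Natural (restricted) cubic spline basis: linear + k-2 restricted terms."""

    knots: np.ndarray
    basis: np.ndarray

    def transform(self, x) -> np.ndarray:
        return _rcs_matrix(np.asarray(x, dtype=float), self.knots)


def _rcs_matrix(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    k = len(knots)
    t = knots
    denom = (t[-1] - t[0]) ** 2

    def cub(u):
        return np.maximum(u, 0.0) ** 3

    cols = [x]
    for j in range(k - 2):
        term = (
            cub(x - t[j])
            - cub(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + cub(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        ) / denom
        cols.append(term)
    return np.column_stack(cols)


def rcs_basis(x, n_knots: int = 4, knots=None) -> SplineBasis:
    """Restricted cubic spline basis with percentile-placed knots.

    Knots default to the Harrell percentiles (5/35/65/95 for four knots).
    The basis is linear beyond the boundary knots and has ``knots - 1``
    columns (a linear term plus ``knots - 2`` restricted cubic terms).
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        if n_knots not in RCS_PERCENTILES:
            raise InputError("n_knots must be 3, 4 or 5")
        knots = np.percentile(x, RCS_PERCENTILES[n_knots])
    knots = np.asarray(knots, dtype=float)
    if not np.all(np.diff(knots) > 0):
        raise InputError("knots must be strictly increasing")
    return SplineBasis(knots=knots, basis=_rcs_matrix(x, knots))


# ----------------------------------------------------------------------
# Cochran-Armitage trend test
# ----------------------------------------------------------------------

def cochran_armitage_trend(cases, controls, scores=None) -> tuple[float, float]:
    """Linear-trend-in-proportions test across ordered exposure groups.

    Positive Z means the case proportion increases with the group score
    (default scores 0, 1, 2, ...).  Two groups reduce to the uncorrected
    2x2 chi-square.  Returns ``(Z, two-sided p)``.
    """
    r = np.asarray(cases, dtype=float)
    n = r + np.asarray(controls, dtype=float)
    if len(r) < 2:
        raise InputError("trend test requires at least 2 groups")
    if (n <= 0).any():
        raise InputError("empty group row")
    s = np.arange(len(r), dtype=float) if scores is None else np.asarray(scores, dtype=float)
    N = n.sum()
    R = r.sum()
    pbar = R / N
    T = float(r @ s - R * (n @ s) / N)
    var = pbar * (1 - pbar) * float(n @ s**2 - (n @ s) ** 2 / N)
    if var <= 0:
        raise InputError("degenerate trend variance")
    z = T / np.sqrt(var)
    return float(z), float(2.0 * sps.norm.sf(abs(z)))


# ----------------------------------------------------------------------
# additive interaction: RERI and AP
# ----------------------------------------------------------------------

@dataclass
class InteractionEstimate:
    """RERI and AP with 95% CIs from a jointly-fitted indicator model."""

    reri: float
    ap: float
    reri_ci: tuple[float, float]
    ap_ci: tuple[float, float]
    method: str


def reri_ap(
    fit: RegressionFit,
    term_g: str,
    term_l: str,
    term_gl: str,
    method: str = "delta",
    n_boot: int = 2000,
    seed: int = 0,
) -> InteractionEstimate:
    """Relative excess risk due to interaction and attributable proportion.

    The fit must code exposure as three indicators against the doubly
    unexposed reference: ``term_g`` (G only), ``term_l`` (L only) and
    ``term_gl`` (both).  Then ``RERI = e^b_gl - e^b_g - e^b_l + 1`` and
    ``AP = RERI / e^b_gl`` on whichever relative-risk scale the fit used
    (OR for logistic, HR for Cox).  CIs: delta method by default, or a
    parametric bootstrap drawing coefficients from their asymptotic MVN.
    """
    names = [term_g, term_l, term_gl]
    b = np.array([fit[t] for t in names])
    V = fit.cov_block(names)

    e1, e2, e3 = np.exp(b)
    reri = e3 - e1 - e2 + 1.0
    ap = reri / e3

    if method == "delta":
        g_reri = np.array([-e1, -e2, e3])
        se_reri = float(np.sqrt(g_reri @ V @ g_reri))
        g_ap = np.array(
            [
                -np.exp(b[0] - b[2]),
                -np.exp(b[1] - b[2]),
                np.exp(b[0] - b[2]) + np.exp(b[1] - b[2]) - np.exp(-b[2]),
            ]
        )
        se_ap = float(np.sqrt(g_ap @ V @ g_ap))
        reri_ci = (reri - Z975 * se_reri, reri + Z975 * se_reri)
        ap_ci = (ap - Z975 * se_ap, ap + Z975 * se_ap)
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(b, V, size=n_boot)
        ee = np.exp(draws)
        reri_b = ee[:, 2] - ee[:, 0] - ee[:, 1] + 1.0
        ap_b = reri_b / ee[:, 2]
        reri_ci = tuple(np.percentile(reri_b, [2.5, 97.5]))
        ap_ci = tuple(np.percentile(ap_b, [2.5, 97.5]))
    else:
        raise InputError(f"unknown CI method {method!r}")

    return InteractionEstimate(
        reri=float(reri), ap=float(ap), reri_ci=reri_ci, ap_ci=ap_ci, method=method
    )


# ----------------------------------------------------------------------
# per-SNP lifestyle interaction scan
# ----------------------------------------------------------------------

def snp_lifestyle_scan(
    panel: GenotypePanel,
    lifestyle_indicator,
    outcome,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Logistic dosage-by-lifestyle interaction scan, one row per variant.

    Fits ``outcome ~ dosage + lifestyle + dosage:lifestyle + covariates``
    per variant and reports the product-term Wald p.  Variants whose fit
    fails (separation, aliasing of the product term) are flagged with a
    missing p rather than raised.  Output is sorted by ascending p.
    """
    L = np.asarray(lifestyle_indicator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    base = (
        covariates.reset_index(drop=True).astype(float)
        if covariates is not None
        else pd.DataFrame(index=range(len(y)))
    )
    rows = []
    for j, vid in enumerate(panel.variants["id"]):
        dose = panel.dosages[:, j].astype(float)
        X = base.copy()
        X["dosage"] = dose
        X["lifestyle"] = L
        X["gxl"] = dose * L
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", AliasedColumnWarning)
                fit = fit_logistic(X, y)
            if "gxl" not in fit.terms:
                raise InputError("interaction term aliased")
            beta = fit["gxl"]
            se = fit.se_of("gxl")
            rows.append(
                {
                    "SNP": vid,
                    "beta_interaction": beta,
                    "se": se,
                    "or_interaction": float(np.exp(beta)),
                    "p": fit.p_of("gxl"),
                    "converged": fit.converged,
                }
            )
        except Exception as exc:  # degenerate designs are reported, not fatal
            logger.info("scan: variant %s failed (%s)", vid, exc)
            rows.append(
                {
                    "SNP": vid,
                    "beta_interaction": np.nan,
                    "se": np.nan,
                    "or_interaction": np.nan,
                    "p": np.nan,
                    "converged": False,
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values("p", na_position="last", kind="mergesort").reset_index(drop=True)
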