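"""Effectiveness estimation from patient-level cohort data.

The binary outcome is Favorable Immune Response (FIR): a follow-up CD4
lymphocyte count above 500 cells/µL, the lower limit of normal for Ugandan
populations.  Three estimators mirror a standard retrospective-cohort
workflow: per-arm and pooled FIR proportions, the crude odds ratio from the
2×2 arm-by-outcome table, and the adjusted odds ratio from a multivariate
logistic regression on the full covariate set (confounders retained
regardless of univariate significance, two-tailed α = 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "TwoByTwo",
    "LogisticFit",
    "two_by_two",
    "fir_proportions",
    "crude_or",
    "build_design",
    "fit_logistic",
    "fit_summary_frame",
]

Z_95 = 1.959964  # two-sided 95% normal quantile
SEPARATION_BOUND = 15.0  # |log-odds| beyond this flags quasi-separation


@dataclass(frozen=True)
class TwoByTwo:
    """Arm-by-FIR contingency table.

    ``a``/``b``: FIR and non-FIR counts in the PRP (intervention) arm;
    ``c``/``d``: the same in the SOC (comparator) arm.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n_prp(self) -> int:
        return self.a + self.b

    @property
    def n_soc(self) -> int:
        return self.c + self.d


@dataclass(frozen=True)
class LogisticFit:
    """Wald summary of a fitted logistic regression."""

    terms: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    odds_ratios: np.ndarray
    ci95: np.ndarray  # (n_terms, 2) on the OR scale
    p_values: np.ndarray
    n_used: int
    converged: bool

    def term(self, name: str) -> dict[str, float]:
        i = self.terms.index(name)
        return {
            "coef": float(self.coefficients[i]),
            "se": float(self.standard_errors[i]),
            "or": float(self.odds_ratios[i]),
            "ci_low": float(self.ci95[i, 0]),
            "ci_high": float(self.ci95[i, 1]),
            "p": float(self.p_values[i]),
        }


def two_by_two(records: pd.DataFrame) -> TwoByTwo:
    """Tabulate FIR by arm from a cohort frame with ``arm`` and ``fir`` columns."""
    _check_arms(records)
    prp = records[records["arm"] == "PRP"]
    soc = records[records["arm"] == "SOC"]
    return TwoByTwo(
        a=int(prp["fir"].sum()),
        b=int((1 - prp["fir"]).sum()),
        c=int(soc["fir"].sum()),
        d=int((1 - soc["fir"]).sum()),
    )


def fir_proportions(records: pd.DataFrame) -> dict[str, float]:
    """Per-arm and pooled FIR proportions."""
    t = two_by_two(records)
    return {
        "prp": t.a / t.n_prp,
        "soc": t.c / t.n_soc,
        "pooled": (t.a + t.c) / (t.n_prp + t.n_soc),
    }


def _check_arms(records: pd.DataFrame) -> None:
    if records.empty:
        raise ValueError("empty cohort")
    if records["fir"].isna().any():
        raise ValueError("fir must be defined for every record")
    arms = set(records["arm"].unique())
    if arms != {"PRP", "SOC"}:
        raise ValueError(f"cohort must contain both arms, found {sorted(arms)}")


def crude_or(t: TwoByTwo, continuity: bool = True) -> dict[str, float]:
    """Crude odds ratio (a·d)/(b·c) with a Wald 95% CI.

    Zero cells get the Haldane–Anscombe correction (+0.5 to every cell, with
    a warning) when ``continuity`` is true, else raise.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if min(a, b, c, d) == 0.0:
        if not continuity:
            raise ValueError("zero cell in 2x2 table; enable continuity correction")
        warnings.warn(
            "zero cell in 2x2 table: applying Haldane-Anscombe +0.5 correction",
            stacklevel=2,
        )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se_log = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(or_)
    return {
        "or": or_,
        "ci_low": float(np.exp(log_or - Z_95 * se_log)),
        "ci_high": float(np.exp(log_or + Z_95 * se_log)),
        "se_log_or": float(se_log),
    }


# --- regression design ----------------------------------------------------

# Covariate encoding for the adjusted model: follow-up dichotomized at one
# year; ART duration in three bands (<2, 2-3, >3 years); CD4 at ART start in
# three bands (<200, 200-300, >300 cells/µL); regimen indicators against the
# most common regimen as reference.  The same encoding drives the synthetic
# cohort's outcome model, so parameter-recovery simulations fit the
# generating model exactly.

INITIAL_REGIMEN_LEVELS = ("d4T-3TC-NVP", "ZDV-3TC-EFV", "other")
CURRENT_REGIMEN_LEVELS = (
    "ZDV-3TC-NVP",
    "ZDV-3TC-EFV",
    "ZDV-TDF-FTC-LPV/r",
    "other",
)

DESIGN_TERMS = (
    "arm_prp",
    "followup_gt1y",
    "art_2_3y",
    "art_gt3y",
    "age_years",
    "female",
    "init_zdv_3tc_efv",
    "init_other",
    "cur_zdv_3tc_efv",
    "cur_zdv_tdf_ftc_lpvr",
    "cur_other",
    "oi_baseline",
    "oi_followup",
    "adherence_optimal",
    "cd4s_200_300",
    "cd4s_gt300",
)


def build_design(records: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Outcome vector and design matrix (with intercept) for the adjusted model.

    Records with missing adherence are dropped, mirroring complete-case
    analysis of a covariate captured only for part of the cohort.
    """
    rec = records.dropna(subset=["adherence_optimal"])
    X = pd.DataFrame(index=rec.index)
    X["const"] = 1.0
    X["arm_prp"] = (rec["arm"] == "PRP").astype(float)
    X["followup_gt1y"] = (rec["followup_months"] > 12.0).astype(float)
    art_years = rec["art_duration_months"] / 12.0
    X["art_2_3y"] = ((art_years >= 2.0) & (art_years <= 3.0)).astype(float)
    X["art_gt3y"] = (art_years > 3.0).astype(float)
    X["age_years"] = rec["age_years"].astype(float)
    X["female"] = (rec["gender"] == "female").astype(float)
    X["init_zdv_3tc_efv"] = (rec["initial_regimen"] == "ZDV-3TC-EFV").astype(float)
    X["init_other"] = (rec["initial_regimen"] == "other").astype(float)
    X["cur_zdv_3tc_efv"] = (rec["current_regimen"] == "ZDV-3TC-EFV").astype(float)
    X["cur_zdv_tdf_ftc_lpvr"] = (
        rec["current_regimen"] == "ZDV-TDF-FTC-LPV/r"
    ).astype(float)
    X["cur_other"] = (rec["current_regimen"] == "other").astype(float)
    X["oi_baseline"] = rec["oi_baseline"].astype(float)
    X["oi_followup"] = rec["oi_followup"].astype(float)
    X["adherence_optimal"] = rec["adherence_optimal"].astype(float)
    X["cd4s_200_300"] = (
        (rec["cd4_art_start"] >= 200) & (rec["cd4_art_start"] <= 300)
    ).astype(float)
    X["cd4s_gt300"] = (rec["cd4_art_start"] > 300).astype(float)
    y = rec["fir"].astype(float)
    return y, X


def fit_logistic(outcome: pd.Series, design: pd.DataFrame) -> LogisticFit:
    """Maximum-likelihood logistic fit with Wald standard errors.

    Newton/IRLS iterations run to a score tolerance of 1e-8 (at most 100);
    standard errors come from the inverse observed information.  A
    coefficient diverging beyond ±15 on the log-odds scale flags
    (quasi-)separation and the fit is marked non-converged rather than
    silently reported.
    """
    y = np.asarray(outcome, dtype=float)
    X = design.astype(float)
    variances = X.var(axis=0)
    degenerate = [
        c for c in X.columns if c != "const" and variances[c] == 0.0
    ]
    if degenerate:
        raise ValueError(f"zero-variance design columns: {', '.join(degenerate)}")
    if len(y) <= X.shape[1]:
        raise ValueError("more model terms than observations")
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="newton", maxiter=100, tol=1e-8, disp=0)
        except np.linalg.LinAlgError:
            # Newton's Hessian goes singular under (quasi-)separation; a
            # gradient fit still yields coefficients for the divergence check.
            res = model.fit(method="bfgs", maxiter=200, disp=0)
    converged = bool(res.mle_retvals.get("converged", False))
    coefs = np.asarray(res.params)
    if np.any(np.abs(coefs) > SEPARATION_BOUND):
        warnings.warn(
            "possible separation: a coefficient exceeds |15| on the log-odds "
            "scale; fit flagged non-converged",
            stacklevel=2,
        )
        converged = False
    ses = np.asarray(res.bse)
    ors = np.exp(coefs)
    ci = np.column_stack(
        [np.exp(coefs - Z_95 * ses), np.exp(coefs + Z_95 * ses)]
    )
    return LogisticFit(
        terms=tuple(X.columns),
        coefficients=coefs,
        standard_errors=ses,
        odds_ratios=ors,
        ci95=ci,
        p_values=np.asarray(res.pvalues),
        n_used=int(len(y)),
        converged=converged,
    )


def fit_summary_frame(fit: LogisticFit) -> pd.DataFrame:
    """Regression summary as a tidy frame (term, OR, CI bounds, p)."""
    return pd.DataFrame(
        {
            "term": fit.terms,
            "coef": fit.coefficients,
            "or": fit.odds_ratios,
            "ci_low": fit.ci95[:, 0],
            "ci_high": fit.ci95[:, 1],
            "p": fit.p_values,
        }
    )


def write_summary(fit: LogisticFit, path: str | Path) -> None:
    fit_summary_frame(fit).to_csv(path, index=False)
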