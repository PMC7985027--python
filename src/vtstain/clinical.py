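"""Serology correlation and time-to-ESLD survival analysis of staged cohorts.

Stages enter these analyses as case-level summaries (across-rater medians on
the F0-F4 scale, in half steps when the rater count is even).  Serology is
correlated with the median real stage, median virtual stage, their residual,
and the rater IQR via Spearman's rho; survival uses Kaplan-Meier curves with
log-rank tests on median-rounded or F >= 3.5-dichotomized stage, and Cox
proportional-hazards models (Efron ties) adjusting for age and BMI or age and
sex.  The composite end-stage-liver-disease (ESLD) event is the earliest of
ascites, liver-related hospitalization, encephalopathy, variceal bleed,
varices on imaging, hepatocellular carcinoma, dialysis, or prophylactic
propranolol prescription.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)

SODIUM_CAP = 137.0

EVENT_COMPONENTS = (
    "ascites", "liver_hospitalization", "encephalopathy", "variceal_bleed",
    "varices_on_imaging", "hcc", "dialysis", "propranolol_prophylaxis",
)

STAGE_VARIABLES = ("median_real", "median_virtual", "residual", "iqr_real")


@dataclass
class StageSummary:
    """Case-level stage summary feeding the clinical analyses."""

    case_id: object
    median_real: float
    median_virtual: float
    iqr_real: float

    def __post_init__(self) -> None:
        for v in (self.median_real, self.median_virtual):
            if not 0.0 <= v <= 4.0:
                raise ValueError("median stages must lie in [0, 4]")
        if self.iqr_real < 0:
            raise ValueError("IQR must be >= 0")

    @property
    def residual(self) -> float:
        return self.median_real - self.median_virtual


def stage_summaries(real_obs: pd.DataFrame, virtual_obs: pd.DataFrame) -> pd.DataFrame:
    """Per-case medians (type-7 linear-interpolation quantiles) and real IQR."""
    med_r = real_obs.groupby("case_id")["stage"].median()
    iqr_r = real_obs.groupby("case_id")["stage"].agg(
        lambda s: float(np.subtract(*np.percentile(s, [75, 25]))))
    med_v = virtual_obs.groupby("case_id")["stage"].median()
    df = pd.DataFrame({"median_real": med_r, "iqr_real": iqr_r, "median_virtual": med_v})
    df = df.dropna()
    df["residual"] = df["median_real"] - df["median_virtual"]
    return df.reset_index()


def cap_sodium(values: pd.Series | np.ndarray, cap: float = SODIUM_CAP) -> pd.Series | np.ndarray:
    """Cap sodium at 137 mEq/L (the MELD convention); missing passes through."""
    if isinstance(values, pd.Series):
        return values.clip(upper=cap)
    return np.minimum(np.asarray(values, dtype=np.float64), cap)


def ast_alt_ratio(ast: float | np.ndarray, alt: float | np.ndarray) -> float | np.ndarray:
    """AST/ALT ratio; undefined (NaN) when ALT is zero or missing."""
    ast = np.asarray(ast, dtype=np.float64)
    alt = np.asarray(alt, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((alt > 0) & np.isfinite(alt) & np.isfinite(ast), ast / alt, np.nan)
    return float(out) if out.ndim == 0 else out


def serology_correlations(
    summaries: pd.DataFrame,
    clinical: pd.DataFrame,
    markers: list[str] | None = None,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Spearman rho and p per (marker, stage variable), pairwise-complete.

    Stage medians are treated as continuous.  Sodium is capped at 137 before
    correlation; an AST/ALT ratio row is added when both markers are present.
    Cells with fewer than ``min_pairs`` complete pairs or a constant variable
    are reported with NaN and a warning.
    """
    df = summaries.merge(clinical, on="case_id", how="inner")
    if markers is None:
        reserved = set(STAGE_VARIABLES) | {"case_id", "age", "sex", "bmi", "event",
                                           "time", "median_real", "median_virtual",
                                           "residual", "iqr_real"}
        markers = [c for c in clinical.columns
                   if c not in reserved and pd.api.types.is_numeric_dtype(clinical[c])]
    if "sodium" in df.columns:
        df["sodium"] = cap_sodium(df["sodium"])
    if {"ast", "alt"}.issubset(df.columns) and "ast_alt_ratio" not in df.columns:
        df["ast_alt_ratio"] = ast_alt_ratio(df["ast"].to_numpy(), df["alt"].to_numpy())
        if "ast_alt_ratio" not in markers:
            markers = list(markers) + ["ast_alt_ratio"]
    rows = []
    for marker in markers:
        if marker not in df.columns or df[marker].notna().sum() == 0:
            logger.warning("marker %s absent or all-missing; omitted", marker)
            continue
        for var in STAGE_VARIABLES:
            sub = df[[marker, var]].dropna()
            if len(sub) < min_pairs or sub[var].nunique() < 2 or sub[marker].nunique() < 2:
                logger.warning("correlation (%s, %s) undefined on %d pairs",
                               marker, var, len(sub))
                rows.append({"marker": marker, "stage_variable": var, "n": len(sub),
                             "rho": np.nan, "p": np.nan})
                continue
            res = spearmanr(sub[marker], sub[var])
            rows.append({"marker": marker, "stage_variable": var, "n": len(sub),
                         "rho": float(res.statistic), "p": float(res.pvalue)})
    return pd.DataFrame(rows)


def round_half_up(values: np.ndarray) -> np.ndarray:
    """Round half-stage medians to the nearest integer, halves upward (3.5 -> 4)."""
    return np.floor(np.asarray(values, dtype=np.float64) + 0.5)


@dataclass
class SurvivalResult:
    curves: dict
    logrank_stat: float | None
    logrank_p: float | None
    groups: pd.Series
    note: str = ""


def km_logrank(
    summaries: pd.DataFrame,
    clinical: pd.DataFrame,
    stage_col: str = "median_virtual",
    grouping: str = "dichotomized_3_5",
) -> SurvivalResult:
    """Kaplan-Meier curves per stage group with a log-rank test.

    ``grouping='median_rounded'`` uses the median stage rounded half-up to an
    integer; ``'dichotomized_3_5'`` splits at advanced fibrosis, F >= 3.5.
    With fewer than two nonempty groups or no events, curves are returned
    without a test.
    """
    df = summaries.merge(clinical, on="case_id", how="inner")
    if (df["time"] < 0).any():
        raise ValueError("event/censor times must be >= 0")
    if grouping == "median_rounded":
        df["group"] = round_half_up(df[stage_col].to_numpy()).astype(int)
    elif grouping == "dichotomized_3_5":
        df["group"] = np.where(df[stage_col] >= 3.5, "F>=3.5", "F<3.5")
    else:
        raise ValueError("grouping must be 'median_rounded' or 'dichotomized_3_5'")
    curves = {}
    for g, sub in df.groupby("group"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"].astype(bool), label=str(g))
        tbl = kmf.survival_function_.reset_index()
        tbl.columns = ["time", "survival"]
        tbl["at_risk"] = [int((sub["time"] >= t).sum()) for t in tbl["time"]]
        curves[g] = tbl
    if df["group"].nunique() < 2:
        return SurvivalResult(curves, None, None, df["group"], note="single group; no test")
    if df["event"].astype(bool).sum() == 0:
        return SurvivalResult(curves, None, None, df["group"], note="no events; log-rank undefined")
    res = multivariate_logrank_test(df["time"], df["group"], df["event"].astype(bool))
    return SurvivalResult(curves, float(res.test_statistic), float(res.p_value), df["group"])


def coxph(
    summaries: pd.DataFrame,
    clinical: pd.DataFrame,
    stage_col: str = "median_virtual",
    covariates: tuple[str, ...] = ("age", "bmi"),
    dichotomize: bool = False,
) -> dict:
    """Cox proportional-hazards fit of the ESLD hazard on stage.

    Stage enters continuously (median across raters) or dichotomized at
    F >= 3.5.  Ties use the Efron approximation; reports the hazard ratio per
    unit stage with Wald 95% CI and p, and Harrell's concordance.
    """
    df = summaries.merge(clinical, on="case_id", how="inner")
    stage = df[stage_col].to_numpy(dtype=np.float64)
    data = pd.DataFrame({"stage": (stage >= 3.5).astype(float) if dichotomize else stage,
                         "time": df["time"], "event": df["event"].astype(int)})
    for cov in covariates:
        col = df[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            col = pd.factorize(col)[0].astype(float)
        data[cov] = np.asarray(col, dtype=np.float64)
    if not np.isfinite(data.drop(columns=["event"]).to_numpy()).all():
        raise ValueError("covariates must be finite")
    constant = [c for c in data.columns if c not in ("time", "event") and data[c].nunique() < 2]
    if constant:
        raise ValueError(f"constant columns carry no information: {constant}")
    n_events = int(data["event"].sum())
    if n_events < 10:
        logger.warning("only %d events; hazard estimates will be unstable", n_events)
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError/Warning variants
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    s = cph.summary.loc["stage"]
    return {"hr": float(np.exp(s["coef"])),
            "ci_low": float(np.exp(s["coef lower 95%"])),
            "ci_high": float(np.exp(s["coef upper 95%"])),
            "p": float(s["p"]),
            "coef": float(s["coef"]),
            "concordance": float(cph.concordance_index_),
            "n_events": n_events,
            "model": cph}


def composite_event(
    record: dict,
    index_date: float,
    censor_time: float,
) -> tuple[bool, float]:
    """Composite ESLD event from component onset times.

    ``record`` maps component names (see :data:`EVENT_COMPONENTS`) to onset
    dates (same units as ``index_date``) or None/NaN when absent.  The event
    time is the earliest component onset minus the index date; without any
    component the case is censored at ``censor_time`` (days since index).
    """
    onsets = []
    for comp in EVENT_COMPONENTS:
        val = record.get(comp)
        if val is None or (isinstance(val, float) and np.isnan(val)):
            continue
        if val < index_date:
            raise ValueError(f"component {comp} dated before the index date")
        onsets.append(val)
    if onsets:
        return True, float(min(onsets) - index_date)
    if censor_time < 0:
        raise ValueError("censor time must be >= 0")
    return False, float(censor_time)
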