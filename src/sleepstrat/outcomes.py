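"""Survival analysis of risk groups: Cox models, KM curves, propensity weights.

Implements the outcome stage of the pipeline: eligibility filtering (at
least five years of pre-study medical history, no prevalent disease), six
Cox proportional-hazards model variants against the ordinal risk groups (or
AHI severity bands as the sensitivity exposure), Kaplan-Meier disease-free
survival at fixed horizons with pairwise log-rank tests against the
reference group, and multinomial-propensity stabilized inverse weights
trimmed at the 5th/95th percentiles.

Model variants (exposure indicator coded against the reference level):

1. unadjusted; 2. + age, sex, BMI; 3. + comorbidities; 4. + AHI;
5. as 3, excluding subjects prescribed PAP therapy;
6. as 3, excluding subjects younger than 55.

Ties use the Efron approximation; weighted fits use robust (sandwich)
variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .hypnogram_metrics import ahi_severity
from .synthetic import COMORBIDITIES

_BASE_DEMOGRAPHICS = ["age", "sex", "bmi"]

#: Adjustment covariates per Cox model id.
COX_MODEL_COVARIATES: dict[int, list[str]] = {
    1: [],
    2: _BASE_DEMOGRAPHICS,
    3: _BASE_DEMOGRAPHICS + list(COMORBIDITIES),
    4: _BASE_DEMOGRAPHICS + list(COMORBIDITIES) + ["ahi"],
    5: _BASE_DEMOGRAPHICS + list(COMORBIDITIES),
    6: _BASE_DEMOGRAPHICS + list(COMORBIDITIES),
}

AHI_SEVERITY_LEVELS = ["normal", "mild", "moderate", "severe"]


def _outcome_columns(outcome: str) -> tuple[str, str, str]:
    """(event_col, time_col, prevalent_col) naming convention per outcome."""
    if outcome == "death":
        return "event", "time_years", "prevalent_death"
    return f"{outcome}_event", f"{outcome}_time", f"prevalent_{outcome}"


def build_outcome_cohort(
    subjects: pd.DataFrame, outcome: str, min_history_years: float = 5.0
) -> pd.DataFrame:
    """Eligible subset for one outcome.

    Retains subjects with at least ``min_history_years`` of pre-study
    medical history and, when a prevalence flag column exists for the
    outcome, no prevalent occurrence.
    """
    event_col, time_col, prev_col = _outcome_columns(outcome)
    if event_col not in subjects.columns or time_col not in subjects.columns:
        raise ValueError(
            f"unknown outcome {outcome!r}: columns {event_col!r}/{time_col!r} "
            "not found in the subject table"
        )
    keep = subjects["history_years"] >= min_history_years
    if prev_col in subjects.columns:
        keep &= subjects[prev_col] == 0
    return subjects.loc[keep].copy()


@dataclass
class CoxFit:
    """Per-exposure-level hazard ratios from one Cox model variant."""

    model_id: int
    exposure: str
    reference: str
    summary: pd.DataFrame  # index: exposure level; hr, ci_lower, ci_upper, p
    n_samples: int
    n_events: int
    zero_event_levels: list[str] = field(default_factory=list)
    weighted: bool = False

    def hr(self, level: str) -> float:
        return float(self.summary.loc[level, "hr"])

    def ci(self, level: str) -> tuple[float, float]:
        row = self.summary.loc[level]
        return float(row["ci_lower"]), float(row["ci_upper"])


def _exposure_levels(cohort: pd.DataFrame, exposure: str):
    if exposure == "risk_groups":
        levels = sorted(cohort["risk_group"].unique())
        return cohort["risk_group"], levels, levels[0]
    if exposure == "ahi_severity":
        sev = cohort["ahi"].map(ahi_severity)
        levels = [l for l in AHI_SEVERITY_LEVELS if (sev == l).any()]
        return sev, levels, "normal"
    raise ValueError(f"unknown exposure {exposure!r}")


def fit_cox_model(
    cohort: pd.DataFrame,
    model_id: int,
    exposure: str = "risk_groups",
    weights: "WeightVector | None" = None,
    outcome: str = "death",
) -> CoxFit:
    """Fit one of the six Cox model variants on an eligible cohort.

    The exposure enters as indicator variables against the reference level
    (lowest risk group, or normal AHI); hazard ratios are exponentiated
    coefficients with Wald 95% CIs.  Models 5 and 6 apply their exclusions
    here.  A level with zero events is flagged and its CI reported as
    unbounded.
    """
    if model_id not in COX_MODEL_COVARIATES:
        raise ValueError(f"model_id must be 1..6, got {model_id}")
    df = cohort.copy()
    if model_id == 5:
        df = df[df["pap_prescribed"] == 0]
    elif model_id == 6:
        df = df[df["age"] >= 55.0]
    if df.empty:
        raise ValueError(f"cohort empty after model {model_id} exclusions")

    event_col, time_col, _ = _outcome_columns(outcome)
    expo, levels, reference = _exposure_levels(df, exposure)
    covars = COX_MODEL_COVARIATES[model_id]

    fit_df = pd.DataFrame({time_col: df[time_col], event_col: df[event_col]})
    indicator_cols = []
    for level in levels:
        if level == reference:
            continue
        col = f"exp_{level}"
        fit_df[col] = (expo == level).astype(float)
        indicator_cols.append((level, col))
    for c in covars:
        fit_df[c] = df[c].astype(float)

    kwargs = {}
    if weights is not None:
        fit_df["_w"] = weights.weights.loc[df.index].to_numpy()
        kwargs = {"weights_col": "_w", "robust": True}

    cph = CoxPHFitter()
    cph.fit(fit_df, duration_col=time_col, event_col=event_col, **kwargs)

    zero_events = []
    rows = {}
    for level, col in indicator_cols:
        s = cph.summary.loc[col]
        hr = float(np.exp(s["coef"]))
        with np.errstate(over="ignore"):  # separation can push bounds to inf
            lo = float(np.exp(s["coef lower 95%"]))
            hi = float(np.exp(s["coef upper 95%"]))
        if df.loc[(expo == level), event_col].sum() == 0:
            zero_events.append(level)
            lo, hi = 0.0, np.inf
        rows[level] = {"hr": hr, "ci_lower": lo, "ci_upper": hi, "p": float(s["p"])}

    return CoxFit(
        model_id=model_id,
        exposure=exposure,
        reference=str(reference),
        summary=pd.DataFrame.from_dict(rows, orient="index"),
        n_samples=len(df),
        n_events=int(df[event_col].sum()),
        zero_event_levels=zero_events,
        weighted=weights is not None,
    )


def proportional_hazards_check(
    cohort: pd.DataFrame, model_id: int, exposure: str = "risk_groups",
    outcome: str = "death",
) -> pd.DataFrame:
    """Advisory Schoenfeld-residual trend test per covariate (alpha 0.05)."""
    from lifelines.statistics import proportional_hazard_test

    df = cohort.copy()
    if model_id == 5:
        df = df[df["pap_prescribed"] == 0]
    elif model_id == 6:
        df = df[df["age"] >= 55.0]
    event_col, time_col, _ = _outcome_columns(outcome)
    expo, levels, reference = _exposure_levels(df, exposure)
    fit_df = pd.DataFrame({time_col: df[time_col], event_col: df[event_col]})
    for level in levels:
        if level != reference:
            fit_df[f"exp_{level}"] = (expo == level).astype(float)
    for c in COX_MODEL_COVARIATES[model_id]:
        fit_df[c] = df[c].astype(float)
    cph = CoxPHFitter().fit(fit_df, duration_col=time_col, event_col=event_col)
    res = proportional_hazard_test(cph, fit_df, time_transform="rank")
    out = res.summary[["p"]].copy()
    out["flagged"] = out["p"] < 0.05
    return out


# ---------------------------------------------------------------------------
# propensity weights
# ---------------------------------------------------------------------------

#: Default propensity-model covariates.
PROPENSITY_COVARIATES = _BASE_DEMOGRAPHICS + list(COMORBIDITIES) + ["history_years"]


@dataclass
class WeightVector:
    """Stabilized inverse-propensity weights with percentile trim bounds."""

    weights: pd.Series
    trim_lower: float
    trim_upper: float
    mode: str  # "clip" or "exclude"

    def __post_init__(self) -> None:
        if (self.weights <= 0).any():
            raise ValueError("weights must be positive")


def estimate_propensity_weights(
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
    group_col: str = "risk_group",
    mode: str = "clip",
    ridge_c: float = 1e4,
    seed: int = 0,
) -> WeightVector:
    """Multinomial-logistic stabilized inverse-propensity weights.

    The raw weight of subject i in group g is the marginal group frequency
    P(G=g) divided by the fitted conditional probability P(G=g | x_i).
    Weights are then trimmed at their empirical 5th and 95th percentiles:
    ``mode="clip"`` (default) clips to the bounds, preserving sample size;
    ``mode="exclude"`` drops subjects outside the bounds.  ``ridge_c`` is
    the inverse ridge penalty guarding against separation.
    """
    covariates = covariates or [c for c in PROPENSITY_COVARIATES if c in cohort]
    groups, uniques = pd.factorize(cohort[group_col], sort=True)
    if len(uniques) < 2:
        raise ValueError("propensity model needs at least 2 groups")
    X = cohort[covariates].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    lr = LogisticRegression(C=ridge_c, max_iter=5000, random_state=seed)
    lr.fit(X, groups)
    fitted = lr.predict_proba(X)[np.arange(len(groups)), groups]
    if np.any(fitted < 1e-10):
        raise ValueError(
            "near-zero fitted propensity (separation); lower ridge_c to regularize"
        )
    marginal = np.bincount(groups, minlength=len(uniques)) / len(groups)
    raw = marginal[groups] / fitted
    return trim_weights(pd.Series(raw, index=cohort.index), mode=mode)


def trim_weights(raw: pd.Series, mode: str = "clip") -> WeightVector:
    """Trim raw weights at their empirical 5th/95th percentiles.

    ``clip`` bounds extreme weights to the percentile values (sample size
    preserved); ``exclude`` drops subjects outside the bounds.
    """
    lo, hi = np.percentile(raw.to_numpy(), [5.0, 95.0])
    if mode == "clip":
        w = raw.clip(lo, hi)
    elif mode == "exclude":
        w = raw[(raw >= lo) & (raw <= hi)]
    else:
        raise ValueError(f"unknown trim mode {mode!r}")
    return WeightVector(weights=w, trim_lower=float(lo), trim_upper=float(hi), mode=mode)


def standardized_mean_differences(
    cohort: pd.DataFrame,
    covariates: list[str],
    group_col: str = "risk_group",
    weights: WeightVector | None = None,
) -> pd.DataFrame:
    """Pairwise-vs-pooled SMD per covariate and group (balance diagnostic)."""
    w = (weights.weights.reindex(cohort.index).fillna(0.0).to_numpy()
         if weights is not None else np.ones(len(cohort)))
    rows = {}
    for cov in covariates:
        x = cohort[cov].to_numpy(dtype=float)
        mu = np.average(x, weights=w)
        var = np.average((x - mu) ** 2, weights=w)
        sd = np.sqrt(var) if var > 0 else 1.0
        for g in sorted(cohort[group_col].unique()):
            m = (cohort[group_col] == g).to_numpy()
            mug = np.average(x[m], weights=w[m])
            rows.setdefault(cov, {})[g] = (mug - mu) / sd
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------

def logrank_two_groups(
    time_a, event_a, time_b, event_b, weights_a=None, weights_b=None
) -> tuple[float, float]:
    """Two-group log-rank statistic and p-value, optionally weighted.

    Uses the classical hypergeometric-variance statistic on (optionally
    subject-weighted) risk-set and event counts; with unit weights this is
    the standard log-rank test.
    """
    ta = np.asarray(time_a, dtype=float)
    tb = np.asarray(time_b, dtype=float)
    ea = np.asarray(event_a, dtype=float)
    eb = np.asarray(event_b, dtype=float)
    wa = np.ones_like(ta) if weights_a is None else np.asarray(weights_a, dtype=float)
    wb = np.ones_like(tb) if weights_b is None else np.asarray(weights_b, dtype=float)

    event_times = np.unique(np.concatenate([ta[ea > 0], tb[eb > 0]]))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        y1 = wa[ta >= t].sum()
        y2 = wb[tb >= t].sum()
        d1 = wa[(ta == t) & (ea > 0)].sum()
        d2 = wb[(tb == t) & (eb > 0)].sum()
        y = y1 + y2
        d = d1 + d2
        if y <= 1 or d == 0:
            continue
        e1 = d * y1 / y
        o_minus_e += d1 - e1
        var += d * (y1 / y) * (1.0 - y1 / y) * (y - d) / (y - 1.0)
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def km_disease_free_survival(
    cohort: pd.DataFrame,
    outcome: str = "death",
    group_col: str = "risk_group",
    horizons: tuple[float, ...] = (2.0, 4.0, 6.0),
    weights: WeightVector | None = None,
) -> pd.DataFrame:
    """Product-limit survival per group at fixed horizons + log-rank vs reference.

    Returns one row per group with ``S(h)`` columns for each horizon, the
    group size and event count, and the pairwise log-rank statistic and
    p-value against the reference group (the lexicographically first group,
    i.e. RG1).  Groups with zero subjects are omitted with a warning.
    Supplied weights produce the weighted product-limit estimate and the
    weighted log-rank variant.
    """
    import warnings as _warnings

    if cohort.empty:
        raise ValueError("empty cohort")
    event_col, time_col, _ = _outcome_columns(outcome)
    groups = sorted(cohort[group_col].unique())
    reference = groups[0]

    def _arrays(g):
        sub = cohort[cohort[group_col] == g]
        w = (weights.weights.reindex(sub.index).to_numpy()
             if weights is not None else None)
        if w is not None:
            ok = ~np.isnan(w)
            sub, w = sub.iloc[ok], w[ok]
        return sub[time_col].to_numpy(), sub[event_col].to_numpy(), w

    t_ref, e_ref, w_ref = _arrays(reference)
    rows = []
    for g in groups:
        t, e, w = _arrays(g)
        if t.size == 0:
            _warnings.warn(f"group {g!r} has zero subjects; omitted")
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(t, e, weights=w)
        row = {"group": g, "n": int(t.size), "events": int(e.sum())}
        for h in horizons:
            row[f"S({h:g}y)"] = float(kmf.predict(h))
        if g == reference:
            row["logrank_stat"], row["logrank_p"] = np.nan, np.nan
        else:
            row["logrank_stat"], row["logrank_p"] = logrank_two_groups(
                t_ref, e_ref, t, e, w_ref, w
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
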