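"""Survival statistics: Kaplan-Meier, log-rank, Cox regression, power,
multiple-testing adjustment, baseline-table comparisons and dichotomous
classification metrics.

Standard estimators are delegated to lifelines (product-limit estimate,
Mantel-Cox log-rank, Cox partial likelihood with Efron tie handling),
statsmodels (Benjamini-Hochberg) and scipy (Fisher exact, Mann-Whitney);
this module fixes the conventions used throughout the package and the
report shapes the pipeline writes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LogRankResult",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "logrank_power",
    "bh_adjust",
    "baseline_comparison",
    "classification_metrics",
]


@dataclass
class LogRankResult:
    """Mantel-Cox log-rank comparison of two survival curves.

    ``hazard_ratio`` (group2 vs group1) comes from a companion
    single-covariate Cox fit, as is conventional when annotating
    Kaplan-Meier figures.
    """

    chi_square: float
    p_value: float
    hazard_ratio: float | None
    hr_ci: tuple[float, float] | None
    group_names: tuple[str, str]
    event_table: pd.DataFrame | None = None

    def __repr__(self) -> str:  # pragma: no cover
        hr = f", HR={self.hazard_ratio:.3g}" if self.hazard_ratio is not None else ""
        return f"LogRankResult(chi2={self.chi_square:.4g}, p={self.p_value:.4g}{hr})"


def _as_arrays(time, event):
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival sample")
    if np.any(t < 0):
        raise ValueError("negative survival time")
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite survival time")
    return t, e


def km_estimate(time, event) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) survival estimate.

    Returns a data frame with one row per distinct observed time:
    ``time``, ``survival`` (S(t), non-increasing, S(0)=1), ``at_risk``,
    ``events`` and ``censored`` counts.  Suitable for writing as a
    plotting-ready CSV.
    """
    t, e = _as_arrays(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    # drop the implicit S(0)=1 anchor unless observations occur at t=0
    if 0.0 in table.index and 0.0 not in t:
        table = table.drop(index=0.0)
    surv = kmf.survival_function_["KM_estimate"]
    df = pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "survival": surv.reindex(table.index).to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=int),
            "events": table["observed"].to_numpy(dtype=int),
            "censored": table["censored"].to_numpy(dtype=int),
        }
    )
    return df.reset_index(drop=True)


def logrank_test(
    time,
    event,
    group,
    *,
    compute_hr: bool = True,
) -> LogRankResult:
    """Two-group Mantel-Cox log-rank test.

    ``group`` may hold any two distinct labels; the hazard ratio is
    reported for the second group (sorted order) relative to the first,
    estimated by a companion univariate Cox fit (Efron ties) with a Wald
    95% CI.  ``compute_hr=False`` skips the Cox fit (used in large
    calibration loops).
    """
    t, e = _as_arrays(time, event)
    g = np.asarray(group)
    levels = sorted(pd.unique(g).tolist())
    if len(levels) != 2:
        raise ValueError(f"logrank_test requires exactly 2 groups, got {levels}")
    if e.sum() < 1:
        raise ValueError("logrank_test requires at least one event")
    m = g == levels[1]
    res = _ll_logrank(t[~m], t[m], event_observed_A=e[~m], event_observed_B=e[m])
    hr = ci = None
    if compute_hr:
        fit = cox_fit(
            pd.DataFrame({"time": t, "event": e, "group": m.astype(int)}),
            covariates=["group"],
        )
        row = fit.loc["group"]
        hr, ci = float(row["hr"]), (float(row["hr_lo"]), float(row["hr_hi"]))
    event_table = (
        pd.DataFrame(
            {
                "group": levels,
                "n": [int((~m).sum()), int(m.sum())],
                "events": [int(e[~m].sum()), int(e[m].sum())],
            }
        )
    )
    return LogRankResult(
        chi_square=float(res.test_statistic),
        p_value=float(res.p_value),
        hazard_ratio=hr,
        hr_ci=ci,
        group_names=(str(levels[0]), str(levels[1])),
        event_table=event_table,
    )


def cox_fit(
    data: pd.DataFrame,
    covariates: Sequence[str],
    *,
    time_col: str = "time",
    event_col: str = "event",
    mode: str = "multivariate",
    p_enter: float = 0.1,
) -> pd.DataFrame:
    """Cox proportional-hazards regression (partial likelihood, Efron ties).

    ``mode='univariate'`` fits each covariate alone and returns one row per
    covariate.  ``mode='multivariate'`` fits all covariates jointly.
    ``mode='auto'`` first screens covariates univariately and enters those
    with p < ``p_enter`` into a joint model (the screening convention of
    the study this package models).

    Returns a frame indexed by covariate with columns ``hr``, ``hr_lo``,
    ``hr_hi``, ``p``, ``coef``, ``se``.
    """
    covariates = list(covariates)
    for c in covariates + [time_col, event_col]:
        if c not in data.columns:
            raise KeyError(f"column {c!r} missing from data")
    for c in covariates:
        if data[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")
    n_events = int(data[event_col].sum())
    if n_events < 1:
        raise ValueError("Cox regression requires at least one event")
    if len(data) <= len(covariates) + 1:
        raise ValueError(
            f"{len(data)} observations cannot support {len(covariates)} covariates"
        )

    def _single(cols: list[str]) -> pd.DataFrame:
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(
                    data[[time_col, event_col] + cols],
                    duration_col=time_col,
                    event_col=event_col,
                )
        except Exception as exc:  # lifelines ConvergenceError and kin
            raise RuntimeError(f"Cox fit failed for {cols}: {exc}") from exc
        s = cph.summary
        return pd.DataFrame(
            {
                "hr": s["exp(coef)"],
                "hr_lo": s["exp(coef) lower 95%"],
                "hr_hi": s["exp(coef) upper 95%"],
                "p": s["p"],
                "coef": s["coef"],
                "se": s["se(coef)"],
            }
        )

    if mode == "univariate":
        return pd.concat([_single([c]) for c in covariates])
    if mode == "multivariate":
        if n_events < len(covariates):
            raise ValueError(
                f"{n_events} events for {len(covariates)} covariates in multivariate mode"
            )
        return _single(covariates)
    if mode == "auto":
        uni = pd.concat([_single([c]) for c in covariates])
        selected = [c for c in covariates if uni.loc[c, "p"] < p_enter]
        if not selected:
            return uni.iloc[0:0]
        return _single(selected)
    raise ValueError(f"unknown mode {mode!r}")


def logrank_power(hr: float, n_events: int, allocation: float = 0.5, alpha: float = 0.05) -> float:
    """Power of the two-sided log-rank test, Schoenfeld approximation.

    power = Phi(|ln hr| * sqrt(d * p * (1-p)) - z_{1-alpha/2}) for d events
    and allocation fraction p.  At hr=1 this returns the one-sided tail
    alpha/2 of the two-sided construction.
    """
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    if not 0 < allocation < 1:
        raise ValueError("allocation must be in (0,1)")
    z = sps.norm.ppf(1 - alpha / 2)
    delta = abs(np.log(hr)) * np.sqrt(n_events * allocation * (1 - allocation))
    return float(sps.norm.cdf(delta - z))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_exact_p(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Two-sided rule: sum of the probabilities of all tables (with the same
    margins) whose point hypergeometric probability does not exceed the
    observed table's.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("fisher_exact_p expects a 2x2 table")
    return float(sps.fisher_exact(t)[1])


# variables of the baseline table and how each is tested
_CATEGORICAL = [
    "sex",
    "primary_site",
    "differentiation",
    "nodal_status",
    "distribution",
    "neoadjuvant",
    "adjuvant",
    "resection_extent",
    "margin",
]
_CONTINUOUS = [
    "age",
    "interval_to_metastasis",
    "n_metastases",
    "largest_metastasis_cm",
    "preop_cea",
]
_MISSING_TOKENS = {"missing", "unknown", ""}


def baseline_comparison(
    clinical: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    *,
    categorical: Sequence[str] | None = None,
    continuous: Sequence[str] | None = None,
    categorical_test: str = "fisher",
) -> pd.DataFrame:
    """Group comparison of baseline characteristics (Table-1 style).

    Two-sided Fisher exact test for 2x2 categorical variables and
    Mann-Whitney U for continuous ones; categorical variables with more
    than two observed levels fall back to a Pearson chi-square.  Rows with
    missing values (NaN or 'missing'/'unknown') are excluded from the
    tested table and counted in ``n_missing``.  ``categorical_test='chi2'``
    switches 2x2 tables to the uncorrected chi-square.
    """
    labels = pd.Series(labels)
    labels = labels[labels.isin(["high", "low"])]
    df = clinical.set_index("patient_id").loc[labels.index]
    if categorical is None:
        categorical = [c for c in _CATEGORICAL if c in df.columns]
    if continuous is None:
        continuous = [c for c in _CONTINUOUS if c in df.columns]
    rows = []
    for var in categorical:
        col = df[var].astype(str)
        keep = ~col.str.lower().isin(_MISSING_TOKENS)
        tab = pd.crosstab(col[keep], labels[keep])
        n_missing = int((~keep).sum())
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            warnings.warn(f"variable {var!r}: fewer than two levels after missing removal; skipped")
            continue
        if tab.shape == (2, 2) and categorical_test == "fisher":
            p, test = fisher_exact_p(tab.to_numpy()), "fisher"
        else:
            p = float(sps.chi2_contingency(tab.to_numpy(), correction=False)[1])
            test = "chi2"
        rows.append({"variable": var, "test": test, "p": p, "n_missing": n_missing})
    for var in continuous:
        x = pd.to_numeric(df[var], errors="coerce")
        keep = x.notna()
        a = x[keep & (labels == "high")]
        b = x[keep & (labels == "low")]
        if len(a) == 0 or len(b) == 0:
            warnings.warn(f"variable {var!r}: a group is empty after missing removal; skipped")
            continue
        p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append(
            {"variable": var, "test": "mannwhitney", "p": p, "n_missing": int((~keep).sum())}
        )
    return pd.DataFrame(rows)


def classification_metrics(predicted, truth) -> dict:
    """Accuracy / sensitivity / specificity of high-vs-low predictions.

    ``truth`` labels other than 'high'/'low' (the unlabelable patients)
    are excluded from the confusion matrix and counted.
    Sensitivity is for detecting the high-risk class.
    """
    pred = pd.Series(np.asarray(predicted))
    true = pd.Series(np.asarray(truth))
    usable = true.isin(["high", "low"]).to_numpy()
    p, t = pred[usable], true[usable]
    tp = int(((p == "high") & (t == "high")).sum())
    tn = int(((p == "low") & (t == "low")).sum())
    fp = int(((p == "high") & (t == "low")).sum())
    fn = int(((p == "low") & (t == "high")).sum())
    n = tp + tn + fp + fn
    return {
        "n_evaluated": n,
        "n_unlabelable": int((~usable).sum()),
        "accuracy": (tp + tn) / n if n else float("nan"),
        "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
        "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
        "confusion": {"tp": tp, "tn": tn, "fp": fp, "fn": fn},
    }
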