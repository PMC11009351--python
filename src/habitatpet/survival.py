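"""Clinical evaluation of imaging subtypes and ctDNA status.

Kaplan-Meier curves with log-rank tests, univariate/multivariate Cox
proportional-hazards models (Efron tie handling), Harrell's concordance
index with bootstrap confidence intervals for nested model comparison, and
subtype-by-ctDNA cross-tabulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex

__all__ = [
    "km_logrank",
    "cox_fit",
    "concordance_index",
    "compare_models",
    "ctdna_crosstab",
    "KMResult",
    "ModelComparison",
]


@dataclass
class KMResult:
    """Per-group Kaplan-Meier curves plus the log-rank test."""

    curves: dict[str, pd.DataFrame]  # columns: time, survival
    statistic: float
    p_value: float
    df: int


@dataclass
class ModelComparison:
    """C-indices (with bootstrap CIs) for a set of Cox model specifications."""

    specs: dict[str, list[str]]
    c_index: dict[str, float]
    c_ci: dict[str, tuple[float, float]]
    deltas: dict[str, float] = field(default_factory=dict)


def km_logrank(df: pd.DataFrame, group: str, time_col: str = "time",
               event_col: str = "event") -> KMResult:
    """Kaplan-Meier estimates per group and the (g-1)-df log-rank test."""
    groups = df[group].unique()
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for a log-rank test")
    curves = {}
    for g in groups:
        sub = df[df[group] == g]
        if sub[event_col].sum() == 0:
            warnings.warn(f"group {g!r} has no events; retained")
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], sub[event_col])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[str(g)] = sf
    res = multivariate_logrank_test(df[time_col], df[group], df[event_col])
    return KMResult(curves=curves, statistic=float(res.test_statistic),
                    p_value=float(res.p_value), df=len(groups) - 1)


def _design_matrix(df: pd.DataFrame, covariates: list[str],
                   reference: dict[str, str] | None = None) -> pd.DataFrame:
    """Expand categorical covariates against declared reference levels."""
    reference = reference or {}
    out = {}
    for cov in covariates:
        col = df[cov]
        if pd.api.types.is_numeric_dtype(col):
            if col.nunique() <= 1:
                raise ValueError(f"constant covariate: {cov}")
            out[cov] = col.astype(float)
        else:
            levels = list(pd.unique(col))
            ref = reference.get(cov, levels[0])
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent from {cov}")
            for lev in levels:
                if lev == ref:
                    continue
                out[f"{cov}[{lev}]"] = (col == lev).astype(float)
            if len(levels) <= 1:
                raise ValueError(f"constant covariate: {cov}")
    return pd.DataFrame(out, index=df.index)


def cox_fit(df: pd.DataFrame, covariates: list[str], time_col: str = "time",
            event_col: str = "event",
            reference: dict[str, str] | None = None) -> pd.DataFrame:
    """Cox proportional-hazards fit with Efron tie handling.

    Categorical covariates are expanded as indicators against a declared
    reference level (``reference`` maps covariate -> level; default: first
    level observed).  Returns a tidy table with one row per coefficient:
    variable, hr, ci_low, ci_high, p.  Requires >= 10 events.
    """
    if df[event_col].sum() < 10:
        raise ValueError("need at least 10 events for a stable Cox fit")
    X = _design_matrix(df, covariates, reference)
    data = pd.concat([X, df[[time_col, event_col]]], axis=1).dropna()
    n_dropped = len(df) - len(data)
    if n_dropped:
        warnings.warn(f"complete-case analysis dropped {n_dropped} patients")
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col=time_col, event_col=event_col)
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    summ = cph.summary
    return pd.DataFrame({
        "variable": summ.index,
        "hr": summ["exp(coef)"].to_numpy(),
        "ci_low": summ["exp(coef) lower 95%"].to_numpy(),
        "ci_high": summ["exp(coef) upper 95%"].to_numpy(),
        "p": summ["p"].to_numpy(),
    }).reset_index(drop=True)


def concordance_index(risk_scores: np.ndarray, time: np.ndarray,
                      event: np.ndarray) -> float:
    """Harrell's C for risk scores where higher risk means earlier events.

    Ties in the score count 0.5; pairs unusable under right censoring are
    excluded.
    """
    risk = np.asarray(risk_scores, dtype=float)
    if not np.isfinite(risk).all():
        raise ValueError("non-finite risk scores")
    return float(_lifelines_cindex(np.asarray(time), -risk, np.asarray(event)))


def _linear_predictor(df: pd.DataFrame, covariates: list[str], time_col: str,
                      event_col: str, reference: dict[str, str] | None) -> np.ndarray:
    X = _design_matrix(df, covariates, reference)
    data = pd.concat([X, df[[time_col, event_col]]], axis=1)
    cph = CoxPHFitter(penalizer=1e-6)
    cph.fit(data, duration_col=time_col, event_col=event_col)
    return cph.predict_partial_hazard(data).to_numpy()


def compare_models(df: pd.DataFrame, specs: dict[str, list[str]],
                   time_col: str = "time", event_col: str = "event",
                   reference: dict[str, str] | None = None,
                   n_bootstrap: int = 200, seed: int = 0) -> ModelComparison:
    """Fit one Cox model per specification and compare Harrell's C.

    Each spec is a named covariate list (e.g. clinical; clinical + volume +
    subtype; clinical + volume + subtype + ctDNA).  Risk is the in-sample
    linear predictor; C-index CIs come from a seeded patient bootstrap.
    Covariates missing for more than 20% of patients raise an error naming
    them.
    """
    for name, covs in specs.items():
        frac_missing = df[covs].isna().mean()
        bad = list(frac_missing[frac_missing > 0.2].index)
        if bad:
            raise ValueError(f"model {name!r}: covariates missing >20%: {bad}")
    used = df.dropna(subset=sorted({c for covs in specs.values() for c in covs}))
    rng = np.random.default_rng(seed)
    c_index, c_ci = {}, {}
    risks = {}
    for name, covs in specs.items():
        risk = _linear_predictor(used, covs, time_col, event_col, reference)
        risks[name] = risk
        c_index[name] = concordance_index(risk, used[time_col], used[event_col])
        cs = []
        n = len(used)
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            t = used[time_col].to_numpy()[idx]
            e = used[event_col].to_numpy()[idx]
            if e.sum() == 0:
                continue
            try:
                cs.append(concordance_index(risk[idx], t, e))
            except ZeroDivisionError:  # resample without admissible pairs
                continue
        if cs:
            c_ci[name] = (float(np.percentile(cs, 2.5)),
                          float(np.percentile(cs, 97.5)))
        else:
            c_ci[name] = (float("nan"), float("nan"))
    names = list(specs)
    deltas = {f"{b}-{a}": c_index[b] - c_index[a]
              for a, b in zip(names[:-1], names[1:])}
    return ModelComparison(specs=specs, c_index=c_index, c_ci=c_ci, deltas=deltas)


def ctdna_crosstab(df: pd.DataFrame, subtype_col: str = "subtype",
                   ctdna_col: str = "ctdna_clearance") -> pd.DataFrame:
    """Row-normalized percentage of each ctDNA category per subtype.

    Patients with missing ctDNA are excluded; a subtype with no observed
    ctDNA at all is dropped with a warning.  Returns a tidy frame with
    subtype, category, count and pct (each subtype's pct sums to 100).
    """
    sub = df[[subtype_col, ctdna_col]].copy()
    sub = sub[~sub[ctdna_col].isin(["missing"]) & sub[ctdna_col].notna()]
    all_subtypes = set(df[subtype_col].unique())
    kept = set(sub[subtype_col].unique())
    for lost in sorted(all_subtypes - kept):
        warnings.warn(f"subtype {lost!r} has no non-missing ctDNA; excluded")
    if sub.empty:
        raise ValueError("no non-missing ctDNA values")
    counts = sub.groupby([subtype_col, ctdna_col]).size().rename("count").reset_index()
    totals = counts.groupby(subtype_col)["count"].transform("sum")
    counts["pct"] = 100.0 * counts["count"] / totals
    return counts.rename(columns={subtype_col: "subtype", ctdna_col: "category"})
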