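"""Survival validation of a classified HeH cohort.

Given a cohort table with merged risk groups (GR/PR) and three endpoints
(relapse, any event, death), this module reproduces the standard validation
battery for a cytogenetic risk profile:

* Kaplan–Meier curves per group with Greenwood variance and log(−log)
  95% confidence intervals, read at 5 years;
* the log-rank test between groups;
* unadjusted and MRD-adjusted Cox proportional-hazards fits (Efron tie
  correction; MRD entered continuously as ``log10(MRD + 1e-5)``);
* Harrell's concordance index and a Schoenfeld-residual proportionality
  check;
* a subgroup forest (sex, age band, WCC band, NCI risk, MRD band) with
  Cochran's Q heterogeneity test over the subgroup log hazard ratios;
* a demographic comparison table (chi-square, Fisher's exact fallback for
  sparse 2×2 tables) and a definite-vs-provisional comparison.

The survival machinery is backed by lifelines; this module owns the report
assembly, the heterogeneity statistic and the group/band bookkeeping.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, proportional_hazard_test
from lifelines.utils import concordance_index
from scipy import stats

__all__ = [
    "KMCurve",
    "CoxResult",
    "SubgroupForest",
    "prepare_survival_dataset",
    "km_estimate",
    "km_at",
    "logrank",
    "cox_fit",
    "harrell_c",
    "schoenfeld_check",
    "cochran_q",
    "subgroup_forest",
    "run_validation",
    "ENDPOINT_COLUMNS",
    "MRD_EPSILON",
]

ENDPOINT_COLUMNS: dict[str, tuple[str, str]] = {
    "relapse": ("relapse_time", "relapse_ind"),
    "event": ("event_time", "event_ind"),
    "death": ("death_time", "death_ind"),
}

#: Offset used in the continuous MRD transform log10(mrd + MRD_EPSILON);
#: keeps MRD-negative (0) samples finite at the assay's detection floor.
MRD_EPSILON = 1e-5


@dataclass
class KMCurve:
    """Product-limit survival curve with Greenwood variance and log-log CI."""

    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "variance": self.variance,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "at_risk": self.at_risk,
            }
        )


@dataclass
class CoxResult:
    """A fitted proportional-hazards model, one row per covariate."""

    summary: pd.DataFrame  # index: covariate; columns: coef, se, hr, ci, p
    log_likelihood: float
    n: int
    n_events: int
    model: CoxPHFitter = field(repr=False, default=None)

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])

    def ci(self, covariate: str) -> tuple[float, float]:
        row = self.summary.loc[covariate]
        return float(row["hr_lower"]), float(row["hr_upper"])

    def p(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "p"])


@dataclass
class SubgroupForest:
    """Per-subgroup group-effect estimates plus Cochran's Q heterogeneity."""

    rows: pd.DataFrame  # subgroup, level, n, events, hr, ci, p
    q_statistic: float
    q_df: int
    q_p: float
    dropped: tuple[str, ...] = ()


def prepare_survival_dataset(df: pd.DataFrame) -> pd.DataFrame:
    """Add derived analysis columns to a classified cohort table.

    Adds age/WCC bands, MRD dichotomisations at 0.01% and 0.03% (fractions
    1e-4 and 3e-4), the continuous MRD transform, and NCI risk (standard iff
    age 1–9 and WCC < 50×10⁹/L).  Rows are not filtered here.
    """
    out = df.copy()
    if "age_years" in out:
        out["age_band"] = pd.cut(
            out["age_years"],
            bins=[0, 10, 15, 25, np.inf],
            right=False,
            labels=["1-9", "10-14", "15-24", "25+"],
        ).astype(str)
    if "wcc" in out:
        out["wcc_band"] = pd.cut(
            out["wcc"], bins=[0, 50, 100, np.inf], right=False,
            labels=["0-49", "50-99", "100+"],
        ).astype(str)
    if "mrd" in out:
        out["mrd_ge_0.01pct"] = (out["mrd"] >= 1e-4).astype(int)
        out["mrd_ge_0.03pct"] = (out["mrd"] >= 3e-4).astype(int)
        out["log_mrd"] = np.log10(out["mrd"] + MRD_EPSILON)
    if "age_years" in out and "wcc" in out:
        standard = (out["age_years"] >= 1) & (out["age_years"] < 10) & (out["wcc"] < 50)
        out["nci_risk"] = np.where(standard, "standard", "high")
    return out


def km_estimate(
    times, indicators, by_group=None
) -> dict[str, KMCurve]:
    """Kaplan–Meier estimate per group.

    Product-limit estimator with simultaneous decrement at tied event times,
    Greenwood variance and log(−log)-transformed 95% CIs.  With
    ``by_group=None`` a single curve keyed ``"all"`` is returned.
    """
    times = np.asarray(times, dtype=float)
    indicators = np.asarray(indicators, dtype=int)
    if len(times) == 0 or np.all(times <= 0):
        raise ValueError("need at least one positive follow-up time")
    groups = (
        np.asarray(by_group) if by_group is not None else np.repeat("all", len(times))
    )
    curves: dict[str, KMCurve] = {}
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() == 0:
            continue
        kmf = KaplanMeierFitter(label=str(g)).fit(times[mask], indicators[mask])
        tab = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0].to_numpy()
        grid = kmf.survival_function_.index.to_numpy(dtype=float)
        # Greenwood: Var(S) = S^2 * cumsum d / (n (n - d))
        d = tab["observed"].to_numpy(dtype=float)
        n_at = tab["at_risk"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(n_at > d, d / (n_at * (n_at - d)), 0.0)
        var = surv**2 * np.cumsum(terms)
        ci = kmf.confidence_interval_
        curves[str(g)] = KMCurve(
            times=grid,
            survival=surv,
            variance=var,
            ci_lower=ci.iloc[:, 0].to_numpy(),
            ci_upper=ci.iloc[:, 1].to_numpy(),
            at_risk=n_at,
            label=str(g),
        )
    return curves


def km_at(curve: KMCurve, t: float) -> tuple[float, float, float]:
    """Read (survival, ci_lower, ci_upper) from the step function at time t."""
    idx = np.searchsorted(curve.times, t, side="right") - 1
    idx = max(idx, 0)
    return (
        float(curve.survival[idx]),
        float(curve.ci_lower[idx]),
        float(curve.ci_upper[idx]),
    )


def logrank(times, indicators, groups) -> tuple[float, float]:
    """Log-rank chi-square test across groups; returns (statistic, p)."""
    groups = np.asarray(groups)
    if len(pd.unique(groups)) < 2:
        raise ValueError("log-rank test requires at least two groups")
    res = multivariate_logrank_test(
        np.asarray(times, dtype=float), groups, np.asarray(indicators, dtype=int)
    )
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    df: pd.DataFrame,
    covariates: list[str],
    endpoint: str = "relapse",
    duration_col: str | None = None,
    event_col: str | None = None,
    ties: str = "efron",
) -> CoxResult:
    """Fit a Cox proportional-hazards model.

    ``covariates`` are column names (numeric; encode categoricals first).
    The partial likelihood uses the Efron tie correction by default; CIs and
    p-values are Wald.  Raises on zero events or constant covariates.
    """
    if duration_col is None or event_col is None:
        duration_col, event_col = ENDPOINT_COLUMNS[endpoint]
    data = df[[duration_col, event_col] + list(covariates)].dropna()
    n_events = int(data[event_col].sum())
    if n_events < 1:
        raise ValueError("cannot fit a proportional-hazards model with no events")
    for c in covariates:
        if data[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant across all rows")
    cph = CoxPHFitter()
    cph.fit(data, duration_col=duration_col, event_col=event_col)
    s = cph.summary
    out = pd.DataFrame(
        {
            "coef": s["coef"],
            "se": s["se(coef)"],
            "hr": s["exp(coef)"],
            "hr_lower": s["exp(coef) lower 95%"],
            "hr_upper": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    return CoxResult(
        summary=out,
        log_likelihood=float(cph.log_likelihood_),
        n=len(data),
        n_events=n_events,
        model=cph,
    )


def harrell_c(df: pd.DataFrame, result: CoxResult, endpoint: str = "relapse") -> float:
    """Harrell's concordance index of a fitted model on a dataset.

    Fraction of comparable pairs whose predicted risk orders the observed
    survival correctly, ties counted 1/2.
    """
    duration_col, event_col = ENDPOINT_COLUMNS[endpoint]
    covs = list(result.summary.index)
    data = df[[duration_col, event_col] + covs].dropna()
    risk = data[covs].to_numpy() @ result.summary["coef"].to_numpy()
    return float(
        concordance_index(data[duration_col], -risk, data[event_col])
    )


def schoenfeld_check(
    result: CoxResult, df: pd.DataFrame, endpoint: str = "relapse"
) -> dict:
    """Proportional-hazards check via scaled Schoenfeld residuals.

    Residuals are regressed on event time (identity transform); returns
    per-covariate chi-square p-values and a global p from the summed
    chi-square statistics on k degrees of freedom.
    """
    duration_col, event_col = ENDPOINT_COLUMNS[endpoint]
    covs = list(result.summary.index)
    data = df[[duration_col, event_col] + covs].dropna()
    if int(data[event_col].sum()) < 2:
        raise ValueError("proportionality test requires at least two events")
    res = proportional_hazard_test(result.model, data, time_transform="identity")
    stat = res.summary["test_statistic"]
    per_covariate = {
        c: {"statistic": float(stat.loc[c]), "p": float(res.summary["p"].loc[c])}
        for c in stat.index
    }
    global_stat = float(stat.sum())
    global_p = float(stats.chi2.sf(global_stat, df=len(stat)))
    return {"per_covariate": per_covariate, "global_statistic": global_stat,
            "global_p": global_p}


def cochran_q(log_hrs, ses) -> tuple[float, int, float]:
    """Cochran's Q over subgroup log hazard ratios with inverse-variance
    weights; returns (Q, df, p)."""
    b = np.asarray(log_hrs, dtype=float)
    w = 1.0 / np.asarray(ses, dtype=float) ** 2
    pooled = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - pooled) ** 2))
    dof = len(b) - 1
    return q, dof, float(stats.chi2.sf(q, dof)) if dof > 0 else 1.0


def subgroup_forest(
    df: pd.DataFrame,
    variables: list[str] | None = None,
    endpoint: str = "relapse",
    group_col: str = "merged_group",
) -> SubgroupForest:
    """Univariate group-effect Cox fits within each subgroup level, plus a
    Cochran's Q heterogeneity test over the subgroup log hazard ratios.

    Levels with no events in either arm are dropped with a warning.
    """
    if variables is None:
        variables = ["sex", "age_band", "wcc_band", "nci_risk"]
    duration_col, event_col = ENDPOINT_COLUMNS[endpoint]
    work = df[df[group_col].isin(["GR", "PR"])].copy()
    work["_pr"] = (work[group_col] == "PR").astype(int)

    rows, dropped = [], []
    for var in variables:
        for level in pd.unique(work[var].dropna()):
            sub = work[work[var] == level]
            events_by_arm = sub.groupby("_pr")[event_col].sum()
            if len(events_by_arm) < 2 or (events_by_arm < 1).any():
                dropped.append(f"{var}={level}")
                warnings.warn(
                    f"subgroup {var}={level} dropped: an arm has no events",
                    stacklevel=2,
                )
                continue
            res = cox_fit(sub, ["_pr"], duration_col=duration_col, event_col=event_col)
            r = res.summary.loc["_pr"]
            rows.append(
                {
                    "subgroup": var,
                    "level": str(level),
                    "n": res.n,
                    "events": res.n_events,
                    "coef": float(r["coef"]),
                    "se": float(r["se"]),
                    "hr": float(r["hr"]),
                    "hr_lower": float(r["hr_lower"]),
                    "hr_upper": float(r["hr_upper"]),
                    "p": float(r["p"]),
                }
            )
    if not rows:
        raise ValueError("all subgroups dropped: no level has events in both arms")
    table = pd.DataFrame(rows)
    q, dof, p = cochran_q(table["coef"], table["se"])
    return SubgroupForest(rows=table, q_statistic=q, q_df=dof, q_p=p,
                          dropped=tuple(dropped))


def _categorical_p(sub: pd.DataFrame, var: str, group_col: str) -> tuple[float, str]:
    tab = pd.crosstab(sub[var], sub[group_col])
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return float("nan"), "degenerate"
    chi2, p, _, expected = stats.chi2_contingency(tab)
    if (expected < 5).any():
        if tab.shape == (2, 2):
            _, p = stats.fisher_exact(tab)
            return float(p), "fisher"
        return float(p), "chi2_sparse"
    return float(p), "chi2"


def run_validation(
    df: pd.DataFrame,
    out_dir: str | Path | None = None,
    endpoints: tuple[str, ...] = ("relapse", "event", "death"),
    group_col: str = "merged_group",
) -> dict:
    """Produce the full Table-1-style validation report for a classified cohort.

    Returns a nested dict (and optionally writes ``table1.csv``,
    ``km_<endpoint>.csv``, ``forest_<endpoint>.csv`` and ``diagnostics.json``
    to ``out_dir``) containing: group sizes, demographic comparisons,
    per-endpoint event counts, 5-year KM estimates with CI, log-rank p,
    unadjusted and MRD-adjusted hazard ratios with CI and p, concordance,
    proportionality diagnostics, the subgroup forest, and a
    definite-vs-provisional comparison.
    """
    data = prepare_survival_dataset(df)
    analysed = data[data[group_col].isin(["GR", "PR"])].copy()
    if len(analysed) == 0:
        raise ValueError("no GR/PR rows to validate")
    analysed["_pr"] = (analysed[group_col] == "PR").astype(int)
    single_arm = analysed["_pr"].nunique() < 2

    report: dict = {
        "n": {
            "total": int(len(analysed)),
            "GR": int((analysed[group_col] == "GR").sum()),
            "PR": int((analysed[group_col] == "PR").sum()),
        },
        "warnings": [],
    }
    if single_arm:
        report["warnings"].append("single risk group present: no HR rows computed")

    demo_rows = []
    for var in ("sex", "age_band", "wcc_band", "mrd_ge_0.01pct", "mrd_ge_0.03pct"):
        if var not in analysed:
            continue
        counts = pd.crosstab(analysed[var], analysed[group_col])
        p, method = (
            _categorical_p(analysed, var, group_col) if not single_arm else (float("nan"), "degenerate")
        )
        for level, row in counts.iterrows():
            demo_rows.append(
                {
                    "variable": var,
                    "level": str(level),
                    **{g: int(row.get(g, 0)) for g in ("GR", "PR")},
                    "p": p,
                    "method": method,
                }
            )
    report["table1_demographics"] = pd.DataFrame(demo_rows)

    km_frames = {}
    report["endpoints"] = {}
    for ep in endpoints:
        dur, ev = ENDPOINT_COLUMNS[ep]
        if dur not in analysed:
            continue
        block: dict = {
            "events": {
                g: int(analysed.loc[analysed[group_col] == g, ev].sum())
                for g in ("GR", "PR")
            }
        }
        curves = km_estimate(analysed[dur], analysed[ev], analysed[group_col])
        km_frames[ep] = pd.concat(
            [c.to_frame().assign(group=g) for g, c in curves.items()],
            ignore_index=True,
        )
        block["km_5yr"] = {
            g: dict(zip(("survival", "ci_lower", "ci_upper"), km_at(c, 5.0)))
            for g, c in curves.items()
        }
        if not single_arm:
            stat, p = logrank(analysed[dur], analysed[ev], analysed[group_col])
            block["logrank"] = {"statistic": stat, "p": p}
            unadj = cox_fit(analysed, ["_pr"], duration_col=dur, event_col=ev)
            block["unadjusted"] = _hr_block(unadj, "_pr")
            block["concordance"] = harrell_c(
                analysed, unadj, endpoint=ep
            ) if ep in ENDPOINT_COLUMNS else None
            block["proportionality"] = schoenfeld_check(unadj, analysed, endpoint=ep)
            if "log_mrd" in analysed:
                adj = cox_fit(
                    analysed, ["_pr", "log_mrd"], duration_col=dur, event_col=ev
                )
                block["mrd_adjusted"] = _hr_block(adj, "_pr")
            try:
                forest = subgroup_forest(analysed, endpoint=ep, group_col=group_col)
                block["forest"] = {
                    "rows": forest.rows,
                    "heterogeneity": {
                        "Q": forest.q_statistic,
                        "df": forest.q_df,
                        "p": forest.q_p,
                    },
                    "dropped": list(forest.dropped),
                }
            except ValueError as exc:
                report["warnings"].append(f"forest[{ep}]: {exc}")
        report["endpoints"][ep] = block

    report["definite_vs_provisional"] = _definite_vs_provisional(data, endpoints)

    if out_dir is not None:
        _write_report(report, km_frames, Path(out_dir))
    return report


def _hr_block(result: CoxResult, covariate: str) -> dict:
    lo, hi = result.ci(covariate)
    return {
        "hr": result.hr(covariate),
        "ci_lower": lo,
        "ci_upper": hi,
        "p": result.p(covariate),
        "n": result.n,
        "events": result.n_events,
    }


def _definite_vs_provisional(data: pd.DataFrame, endpoints) -> dict:
    if "group" not in data:
        return {}
    prov = data["group"].isin(["P-GR", "P-PR"])
    defi = data["group"].isin(["D-GR", "D-PR"])
    if prov.sum() == 0 or defi.sum() == 0:
        return {"note": "definite or provisional stratum empty"}
    work = data[prov | defi].copy()
    work["_certainty"] = np.where(work["group"].str.startswith("P"), "provisional", "definite")
    out = {
        "n": work["_certainty"].value_counts().to_dict(),
    }
    for ep in endpoints:
        dur, ev = ENDPOINT_COLUMNS[ep]
        if dur not in work:
            continue
        try:
            stat, p = logrank(work[dur], work[ev], work["_certainty"])
            out[ep] = {"logrank_statistic": stat, "logrank_p": p}
        except ValueError:
            continue
    return out


def _fmt(x):
    if isinstance(x, float):
        return float(f"{x:.10g}")
    return x


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, (np.floating, float)):
        return _fmt(float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _write_report(report: dict, km_frames: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report["table1_demographics"].to_csv(
        out_dir / "table1.csv", index=False, float_format="%.10g"
    )
    for ep, frame in km_frames.items():
        frame.to_csv(out_dir / f"km_{ep}.csv", index=False, float_format="%.10g")
    for ep, block in report["endpoints"].items():
        forest = block.get("forest")
        if forest is not None:
            forest["rows"].to_csv(
                out_dir / f"forest_{ep}.csv", index=False, float_format="%.10g"
            )
    with open(out_dir / "diagnostics.json", "w") as f:
        json.dump(_jsonable(report), f, indent=1)
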