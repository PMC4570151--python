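"""Effect estimation: 2x2 odds ratios, group tests, adjusted logistic ORs.

Odds ratios are oriented balanced-relative-to-saline, so OR <1 favors the
balanced crystalloid.  Confidence intervals are Wald intervals on the log
odds ratio with no continuity correction; a zero cell makes the OR
undefined (``defined=False``) rather than raising.  Adjusted ORs come from
unconditional logistic regression of the outcome on the cohort indicator,
the APS, and any residually imbalanced covariates — matched-pair structure
is deliberately not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .matching import EstimationError, build_design

Z95 = stats.norm.ppf(0.975)


@dataclass
class TwoByTwo:
    """Event counts: a/b = balanced events/non-events, c/d = saline."""
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 counts must be non-negative")

    @classmethod
    def from_events(cls, events_balanced: int, n_balanced: int,
                    events_saline: int, n_saline: int) -> "TwoByTwo":
        return cls(events_balanced, n_balanced - events_balanced,
                   events_saline, n_saline - events_saline)


@dataclass
class EffectResult:
    outcome: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float | None = None
    adjusted: bool = False
    adjusters: list[str] = field(default_factory=list)
    defined: bool = True
    counts: TwoByTwo | None = None


def or_2x2(t: TwoByTwo, outcome: str = "") -> EffectResult:
    """Unadjusted odds ratio with 95% Wald CI from a 2x2 table.

    OR = (a/b)/(c/d); CI = exp(ln OR +/- 1.96 sqrt(1/a+1/b+1/c+1/d)).
    Any zero cell yields ``defined=False`` with NaN estimates.
    """
    if min(t.a, t.b, t.c, t.d) == 0:
        return EffectResult(outcome, np.nan, np.nan, np.nan, defined=False,
                            counts=t)
    log_or = np.log(t.a / t.b) - np.log(t.c / t.d)
    se = np.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    p = 2 * stats.norm.sf(abs(log_or) / se)
    return EffectResult(outcome, float(np.exp(log_or)),
                        float(np.exp(log_or - Z95 * se)),
                        float(np.exp(log_or + Z95 * se)),
                        p_value=float(p), counts=t)


def chi_square(table) -> tuple[float, float]:
    """Pearson chi-square without continuity correction; (statistic, P)."""
    arr = np.asarray(table, dtype=float)
    if arr.sum() == 0:
        raise ValueError("all-zero contingency table")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(chi2), float(p)


def t_test(x, y) -> tuple[float, float]:
    """Two-sample pooled-variance Student's t test; (statistic, two-sided P)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("zero pooled variance")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def adjusted_or(outcome_flags: pd.Series, cohort_labels: pd.Series,
                aps: pd.Series | None = None,
                adjusters: pd.DataFrame | None = None,
                outcome: str = "") -> EffectResult:
    """Covariate-adjusted OR from unconditional logistic regression.

    Model: outcome ~ cohort-indicator (+ APS) (+ residual covariates).
    The reported OR is the exponentiated cohort coefficient with its Wald
    95% CI.  Raises :class:`EstimationError` on separation/non-convergence.
    """
    y = outcome_flags.astype(float).to_numpy()
    treat = (cohort_labels == "balanced").astype(float)
    parts = [treat.rename("balanced")]
    names = []
    if aps is not None:
        parts.append(aps.astype(float).rename("aps"))
        names.append("aps")
    if adjusters is not None and adjusters.shape[1] > 0:
        parts.append(adjusters.astype(float))
        names += list(adjusters.columns)
    X = sm.add_constant(pd.concat(parts, axis=1), has_constant="add")
    import warnings
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X.to_numpy(dtype=float)).fit(disp=0, maxiter=200)
    except Exception as exc:
        raise EstimationError(f"adjusted model failed: {exc}") from exc
    params = pd.Series(res.params, index=X.columns)
    if (not res.mle_retvals.get("converged", False)
            or not np.all(np.isfinite(params)) or abs(params["balanced"]) > 30):
        raise EstimationError("adjusted model did not converge")
    se = pd.Series(res.bse, index=X.columns)["balanced"]
    beta = params["balanced"]
    pvals = pd.Series(res.pvalues, index=X.columns)
    return EffectResult(outcome, float(np.exp(beta)),
                        float(np.exp(beta - Z95 * se)),
                        float(np.exp(beta + Z95 * se)),
                        p_value=float(pvals["balanced"]),
                        adjusted=True, adjusters=names)


def estimate_outcome_table(outcome_df: pd.DataFrame, cohort_labels: pd.Series,
                           outcome_cols: list[str],
                           aps: pd.Series | None = None,
                           adjusters: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-outcome 2x2 percentages, unadjusted and adjusted OR rows."""
    rows = []
    n_bal = int((cohort_labels == "balanced").sum())
    n_sal = int((cohort_labels == "saline").sum())
    for col in outcome_cols:
        flags = outcome_df[col].fillna(False).astype(bool)
        a = int(flags[cohort_labels == "balanced"].sum())
        c = int(flags[cohort_labels == "saline"].sum())
        t = TwoByTwo.from_events(a, n_bal, c, n_sal)
        un = or_2x2(t, outcome=col)
        row = {"outcome": col,
               "pct_saline": round(100 * c / n_sal, 2) if n_sal else np.nan,
               "n_saline": c,
               "pct_balanced": round(100 * a / n_bal, 2) if n_bal else np.nan,
               "n_balanced": a,
               "or_unadjusted": un.odds_ratio, "ci_low_unadjusted": un.ci_low,
               "ci_high_unadjusted": un.ci_high, "defined": un.defined}
        try:
            adj = adjusted_or(flags, cohort_labels, aps=aps,
                              adjusters=adjusters, outcome=col)
            row.update({"or_adjusted": adj.odds_ratio,
                        "ci_low_adjusted": adj.ci_low,
                        "ci_high_adjusted": adj.ci_high})
        except EstimationError:
            row.update({"or_adjusted": np.nan, "ci_low_adjusted": np.nan,
                        "ci_high_adjusted": np.nan})
        rows.append(row)
    return pd.DataFrame(rows)


def outcome_table_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Outcome-table analogue straight from published-style event counts.

    ``counts`` needs columns outcome, events_saline, events_balanced,
    n_saline, n_balanced.  Used to reproduce a reported matched-cohort
    table from its printed cells.
    """
    rows = []
    for r in counts.itertuples(index=False):
        t = TwoByTwo.from_events(int(r.events_balanced), int(r.n_balanced),
                                 int(r.events_saline), int(r.n_saline))
        res = or_2x2(t, outcome=r.outcome)
        rows.append({"outcome": r.outcome,
                     "pct_saline": round(100 * r.events_saline / r.n_saline, 2),
                     "n_saline": int(r.events_saline),
                     "pct_balanced": round(100 * r.events_balanced / r.n_balanced, 2),
                     "n_balanced": int(r.events_balanced),
                     "or_unadjusted": res.odds_ratio,
                     "ci_low_unadjusted": res.ci_low,
                     "ci_high_unadjusted": res.ci_high,
                     "defined": res.defined})
    return pd.DataFrame(rows)


def build_report(balance: pd.DataFrame | None,
                 fluid_summary: pd.DataFrame | None,
                 outcome_table: pd.DataFrame | None,
                 outdir=None) -> dict[str, pd.DataFrame]:
    """Assemble the report bundle: matched-characteristics table, fluid
    volume/chloride summary, per-outcome OR table, and forest-plot data.
    Writes CSVs under ``outdir`` when given."""
    report: dict[str, pd.DataFrame] = {}
    report["characteristics"] = (balance if balance is not None
                                 else pd.DataFrame())
    report["fluids"] = (fluid_summary if fluid_summary is not None
                        else pd.DataFrame())
    report["outcomes"] = (outcome_table if outcome_table is not None
                          else pd.DataFrame())
    forest_rows = []
    if outcome_table is not None and not outcome_table.empty:
        for r in outcome_table.itertuples(index=False):
            forest_rows.append({"outcome": r.outcome, "adjusted": False,
                                "or": r.or_unadjusted,
                                "ci_low": r.ci_low_unadjusted,
                                "ci_high": r.ci_high_unadjusted})
            if "or_adjusted" in outcome_table.columns:
                forest_rows.append({"outcome": r.outcome, "adjusted": True,
                                    "or": r.or_adjusted,
                                    "ci_low": r.ci_low_adjusted,
                                    "ci_high": r.ci_high_adjusted})
    report["forest"] = pd.DataFrame(
        forest_rows, columns=["outcome", "adjusted", "or", "ci_low", "ci_high"])
    if outdir is not None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in report.items():
            df.to_csv(outdir / f"report_{name}.csv", index=False)
    return report


def fluid_summary_table(cohort_table: pd.DataFrame) -> pd.DataFrame:
    """Per-cohort totals of monitored-fluid volume and chloride load."""
    rows = []
    for cohort, grp in cohort_table.groupby("cohort"):
        rows.append({
            "cohort": cohort, "n": len(grp),
            "mean_volume_l": grp["total_volume_l"].mean(),
            "median_volume_l": grp["total_volume_l"].median(),
            "mean_chloride_load_mmol": grp["chloride_load_mmol"].mean(),
            "median_chloride_load_mmol": grp["chloride_load_mmol"].median(),
            "mean_delivered_chloride_mmol_per_l":
                grp["mean_chloride_mmol_per_l"].mean(),
        })
    return pd.DataFrame(rows)
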