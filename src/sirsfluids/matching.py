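"""Propensity model, digit-greedy 1:1 matching, and balance diagnostics.

The propensity score is the modeled probability of receiving the calcium-free
balanced crystalloid, fit by logistic regression with backward elimination of
covariates (a term is dropped while its Wald P exceeds the stay threshold,
0.20 by default).  Matching follows the classic case-control greedy macro:
cases (the smaller arm) are paired without replacement to controls whose
score agrees when rounded to d digits, with d stepping from 8 down to 1.
Balance diagnostics give pre/post-match tests and standardized differences;
covariates still different at P <0.1 after matching feed the adjusted
outcome models together with the APS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

DEFAULT_STAY_THRESHOLD = 0.20
DIGIT_TIERS = range(8, 0, -1)


class EstimationError(RuntimeError):
    """Model estimation failed (separation or non-convergence)."""


@dataclass
class PropensityModel:
    retained: list[str]
    params: pd.Series
    scores: pd.Series          # indexed by encounter_id, open interval (0,1)
    candidate: list[str] = field(default_factory=list)

    def predict(self, design: pd.DataFrame) -> pd.Series:
        X = sm.add_constant(design[self.retained], has_constant="add")
        lin = X.to_numpy(dtype=float) @ self.params.reindex(X.columns).to_numpy()
        return pd.Series(1.0 / (1.0 + np.exp(-lin)), index=design.index)


def build_design(cohort_table: pd.DataFrame,
                 covariates: list[str]) -> pd.DataFrame:
    """Expand covariates into a numeric design matrix (dummy-coded
    categoricals with the first level dropped)."""
    df = cohort_table.set_index("encounter_id")[covariates]
    num = df.select_dtypes(include=["number", "bool"]).astype(float)
    cat = df.select_dtypes(exclude=["number", "bool"])
    parts = [num]
    # reference level = modal level, so rare levels become explicit dummies
    # (individually screenable for quasi-separation)
    for col in cat.columns:
        dummies = pd.get_dummies(cat[col], prefix=col, dtype=float)
        ref = f"{col}_{cat[col].mode().iloc[0]}"
        parts.append(dummies.drop(columns=ref))
    return pd.concat(parts, axis=1)


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    import warnings
    arr = X.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, arr).fit(disp=0, maxiter=100)
            if not res.mle_retvals.get("converged", False):
                res = sm.Logit(y, arr).fit(disp=0, method="bfgs", maxiter=500)
        except Exception as exc:  # statsmodels raises on perfect separation
            raise EstimationError(f"propensity fit failed: {exc}") from exc
    params = np.asarray(res.params)
    if (not res.mle_retvals.get("converged", False)
            or not np.all(np.isfinite(params)) or np.any(np.abs(params) > 30)):
        raise EstimationError("propensity fit did not converge "
                              "(possible separation)")
    return res


def _screen_terms(y: np.ndarray, design: pd.DataFrame,
                  terms: list[str]) -> list[str]:
    """Drop binary terms that quasi-separate the arms (one empty
    treatment-by-term cell): backward elimination would discard them with
    P ~ 1, but they stall the likelihood maximization.  A term that
    PERFECTLY predicts the arm (both discordant cells empty) is an
    estimation error, not a screening case.
    """
    kept = []
    seen: set[bytes] = set()
    for t in terms:
        col = design[t].to_numpy(dtype=float)
        key = col.tobytes()
        if key in seen:        # exact duplicate column -> singular design
            continue
        seen.add(key)
        vals = np.unique(col)
        if len(vals) != 2:
            kept.append(t)
            continue
        hi = col == vals.max()
        n10 = np.sum(hi & (y == 0))
        n01 = np.sum(~hi & (y == 1))
        n11 = np.sum(hi & (y == 1))
        n00 = np.sum(~hi & (y == 0))
        if (n10 == 0 and n01 == 0) or (n11 == 0 and n00 == 0):
            raise EstimationError(
                f"covariate {t!r} perfectly predicts treatment")
        if min(n10, n01, n11, n00) == 0:
            continue
        kept.append(t)
    return kept


def fit_propensity(cohort_table: pd.DataFrame, covariates: list[str],
                   stay_threshold: float = DEFAULT_STAY_THRESHOLD
                   ) -> PropensityModel:
    """Backward-elimination logistic propensity model.

    The outcome is cohort=='balanced'.  Starting from all candidate design
    terms, the least-significant term is dropped while its Wald P exceeds
    ``stay_threshold``; the model is refit after each drop.  Raises
    :class:`EstimationError` on separation or non-convergence.
    """
    y = (cohort_table["cohort"] == "balanced").to_numpy(dtype=float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise EstimationError("need at least 2 records per arm")
    design = build_design(cohort_table, covariates)
    terms = [c for c in design.columns if design[c].nunique() > 1]
    terms = _screen_terms(y, design, terms)
    while True:
        X = sm.add_constant(design[terms], has_constant="add")
        res = _fit_logit(y, X)
        pvals = pd.Series(res.pvalues, index=X.columns).drop("const",
                                                             errors="ignore")
        if pvals.empty or pvals.max() <= stay_threshold:
            break
        terms.remove(pvals.idxmax())
    scores = pd.Series(res.predict(X.to_numpy(dtype=float)),
                       index=design.index)
    eps = 1e-12
    scores = scores.clip(eps, 1 - eps)
    params = pd.Series(res.params, index=X.columns)
    return PropensityModel(retained=terms, params=params, scores=scores,
                           candidate=list(design.columns))


@dataclass
class MatchResult:
    pairs: pd.DataFrame        # case_id, control_id, score_case, score_control, tier
    unmatched_cases: list
    unmatched_controls: list

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def matched_ids(self) -> list:
        return list(self.pairs["case_id"]) + list(self.pairs["control_id"])


def greedy_match(scores: pd.Series, labels: pd.Series, seed: int = 0,
                 case_label: str | None = None) -> MatchResult:
    """Digit-precision greedy 1:1 matching without replacement.

    At each tier d = 8 down to 1, every still-unmatched case whose score,
    rounded to d digits, equals some unmatched control's rounded score is
    paired with the lowest-indexed such control.  Case order is shuffled
    once per tier under ``seed``.  The case arm defaults to the smaller arm
    (ties: 'balanced').
    """
    labels = labels.reindex(scores.index)
    arms = labels.dropna().unique().tolist()
    if len(arms) < 2:
        return MatchResult(pd.DataFrame(columns=["case_id", "control_id",
                                                 "score_case", "score_control",
                                                 "tier"]),
                           list(scores.index[labels.notna()]), [])
    if case_label is None:
        counts = labels.value_counts()
        case_label = ("balanced" if "balanced" in counts.index
                      and counts.get("balanced", 0) <= counts.min()
                      else counts.idxmin())
    case_ids = list(scores.index[labels == case_label])
    control_ids = list(scores.index[labels != case_label])
    rng = np.random.default_rng(seed)

    unmatched_cases = list(case_ids)
    control_free = dict.fromkeys(control_ids, True)
    pairs = []
    for d in DIGIT_TIERS:
        if not unmatched_cases:
            break
        buckets: dict[float, list] = {}
        for cid in control_ids:
            if control_free[cid]:
                buckets.setdefault(round(float(scores[cid]), d), []).append(cid)
        order = list(unmatched_cases)
        rng.shuffle(order)
        still = set(unmatched_cases)
        for case in order:
            key = round(float(scores[case]), d)
            pool = buckets.get(key)
            if pool:
                ctrl = pool.pop(0)   # lowest-indexed free control
                control_free[ctrl] = False
                pairs.append((case, ctrl, float(scores[case]),
                              float(scores[ctrl]), d))
                still.discard(case)
        unmatched_cases = [c for c in unmatched_cases if c in still]
    pairs_df = pd.DataFrame(pairs, columns=["case_id", "control_id",
                                            "score_case", "score_control",
                                            "tier"])
    unmatched_controls = [c for c in control_ids if control_free[c]]
    return MatchResult(pairs_df, unmatched_cases, unmatched_controls)


def _smd_continuous(x: np.ndarray, y: np.ndarray) -> float:
    sp = np.sqrt((np.var(x, ddof=1) + np.var(y, ddof=1)) / 2.0)
    return 0.0 if sp == 0 else abs(x.mean() - y.mean()) / sp


def _smd_binary(p1: float, p0: float) -> float:
    pbar = (p1 + p0) / 2.0
    denom = np.sqrt(pbar * (1 - pbar)) if 0 < pbar < 1 else 0.0
    return 0.0 if denom == 0 else abs(p1 - p0) / denom


def _compare(df: pd.DataFrame, cov: str, arm: pd.Series) -> tuple[float, float]:
    """(P value, standardized difference) for one covariate between arms."""
    x = df.loc[arm == "balanced", cov]
    y = df.loc[arm == "saline", cov]
    if pd.api.types.is_numeric_dtype(df[cov]) and df[cov].nunique() > 2:
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            return 1.0, 0.0
        t, p = stats.ttest_ind(x, y, equal_var=True)
        return float(p), _smd_continuous(x.to_numpy(float), y.to_numpy(float))
    tab = pd.crosstab(arm, df[cov])
    if tab.shape[1] < 2:
        return 1.0, 0.0
    chi2, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
    smd = 0.0
    for level in tab.columns:
        p1 = tab.loc["balanced", level] / tab.loc["balanced"].sum()
        p0 = tab.loc["saline", level] / tab.loc["saline"].sum()
        smd = max(smd, _smd_binary(p1, p0))
    return float(p), smd


def balance_table(cohort_table: pd.DataFrame, covariates: list[str],
                  match: MatchResult | None = None,
                  residual_threshold: float = 0.1) -> pd.DataFrame:
    """Pre/post-match balance diagnostics per covariate.

    Continuous covariates use the pooled-variance t test, categoricals the
    chi-square test without continuity correction; standardized differences
    use the pooled standard deviation (max over levels for categoricals).
    ``residual_imbalance`` marks covariates with post-match P below
    ``residual_threshold`` — these feed the adjusted outcome models.
    """
    df = cohort_table.set_index("encounter_id")
    arm = df["cohort"]
    rows = []
    post_df = post_arm = None
    if match is not None and match.n_pairs > 0:
        ids = match.matched_ids()
        post_df = df.loc[ids]
        post_arm = post_df["cohort"]
    for cov in covariates:
        pre_p, pre_smd = _compare(df, cov, arm)
        if post_df is not None:
            post_p, post_smd = _compare(post_df, cov, post_arm)
        else:
            post_p, post_smd = np.nan, np.nan
        rows.append({"covariate": cov, "pre_p": pre_p, "pre_smd": pre_smd,
                     "post_p": post_p, "post_smd": post_smd,
                     "residual_imbalance": bool(post_p < residual_threshold)
                     if post_df is not None else False})
    return pd.DataFrame(rows)


def residual_covariates(balance: pd.DataFrame) -> list[str]:
    return balance.loc[balance["residual_imbalance"], "covariate"].tolist()
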