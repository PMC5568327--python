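"""Group-specific abstinence models.

The modelling pipeline mirrors standard epidemiological practice for
engagement studies: continuous baseline and utilization covariates are
centered at the group median and scaled by (Q3 - median) so a unit change
reads "one quartile above the group median"; network centralities enter on
the square-root scale, unstandardized, as week-1 level and week-2-to-12
change; a reference model is chosen by p-value stepwise selection among
baseline/utilization candidates at alpha = .10; the final logistic model is
maximum likelihood with sandwich (robust) standard errors — identical to a
GEE fit with working-independence correlation when each subject contributes
one record; predictive performance is the cross-validated AUC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

Z95 = 1.959963984540054  # normal 97.5% quantile for Wald intervals

NETWORK_TERMS_ALL = ["sqrt_in_week1", "sqrt_in_change",
                     "sqrt_outaware_week1", "sqrt_outaware_change"]
#: passive users have zero out-degree by definition, so their model carries
#: in-degree terms only
NETWORK_TERMS_PASSIVE = ["sqrt_in_week1", "sqrt_in_change"]


class SeparationError(RuntimeError):
    """The likelihood is degenerate (perfect separation or non-convergence)."""


# ------------------------------------------------------------------ features

def sqrt_change_features(series: pd.DataFrame) -> pd.DataFrame:
    """Square-root-scale week-1 and change network predictors.

    ``series`` is the (metric, week) MultiIndex frame from
    :func:`cessnet.netbuild.weekly_centralities`.  The change is computed on
    the square-root scale: sqrt(cumulative week 12) - sqrt(cumulative week 1).
    """
    last = series.columns.get_level_values("week").max()
    out = pd.DataFrame(index=series.index)
    for metric, stem in (("in_degree", "in"), ("out_degree_aware", "outaware")):
        w1 = np.sqrt(series[(metric, 1)].astype(float))
        wL = np.sqrt(series[(metric, last)].astype(float))
        out[f"sqrt_{stem}_week1"] = w1
        out[f"sqrt_{stem}_change"] = wL - w1
    return out


def scale_covariates(data: pd.DataFrame, labels: pd.DataFrame,
                     columns) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quartile-scale continuous covariates within each engagement group.

    Each value becomes (raw - group median) / (group Q3 - group median),
    quantiles by linear interpolation between order statistics.  When the
    group spread is degenerate (Q3 <= median) the covariate is centered only
    and flagged in the returned scaling table.

    Returns (scaled copy of ``data``, scaling table with one row per
    (group, column)).
    """
    df = data.merge(labels[["user_id", "group"]], on="user_id")
    scaled = df.copy()
    scaled[list(columns)] = scaled[list(columns)].astype(float)
    rows = []
    for grp, sub in df.groupby("group"):
        for col in columns:
            med = float(np.percentile(sub[col].dropna(), 50))
            q3 = float(np.percentile(sub[col].dropna(), 75))
            scale = q3 - med
            degenerate = scale <= 0
            idx = df.index[df["group"] == grp]
            if degenerate:
                scaled.loc[idx, col] = df.loc[idx, col] - med
            else:
                scaled.loc[idx, col] = (df.loc[idx, col] - med) / scale
            rows.append({"group": grp, "column": col, "location": med,
                         "scale": scale, "degenerate": degenerate})
    return scaled, pd.DataFrame(rows)


# ---------------------------------------------------------------- estimation

@dataclass
class ModelFit:
    """A fitted logistic abstinence model with robust inference."""

    group: str
    terms: list
    coef: pd.Series
    robust_se: pd.Series
    zvalues: pd.Series = field(init=False)
    pvalues: pd.Series = field(init=False)
    n: int = 0
    cv_auc: float = float("nan")
    apparent_auc: float = float("nan")

    def __post_init__(self):
        self.zvalues = self.coef / self.robust_se
        self.pvalues = pd.Series(2 * (1 - _norm_cdf(np.abs(self.zvalues))),
                                 index=self.coef.index)

    @property
    def odds_ratios(self) -> pd.DataFrame:
        """OR with Wald 95% CI for every non-intercept term."""
        lo = np.exp(self.coef - Z95 * self.robust_se)
        hi = np.exp(self.coef + Z95 * self.robust_se)
        return pd.DataFrame({"OR": np.exp(self.coef), "LCL": lo, "UCL": hi,
                             "p": self.pvalues})

    def report(self) -> pd.DataFrame:
        tab = self.odds_ratios.reset_index(names="term")
        tab.insert(0, "group", self.group)
        return tab


def _norm_cdf(x):
    from scipy.stats import norm
    return norm.cdf(x)


def _design(data: pd.DataFrame, terms) -> pd.DataFrame:
    X = sm.add_constant(data[list(terms)].astype(float), has_constant="add")
    return X


def _ml_fit(X: pd.DataFrame, y: np.ndarray):
    """Plain ML logistic fit; raises SeparationError on degeneracy."""
    import warnings
    try:
        with warnings.catch_warnings():
            # degeneracy is detected and raised below; don't also warn
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    except Exception as exc:  # PerfectSeparation, LinAlgError, ...
        raise SeparationError(str(exc)) from exc
    if not res.converged or np.abs(res.params).max() > 50 \
            or not np.isfinite(res.bse).all():
        raise SeparationError("logistic fit did not converge cleanly")
    return res


def fit_robust_logistic(data: pd.DataFrame, outcome: str, terms,
                        group: str = "") -> ModelFit:
    """Logistic regression with heteroskedasticity-robust (sandwich) SEs.

    With one record per independent subject this covariance equals the GEE
    working-independence robust covariance, so the point estimates are
    ordinary logistic ML and the SEs are the familiar robust ones.
    """
    import warnings
    y = data[outcome].to_numpy(dtype=float)
    X = _design(data, terms)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                maxiter=200, cov_type="HC0")
    except Exception as exc:
        raise SeparationError(str(exc)) from exc
    if not res.converged or np.abs(res.params).max() > 50:
        raise SeparationError("logistic fit did not converge cleanly")
    return ModelFit(group=group, terms=list(terms),
                    coef=res.params, robust_se=res.bse, n=len(y))


def stepwise_select(data: pd.DataFrame, outcome: str, candidates,
                    alpha: float = 0.10,
                    variant: str = "forward_backward") -> list:
    """Stepwise reference-model selection on Wald p-values.

    ``forward_backward`` (default): repeatedly add the smallest-p candidate
    with p < alpha, then drop any included term whose p >= alpha; iterate to
    a fixed point.  ``forward``: additions only.  Ties are broken by
    candidate order, so selection is deterministic given the data.
    Candidates whose trial fit is degenerate (perfect separation) are
    skipped and reported via the returned list's ``skipped`` attribute.
    """
    if variant not in ("forward_backward", "forward"):
        raise ValueError("variant must be 'forward_backward' or 'forward'")
    y = data[outcome].to_numpy(dtype=float)
    included: list = []
    skipped: list = []
    remaining = [c for c in candidates]
    seen = {frozenset()}
    while True:
        changed = False
        best, best_p = None, alpha
        for cand in remaining:
            try:
                res = _ml_fit(_design(data, included + [cand]), y)
            except SeparationError:
                if cand not in skipped:
                    skipped.append(cand)
                continue
            p = res.pvalues[cand]
            if p < best_p:
                best, best_p = cand, p
        if best is not None:
            included.append(best)
            remaining.remove(best)
            changed = True
        if variant == "forward_backward" and len(included) > 1:
            res = _ml_fit(_design(data, included), y)
            worst = res.pvalues[included].idxmax()
            if res.pvalues[worst] >= alpha:
                included.remove(worst)
                remaining.append(worst)
                changed = True
        state = frozenset(included)
        if not changed or state in seen:
            break
        seen.add(state)

    class _Selection(list):
        pass

    out = _Selection(included)
    out.skipped = skipped
    return out


def or_at_k_ties(or_per_unit: float, k: float,
                 lcl: float | None = None, ucl: float | None = None):
    """Odds ratio for accumulating ``k`` ties of a square-root-scale term.

    The model is linear in sqrt(ties), so k ties correspond to sqrt(k)
    square-root units and OR(k) = (per-unit OR)**sqrt(k).  Confidence limits
    transform endpoint-wise the same way (monotone transformation of the
    per-unit Wald limits).
    """
    if k < 0:
        raise ValueError("tie count k must be non-negative")
    e = math.sqrt(k)
    out = {"OR": or_per_unit ** e}
    if lcl is not None:
        out["LCL"] = lcl ** e
    if ucl is not None:
        out["UCL"] = ucl ** e
    return out


def fit_or_at_k_ties(fit: ModelFit, term: str, k: float) -> dict:
    """:func:`or_at_k_ties` applied to a fitted model's term."""
    ors = fit.odds_ratios
    return or_at_k_ties(ors.loc[term, "OR"], k,
                        ors.loc[term, "LCL"], ors.loc[term, "UCL"])


def cv_auc(data: pd.DataFrame, outcome: str, terms, folds: int = 10,
           seed: int = 0, max_retries: int = 20) -> tuple[float, float]:
    """Cross-validated and apparent AUC of a logistic model.

    Folds are stratified by outcome; the model is refit on each training
    split and the held-out linear predictors are pooled into one rank-based
    AUC.  If a split leaves a training fold with a single outcome class the
    fold assignment is re-randomized (bounded retries).
    """
    y = data[outcome].to_numpy(dtype=float)
    X = _design(data, terms)
    full = _ml_fit(X, y)
    apparent = roc_auc_score(y, full.predict(X))

    for attempt in range(max_retries):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=seed + attempt)
        scores = np.full(len(y), np.nan)
        ok = True
        for train, test in skf.split(X, y):
            if len(np.unique(y[train])) < 2:
                ok = False
                break
            try:
                res = _ml_fit(X.iloc[train], y[train])
            except SeparationError:
                ok = False
                break
            scores[test] = res.predict(X.iloc[test])
        if ok:
            return roc_auc_score(y, scores), apparent
    raise SeparationError(
        f"could not form {folds} folds with both outcome classes")


# ------------------------------------------------------------- orchestration

#: default candidate pool for reference-model selection: continuous baseline
#: scales plus website-utilization metrics (quartile-scaled upstream)
DEFAULT_CANDIDATES = [
    "age", "female", "education_some_college", "employed_fulltime",
    "hispanic", "ttfc_under5min", "ftnd", "confidence_quit", "desire_quit",
    "tempt_social", "tempt_negaffect", "tempt_craving",
    "piq_positive", "piq_negative", "extraversion", "neurosis", "openness",
    "doctor_advice", "illness_smoking", "sn_profile",
    "intention_ex", "intention_med",
    "return_visits", "time_on_site", "days_logged_in",
]

CONTINUOUS_COVARIATES = [
    "age", "ftnd", "confidence_quit", "desire_quit",
    "tempt_social", "tempt_negaffect", "tempt_craving",
    "piq_positive", "piq_negative", "extraversion", "neurosis", "openness",
    "return_visits", "time_on_site", "days_logged_in",
]


def fit_group_models(data: pd.DataFrame, labels: pd.DataFrame,
                     outcome: str = "abstinent_30d", alpha: float = 0.10,
                     folds: int = 10, seed: int = 0,
                     stepwise_variant: str = "forward_backward",
                     candidates=None) -> dict[str, ModelFit]:
    """Reference-model selection plus network terms, per engagement group.

    Passive users receive in-degree terms only; active users all four
    network terms; non-users (no network exposure) are not modelled.
    ``data`` must contain the outcome, candidate covariates (already
    quartile-scaled) and the four square-root network features.
    """
    candidates = list(DEFAULT_CANDIDATES if candidates is None else candidates)
    if "group" in data.columns:
        df = data
    else:
        df = data.merge(labels[["user_id", "group"]], on="user_id")
    fits = {}
    for grp, net_terms in (("passive", NETWORK_TERMS_PASSIVE),
                           ("active", NETWORK_TERMS_ALL)):
        sub = df[df["group"] == grp]
        if sub.empty:
            continue
        # zero-variance columns (possible in small groups) cannot be fit
        cands = [c for c in candidates
                 if c in sub.columns and sub[c].nunique() > 1]
        ref = stepwise_select(sub, outcome, cands, alpha=alpha,
                              variant=stepwise_variant)
        terms = list(ref) + [t for t in net_terms if sub[t].nunique() > 1]
        fit = fit_robust_logistic(sub, outcome, terms, group=grp)
        try:
            fit.cv_auc, fit.apparent_auc = cv_auc(sub, outcome, terms,
                                                  folds=folds, seed=seed)
        except SeparationError:
            pass
        fits[grp] = fit
    return fits
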