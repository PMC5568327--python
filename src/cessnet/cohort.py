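"""Engagement-based stratification of trial participants and group tables.

Participants are partitioned by dichotomizing two 3-month engagement metrics
at zero: *non-users* (no posts, no social-network page views), *passive
users* (page views but no posts) and *active users* (both).  The posts
metric counts messages in blogs, group discussions and the message board —
private messages and wall posts are excluded — so a participant whose only
activity is a wall post classifies as passive; such edge cases are recorded
in an audit frame rather than silently reassigned.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("non_user", "passive", "active")


def classify(profiles: pd.DataFrame) -> pd.DataFrame:
    """Assign each participant a non_user / passive / active label.

    Uses ``total_posts`` and ``total_page_views`` from the utilization
    profile.  The degenerate combination posts > 0 with views = 0 (possible
    in raw logs when a posting page view was not captured) is assigned to
    ``active`` and flagged in the ``anomalous_poster`` column.
    """
    posts = profiles["total_posts"].to_numpy()
    views = profiles["total_page_views"].to_numpy()
    group = np.where(posts > 0, "active",
                     np.where(views > 0, "passive", "non_user"))
    return pd.DataFrame({
        "user_id": profiles["user_id"],
        "group": group,
        "total_posts": posts,
        "total_page_views": views,
        "anomalous_poster": (posts > 0) & (views == 0),
    })


def group_table(roster: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Abstinence-by-group summary: N, median (IQR) posts and page views,
    and count (percent, one decimal) abstinent.  Survey non-response is
    assumed already coded as smoking."""
    df = labels.merge(roster[["user_id", "abstinent_30d"]], on="user_id")
    rows = []
    for grp in GROUPS:
        sub = df[df["group"] == grp]
        n = len(sub)
        row = {"group": grp, "n": n}
        if n:
            for col, name in (("total_posts", "posts"),
                              ("total_page_views", "page_views")):
                q1, med, q3 = np.percentile(sub[col], [25, 50, 75])
                row[f"{name}_median"] = med
                row[f"{name}_iqr"] = f"{q1:g}–{q3:g}"
            abst = int(sub["abstinent_30d"].sum())
            row["n_abstinent"] = abst
            row["pct_abstinent"] = abstinence_percent(abst, n)
        else:
            row.update({"posts_median": np.nan, "posts_iqr": "",
                        "page_views_median": np.nan, "page_views_iqr": "",
                        "n_abstinent": 0, "pct_abstinent": np.nan})
        rows.append(row)
    return pd.DataFrame(rows)


def abstinence_percent(n_abstinent: int, n: int) -> float:
    """Percent abstinent to one decimal, as reported in group tables."""
    if n == 0:
        return float("nan")
    return round(100.0 * n_abstinent / n, 1)


def fisher_exact_2xk(table) -> float:
    """Exact conditional test p-value for a 2 x k contingency table.

    Enumerates every table with the observed margins and sums the
    multivariate hypergeometric probabilities of tables no more probable
    than the observed one (the probability-ordering rule used by R's
    ``fisher.test``).  Deterministic, unlike resampling approximations.
    """
    t = np.asarray(table, dtype="int64")
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("table must be 2 x k")
    rows, cols, n = t.sum(1), t.sum(0), int(t.sum())
    denom = comb(n, int(rows[0]))

    def prob(top) -> float:
        num = 1
        for c, x in zip(cols, top):
            num *= comb(int(c), int(x))
        return num / denom

    p_obs = prob(t[0])
    k = len(cols)

    total = 0.0

    def rec(j, remaining, acc):
        nonlocal total
        if j == k - 1:
            if 0 <= remaining <= cols[j]:
                p = acc * comb(int(cols[j]), int(remaining)) / denom
                if p <= p_obs * (1 + 1e-9):
                    total += p
            return
        for x in range(min(int(remaining), int(cols[j])) + 1):
            rec(j + 1, remaining - x, acc * comb(int(cols[j]), x))

    rec(0, int(rows[0]), 1.0)
    return min(total, 1.0)


def compare_groups(roster: pd.DataFrame, labels: pd.DataFrame,
                   variables: dict) -> pd.DataFrame:
    """Between-group tests for baseline and utilization variables.

    ``variables`` maps column name -> kind:

    - ``"continuous"``: one-way ANOVA (baseline scales),
    - ``"categorical"``: chi-square test of independence,
    - ``"skewed"``: Kruskal-Wallis rank-sum (utilization/network metrics),
    - ``"sparse"``: exact 2 x k Fisher test (rare binary indicators).

    The bespoke content is the dispatch; the standard tests are delegated to
    scipy, except the exact 2 x k Fisher test which is enumerated here
    because resampling implementations are not deterministic.
    """
    df = labels[["user_id", "group"]].merge(roster, on="user_id")
    present = [g for g in GROUPS if (df["group"] == g).any()]
    if len(present) < 2:
        raise ValueError("need at least two non-empty groups to compare")
    rows = []
    for name, kind in variables.items():
        x = df[name]
        row = {"variable": name, "kind": kind, "p_value": np.nan, "note": ""}
        if x.nunique(dropna=True) < 2:
            row["note"] = "constant variable; test skipped"
            rows.append(row)
            continue
        samples = [x[df["group"] == g].dropna() for g in present]
        if kind == "continuous":
            row["p_value"] = stats.f_oneway(*samples).pvalue
        elif kind == "skewed":
            row["p_value"] = stats.kruskal(*samples).pvalue
        elif kind == "categorical":
            tab = pd.crosstab(x, df["group"])
            row["p_value"] = stats.chi2_contingency(tab.to_numpy()).pvalue
        elif kind == "sparse":
            tab = pd.crosstab(x, df["group"])
            if tab.shape[0] != 2:
                row["note"] = "sparse test requires a binary variable"
            else:
                row["p_value"] = fisher_exact_2xk(tab.to_numpy())
        else:
            raise ValueError(f"unknown variable kind {kind!r} for {name}")
        rows.append(row)
    return pd.DataFrame(rows)
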