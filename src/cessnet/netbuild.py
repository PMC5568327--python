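"""Directed reading-tie network from clickstream events.

A tie points from a content author to a reader: the edge Mary -> John means
John accessed content written by Mary.  Ties are aggregated over the blog,
group-discussion and private-message channels (message-board views are
excluded because their page structure does not identify the author read);
at most one tie exists per ordered (author, reader) pair, stamped with the
time and channel of the first qualifying view.

A tie Mary -> John is additionally *aware* when John later responded in the
same thread where he read Mary's content and Mary subsequently viewed John's
response — the awareness chain read(t1) <= respond(t2) <= author-view(t3),
with simultaneous timestamps broken by the event sequence number.  The
out-degree restricted to aware ties ("out-degree-aware") counts only readers
the author knows she has reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

TIE_CHANNELS = frozenset({"blog", "group", "pm"})

TIE_COLUMNS = ["source", "target", "formed_at", "channel", "aware", "aware_at"]

WEEKLY_METRICS = ("in_degree", "out_degree", "out_degree_aware")


class DataIntegrityError(ValueError):
    """An event references content that cannot exist."""


def _empty_ties() -> pd.DataFrame:
    return pd.DataFrame({
        "source": pd.Series(dtype=object),
        "target": pd.Series(dtype=object),
        "formed_at": pd.Series(dtype="datetime64[ns]"),
        "channel": pd.Series(dtype=object),
        "aware": pd.Series(dtype=bool),
        "aware_at": pd.Series(dtype="datetime64[ns]"),
        "seq": pd.Series(dtype="int64"),
    })


def _with_seq(events: pd.DataFrame) -> pd.DataFrame:
    if "seq" not in events.columns:
        events = events.assign(seq=np.arange(len(events), dtype="int64"))
    return events


def _qualifying_views(events: pd.DataFrame, channels, exclusions) -> pd.DataFrame:
    views = events[events["action"] == "view"]
    if views["content_id"].isna().any() or views["author_id"].isna().any():
        bad = views.index[views["content_id"].isna() | views["author_id"].isna()][0]
        raise DataIntegrityError(f"view event at index {bad} references unknown content")
    views = views[views["channel"].isin(channels)]
    views = views[views["user_id"] != views["author_id"]]
    if exclusions:
        views = views[~views["user_id"].isin(exclusions)
                      & ~views["author_id"].isin(exclusions)]
    return views


def build_ties(events: pd.DataFrame, channels=TIE_CHANNELS,
               exclusions=frozenset()) -> pd.DataFrame:
    """Aggregate the clickstream into one directed tie per (author, reader).

    Parameters
    ----------
    events : DataFrame with the event-log schema, time-sorted.
    channels : channels whose views form ties (default blog/group/pm).
    exclusions : account ids (staff, bots) whose events form no ties.
    """
    events = _with_seq(events)
    views = _qualifying_views(events, channels, exclusions)
    if views.empty:
        return _empty_ties()
    first = (views.sort_values(["timestamp", "seq"], kind="stable")
                  .drop_duplicates(["author_id", "user_id"], keep="first"))
    ties = pd.DataFrame({
        "source": first["author_id"].to_numpy(),
        "target": first["user_id"].to_numpy(),
        "formed_at": first["timestamp"].to_numpy(),
        "channel": first["channel"].to_numpy(),
        "aware": False,
        "aware_at": pd.NaT,
        "seq": first["seq"].to_numpy(),
    })
    return ties.sort_values(["formed_at", "seq"], kind="stable",
                            ignore_index=True)


def mark_awareness(ties: pd.DataFrame, events: pd.DataFrame,
                   channels=TIE_CHANNELS, exclusions=frozenset()) -> pd.DataFrame:
    """Flag ties whose read -> respond -> author-view chain completed.

    For a tie source -> target the chain requires, within one thread: the
    target viewed content authored by the source (t1), the target responded
    in that thread (t2 after t1), and the source viewed that response
    (t3 after t2).  ``aware_at`` is the earliest qualifying t3.
    """
    ties = ties.copy()
    if ties.empty:
        return ties
    events = _with_seq(events)
    views = _qualifying_views(events, channels, exclusions)

    # t1: earliest read per (author, reader, thread)
    reads = (views.sort_values(["timestamp", "seq"], kind="stable")
                  .drop_duplicates(["author_id", "user_id", "thread_id"])
                  .rename(columns={"author_id": "source", "user_id": "target",
                                   "timestamp": "t1", "seq": "s1"})
             )[["source", "target", "thread_id", "t1", "s1"]]

    resp = events[events["action"] == "respond"]
    if exclusions:
        resp = resp[~resp["user_id"].isin(exclusions)]
    resp = resp.rename(columns={"user_id": "target", "timestamp": "t2",
                                "seq": "s2", "content_id": "resp_content"}
                       )[["target", "thread_id", "t2", "s2", "resp_content"]]

    chain = reads.merge(resp, on=["target", "thread_id"])
    chain = chain[(chain["t2"] > chain["t1"])
                  | ((chain["t2"] == chain["t1"]) & (chain["s2"] > chain["s1"]))]
    if chain.empty:
        return ties

    # t3: source's views of the target's response content
    av = views.rename(columns={"user_id": "source", "timestamp": "t3",
                               "seq": "s3", "content_id": "resp_content"}
                      )[["source", "resp_content", "t3", "s3"]]
    chain = chain.merge(av, on=["source", "resp_content"])
    chain = chain[(chain["t3"] > chain["t2"])
                  | ((chain["t3"] == chain["t2"]) & (chain["s3"] > chain["s2"]))]
    if chain.empty:
        return ties

    aware_at = (chain.groupby(["source", "target"], sort=False)["t3"].min()
                     .rename("aware_at_new"))
    ties = ties.merge(aware_at, left_on=["source", "target"],
                      right_index=True, how="left")
    hit = ties["aware_at_new"].notna()
    ties.loc[hit, "aware"] = True
    ties.loc[hit, "aware_at"] = ties.loc[hit, "aware_at_new"]
    return ties.drop(columns="aware_at_new")


def weekly_centralities(ties: pd.DataFrame, roster: pd.DataFrame,
                        n_weeks: int = 12) -> pd.DataFrame:
    """Cumulative weekly degree centralities for each trial participant.

    Week w for a participant spans ``[registration + 7(w-1) days,
    registration + 7w days)``; ties are cumulative so each column is
    non-decreasing in w.  Ties to or from background community members count.

    Returns a DataFrame indexed by user_id with MultiIndex columns
    (metric, week) for metric in ``in_degree``/``out_degree``/
    ``out_degree_aware`` and week 1..n_weeks.
    """
    part = roster[roster["is_trial_participant"] & ~roster["is_excluded"]]
    if part["registration_time"].isna().any():
        bad = part.loc[part["registration_time"].isna(), "user_id"].iloc[0]
        raise ValueError(f"participant {bad} has no registration_time")
    uid = part["user_id"].to_numpy()
    reg = part["registration_time"].to_numpy()
    pos = {u: i for i, u in enumerate(uid)}

    out = np.zeros((len(uid), n_weeks, len(WEEKLY_METRICS)), dtype="int64")

    def _accumulate(users, times, metric):
        idx = np.array([pos.get(u, -1) for u in users])
        keep = idx >= 0
        if not keep.any():
            return
        idx, t = idx[keep], times[keep]
        offset = (t - reg[idx]) / np.timedelta64(7, "D")
        week = np.floor(offset).astype("int64") + 1
        keep2 = (week >= 1) & (week <= n_weeks)
        np.add.at(out[:, :, WEEKLY_METRICS.index(metric)],
                  (idx[keep2], week[keep2] - 1), 1)

    if not ties.empty:
        formed = ties["formed_at"].to_numpy()
        _accumulate(ties["target"].to_numpy(), formed, "in_degree")
        _accumulate(ties["source"].to_numpy(), formed, "out_degree")
        aw = ties[ties["aware"]]
        _accumulate(aw["source"].to_numpy(),
                    aw["aware_at"].to_numpy(), "out_degree_aware")

    out = out.cumsum(axis=1)
    cols = pd.MultiIndex.from_product([WEEKLY_METRICS, range(1, n_weeks + 1)],
                                      names=["metric", "week"])
    data = np.concatenate([out[:, :, i] for i in range(len(WEEKLY_METRICS))], axis=1)
    return pd.DataFrame(data, index=pd.Index(uid, name="user_id"), columns=cols)


@dataclass
class NetworkSummary:
    """Whole-network cohesion summary of the aggregated tie graph."""

    n_nodes: int
    n_ties: int
    n_posters: int
    lscc_size: int
    lscc_fraction: float
    avg_path_length: float
    clustering_coefficient: float       # average local, undirected projection
    transitivity: float                 # global triangle ratio, also undirected
    degree_ccdf: pd.DataFrame = field(default_factory=pd.DataFrame)


def degree_ccdf_table(ties: pd.DataFrame) -> pd.DataFrame:
    """Complementary cumulative degree counts: for each degree value d,
    the number of nodes with in-degree (resp. out-degree-aware) >= d."""
    if ties.empty:
        return pd.DataFrame(columns=["degree", "n_in_degree_ge",
                                     "n_out_degree_aware_ge"])
    indeg = ties.groupby("target").size()
    outaw = ties[ties["aware"]].groupby("source").size()
    degrees = np.arange(1, max(int(indeg.max()),
                               int(outaw.max()) if len(outaw) else 1) + 1)
    return pd.DataFrame({
        "degree": degrees,
        "n_in_degree_ge": [(indeg >= d).sum() for d in degrees],
        "n_out_degree_aware_ge": [(outaw >= d).sum() for d in degrees],
    })


def network_summary(ties: pd.DataFrame,
                    clustering: str = "average") -> NetworkSummary:
    """Summarize the aggregated directed network.

    ``avg_path_length`` is the mean directed shortest-path length over all
    ordered node pairs inside the largest strongly connected component.
    ``clustering`` selects which coefficient fills the headline field:
    ``"average"`` (mean local clustering on the undirected projection) or
    ``"transitivity"`` (global triangle ratio); both are always computed.
    """
    if clustering not in ("average", "transitivity"):
        raise ValueError("clustering must be 'average' or 'transitivity'")
    if ties.empty:
        return NetworkSummary(0, 0, 0, 0, float("nan"), float("nan"),
                              float("nan"), float("nan"))
    g = nx.DiGraph()
    g.add_edges_from(zip(ties["source"], ties["target"]))
    lscc = max(nx.strongly_connected_components(g), key=len)
    sub = g.subgraph(lscc)
    if len(lscc) >= 2:
        total = sum(sum(d.values())
                    for _, d in nx.shortest_path_length(sub))
        apl = total / (len(lscc) * (len(lscc) - 1))
    else:
        apl = float("nan")
    und = g.to_undirected()
    avg_local = nx.average_clustering(und)
    trans = nx.transitivity(und)
    return NetworkSummary(
        n_nodes=g.number_of_nodes(),
        n_ties=g.number_of_edges(),
        n_posters=int(ties["source"].nunique()),
        lscc_size=len(lscc),
        lscc_fraction=len(lscc) / g.number_of_nodes(),
        avg_path_length=float(apl),
        clustering_coefficient=float(avg_local if clustering == "average" else trans),
        transitivity=float(trans),
        degree_ccdf=degree_ccdf_table(ties),
    )


def write_edge_list(ties: pd.DataFrame, path) -> None:
    """Edge-list export: delimited text with tie attributes."""
    out = ties[TIE_COLUMNS].copy()
    for col in ("formed_at", "aware_at"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out["aware_at"] = out["aware_at"].fillna("")
    out.to_csv(path, index=False)
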