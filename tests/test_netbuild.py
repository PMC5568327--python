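"""Tie construction, awareness chain, weekly centralities, network summary —
worked examples plus brute-force oracles on random instances."""

import numpy as np
import pandas as pd
import pytest

from cessnet import netbuild, synth
from conftest import make_events, make_roster


# ------------------------------------------------------------- tie formation

def test_view_forms_author_to_reader_tie():
    ev = make_events([
        ("mary", 0, "post", "blog", "c1", "t1", "mary"),
        ("john", 10, "view", "blog", "c1", "t1", "mary"),
    ])
    ties = netbuild.build_ties(ev)
    assert len(ties) == 1
    t = ties.iloc[0]
    assert (t["source"], t["target"]) == ("mary", "john")
    assert t["formed_at"] == synth.EPOCH + pd.Timedelta(minutes=10)
    assert t["channel"] == "blog"


def test_degree_counts_members_not_documents():
    rows = [("mary", i, "post", "blog", f"c{i}", f"t{i}", "mary")
            for i in range(3)]
    rows += [("john", 10 + i, "view", "blog", f"c{i}", f"t{i}", "mary")
             for i in range(3)]
    ties = netbuild.build_ties(make_events(rows))
    assert len(ties) == 1  # three documents, one tie
    assert ties.iloc[0]["formed_at"] == synth.EPOCH + pd.Timedelta(minutes=10)


def test_self_view_board_and_excluded_form_no_ties():
    ev = make_events([
        ("mary", 0, "post", "blog", "c1", "t1", "mary"),
        ("mary", 5, "view", "blog", "c1", "t1", "mary"),       # self
        ("john", 6, "view", "board", "c2", "t2", "ann"),       # board excluded
        ("bot", 7, "view", "blog", "c1", "t1", "mary"),        # excluded account
        ("john", 8, "view", "blog", "c3", "t3", "bot"),        # excluded author
    ])
    ties = netbuild.build_ties(ev, exclusions={"bot"})
    assert ties.empty


def test_view_of_unknown_content_raises():
    ev = make_events([("john", 1, "view", "blog", "c9", "t9", "mary")])
    ev.loc[0, "author_id"] = None
    with pytest.raises(netbuild.DataIntegrityError):
        netbuild.build_ties(ev)


# ---------------------------------------------------------------- awareness

def _awareness_log(respond_first=False):
    """read -> respond -> author views response; optionally permute so the
    author's view precedes the response."""
    t3 = 15 if not respond_first else 8
    return make_events([
        ("mary", 0, "post", "blog", "c1", "t1", "mary"),
        ("john", 5, "view", "blog", "c1", "t1", "mary"),
        ("john", 10, "respond", "blog", "c2", "t1", "john"),
        ("mary", t3, "view", "blog", "c2", "t1", "john"),
    ])


def test_full_chain_marks_aware():
    ev = _awareness_log()
    ties = netbuild.mark_awareness(netbuild.build_ties(ev), ev)
    t = ties.set_index(["source", "target"]).loc[("mary", "john")]
    assert bool(t["aware"])
    assert t["aware_at"] == synth.EPOCH + pd.Timedelta(minutes=15)
    # the reverse tie john->mary (mary read the response) is not aware
    rev = ties.set_index(["source", "target"]).loc[("john", "mary")]
    assert not bool(rev["aware"])


def test_read_without_response_not_aware():
    ev = make_events([
        ("mary", 0, "post", "blog", "c1", "t1", "mary"),
        ("john", 5, "view", "blog", "c1", "t1", "mary"),
    ])
    ties = netbuild.mark_awareness(netbuild.build_ties(ev), ev)
    assert not ties["aware"].any()


def test_response_never_viewed_not_aware():
    ev = make_events([
        ("mary", 0, "post", "blog", "c1", "t1", "mary"),
        ("john", 5, "view", "blog", "c1", "t1", "mary"),
        ("john", 10, "respond", "blog", "c2", "t1", "john"),
    ])
    ties = netbuild.mark_awareness(netbuild.build_ties(ev), ev)
    assert not ties["aware"].any()


def test_awareness_is_order_sensitive():
    ev = _awareness_log(respond_first=True)  # author's view precedes response
    ties = netbuild.mark_awareness(netbuild.build_ties(ev), ev)
    assert not ties["aware"].any()


def test_awareness_timestamp_ties_resolved_by_sequence():
    ev = make_events([
        ("mary", 0, "post", "blog", "c1", "t1", "mary"),
        ("john", 5, "view", "blog", "c1", "t1", "mary"),
        ("john", 5, "respond", "blog", "c2", "t1", "john"),
        ("mary", 5, "view", "blog", "c2", "t1", "john"),
    ])
    ties = netbuild.mark_awareness(netbuild.build_ties(ev), ev)
    t = ties.set_index(["source", "target"]).loc[("mary", "john")]
    assert bool(t["aware"])  # seq order 1 < 2 < 3 at the same minute


def test_pm_thread_supports_awareness_chain():
    ev = make_events([
        ("mary", 0, "send_pm", "pm", "c1", "pm:john:mary", "mary"),
        ("john", 5, "view", "pm", "c1", "pm:john:mary", "mary"),
        ("john", 10, "respond", "pm", "c2", "pm:john:mary", "john"),
        ("mary", 20, "view", "pm", "c2", "pm:john:mary", "john"),
    ])
    ties = netbuild.mark_awareness(netbuild.build_ties(ev), ev)
    t = ties.set_index(["source", "target"]).loc[("mary", "john")]
    assert bool(t["aware"])


# ------------------------------------------------------ weekly centralities

def test_weekly_binning_and_cumulation():
    # reading ties on days 2, 10, 80 -> week1 in-degree 1, change 2
    rows = [(a, 0, "post", "blog", f"c{a}", f"t{a}", a)
            for a in ("a1", "a2", "a3")]
    for a, day in (("a1", 2), ("a2", 10), ("a3", 80)):
        rows.append(("p", day * 24 * 60, "view", "blog", f"c{a}", f"t{a}", a))
    ev = make_events(rows)
    roster = make_roster(["p"])
    series = netbuild.weekly_centralities(netbuild.build_ties(ev), roster)
    s = series.loc["p"]
    assert s[("in_degree", 1)] == 1
    assert s[("in_degree", 12)] == 3
    assert s[("in_degree", 12)] - s[("in_degree", 1)] == 2
    assert (s["out_degree"] == 0).all()


def test_participant_with_no_events_has_zero_series(small_run):
    events, roster, _ = small_run
    ties = netbuild.build_ties(events)
    series = netbuild.weekly_centralities(ties, roster)
    active = set(events["user_id"])
    idle = [u for u in series.index if u not in active]
    if idle:  # generator usually leaves some participants eventless
        assert (series.loc[idle].to_numpy() == 0).all()


def test_missing_registration_time_raises(small_run):
    events, roster, _ = small_run
    broken = roster.copy()
    broken.loc[broken.index[0], "registration_time"] = pd.NaT
    with pytest.raises(ValueError, match="registration_time"):
        netbuild.weekly_centralities(netbuild.build_ties(events), broken)


def _from_scratch_weekly(ties, roster, n_weeks=12):
    """Oracle: rebuild each week's cumulative network from scratch."""
    part = roster[roster["is_trial_participant"] & ~roster["is_excluded"]]
    frames = {}
    for uid, reg in zip(part["user_id"], part["registration_time"]):
        row = {}
        for w in range(1, n_weeks + 1):
            end = reg + pd.Timedelta(days=7 * w)
            upto = ties[ties["formed_at"] < end]
            row[("in_degree", w)] = (upto["target"] == uid).sum()
            row[("out_degree", w)] = (upto["source"] == uid).sum()
            aw = ties[ties["aware"] & (ties["aware_at"] < end)]
            row[("out_degree_aware", w)] = (aw["source"] == uid).sum()
        frames[uid] = row
    out = pd.DataFrame.from_dict(frames, orient="index")
    out.columns = pd.MultiIndex.from_tuples(out.columns,
                                            names=["metric", "week"])
    out.index.name = "user_id"
    return out


def test_weekly_series_matches_from_scratch_rebuild(small_run):
    events, roster, _ = small_run
    ties = netbuild.mark_awareness(netbuild.build_ties(events), events)
    fast = netbuild.weekly_centralities(ties, roster)
    sub = roster[roster["is_trial_participant"]].head(40)
    oracle = _from_scratch_weekly(ties, sub)
    pd.testing.assert_frame_equal(fast.loc[oracle.index].sort_index(axis=1),
                                  oracle.sort_index(axis=1),
                                  check_dtype=False)


def test_weekly_invariants_on_synthetic_run(small_run):
    events, roster, _ = small_run
    ties = netbuild.mark_awareness(netbuild.build_ties(events), events)
    series = netbuild.weekly_centralities(ties, roster)
    for metric in netbuild.WEEKLY_METRICS:
        block = series[metric].to_numpy()
        assert (np.diff(block, axis=1) >= 0).all()  # cumulative, monotone
    assert (series["out_degree_aware"].to_numpy()
            <= series["out_degree"].to_numpy()).all()


def test_degree_conservation(small_run):
    events, roster, _ = small_run
    ties = netbuild.build_ties(events)
    assert ties.groupby("target").size().sum() == len(ties)
    assert ties.groupby("source").size().sum() == len(ties)


def test_centralities_monotone_under_log_extension(small_run):
    events, roster, _ = small_run
    cut = events.iloc[: len(events) // 2]
    t_half = netbuild.build_ties(cut)
    t_full = netbuild.build_ties(events)
    s_half = netbuild.weekly_centralities(t_half, roster)
    s_full = netbuild.weekly_centralities(t_full, roster)
    assert (s_full.to_numpy() >= s_half.to_numpy()).all()


# ----------------------------------------------------------- network summary

def test_lscc_and_path_length_worked_example():
    ties = pd.DataFrame({
        "source": ["A", "B", "B"], "target": ["B", "A", "C"],
        "formed_at": pd.Timestamp("2012-03-01"), "channel": "blog",
        "aware": False, "aware_at": pd.NaT,
    })
    s = netbuild.network_summary(ties)
    assert s.lscc_size == 2
    assert s.avg_path_length == 1.0
    assert s.n_nodes == 3 and s.n_ties == 3 and s.n_posters == 2


def test_triangle_clustering_is_one():
    ties = pd.DataFrame({
        "source": ["A", "B", "C"], "target": ["B", "C", "A"],
        "formed_at": pd.Timestamp("2012-03-01"), "channel": "blog",
        "aware": False, "aware_at": pd.NaT,
    })
    s = netbuild.network_summary(ties)
    assert s.clustering_coefficient == 1.0
    assert s.transitivity == 1.0


def test_empty_tie_list_gives_empty_summary():
    from cessnet.netbuild import _empty_ties
    s = netbuild.network_summary(_empty_ties())
    assert s.n_nodes == 0 and s.n_ties == 0


def brute_force_summary(edges, n):
    """Exhaustive reachability / BFS / triangle oracle for tiny digraphs."""
    import itertools
    adj = {i: set() for i in range(n)}
    for a, b in edges:
        adj[a].add(b)
    # transitive closure by repeated squaring of the boolean matrix
    reach = np.eye(n, dtype=bool)
    A = np.zeros((n, n), dtype=bool)
    for a, b in edges:
        A[a, b] = True
    for _ in range(n):
        reach = reach | (reach @ A)
    mutual = reach & reach.T
    comps = []
    seen = set()
    for i in range(n):
        if i in seen:
            continue
        comp = {j for j in range(n) if mutual[i, j]}
        comps.append(comp)
        seen |= comp
    nodes_with_tie = {a for a, _ in edges} | {b for _, b in edges}
    comps = [c & nodes_with_tie for c in comps if c & nodes_with_tie]
    lscc = max(comps, key=lambda c: (len(c), sorted(c)))
    # BFS shortest paths within the LSCC
    total, pairs = 0, 0
    for s in lscc:
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v in lscc and v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for t in lscc:
            if t != s:
                total += dist[t]
                pairs += 1
    apl = total / pairs if pairs else float("nan")
    # average local clustering on the undirected projection
    und = {i: set() for i in range(n)}
    for a, b in edges:
        if a != b:
            und[a].add(b)
            und[b].add(a)
    cc = []
    for i in nodes_with_tie:
        nb = sorted(und[i])
        if len(nb) < 2:
            cc.append(0.0)
            continue
        links = sum(1 for x, y in itertools.combinations(nb, 2)
                    if y in und[x])
        cc.append(2 * links / (len(nb) * (len(nb) - 1)))
    return len(lscc), apl, float(np.mean(cc))


def test_summary_matches_brute_force_on_random_digraphs():
    rng = np.random.default_rng(42)
    for _ in range(120):
        n = rng.integers(2, 13)
        m = rng.integers(1, n * (n - 1) + 1)
        pairs = [(a, b) for a in range(n) for b in range(n) if a != b]
        idx = rng.choice(len(pairs), size=min(m, len(pairs)), replace=False)
        edges = [pairs[i] for i in idx]
        ties = pd.DataFrame({
            "source": [f"n{a}" for a, _ in edges],
            "target": [f"n{b}" for _, b in edges],
            "formed_at": pd.Timestamp("2012-03-01"), "channel": "blog",
            "aware": False, "aware_at": pd.NaT,
        })
        got = netbuild.network_summary(ties)
        lscc, apl, cc = brute_force_summary(edges, n)
        assert got.lscc_size == lscc
        if not np.isnan(apl):
            assert got.avg_path_length == pytest.approx(apl)
        assert got.clustering_coefficient == pytest.approx(cc)


def test_lscc_fraction_bounded_by_poster_fraction(small_run):
    events, _, _ = small_run
    ties = netbuild.build_ties(events)
    s = netbuild.network_summary(ties)
    assert s.lscc_size <= s.n_posters <= s.n_nodes
    assert s.lscc_fraction <= s.n_posters / s.n_nodes


def test_edge_list_round_trip(tmp_path, small_run):
    events, _, _ = small_run
    ties = netbuild.mark_awareness(netbuild.build_ties(events), events)
    path = tmp_path / "edges.csv"
    netbuild.write_edge_list(ties, path)
    back = pd.read_csv(path)
    assert len(back) == len(ties)
    assert back["aware"].sum() == ties["aware"].sum()
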