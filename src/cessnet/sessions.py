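"""Sessionization of page views and per-user website-utilization metrics.

A session is a maximal run of a user's page views in which no two consecutive
views are separated by more than 30 minutes of inactivity; a gap of exactly
30 minutes does not split.  Session duration is the time from the first to
the last page view, so a single-view session has duration zero.  Only view
events define sessions — posting actions are assumed to co-occur with a page
view of the page being posted to.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SESSION_GAP = pd.Timedelta(minutes=30)

#: channels whose authored messages count as "posts" for engagement metrics
#: (private messages and wall posts are tallied separately)
POST_CHANNELS = frozenset({"blog", "group", "board"})

PROFILE_COLUMNS = [
    "user_id", "return_visits", "time_on_site", "days_logged_in",
    "total_page_views", "total_posts",
    "profiles_viewed", "blog_posts_read", "pms_received",
    "blog_posts", "blog_comments", "group_posts", "wall_posts", "pms_sent",
]


def sessionize(events: pd.DataFrame) -> pd.DataFrame:
    """Partition each user's view events into inactivity-delimited sessions.

    Parameters
    ----------
    events : event-log DataFrame, time-sorted (within each user).

    Returns
    -------
    DataFrame with one row per session: user_id, start_time, end_time,
    n_page_views, duration (minutes).
    """
    views = events[events["action"] == "view"]
    if views.empty:
        return pd.DataFrame(columns=["user_id", "start_time", "end_time",
                                     "n_page_views", "duration"])
    # stable sort groups each user's rows together, preserving time order
    views = views.sort_values("user_id", kind="stable")
    gaps = views.groupby("user_id", sort=False)["timestamp"].diff()
    if (gaps.dropna() < pd.Timedelta(0)).any():
        raise ValueError("events must be time-sorted within each user")
    new_session = gaps.isna() | (gaps > SESSION_GAP)
    sid = new_session.cumsum()
    grouped = views.groupby(sid, sort=False)
    out = grouped.agg(
        user_id=("user_id", "first"),
        start_time=("timestamp", "first"),
        end_time=("timestamp", "last"),
        n_page_views=("timestamp", "size"),
    ).reset_index(drop=True)
    out["duration"] = (out["end_time"] - out["start_time"]
                       ).dt.total_seconds() / 60.0
    return out


def utilization(events: pd.DataFrame, roster: pd.DataFrame,
                window_days: int = 84) -> pd.DataFrame:
    """Per-participant utilization profile over the first ``window_days``
    days following registration.

    Counts: return visits (sessions), minutes on site (summed session
    durations), distinct calendar days with activity, page views, and
    authored posts.  ``total_posts`` counts messages created in blogs, group
    discussions and the message board; private messages and wall posts are
    reported separately.  ``profiles_viewed`` counts views of member profile
    walls, the channel through which profiles are browsed.
    """
    part = roster[roster["is_trial_participant"]]
    reg = part.set_index("user_id")["registration_time"]

    ev = events[events["user_id"].isin(reg.index)].copy()
    ev["_reg"] = ev["user_id"].map(reg)
    win = pd.to_timedelta(window_days, unit="D")
    ev = ev[(ev["timestamp"] >= ev["_reg"])
            & (ev["timestamp"] < ev["_reg"] + win)]

    views = ev[ev["action"] == "view"]
    sess = sessionize(ev)

    def _count(mask_frame):
        return mask_frame.groupby("user_id").size()

    posts = ev[ev["action"].isin(("post", "respond"))]
    prof = pd.DataFrame(index=reg.index)
    prof["return_visits"] = sess.groupby("user_id").size()
    prof["time_on_site"] = sess.groupby("user_id")["duration"].sum()
    prof["days_logged_in"] = (ev.assign(day=ev["timestamp"].dt.normalize())
                                .groupby("user_id")["day"].nunique())
    prof["total_page_views"] = _count(views)
    prof["total_posts"] = _count(posts[posts["channel"].isin(POST_CHANNELS)])
    prof["profiles_viewed"] = _count(views[views["channel"] == "wall"])
    prof["blog_posts_read"] = _count(views[views["channel"] == "blog"])
    # a PM is "received" when the user reads a private message they did not send
    prof["pms_received"] = _count(views[(views["channel"] == "pm")
                                        & (views["author_id"] != views["user_id"])])
    prof["blog_posts"] = _count(posts[(posts["channel"] == "blog")
                                      & (posts["action"] == "post")])
    prof["blog_comments"] = _count(posts[(posts["channel"] == "blog")
                                         & (posts["action"] == "respond")])
    prof["group_posts"] = _count(posts[posts["channel"] == "group"])
    prof["wall_posts"] = _count(posts[posts["channel"] == "wall"])
    prof["pms_sent"] = _count(ev[ev["action"] == "send_pm"])

    prof = prof.fillna(0).astype({c: "int64" for c in prof.columns
                                  if c != "time_on_site"})
    prof["time_on_site"] = prof["time_on_site"].astype(float)
    prof = prof.reset_index().rename(columns={"index": "user_id"})
    return prof[PROFILE_COLUMNS]
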