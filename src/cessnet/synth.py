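"""Synthetic clickstream and cohort generator for an online cessation community.

The generator emulates a mature peer-support website: a background community
of established members plus a smaller trial cohort that registers during an
enrollment window.  Members view, post, respond to, and privately message
each other across five communication channels.  Per-user activity rates carry
log-normal multipliers, producing the heavy-tailed (mean >> median) degree
distributions characteristic of online communities, and a configurable
majority of members are lurkers who read but never post.

The binary 30-day abstinence outcome of each trial participant is drawn from
a logistic model on the participant's *realized* square-root-scale network
centrality trajectory — computed with the exact same tie/centrality code used
by the downstream analysis (:mod:`cessnet.netbuild`) — plus baseline
covariates.  The planted coefficients are returned alongside the data so that
the full pipeline can be validated by parameter recovery.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

CHANNELS = ("blog", "group", "wall", "board", "pm")
ACTIONS = ("view", "post", "respond", "send_pm")

#: study epoch: all synthetic timestamps are offsets from this instant
EPOCH = pd.Timestamp("2012-03-01 00:00:00")

EVENT_COLUMNS = [
    "user_id", "timestamp", "action", "channel",
    "content_id", "thread_id", "author_id",
]

#: baseline covariate columns carried on the roster (numeric encodings)
COVARIATE_COLUMNS = [
    "age", "female", "education_some_college", "employed_fulltime",
    "hispanic", "ttfc_under5min", "ftnd", "confidence_quit", "desire_quit",
    "tempt_social", "tempt_negaffect", "tempt_craving",
    "piq_positive", "piq_negative",
    "extraversion", "neurosis", "openness",
    "doctor_advice", "illness_smoking", "sn_profile",
    "intention_ex", "intention_med",
]

NETWORK_FEATURES = (
    "sqrt_in_week1", "sqrt_in_change",
    "sqrt_outaware_week1", "sqrt_outaware_change",
)


class ConfigError(ValueError):
    """A generator configuration field violates its contract."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic community + trial cohort.

    Activity model: each user u carries a multiplier lam_u ~ LogNormal with
    E[lam_u] = 1 and log-sd ``activity_sigma``; views are Poisson with mean
    ``view_rate * lam_u`` per day over the user's 12-week activity window.
    Non-lurkers author ``1 + Poisson(post_rate * lam_u * study_days)`` content
    items, so the zero-post fraction of the community equals
    ``lurker_fraction`` by construction.

    Outcome model: logit P(abstinent) = ``outcome_intercept`` plus
    ``outcome_coefficients[name] * x_name`` where names are the four
    square-root-scale network features and/or raw roster covariates.
    """

    n_participants: int = 2657
    n_background_members: int = 5000
    study_days: int = 84
    enrollment_days: int = 28
    background_warmup_days: int = 28
    channel_mix: dict = field(default_factory=lambda: {
        "blog": 0.35, "group": 0.25, "wall": 0.15, "board": 0.15, "pm": 0.10,
    })
    activity_sigma: float = 1.6
    view_rate: float = 6.0 / 84.0     # mean views/day at lam = 1
    post_rate: float = 3.0 / 84.0     # extra posts/day at lam = 1 (non-lurkers)
    engagement_decay: float = 2.0     # u**decay front-loads activity into early weeks
    view_recency_items: float = 100.0  # mean look-back (in items) of view targeting
    lurker_fraction: float = 0.66
    reply_prob: float = 0.15
    author_revisit_prob: float = 0.5
    pm_read_prob: float = 0.9
    excluded_fraction: float = 0.01   # staff/bot accounts among background
    outcome_intercept: float = -2.2
    outcome_coefficients: dict = field(default_factory=lambda: {
        "sqrt_in_week1": 0.0,
        "sqrt_in_change": 0.17,
        "sqrt_outaware_week1": 0.0,
        "sqrt_outaware_change": 0.26,
        "age": -0.02,
        "confidence_quit": 0.24,
    })
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_participants", "n_background_members", "study_days",
                     "enrollment_days", "background_warmup_days"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative, got {getattr(self, name)}")
        for name in ("lurker_fraction", "reply_prob", "author_revisit_prob",
                     "pm_read_prob", "excluded_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if set(self.channel_mix) != set(CHANNELS):
            raise ConfigError(f"channel_mix must have keys {CHANNELS}")
        probs = np.array([self.channel_mix[c] for c in CHANNELS], dtype=float)
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigError("channel_mix proportions must be non-negative and sum to 1")
        for name in ("view_rate", "post_rate", "activity_sigma",
                     "view_recency_items"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.engagement_decay <= 0:
            raise ConfigError("engagement_decay must be positive")
        unknown = [k for k in self.outcome_coefficients
                   if k not in NETWORK_FEATURES and k not in COVARIATE_COLUMNS]
        if unknown:
            raise ConfigError(f"outcome_coefficients refer to unknown terms: {unknown}")

    def replace(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)

    def to_yaml(self, path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _seconds_to_ts(seconds: np.ndarray) -> pd.Series:
    return EPOCH + pd.to_timedelta(np.asarray(seconds, dtype="int64"), unit="s")


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Baseline survey covariates with moments typical of adult smokers
    enrolling in an internet cessation trial."""
    c = pd.DataFrame(index=range(n))
    c["age"] = np.clip(rng.normal(42.1, 13.2, n), 18, 80).round(0)
    c["female"] = rng.binomial(1, 0.613, n)
    c["education_some_college"] = rng.binomial(1, 0.729, n)
    c["employed_fulltime"] = rng.binomial(1, 0.455, n)
    c["hispanic"] = rng.binomial(1, 0.061, n)
    c["ttfc_under5min"] = rng.binomial(1, 0.381, n)
    c["ftnd"] = np.clip(rng.normal(5.21, 2.2, n), 0, 10).round(0)
    c["confidence_quit"] = np.clip(rng.normal(3.3, 1.1, n).round(0), 1, 5)
    c["desire_quit"] = np.clip(rng.normal(4.55, 0.6, n).round(0), 1, 5)
    c["tempt_social"] = np.clip(rng.normal(4.0, 0.8, n), 1, 5).round(1)
    c["tempt_negaffect"] = np.clip(rng.normal(4.5, 0.6, n), 1, 5).round(1)
    c["tempt_craving"] = np.clip(rng.normal(3.8, 0.8, n), 1, 5).round(1)
    c["piq_positive"] = np.clip(rng.normal(6.3, 5.0, n), 0, 20).round(0)
    c["piq_negative"] = np.clip(rng.normal(4.4, 4.6, n), 0, 20).round(0)
    c["extraversion"] = np.clip(rng.normal(8.6, 3.2, n), 2, 14).round(0)
    c["neurosis"] = np.clip(rng.normal(8.3, 3.1, n), 2, 14).round(0)
    c["openness"] = np.clip(rng.normal(10.8, 2.5, n), 2, 14).round(0)
    c["doctor_advice"] = rng.binomial(1, 0.623, n)
    c["illness_smoking"] = rng.binomial(1, 0.636, n)
    c["sn_profile"] = rng.binomial(1, 0.898, n)
    c["intention_ex"] = rng.binomial(1, 0.977, n)
    c["intention_med"] = rng.binomial(1, 0.579, n)
    return c


def generate(config: GeneratorConfig):
    """Generate a synthetic event log, participant roster and planted truth.

    Returns
    -------
    events : pandas.DataFrame
        Time-sorted clickstream with columns :data:`EVENT_COLUMNS` plus a
        deterministic tie-breaking ``seq`` column.
    roster : pandas.DataFrame
        One row per community member (trial participants first), with
        registration time, exclusion flags, baseline covariates and — for
        trial participants — the binary ``abstinent_30d`` outcome.
    truth : dict
        The planted outcome model: ``intercept``, ``coefficients`` and the
        realized feature matrix used to draw the outcomes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_p, n_b = config.n_participants, config.n_background_members
    n = n_p + n_b
    day = 86400

    user_id = np.array(
        [f"p{i:06d}" for i in range(n_p)] + [f"b{i:06d}" for i in range(n_b)]
    )
    is_trial = np.zeros(n, dtype=bool)
    is_trial[:n_p] = True

    # staff/bot accounts live in the background community
    is_excluded = np.zeros(n, dtype=bool)
    if n_b:
        is_excluded[n_p:] = rng.random(n_b) < config.excluded_fraction

    # registration: participants enroll during the window; background members
    # have been active since before the trial opened
    reg_s = np.empty(n, dtype="int64")
    reg_s[:n_p] = rng.integers(0, max(config.enrollment_days, 1) * day, n_p)
    reg_s[n_p:] = -rng.integers(0, max(config.background_warmup_days, 1) * day, n_b)

    lam = rng.lognormal(-config.activity_sigma**2 / 2.0, config.activity_sigma, n)
    lurker = rng.random(n) < config.lurker_fraction

    window = config.study_days * day

    # ------------------------------------------------------------------ posts
    def _offsets(size):
        # activity is front-loaded into a user's early weeks: engagement on
        # cessation sites peaks in the first week after registration
        u = rng.random(size) ** config.engagement_decay
        return (u * window).astype("int64")

    n_posts = np.where(
        lurker, 0, 1 + rng.poisson(config.post_rate * lam * config.study_days)
    )
    post_author = np.repeat(np.arange(n), n_posts)
    post_t = reg_s[post_author] + _offsets(post_author.size)
    chan_p = np.array([config.channel_mix[c] for c in CHANNELS])
    post_chan = rng.choice(len(CHANNELS), size=post_author.size, p=chan_p)

    # private messages get an explicit recipient and a pair-conversation thread
    is_pm = post_chan == CHANNELS.index("pm")
    pm_recipient = np.full(post_author.size, -1)
    if is_pm.any() and n > 1:
        rec = rng.integers(0, n - 1, is_pm.sum())
        snd = post_author[is_pm]
        rec = np.where(rec >= snd, rec + 1, rec)  # never message yourself
        pm_recipient[is_pm] = rec

    order = np.argsort(post_t, kind="stable")
    post_author, post_t = post_author[order], post_t[order]
    post_chan, pm_recipient = post_chan[order], pm_recipient[order]
    n_content = post_author.size
    content_id = np.arange(n_content)

    thread_id = content_id.astype(object).copy()
    if n_content:
        lo = np.minimum(post_author, pm_recipient)
        hi = np.maximum(post_author, pm_recipient)
        for i in np.flatnonzero(is_pm[order]):
            thread_id[i] = f"pm:{user_id[lo[i]]}:{user_id[hi[i]]}"
        nonpm = ~is_pm[order]
        thread_id[nonpm] = [f"t{c:07d}" for c in content_id[nonpm]]

    # ------------------------------------------------------------------ views
    # each view picks uniformly among non-PM content that already exists
    n_views = rng.poisson(config.view_rate * lam * config.study_days)
    viewer = np.repeat(np.arange(n), n_views)
    view_t = reg_s[viewer] + _offsets(viewer.size)

    # views favour recent content: look back an Exp-distributed number of
    # items from the newest item existing at view time
    public = np.flatnonzero(~is_pm[order])
    pub_t = post_t[public]
    k = np.searchsorted(pub_t, view_t, side="left")
    keep = k > 0
    viewer, view_t, k = viewer[keep], view_t[keep], k[keep]
    if viewer.size:
        back = np.floor(rng.exponential(config.view_recency_items,
                                        viewer.size)).astype("int64")
        j = k - 1 - back
        fallback = j < 0
        j[fallback] = (rng.random(int(fallback.sum())) * k[fallback]).astype("int64")
        target = public[j]
    else:
        target = np.array([], dtype=int)

    # PM delivery: recipient reads the message shortly after it arrives
    pmi = np.flatnonzero(is_pm[order])
    if pmi.size:
        read = rng.random(pmi.size) < config.pm_read_prob
        pmi = pmi[read]
        # a recipient cannot read mail from before they joined the site
        arrived = np.maximum(post_t[pmi], reg_s[pm_recipient[pmi]])
        pm_view_t = arrived + 60 + rng.exponential(12 * 3600, pmi.size).astype("int64")
        viewer = np.concatenate([viewer, pm_recipient[pmi]])
        view_t = np.concatenate([view_t, pm_view_t])
        target = np.concatenate([target, pmi])

    # -------------------------------------------------- replies and revisits
    # a non-lurking reader responds in-thread with prob reply_prob; the
    # original author then views the response with prob author_revisit_prob
    other = viewer != post_author[target]
    can_reply = other & ~lurker[viewer]
    reply = can_reply & (rng.random(viewer.size) < config.reply_prob)
    ri = np.flatnonzero(reply)
    resp_user = viewer[ri]
    resp_t = view_t[ri] + 60 + rng.exponential(2 * 3600, ri.size).astype("int64")
    resp_parent = target[ri]
    resp_content = n_content + np.arange(ri.size)

    revisit = rng.random(ri.size) < config.author_revisit_prob
    vi = np.flatnonzero(revisit)
    revisit_user = post_author[resp_parent[vi]]
    revisit_t = resp_t[vi] + 60 + rng.exponential(12 * 3600, vi.size).astype("int64")

    # ---------------------------------------------------------- assemble log
    chan_names = np.array(CHANNELS)

    def _frame(users, times, action, channel, cid, tid, authors):
        return pd.DataFrame({
            "user_id": user_id[users], "timestamp": times, "action": action,
            "channel": channel, "content_id": cid, "thread_id": tid,
            "author_id": user_id[authors],
        })

    cid_str = np.array([f"c{c:07d}" for c in range(n_content + ri.size)], dtype=object)

    frames = []
    if n_content:
        frames.append(_frame(
            post_author, post_t,
            np.where(is_pm[order], "send_pm", "post"),
            chan_names[post_chan], cid_str[content_id], thread_id, post_author))
    if viewer.size:
        frames.append(_frame(
            viewer, view_t, "view", chan_names[post_chan[target]],
            cid_str[content_id[target]], thread_id[target], post_author[target]))
    if ri.size:
        frames.append(_frame(
            resp_user, resp_t, "respond", chan_names[post_chan[resp_parent]],
            cid_str[resp_content], thread_id[resp_parent], resp_user))

    # posting on a page implies viewing it: every authored item gets a
    # companion self-view one second later (forms no tie, but counts as a
    # page view for sessionization and engagement metrics)
    if n_content:
        frames.append(_frame(
            post_author, post_t + 1, "view", chan_names[post_chan],
            cid_str[content_id], thread_id, post_author))
    if ri.size:
        frames.append(_frame(
            resp_user, resp_t + 1, "view", chan_names[post_chan[resp_parent]],
            cid_str[resp_content], thread_id[resp_parent], resp_user))
    if vi.size:
        frames.append(_frame(
            revisit_user, revisit_t, "view", chan_names[post_chan[resp_parent[vi]]],
            cid_str[resp_content[vi]], thread_id[resp_parent[vi]], resp_user[vi]))

    if frames:
        events = pd.concat(frames, ignore_index=True)
    else:
        events = pd.DataFrame(columns=EVENT_COLUMNS)
        events["timestamp"] = events.get("timestamp", pd.Series(dtype="int64"))

    events = events.sort_values("timestamp", kind="stable").reset_index(drop=True)
    events["timestamp"] = _seconds_to_ts(events["timestamp"].to_numpy())
    events["seq"] = np.arange(len(events), dtype="int64")
    events = events[EVENT_COLUMNS + ["seq"]]

    # --------------------------------------------------------------- roster
    roster = pd.DataFrame({
        "user_id": user_id,
        "registration_time": _seconds_to_ts(reg_s),
        "is_trial_participant": is_trial,
        "is_excluded": is_excluded,
    })
    roster = pd.concat([roster, _draw_covariates(rng, n)], axis=1)

    # --------------------------------------------------------------- outcome
    # realized centrality trajectories via the analysis code path itself
    from . import model as _model
    from . import netbuild as _netbuild

    excl = set(user_id[is_excluded])
    ties = _netbuild.build_ties(events, exclusions=excl)
    ties = _netbuild.mark_awareness(ties, events, exclusions=excl)
    series = _netbuild.weekly_centralities(ties, roster)
    feats = _model.sqrt_change_features(series)

    part = roster.loc[is_trial, ["user_id"] + COVARIATE_COLUMNS].set_index("user_id")
    X = part.join(feats, how="left").fillna(0.0)
    eta = np.full(len(X), config.outcome_intercept)
    for name, beta in config.outcome_coefficients.items():
        eta += beta * X[name].to_numpy(dtype=float)
    p_abst = 1.0 / (1.0 + np.exp(-eta))
    y = rng.binomial(1, p_abst)

    roster["abstinent_30d"] = 0
    roster.loc[is_trial, "abstinent_30d"] = y

    truth = {
        "intercept": config.outcome_intercept,
        "coefficients": dict(config.outcome_coefficients),
        "features": X[list(NETWORK_FEATURES)],
        "p_abstinent": pd.Series(p_abst, index=X.index),
    }
    return events, roster, truth


# --------------------------------------------------------------------- I/O

class EventLogParseError(ValueError):
    """A row of an on-disk event log violates the schema."""


def write_event_log(events: pd.DataFrame, path) -> None:
    """Write events as UTF-8 comma-delimited text (ISO-8601 timestamps)."""
    out = events[EVENT_COLUMNS].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_event_log(path) -> pd.DataFrame:
    """Read an event log written by :func:`write_event_log`.

    Rows with unknown action/channel tokens or unparseable timestamps are
    rejected with an :class:`EventLogParseError` naming the 1-based line
    number (the header is line 1).
    """
    ev = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in EVENT_COLUMNS if c not in ev.columns]
    if missing:
        raise EventLogParseError(f"event log missing columns: {missing}")
    ev = ev[EVENT_COLUMNS]
    bad = ~ev["action"].isin(ACTIONS)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2
        raise EventLogParseError(
            f"line {line}: unknown action {ev['action'].iloc[line - 2]!r}")
    bad = ~ev["channel"].isin(CHANNELS)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2
        raise EventLogParseError(
            f"line {line}: unknown channel {ev['channel'].iloc[line - 2]!r}")
    ts = pd.to_datetime(ev["timestamp"], format="%Y-%m-%dT%H:%M:%S", errors="coerce")
    if ts.isna().any():
        line = int(np.flatnonzero(ts.isna())[0]) + 2
        raise EventLogParseError(
            f"line {line}: unparseable timestamp {ev['timestamp'].iloc[line - 2]!r}")
    ev["timestamp"] = ts
    ev["seq"] = np.arange(len(ev), dtype="int64")
    return ev


def write_roster(roster: pd.DataFrame, path) -> None:
    out = roster.copy()
    out["registration_time"] = pd.to_datetime(
        out["registration_time"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_roster(path) -> pd.DataFrame:
    roster = pd.read_csv(path)
    roster["registration_time"] = pd.to_datetime(
        roster["registration_time"], format="%Y-%m-%dT%H:%M:%S")
    for col in ("is_trial_participant", "is_excluded"):
        if roster[col].dtype != bool:
            roster[col] = roster[col].astype(str).str.lower().isin(("true", "1"))
    return roster


def events_to_csv_bytes(events: pd.DataFrame) -> bytes:
    buf = io.StringIO()
    write_event_log(events, buf)
    return buf.getvalue().encode()
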