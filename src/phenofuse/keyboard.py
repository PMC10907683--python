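"""Keyboard-dynamics feature extraction.

Raw smartphone keypress streams are segmented into *typing sessions* —
bursts of activity that end when the keyboard is dismissed or after six
seconds of inactivity. Per session we compute inter-key-delay (IKD)
statistics between successive alphanumeric presses (median IKD, an inverse
measure of typing speed; 95th-percentile IKD, a measure of within-session
pausing; mean-absolute-deviation IKD, a variability measure) plus
autocorrect and backspace rates. Sessions are aggregated to participant-days
by averaging, keypress counts by summing, and days with fewer than 750
presses are excluded to ensure stable feature estimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as _date
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KeypressEvent",
    "TypingSession",
    "SessionKeyboardFeatures",
    "KEY_CLASSES",
    "IKD_FEATURES",
    "DAILY_FEATURES",
    "DEFAULT_INACTIVITY_THRESHOLD_S",
    "DEFAULT_VOLUME_THRESHOLD",
    "segment_sessions",
    "session_features",
    "aggregate_daily_keyboard",
    "daily_keyboard_from_frame",
    "transform_and_standardize",
    "StandardizationParams",
]

KEY_CLASSES = ("alphanumeric", "autocorrect", "backspace", "other")

#: session-level statistics that may be undefined (fewer than two
#: successive alphanumeric presses)
IKD_FEATURES = ("median_ikd", "p95_ikd", "mad_ikd")

#: daily feature columns, in the order used throughout the pipeline
DAILY_FEATURES = (
    "median_ikd",
    "p95_ikd",
    "mad_ikd",
    "autocorrect_rate",
    "backspace_rate",
    "total_keypresses",
)

DEFAULT_INACTIVITY_THRESHOLD_S = 6.0
DEFAULT_VOLUME_THRESHOLD = 750


@dataclass(frozen=True)
class KeypressEvent:
    """One keypress: who, when (seconds, millisecond resolution), and what
    kind of key. ``keyboard_dismissed`` marks that the keyboard disappeared
    after this press, which closes the session regardless of timing."""

    participant_id: str
    timestamp: float
    key_class: str
    date: Optional[_date] = None
    keyboard_dismissed: bool = False

    def __post_init__(self) -> None:
        if self.key_class not in KEY_CLASSES:
            raise ValueError(
                f"key_class must be one of {KEY_CLASSES}, got {self.key_class!r}"
            )


@dataclass
class TypingSession:
    participant_id: str
    session_index: int
    events: list[KeypressEvent]
    date: Optional[_date] = None


@dataclass
class SessionKeyboardFeatures:
    """IKD statistics are ``None`` (absent, not zero) when the session has
    fewer than two immediately successive alphanumeric presses."""

    median_ikd: Optional[float]
    p95_ikd: Optional[float]
    mad_ikd: Optional[float]
    autocorrect_rate: float
    backspace_rate: float
    n_keypresses: int


@dataclass
class StandardizationParams:
    """Fitted grand means/SDs so the transform is reproducible and invertible.

    ``log_features`` lists the columns that were natural-log transformed
    before z-scoring.
    """

    means: "pd.Series"
    sds: "pd.Series"
    log_features: tuple[str, ...] = ()

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for col in self.means.index:
            vals = out[col].astype(float)
            if col in self.log_features:
                vals = np.log(vals)
            out[col] = (vals - self.means[col]) / self.sds[col]
        return out

    def invert(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for col in self.means.index:
            vals = out[col].astype(float) * self.sds[col] + self.means[col]
            if col in self.log_features:
                vals = np.exp(vals)
            out[col] = vals
        return out


def segment_sessions(
    events: Sequence[KeypressEvent],
    inactivity_threshold: float = DEFAULT_INACTIVITY_THRESHOLD_S,
) -> list[TypingSession]:
    """Split one participant's time-ordered keypress stream into sessions.

    A session begins at the first press and ends when the keyboard is
    dismissed or after ``inactivity_threshold`` seconds of inactivity; a gap
    of exactly the threshold closes the session. Each session is assigned
    the calendar date of its first keypress.
    """
    events = list(events)
    if not events:
        return []
    pids = {e.participant_id for e in events}
    if len(pids) > 1:
        raise ValueError(f"events mix participants: {sorted(pids)}")
    ts = np.array([e.timestamp for e in events], dtype=float)
    if np.any(np.diff(ts) < 0):
        bad = int(np.argmax(np.diff(ts) < 0)) + 1
        raise ValueError(
            f"events not sorted by timestamp (first violation at index {bad})"
        )
    sessions: list[TypingSession] = []
    current: list[KeypressEvent] = [events[0]]
    for prev, ev in zip(events, events[1:]):
        if prev.keyboard_dismissed or (ev.timestamp - prev.timestamp) >= inactivity_threshold:
            sessions.append(_close(current, len(sessions)))
            current = [ev]
        else:
            current.append(ev)
    sessions.append(_close(current, len(sessions)))
    return sessions


def _close(events: list[KeypressEvent], index: int) -> TypingSession:
    return TypingSession(
        participant_id=events[0].participant_id,
        session_index=index,
        events=events,
        date=events[0].date,
    )


def _ikd_stats(ikds: np.ndarray) -> tuple[float, float, float]:
    med = float(np.median(ikds))
    p95 = float(np.percentile(ikds, 95))  # linear interpolation
    mad = float(np.mean(np.abs(ikds - med)))  # MAD about the median
    return med, p95, mad


def session_features(session: TypingSession) -> SessionKeyboardFeatures:
    """Compute IKD statistics and key-class rates for one session.

    IKDs are delays between *immediately* successive alphanumeric presses;
    an intervening autocorrect/backspace/other press breaks the pair.
    """
    events = session.events
    if not events:
        raise ValueError("session has no events")
    n = len(events)
    classes = [e.key_class for e in events]
    ts = np.array([e.timestamp for e in events], dtype=float)
    alnum = np.array([c == "alphanumeric" for c in classes], dtype=bool)
    pair = alnum[:-1] & alnum[1:]
    ikds = np.diff(ts)[pair]
    if ikds.size >= 1:
        med, p95, mad = _ikd_stats(ikds)
    else:
        med = p95 = mad = None
    return SessionKeyboardFeatures(
        median_ikd=med,
        p95_ikd=p95,
        mad_ikd=mad,
        autocorrect_rate=classes.count("autocorrect") / n,
        backspace_rate=classes.count("backspace") / n,
        n_keypresses=n,
    )


def aggregate_daily_keyboard(
    sessions: Sequence[TypingSession],
    volume_threshold: int = DEFAULT_VOLUME_THRESHOLD,
) -> pd.DataFrame:
    """Aggregate one participant's sessions to daily features.

    Session-level statistics are averaged per day (absent IKD statistics are
    ignored, not treated as zero); keypress counts are summed. ``included``
    flags days meeting the volume threshold (total >= 750 by default).

    Returns a DataFrame with one row per (participant_id, date).
    """
    rows = []
    for s in sessions:
        f = session_features(s)
        rows.append(
            {
                "participant_id": s.participant_id,
                "date": s.date,
                "median_ikd": f.median_ikd,
                "p95_ikd": f.p95_ikd,
                "mad_ikd": f.mad_ikd,
                "autocorrect_rate": f.autocorrect_rate,
                "backspace_rate": f.backspace_rate,
                "n_keypresses": f.n_keypresses,
            }
        )
    frame = pd.DataFrame(rows)
    if frame.empty:
        return pd.DataFrame(
            columns=["participant_id", "date", *DAILY_FEATURES, "included"]
        )
    return _daily_from_session_frame(frame, volume_threshold)


def _daily_from_session_frame(
    frame: pd.DataFrame, volume_threshold: int
) -> pd.DataFrame:
    g = frame.groupby(["participant_id", "date"], sort=True, observed=True)
    daily = g.agg(
        median_ikd=("median_ikd", "mean"),
        p95_ikd=("p95_ikd", "mean"),
        mad_ikd=("mad_ikd", "mean"),
        autocorrect_rate=("autocorrect_rate", "mean"),
        backspace_rate=("backspace_rate", "mean"),
        total_keypresses=("n_keypresses", "sum"),
    ).reset_index()
    daily["included"] = daily["total_keypresses"] >= volume_threshold
    return daily


def daily_keyboard_from_frame(
    keypresses: pd.DataFrame,
    inactivity_threshold: float = DEFAULT_INACTIVITY_THRESHOLD_S,
    volume_threshold: int = DEFAULT_VOLUME_THRESHOLD,
) -> pd.DataFrame:
    """Vectorized segmentation + daily aggregation for a multi-participant
    keypress table.

    Expects columns ``participant_id, timestamp, date, key_class`` and
    optionally ``keyboard_dismissed`` (0/1). ``timestamp`` is seconds
    (float) or ISO-8601 strings; ordering is enforced per participant.
    This is the production path of :func:`segment_sessions` /
    :func:`session_features` / :func:`aggregate_daily_keyboard`; unit tests
    pin the two paths to each other.
    """
    df = keypresses.copy()
    if df.empty:
        return pd.DataFrame(
            columns=["participant_id", "date", *DAILY_FEATURES, "included"]
        )
    bad = set(df["key_class"].unique()) - set(KEY_CLASSES)
    if bad:
        raise ValueError(f"unknown key_class values: {sorted(bad)}")
    if df["timestamp"].dtype == object or str(df["timestamp"].dtype).startswith(
        "datetime"
    ):
        df["timestamp"] = (
            pd.to_datetime(df["timestamp"]).astype("int64") / 1e9
        )
    df["timestamp"] = df["timestamp"].astype(float)
    if "keyboard_dismissed" not in df.columns:
        df["keyboard_dismissed"] = 0
    df["keyboard_dismissed"] = df["keyboard_dismissed"].fillna(0).astype(int)

    df = df.sort_values(["participant_id", "timestamp"], kind="stable").reset_index(
        drop=True
    )
    pid, _ = pd.factorize(df["participant_id"])
    ts = df["timestamp"].to_numpy()
    dismissed = df["keyboard_dismissed"].to_numpy()

    new_participant = np.empty(len(df), dtype=bool)
    new_participant[0] = True
    new_participant[1:] = pid[1:] != pid[:-1]
    gap = np.empty(len(df))
    gap[0] = np.inf
    gap[1:] = ts[1:] - ts[:-1]
    prev_dismissed = np.empty(len(df), dtype=bool)
    prev_dismissed[0] = False
    prev_dismissed[1:] = dismissed[:-1] == 1
    boundary = new_participant | (gap >= inactivity_threshold) | prev_dismissed
    df["session_id"] = np.cumsum(boundary)

    # session date = date of first event in the session
    first = df.groupby("session_id", sort=False).head(1).set_index("session_id")
    df["session_date"] = df["session_id"].map(first["date"])

    alnum = (df["key_class"] == "alphanumeric").to_numpy()
    sid = df["session_id"].to_numpy()
    same_session = np.zeros(len(df), dtype=bool)
    same_session[1:] = sid[1:] == sid[:-1]
    pair = same_session & alnum
    pair[1:] &= alnum[:-1]
    ikd = np.full(len(df), np.nan)
    ikd[pair] = gap[pair]
    df["ikd"] = ikd

    # vectorized session statistics (cythonized groupby kernels; the
    # quantile uses the same linear interpolation as np.percentile)
    g = df.groupby("session_id", sort=True)
    med = g["ikd"].median()
    p95 = g["ikd"].quantile(0.95)
    absdev = (df["ikd"] - df["session_id"].map(med)).abs()
    mad = absdev.groupby(df["session_id"]).mean()
    n = g.size()
    auto = (df["key_class"] == "autocorrect").groupby(df["session_id"]).mean()
    back = (df["key_class"] == "backspace").groupby(df["session_id"]).mean()
    heads = g[["participant_id", "session_date"]].first()
    sess = pd.DataFrame(
        {
            "participant_id": heads["participant_id"],
            "date": heads["session_date"],
            "median_ikd": med,
            "p95_ikd": p95,
            "mad_ikd": mad,
            "autocorrect_rate": auto,
            "backspace_rate": back,
            "n_keypresses": n,
        }
    ).reset_index(drop=True)
    return _daily_from_session_frame(sess, volume_threshold)


def transform_and_standardize(
    table: pd.DataFrame,
    features: Sequence[str] = DAILY_FEATURES,
    log_features: Sequence[str] = ("total_keypresses",),
) -> tuple[pd.DataFrame, StandardizationParams]:
    """Log-transform keypress counts and z-score every feature.

    Each feature column is standardized against the grand mean and SD of the
    supplied table (grand mean 0, overall variance 1). The fitted parameters
    are returned so the transform can be re-applied or inverted exactly.

    Raises ``ValueError`` naming the feature if a column has zero variance.
    """
    features = tuple(features)
    log_features = tuple(f for f in log_features if f in features)
    work = table.copy()
    for col in log_features:
        if (work[col] <= 0).any():
            raise ValueError(f"feature {col!r} must be positive for log transform")
        work[col] = np.log(work[col].astype(float))
    means = work[list(features)].mean()
    sds = work[list(features)].std(ddof=1)
    zero = sds[sds == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance feature(s): {zero}")
    params = StandardizationParams(means=means, sds=sds, log_features=log_features)
    out = table.copy()
    for col in features:
        vals = out[col].astype(float)
        if col in log_features:
            vals = np.log(vals)
        out[col] = (vals - means[col]) / sds[col]
    return out, params
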