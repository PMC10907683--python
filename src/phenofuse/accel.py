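"""In-session accelerometer preprocessing and activity classification.

Accelerometer traces recorded while the participant types are low-pass
filtered with a zero-phase (bidirectional) second-order Butterworth filter
at 4 Hz. Each sample is labelled *active* when the filtered acceleration
magnitude leaves the [0.95, 1.05] g band around gravity (inclusive bounds
are stationary), a session is active when strictly more than 8% of its
samples are, and *upright* when the session's median filtered z is strictly
below 0.1 g with median x inside [-0.2, 0.2] g. Daily movement and upright
rates are the fraction of a day's sessions carrying each label.

Inputs must already be expressed in gravity units (g): the magnitude
thresholds are meaningless in m/s².
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

__all__ = [
    "SessionAccelLabel",
    "DEFAULT_CUTOFF_HZ",
    "DEFAULT_ORDER",
    "DEFAULT_SAMPLING_RATE_HZ",
    "MAGNITUDE_BOUNDS",
    "ACTIVE_FRACTION_THRESHOLD",
    "UPRIGHT_Z_MAX",
    "UPRIGHT_X_BOUND",
    "min_filter_length",
    "lowpass_filter",
    "classify_sample_motion",
    "classify_session_motion",
    "classify_session_upright",
    "label_session",
    "aggregate_daily_accel",
    "daily_accel_from_frame",
]

DEFAULT_CUTOFF_HZ = 4.0
DEFAULT_ORDER = 2
DEFAULT_SAMPLING_RATE_HZ = 10.0
MAGNITUDE_BOUNDS = (0.95, 1.05)  # inclusive -> stationary
ACTIVE_FRACTION_THRESHOLD = 0.08  # strictly greater -> active session
UPRIGHT_Z_MAX = 0.1  # strictly below
UPRIGHT_X_BOUND = 0.2  # inclusive, symmetric


@dataclass
class SessionAccelLabel:
    participant_id: str
    session_index: int
    date: object
    is_active: bool
    is_upright: bool
    n_samples: int
    active_fraction: float
    filtered: bool = True


def min_filter_length(order: int = DEFAULT_ORDER) -> int:
    """Shortest series the zero-phase filter accepts (padding constraint)."""
    return 3 * (order + 1) + 1


def lowpass_filter(
    xyz: np.ndarray,
    sampling_rate: float = DEFAULT_SAMPLING_RATE_HZ,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the last axis.

    Forward-backward application squares the filter magnitude response (the
    gain at the cutoff is 1/2, not 1/sqrt(2)) and cancels the phase. The DC
    component is preserved exactly. ``xyz`` may be (n,) or (..., n).
    """
    xyz = np.asarray(xyz, dtype=float)
    nyquist = sampling_rate / 2.0
    if cutoff >= nyquist:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below the Nyquist frequency {nyquist} Hz"
        )
    if xyz.shape[-1] < min_filter_length(order):
        raise ValueError(
            f"series of length {xyz.shape[-1]} is shorter than the minimum "
            f"filterable length {min_filter_length(order)}"
        )
    b, a = butter(order, cutoff / nyquist)
    return filtfilt(b, a, xyz, axis=-1)


def classify_sample_motion(x, y, z) -> np.ndarray:
    """Per-sample motion label from filtered axes: True = active.

    Active when the magnitude falls below 0.95 g or above 1.05 g; the
    inclusive band in between is stationary (the phone resting at 1 g).
    """
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    if not (np.isfinite(x).all() and np.isfinite(y).all() and np.isfinite(z).all()):
        raise ValueError("non-finite accelerometer values")
    m = np.sqrt(x * x + y * y + z * z)
    lo, hi = MAGNITUDE_BOUNDS
    return (m < lo) | (m > hi)


def classify_session_motion(sample_labels: np.ndarray) -> tuple[bool, float]:
    """Session-level motion label: active iff > 8% of samples are active."""
    labels = np.asarray(sample_labels, dtype=bool)
    if labels.size == 0:
        raise ValueError("session has no labelled samples")
    frac = float(labels.mean())
    return frac > ACTIVE_FRACTION_THRESHOLD, frac


def classify_session_upright(x: np.ndarray, z: np.ndarray) -> bool:
    """Upright iff median(z) < 0.1 strictly and median(x) in [-0.2, 0.2]."""
    med_z = float(np.median(z))
    med_x = float(np.median(x))
    return med_z < UPRIGHT_Z_MAX and -UPRIGHT_X_BOUND <= med_x <= UPRIGHT_X_BOUND


def label_session(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    participant_id: str = "",
    session_index: int = 0,
    date: object = None,
    sampling_rate: float = DEFAULT_SAMPLING_RATE_HZ,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
) -> SessionAccelLabel:
    """Filter one session and derive its motion and upright labels.

    Sessions shorter than the filter's minimum padding length are classified
    on raw magnitudes and flagged ``filtered=False`` rather than discarded.
    """
    xyz = np.vstack([x, y, z]).astype(float)
    filtered = xyz.shape[1] >= min_filter_length(order)
    if filtered:
        xyz = lowpass_filter(xyz, sampling_rate, cutoff, order)
    active = classify_sample_motion(xyz[0], xyz[1], xyz[2])
    is_active, frac = classify_session_motion(active)
    is_upright = classify_session_upright(xyz[0], xyz[2])
    return SessionAccelLabel(
        participant_id=participant_id,
        session_index=session_index,
        date=date,
        is_active=is_active,
        is_upright=is_upright,
        n_samples=xyz.shape[1],
        active_fraction=frac,
        filtered=filtered,
    )


def aggregate_daily_accel(labels: Sequence[SessionAccelLabel]) -> pd.DataFrame:
    """Daily movement and upright rates from labelled sessions.

    movement_rate = active sessions / labelled sessions that day; analogous
    for upright_rate. Days with zero labelled sessions emit no row.
    """
    if not labels:
        return pd.DataFrame(
            columns=[
                "participant_id",
                "date",
                "movement_rate",
                "upright_rate",
                "n_sessions",
            ]
        )
    frame = pd.DataFrame(
        {
            "participant_id": [l.participant_id for l in labels],
            "date": [l.date for l in labels],
            "is_active": [l.is_active for l in labels],
            "is_upright": [l.is_upright for l in labels],
        }
    )
    out = (
        frame.groupby(["participant_id", "date"], sort=True, observed=True)
        .agg(
            movement_rate=("is_active", "mean"),
            upright_rate=("is_upright", "mean"),
            n_sessions=("is_active", "size"),
        )
        .reset_index()
    )
    return out


def daily_accel_from_frame(
    accel: pd.DataFrame,
    sampling_rate: float = DEFAULT_SAMPLING_RATE_HZ,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
) -> pd.DataFrame:
    """Label every (participant, session) in a long-format sample table and
    aggregate to daily rates.

    Expects columns ``participant_id, session_index, date, timestamp_s, x,
    y, z``. Samples are treated as regularly spaced at ``sampling_rate``;
    mild timestamp jitter is tolerated because the magnitude/median
    thresholds are insensitive to it.
    """
    required = {"participant_id", "session_index", "date", "x", "y", "z"}
    missing = required - set(accel.columns)
    if missing:
        raise ValueError(f"accel table missing columns: {sorted(missing)}")
    if accel.empty:
        return aggregate_daily_accel([])
    sort_cols = ["participant_id", "session_index"]
    if "timestamp_s" in accel.columns:
        sort_cols.append("timestamp_s")
    accel = accel.sort_values(sort_cols, kind="stable")
    pid_codes, _ = pd.factorize(accel["participant_id"])
    sidx_codes, _ = pd.factorize(accel["session_index"])
    combined = pid_codes.astype(np.int64) * (sidx_codes.max() + 1) + sidx_codes
    starts = np.flatnonzero(np.r_[True, np.diff(combined) != 0])
    ends = np.r_[starts[1:], len(accel)]
    xs = accel["x"].to_numpy(dtype=float)
    ys = accel["y"].to_numpy(dtype=float)
    zs = accel["z"].to_numpy(dtype=float)
    pids = accel["participant_id"].to_numpy()
    sidxs = accel["session_index"].to_numpy()
    dates = accel["date"].to_numpy()
    meta, series = [], []
    for s, e in zip(starts, ends):
        meta.append((pids[s], sidxs[s], dates[s]))
        series.append(np.vstack([xs[s:e], ys[s:e], zs[s:e]]))
    # filtfilt is applied once per distinct session length so equal-length
    # sessions share a single vectorized call
    labels: list[SessionAccelLabel] = [None] * len(series)  # type: ignore[list-item]
    by_len: dict[int, list[int]] = {}
    for i, arr in enumerate(series):
        by_len.setdefault(arr.shape[1], []).append(i)
    for n, idxs in by_len.items():
        stack = np.stack([series[i] for i in idxs])  # (m, 3, n)
        if n >= min_filter_length(order):
            stack = lowpass_filter(stack, sampling_rate, cutoff, order)
            was_filtered = True
        else:
            was_filtered = False
        active = classify_sample_motion(
            stack[:, 0, :], stack[:, 1, :], stack[:, 2, :]
        )
        frac = active.mean(axis=1)
        med_x = np.median(stack[:, 0, :], axis=1)
        med_z = np.median(stack[:, 2, :], axis=1)
        for row, i in enumerate(idxs):
            pid, sidx, date = meta[i]
            labels[i] = SessionAccelLabel(
                participant_id=pid,
                session_index=sidx,
                date=date,
                is_active=bool(frac[row] > ACTIVE_FRACTION_THRESHOLD),
                is_upright=bool(
                    med_z[row] < UPRIGHT_Z_MAX
                    and -UPRIGHT_X_BOUND <= med_x[row] <= UPRIGHT_X_BOUND
                ),
                n_samples=n,
                active_fraction=float(frac[row]),
                filtered=was_filtered,
            )
    return aggregate_daily_accel(labels)
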