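"""Synthetic digital-phenotyping study generator.

Generates a complete study from known ground truth — raw keypress streams,
in-session accelerometer traces, and daily Likert self-report panels — so
that feature extraction, the ICA decomposition, and the mixed-effects
fusion can all be validated by parameter recovery without any real data.

Generative structure, mirroring the analysis model it is meant to test:

1. Per participant-day, latent behavioural targets (typing speed, delay
   dispersion, autocorrect/backspace propensities, keypress volume,
   movement and upright propensities) are drawn from independent Gaussians
   and turned into raw event streams: sessions of log-normally distributed
   inter-key delays separated by > 6 s gaps, and per-session accelerometer
   traces that are flat around 1 g (stationary) or carry low-frequency
   motion bursts (active), in upright or flat orientation.
2. The daily feature vector x_ijk entering the outcome model is the
   *measured* one: the generator runs the same keyboard/accelerometer
   feature extractors the pipeline uses on its own raw streams, then
   standardizes. The planted fixed effects are therefore true coefficients
   of the features the pipeline will observe, so end-to-end recovery error
   reflects pipeline defects, not generator round-trip noise.
3. Each independent component follows the nested random-intercept model
   y = beta0 + b_i + b_ij + beta1' x + eps with known variance components,
   and the self-report items are exp(A_true y + intercept + noise) rounded
   to the Likert grid.

Random effects and residuals default to Laplace draws (``latent_family``)
because temporally concatenated ICA cannot identify Gaussian sources;
:func:`simulate_latents` (used to test the fusion model in isolation)
defaults to Gaussian per the fusion model's own assumptions.

A single master seed makes every bundle reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd

from . import accel as accel_mod
from . import keyboard as keyboard_mod
from .fusion import FIXED_TERMS

__all__ = [
    "SyntheticTruth",
    "default_truth",
    "simulate_latents",
    "simulate_selfreport",
    "simulate_keystrokes",
    "simulate_accelerometer",
    "simulate_study",
]

_DAY_SECONDS = 86400.0
_SESSION_GAP_MIN_S = 30.0  # well above the 6 s session rule


def _block_mixing(p: int, q: int, rng: np.random.Generator) -> np.ndarray:
    """Sparse block-structured loading matrix: each item loads mainly on one
    component (0.35) with small random cross-loadings."""
    A = rng.normal(0.0, 0.03, size=(p, q))
    for i in range(p):
        A[i, i % q] = 0.35 * rng.choice([-1.0, 1.0])
    return A


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic study.

    Scale defaults follow the kind of cohort the pipeline targets: 55
    participants observed for five 7-day weeks, with daily keypress volumes
    around 1100 (so a small fraction of days falls under the 750-press
    filter) and mild day-level missingness per modality, leaving roughly
    32 analysable days per participant.
    """

    n_participants: int = 55
    n_weeks: int = 5
    days_per_week: int = 7
    q: int = 5
    p_items: int = 20
    likert_max: int = 7
    A: Optional[np.ndarray] = None  # p_items x q mixing matrix
    beta0: Optional[np.ndarray] = None  # q
    beta1: Optional[np.ndarray] = None  # q x 8, ordered as FIXED_TERMS
    sigma1_sq: float = 0.30  # participant random-intercept variance
    sigma2_sq: float = 0.15  # week-within-participant variance
    sigma_sq: float = 0.53  # residual variance
    item_noise_sd: float = 0.05  # log-scale self-report noise
    item_intercept: float = 0.92  # log-scale item mean (~2.5 on the Likert scale)
    latent_family: str = "laplace"  # distribution of b_i, b_ij, eps
    n_sessions_per_day: int = 10
    accel_samples_per_session: int = 80
    accel_sampling_rate: float = 10.0
    missing_keyboard: float = 0.02
    missing_accel: float = 0.02
    missing_selfreport: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed + 104729)
        if self.A is None:
            self.A = _block_mixing(self.p_items, self.q, rng)
        self.A = np.asarray(self.A, dtype=float)
        if self.beta0 is None:
            self.beta0 = np.zeros(self.q)
        self.beta0 = np.asarray(self.beta0, dtype=float)
        if self.beta1 is None:
            self.beta1 = self._default_beta1()
        self.beta1 = np.asarray(self.beta1, dtype=float)
        if self.A.shape != (self.p_items, self.q):
            raise ValueError("A must be p_items x q")
        if self.beta1.shape != (self.q, len(FIXED_TERMS)):
            raise ValueError(f"beta1 must be q x {len(FIXED_TERMS)}")
        if min(self.sigma1_sq, self.sigma2_sq, self.sigma_sq) < 0:
            raise ValueError("variance components must be non-negative")
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        if self.latent_family not in ("gaussian", "laplace"):
            raise ValueError(f"unknown latent_family {self.latent_family!r}")

    def _default_beta1(self) -> np.ndarray:
        """Small realistic fixed effects: movement slows component 2 down
        (the planted effect most end-to-end checks target), with a few
        other non-zero entries spread across components."""
        b = np.zeros((self.q, len(FIXED_TERMS)))
        t = {name: i for i, name in enumerate(FIXED_TERMS)}
        if self.q >= 1:
            b[0, t["movement_rate"]] = 0.071
        if self.q >= 2:
            b[1, t["median_ikd"]] = 0.098
            b[1, t["movement_rate"]] = -0.12
        if self.q >= 4:
            b[3, t["median_ikd"]] = -0.094
            b[3, t["total_keypresses"]] = 0.062
        if self.q >= 5:
            b[4, t["total_keypresses"]] = -0.060
        return b

    @property
    def n_days(self) -> int:
        return self.n_weeks * self.days_per_week

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["A"] = self.A.tolist()
        d["beta0"] = self.beta0.tolist()
        d["beta1"] = self.beta1.tolist()
        d["fixed_terms"] = list(FIXED_TERMS)
        return d


def default_truth(**overrides) -> SyntheticTruth:
    return SyntheticTruth(**overrides)


def _draw(family: str, scale_sq: float, size, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean draw with variance ``scale_sq`` from the named family."""
    sd = np.sqrt(scale_sq)
    if family == "gaussian":
        return rng.normal(0.0, sd, size=size)
    # Laplace with variance 2 b^2 = scale_sq
    return rng.laplace(0.0, sd / np.sqrt(2.0), size=size)


def _random_terms(
    truth: SyntheticTruth,
    participant: np.ndarray,
    week: np.ndarray,
    rng: np.random.Generator,
    family: str,
) -> np.ndarray:
    """b_i + b_ij + eps for every row and component: (n_rows, q)."""
    n = len(participant)
    out = np.zeros((n, truth.q))
    pid_codes, _ = pd.factorize(participant)
    cell_codes, _ = pd.factorize(pid_codes * (week.max() + 1) + week)
    b_i = _draw(family, truth.sigma1_sq, (pid_codes.max() + 1, truth.q), rng)
    b_ij = _draw(family, truth.sigma2_sq, (cell_codes.max() + 1, truth.q), rng)
    eps = _draw(family, truth.sigma_sq, (n, truth.q), rng)
    return b_i[pid_codes] + b_ij[cell_codes] + eps


def simulate_latents(
    truth: SyntheticTruth,
    rng: Optional[np.random.Generator] = None,
    family: str = "gaussian",
    feature_cov: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Draw the model's own quantities directly: standardized features x
    from a (configurably correlated) Gaussian, random effects and residuals
    per component, and y = beta0 + b_i + b_ij + beta1' x + eps.

    Returns one row per participant-day with participant_id, week,
    day_of_week, date, the 8 feature columns and IC_1..IC_q outcome
    columns. This is the direct oracle for the fusion model; the raw-stream
    generators below are the oracle for the full pipeline.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    n_feat = len(FIXED_TERMS)
    rows = truth.n_participants * truth.n_days
    if feature_cov is None:
        x = rng.normal(size=(rows, n_feat))
    else:
        x = rng.multivariate_normal(np.zeros(n_feat), feature_cov, size=rows)
    pid = np.repeat(np.arange(truth.n_participants), truth.n_days)
    day = np.tile(np.arange(truth.n_days), truth.n_participants)
    week = day // truth.days_per_week
    rand = _random_terms(truth, pid, week, rng, family)
    y = truth.beta0[None, :] + x @ truth.beta1.T + rand
    start = pd.Timestamp("2023-01-02")
    df = pd.DataFrame(x, columns=list(FIXED_TERMS))
    df.insert(0, "participant_id", [f"P{i:03d}" for i in pid])
    df.insert(1, "date", start + pd.to_timedelta(day, unit="D"))
    df.insert(2, "week", week + 1)
    df.insert(3, "day_of_week", day % truth.days_per_week + 1)
    for c in range(truth.q):
        df[f"IC_{c + 1}"] = y[:, c]
    return df


def simulate_selfreport(
    truth: SyntheticTruth,
    ic_values: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
    discretize: bool = True,
) -> pd.DataFrame:
    """Mix component values into Likert items.

    Log-scale items = A_true @ y + intercept + Gaussian noise; values are
    exponentiated and (by default) rounded half-up and clipped to
    [1, likert_max]. Discretization slightly attenuates downstream ICA
    recovery; ``discretize=False`` gives the continuous panel.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed + 1)
    ic_cols = [f"IC_{c + 1}" for c in range(truth.q)]
    y = ic_values[ic_cols].to_numpy(dtype=float)  # n x q
    log_items = y @ truth.A.T + truth.item_intercept
    log_items = log_items + rng.normal(0.0, truth.item_noise_sd, size=log_items.shape)
    vals = np.exp(log_items)
    if discretize:
        vals = np.clip(np.floor(vals + 0.5), 1, truth.likert_max)
    panel = pd.DataFrame(vals, columns=[f"item_{i + 1:02d}" for i in range(truth.p_items)])
    panel.insert(0, "participant_id", ic_values["participant_id"].to_numpy())
    panel.insert(1, "date", ic_values["date"].to_numpy())
    return panel


def item_catalogue(truth: SyntheticTruth) -> pd.DataFrame:
    """Item -> questionnaire-family labels (synthetic provenance tags)."""
    scales = ("DRSP", "BAM", "BITe", "ASIQ", "PANAS", "INQ", "Misc")
    return pd.DataFrame(
        {
            "item": [f"item_{i + 1:02d}" for i in range(truth.p_items)],
            "scale": [scales[i % len(scales)] for i in range(truth.p_items)],
        }
    )


def _keystroke_arrays(
    truth: SyntheticTruth,
    median_ikd: float,
    log_sd: float,
    autocorrect_rate: float,
    backspace_rate: float,
    volume: int,
    day_start_s: float,
    rng: np.random.Generator,
    session_index_offset: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """One participant-day of raw keypresses.

    Volume is split over ``n_sessions_per_day`` sessions; inter-key delays
    are log-normal with the target median (capped below the 6 s rule so a
    session never splits) and sessions are separated by > 30 s gaps. Key
    classes are Bernoulli draws at the target rates.

    Returns ((timestamps, key-class codes, session indices), session
    starts); timestamps are seconds from the day start and key classes are
    int8 codes into ``keyboard.KEY_CLASSES``.
    """
    n_sessions = truth.n_sessions_per_day
    volume = max(volume, n_sessions)  # at least one press per session
    sizes = rng.multinomial(volume - n_sessions, np.full(n_sessions, 1.0 / n_sessions))
    sizes = sizes + 1
    delays = rng.lognormal(np.log(median_ikd), log_sd, size=volume)
    delays = np.minimum(delays, 5.9)
    u = rng.random(volume)
    # codes into keyboard.KEY_CLASSES: 0 alphanumeric, 1 autocorrect, 2 backspace
    key_class = np.where(
        u < autocorrect_rate,
        np.int8(1),
        np.where(u < autocorrect_rate + backspace_rate, np.int8(2), np.int8(0)),
    )
    gaps = keyboard_mod.DEFAULT_INACTIVITY_THRESHOLD_S + _SESSION_GAP_MIN_S + rng.exponential(
        60.0, size=n_sessions
    )
    ts = np.empty(volume)
    sess = np.empty(volume, dtype=int)
    pos = 0
    t = day_start_s
    session_starts = np.empty(n_sessions)
    for s, size in enumerate(sizes):
        t += gaps[s]
        session_starts[s] = t
        d = delays[pos : pos + size].copy()
        d[0] = 0.0
        ts[pos : pos + size] = t + np.cumsum(d)
        sess[pos : pos + size] = session_index_offset + s
        t = ts[pos + size - 1]
        pos += size
    return (ts, key_class, sess), session_starts




def simulate_keystrokes(
    truth: SyntheticTruth,
    median_ikd: float,
    log_sd: float,
    autocorrect_rate: float,
    backspace_rate: float,
    volume: int,
    day_start_s: float,
    rng: np.random.Generator,
    session_index_offset: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """One participant-day of raw keypresses as a DataFrame; see
    :func:`_keystroke_arrays` for the generative rules."""
    (ts, codes, sess), starts = _keystroke_arrays(
        truth,
        median_ikd,
        log_sd,
        autocorrect_rate,
        backspace_rate,
        volume,
        day_start_s,
        rng,
        session_index_offset,
    )
    events = pd.DataFrame(
        {
            "timestamp": ts,
            "key_class": pd.Categorical.from_codes(
                codes, categories=keyboard_mod.KEY_CLASSES
            ),
            "session_index": sess,
        }
    )
    return events, starts

def _accel_arrays(
    truth: SyntheticTruth,
    n_active: int,
    n_upright: int,
    rng: np.random.Generator,
    session_index_offset: int = 0,
) -> pd.DataFrame:
    """One participant-day of in-session accelerometer traces.

    Exactly ``n_active`` of the day's sessions get a low-frequency motion
    burst covering ~30% of samples (amplitude 0.35 g, far beyond the
    [0.95, 1.05] stationary band), the rest are flat around 1 g with 0.005 g
    noise. ``n_upright`` sessions are in upright orientation (median z
    ~0.02, x ~0), the others flat on the back (z ~0.8). Which sessions get
    which label is randomized independently.
    """
    n_sessions = truth.n_sessions_per_day
    n_samp = truth.accel_samples_per_session
    fs = truth.accel_sampling_rate
    active = np.zeros(n_sessions, dtype=bool)
    active[rng.permutation(n_sessions)[:n_active]] = True
    upright = np.zeros(n_sessions, dtype=bool)
    upright[rng.permutation(n_sessions)[:n_upright]] = True
    tt = np.arange(n_samp) / fs
    xyz = rng.normal(0.0, 0.005, size=(3, n_sessions, n_samp))
    base_up = np.array([0.0, np.sqrt(1 - 0.02**2), 0.02])
    base_flat = np.array([0.0, 0.6, 0.8])
    bases = np.where(upright[None, :], base_up[:, None], base_flat[:, None])
    xyz += bases[:, :, None]
    burst_len = int(0.3 * n_samp)
    for s in np.flatnonzero(active):
        start = rng.integers(0, n_samp - burst_len + 1)
        phase = rng.uniform(0, 2 * np.pi)
        xyz[1, s, start : start + burst_len] += 0.35 * np.sin(
            2 * np.pi * 1.5 * tt[:burst_len] + phase
        )
    return (
        np.repeat(session_index_offset + np.arange(n_sessions), n_samp),
        np.tile(tt, n_sessions),
        xyz[0].ravel(),
        xyz[1].ravel(),
        xyz[2].ravel(),
    )


def simulate_accelerometer(
    truth: SyntheticTruth,
    n_active: int,
    n_upright: int,
    rng: np.random.Generator,
    session_index_offset: int = 0,
) -> pd.DataFrame:
    """One participant-day of accelerometer traces as a DataFrame; see
    :func:`_accel_arrays` for the generative rules."""
    sess, tt, x, y, z = _accel_arrays(
        truth, n_active, n_upright, rng, session_index_offset
    )
    return pd.DataFrame(
        {"session_index": sess, "timestamp_s": tt, "x": x, "y": y, "z": z}
    )


def _latent_targets(truth: SyntheticTruth, z: np.ndarray) -> dict:
    """Map a day's independent standard-normal draws to stream-generation
    targets (positive scales, plausible magnitudes)."""
    return {
        "median_ikd": float(np.exp(np.log(0.25) + 0.15 * z[0])),
        "log_sd": float(np.clip(0.5 + 0.1 * z[1], 0.2, 1.0)),
        "autocorrect_rate": float(np.clip(0.05 + 0.015 * z[3], 0.002, 0.3)),
        "backspace_rate": float(np.clip(0.08 + 0.02 * z[4], 0.002, 0.4)),
        "volume": int(np.round(np.exp(7.0 + 0.2 * z[5]))),
        "movement_propensity": float(np.clip(0.35 + 0.15 * z[6], 0.0, 1.0)),
        "upright_propensity": float(np.clip(0.60 + 0.15 * z[7], 0.0, 1.0)),
    }


def simulate_study(
    truth: SyntheticTruth,
    out_dir: Optional[str] = None,
) -> dict:
    """Generate a full synthetic study bundle.

    Returns a dict with keys ``keypresses``, ``accel``, ``selfreport``
    (DataFrames matching the pipeline's input contracts), ``truth``
    (the SyntheticTruth), ``ic_values`` (the true per-day component
    values) and ``measured_features`` (the standardized measured feature
    table the outcomes were computed from). If ``out_dir`` is given the
    CSVs, the item catalogue, and ``truth.json`` are also written there.

    Per-modality day-level missingness is applied completely at random.
    """
    if truth.n_participants < 1 or truth.n_days < 1:
        raise ValueError("study must have at least one participant and one day")
    rng = np.random.default_rng(truth.seed)
    start = pd.Timestamp("2023-01-02")
    n_sessions = truth.n_sessions_per_day

    kp_parts, ac_parts = [], []
    day_keys = []
    planted = []
    n_samp = truth.accel_samples_per_session
    for i in range(truth.n_participants):
        pid = f"P{i:03d}"
        for d in range(truth.n_days):
            date = start + pd.Timedelta(days=d)
            z = rng.normal(size=8)
            tg = _latent_targets(truth, z)
            n_active = int(np.round(tg["movement_propensity"] * n_sessions))
            n_upright = int(np.round(tg["upright_propensity"] * n_sessions))
            offset = d * n_sessions
            ev, _ = _keystroke_arrays(
                truth,
                tg["median_ikd"],
                tg["log_sd"],
                tg["autocorrect_rate"],
                tg["backspace_rate"],
                tg["volume"],
                day_start_s=d * _DAY_SECONDS + 9 * 3600.0,
                rng=rng,
                session_index_offset=offset,
            )
            kp_parts.append((pid, date, *ev))
            ac = _accel_arrays(
                truth, n_active, n_upright, rng, session_index_offset=offset
            )
            ac_parts.append((pid, date, *ac))
            day_keys.append((pid, date))
            planted.append(tg)

    pid_levels = [f"P{i:03d}" for i in range(truth.n_participants)]
    pid_code = {p: c for c, p in enumerate(pid_levels)}
    kp_sizes = [len(p[2]) for p in kp_parts]
    kp_pid = np.repeat([pid_code[p[0]] for p in kp_parts], kp_sizes)
    kp_date = np.repeat(
        np.array([p[1] for p in kp_parts], dtype="datetime64[ns]"), kp_sizes
    )
    keypresses = pd.DataFrame(
        {
            "participant_id": pd.Categorical.from_codes(kp_pid, categories=pid_levels),
            "date": kp_date,
            "timestamp": np.concatenate([p[2] for p in kp_parts]),
            "key_class": pd.Categorical.from_codes(
                np.concatenate([p[3] for p in kp_parts]),
                categories=keyboard_mod.KEY_CLASSES,
            ),
            "session_index": np.concatenate([p[4] for p in kp_parts]),
        }
    )
    ac_rows = n_sessions * n_samp
    ac_pid = np.repeat([pid_code[p[0]] for p in ac_parts], ac_rows)
    ac_date = np.repeat(
        np.array([p[1] for p in ac_parts], dtype="datetime64[ns]"), ac_rows
    )
    accel = pd.DataFrame(
        {
            "participant_id": pd.Categorical.from_codes(ac_pid, categories=pid_levels),
            "date": ac_date,
            "session_index": np.concatenate([p[2] for p in ac_parts]),
            "timestamp_s": np.concatenate([p[3] for p in ac_parts]),
            "x": np.concatenate([p[4] for p in ac_parts]),
            "y": np.concatenate([p[5] for p in ac_parts]),
            "z": np.concatenate([p[6] for p in ac_parts]),
        }
    )

    # measure the daily features exactly as the pipeline will
    daily_kb = keyboard_mod.daily_keyboard_from_frame(keypresses)
    daily_ac = accel_mod.daily_accel_from_frame(
        accel, sampling_rate=truth.accel_sampling_rate
    )
    measured = daily_kb[daily_kb["included"]].merge(
        daily_ac, on=["participant_id", "date"], how="inner"
    )
    measured_std, _params = keyboard_mod.transform_and_standardize(
        measured, features=FIXED_TERMS
    )

    # outcomes from the measured features under the nested mixed model
    all_days = pd.DataFrame(day_keys, columns=["participant_id", "date"])
    all_days = all_days.merge(
        measured_std[["participant_id", "date", *FIXED_TERMS]],
        on=["participant_id", "date"],
        how="left",
    )
    x = all_days[list(FIXED_TERMS)].fillna(0.0).to_numpy()  # unmeasured days: x at its mean
    day_index = (pd.to_datetime(all_days["date"]) - start).dt.days.to_numpy()
    week = day_index // truth.days_per_week
    pid_arr = all_days["participant_id"].to_numpy()
    rand = _random_terms(truth, pid_arr, week, rng, truth.latent_family)
    y = truth.beta0[None, :] + x @ truth.beta1.T + rand
    ic_values = all_days[["participant_id", "date"]].copy()
    for c in range(truth.q):
        ic_values[f"IC_{c + 1}"] = y[:, c]

    selfreport = simulate_selfreport(truth, ic_values, rng)

    # day-level MCAR missingness per modality
    def _drop_days(frame: pd.DataFrame, rate: float) -> pd.DataFrame:
        if rate <= 0:
            return frame
        keys = frame[["participant_id", "date"]].drop_duplicates()
        keep = keys[rng.random(len(keys)) >= rate]
        return frame.merge(keep, on=["participant_id", "date"], how="inner")

    keypresses = _drop_days(keypresses, truth.missing_keyboard)
    accel = _drop_days(accel, truth.missing_accel)
    selfreport = _drop_days(selfreport, truth.missing_selfreport)

    bundle = {
        "keypresses": keypresses,
        "accel": accel,
        "selfreport": selfreport,
        "truth": truth,
        "ic_values": ic_values,
        "measured_features": measured_std,
        "planted_targets": pd.DataFrame(planted).assign(
            participant_id=[k[0] for k in day_keys],
            date=[k[1] for k in day_keys],
        ),
    }
    if out_dir is not None:
        _write_bundle(bundle, out_dir)
    return bundle


def _write_bundle(bundle: dict, out_dir: str) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kp = bundle["keypresses"].copy()
    base = pd.to_datetime(kp["date"])
    kp["timestamp"] = (
        pd.Timestamp("2023-01-02")
        + pd.to_timedelta(kp["timestamp"], unit="s")
    ).dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    kp["date"] = base.dt.strftime("%Y-%m-%d")
    kp[["participant_id", "timestamp", "date", "key_class"]].to_csv(
        out / "keypresses.csv", index=False
    )
    ac = bundle["accel"].copy()
    ac["date"] = pd.to_datetime(ac["date"]).dt.strftime("%Y-%m-%d")
    ac[["participant_id", "session_index", "date", "timestamp_s", "x", "y", "z"]].to_csv(
        out / "accel.csv", index=False
    )
    sr = bundle["selfreport"].copy()
    sr["date"] = pd.to_datetime(sr["date"]).dt.strftime("%Y-%m-%d")
    sr.to_csv(out / "selfreport.csv", index=False)
    item_catalogue(bundle["truth"]).to_csv(out / "item_catalogue.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(bundle["truth"].to_jsonable(), fh, indent=2)
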