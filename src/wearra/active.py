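"""Guided-test feature extraction.

Five smartphone-style assessments are summarised per participant-day:

* WRT — wrist range of motion: angular velocity is integrated (trapezoid),
  linearly detrended to control gyro drift, and ROM taken as the peak-to-peak
  angle;
* WLK — 30-s walk: steps are detected as peaks of the 0.5-3 Hz band-passed
  magnitude with an adaptive threshold, giving cadence and step regularity;
* PEG — digital 9-hole peg test: completion time and inter-event intervals;
* STS / LTS — postural transitions: the transition interval is read from the
  10-90% crossing of the low-pass vertical-axis component between its two
  quasi-static plateaus, rescaled by 1/0.8 so an (approximately linear)
  transition reports its full duration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import integrate, signal

from .synthetic import GuidedTestRecordings

ACTIVE_DOMAINS = ("WRT", "WLK", "PEG", "STS", "LTS")


# ---------------------------------------------------------------------------
# wrist range of motion
# ---------------------------------------------------------------------------

def extract_wrt_features(omega_deg_s: np.ndarray, sample_rate_hz: float) -> dict[str, float]:
    """ROM (deg), cycle count, and mean angular speed from a gyro stream.

    Gyroscope bias integrates to a linear angle drift; it is removed by
    subtracting the mean angular velocity before integrating (equivalent to a
    linear detrend of the angle anchored on the true drift slope — a
    least-squares line fit would instead tilt an oscillation that does not
    span an integer number of cycles).
    """
    omega = np.asarray(omega_deg_s, dtype=float)
    if omega.size < 5 * sample_rate_hz:
        raise ValueError("wrist recording shorter than 5 s")
    if not np.isfinite(omega).all():
        raise ValueError("non-finite angular velocity samples")
    t = np.arange(omega.size) / sample_rate_hz
    angle = integrate.cumulative_trapezoid(omega - omega.mean(), t, initial=0.0)
    rom = float(angle.max() - angle.min())
    # cycles: zero crossings of the detrended angle / 2
    crossings = int(np.sum(np.abs(np.diff(np.signbit(angle).astype(np.int8)))))
    return {
        "wrt_rom_deg": rom,
        "wrt_cycles": crossings / 2.0,
        "wrt_mean_angular_speed": float(np.mean(np.abs(omega))),
    }


# ---------------------------------------------------------------------------
# 30-s walk
# ---------------------------------------------------------------------------

def extract_wlk_features(accel: np.ndarray, sample_rate_hz: float,
                         peak_frac: float = 0.3,
                         min_step_separation_s: float = 0.25) -> dict[str, float]:
    """Step count, cadence and step regularity from a ~30 s walk recording.

    The tri-axial magnitude is band-passed to 0.5-3 Hz; steps are peaks above
    ``peak_frac`` times the band-passed signal's standard deviation, at least
    ``min_step_separation_s`` apart (the adaptive threshold makes the count
    invariant to global magnitude scaling).  Regularity is the autocorrelation
    at the dominant period.
    """
    accel = np.atleast_2d(np.asarray(accel, dtype=float))
    duration = accel.shape[0] / sample_rate_hz
    feats: dict[str, float] = {"wlk_short_recording": float(duration < 28.0)}
    mag = np.linalg.norm(accel, axis=1) if accel.shape[1] == 3 else accel.ravel()
    mag = mag - mag.mean()
    nyq = sample_rate_hz / 2
    sos = signal.butter(4, [0.5 / nyq, min(3.0, 0.99 * nyq) / nyq], btype="band",
                        output="sos")
    bp = signal.sosfiltfilt(sos, mag)
    sd = bp.std()
    if sd <= 1e-12:
        feats.update({"wlk_steps": 0.0, "wlk_cadence_spm": 0.0,
                      "wlk_regularity": np.nan})
        return feats
    peaks, _ = signal.find_peaks(bp, height=peak_frac * sd,
                                 distance=max(1, int(min_step_separation_s * sample_rate_hz)))
    steps = int(peaks.size)
    feats["wlk_steps"] = float(steps)
    feats["wlk_cadence_spm"] = steps / duration * 60.0
    feats["wlk_regularity"] = _regularity(bp)
    return feats


def _regularity(x: np.ndarray) -> float:
    """Normalised autocorrelation at the dominant non-zero lag."""
    x = x - x.mean()
    ac = signal.correlate(x, x, mode="full")[x.size - 1:]
    if ac[0] <= 0:
        return np.nan
    ac = ac / ac[0]
    # first peak after the first zero crossing of the autocorrelation
    peaks, _ = signal.find_peaks(ac)
    return float(ac[peaks[0]]) if peaks.size else np.nan


# ---------------------------------------------------------------------------
# 9-hole peg test
# ---------------------------------------------------------------------------

def extract_peg_features(events_s: np.ndarray) -> dict[str, float]:
    """Completion time and inter-event interval statistics."""
    ev = np.asarray(events_s, dtype=float)
    if ev.size < 2:
        raise ValueError("peg test needs at least 2 touch events")
    if not np.all(np.diff(ev) > 0):
        raise ValueError("peg touch events must be strictly increasing")
    iv = np.diff(ev)
    return {
        "peg_completion_s": float(ev[-1] - ev[0]),
        "peg_interval_mean_s": float(iv.mean()),
        "peg_interval_sd_s": float(iv.std(ddof=1)) if iv.size > 1 else np.nan,
    }


# ---------------------------------------------------------------------------
# postural transitions
# ---------------------------------------------------------------------------

def extract_transition_features(accel: np.ndarray, sample_rate_hz: float,
                                prefix: str = "sts") -> dict[str, float]:
    """Transition duration, peak magnitude and smoothness for STS/LTS.

    The vertical axis is the one with the largest plateau-to-plateau change of
    its low-pass component.  Duration is (t90 - t10) / 0.8 between the 10% and
    90% crossings of the plateau-to-plateau span, which reports the full
    duration for an approximately linear transition.  Smoothness is -log of
    the mean squared jerk of the magnitude during the transition.
    """
    accel = np.asarray(accel, dtype=float)
    n = accel.shape[0]
    quarter = max(1, n // 4)
    sos = signal.butter(4, min(2.0, 0.45 * sample_rate_hz) / (sample_rate_hz / 2),
                        output="sos")
    low = signal.sosfiltfilt(sos, accel, axis=0)
    spans = np.abs(np.median(low[-quarter:], axis=0) - np.median(low[:quarter], axis=0))
    axis = int(np.argmax(spans))
    v = low[:, axis]
    a0 = float(np.median(v[:quarter]))
    a1 = float(np.median(v[-quarter:]))
    span = a1 - a0
    null = {f"{prefix}_duration_s": np.nan, f"{prefix}_peak_mag": np.nan,
            f"{prefix}_smoothness": np.nan, f"{prefix}_detected": 0.0}
    if abs(span) < 0.1:
        return null  # no plateau structure
    frac = (v - a0) / span
    inside = np.flatnonzero((frac > 0.1) & (frac < 0.9))
    if inside.size == 0:
        # effectively instantaneous transition
        out = dict(null)
        out.update({f"{prefix}_duration_s": 0.0, f"{prefix}_detected": 1.0})
        return out
    t10, t90 = inside[0], inside[-1]
    duration = (t90 - t10 + 1) / sample_rate_hz / 0.8
    mag = np.linalg.norm(accel[t10:t90 + 1], axis=1)
    jerk = np.diff(mag) * sample_rate_hz
    msj = float(np.mean(jerk ** 2)) if jerk.size else np.nan
    return {
        f"{prefix}_duration_s": float(duration),
        f"{prefix}_peak_mag": float(mag.max()) if mag.size else np.nan,
        f"{prefix}_smoothness": -np.log(msj) if msj and msj > 0 else np.nan,
        f"{prefix}_detected": 1.0,
    }


# ---------------------------------------------------------------------------
# per-day assembly
# ---------------------------------------------------------------------------

def extract_guided_day(rec: GuidedTestRecordings) -> dict[str, float]:
    feats: dict[str, float] = {}
    feats.update(extract_wrt_features(rec.wrt, rec.sample_rate_hz))
    feats.update(extract_wlk_features(rec.wlk, rec.sample_rate_hz))
    feats.update(extract_peg_features(rec.peg))
    feats.update(extract_transition_features(rec.sts, rec.sample_rate_hz, "sts"))
    feats.update(extract_transition_features(rec.lts, rec.sample_rate_hz, "lts"))
    return feats


def active_domain_of(feature: str) -> str:
    for dom in ACTIVE_DOMAINS:
        if feature.lower().startswith(dom.lower() + "_"):
            return dom
    raise KeyError(f"unknown active feature {feature!r}")


def summarize_guided_daily(recordings: list[GuidedTestRecordings],
                           missing_days: set[int] | None = None) -> pd.DataFrame:
    """Active features, one row per day, NaN rows for missing days."""
    missing_days = missing_days or set()
    rows = []
    for rec in recordings:
        row = {"participant_id": rec.participant_id, "day_index": rec.day_index}
        if rec.day_index not in missing_days:
            row.update(extract_guided_day(rec))
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in df.columns:
        if col not in ("participant_id", "day_index"):
            active_domain_of(col)
    return df


def active_domain_map(df: pd.DataFrame) -> dict[str, str]:
    return {c: active_domain_of(c) for c in df.columns
            if c not in ("participant_id", "day_index")}
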