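"""Passive actigraphy features, one row per participant-day.

Feature domains:

* ``TVDA``  — total volume of daytime activity: class fractions, MVPA minutes,
  mean and 95th-percentile daytime movement magnitude;
* ``SLEEP`` — main sleep duration per noon-to-noon night;
* ``MORN``  — morning stiffness: movement in the first 30 min after wake-up
  relative to the following hour;
* ``NTR``   — night-time restlessness: movement episodes within the main sleep
  window;
* ``AF``    — activity fragmentation: active->rest transition probability and
  active bout structure;
* ``DEM``   — demographics replicated per row.

Missing values are recorded as NaN and excluded from aggregation denominators,
never imputed as zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import SECONDS_PER_DAY, ActivitySequence, ParticipantRecord, _runs

log = logging.getLogger(__name__)

#: classes counted as "active" for the fragmentation dichotomy
ACTIVE_CLASSES = {"light", "MVPA", "walking", "bicycling", "mixed"}

DOMAINS = ("TVDA", "SLEEP", "MORN", "NTR", "AF", "DEM")


@dataclass
class SleepWindow:
    night_index: int
    onset_s: float
    offset_s: float

    @property
    def duration_h(self) -> float:
        return (self.offset_s - self.onset_s) / 3600.0


# ---------------------------------------------------------------------------
# sleep detection
# ---------------------------------------------------------------------------

def detect_sleep_periods(seq: ActivitySequence,
                         merge_gap_min: float = 30.0) -> list[SleepWindow]:
    """Main sleep window per noon-to-noon night.

    Sleep-labelled runs whose separating gap is <= ``merge_gap_min`` are merged
    (brief awakenings do not split main sleep); the longest merged run whose
    midpoint falls in the night [noon(d), noon(d+1)) is that night's main
    sleep.  Nights without any sleep epochs yield no window.
    """
    if "sleep" not in seq.classes:
        raise ValueError("taxonomy has no sleep class")
    sleep_idx = seq.classes.index("sleep")
    mask = seq.codes == sleep_idx
    runs = _runs(mask)
    if not runs:
        return []
    # merge runs separated by short gaps
    gap_epochs = merge_gap_min * 60.0 / seq.epoch_len_s
    merged: list[list[int]] = []
    for start, stop in runs:
        if merged and start - merged[-1][1] <= gap_epochs:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])

    t0 = seq.epoch_start_s
    total_s = seq.n_epochs * seq.epoch_len_s
    first_night = int(math.floor((t0 - SECONDS_PER_DAY / 2) / SECONDS_PER_DAY))
    last_night = int(math.floor((t0 + total_s - SECONDS_PER_DAY / 2) / SECONDS_PER_DAY))
    windows = []
    for night in range(first_night, last_night + 1):
        night_lo = night * SECONDS_PER_DAY + SECONDS_PER_DAY / 2
        night_hi = night_lo + SECONDS_PER_DAY
        best = None
        for start, stop in merged:
            onset = t0 + start * seq.epoch_len_s
            offset = t0 + stop * seq.epoch_len_s
            mid = (onset + offset) / 2
            if night_lo <= mid < night_hi:
                if best is None or (offset - onset) > (best.offset_s - best.onset_s):
                    best = SleepWindow(night, onset, offset)
        if best is not None:
            windows.append(best)
        else:
            log.debug("no main sleep for night %d of %s", night, seq.participant_id)
    return windows


def _epoch_slice(seq: ActivitySequence, lo_s: float, hi_s: float) -> slice:
    e0 = int(np.ceil((lo_s - seq.epoch_start_s) / seq.epoch_len_s))
    e1 = int(np.ceil((hi_s - seq.epoch_start_s) / seq.epoch_len_s))
    return slice(max(e0, 0), min(max(e1, 0), seq.n_epochs))


# ---------------------------------------------------------------------------
# feature families
# ---------------------------------------------------------------------------

def compute_tvda_features(seq: ActivitySequence, mags: np.ndarray, day: int,
                          sleep_windows: list[SleepWindow] | None = None) -> dict[str, float]:
    """Daytime activity volume for one calendar day.

    Daytime epochs are those of the day outside any main sleep window.
    Fractions are over the whole day (all classes, so they sum to 1); MVPA
    minutes and magnitude summaries use daytime epochs only.
    """
    sl = _epoch_slice(seq, day * SECONDS_PER_DAY, (day + 1) * SECONDS_PER_DAY)
    codes = seq.codes[sl]
    if codes.size == 0:
        return {}
    times = seq.epoch_times()[sl]
    day_mags = mags[sl]
    in_sleep_window = np.zeros(codes.size, dtype=bool)
    for w in sleep_windows or []:
        in_sleep_window |= (times >= w.onset_s) & (times < w.offset_s)
    feats: dict[str, float] = {}
    for i, cname in enumerate(seq.classes):
        feats[f"frac_{cname}"] = float(np.mean(codes == i))
    if "MVPA" in seq.classes:
        mvpa = seq.classes.index("MVPA")
        feats["mvpa_minutes"] = float(np.sum(codes == mvpa) * seq.epoch_len_s / 60.0)
    daytime = day_mags[~in_sleep_window]
    if daytime.size:
        feats["daytime_mag_mean"] = float(daytime.mean())
        feats["daytime_mag_p95"] = float(np.percentile(daytime, 95))
    else:
        feats["daytime_mag_mean"] = np.nan
        feats["daytime_mag_p95"] = np.nan
    return feats


def compute_morning_stiffness(seq: ActivitySequence, mags: np.ndarray,
                              wake_s: float, early_min: float = 30.0,
                              post_min: float = 60.0) -> dict[str, float]:
    """Post-wake movement attenuation.

    Mean magnitude in [wake, wake+30 min) (early), in [wake+30, wake+90 min)
    (post), and their ratio; all features are NaN when less than 90 min of
    data follows wake-up.
    """
    need_s = (early_min + post_min) * 60.0
    end_s = seq.epoch_start_s + seq.n_epochs * seq.epoch_len_s
    null = {"morning_early_mag": np.nan, "morning_post_mag": np.nan,
            "morning_ratio": np.nan}
    if wake_s + need_s > end_s:
        return null
    early = mags[_epoch_slice(seq, wake_s, wake_s + early_min * 60.0)]
    post = mags[_epoch_slice(seq, wake_s + early_min * 60.0, wake_s + need_s)]
    if early.size == 0 or post.size == 0:
        return null
    e, q = float(early.mean()), float(post.mean())
    return {"morning_early_mag": e, "morning_post_mag": q,
            "morning_ratio": e / q if q > 0 else np.nan}


def compute_night_restlessness(seq: ActivitySequence, mags: np.ndarray,
                               window: SleepWindow,
                               threshold: float | None = None) -> dict[str, float]:
    """Movement episodes within a main sleep window.

    An episode is a maximal run of epochs with magnitude above threshold; the
    default threshold is mean + 3 sd of the quiet reference (the below-median
    half of the window's magnitudes).  Windows shorter than 1 h yield NaNs.
    """
    null = {"ntr_episode_count": np.nan, "ntr_restless_minutes": np.nan,
            "ntr_episodes_per_h": np.nan}
    if window.duration_h < 1.0:
        return null
    sl = _epoch_slice(seq, window.onset_s, window.offset_s)
    m = mags[sl]
    if m.size == 0:
        return null
    if threshold is None:
        quiet = m[m <= np.median(m)]
        threshold = float(quiet.mean() + 3.0 * quiet.std())
    above = m > threshold
    episodes = _runs(above)
    restless_min = float(above.sum() * seq.epoch_len_s / 60.0)
    return {"ntr_episode_count": float(len(episodes)),
            "ntr_restless_minutes": restless_min,
            "ntr_episodes_per_h": len(episodes) / window.duration_h}


def compute_activity_fragmentation(seq: ActivitySequence, day: int) -> dict[str, float]:
    """Active/rest bout structure for one day.

    Epochs are dichotomised to active (light/MVPA-type classes) vs rest; the
    transition probability is active->rest transitions divided by active
    epochs, the standard actigraphy fragmentation index.
    """
    sl = _epoch_slice(seq, day * SECONDS_PER_DAY, (day + 1) * SECONDS_PER_DAY)
    codes = seq.codes[sl]
    if codes.size == 0:
        return {}
    active_idx = {i for i, c in enumerate(seq.classes) if c in ACTIVE_CLASSES}
    active = np.isin(codes, list(active_idx))
    n_active = int(active.sum())
    bouts = _runs(active)
    trans = sum(1 for _, stop in bouts if stop < active.size)  # bouts ending in rest
    feats = {"af_bout_count": float(len(bouts))}
    if n_active == 0:
        feats["af_transition_prob"] = np.nan
        feats["af_mean_bout_min"] = np.nan
    else:
        feats["af_transition_prob"] = trans / n_active
        feats["af_mean_bout_min"] = float(
            np.mean([(stop - start) for start, stop in bouts]) * seq.epoch_len_s / 60.0)
    return feats


#: domain of each passive feature name (prefix-matched for class fractions)
def domain_of(feature: str) -> str:
    if feature.startswith(("frac_", "mvpa_", "daytime_")):
        return "TVDA"
    if feature.startswith("sleep_"):
        return "SLEEP"
    if feature.startswith("morning_"):
        return "MORN"
    if feature.startswith("ntr_"):
        return "NTR"
    if feature.startswith("af_"):
        return "AF"
    if feature in ("age", "bmi", "sex_female"):
        return "DEM"
    raise KeyError(f"unknown passive feature {feature!r}")


def summarize_daily(p: ParticipantRecord, seq: ActivitySequence,
                    mags: np.ndarray, n_days: int,
                    missing_days: set[int] | None = None) -> pd.DataFrame:
    """All passive features for one participant, one row per day.

    Wake-up time for day d is the offset of the main sleep window ending that
    morning; night features for day d describe the night *ending* on day d.
    Missing days yield rows of NaNs (kept so aggregation can count them).
    """
    windows = detect_sleep_periods(seq)
    wake_by_day = {int(w.offset_s // SECONDS_PER_DAY): w.offset_s for w in windows}
    window_by_end_day = {int(w.offset_s // SECONDS_PER_DAY): w for w in windows}
    missing_days = missing_days or set()
    rows = []
    for day in range(n_days):
        feats: dict[str, float] = {}
        if day not in missing_days:
            feats.update(compute_tvda_features(seq, mags, day, windows))
            feats.update(compute_activity_fragmentation(seq, day))
            w = window_by_end_day.get(day)
            feats["sleep_duration_h"] = w.duration_h if w else np.nan
            if w is not None:
                feats.update(compute_night_restlessness(seq, mags, w))
            if day in wake_by_day:
                feats.update(compute_morning_stiffness(seq, mags, wake_by_day[day]))
        feats["age"] = p.age
        feats["bmi"] = p.bmi
        feats["sex_female"] = 1.0 if p.sex == "F" else 0.0
        row = {"participant_id": p.participant_id, "day_index": day}
        row.update(feats)
        rows.append(row)
    df = pd.DataFrame(rows)
    # every non-key column must have a domain
    for col in df.columns:
        if col not in ("participant_id", "day_index"):
            domain_of(col)
    return df


def passive_domain_map(df: pd.DataFrame) -> dict[str, str]:
    """feature name -> domain for a daily passive feature table."""
    return {c: domain_of(c) for c in df.columns
            if c not in ("participant_id", "day_index")}
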