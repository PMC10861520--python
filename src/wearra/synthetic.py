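"""Synthetic RA study generator.

Generates everything a wearable RA study would collect, with configurable
group effects (healthy controls vs. moderate vs. severe RA):

* a cohort table with demographics, baseline RAPID-3 and PRO scores,
* per-participant activity label sequences (semi-Markov over a broad activity
  taxonomy, one main sleep block per night that spans midnight),
* per-epoch wrist movement magnitudes and, at small scale, raw tri-axial
  acceleration streams consistent with the same per-class model,
* daily guided-test recordings (wrist ROM, 30-s walk, 9-hole peg,
  sit-to-stand, lie-to-stand).

All draws are keyed on ``cfg.seed`` and the participant id, so an identical
configuration reproduces the data bit for bit regardless of call order.

PRO scores are exact truncated normals on each instrument's range, driven by a
per-participant latent severity shared with the baseline RAPID-3 draw, so PROs
and RAPID-3 correlate within group at ``cfg.pro_severity_coupling``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import (
    BROAD_CLASSES,
    FINE_CLASSES,
    PRO_RANGES,
    RAPID3_RANGE,
    ConfigurationError,
    EffectConfig,
    GroupEffects,
)

SECONDS_PER_DAY = 86400

#: instruments where higher scores mean *better* health (reversed coupling)
_REVERSED = {"FACIT"}


@dataclass
class ParticipantRecord:
    participant_id: str
    group: str  # HC | RA_mod | RA_sev
    age: float
    sex: str  # F | M
    bmi: float
    rapid3_baseline: float
    pro: dict[str, float]
    severity_z: float = 0.0  # latent severity (generative bookkeeping)


@dataclass
class ActivitySequence:
    participant_id: str
    epoch_start_s: float
    epoch_len_s: int
    classes: tuple[str, ...]
    codes: np.ndarray  # int codes into classes, one per epoch

    @property
    def labels(self) -> np.ndarray:
        return np.asarray(self.classes, dtype=object)[self.codes]

    @property
    def n_epochs(self) -> int:
        return int(self.codes.size)

    def epoch_times(self) -> np.ndarray:
        return self.epoch_start_s + self.epoch_len_s * np.arange(self.n_epochs)


@dataclass
class RawTriaxialStream:
    participant_id: str
    sample_rate_hz: float
    start_s: float
    samples: np.ndarray  # (n, 3) in g

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.samples, axis=1)


@dataclass
class GuidedTestRecordings:
    participant_id: str
    day_index: int
    sample_rate_hz: float
    wrt: np.ndarray  # angular velocity, deg/s
    wlk: np.ndarray  # (n, 3) acceleration in g, ~30 s
    peg: np.ndarray  # strictly increasing touch-event times, s
    sts: np.ndarray  # (n, 3) acceleration, one sit-to-stand transition
    lts: np.ndarray  # (n, 3) acceleration, one lie-to-stand transition


def _pid_key(participant_id: str) -> int:
    digest = hashlib.sha256(participant_id.encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def _rng(cfg: EffectConfig, participant_id: str, tag: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed & 0x7FFFFFFF, _pid_key(participant_id), tag])


def _truncnorm_from_latent(v: np.ndarray | float, mean: float, sd: float,
                           lo: float, hi: float) -> np.ndarray | float:
    """Map a standard-normal latent value to a truncated normal draw.

    The marginal over v ~ N(0,1) is exactly TruncNorm(mean, sd; lo, hi);
    sd = 0 degenerates to the (clipped) mean.
    """
    if sd == 0:
        out = np.clip(mean, lo, hi)
        return np.full_like(np.asarray(v, dtype=float), out) if np.ndim(v) else float(out)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = stats.norm.cdf(v)
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def generate_cohort(n_hc: int, n_ra_mod: int, n_ra_sev: int,
                    cfg: EffectConfig) -> list[ParticipantRecord]:
    """Draw a cohort with per-group PRO/demographic distributions.

    Healthy controls get a baseline RAPID-3 of exactly zero; RA groups draw it
    from their configured truncated normal.  A shared latent severity couples
    RAPID-3 and the PRO battery within participant.
    """
    cfg.validate()
    counts = {"HC": n_hc, "RA_mod": n_ra_mod, "RA_sev": n_ra_sev}
    if any(n < 0 for n in counts.values()):
        raise ValueError("cohort counts must be nonnegative")
    rho = cfg.pro_severity_coupling
    records: list[ParticipantRecord] = []
    for group, n in counts.items():
        g = cfg.groups[group]
        for i in range(n):
            pid = f"{group}-{i:03d}"
            rng = _rng(cfg, pid, tag=1)
            z = float(rng.standard_normal())
            age = float(np.clip(g.age[0] + g.age[1] * rng.standard_normal(), 18.0, 95.0))
            bmi = float(np.clip(g.bmi[0] + g.bmi[1] * rng.standard_normal(), 15.0, 60.0))
            sex = "F" if rng.random() < g.female_fraction else "M"
            rapid3 = float(_truncnorm_from_latent(z, g.rapid3[0], g.rapid3[1], *RAPID3_RANGE))
            pro = {}
            for instr, (mean, sd) in g.pro.items():
                direction = -1.0 if instr in _REVERSED else 1.0
                eps = float(rng.standard_normal())
                v = direction * (rho * z + np.sqrt(1.0 - rho ** 2) * eps)
                lo, hi = PRO_RANGES[instr]
                pro[instr] = float(_truncnorm_from_latent(v, mean, sd, lo, hi))
            records.append(ParticipantRecord(pid, group, age, sex, bmi, rapid3, pro, z))
    return records


# ---------------------------------------------------------------------------
# activity sequences
# ---------------------------------------------------------------------------

def _sleep_blocks(g: GroupEffects, n_days: int, cfg: EffectConfig,
                  rng: np.random.Generator,
                  subject_sleep_shift_s: float) -> list[tuple[float, float]]:
    """Main sleep windows (onset_s, offset_s), one per night, centred ~03:00.

    The block for the night ending on morning d spans midnight of day d; day 0
    starts mid-sleep (the study clock starts at local midnight).  A trailing
    block starting on the last evening is included and truncated downstream.
    """
    frac = g.activity_fractions.get("sleep", 0.0)
    if frac <= 0:
        return []
    dur = frac * SECONDS_PER_DAY + subject_sleep_shift_s
    centre = 3 * 3600.0
    blocks = []
    for d in range(n_days + 1):
        jitter_c = rng.normal(0.0, 900.0)
        jitter_d = rng.normal(0.0, cfg.day_sleep_sd_h * 3600.0)
        c = d * SECONDS_PER_DAY + centre + jitter_c
        half = max(1800.0, (dur + jitter_d)) / 2.0
        blocks.append((c - half, c + half))
    return blocks


def simulate_activity_days(p: ParticipantRecord, n_days: int,
                           cfg: EffectConfig) -> ActivitySequence:
    """Semi-Markov activity sequence over the configured taxonomy.

    One main sleep block per night (spanning midnight); waking epochs follow a
    semi-Markov chain whose class entry probabilities are chosen so the
    expected fraction of the *whole day* in each class matches the configured
    activity composition, with geometric dwell times at the configured means.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    cfg.validate()
    classes = BROAD_CLASSES if cfg.taxonomy == "broad" else FINE_CLASSES
    g = cfg.groups[p.group]
    unknown = set(g.activity_fractions) - set(classes)
    if unknown:
        raise ConfigurationError(f"activity fractions name classes outside the "
                                 f"{cfg.taxonomy} taxonomy: {sorted(unknown)}")
    epd = SECONDS_PER_DAY // cfg.epoch_len_s
    total = n_days * epd
    rng = _rng(cfg, p.participant_id, tag=2)
    codes = np.full(total, -1, dtype=np.int16)

    # subject-level heterogeneity: activity share of the energetic classes and
    # habitual sleep duration vary between participants
    s_sd = cfg.subject_activity_log_sd
    subj_act = {c: float(np.exp(rng.normal(-0.5 * s_sd ** 2, s_sd)))  # mean-one
                for c in ("light", "MVPA", "walking", "bicycling")}
    subj_sleep_shift = float(rng.normal(0.0, cfg.subject_sleep_sd_h * 3600.0))

    sleep_idx = classes.index("sleep") if "sleep" in classes else -1
    if sleep_idx >= 0:
        for onset, offset in _sleep_blocks(g, n_days, cfg, rng, subj_sleep_shift):
            e0 = max(0, int(np.ceil(onset / cfg.epoch_len_s)))
            e1 = min(total, int(np.ceil(offset / cfg.epoch_len_s)))
            if e1 > e0:
                codes[e0:e1] = sleep_idx

    wake_classes = [c for c in classes
                    if c != "sleep" and g.activity_fractions.get(c, 0.0) > 0]
    if not wake_classes:
        if (codes == -1).any():
            raise ConfigurationError("no waking class has positive mass but "
                                     "waking epochs exist")
        return ActivitySequence(p.participant_id, 0.0, cfg.epoch_len_s, classes, codes)

    base_fr = np.array([g.activity_fractions[c] * subj_act.get(c, 1.0)
                        for c in wake_classes])
    dwell = np.array([g.dwell_mean_epochs.get(c, 5.0) for c in wake_classes])
    energetic = np.array([c in subj_act for c in wake_classes])
    wake_codes = np.array([classes.index(c) for c in wake_classes], dtype=np.int16)

    # fill each contiguous waking segment (one per day, between sleep blocks)
    # with its own day-level activity multiplier
    for start, stop in _runs(codes == -1):
        fr = base_fr.copy()
        d_sd = cfg.day_activity_log_sd
        day_mult = np.exp(rng.normal(-0.5 * d_sd ** 2, d_sd))  # mean-one
        fr[energetic] *= day_mult
        fr = fr / fr.sum()
        entry = fr / dwell
        entry = entry / entry.sum()
        seg_len = stop - start
        filled = 0
        parts = []
        n_runs = int(seg_len / max(dwell.min(), 1.0) + 20)
        while filled < seg_len:
            ks = rng.choice(len(wake_classes), size=n_runs, p=entry)
            ls = rng.geometric(1.0 / np.maximum(dwell[ks], 1.0))
            parts.append(np.repeat(wake_codes[ks], ls))
            filled += int(ls.sum())
        codes[start:stop] = np.concatenate(parts)[:seg_len]
    return ActivitySequence(p.participant_id, 0.0, cfg.epoch_len_s, classes, codes)


def main_sleep_offsets(seq: ActivitySequence) -> dict[int, float]:
    """Wake-up time (s) per calendar day, from the decoded/true labels.

    Convenience used by the epoch-magnitude generator; the analysis-side sleep
    detector lives in :mod:`wearra.passive`.
    """
    from .passive import detect_sleep_periods  # local import to avoid cycle

    out = {}
    for w in detect_sleep_periods(seq):
        day = int(w.offset_s // SECONDS_PER_DAY)
        out[day] = w.offset_s
    return out


# ---------------------------------------------------------------------------
# epoch magnitudes and raw streams
# ---------------------------------------------------------------------------

def _class_sd(cfg: EffectConfig, classes: tuple[str, ...]) -> np.ndarray:
    default = 0.02
    return np.array([cfg.class_dynamic_sd_g.get(c, default) for c in classes])


def simulate_epoch_magnitudes(seq: ActivitySequence, p: ParticipantRecord,
                              cfg: EffectConfig) -> np.ndarray:
    """Per-epoch mean movement magnitude (g), epoch-aligned with ``seq``.

    The value is the epoch mean of |acceleration magnitude - 1 g| implied by
    the per-class dynamic model (sd_c * sqrt(2/pi), with multiplicative
    within-class noise).  Two RA symptom channels are injected: movement in
    the configured post-wake window is multiplied by the group's morning
    attenuation, and movement episodes are superimposed on sleep at the
    group's hourly rate.  This is the scale bridge that lets full cohorts be
    simulated without synthesising raw 30 Hz data.
    """
    g = cfg.groups[p.group]
    rng = _rng(cfg, p.participant_id, tag=3)
    subj_mag = np.exp(rng.normal(0.0, cfg.subject_mag_log_sd))
    sym_sd = cfg.subject_symptom_log_sd
    subj_rate = np.exp(rng.normal(0.0, sym_sd))
    subj_atten = float(np.clip(g.morning_attenuation * np.exp(rng.normal(0.0, 0.5 * sym_sd)),
                               0.05, 1.0))
    times = seq.epoch_times()
    day_mult = np.exp(rng.normal(0.0, cfg.day_mag_log_sd,
                                 int(times[-1] // SECONDS_PER_DAY) + 1))
    sd = _class_sd(cfg, seq.classes)[seq.codes]
    mags = sd * np.sqrt(2.0 / np.pi) * subj_mag \
        * day_mult[(times // SECONDS_PER_DAY).astype(int)] \
        * np.exp(cfg.epoch_mag_log_sd * rng.standard_normal(seq.n_epochs))

    # morning attenuation after each wake-up
    window = cfg.morning_window_min * 60.0
    for wake in main_sleep_offsets(seq).values():
        mask = (times >= wake) & (times < wake + window)
        mags[mask] *= subj_atten

    # night-time movement episodes within sleep runs
    sleep_idx = seq.classes.index("sleep") if "sleep" in seq.classes else -1
    if sleep_idx >= 0:
        in_sleep = seq.codes == sleep_idx
        runs = _runs(in_sleep)
        lo, hi = cfg.night_episode_len_epochs
        for start, stop in runs:
            hours = (stop - start) * seq.epoch_len_s / 3600.0
            n_ep = rng.poisson(g.night_episode_rate_per_h * subj_rate * hours)
            for _ in range(n_ep):
                e = int(rng.integers(start, stop))
                length = int(rng.integers(lo, hi + 1))
                amp = cfg.night_episode_magnitude_g * np.exp(0.2 * rng.standard_normal())
                mags[e: min(e + length, stop)] = amp
    return mags


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs."""
    if mask.size == 0:
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    stops = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts = [0] + starts
    if mask[-1]:
        stops = stops + [mask.size]
    return list(zip(starts, stops))


_CLASS_FREQ_HZ = {"light": 1.2, "MVPA": 2.0, "walking": 1.8, "bicycling": 1.5}


def synthesize_raw_stream(seq: ActivitySequence, cfg: EffectConfig,
                          group: GroupEffects | None = None,
                          participant: ParticipantRecord | None = None) -> RawTriaxialStream:
    """Raw tri-axial acceleration consistent with the per-class epoch model.

    Each epoch carries a slowly re-orienting gravity unit vector (class-specific
    orientation-change rate) plus a zero-mean dynamic component whose standard
    deviation increases sleep < sedentary < light < MVPA; ambulatory classes add
    a periodic component at a class-typical step frequency so spectral features
    are informative.  Morning attenuation and night episodes are applied when a
    participant record is given (to resolve the group).
    """
    fs = cfg.sample_rate_hz
    n_per = int(round(fs * seq.epoch_len_s))
    total = n_per * seq.n_epochs
    rng = _rng(cfg, seq.participant_id, tag=4)
    g = group
    if g is None and participant is not None:
        g = cfg.groups[participant.group]

    sd_epoch = _class_sd(cfg, seq.classes)[seq.codes]
    rate_epoch = np.array([cfg.class_orientation_rate.get(c, 0.01)
                           for c in seq.classes])[seq.codes]

    atten = np.ones(seq.n_epochs)
    if g is not None and participant is not None:
        window = cfg.morning_window_min * 60.0
        times = seq.epoch_times()
        for wake in main_sleep_offsets(seq).values():
            atten[(times >= wake) & (times < wake + window)] = g.morning_attenuation

    out = np.empty((total, 3))
    grav = np.array([0.0, 0.0, 1.0])
    t_epoch = np.arange(n_per) / fs
    for e in range(seq.n_epochs):
        step = rng.standard_normal(3) * rate_epoch[e] * seq.epoch_len_s
        grav = grav + step
        grav = grav / np.linalg.norm(grav)
        sd = sd_epoch[e] * atten[e]
        dyn = rng.standard_normal((n_per, 3)) * sd
        cname = seq.classes[seq.codes[e]]
        if cname in _CLASS_FREQ_HZ:
            f0 = _CLASS_FREQ_HZ[cname] * np.exp(0.05 * rng.standard_normal())
            phase = rng.uniform(0, 2 * np.pi)
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            dyn += np.outer(np.sin(2 * np.pi * f0 * t_epoch + phase) * sd * 1.5, axis)
        out[e * n_per:(e + 1) * n_per] = grav + dyn
    return RawTriaxialStream(seq.participant_id, fs, seq.epoch_start_s, out)


# ---------------------------------------------------------------------------
# guided tests
# ---------------------------------------------------------------------------

def simulate_guided_tests(p: ParticipantRecord, n_days: int,
                          cfg: EffectConfig) -> list[GuidedTestRecordings]:
    """One recording of each guided test per study day.

    Group effects: reduced wrist ROM amplitude, slower walking cadence, longer
    peg inter-event intervals, and longer sit/lie-to-stand transitions in RA.
    A lognormal subject factor (cv ``guided_subject_cv``) and day factor
    (cv ``guided_day_cv``) multiply each test's group mean.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    g = cfg.groups[p.group]
    fs = cfg.guided_sample_rate_hz
    rng = _rng(cfg, p.participant_id, tag=5)

    def lognoise(cv: float) -> float:
        return float(np.exp(rng.normal(0.0, cv)))

    subj = {k: lognoise(cfg.guided_subject_cv)
            for k in ("rom", "cad", "peg", "sts", "lts")}

    recordings = []
    for day in range(n_days):
        dayf = {k: lognoise(cfg.guided_day_cv) for k in subj}
        # wrist ROM: angle (rom/2)·sin(2π f0 t) -> ω = rom·π·f0·cos(2π f0 t)
        rom = g.wrist_rom_deg * subj["rom"] * dayf["rom"]
        f0 = 0.5
        t = np.arange(int(10 * fs)) / fs
        wrt = rom * np.pi * f0 * np.cos(2 * np.pi * f0 * t)
        wrt = wrt + rng.normal(0.0, 2.0, t.size) + rng.normal(0.0, 1.0)  # noise + bias

        # 30-s walk: periodic vertical oscillation at the step frequency
        cad = g.walk_cadence_spm * subj["cad"] * dayf["cad"]
        fstep = cad / 60.0
        tw = np.arange(int(30 * fs)) / fs
        amp = cfg.walk_step_amp_g
        z = 1.0 + amp * np.sin(2 * np.pi * fstep * tw + rng.uniform(0, 2 * np.pi))
        z += rng.normal(0.0, 0.15 * amp, tw.size)
        wlk = np.column_stack([rng.normal(0, 0.05 * amp, tw.size),
                               rng.normal(0, 0.05 * amp, tw.size), z])

        # 9-hole peg: 9 touch events, first at 0
        mean_iv = g.peg_interval_s * subj["peg"] * dayf["peg"]
        ivs = np.maximum(0.2, rng.normal(mean_iv, cfg.peg_jitter_s, 8))
        peg = np.concatenate([[0.0], np.cumsum(ivs)])

        sts = _transition_stream(g.sts_duration_s * subj["sts"] * dayf["sts"], fs, rng)
        lts = _transition_stream(g.lts_duration_s * subj["lts"] * dayf["lts"], fs, rng)
        recordings.append(GuidedTestRecordings(p.participant_id, day, fs,
                                               wrt, wlk, peg, sts, lts))
    return recordings


def _transition_stream(duration_s: float, fs: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Two quasi-static orientation plateaus joined by a linear ramp."""
    pre = int(2.5 * fs)
    ramp = max(2, int(round(duration_s * fs)))
    post = int(2.5 * fs)
    z0, z1 = 0.55, 1.0
    z = np.concatenate([np.full(pre, z0), np.linspace(z0, z1, ramp), np.full(post, z1)])
    x = np.sqrt(np.clip(1.0 - z ** 2, 0.0, None))
    n = z.size
    out = np.column_stack([x, np.zeros(n), z])
    out += rng.normal(0.0, 0.01, (n, 3))
    return out


# ---------------------------------------------------------------------------
# study assembly and CSV export
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    """Container for a fully simulated study (label-level, no raw streams)."""

    cfg: EffectConfig
    records: list[ParticipantRecord]
    n_days: int
    sequences: dict[str, ActivitySequence] = field(default_factory=dict)
    magnitudes: dict[str, np.ndarray] = field(default_factory=dict)
    guided: dict[str, list[GuidedTestRecordings]] = field(default_factory=dict)
    missing_days: dict[str, set[int]] = field(default_factory=dict)


def simulate_study(cfg: EffectConfig, n_hc: int = 30, n_ra_mod: int = 13,
                   n_ra_sev: int = 15, n_days: int = 14) -> StudyData:
    """Simulate a full study at label/epoch-magnitude resolution."""
    records = generate_cohort(n_hc, n_ra_mod, n_ra_sev, cfg)
    study = StudyData(cfg=cfg, records=records, n_days=n_days)
    for p in records:
        seq = simulate_activity_days(p, n_days, cfg)
        study.sequences[p.participant_id] = seq
        study.magnitudes[p.participant_id] = simulate_epoch_magnitudes(seq, p, cfg)
        study.guided[p.participant_id] = simulate_guided_tests(p, n_days, cfg)
        if cfg.dropout_per_day > 0:
            rng = _rng(cfg, p.participant_id, tag=6)
            gone = {d for d in range(n_days) if rng.random() < cfg.dropout_per_day}
            study.missing_days[p.participant_id] = gone
        else:
            study.missing_days[p.participant_id] = set()
    return study


def cohort_frame(records: list[ParticipantRecord]):
    """Cohort as a tidy DataFrame (one row per participant)."""
    import pandas as pd

    rows = []
    for p in records:
        row = {"participant_id": p.participant_id, "group": p.group, "age": p.age,
               "sex": p.sex, "bmi": p.bmi, "rapid3_baseline": p.rapid3_baseline}
        row.update(p.pro)
        rows.append(row)
    return pd.DataFrame(rows)


def write_run(study: StudyData, out_dir) -> None:
    """Write cohort/PRO/activity CSVs plus a manifest under ``out_dir``."""
    import json
    from pathlib import Path

    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_frame(study.records).to_csv(out / "cohort.csv", index=False)
    pro_rows = [
        {"participant_id": p.participant_id, "instrument": k, "score": v}
        for p in study.records for k, v in p.pro.items()
    ]
    pd.DataFrame(pro_rows).to_csv(out / "pro.csv", index=False)
    act_rows = []
    for pid, seq in study.sequences.items():
        act_rows.append(pd.DataFrame({
            "participant_id": pid,
            "epoch_start_s": seq.epoch_times(),
            "label": seq.labels,
            "magnitude_g": study.magnitudes[pid],
        }))
    if act_rows:
        pd.concat(act_rows).to_csv(out / "activity.csv", index=False)
    manifest = {"seed": study.cfg.seed, "config_hash": study.cfg.config_hash(),
                "n_participants": len(study.records), "n_days": study.n_days}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
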