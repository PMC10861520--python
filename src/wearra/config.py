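"""Study configuration: group effect sizes, instrument ranges, sensor model.

The defaults encode the cohort the analyses are designed for: healthy controls
(HC) and RA participants split into moderate (RA_mod) and severe (RA_sev)
disability by their baseline RAPID-3.  PRO means/SDs follow the published
baseline table of the weaRAble-PRO-style study population; sensor effect sizes
(activity composition, morning attenuation, night-time restlessness, transition
slowing, wrist range of motion) encode the qualitative group differences the
analysis is meant to detect, at magnitudes typical of actigraphy studies in RA.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

GROUPS = ("HC", "RA_mod", "RA_sev")

BROAD_CLASSES = ("sleep", "sedentary", "light", "MVPA")
FINE_CLASSES = ("sleep", "sitting/standing", "mixed", "vehicle", "walking", "bicycling")

#: score range of each patient-reported instrument (lo, hi)
PRO_RANGES: dict[str, tuple[float, float]] = {
    "HAQ-DI": (0.0, 3.0),
    "RASIQ-pain": (0.0, 100.0),
    "RASIQ-stiffness": (0.0, 100.0),
    "RASIQ-impact": (0.0, 100.0),
    "FACIT": (0.0, 52.0),
    "PROMIS-sleep": (20.0, 80.0),
    "PROMIS-pain": (20.0, 80.0),
}

RAPID3_RANGE = (0.0, 10.0)


class ConfigurationError(ValueError):
    """Raised when an EffectConfig violates its invariants."""


@dataclass
class GroupEffects:
    """Per-group generative parameters.

    pro maps instrument name to (mean, sd) on the instrument scale; sd = 0 is
    allowed and yields a degenerate (constant) distribution.  activity
    fractions cover the broad taxonomy including sleep and must sum to 1.
    Dwell means are in 30-s epochs for the waking classes.  morning_attenuation
    multiplies post-wake movement (1 = no stiffness effect), night_episode_rate
    is movement episodes per hour of sleep, transition durations are seconds,
    wrist_rom degrees, walk cadence steps/min, peg interval seconds.
    """

    pro: dict[str, tuple[float, float]]
    rapid3: tuple[float, float]
    age: tuple[float, float]
    bmi: tuple[float, float]
    female_fraction: float
    activity_fractions: dict[str, float]
    dwell_mean_epochs: dict[str, float]
    morning_attenuation: float
    night_episode_rate_per_h: float
    sts_duration_s: float
    lts_duration_s: float
    wrist_rom_deg: float
    walk_cadence_spm: float
    peg_interval_s: float


@dataclass
class EffectConfig:
    """Full generator configuration; identical configs give identical data."""

    groups: dict[str, GroupEffects]
    seed: int = 0
    epoch_len_s: int = 30
    sample_rate_hz: float = 30.0
    taxonomy: str = "broad"
    # per-class sd of the dynamic (non-gravity) acceleration component, in g
    class_dynamic_sd_g: dict[str, float] = field(
        default_factory=lambda: {"sleep": 0.005, "sedentary": 0.02, "light": 0.06, "MVPA": 0.15}
    )
    # per-class rate of slow gravity-orientation change (rad/s)
    class_orientation_rate: dict[str, float] = field(
        default_factory=lambda: {"sleep": 0.002, "sedentary": 0.01, "light": 0.05, "MVPA": 0.15}
    )
    pro_severity_coupling: float = 0.7  # latent-severity correlation of PROs and RAPID-3
    morning_window_min: float = 30.0  # post-wake window attenuated by morning stiffness
    night_episode_magnitude_g: float = 0.05
    night_episode_len_epochs: tuple[int, int] = (1, 4)
    # between-subject and day-to-day heterogeneity (log-scale sd of the
    # multiplicative factors applied to the group-level parameters)
    subject_activity_log_sd: float = 0.35  # light/MVPA share per subject
    day_activity_log_sd: float = 0.40  # light/MVPA share per waking day
    subject_sleep_sd_h: float = 0.4
    day_sleep_sd_h: float = 0.3
    subject_mag_log_sd: float = 0.20  # overall movement magnitude per subject
    day_mag_log_sd: float = 0.25
    epoch_mag_log_sd: float = 0.15
    subject_symptom_log_sd: float = 0.3  # night-episode rate, morning attenuation
    # between-day / between-subject noise scales for guided tests
    guided_day_cv: float = 0.25  # day-to-day coefficient of variation
    guided_subject_cv: float = 0.25  # between-subject coefficient of variation
    walk_step_amp_g: float = 0.25
    peg_jitter_s: float = 0.3
    guided_sample_rate_hz: float = 50.0
    dropout_per_day: float = 0.0  # probability a participant-day is missing

    def validate(self) -> None:
        for name, g in self.groups.items():
            fr = g.activity_fractions
            if abs(sum(fr.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"activity fractions for {name} must sum to 1")
            if any(v < 0 for v in fr.values()):
                raise ConfigurationError(f"negative activity fraction in {name}")
            for instr, (_, sd) in g.pro.items():
                if sd < 0:
                    raise ConfigurationError(f"negative dispersion for {instr} in {name}")
            if any(d <= 0 for d in g.dwell_mean_epochs.values()):
                raise ConfigurationError(f"non-positive dwell mean in {name}")
        if self.taxonomy not in ("broad", "fine"):
            raise ConfigurationError(f"unknown taxonomy {self.taxonomy!r}")
        if not 0.0 <= self.pro_severity_coupling <= 1.0:
            raise ConfigurationError("pro_severity_coupling must be in [0, 1]")

    def config_hash(self) -> str:
        """Stable hash of the full configuration (reproducibility audit)."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def default_config(seed: int = 0) -> EffectConfig:
    """Study-default configuration.

    PRO and demographic means/SDs are the baseline values of the target
    population (HC n=28-30, RA mod n=13, RA sev n=15 style cohort); healthy
    controls have RAPID-3 and HAQ-DI fixed at zero.  Activity composition gives
    HC > RA_mod > RA_sev in MVPA and slightly longer sleep/sedentary time in
    RA, and the RA symptom channels (morning attenuation < 1, higher night
    episode rates, slower transitions, reduced wrist ROM, slower peg/walk) are
    graded with severity.
    """
    hc = GroupEffects(
        pro={
            "HAQ-DI": (0.0, 0.0),
            "RASIQ-pain": (3.1, 6.7),
            "RASIQ-stiffness": (5.9, 9.5),
            "RASIQ-impact": (47.3, 5.0),
            "FACIT": (49.2, 2.9),
            "PROMIS-sleep": (49.6, 2.8),
            "PROMIS-pain": (42.2, 4.8),
        },
        rapid3=(0.0, 0.0),
        age=(58.4, 9.9),
        bmi=(25.8, 4.6),
        female_fraction=0.89,
        activity_fractions={"sleep": 0.33, "sedentary": 0.40, "light": 0.22, "MVPA": 0.05},
        dwell_mean_epochs={"sedentary": 20.0, "light": 6.0, "MVPA": 4.0},
        morning_attenuation=1.0,
        night_episode_rate_per_h=0.5,
        sts_duration_s=1.5,
        lts_duration_s=2.0,
        wrist_rom_deg=90.0,
        walk_cadence_spm=110.0,
        peg_interval_s=1.0,
    )
    ra_mod = GroupEffects(
        pro={
            "HAQ-DI": (0.63, 0.36),
            "RASIQ-pain": (32.1, 20.8),
            "RASIQ-stiffness": (33.9, 18.9),
            "RASIQ-impact": (53.9, 5.1),
            "FACIT": (38.9, 4.3),
            "PROMIS-sleep": (52.7, 4.2),
            "PROMIS-pain": (54.2, 7.29),
        },
        rapid3=(3.2, 0.7),
        age=(56.9, 11.4),
        bmi=(31.1, 5.9),
        female_fraction=0.84,
        activity_fractions={"sleep": 0.35, "sedentary": 0.445, "light": 0.17, "MVPA": 0.035},
        dwell_mean_epochs={"sedentary": 24.0, "light": 5.0, "MVPA": 3.0},
        morning_attenuation=0.7,
        night_episode_rate_per_h=1.5,
        sts_duration_s=2.4,
        lts_duration_s=3.2,
        wrist_rom_deg=70.0,
        walk_cadence_spm=100.0,
        peg_interval_s=1.4,
    )
    ra_sev = GroupEffects(
        pro={
            "HAQ-DI": (1.03, 0.42),
            "RASIQ-pain": (56.2, 11.6),
            "RASIQ-stiffness": (51.6, 10.2),
            "RASIQ-impact": (50.8, 7.6),
            "FACIT": (31.9, 7.6),
            "PROMIS-sleep": (52.4, 4.3),
            "PROMIS-pain": (58.8, 4.6),
        },
        rapid3=(5.3, 1.1),
        age=(60.4, 7.1),
        bmi=(31.7, 8.6),
        female_fraction=0.93,
        activity_fractions={"sleep": 0.36, "sedentary": 0.47, "light": 0.15, "MVPA": 0.02},
        dwell_mean_epochs={"sedentary": 28.0, "light": 4.5, "MVPA": 2.5},
        morning_attenuation=0.5,
        night_episode_rate_per_h=2.0,
        sts_duration_s=3.0,
        lts_duration_s=4.0,
        wrist_rom_deg=55.0,
        walk_cadence_spm=92.0,
        peg_interval_s=1.8,
    )
    cfg = EffectConfig(groups={"HC": hc, "RA_mod": ra_mod, "RA_sev": ra_sev}, seed=seed)
    cfg.validate()
    return cfg
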