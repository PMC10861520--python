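"""Study-level experiment drivers.

Each driver simulates (or is handed) a study, builds feature matrices from the
configured sources (PRO questionnaires, active guided tests, passive
actigraphy), and evaluates penalised models with subject-wise cross-validation:

* RA identification: RA vs HC from active, passive, and combined sensor
  features;
* severity stratification: moderate vs severe RA from PROs with and without
  sensor augmentation;
* RAPID-3 regression: continuous severity from PRO + sensor features (healthy
  controls carry a baseline RAPID-3 of zero by assignment);
* days-of-data sufficiency: classification performance as a function of the
  number of (non-contiguous) study days averaged per participant, and feature
  reliability (ICC) as a function of contiguous days.

Every report embeds the configuration hash and the seeds used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import active as act
from . import passive as pas
from . import stats as st
from .config import EffectConfig, default_config
from .modeling import (
    CvReport,
    FeatureMatrix,
    PenaltySpec,
    aggregate_features,
    combine_matrices,
    run_cv,
)
from .synthetic import StudyData, cohort_frame, simulate_study

log = logging.getLogger(__name__)

PRO_DOMAIN = "PRO"


@dataclass
class ExperimentConfig:
    n_hc: int = 30
    n_ra_mod: int = 13
    n_ra_sev: int = 15
    study_days: int = 14
    sources: tuple[str, ...] = ("PRO", "active", "passive")
    aggregation: str = "fortnightly"
    penalty_family: str = "elastic_net"
    alpha_mix: float = 0.5
    k_folds: int = 5
    seed: int = 0
    d_grid: tuple[int, ...] = (2, 4, 7, 10, 14)
    permutations: int = 100
    n_lambda: int = 20
    effects: EffectConfig | None = None

    def effect_config(self) -> EffectConfig:
        return self.effects if self.effects is not None else default_config(self.seed)


@dataclass
class StudyFeatures:
    """Daily feature tables per source, plus cohort labels."""

    cohort: pd.DataFrame
    daily: dict[str, pd.DataFrame]  # source -> daily table
    domains: dict[str, dict[str, str]]  # source -> feature -> domain

    def matrix(self, sources: tuple[str, ...], aggregation: str) -> FeatureMatrix:
        mats = [aggregate_features(self.daily[s], aggregation, self.domains[s])
                for s in sources]
        return mats[0] if len(mats) == 1 else combine_matrices(*mats)


def build_study_features(study: StudyData) -> StudyFeatures:
    """Run the feature extractors over a simulated study."""
    passive_frames = []
    active_frames = []
    pro_rows = []
    for p in study.records:
        seq = study.sequences[p.participant_id]
        mags = study.magnitudes[p.participant_id]
        gone = study.missing_days[p.participant_id]
        passive_frames.append(pas.summarize_daily(p, seq, mags, study.n_days, gone))
        active_frames.append(act.summarize_guided_daily(
            study.guided[p.participant_id], gone))
        for d in range(study.n_days):
            row = {"participant_id": p.participant_id, "day_index": d}
            row.update(p.pro)
            pro_rows.append(row)
    passive_daily = pd.concat(passive_frames, ignore_index=True)
    active_daily = pd.concat(active_frames, ignore_index=True)
    pro_daily = pd.DataFrame(pro_rows)
    pro_cols = [c for c in pro_daily.columns
                if c not in ("participant_id", "day_index")]
    return StudyFeatures(
        cohort=cohort_frame(study.records),
        daily={"passive": passive_daily, "active": active_daily, "PRO": pro_daily},
        domains={"passive": pas.passive_domain_map(passive_daily),
                 "active": act.active_domain_map(active_daily),
                 "PRO": {c: PRO_DOMAIN for c in pro_cols}},
    )


def prepare_study(cfg: ExperimentConfig) -> StudyFeatures:
    study = simulate_study(cfg.effect_config(), cfg.n_hc, cfg.n_ra_mod,
                           cfg.n_ra_sev, cfg.study_days)
    return build_study_features(study)


def _labels(cohort: pd.DataFrame, task: str) -> pd.Series:
    s = cohort.set_index("participant_id")
    if task == "ra_vs_hc":
        return (s["group"] != "HC").astype(int)
    if task == "mod_vs_sev":
        sub = s[s["group"] != "HC"]
        return (sub["group"] == "RA_sev").astype(int)
    if task == "rapid3":
        return s["rapid3_baseline"]
    raise ValueError(task)


def _report_header(cfg: ExperimentConfig) -> dict:
    return {"config_hash": cfg.effect_config().config_hash(), "seed": cfg.seed,
            "aggregation": cfg.aggregation, "penalty": cfg.penalty_family}


def _cv(features: StudyFeatures, sources: tuple[str, ...], labels: pd.Series,
        cfg: ExperimentConfig, task: str = "classification",
        seed: int | None = None) -> CvReport:
    matrix = features.matrix(sources, cfg.aggregation)
    keep = matrix.X.index.get_level_values("participant_id").isin(labels.index)
    matrix = FeatureMatrix(matrix.X[keep], matrix.aggregation, matrix.domains)
    pen = PenaltySpec(cfg.penalty_family, alpha_mix=cfg.alpha_mix)
    return run_cv(matrix, labels, pen, task=task, k=cfg.k_folds,
                  seed=cfg.seed if seed is None else seed,
                  n_lambda=cfg.n_lambda)


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def run_ra_identification(cfg: ExperimentConfig,
                          features: StudyFeatures | None = None) -> dict:
    """RA vs HC per feature source and combined, subject-wise metrics.

    Reports F1/kappa/AUROC per source plus the misclassified participants and
    their overlap between the active-only and passive-only models.
    """
    features = features or prepare_study(cfg)
    labels = _labels(features.cohort, "ra_vs_hc")
    source_sets = {"active": ("active",), "passive": ("passive",),
                   "active+passive": ("active", "passive")}
    if "PRO" in cfg.sources:
        source_sets["PRO+active+passive"] = ("PRO", "active", "passive")
    report = _report_header(cfg)
    report["task"] = "RA identification (RA vs HC)"
    report["sources"] = {}
    missets = {}
    for name, srcs in source_sets.items():
        cv = _cv(features, srcs, labels, cfg)
        wrong = cv.subjects.loc[cv.subjects["y"] != cv.subjects["pred"],
                                "participant_id"].tolist()
        missets[name] = set(wrong)
        report["sources"][name] = {
            "subject_metrics": cv.subject_metrics,
            "observation_metrics": cv.observation_metrics,
            "misclassified": sorted(wrong),
            "chosen_lambdas": cv.chosen_lambdas,
        }
    report["misclassified_overlap_active_passive"] = sorted(
        missets.get("active", set()) & missets.get("passive", set()))
    return report


def run_severity_stratification(cfg: ExperimentConfig,
                                features: StudyFeatures | None = None) -> dict:
    """Moderate vs severe RA: PRO-only vs PRO + sensor augmentation."""
    features = features or prepare_study(cfg)
    labels = _labels(features.cohort, "mod_vs_sev")
    if labels.nunique() < 2 or labels.value_counts().min() == 0:
        raise ValueError("both RA severity groups must be present")
    source_sets = {"PRO": ("PRO",), "PRO+active": ("PRO", "active"),
                   "PRO+passive": ("PRO", "passive"),
                   "PRO+active+passive": ("PRO", "active", "passive")}
    report = _report_header(cfg)
    report["task"] = "RA severity stratification (mod vs sev)"
    report["sources"] = {}
    for name, srcs in source_sets.items():
        cv = _cv(features, srcs, labels, cfg)
        report["sources"][name] = {
            "subject_metrics": cv.subject_metrics,
            "observation_metrics": cv.observation_metrics,
            "misclassified": sorted(cv.subjects.loc[
                cv.subjects["y"] != cv.subjects["pred"], "participant_id"]),
        }
    return report


def run_rapid3_regression(cfg: ExperimentConfig,
                          features: StudyFeatures | None = None) -> dict:
    """Continuous RAPID-3 estimation from PRO + sensor features.

    Subject predictions are out-of-fold means over a participant's periods;
    reports r2/MAE/RMSE plus Pearson and Spearman of predicted vs actual, and
    the per-participant scatter (including the HC near-zero behaviour).
    """
    features = features or prepare_study(cfg)
    labels = _labels(features.cohort, "rapid3")
    cv = _cv(features, tuple(cfg.sources), labels, cfg, task="regression")
    subj = cv.subjects
    pear = st.correlation(subj["y"], subj["pred"], "pearson")
    spear = st.correlation(subj["y"], subj["pred"], "spearman")
    hc_ids = set(features.cohort.loc[features.cohort["group"] == "HC",
                                     "participant_id"])
    hc_pred = subj.loc[subj["participant_id"].isin(hc_ids), "pred"]
    report = _report_header(cfg)
    report["task"] = "RAPID-3 regression"
    report["subject_metrics"] = cv.subject_metrics
    report["observation_metrics"] = cv.observation_metrics
    report["pearson_r"] = pear.r
    report["spearman_rho"] = spear.r
    report["hc_median_abs_prediction"] = float(hc_pred.abs().median())
    report["scatter"] = subj.to_dict(orient="records")
    return report


def run_days_subsampling(cfg: ExperimentConfig,
                         features: StudyFeatures | None = None,
                         sources: tuple[str, ...] = ("active", "passive")) -> dict:
    """Subject-wise F1 vs number of non-contiguous days averaged.

    For each d in the grid, ``cfg.permutations`` random subsets of d distinct
    days are drawn per participant, daily features are averaged over the
    subset, and a fresh subject-wise CV (folds re-drawn per permutation) gives
    one F1; the median and IQR over permutations are reported per d.
    """
    features = features or prepare_study(cfg)
    labels = _labels(features.cohort, "ra_vs_hc")
    daily_sets = [features.daily[s] for s in sources]
    domains: dict[str, str] = {}
    for s in sources:
        domains.update(features.domains[s])
    daily = daily_sets[0]
    for other in daily_sets[1:]:
        daily = daily.merge(other, on=["participant_id", "day_index"])
    feats = [c for c in daily.columns if c not in ("participant_id", "day_index")]
    ss = np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 77])
    report = _report_header(cfg)
    report["task"] = "days-of-data sufficiency"
    report["permutations"] = cfg.permutations
    curve = []
    for d in cfg.d_grid:
        if d > cfg.study_days:
            log.warning("d=%d exceeds study_days=%d; omitted", d, cfg.study_days)
            continue
        f1s = []
        for perm in range(cfg.permutations):
            rng = np.random.default_rng(ss.spawn(1)[0])
            sampled = []
            for pid, sub in daily.groupby("participant_id", sort=True):
                days = rng.choice(cfg.study_days, size=d, replace=False)
                sampled.append(sub[sub["day_index"].isin(days)])
            subset = pd.concat(sampled)
            avg = subset.groupby("participant_id")[feats].mean()
            avg["period_id"] = 0
            avg = avg.set_index("period_id", append=True)
            matrix = FeatureMatrix(avg, "fortnightly", domains)
            pen = PenaltySpec(cfg.penalty_family, alpha_mix=cfg.alpha_mix)
            cv = run_cv(matrix, labels, pen, k=cfg.k_folds,
                        seed=int(rng.integers(2 ** 31)), n_lambda=cfg.n_lambda)
            f1s.append(cv.subject_metrics["macro_f1"])
        q1, q2, q3 = np.percentile(f1s, [25, 50, 75])
        curve.append({"d": int(d), "median_f1": float(q2), "q1": float(q1),
                      "q3": float(q3), "iqr": float(q3 - q1)})
    report["curve"] = curve
    return report


def run_icc_vs_days(cfg: ExperimentConfig,
                    features: StudyFeatures | None = None,
                    sources: tuple[str, ...] = ("active", "passive")) -> dict:
    """Feature test-retest reliability ICC(3,d) vs contiguous days, per group."""
    features = features or prepare_study(cfg)
    frames = []
    for s in sources:
        daily = features.daily[s].merge(
            features.cohort[["participant_id", "group"]], on="participant_id")
        daily["ra"] = np.where(daily["group"] == "HC", "HC", "RA")
        feat_cols = [c for c in features.daily[s].columns
                     if c not in ("participant_id", "day_index")]
        frames.append(st.icc_vs_days(daily, feat_cols,
                                     d_grid=[d for d in cfg.d_grid if d >= 2],
                                     group_col="ra"))
    icc = pd.concat(frames, ignore_index=True)
    summary = (icc.groupby(["group", "d"])["icc"]
               .agg(median="median",
                    q1=lambda v: float(np.percentile(v, 25)),
                    q3=lambda v: float(np.percentile(v, 75)))
               .reset_index())
    report = _report_header(cfg)
    report["task"] = "ICC vs days"
    report["summary"] = summary.to_dict(orient="records")
    report["table"] = icc.to_dict(orient="records")
    return report


def run_univariate_report(cfg: ExperimentConfig,
                          features: StudyFeatures | None = None) -> pd.DataFrame:
    """Fortnightly-average univariate group comparisons with BH correction."""
    features = features or prepare_study(cfg)
    mats = features.matrix(("active", "passive"), "fortnightly")
    subject = mats.X.groupby(level="participant_id").mean()
    groups = features.cohort.set_index("participant_id")["group"].loc[subject.index]
    return st.univariate_feature_report(subject, groups, mats.domains)
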