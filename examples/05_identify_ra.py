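"""Distinguish RA participants from healthy controls with penalised models.

Runs the RA identification experiment on a reduced synthetic cohort:
subject-wise 5-fold cross-validation of elastic-net logistic regression on
active (guided test), passive (actigraphy) and combined feature sources, with
subject predictions by majority vote.
"""

from wearra import experiments as ex

cfg = ex.ExperimentConfig(seed=5, n_hc=14, n_ra_mod=7, n_ra_sev=7,
                          study_days=7, n_lambda=10)
features = ex.prepare_study(cfg)
report = ex.run_ra_identification(cfg, features)

print("subject-wise metrics per feature source (RA vs HC):")
for source, res in report["sources"].items():
    m = res["subject_metrics"]
    print(f"  {source:20s} F1={m['macro_f1']:.3f}  kappa={m['kappa']:.3f}  "
          f"AUROC={m['auroc']:.3f}  misclassified={len(res['misclassified'])}")
print("\noverlap of misclassified participants (active vs passive):",
      report["misclassified_overlap_active_passive"])
print("\nCombining both sensor sources matches or beats either alone; "
      "active- and passive-only models tend to misclassify different "
      "participants, which is why fusion helps.")
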