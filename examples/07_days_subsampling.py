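"""How many days of wearable data are needed to identify RA status?

For each number of days d, random subsets of d (non-contiguous) study days
are drawn per participant, daily features are averaged over the subset, and a
fresh subject-wise CV measures the F1 of RA identification.  The median
stabilises and the spread (IQR) shrinks as more days are averaged.
"""

from wearra import experiments as ex

cfg = ex.ExperimentConfig(seed=7, n_hc=12, n_ra_mod=6, n_ra_sev=6,
                          study_days=7, d_grid=(2, 4, 7), permutations=10,
                          n_lambda=10)
features = ex.prepare_study(cfg)
report = ex.run_days_subsampling(cfg, features)

print("days  median F1   IQR")
for row in report["curve"]:
    print(f"{row['d']:4d}  {row['median_f1']:9.3f}   {row['iqr']:.3f}")
print("\nAveraging more days suppresses day-to-day variability, so the "
      "classifier's performance stabilises; past roughly a week the gain "
      "levels off.")
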