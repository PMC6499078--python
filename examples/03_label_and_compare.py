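"""Label high-SMME predictions and characterize the high/low groups.

Each prediction's "mean covariance" (average across-replicate covariance
with every other sampled prediction) measures how consistently it covaries
with the rest of the sample; the upper 20% are labeled high-SMME.  The
synthetic study plants a harbour-like region with strong extra shared
error and elevated urban covariates, so the high group should be enriched
for that region and its covariates.
"""

import sumaerr as s

table, meta, _ = s.simulate_study(n_pred=4000, seed=3)
sub, sub_meta = s.subsample(table, meta, s.SampleSpec(sample_size=1000, n_repeats=1, seed=0))[0]

pairs = s.pairwise_stats(sub)
mean_cov = s.mean_covariances(pairs, n_pred=sub.n_pred)
labels = s.dichotomize(mean_cov, percentile=80, prediction_ids=sub.prediction_ids)
print(f"threshold (80th pct of mean covariance): {labels.threshold:.3f} ppb^2")
print(f"labeled high: {labels.n_high}/{len(labels.frame)}")

region_share = (sub_meta["region"] == "long_beach").mean()
high = labels.labels.to_numpy() == "high"
region_share_high = (sub_meta.loc[high, "region"] == "long_beach").mean()
print(f"\nregion share of sample: {100 * region_share:.0f}%  "
      f"-> share of high-SMME labels: {100 * region_share_high:.0f}%")

comp = s.compare_groups(labels, sub_meta, ["traffic_density", "population_density", "nonfreeway_nox", "min_temperature"])
print("\nWelch comparison of covariates (low vs high SMME):")
print(comp[["variable", "low_mean", "high_mean", "p_value", "ci_low", "ci_high"]].round(3).to_string(index=False))

tab = s.tabulate_labels(labels, sub_meta, "period")
print("\nlabel distribution across time periods (column %):")
print(tab.round(1).to_string(index=False))
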