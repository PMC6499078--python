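"""Seeded subsampling, repeat robustness, and representativeness.

Large prediction sets make the ~n^2/2 pairwise covariance computation
expensive, so components are estimated on a random subsample; repeated
independent samples check that the estimates do not depend on the draw,
and a representativeness report compares sample and population
distributions.
"""

import sumaerr as s

table, meta, _ = s.simulate_study(n_pred=4000, seed=2)

# 5 independent samples of 800 predictions, one full fit each
result = s.run_suma(table, meta, s.SampleSpec(sample_size=800, n_repeats=5, seed=0))
print("per-repeat component estimates:")
print(result.summary.round(6).to_string())
print("\nacross-repeat spread (robustness of the point estimates):")
print(result.spread().round(6).to_string())

# Is the headline sample representative of the population?
_, sample_meta = s.subsample(table, meta, s.SampleSpec(800, 1, 0))[0]
rep = s.representativeness_report(sample_meta, meta, ["traffic_density", "period"])
print("\nsample vs population distribution (quartile bins / categories):")
print(rep[["variable", "bin", "population_pct", "sample_pct", "abs_pct_diff"]].round(1).to_string(index=False))
print(f"\nmax |sample - population| share: {rep['max_abs_pct_diff'].max():.1f} percentage points")
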