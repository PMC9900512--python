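"""The full chain on synthetic data: does the estimator recover the truth?

Simulates a world with known catchability q_true per gear, observes bycatch
through a Poisson model, then estimates rates q = T_b/(T_p*F), summarizes
them by geometric mean, and extrapolates annual totals over risk indices.
"""

from bycatchrisk import run_demo

bundle, result = run_demo(seed=1)

print("rate summaries (geometric mean with lower/upper brackets):")
print(result.summary.to_string(index=False))

merged = result.summary.merge(bundle.q_true, on=["species", "gear"])
merged["recovered/true"] = merged["gm_rate"] / merged["q_true"]
print("\nrecovery of the generating catchability (1.0 = perfect):")
print(merged[["species", "gear", "n", "recovered/true"]].to_string(index=False))

print("\ngeometric mean of annual extrapolated bycatch (turtles/yr):")
print(result.annual.to_string(index=False))

print("\nbycatch as percent of the modelled coastal population:")
print(result.percent.groupby("species")["percent"].agg(["min", "max"]).to_string())

print("\neffort trends (Pearson r of total effort vs year):")
print(result.effort_trends.to_string(index=False))
print("\n(the demo world builds in a declining trawl trend and rising")
print(" gillnet/recreational trends; the r values above recover them)")
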