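"""Differential PDUI usage between two groups with 3'UTR trend calls.

Simulates a two-group cohort in which 20% of features carry a -0.3 PDUI
shift (3'UTR shortening) and recovers them with the Mann-Whitney test,
BH adjustment, and the effect-size/significance trend gate.
"""

from apakit import differential_usage, gen_usage

synth = gen_usage(n_features=200, n_per_group=30, frac_affected=0.2,
                  delta=-0.3, noise_sd=0.1, seed=1)
table = differential_usage(synth.usage, synth.groups)

counts = table["trend"].value_counts()
print(f"tested {len(table)} features across 30 vs 30 samples")
print(counts.to_string())
# 40 features were simulated with shortened 3'UTRs; "shortened" calls
# should recover nearly all of them with essentially no false calls.

merged = table.merge(synth.truth, on="feature_id")
tp = ((merged["affected"]) & (merged["trend"] == "shortened")).sum()
fp = ((~merged["affected"]) & (merged["trend"] != "unchanged")).sum()
print(f"\nrecovered {tp}/{merged['affected'].sum()} injected features; "
      f"{fp} false call(s) among {len(merged) - merged['affected'].sum()} nulls")

print("\nstrongest calls (delta = mean group2 - mean group1):")
print(table.nsmallest(3, "delta")[
    ["feature_id", "delta", "p", "q", "trend"]].to_string(index=False))
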