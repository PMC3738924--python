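"""Rarefaction, extrapolation and the comparison-point rule on a toy assemblage.

Run: python examples/accumulation_basics.py
"""

from biotrend import bootstrap_sd, comparison_point, extrapolate, rarefy, unseen_species

# an assemblage of 6 records over 3 species: one common, one doubleton, one singleton
counts = [3, 2, 1]

print("observed: n=6 records, S_obs=3 species, f1=1 singleton, f2=1 doubleton")
print(f"rarefied to 3 records:      {rarefy(counts, 3):.4f} expected species")
print(f"estimated unseen species:   {unseen_species(counts):.4f}")
print(f"extrapolated to 12 records: {extrapolate(counts, 6):.4f} expected species")
print(f"bootstrap SD at 12 records: {bootstrap_sd(counts, 12, B=500, seed=1):.4f}")

# comparing two periods sampled with unequal effort
for n1, n2 in [(100, 250), (100, 400)]:
    plan = comparison_point(n1, n2)
    print(
        f"efforts ({n1}, {n2}): compare at {plan.cp} records "
        f"(pre {plan.mode_pre}, post {plan.mode_post})"
    )

# The rarefied value interpolates the accumulation curve; the extrapolated
# value extends it using the singleton/doubleton-driven unseen-species
# estimate (never beyond 3x the observed effort). The comparison point is
# the shared effort at which two periods' richness values can be compared
# without effort bias.
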