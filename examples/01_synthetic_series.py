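"""Generate the reference synthetic analog series and inspect its ground truth.

A 4-aminoquinoline scaffold is decorated with 5 R1 × 10 R3 substituents to
give 50 compounds with additive per-target pIC50 contributions, Gaussian
assay noise, five injected activity cliffs sharing one generator compound,
one injected selectivity switch, and one injected dual pair.
"""

from cliffscape import activity_range, default_series_spec, generate_series

spec = default_series_spec(seed=7)
table, truth = generate_series(spec)

print(f"compounds: {len(table)}  pairs: {table.n_pairs}")
for target in table.targets:
    lo, hi = activity_range(table, target)
    print(f"{target}: pIC50 range {lo:.2f} – {hi:.2f}")
print(f"designated cliff generator: compound {truth.generator_id}")
print("injected pairs (i, j, target, forced gap):")
for p in truth.injected_pairs:
    print(f"  {p['i']:>2} – {p['j']:>2}  {p['target']:<6} Δ = {p['delta']}")

# The ranges show a rough landscape for the first target (large substituent
# effects plus the injected cliffs) and a smooth one for the second; every
# injected pair above has a pIC50 gap far beyond the 1-log-unit cliff
# threshold, so the landscape analysis should flag all of them.
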