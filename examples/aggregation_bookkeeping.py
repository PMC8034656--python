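"""Quantify DOX self-aggregation during carrier loading.

High DOX concentrations, high pH and Mg2+ drive DOX to precipitate as
self-aggregates that centrifugation cannot distinguish from drug-loaded
carriers.  The bookkeeping is A480-based: the supernatant absorbance after
centrifugation, relative to t = 0, gives the free concentration, and the
complement is the aggregate.
"""

from doxorigami import AggregationSample, c_aggregate, c_free_from_a480, dox_per_bp

# a 200 uM DOX loading mix with 2.5 nM triangle DONs (c_bp = 18 uM):
# after 24 h and centrifugation the supernatant A480 dropped to 40% of t=0
sample = AggregationSample(
    c0=200e-6, a480_t0=2.30, a480_supernatant=0.92, c_bp=18e-6,
    label="pH 8.0, 12.5 mM Mg2+, 24 h",
)

c_free = c_free_from_a480(sample)
c_agg = c_aggregate(sample)
ratio = dox_per_bp(c_agg, sample.c_bp)

print(f"{sample.label}")
print(f"c_free      = {c_free*1e6:.0f} uM (still in solution)")
print(f"c_aggregate = {c_agg*1e6:.0f} uM (precipitated)")
print(f"DOX/bp in precipitate = {ratio:.1f}")
# DOX/bp of 1 is the intercalation ceiling: a ratio of ~7 means the pellet
# is mostly free-DOX aggregate, not drug-loaded carrier — quantifying
# loading from the pellet would overestimate it several-fold
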