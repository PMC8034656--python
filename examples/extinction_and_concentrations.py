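"""Extinction and concentration calculus for DNA origami designs.

Computes the design-weighted 260 nm extinction coefficient per nucleotide
and converts a DON concentration into nucleotide and base-pair
concentrations — the bookkeeping every titration and digestion analysis
rests on.
"""

from doxorigami import (
    c_bp_from_don_concentration,
    c_nt_from_a260,
    default_registry,
    eps260_per_nt,
)

registry = default_registry()
triangle = registry["triangle"]

eps = eps260_per_nt(triangle)
print(f"triangle: N_ds = {triangle.n_ds}, N_ss = {triangle.n_ss}")
print(f"eps260/nt = {eps:.0f} M^-1 cm^-1")
# fully hybridized -> the 6700 double-stranded limit

c_don = 2.5e-9  # 2.5 nM DONs, a typical loading stock
c_bp = c_bp_from_don_concentration(c_don, triangle)
print(f"{c_don*1e9:.1f} nM triangle = {c_bp*1e6:.1f} uM base pairs")
# each 7249-bp structure carries N_ds/2 base pairs, so 2.5 nM ~ 18 uM bp

a260 = 0.067  # DOX-corrected absorbance of a DON solution
c_nt = c_nt_from_a260(a260, eps, path_cm=1.0)
print(f"A260 = {a260} -> c(nt) = {c_nt*1e6:.1f} uM nucleotides (Beer-Lambert)")
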