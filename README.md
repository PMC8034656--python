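# doxorigami

Quantitative analysis of doxorubicin (DOX) loading into DNA origami
nanostructures (DONs) and of its release when the carrier is digested by
DNase I.

DNA origami is an attractive chemotherapeutic carrier: DOX intercalates into
double-stranded DNA, so a folded origami structure is a dense, addressable
reservoir of binding sites. Turning spectroscopy of such samples into
numbers — how much drug is bound, how fast the carrier is degraded, how fast
the drug comes back out — requires a consistent chain of calculus which this
package implements end to end for people doing DON drug-loading experiments:

* **Extinction/concentration bookkeeping** — the design-weighted extinction
  coefficient per nucleotide at 260 nm,
  ε₂₆₀/nt = (6700·N_ds + 10000·N_ss)/(N_ds + N_ss) M⁻¹cm⁻¹, Beer–Lambert
  concentration calculus, and the nucleotide → base-pair conversion
  (bp = N_ds/2) for arbitrary designs kept in an editable registry.
* **A 1:2 DOX–base-pair binding model** — sequential equilibria
  DOX + bp ⇌ DOX·bp (K₁₁) and DOX·bp + bp ⇌ DOX·bp₂ (K₁₂). The observed
  change of a physical property Y (fluorescence quantum yield Φ or
  absorbance) follows

      ΔY_obs = (y_Δ11·K₁₁·c + y_Δ12·K₁₁K₁₂·c²) / (1 + K₁₁·c + K₁₁K₁₂·c²),

  where c = c(bp)_ub, the unbound base-pair concentration, is the physical
  root of the cubic mass balance in [0, c(bp)₀]. Titration fitting shares
  K₁₁/K₁₂ across emission channels; with the constants fixed the extinction
  deltas follow by linear least squares.
* **An inverse model for release kinetics** — during digestion the DOX
  quantum yield recovers; the quadratic rearrangement of the isotherm maps
  each observed ΔΦ_obs back to c(bp)_ub, hence to the bound fraction
  f_b = 1 − 1/(1 + K₁₁c + K₁₁K₁₂c²) and to
  % released = 100·(f_b(intact) − f_b(t))/f_b(intact). Combined with
  % intact from the A260 hyperchromicity, linear-phase regression yields
  digestion and release rates and the **relative dose** — moles of DOX
  released per minute.
* **Aggregation bookkeeping** — free vs precipitated DOX from A480 before
  and after centrifugation (c_aggregate = c₀ − c_free) and the DOX/bp ratio
  of the pellet, which flags when a "drug-loaded" pellet is mostly free-DOX
  aggregate.
* **Seeded synthetic-data generators** — titrations, digestion time courses
  and aggregation tables with planted parameters, so the whole pipeline is
  verifiable by parameter recovery without any experimental data.

## Worked example

Fit the binding model to a (synthetic) fluorescence titration of DNA base
pairs into 3 μM DOX:

```bash
python examples/fit_titration.py
```

```
planted:   K11 = 2e+05 M^-1, K12 = 2.6e+05 M^-1
recovered: K11 = 1.95e+05 M^-1, K12 = 2.53e+05 M^-1
log10 errors: 0.010, 0.011
494 nm quantum-yield deltas: Phi_d11 = -0.492, Phi_d12 = -0.934
bp/DOX =  1: f_b = 0.326
bp/DOX =  5: f_b = 0.881
bp/DOX = 10: f_b = 0.972
bp/DOX = 40: f_b = 0.999
```

At 1% proxy noise the association constants come back within ~2–3% of the
planted values (0.01 in log₁₀). The quantum-yield deltas say the 1:1
complex keeps roughly half the free-DOX quantum yield while the 1:2 complex
is almost fully quenched — that contrast is what lets fluorescence separate
the two bound species. The f_b column is the loading curve: by 10 base
pairs per DOX, ~97% of the drug is bound.

Digestion and release, on a synthetic 2 nM triangle loaded at 3 μM DOX
(`python examples/digestion_release.py`):

```
bound fraction before digestion: f_b = 0.878
digestion rate: -10.34 +- 1.18 % intact/min (window (0.0, 2.5) min)
release rate:   +4.51 +- 0.06 % released/min
relative dose:  118.7 nM DOX released/min
released-vs-digested correlation: 0.966
```

The carrier loses ~10% of its double-stranded residues per minute in the
initial phase while ~4.5% of the bound drug is released per minute; scaled
by the bound pool (0.878 × 3 μM) that is a relative dose of ~0.12 μM/min.
Release correlates with — but lags — structure loss, because excess intact
base pairs rebind drug early in the digestion.

The other examples (`extinction_and_concentrations.py`,
`aggregation_bookkeeping.py`) cover the concentration calculus and the
aggregation arithmetic. A thin CLI wraps the same functions
(`doxorigami fit-titration`, `analyze-digestion`, `aggregate`,
`simulate-titration`, `simulate-digestion`, `extinction`).

## Layout

```
src/doxorigami/     spectra, designs, binding, digestion, aggregation,
                    synthetic, tables, cli
examples/           one narrative script per capability
tests/              pytest suite (unit, property-based, end-to-end)
docs/methods.md     models, assumptions, numerical choices, limitations
```
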