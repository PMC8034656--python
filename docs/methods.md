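# Methods

This note documents the models implemented in `doxorigami`, the choices made
where the underlying methodology leaves room, and what the synthetic-data
verification does and does not demonstrate.

## Observables and normalisation

All fluorescence observables are *quantum-yield proxies*: integrated
emission divided by the absorbed-light fraction (1 − T) at the excitation
wavelength, with T = 10^(−A) the transmittance. This corrects for the
hypochromic loss of excitation efficiency as DOX binds DNA, so the proxy
tracks the quantum yield of the emitting population rather than raw
intensity. Proxies are always normalised by a free-DOX reference measured
in the same run (Φ/Φ₀), which makes the fitted quantum-yield deltas
dimensionless and confined to [−1, 0].

The default emission integration window is 500–700 nm (the DOX emission
band under 450–494 nm excitation); it is configurable because different
instruments clip the band differently. An optional scattering-baseline
correction (subtract the absorbance at a 700 nm reference) exists but is
off by default — scattering contamination is better handled by preferring
the fluorescence channel.

Sign convention, stated once and enforced by validation: every delta
(ΔΦ_obs, Φ_Δ11, Φ_Δ12, ΔA_obs, ε_Δ) is *complex minus free*, hence ≤ 0 for
quenching and hypochromicity.

## Extinction and concentration calculus

A design is two counts: hybridized nucleotides N_ds (even; base pairs =
N_ds/2) and unpaired nucleotides N_ss. The per-nucleotide extinction
coefficient at 260 nm is the count-weighted average of 6700 (double-
stranded) and 10000 (single-stranded) M⁻¹cm⁻¹, bounded by those limits.
DNA concentrations follow Beer–Lambert on the DOX-corrected A260 (the
free-DOX 260 nm contribution is subtracted first, via
`spectra.subtract_reference`). Base-pair bookkeeping uses bp = N_ds/2
throughout; secondary-structure pairing inside unpaired scaffold loops is
not computed here — fold it into `n_ds` when registering a design.

The shipped registry contains the fully hybridized triangle
(N_ds = 14498 = 2 × 7249, N_ss = 0, the only default design without
single-stranded regions) plus placeholder entries for bowtie, double-L,
capsule and 24HB whose exact counts depend on the specific designs; these
are flagged editable and should be replaced with the user's own counts.

## The 1:2 binding model

Two sequential equilibria, base pair as guest: K₁₁ for DOX·bp, K₁₂
(stepwise) for DOX·bp₂. The observable isotherm, the cubic mass balance
for the unbound base-pair concentration, the bound fraction, and the
quadratic inversion are implemented exactly as stated in the README.

Numerical choices:

* **Cubic root (mass balance).** The residual g(c) = Ac³ + Bc² + Cc −
  c(bp)₀ satisfies g(0) < 0 and g(c(bp)₀) ≥ 0, so the physical root is
  bracketed by [0, c(bp)₀]. Companion-matrix (`numpy.roots`) candidates
  are filtered to that interval and the root is polished by bracketed
  refinement (`brentq`) at machine tolerance; the accepted root must
  satisfy the residual to 1 × 10⁻⁹ relative to the dominant polynomial
  term. Degenerate inputs short-circuit: c(DOX)₀ = 0 returns c(bp)₀
  exactly (the cubic cancels identically), c(bp)₀ = 0 returns 0.
* **Quadratic root (inversion).** For a physical observable
  (Φ_Δ12 < ΔΦ_obs < 0) the leading coefficient is positive and the
  constant term negative, so exactly one root is non-negative; it is
  computed with the numerically stable quadratic branch and verified to
  round-trip through the forward isotherm to 1 × 10⁻⁶ relative. At the
  saturation limit ΔΦ_obs = Φ_Δ12 the inversion is degenerate and a
  dedicated `SaturationError` tells the caller to treat f_b as 1.
* **Titration fitting.** Nonlinear least squares (lmfit) over
  {log₁₀K₁₁, log₁₀K₁₂, per-channel Φ_Δ11, Φ_Δ12}, K shared across the
  default channels (450, 460, 470, 480, 494 nm), channels weighted
  equally. Every residual evaluates the isotherm at the mass-balance
  root, so depletion of both drug and base pairs is exact. Multi-start:
  log₁₀K initialised on a 3 × 3 grid over [3.5, 6.5] with small seeded
  jitter (default seed 20210228), bounds log₁₀K ∈ [0, 9] and deltas ∈
  [−1, 0]; the best χ² solution wins, parameters pinned at bounds are
  flagged. Standard errors come from the Jacobian; K uncertainties are
  transported from log space by the delta method. Preconditions: ≥ 6
  points spanning ≥ 10× in positive c(bp)₀. Titration points are assumed
  equilibrated (binding equilibrates within seconds at these
  concentrations); no kinetic correction is applied.
* **Absorbance deltas.** With K fixed the isotherm is linear in the
  deltas, so per-wavelength (ε_Δ11, ε_Δ12) come from a linear
  least-squares solve on the complex mole fractions; a rank-deficient
  design matrix (all points in one binding regime) triggers a
  conditioning warning rather than silent garbage.
* **Loading kinetics.** A single-exponential a·e^(−bt) + c (lmfit,
  b ≥ 0) summarises equilibration time courses; constant data returns
  b = 0 with a `no_decay` flag instead of a spurious rate.

The low-base-pair limit of bound DOX per total base pair has the closed
form K₁₁c(DOX)₀/(1 + K₁₁c(DOX)₀) (as c(bp)₀ → 0 the denominator species
vanish); a numerical variant scans c(bp)₀ → 0 through the full mass
balance and verifies convergence to the same value. At the averaged
constants (K₁₁ = 2.0 × 10⁵ M⁻¹) and 3 μM DOX this limit is 0.375 DOX/bp.

## Digestion and release

% intact is read off the A260 trace between its two plateaus. The progress
ratio (A₂₆₀(t) − A₂₆₀(intact))/(A₂₆₀(digested) − A₂₆₀(intact)) measures
digestion *progress* (0 at t = 0); the package reports
% intact = 100 − progress so curves start at 100, and exposes both
orientations (`digestion_progress`, `percent_intact`) to keep the
convention explicit.

Release analysis is measurement-driven, never a pure model prediction:
each time point's ΔΦ_obs is inverted to c(bp)_ub, then f_b, then
% released relative to the pre-DNase state. The free-DOX reference for a
digestion run must be a matching-concentration free-DOX + DNase control —
it is a required input, not assumed equal to the titration reference.
% released is deliberately *not* clipped to [0, 100]: noise-driven
overshoot is reported raw with a warning, because clipping hides
pathologies.

The initial-linear-phase window for rate regression defaults to the
longest initial run of points with % intact ≥ 70 (minimum 4 points);
fixed-count and R²-expanding rules are selectable. The release-rate
regression reuses the time window selected on the % intact series, so both
rates describe the same phase of the same digestion. Rates are ordinary
least-squares slopes with standard errors; the relative dose is
rate/100 × f_b(intact) × c(DOX)₀, in M/min.

## Aggregation

Free DOX after incubation + centrifugation is c₀ × A₄₈₀(sup)/A₄₈₀(t₀)
(Beer–Lambert linearity of the supernatant is assumed, as in the
underlying protocol; both absorbances must share the same geometry).
c_aggregate = c₀ − c_free, floored at 0 with a warning when noise pushes
c_free marginally (≤ 2%, configurable) above c₀ and rejected beyond that.
The pellet's DOX/bp ratio is flagged above 1 — the intercalation ceiling —
since a higher ratio means the precipitate is dominated by free-DOX
aggregate rather than drug-loaded carrier. DOX-only controls (c_bp = 0)
return an undefined marker, not a number. The solubility conversion uses
the free-base molar mass 543.52 g/mol (the deprotonated, poorly soluble
species): 0.3 mg/ml ≈ 0.55 mM.

## Synthetic data and what passing tests mean

The generators emulate the three experimental designs with planted truth:

* **Titration**: 3 μM total DOX, a 0–40 bp/DOX grid (12 points), planted
  K₁₁ = 2.0 × 10⁵ M⁻¹, K₁₂ = 2.6 × 10⁵ M⁻¹, Φ_Δ11 = −0.48, Φ_Δ12 = −0.933
  on all five channels, 494 nm extinction deltas −4200/−3300 M⁻¹cm⁻¹.
  Noise: 1% multiplicative Gaussian on the Φ/Φ₀ proxy (shot-like,
  signal-proportional), 0.002 AU additive on absorbance.
* **Digestion**: 2 nM DONs; intact fraction decays as e^(−k_eff·t) with
  k_eff = k_dig/(1 + inhibition × bound-DOX per bp), emulating the
  slowdown of DNase I by bound drug (inhibition factor 5 per DOX/bp,
  illustrative). Presets: triangle k_dig = 0.25 min⁻¹ (drug-free
  digestion ≥ 99% complete within ~20 min) and 24HB 100× slower,
  spanning the two-orders-of-magnitude superstructure range. A260
  interpolates between plateaus (30% hyperchromicity); fluorescence
  follows the equilibrium over the remaining base pairs, or — with
  `coupled_release=True` — a release curve tied one-to-one to the
  digested fraction, the regime in which % released and % digested
  correlate perfectly.
* **Aggregation**: planted retention fractions mapped through A480 pairs.

The forward digestion model is an emulator for exercising the inverse
pipeline, not a mechanistic claim about DNase kinetics. Seeds fix all
randomness; identical configurations produce byte-identical CSVs.

Verification is by parameter recovery: noiseless generation followed by
analysis is the identity to solver tolerance; at 1% noise the median
absolute log₁₀ error of the recovered constants over seeds 1–3 stays
within 0.1. Problem sizes in the test suite (12-point titrations,
25-point time courses, 10³ random solver inputs) were chosen so the full
suite runs in well under a minute while keeping the recovery statistics
meaningful.

What passing does **not** show: recovery from data whose noise is
correlated across wavelengths or drifts in time, instrument-specific
inner-filter geometry, DOX dimerisation/oligomerisation equilibria in
solution, sequence-dependent binding (GC vs AT), lattice/neighbour-
exclusion binding models, or mechanistic enzyme kinetics — all outside
this package's scope. Absolute experimental digestion rates are not
reproducible from first principles (they depend on enzyme activity,
temperature and superstructure); the package validates *rate recovery*
on synthetic courses and faithful arithmetic on measured ones.

## Known limitations

* The registry's non-triangle designs are placeholders to be edited; no
  caDNAno/sequence-level parsing is attempted.
* The 1:2 model treats base pairs as independent identical sites; dense
  DOX loading violates neighbour exclusion before f_b does.
* The inversion is undefined at exact saturation (handled by
  `SaturationError`) and increasingly noise-sensitive near it.
* Bound fractions in digestion samples are taken from measurement via the
  inverse model, not predicted from nominal concentrations — forward
  predictions at nominal concentrations can deviate from measured bound
  fractions and are not used for release calculus.
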