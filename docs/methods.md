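# Methods

This note documents the model, the self-consistent solution implemented in
`floryfit`, the fitting procedure, the synthetic-data generator, and the
numerical choices that a maintainer would want spelled out.

## 1. Model and exact landmarks

Two-component Flory–Huggins free energy per lattice site, k_BT = 1:

    f(φ) = (φ/N) ln φ + (1−φ) ln(1−φ) + χ φ(1−φ),

with N ≥ 1 the effective chain length (number of lattice sites per solute;
real-valued, because fits to protein data produce non-integer values) and
χ > 0 the net polymer–solvent contact energy. Chemical potential and
osmotic pressure follow analytically:

    μ(φ) = f′(φ) = (ln φ + 1)/N − ln(1−φ) − 1 + χ(1−2φ),
    Π(φ) = φf′ − f = −ln(1−φ) − γφ − χφ²,     γ ≡ 1 − 1/N.

* Spinodal: f″ = 1/(Nφ) + 1/(1−φ) − 2χ = 0 is the quadratic
  2χφ² − (2χ−γ)φ + 1/N = 0; the dilute root is recovered from the root
  product φ₋φ₊ = 1/(2Nχ) to avoid cancellation at large χ. Its large-χ
  limit is the power law φ₋^spi ≈ 1/(2Nχ).
* Critical point: f″ = f‴ = 0 gives χ_c = (1+1/√N)²/2, φ_c = 1/(1+√N).
* Ginzburg–Landau binodal: expanding f about (φ_c, χ_c) to fourth order
  leaves a symmetric double well −δχ·δφ² + (f⁗_c/24)δφ⁴ whose common
  tangent touches at φ_c ± α with α = √(6δχ)·N^{3/4}/(1+√N)²
  (the near-critical spinodal has the same form with √2 instead of √6).
  The pair is returned **unclipped** even when it leaves (0,1) far from
  χ_c — the self-consistent maps are defined on all of ℝ and use it as
  their initial guess; clipping would change the orbits.

All coefficients above are verified in the test suite against their
definitional conditions (root-finding on f″, simultaneous f″ = f‴ = 0,
width-coefficient comparison against the numerical oracle), so a
transcription error in any closed form cannot pass silently.

## 2. Self-consistent binodal solution

Equality of μ and Π between phases, with the two exponents computed from a
trial pair,

    x = 2χ(φ₊−φ₋),        y = γ(φ₊−φ₋) + χ(φ₊²−φ₋²),

gives φ₋/φ₊ = e^{−N(x−y)} from the μ equation and, after substituting into
the Π equation, the update operator **G**:

    φ₊′ = (1 − e^{−y}) / (1 − e^{−N(x−y)−y}),     φ₋′ = φ₊′ e^{−N(x−y)}.

Its fixed points are: the binodal (the flow's unique attractor) and, on the
diagonal φ₋ = φ₊, exactly the two spinodal compositions (the diagonal
limit of the fixed-point condition reduces to the spinodal quadratic) —
which is also why the spinodal is not a usable initial guess. At N = 1 the
operator degenerates to the scalar logistic map
g(φ) = 1/(1+e^{χ(1−2φ)}) with exact branch symmetry φ₊ = 1−φ₋; |g′| = 1
exactly at the critical point (0.5, 2), so contraction slows to a halt at
criticality and is fastest at large χ.

### Closed forms

With reduced parameters α (GL half-width) and Δ = φ_c, the exponents at
the GL guess collapse to

    A = 2α(γ + 2χΔ),      B = 2Nα(2χ(1−Δ) − γ),

and one application of **G** is the explicit first-order binodal
φ₊ = (1−e^{−A})/(1−e^{−A−B}), φ₋ = φ₊e^{−B}. Under the polymer–solvent
relabeling (φ → 1−φ, N → 1/N, χ → Nχ), which exchanges the branches, A and
B swap. Re-evaluating the exponents on the first-order pair uses only the
pair width D = (1−e^{−A})(1−e^{−B})/(1−e^{−A−B}) (invariant under the
relabeling, as is the second-order denominator) and the pair sum, and one
more application gives the second-order closed form. By construction the
order-k expression equals k applications of **G** to the GL pair, and the
test suite asserts this to 1e-12 — the closed forms and the map are two
codings of the same algebra, not two approximations.

### Scaling law

Substituting the trivial guess (φ₋, φ₊) = (0, 1) into **G** gives
e^{−x} → e^{−2χ}, e^{−y} → e^{−γ−χ}, hence the exponential dilute-branch
law φ₋^bin ≈ e^{−N(χ−γ)} (e^{−χ} at N = 1). The contrast with the
spinodal's 1/(2Nχ) power law is the model's explanation for LLPS spanning
decades of concentration.

### Newton acceleration

Expanding the self-consistent condition to first order around the current
iterate gives the improved maps

    h(φ) = φ + (g(φ)−φ)/(1−g′(φ)),      H(φ) = φ + (1−J)⁻¹(G(φ)−φ),

with J the analytic Jacobian of **G**. Both reduce to the plain map where
the derivative vanishes and fall back to it (recorded in the orbit
metadata) when the correction is singular (|1−g′| or |det(1−J)| < 1e-14,
which happens at criticality where the spectral radius of J reaches 1).
In practice the accelerated orbit reaches the oracle to 1e-6 in ln φ in
4–5 iterations at N = 100 over (χ_c, 2χ_c] and to 1e-10 residual in ≤ 10;
we quote and test "a handful" (≤ 6 to 1e-6) rather than a smaller count,
which in our hands holds only as visual-overlap accuracy.

### Solver policy

* Default analytic method is the second-order closed form; default
  iterative method is the Newton-accelerated map.
* Stopping rule: common-tangent residual max(|Δμ|, |ΔΠ|) < 1e-10 or 50
  iterations (iteration-count observations are accuracy statements, not
  stopping rules).
* Branch identity φ₋ ≤ φ₊ is enforced by ordering after every step; a
  collapsed pair (|φ₊−φ₋| < 1e-12 with χ > χ_c + 1e-6) raises a
  convergence failure rather than returning the trivial diagonal.
* Near-critical guard: for χ − χ_c < 1e-6 the GL pair is returned directly
  (the maps are non-contractive there and the GL solution is exact in that
  limit).
* The dilute branch is carried in the log domain (ln φ₋) through every
  map application; e^{−N(x−y)} is never formed bare. When
  ln φ₋ < −650 — routine at large Nχ given the scaling law — the orbit
  switches to extended precision (mpmath), with working precision grown
  with χ so that 1−φ₊ ~ e^{−γ−χ} also stays resolvable.

## 3. Numerical oracle

`oracle_binodal` solves μ(φ₊) = μ(φ₋), Π(φ₊) = Π(φ₋) independently of the
maps: an outer bracketed root-find on the chemical-potential level μ
(the Π-mismatch is strictly increasing in μ since dΠ = φ dμ), inner
bracketed solves per branch on (0, φ₋^spi) and (φ₊^spi, 1), and a final
2-D Newton polish. All dilute-branch work uses t = ln φ and all
dense-branch work w = ln(1−φ); residuals are evaluated in those charts,
which is what makes the default 1e-12 residual contract attainable at
large χ where 1−φ₊ is tiny. Nested bracketing was chosen over a 2-D
Newton for global robustness near χ_c; the Newton polish supplies the last
digits. The same ln φ₋ < −650 rule switches the whole construction to
mpmath. The oracle is a correctness reference, not a fast path.

## 4. Fitting measured coexistence curves

* Temperature enters through χ(Δϵ, T) = Δϵ/(RT), with Δϵ in kJ/mol and R
  the gas constant — a purely enthalpic interaction, giving UCST behavior
  as observed for A1-LCD. Any coordination-number prefactor is absorbed
  into Δϵ.
* Concentrations convert to volume fractions via φ = cM/ρ with defaults
  M = 13.1 kDa and ρ = 1.35 g/cm³ (1 mM → φ = 9.704e-3). The mol/L path
  multiplies into mass concentration first so that datasets expressed
  consistently in either unit give bitwise-identical fits.
* Objective: squared residuals in ln(concentration), dilute and dense
  branches pooled. The log metric is the natural choice because the two
  branches differ by orders of magnitude (scaling law above) and published
  coexistence plots are read on log axes; no further weighting is applied.
* Cloud-point rows are critical-point estimates, not coexistence points;
  they are excluded by default and, when explicitly included, are compared
  against ln φ_c(N).
* Optimization: one shared N (outer) and one Δϵ per variant (inner), each
  by a deterministic coarse grid followed by bounded Brent refinement with
  fixed brackets — no stochastic restarts, so fits are bit-reproducible
  and invariant under row order (rows are canonically sorted) and variant
  relabeling. Initialization is deterministic: N₀ = residue count of the
  reference protein; Δϵ₀ from the highest-temperature dilute point through
  the scaling law. Trial parameters that make a measured temperature
  supercritical incur a smooth quadratic penalty instead of a
  discontinuity.
* Predictions use the second-order closed-form binodal: it is smooth in
  (N, Δϵ), accurate to a few percent in ln φ across the fitted range, and
  orders of magnitude cheaper than converged iteration — the property that
  makes nested 1-D fitting practical.
* Reported per variant: Δϵ, E = −NΔϵ, ΔE = E_variant − E_reference
  (reference variant configurable, default label "WT").
* Per-residue decomposition assumes the linear composition model
  E_variant = E₀ + Σᵢ nᵢΔEᵢ; since ΔE values are differences from the
  reference sequence, E₀ cancels and the system ΔE_variant = Σᵢ Δnᵢ ΔEᵢ
  is solved exactly when square, by least squares when overdetermined
  (rank deficiency raises an error listing the unresolved combinations).
  Where several variants independently isolate the same residue swap
  (e.g. the Gly/Ser series), the per-variant estimates are reported with
  their spread as the uncertainty; no bootstrap is claimed.

One published inconsistency is handled explicitly: for the A1-LCD aromatic
series, the quoted per-residue difference ΔE_Phe − ΔE_Tyr = 0.8 kJ/mol is
not recoverable by direct algebra from the tabulated variant ΔE values
(the first tabulated variant alone gives 5.5/12 ≈ 0.46). The package
therefore treats 0.8 as a printed input (`floryfit.data.ARO_PHE_MINUS_TYR`)
when reproducing the downstream Tyr/Phe energies (−4.2 and −3.4 kJ/mol),
rather than silently substituting its own value.

## 5. Synthetic data generator

`SyntheticDatasetSpec` emulates temperature-resolved variant panels of the
A1-LCD type: per variant, one dilute and one dense concentration per
temperature, multiplicative lognormal noise. Defaults — chosen once as the
study conditions — are N = 150 (protein-scale, near the fitted A1-LCD
value), three variants with Δϵ ∈ {1.59, 1.70, 1.50} kJ/mol (a protein-level
spread of roughly ±15 kJ/mol, comparable to the measured variant range),
15 temperatures spanning 270–305 K (all subcritical for every default
variant; supercritical temperatures simply produce no rows), and noise
σ = 0.05. Ground truth travels in a JSON sidecar; a fixed seed gives
byte-identical files.

The generator's forward model is the same second-order closed form the
fitter inverts. Passing recovery tests therefore demonstrates that the
pipeline is correctly implemented, deterministic, and well-conditioned at
realistic noise — not that the Flory–Huggins model is an adequate
description of any particular protein. Real data additionally contain
temperature-dependent Δϵ, branch-dependent error structure, finite
critical-region rounding and instrument censoring, none of which are
emulated.

## 6. Known limitations

* Two components only: no ternary mixtures, gradient/surface-tension
  terms, electrostatics, or sticker–spacer microstructure.
* χ is purely enthalpic in the fit; entropic (temperature-independent)
  contributions to χ are absorbed into Δϵ and LCST behavior is out of
  scope.
* The per-residue decomposition is composition-only; sequence-order
  effects (charge patterning, aromatic spacing) are outside the linear
  model.
* With dilute-branch-only data, N and Δϵ are nearly degenerate (the dilute
  log-slope constrains mainly NΔϵ); identifiability then rests on the
  dense branch and on temperature curvature, and fitted spreads widen
  accordingly — the fit reports residuals rather than hiding this.
* Headline experimental numbers (N = 158.6, E_WT = −251.9 kJ/mol and the
  variant ΔE table) require the original measurement dataset, which is not
  redistributed here; the package carries the published values as data and
  documents the CSV schema needed to re-run the fit on the real
  measurements.
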