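# Methods

This note documents the models implemented in `quake_biogeo`, their
assumptions, the defaults and why, the numerical choices, and what the
synthetic-data generators do and do not emulate.

## Isotope algebra and calibrations

All delta values are permil deviations from the conventional standards
(VSMOW, VPDB, VCDT). Fractionation factors use the exact form
alpha = (1000 + dA)/(1000 + dB); no linear (eps ~ 1000 ln alpha)
approximation is used anywhere, so the chain rule
alpha(A,C) = alpha(A,B)·alpha(B,C) holds to machine precision. Deltas at or
below −1000 ‰ (non-positive ratios) are rejected. All permil arithmetic is
double precision; rounding happens only at presentation (2 decimals for
alpha, 1 for permil values by default in the examples).

Equilibrium fractionation for H2–H2O(l) and CH4–H2O(l) is the published
polynomial-in-1/T calibration (Horibe & Craig 1995), stored with
provenance in `data/calibrations.tsv` as the inverse-factor polynomial
1/alpha = c0 + c2/T² + c4/T⁴ + c6/T⁶. The H2–H2O curve reproduces the
anchor values 0.23/0.26/0.31 at 4/25/55 °C within ±0.005 and equals 0.2200
at 0 °C. Validity ranges are 0–400 °C (H2–H2O; the upper part is a mild
extrapolation used only for classifying hydrothermal H2) and 0–100 °C
(CH4–H2O). Evaluation outside the range raises; inversion
(`temperature_from_alpha`) brackets the monotone curve with Brent's method
to |alpha residual| ≈ 1e-12, i.e. temperatures to well under 0.01 °C.

The methanotrophy trajectory moves residual CH4 along
(d13C, dD) -> (d13C + s, dD + 10·s); the slope 10 is the literature value
for microbial CH4 oxidation and is a parameter.

## Keeling regression and Fe–H2O alpha fits

The Keeling estimator is ordinary least squares of dD_H2 on the reciprocal
mixing ratio (the conventional choice, and exact on the two-endmember
mixing model: observed delta is affine in 1/c with slope
c_bg·(d_bg − d_src)). The intercept standard error is the OLS one
(reported for n ≥ 3, NaN otherwise); a degenerate design (all mixing
ratios equal) raises. A geometric-mean (model-II) variant was considered
and rejected as the default because OLS is unbiased under the
noise-on-delta model the generators implement.

Batch alpha fitting regresses (1000 + dD_H2) on (1000 + dD_H2O) through
the origin, alpha = Σxy/Σx². This weights batches equally and is exact on
the linear fractionation model, unlike averaging per-point ratios.

`classify_h2_origin` compares an apparent alpha with the equilibrium curve
at the given temperature: within ±0.02 → equilibrated; below the band →
low-temperature water–rock; alpha ≥ 0.6 → high-temperature kinetic
(fault-melt H2 is ~0.8, hydrothermal equilibrium 0.6–0.7 at 300–400 °C).
Both thresholds are parameters. Values above the band but below 0.6 have
no physical interpretation in this scheme and raise.

## Pore-water contamination correction

The correction assumes (i) linear volumetric mixing of indigenous fluid
and seawater, and (ii) zero indigenous sulfate, valid for the prism units
U1–U3 where past sulfate reduction exhausted sulfate. Then
f = SO4_obs/28 mM and the zero-sulfate extrapolation of any conservative
species equals unmixing (c − f·c_sw)/(1 − f); the package asserts this
equivalence by property test. The seawater SO4 reference (28 mM) is a
standard open-ocean value stored with provenance (the profile chlorinity,
560 mM, is the value the data themselves constrain); the "up to 40 %"
contamination diagnosis is insensitive to ±1 mM in this reference.

Assumption (ii) fails below the decollement (U5 carries real basement
sulfate), so correction is masked off for U4+ by default (configurable).
Negative extrapolated concentrations are reported as-is with a warning
flag rather than clamped — they are the diagnostic of assumption
violation. Correction is idempotent: a corrected table has zero sulfate,
hence f = 0 on re-correction. Depths are sample midpoints in mbsf; unit
intervals are half-open [top, bottom) (deepest closed) so printed shared
boundaries are unambiguous, and overlapping intervals are rejected at
load. Units 6 and 7 are delimited jointly in the source lithology; the
table assigns the joint interval to U6.

## Multiple sulfur isotopes

Δ33S uses the exact exponential reference array with exponent fixed at
0.515; λ33 of actual processes is a free parameter (observations give
~0.514) constrained to the mass-dependent window [0.500, 0.520]. The MSR
forward model constructs the product sulfide so that ε34/λ33 of the
(sulfate, sulfide) pair round-trip exactly. A consequence of the exact
formulation worth noting: fractionating with λ33 = 0.515 preserves Δ33S
exactly only for pools on the reference array; off-array Δ33S scales by
((1000 + d34_sulfide)/(1000 + d34_sulfate))^0.515 (e.g. seawater's
+0.050 ‰ → +0.048 ‰ under ε34 = 68 ‰), a sub-analytical-precision effect.

Mixing is molar mass balance on 32S/33S/34S abundances: each pool's
per-unit-sulfur isotope moles are computed from its ratios on the VCDT
absolute scale (shipped in `data/reference_ratios.tsv`), summed with the
mixing weights, and re-expressed as deltas. Endmembers are assumed to
carry equal sulfur per unit mixing fraction unless explicit contents are
given. Results are insensitive to the absolute reference ratios to first
order (rescaling them ×2 moves d34S by ~0.02 ‰ and Δ33S by < 1e-3 ‰,
asserted by test); the curvature of the mixing trend in (δ34S, Δ33S) space
comes from re-evaluating Δ33S along the (nearly straight) mixing line in
delta space.

## Energetics

ΔGr = ΔG° + RT ln Q with R = 8.314462618 J mol⁻¹ K⁻¹. ΔG° for the three
reactions is assembled from a shipped species table of SUPCRT92-lineage
aqueous formation energies (25 °C, 1 bar compilation values shifted to
500 bar with the partial-molal-volume term), so Hess closure
ΔG°(r3) = ΔG°(r2) − ΔG°(r1) is exact by construction: −196.7, −173.7 and
+23.0 kJ/mol. The table documents source and retrieval date; its realistic
uncertainty is a few kJ/mol, which is why all threshold statements are
made at order-of-magnitude precision and the speciation target at a
factor of 2.

Activity model: B-dot extended Debye–Hückel
(log10 γ = −Az²√I/(1 + Bå√I) + Ḃ·I) with Helgeson 25 °C constants and
Kielland ion sizes. Neutral species (CO2(aq), CH4(aq), H2(aq), CH3COOH)
default to γ = 1; a Setchenow option (log10 γ = b·I) exists but the
dominant uncertainty is ΔG°, not salting-out. Water activity is fixed at
1; pH is on the activity scale; molality ≈ molarity is accepted at these
conditions. Default ionic strength 0.66 mol/kg (seawater-like, consistent
with 560 mM chloride).

Speciation: monoprotic mass balance for acetate (pKa 4.66 at 25 °C /
500 bar) and three-species carbonate mass balance (pK1 6.13, pK2 10.11).
At the study conditions (1 mM total acetate, pH 7.9) the neutral
acetic-acid activity evaluates to 4.0e-7, within a factor of 1.4 of the
reported 2.8e-7 — the difference is consistent with the constant-table
provenance — and is exactly linear in the total. Threshold activities
solve ΔGr = 0 by bracketed root finding on log10 a (Brent, bracket
[1e-12, 1], verified |ΔGr| < 0.01 kJ/mol at the root); the quotient is
monotone in the free species so the root is unique, and a missing sign
change raises. Computed thresholds at 1 mM acetate: a[H2] = 10^-7.58
(homoacetogenesis) and 10^-8.38 (methanogenesis), i.e. the ~1e-7 and
~1e-8 orders of magnitude with homoacetogenesis needing roughly one order
of magnitude more H2. Note that with these constants hydrogenotrophic
methanogenesis is still marginally exergonic (−8.7 kJ/mol) at
a[H2] = 1e-8: its threshold sits just below the nominal background level,
within the stated constant uncertainty, so "shut off at background" holds
cleanly for homoacetogenesis but only to within a few kJ/mol for
methanogenesis.

SolutionCondition pins T and P to the single (25 °C, 500 bar) point of the
constant table; temperature or pressure extrapolation of ΔG° is out of
scope, as are Pitzer-model activities and mineral saturation.

## Density estimators

Endpoint dilution: density = (1/v_inoculum)·step_factor^k·slurry_dilution
with k the highest positive step (1-based). Defaults encode the protocol
volumes: 0.5 mL transferred into 5.0 mL per step (factor 11) and 0.5 g
sediment (≈ 0.5 mL) in 5 mL slurry (dilution 10); all overridable. This is
an endpoint convention, not an MPN likelihood, because the protocol runs
single tubes per dilution; its quantization bound is one step factor.
All-negative series return a below-detection marker carrying the k = 0
formula value as the detection limit; non-monotone positivity warns and
uses the highest positive. Filter counts use the single geometric formula
mean·(filter area/field area)/volume·dilution, warning below 100 fields.

## Synthetic generators

A single integer seed drives a named SeedSequence substream per generator,
so adding generators never perturbs existing streams and identical
configs give byte-identical tables. Defaults mirror the study setting:
H2 peaks of 209 and 26 μM at 695 and 818.5 mbsf over a < 3 μM background
(Gaussian peak shape, width 1.5 m — the shape and width are testability
choices, only locations and amplitudes are constrained); CH4 1–20 mM in
the prism and < 5 mM below the decollement; d13C_CH4 drifting −64 → −84 ‰
with depth with a ~60 ‰ CH4–CO2 separation; air Keeling background
0.5 ppmv at +150 ‰ against a −850 ‰ source; Fe–H2O alphas 0.13/0.19/0.23
at 4/25/55 °C with water dD spanning 0 to +3000 ‰ and 10 ‰ noise (the
measurement uncertainty of dD_H2); pore-water rows as exact convex
combinations of a prism endmember (Cl 559 mM, zero sulfate, NH4 1.5 mM,
dD_H2O +3 ‰) and seawater at f ≤ 0.4; sulfide records from MSR
(ε34 ∈ [10, 68] ‰, λ33 = 0.514) mixed with juvenile sulfur; dilution
positivity as Poisson presence with the per-step effective inoculum
volume implied by the estimator convention (which makes noise-free
recovery exact to within the one-step quantization).

What the generators do **not** emulate — and hence what passing tests do
not establish about real data: depth covariance and diffusion structure in
profiles, degassing losses of CH4/H2 during recovery, correlated
(non-Gaussian) isotope measurement errors, heterogeneous sulfur contents
between mixing endmembers, carry-over and inhibition artefacts in
cultivation series, and any microbial community composition (sequencing is
out of scope). Estimator performance on expedition data therefore carries
the usual field caveats; the suite establishes algebraic correctness,
statistical calibration under the stated noise models, and internal
consistency.

## Pipeline and I/O

One TSV dialect (UTF-8, '.' decimal, 'NA' missing) everywhere, for
bit-exact reproducibility. Readers validate required columns by name and
report non-numeric cells with their line number; extra columns pass
through. The end-to-end pipeline runs six stages (pore-water correction,
CH4 systematics, Keeling fit, Fe–H2O alpha fits, sulfur statistics,
energetics) on simulated inputs and writes a manifest with the seed,
config and sha256 hashes of every shipped constant table: equal manifests
imply byte-identical outputs. Logging goes to stderr; results never do.

## Problem sizes

Defaults are sized for interactive use: ~70-row gas profiles, 12-sample
pore-water and Keeling tables, 8-level batches, 20-row sulfur tables,
500–1000-replicate Monte-Carlo checks. The full test suite runs in a few
seconds on one CPU.
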