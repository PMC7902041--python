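# Methods

This note records the models, estimators, conventions and defaults behind
`ocuqtl`, and what the synthetic-data tests do and do not demonstrate.

## Forward perfusion model (simkit)

A perfused enucleated eye is modelled as a pressure-dependent capacitor
(compliance φ(P) = φ_r(13+γ)/(P+γ)), drained by the aqueous outflow pathway
(facility C, flow C·P) and fed through the cannulation needle and in-line
capillary (resistance R_n, inflow Q_in = (P_a − P)/R_n). Optional
viscoelastic creep adds a first-order volume state:

    φ(P)·dP/dt = Q_in − C·P − dV_c/dt
    dV_c/dt    = (c_creep·(P − P_base) − V_c)/τ_creep

The applied pressure P_a is piecewise constant following the protocol. The
system is integrated per level with LSODA at rtol = atol = 1e-8; recorded
pressure and flow carry independent Gaussian sensor noise per sample, while
the applied-pressure channel is the noise-free command signal. System
(tubing) compliance is assumed calibrated out and is not modelled.

Default protocol: baseline 8 mmHg; 9 ascending then 8 descending steps of
1.5 mmHg (8 → 21.5 → 9.5 mmHg, straddling the 13 mmHg reference); 240 s per
level; 2 Hz sampling. Default sensor noise is 0.05 mmHg (pressure) and
0.1 nl/s (flow), about 5% of the characteristic signal amplitudes (1.5 mmHg
steps; ~2 nl/s steady flows). Default eye: φ_r = 45 nl/mmHg, γ = 10 mmHg,
C = 0.07 nl/s/mmHg (typical mouse outflow facility), R_n = 0.5 mmHg·s/nl,
mass 21.1 mg. These magnitudes reproduce normalised compliances around
2.3–2.5 nl/mmHg/μl, the range reported for mouse eyes. Units are fixed
package-wide: mmHg, nl, nl/s, s, with eye volume in μl; conversions happen
only at I/O boundaries.

Creep with c_creep > 0 makes the eye viscoelastic: over a long step the
extra volume c_creep·ΔP is absorbed slowly (τ_creep default 90 s). The
Volume Filling method integrates all of it; the Step Response fit is
dominated by the fast elastic transient. This asymmetry is the mechanism
behind the VF-above-SR bias the package's comparison stage demonstrates.

### RI genotypes and trait architecture

Recombinant inbred strains are simulated as homozygous B/D mosaics: per
chromosome a two-state Markov chain whose adjacent-marker switching
probability is the sib-mating RI expansion R = 4r/(1+6r) of the Haldane
recombination fraction r of the cM gap. The default synthetic map has 19
autosome-like chromosomes with mouse-like genetic lengths (~1440 cM total),
markers every 2 cM, and a fixed physical scale of 2 Mb/cM. True RI genomes
are not Markov (the chain composition identity fails across intervals), but
the same approximation underlies standard interval-mapping conditionals, so
generator and estimator are consistent by construction.

The trait plants one additive QTL: strain value = base + a·(dosage − ½) +
strain-level noise, per-eye value adds eye-level noise. The allele effect a
is sized from the theoretical dosage variance ¼ so the QTL contributes the
requested fraction of QTL-plus-strain-environment variance; the realized
fraction (a sample quantity) is reported alongside. Defaults: base
2.4 nl/mmHg/μl, variance fraction 0.37, strain SD 0.20, eye SD 0.25 — with
8 eyes per strain these give broad-sense heritabilities near 0.5–0.6, the
regime reported for this trait. Dominance, epistasis, X-linkage and sex
effects are out of scope.

## Compliance estimation (perfusion)

**Segmentation.** Steps are delimited by changes in the applied-pressure
channel; one segment per constant level after the first. Plateau statistics
use the trailing 25% of each level; with the default protocol that window
starts ≥ 7 relaxation time constants after the step, so plateau means are
steady to well below the noise floor.

**Facility.** OLS of plateau-mean flow on plateau-mean pressure across all
segments; the slope is C, the intercept is retained as a diagnostic, and a
negative slope is flagged but not discarded. C is estimated once per eye
and held fixed in both per-step estimators.

**Volume Filling.** ΔV is the trapezoidal integral of Q_in − C·P over the
segment (the integrand vanishes on bounding plateaus); ΔP the plateau-mean
difference, with a 0.2 mmHg floor below which the segment is rejected. The
estimate φ = ΔV/ΔP is a secant, assigned to the step midpoint pressure. Its
SE propagates plateau-pressure SEs and flow noise (plateau residual SD
integrated with the trapezoid weights).

**Step Response.** The measured transient of an ascending step is fit by
least squares to the numerically integrated governing ODE (fixed-step RK4
on the sample grid — one step per 0.5 s sample against relaxation times of
tens of seconds), with the local compliance φ (anchored at the pre-step
plateau pressure) and a per-step γ free and C fixed. A closed-form solution
exists for this ODE but is not used; round-trip tests against the forward
simulator pin the numerical route to within 0.5%. The starting point comes
from the initial pressure slope; additional γ starts are tried only when
the first fit fails or pins a bound, which is also flagged. SEs come from
the Jacobian at the optimum. Whether the original instrument shared one γ
per eye or per step is ambiguous; per-step is implemented, and the pooled
fit below re-estimates a single eye-level γ anyway.

**Reference compliance.** φ(P) = φ_r(13+γ)/(P+γ) is fit to the per-step
estimates by weighted (1/SE², SEs floored at 1e-6·φ for conditioning; unit
weights when SEs are absent) nonlinear least squares with γ > 0, multi-start
over γ ∈ {1, 3, 10, 30, 100}, requiring ≥ 3 steps at ≥ 3 distinct
pressures. Normalisation: volume = mass/1.103 mg·μl⁻¹, φ_norm = φ_r/volume,
SE scaled by 1/volume.

On noise-free, creep-off simulated eyes the VF and SR per-step estimates
agree with the analytic secant/local compliance to < 0.5%, and the facility
regression recovers C to < 1%; these bounds are enforced by tests.

## Quality control and derived phenotypes (phenotypes)

The QC cascade is fixed: (1) flag records whose relative SE on φ_r strictly
exceeds the 85th percentile of the data set, per method; (2) per animal,
keep the unflagged eye with lower SE (ties break OD before OS; an
uncertainty-flagged eye always loses); (3) flag within-strain values beyond
1.5·IQR of the quartiles, computed among survivors of the first two stages.
All quantiles use linear interpolation of order statistics (numpy's
default), the one convention applied package-wide. QC annotates rather than
drops, thresholds are always computed on the full table, so the cascade is
idempotent and counts reconcile at every stage.

Strain aggregation reports mean, SD and a t-based 95% CI per strain plus a
one-way ANOVA p-value as a diagnostic. Heritability is computed literally
from dispersions: V_g = SD of strain means, V_e = mean within-strain SD,
H² = V_g/(V_g+V_e). The symbols suggest variances, but the SD form is the
convention this trait is reported with; a variance-based variant exists
behind `use_variances=True` and is not the default. H² is scale-invariant
and bounded in [0, 1] in either form.

The effective modulus treats the eye as an isotropic, incompressible,
homogeneous thin-walled sphere: E = (3R/4t)(V/φ + P) with R = (3V/4π)^⅓,
evaluated in mmHg and converted at 1 mmHg = 0.133322 kPa. Central corneal
thickness stands in for shell thickness; strains without thickness data are
dropped from the modulus analysis only. Method agreement uses Bland–Altman
(bias, ±1.96 SD limits, trend slope of difference on pair mean), and
phenotype correlations use Pearson r with two-sided p.

## Interval mapping (linkage)

Expected D-allele dosage is computed on a 1 cM pseudomarker grid (union
with the typed markers, where dosage equals the call exactly) by
conditioning on the nearest typed flanking markers through the two-interval
two-state chain with RI-expanded Haldane recombination fractions; single
flanks apply at chromosome ends and around missing data, and a strain
untyped on a whole chromosome gets dosage 0.5 there. No multi-marker HMM is
used — RI panels are near-fully typed.

At each position, strain means (equally weighted) are regressed on dosage;
LRS = n·ln(RSS₀/RSS₁), LOD = LRS/(2·ln 10), the additive effect is the
regression slope (positive = D allele increases the trait; the
half-difference convention is reported alongside), and variance explained
is 1 − RSS₁/RSS₀. Zero-variance positions record LRS 0 with a flag.
Thresholds come from permuting phenotype values across strains (default
2000 permutations), taking the genome-wide maximum LRS each time, and
reading the 95th (significant, genome-wide p < 0.05) and 37th (suggestive,
p < 0.63) percentiles. Peaks are greedy local maxima above the suggestive
threshold; support extends to a 1.5-LOD-equivalent LRS drop, snaps outward
to the nearest typed markers, and the candidate window widens those bounds
by 1 Mb per side (the mapping precision of BXD-density genotyping).
Reported peak variance explained is not corrected for the upward bias
introduced by resampling RI strains (winner's curse); users should read it
as an upper estimate.

Calibration: under a null phenotype the genome-wide rejection rate at the
permutation significant threshold is 0.05 within binomial error (verified
over 500 replicate scans). On this mouse-scale map the thresholds land near
LRS 11 (suggestive) and 17–19 (significant), matching values conventional
for BXD scans. A consequence worth stating: a QTL explaining 37% of
strain-mean variance in a 20-strain panel has expected peak
LRS ≈ −20·ln(0.63) ≈ 9.2, below the suggestive threshold, so its detection
probability is near 50%, not near certainty — single-study hits at this
effect size carry substantial luck, and their reported effect sizes are
inflated by the conditioning.

## What the synthetic tests do and do not show

The generator reproduces the statistical structure the estimators assume:
the exact compliance law, homogeneous Gaussian sensor noise, perfectly
known step timing, a calibrated-out system compliance, Markov RI genomes
and a single additive QTL. Passing tests therefore demonstrate correctness
of the estimators and pipeline plumbing under those assumptions, and the
creep experiments demonstrate the directional VF/SR split that
viscoelasticity produces. They do not certify behaviour under cannulation
leaks, flow spikes, corneal hydration drift, non-Gaussian sensor artefacts,
genotyping error, or polygenic architectures — none of which are modelled.

## Problem sizes and numerics

Default analysis sizes were chosen so the whole suite runs comfortably on a
single CPU: the end-to-end recovery study uses 20 strains × 8 eyes (the
target sampling depth of the emulated experiment), permutation calibration
uses 500 replicates × 500 permutations, and power experiments use 100
replicate panels. ODE tolerances are 1e-8; nonlinear fits run to
xtol/ftol 1e-12 or tighter; trapezoidal quadrature at 2 Hz sampling leaves
volume-conservation errors below 0.1%. Degenerate inputs (single pressure
level, tiny ΔP, zero dosage variance, single-strain panels, constant
phenotypes) raise or flag rather than returning silent numbers.
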