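# Methods

This note documents the statistical procedures, the synthetic-data models
behind the tests, the defaults and the numerical choices, in the package's
own terms.

## Spectral-count differential abundance

The model treats a protein's pooled spectrum counts in two conditions as a
two-cell table. After a pseudocount of 1 per cell (so proteins absent from
a run remain testable and log-ratios are always finite) each run is scaled
to the mean adjusted total; with a balanced 2×2 design this makes the two
condition totals equal, and the G-test expecteds reduce to the mean of the
two pooled values. The two-cell statistic

G = 2[o_t ln(o_t/ê_t) + o_c ln(o_c/ê_c)]

is exactly the likelihood-ratio statistic of the conditional binomial
model (the protein's total split between conditions against the fixed
proportion N_t/(N_t+N_c)); the test suite verifies this identity against
an independent binomial log-pmf evaluation, and χ²(1) upper tails against
`erfc(√(G/2))`. No continuity correction is applied.

Selection combines three conditions conjunctively: χ²(1) p < 0.05, a
false-discovery criterion, and replicate consistency. The FDR criterion is
implemented in two modes. The default, `literal`, applies the per-protein
inequality p_j ≤ q·j/t with t the number of identified proteins and ties
in p broken lexicographically by protein id for reproducibility. The
`step_up` mode is the standard Benjamini–Hochberg procedure (delegated to
statsmodels); it dominates the literal rule, so literal calls are always a
subset — a relation asserted per-seed in the tests. Replicate consistency
defaults to the strictest reading: every treatment replicate strictly
above (UP) or below (DOWN) every control replicate, ties failing; a
pooled-comparison mode is available, and with one run per side (the
within-condition null estimate) consistency degenerates to a sign check.

## Operon refinement

Discretization maps (expression − base) differences to levels with
half-open bins [k−0.5, k+0.5) → k on the positive side, saturating at ±4.
The zero bin is [−0.5, 0.5) — closed on the left, so −0.5 maps to 0 — and
the remaining negative bins mirror the positive ones with the closure
reversed, e.g. (−2.5, −1.5] → −2. Mirror symmetry level(−d) = −level(d)
therefore holds everywhere except on bin edges, where the stated closures
decide.

The frequency tables f_op and f_bp are relative (per-class) distributions
of the microarray score X over the confident pairs only, so class
imbalance does not bias the log-odds. Additive smoothing α = 0.5 over the
full support 0..n_arrays keeps both densities positive; without it a
never-observed X would make ln(f_bp/f_op) undefined. "Same expression
level" is implemented as the global count of arrays with equal discretized
levels across all provided arrays.

Only ambiguous pairs (scores in [1.5, 5]) are adjusted; pairs whose genes
lack expression data keep raw scores and raw calls. The final call
threshold τ is not part of the original scoring scheme, which only
reports resulting unit counts; the package exposes it as a parameter with
default 3.25, the midpoint of the ambiguous band, and requires it to lie
inside (1.5, 5) so confident pairs can never be re-called. Transcription
units are maximal chains of operon-pair calls, giving the identity
#TUs = #genes − #operon-pair calls, asserted on every instance.

## Correlation grid

Cells are squared Pearson correlations of log2 ratios (Spearman optional).
With fewer than 3 pairs or a constant variable the cell is reported as
undefined (None/missing), never 0. Fold filters apply to the side named by
the cell label; direction-3 cells filter both sides, making them symmetric
by construction. The packaged 61-record worked example ships inside the
package with a SHA-256 integrity check; its computed R² values are
whatever the printed one-decimal ratios give.

## Metabolite response

Responses are peak_area / internal_standard_area / sample_mass; the
internal standard and mass are per-sample quantities, so the response is
invariant to any whole-sample rescaling (recovery, derivatization,
injection volume). Ratios and t-tests are computed on these responses —
equivalent up to a constant factor to concentrations per gram, which
cancels in both the ratio and the test. The default test is the classical
equal-variance two-sample Student t (two-sided); with duplicate cultures
per condition it has exactly 2 degrees of freedom. Welch's variant is
behind a flag and never silently substituted. No multiplicity correction
is applied across metabolites, matching standard practice for these small
panels.

## Synthetic-data generators

All generators are pure functions of a `SimulationConfig` (seed included);
repeated calls are identical, asserted in tests.

**Spectral counts.** 1,000 proteins, 2 conditions × 2 replicate runs,
expected 25,000 total spectra per run — a typical multidimensional-LC
shotgun depth. Baseline relative abundances are log-normal (σ = 1.2),
giving the heavy-tailed SpC distribution real experiments show. Counts are
negative-binomial with var = m + φm²; φ = 0.03 was calibrated once so the
within-condition replicate-vs-replicate comparison flags ~1–2% of
proteins, the null-discovery behavior reported for real duplicate
cultures; φ = 0 degenerates to Poisson. Planted effects (5% UP, 5% DOWN at
|log2| = 2 by default) multiply treatment means. The generator does not
emulate peptide-level identification noise, shared-peptide ambiguity or
run-order effects, so passing recovery tests speaks to the statistics, not
to identification artifacts.

**Expression with operons.** 1,808 genes partitioned into units by a size
distribution with mean ≈ 1.8 genes/unit; 16 arrays of which the first 2
are unstressed baselines. Each unit draws a latent per-array profile
(σ = 1.5, zero on baselines) and gene g observes
μ_g + ρ·L_unit + (1−ρ)·P_g + ε, with private profile P_g, measurement
noise σ = 0.3 and within-operon mixing weight ρ = 0.8. At ρ = 1, σ = 0 all
operon co-members are identical, so X = n_arrays — the degenerate case the
tests pin. Prediction scores are class-conditional: confident draws fall
on the correct side of the 1.5/5 cutoffs; an ambiguous fraction (0.3)
falls in [1.5, 5] with only a mild triangular-density signal, which is
precisely the information gap the expression adjustment can close. Probe
effects and between-study normalization are not modeled.

**Metabolites.** 45 metabolites, 3 time points, duplicate cultures per
condition. Latent per-gram concentrations are log-normal with replicate
CV 0.15; 20% of metabolites are planted at 2-fold changes (alternating
directions). Peak areas fold in sample mass and a per-sample log-normal
recovery factor (σ = 0.2) that also scales the internal-standard area, so
only the internal-standard normalization recovers the planted ratios —
which is what the recovery test demonstrates.

## Problem sizes and tolerances

Simulation-based checks run 20 seeds at the default scales above (the
acceptance script derives child seeds from a single command-line seed and
keeps them below 2³¹). Exact identities (G-test vs oracle) are asserted at
1e-9; run-total conservation at 1e-9 relative; parameter-recovery
assertions use sampling-error-sized tolerances stated in each test.
Degenerate inputs (empty tables, missing internal standards, non-finite
expression values, non-consecutive gene pairs, τ outside the ambiguous
band) raise named errors rather than propagating NaNs.

## Known limitations

The literal FDR inequality is not a formal step-up procedure; it is
deliberately the more conservative reading and the default. The two-cell
G-test assumes count sampling close to multinomial — under strong
overdispersion it is anti-conservative, which is why the generator's
dispersion is anchored to observed replicate-vs-replicate null behavior
rather than chosen freely. The correlation grid treats significance flags
as given inputs and does not model how they were produced. TSV outputs
spell the non-differential status as the literal string "NULL"; when
reading them back with pandas, pass `keep_default_na=False`.
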