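# Methods

## Complex identification from co-fractionation

### Model

A stable stoichiometric complex behaves as a single species on a column:
its subunits share one elution profile per chromatographic step, up to
measurement noise. Unrelated proteins elute according to their own
physicochemistry, so their profiles match the bait's only by chance, and
the chance of matching in *every* one of several orthogonal steps decays
quickly. The pipeline therefore scores each protein by the Pearson
correlation (PCC) of its concatenated ("stitched") per-step Z-profiles
against the bait's.

Z-scoring is done **per protein per step**, across that step's fractions,
and stitching concatenates the per-step Z-arrays; the concatenation is
*not* re-standardized. This keeps each step's shape information on a
common scale regardless of how much material entered the step, and makes
the stitched profile invariant to per-step abundance changes (material is
lost exponentially across a multi-step purification).

Sample (n−1) standard deviations are used throughout — for replicate SDs
and inside the Z-score. The choice is a convention; with triplicates the
difference from the population form is a constant factor that cancels in
the correlation.

### Missing data

DIA quantification is bounded by the ion library (IL): a protein absent
from a step's IL *cannot* be quantified there, which is censoring, not
absence. The rules are:

* a protein with no quantified value anywhere in a step has no profile
  for that step, and is excluded from stitching (reported separately);
* a protein quantified in a step but missing in some fractions is below
  detection there; those fractions count as 0 before Z-scoring;
* missing cells are never imputed at the I/O layer — downstream stages
  decide.

The bait missing any step is an error rather than an exclusion: nothing
can be ranked against a bait that was not followed through every column.

### Partner detection

Ranked by PCC, the unrelated bulk of the proteome traces a smooth curve
(it is a sorted sample, i.e. an empirical quantile curve). The decision
stage fits a degree-5 polynomial to the bottom of the rank–PCC curve —
first excluding the bait and the rank-2 candidate, then iterating the
exclusion set to a fixed point as candidates are flagged — and
extrapolates it over the excluded top ranks. A candidate is flagged while

1. its residual above the extrapolated trend exceeds `c × RMSE` of the
   fitted points (`c = 3`), **and**
2. its PCC is at least `min_pcc = 0.9`.

The second condition is load-bearing, and worth explaining. Residuals of
a fitted *sorted* curve are tiny and strongly autocorrelated, so the fit
RMSE severely understates how far the top order statistic of unrelated
proteins can sit above the curve: in simulation, the best unrelated
protein clears 3×RMSE in roughly half of all runs. No residual-only band
fixes this, because the distributions of "best chance co-elution" and
"true partner" overlap in residual terms while remaining separated in
absolute correlation: subunits of a stable complex track each other at
PCC ≳ 0.95 across a full multi-step purification, whereas the best chance
match across five orthogonal steps rarely exceeds ~0.8. A minimum
correlation of 0.9 — the conventional co-elution cutoff for stable
complexes — therefore gates the residual test. Both thresholds are
parameters; `min_pcc=None` recovers the pure residual rule. Lowering `c`
can only grow the flagged set.

The trend is fit on PCC versus rank index (the x-axis of the sorted
curve). With `N` proteins and one candidate under test, the fit uses the
bottom `N − 2` points.

### Absolute semi-quantification

DIA areas are relative; mass is assigned through a calibration series of
known amounts of the purified recombinant bait, fit as a straight line in
log10(signal)–log10(mass). The log–log form is the natural choice for a
tenfold dilution series spanning up to eight decades; the instrument
response is a power law over its dynamic range. Replicate signals are
averaged per calibrant mass before fitting. Points outside the power-law
regime are handled by rule: non-positive signals are below detection and
dropped; top-of-range points whose (averaged) signal does not exceed the
next-lower calibrant's are saturated and trimmed. Unknowns are read off
by inverse prediction, with an interval from mapping ±1 residual SD (in
log signal) through the inverse; predictions outside the calibrated
signal range carry an extrapolation flag.

Purification bookkeeping uses mass fractions: purity % = 100·bait/total,
fold enrichment = stage mass fraction over the starting material's. Bait
masses are carried in pg, totals in µg.

## Copy-number pipeline

### Normalization

Input tracks are binned coverage (bedGraph). Both sample and diploid
reference are CPM-scaled (value·10⁶/Σ(value·width)), re-binned to a
common grid (default 5 kb) by width-weighted mean, and divided
bin-by-bin; bins with zero reference coverage are undefined and dropped.
The ratio track is rescaled so its mean over unmasked (euchromatic) bins
is 1, making ⟨CN⟩ a copy number relative to the fully endoreplicated
genome. Pericentric/sub-telomeric regions enter as a BED mask and are
excluded from all means; the reported coordinates in domain tables are
1-based inclusive (internally everything is 0-based half-open).

### UR domain calling

Per chromosome arm: bins strictly below the arm mean (computed over
unmasked bins) are marked; consecutive marked bins are merged, tolerating
up to `gap_tol = 1` intervening above-mean bins; merged runs spanning at
least `min_length = 100 kb` and clear of the mask are reported. Because
gap-tolerant merging lets shallow noise bins adjacent to a deep run chain
onto it, run edges are refined: edge bins above the midpoint between the
arm mean and the run's below-mean core are trimmed. On planted 150 kb
dips at depth 0.5 with per-bin noise SD 0.05, boundaries land within one
bin of truth. Strict inequalities are used both for "below the mean" and
for the suppression call below; an arm shorter than `min_length`
produces no calls and a warning.

### Recovery and suppression

`recovery(c, m) = 100·(m − c)/(1 − c)` is affine in the mutant copy
number: 0 when the mutant equals the control, 100 at full restoration,
negative when the mutant deepens the deficit, above 100 on overshoot. It
is undefined when the control shows no deficit (c ≥ 1).

Per-domain mutant p-values are the arithmetic mean of supplied per-bin
p-values. A domain's UR is *suppressed* by a mutant when that mean is
strictly below α = 0.01 **and** the recovery is positive — a mutant that
deepens underreplication has not suppressed it, however significant the
change. Summaries follow the length-adjusted convention: ⟨CN⟩ and
⟨Recovery⟩ are length-weighted means (Σ L·x / Σ L) with equally weighted
SDs; domain length itself is averaged unweighted. Splitting a domain into
contiguous halves with the same per-bp values leaves all weighted
summaries unchanged.

Per-bin differential p-values are an **input channel**: the intended
source is a count-based differential-coverage model run upstream. The
packaged `perbin_test` (Welch t on log bin values across replicates) is a
clearly labeled stand-in with approximately nominal type-I error, not a
re-implementation of such a model.

### qPCR ΔΔCt

`⟨ΔΔCt⟩ = (⟨Ct_t⟩ − ⟨Ct_ctrl⟩)_sample − (⟨Ct_t⟩ − ⟨Ct_ctrl⟩)_diploid`,
copy number `2^−⟨ΔΔCt⟩`, and
`σ_ΔΔCt = sqrt((σ²_target + σ²_control)/2)` over the sample group's
replicates, with CI `[2^(−⟨ΔΔCt⟩−σ), 2^(−⟨ΔΔCt⟩+σ)]`. Note the σ
propagation *averages* the two variances instead of summing them and
ignores the diploid group's spread; this is not the orthodox
error-propagation formula, but it is the protocol's stated rule and is
implemented verbatim — fidelity over orthodoxy. Treat the CI as the
protocol defines it, not as a calibrated frequentist interval.

## Colocalization

Two equal-shape intensity images are Z-normalized per channel over all
pixels and compared by squared Pearson correlation, overall and after
exclusion rules remove channel-exclusive lobes of the (Z_a, Z_b) scatter.
Each rule is a conjunction of threshold inequalities on the two Z values;
the defaults exclude (Z_b > 1, Z_a < 3) and (Z_b < 1, Z_a > 3). Since
Pearson r is affine-invariant, r² on Z equals r² on raw intensities. No
registration, background subtraction or segmentation is attempted.

## Synthetic data

The generators are pure functions of (spec, seed) and emit the same
TSV/bedGraph formats the readers consume, with ground truth alongside.

**Fractionation** emulates the study conditions: five steps of
20+14+17+16+16 fractions (within the observed 14–20 per-step range,
totalling 83), 138 background proteins plus planted complex members
(140 quantifiable proteins by default), two spike-in references at
constant amount, and triplicate acquisitions. Elution peaks are Gaussian
in fraction index — background proteins draw independent centers/widths
per step, complex members share their complex's (± optional jitter).
Noise is multiplicative lognormal per replicate acquisition (default
σ = 0.2, a 20% CV — MS intensity noise is proportional, not additive),
plus a lognormal per-run injection-drift factor common to all proteins in
the run, which spike normalization must cancel. A detection limit
optionally censors a protein from a step's table, emulating ion-library
censoring.

What this does *not* emulate: systematic co-elution structure among
background proteins (real proteomes contain many complexes, giving a
denser top of the rank–PCC curve than independent backgrounds produce),
peptide-level effects, retention-time drift, or interference. Passing the
partner-recovery test therefore shows the statistical machinery works
under chance co-elution, not that any particular real dataset will
separate as cleanly.

**Copy number** builds flat arms with planted depth-reduced domains;
the diploid reference is flat everywhere; a mutant restores
`recovery/100` of each domain's deficit
(`depth_mut = depth + r·(1 − depth)`). Per-bin Gaussian noise (default
SD 0.05) and a per-replicate library-size factor are applied. Real
polytene coverage is autocorrelated along the genome and has
mappability structure; white per-bin noise is a simplification that makes
boundary recovery slightly *harder* than smooth noise would.

**Titration** draws a log–log line with multiplicative signal noise.

## Numerical choices

* Polynomial trend fits use `numpy.polynomial.Polynomial.fit` (domain-
  mapped basis) for conditioning at degree 5; an ill-conditioned fit
  raises with advice to lower the degree.
* Pearson correlations are clipped into [−1, 1]; a zero-variance profile
  has no defined correlation and is ranked last with a warning, never
  silently given 0.
* PCC ties in the ranking are broken by protein id for determinism.
* Peak-fraction selection is exhaustive over all windows up to size k;
  ties keep the earliest window and are flagged.
* Single-replicate cells report SD 0 with a warning rather than erroring.
* All randomness flows through `numpy.random.default_rng(seed)`.

## Problem sizes

Stochastic checks run at the sizes the defaults define: 100 seeded
fractionation datasets per condition (each 140 proteins × 83 fractions ×
3 replicates) for partner-detection operating characteristics; 2 Mb-scale
arms at 5 kb bins for copy-number round trips; 4,000 null bins for the
per-bin test's type-I error.

## Known limitations

* Single-bait design: no all-vs-all complexome inference and no FDR
  across multiple baits.
* The partner rule's `min_pcc = 0.9` default is calibrated for stable
  stoichiometric complexes followed through ≥3 orthogonal steps; weak or
  substoichiometric interactors will sit below it by design.
* The UR caller assumes reasonably uniform bins and a unimodal
  "below the arm mean" criterion; nested or shoulder domains are merged
  or trimmed, not decomposed.
* Excel input is not parsed; quantification tables are consumed as
  delimited text.
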