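# Methods

## Scope and model

`figgkin` evaluates pairwise kinship inference from dense biallelic autosomal
SNP data under two stressors — shrinking marker panels and rising genotyping
error — and provides a linear fusion of four estimators that is robust to the
latter.  Everything is driven by simulation with exact ground truth: founder
haplotypes are synthetic, inheritance is simulated by gamete dropping, and
the true IBD mosaic of every pair is tracked analytically, so detector output
can be scored against truth rather than against another tool.

## Genetic map and founders

A `GeneticMap` is a per-chromosome monotone piecewise-linear bp↔cM table.
Synthetic maps use a constant recombination rate (default 1 cM/Mb), with
chromosome genetic lengths proportional to the sex-averaged human autosome
lengths and rescaled to a requested genome total (default 3346.30 cM for the
full 22-autosome design).  The constant rate makes physical thresholds (Mb)
and genetic thresholds (cM) commensurate, which matters because the segment
detectors mix both unit systems.

Founder haplotypes are drawn site-independently: marker alternate-allele
frequencies come from uniform(0.05, 0.5) (the post-MAF-filter spectrum of the
reference data is not published; uniform above the 0.05 filter is the
agnostic choice), positions are uniform on the genetic map, and alleles are
independent Bernoulli draws per haplotype.  There is deliberately **no
linkage disequilibrium**: the no-LD null makes chance IBS-run statistics
analytically checkable.  Consequences: (i) phasing is exact by construction,
so the phased detector sees idealised input; (ii) the LD-driven
overestimation that redundant ultra-dense panels can cause in real data does
not occur here and is out of scope.

## Pedigree template and simulation

The family template is a fixed 11-founder pedigree: a founding couple with
two full-sib lines of depth four, plus a half-sib line of depth three through
the patriarch's second spouse; each generation marries in one founder.  Its
30 designated pairs realise first- through seventh-degree relationships and
unrelated pairs with counts (3, 5, 6, 4, 4, 3, 2, 3), so the full design —
18 families per replicate from a 208-founder pool, 10 replicates — yields
540/900/1080/720/720/540/360/540 pairs by degree.  Kinship is computed
exactly in rational arithmetic by the standard recursion; degrees follow
θ = 1/2^(d+1).  Inbreeding and twins are excluded (the twin bin exists only
as a classification outcome).

Meioses drop crossovers as a Poisson process (count ~ Poisson(L_cM/100), no
interference, sex-averaged map) with breakpoints uniform in cM.  Ancestry is
carried as piecewise-constant founder-haplotype label tracks; true IBD1/IBD2
intervals for any pair fall out of a four-track label sweep (IBD2 where the
two label pairs match bijectively, IBD1 where exactly one label is shared;
IBD2 is never double-counted as IBD1).

## Error model

Per-genotype errors of three types: drop-in (homozygote → heterozygote),
drop-out (heterozygote → random homozygote), switch (opposite homozygote).
Each genotype is hit independently with the configured rate; the type is
drawn from composition weights restricted to the types applicable to the
genotype class and renormalised (the default composition is uniform over
applicable types; the source simulations specify only a rate, not a mix).
The injector never creates missing calls; the discordance classifier counts
missing-involved sites separately and excludes them from rate denominators.
A phased variant re-phases altered sites arbitrarily, idealising a phaser
that sees the erroneous genotypes.  Error grids share one uniform draw per
genotype across rates (common random numbers), so hit sets are nested in the
rate — a variance-reduction choice that makes monotone degradation trends
testable without replication.

## Estimators

**Method of moments.** θ = (N_het,het − 2·N_opp)/(N_het^a + N_het^b) over
sites non-missing in both individuals — the homogeneous-population IBS-count
form (the simulation is a single panmictic population).  It can be negative;
it is undefined when neither individual has a heterozygous site.

**IBD-run detector (phase-free).** Maximal runs free of opposite
homozygotes, emitted as IBD1 iff ≥ 2 cM *and* ≥ 186 markers.
Identical-genotype sub-runs meeting the same thresholds are emitted as IBD2
and excluded from IBD1 — this is on by default because a full sib's
θ = κ2/2 + κ1/4 is structurally underestimated (≈ 0.19 instead of 0.25) if
diploid matches are folded into IBD1.  θ adds the supplemental constant
0.00138, which also bounds it away from zero (used by the fusion ratios).

**Probability-thresholded detector (phase-free).** IBD1 candidates are
opposite-homozygote-free runs, IBD2 candidates identical-genotype runs; a
candidate is emitted iff its chance-compatibility probability under
Hardy–Weinberg — per-site 1 − 2p²q² (IBD1) and p⁴ + (2pq)² + q⁴ (IBD2),
multiplied across the run — is below 10⁻⁸ *and* its physical span reaches
5 Mb (IBD1) / 2 Mb (IBD2).  An error-tolerance knob bridges isolated
incompatible sites at ≤ 1 per 100 markers (the original tool's built-in
error model is unpublished; a density cap is the minimal analogue).  IBD2
intervals are subtracted from IBD1 without re-thresholding the pieces.

**Haplotype-match detector (phased).** All four cross-individual haplotype
pairings are scanned for maximal exact-match runs; a run is reported iff it
contains at least one fully matching word of a fixed aligned 64-marker grid
(the hash-seed condition) and spans ≥ 3 cM.  Intervals where both haplotypes
pair off are IBD2; single-pairing coverage is IBD1.  The word seed doubles
as the chance-match filter: at MAF ≥ 0.05 a 64-marker spurious seed has
probability < 10⁻¹², so unrelated pairs essentially never yield segments.

All three detectors are verified against independent brute-force reference
scanners on randomized instances (planted shared stretches, missing data,
randomized thresholds).

### Threshold scaling and the desk-scale study conditions

The marker-count and probability thresholds (186 markers, 10⁻⁸, 64-marker
words) are the detectors' *density-invariant* false-positive control, so
they are never rescaled.  What must be preserved when scaling the experiment
down is the **marker density**: the full design's minimum adequate panel is
164 K SNPs over 3346.30 cM ≈ 49 markers/cM.  The desk-scale defaults
therefore place 20 K markers on a 400 cM scaled 22-autosome genome
(50 markers/cM), reproducing the adequate-density regime at ~1/8 of the
compute.  Panel-ladder experiments then hold the tool settings fixed while
the panel shrinks — exactly the design that produces the characteristic
sharp degradation of segment-based methods on small panels, because the
fixed marker-count thresholds translate into ever-longer effective minimum
segment lengths.

A known consequence of the scaled genome: the between-pair variance of
*true* pedigree kinship grows as 1/L(genome), √8.4-fold here.  Second-degree
pairs then overlap the neighbouring threshold intervals often enough that
even a perfect estimator caps second-degree sensitivity near 0.91 on the
desk cohort (first degree still reaches 0.98).  This is a property of the
scaled conditions, not of the estimators; per-degree mean θ remains
unbiased within Monte-Carlo error for degrees 1–4 for all four methods.

## Classification and metrics

Degree bins are left-closed intervals at the geometric midpoints
1/2^((2k+3)/2) between consecutive expected θ values; anything below
1/2^(17/2), including negative estimates, is unrelated.  Reference ranges
are per-class min–max of θ on the reference condition (a quantile option
exists); the min–max choice reproduces the observed zero lower bounds of
segment-based estimators for distant classes.  Sensitivity, PPV, accuracy
and the overlapping rate are computed from the confusion matrix; undefined
estimates count against sensitivity and accuracy but never enter an
inferred class (so PPV denominators exclude them).

## Combination model

Features: the four θ values, six differences, three ratios with the
IBD-run θ as denominator (13 in all).  Training pools all error levels
{0, 0.1, 0.5, 1, 5, 10}% with the error-free expected kinship coefficient as
the target throughout — the only reading under which a single model serves
every error level.  Selection is bidirectional stepwise by the
small-sample-corrected information criterion (AICc; the original procedure
names only "stepwise"), refit on all data, with a seeded 10-fold CV R²
reported alongside.  Fit on error-free data alone the model reproduces the
expected θ at R² ≈ 1; fit on the pooled ladder its in-sample R² drops to
≈ 0.78 because features at 5–10% error carry little information about the
error-free target — the pooled model trades zero-error sharpness for the
flat accuracy profile across error rates that makes it useful.  The
published models M1–M7 are bundled as constants and never overwritten by
refitting.

## Numerical choices and degenerate inputs

Segment endpoints sit on marker positions; single-marker pieces (zero
genetic length) are dropped.  κ conversions clip (with a warning) if summed
segment lengths exceed the genome length.  Run probability products are
accumulated in log10.  Missing genotypes are neutral inside runs: they never
break a run and contribute no probability evidence.  All randomness flows
from `numpy.random.SeedSequence` spawns of a single seed; equal configs give
byte-identical outputs.

## Limitations

* No LD, no population structure, uniform recombination rate: absolute
  accuracies are not comparable to runs on real reference panels, and
  LD-driven effects (pruning recommendations, ultra-dense-panel
  overestimation) are out of scope.
* Statistical phasing is not modelled; the phased detector sees truth-phased
  (or idealised re-phased) haplotypes, so its real-world sensitivity to
  phasing error is understated.
* The scaled desk genome inflates pedigree-sampling variance (see above).
* The bundled M1–M7 coefficients were estimated on real reference data;
  refits on synthetic cohorts reproduce their structure and magnitude, not
  their exact values.
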