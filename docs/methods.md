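# Methods

This note documents the models and numerical choices behind each stage,
what the synthetic-data generator does and does not emulate, and the
design decisions taken where the design was genuinely open.

## Phenotype model

Seedling damage is recorded daily on the 1–9 SES scale and summarised as
the trapezoid-rule area under the damage curve (AUC, score·days).  A
constant score *s* over *n* days gives `s·(n−1)·Δt`; the 5-day screen
ceiling is therefore 36 and an 8-day screen's is 63.  AUCs from screens
of different lengths are never compared on the raw scale; all comparisons
are within one experiment.  Cross-population line means average
replicates within each BPH population first and then weight populations
equally, regardless of replicate counts.  The scoring start rule (days
after infestation, death of the susceptible check) is assay metadata; the
package takes the score series as given.

Extreme-pool selection takes the lowest-AUC lines as the resistant pool
and the highest as the susceptible pool, with boundary ties broken by
ascending line id so membership is deterministic and order-invariant.

## Synthetic BIL population

Each line descends from its own F₁ plant through `n_backcrosses`
backcrosses to the recurrent parent and `n_selfings` selfing generations
(defaults 3 and 4: a BC₃F₅).  Meioses follow a no-interference model — a
Poisson number of crossovers per chromosome (default 1.5) placed
uniformly — because no genetic map is assumed.  Markers sit on a regular
grid (default 25 kb); planted QTL positions are simulated as extra loci
so their dosage is exact rather than interpolated.

**Selection during backcrossing.**  By default
(`select_resistant_backcross=True`) the gamete transmitted at each
backcross must carry the donor allele at every planted QTL, emulating the
phenotypic selection of resistant plants in each backcross generation of
the breeding scheme this design mirrors.  Selfing generations are
unselected, so QTLs segregate ≈1:1 among finished lines while unlinked
background remains at the unselected expectation `(1/2)^(b+1)` (1/16 for
BC₃).  Without this selection a rare donor allele (expected in ~6 of 105
lines) gives the bulked-segregant scan little power and drift peaks can
dominate; with it, the resistant pool approaches fixation for the donor
allele at the QTL, matching the near-100% SNP-indexes a real scan of this
design shows.  The `(1/2)^(b+1)` donor-fraction property is asserted with
selection off, which is the condition under which it is derived.  An
optional `retained_intervals` list additionally enforces marker-assisted
foreground retention (off by default).

**Default architecture.**  Two QTLs of 10 and 8 score·days on two
separate 30-Mb chromosomes (positions 6.78 and 16.22 Mb).  Placing both
on one chromosome is equally supported, but whole-chromosome linkage
then merges them into a single called region, which makes per-QTL
localization ill-posed in the recovery suite.

**Phenotypes.**  A line's genetic AUC is
`baseline − Σ effect·(dosage/2)` (baseline 34 by default, near the
susceptible parent).  Daily scores are reconstructed as a linear damage
ramp symmetric about its mean — any such ramp has trapezoid AUC exactly
`mean·(n−1)` — with the slope capped to stay on the 1–9 scale, then
perturbed with N(0, `noise_sd`) noise (default SD 1) and clamped to
[1, 9].  With zero noise the AUC gap between an all-donor and a no-donor
line equals the summed QTL effects exactly.

**Pooled sequencing.**  Per site and pool, depth ~ Poisson(`mean_depth`,
default 20× — comfortably above a 6× analysis floor) and donor reads ~
Binomial(depth, pool donor-allele frequency).  A Poisson rather than
negative-binomial depth model keeps the null simulation and the generator
aligned; overdispersed depth mainly widens the depth distribution across
sites, which the depth-stratified thresholds absorb.

**Mutant population.**  Per-line mutation counts are Poisson (default
9.6/line, a rate reported for a comparable fast-neutron rice population),
positions uniform, and types multinomial with the 56/23/21%
SBS/deletion/insertion spectrum.

**What the generator does not emulate** — and hence what green tests do
not certify about real data: read-level artifacts (mapping error, allele
bias, duplicate reads), restriction-site dropout of ddRAD libraries,
shared pedigree between lines (each line's lineage is independent),
epistasis, and genotype–environment interaction beyond a per-population
effect multiplier.

## QTL-seq scan

SNP-index is the donor read fraction; zero-depth sites are masked (NaN),
never zero, and masks propagate to ΔSNP and window means.  The delta is
stored as `|SI_S − SI_R|` only; no signed version exists.  Windows are
anchored at position 1, advanced by `step` (default 10 kb), with
half-open bp membership `[start, start+window)`; a terminal window is
truncated at the chromosome end.  Windows with fewer than `min_snps`
(default 3) informative sites are reported but masked.  Window counts are
convention-dependent and are never asserted against any external total.

**Null model.**  Under no QTL, each pool's member genotypes are resampled
from the population's expected genotype frequencies — by default
estimated from the data as the genome-wide donor read fraction with an
inbred heterozygosity `2p(1−p)(1−F)`, `F = 1 − (1/2)⁴` — then reads are
drawn binomially at the observed depths.  Two summaries are produced:

* *Per-site thresholds* (`null_thresholds`), stratified by depth in 5×
  bins up to 100×, made monotone non-increasing in depth by a running
  minimum from deep to shallow.  These correspond to the per-position
  confidence bands drawn on scan plots.
* *Window thresholds* (`window_null_quantiles`).  The pools hold the same
  individuals at every site, so the genotype-sampling component of ΔSNP
  is shared across linked sites rather than averaging away with window
  size.  Each null draw therefore resamples the pool frequencies once
  per chromosome and draws read noise per site; quantiles of the
  resulting null window means calibrate window significance.  This
  assumes complete linkage within a window, which is exact for tightly
  linked windows and conservative where recombination decorrelates sites
  within the window span.

**Discrete-null thresholds.**  At moderate depth the null |ΔSNP| is
discrete (a pool-frequency lattice times binomial read counts) and a
plain empirical quantile can land on either side of a probability atom,
flipping the realized test size between ~2% and ~10% across simulation
seeds.  Following exact-test practice, the threshold is the atom whose
achievable strict-exceedance size is closest to the nominal level
(`null_quantile`), and significance is strict exceedance.  At depth 20
with pools of 19 and 16 this realizes a 5.0% size, stable across seeds.

QTL calls merge maximal runs of overlapping significant windows and
report the peak (maximum mean-ΔSNP) window.  The model-style entry point
is `QtlSeqScan(records, chrom_lengths, pool_sizes).fit(...)`, returning a
`QtlSeqScanResult` with the per-site records, the window table, the
calls, and a `summary()`.

## Variant ingestion and effect annotation

VCF 4.x with per-sample AD is read via pysam; multiallelic records are
skipped with a warning by default (the analysis is strictly biallelic) or
split on request.  Filters retain sites with site quality ≥ 15, base
quality ≥ 20 and total depth ≥ 6 in every pool used downstream; removal
counts are logged.

Gene models carry ordered CDS segments (1-based inclusive, 5′→3′ in
coding order) and the spliced CDS.  CDS length must be a codon multiple;
a missing start codon warns but does not error.  The CDS coordinate of a
genomic position accumulates segment offsets in coding order (counted
from the 3′-most genomic boundary on the minus strand).  Substitutions
are translated codon-wise with the standard genetic code; indels with a
net length change divisible by 3 are in-frame (reporting residues
gained/lost), others frameshift.  Conventions: amino-acid position
`ceil(cds_pos/3)`; protein length `cds_length/3 − 1` (stop excluded) —
the only convention consistent with the published coordinate pairs this
package reproduces (e.g. CDS 1527 → protein 508).  Several published
rows whose printed CDS length conflicts with their own printed protein
length (a different transcript isoform) are excluded from the fixture of
asserted coordinate pairs; the package requires an explicit gene model
and never guesses isoforms.

## Haplotype patterns, DRR, painting

HP1 is reserved for the wild-type line's exact vector; remaining patterns
are numbered by descending count of fully-genotyped member lines with
lexicographic tie-breaks, so numbering is deterministic (the published
ordering beyond HP1 is not stated).  Heterozygous calls are a distinct
allele state.  A line with missing calls is assigned only if its
non-missing alleles match exactly one existing pattern; otherwise it
stays unassigned.  DRR divides a pattern's mean AUC by the wild-type
pattern's mean within the same BPH population, reported to 3 decimals;
cross-population ratios are never computed.

Introgression painting classifies each parent-informative marker as
donor / recipient / heterozygous / unknown, merges runs into segments
with boundaries at inter-marker midpoints, and reports per-line donor
spans.  Markers monomorphic between the parents are excluded with a
warning; het segments count half in the painted donor fraction.

## Association

One-way ANOVA across genotype classes; for two classes this equals
simple linear regression on allele dosage (F = t², identical R²).  PVE is
`100·SSB/SST`.  Stars follow * P < 0.05, ** P < 0.001; raw P values are
reported with no correction by default, Benjamini–Hochberg behind a flag.
HP-level association runs the ANOVA across patterns, then compares each
non-WT pattern with the WT by pooled-variance t test, attaching a DRR
where P < 0.05; degenerate zero-variance groups are declared separated
(P = 0) when their means differ.  Tukey HSD letters use statsmodels'
pairwise tests with an insert-and-absorb compact letter display; with
zero pooled variance, unequal-mean groups are all distinct.  Resistance
classes are check-anchored: sharing a letter with the resistant check and
none with the susceptible check is R, the converse S, anything else MR;
if the checks share a letter the assay lacks resolution and
classification is refused.  The R/MR/S rule is a package definition — the
published tables show classes and letters side by side without stating a
cutoff.

## LD and Gabriel blocks

Locus filters: MAF > 0.05 and call rate > 0.50; the Hardy–Weinberg filter
is disabled, as appropriate for inbred lines.  Homozygote pairs and
single heterozygotes contribute phase-known haplotypes directly; only
double heterozygotes are EM-phased (the EM reduces exactly to direct
counting when none exist).  D′ confidence intervals come from a
likelihood profile over a 101-point D′ grid with allele frequencies held
at their estimates; the CI is the 5th–95th percentile of the normalized
profile.  Gabriel calling uses the published defaults: strong LD when the
CI is [≥0.70, ≥0.98], strong recombination when the upper bound is
< 0.90, a block when ≥95% of informative pairs in a span are strong LD,
with maximal non-overlapping blocks taken greedily longest-first.  Pairs
are reported unpruned; any r² significance screen is left to the caller.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is bit-reproducible.
The test and acceptance suites run at desk scale: the recovery suite uses
20 replicate experiments of the default design (105 lines, 2 × 30 Mb,
2,400 sites, 800 null draws per window scan); null calibration uses
10,000 threshold and 10,000 fresh draws per-site, and 400 disjoint
fully-linked windows genome-wide; the annotation oracle fuzzes 1,000
genes; ANOVA calibration uses 2,000 null replicates at n = 95.  These
sizes were chosen to put Monte-Carlo standard errors well inside the
asserted tolerance bands.

## Known limitations

The window null assumes complete within-window linkage, making window
thresholds conservative where internal recombination is appreciable.
Null genotype frequencies are a single genome-wide estimate; regions
whose allele frequency deviates strongly (e.g. under linkage drag around
selected QTLs) are tested against that global null.  HP mining does not
impute missing genotypes or phase heterozygous vectors (the lines are
inbred).  The LD module is biallelic-only and implements the
confidence-interval block rule, not four-gamete or solid-spine rules.
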