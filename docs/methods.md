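# Methods

This note documents the models and procedures implemented in
`lesionseg`, the assumptions behind the synthetic-cohort simulator, the
numerical choices made where the design was genuinely open, and what
the validation suite does and does not demonstrate about real data.

## Coordinate and orientation conventions

All internal coordinates are 0-based half-open; VCF-style 1-based
tables are converted at the reader boundary.  Autosomes are diploid
and an `X`/`chrX` chromosome haploid for composition and rate
calculations.  "From X" always refers to the base X on the
lesion-containing strand: calls and compositions from reverse-lesion
segments are reverse complemented before any tally.  For replication
analyses, strand bias (RSB) re-orients fork directionality so the
lesion strand is the reverse strand; RSB > 0 then always means
lagging-strand synthesis over the lesion-containing template.

## Lesion-strand phasing

Informative mutations are substitutions from T (reference T or A on
the forward strand) with VAF > 10%, the filter that removes calls from
contaminating non-clonal cells.  Their strand-of-origin labels form a
Bernoulli sequence per chromosome, segmented by recursive binary
segmentation: a split is accepted when twice the log-likelihood gain
exceeds a stiff BIC-style penalty (4·log n; genuine strand switches
carry gains in the hundreds), with a minimum of 50 informative
mutations per segment (configurable; the source analyses do not state
their minimum).  Segment boundaries are placed midway between the
flanking informative mutations and extended to chromosome ends, so
classified plus unresolved segments always tile the genome.  Segment
classes use the strict thresholds S > 0.33 (forward) and S < −0.33
(reverse); a score exactly at the threshold stays unresolved.  A
tumour is symmetric when more than 99% of autosomal mutations lie in
segments with |S| < 0.2.

## Rates, spectra and multiallelism

Spectra are 192-vectors (12 substitution types × 16 flank
combinations).  The aggregate rate collapses to 64 trinucleotide
contexts and reports the weighted mean of per-context rates, weights
being the trinucleotide fractions of a reference composition (the
whole supplied genome by default).  Mutations in a context with zero
composition are rejected as inconsistent input.  The multiallelic rate
treats an allele as supported by ≥ 2 qualifying reads (inputs carry
already quality-filtered allele depths; the ≥ Q20 rule lives in the
simulator/reader); sites with fewer than two supported alleles leave
the denominator, and context weights are renormalised over occupied
contexts, so empty contexts contribute nothing rather than zero.
Subtracted spectra are rescaled so the absolute residual area is 100.
Bootstrap CIs resample analysed intervals with replacement within
tumour; 100 replicates, percentile 95% bounds, seeded.

A tiled `CompositionIndex` serves exact segment compositions from
precomputed 200 kb tile counts with directly scanned partial edges;
it is bit-identical to the direct computation and removes the
dominant cost of per-tumour phased-space compositions.

## Replication strand

Timing tracks are tags-per-million normalised, smoothed over five
10 kb windows (a 50 kb centred span, truncated at chromosome ends)
and combined as (E − L)/(E + L).  Timing-derived fork directionality
is the central difference (rt[i+1] − rt[i−1])/2; Okazaki-based RFD is
(R − F)/(R + F) on the same grid.  Both are ranked into 21 quantile
bins (stable ties, so binning is monotone); downstream analyses use
Okazaki bins only where they differ from the timing bins by fewer
than four bins (19% of the category range).  Whether "four bins" is a
strict or inclusive bound is ambiguous in prose; the strict reading
is the default and the bound is configurable.  Forward-strand lesions
under a rightward fork (and reverse-strand lesions under a leftward
fork) are lagging-strand templates.

The window regression partitions the genome into 10 kb windows and,
separately for forward- and reverse-lesion space, models the
aggregate per-window mutation rate on: expressed template-strand
fraction, expressed non-template fraction, residual genic fraction,
and replication time and RSB rescaled to [0, 1] via f = 1 − (1 − r)/2.
Fitting is ordinary least squares (statsmodels); rank-deficient
designs are rejected with the collinear columns named.

## Transcription and TCR

Nascent expression is intronic reads per kilobase of analysed intron,
normalised to TPM within each library and averaged over libraries.
Overlapping genes are excluded hierarchically from the most expressed
down.  Expression strata come from a grid-search piecewise-linear
least-squares fit (flat – sloped – flat, continuous) of per-gene
mutation rate against log nascent TPM: 50 log-spaced candidates per
breakpoint, deterministic; zero-TPM genes enter the fit at a
pseudo-floor of min(positive)/10 but stratum rules apply to raw TPM.
Stratum 1 is below the lower breakpoint, stratum 6 above the upper,
and strata 2–5 are quantile quartiles of the mid-range.  A gene wholly
inside a classified segment is a template-strand-lesion gene when the
lesion strand is its transcription template (plus-strand gene in a
reverse-lesion segment or minus-strand gene in a forward-lesion
segment).  Repair efficiency is (observed/expected) × 100 with the
expectation taken from stratum 1 averaged over the two orientations.

## Clusters and alignment enumeration

Clusters are transitive chains of same-tumour substitutions spaced
below X nt (X = 11 tight, 101 standard, 201 wide), so a cluster's span
can exceed X.  Null cohorts keep each tumour's mutation count but draw
positions without replacement from the other tumours; enrichment is a
two-sided Fisher test of clustered/unclustered counts against the
rounded mean of the permuted cohorts.  Inside a classified segment the
first-replicated (upstream) member is the leftmost site for
reverse-strand lesions and the rightmost for forward-strand lesions.
Read-level phasing calls a pair (≤ 75 nt apart) same-chromosome when
at least one qualifying read carries both mutant alleles.

For an indel–substitution pair (indels require ≥ 3 supporting reads;
observed pairs additionally require two reads phasing both mutations,
a filter impossible for permuted data and therefore conservative),
ancestral and derived sequences are built from the reference with
100 nt flanks, oriented so the forward strand reads as newly
synthesized over the lesion-containing template.  Every gap placement
is scored; placements with exactly one gap and one mismatch are the
equally optimal solutions ("equally scoring" is interpreted as the
minimum edit configuration), each weighted 1/n with weights summing
to one exactly.  A pair admitting a zero-mismatch placement is a pure
indel and is rejected.  Substitution offsets are signed along the
synthesis direction (≥ +1 downstream); the up/downstream bias
(down − up)/(down + up) of definitively-sided pairs is tested against
10,000 random lesion-strand relabellings with an add-one-corrected
two-sided empirical P.  Cluster-length distributions between extreme
RSB bins (|RSB| > 0.51) are compared by two-sample two-sided KS, with
a power simulation that distorts the short(≤10)/long(>10) sampling
mix by d ∈ [0, 0.1] in steps of 0.0005, 100 bootstraps per d.

## Positional profiles

Expected counts at each offset around aligned regions sum, over
tumours, per-trinucleotide genome-wide rates matched to the segment
class covering the region, multiplied by the chromosome ploidy (rates
are per ploidy-weighted base).  Excess per Mb is
(obs − exp)·10⁶/count_i with count_i the number of regions non-N at
offset i; enrichment is the relative difference.  Rolling means use
centred truncated windows (51 bp for nucleosome-centred, 21 bp for
motif-centred plots).  Within a motif span only mutations matching the
consensus base are counted; flanks take all.  Major-groove labels
repeat every ±10.3 bp from the dyad with 5.15 bp spans, symmetric
about the dyad.  Damage-versus-repair classification uses 95%
bootstrap CIs over regions: elevated mutation with elevated
multiallelism = slow repair; elevated mutation without = excess
damage; reduced mutation without reduced multiallelism = protected.

Note that per-position enrichment has a negative small-count bias
(E[(O−E)/(O+E)] < 0 for Poisson counts at small expectation), so
null-calibration checks use region counts giving several expected
counts per position and additionally verify the aggregated
observed/expected ratio, which is unbiased.

## NER-TRIM analyses

Per-origin-base relative-difference curves compare the template-strand
rate at each expression stratum with the stratum-1 rate,
(obs − exp)/(obs + exp), with gene-level bootstrap CIs (100
replicates).  VAF quantiles are empirical-CDF positions (rank/n, ties
sharing the maximum rank — the rank−0.5 convention is equally
defensible and configurable at the ECDF step), grouped into 200 bins
of 0.005 using exact integer rank arithmetic.  Each bin contributes a
2×2 Fisher table of stratum-6 overlap for a focal tumour (or group)
against the aggregated asymmetric background excluding the focal
tumour; odds ratios are sample cross-products (Haldane–Anscombe
corrected and flagged on zero cells) with exact two-tailed P.
Labelled-set VAF bias uses a two-tailed Wilcoxon rank-sum on VAF
quantiles, Bonferroni corrected over groups.

## The simulator

The simulator generates everything the analysis consumes, with truth
labels.  Its defaults define the standard validation conditions:

* **Genome and cohort**: four 20 Mb chromosomes of uniform random
  sequence, 5% of the genome masked in 50 kb blocks, 12 tumours.
  Lesion-strand segregation is drawn per 10 Mb block, emulating
  chromosome-scale asymmetry segments; a configurable fraction of
  tumours retain both daughters ("symmetric" twins).
* **Damage**: per-base, per-strand adduct probabilities
  T = 4·10⁻⁴, C = 4·10⁻⁵, G = 1.2·10⁻⁵, A = 2·10⁻⁶ — a
  high-dose alkylation regime giving ~25–30 substitutions/Mb and >80%
  of substitutions from T, with the A rate kept low so that apparent
  A-origin mutations are dominated by repair-resynthesis (TRIM)
  rather than direct damage.
* **Persistence and miscoding**: lesions survive each cell cycle with
  p = 0.5 over 4 generations; each replication over a surviving
  lesion miscodes with p = 0.15, drawing the alternative allele from
  a per-base distribution (T→A dominant).  Alleles fixed at
  generation g take mean VAF 0.5·(1/2)^(g−1) per retained lineage
  (0.25 base in symmetric tumours), giving multiallelic sites and
  subclonal tiers.  Read depths are Poisson (60×) with beta-noised
  VAFs and multinomially allocated allele counts.
* **Repair**: TCR removes template-strand lesions with per-generation
  probability 0.8 · min(log(1+TPM)/log(1+4), 1) — log-linear in
  nascent expression, saturating at 4 TPM — and accessibility scales
  a global NER term (0.05 × accessibility).  Three NER rounds precede
  the first replication, while both damaged strands are duplexed.
* **TRIM**: when a generation-1 repair event's ~26 nt excision span
  contains an opposite-strand lesion, resynthesis over that lesion
  emits a mutation with opposite strand asymmetry, flagged shared
  between daughters (VAF 0.5 even in symmetric tumours).
* **Translesion artefacts**: with p = 0.02 a bypass event adds a
  collateral substitution 1–10 nt downstream along the synthesis
  direction, preferentially targeting a template G (G→T, 80%); with
  p = 0.01 a T lesion is skipped, producing a 1 bp T deletion from the
  lesion strand plus a characteristic downstream substitution (A→C /
  G→T); collateral insertions occur at p = 0.005, plus a thin
  background 1 bp indel rate (2·10⁻⁷/bp).
* **Annotation**: ~400 non-overlapping genes (20–250 kb, log-normal
  nascent TPM with a 25% zero-expression mass), gene orientation
  co-oriented with fork direction with probability 0.65; sinusoidal
  replication-timing tracks with Poisson early/late and Okazaki
  counts; accessibility peaks over ~300 planted motifs (16 bp, fixed
  consensus written into the sequence, shared per-position
  information content); nucleosome dyads every ~200 bp.  Optional
  per-position damage modulation plants motif protection (×0.3 at
  high-information positions), a motif damage hotspot (placed on a T,
  the adduct-prone base), and 10.3 bp-periodic nucleosome modulation.

All outputs are a deterministic function of the seed (independent
`SeedSequence` streams per tumour).

### What the simulator does and does not emulate

It reproduces the statistical structure the analyses assume:
strand-phased T-biased damage, block-wise segregation, persistence →
multiallelism, expression-saturating TCR, accessibility-dependent
repair, collateral clusters, strand-biased skip deletions, TRIM with
shared doubled-VAF mutations, and fork-correlated gene orientation.
It does not emulate sequence-context-dependent damage chemistry,
copy-number or structural variation, tumour cellularity below 100%,
mapping artefacts, or realistic genome composition (uniform random
sequence); passing tests therefore demonstrate correctness of the
inference machinery under the modelled generative process, not
robustness to every property of real tumour data.

## Validation scales and statistical power

The suite runs at desk scale (tens of Mb, 8–12 tumours, ~3·10⁴
mutations per cohort) rather than the hundreds of tumours and
gigabase genomes of a real study; cohort sizes were chosen so each
check has adequate counts.  Permutation-null calibration of the
cluster odds ratio uses a dense small-genome configuration (8 tumours
× ~3,000 substitutions on 4 Mb) because the stability of an odds
ratio needs large expected pair counts, which at study-like density
would require an impractically large genome.  The twin-tumour
top-VAF-bin enrichment compares 6 symmetric against 6 asymmetric
tumours; its direction (odds ratio > 1) is robust across seeds while
nominal significance has partial power at this cohort size, so the
fixed-seed suite documents one deterministic realisation.

## Known limitations

* The binary-segmentation change-point detector is deliberately
  simple; boundary placement can differ from more elaborate
  segmentation by up to half the local inter-mutation spacing
  (tolerated by the ≥95% per-base recovery requirement).
* The breakpoint grid search for expression strata recovers
  breakpoints to ~25% rather than matching any particular external
  segmented-regression implementation.
* Per-position profile classification requires feature counts large
  enough for bootstrap CIs to exclude zero; sparse feature sets
  return "neutral" rather than guessing.
* Odds ratios are sample cross-product ratios; conditional-MLE
  estimates (as some exact-test implementations report) can differ
  slightly for small tables.
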