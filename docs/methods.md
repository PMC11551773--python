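# Methods

This note documents the models and procedures `checflow` implements, the
conventions and parameter defaults it fixes where prose descriptions are
ambiguous, what the synthetic generators do and do not emulate, and known
limitations.

## Coordinates and annotation

All coordinates are 0-based, half-open internally.  GFF3 input (1-based,
inclusive) is converted on read; BED/BedGraph and the package's TSV
annotation format are native.  A transcript records its strand, TSS base,
stop-codon base and span; gene ids are unique.

**Promoters.** A promoter extends upstream from the TSS until the first
of: 700 bp (`max_len`), the span of any other transcript on either strand,
or the chromosome boundary.  Divergent gene pairs may therefore share
intergenic sequence — only transcript *spans* truncate, promoters do not
truncate each other, and shared regions are not split.  A gene whose TSS
is covered by another transcript's span gets a zero-length promoter and is
excluded with a warning.  There is no minimum-length filter beyond 1 bp.

**Expression quantification windows** are anchored on the stop codon
(400 bp upstream through 200 bp downstream, strand-aware, clipped to the
chromosome).  Anchoring on the stop codon rather than the TSS reflects the
3′-biased chemistry of poly(T)-primed RNA libraries, where reads pile up
at transcript ends; a TSS-anchored reading of "400 bp upstream" would
miss most of that signal.

## Signal tracks

Tracks are dense per-base float arrays per chromosome; BedGraph runs are
expanded on read and re-merged on write with values serialized at full
precision (`repr`), so write/read round-trips are exact.  Cut-site tracks
are normalized to a genome-wide sum of 1e7 (counts per 10 million); the
genome-wide z-score and all promoter z-scores use the sample SD (ddof=1).
Rolling means are centered with truncated windows at the edges —
one convention shared by meta-profiles, TSS-distance smoothing and the
sorted rolling profiles.

Meta-profiles average the signal in ±flank bp around anchors
(minus-strand anchors reversed), drop anchors within flank of a
chromosome end, and smooth with a centered rolling mean (default width
5 bp).

## Promoter binding, targets, calibration

Binding is the promoter signal sum rescaled to the maximal promoter
length: `sum/len × 700`, making truncated promoters comparable under
uniform signal.  Targets are promoters with binding z ≥ 3 across all
promoters of the sample; the threshold and the spike-in promoter list
(ARO9, ARO10, NAF1) are configuration values.  In spike-in samples the
spike promoters are excluded from the z-score statistics (their own z is
computed against the remaining promoters' mean/SD): the spike signal is an
external calibrant, not part of the TF's binding distribution, and
including three extreme promoters would distort the SD of every sample in
proportion to its spike take-up.

The calibration statistic is Σ binding(non-spike) / Σ binding(spike).  It
is invariant to depth normalization (the scale cancels) and linear in the
non-spike signal.

The TSS-distance of peak binding smooths the promoter signal with a
centered rolling mean (default 50 bp) and reports the distance from the
TSS base to the argmax, ties broken toward the TSS; flat profiles return
0 with an explicit flag.

## Expression and differential expression

Counts are scaled per sample to 1e6 and log2(x+1)-transformed (pseudocount
1 keeps zeros at 0).  Samples under 200 000 raw reads are dropped.  The
expression filter retains genes with ≥ 4.5 log2 units in at least
ceil(0.025 × n_samples) samples — the ceiling is forced by the worked
ratio 27/1076 (0.025 × 1076 = 26.9).

For overexpression samples, log2 fold-change against the per-gene median
of wild-type samples is z-scored within 10 equal-size bins of reference
expression.  Binning details are deterministic: genes are pre-sorted by
gene id so that ties in reference level resolve stably, and remainder
genes go to the lowest bins.  |z| > 2 sets the DE flag; the per-bin
Welch t-test of bound vs unbound fold-changes is computed and reported
but does not gate the flag — the two criteria are intertwined in typical
descriptions of this procedure, so both are exposed and the
deterministic one drives the flag.

Library fold-change is the mean over the 5 highest-abundance strains minus
the mean over the 5 lowest; abundance ties at the boundary break by sample
id (logged).  The display-normalized matrix is per-gene mean-centered,
anchored to the 5 lowest-abundance strains, ordered by abundance and
smoothed over 3 strains.

## Induction scores

Strain abundance is the median log2 fluorescence of the retained cells
minus the median over background runs of each run's median log2
fluorescence.  Cells are retained by a two-component Gaussian mixture on
log2 fluorescence: the component with more members is taken as cells
(debris/noise is assumed the minority), and members within 2 SD of that
component's mean are kept.  If the component means fall within 0.1 log2
units the fit is considered degenerate and all cells are kept, flagged.
Logs are base 2 throughout.  The mixture fit uses a fixed random state and
quantile-based initialization so results are deterministic.

The induction score is Spearman's ρ (average ranks on ties) between a
gene's expression and TF abundance across strains; two-sided p-values use
the t approximation, with p = 0 at |ρ| = 1.  BH correction runs within
each library over all non-constant genes; significance means q < 0.05.
The alpha is a configuration value — the q-threshold, not any implied
ρ cutoff, is the operative rule.  Induced targets are the significant
genes of the required sign intersected with the native TF's target set;
the cross-library comparison correlates (Pearson) the per-library ρ
vectors over a caller-supplied gene union, pairwise-deleting missing
values.

## Motifs

Canonical indexing maps each x-mer and its reverse complement to one
class: 4^x/2 classes for odd x (no odd-length DNA word is its own reverse
complement); even x is allowed and yields (4^x + #palindromes)/2 classes,
logged as deviating from the odd-x formula.  Scanning is forward-only
(canonicalization covers both strands) and overlapping occurrences all
count; occurrences in two overlapping promoters count once per promoter.

Each occurrence starting inside a promoter is scored by the mean
normalized signal in [mid − w/2, mid − w/2 + w), w = 20, mid = start +
floor(x/2); windows that leave the chromosome are skipped and counted.
Note that an even window is asymmetric about the x-mer midpoint, so exact
strand-mirror invariance of the score table holds for odd windows (the
tests use w = 21 for that invariance; the default w = 20 matches the
20 bp convention and differs from its mirrored counterpart by a 1 bp
window shift only).

The PWM is built from the ten top-scoring classes.  Because all inputs
are equal-length words, "alignment" to the top class is an exhaustive
ungapped offset-and-orientation search maximizing matches (offsets up to
±(x−1); ties prefer the smaller |offset|, then the forward orientation).
This reproduces the intent of registering shifted variants without an
unconstrained gap model, and is isolated in one function so a gapped
aligner could be substituted.  Each class contributes its mean signal as
weight to per-position base counts; columns are normalized to
probabilities and positions with total weight below 50% of the maximum
are trimmed.  PWMs are exported as TSV and minimal MEME format.

## Promoter features and profiles

The OPN score is log2(mean occupancy in [TSS−400, TSS−200)) − log2(mean
occupancy in [TSS−150, TSS)), strand-aware, half-open (the prose bounds
"200–400 bp" and "to 150 bp" are inclusive-ambiguous; half-open intervals
are fixed here).  Promoters shorter than 400 bp get a missing value, as
do promoters with a zero-occupancy region unless a pseudocount is
supplied.  The score is invariant to global occupancy scaling, so raw or
depth-normalized occupancy give identical results; normalized is used.

Expression flexibility is the difference between the 99.95th and 0.05th
percentile of a gene's log2 fold-changes across conditions, using the
linear-interpolation percentile convention — at small condition counts
this collapses (to within interpolation error) to max − min.  The
bound-TF count is the number of per-TF z-scored binding columns at
z ≥ 3 (inclusive).  Binary class features (e.g. STM membership) are 0/1
indicators whose rolling profiles are fraction curves.

Sorted rolling profiles sort genes ascending by a key (ties broken by
gene id), drop genes missing the key, and report the centered rolling
mean and SEM (sample SD / √n) with truncated edge windows.  Window sizes
are always caller-supplied (figures in this line of analysis typically
use 50, 120, 150 or 500).

## Synthetic data

The generators are pure functions of (parameters, seed) via
`numpy.random.default_rng`; identical calls are byte-reproducible.

The default world is one 600 kb chromosome with 300 genes in uniform 2 kb
slots on alternating strands, leaving full 700 bp promoters except for
three engineered close-neighbor pairs whose promoters truncate to 400 bp.
Three genes disjoint from all TF targets are designated spike-in
promoters.  Each of 3 TFs gets a random 7-bp consensus written into the
sequence ~200 bp upstream of the TSS of each of its 20 targets (target
sets are disjoint across TFs).

ChEC tracks are uniform-rate Poisson background plus Gaussian bumps
(SD 25 bp) at planted motif sites, sized so the 700 bp promoter sum is
`enrichment`-fold background (default 10), at a default depth of 1e6
reads.  `spike_fraction` adds spike-promoter bumps carrying that fraction
of the non-spike read mass — defined relative to the non-spike mass so
that doubling the fraction exactly doubles the spike signal and halves
the calibration ratio; at 0.1 this approximates a spike-in strain at ~10%
of the population.

Nucleosome tracks are lognormal noise around occupancy 1; the proximal
region [TSS−150, TSS) is multiplied by (1 + effect) for planted low-OPN
genes and divided by it for high-OPN genes (default effect 1.0, i.e.
OPN = ±1), with classes alternating over genes.

Expression libraries have 38 strains with abundances log-spaced over
2^0–2^6 (log2 fluorescence units over an autofluorescence background of
50 a.u.).  Responder genes follow a Hill response, log2 expression =
base + amplitude · a/(a + half_max) with amplitude 2 and half_max 8, so
~89% of the amplitude is realized across the library — the abundance
range was chosen so that a planted amplitude is essentially attained, as
in libraries selected to span the expression range.  Per-strain counts
are multinomial at 2e6 reads on 2^(log2 expression + N(0, 0.5)) noise;
per-cell fluorescence is lognormal around each strain's abundance with a
10% low-fluorescence debris component 3 log2 units below the cells, plus
four non-fluorescent background runs.

**What the generators do not emulate:** realistic yeast promoter grammar
or nucleotide composition, sequence-driven nucleosome positioning,
fragment-length structure of MNase digestion, UMI/PCR artifacts, batch
effects, or correlated gene programs.  Passing recovery tests therefore
demonstrates the correctness and calibration of the statistics under
their own model assumptions (Poisson counts, lognormal noise, monotone
responses) — not robustness to the full complexity of experimental data.

## Problem sizes and numerical choices

Recovery and calibration checks run on the 300-gene/600 kb world with
10–20 replicate seeds, 2000-gene null libraries for FDR calibration, and
50 (30 in the acceptance script) replicates for the DE null — sizes at
which all statistics are stable and the full suite completes in well
under a minute per module.  Degenerate inputs fail loudly: all-zero
tracks, constant tracks, zero-variance binding vectors, empty matrices,
bins with fewer than two genes and windows larger than the input all
raise or warn as documented in the docstrings.

## Known limitations

- Promoter truncation scans all transcripts on a chromosome per gene
  (O(n²) per chromosome); fine at yeast scale, would need an interval
  index for large genomes.
- The ungapped PWM alignment cannot register motifs whose optimal
  registration requires internal gaps.
- `estimate_abundance` assumes debris is the minority component; a
  majority-debris sample would be mis-gated (the fallback flag does not
  cover this case).
- The even-window strand asymmetry in k-mer scoring (above) is inherent
  to the 20 bp convention, not a bug; use an odd window where exact
  strand symmetry matters.
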