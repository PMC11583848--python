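# Methods

`ptmd` implements the computational side of a selective ribosome profiling
study of P-site tRNA-mediated mRNA decay (PTMD): the codon- and tRNA-level
determinants of CCR4-NOT (CNOT3) recruitment to translating ribosomes, and
the consequences for mRNA stability.  This note documents the models, the
estimators, the synthetic-data generator that stands in for sequencing data,
and the numerical and design choices that were genuinely open.

## Footprint processing

Ribosome footprints are counted *species*: unique (transcript, 5' position,
read length) triples with summed counts.  Species are the finest
reproducible unit and the level at which the enrichment test operates;
duplicate records are merged on load.  Only 29, 30, 32 and 35 nt reads are
analysed by default — the lengths with clean triplet periodicity — and the
P-site codon is placed at a fixed offset from the 5' end: the 13th
nucleotide (1-based) for 29–30 nt reads and the 14th for 32/35 nt reads.
The offset convention ("the 13th nucleotide is the *first* nucleotide of
the P-site codon") is the standard ribo-seq convention; it is isolated in
one table (`footprints.P_SITE_OFFSETS`) so an alternative convention is a
one-line change.  E- and A-site codons sit one codon 5' and 3' of the
P-site.  Footprints whose P-site start is out of the CDS reading frame are
excluded from codon counting rather than rounded to the nearest frame;
out-of-CDS sites are flagged per site.  All exclusions are tallied in a QC
report so counts are conserved end to end.  Coordinates are 0-based
half-open internally; 1-based numbers appear only in human-facing text.

BAM input (transcriptome alignments) uses primary, forward-strand records
only, with read length taken as the CIGAR-consumed query length; a plain
TSV of (transcript, position, length, count) is equivalent and is the
format the simulator writes.

## Enrichment statistics

IP-enriched footprint species are identified with a two-sided Fisher's
exact test on [[ip_count, ip_total − ip_count], [input_count, input_total −
input_count]], Benjamini–Hochberg corrected across all species in the union
of the two libraries, at FDR < 0.01, keeping only species whose proportions
point toward the IP.  Two-sidedness plus a direction flag is the
conservative reading when sidedness is unspecified.  The p-value is
computed from exact integer hypergeometric numerators (Python big-int
combinatorics); two-sided tail membership is decided by integer comparison,
so there is no floating-point tie tolerance.  This matters for the
package's exactness guarantee (agreement with a brute-force enumeration
oracle to better than 1e-12 over all tables with margins ≤ 30) and costs
little: the support of each species' conditional distribution has at most
ip_count + input_count + 1 points.

Per-codon site enrichment is the percentage of enriched footprints
(count-weighted) bearing a codon at the E-, P- or A-site divided by the
percentage of input footprints bearing it.  Percentages are normalized over
the sense codons observed in the input, which yields the invariant
Σ ratio·pct_input = 100; stop codons are tallied separately; codons
unobserved in the input get an undefined ratio, never infinity.  The same
percentage-ratio statistic is applied to amino acids and to (E, P, A)
tripeptides, and an amino-acid × site matrix is emitted for sequence-logo
rendering.

Two numerator choices are exposed.  `selection="enriched"` is the
significance-thresholded statistic described above.  `selection="ip"` uses
all IP footprints and is the estimator used for quantitative recovery and
rank comparisons: at desk-scale depth the thresholded statistic is a
censored estimator (codons whose species never clear FDR collapse toward
zero), whereas the direct IP-share ratio converges to the underlying
acceptance weight for every codon.  With the default simulated depth
(2×10⁵ per library) the direct P-site ratios recover injected recruitment
weights to a few percent and rank-correlate with an all-distinct weight
vector at Spearman ρ > 0.99; the thresholded statistic recovers the
injected *ranking* (CGG > CGA > AGG > rest) on a deep-coverage design.

The weighted codon score of an mRNA is Σ(weights over ORF sense codons) /
(number of ORF sense codons), with weights defaulting to the P-site
enrichment ratios of CGG, CGA and AGG.  Stop codons are excluded from
numerator and denominator; ambiguous codons contribute zero weight but stay
in the denominator.

External per-codon metrics (tAI, codon stability coefficients, dwell
times) are correlated with log2 site-enrichment ratios (Pearson default,
Spearman optional); ratios are log-transformed because they are
multiplicative.

## Decay kinetics

Labeled-fraction and reporter time courses are fit with a single
exponential, y(t) = exp(−kt), by least squares on ln y against t after
normalizing to the t = 0 mean.  Points at or below a floor (default 0.01)
are excluded before the log; a non-positive fitted rate flags the
transcript stable, too few surviving points flag it unfit — flags, never
silent drops.  Replicates are averaged per timepoint before fitting.  The
fit is exact on noise-free data (t½ recovered to 1e-9 h on the
0/1/2/4/8/12 h grid) and recovers t½ with < 10% median absolute relative
error at Gaussian noise sd 0.02.  The log-linear estimator is biased when
the observed fractions approach the noise floor (additive noise on a small
positive quantity is asymmetric after log); averaging replicates before
fitting mitigates this, and the floor is configurable.

Stability comparisons use a one-sided Wilcoxon rank-sum test of a
transcript stratum against the background of all other transcripts:
exact when both samples are ≤ 12 and tie-free, otherwise the normal
approximation with midrank tie correction and continuity correction.  ECDF
coordinates for both groups are emitted for cumulative-distribution plots.
The default "high score" stratum is the top 1000 transcripts by weighted
score; codon-defined strata (e.g. mRNAs rich in CGC/AGA/CGU) drop members
that also carry a top-1000 score before testing, so overlap with the
high-score set cannot carry the signal.  Simulated analyses scale the
stratum to 10% of the simulated transcriptome.

## Dwell times and the conditional correlation

Per-codon A-site dwell time is a ratio estimator: the codon's share of
count-weighted A-site observations over its share of eligible A-site
positions, with each transcript's positions weighted by that transcript's
footprint total.  The weighting makes the estimate invariant to transcript
abundance by construction.  Start/stop codons and the two outermost codons
of each ORF are excluded from eligibility.  An external per-codon dwell
table is accepted wherever an estimated one is, since published dwell-time
sets are commonly taken from independent data.

The conditional analysis partitions footprints by P-site codon class
(CGG/CGA/AGG vs everything else) *before* recomputing the A-site
enrichment table on each partition, then reports the Pearson correlation of
partition-specific log2 A-site enrichment with log2 dwell.  Partition
tables default to the direct IP-share ratio: sub-partitions are usually too
sparse for per-species significance calling, and the direct ratio keeps the
complement partition's correlation well-defined (the thresholded variant is
available).  Significance of a correlation is judged against a
codon-label permutation band (default 10,000 shuffles, 2.5–97.5
percentiles).

One caveat discovered during validation and encoded in the tests: if the
dwell table is estimated from the *same* input library that forms the
enrichment denominator, the two quantities share sampling noise and are
anti-correlated under the null (the shared multinomial fluctuation enters
the dwell numerator and the ratio denominator).  Null-calibration analyses
therefore estimate dwell from an independent input realization — the
in-data analogue of using an external dwell table.

## tRNA D-arm features and PTMD classes

Each tRNA is reduced to the features the structural model identifies:
the Sprinzl 13:22:46 base triple in/near the D-stem, and the length of the
D-loop α element — the segment preceding the universally conserved GG
motif.  Classification is three-outcome with steric precedence: an α
element of two or more nucleotides is **blocking** (the extra nucleotide
clashes with CNOT3 in the E-site) regardless of the triplet; otherwise a
U13:A22:A46 triplet is **promoting** (it hydrogen-bonds CNOT3); otherwise
**neutral**.  The blocking-over-promoting precedence is a package decision:
the steric argument overrides favorable hydrogen bonding, and the
combination does not occur among natural tRNAs examined, so the rule is
explicit and logged.

Records carry explicit coordinates (TSV input) or a dot-bracket cloverleaf
from which the arms are delimited by paired-region order: acceptor stem
outermost, then D-, anticodon- and T-stems 5'→3'.  Position 13 is the
fourth nucleotide of the D-stem region whether or not it is Watson–Crick
paired, so trans-Hoogsteen G13:A22 pairs (type-II tRNAs such as Leu/Ser)
parse correctly and are flagged; they classify as they fall under the two
rules, with a distinguishing flag.  The α element is everything in the
D-loop before its first GG; a missing GG is a parse failure (the record is
left unclassified), a second GG only warns and the first is used.  For
noncanonical D-loops the first-GG rule is the declared convention.
Modified bases are reduced to their parent base (m7G46 → G46) before
triplet matching — recruitment does not depend on tRNA modifications, so
parent-base identity is the relevant feature.  De novo cloverleaf folding
is deliberately out of scope; Sprinzl assignment is a solved upstream
problem.

Codons inherit the class of their decoding tRNA(s) through a decoding
table built with standard Crick wobble at anticodon position 34
(G34 reads C/U, U34 reads A/G, C34 reads G, A34 reads U; configurable).
A sense codon with no decoder is a hard error.  Codons decoded by tRNAs of
different classes are flagged ambiguous and resolved blocking > promoting >
neutral.  Per-transcript class densities (fractions of all ORF codons;
stops and unclassified codons stay in the denominator only) feed the same
stratified stability test used for weighted scores.  Anticodon-stem
variation measurably modulates recruitment in experiments but no
quantitative rule exists, so it is not part of the three-class output.

## The synthetic-data generator

The generator produces every input the pipeline reads, with known ground
truth, emulating the structure of the deposited study data (two-library
footprint counts with triplet periodicity, P-site-dependent IP enrichment,
A-site-dependent dwell, labeled-fraction decay over 0/1/2/4/8/12 h in two
genetic conditions):

- **Transcriptome** — AUG…stop ORFs with internal codons drawn from a
  codon-frequency table (uniform over the 61 sense codons by default, the
  simplest null), 5'UTRs ≥ 13 nt and 3'UTRs ≥ 24 nt so every offset fits.
- **Footprints** — a ribosome placement (P-site at an internal codon,
  first/last two codons excluded, so E/P/A are always sense codons) is
  drawn with probability ∝ abundance × dwell(A-site codon); abundance is
  uniform per transcript by default.  The IP library multiplies the
  acceptance weight by the P-site codon's recruitment weight — the
  mechanism under study, isolated to the P-site for clean recovery tests —
  with defaults CGG 4, CGA 3, AGG 2, all else 1.  Optionally the IP weight
  also carries dwell^γ for P-site codons in a coupling set, which creates
  the P-site-conditioned dwell signal.  Read length is drawn from
  {29: 0.4, 30: 0.3, 32: 0.2, 35: 0.1} and the 5' end back-calculated from
  the offset rule, so frame assignment is exact by construction.  Totals
  equal the requested depth (2×10⁵ per library by default; IP rejection is
  renormalized).
- **Decay** — per-transcript baseline half-lives are log-normal (median
  4 h, sd 0.5 log2 units, the scale of mammalian mRNA turnover); in the
  perturbed condition the top-scoring 10% of transcripts (by true weighted
  score) have their half-life multiplied by 2.  Observation noise is
  binomial (1000 reads) by default, matching the count origin of
  conversion fractions; Gaussian and noise-free modes exist.
- **tRNAs** — a canonical type-I scaffold realizes any requested
  (13, 22, 46, α-length, anticodon) tuple, with the D-loop constructed as
  α×A + GG + β so the parser recovers exactly the requested α length.  A
  complete 61-codon panel mirrors the study's landscape: promoting D-arms
  on the CGG/CGA/AGG decoders, extended-α (blocking) D-arms on the
  N/K/I/Y/M/F/T decoders, the common C13:G22:G46 configuration elsewhere.

Everything is deterministic given the config seed, with independent salted
streams per stage, and generated at run time — no data files ship with the
package.

What the generator does **not** emulate: sequence-level read errors and
adapters, nucleotide-level conversion calling, initiation dynamics,
non-uniform transcript abundance (available as a knob, uniform by
default), biological covariation between codon usage and half-life beyond
the injected score–stability link.  Passing tests therefore demonstrate
that the estimators recover the generative model they assume and that the
statistics are exact/calibrated — not that the biological conclusions
reproduce from raw reads.

## Problem sizes

Simulated analyses use transcriptomes of 25–400 transcripts of 90–240
codons at 2×10⁵ footprints per library: small enough to run in seconds,
deep enough per species (or per codon) for the statistic being exercised.
Two designs recur: a *deep-coverage* design (25 transcripts, one read
length) when per-species Fisher significance is needed, and a *broad*
design (120–400 transcripts, 4 lengths) for ratio, dwell, decay and
correlation recovery.  Null calibration of the stratified test uses 1000
simulated nulls; permutation bands use 2000–10,000 shuffles.

## Known limitations

- The significance-thresholded enrichment ratio is depth-dependent by
  nature; cross-dataset comparisons of its magnitude require matched depth
  (the direct IP-share ratio does not).
- The exponential fit assumes a single decay regime and no synthesis
  during the chase; multi-compartment kinetics are out of scope.
- Wobble rules are a configurable approximation; inosine-34 decoders and
  organism-specific decoding differences must be supplied by the caller.
- The α-element boundary for deeply noncanonical D-loops follows the
  first-GG convention; long type-II D-loops can exceed the α lengths seen
  in the tRNAs that motivated the rule, and such records carry flags so
  downstream users can treat them separately.
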