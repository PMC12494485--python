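# Methods

This note documents the models and procedures the toolkit implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Coverage and the mismatch filter

Read recruitment is consumed, not performed: inputs are alignment records
(SAM/BAM with an NM tag, or an equivalent TSV).  Only primary alignments
contribute depth — secondary and supplementary placements would double-count
a read.  The mismatch filter keeps alignments with at most `max_mismatches`
edits (default 1, i.e. alignments with two or more mismatches are removed);
the NM-style edit count is taken as provided by the mapper, so indels count
toward it however the upstream tool counted them.  Depth at base *i* is the
number of retained alignments whose aligned reference span contains *i*;
clipped read bases contribute nothing.  Coverage is accumulated with a
difference array (O(reads + genome length)) and validated in tests against a
per-base counting loop.  All internal coordinates are 0-based half-open; BED
and bedGraph are emitted natively, GFF3 is converted on ingestion.

A genome's mean coverage is the length-weighted mean over its member contigs
(total aligned bases / genome length), not the mean of per-contig means —
the distinction matters for multi-contig MAGs with uneven contig sizes.

## Island calling

Islands are maximal runs of under-recruited bases under a two-regime rule
keyed on the genome mean *c̄*:

| regime | applies when | per-base predicate | min length |
|---|---|---|---|
| drop | *c̄* ≥ `high_cov_threshold` (5×) | depth ≤ (1 − `drop_fraction`) · *c̄* | `min_len_drop` (100 b) |
| zero | `low_cov_threshold` (2×) ≤ *c̄* < 5× | depth = 0 | `min_len_zero` (200 b) |
| — | *c̄* < 2× | no calls | — |

Interpretation choices, fixed and unit-tested at their boundaries:

* "dropped ≥ 25%" means *at or below* 0.75 × mean (boundary inclusive);
* a mean of exactly 5× uses the drop rule; "between 2× and 5×" is [2, 5);
* the predicate is evaluated per base, not on windowed averages — a single
  above-threshold base terminates a run, which keeps calls deterministic and
  maximal by construction;
* islands never span contig boundaries; runs touching a contig end are kept
  and flagged `at_contig_edge` (terminus exclusion is an AMG-curation
  concern, not an island concern);
* no gap merging by default; `gap_merge > 0` optionally fuses runs separated
  by at most that many failing bases, at the cost of the per-base invariant.

The caller is checked for set-identity against an independent base-at-a-time
scanner on a thousand random tracks per run, and for exact maximality
(extending any call by one base violates the predicate or the contig bound).

## Island genes and category profiles

A gene belongs to an island when the intervals overlap by at least one base
("fully or partially contained", read literally — no minimum overlap
fraction).  A gene overlapping two islands appears in two pairs but is
counted once in category profiles (deduplicated by protein id).  Profiles
use per-hit accounting: a protein whose eggNOG annotation carries the
category string "EGP" contributes one hit to each of E, G and P; repeats
from multiple COGs on one protein are kept, never deduplicated at the
(protein, letter) level.  Letters whose share falls below `others_threshold`
(2%) are folded into an "Others" bucket at reporting time.  Because rankings
are sometimes quoted "excluding category S" (function unknown), an
`exclude_S` mode removes S from both numerator and denominator; the default
keeps S.  Top-COG tables rank by descending gene count with a lexicographic
tie-break, so output is deterministic.

## Curation decision rules

All thresholds are literal (≥ vs > exactly as stated) and an absent tool
score means "tool did not run", never zero:

* **candidate screen**: length ≥ 5,000 b and at least one of VirSorter2
  ≥ 0.7, DeepVirFinder ≥ 0.9 with P ≤ 0.05, Seeker ≥ 0.9, positive VIBRANT
  call;
* **vOTU retention**: length ≥ 5,000 b and (≥ 1 viral gene, or no viral and
  no host gene, or no viral gene but VirSorter2 ≥ 0.95 or > 2 hallmark
  genes) — the hallmark route deliberately tolerates host genes, matching
  the stated disjunction;
* **MAG tiers**: high iff completeness > 90 and contamination < 5; else
  medium iff completeness ≥ 50 and contamination < 10; else rejected — a
  partition, every MAG lands in exactly one tier;
* **lifestyle**: the larger of the virulent/temperate scores wins when
  ≥ 0.80; exact ties are unassigned (conservative, the source protocol is
  silent);
* **taxonomy call filters**: bit-score ≥ 50, percent identity > 90,
  virus score > 0.7, keyed by the score kind;
* **sequence matches**: protein hits ≥ 80% identity and ≥ 80% query
  coverage; gene/tRNA hits ≥ 90/90.

## Consensus taxonomy

Ranks are evaluated independently: at each rank, the consensus is the single
name proposed by all classifiers that assigned anything there; any
disagreement — or no assignment — yields "unclassified".  Silent classifiers
abstain rather than veto.  Parent/child conflicts are not reconciled by
default (an agreeing family under a disagreeing class stays named); a
`truncate_below_conflict` mode forces every rank below the first
unclassified one to unclassified for users who want lineage consistency.

## Host associations and AMGs

A vOTU's host-specificity type depends only on its set of distinct linked
MAGs: one MAG → `unique`; several MAGs sharing one (known) family →
`multiple_family_consensus`; anything else — including MAGs with missing
family annotation — `multiple_class_or_higher`.  Repeated links to the same
MAG collapse to distinct (vOTU, MAG) pairs before typing.

AMG calls from the two callers are combined by union (an intersection mode
exists behind a flag; the union reading of "combined" is the default),
deduplicated by (vOTU, gene index, COG) with caller sets merged, then calls
on the first or last gene of a contig are removed — contig termini are prone
to assembly artefacts and prophage-boundary misassignment.  An alternative
`bp_buffer` edge mode removes genes within a configurable distance (default
500 bp) of a terminus instead.

## Abundance

TPM is the standard rate-sum normalization: per sample, rate = count/length,
TPM = 10⁶ · rate / Σ rates.  All-zero sample columns stay all-zero.
Genome-level TPM pools member-contig counts over the genome length before
normalizing — not the mean of contig TPMs, which would weight short contigs
up.  Display values use log10(TPM + 1).  Taxon aggregation sums member
TPMs and conserves column totals exactly; TPM is invariant to scaling a
sample's counts, so sequencing depth divides out.

## Synthetic data

The generator emulates pooled-sample read recruitment with planted ground
truth; defaults are one ~8–12 kb contig per genome at 8–30× baseline, two
planted islands of 300–800 b at a quarter of baseline depth, 100 b reads
(the study's read length), and per-alignment mismatch counts massed on 0–1
(0.80/0.12/0.06/0.02 over 0–3).

* **Poisson mode** draws read starts as Poisson with rate
  `target_depth(read midpoint) / read_length`, so expected per-base depth is
  a symmetric 100 b moving average of the planted rectangle: island edges
  blur by roughly ±16 b at the default drop threshold, which bounds the
  boundary accuracy any caller can achieve on these data.  The total rate is
  scaled by 1/P(mismatches ≤ 1) so the planted depth refers to alignments
  that survive the mismatch filter.
* **Noiseless mode** tiles each constant-depth region with region-spanning
  zero-mismatch alignments: coverage is exactly rectangular and recovery can
  be asserted boundary-exact.

Planted islands never overlap, keep two read lengths of separation and stay
clear of contig edges, so truth is unambiguous under maximal-run detection.
Classifier tables follow a prefix-depth model: each classifier assigns a
lineage prefix of uniform random depth (0–8 ranks) and errs independently
per rank with probability 1 − `classifier_agreement`, wrong names drawn
uniformly from `n_decoy_names` decoys.  This yields a closed-form named-rank
probability — enumerate the binomial number of assigners k, then
aᵏ + (1−a)ᵏ/m^(k−1) for all-agree — which the consensus module is tested
against.  Host links are unique / same-family / cross-class in proportions
0.70/0.25/0.05 by default, realistic for a phage-dominated community with
moderate host specificity.  AMG tables plant interior truths (each seen by
either caller with probability 0.8, at least one guaranteed) plus decoys at
gene index 1 and N that curation must remove.

What the generator does **not** emulate: real sequence content (alignments
are coordinates, not nucleotides), mapper-specific biases (MAPQ, multi-
mapping, GC skew), inter-sample composition structure beyond a lognormal
abundance factor, and taxonomically structured classifier errors.  Passing
recovery tests therefore demonstrates correctness of the detection and
decision logic under the stated statistical model, not robustness to
mapper artefacts on real reads.

## Determinism and problem sizes

All randomness flows from a single integer seed through
`numpy.random.default_rng`; coordinates are integer arithmetic, and every
output table is written with fixed float formatting, so identical configs
reproduce identical bytes (the run manifest records per-stage parameters and
SHA-256 checksums and is itself reproduced).  Validation runs use sizes that
keep the whole suite in seconds on one core — 1,000 random tracks for oracle
equivalence, 20 genomes for planted-island recovery, 1,000 vOTUs for the
consensus closed-form check, 100 random matrices for TPM conservation —
chosen so that binomial/Poisson standard errors are small relative to the
asserted tolerances.

## Known limitations

* Headline counts from any particular field study (numbers of islands,
  vOTUs, AMGs) depend on raw reads and upstream assembly/binning tools and
  are not reproducible from tabular inputs; the validation targets are
  therefore properties (oracle agreement, planted-truth recovery,
  conservation laws), not those counts.
* The per-base island predicate is deliberately unsmoothed; on very deep
  genomes a single noisy base can split a biological island into two calls.
  `gap_merge` mitigates this at the user's choice.
* Lifestyle, quality and classifier scores are consumed as given; no
  attempt is made to recalibrate upstream tools against each other.
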