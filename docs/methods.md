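# Methods

This note documents the models behind isosim, the parameters that matter,
the choices made where the design was genuinely open, and what the
synthetic fixtures do and do not demonstrate about real data.

## Coordinate conventions

All in-memory coordinates are 1-based inclusive (the GTF convention).
Introns ("junctions") are stored as `[exon_end + 1, next_exon_start − 1]`
pairs, so junction-chain equality — the primitive underlying FSM/ISM calls
and TP matching — is an exact integer comparison with no tolerance. BED
output is converted to 0-based half-open only at the writer boundary.
Exons are sorted and validated at construction; out-of-order exon records
in input GTFs are normalized silently (annotations in the wild are not
consistent about record order).

## Structural classification

A query transcript is compared against same-strand overlapping reference
transcripts through a fixed cascade: FSM (chain equality) → ISM (contiguous
sub-chain; prefix, suffix or internal run — a *non-contiguous* subset is
exon-skipping and falls through to NIC) → fusion (exonic overlap with two
or more clusters of mutually non-overlapping genes; checked before NIC/NNC
so a gene-spanning chain is not absorbed by splice-site novelty) → NIC
(every donor and every acceptor annotated somewhere among overlapping
same-strand transcripts, i.e. "in catalog" is annotation-wide, not
gene-restricted) → NNC (at least one unannotated splice site). Queries with
no same-strand overlap are antisense (opposite-strand overlap) or
intergenic (none); same-strand overlap matching no rule — typically a
mono-exon transcript inside an intron — is genic. Mono-exon queries are FSM
against an overlapping mono-exon reference, ISM when strictly contained in
an exon of a multi-exon reference (no boundary slack; the tolerance real
classifiers apply at exon edges is not standardized, so we use strict
containment), else genic/antisense/intergenic by overlap. We emit a single
`genic` label rather than splitting genic-genomic from genic-intron.

Associated-transcript ties are broken deterministically: most shared
junctions, then longest spliced length, then lexicographically smallest id.

*Potential* categories — what a transcript would be called if it were
deleted and rediscovered — are computed by classifying each transcript with
itself excluded from the reference. Internal consistency is the design
requirement here: the same classifier assigns potential categories, audits
the deletion design, and attributes false positives during evaluation, so
category semantics cannot drift between stages. Corner-case divergence from
any particular external classifier's behavior is accepted and documented.

## Novelty selection

Deleting transcripts changes the annotation that defines everyone else's
category, so selection is not independent per transcript. The algorithm is
greedy and seeded: candidate lists per category are shuffled; a candidate
is accepted only if (a) its spliced length is at least `min_length`
(default 200 nt, to avoid simulating small RNAs), (b) its associated
reference transcript has not itself been selected for deletion, and (c)
re-classification against the provisional reduced annotation still yields
the assigned category. Accepting a candidate locks its associated
transcript as retained. A final audit re-classifies every selected
transcript against the finished reduced annotation and swaps out violators
(up to 10 rounds), drawing replacements under the same rules. Requests
exceeding the candidate supply degrade to the achieved count with a
warning, never an error. A transcript may serve as the retained anchor for
several deleted novels; only deletion conflicts are locked.

Known (FSM) transcripts are drawn uniformly from the non-deleted pool
subject to the same length floor.

## Expression assignment

Three modes set per-transcript read counts, which are then rescaled by
largest-remainder rounding so they sum *exactly* to `long_count`:

* `equal` — identical values for every simulated transcript;
* `custom` — negative binomial draws, parameterized as (size, mean), one
  distribution for known and one for novel transcripts (defaults size 2,
  mean 100/20);
* `sample` — inverse-transform sampling from the ECDF of a user-supplied
  raw-count table, so simulated expression follows an observed library.

`diff_exp` biases high expression toward known transcripts without
changing the marginal value distribution. The mechanism is a weighted
order: sampled values are sorted descending and assigned to transcripts in
the order of a weighted sample without replacement (Efraimidis–Spirakis
keys `u^(1/w)`), with weight `exp(diff_exp)` for known and 1 for novel
transcripts. At `diff_exp = 0` the allocation is exchangeable; for larger
values the odds that a known transcript receives the next-largest value
grow by the factor `exp(diff_exp)`, giving a monotone expectation ordering
(verified by Monte-Carlo in the tests). TPM is computed as
length-normalized read rate scaled to 10⁶.

`iso_complex` draws, per gene, the number of expressed isoforms from an
empirical per-gene isoform-count distribution (truncated to the isoforms
available); surplus known isoforms get zero reads, novel transcripts are
never silenced (they are the objects under study).

## Long-read generator

Reads are produced per transcript at exactly the designed counts. Each read
takes the transcript sequence, applies 5'/3' truncation, then an i.i.d.
per-base error process: substitution with probability `mismatch_rate`
(to a uniformly random different base), deletion with `deletion_rate`, and
insertion of a random base after a position with `insertion_rate`. The
applied edit script is tallied per read in the truth table, so error rates
are measured alignment-free as operations over template bases; an
independent aligner (edlib) cross-checks that recorded operations track the
minimal edit distance. cDNA reads are drawn from sense or antisense with
probability ½; direct-RNA reads are sense-only, as in the protocol.

Platform profiles are fixed at the per-base rates: cDNA-ONT
mismatch 2.8%, insertion 1.9%, deletion 3.5%; dRNA-ONT 3.6%/3.0%/5.7%;
PacBio substitution 1.731%, insertion 2.204%, deletion 1.090%. The profile
*totals* (8.2%, 12.3%, 5.03%) are the operative targets the generator is
tested against; quoted one-decimal "average" error rates for these
platforms round slightly differently than the component sums.

Truncation is geometric-tailed per end (mean bases lost; 0 disables),
defaulting to a 100-nt-mean 5' truncation for ONT and none for PacBio
(HiFi-like). These magnitudes are configuration knobs producing ISM-like
partial reads, not calibrated claims about any instrument — real ONT
truncation length distributions are library- and basecaller-dependent.
Quality strings are constant at the Phred value of the profile's total
error rate; per-base quality realism is out of scope.

## Short-read generator

Fragments are sampled per transcript proportional to long-read TPM
(multinomial), with normal fragment lengths (mean 250, sd 25 — the
conventional defaults of transcript-level read simulators), clamped to
[read length, transcript length]. Mate 1 is the fragment's first 100 nt,
mate 2 the reverse complement of its last 100 nt; substitutions are uniform
i.i.d. at 0.5%. The truth table stores fragment coordinates in transcript
space; genomic coverage, junction-spanning read counts and read-start
positions are obtained by projecting through the exon structure, which has
identical semantics to aligning error-free reads but requires no aligner.

## CAGE model

TSS support is Bernoulli with
`logit(pi) = b0 + b1·X1 + b2·X2`, where `X1 = log` TSS ratio (mean
short-read coverage over the 100 bp downstream of the TSS over the 100 bp
upstream; pseudocount 0.01 added to both means) and `X2 = log` proportion
of reads starting in the 20-bp window downstream of the TSS (floored at
`1/(2·total reads)` so the log stays finite; all simulated fragments count
in the denominator). The fit is unpenalized maximum likelihood
(scikit-learn), reported with stratified k-fold cross-validated accuracy.

Peak geometry is kept as two *groups* — supporting and non-supporting —
each holding the joint empirical distribution of (length, signed
center-to-TSS distance), resampled as observed pairs so the
length–distance dependence is preserved. Supporting peaks are placed at
the sampled distance and clipped to overlap the TSS (overlap being their
defining property); non-supporting peaks are placed relative to a random
TSS with overlap disallowed, at the requested proportion of all peaks. No
pre-trained real-data model is shipped; `train` mode fits one from any
annotation + CAGE BED, and `CageLogisticModel.synthetic_default()`
provides a clearly-labelled synthetic stand-in for pipeline runs.

## Evaluation

A predicted multi-exon transcript is TP when its junction chain equals a
simulated *expressed* transcript's and both end offsets are ≤ 50 nt —
"within 50 nt" is taken inclusive, and the boundary is tested explicitly at
50 and 51. Junction match with an end beyond 50 nt is PTP. Mono-exon
predictions match overlapping mono-exon simulated transcripts under the
same end rule. The reference set is the simulated expressed transcripts,
not the whole reduced annotation: an annotated but never-simulated
transcript that a tool reports is an FP, symmetrically for known and novel.
Each simulated transcript can yield at most one TP (smallest maximum end
offset wins); redundant junction-matching predictions are FPs flagged as
duplicates, so sensitivity cannot be inflated by emitting copies.
Unmatched predictions are structurally classified against the reduced
annotation for per-category FP attribution. Metrics follow the formulas in
the README; 0/0 is reported as NA, never 0. Per-category precision uses
only TP and FP (PTP is reported separately through PDR/FDR). Gene-level
definitions: a simulated gene is detected when any of its expressed
isoforms is TP or PTP; predicted genes mapping to no simulated gene are
gene FPs.

## Synthetic fixtures

Fixtures lay out dedicated loci per category (see `fixtures.py` docstring)
along synthetic chromosomes, with i.i.d. uniform sequence and canonical
GT/AG dinucleotides planted at intron edges. Candidate guarantees are
verified by running the classifier on the generated annotation, not
assumed from construction. The fixtures emulate the *combinatorial*
structure that classification and evaluation depend on — junction sharing,
truncation, site recombination, locus overlap — and a long-tailed count
table for sample mode. They do not emulate realistic human gene
architecture, GC/repeat structure, paralogy, or expression correlation
between isoforms; tests passing on fixtures therefore validate the logic
and the stochastic calibration of the generators, not performance claims
about any particular organism or library.

## Problem sizes and numerical choices

The test suite and the acceptance script run the novelty-fidelity check at
1000 requested transcripts per novel category against fixtures guaranteeing
1250 candidates each (~27,000 transcripts, ~40 Mb of synthetic genome), and
measure error rates over ≥ 10⁶ template bases per platform — sizes at which
binomial standard errors are a few parts in 10⁴ and the checks are sharp.
Stochastic assertions use 3-standard-error bounds with fixed seeds.
Degenerate inputs are defined rather than erroring where a definition
exists: empty annotation → intergenic; zero coverage → TSS ratio 1; empty
metrics denominators → NA; `long_count` below the transcript count →
zero-read transcripts with a warning.

## Known limitations

* Error processes are i.i.d. per base: no homopolymer, k-mer-context or
  quality-correlated structure, and no chimeric/split reads.
* Junction "coverage" counts simulated junction-spanning mates from truth
  coordinates; a real aligner's mapping ambiguity is absent.
* Single-sample simulation only; no replicate or differential design.
* Mono-exon matching (classification and evaluation) uses strict
  containment/overlap rules; tools calibrated to slack-tolerant
  classifiers may see slightly stricter calls on mono-exon transcripts.
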