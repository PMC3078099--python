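# Methods

`polyamp` processes pooled, barcoded amplicon sequencing of polyploid
individuals: many samples, several gene regions, and — at nuclear loci of an
allotetraploid — up to four alleles per sample (two homeologous copies, up
to two alleles each) are sequenced together in one run and separated
computationally afterwards. This note documents the models and procedures,
the parameters that matter, what the synthetic data generator does and does
not emulate, and the numerical choices behind the implementation.

## Barcode words and the checksum

Each sample's amplicons carry a 4-base word at the 5' end of every read: a
3-bp barcode plus one checksum base, followed by a ligation T and the PCR
primer. With base indices A=0, C=1, G=2, T=3, the checksum base is chosen so
that the four indices sum to 0 mod 4. Exactly 64 of the 256 possible 4-mers
are valid, and any single-base miscall shifts the sum mod 4, so every single
substitution in the word is detected. Deconvolution is exact-match only:
words failing the checksum (`checksum_fail`), valid words absent from the
sample sheet (`unknown_word`), and reads too short or fragmented to carry a
word (`word_missing`) are discarded with a logged reason, never rescued.
The checksum detects substitutions; a deletion inside the word generally
shifts the frame and surfaces as either a checksum failure or an unknown
word, but no guarantee is made for indels.

## Region assignment and trimming

Reads are assigned to gene regions by fuzzy primer matching: each region's
forward and reverse primer is searched within the first 40 start positions
of the read, allowing at most 1 substitution (N counts as a mismatch).
Which primer matches determines the orientation — the ligation is
non-directional, so about half the molecules present the reverse primer
behind the barcode. A primer suffix of at least 10 bases at position 0
still assigns a region so that fragmented reads are counted as
`word_missing` rather than unmatched. Ties between regions are dropped as
`ambiguous`. The insert is excised between the 5' primer and the reverse
complement of the opposite primer; because errors in the 3' primer merely
shift a trim point (they cannot misassign a sample), that search tolerates
3 mismatches, with the library adapter and a partial primer prefix as
fallbacks for error-riddled or truncated tails. Reverse-orientation inserts
are reverse-complemented (and their qualities reversed) so all downstream
processing sees the forward strand. Internally all intervals are 0-based
half-open; written reports are 1-based closed.

## Quality control

Three steps, in order, per read:

1. **End trimming.** A 10-base window slides inward from each end until its
   mean phred quality reaches 15; the cut then advances to the first base
   at or above the threshold. A read may be consumed entirely.
2. **Masking.** Every base with quality below 15 becomes N. Qualities and
   length are unchanged; N never votes in any downstream comparison.
3. **Length filter.** Reads shorter than 100 bp are removed. The threshold
   is a deliberate floor — roughly a quarter of a 400-450 bp amplicon —
   below which a read cannot anchor an alignment usefully.

QC is idempotent. The window rule and the 100 bp floor are this package's
own defaults (exposed in `QcParams`); the Q15 mask matches the quality
cutoff used to define the post-QC error rate.

## Alignment and allele calling

Each (sample, region) read group is star-aligned: the longest read (ties
broken by smallest identifier) is the pivot, every other read is aligned to
it with affine gap costs (match +2, mismatch −2, N neutral, gap open −8,
extend −1, end gaps free), and the pairwise alignments are merged
column-wise ("once a gap, always a gap"). Leading and trailing gaps record
truncation, not deletion, and are treated as missing data.

Alleles are called from the alignment in four steps:

1. **Variable columns.** A column is variable only if at least two distinct
   non-N symbols are each carried by ≥2 reads. Variation supported by a
   single read is indistinguishable from PCR/sequencing error and never
   counts toward allele differences.
2. **Leader clustering.** Reads are visited most-informative first and join
   the largest cluster whose majority pattern they do not contradict at any
   mutually determined variable column; a read conflicting with every
   cluster founds a new one. Masked (N) and uncovered positions are
   wildcards.
3. **Consistency merging.** Two clusters are distinct alleles only if they
   differ *consistently* at ≥2 (`min_diff`) variable columns — at each such
   column, more than 80% (`consistency`) of each cluster's informative
   reads must carry its consensus base. Clusters failing this against some
   equal-or-larger cluster are merged into it. Columns inside mononucleotide
   runs longer than 5 bp (measured on the ungapped consensus, including
   adjacent gap columns) never count: length variation there is unreliable
   in pyrosequencing-style data.
4. **Flags.** Clusters with fewer than 2 supporting reads or below 5% of
   the group are flagged `low_support`; when more unflagged alleles remain
   than the locus ploidy allows (2 × expected copies), the lowest-support
   extras are flagged `surplus`. Flagged calls are excluded from copy
   analysis and handed to the chimera scan.

Consensus is the per-column majority over {A, C, G, T, −}; ties resolve to
the symbol backed by the highest summed per-base quality (erroneous calls
carry low scores by construction of the masking threshold), then
alphabetically. Terminal columns with no coverage in a cluster are dropped
from its consensus rather than reported as N.

The one-read-cannot-found-an-allele floor has a visible consequence used
throughout the tests: a truth allele that drew fewer than 2 reads is
unobservable *by design*, which is precisely the sampling risk the depth
model below quantifies. Recovery statistics therefore condition on alleles
with ≥2 emitted reads.

## Homeologous copy partition

For a two-copy nuclear region, all unflagged allele consensi across samples
are star-aligned and single-linkage clustered on the count of disagreeing
columns; the tree is cut into two groups, accepted only if the mean
between-group distance exceeds twice the largest within-group distance
(otherwise all alleles stay `unassigned` with a warning). The group with
more supporting reads is labelled B — copy B consistently over-amplifies in
this system — and alleles are numbered per sample within each copy (A1, A2,
B1, B2). The partition reports:

- **fixed differences**: columns where every A member carries one base and
  every B member a different base (gap-free columns only);
- **shared polymorphisms**: columns polymorphic within both groups with the
  same segregating bases — evidence against clean copy separation, expected
  to be zero for functionally diploidized homeologues;
- **diagnostic indels**: maximal column blocks gapped in all of one group
  and none of the other, e.g. the 7-bp indel separating one nuclear copy
  pair.

`code_indels` converts shared gap blocks (identical start and end, carried
by ≥2 sequences but not all) into appended binary columns written as a/c,
so that downstream distance software weights each indel as one
transversion. Singleton blocks and blocks inside >5 bp mononucleotide runs
are not scored.

## Sequencing error rate

Within a single-copy (plastid) region, every read of a sample should match
the sample consensus, so the error rate is estimated as non-consensus,
non-N calls divided by all non-N calls, over columns containing no gaps
(length variation excluded — the same exclusions that define the masking
step). On synthetic data this estimator tracks the realized post-mask
substitution rate (injected errors that escaped masking) to well within
binomial error.

## PCR-recombinant (chimera) detection

A PCR chimera is a read whose two ends derive from different template
alleles. Candidates are the flagged calls of a group (low-support or
surplus); common alleles are the unflagged calls at ≥5% of group reads, and
at least two must exist. A candidate is recombinant iff some breakpoint
splits it into a prefix within 1 mismatch (`parent_tolerance`) of common
allele X over ≥30 matched bases (`min_segment`) and a suffix likewise
matching a different common allele Y — while the candidate matches no
single common allele within 2 mismatches overall. N columns are neutral;
gap columns within coverage count as mismatches. The reported breakpoint
interval is the full column range over which the split holds, for the
parent pair supporting the most breakpoints.

Multi-read candidates whose consensus scans clean are additionally scanned
read by read: chimeras with the same parents but different breakpoints
co-cluster into a consensus with no single junction, yet every member read
has one; the cluster is called recombinant only if all members are.
Recombinant-flagged reads are excluded from the "useful read" counts.

Two structural limits follow directly from the rule and are not defects of
the detector: a chimera whose breakpoint leaves fewer than the tolerated
number of diagnostic sites on one flank is, operationally, its majority
parent plus PCR error and is absorbed harmlessly into that allele; and a
candidate carrying ≥2 unmasked sequencing errors in one flank can exceed
the per-segment tolerance. Sensitivity statements in the tests are
therefore made over *rule-resolvable* chimeras — those lying more than 2
real substitutions from every common allele — where the detector flags
91-98% across seeds, with no recombinant verdicts on true alleles.

## Read depth: the inverse coupon collector

With allele proportions p₁…p_k, the probability that n reads drawn with
replacement contain every allele is, by inclusion-exclusion over subsets S:

    P(n) = Σ_S (−1)^|S| (1 − Σ_{i∈S} p_i)^n

`min_reads(p, c)` returns the smallest n with P(n) ≥ c. The analytic engine
is exact and deterministic; a multinomial Monte-Carlo estimator (default
10,000 replicates) is kept as a cross-check and for fidelity to the
original simulation design. For four equal alleles the 95% threshold falls
between 15 and 16 reads — P(15) = 0.9467, P(16) = 0.9600 — so the analytic
minimum is 16, consistent with the simulation-based "at least 15" within
Monte-Carlo error. A B:A copy ratio r maps to the two-category vector
(1, r)/(1+r); with r = 1.29 both copies are seen with 95% confidence at 6
reads, and unequal four-allele cases split each copy's mass equally between
its alleles unless explicit proportions are given.

Whether allele amplification is in fact even is tested by regressing copy-B
read counts on copy-A counts per sample, forced through the origin:
slope = ΣAB/ΣA², with the standard error from the residual variance of the
origin-forced fit, and t = (slope − 1)/SE on n − 1 degrees of freedom
(two-sided). A perfect proportional fit has SE 0 and reports t = ∞ with a
note.

## The synthetic data generator

`simdata.simulate_dataset` emulates a pooled quarter-plate-style run and is
the package's test bed. Default study conditions:

- **Design**: 16 tetraploid samples × 5 regions — three single-copy plastid
  regions (~400-440 bp, 2 region haplotypes) and two nuclear regions with
  diverged homeologous copies: one 475 bp pair separated by 19 fixed
  substitutions plus a 7-bp indel with B:A read ratio 1.29, one 412 bp pair
  separated by 35 fixed substitutions plus four indels of 1-4 bp with ratio
  1.87. Each copy has two alleles differing by 4 substitutions; a sample is
  heterozygous at a copy with probability 0.6.
- **Reads**: full-amplicon reads in the barcode-word + T + primer + insert
  + reverse-primer + adapter layout, forward or reverse orientation with
  equal probability; 30-80 reads per (sample, region), uniform (a negative
  binomial option reproduces more over-dispersed yields); an optional
  truncation model draws lengths from N(278, 153) clipped at 40 bp.
- **Errors**: each base substituted independently at rate 0.005 (applied to
  the whole read, so ~2% of reads draw an error inside the 4-base barcode
  word and exercise the checksum, matching the observed rejection rate).
  Correct bases draw qualities from N(34, 5); erroneous bases receive
  sub-threshold quality (masked to N by QC) with probability 0.8, leaving a
  ~0.1% post-mask residual — the order of the 0.13% residual error the
  workflow is calibrated against.
- **Chimeras**: 3% of nuclear reads are single-junction recombinants of two
  of the sample's alleles, one from each copy, with the breakpoint uniform
  at least 30 bp from both ends and mapped through a pairwise alignment of
  the parents so the junction carries no spurious indel (template switching
  resumes at the homologous position). Within-copy chimeras are not
  generated: at ~4 substitutions between sister alleles they fall below the
  2-bp stringency and are operationally identical to PCR point errors.
- **Truth tables** record every allele, every read's source (or parent pair
  and breakpoint), injected error positions, and dropout cells, enabling
  exact round-trip evaluation.

What the generator does **not** emulate: flowgram-space homopolymer errors
(substitution-only by default), primer-binding bias, PCR duplicates,
cross-sample contamination, or quality decay along the read. Passing tests
on this generator therefore demonstrate the logic of deconvolution, QC,
allele separation and chimera detection — not robustness to every 454
artifact; in particular, real homopolymer indel noise is handled only
insofar as the >5 bp repeat exclusions discard it.

## Problem sizes and determinism

End-to-end checks run at 16 samples × 5 regions with 30-80 reads per cell
(≈4,400 reads, ≈150 truth alleles), once error-free and once at the 0.5%
error / 3% chimera condition; unit tests use 4-8 samples and 300-360 bp
regions. All stochastic components thread a single seeded NumPy generator:
the same seed reproduces byte-identical datasets, and Monte-Carlo
routines accept explicit seeds. Consensus ties, cluster visit order,
pivot selection and label assignment are all deterministic.

## Known limitations

- A chimeric haplotype amplified early enough to reach ≥2 reads at the same
  breakpoint presents as a legitimate minority allele; it is caught only
  when it exceeds the ploidy limit (surplus) or stays under the 5%
  minority threshold. A paired repeat of the same individual remains the
  reliable guard, as in the original repeatability design.
- Only two-parent, single-junction chimeras are modelled and detected.
- The copy partition assumes exactly two homeologous copy groups; loci with
  a genuinely duplicated copy (more than two groups) surface as surplus
  alleles and separation warnings rather than a three-way split.
- `estimate_error_rate` requires a single-copy region; it has no model for
  allele mixtures.
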