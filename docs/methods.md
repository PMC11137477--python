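# Methods

`liftcompare` compares a gene annotation on a reference assembly with the same
annotation lifted onto a target assembly. Its working assumption is the
lift-over contract: feature IDs are preserved, so identity of a gene or
transcript ID across the two annotations means "the same feature", and every
comparison reduces to sequence- and coordinate-level questions about matched
IDs. Three analyses are built on that contract — per-transcript variant
effects, gene-order synteny, and paralog copy number — plus a synthetic-genome
generator that provides ground truth for all of them.

## Pairwise alignment

All sequence comparisons use global (Needleman–Wunsch) alignment with affine
gap penalties, computed by Biopython's `PairwiseAligner` (Gotoh algorithm,
end gaps penalized). Conventions fixed by this package:

* A gap of length L costs `gap_open + (L−1)·gap_extend`.
* Nucleotide defaults: match +1, mismatch −1, gap open 2, gap extend 1.
  IUPAC ambiguity codes (N, R, Y, …) score −1 against everything, including
  themselves, and never count as matches: an uncertain base should not inflate
  identity. Protein defaults: BLOSUM62, gap open 11, gap extend 1 — the
  conventional defaults of the alignment-library ecosystem; all are
  configurable on the CLI (`--nt-match`, `--gap-open`, `--protein-matrix`, …).
* Percent identity = identical aligned columns / total alignment columns, so
  gap columns count against identity. This is the strictest common definition
  and makes indels visible in the identity number, which the variant-effect
  rules rely on.
* Among co-optimal alignments the first in the aligner's deterministic
  enumeration order is used, making every downstream call and output file
  bit-reproducible across runs on the same inputs.

Translation uses the standard genetic code only (no selenocysteine or
readthrough handling). Internal stop codons are emitted as `*` — they are
evidence for the stop-gain rule, not errors; one trailing stop is trimmed and
a trailing partial codon is dropped.

## Variant effects

For every reference transcript: if its ID is absent from the target, it is
`unmapped`. Otherwise the spliced transcripts are aligned for a nucleotide
identity; if both annotations give the transcript a CDS, the CDS pair and the
translated proteins are aligned as well and effects are detected on the CDS
alignment (not the whole-transcript alignment — the taxonomy is
protein-centric, so a UTR-only change yields nt identity < 1 with effect
`identical`; both numbers are reported so users can re-bin).

Detection rules, each firing independently:

* **Truncations.** Three or more target-row gap columns in a terminal region
  of the CDS alignment — before the target's third aligned base (5′) or after
  its third-from-last (3′) — remove the reference start or stop codon and are
  called 5′/3′ truncation. Aggregating over a terminal *region* rather than
  requiring a single gap run that touches the exact first/last column makes
  the call robust to co-optimal alignments that anchor one or two
  chance-matching target bases beyond the deleted terminus; fewer than one
  codon of aligned sequence at a terminus is not evidence the terminus
  survived. Truncation gaps are excluded from the indel rules below.
* **Frameshift / in-frame indels.** Any remaining gap run with length ≢ 0
  (mod 3) is a frameshift; multiple-of-3 runs are in-frame deletions (target
  gaps) or insertions (reference gaps). Terminal reference-row gaps (extra
  target sequence at a CDS end) have no category of their own and are
  classified by the same length rule. Each run is classified independently,
  so a frameshift with a nearby compensatory indel still reports frameshift
  while its protein identity stays high.
* **Start loss.** The target bases aligned across the reference start codon
  contain no gap and do not read ATG. Defined on the reference start codon's
  columns so that start loss (a point mutation) and 5′ truncation (a deletion)
  are mutually exclusive.
* **Stop gain.** The aligned target protein contains `*` strictly before the
  column of the reference protein's last residue.
* **Synonymous / nonsynonymous.** Nonsynonymous: any substitution column in
  the protein alignment. Synonymous: substitution columns in the CDS
  alignment but identical proteins. Identical: identical CDS.

Because a transcript may carry several variants and the goal is a one-line
functional summary, only the most severe detected effect is reported. The
severity order (least → most) is: identical, synonymous, nonsynonymous,
in-frame deletion, in-frame insertion, 5′ truncation, 3′ truncation, start
loss, stop gain, frameshift. Only synonymous < frameshift is dictated by the
method's worked example; the rest is this package's ordering by expected
functional disruption and can be overridden (`severity_ranks`).

## Synteny

Genes present in both annotations are sorted by (chromosome, start
coordinate, gene ID) within each annotation and given ordinal positions
1..N; each gene is a point at (reference ordinal, target ordinal). Chromosome
order is the order of first appearance among that annotation's gene records —
file order, so the two annotations may use different chromosome naming.
Ordinals are computed over the shared gene set only and are therefore always
dense permutations of 1..N on both axes.

The dot plot colors points by sequence identity, interpolating green
(identity 1.0) to red (identity ≤ 0.5, the configurable floor; the endpoints
are this package's choice). Identity comes from the lift-over's `sequence_ID`
attribute when the target annotation carries one, is otherwise recomputed by
aligning the longest isoform's transcripts, and can be skipped (`--no-align`,
gray points). Gray lines mark chromosome boundaries on both axes.

Two rearrangement summaries are available. The order edit distance is the
Levenshtein distance between the two genome-wide gene-ID sequences
(chromosomes concatenated in the order above; one gene = one symbol;
`--per-chromosome` additionally reports one distance per reference
chromosome, restricted to genes on that chromosome in both annotations). The
translocation count is the number of genes whose chromosome assignment
differs between the annotations. The latter is the right per-gene signal:
ordinal inequality cannot count translocations, because relocating a single
gene shifts the ordinal of every gene between its old and new positions by
one — a permutation cannot differ from the identity at exactly one point —
so the ordinal-mismatch count scales with the distance moved, not with the
number of moved genes.

## Paralog clusters and copy number

Each gene contributes one sequence: the translated CDS of its longest spliced
isoform if coding (ties broken by smaller transcript ID), else the spliced
transcript; protein and nucleotide sequences are never compared to each
other. Two genes may share a cluster when they are ≥ 90% identical across
≥ 90% of both of their lengths (`--min-seq-id`, `--min-coverage`). The
coverage test decomposes into a length-ratio bound (the shorter sequence is
≥ 90% of the longer) plus an aligned-span bound (within the mutually aligned
region, ≥ 90% of each sequence's residues are present) — the alignment-level
meaning of bidirectional coverage.

Clustering is greedy and representative-based with exact global alignment:
genes in decreasing length order (ties by ID) either join the oldest existing
cluster whose representative passes the criterion or found a new one. This
trades the k-mer prefilter heuristics of dedicated clustering engines for
exactness and full determinism, which desk-scale inputs afford.

Target clusters are derived by dropping members absent from the target and
attaching each extra gene copy (target-only IDs of the form
`<gene>_<n>`, the convention of lift-over copy search, configurable via
`--copy-suffix`) to its source gene's cluster, recorded against the cluster
member with the highest alignment identity to the copy (ties to the smaller
ID). The search is restricted to the source gene's own cluster because the
copy's ID already names its origin. Per cluster, the target-minus-reference
member count is the copy-number delta; the summary totals clusters and copies
gained and lost. Without extra copies in the target annotation only losses
can be observed.

## Synthetic genomes and ground truth

The generator builds a reference genome from an explicit blueprint:
chromosomes are alternations of random intergenic spacers (50–150 bp) and
gene models on either strand. Coding genes have a complete ORF of 60–120
codons (ATG start, single terminal stop, no internal stops), 10–30 bp UTRs,
and 1–3 exons separated by 20–60 bp introns; noncoding genes are 200–400 bp.
These sizes keep every alignment in the test suite fast while leaving room
for internal events at least 9 nt from CDS ends; they model gene structure,
not genome composition (no repeats, no isoforms, no sequencing error), so
passing tests demonstrate correctness of the comparison logic, not robustness
to repetitive or noisy real genomes.

Mutations are applied to the blueprint, never to flat sequences, so exon cut
points and downstream coordinates shift consistently, and the mutated
blueprint is re-realized into the target genome. One event per gene keeps
expected labels unambiguous; each spec carries its own seed, recorded in the
truth table. Event classes cover the nine effect categories, a
synonymous+frameshift composite (whose expected reduction is frameshift),
gene deletion, gene duplication (copies named `<gene>_<n>`, optionally with
~2% codon-level substitutions), and translocation between chromosomes. The
truth table states the expected effect label, copy-number delta and
chromosome move per gene; applying an empty spec list reproduces the
reference byte-for-byte.

## Numerical and degenerate-input choices

* Both-empty alignment input is an error; one empty side yields an all-gap
  alignment scored as a single terminal gap.
* `percent_identity` on a zero-column alignment is an error.
* Features on sequences absent from the FASTA, or extending past a sequence
  end, are hard errors — silent truncation would corrupt every identity
  downstream.
* Target-only gene IDs that match no reference gene even after suffix
  stripping are reported and excluded from all analyses.
* All tie-breaks (isoform length ties, equal start coordinates, clustering
  order, equal-identity paralog attachment) resolve lexicographically by ID.

## Problem sizes

The test suite and the acceptance script run on genomes of 15–90 genes over
1–3 chromosomes, 1,000 random alignment-oracle pairs of length ≤ 8, all
permutations of ≤ 6 symbols (plus sampled permutations of 7–8) for the edit
distance oracle, and protein families of 250–300 residues — sizes at which
exact alignment-based clustering and brute-force oracles are comfortably
exact, chosen so the whole validation completes in seconds.

## Known limitations

* Alignment gap parameters and the identity denominator are conventions, not
  published values; counts on real data shift with these settings.
* Trans-splicing, selenoproteins, and transcript-level isoform differences
  between annotations are out of scope.
* The greedy representative clustering can split families whose members chain
  through intermediates (single-linkage would merge them); the 90/90
  criterion is evaluated against cluster representatives.
* The severity order beyond synonymous < frameshift is a modeling choice;
  downstream users can re-rank.
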