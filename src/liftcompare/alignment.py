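"""Global pairwise alignment with affine gaps, percent identity, and translation.

Needleman–Wunsch global alignment is delegated to Biopython's C-implemented
``PairwiseAligner`` (Gotoh affine gaps, end gaps penalized). This module fixes
the scoring conventions the rest of the toolkit relies on:

* a gap of length L costs ``gap_open + (L - 1) * gap_extend``;
* nucleotide scoring is match/mismatch over A/C/G/T, with IUPAC ambiguity
  codes (N, R, Y, ...) always scored as mismatches — even against themselves —
  and excluded from the match count, so uncertain bases never inflate identity;
* protein scoring uses a named substitution matrix (BLOSUM62 by default) whose
  alphabet includes ``*``, so premature stops arising from frameshifts align
  like any other residue;
* among co-optimal alignments the first in the aligner's deterministic
  enumeration order is returned, making every downstream effect call and
  output file bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .annotation_io import LiftCompareError

NT_ALPHABET = "ACGTUNRYSWKMBDHV"
UNAMBIGUOUS_NT = set("ACGT")
STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution scores plus affine gap penalties for one alphabet.

    ``gap_open``/``gap_extend`` are non-negative penalties; a length-L gap
    costs ``gap_open + (L - 1) * gap_extend``.
    """

    alphabet: str                      # "nucleotide" | "protein"
    match: int = 1
    mismatch: int = -1
    matrix_name: str | None = None     # protein only
    gap_open: int = 2
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")

    @classmethod
    def nucleotide(cls, match: int = 1, mismatch: int = -1,
                   gap_open: int = 2, gap_extend: int = 1) -> "ScoringScheme":
        return cls("nucleotide", match=match, mismatch=mismatch,
                   gap_open=gap_open, gap_extend=gap_extend)

    @classmethod
    def protein(cls, matrix: str = "BLOSUM62",
                gap_open: int = 11, gap_extend: int = 1) -> "ScoringScheme":
        return cls("protein", matrix_name=matrix, gap_open=gap_open,
                   gap_extend=gap_extend)

    def score(self, x: str, y: str) -> float:
        """Substitution score for one symbol pair (symmetric)."""
        if self.alphabet == "nucleotide":
            if x == y and x in UNAMBIGUOUS_NT:
                return self.match
            return self.mismatch
        matrix = _protein_matrix(self.matrix_name or "BLOSUM62")
        return matrix[x, y]

    def substitution_matrix(self):
        if self.alphabet == "nucleotide":
            return _nt_matrix(self.match, self.mismatch)
        return _protein_matrix(self.matrix_name or "BLOSUM62")

    def is_match(self, x: str, y: str) -> bool:
        """Whether a column counts toward identity (ambiguity codes never do)."""
        if x != y:
            return False
        if self.alphabet == "nucleotide":
            return x in UNAMBIGUOUS_NT
        return x != "X"


@lru_cache(maxsize=None)
def _nt_matrix(match: int, mismatch: int):
    m = substitution_matrices.Array(NT_ALPHABET, dims=2)
    for x in NT_ALPHABET:
        for y in NT_ALPHABET:
            m[x, y] = match if (x == y and x in UNAMBIGUOUS_NT) else mismatch
    return m


@lru_cache(maxsize=None)
def _protein_matrix(name: str):
    return substitution_matrices.load(name)


@dataclass
class PairwiseAlignment:
    """Two gap-padded sequences of equal length plus score and match count."""

    aligned_a: str
    aligned_b: str
    score: float
    matches: int = field(init=False)
    columns: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences differ in length")
        self.columns = len(self.aligned_a)
        # matches are recomputed by global_align with scheme awareness; the
        # plain-equality default covers manually built alignments in tests
        self.matches = sum(1 for x, y in zip(self.aligned_a, self.aligned_b)
                           if x == y and x != "-")


@lru_cache(maxsize=None)
def _aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = scheme.substitution_matrix()
    aligner.open_gap_score = -scheme.gap_open
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def _gap_cost(length: int, scheme: ScoringScheme) -> float:
    return scheme.gap_open + (length - 1) * scheme.gap_extend if length else 0


def global_align(a: str, b: str, scheme: ScoringScheme | None = None) -> PairwiseAlignment:
    """Optimal global alignment of *a* and *b* under *scheme*.

    Defaults to the nucleotide scheme. One empty input yields an all-gap
    alignment against the other; two empty inputs are an error.
    """
    if scheme is None:
        scheme = ScoringScheme.nucleotide()
    if not a and not b:
        raise LiftCompareError("cannot align two empty sequences")
    if not a or not b:
        other = a or b
        aln = PairwiseAlignment("-" * len(other) if not a else a,
                                "-" * len(other) if not b else b,
                                score=-_gap_cost(len(other), scheme))
        aln.matches = 0
        return aln
    try:
        result = _aligner(scheme).align(a, b)
    except ValueError as exc:  # symbol outside the matrix alphabet
        raise LiftCompareError(f"cannot align: {exc}") from exc
    best = result[0]
    aligned_a, aligned_b = str(best[0]), str(best[1])
    aln = PairwiseAlignment(aligned_a, aligned_b, score=best.score)
    aln.matches = sum(1 for x, y in zip(aligned_a, aligned_b)
                      if x != "-" and y != "-" and scheme.is_match(x, y))
    return aln


def percent_identity(aln: PairwiseAlignment) -> float:
    """Identity as matches over total alignment columns (gaps count against)."""
    if aln.columns == 0:
        raise LiftCompareError("alignment has no columns")
    return aln.matches / aln.columns


def translate(cds: str) -> str:
    """Translate a CDS with the standard genetic code.

    Internal stop codons are emitted as ``*`` (they are evidence of variant
    effects, not errors); one trailing stop is trimmed; a trailing partial
    codon is dropped. Sequences shorter than one codon are an error.
    """
    if len(cds) < 3:
        raise LiftCompareError(f"CDS of length {len(cds)} is shorter than one codon")
    trimmed = cds[:len(cds) - len(cds) % 3]
    protein = str(Seq(trimmed).translate(table=1))
    if protein.endswith("*"):
        protein = protein[:-1]
    return protein
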