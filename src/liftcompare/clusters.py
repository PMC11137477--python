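"""Paralog clustering and gene copy-number comparison.

Reference genes are grouped into paralog families: two genes belong together
when they are at least 90% identical across at least 90% of both of their
lengths (both thresholds adjustable). Protein-coding genes are clustered on
the amino acid sequence of their longest isoform, noncoding genes on the
nucleotide sequence; the two alphabets never mix.

Clustering is greedy and representative-based: genes are processed in
decreasing sequence length (ties by ID) and each joins the first existing
cluster whose representative passes the identity/coverage test, else founds a
new cluster. With exact global alignment behind the test this is affordable at
desk scale and fully deterministic.

Target clusters are derived from reference clusters by dropping genes absent
from the target and attaching extra gene copies (IDs suffixed by the upstream
mapper's copy search) to the cluster of their closest paralog; the per-cluster
size difference is the copy-number gain or loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .alignment import ScoringScheme, global_align, percent_identity, translate
from .annotation_io import (Annotation, Assembly, FeatureMatch, LiftCompareError,
                            extract_cds_sequence, extract_transcript_sequence,
                            longest_isoform)


@dataclass
class ClusterInput:
    """One gene's clustering sequence: the longest isoform's protein or RNA."""

    gene_id: str
    sequence: str
    alphabet: str  # "protein" | "nucleotide"


@dataclass
class Cluster:
    cluster_id: str
    representative: str
    members: list[str]


@dataclass
class ClusterComparison:
    cluster_id: str
    ref_members: list[str]
    tgt_members: list[str]
    #: extra-copy ID -> the cluster member it is closest to by identity
    attachments: dict[str, str] = field(default_factory=dict)

    @property
    def ref_count(self) -> int:
        return len(self.ref_members)

    @property
    def tgt_count(self) -> int:
        return len(self.tgt_members)

    @property
    def delta(self) -> int:
        return self.tgt_count - self.ref_count


def build_cluster_inputs(asm: Assembly, ann: Annotation,
                         gene_ids: list[str] | None = None,
                         id_map: dict[str, str] | None = None) -> list[ClusterInput]:
    """Clustering sequence per gene: translated CDS if the longest isoform is
    coding, spliced transcript otherwise.

    ``id_map`` relabels output gene IDs (used when extracting extra-copy
    sequences whose annotation IDs carry the copy suffix).
    """
    inputs = []
    for gid in gene_ids if gene_ids is not None else ann.gene_ids():
        tid = longest_isoform(ann, gid)
        cds = extract_cds_sequence(asm, ann, tid)
        out_id = (id_map or {}).get(gid, gid)
        if cds is not None and len(cds) >= 3:
            inputs.append(ClusterInput(out_id, translate(cds), "protein"))
        else:
            inputs.append(ClusterInput(out_id, extract_transcript_sequence(asm, ann, tid),
                                       "nucleotide"))
    return inputs


def _scheme_for(alphabet: str, nt_scheme: ScoringScheme | None,
                aa_scheme: ScoringScheme | None) -> ScoringScheme:
    if alphabet == "protein":
        return aa_scheme or ScoringScheme.protein()
    return nt_scheme or ScoringScheme.nucleotide()


def pair_identity(a: ClusterInput, b: ClusterInput,
                  nt_scheme: ScoringScheme | None = None,
                  aa_scheme: ScoringScheme | None = None) -> float:
    """Global-alignment identity (matches / columns) of two same-alphabet genes."""
    if a.alphabet != b.alphabet:
        raise LiftCompareError(
            f"cannot align {a.alphabet} {a.gene_id!r} against {b.alphabet} {b.gene_id!r}")
    return percent_identity(global_align(a.sequence, b.sequence,
                                         _scheme_for(a.alphabet, nt_scheme, aa_scheme)))


def pair_similar(a: ClusterInput, b: ClusterInput,
                 min_id: float = 0.9, min_cov: float = 0.9,
                 nt_scheme: ScoringScheme | None = None,
                 aa_scheme: ScoringScheme | None = None) -> bool:
    """Whether two genes meet the identity-and-bidirectional-coverage criterion.

    Requires (1) alignment identity >= ``min_id``; (2) the shorter sequence at
    least ``min_cov`` of the longer one's length; (3) the mutually aligned
    span (columns between the terminal gaps of either row) covering at least
    ``min_cov`` of each sequence.
    """
    if a.alphabet != b.alphabet:
        raise LiftCompareError("mixed-alphabet comparison attempted")
    la, lb = len(a.sequence), len(b.sequence)
    if min(la, lb) < min_cov * max(la, lb):
        return False
    aln = global_align(a.sequence, b.sequence,
                       _scheme_for(a.alphabet, nt_scheme, aa_scheme))
    if percent_identity(aln) < min_id:
        return False
    for own, other in ((aln.aligned_a, aln.aligned_b), (aln.aligned_b, aln.aligned_a)):
        non_gap = [i for i, c in enumerate(other) if c != "-"]
        lo, hi = non_gap[0], non_gap[-1]
        covered = sum(1 for c in own[lo:hi + 1] if c != "-")
        if covered < min_cov * len(own.replace("-", "")):
            return False
    return True


def cluster_reference(inputs: list[ClusterInput],
                      min_id: float = 0.9, min_cov: float = 0.9,
                      nt_scheme: ScoringScheme | None = None,
                      aa_scheme: ScoringScheme | None = None) -> list[Cluster]:
    """Greedy representative-based clustering of the reference genes.

    Deterministic: inputs sorted by decreasing length then ID; each joins the
    first (oldest) cluster whose representative it matches, else founds one.
    """
    by_id = {}
    for inp in inputs:
        if inp.gene_id in by_id:
            raise LiftCompareError(f"duplicate clustering input for {inp.gene_id!r}")
        by_id[inp.gene_id] = inp
    ordered = sorted(inputs, key=lambda i: (-len(i.sequence), i.gene_id))
    clusters: list[Cluster] = []
    for inp in ordered:
        placed = False
        for cl in clusters:
            rep = by_id[cl.representative]
            if rep.alphabet != inp.alphabet:
                continue
            if pair_similar(inp, rep, min_id, min_cov, nt_scheme, aa_scheme):
                cl.members.append(inp.gene_id)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(f"cluster_{len(clusters) + 1}",
                                    representative=inp.gene_id,
                                    members=[inp.gene_id]))
    return clusters


def derive_target_clusters(ref_clusters: list[Cluster], match: FeatureMatch,
                           ref_inputs: list[ClusterInput],
                           extra_inputs: list[ClusterInput] | None = None,
                           nt_scheme: ScoringScheme | None = None,
                           aa_scheme: ScoringScheme | None = None,
                           ) -> list[ClusterComparison]:
    """Target-side cluster membership and per-cluster copy-number change.

    Genes absent from the target are dropped; each extra copy joins the
    cluster of its source gene, recorded against its closest paralog there
    (highest global-alignment identity; ties to the smaller gene ID). Extra
    copies whose source gene was never clustered are skipped (reported in the
    returned comparisons' attachments as absent).
    """
    ref_by_id = {i.gene_id: i for i in ref_inputs}
    extra_by_id = {i.gene_id: i for i in (extra_inputs or [])}
    cluster_of: dict[str, Cluster] = {m: cl for cl in ref_clusters for m in cl.members}
    comparisons = {cl.cluster_id: ClusterComparison(
        cl.cluster_id,
        ref_members=list(cl.members),
        tgt_members=[m for m in cl.members if m in match.shared_gene_ids])
        for cl in ref_clusters}

    for copy_id in sorted(match.extra_copy_ids):
        source = match.extra_copy_ids[copy_id]
        cl = cluster_of.get(source)
        if cl is None or copy_id not in extra_by_id:
            continue
        copy_inp = extra_by_id[copy_id]
        best: tuple[float, str] | None = None
        for member in cl.members:
            member_inp = ref_by_id.get(member)
            if member_inp is None or member_inp.alphabet != copy_inp.alphabet:
                continue
            ident = pair_identity(copy_inp, member_inp, nt_scheme, aa_scheme)
            if best is None or ident > best[0] or (ident == best[0] and member < best[1]):
                best = (ident, member)
        comp = comparisons[cl.cluster_id]
        comp.tgt_members.append(copy_id)
        comp.attachments[copy_id] = best[1] if best else source
    return [comparisons[cl.cluster_id] for cl in ref_clusters]


@dataclass
class CopyNumberSummary:
    clusters_lost: int
    clusters_gained: int
    clusters_unchanged: int
    copies_lost: int
    copies_gained: int
    min_cluster_size: int
    max_cluster_size: int


def summarize_copy_number(comparisons: list[ClusterComparison]) -> CopyNumberSummary:
    deltas = [c.delta for c in comparisons]
    sizes = [c.ref_count for c in comparisons] or [0]
    return CopyNumberSummary(
        clusters_lost=sum(d < 0 for d in deltas),
        clusters_gained=sum(d > 0 for d in deltas),
        clusters_unchanged=sum(d == 0 for d in deltas),
        copies_lost=sum(-d for d in deltas if d < 0),
        copies_gained=sum(d for d in deltas if d > 0),
        min_cluster_size=min(sizes),
        max_cluster_size=max(sizes),
    )


def write_clusters_tsv(comparisons: list[ClusterComparison], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("cluster_id\tref_count\ttgt_count\tref_members\ttgt_members\n")
        for c in comparisons:
            out.write(f"{c.cluster_id}\t{c.ref_count}\t{c.tgt_count}\t"
                      f"{','.join(c.ref_members)}\t{','.join(c.tgt_members)}\n")


def write_cluster_summary(summary: CopyNumberSummary, path: str | Path) -> None:
    with open(path, "w") as out:
        out.write(f"clusters_with_copy_loss\t{summary.clusters_lost}\n"
                  f"clusters_with_copy_gain\t{summary.clusters_gained}\n"
                  f"clusters_unchanged\t{summary.clusters_unchanged}\n"
                  f"total_copies_lost\t{summary.copies_lost}\n"
                  f"total_copies_gained\t{summary.copies_gained}\n"
                  f"cluster_size_min\t{summary.min_cluster_size}\n"
                  f"cluster_size_max\t{summary.max_cluster_size}\n")
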