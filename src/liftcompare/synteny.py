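"""Gene-order comparison between two annotations.

Each gene present in both annotations receives an ordinal position in each
genome (genes sorted by chromosome, then start coordinate, then gene ID), and
the pairs are drawn as a dot plot: collinear genomes put every point on the
main diagonal, translocations and reorderings fall off it. Point color encodes
sequence identity (green high, red low). Optionally the Levenshtein edit
distance between the two gene orders quantifies the overall rearrangement.

Chromosome order within one genome is the order of first appearance of each
chromosome among that annotation's gene records — file order, so reference and
target may use entirely different chromosome naming.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .annotation_io import Annotation, FeatureMatch, LiftCompareError


@dataclass
class SyntenyRecord:
    gene_id: str
    ref_ordinal: int
    tgt_ordinal: int
    ref_chrom: str
    tgt_chrom: str
    identity: float | None = None


def chromosome_order(ann: Annotation, gene_ids: set[str] | None = None) -> list[str]:
    """Chromosomes in order of first appearance among (selected) gene records."""
    order: list[str] = []
    for gene in ann.genes:
        if gene_ids is not None and gene.id not in gene_ids:
            continue
        if gene.seqid not in order:
            order.append(gene.seqid)
    return order


def ordinal_positions(ann: Annotation, gene_ids: set[str],
                      chrom_order: list[str]) -> dict[str, int]:
    """Rank 1..N of each selected gene under (chromosome, start, ID) sorting."""
    rank = {c: i for i, c in enumerate(chrom_order)}
    genes = [g for g in ann.genes if g.id in gene_ids]
    missing = gene_ids - {g.id for g in genes}
    if missing:
        raise LiftCompareError(f"genes not in annotation: {sorted(missing)[:5]}")
    for g in genes:
        if g.seqid not in rank:
            raise LiftCompareError(f"gene {g.id!r} on chromosome {g.seqid!r} "
                                   "absent from the chromosome order")
    genes.sort(key=lambda g: (rank[g.seqid], g.start, g.id))
    return {g.id: i for i, g in enumerate(genes, 1)}


def build_synteny_table(ref_ann: Annotation, tgt_ann: Annotation,
                        match: FeatureMatch,
                        identities: dict[str, float] | None = None,
                        ) -> list[SyntenyRecord]:
    """One record per shared gene; unmapped and extra-copy genes are excluded.

    Ordinals are recomputed over the shared set only, so they are always dense
    permutations of 1..N on both axes.
    """
    shared = match.shared_gene_ids
    identities = identities or {}
    ref_ord = ordinal_positions(ref_ann, shared, chromosome_order(ref_ann, shared))
    tgt_ord = ordinal_positions(tgt_ann, shared, chromosome_order(tgt_ann, shared))
    records = [
        SyntenyRecord(gene_id=gid,
                      ref_ordinal=ref_ord[gid], tgt_ordinal=tgt_ord[gid],
                      ref_chrom=ref_ann.gene(gid).seqid,
                      tgt_chrom=tgt_ann.gene(gid).seqid,
                      identity=identities.get(gid))
        for gid in shared
    ]
    records.sort(key=lambda r: r.ref_ordinal)
    return records


def translocated_records(records: list[SyntenyRecord]) -> list[SyntenyRecord]:
    """Records whose gene changed chromosome between the annotations.

    This is the per-gene translocation signal: a gene moved between
    chromosomes lands in an off-diagonal chromosome block of the dot plot.
    (Plain ordinal inequality is not usable for counting translocations: one
    relocated gene shifts the ordinal of every gene between its old and new
    position by one, so the ordinal-mismatch count scales with the distance
    moved, not with the number of moved genes.) Meaningful when the two
    annotations use comparable chromosome names, as lift-over outputs do.
    """
    return [r for r in records if r.ref_chrom != r.tgt_chrom]


def gene_order(ann: Annotation, gene_ids: set[str]) -> list[str]:
    """Shared genes as one genome-wide sequence in ordinal order."""
    ordinals = ordinal_positions(ann, gene_ids, chromosome_order(ann, gene_ids))
    return [gid for gid, _ in sorted(ordinals.items(), key=lambda kv: kv[1])]


def order_edit_distance(ref_order: list[str], tgt_order: list[str]) -> int:
    """Levenshtein distance between two gene orders (one gene = one symbol)."""
    if sorted(ref_order) != sorted(tgt_order):
        raise LiftCompareError("gene orders are not permutations of the same ID set")
    if not ref_order:
        return 0
    codes = {gid: i for i, gid in enumerate(ref_order)}
    a = np.array([codes[g] for g in ref_order])
    b = np.array([codes[g] for g in tgt_order])
    m = len(b)
    idx = np.arange(m + 1)
    prev = idx.copy()
    for i, ai in enumerate(a, 1):
        cur = np.empty(m + 1, dtype=np.int64)
        cur[0] = i
        cur[1:] = np.minimum(prev[:-1] + (b != ai), prev[1:] + 1)
        # enforce cur[j] <= cur[j-1] + 1 (insertions) via a prefix scan
        cur = np.minimum.accumulate(cur - idx) + idx
        prev = cur
    return int(prev[m])


def render_dotplot(records: list[SyntenyRecord], out_path: str | Path,
                   identity_floor: float = 0.5) -> None:
    """Draw the ordinal-vs-ordinal dot plot.

    Colors interpolate green (identity 1.0) to red (identity <= floor);
    records without identity are neutral gray. Gray lines separate
    chromosomes on both axes.
    """
    if not records:
        raise LiftCompareError("cannot plot an empty synteny table")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap, Normalize

    cmap = LinearSegmentedColormap.from_list("identity", ["red", "green"])
    norm = Normalize(vmin=identity_floor, vmax=1.0, clip=True)
    xs = [r.ref_ordinal for r in records]
    ys = [r.tgt_ordinal for r in records]
    colors = ["0.6" if r.identity is None else cmap(norm(r.identity)) for r in records]

    fig, ax = plt.subplots(figsize=(7, 7))
    ax.scatter(xs, ys, c=colors, s=12, linewidths=0)
    for pos in _chrom_boundaries(records, axis="ref"):
        ax.axvline(pos, color="0.7", linewidth=0.8)
    for pos in _chrom_boundaries(records, axis="tgt"):
        ax.axhline(pos, color="0.7", linewidth=0.8)
    ax.set_xlabel("ordinal position in reference")
    ax.set_ylabel("ordinal position in target")
    fig.colorbar(plt.cm.ScalarMappable(norm=norm, cmap=cmap), ax=ax,
                 label="sequence identity", shrink=0.7)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def _chrom_boundaries(records: list[SyntenyRecord], axis: str) -> list[float]:
    key = (lambda r: (r.ref_ordinal, r.ref_chrom)) if axis == "ref" \
        else (lambda r: (r.tgt_ordinal, r.tgt_chrom))
    ordered = sorted(key(r) for r in records)
    return [0.5 * (o1 + o2) for (o1, c1), (o2, c2) in zip(ordered, ordered[1:])
            if c1 != c2]


def write_synteny_tsv(records: list[SyntenyRecord], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("gene_id\tref_chrom\tref_ordinal\ttgt_chrom\ttgt_ordinal\tidentity\n")
        for r in records:
            ident = "NA" if r.identity is None else f"{r.identity:.6f}"
            out.write(f"{r.gene_id}\t{r.ref_chrom}\t{r.ref_ordinal}\t"
                      f"{r.tgt_chrom}\t{r.tgt_ordinal}\t{ident}\n")
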