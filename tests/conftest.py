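from __future__ import annotations

import numpy as np
import pytest

from liftcompare.annotation_io import Annotation, Assembly, Feature
from liftcompare.fixtures import (GenomeFixture, apply_mutations, make_reference,
                                  standard_mutation_specs)

AA20 = "ARNDCQEGHILKMFPSTWYV"


def build_annotation(genes) -> Annotation:
    """Assemble a small Annotation from nested tuples.

    ``genes`` is a list of
    ``(gene_id, seqid, strand, [(tid, [(x1, x2), ...exons], [(c1, c2, phase), ...cds])])``.
    Gene/transcript spans are derived from the exons.
    """
    ann = Annotation()
    for gene_id, seqid, strand, transcripts in genes:
        exon_spans = [span for _, exons, _ in transcripts for span in exons]
        g1, g2 = min(s for s, _ in exon_spans), max(e for _, e in exon_spans)
        ann.add_gene(Feature(gene_id, "gene", seqid, g1, g2, strand))
        for tid, exons, cds in transcripts:
            t1, t2 = min(s for s, _ in exons), max(e for _, e in exons)
            ann.add_transcript(Feature(tid, "mRNA", seqid, t1, t2, strand,
                                       parent_id=gene_id))
            for n, (x1, x2) in enumerate(exons, 1):
                ann.add_child(Feature(f"{tid}.exon{n}", "exon", seqid, x1, x2,
                                      strand, parent_id=tid))
            for n, (c1, c2, phase) in enumerate(cds, 1):
                ann.add_child(Feature(f"{tid}.cds{n}", "CDS", seqid, c1, c2,
                                      strand, phase=phase, parent_id=tid))
    ann.validate()
    return ann


def make_protein_family(rng: np.random.Generator, founder_len: int,
                        n_members: int, divergence: float) -> list[str]:
    """A founder protein plus members with the given substitution fraction."""
    founder = "".join(AA20[i] for i in rng.integers(0, 20, size=founder_len))
    members = [founder]
    for _ in range(n_members - 1):
        seq = list(founder)
        k = max(1, round(divergence * founder_len)) if divergence > 0 else 0
        for pos in rng.choice(founder_len, size=k, replace=False):
            choices = [c for c in AA20 if c != seq[pos]]
            seq[pos] = choices[rng.integers(0, len(choices))]
        members.append("".join(seq))
    return members


@pytest.fixture(scope="session")
def standard_fixture() -> tuple[GenomeFixture, GenomeFixture]:
    """The 50-gene, 3-chromosome reference with one event of every class."""
    ref = make_reference(n_genes=50, n_chroms=3, coding_fraction=0.8, seed=1)
    tgt = apply_mutations(ref, standard_mutation_specs(ref, seed=1))
    return ref, tgt


@pytest.fixture()
def tiny_assembly() -> Assembly:
    return Assembly({"chr1": "ATGCCCAAATTTGGGCCCATG"})
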