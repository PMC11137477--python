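"""Synthetic assembly/annotation pairs with a recorded ground truth.

The generator builds a reference genome from an explicit blueprint — per
chromosome, an alternation of intergenic spacers and gene models (UTRs, a
valid ORF for coding genes, exon splits, introns, strand) — and realizes it
into an :class:`~liftcompare.annotation_io.Assembly` plus
:class:`~liftcompare.annotation_io.Annotation`. Mutations are applied to the
blueprint, never to flat sequences, so downstream coordinates always shift
consistently; re-realizing the edited blueprint yields the target genome and a
truth table stating, per gene, the injected event and the effect label,
copy-number delta or ordinal displacement each analysis module is expected to
recover.

What this emulates: the situation after an annotation lift-over, where the
target annotation shares feature IDs with the reference and differs by known,
isolated events. What it does not emulate: repeats, alternative splicing,
sequencing error, or multiple interacting events per gene (one event per gene
keeps the expected labels unambiguous; events sit >= 9 nt away from CDS ends
unless they target a terminus).
"""

from __future__ import annotations

import copy
import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq, reverse_complement

from .annotation_io import (Annotation, Assembly, Feature, LiftCompareError,
                            write_fasta, write_gff3)

STOP_CODONS = ("TAA", "TAG", "TGA")
NON_STOP_CODONS = tuple(
    c for c in ("".join(p) for p in itertools.product("ACGT", repeat=3))
    if c not in STOP_CODONS)
BASES = "ACGT"

EFFECT_EVENTS = (
    "synonymous_snp", "nonsynonymous_snp", "inframe_del", "inframe_ins",
    "start_loss", "five_prime_trunc", "three_prime_trunc",
    "frameshift_indel", "stop_gain_snp",
)
ALL_EVENTS = ("none",) + EFFECT_EVENTS + (
    "syn_plus_frameshift", "gene_deletion", "gene_duplication", "translocation")

#: effect label the variants module is expected to report for each event
EXPECTED_EFFECT = {
    "none": "identical",
    "synonymous_snp": "synonymous",
    "nonsynonymous_snp": "nonsynonymous",
    "inframe_del": "inframe_deletion",
    "inframe_ins": "inframe_insertion",
    "start_loss": "start_lost",
    "five_prime_trunc": "five_prime_truncation",
    "three_prime_trunc": "three_prime_truncation",
    "frameshift_indel": "frameshift",
    "stop_gain_snp": "stop_gained",
    "syn_plus_frameshift": "frameshift",
    "gene_deletion": "unmapped",
    "gene_duplication": "identical",
    "translocation": "identical",
}


@dataclass
class MutationSpec:
    gene_id: str
    event: str
    position: int | None = None    # codon index within the CDS, generator picks if None
    length: int = 1                # codons (in-frame events) or bases (frameshift)
    copies: int = 1                # gene_duplication only
    sub_rate: float = 0.0          # substitution rate applied to duplicated copies
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.event not in ALL_EVENTS:
            raise ValueError(f"unknown event {self.event!r}")


# ---------------------------------------------------------------------------
# Blueprint


@dataclass
class _Spacer:
    seq: str


@dataclass
class _GeneBP:
    gene_id: str
    strand: str
    coding: bool
    utr5: str = ""
    cds: str = ""
    utr3: str = ""
    body: str = ""                      # noncoding exonic sequence
    splits: list[int] = field(default_factory=list)   # cut points in mRNA coords
    introns: list[str] = field(default_factory=list)

    @property
    def mrna(self) -> str:
        return self.utr5 + self.cds + self.utr3 if self.coding else self.body


@dataclass
class _ChromBP:
    name: str
    items: list = field(default_factory=list)


@dataclass
class GenomeFixture:
    """A realized synthetic genome plus the blueprint it came from."""

    assembly: Assembly
    annotation: Annotation
    blueprint: list[_ChromBP]
    truth: pd.DataFrame | None = None

    def write(self, out_dir: str | Path, prefix: str) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.assembly, out_dir / f"{prefix}.fa")
        write_gff3(self.annotation, out_dir / f"{prefix}.gff3")
        if self.truth is not None:
            self.truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reference generation


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _make_gene(rng: np.random.Generator, gene_id: str, coding: bool) -> _GeneBP:
    strand = "+" if rng.integers(0, 2) == 0 else "-"
    gb = _GeneBP(gene_id=gene_id, strand=strand, coding=coding)
    if coding:
        n_codons = int(rng.integers(60, 121))  # incl. start and stop
        internal = [NON_STOP_CODONS[i]
                    for i in rng.integers(0, len(NON_STOP_CODONS), size=n_codons - 2)]
        gb.cds = "ATG" + "".join(internal) + STOP_CODONS[rng.integers(0, 3)]
        gb.utr5 = _random_seq(rng, int(rng.integers(10, 31)))
        gb.utr3 = _random_seq(rng, int(rng.integers(10, 31)))
    else:
        gb.body = _random_seq(rng, int(rng.integers(200, 401)))
    n_exons = int(rng.integers(1, 4))
    mrna_len = len(gb.mrna)
    cuts = sorted(set(int(c) for c in rng.integers(1, mrna_len, size=n_exons - 1)))
    gb.splits = cuts
    gb.introns = [_random_seq(rng, int(rng.integers(20, 61))) for _ in cuts]
    return gb


def make_reference(n_genes: int, n_chroms: int = 1, coding_fraction: float = 0.8,
                   seed: int = 0) -> GenomeFixture:
    """Generate a deterministic reference genome with *n_genes* embedded genes.

    Coding genes carry a complete ORF (ATG start, single terminal stop,
    length a multiple of 3) split across 1–3 exons; both strands are used.
    """
    if n_genes < 1:
        raise LiftCompareError("need at least one gene")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    chroms = [_ChromBP(name=f"chr{i + 1}") for i in range(n_chroms)]
    for g in range(n_genes):
        gene_id = f"g{g + 1:0{width}d}"
        coding = rng.random() < coding_fraction
        chrom = chroms[g % n_chroms]
        chrom.items.append(_Spacer(_random_seq(rng, int(rng.integers(50, 151)))))
        chrom.items.append(_make_gene(rng, gene_id, coding))
    for chrom in chroms:
        chrom.items.append(_Spacer(_random_seq(rng, int(rng.integers(50, 151)))))
    return realize(chroms)


# ---------------------------------------------------------------------------
# Realization (blueprint -> Assembly + Annotation)


def realize(blueprint: list[_ChromBP]) -> GenomeFixture:
    sequences: dict[str, str] = {}
    ann = Annotation(source_dialect="GFF3")
    gene_records = []  # (chrom, gene features...) collected then added in order
    for chrom in blueprint:
        parts: list[str] = []
        offset = 0
        for item in chrom.items:
            if isinstance(item, _Spacer):
                parts.append(item.seq)
                offset += len(item.seq)
                continue
            region, feats = _realize_gene(item, chrom.name, offset)
            parts.append(region)
            offset += len(region)
            gene_records.append(feats)
        sequences[chrom.name] = "".join(parts)
        if not sequences[chrom.name]:
            raise LiftCompareError(f"chromosome {chrom.name} is empty")
    for gene, transcript, children in gene_records:
        ann.add_gene(gene)
        ann.add_transcript(transcript)
        for child in children:
            ann.add_child(child)
    ann.validate()
    return GenomeFixture(Assembly(sequences), ann, blueprint)


def _realize_gene(gb: _GeneBP, chrom: str, offset: int):
    mrna = gb.mrna
    cuts = [0] + [c for c in gb.splits if 0 < c < len(mrna)] + [len(mrna)]
    introns = gb.introns[:len(cuts) - 2]
    # exon i covers mRNA (cuts[i], cuts[i+1]]; sense coords add intron lengths
    exon_sense: list[tuple[int, int, int, int]] = []  # (m1, m2, s1, s2) 1-based
    region_parts: list[str] = []
    intron_shift = 0
    for i in range(len(cuts) - 1):
        m1, m2 = cuts[i] + 1, cuts[i + 1]
        s1, s2 = m1 + intron_shift, m2 + intron_shift
        exon_sense.append((m1, m2, s1, s2))
        region_parts.append(mrna[m1 - 1:m2])
        if i < len(introns):
            region_parts.append(introns[i])
            intron_shift += len(introns[i])
    sense = "".join(region_parts)
    region = reverse_complement(sense) if gb.strand == "-" else sense
    length = len(sense)

    def genomic(s1: int, s2: int) -> tuple[int, int]:
        if gb.strand == "-":
            return offset + length - s2 + 1, offset + length - s1 + 1
        return offset + s1, offset + s2

    tid = f"{gb.gene_id}.t1"
    exon_feats = []
    for n, (_, _, s1, s2) in enumerate(exon_sense, 1):
        g1, g2 = genomic(s1, s2)
        exon_feats.append(Feature(f"{tid}.exon{n}", "exon", chrom, g1, g2,
                                  gb.strand, parent_id=tid))
    cds_feats = []
    if gb.coding and gb.cds:
        c1, c2 = len(gb.utr5) + 1, len(gb.utr5) + len(gb.cds)  # mRNA coords
        cum = 0
        segs = []
        for (m1, m2, s1, s2) in exon_sense:
            o1, o2 = max(m1, c1), min(m2, c2)
            if o1 > o2:
                continue
            phase = (-cum) % 3
            segs.append((s1 + (o1 - m1), s1 + (o2 - m1), phase))
            cum += o2 - o1 + 1
        for n, (s1, s2, phase) in enumerate(segs, 1):
            g1, g2 = genomic(s1, s2)
            cds_feats.append(Feature(f"{tid}.cds{n}", "CDS", chrom, g1, g2,
                                     gb.strand, phase=phase, parent_id=tid))
    start = min(f.start for f in exon_feats)
    end = max(f.end for f in exon_feats)
    gene = Feature(gb.gene_id, "gene", chrom, start, end, gb.strand)
    transcript = Feature(tid, "mRNA" if gb.coding else "ncRNA", chrom, start, end,
                         gb.strand, parent_id=gb.gene_id)
    children = sorted(exon_feats + cds_feats, key=lambda f: f.start)
    return region, (gene, transcript, children)


# ---------------------------------------------------------------------------
# Mutation machinery


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate(table=1))


def _shift_splits(gb: _GeneBP, pos: int, delta: int) -> None:
    """Adjust exon cut points after an edit of size *delta* at mRNA position *pos*."""
    new: list[int] = []
    for s in gb.splits:
        if delta < 0:  # deletion of -delta bases starting at pos
            if s < pos:
                new.append(s)
            elif s >= pos - delta:
                new.append(s + delta)
            else:
                new.append(pos - 1)
        else:          # insertion of delta bases after pos - 1
            new.append(s if s < pos else s + delta)
    mrna_len = len(gb.mrna) + delta  # caller edits the sequence around this call
    cleaned = sorted({s for s in new if 0 < s})
    gb.splits = [min(s, max(mrna_len - 1, 1)) for s in cleaned]
    gb.splits = sorted(set(gb.splits))
    gb.introns = gb.introns[:len(gb.splits)]


def _edit_cds(gb: _GeneBP, cds_offset: int, old_len: int, replacement: str) -> None:
    """Replace ``cds[cds_offset:cds_offset+old_len]`` and shift splits."""
    delta = len(replacement) - old_len
    pos = len(gb.utr5) + cds_offset + 1  # 1-based mRNA position of the edit
    if delta:
        _shift_splits(gb, pos, delta)
    gb.cds = gb.cds[:cds_offset] + replacement + gb.cds[cds_offset + old_len:]


def _internal_codon_indices(gb: _GeneBP) -> list[int]:
    n = len(gb.cds) // 3
    return list(range(3, n - 3))  # >= 9 nt away from both CDS ends


def _hamming1_codons(codon: str):
    for i in range(3):
        for base in BASES:
            if base != codon[i]:
                yield codon[:i] + base + codon[i + 1:]


def _find_codon_edit(gb: _GeneBP, rng: np.random.Generator, want) -> tuple[int, str]:
    """First internal codon (in shuffled order) with a 1-substitution neighbor
    accepted by *want*(old_aa, new_codon); raises if none exists."""
    indices = _internal_codon_indices(gb)
    rng.shuffle(indices)
    for idx in indices:
        codon = gb.cds[3 * idx:3 * idx + 3]
        alts = [alt for alt in _hamming1_codons(codon)
                if want(_translate_codon(codon), alt)]
        if alts:
            return idx, alts[int(rng.integers(0, len(alts)))]
    raise LiftCompareError(f"gene {gb.gene_id!r}: no codon admits the requested edit")


def _require_coding(gb: _GeneBP, event: str) -> None:
    if not gb.coding:
        raise LiftCompareError(f"event {event!r} requires a coding gene, "
                               f"but {gb.gene_id!r} is noncoding")


def _pick_codon(gb: _GeneBP, rng: np.random.Generator, spec: MutationSpec,
                span: int = 1) -> int:
    if spec.position is not None:
        return spec.position
    candidates = [i for i in _internal_codon_indices(gb)
                  if i + span <= len(gb.cds) // 3 - 3]
    if not candidates:
        raise LiftCompareError(f"gene {gb.gene_id!r}: CDS too short for the event")
    return int(candidates[rng.integers(0, len(candidates))])


def _apply_snp(gb: _GeneBP, rng: np.random.Generator, kind: str) -> None:
    if kind == "synonymous_snp":
        want = lambda aa, alt: _translate_codon(alt) == aa and alt not in STOP_CODONS
    elif kind == "nonsynonymous_snp":
        want = lambda aa, alt: _translate_codon(alt) not in (aa, "*")
    else:  # stop_gain_snp
        want = lambda aa, alt: alt in STOP_CODONS
    idx, alt = _find_codon_edit(gb, rng, want)
    _edit_cds(gb, 3 * idx, 3, alt)


def _mutate_copy(gb: _GeneBP, rng: np.random.Generator, sub_rate: float) -> None:
    if sub_rate <= 0:
        return
    if gb.coding:
        n = len(gb.cds) // 3
        for idx in range(1, n - 1):
            if rng.random() < sub_rate * 3:
                codon = gb.cds[3 * idx:3 * idx + 3]
                alts = [a for a in _hamming1_codons(codon) if a not in STOP_CODONS]
                alt = alts[int(rng.integers(0, len(alts)))]
                gb.cds = gb.cds[:3 * idx] + alt + gb.cds[3 * idx + 3:]
    else:
        seq = list(gb.body)
        for i in range(len(seq)):
            if rng.random() < sub_rate:
                seq[i] = rng.choice([b for b in BASES if b != seq[i]])
        gb.body = "".join(seq)


def apply_mutations(reference: GenomeFixture,
                    specs: list[MutationSpec]) -> GenomeFixture:
    """Apply at most one event per gene and realize the mutated target genome.

    Returns a fixture whose ``truth`` table records, for every reference gene,
    the injected event, the effect label the variants module should report,
    the expected cluster copy-number delta, and whether the gene moved
    between chromosomes. Applying an empty spec list yields a target
    byte-identical to the reference.
    """
    blueprint = copy.deepcopy(reference.blueprint)
    genes: dict[str, tuple[_ChromBP, int]] = {}
    coding: dict[str, bool] = {}
    for chrom in blueprint:
        for i, item in enumerate(chrom.items):
            if isinstance(item, _GeneBP):
                genes[item.gene_id] = (chrom, i)
                coding[item.gene_id] = item.coding
    seen: set[str] = set()
    rows = []
    for spec in specs:
        if spec.gene_id not in genes:
            raise LiftCompareError(f"mutation spec names unknown gene {spec.gene_id!r}")
        if spec.gene_id in seen and spec.event != "none":
            raise LiftCompareError(f"multiple events for gene {spec.gene_id!r}")
        seen.add(spec.gene_id)
        rng = np.random.default_rng(spec.seed if spec.seed is not None
                                    else abs(hash(spec.gene_id)) % 2**31)
        # locate at apply time: earlier insertions shift item indices
        chrom, idx = next((c, i) for c in blueprint for i, item in enumerate(c.items)
                          if isinstance(item, _GeneBP) and item.gene_id == spec.gene_id)
        gb = chrom.items[idx]
        delta, moved = 0, False
        event = spec.event
        if event in ("synonymous_snp", "nonsynonymous_snp", "stop_gain_snp"):
            _require_coding(gb, event)
            _apply_snp(gb, rng, event)
        elif event == "start_loss":
            _require_coding(gb, event)
            if not gb.cds.startswith("ATG"):
                raise LiftCompareError(f"gene {gb.gene_id!r} has no ATG start")
            _edit_cds(gb, 0, 3, "ATA")
        elif event == "inframe_del":
            _require_coding(gb, event)
            i = _pick_codon(gb, rng, spec, span=spec.length)
            _edit_cds(gb, 3 * i, 3 * spec.length, "")
        elif event == "inframe_ins":
            _require_coding(gb, event)
            i = _pick_codon(gb, rng, spec)
            ins = "".join(NON_STOP_CODONS[j] for j in
                          rng.integers(0, len(NON_STOP_CODONS), size=spec.length))
            _edit_cds(gb, 3 * i, 0, ins)
        elif event == "frameshift_indel":
            _require_coding(gb, event)
            if spec.length % 3 == 0:
                raise LiftCompareError("frameshift length must not be a multiple of 3")
            i = _pick_codon(gb, rng, spec)
            _edit_cds(gb, 3 * i, spec.length, "")
        elif event == "syn_plus_frameshift":
            _require_coding(gb, event)
            _apply_snp(gb, rng, "synonymous_snp")
            i = _pick_codon(gb, rng, spec)
            _edit_cds(gb, 3 * i, 1, "")
        elif event == "five_prime_trunc":
            _require_coding(gb, event)
            m = max(spec.length, 1) if spec.length >= 1 else 1
            m = max(m, 3)  # must remove the whole start codon and then some
            _edit_cds(gb, 0, 3 * m, "")
        elif event == "three_prime_trunc":
            _require_coding(gb, event)
            m = max(spec.length, 3)
            _edit_cds(gb, len(gb.cds) - 3 * m, 3 * m, "")
        elif event == "gene_deletion":
            chrom.items[idx] = _Spacer("")
        elif event == "gene_duplication":
            for n in range(1, spec.copies + 1):
                dup = copy.deepcopy(gb)
                dup.gene_id = f"{gb.gene_id}_{n}"
                _mutate_copy(dup, rng, spec.sub_rate)
                dest = blueprint[int(rng.integers(0, len(blueprint)))]
                pos = int(rng.integers(0, len(dest.items) + 1))
                dest.items[pos:pos] = [_Spacer(_random_seq(rng, 60)), dup]
            delta = spec.copies
        elif event == "translocation":
            if len(blueprint) < 2:
                raise LiftCompareError("translocation requires >= 2 chromosomes")
            others = [c for c in blueprint if c.name != chrom.name]
            dest = others[int(rng.integers(0, len(others)))]
            chrom.items[idx] = _Spacer("")
            pos = int(rng.integers(0, len(dest.items) + 1))
            dest.items[pos:pos] = [_Spacer(_random_seq(rng, 60)), gb]
            moved = True
        elif event != "none":
            raise LiftCompareError(f"unhandled event {event!r}")
        expected = EXPECTED_EFFECT[event]
        if not coding[spec.gene_id] and expected != "unmapped":
            expected = "noncoding"  # no protein, hence no effect label
        rows.append({"gene_id": spec.gene_id, "event": event,
                     "expected_effect": expected,
                     "expected_copy_delta": delta,
                     "expected_moved": moved,
                     "seed": spec.seed if spec.seed is not None else -1})
    for gid in genes:
        if gid not in seen:
            rows.append({"gene_id": gid, "event": "none",
                         "expected_effect": "identical" if coding[gid] else "noncoding",
                         "expected_copy_delta": 0, "expected_moved": False,
                         "seed": -1})
    target = realize(blueprint)
    order = {gid: i for i, gid in enumerate(genes)}
    rows.sort(key=lambda r: order[r["gene_id"]])
    target.truth = pd.DataFrame(rows)
    return target


def standard_mutation_specs(reference: GenomeFixture, seed: int = 0,
                            events: tuple[str, ...] | None = None) -> list[MutationSpec]:
    """Assign one event of each class to a distinct compatible gene.

    Default event set covers every class the generator knows (translocation is
    skipped on single-chromosome references). Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    if events is None:
        events = tuple(e for e in ALL_EVENTS if e != "none")
        if len(reference.blueprint) < 2:
            events = tuple(e for e in events if e != "translocation")
    coding = {item.gene_id for c in reference.blueprint for item in c.items
              if isinstance(item, _GeneBP) and item.coding}
    pool = [item.gene_id for c in reference.blueprint for item in c.items
            if isinstance(item, _GeneBP)]
    rng.shuffle(pool)
    needs_cds = set(EFFECT_EVENTS) | {"syn_plus_frameshift"}
    specs, used = [], set()
    for event in events:
        gid = next((g for g in pool if g not in used
                    and (event not in needs_cds or g in coding)), None)
        if gid is None:
            raise LiftCompareError(f"no unused compatible gene for event {event!r}")
        used.add(gid)
        specs.append(MutationSpec(gid, event, sub_rate=0.02 if event == "gene_duplication" else 0.0,
                                  seed=int(rng.integers(0, 2**31))))
    return specs


def effects_panel(n_per_class: int = 10, seed: int = 1,
                  ) -> tuple[GenomeFixture, GenomeFixture]:
    """Reference/target pair with *n_per_class* coding genes per effect class.

    The workhorse integration fixture: every gene carries exactly one injected
    event from the nine effect classes, so the variants module should recover
    the truth table's label for 100% of transcripts.
    """
    n = n_per_class * len(EFFECT_EVENTS)
    ref = make_reference(n_genes=n, n_chroms=2, coding_fraction=1.0, seed=seed)
    gene_ids = ref.annotation.gene_ids()
    rng = np.random.default_rng(seed + 1)
    specs = [MutationSpec(gid, EFFECT_EVENTS[i % len(EFFECT_EVENTS)],
                          seed=int(rng.integers(0, 2**31)))
             for i, gid in enumerate(gene_ids)]
    return ref, apply_mutations(ref, specs)
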