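"""Coding gene structures and intron marks in protein coordinates.

A gene structure is the ordered list of CDS exons of one transcript in
genomic coordinates. Each internal exon junction is an intron; an intron
is summarised in protein space by an *intron mark*: the 1-based index of
the anchor residue plus the intron phase, where

    phase         = (CDS nucleotides upstream of the intron) mod 3
    anchor_residue = floor(cds_offset / 3) + 1

A single anchoring rule is used for all phases: a phase-0 intron anchors
to the residue immediately following the splice, phase-1/2 introns to the
residue whose codon the intron splits. This gives one uniform
(residue, phase) key for homology comparison across genes.

Coordinates are 1-based inclusive (GFF3 dialect) throughout.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Optional

import gffutils
from Bio.Seq import Seq

__all__ = [
    "GeneStructure",
    "IntronMark",
    "GeneStructureError",
    "parse_gene_structures",
    "parse_exon_table",
    "introns_from_structure",
    "validate_structure",
]


class GeneStructureError(ValueError):
    """Raised for structurally invalid gene models; names the gene."""

    def __init__(self, gene_id: str, message: str):
        self.gene_id = gene_id
        super().__init__(f"gene {gene_id!r}: {message}")


@dataclass(frozen=True)
class IntronMark:
    """An intron located in protein coordinates.

    Attributes
    ----------
    gene_id : str
        Gene/protein identifier the mark belongs to.
    anchor_residue : int
        1-based protein index of the residue whose codon contains (phase
        1/2) or immediately follows (phase 0) the splice site.
    phase : int
        Intron phase, 0/1/2 = CDS nucleotides upstream of the intron mod 3.
    cds_offset : int
        Number of coding nucleotides upstream of the intron; kept for
        exact round-trip checks and alignment-invariant intron identity.
    """

    gene_id: str
    anchor_residue: int
    phase: int
    cds_offset: int

    def __post_init__(self):
        if self.phase not in (0, 1, 2):
            raise GeneStructureError(self.gene_id, f"invalid phase {self.phase}")
        if self.cds_offset <= 0:
            raise GeneStructureError(
                self.gene_id, f"cds_offset must be positive, got {self.cds_offset}"
            )
        if self.anchor_residue != self.cds_offset // 3 + 1:
            raise GeneStructureError(
                self.gene_id,
                f"anchor {self.anchor_residue} inconsistent with offset {self.cds_offset}",
            )

    @classmethod
    def from_offset(cls, gene_id: str, cds_offset: int) -> "IntronMark":
        return cls(
            gene_id=gene_id,
            anchor_residue=cds_offset // 3 + 1,
            phase=cds_offset % 3,
            cds_offset=cds_offset,
        )

    @classmethod
    def from_anchor(cls, gene_id: str, anchor_residue: int, phase: int) -> "IntronMark":
        return cls(
            gene_id=gene_id,
            anchor_residue=anchor_residue,
            phase=phase,
            cds_offset=(anchor_residue - 1) * 3 + phase,
        )


@dataclass
class GeneStructure:
    """Ordered CDS exons of one coding transcript.

    ``exons`` are (start, end) pairs in genomic coordinates, 1-based
    inclusive, listed in *transcription* order: ascending on the plus
    strand, descending on the minus strand.
    """

    gene_id: str
    strand: str
    exons: list[tuple[int, int]]
    contig_id: Optional[str] = None
    annotated_phases: Optional[list[int]] = field(default=None, repr=False)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise GeneStructureError(self.gene_id, f"invalid strand {self.strand!r}")
        if not self.exons:
            raise GeneStructureError(self.gene_id, "no CDS exons")
        for s, e in self.exons:
            if s > e or s < 1:
                raise GeneStructureError(self.gene_id, f"invalid exon ({s},{e})")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise GeneStructureError(
                    self.gene_id, f"overlapping CDS exons ({s1},{e1}) and ({s2},{e2})"
                )
        if self.cds_length % 3 != 0:
            raise GeneStructureError(
                self.gene_id, f"CDS length {self.cds_length} not divisible by 3"
            )
        # transcription order must be monotone in the right direction
        starts = [s for s, _ in self.exons]
        if self.strand == "+":
            if starts != sorted(starts):
                raise GeneStructureError(
                    self.gene_id, "plus-strand exons not in ascending order"
                )
        else:
            if starts != sorted(starts, reverse=True):
                raise GeneStructureError(
                    self.gene_id, "minus-strand exons not in descending order"
                )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def spliced_cds(self, contig_seq: str) -> str:
        """Splice the CDS out of a contig sequence (transcription order)."""
        parts = []
        for s, e in sorted(self.exons):
            parts.append(contig_seq[s - 1 : e])
        cds = "".join(parts)
        if self.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return cds


def introns_from_structure(s: GeneStructure) -> list[IntronMark]:
    """Derive one intron mark per internal exon junction.

    The cumulative coding length upstream of each junction gives the CDS
    offset; phase and anchor residue follow from it. The annotated GFF3
    phase column, when present, is cross-checked: disagreement raises a
    warning but the computed value wins (annotation phase fields are
    frequently wrong).
    """
    marks = []
    cumulative = 0
    for s_, e_ in s.exons[:-1]:
        cumulative += e_ - s_ + 1
        marks.append(IntronMark.from_offset(s.gene_id, cumulative))
    if s.annotated_phases is not None:
        _check_annotated_phases(s, marks)
    return marks


def _check_annotated_phases(s: GeneStructure, marks: list[IntronMark]) -> None:
    # GFF3 phase of exon i+1 equals (3 - cds_offset_i mod 3) mod 3
    for i, mark in enumerate(marks):
        annotated = s.annotated_phases[i + 1]
        expected = (3 - mark.cds_offset % 3) % 3
        if annotated is not None and annotated != expected:
            warnings.warn(
                f"gene {s.gene_id!r}: annotated phase {annotated} of exon "
                f"{i + 2} disagrees with computed {expected}; using computed",
                stacklevel=3,
            )


def parse_gene_structures(gff3_source: str | os.PathLike) -> list[GeneStructure]:
    """Parse gene structures from GFF3 CDS features.

    Parameters
    ----------
    gff3_source : path or str
        Path to a GFF3 file, or GFF3 text itself (detected by content).

    CDS features are grouped by their ``Parent`` attribute; exons are
    returned in transcription order. A CDS without a parent, overlapping
    CDS segments, or a total CDS length not divisible by 3 raise
    :class:`GeneStructureError` naming the gene.
    """
    text_input = isinstance(gff3_source, str) and "\n" in gff3_source
    if text_input:
        db = gffutils.create_db(
            gff3_source, ":memory:", from_string=True, merge_strategy="create_unique"
        )
    else:
        db = gffutils.create_db(
            str(gff3_source), ":memory:", merge_strategy="create_unique"
        )

    by_parent: dict[str, list] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent")
        if not parents:
            name = cds.attributes.get("ID", ["<unnamed CDS>"])[0]
            raise GeneStructureError(name, "CDS feature lacks a Parent attribute")
        by_parent.setdefault(parents[0], []).append(cds)

    structures = []
    for parent_id, segments in sorted(by_parent.items()):
        strands = {c.strand for c in segments}
        if len(strands) != 1 or strands <= {".", "?"}:
            raise GeneStructureError(parent_id, f"inconsistent strand {strands}")
        strand = strands.pop()
        contigs = {c.seqid for c in segments}
        if len(contigs) != 1:
            raise GeneStructureError(parent_id, f"CDS spans contigs {contigs}")
        segments.sort(key=lambda c: c.start, reverse=(strand == "-"))
        phases = [
            int(c.frame) if c.frame not in (None, ".") else None for c in segments
        ]
        structures.append(
            GeneStructure(
                gene_id=parent_id,
                strand=strand,
                exons=[(c.start, c.end) for c in segments],
                contig_id=contigs.pop(),
                annotated_phases=phases,
            )
        )
    return structures


def parse_exon_table(source: str | os.PathLike) -> list[GeneStructure]:
    """Parse the simple exon-table alternative to GFF3.

    Tab-separated columns: gene_id, strand, exon_start, exon_end, one row
    per exon, rows in transcription order within each gene.
    """
    if isinstance(source, str) and "\n" in source:
        lines = source.splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    rows: dict[str, list] = {}
    strands: dict[str, str] = {}
    for ln in lines:
        ln = ln.strip()
        if not ln or ln.startswith("#") or ln.startswith("gene_id\t"):
            continue
        gene_id, strand, start, end = ln.split("\t")[:4]
        rows.setdefault(gene_id, []).append((int(start), int(end)))
        strands[gene_id] = strand
    return [
        GeneStructure(gene_id=g, strand=strands[g], exons=ex)
        for g, ex in rows.items()
    ]


def validate_structure(
    s: GeneStructure,
    protein: str,
    contig_seq: Optional[str] = None,
) -> dict:
    """Check a gene structure against its protein product.

    The spliced CDS length must equal ``3*len(protein)`` (stop-exclusive)
    or ``3*(len(protein)+1)`` (stop-inclusive); both conventions are
    accepted and which one matched is recorded. When the contig sequence
    is available the spliced CDS is translated and compared residue by
    residue.

    Returns a report dict with keys ``ok``, ``stop_inclusive``,
    ``message``. Raises :class:`GeneStructureError` on hard mismatch.
    """
    protein = protein.rstrip("*")
    n = s.cds_length
    if n == 3 * (len(protein) + 1):
        stop_inclusive = True
    elif n == 3 * len(protein):
        stop_inclusive = False
    else:
        raise GeneStructureError(
            s.gene_id,
            f"CDS length {n} matches neither 3*{len(protein)} nor "
            f"3*({len(protein)}+1)",
        )
    if contig_seq is not None:
        cds = s.spliced_cds(contig_seq)
        if stop_inclusive:
            cds = cds[:-3]
        translated = str(Seq(cds).translate())
        if translated != protein:
            for i, (a, b) in enumerate(zip(translated, protein), start=1):
                if a != b:
                    raise GeneStructureError(
                        s.gene_id,
                        f"translation mismatch at residue {i}: {a} != {b}",
                    )
            raise GeneStructureError(s.gene_id, "translation length mismatch")
    return {
        "ok": True,
        "stop_inclusive": stop_inclusive,
        "message": f"CDS consistent ({'stop-inclusive' if stop_inclusive else 'stop-exclusive'})",
    }
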