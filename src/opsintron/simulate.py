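"""Synthetic protein families with planted, clade-specific intron positions.

The generator emulates the statistical structure the downstream analysis
assumes: a multi-clade protein family diverged from clade consensus
sequences, CDS-level gene structures carrying clade-conserved introns
(position and phase), configurable intron loss and positional jitter,
alternative alignments, and bootstrap-style tree sets with planted rogue
taxa. Because the family is built top-down from a known ancestral column
architecture, the true residue homology (hence the true alignment and the
true alignment column of every planted intron) is known by construction.

Construction outline, all randomness drawn from one seeded generator:

1. An ancestral core of ``protein_length`` columns with uniform residues.
2. Per clade, seeded indel events on the core (deletions of core columns,
   insertions of clade-private columns) define the clade's row in the
   true alignment; substitutions at ``substitution_rate`` give the clade
   consensus, and a second round per member gives the member sequences.
   Members of one clade share the clade's column mask, so planted anchor
   residues are homologous within a clade by construction.
3. Each planted (anchor, phase) is realised per member with probability
   ``1 - intron_loss_prob``, shifted by a uniform integer in
   [-jitter, +jitter] and clamped to the valid residue range.
4. The CDS is built by back-translating the member protein with uniform
   synonymous codons plus a stop codon, and intron sequences (GT..AG,
   lengths from ``intron_length_range``) are inserted at the nucleotide
   offsets realising the requested phases. Genes alternate between plus
   and minus strand placement on per-gene contigs.
5. The bootstrap-style tree set is the clade backbone with each rogue
   taxon re-attached to a uniformly random edge in every replicate.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import dendropy
import numpy as np

from .gene_structure import GeneStructure, IntronMark

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_family",
    "simulate_tree_set",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# codon choices per residue (standard code), fixed order for determinism
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}

_FLANK = 30  # nt of random sequence on each side of a synthetic gene


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of one synthetic family.

    ``planted_introns`` holds, per clade, a list of (anchor_residue,
    phase) pairs in clade-consensus protein coordinates. Anchors must lie
    in [1, protein_length] and phases in {0, 1, 2}. A fixed seed yields
    byte-identical output files.
    """

    seed: int = 0
    n_clades: int = 2
    seqs_per_clade: int = 8
    protein_length: int = 250
    substitution_rate: float = 0.05
    planted_introns: list[list[tuple[int, int]]] = field(
        default_factory=lambda: [[(60, 0), (120, 1), (180, 2)], [(90, 0), (200, 1)]]
    )
    intron_loss_prob: float = 0.0
    intron_jitter: int = 0
    intron_length_range: tuple[int, int] = (60, 300)
    indel_rate: float = 0.0
    n_trees: int = 100
    rogue_taxa: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if self.n_clades < 1 or self.seqs_per_clade < 1:
            raise SimulationError("need at least one clade with one sequence")
        if self.protein_length < 10:
            raise SimulationError("protein_length must be >= 10")
        if not 0 <= self.substitution_rate <= 1:
            raise SimulationError("substitution_rate must be in [0,1]")
        if not 0 <= self.intron_loss_prob <= 1:
            raise SimulationError("intron_loss_prob must be in [0,1]")
        if not 0 <= self.indel_rate <= 1:
            raise SimulationError("indel_rate must be in [0,1]")
        if self.intron_jitter < 0:
            raise SimulationError("intron_jitter must be >= 0")
        lo, hi = self.intron_length_range
        if lo < 4 or hi < lo:
            raise SimulationError("intron_length_range must satisfy 4 <= min <= max")
        if len(self.planted_introns) != self.n_clades:
            raise SimulationError(
                f"planted_introns has {len(self.planted_introns)} clades, "
                f"config says {self.n_clades}"
            )
        for marks in self.planted_introns:
            for anchor, phase in marks:
                if not 1 <= anchor <= self.protein_length:
                    raise SimulationError(
                        f"planted anchor {anchor} outside [1,{self.protein_length}]"
                    )
                if phase not in (0, 1, 2):
                    raise SimulationError(f"planted phase {phase} not in 0/1/2")


@dataclass
class SyntheticDataset:
    """One realised synthetic family plus its ground truth."""

    config: SimulationConfig
    proteins: dict[str, str]
    structures: dict[str, GeneStructure]
    contigs: dict[str, str]
    true_alignment: dict[str, str]
    clade_map: dict[str, str]
    truth: dict
    tree_set: list[str]

    @property
    def clades(self) -> list[str]:
        return sorted(set(self.clade_map.values()))

    def marks(self) -> dict[str, list[IntronMark]]:
        """Realised intron marks per sequence, from the truth record."""
        out = {}
        for seq_id, entries in self.truth["realized"].items():
            out[seq_id] = [
                IntronMark.from_offset(seq_id, e["cds_offset"]) for e in entries
            ]
        return out

    # ------------------------------------------------------------------ io

    def gff3_text(self) -> str:
        lines = ["##gff-version 3"]
        for seq_id in sorted(self.structures):
            s = self.structures[seq_id]
            genomic = sorted(s.exons)
            gene_start, gene_end = genomic[0][0], genomic[-1][1]
            lines.append(
                f"{s.contig_id}\topsintron-sim\tgene\t{gene_start}\t{gene_end}"
                f"\t.\t{s.strand}\t.\tID=gene:{seq_id}"
            )
            lines.append(
                f"{s.contig_id}\topsintron-sim\tmRNA\t{gene_start}\t{gene_end}"
                f"\t.\t{s.strand}\t.\tID={seq_id};Parent=gene:{seq_id}"
            )
            cumulative = 0
            for i, (es, ee) in enumerate(s.exons):  # transcription order
                phase = (3 - cumulative % 3) % 3
                lines.append(
                    f"{s.contig_id}\topsintron-sim\tCDS\t{es}\t{ee}\t.\t{s.strand}"
                    f"\t{phase}\tID=cds:{seq_id}.{i + 1};Parent={seq_id}"
                )
                cumulative += ee - es + 1
        return "\n".join(lines) + "\n"

    def write(self, outdir: str | os.PathLike) -> dict[str, str]:
        """Write all artefacts; returns {name: path}. Deterministic bytes."""
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        paths = {}

        def _fasta(name, records):
            path = os.path.join(outdir, name)
            with open(path, "w") as fh:
                for sid in sorted(records):
                    fh.write(f">{sid}\n{records[sid]}\n")
            paths[name] = path

        _fasta("proteins.fasta", self.proteins)
        _fasta("genome.fasta", self.contigs)
        _fasta("alignment.true.fasta", self.true_alignment)

        path = os.path.join(outdir, "structures.gff3")
        with open(path, "w") as fh:
            fh.write(self.gff3_text())
        paths["structures.gff3"] = path

        path = os.path.join(outdir, "clades.tsv")
        with open(path, "w") as fh:
            fh.write("taxon\tclade\n")
            for sid in sorted(self.clade_map):
                fh.write(f"{sid}\t{self.clade_map[sid]}\n")
        paths["clades.tsv"] = path

        path = os.path.join(outdir, "trees.nwk")
        with open(path, "w") as fh:
            fh.write("\n".join(self.tree_set) + "\n")
        paths["trees.nwk"] = path

        path = os.path.join(outdir, "truth.json")
        with open(path, "w") as fh:
            json.dump(
                {"config": asdict(self.config), **self.truth},
                fh,
                indent=1,
                sort_keys=True,
            )
        paths["truth.json"] = path
        return paths


# ---------------------------------------------------------------------------
# family simulation


def _mutate(residues: list[str], rate: float, rng) -> list[str]:
    out = list(residues)
    hits = np.nonzero(rng.random(len(out)) < rate)[0]
    for i in hits:
        choices = [a for a in AMINO_ACIDS if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return out


def simulate_family(config: SimulationConfig) -> SyntheticDataset:
    """Generate one labelled synthetic family from a validated config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.protein_length
    clade_names = [f"clade{chr(ord('A') + c)}" for c in range(config.n_clades)]

    # --- column architecture: core columns + per-clade indel events
    ancestor = [AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=L)]
    half = config.indel_rate / 2.0
    deleted = {
        name: set(np.nonzero(rng.random(L) < half)[0]) for name in clade_names
    }
    insertions: dict[str, dict[int, int]] = {}  # clade -> {junction: run length}
    for name in clade_names:
        ins = {}
        for j in np.nonzero(rng.random(L + 1) < half)[0]:
            ins[int(j)] = int(rng.integers(1, 4))
        insertions[name] = ins

    # global column order: at junction j, each clade's private insertion run,
    # then core column j
    columns: list[tuple[str, int | str]] = []  # ("core", i) or (clade, junction.k)
    for j in range(L + 1):
        for name in clade_names:
            run = insertions[name].get(j, 0)
            for k in range(run):
                columns.append((name, f"{j}.{k}"))
        if j < L:
            columns.append(("core", j))

    # --- clade consensus rows over the global columns
    clade_rows: dict[str, list[str]] = {}
    for name in clade_names:
        row = []
        for owner, key in columns:
            if owner == "core":
                if key in deleted[name]:
                    row.append("-")
                else:
                    row.append(ancestor[key])
            elif owner == name:
                row.append(AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))])
            else:
                row.append("-")
        present = [i for i, ch in enumerate(row) if ch != "-"]
        mutated = _mutate([row[i] for i in present], config.substitution_rate, rng)
        for i, ch in zip(present, mutated):
            row[i] = ch
        clade_rows[name] = row

    # --- members: per-sequence substitutions on the clade consensus
    proteins: dict[str, str] = {}
    aligned: dict[str, str] = {}
    clade_map: dict[str, str] = {}
    members: dict[str, list[str]] = {name: [] for name in clade_names}
    for name in clade_names:
        present = [i for i, ch in enumerate(clade_rows[name]) if ch != "-"]
        for m in range(config.seqs_per_clade):
            seq_id = f"{name}_s{m + 1:02d}"
            row = list(clade_rows[name])
            mutated = _mutate([row[i] for i in present], config.substitution_rate, rng)
            for i, ch in zip(present, mutated):
                row[i] = ch
            aligned[seq_id] = "".join(row)
            proteins[seq_id] = "".join(ch for ch in row if ch != "-")
            clade_map[seq_id] = name
            members[name].append(seq_id)

    # --- planted introns: clade-level truth with true alignment columns
    planted_truth: dict[str, list[dict]] = {}
    for name, planted in zip(clade_names, config.planted_introns):
        present = [i for i, ch in enumerate(clade_rows[name]) if ch != "-"]
        n_res = len(present)
        entries = []
        for anchor, phase in planted:
            eff_anchor, clamped = anchor, False
            if eff_anchor > n_res:
                eff_anchor, clamped = n_res, True
            if eff_anchor == 1 and phase == 0:  # offset 0 is not an intron
                eff_anchor, clamped = 2, True
            entries.append(
                {
                    "anchor": int(eff_anchor),
                    "phase": int(phase),
                    "true_column": int(present[eff_anchor - 1] + 1),
                    "requested_anchor": int(anchor),
                    "clamped": clamped,
                }
            )
        planted_truth[name] = entries

    # --- realise marks per member (loss, jitter, clamping)
    realized: dict[str, list[dict]] = {}
    for name in clade_names:
        for seq_id in members[name]:
            n_res = len(proteins[seq_id])
            entries = []
            used_offsets = set()
            for idx, planted in enumerate(planted_truth[name]):
                if rng.random() < config.intron_loss_prob:
                    continue
                anchor = planted["anchor"]
                if config.intron_jitter:
                    anchor += int(
                        rng.integers(-config.intron_jitter, config.intron_jitter + 1)
                    )
                clamped = False
                if anchor < 1:
                    anchor, clamped = 1, True
                if anchor > n_res:
                    anchor, clamped = n_res, True
                phase = planted["phase"]
                if anchor == 1 and phase == 0:
                    anchor, clamped = 2, True
                offset = (anchor - 1) * 3 + phase
                if offset in used_offsets:
                    continue  # jitter collision: one intron per offset
                used_offsets.add(offset)
                entries.append(
                    {
                        "anchor": int(anchor),
                        "phase": int(phase),
                        "cds_offset": int(offset),
                        "planted_index": idx,
                        "clamped": clamped or planted["clamped"],
                    }
                )
            entries.sort(key=lambda e: e["cds_offset"])
            realized[seq_id] = entries

    # --- gene structures: back-translate, insert introns, place on contigs
    structures: dict[str, GeneStructure] = {}
    contigs: dict[str, str] = {}
    for gi, seq_id in enumerate(sorted(proteins)):
        protein = proteins[seq_id]
        codons = [
            _CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein
        ]
        cds = "".join(codons) + "TAA"
        offsets = [e["cds_offset"] for e in realized[seq_id]]
        pieces = []  # (kind, seq) alternating exon/intron
        prev = 0
        for off in offsets:
            pieces.append(("exon", cds[prev:off]))
            ilen = int(
                rng.integers(
                    config.intron_length_range[0], config.intron_length_range[1] + 1
                )
            )
            inner = "".join(
                "ACGT"[i] for i in rng.integers(4, size=max(ilen - 4, 0))
            )
            pieces.append(("intron", "GT" + inner + "AG"))
            prev = off
        pieces.append(("exon", cds[prev:]))

        gene_seq = "".join(s for _, s in pieces)
        strand = "+" if gi % 2 == 0 else "-"
        flank5 = "".join("ACGT"[i] for i in rng.integers(4, size=_FLANK))
        flank3 = "".join("ACGT"[i] for i in rng.integers(4, size=_FLANK))

        # exon spans in sense-of-transcription coordinates within the gene
        sense_spans = []
        pos = 1
        for kind, s in pieces:
            if kind == "exon":
                sense_spans.append((pos, pos + len(s) - 1))
            pos += len(s)
        G = len(gene_seq)
        if strand == "+":
            contig_seq = flank5 + gene_seq + flank3
            exons = [(_FLANK + s, _FLANK + e) for s, e in sense_spans]
        else:
            contig_seq = flank5 + _revcomp(gene_seq) + flank3
            exons = [
                (_FLANK + G - e + 1, _FLANK + G - s + 1) for s, e in sense_spans
            ]  # still transcription order: descending contig start
        contig_id = f"contig_{seq_id}"
        contigs[contig_id] = contig_seq
        structures[seq_id] = GeneStructure(
            gene_id=seq_id, strand=strand, exons=exons, contig_id=contig_id
        )

    # --- tree set with planted rogues
    taxa = sorted(proteins)
    unknown = [t for t in config.rogue_taxa if t not in taxa]
    if unknown:
        raise SimulationError(f"rogue taxa not in the family: {unknown}")
    backbone_taxa = [t for t in taxa if t not in config.rogue_taxa]
    backbone = _ladder_backbone(backbone_taxa, clade_map)
    tree_seed = int(rng.integers(2**31))
    tree_set = simulate_tree_set(
        backbone, config.rogue_taxa, config.n_trees, tree_seed
    )

    truth = {
        "planted": planted_truth,
        "realized": realized,
        "rogue_taxa": list(config.rogue_taxa),
        "backbone": backbone,
    }
    return SyntheticDataset(
        config=config,
        proteins=proteins,
        structures=structures,
        contigs=contigs,
        true_alignment=aligned,
        clade_map=clade_map,
        truth=truth,
        tree_set=tree_set,
    )


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def _ladder_backbone(taxa: Sequence[str], clade_map: dict[str, str]) -> str:
    """Fully resolved backbone: ladders within clades, ladder of clades."""
    by_clade: dict[str, list[str]] = {}
    for t in taxa:
        by_clade.setdefault(clade_map.get(t, "_"), []).append(t)

    def ladder(items: list[str]) -> str:
        node = items[0]
        for nxt in items[1:]:
            node = f"({node},{nxt})"
        return node

    subtrees = [ladder(sorted(ms)) for _, ms in sorted(by_clade.items())]
    tree = subtrees[0]
    for nxt in subtrees[1:]:
        tree = f"({tree},{nxt})"
    return tree + ";"


# ---------------------------------------------------------------------------
# tree-set simulation


def simulate_tree_set(
    backbone: str,
    rogue_taxa: Sequence[str],
    n_trees: int,
    seed: int,
) -> list[str]:
    """Replicate a backbone tree, attaching each rogue to a random edge.

    Every output tree is the backbone with each rogue taxon grafted onto
    an independently, uniformly chosen edge (any edge below the root).
    All trees therefore share one leaf set; with no rogues the output is
    ``n_trees`` copies of the backbone.
    """
    rng = np.random.default_rng(seed)
    ref = dendropy.Tree.get(data=backbone, schema="newick", preserve_underscores=True)
    leaves = {lf.taxon.label for lf in ref.leaf_node_iter()}
    if len(leaves) < 3:
        raise SimulationError("backbone must have at least 3 leaves")
    clash = set(rogue_taxa) & leaves
    if clash:
        raise SimulationError(f"rogue taxa already in backbone: {sorted(clash)}")
    for node in ref.preorder_node_iter():
        if node.parent_node is not None and not node.is_leaf():
            if len(node.child_nodes()) != 2:
                raise SimulationError("backbone must be fully resolved")

    out = []
    for _ in range(n_trees):
        tree = dendropy.Tree.get(data=backbone, schema="newick", preserve_underscores=True)
        for rogue in rogue_taxa:
            nodes = [
                nd for nd in tree.preorder_node_iter() if nd.parent_node is not None
            ]
            target = nodes[int(rng.integers(len(nodes)))]
            parent = target.parent_node
            parent.remove_child(target)
            mid = parent.new_child()
            mid.add_child(target)
            taxon = tree.taxon_namespace.get_taxon(rogue)
            if taxon is None:
                taxon = tree.taxon_namespace.new_taxon(rogue)
            mid.new_child(taxon=taxon)
        out.append(
            tree.as_string(
                schema="newick",
                suppress_rooting=True,
                suppress_edge_lengths=True,
                unquoted_underscores=True,
            ).strip()
        )
    return out
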