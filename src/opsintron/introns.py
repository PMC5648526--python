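"""Intron position/phase homology mapping on protein alignments.

Intron marks derived from gene structures are projected onto one or more
multiple sequence alignments of the corresponding proteins. Introns are
considered potentially homologous when they fall at the same alignment
column (within an optional window) with the same phase; positions carried
by most members of a clade are reported as clade-conserved; conserved
positions of two clades are tested for overlap; and the whole procedure
can be repeated over alternative alignments of the same sequences to
check robustness against alignment artefacts.

The homology key is (anchor-residue alignment column, phase): introns of
different phase are never clustered together, because phase-discordant
introns cannot be homologous without intron sliding. Cross-alignment
correspondence of clusters uses alignment-invariant intron identities
(seq_id, cds_offset, phase) rather than column numbers, which are not
comparable between alignments.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

from .gene_structure import IntronMark

__all__ = [
    "AlignedSequence",
    "MappedIntron",
    "IntronCluster",
    "CladeConservationReport",
    "OverlapReport",
    "RobustnessReport",
    "read_alignment_fasta",
    "read_clade_table",
    "map_intron_to_alignment",
    "map_marks",
    "cluster_introns",
    "clade_conserved_positions",
    "compare_clades",
    "cross_alignment_robustness",
    "render_intron_map",
]

GAP_CHARS = frozenset("-.")


class MappingError(ValueError):
    pass


@dataclass
class AlignedSequence:
    """One row of a protein alignment with a residue-to-column map."""

    seq_id: str
    aligned: str
    _res2col: list[int] = field(init=False, repr=False)

    def __post_init__(self):
        self._res2col = [
            i + 1 for i, ch in enumerate(self.aligned) if ch not in GAP_CHARS
        ]

    @property
    def ungapped(self) -> str:
        return "".join(ch for ch in self.aligned if ch not in GAP_CHARS)

    @property
    def n_residues(self) -> int:
        return len(self._res2col)

    def column_of(self, residue_index: int) -> int:
        """1-based alignment column of the 1-based residue index."""
        if not 1 <= residue_index <= self.n_residues:
            raise MappingError(
                f"{self.seq_id}: residue {residue_index} outside "
                f"[1,{self.n_residues}]"
            )
        return self._res2col[residue_index - 1]


@dataclass(frozen=True)
class MappedIntron:
    """An intron mark projected to an alignment column."""

    mark: IntronMark
    column: int

    @property
    def seq_id(self) -> str:
        return self.mark.gene_id

    @property
    def phase(self) -> int:
        return self.mark.phase

    @property
    def identity(self) -> tuple[str, int, int]:
        """Alignment-invariant identity: (seq_id, cds_offset, phase)."""
        return (self.mark.gene_id, self.mark.cds_offset, self.mark.phase)


@dataclass
class IntronCluster:
    """A group of mapped introns sharing phase and (windowed) column."""

    column: int  # representative (leftmost member) column
    phase: int
    members: list[MappedIntron]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def seq_ids(self) -> set[str]:
        return {m.seq_id for m in self.members}

    @property
    def member_identities(self) -> frozenset[tuple[str, int, int]]:
        return frozenset(m.identity for m in self.members)

    @property
    def key(self) -> tuple[int, int]:
        return (self.column, self.phase)


@dataclass
class ConservedPosition:
    cluster: IntronCluster
    clade: str
    carriers: list[str]  # clade members carrying the intron
    clade_size: int
    other_carriers: list[str]  # cluster members outside the clade

    @property
    def fraction(self) -> float:
        return len(self.carriers) / self.clade_size


@dataclass
class CladeConservationReport:
    clade: str
    clade_size: int
    conserved: list[ConservedPosition]
    min_fraction: float
    min_members: int
    window: int

    @property
    def positions(self) -> list[tuple[int, int]]:
        return [(p.cluster.column, p.cluster.phase) for p in self.conserved]


@dataclass
class OverlapReport:
    clade_a: str
    clade_b: str
    window: int
    overlaps: list[tuple[ConservedPosition, ConservedPosition]]
    nearest: list[tuple[tuple[int, int], tuple[int, int], int]]
    # ((col_a, phase_a), (col_b, phase_b), |delta column|) for all cross pairs

    @property
    def overlap_count(self) -> int:
        return len(self.overlaps)


@dataclass
class RobustnessReport:
    alignment_names: list[str]
    conserved_by_alignment: dict[str, list[ConservedPosition]]
    groups: list[dict]  # one per correspondence group of conserved positions
    jaccard_min: float

    @property
    def robust_groups(self) -> list[dict]:
        return [g for g in self.groups if g["robust"]]


# ---------------------------------------------------------------------------
# input


def read_alignment_fasta(
    source: str | os.PathLike,
    proteins: Optional[dict[str, str]] = None,
) -> list[AlignedSequence]:
    """Read an aligned FASTA; optionally enforce that each row's ungapped
    sequence equals the given input protein exactly."""
    records = list(SeqIO.parse(str(source), "fasta"))
    if not records:
        raise MappingError(f"no sequences in alignment {source}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise MappingError(f"ragged alignment {source}: row lengths {sorted(lengths)}")
    out = [AlignedSequence(r.id, str(r.seq).upper()) for r in records]
    if proteins is not None:
        for row in out:
            expected = proteins.get(row.seq_id)
            if expected is not None and row.ungapped != expected.upper().rstrip("*"):
                raise MappingError(
                    f"{row.seq_id}: ungapped alignment row differs from input protein"
                )
    return out


def read_clade_table(source: str | os.PathLike) -> dict[str, str]:
    """Read taxon<TAB>clade assignments (optional header line)."""
    out = {}
    with open(source) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#") or ln == "taxon\tclade":
                continue
            taxon, clade = ln.split("\t")[:2]
            out[taxon] = clade
    return out


# ---------------------------------------------------------------------------
# mapping and clustering


def map_intron_to_alignment(mark: IntronMark, seq: AlignedSequence) -> MappedIntron:
    """Project a mark onto the alignment column of its anchor residue."""
    if mark.anchor_residue > seq.n_residues:
        raise MappingError(
            f"gene {mark.gene_id!r}: anchor residue {mark.anchor_residue} beyond "
            f"sequence length {seq.n_residues}"
        )
    return MappedIntron(mark=mark, column=seq.column_of(mark.anchor_residue))


def map_marks(
    marks: Iterable[IntronMark], alignment: Sequence[AlignedSequence]
) -> list[MappedIntron]:
    """Map many marks onto one alignment, matching rows by sequence id."""
    rows = {row.seq_id: row for row in alignment}
    out = []
    for mark in marks:
        row = rows.get(mark.gene_id)
        if row is None:
            raise MappingError(f"gene {mark.gene_id!r} not in alignment")
        out.append(map_intron_to_alignment(mark, row))
    return out


def cluster_introns(
    mapped: Sequence[MappedIntron], window: int = 0
) -> list[IntronCluster]:
    """Group mapped introns sharing phase within a column window.

    With ``window=0`` introns cluster iff they share exact column and
    phase. With ``window>0`` a greedy left-to-right pass over the
    column-sorted introns of each phase opens a cluster at the leftmost
    unassigned intron and absorbs introns within ``window`` columns of
    that representative. At most one intron per sequence joins a cluster;
    the one nearest the representative wins (ties to the lower column)
    and the displaced intron seeds a new cluster.
    """
    if window < 0:
        raise MappingError("window must be >= 0")
    clusters: list[IntronCluster] = []
    by_phase: dict[int, list[MappedIntron]] = {}
    for mi in mapped:
        by_phase.setdefault(mi.phase, []).append(mi)
    for phase in sorted(by_phase):
        pool = sorted(by_phase[phase], key=lambda m: (m.column, m.seq_id))
        current: Optional[IntronCluster] = None
        for mi in pool:
            if current is not None and mi.column - current.column <= window:
                prior = next(
                    (m for m in current.members if m.seq_id == mi.seq_id), None
                )
                if prior is None:
                    current.members.append(mi)
                    continue
                # same sequence twice in the window: nearest to the
                # representative stays (sorted order makes prior nearest
                # or tied-lower), the newcomer opens the next cluster
            current = IntronCluster(column=mi.column, phase=phase, members=[mi])
            clusters.append(current)
    clusters.sort(key=lambda c: (c.column, c.phase))
    return clusters


# ---------------------------------------------------------------------------
# conservation, overlap, robustness


def clade_conserved_positions(
    clusters: Sequence[IntronCluster],
    clade_map: dict[str, str],
    clade: str,
    min_fraction: float = 0.9,
    min_members: int = 2,
    window: int = 0,
) -> CladeConservationReport:
    """Report clusters carried by at least ``min_fraction`` of a clade.

    A cluster is clade-conserved iff at least ``min_fraction`` of the
    clade's sequences and at least ``min_members`` sequences in absolute
    terms carry a member intron. Carriers from other clades are listed
    but do not count toward the fraction. Sequences in clusters that are
    missing from the clade table are excluded with a warning.
    """
    if not 0 < min_fraction <= 1:
        raise MappingError("min_fraction must be in (0,1]")
    clade_members = {t for t, c in clade_map.items() if c == clade}
    if not clade_members:
        raise MappingError(f"clade {clade!r} has no members in the clade table")
    conserved = []
    warned: set[str] = set()
    for cluster in clusters:
        carriers, others = [], []
        for sid in sorted(cluster.seq_ids):
            if sid in clade_members:
                carriers.append(sid)
            elif sid in clade_map:
                others.append(sid)
            else:
                if sid not in warned:
                    warnings.warn(
                        f"sequence {sid!r} not in the clade table; excluded",
                        stacklevel=2,
                    )
                    warned.add(sid)
        if (
            carriers
            and len(carriers) >= min_members
            and len(carriers) / len(clade_members) >= min_fraction
        ):
            conserved.append(
                ConservedPosition(
                    cluster=cluster,
                    clade=clade,
                    carriers=carriers,
                    clade_size=len(clade_members),
                    other_carriers=others,
                )
            )
    conserved.sort(key=lambda p: p.cluster.key)
    return CladeConservationReport(
        clade=clade,
        clade_size=len(clade_members),
        conserved=conserved,
        min_fraction=min_fraction,
        min_members=min_members,
        window=window,
    )


def compare_clades(
    a: CladeConservationReport,
    b: CladeConservationReport,
    window: int = 0,
) -> OverlapReport:
    """Test whether two clades' conserved intron positions overlap.

    A pair of conserved positions overlaps iff the phases are equal and
    the column distance is at most ``window``. The nearest-distance table
    for every cross-clade pair is reported regardless, so near-misses
    (similar position, or same column with different phase) stay visible.
    """
    overlaps = []
    nearest = []
    for pa in a.conserved:
        for pb in b.conserved:
            d = abs(pa.cluster.column - pb.cluster.column)
            nearest.append((pa.cluster.key, pb.cluster.key, d))
            if pa.cluster.phase == pb.cluster.phase and d <= window:
                overlaps.append((pa, pb))
    nearest.sort(key=lambda t: (t[2], t[0], t[1]))
    return OverlapReport(
        clade_a=a.clade,
        clade_b=b.clade,
        window=window,
        overlaps=overlaps,
        nearest=nearest,
    )


def cross_alignment_robustness(
    alignments: dict[str, Sequence[AlignedSequence]],
    marks: Sequence[IntronMark],
    clade_map: dict[str, str],
    clades: Optional[Sequence[str]] = None,
    min_fraction: float = 0.9,
    min_members: int = 2,
    window: int = 0,
    jaccard_min: float = 0.5,
) -> RobustnessReport:
    """Check which conserved positions survive in every alignment.

    The pipeline (map, cluster, clade conservation) is run independently
    per alignment; conserved positions are then matched across alignments
    by Jaccard similarity of their alignment-invariant member identities.
    A position is *robust* iff every alignment contains a matching
    conserved position (Jaccard >= ``jaccard_min``).
    """
    names = sorted(alignments)
    seq_sets = {
        name: {row.seq_id for row in alignments[name]} for name in names
    }
    reference_set = seq_sets[names[0]]
    for name in names[1:]:
        if seq_sets[name] != reference_set:
            raise MappingError(
                f"alignment {name!r} has a different sequence set than "
                f"{names[0]!r}"
            )
    if clades is None:
        clades = sorted(set(clade_map.values()))

    conserved_by_alignment: dict[str, list[ConservedPosition]] = {}
    for name in names:
        mapped = map_marks(marks, alignments[name])
        clusters = cluster_introns(mapped, window=window)
        found: list[ConservedPosition] = []
        for clade in clades:
            report = clade_conserved_positions(
                clusters,
                clade_map,
                clade,
                min_fraction=min_fraction,
                min_members=min_members,
                window=window,
            )
            found.extend(report.conserved)
        conserved_by_alignment[name] = found

    # correspondence groups: greedy chaining from the first alignment's
    # positions; Jaccard of member identities is symmetric so group
    # membership does not depend on which side is "reference"
    groups: list[dict] = []
    claimed: dict[str, set[int]] = {name: set() for name in names}
    for ref_name in names:
        for i, pos in enumerate(conserved_by_alignment[ref_name]):
            if i in claimed[ref_name]:
                continue
            group = {"clade": pos.clade, "by_alignment": {ref_name: pos}}
            claimed[ref_name].add(i)
            ident = pos.cluster.member_identities
            for other in names:
                if other == ref_name:
                    continue
                best_j, best_sim = None, 0.0
                for j, cand in enumerate(conserved_by_alignment[other]):
                    if j in claimed[other] or cand.clade != pos.clade:
                        continue
                    sim = _jaccard(ident, cand.cluster.member_identities)
                    if sim > best_sim:
                        best_j, best_sim = j, sim
                if best_j is not None and best_sim >= jaccard_min:
                    claimed[other].add(best_j)
                    group["by_alignment"][other] = conserved_by_alignment[other][
                        best_j
                    ]
            group["robust"] = set(group["by_alignment"]) == set(names)
            group["missing_in"] = sorted(set(names) - set(group["by_alignment"]))
            groups.append(group)
    return RobustnessReport(
        alignment_names=names,
        conserved_by_alignment=conserved_by_alignment,
        groups=groups,
        jaccard_min=jaccard_min,
    )


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


# ---------------------------------------------------------------------------
# rendering


def render_intron_map(
    alignment: Sequence[AlignedSequence],
    mapped: Sequence[MappedIntron],
    clade_map: dict[str, str],
    out_path: str | os.PathLike,
    conserved: Optional[Sequence[ConservedPosition]] = None,
) -> str:
    """Draw the alignment as grey rows with coloured intron bars.

    One row per sequence (grouped by clade), a coloured vertical tick at
    each mapped intron column (colour by phase), and translucent vertical
    bands behind clade-conserved positions.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = sorted(alignment, key=lambda r: (clade_map.get(r.seq_id, "~"), r.seq_id))
    index = {row.seq_id: i for i, row in enumerate(rows)}
    n_cols = len(rows[0].aligned)
    phase_colors = {0: "#d62728", 1: "#1f77b4", 2: "#2ca02c"}

    fig, ax = plt.subplots(
        figsize=(max(6.0, n_cols / 40.0), max(2.0, 0.22 * len(rows)))
    )
    for row in rows:
        y = index[row.seq_id]
        spans = _residue_spans(row.aligned)
        for start, end in spans:
            ax.plot([start, end], [y, y], color="0.75", lw=3, solid_capstyle="butt")
    if conserved:
        for pos in conserved:
            ax.axvspan(
                pos.cluster.column - 0.5,
                pos.cluster.column + 0.5,
                color=phase_colors[pos.cluster.phase],
                alpha=0.15,
            )
    for mi in mapped:
        y = index.get(mi.seq_id)
        if y is None:
            continue
        ax.plot(
            [mi.column, mi.column],
            [y - 0.35, y + 0.35],
            color=phase_colors[mi.phase],
            lw=1.8,
        )
    ax.set_yticks(range(len(rows)))
    ax.set_yticklabels([r.seq_id for r in rows], fontsize=6)
    ax.set_xlabel("alignment column")
    ax.set_xlim(0, n_cols + 1)
    ax.invert_yaxis()
    handles = [
        plt.Line2D([0], [0], color=c, lw=2, label=f"phase {p}")
        for p, c in phase_colors.items()
    ]
    ax.legend(handles=handles, fontsize=6, loc="upper right")
    fig.tight_layout()
    fig.savefig(str(out_path), dpi=150)
    plt.close(fig)
    return str(out_path)


def _residue_spans(aligned: str) -> list[tuple[int, int]]:
    spans = []
    start = None
    for i, ch in enumerate(aligned, start=1):
        if ch not in GAP_CHARS:
            if start is None:
                start = i
        elif start is not None:
            spans.append((start, i - 1))
            start = None
    if start is not None:
        spans.append((start, len(aligned)))
    return spans
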