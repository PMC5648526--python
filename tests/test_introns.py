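"""Intron projection, clustering, conservation, overlap, robustness."""

import numpy as np
import pytest

from opsintron.gene_structure import IntronMark
from opsintron.introns import (
    AlignedSequence,
    MappedIntron,
    MappingError,
    clade_conserved_positions,
    cluster_introns,
    compare_clades,
    cross_alignment_robustness,
    map_intron_to_alignment,
    map_marks,
)


def _mark(gene, anchor, phase):
    return IntronMark.from_anchor(gene, anchor, phase)


def _mi(gene, column, phase, offset=None):
    offset = offset if offset is not None else column * 3 + phase
    return MappedIntron(mark=IntronMark.from_offset(gene, offset), column=column)


def _mi_at(gene, column, phase):
    # build a MappedIntron with an arbitrary distinct offset realising phase
    return MappedIntron(
        mark=IntronMark.from_offset(gene, (column + 1) * 3 + phase), column=column
    )


class TestMapping:
    def test_ungapped_sequence_is_identity(self):
        seq = AlignedSequence("s", "MKVLTSA")
        mi = map_intron_to_alignment(_mark("s", 5, 0), seq)
        assert mi.column == 5 and mi.phase == 0

    def test_gaps_shift_columns(self):
        # non-gap characters of M--KVLTS sit at columns 1,4,5,6,7,8
        seq = AlignedSequence("s", "M--KVLTS")
        assert map_intron_to_alignment(_mark("s", 3, 1), seq).column == 5
        assert map_intron_to_alignment(_mark("s", 4, 1), seq).column == 6

    def test_anchor_beyond_sequence_names_gene(self):
        seq = AlignedSequence("s", "MK")
        with pytest.raises(MappingError, match="'s'"):
            map_intron_to_alignment(_mark("s", 10, 0), seq)

    def test_gap_column_prefix_translates_all_columns(self):
        rows = [AlignedSequence("a", "MKVL"), AlignedSequence("b", "M-VL")]
        padded = [AlignedSequence(r.seq_id, "----" + r.aligned) for r in rows]
        marks = [_mark("a", 3, 0), _mark("b", 3, 2)]
        before = map_marks(marks, rows)
        after = map_marks(marks, padded)
        for x, y in zip(before, after):
            assert y.column == x.column + 4
            assert y.identity == x.identity


def _brute_force_clusters(mapped, window=0):
    """Transitive closure over the relation: same phase and |dcol| <= window."""
    parent = list(range(len(mapped)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(mapped)):
        for j in range(i + 1, len(mapped)):
            if (
                mapped[i].phase == mapped[j].phase
                and abs(mapped[i].column - mapped[j].column) <= window
            ):
                parent[find(i)] = find(j)
    groups = {}
    for i, mi in enumerate(mapped):
        groups.setdefault(find(i), []).append(mi)
    return {frozenset(m.identity for m in g) for g in groups.values()}


class TestClustering:
    def test_phase_always_separates(self):
        mapped = [
            _mi_at("a", 12, 0),
            _mi_at("b", 12, 0),
            _mi_at("c", 12, 0),
            _mi_at("d", 12, 1),
        ]
        clusters = cluster_introns(mapped, window=0)
        assert sorted(c.size for c in clusters) == [1, 3]

    def test_window_merges_adjacent_columns(self):
        clusters = cluster_introns([_mi_at("a", 12, 0), _mi_at("b", 13, 0)], window=1)
        assert len(clusters) == 1 and clusters[0].size == 2

    def test_empty_input(self):
        assert cluster_introns([]) == []

    def test_one_intron_per_sequence_per_cluster(self):
        mapped = [
            MappedIntron(IntronMark.from_offset("a", 36), 12),
            MappedIntron(IntronMark.from_offset("a", 39), 13),
            MappedIntron(IntronMark.from_offset("b", 39), 13),
        ]
        clusters = cluster_introns(mapped, window=2)
        assert all(
            len({m.seq_id for m in c.members}) == len(c.members) for c in clusters
        )

    def test_greedy_equals_brute_force_at_window_zero(self):
        """Oracle equivalence on seeded random datasets of <= 30 sequences."""
        rng = np.random.default_rng(42)
        for _ in range(40):
            n_seq = int(rng.integers(2, 31))
            mapped = []
            for s in range(n_seq):
                seen = set()
                for _ in range(int(rng.integers(0, 4))):
                    col = int(rng.integers(1, 40))
                    phase = int(rng.integers(0, 3))
                    if (col, phase) in seen:  # one intron per CDS offset
                        continue
                    seen.add((col, phase))
                    mapped.append(
                        MappedIntron(
                            IntronMark.from_offset(f"s{s}", col * 3 + phase), col
                        )
                    )
            greedy = {c.member_identities for c in cluster_introns(mapped, window=0)}
            assert greedy == _brute_force_clusters(mapped, window=0)

    def test_window_monotonicity(self):
        """Enlarging the window never decreases any cluster's size."""
        rng = np.random.default_rng(5)
        mapped = [
            MappedIntron(
                IntronMark.from_offset(f"s{i}", int(c) * 3 + int(p)), int(c)
            )
            for i, (c, p) in enumerate(
                zip(rng.integers(1, 25, size=60), rng.integers(0, 3, size=60))
            )
        ]
        prev_max = 0
        for window in (0, 1, 2, 4, 8):
            sizes = sorted(
                (c.size for c in cluster_introns(mapped, window=window)),
                reverse=True,
            )
            assert sizes[0] >= prev_max
            prev_max = sizes[0]


class TestConservation:
    def _clusters_for(self, carried_by, column=10, phase=0):
        mapped = [_mi_at(sid, column, phase) for sid in carried_by]
        return cluster_introns(mapped)

    def test_full_clade_conserved(self):
        clade_map = {f"s{i}": "A" for i in range(5)}
        clusters = self._clusters_for([f"s{i}" for i in range(5)])
        rep = clade_conserved_positions(clusters, clade_map, "A", min_fraction=0.9)
        assert len(rep.conserved) == 1 and rep.conserved[0].fraction == 1.0

    @pytest.mark.parametrize("min_fraction, expect", [(0.8, 1), (0.9, 0)])
    def test_four_of_five_threshold_arithmetic(self, min_fraction, expect):
        clade_map = {f"s{i}": "A" for i in range(5)}
        clusters = self._clusters_for([f"s{i}" for i in range(4)])
        rep = clade_conserved_positions(
            clusters, clade_map, "A", min_fraction=min_fraction
        )
        assert len(rep.conserved) == expect

    def test_min_members_absolute_floor(self):
        clade_map = {"s0": "A"}
        clusters = self._clusters_for(["s0"])
        rep = clade_conserved_positions(
            clusters, clade_map, "A", min_fraction=0.5, min_members=2
        )
        assert rep.conserved == []

    def test_other_clade_carriers_reported_not_counted(self):
        clade_map = {"a1": "A", "a2": "A", "b1": "B"}
        clusters = self._clusters_for(["a1", "a2", "b1"])
        rep = clade_conserved_positions(clusters, clade_map, "A", min_fraction=0.9)
        (pos,) = rep.conserved
        assert pos.carriers == ["a1", "a2"] and pos.other_carriers == ["b1"]
        assert pos.fraction == 1.0

    def test_unknown_taxon_warns_and_excluded(self):
        clade_map = {"a1": "A", "a2": "A"}
        clusters = self._clusters_for(["a1", "a2", "mystery"])
        with pytest.warns(UserWarning, match="mystery"):
            rep = clade_conserved_positions(clusters, clade_map, "A")
        assert rep.conserved[0].carriers == ["a1", "a2"]

    def test_raising_min_fraction_never_adds_positions(self):
        clade_map = {f"s{i}": "A" for i in range(6)}
        mapped = []
        for i in range(6):
            mapped.append(_mi_at(f"s{i}", 10, 0))
        for i in range(4):
            mapped.append(_mi_at(f"s{i}", 20, 1))
        clusters = cluster_introns(mapped)
        prev = None
        for f in (0.5, 0.7, 0.9, 1.0):
            n = len(
                clade_conserved_positions(
                    clusters, clade_map, "A", min_fraction=f
                ).conserved
            )
            if prev is not None:
                assert n <= prev
            prev = n

    def test_noise_free_recovery_of_planted_positions(self, noise_free_dataset):
        ds = noise_free_dataset
        rows = [AlignedSequence(k, v) for k, v in ds.true_alignment.items()]
        marks = [m for ms in ds.marks().values() for m in ms]
        clusters = cluster_introns(map_marks(marks, rows))
        for clade in ds.clades:
            rep = clade_conserved_positions(clusters, ds.clade_map, clade)
            expected = sorted(
                (e["true_column"], e["phase"]) for e in ds.truth["planted"][clade]
            )
            assert rep.positions == expected


class TestOverlap:
    def _report(self, clade, keys, clade_map):
        mapped = []
        members = [t for t, c in clade_map.items() if c == clade]
        for col, phase in keys:
            mapped.extend(_mi_at(m, col, phase) for m in members)
        clusters = cluster_introns(mapped)
        return clade_conserved_positions(clusters, clade_map, clade)

    CLADES = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}

    def test_disjoint_positions_no_overlap(self):
        a = self._report("A", [(10, 0), (50, 2), (90, 0)], self.CLADES)
        b = self._report("B", [(30, 1), (70, 0)], self.CLADES)
        assert compare_clades(a, b, window=0).overlap_count == 0

    def test_shared_position_counts(self):
        a = self._report("A", [(10, 0), (50, 2), (90, 0)], self.CLADES)
        b = self._report("B", [(10, 0)], self.CLADES)
        assert compare_clades(a, b, window=0).overlap_count == 1

    def test_near_miss_reported_in_nearest_table(self):
        a = self._report("A", [(10, 0)], self.CLADES)
        b = self._report("B", [(12, 0)], self.CLADES)
        report = compare_clades(a, b, window=0)
        assert report.overlap_count == 0
        assert report.nearest[0][2] == 2

    def test_same_column_different_phase_never_overlaps(self):
        a = self._report("A", [(10, 0)], self.CLADES)
        b = self._report("B", [(10, 1)], self.CLADES)
        assert compare_clades(a, b, window=3).overlap_count == 0


class TestRobustness:
    def test_identical_alignments_all_robust(self, noise_free_dataset):
        ds = noise_free_dataset
        rows = [AlignedSequence(k, v) for k, v in ds.true_alignment.items()]
        marks = [m for ms in ds.marks().values() for m in ms]
        rob = cross_alignment_robustness(
            {"one": rows, "two": rows}, marks, ds.clade_map
        )
        assert rob.groups and all(g["robust"] for g in rob.groups)

    def test_gap_padding_preserves_robustness(self, noise_free_dataset):
        """Inserting all-gap columns changes columns but not identities."""
        ds = noise_free_dataset
        rows = [AlignedSequence(k, v) for k, v in ds.true_alignment.items()]
        padded = [
            AlignedSequence(r.seq_id, r.aligned[:50] + "---" + r.aligned[50:])
            for r in rows
        ]
        marks = [m for ms in ds.marks().values() for m in ms]
        rob = cross_alignment_robustness(
            {"plain": rows, "padded": padded}, marks, ds.clade_map
        )
        n_planted = sum(len(v) for v in ds.truth["planted"].values())
        assert len(rob.robust_groups) == len(rob.groups) == n_planted

    def test_scrambled_region_flags_cluster_non_robust(self):
        """If a second alignment splits one clade's anchors 2+1 across
        columns, the planted cluster fails the Jaccard match and is
        flagged as missing from that alignment."""
        clade_map = {"a1": "A", "a2": "A", "a3": "A"}
        rows_a = [AlignedSequence(s, "MKVLTSAQ") for s in clade_map]
        # alignment B shifts a3's anchor residue to a different column
        rows_b = [
            AlignedSequence("a1", "MKVLTSAQ-"),
            AlignedSequence("a2", "MKVLTSAQ-"),
            AlignedSequence("a3", "MKVL-TSAQ"),
        ]
        marks = [_mark(s, 5, 0) for s in clade_map]
        rob = cross_alignment_robustness(
            {"A": rows_a, "B": rows_b},
            marks,
            clade_map,
            min_fraction=0.6,
            min_members=2,
            jaccard_min=0.8,
        )
        flagged = [g for g in rob.groups if not g["robust"]]
        assert flagged

    def test_sequence_set_mismatch_rejected(self):
        rows_a = [AlignedSequence("a", "MK"), AlignedSequence("b", "MK")]
        rows_b = [AlignedSequence("a", "MK")]
        with pytest.raises(MappingError, match="different sequence set"):
            cross_alignment_robustness({"A": rows_a, "B": rows_b}, [], {"a": "A"})
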