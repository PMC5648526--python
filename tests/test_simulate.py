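"""Synthetic-family generator: determinism, planted truth, noise models."""

import numpy as np
import pytest

from opsintron.gene_structure import introns_from_structure
from opsintron.simulate import (
    SimulationConfig,
    SimulationError,
    simulate_family,
    simulate_tree_set,
)
from opsintron.stability import tree_set_from_newicks


def _config(**kw):
    base = dict(
        seed=3,
        n_clades=2,
        seqs_per_clade=4,
        protein_length=120,
        substitution_rate=0.05,
        planted_introns=[[(30, 0), (60, 1)], [(45, 2)]],
        n_trees=3,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"seqs_per_clade": 0},
            {"substitution_rate": 1.5},
            {"intron_jitter": -1},
            {"planted_introns": [[(30, 0)]]},  # wrong clade count
            {"planted_introns": [[(500, 0)], []]},  # anchor out of range
            {"planted_introns": [[(30, 3)], []]},  # bad phase
        ],
    )
    def test_impossible_configs_rejected(self, kw):
        with pytest.raises(SimulationError):
            simulate_family(_config(**kw))


class TestDeterminism:
    def test_same_seed_gives_identical_bytes(self, tmp_path):
        a = simulate_family(_config()).write(tmp_path / "a")
        b = simulate_family(_config()).write(tmp_path / "b")
        for name in a:
            assert open(a[name], "rb").read() == open(b[name], "rb").read(), name

    def test_different_seed_changes_sequences(self):
        ds1 = simulate_family(_config(seed=1))
        ds2 = simulate_family(_config(seed=2))
        assert ds1.proteins != ds2.proteins


class TestPlantedTruth:
    def test_noise_free_members_carry_exact_marks(self, noise_free_dataset):
        ds = noise_free_dataset
        for clade, planted in zip(ds.clades, ds.config.planted_introns):
            expected = sorted(planted)
            for seq_id, c in ds.clade_map.items():
                if c != clade:
                    continue
                realized = sorted(
                    (e["anchor"], e["phase"])
                    for e in ds.truth["realized"][seq_id]
                )
                assert realized == expected

    def test_marks_survive_gff_round_trip(self, noise_free_dataset):
        """plant -> write GFF3 -> parse -> derive recovers (anchor, phase)."""
        from opsintron.gene_structure import parse_gene_structures

        ds = noise_free_dataset
        parsed = {s.gene_id: s for s in parse_gene_structures(ds.gff3_text())}
        for seq_id, entries in ds.truth["realized"].items():
            derived = introns_from_structure(parsed[seq_id])
            assert [(m.anchor_residue, m.phase) for m in derived] == [
                (e["anchor"], e["phase"]) for e in entries
            ]

    def test_phase_realization_all_phases(self, noise_free_dataset):
        """Recomputing phase from each CDS offset matches the request;
        the planted set covers phases 0, 1 and 2."""
        ds = noise_free_dataset
        phases_seen = set()
        for entries in ds.truth["realized"].values():
            for e in entries:
                assert e["cds_offset"] % 3 == e["phase"]
                phases_seen.add(e["phase"])
        assert phases_seen == {0, 1, 2}

    def test_translation_consistency(self, noisy_dataset):
        """Splicing introns out of each synthetic gene and translating
        reproduces the protein exactly (noisy config included)."""
        from opsintron.gene_structure import validate_structure

        ds = noisy_dataset
        for seq_id, s in ds.structures.items():
            report = validate_structure(s, ds.proteins[seq_id], ds.contigs[s.contig_id])
            assert report["ok"]

    def test_true_alignment_matches_proteins(self, noisy_dataset):
        ds = noisy_dataset
        widths = {len(row) for row in ds.true_alignment.values()}
        assert len(widths) == 1
        for seq_id, row in ds.true_alignment.items():
            assert row.replace("-", "") == ds.proteins[seq_id]

    def test_loss_rate_matches_binomial_expectation(self):
        """With loss probability 0.2 and 10 members, the mean carrier
        count per planted intron follows Binomial(10, 0.8)."""
        n_rep, members, p_loss = 250, 10, 0.2
        counts = []
        for rep in range(n_rep):
            ds = simulate_family(
                SimulationConfig(
                    seed=50_000 + rep,
                    n_clades=1,
                    seqs_per_clade=members,
                    protein_length=40,
                    substitution_rate=0.0,
                    planted_introns=[[(20, 0)]],
                    intron_loss_prob=p_loss,
                    n_trees=1,
                )
            )
            counts.append(
                sum(len(v) for v in ds.truth["realized"].values())
            )
        mean = np.mean(counts)
        expected = members * (1 - p_loss)  # 8.0
        mc_sigma = np.sqrt(members * p_loss * (1 - p_loss) / n_rep)
        assert abs(mean - expected) < 4 * mc_sigma

    def test_jitter_keeps_anchor_within_bounds(self):
        ds = simulate_family(
            _config(intron_jitter=5, planted_introns=[[(2, 0), (119, 2)], [(60, 1)]])
        )
        for seq_id, entries in ds.truth["realized"].items():
            n = len(ds.proteins[seq_id])
            for e in entries:
                assert 1 <= e["anchor"] <= n
                assert 0 < e["cds_offset"] < 3 * (n + 1)


class TestTreeSets:
    BACKBONE = "((a,b),c);"

    def test_no_rogues_copies_backbone(self):
        trees = simulate_tree_set(self.BACKBONE, [], 5, seed=0)
        assert len(trees) == 5 and len(set(trees)) == 1

    def test_rogue_not_allowed_in_backbone(self):
        with pytest.raises(SimulationError, match="already in backbone"):
            simulate_tree_set(self.BACKBONE, ["a"], 1, seed=0)

    def test_tiny_backbone_rejected(self):
        with pytest.raises(SimulationError, match="3 leaves"):
            simulate_tree_set("(a,b);", ["r"], 1, seed=0)

    def test_unresolved_backbone_rejected(self):
        with pytest.raises(SimulationError, match="resolved"):
            simulate_tree_set("((a,b,c),d);", ["r"], 1, seed=0)

    def test_seed_fixed_gives_identical_newick(self):
        a = simulate_tree_set(self.BACKBONE, ["r"], 10, seed=4)
        b = simulate_tree_set(self.BACKBONE, ["r"], 10, seed=4)
        assert a == b

    def test_attachment_uniform_over_edges(self):
        """On ((a,b),c) the 4 attachment edges give 4 distinguishable
        topologies; a chi-square test accepts uniform frequencies."""
        from scipy.stats import chisquare

        n = 800
        trees = simulate_tree_set(self.BACKBONE, ["r"], n, seed=9)
        counts = {}
        for nw in trees:
            counts[_canonical(nw)] = counts.get(_canonical(nw), 0) + 1
        assert len(counts) == 4
        stat, p = chisquare(list(counts.values()))
        assert p > 0.01

    def test_all_trees_share_leaf_set(self):
        trees = simulate_tree_set(self.BACKBONE, ["r1", "r2"], 20, seed=2)
        ts = tree_set_from_newicks(trees)  # raises on mismatched leaf sets
        assert ts.n_taxa == 5 and ts.n_trees == 20


def _canonical(newick: str) -> str:
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    for node in tree.preorder_node_iter():
        node._child_nodes.sort(
            key=lambda nd: min(lf.taxon.label for lf in nd.leaf_iter())
        )
    return tree.as_string(schema="newick", suppress_rooting=True).strip()
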