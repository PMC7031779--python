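import xml.etree.ElementTree as ET

import pytest

import revenant as r
from revenant.gene_tree import (
    EventLogIntegrityError,
    build_gene_tree,
    emit_reconciliation,
    prune_gene_tree,
    reconciliation_event_counts,
    root_genome_origination_events,
)
from revenant.genome import GenomeEvent
from revenant.species_tree import load_user_tree


def two_tip_log(extra=()):
    """Event log for one root-genome family on the tree (A:2,B:2)."""
    tree = load_user_tree("(A:2,B:2);")
    root = tree.root_id
    log = [
        GenomeEvent(0.0, "O", root, family_ids=(1,), copy_map={(1, 0): (1,)}),
        GenomeEvent(0.0, "SP", root, family_ids=(1,), copy_map={(1, 1): (2, 3)}),
        *extra,
        GenomeEvent(2.0, "END", "A", family_ids=(1,), copy_map={(1, 2): ()}),
        GenomeEvent(2.0, "END", "B", family_ids=(1,), copy_map={(1, 3): ()}),
    ]
    return tree, log


def ghost_donor_case():
    """Donor lineage B transfers into A, then goes extinct.

    The motivating ghost-lineage scenario: the pruned species tree does not contain
    B, yet a copy of the family survives in A only because B donated it.
    """
    tree = load_user_tree("(A:3,B:1.5);")  # B extinct at 1.5
    root = tree.root_id
    log = [
        GenomeEvent(0.0, "O", root, family_ids=(1,), copy_map={(1, 0): (1,)}),
        GenomeEvent(0.0, "SP", root, family_ids=(1,), copy_map={(1, 1): (2, 3)}),
        # A loses its own copy before the transfer arrives
        GenomeEvent(0.5, "L", "A", start=0, extension=1,
                    family_ids=(1,), copy_map={(1, 2): ()}),
        # B (the future ghost) donates into A
        GenomeEvent(1.0, "T", "B", recipient_id="A", start=0, extension=1,
                    family_ids=(1,), copy_map={(1, 3): (4,)}),
        GenomeEvent(1.5, "EX", "B", family_ids=(1,), copy_map={(1, 3): ()}),
        GenomeEvent(3.0, "END", "A", family_ids=(1,), copy_map={(1, 4): ()}),
    ]
    return tree, log


class TestBuild:
    def test_no_event_family_congruent_with_species_tree(self):
        tree, log = two_tip_log()
        gt = build_gene_tree(1, log, tree)
        counts = gt.event_counts()
        assert counts == {"ORIGINATION": 1, "SPECIATION": 1, "PRESENT": 2}
        assert sorted(l.species_lineage for l in gt.leaves()) == ["A", "B"]

    def test_terminal_duplication_adds_cherry(self):
        extra = [
            GenomeEvent(1.0, "D", "A", start=0, extension=1,
                        family_ids=(1,), copy_map={(1, 2): (9,)}),
            GenomeEvent(2.0, "END", "A", family_ids=(1,), copy_map={(1, 9): ()}),
        ]
        tree, log = two_tip_log(extra)
        # patch A's END record: both copies now present
        gt = build_gene_tree(1, log, tree)
        assert gt.event_counts()["DUPLICATION"] == 1
        assert len(gt.leaves("PRESENT")) == 3
        dup = next(n for n in gt.nodes.values() if n.event == "DUPLICATION")
        assert dup.species_lineage == "A" and len(dup.children) == 2

    def test_unknown_copy_raises_integrity_error(self):
        tree, log = two_tip_log()
        bad = log[:1] + [
            GenomeEvent(1.0, "D", "A", start=0, extension=1,
                        family_ids=(1,), copy_map={(1, 77): (78,)})
        ]
        with pytest.raises(EventLogIntegrityError, match="77"):
            build_gene_tree(1, bad, tree)

    def test_missing_origination_raises(self):
        tree, log = two_tip_log()
        with pytest.raises(EventLogIntegrityError, match="origination"):
            build_gene_tree(2, log[1:], tree)

    def test_times_increase_root_to_leaf(self, small_gene_trees):
        for gt in small_gene_trees.values():
            for node in gt.nodes.values():
                for c in node.children:
                    assert gt.nodes[c].time >= node.time

    def test_node_times_lie_on_species_branches(self, small_run, small_gene_trees):
        tree = small_run[0]
        for gt in small_gene_trees.values():
            for node in gt.nodes.values():
                sp = tree.nodes[node.species_lineage]
                assert sp.t_start - 1e-9 <= node.time <= sp.t_end + 1e-9

    def test_present_leaves_match_surviving_copies(self, small_run, small_gene_trees):
        tree, _, _, result = small_run
        alive = set(tree.alive_at_end())
        for fam, gt in small_gene_trees.items():
            copies = sum(
                1 for lid in alive for g in result.genomes[lid].genes
                if g.family_id == fam
            )
            assert len(gt.leaves("PRESENT")) == copies


class TestPrune:
    def test_identity_without_losses(self):
        tree, log = two_tip_log()
        gt = build_gene_tree(1, log, tree)
        pruned = prune_gene_tree(gt)
        assert pruned.event_counts() == gt.event_counts()

    def test_all_lost_returns_none(self):
        tree = load_user_tree("(A:2,B:2);")
        root = tree.root_id
        log = [
            GenomeEvent(0.0, "O", root, family_ids=(1,), copy_map={(1, 0): (1,)}),
            GenomeEvent(0.5, "L", root, start=0, extension=1,
                        family_ids=(1,), copy_map={(1, 1): ()}),
        ]
        gt = build_gene_tree(1, log, tree)
        assert prune_gene_tree(gt) is None

    def test_idempotent(self, small_gene_trees):
        for gt in small_gene_trees.values():
            once = prune_gene_tree(gt)
            if once is None:
                continue
            twice = prune_gene_tree(once)
            assert {n.node_id for n in once.nodes.values()} == {
                n.node_id for n in twice.nodes.values()
            }

    def test_ghost_donor_copy_survives_pruning(self):
        tree, log = ghost_donor_case()
        gt = build_gene_tree(1, log, tree)
        # complete tree shows the donor path through B
        assert any(n.species_lineage == "B" for n in gt.nodes.values())
        assert gt.event_counts()["TRANSFER_DEPART"] == 1
        pruned = prune_gene_tree(gt)
        assert pruned is not None
        leaves = pruned.leaves("PRESENT")
        assert len(leaves) == 1 and leaves[0].species_lineage == "A"
        # no donor-lineage leaf remains in the observable tree
        assert all(n.event != "EXTINCTION" for n in pruned.nodes.values())


class TestReconciliation:
    def test_no_event_family_all_speciations(self):
        tree, log = two_tip_log()
        gt = build_gene_tree(1, log, tree)
        xml = emit_reconciliation(gt, tree)
        doc = ET.fromstring(xml)
        ns = {"r": "http://www.recg.org"}
        assert len(doc.findall(".//r:speciation", ns)) == 1
        assert len(doc.findall(".//r:duplication", ns)) == 0
        assert len(doc.findall(".//r:leaf", ns)) == 2

    def test_single_duplication_tagged_once(self):
        extra = [
            GenomeEvent(1.0, "D", "A", start=0, extension=1,
                        family_ids=(1,), copy_map={(1, 2): (9,)}),
            GenomeEvent(2.0, "END", "A", family_ids=(1,), copy_map={(1, 9): ()}),
        ]
        tree, log = two_tip_log(extra)
        gt = build_gene_tree(1, log, tree)
        doc = ET.fromstring(emit_reconciliation(gt, tree))
        ns = {"r": "http://www.recg.org"}
        assert len(doc.findall(".//r:duplication", ns)) == 1

    def test_transfer_tags_reference_donor_and_recipient(self):
        tree, log = ghost_donor_case()
        gt = build_gene_tree(1, log, tree)
        doc = ET.fromstring(emit_reconciliation(gt, tree))
        ns = {"r": "http://www.recg.org"}
        out = doc.findall(".//r:branchingOut", ns)
        back = doc.findall(".//r:transferBack", ns)
        assert len(out) == 1 and out[0].get("speciesLocation") == "B"
        assert len(back) == 1 and back[0].get("destinationSpecies") == "A"

    def test_event_counts_match_log_exactly(self, small_run, small_gene_trees):
        _, _, _, result = small_run
        for fam, gt in small_gene_trees.items():
            rc = reconciliation_event_counts(gt)
            for typ in "DTL":
                in_log = sum(
                    sum(1 for (f, _) in e.copy_map if f == fam)
                    for e in result.event_log
                    if e.type == typ
                )
                assert rc[typ] == in_log, (fam, typ)

    def test_species_tree_clades_present(self, small_run, small_gene_trees):
        tree = small_run[0]
        fam = next(iter(small_gene_trees))
        doc = ET.fromstring(emit_reconciliation(small_gene_trees[fam], tree))
        ns = {"r": "http://www.recg.org"}
        names = {e.text for e in doc.findall(".//r:spTree//r:name", ns)}
        assert names == set(tree.nodes)
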