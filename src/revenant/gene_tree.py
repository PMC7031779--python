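"""Per-family gene trees replayed from the event log, plus reconciliations.

A gene tree records the genealogy of every copy of one family across the
species tree.  It is rebuilt by replaying the global event log in time
order: speciations bifurcate every copy present in the parent lineage,
duplications and transfers bifurcate single copies, losses and lineage
extinctions terminate them, and copies alive at the end of the simulation
become PRESENT leaves.  Inversions and transpositions never create nodes —
they rearrange neighbourhoods, not genealogy.

The *complete* gene tree keeps everything, including copies whose entire
history runs through lineages that later die: pruning to the *observable*
tree keeps exactly the ancestors of PRESENT leaves, which is how a transfer
from an extinct (ghost) donor leaves a surviving gene with no donor-side
relatives in the observable data.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Optional

from .genome import GenomeEvent
from .species_tree import CompleteSpeciesTree, Fate

__all__ = [
    "GeneTreeNode",
    "GeneTree",
    "build_gene_tree",
    "build_all_gene_trees",
    "prune_gene_tree",
    "emit_reconciliation",
    "reconciliation_event_counts",
]

BIFURCATING = ("SPECIATION", "DUPLICATION", "TRANSFER_DEPART")
TERMINAL = ("LOSS", "EXTINCTION", "PRESENT")


@dataclass
class GeneTreeNode:
    node_id: int
    family_id: int
    copy_id: int
    species_lineage: str
    time: float
    event: str  # ORIGINATION SPECIATION DUPLICATION TRANSFER_DEPART LOSS EXTINCTION PRESENT
    children: list[int] = field(default_factory=list)
    parent: Optional[int] = None

    @property
    def leaf_name(self) -> str:
        return f"{self.species_lineage}_{self.family_id}_{self.copy_id}"


@dataclass
class GeneTree:
    family_id: int
    nodes: dict[int, GeneTreeNode]
    root_id: int
    pruned: bool = False

    def __len__(self) -> int:
        return len(self.nodes)

    def leaves(self, event: str | None = None) -> list[GeneTreeNode]:
        out = [n for n in self.nodes.values() if not n.children]
        if event is not None:
            out = [n for n in out if n.event == event]
        return out

    def event_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for n in self.nodes.values():
            out[n.event] = out.get(n.event, 0) + 1
        return out

    def branch_length(self, node_id: int) -> float:
        n = self.nodes[node_id]
        if n.parent is None:
            return 0.0
        return n.time - self.nodes[n.parent].time

    def to_newick(self, precision: int = 10) -> str:
        fmt = f"%.{precision}g"

        def rec(nid: int) -> str:
            n = self.nodes[nid]
            bl = fmt % self.branch_length(nid)
            if n.children:
                inner = ",".join(rec(c) for c in n.children)
                return f"({inner}){n.leaf_name}:{bl}"
            return f"{n.leaf_name}:{bl}"

        return rec(self.root_id) + ";"


class EventLogIntegrityError(ValueError):
    """The event log references a copy before anything created it."""


class _Builder:
    def __init__(self, family_id: int):
        self.family_id = family_id
        self.nodes: dict[int, GeneTreeNode] = {}
        self.next_id = 0
        # (lineage, copy_id) -> parent node awaiting this copy's next event
        self.active: dict[tuple[str, int], int] = {}
        self.root_id: Optional[int] = None

    def new_node(
        self, copy_id: int, lineage: str, time: float, event: str, parent: Optional[int]
    ) -> int:
        nid = self.next_id
        self.next_id += 1
        self.nodes[nid] = GeneTreeNode(
            nid, self.family_id, copy_id, lineage, time, event, [], parent
        )
        if parent is not None:
            self.nodes[parent].children.append(nid)
        return nid

    def close(self, lineage: str, copy_id: int) -> int:
        key = (lineage, copy_id)
        if key not in self.active:
            raise EventLogIntegrityError(
                f"family {self.family_id}: copy {copy_id} referenced in lineage "
                f"{lineage} before any event created it"
            )
        return self.active.pop(key)


def build_gene_tree(
    family_id: int,
    event_log: list[GenomeEvent],
    species_tree: CompleteSpeciesTree,
) -> GeneTree:
    """Replay the event log and build the complete gene tree of one family.

    The log must contain the family's origination (or its presence in the
    root genome, encoded as an origination at the root's start time) and the
    SP/EX/END species records of every lineage the family ever occupied.
    """
    b = _Builder(family_id)
    events = sorted(
        (e for e in event_log if family_id in e.family_ids or e.type in ("SP", "EX", "END")),
        key=lambda e: e.time,
    )
    for e in events:
        if e.type == "O" and family_id in e.family_ids:
            new_copy = next(v[0] for (fam, _), v in e.copy_map.items() if fam == family_id)
            root = b.new_node(new_copy, e.lineage_id, e.time, "ORIGINATION", None)
            b.root_id = root
            b.active[(e.lineage_id, new_copy)] = root
        elif e.type == "D":
            for (fam, old), new in e.copy_map.items():
                if fam != family_id:
                    continue
                parent = b.close(e.lineage_id, old)
                node = b.new_node(old, e.lineage_id, e.time, "DUPLICATION", parent)
                b.active[(e.lineage_id, old)] = node
                b.active[(e.lineage_id, new[0])] = node
        elif e.type == "T":
            for (fam, old), new in e.copy_map.items():
                if fam != family_id:
                    continue
                parent = b.close(e.lineage_id, old)
                node = b.new_node(old, e.lineage_id, e.time, "TRANSFER_DEPART", parent)
                b.active[(e.lineage_id, old)] = node
                b.active[(e.recipient_id, new[0])] = node
        elif e.type == "L":
            for (fam, old), _ in e.copy_map.items():
                if fam != family_id:
                    continue
                parent = b.close(e.lineage_id, old)
                b.new_node(old, e.lineage_id, e.time, "LOSS", parent)
        elif e.type == "SP":
            node_sp = species_tree.nodes[e.lineage_id]
            c1, c2 = node_sp.children
            for (fam, old), new in e.copy_map.items():
                if fam != family_id:
                    continue
                parent = b.close(e.lineage_id, old)
                node = b.new_node(old, e.lineage_id, e.time, "SPECIATION", parent)
                b.active[(c1, new[0])] = node
                b.active[(c2, new[1])] = node
        elif e.type == "EX":
            for (fam, old), _ in e.copy_map.items():
                if fam != family_id:
                    continue
                parent = b.close(e.lineage_id, old)
                b.new_node(old, e.lineage_id, e.time, "EXTINCTION", parent)
        elif e.type == "END":
            for (fam, old), _ in e.copy_map.items():
                if fam != family_id:
                    continue
                parent = b.close(e.lineage_id, old)
                b.new_node(old, e.lineage_id, e.time, "PRESENT", parent)

    if b.root_id is None:
        raise EventLogIntegrityError(
            f"family {family_id}: no origination found in the event log"
        )
    if b.active:
        dangling = sorted(b.active)
        raise EventLogIntegrityError(
            f"family {family_id}: copies never terminated: {dangling}"
        )
    return GeneTree(family_id, b.nodes, b.root_id, pruned=False)


def root_genome_origination_events(
    root_genome, species_tree: CompleteSpeciesTree
) -> list[GenomeEvent]:
    """Synthesize origination records for the families of the root genome.

    Families present in the initial genome have no origination in the event
    log; these records place their gene-tree roots at the root lineage's
    start so every family replays uniformly.
    """
    t0 = species_tree.nodes[species_tree.root_id].t_start
    return [
        GenomeEvent(
            time=t0, type="O", lineage_id=species_tree.root_id,
            start=i, extension=1, family_ids=(g.family_id,),
            copy_map={(g.family_id, 0): (g.copy_id,)},
        )
        for i, g in enumerate(root_genome.genes)
    ]


def build_all_gene_trees(result, root_genome, species_tree) -> dict[int, GeneTree]:
    """Complete gene trees for every family ever seen in a simulation."""
    log = root_genome_origination_events(root_genome, species_tree) + list(result.event_log)
    return {
        fam: build_gene_tree(fam, log, species_tree) for fam in result.family_ids()
    }


def prune_gene_tree(gt: GeneTree) -> Optional[GeneTree]:
    """Observable gene tree: ancestors of PRESENT leaves only.

    Unary nodes are suppressed (branch durations summed, i.e. child nodes
    keep their absolute times and reattach to the nearest kept ancestor).
    Returns None when no copy survives to the present.
    """
    keep: set[int] = set()
    for leaf in gt.leaves("PRESENT"):
        nid: Optional[int] = leaf.node_id
        while nid is not None and nid not in keep:
            keep.add(nid)
            nid = gt.nodes[nid].parent
    if not keep:
        return None

    nodes: dict[int, GeneTreeNode] = {}

    def build(old_id: int, new_parent: Optional[int], suppress_unary: bool = True) -> int:
        node = gt.nodes[old_id]
        kept_children = [c for c in node.children if c in keep]
        if suppress_unary:
            while len(kept_children) == 1:
                node = gt.nodes[kept_children[0]]
                kept_children = [c for c in node.children if c in keep]
        new = GeneTreeNode(
            node.node_id, node.family_id, node.copy_id, node.species_lineage,
            node.time, node.event, [], new_parent,
        )
        nodes[new.node_id] = new
        if new_parent is not None:
            nodes[new_parent].children.append(new.node_id)
        for c in kept_children:
            build(c, new.node_id)
        return new.node_id

    # the origination root is legitimately unary and is kept; unary chains
    # created by the pruning itself are suppressed below it
    root = build(gt.root_id, None, suppress_unary=False)
    return GeneTree(gt.family_id, nodes, root, pruned=True)


# ---------------------------------------------------------------------------
# RecPhyloXML
# ---------------------------------------------------------------------------

_RECPHYLO_NS = "http://www.recg.org"


def _species_clade(tree: CompleteSpeciesTree, nid: str, parent: ET.Element) -> None:
    node = tree.nodes[nid]
    clade = ET.SubElement(parent, "clade")
    ET.SubElement(clade, "name").text = nid
    ET.SubElement(clade, "branch_length").text = repr(node.duration)
    for c in node.children:
        _species_clade(tree, c, clade)


def _gene_clade(
    gt: GeneTree, nid: int, parent: ET.Element, arriving_transfer: bool
) -> None:
    node = gt.nodes[nid]
    if node.species_lineage is None:  # defensive: every node must map somewhere
        raise ValueError(f"gene-tree node {nid} has no species assignment")
    clade = ET.SubElement(parent, "clade")
    ET.SubElement(clade, "name").text = node.leaf_name
    ET.SubElement(clade, "branch_length").text = repr(gt.branch_length(nid))
    ev = ET.SubElement(clade, "eventsRec")
    if arriving_transfer:
        ET.SubElement(ev, "transferBack", destinationSpecies=node.species_lineage)
    loc = {"speciesLocation": node.species_lineage}
    if node.event == "SPECIATION":
        ET.SubElement(ev, "speciation", **loc)
    elif node.event == "DUPLICATION":
        ET.SubElement(ev, "duplication", **loc)
    elif node.event == "TRANSFER_DEPART":
        ET.SubElement(ev, "branchingOut", **loc)
    elif node.event == "LOSS":
        ET.SubElement(ev, "loss", **loc)
    elif node.event in ("PRESENT", "EXTINCTION"):
        # tips of the *complete* species tree: extinct lineages are tips too
        ET.SubElement(ev, "leaf", **loc)
    for c in node.children:
        child = gt.nodes[c]
        arriving = (
            node.event == "TRANSFER_DEPART"
            and child.species_lineage != node.species_lineage
        )
        _gene_clade(gt, c, clade, arriving)


def emit_reconciliation(gt: GeneTree, species_tree: CompleteSpeciesTree) -> str:
    """RecPhyloXML document pairing one gene tree with the species tree.

    Transfer departures are tagged ``branchingOut`` on the donor side, and
    the recipient-side child carries ``transferBack`` with the destination
    species, the convention reconciliation viewers expect.  The unary
    origination root is skipped: the document's gene-tree root is the first
    binary (or terminal) node.
    """
    rec = ET.Element("recPhylo", xmlns=_RECPHYLO_NS)
    sp = ET.SubElement(rec, "spTree")
    phylo_s = ET.SubElement(sp, "phylogeny", rooted="true")
    _species_clade(species_tree, species_tree.root_id, phylo_s)

    gtx = ET.SubElement(rec, "recGeneTree")
    phylo_g = ET.SubElement(gtx, "phylogeny", rooted="true")
    root = gt.nodes[gt.root_id]
    start = root
    while start.event == "ORIGINATION" and len(start.children) == 1:
        start = gt.nodes[start.children[0]]
    _gene_clade(gt, start.node_id, phylo_g, arriving_transfer=False)
    ET.indent(rec)
    return ET.tostring(rec, encoding="unicode", xml_declaration=True)


def reconciliation_event_counts(gt: GeneTree) -> dict[str, int]:
    """D / T / L counts as they appear in the reconciliation of one family."""
    counts = gt.event_counts()
    return {
        "D": counts.get("DUPLICATION", 0),
        "T": counts.get("TRANSFER_DEPART", 0),
        "L": counts.get("LOSS", 0),
    }
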