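"""Birth-death simulation of complete species trees.

The *complete* species tree keeps every lineage ever born, including those
that go extinct before the present.  Genomes later evolve along all of its
branches, so extinct lineages can act as donors of lateral gene transfers
whose descendants survive — the "ghost lineage" scenario this simulator
exists to produce.

Conventions: time is absolute, increasing from the root at t = 0; a lineage
occupies the half-open interval (t_start, t_end]; branch lengths written to
Newick are durations t_end - t_start.  Lineages are labelled "n1" (root),
"n2", ... in order of creation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import dendropy
import numpy as np

__all__ = [
    "Fate",
    "LineageNode",
    "CompleteSpeciesTree",
    "RateFunction",
    "LineageCountProfile",
    "TotalExtinctionError",
    "simulate_complete_tree",
    "simulate_with_profile",
    "prune_extinct",
    "load_user_tree",
    "alive_at",
]


class Fate(str, Enum):
    SPECIATED = "SPECIATED"
    EXTINCT = "EXTINCT"
    ALIVE_AT_END = "ALIVE_AT_END"


class TotalExtinctionError(ValueError):
    """Raised when an operation requires survivors but the whole tree died."""


@dataclass
class LineageNode:
    lineage_id: str
    parent_id: Optional[str]
    t_start: float
    t_end: Optional[float] = None
    fate: Optional[Fate] = None
    children: tuple[str, ...] = ()

    @property
    def duration(self) -> float:
        if self.t_end is None:
            raise ValueError(f"lineage {self.lineage_id} is still open")
        return self.t_end - self.t_start


@dataclass
class CompleteSpeciesTree:
    """Rooted binary tree with absolute node times, extinct lineages retained."""

    nodes: dict[str, LineageNode]
    root_id: str
    stop_time: float
    totally_extinct: bool = False

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        roots = [n for n in self.nodes.values() if n.parent_id is None]
        if len(roots) != 1 or roots[0].lineage_id != self.root_id:
            raise ValueError("tree must have exactly one root matching root_id")
        for n in self.nodes.values():
            if n.fate is Fate.SPECIATED and len(n.children) != 2:
                raise ValueError(f"{n.lineage_id}: SPECIATED requires 2 children")
            if n.fate in (Fate.EXTINCT, Fate.ALIVE_AT_END) and n.children:
                raise ValueError(f"{n.lineage_id}: terminal fate with children")
            for c in n.children:
                child = self.nodes[c]
                if child.parent_id != n.lineage_id:
                    raise ValueError(f"{c}: parent link mismatch")
                if abs(child.t_start - n.t_end) > 1e-12:
                    raise ValueError(f"{c}: t_start != parent t_end")

    # -- queries ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    def tips(self) -> list[LineageNode]:
        return [n for n in self.nodes.values() if not n.children]

    def alive_at_end(self) -> list[str]:
        return sorted(
            (n.lineage_id for n in self.nodes.values() if n.fate is Fate.ALIVE_AT_END),
            key=_label_key,
        )

    def extinct(self) -> list[str]:
        return sorted(
            (n.lineage_id for n in self.nodes.values() if n.fate is Fate.EXTINCT),
            key=_label_key,
        )

    def ancestors(self, lineage_id: str) -> list[str]:
        """Chain of ancestor ids from parent up to the root."""
        out = []
        cur = self.nodes[lineage_id].parent_id
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur].parent_id
        return out

    def mrca_divergence_time(self, a: str, b: str) -> float:
        """Time at which the lineages leading to a and b split (t_end of MRCA)."""
        if a == b:
            raise ValueError("identical lineages have no divergence time")
        anc_a = set([a] + self.ancestors(a))
        cur = b
        while cur not in anc_a:
            cur = self.nodes[cur].parent_id
            if cur is None:  # pragma: no cover - root is a common ancestor
                raise ValueError("disconnected lineages")
        mrca = self.nodes[cur]
        if mrca.lineage_id in (a, b):
            # one is ancestral to the other: divergence at the ancestor's end
            return mrca.t_end if mrca.t_end is not None else self.stop_time
        return mrca.t_end

    def root_to_tip_time(self, lineage_id: str) -> float:
        node = self.nodes[lineage_id]
        if node.children:
            raise ValueError(f"{lineage_id} is not a tip")
        return node.t_end - self.nodes[self.root_id].t_start

    def speciation_events(self) -> list[tuple[float, str, str, str]]:
        """(time, parent, child1, child2) sorted by time."""
        out = [
            (n.t_end, n.lineage_id, n.children[0], n.children[1])
            for n in self.nodes.values()
            if n.fate is Fate.SPECIATED
        ]
        out.sort(key=lambda e: (e[0], _label_key(e[1])))
        return out

    # -- Newick ----------------------------------------------------------

    def to_newick(self, precision: int = 10) -> str:
        fmt = f"%.{precision}g"

        def rec(nid: str) -> str:
            n = self.nodes[nid]
            bl = fmt % n.duration
            if n.children:
                inner = ",".join(rec(c) for c in n.children)
                return f"({inner}){n.lineage_id}:{bl}"
            return f"{n.lineage_id}:{bl}"

        return rec(self.root_id) + ";"


def _label_key(label: str):
    """Sort 'n10' after 'n2'; fall back to plain string order."""
    if label.startswith("n") and label[1:].isdigit():
        return (0, int(label[1:]), "")
    return (1, 0, label)


# ---------------------------------------------------------------------------
# Rate functions and profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateFunction:
    """Constant or piecewise-constant intensity over [0, stop_time].

    Piecewise values are ``((t0, t1, rate), ...)`` with contiguous ordered
    intervals.  Rates are per lineage per unit time.
    """

    kind: str  # CONSTANT | PIECEWISE
    values: tuple

    @staticmethod
    def constant(rate: float) -> "RateFunction":
        if rate < 0:
            raise ValueError("rate must be >= 0")
        return RateFunction("CONSTANT", (float(rate),))

    @staticmethod
    def piecewise(intervals: Sequence[tuple[float, float, float]]) -> "RateFunction":
        ivs = tuple((float(a), float(b), float(r)) for a, b, r in intervals)
        if not ivs:
            raise ValueError("piecewise rate needs at least one interval")
        for (a, b, r) in ivs:
            if b <= a or r < 0:
                raise ValueError(f"bad interval ({a}, {b}, {r})")
        for prev, nxt in zip(ivs, ivs[1:]):
            if abs(prev[1] - nxt[0]) > 1e-12:
                raise ValueError("piecewise intervals must be contiguous and ordered")
        return RateFunction("PIECEWISE", ivs)

    def at(self, t: float) -> float:
        if self.kind == "CONSTANT":
            return self.values[0]
        for a, b, r in self.values:
            if a <= t < b:
                return r
        # fall through: clamp to last interval (covers t == stop_time exactly)
        return self.values[-1][2]

    def next_boundary(self, t: float) -> float:
        """Smallest interval boundary strictly greater than t (inf if none)."""
        if self.kind == "CONSTANT":
            return float("inf")
        for a, b, _ in self.values:
            if b > t:
                return b
        return float("inf")


@dataclass(frozen=True)
class LineageCountProfile:
    """Required number of living lineages at each integer time unit."""

    targets: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if not self.targets:
            raise ValueError("profile must be non-empty")
        prev = 0
        for unit, count in self.targets:
            if unit <= prev:
                raise ValueError("time units must be strictly increasing positive")
            if count < 1:
                raise ValueError(
                    "lineage-count targets must be >= 1; use ordinary "
                    "simulation for extinction"
                )
            prev = unit


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


class _TreeBuilder:
    """Mutable state shared by the Gillespie variants."""

    def __init__(self) -> None:
        self.nodes: dict[str, LineageNode] = {}
        self.counter = 1
        root = LineageNode("n1", None, 0.0)
        self.nodes["n1"] = root
        self.alive: list[str] = ["n1"]

    def new_label(self) -> str:
        self.counter += 1
        return f"n{self.counter}"

    def speciate(self, lineage_id: str, t: float) -> tuple[str, str]:
        node = self.nodes[lineage_id]
        c1, c2 = self.new_label(), self.new_label()
        node.t_end = t
        node.fate = Fate.SPECIATED
        node.children = (c1, c2)
        self.nodes[c1] = LineageNode(c1, lineage_id, t)
        self.nodes[c2] = LineageNode(c2, lineage_id, t)
        self.alive.remove(lineage_id)
        self.alive.extend((c1, c2))
        return c1, c2

    def go_extinct(self, lineage_id: str, t: float) -> None:
        node = self.nodes[lineage_id]
        node.t_end = t
        node.fate = Fate.EXTINCT
        self.alive.remove(lineage_id)

    def finish(self, stop_time: float) -> CompleteSpeciesTree:
        for lid in self.alive:
            n = self.nodes[lid]
            n.t_end = stop_time
            n.fate = Fate.ALIVE_AT_END
        return CompleteSpeciesTree(
            nodes=self.nodes,
            root_id="n1",
            stop_time=stop_time,
            totally_extinct=not self.alive,
        )


def simulate_complete_tree(
    speciation: RateFunction | float,
    extinction: RateFunction | float,
    stop_time: float | None = None,
    seed: int | None = None,
    stop_total_lineages: int | None = None,
    rng: np.random.Generator | None = None,
) -> CompleteSpeciesTree:
    """Simulate a complete birth-death species tree with the Gillespie algorithm.

    With N alive lineages and rates lam, mu the waiting time to the next event
    is Exp(N*(lam+mu)); the event is a speciation with probability
    lam/(lam+mu) and strikes a uniformly chosen alive lineage.  Piecewise
    rates are handled by rejecting draws that overshoot an interval boundary
    and redrawing from the boundary, which is exact for piecewise-constant
    intensities.

    Stops at ``stop_time``, or (if ``stop_total_lineages`` is given) as soon
    as the total number of lineages ever created reaches that count.  Total
    extinction is flagged on the returned tree, not raised.
    """
    lam = speciation if isinstance(speciation, RateFunction) else RateFunction.constant(speciation)
    mu = extinction if isinstance(extinction, RateFunction) else RateFunction.constant(extinction)
    if stop_time is None and stop_total_lineages is None:
        raise ValueError("provide stop_time and/or stop_total_lineages")
    if stop_time is not None and stop_time <= 0:
        raise ValueError("stop_time must be > 0")
    if stop_total_lineages is not None and stop_total_lineages < 1:
        raise ValueError("stop_total_lineages must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    b = _TreeBuilder()
    t = 0.0
    horizon = float("inf") if stop_time is None else stop_time
    while b.alive:
        if stop_total_lineages is not None and b.counter >= stop_total_lineages:
            break
        l_rate, m_rate = lam.at(t), mu.at(t)
        total = len(b.alive) * (l_rate + m_rate)
        boundary = min(lam.next_boundary(t), mu.next_boundary(t), horizon)
        if total == 0.0:
            if boundary >= horizon:
                break
            t = boundary
            continue
        wait = rng.exponential(1.0 / total)
        if t + wait > boundary:
            t = boundary  # redraw with the post-boundary rates (or stop)
            if t >= horizon:
                break
            continue
        t += wait
        target = b.alive[rng.integers(len(b.alive))]
        if rng.random() < l_rate / (l_rate + m_rate):
            b.speciate(target, t)
        else:
            b.go_extinct(target, t)
    end = stop_time if stop_time is not None else t
    return b.finish(end)


def simulate_with_profile(
    profile: LineageCountProfile,
    extinction: RateFunction | float,
    seed: int | None = None,
    speciation: RateFunction | float = 0.0,
) -> CompleteSpeciesTree:
    """Simulate a tree constrained to hit exact alive-lineage counts.

    Within each time unit an ordinary birth-death simulation runs; at the
    unit boundary uniformly chosen lineages are forced to speciate (or go
    extinct) until the alive count equals the profile target exactly.
    """
    lam = speciation if isinstance(speciation, RateFunction) else RateFunction.constant(speciation)
    mu = extinction if isinstance(extinction, RateFunction) else RateFunction.constant(extinction)
    rng = np.random.default_rng(seed)
    targets = dict(profile.targets)
    last_unit = max(targets)

    b = _TreeBuilder()
    t = 0.0
    for unit in range(1, last_unit + 1):
        unit_end = float(unit)
        # free birth-death inside the unit
        while b.alive:
            l_rate, m_rate = lam.at(t), mu.at(t)
            total = len(b.alive) * (l_rate + m_rate)
            boundary = min(lam.next_boundary(t), mu.next_boundary(t), unit_end)
            if total == 0.0:
                t = boundary
                if t >= unit_end:
                    break
                continue
            wait = rng.exponential(1.0 / total)
            if t + wait > boundary:
                t = boundary
                if t >= unit_end:
                    break
                continue
            t += wait
            target = b.alive[rng.integers(len(b.alive))]
            if rng.random() < l_rate / (l_rate + m_rate):
                b.speciate(target, t)
            elif len(b.alive) > 1:
                b.go_extinct(target, t)
            # the last lineage never dies: profile targets are >= 1 and a
            # dead tree could not be steered back to any of them
        t = unit_end
        if unit in targets:
            want = targets[unit]
            while len(b.alive) < want:
                victim = b.alive[rng.integers(len(b.alive))]
                b.speciate(victim, unit_end)
            while len(b.alive) > want:
                victim = b.alive[rng.integers(len(b.alive))]
                b.go_extinct(victim, unit_end)
        if not b.alive:
            break
    return b.finish(float(last_unit))


def caterpillar_sampling_tree(stop_time: float, sample_times: Sequence[float]) -> CompleteSpeciesTree:
    """One backbone lineage with zero-length side tips at given times.

    Each side tip terminates at the moment it branches, so its genome is an
    exact snapshot of the backbone genome at that time — a cheap way to
    sample one lineage's evolving genome along a long run (e.g. for
    stationary family-size distributions).
    """
    times = sorted(set(float(t) for t in sample_times))
    if not times or times[0] <= 0 or times[-1] >= stop_time:
        raise ValueError("sample times must lie strictly inside (0, stop_time)")
    nodes: dict[str, LineageNode] = {}
    counter = 1
    cur = "n1"
    nodes[cur] = LineageNode(cur, None, 0.0)
    for t in times:
        tip, cont = f"n{counter + 1}", f"n{counter + 2}"
        counter += 2
        nodes[cur].t_end = t
        nodes[cur].fate = Fate.SPECIATED
        nodes[cur].children = (tip, cont)
        nodes[tip] = LineageNode(tip, cur, t, t, Fate.EXTINCT)
        nodes[cont] = LineageNode(cont, cur, t)
        cur = cont
    nodes[cur].t_end = stop_time
    nodes[cur].fate = Fate.ALIVE_AT_END
    return CompleteSpeciesTree(nodes, "n1", stop_time)


def alive_just_after(tree: CompleteSpeciesTree, t: float) -> set[str]:
    """Lineages alive immediately after time t (children born at t included)."""
    out = set()
    for n in tree.nodes.values():
        if n.t_start <= t and (
            n.t_end > t or (n.fate is Fate.ALIVE_AT_END and n.t_end == t)
        ):
            out.add(n.lineage_id)
    return out


def alive_at(tree: CompleteSpeciesTree, t: float) -> set[str]:
    """Set of lineages alive at absolute time t: {l : t_start < t <= t_end}."""
    if not (0.0 < t <= tree.stop_time):
        raise ValueError(f"t={t} outside (0, {tree.stop_time}]")
    return {
        n.lineage_id
        for n in tree.nodes.values()
        if n.t_start < t <= n.t_end
    }


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------


def prune_extinct(tree: CompleteSpeciesTree) -> CompleteSpeciesTree:
    """Reconstructed tree of survivors.

    Keeps exactly the lineages ancestral to at least one ALIVE_AT_END tip,
    suppressing degree-2 nodes by summing branch durations, so every
    root-to-surviving-tip path length is preserved exactly.
    """
    survivors = set(tree.alive_at_end())
    if not survivors:
        raise TotalExtinctionError("nothing survives to the end of the simulation")

    keep = set(survivors)
    for s in survivors:
        keep.update(tree.ancestors(s))

    def build(nid: str, t_start: float, out: dict[str, LineageNode], parent: Optional[str]) -> str:
        """Descend through kept nodes, splicing out unary chains."""
        node = tree.nodes[nid]
        kept_children = [c for c in node.children if c in keep]
        while len(kept_children) == 1:
            node = tree.nodes[kept_children[0]]
            kept_children = [c for c in node.children if c in keep]
        new = LineageNode(
            node.lineage_id, parent, t_start, node.t_end, node.fate, ()
        )
        out[new.lineage_id] = new
        if kept_children:
            ids = tuple(build(c, node.t_end, out, node.lineage_id) for c in kept_children)
            new.children = ids
            new.fate = Fate.SPECIATED
        return new.lineage_id

    out: dict[str, LineageNode] = {}
    root_id = build(tree.root_id, tree.nodes[tree.root_id].t_start, out, None)
    return CompleteSpeciesTree(out, root_id, tree.stop_time, totally_extinct=False)


# ---------------------------------------------------------------------------
# Newick input
# ---------------------------------------------------------------------------


def load_user_tree(newick_text: str, tol: float = 1e-9) -> CompleteSpeciesTree:
    """Build a CompleteSpeciesTree from a user Newick string.

    Node times are reconstructed from branch lengths with the root at t = 0.
    Tips at the maximal depth are ALIVE_AT_END; strictly shallower tips are
    EXTINCT (the tree is read as a chronogram of a partly extinct clade).
    Unlabelled nodes get fresh "n<k>" labels in preorder.
    """
    try:
        dt = dendropy.Tree.get(
            data=newick_text, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"unparseable Newick: {exc}") from exc

    seed = dt.seed_node
    used: set[str] = set()
    for nd in dt.preorder_node_iter():
        lbl = nd.taxon.label if nd.taxon is not None else nd.label
        if lbl:
            used.add(str(lbl))

    counter = [0]

    def fresh() -> str:
        while True:
            counter[0] += 1
            cand = f"n{counter[0]}"
            if cand not in used:
                return cand

    nodes: dict[str, LineageNode] = {}

    def visit(nd, t_start: float, parent: Optional[str]) -> str:
        kids = nd.child_nodes()
        if kids and len(kids) != 2:
            raise ValueError(
                f"non-binary node with {len(kids)} children "
                f"(near '{nd.label or nd.taxon or '?'}')"
            )
        lbl = nd.taxon.label if nd.taxon is not None else nd.label
        name = str(lbl) if lbl else fresh()
        if nd.parent_node is not None and nd.edge.length is None:
            raise ValueError(f"missing branch length above node '{name}'")
        t_end = t_start + (nd.edge.length or 0.0)
        node = LineageNode(name, parent, t_start, t_end)
        nodes[name] = node
        if kids:
            node.fate = Fate.SPECIATED
            node.children = tuple(visit(k, t_end, name) for k in kids)
        return name

    root_id = visit(seed, 0.0, None)
    depth = max(n.t_end for n in nodes.values() if not n.children)
    for n in nodes.values():
        if not n.children:
            n.fate = Fate.ALIVE_AT_END if n.t_end >= depth - tol else Fate.EXTINCT
            if n.fate is Fate.ALIVE_AT_END:
                n.t_end = depth  # snap away float dust so invariants hold exactly
    return CompleteSpeciesTree(nodes, root_id, stop_time=depth)
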