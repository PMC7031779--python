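"""Circular genomes of oriented gene copies, and the atomic events on them.

A genome is a circular ordered list of oriented gene copies; positions are
0-based and all segment arithmetic is modulo the genome size.  Six event
types act on genomes: originations (O), duplications (D), losses (L),
inversions (I), transpositions (P) and lateral transfers (T).  D/L/I/P/T
each have an *effective rate* (events per gene per unit time, folding
occurrence and fixation into one intensity) and an *extension* parameter,
the mean number of contiguous genes affected; origination is per lineage
and always single-gene.

In Gf mode the genome additionally carries one intergene length after each
gene; inversion and transposition breakpoints fall uniformly on intergenic
nucleotides and conserve the total intergenic length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "GeneCopy",
    "Genome",
    "RateConfig",
    "FamilyRates",
    "GenomeEvent",
    "init_root_genome",
    "total_rate",
    "sample_extension",
    "apply_duplication",
    "apply_loss",
    "apply_inversion",
    "apply_transposition",
    "apply_origination",
    "apply_transfer",
    "choose_recipient",
]

GENE_EVENT_TYPES = ("D", "L", "I", "P", "T")


@dataclass(frozen=True)
class GeneCopy:
    family_id: int
    copy_id: int
    orientation: int  # +1 or -1
    length_nt: int = 1

    def flipped(self) -> "GeneCopy":
        return replace(self, orientation=-self.orientation)

    def __str__(self) -> str:
        sign = "+" if self.orientation > 0 else "-"
        return f"{sign}{self.family_id}.{self.copy_id}"


@dataclass
class Genome:
    """Circular ordered gene content of one species lineage.

    ``intergenes`` (Gf mode only) holds ``intergenes[i]`` = length of the
    intergenic region immediately after ``genes[i]``; its length always
    equals the gene count.
    """

    lineage_id: str
    genes: list[GeneCopy] = field(default_factory=list)
    intergenes: Optional[list[float]] = None

    def __len__(self) -> int:
        return len(self.genes)

    def __post_init__(self) -> None:
        if self.intergenes is not None and len(self.intergenes) != len(self.genes):
            raise ValueError("intergene count must equal gene count")

    def family_sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for g in self.genes:
            out[g.family_id] = out.get(g.family_id, 0) + 1
        return out

    def segment_indices(self, start: int, k: int) -> list[int]:
        n = len(self.genes)
        if not (1 <= k <= n):
            raise ValueError(f"extension {k} outside [1, {n}]")
        return [(start + i) % n for i in range(k)]

    def copy_content(self, lineage_id: Optional[str] = None) -> "Genome":
        return Genome(
            lineage_id or self.lineage_id,
            list(self.genes),
            None if self.intergenes is None else list(self.intergenes),
        )


@dataclass(frozen=True)
class FamilyRates:
    """Gm-mode per-family overrides for duplication, loss and transfer."""

    duplication: Optional[float] = None
    loss: Optional[float] = None
    transfer: Optional[float] = None


@dataclass
class RateConfig:
    """Effective rates and extension means for all six event types.

    Rates for D/L/I/P/T are per gene per unit time; origination is per
    lineage per unit time.  ``transfer_bias`` (alpha >= 0) biases transfer
    recipients toward close relatives; 0 means uniform.  ``lineage_overrides``
    (Gu) swaps the whole config on given lineages; ``family_overrides`` (Gm)
    overrides D/L/T rates per gene family.
    """

    duplication: float = 0.0
    loss: float = 0.0
    inversion: float = 0.0
    transposition: float = 0.0
    transfer: float = 0.0
    origination: float = 0.0
    duplication_extension: float = 1.0
    loss_extension: float = 1.0
    inversion_extension: float = 1.0
    transposition_extension: float = 1.0
    transfer_extension: float = 1.0
    transfer_bias: float = 0.0
    lineage_overrides: dict[str, "RateConfig"] = field(default_factory=dict)
    family_overrides: dict[int, FamilyRates] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "duplication", "loss", "inversion", "transposition",
            "transfer", "origination", "transfer_bias",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} rate must be finite and >= 0, got {v}")
        for name in GENE_EVENT_TYPES:
            v = self.extension_mean(name)
            if not np.isfinite(v) or v < 1:
                raise ValueError(f"extension mean for {name} must be >= 1, got {v}")

    _RATE_ATTR = {
        "D": "duplication",
        "L": "loss",
        "I": "inversion",
        "P": "transposition",
        "T": "transfer",
    }

    def rate(self, event_type: str) -> float:
        return getattr(self, self._RATE_ATTR[event_type])

    def extension_mean(self, event_type: str) -> float:
        return getattr(self, self._RATE_ATTR[event_type] + "_extension")

    def for_lineage(self, lineage_id: str) -> "RateConfig":
        return self.lineage_overrides.get(lineage_id, self)

    def gene_rate(self, event_type: str, family_id: int) -> float:
        """Per-gene rate for one event type, resolving Gm family overrides."""
        fam = self.family_overrides.get(family_id)
        if fam is not None:
            override = {
                "D": fam.duplication, "L": fam.loss, "T": fam.transfer,
            }.get(event_type)
            if override is not None:
                return override
        return self.rate(event_type)

    @property
    def per_gene_total(self) -> float:
        return sum(self.rate(e) for e in GENE_EVENT_TYPES)


@dataclass
class GenomeEvent:
    """One atomic record in the global event log.

    ``copy_map`` maps source copy keys ``(family_id, copy_id)`` to the copy
    ids they create (one new id for D/T/O; a pair for speciation records).
    Species-level records (SP, EX, END) are logged alongside genome-level
    ones so gene trees can be replayed from the log alone.
    """

    time: float
    type: str  # O D L I P T SP EX END
    lineage_id: str
    recipient_id: Optional[str] = None
    start: Optional[int] = None
    extension: Optional[int] = None
    family_ids: tuple[int, ...] = ()
    copy_map: dict[tuple[int, int], tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.type == "T":
            if self.recipient_id is None or self.recipient_id == self.lineage_id:
                raise ValueError("transfer needs a recipient distinct from the donor")
        if self.extension is not None and self.extension < 1:
            raise ValueError("extension must be >= 1")


# ---------------------------------------------------------------------------
# Construction and sampling
# ---------------------------------------------------------------------------


def init_root_genome(
    n_genes: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    lineage_id: str = "n1",
    with_intergenes: bool = False,
    total_intergene_length: float = 1.0,
) -> Genome:
    """Initial genome: ``n_genes`` single-copy families, random orientations.

    In Gf mode initial intergene lengths are a flat Dirichlet draw scaled to
    ``total_intergene_length``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    genes = [
        GeneCopy(fam, 1, 1 if rng.random() < 0.5 else -1)
        for fam in range(1, n_genes + 1)
    ]
    intergenes = None
    if with_intergenes:
        intergenes = list(rng.dirichlet(np.ones(n_genes)) * total_intergene_length)
    return Genome(lineage_id, genes, intergenes)


def total_rate(genome: Genome, rates: RateConfig) -> float:
    """Total event propensity of one genome: sum of per-gene rates + origination."""
    if rates.family_overrides:
        per_gene = sum(
            rates.gene_rate(e, g.family_id)
            for g in genome.genes
            for e in GENE_EVENT_TYPES
        )
    else:
        per_gene = len(genome) * rates.per_gene_total
    return per_gene + rates.origination


def sample_extension(mean: float, rng: np.random.Generator) -> int:
    """Number of contiguous genes hit by one event: Geometric on {1,2,...}.

    Success probability 1/mean so the expectation equals the configured
    extension parameter; the caller truncates to the current genome size.
    """
    if mean < 1:
        raise ValueError("extension mean must be >= 1")
    if mean == 1.0:
        return 1
    return int(rng.geometric(1.0 / mean))


# ---------------------------------------------------------------------------
# Atomic events (mutate in place, return the genome for chaining)
# ---------------------------------------------------------------------------


def apply_duplication(
    genome: Genome, start: int, k: int, new_copy_ids: Iterable[int]
) -> Genome:
    """Tandem duplication: the k-gene segment is copied immediately after itself."""
    idx = genome.segment_indices(start, k)
    new_ids = list(new_copy_ids)
    if len(new_ids) != k:
        raise ValueError("need one new copy id per duplicated gene")
    copies = [
        replace(genome.genes[i], copy_id=cid) for i, cid in zip(idx, new_ids)
    ]
    insert_at = idx[-1] + 1  # tandem: directly after the template segment
    genome.genes[insert_at:insert_at] = copies
    if genome.intergenes is not None:
        genome.intergenes[insert_at:insert_at] = [genome.intergenes[i] for i in idx]
    return genome


def apply_loss(genome: Genome, start: int, k: int) -> Genome:
    """Remove a k-gene segment (may wrap); an empty genome is permitted."""
    idx = genome.segment_indices(start, k)
    drop = set(idx)
    if genome.intergenes is not None:
        # deleted genes take their trailing intergenes with them
        genome.intergenes = [
            v for i, v in enumerate(genome.intergenes) if i not in drop
        ]
    genome.genes = [g for i, g in enumerate(genome.genes) if i not in drop]
    return genome


def apply_inversion(genome: Genome, start: int, k: int) -> Genome:
    """Reverse a k-gene segment and flip every orientation inside it."""
    idx = genome.segment_indices(start, k)
    flipped = [genome.genes[i].flipped() for i in reversed(idx)]
    for i, g in zip(idx, flipped):
        genome.genes[i] = g
    if genome.intergenes is not None and k > 1:
        # intergenes internal to the segment travel with it, reversed;
        # the segment-final intergene stays put as the new boundary
        inner = [genome.intergenes[i] for i in idx[:-1]]
        for i, v in zip(idx[:-1], reversed(inner)):
            genome.intergenes[i] = v
    return genome


def apply_transposition(genome: Genome, start: int, k: int, insert_after: int) -> Genome:
    """Excise a k-gene segment and reinsert it after position ``insert_after``.

    ``insert_after`` indexes the original genome and must lie outside the
    moved segment; order and orientations are preserved.
    """
    n = len(genome.genes)
    if not (1 <= k <= n - 1):
        raise ValueError(f"transposition extension {k} outside [1, {n - 1}]")
    idx = genome.segment_indices(start, k)
    if insert_after in idx:
        raise ValueError("insertion point lies inside the moved segment")
    moved = [genome.genes[i] for i in idx]
    moved_ig = [genome.intergenes[i] for i in idx] if genome.intergenes is not None else None
    drop = set(idx)
    anchor_gene = genome.genes[insert_after]
    genome.genes = [g for i, g in enumerate(genome.genes) if i not in drop]
    if genome.intergenes is not None:
        genome.intergenes = [v for i, v in enumerate(genome.intergenes) if i not in drop]
    at = genome.genes.index(anchor_gene) + 1
    genome.genes[at:at] = moved
    if genome.intergenes is not None:
        genome.intergenes[at:at] = moved_ig
    return genome


def apply_origination(
    genome: Genome,
    position: int,
    new_family_id: int,
    orientation: int,
    existing_families: set[int] | None = None,
) -> Genome:
    """Insert one brand-new single-copy family at ``position``."""
    if existing_families is not None and new_family_id in existing_families:
        raise ValueError(f"family id {new_family_id} already in use")
    gene = GeneCopy(new_family_id, 1, orientation)
    pos = position if genome.genes else 0
    genome.genes.insert(pos, gene)
    if genome.intergenes is not None:
        if len(genome.intergenes) == 0:
            genome.intergenes = [0.0]
        else:
            # split the intergene preceding the insertion point in half
            prev = (pos - 1) % len(genome.intergenes)
            half = genome.intergenes[prev] / 2.0
            genome.intergenes[prev] = half
            genome.intergenes.insert(pos, half)
    return genome


def apply_transfer(
    donor_genome: Genome,
    start: int,
    k: int,
    recipient_genome: Genome,
    insert_pos: int,
    new_copy_ids: Iterable[int],
) -> tuple[Genome, Genome]:
    """Additive transfer: copy a donor segment into the recipient.

    The donor keeps its copy; the recipient gains fresh copies (orientations
    preserved) inserted before ``insert_pos``.
    """
    idx = donor_genome.segment_indices(start, k)
    new_ids = list(new_copy_ids)
    if len(new_ids) != k:
        raise ValueError("need one new copy id per transferred gene")
    copies = [
        replace(donor_genome.genes[i], copy_id=cid) for i, cid in zip(idx, new_ids)
    ]
    pos = insert_pos if recipient_genome.genes else 0
    recipient_genome.genes[pos:pos] = copies
    if recipient_genome.intergenes is not None:
        if donor_genome.intergenes is not None:
            incoming = [donor_genome.intergenes[i] for i in idx]
        else:
            incoming = [0.0] * k
        recipient_genome.intergenes[pos:pos] = incoming
    return donor_genome, recipient_genome


def total_intergene_length(genome: Genome) -> float:
    if genome.intergenes is None:
        raise ValueError("genome carries no intergenes (not in Gf mode)")
    return float(sum(genome.intergenes))


def locate_intergenic(genome: Genome, u: float) -> tuple[int, float]:
    """Map a global intergenic coordinate u in [0, total) to (index, offset)."""
    acc = 0.0
    for i, v in enumerate(genome.intergenes):
        if u < acc + v:
            return i, u - acc
        acc += v
    return len(genome.intergenes) - 1, genome.intergenes[-1]


def apply_inversion_intergenic(
    genome: Genome, i: int, a: float, j: int, b: float
) -> tuple[int, int]:
    """Gf inversion defined by two intergenic breakpoints.

    Cut 1 falls in the intergene after gene ``i`` at offset ``a``; cut 2 in
    the intergene after gene ``j`` at offset ``b``.  The circular segment of
    genes i+1..j (forward) is reversed and flipped, and the cut intergene
    pieces are rejoined so total intergenic length is conserved exactly.
    Returns (start, k) of the affected gene segment for logging.
    """
    n = len(genome.genes)
    ig = genome.intergenes
    if i == j:
        return ((i + 1) % n, 0)  # both cuts in one intergene: no gene moves
    k = (j - i) % n
    seg = [(i + 1 + t) % n for t in range(k)]
    flipped = [genome.genes[p].flipped() for p in reversed(seg)]
    for p, g in zip(seg, flipped):
        genome.genes[p] = g
    gi, gj = ig[i], ig[j]
    new_inner = [ig[(j - t) % n] for t in range(1, k)]
    ig[i] = a + b
    for t, v in zip(range(1, k), new_inner):
        ig[(i + t) % n] = v
    ig[j] = (gi - a) + (gj - b)
    return (seg[0], k)


def apply_transposition_intergenic(
    genome: Genome, i: int, a: float, j: int, b: float, u3: float
) -> tuple[int, int]:
    """Gf transposition: excise the segment between two intergenic cuts and
    reinsert it at a third cut, ``u3`` being a global coordinate uniform on
    the intergenic length that remains after excision (so the insertion
    point is uniform over remaining intergenic nucleotides, the same
    length-weighted rule the inversion cuts follow).  Total intergenic
    length is conserved exactly.
    Returns (start, k) of the moved gene segment (pre-event coordinates).
    """
    n = len(genome.genes)
    ig = genome.intergenes
    if i == j:
        raise ValueError("transposition cuts must fall in distinct intergenes")
    k = (j - i) % n
    seg = [(i + 1 + t) % n for t in range(k)]
    moved_genes = [genome.genes[p] for p in seg]
    inner_ig = [ig[p] for p in seg[:-1]]  # after each moved gene but the last
    lead = ig[i] - a  # piece preceding the first moved gene
    trail = b         # piece following the last moved gene

    keep = [p for p in range(n) if p not in set(seg)]
    genes_kept = [genome.genes[p] for p in keep]
    ig_kept = [ig[p] for p in keep]
    pos_i = keep.index(i)
    ig_kept[pos_i] = a + (ig[j] - b)  # donor flanks fuse at the excision site

    remaining = sum(ig_kept)
    if not (0.0 <= u3 < remaining + 1e-9):
        raise ValueError("insertion coordinate outside remaining intergenic length")
    acc = 0.0
    pos_h, c = len(ig_kept) - 1, ig_kept[-1]
    for p, v in enumerate(ig_kept):
        if u3 < acc + v:
            pos_h, c = p, u3 - acc
            break
        acc += v
    w = ig_kept[pos_h]
    new_genes = genes_kept[: pos_h + 1] + moved_genes + genes_kept[pos_h + 1 :]
    new_ig = (
        ig_kept[:pos_h]
        + [c + lead]                # insertion-site gene .. first moved gene
        + inner_ig
        + [trail + (w - c)]         # last moved gene .. next kept gene
        + ig_kept[pos_h + 1 :]
    )
    genome.genes = new_genes
    genome.intergenes = new_ig
    return (seg[0], k)


def choose_recipient(
    alive: Iterable[str],
    donor: str,
    tree,
    alpha: float,
    time: float,
    rng: np.random.Generator,
) -> Optional[str]:
    """Pick a lateral-transfer recipient among lineages alive at the event time.

    alpha = 0 gives a uniform choice over ``alive`` minus the donor; alpha > 0
    weights each candidate by exp(-alpha * d) where d is the patristic
    distance to the donor at the event time (2 * time since divergence), so
    large alpha concentrates transfers on close relatives.  Returns None when
    the donor is the only lineage alive (the caller discards the event).
    """
    candidates = sorted(set(alive) - {donor})
    if not candidates:
        return None
    if alpha == 0.0:
        return candidates[rng.integers(len(candidates))]
    dists = np.array(
        [2.0 * (time - tree.mrca_divergence_time(donor, c)) for c in candidates]
    )
    w = np.exp(-alpha * (dists - dists.min()))
    w /= w.sum()
    return candidates[rng.choice(len(candidates), p=w)]
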