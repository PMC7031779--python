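"""Genome evolution along the complete species tree (G / Gu / Gm / Gf modes).

One global Gillespie clock runs over the union of lineages alive at each
moment, interleaved with the (already simulated) speciation and extinction
times of the species tree.  Running in global time order is what makes
lateral transfers correct: the recipient is sampled among the lineages alive
at the moment the transfer fires — including lineages that will later go
extinct, the ghost-donor/ghost-recipient scenarios this simulator exists to
produce.

Species-level bookkeeping (SP, EX, END records with copy mappings) is
written into the same event log as genome-level events so that gene trees
can be replayed from the log alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as _replace
from typing import Optional

import numpy as np

from .genome import (
    GENE_EVENT_TYPES,
    Genome,
    GenomeEvent,
    RateConfig,
    apply_duplication,
    apply_inversion,
    apply_inversion_intergenic,
    apply_loss,
    apply_origination,
    apply_transfer,
    apply_transposition,
    apply_transposition_intergenic,
    choose_recipient,
    locate_intergenic,
    sample_extension,
    total_intergene_length,
    total_rate,
)
from .species_tree import CompleteSpeciesTree, Fate

logger = logging.getLogger(__name__)

__all__ = ["EvolutionResult", "evolve_genomes"]

MODES = ("G", "Gu", "Gm", "Gf")


@dataclass
class EvolutionResult:
    """Everything the G step produces.

    ``genomes`` maps every lineage id to its genome at the *end* of that
    lineage (extinction time, speciation time, or the present).
    """

    event_log: list[GenomeEvent]
    genomes: dict[str, Genome]
    mode: str
    seed: Optional[int] = None

    def events_of_type(self, *types: str) -> list[GenomeEvent]:
        return [e for e in self.event_log if e.type in types]

    def events_for_family(self, family_id: int) -> list[GenomeEvent]:
        return [e for e in self.event_log if family_id in e.family_ids]

    def family_ids(self) -> list[int]:
        fams: set[int] = set()
        for e in self.event_log:
            fams.update(e.family_ids)
        for g in self.genomes.values():
            fams.update(gene.family_id for gene in g.genes)
        return sorted(fams)


class _CopyIdAllocator:
    """Fresh copy ids per family; every copy id is unique within its family."""

    def __init__(self) -> None:
        self._next: dict[int, int] = {}

    def seed_family(self, family_id: int, highest_used: int) -> None:
        cur = self._next.get(family_id, 1)
        self._next[family_id] = max(cur, highest_used + 1)

    def fresh(self, family_id: int) -> int:
        nxt = self._next.get(family_id, 1)
        self._next[family_id] = nxt + 1
        return nxt


def _validate_overrides(tree: CompleteSpeciesTree, rates: RateConfig, root_families: set[int]) -> None:
    for lid in rates.lineage_overrides:
        if lid not in tree.nodes:
            raise ValueError(f"lineage override references unknown lineage '{lid}'")
    # Family overrides may reference originated-later families only if the
    # user pre-declares them; ids below the root range must exist.
    for fam in rates.family_overrides:
        if fam < 1:
            raise ValueError(f"family override references invalid family id {fam}")


def evolve_genomes(
    tree: CompleteSpeciesTree,
    root_genome: Genome,
    rates: RateConfig,
    mode: str = "G",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> EvolutionResult:
    """Evolve genomes along every branch of the complete species tree.

    At each speciation the parent genome is copied verbatim into both
    children (with fresh copy ids, recorded in an SP log entry); at an
    extinction the genome stops evolving (EX entry); lineages alive at the
    end get END entries.  Gu and Gm modes resolve per-lineage and per-family
    rate overrides; Gf maintains intergene lengths with breakpoints drawn
    uniformly on intergenic nucleotides.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if rng is None:
        rng = np.random.default_rng(seed)
    root_fams = {g.family_id for g in root_genome.genes}
    _validate_overrides(tree, rates, root_fams)
    if mode == "Gf" and root_genome.intergenes is None:
        raise ValueError("Gf mode needs a root genome with intergenes")
    if mode != "Gf" and root_genome.intergenes is not None:
        raise ValueError("intergenes supplied but mode is not Gf")

    alloc = _CopyIdAllocator()
    for g in root_genome.genes:
        alloc.seed_family(g.family_id, g.copy_id)
    next_family = [max(root_fams, default=0) + 1]

    log: list[GenomeEvent] = []
    final_genomes: dict[str, Genome] = {}

    root = tree.nodes[tree.root_id]
    live: dict[str, Genome] = {tree.root_id: root_genome.copy_content(tree.root_id)}

    # schedule of species-level events, in time order
    sched: list[tuple[float, int, str, str]] = []  # (time, priority, kind, lineage)
    # at equal times a speciation must precede the extinction/end of the
    # lineages it creates (zero-length branches are legal snapshot tips)
    for n in tree.nodes.values():
        if n.fate is Fate.SPECIATED:
            sched.append((n.t_end, 0, "SP", n.lineage_id))
        elif n.fate is Fate.EXTINCT:
            sched.append((n.t_end, 1, "EX", n.lineage_id))
        elif n.fate is Fate.ALIVE_AT_END:
            sched.append((n.t_end, 2, "END", n.lineage_id))
    sched.sort(key=lambda e: (e[0], e[1], e[3]))

    def lineage_rates(lid: str) -> RateConfig:
        return rates.for_lineage(lid)

    def lineage_propensity(lid: str) -> float:
        return total_rate(live[lid], lineage_rates(lid))

    t = root.t_start
    for ev_time, _prio, kind, lid in sched:
        # --- genome-level Gillespie between t and ev_time -----------------
        while True:
            props = {l: lineage_propensity(l) for l in live}
            total = sum(props.values())
            if total <= 0.0:
                break
            wait = rng.exponential(1.0 / total)
            if t + wait >= ev_time:
                break
            t += wait
            _fire_genome_event(
                t, live, props, total, rates, mode, tree, rng, alloc, next_family, log
            )
        t = ev_time
        # --- species-level event ------------------------------------------
        if kind == "SP":
            node = tree.nodes[lid]
            genome = live.pop(lid)
            final_genomes[lid] = genome
            c1, c2 = node.children
            copy_map: dict[tuple[int, int], tuple[int, ...]] = {}
            child_genomes = [Genome(c1, []), Genome(c2, [])]
            for gene in genome.genes:
                id1 = alloc.fresh(gene.family_id)
                id2 = alloc.fresh(gene.family_id)
                copy_map[(gene.family_id, gene.copy_id)] = (id1, id2)
                child_genomes[0].genes.append(_replace(gene, copy_id=id1))
                child_genomes[1].genes.append(_replace(gene, copy_id=id2))
            if genome.intergenes is not None:
                child_genomes[0].intergenes = list(genome.intergenes)
                child_genomes[1].intergenes = list(genome.intergenes)
            live[c1], live[c2] = child_genomes
            log.append(
                GenomeEvent(
                    time=t, type="SP", lineage_id=lid, recipient_id=None,
                    family_ids=tuple(sorted({g.family_id for g in genome.genes})),
                    copy_map=copy_map,
                )
            )
        elif kind == "EX":
            genome = live.pop(lid)
            final_genomes[lid] = genome
            log.append(
                GenomeEvent(
                    time=t, type="EX", lineage_id=lid,
                    family_ids=tuple(sorted({g.family_id for g in genome.genes})),
                    copy_map={(g.family_id, g.copy_id): () for g in genome.genes},
                )
            )
        else:  # END
            genome = live.pop(lid)
            final_genomes[lid] = genome
            log.append(
                GenomeEvent(
                    time=t, type="END", lineage_id=lid,
                    family_ids=tuple(sorted({g.family_id for g in genome.genes})),
                    copy_map={(g.family_id, g.copy_id): () for g in genome.genes},
                )
            )

    return EvolutionResult(event_log=log, genomes=final_genomes, mode=mode, seed=seed)


def _pick_gene_event(
    genome: Genome, cfg: RateConfig, u: float
) -> tuple[str, Optional[int]]:
    """Resolve which event type (and, with Gm overrides, which gene) fires.

    ``u`` is uniform on [0, lineage propensity).  Returns (type, start) where
    start is None unless family overrides forced a per-gene walk.
    """
    n = len(genome)
    if not cfg.family_overrides:
        acc = 0.0
        for e in GENE_EVENT_TYPES:
            acc += n * cfg.rate(e)
            if u < acc:
                return e, None
        return "O", None
    acc = 0.0
    for i, gene in enumerate(genome.genes):
        for e in GENE_EVENT_TYPES:
            acc += cfg.gene_rate(e, gene.family_id)
            if u < acc:
                return e, i
    return "O", None


def _fire_genome_event(
    t: float,
    live: dict[str, Genome],
    props: dict[str, float],
    total: float,
    rates: RateConfig,
    mode: str,
    tree: CompleteSpeciesTree,
    rng: np.random.Generator,
    alloc: _CopyIdAllocator,
    next_family: list[int],
    log: list[GenomeEvent],
) -> None:
    # choose the lineage proportionally to its propensity
    u = rng.random() * total
    acc = 0.0
    lid = next(iter(live))
    for cand in live:
        acc += props[cand]
        if u < acc:
            lid = cand
            break
    genome = live[lid]
    cfg = rates.for_lineage(lid)
    ev_type, forced_start = _pick_gene_event(genome, cfg, rng.random() * props[lid])
    n = len(genome)

    if ev_type == "O":
        fam = next_family[0]
        next_family[0] += 1
        pos = int(rng.integers(n + 1)) if n else 0
        orientation = 1 if rng.random() < 0.5 else -1
        apply_origination(genome, pos, fam, orientation)
        alloc.seed_family(fam, 1)
        log.append(
            GenomeEvent(
                time=t, type="O", lineage_id=lid, start=pos, extension=1,
                family_ids=(fam,), copy_map={(fam, 0): (1,)},
            )
        )
        return

    # Gf rearrangements are driven by intergenic breakpoints
    if mode == "Gf" and ev_type in ("I", "P") and n >= 2:
        _fire_intergenic_rearrangement(t, lid, genome, ev_type, rng, log)
        return

    k = min(sample_extension(cfg.extension_mean(ev_type), rng), n)
    start = forced_start if forced_start is not None else int(rng.integers(n))
    seg = genome.segment_indices(start, k)
    seg_genes = [genome.genes[i] for i in seg]
    fams = tuple(g.family_id for g in seg_genes)

    if ev_type == "D":
        new_ids = [alloc.fresh(g.family_id) for g in seg_genes]
        apply_duplication(genome, start, k, new_ids)
        log.append(
            GenomeEvent(
                time=t, type="D", lineage_id=lid, start=start, extension=k,
                family_ids=fams,
                copy_map={
                    (g.family_id, g.copy_id): (nid,)
                    for g, nid in zip(seg_genes, new_ids)
                },
            )
        )
    elif ev_type == "L":
        apply_loss(genome, start, k)
        log.append(
            GenomeEvent(
                time=t, type="L", lineage_id=lid, start=start, extension=k,
                family_ids=fams,
                copy_map={(g.family_id, g.copy_id): () for g in seg_genes},
            )
        )
    elif ev_type == "I":
        apply_inversion(genome, start, k)
        log.append(
            GenomeEvent(
                time=t, type="I", lineage_id=lid, start=start, extension=k,
                family_ids=fams,
            )
        )
    elif ev_type == "P":
        if n < 2:
            return  # a one-gene circular genome cannot transpose
        k = min(k, n - 1)
        seg = genome.segment_indices(start, k)
        seg_genes = [genome.genes[i] for i in seg]
        fams = tuple(g.family_id for g in seg_genes)
        outside = [i for i in range(n) if i not in set(seg)]
        insert_after = outside[rng.integers(len(outside))]
        apply_transposition(genome, start, k, insert_after)
        log.append(
            GenomeEvent(
                time=t, type="P", lineage_id=lid, start=start, extension=k,
                family_ids=fams,
            )
        )
    elif ev_type == "T":
        recipient = choose_recipient(
            live.keys(), lid, tree, cfg.transfer_bias, t, rng
        )
        if recipient is None:
            logger.info("transfer at t=%.6g aborted: %s is the only lineage alive", t, lid)
            return
        rec_genome = live[recipient]
        new_ids = [alloc.fresh(g.family_id) for g in seg_genes]
        insert_pos = int(rng.integers(len(rec_genome) + 1)) if len(rec_genome) else 0
        apply_transfer(genome, start, k, rec_genome, insert_pos, new_ids)
        log.append(
            GenomeEvent(
                time=t, type="T", lineage_id=lid, recipient_id=recipient,
                start=start, extension=k, family_ids=fams,
                copy_map={
                    (g.family_id, g.copy_id): (nid,)
                    for g, nid in zip(seg_genes, new_ids)
                },
            )
        )


def _fire_intergenic_rearrangement(
    t: float,
    lid: str,
    genome: Genome,
    ev_type: str,
    rng: np.random.Generator,
    log: list[GenomeEvent],
) -> None:
    """Gf-mode inversion/transposition with uniform intergenic breakpoints."""
    total_ig = total_intergene_length(genome)
    if total_ig <= 0.0:
        return
    i, a = locate_intergenic(genome, rng.random() * total_ig)
    j, b = locate_intergenic(genome, rng.random() * total_ig)
    if i == j:
        return  # both cuts in one intergene: nothing moves
    if ev_type == "I":
        seg_genes = [
            genome.genes[(i + 1 + s) % len(genome.genes)]
            for s in range((j - i) % len(genome.genes))
        ]
        start, k = apply_inversion_intergenic(genome, i, a, j, b)
        if k:
            log.append(
                GenomeEvent(
                    time=t, type="I", lineage_id=lid, start=start, extension=k,
                    family_ids=tuple(g.family_id for g in seg_genes),
                )
            )
    else:
        n = len(genome.genes)
        k = (j - i) % n
        if k >= n:
            return
        seg = [(i + 1 + s) % n for s in range(k)]
        seg_genes = [genome.genes[p] for p in seg]
        # remaining intergenic length after excision
        excised = (genome.intergenes[i] - a) + b + sum(
            genome.intergenes[p] for p in seg[:-1]
        )
        remaining = total_ig - excised
        if remaining <= 0.0:
            return
        u3 = rng.random() * remaining
        start, k = apply_transposition_intergenic(genome, i, a, j, b, u3)
        log.append(
            GenomeEvent(
                time=t, type="P", lineage_id=lid, start=start, extension=k,
                family_ids=tuple(g.family_id for g in seg_genes),
            )
        )
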