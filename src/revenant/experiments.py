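"""Canned validation experiments over the simulator.

Each function sets up the study conditions for one of the statistical
properties a correct implementation must reproduce, runs the simulator, and
returns the measured quantities.  They are used both by the test suite and
by the reproduction script, so the conditions (sample sizes, rates,
durations) are defined in exactly one place; docs/methods.md discusses why
each condition looks the way it does.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np

from .diagnostics import (
    ValidationReport,
    check_event_frequencies,
    check_family_size_tail,
    check_intergene_dirichlet,
    check_waiting_times,
)
from .gene_tree import GeneTree, GeneTreeNode, build_gene_tree, prune_gene_tree
from .genome import GenomeEvent, RateConfig, init_root_genome
from .genome_sim import evolve_genomes
from .sequence_sim import SubstitutionModel, simulate_alignment
from .species_tree import (
    caterpillar_sampling_tree,
    load_user_tree,
    simulate_complete_tree,
)

__all__ = [
    "waiting_time_experiment",
    "birth_death_moment_experiment",
    "intergene_equilibrium_experiment",
    "event_frequency_experiment",
    "family_size_regime_experiments",
    "jc_divergence_experiment",
    "ghost_donor_experiment",
]


def waiting_time_experiment(
    seed: int, n_genes: int = 100, rate: float = 0.05, target_events: int = 10_000
) -> ValidationReport:
    """Inter-event waits on a single lineage at fixed genome size.

    Only inversions and transpositions fire (both size-preserving), so the
    total propensity R = n (r_I + r_P) is constant and waits must be Exp(R).
    """
    R = n_genes * 2 * rate
    stop = (target_events * 1.15) / R  # margin so we collect enough waits
    tree = simulate_complete_tree(0.0, 0.0, stop_time=stop, seed=seed)
    rng = np.random.default_rng(seed)
    genome = init_root_genome(n_genes, rng=rng)
    res = evolve_genomes(
        tree, genome, RateConfig(inversion=rate, transposition=rate), "G", rng=rng
    )
    times = np.array([e.time for e in res.event_log if e.type in ("I", "P")])
    waits = np.diff(np.concatenate([[0.0], times]))[:target_events]
    return check_waiting_times(waits, R)


def birth_death_moment_experiment(
    seed: int, n_reps: int = 10_000, lam: float = 1.0, mu: float = 0.5, t: float = 2.0
) -> dict:
    """Mean number of surviving lineages vs the closed form e^{(lam-mu)t}."""
    rng = np.random.default_rng(seed)
    counts = np.array([
        len(
            simulate_complete_tree(
                lam, mu, stop_time=t, seed=int(rng.integers(2**31))
            ).alive_at_end()
        )
        for _ in range(n_reps)
    ])
    mean = float(counts.mean())
    se = float(counts.std(ddof=1) / math.sqrt(n_reps))
    expected = math.exp((lam - mu) * t)
    return {
        "mean": mean, "se": se, "expected": expected,
        "z": (mean - expected) / se, "n": n_reps,
    }


def intergene_equilibrium_experiment(
    seed: int, m: int = 20, reps: int = 300, branch: float = 60.0, rate: float = 0.05
) -> ValidationReport:
    """Normalized intergene marginals after a long rearrangement-only Gf run.

    The branch length gives every replicate several hundred events of
    burn-in from its flat-Dirichlet start, so the sampled vectors are
    equilibrium draws; marginals are pooled across replicates and tips.
    """
    rng = np.random.default_rng(seed)
    rates = RateConfig(inversion=rate, transposition=rate)
    vecs = []
    for _ in range(reps):
        genome = init_root_genome(
            m, rng=rng, with_intergenes=True, total_intergene_length=1.0
        )
        tree = load_user_tree(f"(A:{branch},B:{branch});")
        res = evolve_genomes(tree, genome, rates, "Gf", rng=rng)
        vecs.append(res.genomes["A"].intergenes)
        vecs.append(res.genomes["B"].intergenes)
    return check_intergene_dirichlet(vecs)


def event_frequency_experiment(
    seed: int, n_genes: int = 2000, duration: float = 5.0
) -> ValidationReport:
    """Event-type counts under rates 2:1:1:1:1 with geometric extensions."""
    rates = RateConfig(
        duplication=0.2, loss=0.1, inversion=0.1, transposition=0.1, transfer=0.1,
        duplication_extension=2.0, loss_extension=2.0, inversion_extension=2.0,
        transposition_extension=2.0, transfer_extension=2.0,
    )
    tree = load_user_tree(f"(A:{duration},B:{duration});")
    rng = np.random.default_rng(seed)
    genome = init_root_genome(n_genes, rng=rng)
    res = evolve_genomes(tree, genome, rates, "G", rng=rng)
    return check_event_frequencies(res.event_log, rates)


def family_size_regime_experiments(seed: int) -> tuple[ValidationReport, ValidationReport]:
    """Family-size tails in the two duplication/loss regimes.

    Duplication-dominant: clade-wide family sizes on a growing birth-death
    species tree, where exponentially growing origination opportunity makes
    family ages exponentially tilted toward young — the mechanism that
    produces a genuine power-law size distribution.  Loss-dominant:
    per-genome sizes sampled at stationarity along a single lineage (via
    zero-length snapshot tips), where the stationary size law has an
    exponential-type tail.
    """
    rng = np.random.default_rng(seed)

    # --- duplication > loss -------------------------------------------------
    sup_rates = RateConfig(duplication=0.3, loss=0.2, origination=1.0)
    sup_sizes: list[int] = []
    for _ in range(6):
        while True:
            tree = simulate_complete_tree(
                0.2, 0.05, stop_time=25.0, seed=int(rng.integers(2**31))
            )
            if not tree.totally_extinct:
                break
        genome = init_root_genome(5, rng=rng)
        res = evolve_genomes(tree, genome, sup_rates, "G", rng=rng)
        global_sizes: Counter = Counter()
        for lid in tree.alive_at_end():
            for fam, count in res.genomes[lid].family_sizes().items():
                global_sizes[fam] += count
        sup_sizes.extend(global_sizes.values())
    sup_report = check_family_size_tail(sup_sizes, 0.3, 0.2)

    # --- loss > duplication -------------------------------------------------
    sub_rates = RateConfig(duplication=1.9, loss=2.0, origination=20.0)
    burn, spacing, n_snapshots = 60.0, 3.0, 160
    stop = burn + spacing * n_snapshots + 1.0
    tree = caterpillar_sampling_tree(
        stop, [burn + spacing * i for i in range(n_snapshots)]
    )
    genome = init_root_genome(50, rng=rng)
    res = evolve_genomes(tree, genome, sub_rates, "G", rng=rng)
    sub_sizes: list[int] = []
    for lid, g in res.genomes.items():
        if tree.nodes[lid].fate.value == "EXTINCT":  # the snapshot tips
            sub_sizes.extend(g.family_sizes().values())
    sub_report = check_family_size_tail(sub_sizes, 1.9, 2.0)
    return sup_report, sub_report


def _two_leaf_tree(t: float) -> GeneTree:
    nodes = {
        0: GeneTreeNode(0, 1, 1, "n1", 0.0, "SPECIATION", [1, 2], None),
        1: GeneTreeNode(1, 1, 2, "n2", t, "PRESENT", [], 0),
        2: GeneTreeNode(2, 1, 3, "n3", t, "PRESENT", [], 0),
    }
    return GeneTree(1, nodes, 0)


def jc_divergence_experiment(seed: int, t: float = 0.2, sites: int = 100_000) -> dict:
    """Observed two-leaf JC divergence vs 3/4 (1 - e^{-8t/3})."""
    seqs = simulate_alignment(_two_leaf_tree(t), SubstitutionModel.jc(), sites, seed=seed)
    a, b = seqs.values()
    observed = sum(x != y for x, y in zip(a, b)) / len(a)
    expected = 0.75 * (1.0 - math.exp(-8.0 * t / 3.0))
    se = math.sqrt(expected * (1.0 - expected) / sites)
    return {
        "observed": observed, "expected": expected, "se": se,
        "z": (observed - expected) / se, "n": sites,
    }


def ghost_donor_experiment() -> dict:
    """Transfer from a lineage that later goes extinct (handcrafted log).

    The donor B dies at t = 1.5 and is absent from the pruned species tree,
    yet the transferred copy survives in A: the complete gene tree shows the
    donor path, the pruned gene tree keeps exactly the surviving copy.
    """
    tree = load_user_tree("(A:3,B:1.5);")
    root = tree.root_id
    log = [
        GenomeEvent(0.0, "O", root, family_ids=(1,), copy_map={(1, 0): (1,)}),
        GenomeEvent(0.0, "SP", root, family_ids=(1,), copy_map={(1, 1): (2, 3)}),
        GenomeEvent(0.5, "L", "A", start=0, extension=1,
                    family_ids=(1,), copy_map={(1, 2): ()}),
        GenomeEvent(1.0, "T", "B", recipient_id="A", start=0, extension=1,
                    family_ids=(1,), copy_map={(1, 3): (4,)}),
        GenomeEvent(1.5, "EX", "B", family_ids=(1,), copy_map={(1, 3): ()}),
        GenomeEvent(3.0, "END", "A", family_ids=(1,), copy_map={(1, 4): ()}),
    ]
    complete = build_gene_tree(1, log, tree)
    pruned = prune_gene_tree(complete)
    donor_in_complete = any(
        n.species_lineage == "B" for n in complete.nodes.values()
    )
    surviving = pruned.leaves("PRESENT") if pruned is not None else []
    return {
        "donor_path_in_complete_tree": donor_in_complete,
        "transfer_nodes": complete.event_counts().get("TRANSFER_DEPART", 0),
        "surviving_copies": len(surviving),
        "surviving_lineages": sorted({n.species_lineage for n in surviving}),
        "donor_leaves_in_pruned": (
            0 if pruned is None else sum(
                1 for n in pruned.leaves() if n.species_lineage == "B"
            )
        ),
    }
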