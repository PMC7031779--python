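"""Output-directory layout and the T -> G -> S pipeline.

Each mode writes a self-contained tier under the run directory::

    out/
      T/CompleteTree.nwk  ExtantTree.nwk  Events.tsv  manifest.json
      G/Events.tsv  Genomes/<lineage>.tsv  Families/<fam>_events.tsv
        GeneTrees/<fam>_complete.nwk  <fam>_pruned.nwk
        Reconciliations/<fam>.recphyloxml  lost_families.txt  manifest.json
      S/Sequences/<fam>.fasta  manifest.json

Coordinates and conventions: genome positions are 0-based, times are
absolute with the root at 0, Newick branch lengths are durations (T and G
tiers) or expected substitutions per site (scaled S trees).  Every manifest
records the tool version, the full config echo and the seed, which is
sufficient to reproduce the run byte-identically.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .config import ConfigError, RunConfig
from .gene_tree import (
    GeneTree,
    build_all_gene_trees,
    emit_reconciliation,
    prune_gene_tree,
)
from .genome import FamilyRates, Genome, RateConfig, init_root_genome
from .genome_sim import EvolutionResult, evolve_genomes
from .sequence_sim import BranchScaling, SubstitutionModel, simulate_alignment
from .species_tree import (
    CompleteSpeciesTree,
    Fate,
    RateFunction,
    TotalExtinctionError,
    load_user_tree,
    prune_extinct,
    simulate_complete_tree,
)

logger = logging.getLogger(__name__)

__all__ = ["run_T", "run_G", "run_S", "run_pipeline"]


def _write_manifest(outdir: Path, mode: str, config: RunConfig, outputs: list[str],
                    extra: dict | None = None) -> None:
    manifest = {
        "tool": "revenant",
        "version": __version__,
        "mode": mode,
        "seed": config.seed,
        "config": {k: v for k, v in config.params.items()},
        "outputs": sorted(outputs),
    }
    if extra:
        manifest.update(extra)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


# ---------------------------------------------------------------------------
# T mode
# ---------------------------------------------------------------------------


def run_T(
    config: RunConfig,
    outdir: str | Path,
    resample_until_survival: bool = False,
    max_retries: int = 100,
) -> CompleteSpeciesTree:
    out = Path(outdir) / "T"
    out.mkdir(parents=True, exist_ok=True)
    lam = RateFunction.constant(config["SPECIATION_RATE"])
    mu = RateFunction.constant(config["EXTINCTION_RATE"])
    stop_time = config["STOP_TIME"] or None
    stop_lineages = config["STOP_LINEAGES"] or None
    seed = config.seed
    tree = simulate_complete_tree(lam, mu, stop_time, seed, stop_lineages)
    attempt = 0
    while tree.totally_extinct and resample_until_survival and attempt < max_retries:
        attempt += 1
        tree = simulate_complete_tree(lam, mu, stop_time, seed + attempt, stop_lineages)
    if tree.totally_extinct:
        logger.warning("T: total extinction — no pruned tree written")

    outputs = []
    (out / "CompleteTree.nwk").write_text(tree.to_newick() + "\n")
    outputs.append("CompleteTree.nwk")
    if not tree.totally_extinct:
        pruned = prune_extinct(tree)
        (out / "ExtantTree.nwk").write_text(pruned.to_newick() + "\n")
        outputs.append("ExtantTree.nwk")

    rows = ["time\tevent\tlineage\tchild1\tchild2"]
    for t, parent, c1, c2 in tree.speciation_events():
        rows.append(f"{t:.10g}\tSP\t{parent}\t{c1}\t{c2}")
    for lid in tree.extinct():
        rows.append(f"{tree.nodes[lid].t_end:.10g}\tEX\t{lid}\t\t")
    for lid in tree.alive_at_end():
        rows.append(f"{tree.nodes[lid].t_end:.10g}\tEND\t{lid}\t\t")
    (out / "Events.tsv").write_text("\n".join(rows) + "\n")
    outputs.append("Events.tsv")
    _write_manifest(
        out, "T", config, outputs,
        {"totally_extinct": tree.totally_extinct, "resample_attempts": attempt},
    )
    return tree


# ---------------------------------------------------------------------------
# G mode
# ---------------------------------------------------------------------------


def _rates_from_config(config: RunConfig) -> RateConfig:
    p = config.params
    rates = RateConfig(
        duplication=p["DUPLICATION_RATE"],
        loss=p["LOSS_RATE"],
        inversion=p["INVERSION_RATE"],
        transposition=p["TRANSPOSITION_RATE"],
        transfer=p["TRANSFER_RATE"],
        origination=p["ORIGINATION_RATE"],
        duplication_extension=p["DUPLICATION_EXTENSION"],
        loss_extension=p["LOSS_EXTENSION"],
        inversion_extension=p["INVERSION_EXTENSION"],
        transposition_extension=p["TRANSPOSITION_EXTENSION"],
        transfer_extension=p["TRANSFER_EXTENSION"],
        transfer_bias=p["TRANSFER_BIAS"],
    )
    mode = config.mode
    if mode == "Gu":
        path = p["LINEAGE_RATES_FILE"]
        if not path:
            raise ConfigError("Gu mode requires LINEAGE_RATES_FILE")
        rates.lineage_overrides.update(_read_lineage_rates(path, rates))
    if mode == "Gm":
        path = p["FAMILY_RATES_FILE"]
        if not path:
            raise ConfigError("Gm mode requires FAMILY_RATES_FILE")
        rates.family_overrides.update(_read_family_rates(path))
    return rates


def _read_lineage_rates(path: str, base: RateConfig) -> dict[str, RateConfig]:
    """TSV: lineage, then any of the five rate columns to override."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if "lineage" not in df.columns:
        raise ConfigError(f"{path}: lineage-rates table needs a 'lineage' column")
    colmap = {
        "duplication": "duplication", "loss": "loss", "inversion": "inversion",
        "transposition": "transposition", "transfer": "transfer",
        "origination": "origination",
    }
    out: dict[str, RateConfig] = {}
    for _, row in df.iterrows():
        kwargs = {
            attr: float(row[col])
            for col, attr in colmap.items()
            if col in df.columns and not pd.isna(row[col])
        }
        merged = {
            **{k: getattr(base, k) for k in (
                "duplication", "loss", "inversion", "transposition", "transfer",
                "origination", "duplication_extension", "loss_extension",
                "inversion_extension", "transposition_extension",
                "transfer_extension", "transfer_bias",
            )},
            **kwargs,
        }
        out[str(row["lineage"])] = RateConfig(**merged)
    return out


def _read_family_rates(path: str) -> dict[int, FamilyRates]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if "family" not in df.columns:
        raise ConfigError(f"{path}: family-rates table needs a 'family' column")
    out: dict[int, FamilyRates] = {}
    for _, row in df.iterrows():
        out[int(row["family"])] = FamilyRates(
            duplication=None if "duplication" not in df.columns or pd.isna(row.get("duplication")) else float(row["duplication"]),
            loss=None if "loss" not in df.columns or pd.isna(row.get("loss")) else float(row["loss"]),
            transfer=None if "transfer" not in df.columns or pd.isna(row.get("transfer")) else float(row["transfer"]),
        )
    return out


def _fmt_copy_map(copy_map: dict) -> str:
    parts = []
    for (fam, old), new in sorted(copy_map.items()):
        tgt = ",".join(str(x) for x in new) if new else "-"
        parts.append(f"{fam}.{old}>{tgt}")
    return ";".join(parts)


def write_event_log(path: Path, events) -> None:
    rows = ["time\ttype\tlineage\trecipient\tstart\textension\tfamilies\tcopy_map"]
    for e in events:
        rows.append(
            f"{e.time:.10g}\t{e.type}\t{e.lineage_id}\t{e.recipient_id or ''}\t"
            f"{'' if e.start is None else e.start}\t"
            f"{'' if e.extension is None else e.extension}\t"
            f"{','.join(str(f) for f in e.family_ids)}\t{_fmt_copy_map(e.copy_map)}"
        )
    path.write_text("\n".join(rows) + "\n")


def run_G(
    config: RunConfig, outdir: str | Path, tree: CompleteSpeciesTree | None = None
) -> tuple[EvolutionResult, dict[int, GeneTree]]:
    out = Path(outdir) / "G"
    if tree is None:
        tree_file = config["TREE_FILE"] or str(Path(outdir) / "T" / "CompleteTree.nwk")
        if not Path(tree_file).exists():
            raise ConfigError(
                f"G mode needs a complete species tree; '{tree_file}' not found "
                "(run T first or set TREE_FILE)"
            )
        tree = load_user_tree(Path(tree_file).read_text())
    out.mkdir(parents=True, exist_ok=True)
    (out / "Genomes").mkdir(exist_ok=True)
    (out / "GeneTrees").mkdir(exist_ok=True)
    (out / "Families").mkdir(exist_ok=True)
    (out / "Reconciliations").mkdir(exist_ok=True)

    mode = config.mode
    rates = _rates_from_config(config)
    seed = config.seed
    rng = np.random.default_rng(seed)
    root_genome = init_root_genome(
        config["INITIAL_GENOME_SIZE"],
        rng=rng,
        lineage_id=tree.root_id,
        with_intergenes=(mode == "Gf"),
        total_intergene_length=config["TOTAL_INTERGENE_LENGTH"],
    )
    result = evolve_genomes(tree, root_genome.copy_content(), rates, mode, rng=rng)

    outputs = []
    write_event_log(out / "Events.tsv", result.event_log)
    outputs.append("Events.tsv")

    for lid, genome in result.genomes.items():
        rows = ["position\tfamily\tcopy\torientation" + ("\tintergene" if genome.intergenes is not None else "")]
        for i, g in enumerate(genome.genes):
            row = f"{i}\t{g.family_id}\t{g.copy_id}\t{'+' if g.orientation > 0 else '-'}"
            if genome.intergenes is not None:
                row += f"\t{genome.intergenes[i]:.10g}"
            rows.append(row)
        (out / "Genomes" / f"{lid}.tsv").write_text("\n".join(rows) + "\n")
    outputs.append("Genomes/")

    gene_trees = build_all_gene_trees(result, root_genome, tree)
    lost = []
    for fam, gt in gene_trees.items():
        write_event_log(
            out / "Families" / f"{fam}_events.tsv",
            [e for e in result.event_log if fam in e.family_ids],
        )
        (out / "GeneTrees" / f"{fam}_complete.nwk").write_text(gt.to_newick() + "\n")
        pruned = prune_gene_tree(gt)
        if pruned is None:
            lost.append(fam)
        else:
            (out / "GeneTrees" / f"{fam}_pruned.nwk").write_text(pruned.to_newick() + "\n")
        (out / "Reconciliations" / f"{fam}.recphyloxml").write_text(
            emit_reconciliation(gt, tree) + "\n"
        )
    (out / "lost_families.txt").write_text("\n".join(str(f) for f in lost) + ("\n" if lost else ""))
    outputs += ["GeneTrees/", "Families/", "Reconciliations/", "lost_families.txt"]
    _write_manifest(out, mode, config, outputs, {"n_families": len(gene_trees), "n_lost": len(lost)})
    return result, gene_trees


# ---------------------------------------------------------------------------
# S mode
# ---------------------------------------------------------------------------


def _model_from_config(config: RunConfig) -> SubstitutionModel:
    level = config["MODEL_LEVEL"]
    if level == "NUCLEOTIDE":
        return SubstitutionModel.hky(kappa=config["KAPPA"])
    if level == "CODON":
        return SubstitutionModel.gy94(kappa=config["KAPPA"], omega=config["OMEGA"])
    return SubstitutionModel.lg()


def _read_branch_scaling(path: str) -> dict[int, float]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return {int(r["node"]): float(r["factor"]) for _, r in df.iterrows()}


def run_S(
    config: RunConfig,
    outdir: str | Path,
    gene_trees: dict[int, GeneTree] | None = None,
) -> dict[int, dict[str, str]]:
    out = Path(outdir) / "S"
    out.mkdir(parents=True, exist_ok=True)
    (out / "Sequences").mkdir(exist_ok=True)
    if gene_trees is None:
        gdir = Path(config["GENE_TREES_DIR"] or Path(outdir) / "G" / "GeneTrees")
        if not gdir.exists():
            raise ConfigError(f"S mode needs gene trees; '{gdir}' not found (run G first)")
        gene_trees = _load_gene_trees(gdir)

    model = _model_from_config(config)
    branch_factors = (
        _read_branch_scaling(config["BRANCH_SCALING_TABLE"])
        if config["BRANCH_SCALING_TABLE"]
        else {}
    )
    scaling = BranchScaling(config["GLOBAL_SCALING"], branch_factors)
    include_extinct = config["INCLUDE_EXTINCT"] == "1"
    seed = config.seed

    alignments: dict[int, dict[str, str]] = {}
    outputs = []
    n_empty = 0
    for i, (fam, gt) in enumerate(sorted(gene_trees.items())):
        seqs = simulate_alignment(
            gt, model, config["ROOT_LENGTH"],
            seed=(seed + i) % 2**31,
            scaling=scaling, include_all_leaves=include_extinct,
        )
        if not seqs:
            n_empty += 1
            continue
        alignments[fam] = seqs
        fasta = "".join(f">{name}\n{seq}\n" for name, seq in sorted(seqs.items()))
        (out / "Sequences" / f"{fam}.fasta").write_text(fasta)
        outputs.append(f"Sequences/{fam}.fasta")
    if n_empty:
        logger.warning("S: %d families have no surviving sequences", n_empty)
    _write_manifest(out, "S", config, outputs, {"n_families": len(alignments)})
    return alignments


def _load_gene_trees(gdir: Path) -> dict[int, GeneTree]:
    """Reload complete gene trees written by the G step.

    Newick keeps times and tip labels (<lineage>_<family>_<copy>) but not
    event labels; tips at the maximum depth are treated as PRESENT, which is
    all sequence simulation needs.
    """
    import dendropy

    from .gene_tree import GeneTreeNode

    out: dict[int, GeneTree] = {}
    for path in sorted(gdir.glob("*_complete.nwk")):
        fam = int(path.name.split("_")[0])
        dt = dendropy.Tree.get(
            path=str(path), schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        nodes: dict[int, GeneTreeNode] = {}
        counter = [0]

        def visit(nd, t_start: float, parent: Optional[int]) -> int:
            nid = counter[0]
            counter[0] += 1
            label = str(nd.taxon.label if nd.taxon is not None else nd.label or "")
            label = label.replace(" ", "_")
            parts = label.rsplit("_", 2)
            lineage, copy_id = (parts[0], int(parts[2])) if len(parts) == 3 else (label, 0)
            t = t_start + (nd.edge.length or 0.0)
            node = GeneTreeNode(nid, fam, copy_id, lineage, t, "SPECIATION", [], parent)
            nodes[nid] = node
            if parent is not None:
                nodes[parent].children.append(nid)
            for k in nd.child_nodes():
                visit(k, t, nid)
            return nid

        root = visit(dt.seed_node, 0.0, None)
        depth = max(n.time for n in nodes.values() if not n.children)
        for n in nodes.values():
            if not n.children:
                n.event = "PRESENT" if n.time >= depth - 1e-9 else "EXTINCTION"
            elif len(n.children) == 1:
                n.event = "ORIGINATION"
        out[fam] = GeneTree(fam, nodes, root, pruned=False)
    return out


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def run_pipeline(
    t_config: RunConfig,
    g_config: RunConfig,
    s_config: RunConfig,
    outdir: str | Path,
    resample_until_survival: bool = False,
):
    """Full T -> G -> S chain into one output directory."""
    outdir = Path(outdir)
    tree = run_T(t_config, outdir, resample_until_survival=resample_until_survival)
    if tree.totally_extinct:
        raise TotalExtinctionError(
            "species tree went totally extinct; rerun with another seed or "
            "--resample-until-survival"
        )
    result, gene_trees = run_G(g_config, outdir, tree=tree)
    alignments = run_S(s_config, outdir, gene_trees=gene_trees)
    return tree, result, gene_trees, alignments
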