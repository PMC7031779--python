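"""Apply the validation battery to the files of a finished run directory."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .diagnostics import (
    ValidationReport,
    check_event_frequencies,
    check_family_size_tail,
    check_waiting_times,
)
from .genome import GENE_EVENT_TYPES, GenomeEvent

__all__ = ["read_event_log", "validate_run_dir"]


def read_event_log(path: Path) -> list[GenomeEvent]:
    """Re-read an Events.tsv written by the G step."""
    events: list[GenomeEvent] = []
    lines = path.read_text().splitlines()
    for line in lines[1:]:
        time, etype, lineage, recipient, start, ext, fams, cmap = line.split("\t")
        copy_map: dict[tuple[int, int], tuple[int, ...]] = {}
        if cmap:
            for entry in cmap.split(";"):
                src, tgt = entry.split(">")
                fam_s, old_s = src.split(".")
                new = () if tgt == "-" else tuple(int(x) for x in tgt.split(","))
                copy_map[(int(fam_s), int(old_s))] = new
        events.append(
            GenomeEvent(
                time=float(time),
                type=etype,
                lineage_id=lineage,
                recipient_id=recipient or None,
                start=int(start) if start else None,
                extension=int(ext) if ext else None,
                family_ids=tuple(int(f) for f in fams.split(",")) if fams else (),
                copy_map=copy_map,
            )
        )
    return events


def validate_run_dir(run_dir: Path) -> list[ValidationReport]:
    """Waiting-time, event-frequency and family-size checks on a G run.

    The intergene check needs replicated equilibrium snapshots, which a
    single run directory does not store; it is exercised by the library API
    instead.
    """
    events_path = run_dir / "G" / "Events.tsv"
    if not events_path.exists():
        raise FileNotFoundError(f"{events_path} not found; run the G step first")
    manifest_path = run_dir / "G" / "manifest.json"
    import json

    cfg = json.loads(manifest_path.read_text())["config"]
    from .genome import RateConfig

    rates = RateConfig(
        duplication=cfg["DUPLICATION_RATE"],
        loss=cfg["LOSS_RATE"],
        inversion=cfg["INVERSION_RATE"],
        transposition=cfg["TRANSPOSITION_RATE"],
        transfer=cfg["TRANSFER_RATE"],
        origination=cfg["ORIGINATION_RATE"],
        duplication_extension=cfg["DUPLICATION_EXTENSION"],
        loss_extension=cfg["LOSS_EXTENSION"],
        inversion_extension=cfg["INVERSION_EXTENSION"],
        transposition_extension=cfg["TRANSPOSITION_EXTENSION"],
        transfer_extension=cfg["TRANSFER_EXTENSION"],
    )
    events = read_event_log(events_path)
    reports: list[ValidationReport] = []

    gene_events = [e for e in events if e.type in GENE_EVENT_TYPES]
    if len(gene_events) >= 1000:
        reports.append(check_event_frequencies(events, rates))

    # waiting times are only Exp(R) at constant R: genome-size-preserving
    # runs (inversions/transpositions only, one lineage) qualify
    if gene_events and all(e.type in ("I", "P") for e in gene_events) and len(gene_events) >= 100:
        if len({e.lineage_id for e in gene_events}) == 1:
            n0 = cfg["INITIAL_GENOME_SIZE"]
            rate = n0 * (rates.inversion + rates.transposition)
            times = np.array([e.time for e in gene_events])
            waits = np.diff(np.concatenate([[0.0], times]))
            reports.append(check_waiting_times(waits, rate))

    # family sizes across all end-of-lineage genomes
    sizes: dict[tuple[str, int], int] = {}
    for gpath in sorted((run_dir / "G" / "Genomes").glob("*.tsv")):
        for line in gpath.read_text().splitlines()[1:]:
            fam = int(line.split("\t")[1])
            key = (gpath.stem, fam)
            sizes[key] = sizes.get(key, 0) + 1
    if sizes:
        reports.append(
            check_family_size_tail(
                list(sizes.values()), rates.duplication, rates.loss
            )
        )
    return reports
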