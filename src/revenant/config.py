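"""Plain-text ``KEY VALUE`` run configuration.

One flat file per mode; ``#`` starts a comment.  Unknown keys are rejected
(misspelled rates silently defaulting to zero would invalidate a whole
simulation), all rates must parse as non-negative numbers, and the seed is
echoed verbatim into the run manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Optional

__all__ = ["RunConfig", "ConfigError", "parse_config", "CONFIG_SCHEMAS"]


class ConfigError(ValueError):
    pass


def _nonneg(key: str):
    def conv(raw: str) -> float:
        v = float(raw)
        if v < 0:
            raise ConfigError(f"{key} must be >= 0, got {raw}")
        return v

    return conv


def _posint(key: str):
    def conv(raw: str) -> int:
        v = int(raw)
        if v < 1:
            raise ConfigError(f"{key} must be a positive integer, got {raw}")
        return v

    return conv


def _geq1(key: str):
    def conv(raw: str) -> float:
        v = float(raw)
        if v < 1:
            raise ConfigError(f"{key} must be >= 1, got {raw}")
        return v

    return conv


def _choice(key: str, options: tuple[str, ...]):
    def conv(raw: str) -> str:
        if raw not in options:
            raise ConfigError(f"{key} must be one of {options}, got {raw}")
        return raw

    return conv


# key -> (converter, default); default None marks a required key unless the
# schema's alternatives rule says otherwise.
CONFIG_SCHEMAS: dict[str, dict[str, tuple[Callable[[str], Any], Any]]] = {
    "T": {
        "SPECIATION_RATE": (_nonneg("SPECIATION_RATE"), None),
        "EXTINCTION_RATE": (_nonneg("EXTINCTION_RATE"), None),
        "STOP_TIME": (_nonneg("STOP_TIME"), 0.0),
        "STOP_LINEAGES": (_posint("STOP_LINEAGES"), 0),
        "SEED": (int, 0),
    },
    "G": {
        "MODE": (_choice("MODE", ("G", "Gu", "Gm", "Gf")), "G"),
        "TREE_FILE": (str, ""),
        "INITIAL_GENOME_SIZE": (_posint("INITIAL_GENOME_SIZE"), 100),
        "DUPLICATION_RATE": (_nonneg("DUPLICATION_RATE"), 0.0),
        "LOSS_RATE": (_nonneg("LOSS_RATE"), 0.0),
        "INVERSION_RATE": (_nonneg("INVERSION_RATE"), 0.0),
        "TRANSPOSITION_RATE": (_nonneg("TRANSPOSITION_RATE"), 0.0),
        "TRANSFER_RATE": (_nonneg("TRANSFER_RATE"), 0.0),
        "ORIGINATION_RATE": (_nonneg("ORIGINATION_RATE"), 0.0),
        "DUPLICATION_EXTENSION": (_geq1("DUPLICATION_EXTENSION"), 1.0),
        "LOSS_EXTENSION": (_geq1("LOSS_EXTENSION"), 1.0),
        "INVERSION_EXTENSION": (_geq1("INVERSION_EXTENSION"), 1.0),
        "TRANSPOSITION_EXTENSION": (_geq1("TRANSPOSITION_EXTENSION"), 1.0),
        "TRANSFER_EXTENSION": (_geq1("TRANSFER_EXTENSION"), 1.0),
        "TRANSFER_BIAS": (_nonneg("TRANSFER_BIAS"), 0.0),
        "TOTAL_INTERGENE_LENGTH": (_nonneg("TOTAL_INTERGENE_LENGTH"), 1.0),
        "LINEAGE_RATES_FILE": (str, ""),
        "FAMILY_RATES_FILE": (str, ""),
        "SEED": (int, 0),
    },
    "S": {
        "MODEL_LEVEL": (_choice("MODEL_LEVEL", ("NUCLEOTIDE", "CODON", "AMINO_ACID")), "NUCLEOTIDE"),
        "KAPPA": (_nonneg("KAPPA"), 2.0),
        "OMEGA": (_nonneg("OMEGA"), 0.2),
        "ROOT_LENGTH": (_posint("ROOT_LENGTH"), 300),
        "GLOBAL_SCALING": (_nonneg("GLOBAL_SCALING"), 1.0),
        "BRANCH_SCALING_TABLE": (str, ""),
        "GENE_TREES_DIR": (str, ""),
        "INCLUDE_EXTINCT": (_choice("INCLUDE_EXTINCT", ("0", "1")), "0"),
        "SEED": (int, 0),
    },
}


@dataclass
class RunConfig:
    mode: str
    params: dict[str, Any]
    path: Optional[Path] = None

    def __getitem__(self, key: str) -> Any:
        return self.params[key]

    @property
    def seed(self) -> int:
        return int(self.params.get("SEED", 0))


def parse_config(path: str | Path, mode: str) -> RunConfig:
    """Read and validate one flat KEY VALUE config file for a given mode."""
    schema_mode = "G" if mode in ("G", "Gu", "Gm", "Gf") else mode
    if schema_mode not in CONFIG_SCHEMAS:
        raise ConfigError(f"unknown mode '{mode}'")
    schema = CONFIG_SCHEMAS[schema_mode]
    path = Path(path)
    params: dict[str, Any] = {k: d for k, (_, d) in schema.items()}
    seen: set[str] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise ConfigError(f"{path}:{lineno}: expected 'KEY VALUE', got '{raw.strip()}'")
        key, value = parts
        if key not in schema:
            raise ConfigError(f"{path}:{lineno}: unknown key '{key}'")
        if key in seen:
            raise ConfigError(f"{path}:{lineno}: duplicate key '{key}'")
        seen.add(key)
        conv, _ = schema[key]
        try:
            params[key] = conv(value)
        except ConfigError:
            raise
        except Exception as exc:
            raise ConfigError(f"{path}:{lineno}: bad value for '{key}': {exc}") from exc
    if schema_mode == "T":
        missing = [k for k in ("SPECIATION_RATE", "EXTINCTION_RATE") if k not in seen]
        if missing:
            raise ConfigError(f"{path}: missing required key(s) {missing}")
        if params["STOP_TIME"] <= 0 and params["STOP_LINEAGES"] <= 0:
            raise ConfigError(f"{path}: need STOP_TIME > 0 or STOP_LINEAGES >= 1")
    if mode != schema_mode:
        params["MODE"] = mode
    return RunConfig(mode=params.get("MODE", mode), params=params, path=path)
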