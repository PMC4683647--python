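"""File dialects: cross-table TSV, marker-matrix TSV, parent-panel TSV,
assembly tables, and YAML run/model configuration.

TSV (not CSV) throughout, because diploid call tokens contain ``/`` and the
source tables are tab-shaped.  Marker column ids encode chromosome and
1-based position (``Fvb6_35142280``), split at the final underscore.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import asdict, dataclass, field
from fractions import Fraction
from pathlib import Path

import pandas as pd
import yaml

from .containers import (
    CrossRecord,
    CrossTable,
    Marker,
    MarkerGenotypeMatrix,
    ParentPanel,
    ParentRecord,
    parse_call,
    parse_marker_id,
)
from .model import (
    MITOTYPES,
    MODEL_LOCI,
    Cytotype,
    Locus,
    ModelError,
    SexPhenotype,
    ViabilityRule,
)

__all__ = [
    "RunConfig",
    "read_cross_table",
    "write_cross_table",
    "write_cross_table_rows",
    "read_marker_matrix",
    "write_marker_matrix",
    "write_marker_matrix_rows",
    "read_parent_panel",
    "read_assembly_table",
    "load_run_config",
    "dump_run_config",
    "load_model_config",
]

log = logging.getLogger("gynomap")

CROSS_COLUMNS = ["cross_type", "dam", "sire", "n_female", "n_herm"]
MARKER_META_COLUMNS = ["individual", "family", "sex"]


class FileFormatError(ModelError):
    """A file did not match its dialect; the message carries coordinates."""


@dataclass
class RunConfig:
    """Pipeline thresholds and paths; round-trips through YAML."""

    model_file: str | None = None
    seed: int = 0
    n_min: int = 10
    alpha: float = 0.05
    lod_threshold: float = 3.0
    window_size: int = 1_000_000
    output_dir: str = "."
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_min <= 0 or self.alpha <= 0 or self.lod_threshold <= 0 or self.window_size <= 0:
            raise ModelError("thresholds must be positive")


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def dump_run_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
    log.info("wrote run config to %s", path)


# ---------------------------------------------------------------------------
# Cross tables
# ---------------------------------------------------------------------------


def read_cross_table(path) -> CrossTable:
    """Read a cross-table TSV (columns cross_type, dam, sire, n_female,
    n_herm; extras preserved).  Zero-progeny rows are kept and exposed via
    :attr:`CrossTable.zero_progeny`."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except OSError as exc:
        raise FileFormatError(f"cannot read cross table {path}: {exc}") from exc
    missing = [c for c in CROSS_COLUMNS if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing column(s) {missing}")
    records = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # 1-based, after the header
        counts = []
        for col in ("n_female", "n_herm"):
            token = row[col].strip()
            if not token.lstrip("-").isdigit():
                raise FileFormatError(
                    f"{path}:{line_no}: non-integer {col} value {token!r}"
                )
            counts.append(int(token))
        records.append(
            CrossRecord(row["cross_type"], row["dam"], row["sire"], *counts)
        )
    keys = [(r.cross_type, r.dam, r.sire) for r in records]
    dupes = {k for k in keys if keys.count(k) > 1}
    if dupes:
        raise FileFormatError(f"{path}: duplicate cross rows {sorted(dupes)}")
    extra_cols = [c for c in df.columns if c not in CROSS_COLUMNS]
    extra = df[extra_cols] if extra_cols else None
    table = CrossTable(records, extra=extra)
    if table.zero_progeny:
        log.info(
            "%s: %d zero-progeny row(s) flagged", path, len(table.zero_progeny)
        )
    return table


def write_cross_table_rows(rows: Sequence[Mapping], path) -> None:
    df = pd.DataFrame(rows, columns=CROSS_COLUMNS if rows else CROSS_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    log.info("wrote %d cross rows to %s", len(df), path)


def write_cross_table(table: CrossTable, path) -> None:
    write_cross_table_rows(table.to_frame().to_dict("records"), path)


# ---------------------------------------------------------------------------
# Marker matrices
# ---------------------------------------------------------------------------


def read_marker_matrix(path, design: str = "selfed-F2") -> MarkerGenotypeMatrix:
    """Read a marker-matrix TSV: columns individual, family, sex, then one
    column per marker with calls like ``G/T``, ``T``, or ``.`` for missing."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except OSError as exc:
        raise FileFormatError(f"cannot read marker matrix {path}: {exc}") from exc
    missing = [c for c in MARKER_META_COLUMNS if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing column(s) {missing}")
    marker_cols = [c for c in df.columns if c not in MARKER_META_COLUMNS]
    if not marker_cols:
        raise FileFormatError(f"{path}: no marker columns found")
    markers = [parse_marker_id(c) for c in marker_cols]
    sex_map = {"F": SexPhenotype.FEMALE, "H": SexPhenotype.HERMAPHRODITE}
    sexes = []
    for idx, token in enumerate(df["sex"]):
        if token not in sex_map:
            raise FileFormatError(
                f"{path}:{idx + 2}: unknown sex phenotype {token!r}"
            )
        sexes.append(sex_map[token])
    for col in marker_cols:
        for idx, token in enumerate(df[col]):
            try:
                parse_call(token)
            except ModelError as exc:
                raise FileFormatError(
                    f"{path}:{idx + 2}: column {col!r}: {exc}"
                ) from exc
    calls = df[marker_cols].copy()
    calls.index = pd.Index(df["individual"], name="individual")
    families = df["family"].unique()
    return MarkerGenotypeMatrix(
        markers=markers,
        calls=calls,
        sex=pd.Series(sexes, index=calls.index),
        family=families[0] if len(families) == 1 else "",
        design=design,
    )


def write_marker_matrix_rows(
    rows: Sequence[Mapping], marker_ids: Sequence[str], path
) -> None:
    df = pd.DataFrame(rows, columns=MARKER_META_COLUMNS + list(marker_ids))
    df.to_csv(path, sep="\t", index=False)
    log.info("wrote %d individuals to %s", len(df), path)


def write_marker_matrix(matrix: MarkerGenotypeMatrix, path) -> None:
    rows = []
    for ind in matrix.calls.index:
        row = {
            "individual": ind,
            "family": matrix.family,
            "sex": matrix.sex.loc[ind].value,
        }
        row.update(matrix.calls.loc[ind].to_dict())
        rows.append(row)
    write_marker_matrix_rows(rows, [m.id for m in matrix.markers], path)


# ---------------------------------------------------------------------------
# Parent panels and assembly tables
# ---------------------------------------------------------------------------


def read_parent_panel(path, loci: Sequence[Locus] = MODEL_LOCI) -> ParentPanel:
    """Read a panel TSV: id, population, sex, mitotype, plus optional
    genotype-constraint columns named after loci (e.g. ``LG6``)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["id", "population", "sex", "mitotype"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing column(s) {missing}")
    sex_map = {"F": SexPhenotype.FEMALE, "H": SexPhenotype.HERMAPHRODITE}
    locus_cols = [l.name for l in loci if l.name in df.columns]
    parents = []
    for idx, row in df.iterrows():
        if row["sex"] not in sex_map:
            raise FileFormatError(f"{path}:{idx + 2}: unknown sex {row['sex']!r}")
        constraints = {
            name: row[name] for name in locus_cols if row[name].strip()
        }
        parents.append(
            ParentRecord(
                id=row["id"],
                population=row["population"],
                sex=sex_map[row["sex"]],
                cytotype=MITOTYPES.get(
                    row["mitotype"], Cytotype(row["mitotype"], True)
                ),
                constraints=constraints or None,
            )
        )
    return ParentPanel(parents)


def read_assembly_table(path) -> dict[str, int]:
    """Read a chromosome-length TSV (columns chromosome, length)."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "length": int})
    for col in ("chromosome", "length"):
        if col not in df.columns:
            raise FileFormatError(f"{path}: missing column {col!r}")
    return dict(zip(df["chromosome"], df["length"]))


# ---------------------------------------------------------------------------
# Model configuration (YAML)
# ---------------------------------------------------------------------------


@dataclass
class ModelConfig:
    loci: tuple[Locus, ...]
    viability: tuple[ViabilityRule, ...]
    cytotypes: dict[str, Cytotype]
    phenotype_rule: str = "cms-restorer"


def load_model_config(path) -> ModelConfig:
    """Load a model definition: loci (dominance order), phenotype rule
    selection, viability rules, and the cytotype table."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    loci = tuple(
        Locus(entry["name"], tuple(entry["alleles"]))
        for entry in data.get("loci", [])
    ) or MODEL_LOCI
    rules = tuple(
        ViabilityRule.make(
            entry["genotype"], Fraction(str(entry["survival"])), entry.get("name", "")
        )
        for entry in data.get("viability", [])
    )
    cytotypes = {
        label: Cytotype(label, bool(spec.get("cms", True)))
        for label, spec in (data.get("cytotypes") or {}).items()
    } or dict(MITOTYPES)
    return ModelConfig(
        loci=loci,
        viability=rules,
        cytotypes=cytotypes,
        phenotype_rule=data.get("phenotype_rule", "cms-restorer"),
    )
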