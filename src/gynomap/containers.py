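"""Shared in-memory containers: cross tables, parent panels, marker matrices."""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass, field

import pandas as pd

from .model import MITOTYPES, Cytotype, ModelError, SexPhenotype

__all__ = [
    "CrossRecord",
    "CrossTable",
    "ParentRecord",
    "ParentPanel",
    "Marker",
    "MarkerGenotypeMatrix",
    "parse_call",
    "parse_marker_id",
]


@dataclass(frozen=True)
class CrossRecord:
    """One dam × sire family with observed sex counts (a cross-table row)."""

    cross_type: str
    dam: str
    sire: str
    n_female: int
    n_herm: int

    def __post_init__(self) -> None:
        if self.n_female < 0 or self.n_herm < 0:
            raise ModelError("progeny counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_female + self.n_herm

    @property
    def is_self(self) -> bool:
        return self.dam == self.sire


@dataclass
class CrossTable:
    """A crossing design: a list of :class:`CrossRecord` plus any extra
    columns carried along from the source file."""

    records: list[CrossRecord]
    extra: pd.DataFrame | None = None

    def __iter__(self) -> Iterator[CrossRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def zero_progeny(self) -> list[CrossRecord]:
        return [r for r in self.records if r.n_total == 0]

    def parents(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.dam)
            seen.setdefault(r.sire)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cross_type": [r.cross_type for r in self.records],
                "dam": [r.dam for r in self.records],
                "sire": [r.sire for r in self.records],
                "n_female": [r.n_female for r in self.records],
                "n_herm": [r.n_herm for r in self.records],
            }
        )


@dataclass(frozen=True)
class ParentRecord:
    """A panel entry: one parent plant with its observed sex and mitotype."""

    id: str
    population: str
    sex: SexPhenotype
    cytotype: Cytotype
    constraints: Mapping[str, str] | None = None  # locus name -> diploid string


@dataclass
class ParentPanel:
    parents: list[ParentRecord]

    def __post_init__(self) -> None:
        ids = [p.id for p in self.parents]
        if len(set(ids)) != len(ids):
            raise ModelError("parent ids must be unique")
        self._by_id = {p.id: p for p in self.parents}

    def __iter__(self) -> Iterator[ParentRecord]:
        return iter(self.parents)

    def __len__(self) -> int:
        return len(self.parents)

    def __getitem__(self, pid: str) -> ParentRecord:
        try:
            return self._by_id[pid]
        except KeyError:
            raise ModelError(f"parent {pid!r} not in panel") from None

    def __contains__(self, pid: str) -> bool:
        return pid in self._by_id


# ---------------------------------------------------------------------------
# Marker matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Marker:
    id: str
    chromosome: str
    position: int  # 1-based


def parse_marker_id(marker_id: str) -> Marker:
    """Parse ids of the form ``Fvb6_35142280`` (chromosome, 1-based position
    split at the final underscore)."""
    chrom, _, pos = marker_id.rpartition("_")
    if not chrom or not pos.isdigit():
        raise ModelError(
            f"marker id {marker_id!r} does not encode chromosome_position"
        )
    return Marker(marker_id, chrom, int(pos))


def parse_call(token: str) -> frozenset[str] | None:
    """Parse a diploid marker call: ``"G/T"`` het, ``"T"`` homozygote,
    ``"."`` missing."""
    token = token.strip()
    if token == "." or token == "":
        return None
    if "/" in token:
        a, b = token.split("/", 1)
        if not a or not b:
            raise ModelError(f"malformed call token {token!r}")
        return frozenset((a, b))
    return frozenset((token,))


def format_call(call: frozenset[str] | None) -> str:
    if call is None:
        return "."
    alleles = sorted(call)
    return alleles[0] if len(alleles) == 1 else "/".join(alleles)


@dataclass
class MarkerGenotypeMatrix:
    """Per-individual diploid marker calls with positions and sex phenotypes.

    ``calls`` is indexed by individual id with one column per marker id,
    holding raw tokens ("G/T", "T", "."); ``sex`` is aligned with the index.
    ``design`` labels the family design ("selfed-F2" or "outcross").
    """

    markers: list[Marker]
    calls: pd.DataFrame
    sex: pd.Series
    family: str = ""
    design: str = "selfed-F2"

    def __post_init__(self) -> None:
        ids = [m.id for m in self.markers]
        missing = [m for m in ids if m not in self.calls.columns]
        if missing:
            raise ModelError(f"calls missing marker columns: {missing}")
        by_chrom: dict[str, int] = {}
        for m in sorted(self.markers, key=lambda m: (m.chromosome, m.position)):
            prev = by_chrom.get(m.chromosome)
            if prev is not None and m.position <= prev:
                raise ModelError(
                    f"marker positions must be strictly increasing on "
                    f"{m.chromosome} (offender {m.id})"
                )
            by_chrom[m.chromosome] = m.position
        if not self.sex.index.equals(self.calls.index):
            raise ModelError("sex index must match calls index")

    def marker(self, marker_id: str) -> Marker:
        for m in self.markers:
            if m.id == marker_id:
                return m
        raise ModelError(f"marker {marker_id!r} not in matrix")

    def markers_on(self, chromosome: str) -> list[Marker]:
        return sorted(
            (m for m in self.markers if m.chromosome == chromosome),
            key=lambda m: m.position,
        )

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.markers:
            seen.setdefault(m.chromosome)
        return list(seen)

    def genotypes(self, marker_id: str) -> pd.Series:
        """Parsed calls (frozensets, None for missing) for one marker."""
        return self.calls[marker_id].map(parse_call)

    def n_individuals(self) -> int:
        return len(self.calls)
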