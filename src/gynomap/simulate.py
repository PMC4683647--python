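"""Cross and marker-data simulator.

Emulates the study's crossing designs end to end: parent panels drawn under
Hardy–Weinberg from per-population allele frequencies, crosses producing
progeny by independent assortment of the three model loci, markers linked to
the LG6 sterility locus recombining under the Haldane map function, optional
genotype-dependent lethality, and i.i.d. missing marker calls.  Everything is
seeded: one master seed, with per-family substreams derived by stable hashing
of the family id so adding a family never perturbs the others.
"""

from __future__ import annotations

import math
import zlib
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .containers import Marker
from .model import (
    MITOTYPES,
    MODEL_LOCI,
    Cytotype,
    Locus,
    ModelError,
    MultilocusGenotype,
    PhenotypeRule,
    SexPhenotype,
    ViabilityRule,
    cms_restorer_phenotype,
    phenotype_of,
    progeny_distribution,
)

__all__ = [
    "PanelSpec",
    "CrossSpec",
    "MarkerMap",
    "ProgenyRecord",
    "NM_LNF_PANEL",
    "OR_MRD_PANEL",
    "haldane",
    "simulate_panel",
    "simulate_cross",
    "simulate_family_counts",
    "emit_fixture_tables",
    "family_rng",
]

#: Default physical-to-genetic scale (cM per Mb), applied through the Haldane
#: map function when only physical marker positions are known.
DEFAULT_CM_PER_MB = 3.5


def haldane(distance_cm: float) -> float:
    """Haldane map function (no interference): cM distance → recombination
    fraction."""
    if distance_cm < 0:
        raise ModelError("map distance must be non-negative")
    return 0.5 * (1.0 - math.exp(-2.0 * distance_cm / 100.0))


def family_rng(master_seed: int, family_id: str) -> np.random.Generator:
    """Independent, reproducible substream for one family.

    The substream key is a stable CRC32 hash of the family id, so streams are
    insensitive to the order families are simulated in.
    """
    key = zlib.crc32(family_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([master_seed, key]))


# ---------------------------------------------------------------------------
# Parent panels
# ---------------------------------------------------------------------------


def _validate_freqs(freqs: Mapping[str, float], what: str) -> None:
    vals = list(freqs.values())
    if any(v < 0 or v > 1 for v in vals) or abs(sum(vals) - 1.0) > 1e-9:
        raise ModelError(f"{what} frequencies must lie in [0,1] and sum to 1")


@dataclass(frozen=True)
class PanelSpec:
    """Specification of a parent panel.

    ``allele_freqs`` maps locus name → {allele: frequency}; ``mitotype_freqs``
    maps mitotype label → frequency.  If ``sex_constraint`` is set, genotypes
    are rejection-sampled until the phenotype matches.
    """

    population: str
    allele_freqs: Mapping[str, Mapping[str, float]]
    mitotype_freqs: Mapping[str, float]
    n_parents: int
    sex_constraint: SexPhenotype | None = None
    loci: tuple[Locus, ...] = MODEL_LOCI
    max_attempts: int = 100_000

    def __post_init__(self) -> None:
        if self.n_parents < 0:
            raise ModelError("n_parents must be non-negative")
        for locus in self.loci:
            freqs = self.allele_freqs.get(locus.name)
            if freqs is None or set(freqs) != set(locus.alleles):
                raise ModelError(
                    f"allele frequencies required for both alleles of {locus.name}"
                )
            _validate_freqs(freqs, locus.name)
        _validate_freqs(self.mitotype_freqs, "mitotype")


def _panel_preset(
    population: str,
    ms: Fraction,
    r: Fraction,
    t: Fraction,
    mitotypes: Mapping[str, float],
    **kw,
) -> PanelSpec:
    return PanelSpec(
        population=population,
        allele_freqs={
            "LG4": {"MS": float(ms), "mf": float(1 - ms)},
            "LG6": {"R": float(1 - r), "r": float(r)},
            "LGx": {"T": float(1 - t), "t": float(t)},
        },
        mitotype_freqs=dict(mitotypes),
        **kw,
    )


def NM_LNF_PANEL(n_parents: int, sex_constraint: SexPhenotype | None = None) -> PanelSpec:
    """New Mexico study population preset: *r* common (9/12), *MS* absent,
    *t* rare (1/12); mitotype F fixed."""
    return _panel_preset(
        "NM-LNF",
        ms=Fraction(0),
        r=Fraction(9, 12),
        t=Fraction(1, 12),
        mitotypes={"F": 1.0},
        n_parents=n_parents,
        sex_constraint=sex_constraint,
    )


def OR_MRD_PANEL(n_parents: int, sex_constraint: SexPhenotype | None = None) -> PanelSpec:
    """Oregon study population preset: *MS* at 3/12, *r* rare (1/12), *t*
    rare (1/12); mitotypes 90% C and 10% B."""
    return _panel_preset(
        "OR-MRD",
        ms=Fraction(3, 12),
        r=Fraction(1, 12),
        t=Fraction(1, 12),
        mitotypes={"C": 0.9, "B": 0.1},
        n_parents=n_parents,
        sex_constraint=sex_constraint,
    )


def _draw_genotype(
    spec: PanelSpec, rng: np.random.Generator
) -> MultilocusGenotype:
    labels = list(spec.mitotype_freqs)
    probs = [spec.mitotype_freqs[l] for l in labels]
    mito = labels[rng.choice(len(labels), p=probs)]
    cytotype = MITOTYPES.get(mito, Cytotype(mito, True))
    alleles = []
    for locus in spec.loci:
        freqs = spec.allele_freqs[locus.name]
        symbols = list(locus.alleles)
        p = [freqs[s] for s in symbols]
        pair = tuple(symbols[i] for i in rng.choice(len(symbols), size=2, p=p))
        alleles.append(pair)
    return MultilocusGenotype(spec.loci, tuple(alleles), cytotype)


def simulate_panel(
    spec: PanelSpec,
    seed: int,
    rule: PhenotypeRule = cms_restorer_phenotype,
) -> list[MultilocusGenotype]:
    """Draw parent genotypes under Hardy–Weinberg per locus, rejection
    sampling to the sex constraint when one is given."""
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    panel = []
    for _ in range(spec.n_parents):
        for _attempt in range(spec.max_attempts):
            g = _draw_genotype(spec, rng)
            if spec.sex_constraint is None or phenotype_of(g, rule) is spec.sex_constraint:
                panel.append(g)
                break
        else:
            raise ModelError(
                f"could not satisfy sex constraint {spec.sex_constraint} at the "
                f"given allele frequencies after {spec.max_attempts} attempts"
            )
    return panel


# ---------------------------------------------------------------------------
# Linked markers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerMap:
    """Markers on the chromosome carrying one anchored model locus.

    Each marker recombines with the anchored locus at the fraction given by
    the map function applied to their physical distance.  ``alleles`` maps
    marker id → the two allele symbols segregating at the marker.
    """

    markers: tuple[Marker, ...]
    anchored_locus: str
    anchored_position: int
    chromosome: str
    alleles: Mapping[str, tuple[str, str]] = field(default_factory=dict)
    cm_per_mb: float = DEFAULT_CM_PER_MB

    def __post_init__(self) -> None:
        pos = [m.position for m in self.markers]
        if any(m.chromosome != self.chromosome for m in self.markers):
            raise ModelError("all markers must lie on the map's chromosome")
        if sorted(pos) != pos or len(set(pos)) != len(pos):
            raise ModelError("marker positions must be strictly increasing")

    def recombination_fraction(self, marker: Marker) -> float:
        dist_cm = abs(marker.position - self.anchored_position) / 1e6 * self.cm_per_mb
        return haldane(dist_cm)

    def marker_alleles(self, marker: Marker) -> tuple[str, str]:
        return tuple(self.alleles.get(marker.id, ("A", "B")))  # type: ignore[return-value]


Phase = Mapping[str, tuple[str, str]]  # marker id -> allele on (hap0, hap1)


@dataclass(frozen=True)
class CrossSpec:
    """One simulated family.

    ``dam_phase``/``sire_phase`` give, per marker, the allele riding on each
    parental haplotype; haplotype 0 carries the first allele of the parent's
    (dominance-ordered) pair at the anchored locus.  Omitted phases are
    randomized from the family substream.  A self uses the dam's genotype and
    phase for both roles.
    """

    family_id: str
    dam_id: str
    sire_id: str
    dam: MultilocusGenotype
    sire: MultilocusGenotype
    n: int
    seed: int
    viability: tuple[ViabilityRule, ...] = ()
    dropout: float = 0.0
    cross_type: str = ""
    dam_phase: Phase | None = None
    sire_phase: Phase | None = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ModelError("progeny count must be non-negative")
        if not 0 <= self.dropout <= 1:
            raise ModelError("dropout must lie in [0, 1]")

    @property
    def is_self(self) -> bool:
        return self.dam_id == self.sire_id

    def resolved_cross_type(self, rule: PhenotypeRule = cms_restorer_phenotype) -> str:
        if self.cross_type:
            return self.cross_type
        if self.is_self:
            return "H-SELF"
        dam_sex = phenotype_of(self.dam, rule)
        return "F x H" if dam_sex is SexPhenotype.FEMALE else "H x H"


@dataclass(frozen=True)
class ProgenyRecord:
    individual_id: str
    family_id: str
    genotype: MultilocusGenotype
    phenotype: SexPhenotype
    marker_calls: Mapping[str, str] = field(default_factory=dict)


def _random_phase(
    parent: MultilocusGenotype,
    marker_map: MarkerMap,
    rng: np.random.Generator,
) -> dict[str, tuple[str, str]]:
    phase = {}
    for m in marker_map.markers:
        a1, a2 = marker_map.marker_alleles(m)
        # each haplotype gets an independent allele draw; heterozygous
        # markers end up in a random phase relative to the anchored locus
        phase[m.id] = (
            a1 if rng.random() < 0.5 else a2,
            a1 if rng.random() < 0.5 else a2,
        )
    return phase


def _gamete(
    parent: MultilocusGenotype,
    phase: Phase | None,
    marker_map: MarkerMap | None,
    rng: np.random.Generator,
) -> tuple[dict[str, str], dict[str, str]]:
    """Draw one gamete: (model-locus alleles, marker alleles)."""
    locus_alleles = {}
    anchored_hap = 0
    for locus, pair in zip(parent.loci, parent.alleles):
        hap = int(rng.integers(2))
        locus_alleles[locus.name] = pair[hap]
        if marker_map is not None and locus.name == marker_map.anchored_locus:
            anchored_hap = hap
    marker_alleles: dict[str, str] = {}
    if marker_map is not None:
        assert phase is not None
        for m in marker_map.markers:
            r = marker_map.recombination_fraction(m)
            hap = anchored_hap if rng.random() >= r else 1 - anchored_hap
            marker_alleles[m.id] = phase[m.id][hap]
    return locus_alleles, marker_alleles


def simulate_cross(
    spec: CrossSpec,
    marker_map: MarkerMap | None = None,
    rule: PhenotypeRule = cms_restorer_phenotype,
) -> list[ProgenyRecord]:
    """Simulate one family: model loci assort independently, linked markers
    recombine with the anchored locus, the cytotype is copied from the dam,
    viability is applied before output, and missing marker calls are
    inserted i.i.d. at the dropout rate."""
    rng = family_rng(spec.seed, spec.family_id)
    dam_phase = spec.dam_phase
    sire_phase = spec.sire_phase
    if marker_map is not None:
        if dam_phase is None:
            dam_phase = _random_phase(spec.dam, marker_map, rng)
        if sire_phase is None:
            sire_phase = dam_phase if spec.is_self else _random_phase(
                spec.sire, marker_map, rng
            )
    out: list[ProgenyRecord] = []
    for i in range(spec.n):
        egg_loci, egg_markers = _gamete(spec.dam, dam_phase, marker_map, rng)
        pol_loci, pol_markers = _gamete(spec.sire, sire_phase, marker_map, rng)
        child = MultilocusGenotype(
            spec.dam.loci,
            tuple(
                (egg_loci[l.name], pol_loci[l.name]) for l in spec.dam.loci
            ),
            spec.dam.cytotype,
        )
        surv = 1.0
        for vrule in spec.viability:
            if vrule.matches(child):
                surv *= float(vrule.survival)
        if rng.random() >= surv:
            continue
        calls = {}
        if marker_map is not None:
            for m in marker_map.markers:
                if spec.dropout > 0 and rng.random() < spec.dropout:
                    calls[m.id] = "."
                else:
                    pair = sorted((egg_markers[m.id], pol_markers[m.id]))
                    calls[m.id] = pair[0] if pair[0] == pair[1] else "/".join(pair)
        out.append(
            ProgenyRecord(
                individual_id=f"{spec.family_id}-{i + 1:04d}",
                family_id=spec.family_id,
                genotype=child,
                phenotype=phenotype_of(child, rule),
                marker_calls=calls,
            )
        )
    return out


def simulate_family_counts(
    dam: MultilocusGenotype,
    sire: MultilocusGenotype,
    n: int,
    rng: np.random.Generator,
    viability: Sequence[ViabilityRule] = (),
    rule: PhenotypeRule = cms_restorer_phenotype,
) -> tuple[int, int]:
    """Fast path: (n_female, n_herm) for one family without marker data.

    Exact survivor-class probabilities come from the rational model; only the
    binomial sampling is stochastic.
    """
    dist = progeny_distribution(dam, sire, list(viability), rule)
    f = float(
        sum(p for (_, sex), p in dist.items() if sex is SexPhenotype.FEMALE)
    )
    if viability:
        raw = progeny_distribution(dam, sire, (), rule)
        mass = 0.0
        for (g, _), p in raw.items():
            s = 1.0
            for vrule in viability:
                if vrule.matches(g):
                    s *= float(vrule.survival)
            mass += float(p) * s
        survivors = int(rng.binomial(n, mass))
    else:
        survivors = n
    k = int(rng.binomial(survivors, f)) if survivors else 0
    return k, survivors - k


def emit_fixture_tables(
    families: Sequence[tuple[CrossSpec, Sequence[ProgenyRecord]]],
    cross_path,
    marker_path,
    rule: PhenotypeRule = cms_restorer_phenotype,
) -> None:
    """Write a cross-table TSV and a marker-matrix TSV for simulated
    families; both round-trip losslessly through the package readers."""
    # deferred import: io depends on containers only, but keep cycles out
    from . import io as gio

    cross_rows = []
    marker_ids: list[str] = []
    for spec, progeny in families:
        nf = sum(p.phenotype is SexPhenotype.FEMALE for p in progeny)
        nh = len(progeny) - nf
        cross_rows.append(
            {
                "cross_type": spec.resolved_cross_type(rule),
                "dam": spec.dam_id,
                "sire": spec.sire_id,
                "n_female": nf,
                "n_herm": nh,
            }
        )
        for p in progeny:
            for mid in p.marker_calls:
                if mid not in marker_ids:
                    marker_ids.append(mid)
    gio.write_cross_table_rows(cross_rows, cross_path)

    indiv_rows = []
    for spec, progeny in families:
        for p in progeny:
            row = {
                "individual": p.individual_id,
                "family": p.family_id,
                "sex": p.phenotype.value,
            }
            for mid in marker_ids:
                row[mid] = p.marker_calls.get(mid, ".")
            indiv_rows.append(row)
    gio.write_marker_matrix_rows(indiv_rows, marker_ids, marker_path)
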