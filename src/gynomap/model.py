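"""Three-locus epistatic model of sex determination in gynodioecious strawberry.

The model combines a maternally inherited cytoplasmic male sterility (CMS)
factor with three unlinked nuclear loci:

* ``LG4`` (*MS/mf*) — a dominant male-sterility ("inhibitor") locus. A single
  *MS* copy blocks the LG6 restorer, so *MS_* plants on a CMS cytoplasm are
  female. *MS* is both dominant to *mf* and epistatically dominant to *R*.
* ``LG6`` (*R/r*) — a restorer-of-fertility locus. One dominant *R* copy
  restores pollen function; *rr* plants on a CMS cytoplasm are female.
* ``LGx`` (*T/t*) — a third locus at which homozygosity for the recessive *t*
  also disrupts pollen production (its mechanism is left open; an alternative
  phenotype rule treating it as a restorer of a second CMS is pluggable).

A plant is FEMALE iff its cytoplasm carries CMS and it carries at least one
*MS*, or is *rr*, or is *tt*; otherwise it is a HERMAPHRODITE.  Without a
sterilizing cytoplasm every nuclear genotype phenotypes as hermaphrodite.

All gamete / progeny / sex-ratio distributions are exact rationals
(:class:`fractions.Fraction`), so the printed expected ratios (1:3, 1:1, 0:1,
7:9, 2:1) are reproduced bit-exactly.  Floats only appear downstream, in the
statistics.
"""

from __future__ import annotations

from collections.abc import Callable, Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from itertools import product

__all__ = [
    "Locus",
    "Cytotype",
    "SexPhenotype",
    "MultilocusGenotype",
    "ViabilityRule",
    "RatioHypothesis",
    "ModelError",
    "UnknownAlleleError",
    "LG4",
    "LG6",
    "LGX",
    "MODEL_LOCI",
    "MITOTYPES",
    "RR_SEMILETHAL",
    "cms_restorer_phenotype",
    "second_cms_phenotype",
    "phenotype_of",
    "gamete_distribution",
    "progeny_distribution",
    "expected_ratio",
    "ratio_hypothesis",
]


class ModelError(ValueError):
    """Raised for genotype/model inconsistencies."""


class UnknownAlleleError(ModelError):
    """An allele symbol does not belong to the named locus."""

    def __init__(self, locus_name: str, symbol: str):
        self.locus_name = locus_name
        self.symbol = symbol
        super().__init__(f"unknown allele {symbol!r} for locus {locus_name!r}")


@dataclass(frozen=True)
class Locus:
    """A biallelic nuclear locus; ``alleles`` lists the dominant symbol first."""

    name: str
    alleles: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.alleles) != 2 or self.alleles[0] == self.alleles[1]:
            raise ModelError(
                f"locus {self.name!r} needs exactly two distinct allele symbols"
            )

    @property
    def dominant(self) -> str:
        return self.alleles[0]

    @property
    def recessive(self) -> str:
        return self.alleles[1]

    def parse_diploid(self, text: str) -> tuple[str, str]:
        """Parse a diploid genotype string such as ``"MSmf"`` or ``"Rr"``.

        The pair is returned in dominance order (dominant allele first).
        """
        for a, b in product(self.alleles, repeat=2):
            if a + b == text:
                return self.order((a, b))
        raise UnknownAlleleError(self.name, text)

    def order(self, pair: Iterable[str]) -> tuple[str, str]:
        """Normalize an unordered allele pair to dominance order."""
        pair = tuple(pair)
        for allele in pair:
            if allele not in self.alleles:
                raise UnknownAlleleError(self.name, allele)
        return tuple(sorted(pair, key=self.alleles.index))  # type: ignore[return-value]


LG4 = Locus("LG4", ("MS", "mf"))
LG6 = Locus("LG6", ("R", "r"))
LGX = Locus("LGx", ("T", "t"))

#: The loci of the default model, in canonical order.
MODEL_LOCI: tuple[Locus, ...] = (LG4, LG6, LGX)


@dataclass(frozen=True)
class Cytotype:
    """A maternally inherited mitotype; ``cms_present`` marks a sterilizing
    cytoplasm."""

    label: str
    cms_present: bool = True

    def __post_init__(self) -> None:
        if not self.label:
            raise ModelError("cytotype label must be non-empty")


#: Mitotypes observed in the two study populations.  All three carry the
#: CMS-like mitochondrial factor in the default model.
MITOTYPES: dict[str, Cytotype] = {
    "B": Cytotype("B", True),
    "C": Cytotype("C", True),
    "F": Cytotype("F", True),
}


class SexPhenotype(Enum):
    FEMALE = "F"
    HERMAPHRODITE = "H"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class MultilocusGenotype:
    """Diploid genotype at every model locus plus the (maternal) cytotype.

    ``alleles`` is aligned with ``loci``; each pair is stored in dominance
    order so equal genotypes hash equally regardless of input order.
    """

    loci: tuple[Locus, ...]
    alleles: tuple[tuple[str, str], ...]
    cytotype: Cytotype

    def __post_init__(self) -> None:
        if len(self.loci) != len(self.alleles):
            raise ModelError("one allele pair required per locus")
        ordered = tuple(
            locus.order(pair) for locus, pair in zip(self.loci, self.alleles)
        )
        object.__setattr__(self, "alleles", ordered)

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_symbols(
        cls,
        *diploids: str,
        cytotype: Cytotype,
        loci: Sequence[Locus] = MODEL_LOCI,
    ) -> "MultilocusGenotype":
        """Build from diploid strings in locus order, e.g.
        ``from_symbols("mfmf", "Rr", "TT", cytotype=MITOTYPES["F"])``."""
        if len(diploids) != len(loci):
            raise ModelError(
                f"expected {len(loci)} diploid genotypes, got {len(diploids)}"
            )
        alleles = tuple(
            locus.parse_diploid(text) for locus, text in zip(loci, diploids)
        )
        return cls(tuple(loci), alleles, cytotype)

    # -- accessors ------------------------------------------------------
    def _index(self, locus: str | Locus) -> int:
        name = locus.name if isinstance(locus, Locus) else locus
        for i, loc in enumerate(self.loci):
            if loc.name == name:
                return i
        raise ModelError(f"locus {name!r} not present in genotype")

    def pair(self, locus: str | Locus) -> tuple[str, str]:
        return self.alleles[self._index(locus)]

    def has_allele(self, locus: str | Locus, allele: str) -> bool:
        return allele in self.pair(locus)

    def is_homozygous(self, locus: str | Locus, allele: str) -> bool:
        return self.pair(locus) == (allele, allele)

    def is_heterozygous(self, locus: str | Locus) -> bool:
        a, b = self.pair(locus)
        return a != b

    @property
    def n_heterozygous(self) -> int:
        return sum(a != b for a, b in self.alleles)

    def diploid(self, locus: str | Locus) -> str:
        return "".join(self.pair(locus))

    def label(self) -> str:
        return " ".join("".join(pair) for pair in self.alleles)

    def __str__(self) -> str:
        return f"{self.label()} [{self.cytotype.label}]"


# ---------------------------------------------------------------------------
# Phenotype rules
# ---------------------------------------------------------------------------

PhenotypeRule = Callable[[MultilocusGenotype], SexPhenotype]


def cms_restorer_phenotype(g: MultilocusGenotype) -> SexPhenotype:
    """Default rule: FEMALE iff CMS and (carries *MS*, or *rr*, or *tt*)."""
    if not g.cytotype.cms_present:
        return SexPhenotype.HERMAPHRODITE
    if (
        g.has_allele(LG4, "MS")
        or g.is_homozygous(LG6, "r")
        or g.is_homozygous(LGX, "t")
    ):
        return SexPhenotype.FEMALE
    return SexPhenotype.HERMAPHRODITE


def second_cms_phenotype(second_cms_labels: Iterable[str]) -> PhenotypeRule:
    """Alternative rule: LGx restores a *second* CMS rather than acting as an
    independent recessive sterility locus.

    *tt* then sterilizes only on cytoplasms in ``second_cms_labels``; the
    *MS*/*rr* paths still require the primary CMS.
    """
    labels = frozenset(second_cms_labels)

    def rule(g: MultilocusGenotype) -> SexPhenotype:
        primary = g.cytotype.cms_present and (
            g.has_allele(LG4, "MS") or g.is_homozygous(LG6, "r")
        )
        secondary = g.cytotype.label in labels and g.is_homozygous(LGX, "t")
        return SexPhenotype.FEMALE if (primary or secondary) else SexPhenotype.HERMAPHRODITE

    return rule


def phenotype_of(
    g: MultilocusGenotype, rule: PhenotypeRule = cms_restorer_phenotype
) -> SexPhenotype:
    """Sex phenotype of a multilocus genotype under a phenotype rule."""
    return rule(g)


# ---------------------------------------------------------------------------
# Viability selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ViabilityRule:
    """Genotype-dependent survival, applied before phenotyping.

    ``genotype_classes`` maps locus name to a diploid genotype string; the
    rule matches a progeny genotype only if *every* listed locus matches
    (conjunctive).  Unmatched progeny survive with probability 1.
    """

    genotype_classes: tuple[tuple[str, str], ...]
    survival: Fraction
    name: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.survival <= 1:
            raise ModelError("survival must lie in [0, 1]")

    @classmethod
    def make(
        cls,
        classes: Mapping[str, str],
        survival: Fraction | int | str,
        name: str = "",
    ) -> "ViabilityRule":
        return cls(tuple(sorted(classes.items())), Fraction(survival), name)

    def matches(self, g: MultilocusGenotype) -> bool:
        for locus_name, diploid in self.genotype_classes:
            locus = g.loci[g._index(locus_name)]
            if g.pair(locus_name) != locus.parse_diploid(diploid):
                return False
        return True


#: Named preset: half of the *Rr* progeny class dies (i.e. 25% of the
#: offspring of an rr × Rr cross), turning an expected 1:1 into 2:1.
RR_SEMILETHAL = ViabilityRule.make({"LG6": "Rr"}, Fraction(1, 2), name="half-of-Rr-die")


def _survival(g: MultilocusGenotype, rules: Sequence[ViabilityRule]) -> Fraction:
    s = Fraction(1)
    for rule in rules:
        if rule.matches(g):
            s *= rule.survival
    return s


# ---------------------------------------------------------------------------
# Exact distributions
# ---------------------------------------------------------------------------


def gamete_distribution(
    g: MultilocusGenotype,
) -> dict[tuple[str, ...], Fraction]:
    """Exact haploid gamete distribution under independent assortment.

    Keys are allele tuples aligned with ``g.loci``; probabilities sum to 1
    exactly.  (Gametes for markers *linked* to a model locus are produced by
    the cross simulator, not here.)
    """
    per_locus: list[dict[str, Fraction]] = []
    for pair in g.alleles:
        if pair[0] == pair[1]:
            per_locus.append({pair[0]: Fraction(1)})
        else:
            per_locus.append({pair[0]: Fraction(1, 2), pair[1]: Fraction(1, 2)})
    dist: dict[tuple[str, ...], Fraction] = {}
    for combo in product(*(d.items() for d in per_locus)):
        alleles = tuple(a for a, _ in combo)
        p = Fraction(1)
        for _, q in combo:
            p *= q
        dist[alleles] = dist.get(alleles, Fraction(0)) + p
    return dist


def _check_compatible(dam: MultilocusGenotype, sire: MultilocusGenotype) -> None:
    if tuple(l.name for l in dam.loci) != tuple(l.name for l in sire.loci):
        raise ModelError("dam and sire must share the same loci")


def progeny_distribution(
    dam: MultilocusGenotype,
    sire: MultilocusGenotype,
    rules: Sequence[ViabilityRule] = (),
    rule: PhenotypeRule = cms_restorer_phenotype,
) -> dict[tuple[MultilocusGenotype, SexPhenotype], Fraction]:
    """Exact distribution over surviving progeny (genotype, phenotype).

    The cytoplasm is inherited from the dam only.  Viability rules multiply
    the genotype probabilities before renormalization; if no progeny class
    survives a :class:`ModelError` is raised.
    """
    _check_compatible(dam, sire)
    dist: dict[MultilocusGenotype, Fraction] = {}
    for egg, p_egg in gamete_distribution(dam).items():
        for pollen, p_pollen in gamete_distribution(sire).items():
            child = MultilocusGenotype(
                dam.loci, tuple(zip(egg, pollen)), dam.cytotype
            )
            dist[child] = dist.get(child, Fraction(0)) + p_egg * p_pollen
    weighted = {g: p * _survival(g, rules) for g, p in dist.items()}
    total = sum(weighted.values())
    if total == 0:
        raise ModelError("no viable progeny class")
    return {
        (g, phenotype_of(g, rule)): p / total
        for g, p in weighted.items()
        if p > 0
    }


@dataclass(frozen=True)
class RatioHypothesis:
    """A candidate female:hermaphrodite ratio.

    ``label`` follows the female:hermaphrodite convention of the cross tables
    (so a female fraction of 7/16 is labelled ``7:9``).  ``provenance``
    optionally records the parental genotype pair that generated it.
    """

    label: str
    female_fraction: Fraction
    provenance: tuple[MultilocusGenotype, MultilocusGenotype] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.female_fraction <= 1:
            raise ModelError("female fraction must lie in [0, 1]")

    @property
    def ratio(self) -> tuple[int, int]:
        f = self.female_fraction
        return (f.numerator, f.denominator - f.numerator)

    @property
    def n_heterozygous_parents(self) -> int | None:
        if self.provenance is None:
            return None
        return sum(g.n_heterozygous for g in self.provenance)


def ratio_hypothesis(label: str) -> RatioHypothesis:
    """Parse a female:hermaphrodite ratio label such as ``"1:3"``."""
    f_part, h_part = (int(x) for x in label.split(":"))
    if f_part < 0 or h_part < 0 or f_part + h_part == 0:
        raise ModelError(f"invalid ratio label {label!r}")
    return RatioHypothesis(label, Fraction(f_part, f_part + h_part))


def expected_ratio(
    dam: MultilocusGenotype,
    sire: MultilocusGenotype,
    rules: Sequence[ViabilityRule] = (),
    rule: PhenotypeRule = cms_restorer_phenotype,
) -> RatioHypothesis:
    """Exact expected female:hermaphrodite ratio for a cross, as a reduced
    integer pair plus the female fraction."""
    dist = progeny_distribution(dam, sire, rules, rule)
    f = sum(
        (p for (_, sex), p in dist.items() if sex is SexPhenotype.FEMALE),
        Fraction(0),
    )
    num, den = f.numerator, f.denominator
    return RatioHypothesis(f"{num}:{den - num}", f, provenance=(dam, sire))
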