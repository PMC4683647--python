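"""Bundled study tables and deterministic synthetic fixtures.

``load_cross_table`` / ``load_parent_panel`` / ``load_published_genotypes``
return the printed crossing results (71 families, with transcription flags),
the 12-parent panel, and the published parental genotype assignments.

``mapping_family_matrix`` is a *synthetic* reconstruction of the 41-progeny
selfed mapping family's LG6 marker data: the printed summary of that family
fixes the sex counts (8 females, 33 hermaphrodites), the perfect-match
marker span, and which flanking markers mismatch in how many individuals;
individual-level calls are reconstructed to honor exactly those summaries
under a selfed-F2 coupling model.  ``synthetic_ppr_annotation`` likewise
generates a genome annotation whose PPR class reproduces the printed density
facts (653 genes at mean 2.9/Mb; 15/12/10 in the nested sterility-region
spans; a single denser cluster elsewhere).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .containers import (
    CrossRecord,
    CrossTable,
    Marker,
    MarkerGenotypeMatrix,
    ParentPanel,
)
from .model import SexPhenotype
from .windows import GeneRecord

__all__ = [
    "load_cross_table",
    "load_cross_frame",
    "load_parent_panel",
    "load_published_genotypes",
    "mapping_family_matrix",
    "synthetic_ppr_annotation",
    "write_synthetic_ppr_gff3",
    "SYNTHETIC_ASSEMBLY",
    "STERILITY_INTERVAL",
]

#: Bounds of the male-sterility candidate interval on Fvb6 (the nearest
#: mismatching markers) used by the synthetic fixtures.
STERILITY_INTERVAL = ("Fvb6", 34_839_229, 36_607_138)


def _data_path(name: str):
    return resources.files("gynomap.data").joinpath(name)


def load_cross_frame() -> pd.DataFrame:
    """The full curated crossing-results fixture, flags and all."""
    with resources.as_file(_data_path("crosses_table1.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)


def load_cross_table() -> CrossTable:
    """The 71-family cross table as a :class:`CrossTable`."""
    from . import io as gio

    with resources.as_file(_data_path("crosses_table1.tsv")) as p:
        return gio.read_cross_table(p)


def load_parent_panel() -> ParentPanel:
    from . import io as gio

    with resources.as_file(_data_path("parents.tsv")) as p:
        return gio.read_parent_panel(p)


def load_published_genotypes() -> dict[str, tuple[str, str, str]]:
    """Published parental genotype assignments (LG4, LG6, LGx diploids)."""
    with resources.as_file(_data_path("published_genotypes.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    return {
        row["id"]: (row["LG4"], row["LG6"], row["LGx"])
        for _, row in df.iterrows()
    }


# ---------------------------------------------------------------------------
# Synthetic mapping family (selfed F2, 41 progeny)
# ---------------------------------------------------------------------------

# ten markers spanning the perfect-match run (first/last anchor the span)
_PERFECT_POSITIONS = (
    34_958_975,
    35_042_000,
    35_142_280,
    35_142_453,
    35_250_000,
    35_400_000,
    35_560_000,
    35_700_000,
    35_880_000,
    36_048_692,
)
_UPSTREAM_POSITIONS = (34_763_259, 34_839_229)  # one female mismatches
_DOWNSTREAM_POSITION = 36_607_138  # one female and two hermaphrodites mismatch


def mapping_family_matrix(
    n_female: int = 8,
    n_herm: int = 33,
    with_missing: bool = True,
) -> MarkerGenotypeMatrix:
    """Synthetic selfed-F2 marker matrix for the LG6 mapping family.

    The coupling allele (riding with the sterility allele *r*) is ``T``; the
    alternate is ``G``.  All females are ``T`` homozygotes and no
    hermaphrodite is, across the ten perfect-run markers; the flanking
    markers carry the recombinant individuals the printed summary describes
    (one female upstream; one female and two hermaphrodites downstream).
    ``with_missing`` drops one hermaphrodite call inside the run, to mirror
    scattered missing data.
    """
    positions = list(_UPSTREAM_POSITIONS) + list(_PERFECT_POSITIONS) + [
        _DOWNSTREAM_POSITION
    ]
    markers = [Marker(f"Fvb6_{p}", "Fvb6", p) for p in sorted(positions)]
    females = [f"F{i + 1:02d}" for i in range(n_female)]
    herms = [f"H{i + 1:02d}" for i in range(n_herm)]
    individuals = females + herms
    # selfed-F2 carrier split: about one third of the dominant class is
    # homozygous for the alternate allele, the rest heterozygous
    n_hom_alt = n_herm // 3
    base_calls = {}
    for ind in females:
        base_calls[ind] = "T"
    for i, ind in enumerate(herms):
        base_calls[ind] = "G" if i < n_hom_alt else "G/T"
    data = {m.id: [base_calls[ind] for ind in individuals] for m in markers}
    frame = pd.DataFrame(data, index=pd.Index(individuals, name="individual"))

    # recombinants at the flanks (mismatching the perfect coupling pattern)
    for pos in _UPSTREAM_POSITIONS:
        frame.loc["F01", f"Fvb6_{pos}"] = "G/T"
    down = f"Fvb6_{_DOWNSTREAM_POSITION}"
    frame.loc["F02", down] = "G/T"
    frame.loc["H01", down] = "T"
    frame.loc["H02", down] = "T"
    if with_missing and n_herm >= 3:
        frame.loc["H03", "Fvb6_35250000"] = "."

    sex = pd.Series(
        [SexPhenotype.FEMALE] * n_female + [SexPhenotype.HERMAPHRODITE] * n_herm,
        index=frame.index,
    )
    return MarkerGenotypeMatrix(
        markers=markers,
        calls=frame,
        sex=sex,
        family="NM-LNF23-self",
        design="selfed-F2",
    )


# ---------------------------------------------------------------------------
# Synthetic genome annotation for the gene-class density scan
# ---------------------------------------------------------------------------

#: Chromosome lengths (bp) chosen so 653 class genes give a genome-wide mean
#: density of 2.9 per Mb.
SYNTHETIC_ASSEMBLY: dict[str, int] = {
    "Fvb1": 23_170_000,
    "Fvb2": 28_000_000,
    "Fvb3": 33_000_000,
    "Fvb4": 33_000_000,
    "Fvb5": 29_000_000,
    "Fvb6": 39_000_000,
    "Fvb7": 40_000_000,
}

_TOTAL_PPR = 653
# featured placements: the sterility-interval cluster on Fvb6 ...
_FVB6_CLUSTER = (
    [35_020_000 + 45_000 * i for i in range(10)]  # 10 in [35.0, 35.5) Mb
    + [35_610_000, 35_890_000]  # +2 in [35.5, 36.0) Mb
    + [34_900_000, 34_960_000, 36_300_000]  # +3 elsewhere in the interval
)
# ... and one denser cluster on Fvb5 (peak window count 13 > 12)
_FVB5_CLUSTER = [14_050_000 + 70_000 * i for i in range(13)]
# background genes avoid these zones so the featured counts stay exact
_EXCLUSION = {
    "Fvb5": (14_000_000, 15_000_000),
    "Fvb6": (34_000_000, 37_000_000),
}


def _background_positions(chrom: str, n: int) -> list[int]:
    length = SYNTHETIC_ASSEMBLY[chrom]
    zone = _EXCLUSION.get(chrom)
    usable = length - (zone[1] - zone[0] if zone else 0)
    out = []
    for i in range(n):
        u = int(usable * (i + 0.5) / n)
        if zone and u >= zone[0]:
            u += zone[1] - zone[0]
        out.append(u + 1)  # 1-based
    return out


def synthetic_ppr_annotation() -> tuple[list[GeneRecord], dict[str, int]]:
    """Deterministic synthetic annotation: 653 PPR genes (plus a sprinkling
    of other-class genes) over a 225.17 Mb toy genome."""
    genes: list[GeneRecord] = []
    counter = 0

    def add(chrom: str, start: int, classes: frozenset[str]) -> None:
        nonlocal counter
        counter += 1
        prefix = "PPR" if "PPR" in classes else "GEN"
        genes.append(
            GeneRecord(
                chromosome=chrom,
                start=start,
                end=start + 2_999,
                strand="+" if counter % 2 else "-",
                gene_id=f"{prefix}{counter:05d}",
                classes=classes,
            )
        )

    ppr = frozenset({"PPR"})
    for pos in _FVB6_CLUSTER:
        add("Fvb6", pos, ppr)
    for pos in _FVB5_CLUSTER:
        add("Fvb5", pos, ppr)
    n_background = _TOTAL_PPR - len(_FVB6_CLUSTER) - len(_FVB5_CLUSTER)
    total_len = sum(SYNTHETIC_ASSEMBLY.values())
    alloc = {
        chrom: int(round(n_background * length / total_len))
        for chrom, length in SYNTHETIC_ASSEMBLY.items()
    }
    # largest-chromosome absorbs rounding drift
    drift = n_background - sum(alloc.values())
    alloc["Fvb7"] += drift
    for chrom, n in alloc.items():
        for pos in _background_positions(chrom, n):
            add(chrom, pos, ppr)
    other = frozenset({"OTHER"})
    for i in range(40):
        chrom = list(SYNTHETIC_ASSEMBLY)[i % 7]
        add(chrom, 1_000_000 + 500_000 * (i // 7) + 37_000, other)
    return genes, dict(SYNTHETIC_ASSEMBLY)


def write_synthetic_ppr_gff3(path, class_key: str = "gene_class") -> None:
    """Write the synthetic annotation as GFF3 (type ``gene``, class labels
    under ``class_key``)."""
    genes, assembly = synthetic_ppr_annotation()
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in assembly.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start)):
            classes = ",".join(sorted(g.classes))
            fh.write(
                f"{g.chromosome}\tgynomap\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id};{class_key}={classes}\n"
            )
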