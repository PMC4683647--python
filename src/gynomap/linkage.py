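"""Single-family mapping of binary male sterility.

Male sterility is coded as a recessive Mendelian locus (sterile *rr*,
fertile *R–*; a dominant coding is available for the inhibitor-locus case).
For a selfed-F2 family and a codominant marker, the two-point LOD against
the trait is

    LOD(r) = Σ_individuals log10[ P(marker class, trait class | r)
                                  / P(marker class, trait class | r = 1/2) ]

with joint class probabilities obtained by squaring the coupling-phase
gamete frequencies {(1−r)/2, (1−r)/2, r/2, r/2} through selfing and
collapsing the trait by dominance.  The phase is resolved by maximizing over
both assignments; individuals missing at a marker are dropped for that
marker only.  For a perfectly cosegregating marker the maximum (at r = 0)
has the closed form n_rr·log10(4) + n_R–·log10(4/3).

The candidate region for the sterility locus is the maximal run of markers
that perfectly match the trait, bounded by the nearest flanking markers with
at least one mismatch; its length is the simple position difference in Mb.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import Marker, MarkerGenotypeMatrix
from .model import ModelError, SexPhenotype

__all__ = [
    "code_trait",
    "joint_class_probabilities",
    "two_point_lod",
    "scan_chromosome",
    "cosegregation_interval",
    "LodResult",
    "LodProfile",
    "CosegInterval",
    "TwoPointLodScan",
    "DEFAULT_LOD_THRESHOLD",
]

DEFAULT_LOD_THRESHOLD = 3.0
DEFAULT_GRID_STEP = 0.005

#: marker classes relative to the coupling allele
_CC, _HET, _OO = 0, 1, 2
#: trait classes
_RECESSIVE, _DOMINANT = 0, 1


def code_trait(
    phenotypes: Sequence[SexPhenotype], model: str = "recessive"
) -> list[str]:
    """Code sex phenotypes as trait genotype classes.

    ``recessive`` (the restorer-locus case): FEMALE → ``rr``, HERMAPHRODITE →
    ``R-`` (dominant class, genotype ambiguous).  ``dominant`` (the
    inhibitor-locus case): FEMALE → ``S-``, HERMAPHRODITE → ``ss``.
    """
    if model == "recessive":
        return [
            "rr" if p is SexPhenotype.FEMALE else "R-" for p in phenotypes
        ]
    if model == "dominant":
        return ["S-" if p is SexPhenotype.FEMALE else "ss" for p in phenotypes]
    raise ModelError(f"unknown trait model {model!r}")


def _trait_class(sex: SexPhenotype, model: str) -> int:
    # which sex is the homozygous-recessive trait class
    if model == "recessive":
        return _RECESSIVE if sex is SexPhenotype.FEMALE else _DOMINANT
    if model == "dominant":
        return _RECESSIVE if sex is SexPhenotype.HERMAPHRODITE else _DOMINANT
    raise ModelError(f"unknown trait model {model!r}")


@lru_cache(maxsize=4096)
def joint_class_probabilities(r: float) -> np.ndarray:
    """P(marker class, trait class | r) for a selfed F2 in coupling phase.

    Rows: marker class (hom-coupling, het, hom-other); columns: trait class
    (homozygous recessive, dominant).  Computed by enumerating the 4×4
    products of the four gamete types; the recessive trait allele rides with
    the coupling marker allele.
    """
    # gametes: (marker allele index, trait allele index); trait 1 = recessive
    gametes = (
        ((0, 1), (1.0 - r) / 2.0),  # coupling marker with recessive allele
        ((1, 0), (1.0 - r) / 2.0),
        ((0, 0), r / 2.0),
        ((1, 1), r / 2.0),
    )
    out = np.zeros((3, 2))
    for (m1, t1), p1 in gametes:
        for (m2, t2), p2 in gametes:
            mclass = m1 + m2  # 0: cc, 1: het, 2: oo
            tclass = _RECESSIVE if (t1 == 1 and t2 == 1) else _DOMINANT
            out[mclass, tclass] += p1 * p2
    return out


@dataclass(frozen=True)
class LodResult:
    marker_id: str
    max_lod: float
    r_hat: float
    n_informative: int
    coupling_allele: str | None
    applied: bool = True


def _classify_calls(
    matrix: MarkerGenotypeMatrix, marker_id: str
) -> tuple[list[tuple[int, SexPhenotype]], list[str]]:
    """(marker-class-index-relative-to-allele0, sex) per informative
    individual, plus the marker's allele list."""
    calls = matrix.genotypes(marker_id)
    alleles = sorted({a for c in calls.dropna() for a in c})
    observations = []
    for ind in calls.index:
        call = calls.loc[ind]
        if call is None:
            continue
        observations.append((call, matrix.sex.loc[ind]))
    return observations, alleles


def two_point_lod(
    matrix: MarkerGenotypeMatrix,
    marker_id: str,
    trait_model: str = "recessive",
    grid: Sequence[float] | None = None,
) -> LodResult:
    """Two-point LOD of one marker against the binary trait (selfed F2).

    Returns the maximum over the recombination-fraction grid and both phase
    assignments.  Monomorphic markers are flagged (``applied=False``).
    """
    if matrix.design != "selfed-F2":
        raise ModelError(
            "two-point LOD is defined for selfed-F2 families; "
            f"matrix design is {matrix.design!r}"
        )
    if grid is None:
        grid = np.arange(0.0, 0.5 + 1e-12, DEFAULT_GRID_STEP)
    observations, alleles = _classify_calls(matrix, marker_id)
    if len(alleles) < 2:
        return LodResult(marker_id, float("nan"), float("nan"), 0, None, applied=False)
    if len(alleles) > 2:
        raise ModelError(
            f"marker {marker_id!r} has {len(alleles)} alleles; the selfed-F2 "
            "model requires a biallelic marker"
        )
    a0, a1 = alleles
    best = (-math.inf, 0.5, a0)
    null = joint_class_probabilities(0.5)
    for coupling in (a0, a1):
        other = a1 if coupling == a0 else a0
        classes = []
        for call, sex in observations:
            if call == frozenset((coupling,)):
                mclass = _CC
            elif call == frozenset((other,)):
                mclass = _OO
            else:
                mclass = _HET
            classes.append((mclass, _trait_class(sex, trait_model)))
        for r in grid:
            probs = joint_class_probabilities(float(r))
            lod = 0.0
            for mclass, tclass in classes:
                p = probs[mclass, tclass]
                if p <= 0.0:
                    lod = -math.inf
                    break
                lod += math.log10(p / null[mclass, tclass])
            if lod > best[0]:
                best = (lod, float(r), coupling)
    return LodResult(marker_id, best[0], best[1], len(observations), best[2])


@dataclass
class LodProfile:
    """Per-marker LOD values for a matrix, plus the significance calls."""

    frame: pd.DataFrame  # marker, chromosome, position, lod, r_hat, n, significant
    threshold: float

    @property
    def significant(self) -> list[str]:
        return list(self.frame.loc[self.frame["significant"], "marker"])

    def peak(self) -> pd.Series:
        applied = self.frame.dropna(subset=["lod"])
        if applied.empty:
            raise ModelError("no marker with a defined LOD")
        return applied.loc[applied["lod"].idxmax()]


def scan_chromosome(
    matrix: MarkerGenotypeMatrix,
    trait_model: str = "recessive",
    grid: Sequence[float] | None = None,
    lod_threshold: float = DEFAULT_LOD_THRESHOLD,
) -> LodProfile:
    """Two-point LOD for every marker; markers above the threshold (the
    study's LOD > 3 rule) are flagged significant."""
    rows = []
    for m in matrix.markers:
        res = two_point_lod(matrix, m.id, trait_model, grid)
        rows.append(
            {
                "marker": m.id,
                "chromosome": m.chromosome,
                "position": m.position,
                "lod": res.max_lod if res.applied else float("nan"),
                "r_hat": res.r_hat,
                "n": res.n_informative,
                "significant": res.applied and res.max_lod > lod_threshold,
            }
        )
    return LodProfile(pd.DataFrame(rows), lod_threshold)


def _mismatch_count(
    matrix: MarkerGenotypeMatrix, marker_id: str, trait_model: str
) -> int | None:
    """Individuals impossible at r = 0 under the best phase; None if the
    marker is monomorphic."""
    observations, alleles = _classify_calls(matrix, marker_id)
    if len(alleles) < 2:
        return None
    counts = []
    for coupling in alleles:
        bad = 0
        for call, sex in observations:
            hom_coupling = call == frozenset((coupling,))
            recessive = _trait_class(sex, trait_model) == _RECESSIVE
            if recessive != hom_coupling:
                bad += 1
        counts.append(bad)
    return min(counts)


@dataclass(frozen=True)
class CosegInterval:
    chromosome: str
    span_start: int  # first perfectly matching marker
    span_end: int  # last perfectly matching marker
    lower_bound: int  # nearest mismatching marker upstream (or chromosome end)
    upper_bound: int  # nearest mismatching marker downstream (or chromosome end)
    length_mb: float
    unbounded_low: bool = False
    unbounded_high: bool = False

    @property
    def unbounded(self) -> bool:
        return self.unbounded_low or self.unbounded_high


def cosegregation_interval(
    matrix: MarkerGenotypeMatrix,
    trait_model: str = "recessive",
    chromosome: str | None = None,
    mismatch_tolerance: int = 0,
    grid: Sequence[float] | None = None,
) -> CosegInterval:
    """Candidate interval: the maximal run of zero-mismatch markers around
    the LOD peak, bounded by the nearest flanking mismatching markers.

    ``mismatch_tolerance`` relaxes the "perfect" definition for noisy data
    (default 0).  Length is the simple bound-position difference in Mb,
    rounded to 3 decimals.
    """
    profile = scan_chromosome(matrix, trait_model, grid)
    if chromosome is None:
        chromosome = str(profile.peak()["chromosome"])
    markers = matrix.markers_on(chromosome)
    if not markers:
        raise ModelError(f"no markers on chromosome {chromosome!r}")
    mismatches = {m.id: _mismatch_count(matrix, m.id, trait_model) for m in markers}
    perfect = [
        m
        for m in markers
        if mismatches[m.id] is not None and mismatches[m.id] <= mismatch_tolerance
    ]
    if not perfect:
        raise ModelError("no candidate interval: no perfectly cosegregating marker")
    chrom_profile = profile.frame[
        (profile.frame["chromosome"] == chromosome)
        & profile.frame["marker"].isin([m.id for m in perfect])
    ].dropna(subset=["lod"])
    peak_id = chrom_profile.loc[chrom_profile["lod"].idxmax(), "marker"]
    peak_idx = next(i for i, m in enumerate(markers) if m.id == peak_id)

    def is_perfect(i: int) -> bool:
        c = mismatches[markers[i].id]
        return c is not None and c <= mismatch_tolerance

    lo = peak_idx
    while lo > 0 and is_perfect(lo - 1):
        lo -= 1
    hi = peak_idx
    while hi < len(markers) - 1 and is_perfect(hi + 1):
        hi += 1
    # flanking mismatching markers (monomorphic markers cannot mismatch and
    # do not bound the interval)
    lower, unbounded_low = markers[0].position, True
    for i in range(lo - 1, -1, -1):
        c = mismatches[markers[i].id]
        if c is not None and c > mismatch_tolerance:
            lower, unbounded_low = markers[i].position, False
            break
    upper, unbounded_high = markers[-1].position, True
    for i in range(hi + 1, len(markers)):
        c = mismatches[markers[i].id]
        if c is not None and c > mismatch_tolerance:
            upper, unbounded_high = markers[i].position, False
            break
    return CosegInterval(
        chromosome=chromosome,
        span_start=markers[lo].position,
        span_end=markers[hi].position,
        lower_bound=lower,
        upper_bound=upper,
        length_mb=round((upper - lower) / 1e6, 3),
        unbounded_low=unbounded_low,
        unbounded_high=unbounded_high,
    )


class TwoPointLodScan(BaseEstimator):
    """Estimator: LOD profile and cosegregation interval for one family.

    After :meth:`fit`, exposes ``lod_profile_`` (a DataFrame), ``peak_``
    (the max-LOD marker row), and ``interval_`` (a :class:`CosegInterval`,
    or None when no marker perfectly cosegregates).
    """

    def __init__(
        self,
        trait_model: str = "recessive",
        grid_step: float = DEFAULT_GRID_STEP,
        lod_threshold: float = DEFAULT_LOD_THRESHOLD,
        mismatch_tolerance: int = 0,
    ):
        self.trait_model = trait_model
        self.grid_step = grid_step
        self.lod_threshold = lod_threshold
        self.mismatch_tolerance = mismatch_tolerance

    def _grid(self) -> np.ndarray:
        return np.arange(0.0, 0.5 + 1e-12, self.grid_step)

    def fit(self, matrix: MarkerGenotypeMatrix, y=None) -> "TwoPointLodScan":
        profile = scan_chromosome(
            matrix, self.trait_model, self._grid(), self.lod_threshold
        )
        self.lod_profile_ = profile.frame
        self.profile_ = profile
        self.peak_ = profile.peak()
        try:
            self.interval_ = cosegregation_interval(
                matrix,
                self.trait_model,
                mismatch_tolerance=self.mismatch_tolerance,
                grid=self._grid(),
            )
        except ModelError:
            self.interval_ = None
        return self
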