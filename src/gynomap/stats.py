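"""Segregation statistics: χ² goodness of fit against ratio hypotheses,
exact tests for degenerate (0:1) hypotheses, Fisher's exact 2×2 marker–sex
association, and best-fit ranking among model-generated ratio hypotheses.

Conventions follow the source study's usage: Pearson χ² without continuity
correction, df = 1 for two-class ratios, families with fewer than 10 sexed
progeny are reported as not applied, and no multiple-testing correction is
applied by default (Bonferroni/Benjamini–Hochberg are available behind a
flag).
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats as sps

from .containers import MarkerGenotypeMatrix
from .model import ModelError, RatioHypothesis, SexPhenotype

__all__ = [
    "ObservedCounts",
    "TestResult",
    "chisq_gof",
    "exact_zero_class_test",
    "fisher_exact_2x2",
    "best_fit_ratio",
    "marker_sex_association",
    "adjust_pvalues",
    "DEFAULT_MIN_FAMILY_SIZE",
]

#: Families below this total are reported without a statistic (the study's
#: "NA" rule for family size < 10).
DEFAULT_MIN_FAMILY_SIZE = 10


@dataclass(frozen=True)
class ObservedCounts:
    n_female: int
    n_herm: int

    def __post_init__(self) -> None:
        if self.n_female < 0 or self.n_herm < 0:
            raise ModelError("counts must be non-negative integers")

    @property
    def total(self) -> int:
        return self.n_female + self.n_herm


@dataclass(frozen=True)
class TestResult:
    """Outcome of a segregation test.

    ``applied`` is False when the family was too small for the test (the
    statistic and p-value are then NaN).  ``anomaly`` flags observations in
    the impossible class of a degenerate hypothesis.
    """

    statistic: float
    df: int
    p_value: float
    applied: bool = True
    hypothesis: RatioHypothesis | None = None
    anomaly: bool = False

    def __post_init__(self) -> None:
        if self.applied and not math.isnan(self.statistic) and self.statistic < 0:
            raise ModelError("statistic must be non-negative")


def _not_applied(hyp: RatioHypothesis | None = None) -> TestResult:
    return TestResult(float("nan"), 1, float("nan"), applied=False, hypothesis=hyp)


def chisq_gof(
    obs: ObservedCounts,
    hyp: RatioHypothesis,
    min_family_size: int = DEFAULT_MIN_FAMILY_SIZE,
    continuity_correction: bool = False,
) -> TestResult:
    """Pearson χ² goodness of fit of observed sex counts against a ratio.

    No continuity correction by default (this reproduces the published
    values); df = 1; hypotheses with a zero class (0:1 or 1:0) must go
    through :func:`exact_zero_class_test`.
    """
    n = obs.total
    if n == 0:
        raise ModelError("cannot test a family with zero sexed progeny")
    f = hyp.female_fraction
    if f == 0 or f == 1:
        raise ModelError(
            "hypothesis has a zero expected class; use exact_zero_class_test"
        )
    if n < min_family_size:
        return _not_applied(hyp)
    expected = np.array([float(n * f), float(n * (1 - f))])
    observed = np.array([obs.n_female, obs.n_herm], dtype=float)
    if continuity_correction:
        stat = float(np.sum((np.abs(observed - expected) - 0.5) ** 2 / expected))
    else:
        stat, _ = sps.chisquare(observed, expected)
        stat = float(stat)
    p = float(sps.chi2.sf(stat, df=1))
    return TestResult(stat, 1, p, hypothesis=hyp)


def exact_zero_class_test(
    obs: ObservedCounts, hyp: RatioHypothesis
) -> TestResult:
    """Exact handling of degenerate hypotheses (female fraction 0 or 1).

    A perfect fit (no observation in the impossible class) yields statistic
    0 and p 1.  Any observation in the zero class rejects the hypothesis
    outright under the exact model (p = 0) and is flagged as an anomaly —
    one anomalous female in an otherwise all-hermaphrodite family is a known
    occurrence in real data; anomaly-tolerant scoring lives in the genotype
    inference engine.
    """
    f = hyp.female_fraction
    if f != 0 and f != 1:
        raise ModelError("exact_zero_class_test requires a 0:1 or 1:0 hypothesis")
    bad = obs.n_female if f == 0 else obs.n_herm
    if bad == 0:
        return TestResult(0.0, 1, 1.0, hypothesis=hyp)
    return TestResult(float("inf"), 1, 0.0, hypothesis=hyp, anomaly=True)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p-value for a 2×2 table.

    Two-sided by the minimum-likelihood method: the sum of hypergeometric
    probabilities of all tables (with the observed margins) no more probable
    than the observed one — stated explicitly because two-sided conventions
    differ.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ModelError("fisher_exact_2x2 needs a 2×2 table of non-negative counts")
    if t.sum() == 0:
        raise ModelError("all-zero table")
    _, p = sps.fisher_exact(t, alternative="two-sided")
    return float(p)


def best_fit_ratio(
    obs: ObservedCounts,
    hypotheses: Sequence[RatioHypothesis],
    min_family_size: int = DEFAULT_MIN_FAMILY_SIZE,
) -> list[TestResult]:
    """Rank ratio hypotheses for one family by goodness of fit.

    Results are sorted by descending p-value; ties are broken by fewer
    heterozygous loci in the hypothesis' provenance (parsimony), then by
    label order.  All results are returned.
    """
    if not hypotheses:
        raise ModelError("at least one hypothesis required")
    results = []
    for hyp in hypotheses:
        if hyp.female_fraction in (0, 1):
            results.append(exact_zero_class_test(obs, hyp))
        else:
            results.append(chisq_gof(obs, hyp, min_family_size=min_family_size))

    def key(res: TestResult):
        p = -1.0 if math.isnan(res.p_value) else res.p_value
        hyp = res.hypothesis
        n_het = hyp.n_heterozygous_parents if hyp is not None else None
        return (-p, n_het if n_het is not None else 99, hyp.label if hyp else "")

    return sorted(results, key=key)


def marker_sex_association(
    matrix: MarkerGenotypeMatrix, marker_id: str
) -> tuple[TestResult, bool]:
    """Fisher's exact test of marker–sex association under recessive-coupling
    coding, plus a perfect-cosegregation flag.

    The 2×2 table is (female, hermaphrodite) × (homozygous for the coupling
    allele, other); the coupling allele is the one whose homozygotes are most
    enriched in females.  Missing calls are dropped.  The flag is True iff no
    non-missing call mismatches the recessive-coupling expectation.
    """
    calls = matrix.genotypes(marker_id)
    sexes = matrix.sex
    keep = calls.notna()
    calls, sexes = calls[keep], sexes[keep]
    alleles = sorted({a for c in calls for a in c})
    if len(alleles) < 2:
        return _not_applied(), False
    for sex_class in (SexPhenotype.FEMALE, SexPhenotype.HERMAPHRODITE):
        if not (sexes == sex_class).any():
            raise ModelError(
                f"no non-missing calls for phenotype class {sex_class.value}"
            )

    def table_for(coupling: str) -> np.ndarray:
        hom = calls.map(lambda c: c == frozenset((coupling,)))
        fem = sexes == SexPhenotype.FEMALE
        return np.array(
            [
                [int((fem & hom).sum()), int((fem & ~hom).sum())],
                [int((~fem & hom).sum()), int((~fem & ~hom).sum())],
            ]
        )

    def score(tab: np.ndarray) -> float:
        fem_hom = tab[0, 0] / max(tab[0].sum(), 1)
        herm_hom = tab[1, 0] / max(tab[1].sum(), 1)
        return fem_hom - herm_hom

    best = max(alleles, key=lambda a: score(table_for(a)))
    tab = table_for(best)
    p = fisher_exact_2x2(tab)
    stat_result = TestResult(float("nan"), 1, p)
    mismatches = tab[0, 1] + tab[1, 0]  # females not hom-coupling + herms hom
    return stat_result, mismatches == 0


def adjust_pvalues(p_values: Sequence[float], method: str = "none") -> list[float]:
    """Optional multiple-testing adjustment ("none", "bonferroni", "bh").

    Off by default, matching the source analyses.
    """
    p = np.asarray(p_values, dtype=float)
    if method == "none":
        return list(p)
    if method == "bonferroni":
        return list(np.minimum(p * len(p), 1.0))
    if method == "bh":
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(ranked, 1.0)
        return list(out)
    raise ModelError(f"unknown adjustment method {method!r}")
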