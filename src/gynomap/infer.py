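"""Joint inference of parental genotypes from a crossing design's progeny
sex ratios.

The published analysis reasons cross by cross ("this self fits 1:3, so the
parent is Rr ..."); here that reasoning is formalized as a single exhaustive
search: every parent gets a phenotype-consistent hypothesis space, the joint
score of an assignment is the sum over families of the binomial log-likelihood
of the observed female/hermaphrodite counts at the model-predicted female
fraction, minus a homozygote-parsimony penalty per heterozygous locus, and a
branch-and-bound search returns the maximizing assignment(s) with ties
surfaced, never broken silently.

The parsimony penalty (``het_penalty``, in nats per heterozygous locus)
encodes the same Occam principle the cross-by-cross reasoning uses:
heterozygosity is invoked only where segregation data demand it.  Setting it
to 0 recovers pure maximum likelihood.

An anomaly tolerance ``anomaly_eps`` (a small per-progeny misclassification
probability) keeps a single unexpected female in an otherwise 0:1 family from
zeroing the likelihood; set it to 0 for strict scoring.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from itertools import product

from sklearn.base import BaseEstimator

from .containers import CrossRecord, CrossTable, ParentPanel, ParentRecord
from .model import (
    LG4,
    LG6,
    LGX,
    MODEL_LOCI,
    ModelError,
    MultilocusGenotype,
    PhenotypeRule,
    RR_SEMILETHAL,
    SexPhenotype,
    ViabilityRule,
    cms_restorer_phenotype,
    expected_ratio,
    phenotype_of,
)
from .stats import ObservedCounts, TestResult, chisq_gof, exact_zero_class_test

__all__ = [
    "CrossScopedViability",
    "MRD93_INTERPOP_LETHAL",
    "GenotypeAssignment",
    "FitReport",
    "ParentalGenotypeInference",
    "enumerate_parent_hypotheses",
    "score_assignment",
    "infer_genotypes",
]


@dataclass(frozen=True)
class CrossScopedViability:
    """A viability rule applied only to crosses matching a scope.

    The study's one observed case — half of the *Rr* progeny dying when
    OR-MRD93 sires an interpopulation cross — ships as the preset
    :data:`MRD93_INTERPOP_LETHAL`.
    """

    rule: ViabilityRule
    sire_ids: frozenset[str] | None = None
    dam_ids: frozenset[str] | None = None
    interpopulation_only: bool = False
    name: str = ""

    def applies(self, cross: CrossRecord, panel: ParentPanel) -> bool:
        if self.sire_ids is not None and cross.sire not in self.sire_ids:
            return False
        if self.dam_ids is not None and cross.dam not in self.dam_ids:
            return False
        if self.interpopulation_only:
            if panel[cross.dam].population == panel[cross.sire].population:
                return False
        return True


MRD93_INTERPOP_LETHAL = CrossScopedViability(
    rule=RR_SEMILETHAL,
    sire_ids=frozenset({"OR-MRD93"}),
    interpopulation_only=True,
    name="half-of-Rr-die (OR-MRD93-sired interpopulation crosses)",
)


# ---------------------------------------------------------------------------
# Hypothesis spaces
# ---------------------------------------------------------------------------

_DIPLOIDS = {
    "LG4": ("mfmf", "MSmf", "MSMS"),
    "LG6": ("RR", "Rr", "rr"),
    "LGx": ("TT", "Tt", "tt"),
}


def enumerate_parent_hypotheses(
    parent: ParentRecord,
    rule: PhenotypeRule = cms_restorer_phenotype,
    include_msms: bool = False,
) -> list[MultilocusGenotype]:
    """Phenotype-consistent genotype hypotheses for one parent.

    A hermaphrodite cannot carry a dominant sterility allele, so its space is
    mfmf × {RR, Rr} × {TT, Tt}.  Females get every genotype that phenotypes
    female; *MSMS* homozygotes are excluded by default (hermaphrodite sires
    are necessarily *mfmf* under the model, so *MS* only transmits maternally
    and is effectively always heterozygous) but representable via
    ``include_msms``.  User constraints intersect the space.
    """
    lg4_space = _DIPLOIDS["LG4"] if include_msms else _DIPLOIDS["LG4"][:2]
    out = []
    for d4, d6, dx in product(lg4_space, _DIPLOIDS["LG6"], _DIPLOIDS["LGx"]):
        g = MultilocusGenotype.from_symbols(
            d4, d6, dx, cytotype=parent.cytotype
        )
        if phenotype_of(g, rule) is not parent.sex:
            continue
        if parent.constraints:
            ok = all(
                g.pair(name) == g.loci[g._index(name)].parse_diploid(want)
                for name, want in parent.constraints.items()
            )
            if not ok:
                continue
        # order: fewest heterozygous loci first (good incumbents early)
        out.append(g)
    out.sort(key=lambda g: (g.n_heterozygous, g.label()))
    if not out:
        raise ModelError(
            f"no genotype hypothesis satisfies the constraints for {parent.id}"
        )
    return out


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def _effective_fraction(p: float, eps: float) -> float:
    return p * (1.0 - eps) + (1.0 - p) * eps


class _Scorer:
    """Caches expected female fractions and per-cross log-likelihood terms."""

    def __init__(
        self,
        crosses: Sequence[CrossRecord],
        panel: ParentPanel,
        presets: Sequence[CrossScopedViability],
        anomaly_eps: float,
        rule: PhenotypeRule,
    ):
        self.crosses = list(crosses)
        self.panel = panel
        self.rule = rule
        self.eps = anomaly_eps
        self.cross_rules: list[tuple[ViabilityRule, ...]] = [
            tuple(p.rule for p in presets if p.applies(c, panel))
            for c in crosses
        ]
        self._frac_cache: dict = {}
        self._ll_cache: dict = {}
        # saturated (maximum-achievable) log-likelihood kernel per cross
        self.saturated = []
        lo, hi = max(anomaly_eps, 1e-12), 1.0 - max(anomaly_eps, 1e-12)
        for c in crosses:
            phat = min(max(c.n_female / c.n_total, lo), hi)
            self.saturated.append(self._kernel(c, phat))

    @staticmethod
    def _kernel(c: CrossRecord, p: float) -> float:
        if p <= 0.0:
            return 0.0 if c.n_female == 0 else -math.inf
        if p >= 1.0:
            return 0.0 if c.n_herm == 0 else -math.inf
        return c.n_female * math.log(p) + c.n_herm * math.log(1.0 - p)

    def fraction(self, i: int, dam: MultilocusGenotype, sire: MultilocusGenotype) -> float:
        key = (dam, sire, self.cross_rules[i])
        frac = self._frac_cache.get(key)
        if frac is None:
            frac = float(
                expected_ratio(dam, sire, self.cross_rules[i], self.rule).female_fraction
            )
            self._frac_cache[key] = frac
        return frac

    def loglik(self, i: int, dam: MultilocusGenotype, sire: MultilocusGenotype) -> float:
        key = (i, dam, sire)
        ll = self._ll_cache.get(key)
        if ll is None:
            p = _effective_fraction(self.fraction(i, dam, sire), self.eps)
            ll = self._kernel(self.crosses[i], p)
            self._ll_cache[key] = ll
        return ll

    def binom_const(self, i: int) -> float:
        c = self.crosses[i]
        return (
            math.lgamma(c.n_total + 1)
            - math.lgamma(c.n_female + 1)
            - math.lgamma(c.n_herm + 1)
        )


@dataclass
class GenotypeAssignment:
    """A joint parental genotype assignment with its fit."""

    genotypes: dict[str, MultilocusGenotype]
    log_likelihood: float  # binomial data log-likelihood (with constants)
    log_posterior: float  # penalized score used for ranking
    per_cross: dict[tuple[str, str, str], TestResult] = field(default_factory=dict)
    viability_preset: str = ""

    def label(self, parent_id: str) -> str:
        return self.genotypes[parent_id].label()


@dataclass
class FitReport:
    """Outcome of :func:`infer_genotypes`.

    ``ties`` lists alternative assignments whose score equals the best (up to
    a numerical tolerance), exhaustively up to ``max_ties`` per connected
    component.  ``undetermined`` lists (parent, locus) coordinates whose
    alternatives leave the data likelihood unchanged — loci with no
    informative segregation in the design.
    """

    best: GenotypeAssignment
    ties: list[dict[str, MultilocusGenotype]]
    undetermined: list[tuple[str, str, tuple[str, ...]]]
    failing_crosses: list[tuple[str, str, str]]
    excluded_crosses: list[tuple[str, str, str]]
    preset_log_likelihoods: dict[str, float]
    n_evaluated: int

    def ml_set(self) -> list[dict[str, MultilocusGenotype]]:
        return [self.best.genotypes] + self.ties


def score_assignment(
    assignment: Mapping[str, MultilocusGenotype],
    crosses: CrossTable | Sequence[CrossRecord],
    panel: ParentPanel,
    presets: Sequence[CrossScopedViability] = (),
    n_min: int = 10,
    anomaly_eps: float = 0.01,
    rule: PhenotypeRule = cms_restorer_phenotype,
) -> tuple[float, dict[tuple[str, str, str], TestResult]]:
    """Joint binomial log-likelihood of an assignment plus per-cross χ²
    diagnostics.  Families with fewer than ``n_min`` sexed progeny are
    excluded from both."""
    records = [c for c in crosses if c.n_total >= n_min]
    scorer = _Scorer(records, panel, presets, anomaly_eps, rule)
    total = 0.0
    diagnostics: dict[tuple[str, str, str], TestResult] = {}
    for i, c in enumerate(records):
        dam_g, sire_g = assignment[c.dam], assignment[c.sire]
        total += scorer.loglik(i, dam_g, sire_g) + scorer.binom_const(i)
        ratio = expected_ratio(dam_g, sire_g, scorer.cross_rules[i], rule)
        obs = ObservedCounts(c.n_female, c.n_herm)
        if ratio.female_fraction in (0, 1):
            diagnostics[(c.cross_type, c.dam, c.sire)] = exact_zero_class_test(obs, ratio)
        else:
            diagnostics[(c.cross_type, c.dam, c.sire)] = chisq_gof(
                obs, ratio, min_family_size=n_min
            )
    return total, diagnostics


# ---------------------------------------------------------------------------
# Branch-and-bound search
# ---------------------------------------------------------------------------


def _connected_components(
    parent_ids: Sequence[str], crosses: Sequence[CrossRecord]
) -> list[list[str]]:
    parent_ids = list(parent_ids)
    index = {p: i for i, p in enumerate(parent_ids)}
    root = list(range(len(parent_ids)))

    def find(i: int) -> int:
        while root[i] != i:
            root[i] = root[root[i]]
            i = root[i]
        return i

    for c in crosses:
        a, b = find(index[c.dam]), find(index[c.sire])
        if a != b:
            root[a] = b
    groups: dict[int, list[str]] = {}
    for p, i in index.items():
        groups.setdefault(find(i), []).append(p)
    return list(groups.values())


class _ComponentSearch:
    def __init__(
        self,
        parents: Sequence[str],
        hypotheses: Mapping[str, Sequence[MultilocusGenotype]],
        crosses: Sequence[CrossRecord],
        scorer: _Scorer,
        het_penalty: float,
        tie_tol: float,
        max_ties: int,
    ):
        # Order parents so well-connected ones (many distinct partners, e.g.
        # hermaphrodites serving as sires across the design) are placed
        # first; leaf-like parents then close all their crosses at once and
        # can be collapsed to their conditional argmax set.
        partners: dict[str, set[str]] = {p: set() for p in parents}
        weight = {p: 0 for p in parents}
        for c in crosses:
            partners[c.dam].add(c.sire)
            partners[c.sire].add(c.dam)
            weight[c.dam] += c.n_total
            weight[c.sire] += c.n_total
        self.order: list[str] = sorted(
            parents, key=lambda p: (-len(partners[p]), -weight[p], p)
        )
        self.partners = partners
        self.hyp = {p: list(hypotheses[p]) for p in parents}
        self.scorer = scorer
        self.lam = het_penalty
        self.tie_tol = tie_tol
        self.max_ties = max_ties
        # crosses closed when the k-th parent is placed
        placed: set[str] = set()
        self.closing: list[list[int]] = []
        for p in self.order:
            placed.add(p)
            self.closing.append(
                [
                    i
                    for i, c in enumerate(scorer.crosses)
                    if c.dam in placed
                    and c.sire in placed
                    and (c.dam == p or c.sire == p)
                ]
            )
        # bound after placing k parents = sum of saturated ll of crosses not
        # yet closed at depth k
        closed_at: set[int] = set()
        bounds = []
        for k in range(len(self.order)):
            closed_at.update(self.closing[k])
            open_ll = sum(
                scorer.saturated[i]
                for i in range(len(scorer.crosses))
                if i not in closed_at
            )
            bounds.append(open_ll)
        self.open_bound = bounds  # after placing parent k (0-based)
        self.best = -math.inf
        self.solutions: list[tuple[float, dict[str, MultilocusGenotype]]] = []
        self.n_evaluated = 0

    def run(self) -> None:
        self._dfs(0, 0.0, {})

    def _dfs(self, depth: int, score: float, partial: dict[str, MultilocusGenotype]) -> None:
        if depth == len(self.order):
            self.n_evaluated += 1
            if score > self.best + self.tie_tol:
                self.best = score
                self.solutions = [
                    s for s in self.solutions if s[0] >= self.best - self.tie_tol
                ]
            if score >= self.best - self.tie_tol and len(self.solutions) < self.max_ties:
                self.solutions.append((score, dict(partial)))
            return
        pid = self.order[depth]
        # when every partner is already placed this parent's contribution is
        # separable: only its conditional argmax set can appear in an optimal
        # (or tied) assignment
        separable = all(q in partial or q == pid for q in self.partners[pid])
        deltas = []
        for g in self.hyp[pid]:
            partial[pid] = g
            delta = -self.lam * g.n_heterozygous
            for i in self.closing[depth]:
                c = self.scorer.crosses[i]
                ll = self.scorer.loglik(i, partial[c.dam], partial[c.sire])
                delta += ll
                if ll == -math.inf:
                    delta = -math.inf
                    break
            deltas.append(delta)
        cutoff = max(deltas) - self.tie_tol if separable and deltas else -math.inf
        for g, delta in zip(self.hyp[pid], deltas):
            if delta == -math.inf or delta < cutoff:
                continue
            partial[pid] = g
            new_score = score + delta
            if new_score + self.open_bound[depth] >= self.best - self.tie_tol:
                self._dfs(depth + 1, new_score, partial)
        del partial[pid]


def infer_genotypes(
    panel: ParentPanel,
    crosses: CrossTable | Sequence[CrossRecord],
    presets: Sequence[CrossScopedViability] = (),
    n_min: int = 10,
    alpha: float = 0.05,
    het_penalty: float = 2.5,
    anomaly_eps: float = 0.01,
    rule: PhenotypeRule = cms_restorer_phenotype,
    include_msms: bool = False,
    include_small_families: bool = False,
    max_hypothesis_product: float = 1e12,
    max_ties: int = 64,
    tie_tol: float = 1e-9,
) -> FitReport:
    """Maximum-(penalized-)likelihood parental genotype assignment.

    Connected components of the crossing design are solved independently by
    exhaustive search with branch-and-bound pruning on the running score.
    When viability ``presets`` are supplied the search runs both with and
    without them and reports both best log-likelihoods (model selection for
    the lethality hypothesis); the returned assignment is the with-preset
    fit.
    """
    all_records = list(crosses)
    for c in all_records:
        if c.dam not in panel or c.sire not in panel:
            raise ModelError(
                f"cross {c.dam} × {c.sire} references parents missing from the panel"
            )
    effective_n_min = 1 if include_small_families else n_min
    usable = [c for c in all_records if c.n_total >= effective_n_min]
    excluded = [
        (c.cross_type, c.dam, c.sire)
        for c in all_records
        if c.n_total < effective_n_min
    ]
    hypotheses = {
        p.id: enumerate_parent_hypotheses(p, rule, include_msms=include_msms)
        for p in panel
    }

    def solve(active_presets: Sequence[CrossScopedViability]):
        combined: dict[str, MultilocusGenotype] = {}
        combined_ties: list[list[tuple[dict[str, MultilocusGenotype], float]]] = []
        total_score = 0.0
        n_eval = 0
        for component in _connected_components([p.id for p in panel], usable):
            size = 1.0
            for p in component:
                size *= len(hypotheses[p])
            if size > max_hypothesis_product:
                raise ModelError(
                    f"hypothesis space for component {sorted(component)} has "
                    f"{size:.3g} assignments (cap {max_hypothesis_product:.3g}); "
                    "add genotype constraints to the panel to shrink it"
                )
            comp_crosses = [
                i for i, c in enumerate(usable) if c.dam in component
            ]
            comp_scorer = _Scorer(
                [usable[i] for i in comp_crosses], panel, active_presets, anomaly_eps, rule
            )
            search = _ComponentSearch(
                component,
                hypotheses,
                [usable[i] for i in comp_crosses],
                comp_scorer,
                het_penalty,
                tie_tol,
                max_ties,
            )
            search.run()
            if not search.solutions:
                raise ModelError(
                    f"no assignment with finite likelihood for component "
                    f"{sorted(component)}; consider anomaly_eps > 0"
                )
            best_score, best_assign = max(search.solutions, key=lambda s: s[0])
            combined.update(best_assign)
            total_score += best_score
            n_eval += search.n_evaluated
            combined_ties.append(
                [
                    (assign, s)
                    for s, assign in search.solutions
                    if s >= best_score - tie_tol
                ]
            )
        return combined, total_score, combined_ties, n_eval

    assignment, score, component_ties, n_eval = solve(presets)
    preset_lls: dict[str, float] = {}
    ll_with, diagnostics = score_assignment(
        assignment, usable, panel, presets, effective_n_min, anomaly_eps, rule
    )
    preset_lls["with_preset" if presets else "no_preset"] = ll_with
    if presets:
        assignment_no, _, _, _ = solve(())
        ll_no, _ = score_assignment(
            assignment_no, usable, panel, (), effective_n_min, anomaly_eps, rule
        )
        preset_lls["no_preset"] = ll_no

    # ties: alternative full assignments (cartesian across components, capped)
    ties: list[dict[str, MultilocusGenotype]] = []
    for combo in product(*[[a for a, _ in group] for group in component_ties]):
        merged: dict[str, MultilocusGenotype] = {}
        for part in combo:
            merged.update(part)
        if merged != assignment:
            ties.append(merged)
        if len(ties) >= max_ties:
            break

    # coordinates whose alternatives leave the data likelihood unchanged
    scorer = _Scorer(usable, panel, presets, anomaly_eps, rule)

    def data_ll(assign: Mapping[str, MultilocusGenotype]) -> float:
        return sum(
            scorer.loglik(i, assign[c.dam], assign[c.sire])
            for i, c in enumerate(usable)
        )

    base_ll = data_ll(assignment)
    undetermined: list[tuple[str, str, tuple[str, ...]]] = []
    for p in panel:
        for locus in MODEL_LOCI:
            alts = []
            for g in hypotheses[p.id]:
                if g == assignment[p.id] or g.pair(locus) == assignment[p.id].pair(locus):
                    continue
                others_same = all(
                    g.pair(l) == assignment[p.id].pair(l)
                    for l in MODEL_LOCI
                    if l.name != locus.name
                )
                if not others_same:
                    continue
                trial = dict(assignment)
                trial[p.id] = g
                if abs(data_ll(trial) - base_ll) <= 1e-6:
                    alts.append(g.diploid(locus))
            if alts:
                undetermined.append((p.id, locus.name, tuple(alts)))

    failing = [
        key
        for key, res in diagnostics.items()
        if res.applied and not math.isnan(res.p_value) and res.p_value < alpha
    ]
    best = GenotypeAssignment(
        genotypes=assignment,
        log_likelihood=ll_with,
        log_posterior=score,
        per_cross=diagnostics,
        viability_preset=", ".join(p.name for p in presets),
    )
    return FitReport(
        best=best,
        ties=ties,
        undetermined=undetermined,
        failing_crosses=failing,
        excluded_crosses=excluded,
        preset_log_likelihoods=preset_lls,
        n_evaluated=n_eval,
    )


class ParentalGenotypeInference(BaseEstimator):
    """Scikit-learn-style estimator wrapping :func:`infer_genotypes`.

    Parameters mirror the function; after :meth:`fit` the fitted attributes
    are ``assignment_`` (parent id → genotype), ``report_`` (the full
    :class:`FitReport`), ``log_likelihood_`` and ``log_posterior_``.
    """

    def __init__(
        self,
        presets: Sequence[CrossScopedViability] = (),
        n_min: int = 10,
        alpha: float = 0.05,
        het_penalty: float = 2.5,
        anomaly_eps: float = 0.01,
        include_msms: bool = False,
        include_small_families: bool = False,
        max_hypothesis_product: float = 1e12,
        max_ties: int = 64,
    ):
        self.presets = presets
        self.n_min = n_min
        self.alpha = alpha
        self.het_penalty = het_penalty
        self.anomaly_eps = anomaly_eps
        self.include_msms = include_msms
        self.include_small_families = include_small_families
        self.max_hypothesis_product = max_hypothesis_product
        self.max_ties = max_ties

    def fit(self, crosses: CrossTable, panel: ParentPanel) -> "ParentalGenotypeInference":
        report = infer_genotypes(
            panel,
            crosses,
            presets=self.presets,
            n_min=self.n_min,
            alpha=self.alpha,
            het_penalty=self.het_penalty,
            anomaly_eps=self.anomaly_eps,
            include_msms=self.include_msms,
            include_small_families=self.include_small_families,
            max_hypothesis_product=self.max_hypothesis_product,
            max_ties=self.max_ties,
        )
        self.report_ = report
        self.assignment_ = report.best.genotypes
        self.log_likelihood_ = report.best.log_likelihood
        self.log_posterior_ = report.best.log_posterior
        return self

    def predict(self, crosses: CrossTable | Sequence[CrossRecord]):
        """Predicted female fractions for crosses under the fitted
        assignment."""
        if not hasattr(self, "assignment_"):
            raise ModelError("estimator is not fitted")
        out = []
        for c in crosses:
            ratio = expected_ratio(
                self.assignment_[c.dam], self.assignment_[c.sire], ()
            )
            out.append(float(ratio.female_fraction))
        return out
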