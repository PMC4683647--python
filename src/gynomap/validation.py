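"""Seeded validation studies for the simulator and the inference engine:
type-I-error calibration of the segregation χ² under the model, and
parameter recovery of generating parental genotypes from synthetic diallels.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

from .containers import CrossRecord, CrossTable, ParentPanel, ParentRecord
from .infer import FitReport, infer_genotypes
from .model import (
    MITOTYPES,
    MODEL_LOCI,
    MultilocusGenotype,
    SexPhenotype,
    ratio_hypothesis,
)
from .simulate import (
    NM_LNF_PANEL,
    OR_MRD_PANEL,
    family_rng,
    simulate_family_counts,
    simulate_panel,
)
from .stats import ObservedCounts, chisq_gof

__all__ = [
    "chisq_calibration_study",
    "diallel_recovery_study",
    "assignment_recovered",
    "RecoveryResult",
]


def chisq_calibration_study(
    n_families: int = 500,
    n_progeny: int = 50,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Fraction of simulated *Rr*-self families rejected by the χ² test
    against 1:3 at ``alpha`` — the test's realized type-I error under the
    model (should sit near, and not far above, the nominal level)."""
    parent = MultilocusGenotype.from_symbols(
        "mfmf", "Rr", "TT", cytotype=MITOTYPES["F"]
    )
    hyp = ratio_hypothesis("1:3")
    rejected = 0
    for i in range(n_families):
        rng = family_rng(seed, f"calibration-{i}")
        nf, nh = simulate_family_counts(parent, parent, n_progeny, rng)
        res = chisq_gof(ObservedCounts(nf, nh), hyp)
        if res.applied and res.p_value < alpha:
            rejected += 1
    return rejected / n_families


def assignment_recovered(
    truth: Mapping[str, MultilocusGenotype], report: FitReport
) -> bool:
    """True when the generating assignment is among the reported
    maximum-likelihood set; coordinates flagged undetermined (no informative
    segregation) count as ties."""
    undetermined: dict[tuple[str, str], set[str]] = {}
    for pid, locus_name, alts in report.undetermined:
        undetermined.setdefault((pid, locus_name), set()).update(alts)
    for assignment in report.ml_set():
        ok = True
        for pid, true_g in truth.items():
            for locus in MODEL_LOCI:
                want = true_g.diploid(locus)
                got = assignment[pid].diploid(locus)
                if got == want:
                    continue
                if want in undetermined.get((pid, locus.name), ()):
                    continue
                ok = False
                break
            if not ok:
                break
        if ok:
            return True
    return False


@dataclass
class RecoveryResult:
    n_replicates: int
    n_recovered: int

    @property
    def rate(self) -> float:
        return self.n_recovered / self.n_replicates


def diallel_recovery_study(
    n_replicates: int = 100,
    n_parents: int = 6,
    n_progeny: int = 50,
    seed: int = 0,
    het_penalty: float = 2.5,
) -> RecoveryResult:
    """Recovery of generating genotypes from full synthetic diallels.

    Each replicate draws a panel of hermaphrodite parents (a full diallel
    needs every parent as both dam and sire, which only hermaphrodites can
    serve) from one of the two study populations' allele-frequency presets,
    alternating presets between replicates; simulates all ordered crosses
    including selfs at ``n_progeny`` per family; and checks that the
    generating assignment is in the inferred maximum-likelihood set.
    """
    n_recovered = 0
    for rep in range(n_replicates):
        preset = NM_LNF_PANEL if rep % 2 == 0 else OR_MRD_PANEL
        spec = preset(n_parents, sex_constraint=SexPhenotype.HERMAPHRODITE)
        rep_seed = (seed * 100_003 + rep) % (2**31)
        genotypes = simulate_panel(spec, rep_seed)
        ids = [f"P{i + 1}" for i in range(n_parents)]
        truth = dict(zip(ids, genotypes))
        panel = ParentPanel(
            [
                ParentRecord(
                    id=pid,
                    population=spec.population,
                    sex=SexPhenotype.HERMAPHRODITE,
                    cytotype=truth[pid].cytotype,
                )
                for pid in ids
            ]
        )
        records = []
        for dam in ids:
            for sire in ids:
                rng = family_rng(rep_seed, f"{dam}x{sire}")
                nf, nh = simulate_family_counts(
                    truth[dam], truth[sire], n_progeny, rng
                )
                records.append(
                    CrossRecord(
                        "H-SELF" if dam == sire else "H x H", dam, sire, nf, nh
                    )
                )
        report = infer_genotypes(
            panel, CrossTable(records), het_penalty=het_penalty
        )
        if assignment_recovered(truth, report):
            n_recovered += 1
    return RecoveryResult(n_replicates, n_recovered)
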