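"""Two-point LOD mapping and the perfect-cosegregation interval."""

import math
from itertools import product

import numpy as np
import pandas as pd
import pytest

from gynomap import (
    Marker,
    MarkerGenotypeMatrix,
    ModelError,
    SexPhenotype,
    TwoPointLodScan,
    code_trait,
    cosegregation_interval,
    scan_chromosome,
    two_point_lod,
)
from gynomap.linkage import joint_class_probabilities
from gynomap.simulate import CrossSpec, MarkerMap, simulate_cross
from gynomap.io import write_marker_matrix, read_marker_matrix

from conftest import genotype

F, H = SexPhenotype.FEMALE, SexPhenotype.HERMAPHRODITE


def small_matrix(calls, sexes, positions=None):
    """Build a matrix from {marker_id: [calls]} and a sex list."""
    individuals = [f"I{i:03d}" for i in range(len(sexes))]
    markers = []
    for mid in calls:
        chrom, _, pos = mid.rpartition("_")
        markers.append(Marker(mid, chrom, int(pos)))
    return MarkerGenotypeMatrix(
        markers=markers,
        calls=pd.DataFrame(calls, index=individuals),
        sex=pd.Series(sexes, index=individuals),
    )


class TestTraitCoding:
    def test_recessive_coding(self):
        assert code_trait([F, H, H]) == ["rr", "R-", "R-"]

    def test_all_dominant_class(self):
        assert code_trait([H, H]) == ["R-", "R-"]

    def test_dominant_coding(self):
        assert code_trait([F, H], model="dominant") == ["S-", "ss"]


def _oracle_probs(r):
    """Brute-force 4×4 gamete products, independent of the implementation."""
    gametes = [("c", "r", (1 - r) / 2), ("o", "R", (1 - r) / 2),
               ("c", "R", r / 2), ("o", "r", r / 2)]
    out = {}
    for (m1, t1, p1), (m2, t2, p2) in product(gametes, repeat=2):
        n_c = (m1 == "c") + (m2 == "c")
        mclass = {2: 0, 1: 1, 0: 2}[n_c]
        tclass = 0 if (t1 == "r" and t2 == "r") else 1
        out[(mclass, tclass)] = out.get((mclass, tclass), 0.0) + p1 * p2
    return out


class TestJointProbabilities:
    @pytest.mark.parametrize("r", [0.0, 0.05, 0.123, 0.25, 0.5])
    def test_matches_gamete_enumeration(self, r):
        probs = joint_class_probabilities(r)
        oracle = _oracle_probs(r)
        for (mclass, tclass), p in oracle.items():
            assert probs[mclass, tclass] == pytest.approx(p, abs=1e-12)
        assert probs.sum() == pytest.approx(1.0)


class TestTwoPointLod:
    def test_perfect_cosegregation_closed_form(self):
        calls = {"Fvb6_100": ["T"] * 8 + ["G/T"] * 22 + ["G"] * 11}
        m = small_matrix(calls, [F] * 8 + [H] * 33)
        res = two_point_lod(m, "Fvb6_100")
        closed = 8 * math.log10(4) + 33 * math.log10(4 / 3)
        assert res.max_lod == pytest.approx(closed, abs=1e-9)
        assert res.r_hat == 0.0

    def test_single_informative_individual(self):
        # one recessive homozygote in coupling: log10(4)
        m = small_matrix({"Fvb6_100": ["T", "G"]}, [F, H])
        res = two_point_lod(m, "Fvb6_100")
        assert res.max_lod == pytest.approx(math.log10(4) + math.log10(4 / 3), abs=1e-9)

    def test_lod_at_half_is_zero_for_any_data(self):
        calls = {"Fvb6_100": ["T", "G/T", "G", "T", "G/T", "G", "T", "G", "G/T", "T"]}
        m = small_matrix(calls, [F, H, H, F, H, H, F, H, F, H])
        res = two_point_lod(m, "Fvb6_100", grid=[0.5])
        assert res.max_lod == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_marker_flagged(self):
        m = small_matrix({"Fvb6_100": ["T"] * 6}, [F, H, H, H, F, H])
        res = two_point_lod(m, "Fvb6_100")
        assert not res.applied

    def test_missing_calls_dropped_per_marker(self):
        calls = {"Fvb6_100": ["T"] * 7 + ["."] + ["G/T"] * 22 + ["G"] * 11}
        m = small_matrix(calls, [F] * 8 + [H] * 33)
        res = two_point_lod(m, "Fvb6_100")
        assert res.n_informative == 40
        closed = 7 * math.log10(4) + 33 * math.log10(4 / 3)
        assert res.max_lod == pytest.approx(closed, abs=1e-9)

    def test_recombinants_lower_lod(self):
        base = ["T"] * 8 + ["G/T"] * 22 + ["G"] * 11
        lods = []
        for n_recomb in range(3):
            calls = list(base)
            for i in range(n_recomb):
                calls[i] = "G/T"  # recombinant female
            m = small_matrix({"Fvb6_100": calls}, [F] * 8 + [H] * 33)
            lods.append(two_point_lod(m, "Fvb6_100").max_lod)
        assert lods[0] > lods[1] > lods[2]

    def test_outcross_design_rejected(self):
        m = small_matrix({"Fvb6_100": ["T", "G"]}, [F, H])
        m.design = "outcross"
        with pytest.raises(ModelError, match="selfed-F2"):
            two_point_lod(m, "Fvb6_100")


class TestScan:
    def test_mapping_family_peak_and_significance(self, mapping_matrix):
        profile = scan_chromosome(mapping_matrix)
        peak = profile.peak()
        assert peak["lod"] == pytest.approx(
            8 * math.log10(4) + 33 * math.log10(4 / 3), abs=1e-9
        )
        assert peak["r_hat"] == 0.0
        assert len(profile.significant) == len(mapping_matrix.markers)

    def test_simulated_scan_localizes_trait_locus(self):
        """With markers every 1 Mb, the LOD peak lands within 2 Mb of the
        true locus in nearly every seeded replicate."""
        g = genotype("mfmf", "Rr", "TT")
        positions = [1_000_000 * (i + 1) for i in range(12)]
        markers = tuple(Marker(f"Fvb6_{p}", "Fvb6", p) for p in positions)
        mmap = MarkerMap(
            markers=markers,
            anchored_locus="LG6",
            anchored_position=6_000_000,
            chromosome="Fvb6",
            alleles={m.id: ("G", "T") for m in markers},
            cm_per_mb=3.5,
        )
        phase = {m.id: ("G", "T") for m in markers}
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            spec = CrossSpec(
                family_id=f"scan{rep}",
                dam_id="P",
                sire_id="P",
                dam=g,
                sire=g,
                n=41,
                seed=777,
                dam_phase=phase,
                sire_phase=phase,
            )
            progeny = simulate_cross(spec, mmap)
            calls = {
                m.id: [p.marker_calls[m.id] for p in progeny] for m in markers
            }
            matrix = small_matrix(calls, [p.phenotype for p in progeny])
            peak = scan_chromosome(matrix).peak()
            if abs(peak["position"] - 6_000_000) <= 2_000_000:
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_unlinked_trait_rarely_significant(self):
        g = genotype("mfmf", "Rr", "TT")
        marker = Marker("Fvb1_5000000", "Fvb1", 5_000_000)
        mmap = MarkerMap(
            markers=(marker,),
            anchored_locus="LG6",
            anchored_position=500_000_000,  # effectively unlinked
            chromosome="Fvb1",
            alleles={marker.id: ("A", "C")},
        )
        phase = {marker.id: ("A", "C")}
        sig = 0
        n_rep = 40
        for rep in range(n_rep):
            spec = CrossSpec(
                family_id=f"null{rep}",
                dam_id="P",
                sire_id="P",
                dam=g,
                sire=g,
                n=41,
                seed=31,
                dam_phase=phase,
                sire_phase=phase,
            )
            progeny = simulate_cross(spec, mmap)
            calls = {marker.id: [p.marker_calls[marker.id] for p in progeny]}
            matrix = small_matrix(calls, [p.phenotype for p in progeny])
            res = two_point_lod(matrix, marker.id)
            if res.applied and res.max_lod > 3:
                sig += 1
        assert sig <= 0.05 * n_rep + 1

    def test_single_perfect_marker_profile(self):
        calls = {"Fvb6_100": ["T"] * 8 + ["G/T"] * 22 + ["G"] * 11}
        m = small_matrix(calls, [F] * 8 + [H] * 33)
        profile = scan_chromosome(m)
        assert len(profile.frame) == 1
        assert profile.significant == ["Fvb6_100"]


class TestCosegInterval:
    def test_mapping_family_interval(self, mapping_matrix):
        interval = cosegregation_interval(mapping_matrix)
        assert interval.lower_bound == 34_839_229
        assert interval.upper_bound == 36_607_138
        assert interval.length_mb == 1.768
        assert interval.span_start == 34_958_975
        assert interval.span_end == 36_048_692
        assert not interval.unbounded

    def test_all_perfect_markers_unbounded(self):
        perfect = ["T"] * 4 + ["G/T"] * 5 + ["G"] * 3
        calls = {f"Fvb6_{p}": list(perfect) for p in (100, 2000, 30000)}
        m = small_matrix(calls, [F] * 4 + [H] * 8)
        interval = cosegregation_interval(m)
        assert interval.unbounded_low and interval.unbounded_high
        assert (interval.lower_bound, interval.upper_bound) == (100, 30000)

    def test_near_perfect_markers_excluded_from_span(self):
        """Markers with one or two mismatches just outside the run bound the
        interval instead of extending it."""
        base = ["T"] * 4 + ["G/T"] * 5 + ["G"] * 3
        one_bad = ["G/T"] + base[1:]
        two_bad = ["G/T", "G/T"] + base[2:]
        calls = {
            "Fvb6_1000000": one_bad,
            "Fvb6_2000000": base,
            "Fvb6_3000000": base,
            "Fvb6_4000000": two_bad,
        }
        m = small_matrix(calls, [F] * 4 + [H] * 8)
        interval = cosegregation_interval(m)
        assert (interval.span_start, interval.span_end) == (2_000_000, 3_000_000)
        assert (interval.lower_bound, interval.upper_bound) == (1_000_000, 4_000_000)
        assert interval.length_mb == 3.0
        relaxed = cosegregation_interval(m, mismatch_tolerance=2)
        assert relaxed.unbounded

    def test_no_perfect_marker_errors(self):
        calls = {"Fvb6_100": ["G/T", "G/T", "T", "G"]}
        m = small_matrix(calls, [F, F, H, H])
        with pytest.raises(ModelError, match="no candidate interval"):
            cosegregation_interval(m)


class TestEstimator:
    def test_fit_exposes_profile_interval_and_peak(self, mapping_matrix, tmp_path):
        est = TwoPointLodScan().fit(mapping_matrix)
        assert est.peak_["lod"] > est.lod_threshold
        assert est.interval_.length_mb == 1.768
        assert set(est.lod_profile_.columns) >= {
            "marker",
            "chromosome",
            "position",
            "lod",
            "r_hat",
            "significant",
        }
        # round-trips through the TSV dialect unchanged
        path = tmp_path / "matrix.tsv"
        write_marker_matrix(mapping_matrix, path)
        again = TwoPointLodScan().fit(read_marker_matrix(path))
        pd.testing.assert_frame_equal(est.lod_profile_, again.lod_profile_)
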