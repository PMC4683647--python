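"""Cross simulator: Hardy–Weinberg panels, seeded determinism, segregation
of linked markers, viability distortion, fixture round-trips."""

import math

import numpy as np
import pytest

from gynomap import (
    CrossSpec,
    Marker,
    MarkerMap,
    ModelError,
    NM_LNF_PANEL,
    OR_MRD_PANEL,
    PanelSpec,
    RR_SEMILETHAL,
    SexPhenotype,
    fisher_exact_2x2,
    haldane,
    phenotype_of,
    simulate_cross,
    simulate_panel,
)
from gynomap.io import read_cross_table, read_marker_matrix
from gynomap.simulate import emit_fixture_tables, simulate_family_counts, family_rng

from conftest import genotype


class TestPanels:
    def test_allele_counts_near_preset_frequencies(self):
        spec = NM_LNF_PANEL(300)
        panel = simulate_panel(spec, seed=5)
        r_count = sum(g.pair("LG6").count("r") for g in panel)
        # 600 alleles at freq 0.75 -> binomial 3-sigma band
        assert abs(r_count - 450) < 3 * math.sqrt(600 * 0.75 * 0.25)
        assert all(g.pair("LG4") == ("mf", "mf") for g in panel)

    def test_mitotype_frequencies(self):
        panel = simulate_panel(OR_MRD_PANEL(400), seed=9)
        n_c = sum(g.cytotype.label == "C" for g in panel)
        assert abs(n_c - 360) < 3 * math.sqrt(400 * 0.9 * 0.1)

    def test_no_sterility_alleles_all_hermaphrodite(self):
        spec = PanelSpec(
            population="X",
            allele_freqs={
                "LG4": {"MS": 0.0, "mf": 1.0},
                "LG6": {"R": 1.0, "r": 0.0},
                "LGx": {"T": 1.0, "t": 0.0},
            },
            mitotype_freqs={"F": 1.0},
            n_parents=20,
        )
        panel = simulate_panel(spec, seed=1)
        assert all(phenotype_of(g) is SexPhenotype.HERMAPHRODITE for g in panel)

    def test_unsatisfiable_constraint_errors(self):
        spec = PanelSpec(
            population="X",
            allele_freqs={
                "LG4": {"MS": 0.0, "mf": 1.0},
                "LG6": {"R": 1.0, "r": 0.0},
                "LGx": {"T": 1.0, "t": 0.0},
            },
            mitotype_freqs={"F": 1.0},
            n_parents=1,
            sex_constraint=SexPhenotype.FEMALE,
            max_attempts=200,
        )
        with pytest.raises(ModelError, match="constraint"):
            simulate_panel(spec, seed=1)

    def test_bad_frequencies_rejected(self):
        with pytest.raises(ModelError):
            PanelSpec(
                population="X",
                allele_freqs={
                    "LG4": {"MS": 0.5, "mf": 0.4},
                    "LG6": {"R": 1.0, "r": 0.0},
                    "LGx": {"T": 1.0, "t": 0.0},
                },
                mitotype_freqs={"F": 1.0},
                n_parents=1,
            )


def _map(positions=(34_000_000, 35_142_280, 36_500_000), anchor=35_142_280):
    markers = tuple(Marker(f"Fvb6_{p}", "Fvb6", p) for p in positions)
    return MarkerMap(
        markers=markers,
        anchored_locus="LG6",
        anchored_position=anchor,
        chromosome="Fvb6",
        alleles={m.id: ("G", "T") for m in markers},
    )


def _spec(dam, sire, n, seed=3, **kw):
    return CrossSpec(
        family_id="FAM",
        dam_id="D",
        sire_id="S" if dam is not sire else "D",
        dam=dam,
        sire=sire,
        n=n,
        seed=seed,
        **kw,
    )


class TestCrosses:
    def test_forced_zero_females(self):
        progeny = simulate_cross(
            _spec(genotype("mfmf", "rr", "TT"), genotype("mfmf", "RR", "TT"), 1000)
        )
        assert len(progeny) == 1000
        assert all(p.phenotype is SexPhenotype.HERMAPHRODITE for p in progeny)

    def test_selfed_heterozygote_fraction_within_binomial_error(self):
        g = genotype("mfmf", "Rr", "TT")
        progeny = simulate_cross(_spec(g, g, 10_000))
        frac = np.mean([p.phenotype is SexPhenotype.FEMALE for p in progeny])
        assert abs(frac - 0.25) < 3 * math.sqrt(0.25 * 0.75 / 10_000)

    def test_lethality_preset_gives_two_to_one(self):
        progeny = simulate_cross(
            _spec(
                genotype("mfmf", "rr", "TT"),
                genotype("mfmf", "Rr", "TT"),
                10_000,
                viability=(RR_SEMILETHAL,),
            )
        )
        n = len(progeny)
        assert n < 10_000  # a quarter of conceptions die
        frac = np.mean([p.phenotype is SexPhenotype.FEMALE for p in progeny])
        assert abs(frac - 2 / 3) < 3 * math.sqrt((2 / 3) * (1 / 3) / n)

    def test_empty_family(self):
        assert simulate_cross(_spec(genotype("mfmf", "Rr", "TT"), genotype("mfmf", "Rr", "TT"), 0)) == []

    def test_determinism_and_family_stream_independence(self):
        g = genotype("mfmf", "Rr", "Tt")
        a = simulate_cross(_spec(g, g, 50, seed=42), _map())
        b = simulate_cross(_spec(g, g, 50, seed=42), _map())
        assert a == b
        c = simulate_cross(_spec(g, g, 50, seed=43), _map())
        assert a != c

    def test_progeny_phenotypes_consistent_with_model(self):
        dam = genotype("MSmf", "Rr", "Tt")
        sire = genotype("mfmf", "Rr", "Tt")
        for p in simulate_cross(_spec(dam, sire, 400)):
            assert p.phenotype is phenotype_of(p.genotype)

    def test_dropout_rate(self):
        g = genotype("mfmf", "Rr", "TT")
        progeny = simulate_cross(_spec(g, g, 2000, dropout=0.05), _map())
        calls = [c for p in progeny for c in p.marker_calls.values()]
        missing = sum(c == "." for c in calls)
        rate = missing / len(calls)
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / len(calls))


class TestLinkedMarkers:
    def test_zero_recombination_perfect_cosegregation(self):
        g = genotype("mfmf", "Rr", "TT")
        mmap = _map(positions=(35_142_280,), anchor=35_142_280)
        phase = {"Fvb6_35142280": ("G", "T")}  # T rides with r (hap1)
        progeny = simulate_cross(
            _spec(g, g, 300, dam_phase=phase, sire_phase=phase), mmap
        )
        for p in progeny:
            call = p.marker_calls["Fvb6_35142280"]
            if p.phenotype is SexPhenotype.FEMALE:
                assert call == "T"
            else:
                assert call in ("G", "G/T")

    def test_free_recombination_mostly_nonsignificant(self):
        g = genotype("mfmf", "Rr", "TT")
        # 200 cM away -> recombination fraction ~ 0.5
        mmap = _map(positions=(95_142_280,), anchor=35_142_280)
        phase = {"Fvb6_95142280": ("G", "T")}
        nonsig = 0
        n_fam = 40
        for fam in range(n_fam):
            spec = CrossSpec(
                family_id=f"LD{fam}",
                dam_id="D",
                sire_id="D",
                dam=g,
                sire=g,
                n=40,
                seed=17,
                dam_phase=phase,
                sire_phase=phase,
            )
            progeny = simulate_cross(spec, mmap)
            tab = [[0, 0], [0, 0]]
            for p in progeny:
                row = 0 if p.phenotype is SexPhenotype.FEMALE else 1
                col = 0 if p.marker_calls["Fvb6_95142280"] == "T" else 1
                tab[row][col] += 1
            if sum(map(sum, tab)) and fisher_exact_2x2(tab) >= 0.05:
                nonsig += 1
        assert nonsig >= 0.9 * n_fam

    def test_haldane_limits(self):
        assert haldane(0.0) == 0.0
        assert haldane(1e9) == pytest.approx(0.5)
        assert haldane(10.0) == pytest.approx(0.5 * (1 - math.exp(-0.2)))


class TestFixtureEmission:
    def test_round_trip(self, tmp_path):
        g = genotype("mfmf", "Rr", "TT")
        mmap = _map()
        spec = _spec(g, g, 12, seed=5)
        progeny = simulate_cross(spec, mmap)
        cross_path = tmp_path / "crosses.tsv"
        marker_path = tmp_path / "markers.tsv"
        emit_fixture_tables([(spec, progeny)], cross_path, marker_path)
        table = read_cross_table(cross_path)
        assert len(table) == 1
        nf = sum(p.phenotype is SexPhenotype.FEMALE for p in progeny)
        assert table.records[0].n_female == nf
        assert table.records[0].n_herm == len(progeny) - nf
        matrix = read_marker_matrix(marker_path)
        assert matrix.n_individuals() == len(progeny)
        assert [m.id for m in matrix.markers] == [m.id for m in mmap.markers]
        for p in progeny:
            for mid, call in p.marker_calls.items():
                assert matrix.calls.loc[p.individual_id, mid] == call

    def test_empty_family_list_header_only(self, tmp_path):
        cross_path = tmp_path / "crosses.tsv"
        marker_path = tmp_path / "markers.tsv"
        emit_fixture_tables([], cross_path, marker_path)
        assert len(read_cross_table(cross_path)) == 0

    def test_seeded_rerun_byte_identical(self, tmp_path):
        g = genotype("mfmf", "Rr", "Tt")
        files = []
        for run in ("a", "b"):
            spec = _spec(g, g, 30, seed=99)
            progeny = simulate_cross(spec, _map())
            cp, mp = tmp_path / f"c{run}.tsv", tmp_path / f"m{run}.tsv"
            emit_fixture_tables([(spec, progeny)], cp, mp)
            files.append((cp.read_bytes(), mp.read_bytes()))
        assert files[0] == files[1]


def test_fast_count_path_matches_model_expectation():
    dam, sire = genotype("mfmf", "rr", "TT"), genotype("mfmf", "Rr", "TT")
    rng = family_rng(123, "fast")
    nf, nh = simulate_family_counts(dam, sire, 20_000, rng, (RR_SEMILETHAL,))
    total = nf + nh
    assert abs(total - 15_000) < 3 * math.sqrt(20_000 * 0.75 * 0.25)
    assert abs(nf / total - 2 / 3) < 3 * math.sqrt((2 / 3) * (1 / 3) / total)
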