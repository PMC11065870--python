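"""Residue/adduct mass arithmetic, combinatorial ladders and degeneracies."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glycolattice.glycomass import (
    AdductTable,
    GlycanComposition,
    InsufficientDataError,
    UnknownResidueError,
    composition_mass,
    degeneracy_report,
    enumerate_ladder,
    find_compositions,
    repeat_unit,
    residue_mass,
)

RESIDUE_NAMES = ["Hex", "HexNAc", "Fuc", "Neu5Ac", "branch"]


class TestResidueMass:
    @pytest.mark.parametrize(
        "name, kind, expected, places",
        [
            ("Fuc", "average", 146.14, 2),
            ("Neu5Ac", "average", 291.26, 2),
            ("branch", "average", 365.33, 2),
            ("Neu5Ac", "mono", 291.0954, 4),
        ],
    )
    def test_printed_residue_increments(self, name, kind, expected, places):
        assert residue_mass(name, kind) == pytest.approx(expected, abs=10 ** -places)

    def test_branch_is_exact_sum_of_hexnac_and_hex(self):
        for kind in ("mono", "average"):
            assert residue_mass("branch", kind) == residue_mass(
                "HexNAc", kind
            ) + residue_mass("Hex", kind)

    def test_unknown_residue_raises(self):
        with pytest.raises(UnknownResidueError):
            residue_mass("Xyl", "average")

    def test_kind_must_be_explicit_and_valid(self):
        with pytest.raises(ValueError):
            residue_mass("Fuc", "avg")
        with pytest.raises(TypeError):
            residue_mass("Fuc")  # no default convention


class TestCompositionMass:
    @pytest.mark.parametrize(
        "counts, kind, expected, places",
        [
            ({}, "average", 0.0, 6),
            ({"branch": 1, "Neu5Ac": 1, "Fuc": 1}, "mono", 802.3, 1),
            ({"branch": 2, "Fuc": 1}, "mono", 876.3, 1),
            ({"branch": 2}, "average", 730.67, 2),
            ({"Fuc": 5}, "average", 730.71, 2),
            ({"Fuc": 2}, "average", 292.28, 2),
        ],
    )
    def test_composite_masses(self, counts, kind, expected, places):
        assert composition_mass(counts, kind) == pytest.approx(
            expected, abs=10 ** -places
        )

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            composition_mass({"Fuc": -1}, "average")
        with pytest.raises(ValueError):
            GlycanComposition(Fuc=-2)

    @given(
        counts_a=st.dictionaries(
            st.sampled_from(RESIDUE_NAMES), st.integers(0, 20), max_size=5
        ),
        counts_b=st.dictionaries(
            st.sampled_from(RESIDUE_NAMES), st.integers(0, 20), max_size=5
        ),
    )
    @settings(derandomize=True, max_examples=60)
    def test_additive_over_union(self, counts_a, counts_b):
        a, b = GlycanComposition(counts_a), GlycanComposition(counts_b)
        for kind in ("mono", "average"):
            assert composition_mass(a + b, kind) == pytest.approx(
                composition_mass(a, kind) + composition_mass(b, kind), rel=1e-12
            )

    @given(
        counts=st.dictionaries(
            st.sampled_from(RESIDUE_NAMES), st.integers(0, 20), max_size=5
        ),
        extra=st.sampled_from(RESIDUE_NAMES),
    )
    @settings(derandomize=True, max_examples=60)
    def test_adding_a_residue_strictly_increases_mass(self, counts, extra):
        comp = GlycanComposition(counts)
        bigger = comp + GlycanComposition({extra: 1})
        assert composition_mass(bigger, "average") > composition_mass(comp, "average")


class TestEnumerateLadder:
    def test_small_range_masses(self):
        ladder = enumerate_ladder({"Fuc": 1, "Neu5Ac": 1, "branch": 0}, "average")
        masses = [e.delta_mass for e in ladder]
        assert masses == pytest.approx([0.0, 146.14, 291.26, 437.40], abs=0.005)

    def test_all_zero_ranges_single_entry(self):
        ladder = enumerate_ladder({"Fuc": 0, "branch": 0}, "average")
        assert len(ladder) == 1 and ladder[0].delta_mass == 0.0

    def test_empty_ranges_give_zero_entry_not_error(self):
        assert enumerate_ladder({}, "average")[0].delta_mass == 0.0

    def test_unit_counts_follow_lattice_multiplicities(self):
        ladder = enumerate_ladder({"Fuc": 2, "Neu5Ac": 2, "branch": 2}, "average")
        for entry in ladder:
            c = entry.composition
            assert entry.unit_count == 2 * c["Fuc"] + 4 * c["Neu5Ac"] + 5 * c["branch"]
        masses = [e.delta_mass for e in ladder]
        assert masses == sorted(masses)

    def test_near_degenerate_pair_present(self):
        ladder = enumerate_ladder({"Fuc": 5, "branch": 2}, "average")
        masses = np.array([e.delta_mass for e in ladder])
        pair = np.sort(masses[(masses > 730) & (masses < 731)])
        assert pair == pytest.approx([730.67, 730.71], abs=0.005)


class TestRepeatUnit:
    def test_exactly_periodic_ladder(self):
        mean, sd = repeat_unit(73.0 * np.arange(10), merge_tol=1.5)
        assert mean == pytest.approx(73.0, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_per_unit_spacing_of_each_addition_type(self):
        # one residue of each type divided by its lattice multiplicity
        assert residue_mass("Fuc", "average") / 2 == pytest.approx(73.07, abs=0.005)
        assert residue_mass("Neu5Ac", "average") / 4 == pytest.approx(72.81, abs=0.005)
        assert residue_mass("branch", "average") / 5 == pytest.approx(73.07, abs=0.005)

    def test_full_combinatorial_ladder_reproduces_lattice_unit(self):
        ladder = enumerate_ladder({"Fuc": 6, "Neu5Ac": 16, "branch": 10}, "average")
        mean, sd = repeat_unit(ladder, merge_tol=1.5)
        assert mean == pytest.approx(72.95, abs=0.69)
        assert sd <= 0.69

    def test_too_few_masses_raise(self):
        with pytest.raises(InsufficientDataError):
            repeat_unit([0.0, 73.0])
        with pytest.raises(InsufficientDataError):
            repeat_unit([0.0, 0.5, 1.0], merge_tol=5.0)  # collapses to one mass


def _oracle_compositions(delta, tol, ranges, kind):
    """Independent brute-force enumeration used to check find_compositions."""
    names = sorted(ranges)
    hits = set()
    for counts in itertools.product(*(range(ranges[n] + 1) for n in names)):
        comp = dict(zip(names, counts))
        if abs(composition_mass(comp, kind) - delta) <= tol:
            hits.add(tuple(sorted((k, v) for k, v in comp.items() if v)))
    return hits


class TestFindCompositions:
    def test_sialic_vs_difucosyl_near_degeneracy(self):
        matches = find_compositions(
            291.26, 1.1, {"Fuc": 5, "Neu5Ac": 3, "branch": 3}, "average"
        )
        assert [dict(m.composition) for m in matches] == [{"Neu5Ac": 1}, {"Fuc": 2}]
        assert matches[0].error == pytest.approx(0.0, abs=0.01)
        assert matches[1].error == pytest.approx(1.02, abs=0.01)

    def test_zero_delta_matches_empty_composition_only(self):
        matches = find_compositions(0.0, 0.5, {"Fuc": 3, "branch": 3}, "average")
        assert len(matches) == 1 and matches[0].composition.total_residues == 0

    def test_branch_plus_sialic_combination(self):
        matches = find_compositions(
            657.0, 1.0, {"Fuc": 4, "Neu5Ac": 2, "branch": 2}, "average"
        )
        assert dict(matches[0].composition) == {"Neu5Ac": 1, "branch": 1}
        assert matches[0].error == pytest.approx(-0.41, abs=0.01)

    def test_requires_positive_tolerance(self):
        with pytest.raises(ValueError):
            find_compositions(100.0, 0.0, {"Fuc": 2}, "average")

    @given(
        delta=st.floats(0.0, 2000.0),
        tol=st.floats(0.1, 5.0),
    )
    @settings(derandomize=True, max_examples=40)
    def test_agrees_with_exhaustive_oracle(self, delta, tol):
        ranges = {"Fuc": 4, "Neu5Ac": 4, "branch": 4}
        got = {
            tuple(sorted(m.composition.items()))
            for m in find_compositions(delta, tol, ranges, "average")
        }
        assert got == _oracle_compositions(delta, tol, ranges, "average")

    def test_deterministic_tie_break_order(self):
        matches = find_compositions(
            730.7, 1.0, {"Fuc": 5, "branch": 2}, "average"
        )
        # smaller |error| first: branch2 (730.67, -0.03) then Fuc5 (730.71, +0.01)?
        errors = [abs(m.error) for m in matches]
        assert errors == sorted(errors)


class TestDegeneracyReport:
    def test_branch2_vs_fuc5_group(self):
        ladder = enumerate_ladder({"Fuc": 5, "branch": 2}, "average")
        report = degeneracy_report(ladder, tol=0.1)
        grouped = [
            g for g in report
            if len(g["compositions"]) > 1
            and any(abs(m - 730.67) < 0.1 for m in g["masses"])
        ]
        assert len(grouped) == 1
        members = {str(c) for c in grouped[0]["compositions"]}
        assert members == {"branch2", "Fuc5"}
        assert grouped[0]["pairwise_gaps"][0] == pytest.approx(0.04, abs=0.01)

    def test_zero_tolerance_gives_singletons(self):
        ladder = enumerate_ladder({"Fuc": 3, "Neu5Ac": 2}, "average")
        report = degeneracy_report(ladder, tol=0.0)
        assert all(len(g["compositions"]) == 1 for g in report)

    def test_sialic_difucosyl_group_at_wider_tolerance(self):
        ladder = enumerate_ladder({"Fuc": 2, "Neu5Ac": 1}, "average")
        report = degeneracy_report(ladder, tol=1.1)
        pair = [g for g in report if len(g["compositions"]) == 2]
        assert len(pair) == 1
        assert {str(c) for c in pair[0]["compositions"]} == {"Neu5Ac1", "Fuc2"}


class TestAdductTable:
    def test_builtin_shifts(self, adducts):
        assert adducts.mass("phospho") == pytest.approx(79.98, abs=0.005)
        assert adducts.mass("palmitoyl") == pytest.approx(238.41, abs=0.005)
        assert adducts.mass("PE") == pytest.approx(731.0, abs=0.5)

    def test_csv_round_trip_is_bit_exact(self, adducts, tmp_path):
        path = tmp_path / "adducts.csv"
        adducts.to_csv(path)
        back = AdductTable.from_csv(path)
        assert back.names() == adducts.names()
        for name in adducts.names():
            assert back.mass(name) == adducts.mass(name)  # exact, not approx
            assert back.adduct_class(name) == adducts.adduct_class(name)

    def test_positive_shift_enforced(self):
        from glycolattice.glycomass import AdductEntry

        with pytest.raises(ValueError):
            AdductEntry("bogus", -5.0, "PTM")
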