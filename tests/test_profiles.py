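"""Profiles: normalization, weighted descriptors, composition, set algebra."""

from __future__ import annotations

import numpy as np
import pytest

import massdiv as md
from massdiv.formulas import MolecularFormula, parse_formula
from massdiv.profiles import (
    SampleProfile,
    composition_percentages,
    series_query,
    shared_exclusive,
    weighted_descriptors,
)


def _profile(weights: dict[str, float], sid="S") -> SampleProfile:
    return SampleProfile(sid, {parse_formula(k): v for k, v in weights.items()})


class TestProfile:
    def test_normalization(self):
        p = _profile({"C6H8O6": 3.0, "C7H6O5": 1.0})
        vals = sorted(p.intensities.values())
        assert vals == pytest.approx([0.25, 0.75])
        assert sum(p.intensities.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_formula(self):
        p = _profile({"C6H8O6": 42.0})
        assert list(p.intensities.values()) == [1.0]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            SampleProfile("S", {})

    def test_build_profile_from_assignments(self, small_pipeline):
        p = small_pipeline.profiles[0]
        assert sum(p.intensities.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v > 0 for v in p.intensities.values())


class TestWeightedDescriptors:
    def test_equal_weights_are_arithmetic_means(self):
        # H/C 1 (C6H6O) vs 2 (C6H12O): equal weights average to 1.5
        p = _profile({"C6H6O": 1.0, "C6H12O": 1.0})
        assert weighted_descriptors(p).h_c_w == pytest.approx(1.5)

    def test_single_formula_identity(self):
        p = _profile({"C7H6O5": 1.0})
        d = weighted_descriptors(p)
        assert d.aimod_w == pytest.approx(2.5 / 4.5)
        assert d.dbe_w == pytest.approx(5.0)

    def test_frozen_mixture_value(self):
        # aimod(C7H6O5) = 0.5556, aimod(C18H34O5) = 0 -> 0.8 * 0.5556
        p = _profile({"C7H6O5": 0.8, "C18H34O5": 0.2})
        assert weighted_descriptors(p).aimod_w == pytest.approx(0.8 * 2.5 / 4.5, abs=1e-9)

    def test_bounded_by_extrema(self, small_pipeline):
        from massdiv.formulas import aimod, dbe
        for p in small_pipeline.profiles:
            d = weighted_descriptors(p)
            fs = list(p.intensities)
            for val, fn in ((d.h_c_w, lambda f: f.h / f.c), (d.o_c_w, lambda f: f.o / f.c),
                            (d.dbe_w, dbe), (d.aimod_w, aimod)):
                vals = [fn(f) for f in fs]
                assert min(vals) - 1e-12 <= val <= max(vals) + 1e-12


class TestComposition:
    def test_count_basis(self):
        p = _profile({"C10H20O4": 1, "C12H24O4": 1, "C10H21NO4": 1, "C10H20O4S": 1})
        pc = composition_percentages(p, basis="count")
        assert pc == {"CHO": 50.0, "CHON": 25.0, "CHOS": 25.0}

    def test_intensity_basis(self):
        p = _profile({"C10H20O4": 0.7, "C12H24O4": 0.1, "C10H21NO4": 0.1, "C10H20O4S": 0.1})
        pc = composition_percentages(p, basis="intensity")
        assert pc["CHO"] == pytest.approx(80.0)
        assert pc["CHON"] == pytest.approx(10.0)

    def test_single_class_is_100(self):
        pc = composition_percentages(_profile({"C10H20O4": 1.0}))
        assert pc == {"CHO": 100.0}

    @pytest.mark.parametrize("basis", ["count", "intensity"])
    @pytest.mark.parametrize("grouping", ["heteroatomic", "compound_class"])
    def test_sums_to_100(self, small_pipeline, basis, grouping):
        for p in small_pipeline.profiles:
            pc = composition_percentages(p, basis=basis, grouping=grouping)
            assert sum(pc.values()) == pytest.approx(100.0, abs=1e-6)


class TestSharedExclusive:
    def test_basic_set_algebra(self):
        a = _profile({"C6H8O6": 1, "C7H6O5": 1}, "A")
        b = _profile({"C7H6O5": 1, "C6H6O3": 1}, "B")
        excl, shared = shared_exclusive([a, b])
        assert excl["A"] == {parse_formula("C6H8O6")}
        assert excl["B"] == {parse_formula("C6H6O3")}
        assert shared == {parse_formula("C7H6O5")}

    def test_identical_profiles(self):
        a = _profile({"C6H8O6": 1, "C7H6O5": 1}, "A")
        b = _profile({"C6H8O6": 2, "C7H6O5": 3}, "B")
        excl, shared = shared_exclusive([a, b])
        assert excl["A"] == excl["B"] == set()
        assert shared == a.formulas

    def test_disjoint_profiles(self):
        a = _profile({"C6H8O6": 1}, "A")
        b = _profile({"C6H6O3": 1}, "B")
        excl, shared = shared_exclusive([a, b])
        assert shared == set()
        assert excl["A"] == a.formulas and excl["B"] == b.formulas

    def test_three_way_partition(self):
        a = _profile({"C6H8O6": 1, "C7H6O5": 1, "C8H8O2": 1}, "A")
        b = _profile({"C7H6O5": 1, "C8H8O2": 1}, "B")
        c = _profile({"C7H6O5": 1, "C9H10O2": 1}, "C")
        excl, shared = shared_exclusive([a, b, c])
        assert shared == {parse_formula("C7H6O5")}
        assert excl["A"] == {parse_formula("C6H8O6")}
        assert excl["B"] == set()            # C8H8O2 also in A
        assert excl["C"] == {parse_formula("C9H10O2")}
        # exclusives never overlap other profiles
        for sid, p in (("A", a), ("B", b), ("C", c)):
            assert excl[sid] <= p.formulas

    def test_permutation_invariant(self):
        a = _profile({"C6H8O6": 1, "C7H6O5": 1}, "A")
        b = _profile({"C7H6O5": 1}, "B")
        c = _profile({"C6H6O3": 1, "C7H6O5": 1}, "C")
        r1 = shared_exclusive([a, b, c])
        r2 = shared_exclusive([c, a, b])
        assert r1 == r2

    def test_requires_two(self):
        with pytest.raises(ValueError):
            shared_exclusive([_profile({"C6H8O6": 1})])


class TestSeriesQuery:
    # the shared terpenoid formulas reported across the two algal species
    SHARED = [parse_formula(t) for t in (
        "C10H16O", "C10H16O2", "C10H16O3", "C10H16O4", "C10H16O5", "C10H16N2O2",
        "C15H24O2", "C15H24O3", "C15H24O4", "C15H24O6", "C7H6O5",
    )]

    def test_monoterpene_ladder(self):
        hits = series_query(self.SHARED, 10, 16, (1, 5))
        assert [str(f) for f in hits] == ["C10H16O", "C10H16O2", "C10H16O3",
                                          "C10H16O4", "C10H16O5"]

    def test_nitrogen_variant(self):
        hits = series_query(self.SHARED, 10, 16, (1, 5), extra_elements={"N": 2})
        assert [str(f) for f in hits] == ["C10H16N2O2"]

    def test_sesquiterpenes(self):
        pool = [parse_formula(t) for t in ("C15H24O2", "C15H24O3", "C15H24O4", "C15H24O6")]
        assert series_query(pool, 15, 24, (2, 6)) == pool

    def test_empty_range_errors(self):
        with pytest.raises(ValueError):
            series_query(self.SHARED, 10, 16, (5, 1))
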