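"""CSP combination, thresholding, CHESPA projection, sequence comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from allokit.shifts import (
    ChespaRecord,
    CSPRecord,
    ShiftTable,
    chespa,
    combined_csp,
    count_substitutions,
    csp_threshold,
    select_perturbed,
)
from allokit.simulate import ScenarioSpec, gen_homologue_pair, gen_shift_tables


def table(shifts, unobserved=(), name=""):
    return ShiftTable(dict(shifts), frozenset(unobserved), name)


class TestCombinedCSP:
    def test_identical_tables_give_zero(self):
        t = table({1: (8.1, 119.0), 2: (8.5, 121.5)})
        recs, missing = combined_csp(t, t)
        assert all(r.combined == 0.0 for r in recs)
        assert missing == []

    def test_weighted_arithmetic(self):
        a = table({1: (8.00, 120.00)})
        b = table({1: (8.03, 120.20)})
        recs, _ = combined_csp(a, b, weight=0.2)
        assert recs[0].combined == pytest.approx(0.05, rel=1e-12)

    def test_homogeneity(self):
        a = table({1: (8.0, 120.0)})
        b1 = table({1: (8.02, 120.1)})
        b2 = table({1: (8.04, 120.2)})
        (r1,), _ = combined_csp(a, b1)
        (r2,), _ = combined_csp(a, b2)
        assert r2.combined == pytest.approx(2 * r1.combined, rel=1e-12)

    def test_symmetric_in_table_order(self):
        a = table({1: (8.0, 120.0), 2: (7.9, 118.0)})
        b = table({1: (8.1, 121.0), 2: (7.8, 117.5)})
        ra, _ = combined_csp(a, b)
        rb, _ = combined_csp(b, a)
        assert [r.combined for r in ra] == [r.combined for r in rb]

    def test_missing_residues_reported(self):
        a = table({1: (8.0, 120.0), 2: (7.9, 118.0)})
        b = table({1: (8.1, 121.0), 3: (8.2, 122.0)})
        recs, missing = combined_csp(a, b)
        assert [r.residue_id for r in recs] == [1]
        assert missing == [2, 3]

    def test_disjoint_tables_rejected(self):
        with pytest.raises(ValueError):
            combined_csp(table({1: (8.0, 120.0)}), table({2: (8.0, 120.0)}))


class TestThreshold:
    def test_mean_plus_half_sd(self):
        assert csp_threshold([0.05, 0.10, 0.15]) == pytest.approx(0.125, rel=1e-12)

    def test_equal_values_give_the_value(self):
        assert csp_threshold([0.07, 0.07, 0.07]) == pytest.approx(0.07)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        vals=st.lists(st.floats(0.0, 1.0), min_size=2, max_size=30),
        shift=st.floats(-0.5, 0.5),
    )
    def test_translation_equivariance(self, vals, shift):
        base = csp_threshold(vals)
        moved = csp_threshold([v + shift for v in vals])
        assert moved == pytest.approx(base + shift, abs=1e-9)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            csp_threshold([0.1])


class TestSelectPerturbed:
    def test_empty_input(self):
        assert select_perturbed([], 0.1) == []

    def test_strictly_above_threshold(self):
        recs = [CSPRecord(10, 0, 0, 0.12), CSPRecord(11, 0, 0, 0.05)]
        assert select_perturbed(recs, 0.1) == [10]

    def test_spiked_construct_recovered_exactly(self):
        spec = ScenarioSpec(seed=11)
        tables, truth = gen_shift_tables(spec)
        recs, _ = combined_csp(tables["apo_wt"], tables["mut_spiked"])
        thr = csp_threshold([r.combined for r in recs])
        assert tuple(select_perturbed(recs, thr)) == tuple(sorted(truth["spiked"]))


class TestChespa:
    def test_identical_perturbation(self):
        apo = table({1: (8.0, 120.0)})
        holo = table({1: (8.1, 120.5)})
        recs, _ = chespa(apo, holo, holo)
        assert recs[0].cos_theta == pytest.approx(1.0)
        assert recs[0].fraction_x == pytest.approx(1.0)

    def test_orthogonal_perturbation(self):
        apo = table({1: (8.0, 120.0)})
        holo = table({1: (8.1, 120.0)})      # A = (0.1, 0)
        mut = table({1: (8.0, 120.5)})       # B = (0, 0.1) in weighted space
        recs, _ = chespa(apo, holo, mut)
        assert recs[0].cos_theta == pytest.approx(0.0, abs=1e-12)
        assert recs[0].fraction_x == pytest.approx(0.0, abs=1e-12)

    def test_antiparallel_half_magnitude(self):
        apo = table({1: (8.0, 120.0)})
        holo = table({1: (8.1, 120.0)})      # A = (0.10, 0)
        mut = table({1: (7.95, 120.0)})      # B = (-0.05, 0)
        recs, _ = chespa(apo, holo, mut)
        assert recs[0].cos_theta == pytest.approx(-1.0)
        assert recs[0].fraction_x == pytest.approx(-0.5)

    def test_small_vectors_excluded_not_divided(self):
        apo = table({1: (8.0, 120.0), 2: (8.0, 120.0)})
        holo = table({1: (8.1, 120.0), 2: (8.001, 120.0)})
        mut = table({1: (8.05, 120.0), 2: (8.3, 120.0)})
        recs, excluded = chespa(apo, holo, mut, min_magnitude=0.02)
        assert [r.residue_id for r in recs] == [1]
        assert excluded == [2]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 10.0))
    def test_cosine_invariant_under_positive_rescaling(self, scale):
        apo = table({1: (8.0, 120.0)})
        holo = table({1: (8.08, 120.4)})
        mut = table({1: (8.0 + 0.06 * scale, 120.0 + 0.3 * scale)})
        recs, _ = chespa(apo, holo, mut, min_magnitude=1e-9)
        base, _ = chespa(apo, holo, table({1: (8.06, 120.3)}), min_magnitude=1e-9)
        assert recs[0].cos_theta == pytest.approx(base[0].cos_theta, abs=1e-9)

    def test_sign_flips_under_negation(self):
        apo = table({1: (8.0, 120.0)})
        holo = table({1: (8.1, 120.5)})
        mut_pos = table({1: (8.05, 120.25)})
        mut_neg = table({1: (7.95, 119.75)})
        (rp,), _ = chespa(apo, holo, mut_pos)
        (rn,), _ = chespa(apo, holo, mut_neg)
        assert rn.cos_theta == pytest.approx(-rp.cos_theta)

    def test_generated_parallel_construct(self):
        tables, truth = gen_shift_tables(ScenarioSpec(seed=4))
        recs, _ = chespa(tables["apo_wt"], tables["holo_wt"], tables["mut_parallel"])
        assert recs, "no residues above the magnitude filter"
        assert all(r.cos_theta == pytest.approx(1.0, abs=1e-9) for r in recs)
        assert all(r.fraction_x == pytest.approx(0.5, abs=1e-9) for r in recs)

    def test_generated_negative_residues(self):
        tables, truth = gen_shift_tables(ScenarioSpec(seed=4))
        recs, _ = chespa(
            tables["apo_wt"], tables["holo_wt"], tables["mut_antiparallel"]
        )
        by_res = {r.residue_id: r for r in recs}
        for rid in truth["negative"]:
            if rid in by_res:
                assert by_res[rid].cos_theta == pytest.approx(-1.0, abs=1e-9)


class TestCountSubstitutions:
    def test_identical(self):
        assert count_substitutions("ACDEF", "ACDEF") == (0, 5, 0)

    def test_single_mismatch(self):
        assert count_substitutions("ACDEF", "ACDFF") == (1, 5, 0)

    def test_symmetry(self):
        a, b = "ACDEFGHIKL", "ACDEFGHLKI"
        assert count_substitutions(a, b)[0] == count_substitutions(b, a)[0]

    def test_unequal_lengths_aligned_with_gap(self):
        subs, aligned, gaps = count_substitutions("ACDEFGHIKL", "ACDEGHIKL")
        assert gaps == 1
        assert subs == 0
        assert aligned == 9

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            count_substitutions("", "ACD")

    def test_synthetic_homologue_pair(self):
        """The generated orthologue stand-in differs at exactly the designated
        positions: 16 substitutions over 206 residues, including the
        threonine/serine toggle site."""
        a, b, positions = gen_homologue_pair(ScenarioSpec(seed=0))
        subs, aligned, gaps = count_substitutions(a, b)
        assert (subs, aligned, gaps) == (16, 206, 0)
        assert len(positions) == 16
        assert a[163] == "T" and b[163] == "S"


class TestShiftTable:
    def test_overlap_between_observed_and_unobserved_rejected(self):
        with pytest.raises(ValueError):
            ShiftTable({1: (8.0, 120.0)}, frozenset({1}))

    def test_unobserved_listed_but_not_in_statistics(self):
        tables, _ = gen_shift_tables(ScenarioSpec(seed=2))
        t = tables["apo_wt"]
        assert set(range(167, 176)) <= set(t.unobserved)
        assert not (set(t.unobserved) & set(t.shifts))
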