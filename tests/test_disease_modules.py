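"""Relative risk, chi-square association, and disease-to-module mapping."""

import random

import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from netmod.disease_genes import DiseaseGeneMap
from netmod.disease_modules import (
    disease_to_modules,
    jaccard_between_diseases,
    module_rr,
    score_modules,
    select_disease_modules,
)
from netmod.modules import Module, ModulePartition
from netmod.synthetic import planted_disease_cohort


def stats_for(k, m, S, N, **kw):
    members = {f"G{i}" for i in range(m)}
    seeds = {f"G{i}" for i in range(k)} | {f"X{i}" for i in range(S - k)}
    return module_rr("M", members, seeds, S, N, **kw)


class TestModuleRR:
    def test_worked_example(self):
        """305-protein module with 45 of the 921 mapped seed genes in a
        12,084-protein background has RR 1.94."""
        s = stats_for(45, 305, 921, 12084)
        assert round(s.rr, 2) == 1.94
        assert s.rr == pytest.approx((45 / 305) / (921 / 12084))

    def test_null_table_rr_one_chi2_zero(self):
        s = stats_for(10, 100, 50, 500)  # k/m == S/N == 0.1
        assert s.rr == pytest.approx(1.0)
        assert s.chi2 == pytest.approx(0.0)
        assert s.p_raw == pytest.approx(1.0)

    def test_chi2_matches_direct_formula(self):
        rng = random.Random(0)
        for _ in range(30):
            N = rng.randint(50, 500)
            m = rng.randint(5, N // 2)
            S = rng.randint(5, N // 2)
            k = rng.randint(1, min(m, S))
            s = stats_for(k, m, S, N)
            # independent oracle: sum over cells of (O-E)^2 / E
            table = [[k, m - k], [S - k, N - m - (S - k)]]
            chi2 = 0.0
            for i in range(2):
                for j in range(2):
                    e = sum(table[i]) * (table[0][j] + table[1][j]) / N
                    chi2 += (table[i][j] - e) ** 2 / e
            assert s.chi2 == pytest.approx(chi2)
            assert s.p_raw == pytest.approx(float(sps.chi2.sf(chi2, 1)))

    def test_chi2_agrees_with_scipy_contingency(self):
        s = stats_for(45, 305, 921, 12084)
        table = [[45, 260], [876, 10903]]
        chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
        assert s.chi2 == pytest.approx(float(chi2))
        assert s.p_raw == pytest.approx(float(p))

    def test_yates_correction_shrinks_statistic(self):
        plain = stats_for(10, 40, 50, 400)
        yates = stats_for(10, 40, 50, 400, yates=True)
        assert yates.chi2 < plain.chi2

    @given(st.integers(1, 8))
    @settings(max_examples=8, deadline=None)
    def test_rr_invariant_under_common_scaling(self, factor):
        base = stats_for(6, 30, 40, 300)
        scaled = stats_for(6 * factor, 30 * factor, 40 * factor, 300 * factor)
        assert scaled.rr == pytest.approx(base.rr)

    def test_zero_background_raises(self):
        with pytest.raises(ValueError):
            module_rr("M", {"G1"}, set(), 0, 100)


def make_partition(member_sets):
    modules = tuple(
        Module(f"M{i + 1}", frozenset(ms)) for i, ms in enumerate(member_sets)
    )
    return ModulePartition(modules=modules, source_graph_nodes=sum(len(ms) for ms in member_sets))


class TestSelectDiseaseModules:
    def test_threshold_boundary_excludes_below(self):
        s_lo = stats_for(29, 150, 200, 1500)   # rr 1.45
        s_hi = stats_for(45, 150, 200, 1500)   # rr 2.25
        selected = select_disease_modules([s_lo, s_hi], rr_threshold=2.0)
        assert [x.rr for x in selected] == [s_hi.rr]
        assert select_disease_modules([s_lo], rr_threshold=s_lo.rr) == [s_lo]

    def test_anchor_module_equals_fixed_threshold(self):
        sets = [{f"A{i}" for i in range(20)}, {f"B{i}" for i in range(30)},
                {f"C{i}" for i in range(25)}]
        seeds = {f"A{i}" for i in range(10)} | {f"B{i}" for i in range(6)} | {"C0"}
        p = make_partition(sets)
        stats_list = score_modules(p, seeds)
        anchor = next(s for s in stats_list if s.module_id == "M2")
        by_anchor = select_disease_modules(stats_list, threshold_from_module="M2")
        by_value = select_disease_modules(stats_list, rr_threshold=anchor.rr)
        assert by_anchor == by_value

    def test_missing_anchor_raises(self):
        s = stats_for(5, 20, 50, 400)
        with pytest.raises(ValueError):
            select_disease_modules([s], threshold_from_module="NOPE")

    def test_selection_non_increasing_in_threshold(self):
        rng = random.Random(1)
        stats_list = [stats_for(rng.randint(1, 20), 50, 300, 2000) for _ in range(15)]
        sizes = [len(select_disease_modules(stats_list, rr_threshold=t))
                 for t in (0.5, 1.0, 1.5, 2.0, 3.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_planted_disease_modules_all_recovered(self):
        """10 modules with 5x seed density pass the RR filter, the 40
        background modules do not, in >= 19 of 20 seeded cohorts."""
        successes = 0
        for seed in range(20):
            members, seeds, planted = planted_disease_cohort(
                n_modules=50, module_size=120, n_disease_modules=10,
                density_disease=0.30, density_background=0.06, seed=seed,
            )
            p = make_partition(members)
            stats_list = score_modules(p, seeds)
            selected = {s.module_id for s in
                        select_disease_modules(stats_list, rr_threshold=1.5)}
            expected = {f"M{i + 1}" for i in planted}
            successes += selected == expected
        assert successes >= 19


class TestDiseaseToModules:
    def test_concentrated_disease_maps_to_its_module(self):
        sets = [{f"A{i}" for i in range(10)}, {f"B{i}" for i in range(10)}]
        dmap = DiseaseGeneMap(frozenset(("D1", f"A{i}") for i in range(5)))
        result = disease_to_modules(dmap, make_partition(sets), rr_threshold=1.0)
        assert result.modules_of("D1") == ["M1"]

    def test_uniform_disease_maps_nowhere_above_one(self):
        sets = [{f"A{i}" for i in range(10)}, {f"B{i}" for i in range(10)}]
        pairs = {("D1", f"A{i}") for i in range(5)} | {("D1", f"B{i}") for i in range(5)}
        result = disease_to_modules(DiseaseGeneMap(frozenset(pairs)),
                                    make_partition(sets), rr_threshold=1.0)
        assert result.modules_of("D1") == []

    def test_two_disease_planted_homes_recovered(self):
        rng = random.Random(9)
        sets = [{f"B{b}G{i}" for i in range(40)} for b in range(4)]
        pairs = set()
        for disease, home in (("D1", 0), ("D2", 2)):
            pairs |= {(disease, g) for g in rng.sample(sorted(sets[home]), 15)}
            pairs |= {(disease, g) for g in rng.sample(sorted(sets[(home + 1) % 4]), 2)}
        result = disease_to_modules(DiseaseGeneMap(frozenset(pairs)),
                                    make_partition(sets), rr_threshold=1.5)
        assert result.modules_of("D1") == ["M1"]
        assert result.modules_of("D2") == ["M3"]


class TestJaccard:
    def test_hand_cases(self):
        pairs = (
            {("D1", "A"), ("D1", "B"), ("D1", "C"),
             ("D2", "B"), ("D2", "C"), ("D2", "D"),
             ("D3", "A"), ("D3", "B"), ("D3", "C"),
             ("D4", "X")}
        )
        j = jaccard_between_diseases(DiseaseGeneMap(frozenset(pairs)))
        assert j[("D1", "D2")] == pytest.approx(0.5)   # {B,C} / {A,B,C,D}
        assert j[("D1", "D3")] == pytest.approx(1.0)
        assert j[("D1", "D4")] == pytest.approx(0.0)

    def test_single_disease_raises(self):
        with pytest.raises(ValueError):
            jaccard_between_diseases(DiseaseGeneMap(frozenset({("D1", "A")})))
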