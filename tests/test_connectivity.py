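"""Connectivity mathematics: ES against brute-force oracles, WTCS/NCS/tau
conventions, compound summaries and the dual-threshold prioritization."""

import itertools

import numpy as np
import pandas as pd
import pytest
from conftest import brute_force_es, percentile_oracle, unweighted_ks
from hypothesis import given, settings
from hypothesis import strategies as st

from adipomap.connectivity import (
    attach_tau,
    enrichment_score,
    merge_timepoint_candidates,
    normalize_ncs,
    prioritize,
    rank_signature,
    score_compendium,
    summarize_compounds,
    tau_score,
    wtcs,
)
from adipomap.errors import EmptyOverlapError
from adipomap.synthetic import (
    GeneratorConfig,
    generate_reference_compendium,
    planted_query,
)


def _ranked(values: dict[str, float]) -> pd.Series:
    return rank_signature(pd.Series(values))


class TestEnrichmentScore:
    def test_top_gene_hits_full_deviation(self):
        ranked = _ranked({"g1": 3.0, "g2": 2.0, "g3": 1.0})
        assert enrichment_score(ranked, {"g1"}) == pytest.approx(1.0)

    def test_bottom_gene_gives_negative_unit_deviation(self):
        ranked = _ranked({"g1": 3.0, "g2": 2.0, "g3": 1.0})
        assert enrichment_score(ranked, {"g3"}) == pytest.approx(-1.0)

    def test_matches_brute_force_on_all_six_gene_pairs(self):
        """Exhaustive oracle equivalence: every 2-gene subset of every
        permutation of a 6-gene list."""
        values = [6.0, 5.0, 4.0, 3.0, 2.0, 1.0]
        genes = [f"g{i}" for i in range(6)]
        for perm in itertools.permutations(genes):
            ranked_pairs = list(zip(perm, values))
            ranked = pd.Series(dict(ranked_pairs)).loc[list(perm)]
            for subset in itertools.combinations(genes, 2):
                expected = brute_force_es(ranked_pairs, subset)
                got = enrichment_score(ranked, subset)
                assert got == pytest.approx(expected, abs=1e-12)

    def test_weight_zero_reduces_to_classical_ks(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            genes = [f"g{i}" for i in range(n)]
            values = rng.normal(size=n)
            ranked = rank_signature(pd.Series(values, index=genes))
            size = int(rng.integers(1, n))
            subset = rng.choice(genes, size=size, replace=False)
            expected = unweighted_ks(list(ranked.items()), subset)
            assert enrichment_score(ranked, subset, weight=0.0) == pytest.approx(
                expected, abs=1e-12
            )

    def test_empty_intersection_raises_with_zero_overlap(self):
        ranked = _ranked({"g1": 1.0, "g2": 0.5})
        with pytest.raises(EmptyOverlapError) as err:
            enrichment_score(ranked, {"zz"})
        assert err.value.overlap == 0.0

    def test_full_list_set_is_undefined(self):
        ranked = _ranked({"g1": 1.0, "g2": 0.5})
        with pytest.raises(ValueError, match="entire"):
            enrichment_score(ranked, {"g1", "g2"})

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_es_bounded_in_unit_interval(self, data):
        n = data.draw(st.integers(3, 30))
        values = data.draw(
            st.lists(st.floats(-5, 5, allow_nan=False), min_size=n, max_size=n)
        )
        size = data.draw(st.integers(1, n - 1))
        genes = [f"g{i}" for i in range(n)]
        ranked = rank_signature(pd.Series(values, index=genes))
        subset = genes[:size]
        es = enrichment_score(ranked, subset)
        assert -1.0 <= es <= 1.0


class TestWtcs:
    @pytest.mark.parametrize(
        "up, down, expected",
        [(0.8, -0.6, 0.7), (0.5, 0.3, 0.0), (-0.6, 0.4, -0.5), (0.0, 0.4, 0.0)],
    )
    def test_direct_formula(self, up, down, expected):
        assert wtcs(up, down) == pytest.approx(expected)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        up=st.floats(-1, 1, allow_nan=False), down=st.floats(-1, 1, allow_nan=False)
    )
    def test_swapping_query_sets_negates_wtcs(self, up, down):
        assert wtcs(down, up) == pytest.approx(-wtcs(up, down))


class TestNcs:
    def test_positive_group_normalized_by_mean(self):
        records = pd.DataFrame(
            {"perturbagen": ["a", "b"], "cell_line": ["x", "x"],
             "wtcs": [0.4, 0.8]}
        )
        ncs = normalize_ncs(records)["ncs"]
        assert list(ncs.round(3)) == [0.667, 1.333]

    def test_all_zero_group_stays_zero(self):
        records = pd.DataFrame(
            {"perturbagen": ["a", "b"], "cell_line": ["x", "x"], "wtcs": [0.0, 0.0]}
        )
        assert (normalize_ncs(records)["ncs"] == 0).all()

    def test_lone_negative_value_normalizes_to_minus_one(self):
        records = pd.DataFrame(
            {"perturbagen": ["a"], "cell_line": ["x"], "wtcs": [-0.5]}
        )
        assert normalize_ncs(records)["ncs"].iloc[0] == pytest.approx(-1.0)


class TestTau:
    def test_counting_pool_members_below(self):
        assert tau_score(-0.25, [0.1, 0.2, 0.3, 0.4]) == pytest.approx(-50.0)

    def test_extreme_negative_value(self):
        assert tau_score(-9.0, [0.1, 0.2, 0.3]) == pytest.approx(-100.0)

    def test_zero_ncs_is_zero_tau(self):
        assert tau_score(0.0, [0.1, 0.2]) == 0.0

    def test_small_pool_rejected(self):
        with pytest.raises(ValueError):
            tau_score(1.0, [0.5])

    def test_tau_monotone_in_ncs_over_fixed_pool(self):
        pool = np.linspace(0.05, 2.0, 40)
        taus = [tau_score(x, pool) for x in np.linspace(-3, 3, 61)]
        assert all(b >= a - 1e-12 for a, b in zip(taus, taus[1:]))

    def test_attach_tau_bounds_and_extreme(self, small_config):
        comp, truth = generate_reference_compendium(small_config)
        records = attach_tau(
            normalize_ncs(score_compendium(comp, planted_query(truth.program)))
        )
        assert records["tau"].between(-100, 100).all()
        most_negative = records["ncs"].idxmin()
        assert records.loc[most_negative, "tau"] == -100.0


class TestSummaries:
    def _records(self, ncs_by_pert: dict[str, list[float]]) -> pd.DataFrame:
        rows = []
        for pert, values in ncs_by_pert.items():
            for i, v in enumerate(values):
                rows.append(
                    {"perturbagen": pert, "cell_line": f"c{i}", "ncs": v, "tau": v}
                )
        return pd.DataFrame(rows)

    def test_single_cell_line_raw_stat_is_that_ncs(self):
        records = self._records({"a": [-1.5], "b": [0.2]})
        summary = summarize_compounds(records).set_index("perturbagen")
        assert summary.loc["a", "raw_stat"] == pytest.approx(-1.5)

    def test_constant_vector_raw_stat(self):
        records = self._records({"a": [-2.0, -2.0, -2.0], "b": [0.1, 0.2, 0.3]})
        summary = summarize_compounds(records).set_index("perturbagen")
        assert summary.loc["a", "raw_stat"] == pytest.approx(-2.0)

    def test_nine_cell_line_quantiles_match_oracle(self):
        rng = np.random.default_rng(7)
        ncs = list(rng.normal(size=9))
        records = self._records({"a": ncs, "b": list(rng.normal(size=9))})
        summary = summarize_compounds(records).set_index("perturbagen")
        q33 = percentile_oracle(ncs, 33)
        q67 = percentile_oracle(ncs, 67)
        expected = q33 if abs(q33) >= abs(q67) else q67
        assert summary.loc["a", "raw_stat"] == pytest.approx(expected)

    def test_summary_score_is_leave_one_out_percentile(self):
        records = self._records({"a": [-3.0], "b": [-1.0], "c": [0.5], "d": [0.1]})
        summary = summarize_compounds(records).set_index("perturbagen")
        assert summary.loc["a", "summary_score"] == pytest.approx(-100.0)
        assert summary.loc["b", "summary_score"] == pytest.approx(-100 * 2 / 3)


class TestPrioritize:
    def test_planted_antagonists_are_the_only_survivors(self):
        cfg = GeneratorConfig(seed=8, n_perturbagens=552, n_planted_antagonists=50,
                              planted_effect=0.9, n_genes=500, program_size=200)
        comp, truth = generate_reference_compendium(cfg)
        records = attach_tau(
            normalize_ncs(score_compendium(comp, planted_query(truth.program)))
        )
        result = prioritize(summarize_compounds(records), query_label="q")
        survivors = set(result.candidates["perturbagen"])
        assert survivors <= set(truth.of("antagonist"))

    def test_boundary_thresholds_empty_output(self):
        summaries = pd.DataFrame(
            {"perturbagen": ["a"], "summary_score": [-100.0],
             "median_tau": [-100.0], "raw_stat": [-3.0], "n_cell_lines": [1]}
        )
        result = prioritize(summaries, -100.0, -100.0)
        assert result.candidates.empty

    def test_output_sorted_ascending_by_median_tau(self):
        summaries = pd.DataFrame(
            {
                "perturbagen": ["a", "b", "c", "d"],
                "summary_score": [-99.5, -99.9, -99.7, -10.0],
                "median_tau": [-99.2, -100.0, -99.6, -100.0],
            }
        )
        result = prioritize(summaries, query_label="q")
        assert result.n_stage1 == 3 and result.n_stage2 == 3
        assert list(result.candidates["perturbagen"]) == ["b", "c", "a"]

    def test_threshold_domain_validated(self):
        with pytest.raises(ValueError):
            prioritize(pd.DataFrame(), summary_threshold=5.0)


class TestMerge:
    def _candidates(self, names, query):
        return pd.DataFrame(
            {"perturbagen": names, "median_tau": -99.5, "summary_score": -99.5,
             "query": query}
        )

    def test_union_of_three_and_six_with_two_shared_is_seven(self):
        day4 = self._candidates(["purmorphamine", "DY-131", "SB-225002"], "d4")
        day13 = self._candidates(
            ["purmorphamine", "DY-131", "emetine", "kinetin-riboside",
             "SB-206553", "chelidonine"],
            "d13",
        )
        merged = merge_timepoint_candidates(day4, day13)
        assert len(merged) == 7
        dual = merged[merged["n_queries"] == 2]
        assert set(dual["perturbagen"]) == {"purmorphamine", "DY-131"}

    def test_identical_lists_merge_to_one_dual_tagged_copy(self):
        a = self._candidates(["x", "y"], "d4")
        b = self._candidates(["x", "y"], "d13")
        merged = merge_timepoint_candidates(a, b)
        assert len(merged) == 2
        assert (merged["queries"] == "d13,d4").all()

    def test_disjoint_lists_concatenate(self):
        merged = merge_timepoint_candidates(
            self._candidates(["a", "b"], "d4"), self._candidates(["c", "d", "e"], "d13")
        )
        assert len(merged) == 5
        assert (merged["n_queries"] == 1).all()


class TestScoreCompendium:
    def test_rejects_low_overlap_queries(self, small_config):
        comp, truth = generate_reference_compendium(small_config)
        query = planted_query(truth.program, k=20)
        query.up = query.up[:2] + ["ZZ1", "ZZ2", "ZZ3"]  # 40% overlap
        records = score_compendium(comp, query, min_overlap=0.5)
        assert records.empty

    def test_wtcs_zero_when_es_signs_agree(self, small_config):
        comp, truth = generate_reference_compendium(small_config)
        records = score_compendium(comp, planted_query(truth.program))
        same_sign = records[(records["es_up"] * records["es_down"]) > 0]
        assert (same_sign["wtcs"] == 0).all()
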