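"""Normalization, NB differential expression, partition and orthogroup summaries."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from mycopan.expression import (
    DEConfig,
    normalize_counts,
    orthogroup_regulation,
    ssp_regulation_table,
    summarize_by_partition,
    upset_counts,
)
from mycopan.expression import test_de as nb_wald_de  # avoid pytest collection
from mycopan.synthetic import SimulationConfig, simulate_counts


def _matrix(data, samples):
    return pd.DataFrame(
        data, index=[f"g{i}" for i in range(len(data))], columns=samples
    )


class TestNormalizeCounts:
    def test_identical_samples_have_unit_factors(self):
        counts = _matrix([[10, 10], [200, 200], [5, 5]], ["a", "b"])
        factors, _ = normalize_counts(counts)
        assert np.allclose(factors, [1.0, 1.0])

    def test_doubled_library_gets_factor_two(self):
        counts = _matrix([[10, 20], [200, 400], [5, 10]], ["a", "b"])
        factors, normalized = normalize_counts(counts)
        assert np.allclose(factors / factors.iloc[0], [1.0, 2.0])
        assert np.allclose(normalized["a"], normalized["b"])

    def test_matches_hand_median_of_ratios_oracle(self, rng):
        # odd gene count so the linear- and log-scale medians coincide
        counts = _matrix(rng.integers(1, 500, size=(21, 4)), list("abcd"))
        factors, _ = normalize_counts(counts)
        ref = np.exp(np.log(counts.to_numpy(float)).mean(axis=1))
        expected = np.median(counts.to_numpy(float) / ref[:, None], axis=0)
        assert np.allclose(factors, expected)

    def test_matches_pydeseq2_size_factors(self, rng):
        pydeseq2_dds = pytest.importorskip("pydeseq2.dds")
        counts = _matrix(rng.integers(1, 800, size=(60, 4)), list("abcd"))
        meta = pd.DataFrame(
            {"condition": ["A", "A", "B", "B"]}, index=counts.columns
        )
        dds = pydeseq2_dds.DeseqDataSet(
            counts=counts.T, metadata=meta, design="~condition", quiet=True
        )
        dds.fit_size_factors()
        factors, _ = normalize_counts(counts)
        assert np.allclose(
            factors.to_numpy(), dds.obs["size_factors"].to_numpy(), rtol=1e-6
        )

    def test_all_genes_with_zero_rejected(self):
        counts = _matrix([[0, 5], [3, 0]], ["a", "b"])
        with pytest.raises(ValueError, match="zero"):
            normalize_counts(counts)


class TestTestDe:
    conditions = pd.Series(
        ["ECM", "ECM", "FLM", "FLM"], index=["e1", "e2", "f1", "f2"]
    )

    def test_identical_conditions_are_ns(self):
        counts = _matrix([[50, 50, 50, 50], [7, 7, 7, 7]], self.conditions.index)
        res = nb_wald_de(counts, self.conditions)
        assert (res.call == "ns").all()
        assert np.allclose(res.log2fc, 0.0)

    def test_all_zero_gene_excluded_but_reported(self):
        counts = _matrix(
            [[0, 0, 0, 0], [60, 55, 50, 52], [400, 380, 100, 90]],
            self.conditions.index,
        )
        res = nb_wald_de(counts, self.conditions).set_index("gene_id")
        assert res.loc["g0", "call"] == "ns"
        assert np.isnan(res.loc["g0", "p_value"])

    def test_single_replicate_rejected(self):
        cond = pd.Series(["ECM", "FLM", "FLM"], index=["a", "b", "c"])
        counts = _matrix([[5, 5, 5]], cond.index)
        with pytest.raises(ValueError, match="fewer than 2"):
            nb_wald_de(counts, cond)

    def test_sensitivity_and_fdr_on_simulated_truth(self):
        cfg = SimulationConfig(
            seed=31, nb_dispersion=0.05, lfc_magnitude=2.0, n_replicates=4,
            de_fraction_by_partition={"core": 0.1},
        )
        labels = pd.Series(["core"] * 2_000, index=[f"g{i}" for i in range(2_000)])
        counts, samples, truth = simulate_counts(cfg, labels)
        res = nb_wald_de(counts, samples.set_index("sample_id")["condition"])
        called = res.set_index("gene_id").call != "ns"
        is_de = truth.set_index("gene_id").is_de
        sensitivity = (called & is_de).sum() / is_de.sum()
        fdr = (called & ~is_de).sum() / max(1, called.sum())
        assert sensitivity >= 0.8
        assert fdr <= 0.1

    def test_bh_adjustment_monotone_in_raw_p(self):
        cfg = SimulationConfig(seed=32, n_replicates=3)
        labels = pd.Series(["core"] * 300, index=[f"g{i}" for i in range(300)])
        counts, samples, _ = simulate_counts(cfg, labels)
        res = nb_wald_de(counts, samples.set_index("sample_id")["condition"]).dropna()
        ordered = res.sort_values("p_value")
        assert (ordered.fdr.cummax() == ordered.fdr).all()

    def test_calls_invariant_under_sample_reordering(self):
        cfg = SimulationConfig(seed=33, n_replicates=3)
        labels = pd.Series(["core"] * 200, index=[f"g{i}" for i in range(200)])
        counts, samples, _ = simulate_counts(cfg, labels)
        cond = samples.set_index("sample_id")["condition"]
        res_a = nb_wald_de(counts, cond)
        shuffled = counts[list(reversed(counts.columns))]
        res_b = nb_wald_de(shuffled, cond)
        assert (res_a.call == res_b.call).all()


class TestSummarizeByPartition:
    def test_printed_row_arithmetic(self):
        # 750 up-regulated genes, 42 of them specific -> 5.6% specific
        de = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(750)],
                "call": ["up"] * 750,
            }
        )
        parts = {f"g{i}": "specific" if i < 42 else ("core" if i < 42 + 452 else "accessory") for i in range(750)}
        out = summarize_by_partition(de, parts).set_index("direction")
        row = out.loc["up"]
        assert (row.total, row.core, row.accessory, row.specific) == (750, 452, 256, 42)
        assert row.percent_specific == 5.6

    def test_zero_degs_flagged_not_crashed(self):
        de = pd.DataFrame({"gene_id": ["g0"], "call": ["ns"]})
        out = summarize_by_partition(de, {"g0": "core"}).set_index("direction")
        assert out.loc["up"].total == 0
        assert out.loc["up"].percent_specific == 0.0
        assert not out.loc["up"].defined

    def test_random_fixture_percentages_recompute(self, rng):
        calls = rng.choice(["up", "down", "ns"], size=400)
        parts_arr = rng.choice(["core", "accessory", "specific"], size=400)
        de = pd.DataFrame({"gene_id": [f"g{i}" for i in range(400)], "call": calls})
        parts = {f"g{i}": parts_arr[i] for i in range(400)}
        out = summarize_by_partition(de, parts, genome_total_genes=400)
        for _, row in out.iterrows():
            assert row.core + row.accessory + row.specific == row.total or row.direction == "genome"
            if row.total:
                assert row.percent_specific == pytest.approx(
                    round(100.0 * row.specific / row.total, 1), abs=0.051
                )


class TestOrthogroupRegulation:
    orthogroups = pd.DataFrame(
        {
            "og_id": ["og1", "og1", "og2", "og2"],
            "species_id": ["s1", "s2", "s1", "s2"],
            "gene_id": ["a1", "b1", "a2", "b2"],
        }
    )

    def test_single_up_gene_puts_orthogroup_in_up_set(self):
        de = {"s1": pd.DataFrame({"gene_id": ["a1", "a2"], "call": ["up", "ns"]})}
        reg = orthogroup_regulation(de, self.orthogroups)
        assert reg["s1"]["up"] == {"og1"}
        assert reg["s1"]["down"] == set()

    def test_identical_deg_sets_intersect_fully(self):
        de = {
            sp: pd.DataFrame({"gene_id": [f"{p}1", f"{p}2"], "call": ["up", "up"]})
            for sp, p in (("s1", "a"), ("s2", "b"))
        }
        reg = orthogroup_regulation(de, self.orthogroups)
        sets = {sp: reg[sp]["up"] for sp in reg}
        counts = upset_counts(sets)
        assert counts[frozenset({"s1", "s2"})] == 2

    def test_both_directions_allowed_for_one_orthogroup(self):
        og = pd.DataFrame(
            {"og_id": ["og1", "og1"], "species_id": ["s1", "s1"], "gene_id": ["x", "y"]}
        )
        de = {"s1": pd.DataFrame({"gene_id": ["x", "y"], "call": ["up", "down"]})}
        reg = orthogroup_regulation(de, og)
        assert reg["s1"]["up"] == reg["s1"]["down"] == {"og1"}


class TestUpsetCounts:
    def test_disjoint_sets_only_singletons(self):
        counts = upset_counts({"a": {1, 2}, "b": {3}})
        assert counts[frozenset({"a"})] == 2
        assert counts[frozenset({"b"})] == 1
        assert counts[frozenset({"a", "b"})] == 0

    def test_nested_sets(self):
        counts = upset_counts({"a": {1, 2}, "b": {1, 2, 3}})
        assert counts[frozenset({"a", "b"})] == 2
        assert counts[frozenset({"b"})] == 1
        assert counts[frozenset({"a"})] == 0

    def test_counts_sum_to_union_and_match_powerset_oracle(self, rng):
        names = ["s1", "s2", "s3", "s4", "s5"]
        sets = {
            n: set(rng.choice(40, size=int(rng.integers(5, 20)), replace=False))
            for n in names
        }
        counts = upset_counts(sets)
        union = set().union(*sets.values())
        assert sum(counts.values()) == len(union)
        # oracle: exhaustive inclusion-exclusion by membership pattern
        for r in range(1, 6):
            for sub in combinations(names, r):
                inside = set.intersection(*(sets[n] for n in sub))
                outside = set().union(*(sets[n] for n in names if n not in sub)) if len(sub) < 5 else set()
                assert counts[frozenset(sub)] == len(inside - outside)


class TestSspRegulationTable:
    def test_printed_row_arithmetic(self):
        # 400 expressed SSPs, 283 specific -> 71% specific
        genes = [f"g{i}" for i in range(400)]
        classes = {g: "SSP" for g in genes}
        parts = {
            g: "specific" if i < 283 else ("core" if i < 283 + 60 else "accessory")
            for i, g in enumerate(genes)
        }
        normalized = pd.DataFrame(
            {"e1": 50.0, "e2": 50.0, "f1": 50.0, "f2": 50.0}, index=genes
        )
        cond = pd.Series(["ECM", "ECM", "FLM", "FLM"], index=normalized.columns)
        de = pd.DataFrame({"gene_id": genes, "call": ["ns"] * 400})
        out = ssp_regulation_table(de, classes, parts, normalized, cond).set_index(
            "category"
        )
        row = out.loc["expressed"]
        assert (row.n_ssp, row.core, row.accessory, row.specific) == (400, 60, 57, 283)
        assert row.percent_specific == 71

    def test_no_ssp_genes_gives_zero_rows(self):
        normalized = pd.DataFrame({"e1": [10.0], "f1": [10.0]}, index=["g0"])
        cond = pd.Series(["ECM", "FLM"], index=["e1", "f1"])
        de = pd.DataFrame({"gene_id": ["g0"], "call": ["ns"]})
        out = ssp_regulation_table(
            de, {"g0": "non_secreted"}, {"g0": "core"}, normalized, cond
        )
        assert (out.n_ssp == 0).all()

    def test_expression_floor_filters_low_genes(self):
        genes = ["lo", "hi"]
        normalized = pd.DataFrame({"e1": [1.0, 50.0], "f1": [1.0, 50.0]}, index=genes)
        cond = pd.Series(["ECM", "FLM"], index=["e1", "f1"])
        de = pd.DataFrame({"gene_id": genes, "call": ["ns", "ns"]})
        out = ssp_regulation_table(
            de,
            {g: "SSP" for g in genes},
            {g: "core" for g in genes},
            normalized,
            cond,
            expression_floor=5.0,
        ).set_index("category")
        assert out.loc["expressed"].n_ssp == 1
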