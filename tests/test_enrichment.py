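import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metsig.containers import MetsigError
from metsig.enrichment import (
    fisher_enrichment,
    knockdown_targets,
    map_tf_targets,
    multiway_intersection,
    upstream_window,
)

from test_essentiality import fisher_enumeration_oracle


def loci_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def sites_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


class TestUpstreamWindow:
    def test_plus_strand_window_precedes_start(self):
        assert upstream_window(10_000, 11_000, "+") == (8_000, 10_000)

    def test_minus_strand_window_follows_end(self):
        assert upstream_window(4_000, 5_000, "-") == (5_000, 7_000)

    def test_clipped_at_zero(self):
        assert upstream_window(500, 1_500, "+") == (0, 500)


class TestMapTfTargets:
    def test_interval_arithmetic_examples(self):
        loci = loci_frame([
            ("chr1", 10_000, 11_000, "gA", 0, "+"),
            ("chr1", 4_000, 5_000, "gB", 0, "-"),
        ])
        sites = sites_frame([
            ("chr1", 8_500, 8_600, "TF1"),   # inside gA's [8000, 10000) window
            ("chr1", 7_900, 8_000, "TF2"),   # ends exactly at window start: excluded
            ("chr1", 6_900, 7_100, "TF3"),   # overlaps gB's [5000, 7000) window
        ])
        targets = map_tf_targets(sites, loci)
        assert targets["TF1"] == {"gA"}
        assert targets["TF2"] == set()
        assert targets["TF3"] == {"gB"}

    def test_strand_naive_mode_ignores_strand(self):
        loci = loci_frame([("chr1", 4_000, 5_000, "gB", 0, "-")])
        sites = sites_frame([("chr1", 2_500, 2_600, "TF1")])  # in [2000, 4000)
        assert map_tf_targets(sites, loci)["TF1"] == set()
        assert map_tf_targets(sites, loci, strand_aware=False)["TF1"] == {"gB"}

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        loci = loci_frame([
            ("chr1", 10_000 * (i + 1), 10_000 * (i + 1) + 500, f"g{i}", 0, rng.choice(["+", "-"]))
            for i in range(20)
        ])
        sites = sites_frame([
            ("chr1", int(p), int(p) + 100, "TF1")
            for p in rng.integers(0, 220_000, size=30)
        ])
        t1 = map_tf_targets(sites, loci)
        t2 = map_tf_targets(sites.iloc[::-1], loci.iloc[::-1])
        assert t1 == t2

    def test_malformed_records_rejected_per_record(self):
        loci = loci_frame([
            ("chr1", 10_000, 9_000, "bad", 0, "+"),
            ("chr1", 10_000, 11_000, "good", 0, "+"),
        ])
        sites = sites_frame([("chr1", 9_000, 9_100, "TF1")])
        assert map_tf_targets(sites, loci)["TF1"] == {"good"}


class TestKnockdownTargets:
    def test_strict_threshold(self):
        km = pd.DataFrame({"kd1": [-0.6, -0.5, -0.4]}, index=["a", "b", "c"])
        assert knockdown_targets(km)["kd1"] == {"a"}

    def test_planted_targets_recovered_exactly(self):
        from metsig.simulate import SimConfig, generate_regulator_data, make_truth

        config = SimConfig(n_genes=800, seed=21)
        truth = make_truth(config)
        _, _, km = generate_regulator_data(truth, config)
        found = knockdown_targets(km)
        assert found == truth.knockdown_targets


class TestFisherEnrichment:
    def test_query_equals_set_gives_point_mass(self):
        universe = {f"g{i}" for i in range(20)}
        query = {f"g{i}" for i in range(5)}
        report = fisher_enrichment(query, {"self": query}, universe)
        oracle = fisher_enumeration_oracle(5, 5, 5, 20)
        assert report.table.loc["self", "fisher_p"] == pytest.approx(oracle, rel=1e-10)

    def test_disjoint_set_not_enriched(self):
        universe = {f"g{i}" for i in range(20)}
        report = fisher_enrichment(
            {f"g{i}" for i in range(5)}, {"other": {f"g{i}" for i in range(10, 15)}}, universe
        )
        assert report.table.loc["other", "fisher_p"] == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        genes = [f"g{i}" for i in range(n)]
        query = set(rng.choice(genes, int(rng.integers(1, n)), replace=False))
        target = set(rng.choice(genes, int(rng.integers(1, n)), replace=False))
        report = fisher_enrichment(query, {"s": target}, set(genes))
        a = len(query & target)
        assert report.table.loc["s", "fisher_p"] == pytest.approx(
            fisher_enumeration_oracle(a, len(query), len(target), n), rel=1e-9
        )

    def test_monotone_in_overlap(self):
        # moving one query gene into the set (margins fixed) can only shrink p
        universe = {f"g{i}" for i in range(40)}
        target = {f"g{i}" for i in range(10)}
        low = {f"g{i}" for i in range(8, 18)}   # overlap 2
        high = {f"g{i}" for i in range(7, 17)}  # overlap 3
        r_low = fisher_enrichment(low, {"t": target}, universe).table.loc["t", "fisher_p"]
        r_high = fisher_enrichment(high, {"t": target}, universe).table.loc["t", "fisher_p"]
        assert r_high < r_low


class TestMultiwayIntersection:
    def test_identical_sets_fill_only_core(self):
        s = {"a", "b"}
        regions = multiway_intersection({"x": set(s), "y": set(s), "z": set(s)})
        assert regions[("x", "y", "z")] == s
        assert all(not v for k, v in regions.items() if k != ("x", "y", "z"))

    def test_disjoint_sets_fill_only_singletons(self):
        regions = multiway_intersection({"x": {"a"}, "y": {"b"}})
        assert regions[("x",)] == {"a"}
        assert regions[("y",)] == {"b"}
        assert regions[("x", "y")] == set()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_regions_partition_the_union(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(30)]
        sets = {
            name: set(rng.choice(genes, int(rng.integers(1, 25)), replace=False))
            for name in ["a", "b", "c", "d"]
        }
        regions = multiway_intersection(sets)
        union = set().union(*sets.values())
        assert set().union(*regions.values()) == union
        assert sum(len(v) for v in regions.values()) == len(union)
        # brute-force check of one region
        core = {g for g in union if all(g in s for s in sets.values())}
        assert regions[("a", "b", "c", "d")] == core

    def test_arity_bounds(self):
        with pytest.raises(MetsigError):
            multiway_intersection({"only": {"a"}})
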