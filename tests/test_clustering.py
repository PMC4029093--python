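"""Density-hierarchy clustering: oracle equivalence, invariants, filters."""

import numpy as np
import pandas as pd
import pytest

from cagepeaks import (
    add_stability,
    cluster_sites,
    compute_hierarchical_stability,
    density_filter,
    legacy_filter,
)
from oracles import brute_force_hierarchy, random_sites


def impl_as_dict(df, pos):
    p2i = {p: i for i, p in enumerate(pos)}
    return {
        (p2i[s], p2i[e]): (mn, mx)
        for s, e, mn, mx in zip(df["start"], df["end"], df["min_d"], df["max_d"])
    }


class TestClusterSites:
    def test_single_site(self):
        df = cluster_sites([100], [5])
        row = df.iloc[0]
        assert (row.start, row.end, row.tag_sum) == (100, 100, 5)
        assert row.min_d == 0 and np.isinf(row.max_d)

    def test_two_equal_sites(self):
        df = cluster_sites([0, 100], [10, 10])
        got = {
            (s, e): (mn, mx)
            for s, e, mn, mx in zip(df.start, df.end, df.min_d, df.max_d)
        }
        assert got == {
            (0, 100): (0.0, 0.1),
            (0, 0): (0.1, np.inf),
            (100, 100): (0.1, np.inf),
        }

    def test_three_sites_against_oracle(self):
        pos, cnt = [0, 10, 20], [10, 1, 10]
        df = cluster_sites(pos, cnt)
        assert impl_as_dict(df, pos) == brute_force_hierarchy(pos, cnt)
        got = impl_as_dict(df, pos)
        assert (0, 2) in got  # whole span, T=21
        assert (0, 0) in got and (2, 2) in got
        # every child's min_d equals its parent's max_d
        for _, row in df.iterrows():
            if row.parent >= 0:
                assert row.min_d == df.loc[row.parent, "max_d"]

    def test_oracle_equivalence_random(self, rng):
        for _ in range(200):
            pos, cnt = random_sites(rng)
            df = cluster_sites(pos, cnt)
            assert impl_as_dict(df, pos) == brute_force_hierarchy(pos, cnt)

    def test_laminarity(self, rng):
        for _ in range(50):
            pos, cnt = random_sites(rng)
            df = cluster_sites(pos, cnt)
            iv = list(zip(df["start"], df["end"]))
            for i in range(len(iv)):
                for j in range(i + 1, len(iv)):
                    (s1, e1), (s2, e2) = iv[i], iv[j]
                    disjoint = e1 < s2 or e2 < s1
                    nested = (s1 <= s2 and e2 <= e1) or (s2 <= s1 and e1 <= e2)
                    assert disjoint or nested

    def test_count_scaling_and_translation(self, rng):
        pos, cnt = random_sites(rng)
        base = cluster_sites(pos, cnt)
        scaled = cluster_sites(pos, cnt * 2)
        assert np.array_equal(scaled["min_d"], base["min_d"] * 2)
        assert np.array_equal(
            scaled["max_d"].replace(np.inf, -1), (base["max_d"] * 2).replace(np.inf, -1)
        )
        shifted = cluster_sites(pos + 1000, cnt)
        assert np.array_equal(shifted["start"], base["start"] + 1000)
        assert np.array_equal(shifted["min_d"], base["min_d"])

    def test_input_validation(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            cluster_sites([5, 5], [1, 1])
        with pytest.raises(ValueError, match="positive"):
            cluster_sites([1, 2], [1, 0])


class TestDensityFilter:
    def _clusters(self, rows):
        df = pd.DataFrame(
            rows, columns=["start", "end", "tag_sum", "parent"]
        )
        df["chrom"], df["strand"] = "chr1", "+"
        df["n_sites"], df["min_d"], df["max_d"] = 1, 0.0, np.inf
        return df

    def test_threshold_is_strict_below(self):
        # T=1 over [0,100] in a 1e6 library: tpm/base = 1/101 < 0.1 -> dropped
        df = self._clusters([(0, 100, 1.0, -1), (50, 50, 5.0, 0)])
        out = density_filter(df, 1_000_000, 0.1)
        assert list(out["start"]) == [50]  # singleton T=5 -> tpm/base 5, kept
        assert out["parent"].iloc[0] == -1  # re-wired to root

    def test_exact_threshold_kept(self):
        # tpm_per_base exactly 0.1: T=25 over 250 bases in 1e6 library
        df = self._clusters([(0, 249, 25.0, -1)])
        out = density_filter(df, 1_000_000, 0.1)
        assert len(out) == 1

    def test_rewire_to_nearest_surviving_ancestor(self):
        # chain root(big T) -> mid(tiny T, dropped) -> leaf(big T)
        df = self._clusters([(0, 200, 500.0, -1), (10, 100, 0.001, 0), (20, 20, 100.0, 1)])
        out = density_filter(df, 1_000_000, 0.1)
        assert len(out) == 2
        leaf = out.loc[out["start"] == 20].iloc[0]
        assert out.loc[leaf["parent"], "start"] == 0

    def test_negative_threshold_errors(self):
        with pytest.raises(ValueError):
            density_filter(self._clusters([(0, 0, 1.0, -1)]), 100, -0.5)


class TestStability:
    def test_ratio_and_ceiling(self):
        df = pd.DataFrame(
            {
                "min_d": [0.0, 0.1, 2.0],
                "max_d": [0.5, np.inf, 6.0],
                "parent": [-1, 0, 0],
            }
        )
        out = add_stability(df, ceiling=1000.0)
        assert list(out["stability"]) == [1000.0, 1000.0, 3.0]
        clipped = add_stability(
            pd.DataFrame({"min_d": [0.001], "max_d": [10.0], "parent": [-1]}),
            ceiling=1000.0, clip_finite=True,
        )
        assert clipped["stability"].iloc[0] == 1000.0

    def test_hierarchical_sum(self):
        df = pd.DataFrame({"parent": [-1, 0, 1], "stability": [2.0, 3.0, 4.0]})
        out = compute_hierarchical_stability(df)
        assert list(out["hier_stability"]) == [2.0, 5.0, 9.0]

    def test_parent_child_example(self):
        df = pd.DataFrame({"parent": [-1, 0], "stability": [3.0, 2.0]})
        out = compute_hierarchical_stability(df)
        assert out["hier_stability"].iloc[1] == 5.0

    def test_orphan(self):
        df = pd.DataFrame({"parent": [-1], "stability": [7.0]})
        assert compute_hierarchical_stability(df)["hier_stability"].iloc[0] == 7.0

    def test_cycle_detected(self):
        df = pd.DataFrame({"parent": [1, 0], "stability": [1.0, 1.0]})
        with pytest.raises(ValueError, match="cycle"):
            compute_hierarchical_stability(df)


class TestLegacyFilter:
    def _df(self, rows):
        df = pd.DataFrame(rows, columns=["start", "end", "tag_sum", "stability"])
        df["chrom"], df["strand"], df["parent"] = "chr1", "+", -1
        return df

    @pytest.mark.parametrize(
        "tag_sum,stability,length,kept",
        [
            (29, 5.0, 50, False),   # < 30 tags
            (30, 5.0, 50, True),
            (100, 1.9, 50, False),  # < 2 stability
            (100, 2.0, 50, True),
            (100, 5.0, 201, False),  # longer than 200 bp
            (100, 5.0, 200, True),
        ],
    )
    def test_boundaries(self, tag_sum, stability, length, kept):
        df = self._df([(0, length - 1, tag_sum, stability)])
        assert (len(legacy_filter(df)) == 1) is kept

    def test_collapse_keeps_outermost_only(self):
        df = self._df(
            [(0, 150, 100, 5.0), (10, 50, 90, 5.0), (400, 420, 50, 3.0)]
        )
        out = legacy_filter(df)
        assert sorted(zip(out["start"], out["end"])) == [(0, 150), (400, 420)]
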