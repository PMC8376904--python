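"""Frequencies, enrichment ratios, plot normalization and the 4D rule,
cross-checked against an exact rational-arithmetic oracle."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fretseq import (
    PoolCounts,
    build_enrichment_table,
    enrichment,
    filter_positive,
    frequencies,
    plot_normalize,
    rank_and_calibrate,
    select_4d,
    to_cpm,
)
from fretseq.enrichment import SORTED_GROUPS


def pool(group, counts, level="aa"):
    return PoolCounts(
        group=group, counts=counts, total_reads=sum(counts.values()), level=level
    )


class TestCpm:
    def test_arithmetic(self):
        cpm = to_cpm(pool("INPUT", {"a": 2, "b": 99_998}))
        assert cpm["a"] == pytest.approx(20.0)

    def test_single_variant_is_a_million(self):
        cpm = to_cpm(pool("INPUT", {"a": 123}))
        assert cpm["a"] == 1e6

    def test_toy_table(self):
        cpm = to_cpm(pool("INPUT", {"a": 10, "b": 90}))
        assert cpm == {"a": 1e5, "b": 9e5}

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            to_cpm(pool("INPUT", {}))


class TestFilterPositive:
    def test_strictness_at_threshold(self):
        kept = filter_positive({"at": 10.0, "just_above": 10.01, "below": 9.9})
        assert kept == {"just_above"}

    def test_all_below_gives_empty_set(self):
        assert filter_positive({"a": 1.0, "b": 0.0}) == set()


class TestFrequencies:
    def test_hand_example(self):
        f = frequencies(pool("INPUT", {"a": 10, "b": 30, "c": 60}))
        assert f == {"a": 0.1, "b": 0.3, "c": 0.6}

    def test_single_variant(self):
        assert frequencies(pool("INPUT", {"a": 7}))["a"] == 1.0

    @given(
        counts=st.dictionaries(
            st.text(alphabet="ACDE", min_size=3, max_size=3),
            st.integers(min_value=1, max_value=10_000),
            min_size=1,
            max_size=50,
        )
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_matches_rational_oracle(self, counts):
        f = frequencies(pool("INPUT", counts))
        total = sum(counts.values())
        for v, c in counts.items():
            assert f[v] == pytest.approx(float(Fraction(c, total)), rel=1e-15)
        assert sum(f.values()) == pytest.approx(1.0, abs=1e-12)


class TestEnrichmentRatio:
    def test_unchanged_frequency_is_one(self):
        assert enrichment(0.01, 0.01) == 1.0

    def test_doubling(self):
        assert enrichment(0.02, 0.01) == pytest.approx(2.0)

    def test_hand_computation_via_eq1_then_eq2(self):
        f_in = frequencies(pool("INPUT", {"a": 50, "b": 50}))
        f_srt = frequencies(pool("KAH", {"a": 75, "b": 25}))
        assert enrichment(f_srt["a"], f_in["a"]) == pytest.approx(1.5)
        assert enrichment(f_srt["b"], f_in["b"]) == pytest.approx(0.5)

    def test_zero_input_frequency_undefined(self):
        assert math.isnan(enrichment(0.01, 0.0))


class TestPlotNormalize:
    def test_continuity_at_one(self):
        assert plot_normalize(1.0) == 0.0
        assert plot_normalize(1.0 + 1e-12) == pytest.approx(0.0, abs=1e-11)

    @pytest.mark.parametrize("e,expected", [(0.5, -0.5), (10.0, 1.0), (0.0, -1.0)])
    def test_branches(self, e, expected):
        assert plot_normalize(e) == pytest.approx(expected)

    @given(
        e=st.lists(
            st.floats(min_value=0.0, max_value=1e6, allow_nan=False),
            min_size=2,
            max_size=20,
        )
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_monotone_nondecreasing(self, e):
        e = sorted(e)
        out = plot_normalize(np.array(e))
        assert (np.diff(out) >= -1e-15).all()

    def test_nan_propagates(self):
        assert math.isnan(plot_normalize(float("nan")))


class TestSelect4D:
    def _table(self, e_kah, e_kdl, e_kal, e_kdh):
        df = pd.DataFrame(
            {
                "E_KAH": [e_kah],
                "E_KDL": [e_kdl],
                "E_KAL": [e_kal],
                "E_KDH": [e_kdh],
            },
            index=pd.Index(["AAA"], name="aa"),
        )
        df["contains_stop"] = False
        e_ok = df[[f"E_{g}" for g in SORTED_GROUPS]].notna().all(axis=1)
        df["passes_4d"] = (
            e_ok
            & (df["E_KAH"] > 1)
            & (df["E_KDL"] > 1)
            & (df["E_KAL"] < 1)
            & (df["E_KDH"] < 1)
        )
        return df

    @pytest.mark.parametrize(
        "es,selected",
        [
            ((2.0, 1.5, 0.5, 0.8), True),
            ((2.0, 1.5, 1.2, 0.8), False),   # KAL fails
            ((1.0, 1.5, 0.5, 0.5), False),   # strict > at the KAH boundary
            ((2.0, 1.0, 0.5, 0.5), False),   # strict > at the KDL boundary
        ],
    )
    def test_strict_rule(self, es, selected):
        assert (select_4d(self._table(*es)) == ["AAA"]) is selected


class TestRankAndCalibrate:
    def _table(self, products, wt_product=None):
        rows = dict(products)
        if wt_product is not None:
            rows["VNV"] = wt_product
        idx = sorted(rows)
        df = pd.DataFrame(index=pd.Index(idx, name="aa"))
        for g in SORTED_GROUPS:
            df[f"E_{g}"] = [2.0 if g in ("KAH", "KDL") else 0.5 for _ in idx]
        df["product_score"] = [rows[v] for v in idx]
        df["contains_stop"] = False
        df["passes_4d"] = [v in products for v in idx]  # WT itself not a candidate
        return df

    def test_ranking_and_wt_threshold(self):
        table = self._table({"XAA": 6.0, "YAA": 3.0}, wt_product=4.0)
        res = rank_and_calibrate(table, wt_variant="VNV")
        assert res.ranked == ["XAA", "YAA"]
        assert res.above_wt == ["XAA"]
        assert res.wt_product == 4.0

    def test_all_below_wt(self):
        table = self._table({"XAA": 1.5, "YAA": 2.0}, wt_product=9.0)
        res = rank_and_calibrate(table, wt_variant="VNV")
        assert res.above_wt == []

    def test_tie_broken_lexicographically(self):
        table = self._table({"CCC": 5.0, "AAA": 5.0, "BBB": 5.0})
        res = rank_and_calibrate(table)
        assert res.ranked == ["AAA", "BBB", "CCC"]

    def test_absent_wt_still_ranks(self):
        table = self._table({"XAA": 6.0})
        res = rank_and_calibrate(table, wt_variant="ZZZ")
        assert res.ranked == ["XAA"]
        assert res.above_wt is None and res.wt_product is None


class TestBuildEnrichmentTable:
    @staticmethod
    def pools_fixture():
        """10-variant hand-built counts over all six pools (AA level)."""
        variants = ["ACI", "HWF", "VNV", "SRE", "GGG", "WWW", "KKK", "LLL", "MMM", "*CI"]
        base = {v: 20_000 for v in variants}
        input_ka = dict(base)
        input_ka["MMM"] = 1          # CPM ~5.6 in the KA input: fails CPM > 10
        input_kd = dict(base)
        kah = dict(base, ACI=80_000, HWF=60_000, GGG=50_000, MMM=1)  # GGG: misfolded-like
        kal = dict(base, ACI=4_000, HWF=6_000, MMM=1)
        kdh = dict(base, GGG=60_000)
        kdl = dict(base, ACI=50_000, HWF=36_000, GGG=2_000)
        return {
            "INPUT_KA": pool("INPUT_KA", input_ka),
            "INPUT_KD": pool("INPUT_KD", input_kd),
            "KAH": pool("KAH", kah),
            "KAL": pool("KAL", kal),
            "KDH": pool("KDH", kdh),
            "KDL": pool("KDL", kdl),
        }

    def test_matches_rational_oracle_exactly(self):
        pools = self.pools_fixture()
        table = build_enrichment_table(pools)
        for g in SORTED_GROUPS:
            inp = "INPUT_KA" if g in ("KAH", "KAL") else "INPUT_KD"
            total_s = pools[g].total_reads
            total_i = pools[inp].total_reads
            for v in table.index:
                c_s = pools[g].counts.get(v, 0)
                c_i = pools[inp].counts.get(v, 0)
                f_oracle = Fraction(c_s, total_s)
                assert table.at[v, f"f_{g}"] == pytest.approx(float(f_oracle), rel=1e-14)
                cpm_i = Fraction(c_i * 10**6, total_i)
                e = table.at[v, f"E_{g}"]
                if cpm_i > 10:
                    e_oracle = Fraction(c_s, total_s) / Fraction(c_i, total_i)
                    assert e == pytest.approx(float(e_oracle), rel=1e-12)
                else:
                    assert math.isnan(e)
            f_sum = sum(table[f"f_{g}"])
            assert f_sum == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_selection_answer_sheet(self):
        # exhaustive expectation for the fixture: ACI and HWF satisfy all
        # four criteria; GGG is high in both contexts (misfolded pattern);
        # MMM has undefined KA-side E; *CI carries a stop.
        table = build_enrichment_table(self.pools_fixture())
        assert select_4d(table) == ["ACI", "HWF"]
        assert not table.at["GGG", "passes_4d"]
        assert math.isnan(table.at["MMM", "E_KAH"])
        assert table.at["*CI", "contains_stop"] and not table.at["*CI", "passes_4d"]
        res = rank_and_calibrate(table, wt_variant="VNV")
        assert res.ranked == ["ACI", "HWF"]  # ACI product > HWF product
        assert res.above_wt == ["ACI", "HWF"]  # WT product < both

    def test_scale_invariance_of_enrichment(self):
        pools = self.pools_fixture()
        table1 = build_enrichment_table(pools)
        scaled = dict(pools)
        kah = {v: 7 * c for v, c in pools["KAH"].counts.items()}
        scaled["KAH"] = pool("KAH", kah)
        table2 = build_enrichment_table(scaled)
        pd.testing.assert_series_equal(table1["E_KAH"], table2["E_KAH"])

    def test_shared_input_pool_accepted(self):
        pools = self.pools_fixture()
        shared = pools.pop("INPUT_KA")
        pools.pop("INPUT_KD")
        pools["INPUT"] = PoolCounts(
            group="INPUT",
            counts=shared.counts,
            total_reads=shared.total_reads,
            level="aa",
        )
        table = build_enrichment_table(pools)
        assert (table["cpm_INPUT_KA"] == table["cpm_INPUT_KD"]).all()

    def test_deterministic(self):
        t1 = build_enrichment_table(self.pools_fixture())
        t2 = build_enrichment_table(self.pools_fixture())
        pd.testing.assert_frame_equal(t1, t2)
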