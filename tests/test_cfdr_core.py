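import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pleiocfdr import cfdr_core as cc


def brute_force_cfdr(p, q):
    """O(N^2) counting oracle, independent of the Fenwick-tree path."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    out = np.empty_like(p)
    for i in range(p.size):
        qc = int((q <= q[i]).sum())
        joint = int(((p <= p[i]) & (q <= q[i])).sum())
        out[i] = min(1.0, p[i] * qc / joint)
    return out


class TestConditionalFdr:
    def test_small_table_against_counting_oracle(self):
        p1 = [0.001, 0.02, 0.04, 0.5, 0.9]
        p2 = [0.01, 0.03, 0.5, 0.6, 0.2]
        expected = [0.001, 0.02, 0.04 * 4 / 3, 0.5 * 5 / 4, 0.9]  # frozen oracle values
        got = cc.conditional_fdr(p1, p2)
        np.testing.assert_allclose(got, expected, rtol=1e-14)
        np.testing.assert_array_equal(got, brute_force_cfdr(p1, p2))

    def test_single_snp_is_own_p(self):
        assert cc.conditional_fdr([0.037], [0.5])[0] == pytest.approx(0.037)

    def test_reduces_to_unconditional_when_q_all_one(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(
            cc.conditional_fdr(p, np.ones(4)), [0.04, 0.04, 0.04, 0.04], rtol=1e-14
        )

    def test_capping_at_one(self):
        got = cc.conditional_fdr([0.8, 0.9, 0.95], [0.01, 0.005, 0.008])
        # SNP1 raw value .8*3/1 = 2.4 -> capped
        np.testing.assert_allclose(got, [1.0, 0.9, 0.95], rtol=1e-14)

    def test_tied_p_values_share_largest_count(self):
        p = [0.1, 0.1, 0.5]
        q = [0.9, 0.9, 0.2]
        got = cc.conditional_fdr(p, q)
        np.testing.assert_array_equal(got, brute_force_cfdr(p, q))
        # both tied SNPs count each other: qc=3, joint=2 -> .1*3/2 each
        np.testing.assert_allclose(got[:2], [0.15, 0.15], rtol=1e-14)

    def test_matches_oracle_on_random_tables(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 120))
            p = rng.uniform(1e-9, 1, n)
            q = rng.uniform(1e-9, 1, n)
            if rng.random() < 0.5:  # inject ties
                p = np.round(p, 2).clip(1e-9)
                q = np.round(q, 2).clip(1e-9)
            np.testing.assert_array_equal(cc.conditional_fdr(p, q), brute_force_cfdr(p, q))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=40),
        st.data(),
    )
    def test_property_range_and_oracle(self, p, data):
        q = data.draw(
            st.lists(st.floats(min_value=1e-6, max_value=1.0),
                     min_size=len(p), max_size=len(p))
        )
        got = cc.conditional_fdr(p, q)
        assert ((got > 0) & (got <= 1)).all()
        np.testing.assert_array_equal(got, brute_force_cfdr(p, q))

    def test_permutation_invariance(self, rng):
        p = rng.uniform(1e-6, 1, 200)
        q = rng.uniform(1e-6, 1, 200)
        base = cc.conditional_fdr(p, q)
        perm = rng.permutation(200)
        np.testing.assert_array_equal(cc.conditional_fdr(p[perm], q[perm]), base[perm])

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [1.2, 0.5], [np.nan, 0.5], []])
    def test_invalid_p_rejected(self, bad):
        with pytest.raises(ValueError):
            cc.conditional_fdr(bad, [0.5] * len(bad))


class TestCcfdr:
    def test_maximum_rule(self):
        assert cc.compute_ccfdr([0.01], [0.04])[0] == 0.04

    def test_identical_inputs(self):
        x = np.array([0.2, 0.8])
        np.testing.assert_array_equal(cc.compute_ccfdr(x, x), x)

    def test_capped_value_dominates(self):
        assert cc.compute_ccfdr([1.0], [0.001])[0] == 1.0

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError):
            cc.compute_ccfdr([0.1], [0.1, 0.2])

    def test_ccfdr_at_least_each_direction(self, rng):
        a, b = rng.uniform(0, 1, 100), rng.uniform(0, 1, 100)
        ccf = cc.compute_ccfdr(a, b)
        assert (ccf >= a).all() and (ccf >= b).all()


class TestUnconditionalFdr:
    def test_hand_example(self):
        np.testing.assert_allclose(
            cc.unconditional_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4, rtol=1e-14
        )

    def test_single_p(self):
        assert cc.unconditional_fdr([0.3])[0] == pytest.approx(0.3)

    def test_equals_cfdr_with_unit_conditional(self, rng):
        p = rng.uniform(1e-6, 1, 200)
        np.testing.assert_array_equal(
            cc.unconditional_fdr(p), cc.conditional_fdr(p, np.ones(200))
        )


class TestManhattan:
    def test_reference_line_is_1_3_at_threshold_005(self):
        df, line = cc.manhattan_table([0.05], threshold=0.05)
        assert line == 1.3
        assert df["y"].iloc[0] == pytest.approx(1.30103, abs=1e-5)
        assert not df["above_line"].iloc[0]  # significance is strict

    @pytest.mark.parametrize("value,y,above", [(1.0, 0.0, False), (0.001, 3.0, True)])
    def test_log_identities(self, value, y, above):
        df, _ = cc.manhattan_table([value])
        assert df["y"].iloc[0] == pytest.approx(y)
        assert bool(df["above_line"].iloc[0]) is above

    def test_nonpositive_value_error(self):
        with pytest.raises(ValueError):
            cc.manhattan_table([0.0])


class TestCfdrTable:
    def make_merged(self, rng, n=300):
        return pd.DataFrame(
            {
                "snp_id": [f"rs{i}" for i in range(n)],
                "chrom": "1",
                "pos": np.arange(n) * 100 + 1,
                "p1": rng.uniform(1e-6, 1, n),
                "p2": rng.uniform(1e-6, 1, n),
            }
        )

    def test_invariants(self, rng):
        table = cc.cfdr_table(self.make_merged(rng))
        assert (table["ccfdr"] == np.maximum(table["cfdr_1_given_2"],
                                             table["cfdr_2_given_1"])).all()
        for col in ("cfdr_1_given_2", "cfdr_2_given_1", "ccfdr"):
            assert ((table[col] > 0) & (table[col] <= 1)).all()
        assert (table["sig_conjunction"] == (table["ccfdr"] < 0.05)).all()

    def test_monotone_flag_orders_by_p(self, rng):
        merged = self.make_merged(rng)
        table = cc.cfdr_table(merged, monotone=True)
        ordered = table.sort_values("p1")["cfdr_1_given_2"].to_numpy()
        assert (np.diff(ordered) >= 0).all()

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            cc.cfdr_table(pd.DataFrame(columns=["p1", "p2"]))
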