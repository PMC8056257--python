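import numpy as np
import pandas as pd
import pytest

from pleiocfdr import ld_tools
from pleiocfdr.ld_tools import DosagePanel, LDPairSet, compute_r2, max_r2_to_set, prune_ld


def panel_from_columns(**cols):
    ids = list(cols)
    return DosagePanel(snp_ids=ids, matrix=np.column_stack([cols[s] for s in ids]))


class TestComputeR2:
    def test_identical_vectors_give_one(self):
        ld = compute_r2(panel_from_columns(a=[0, 1, 2, 1], b=[0, 1, 2, 1]))
        assert ld.r2("a", "b") == pytest.approx(1.0)

    def test_hand_example(self):
        # cov=1/3, variances 2/3 each -> r=0.5, r2=0.25
        ld = compute_r2(panel_from_columns(a=[0, 1, 2, 1], b=[0, 1, 1, 2]))
        assert ld.r2("a", "b") == pytest.approx(0.25, abs=1e-12)

    def test_zero_variance_column_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            ld = compute_r2(panel_from_columns(a=[0, 1, 2, 1], b=[1, 1, 1, 1]))
        assert len(ld) == 0

    def test_fewer_than_two_individuals_error(self):
        with pytest.raises(ValueError, match="individuals"):
            compute_r2(DosagePanel(snp_ids=["a"], matrix=[[1.0]]))

    def test_matches_bruteforce_pearson(self, rng):
        for _ in range(5):
            X = rng.integers(0, 3, size=(30, 20)).astype(float)
            X += rng.normal(0, 0.01, X.shape)  # avoid accidental zero variance
            ids = [f"s{i}" for i in range(20)]
            ld = compute_r2(DosagePanel(snp_ids=ids, matrix=X), window_bp=None)
            for i in range(20):
                for j in range(i + 1, 20):
                    x, y = X[:, i], X[:, j]
                    r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
                        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
                    )
                    assert ld.r2(ids[i], ids[j]) == pytest.approx(r**2, abs=1e-12)

    def test_window_restricts_pairs(self):
        panel = DosagePanel(
            snp_ids=["a", "b"], matrix=[[0, 1], [1, 0], [2, 2], [1, 0]],
            chrom=np.array(["1", "1"]), pos=np.array([100, 2_000_000]),
        )
        assert len(compute_r2(panel, window_bp=1_000_000)) == 0
        assert len(compute_r2(panel, window_bp=None)) == 1


def snps_frame(mafs, chrom=None, pos=None):
    ids = sorted(mafs)
    df = pd.DataFrame({"snp_id": ids, "maf": [mafs[s] for s in ids]})
    if chrom is not None:
        df["chrom"] = chrom
        df["pos"] = pos
    return df


class TestPruneLD:
    def test_greedy_trace_example(self):
        # A-B r2=.5 removes B (maf .1 < .3); A-C r2=.25 then removes A (.3 < .4)
        snps = snps_frame({"A": 0.3, "B": 0.1, "C": 0.4})
        ld = LDPairSet.from_pairs([("A", "B", 0.5), ("A", "C", 0.25), ("B", "C", 0.1)])
        kept, removed = prune_ld(snps, ld, 0.2)
        assert kept == {"C"}
        reasons = dict(zip(removed["snp_id"], removed["reason"]))
        assert "vs A" in reasons["B"] and "vs C" in reasons["A"]

    def test_no_pair_above_threshold_keeps_all(self):
        snps = snps_frame({"A": 0.3, "B": 0.1})
        kept, removed = prune_ld(snps, LDPairSet.from_pairs([("A", "B", 0.15)]), 0.2)
        assert kept == {"A", "B"} and len(removed) == 0

    def test_threshold_is_strict(self):
        snps = snps_frame({"A": 0.3, "B": 0.1})
        kept, _ = prune_ld(snps, LDPairSet.from_pairs([("A", "B", 0.2)]), 0.2)
        assert kept == {"A", "B"}

    def test_equal_maf_removes_lexicographically_larger(self):
        snps = snps_frame({"A": 0.3, "B": 0.3})
        kept, _ = prune_ld(snps, LDPairSet.from_pairs([("A", "B", 0.9)]), 0.2)
        assert kept == {"A"}

    def test_negative_threshold_error(self):
        with pytest.raises(ValueError):
            prune_ld(snps_frame({"A": 0.3}), LDPairSet.from_pairs([]), -0.1)

    def test_kept_set_edge_free_and_idempotent_fuzzed(self, rng):
        for trial in range(25):
            n = int(rng.integers(5, 40))
            ids = [f"s{i:02d}" for i in range(n)]
            mafs = dict(zip(ids, rng.uniform(0.01, 0.5, n).round(3)))
            pairs = []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.15:
                        pairs.append((ids[i], ids[j], float(rng.random())))
            ld = LDPairSet.from_pairs(pairs)
            kept, removed = prune_ld(snps_frame(mafs), ld, 0.2)
            assert kept | set(removed["snp_id"]) == set(ids)
            assert kept.isdisjoint(set(removed["snp_id"]))
            for a, b, r2 in pairs:  # exhaustive edge-free scan
                assert not (r2 > 0.2 and a in kept and b in kept)
            sub = snps_frame({s: mafs[s] for s in kept})
            sub_ld = LDPairSet.from_pairs([p for p in pairs if p[0] in kept and p[1] in kept])
            kept2, removed2 = prune_ld(sub, sub_ld, 0.2)
            assert kept2 == kept and len(removed2) == 0

    def test_deterministic_order_uses_positions(self):
        # same MAF everywhere: B-C (earliest positions) processed first
        snps = snps_frame({"A": 0.2, "B": 0.2, "C": 0.2},
                          chrom=["1", "1", "1"], pos=[300, 100, 200])
        ld = LDPairSet.from_pairs([("A", "B", 0.9), ("B", "C", 0.9)])
        kept, _ = prune_ld(snps, ld, 0.2)
        # B-C first (pos 100 < 300): drop C; then A-B: drop B
        assert kept == {"A"}


class TestMaxR2ToSet:
    ld = LDPairSet.from_pairs([("q", "x", 0.5), ("q", "y", 0.9)])

    def test_query_in_reference_is_one(self):
        assert max_r2_to_set("q", {"q", "x"}, self.ld) == 1.0

    def test_maximum_over_pairs(self):
        assert max_r2_to_set("q", {"x", "y"}, self.ld) == 0.9

    def test_absent_pairs_default_zero(self):
        assert max_r2_to_set("nolink", {"x", "y"}, self.ld) == 0.0


class TestLDFiles:
    def test_ld_file_roundtrip(self, tmp_path):
        ld = LDPairSet.from_pairs([("b", "a", 0.5), ("a", "c", 0.9)])
        pos = pd.DataFrame({"snp_id": ["a", "b", "c"], "chrom": ["1", "1", "2"],
                            "pos": [100, 200, 300]})
        path = tmp_path / "pairs.ld"
        ld_tools.write_ld_file(ld, path, positions=pos)
        again = ld_tools.read_ld_file(path)
        assert again.r2("a", "b") == 0.5 and again.r2("c", "a") == 0.9
        assert again.source == "file"

    def test_missing_columns_error(self, tmp_path):
        path = tmp_path / "bad.ld"
        path.write_text("SNP_A SNP_B\nx y\n")
        with pytest.raises(KeyError):
            ld_tools.read_ld_file(path)

    def test_dosage_panel_roundtrip(self, tmp_path):
        panel = DosagePanel(snp_ids=["a", "b"], matrix=[[0.0, 2.0], [1.0, 1.0]])
        ld_tools.write_dosage_panel(panel, tmp_path / "panel.tsv")
        again = ld_tools.read_dosage_panel(tmp_path / "panel.tsv")
        assert again.snp_ids == ["a", "b"]
        np.testing.assert_array_equal(again.matrix, panel.matrix)
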