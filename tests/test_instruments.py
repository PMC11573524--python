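"""Instrument selection: cis window, clumping, exclusion, F statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrmediate.instruments import (ClumpParams, GeneRegion, LdMatrix,
                                   clump, exclude_confounder_snps,
                                   f_statistics, read_blocklist,
                                   read_ld_matrix, select_cis_snps)

from conftest import make_table

REGION = GeneRegion("GENE", "1", 1_000_000, 1_050_000, flank_kb=100.0)


class TestSelectCis:
    def test_window_boundaries_inclusive(self):
        lo, hi = REGION.window
        table = make_table([
            {"snp_id": "at_lo", "pos": lo},
            {"snp_id": "below", "pos": lo - 1},
            {"snp_id": "at_hi", "pos": hi},
            {"snp_id": "above", "pos": hi + 1},
        ])
        kept = select_cis_snps(table, REGION)
        assert sorted(kept.df["snp_id"]) == ["at_hi", "at_lo"]

    def test_pvalue_threshold_strict(self):
        table = make_table([
            {"snp_id": "at", "pval": 5e-8},
            {"snp_id": "under", "pval": 4.999e-8},
        ])
        kept = select_cis_snps(table, REGION, p_threshold=5e-8)
        assert list(kept.df["snp_id"]) == ["under"]

    def test_toy_table_manual_filter(self):
        # oracle: row-by-row manual filter of a printed 6-SNP table
        lo, hi = REGION.window
        table = make_table([
            {"snp_id": "s1", "pos": lo + 10, "pval": 1e-9},   # keep
            {"snp_id": "s2", "pos": lo + 20, "pval": 1e-3},   # p fails
            {"snp_id": "s3", "pos": hi - 10, "pval": 1e-12},  # keep
            {"snp_id": "s4", "pos": hi + 99, "pval": 1e-12},  # window fails
            {"snp_id": "s5", "pos": lo + 30, "pval": 1e-8},   # keep
            {"snp_id": "s6", "pos": lo + 40, "pval": 1e-9,
             "chrom": "2"},                                   # chrom fails
        ])
        kept = select_cis_snps(table, REGION)
        assert sorted(kept.df["snp_id"]) == ["s1", "s3", "s5"]

    def test_eaf_filter_literal_and_strict(self):
        table = make_table([
            {"snp_id": "common", "eaf": 0.30},
            {"snp_id": "rare_ea", "eaf": 0.005},
            {"snp_id": "rare_oa", "eaf": 0.995},
        ])
        literal = select_cis_snps(table, REGION, eaf_min=0.01)
        assert sorted(literal.df["snp_id"]) == ["common", "rare_oa"]
        strict = select_cis_snps(table, REGION, eaf_min=0.01,
                                 strict_maf=True)
        assert list(strict.df["snp_id"]) == ["common"]

    def test_raising_p_threshold_never_shrinks(self):
        table = make_table([{"snp_id": f"s{i}", "pval": 10.0**-i}
                            for i in range(1, 12)])
        sizes = [len(select_cis_snps(table, REGION, p_threshold=p))
                 for p in (1e-10, 1e-8, 1e-4, 1e-2)]
        assert sizes == sorted(sizes)


def ld_from_pairs(snp_ids, pairs):
    n = len(snp_ids)
    idx = {s: i for i, s in enumerate(snp_ids)}
    mat = np.eye(n)
    for a, b, r2 in pairs:
        mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = r2
    return LdMatrix(snp_ids, mat)


def assert_ld_valid(inst, ld):
    """Exhaustive pairwise check of the clumping invariant."""
    for a, b in itertools.combinations(inst.snp_ids, 2):
        assert ld.lookup(a, b) <= inst.r2_applied + 1e-12


class TestClump:
    def test_dominant_snp_wins(self):
        table = make_table([{"snp_id": "a", "pval": 1e-10, "pos": 100},
                            {"snp_id": "b", "pval": 1e-9, "pos": 200}])
        ld = ld_from_pairs(["a", "b"], [("a", "b", 0.9)])
        inst = clump(table, ld, ClumpParams(min_snps=1))
        assert inst.snp_ids == ["a"]
        assert_ld_valid(inst, ld)

    def test_independent_snps_all_retained(self):
        table = make_table([{"snp_id": s, "pos": p}
                            for s, p in (("a", 100), ("b", 200), ("c", 300))])
        ld = ld_from_pairs(["a", "b", "c"], [])
        inst = clump(table, ld, ClumpParams())
        assert sorted(inst.snp_ids) == ["a", "b", "c"]
        assert inst.r2_applied == 0.3

    def test_adaptive_fallback_branch(self):
        """5-SNP chain: r2<0.3 leaves 2 survivors (< min_snps=3), so the
        run falls back to r2<0.4 which yields 3; both branches checked
        against the exhaustive pairwise oracle."""
        snps = ["s1", "s2", "s3", "s4", "s5"]
        table = make_table([{"snp_id": s, "pval": 10.0**-(10 - i),
                             "pos": 100 * (i + 1)}
                            for i, s in enumerate(snps)])
        # at 0.3 the index s1 removes s2/s3/s4, leaving {s1, s5};
        # at 0.4 s3 survives s1 (0.35) and tolerates s5 (0.38)
        pairs = [("s1", "s2", 0.50), ("s1", "s3", 0.35),
                 ("s1", "s4", 0.45), ("s1", "s5", 0.20),
                 ("s3", "s4", 0.45), ("s3", "s5", 0.38)]
        ld = ld_from_pairs(snps, pairs)
        params = ClumpParams(r2_primary=0.3, r2_fallback=0.4, min_snps=3)

        primary = clump(table, ld, ClumpParams(r2_primary=0.3,
                                               r2_fallback=0.3, min_snps=1))
        assert len(primary) == 2
        assert_ld_valid(primary, ld)

        inst = clump(table, ld, params)
        assert len(inst) == 3
        assert inst.r2_applied == 0.4
        assert_ld_valid(inst, ld)

    def test_three_survivors_do_not_trigger_fallback(self):
        # |set| == min_snps at the primary threshold stands
        snps = ["a", "b", "c", "d"]
        table = make_table([{"snp_id": s, "pval": 10.0**-(9 - i),
                             "pos": 100 * (i + 1)}
                            for i, s in enumerate(snps)])
        ld = ld_from_pairs(snps, [("a", "b", 0.9)])
        inst = clump(table, ld, ClumpParams())
        assert len(inst) == 3
        assert inst.r2_applied == 0.3

    def test_row_order_invariance(self):
        rng = np.random.default_rng(7)
        snps = [f"s{i}" for i in range(8)]
        pairs = [(a, b, float(rng.uniform(0, 1)))
                 for a, b in itertools.combinations(snps, 2)]
        ld = ld_from_pairs(snps, pairs)
        rows = [{"snp_id": s, "pval": float(rng.uniform(1e-12, 1e-8)),
                 "pos": 100 * (i + 1)} for i, s in enumerate(snps)]
        baseline = clump(make_table(rows), ld, ClumpParams()).snp_ids
        for seed in range(3):
            shuffled = list(rows)
            np.random.default_rng(seed).shuffle(shuffled)
            assert clump(make_table(shuffled), ld,
                         ClumpParams()).snp_ids == baseline

    @given(st.integers(0, 2**31 - 1))
    def test_ld_validity_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 10))
        snps = [f"s{i}" for i in range(n)]
        # random correlation-like symmetric r2 matrix
        mat = rng.uniform(0, 1, (n, n))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 1.0)
        ld = LdMatrix(snps, mat)
        rows = [{"snp_id": s, "pval": float(rng.uniform(1e-12, 1e-8)),
                 "pos": int(100 * (i + 1))} for i, s in enumerate(snps)]
        inst = clump(make_table(rows), ld,
                     ClumpParams(r2_primary=0.3, r2_fallback=0.6,
                                 min_snps=2))
        assert len(inst) >= 1
        assert_ld_valid(inst, ld)

    def test_window_limits_removal(self):
        # high r2 but farther apart than the window -> both kept
        table = make_table([{"snp_id": "a", "pval": 1e-10, "pos": 100},
                            {"snp_id": "b", "pval": 1e-9,
                             "pos": 100 + 11_000_000}])
        ld = ld_from_pairs(["a", "b"], [("a", "b", 0.9)])
        inst = clump(table, ld, ClumpParams(min_snps=1, window_kb=10_000))
        assert sorted(inst.snp_ids) == ["a", "b"]

    def test_missing_ld_entry_is_error(self):
        table = make_table([{"snp_id": "a"}, {"snp_id": "zzz"}])
        ld = ld_from_pairs(["a"], [])
        with pytest.raises(ValueError, match="zzz"):
            clump(table, ld, ClumpParams())


class TestExcludeConfounders:
    def make_inst(self):
        table = make_table([{"snp_id": "a"}, {"snp_id": "b"},
                            {"snp_id": "c"}])
        ld = ld_from_pairs(["a", "b", "c"], [])
        return clump(table, ld, ClumpParams()), table

    def test_disjoint_blocklist_is_noop(self):
        inst, _ = self.make_inst()
        block = pd.DataFrame({"snp_id": ["x"], "trait": ["bmi"]})
        out = exclude_confounder_snps(inst, block)
        assert out.snp_ids == inst.snp_ids

    def test_overlap_removed_with_provenance(self):
        inst, _ = self.make_inst()
        block = pd.DataFrame({"snp_id": ["b"], "trait": ["smoking"]})
        out = exclude_confounder_snps(inst, block)
        assert sorted(out.snp_ids) == ["a", "c"]
        assert out.provenance["confounder_removed"] == 1

    def test_all_blocklisted_gives_empty_set(self):
        inst, _ = self.make_inst()
        block = pd.DataFrame({"snp_id": ["a", "b", "c"],
                              "trait": ["bmi"] * 3})
        out = exclude_confounder_snps(inst, block)
        assert out.snp_ids == []


class TestFStatistics:
    def test_closed_form_and_mean(self):
        table = make_table([
            {"snp_id": "a", "beta": 0.1, "se": 0.01},    # F = 100
            {"snp_id": "b", "beta": 0.05, "se": 0.01},   # F = 25
            {"snp_id": "c", "beta": 0.2, "se": 0.01},    # F = 400
        ])
        inst = f_statistics(table)
        assert inst.f_stats["a"] == pytest.approx(100.0)
        assert inst.mean_f == pytest.approx(175.0)
        assert not inst.weak_instrument_flag

    def test_zero_beta_flags_weak(self):
        table = make_table([{"snp_id": "a", "beta": 0.0}])
        inst = f_statistics(table)
        assert inst.f_stats["a"] == 0.0
        assert inst.weak_instrument_flag


class TestFileReaders:
    def test_ld_long_and_square_agree(self, tmp_path):
        long_path = tmp_path / "ld_long.tsv"
        pd.DataFrame({"snp_a": ["a", "a"], "snp_b": ["b", "c"],
                      "r2": [0.5, 0.1]}).to_csv(long_path, sep="\t",
                                                index=False)
        ld_long = read_ld_matrix(long_path)

        sq = pd.DataFrame(np.eye(3), index=["a", "b", "c"],
                          columns=["a", "b", "c"])
        sq.loc["a", "b"] = sq.loc["b", "a"] = 0.5
        sq.loc["a", "c"] = sq.loc["c", "a"] = 0.1
        sq_path = tmp_path / "ld_sq.tsv"
        sq.to_csv(sq_path, sep="\t")
        ld_sq = read_ld_matrix(sq_path)

        for x, y in itertools.combinations("abc", 2):
            assert ld_long.lookup(x, y) == ld_sq.lookup(x, y)

    def test_blocklist_reader(self, tmp_path):
        path = tmp_path / "block.tsv"
        pd.DataFrame({"snp_id": ["rs1"], "trait": ["bmi"]}).to_csv(
            path, sep="\t", index=False)
        assert read_blocklist(path).loc[0, "trait"] == "bmi"
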