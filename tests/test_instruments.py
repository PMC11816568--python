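import numpy as np
import pandas as pd
import pytest

from mrchain import (
    ClumpConfig,
    LDTable,
    build_instrument_set,
    exclude_confounded,
    f_statistic,
    ld_clump,
    select_by_pvalue,
)
from mrchain.instruments import f_statistic_variance_explained

from conftest import make_records


def _rec(snp, chrom, pos, beta=0.1, se=0.02, p=1e-8, eaf=0.3, n=5000):
    return (snp, str(chrom), pos, "A", "G", eaf, beta, se, p, n)


class TestPValueFilter:
    def test_strict_threshold(self):
        df = make_records(
            [_rec("rs1", 1, 100, p=1e-6), _rec("rs2", 1, 200, p=2e-5), _rec("rs3", 1, 300, p=1e-8)]
        )
        out = select_by_pvalue(df, 1e-5)
        assert list(out["SNP"]) == ["rs1", "rs3"]

    def test_threshold_one_keeps_all(self):
        df = make_records([_rec("rs1", 1, 100, p=0.99), _rec("rs2", 1, 200, p=0.5)])
        assert len(select_by_pvalue(df, 1.0)) == 2

    def test_null_snps_rarely_pass(self):
        # 1000 uniform p-values against 1e-5: expected Binomial(1000, 1e-5) hits
        rng = np.random.default_rng(7)
        df = make_records(
            [_rec(f"rs{i}", 1, 100 + i, p=float(rng.uniform())) for i in range(1000)]
        )
        assert len(select_by_pvalue(df, 1e-5)) == 0


class TestClump:
    def test_hand_traced_greedy(self):
        # rs2 is in LD with the stronger rs1 and must go; rs3 is independent.
        df = make_records(
            [
                _rec("rs1", 1, 1000, p=1e-9),
                _rec("rs2", 1, 1500, p=1e-7),
                _rec("rs3", 1, 2000, p=1e-6),
            ]
        )
        ld = LDTable([("rs1", "rs2", 0.5), ("rs1", "rs3", 0.0001), ("rs2", "rs3", 0.0001)])
        out = ld_clump(df, ld, ClumpConfig())
        assert list(out["SNP"]) == ["rs1", "rs3"]

    def test_different_chromosomes_all_retained(self):
        df = make_records([_rec("rs1", 1, 1000, p=1e-9), _rec("rs2", 2, 1000, p=1e-8)])
        ld = LDTable([("rs1", "rs2", 0.99)])
        assert len(ld_clump(df, ld, ClumpConfig())) == 2

    def test_window_boundary_exclusive_beyond(self):
        # 10,001 kb apart: outside the inclusive 10,000 kb window, r2 ignored
        df = make_records(
            [_rec("rs1", 1, 1000, p=1e-9), _rec("rs2", 1, 1000 + 10_001_000, p=1e-8)]
        )
        ld = LDTable([("rs1", "rs2", 0.9)])
        assert len(ld_clump(df, ld, ClumpConfig())) == 2

    def test_unknown_r2_within_window_drops_weaker(self):
        df = make_records([_rec("rs1", 1, 1000, p=1e-9), _rec("rs2", 1, 2000, p=1e-8)])
        out, log = ld_clump(df, LDTable(), ClumpConfig(), return_log=True)
        assert list(out["SNP"]) == ["rs1"]
        assert "unknown" in log["rs2"]

    def test_retained_pairwise_constraint(self):
        # random instance with a complete LD table: no retained in-window pair
        # may exceed r2_max
        rng = np.random.default_rng(3)
        n = 15
        df = make_records(
            [_rec(f"rs{i}", 1, 1000 + i * 500, p=float(rng.uniform(1e-9, 1e-6))) for i in range(n)]
        )
        ld = LDTable()
        for i in range(n):
            for j in range(i + 1, n):
                ld.add(f"rs{i}", f"rs{j}", float(rng.uniform(0, 0.004)))
        cfg = ClumpConfig(r2_max=0.002)
        out = ld_clump(df, ld, cfg)
        kept = list(out["SNP"])
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                assert ld.r2(a, b) <= cfg.r2_max


class TestFStatistic:
    def test_arithmetic(self):
        assert f_statistic(0.1, 0.02) == pytest.approx(25.0)
        assert f_statistic(0.03, 0.02) == pytest.approx(2.25)

    def test_equals_squared_z(self):
        rng = np.random.default_rng(0)
        beta, se = rng.normal(0, 1, 50), rng.uniform(0.01, 1, 50)
        np.testing.assert_allclose(f_statistic(beta, se), (beta / se) ** 2)
        assert (f_statistic(beta, se) >= 0).all()

    def test_variance_explained_form(self):
        # moderate effect: both forms agree on the order of magnitude
        f = f_statistic_variance_explained(0.1, 0.3, 5000)
        r2 = 2 * 0.3 * 0.7 * 0.01
        assert f == pytest.approx((5000 - 2) * r2 / (1 - r2))


class TestBlacklistFilter:
    def test_empty_blacklist_identity(self, toy_records):
        out = exclude_confounded(toy_records, None)
        pd.testing.assert_frame_equal(out, toy_records.reset_index(drop=True))

    def test_single_exclusion_logged(self, toy_records):
        bl = pd.DataFrame({"SNP": ["rs2"], "TRAIT": ["smoking"]})
        out, log = exclude_confounded(toy_records, bl, return_log=True)
        assert list(out["SNP"]) == ["rs1", "rs3"]
        assert "smoking" in log["rs2"]

    def test_duplicate_entries_removed_once_both_traits_logged(self, toy_records):
        bl = pd.DataFrame({"SNP": ["rs2", "rs2"], "TRAIT": ["smoking", "BMI"]})
        out, log = exclude_confounded(toy_records, bl, return_log=True)
        assert list(out["SNP"]) == ["rs1", "rs3"]
        assert "smoking" in log["rs2"] and "BMI" in log["rs2"]


class TestBuildInstrumentSet:
    def _fixture(self):
        # engineered so each filter drops exactly one of five SNPs
        df = make_records(
            [
                _rec("rs_keep", 1, 1000, beta=0.2, se=0.02, p=1e-9),
                _rec("rs_p", 1, 200_000, beta=0.2, se=0.02, p=0.5),  # p filter
                _rec("rs_ld", 1, 2000, beta=0.2, se=0.02, p=1e-8),  # clumped vs rs_keep
                _rec("rs_weak", 2, 1000, beta=0.02, se=0.02, p=1e-6),  # F = 1
                _rec("rs_conf", 3, 1000, beta=0.2, se=0.02, p=1e-9),  # blacklisted
            ]
        )
        ld = LDTable(
            [
                ("rs_keep", "rs_ld", 0.8),
                ("rs_keep", "rs_p", 0.0),
                ("rs_ld", "rs_p", 0.0),
            ]
        )
        bl = pd.DataFrame({"SNP": ["rs_conf"], "TRAIT": ["BMI"]})
        return df, ld, bl

    def test_each_filter_drops_one(self):
        df, ld, bl = self._fixture()
        iset = build_instrument_set(df, ld, bl, ClumpConfig())
        assert iset.status == "ok"
        assert list(iset.records["SNP"]) == ["rs_keep"]
        dropped = iset.provenance.set_index("SNP")
        assert dropped.loc["rs_p", "rule"] == "p_threshold"
        assert dropped.loc["rs_ld", "rule"] == "ld_clump"
        assert dropped.loc["rs_weak", "rule"] == "f_statistic"
        assert dropped.loc["rs_conf", "rule"] == "blacklist"
        assert (dropped["status"] == "dropped").sum() == 4

    def test_f_exactly_at_bound_is_kept(self):
        # F = (beta/se)^2 = 10 exactly: the rule drops only F *below* 10
        beta = 0.02 * np.sqrt(10.0)
        df = make_records([_rec("rs1", 1, 1000, beta=beta, se=0.02, p=1e-9)])
        iset = build_instrument_set(df, LDTable(), None, ClumpConfig())
        assert list(iset.records["SNP"]) == ["rs1"]

    def test_all_null_gives_insufficient_status(self):
        df = make_records([_rec("rs1", 1, 1000, p=0.5), _rec("rs2", 2, 1000, p=0.9)])
        iset = build_instrument_set(df, LDTable(), None, ClumpConfig())
        assert iset.status == "insufficient_instruments"
        assert iset.n_snp == 0

    def test_order_independence(self):
        df, ld, bl = self._fixture()
        base = build_instrument_set(df, ld, bl, ClumpConfig())
        rng = np.random.default_rng(1)
        for _ in range(5):
            perm = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
            out = build_instrument_set(perm, ld, bl, ClumpConfig())
            assert list(out.records["SNP"]) == list(base.records["SNP"])

    def test_monotone_in_p_threshold(self):
        # Block LD (high within, negligible across): relaxing the p-threshold
        # can only add clump representatives, never lose one.
        rng = np.random.default_rng(5)
        n, block_size = 30, 3
        df = make_records(
            [
                _rec(f"rs{i}", 1, 1000 + i * 400, p=float(rng.uniform(1e-9, 1e-3)))
                for i in range(n)
            ]
        )
        ld = LDTable()
        for i in range(n):
            for j in range(i + 1, n):
                same_block = i // block_size == j // block_size
                ld.add(f"rs{i}", f"rs{j}", 0.8 if same_block else 0.0001)
        sizes = [
            build_instrument_set(df, ld, None, ClumpConfig(p_threshold=t)).n_snp
            for t in (1e-8, 1e-6, 1e-4, 1e-2)
        ]
        assert sizes == sorted(sizes)
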