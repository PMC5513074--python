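import numpy as np
import pandas as pd
import pytest

from riboxi import diffcall as dc
from riboxi import endcount as ec


def nb_counts(rng, mean, alpha, size):
    """Negative-binomial draws parameterized by mean and dispersion alpha."""
    if alpha <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def make_matrix(counts, n_ctrl=3, n_oxi=3):
    samples = [f"control_{i+1}" for i in range(n_ctrl)] + [
        f"oxidized_{i+1}" for i in range(n_oxi)
    ]
    design = pd.DataFrame(
        {
            "sample": samples,
            "condition": ["control"] * n_ctrl + ["oxidized"] * n_oxi,
            "replicate": list(range(1, n_ctrl + 1)) + list(range(1, n_oxi + 1)),
        }
    )
    df = pd.DataFrame(counts, columns=samples, index=pd.RangeIndex(1, len(counts) + 1, name="pos"))
    return ec.EndCountMatrix(reference_name="ref", counts=df, design=design)


def oracle_median_of_ratios(K):
    """Independent loop-based median-of-ratios implementation."""
    K = np.asarray(K, dtype=float)
    gms = []
    for row in K:
        if (row > 0).all():
            gms.append((row, np.exp(np.mean(np.log(row)))))
    out = []
    for j in range(K.shape[1]):
        ratios = [row[j] / gm for row, gm in gms]
        out.append(np.median(ratios))
    return np.array(out)


def oracle_bh(p):
    """Sort-based step-up BH formula."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adj[i] = running_min
    return adj


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        rng = np.random.default_rng(1)
        col = rng.integers(1, 100, size=200)
        K = np.column_stack([col] * 6)
        sf = dc.size_factors(make_matrix(K).counts)
        assert np.allclose(sf.factors, 1.0)
        assert sf.method == "median_of_ratios"

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(2)
        K = rng.integers(1, 100, size=(300, 6))
        K2 = K.copy()
        K2[:, 0] *= 2
        sf = dc.size_factors(make_matrix(K2).counts).factors.to_numpy()
        assert sf[0] / sf[1] == pytest.approx(
            2 * dc.size_factors(make_matrix(K).counts).factors.iloc[0]
            / dc.size_factors(make_matrix(K).counts).factors.iloc[1],
            rel=1e-9,
        )

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(3)
        K = nb_counts(rng, 50, 0.2, (500, 6)) + 1
        sf = dc.size_factors(make_matrix(K).counts).factors.to_numpy()
        assert np.allclose(sf, oracle_median_of_ratios(K))

    def test_matches_pydeseq2(self):
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet

        rng = np.random.default_rng(4)
        K = nb_counts(rng, 80, 0.1, (200, 6)) + 1
        matrix = make_matrix(K)
        sf = dc.size_factors(matrix.counts).factors.to_numpy()
        meta = matrix.design.set_index("sample")[["condition"]]
        dds = DeseqDataSet(
            counts=matrix.counts.T, metadata=meta, design="~condition", quiet=True
        )
        dds.fit_size_factors()
        assert np.allclose(sf, dds.obs["size_factors"].to_numpy(), rtol=1e-6)

    def test_sparse_matrix_uses_library_size_fallback(self):
        K = np.zeros((100, 6), dtype=int)
        K[:5] = [[10, 20, 30, 1, 2, 3]] * 5  # only 5 all-positive positions
        K[50, 0] = 100
        sf = dc.size_factors(make_matrix(K).counts)
        assert sf.method == "library_size"

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            dc.size_factors(make_matrix(np.zeros((50, 6), dtype=int)).counts)


class TestDispersion:
    def test_poisson_counts_give_small_dispersion(self):
        rng = np.random.default_rng(5)
        K = rng.poisson(100, size=(2000, 6))
        m = make_matrix(K)
        sf = dc.size_factors(m.counts)
        model = dc.estimate_dispersion(m, sf)
        assert np.median(model.final) <= 0.01

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(6)
        K = nb_counts(rng, 100, 0.2, (2000, 6))
        m = make_matrix(K)
        model = dc.estimate_dispersion(m, dc.size_factors(m.counts))
        raw_med = np.nanmedian(model.raw)
        assert 0.1 <= raw_med <= 0.4

    def test_constant_counts_hit_floor(self):
        K = np.full((60, 6), 50)
        m = make_matrix(K)
        model = dc.estimate_dispersion(m, dc.size_factors(m.counts))
        assert (model.raw == 0).all()
        assert (model.final >= dc.DISPERSION_FLOOR).all()

    def test_no_replication_falls_back(self):
        rng = np.random.default_rng(7)
        K = rng.poisson(50, size=(100, 2))
        m = make_matrix(K, n_ctrl=1, n_oxi=1)
        with pytest.warns(UserWarning, match="fallback"):
            model = dc.estimate_dispersion(m, dc.size_factors(m.counts))
        assert np.allclose(model.final, dc.FALLBACK_DISPERSION)


class TestWald:
    def test_equal_means_give_null_result(self):
        K = np.full((100, 6), 64)
        res = dc.wald_test(make_matrix(K))
        assert np.allclose(res["log2fc"], 0.0)
        assert (res["pvalue"].dropna() > 0.9).all()

    def test_zero_control_prior_formula(self):
        # oxidized mean 256 vs all-zero control with prior 0.5:
        # log2fc = log2(256.5 / 0.5) ~ 9.0
        K = np.zeros((60, 6), dtype=int)
        rng = np.random.default_rng(8)
        K[:, 3:] = 256
        K[0:50, :3] = rng.integers(20, 40, size=(50, 3))  # background rows
        m = make_matrix(K)
        sf = dc.SizeFactors(factors=pd.Series(1.0, index=m.counts.columns), method="library_size")
        res = dc.wald_test(m, sf=sf)
        target = res.iloc[55]
        assert target["baseMean_ctrl"] == 0
        assert target["log2fc"] == pytest.approx(np.log2(256.5 / 0.5), abs=1e-9)

    def test_low_count_positions_excluded_from_testing(self):
        K = np.zeros((50, 6), dtype=int)
        K[0] = [50, 60, 55, 70, 65, 60]
        K[1] = [1, 0, 0, 1, 0, 0]  # total 2 < 10
        res = dc.wald_test(make_matrix(K))
        assert np.isnan(res.loc[res["pos"] == 2, "pvalue"]).all()
        assert not np.isnan(res.loc[res["pos"] == 1, "pvalue"]).any()

    def test_null_type_i_error_roughly_nominal(self):
        rng = np.random.default_rng(9)
        mu = rng.lognormal(np.log(100), 0.4, size=5000)
        K = np.column_stack([nb_counts(rng, mu, 0.1, 5000) for _ in range(6)])
        res = dc.wald_test(make_matrix(K))
        p = res["pvalue"].dropna()
        frac = (p < 0.05).mean()
        assert 0.02 <= frac <= 0.08

    def test_monotonicity_in_oxidized_count(self):
        # raising the oxidized count at one position never lowers its log2fc
        rng = np.random.default_rng(10)
        base = nb_counts(rng, 50, 0.1, (200, 6))
        m0 = make_matrix(base)
        sf = dc.size_factors(m0.counts)
        disp = dc.estimate_dispersion(m0, sf)
        prev = -np.inf
        for bump in (0, 10, 100, 1000):
            K = base.copy()
            K[17, 3] += bump
            res = dc.wald_test(make_matrix(K), sf=sf, dispersions=disp)
            lfc = res.loc[res["pos"] == 18, "log2fc"].iloc[0]
            assert lfc >= prev
            prev = lfc

    def test_sample_scaling_leaves_lfc_invariant(self):
        rng = np.random.default_rng(11)
        K = nb_counts(rng, 200, 0.05, (400, 6)) + 100
        m1 = make_matrix(K)
        K2 = K.copy()
        K2[:, 0] *= 3
        m2 = make_matrix(K2)
        r1 = dc.wald_test(m1)
        r2 = dc.wald_test(m2)
        assert np.abs(r1["log2fc"] - r2["log2fc"]).max() < 0.01


class TestBH:
    def test_worked_example(self):
        assert np.allclose(dc.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert dc.bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_equal_p_unchanged(self):
        assert np.allclose(dc.bh_adjust([0.4] * 10), 0.4)

    def test_nan_passthrough(self):
        out = dc.bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        # NaN does not count toward the number of tests
        assert np.allclose(out[[0, 2]], dc.bh_adjust([0.01, 0.04]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dc.bh_adjust([0.5, 1.5])

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            p = rng.random(rng.integers(1, 200))
            assert np.allclose(dc.bh_adjust(p), oracle_bh(p))

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(13)
        for _ in range(20):
            p = rng.random(100) ** 2
            assert np.allclose(dc.bh_adjust(p), sm.multipletests(p, method="fdr_bh")[1])

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(14)
        p = rng.random(500)
        assert (dc.bh_adjust(p) >= p - 1e-12).all()


class TestCallSites:
    @staticmethod
    def frame(lfc, padj):
        return pd.DataFrame(
            {"pos": [1], "base": ["A"], "baseMean_ctrl": [0.0], "baseMean_oxi": [100.0],
             "log2fc": [lfc], "se": [0.1], "pvalue": [padj], "padj": [padj]}
        )

    @pytest.mark.parametrize(
        "lfc,padj,tier",
        [
            (10.0, 1.5e-13, "high_confidence"),
            (6.5, 1e-5, "relaxed"),
            (8.0, 0.01, "none"),
            (7.0, 1e-9, "relaxed"),  # strict '>' boundary for the high tier
            (6.0, 1e-9, "none"),  # strict '>' boundary for the relaxed tier
            (5.9, 1e-9, "none"),
        ],
    )
    def test_tier_thresholds(self, lfc, padj, tier):
        out = dc.call_sites(self.frame(lfc, padj))
        assert out["tier"].iloc[0] == tier

    def test_high_confidence_subset_of_relaxed(self):
        rng = np.random.default_rng(15)
        frames = pd.concat(
            [self.frame(lfc, padj) for lfc, padj in zip(rng.uniform(0, 12, 100), rng.random(100) * 1e-3)]
        )
        out = dc.call_sites(frames.reset_index(drop=True))
        high = out["tier"] == "high_confidence"
        relaxed_mask = (out["log2fc"] > 6) & (out["padj"] < 1e-4)
        assert (relaxed_mask[high]).all()


class TestBackToBack:
    @staticmethod
    def calls(rows):
        return pd.DataFrame(rows, columns=["pos", "tier"])

    def test_masked_upstream_site_flagged(self):
        # planted pair (p, p+1), downstream fully methylated: p uncalled
        calls = self.calls([(100, "none"), (101, "high_confidence")])
        out = dc.annotate_backtoback(calls, [100, 101])
        assert out.loc[out["pos"] == 100, "backtoback_flag"].iloc[0] == "possibly_masked"

    def test_both_called_pair_flagged_masking_possible_only(self):
        calls = self.calls([(200, "high_confidence"), (201, "high_confidence")])
        out = dc.annotate_backtoback(calls, [200, 201])
        assert out.loc[out["pos"] == 200, "backtoback_flag"].iloc[0] == "masking_possible"
        assert out.loc[out["pos"] == 201, "backtoback_flag"].iloc[0] == ""

    def test_isolated_site_unflagged(self):
        out = dc.annotate_backtoback(self.calls([(300, "high_confidence")]), [300])
        assert out["backtoback_flag"].iloc[0] == ""


class TestEvaluate:
    @staticmethod
    def calls(tiers):
        return pd.DataFrame({"pos": list(range(1, len(tiers) + 1)), "tier": tiers})

    def test_perfect_recovery(self):
        calls = self.calls(["high_confidence"] * 5)
        summary, table = dc.evaluate_against_known(calls, [1, 2, 3, 4, 5])
        assert summary["sensitivity"] == 1.0
        assert summary["novel_count"] == 0

    def test_missed_site_listed(self):
        calls = self.calls(["high_confidence", "none", "high_confidence"])
        summary, table = dc.evaluate_against_known(calls, [1, 2, 3])
        assert summary["missed"] == [2]
        assert set(table.loc[table["status"] == "missed", "pos"]) == {2}

    def test_novel_counted(self):
        calls = self.calls(["high_confidence", "high_confidence"])
        summary, _ = dc.evaluate_against_known(calls, [1])
        assert summary["novel_count"] == 1

    def test_empty_known_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            dc.evaluate_against_known(self.calls(["none"]), [])
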