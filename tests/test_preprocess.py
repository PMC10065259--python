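import subprocess
import sys

import numpy as np
import pytest
from scipy.stats import rankdata

import momfa
from momfa.preprocess import cpm
from momfa.types import MomfaError


def make_counts(values, name="v"):
    values = np.asarray(values, dtype=float)
    return momfa.OmicView(
        name,
        [f"G{i + 1}" for i in range(values.shape[0])],
        [f"s{j + 1}" for j in range(values.shape[1])],
        values,
        "counts",
    )


class TestLowExpressionFilter:
    def test_all_zero_gene_removed(self):
        v = make_counts([[0, 0], [5, 5], [100, 100]])
        out = momfa.filter_low_expression(v, 5, 0.1)
        assert "G1" not in out.feature_ids

    def test_boundary_fraction_inclusive(self):
        # 10 samples; gene crosses 5 cpm in exactly one sample: 1/10 >= 0.10
        counts = np.ones((2, 10)) * 1000
        gene = np.zeros(10)
        gene[0] = 11  # lib ~2011, cpm ~5470 >= 5 in that sample only
        counts = np.vstack([counts, gene])
        v = make_counts(counts)
        out = momfa.filter_low_expression(v, 5, 0.10)
        assert "G3" in out.feature_ids

    def test_zero_min_cpm_keeps_everything(self):
        v = make_counts([[0, 1], [2, 3]])
        out = momfa.filter_low_expression(v, 0, 0.5)
        assert out.feature_ids == v.feature_ids

    def test_empty_result_warns(self):
        v = make_counts([[1, 1], [1, 1]])
        with pytest.warns(UserWarning, match="removed every feature"):
            momfa.filter_low_expression(v, 1e9, 1.0)

    def test_order_preserved(self):
        rng = np.random.default_rng(0)
        v = make_counts(rng.integers(0, 50, (40, 6)))
        out = momfa.filter_low_expression(v, 5, 0.5)
        kept = [f for f in v.feature_ids if f in set(out.feature_ids)]
        assert out.feature_ids == kept


class TestTMM:
    def test_identical_samples_unit_factors(self):
        v = make_counts(np.tile([[10], [20], [30]], (1, 2)))
        np.testing.assert_allclose(momfa.tmm_factors(v), [1.0, 1.0])

    def test_pure_depth_difference_unit_factors(self):
        a = np.array([10.0, 20, 30, 40])
        v = make_counts(np.column_stack([a, 2 * a]))
        np.testing.assert_allclose(momfa.tmm_factors(v), [1.0, 1.0])

    def test_all_zero_sample_rejected(self):
        v = make_counts([[0, 1], [0, 2]])
        with pytest.raises(MomfaError, match="s1"):
            momfa.tmm_factors(v)

    def test_spiked_toy_matches_hand_computation(self):
        # 6 genes, 3 samples, one gene spiked 8-fold in sample 3;
        # oracle below recomputes M/A, rank trimming, and precision
        # weights from their definitions
        counts = np.array(
            [
                [100, 110, 95],
                [200, 190, 210],
                [50, 55, 45],
                [400, 420, 380],
                [80, 85, 640],  # spiked in s3
                [150, 160, 140],
            ],
            dtype=float,
        )
        v = make_counts(counts)
        got = momfa.tmm_factors(v)
        expected = _tmm_oracle(counts, trim_m=0.30, trim_a=0.05)
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_matches_edger_reference(self, tmp_path):
        # independent cross-check against the Bioconductor implementation
        rng = np.random.default_rng(42)
        x = rng.negative_binomial(5, 0.01, size=(300, 5)).astype(float)
        x[:50, 2] *= 4
        v = make_counts(x)
        ours = momfa.tmm_factors(v)
        mat = tmp_path / "counts.tsv"
        np.savetxt(mat, x, fmt="%d", delimiter="\t")
        script = (
            "suppressMessages(library(edgeR));"
            f"x <- as.matrix(read.table('{mat}', sep='\\t'));"
            "cat(sprintf('%.12f', calcNormFactors(x, method='TMM')), sep='\\n')"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        ref = np.array([float(t) for t in out.stdout.split()])
        np.testing.assert_allclose(ours, ref, atol=1e-8)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(7)
        v = make_counts(rng.integers(1, 500, (100, 8)))
        f = momfa.tmm_factors(v)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)


def _tmm_oracle(counts, trim_m, trim_a):
    """Direct transcription of the trimmed-mean-of-M-values definition."""
    lib = counts.sum(axis=0)
    uq = np.array([np.quantile(counts[:, j] / lib[j], 0.75)
                   for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = []
    for j in range(counts.shape[1]):
        ok = (counts[:, j] > 0) & (counts[:, ref] > 0)
        po, pr = counts[ok, j] / lib[j], counts[ok, ref] / lib[ref]
        m = np.log2(po / pr)
        a = 0.5 * np.log2(po * pr)
        if np.max(np.abs(m)) < 1e-6:
            factors.append(1.0)
            continue
        w = (lib[j] - counts[ok, j]) / (lib[j] * counts[ok, j]) + (
            lib[ref] - counts[ok, ref]
        ) / (lib[ref] * counts[ok, ref])
        n = m.size
        lo_m, lo_a = np.floor(n * trim_m) + 1, np.floor(n * trim_a) + 1
        keep = (
            (rankdata(m) >= lo_m)
            & (rankdata(m) <= n + 1 - lo_m)
            & (rankdata(a) >= lo_a)
            & (rankdata(a) <= n + 1 - lo_a)
        )
        factors.append(2 ** (np.sum(m[keep] / w[keep]) / np.sum(1 / w[keep])))
    factors = np.asarray(factors)
    return factors / np.exp(np.mean(np.log(factors)))


class TestCPM:
    def test_single_sample_arithmetic(self):
        v = make_counts([[1], [1], [2]])
        out = momfa.normalize_cpm(v, np.array([1.0]), log2_transform=False)
        np.testing.assert_allclose(out.values[:, 0], [250000, 250000, 500000])

    def test_depth_scale_invariance(self):
        v = make_counts([[10, 20], [30, 60], [60, 120]])
        out = momfa.normalize_cpm(v, np.ones(2), log2_transform=False)
        np.testing.assert_allclose(out.values[:, 0], out.values[:, 1])

    def test_unit_factors_match_classic_cpm(self):
        rng = np.random.default_rng(1)
        v = make_counts(rng.integers(1, 100, (20, 4)))
        out = momfa.normalize_cpm(v, np.ones(4), log2_transform=False)
        np.testing.assert_allclose(out.values, cpm(v))

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(2)
        v = make_counts(rng.integers(0, 100, (30, 3)) + 1)
        out = momfa.normalize_cpm(v, np.ones(3), log2_transform=False)
        np.testing.assert_allclose(out.values.sum(axis=0), 1e6)

    def test_factor_count_mismatch_rejected(self):
        v = make_counts([[1, 2]])
        with pytest.raises(MomfaError):
            momfa.normalize_cpm(v, np.ones(3))


class TestPQN:
    def _abundance(self, values):
        values = np.asarray(values, dtype=float)
        return momfa.OmicView(
            "ab", [f"F{i}" for i in range(values.shape[0])],
            [f"s{j}" for j in range(values.shape[1])], values, "abundance",
        )

    def test_identical_samples_no_change(self):
        v = self._abundance(np.tile([[2.0], [4.0], [6.0]], (1, 3)))
        out, dil = momfa.pqn_normalize(v, log2_transform=False)
        np.testing.assert_allclose(dil, 1.0)
        np.testing.assert_allclose(out.values, v.values)

    def test_exact_threefold_dilution(self):
        base = np.array([1.0, 2.0, 5.0, 9.0])
        v = self._abundance(np.column_stack([base, base, 3 * base]))
        out, dil = momfa.pqn_normalize(v, log2_transform=False)
        np.testing.assert_allclose(dil, [1.0, 1.0, 3.0])
        np.testing.assert_allclose(out.values[:, 2], base)

    def test_zero_sample_rejected(self):
        v = self._abundance([[0.0, 1.0], [0.0, 2.0]])
        with pytest.raises(MomfaError, match="s0"):
            momfa.pqn_normalize(v)

    def test_dilution_free_factors_near_one(self):
        # factors shrink toward 1 as the feature count grows
        errs = []
        for d in (50, 800):
            rng = np.random.default_rng(d)
            vals = np.exp(rng.normal(2, 0.3, size=(d, 6)))
            v = self._abundance(vals)
            _, dil = momfa.pqn_normalize(v)
            errs.append(np.abs(dil - 1).max())
        assert errs[1] < errs[0] < 0.5


class TestTopVariance:
    def test_identity_when_k_large(self):
        rng = np.random.default_rng(0)
        v = make_counts(rng.integers(0, 9, (5, 4)))
        assert momfa.select_top_variance(v, 5) is v

    def test_picks_largest_variances(self):
        vals = np.array([[1, 1], [1, 3], [1, 5], [1, 7], [1, 9]], dtype=float)
        v = momfa.OmicView("n", list("abcde"), ["x", "y"], vals, "normalized")
        out = momfa.select_top_variance(v, 2)
        assert out.feature_ids == ["d", "e"]

    def test_agrees_with_sort_oracle(self):
        rng = np.random.default_rng(4)
        vals = rng.standard_normal((1000, 12))
        ids = [f"f{i:04d}" for i in range(1000)]
        v = momfa.OmicView("n", ids, [f"s{j}" for j in range(12)], vals,
                           "normalized")
        out = momfa.select_top_variance(v, 100)
        var = vals.var(axis=1, ddof=1)
        expected = set(
            sorted(ids, key=lambda f: (-var[ids.index(f)], f))[:100]
        )
        assert set(out.feature_ids) == expected

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(5)
        vals = rng.standard_normal((50, 8))
        ids = [f"f{i}" for i in range(50)]
        v1 = momfa.OmicView("n", ids, [f"s{j}" for j in range(8)], vals,
                            "normalized")
        perm = rng.permutation(8)
        v2 = momfa.OmicView("n", ids, [f"s{j}" for j in perm],
                            vals[:, perm], "normalized")
        assert (momfa.select_top_variance(v1, 10).feature_ids
                == momfa.select_top_variance(v2, 10).feature_ids)

    def test_nonpositive_k_rejected(self):
        v = make_counts([[1, 2]])
        with pytest.raises(MomfaError):
            momfa.select_top_variance(v, 0)


class TestUnitVarianceScale:
    def test_constant_feature_dropped_with_warning(self):
        vals = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        v = momfa.OmicView("n", ["c", "d"], ["x", "y", "z"], vals, "normalized")
        with pytest.warns(UserWarning, match="zero-variance"):
            out = momfa.unit_variance_scale(v)
        assert out.feature_ids == ["d"]

    def test_output_variances_are_one(self):
        rng = np.random.default_rng(6)
        vals = rng.standard_normal((20, 15)) * 5 + 2
        v = momfa.OmicView("n", [f"f{i}" for i in range(20)],
                           [f"s{j}" for j in range(15)], vals, "normalized")
        out = momfa.unit_variance_scale(v)
        np.testing.assert_allclose(out.values.var(axis=1, ddof=1), 1.0,
                                   atol=1e-12)
        np.testing.assert_allclose(out.values.mean(axis=1), 0.0, atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        vals = rng.standard_normal((10, 9))
        v = momfa.OmicView("n", [f"f{i}" for i in range(10)],
                           [f"s{j}" for j in range(9)], vals, "normalized")
        once = momfa.unit_variance_scale(v)
        twice = momfa.unit_variance_scale(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)
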