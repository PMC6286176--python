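"""Size factors, log2FC flagging, permutation test, BH, and the DE filter."""
import numpy as np
import pandas as pd
import pytest

from methseek.consolidate import CountMatrix
from methseek.core import MethylationSite
from methseek.screen import (
    ScreenParams,
    apply_de_filter,
    bh_adjust,
    log2fc_screen,
    permutation_test,
    run_screen,
    size_factors,
)

from oracles import bh_step_up, median_of_ratios


def matrix(counts, samples=None, condition=None):
    counts = np.asarray(counts)
    n_sites, n_samples = counts.shape
    samples = samples or [f"s{j}" for j in range(n_samples)]
    condition = condition or {
        s: ("M1" if j < n_samples // 2 else "M2") for j, s in enumerate(samples)
    }
    sites = [MethylationSite("chr1", 1000 * i, 1000 * i + 500) for i in range(n_sites)]
    return CountMatrix(sites, samples, counts, condition)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = np.array([[5, 5], [8, 8], [12, 12]])
        assert np.allclose(size_factors(counts), [1.0, 1.0])

    def test_doubled_column_gives_sqrt2_factors(self):
        a = np.array([4, 9, 25])
        counts = np.column_stack([a, 2 * a])
        assert np.allclose(size_factors(counts), [1 / np.sqrt(2), np.sqrt(2)])

    def test_matches_median_of_ratios_oracle(self, rng):
        counts = rng.integers(1, 200, size=(50, 4))
        assert np.allclose(size_factors(counts), median_of_ratios(counts))

    def test_cross_checks_against_deseq2_normalization(self, rng):
        pydeseq2 = pytest.importorskip("pydeseq2.preprocessing")
        counts = rng.integers(1, 500, size=(80, 6))
        _, sf = pydeseq2.deseq2_norm(pd.DataFrame(counts.T))  # samples x genes
        assert np.allclose(size_factors(counts), np.asarray(sf).ravel())

    def test_no_all_positive_site_is_a_hard_error(self):
        counts = np.array([[0, 5], [3, 0]])
        with pytest.raises(ValueError, match="pseudocount or more data"):
            size_factors(counts)


class TestLog2fcScreen:
    def test_equal_group_means_give_zero_unflagged(self):
        table = log2fc_screen(matrix([[10, 10, 10, 10]] * 3))
        assert np.allclose(table["log2fc"], 0.0)
        assert not table["flagged"].any()

    def test_exact_doubling_sits_on_the_strict_boundary(self):
        # balanced matrix so every size factor is 1; site 0 has normalized
        # means A = 9, B = 4, and with pseudocount 1, log2(10/5) = 1 exactly:
        # on the strict > 1.0 boundary, so NOT flagged
        m = matrix([[9, 9, 4, 4], [4, 4, 9, 9], [6, 6, 6, 6]])
        table = log2fc_screen(m)
        assert np.allclose(size_factors(m), 1.0)
        assert table["log2fc"][0] == pytest.approx(1.0)
        assert not table["flagged"].any()

    def test_swapping_condition_labels_negates_log2fc(self, rng):
        counts = rng.integers(1, 100, size=(20, 4))
        m1 = matrix(counts)
        m2 = matrix(counts, condition={s: ("M2" if j < 2 else "M1") for j, s in enumerate(m1.samples)})
        t1, t2 = log2fc_screen(m1), log2fc_screen(m2)
        assert np.allclose(t1["log2fc"], -t2["log2fc"])
        assert (t1["flagged"] == t2["flagged"]).all()

    def test_scaling_one_sample_leaves_log2fc_unchanged(self, rng):
        """Normalization invariance, in its identifiable form: size factors
        are defined only up to a common scale, so scaling one sample's raw
        counts by c multiplies its factor relative to every other sample's
        by exactly c, and no log2FC moves (all normalized counts pick up a
        common c^(1/m) scale that cancels in the ratio; tested with a
        pseudocount small enough not to mask the cancellation)."""
        counts = rng.integers(1, 100, size=(30, 4)).astype(float)
        params = ScreenParams(pseudocount=1e-12)
        base_sf = size_factors(counts)
        base_lfc = log2fc_screen(matrix(counts.astype(int) * 4), params)["log2fc"]
        for c in (0.5, 2, 10):
            scaled = counts * 4
            scaled[:, 1] *= c
            sf = size_factors(scaled)
            expected_ratio = base_sf[1] / base_sf * c
            expected_ratio[1] = 1.0
            assert np.allclose(sf[1] / sf, expected_ratio, atol=1e-9)
            lfc = log2fc_screen(matrix(scaled.astype(int)), params)["log2fc"]
            assert np.allclose(lfc, base_lfc, atol=1e-9)

    def test_single_condition_is_an_error(self):
        m = matrix([[5, 6]], condition={"s0": "M1", "s1": "M1"})
        with pytest.raises(ValueError, match="2 condition"):
            log2fc_screen(m)


class TestPermutationTest:
    def test_constant_site_has_p_one(self):
        m = matrix([[7, 7, 7, 7]])
        assert permutation_test(m, ScreenParams(seed=1))[0] == 1.0

    def test_2v2_design_enumerates_all_six_splits(self):
        # strong effect: the observed split should be (near) the most extreme
        m = matrix([[100, 110, 3, 4], [50, 55, 50, 52]])
        p = permutation_test(m, ScreenParams(seed=1))
        # p = (1 + #{null >= obs}) / (1 + 6); site 0: only the observed and
        # its complement reach the observed |log2fc|
        assert p[0] == pytest.approx(3 / 7)
        assert set((p * 7 - 1).round().astype(int)) <= set(range(7))

    def test_same_seed_reproduces_exactly(self, rng):
        counts = rng.integers(1, 100, size=(15, 12))
        m = matrix(counts)
        params = ScreenParams(n_permutations=200, seed=42)
        assert np.array_equal(permutation_test(m, params), permutation_test(m, params))

    def test_null_pvalues_are_super_uniform(self, rng):
        """With no condition effect, the rejection rate at alpha=0.05 stays
        within the 99% binomial envelope."""
        counts = rng.poisson(50, size=(600, 8))
        p = permutation_test(matrix(counts), ScreenParams(seed=7))
        alpha = 0.05
        hits = int((p <= alpha).sum())
        n = len(p)
        sd = np.sqrt(n * alpha * (1 - alpha))
        assert hits <= n * alpha + 2.58 * sd

    def test_fewer_than_two_per_group_is_an_error(self):
        m = matrix([[5, 6, 7]], samples=["a", "b", "c"],
                   condition={"a": "M1", "b": "M2", "c": "M2"})
        with pytest.raises(ValueError, match=">= 2 samples"):
            permutation_test(m)


class TestBhAdjust:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_applied_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_all_equal_ps_stay_equal(self):
        assert np.allclose(bh_adjust([0.2] * 5), 0.2)

    def test_matches_brute_force_oracle_on_random_vectors(self, rng):
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 60)))
            assert np.allclose(bh_adjust(p), bh_step_up(p))

    def test_adjusted_never_below_raw(self, rng):
        p = rng.random(100)
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_adjust([0.5, 1.2])


class TestApplyDeFilter:
    TABLE = pd.DataFrame(
        {
            "gene": ["kept", "padj_boundary", "lfc_boundary", "neg_boundary", "strong_neg"],
            "padj": [0.04, 0.05, 0.01, 0.01, 0.001],
            "log2fc": [1.5, 3.0, 1.0, -1.0, -2.5],
        }
    )

    def test_strict_inequalities_on_both_criteria(self):
        kept = apply_de_filter(self.TABLE)
        assert kept["gene"].tolist() == ["kept", "strong_neg"]

    def test_missing_column_is_named(self):
        with pytest.raises(ValueError, match="padj"):
            apply_de_filter(self.TABLE.drop(columns=["padj"]))


class TestRunScreen:
    def test_flag_requires_both_lfc_and_padj_when_pvalues_present(self, rng):
        counts = rng.poisson(30, size=(40, 8))
        counts[:5, :4] *= 8  # strong M1 effect at 5 sites
        table = run_screen(matrix(counts), ScreenParams(seed=3))
        assert {"log2fc", "perm_p", "padj", "flagged"} <= set(table.columns)
        assert (~table["flagged"] | ((table["log2fc"].abs() > 1.0) & (table["padj"] < 0.05))).all()
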