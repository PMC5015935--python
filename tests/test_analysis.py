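import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from screenerr import (
    CountMatrix,
    FitnessSpec,
    ScenarioConfig,
    barcode_concordance,
    compare_recombination,
    correct_recombination_frequency,
    gc_bias_test,
    log2fc,
    make_orf_bc_library,
    measured_recombination_frequency,
    normalize_counts,
    recombination_estimate,
    run_screen_scenario,
    subpool_distortion,
)
from screenerr.packaging import default_recombination_model


class TestNormalize:
    def test_column_at_total_unchanged(self):
        cm = CountMatrix(["a", "b", "c"], ["s"], np.array([[1], [1], [2]]))
        out = normalize_counts(cm, total=4)
        np.testing.assert_allclose(out.counts[:, 0], [1, 1, 2])
        assert out.normalized

    def test_columns_sum_to_total_and_preserve_proportions(self, rng):
        counts = rng.poisson(100, size=(50, 3)) + 1
        cm = CountMatrix([f"e{i}" for i in range(50)], ["a", "b", "c"], counts)
        out = normalize_counts(cm)
        np.testing.assert_allclose(out.counts.sum(axis=0), 1e6, rtol=1e-9)
        for j in range(3):
            np.testing.assert_allclose(
                out.counts[:, j] / out.counts[:, j].sum(),
                counts[:, j] / counts[:, j].sum(),
                rtol=1e-12,
            )

    def test_zero_sum_column_rejected(self):
        cm = CountMatrix(["a", "b"], ["s1", "s2"], np.array([[1, 0], [2, 0]]))
        with pytest.raises(ValueError, match="zero-sum"):
            normalize_counts(cm)


class TestLog2FC:
    def test_identity_gives_zero(self):
        x = np.array([3.0, 5.0, 9.0])
        np.testing.assert_array_equal(log2fc(x, x), 0.0)

    def test_exact_power_of_two(self):
        assert log2fc(np.array([100.0]), np.array([400.0]), pseudocount=0)[0] == 2.0

    def test_pseudocount_guards_empty_elements(self):
        assert log2fc(np.array([0.0]), np.array([0.0]), pseudocount=1)[0] == 0.0

    def test_misaligned_series_rejected(self):
        ref = pd.Series([1.0], index=["a"])
        end = pd.Series([1.0], index=["b"])
        with pytest.raises(ValueError, match="element sets"):
            log2fc(ref, end)

    def test_series_aligned_by_label_not_position(self):
        ref = pd.Series([100.0, 400.0], index=["a", "b"])
        end = pd.Series([1600.0, 400.0], index=["b", "a"])
        out = log2fc(ref, end, pseudocount=0)
        assert out["a"] == 2.0 and out["b"] == 2.0


class TestConcordance:
    def test_all_positive_group(self):
        out = barcode_concordance([1.2, 0.8, 2.0], ["o1"] * 3)
        assert out.loc["o1", "sign_agreement"] == 1.0

    def test_split_group(self):
        out = barcode_concordance([1.0, -1.0], ["o1", "o1"])
        assert out.loc["o1", "sign_agreement"] == 0.5

    def test_singleton_is_nan(self):
        out = barcode_concordance([1.0], ["o1"])
        assert math.isnan(out.loc["o1", "sign_agreement"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            barcode_concordance([], [])

    def test_higher_recombination_rate_lowers_concordance(self):
        # paired screens differing only in vector design: the long-homology
        # layout recombines ~5x more often and should show lower mean sign
        # agreement among strong-fitness ORFs
        enr = [f"ORF{i:04d}" for i in range(5)]
        dep = [f"ORF{i:04d}" for i in range(5, 10)]
        fit = FitnessSpec.with_effects(enr, dep, 0.3, -0.3)
        model = default_recombination_model()

        def mean_agreement(design, seed):
            lib = make_orf_bc_library(20, 5, 30, design, rng=np.random.default_rng(1234))
            cfg = ScenarioConfig(representation=50, seed=seed, benzonase_units=500)
            ds = run_screen_scenario(cfg, lib, fit, model=model)
            conc = barcode_concordance(ds.log2fc().to_numpy(), ds.library.orf_ids)
            return conc.loc[enr + dep, "sign_agreement"].mean()

        seeds = range(50)
        a5 = np.array([mean_agreement("5BC", s) for s in seeds])
        a3 = np.array([mean_agreement("3BC", s) for s in seeds])
        assert a3.mean() > a5.mean()
        assert np.mean(a3 >= a5) > 0.8


class TestRecombinationFrequency:
    @pytest.mark.parametrize(
        "k,n,expected_pct", [(17, 65, 26.15), (3, 55, 5.45), (0, 33, 0.0)]
    )
    def test_measured_frequency_from_counts(self, eleven_lib, rng, k, n, expected_pct):
        truth_pairs = list(eleven_lib.pairing())
        observed = [truth_pairs[int(i)] for i in rng.integers(0, 11, n)]
        # recombine k of them deterministically: rotate the barcode
        for i in range(k):
            orf, _ = observed[i]
            j = list(eleven_lib.orf_ids).index(orf)
            observed[i] = (orf, eleven_lib.bc_ids[(j + 1) % 11])
        est = measured_recombination_frequency(observed, eleven_lib)
        assert est.n_recombined == k
        assert 100 * est.f_measured == pytest.approx(expected_pct, abs=0.005)

    def test_unknown_id_rejected(self, eleven_lib):
        with pytest.raises(ValueError, match="unknown"):
            measured_recombination_frequency([("nope", "BC00000")], eleven_lib)

    @pytest.mark.parametrize(
        "f,h,expected",
        [(0.2615, 1 / 11, 0.2853), (0.0545, 1 / 11, 0.0595), (0.123, 0.0, 0.123)],
    )
    def test_correction_formula(self, f, h, expected):
        assert correct_recombination_frequency(f, h) == pytest.approx(expected, abs=5e-5)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(f=st.floats(0, 1), h=st.floats(0, 1))
    def test_correction_bounds(self, f, h):
        out = correct_recombination_frequency(f, h)
        assert f <= out <= 2 * f

    def test_full_estimate_applies_library_homozygosity(self, eleven_lib):
        pairs = list(eleven_lib.pairing())
        est = recombination_estimate(pairs, eleven_lib)
        assert est.h == pytest.approx(1 / 11)
        assert est.f_measured == 0.0 and est.f_true_est == 0.0


class TestCompareRecombination:
    def test_identical_rates_not_significant(self):
        assert compare_recombination(10, 100, 10, 100) == pytest.approx(1.0)

    def test_assay_rates_differ_strongly(self):
        p = compare_recombination(17, 65, 3, 55)
        assert p < 1e-3
        # same order of magnitude as the published 1.5e-4
        assert 1e-5 < p < 1e-3

    def test_both_zero(self):
        assert compare_recombination(0, 40, 0, 25) == 1.0

    def test_fisher_alternative_agrees_in_direction(self):
        assert compare_recombination(17, 65, 3, 55, method="fisher") < 0.01


class TestGcBias:
    def test_perfect_anticorrelation(self, rng):
        gc = rng.uniform(0.3, 0.7, 100)
        rep = gc_bias_test(-gc, gc)
        assert rep.pearson_r == pytest.approx(-1.0)

    def test_matches_textbook_formula_on_five_points(self):
        gc = np.array([0.40, 0.45, 0.50, 0.55, 0.60])
        y = np.array([0.2, -0.1, 0.05, -0.3, -0.25])
        rep = gc_bias_test(y, gc)
        # hand computation: r = sum((x-xb)(y-yb)) / sqrt(sum sq * sum sq)
        xb, yb = gc.mean(), y.mean()
        r_hand = ((gc - xb) * (y - yb)).sum() / math.sqrt(
            (((gc - xb) ** 2).sum()) * (((y - yb) ** 2).sum())
        )
        assert rep.pearson_r == pytest.approx(r_hand, abs=1e-12)
        t = r_hand * math.sqrt(3 / (1 - r_hand**2))
        assert rep.p_value == pytest.approx(2 * stats.t.sf(abs(t), 3), rel=1e-9)

    def test_permutation_null_rarely_significant(self, rng):
        y = rng.normal(size=1000)
        gc = rng.uniform(0.4, 0.6, 1000)
        hits = 0
        for _ in range(20):
            perm = rng.permutation(gc)
            if abs(gc_bias_test(y, perm).pearson_r) >= 0.1:
                hits += 1
        assert hits <= 1  # |r| < 0.1 in >= 95% of permutations

    def test_affine_invariance_and_sign_flip(self, rng):
        y = rng.normal(size=200)
        gc = rng.uniform(0.3, 0.7, 200)
        base = gc_bias_test(y, gc).pearson_r
        assert gc_bias_test(3.0 * y + 2.0, gc).pearson_r == pytest.approx(base, abs=1e-12)
        assert gc_bias_test(y, 0.5 * gc + 0.1).pearson_r == pytest.approx(base, abs=1e-12)
        assert gc_bias_test(-y, gc).pearson_r == pytest.approx(-base, abs=1e-12)

    def test_constant_input_reported_as_nan(self):
        rep = gc_bias_test(np.zeros(10), np.full(10, 0.5))
        assert math.isnan(rep.pearson_r) and rep.note is not None

    def test_strata_binning(self, rng):
        gc = np.repeat([0.40, 0.45, 0.50, 0.55, 0.60], 20)
        rep = gc_bias_test(rng.normal(size=100), gc)
        assert len(rep.binned) == 5
        assert rep.binned["n"].tolist() == [20] * 5


class TestSubpoolDistortion:
    def test_equal_reads_give_unit_spread(self):
        reads = np.full(10, 100.0)
        pools = np.repeat(["p0", "p1"], 5)
        out = subpool_distortion(reads, pools, {"p0": 1e6, "p1": 2e6})
        assert out.spread == pytest.approx(1.0)
        assert math.isnan(out.spearman_rho)

    def test_missing_titer_rejected(self):
        with pytest.raises(ValueError, match="titer"):
            subpool_distortion(np.ones(4), ["p0", "p0", "p1", "p1"], {"p0": 1e6})

    def test_titer_inverse_reads_give_negative_rank_correlation(self):
        titers = {f"p{i}": t for i, t in enumerate([1e6, 2e6, 4e6, 8e6])}
        pools = np.repeat(sorted(titers), 5)
        reads = np.concatenate([np.full(5, 1e6 / titers[p]) for p in sorted(titers)])
        out = subpool_distortion(reads, pools, titers)
        assert out.spearman_rho == pytest.approx(-1.0)
        assert out.spread == pytest.approx(8.0)
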