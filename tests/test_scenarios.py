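import math

import numpy as np
import pytest

from screenerr import (
    FitnessSpec,
    MOCK_GC_STRATA,
    ScenarioConfig,
    gc_fraction,
    make_orf_bc_library,
    run_recomb_assay_scenario,
    run_screen_scenario,
    simulate_growth,
    subpool_distortion,
    read_counts,
    read_library,
)
from screenerr.packaging import RecombinationModel
from scipy import stats


class TestOrfBcLibrary:
    def test_assay_sublibrary_shape(self):
        lib = make_orf_bc_library(11, 1, 30, "5BC", rng=np.random.default_rng(0))
        assert lib.n == 11
        assert all(len(c.bc_seq) == 30 for c in lib.clones)
        np.testing.assert_allclose(lib.abundance, 1 / 11)

    def test_barcodes_per_orf(self):
        lib = make_orf_bc_library(7, 5, rng=np.random.default_rng(0))
        counts = {o: 0 for o in set(lib.orf_ids)}
        for o in lib.orf_ids:
            counts[o] += 1
        assert set(counts.values()) == {5}
        assert len({c.bc_seq for c in lib.clones}) == lib.n  # collision-free

    def test_seed_determinism_and_disjoint_barcode_sets(self):
        a = make_orf_bc_library(20, 2, rng=np.random.default_rng(1))
        b = make_orf_bc_library(20, 2, rng=np.random.default_rng(1))
        c = make_orf_bc_library(20, 2, rng=np.random.default_rng(2))
        assert [x.bc_seq for x in a.clones] == [x.bc_seq for x in b.clones]
        assert not ({x.bc_seq for x in a.clones} & {x.bc_seq for x in c.clones})

    def test_barcode_space_exhaustion_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            make_orf_bc_library(20, 1, bc_len=2, rng=np.random.default_rng(0))


class TestMockLibrary:
    def test_composition(self, mock_lib):
        assert mock_lib.n == 1000
        strata, counts = np.unique(mock_lib.gc, return_counts=True)
        np.testing.assert_allclose(strata, MOCK_GC_STRATA)
        assert counts.tolist() == [200] * 5

    def test_template_gc_is_exact(self, mock_lib):
        for clone in mock_lib.clones[::97]:
            assert gc_fraction(clone.bc_seq) == pytest.approx(clone.gc_fraction, abs=1e-12)

    def test_sequences_unique(self, mock_lib):
        assert len({c.bc_seq for c in mock_lib.clones}) == 1000


class TestSimulateGrowth:
    def test_neutral_expectation_unchanged(self):
        a = np.array([0.2, 0.3, 0.5])
        out = simulate_growth(a, 0.0, 10, 1000, stochastic=False)
        np.testing.assert_allclose(out, a, rtol=1e-12)

    def test_single_enricher_closed_form(self):
        a = np.full(10, 0.1)
        s = np.zeros(10)
        s[0] = 0.1
        out = simulate_growth(a, s, 10, 1000, stochastic=False)
        # relative weight doubles vs neutral elements before renormalization
        assert out[0] / out[1] == pytest.approx(2.0, rel=1e-12)

    def test_drift_variance_scales_inversely_with_representation(self):
        a = np.full(50, 1 / 50)
        reps = (250, 2500)
        variances = []
        for rep in reps:
            finals = np.array(
                [
                    simulate_growth(a, 0.0, 5, rep, np.random.default_rng(seed))
                    for seed in range(100)
                ]
            )
            variances.append(finals.var(axis=0, ddof=1).mean())
        ratio = variances[0] / variances[1]
        assert 5 < ratio < 20  # expected 10, within sampling error

    def test_rejects_bad_representation(self):
        with pytest.raises(ValueError):
            simulate_growth(np.ones(3) / 3, 0.0, 5, 0, np.random.default_rng(0))


class TestRecombAssayScenario:
    def test_individual_mode_measures_zero_at_any_switch_rate(self):
        model = RecombinationModel(rates={"5BC": 0.9, "3BC": 0.9, "TRE": 0.9})
        for seed in (0, 1, 2):
            _, est = run_recomb_assay_scenario(
                11, "5BC", "individual", 200, model=model, seed=seed
            )
            assert est.f_measured == 0.0 and est.f_true_est == 0.0

    def test_pooled_mode_recovers_detectable_fraction(self):
        _, est = run_recomb_assay_scenario(11, "5BC", "pooled", 10**5, seed=3)
        expected = 0.2877 * (1 - 1 / 11)
        se = math.sqrt(expected * (1 - expected) / 10**5)
        assert abs(est.f_measured - expected) < 3 * se
        assert est.f_true_est == pytest.approx(est.f_measured * (1 + 1 / 11))

    def test_single_clone_cannot_recombine_detectably(self):
        model = RecombinationModel(rates={"5BC": 1.0, "3BC": 1.0, "TRE": 1.0})
        _, est = run_recomb_assay_scenario(1, "5BC", "pooled", 100, model=model, seed=0)
        assert est.f_measured == 0.0

    def test_switch_probability_recovery_within_binomial_ci(self):
        # the estimator p_hat = f_measured / (1 - h) should cover the
        # configured switch probability via the scaled exact 95% CI
        p_true = 0.2877
        h = 1 / 11
        covered = 0
        n_seq = 500
        reps = 200
        for seed in range(reps):
            _, est = run_recomb_assay_scenario(11, "5BC", "pooled", n_seq, seed=seed)
            ci = stats.binomtest(est.n_recombined, est.n_analyzed).proportion_ci(0.95)
            if ci.low / (1 - h) <= p_true <= ci.high / (1 - h):
                covered += 1
        assert covered / reps >= 0.93


class TestScreenScenario:
    def test_identical_config_and_seed_reproduce_dataset(self, mock_lib):
        cfg = ScenarioConfig(representation=50, seed=9, depth_per_element=100)
        a = run_screen_scenario(cfg, mock_lib)
        b = run_screen_scenario(cfg, mock_lib)
        np.testing.assert_array_equal(a.counts_ref.counts, b.counts_ref.counts)
        np.testing.assert_array_equal(a.counts_end.counts, b.counts_end.counts)

    def test_contaminated_reference_loses_effective_cycles(self, mock_lib):
        cfg = ScenarioConfig(representation=200, seed=1)
        ds = run_screen_scenario(cfg, mock_lib)
        gap = ds.n_eff_end - ds.n_eff_ref
        assert gap > 4  # ~70x template excess costs ~6 effective cycles

    def test_contaminated_reference_induces_negative_gc_trend(self, mock_lib):
        cfg = ScenarioConfig(representation=200, seed=2)
        rep = run_screen_scenario(cfg, mock_lib).gc_bias()
        assert rep.pearson_r < 0 and rep.p_value < 0.01
        medians = rep.binned["median"].to_numpy()
        assert medians[-1] < medians[0]  # 60% GC stratum below 40% stratum

    def test_clean_reference_shows_no_gc_trend(self, mock_lib):
        cfg = ScenarioConfig(
            representation=200, seed=2, benzonase_units=500, dna_input_fraction=0.1
        )
        rep = run_screen_scenario(cfg, mock_lib).gc_bias()
        assert rep.p_value > 0.01

    def test_ground_truth_recovery_under_graded_fitness(self):
        lib = make_orf_bc_library(200, 1, rng=np.random.default_rng(3))
        s_rng = np.random.default_rng(4)
        fit = FitnessSpec(
            s_by_orf={o: float(s) for o, s in zip(sorted(set(lib.orf_ids)), s_rng.uniform(-0.15, 0.15, 200))}
        )
        rhos = []
        for seed in range(5):
            cfg = ScenarioConfig(representation=1000, seed=seed, benzonase_units=500)
            ds = run_screen_scenario(cfg, lib, fit)
            rho = stats.spearmanr(ds.truth_log2fc, ds.log2fc().to_numpy()).statistic
            rhos.append(rho)
        assert np.median(rhos) >= 0.95

    def test_enrichers_rank_at_top(self):
        lib = make_orf_bc_library(200, 1, rng=np.random.default_rng(5))
        enr = sorted(set(lib.orf_ids))[:10]
        fit = FitnessSpec.with_effects(enrichers=enr)
        cfg = ScenarioConfig(representation=1000, seed=6, benzonase_units=500)
        ds = run_screen_scenario(cfg, lib, fit)
        top = set(np.array(ds.library.orf_ids)[np.argsort(ds.log2fc().to_numpy())[-10:]])
        assert len(top & set(enr)) >= 8

    def test_subpool_distortion_in_contaminated_reference(self):
        # five subpools at equal cell representation but 4x titer range: the
        # carryover plasmid load is titer-inverse, distorting reference reads
        titers = {f"pool{i:02d}": t * 1e6 for i, t in enumerate([1.0, 1.5, 2.0, 3.0, 4.0])}
        lib = make_orf_bc_library(
            100, 1, subpools=5, rng=np.random.default_rng(8), subpool_titers=titers
        )
        cfg = ScenarioConfig(representation=200, seed=8)
        ds = run_screen_scenario(cfg, lib)
        reads = ds.counts_ref.column("reference").to_numpy()
        out = subpool_distortion(reads, ds.library.subpool_ids, titers)
        assert out.spearman_rho < 0
        assert 2.0 <= out.spread <= 10.0

    def test_dataset_directory_round_trips(self, tmp_path, mock_lib):
        cfg = ScenarioConfig(representation=20, seed=11, depth_per_element=50)
        ds = run_screen_scenario(cfg, mock_lib)
        ds.write(tmp_path / "ds", include_provirus=False, comments=["screenerr test seed=11"])
        lib = read_library(tmp_path / "ds" / "library.tsv")
        assert lib.n == mock_lib.n
        ref = read_counts(tmp_path / "ds" / "counts_ref.tsv")
        np.testing.assert_array_equal(ref.counts[:, 0], ds.counts_ref.counts[:, 0])
        assert (tmp_path / "ds" / "config.yaml").exists()
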