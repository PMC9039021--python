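"""Simulator: branching-process preamplification, Poisson occupancy,
amplitude model, replicate loading, determinism."""

import numpy as np
import pytest

from raredrop import SimConfig, simulate_experiment, simulate_preamp, simulate_well
from raredrop.errors import InvalidParameterError


class TestSimulatePreamp:
    def test_zero_template_stays_zero(self):
        assert simulate_preamp(0, cycles=8, efficiency=1.0, rng=1) == 0

    def test_perfect_efficiency_is_deterministic_doubling(self):
        assert simulate_preamp(50, cycles=8, efficiency=1.0, rng=1) == 50 * 2**8

    def test_no_cycles_is_identity(self):
        assert simulate_preamp(37, cycles=0, efficiency=0.5, rng=1) == 37

    def test_output_never_below_input(self, rng):
        for _ in range(100):
            k = int(rng.integers(1, 30))
            assert simulate_preamp(k, 4, 0.3, rng) >= k

    def test_monte_carlo_mean_matches_closed_form(self, rng):
        # E[output] = k (1+e)^cycles for a per-molecule Bernoulli duplication
        k, cycles, e = 50, 8, 0.9
        runs = np.array([simulate_preamp(k, cycles, e, rng) for _ in range(10_000)])
        expected = k * (1 + e) ** cycles
        assert runs.mean() == pytest.approx(expected, rel=0.02)

    @pytest.mark.parametrize(
        "k,cycles,e",
        [(-1, 4, 0.5), (10, -2, 0.5), (10, 4, 1.5), (10, 4, -0.1), (2.5, 4, 0.5)],
    )
    def test_invalid_parameters_rejected(self, k, cycles, e):
        with pytest.raises(InvalidParameterError):
            simulate_preamp(k, cycles, e, rng=0)


class TestSimulateWell:
    def test_partition_count_matches_config(self):
        config = SimConfig(conc_mut=10, conc_wt=10, n_partitions=500, seed=1)
        records, _ = simulate_well(config)
        assert len(records) == 500

    def test_no_mutant_no_artifacts_means_no_fam_signal(self, qx200):
        config = SimConfig(
            conc_mut=0.0, conc_wt=50.0, fp_artifact_rate=0.0, cross_hyb_rate=0.0,
            rain_fraction=0.0, n_partitions=5000,
        )
        for seed in range(10):
            records, _ = simulate_well(config, rng_seed=seed)
            assert all(r.fam_rfu < qx200.fam_threshold_rfu for r in records)

    def test_hex_positive_fraction_follows_poisson_occupancy(self, qx200):
        # lambda_wt = 0.5/partition -> positive fraction 1 - e^-0.5
        n_part = 20_000
        config = SimConfig(
            conc_mut=0.0, conc_wt=0.5 * n_part / 5.0, sample_volume_ul=5.0,
            preamp_cycles=0, n_partitions=n_part, rain_fraction=0.0,
            fp_artifact_rate=0.0,
        )
        fracs = []
        for seed in range(50):
            records, _ = simulate_well(config, rng_seed=seed)
            hex_pos = sum(r.hex_rfu >= qx200.hex_threshold_rfu for r in records)
            fracs.append(hex_pos / n_part)
        fracs = np.array(fracs)
        expected = 1 - np.exp(-0.5)
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - expected) < 3 * se

    def test_same_seed_reproduces_identical_records(self):
        config = SimConfig(conc_mut=20, conc_wt=40, n_partitions=2000, seed=7)
        a, truth_a = simulate_well(config, rng_seed=123)
        b, truth_b = simulate_well(config, rng_seed=123)
        assert a == b
        assert truth_a == truth_b

    def test_truth_reports_loaded_and_post_preamp_copies(self):
        config = SimConfig(conc_mut=30, conc_wt=60, preamp_cycles=4,
                           preamp_efficiency=0.8, n_partitions=1000, seed=5)
        _, truth = simulate_well(config)
        assert truth.copies_mut_loaded[0] >= 0
        assert truth.post_preamp_mut[0] >= truth.copies_mut_loaded[0]
        assert truth.post_preamp_wt[0] >= truth.copies_wt_loaded[0]


class TestSimulateExperiment:
    def test_one_well_per_replicate_with_independent_loads(self):
        config = SimConfig(conc_mut=50, conc_wt=50, n_replicates=3,
                           n_partitions=200, seed=2)
        result = simulate_experiment(config)
        assert len(result.wells) == 3
        assert len(result.truth.copies_mut_loaded) == 3

    def test_expected_load_matches_concentration_times_volume(self):
        config = SimConfig(conc_mut=40.0, conc_wt=0.0, sample_volume_ul=5.0,
                           preamp_cycles=0, n_partitions=10, n_replicates=2)
        loads = []
        for seed in range(200):
            result = simulate_experiment(
                SimConfig(**{**config.__dict__, "seed": seed})
            )
            loads.extend(result.truth.copies_mut_loaded)
        loads = np.array(loads, dtype=float)
        expected = 40.0 * 5.0
        se = loads.std(ddof=1) / np.sqrt(len(loads))
        assert abs(loads.mean() - expected) < 3 * se

    def test_true_vaf_is_concentration_ratio(self):
        config = SimConfig(conc_mut=25, conc_wt=75, n_partitions=100, seed=0)
        assert simulate_experiment(config).truth.true_vaf == pytest.approx(0.25)

    def test_fam_positive_count_increases_with_concentration(self, qx200):
        means = []
        for conc in (5.0, 20.0, 80.0):
            counts = []
            for seed in range(8):
                config = SimConfig(conc_mut=conc, conc_wt=0.0, preamp_cycles=0,
                                   n_partitions=5000, rain_fraction=0.0,
                                   fp_artifact_rate=0.0, seed=seed)
                records, _ = simulate_well(config)
                counts.append(sum(r.fam_rfu >= qx200.fam_threshold_rfu for r in records))
            means.append(np.mean(counts))
        assert means[0] < means[1] < means[2]


class TestSimConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"conc_mut": -1.0, "conc_wt": 0.0},
            {"conc_mut": 0.0, "conc_wt": 0.0, "rain_fraction": 1.2},
            {"conc_mut": 0.0, "conc_wt": 0.0, "n_partitions": 0},
            {"conc_mut": 0.0, "conc_wt": 0.0, "n_replicates": 0},
            {"conc_mut": 0.0, "conc_wt": 0.0, "preamp_efficiency": -0.2},
            # positive cloud mean must exceed negative cloud mean
            {"conc_mut": 0.0, "conc_wt": 0.0,
             "neg_cloud": ((5000.0, 100.0), (600.0, 100.0)),
             "pos_cloud": ((4000.0, 100.0), (3800.0, 100.0))},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            SimConfig(**kwargs)

    def test_platform_factory_sets_geometry(self):
        droplet = SimConfig.for_platform("qx200", conc_mut=1, conc_wt=1)
        nano = SimConfig.for_platform("qiacuity", conc_mut=1, conc_wt=1)
        assert (droplet.n_partitions, droplet.partition_volume_nl) == (20_000, 0.85)
        assert (nano.n_partitions, nano.partition_volume_nl) == (8_500, 1.34)
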