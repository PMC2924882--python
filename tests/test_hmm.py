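import numpy as np
import pytest

import _oracles
from cnvassoc.containers import SignalMatrix, SnpMap
from cnvassoc.hmm import (
    CN_OF_STATE,
    N_STATES,
    HmmParams,
    TrainConfig,
    baum_welch_transitions,
    call_segments,
    component_weights,
    decode_cohort,
    default_params,
    emission_loglik,
    emission_logliks,
    fit_baf_params,
    fit_lrr_params,
    stationary_distribution,
    suppress_short_segments,
    train,
    viterbi_decode,
)
from cnvassoc.hmm import _viterbi_batch
from cnvassoc.simulate import CnvRegion, SimulationConfig, simulate_cohort


def _signal(lrr, baf, mask=None):
    lrr = np.atleast_2d(np.asarray(lrr, float))
    baf = np.atleast_2d(np.asarray(baf, float))
    return SignalMatrix(
        samples=[f"s{i}" for i in range(lrr.shape[0])],
        snps=[f"m{j}" for j in range(lrr.shape[1])],
        lrr=lrr,
        baf=baf,
        mask=np.zeros(lrr.shape, bool) if mask is None else np.atleast_2d(mask),
    )


def _map_one_chrom(n, chrom="1"):
    return SnpMap(
        ids=[f"m{j}" for j in range(n)],
        chrom=[chrom] * n,
        pos=[1000 * (j + 1) for j in range(n)],
    )


class TestEmissions:
    def test_state_copy_number_mapping_is_fixed(self):
        assert list(CN_OF_STATE) == [0, 1, 2, 2, 3, 4]

    def test_diploid_het_mode(self):
        params = default_params()
        base = emission_loglik(0.0, 0.5, 2, 0.5, params)
        for d_lrr in (-0.1, 0.1):
            assert emission_loglik(d_lrr, 0.5, 2, 0.5, params) < base
        assert np.isfinite(base)

    def test_gaussian_tail_when_outlier_off(self):
        params = default_params(outlier_weight=0.0)
        # 10 sd away on LRR at the het BAF mode, pB = 0.5
        ll = emission_loglik(params.lrr_mean[2] + 10 * params.lrr_sd, 0.5, 2, 0.5, params)
        sd = params.lrr_sd
        lrr_logpdf = -0.5 * 100 - np.log(sd * np.sqrt(2 * np.pi))
        w = component_weights(2, np.asarray(0.5))
        baf_dens = float(
            w[1] / (params.baf_sds[2][1] * np.sqrt(2 * np.pi))
            + w[0] * _norm_pdf(0.5, 0.0, params.baf_sds[2][0])
            + w[2] * _norm_pdf(0.5, 1.0, params.baf_sds[2][2])
        )
        assert ll == pytest.approx(lrr_logpdf + np.log(baf_dens), abs=1e-6)

    def test_masked_point_contributes_zero(self):
        params = default_params()
        sig = _signal([[0.0, np.nan]], [[0.5, np.nan]])
        logem = emission_logliks(sig, params, np.full(2, 0.5))
        assert np.all(logem[0, 1, :] == 0.0)

    def test_boundary_point_mass(self):
        params = default_params()
        # homozygous BAF exactly 0: half the AA component's mass collapses there
        ll0 = emission_loglik(0.0, 0.0, 2, 0.5, params)
        assert np.isfinite(ll0)
        w = component_weights(2, np.asarray(0.5))
        assert float(w[0]) == pytest.approx(0.25)

    def test_loh_weights(self):
        w = component_weights(3, np.asarray(0.3))
        np.testing.assert_allclose(w, [0.7, 0.3])


def _norm_pdf(x, m, s):
    return np.exp(-0.5 * ((x - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))


class TestViterbi:
    def test_single_snp_chain(self):
        params = default_params()
        states, cn = viterbi_decode([0.0], [0.5], params, [0.5])
        sig = _signal([[0.0]], [[0.5]])
        logem = emission_logliks(sig, params, np.asarray([0.5]))[0, 0]
        expect = int(np.argmax(np.log(params.initial) + logem))
        assert states[0] == expect

    def test_matches_exhaustive_enumeration(self, rng):
        """Decoded path score equals the 6^T maximum exactly on random chains."""
        for _ in range(20):
            T = int(rng.integers(2, 7))
            log_init = np.log(rng.dirichlet(np.ones(N_STATES)))
            log_trans = np.log(rng.dirichlet(np.ones(N_STATES), size=N_STATES))
            logem = rng.normal(0, 2, size=(T, N_STATES))
            states = _viterbi_batch(logem[None], log_trans, log_init)[0]
            tensor = _oracles.path_score_tensor(log_init, log_trans, logem)
            assert tensor[tuple(states)] == tensor.max()

    def test_planted_run_recovered(self):
        params = default_params()
        lrr = np.zeros(15)
        baf = np.full(15, 0.5)
        lrr[5:10] = params.lrr_mean[1]
        baf[5:10] = 0.0  # hemizygous: single allele
        states, cn = viterbi_decode(lrr, baf, params, np.full(15, 0.5))
        np.testing.assert_array_equal(cn[5:10], 1)
        np.testing.assert_array_equal(cn[:5], 2)
        np.testing.assert_array_equal(cn[10:], 2)

    def test_empty_chromosome(self):
        params = default_params()
        states, cn = viterbi_decode(
            np.empty(0), np.empty(0), params, np.empty(0)
        )
        assert states.size == 0 and cn.size == 0


class TestSegments:
    def test_all_diploid_empty(self):
        assert call_segments(np.full(10, 2)) == []

    def test_short_run_filtered(self):
        assert call_segments([2, 2, 1, 1, 2], min_snps=3) == []

    def test_two_segments(self):
        segs = call_segments([2, 1, 1, 1, 3, 3, 3, 3], min_snps=3)
        assert [(s.copy_number, s.n_snps, s.start, s.end) for s in segs] == [
            (1, 3, 1, 3),
            (3, 4, 4, 7),
        ]

    def test_suppress_short_segments(self):
        snp_map = _map_one_chrom(6)
        states = np.asarray([[2, 1, 1, 2, 2, 2]], dtype=np.int8)
        fixed = suppress_short_segments(states, snp_map, min_snps=3)
        np.testing.assert_array_equal(fixed[0], [2, 2, 2, 2, 2, 2])
        states = np.asarray([[2, 1, 1, 1, 2, 2]], dtype=np.int8)
        fixed = suppress_short_segments(states, snp_map, min_snps=3)
        np.testing.assert_array_equal(fixed[0], states[0])


class TestLrrFit:
    def test_moment_recovery_all_cn2(self, rng):
        lrr = rng.normal(0.0, 0.2, size=(50, 40))
        sig = _signal(lrr, np.full_like(lrr, 0.5))
        states = np.full(lrr.shape, 2, dtype=np.int8)
        mean, sd, filled = fit_lrr_params(sig, states, min_count=10,
                                          previous=default_params().lrr_mean)
        se = 0.2 / np.sqrt(lrr.size)
        assert abs(mean[2]) < 2 * se + 1e-9
        assert sd == pytest.approx(0.2, rel=0.05)

    def test_line_fills_unpopulated(self):
        lrr = np.concatenate([
            np.full(600, -0.6), np.full(600, 0.0), np.full(600, 0.4),
        ])[None, :]
        states = np.concatenate([
            np.full(600, 1), np.full(600, 2), np.full(600, 4),
        ])[None, :].astype(np.int8)
        sig = _signal(lrr, np.full_like(lrr, 0.5))
        mean, sd, filled = fit_lrr_params(sig, states, min_count=500)
        slope, intercept = np.polyfit([1, 2, 3], [-0.6, 0.0, 0.4], 1)
        assert mean[0] == pytest.approx(intercept, abs=1e-9)
        assert mean[5] == pytest.approx(slope * 4 + intercept, abs=1e-9)
        assert sorted(filled) == [0, 4]

    def test_two_point_line(self):
        lrr = np.concatenate([np.full(600, -0.7), np.full(600, 0.0)])[None, :]
        states = np.concatenate([np.full(600, 1), np.full(600, 2)])[None, :].astype(np.int8)
        sig = _signal(lrr, np.full_like(lrr, 0.5))
        mean, _, _ = fit_lrr_params(sig, states, min_count=500)
        np.testing.assert_allclose(mean[[0, 4, 5]], [-1.4, 0.7, 1.4], atol=1e-9)

    def test_no_cn2_errors(self):
        lrr = np.full((1, 10), -0.6)
        states = np.full((1, 10), 1, dtype=np.int8)
        sig = _signal(lrr, np.full_like(lrr, 0.5))
        with pytest.raises(ValueError, match="CN2"):
            fit_lrr_params(sig, states, min_count=5)


class TestBafFit:
    def test_recovers_cluster_moments(self, rng):
        n = 3000
        comp = rng.integers(0, 3, n)
        baf = np.clip(
            np.choose(comp, [0.0, 0.5, 1.0]) + rng.normal(0, 0.03, n), 0, 1
        )[None, :]
        sig = _signal(np.zeros_like(baf), baf)
        states = np.full(baf.shape, 2, dtype=np.int8)
        params = default_params()
        means, sds, flags = fit_baf_params(sig, states, params)
        assert means[2][1] == pytest.approx(0.5, abs=0.01)
        assert sds[2][1] == pytest.approx(0.03, rel=0.25)
        # unsupported states keep previous values and are flagged
        assert any(s == 1 for s, _k in flags)
        np.testing.assert_array_equal(means[1], params.baf_means[1])

    def test_symmetry(self, rng):
        vals = np.concatenate([
            np.full(500, 0.33), np.full(500, 0.67),
        ]) + rng.normal(0, 0.01, 1000)
        sig = _signal(np.zeros((1, 1000)), np.clip(vals, 0, 1)[None, :])
        states = np.full((1, 1000), 4, dtype=np.int8)
        means, _, _ = fit_baf_params(sig, states, default_params())
        assert means[4][1] + means[4][2] == pytest.approx(1.0, abs=0.01)


class TestBaumWelch:
    def test_three_snp_exhaustive_oracle(self, rng):
        params = default_params()
        trans = rng.dirichlet(np.full(N_STATES, 5.0), size=N_STATES)
        init = rng.dirichlet(np.ones(N_STATES))
        logem = rng.normal(0, 1, size=(3, N_STATES))
        from cnvassoc.hmm import _forward_backward_counts

        counts = _forward_backward_counts(logem[None], trans, init)
        em = np.exp(logem - logem.max(axis=1, keepdims=True))
        expect = _oracles.expected_transitions_enumeration(init, trans, em)
        np.testing.assert_allclose(counts, expect, atol=1e-10)

    def test_chromosome_weighted_mean(self):
        # two chromosomes with equal SNP counts: result = (A1 + A2) / 2
        params = default_params()
        snp_map = SnpMap(
            ids=[f"m{j}" for j in range(8)],
            chrom=["1"] * 4 + ["2"] * 4,
            pos=[1000 * (j + 1) for j in range(8)],
        )
        rng = np.random.default_rng(5)
        lrr = rng.normal(0, 0.2, (30, 8))
        baf = np.clip(rng.choice([0.0, 0.5, 1.0], (30, 8)) + rng.normal(0, 0.03, (30, 8)), 0, 1)
        sig = _signal(lrr, baf)
        pB = np.full(8, 0.5)
        A = baum_welch_transitions(sig, snp_map, params, pB)
        from cnvassoc.hmm import _forward_backward_counts, emission_logliks

        logem = emission_logliks(sig, params, pB)
        parts = []
        for cols in (slice(0, 4), slice(4, 8)):
            counts = _forward_backward_counts(
                logem[:, cols, :], params.transition, params.initial
            )
            parts.append(counts / counts.sum(axis=1, keepdims=True))
        expect = (parts[0] + parts[1]) / 2
        expect /= expect.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(A, expect, atol=1e-12)

    def test_rows_stochastic(self, small_cohort):
        from cnvassoc.signal_prep import signals_from_raw

        sig = signals_from_raw(small_cohort.intensities)
        params = default_params()
        A = baum_welch_transitions(
            sig, small_cohort.snp_map, params, small_cohort.snp_map.pfb
        )
        np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(A >= 0)

    def test_near_diagonal_recovery(self):
        """Simulated near-diagonal transitions recovered within +-0.02."""
        config = SimulationConfig(
            n_cases=100, n_controls=100, n_snps_per_chrom=200,
            cnv_regions=[
                CnvRegion("1", 40, 10, 1, 0.15, 0.15),
                CnvRegion("1", 120, 10, 3, 0.15, 0.15),
            ],
            seed=9,
        )
        cohort = simulate_cohort(config, raw=False)
        params = default_params()
        A = baum_welch_transitions(
            cohort.signals, cohort.snp_map, params, cohort.snp_map.pfb
        )
        # dominant diploid self-transition is close to its planted value
        assert A[2, 2] == pytest.approx(params.transition[2, 2], abs=0.02)


class TestStationary:
    def test_uniform_for_doubly_stochastic(self):
        params = default_params()
        pi = stationary_distribution(params.transition)
        np.testing.assert_allclose(pi, np.full(6, 1 / 6), atol=1e-9)

    def test_fixed_point(self, rng):
        A = rng.dirichlet(np.ones(6), size=6)
        pi = stationary_distribution(A)
        np.testing.assert_allclose(pi @ A, pi, atol=1e-9)


@pytest.fixture(scope="module")
def training_cohort():
    config = SimulationConfig(
        n_cases=60, n_controls=60, n_snps_per_chrom=150,
        n_chromosomes=2,
        cnv_regions=[
            CnvRegion("1", 30, 8, 1, 0.20, 0.20),
            CnvRegion("1", 90, 10, 3, 0.20, 0.20),
            CnvRegion("2", 50, 12, 1, 0.20, 0.20),
            CnvRegion("2", 110, 8, 3, 0.15, 0.15),
        ],
        seed=21,
    )
    return simulate_cohort(config, raw=False)


class TestTraining:
    def test_recovery_and_convergence(self, training_cohort):
        cohort = training_cohort
        config = TrainConfig(min_state_count=50)
        result = train(default_params(), cohort.signals, cohort.snp_map, config)
        assert result.converged
        assert result.history[-1] < config.tol
        params = result.params
        truth = cohort.truth.lrr_mean_by_cn
        for state, cn in ((1, 1), (2, 2), (4, 3)):
            assert params.lrr_mean[state] == pytest.approx(truth[cn], abs=0.05)
        assert params.lrr_sd == pytest.approx(cohort.truth.lrr_sd, rel=0.10)
        np.testing.assert_allclose(params.transition.sum(axis=1), 1.0, atol=1e-9)
        params.validate()

    def test_initialization_independence(self, training_cohort):
        """Data-informed parameters converge to the same values from different
        starts; components never visited by the calls keep their (different)
        initializations and are flagged, so they are excluded."""
        cohort = training_cohort
        config = TrainConfig(min_state_count=50)
        a = train(default_params(), cohort.signals, cohort.snp_map, config)
        perturbed = default_params(
            lrr_mean=(-3.3, -0.56, 0.04, 0.04, 0.34, 0.62),
            lrr_sd=0.25,
            baf_sd=0.05,
            diag=0.995,
        )
        b = train(perturbed, cohort.signals, cohort.snp_map, config)
        assert np.max(np.abs(a.params.lrr_mean - b.params.lrr_mean)) < 1e-3
        assert abs(a.params.lrr_sd - b.params.lrr_sd) < 1e-3
        assert np.max(np.abs(a.params.transition - b.params.transition)) < 1e-3
        assert np.max(np.abs(a.params.initial - b.params.initial)) < 1e-3
        dead = set(a.flags["baf_unsupported"]) | set(b.flags["baf_unsupported"])
        for s in range(N_STATES):
            for k in range(len(a.params.baf_means[s])):
                if (s, k) in dead:
                    continue
                assert abs(a.params.baf_means[s][k] - b.params.baf_means[s][k]) < 1e-3
                assert abs(a.params.baf_sds[s][k] - b.params.baf_sds[s][k]) < 1e-3

    def test_training_is_deterministic(self, training_cohort):
        cohort = training_cohort
        config = TrainConfig(min_state_count=50, max_iter=3)
        a = train(default_params(), cohort.signals, cohort.snp_map, config)
        b = train(default_params(), cohort.signals, cohort.snp_map, config)
        np.testing.assert_array_equal(a.params.to_vector(), b.params.to_vector())

    def test_converged_input_stops_immediately(self, training_cohort):
        cohort = training_cohort
        config = TrainConfig(min_state_count=50)
        first = train(default_params(), cohort.signals, cohort.snp_map, config)
        again = train(first.params, cohort.signals, cohort.snp_map, config)
        assert again.n_iterations == 1
        assert again.history[0] < config.tol


def test_decode_accuracy_on_separated_data(small_cohort):
    """Planted CNVs >= 5 SNPs with >= 3 sd separation: per-SNP accuracy >= 99%."""
    from cnvassoc.signal_prep import signals_from_raw

    sig = signals_from_raw(small_cohort.intensities)
    calls = decode_cohort(sig, small_cohort.snp_map, default_params())
    assert (calls.cn == small_cohort.truth.cn).mean() >= 0.99
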