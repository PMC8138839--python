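"""Emission models, duration models and their estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from transcds.prob_models import (
    DurationModel,
    MarkovChainModel,
    PeriodicMarkovModel,
    PositionalModel,
    duration_logp,
    encode,
    fit_duration,
    score_chain,
    score_periodic,
    score_positional,
)
from transcds import synthetic

LOG_Q = math.log(0.25)


class TestScoreChain:
    def test_uniform_order0(self):
        m = MarkovChainModel.uniform(0)
        assert score_chain(m, "ACGT", 0, 4) == pytest.approx(4 * LOG_Q)

    def test_empty_interval(self):
        m = MarkovChainModel.uniform(2)
        assert score_chain(m, "ACGT", 2, 2) == 0.0

    def test_order1_trained_on_homopolymer(self):
        # transitions A->A dominate; with vanishing pseudocount the score of
        # AAA given a preceding A approaches 3*log(1) = 0
        enc = encode("A" * 50)
        m = MarkovChainModel.fit([(enc, 1, 50)], order=1, pseudocount=1e-12,
                                 min_context_obs=1)
        s = score_chain(m, "AAAA", 1, 4)
        assert s == pytest.approx(0.0, abs=1e-6)

    def test_out_of_range_offsets(self):
        m = MarkovChainModel.uniform(0)
        with pytest.raises(ValueError):
            score_chain(m, "ACGT", 0, 5)

    def test_n_positions_score_zero(self):
        m = MarkovChainModel.uniform(0)
        assert score_chain(m, "ANNA", 0, 4) == pytest.approx(2 * LOG_Q)

    @given(st.text(alphabet="ACGT", min_size=2, max_size=40),
           st.data())
    @settings(max_examples=60, deadline=None)
    def test_additivity_over_splits(self, seq, data):
        m = MarkovChainModel.from_probs(
            np.random.default_rng(5).dirichlet(np.ones(4), size=16))
        b = data.draw(st.integers(0, len(seq)))
        whole = score_chain(m, seq, 0, len(seq))
        split = score_chain(m, seq, 0, b) + score_chain(m, seq, b, len(seq))
        assert whole == pytest.approx(split, abs=1e-9)


class TestScorePeriodic:
    def test_identical_phases_degenerate_to_chain(self):
        m = MarkovChainModel.from_probs(
            np.random.default_rng(0).dirichlet(np.ones(4), size=4))
        per = PeriodicMarkovModel([m, m, m])
        seq = "ACGTACGTAC"
        assert score_periodic(per, seq, 2, 9, 0) == pytest.approx(
            score_chain(m, seq, 2, 9))

    def test_phase_shift_indexing(self):
        rng = np.random.default_rng(1)
        ms = [MarkovChainModel.from_probs(rng.dirichlet(np.ones(4)))
              for _ in range(3)]
        per = PeriodicMarkovModel(ms)
        seq = "ACGTAC"
        manual = sum(
            float(ms[(1 + i) % 3].per_position_logp(encode(seq))[2 + i])
            for i in range(3)
        )
        assert score_periodic(per, seq, 2, 5, 1) == pytest.approx(manual)

    def test_codon_bias_prefers_in_frame(self):
        """A codon-biased model scores an in-frame run above its frame-shifted
        copy in expectation (Monte-Carlo over ~1000 generated codons)."""
        cfg = synthetic.strong_signal_config(seed=3, n=12)
        corpus, _ = synthetic.generate_corpus(cfg)
        encs = [encode(t.seq) for t in corpus]
        refs = [t.annotation for t in corpus]
        per = PeriodicMarkovModel.fit(
            [(e, r.start + 3, r.end - 3, 0) for e, r in zip(encs, refs)],
            order=2, pseudocount=1.0)
        in_frame = shifted = 0.0
        for e, r in zip(encs, refs):
            a, b = r.start + 3, r.end - 6
            in_frame += score_periodic(per, e, a, b, 0)
            shifted += score_periodic(per, e, a + 1, b + 1, 0)
        assert in_frame > shifted


class TestScorePositional:
    def _atg_model(self):
        cols = np.full((3, 4), 1e-12)
        for j, base in enumerate("ATG"):
            cols[j, "ACGT".index(base)] = 1.0
        cols /= cols.sum(axis=1, keepdims=True)
        return PositionalModel(0, np.log(cols))

    def test_forced_codon(self):
        m = self._atg_model()
        assert score_positional(m, "ATG", 0) == pytest.approx(0.0, abs=1e-9)
        assert score_positional(m, "ATC", 0) < -20

    def test_out_of_bounds_columns_skipped(self):
        m = PositionalModel.uniform(-6, 6)
        # anchor 0: all six upstream columns fall off the sequence edge
        assert score_positional(m, "ACGTACGT", 0) == 0.0

    def test_uniform_window(self):
        m = PositionalModel.uniform(0, 5)
        assert score_positional(m, "ACGTA", 0) == pytest.approx(5 * LOG_Q)


class TestDurationModel:
    def test_point_mass(self):
        d = DurationModel.point_mass(300)
        assert duration_logp(d, 300) == 0.0
        assert duration_logp(d, 299) == -math.inf

    def test_total_mass_is_one(self):
        d = fit_duration([10, 12, 14, 30, 31, 50], smoothing_bandwidth=3.0)
        body = float(np.exp(d.log_pmf).sum())
        # geometric tail sums analytically to tail_mass
        assert body + d.tail_mass == pytest.approx(1.0, abs=1e-9)
        tail_terms = [math.exp(d.logp(d.max_len + m)) for m in range(1, 4000)]
        assert body + sum(tail_terms) == pytest.approx(1.0, abs=1e-6)

    def test_below_min_is_impossible(self):
        d = fit_duration([30, 33, 36], smoothing_bandwidth=1.0, step=3)
        assert d.logp(27) == -math.inf
        assert d.logp(31) == -math.inf  # off the codon grid

    def test_fit_concentrates_near_modes(self):
        d = fit_duration([300, 300, 600], smoothing_bandwidth=10.0)
        assert d.logp(300) > d.logp(600) > d.logp(450)

    def test_degenerate_fit_is_near_point_mass(self):
        d = fit_duration([120] * 20, smoothing_bandwidth=0.0)
        assert d.logp(120) == pytest.approx(0.0, abs=1e-9)
        assert d.logp(121) == -math.inf

    def test_fitted_mean_tracks_sample_mean(self):
        rng = np.random.default_rng(7)
        lengths = np.round(np.exp(rng.normal(5.5, 0.4, size=1000))).astype(int)
        d = fit_duration(lengths.tolist(), smoothing_bandwidth=10.0)
        assert d.mean() == pytest.approx(float(lengths.mean()), rel=0.10)

    def test_fit_requires_two_observations(self):
        with pytest.raises(ValueError):
            fit_duration([5], smoothing_bandwidth=1.0)

    def test_sampling_stays_in_support(self):
        d = fit_duration([9, 12, 15, 18, 60], smoothing_bandwidth=2.0, step=3)
        rng = np.random.default_rng(0)
        draws = [d.sample(rng) for _ in range(300)]
        assert all(x >= d.min_len and (x - d.min_len) % 3 == 0 for x in draws)


class TestEstimatorConsistency:
    def test_mle_maximizes_own_training_likelihood(self):
        """The fitted order-0 chain beats random alternatives on the corpus
        it was trained on (direct likelihood enumeration)."""
        rng = np.random.default_rng(11)
        seqs = ["".join(rng.choice(list("ACGT"), p=[.5, .2, .2, .1], size=30))
                for _ in range(20)]
        regions = [(encode(s), 0, len(s)) for s in seqs]
        fitted = MarkovChainModel.fit(regions, order=0, pseudocount=1e-9,
                                      min_context_obs=1)
        ll_fit = sum(score_chain(fitted, s, 0, len(s)) for s in seqs)
        for _ in range(25):
            alt = MarkovChainModel.from_probs(rng.dirichlet(np.ones(4)))
            ll_alt = sum(score_chain(alt, s, 0, len(s)) for s in seqs)
            assert ll_fit >= ll_alt

    def test_constructor_rejects_unnormalized(self):
        bad = np.log(np.array([[0.5, 0.2, 0.2, 0.2]]))
        with pytest.raises(ValueError):
            MarkovChainModel(0, bad, np.full(4, LOG_Q))
        with pytest.raises(ValueError):
            PositionalModel(0, bad)
        with pytest.raises(ValueError):
            DurationModel(1, np.log(np.array([0.5, 0.4])))
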