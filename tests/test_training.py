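"""GC binning, supervised estimation and bundle persistence."""

import json
import math

import numpy as np
import pytest

from transcds import synthetic
from transcds.ghmm import viterbi_decode
from transcds.prob_models import MarkovChainModel, encode
from transcds.training import (
    BundleFormatError,
    TrainedBundle,
    TrainingConfig,
    assign_bin,
    codon_phase_tv,
    corpus_loglik,
    gc_fraction,
    load_bundle,
    save_bundle,
    train,
)


class TestGcFraction:
    @pytest.mark.parametrize("seq,expected", [
        ("ATGC", 0.5),
        ("GGCC", 1.0),
        ("ANGC", 2 / 3),
        ("NNN", 0.5),
    ])
    def test_examples(self, seq, expected):
        assert gc_fraction(seq) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            gc_fraction("")


class TestAssignBin:
    edges = (0.45, 0.55)

    def test_interior(self):
        assert assign_bin(self.edges, 0.5) == 1

    def test_half_open_edge(self):
        assert assign_bin(self.edges, 0.45) == 1

    def test_upper_boundary(self):
        assert assign_bin(self.edges, 1.0) == 2
        assert assign_bin(self.edges, 0.0) == 0


class TestEstimation:
    def test_laplace_formula_on_homopolymer(self):
        n = 40
        regions = [(encode("A" * n), 0, n)]
        m = MarkovChainModel.fit(regions, order=0, pseudocount=1.0)
        assert math.exp(m.logprob[0, 0]) == pytest.approx((n + 1) / (n + 4))

    def test_utr_presence_frequencies(self, strong_bundle):
        # the strong-signal generator nearly always emits both UTRs, so the
        # estimated empty-UTR probabilities are near the smoothing floor
        ps = strong_bundle.paramsets[1]
        assert ps.p_utr5_empty < 0.1
        assert ps.p_utr3_empty < 0.1

    def test_too_few_transcripts_rejected(self):
        corpus, _ = synthetic.generate_corpus(
            synthetic.strong_signal_config(seed=1, n=10))
        with pytest.raises(ValueError, match="at least"):
            train(corpus, TrainingConfig())

    def test_invalid_annotations_skipped_with_warning(self):
        corpus, _ = synthetic.generate_corpus(
            synthetic.strong_signal_config(seed=1, n=60))
        negs, _ = synthetic.generate_corpus(synthetic.strong_signal_config(
            seed=2, n=6, frac_noncoding=1.0))
        with pytest.warns(UserWarning, match="skipped"):
            bundle = train(corpus + negs, TrainingConfig())
        assert bundle.metadata["n_skipped"] == 6
        assert bundle.metadata["n_train"] == 60

    def test_likelihood_improves_over_uniform_baseline(self, strong_bundle,
                                                       strong_test_corpus):
        uniform = TrainedBundle(
            gc_bin_edges=strong_bundle.gc_bin_edges,
            paramsets=[p.uniformized() for p in strong_bundle.paramsets],
            metadata={},
        )
        ll_fit = corpus_loglik(strong_bundle, strong_test_corpus)
        ll_uni = corpus_loglik(uniform, strong_test_corpus)
        assert ll_fit > ll_uni

    def test_sparse_bins_borrow_nearest(self):
        cfg = synthetic.strong_signal_config(seed=4, n=80)
        corpus, _ = synthetic.generate_corpus(cfg)
        bundle = train(corpus, TrainingConfig())
        # strong-signal corpora sit in a narrow GC band; some bins borrow
        borrowed = bundle.metadata["borrowed_bins"]
        counts = bundle.metadata["bin_counts"]
        for bin_str, src in borrowed.items():
            assert counts[int(bin_str)] < 30
            if src >= 0:
                assert counts[src] >= 30

    def test_recovery_error_shrinks_with_training_size(self):
        """Estimation error of the codon-phase conditionals decreases as the
        training corpus grows (fixed seed)."""
        cfg = TrainingConfig(gc_bin_edges=(), min_train_sequences=50)
        base, _ = synthetic.generate_corpus(
            synthetic.strong_signal_config(seed=31, n=300))
        truth_bundle = train(base, cfg)
        ps = truth_bundle.paramsets[0]
        small = synthetic.sample_corpus_from_paramset(
            ps, 150, seed=32, forbid_internal_stops=False)
        large = synthetic.sample_corpus_from_paramset(
            ps, 900, seed=33, forbid_internal_stops=False)
        tv_small = codon_phase_tv(ps.cds_model,
                                  train(small, cfg).paramsets[0].cds_model,
                                  large)
        tv_large = codon_phase_tv(ps.cds_model,
                                  train(large, cfg).paramsets[0].cds_model,
                                  large)
        assert tv_large < tv_small


class TestBundlePersistence:
    def test_round_trip_field_equality(self, strong_bundle, tmp_path):
        p = tmp_path / "model.json"
        save_bundle(strong_bundle, p)
        loaded = load_bundle(p)
        assert loaded.to_payload() == strong_bundle.to_payload()

    def test_decoding_is_bit_identical_after_reload(self, strong_bundle,
                                                    strong_test_corpus,
                                                    tmp_path):
        p = tmp_path / "model.json"
        save_bundle(strong_bundle, p)
        loaded = load_bundle(p)
        for t in strong_test_corpus[:5]:
            a1 = strong_bundle.params_for(gc_fraction(t.seq)).full_architecture()
            a2 = loaded.params_for(gc_fraction(t.seq)).full_architecture()
            s1 = viterbi_decode(a1, t.seq)
            s2 = viterbi_decode(a2, t.seq)
            assert s1.log_score == s2.log_score  # exact, not approx
            assert s1.segments == s2.segments

    def test_edited_file_fails_checksum(self, strong_bundle, tmp_path):
        p = tmp_path / "model.json"
        save_bundle(strong_bundle, p)
        doc = json.loads(p.read_text())
        doc["payload"]["metadata"]["n_train"] = -5
        p.write_text(json.dumps(doc))
        with pytest.raises(BundleFormatError, match="checksum"):
            load_bundle(p)

    def test_negative_count_rejected_even_with_valid_checksum(
            self, strong_bundle, tmp_path):
        import hashlib
        p = tmp_path / "model.json"
        save_bundle(strong_bundle, p)
        doc = json.loads(p.read_text())
        doc["payload"]["metadata"]["n_train"] = -5
        canon = json.dumps(doc["payload"], sort_keys=True,
                           separators=(",", ":"))
        doc["sha256"] = hashlib.sha256(canon.encode()).hexdigest()
        p.write_text(json.dumps(doc))
        with pytest.raises(BundleFormatError, match="negative"):
            load_bundle(p)

    def test_version_mismatch(self, strong_bundle, tmp_path):
        p = tmp_path / "model.json"
        save_bundle(strong_bundle, p)
        doc = json.loads(p.read_text())
        doc["format_version"] = 99
        p.write_text(json.dumps(doc))
        with pytest.raises(BundleFormatError, match="version"):
            load_bundle(p)

    def test_truncated_file(self, strong_bundle, tmp_path):
        p = tmp_path / "model.json"
        save_bundle(strong_bundle, p)
        p.write_text(p.read_text()[:200])
        with pytest.raises(BundleFormatError):
            load_bundle(p)
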