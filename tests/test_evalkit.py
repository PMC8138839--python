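"""Metric definitions and validation-set constructions."""

from fractions import Fraction

import numpy as np
import pytest

from transcds import synthetic
from transcds.evalkit import (
    EvalOutcome,
    build_mixed_negative_run,
    build_testsets,
    dataset_manifest,
    evaluate_calls,
    evaluate_negatives,
    match_call,
    precision_recall_f1,
    specificity_as_printed,
)
from transcds.predict import CdsCall
from transcds.seqio import ReferenceCds, Transcript, reverse_complement


def _call(start, end, strand="+", has_start=True, has_stop=True, frame=0,
          tid="t"):
    return CdsCall(transcript_id=tid, start=start, end=end, strand=strand,
                   frame=frame, has_start=has_start, has_stop=has_stop,
                   log_score=0.0)


class TestMatchCall:
    ref = ReferenceCds(start=10, end=43, strand="+")

    def test_exact_match_is_tp_under_both(self):
        c = _call(10, 43)
        assert match_call(self.ref, c, "stop_match") == "TP"
        assert match_call(self.ref, c, "full_cds_match") == "TP"

    def test_correct_stop_wrong_start(self):
        # start 3 nt downstream: stop criterion forgives, full does not
        c = _call(13, 43)
        assert match_call(self.ref, c, "stop_match") == "TP"
        assert match_call(self.ref, c, "full_cds_match") == "FP"

    def test_no_call_is_fn_under_both(self):
        assert match_call(self.ref, None, "stop_match") == "FN"
        assert match_call(self.ref, None, "full_cds_match") == "FN"

    def test_strand_mismatch_is_fp(self):
        c = _call(10, 43, strand="-", frame=0)
        assert match_call(self.ref, c, "full_cds_match") == "FP"

    def test_minus_strand_stop_anchor(self):
        # on the minus strand the stop codon sits at the interval start
        ref = ReferenceCds(start=10, end=43, strand="-")
        assert match_call(ref, _call(10, 49, strand="-"), "stop_match") == "TP"
        assert match_call(ref, _call(13, 43, strand="-"), "stop_match") == "FP"

    def test_id_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="evaluated against"):
            match_call(self.ref, _call(10, 43, tid="other"), "stop_match",
                       transcript_id="t")


class TestMetrics:
    def test_printed_formulas(self):
        out = EvalOutcome(tp=8, fp=2, fn=0)
        p, r, f1 = precision_recall_f1(out)
        assert (p, r) == (0.8, 1.0)
        assert f1 == pytest.approx(2 * 0.8 / 1.8)

    def test_degenerate_conventions(self):
        assert precision_recall_f1(EvalOutcome(fn=5)) == (0.0, 0.0, 0.0)
        assert precision_recall_f1(EvalOutcome()) == (0.0, 0.0, 0.0)

    @pytest.mark.parametrize("tp,fp,fn", [(5, 2, 2), (1, 3, 3), (9, 0, 0)])
    def test_equal_precision_recall_equals_f1(self, tp, fp, fn):
        p, r, f1 = precision_recall_f1(EvalOutcome(tp=tp, fp=fp, fn=fn))
        assert p == r
        assert f1 == pytest.approx(p)

    def test_specificity_forms(self):
        rep = specificity_as_printed(EvalOutcome(fp=5, tn=95,
                                                 criterion="any_call"))
        assert rep.printed_form == pytest.approx(0.05)
        assert rep.standard_form == pytest.approx(0.95)
        rep0 = specificity_as_printed(EvalOutcome(fp=0, tn=10,
                                                  criterion="any_call"))
        assert (rep0.printed_form, rep0.standard_form) == (0.0, 1.0)

    def test_specificity_forms_are_complements(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            fp, tn = int(rng.integers(0, 50)), int(rng.integers(1, 50))
            rep = specificity_as_printed(EvalOutcome(fp=fp, tn=tn,
                                                     criterion="any_call"))
            assert rep.printed_form + rep.standard_form == pytest.approx(1.0)

    def test_empty_negative_set_errors(self):
        with pytest.raises(ValueError):
            specificity_as_printed(EvalOutcome(tp=3, criterion="any_call"))

    def test_counts_agree_with_independent_recount(self):
        """Module totals equal a from-scratch recount with exact fractions."""
        ref = ReferenceCds(start=6, end=27, strand="+")
        calls = [_call(6, 27), _call(9, 27), _call(6, 24), None, _call(6, 27)]
        out = evaluate_calls([(ref, c) for c in calls], "full_cds_match")
        labels = []
        for c in calls:
            if c is None:
                labels.append("FN")
            elif (c.start, c.end, c.strand) == (6, 27, "+"):
                labels.append("TP")
            else:
                labels.append("FP")
        assert (out.tp, out.fp, out.fn) == (labels.count("TP"),
                                            labels.count("FP"),
                                            labels.count("FN"))
        p, _, _ = precision_recall_f1(out)
        assert p == pytest.approx(
            float(Fraction(labels.count("TP"),
                           labels.count("TP") + labels.count("FP"))))


@pytest.fixture(scope="module")
def full_corpus():
    corpus, _ = synthetic.generate_corpus(
        synthetic.strong_signal_config(seed=88, n=50))
    return corpus


class TestBuildTestsets:
    def test_deterministic_under_seed(self, full_corpus):
        a = build_testsets(full_corpus, seed=5)
        b = build_testsets(full_corpus, seed=5)
        for key in a:
            assert [(t.id, t.seq, t.annotation) for t in a[key]] == \
                [(t.id, t.seq, t.annotation) for t in b[key]]

    def test_minimum_size_rule(self, full_corpus):
        sets = build_testsets(full_corpus, seed=5)
        by_id = {t.id: t for t in full_corpus}
        for key in ("no_start", "no_stop", "no_start_no_stop"):
            for t in sets[key]:
                src = by_id[t.id]
                r = src.annotation
                if key == "no_start":
                    fallback = len(src) - (r.start + 3)
                elif key == "no_stop":
                    fallback = r.end - 3
                else:
                    fallback = (r.end - 3) - (r.start + 3)
                assert len(t) >= min(150, fallback)

    def test_derived_sequences_are_substrings(self, full_corpus):
        sets = build_testsets(full_corpus, seed=5)
        by_id = {t.id: t.seq for t in full_corpus}
        for key, rows in sets.items():
            for t in rows:
                src = by_id[t.id]
                assert t.seq in src or reverse_complement(t.seq) in src

    def test_no_start_coordinate_bookkeeping(self, full_corpus):
        """The retained fragment re-translates in register: its annotated
        frame aligns its codons with the source CDS codons."""
        sets = build_testsets(full_corpus, seed=5)
        by_id = {t.id: t for t in full_corpus}
        for t in sets["no_start"]:
            r = t.annotation
            src = by_id[t.id]
            sr = src.annotation
            u = len(src) - len(t)  # bases pruned from the 5' end
            assert r.frame == (u - sr.start) % 3
            assert not r.has_start and r.has_stop
            # the stop codon is preserved at the annotated end
            assert t.seq[r.end - 3:r.end] == src.seq[sr.end - 3:sr.end]
            # first complete codon of the fragment is a codon of the source
            off = (3 - r.frame) % 3
            assert (u + off - sr.start) % 3 == 0

    def test_strand_blind_flips_half(self, full_corpus):
        sets = build_testsets(full_corpus, seed=5)
        flipped = [t for t in sets["full_strand_blind"]
                   if t.annotation.strand == "-"]
        assert len(flipped) == len(full_corpus) // 2

    def test_utr3_negatives_content(self, full_corpus):
        sets = build_testsets(full_corpus, seed=5)
        by_id = {t.id: t for t in full_corpus}
        for t in sets["utr3_negatives"]:
            src = by_id[t.id]
            assert t.seq == src.seq[src.annotation.end:]
            assert t.annotation is None


class TestMixedNegativeRun:
    def test_counts_and_truth_table(self, full_corpus):
        negs, _ = synthetic.generate_corpus(synthetic.strong_signal_config(
            seed=9, n=20, frac_noncoding=1.0))
        partial = build_testsets(full_corpus, seed=1)["no_start"]
        records, truth = build_mixed_negative_run(
            full_corpus, partial, negs, seed=2, n_full=30, n_partial=30)
        assert len(records) == 30 + 30 + len(negs)
        assert truth["is_coding"].sum() == 60
        assert list(truth["id"]) == [t.id for t in records]

    def test_short_negatives_excluded(self, full_corpus):
        negs = [Transcript(id="short", seq="ACGT" * 20)]  # 80 nt < 200
        with pytest.raises(ValueError, match="length filter"):
            build_mixed_negative_run(full_corpus, full_corpus, negs, seed=0,
                                     n_full=5, n_partial=5)

    def test_scales_down_with_warning(self, full_corpus):
        negs, _ = synthetic.generate_corpus(synthetic.strong_signal_config(
            seed=9, n=5, frac_noncoding=1.0))
        with pytest.warns(UserWarning, match="scaling down"):
            records, truth = build_mixed_negative_run(
                full_corpus, full_corpus, negs, seed=0,
                n_full=500, n_partial=10)
        assert truth["is_coding"].sum() == len(full_corpus) + 10

    def test_reproducible(self, full_corpus):
        negs, _ = synthetic.generate_corpus(synthetic.strong_signal_config(
            seed=9, n=10, frac_noncoding=1.0))
        r1, t1 = build_mixed_negative_run(full_corpus, full_corpus, negs,
                                          seed=4, n_full=10, n_partial=10)
        r2, t2 = build_mixed_negative_run(full_corpus, full_corpus, negs,
                                          seed=4, n_full=10, n_partial=10)
        assert [t.id for t in r1] == [t.id for t in r2]
        assert t1.equals(t2)


def test_manifest_columns(full_corpus):
    df = dataset_manifest(full_corpus[:5], origin="full")
    assert list(df["origin"].unique()) == ["full"]
    assert set(df.columns) >= {"id", "cds_start", "cds_end", "strand",
                               "frame", "has_start", "has_stop", "is_coding"}
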