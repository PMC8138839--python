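"""Evaluation protocol: confusion-table metrics and derived test sets.

Two match criteria are used for positive sets: ``stop_match`` counts a
prediction correct when its stop codon coincides with the reference (start
may differ), ``full_cds_match`` only when start, end and strand all coincide.
A sequence with no prediction is a false negative; any other prediction is a
false positive.  On negative sets any prediction at all is a false positive
(``any_call``).

Specificity is reported in two forms: the *printed form* FP/(FP+TN) — a
false-positive rate — and the conventional *standard form* TN/(TN+FP); the
two always sum to one and reports carry both, clearly labeled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .seqio import ReferenceCds, Transcript, reverse_complement

CRITERIA = ("stop_match", "full_cds_match", "any_call")


@dataclass(frozen=True)
class EvalOutcome:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    criterion: str = "stop_match"

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _stop_anchor(x) -> Tuple[str, int]:
    """(strand, position just past the stop codon in reading orientation)."""
    return (x.strand, x.end) if x.strand == "+" else (x.strand, x.start)


def match_call(ref: ReferenceCds, call, criterion: str,
               transcript_id: Optional[str] = None) -> str:
    """Label a single prediction TP / FP / FN against its reference."""
    if criterion not in ("stop_match", "full_cds_match"):
        raise ValueError(f"criterion {criterion!r} needs a positive reference")
    if call is not None and transcript_id is not None:
        cid = getattr(call, "transcript_id", transcript_id)
        if cid != transcript_id:
            raise ValueError(
                f"call for {cid!r} evaluated against reference {transcript_id!r}"
            )
    if call is None:
        return "FN"
    if criterion == "stop_match":
        ok = (ref.has_stop and call.has_stop
              and _stop_anchor(ref) == _stop_anchor(call))
    else:
        ok = (call.start, call.end, call.strand) == (ref.start, ref.end, ref.strand)
    return "TP" if ok else "FP"


def evaluate_calls(pairs: Sequence[Tuple[ReferenceCds, object]],
                   criterion: str) -> EvalOutcome:
    tp = fp = fn = 0
    for ref, call in pairs:
        label = match_call(ref, call, criterion)
        tp += label == "TP"
        fp += label == "FP"
        fn += label == "FN"
    return EvalOutcome(tp=tp, fp=fp, fn=fn, tn=0, criterion=criterion)


def evaluate_negatives(calls: Sequence[object]) -> EvalOutcome:
    """On a negative set any prediction is a false positive."""
    fp = sum(1 for c in calls if c is not None)
    return EvalOutcome(fp=fp, tn=len(calls) - fp, criterion="any_call")


def precision_recall_f1(out: EvalOutcome) -> Tuple[float, float, float]:
    precision = out.tp / (out.tp + out.fp) if out.tp + out.fp else 0.0
    recall = out.tp / (out.tp + out.fn) if out.tp + out.fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return precision, recall, f1


@dataclass(frozen=True)
class SpecificityReport:
    printed_form: float   # FP / (FP + TN), a false-positive rate
    standard_form: float  # TN / (TN + FP)


def specificity_as_printed(out: EvalOutcome) -> SpecificityReport:
    if out.fp + out.tn == 0:
        raise ValueError("empty negative set: fp + tn == 0")
    fpr = out.fp / (out.fp + out.tn)
    return SpecificityReport(printed_form=fpr, standard_form=1.0 - fpr)


# ---------------------------------------------------------------------------
# Test-set constructions
# ---------------------------------------------------------------------------

def _require_complete(t: Transcript) -> ReferenceCds:
    ref = t.annotation
    if ref is None or not (ref.has_start and ref.has_stop) or ref.strand != "+":
        raise ValueError(
            f"transcript {t.id}: test-set construction needs complete "
            "plus-strand annotations"
        )
    return ref


def truncate_no_start(t: Transcript, rng: np.random.Generator,
                      min_len: int = 150) -> Optional[Transcript]:
    """Prune the 5' part at a random point inside the CDS, eliminating the
    start codon; the result keeps at least ``min_len`` nt when the source
    permits, otherwise only the start codon (and 5'UTR) is pruned."""
    ref = _require_complete(t)
    if ref.end - ref.start < 9:  # no CDS interior to retain
        return None
    lo = ref.start + 3
    hi = min(ref.end - 4, len(t) - min_len)
    u = int(rng.integers(lo, hi + 1)) if hi >= lo else lo
    new_ref = ReferenceCds(start=0, end=ref.end - u, strand="+",
                           has_start=False, has_stop=True,
                           frame=(u - ref.start) % 3)
    return Transcript(id=t.id, seq=t.seq[u:], annotation=new_ref)


def truncate_no_stop(t: Transcript, rng: np.random.Generator,
                     min_len: int = 150) -> Optional[Transcript]:
    """Prune the 3' part at a random point inside the CDS, eliminating the
    stop codon (the 3'UTR goes with it)."""
    ref = _require_complete(t)
    if ref.end - ref.start < 9:
        return None
    lo = max(ref.start + 4, min_len)
    hi = ref.end - 3
    v = int(rng.integers(lo, hi + 1)) if hi >= lo else hi
    if v <= ref.start + 3:
        return None
    new_ref = ReferenceCds(start=ref.start, end=v, strand="+",
                           has_start=True, has_stop=False, frame=0)
    return Transcript(id=t.id, seq=t.seq[:v], annotation=new_ref)


def truncate_both(t: Transcript, rng: np.random.Generator,
                  min_len: int = 150) -> Optional[Transcript]:
    """Prune both ends, retaining only an interior piece of the CDS."""
    ref = _require_complete(t)
    if ref.end - ref.start < 9:
        return None
    lo_u, hi_v = ref.start + 3, ref.end - 3
    if hi_v - lo_u >= min_len:
        u = int(rng.integers(lo_u, hi_v - min_len + 1))
        v = int(rng.integers(u + min_len, hi_v + 1))
    else:
        u, v = lo_u, hi_v
    if v <= u:
        return None
    new_ref = ReferenceCds(start=0, end=v - u, strand="+",
                           has_start=False, has_stop=False,
                           frame=(u - ref.start) % 3)
    return Transcript(id=t.id, seq=t.seq[u:v], annotation=new_ref)


def flip_to_reverse_complement(t: Transcript) -> Transcript:
    """Replace a transcript by its reverse complement, mapping the
    annotation into the new coordinates with strand '-'."""
    ref = _require_complete(t)
    L = len(t)
    new_ref = ReferenceCds(start=L - ref.end, end=L - ref.start, strand="-",
                           has_start=ref.has_start, has_stop=ref.has_stop,
                           frame=ref.frame)
    return Transcript(id=t.id, seq=reverse_complement(t.seq),
                      annotation=new_ref)


def build_testsets(full_set: Sequence[Transcript], seed: int,
                   min_len: int = 150) -> Dict[str, List[Transcript]]:
    """The derived validation sets: strand-specific and strand-blind
    full-length sets, the three partial-transcript sets and the 3'UTR
    negative set.  Fixed ``seed`` makes every construction reproducible."""
    for t in full_set:
        _require_complete(t)
    rng = np.random.default_rng(seed)
    out: Dict[str, List[Transcript]] = {}
    out["full_strand_specific"] = list(full_set)

    n = len(full_set)
    flip = set(rng.choice(n, size=n // 2, replace=False).tolist())
    out["full_strand_blind"] = [
        flip_to_reverse_complement(t) if i in flip else t
        for i, t in enumerate(full_set)
    ]

    excluded = 0
    for key, fn in (("no_start", truncate_no_start),
                    ("no_stop", truncate_no_stop),
                    ("no_start_no_stop", truncate_both)):
        rows = []
        for t in full_set:
            d = fn(t, rng, min_len=min_len)
            if d is None:
                excluded += 1
            else:
                rows.append(d)
        out[key] = rows
    if excluded:
        warnings.warn(f"{excluded} transcripts excluded from partial sets "
                      "(CDS interior too short)")

    negs = []
    for t in full_set:
        utr3 = t.seq[t.annotation.end:]
        if utr3:
            negs.append(Transcript(id=t.id, seq=utr3))
    out["utr3_negatives"] = negs
    return out


def build_mixed_negative_run(full: Sequence[Transcript],
                             partial: Sequence[Transcript],
                             negatives: Sequence[Transcript], seed: int,
                             n_full: int = 500, n_partial: int = 500,
                             min_negative_len: int = 200,
                             ) -> Tuple[List[Transcript], pd.DataFrame]:
    """Mixed coding/non-coding dataset: ``n_full`` full-length and
    ``n_partial`` partial transcripts shuffled among the non-coding
    sequences (>= ``min_negative_len`` nt), with a truth table."""
    rng = np.random.default_rng(seed)
    negs = [t for t in negatives if len(t) >= min_negative_len]
    if not negs:
        raise ValueError("no usable negative sequences (length filter)")

    def take(pool: Sequence[Transcript], k: int, label: str) -> List[Transcript]:
        if len(pool) < k:
            warnings.warn(f"only {len(pool)} {label} transcripts available; "
                          f"requested {k} — scaling down")
            k = len(pool)
        idx = rng.choice(len(pool), size=k, replace=False)
        return [pool[i] for i in sorted(idx.tolist())]

    records = ([(t, True) for t in take(full, n_full, "full-length")]
               + [(t, True) for t in take(partial, n_partial, "partial")]
               + [(t, False) for t in negs])
    order = rng.permutation(len(records))
    shuffled = [records[i] for i in order]
    truth = pd.DataFrame(
        {"id": [t.id for t, _ in shuffled],
         "is_coding": [c for _, c in shuffled]}
    )
    return [t for t, _ in shuffled], truth


def dataset_manifest(transcripts: Sequence[Transcript],
                     origin: str) -> pd.DataFrame:
    """Tab-separable truth table for a derived dataset."""
    rows = []
    for t in transcripts:
        r = t.annotation
        rows.append({
            "id": t.id, "origin": origin, "length": len(t),
            "cds_start": r.start if r else pd.NA,
            "cds_end": r.end if r else pd.NA,
            "strand": r.strand if r else pd.NA,
            "frame": r.frame if r else pd.NA,
            "has_start": r.has_start if r else False,
            "has_stop": r.has_stop if r else False,
            "is_coding": r is not None,
        })
    return pd.DataFrame(rows)


def metrics_row(name: str, out: EvalOutcome) -> dict:
    p, r, f1 = precision_recall_f1(out)
    return {"set": name, "criterion": out.criterion, "n": out.n,
            "tp": out.tp, "fp": out.fp, "fn": out.fn, "tn": out.tn,
            "precision": p, "recall": r, "f1": f1}
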