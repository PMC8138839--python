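"""Prediction orchestration: GC-bin selection, full vs partial architecture,
strand-specific vs strand-blind decoding, and coding-potential
classification.

Strand-blind mode decodes both the input sequence and its reverse complement
with the same strand-specific model and keeps the higher-scoring call, mapped
back to input coordinates (plus strand preferred on exact ties).  A call is
emitted only when the best path contains a coding segment and beats the best
non-coding path by at least the score margin.
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

from .ghmm import (
    SequenceScorer,
    best_noncoding_score,
    extract_cds_call,
    viterbi_decode,
)
from .seqio import START_CODON, STOP_CODONS, Transcript, reverse_complement
from .training import TrainedBundle, gc_fraction

logger = logging.getLogger("transcds")

DEFAULT_MIN_LENGTH = 60


@dataclass(frozen=True)
class CdsCall:
    """A predicted CDS interval in input-transcript coordinates."""

    transcript_id: str
    start: int
    end: int
    strand: str
    frame: int
    has_start: bool
    has_stop: bool
    log_score: float
    model_tag: str = "full"
    gc_bin: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("invalid call interval")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.has_start and self.has_stop and (self.end - self.start) % 3:
            raise ValueError("complete call length must be a multiple of 3")

    def oriented_cds(self, seq: str) -> str:
        sub = seq[self.start:self.end]
        return reverse_complement(sub) if self.strand == "-" else sub


def _check_call_invariants(call: CdsCall, seq: str) -> None:
    cds = call.oriented_cds(seq)
    if call.has_start and not cds.startswith(START_CODON):
        raise RuntimeError(f"{call.transcript_id}: called CDS lacks ATG")
    if call.has_stop and cds[-3:] not in STOP_CODONS:
        raise RuntimeError(f"{call.transcript_id}: called CDS lacks stop codon")
    if call.has_start and call.has_stop:
        for i in range(0, len(cds) - 3, 3):
            if cds[i:i + 3] in STOP_CODONS and i > 0:
                raise RuntimeError(
                    f"{call.transcript_id}: internal in-frame stop at {i}"
                )


def predict_one(bundle: TrainedBundle, t: Transcript, mode: str = "full",
                strand: str = "plus", margin: float = 0.0,
                min_length: int = DEFAULT_MIN_LENGTH) -> Optional[CdsCall]:
    """Predict the CDS of one transcript; ``None`` when no confident call."""
    if strand not in ("plus", "both"):
        raise ValueError("strand must be 'plus' or 'both'")
    L = len(t)
    if L < min_length:
        logger.info("id=%s outcome=skipped reason=below_min_length len=%d",
                    t.id, L)
        return None
    gc = gc_fraction(t.seq)
    gc_bin = bundle.bin_for(gc)
    arch = bundle.paramsets[gc_bin].architecture(mode)

    candidates: List[Tuple[str, str]] = [("+", t.seq)]
    if strand == "both":
        candidates.append(("-", reverse_complement(t.seq)))

    best = None  # (score, is_coding, strand, path, noncoding_score)
    for strand_tag, seq in candidates:
        scorer = SequenceScorer(seq)
        path = viterbi_decode(arch, seq, scorer)
        if path is None:
            continue
        region = extract_cds_call(path, L)
        nc = best_noncoding_score(arch, seq, scorer)
        key = (path.log_score, region is not None)
        if best is None or key > (best[0], best[1]):
            best = (path.log_score, region is not None, strand_tag, region, nc)
    if best is None:
        logger.info("id=%s gc=%.3f bin=%d outcome=no_path", t.id, gc, gc_bin)
        return None
    score, is_coding, strand_tag, region, nc = best
    if region is None or score - nc < margin:
        logger.info("id=%s gc=%.3f bin=%d strand=%s score=%.3f outcome=no_call",
                    t.id, gc, gc_bin, strand_tag, score)
        return None
    if strand_tag == "-":
        start, end = L - region.end, L - region.start
    else:
        start, end = region.start, region.end
    call = CdsCall(
        transcript_id=t.id, start=start, end=end, strand=strand_tag,
        frame=region.frame, has_start=region.has_start,
        has_stop=region.has_stop, log_score=score, model_tag=mode,
        gc_bin=gc_bin,
    )
    _check_call_invariants(call, t.seq)
    logger.info("id=%s gc=%.3f bin=%d strand=%s score=%.3f outcome=called "
                "cds=%d-%d", t.id, gc, gc_bin, strand_tag, score, start, end)
    return call


@dataclass(frozen=True)
class PredictionResult:
    """Per-sequence outcome of a batch run; ``error`` isolates failures."""

    id: str
    transcript: Optional[Transcript]
    call: Optional[CdsCall]
    error: Optional[str] = None


def _as_transcript(item: Union[Transcript, Tuple[str, str]]) -> Transcript:
    if isinstance(item, Transcript):
        return item
    rec_id, seq = item
    return Transcript(id=rec_id, seq=seq.upper())


def _predict_chunk(args) -> List[PredictionResult]:
    bundle, items, mode, strand, margin, min_length = args
    out: List[PredictionResult] = []
    for item in items:
        rec_id = item.id if isinstance(item, Transcript) else item[0]
        try:
            t = _as_transcript(item)
            call = predict_one(bundle, t, mode=mode, strand=strand,
                               margin=margin, min_length=min_length)
            out.append(PredictionResult(id=t.id, transcript=t, call=call))
        except Exception as exc:  # noqa: BLE001 — per-sequence isolation
            out.append(PredictionResult(id=rec_id, transcript=None,
                                        call=None, error=str(exc)))
    return out


def predict_many(bundle: TrainedBundle,
                 transcripts: Sequence[Union[Transcript, Tuple[str, str]]],
                 mode: str = "full", strand: str = "plus",
                 workers: int = 1, margin: float = 0.0,
                 min_length: int = DEFAULT_MIN_LENGTH,
                 ) -> List[PredictionResult]:
    """Batch prediction, input order preserved, output independent of the
    worker count (per-sequence computation is pure); per-sequence errors are
    captured in the result rows and the batch continues."""
    items = list(transcripts)
    if not items:
        return []
    if workers <= 1 or len(items) < 2 * workers:
        return _predict_chunk((bundle, items, mode, strand, margin, min_length))
    chunk = (len(items) + workers - 1) // workers
    jobs = [(bundle, items[i:i + chunk], mode, strand, margin, min_length)
            for i in range(0, len(items), chunk)]
    with ProcessPoolExecutor(max_workers=workers) as pool:
        parts = list(pool.map(_predict_chunk, jobs))
    return [r for part in parts for r in part]


def classify_coding(bundle: TrainedBundle, t: Transcript, margin: float = 0.0,
                    mode: str = "full", strand: str = "both",
                    min_length: int = DEFAULT_MIN_LENGTH) -> str:
    """Coding-potential label: ``coding`` iff a CDS call clears the margin."""
    call = predict_one(bundle, t, mode=mode, strand=strand, margin=margin,
                       min_length=min_length)
    return "coding" if call is not None else "noncoding"
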