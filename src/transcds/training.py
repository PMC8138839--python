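"""Supervised parameter estimation and model-bundle persistence.

Training is fully supervised from complete annotated transcripts (no
expectation-maximization): coding periodic chains are counted from in-frame
codon positions between the start and stop codons, UTR chains from their
regions, start/stop positional windows from aligned anchors, the complete-CDS
duration from CDS interior lengths (quantized to codon multiples) and the
partial-CDS duration from simulated uniform truncations of the training CDSs.
Transcripts are partitioned into GC-content bins, each bin carrying its own
full and partial architecture; sparse bins borrow the nearest populated bin.
"""

from __future__ import annotations

import bisect
import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .ghmm import GhmmArchitecture, GhmmState, _START_IDS, _STOP_IDS
from .prob_models import (
    NEG_INF,
    DurationModel,
    MarkovChainModel,
    PeriodicMarkovModel,
    PositionalModel,
    encode,
    fit_duration,
)
from .seqio import Transcript

BUNDLE_FORMAT = "transcds-bundle"
BUNDLE_VERSION = 1


class BundleFormatError(ValueError):
    """Corrupt, truncated or incompatible bundle file."""


def gc_fraction(seq: str) -> float:
    """(G+C)/(A+C+G+T); N is excluded from both sides, all-N gives 0.5."""
    if not seq:
        raise ValueError("gc_fraction of empty sequence")
    up = seq.upper()
    gc = up.count("G") + up.count("C")
    acgt = gc + up.count("A") + up.count("T")
    return gc / acgt if acgt else 0.5


def assign_bin(edges: Sequence[float], gc: float) -> int:
    """Index of the half-open GC interval containing ``gc``; the intervals
    are [0,e1), [e1,e2), ..., [ek,1] so gc == 1.0 maps to the last bin."""
    return bisect.bisect_right(list(edges), gc)


@dataclass
class TrainingConfig:
    gc_bin_edges: Tuple[float, ...] = (0.45, 0.55)
    cds_order: int = 4
    utr_order: int = 3
    pseudocount: float = 1.0
    min_context_obs: int = 10
    start_window: Tuple[int, int] = (-6, 12)   # (window_start, length)
    stop_window: Tuple[int, int] = (0, 6)
    duration_bandwidth: float = 9.0            # nt, Gaussian sigma
    duration_tail_mass: Optional[float] = None  # None: Laplace exceedance
    min_train_sequences: int = 50
    min_bin_sequences: int = 30
    partial_min_retained: int = 150
    truncation_seed: int = 727  # partial-duration simulation stream

    def to_dict(self) -> dict:
        d = asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)  # JSON-stable representation
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingConfig":
        d = dict(d)
        for key in ("gc_bin_edges", "start_window", "stop_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# flat prior over the completeness scenarios a fragment may be in; emissions
# and durations dominate decoding, these only arbitrate near-ties
_PARTIAL_INITIAL = {"UTR": 0.2, "Start": 0.2, "pCDS0": 0.2, "pCDS1": 0.2,
                    "pCDS2": 0.2}
_P_STOP_PRESENT = 0.5  # coding fragment retains its stop codon


@dataclass
class ParamSet:
    """All fitted parameters of one GC bin."""

    cds_model: PeriodicMarkovModel
    utr5_model: MarkovChainModel
    utr3_model: MarkovChainModel
    start_model: PositionalModel
    stop_model: PositionalModel
    fullcds_duration: DurationModel
    pcds_duration: DurationModel
    p_utr5_empty: float
    p_utr3_empty: float
    utr5_mean: float
    utr3_mean: float
    background_logp: Optional[np.ndarray] = None  # overall base composition
    n_train: int = 0

    def __post_init__(self) -> None:
        self._arch_cache: Dict[str, GhmmArchitecture] = {}
        for p in (self.p_utr5_empty, self.p_utr3_empty):
            if not (0.0 < p < 1.0):
                raise ValueError("empty-UTR probabilities must be in (0,1)")
        if self.n_train < 0:
            raise ValueError("negative training count")

    # -- helpers ---------------------------------------------------------
    @staticmethod
    def _geo_q(mean: float) -> float:
        return max(0.0, (mean - 1.0) / mean) if mean > 1.0 else 0.0

    def _utr_state(self, name: str, model: MarkovChainModel, mean: float,
                   p_empty: float, allow_empty: bool = True) -> GhmmState:
        q = self._geo_q(mean)
        return GhmmState(
            name=name, emission=model, duration_kind="geometric",
            self_loop_logp=math.log(q) if q > 0 else NEG_INF,
            empty_logp=math.log(p_empty) if allow_empty else NEG_INF,
        )

    def _codon_states(self) -> Dict[str, GhmmState]:
        bg = self.background_logp
        return {
            "Start": GhmmState("Start", self.start_model, "fixed", fixed_len=3,
                               allowed_triplets=_START_IDS,
                               flank_background=bg),
            "Stop": GhmmState("Stop", self.stop_model, "fixed", fixed_len=3,
                              allowed_triplets=_STOP_IDS,
                              flank_background=bg),
        }

    def full_architecture(self) -> GhmmArchitecture:
        if "full" not in self._arch_cache:
            states = {
                "UTR5": self._utr_state("UTR5", self.utr5_model,
                                        self.utr5_mean, self.p_utr5_empty),
                **self._codon_states(),
                "fullCDS": GhmmState("fullCDS", self.cds_model, "explicit",
                                     duration=self.fullcds_duration),
                "UTR3": self._utr_state("UTR3", self.utr3_model,
                                        self.utr3_mean, self.p_utr3_empty),
            }
            trans = {("UTR5", "Start"): 0.0, ("Start", "fullCDS"): 0.0,
                     ("fullCDS", "Stop"): 0.0, ("Stop", "UTR3"): 0.0}
            self._arch_cache["full"] = GhmmArchitecture(
                states=states, transitions=trans,
                initial={"UTR5": 0.0}, final={"UTR3", "UTR5"},
            )
        return self._arch_cache["full"]

    def partial_architecture(self) -> GhmmArchitecture:
        if "partial" not in self._arch_cache:
            states = {
                "UTR": self._utr_state("UTR", self.utr5_model, self.utr5_mean,
                                       self.p_utr5_empty, allow_empty=False),
                **self._codon_states(),
                "fullCDS": GhmmState("fullCDS", self.cds_model, "explicit",
                                     duration=self.fullcds_duration),
                "pCDS0": GhmmState("pCDS0", self.cds_model, "explicit",
                                   duration=self.pcds_duration),
                "pCDS1": GhmmState("pCDS1", self.cds_model, "explicit",
                                   duration=self.pcds_duration),
                "pCDS2": GhmmState("pCDS2", self.cds_model, "explicit",
                                   duration=self.pcds_duration),
                "UTR3": self._utr_state("UTR3", self.utr3_model,
                                        self.utr3_mean, self.p_utr3_empty),
            }
            lg = math.log(_P_STOP_PRESENT)
            trans = {("UTR", "Start"): 0.0, ("Start", "fullCDS"): 0.0,
                     ("fullCDS", "Stop"): lg, ("pCDS0", "Stop"): lg,
                     ("pCDS1", "Stop"): lg, ("pCDS2", "Stop"): lg,
                     ("Stop", "UTR3"): 0.0}
            initial = {k: math.log(v) for k, v in _PARTIAL_INITIAL.items()}
            self._arch_cache["partial"] = GhmmArchitecture(
                states=states, transitions=trans, initial=initial,
                final={"UTR3", "fullCDS", "pCDS0", "pCDS1", "pCDS2", "UTR"},
            )
        return self._arch_cache["partial"]

    def architecture(self, mode: str) -> GhmmArchitecture:
        if mode == "full":
            return self.full_architecture()
        if mode == "partial":
            return self.partial_architecture()
        raise ValueError(f"unknown mode {mode!r}")

    def uniformized(self) -> "ParamSet":
        """Same structure with uninformative emissions and flat durations
        (baseline for likelihood comparisons)."""
        def flat_dur(d: DurationModel) -> DurationModel:
            n = d.log_pmf.size
            return DurationModel(d.min_len, np.full(n, -math.log(n)),
                                 step=d.step)
        return ParamSet(
            cds_model=PeriodicMarkovModel(
                [MarkovChainModel.uniform(self.cds_model.order)] * 3),
            utr5_model=MarkovChainModel.uniform(self.utr5_model.order),
            utr3_model=MarkovChainModel.uniform(self.utr3_model.order),
            start_model=PositionalModel.uniform(
                self.start_model.window_start, self.start_model.length),
            stop_model=PositionalModel.uniform(
                self.stop_model.window_start, self.stop_model.length),
            fullcds_duration=flat_dur(self.fullcds_duration),
            pcds_duration=flat_dur(self.pcds_duration),
            p_utr5_empty=0.5, p_utr3_empty=0.5,
            utr5_mean=2.0, utr3_mean=2.0,
            background_logp=np.full(4, math.log(0.25)),
            n_train=self.n_train,
        )

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "cds_model": self.cds_model.to_dict(),
            "utr5_model": self.utr5_model.to_dict(),
            "utr3_model": self.utr3_model.to_dict(),
            "start_model": self.start_model.to_dict(),
            "stop_model": self.stop_model.to_dict(),
            "fullcds_duration": self.fullcds_duration.to_dict(),
            "pcds_duration": self.pcds_duration.to_dict(),
            "p_utr5_empty": self.p_utr5_empty,
            "p_utr3_empty": self.p_utr3_empty,
            "utr5_mean": self.utr5_mean,
            "utr3_mean": self.utr3_mean,
            "background_logp": (None if self.background_logp is None
                                else self.background_logp.tolist()),
            "n_train": self.n_train,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParamSet":
        return cls(
            cds_model=PeriodicMarkovModel.from_dict(d["cds_model"]),
            utr5_model=MarkovChainModel.from_dict(d["utr5_model"]),
            utr3_model=MarkovChainModel.from_dict(d["utr3_model"]),
            start_model=PositionalModel.from_dict(d["start_model"]),
            stop_model=PositionalModel.from_dict(d["stop_model"]),
            fullcds_duration=DurationModel.from_dict(d["fullcds_duration"]),
            pcds_duration=DurationModel.from_dict(d["pcds_duration"]),
            p_utr5_empty=d["p_utr5_empty"], p_utr3_empty=d["p_utr3_empty"],
            utr5_mean=d["utr5_mean"], utr3_mean=d["utr3_mean"],
            background_logp=(None if d.get("background_logp") is None
                             else np.array(d["background_logp"])),
            n_train=d["n_train"],
        )


@dataclass
class TrainedBundle:
    """GC-binned parameter sets plus training metadata."""

    gc_bin_edges: Tuple[float, ...]
    paramsets: List[ParamSet]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.paramsets) != len(self.gc_bin_edges) + 1:
            raise ValueError("need one parameter set per GC bin")

    @property
    def n_bins(self) -> int:
        return len(self.paramsets)

    def bin_for(self, gc: float) -> int:
        return assign_bin(self.gc_bin_edges, gc)

    def params_for(self, gc: float) -> ParamSet:
        return self.paramsets[self.bin_for(gc)]

    def to_payload(self) -> dict:
        return {
            "gc_bin_edges": list(self.gc_bin_edges),
            "paramsets": [p.to_dict() for p in self.paramsets],
            "metadata": self.metadata,
        }

    @classmethod
    def from_payload(cls, payload: dict) -> "TrainedBundle":
        meta = payload.get("metadata", {})
        for key in ("bin_counts", "n_train", "n_skipped"):
            val = meta.get(key)
            vals = val if isinstance(val, list) else [val]
            if any(isinstance(v, (int, float)) and v < 0 for v in vals):
                raise BundleFormatError(f"metadata {key} holds a negative count")
        return cls(
            gc_bin_edges=tuple(payload["gc_bin_edges"]),
            paramsets=[ParamSet.from_dict(p) for p in payload["paramsets"]],
            metadata=meta,
        )


def _valid_training_transcript(t: Transcript) -> bool:
    r = t.annotation
    return (r is not None and r.has_start and r.has_stop and r.strand == "+"
            and r.frame == 0 and (r.end - r.start) % 3 == 0
            and r.end - r.start >= 9)


def _fit_paramset(transcripts: Sequence[Transcript],
                  cfg: TrainingConfig) -> ParamSet:
    encs = [encode(t.seq) for t in transcripts]
    refs = [t.annotation for t in transcripts]
    pc, mco = cfg.pseudocount, cfg.min_context_obs

    utr5_regions = [(e, 0, r.start) for e, r in zip(encs, refs) if r.start > 0]
    utr3_regions = [(e, r.end, len(e)) for e, r in zip(encs, refs)
                    if r.end < len(e)]
    cds_regions = [(e, r.start + 3, r.end - 3, 0) for e, r in zip(encs, refs)]

    utr5_model = MarkovChainModel.fit(utr5_regions, cfg.utr_order, pc, mco)
    utr3_model = MarkovChainModel.fit(utr3_regions, cfg.utr_order, pc, mco)
    cds_model = PeriodicMarkovModel.fit(cds_regions, cfg.cds_order, pc, mco)
    start_model = PositionalModel.fit(
        [(e, r.start) for e, r in zip(encs, refs)],
        cfg.start_window[0], cfg.start_window[1], pc)
    stop_model = PositionalModel.fit(
        [(e, r.end - 3) for e, r in zip(encs, refs)],
        cfg.stop_window[0], cfg.stop_window[1], pc)

    interiors = [r.end - r.start - 6 for r in refs if r.end - r.start >= 9]
    fullcds_duration = fit_duration(interiors, cfg.duration_bandwidth, step=3,
                                    tail_mass=cfg.duration_tail_mass)

    # partial-CDS durations from simulated uniform truncations of the
    # training CDSs (no natural partial training data exist)
    rng = np.random.default_rng(cfg.truncation_seed)
    plens: List[int] = []
    floor = cfg.partial_min_retained
    for t, r in zip(transcripts, refs):
        lo, hi = r.start + 3, min(r.end - 4, len(t) - floor)
        u = int(rng.integers(lo, hi + 1)) if hi >= lo else lo
        plens.append(r.end - 3 - u)                       # no-start style
        lo_u, hi_v = r.start + 3, r.end - 3
        if hi_v - lo_u >= floor:
            u2 = int(rng.integers(lo_u, hi_v - floor + 1))
            v2 = int(rng.integers(u2 + floor, hi_v + 1))
        else:
            u2, v2 = lo_u, hi_v
        if v2 > u2:
            plens.append(v2 - u2)                         # interior-only style
    pcds_duration = fit_duration(plens, cfg.duration_bandwidth, step=1,
                                 tail_mass=cfg.duration_tail_mass)

    n = len(transcripts)
    n5_empty = sum(1 for r in refs if r.start == 0)
    n3_empty = sum(1 for e, r in zip(encs, refs) if r.end == len(e))
    utr5_lens = [r.start for r in refs if r.start > 0]
    utr3_lens = [len(e) - r.end for e, r in zip(encs, refs) if len(e) > r.end]
    base_counts = np.full(4, pc)
    for e in encs:
        base_counts += np.bincount(e[e != 4], minlength=4)[:4]
    return ParamSet(
        cds_model=cds_model, utr5_model=utr5_model, utr3_model=utr3_model,
        start_model=start_model, stop_model=stop_model,
        fullcds_duration=fullcds_duration, pcds_duration=pcds_duration,
        p_utr5_empty=(n5_empty + pc) / (n + 2 * pc),
        p_utr3_empty=(n3_empty + pc) / (n + 2 * pc),
        utr5_mean=float(np.mean(utr5_lens)) if utr5_lens else 1.0,
        utr3_mean=float(np.mean(utr3_lens)) if utr3_lens else 1.0,
        background_logp=np.log(base_counts / base_counts.sum()),
        n_train=n,
    )


def train(annotated: Sequence[Transcript],
          config: Optional[TrainingConfig] = None) -> TrainedBundle:
    """Estimate a GC-binned model bundle from complete annotated transcripts."""
    cfg = config or TrainingConfig()
    usable = [t for t in annotated if _valid_training_transcript(t)]
    n_skipped = len(annotated) - len(usable)
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} transcripts with invalid or "
                      "incomplete annotations")
    if not usable:
        raise ValueError("no valid training transcripts")
    if len(usable) < cfg.min_train_sequences:
        raise ValueError(
            f"need at least {cfg.min_train_sequences} training transcripts, "
            f"got {len(usable)}"
        )

    edges = list(cfg.gc_bin_edges)
    n_bins = len(edges) + 1
    members: List[List[Transcript]] = [[] for _ in range(n_bins)]
    for t in usable:
        members[assign_bin(edges, gc_fraction(t.seq))].append(t)

    centers = []
    bounds = [0.0] + edges + [1.0]
    for i in range(n_bins):
        centers.append(0.5 * (bounds[i] + bounds[i + 1]))

    fitted: Dict[int, ParamSet] = {}
    for i in range(n_bins):
        if len(members[i]) >= cfg.min_bin_sequences:
            fitted[i] = _fit_paramset(members[i], cfg)
    borrowed: Dict[int, int] = {}
    if not fitted:
        global_ps = _fit_paramset(usable, cfg)
        paramsets = [global_ps] * n_bins
        borrowed = {i: -1 for i in range(n_bins)}  # -1: pooled fallback
    else:
        paramsets = []
        for i in range(n_bins):
            if i in fitted:
                paramsets.append(fitted[i])
            else:
                j = min(fitted, key=lambda k: abs(centers[k] - centers[i]))
                paramsets.append(fitted[j])
                borrowed[i] = j

    meta = {
        "format_version": BUNDLE_VERSION,
        "n_train": len(usable),
        "n_skipped": n_skipped,
        "bin_counts": [len(m) for m in members],
        "borrowed_bins": {str(k): v for k, v in borrowed.items()},
        "config": cfg.to_dict(),
    }
    return TrainedBundle(gc_bin_edges=tuple(edges), paramsets=paramsets,
                         metadata=meta)


# ---------------------------------------------------------------------------
# Bundle persistence: versioned JSON with a payload checksum
# ---------------------------------------------------------------------------

def _payload_digest(payload: dict) -> str:
    canon = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()


def save_bundle(bundle: TrainedBundle, path) -> None:
    payload = bundle.to_payload()
    doc = {
        "format": BUNDLE_FORMAT,
        "format_version": BUNDLE_VERSION,
        "sha256": _payload_digest(payload),
        "payload": payload,
    }
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_bundle(path) -> TrainedBundle:
    try:
        with open(path, "rt", encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise BundleFormatError(f"truncated or malformed bundle file: {exc}")
    if doc.get("format") != BUNDLE_FORMAT:
        raise BundleFormatError("not a model bundle file")
    if doc.get("format_version") != BUNDLE_VERSION:
        raise BundleFormatError(
            f"bundle format version {doc.get('format_version')} is not "
            f"supported (expected {BUNDLE_VERSION})"
        )
    payload = doc.get("payload")
    if payload is None or _payload_digest(payload) != doc.get("sha256"):
        raise BundleFormatError("bundle checksum mismatch (file edited or "
                                "truncated)")
    try:
        return TrainedBundle.from_payload(payload)
    except (KeyError, ValueError) as exc:
        if isinstance(exc, BundleFormatError):
            raise
        raise BundleFormatError(f"invalid bundle payload: {exc}")


def codon_phase_tv(true_model: "PeriodicMarkovModel",
                   est_model: "PeriodicMarkovModel",
                   transcripts: Sequence[Transcript]) -> float:
    """Occupancy-weighted mean total-variation distance between two periodic
    chains' conditional distributions.

    Contexts are weighted by how often they occur at each codon phase in the
    CDS interiors of ``transcripts`` (the expectation of the per-context TV
    under the generating process); contexts that never occur carry no weight.
    """
    if true_model.order != est_model.order:
        raise ValueError("models must share one order")
    k = true_model.order
    num = 0.0
    den = 0.0
    weights = [np.zeros(4 ** k) for _ in range(3)]
    for t in transcripts:
        r = t.annotation
        enc = encode(t.seq)
        for i in range(r.start + 3 + k, r.end - 3):
            ctx = enc[i - k:i]
            if np.any(ctx == 4):
                continue
            idx = 0
            for c in ctx:
                idx = idx * 4 + int(c)
            weights[(i - (r.start + 3)) % 3][idx] += 1
    for p in range(3):
        pt = np.exp(true_model.phase_models[p].logprob)
        pe = np.exp(est_model.phase_models[p].logprob)
        tv = 0.5 * np.abs(pt - pe).sum(axis=1)
        num += float((weights[p] * tv).sum())
        den += float(weights[p].sum())
    if den == 0:
        raise ValueError("no codon contexts observed")
    return num / den


def annotated_path_segments(t: Transcript) -> list:
    """The state segmentation implied by a complete annotation (zero-length
    UTR segments included), for likelihood evaluation under the full model."""
    r = t.annotation
    L = len(t)
    return [("UTR5", 0, r.start), ("Start", r.start, r.start + 3),
            ("fullCDS", r.start + 3, r.end - 3), ("Stop", r.end - 3, r.end),
            ("UTR3", r.end, L)]


def corpus_loglik(bundle: TrainedBundle, transcripts: Sequence[Transcript]) -> float:
    """Total log-likelihood of the annotated paths of complete transcripts."""
    from .ghmm import score_path
    total = 0.0
    for t in transcripts:
        ps = bundle.params_for(gc_fraction(t.seq))
        total += score_path(ps.full_architecture(), t.seq,
                            annotated_path_segments(t))
    return total
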