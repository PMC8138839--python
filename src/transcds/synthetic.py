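"""Synthetic transcript corpora with the statistical structure the decoder
assumes: 5'UTR + ATG + in-frame sense-codon run + stop codon + 3'UTR, with
controllable codon usage, UTR composition, length distributions, GC target
and a fraction of non-coding sequences emulating ncRNA (compositional only).

Two generators are provided: :func:`generate_corpus` draws from an explicit
:class:`GeneratorConfig`, and :func:`sample_corpus_from_paramset` draws from
a fitted parameter set (used for parameter-recovery experiments).  Both are
deterministic under their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import evalkit
from .prob_models import MarkovChainModel, N_CODE, encode
from .seqio import ReferenceCds, STOP_CODONS, Transcript
from .training import ParamSet

BASES = "ACGT"
SENSE_CODONS = tuple(
    a + b + c
    for a in BASES for b in BASES for c in BASES
    if a + b + c not in STOP_CODONS
)


@dataclass(frozen=True)
class LengthDist:
    """Small family of integer length distributions.

    kind ``constant``: always ``a``; ``uniform``: integer uniform on
    [a, b]; ``geometric``: min_value + geometric with mean ``a``;
    ``lognormal``: round(exp(N(log a, b))) clipped at ``min_value``.
    """

    kind: str
    a: float
    b: float = 0.0
    min_value: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "uniform", "geometric", "lognormal"):
            raise ValueError(f"unknown length distribution {self.kind!r}")

    def sample(self, rng: np.random.Generator) -> int:
        if self.kind == "constant":
            return int(self.a)
        if self.kind == "uniform":
            return int(rng.integers(int(self.a), int(self.b) + 1))
        if self.kind == "geometric":
            mean_excess = self.a - self.min_value
            if mean_excess <= 0:
                return self.min_value
            p = 1.0 / (mean_excess + 1.0)
            return self.min_value + int(rng.geometric(p)) - 1
        val = int(round(math.exp(rng.normal(math.log(self.a), self.b))))
        return max(self.min_value, val)

    def mean(self, n: int = 20000, seed: int = 0) -> float:
        rng = np.random.default_rng(seed)
        return float(np.mean([self.sample(rng) for _ in range(n)]))


def _norm(d: Dict[str, float]) -> Dict[str, float]:
    tot = sum(d.values())
    if tot <= 0:
        raise ValueError("distribution has no mass")
    return {k: v / tot for k, v in d.items()}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a synthetic corpus."""

    seed: int = 0
    n: int = 100
    codon_usage: Dict[str, float] = field(default_factory=dict)
    stop_usage: Dict[str, float] = field(
        default_factory=lambda: {"TAA": 0.30, "TAG": 0.24, "TGA": 0.46})
    utr5_comp: Dict[str, float] = field(
        default_factory=lambda: {"A": 0.33, "C": 0.17, "G": 0.16, "T": 0.34})
    utr3_comp: Dict[str, float] = field(
        default_factory=lambda: {"A": 0.31, "C": 0.17, "G": 0.18, "T": 0.34})
    start_context: Optional[Dict[int, Dict[str, float]]] = None
    len_cds: LengthDist = LengthDist("lognormal", 110.0, 0.35, min_value=40)
    len_utr5: LengthDist = LengthDist("geometric", 60.0, min_value=0)
    len_utr3: LengthDist = LengthDist("geometric", 150.0, min_value=0)
    gc_target: Optional[float] = None
    gc_tol: float = 0.05
    frac_noncoding: float = 0.0
    len_noncoding: Optional[LengthDist] = None
    max_gc_attempts: int = 200

    def __post_init__(self) -> None:
        if self.codon_usage:
            missing = set(SENSE_CODONS) - set(self.codon_usage)
            extra = set(self.codon_usage) - set(SENSE_CODONS)
            if missing or extra:
                raise ValueError("codon_usage must cover the 61 sense codons")
        if self.len_cds.kind != "constant" and self.len_cds.min_value < 2:
            raise ValueError("len_cds support must be >= 2 codons")
        if not (0.0 <= self.frac_noncoding <= 1.0):
            raise ValueError("frac_noncoding must be in [0,1]")


# Kozak-flavoured context immediately upstream of the start codon
_DEFAULT_START_CONTEXT = {
    -6: {"A": 0.20, "C": 0.25, "G": 0.45, "T": 0.10},
    -5: {"A": 0.15, "C": 0.50, "G": 0.20, "T": 0.15},
    -4: {"A": 0.15, "C": 0.50, "G": 0.15, "T": 0.20},
    -3: {"A": 0.55, "C": 0.05, "G": 0.35, "T": 0.05},
    -2: {"A": 0.20, "C": 0.45, "G": 0.15, "T": 0.20},
    -1: {"A": 0.15, "C": 0.55, "G": 0.15, "T": 0.15},
}


def strong_signal_config(seed: int = 0, n: int = 100, **overrides
                         ) -> GeneratorConfig:
    """Strongly codon-biased conditions: codon usage drawn once from a sparse
    Dirichlet (highly non-uniform); the usage table is part of the preset and
    does not vary with the corpus seed."""
    usage_rng = np.random.default_rng(901_000)
    weights = usage_rng.dirichlet(np.full(len(SENSE_CODONS), 0.35))
    usage = _norm(dict(zip(SENSE_CODONS, weights.tolist())))
    cfg = GeneratorConfig(seed=seed, n=n, codon_usage=usage,
                          start_context=_DEFAULT_START_CONTEXT)
    return replace(cfg, **overrides) if overrides else cfg


def weak_signal_config(seed: int = 0, n: int = 100, **overrides
                       ) -> GeneratorConfig:
    """Near-uniform codon usage and UTR composition: little to discriminate
    coding from non-coding beyond the ORF structure itself."""
    usage_rng = np.random.default_rng(902_000)
    weights = usage_rng.dirichlet(np.full(len(SENSE_CODONS), 80.0))
    usage = _norm(dict(zip(SENSE_CODONS, weights.tolist())))
    comp = {"A": 0.26, "C": 0.24, "G": 0.24, "T": 0.26}
    cfg = GeneratorConfig(seed=seed, n=n, codon_usage=usage,
                          utr5_comp=comp, utr3_comp=comp, start_context=None)
    return replace(cfg, **overrides) if overrides else cfg


def _sample_comp(rng: np.random.Generator, comp: Dict[str, float],
                 length: int) -> str:
    if length == 0:
        return ""
    bases = list(comp)
    probs = np.array([comp[b] for b in bases])
    probs = probs / probs.sum()
    return "".join(rng.choice(bases, size=length, p=probs).tolist())


def _sample_positive(rng: np.random.Generator, cfg: GeneratorConfig,
                     codons: Sequence[str], codon_p: np.ndarray,
                     stops: Sequence[str], stop_p: np.ndarray,
                     ) -> Tuple[str, ReferenceCds]:
    u5 = cfg.len_utr5.sample(rng)
    u3 = cfg.len_utr3.sample(rng)
    ncod = max(cfg.len_cds.min_value, cfg.len_cds.sample(rng))
    utr5 = list(_sample_comp(rng, cfg.utr5_comp, u5))
    if cfg.start_context:
        for off, dist in cfg.start_context.items():
            pos = u5 + off
            if 0 <= pos < u5:
                bases = list(dist)
                p = np.array([dist[b] for b in bases])
                utr5[pos] = str(rng.choice(bases, p=p / p.sum()))
    body = "".join(rng.choice(codons, size=ncod, p=codon_p).tolist())
    stop = str(rng.choice(stops, p=stop_p))
    utr3 = _sample_comp(rng, cfg.utr3_comp, u3)
    seq = "".join(utr5) + "ATG" + body + stop + utr3
    start = u5
    end = u5 + 3 + 3 * ncod + 3
    ref = ReferenceCds(start=start, end=end, strand="+",
                       has_start=True, has_stop=True, frame=0)
    return seq, ref


def generate_corpus(cfg: GeneratorConfig
                    ) -> Tuple[List[Transcript], pd.DataFrame]:
    """Generate ``cfg.n`` transcripts (positives with exact annotations and
    optionally non-coding negatives) plus a truth table.

    Positives are UTR5 + ATG + sense-codon run + stop + UTR3, so the coding
    region never contains an in-frame stop.  Negatives are drawn from the
    3'UTR composition with no constraint against chance ORFs.  When
    ``gc_target`` is set, sequences are redrawn until their GC content is
    within ``gc_tol`` (bounded attempts, then an error).
    """
    usage = _norm(cfg.codon_usage) if cfg.codon_usage else _norm(
        dict.fromkeys(SENSE_CODONS, 1.0))
    codons = list(usage)
    codon_p = np.array([usage[c] for c in codons])
    stops = list(_norm(cfg.stop_usage))
    stop_p = np.array([_norm(cfg.stop_usage)[s] for s in stops])
    len_nc = cfg.len_noncoding or LengthDist("lognormal", 600.0, 0.4,
                                             min_value=200)

    rng = np.random.default_rng(cfg.seed)
    n_neg = int(round(cfg.frac_noncoding * cfg.n))
    n_pos = cfg.n - n_neg
    transcripts: List[Transcript] = []
    rows: List[dict] = []

    def admit(seq: str) -> bool:
        if cfg.gc_target is None:
            return True
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        return abs(gc - cfg.gc_target) <= cfg.gc_tol

    for i in range(n_pos):
        for attempt in range(cfg.max_gc_attempts):
            seq, ref = _sample_positive(rng, cfg, codons, codon_p, stops, stop_p)
            if admit(seq):
                break
        else:
            raise ValueError(
                f"gc_target {cfg.gc_target} infeasible within "
                f"{cfg.max_gc_attempts} attempts"
            )
        t = Transcript(id=f"pos{i:05d}", seq=seq, annotation=ref)
        transcripts.append(t)
        rows.append({"id": t.id, "is_coding": True, "start": ref.start,
                     "end": ref.end, "strand": ref.strand, "frame": ref.frame,
                     "has_start": True, "has_stop": True, "length": len(seq)})
    for i in range(n_neg):
        for attempt in range(cfg.max_gc_attempts):
            seq = _sample_comp(rng, cfg.utr3_comp, max(1, len_nc.sample(rng)))
            if admit(seq):
                break
        else:
            raise ValueError("gc_target infeasible for negative sequences")
        t = Transcript(id=f"neg{i:05d}", seq=seq)
        transcripts.append(t)
        rows.append({"id": t.id, "is_coding": False, "start": pd.NA,
                     "end": pd.NA, "strand": pd.NA, "frame": pd.NA,
                     "has_start": False, "has_stop": False,
                     "length": len(seq)})
    truth = pd.DataFrame(rows)
    return transcripts, truth


def degrade(corpus: Sequence[Transcript], kind: str, seed: int,
            min_len: int = 150) -> List[Transcript]:
    """Derived corpora mirroring the validation-set constructions:
    ``no_start`` / ``no_stop`` / ``no_start_no_stop`` truncations or
    ``strand_blind`` (random half reverse-complemented)."""
    rng = np.random.default_rng(seed)
    if kind == "strand_blind":
        n = len(corpus)
        flip = set(rng.choice(n, size=n // 2, replace=False).tolist())
        return [evalkit.flip_to_reverse_complement(t) if i in flip else t
                for i, t in enumerate(corpus)]
    fn = {"no_start": evalkit.truncate_no_start,
          "no_stop": evalkit.truncate_no_stop,
          "no_start_no_stop": evalkit.truncate_both}.get(kind)
    if fn is None:
        raise ValueError(f"unknown degradation {kind!r}")
    out = []
    for t in corpus:
        d = fn(t, rng, min_len=min_len)
        if d is not None:
            out.append(d)
    return out


# ---------------------------------------------------------------------------
# Sampling from a fitted parameter set (parameter-recovery experiments)
# ---------------------------------------------------------------------------

def _chain_sample(model: MarkovChainModel, rng: np.random.Generator,
                  prefix: List[int]) -> int:
    k = model.order
    if k == 0 or len(prefix) < k or any(c == N_CODE for c in prefix[-k:]):
        p = np.exp(model.marginal_logp)
    else:
        idx = 0
        for c in prefix[-k:]:
            idx = idx * 4 + c
        p = np.exp(model.logprob[idx])
    return int(rng.choice(4, p=p / p.sum()))


def _positional_codon_probs(model, allowed: Sequence[str]) -> np.ndarray:
    """Probability of each allowed triplet under the model's codon columns
    (window offsets 0..2), renormalized over the allowed set."""
    logp = []
    for codon in allowed:
        v = 0.0
        for j, ch in enumerate(codon):
            col = j - model.window_start
            if 0 <= col < model.length:
                v += float(model.col_logp[col, "ACGT".index(ch)])
        logp.append(v)
    p = np.exp(np.array(logp) - max(logp))
    return p / p.sum()


def sample_corpus_from_paramset(ps: ParamSet, n: int, seed: int,
                                forbid_internal_stops: bool = True,
                                ) -> List[Transcript]:
    """Draw complete annotated transcripts from a fitted parameter set under
    the full-transcript architecture's generative reading.

    With ``forbid_internal_stops`` the coding run rejects in-frame stop
    codons (biological transcripts); without it, the sample law is exactly
    the fitted emission/duration model, which is what parameter-recovery
    experiments need.
    """
    rng = np.random.default_rng(seed)
    stop_p = _positional_codon_probs(ps.stop_model, STOP_CODONS)
    out: List[Transcript] = []
    q5 = ParamSet._geo_q(ps.utr5_mean)
    q3 = ParamSet._geo_q(ps.utr3_mean)

    def geo_len(p_empty: float, q: float) -> int:
        if rng.random() < p_empty:
            return 0
        if q <= 0.0:
            return 1
        return int(rng.geometric(1.0 - q))

    for i in range(n):
        prefix: List[int] = []
        u5 = geo_len(ps.p_utr5_empty, q5)
        for _ in range(u5):
            prefix.append(_chain_sample(ps.utr5_model, rng, prefix))
        start = len(prefix)
        prefix.extend(encode("ATG").tolist())
        interior = ps.fullcds_duration.sample(rng)
        ncod = interior // 3
        for _ in range(ncod):
            while True:
                codon = []
                for p in range(3):
                    codon.append(_chain_sample(
                        ps.cds_model.phase_models[p], rng, prefix + codon))
                tri = "".join("ACGT"[c] for c in codon)
                if not (forbid_internal_stops and tri in STOP_CODONS):
                    break
            prefix.extend(codon)
        stop = str(rng.choice(list(STOP_CODONS), p=stop_p))
        prefix.extend(encode(stop).tolist())
        end = len(prefix)
        u3 = geo_len(ps.p_utr3_empty, q3)
        for _ in range(u3):
            prefix.append(_chain_sample(ps.utr3_model, rng, prefix))
        seq = "".join("ACGT"[c] for c in prefix)
        ref = ReferenceCds(start=start, end=end, strand="+",
                           has_start=True, has_stop=True, frame=0)
        out.append(Transcript(id=f"gen{i:05d}", seq=seq, annotation=ref))
    return out
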