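"""Emission and duration models that parameterize GHMM states.

Three emission families are provided:

* :class:`MarkovChainModel` — an order-``k`` nucleotide chain (UTR states);
* :class:`PeriodicMarkovModel` — three order-``k`` chains cycling with codon
  position (coding states);
* :class:`PositionalModel` — an ungapped per-column weight matrix anchored at
  a codon (start / stop states).

plus :class:`DurationModel`, a smoothed empirical probability mass over
segment lengths with a geometric tail, used by the explicit-duration coding
states.

Sequences are scored against the *input* sequence context: the conditioning
``k``-mer of a position is taken from the preceding bases of the sequence
itself, crossing segment boundaries, which makes chain scores additive over
interval splits.  Positions holding ``N`` contribute log 1 = 0; conditioning
contexts that reach outside the sequence or contain ``N`` fall back to the
model's order-0 marginal.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np

BASES = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
N_CODE = 4
NEG_INF = float("-inf")

_NORM_TOL = 1e-9


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string as int8 codes (A=0,C=1,G=2,T=3,N=4)."""
    try:
        return np.fromiter((_CODE[c] for c in seq), dtype=np.int8, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide {exc.args[0]!r}") from None


def decode(codes: Sequence[int]) -> str:
    return "".join("ACGTN"[c] for c in codes)


def _check_rows_normalized(p: np.ndarray, what: str) -> None:
    sums = p.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=_NORM_TOL, rtol=0.0):
        raise ValueError(f"{what}: probabilities do not sum to 1 (max err "
                         f"{np.abs(sums - 1).max():.3g})")


def kmer_index(enc: np.ndarray, start: int, k: int) -> int:
    """Index of the k-mer enc[start:start+k] in lexicographic base-4 order."""
    idx = 0
    for c in enc[start:start + k]:
        idx = idx * 4 + int(c)
    return idx


class MarkovChainModel:
    """Order-``k`` Markov chain over {A,C,G,T} with Laplace-smoothed, total
    conditional tables and an order-0 marginal used for degenerate contexts."""

    def __init__(self, order: int, logprob: np.ndarray,
                 marginal_logp: np.ndarray, pseudocount: float = 1.0):
        if order < 0:
            raise ValueError("order must be non-negative")
        logprob = np.asarray(logprob, dtype=float).reshape(4 ** order, 4)
        marginal_logp = np.asarray(marginal_logp, dtype=float).reshape(4)
        _check_rows_normalized(np.exp(logprob), "MarkovChainModel conditionals")
        _check_rows_normalized(np.exp(marginal_logp), "MarkovChainModel marginal")
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        self.order = order
        self.logprob = logprob
        self.marginal_logp = marginal_logp
        self.pseudocount = float(pseudocount)

    @classmethod
    def uniform(cls, order: int) -> "MarkovChainModel":
        lp = np.full((4 ** order, 4), math.log(0.25))
        return cls(order, lp, np.full(4, math.log(0.25)))

    @classmethod
    def from_probs(cls, probs: np.ndarray, pseudocount: float = 1.0,
                   marginal: Optional[np.ndarray] = None) -> "MarkovChainModel":
        probs = np.asarray(probs, dtype=float)
        order = int(round(math.log(probs.size // 4, 4)))
        if marginal is None:
            marginal = probs.reshape(4 ** order, 4).mean(axis=0)
            marginal = marginal / marginal.sum()
        with np.errstate(divide="ignore"):
            return cls(order, np.log(probs), np.log(np.asarray(marginal, float)),
                       pseudocount)

    @classmethod
    def fit(cls, regions: Iterable[tuple[np.ndarray, int, int]], order: int,
            pseudocount: float = 1.0, min_context_obs: int = 10,
            ) -> "MarkovChainModel":
        """Estimate from ``(encoded_seq, from, to)`` regions.

        Conditioning contexts are taken from the sequence and may extend left
        of ``from``.  Contexts observed fewer than ``min_context_obs`` times
        back off to the estimate of their (order-1) suffix context, recursively
        down to order 0.
        """
        counts = [np.zeros((4 ** j, 4)) for j in range(order + 1)]
        for enc, a, b in regions:
            enc = np.asarray(enc)
            for i in range(a, b):
                s = int(enc[i])
                if s == N_CODE:
                    continue
                for j in range(order + 1):
                    if i - j < 0:
                        break
                    ctx = enc[i - j:i]
                    if np.any(ctx == N_CODE):
                        break
                    counts[j][kmer_index(enc, i - j, j), s] += 1
        pc = pseudocount
        probs = [np.empty((4 ** j, 4)) for j in range(order + 1)]
        probs[0][:] = (counts[0] + pc) / (counts[0].sum() + 4 * pc)
        for j in range(1, order + 1):
            totals = counts[j].sum(axis=1)
            for c in range(4 ** j):
                if totals[c] >= min_context_obs:
                    probs[j][c] = (counts[j][c] + pc) / (totals[c] + 4 * pc)
                else:
                    probs[j][c] = probs[j - 1][c % (4 ** (j - 1))]
        marginal = (counts[0] + pc) / (counts[0].sum() + 4 * pc)
        with np.errstate(divide="ignore"):
            return cls(order, np.log(probs[order]), np.log(marginal.ravel()), pc)

    def per_position_logp(self, enc: np.ndarray) -> np.ndarray:
        """log P(enc[i] | preceding k bases) for every position of ``enc``."""
        enc = np.asarray(enc, dtype=np.int64)
        L = len(enc)
        k = self.order
        sym_is_n = enc == N_CODE
        sym = np.where(sym_is_n, 0, enc)
        if k == 0:
            out = self.logprob[0, sym].copy()
        else:
            ctx = np.zeros(L, dtype=np.int64)
            valid = np.ones(L, dtype=bool)
            valid[:min(k, L)] = False
            for t in range(1, k + 1):
                ok_t = np.zeros(L, dtype=bool)
                prev = np.zeros(L, dtype=np.int64)
                if t < L:
                    prev[t:] = enc[:L - t]
                    ok_t[t:] = enc[:L - t] != N_CODE
                valid &= ok_t
                ctx += np.where(ok_t, prev, 0) * 4 ** (t - 1)
            out = np.where(valid, self.logprob[np.minimum(ctx, 4 ** k - 1), sym],
                           self.marginal_logp[sym])
        out[sym_is_n] = 0.0
        return out

    def to_dict(self) -> dict:
        return {
            "kind": "chain",
            "order": self.order,
            "logprob": self.logprob.tolist(),
            "marginal_logp": self.marginal_logp.tolist(),
            "pseudocount": self.pseudocount,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MarkovChainModel":
        return cls(d["order"], np.array(d["logprob"]),
                   np.array(d["marginal_logp"]), d["pseudocount"])


def score_chain(model: MarkovChainModel, seq, start: int, end: int) -> float:
    """Sum of conditional log-probabilities of symbols in ``[start, end)``."""
    enc = encode(seq) if isinstance(seq, str) else np.asarray(seq)
    if not (0 <= start <= end <= len(enc)):
        raise ValueError(f"interval [{start},{end}) out of range for length {len(enc)}")
    if start == end:
        return 0.0
    return float(model.per_position_logp(enc)[start:end].sum())


class PeriodicMarkovModel:
    """Three Markov chains of identical order indexed by codon position."""

    def __init__(self, phase_models: Sequence[MarkovChainModel]):
        if len(phase_models) != 3:
            raise ValueError("need exactly 3 phase models")
        orders = {m.order for m in phase_models}
        if len(orders) != 1:
            raise ValueError("phase models must share one order")
        self.phase_models = tuple(phase_models)
        self.order = phase_models[0].order

    @classmethod
    def fit(cls, regions: Iterable[tuple[np.ndarray, int, int, int]], order: int,
            pseudocount: float = 1.0, min_context_obs: int = 10,
            ) -> "PeriodicMarkovModel":
        """Estimate from ``(encoded_seq, from, to, phase_at_from)`` regions."""
        per_phase: list[list[tuple[np.ndarray, int, int]]] = [[], [], []]
        for enc, a, b, f in regions:
            # split region positions by phase; fit() consumes single positions
            for p in range(3):
                off = (p - f) % 3
                for i in range(a + off, b, 3):
                    per_phase[p].append((enc, i, i + 1))
        return cls([
            MarkovChainModel.fit(per_phase[p], order, pseudocount, min_context_obs)
            for p in range(3)
        ])

    def to_dict(self) -> dict:
        return {"kind": "periodic",
                "phase_models": [m.to_dict() for m in self.phase_models]}

    @classmethod
    def from_dict(cls, d: dict) -> "PeriodicMarkovModel":
        return cls([MarkovChainModel.from_dict(m) for m in d["phase_models"]])


def score_periodic(model: PeriodicMarkovModel, seq, start: int, end: int,
                   phase_at_start: int) -> float:
    """Score ``[start, end)`` threading codon phase from ``phase_at_start``."""
    enc = encode(seq) if isinstance(seq, str) else np.asarray(seq)
    if not (0 <= start <= end <= len(enc)):
        raise ValueError(f"interval [{start},{end}) out of range")
    if start == end:
        return 0.0
    arrs = [m.per_position_logp(enc) for m in model.phase_models]
    idx = np.arange(start, end)
    phases = (phase_at_start + idx - start) % 3
    return float(sum(arrs[p][i] for p, i in zip(phases, idx)))


class PositionalModel:
    """Per-column nucleotide distributions over a window anchored at a codon's
    first base; columns falling outside the sequence are skipped."""

    def __init__(self, window_start: int, col_logp: np.ndarray):
        col_logp = np.asarray(col_logp, dtype=float)
        if col_logp.ndim != 2 or col_logp.shape[1] != 4 or col_logp.shape[0] < 1:
            raise ValueError("col_logp must be (length, 4)")
        _check_rows_normalized(np.exp(col_logp), "PositionalModel columns")
        self.window_start = int(window_start)
        self.col_logp = col_logp

    @property
    def length(self) -> int:
        return self.col_logp.shape[0]

    @classmethod
    def uniform(cls, window_start: int, length: int) -> "PositionalModel":
        return cls(window_start, np.full((length, 4), math.log(0.25)))

    @classmethod
    def fit(cls, windows: Iterable[tuple[np.ndarray, int]], window_start: int,
            length: int, pseudocount: float = 1.0) -> "PositionalModel":
        """Estimate from ``(encoded_seq, anchor)`` pairs; out-of-bounds and N
        cells are simply not counted."""
        counts = np.zeros((length, 4))
        for enc, anchor in windows:
            enc = np.asarray(enc)
            for j in range(length):
                pos = anchor + window_start + j
                if 0 <= pos < len(enc) and enc[pos] != N_CODE:
                    counts[j, enc[pos]] += 1
        probs = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True)
                                          + 4 * pseudocount)
        with np.errstate(divide="ignore"):
            return cls(window_start, np.log(probs))

    def to_dict(self) -> dict:
        return {"kind": "positional", "window_start": self.window_start,
                "col_logp": self.col_logp.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "PositionalModel":
        return cls(d["window_start"], np.array(d["col_logp"]))


def score_positional(model: PositionalModel, seq, anchor: int) -> float:
    enc = encode(seq) if isinstance(seq, str) else np.asarray(seq)
    total = 0.0
    for j in range(model.length):
        pos = anchor + model.window_start + j
        if 0 <= pos < len(enc) and enc[pos] != N_CODE:
            total += float(model.col_logp[j, enc[pos]])
    return total


class DurationModel:
    """Probability mass over segment lengths ``min_len + i*step`` for
    ``i = 0..n-1``, with a geometric continuation beyond ``max_len`` carrying
    ``tail_mass``:  P(max_len + m*step) = tail_mass * (1-q) * q**(m-1)."""

    def __init__(self, min_len: int, log_pmf: np.ndarray, step: int = 1,
                 tail_mass: float = 0.0, tail_log_q: float = NEG_INF):
        log_pmf = np.asarray(log_pmf, dtype=float).ravel()
        if min_len < 1 or step not in (1, 3) or log_pmf.size < 1:
            raise ValueError("bad DurationModel geometry")
        if not (0.0 <= tail_mass < 1.0):
            raise ValueError("tail_mass must be in [0, 1)")
        total = float(np.exp(log_pmf).sum()) + tail_mass
        if abs(total - 1.0) > _NORM_TOL * max(1, log_pmf.size):
            raise ValueError(f"duration mass sums to {total}, not 1")
        if tail_mass > 0 and not (tail_log_q < 0):
            raise ValueError("geometric tail requires log q < 0")
        self.min_len = int(min_len)
        self.step = int(step)
        self.log_pmf = log_pmf
        self.tail_mass = float(tail_mass)
        self.tail_log_q = float(tail_log_q)

    @property
    def max_len(self) -> int:
        return self.min_len + (self.log_pmf.size - 1) * self.step

    @classmethod
    def point_mass(cls, length: int, step: int = 1) -> "DurationModel":
        return cls(length, np.zeros(1), step=step)

    def logp(self, length: int) -> float:
        if length < self.min_len or (length - self.min_len) % self.step:
            return NEG_INF
        if length <= self.max_len:
            return float(self.log_pmf[(length - self.min_len) // self.step])
        if self.tail_mass == 0.0:
            return NEG_INF
        m = (length - self.max_len) // self.step
        log_1mq = math.log1p(-math.exp(self.tail_log_q))
        return math.log(self.tail_mass) + log_1mq + (m - 1) * self.tail_log_q

    def logp_array(self, lengths: np.ndarray) -> np.ndarray:
        lengths = np.asarray(lengths)
        out = np.full(lengths.shape, NEG_INF)
        ok = (lengths >= self.min_len) & ((lengths - self.min_len) % self.step == 0)
        body = ok & (lengths <= self.max_len)
        idx = np.clip((lengths - self.min_len) // self.step, 0, self.log_pmf.size - 1)
        out[body] = self.log_pmf[idx[body]]
        if self.tail_mass > 0:
            tail = ok & (lengths > self.max_len)
            if tail.any():
                m = (lengths[tail] - self.max_len) // self.step
                log_1mq = math.log1p(-math.exp(self.tail_log_q))
                out[tail] = (math.log(self.tail_mass) + log_1mq
                             + (m - 1) * self.tail_log_q)
        return out

    def mean(self) -> float:
        lens = self.min_len + self.step * np.arange(self.log_pmf.size)
        m = float((np.exp(self.log_pmf) * lens).sum())
        if self.tail_mass > 0:
            q = math.exp(self.tail_log_q)
            m += self.tail_mass * (self.max_len + self.step / (1 - q))
        return m

    def search_horizon(self, tail_means: float = 10.0) -> int:
        """Longest duration worth scanning: support end plus a few geometric
        tail means (truncation error beyond is negligible)."""
        if self.tail_mass == 0.0:
            return self.max_len
        q = math.exp(self.tail_log_q)
        return self.max_len + int(math.ceil(tail_means * self.step / (1 - q)))

    def sample(self, rng: np.random.Generator) -> int:
        body_p = np.exp(self.log_pmf)
        total = body_p.sum()
        if rng.random() < total / (total + self.tail_mass):
            i = rng.choice(self.log_pmf.size, p=body_p / total)
            return self.min_len + self.step * int(i)
        q = math.exp(self.tail_log_q)
        m = int(rng.geometric(1 - q))  # number of extra steps beyond max_len, >= 1
        return self.max_len + self.step * m

    def to_dict(self) -> dict:
        return {"min_len": self.min_len, "step": self.step,
                "log_pmf": self.log_pmf.tolist(),
                "tail_mass": self.tail_mass, "tail_log_q": self.tail_log_q}

    @classmethod
    def from_dict(cls, d: dict) -> "DurationModel":
        return cls(d["min_len"], np.array(d["log_pmf"]), d["step"],
                   d["tail_mass"], d["tail_log_q"])


def duration_logp(model: DurationModel, length: int) -> float:
    if length < 1:
        raise ValueError("length must be >= 1")
    return model.logp(length)


def fit_duration(lengths: Sequence[int], smoothing_bandwidth: float = 30.0,
                 step: int = 1,
                 tail_mass: Optional[float] = None) -> DurationModel:
    """Kernel-smoothed empirical duration distribution.

    A Gaussian kernel of standard deviation ``smoothing_bandwidth`` (in
    nucleotides) is applied to the histogram of observed lengths over
    ``[min, max]`` on the given step grid; the body is renormalized to
    ``1 - tail_mass`` and the geometric tail decay is matched to the mean
    excess of the upper decile of the observations.  By default the tail
    carries the Laplace exceedance estimate 1/(n+1) of the probability of a
    length beyond the observed maximum (a fixed tail would systematically
    inflate the mean on refits).
    """
    lengths = np.asarray(list(lengths), dtype=int)
    if lengths.size < 2:
        raise ValueError("need at least 2 duration observations")
    if np.any(lengths < 1):
        raise ValueError("durations must be positive")
    if step == 3:
        lengths = (np.maximum(lengths, 3) // 3) * 3
    if tail_mass is None:
        tail_mass = 1.0 / (lengths.size + 1.0)
    lo, hi = int(lengths.min()), int(lengths.max())
    grid = np.arange(lo, hi + 1, step)
    hist = np.zeros(grid.size)
    idx = (lengths - lo) // step
    np.add.at(hist, idx, 1.0)
    sigma_steps = smoothing_bandwidth / step
    if sigma_steps > 1e-9:
        from scipy.ndimage import gaussian_filter1d
        hist = gaussian_filter1d(hist, sigma=sigma_steps, mode="constant")
    hist = np.maximum(hist, 1e-300)
    if lo == hi and smoothing_bandwidth <= 1e-9:
        tail_mass = 0.0
    body = hist / hist.sum() * (1.0 - tail_mass)
    if tail_mass > 0:
        p90 = np.percentile(lengths, 90)
        top = lengths[lengths >= p90]
        decay_steps = max(1.0, float(np.mean(top) - p90) / step)
        q = decay_steps / (decay_steps + 1.0)
        tail_log_q = math.log(q)
    else:
        tail_log_q = NEG_INF
    return DurationModel(lo, np.log(body), step=step, tail_mass=tail_mass,
                         tail_log_q=tail_log_q)
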