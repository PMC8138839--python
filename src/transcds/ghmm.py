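"""Generalized (hidden semi-Markov) transcript architectures and an exact
explicit-duration Viterbi decoder.

A :class:`GhmmArchitecture` is a directed acyclic graph of segment-emitting
states.  Three duration kinds exist:

* ``fixed`` — the state always emits exactly ``fixed_len`` bases (start and
  stop codons, scored by a positional window model and hard-constrained to
  the legal triplets);
* ``explicit`` — segment length is drawn from a :class:`DurationModel`
  (the coding states ``fullCDS`` and ``pCDS0/1/2``);
* ``geometric`` — segment length is geometric via a self-loop probability,
  with an optional point mass at length zero so UTRs may be absent.

Coding states are hard-constrained to translatable output: a ``Start``
segment must read ATG, a ``Stop`` segment must read a stop codon, no complete
in-frame codon inside a coding segment may be a stop, and a coding segment
that hands over to ``Stop`` must end on a codon boundary.

The decoder is exact: it maximizes the joint log-probability
initial + sum(emissions) + sum(durations) + sum(transitions) over all
admissible segmentations, returning ``None`` when no admissible path exists.
Ties are broken toward paths with a coding segment, then longer coding
segments, then leftmost placement, via deterministic scan order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .prob_models import (
    NEG_INF,
    N_CODE,
    DurationModel,
    MarkovChainModel,
    PeriodicMarkovModel,
    PositionalModel,
    encode,
)
from .seqio import START_CODON, STOP_CODONS

CODING_PHASE = {"fullCDS": 0, "pCDS0": 0, "pCDS1": 1, "pCDS2": 2}
NONCODING_NAMES = frozenset({"UTR5", "UTR", "UTR3"})
CANONICAL_NAMES = frozenset(
    {"UTR5", "Start", "fullCDS", "Stop", "UTR3", "UTR", "pCDS0", "pCDS1", "pCDS2"}
)

# order in which final candidates are scanned; earlier wins exact ties, so a
# coding ending is preferred over a UTR-only ending
_FINAL_PREFERENCE = ("Stop", "UTR3", "fullCDS", "pCDS0", "pCDS1", "pCDS2",
                     "Start", "UTR", "UTR5")


def _triplet_ids(codons: Iterable[str]) -> frozenset[int]:
    out = set()
    for c in codons:
        i = 0
        for ch in c:
            i = i * 4 + "ACGT".index(ch)
        out.add(i)
    return frozenset(out)


_START_IDS = _triplet_ids([START_CODON])
_STOP_IDS = _triplet_ids(STOP_CODONS)


@dataclass
class GhmmState:
    """One GHMM state: an emission model bound to a duration regime."""

    name: str
    emission: object  # MarkovChainModel | PeriodicMarkovModel | PositionalModel
    duration_kind: str  # "explicit" | "geometric" | "fixed"
    fixed_len: Optional[int] = None
    duration: Optional[DurationModel] = None
    self_loop_logp: float = NEG_INF
    empty_logp: float = NEG_INF
    allowed_triplets: Optional[frozenset] = None  # encoded triplet ids
    # positional-window columns outside the owned fixed_len bases re-score
    # bases emitted by neighboring states; with a background they contribute
    # log-odds (signal-sensor scoring) instead of double-counting probability
    flank_background: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.duration_kind not in ("explicit", "geometric", "fixed"):
            raise ValueError(f"bad duration_kind {self.duration_kind!r}")
        if self.duration_kind == "fixed":
            if not self.fixed_len or self.fixed_len < 1:
                raise ValueError(f"state {self.name}: fixed_len required")
            if self.name in ("Start", "Stop") and self.fixed_len != 3:
                raise ValueError(f"state {self.name}: fixed_len must be 3")
        if self.duration_kind == "explicit":
            if self.duration is None:
                raise ValueError(f"state {self.name}: DurationModel required")
            if self.name in CANONICAL_NAMES and self.name not in CODING_PHASE:
                raise ValueError(
                    f"state {self.name}: only coding states are explicit-duration"
                )
        if self.duration_kind == "geometric":
            if isinstance(self.emission, (PeriodicMarkovModel, PositionalModel)):
                raise ValueError(
                    f"state {self.name}: geometric states use chain emissions"
                )
            if self.self_loop_logp > 0.0:
                raise ValueError("self-loop log-probability must be <= 0")

    @property
    def log_1m_self(self) -> float:
        if self.self_loop_logp == NEG_INF:
            return 0.0
        return math.log1p(-math.exp(self.self_loop_logp))

    @property
    def log_1m_empty(self) -> float:
        if self.empty_logp == NEG_INF:
            return 0.0
        return math.log1p(-math.exp(self.empty_logp))

    @property
    def coding_phase(self) -> Optional[int]:
        return CODING_PHASE.get(self.name)


@dataclass
class GhmmArchitecture:
    """States, transitions, initial distribution and final-state set."""

    states: Dict[str, GhmmState]
    transitions: Dict[Tuple[str, str], float]  # log-probabilities
    initial: Dict[str, float]  # log-probabilities
    final: Set[str]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for (a, b) in self.transitions:
            if a not in self.states or b not in self.states:
                raise ValueError(f"transition {a}->{b} references unknown state")
            if a == b:
                raise ValueError("self transitions are modeled by self_loop_logp")
        for s in self.initial:
            if s not in self.states:
                raise ValueError(f"initial state {s} unknown")
        for s in self.final:
            if s not in self.states:
                raise ValueError(f"final state {s} unknown")
        tot = sum(math.exp(p) for p in self.initial.values())
        if abs(tot - 1.0) > 1e-6:
            raise ValueError(f"initial distribution sums to {tot}, not 1")
        for name, st in self.states.items():
            out = sum(
                math.exp(p) for (a, _b), p in self.transitions.items() if a == name
            )
            if st.duration_kind == "geometric" and st.self_loop_logp > NEG_INF:
                out *= 1.0 - math.exp(st.self_loop_logp)
                out += math.exp(st.self_loop_logp)
            if out > 1.0 + 1e-6:
                raise ValueError(f"state {name}: outgoing mass {out} exceeds 1")
        self._topo_order()  # raises on cycles

    def _topo_order(self) -> List[str]:
        preds: Dict[str, Set[str]] = {n: set() for n in self.states}
        succs: Dict[str, Set[str]] = {n: set() for n in self.states}
        for (a, b) in self.transitions:
            preds[b].add(a)
            succs[a].add(b)
        order, ready = [], [n for n in self.states if not preds[n]]
        remaining = {n: set(p) for n, p in preds.items()}
        while ready:
            n = ready.pop(0)
            order.append(n)
            for m in succs[n]:
                remaining[m].discard(n)
                if not remaining[m] and m not in order and m not in ready:
                    ready.append(m)
        if len(order) != len(self.states):
            raise ValueError("transition graph between states must be acyclic")
        return order

    def predecessors(self, name: str) -> List[str]:
        return [a for (a, b) in self.transitions if b == name]

    def noncoding_subarchitecture(self) -> Optional["GhmmArchitecture"]:
        """The restriction of this architecture to UTR states, used to score
        the best path with no coding segment (``None`` if that path family is
        empty)."""
        keep = {n: s for n, s in self.states.items() if n in NONCODING_NAMES}
        init = {n: p for n, p in self.initial.items() if n in keep}
        fin = {n for n in self.final if n in keep}
        if not keep or not init or not fin:
            return None
        trans = {
            (a, b): p for (a, b), p in self.transitions.items()
            if a in keep and b in keep
        }
        arch = object.__new__(GhmmArchitecture)
        arch.states, arch.transitions, arch.initial, arch.final = (
            keep, trans, init, fin
        )
        return arch


@dataclass
class StatePath:
    """An admissible segmentation: ordered ``(state, from, to)`` segments
    tiling the sequence (zero-length segments mark traversed-but-empty
    states) and its joint log-probability."""

    segments: List[Tuple[str, int, int]]
    log_score: float

    def nonzero(self) -> List[Tuple[str, int, int]]:
        return [s for s in self.segments if s[2] > s[1]]


@dataclass(frozen=True)
class CodingRegion:
    """Coding interval extracted from a state path (decoder coordinates)."""

    start: int
    end: int
    frame: int
    has_start: bool
    has_stop: bool


class SequenceScorer:
    """Per-sequence cache of emission arrays shared by decoder, path scorer
    and oracle."""

    def __init__(self, seq: str):
        self.seq = seq
        self.enc = encode(seq)
        self.L = len(seq)
        self._chain: Dict[int, np.ndarray] = {}  # id(model) -> cumsum array
        self._periodic: Dict[int, np.ndarray] = {}  # id(model) -> (3, L+1)
        self._positional: Dict[tuple, np.ndarray] = {}
        codon_ids = np.full(self.L, -1, dtype=np.int64)
        if self.L >= 3:
            e = self.enc.astype(np.int64)
            valid = (e[:-2] != N_CODE) & (e[1:-1] != N_CODE) & (e[2:] != N_CODE)
            ids = e[:-2] * 16 + e[1:-1] * 4 + e[2:]
            codon_ids[: self.L - 2] = np.where(valid, ids, -1)
        self.codon_ids = codon_ids
        # prefix counts of in-frame stop-codon starts by residue class of i mod 3
        is_stop = np.isin(codon_ids, list(_STOP_IDS))
        self.stop_prefix = np.zeros((3, self.L + 1), dtype=np.int64)
        for c in range(3):
            m = np.zeros(self.L)
            m[c::3] = is_stop[c::3]
            self.stop_prefix[c, 1:] = np.cumsum(m)

    # -- chain emissions -------------------------------------------------
    def chain_cumsum(self, model: MarkovChainModel) -> np.ndarray:
        key = id(model)
        if key not in self._chain:
            e = model.per_position_logp(self.enc)
            cs = np.zeros(self.L + 1)
            cs[1:] = np.cumsum(e)
            self._chain[key] = cs
        return self._chain[key]

    def chain_segment(self, model: MarkovChainModel, a: int, b: int) -> float:
        cs = self.chain_cumsum(model)
        return float(cs[b] - cs[a])

    # -- periodic emissions ----------------------------------------------
    def periodic_cumsum(self, model: PeriodicMarkovModel) -> np.ndarray:
        """C[r, j] = sum_{i<j} e_{(i+r) mod 3}(i); a segment starting at
        ``a`` with phase ``f`` uses r = (f - a) mod 3."""
        key = id(model)
        if key not in self._periodic:
            e3 = np.stack([m.per_position_logp(self.enc)
                           for m in model.phase_models])
            C = np.zeros((3, self.L + 1))
            idx = np.arange(self.L)
            for r in range(3):
                C[r, 1:] = np.cumsum(e3[(idx + r) % 3, idx])
            self._periodic[key] = C
        return self._periodic[key]

    def periodic_segment(self, model: PeriodicMarkovModel, a: int, b: int,
                         phase: int) -> float:
        C = self.periodic_cumsum(model)
        r = (phase - a) % 3
        return float(C[r, b] - C[r, a])

    # -- coding constraints ----------------------------------------------
    def internal_stops(self, a: int, b: int, phase: int) -> int:
        """Number of complete in-frame stop codons inside ``[a, b)`` read at
        codon ``phase`` from ``a``."""
        if b - a < 3:
            return 0
        c = (a - phase) % 3
        hi = max(a, b - 2)
        return int(self.stop_prefix[c, hi] - self.stop_prefix[c, a])

    def triplet_ok(self, a: int, allowed: frozenset) -> bool:
        if a < 0 or a + 3 > self.L:
            return False
        cid = int(self.codon_ids[a])
        return cid >= 0 and cid in allowed

    # -- positional emissions --------------------------------------------
    def positional_anchor_scores(self, model: PositionalModel,
                                 background: Optional[np.ndarray] = None,
                                 owned_len: int = 0) -> np.ndarray:
        """Vector of window scores for every anchor position.

        With a ``background``, columns at window offsets outside
        ``[0, owned_len)`` contribute log-odds against it rather than raw
        log-probability (those bases are emitted by neighboring states)."""
        key = (id(model), id(background), owned_len)
        if key in self._positional:
            return self._positional[key]
        out = np.zeros(self.L)
        enc = self.enc.astype(np.int64)
        anchors = np.arange(self.L)
        for j in range(model.length):
            off = model.window_start + j
            pos = anchors + off
            ok = (pos >= 0) & (pos < self.L)
            p = pos[ok]
            sym = enc[p]
            notn = sym != N_CODE
            contrib = np.zeros(p.size)
            col = model.col_logp[j, sym[notn]]
            if background is not None and not (0 <= off < owned_len):
                col = col - background[sym[notn]]
            contrib[notn] = col
            out[ok] += contrib
        self._positional[key] = out
        return out


def _segment_emission(scorer: SequenceScorer, state: GhmmState, a: int,
                      b: int) -> float:
    em = state.emission
    if isinstance(em, PositionalModel):
        fs = scorer.positional_anchor_scores(em, state.flank_background,
                                             state.fixed_len or 0)
        return float(fs[a])
    if isinstance(em, PeriodicMarkovModel):
        phase = state.coding_phase or 0
        return scorer.periodic_segment(em, a, b, phase)
    return scorer.chain_segment(em, a, b)


def _segment_duration_logp(state: GhmmState, d: int, censored: bool) -> float:
    if state.duration_kind == "fixed":
        return 0.0 if d == state.fixed_len else NEG_INF
    if state.duration_kind == "explicit":
        return state.duration.logp(d)
    # geometric
    if d < 1:
        return NEG_INF
    v = state.log_1m_empty
    if d > 1:
        if state.self_loop_logp == NEG_INF:
            return NEG_INF
        v += (d - 1) * state.self_loop_logp
    if not censored:
        v += state.log_1m_self
    return v


def _segment_constraint_ok(scorer: SequenceScorer, state: GhmmState, a: int,
                           b: int, next_state: Optional[str]) -> bool:
    if state.duration_kind == "fixed" and state.allowed_triplets is not None:
        if b - a != 3 or not scorer.triplet_ok(a, state.allowed_triplets):
            return False
    phase = state.coding_phase
    if phase is not None:
        if scorer.internal_stops(a, b, phase) > 0:
            return False
        if next_state is not None and (phase + b - a) % 3 != 0:
            # hand-over to Stop must land on a codon boundary
            return False
    return True


def score_path(arch: GhmmArchitecture, seq: str,
               segments: Sequence[Tuple[str, int, int]],
               scorer: Optional[SequenceScorer] = None) -> float:
    """Joint log-probability of an explicit segmentation (the quantity the
    decoder maximizes).  Zero-length segments are admitted for geometric
    states with an empty-length probability.  Returns ``-inf`` for
    inadmissible paths."""
    if scorer is None:
        scorer = SequenceScorer(seq)
    L = scorer.L
    if not segments:
        return NEG_INF
    pos = 0
    total = 0.0
    prev: Optional[str] = None
    for k, (name, a, b) in enumerate(segments):
        if name not in arch.states or a != pos or b < a:
            return NEG_INF
        st = arch.states[name]
        if prev is None:
            total += arch.initial.get(name, NEG_INF)
        else:
            total += arch.transitions.get((prev, name), NEG_INF)
        if a == b:
            total += st.empty_logp
        else:
            nxt = segments[k + 1][0] if k + 1 < len(segments) else None
            if st.coding_phase is not None and nxt is not None:
                follows_stop = nxt == "Stop"
            else:
                follows_stop = False
            if not _segment_constraint_ok(
                scorer, st, a, b, "Stop" if follows_stop else None
            ):
                return NEG_INF
            censored = (k == len(segments) - 1)
            total += _segment_emission(scorer, st, a, b)
            total += _segment_duration_logp(st, b - a, censored)
        pos = b
        prev = name
        if total == NEG_INF:
            return NEG_INF
    if pos != L or segments[-1][0] not in arch.final:
        return NEG_INF
    return total


# ---------------------------------------------------------------------------
# Viterbi decoding
# ---------------------------------------------------------------------------

_SRC_INIT = ("init", None)


class _StateDP:
    __slots__ = ("state", "enter", "enter_src", "done_any", "done_c0",
                 "bp_any", "bp_c0", "in_arr", "geo_G", "fixed_scores")

    def __init__(self, state: GhmmState, L: int):
        self.state = state
        self.enter = np.full(L + 1, NEG_INF)
        self.enter_src: list = [None] * (L + 1)
        self.done_any = np.full(L + 1, NEG_INF)
        self.done_c0 = None
        self.bp_any = np.full(L + 1, -1, dtype=np.int64)
        self.bp_c0 = None
        self.in_arr = None
        self.geo_G = None
        self.fixed_scores = None


def _update(target: np.ndarray, src_list: list, cand: np.ndarray, tag) -> None:
    upd = cand > target
    if upd.any():
        target[upd] = cand[upd]
        for j in np.nonzero(upd)[0]:
            src_list[j] = tag


def viterbi_decode(arch: GhmmArchitecture, seq: str,
                   scorer: Optional[SequenceScorer] = None,
                   ) -> Optional[StatePath]:
    """Maximum-probability segmentation of ``seq`` under ``arch``; ``None``
    when no admissible path exists."""
    if scorer is None:
        scorer = SequenceScorer(seq)
    L = scorer.L
    if L < 1:
        return None
    order = arch._topo_order()
    dp: Dict[str, _StateDP] = {n: _StateDP(arch.states[n], L) for n in arch.states}

    for name in order:
        st = arch.states[name]
        cell = dp[name]
        # ---- entries ----------------------------------------------------
        if name in arch.initial:
            cell.enter[0] = arch.initial[name]
            cell.enter_src[0] = _SRC_INIT
        for r in arch.predecessors(name):
            t = arch.transitions[(r, name)]
            rc = dp[r]
            rstate = arch.states[r]
            if rstate.duration_kind == "geometric":
                done = (rc.in_arr + rstate.log_1m_self
                        if rc.in_arr is not None
                        else np.full(L + 1, NEG_INF))
            elif rstate.coding_phase is not None and name == "Stop":
                done = rc.done_c0
            else:
                done = rc.done_any
            _update(cell.enter, cell.enter_src, done + t, ("done", r))
            if rstate.empty_logp > NEG_INF:
                _update(cell.enter, cell.enter_src,
                        rc.enter + rstate.empty_logp + t, ("empty", r))

        # ---- segment completions ---------------------------------------
        if st.duration_kind == "fixed":
            d = st.fixed_len
            if d <= L:
                em = st.emission
                if isinstance(em, PositionalModel):
                    fs = scorer.positional_anchor_scores(
                        em, st.flank_background, d).copy()
                else:
                    cs = scorer.chain_cumsum(em)
                    fs = np.full(L, NEG_INF)
                    fs[: L - d + 1] = cs[d:] - cs[: L - d + 1]
                if st.allowed_triplets is not None:
                    ok = np.zeros(L, dtype=bool)
                    cid = scorer.codon_ids
                    ok[: max(0, L - 2)] = np.isin(
                        cid[: max(0, L - 2)], list(st.allowed_triplets)
                    )
                    fs = np.where(ok, fs, NEG_INF)
                cell.done_any[d:] = cell.enter[:-d] + fs[: L - d + 1]
                cell.bp_any[d:] = np.arange(0, L - d + 1)
        elif st.duration_kind == "explicit":
            phase = st.coding_phase
            dur = st.duration
            horizon = min(L, dur.search_horizon())
            cell.done_c0 = np.full(L + 1, NEG_INF)
            cell.bp_c0 = np.full(L + 1, -1, dtype=np.int64)
            starts = np.nonzero(np.isfinite(cell.enter))[0]
            if isinstance(st.emission, PeriodicMarkovModel):
                C = scorer.periodic_cumsum(st.emission)
            else:
                C = None
                cs = scorer.chain_cumsum(st.emission)
            for a in starts:
                jmax = min(L, a + horizon)
                jmin = a + max(1, dur.min_len)
                if jmin > jmax:
                    continue
                js = np.arange(jmin, jmax + 1)
                ds = js - a
                if C is not None:
                    r = (phase - a) % 3
                    emit = C[r, js] - C[r, a]
                else:
                    emit = cs[js] - cs[a]
                vals = cell.enter[a] + emit + dur.logp_array(ds)
                if phase is not None:
                    c = (a - phase) % 3
                    hi = np.maximum(a, js - 2)
                    nstop = scorer.stop_prefix[c, hi] - scorer.stop_prefix[c, a]
                    vals = np.where(nstop == 0, vals, NEG_INF)
                upd = vals > cell.done_any[js]
                cell.done_any[js[upd]] = vals[upd]
                cell.bp_any[js[upd]] = a
                if phase is not None:
                    boundary = (phase + ds) % 3 == 0
                    vb = np.where(boundary, vals, NEG_INF)
                    upd = vb > cell.done_c0[js]
                    cell.done_c0[js[upd]] = vb[upd]
                    cell.bp_c0[js[upd]] = a
                else:
                    cell.done_c0 = cell.done_any
                    cell.bp_c0 = cell.bp_any
        else:  # geometric
            cs = scorer.chain_cumsum(st.emission)
            c = st.self_loop_logp
            in_arr = np.full(L + 1, NEG_INF)
            if c == NEG_INF:
                in_arr[1:] = (cell.enter[:-1] + st.log_1m_empty
                              + (cs[1:] - cs[:-1]))
                G = None
            else:
                a_idx = np.arange(L + 1)
                G = cell.enter + st.log_1m_empty - cs - a_idx * c
                M = np.maximum.accumulate(G[:-1])
                j_idx = np.arange(1, L + 1)
                in_arr[1:] = cs[1:] + (j_idx - 1) * c + M
            cell.in_arr = in_arr
            cell.geo_G = G
            cell.done_any = in_arr + st.log_1m_self  # used only via preds

    # ---- termination ----------------------------------------------------
    names_sorted = [n for n in _FINAL_PREFERENCE if n in arch.final]
    names_sorted += [n for n in order if n in arch.final and n not in names_sorted]
    best = (NEG_INF, None, None)  # score, state, kind
    for n in names_sorted:
        st = arch.states[n]
        cell = dp[n]
        if st.duration_kind == "geometric":
            v = float(cell.in_arr[L]) if cell.in_arr is not None else NEG_INF
        else:
            v = float(cell.done_any[L])
        if v > best[0]:
            best = (v, n, "seg")
        if st.empty_logp > NEG_INF:
            v = float(cell.enter[L] + st.empty_logp)
            if v > best[0]:
                best = (v, n, "empty")
    score, name, kind = best
    if name is None or score == NEG_INF or not math.isfinite(score):
        return None

    # ---- backtrace -------------------------------------------------------
    segments: List[Tuple[str, int, int]] = []
    pos = L
    variant = "any"
    while True:
        st = arch.states[name]
        cell = dp[name]
        if kind == "empty":
            segments.append((name, pos, pos))
            src = cell.enter_src[pos]
        else:
            if st.duration_kind == "fixed":
                a = pos - st.fixed_len
            elif st.duration_kind == "explicit":
                a = int(cell.bp_c0[pos] if variant == "c0" else cell.bp_any[pos])
            else:  # geometric
                if st.self_loop_logp == NEG_INF:
                    a = pos - 1
                else:
                    a = int(np.argmax(cell.geo_G[:pos]))
            segments.append((name, a, pos))
            pos = a
            src = cell.enter_src[pos]
        if src is None:
            raise RuntimeError("backtrace lost its way")  # pragma: no cover
        mode, r = src
        if mode == "init":
            break
        if mode == "empty":
            name, kind = r, "empty"
        else:
            prev_state = arch.states[r]
            variant = ("c0" if prev_state.coding_phase is not None
                       and name == "Stop" else "any")
            name, kind = r, "seg"
    segments.reverse()
    return StatePath(segments=segments, log_score=float(score))


def best_noncoding_score(arch: GhmmArchitecture, seq: str,
                         scorer: Optional[SequenceScorer] = None) -> float:
    """Score of the best path through UTR states only (no coding segment)."""
    sub = arch.noncoding_subarchitecture()
    if sub is None:
        return NEG_INF
    path = viterbi_decode(sub, seq, scorer)
    return path.log_score if path is not None else NEG_INF


def extract_cds_call(path: StatePath, seq_len: int) -> Optional[CodingRegion]:
    """Coding interval spanned by Start..Stop (inclusive of both codons when
    present) of a decoded path; ``None`` when the path has no coding state."""
    coding = [
        (n, a, b) for (n, a, b) in path.segments
        if b > a and (n in CODING_PHASE or n in ("Start", "Stop"))
    ]
    if not coding:
        return None
    nz = path.nonzero()
    idx = [i for i, seg in enumerate(nz) if seg in coding]
    if idx != list(range(idx[0], idx[0] + len(idx))):
        raise ValueError("coding segments are not contiguous in the path")
    start = coding[0][1]
    end = coding[-1][2]
    has_start = any(n == "Start" for n, _, _ in coding)
    has_stop = any(n == "Stop" for n, _, _ in coding)
    first = coding[0][0]
    frame = 0 if first in ("Start", "fullCDS") else CODING_PHASE[first]
    if not (0 <= start < end <= seq_len):
        raise ValueError("coding interval out of bounds")
    return CodingRegion(start=start, end=end, frame=frame,
                        has_start=has_start, has_stop=has_stop)
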