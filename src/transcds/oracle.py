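"""Exhaustive reference decoder for tiny inputs.

Enumerates every admissible segmentation of a sequence under an architecture
and scores each with the definitional :func:`transcds.ghmm.score_path`.  It
shares the emission primitives with the decoder but is independent of the
Viterbi dynamic program, so it serves as its correctness oracle on toy
problems (small alphabetically-enumerable search spaces only — the cost is
exponential in sequence length).
"""

from __future__ import annotations

from typing import Iterator, List, Sequence, Tuple

import math

import numpy as np

from .ghmm import GhmmArchitecture, GhmmState, SequenceScorer, StatePath, score_path
from .prob_models import NEG_INF, DurationModel, MarkovChainModel

Segment = Tuple[str, int, int]


def random_toy_architecture(rng: np.random.Generator,
                            max_states: int = 3) -> GhmmArchitecture:
    """A small random architecture (acyclic between states) mixing duration
    kinds, with continuous random parameters; used to exercise the decoder
    against the enumeration oracle."""
    n = int(rng.integers(1, max_states + 1))
    names = [f"S{i}" for i in range(n)]
    states = {}
    for name in names:
        order = int(rng.integers(0, 2))
        probs = rng.dirichlet(np.full(4, 1.0), size=4 ** order)
        emission = MarkovChainModel.from_probs(probs)
        kind = rng.choice(["geometric", "explicit", "fixed"],
                          p=[0.45, 0.35, 0.2])
        if kind == "geometric":
            q = float(rng.uniform(0.2, 0.8))
            empty = (math.log(float(rng.uniform(0.1, 0.4)))
                     if rng.random() < 0.3 else NEG_INF)
            states[name] = GhmmState(name, emission, "geometric",
                                     self_loop_logp=math.log(q),
                                     empty_logp=empty)
        elif kind == "explicit":
            min_len = int(rng.integers(1, 3))
            width = int(rng.integers(1, 4))
            pmf = rng.dirichlet(np.full(width, 1.0))
            if rng.random() < 0.5:
                tail = float(rng.uniform(0.02, 0.15))
                dur = DurationModel(min_len, np.log(pmf * (1 - tail)),
                                    tail_mass=tail,
                                    tail_log_q=math.log(rng.uniform(0.3, 0.7)))
            else:
                dur = DurationModel(min_len, np.log(pmf))
            states[name] = GhmmState(name, emission, "explicit", duration=dur)
        else:
            states[name] = GhmmState(name, emission, "fixed",
                                     fixed_len=int(rng.integers(1, 4)))
    transitions = {}
    for i in range(n):
        succ = [j for j in range(i + 1, n) if rng.random() < 0.6]
        if succ:
            w = rng.dirichlet(np.full(len(succ), 1.0)) * rng.uniform(0.5, 0.95)
            for j, p in zip(succ, w):
                transitions[(names[i], names[j])] = math.log(float(p))
    k = int(rng.integers(1, n + 1))
    init_states = rng.choice(n, size=k, replace=False)
    iw = rng.dirichlet(np.full(k, 1.0))
    initial = {names[int(i)]: math.log(float(p))
               for i, p in zip(init_states, iw)}
    n_final = int(rng.integers(1, n + 1))
    final = {names[int(i)] for i in rng.choice(n, size=n_final, replace=False)}
    return GhmmArchitecture(states=states, transitions=transitions,
                            initial=initial, final=final)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length).tolist())


def enumerate_paths(arch: GhmmArchitecture, seq_len: int,
                    max_segments: int = 64) -> Iterator[List[Segment]]:
    """All state paths whose segments tile ``[0, seq_len)``.

    Zero-length segments are emitted for geometric states that admit them
    (the architecture graph is acyclic, so chains of empties terminate).
    """

    def rec(pos: int, state: str, prefix: List[Segment]) -> Iterator[List[Segment]]:
        if len(prefix) > max_segments:
            return
        st = arch.states[state]
        durations: List[int] = []
        if st.empty_logp > NEG_INF:
            durations.append(0)
        remaining = seq_len - pos
        if st.duration_kind == "fixed":
            if st.fixed_len <= remaining:
                durations.append(st.fixed_len)
        else:
            durations.extend(range(1, remaining + 1))
        for d in durations:
            seg = (state, pos, pos + d)
            new_pos = pos + d
            new_prefix = prefix + [seg]
            if new_pos == seq_len and state in arch.final:
                yield new_prefix
            for (a, b), _ in arch.transitions.items():
                if a == state:
                    yield from rec(new_pos, b, new_prefix)

    for s0 in arch.initial:
        yield from rec(0, s0, [])


def _tie_key(segments: Sequence[Segment]) -> tuple:
    coding = [(n, a, b) for n, a, b in segments
              if n in ("Start", "fullCDS", "Stop", "pCDS0", "pCDS1", "pCDS2")
              and b > a]
    if not coding:
        return (0, 0, 0)
    start = min(a for _, a, _ in coding)
    end = max(b for _, _, b in coding)
    return (1, end - start, -start)


def brute_force_decode(arch: GhmmArchitecture, seq: str,
                       tol: float = 1e-9,
                       ) -> Tuple[float, List[StatePath]]:
    """Best score over all segmentations and the set of optimal paths
    (within ``tol`` of the optimum), sorted by the declared tie-break
    preference (coding first, longer coding segment, leftmost)."""
    scorer = SequenceScorer(seq)
    best = NEG_INF
    scored: List[Tuple[float, List[Segment]]] = []
    for segs in enumerate_paths(arch, scorer.L):
        sc = score_path(arch, seq, segs, scorer)
        if sc == NEG_INF:
            continue
        scored.append((sc, segs))
        if sc > best:
            best = sc
    if best == NEG_INF:
        return NEG_INF, []
    optima = [
        StatePath(segments=list(segs), log_score=sc)
        for sc, segs in scored
        if sc >= best - tol
    ]
    optima.sort(key=lambda p: (p.log_score, _tie_key(p.segments)), reverse=True)
    return best, optima
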