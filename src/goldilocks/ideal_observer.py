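"""Sequential Dirichlet-multinomial ideal observers.

Two normative learners assign each event in a visual-event sequence a
*surprisal* value, the negative log posterior-predictive probability of the
event given everything observed so far in that sequence:

* the **unigram** model treats events as exchangeable draws from one
  categorical distribution over the K objects, and
* the **transitional** (bigram) model conditions each event on the identity
  of the immediately preceding event, maintaining one Dirichlet-multinomial
  row per predecessor.

Both start from a symmetric Dirichlet prior (``alpha`` pseudo-counts per
cell, default 1 — the Laplace "uninformative" choice) and update by simple
count increments, so the posterior predictive for object ``i`` is always

    p_i = (counts_i + alpha_i) / (sum_j counts_j + sum_j alpha_j).

Surprisal is reported in bits (−log2 p). Downstream regressions standardize
surprisal, so the log base only affects reported magnitudes, never
inference.

Model state resets at every sequence boundary: each trial introduces a fresh
object/box binding, so counts never carry over between trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sequences import SequenceSet, SequenceSpec

__all__ = [
    "DirichletCounts",
    "TransitionCounts",
    "SurprisalTrace",
    "predictive_distribution",
    "update",
    "unigram_surprisal_trace",
    "transitional_surprisal_trace",
    "score_sequence_set",
    "traces_to_frame",
]


@dataclass(frozen=True)
class DirichletCounts:
    """Posterior state of a single Dirichlet-multinomial cell block.

    ``alpha`` are strictly positive pseudo-counts (the prior); ``counts``
    are the non-negative observation tallies accumulated so far. The object
    is immutable: :func:`update` returns a new instance.
    """

    alpha: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        if a.ndim != 1 or c.shape != a.shape:
            raise ValueError("alpha and counts must be 1-D arrays of equal length")
        if np.any(a <= 0):
            raise ValueError("all alpha pseudo-counts must be > 0")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "alpha", a)
        object.__setattr__(self, "counts", c)
        self.alpha.setflags(write=False)
        self.counts.setflags(write=False)

    @classmethod
    def uniform(cls, k: int, alpha: float = 1.0) -> "DirichletCounts":
        return cls(np.full(k, float(alpha)), np.zeros(k))

    @property
    def k(self) -> int:
        return self.alpha.shape[0]

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class TransitionCounts:
    """First-order transition tallies plus a marginal state for event 0."""

    alpha: float
    counts: np.ndarray  # (K, K); counts[i, j] = transitions i -> j
    marginal: DirichletCounts

    @classmethod
    def uniform(cls, k: int, alpha: float = 1.0) -> "TransitionCounts":
        return cls(float(alpha), np.zeros((k, k)), DirichletCounts.uniform(k, alpha))

    def row(self, i: int) -> DirichletCounts:
        k = self.counts.shape[0]
        return DirichletCounts(np.full(k, self.alpha), self.counts[i].copy())


@dataclass(frozen=True)
class SurprisalTrace:
    """Per-event surprisal (bits) under both observers, for one sequence."""

    sequence_id: str
    unigram: np.ndarray
    transitional: np.ndarray
    unigram_p: np.ndarray
    transitional_p: np.ndarray
    object_ids: np.ndarray

    def __len__(self) -> int:
        return len(self.unigram)


def predictive_distribution(state: DirichletCounts) -> np.ndarray:
    """Posterior-predictive probabilities (counts + alpha) / (total + sum alpha)."""
    num = state.counts + state.alpha
    return num / num.sum()


def update(state: DirichletCounts, observed: int) -> DirichletCounts:
    """Return a new state with one more observation of ``observed``."""
    if not 0 <= observed < state.k:
        raise ValueError(f"observed object id {observed} out of range [0, {state.k})")
    counts = state.counts.copy()
    counts[observed] += 1
    return DirichletCounts(state.alpha.copy(), counts)


def _object_ids(seq: SequenceSpec | Sequence[int] | np.ndarray) -> tuple[np.ndarray, int]:
    if isinstance(seq, SequenceSpec):
        return seq.object_ids, seq.n_objects
    ids = np.asarray(seq, dtype=int)
    if ids.ndim != 1 or ids.size == 0:
        raise ValueError("sequence must contain at least one event")
    if np.any(ids < 0):
        raise ValueError("object ids must be non-negative")
    # bare id lists default to the 3-object design unless they reference more
    k = max(3, int(ids.max()) + 1)
    return ids, k


def unigram_surprisal_trace(
    seq: SequenceSpec | Sequence[int],
    alpha: float = 1.0,
    n_objects: int | None = None,
    return_probabilities: bool = False,
):
    """Per-event unigram surprisal in bits.

    Event t is scored against the predictive distribution formed from events
    0..t-1 (plus the prior) and is only then absorbed into the counts.
    """
    ids, k = _object_ids(seq)
    if n_objects is not None:
        k = int(n_objects)
    if np.any(ids >= k):
        raise ValueError("object id out of range for given n_objects")
    counts = np.zeros(k)
    a_tot = k * alpha
    probs = np.empty(len(ids))
    for t, obj in enumerate(ids):
        probs[t] = (counts[obj] + alpha) / (t + a_tot)
        counts[obj] += 1
    surprisal = -np.log2(probs)
    if return_probabilities:
        return surprisal, probs
    return surprisal


def transitional_surprisal_trace(
    seq: SequenceSpec | Sequence[int],
    alpha: float = 1.0,
    n_objects: int | None = None,
    return_probabilities: bool = False,
):
    """Per-event transitional (bigram) surprisal in bits.

    The first event has no predecessor, so it is scored by the marginal
    Dirichlet-multinomial prior exactly as the unigram model would score it;
    every later event t is scored by row ``object_{t-1}`` of the transition
    count matrix, then the (object_{t-1}, object_t) cell is incremented.
    """
    ids, k = _object_ids(seq)
    if n_objects is not None:
        k = int(n_objects)
    if np.any(ids >= k):
        raise ValueError("object id out of range for given n_objects")
    trans = np.zeros((k, k))
    a_tot = k * alpha
    probs = np.empty(len(ids))
    probs[0] = alpha / a_tot  # uniform prior, zero observations
    for t in range(1, len(ids)):
        prev, cur = ids[t - 1], ids[t]
        row = trans[prev]
        probs[t] = (row[cur] + alpha) / (row.sum() + a_tot)
        row[cur] += 1
    surprisal = -np.log2(probs)
    if return_probabilities:
        return surprisal, probs
    return surprisal


def score_sequence(seq: SequenceSpec, alpha: float = 1.0) -> SurprisalTrace:
    """Both surprisal traces for a single sequence (state reset per call)."""
    uni, uni_p = unigram_surprisal_trace(seq, alpha, return_probabilities=True)
    trans, trans_p = transitional_surprisal_trace(seq, alpha, return_probabilities=True)
    return SurprisalTrace(
        sequence_id=seq.sequence_id,
        unigram=uni,
        transitional=trans,
        unigram_p=uni_p,
        transitional_p=trans_p,
        object_ids=seq.object_ids,
    )


def score_sequence_set(sset: SequenceSet | Iterable[SequenceSpec], alpha: float = 1.0) -> list[SurprisalTrace]:
    seqs = sset.sequences if isinstance(sset, SequenceSet) else list(sset)
    return [score_sequence(s, alpha) for s in seqs]


def traces_to_frame(traces: Iterable[SurprisalTrace]) -> pd.DataFrame:
    """Long-format table, one row per (sequence, event)."""
    rows = []
    for tr in traces:
        for t in range(len(tr)):
            rows.append(
                {
                    "sequence_id": tr.sequence_id,
                    "event_index": t,
                    "object_id": int(tr.object_ids[t]),
                    "unigram_surprisal_bits": tr.unigram[t],
                    "transitional_surprisal_bits": tr.transitional[t],
                    "unigram_p": tr.unigram_p[t],
                    "transitional_p": tr.transitional_p[t],
                }
            )
    return pd.DataFrame(rows)
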