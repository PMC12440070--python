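"""Definition-level brute-force enumeration of LC intervals.

The reference against which the windowed engine is validated: every
interval of length <= w is tested directly against the definitions.

* good interval:    S > 0 and no proper prefix or suffix scores strictly
                    higher (an equal-scoring prefix/suffix is allowed);
* perfect interval: S > 0 and no proper substring scores strictly higher.

Every perfect interval is good.  Sub-k-mer-length substrings score 0, so
S > 0 already dominates them.  The enumeration is O(w^2) per position and
guarded against accidental genome-scale use; it exists for testing only.
"""
from __future__ import annotations

from typing import List, Tuple

import numpy as np

from .engine import EncodedSequence, LCInterval, _prefix_scores, kmer_codes
from .model import ParameterError, ScoreTables


class SizeError(ParameterError):
    """The requested brute-force run exceeds the desk-scale guard."""


def _valid_runs(kvalid: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal runs [a, b] of consecutive valid k-mer start indices."""
    runs = []
    a = None
    for i, v in enumerate(kvalid.tolist()):
        if v and a is None:
            a = i
        elif not v and a is not None:
            runs.append((a, i - 1))
            a = None
    if a is not None:
        runs.append((a, len(kvalid) - 1))
    return runs


def all_good_intervals(
    seq: EncodedSequence,
    tables: ScoreTables,
    *,
    max_evals: int = 10_000_000,
) -> List[LCInterval]:
    """Exact set of good LC intervals of length <= w, sorted by position.

    For each start, prefix scores over every end are computed in one pass;
    running maxima over prefixes and (across starts) suffixes test the
    goodness condition exactly.
    """
    k, w = tables.model.k, tables.w
    n = len(seq)
    if n * w > max_evals:
        raise SizeError(
            f"brute-force enumeration over {n} bases x window {w} exceeds the "
            f"guard of {max_evals} score evaluations"
        )
    kcodes, kvalid = kmer_codes(seq, k)
    max_kmers = w - k + 1
    out: List[LCInterval] = []
    for a, b in _valid_runs(kvalid):
        nrun = b - a + 1
        # sufmax[e] = max over already-seen starts i' > i of S(i', e)
        sufmax = np.full(nrun, -np.inf)
        for i in range(nrun - 1, -1, -1):
            m = min(max_kmers, nrun - i)
            scores = _prefix_scores(kcodes[a + i : a + i + m], tables)
            pref_before = np.empty(m)
            pref_before[0] = -np.inf  # no proper >=k-base prefix
            if m > 1:
                pref_before[1:] = np.maximum.accumulate(scores)[:-1]
            good = (scores > 0.0) & (scores >= pref_before) & (scores >= sufmax[i : i + m])
            for rel in np.nonzero(good)[0]:
                start = a + i
                end = a + i + int(rel) + k - 1
                out.append(LCInterval(seq.name, start, end, float(scores[rel])))
            np.maximum(sufmax[i : i + m], scores, out=sufmax[i : i + m])
    out.sort(key=lambda iv: (iv.start, iv.end))
    return out


def all_perfect_intervals(
    seq: EncodedSequence,
    tables: ScoreTables,
    *,
    max_len: int = 300,
) -> List[LCInterval]:
    """Exact set of perfect LC intervals of length <= w (cubic check).

    M(i, e) = best score over substrings of the interval with start k-mer i
    and end k-mer e is built by dynamic programming; an interval is perfect
    iff its own score is positive and not exceeded by M of its two maximal
    proper sub-intervals (substrings shorter than k score 0).
    """
    k, w = tables.model.k, tables.w
    n = len(seq)
    if n > max_len:
        raise SizeError(f"perfect-interval enumeration limited to {max_len} bases, got {n}")
    kcodes, kvalid = kmer_codes(seq, k)
    max_kmers = w - k + 1
    out: List[LCInterval] = []
    for a, b in _valid_runs(kvalid):
        nrun = b - a + 1
        S = np.full((nrun, nrun), -np.inf)
        for i in range(nrun):
            m = min(max_kmers, nrun - i)
            S[i, i : i + m] = _prefix_scores(kcodes[a + i : a + i + m], tables)
        M = np.full((nrun, nrun), -np.inf)
        for length in range(nrun):  # e - i = length
            for i in range(nrun - length):
                e = i + length
                if e - i + 1 > max_kmers:
                    continue
                inner = 0.0  # substrings shorter than k bases score 0
                if e > i:
                    inner = max(inner, M[i + 1, e], M[i, e - 1])
                s = S[i, e]
                M[i, e] = max(s, inner)
                if s > 0.0 and s >= inner:
                    out.append(LCInterval(seq.name, a + i, a + e + k - 1, float(s)))
    out.sort(key=lambda iv: (iv.start, iv.end))
    return out


def base_union(intervals: List[LCInterval], n: int) -> np.ndarray:
    """Boolean per-base coverage mask of a list of closed intervals."""
    mask = np.zeros(n, dtype=bool)
    for iv in intervals:
        mask[iv.start : iv.end + 1] = True
    return mask


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard similarity of two coverage masks; 1.0 when both are empty."""
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
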