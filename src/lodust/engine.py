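"""Windowed search for good low-complexity (LC) intervals.

A closed interval [i, j] (base coordinates) is a *good* LC interval when
its score S(i, j) is positive and no proper prefix or suffix scores
strictly higher (ties allowed).  For each end position j whose terminal
k-mer repeats within the trailing window of w bases, a backward pass over
suffix scores collects candidate start positions and a forward pass tests
each candidate: [i, j] is good iff j maximises S(i, j') over j' <= j.

Heuristics on top of the exact per-position test:

* skip j entirely when its terminal k-mer is unique in the window (the
  forward pass could never reach j);
* prune candidate starts whose suffix is mostly window-unique k-mers
  (each such k-mer contributes -T and cannot gain for any end <= j);
* extend a reported full-window interval by one base without re-searching
  while the incoming k-mer repeats and the window score does not drop;
* X-drop trimming of reported intervals at internal score valleys.

The search is deterministic and strand symmetry is obtained by scanning
both the sequence and its reverse complement and merging the union.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .model import (
    DEFAULT_RHO,
    DEFAULT_XDROP,
    ScoreTables,
)

# 2-bit base codes; anything outside ACGT/acgt is invalid.
_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase


@dataclass(frozen=True)
class EncodedSequence:
    """2-bit-coded DNA with a validity mask for ambiguous bases."""

    name: str
    codes: np.ndarray  # uint8, 0..3 where valid
    valid: np.ndarray  # bool

    def __len__(self) -> int:
        return len(self.codes)

    @classmethod
    def from_string(cls, name: str, seq: str) -> "EncodedSequence":
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        codes = _BASE_CODE[raw]
        valid = codes != 255
        codes = np.where(valid, codes, 0).astype(np.uint8)
        return cls(name=name, codes=codes, valid=valid)

    def to_string(self) -> str:
        out = np.frombuffer(b"ACGT", dtype=np.uint8)[self.codes].copy()
        out[~self.valid] = ord("N")
        return out.tobytes().decode("ascii")


def reverse_complement(seq: EncodedSequence) -> EncodedSequence:
    """Watson-Crick complement, reversed; invalid bases stay invalid."""
    codes = (3 - seq.codes[::-1]).astype(np.uint8)
    valid = seq.valid[::-1].copy()
    codes = np.where(valid, codes, 0).astype(np.uint8)
    return EncodedSequence(name=seq.name, codes=codes, valid=valid)


def kmer_codes(seq: EncodedSequence, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Integer codes and validity for every k-mer start of ``seq``.

    Returns (codes, valid) of length len(seq) - k + 1; a k-mer is valid
    iff all k of its bases are.
    """
    n = len(seq)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(seq.codes.astype(np.int64), k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = win @ powers
    vwin = np.lib.stride_tricks.sliding_window_view(seq.valid, k)
    valid = vwin.all(axis=1)
    return codes, valid


@dataclass(frozen=True)
class LCInterval:
    """A scored low-complexity interval, closed [start, end] in 0-based bases.

    ``extended`` marks an interval produced by the O(1) full-window slide
    rather than by the verified backward/forward search; such intervals
    still guarantee S > 0 but not prefix/suffix maximality.
    """

    name: str
    start: int
    end: int
    score: float
    extended: bool = False

    def __len__(self) -> int:
        return self.end - self.start + 1

    def to_bed(self) -> Tuple[str, int, int]:
        """0-based half-open BED coordinates."""
        return self.name, self.start, self.end + 1


@dataclass(frozen=True)
class CandidateStart:
    """A candidate interval start collected by the backward pass."""

    i: int      # base coordinate of the first base of the candidate
    v: float    # suffix score S(i, j) at collection time


class WindowState:
    """Rolling k-mer counts over the trailing window of a scan.

    Tracks the window start (as a k-mer start index into the sequence's
    k-mer array) and the occurrence count of every k-mer code currently
    inside the window.  The ring holds at most w - k + 1 k-mers.
    """

    def __init__(self, k: int, w: int):
        self.k = k
        self.w = w
        self.max_kmers = w - k + 1
        self.counts = np.zeros(4 ** k, dtype=np.int32)
        self.ws = 0        # k-mer index of the oldest window entry
        self.j = -1        # current end base position

    def window_codes(self, kcodes: np.ndarray, p: int) -> np.ndarray:
        """K-mer codes currently in the window ending at k-mer index p."""
        return kcodes[self.ws : p + 1]


# ---------------------------------------------------------------------------
# Score passes (vectorised)
# ---------------------------------------------------------------------------

def _occ_ranks(a: np.ndarray) -> np.ndarray:
    """occ[i] = number of occurrences of a[i] within a[: i + 1].

    Stable argsort groups equal codes in original order, so the offset of
    an element within its group is its occurrence number minus one.
    """
    n = a.size
    if n == 0:
        return np.empty(0, dtype=np.int64)
    order = np.argsort(a, kind="stable")
    s = a[order]
    starts = np.empty(n, dtype=bool)
    starts[0] = True
    starts[1:] = s[1:] != s[:-1]
    pos = np.arange(n)
    group_first = pos[starts][np.cumsum(starts) - 1]
    ranks_sorted = pos - group_first + 1
    out = np.empty(n, dtype=np.int64)
    out[order] = ranks_sorted
    return out


def _occ_ranks_from_right(a: np.ndarray) -> np.ndarray:
    """occ[i] = number of occurrences of a[i] within a[i:]."""
    return _occ_ranks(a[::-1])[::-1]


def _prefix_u(codes: np.ndarray, T: float) -> np.ndarray:
    """Running U = sum_t log c_t! - T*ell over prefixes, one entry per k-mer."""
    occ = _occ_ranks(codes)
    return np.cumsum(np.log(occ) - T)


def _prefix_scores(codes: np.ndarray, tables: ScoreTables) -> np.ndarray:
    """S(i, j') for every prefix end j' of the k-mer slice ``codes``."""
    u = _prefix_u(codes, tables.T)
    ell = np.arange(1, codes.size + 1)
    return u - tables.f[ell]


def _suffix_u(codes: np.ndarray, T: float) -> np.ndarray:
    """Running U over suffixes: entry p covers codes[p:]."""
    occ = _occ_ranks_from_right(codes)
    return np.cumsum((np.log(occ) - T)[::-1])[::-1]


def _suffix_scores(codes: np.ndarray, tables: ScoreTables) -> np.ndarray:
    """S(i', j) for every suffix start i' of the k-mer slice ``codes``."""
    u = _suffix_u(codes, tables.T)
    ell = codes.size - np.arange(codes.size)
    return u - tables.f[ell]


# ---------------------------------------------------------------------------
# Backward / Forward passes
# ---------------------------------------------------------------------------

def _backward_candidates(
    wc: np.ndarray,
    uniq: np.ndarray,
    tables: ScoreTables,
    rho: float,
) -> List[Tuple[int, float]]:
    """Candidate start positions (relative to the window) in ascending order.

    A relative k-mer start p survives when

    * its suffix score v = S(p, j) is positive (a reported interval needs
      S > 0, and Forward returns exactly v when the interval is good);
    * v is >= the score of every shorter suffix (visited before it in the
      right-to-left scan);
    * v is >= the score of the one-base-longer suffix (if [p-1, j] scored
      higher, [p, j] cannot be the good interval ending at j);
    * the fraction of window-unique k-mers in the suffix is <= rho.
    """
    nw = wc.size
    s = _suffix_scores(wc, tables)
    ell = nw - np.arange(nw)
    ok = s > 0.0
    # best score among strictly shorter suffixes
    best_shorter = np.empty(nw)
    best_shorter[nw - 1] = -np.inf
    if nw > 1:
        best_shorter[: nw - 1] = np.maximum.accumulate(s[::-1])[::-1][1:]
    ok &= s >= best_shorter
    # one-base-longer suffix must not score higher
    longer_ok = np.ones(nw, dtype=bool)
    longer_ok[1:] = s[1:] >= s[:-1]
    ok &= longer_ok
    # unique-k-mer enrichment prune
    if rho < 1.0:
        uq = np.cumsum(uniq[::-1].astype(np.int64))[::-1]
        ok &= uq <= rho * ell
    idx = np.nonzero(ok)[0]
    return [(int(p), float(s[p])) for p in idx]


def backward_scan(
    state: WindowState,
    kcodes: np.ndarray,
    p: int,
    tables: ScoreTables,
    rho: float = DEFAULT_RHO,
) -> List[CandidateStart]:
    """Collect candidate starts for intervals ending at k-mer index p."""
    wc = state.window_codes(kcodes, p)
    uniq = state.counts[wc] == 1
    rel = _backward_candidates(wc, uniq, tables, rho)
    return [CandidateStart(i=state.ws + r, v=v) for r, v in rel]


def forward_extend(
    kcodes: np.ndarray,
    i_k: int,
    p: int,
    tables: ScoreTables,
) -> Tuple[int, float]:
    """argmax_{i < j' <= j} S(i, j') for start k-mer i_k and end k-mer p.

    Returns (jstar, sstar) with jstar a base coordinate; ties broken by
    the largest j' so the longest good interval wins.
    """
    k = tables.model.k
    scores = _prefix_scores(kcodes[i_k : p + 1], tables)
    sstar = float(scores.max())
    rel = scores.size - 1 - int(np.argmax(scores[::-1]))  # last index attaining max
    return i_k + k - 1 + rel, sstar


# ---------------------------------------------------------------------------
# Whole-strand scan
# ---------------------------------------------------------------------------

def _scan_raw(
    seq: EncodedSequence,
    tables: ScoreTables,
    rho: float = DEFAULT_RHO,
) -> List[LCInterval]:
    """All good LC intervals reported position by position, pre-trim, pre-merge."""
    k, w, T = tables.model.k, tables.w, tables.T
    n = len(seq)
    if n < k:
        return []
    kcodes, kvalid = kmer_codes(seq, k)
    nk = kcodes.size
    state = WindowState(k, w)
    counts = state.counts
    log_t = T
    out: List[LCInterval] = []
    prev: Optional[Tuple[int, int]] = None  # last raw interval (start, end)
    prev_u: Optional[float] = None          # its U when it spans the full window
    kvalid_list = kvalid.tolist()
    kcodes_list = kcodes.tolist()

    for p in range(nk):
        if not kvalid_list[p]:
            # non-ACGT base: flush the window entirely
            if p > state.ws:
                counts[kcodes[state.ws : p]] = 0
            state.ws = p + 1
            prev = None
            prev_u = None
            continue
        removed_log: Optional[float] = None
        nws = p + 1 - state.max_kmers
        if nws > state.ws:
            if nws == state.ws + 1:
                t0 = kcodes_list[state.ws]
                removed_log = math.log(counts[t0])
                counts[t0] -= 1
            else:
                np.subtract.at(counts, kcodes[state.ws : nws], 1)
            state.ws = nws
        t = kcodes_list[p]
        counts[t] += 1
        c = int(counts[t])
        j = p + k - 1
        state.j = j

        # Full-window extension heuristic: slide a full-window good interval
        # forward in O(1) while the incoming k-mer repeats, the interval's U
        # does not decrease, and the slid window still scores positive;
        # otherwise fall through to the verified search.
        if (
            prev is not None
            and prev_u is not None
            and removed_log is not None
            and prev[1] == j - 1
            and prev[1] - prev[0] + 1 == w
            and c >= 2
            and math.log(c) >= log_t
        ):
            new_u = prev_u + math.log(c) - removed_log
            score = new_u - tables.f[state.max_kmers]
            if score > 0.0:
                prev_u = new_u
                iv = LCInterval(seq.name, j - w + 1, j, float(score), extended=True)
                out.append(iv)
                prev = (iv.start, iv.end)
                continue

        # Skip rule: a window-unique terminal k-mer cannot end a good interval.
        if c < 2:
            continue

        cands = backward_scan(state, kcodes, p, tables, rho)
        for cand in cands:
            i_k = cand.i
            jstar, sstar = forward_extend(kcodes, i_k, p, tables)
            if jstar == j and sstar > 0.0:
                iv = LCInterval(seq.name, i_k, j, sstar)
                out.append(iv)
                prev = (iv.start, iv.end)
                if iv.end - iv.start + 1 == w:
                    prev_u = sstar + tables.f[state.max_kmers]
                else:
                    prev_u = None
                # any later candidate start is contained in [i_k, j]
                break
    return out


def xdrop_trim(
    interval: LCInterval,
    kcodes: np.ndarray,
    tables: ScoreTables,
    x: float = DEFAULT_XDROP,
) -> LCInterval:
    """Trim an interval at internal X-drop valleys of the running U score.

    A good interval attains its score maximum at both ends, so a drop can
    only be internal: a long non-repetitive spacer absorbed between two
    repetitive blocks.  Scanning the prefix U left to right, a position
    violates the X-drop condition when U falls more than ``x`` below the
    running maximum *after that maximum has become positive* (before any
    repeat is established the initial unique-k-mer dip is expected and must
    not trim exact tandem arrays).  The left end moves past the last
    violating position; the right end is trimmed symmetrically from the
    suffix scan.  Never widens; ``x = inf`` (or None) is the identity.
    """
    if x is None or not math.isfinite(x):
        return interval
    k = tables.model.k
    i_k = interval.start
    p = interval.end - k + 1
    sub = kcodes[i_k : p + 1]
    if sub.size == 0:
        return interval

    u_pre = _prefix_u(sub, tables.T)
    runmax = np.maximum.accumulate(u_pre)
    viol = (runmax > 0.0) & (u_pre < runmax - x)
    left_rel = 0
    if viol.any():
        left_rel = int(np.nonzero(viol)[0][-1]) + 1

    u_suf = _suffix_u(sub, tables.T)
    runmax_r = np.maximum.accumulate(u_suf[::-1])[::-1]
    viol_r = (runmax_r > 0.0) & (u_suf < runmax_r - x)
    right_rel = sub.size - 1
    if viol_r.any():
        right_rel = int(np.nonzero(viol_r)[0][0]) - 1

    if left_rel == 0 and right_rel == sub.size - 1:
        return interval

    def _rescored(lo_rel: int, hi_rel: int) -> LCInterval:
        new_start = i_k + lo_rel
        new_end = i_k + hi_rel + k - 1
        score = float(_prefix_scores(kcodes[new_start : new_end - k + 2], tables)[-1])
        return LCInterval(interval.name, new_start, new_end, score)

    if right_rel >= left_rel:
        return _rescored(left_rel, right_rel)
    # The two trims cross: the interval has an internal valley both scans cut
    # through.  Keep the higher-scoring flank (ties favour the right flank,
    # which ends at the position the search reported).
    right_flank = _rescored(left_rel, sub.size - 1)
    left_flank = _rescored(0, right_rel)
    return right_flank if right_flank.score >= left_flank.score else left_flank


def merge_intervals(intervals: Sequence[LCInterval]) -> List[LCInterval]:
    """Merge overlapping or book-ended closed intervals into maximal blocks.

    The merged score is the maximum of the member scores.
    """
    by_name: dict = {}
    order: List[str] = []
    for iv in intervals:
        if iv.name not in by_name:
            by_name[iv.name] = []
            order.append(iv.name)
        by_name[iv.name].append(iv)
    out: List[LCInterval] = []
    for name in order:
        ivs = sorted(by_name[name], key=lambda v: (v.start, v.end))
        cur = ivs[0]
        for iv in ivs[1:]:
            if iv.start <= cur.end + 1:
                cur = LCInterval(name, cur.start, max(cur.end, iv.end), max(cur.score, iv.score))
            else:
                out.append(cur)
                cur = iv
        out.append(cur)
    return out


def scan_strand(
    seq: EncodedSequence,
    tables: ScoreTables,
    *,
    xdrop: Optional[float] = DEFAULT_XDROP,
    rho: float = DEFAULT_RHO,
    raw: bool = False,
) -> List[LCInterval]:
    """Good LC intervals of one strand orientation of ``seq``.

    With ``raw=True`` returns the per-position reported intervals before
    X-drop trimming and merging (used by the definitional validity tests);
    otherwise intervals are trimmed and merged into sorted, non-overlapping
    blocks.
    """
    ivs = _scan_raw(seq, tables, rho=rho)
    if raw:
        return ivs
    if not ivs:
        return []
    kcodes, _ = kmer_codes(seq, tables.model.k)
    trimmed = [xdrop_trim(iv, kcodes, tables, xdrop) for iv in ivs]
    return merge_intervals(trimmed)


def scan_symmetric(
    seq: EncodedSequence,
    tables: ScoreTables,
    *,
    xdrop: Optional[float] = DEFAULT_XDROP,
    rho: float = DEFAULT_RHO,
) -> List[LCInterval]:
    """Strand-symmetric LC intervals: the union of both strand scans.

    The output is invariant under reverse-complementing the input because
    the union of the two per-strand results is itself strand symmetric.
    """
    n = len(seq)
    fwd = scan_strand(seq, tables, xdrop=xdrop, rho=rho)
    rev = scan_strand(reverse_complement(seq), tables, xdrop=xdrop, rho=rho)
    mapped = [
        LCInterval(seq.name, n - 1 - iv.end, n - 1 - iv.start, iv.score) for iv in rev
    ]
    if not fwd and not mapped:
        return []
    return merge_intervals(list(fwd) + mapped)


def find_intervals_at(
    j: int,
    seq: EncodedSequence,
    tables: ScoreTables,
    *,
    rho: float = DEFAULT_RHO,
) -> List[LCInterval]:
    """Good LC intervals ending exactly at base position j (test helper).

    Runs the scan up to j and returns the raw intervals with end == j.
    """
    ivs = _scan_raw(seq, tables, rho=rho)
    return [iv for iv in ivs if iv.end == j]
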