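"""Statistical model of k-mer counts for low-complexity (LC) scoring.

The complexity of a DNA string x is measured from its k-mer count vector
c = (c_t).  Under a multinomial null model with k-mer frequencies q_t, the
expected value of sum_t log c_t! for a random string with ell k-mers is the
scaling function f(ell).  The centred score

    Q(c) = sum_t log c_t! - f(ell)

approaches 0 on random strings of any length and grows on compositionally
repetitive ones.  Thresholding per k-mer gives the working score

    S(c) = Q(c) - T * ell = sum_t log c_t! - T * ell - f(ell)

with T in nats per k-mer (default 0.6, below log 2 so that a duplicated
k-mer pair still gains score).  A string contains an LC substring iff
S > 0.  All logarithms are natural.

The null frequencies come from genome-wide GC content alone: bases are
modelled i.i.d. with P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2, so a
k-mer's frequency depends only on its number m of G/C bases.  Only the
k+1 GC classes are stored; f(ell) is then a sum of k+1 Poisson
expectations weighted by the class sizes C(k,m) * 2**k instead of 4**k
per-k-mer terms.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy.special import comb, gammaln
from scipy.stats import binom

# Package-wide defaults.
DEFAULT_K = 7
DEFAULT_W = 5000
DEFAULT_T = 0.6
DEFAULT_XDROP = 20.0
DEFAULT_RHO = 0.5
GC_EPS = 1e-6  # estimated GC is clamped into [GC_EPS, 1 - GC_EPS]

MAX_K = 12


class ParameterError(ValueError):
    """A model or search parameter is outside its valid range."""


# ---------------------------------------------------------------------------
# Frequency model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrequencyModel:
    """Null k-mer frequencies derived from genome-wide GC content.

    Attributes
    ----------
    k : int
        k-mer length.
    gc : float
        Genome-wide GC fraction in (0, 1).
    q_by_gc_class : ndarray, shape (k+1,)
        q[m], the frequency of any single k-mer containing m G/C bases.
    r_by_gc_class : ndarray, shape (k+1,)
        r[m] = 4**k * q[m], enrichment relative to the uniform model.
    """

    k: int
    gc: float
    q_by_gc_class: np.ndarray
    r_by_gc_class: np.ndarray

    def class_sizes(self) -> np.ndarray:
        """Number of distinct k-mers in each GC class: C(k, m) * 2**k."""
        return comb(self.k, np.arange(self.k + 1)) * 2.0 ** self.k


def gc_to_frequency_model(gc: float, k: int = DEFAULT_K) -> FrequencyModel:
    """Build the GC-class frequency model for an i.i.d. base composition.

    Parameters
    ----------
    gc : float
        GC fraction, strictly inside (0, 1).
    k : int
        k-mer length, 1 <= k <= 12.
    """
    if not (0.0 < gc < 1.0):
        raise ParameterError(f"gc must be in (0, 1), got {gc!r}")
    if not (isinstance(k, (int, np.integer)) and 1 <= k <= MAX_K):
        raise ParameterError(f"k must be an integer in [1, {MAX_K}], got {k!r}")
    m = np.arange(k + 1)
    q = (gc / 2.0) ** m * ((1.0 - gc) / 2.0) ** (k - m)
    r = 4.0 ** k * q
    return FrequencyModel(k=int(k), gc=float(gc), q_by_gc_class=q, r_by_gc_class=r)


# ---------------------------------------------------------------------------
# The scaling function f(ell)
# ---------------------------------------------------------------------------

def _poisson_mean_log_factorial(lam: np.ndarray, rel_tol: float = 1e-12) -> np.ndarray:
    """E[log N!] for N ~ Poisson(lam), element-wise over an array of rates.

    The series sum_{n>=0} log(n!) * e^{-lam} lam^n / n! is accumulated until
    n exceeds every rate and the largest remaining term is below
    ``rel_tol`` times the running sum (bounded, deterministic truncation).
    """
    lam = np.asarray(lam, dtype=float)
    pmf = np.exp(-lam)  # n = 0 term of the Poisson pmf
    acc = np.zeros_like(lam)
    lam_max = float(lam.max()) if lam.size else 0.0
    log_fact = 0.0
    n = 0
    while True:
        n += 1
        pmf = pmf * lam / n
        log_fact += math.log(n)
        term = log_fact * pmf
        acc += term
        # n = 1 contributes log 1! = 0; never stop before the n = 2 term.
        if n >= 2 and n > lam_max and float(term.max(initial=0.0)) <= rel_tol * max(float(acc.max(initial=0.0)), 1e-300):
            break
        if n > 100000:  # unreachable for sane rates; guards an infinite loop
            raise RuntimeError("Poisson series failed to converge")
    return acc


def compute_f_table(model: FrequencyModel, max_ell: int) -> np.ndarray:
    """Poisson-approximate scaling table f(ell) for ell = 0..max_ell.

    f(ell) = sum_m C(k,m) 2**k * E[log N!],  N ~ Poisson(ell * q[m]),
    i.e. the expected sum of log-factorial counts for a random string with
    ell k-mers.  f(0) = 0 and the table is non-decreasing.
    """
    if max_ell < 1:
        raise ParameterError(f"max_ell must be >= 1, got {max_ell}")
    ell = np.arange(max_ell + 1, dtype=float)
    weights = model.class_sizes()
    f = np.zeros(max_ell + 1)
    for m, (qm, wm) in enumerate(zip(model.q_by_gc_class, weights)):
        f += wm * _poisson_mean_log_factorial(ell * qm)
    return f


def compute_f_table_exact(model: FrequencyModel, max_ell: int) -> np.ndarray:
    """Exact binomial-form scaling table; the oracle for ``compute_f_table``.

    Under the multinomial model each count is marginally
    Binomial(ell, q_t), so
    f(ell) = sum_m C(k,m) 2**k * sum_n binom.pmf(n; ell, q[m]) * log n!.
    Quadratic in max_ell; intended for validation at modest ell only.
    """
    if max_ell < 1:
        raise ParameterError(f"max_ell must be >= 1, got {max_ell}")
    n = np.arange(max_ell + 1)
    log_fact = gammaln(n + 1.0)
    ell_col = np.arange(max_ell + 1)[:, None]
    weights = model.class_sizes()
    f = np.zeros(max_ell + 1)
    for m, (qm, wm) in enumerate(zip(model.q_by_gc_class, weights)):
        pmf = binom.pmf(n[None, :], ell_col, qm)  # rows: ell, cols: n
        f += wm * (pmf @ log_fact)
    return f


# ---------------------------------------------------------------------------
# Count containers and score tables
# ---------------------------------------------------------------------------

@dataclass
class KmerCounts:
    """A k-mer count multiset c_t with its total ell = sum_t c_t.

    ``counts`` maps a k-mer identifier (string or integer code) to its
    occurrence count; identity of the keys is irrelevant to every score.
    """

    counts: Mapping
    k: Optional[int] = None

    def __post_init__(self) -> None:
        for c in self.counts.values():
            if c < 0:
                raise ParameterError("k-mer counts must be non-negative")

    @property
    def ell(self) -> int:
        return int(sum(self.counts.values()))

    def count_values(self) -> np.ndarray:
        """The multiset of non-zero counts as an int array."""
        vals = np.asarray([c for c in self.counts.values() if c > 0], dtype=np.int64)
        return vals

    @classmethod
    def from_sequence(cls, seq: str, k: int) -> "KmerCounts":
        """Count the k-mers of ``seq``; windows touching non-ACGT are skipped."""
        if not (1 <= k <= MAX_K):
            raise ParameterError(f"k must be in [1, {MAX_K}], got {k}")
        s = seq.upper()
        counts: Counter = Counter()
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if all(b in "ACGT" for b in kmer):
                counts[kmer] += 1
        return cls(counts=counts, k=k)


@dataclass(frozen=True)
class ScoreTables:
    """Precomputed tables for scoring intervals inside a context window.

    Holds the per-k-mer threshold T, the window size w in bases, a table of
    log n! for n = 0..w, and f(ell) for ell = 0..w-k+1 under ``model``.
    """

    model: FrequencyModel
    w: int
    T: float
    log_fact: np.ndarray
    f: np.ndarray

    @classmethod
    def build(cls, model: FrequencyModel, w: int = DEFAULT_W, T: float = DEFAULT_T) -> "ScoreTables":
        if w < model.k:
            raise ParameterError(f"window w={w} smaller than k={model.k}")
        if not (0.0 < T < math.log(4.0)):
            raise ParameterError(f"T must be in (0, log 4), got {T}")
        # Cumulative-sum log-factorial table; exact, no Stirling.
        log_fact = np.concatenate(([0.0], np.cumsum(np.log(np.arange(1, w + 1, dtype=float)))))
        f = compute_f_table(model, w - model.k + 1)
        return cls(model=model, w=int(w), T=float(T), log_fact=log_fact, f=f)

    @property
    def max_ell(self) -> int:
        """Largest k-mer count the f table covers (= w - k + 1)."""
        return len(self.f) - 1


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def _check_ell(ell: int, tables: ScoreTables) -> None:
    if ell > tables.max_ell:
        raise ParameterError(
            f"ell={ell} exceeds the score table range ({tables.max_ell})"
        )


def score_Q(counts: KmerCounts, tables: ScoreTables) -> float:
    """Length-scaled complexity score Q = sum_t log c_t! - f(ell)."""
    vals = counts.count_values()
    ell = int(vals.sum())
    _check_ell(ell, tables)
    return float(np.sum(tables.log_fact[vals]) - tables.f[ell])


def score_S(counts: KmerCounts, tables: ScoreTables) -> float:
    """Thresholded score S = Q - T*ell; S > 0 flags an LC substring."""
    vals = counts.count_values()
    ell = int(vals.sum())
    _check_ell(ell, tables)
    return float(np.sum(tables.log_fact[vals]) - tables.T * ell - tables.f[ell])


def u_score_step(prev_u: float, new_count: int, T: float) -> float:
    """One incremental update of U = sum_t log c_t! - T*ell.

    ``new_count`` is the count of the incoming k-mer within the interval
    *after* inclusion; U of the empty interval is 0.
    """
    if new_count < 1:
        raise ParameterError(f"new_count must be >= 1, got {new_count}")
    return prev_u + math.log(new_count) - T


def sdust_score(counts: KmerCounts, T: float = DEFAULT_T) -> float:
    """The DUST/SDUST-style score (1/ell) sum_t c_t (c_t - 1)/2 - T.

    Grows linearly with ell on repeats, which is why the classic scorer
    over-calls long windows; provided for comparison only.
    """
    vals = counts.count_values()
    ell = int(vals.sum())
    if ell < 1:
        raise ParameterError("sdust_score undefined for ell = 0")
    return float(np.sum(vals * (vals - 1) / 2.0) / ell - T)


def entropy_score(counts: KmerCounts, T: float = DEFAULT_T) -> float:
    """Shannon-entropy scorer S_E = (1/ell) sum_t c_t log c_t - T.

    Equals log(ell) - H(c/ell) - T where H is the Shannon entropy of the
    empirical k-mer distribution; only meaningful for ell <= 4**k.
    """
    vals = counts.count_values()
    ell = int(vals.sum())
    if ell < 1:
        raise ParameterError("entropy_score undefined for ell = 0")
    if counts.k is not None and ell > 4 ** counts.k:
        raise ParameterError(f"entropy_score requires ell <= 4**k, got ell={ell}")
    v = vals.astype(float)
    return float(np.sum(v * np.log(v)) / ell - T)


def min_detectable_copies(k: int, r: float, T: float = DEFAULT_T) -> float:
    """Approximate minimum number of exact tandem copies that score positive.

    For a repeat with unit length r > k whose unit k-mers are all distinct
    and negligible f, the smallest copy number an S > 0 interval can reach
    is 3 + (k-1)/r + (3T - log 2 - log 3)/(log 4 - T); at the default
    T = 0.6 the r-independent part is ~3.01.  Natural logarithms.
    """
    if not (0.0 < T < math.log(4.0)):
        raise ParameterError(f"T must be in (0, log 4), got {T}")
    if not r > k:
        raise ParameterError(f"repeat unit length r={r} must exceed k={k}")
    return 3.0 + (k - 1) / r + (3.0 * T - math.log(2.0) - math.log(3.0)) / (math.log(4.0) - T)
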