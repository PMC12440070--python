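"""Deterministic synthetic DNA for tests and calibration.

Random GC-biased strings, tandem arrays with controlled unit length, copy
number and divergence, and host+insert composites.  All draws come from
numpy's PCG64 generator using integer variates only (thresholds on 32-bit
draws), so fixtures regenerate bit-identically across platforms.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import ParameterError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_SCALE = 1 << 32


@dataclass(frozen=True)
class RepeatSpec:
    """Parameters of a synthetic tandem repeat array.

    unit_length in bases; copies may be fractional (the array is truncated
    to floor(copies * unit_length) bases); divergence is the per-base
    substitution probability applied independently to every base of the
    array after tiling.
    """

    unit_length: int
    copies: float
    divergence: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.unit_length < 1:
            raise ParameterError(f"unit_length must be >= 1, got {self.unit_length}")
        if self.copies < 0:
            raise ParameterError(f"copies must be >= 0, got {self.copies}")
        if not (0.0 <= self.divergence <= 1.0):
            raise ParameterError(f"divergence must be in [0, 1], got {self.divergence}")


def _draw_codes(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    """i.i.d. base codes with P(G) = P(C) = gc/2 via integer thresholding."""
    if length == 0:
        return np.empty(0, dtype=np.uint8)
    at = (1.0 - gc) / 2.0
    g = gc / 2.0
    cuts = np.array(
        [round(at * _SCALE), round((at + g) * _SCALE), round((at + 2 * g) * _SCALE)],
        dtype=np.int64,
    )
    u = rng.integers(0, _SCALE, size=length, dtype=np.int64)
    return np.searchsorted(cuts, u, side="right").astype(np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def random_dna(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """A random DNA string with the given GC bias; deterministic in seed."""
    if length < 0:
        raise ParameterError(f"length must be >= 0, got {length}")
    if not (0.0 < gc < 1.0):
        raise ParameterError(f"gc must be in (0, 1), got {gc}")
    rng = np.random.default_rng(seed)
    return _codes_to_str(_draw_codes(rng, length, gc))


def tandem_array(spec: RepeatSpec, gc: float = 0.5) -> str:
    """A tandem repeat array: a random unit tiled and point-mutated.

    The unit is drawn once, tiled to floor(copies * unit_length) bases and
    every base substituted with probability ``spec.divergence`` (to one of
    the three other bases, uniformly).
    """
    if not (0.0 < gc < 1.0):
        raise ParameterError(f"gc must be in (0, 1), got {gc}")
    rng = np.random.default_rng(spec.seed)
    unit = _draw_codes(rng, spec.unit_length, gc)
    total = int(math.floor(spec.copies * spec.unit_length))
    if total == 0:
        return ""
    reps = -(-total // spec.unit_length)  # ceil
    arr = np.tile(unit, reps)[:total].copy()
    if spec.divergence > 0.0:
        thr = round(spec.divergence * _SCALE)
        u = rng.integers(0, _SCALE, size=total, dtype=np.int64)
        shift = rng.integers(1, 4, size=total, dtype=np.int64)
        mut = u < thr
        arr = np.where(mut, (arr.astype(np.int64) + shift) % 4, arr).astype(np.uint8)
    return _codes_to_str(arr)


def implant(host: str, insert: str, position: int) -> str:
    """Splice ``insert`` into ``host`` at ``position``."""
    if not (0 <= position <= len(host)):
        raise ParameterError(
            f"position {position} outside [0, {len(host)}]"
        )
    return host[:position] + insert + host[position:]
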