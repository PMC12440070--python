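"""FASTA input, BED and soft-masked FASTA output, GC estimation."""
from __future__ import annotations

import gzip
import io as _io
import logging
from typing import IO, Iterable, Iterator, List, Sequence, Tuple, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .engine import LCInterval
from .model import GC_EPS, ParameterError

logger = logging.getLogger("lodust")

_GZIP_MAGIC = b"\x1f\x8b"


class FastaParseError(ValueError):
    """Malformed FASTA input."""


def _open_text(source: Union[str, IO]) -> IO:
    """Open a path or stream as text, transparently decompressing gzip."""
    if hasattr(source, "read"):
        data = source.read()
        if isinstance(data, str):
            return _io.StringIO(data)
        if data[:2] == _GZIP_MAGIC:
            data = gzip.decompress(data)
        return _io.StringIO(data.decode("ascii"))
    with open(source, "rb") as fh:
        magic = fh.read(2)
    if magic == _GZIP_MAGIC:
        return gzip.open(source, "rt")
    return open(source, "rt")


def read_fasta(source: Union[str, IO]) -> Iterator[Tuple[str, str]]:
    """Yield (name, sequence) records in file order.

    The record name is the first whitespace-delimited header token and the
    sequence case is preserved (soft-masked input stays lowercase).
    Sequence data before the first header is a parse error.
    """
    handle = _open_text(source)
    try:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"line {lineno}: sequence data before the first '>' header"
                )
            break
        handle.seek(0)
        for name, seq in SimpleFastaParser(handle):
            yield name.split()[0] if name.split() else "", seq
    finally:
        handle.close()


def write_bed(
    intervals: Iterable[LCInterval],
    stream: IO,
    *,
    with_score: bool = False,
) -> None:
    """Write merged intervals as 3-column BED (0-based, half-open).

    Intervals are assumed sorted and merged per record; ``with_score``
    appends the detection score as a 4th column.
    """
    for iv in intervals:
        name, start, end = iv.to_bed()
        if with_score:
            stream.write(f"{name}\t{start}\t{end}\t{iv.score:.4f}\n")
        else:
            stream.write(f"{name}\t{start}\t{end}\n")


def mask_sequence(seq: str, intervals: Sequence[LCInterval]) -> str:
    """Soft-mask (lowercase) the bases of ``seq`` covered by ``intervals``."""
    chars = list(seq)
    for iv in intervals:
        for p in range(iv.start, min(iv.end + 1, len(chars))):
            chars[p] = chars[p].lower()
    return "".join(chars)


def write_masked_fasta(
    records: Sequence[Tuple[str, str]],
    intervals: Iterable[LCInterval],
    stream: IO,
    *,
    width: int = 60,
) -> None:
    """Write records with interval-covered bases lowercased, 60-col wrapped."""
    by_name: dict = {}
    for iv in intervals:
        by_name.setdefault(iv.name, []).append(iv)
    for name, seq in records:
        masked = mask_sequence(seq, by_name.get(name, []))
        stream.write(f">{name}\n")
        for i in range(0, len(masked), width):
            stream.write(masked[i : i + width] + "\n")


def estimate_gc(records: Iterable[Tuple[str, str]]) -> float:
    """Pooled GC fraction (#G + #C) / (#A + #C + #G + #T) over all records.

    Ambiguous bases are excluded; the estimate is clamped into
    [GC_EPS, 1 - GC_EPS] (with a warning) so the frequency model stays
    strictly positive even for single-letter genomes.
    """
    at = gc = 0
    for _, seq in records:
        s = seq.upper()
        at += s.count("A") + s.count("T")
        gc += s.count("G") + s.count("C")
    total = at + gc
    if total == 0:
        raise ParameterError(
            "no unambiguous A/C/G/T bases in the input; pass an explicit --gc"
        )
    frac = gc / total
    if frac < GC_EPS or frac > 1.0 - GC_EPS:
        logger.warning(
            "estimated GC %.3g is degenerate; clamping into (%g, %g)",
            frac, GC_EPS, 1.0 - GC_EPS,
        )
        frac = min(max(frac, GC_EPS), 1.0 - GC_EPS)
    return frac
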