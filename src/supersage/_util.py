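"""Small shared helpers: reverse complement, rounding and file opening."""

from __future__ import annotations

import gzip
import math
from pathlib import Path
from typing import IO

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def percent(numerator: float, denominator: float, decimals: int = 2,
            mode: str = "half_even") -> float:
    """Percentage of ``numerator`` over ``denominator``.

    ``mode`` selects how the printed figure is produced: ``half_even``
    (banker's rounding, the default used in all reports) or ``truncate``
    (drop digits beyond ``decimals`` without rounding). Returns NaN when
    the denominator is zero, so empty classes are reported as undefined
    rather than 0%.
    """
    if denominator == 0:
        return math.nan
    value = 100.0 * numerator / denominator
    if mode == "half_even":
        return round(value, decimals)
    if mode == "truncate":
        scale = 10 ** decimals
        return math.floor(value * scale) / scale
    raise ValueError(f"unknown rounding mode: {mode!r}")


def open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    """Open plain or gzip-compressed text transparently (by .gz suffix)."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest single-base run in ``seq`` (0 if empty)."""
    best = 0
    run = 0
    prev = ""
    for base in seq:
        if base == prev:
            run += 1
        else:
            run = 1
            prev = base
        if run > best:
            best = run
    return best
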