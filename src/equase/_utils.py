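"""Small shared helpers."""

from __future__ import annotations

import gzip
import io
import math
from decimal import ROUND_HALF_UP, Decimal
from typing import IO, Iterator, Union

PathOrStream = Union[str, "io.IOBase", IO[str]]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention of printed tables).

    Python's built-in round() is banker's rounding; summary percentages are
    instead quantized half-up on the decimal representation.
    """
    if not math.isfinite(x):
        return x
    exp = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(exp, rounding=ROUND_HALF_UP))


def open_text(source: PathOrStream) -> Iterator[str]:
    """Yield lines from a path (plain or .gz) or an already-open stream."""
    if hasattr(source, "read"):
        yield from source  # type: ignore[misc]
        return
    opener = gzip.open if str(source).endswith(".gz") else open
    with opener(source, "rt") as handle:  # type: ignore[arg-type]
        yield from handle
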