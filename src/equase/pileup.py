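"""Parsing of samtools-mpileup base columns into per-locus nucleotide tallies.

The base column grammar handled here is that of samtools >= 1.x without the
mapping-quality extensions: ``.``/``,`` reference matches, explicit calls in
either case, ``^X`` read starts (X is a mapping quality, consumed), ``$`` read
ends, ``+k<seq>``/``-k<seq>`` indel descriptors, ``*`` deletion placeholders,
``N``/``n`` ambiguous calls and ``>``/``<`` reference skips (counted apart,
excluded from nucleotide tallies — RNA-seq pileups carry them at splice
junctions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Dict, Iterable, Iterator, List, Union

from equase._utils import open_text

logger = logging.getLogger(__name__)

NUCLEOTIDES = ("A", "C", "G", "T")


class PileupParseError(ValueError):
    """Raised on a malformed mpileup line or base column."""


@dataclass
class LocusTally:
    """Per-nucleotide read counts observed at one genomic position.

    ``depth`` is the number of base-level calls (ACGT + N + deletion
    placeholders); reference skips are tracked in ``skip_count`` and are not
    part of ``depth``.
    """

    chrom: str
    pos: int
    ref: str
    counts: Dict[str, int] = field(default_factory=lambda: {b: 0 for b in NUCLEOTIDES})
    n_count: int = 0
    del_count: int = 0
    skip_count: int = 0

    @property
    def depth(self) -> int:
        return sum(self.counts.values()) + self.n_count + self.del_count

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for base in NUCLEOTIDES:
            self.counts.setdefault(base, 0)
        if any(v < 0 for v in self.counts.values()) or self.n_count < 0 or self.del_count < 0:
            raise ValueError("counts must be non-negative")

    def to_mpileup_line(self) -> str:
        """Serialize to a minimal single-sample mpileup line.

        Reference matches are emitted as ``.``/``,`` split between strands,
        mismatches as upper-case letters; a parse round-trip reproduces the
        tally (skips are appended as ``>``).
        """
        parts: List[str] = []
        for base in NUCLEOTIDES:
            n = self.counts[base]
            if base == self.ref.upper():
                parts.append("." * (n - n // 2) + "," * (n // 2))
            else:
                parts.append(base * n)
        if self.ref.upper() not in NUCLEOTIDES:
            n = self.n_count
            parts.append("." * (n - n // 2) + "," * (n // 2))
        else:
            parts.append("N" * self.n_count)
        parts.append("*" * self.del_count)
        parts.append(">" * self.skip_count)
        bases = "".join(parts) or "*"
        quals = "I" * max(self.depth + self.skip_count, 1)
        return f"{self.chrom}\t{self.pos}\t{self.ref}\t{self.depth + self.skip_count}\t{bases}\t{quals}"


def tally_bases(
    bases: str,
    ref: str,
    *,
    chrom: str = "?",
    pos: int = 0,
) -> LocusTally:
    """Walk one mpileup base column and count each nucleotide call.

    ``.``/``,`` are credited to ``ref``; case is folded (strand-insensitive);
    ``^`` consumes the following mapping-quality character; ``$`` is skipped;
    ``+k``/``-k`` indel runs consume k bases without counting them.
    """
    ref_up = ref.upper()
    counts = {b: 0 for b in NUCLEOTIDES}
    n_count = 0
    del_count = 0
    skip_count = 0
    i = 0
    length = len(bases)
    while i < length:
        c = bases[i]
        if c in ".,":
            if ref_up in counts:
                counts[ref_up] += 1
            else:
                n_count += 1
        elif c in "ACGTacgt":
            counts[c.upper()] += 1
        elif c in "Nn":
            n_count += 1
        elif c == "*":
            del_count += 1
        elif c in "><":
            skip_count += 1
        elif c == "^":
            i += 1  # the next char is a mapping quality, not a call
            if i >= length:
                raise PileupParseError(
                    f"{chrom}:{pos}: dangling '^' at end of base column"
                )
        elif c == "$":
            pass
        elif c in "+-":
            j = i + 1
            while j < length and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError(
                    f"{chrom}:{pos}: malformed indel, non-digit after '{c}'"
                )
            indel_len = int(bases[i + 1 : j])
            i = j + indel_len - 1
            if i >= length:
                raise PileupParseError(
                    f"{chrom}:{pos}: indel run of length {indel_len} overruns column"
                )
        else:
            raise PileupParseError(
                f"{chrom}:{pos}: unknown character {c!r} in base column"
            )
        i += 1
    return LocusTally(
        chrom=chrom,
        pos=max(pos, 1),
        ref=ref,
        counts=counts,
        n_count=n_count,
        del_count=del_count,
        skip_count=skip_count,
    )


def parse_mpileup(source: Union[str, IO[str], Iterable[str]]) -> Iterator[LocusTally]:
    """Parse single-sample mpileup text into LocusTally values, in input order.

    ``source`` may be a path (plain or gzip) or an iterable of lines. If the
    reported depth column disagrees with the parsed calls, the mismatch is
    logged and the parsed total wins.
    """
    for lineno, line in enumerate(open_text(source), start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise PileupParseError(
                f"line {lineno}: expected >= 6 tab-separated columns, got {len(fields)}"
            )
        chrom, pos_s, ref, depth_s, bases = fields[0], fields[1], fields[2], fields[3], fields[4]
        try:
            pos = int(pos_s)
        except ValueError as exc:
            raise PileupParseError(f"line {lineno}: non-integer position {pos_s!r}") from exc
        try:
            reported_depth = int(depth_s)
        except ValueError as exc:
            raise PileupParseError(f"line {lineno}: non-integer depth {depth_s!r}") from exc
        if reported_depth == 0 and bases in ("*", ""):
            yield LocusTally(chrom=chrom, pos=pos, ref=ref)
            continue
        tally = tally_bases(bases, ref, chrom=chrom, pos=pos)
        parsed_total = tally.depth + tally.skip_count
        if parsed_total != reported_depth:
            logger.warning(
                "%s:%d (line %d): reported depth %d != parsed calls %d; trusting parsed",
                chrom,
                pos,
                lineno,
                reported_depth,
                parsed_total,
            )
        yield tally


def write_tally_table(tallies: Iterable[LocusTally], handle: IO[str]) -> None:
    """Write a tab-delimited per-locus tally table."""
    handle.write("chrom\tpos\tref\tA\tC\tG\tT\tN\tdel\tdepth\n")
    for t in tallies:
        handle.write(
            f"{t.chrom}\t{t.pos}\t{t.ref}\t"
            + "\t".join(str(t.counts[b]) for b in NUCLEOTIDES)
            + f"\t{t.n_count}\t{t.del_count}\t{t.depth}\n"
        )
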