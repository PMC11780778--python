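"""Variant-consequence filtering and histone-mark interval overlap.

Consequence terms come from VEP tab-delimited output (one row per
variant/feature pair; rows for one locus are merged by union of terms).
Peaks come from BED records, converted from 0-based half-open to the
pipeline's 1-based closed coordinates on read.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Dict, FrozenSet, Iterable, List, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from equase._utils import open_text, round_half_up
from equase.haplotypes import Haplotype

logger = logging.getLogger(__name__)

HISTONE_MARKS = ("H3K27ac", "H3K4me1", "H3K4me3", "H3K27me3")

# Terms that, when they exhaust a locus's annotation, exclude it.
NONINFORMATIVE_TERMS = frozenset({"intron_variant", "intergenic_variant"})

KNOWN_TERMS = frozenset(
    {
        "3_prime_UTR_variant",
        "5_prime_UTR_variant",
        "missense_variant",
        "synonymous_variant",
        "stop_gained",
        "stop_lost",
        "stop_retained_variant",
        "start_lost",
        "splice_region_variant",
        "splice_donor_variant",
        "splice_acceptor_variant",
        "splice_donor_region_variant",
        "splice_polypyrimidine_tract_variant",
        "non_coding_transcript_exon_variant",
        "non_coding_transcript_variant",
        "coding_sequence_variant",
        "frameshift_variant",
        "inframe_insertion",
        "inframe_deletion",
        "upstream_gene_variant",
        "downstream_gene_variant",
        "intron_variant",
        "intergenic_variant",
    }
)


@dataclass(frozen=True)
class ConsequenceRecord:
    """Merged VEP annotation for one locus."""

    chrom: str
    pos: int
    gene_id: str
    gene_symbol: str
    consequence_terms: FrozenSet[str]

    def __post_init__(self) -> None:
        if not self.consequence_terms:
            raise ValueError(f"{self.chrom}:{self.pos}: empty consequence set")


@dataclass(frozen=True)
class PeakInterval:
    """One histone-mark interval, stored 1-based closed."""

    chrom: str
    start: int
    end: int
    mark: str
    tissue: str
    sample: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"peak end {self.end} < start {self.start}")
        if self.mark not in HISTONE_MARKS:
            raise ValueError(f"unknown histone mark {self.mark!r}")


def split_terms(raw: str) -> Set[str]:
    """Split a VEP consequence string on ',' and '&' into atomic terms."""
    terms = set()
    for chunk in raw.replace("&", ",").split(","):
        chunk = chunk.strip()
        if chunk:
            terms.add(chunk)
    return terms


def read_vep_table(source: Union[str, IO[str]]) -> List[ConsequenceRecord]:
    """Read VEP tab-delimited output, merging rows per locus by term union.

    Requires columns Location (chrom:pos), Gene and Consequence; SYMBOL is
    used for the gene symbol when present.
    """
    df = pd.read_csv(source, sep="\t", dtype=str, comment=None)
    df.columns = [c.lstrip("#") for c in df.columns]
    required = {"Location", "Gene", "Consequence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"VEP table missing columns: {sorted(missing)}")
    merged: Dict[Tuple[str, int], Dict[str, object]] = {}
    for row in df.itertuples(index=False):
        loc = str(getattr(row, "Location"))
        chrom, _, pos_s = loc.partition(":")
        pos = int(pos_s.split("-")[0])
        key = (chrom, pos)
        entry = merged.setdefault(
            key,
            {"gene": "", "symbol": "", "terms": set()},
        )
        gene = str(getattr(row, "Gene", "") or "")
        if gene and gene != "-":
            entry["gene"] = gene
        symbol = str(getattr(row, "SYMBOL", "") or "") if hasattr(row, "SYMBOL") else ""
        if symbol and symbol != "-":
            entry["symbol"] = symbol
        entry["terms"] |= split_terms(str(getattr(row, "Consequence")))  # type: ignore[operator]
    return [
        ConsequenceRecord(
            chrom=chrom,
            pos=pos,
            gene_id=str(entry["gene"]),
            gene_symbol=str(entry["symbol"]),
            consequence_terms=frozenset(entry["terms"]),  # type: ignore[arg-type]
        )
        for (chrom, pos), entry in merged.items()
    ]


def filter_consequences(
    records: Iterable[ConsequenceRecord],
) -> Tuple[List[ConsequenceRecord], List[ConsequenceRecord]]:
    """Partition loci into (kept, removed).

    A locus is removed iff every one of its terms is intronic/intergenic;
    any other functional class rescues it. Unknown terms warn and count as
    functional (the locus is kept).
    """
    kept: List[ConsequenceRecord] = []
    removed: List[ConsequenceRecord] = []
    for rec in records:
        unknown = rec.consequence_terms - KNOWN_TERMS
        if unknown:
            logger.warning(
                "%s:%d: unknown consequence term(s) %s, treating as functional",
                rec.chrom,
                rec.pos,
                sorted(unknown),
            )
        if rec.consequence_terms <= NONINFORMATIVE_TERMS:
            removed.append(rec)
        else:
            kept.append(rec)
    return kept, removed


def consequence_type_summary(records: Sequence[ConsequenceRecord]) -> pd.DataFrame:
    """Count loci per sorted, ampersand-joined term combination.

    Percent is of all supplied loci, half-up to 2 decimals, descending by
    count.
    """
    combos = Counter(
        "&".join(sorted(rec.consequence_terms)) for rec in records
    )
    total = sum(combos.values())
    rows = [
        {
            "consequence_combination": combo,
            "count": count,
            "percent": round_half_up(100.0 * count / total, 2),
        }
        for combo, count in sorted(combos.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["consequence_combination", "count", "percent"])


def haplotype_region(hap: Haplotype) -> Tuple[str, int, int]:
    """Interval spanning the first to last heterozygous position (inclusive)."""
    positions = [locus.pos for locus in hap.loci]
    return hap.chrom, min(positions), max(positions)


class PeakIndex:
    """Peaks grouped by (chrom, tissue, sample, mark) for interval queries."""

    def __init__(self, peaks: Iterable[PeakInterval] = ()) -> None:
        self._groups: Dict[Tuple[str, str, str, str], List[Tuple[int, int]]] = {}
        self._arrays: Dict[Tuple[str, str, str, str], Tuple[np.ndarray, np.ndarray]] | None = None
        for peak in peaks:
            self.add(peak)

    def add(self, peak: PeakInterval) -> None:
        key = (peak.chrom, peak.tissue, peak.sample, peak.mark)
        self._groups.setdefault(key, []).append((peak.start, peak.end))
        self._arrays = None

    def __len__(self) -> int:
        return sum(len(v) for v in self._groups.values())

    def _built(self) -> Dict[Tuple[str, str, str, str], Tuple[np.ndarray, np.ndarray]]:
        if self._arrays is None:
            self._arrays = {
                key: (
                    np.asarray([s for s, _ in ivs], dtype=np.int64),
                    np.asarray([e for _, e in ivs], dtype=np.int64),
                )
                for key, ivs in self._groups.items()
            }
        return self._arrays

    def query(
        self, chrom: str, start: int, end: int, tissue: str, sample: str
    ) -> Set[str]:
        """Marks with >= 1 bp closed-interval overlap for this tissue/sample."""
        arrays = self._built()
        hits: Set[str] = set()
        for mark in HISTONE_MARKS:
            group = arrays.get((chrom, tissue, sample, mark))
            if group is None:
                continue
            starts, ends = group
            if bool(np.any((starts <= end) & (ends >= start))):
                hits.add(mark)
        return hits


def read_peak_bed(
    source: Union[str, IO[str]],
    *,
    mark: str | None = None,
    tissue: str | None = None,
    sample: str | None = None,
) -> List[PeakInterval]:
    """Read BED3+ peaks, converting to 1-based closed coordinates.

    With a plain BED3, ``mark``/``tissue``/``sample`` must be supplied;
    otherwise columns 4-6 carry mark, tissue and sample labels.
    """
    peaks: List[PeakInterval] = []
    for lineno, line in enumerate(open_text(source), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"BED line {lineno}: fewer than 3 columns")
        chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
        row_mark = fields[3] if len(fields) > 3 else mark
        row_tissue = fields[4] if len(fields) > 4 else tissue
        row_sample = fields[5] if len(fields) > 5 else sample
        if row_mark is None or row_tissue is None or row_sample is None:
            raise ValueError(
                f"BED line {lineno}: mark/tissue/sample labels missing "
                "(supply them as columns 4-6 or as reader arguments)"
            )
        peaks.append(
            PeakInterval(
                chrom=chrom,
                start=start0 + 1,  # BED is 0-based half-open
                end=end0,
                mark=row_mark,
                tissue=row_tissue,
                sample=row_sample,
            )
        )
    return peaks


def overlap_marks(
    region: Tuple[str, int, int],
    peaks: PeakIndex,
    tissue: str,
    sample: str,
) -> Set[str]:
    """Histone marks whose same-tissue/sample peaks intersect the region."""
    chrom, start, end = region
    return peaks.query(chrom, start, end, tissue, sample)


@dataclass
class MarkSummary:
    """Counts derived from per-locus mark sets (upset-plot style)."""

    n_total: int
    per_mark: Dict[str, int]
    n_with_any: int
    n_multi: int
    pct_with_any: float
    pct_multi_of_with: float
    exclusive_combinations: Dict[FrozenSet[str], int] = field(default_factory=dict)


def mark_combination_summary(mark_sets: Sequence[Set[str]]) -> MarkSummary:
    """Summarize mark membership across loci.

    ``pct_with_any`` is the with->=1-mark share of all loci;
    ``pct_multi_of_with`` is the >=2-mark share of the with-mark loci. Both
    half-up to 1 decimal. Exclusive-combination counts partition the
    with-mark loci.
    """
    n_total = len(mark_sets)
    per_mark = {mark: 0 for mark in HISTONE_MARKS}
    combos: Counter = Counter()
    n_with_any = 0
    n_multi = 0
    for marks in mark_sets:
        for mark in marks:
            per_mark[mark] += 1
        if marks:
            n_with_any += 1
            combos[frozenset(marks)] += 1
            if len(marks) >= 2:
                n_multi += 1
    pct_any = round_half_up(100.0 * n_with_any / n_total, 1) if n_total else float("nan")
    pct_multi = round_half_up(100.0 * n_multi / n_with_any, 1) if n_with_any else float("nan")
    return MarkSummary(
        n_total=n_total,
        per_mark=per_mark,
        n_with_any=n_with_any,
        n_multi=n_multi,
        pct_with_any=pct_any,
        pct_multi_of_with=pct_multi,
        exclusive_combinations=dict(combos),
    )
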