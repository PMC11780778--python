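"""Phased haplotype blocks and per-haplotype allele expression aggregation.

A haplotype block is an ordered set of heterozygous loci on one chromosome
with the nucleotide each chromosome copy carries. Per-locus nucleotide
tallies are summed according to the haplotype sequence to give the two
allele expression values that are compared downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Dict, Iterable, List, Mapping, Tuple, Union

import pandas as pd

from equase.pileup import NUCLEOTIDES, LocusTally

logger = logging.getLogger(__name__)

HAPLOTYPE_COLUMNS = [
    "sample",
    "tissue",
    "haplotype_block_id",
    "chrom",
    "pos",
    "allele_h1",
    "allele_h2",
]

_SEX_CHROMS = {"X", "Y", "CHRX", "CHRY"}


class HaplotypeTableError(ValueError):
    """Raised when a phased-loci table violates the haplotype contract."""


@dataclass(frozen=True)
class HetLocus:
    """A phased heterozygous position with its two haplotype nucleotides."""

    chrom: str
    pos: int
    allele_h1: str
    allele_h2: str

    def __post_init__(self) -> None:
        if self.allele_h1 == self.allele_h2:
            raise HaplotypeTableError(
                f"{self.chrom}:{self.pos}: alleles are identical ({self.allele_h1}), not heterozygous"
            )
        for allele in (self.allele_h1, self.allele_h2):
            if allele not in NUCLEOTIDES:
                raise HaplotypeTableError(
                    f"{self.chrom}:{self.pos}: allele {allele!r} not one of A/C/G/T"
                )


@dataclass
class Haplotype:
    """One phased block: sample/tissue context plus its ordered het loci."""

    sample_id: str
    tissue: str
    block_id: str
    loci: Tuple[HetLocus, ...]
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not self.loci:
            raise HaplotypeTableError(f"block {self.block_id}: no loci")
        chroms = {locus.chrom for locus in self.loci}
        if len(chroms) > 1:
            raise HaplotypeTableError(
                f"block {self.block_id}: loci span multiple chromosomes {sorted(chroms)}"
            )
        self.loci = tuple(sorted(self.loci, key=lambda l: l.pos))
        positions = [l.pos for l in self.loci]
        if len(set(positions)) != len(positions):
            raise HaplotypeTableError(f"block {self.block_id}: duplicate positions")

    @property
    def chrom(self) -> str:
        return self.loci[0].chrom


@dataclass
class AlleleExpression:
    """Summed haplotype-level expression values for one comparison.

    ``other_count`` tracks reads matching neither phased allele (kept for QC,
    excluded from both expression values).
    """

    haplotype: Haplotype
    expr_h1: int
    expr_h2: int
    n_loci_observed: int
    other_count: int = 0

    def __post_init__(self) -> None:
        if self.expr_h1 < 0 or self.expr_h2 < 0:
            raise ValueError("expression values must be non-negative")
        if self.n_loci_observed > len(self.haplotype.loci):
            raise ValueError("n_loci_observed exceeds number of loci in haplotype")


def _is_sex_chrom(chrom: str) -> bool:
    return chrom.upper() in _SEX_CHROMS


def read_haplotype_table(
    source: Union[str, IO[str]],
    *,
    keep_sex_chromosomes: bool = False,
) -> List[Haplotype]:
    """Read a tab-delimited phased-loci table into Haplotype blocks.

    Rows are grouped by (sample, tissue, haplotype_block_id); loci within a
    block are sorted by position. Blocks on sex chromosomes are dropped by
    default, mirroring the autosomal focus of the analysis.
    """
    df = pd.read_csv(source, sep="\t", dtype=str)
    missing = [c for c in HAPLOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise HaplotypeTableError(f"haplotype table missing columns: {missing}")
    df["pos"] = df["pos"].astype(int)

    haplotypes: List[Haplotype] = []
    n_sex_dropped = 0
    for (sample, tissue, block), grp in df.groupby(
        ["sample", "tissue", "haplotype_block_id"], sort=False
    ):
        loci = tuple(
            HetLocus(row.chrom, row.pos, row.allele_h1, row.allele_h2)
            for row in grp.itertuples(index=False)
        )
        hap = Haplotype(sample_id=sample, tissue=tissue, block_id=block, loci=loci)
        if not keep_sex_chromosomes and _is_sex_chrom(hap.chrom):
            n_sex_dropped += 1
            continue
        haplotypes.append(hap)
    if n_sex_dropped:
        logger.info("dropped %d haplotype block(s) on sex chromosomes", n_sex_dropped)
    return haplotypes


def aggregate_allele_expression(
    hap: Haplotype,
    tallies: Mapping[Tuple[str, int], LocusTally],
) -> AlleleExpression:
    """Sum per-locus nucleotide counts into the two haplotype expression values.

    Loci absent from ``tallies`` contribute nothing and are excluded from
    ``n_loci_observed``; reads matching neither phased allele go to
    ``other_count``.
    """
    expr_h1 = 0
    expr_h2 = 0
    other = 0
    n_observed = 0
    for locus in hap.loci:
        tally = tallies.get((locus.chrom, locus.pos))
        if tally is None:
            continue
        n_observed += 1
        expr_h1 += tally.counts.get(locus.allele_h1, 0)
        expr_h2 += tally.counts.get(locus.allele_h2, 0)
        other += sum(
            count
            for base, count in tally.counts.items()
            if base not in (locus.allele_h1, locus.allele_h2)
        )
    return AlleleExpression(
        haplotype=hap,
        expr_h1=expr_h1,
        expr_h2=expr_h2,
        n_loci_observed=n_observed,
        other_count=other,
    )


def tally_lookup(tallies: Iterable[LocusTally]) -> Dict[Tuple[str, int], LocusTally]:
    """Index tallies by (chrom, pos) for aggregation."""
    return {(t.chrom, t.pos): t for t in tallies}


def allele_expression_frame(expressions: Iterable[AlleleExpression]) -> pd.DataFrame:
    """Tabulate per-comparison allele expression values."""
    rows = [
        {
            "sample": ae.haplotype.sample_id,
            "tissue": ae.haplotype.tissue,
            "block": ae.haplotype.block_id,
            "expr_h1": ae.expr_h1,
            "expr_h2": ae.expr_h2,
            "n_loci_observed": ae.n_loci_observed,
            "other_count": ae.other_count,
        }
        for ae in expressions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample",
            "tissue",
            "block",
            "expr_h1",
            "expr_h2",
            "n_loci_observed",
            "other_count",
        ],
    )
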