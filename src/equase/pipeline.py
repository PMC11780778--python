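"""End-to-end orchestration: discovery and validation runs with manifests.

A run manifest records input checksums, the config snapshot, per-stage
timings and the filter-chain counts (comparisons formed >= surviving
coverage >= significant), so any stage can be reproduced from it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd

from equase import __version__
from equase.annotation import (
    HISTONE_MARKS,
    PeakIndex,
    filter_consequences,
    haplotype_region,
    overlap_marks,
    read_peak_bed,
    read_vep_table,
)
from equase.haplotypes import aggregate_allele_expression, read_haplotype_table, tally_lookup
from equase.pileup import parse_mpileup
from equase.stats import SignificanceConfig, call_ase, results_frame, tissue_summary
from equase.validation import (
    DiscoveryCall,
    comparisons_frame,
    concordance_summary,
    replicate_ase,
)

logger = logging.getLogger(__name__)


class ConfigurationError(RuntimeError):
    """Raised before any computation when required inputs are missing."""


@dataclass
class DiscoveryConfig:
    haplotypes: str
    out_dir: str
    pileup: Optional[str] = None  # single file shared by all sample x tissue
    pileup_dir: Optional[str] = None  # expects <sample>.<tissue>.mpileup
    peaks: Optional[str] = None
    vep: Optional[str] = None
    keep_sex_chromosomes: bool = False
    significance: SignificanceConfig = field(default_factory=SignificanceConfig)


@dataclass
class ValidationConfig:
    discovery_loci: str
    sample_sheet: str  # TSV: sample_id, group, mpileup
    out_dir: str
    min_minor: int = 2
    significance: SignificanceConfig = field(default_factory=SignificanceConfig)


def _sha256(path: str) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _require(path: Optional[str], what: str) -> str:
    if path is None:
        raise ConfigurationError(f"missing required input: {what}")
    if not Path(path).exists():
        raise ConfigurationError(f"{what} not found: {path}")
    return path


def _write_manifest(out_dir: Path, manifest: Dict) -> Path:
    path = out_dir / "manifest.json"
    with open(path, "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True, default=str)
        handle.write("\n")
    return path


def run_discovery(cfg: DiscoveryConfig) -> Dict:
    """Execute pileup counting -> aggregation -> calling -> annotation.

    Writes the master resource table, per-tissue subsets, the significant
    discovery-loci table (validation input), the removed-loci sidecar when
    consequences are supplied, and the manifest. Returns the manifest dict.
    """
    _require(cfg.haplotypes, "haplotype table")
    if cfg.pileup is None and cfg.pileup_dir is None:
        raise ConfigurationError("missing required input: pileup (file or directory)")
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest: Dict = {
        "tool_version": __version__,
        "run_type": "discovery",
        "config": {
            "haplotypes": cfg.haplotypes,
            "pileup": cfg.pileup,
            "pileup_dir": cfg.pileup_dir,
            "peaks": cfg.peaks,
            "vep": cfg.vep,
            "keep_sex_chromosomes": cfg.keep_sex_chromosomes,
            "significance": asdict(cfg.significance),
        },
        "inputs": {},
        "counts": {},
        "timings_s": {},
        "failed_stage": None,
    }
    for label, path in (("haplotypes", cfg.haplotypes), ("peaks", cfg.peaks), ("vep", cfg.vep)):
        if path:
            manifest["inputs"][label] = {"path": path, "sha256": _sha256(path)}

    stage = "read_haplotypes"
    try:
        t0 = time.monotonic()
        haplotypes = read_haplotype_table(
            cfg.haplotypes, keep_sex_chromosomes=cfg.keep_sex_chromosomes
        )
        manifest["counts"]["blocks_read"] = len(haplotypes)
        manifest["counts"]["loci_read"] = sum(len(h.loci) for h in haplotypes)
        manifest["timings_s"][stage] = round(time.monotonic() - t0, 3)

        stage = "pileup_counting"
        t0 = time.monotonic()
        lookups: Dict[Tuple[str, str], Dict] = {}
        pairs = sorted({(h.sample_id, h.tissue) for h in haplotypes})
        if cfg.pileup is not None:
            shared = tally_lookup(parse_mpileup(_require(cfg.pileup, "pileup")))
            for pair in pairs:
                lookups[pair] = shared
        else:
            for sample, tissue in pairs:
                path = Path(cfg.pileup_dir) / f"{sample}.{tissue}.mpileup"
                lookups[(sample, tissue)] = tally_lookup(
                    parse_mpileup(_require(str(path), f"pileup for {sample}/{tissue}"))
                )
        manifest["timings_s"][stage] = round(time.monotonic() - t0, 3)

        stage = "aggregate"
        t0 = time.monotonic()
        comparisons = [
            aggregate_allele_expression(h, lookups[(h.sample_id, h.tissue)])
            for h in haplotypes
        ]
        manifest["counts"]["comparisons_formed"] = len(comparisons)
        manifest["timings_s"][stage] = round(time.monotonic() - t0, 3)

        stage = "call_ase"
        t0 = time.monotonic()
        results = call_ase(comparisons, cfg.significance)
        manifest["counts"]["comparisons_surviving_coverage"] = len(results)
        manifest["counts"]["significant_calls"] = sum(r.significant for r in results)
        manifest["timings_s"][stage] = round(time.monotonic() - t0, 3)

        stage = "annotate"
        t0 = time.monotonic()
        resource = results_frame(results)
        if cfg.vep:
            records = read_vep_table(cfg.vep)
            kept, removed = filter_consequences(records)
            by_locus = {(r.chrom, r.pos): r for r in kept}
            genes, combos = [], []
            for res in results:
                hap = res.comparison.haplotype
                terms: set = set()
                gene = ""
                for locus in hap.loci:
                    rec = by_locus.get((locus.chrom, locus.pos))
                    if rec is None:
                        continue
                    terms |= rec.consequence_terms
                    gene = gene or rec.gene_id
                genes.append(gene)
                combos.append("&".join(sorted(terms)))
            resource["gene"] = genes
            resource["consequence_combination"] = combos
            removed_df = pd.DataFrame(
                [
                    {
                        "chrom": r.chrom,
                        "pos": r.pos,
                        "gene": r.gene_id,
                        "consequence_combination": "&".join(sorted(r.consequence_terms)),
                    }
                    for r in removed
                ],
                columns=["chrom", "pos", "gene", "consequence_combination"],
            )
            removed_df.to_csv(
                out_dir / "removed_loci.tsv", sep="\t", index=False, lineterminator="\n"
            )
            manifest["counts"]["loci_removed_intronic_intergenic"] = len(removed)
        if cfg.peaks:
            index = PeakIndex(read_peak_bed(cfg.peaks))
            mark_flags = {mark: [] for mark in HISTONE_MARKS}
            for res in results:
                hap = res.comparison.haplotype
                marks = overlap_marks(
                    haplotype_region(hap), index, hap.tissue, hap.sample_id
                )
                for mark in HISTONE_MARKS:
                    mark_flags[mark].append(mark in marks)
            for mark in HISTONE_MARKS:
                resource[mark] = mark_flags[mark]
        manifest["timings_s"][stage] = round(time.monotonic() - t0, 3)

        stage = "write_outputs"
        t0 = time.monotonic()
        resource.to_csv(
            out_dir / "resource.tsv", sep="\t", index=False, lineterminator="\n"
        )
        for tissue, sub in resource.groupby("tissue", sort=True):
            sub.to_csv(
                out_dir / f"resource.{tissue}.tsv",
                sep="\t",
                index=False,
                lineterminator="\n",
            )
        tissue_summary(results).to_csv(
            out_dir / "tissue_summary.tsv", sep="\t", index=False, lineterminator="\n"
        )
        _write_discovery_loci(results, out_dir / "discovery_loci.tsv")
        manifest["timings_s"][stage] = round(time.monotonic() - t0, 3)
    except ConfigurationError:
        raise
    except Exception:
        manifest["failed_stage"] = stage
        _write_manifest(out_dir, manifest)
        raise

    _write_manifest(out_dir, manifest)
    return manifest


def _write_discovery_loci(results, path: Path) -> None:
    """Per-locus favored/other alleles for significant calls (validation input)."""
    rows: Dict[Tuple[str, int], Dict] = {}
    for res in results:
        if not res.significant or res.favored == "none":
            continue
        hap = res.comparison.haplotype
        for locus in hap.loci:
            fav = locus.allele_h1 if res.favored == "h1" else locus.allele_h2
            oth = locus.allele_h2 if res.favored == "h1" else locus.allele_h1
            rows.setdefault(
                (locus.chrom, locus.pos),
                {
                    "chrom": locus.chrom,
                    "pos": locus.pos,
                    "allele_favored": fav,
                    "allele_other": oth,
                    "block": hap.block_id,
                    "sample": hap.sample_id,
                    "tissue": hap.tissue,
                },
            )
    df = pd.DataFrame(
        sorted(rows.values(), key=lambda r: (r["chrom"], r["pos"])),
        columns=["chrom", "pos", "allele_favored", "allele_other", "block", "sample", "tissue"],
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_discovery_loci(path: str) -> List[DiscoveryCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "allele_favored", "allele_other"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(
            f"discovery loci table missing columns: {sorted(missing)}"
        )
    return [
        DiscoveryCall(row.chrom, int(row.pos), row.allele_favored, row.allele_other)
        for row in df.itertuples(index=False)
    ]


def run_validation(cfg: ValidationConfig) -> Dict:
    """Replicate discovery loci across a validation cohort.

    The sample sheet is a TSV with columns sample_id, group and mpileup (path
    to that sample's pileup restricted to the discovery loci).
    """
    _require(cfg.discovery_loci, "discovery loci table")
    _require(cfg.sample_sheet, "sample sheet")
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest: Dict = {
        "tool_version": __version__,
        "run_type": "validation",
        "config": {
            "discovery_loci": cfg.discovery_loci,
            "sample_sheet": cfg.sample_sheet,
            "min_minor": cfg.min_minor,
            "significance": asdict(cfg.significance),
        },
        "inputs": {
            "discovery_loci": {"path": cfg.discovery_loci, "sha256": _sha256(cfg.discovery_loci)},
            "sample_sheet": {"path": cfg.sample_sheet, "sha256": _sha256(cfg.sample_sheet)},
        },
        "counts": {},
        "timings_s": {},
        "failed_stage": None,
    }

    discovery = read_discovery_loci(cfg.discovery_loci)
    sheet = pd.read_csv(cfg.sample_sheet, sep="\t", dtype=str)
    for col in ("sample_id", "mpileup"):
        if col not in sheet.columns:
            raise ConfigurationError(f"sample sheet missing column: {col}")
    if sheet.empty:
        logger.warning("empty validation sample sheet; writing empty outputs")
    tallies = {}
    groups = {}
    for row in sheet.itertuples(index=False):
        path = row.mpileup
        if not Path(path).exists():
            raise ConfigurationError(
                f"mpileup for sample {row.sample_id} not found: {path}"
            )
        tallies[row.sample_id] = tally_lookup(parse_mpileup(path))
        groups[row.sample_id] = getattr(row, "group", "") or ""

    t0 = time.monotonic()
    comparisons = replicate_ase(
        tallies, discovery, groups, cfg.significance, cfg.min_minor
    )
    manifest["counts"]["discovery_loci"] = len(discovery)
    manifest["counts"]["samples"] = len(tallies)
    manifest["counts"]["comparisons"] = len(comparisons)
    manifest["counts"]["significant"] = sum(c.significant for c in comparisons)
    manifest["timings_s"]["replicate"] = round(time.monotonic() - t0, 3)

    frame = comparisons_frame(comparisons)
    frame.to_csv(
        out_dir / "validation_comparisons.tsv", sep="\t", index=False, lineterminator="\n"
    )
    summary = concordance_summary(comparisons)
    summary_rows = {
        "n_comparisons": summary.n_comparisons,
        "n_significant": summary.n_significant,
        "pct_significant": summary.pct_significant,
        "n_direction_match": summary.n_direction_match,
        "pct_direction_match": summary.pct_direction_match,
        "n_loci": summary.n_loci,
        "n_loci_any_replication": summary.n_loci_any_replication,
        "pct_loci_any_replication": summary.pct_loci_any_replication,
        "n_loci_ge90": summary.n_loci_ge90,
        "pct_loci_ge90": summary.pct_loci_ge90,
    }
    pd.DataFrame([summary_rows]).to_csv(
        out_dir / "concordance_summary.tsv", sep="\t", index=False, lineterminator="\n"
    )
    with open(out_dir / "concordance_summary.txt", "w") as handle:
        for key, value in summary_rows.items():
            handle.write(f"{key}\t{value}\n")
    if summary.per_locus is not None:
        summary.per_locus.to_csv(
            out_dir / "per_locus_replication.tsv", sep="\t", index=False, lineterminator="\n"
        )
    _write_manifest(out_dir, manifest)
    return manifest
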