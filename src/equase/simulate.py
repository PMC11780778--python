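"""Synthetic cohorts with the statistical structure the caller assumes.

Generates phased two-haplotype genes (1-20 het loci), negative-binomial
per-locus depth, binomial allele sampling with a configurable haplotype
effect and per-read miscall rate, randomly placed histone peaks and
VEP-style consequence rows — all emitted in the exact text formats the
pipeline reads, alongside ground-truth labels.

Read-level detail is abstracted away: mpileup base columns are synthesized
directly from counts, since the pipeline never sees alignments. One RNG
stream per (sample, tissue) is derived from the master seed by stable
hashing, so adding samples never perturbs existing ones.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from equase.annotation import HISTONE_MARKS
from equase.pileup import NUCLEOTIDES, LocusTally

_FUNCTIONAL_TERMS = (
    "3_prime_UTR_variant",
    "missense_variant",
    "synonymous_variant",
    "5_prime_UTR_variant",
)


@dataclass
class SimulationConfig:
    """Knobs for cohort generation; ``seed`` is mandatory."""

    seed: int
    n_genes: int = 50
    loci_per_gene_mean: float = 3.0
    loci_per_gene_max: int = 20
    depth_mean: float = 100.0
    depth_dispersion: float = 10.0
    prop_ase: float = 0.0
    effect: float = 0.8
    error_rate: float = 0.0
    n_samples: int = 2
    tissues: Tuple[str, ...] = ("liver", "heart")
    n_chroms: int = 2
    peak_overlap_fraction: float = 0.5
    prop_intronic: float = 0.0
    beta_binomial_rho: float = 0.0  # >0 adds allele-fraction overdispersion

    def __post_init__(self) -> None:
        self.tissues = tuple(self.tissues)
        if not 0.0 <= self.prop_ase <= 1.0:
            raise ValueError("prop_ase must be in [0, 1]")
        if not 0.5 < self.effect < 1.0:
            raise ValueError("effect must be in (0.5, 1)")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth label for one simulated gene/block."""

    gene_id: str
    block_id: str
    chrom: str
    is_ase: bool
    true_fraction: float
    favored: str  # "h1" | "h2"

    def __post_init__(self) -> None:
        if self.is_ase != (self.true_fraction != 0.5):
            raise ValueError("is_ase must mirror true_fraction != 0.5")


def _stream(seed: int, label: str) -> np.random.Generator:
    """Independent, stable RNG stream for one labelled purpose."""
    digest = hashlib.sha256(f"{seed}|{label}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:16], "little"))


def simulate_locus_counts(
    depth_mean: float,
    depth_dispersion: float,
    allele_fraction: float,
    error_rate: float,
    rng: np.random.Generator,
    *,
    chrom: str = "chr1",
    pos: int = 1,
    allele1: str = "A",
    allele2: str = "G",
    beta_binomial_rho: float = 0.0,
) -> LocusTally:
    """Draw one locus tally: NB depth, binomial allele split, uniform miscalls.

    ``allele_fraction`` is the probability a read carries ``allele1``. Each
    read is independently miscalled with probability ``error_rate`` to one of
    the three other bases uniformly. Depth is truncated at 1 so every locus
    appears in the pileup.
    """
    if not 0.0 < allele_fraction < 1.0:
        raise ValueError("allele_fraction must be in (0, 1)")
    p_nb = depth_dispersion / (depth_dispersion + depth_mean)
    depth = max(1, int(rng.negative_binomial(depth_dispersion, p_nb)))
    frac = allele_fraction
    if beta_binomial_rho > 0.0:
        # mean-preserving beta prior with intraclass correlation rho
        conc = (1.0 - beta_binomial_rho) / beta_binomial_rho
        frac = float(rng.beta(allele_fraction * conc, (1.0 - allele_fraction) * conc))
        frac = min(max(frac, 1e-9), 1.0 - 1e-9)
    k1 = int(rng.binomial(depth, frac))
    k2 = depth - k1
    counts = {b: 0 for b in NUCLEOTIDES}
    for allele, k in ((allele1, k1), (allele2, k2)):
        n_err = int(rng.binomial(k, error_rate)) if error_rate > 0 else 0
        counts[allele] += k - n_err
        if n_err:
            others = [b for b in NUCLEOTIDES if b != allele]
            for base, extra in zip(others, rng.multinomial(n_err, [1 / 3] * 3)):
                counts[base] += int(extra)
    return LocusTally(chrom=chrom, pos=pos, ref=allele1, counts=counts)


@dataclass
class SimulatedCohort:
    """In-memory cohort: input tables plus ground truth."""

    config: SimulationConfig
    haplotype_table: pd.DataFrame
    mpileups: Dict[Tuple[str, str], List[LocusTally]]
    peak_rows: List[Tuple[str, int, int, str, str, str]]  # BED coords (0-based)
    consequence_table: pd.DataFrame
    truth: List[TruthRecord] = field(default_factory=list)

    @property
    def samples(self) -> List[str]:
        return sorted({s for s, _ in self.mpileups})


def _gene_structure(cfg: SimulationConfig):
    rng = _stream(cfg.seed, "structure")
    genes = []
    for g in range(cfg.n_genes):
        gene_id = f"GENE{g:05d}"
        block_id = f"block{g:05d}"
        chrom = f"chr{1 + g % cfg.n_chroms}"
        while True:
            n_loci = int(rng.poisson(cfg.loci_per_gene_mean))
            if 1 <= n_loci <= cfg.loci_per_gene_max:
                break
        span_start = 10_000 + (g // cfg.n_chroms) * 100_000
        offsets = rng.choice(5_000, size=n_loci, replace=False)
        positions = sorted(int(span_start + o) for o in offsets)
        loci = []
        for pos in positions:
            a1, a2 = rng.choice(len(NUCLEOTIDES), size=2, replace=False)
            loci.append((pos, NUCLEOTIDES[a1], NUCLEOTIDES[a2]))
        is_ase = bool(rng.random() < cfg.prop_ase)
        favored = "h1" if rng.random() < 0.5 else "h2"
        if is_ase:
            fraction = cfg.effect if favored == "h1" else 1.0 - cfg.effect
        else:
            fraction = 0.5
            favored = "h1"
        if cfg.prop_intronic > 0 and rng.random() < cfg.prop_intronic:
            term = "intron_variant"
        else:
            term = str(rng.choice(_FUNCTIONAL_TERMS))
        genes.append(
            {
                "gene_id": gene_id,
                "block_id": block_id,
                "chrom": chrom,
                "loci": loci,
                "is_ase": is_ase,
                "fraction": fraction,
                "favored": favored,
                "term": term,
            }
        )
    return genes


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Generate a full cohort; deterministic for a fixed config."""
    genes = _gene_structure(cfg)
    samples = [f"sample{s + 1}" for s in range(cfg.n_samples)]

    hap_rows = []
    for sample in samples:
        for tissue in cfg.tissues:
            for gene in genes:
                for pos, a1, a2 in gene["loci"]:
                    hap_rows.append(
                        {
                            "sample": sample,
                            "tissue": tissue,
                            "haplotype_block_id": gene["block_id"],
                            "chrom": gene["chrom"],
                            "pos": pos,
                            "allele_h1": a1,
                            "allele_h2": a2,
                        }
                    )
    hap_table = pd.DataFrame(
        hap_rows,
        columns=[
            "sample",
            "tissue",
            "haplotype_block_id",
            "chrom",
            "pos",
            "allele_h1",
            "allele_h2",
        ],
    )

    mpileups: Dict[Tuple[str, str], List[LocusTally]] = {}
    for sample in samples:
        for tissue in cfg.tissues:
            rng = _stream(cfg.seed, f"counts|{sample}|{tissue}")
            tallies: List[LocusTally] = []
            for gene in genes:
                for pos, a1, a2 in gene["loci"]:
                    tallies.append(
                        simulate_locus_counts(
                            cfg.depth_mean,
                            cfg.depth_dispersion,
                            gene["fraction"],
                            cfg.error_rate,
                            rng,
                            chrom=gene["chrom"],
                            pos=pos,
                            allele1=a1,
                            allele2=a2,
                            beta_binomial_rho=cfg.beta_binomial_rho,
                        )
                    )
            tallies.sort(key=lambda t: (t.chrom, t.pos))
            mpileups[(sample, tissue)] = tallies

    peak_rows: List[Tuple[str, int, int, str, str, str]] = []
    for sample in samples:
        for tissue in cfg.tissues:
            rng = _stream(cfg.seed, f"peaks|{sample}|{tissue}")
            for gene in genes:
                if rng.random() >= cfg.peak_overlap_fraction:
                    continue
                positions = [p for p, _, _ in gene["loci"]]
                centre = int(rng.integers(min(positions), max(positions) + 1))
                half = int(rng.integers(200, 1_000))
                mark = str(rng.choice(HISTONE_MARKS))
                peak_rows.append(
                    (
                        gene["chrom"],
                        max(0, centre - half),  # BED 0-based half-open
                        centre + half,
                        mark,
                        tissue,
                        sample,
                    )
                )

    vep_rows = []
    for gene in genes:
        for pos, a1, a2 in gene["loci"]:
            vep_rows.append(
                {
                    "Uploaded_variation": f"{gene['chrom']}_{pos}_{a1}/{a2}",
                    "Location": f"{gene['chrom']}:{pos}",
                    "Allele": a2,
                    "Gene": gene["gene_id"],
                    "Feature": f"{gene['gene_id']}.t1",
                    "Feature_type": "Transcript",
                    "Consequence": gene["term"],
                    "SYMBOL": gene["gene_id"],
                }
            )
    vep_table = pd.DataFrame(
        vep_rows,
        columns=[
            "Uploaded_variation",
            "Location",
            "Allele",
            "Gene",
            "Feature",
            "Feature_type",
            "Consequence",
            "SYMBOL",
        ],
    )

    truth = [
        TruthRecord(
            gene_id=g["gene_id"],
            block_id=g["block_id"],
            chrom=g["chrom"],
            is_ase=g["is_ase"],
            true_fraction=g["fraction"],
            favored=g["favored"],
        )
        for g in genes
    ]
    return SimulatedCohort(
        config=cfg,
        haplotype_table=hap_table,
        mpileups=mpileups,
        peak_rows=peak_rows,
        consequence_table=vep_table,
        truth=truth,
    )


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> Dict[str, Path]:
    """Write every cohort artifact as plain text; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    hap_path = out / "haplotypes.tsv"
    cohort.haplotype_table.to_csv(hap_path, sep="\t", index=False, lineterminator="\n")
    paths["haplotypes"] = hap_path

    for (sample, tissue), tallies in sorted(cohort.mpileups.items()):
        mp_path = out / f"{sample}.{tissue}.mpileup"
        with open(mp_path, "w") as handle:
            for tally in tallies:
                handle.write(tally.to_mpileup_line() + "\n")
        paths[f"mpileup:{sample}:{tissue}"] = mp_path

    bed_path = out / "peaks.bed"
    with open(bed_path, "w") as handle:
        for chrom, start, end, mark, tissue, sample in cohort.peak_rows:
            handle.write(f"{chrom}\t{start}\t{end}\t{mark}\t{tissue}\t{sample}\n")
    paths["peaks"] = bed_path

    vep_path = out / "consequences.tsv"
    table = cohort.consequence_table.rename(
        columns={"Uploaded_variation": "#Uploaded_variation"}
    )
    table.to_csv(vep_path, sep="\t", index=False, lineterminator="\n")
    paths["consequences"] = vep_path

    truth_path = out / "truth.tsv"
    truth_cols = ["gene_id", "block_id", "chrom", "is_ase", "true_fraction", "favored"]
    pd.DataFrame([asdict(t) for t in cohort.truth], columns=truth_cols).to_csv(
        truth_path, sep="\t", index=False, lineterminator="\n"
    )
    paths["truth"] = truth_path

    cfg_path = out / "sim_config.json"
    with open(cfg_path, "w") as handle:
        json.dump(asdict(cohort.config), handle, indent=2, sort_keys=True)
        handle.write("\n")
    paths["config"] = cfg_path
    return paths
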