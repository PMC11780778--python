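"""Replication of discovery ASE loci in an independent cohort.

Validation comparisons orient allele 1 as the discovery-favored allele, so
direction concordance reduces to a positive fold change. Significance uses
the discovery criteria (|aeFC| >= threshold, BH-adjusted p <= alpha) after a
heterozygosity filter on the validation counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Hashable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from equase._utils import round_half_up
from equase.pileup import LocusTally
from equase.stats import SignificanceConfig, bh_adjust, binomial_test, compute_aefc

logger = logging.getLogger(__name__)

LocusKey = Tuple[str, int]


@dataclass(frozen=True)
class DiscoveryCall:
    """Per-locus discovery outcome: the favored allele and its counterpart."""

    chrom: str
    pos: int
    allele_favored: str
    allele_other: str


@dataclass
class ValidationComparison:
    """One sample x locus replication comparison.

    ``count_a1`` supports the discovery-favored allele; ``direction_match``
    is therefore simply aefc > 0.
    """

    sample_id: str
    group: str
    chrom: str
    pos: int
    count_a1: int
    count_a2: int
    aefc: float
    p_raw: float
    p_adj: float
    significant: bool
    direction_match: bool


def heterozygosity_filter(
    tally: LocusTally,
    alleles: Tuple[str, str],
    min_minor: int = 2,
) -> bool:
    """Keep a validation locus iff both discovery alleles are observed.

    Requires >= ``min_minor`` reads supporting each allele; homozygous
    expression (one allele absent) is dropped.
    """
    a1, a2 = alleles
    return tally.counts.get(a1, 0) >= min_minor and tally.counts.get(a2, 0) >= min_minor


def replicate_ase(
    tallies: Mapping[str, Mapping[LocusKey, LocusTally]],
    discovery: Sequence[DiscoveryCall],
    groups: Mapping[str, str] | None = None,
    cfg: SignificanceConfig | None = None,
    min_minor: int = 2,
) -> List[ValidationComparison]:
    """Test every surviving sample x locus pair against the discovery calls.

    ``tallies`` maps sample_id -> (chrom, pos) -> LocusTally; loci present in
    the tallies but absent from the discovery set are skipped with a warning.
    BH is applied across the whole validation cohort (single family).
    """
    cfg = cfg or SignificanceConfig()
    groups = groups or {}
    by_locus: Dict[LocusKey, DiscoveryCall] = {
        (call.chrom, call.pos): call for call in discovery
    }
    pending: List[Tuple[str, DiscoveryCall, int, int]] = []
    for sample_id in sorted(tallies):
        sample_tallies = tallies[sample_id]
        for key in sorted(sample_tallies):
            call = by_locus.get(key)
            if call is None:
                logger.warning(
                    "sample %s: locus %s:%d absent from discovery set, skipped",
                    sample_id,
                    key[0],
                    key[1],
                )
                continue
            tally = sample_tallies[key]
            if not heterozygosity_filter(
                tally, (call.allele_favored, call.allele_other), min_minor
            ):
                continue
            pending.append(
                (
                    sample_id,
                    call,
                    tally.counts.get(call.allele_favored, 0),
                    tally.counts.get(call.allele_other, 0),
                )
            )
    if not pending:
        return []
    aefcs = [compute_aefc(c1, c2, cfg.pseudocount) for _, _, c1, c2 in pending]
    p_raw = [binomial_test(c1, c1 + c2) for _, _, c1, c2 in pending]
    p_adj = bh_adjust(p_raw)
    out: List[ValidationComparison] = []
    for (sample_id, call, c1, c2), fc, pr, pa in zip(pending, aefcs, p_raw, p_adj):
        passes_fc = math.isinf(fc) or (not math.isnan(fc) and abs(fc) >= cfg.aefc_threshold)
        out.append(
            ValidationComparison(
                sample_id=sample_id,
                group=groups.get(sample_id, ""),
                chrom=call.chrom,
                pos=call.pos,
                count_a1=c1,
                count_a2=c2,
                aefc=fc,
                p_raw=pr,
                p_adj=float(pa),
                significant=bool(passes_fc and pa <= cfg.alpha),
                direction_match=bool(not math.isnan(fc) and fc > 0),
            )
        )
    return out


@dataclass
class ConcordanceSummary:
    n_comparisons: int
    n_significant: int
    pct_significant: float  # integer-rounded
    n_direction_match: int  # among significant comparisons
    pct_direction_match: float  # 1 decimal
    n_loci: int
    n_loci_any_replication: int
    pct_loci_any_replication: float  # 1 decimal
    n_loci_ge90: int
    pct_loci_ge90: float  # 1 decimal
    per_locus: pd.DataFrame | None = None


def concordance_summary(
    comparisons: Sequence[ValidationComparison],
) -> ConcordanceSummary:
    """Cohort-level replication statistics.

    Per-locus replication fractions use each locus's surviving-sample count
    as denominator; the >= 90% threshold is inclusive.
    """
    n = len(comparisons)
    if n == 0:
        nan = float("nan")
        return ConcordanceSummary(0, 0, nan, 0, nan, 0, 0, nan, 0, nan, None)
    n_sig = sum(c.significant for c in comparisons)
    n_dir = sum(c.significant and c.direction_match for c in comparisons)
    per_locus_rows: Dict[LocusKey, List[int]] = {}
    for c in comparisons:
        counts = per_locus_rows.setdefault((c.chrom, c.pos), [0, 0])
        counts[0] += 1
        counts[1] += int(c.significant)
    per_locus = pd.DataFrame(
        [
            {
                "chrom": chrom,
                "pos": pos,
                "n_samples": tested,
                "n_significant": sig,
                "replication_fraction": sig / tested,
            }
            for (chrom, pos), (tested, sig) in sorted(per_locus_rows.items())
        ]
    )
    n_loci = len(per_locus)
    n_any = int((per_locus["n_significant"] >= 1).sum())
    n_ge90 = int((per_locus["replication_fraction"] >= 0.9).sum())
    return ConcordanceSummary(
        n_comparisons=n,
        n_significant=n_sig,
        pct_significant=round_half_up(100.0 * n_sig / n, 0),
        n_direction_match=n_dir,
        pct_direction_match=round_half_up(100.0 * n_dir / n_sig, 1) if n_sig else float("nan"),
        n_loci=n_loci,
        n_loci_any_replication=n_any,
        pct_loci_any_replication=round_half_up(100.0 * n_any / n_loci, 1),
        n_loci_ge90=n_ge90,
        pct_loci_ge90=round_half_up(100.0 * n_ge90 / n_loci, 1),
        per_locus=per_locus,
    )


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    eta_squared: float
    ss_between: float
    ss_within: float
    ss_total: float


def anova_eta_squared(
    values: Sequence[float],
    groups: Sequence[Hashable],
) -> AnovaResult:
    """One-way fixed-effects ANOVA with eta-squared effect size.

    eta_squared = SS_between / SS_total. If all values are identical the F
    statistic is undefined (NaN) and eta_squared is 0.
    """
    y = np.asarray(values, dtype=float)
    labels = np.empty(len(groups), dtype=object)
    labels[:] = list(groups)
    if y.size != labels.size:
        raise ValueError("values and groups must have equal length")
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("ANOVA requires >= 2 groups")
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_between = 0.0
    ss_within = 0.0
    for g in uniq:
        sub = y[labels == g]
        if sub.size == 0:
            raise ValueError(f"group {g!r} has no values")
        ss_between += sub.size * (sub.mean() - grand) ** 2
        ss_within += float(((sub - sub.mean()) ** 2).sum())
    df_between = len(uniq) - 1
    df_within = y.size - len(uniq)
    if df_within < 1:
        raise ValueError("ANOVA requires at least one group with >= 2 values")
    if ss_total == 0.0:
        return AnovaResult(float("nan"), df_between, df_within, 0.0, 0.0, 0.0, 0.0)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    f_stat = ms_between / ms_within if ms_within > 0 else float("inf")
    return AnovaResult(
        f_statistic=float(f_stat),
        df_between=df_between,
        df_within=df_within,
        eta_squared=float(ss_between / ss_total),
        ss_between=float(ss_between),
        ss_within=float(ss_within),
        ss_total=ss_total,
    )


def comparisons_frame(comparisons: Sequence[ValidationComparison]) -> pd.DataFrame:
    """Tabulate validation comparisons (the cohort data-frame layout)."""
    return pd.DataFrame(
        [
            {
                "sample": c.sample_id,
                "group": c.group,
                "chrom": c.chrom,
                "pos": c.pos,
                "count_a1": c.count_a1,
                "count_a2": c.count_a2,
                "aefc": c.aefc,
                "p_raw": c.p_raw,
                "p_adj": c.p_adj,
                "significant": c.significant,
                "direction_match": c.direction_match,
            }
            for c in comparisons
        ],
        columns=[
            "sample",
            "group",
            "chrom",
            "pos",
            "count_a1",
            "count_a2",
            "aefc",
            "p_raw",
            "p_adj",
            "significant",
            "direction_match",
        ],
    )
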