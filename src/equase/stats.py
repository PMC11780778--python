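"""Allelic-imbalance statistics: aeFC, exact binomial test, BH adjustment,
significance criteria and tissue-level summaries.

Significance requires all three of: |aeFC| >= 2 (log2 scale; an infinite
aeFC from a zero side passes), BH-adjusted p <= 0.05, and at least one
allele expression value >= 5 — applied after the coverage >= 10 filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, Hashable, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from equase._utils import round_half_up
from equase.haplotypes import AlleleExpression

# Above this trial count the exact integer-arithmetic path becomes slow and
# floating-point summation (scipy) is indistinguishable at double precision.
_EXACT_N_MAX = 256


@dataclass
class SignificanceConfig:
    """Thresholds for calling a comparison significant."""

    coverage_min: int = 10
    aefc_threshold: float = 2.0
    alpha: float = 0.05
    min_expr: int = 5
    fdr_family: str = "sample_tissue"  # or "global"
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if self.coverage_min <= 0 or self.aefc_threshold <= 0 or self.min_expr <= 0:
            raise ValueError("thresholds must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.fdr_family not in ("sample_tissue", "global"):
            raise ValueError("fdr_family must be 'sample_tissue' or 'global'")


@dataclass
class ASEResult:
    """Outcome of one allele-expression comparison."""

    comparison: AlleleExpression
    aefc: float
    p_raw: float
    p_adj: float
    significant: bool
    favored: str  # "h1" | "h2" | "none"


def coverage_filter(ae: AlleleExpression, coverage_min: int = 10) -> bool:
    """Keep a comparison iff at least one allele meets the coverage threshold."""
    return max(ae.expr_h1, ae.expr_h2) >= coverage_min


def compute_aefc(expr_h1: float, expr_h2: float, pseudocount: float = 0.0) -> float:
    """log2(allele-1 expression) - log2(allele-2 expression).

    A zero on exactly one side gives signed infinity; (0, 0) gives NaN (such
    comparisons are removed upstream by the coverage filter).
    """
    a = expr_h1 + pseudocount
    b = expr_h2 + pseudocount
    if a == 0 and b == 0:
        return math.nan
    if a == 0:
        return -math.inf
    if b == 0:
        return math.inf
    return math.log2(a) - math.log2(b)


def binomial_test(k: int, n: int) -> float:
    """Exact two-sided binomial p-value at success probability 1/2.

    Minimum-likelihood definition: the sum of P(X=i) over all outcomes i no
    more likely than the observed k. At p = 1/2 the point probabilities are
    binomial coefficients over 2**n, so for moderate n the tail membership
    test is done in exact integer arithmetic (no floating-point ties).
    """
    if n < 1:
        raise ValueError("binomial test requires n >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    if n > _EXACT_N_MAX:
        return float(sps.binomtest(k, n, 0.5).pvalue)
    weights = [math.comb(n, i) for i in range(n + 1)]
    observed = weights[k]
    total = sum(w for w in weights if w <= observed)
    return min(1.0, total / (1 << n))


def bh_adjust(
    p_values: Sequence[float],
    family: Sequence[Hashable] | None = None,
) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, optionally within families.

    Within each family: adj_(i) = min over j >= i of (m/j) * p_(j), capped at
    1, with the original order restored. Ties share identical adjusted values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = np.empty_like(p)
    if family is None:
        groups: Dict[Hashable, np.ndarray] = {None: np.arange(p.size)}
    else:
        if len(family) != p.size:
            raise ValueError("family labels must match p-values in length")
        fam = np.empty(len(family), dtype=object)
        fam[:] = list(family)  # keeps tuple labels from expanding to 2-D
        codes, _ = pd.factorize(fam)
        groups = {code: np.flatnonzero(codes == code) for code in np.unique(codes)}
    for idx in groups.values():
        sub = p[idx]
        m = sub.size
        order = np.argsort(sub, kind="mergesort")
        ranked = sub[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        ranked = np.minimum(ranked, 1.0)
        out = np.empty(m)
        out[order] = ranked
        adjusted[idx] = out
    return adjusted


def _favored(aefc: float) -> str:
    if math.isnan(aefc) or aefc == 0:
        return "none"
    return "h1" if aefc > 0 else "h2"


def call_ase(
    comparisons: Sequence[AlleleExpression],
    cfg: SignificanceConfig | None = None,
) -> List[ASEResult]:
    """Run the fixed calling pipeline over a batch of comparisons.

    Order: coverage filter -> aeFC -> exact binomial p -> BH within
    ``cfg.fdr_family`` -> significance test. Returns results only for
    comparisons surviving the coverage filter, in input order.
    """
    cfg = cfg or SignificanceConfig()
    survivors = [ae for ae in comparisons if coverage_filter(ae, cfg.coverage_min)]
    if not survivors:
        return []
    aefcs = [compute_aefc(ae.expr_h1, ae.expr_h2, cfg.pseudocount) for ae in survivors]
    p_raw = [binomial_test(ae.expr_h1, ae.expr_h1 + ae.expr_h2) for ae in survivors]
    if cfg.fdr_family == "sample_tissue":
        family: Sequence[Hashable] | None = [
            (ae.haplotype.sample_id, ae.haplotype.tissue) for ae in survivors
        ]
    else:
        family = None
    p_adj = bh_adjust(p_raw, family)
    results = []
    for ae, fc, pr, pa in zip(survivors, aefcs, p_raw, p_adj):
        passes_fc = math.isinf(fc) or (not math.isnan(fc) and abs(fc) >= cfg.aefc_threshold)
        significant = bool(
            passes_fc and pa <= cfg.alpha and max(ae.expr_h1, ae.expr_h2) >= cfg.min_expr
        )
        results.append(
            ASEResult(
                comparison=ae,
                aefc=fc,
                p_raw=pr,
                p_adj=float(pa),
                significant=significant,
                favored=_favored(fc),
            )
        )
    return results


def results_frame(results: Sequence[ASEResult]) -> pd.DataFrame:
    """Tabulate call results as the master resource layout."""
    rows = [
        {
            "sample": r.comparison.haplotype.sample_id,
            "tissue": r.comparison.haplotype.tissue,
            "block": r.comparison.haplotype.block_id,
            "gene": r.comparison.haplotype.gene_id or "",
            "expr_h1": r.comparison.expr_h1,
            "expr_h2": r.comparison.expr_h2,
            "n_loci_observed": r.comparison.n_loci_observed,
            "other_count": r.comparison.other_count,
            "aefc": r.aefc,
            "p_raw": r.p_raw,
            "p_adj": r.p_adj,
            "significant": r.significant,
            "favored": r.favored,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample",
            "tissue",
            "block",
            "gene",
            "expr_h1",
            "expr_h2",
            "n_loci_observed",
            "other_count",
            "aefc",
            "p_raw",
            "p_adj",
            "significant",
            "favored",
        ],
    )


def tissue_summary(
    results: Union[Sequence[ASEResult], pd.DataFrame],
) -> pd.DataFrame:
    """Per-tissue comparison/significant counts with half-up 2-decimal percents.

    A tissue with zero comparisons reports NaN percent.
    """
    if isinstance(results, pd.DataFrame):
        df = results[["tissue", "significant"]].copy()
    else:
        df = pd.DataFrame(
            {
                "tissue": [r.comparison.haplotype.tissue for r in results],
                "significant": [r.significant for r in results],
            }
        )
    if df.empty:
        return pd.DataFrame(columns=["tissue", "comparisons", "n_significant", "percent"])
    grouped = df.groupby("tissue", sort=True)["significant"].agg(["size", "sum"])
    out = pd.DataFrame(
        {
            "tissue": grouped.index,
            "comparisons": grouped["size"].astype(int).values,
            "n_significant": grouped["sum"].astype(int).values,
        }
    ).reset_index(drop=True)
    out["percent"] = [
        round_half_up(100.0 * s / c, 2) if c else math.nan
        for s, c in zip(out["n_significant"], out["comparisons"])
    ]
    return out


def overall_percent(n_significant: int, n_comparisons: int) -> float:
    """Significant share of all comparisons, half-up to 2 decimals."""
    if n_comparisons == 0:
        return math.nan
    return round_half_up(100.0 * n_significant / n_comparisons, 2)
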