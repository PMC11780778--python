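"""Independent oracle implementations used only by the test suite.

Each oracle takes a deliberately different route from the package code:
regex scanning vs character walk, exact rationals vs integer tails, naive
O(m^2) minimization vs vectorized cumulative minima, all-pairs interval
scans vs indexed queries.
"""

from __future__ import annotations

import re
from collections import Counter
from fractions import Fraction
from math import comb
from typing import Dict, List, Sequence, Set, Tuple

_PILEUP_TOKEN = re.compile(
    r"(\^.)|(\$)|([+-])(\d+)|([.,])|([ACGTacgt])|([Nn])|(\*)|([><])"
)


def regex_tally(bases: str, ref: str) -> Dict[str, int]:
    """Regex-scanner tally of an mpileup base column.

    Returns counts for A/C/G/T plus 'N', 'del' and 'skip' keys.
    """
    counts: Counter = Counter({b: 0 for b in "ACGT"})
    counts["N"] = counts["del"] = counts["skip"] = 0
    i = 0
    while i < len(bases):
        m = _PILEUP_TOKEN.match(bases, i)
        if m is None:
            raise ValueError(f"unparseable at offset {i}: {bases[i:]!r}")
        if m.group(3):  # indel: skip the run
            i = m.end() + int(m.group(4))
            continue
        if m.group(5):
            if ref.upper() in "ACGT":
                counts[ref.upper()] += 1
            else:
                counts["N"] += 1
        elif m.group(6):
            counts[m.group(6).upper()] += 1
        elif m.group(7):
            counts["N"] += 1
        elif m.group(8):
            counts["del"] += 1
        elif m.group(9):
            counts["skip"] += 1
        i = m.end()
    return dict(counts)


def enum_binomial_two_sided(k: int, n: int) -> float:
    """Two-sided minimum-likelihood binomial p at p=1/2 by full enumeration,
    in exact rational arithmetic."""
    probs = [Fraction(comb(n, i), 2**n) for i in range(n + 1)]
    observed = probs[k]
    total = sum(p for p in probs if p <= observed)
    return float(min(Fraction(1), total))


def enum_binomial_all(n: int) -> List[float]:
    """Two-sided minimum-likelihood p for every k in 0..n, exact rationals."""
    probs = [Fraction(comb(n, i), 2**n) for i in range(n + 1)]
    out = []
    for k in range(n + 1):
        observed = probs[k]
        total = sum(p for p in probs if p <= observed)
        out.append(float(min(Fraction(1), total)))
    return out


def naive_bh(p_values: Sequence[float]) -> List[float]:
    """O(m^2) step-up BH: adj_i = min over j with rank >= rank_i of (m/j)p_(j)."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    ranks = [0] * m
    for rank, idx in enumerate(order, start=1):
        ranks[idx] = rank
    adjusted = []
    for i in range(m):
        candidates = [
            p_values[j] * m / ranks[j] for j in range(m) if ranks[j] >= ranks[i]
        ]
        adjusted.append(min(1.0, min(candidates)))
    return adjusted


def brute_force_overlap(
    region: Tuple[str, int, int],
    peaks: Sequence[Tuple[str, int, int, str, str, str]],
    tissue: str,
    sample: str,
) -> Set[str]:
    """All-pairs closed-interval intersection; peaks are 1-based closed tuples
    (chrom, start, end, mark, tissue, sample)."""
    chrom, start, end = region
    hits = set()
    for p_chrom, p_start, p_end, mark, p_tissue, p_sample in peaks:
        if (
            p_chrom == chrom
            and p_tissue == tissue
            and p_sample == sample
            and p_start <= end
            and p_end >= start
        ):
            hits.add(mark)
    return hits


def anova_ss_oracle(values: Sequence[float], groups: Sequence) -> Tuple[float, float, float]:
    """Textbook sums-of-squares via the computational formulas.

    SS_total = sum(y^2) - (sum y)^2 / N; SS_between = sum(T_g^2/n_g) - CF.
    """
    n = len(values)
    total = sum(values)
    cf = total * total / n
    ss_total = sum(v * v for v in values) - cf
    by_group: Dict = {}
    for v, g in zip(values, groups):
        by_group.setdefault(g, []).append(v)
    ss_between = sum(sum(vs) ** 2 / len(vs) for vs in by_group.values()) - cf
    return ss_between, ss_total - ss_between, ss_total
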