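"""Independent brute-force oracles used to cross-check the implementations.

Everything here enumerates directly from definitions (string tallies,
all-pairs comparisons) and shares no code with the package internals.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def entropy_oracle(counts: dict) -> float:
    """-sum p log2 p over explicit haplotype counts."""
    n = sum(counts.values())
    s = 0.0
    for c in counts.values():
        p = c / n
        s -= p * math.log2(p)
    return s


def window_counts_oracle(alleles: np.ndarray, lo: int, hi: int) -> dict:
    """Tally haplotype strings over rows [lo, hi) by direct concatenation."""
    tally = Counter()
    for col in range(alleles.shape[1]):
        key = "".join(str(int(a)) for a in alleles[lo:hi, col])
        tally[key] += 1
    return dict(tally)


def windowed_entropy_oracle(alleles: np.ndarray, center: int, w: int) -> float:
    h = (w - 1) // 2
    return entropy_oracle(window_counts_oracle(alleles, center - h, center + h + 1))


def ehh_oracle(alleles: np.ndarray, core: int, offset: int) -> float:
    """All-pairs EHH: among chromosome pairs agreeing at the core, the
    fraction identical over every SNP between the core and core+offset."""
    n = alleles.shape[1]
    core_pairs = 0
    ext_pairs = 0
    lo, hi = (core + offset, core) if offset < 0 else (core, core + offset)
    for i in range(n):
        for j in range(i + 1, n):
            if alleles[core, i] != alleles[core, j]:
                continue
            core_pairs += 1
            if all(alleles[k, i] == alleles[k, j] for k in range(lo, hi + 1)):
                ext_pairs += 1
    if core_pairs == 0:
        return float("nan")
    return ext_pairs / core_pairs


def integrated_ehh_oracle(alleles: np.ndarray, core: int, w: int) -> float:
    """Trapezoidal integral of the all-pairs EHH curve, both directions."""
    h = (w - 1) // 2
    total = 0.0
    for direction in (-1, +1):
        curve = [ehh_oracle(alleles, core, direction * x) for x in range(h + 1)]
        for x in range(h):
            total += (curve[x] + curve[x + 1]) / 2.0
    return total
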