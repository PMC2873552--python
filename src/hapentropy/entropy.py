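"""Windowed haplotype Shannon entropy.

The statistic: within a window of ``w`` consecutive SNPs centred on a focal
SNP, count how often each distinct haplotype (the ordered allele string over
the window) occurs among the ``n`` chromosomes, and compute

    S = -sum_i p_i * log2(p_i)

over the haplotype frequencies ``p_i``. S is 0 when all haplotypes are
identical (one class) and reaches its maximum log2(n) when all n haplotypes
are distinct. Low S marks strong linkage disequilibrium: one or a few
haplotypes dominate the window.

Scan filters mirror standard practice for this statistic: a focal SNP is
scored only if a full centred window fits inside its chromosome, windows
spanning more than ``max_span_bp`` base pairs (default 200 kb) are excluded,
and SNPs on sex chromosomes can be dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import HaplotypePanel

__all__ = [
    "WindowSpec",
    "HaplotypeCounts",
    "EntropyTrack",
    "count_window_haplotypes",
    "entropy",
    "entropy_difference",
    "scan_entropy",
    "DEFAULT_SEX_CHROMS",
]

logger = logging.getLogger(__name__)

DEFAULT_SEX_CHROMS = frozenset({"X", "Y", "chrX", "chrY"})


@dataclass(frozen=True)
class WindowSpec:
    """Scan window geometry.

    w : window size in SNPs; must be odd so the window centres on the
        focal SNP with (w-1)/2 SNPs on each side.
    max_span_bp : windows whose first-to-last SNP distance exceeds this
        are excluded from the scan (long segments carry little comparable
        information and would distort the empirical null).
    """

    w: int = 21
    max_span_bp: int = 200_000

    def __post_init__(self) -> None:
        if self.w < 1 or self.w % 2 == 0:
            raise ValueError(f"window size must be an odd positive integer, got {self.w}")
        if self.max_span_bp <= 0:
            raise ValueError("max_span_bp must be positive")

    @property
    def radius(self) -> int:
        return (self.w - 1) // 2


@dataclass
class HaplotypeCounts:
    """Occurrence count per distinct haplotype string in one window."""

    counts: dict[str, int]
    n: int

    def __post_init__(self) -> None:
        if self.counts and sum(self.counts.values()) != self.n:
            raise ValueError("haplotype counts do not sum to n")


@dataclass
class EntropyTrack:
    """Per-SNP entropy scores for one population.

    ``S`` is NaN wherever ``valid`` is False (chromosome edge, span filter,
    sex-chromosome filter). ``filter_counts`` is the audit trail of how many
    SNPs each exclusion removed.
    """

    chrom: np.ndarray
    pos: np.ndarray
    snp_id: np.ndarray
    S: np.ndarray
    span_bp: np.ndarray
    valid: np.ndarray
    filter_counts: dict[str, int] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "snp_id": self.snp_id,
                "S": self.S,
                "span_bp": self.span_bp,
                "valid": self.valid,
            }
        )

    def to_tsv(self, path) -> None:
        df = self.to_dataframe()
        df["S"] = df["S"].map(lambda v: f"{v:.6f}" if np.isfinite(v) else "NA")
        df.to_csv(path, sep="\t", index=False)


def count_window_haplotypes(
    panel: HaplotypePanel, center: int, spec: WindowSpec
) -> HaplotypeCounts:
    """Tally distinct haplotype strings in the window centred on ``center``.

    Raises ``IndexError`` if the window runs past the panel edge and
    ``ValueError`` if it crosses a chromosome boundary.
    """
    h = spec.radius
    lo, hi = center - h, center + h + 1
    if lo < 0 or hi > panel.n_snps:
        raise IndexError(
            f"window of {spec.w} SNPs around index {center} extends past the panel edge"
        )
    block = panel.chrom[lo:hi]
    if not all(c == block[0] for c in block):
        raise ValueError(
            f"window around index {center} crosses a chromosome boundary"
        )
    window = panel.alleles[lo:hi]
    keys, counts = _window_class_counts(window)
    return HaplotypeCounts(counts=dict(zip(keys, counts)), n=panel.n_chrom)


def _window_class_counts(window: np.ndarray) -> tuple[list[str], list[int]]:
    """Distinct haplotype strings (column-wise) and their counts."""
    uniq, counts = np.unique(window.T, axis=0, return_counts=True)
    keys = ["".join(str(int(a)) for a in row) for row in uniq]
    return keys, [int(c) for c in counts]


def entropy(counts: HaplotypeCounts | dict[str, int]) -> float:
    """Shannon entropy in bits of the haplotype frequency distribution."""
    if isinstance(counts, HaplotypeCounts):
        values = np.asarray(list(counts.counts.values()), dtype=float)
        n = counts.n
    else:
        values = np.asarray(list(counts.values()), dtype=float)
        n = values.sum()
    if values.size == 0 or n < 1:
        raise ValueError("entropy undefined for empty haplotype counts")
    p = values / n
    return float(-np.sum(p * np.log2(p)))


def entropy_difference(s_pop1: float, s_pop2: float) -> float:
    """dS = S_pop1 - S_pop2; NaN propagates from either side."""
    return s_pop1 - s_pop2


def _entropy_from_count_array(counts: np.ndarray, n: int) -> float:
    p = counts / n
    return float(-np.sum(p * np.log2(p)))


def scan_entropy(
    panel: HaplotypePanel,
    spec: WindowSpec = WindowSpec(),
    exclude_sex: bool = True,
    sex_chroms: frozenset[str] | set[str] = DEFAULT_SEX_CHROMS,
) -> EntropyTrack:
    """Per-SNP windowed entropy scan with edge, span and sex-chromosome filters.

    Every SNP of the panel gets a record; ``valid`` is False (and S is NaN)
    at the (w-1)/2 edge SNPs of each chromosome, where the window spans more
    than ``spec.max_span_bp``, and on excluded sex chromosomes.
    """
    n = panel.n_snps
    S = np.full(n, np.nan)
    span = np.full(n, -1, dtype=np.int64)
    valid = np.zeros(n, dtype=bool)
    h = spec.radius
    n_edge = n_span = n_sex = 0

    for start, stop in panel.chrom_blocks():
        label = panel.chrom[start]
        if exclude_sex and label in sex_chroms:
            n_sex += stop - start
            continue
        block_len = stop - start
        n_edge += min(2 * h, block_len)
        if block_len < spec.w:
            continue
        pos = panel.pos[start:stop]
        centers = np.arange(h, block_len - h)
        spans = pos[centers + h] - pos[centers - h]
        span[start + centers] = spans
        ok = spans <= spec.max_span_bp
        n_span += int((~ok).sum())
        alleles = panel.alleles[start:stop]
        for c in centers[ok]:
            window = alleles[c - h : c + h + 1]
            _, counts = np.unique(window.T, axis=0, return_counts=True)
            S[start + c] = _entropy_from_count_array(counts.astype(float), panel.n_chrom)
            valid[start + c] = True

    fc = {"edge_skipped": n_edge, "span_excluded": n_span, "sex_excluded": n_sex}
    logger.info(
        "entropy scan: %d SNPs, %d valid; excluded %d edge, %d span>%d bp, %d sex-chromosome",
        n, int(valid.sum()), n_edge, n_span, spec.max_span_bp, n_sex,
    )
    return EntropyTrack(
        chrom=panel.chrom.copy(),
        pos=panel.pos.copy(),
        snp_id=panel.snp_id.copy(),
        S=S,
        span_bp=span,
        valid=valid,
        filter_counts=fc,
    )
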