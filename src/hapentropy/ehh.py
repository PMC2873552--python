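"""Extended haplotype homozygosity (EHH) and its window-integrated score.

EHH at offset x from a core SNP is the probability that two randomly chosen
chromosomes that agree at the core are identical over every SNP between the
core and offset x. Integrating the EHH decay curve over the window gives a
single long-range-LD score I per SNP: large I means haplotypes extend far
without recombination having broken them up.

This is the site-level (pooled-allele) form: pair counts are accumulated
across both core allele classes,

    EHH(x) = sum_h C(m_h, 2) / sum_a C(n_a, 2),

where n_a are the core allele counts and m_h the counts of distinct
haplotypes over the interval from the core to offset x. Offsets are SNP
indices, not base pairs, so the score is directly comparable across windows
regardless of physical segment length. I is the trapezoidal integral of
EHH over offsets, both directions summed; with window w it lies in
[0, w-1]. EHH-based scores are known to be unstable when the core minor
allele frequency is low, so the scan flags cores with MAF < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .entropy import WindowSpec
from .panel import HaplotypePanel

__all__ = ["EHHProfile", "IntegratedEHH", "ehh_profile", "integrated_ehh", "scan_integrated_ehh"]


@dataclass
class EHHProfile:
    """EHH decay curve around one core SNP.

    ``offsets`` run from -(w-1)/2 to +(w-1)/2 in SNP-index units; ``ehh``
    holds the homozygosity at each offset (NaN everywhere when the core has
    no agreeing pair, i.e. all alleles are singletons — ``defined`` False).
    """

    core: int
    offsets: np.ndarray
    ehh: np.ndarray
    maf: float
    defined: bool = True


@dataclass
class IntegratedEHH:
    """Trapezoidal integral I of an EHH profile and its natural-log scale."""

    I: float
    log_I: float
    defined: bool = True


def _pair_count(counts: np.ndarray) -> float:
    return float((counts * (counts - 1)).sum() / 2.0)


def ehh_profile(panel: HaplotypePanel, core: int, spec: WindowSpec) -> EHHProfile:
    """EHH at every offset of the centred window around ``core``.

    The denominator is the number of chromosome pairs agreeing at the core
    site; if zero (every core allele a singleton) the profile is undefined
    and flagged rather than scored.
    """
    h = spec.radius
    if core - h < 0 or core + h + 1 > panel.n_snps:
        raise IndexError(f"centred window of {spec.w} SNPs does not fit around index {core}")
    block = panel.chrom[core - h : core + h + 1]
    if not all(c == block[0] for c in block):
        raise ValueError(f"window around index {core} crosses a chromosome boundary")

    a = panel.alleles
    core_alleles = a[core]
    _, core_counts = np.unique(core_alleles, return_counts=True)
    denom = _pair_count(core_counts)
    freq1 = core_alleles.mean() if panel.biallelic else np.nan
    maf = float(min(freq1, 1 - freq1)) if panel.biallelic else float("nan")

    offsets = np.arange(-h, h + 1)
    ehh = np.full(2 * h + 1, np.nan)
    if denom == 0:
        return EHHProfile(core=core, offsets=offsets, ehh=ehh, maf=maf, defined=False)

    # grow the haplotype grouping outward one SNP at a time in each direction
    for direction in (+1, -1):
        labels = _group_labels(core_alleles)
        ehh[h] = 1.0
        for x in range(1, h + 1):
            site = a[core + direction * x]
            labels = _refine_labels(labels, site)
            _, counts = np.unique(labels, return_counts=True)
            ehh[h + direction * x] = _pair_count(counts) / denom
    return EHHProfile(core=core, offsets=offsets, ehh=ehh, maf=maf, defined=True)


def _group_labels(values: np.ndarray) -> np.ndarray:
    _, labels = np.unique(values, return_inverse=True)
    return labels


def _refine_labels(labels: np.ndarray, site: np.ndarray) -> np.ndarray:
    """Split existing haplotype classes by the alleles at one more site."""
    combined = labels.astype(np.int64) * (site.max() + 1) + site
    return _group_labels(combined)


def integrated_ehh(profile: EHHProfile) -> IntegratedEHH:
    """Trapezoidal integral of the EHH curve, both directions summed."""
    if not profile.defined:
        return IntegratedEHH(I=float("nan"), log_I=float("nan"), defined=False)
    h = (len(profile.offsets) - 1) // 2
    e = profile.ehh
    right = np.trapezoid(e[h:], dx=1.0) if h > 0 else 0.0
    left = np.trapezoid(e[: h + 1][::-1], dx=1.0) if h > 0 else 0.0
    I = float(left + right)
    log_I = float(np.log(I)) if I > 0 else float("nan")
    return IntegratedEHH(I=I, log_I=log_I, defined=True)


def scan_integrated_ehh(
    panel: HaplotypePanel,
    spec: WindowSpec = WindowSpec(),
    maf_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-SNP integrated EHH track.

    Returns a DataFrame with columns chrom, pos, snp_id, I, log_I, maf,
    low_maf, valid. Edge SNPs (no full centred window) are invalid; the
    physical span of the window is deliberately ignored so that I is
    comparable to the entropy scan SNP-for-SNP. Undefined cores (no
    agreeing pair) stay NaN, never zero.
    """
    n = panel.n_snps
    I = np.full(n, np.nan)
    log_I = np.full(n, np.nan)
    maf = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    h = spec.radius

    for start, stop in panel.chrom_blocks():
        if stop - start < spec.w:
            continue
        for c in range(start + h, stop - h):
            prof = ehh_profile(panel, c, spec)
            maf[c] = prof.maf
            res = integrated_ehh(prof)
            if res.defined:
                I[c] = res.I
                log_I[c] = res.log_I
                valid[c] = True

    return pd.DataFrame(
        {
            "chrom": panel.chrom,
            "pos": panel.pos,
            "snp_id": panel.snp_id,
            "I": I,
            "log_I": log_I,
            "maf": maf,
            "low_maf": maf < maf_threshold,
            "valid": valid,
        }
    )
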