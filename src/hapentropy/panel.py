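"""Phased haplotype panel: the in-memory container every statistic consumes.

A panel is an ``n_snps x n_chrom`` matrix of integer allele codes plus
per-SNP metadata (chromosome label, 1-based position, SNP identifier).
Each column is one haploid chromosome; diploid donors contribute two
columns. Positions must be strictly increasing within a chromosome and no
allele may be missing — statistics over partially observed haplotype
strings are undefined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HaplotypePanel", "PanelError"]


class PanelError(ValueError):
    """Raised when panel contents violate the container's invariants."""


@dataclass
class HaplotypePanel:
    """Phased biallelic (or, permissively, multi-allelic) haplotype matrix.

    Parameters
    ----------
    chrom
        Chromosome label per SNP, shape ``(n_snps,)``.
    pos
        1-based base-pair coordinate per SNP, strictly increasing within
        each chromosome.
    snp_id
        SNP identifier per SNP (e.g. rsID).
    alleles
        Integer allele codes, shape ``(n_snps, n_chrom)``. ``0/1`` in
        biallelic mode; larger codes allowed when ``biallelic=False``.
    biallelic
        When True (default) every SNP row must carry at most two distinct
        allele codes.
    """

    chrom: np.ndarray
    pos: np.ndarray
    snp_id: np.ndarray
    alleles: np.ndarray
    biallelic: bool = True
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.alleles = np.asarray(self.alleles)
        if not self._validated:
            self.validate()
            self._validated = True

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        a = self.alleles
        if a.ndim != 2:
            raise PanelError("alleles must be a 2-D (n_snps x n_chrom) matrix")
        n_snps, n_chrom = a.shape
        if len(self.chrom) != n_snps or len(self.pos) != n_snps or len(self.snp_id) != n_snps:
            raise PanelError("metadata length does not match allele row count")
        if n_snps and n_chrom < 2:
            raise PanelError("a panel needs at least 2 chromosome columns")
        if not np.issubdtype(a.dtype, np.integer):
            raise PanelError("allele codes must be integers; recode on load")
        if n_snps and a.min() < 0:
            raise PanelError("negative allele code (missing calls must be resolved on load)")
        seen: set = set()
        for start, stop in self._chrom_blocks():
            label = self.chrom[start]
            if label in seen:
                raise PanelError(f"panel not sorted: chromosome {label!r} rows are not contiguous")
            seen.add(label)
            p = self.pos[start:stop]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise PanelError(
                    f"positions not strictly increasing on chromosome {label!r}"
                )
        if self.biallelic and n_snps:
            # <=2 distinct codes per row and codes within {0,1}
            if a.max() > 1:
                raise PanelError("allele code >1 in biallelic mode")

    def _chrom_blocks(self) -> list[tuple[int, int]]:
        """Contiguous [start, stop) row ranges sharing one chromosome label."""
        blocks: list[tuple[int, int]] = []
        n = len(self.chrom)
        i = 0
        while i < n:
            j = i + 1
            while j < n and self.chrom[j] == self.chrom[i]:
                j += 1
            blocks.append((i, j))
            i = j
        return blocks

    # -- views -----------------------------------------------------------

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_chrom(self) -> int:
        return self.alleles.shape[1]

    def chrom_blocks(self) -> list[tuple[int, int]]:
        return self._chrom_blocks()

    def take_snps(self, index: np.ndarray) -> "HaplotypePanel":
        """Row-subset panel (keeps all chromosome columns)."""
        return HaplotypePanel(
            chrom=self.chrom[index],
            pos=self.pos[index],
            snp_id=self.snp_id[index],
            alleles=self.alleles[index],
            biallelic=self.biallelic,
        )

    def take_chromosomes(self, columns: np.ndarray) -> "HaplotypePanel":
        """Column-subset panel (e.g. split one population into two)."""
        return HaplotypePanel(
            chrom=self.chrom,
            pos=self.pos,
            snp_id=self.snp_id,
            alleles=self.alleles[:, columns],
            biallelic=self.biallelic,
        )

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP (biallelic codes 0/1)."""
        freq1 = self.alleles.mean(axis=1)
        return np.minimum(freq1, 1.0 - freq1)

    def same_sites(self, other: "HaplotypePanel") -> bool:
        return (
            self.n_snps == other.n_snps
            and bool(np.all(self.chrom == other.chrom))
            and bool(np.all(self.pos == other.pos))
            and bool(np.all(self.snp_id == other.snp_id))
        )

    def equals(self, other: "HaplotypePanel") -> bool:
        return self.same_sites(other) and bool(np.array_equal(self.alleles, other.alleles))
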