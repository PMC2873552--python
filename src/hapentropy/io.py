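"""Readers and writers for the formats the tool touches, plus test fixtures.

Panels come in two dialects:

* **phased VCF** — standard VCF with phased diploid genotypes (``GT`` uses
  ``|``); each sample contributes two chromosome columns. Read through
  cyvcf2; alleles recoded REF→0, ALT→1.
* **legacy HapMap phased text** — the whitespace-separated dialect of the
  HapMap phased-haplotype downloads: a header ``rsID position_b36 <one
  column name per chromosome>``, then one row per SNP with rsID, position
  and one allele character per chromosome. The public files are
  per-chromosome and carry no chromosome column, so this writer emits a
  ``#chrom=<label>`` comment line which the reader honors (default
  ``chr1``). Nucleotide alphabets are recoded to 0/1 in lexicographic
  order; a ``{0,1}`` digit alphabet is taken as already coded, which makes
  simulator output round-trip bit-exactly.

Gene tables are read from BED (0-based half-open, converted to 1-based
inclusive) or GFF3 (already 1-based inclusive; gene name taken from the
``Name=``, ``gene_name=``, ``gene=`` or ``ID=`` attribute, first found).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import HaplotypePanel, PanelError
from .pipeline import GeneTable

__all__ = [
    "PanelSource",
    "FixtureSpec",
    "read_panel",
    "write_panel",
    "read_gene_table",
    "generate_fixture",
]

logger = logging.getLogger(__name__)

DIALECT_VCF = "phased-vcf"
DIALECT_HAPMAP = "hapmap-phased-text"
MISSING_TEXT = {".", "N", "-", "?"}


@dataclass
class PanelSource:
    """Where and how to read a haplotype panel."""

    path: str | Path
    dialect: str | None = None  # auto-sniffed when None
    region: str | None = None  # "chrom" or "chrom:start-end"
    samples: list[str] | None = None
    drop_missing: bool = False  # drop SNPs with any missing call instead of erroring
    default_chrom: str = "chr1"  # hapmap dialect only


@dataclass
class FixtureSpec:
    """Recipe for a synthetic panel with a known haplotype frequency spectrum.

    Each window of ``n_snps`` SNPs is populated by assigning chromosomes to
    haplotype classes with the given probabilities, so the expected entropy
    is computable in closed form from the spectrum.
    """

    n_chrom: int = 120
    n_snps: int = 21
    spectrum: tuple[float, ...] = (1.0,)
    seed: int = 0
    chrom: str = "chr1"
    spacing_bp: int = 1000

    def __post_init__(self) -> None:
        if abs(sum(self.spectrum) - 1.0) > 1e-9:
            raise ValueError("haplotype class probabilities must sum to 1")
        if len(self.spectrum) > self.n_chrom:
            raise ValueError("more haplotype classes than chromosomes")
        if len(self.spectrum) > 2**self.n_snps:
            raise ValueError("spectrum infeasible: more classes than distinct haplotypes")


# --------------------------------------------------------------------------
# reading


def read_panel(source: PanelSource | str | Path) -> HaplotypePanel:
    """Load a phased panel, auto-detecting the dialect unless given."""
    if not isinstance(source, PanelSource):
        source = PanelSource(path=source)
    path = Path(source.path)
    dialect = source.dialect or sniff_dialect(path)
    if dialect == DIALECT_VCF:
        panel = _read_vcf(source)
    elif dialect == DIALECT_HAPMAP:
        panel = _read_hapmap_text(source)
    else:
        raise ValueError(f"unknown panel dialect {dialect!r}")
    logger.info("read %d SNPs x %d chromosomes from %s (%s)",
                panel.n_snps, panel.n_chrom, path, dialect)
    return panel


def sniff_dialect(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line.startswith("##fileformat=VCF") or line.startswith("#CHROM"):
                return DIALECT_VCF
            if line.startswith("#chrom=") or line.split()[0].lower() in {"rsid", "rs#"}:
                return DIALECT_HAPMAP
            break
    raise ValueError(f"cannot sniff panel dialect of {path}")


def _read_vcf(source: PanelSource) -> HaplotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(source.path))
    if source.samples is not None:
        vcf.set_samples(source.samples)
    it = vcf(source.region) if source.region else vcf
    chroms, pos, ids, rows = [], [], [], []
    drop = 0
    for v in it:
        gts = v.genotypes  # [a0, a1, phased] per sample
        allele_row = []
        missing = False
        for g in gts:
            *calls, phased = g
            if any(c < 0 for c in calls):
                missing = True
            if len(calls) > 1 and not phased and not missing:
                raise PanelError(
                    f"unphased genotype at {v.CHROM}:{v.POS} — panel must be phased ('|')"
                )
            allele_row.extend(calls)
        if missing:
            if source.drop_missing:
                drop += 1
                continue
            raise PanelError(f"missing call at {v.CHROM}:{v.POS}")
        chroms.append(v.CHROM)
        pos.append(v.POS)
        ids.append(v.ID or f"{v.CHROM}:{v.POS}")
        rows.append(allele_row)
    if drop:
        logger.info("dropped %d sites with missing calls", drop)
    return _build_sorted_panel(chroms, pos, ids, np.asarray(rows, dtype=np.int16))


def _read_hapmap_text(source: PanelSource) -> HaplotypePanel:
    path = Path(source.path)
    chrom = source.default_chrom
    header_cols: list[str] | None = None
    ids, pos, raw_rows = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#chrom="):
                chrom = line.split("=", 1)[1].strip()
                continue
            if line.startswith("#"):
                continue
            fields = line.split()
            if header_cols is None and not fields[1].isdigit():
                header_cols = fields
                continue
            ids.append(fields[0])
            pos.append(int(fields[1]))
            raw_rows.append(fields[2:])
    if not raw_rows:
        return HaplotypePanel(
            chrom=np.empty(0, dtype=object), pos=np.empty(0, dtype=np.int64),
            snp_id=np.empty(0, dtype=object), alleles=np.empty((0, 2), dtype=np.int8),
        )
    widths = {len(r) for r in raw_rows}
    if len(widths) != 1:
        raise PanelError("ragged rows: unequal chromosome column counts")
    coded, keep = _recode_rows(raw_rows, drop_missing=source.drop_missing)
    ids = [i for i, k in zip(ids, keep) if k]
    pos = [p for p, k in zip(pos, keep) if k]
    if source.samples is not None and header_cols is not None:
        name_by_col = header_cols[2:]
        cols = [i for i, n in enumerate(name_by_col) if n in source.samples]
        coded = coded[:, cols]
    return _build_sorted_panel([chrom] * len(ids), pos, ids, coded)


def _recode_rows(raw_rows: list[list[str]], drop_missing: bool) -> tuple[np.ndarray, list[bool]]:
    coded_rows: list[np.ndarray] = []
    keep: list[bool] = []
    for r, row in enumerate(raw_rows):
        symbols = set(row)
        if symbols & MISSING_TEXT:
            if drop_missing:
                keep.append(False)
                continue
            raise PanelError(f"missing allele call in row {r}")
        alphabet = sorted(symbols)
        if alphabet in (["0"], ["1"], ["0", "1"]):
            mapping = {"0": 0, "1": 1}  # already coded; preserve round trip
        else:
            mapping = {s: i for i, s in enumerate(alphabet)}  # lexicographic
        coded_rows.append(np.array([mapping[s] for s in row], dtype=np.int16))
        keep.append(True)
    coded = np.vstack(coded_rows) if coded_rows else np.empty((0, 0), dtype=np.int16)
    return coded, keep


def _build_sorted_panel(chroms, pos, ids, alleles) -> HaplotypePanel:
    chroms = np.asarray(chroms, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    ids = np.asarray(ids, dtype=object)
    order = np.lexsort((pos, chroms.astype(str)))
    chroms, pos, ids, alleles = chroms[order], pos[order], ids[order], alleles[order]
    dup = np.zeros(len(pos), dtype=bool)
    if len(pos) > 1:
        dup[1:] = (pos[1:] == pos[:-1]) & (chroms[1:] == chroms[:-1])
    if dup.any():
        i = int(np.argmax(dup))
        raise PanelError(f"duplicate position {chroms[i]}:{pos[i]}")
    biallelic = alleles.size == 0 or alleles.max() <= 1
    return HaplotypePanel(
        chrom=chroms, pos=pos, snp_id=ids,
        alleles=alleles.astype(np.int8 if biallelic else np.int16),
        biallelic=bool(biallelic),
    )


# --------------------------------------------------------------------------
# writing


def write_panel(panel: HaplotypePanel, path: str | Path, dialect: str = DIALECT_HAPMAP) -> None:
    """Write a panel so that :func:`read_panel` recovers it bit-exactly."""
    path = Path(path)
    if dialect == DIALECT_HAPMAP:
        _write_hapmap_text(panel, path)
    elif dialect == DIALECT_VCF:
        _write_vcf(panel, path)
    else:
        raise ValueError(f"unknown panel dialect {dialect!r}")


def _write_hapmap_text(panel: HaplotypePanel, path: Path) -> None:
    chrom_labels = {str(c) for c in panel.chrom}
    if len(chrom_labels) > 1:
        raise ValueError("the HapMap phased text dialect holds one chromosome per file")
    with open(path, "w") as fh:
        label = next(iter(chrom_labels)) if chrom_labels else "chr1"
        fh.write(f"#chrom={label}\n")
        names = " ".join(f"hap{i}" for i in range(panel.n_chrom))
        fh.write(f"rsID position_b36 {names}\n")
        for i in range(panel.n_snps):
            row = " ".join(str(int(a)) for a in panel.alleles[i])
            fh.write(f"{panel.snp_id[i]} {panel.pos[i]} {row}\n")


def _write_vcf(panel: HaplotypePanel, path: Path) -> None:
    if panel.n_chrom % 2:
        raise ValueError("VCF output needs an even number of chromosomes (diploid samples)")
    n_samples = panel.n_chrom // 2
    sample_names = [f"sample{i}" for i in range(n_samples)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(str(c) for c in panel.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names) + "\n")
        for i in range(panel.n_snps):
            gts = "\t".join(
                f"{panel.alleles[i, 2 * s]}|{panel.alleles[i, 2 * s + 1]}"
                for s in range(n_samples)
            )
            fh.write(
                f"{panel.chrom[i]}\t{panel.pos[i]}\t{panel.snp_id[i]}\tA\tC\t.\t.\t.\tGT\t{gts}\n"
            )


# --------------------------------------------------------------------------
# gene annotations


def read_gene_table(path: str | Path, fmt: str | None = None) -> GeneTable:
    """Read transcribed-region intervals from BED or GFF3.

    BED intervals (0-based, half-open) are converted to the internal
    1-based inclusive convention: start+1, end unchanged.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in {".gff", ".gff3"} else "bed"
    if fmt == "bed":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, usecols=[0, 1, 2, 3],
            names=["chrom", "start0", "end", "gene"],
        )
        out = pd.DataFrame(
            {"gene": df["gene"], "chrom": df["chrom"],
             "start": df["start0"] + 1, "end": df["end"]}
        )
    elif fmt == "gff3":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "source", "type", "start", "end",
                   "score", "strand", "phase", "attributes"],
        )
        df = df[df["type"].isin(["gene", "transcript", "mRNA"])]
        out = pd.DataFrame(
            {"gene": df["attributes"].map(_gff_name), "chrom": df["chrom"],
             "start": df["start"], "end": df["end"]}
        )
    else:
        raise ValueError(f"unknown gene table format {fmt!r}")
    return GeneTable(intervals=out.reset_index(drop=True))


def _gff_name(attributes: str) -> str:
    fields = dict(
        kv.split("=", 1) for kv in attributes.strip().split(";") if "=" in kv
    )
    for key in ("Name", "gene_name", "gene", "ID"):
        if key in fields:
            return fields[key]
    return attributes


# --------------------------------------------------------------------------
# fixtures


def generate_fixture(spec: FixtureSpec) -> HaplotypePanel:
    """Panel whose haplotype class structure is known by construction.

    Chromosomes are assigned to ``len(spectrum)`` distinct haplotype
    classes with the given probabilities; class patterns are distinct
    binary strings over the window, so windowed entropy equals the entropy
    of the realized class counts.
    """
    rng = np.random.default_rng(spec.seed)
    n_classes = len(spec.spectrum)
    patterns = _distinct_patterns(n_classes, spec.n_snps, rng)
    assignment = rng.choice(n_classes, size=spec.n_chrom, p=list(spec.spectrum))
    alleles = patterns[:, assignment]  # (n_snps, n_chrom)
    pos = (np.arange(spec.n_snps) + 1) * spec.spacing_bp
    return HaplotypePanel(
        chrom=np.full(spec.n_snps, spec.chrom, dtype=object),
        pos=pos,
        snp_id=np.array([f"fx{i}" for i in range(spec.n_snps)], dtype=object),
        alleles=alleles.astype(np.int8),
    )


def _distinct_patterns(n_classes: int, n_snps: int, rng: np.random.Generator) -> np.ndarray:
    """n_snps x n_classes binary matrix with distinct columns."""
    seen: set[tuple[int, ...]] = set()
    cols = []
    while len(cols) < n_classes:
        c = tuple(int(b) for b in rng.integers(0, 2, size=n_snps))
        if c not in seen:
            seen.add(c)
            cols.append(c)
    return np.array(cols, dtype=np.int8).T
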