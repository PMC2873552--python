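"""Two-population entropy-difference scan and downstream analyses.

The scan compares windowed haplotype entropy between two populations typed
on the same SNPs: dS = S_pop1 - S_pop2 per SNP. One population serves as
the neutral reference for the other, so extreme dS flags LD specific to the
lower-entropy population without needing a demographic model. Significance
is empirical: each dS is ranked within the genome-wide dS distribution
itself, one-sided within its own sign direction, with no multiple-testing
correction — the assumption being that most of the genome is neutral with
respect to differentiating the two populations. SNPs in the extreme tails
(default 0.1% per tail) are the candidate population-specific LD
signatures; they are mapped to genes through transcribed-region intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .entropy import EntropyTrack, WindowSpec, scan_entropy
from .panel import HaplotypePanel

__all__ = [
    "DeltaTrack",
    "GeneTable",
    "SignatureGene",
    "delta_scan",
    "empirical_pvalues",
    "select_signatures",
    "map_to_genes",
    "window_sweep",
    "compare_entropy_distributions",
    "overlap_test",
]

logger = logging.getLogger(__name__)

TAIL_NONE = "none"
TAIL_POP1 = "pop1_specific_LD"  # lower tail: pop1 entropy deficit
TAIL_POP2 = "pop2_specific_LD"  # upper tail: pop2 entropy deficit


@dataclass
class DeltaTrack:
    """Per-SNP entropy difference with empirical significance.

    ``dS`` and ``p_emp`` are NaN where either population's window was
    invalid. ``tail`` labels signature SNPs: the upper dS tail means the
    second population has the entropy deficit (LD specific to pop2), the
    lower tail conversely.
    """

    chrom: np.ndarray
    pos: np.ndarray
    snp_id: np.ndarray
    S_pop1: np.ndarray
    S_pop2: np.ndarray
    dS: np.ndarray
    valid: np.ndarray
    p_emp: np.ndarray | None = None
    tail: np.ndarray | None = None
    filter_counts: dict[str, int] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "snp_id": self.snp_id,
                "S_pop1": self.S_pop1,
                "S_pop2": self.S_pop2,
                "dS": self.dS,
            }
        )
        if self.p_emp is not None:
            df["p_emp"] = self.p_emp
        if self.tail is not None:
            df["tail"] = self.tail
        df["valid"] = self.valid
        return df

    def to_tsv(self, path) -> None:
        df = self.to_dataframe()
        for col in ("S_pop1", "S_pop2", "dS"):
            df[col] = df[col].map(lambda v: f"{v:.6f}" if np.isfinite(v) else "NA")
        if "p_emp" in df:
            df["p_emp"] = df["p_emp"].map(lambda v: f"{v:.6e}" if np.isfinite(v) else "NA")
        df.to_csv(path, sep="\t", index=False)


@dataclass
class GeneTable:
    """Transcribed-region intervals used to assign SNPs to genes.

    ``intervals`` columns: gene, chrom, start, end — 1-based inclusive on
    both ends. One gene may span several rows.
    """

    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "chrom", "start", "end"}
        if not required.issubset(self.intervals.columns):
            raise ValueError(f"gene table needs columns {sorted(required)}")
        bad = self.intervals["start"] > self.intervals["end"]
        if bad.any():
            raise ValueError("malformed gene interval: start > end")


@dataclass
class SignatureGene:
    gene: str
    chrom: str
    best_p: float
    n_snps: int
    population: str


def delta_scan(
    panel1: HaplotypePanel,
    panel2: HaplotypePanel,
    spec: WindowSpec = WindowSpec(),
    exclude_sex: bool = True,
    compute_p: bool = True,
    tail_fraction: float = 0.001,
) -> DeltaTrack:
    """Scan both panels and compute dS = S_pop1 - S_pop2 per jointly valid SNP."""
    if not panel1.same_sites(panel2):
        idx = _first_site_mismatch(panel1, panel2)
        raise ValueError(f"panels disagree on SNP set; first discordant site at row {idx}")
    t1 = scan_entropy(panel1, spec, exclude_sex=exclude_sex)
    t2 = scan_entropy(panel2, spec, exclude_sex=exclude_sex)
    return delta_from_tracks(t1, t2, compute_p=compute_p, tail_fraction=tail_fraction)


def delta_from_tracks(
    t1: EntropyTrack,
    t2: EntropyTrack,
    compute_p: bool = True,
    tail_fraction: float = 0.001,
) -> DeltaTrack:
    valid = t1.valid & t2.valid
    dS = np.where(valid, t1.S - t2.S, np.nan)
    track = DeltaTrack(
        chrom=t1.chrom,
        pos=t1.pos,
        snp_id=t1.snp_id,
        S_pop1=t1.S,
        S_pop2=t2.S,
        dS=dS,
        valid=valid,
        filter_counts={f"pop1_{k}": v for k, v in t1.filter_counts.items()}
        | {f"pop2_{k}": v for k, v in t2.filter_counts.items()},
    )
    if compute_p:
        p = np.full(len(dS), np.nan)
        p[valid] = empirical_pvalues(dS[valid])
        track.p_emp = p
        track.tail = _assign_tails(dS, p, valid, tail_fraction)
    return track


def _first_site_mismatch(p1: HaplotypePanel, p2: HaplotypePanel) -> int:
    n = min(p1.n_snps, p2.n_snps)
    for i in range(n):
        if (p1.chrom[i] != p2.chrom[i] or p1.pos[i] != p2.pos[i]
                or p1.snp_id[i] != p2.snp_id[i]):
            return i
    return n


def empirical_pvalues(values: np.ndarray) -> np.ndarray:
    """One-sided empirical rank p within the observed sign direction.

    For a value at or above the median, p = (# values >= it) / M; below the
    median, p = (# values <= it) / M. The most extreme value scores 1/M.
    """
    v = np.asarray(values, dtype=float)
    M = v.size
    if M < 1000:
        warnings.warn(
            f"only {M} values for the empirical null; tail p-values will be coarse",
            stacklevel=2,
        )
    if M == 0:
        return np.empty(0)
    order = np.sort(v)
    if order[0] == order[-1]:
        warnings.warn("degenerate distribution: all values identical; p = 1", stacklevel=2)
        return np.ones(M)
    med = np.median(v)
    n_ge = M - np.searchsorted(order, v, side="left")
    n_le = np.searchsorted(order, v, side="right")
    return np.where(v >= med, n_ge, n_le) / M


def _assign_tails(
    dS: np.ndarray, p: np.ndarray, valid: np.ndarray, tail_fraction: float
) -> np.ndarray:
    tail = np.full(len(dS), TAIL_NONE, dtype=object)
    if tail_fraction <= 0:
        return tail
    med = np.median(dS[valid]) if valid.any() else 0.0
    in_tail = valid & (p <= tail_fraction)
    tail[in_tail & (dS >= med)] = TAIL_POP2
    tail[in_tail & (dS < med)] = TAIL_POP1
    return tail


def select_signatures(
    track: DeltaTrack, tail_fraction: float = 0.001
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Signature SNP lists for the two tails (ties at the threshold included).

    Returns (pop1_specific, pop2_specific): the lower-dS tail flags LD
    specific to population 1, the upper tail LD specific to population 2.
    """
    if track.p_emp is None:
        raise ValueError("empirical p-values not computed on this track")
    df = track.to_dataframe()
    tail = _assign_tails(track.dS, track.p_emp, track.valid, tail_fraction)
    df["tail"] = tail
    pop1 = df[tail == TAIL_POP1].sort_values("p_emp").reset_index(drop=True)
    pop2 = df[tail == TAIL_POP2].sort_values("p_emp").reset_index(drop=True)
    logger.info("signatures at tail %.4g: %d pop1-specific, %d pop2-specific",
                tail_fraction, len(pop1), len(pop2))
    return pop1, pop2


def map_to_genes(
    snps: pd.DataFrame, genes: GeneTable, population: str = ""
) -> list[SignatureGene]:
    """Assign signature SNPs to every gene whose transcribed region contains them.

    ``snps`` needs columns chrom, pos, p_emp. Gene p is the minimum SNP p
    over mapped SNPs (``reduction='mean'`` not offered here; see
    :func:`map_to_genes_df`). Genes on chromosomes absent from the SNP set
    are skipped with a warning. Result sorted by best_p.
    """
    out: dict[str, SignatureGene] = {}
    snp_chroms = set(snps["chrom"])
    for (gene, chrom), rows in genes.intervals.groupby(["gene", "chrom"], sort=False):
        if chrom not in snp_chroms:
            logger.warning("gene %s on chromosome %r absent from SNP set; skipped", gene, chrom)
            continue
        sub = snps[snps["chrom"] == chrom]
        hit = np.zeros(len(sub), dtype=bool)
        for _, iv in rows.iterrows():
            hit |= (sub["pos"].to_numpy() >= iv["start"]) & (sub["pos"].to_numpy() <= iv["end"])
        if hit.any():
            mapped = sub[hit]
            out[gene] = SignatureGene(
                gene=gene,
                chrom=str(chrom),
                best_p=float(mapped["p_emp"].min()),
                n_snps=int(hit.sum()),
                population=population,
            )
    return sorted(out.values(), key=lambda g: g.best_p)


def map_to_genes_df(snps: pd.DataFrame, genes: GeneTable, population: str = "") -> pd.DataFrame:
    recs = map_to_genes(snps, genes, population)
    return pd.DataFrame(
        [(g.gene, g.chrom, g.best_p, g.n_snps, g.population) for g in recs],
        columns=["gene", "chrom", "best_p", "n_snps", "population"],
    )


def window_sweep(
    panel1: HaplotypePanel,
    panel2: HaplotypePanel,
    sizes: list[int],
    spec_template: WindowSpec = WindowSpec(),
    n_boot: int = 200,
    seed: int = 0,
    exclude_sex: bool = True,
) -> pd.DataFrame:
    """Median S per population (with bootstrap 95% CI), max S and median |dS|
    as a function of window size.

    Used to pick a working window: too small and windows hold little
    diversity, too large and every haplotype becomes unique (entropy
    saturation at log2(n)); the between-population difference peaks in
    between.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for w in sizes:
        if w % 2 == 0 or w < 1:
            raise ValueError(f"window sizes must be odd positive, got {w}")
        if w > panel1.n_snps:
            warnings.warn(f"window size {w} exceeds SNP count; skipped", stacklevel=2)
            continue
        spec = WindowSpec(w=w, max_span_bp=spec_template.max_span_bp)
        track = delta_scan(panel1, panel2, spec, exclude_sex=exclude_sex, compute_p=False)
        m = track.valid
        if not m.any():
            warnings.warn(f"window size {w}: no valid SNPs; skipped", stacklevel=2)
            continue
        s1, s2, d = track.S_pop1[m], track.S_pop2[m], track.dS[m]
        lo1, hi1 = _bootstrap_median_ci(s1, n_boot, rng)
        lo2, hi2 = _bootstrap_median_ci(s2, n_boot, rng)
        rows.append(
            {
                "w": w,
                "median_S_pop1": float(np.median(s1)),
                "ci_lo_pop1": lo1,
                "ci_hi_pop1": hi1,
                "median_S_pop2": float(np.median(s2)),
                "ci_lo_pop2": lo2,
                "ci_hi_pop2": hi2,
                "max_S": float(max(s1.max(), s2.max())),
                "median_abs_dS": float(np.median(np.abs(d))),
                "n_valid": int(m.sum()),
            }
        )
    return pd.DataFrame(rows)


def _bootstrap_median_ci(
    x: np.ndarray, n_boot: int, rng: np.random.Generator
) -> tuple[float, float]:
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    meds = np.median(x[idx], axis=1)
    return float(np.quantile(meds, 0.025)), float(np.quantile(meds, 0.975))


def compare_entropy_distributions(
    t1: EntropyTrack, t2: EntropyTrack
) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U between the valid S values of two tracks.

    Returns (U, p, label-of-greater-median-population).
    """
    s1 = t1.S[t1.valid]
    s2 = t2.S[t2.valid]
    if s1.size < 2 or s2.size < 2:
        raise ValueError("need at least 2 valid S values per population")
    u, p = stats.mannwhitneyu(s1, s2, alternative="two-sided")
    greater = "pop1" if np.median(s1) > np.median(s2) else "pop2"
    return float(u), float(p), greater


def overlap_test(
    list_a: list[str], list_b: list[str], universe_size: int, method: str = "chi2"
) -> dict:
    """Is the overlap between two gene lists larger than chance?

    Expected overlap under independence is |A||B|/U; the test is the 2x2
    chi-square (no continuity correction) over membership in each list.
    With expected counts below 5 the chi-square approximation is poor — a
    warning is issued and ``method='fisher'`` (one-sided enrichment) is
    available.
    """
    A = {g.upper() for g in list_a}
    B = {g.upper() for g in list_b}
    if universe_size < max(len(A), len(B)):
        raise ValueError("universe smaller than a gene list")
    observed = len(A & B)
    expected = len(A) * len(B) / universe_size
    table = np.array(
        [
            [observed, len(A) - observed],
            [len(B) - observed, universe_size - len(A) - len(B) + observed],
        ]
    )
    if expected < 5 and method == "chi2":
        warnings.warn(
            f"expected overlap {expected:.3g} < 5: chi-square approximation is rough; "
            "consider method='fisher'",
            stacklevel=2,
        )
    if method == "fisher":
        _, p = stats.fisher_exact(table, alternative="greater")
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {"expected": expected, "observed": observed, "p": float(p), "method": method}
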