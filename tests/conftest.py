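"""Shared fixtures: hand-built panels, random panels, and the scaled
gradient-recombination replicate set reused by the simulation-based checks."""

from __future__ import annotations

import numpy as np
import pytest

from hapentropy import (
    HaplotypePanel,
    SimConfig,
    WindowSpec,
    run_replicates,
    scan_entropy,
)
from hapentropy.ehh import scan_integrated_ehh


def make_panel(alleles, pos=None, chrom=None, ids=None, biallelic=True) -> HaplotypePanel:
    """Panel from an (n_snps x n_chrom) array with default metadata."""
    a = np.asarray(alleles)
    n = a.shape[0]
    return HaplotypePanel(
        chrom=np.asarray(chrom if chrom is not None else ["chr1"] * n, dtype=object),
        pos=np.asarray(pos if pos is not None else (np.arange(n) + 1) * 1000, dtype=np.int64),
        snp_id=np.asarray(ids if ids is not None else [f"rs{i}" for i in range(n)], dtype=object),
        alleles=a,
        biallelic=biallelic,
    )


def random_panel(rng: np.random.Generator, n_snps: int, n_chrom: int) -> HaplotypePanel:
    return make_panel(rng.integers(0, 2, size=(n_snps, n_chrom)).astype(np.int8))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def gradient_reps():
    """Ten scaled replicates of the gradient-recombination model chromosome
    with entropy scans (w=21 and w=5) and an integrated-EHH scan (w=21).

    N=1000 diploids, 1000 generations, 500 loci, 120 sampled chromosomes —
    the package's desk-scale rendition of the model-chromosome experiment.
    """
    cfg = SimConfig(L=500, N=1000, G=1000, mu=2.0e-9, n_sample=120, seed=42)
    results = run_replicates(cfg, reps=10)
    spec21 = WindowSpec(w=21, max_span_bp=10**9)
    spec5 = WindowSpec(w=5, max_span_bp=10**9)
    S21, S5, I21 = [], [], []
    for res in results:
        S21.append(scan_entropy(res.panel, spec21, exclude_sex=False).S)
        S5.append(scan_entropy(res.panel, spec5, exclude_sex=False).S)
        I21.append(scan_integrated_ehh(res.panel, spec21)["I"].to_numpy())
    return {
        "cfg": cfg,
        "results": results,
        "S21": np.vstack(S21),  # (reps, L), NaN at edges
        "S5": np.vstack(S5),
        "I21": np.vstack(I21),
    }
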