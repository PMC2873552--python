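"""Windowed haplotype entropy: examples, filters and invariance properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapentropy import (
    HaplotypeCounts,
    WindowSpec,
    count_window_haplotypes,
    entropy,
    entropy_difference,
    scan_entropy,
)
from hapentropy.panel import PanelError, HaplotypePanel

from conftest import make_panel, random_panel
from oracles import entropy_oracle, windowed_entropy_oracle


class TestWindowCounting:
    def test_identical_chromosomes_collapse_to_one_class(self):
        panel = make_panel(np.zeros((3, 4), dtype=np.int8))
        counts = count_window_haplotypes(panel, 1, WindowSpec(w=3))
        assert counts.counts == {"000": 4}
        assert counts.n == 4

    def test_pairwise_distinct_chromosomes_are_all_singletons(self):
        # 4 distinct columns over 3 SNPs
        panel = make_panel(np.array([[0, 0, 1, 1], [0, 1, 0, 1], [0, 0, 0, 1]], dtype=np.int8))
        counts = count_window_haplotypes(panel, 1, WindowSpec(w=3))
        assert len(counts.counts) == 4
        assert set(counts.counts.values()) == {1}

    def test_mixed_window_tally_matches_hand_count(self):
        # chromosomes (rows here transposed): 3x"000", 2x"010", 1x"111"
        chroms = np.array(
            [[0, 0, 0], [0, 0, 0], [0, 0, 0], [0, 1, 0], [0, 1, 0], [1, 1, 1]], dtype=np.int8
        ).T
        panel = make_panel(chroms)
        counts = count_window_haplotypes(panel, 1, WindowSpec(w=3))
        assert counts.counts == {"000": 3, "010": 2, "111": 1}

    def test_window_past_edge_raises(self):
        panel = make_panel(np.zeros((5, 4), dtype=np.int8))
        with pytest.raises(IndexError):
            count_window_haplotypes(panel, 0, WindowSpec(w=3))

    def test_window_across_chromosome_boundary_raises(self):
        panel = make_panel(
            np.zeros((4, 4), dtype=np.int8),
            chrom=["chr1", "chr1", "chr2", "chr2"],
            pos=[100, 200, 100, 200],
        )
        with pytest.raises(ValueError, match="boundary"):
            count_window_haplotypes(panel, 2, WindowSpec(w=3))


class TestEntropy:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"h": 120}, 0.0),  # all haplotypes identical
            ({f"h{i}": 1 for i in range(120)}, math.log2(120)),  # all distinct
            ({"a": 2, "b": 1, "c": 1}, 1.5),
            ({"a": 90, "b": 30}, 0.8112781244591328),
        ],
    )
    def test_known_values(self, counts, expected):
        assert entropy(counts) == pytest.approx(expected, abs=1e-12)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            entropy({})
        with pytest.raises(ValueError):
            entropy(HaplotypeCounts(counts={}, n=0))

    @settings(max_examples=300, derandomize=True)
    @given(
        st.lists(st.integers(min_value=1, max_value=500), min_size=1, max_size=40)
    )
    def test_matches_brute_force_oracle(self, raw_counts):
        counts = {f"h{i}": c for i, c in enumerate(raw_counts)}
        assert entropy(counts) == pytest.approx(entropy_oracle(counts), abs=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(st.integers(min_value=1, max_value=200), min_size=2, max_size=20),
        st.data(),
    )
    def test_merging_two_classes_never_increases_entropy(self, raw_counts, data):
        counts = {f"h{i}": c for i, c in enumerate(raw_counts)}
        i = data.draw(st.integers(0, len(raw_counts) - 2))
        merged = dict(counts)
        merged[f"h{i}"] = merged[f"h{i}"] + merged.pop(f"h{i + 1}")
        assert entropy(merged) <= entropy(counts) + 1e-12

    def test_entropy_bounds_on_random_windows(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 30))
            panel = random_panel(rng, 5, n)
            s = entropy(count_window_haplotypes(panel, 2, WindowSpec(w=5)))
            assert -1e-12 <= s <= math.log2(n) + 1e-12


class TestEntropyDifference:
    def test_identity_and_antisymmetry(self):
        assert entropy_difference(3.2, 3.2) == 0.0
        assert entropy_difference(5.0, 2.0) == 3.0
        assert entropy_difference(2.0, 5.0) == -3.0

    def test_limit_case_span(self):
        assert entropy_difference(math.log2(120), 0.0) == pytest.approx(6.906890595608519)

    def test_nan_propagates(self):
        assert np.isnan(entropy_difference(float("nan"), 1.0))


class TestScan:
    def test_edge_arithmetic_100_snps_w21(self, rng):
        panel = random_panel(rng, 100, 10)
        track = scan_entropy(panel, WindowSpec(w=21, max_span_bp=10**9), exclude_sex=False)
        assert int(track.valid.sum()) == 80
        assert not track.valid[:10].any() and not track.valid[-10:].any()
        assert track.filter_counts["edge_skipped"] == 20

    def test_long_span_windows_excluded(self, rng):
        pos = (np.arange(30) + 1) * 1000
        pos[15:] += 250_000  # a 250 kb gap between SNP 14 and 15
        panel = make_panel(rng.integers(0, 2, (30, 8)).astype(np.int8), pos=pos)
        track = scan_entropy(panel, WindowSpec(w=5, max_span_bp=200_000), exclude_sex=False)
        straddle = [i for i in range(2, 28) if pos[i + 2] - pos[i - 2] > 200_000]
        assert straddle  # the fixture does create offending windows
        assert not track.valid[straddle].any()
        assert track.filter_counts["span_excluded"] == len(straddle)
        kept = [i for i in range(2, 28) if i not in straddle]
        assert track.valid[kept].all()

    def test_all_identical_panel_scores_zero(self):
        panel = make_panel(np.ones((40, 6), dtype=np.int8))
        track = scan_entropy(panel, WindowSpec(w=5, max_span_bp=10**9), exclude_sex=False)
        assert np.allclose(track.S[track.valid], 0.0)

    def test_sex_chromosomes_excluded_when_flagged(self, rng):
        a = rng.integers(0, 2, (40, 6)).astype(np.int8)
        chrom = ["chr2"] * 20 + ["chrX"] * 20
        pos = list(range(1000, 21000, 1000)) * 2
        panel = make_panel(a, chrom=chrom, pos=pos)
        track = scan_entropy(panel, WindowSpec(w=5, max_span_bp=10**9), exclude_sex=True)
        assert not track.valid[20:].any()
        assert track.filter_counts["sex_excluded"] == 20
        track2 = scan_entropy(panel, WindowSpec(w=5, max_span_bp=10**9), exclude_sex=False)
        assert track2.valid[20:].sum() == 16

    def test_column_permutation_leaves_track_unchanged(self, rng):
        panel = random_panel(rng, 30, 12)
        perm = rng.permutation(12)
        permuted = panel.take_chromosomes(perm)
        spec = WindowSpec(w=5, max_span_bp=10**9)
        t1 = scan_entropy(panel, spec, exclude_sex=False)
        t2 = scan_entropy(permuted, spec, exclude_sex=False)
        np.testing.assert_array_equal(t1.valid, t2.valid)
        np.testing.assert_allclose(t1.S[t1.valid], t2.S[t2.valid], atol=1e-12)

    def test_duplicating_every_chromosome_leaves_entropy_unchanged(self, rng):
        panel = random_panel(rng, 30, 9)
        doubled = make_panel(np.hstack([panel.alleles, panel.alleles]))
        spec = WindowSpec(w=5, max_span_bp=10**9)
        t1 = scan_entropy(panel, spec, exclude_sex=False)
        t2 = scan_entropy(doubled, spec, exclude_sex=False)
        np.testing.assert_allclose(t1.S[t1.valid], t2.S[t2.valid], atol=1e-12)

    def test_scan_matches_windowed_oracle(self, rng):
        panel = random_panel(rng, 25, 10)
        track = scan_entropy(panel, WindowSpec(w=7, max_span_bp=10**9), exclude_sex=False)
        for c in np.flatnonzero(track.valid):
            assert track.S[c] == pytest.approx(
                windowed_entropy_oracle(panel.alleles, c, 7), abs=1e-12
            )

    def test_unsorted_panel_rejected_at_construction(self):
        with pytest.raises(PanelError, match="not strictly increasing"):
            make_panel(np.zeros((3, 4), dtype=np.int8), pos=[300, 200, 100])
        with pytest.raises(PanelError, match="not sorted"):
            HaplotypePanel(
                chrom=np.array(["chr1", "chr2", "chr1"], dtype=object),
                pos=np.array([1, 1, 2]),
                snp_id=np.array(["a", "b", "c"], dtype=object),
                alleles=np.zeros((3, 4), dtype=np.int8),
            )


def test_even_or_nonpositive_window_rejected():
    with pytest.raises(ValueError):
        WindowSpec(w=20)
    with pytest.raises(ValueError):
        WindowSpec(w=-3)
    with pytest.raises(ValueError):
        WindowSpec(w=21, max_span_bp=0)
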