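"""Window extension, merging, FDR adjustment, FPR permutation, locus calling
and phasiRNA extraction."""

import numpy as np
import pytest

from phasikit.io_formats import ReadPlacement, UniqueRead
from phasikit.loci import (
    Interval,
    PhasLocus,
    adjust_intervals,
    adjust_pvalues,
    call_loci,
    estimate_fpr,
    extend_windows,
    extract_phasirnas,
    merge_windows,
    phasirna_count_matrix,
)
from phasikit.phasing import PhaseParams, PhaseWindow, scan_genome


def window(contig="c", start=1000, cycle=21, p=0.01, score=8.0, n=10, k=10):
    return PhaseWindow(
        contig=contig, start=start, cycle=cycle, n=n, k=k, p_value=p,
        max_phase_score=score, window=cycle * 10,
    )


def interval(contig="c", start=900, end=1309, cycle=21, p=0.01, anchor=1000, score=8.0):
    return Interval(
        contig=contig, start=start, end=end, cycle=cycle, p_value=p,
        anchor=anchor, max_phase_score=score,
    )


class TestExtendWindows:
    def test_stated_extension(self):
        out = extend_windows([window(start=1000, p=0.01)], {"c": 10_000})
        assert (out[0].start, out[0].end) == (900, 1309)

    def test_edge_clamp(self):
        out = extend_windows([window(start=50, p=0.01)], {"c": 300})
        assert (out[0].start, out[0].end) == (1, 300)

    def test_gate_excludes_non_significant(self):
        assert extend_windows([window(p=0.2)], {"c": 10_000}) == []
        assert extend_windows([window(p=0.05)], {"c": 10_000}) == []


class TestMergeWindows:
    def test_min_p_retained(self):
        merged = merge_windows(
            [interval(start=900, end=1310, p=0.01), interval(start=1050, end=1460, p=0.001)]
        )
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end, merged[0].p_value) == (900, 1460, 0.001)

    def test_disjoint_unchanged_and_cycle_separated(self):
        a, b = interval(end=1000), interval(start=2000, end=2500)
        assert len(merge_windows([a, b])) == 2
        c24 = interval(cycle=24)
        assert len(merge_windows([interval(), c24])) == 2

    def test_idempotence(self):
        ivs = [interval(start=s, end=s + 400, p=0.05 / (i + 1)) for i, s in enumerate(range(900, 2100, 300))]
        once = merge_windows(ivs)
        twice = merge_windows(once)
        assert [(m.start, m.end, m.p_value) for m in once] == [
            (m.start, m.end, m.p_value) for m in twice
        ]

    def test_anchor_follows_min_p_member(self):
        a = interval(p=0.01, anchor=1000)
        b = interval(start=1100, end=1500, p=0.001, anchor=1200)
        assert merge_windows([a, b])[0].anchor == 1200


class TestAdjustPvalues:
    def test_hand_computed_bh(self):
        adjusted = adjust_pvalues([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adjusted, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_ties(self):
        assert adjust_pvalues([0.03])[0] == pytest.approx(0.03)
        assert np.allclose(adjust_pvalues([0.02, 0.02, 0.02]), 0.02)

    def test_reference_universe_padding(self):
        """An interval's adjusted value accounts for all tests scanned, not
        only those surviving the extension gate."""
        ivs = [interval(p=1e-4)]
        adjust_intervals(ivs, {21: [1e-4] + [1.0] * 9999})
        assert ivs[0].p_adjusted == pytest.approx(1e-4 * 10_000 / 1, rel=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([])


class TestCallLoci:
    def make(self, score, p_adj):
        iv = interval(score=score)
        iv.p_adjusted = p_adj
        return iv

    def test_threshold_logic_is_strict(self):
        assert len(call_loci([self.make(6.1, 0.01)])) == 1
        assert call_loci([self.make(5.0, 0.01)]) == []
        assert call_loci([self.make(8.0, 0.06)]) == []

    def test_naming_serials_per_contig_in_coordinate_order(self):
        ivs = []
        for contig, start in [("c2", 5000), ("c1", 3000), ("c1", 500)]:
            iv = interval(contig=contig, start=start, end=start + 400)
            iv.p_adjusted = 0.001
            ivs.append(iv)
        names = [l.name for l in call_loci(ivs)]
        assert names == ["PHAS_c1_1", "PHAS_c1_2", "PHAS_c2_1"]
        # pure function of coordinates: re-calling gives identical names
        assert [l.name for l in call_loci(ivs)] == names


def phased_placements(contig="c", p1=1000, m=10, cycle=21, count=5, gap_at=None):
    pls = []
    for j in range(m):
        if j == gap_at:
            continue
        seq = "".join("ACGT"[(j * 7 + i) % 4] for i in range(cycle))
        pls.append(ReadPlacement(UniqueRead(seq, {"l": count}), contig, p1 + j * cycle, "+"))
    return pls


class TestExtractPhasirnas:
    def locus(self, start=900, end=1400, anchor=1000):
        return PhasLocus(
            name="PHAS_c_1", contig="c", start=start, end=end, cycle=21,
            p_value=1e-9, p_adjusted=1e-7, max_phase_score=20, anchor=anchor,
        )

    def test_noise_free_extraction_and_numbering(self):
        pls = phased_placements()
        out = extract_phasirnas(self.locus(), pls)
        assert [p.name for p in out] == [f"PHAS_c_1_siR{i}" for i in range(1, 11)]
        assert all(p.position % 21 == 1000 % 21 for p in out)
        assert out[0].register_name == "PHAS_c_1_D1(+)"

    def test_duplex_doubles_phasirnas(self):
        pls = phased_placements()
        pls += [
            ReadPlacement(UniqueRead("G" * 21, {"l": 1}), "c", p.start - 2, "-")
            for p in list(pls)
        ]
        assert len(extract_phasirnas(self.locus(), pls)) == 20

    def test_gap_keeps_numbering_dense(self):
        out = extract_phasirnas(self.locus(), phased_placements(gap_at=3))
        assert len(out) == 9
        assert [p.name for p in out] == [f"PHAS_c_1_siR{i}" for i in range(1, 10)]

    def test_empty_register(self):
        assert extract_phasirnas(self.locus(anchor=1005), phased_placements()) == []

    def test_count_matrix_shape(self):
        locus = self.locus()
        locus.phasirnas = extract_phasirnas(locus, phased_placements())
        mat = phasirna_count_matrix([locus])
        assert mat.shape == (10, 1)
        assert (mat["l"] == 5).all()


class TestEstimateFpr:
    P = PhaseParams(cycle=21)

    def test_perfectly_phased_interval_has_tiny_fpr(self):
        pls = phased_placements(p1=1000, count=5)
        iv = interval(start=900, end=1309, p=1e-12, anchor=1000)
        fpr = estimate_fpr(iv, pls, self.P, n_permutations=1000, seed=7)
        assert fpr <= 0.01

    def test_uniform_interval_fpr_is_calibrated(self):
        """On unstructured reads the observed best-window p is typical of
        the permutation distribution: median FPR over seeds is central."""
        rng = np.random.default_rng(11)
        fprs = []
        for seed in range(9):
            starts = rng.integers(900, 1500, size=25)
            pls = [
                ReadPlacement(UniqueRead("A" * 21, {"l": 1}), "c", int(s), "+")
                for s in starts
            ]
            from phasikit.loci import _best_window_p
            from phasikit.phasing import aggregate_occupancy

            occ = aggregate_occupancy(pls, 21)["c"]
            observed = _best_window_p(occ.positions, occ.abundance, 900, 1520, self.P)
            iv = interval(start=900, end=1520, p=observed)
            fprs.append(estimate_fpr(iv, pls, self.P, n_permutations=100, seed=seed))
        assert 0.2 <= float(np.median(fprs)) <= 0.8

    def test_permutation_floor(self):
        with pytest.raises(ValueError):
            estimate_fpr(interval(), [], self.P, n_permutations=0, seed=1)
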