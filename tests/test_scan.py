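"""Binomial scan statistics, FDR, and interval/block estimation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import dmimap as dm
from dmimap.scan import ScanResult


def exact_binomial_tail(k, n, p0):
    """Independent oracle: direct enumeration of the binomial pmf."""
    return sum(math.comb(n, j) * p0 ** j * (1 - p0) ** (n - j)
               for j in range(k, n + 1))


def bh_oracle(p):
    """Hand-rolled Benjamini-Hochberg step-up."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[idx] * m / rank)
        q[idx] = prev
    return q


def make_scan(k_by_locus, positions=None, chromosomes=None, n=10, p0=0.05,
              alpha=0.05):
    k = np.asarray(k_by_locus, dtype=int)
    m = len(k)
    pos = np.asarray(positions if positions is not None
                     else np.arange(1, m + 1) * 2080)
    chrom = np.asarray(chromosomes if chromosomes is not None
                       else np.zeros(m, dtype=int))
    p = dm.binomial_tail(k, n, p0)
    q = dm.fdr_adjust(p)
    return ScanResult(chromosome=chrom, position=pos, k=k, p=p, q=q,
                      significant=q < alpha, n_pops=n, p0=p0, alpha=alpha)


class TestBinomialTail:
    def test_zero_count_has_probability_one(self):
        assert dm.binomial_tail(0, 10, 0.05) == 1.0

    def test_all_populations_extreme(self):
        assert dm.binomial_tail(10, 10, 0.05) == pytest.approx(0.05 ** 10, rel=1e-9)

    def test_two_of_five_example(self):
        expected = 1 - 0.95 ** 5 - 5 * 0.05 * 0.95 ** 4
        assert dm.binomial_tail(2, 5, 0.05) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.02259, abs=5e-6)

    @pytest.mark.parametrize("n", [3, 5, 10])
    def test_matches_exhaustive_enumeration(self, n):
        for k in range(n + 1):
            assert dm.binomial_tail(k, n, 0.05) == \
                pytest.approx(exact_binomial_tail(k, n, 0.05), rel=1e-10)

    @given(n=st.integers(1, 20), p0=st.floats(0.01, 0.5))
    def test_monotone_in_k(self, n, p0):
        p = dm.binomial_tail(np.arange(n + 1), n, p0)
        assert (np.diff(p) < 0).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dm.binomial_tail(11, 10, 0.05)
        with pytest.raises(ValueError):
            dm.binomial_tail(1, 10, 0.0)


class TestFDR:
    def test_textbook_example(self):
        q = dm.fdr_adjust([0.01, 0.02, 0.9])
        assert q == pytest.approx([0.03, 0.03, 0.9])

    def test_equal_and_single_pvalues_unchanged(self):
        assert dm.fdr_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)
        assert dm.fdr_adjust([0.07]) == pytest.approx([0.07])

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=40))
    def test_matches_hand_rolled_bh(self, p):
        assert dm.fdr_adjust(p) == pytest.approx(bh_oracle(p), rel=1e-9)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(0)
        p = rng.random(100)
        assert (dm.fdr_adjust(p) >= p - 1e-12).all()


class TestTwoLocusEstimation:
    def test_support_drop_selects_loci_within_two_logs(self):
        # -log10 p profile ~ (.., 9.5, 11, 12, 11, 9.5, ..) via crafted k
        # values is hard with discrete k; craft ScanResult directly instead.
        nl10 = np.array([1, 9.5, 11, 12, 11, 9.5, 1, 12.5, 1], dtype=float)
        chrom = np.array([0] * 7 + [1] * 2)
        pos = np.array([1, 2, 3, 4, 5, 6, 7, 1, 2]) * 1000
        p = 10.0 ** -nl10
        scan = ScanResult(chromosome=chrom, position=pos, k=np.zeros(9, int),
                          p=p, q=p, significant=p < 1e-5, n_pops=10,
                          p0=0.05, alpha=0.05)
        ests = dm.estimate_two_locus(scan, support_drop=2.0, method="drop")
        assert ests is not None
        assert (ests[0].start, ests[0].end) == (3000, 5000)
        assert ests[0].peak_position == 4000
        assert (ests[1].start, ests[1].end) == (1000, 1000)  # single locus

    def test_block_method_takes_contiguous_significant_run(self):
        # significant loci 1..3 are contiguous around the peak; the isolated
        # significant locus at index 5 does not stretch the interval
        k = [0, 6, 10, 6, 0, 6, 0] + [10, 0]
        scan = make_scan(k, chromosomes=[0] * 7 + [1] * 2)
        assert scan.significant[[1, 2, 3, 5, 7]].all()
        ests = dm.estimate_two_locus(scan, method="block")
        assert (ests[0].start, ests[0].end) == (2 * 2080, 4 * 2080)
        assert ests[0].n_loci == 3
        assert (ests[1].start, ests[1].end) == (8 * 2080, 8 * 2080)

    def test_block_and_drop_agree_on_a_single_plateau(self):
        k = [0, 10, 10, 10, 0] + [0, 10, 0]
        scan = make_scan(k, chromosomes=[0] * 5 + [1] * 3)
        block = dm.estimate_two_locus(scan, method="block")
        drop = dm.estimate_two_locus(scan, method="drop")
        assert [(e.start, e.end) for e in block] == [(e.start, e.end) for e in drop]

    def test_no_call_when_one_chromosome_is_silent(self):
        k = [0, 10, 0] + [0, 1, 0]
        scan = make_scan(k, chromosomes=[0, 0, 0, 1, 1, 1])
        assert scan.significant[1] and not scan.significant[4]
        assert dm.estimate_two_locus(scan) is None

    def test_intervals_on_both_chromosomes(self):
        k = [0, 10, 10, 0] + [0, 10, 0, 0]
        scan = make_scan(k, chromosomes=[0] * 4 + [1] * 4)
        ests = dm.estimate_two_locus(scan)
        assert [e.chromosome for e in ests] == [0, 1]
        for e in ests:
            assert e.mode == "two_locus" and e.start <= e.end

    def test_natural_log_base_widens_the_drop(self):
        nl10 = np.array([5.0, 9.0, 5.0, 9.0])
        p = 10.0 ** -nl10
        scan = ScanResult(chromosome=np.array([0, 0, 1, 1]),
                          position=np.array([1000, 2000, 1000, 2000]),
                          k=np.zeros(4, int), p=p, q=p,
                          significant=np.array([False, True, False, True]),
                          n_pops=10, p0=0.05, alpha=0.05)
        in10 = dm.estimate_two_locus(scan, support_drop=2.0, log_base="10",
                                     method="drop")
        ine = dm.estimate_two_locus(scan, support_drop=2.0, log_base="e",
                                    method="drop")
        assert in10[0].width == 0          # 4 logs10 below peak: excluded
        assert ine[0].width == 0           # 2 natural logs ~ 0.87 log10: excluded
        wide = dm.estimate_two_locus(scan, support_drop=10.0, log_base="e",
                                     method="drop")
        assert wide[0].width == 1000       # 10 nat logs ~ 4.3 log10: included


class TestMultiLocusEstimation:
    def test_adjacent_pair_forms_one_block(self):
        scan = make_scan([0, 10, 10, 0, 0], positions=[104160 - 4160, 104160,
                                                       108320, 112480, 116640])
        blocks = dm.estimate_multi_locus(scan)
        assert len(blocks) == 1
        assert (blocks[0].start, blocks[0].end) == (104160, 108320)

    def test_isolated_single_locus_is_discarded(self):
        blocks = dm.estimate_multi_locus(make_scan([0, 10, 0, 0, 0]))
        assert blocks == []

    def test_merge_threshold_at_6240_bp(self):
        # two 2-locus runs separated by one quiet locus; end-to-start gap 5000
        pos = [1000, 2000, 4500, 7000, 8000]
        blocks = dm.estimate_multi_locus(make_scan([10, 10, 0, 10, 10], positions=pos))
        assert len(blocks) == 1 and (blocks[0].start, blocks[0].end) == (1000, 8000)
        # same structure with a 10,000 bp gap: stays two estimates
        pos = [1000, 2000, 6000, 12000, 13000]
        blocks = dm.estimate_multi_locus(make_scan([10, 10, 0, 10, 10], positions=pos))
        assert [(b.start, b.end) for b in blocks] == [(1000, 2000), (12000, 13000)]

    def test_blocks_never_cross_chromosomes(self):
        scan = make_scan([10, 10, 10, 10], positions=[19_000, 20_000, 1000, 2000],
                         chromosomes=[0, 0, 1, 1])
        blocks = dm.estimate_multi_locus(scan)
        assert [(b.chromosome, b.start, b.end) for b in blocks] == \
            [(0, 19_000, 20_000), (1, 1000, 2000)]

    @given(st.lists(st.booleans(), min_size=2, max_size=60))
    def test_merging_is_idempotent(self, sig):
        m = len(sig)
        scan = make_scan([10 if s else 0 for s in sig],
                         positions=np.arange(1, m + 1) * 2080)
        blocks = dm.estimate_multi_locus(scan)
        # re-merging changes nothing: all surviving gaps exceed the threshold
        for b1, b2 in zip(blocks, blocks[1:]):
            assert b2.start - b1.end > 6240
        for b in blocks:
            assert b.n_loci >= 2 and b.start <= b.end

    def test_monotone_k_never_increases_p(self, two_locus_envelope):
        p = dm.binomial_tail(np.arange(11), 10, 0.05)
        assert (np.diff(p) < 0).all()


class TestScanFrequencies:
    def test_counts_extreme_populations_per_locus(self):
        from dmimap.drift import DriftEnvelope

        env = DriftEnvelope(chromosome=np.zeros(4, int),
                            position=np.arange(1, 5) * 100, generations=(10,),
                            lower=np.full((1, 4), 0.3), upper=np.full((1, 4), 0.7),
                            n_neutral_sims=100)
        freqs = np.array([
            [0.9, 0.5, 0.2, 0.5],
            [0.8, 0.5, 0.5, 0.5],
            [0.9, 0.5, 0.5, 0.7],   # 0.7 is on the bound: not extreme
        ])
        scan = dm.scan_frequencies(freqs, env, 10, p0=0.05, alpha=0.05)
        assert scan.k.tolist() == [3, 0, 1, 0]
        assert scan.n_pops == 3
        assert scan.p[1] == 1.0
        assert scan.significant[0] and not scan.significant[2]
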