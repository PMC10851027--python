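"""Numba kernel for the Wright-Fisher reproduction step.

Haplotypes are bit-packed: column (locus) ``c`` lives in word ``c // 64``,
bit ``c % 64`` (little-endian), so a gamete is assembled from its two
parental haplotypes with word-level masking. A crossover at column ``c``
toggles which parent supplies all loci at columns >= c on that chromosome;
the parity mask is built by XOR-ing precomputed suffix masks, one per
crossover, restricted to the chromosome span.

Crossover counts are Poisson with mean equal to the chromosome's map
integral (no interference); counts are capped at 63 per chromosome per
meiosis, far beyond any realistic draw for map lengths ~1 Morgan.
"""

import numpy as np
from numba import njit

_MAX_XO = 63


@njit(cache=True)
def reproduce(haps, cum_w, chrom_starts, chrom_ends, cum_map, map_bp,
              map_rate, map_total, col_pos, suffix, rng, out):
    """One generation of fitness-proportional Wright-Fisher reproduction.

    haps : (2N, n_words) uint64, rows 2i/2i+1 are individual i's haplotypes
    cum_w : (N,) cumulative fitness weights (strictly positive total)
    chrom_starts/ends : per-chromosome half-open column ranges
    cum_map/map_bp/map_rate/map_total : piecewise recombination map per
        chromosome (cumulative crossovers, segment start bp, per-bp rate,
        map integral)
    col_pos : (n_loci,) locus bp positions (float), sorted within chromosome
    suffix : (n_loci+1, n_words) uint64; suffix[c] has bits c..n_loci-1 set
    out : (2N, n_words) uint64, overwritten with the offspring haplotypes
    """
    n2 = haps.shape[0]
    nw = haps.shape[1]
    n = n2 // 2
    ncr = len(chrom_starts)
    total_w = cum_w[n - 1]
    mask = np.empty(nw, dtype=np.uint64)
    xo = np.empty(_MAX_XO, dtype=np.int64)
    for i in range(n):
        p1 = np.searchsorted(cum_w, rng.random() * total_w)
        p2 = np.searchsorted(cum_w, rng.random() * total_w)
        while p2 == p1:
            p2 = np.searchsorted(cum_w, rng.random() * total_w)
        for which in range(2):
            par = p1 if which == 0 else p2
            row = 2 * par
            g = 2 * i + which
            for w in range(nw):
                mask[w] = np.uint64(0)
            for c in range(ncr):
                lo = chrom_starts[c]
                hi = chrom_ends[c]
                # independent assortment: fair-coin starting haplotype
                if rng.random() < 0.5:
                    for w in range(nw):
                        mask[w] ^= suffix[lo, w] ^ suffix[hi, w]
                k = rng.poisson(map_total[c])
                if k > _MAX_XO:
                    k = _MAX_XO
                for j in range(k):
                    u = rng.random() * map_total[c]
                    seg = np.searchsorted(cum_map[c], u, side="right") - 1
                    if seg < 0:
                        seg = 0
                    bp = map_bp[c, seg] + (u - cum_map[c, seg]) / map_rate[c, seg]
                    col = lo + np.searchsorted(col_pos[lo:hi], bp)
                    xo[j] = col
                for j in range(k):
                    for w in range(nw):
                        mask[w] ^= suffix[xo[j], w] ^ suffix[hi, w]
            for w in range(nw):
                m = mask[w]
                out[g, w] = (haps[row, w] & ~m) | (haps[row + 1, w] & m)


def make_suffix_masks(n_loci: int) -> np.ndarray:
    """suffix[c, w] = bits set for all locus columns >= c inside word w."""
    nw = (n_loci + 63) // 64
    ones = np.uint64(0xFFFFFFFFFFFFFFFF)
    suf = np.zeros((n_loci + 1, nw), dtype=np.uint64)
    for c in range(n_loci + 1):
        w = c // 64
        if w < nw:
            suf[c, w] = ones << np.uint64(c % 64)
            suf[c, w + 1:] = ones
    return suf
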