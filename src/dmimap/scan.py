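"""Binomial scan for parallel extreme allele-frequency change.

Across a set of replicate populations, each locus gets a count ``k`` of
populations whose frequency is extreme relative to the neutral drift
envelope. Under neutrality each population is extreme with probability
``p0`` (the envelope's tail probability, 0.05), so the upper-tail binomial
probability P(X >= k), X ~ Binomial(n_pops, p0), measures how surprising
parallel extremeness is. P-values are Benjamini-Hochberg adjusted across
all scanned loci genome-wide; loci with q < alpha are "significant".

Two estimation modes turn significant loci into mapped intervals:

* two-locus: per chromosome, an interval around the locus with the maximum
  -log10(p). The default ``block`` rule takes the maximal run of contiguous
  significant loci containing that peak; the ``drop`` rule instead spans all
  loci on the chromosome whose -log10(p) lies within ``support_drop``
  (default 2, a LOD-style ~95% support interval) of the maximum. No
  estimate at all is made unless *both* chromosomes carry at least one
  significant locus.
* multi-locus: maximal runs of consecutive significant loci with at least
  ``min_loci`` members become blocks; blocks closer than ``merge_bp``
  (end-to-start, inclusive) are merged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .drift import DriftEnvelope, flag_extreme

__all__ = [
    "ScanResult",
    "DMIEstimate",
    "binomial_tail",
    "fdr_adjust",
    "scan_frequencies",
    "estimate_two_locus",
    "estimate_multi_locus",
]


def binomial_tail(k, n: int, p0: float):
    """Upper-tail binomial probability P(X >= k) with X ~ Binomial(n, p0)."""
    k_arr = np.asarray(k)
    if np.any(k_arr < 0) or np.any(k_arr > n) or n < 1:
        raise ValueError("need 0 <= k <= n with n >= 1")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    p = stats.binom.sf(k_arr - 1, n, p0)
    return float(p) if np.isscalar(k) else p


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ScanResult:
    """Per-locus scan statistics across one set of replicate populations."""

    chromosome: np.ndarray
    position: np.ndarray
    k: np.ndarray           # populations flagged extreme
    p: np.ndarray           # binomial upper-tail probability
    q: np.ndarray           # BH-adjusted
    significant: np.ndarray  # q < alpha (strict)
    n_pops: int
    p0: float
    alpha: float

    @property
    def neg_log10_p(self) -> np.ndarray:
        return -np.log10(self.p)

    def chromosomes(self) -> np.ndarray:
        return np.unique(self.chromosome)


def scan_frequencies(
    frequencies: np.ndarray,
    envelope: DriftEnvelope,
    generation: int,
    p0: float | None = None,
    alpha: float = 0.05,
) -> ScanResult:
    """Scan a (n_pops, n_loci) frequency matrix for one replicate set.

    ``p0`` defaults to the envelope's nominal tail probability rather than
    a re-estimated empirical rate, matching how the envelope was built.
    """
    freqs = np.atleast_2d(np.asarray(frequencies, dtype=np.float64))
    extreme = flag_extreme(freqs, envelope, generation)
    k = extreme.sum(axis=0).astype(np.int64)
    n_pops = freqs.shape[0]
    if p0 is None:
        p0 = envelope.tail_prob
    p = binomial_tail(k, n_pops, p0)
    q = fdr_adjust(p)
    return ScanResult(
        chromosome=envelope.chromosome.copy(),
        position=envelope.position.copy(),
        k=k,
        p=p,
        q=q,
        significant=q < alpha,
        n_pops=n_pops,
        p0=p0,
        alpha=alpha,
    )


@dataclass(frozen=True)
class DMIEstimate:
    """A mapped genomic interval (closed, 1-based bp) with its peak statistic."""

    mode: str               # "two_locus" | "multi_locus"
    chromosome: int
    start: int
    end: int
    peak_position: int
    peak_neglog10p: float
    n_loci: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("interval start must be <= end")

    @property
    def width(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


def estimate_two_locus(
    scan: ScanResult,
    support_drop: float = 2.0,
    log_base: str = "10",
    method: str = "block",
) -> list[DMIEstimate] | None:
    """Two-locus interval estimation; one interval per chromosome, or no call.

    ``method="block"`` (default): the interval is the maximal run of
    contiguous significant loci containing the chromosome's peak -log10(p).
    With only ~n_pops+1 distinct binomial p-values available, this run acts
    as the discrete ~95% support set around the peak.

    ``method="drop"``: the interval spans the positional min/max of all loci
    on the chromosome whose log-p support is within ``support_drop`` of the
    maximum -log(p) (LOD-style; drop in log10 units by default,
    ``log_base="e"`` for natural-log units).

    If any chromosome lacks a significant locus no DMI is estimated (a
    "no call", counted against detectability).
    """
    if log_base not in ("10", "e"):
        raise ValueError("log_base must be '10' or 'e'")
    if method not in ("block", "drop"):
        raise ValueError("method must be 'block' or 'drop'")
    drop10 = support_drop if log_base == "10" else support_drop / np.log(10.0)
    nl10 = scan.neg_log10_p
    estimates = []
    for c in scan.chromosomes():
        idx = np.flatnonzero(scan.chromosome == c)
        sig = scan.significant[idx]
        if not sig.any():
            return None
        peak_local = int(np.argmax(nl10[idx]))
        if method == "block":
            lo = hi = peak_local  # peak has min p hence min q: significant
            while lo > 0 and sig[lo - 1]:
                lo -= 1
            while hi < len(idx) - 1 and sig[hi + 1]:
                hi += 1
            qual = idx[lo:hi + 1]
        else:
            peak = nl10[idx[peak_local]]
            qual = idx[nl10[idx] >= peak - drop10]
        pos = scan.position[qual]
        estimates.append(
            DMIEstimate(
                mode="two_locus",
                chromosome=int(c),
                start=int(pos.min()),
                end=int(pos.max()),
                peak_position=int(scan.position[idx[peak_local]]),
                peak_neglog10p=float(nl10[idx[peak_local]]),
                n_loci=int(len(qual)),
            )
        )
    return estimates


def estimate_multi_locus(
    scan: ScanResult,
    merge_bp: int = 6240,
    min_loci: int = 2,
) -> list[DMIEstimate]:
    """Block calls: runs of adjacent significant loci, merged when close.

    Maximal runs of consecutive significant loci (in locus order, per
    chromosome) are kept when they contain at least ``min_loci`` loci; runs
    whose end-to-start gap is <= ``merge_bp`` are then merged into a single
    estimate. Merging is idempotent and never crosses a chromosome
    boundary.
    """
    estimates: list[DMIEstimate] = []
    nl10 = scan.neg_log10_p
    for c in scan.chromosomes():
        idx = np.flatnonzero(scan.chromosome == c)
        sig = scan.significant[idx]
        if not sig.any():
            continue
        # maximal runs of consecutive True
        padded = np.concatenate([[False], sig, [False]])
        starts = np.flatnonzero(padded[1:] & ~padded[:-1])
        ends = np.flatnonzero(~padded[1:] & padded[:-1])  # exclusive
        runs = [(s, e) for s, e in zip(starts, ends) if e - s >= min_loci]
        if not runs:
            continue
        merged = [runs[0]]
        for s, e in runs[1:]:
            ps, pe = merged[-1]
            gap = scan.position[idx[s]] - scan.position[idx[pe - 1]]
            if gap <= merge_bp:
                merged[-1] = (ps, e)
            else:
                merged.append((s, e))
        for s, e in merged:
            cols = idx[s:e]
            peak_col = cols[np.argmax(nl10[cols])]
            estimates.append(
                DMIEstimate(
                    mode="multi_locus",
                    chromosome=int(c),
                    start=int(scan.position[cols[0]]),
                    end=int(scan.position[cols[-1]]),
                    peak_position=int(scan.position[peak_col]),
                    peak_neglog10p=float(nl10[peak_col]),
                    n_loci=int(e - s),
                )
            )
    return estimates
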