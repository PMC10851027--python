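"""Genome architecture for hybrid-population simulations.

The simulated genome mimics *Caenorhabditis*-style autosomes: each
chromosome has a central low-recombination domain (LRR) flanked by two
high-recombination arms (HRR), with a grid of evenly spaced neutral
ancestry markers. Dobzhansky-Muller incompatibility (DMI) locus pairs are
placed either deterministically (one locus on an arm of chromosome 1, the
partner in the center of chromosome 2) or uniformly at random across both
autosomes.

Coordinates are 1-based inclusive base pairs and intervals are closed.
Recombination rates are per-bp per-generation; 1 cM/Mb == 1e-8 per bp.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "GenomeConfig",
    "Locus",
    "DMISpec",
    "FitnessModel",
    "ExperimentConfig",
    "RecombinationMap",
    "LocusTable",
    "build_marker_grid",
    "place_two_locus_dmi",
    "place_multi_locus_dmis",
    "build_locus_table",
]

Interaction = Literal["one_way", "two_way"]
Dominance = Literal["dominant", "recessive"]


@dataclass(frozen=True)
class GenomeConfig:
    """Chromosome count/length, recombination landscape and marker grid.

    Defaults follow a two-autosome genome of 20.8 Mb chromosomes with
    10 cM/Mb arms (``arm_rate=1e-7``), a 0.1 cM/Mb center (``center_rate=
    1e-9``) occupying the middle 50% of the chromosome (arm 25% | center
    50% | arm 25%), and 5000 evenly spaced markers per chromosome.
    """

    n_chromosomes: int = 2
    chrom_length: int = 20_800_000
    arm_rate: float = 1e-7
    center_rate: float = 1e-9
    center_fraction: float = 0.5
    markers_per_chromosome: int = 5000

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be > 0")
        if self.arm_rate < 0 or self.center_rate < 0:
            raise ValueError("recombination rates must be >= 0")
        if not 0.0 <= self.center_fraction <= 1.0:
            raise ValueError("center_fraction must be in [0, 1]")
        if self.markers_per_chromosome < 1:
            raise ValueError("markers_per_chromosome must be >= 1")
        if self.markers_per_chromosome >= self.chrom_length:
            raise ValueError("more markers than base pairs")

    @property
    def center_bounds(self) -> tuple[int, int]:
        """(start, end] bp bounds of the central low-recombination domain."""
        lo = round(self.chrom_length * (1.0 - self.center_fraction) / 2.0)
        hi = round(self.chrom_length * (1.0 + self.center_fraction) / 2.0)
        return lo, hi

    def domain_of(self, position: int) -> str:
        """Return ``'arm'`` or ``'center'`` for a 1-based bp position."""
        if not 1 <= position <= self.chrom_length:
            raise ValueError(f"position {position} outside [1, {self.chrom_length}]")
        lo, hi = self.center_bounds
        return "center" if lo < position <= hi else "arm"

    def recombination_map(self) -> "RecombinationMap":
        lo, hi = self.center_bounds
        breaks = np.array([0.0, float(lo), float(hi), float(self.chrom_length)])
        rates = np.array([self.arm_rate, self.center_rate, self.arm_rate])
        # degenerate center (fraction 0 or 1) collapses to a flat map
        keep = np.diff(breaks) > 0
        if not keep.all():
            rates = rates[keep]
            breaks = np.concatenate([[0.0], breaks[1:][keep]])
        return RecombinationMap(breakpoints=breaks, rates=rates)


@dataclass(frozen=True)
class RecombinationMap:
    """Piecewise-constant per-bp recombination map over one chromosome.

    ``breakpoints`` has one more entry than ``rates``; segment ``i`` spans
    ``(breakpoints[i], breakpoints[i+1]]`` with rate ``rates[i]``.
    """

    breakpoints: np.ndarray
    rates: np.ndarray

    @property
    def cumulative(self) -> np.ndarray:
        """Cumulative expected crossovers at each segment start."""
        seg = self.rates * np.diff(self.breakpoints)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def total(self) -> float:
        """Expected crossovers per meiosis for this chromosome (map integral)."""
        return float(self.cumulative[-1])

    def sample_positions(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` crossover bp positions by inverse-CDF of the map."""
        if n == 0:
            return np.empty(0)
        u = rng.random(n) * self.total
        cum = self.cumulative
        seg = np.searchsorted(cum, u, side="right") - 1
        seg = np.clip(seg, 0, len(self.rates) - 1)
        return self.breakpoints[seg] + (u - cum[seg]) / self.rates[seg]


@dataclass(frozen=True)
class Locus:
    """A tracked position: ``role`` is ``'marker'`` or ``'dmi'``."""

    chromosome: int
    position: int
    role: str = "marker"

    def __post_init__(self) -> None:
        if self.chromosome < 0:
            raise ValueError("chromosome index must be >= 0")
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")
        if self.role not in ("marker", "dmi"):
            raise ValueError(f"unknown locus role {self.role!r}")


@dataclass(frozen=True)
class DMISpec:
    """One pair of incompatible loci.

    ``s`` is the selection coefficient per *expressed* incompatibility. For
    a one-way DMI the species-1 allele at ``locus_a`` is incompatible with
    the species-2 allele at ``locus_b``. A two-way DMI adds the reciprocal
    interaction, so both (A1, B2) and (A2, B1) are deleterious.
    Dominance is per locus: a 'dominant' incompatibility allele only needs
    one copy to count as carried, a 'recessive' one needs two.
    """

    locus_a: Locus
    locus_b: Locus
    interaction: Interaction = "one_way"
    dominance_a: Dominance = "dominant"
    dominance_b: Dominance = "dominant"
    s: float = 0.0

    def __post_init__(self) -> None:
        if self.locus_a.chromosome == self.locus_b.chromosome:
            raise ValueError("DMI partner loci must be on different chromosomes")
        if not 0.0 <= self.s <= 1.0:
            raise ValueError("selection coefficient must be in [0, 1]")
        if self.interaction not in ("one_way", "two_way"):
            raise ValueError(f"unknown interaction {self.interaction!r}")
        for d in (self.dominance_a, self.dominance_b):
            if d not in ("dominant", "recessive"):
                raise ValueError(f"unknown dominance {d!r}")

    def neutralized(self) -> "DMISpec":
        """Copy of this spec with ``s = 0`` (for drift-only null runs)."""
        return replace(self, s=0.0)


@dataclass(frozen=True)
class FitnessModel:
    """How expressed incompatibilities combine into relative fitness.

    ``additive``: w = max(0, 1 - sum(s_i)) (floored at zero when
    ``floor_at_zero``); ``multiplicative``: w = prod(1 - s_i). Two-way DMI
    scenarios use the multiplicative rule; the 10-pair one-way scenario uses
    the additive rule.
    """

    composition: Literal["additive", "multiplicative"] = "multiplicative"
    floor_at_zero: bool = True

    def __post_init__(self) -> None:
        if self.composition not in ("additive", "multiplicative"):
            raise ValueError(f"unknown composition {self.composition!r}")


@dataclass
class ExperimentConfig:
    """Design of an evolve-and-resequence mapping experiment.

    Defaults are desk-scale (50 replicate sets, 200 neutral simulations);
    the study-scale values are 500 and 1000 respectively.
    """

    n_individuals: int = 1000
    n_replicate_pops: int = 10
    sample_generations: tuple[int, ...] = (100,)
    n_replicate_sets: int = 50
    n_neutral_sims: int = 200
    extreme_tail_prob: float = 0.05
    fdr_alpha: float = 0.05
    interval_method: str = "block"
    support_drop: float = 2.0
    block_merge_bp: int = 6240
    block_min_loci: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_individuals", "n_replicate_pops", "n_replicate_sets",
                     "n_neutral_sims", "block_min_loci"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        self.sample_generations = tuple(int(g) for g in self.sample_generations)
        if any(g < 1 for g in self.sample_generations):
            raise ValueError("sample generations are 1-based (1 = F1 founding)")
        if not 0.0 < self.extreme_tail_prob < 1.0:
            raise ValueError("extreme_tail_prob must be in (0, 1)")
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if self.support_drop <= 0:
            raise ValueError("support_drop must be > 0")
        if self.interval_method not in ("block", "drop"):
            raise ValueError("interval_method must be 'block' or 'drop'")
        if self.block_merge_bp < 0:
            raise ValueError("block_merge_bp must be >= 0")


def build_marker_grid(config: GenomeConfig) -> list[Locus]:
    """Evenly spaced interior markers: position round(i*L/(m+1)), i=1..m.

    Returns ``markers_per_chromosome`` loci per chromosome, sorted by
    (chromosome, position), with no duplicate positions.
    """
    m = config.markers_per_chromosome
    L = config.chrom_length
    positions = np.rint(np.arange(1, m + 1) * (L / (m + 1))).astype(np.int64)
    if len(np.unique(positions)) != m:
        raise ValueError("marker grid too dense: duplicate positions after rounding")
    return [
        Locus(chromosome=c, position=int(p), role="marker")
        for c in range(config.n_chromosomes)
        for p in positions
    ]


def place_two_locus_dmi(
    config: GenomeConfig,
    s: float,
    interaction: Interaction = "one_way",
    dominance_a: Dominance = "dominant",
    dominance_b: Dominance = "dominant",
) -> DMISpec:
    """Single DMI pair: locus A mid right arm of chromosome 1 (HRR), locus B
    mid-center of chromosome 2 (LRR).

    Positions default to round(0.875*L) and round(0.5*L); both are
    overridable by constructing a :class:`DMISpec` directly.
    """
    if config.n_chromosomes < 2:
        raise ValueError("two-locus DMI needs at least two chromosomes")
    pos_a = round(0.875 * config.chrom_length)
    pos_b = round(0.5 * config.chrom_length)
    return DMISpec(
        locus_a=Locus(0, pos_a, role="dmi"),
        locus_b=Locus(1, pos_b, role="dmi"),
        interaction=interaction,
        dominance_a=dominance_a,
        dominance_b=dominance_b,
        s=s,
    )


def place_multi_locus_dmis(
    config: GenomeConfig,
    n_pairs: int,
    s: float,
    rng: np.random.Generator,
) -> list[DMISpec]:
    """Place ``n_pairs`` one-way dominant x dominant DMI pairs uniformly at
    random, irrespective of recombination domain; partner loci land on
    different chromosomes (one locus of each pair per autosome).

    Positions may coincide with marker positions, but not with each other
    (duplicates on a chromosome are redrawn so every tracked locus is
    distinct).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if config.n_chromosomes < 2:
        raise ValueError("multi-locus DMIs need at least two chromosomes")
    L = config.chrom_length
    used: dict[int, set[int]] = {0: set(), 1: set()}

    def draw(chrom: int) -> int:
        while True:
            p = int(rng.integers(1, L + 1))
            if p not in used[chrom]:
                used[chrom].add(p)
                return p

    specs = []
    for _ in range(n_pairs):
        specs.append(
            DMISpec(
                locus_a=Locus(0, draw(0), role="dmi"),
                locus_b=Locus(1, draw(1), role="dmi"),
                interaction="one_way",
                dominance_a="dominant",
                dominance_b="dominant",
                s=s,
            )
        )
    return specs


@dataclass(frozen=True)
class LocusTable:
    """Sorted, deduplicated table of every tracked locus (markers + DMIs).

    ``chromosome``/``position`` are parallel arrays sorted by (chromosome,
    position). ``dmi_a_cols``/``dmi_b_cols`` map each DMI spec to its column
    indices. ``chrom_starts``/``chrom_ends`` delimit each chromosome's
    half-open column range.
    """

    chromosome: np.ndarray
    position: np.ndarray
    dmi_a_cols: np.ndarray
    dmi_b_cols: np.ndarray
    chrom_starts: np.ndarray
    chrom_ends: np.ndarray

    @property
    def n_loci(self) -> int:
        return len(self.position)

    def column_of(self, chrom: int, position: int) -> int:
        lo, hi = self.chrom_starts[chrom], self.chrom_ends[chrom]
        i = lo + np.searchsorted(self.position[lo:hi], position)
        if i >= hi or self.position[i] != position:
            raise KeyError(f"locus chr{chrom}:{position} not tracked")
        return int(i)


def build_locus_table(config: GenomeConfig, dmis: Sequence[DMISpec]) -> LocusTable:
    """Merge the marker grid and DMI loci into one sorted column table."""
    markers = build_marker_grid(config)
    per_chrom: list[set[int]] = [set() for _ in range(config.n_chromosomes)]
    for loc in markers:
        per_chrom[loc.chromosome].add(loc.position)
    for spec in dmis:
        for loc in (spec.locus_a, spec.locus_b):
            if loc.position > config.chrom_length:
                raise ValueError("DMI locus beyond chromosome end")
            per_chrom[loc.chromosome].add(loc.position)

    chroms, positions, starts, ends = [], [], [], []
    offset = 0
    for c in range(config.n_chromosomes):
        pos = np.array(sorted(per_chrom[c]), dtype=np.int64)
        chroms.append(np.full(len(pos), c, dtype=np.int64))
        positions.append(pos)
        starts.append(offset)
        offset += len(pos)
        ends.append(offset)

    chromosome = np.concatenate(chroms)
    position = np.concatenate(positions)
    starts_a = np.array(starts, dtype=np.int64)
    ends_a = np.array(ends, dtype=np.int64)

    table = LocusTable(
        chromosome=chromosome,
        position=position,
        dmi_a_cols=np.empty(len(dmis), dtype=np.int64),
        dmi_b_cols=np.empty(len(dmis), dtype=np.int64),
        chrom_starts=starts_a,
        chrom_ends=ends_a,
    )
    for i, spec in enumerate(dmis):
        table.dmi_a_cols[i] = table.column_of(spec.locus_a.chromosome, spec.locus_a.position)
        table.dmi_b_cols[i] = table.column_of(spec.locus_b.chromosome, spec.locus_b.position)
    return table
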