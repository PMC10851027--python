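"""Individual-based Wright-Fisher simulation of hybrid populations.

Populations of N diploids are founded entirely from F1 hybrids: every
individual starts heterozygous at every tracked locus, carrying one
haplotype from each parental species (allele 0 = species 1, allele 1 =
species 2). Each generation, N offspring are produced by sampling two
distinct parents per offspring with probability proportional to relative
fitness (soft selection, constant N), one recombinant gamete per parent.
There is no mutation, migration or selfing; selection acts only through
expressed Dobzhansky-Muller incompatibilities.

Internally haplotypes are bit-packed into uint64 words and the
reproduction step runs in a compiled kernel; :func:`meiosis` is a plain
numpy reference implementation of gamete formation used for validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _kernels
from .genome import (DMISpec, FitnessModel, GenomeConfig, LocusTable,
                     build_locus_table)

__all__ = [
    "ExtinctionError",
    "PopulationState",
    "Trajectory",
    "dmi_expressed",
    "individual_fitness",
    "meiosis",
    "advance_generation",
    "run_replicate",
]


class ExtinctionError(RuntimeError):
    """Raised when no individual has positive fitness (population cannot reproduce)."""


# ---------------------------------------------------------------------------
# DMI expression and fitness


def _carried(copies, dominance: str):
    """Carriage test for an incompatibility allele given its dominance."""
    if dominance == "dominant":
        return copies >= 1
    return copies == 2


def dmi_expressed(genotype_a: int, genotype_b: int, spec: DMISpec) -> tuple[str, ...]:
    """Which incompatibilities of ``spec`` are expressed in one individual.

    ``genotype_a``/``genotype_b`` count copies of the *species-1* allele at
    locus A and locus B (0, 1 or 2). One-way DMIs have a single potential
    incompatibility between the species-1 allele at A and the species-2
    allele at B, labelled ``"A1xB2"``; a dominant side is expressed with one
    carried copy, a recessive side needs two. Two-way DMIs additionally test
    the reciprocal ``"A2xB1"`` interaction; under recessive x recessive the
    two can never be expressed simultaneously.
    """
    for g in (genotype_a, genotype_b):
        if g not in (0, 1, 2):
            raise ValueError(f"genotype must be 0, 1 or 2, got {g!r}")
    out = []
    if _carried(genotype_a, spec.dominance_a) and _carried(2 - genotype_b, spec.dominance_b):
        out.append("A1xB2")
    if spec.interaction == "two_way":
        if _carried(2 - genotype_a, spec.dominance_a) and _carried(genotype_b, spec.dominance_b):
            out.append("A2xB1")
    return tuple(out)


def individual_fitness(
    expressed_counts: Sequence[int],
    specs: Sequence[DMISpec],
    model: FitnessModel,
) -> float:
    """Relative fitness from per-DMI expressed-incompatibility counts.

    Additive: ``w = 1 - sum(n_i * s_i)``, floored at 0 when the model says
    so; multiplicative: ``w = prod((1 - s_i) ** n_i)``. No expression gives
    ``w = 1``.
    """
    if len(expressed_counts) != len(specs):
        raise ValueError("expressed_counts must align with specs")
    if model.composition == "additive":
        w = 1.0 - sum(n * spec.s for n, spec in zip(expressed_counts, specs))
        if model.floor_at_zero:
            w = max(0.0, w)
        return w
    w = 1.0
    for n, spec in zip(expressed_counts, specs):
        w *= (1.0 - spec.s) ** n
    return w


def _expression_counts(ga: np.ndarray, gb: np.ndarray, spec: DMISpec) -> np.ndarray:
    """Vectorized expressed-incompatibility count per individual."""
    n = (_carried(ga, spec.dominance_a) & _carried(2 - gb, spec.dominance_b)).astype(np.int64)
    if spec.interaction == "two_way":
        n += _carried(2 - ga, spec.dominance_a) & _carried(gb, spec.dominance_b)
    return n


def population_fitness(
    genotypes_a: np.ndarray,
    genotypes_b: np.ndarray,
    specs: Sequence[DMISpec],
    model: FitnessModel,
) -> np.ndarray:
    """Relative fitness for every individual.

    ``genotypes_a``/``genotypes_b`` are (n_dmis, N) species-1 allele copy
    counts at each DMI's A and B locus.
    """
    n_ind = genotypes_a.shape[1] if len(specs) else 0
    if model.composition == "additive":
        w = np.ones(n_ind)
        for i, spec in enumerate(specs):
            w -= spec.s * _expression_counts(genotypes_a[i], genotypes_b[i], spec)
        if model.floor_at_zero:
            np.maximum(w, 0.0, out=w)
    else:
        w = np.ones(n_ind)
        for i, spec in enumerate(specs):
            w *= (1.0 - spec.s) ** _expression_counts(genotypes_a[i], genotypes_b[i], spec)
    return w


# ---------------------------------------------------------------------------
# Packed-haplotype state


def pack_haplotypes(bits: np.ndarray) -> np.ndarray:
    """(n, L) 0/1 array -> (n, ceil(L/64)) uint64, little-endian bit order."""
    n, L = bits.shape
    nw = (L + 63) // 64
    padded = np.zeros((n, nw * 8), dtype=np.uint8)
    padded[:, : (L + 7) // 8] = np.packbits(bits.astype(np.uint8), axis=1, bitorder="little")
    return np.ascontiguousarray(padded).view(np.uint64)


def unpack_haplotypes(packed: np.ndarray, n_loci: int) -> np.ndarray:
    """Inverse of :func:`pack_haplotypes`."""
    return np.unpackbits(packed.view(np.uint8), axis=1, bitorder="little")[:, :n_loci]


@dataclass
class PopulationState:
    """N diploid individuals as 2N packed ancestry haplotypes.

    ``generation`` counts from 1 (the founding F1 population). Row ``2i``
    and ``2i + 1`` of the packed array are individual ``i``'s haplotypes.
    """

    packed: np.ndarray
    loci: LocusTable
    generation: int = 1

    @property
    def n_individuals(self) -> int:
        return self.packed.shape[0] // 2

    @property
    def haplotypes(self) -> np.ndarray:
        """Unpacked (2N, n_loci) 0/1 ancestry matrix (0 = species 1)."""
        return unpack_haplotypes(self.packed, self.loci.n_loci)

    def genotypes_at(self, cols: np.ndarray) -> np.ndarray:
        """Species-1 allele copy count (0/1/2) per individual at columns.

        Returns shape (len(cols), N). Packed bit 1 is the species-2 allele,
        so the species-1 copy count is 2 minus the bit sum.
        """
        cols = np.asarray(cols, dtype=np.int64)
        words = self.packed[:, cols >> 6]
        bits = (words >> (cols & 63).astype(np.uint64)) & np.uint64(1)
        return (2 - (bits[0::2] + bits[1::2]).T).astype(np.int64)

    def species1_frequencies(self) -> np.ndarray:
        """Per-locus frequency of the species-1 allele.

        Computed as an exact integer count over 2N so the result is the
        correctly rounded double of k/2N.
        """
        bits = unpack_haplotypes(self.packed, self.loci.n_loci)
        n2 = bits.shape[0]
        return (n2 - bits.sum(axis=0, dtype=np.int64)) / n2

    @classmethod
    def founding_f1(cls, n_individuals: int, loci: LocusTable) -> "PopulationState":
        """All-F1 founding population: every individual heterozygous everywhere."""
        bits = np.zeros((2 * n_individuals, loci.n_loci), dtype=np.uint8)
        bits[1::2, :] = 1  # one species-2 haplotype per individual
        return cls(packed=pack_haplotypes(bits), loci=loci, generation=1)


@dataclass(frozen=True)
class _SimContext:
    """Precomputed kernel arguments for one genome architecture."""

    chrom_starts: np.ndarray
    chrom_ends: np.ndarray
    cum_map: np.ndarray
    map_bp: np.ndarray
    map_rate: np.ndarray
    map_total: np.ndarray
    col_pos: np.ndarray
    suffix: np.ndarray


def _build_context(config: GenomeConfig, loci: LocusTable) -> _SimContext:
    rmap = config.recombination_map()
    nc = config.n_chromosomes
    nseg = len(rmap.rates)
    cum_map = np.tile(rmap.cumulative[:nseg], (nc, 1))
    map_bp = np.tile(rmap.breakpoints[:nseg], (nc, 1))
    map_rate = np.tile(rmap.rates, (nc, 1))
    map_total = np.full(nc, rmap.total)
    return _SimContext(
        chrom_starts=loci.chrom_starts.copy(),
        chrom_ends=loci.chrom_ends.copy(),
        cum_map=cum_map,
        map_bp=map_bp,
        map_rate=map_rate,
        map_total=map_total,
        col_pos=loci.position.astype(np.float64),
        suffix=_kernels.make_suffix_masks(loci.n_loci),
    )


# ---------------------------------------------------------------------------
# Meiosis (reference implementation) and generation stepping


def meiosis(
    parent_haplotypes: np.ndarray,
    config: GenomeConfig,
    loci: LocusTable,
    rng: np.random.Generator,
) -> np.ndarray:
    """Form one gamete from a (2, n_loci) parental haplotype pair.

    Per chromosome: crossover count ~ Poisson(map integral), crossover bp
    positions by inverse-CDF of the cumulative recombination map, source
    haplotype alternating across crossover points from a fair-coin start;
    chromosomes assort independently. This is the readable reference path;
    the engine applies the same scheme in a compiled kernel.
    """
    hap = np.asarray(parent_haplotypes)
    if hap.shape != (2, loci.n_loci):
        raise ValueError("expected a (2, n_loci) haplotype pair")
    rmap = config.recombination_map()
    gamete = np.empty(loci.n_loci, dtype=hap.dtype)
    for c in range(config.n_chromosomes):
        lo, hi = loci.chrom_starts[c], loci.chrom_ends[c]
        pos = loci.position[lo:hi]
        n_xo = rng.poisson(rmap.total)
        bp = np.sort(rmap.sample_positions(n_xo, rng))
        switch_cols = np.searchsorted(pos, bp)
        take = np.full(hi - lo, rng.integers(0, 2), dtype=np.int64)
        for col in switch_cols:
            take[col:] ^= 1
        gamete[lo:hi] = hap[take, np.arange(lo, hi)]
    return gamete


def _fitness_of_state(
    state: PopulationState, specs: Sequence[DMISpec], model: FitnessModel
) -> np.ndarray:
    if not specs:
        return np.ones(state.n_individuals)
    ga = state.genotypes_at(state.loci.dmi_a_cols)  # (n_dmis, N)
    gb = state.genotypes_at(state.loci.dmi_b_cols)
    return population_fitness(ga, gb, specs, model)


def advance_generation(
    state: PopulationState,
    specs: Sequence[DMISpec],
    model: FitnessModel,
    config: GenomeConfig,
    rng: np.random.Generator,
    _ctx: _SimContext | None = None,
) -> PopulationState:
    """One Wright-Fisher generation under DMI selection.

    N offspring are produced; each offspring's two (distinct) parents are
    drawn with probability proportional to fitness and contribute one
    recombinant gamete each. Raises :class:`ExtinctionError` when no
    individual has positive fitness.
    """
    w = _fitness_of_state(state, specs, model)
    if np.all(w <= 0.0):
        raise ExtinctionError(
            f"no individual with positive fitness at generation {state.generation}"
        )
    if np.count_nonzero(w > 0.0) < 2:
        raise ExtinctionError("fewer than two individuals with positive fitness")
    ctx = _ctx or _build_context(config, state.loci)
    cum_w = np.cumsum(w)
    out = np.empty_like(state.packed)
    _kernels.reproduce(
        state.packed, cum_w, ctx.chrom_starts, ctx.chrom_ends, ctx.cum_map,
        ctx.map_bp, ctx.map_rate, ctx.map_total, ctx.col_pos, ctx.suffix,
        rng, out,
    )
    return PopulationState(packed=out, loci=state.loci, generation=state.generation + 1)


@dataclass
class Trajectory:
    """Species-1 allele frequencies at every tracked locus, per sampled generation."""

    chromosome: np.ndarray
    position: np.ndarray
    generations: tuple[int, ...]
    frequencies: np.ndarray  # (n_generations, n_loci)
    seed: object = None

    def at_generation(self, generation: int) -> np.ndarray:
        try:
            i = self.generations.index(generation)
        except ValueError:
            raise KeyError(f"generation {generation} was not sampled") from None
        return self.frequencies[i]


def run_replicate(
    config: GenomeConfig,
    specs: Sequence[DMISpec],
    model: FitnessModel,
    n_individuals: int,
    sample_generations: Sequence[int],
    seed,
    loci: LocusTable | None = None,
) -> Trajectory:
    """Simulate one population from its F1 founding and record frequencies.

    ``sample_generations`` uses the 1-based convention where generation 1 is
    the founding F1 population (all frequencies exactly 0.5). ``seed`` may
    be an int or a ``numpy.random.SeedSequence``; identical seeds give
    bit-identical trajectories.
    """
    gens = sorted(set(int(g) for g in sample_generations))
    if not gens or gens[0] < 1:
        raise ValueError("sample_generations must be >= 1")
    if loci is None:
        loci = build_locus_table(config, specs)
    ctx = _build_context(config, loci)
    rng = np.random.default_rng(seed)
    state = PopulationState.founding_f1(n_individuals, loci)
    freqs = np.empty((len(gens), loci.n_loci))
    for i, g in enumerate(gens):
        while state.generation < g:
            state = advance_generation(state, specs, model, config, rng, _ctx=ctx)
        freqs[i] = state.species1_frequencies()
    return Trajectory(
        chromosome=loci.chromosome.copy(),
        position=loci.position.copy(),
        generations=tuple(gens),
        frequencies=freqs,
        seed=seed,
    )
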