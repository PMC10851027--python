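"""Neutral drift envelopes: what allele frequencies drift alone can produce.

The detection procedure needs, for every locus and sampling generation, the
band of allele frequencies plausibly reached by genetic drift without
selection. The band is estimated empirically: many neutral replicates are
run with the *same* genome architecture (markers, recombination landscape
and DMI loci all present, but every selection coefficient forced to zero),
and the per-locus 2.5th/97.5th percentiles of the final frequencies across
replicates form the envelope. A frequency strictly outside its locus's band
is deemed "extreme"; by construction a fresh neutral locus is flagged with
probability ~= ``tail_prob`` (default 0.05, split across both tails).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome import DMISpec, FitnessModel, GenomeConfig, LocusTable, build_locus_table
from .simulate import run_replicate

__all__ = ["DriftEnvelope", "build_envelope", "flag_extreme"]


@dataclass
class DriftEnvelope:
    """Per-locus, per-generation neutral frequency percentile bounds."""

    chromosome: np.ndarray
    position: np.ndarray
    generations: tuple[int, ...]
    lower: np.ndarray  # (n_generations, n_loci)
    upper: np.ndarray
    n_neutral_sims: int
    tail_prob: float = 0.05

    def __post_init__(self) -> None:
        if np.any(self.lower > self.upper):
            raise ValueError("envelope lower bound exceeds upper bound")

    def bounds_at(self, generation: int) -> tuple[np.ndarray, np.ndarray]:
        try:
            i = self.generations.index(generation)
        except ValueError:
            raise KeyError(
                f"no envelope for generation {generation}; have {self.generations}"
            ) from None
        return self.lower[i], self.upper[i]


def build_envelope(
    config: GenomeConfig,
    dmis: Sequence[DMISpec],
    n_individuals: int,
    sample_generations: Sequence[int],
    n_neutral_sims: int,
    seed,
    tail_prob: float = 0.05,
    loci: LocusTable | None = None,
) -> DriftEnvelope:
    """Run neutral replicates and record per-locus frequency percentiles.

    The neutral runs reuse the selection engine with every DMI's ``s`` set
    to zero, so linkage structure (and the DMI loci themselves) are
    identical to the non-neutral simulations. Percentiles are empirical
    order statistics (linear interpolation), computed per locus.
    """
    if n_neutral_sims < 2:
        raise ValueError("need at least 2 neutral simulations")
    if not 0.0 < tail_prob < 1.0:
        raise ValueError("tail_prob must be in (0, 1)")
    neutral = [spec.neutralized() for spec in dmis]
    if loci is None:
        loci = build_locus_table(config, neutral)
    gens = tuple(sorted(set(int(g) for g in sample_generations)))
    model = FitnessModel()
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    freqs = np.empty((n_neutral_sims, len(gens), loci.n_loci))
    for k, child in enumerate(root.spawn(n_neutral_sims)):
        traj = run_replicate(config, neutral, model, n_individuals, gens, child, loci=loci)
        freqs[k] = traj.frequencies
    lower = np.quantile(freqs, tail_prob / 2.0, axis=0)
    upper = np.quantile(freqs, 1.0 - tail_prob / 2.0, axis=0)
    return DriftEnvelope(
        chromosome=loci.chromosome.copy(),
        position=loci.position.copy(),
        generations=gens,
        lower=lower,
        upper=upper,
        n_neutral_sims=n_neutral_sims,
        tail_prob=tail_prob,
    )


def flag_extreme(
    frequencies: np.ndarray, envelope: DriftEnvelope, generation: int
) -> np.ndarray:
    """True where a frequency falls strictly outside the neutral envelope.

    ``frequencies`` is (n_loci,) for one population or (n_pops, n_loci);
    values exactly on a bound are not extreme.
    """
    lower, upper = envelope.bounds_at(generation)
    freqs = np.asarray(frequencies, dtype=np.float64)
    if freqs.shape[-1] != len(envelope.position):
        raise ValueError(
            f"frequency vector has {freqs.shape[-1]} loci, envelope has "
            f"{len(envelope.position)}"
        )
    return (freqs < lower) | (freqs > upper)
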