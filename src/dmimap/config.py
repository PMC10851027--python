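"""YAML/JSON experiment configuration.

A config file has up to four sections; every field is optional and falls
back to the package defaults::

    genome:
      chrom_length: 20800000
      markers_per_chromosome: 1000
    fitness:
      composition: multiplicative
    dmis:
      mode: two_locus          # or multi_locus
      s: 0.2
      interaction: one_way
      dominance_a: dominant
      dominance_b: dominant
      # multi_locus mode instead takes: n_pairs, s, placement_seed
    experiment:
      n_replicate_pops: 10
      sample_generations: [10, 100]
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .genome import (DMISpec, ExperimentConfig, FitnessModel, GenomeConfig,
                     place_multi_locus_dmis, place_two_locus_dmi)

__all__ = ["FullConfig", "load_config"]


@dataclass
class FullConfig:
    genome: GenomeConfig
    dmis: list[DMISpec]
    fitness: FitnessModel
    experiment: ExperimentConfig
    mode: str  # "two_locus" | "multi_locus" | "neutral"


def _build_dmis(section: dict, genome: GenomeConfig) -> tuple[list[DMISpec], str]:
    mode = section.get("mode", "two_locus")
    if mode == "neutral":
        return [], mode
    s = float(section.get("s", 0.2))
    if mode == "two_locus":
        dmi = place_two_locus_dmi(
            genome, s=s,
            interaction=section.get("interaction", "one_way"),
            dominance_a=section.get("dominance_a", "dominant"),
            dominance_b=section.get("dominance_b", "dominant"),
        )
        return [dmi], mode
    if mode == "multi_locus":
        rng = np.random.default_rng(int(section.get("placement_seed", 0)))
        return place_multi_locus_dmis(genome, int(section.get("n_pairs", 10)), s, rng), mode
    raise ValueError(f"unknown dmis.mode {mode!r}")


def load_config(path) -> FullConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - {"genome", "dmis", "fitness", "experiment"}
    if unknown:
        raise ValueError(f"{path}: unknown sections {sorted(unknown)}")
    genome = GenomeConfig(**raw.get("genome", {}))
    fitness = FitnessModel(**raw.get("fitness", {}))
    experiment = ExperimentConfig(**raw.get("experiment", {}))
    dmis, mode = _build_dmis(raw.get("dmis", {}), genome)
    return FullConfig(genome=genome, dmis=dmis, fitness=fitness,
                      experiment=experiment, mode=mode)
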