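"""Replicate-set experiments and mapping power metrics.

A "replicate set" is one simulated E&R experiment: ``n_replicate_pops``
independent hybrid populations evolved under the same truth, scanned
jointly. Repeating over many sets gives the power metrics:

* detectability - fraction of sets yielding any estimate (two-locus mode
  makes no call unless both chromosomes have significant loci);
* accuracy - fraction of estimates whose interval contains the true DMI
  position (scored per chromosome: HRR locus and LRR locus separately);
* precision - 1 - interval_width / chromosome_length, over accurate
  estimates only; summarized as the median with a 2.5-97.5% interquantile
  range;
* multi-locus - per set: number of block estimates, fraction of true DMI
  loci contained in >= 1 block, ratio of true loci mapped to number of
  blocks, and block widths as fractions of the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .drift import DriftEnvelope, build_envelope
from .genome import DMISpec, ExperimentConfig, FitnessModel, GenomeConfig, build_locus_table
from .scan import DMIEstimate, estimate_multi_locus, estimate_two_locus, scan_frequencies
from .simulate import run_replicate

__all__ = [
    "score_two_locus",
    "score_multi_locus",
    "run_two_locus_experiment",
    "run_multi_locus_experiment",
    "run_power_experiment",
    "TwoLocusPower",
    "MultiLocusPower",
    "PowerSummary",
]

_ENVELOPE_STREAM = 0
_SET_STREAM = 1


def _quantile_summary(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, 2.5th, 97.5th percentile); NaNs when empty."""
    arr = np.asarray(list(values), dtype=np.float64)
    if arr.size == 0:
        return (float("nan"),) * 3
    return (float(np.median(arr)),
            float(np.quantile(arr, 0.025)),
            float(np.quantile(arr, 0.975)))


def score_two_locus(
    estimates: Sequence[DMIEstimate],
    truth: DMISpec,
    config: GenomeConfig,
) -> dict[int, tuple[bool, float]]:
    """Per-chromosome (accurate, precision) for a two-locus estimate pair.

    An estimate is accurate when its closed interval contains the true DMI
    position on that chromosome; precision = 1 - width/chrom_length is
    reported only for accurate estimates (NaN otherwise).
    """
    true_pos = {truth.locus_a.chromosome: truth.locus_a.position,
                truth.locus_b.chromosome: truth.locus_b.position}
    out: dict[int, tuple[bool, float]] = {}
    for est in estimates:
        if est.chromosome not in true_pos:
            continue
        accurate = est.contains(true_pos[est.chromosome])
        precision = 1.0 - est.width / config.chrom_length if accurate else float("nan")
        out[est.chromosome] = (accurate, precision)
    return out


def score_multi_locus(
    estimates: Sequence[DMIEstimate],
    truth: Sequence[DMISpec],
    config: GenomeConfig,
) -> tuple[int, int, float, list[float]]:
    """(n_estimates, n_true_detected, true_positive_ratio, widths).

    A true DMI locus is detected when any estimate interval contains it;
    the ratio is detected-true-loci over number of estimates (may exceed 1
    when single blocks span several true loci; NaN with zero estimates).
    Widths are fractions of the whole genome.
    """
    true_loci = [(s.locus_a.chromosome, s.locus_a.position) for s in truth]
    true_loci += [(s.locus_b.chromosome, s.locus_b.position) for s in truth]
    detected = sum(
        any(e.chromosome == c and e.contains(p) for e in estimates)
        for c, p in true_loci
    )
    genome_bp = config.n_chromosomes * config.chrom_length
    widths = [e.width / genome_bp for e in estimates]
    ratio = detected / len(estimates) if estimates else float("nan")
    return len(estimates), detected, ratio, widths


@dataclass
class TwoLocusPower:
    """Raw per-set two-locus outcomes plus aggregation helpers."""

    truth: DMISpec
    generations: tuple[int, ...]
    n_sets: int
    n_pops: int
    chrom_length: int
    # records[gen] = list over sets of None (no call) or
    #   {chrom: (accurate, precision)}
    records: dict[int, list] = field(default_factory=dict)

    def detectability(self, generation: int) -> float:
        recs = self.records[generation]
        return sum(r is not None for r in recs) / len(recs)

    def accuracy(self, generation: int, chromosome: int) -> float:
        called = [r[chromosome] for r in self.records[generation] if r is not None]
        if not called:
            return float("nan")
        return sum(acc for acc, _ in called) / len(called)

    def precisions(self, generation: int, chromosome: int) -> np.ndarray:
        called = [r[chromosome] for r in self.records[generation] if r is not None]
        return np.array([prec for acc, prec in called if acc])

    def summary(self) -> pd.DataFrame:
        rows = []
        for g in self.generations:
            for c in (self.truth.locus_a.chromosome, self.truth.locus_b.chromosome):
                med, lo, hi = _quantile_summary(self.precisions(g, c))
                rows.append({
                    "generation": g, "chromosome": c,
                    "detectability": self.detectability(g),
                    "accuracy": self.accuracy(g, c),
                    "precision_median": med,
                    "precision_q025": lo, "precision_q975": hi,
                    "n_sets": self.n_sets, "n_pops": self.n_pops,
                })
        return pd.DataFrame(rows)


@dataclass
class MultiLocusPower:
    """Raw per-set multi-locus outcomes plus aggregation helpers."""

    truth: list[DMISpec]
    generations: tuple[int, ...]
    n_sets: int
    n_pops: int
    # records[gen] = list over sets of (n_estimates, n_detected, ratio, widths)
    records: dict[int, list] = field(default_factory=dict)

    def detected_fraction(self, generation: int) -> np.ndarray:
        n_true = 2 * len(self.truth)
        return np.array([d / n_true for _, d, _, _ in self.records[generation]])

    def ratios(self, generation: int) -> np.ndarray:
        return np.array([r for _, _, r, _ in self.records[generation]
                         if np.isfinite(r)])

    def widths(self, generation: int) -> np.ndarray:
        return np.concatenate(
            [w for _, _, _, w in self.records[generation]] or [np.empty(0)]
        )

    def summary(self) -> pd.DataFrame:
        rows = []
        for g in self.generations:
            recs = self.records[g]
            wmed, wlo, whi = _quantile_summary(self.widths(g))
            rmed, rlo, rhi = _quantile_summary(self.ratios(g))
            rows.append({
                "generation": g,
                "mean_detected_fraction": float(np.mean(self.detected_fraction(g))),
                "mean_n_estimates": float(np.mean([n for n, _, _, _ in recs])),
                "ratio_median": rmed, "ratio_q025": rlo, "ratio_q975": rhi,
                "width_median": wmed, "width_q025": wlo, "width_q975": whi,
                "n_sets": self.n_sets, "n_pops": self.n_pops,
            })
        return pd.DataFrame(rows)


def _simulate_sets(config, dmis, model, exp: ExperimentConfig, envelope, root, loci):
    """Yield (set_index, {generation: ScanResult}) for each replicate set."""
    gens = exp.sample_generations
    for j in range(exp.n_replicate_sets):
        freqs = np.empty((exp.n_replicate_pops, len(gens), loci.n_loci))
        for i in range(exp.n_replicate_pops):
            ss = np.random.SeedSequence(root, spawn_key=(_SET_STREAM, j, i))
            traj = run_replicate(config, dmis, model, exp.n_individuals,
                                 gens, ss, loci=loci)
            freqs[i] = traj.frequencies
        scans = {
            g: scan_frequencies(freqs[:, gi, :], envelope, g,
                                p0=exp.extreme_tail_prob, alpha=exp.fdr_alpha)
            for gi, g in enumerate(gens)
        }
        yield j, scans


def _ensure_envelope(config, dmis, exp: ExperimentConfig, envelope, loci):
    if envelope is not None:
        missing = set(exp.sample_generations) - set(envelope.generations)
        if missing:
            raise ValueError(f"envelope lacks generations {sorted(missing)}")
        return envelope
    return build_envelope(
        config, dmis, exp.n_individuals, exp.sample_generations,
        exp.n_neutral_sims, np.random.SeedSequence(exp.rng_seed, spawn_key=(_ENVELOPE_STREAM,)),
        tail_prob=exp.extreme_tail_prob, loci=loci,
    )


def run_two_locus_experiment(
    config: GenomeConfig,
    dmi: DMISpec,
    model: FitnessModel,
    exp: ExperimentConfig,
    envelope: DriftEnvelope | None = None,
) -> TwoLocusPower:
    """Simulate replicate sets under one two-locus DMI and score the scans."""
    loci = build_locus_table(config, [dmi])
    envelope = _ensure_envelope(config, [dmi], exp, envelope, loci)
    result = TwoLocusPower(
        truth=dmi, generations=exp.sample_generations,
        n_sets=exp.n_replicate_sets, n_pops=exp.n_replicate_pops,
        chrom_length=config.chrom_length,
        records={g: [] for g in exp.sample_generations},
    )
    for _, scans in _simulate_sets(config, [dmi], model, exp, envelope,
                                   exp.rng_seed, loci):
        for g, scan in scans.items():
            ests = estimate_two_locus(scan, support_drop=exp.support_drop,
                                      method=exp.interval_method)
            result.records[g].append(
                None if ests is None else score_two_locus(ests, dmi, config)
            )
    return result


def run_multi_locus_experiment(
    config: GenomeConfig,
    dmis: Sequence[DMISpec],
    model: FitnessModel,
    exp: ExperimentConfig,
    envelope: DriftEnvelope | None = None,
) -> MultiLocusPower:
    """Simulate replicate sets under many DMI pairs and score block calls."""
    dmis = list(dmis)
    loci = build_locus_table(config, dmis)
    envelope = _ensure_envelope(config, dmis, exp, envelope, loci)
    result = MultiLocusPower(
        truth=dmis, generations=exp.sample_generations,
        n_sets=exp.n_replicate_sets, n_pops=exp.n_replicate_pops,
        records={g: [] for g in exp.sample_generations},
    )
    for _, scans in _simulate_sets(config, dmis, model, exp, envelope,
                                   exp.rng_seed, loci):
        for g, scan in scans.items():
            ests = estimate_multi_locus(scan, merge_bp=exp.block_merge_bp,
                                        min_loci=exp.block_min_loci)
            result.records[g].append(score_multi_locus(ests, dmis, config))
    return result


@dataclass
class PowerSummary:
    """Aggregated grid results: one summary frame per parameter cell."""

    cells: list[dict]
    summaries: list[pd.DataFrame]
    failures: list[tuple[dict, str]]

    def frame(self) -> pd.DataFrame:
        frames = []
        for cell, s in zip(self.cells, self.summaries):
            s = s.copy()
            for k, v in cell.items():
                if not isinstance(v, (list, tuple, dict)):
                    s[k] = v
            frames.append(s)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def run_power_experiment(
    config: GenomeConfig,
    cells: Sequence[dict],
    exp: ExperimentConfig,
) -> PowerSummary:
    """Run a grid of parameter cells; failures are recorded, not raised.

    Each cell dict needs ``mode`` (``two_locus``/``multi_locus``) and the
    DMI parameters (``s``, ``interaction``, ``dominance_a``/``b`` or
    ``n_pairs``); optional ``composition`` overrides the fitness rule and
    any ExperimentConfig field may be overridden per cell.
    """
    from dataclasses import replace as dc_replace

    from .genome import place_multi_locus_dmis, place_two_locus_dmi

    summaries, done_cells, failures = [], [], []
    for idx, cell in enumerate(cells):
        try:
            cell_exp = dc_replace(
                exp, **{k: v for k, v in cell.items()
                        if hasattr(exp, k) and k != "rng_seed"},
                rng_seed=int(np.random.SeedSequence(
                    exp.rng_seed, spawn_key=(2, idx)).generate_state(1)[0] % (2**31)),
            )
            if cell["mode"] == "two_locus":
                dmi = place_two_locus_dmi(
                    config, s=cell["s"],
                    interaction=cell.get("interaction", "one_way"),
                    dominance_a=cell.get("dominance_a", "dominant"),
                    dominance_b=cell.get("dominance_b", "dominant"),
                )
                model = FitnessModel(composition=cell.get("composition", "multiplicative"))
                res = run_two_locus_experiment(config, dmi, model, cell_exp)
            elif cell["mode"] == "multi_locus":
                rng = np.random.default_rng(
                    np.random.SeedSequence(exp.rng_seed, spawn_key=(3, idx)))
                dmis = place_multi_locus_dmis(config, cell["n_pairs"], cell["s"], rng)
                model = FitnessModel(composition=cell.get("composition", "additive"))
                res = run_multi_locus_experiment(config, dmis, model, cell_exp)
            else:
                raise ValueError(f"unknown mode {cell['mode']!r}")
            summaries.append(res.summary())
            done_cells.append(cell)
        except Exception as err:  # noqa: BLE001 - grid must survive cell failures
            failures.append((cell, f"{type(err).__name__}: {err}"))
    return PowerSummary(cells=done_cells, summaries=summaries, failures=failures)
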