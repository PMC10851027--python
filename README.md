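# dmimap

Power analysis for mapping **Dobzhansky–Muller incompatibility (DMI) loci**
with evolve-and-resequence (E&R) experiments on hybrid populations.

DMIs are negative epistatic interactions between alleles at two (or more)
loci derived from different species; they underlie much of hybrid
inviability and infertility, yet localizing them in genomes is hard. One
proposed strategy is experimental evolution: found many replicate
populations entirely from F1 hybrids, let selection purge incompatible
genotype combinations for tens to hundreds of generations, and look for
*parallel* extreme allele-frequency changes across the replicates with
pooled sequencing. `dmimap` asks, by forward simulation, when this design
works: for which selection strengths, interaction types (one-way vs
two-way), dominance regimes, recombination environments, experiment
durations and replication levels the DMI loci can be detected, and how
accurately and precisely they are localized.

## Model and method

**Simulator.** N = 1000 diploids evolve in discrete Wright–Fisher
generations at constant size, founded from F1 hybrids (every individual
heterozygous at every locus; species-1 allele frequency exactly 0.5). The
genome mimics two *Caenorhabditis*-style 20.8 Mb autosomes: a central
low-recombination domain (LRR, 0.1 cM/Mb) spanning 50% of each chromosome,
flanked by high-recombination arms (HRR, 10 cM/Mb), with evenly spaced
neutral ancestry markers. Meioses place Poisson crossovers by inverse-CDF
of the recombination map; chromosomes assort independently; there is no new
mutation or migration. A DMI pair (loci A, B on different chromosomes)
penalizes carriers of incompatible allele combinations: one-way DMIs
penalize (A₁, B₂) only; two-way DMIs penalize both (A₁, B₂) and (A₂, B₁).
Dominance is per locus (one carried copy suffices, or two for recessive
alleles). Expressed incompatibilities compose multiplicatively,
w = Π(1 − sᵢ), or additively with a floor, w = max(0, 1 − Σsᵢ); parents are
drawn fitness-proportionally (soft selection).

**Detection.** For each locus, a *drift envelope* — the 2.5th/97.5th
percentiles of its frequency across many neutral replicates of the same
architecture — defines which observed frequencies are "extreme". Across
n replicate populations, k = number of populations extreme at a locus is
scored with the upper-tail binomial probability P(X ≥ k), X ~ Binomial(n,
0.05), Benjamini–Hochberg corrected genome-wide; loci with q < 0.05 are
significant. In the two-locus mode, each chromosome's estimate is the
contiguous block of significant loci containing the peak −log₁₀(p) (no DMI
is estimated unless both chromosomes have significant loci). In the
multi-locus mode, runs of ≥ 2 adjacent significant loci become blocks,
merged when closer than 6240 bp. Estimates are scored against the true
loci: **detectability** (fraction of replicate sets yielding an estimate),
**accuracy** (fraction of estimates containing the true locus), and
**precision** (1 − interval width / chromosome length, over accurate
estimates).

## Worked example

Map a single moderate-effect one-way DMI (s = 0.2) from 10 replicate sets
of 10 populations sampled at generation 50:

```python
import dmimap as dm

genome = dm.GenomeConfig(markers_per_chromosome=500)   # 20.8 Mb chromosomes
dmi = dm.place_two_locus_dmi(genome, s=0.2, interaction="one_way")
experiment = dm.ExperimentConfig(
    n_replicate_pops=10, sample_generations=(50,),
    n_replicate_sets=10, n_neutral_sims=150, rng_seed=7,
)
result = dm.run_two_locus_experiment(genome, dmi, dm.FitnessModel(), experiment)
print(result.summary().to_string(index=False))
```

```
 generation  chromosome  detectability  accuracy  precision_median  precision_q025  precision_q975  n_sets  n_pops
         50           0            1.0       1.0          0.854291        0.843663        0.905240      10      10
         50           1            1.0       1.0          0.376248        0.335180        0.414421      10      10
```

Every replicate set yields an estimate (detectability 1.0) and every
estimate contains the true locus (accuracy 1.0). The arm-linked locus
(chromosome 0, HRR) is localized to ~15% of the chromosome (precision
0.85 ≈ a 3 Mb interval), while the center-linked partner (chromosome 1,
LRR) is only localized to ~62% of the chromosome — recombination rate, not
detection, limits mapping resolution.

The same pipeline is scriptable from the shell (`dmimap simulate`,
`dmimap envelope`, `dmimap detect`, `dmimap power`) with a YAML config; see
`examples/two_locus.yaml`. `dmimap detect` also accepts PoPoolation2
"sync"-format allele counts from real Pool-Seq experiments.

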