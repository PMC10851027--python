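# Methods notes

## Model

Hybrid populations are simulated as discrete-generation Wright–Fisher
populations of N = 1000 monoecious diploids at constant size. Generation 1
is the founding population: every individual is an F1 hybrid, heterozygous
at every tracked locus, so the species-1 allele frequency starts at exactly
0.5 genome-wide and all subsequent variation comes from drift,
recombination and epistatic selection (no new mutation, no migration, no
selfing). Each offspring draws two *distinct* parents with probability
proportional to relative fitness (soft selection keeps N constant), one
recombinant gamete per parent. A population in which no individual has
positive fitness raises an extinction error rather than silently
continuing; with the additive fitness floor and any compatible genotype
present this cannot occur at the parameters studied.

**Genome.** Two 20.8 Mb autosomes model a *Caenorhabditis*-like karyotype:
the central 50% of each chromosome is a low-recombination domain (LRR,
0.1 cM/Mb = 1e-9 per bp per generation) and the flanking 25% arms are
high-recombination (HRR, 10 cM/Mb = 1e-7 per bp), giving a map length of
1.0504 crossovers per meiosis per chromosome. Coordinates are 1-based
inclusive; cM/Mb converts to per-bp rates as r = (cM/Mb)/1e8. Markers are
evenly spaced interior points, round(i·L/(m+1)); the reference design has
5000 per chromosome (10,000 total, 2500 in each center domain). Crossover
counts are Poisson (no interference), positions follow the inverse CDF of
the piecewise-constant map, and chromosomes assort independently.

**Incompatibilities.** A DMI spec names two partner loci on different
chromosomes, an interaction type, per-locus dominance, and a selection
coefficient s per *expressed* incompatibility. One-way: the species-1
allele at A is incompatible with the species-2 allele at B. Two-way: the
reciprocal (A₂, B₁) interaction is additionally deleterious, so only
parentally matched fixed combinations are compatible. Dominance is a
binary carriage threshold (dominant: ≥ 1 copy; recessive: 2 copies); under
recessive × recessive two-way at most one incompatibility can be expressed
in one individual. Fitness composes multiplicatively, w = Π(1 − sᵢ)
(two-way scenarios), or additively with a zero floor, w = max(0, 1 − Σsᵢ)
(the 10-pair one-way scenario). The floor matters only for the strong
multi-locus case (10 × s = 0.145 > 1); a multiplicative switch is provided
because 1 − (1 − 0.145)¹⁰ ≈ 0.79 matches that scenario's intended ~0.8
maximum reduction, but additive-with-floor is the default as the more
literal reading. Two-way selection coefficients are chosen so that the
*maximum* fitness reduction matches the one-way grid: 1 − (1 − s)² ∈
{0.05, 0.2, 0.8} gives s ≈ {0.0253, 0.106, 0.5528}.

**Implementation.** Haplotypes are binary ancestry vectors (0 = species 1),
bit-packed 64 loci per machine word; the per-generation reproduction step
is a compiled (numba) kernel that assembles each gamete by word-level
masking, with crossover columns toggling suffix masks. A plain-numpy
`meiosis` reference implementation shares the crossover sampler and is
cross-validated against the kernel distributionally in the test suite
(mean crossovers, center-domain fraction, neutral WF mean/variance,
heterozygosity decay (1 − 1/2N)^t). Crossovers are capped at 63 per
chromosome per meiosis (P < 1e-50 at these map lengths). All randomness
flows from `numpy.random.SeedSequence` spawns keyed by (stream, set,
population), so replicates are independent and every result is exactly
reproducible from one root seed.

## Detection procedure

1. **Drift envelope.** For each sampling generation, n neutral replicates
   (selection coefficients forced to 0, architecture and linkage identical,
   DMI loci still tracked) give per-locus empirical 2.5th/97.5th frequency
   percentiles (linear-interpolation order statistics, per locus rather
   than pooled: the duration-matched, locus-specific null). A frequency
   strictly outside its band is "extreme"; a fresh neutral locus is flagged
   with probability ≈ 0.05.
2. **Binomial scan.** k = number of replicate populations extreme at a
   locus; p = P(X ≥ k), X ~ Binomial(n_pops, 0.05) — the nominal tail
   probability, not a re-estimated rate; Benjamini–Hochberg adjustment over
   all loci genome-wide; significant ⇔ q < 0.05 (strict).
3. **Two-locus estimate.** Per chromosome, the peak is the maximum
   −log₁₀(p). The default interval is the maximal contiguous run of
   significant loci containing the peak (`interval_method="block"`). A
   LOD-style alternative (`"drop"`) spans all loci within a 2-unit
   −log₁₀(p) drop of the peak (natural-log units selectable). With 10
   populations the binomial p takes only 11 values and a 2-log drop below
   the k = 10 peak excludes even k = 9, so the drop interval collapses to
   the k = 10 plateau; the contiguous-block rule is the default because it
   reproduces the published precision values for both two-way dominance
   scenarios (measured ~82% dominant / ~98% recessive at generation 100
   versus published 78.4% / 96.1%), where the drop rule cannot (~91%
   dominant). No DMI is estimated for a replicate set unless both
   chromosomes carry a significant locus.
4. **Multi-locus estimate.** Maximal runs of ≥ 2 consecutive significant
   loci become blocks; blocks whose end-to-start gap is ≤ 6240 bp
   (inclusive) are merged. Block calls never cross chromosomes and merging
   is idempotent.
5. **Scoring.** Detectability = sets yielding an estimate / sets attempted.
   Accuracy = estimates whose closed interval contains the true locus /
   estimates made, per chromosome (HRR and LRR scored separately).
   Precision = 1 − width/chromosome length, over accurate estimates;
   summaries report medians with 2.5–97.5% interquantile ranges. Multi-locus
   runs additionally report the fraction of true loci inside ≥ 1 block, the
   ratio of true loci mapped to blocks called (can exceed 1 when one block
   spans several true loci), and block widths as genome fractions.

## Problem sizes

The reference design (5000 markers/chromosome, 1000 neutral simulations,
500 replicate sets) is available through configuration; the package
defaults and the shipped analyses are desk-scale, chosen so the full test
suite runs in minutes on one CPU while leaving every estimator untouched:
500–1000 markers per chromosome, 150–300 neutral simulations, 10–50
replicate sets. `scripts/acceptance.py` uses: full marker density and 1000
neutral simulations for the generation-10 no-detection rate (cheap at 10
generations, and the quantity is multiplicity-sensitive); 1000
markers/chromosome, 300 neutral simulations and 50 sets for the two-way
precision medians; and five independent random DMI placements × 10 sets
for the multi-locus detected fraction, because that quantity varies by
several points across placements (the 20 true loci land in different
recombination environments each draw).

## Known discrepancies and limitations

* **Generation-10 weak-selection detectability.** Under the procedure as
  specified (binomial tail + genome-wide BH-FDR), a one-way DMI with
  s = 0.05 produces only a ~1-drift-sd allele-frequency shift by
  generation 10 (per-population flag probability 0.14–0.23 at the DMI
  loci), and ~65–75% of 10-population sets yield no estimate — not the
  ~16% previously reported for this scenario. Flagging on *uncorrected*
  p < .05 instead reproduces ~15% no-detection exactly, so the published
  figure appears to reflect an analysis in which the FDR step was
  ineffective at this time point. This package reports the FDR-corrected
  procedure's value; the sensitivity is documented here deliberately.
* **Multi-locus detected fraction.** At generation 100 with additive
  s = 0.02 and 5 populations, the mean fraction of the 20 true loci inside
  mapped blocks converges to ~82–88% (placement ensembles; flat in marker
  density 1000–5000/chromosome and in envelope size), slightly below the
  ~90% headline. One-way pairs whose partner locus drifts after one-sided
  resolution account for most misses.
* The generator emulates census allele frequencies: Pool-Seq sampling and
  sequencing noise are *not* simulated, so passing tests bound what an
  ideal E&R readout could achieve, not what finite read depth delivers.
  Sync-format input support lets the scan run on real (noisy) data, but
  the envelopes remain drift-only nulls.
* Constant N (no extinction dynamics, despite strong selection scenarios),
  no sex chromosomes or sex-limited expression, no gene flow from parental
  species, no linked DMI partners (always on different chromosomes), no
  crossover interference, perfect synteny.
* Generation counting: generation 1 is the F1 founding census, so a sample
  at generation g reflects g − 1 binomial updates; analytic WF checks in
  the tests use the exact exponent.
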