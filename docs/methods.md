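# Methods

`mutscreen` reimplements, at desk scale and on synthetic data, the analysis
chain of a mutator-strain chemoresistance discovery platform: loss of DNA
mismatch repair (msh2Δ) raises the mutation rate ~10⁴-fold, so a culture of
such a "mutator" yeast strain almost always contains a small subpopulation
already carrying a resistance mutation for a given drug. Selection, growth
kinetics, sequencing and cross-isolate convergence then identify the
resistance target. This note records the models, defaults and numerical
choices, and what the synthetic data does and does not establish.

## Culture dynamics (growth_sim)

Two subpopulations, resistant (density `N_r`, cells/mL) and sensitive
(`N_s`), share one carrying capacity `K`:

    dN_r/dt = g(r_res)  N_r,   dN_s/dt = g(r_sens) N_s
    g(r) = r (1 − (N_r+N_s)/K)  if r > 0   (logistic braking)
    g(r) = r                    if r ≤ 0   (death is not capacity-limited)

Observed signal: `OD(t) = od_per_cell (N_r+N_s) + od_offset + ε`,
`ε ~ N(0, noise_sd²)`, clipped at zero. `od_offset` models absorbance of a
coloured compound. Optional mutation supply converts sensitive births to
resistant at `mu_res` per division (Poisson per step); the default is 0
because the platform's passage design selects standing variation.

Integration is fixed-step Euler at `dt/10` (sampling `dt = 0.25 h`). At the
default rates this biases the recovered exponential rate by ≈ `r·dt/20`
(≈0.6% low), well inside every tolerance used here. With `noise_sd = 0`
and `mu_res = 0` no RNG is consumed, so output is deterministic and
seed-independent. Reader saturation is not modelled (curves stay in the
linear range).

Defaults are the screening conditions: saturation density `K = 1e8`
cells/mL, 1:200 inoculum `N0 = 5e5`, `od_per_cell = 1e-8` (OD ≈ 1 at
saturation), drug-free rate `r_nodrug = 0.46 /h` (≈90 min doubling),
readings every 15 min for 48 h, measurement noise 0.01 OD. Inoculum
density after dilution is not stated by the source protocol; the values
above are ordinary for yeast in synthetic complete medium.

The key emergent quantity is the lag of a culture whose resistant fraction
is `f`: the time for `f·N0·e^{rt}` to reach a fixed detection density, so
lag differences obey `Δlag = ln(f2/f1)/r`. The five screen phenotypes are
parameter regimes (`response_regimes()`): no effect, sensitive (both
strains killed), resistant short lag (`f = 1`: resistance is a direct
consequence of MMR loss), resistant long lag (`f = 1e-5`: selection of a
mutant subpopulation), and the mutator-specific synthetic growth defect.

## Growth metrics and classification (growth_metrics)

The original study's R program for lag/rate estimation is unpublished; the
package uses the standard tangent-intercept method on log-transformed OD:

- blank = median of the first 3 readings (captures compound colour and the
  inoculum signal);
- `mu_max` = maximum sliding-window (5-point) least-squares slope of
  `ln(OD − blank + ε)`, `ε = 1e-6`, over windows whose blank-subtracted OD
  is everywhere ≥ a quantification floor (0.01 OD). The floor is required:
  because the blank contains the inoculum, the log of the subtracted
  signal has divergent slope as `OD − blank → 0`. For a logistic culture
  with inoculum fraction `a = N0/K`, the window at subtracted level `x`
  (as a fraction of capacity) estimates `r(1−x)/(1−a/x)`; at the default
  floor and study geometry this lies within ~1% of `r`, and the error is
  bounded by ~2% for `a ≤ 1e-3`.
- `lag_h` = time where the tangent at the `mu_max` window crosses
  `ln(detection margin)` (0.05 OD above blank), clipped to `[0, t_end]`.
  A well whose OD never exceeds blank + 0.05 is censored (`lag = None`,
  `mu_max = 0`).

All three thresholds (ε, floor, margin) are keyword-configurable.

Classification of a compound from (WT, mutator) drug wells plus DMSO
controls applies, in order: (1) both endpoints < 40% of their controls →
sensitive; (2) WT/mutator endpoint ratio ≤ 0.4 → resistance hit, split at
mutator lag ≥ 24 h (long lag, selection resistance) vs < 24 h (short lag,
MMR-conditional resistance), censored lag counting as long; (3) mutator
endpoint < 40% of its control with WT ≥ 70% of its control → synthetic
growth defect; (4) otherwise no effect. The absolute 24-h rule governs the
call; the relative "≥ 2× control lag" criterion is reported as a separate
flag (`prolonged_vs_control`) rather than entering the decision, because
the final screens are defined by the absolute cutoff. The 70% "WT
unaffected" bound is this package's choice; all rules are ratio-based, so
the call is invariant to rescaling every OD by a common gain.

## Synthetic genomes and the MMR spectrum (synthetic_genome)

Reference genomes are random ACGT with non-overlapping, haploid,
single-transcript ATG…stop ORFs (60–140 codons), strand chosen at random;
coordinates are 1-based inclusive. Codon-aligned homopolymer blocks (runs
of 3 or 6 of one base) are injected into each CDS (`hpr_enrichment`
controls the per-codon probability; at least one run ≥ 3 is guaranteed
when it is positive) so frameshift targets always exist. Genes are
intronless except on request, when one GT…AG intron is inserted for
splice-donor scenarios. Gene set "PATHWAY" is a designated multi-gene set
(≤5 genes) for pathway-level scenarios; other sets are random memberships.

Isolates draw background mutations from an MMR-deficient spectrum:
Bernoulli(`rate_hpr_indel`) ±1 slippage indels per homopolymer site (run
length ≥ `min_hpr_len = 3`; deletions with probability `indel_bias = 0.5`)
and Binomial(`L`, `rate_snv`) substitutions. Defaults
`rate_hpr_indel = 1e-3`, `rate_snv = 2e-6` give each isolate a handful of
background events on a desk-scale genome, so replicate isolates share
essentially no mutations outside the selected target — the regime the
platform exploits. (`min_hpr_len = 3` rather than the ≥4 seen in real
worked examples keeps sites plentiful in short toy genomes.) Sampled
events are kept ≥5 bp apart, which both respects the no-overlap invariant
and keeps the minimal alignment between reference and isolate unique, so
exact calling can equal truth. A planted event (frameshift at an exonic
run by default; missense, nonsense or splice-donor selectable; target a
gene or a random member of a target set) is placed first and protected.
Truth variants are stored left-aligned in VCF anchor-base convention;
applying a truth set to the reference reproduces the isolate exactly.

## Variant identification and annotation (variant_analysis)

Read-level calling is out of scope; isolate chromosomes are compared to the
reference by exact global alignment (edlib, Needleman–Wunsch path) and the
edit script converted to VCF-style variants, then normalized (parsimony +
left-alignment, the vt algorithm). For well-separated mutations this
equals the ground truth exactly — verified as a test, not assumed.

Homopolymer notation follows the field's convention: a deletion at an A₆
repeat followed by C is `A6C > A5C`; an insertion is `CA6 > CA7` (5′
flank). Inside genes the notation is computed on the coding strand —
minus-strand genes are reported as the reverse complement of the
reference — otherwise on the reference strand. Runs shorter than
`min_hpr_len` yield no annotation; the notation string round-trips through
a parser.

Coding effects: SNVs are translated codon-wise on the coding strand
(standard genetic code) into missense (`G65R`), nonsense (`Y71*`) or
synonymous, with the codon change (`GGA>AGA`); CDS indels are frameshift
unless their length is divisible by 3 (`inframe_indel`, an extra class
kept so the annotator is total); variants touching the first two intron
bases are splice-donor (the GT dinucleotide only — no broader consensus
scoring); remaining intronic positions are labelled intronic without
effect prediction; everything else is intergenic.

## Convergence and enrichment (convergence)

Convergence counts *isolates*, not variants: a gene qualifies in an
isolate if it carries ≥1 mutation with a qualifying effect (default
{frameshift, nonsense, splice_donor, missense}; missense is included
because a destabilizing substitution in a transporter can confer
resistance just like a truncation — it is configurable). Genes hit in all
isolates are convergent; ranking is (isolate count desc, gene id asc) and
fewer than 3 isolates sets an `underpowered` flag.

Pathway enrichment is a one-sided hypergeometric test: universe `M`
genes, set size `n`, `N` hit genes, overlap `k` → `P(X ≥ k)`, with
Benjamini–Hochberg q-values across sets and (p, name) ordering. Note that
enlarging the universe with genes outside the sets shifts the null
overlap down, so a fixed overlap becomes *more* significant — the tail
p-value is non-increasing in the universe size.

## Combination-therapy scoring (combo_stats)

Each arm is a binomial proportion: fraction `p̂` of `n` cultures (n = 40
in the study design) that developed resistance, `se = sqrt(p̂(1−p̂)/n)`,
displayed as "P ± S%" with round-half-up integer percentages and the ±
part omitted when `se = 0` exactly (p̂ ∈ {0, 1}). Because published pooled
percentages need not be multiples of 1/n, both a count and a fraction
entry point exist. Arms rank ascending by `p̂` (lower resistant fraction =
more effective), ties alphabetical. No confidence intervals beyond ±1 SE
and no between-arm tests are computed.

## Discovery orchestration (discovery)

`run_resistance_discovery` chains the stages for `n_replicate_cultures`
(default 6, the study's sequencing depth): first exposure (drug
parameters default to the long-lag regime, 72 h), then a drug-free 1:200
passage modelled as carrying the evolved resistant fraction into a fresh
inoculum — drug-free growth moves both subpopulations at the same rate,
so the fraction is conserved and no new mutations are added, which is the
point of the passage (it excludes regulatory adaptation) — then
re-exposure, keeping cultures with lag < 24 h. Kept cultures become
isolate genomes with the configured plant; calling, annotation,
convergence and enrichment run exactly as in the individual modules. The
report is a JSON-serializable dict (plus TSV writers); identical configs
give identical reports. If nothing passes reselection the report is an
explicit empty result. The 96-single-colony variant of the protocol is
represented only through `n_replicate_cultures`; colony bottlenecks are
not modelled.

## Problem sizes

Defaults throughout are desk-scale choices of this package: toy genomes of
1–2 chromosomes × 15–90 kb with 8–40 genes; cohorts of 6 isolates;
classification properties evaluated over 100 seeded noisy replicates per
regime; caller-vs-truth agreement over 50 seeded isolates. These sizes
make every statistical check exact or tightly concentrated while the full
suite runs in well under a minute.

## What the synthetic data does not show

The generator emulates the *structure* of the study's data (lag-phase
signatures; ±1 slippage indels at homopolymer runs with planted convergent
inactivating events), not its wet-lab content: no read-level sequencing
error, alignment ambiguity, diploidy/heterozygosity, structural variation,
real chromosome composition, pharmacokinetics, or spatial structure. The
published screen tallies (e.g. 88 broadly sensitive compounds) and the
specific resistance loci are facts about the wet-lab screen and cannot be
reproduced from a desk; passing tests show the pipeline recovers planted
truth under the stated spectrum, not that it would handle raw reads.
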