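# mutscreen

Drug-resistance mechanisms can be discovered rapidly by exploiting DNA
mismatch-repair-deficient (*msh2*Δ) "mutator" yeast: the ~10⁴-fold elevated
mutation rate guarantees that a culture contains rare variants resistant to
almost any compound, selection under drug produces a characteristic
**prolonged lag phase** as the minority expands, and whole-genome sequencing
of replicate resistant isolates reveals the target as the one gene (or
pathway) inactivated in *every* isolate — typically by ±1 frameshifts at
homopolymer runs, the signature mutation class of MMR loss.

`mutscreen` is a tested, desk-scale implementation of that whole analysis
chain for methods development and teaching: every step runs on synthetic
data with known ground truth.

**For whom:** computational biologists studying chemoresistance screens,
growth-curve analysis, or mutator-genome variant calling, who need a fully
seeded, ground-truthed sandbox of the select → passage → reselect →
sequence → converge protocol.

## The models and statistics at the core

- **Culture dynamics** — two-type logistic competition with shared capacity
  K: resistant cells grow at `r_res(1 − N/K)`, sensitive cells grow or die
  at `r_sens`; `OD = c·N + offset + noise`. A resistant fraction *f* yields
  lag differences `Δlag = ln(f₂/f₁)/r`.
- **Kinetics** — tangent-intercept method on ln OD: `μ_max` is the steepest
  5-point sliding-window slope, lag is where that tangent crosses the
  detection level; five-way response classification from endpoint ratios
  (hit when WT OD₆₀₀/*msh2*Δ OD₆₀₀ ≤ 0.4) and the 24-h lag cutoff.
- **MMR mutation spectrum** — per-site slippage indels at homopolymer runs
  (run length ≥ 3) plus rare substitutions; planted inactivating events
  (frameshift, missense, nonsense, splice-donor) with truth VCFs.
- **Variant analysis** — exact global alignment, VCF left-alignment,
  homopolymer run notation (`A6C > A5C`, `CA6 > CA7`, coding-strand for
  minus-strand genes), codon-wise effect calls (`G65R`, `Y71*`, splice
  donor GT).
- **Convergence** — isolate-level gene counts; genes hit in all n isolates;
  one-sided hypergeometric gene-set enrichment `P(X ≥ k)` with
  Benjamini–Hochberg correction.
- **Combination scoring** — resistant fraction with the standard error of
  proportion `se = √(p(1−p)/n)`, displayed "P ± S%", arms ranked ascending.

## Worked example

```python
import mutscreen as ms

# a drug well where 1 cell in 100,000 is resistant (sensitive cells stalled)
drug = ms.SimParams(f_res=1e-5, r_res=0.46, r_sens=0.0, noise_sd=0.0)
m = ms.estimate_growth_metrics(ms.simulate_culture(drug))
print(round(m.lag_h, 1), round(m.mu_max, 3), round(m.od_end, 2))
# 30.4 0.449 0.99
```

A 30.4 h lag (≥ 24 h ⇒ selection resistance: the culture regrew from a
rare pre-existing mutant), a recovered growth rate of ~0.45/h, and full
regrowth to OD ≈ 1 by 48 h.

```python
genome = ms.generate_reference(n_chrom=1, chrom_len=25_000, n_genes=12, seed=5)
isolates, truth = ms.generate_isolate_cohort(
    genome, 6, ms.MutationSpectrum(), plant=("GENE006", "frameshift"), seed=5)
anns = {iso: [ms.annotate_effect(v, genome)
              for v in ms.call_variants(genome.chroms, seqs)]
        for iso, seqs in isolates.items()}
print(ms.convergence_analysis(anns).convergent_genes)
# ['GENE006']
```

Six replicate isolates, each with background mutations plus one planted
frameshift; calling and annotation recover `GENE006` as the gene mutated
in all six — the convergence signature that names a resistance target.

The numbered drivers under `analysis/` run the same steps as a narrative
pipeline (simulate plate → metrics/classification → genomes → call/annotate
→ convergence → combination ranking → end-to-end discovery), writing their
tables under `results/`:

```bash
python analysis/01_simulate_screen.py
python analysis/02_growth_metrics.py
# ... through 07_discovery_pipeline.py
```

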