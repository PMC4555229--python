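#!/usr/bin/env python
"""Convergence analysis across the six isolates: which gene is mutated in
all of them, and how do the annotated hit genes enrich in gene sets?

Reads results/annotations.tsv and results/genomes/ (from 04); writes
results/convergence.tsv and results/enrichment.tsv.
"""

from pathlib import Path

import pandas as pd

from mutscreen import (
    DEFAULT_QUALIFYING_EFFECTS,
    Effect,
    EffectAnnotation,
    Variant,
    convergence_analysis,
    pathway_enrichment,
    read_fasta,
    read_gene_sets,
    read_gff3,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ann_path = RESULTS / "annotations.tsv"
    if not ann_path.exists():
        raise SystemExit("run analysis/04_call_annotate.py first")
    df = pd.read_csv(ann_path, sep="\t")
    annotations = {}
    for iso, grp in df.groupby("isolate"):
        annotations[iso] = [
            EffectAnnotation(
                variant=Variant(r.chrom, r.pos, r.ref, r.alt),
                gene_id=None if r.gene == "intergenic" else r.gene,
                effect=Effect(r.effect),
            )
            for r in grp.itertuples()
        ]
    res = convergence_analysis(annotations)
    res.to_frame().to_csv(RESULTS / "convergence.tsv", sep="\t", index=False)
    print(res.to_frame().to_string(index=False))
    print(f"\nconvergent gene(s) hit in all {res.n_isolates} isolates: "
          f"{', '.join(res.convergent_genes) or 'none'}")

    gene_sets = read_gene_sets(RESULTS / "genomes" / "gene_sets.tsv")
    universe = sorted(g.gene_id for g in read_gff3(RESULTS / "genomes" / "reference.gff3"))
    hit = sorted(
        {a.gene_id for al in annotations.values() for a in al
         if a.gene_id and a.effect in DEFAULT_QUALIFYING_EFFECTS}
    )
    enr = pathway_enrichment(hit, gene_sets, universe)
    enr.to_csv(RESULTS / "enrichment.tsv", sep="\t", index=False)
    print("\ngene-set enrichment of hit genes:")
    print(enr.to_string(index=False))


if __name__ == "__main__":
    main()
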