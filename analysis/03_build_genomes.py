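#!/usr/bin/env python
"""Generate the synthetic reference genome and six drug-resistant isolates
with a planted frameshift in one target gene (the mitoxantrone/IPT1-style
single-gene scenario), under the MMR-deficient background spectrum.

Writes results/genomes/: reference FASTA + GFF3 + gene sets TSV, one FASTA
per isolate, and one ground-truth VCF per isolate.
"""

import sys
from pathlib import Path

from mutscreen import (
    MutationSpectrum,
    generate_isolate_cohort,
    generate_reference,
    write_fasta,
    write_gene_sets,
    write_gff3,
    write_vcf,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "genomes"
TARGET = "GENE006"


def main(seed: int = 1) -> None:
    genome = generate_reference(
        n_chrom=2, chrom_len=20_000, n_genes=12, n_sets=3, seed=seed
    )
    isolates, truth = generate_isolate_cohort(
        genome, 6, MutationSpectrum(), plant=(TARGET, "frameshift"), seed=seed
    )
    OUT.mkdir(parents=True, exist_ok=True)
    write_fasta(genome.chroms, OUT / "reference.fa")
    write_gff3(genome.genes, OUT / "reference.gff3")
    write_gene_sets(genome.gene_sets, OUT / "gene_sets.tsv")
    for iso_id, seqs in isolates.items():
        write_fasta(seqs, OUT / f"{iso_id}.fa")
        write_vcf(truth[iso_id], genome.chroms, OUT / f"{iso_id}.truth.vcf")
    n_events = {iso: len(v) for iso, v in truth.items()}
    print(f"reference: {sum(map(len, genome.chroms.values()))} bp, "
          f"{len(genome.genes)} genes, planted frameshift target: {TARGET}")
    print(f"truth events per isolate: {n_events}")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
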