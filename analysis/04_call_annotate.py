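#!/usr/bin/env python
"""Call variants in each isolate against the reference by exact global
alignment, verify the calls against the ground-truth VCFs, and annotate
every call with its coding effect and homopolymer-run notation.

Reads results/genomes/ (from 03_build_genomes.py); writes one call VCF per
isolate plus results/annotations.tsv.
"""

from pathlib import Path

from mutscreen import (
    AnnotatedGenome,
    annotate_effect,
    annotation_frame,
    call_variants,
    read_fasta,
    read_gene_sets,
    read_gff3,
    read_vcf,
    write_vcf,
)

GENOMES = Path(__file__).resolve().parent.parent / "results" / "genomes"
RESULTS = GENOMES.parent


def main() -> None:
    if not (GENOMES / "reference.fa").exists():
        raise SystemExit("run analysis/03_build_genomes.py first")
    genome = AnnotatedGenome(
        chroms=read_fasta(GENOMES / "reference.fa"),
        genes=read_gff3(GENOMES / "reference.gff3"),
        gene_sets=read_gene_sets(GENOMES / "gene_sets.tsv"),
    )
    annotations = {}
    exact = 0
    iso_paths = sorted(p for p in GENOMES.glob("isolate*.fa"))
    for path in iso_paths:
        iso_id = path.stem
        called = call_variants(genome.chroms, read_fasta(path))
        truth = sorted(read_vcf(GENOMES / f"{iso_id}.truth.vcf"),
                       key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
        exact += called == truth
        write_vcf(called, genome.chroms, GENOMES / f"{iso_id}.calls.vcf")
        annotations[iso_id] = [annotate_effect(v, genome) for v in called]
    df = annotation_frame(annotations, genome)
    df.to_csv(RESULTS / "annotations.tsv", sep="\t", index=False)
    print(f"{exact}/{len(iso_paths)} isolates: called variants identical to truth")
    print(df[df.gene != "intergenic"].to_string(index=False))


if __name__ == "__main__":
    main()
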