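"""Synthetic-data generator: toy annotated genomes and mutator isolates.

Emulates the genomic raw material of a mismatch-repair-deficient (msh2)
selection experiment: a reference genome whose coding sequences are seeded
with homopolymer runs (the substrate of replication-slippage indels), and
isolate genomes carrying (i) background mutations drawn from an
MMR-deficient spectrum dominated by +/-1 indels at homopolymer runs and
(ii) optionally one planted inactivating resistance mutation in a target
gene or a random member of a target gene set.  Every isolate comes with its
ground-truth variant list (left-aligned, VCF anchor-base convention), so
downstream callers can be validated by set equality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import AnnotatedGenome, GeneModel, apply_variants, find_homopolymers, revcomp
from .variant_analysis import Variant

__all__ = [
    "MutationSpectrum",
    "generate_reference",
    "mutate_isolate",
    "generate_isolate_cohort",
]

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
_SAFE_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)
#: homopolymer-run codons (runs of one base across codons stay in frame)
_RUN_CODONS = {b: b * 3 for b in _BASES}


@dataclass(frozen=True)
class MutationSpectrum:
    """MMR-deficient mutation spectrum for background mutations.

    Defaults make slippage indels at homopolymer runs the dominant event
    class with a minority of substitutions, at rates giving each isolate a
    handful of background events on a desk-scale genome — so replicate
    isolates share essentially no mutations outside the selected target,
    the regime the platform exploits.
    """

    rate_hpr_indel: float = 1e-3  # per homopolymer site, per isolate
    rate_snv: float = 2e-6  # per base, per isolate
    min_hpr_len: int = 3  # minimum run length counted as a slippage site
    indel_bias: float = 0.5  # P(deletion | slippage event)

    def __post_init__(self) -> None:
        for name in ("rate_hpr_indel", "rate_snv", "indel_bias"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.min_hpr_len < 2:
            raise ValueError("min_hpr_len must be >= 2")


def _random_gene_codons(rng: np.random.Generator, hpr_enrichment: float) -> list[str]:
    n_codons = int(rng.integers(60, 140))
    codons = ["ATG"]
    placed_run = False
    for _ in range(n_codons):
        if hpr_enrichment > 0 and rng.random() < hpr_enrichment:
            base = _BASES[rng.integers(4)]
            codons.append(_RUN_CODONS[base])
            if rng.random() < 0.5:  # half the runs span two codons (length 6)
                codons.append(_RUN_CODONS[base])
            placed_run = True
        else:
            codons.append(_SAFE_CODONS[rng.integers(len(_SAFE_CODONS))])
    if hpr_enrichment > 0 and not placed_run:
        base = _BASES[rng.integers(4)]
        mid = 1 + int(rng.integers(1, len(codons)))
        codons[mid:mid] = [_RUN_CODONS[base], _RUN_CODONS[base]]
    codons.append(_STOPS[rng.integers(3)])
    return codons


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def generate_reference(
    n_chrom: int = 1,
    chrom_len: int = 20_000,
    n_genes: int = 10,
    n_sets: int = 3,
    hpr_enrichment: float = 0.15,
    seed: int = 0,
    intron_genes: int = 0,
) -> AnnotatedGenome:
    """Random annotated genome with homopolymer runs inside CDS.

    Every gene is an intronless ATG...stop ORF unless it is among the first
    ``intron_genes`` genes, which receive one GT...AG intron (for
    splice-donor scenarios).  With ``hpr_enrichment > 0`` every CDS carries
    at least one run of length >= 3.  Gene set "PATHWAY" is a designated
    multi-gene set for pathway-level (bactobolin-style) scenarios; further
    sets are random memberships.
    """
    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    assignments = [chrom_names[i % n_chrom] for i in range(n_genes)]

    chrom_parts: dict[str, list[str]] = {c: [] for c in chrom_names}
    chrom_cursor: dict[str, int] = {c: 0 for c in chrom_names}
    genes: list[GeneModel] = []

    for gi in range(n_genes):
        chrom = assignments[gi]
        codons = _random_gene_codons(rng, hpr_enrichment)
        coding = "".join(codons)

        if gi < intron_genes:
            # insert one intron between two internal codons
            split = 3 * int(rng.integers(5, len(codons) - 5))
            intron = "GT" + _random_seq(rng, int(rng.integers(30, 50))) + "AG"
            exon_lens = (split, len(coding) - split)
            block_coding = coding[:split] + intron + coding[split:]
        else:
            intron = ""
            exon_lens = (len(coding),)
            block_coding = coding

        strand = "+" if rng.random() < 0.5 else "-"
        block = block_coding if strand == "+" else revcomp(block_coding)

        gap = int(rng.integers(100, 300))
        start = chrom_cursor[chrom] + gap + 1  # 1-based gene start
        end = start + len(block) - 1
        if end > chrom_len:
            raise ValueError(
                f"infeasible packing: gene {gi} ends at {end} > chrom_len {chrom_len}"
            )
        chrom_parts[chrom].append(_random_seq(rng, gap))
        chrom_parts[chrom].append(block)
        chrom_cursor[chrom] = end

        if len(exon_lens) == 1:
            exons: tuple[tuple[int, int], ...] = ((start, end),)
        else:
            # coding-strand order exons; map to genomic coordinates
            if strand == "+":
                e1 = (start, start + exon_lens[0] - 1)
                e2 = (e1[1] + len(intron) + 1, end)
            else:
                e1 = (end - exon_lens[0] + 1, end)
                e2 = (start, e1[0] - len(intron) - 1)
            exons = tuple(sorted((e1, e2)))
        genes.append(
            GeneModel(
                gene_id=f"GENE{gi:03d}",
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                exons=exons,
            )
        )

    chroms = {}
    for c in chrom_names:
        tail = chrom_len - chrom_cursor[c]
        chrom_parts[c].append(_random_seq(rng, tail))
        chroms[c] = "".join(chrom_parts[c])
        assert len(chroms[c]) == chrom_len

    gene_ids = [g.gene_id for g in genes]
    gene_sets: dict[str, list[str]] = {}
    if n_sets > 0 and n_genes > 0:
        pathway_size = min(5, n_genes)
        members = rng.choice(n_genes, size=pathway_size, replace=False)
        gene_sets["PATHWAY"] = sorted(gene_ids[i] for i in members)
        for j in range(1, n_sets):
            picks = [gid for gid in gene_ids if rng.random() < 0.3]
            if not picks:
                picks = [gene_ids[int(rng.integers(n_genes))]]
            gene_sets[f"SET{j:02d}"] = picks

    return AnnotatedGenome(chroms=chroms, genes=genes, gene_sets=gene_sets)


def _exonic_runs(genome: AnnotatedGenome, gene: GeneModel, min_len: int):
    """Homopolymer runs fully inside one exon of ``gene`` (1-based)."""
    seq = genome.chroms[gene.chrom]
    out = []
    for rs, re_, base in find_homopolymers(seq, min_len):
        if rs < 2:
            continue
        if any(s <= rs and re_ <= e for s, e in gene.exons):
            out.append((rs, re_, base))
    return out


class _Blocker:
    """Tracks blocked reference intervals so sampled events never overlap
    (pad keeps indel runs and substitutions well separated, preserving the
    uniqueness of the minimal alignment)."""

    def __init__(self, pad: int = 5) -> None:
        self.pad = pad
        self.blocked: dict[str, set[int]] = {}

    def is_free(self, chrom: str, lo: int, hi: int) -> bool:
        b = self.blocked.get(chrom, set())
        return not any(p in b for p in range(lo - self.pad, hi + self.pad + 1))

    def block(self, chrom: str, lo: int, hi: int) -> None:
        self.blocked.setdefault(chrom, set()).update(range(lo - self.pad, hi + self.pad + 1))


def _plant_frameshift(rng, genome, gene, spectrum, blocker) -> Variant:
    runs = [
        r
        for r in _exonic_runs(genome, gene, spectrum.min_hpr_len)
        if blocker.is_free(gene.chrom, r[0] - 1, r[1])
    ]
    if not runs:
        raise ValueError(
            f"gene {gene.gene_id} has no suitable homopolymer run; "
            "regenerate the genome (e.g. raise hpr_enrichment)"
        )
    rs, re_, base = runs[int(rng.integers(len(runs)))]
    seq = genome.chroms[gene.chrom]
    anchor = seq[rs - 2]
    if rng.random() < spectrum.indel_bias:
        v = Variant(gene.chrom, rs - 1, anchor + base, anchor)  # -1 deletion
    else:
        v = Variant(gene.chrom, rs - 1, anchor, anchor + base)  # +1 insertion
    blocker.block(gene.chrom, rs - 1, re_)
    return v


def _plant_substitution(rng, genome, gene, kind: str, blocker) -> Variant:
    """Single-base substitution with a requested coding consequence."""
    from .variant_analysis import _translate_codon

    cds = gene.coding_sequence(genome.chroms)
    n_codons = len(cds) // 3
    order = rng.permutation(n_codons - 2) + 1  # skip start and stop codons
    for codon_i in order:
        ref_codon = cds[3 * codon_i : 3 * codon_i + 3]
        aa_ref = _translate_codon(ref_codon)
        for off in rng.permutation(3):
            for alt_base in _BASES:
                if alt_base == ref_codon[off]:
                    continue
                alt_codon = ref_codon[:off] + alt_base + ref_codon[off + 1 :]
                aa_alt = _translate_codon(alt_codon)
                if kind == "nonsense" and aa_alt != "*":
                    continue
                if kind == "missense" and (aa_alt == aa_ref or aa_alt == "*"):
                    continue
                gpos = gene.genomic_position(3 * codon_i + int(off))
                if not blocker.is_free(gene.chrom, gpos, gpos):
                    continue
                seq = genome.chroms[gene.chrom]
                g_ref = seq[gpos - 1]
                g_alt = alt_base if gene.strand == "+" else revcomp(alt_base)
                blocker.block(gene.chrom, gpos, gpos)
                return Variant(gene.chrom, gpos, g_ref, g_alt)
    raise ValueError(f"could not construct a {kind} substitution in {gene.gene_id}")


def _plant_splice_donor(rng, genome, gene, blocker) -> Variant:
    sites = gene.donor_sites()
    if not sites:
        raise ValueError(f"gene {gene.gene_id} has no intron; cannot hit a splice donor")
    d1, d2 = sites[int(rng.integers(len(sites)))]
    gpos = d1 if rng.random() < 0.5 else d2
    seq = genome.chroms[gene.chrom]
    g_ref = seq[gpos - 1]
    g_alt = "A" if g_ref != "A" else "C"
    blocker.block(gene.chrom, gpos, gpos)
    return Variant(gene.chrom, gpos, g_ref, g_alt)


def mutate_isolate(
    genome: AnnotatedGenome,
    spectrum: MutationSpectrum | None = None,
    plant: tuple[str, str] | None = None,
    seed: int = 0,
) -> tuple[dict[str, str], list[Variant]]:
    """One isolate genome under the MMR-deficient spectrum.

    Parameters
    ----------
    plant
        Optional ``(target, effect_class)``: target is a gene id or a
        gene-set name (a random member gene is then chosen); effect_class is
        one of ``frameshift`` (default inactivating event: +/-1 indel at an
        exonic homopolymer run), ``missense``, ``nonsense``,
        ``splice_donor``. Exactly one planted event is introduced.

    Returns
    -------
    (isolate chromosome sequences, ground-truth Variant list), the truth
    left-aligned and sorted; applying it to the reference reproduces the
    isolate exactly.
    """
    spectrum = spectrum or MutationSpectrum()
    rng = np.random.default_rng(seed)
    blocker = _Blocker()
    variants: list[Variant] = []

    if plant is not None:
        target, kind = plant
        if target in genome.gene_sets:
            members = sorted(genome.gene_sets[target])
            gene = genome.gene_by_id(members[int(rng.integers(len(members)))])
        else:
            gene = genome.gene_by_id(target)
        if kind == "frameshift":
            variants.append(_plant_frameshift(rng, genome, gene, spectrum, blocker))
        elif kind in ("missense", "nonsense"):
            variants.append(_plant_substitution(rng, genome, gene, kind, blocker))
        elif kind == "splice_donor":
            variants.append(_plant_splice_donor(rng, genome, gene, blocker))
        else:
            raise ValueError(f"unknown planted effect class: {kind!r}")

    # background slippage indels at homopolymer sites
    if spectrum.rate_hpr_indel > 0:
        for chrom in sorted(genome.chroms):
            seq = genome.chroms[chrom]
            for rs, re_, base in find_homopolymers(seq, spectrum.min_hpr_len):
                if rs < 2 or rng.random() >= spectrum.rate_hpr_indel:
                    continue
                if not blocker.is_free(chrom, rs - 1, re_):
                    continue
                anchor = seq[rs - 2]
                if rng.random() < spectrum.indel_bias:
                    variants.append(Variant(chrom, rs - 1, anchor + base, anchor))
                else:
                    variants.append(Variant(chrom, rs - 1, anchor, anchor + base))
                blocker.block(chrom, rs - 1, re_)

    # background substitutions
    if spectrum.rate_snv > 0:
        for chrom in sorted(genome.chroms):
            seq = genome.chroms[chrom]
            n = rng.binomial(len(seq), spectrum.rate_snv)
            for pos in sorted(int(p) + 1 for p in rng.choice(len(seq), size=n, replace=False)):
                if not blocker.is_free(chrom, pos, pos):
                    continue
                ref = seq[pos - 1]
                alt = _BASES[rng.integers(4)]
                while alt == ref:
                    alt = _BASES[rng.integers(4)]
                variants.append(Variant(chrom, pos, ref, alt))
                blocker.block(chrom, pos, pos)

    variants.sort(key=lambda v: (v.chrom, v.pos))
    iso = {
        chrom: apply_variants(seq, [v for v in variants if v.chrom == chrom])
        for chrom, seq in genome.chroms.items()
    }
    return iso, variants


def generate_isolate_cohort(
    genome: AnnotatedGenome,
    n_isolates: int,
    spectrum: MutationSpectrum | None = None,
    plant: tuple[str, str] | None = None,
    seed: int = 0,
) -> tuple[dict[str, dict[str, str]], dict[str, list[Variant]]]:
    """Replicate isolates (independent seeds) with a shared planting scheme.

    Returns (isolate_id -> chromosome sequences, isolate_id -> truth set).
    """
    isolates: dict[str, dict[str, str]] = {}
    truth: dict[str, list[Variant]] = {}
    for i in range(n_isolates):
        iso_id = f"isolate{i + 1}"
        seqs, vs = mutate_isolate(
            genome, spectrum, plant=plant, seed=(seed * 10_007 + i) % (2**31)
        )
        isolates[iso_id] = seqs
        truth[iso_id] = vs
    return isolates, truth
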