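"""Desk-scale variant identification, normalization, and annotation.

Variants between a reference and an isolate chromosome are recovered by
exact global alignment (edlib) and reported VCF-style: 1-based position of
the anchor base, ref/alt allele strings, left-aligned so that an indel
inside a homopolymer run is anchored immediately 5' of the run.

Two annotation layers reproduce the reporting conventions of mutator-strain
resistance studies:

- homopolymer-run notation, e.g. a deletion at an A6 repeat followed by a C
  (AAAAAAC) is "A6C > A5C" and an insertion is "CA6 > CA7", computed on the
  coding strand for genic variants (minus-strand genes are reported as the
  reverse complement of the reference);
- coding effects: frameshift, missense (e.g. G65R), nonsense (e.g. Y123*),
  synonymous, splice-donor (GT) disruption, intronic, intergenic.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import edlib

from .genome import AnnotatedGenome, GeneModel, revcomp

__all__ = [
    "Variant",
    "Effect",
    "EffectAnnotation",
    "HomopolymerAnnotation",
    "call_variants",
    "normalize_variant",
    "annotate_homopolymer",
    "annotate_effect",
    "parse_hpr_notation",
    "write_vcf",
    "read_vcf",
    "annotation_frame",
]

_STANDARD_CODE = {}


def _translate_codon(codon: str) -> str:
    from Bio.Seq import Seq

    if codon not in _STANDARD_CODE:
        _STANDARD_CODE[codon] = str(Seq(codon).translate())
    return _STANDARD_CODE[codon]


@dataclass(frozen=True, order=True)
class Variant:
    """Normalized variant: 1-based anchor position, VCF-style alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if not self.ref or not self.alt:
            raise ValueError("empty allele; use VCF anchor-base convention")

    @property
    def vtype(self) -> str:
        if len(self.ref) == len(self.alt):
            return "SNV"
        return "INS" if len(self.alt) > len(self.ref) else "DEL"

    @property
    def indel_length(self) -> int:
        return len(self.alt) - len(self.ref)


class Effect(enum.Enum):
    FRAMESHIFT = "frameshift"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SYNONYMOUS = "synonymous"
    SPLICE_DONOR = "splice_donor"
    INFRAME_INDEL = "inframe_indel"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"


#: effect classes counted as gene-inactivating for convergence analysis
INACTIVATING_EFFECTS = frozenset({Effect.FRAMESHIFT, Effect.NONSENSE, Effect.SPLICE_DONOR})


@dataclass(frozen=True)
class EffectAnnotation:
    variant: Variant
    gene_id: str | None
    effect: Effect
    protein_change: str | None = None  # e.g. G65R, Y123*
    codon_change: str | None = None  # e.g. GGA>AGA, coding strand
    reported_strand_note: bool = False  # minus-strand gene: alleles reported revcomp'd


@dataclass(frozen=True)
class HomopolymerAnnotation:
    """Run-length notation of an indel at a homopolymer, on the reported
    strand (coding strand inside genes, reference strand otherwise)."""

    unit: str  # repeated base
    run_ref: int  # run length in the reference
    run_alt: int  # run length in the isolate
    flank: str  # flanking base shown in the notation
    side: str  # "3p" (deletions: 3' flank) or "5p" (insertions: 5' flank)

    @property
    def notation(self) -> str:
        if self.side == "3p":
            return f"{self.unit}{self.run_ref}{self.flank} > {self.unit}{self.run_alt}{self.flank}"
        return f"{self.flank}{self.unit}{self.run_ref} > {self.flank}{self.unit}{self.run_alt}"


_DEL_STYLE = re.compile(r"^([ACGT])(\d+)([ACGT])$")
_INS_STYLE = re.compile(r"^([ACGT])([ACGT])(\d+)$")


def parse_hpr_notation(notation: str) -> HomopolymerAnnotation:
    """Parse "A6C > A5C" / "CA6 > CA7" back into its fields (round-trip of
    :attr:`HomopolymerAnnotation.notation`)."""
    left, right = (part.strip() for part in notation.split(">"))
    m_l, m_r = _DEL_STYLE.match(left), _DEL_STYLE.match(right)
    if m_l and m_r:
        unit, run_ref, flank = m_l.group(1), int(m_l.group(2)), m_l.group(3)
        if m_r.group(1) != unit or m_r.group(3) != flank:
            raise ValueError(f"inconsistent notation: {notation!r}")
        return HomopolymerAnnotation(unit, run_ref, int(m_r.group(2)), flank, "3p")
    m_l, m_r = _INS_STYLE.match(left), _INS_STYLE.match(right)
    if m_l and m_r:
        flank, unit, run_ref = m_l.group(1), m_l.group(2), int(m_l.group(3))
        if m_r.group(1) != flank or m_r.group(2) != unit:
            raise ValueError(f"inconsistent notation: {notation!r}")
        return HomopolymerAnnotation(unit, run_ref, int(m_r.group(3)), flank, "5p")
    raise ValueError(f"unrecognized homopolymer notation: {notation!r}")


# ---------------------------------------------------------------------------
# calling & normalization

def normalize_variant(seq: str, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-align and parsimony-trim one variant against its chromosome.

    Standard VCF normalization: repeatedly trim identical terminal bases,
    extending left with the previous reference base whenever an allele
    would become empty; finally trim identical leading bases. The result is
    the unique leftmost minimal representation.
    """
    ref, alt = str(ref), str(alt)
    while True:
        if ref and alt and ref[-1] == alt[-1] and not (len(ref) == 1 and len(alt) == 1):
            if len(ref) == 1 or len(alt) == 1:
                if pos == 1:
                    break
                pos -= 1
                b = seq[pos - 1]
                ref, alt = b + ref, b + alt
            ref, alt = ref[:-1], alt[:-1]
        else:
            break
    while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    return pos, ref, alt


_CIGAR_RE = re.compile(r"(\d+)([=XID])")


def call_variants(
    reference: Mapping[str, str], isolate: Mapping[str, str], *, max_length_diff: int = 1000
) -> list[Variant]:
    """Minimal edit set recovering each isolate chromosome from the
    reference, reported as normalized Variants.

    For sparse, well-separated mutations (the synthetic generator's regime)
    the result equals the ground-truth variant set.
    """
    if set(reference) != set(isolate):
        raise ValueError(
            f"chromosome name mismatch: {sorted(reference)} vs {sorted(isolate)}"
        )
    variants: list[Variant] = []
    for chrom in sorted(reference):
        r, q = reference[chrom], isolate[chrom]
        if abs(len(q) - len(r)) > max_length_diff:
            raise ValueError(f"isolate chromosome {chrom} length differs by > {max_length_diff}")
        if r == q:
            continue
        aln = edlib.align(q, r, task="path", mode="NW")
        ri = qi = 0  # 0-based cursors in reference / isolate
        for num_s, op in _CIGAR_RE.findall(aln["cigar"]):
            n = int(num_s)
            if op == "=":
                ri += n
                qi += n
            elif op == "X":
                for k in range(n):
                    variants.append(Variant(chrom, ri + k + 1, r[ri + k], q[qi + k]))
                ri += n
                qi += n
            elif op == "D":  # bases in reference absent from isolate
                if ri == 0:
                    raise ValueError("deletion at chromosome start is unsupported")
                pos, ref_a, alt_a = normalize_variant(
                    r, ri, r[ri - 1 : ri + n], r[ri - 1]
                )
                variants.append(Variant(chrom, pos, ref_a, alt_a))
                ri += n
            elif op == "I":  # bases in isolate absent from reference
                if ri == 0:
                    raise ValueError("insertion before chromosome start is unsupported")
                pos, ref_a, alt_a = normalize_variant(
                    r, ri, r[ri - 1], r[ri - 1] + q[qi : qi + n]
                )
                variants.append(Variant(chrom, pos, ref_a, alt_a))
                qi += n
    return sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))


# ---------------------------------------------------------------------------
# annotation

def _indel_unit(v: Variant) -> str | None:
    """The inserted/deleted sequence for a VCF-style anchored indel, or None."""
    if v.vtype == "INS" and v.alt[0] == v.ref and len(v.ref) == 1:
        return v.alt[1:]
    if v.vtype == "DEL" and v.alt == v.ref[0] and len(v.alt) == 1:
        return v.ref[1:]
    return None


def annotate_homopolymer(
    v: Variant,
    genome: AnnotatedGenome | Mapping[str, str],
    *,
    min_hpr_len: int = 3,
) -> HomopolymerAnnotation | None:
    """Run-length notation for indels extending/contracting a homopolymer
    run of length >= ``min_hpr_len`` on the reported strand; None otherwise.

    ``v`` must be normalized (left-aligned), so the indel is anchored on
    the base immediately 5' of the run on the reference strand.
    """
    if isinstance(genome, AnnotatedGenome):
        chroms = genome.chroms
        gene = genome.gene_at(v.chrom, v.pos + 1)
    else:
        chroms, gene = genome, None
    seq = chroms[v.chrom]

    unit_seq = _indel_unit(v)
    if unit_seq is None or len(set(unit_seq)) != 1:
        return None
    base = unit_seq[0]
    k = len(unit_seq)

    # maximal run of `base` in the reference beginning right after the anchor
    i = v.pos  # 0-based index of the base after the anchor
    run_start = i
    run_end = i
    while run_end < len(seq) and seq[run_end] == base:
        run_end += 1
    run_ref = run_end - run_start
    if run_ref < min_hpr_len:
        return None
    run_alt = run_ref + (k if v.vtype == "INS" else -k)

    strand = gene.strand if gene is not None else "+"
    if strand == "+":
        flank3 = seq[run_end] if run_end < len(seq) else ""
        flank5 = seq[run_start - 1]
        unit = base
    else:
        unit = revcomp(base)
        # coding-strand 3' flank is the reverse complement of the base 5'
        # of the run on the reference strand, and vice versa
        flank3 = revcomp(seq[run_start - 1])
        flank5 = revcomp(seq[run_end]) if run_end < len(seq) else ""
    if v.vtype == "DEL":
        return HomopolymerAnnotation(unit, run_ref, run_alt, flank3, "3p")
    return HomopolymerAnnotation(unit, run_ref, run_alt, flank5, "5p")


def _affected_positions(v: Variant) -> tuple[int, int]:
    """Inclusive range of reference positions altered by the variant."""
    if v.vtype == "SNV":
        return v.pos, v.pos + len(v.ref) - 1
    if v.vtype == "DEL":
        return v.pos + 1, v.pos + len(v.ref) - 1
    # insertion: the junction between anchor and the next base
    return v.pos, v.pos + 1


def annotate_effect(v: Variant, genome: AnnotatedGenome) -> EffectAnnotation:
    """Coding consequence of a normalized variant against the gene models."""
    if v.chrom not in genome.chroms:
        raise ValueError(f"variant on unknown chromosome {v.chrom!r}")
    lo, hi = _affected_positions(v)
    gene = None
    for g in genome.genes:
        if g.chrom == v.chrom and not (hi < g.start or lo > g.end):
            gene = g
            break
    if gene is None:
        return EffectAnnotation(v, None, Effect.INTERGENIC)

    note = gene.strand == "-"

    for d1, d2 in gene.donor_sites():
        if lo <= d1 <= hi or lo <= d2 <= hi:
            return EffectAnnotation(v, gene.gene_id, Effect.SPLICE_DONOR, reported_strand_note=note)

    in_exon = any(
        not (hi < s or lo > e) for s, e in gene.exons
    )
    if not in_exon:
        return EffectAnnotation(v, gene.gene_id, Effect.INTRONIC, reported_strand_note=note)

    if v.vtype == "SNV":
        ci = gene.cds_index(v.pos)
        if ci is None:  # SNV at intron boundary bases handled above/intronic
            return EffectAnnotation(v, gene.gene_id, Effect.INTRONIC, reported_strand_note=note)
        cds = gene.coding_sequence(genome.chroms)
        codon_i, off = divmod(ci, 3)
        ref_codon = cds[3 * codon_i : 3 * codon_i + 3]
        alt_base = v.alt if gene.strand == "+" else revcomp(v.alt)
        alt_codon = ref_codon[:off] + alt_base + ref_codon[off + 1 :]
        aa_ref = _translate_codon(ref_codon)
        aa_alt = _translate_codon(alt_codon)
        n = codon_i + 1
        codon_change = f"{ref_codon}>{alt_codon}"
        if aa_alt == aa_ref:
            return EffectAnnotation(
                v, gene.gene_id, Effect.SYNONYMOUS, f"{aa_ref}{n}{aa_alt}", codon_change, note
            )
        if aa_alt == "*":
            return EffectAnnotation(
                v, gene.gene_id, Effect.NONSENSE, f"{aa_ref}{n}*", codon_change, note
            )
        return EffectAnnotation(
            v, gene.gene_id, Effect.MISSENSE, f"{aa_ref}{n}{aa_alt}", codon_change, note
        )

    # indel overlapping an exon
    if abs(v.indel_length) % 3 != 0:
        return EffectAnnotation(v, gene.gene_id, Effect.FRAMESHIFT, reported_strand_note=note)
    return EffectAnnotation(v, gene.gene_id, Effect.INFRAME_INDEL, reported_strand_note=note)


# ---------------------------------------------------------------------------
# VCF + annotation tables

def write_vcf(
    variants: list[Variant], chroms: Mapping[str, str], path: str | Path, sample: str = "isolate"
) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        "##source=mutscreen",
    ]
    for name in sorted(chroms):
        lines.append(f"##contig=<ID={name},length={len(chroms[name])}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
        lines.append(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> list[Variant]:
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                out.append(Variant(rec.chrom, rec.pos, rec.ref, alt))
    return out


def annotation_frame(annotations, genome: AnnotatedGenome, *, min_hpr_len: int = 3):
    """Per-variant annotation table (gene, effect, protein change, run
    notation, position) for report/TSV output."""
    import pandas as pd

    rows = []
    for isolate_id, anns in annotations.items():
        for a in anns:
            hpr = annotate_homopolymer(a.variant, genome, min_hpr_len=min_hpr_len)
            rows.append(
                {
                    "isolate": isolate_id,
                    "chrom": a.variant.chrom,
                    "pos": a.variant.pos,
                    "ref": a.variant.ref,
                    "alt": a.variant.alt,
                    "gene": a.gene_id or "intergenic",
                    "effect": a.effect.value,
                    "protein_change": a.protein_change or "",
                    "codon_change": a.codon_change or "",
                    "hpr_notation": hpr.notation if hpr else "",
                    "revcomp_reported": a.reported_strand_note,
                }
            )
    return pd.DataFrame(rows)
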