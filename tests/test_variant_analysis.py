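"""Variant calling, left-alignment, homopolymer notation, coding effects."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mutscreen import (
    AnnotatedGenome,
    Effect,
    GeneModel,
    MutationSpectrum,
    Variant,
    annotate_effect,
    annotate_homopolymer,
    apply_variants,
    call_variants,
    generate_reference,
    mutate_isolate,
    normalize_variant,
    parse_hpr_notation,
    read_vcf,
    revcomp,
    write_vcf,
)

# ---------------------------------------------------------------------------
# calling & normalization


def test_identical_sequences_yield_no_variants(toy_genome):
    assert call_variants(toy_genome.chroms, dict(toy_genome.chroms)) == []


def test_chromosome_name_mismatch_errors(toy_genome):
    with pytest.raises(ValueError, match="mismatch"):
        call_variants(toy_genome.chroms, {"weird": "ACGT"})


def test_called_variants_equal_truth_on_seeded_isolates(toy_genome):
    spectrum = MutationSpectrum(rate_snv=1e-4)
    for seed in range(10):
        iso, truth = mutate_isolate(
            toy_genome, spectrum, plant=("GENE005", "frameshift"), seed=seed
        )
        called = call_variants(toy_genome.chroms, iso)
        assert called == sorted(truth, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))


def test_deletion_anywhere_in_run_reports_leftmost():
    """Deleting any A of CAAAAAAC gives the same left-aligned call, anchored
    immediately 5' of the run (enumeration over equivalent placements)."""
    ref = "GGTT" + "C" + "A" * 6 + "C" + "GGTT"
    run_start = 6  # 1-based position of the first A
    calls = set()
    for i in range(6):  # delete the (i+1)-th A
        j = run_start - 1 + i  # 0-based index of the deleted A
        mutant = ref[:j] + ref[j + 1 :]
        (v,) = call_variants({"c": ref}, {"c": mutant})
        calls.add((v.pos, v.ref, v.alt))
    assert calls == {(run_start - 1, "CA", "C")}


@given(st.data())
def test_normalization_is_canonical_over_equivalent_placements(data):
    """For a random single-base indel, normalizing any equivalent
    (position-shifted) representation yields the same triple."""
    rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
    seq = "".join(rng.choice(list("ACGT"), size=60))
    pos = int(data.draw(st.integers(2, 58)))
    base = data.draw(st.sampled_from("ACGT"))
    is_del = data.draw(st.booleans())
    if is_del:
        anchor = seq[pos - 2]
        target = seq[pos - 1]
        rep = normalize_variant(seq, pos - 1, anchor + target, anchor)
    else:
        anchor = seq[pos - 2]
        rep = normalize_variant(seq, pos - 1, anchor, anchor + base)
    # re-normalizing the normalized form is a fixed point
    assert normalize_variant(seq, *rep) == rep
    # the canonical form reproduces the same mutant string
    v = Variant("c", *rep)
    j = pos - 1
    mutant = seq[:j] + seq[j + 1 :] if is_del else seq[:j] + base + seq[j:]
    assert apply_variants(seq, [v]) == mutant


# ---------------------------------------------------------------------------
# homopolymer notation


def test_deletion_notation_a6c_to_a5c():
    chroms = {"c": "GGC" + "A" * 6 + "CGGTT"}
    h = annotate_homopolymer(Variant("c", 3, "CA", "C"), chroms)
    assert h.notation == "A6C > A5C"
    assert (h.unit, h.run_ref, h.run_alt, h.flank, h.side) == ("A", 6, 5, "C", "3p")


def test_insertion_notation_ca6_to_ca7():
    chroms = {"c": "GGC" + "A" * 6 + "CGGTT"}
    h = annotate_homopolymer(Variant("c", 3, "C", "CA"), chroms)
    assert h.notation == "CA6 > CA7"
    assert (h.unit, h.run_ref, h.run_alt, h.flank, h.side) == ("A", 6, 7, "C", "5p")


def test_snv_and_short_runs_return_none():
    chroms = {"c": "GGCAACGGTT"}
    assert annotate_homopolymer(Variant("c", 4, "A", "T"), chroms) is None
    assert annotate_homopolymer(Variant("c", 3, "CA", "C"), chroms) is None  # run of 2


def test_notation_roundtrip():
    for s, fields in [
        ("A6C > A5C", ("A", 6, 5, "C", "3p")),
        ("CA6 > CA7", ("A", 6, 7, "C", "5p")),
        ("T12G > T11G", ("T", 12, 11, "G", "3p")),
    ]:
        h = parse_hpr_notation(s)
        assert (h.unit, h.run_ref, h.run_alt, h.flank, h.side) == fields
        assert h.notation == s
    with pytest.raises(ValueError):
        parse_hpr_notation("A6C > T5C")


def test_notation_fuzz_against_run_scanner():
    """On every run of a random 200-bp sequence, single-base indels get the
    run lengths a brute-force scanner reports."""
    rng = np.random.default_rng(1234)
    seq = "".join(rng.choice(list("ACGT"), p=[0.4, 0.1, 0.1, 0.4], size=200))
    chroms = {"c": seq}

    def scan_run(i0):  # brute-force maximal run through 0-based index i0
        b = seq[i0]
        lo = i0
        while lo > 0 and seq[lo - 1] == b:
            lo -= 1
        hi = i0
        while hi + 1 < len(seq) and seq[hi + 1] == b:
            hi += 1
        return lo, hi, b

    checked = 0
    for i0 in range(1, len(seq) - 1):
        lo, hi, b = scan_run(i0)
        run_len = hi - lo + 1
        if run_len < 3 or lo == 0 or hi == len(seq) - 1:
            continue
        anchor = seq[lo - 1]
        h_del = annotate_homopolymer(Variant("c", lo, anchor + b, anchor), chroms)
        h_ins = annotate_homopolymer(Variant("c", lo, anchor, anchor + b), chroms)
        assert (h_del.run_ref, h_del.run_alt, h_del.flank) == (run_len, run_len - 1, seq[hi + 1])
        assert (h_ins.run_ref, h_ins.run_alt, h_ins.flank) == (run_len, run_len + 1, anchor)
        checked += 1
    assert checked >= 5


def _intronless_gene_genome(coding: str, strand: str, pad: str = "TTGGCC"):
    block = coding if strand == "+" else revcomp(coding)
    chrom = pad + block + pad
    gene = GeneModel(
        "G1", "chr1", len(pad) + 1, len(pad) + len(block), strand,
        ((len(pad) + 1, len(pad) + len(block)),),
    )
    return AnnotatedGenome(chroms={"chr1": chrom}, genes=[gene], gene_sets={})


def test_minus_strand_notation_uses_coding_strand():
    """A run reported for a minus-strand gene uses the reverse complement:
    a plus-strand T-run with 5' G reads as an A-run followed by C."""
    coding = "ATG" + "GCT" * 5 + "AAAAAA" + "C" + "GCGCT" + "TAA"  # A6 then C on coding strand
    genome = _intronless_gene_genome(coding, "-")
    # locate the T-run on the reference (plus) strand
    chrom = genome.chroms["chr1"]
    i = chrom.index("TTTTTT")
    anchor = chrom[i - 1]
    v = Variant("chr1", i, anchor + "T", anchor)  # delete one T, left-aligned
    h = annotate_homopolymer(v, genome)
    assert h.unit == "A" and h.flank == "C" and h.side == "3p"
    assert h.notation == "A6C > A5C"


# ---------------------------------------------------------------------------
# coding effects


def test_missense_g65r():
    """GGA -> AGA at codon 65: glycine to arginine, reported G65R."""
    coding = "ATG" + "GCT" * 63 + "GGA" + "GCT" * 5 + "TAA"
    for strand in ("+", "-"):
        genome = _intronless_gene_genome(coding, strand)
        gene = genome.genes[0]
        gpos = gene.genomic_position(3 * 64)  # first base of codon 65
        ref = genome.chroms["chr1"][gpos - 1]
        alt = "A" if strand == "+" else revcomp("A")
        ann = annotate_effect(Variant("chr1", gpos, ref, alt), genome)
        assert ann.effect is Effect.MISSENSE
        assert ann.protein_change == "G65R"
        assert ann.codon_change == "GGA>AGA"
        assert ann.reported_strand_note is (strand == "-")


def test_nonsense_tat_taa():
    coding = "ATG" + "GCT" * 9 + "TAT" + "GCT" * 5 + "TAA"
    genome = _intronless_gene_genome(coding, "+")
    gene = genome.genes[0]
    gpos = gene.genomic_position(3 * 10 + 2)  # third base of codon 11 (TAT)
    ann = annotate_effect(Variant("chr1", gpos, "T", "A"), genome)
    assert ann.effect is Effect.NONSENSE
    assert ann.protein_change == "Y11*"
    assert ann.codon_change == "TAT>TAA"


def test_synonymous_substitution():
    coding = "ATG" + "GCT" * 10 + "TAA"
    genome = _intronless_gene_genome(coding, "+")
    gene = genome.genes[0]
    gpos = gene.genomic_position(3 * 1 + 2)  # GCT -> GCC, both Ala
    ann = annotate_effect(Variant("chr1", gpos, "T", "C"), genome)
    assert ann.effect is Effect.SYNONYMOUS
    assert ann.protein_change == "A2A"


def test_splice_donor_and_intronic(toy_genome):
    gene = next(g for g in toy_genome.genes if g.introns)
    d1, _ = gene.donor_sites()[0]
    seq = toy_genome.chroms[gene.chrom]
    ref = seq[d1 - 1]
    alt = "A" if ref != "A" else "C"
    ann = annotate_effect(Variant(gene.chrom, d1, ref, alt), toy_genome)
    assert ann.effect is Effect.SPLICE_DONOR and ann.gene_id == gene.gene_id
    assert ann.protein_change is None

    s, e = gene.introns[0]
    mid = (s + e) // 2
    ref = seq[mid - 1]
    ann2 = annotate_effect(Variant(gene.chrom, mid, ref, "A" if ref != "A" else "C"), toy_genome)
    assert ann2.effect is Effect.INTRONIC


def test_single_base_deletion_in_cds_is_frameshift(toy_genome):
    gene = next(g for g in toy_genome.genes if not g.introns)
    s, e = gene.exons[0]
    pos = s + 10
    seq = toy_genome.chroms[gene.chrom]
    ann = annotate_effect(Variant(gene.chrom, pos, seq[pos - 1 : pos + 1], seq[pos - 1]), toy_genome)
    assert ann.effect is Effect.FRAMESHIFT
    assert ann.protein_change is None


def test_inframe_indel_and_intergenic(toy_genome):
    gene = next(g for g in toy_genome.genes if not g.introns)
    s, _ = gene.exons[0]
    seq = toy_genome.chroms[gene.chrom]
    pos = s + 10
    ann = annotate_effect(
        Variant(gene.chrom, pos, seq[pos - 1 : pos + 3], seq[pos - 1]), toy_genome
    )
    assert ann.effect is Effect.INFRAME_INDEL

    last_gene_end = max(g.end for g in toy_genome.genes if g.chrom == gene.chrom)
    pos2 = last_gene_end + 50
    ann2 = annotate_effect(
        Variant(gene.chrom, pos2, seq[pos2 - 1], "A" if seq[pos2 - 1] != "A" else "C"),
        toy_genome,
    )
    assert ann2.effect is Effect.INTERGENIC and ann2.gene_id is None


def test_unknown_chromosome_errors(toy_genome):
    with pytest.raises(ValueError, match="unknown chromosome"):
        annotate_effect(Variant("chr99", 10, "A", "C"), toy_genome)


def test_protein_change_present_iff_coding_substitution(toy_genome):
    """Invariant: protein_change accompanies missense/nonsense/synonymous
    calls and nothing else, across a cohort of annotated isolates."""
    iso, truth = mutate_isolate(
        toy_genome, MutationSpectrum(rate_snv=2e-4), plant=("GENE004", "nonsense"), seed=21
    )
    coding = {Effect.MISSENSE, Effect.NONSENSE, Effect.SYNONYMOUS}
    for v in call_variants(toy_genome.chroms, iso):
        ann = annotate_effect(v, toy_genome)
        assert (ann.protein_change is not None) == (ann.effect in coding)


def test_vcf_roundtrip(tmp_path, toy_genome):
    _, truth = mutate_isolate(toy_genome, MutationSpectrum(rate_snv=1e-4), seed=13)
    path = tmp_path / "truth.vcf"
    write_vcf(truth, toy_genome.chroms, path)
    assert read_vcf(path) == sorted(truth, key=lambda v: (v.chrom, v.pos))
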