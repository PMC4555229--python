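"""Annotated-genome domain types and FASTA/GFF3/gene-set I/O.

The coordinate system is 1-based inclusive throughout (genomic positions as
printed in mutation tables); sequences are uppercase ACGT strings. Genes are
haploid, non-overlapping, single-transcript models whose exons are CDS
(an ATG...stop open reading frame on the coding strand), optionally split by
introns whose 5' end carries the GT splice-donor consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneModel",
    "AnnotatedGenome",
    "revcomp",
    "find_homopolymers",
    "apply_variants",
    "write_fasta",
    "read_fasta",
    "write_gff3",
    "read_gff3",
    "write_gene_sets",
    "read_gene_sets",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """One gene: 1-based inclusive coordinates, exons in genomic order.

    Introns are implied between consecutive exons; each intron starts (on
    the coding strand) with the GT splice-donor dinucleotide.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str  # "+" or "-"
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for s, e in self.exons:
            if not (self.start <= s <= e <= self.end):
                raise ValueError(f"exon ({s},{e}) outside gene bounds of {self.gene_id}")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        )

    def donor_sites(self) -> tuple[tuple[int, int], ...]:
        """Genomic positions (5'->3' on the coding strand) of each intron's
        GT splice-donor dinucleotide."""
        sites = []
        for s, e in self.introns:
            if self.strand == "+":
                sites.append((s, s + 1))
            else:
                sites.append((e, e - 1))
        return tuple(sites)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def coding_sequence(self, chroms: dict[str, str]) -> str:
        seq = chroms[self.chrom]
        parts = [seq[s - 1 : e] for s, e in self.exons]
        cds = "".join(parts)
        return revcomp(cds) if self.strand == "-" else cds

    def cds_index(self, pos: int) -> int | None:
        """0-based index of genomic position ``pos`` in the coding sequence,
        or None when the position is not exonic."""
        offset = 0
        if self.strand == "+":
            for s, e in self.exons:
                if s <= pos <= e:
                    return offset + (pos - s)
                offset += e - s + 1
        else:
            for s, e in reversed(self.exons):
                if s <= pos <= e:
                    return offset + (e - pos)
                offset += e - s + 1
        return None

    def genomic_position(self, cds_index: int) -> int:
        """Inverse of :meth:`cds_index`."""
        offset = cds_index
        if self.strand == "+":
            for s, e in self.exons:
                if offset < e - s + 1:
                    return s + offset
                offset -= e - s + 1
        else:
            for s, e in reversed(self.exons):
                if offset < e - s + 1:
                    return e - offset
                offset -= e - s + 1
        raise IndexError(f"cds_index {cds_index} beyond CDS of {self.gene_id}")


@dataclass
class AnnotatedGenome:
    """Chromosome sequences + gene models + gene-set membership."""

    chroms: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)
    gene_sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.chroms.items():
            if set(seq) - set("ACGT"):
                raise ValueError(f"chromosome {name} contains non-ACGT characters")
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            if g.chrom not in self.chroms:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if g.end > len(self.chroms[g.chrom]) or g.start < 1:
                raise ValueError(f"gene {g.gene_id} outside chromosome bounds")
            by_chrom.setdefault(g.chrom, []).append(g)
        for glist in by_chrom.values():
            glist = sorted(glist, key=lambda g: g.start)
            for a, b in zip(glist, glist[1:]):
                if b.start <= a.end:
                    raise ValueError(f"overlapping genes {a.gene_id} and {b.gene_id}")

    def gene_by_id(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def gene_at(self, chrom: str, pos: int) -> GeneModel | None:
        for g in self.genes:
            if g.chrom == chrom and g.contains(pos):
                return g
        return None

    @property
    def universe(self) -> list[str]:
        return sorted(g.gene_id for g in self.genes)


def find_homopolymers(seq: str, min_len: int = 3) -> list[tuple[int, int, str]]:
    """Maximal single-base runs of length >= ``min_len``.

    Returns 1-based inclusive (start, end, base) tuples.
    """
    runs = []
    i, n = 0, len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i + 1, j, seq[i]))
        i = j
    return runs


def apply_variants(seq: str, variants) -> str:
    """Apply non-overlapping VCF-style variants (sorted internally) to a
    chromosome sequence and return the mutant sequence.

    Each variant must carry 1-based ``pos`` plus ``ref``/``alt`` allele
    strings whose ref matches the sequence.
    """
    out = seq
    for v in sorted(variants, key=lambda v: v.pos, reverse=True):
        i = v.pos - 1
        if out[i : i + len(v.ref)] != v.ref:
            raise ValueError(
                f"ref mismatch at pos {v.pos}: expected {v.ref!r}, "
                f"found {out[i : i + len(v.ref)]!r}"
            )
        out = out[:i] + v.alt + out[i + len(v.ref) :]
    return out


# ---------------------------------------------------------------------------
# file formats

def write_fasta(chroms: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in chroms.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
        lines.append(
            f"{g.chrom}\tmutscreen\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id}"
        )
        lines.append(
            f"{g.chrom}\tmutscreen\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id}.t1;Parent={g.gene_id}"
        )
        exons = g.exons if g.strand == "+" else tuple(reversed(g.exons))
        phase, k = 0, 1
        for s, e in exons:
            lines.append(
                f"{g.chrom}\tmutscreen\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.e{k};Parent={g.gene_id}.t1"
            )
            lines.append(
                f"{g.chrom}\tmutscreen\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\t"
                f"ID={g.gene_id}.c{k};Parent={g.gene_id}.t1"
            )
            phase = (3 - ((e - s + 1 - phase) % 3)) % 3
            k += 1
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    import gffutils

    body = [
        ln for ln in Path(path).read_text().splitlines() if ln and not ln.startswith("#")
    ]
    if not body:
        return []
    db = gffutils.create_db(str(path), ":memory:", keep_order=True, merge_strategy="error")
    genes = []
    for feat in db.features_of_type("gene"):
        exons = tuple(
            sorted(
                (e.start, e.end)
                for e in db.children(feat, featuretype="exon")
            )
        )
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                exons=exons or ((feat.start, feat.end),),
            )
        )
    return genes


def write_gene_sets(gene_sets: dict[str, list[str]], path: str | Path) -> None:
    lines = ["set_name\tgene_id"]
    for name in sorted(gene_sets):
        for gid in gene_sets[name]:
            lines.append(f"{name}\t{gid}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines()[1:]:
        if not line.strip():
            continue
        name, gid = line.split("\t")
        sets.setdefault(name, []).append(gid)
    return sets
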