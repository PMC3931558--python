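"""Gene models and point-mutation effect classification.

The classifier re-implements the minimal subset of an annotator needed for a
suppressor-candidate scan: coding substitutions are translated on the coding
strand with the standard genetic code (stop gain -> ``nonsense``, amino-acid
change -> ``missense``, silent -> ``synonymous``), positions in the first or
last two bases of an intron are ``splice_site`` (the standard donor/acceptor
definition), and everything else is ``noncoding``.  Each gene carries a single
transcript whose exons are entirely coding; there is no isoform arbitration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

EFFECT_CLASSES = ("missense", "nonsense", "splice_site", "synonymous", "noncoding")


@dataclass(frozen=True)
class Exon:
    start: int  # 1-based, inclusive
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"exon start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[Exon] = field(default_factory=list)  # genomic order, non-overlapping

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(f"exons of {self.gene_id} overlap or are unordered")
        if self.cds_length % 3 != 0:
            raise ValueError(f"CDS length of {self.gene_id} not divisible by 3")

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def cds_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def cds_index(self, pos: int) -> int | None:
        """0-based index of ``pos`` within the coding sequence, or None if intronic."""
        offset = 0
        forward = None
        for exon in self.exons:
            if exon.start <= pos <= exon.end:
                forward = offset + (pos - exon.start)
                break
            offset += len(exon)
        if forward is None:
            return None
        if self.strand == "+":
            return forward
        return self.cds_length - 1 - forward

    def is_splice_site(self, pos: int) -> bool:
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end < pos <= a.end + 2 or b.start - 2 <= pos < b.start:
                return True
        return False

    def cds_sequence(self, genome) -> str:
        spliced = "".join(genome.fetch(self.chrom, e.start, e.end) for e in self.exons)
        if self.strand == "-":
            spliced = str(Seq(spliced).reverse_complement())
        return spliced


def classify_effect(chrom: str, pos: int, ref: str, alt: str,
                    gene_models: list[GeneModel], genome) -> str:
    """Effect class of the substitution ``ref``->``alt`` at ``chrom:pos``.

    Raises ``ValueError`` when ``ref`` disagrees with the genome base.
    """
    genome_base = genome.get_base(chrom, pos)
    if genome_base != ref:
        raise ValueError(
            f"ref allele {ref!r} at {chrom}:{pos} disagrees with genome base {genome_base!r}")
    if alt == ref:
        raise ValueError(f"alt equals ref at {chrom}:{pos}")
    for gene in gene_models:
        if gene.chrom != chrom or not gene.contains(pos):
            continue
        idx = gene.cds_index(pos)
        if idx is None:
            return "splice_site" if gene.is_splice_site(pos) else "noncoding"
        cds = gene.cds_sequence(genome)
        codon_i, within = divmod(idx, 3)
        codon = cds[3 * codon_i : 3 * codon_i + 3]
        alt_coding = alt if gene.strand == "+" else str(Seq(alt).complement())
        mutant = codon[:within] + alt_coding + codon[within + 1 :]
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq(mutant).translate())
        if aa_alt == aa_ref:
            return "synonymous"
        if aa_alt == "*":
            return "nonsense"
        return "missense"
    return "noncoding"
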