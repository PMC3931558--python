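"""File I/O for the pipeline's standard formats.

Conventions: VCF and GFF3 are 1-based inclusive, BED is 0-based half-open;
all internal computation is 1-based and conversion happens only here.  Every
writer/reader pair here round-trips its own output.
"""

from __future__ import annotations

import json

import gffutils
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .effects import Exon, GeneModel
from .pool_seq import SiteCounts


class VcfFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def write_gff3(path, genes: list[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\tsupmap\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t."
                     f"\tID={g.gene_id}\n")
            for i, e in enumerate(g.exons):
                fh.write(f"{g.chrom}\tsupmap\texon\t{e.start}\t{e.end}\t.\t{g.strand}"
                         f"\t.\tID={g.gene_id}.e{i};Parent={g.gene_id}\n")


def read_gff3(path) -> list[GeneModel]:
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for grec in db.features_of_type("gene"):
        exons = sorted(
            (Exon(e.start, e.end) for e in db.children(grec, featuretype="exon")),
            key=lambda e: e.start)
        genes.append(GeneModel(grec.id, grec.seqid, grec.strand, exons))
    return genes


# ---------------------------------------------------------------------------
# TSV / BED tables
# ---------------------------------------------------------------------------

def write_markers_tsv(path, markers: pd.DataFrame) -> None:
    markers.to_csv(path, sep="\t", index=False)


def read_markers_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_bed(path, intervals: list[tuple[str, int, int]], names=None) -> None:
    """1-based inclusive (start, end) tuples are written as 0-based half-open."""
    with open(path, "w") as fh:
        for i, (chrom, start, end) in enumerate(intervals):
            name = names[i] if names else f"region_{i}"
            fh.write(f"{chrom}\t{max(start - 1, 0)}\t{end}\t{name}\n")


def read_bed(path) -> list[tuple[str, int, int]]:
    """Returns (chrom, start0, end0) half-open as stored in the file."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (set, frozenset)):
        return sorted(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_pool_vcf(path, sites: list[SiteCounts], sample_name: str,
                   contigs: dict[str, int]) -> None:
    """One record per site with AD (ref,alt) and DP per sample, plus an INFO
    flag HAWAIIAN_MARKER distinguishing strain-diagnostic markers from novel
    variants.  Input must be sorted by (chrom, pos) in contig order with no
    duplicate (chrom, pos, alt)."""
    order = {c: i for i, c in enumerate(contigs)}
    keys = [(order[s.chrom], s.pos) for s in sites]
    if any(b < a for a, b in zip(keys, keys[1:])):
        raise VcfFormatError("sites must be sorted by (chromosome, position)")
    triples = [(s.chrom, s.pos, s.alt) for s in sites]
    if len(set(triples)) != len(triples):
        raise VcfFormatError("duplicate (chrom, pos, alt) site")
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("HAWAIIAN_MARKER", 0, "Flag",
                    "Known strain-diagnostic marker site")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    header.add_sample(sample_name)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for s in sites:
            rec = vf.new_record(contig=s.chrom, start=s.pos - 1, stop=s.pos,
                                alleles=(s.ref, s.alt))
            if s.is_marker:
                rec.info["HAWAIIAN_MARKER"] = True
            rec.samples[sample_name]["AD"] = (s.ref_count, s.alt_count)
            rec.samples[sample_name]["DP"] = s.depth
            vf.write(rec)


def read_pool_vcf(path) -> pd.DataFrame:
    """Pool VCF -> DataFrame (chrom, pos, ref, alt, ref_count, alt_count,
    depth, freq, is_marker).  ``freq`` is NaN at depth 0."""
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        if "AD" not in vf.header.formats:
            raise VcfFormatError(
                f"{path}: FORMAT field 'AD' (allelic depths) is required but missing")
        sample = list(vf.header.samples)[0]
        for rec in vf:
            ad = rec.samples[sample].get("AD")
            if ad is None or ad[0] is None:
                ref_c, alt_c = 0, 0
            else:
                ref_c, alt_c = int(ad[0]), int(ad[1])
            depth = ref_c + alt_c
            rows.append((rec.contig, rec.pos, rec.ref, rec.alts[0], ref_c, alt_c,
                         depth, alt_c / depth if depth else np.nan,
                         bool(rec.info.get("HAWAIIAN_MARKER", False))))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "ref_count",
                                       "alt_count", "depth", "freq", "is_marker"])


def vcf_contigs(path) -> dict[str, int]:
    with pysam.VariantFile(str(path)) as vf:
        return {name: c.length for name, c in vf.header.contigs.items()}
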