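"""Readers and writers for the standard formats at the package boundary.

GFF3 (1-based inclusive) and VCF (1-based) are converted to the internal
0-based half-open convention here and nowhere else.  GFF3 parsing goes through
gffutils; FASTA through Bio.SeqIO; VCF reading through pysam.
"""
from __future__ import annotations

import os
from pathlib import Path

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel, Variant

# ---------------------------------------------------------------------------
# GFF3

_FEATURE_MAP = {
    "exon": "exons",
    "CDS": "cds",
    "five_prime_UTR": "utr5",
    "three_prime_UTR": "utr3",
}


def write_gff3(genes: list[GeneModel], path: str | os.PathLike) -> None:
    """Write gene/mRNA/exon/CDS/UTR features, 1-based inclusive coordinates."""
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
        src = "pangenefam"

        def row(ftype: str, s: int, e: int, attrs: str) -> str:
            return "\t".join(
                [g.chrom, src, ftype, str(s + 1), str(e), ".", g.strand, ".", attrs]
            )

        mrna_id = f"{g.gene_id}.mrna1"
        lines.append(row("gene", g.start, g.end, f"ID={g.gene_id}"))
        lines.append(row("mRNA", g.start, g.end, f"ID={mrna_id};Parent={g.gene_id}"))
        for ftype, attr in _FEATURE_MAP.items():
            for i, (s, e) in enumerate(getattr(g, attr), 1):
                lines.append(
                    row(ftype, s, e, f"ID={mrna_id}.{ftype}.{i};Parent={mrna_id}")
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | os.PathLike, genome_id: str) -> list[GeneModel]:
    """Parse one genome's annotation into ranked GeneModels.

    Rank is (re)assigned from genomic order per chromosome, so a round-trip
    through GFF3 preserves it for gap-free single-chromosome layouts.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        kwargs: dict[str, list] = {v: [] for v in _FEATURE_MAP.values()}
        for child in db.children(feat.id):
            attr = _FEATURE_MAP.get(child.featuretype)
            if attr is not None:
                kwargs[attr].append((child.start - 1, child.end))
        genes.append(
            GeneModel(
                gene_id=feat.id,
                genome_id=genome_id,
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                rank=-1,
                **kwargs,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    rank_counter: dict[str, int] = {}
    for g in genes:
        g.rank = rank_counter.get(g.chrom, 0)
        rank_counter[g.chrom] = g.rank + 1
    return genes


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(seqs: dict[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(s.upper()), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# VCF

_VCF_HEADER = """##fileformat=VCFv4.2
##source=pangenefam
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(
    variants: list[Variant],
    genotypes: dict[str, list[int]],
    accessions: list[str],
    path: str | os.PathLike,
    contigs: list[str] | None = None,
) -> None:
    """Write a minimal VCF v4.2 with one pseudo-accession per sample column.

    ``genotypes[variant_id]`` holds 0/1 presence per accession (same order as
    ``accessions``).
    """
    out = [_VCF_HEADER.rstrip("\n")]
    for c in contigs or sorted({v.chrom for v in variants}):
        out.append(f"##contig=<ID={c}>")
    out.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(accessions)
    )
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt)):
        gts = genotypes.get(v.variant_id, [0] * len(accessions))
        cols = [v.chrom, str(v.pos), v.variant_id, v.ref, v.alt, ".", "PASS", ".", "GT"]
        cols += ["0/1" if g else "0/0" for g in gts]
        out.append("\t".join(cols))
    Path(path).write_text("\n".join(out) + "\n")


def read_vcf(path: str | os.PathLike) -> tuple[list[Variant], dict[str, list[int]], list[str]]:
    """Read variants plus per-accession presence (any non-ref allele)."""
    variants: list[Variant] = []
    genotypes: dict[str, list[int]] = {}
    with pysam.VariantFile(str(path)) as vf:
        accessions = list(vf.header.samples)
        for i, rec in enumerate(vf):
            vid = rec.id if rec.id not in (None, ".") else f"var{i}"
            for alt in rec.alts or ():
                v = Variant(rec.chrom, rec.pos, rec.ref, alt, variant_id=vid)
                variants.append(v)
                genotypes[vid] = [
                    int(any(a not in (0, None) for a in rec.samples[s]["GT"]))
                    for s in accessions
                ]
    return variants, genotypes, accessions


# ---------------------------------------------------------------------------
# TSV helpers


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
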