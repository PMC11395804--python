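"""Strand-aware variant consequence classification over gene models.

Implements the Sequence Ontology / Ensembl-VEP conventions for the splice and
gene-region classes: splice donor = first 2 intronic bases at an intron's 5'
end, splice acceptor = last 2 at its 3' end (transcription orientation),
splice region = 1-3 exonic or 3-8 intronic bases from an exon/intron junction
excluding donor/acceptor bases, plus intron / coding_sequence / 5' and 3' UTR
/ upstream / downstream (5 kb window) classes.  When several apply, the
primary call is the most severe under a fixed precedence; all are retained.

Only SNVs are fully supported; indels are classified by their start position.
One canonical transcript per gene is assumed.
"""
from __future__ import annotations

from collections import defaultdict

import pandas as pd

from .models import GeneModel, Variant

# precedence: smaller rank = more severe
SEVERITY: dict[str, int] = {
    "splice_acceptor": 0,
    "splice_donor": 0,
    "splice_region": 1,
    "coding_sequence": 2,
    "utr5": 3,
    "utr3": 3,
    "intron": 4,
    "upstream": 5,
    "downstream": 5,
}

CONSEQUENCE_CLASSES = tuple(SEVERITY)

DEFAULT_WINDOW = 5000

SPLICE_REGION_EXONIC = 3  # 1..3 exonic bases from a junction
SPLICE_REGION_INTRONIC = (3, 8)  # 3..8 intronic bases from a junction
SPLICE_SITE_BASES = 2  # donor/acceptor extent


def _in_any(pos: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s <= pos < e for s, e in intervals)


def classify_position(pos0: int, gene: GeneModel, window: int = DEFAULT_WINDOW) -> list[str]:
    """All consequence classes that apply to a 0-based position, unsorted.

    Returns an empty list when the position is outside the gene body and the
    up/downstream windows.
    """
    classes: list[str] = []
    fwd = gene.strand == "+"

    if pos0 < gene.start or pos0 >= gene.end:
        # flanks: upstream is 5' of the transcript, downstream 3'
        if gene.start - window <= pos0 < gene.start:
            classes.append("upstream" if fwd else "downstream")
        elif gene.end <= pos0 < gene.end + window:
            classes.append("downstream" if fwd else "upstream")
        return classes

    in_exon = _in_any(pos0, gene.exons)
    if in_exon:
        if _in_any(pos0, gene.cds):
            classes.append("coding_sequence")
        if _in_any(pos0, gene.utr5):
            classes.append("utr5")
        if _in_any(pos0, gene.utr3):
            classes.append("utr3")
        # exonic splice-region bases: within 3 bases of an intron junction
        for istart, iend in gene.introns:
            if istart - SPLICE_REGION_EXONIC <= pos0 < istart:
                classes.append("splice_region")
                break
            if iend <= pos0 < iend + SPLICE_REGION_EXONIC:
                classes.append("splice_region")
                break
        return classes

    # intronic position
    for istart, iend in gene.introns:
        if not istart <= pos0 < iend:
            continue
        # offsets from the genomic left/right ends of the intron (1-based)
        off_left = pos0 - istart + 1
        off_right = iend - pos0
        off5, off3 = (off_left, off_right) if fwd else (off_right, off_left)
        if off5 <= SPLICE_SITE_BASES:
            classes.append("splice_donor")
        if off3 <= SPLICE_SITE_BASES:
            classes.append("splice_acceptor")
        lo, hi = SPLICE_REGION_INTRONIC
        if (lo <= off5 <= hi) or (lo <= off3 <= hi):
            classes.append("splice_region")
        classes.append("intron")
        break
    return classes


def annotate(
    variant: Variant, gene: GeneModel, window: int = DEFAULT_WINDOW
) -> dict | None:
    """Classify one variant against one gene.

    Returns ``{"variant_id", "gene_id", "consequence", "severity_rank",
    "all_classes"}`` with the primary call chosen by the fixed precedence, or
    None when the variant is outside the gene and its windows or on another
    chromosome.
    """
    if variant.chrom != gene.chrom:
        return None
    classes = classify_position(variant.pos0, gene, window)
    if not classes:
        return None
    primary = min(classes, key=lambda c: (SEVERITY[c], c))
    return {
        "variant_id": variant.variant_id,
        "gene_id": gene.gene_id,
        "consequence": primary,
        "severity_rank": SEVERITY[primary],
        "all_classes": sorted(set(classes), key=lambda c: (SEVERITY[c], c)),
    }


def annotate_all(
    variants: list[Variant],
    genes: list[GeneModel],
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Primary consequence call per (variant, overlapping gene)."""
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_chrom[g.chrom].append(g)
    rows = []
    for v in variants:
        for g in by_chrom.get(v.chrom, []):
            call = annotate(v, g, window)
            if call is not None:
                call = dict(call)
                call["all_classes"] = ",".join(call["all_classes"])
                rows.append(call)
    return pd.DataFrame(
        rows, columns=["variant_id", "gene_id", "consequence", "severity_rank", "all_classes"]
    )


def summarize_load(
    calls: pd.DataFrame,
    genotypes: dict[str, list[int]],
    accessions: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene, per-accession variant burden split by consequence class.

    Returns (load, profile): ``load`` is a long-form table (gene_id,
    accession, consequence, count) restricted to accessions carrying the
    variant; ``profile`` aggregates per-gene class counts and ranks genes by
    total burden (waterfall order).
    """
    rows = []
    for rec in calls.itertuples(index=False):
        carriers = genotypes.get(rec.variant_id)
        if carriers is None:
            continue
        for acc, carried in zip(accessions, carriers):
            if carried:
                rows.append((rec.gene_id, acc, rec.consequence))
    load = (
        pd.DataFrame(rows, columns=["gene_id", "accession", "consequence"])
        .groupby(["gene_id", "accession", "consequence"])
        .size()
        .reset_index(name="count")
        if rows
        else pd.DataFrame(columns=["gene_id", "accession", "consequence", "count"])
    )
    profile = (
        calls.groupby(["gene_id", "consequence"]).size().unstack(fill_value=0)
        if len(calls)
        else pd.DataFrame()
    )
    if len(profile):
        profile["total"] = profile.sum(axis=1)
        profile = profile.sort_values("total", ascending=False)
    return load, profile
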