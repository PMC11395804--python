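"""Core data model shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the package; GFF3 and VCF
I/O convert to/from their 1-based conventions at the boundary (`pangenefam.io`).
An interval is a plain ``(start, end)`` tuple with ``start < end``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

Interval = tuple[int, int]


class PangeneClass(str, Enum):
    """Occupancy class of a syntelog group across the analyzed genomes."""

    CORE = "core"
    SOFTCORE = "softcore"
    DISPENSABLE = "dispensable"
    PRIVATE = "private"


def _total_len(intervals: list[Interval]) -> int:
    return sum(e - s for s, e in intervals)


@dataclass
class GeneModel:
    """Strand-aware gene with exon/CDS/UTR intervals on one chromosome.

    ``rank`` is the ordinal position of the gene along its chromosome (0-based,
    unique within a genome/chromosome); it is the coordinate system of the
    collinearity chaining.  Interval lists are sorted by genomic start and
    non-overlapping; CDS intervals are contained in exons.
    """

    gene_id: str
    genome_id: str
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'
    rank: int
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        for name in ("exons", "cds", "utr5", "utr3"):
            ivs = getattr(self, name)
            setattr(self, name, sorted(tuple(iv) for iv in ivs))

    @property
    def cds_length(self) -> int:
        return _total_len(self.cds)

    @property
    def gene_length(self) -> int:
        return self.end - self.start

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> list[Interval]:
        """Gaps between consecutive exons, in genomic order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out

    def iter_positions(self, intervals: list[Interval]) -> Iterator[int]:
        for s, e in intervals:
            yield from range(s, e)


@dataclass(frozen=True)
class AnchorPair:
    """Similarity-supported gene pair between two distinct genomes."""

    gene_a: str
    gene_b: str
    score: float

    def __post_init__(self) -> None:
        if self.score <= 0:
            raise ValueError("anchor score must be > 0")


@dataclass
class CollinearBlock:
    """A maximal chain of rank-monotone anchors for one genome pair."""

    genome_a: str
    genome_b: str
    anchors: list[AnchorPair]
    orientation: str  # 'same' or 'inverted'
    chain_score: float

    def __len__(self) -> int:
        return len(self.anchors)


@dataclass
class SyntelogGroup:
    """Cross-genome cluster of positionally homologous genes.

    ``members`` maps genome id to the (possibly tandem-duplicated) gene ids it
    contributes; occupancy counts genomes, not gene copies.
    """

    sg_id: str
    members: dict[str, list[str]]
    pangene_class: PangeneClass | None = None

    @property
    def occupancy(self) -> int:
        return sum(1 for genes in self.members.values() if genes)

    @property
    def gene_ids(self) -> list[str]:
        return [g for genes in self.members.values() for g in genes]


@dataclass(frozen=True)
class DomainHit:
    """One conserved-domain hit on a gene product (protein coordinates)."""

    gene_id: str
    domain_id: str  # 'NTD' or 'CTD'
    evalue: float
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError("evalue must be > 0")
        if self.start > self.end:
            raise ValueError("domain hit start > end")


@dataclass
class FamilyCall:
    """Per-gene family membership with its evidence basis."""

    gene_id: str
    is_member: bool
    basis: str | None = None  # 'domain' | 'propagated'
    typicality: str | None = None  # 'typical' | 'atypical'
    subfamily: str = "unassigned"


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide (or start-anchored) variant on one chromosome."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    variant_id: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def pos0(self) -> int:
        return self.pos - 1


@dataclass
class KaKsResult:
    """Nei–Gojobori site counts, proportions, distances and omega for a pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float | None
    dN: float | None
    omega: float | None
    saturated: bool = False

    @property
    def below_reporting_cutoff(self) -> bool | None:
        """Flag for the omega < 4 reporting filter (None when undefined)."""
        if self.omega is None:
            return None
        return self.omega < 4.0


@dataclass
class CoexpressionModule:
    """Gene set from the mutual-rank network with its cohesiveness score."""

    genes: frozenset[str]
    cohesiveness: float
    p_value: float

    @property
    def passes(self) -> bool:
        return self.p_value < 0.1

    def __len__(self) -> int:
        return len(self.genes)
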