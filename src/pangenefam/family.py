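"""Conserved-domain gene-family identification with syntelog propagation.

A gene is a seed family member when it carries both the N-terminal (NTD) and
C-terminal (CTD) family domains at the e-value threshold (default 1e-5,
inclusive); membership then propagates to every syntelog-group co-member.
Members retaining both domains are typical; members lacking one or both
(usually via truncation) are atypical.  Subfamily labels come from the nearest
labeled reference sequence by global identity, a stand-in for tree-based
subfamily assignment.
"""
from __future__ import annotations

from collections import defaultdict

import pandas as pd
from Bio import Align
from scipy.stats import mannwhitneyu

from .models import DomainHit, FamilyCall, GeneModel, SyntelogGroup

DOMAIN_IDS = frozenset({"NTD", "CTD"})
DEFAULT_E_THRESHOLD = 1e-5


def _passing_domains(
    hits: list[DomainHit], e_threshold: float
) -> dict[str, set[str]]:
    """gene_id -> set of domain roles with >= 1 hit at the threshold."""
    out: dict[str, set[str]] = defaultdict(set)
    for h in hits:
        if h.domain_id not in DOMAIN_IDS:
            raise ValueError(f"unknown domain_id {h.domain_id!r} (expected NTD/CTD)")
        if h.evalue <= e_threshold:
            out[h.gene_id].add(h.domain_id)
    return out


def call_family_by_domain(
    hits: list[DomainHit], e_threshold: float = DEFAULT_E_THRESHOLD
) -> set[str]:
    """Seed members: genes with >= 1 NTD and >= 1 CTD hit at the threshold."""
    doms = _passing_domains(hits, e_threshold)
    return {g for g, d in doms.items() if d >= DOMAIN_IDS}


def propagate_membership(
    seeds: set[str], sgs: list[SyntelogGroup]
) -> dict[str, FamilyCall]:
    """Extend membership to all SG co-members of seed genes.

    Domain evidence takes precedence: a gene that is itself a seed keeps
    basis='domain' even when it is also a syntelog of another seed.  SGs with
    no seed contribute no members.  Propagation is idempotent.
    """
    calls: dict[str, FamilyCall] = {
        g: FamilyCall(gene_id=g, is_member=True, basis="domain") for g in seeds
    }
    for sg in sgs:
        gene_ids = sg.gene_ids
        if not seeds.intersection(gene_ids):
            continue
        for gid in gene_ids:
            if gid not in calls:
                calls[gid] = FamilyCall(gene_id=gid, is_member=True, basis="propagated")
    return calls


def classify_typicality(
    calls: dict[str, FamilyCall],
    hits: list[DomainHit],
    e_threshold: float = DEFAULT_E_THRESHOLD,
    require_both: bool = True,
) -> None:
    """Label members typical/atypical in place.

    Typical requires both domains at the threshold; with ``require_both``
    False only genes lacking *both* domains are atypical (the alternative
    reading of "lacked conserved domains").
    """
    doms = _passing_domains(hits, e_threshold)
    for call in calls.values():
        present = doms.get(call.gene_id, set())
        if require_both:
            call.typicality = "typical" if present >= DOMAIN_IDS else "atypical"
        else:
            call.typicality = "atypical" if not present else "typical"


def family_sgs(calls: dict[str, FamilyCall], sgs: list[SyntelogGroup]) -> list[SyntelogGroup]:
    """SGs containing at least one family member."""
    member_ids = set(calls)
    return [sg for sg in sgs if member_ids.intersection(sg.gene_ids)]


def build_pav(
    calls: dict[str, FamilyCall],
    sgs: list[SyntelogGroup],
    genomes: list[str],
) -> tuple[pd.DataFrame, pd.Series]:
    """Family PAV status matrix and per-genome private-SG counts.

    One row per family SG, one column per genome; cells are 'absent',
    'typical', 'atypical' or 'both' depending on the typicality of that
    genome's members.  Private counts tally family SGs with occupancy 1 per
    genome.
    """
    fam = family_sgs(calls, sgs)
    status = {}
    private = pd.Series(0, index=list(genomes), dtype=int)
    for sg in fam:
        row = []
        for genome in genomes:
            kinds = {
                calls[g].typicality
                for g in sg.members.get(genome, [])
                if g in calls
            }
            if not kinds:
                row.append("absent")
            elif kinds == {"typical"}:
                row.append("typical")
            elif kinds == {"atypical"}:
                row.append("atypical")
            else:
                row.append("both")
        status[sg.sg_id] = row
        if sg.occupancy == 1:
            (genome,) = [g for g, m in sg.members.items() if m]
            private[genome] += 1
    pav = pd.DataFrame.from_dict(status, orient="index", columns=list(genomes))
    return pav, private


def compare_lengths(
    calls: dict[str, FamilyCall], genes: dict[str, GeneModel]
) -> dict:
    """Rank-based comparison of CDS/gene lengths, typical vs atypical.

    Returns medians per group plus a one-sided Mann-Whitney U test of the
    hypothesis that atypical members are shorter; an explicit empty result is
    returned when either group is empty.
    """
    typical = [g for g, c in calls.items() if c.typicality == "typical"]
    atypical = [g for g, c in calls.items() if c.typicality == "atypical"]
    out: dict = {"n_typical": len(typical), "n_atypical": len(atypical)}
    if not typical or not atypical:
        out["comparison"] = None
        return out
    for metric in ("cds_length", "gene_length"):
        t = [getattr(genes[g], metric) for g in typical]
        a = [getattr(genes[g], metric) for g in atypical]
        stat, p = mannwhitneyu(a, t, alternative="less")
        out[metric] = {
            "median_typical": float(pd.Series(t).median()),
            "median_atypical": float(pd.Series(a).median()),
            "U": float(stat),
            "p_value": float(p),
        }
    out["comparison"] = "mannwhitneyu"
    return out


# ---------------------------------------------------------------------------
# Subfamily assignment (nearest labeled reference)


def _global_identity(aligner: Align.PairwiseAligner, a: str, b: str) -> float:
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    total = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / total if total else 0.0


def assign_subfamily(
    member_seqs: dict[str, str],
    reference_seqs: dict[str, str],
    reference_labels: dict[str, str],
    min_identity: float = 0.30,
) -> dict[str, str]:
    """Label each member with its highest-identity reference's subfamily.

    Global pairwise identity (matches over aligned columns); members below
    ``min_identity`` to every reference stay 'unassigned'.  Ties break by
    lexicographic reference id.
    """
    if not reference_seqs:
        raise ValueError("empty reference set")
    aligner = Align.PairwiseAligner(
        mode="global", match_score=1, mismatch_score=0,
        open_gap_score=-1, extend_gap_score=-0.5,
    )
    labels: dict[str, str] = {}
    for gid, seq in sorted(member_seqs.items()):
        best_ref, best_ident = None, -1.0
        for rid, rseq in sorted(reference_seqs.items()):
            ident = _global_identity(aligner, seq, rseq)
            if ident > best_ident:
                best_ref, best_ident = rid, ident
        if best_ident >= min_identity:
            labels[gid] = reference_labels[best_ref]
        else:
            labels[gid] = "unassigned"
    return labels


def calls_table(calls: dict[str, FamilyCall]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": c.gene_id,
            "is_member": c.is_member,
            "basis": c.basis,
            "typicality": c.typicality,
            "subfamily": c.subfamily,
        }
        for c in sorted(calls.values(), key=lambda c: c.gene_id)
    ]
    return pd.DataFrame(rows)
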