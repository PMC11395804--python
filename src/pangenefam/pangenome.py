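"""Syntelog-group construction and pangene occupancy classification.

Pipeline: reciprocal-best similarity anchors per genome pair -> collinear
chaining (weighted longest-monotone-subsequence with rank-gap limits) ->
anchor graph clustering into syntelog groups (SGs) with per-genome conflict
resolution -> occupancy classes (core / softcore / dispensable / private),
pan/core accumulation curves and per-class gene-feature summaries.
"""
from __future__ import annotations

from collections import defaultdict
from fractions import Fraction

import networkx as nx
import numpy as np
import pandas as pd

from .models import AnchorPair, CollinearBlock, GeneModel, PangeneClass, SyntelogGroup

# ---------------------------------------------------------------------------
# Anchors


def compute_anchors(
    similarity: pd.DataFrame,
    genes: dict[str, GeneModel],
    near_best: float = 0.9,
) -> dict[tuple[str, str], list[AnchorPair]]:
    """Reciprocal-best anchors per genome pair from a similarity table.

    ``similarity`` has columns gene_a, gene_b, score.  A pair is retained when
    each gene's score is within ``near_best`` of that gene's best score against
    the partner genome (``near_best=1`` is strict reciprocal-best; < 1 lets
    tandem-array copies survive as extra anchors).
    """
    if near_best <= 0 or near_best > 1:
        raise ValueError("near_best must be in (0, 1]")
    best: dict[tuple[str, str], float] = {}
    rows = []
    for ga, gb, score in similarity[["gene_a", "gene_b", "score"]].itertuples(index=False):
        for g in (ga, gb):
            if g not in genes:
                raise KeyError(f"gene id {g!r} absent from annotations")
        if genes[ga].genome_id == genes[gb].genome_id:
            continue
        if genes[ga].genome_id > genes[gb].genome_id:
            ga, gb = gb, ga
        score = float(score)
        rows.append((ga, gb, score))
        ka = (ga, genes[gb].genome_id)
        kb = (gb, genes[ga].genome_id)
        best[ka] = max(best.get(ka, 0.0), score)
        best[kb] = max(best.get(kb, 0.0), score)
    anchors: dict[tuple[str, str], list[AnchorPair]] = defaultdict(list)
    for ga, gb, score in sorted(set(rows)):
        if score >= near_best * best[(ga, genes[gb].genome_id)] and score >= near_best * best[(gb, genes[ga].genome_id)]:
            pair = (genes[ga].genome_id, genes[gb].genome_id)
            anchors[pair].append(AnchorPair(ga, gb, score))
    return dict(anchors)


# ---------------------------------------------------------------------------
# Collinear chaining


def _best_chain(
    pts: list[tuple[int, int, float, int]], direction: int, max_gap: int
) -> tuple[float, list[int]]:
    """Best-scoring monotone chain over (rank_a, rank_b, score, idx) points.

    ``direction`` +1 requires rank_b increasing, -1 decreasing; consecutive
    anchors must be within ``max_gap`` ranks on both genomes.  Returns
    (score, member indices in rank_a order).
    """
    pts = sorted(pts, key=lambda p: (p[0], p[1]))
    n = len(pts)
    dp = [p[2] for p in pts]
    prev = [-1] * n
    for i in range(n):
        ra_i, rb_i, sc_i, _ = pts[i]
        for j in range(i):
            ra_j, rb_j, _, _ = pts[j]
            if ra_j >= ra_i:
                continue
            if ra_i - ra_j > max_gap:
                continue
            if direction * (rb_i - rb_j) <= 0:
                continue
            if abs(rb_i - rb_j) > max_gap:
                continue
            if dp[j] + sc_i > dp[i]:
                dp[i] = dp[j] + sc_i
                prev[i] = j
    # tie-break: highest score, then smallest starting rank_a
    end = max(range(n), key=lambda i: (dp[i], -pts[i][0]))
    chain = []
    i = end
    while i != -1:
        chain.append(pts[i][3])
        i = prev[i]
    chain.reverse()
    return dp[end], chain


def chain_collinear(
    anchors: list[AnchorPair],
    genes: dict[str, GeneModel],
    max_gap: int = 10,
    min_block: int = 5,
) -> list[CollinearBlock]:
    """Partition anchors of one genome pair into maximal collinear blocks.

    Repeatedly extracts the best-scoring rank-monotone chain (same or inverted
    orientation) under the gap limit, assigning each anchor to at most one
    block; chains shorter than ``min_block`` anchors are discarded.
    """
    if not anchors:
        return []
    genome_a = genes[anchors[0].gene_a].genome_id
    genome_b = genes[anchors[0].gene_b].genome_id
    remaining = {
        i: (genes[a.gene_a].rank, genes[a.gene_b].rank, a.score, i)
        for i, a in enumerate(anchors)
    }
    blocks: list[CollinearBlock] = []
    while remaining:
        pts = list(remaining.values())
        fwd_score, fwd = _best_chain(pts, +1, max_gap)
        rev_score, rev = _best_chain(pts, -1, max_gap)
        if fwd_score >= rev_score:
            score, chain, orient = fwd_score, fwd, "same"
        else:
            score, chain, orient = rev_score, rev, "inverted"
        if len(chain) < min_block:
            break
        blocks.append(
            CollinearBlock(
                genome_a=genome_a,
                genome_b=genome_b,
                anchors=[anchors[i] for i in chain],
                orientation=orient,
                chain_score=score,
            )
        )
        for i in chain:
            del remaining[i]
    return blocks


# ---------------------------------------------------------------------------
# Tandem arrays


def detect_tandem_arrays(
    gene_ids: list[str],
    genes: dict[str, GeneModel],
    max_intervening: int = 1,
) -> list[list[str]]:
    """Group same-genome genes into tandem arrays by rank adjacency.

    Two genes on the same chromosome belong to one array when separated by at
    most ``max_intervening`` intervening genes; arrays are the transitive
    closure of that relation.  Returns arrays sorted by rank.
    """
    by_chrom: dict[tuple[str, str], list[GeneModel]] = defaultdict(list)
    for gid in gene_ids:
        g = genes[gid]
        by_chrom[(g.genome_id, g.chrom)].append(g)
    arrays: list[list[str]] = []
    for _, members in sorted(by_chrom.items()):
        members.sort(key=lambda g: g.rank)
        current = [members[0]]
        for g in members[1:]:
            if g.rank - current[-1].rank - 1 <= max_intervening:
                current.append(g)
            else:
                arrays.append([m.gene_id for m in current])
                current = [g]
        arrays.append([m.gene_id for m in current])
    return arrays


# ---------------------------------------------------------------------------
# Syntelog groups


def attach_adjacent_anchors(
    blocks: list[CollinearBlock],
    anchors: dict[tuple[str, str], list[AnchorPair]],
    genes: dict[str, GeneModel],
    max_intervening: int = 1,
) -> list[AnchorPair]:
    """Recover tandem-array anchors the strict-monotone chaining cannot hold.

    An unchained anchor is attached when it shares one endpoint gene with a
    chained anchor and its other endpoint sits within ``max_intervening + 1``
    ranks of that chained anchor's corresponding endpoint (same chromosome).
    This is exactly the situation of a tandem copy competing with its template
    for the same partner rank; unrelated near-best anchors stay out.
    """
    chained: set[tuple[str, str]] = set()
    partners: dict[str, set[str]] = defaultdict(set)
    for block in blocks:
        for a in block.anchors:
            chained.add((a.gene_a, a.gene_b))
            partners[a.gene_a].add(a.gene_b)
            partners[a.gene_b].add(a.gene_a)

    def adjacent(g1: str, g2: str) -> bool:
        a, b = genes[g1], genes[g2]
        return (
            a.genome_id == b.genome_id
            and a.chrom == b.chrom
            and abs(a.rank - b.rank) <= max_intervening + 1
        )

    extra: list[AnchorPair] = []
    for pair in sorted(anchors):
        for a in anchors[pair]:
            if (a.gene_a, a.gene_b) in chained:
                continue
            if any(adjacent(a.gene_a, p) for p in partners[a.gene_b]) or any(
                adjacent(a.gene_b, p) for p in partners[a.gene_a]
            ):
                extra.append(a)
    return extra


def build_syntelog_groups(
    blocks: list[CollinearBlock],
    genes: dict[str, GeneModel],
    max_intervening: int = 1,
    extra_anchors: list[AnchorPair] | None = None,
    tandem_pairs: list[tuple[str, str, float]] | None = None,
) -> list[SyntelogGroup]:
    """Cluster in-block anchors into syntelog groups.

    Genes are nodes, in-block anchor pairs (plus any ``extra_anchors``, e.g.
    tandem attachments) weighted edges; ``tandem_pairs`` adds same-genome
    similarity edges between rank-adjacent genes so tandem arrays stay in one
    SG even when (as for private arrays) no cross-genome anchor exists.
    Connected components become SG candidates.  Within a component a genome may contribute several
    genes only if they form one tandem array; otherwise the best-connected
    array (largest total anchor weight to the rest of the component, ties by
    lexicographic gene id) is kept and the remainder re-seeded as private
    singleton SGs.  Genes appearing in no block become singleton SGs.
    """
    graph = nx.Graph()
    all_edges = [a for block in blocks for a in block.anchors]
    all_edges += list(extra_anchors or [])
    for a in all_edges:
        w = a.score
        if graph.has_edge(a.gene_a, a.gene_b):
            w = max(w, graph[a.gene_a][a.gene_b]["weight"])
        graph.add_edge(a.gene_a, a.gene_b, weight=w)
    for ga, gb, score in tandem_pairs or []:
        a, b = genes[ga], genes[gb]
        if (
            a.genome_id == b.genome_id
            and a.chrom == b.chrom
            and abs(a.rank - b.rank) <= max_intervening + 1
            and not graph.has_edge(ga, gb)
        ):
            graph.add_edge(ga, gb, weight=float(score))

    sgs: list[SyntelogGroup] = []
    leftovers: list[str] = []
    for comp in sorted(nx.connected_components(graph), key=lambda c: min(c)):
        by_genome: dict[str, list[str]] = defaultdict(list)
        for gid in comp:
            by_genome[genes[gid].genome_id].append(gid)
        members: dict[str, list[str]] = {}
        for genome_id, gids in sorted(by_genome.items()):
            arrays = detect_tandem_arrays(gids, genes, max_intervening)
            if len(arrays) > 1:
                others = comp - set(gids)

                def array_weight(arr: list[str]) -> float:
                    return sum(
                        graph[g][o]["weight"]
                        for g in arr
                        for o in graph.neighbors(g)
                        if o in others
                    )

                arrays.sort(key=lambda arr: (-array_weight(arr), arr[0]))
                for arr in arrays[1:]:
                    leftovers.extend(arr)
                arrays = arrays[:1]
            members[genome_id] = sorted(arrays[0], key=lambda g: genes[g].rank)
        sgs.append(SyntelogGroup(sg_id="", members=members))

    clustered = {g for sg in sgs for g in sg.gene_ids}
    for gid in sorted(set(genes) - clustered):
        leftovers.append(gid)
    for gid in sorted(set(leftovers)):
        sgs.append(SyntelogGroup(sg_id="", members={genes[gid].genome_id: [gid]}))

    sgs.sort(key=lambda sg: min(sg.gene_ids))
    for i, sg in enumerate(sgs):
        sg.sg_id = f"SG{i:06d}"
    return sgs


# ---------------------------------------------------------------------------
# Occupancy classification


def classify_occupancy(occupancy: int, n_genomes: int) -> PangeneClass:
    """Map genome occupancy to a pangene class.

    core: present in all genomes; softcore: in over 90% of genomes but not
    all (exact rational arithmetic, so K=27 yields occupancy 25-26); private:
    exactly one genome; dispensable: everything in between.
    """
    if not 1 <= occupancy <= n_genomes:
        raise ValueError(f"occupancy {occupancy} outside [1, {n_genomes}]")
    if occupancy == n_genomes:
        return PangeneClass.CORE
    if occupancy == 1:
        return PangeneClass.PRIVATE
    if Fraction(occupancy, n_genomes) > Fraction(9, 10):
        return PangeneClass.SOFTCORE
    return PangeneClass.DISPENSABLE


def classify_groups(sgs: list[SyntelogGroup], n_genomes: int) -> None:
    """Assign pangene_class to every SG in place."""
    for sg in sgs:
        sg.pangene_class = classify_occupancy(sg.occupancy, n_genomes)


def softcore_occupancies(n_genomes: int) -> list[int]:
    """All occupancy counts the rule classifies softcore for K genomes."""
    return [
        occ
        for occ in range(1, n_genomes + 1)
        if classify_occupancy(occ, n_genomes) is PangeneClass.SOFTCORE
    ]


def dispensable_occupancies(n_genomes: int) -> list[int]:
    return [
        occ
        for occ in range(1, n_genomes + 1)
        if classify_occupancy(occ, n_genomes) is PangeneClass.DISPENSABLE
    ]


# ---------------------------------------------------------------------------
# Pangenome matrix, curves, summaries


def pangenome_matrix(sgs: list[SyntelogGroup], genomes: list[str]) -> pd.DataFrame:
    """SG x genome member-count matrix (0 = absent)."""
    data = {
        sg.sg_id: [len(sg.members.get(g, [])) for g in genomes] for sg in sgs
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=list(genomes))


def accumulation_curves(
    matrix: pd.DataFrame, n_orderings: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Mean pan- and core-SG counts over random genome orderings.

    For each ordering, pan(m) counts SGs present in >= 1 of the first m
    genomes and core(m) those present in all m; means and standard deviations
    over orderings are reported per m.
    """
    if matrix.empty:
        raise ValueError("empty pangenome matrix")
    present = (matrix.values > 0)
    n_genomes = present.shape[1]
    rng = np.random.default_rng(seed)
    pan = np.zeros((n_orderings, n_genomes))
    core = np.zeros((n_orderings, n_genomes))
    for it in range(n_orderings):
        order = rng.permutation(n_genomes)
        seen_any = np.zeros(present.shape[0], dtype=bool)
        seen_all = np.ones(present.shape[0], dtype=bool)
        for m, g in enumerate(order):
            seen_any |= present[:, g]
            seen_all &= present[:, g]
            pan[it, m] = seen_any.sum()
            core[it, m] = seen_all.sum()
    return pd.DataFrame(
        {
            "m": np.arange(1, n_genomes + 1),
            "pan_mean": pan.mean(axis=0),
            "pan_std": pan.std(axis=0),
            "core_mean": core.mean(axis=0),
            "core_std": core.std(axis=0),
        }
    )


def summarize_gene_features(
    sgs: list[SyntelogGroup], genes: dict[str, GeneModel]
) -> pd.DataFrame:
    """Per-gene CDS length and exon count labeled with the SG pangene class."""
    rows = []
    for sg in sgs:
        for gid in sg.gene_ids:
            g = genes[gid]
            rows.append(
                {
                    "gene_id": gid,
                    "genome_id": g.genome_id,
                    "sg_id": sg.sg_id,
                    "pangene_class": sg.pangene_class.value if sg.pangene_class else None,
                    "cds_length": g.cds_length,
                    "gene_length": g.gene_length,
                    "exon_count": g.exon_count,
                }
            )
    return pd.DataFrame(rows)


def sg_table(sgs: list[SyntelogGroup]) -> pd.DataFrame:
    """Long-form SG membership table (sg_id, genome, gene_id, occupancy, class)."""
    rows = []
    for sg in sgs:
        for genome, gids in sorted(sg.members.items()):
            for gid in gids:
                rows.append(
                    {
                        "sg_id": sg.sg_id,
                        "genome_id": genome,
                        "gene_id": gid,
                        "occupancy": sg.occupancy,
                        "pangene_class": sg.pangene_class.value if sg.pangene_class else None,
                    }
                )
    return pd.DataFrame(rows)


def build_pangenome(
    similarity: pd.DataFrame,
    genes: dict[str, GeneModel],
    near_best: float = 0.9,
    max_gap: int = 10,
    min_block: int = 5,
    max_intervening: int = 1,
) -> list[SyntelogGroup]:
    """End-to-end: anchors -> blocks per genome pair -> classified SGs."""
    anchors = compute_anchors(similarity, genes, near_best=near_best)
    blocks: list[CollinearBlock] = []
    for pair in sorted(anchors):
        blocks.extend(chain_collinear(anchors[pair], genes, max_gap, min_block))
    extra = attach_adjacent_anchors(blocks, anchors, genes, max_intervening)
    tandem_pairs = [
        (ga, gb, float(score))
        for ga, gb, score in similarity[["gene_a", "gene_b", "score"]].itertuples(index=False)
        if genes[ga].genome_id == genes[gb].genome_id
    ]
    sgs = build_syntelog_groups(blocks, genes, max_intervening, extra, tandem_pairs)
    n_genomes = len({g.genome_id for g in genes.values()})
    classify_groups(sgs, n_genomes)
    return sgs
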