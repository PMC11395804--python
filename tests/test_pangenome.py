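"""Anchors, collinear chaining, syntelog grouping, occupancy classes."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pangenefam.models import AnchorPair, GeneModel, PangeneClass
from pangenefam.pangenome import (
    accumulation_curves,
    build_pangenome,
    build_syntelog_groups,
    chain_collinear,
    classify_occupancy,
    compute_anchors,
    detect_tandem_arrays,
    pangenome_matrix,
    sg_table,
    summarize_gene_features,
)


def mk_gene(gene_id: str, genome: str, rank: int, chrom: str = "chr1") -> GeneModel:
    start = 1000 + 5000 * rank
    return GeneModel(
        gene_id=gene_id, genome_id=genome, chrom=chrom, start=start,
        end=start + 1000, strand="+", rank=rank,
        exons=[(start, start + 1000)], cds=[(start, start + 1000)],
    )


# --- occupancy classification ----------------------------------------------


@pytest.mark.parametrize(
    "occ,n,expected",
    [
        (27, 27, PangeneClass.CORE),
        (26, 27, PangeneClass.SOFTCORE),
        (25, 27, PangeneClass.SOFTCORE),
        (24, 27, PangeneClass.DISPENSABLE),
        (2, 27, PangeneClass.DISPENSABLE),
        (1, 27, PangeneClass.PRIVATE),
        (10, 10, PangeneClass.CORE),
        (9, 10, PangeneClass.DISPENSABLE),  # strict 'over 90%': 9/10 is not
        (11, 12, PangeneClass.SOFTCORE),
    ],
)
def test_classify_occupancy(occ, n, expected):
    assert classify_occupancy(occ, n) is expected


@settings(derandomize=True, max_examples=200)
@given(st.integers(min_value=1, max_value=500), st.integers(min_value=1, max_value=500))
def test_classification_is_total_and_consistent(occ, n):
    """Every feasible occupancy gets exactly one class, and the class
    boundaries respect the occupancy ordering (core at the top, private at
    the bottom, softcore strictly between dispensable and core)."""
    if occ > n:
        with pytest.raises(ValueError):
            classify_occupancy(occ, n)
        return
    cls = classify_occupancy(occ, n)
    assert (cls is PangeneClass.CORE) == (occ == n)
    assert (cls is PangeneClass.PRIVATE) == (occ == 1 and n > 1)
    if cls is PangeneClass.SOFTCORE:
        assert 10 * occ > 9 * n
        assert classify_occupancy(occ - 1, n) in (
            PangeneClass.SOFTCORE, PangeneClass.DISPENSABLE, PangeneClass.PRIVATE
        )


def test_classify_occupancy_total_and_exhaustive():
    for n in range(1, 31):
        classes = [classify_occupancy(o, n) for o in range(1, n + 1)]
        assert all(isinstance(c, PangeneClass) for c in classes)
    with pytest.raises(ValueError):
        classify_occupancy(0, 27)
    with pytest.raises(ValueError):
        classify_occupancy(28, 27)


# --- anchors ----------------------------------------------------------------


def _sim_table(rows):
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])


def test_reciprocal_best_anchor_retained():
    genes = {g.gene_id: g for g in [mk_gene("A1", "A", 0), mk_gene("B1", "B", 0)]}
    anchors = compute_anchors(_sim_table([("A1", "B1", 100.0)]), genes, near_best=1.0)
    assert anchors[("A", "B")] == [AnchorPair("A1", "B1", 100.0)]


def test_non_reciprocal_anchor_dropped_under_strict_rbh():
    genes = {
        g.gene_id: g
        for g in [mk_gene("A1", "A", 0), mk_gene("A2", "A", 1),
                  mk_gene("B1", "B", 0)]
    }
    # A1's best is B1, but B1's best is A2
    table = _sim_table([("A1", "B1", 80.0), ("A2", "B1", 100.0)])
    anchors = compute_anchors(table, genes, near_best=1.0)
    pairs = {(a.gene_a, a.gene_b) for a in anchors[("A", "B")]}
    assert pairs == {("A2", "B1")}


def test_near_best_keeps_tandem_copy():
    genes = {
        g.gene_id: g
        for g in [mk_gene("A1", "A", 0), mk_gene("B1", "B", 0),
                  mk_gene("B1p", "B", 1)]
    }
    table = _sim_table([("A1", "B1", 100.0), ("A1", "B1p", 95.0)])
    anchors = compute_anchors(table, genes, near_best=0.9)
    pairs = {(a.gene_a, a.gene_b) for a in anchors[("A", "B")]}
    assert pairs == {("A1", "B1"), ("A1", "B1p")}


def test_unknown_gene_id_is_an_error():
    genes = {"A1": mk_gene("A1", "A", 0)}
    with pytest.raises(KeyError):
        compute_anchors(_sim_table([("A1", "ZZ", 10.0)]), genes)


# --- collinear chaining -----------------------------------------------------


def _anchors_from_ranks(pairs, score=10.0):
    """pairs: list of (rank_a, rank_b[, score]). Builds genes + anchors."""
    genes, anchors = {}, []
    for i, p in enumerate(pairs):
        ra, rb = p[0], p[1]
        sc = p[2] if len(p) > 2 else score
        ga, gb = f"A{ra}", f"B{rb}"
        genes.setdefault(ga, mk_gene(ga, "A", ra))
        genes.setdefault(gb, mk_gene(gb, "B", rb))
        anchors.append(AnchorPair(ga, gb, sc))
    return anchors, genes


def brute_force_best_chain(pairs, max_gap):
    """Independent oracle: exhaustive DFS over monotone chains (<= 12 anchors)."""
    best = 0.0
    n = len(pairs)

    def extend(idx, chain_score, last, direction):
        nonlocal best
        best = max(best, chain_score)
        ra0, rb0, sc0 = last
        for j in range(n):
            ra, rb, sc = pairs[j]
            if ra <= ra0 or ra - ra0 > max_gap or abs(rb - rb0) > max_gap:
                continue
            for d in ([direction] if direction else [+1, -1]):
                if d * (rb - rb0) > 0:
                    extend(j, chain_score + sc, (ra, rb, sc), d)

    for i in range(n):
        extend(i, pairs[i][2], pairs[i], 0)
    return best


def test_perfect_collinear_run_is_one_block():
    anchors, genes = _anchors_from_ranks([(i, i) for i in range(10)])
    blocks = chain_collinear(anchors, genes, max_gap=10, min_block=5)
    assert len(blocks) == 1
    assert len(blocks[0]) == 10
    assert blocks[0].orientation == "same"


def test_short_chain_below_min_block_is_dropped():
    anchors, genes = _anchors_from_ranks([(i, i) for i in range(4)])
    assert chain_collinear(anchors, genes, max_gap=10, min_block=5) == []


def test_two_interleaved_inversions_found_with_orientations():
    fwd = [(2 * i, 2 * i) for i in range(6)]
    inv = [(2 * i + 1, 60 - 2 * i) for i in range(6)]
    anchors, genes = _anchors_from_ranks(fwd + inv)
    blocks = chain_collinear(anchors, genes, max_gap=12, min_block=5)
    assert sorted(b.orientation for b in blocks) == ["inverted", "same"]
    assert all(len(b) == 6 for b in blocks)


def test_chain_score_matches_brute_force_on_random_sets():
    rng = np.random.default_rng(11)
    for _ in range(100):
        n = int(rng.integers(2, 13))
        ranks_a = rng.choice(30, size=n, replace=False)
        ranks_b = rng.choice(30, size=n, replace=False)
        scores = rng.uniform(1, 10, size=n).round(3)
        pairs = list(zip(ranks_a.tolist(), ranks_b.tolist(), scores.tolist()))
        anchors, genes = _anchors_from_ranks(pairs)
        blocks = chain_collinear(anchors, genes, max_gap=8, min_block=1)
        got = max((b.chain_score for b in blocks), default=0.0)
        assert got == pytest.approx(brute_force_best_chain(pairs, max_gap=8))


# --- tandem arrays ----------------------------------------------------------


def test_tandem_array_rules():
    genes = {f"G{r}": mk_gene(f"G{r}", "A", r) for r in (10, 11, 12, 13, 20)}
    assert detect_tandem_arrays(["G10", "G11"], genes, 1) == [["G10", "G11"]]
    assert detect_tandem_arrays(["G10", "G20"], genes, 1) == [["G10"], ["G20"]]
    # transitive closure across a 1-gene gap
    assert detect_tandem_arrays(["G10", "G12", "G13"], genes, 1) == [
        ["G10", "G12", "G13"]
    ]


# --- syntelog group construction -------------------------------------------


def _block(anchors, genes):
    return chain_collinear(anchors, genes, max_gap=10, min_block=1)


def test_triangle_component_is_one_group_with_occupancy_three():
    genes = {}
    anchors = []
    for pair in (("A", "B"), ("B", "C"), ("A", "C")):
        for r in range(5):
            for gnm in pair:
                genes.setdefault(f"{gnm}{r}", mk_gene(f"{gnm}{r}", gnm, r))
            anchors.append(AnchorPair(f"{pair[0]}{r}", f"{pair[1]}{r}", 50.0))
    blocks = []
    for pair in (("A", "B"), ("B", "C"), ("A", "C")):
        sub = [a for a in anchors if a.gene_a.startswith(pair[0]) and a.gene_b.startswith(pair[1])]
        blocks += chain_collinear(sub, genes, max_gap=10, min_block=3)
    sgs = build_syntelog_groups(blocks, genes)
    by_occ = [sg for sg in sgs if sg.occupancy == 3]
    assert len(by_occ) == 5
    assert all(len(sg.gene_ids) == 3 for sg in by_occ)


def test_gene_without_anchors_becomes_private_singleton():
    genes = {"A1": mk_gene("A1", "A", 0), "B1": mk_gene("B1", "B", 0)}
    sgs = build_syntelog_groups([], genes)
    assert len(sgs) == 2
    assert all(sg.occupancy == 1 for sg in sgs)


def test_same_genome_conflict_resolved_by_anchor_weight():
    # component A1-B1 (100) and A1-B9 (40); B1, B9 not adjacent
    genes = {
        "A1": mk_gene("A1", "A", 0),
        "B1": mk_gene("B1", "B", 0),
        "B9": mk_gene("B9", "B", 9),
    }
    blocks = chain_collinear([AnchorPair("A1", "B1", 100.0)], genes, 10, 1)
    blocks += chain_collinear([AnchorPair("A1", "B9", 40.0)], genes, 10, 1)
    sgs = build_syntelog_groups(blocks, genes)
    main = next(sg for sg in sgs if "A1" in sg.gene_ids)
    assert main.members["B"] == ["B1"]
    assert any(sg.gene_ids == ["B9"] for sg in sgs)


# --- matrix, curves, summaries ---------------------------------------------


def test_accumulation_curves_monotone_with_correct_endpoints(small_sim):
    sgs = build_pangenome(small_sim.similarity, small_sim.all_genes)
    genomes = sorted(small_sim.genomes)
    matrix = pangenome_matrix(sgs, genomes)
    curves = accumulation_curves(matrix, n_orderings=20, seed=3)
    assert (np.diff(curves["pan_mean"]) >= -1e-9).all()
    assert (np.diff(curves["core_mean"]) <= 1e-9).all()
    n_core = sum(sg.pangene_class is PangeneClass.CORE for sg in sgs)
    assert curves["pan_mean"].iloc[-1] == len(sgs)
    assert curves["core_mean"].iloc[-1] == n_core
    # m=1: pan(1) = core(1) = gene-bearing SG count of the sampled genome
    assert curves["pan_mean"].iloc[0] == pytest.approx(curves["core_mean"].iloc[0])


def test_all_core_matrix_gives_flat_pan_curve():
    matrix = pd.DataFrame(np.ones((8, 4), dtype=int),
                          index=[f"SG{i}" for i in range(8)],
                          columns=list("ABCD"))
    curves = accumulation_curves(matrix, n_orderings=5, seed=0)
    assert (curves["pan_mean"] == 8).all()
    assert (curves["core_mean"] == 8).all()


def test_cds_length_and_exon_count_summaries():
    g = GeneModel(
        gene_id="X", genome_id="A", chrom="chr1", start=0, end=700, strand="+",
        rank=0, exons=[(0, 300), (400, 700)], cds=[(0, 300), (400, 700)],
    )
    assert g.cds_length == 600
    assert g.exon_count == 2


def test_planted_core_genes_have_longer_cds_than_private(small_sim):
    sgs = build_pangenome(small_sim.similarity, small_sim.all_genes)
    feats = summarize_gene_features(sgs, small_sim.all_genes)
    means = feats.groupby("pangene_class")["cds_length"].mean()
    assert means["core"] > means["private"]


# --- recovery ---------------------------------------------------------------


def _partition(membership):
    inv = {}
    for g, s in membership.items():
        inv.setdefault(s, set()).add(g)
    return {frozenset(v) for v in inv.values()}


def test_noiseless_recovery_is_exact(small_sim):
    sgs = build_pangenome(small_sim.similarity, small_sim.all_genes)
    pred = {g: sg.sg_id for sg in sgs for g in sg.gene_ids}
    assert _partition(pred) == _partition(small_sim.truth.sg_membership)
    for sg in sgs:
        truth_cls = small_sim.truth.sg_class[
            small_sim.truth.sg_membership[sg.gene_ids[0]]
        ]
        assert sg.pangene_class.value == truth_cls


def test_recovery_with_rank_shuffle_noise():
    from pangenefam import SimConfig, generate_pangenome

    cfg = SimConfig(
        n_genomes=6, genes_per_genome=80,
        class_mix={"core": 0.5, "softcore": 0.0, "dispensable": 0.3, "private": 0.2},
        tandem_rate=0.0, rearrangement_rate=0.05, seed=5,
    )
    sim = generate_pangenome(cfg)
    sgs = build_pangenome(sim.similarity, sim.all_genes)
    truth_part = _partition(sim.truth.sg_membership)
    pred_part = _partition({g: sg.sg_id for sg in sgs for g in sg.gene_ids})
    matched = sum(1 for grp in truth_part if grp in pred_part)
    assert matched / len(truth_part) >= 0.95


def test_every_gene_in_exactly_one_group(small_sim):
    sgs = build_pangenome(small_sim.similarity, small_sim.all_genes)
    seen = [g for sg in sgs for g in sg.gene_ids]
    assert len(seen) == len(set(seen)) == len(small_sim.all_genes)
    table = sg_table(sgs)
    assert set(table["gene_id"]) == set(small_sim.all_genes)
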