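"""Expression normalization, differential expression, and mutual-rank
coexpression module detection.

FPKM normalization, a simplified DESeq2-style differential-expression stage
(median-of-ratios size factors, Welch t-test on log2 normalized counts,
Benjamini-Hochberg adjustment; DEG iff |log2FC| > 1 and FDR < 0.05), mutual
ranks MR(i,j) = sqrt(rank_i(j) * rank_j(i)) of Pearson correlations on
log2(FPKM+1), exponential edge weights exp(-(MR-1)/x) for decay scales
x in {5, 10, 25, 50, 100}, edge retention iff PCC > 0 and weight > 0.01, and
a ClusterONE-style greedy cohesiveness module finder with modules kept at
p < 0.1.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import CoexpressionModule

DECAY_SCALES = (5, 10, 25, 50, 100)
EDGE_WEIGHT_CUTOFF = 0.01
MODULE_P_CUTOFF = 0.1


# ---------------------------------------------------------------------------
# Normalization


def compute_fpkm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """FPKM(g, s) = counts * 1e9 / (length(g) * total_counts(s))."""
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()[:5]
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("per-sample totals must be > 0")
    return counts * 1e9 / np.outer(lengths, totals)


# ---------------------------------------------------------------------------
# Differential expression (simplified DESeq2-style stand-in)


def _median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors from genes expressed in every sample."""
    logc = np.log(counts.where(counts > 0))
    ref = logc.mean(axis=1)
    usable = ref.notna()
    if not usable.any():
        return pd.Series(1.0, index=counts.columns)
    ratios = logc.loc[usable].sub(ref[usable], axis=0)
    sf = np.exp(ratios.median(axis=0))
    return sf.fillna(1.0)


def differential_expression(
    counts: pd.DataFrame,
    condition_labels: pd.Series,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Two-condition differential expression.

    Median-of-ratios library normalization, log2 fold-change from normalized
    means with pseudocount 1, Welch t-test per gene on log2(normalized + 1),
    BH adjustment; ``is_deg`` iff |log2fc| > ``lfc_threshold`` and
    fdr < ``fdr_threshold``.  With < 2 samples in a condition the test is
    skipped (p and fdr NaN) and log2fc still reported.
    """
    labels = condition_labels.reindex(counts.columns)
    conds = sorted(labels.dropna().unique())
    if len(conds) != 2:
        raise ValueError(f"expected exactly 2 conditions, got {conds}")
    a_cols = labels.index[labels == conds[0]]
    b_cols = labels.index[labels == conds[1]]
    sf = _median_of_ratios(counts)
    norm = counts / sf
    log_norm = np.log2(norm + 1)
    mean_a = norm[a_cols].mean(axis=1)
    mean_b = norm[b_cols].mean(axis=1)
    log2fc = np.log2((mean_b + 1) / (mean_a + 1))
    if len(a_cols) >= 2 and len(b_cols) >= 2:
        t, p = stats.ttest_ind(
            log_norm[b_cols], log_norm[a_cols], axis=1, equal_var=False
        )
        p = pd.Series(p, index=counts.index)
        # zero-variance genes with equal means: no evidence of change
        p = p.fillna(1.0)
        fdr = pd.Series(
            multipletests(p.values, method="fdr_bh")[1], index=counts.index
        )
    else:
        p = pd.Series(np.nan, index=counts.index)
        fdr = pd.Series(np.nan, index=counts.index)
    is_deg = (log2fc.abs() > lfc_threshold) & (fdr < fdr_threshold)
    return pd.DataFrame(
        {
            "gene_id": counts.index,
            "log2fc": log2fc.values,
            "p_value": p.values,
            "fdr": fdr.values,
            "is_deg": is_deg.fillna(False).values,
        }
    ).set_index("gene_id")


# ---------------------------------------------------------------------------
# Mutual-rank network


def mutual_rank(
    fpkm: pd.DataFrame, gene_subset: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations on log2(FPKM+1) and mutual ranks.

    For gene i, partners are ranked 1..n-1 by descending correlation (self
    excluded, ties by gene id); MR(i,j) = sqrt(rank_i(j) * rank_j(i)).
    Zero-variance genes are excluded.
    """
    x = fpkm.loc[gene_subset] if gene_subset is not None else fpkm
    if x.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    logx = np.log2(x + 1)
    variances = logx.var(axis=1)
    keep = variances > 0
    logx = logx.loc[keep]
    gene_ids = list(logx.index)
    n = len(gene_ids)
    pcc = np.corrcoef(logx.values)
    pcc = pd.DataFrame(pcc, index=gene_ids, columns=gene_ids)
    # ranks: per row, order partners by (-pcc, gene id)
    ranks = np.zeros((n, n))
    order_ids = np.array(gene_ids)
    for i in range(n):
        partners = [(j, -pcc.values[i, j], order_ids[j]) for j in range(n) if j != i]
        partners.sort(key=lambda t: (t[1], t[2]))
        for r, (j, _, _) in enumerate(partners, start=1):
            ranks[i, j] = r
    mr = np.sqrt(ranks * ranks.T)
    np.fill_diagonal(mr, 0.0)
    return pcc, pd.DataFrame(mr, index=gene_ids, columns=gene_ids)


def edge_weight(mr_value: float, x: float = 5, decreasing: bool = True) -> float:
    """Exponential edge weight exp(-(MR-1)/x) in (0, 1]; MR = 1 gives 1."""
    if mr_value < 1:
        raise ValueError("mutual rank must be >= 1")
    sign = -1.0 if decreasing else 1.0
    return math.exp(sign * (mr_value - 1) / x)


def build_network(
    pcc: pd.DataFrame,
    mr: pd.DataFrame,
    x: float = 5,
    weight_cutoff: float = EDGE_WEIGHT_CUTOFF,
    decreasing: bool = True,
) -> nx.Graph:
    """Graph of gene pairs passing the conjunction PCC > 0 and weight > cutoff."""
    graph = nx.Graph()
    graph.add_nodes_from(pcc.index)
    ids = list(pcc.index)
    for i, gi in enumerate(ids):
        for gj in ids[i + 1 :]:
            if pcc.loc[gi, gj] <= 0:
                continue
            w = edge_weight(mr.loc[gi, gj], x, decreasing)
            if w > weight_cutoff:
                graph.add_edge(gi, gj, weight=w, pcc=float(pcc.loc[gi, gj]),
                               mr=float(mr.loc[gi, gj]))
    return graph


def edge_table(pcc: pd.DataFrame, mr: pd.DataFrame,
               scales: tuple = DECAY_SCALES) -> pd.DataFrame:
    """Long-form edge list with weights at every decay scale."""
    ids = list(pcc.index)
    rows = []
    for i, gi in enumerate(ids):
        for gj in ids[i + 1 :]:
            m = float(mr.loc[gi, gj])
            row = {"gene_a": gi, "gene_b": gj, "pcc": float(pcc.loc[gi, gj]), "mr": m}
            for x in scales:
                row[f"weight_{x}"] = edge_weight(m, x)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohesiveness-based module detection (ClusterONE-style)


@dataclass
class _GrowState:
    """Incremental cohesiveness bookkeeping for one growing module."""

    graph: nx.Graph
    members: set[str] = field(default_factory=set)
    w_in: float = 0.0
    w_bound: float = 0.0

    def cohesiveness(self, penalty: float) -> float:
        denom = self.w_in + self.w_bound + penalty * len(self.members)
        return self.w_in / denom if denom > 0 else 0.0

    def delta(self, node: str, add: bool) -> tuple[float, float]:
        """(w_in, w_bound) after adding/removing ``node``."""
        to_in = sum(
            d["weight"] for _, nb, d in self.graph.edges(node, data=True)
            if nb in self.members and nb != node
        )
        total = sum(d["weight"] for _, _, d in self.graph.edges(node, data=True))
        if add:
            return self.w_in + to_in, self.w_bound - to_in + (total - to_in)
        return self.w_in - to_in, self.w_bound + to_in - (total - to_in)

    def apply(self, node: str, add: bool) -> None:
        self.w_in, self.w_bound = self.delta(node, add)
        (self.members.add if add else self.members.discard)(node)

    def boundary(self) -> set[str]:
        out = set()
        for m in self.members:
            out.update(nb for nb in self.graph.neighbors(m) if nb not in self.members)
        return out


def _grow_module(graph: nx.Graph, seed: str, penalty: float) -> set[str]:
    state = _GrowState(graph)
    state.apply(seed, add=True)
    improved = True
    while improved:
        improved = False
        best_gain, best_node, best_add = 0.0, None, True
        f0 = state.cohesiveness(penalty)
        for node in sorted(state.boundary()):
            w_in, w_bound = state.delta(node, add=True)
            denom = w_in + w_bound + penalty * (len(state.members) + 1)
            f1 = w_in / denom if denom > 0 else 0.0
            if f1 - f0 > best_gain + 1e-12:
                best_gain, best_node, best_add = f1 - f0, node, True
        if len(state.members) > 1:
            for node in sorted(state.members):
                if node == seed:
                    continue
                w_in, w_bound = state.delta(node, add=False)
                denom = w_in + w_bound + penalty * (len(state.members) - 1)
                f1 = w_in / denom if denom > 0 else 0.0
                if f1 - f0 > best_gain + 1e-12:
                    best_gain, best_node, best_add = f1 - f0, node, False
        if best_node is not None:
            state.apply(best_node, best_add)
            improved = True
    return set(state.members)


def _overlap_score(a: set[str], b: set[str]) -> float:
    inter = len(a & b)
    return inter * inter / (len(a) * len(b)) if a and b else 0.0


def _module_pvalue(graph: nx.Graph, members: set[str]) -> float:
    """One-sided Mann-Whitney U: internal edge weights exceed boundary weights."""
    internal, boundary = [], []
    for u, v, d in graph.edges(data=True):
        u_in, v_in = u in members, v in members
        if u_in and v_in:
            internal.append(d["weight"])
        elif u_in or v_in:
            boundary.append(d["weight"])
    if not internal:
        return 1.0
    if not boundary:
        return 0.0
    _, p = stats.mannwhitneyu(internal, boundary, alternative="greater")
    return float(p)


def find_modules(
    graph: nx.Graph,
    penalty: float = 2.0,
    min_size: int = 3,
    overlap_threshold: float = 0.8,
    p_cutoff: float = MODULE_P_CUTOFF,
    seed: int = 0,
) -> list[CoexpressionModule]:
    """Greedy seed-and-grow cohesiveness clustering.

    Seeds are uncovered nodes in descending weighted-degree order (ties by
    gene id); each grows/shrinks by single-node moves maximizing
    f(V) = w_in / (w_in + w_bound + penalty * |V|).  Grown sets with pairwise
    overlap score >= ``overlap_threshold`` are merged, sets below ``min_size``
    dropped, and modules retained iff the internal-vs-boundary rank-test
    p-value is < ``p_cutoff``.  Deterministic given the tie-break rules (the
    ``seed`` argument is accepted for interface stability).
    """
    wdeg = {
        n: sum(d["weight"] for _, _, d in graph.edges(n, data=True))
        for n in graph.nodes
    }
    order = sorted(graph.nodes, key=lambda n: (-wdeg[n], n))
    covered: set[str] = set()
    raw: list[set[str]] = []
    for node in order:
        if node in covered or wdeg[node] == 0:
            continue
        members = _grow_module(graph, node, penalty)
        covered |= members
        if members not in raw:
            raw.append(members)
    # merge overlapping modules (single pass to fixed point)
    merged = True
    while merged:
        merged = False
        for i in range(len(raw)):
            for j in range(i + 1, len(raw)):
                if _overlap_score(raw[i], raw[j]) >= overlap_threshold:
                    raw[i] = raw[i] | raw[j]
                    del raw[j]
                    merged = True
                    break
            if merged:
                break
    modules = []
    for members in raw:
        if len(members) < min_size:
            continue
        state = _GrowState(graph)
        for m in sorted(members):
            state.apply(m, add=True)
        p = _module_pvalue(graph, members)
        if p < p_cutoff:
            modules.append(
                CoexpressionModule(
                    genes=frozenset(members),
                    cohesiveness=state.cohesiveness(penalty),
                    p_value=p,
                )
            )
    modules.sort(key=lambda m: (-m.cohesiveness, sorted(m.genes)))
    return modules


def modules_table(modules: list[CoexpressionModule]) -> pd.DataFrame:
    rows = []
    for i, mod in enumerate(modules):
        for g in sorted(mod.genes):
            rows.append(
                {
                    "module_id": f"M{i:03d}",
                    "gene_id": g,
                    "cohesiveness": mod.cohesiveness,
                    "p_value": mod.p_value,
                }
            )
    return pd.DataFrame(rows, columns=["module_id", "gene_id", "cohesiveness", "p_value"])
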