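"""Nei–Gojobori (1986) Ka/Ks estimation for gapless codon alignments.

The estimator counts, per codon, the fraction of one-step nucleotide changes
that are synonymous (site counting), averages synonymous/nonsynonymous
difference counts over all mutational pathways between codon pairs (pathway
counting), applies the Jukes–Cantor multiple-hit correction to both
proportions, and reports omega = dN/dS.  Changes that create a stop codon are
scored nonsynonymous for site counting; pathways passing through a stop codon
are excluded from the pathway average unless every pathway does.

Alignment (MUSCLE/PAL2NAL-style codon back-threading) is upstream of this
module: inputs are already codon-aligned, gapless, stop-free sequences.
"""
from __future__ import annotations

import math
from functools import lru_cache
from itertools import permutations

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .models import KaKsResult

BASES = "ACGT"
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)


class SequenceError(ValueError):
    """Raised for invalid codon sequences (length, alphabet, internal stops)."""


class SaturationError(ValueError):
    """Raised when a proportion of differences is beyond the JC69 domain."""


def _codons(seq: str) -> list[str]:
    seq = seq.upper()
    if len(seq) % 3:
        raise SequenceError("sequence length not divisible by 3")
    out = []
    for i in range(0, len(seq), 3):
        c = seq[i : i + 3]
        if any(b not in BASES for b in c):
            raise SequenceError(f"ambiguous or invalid codon {c!r}")
        if c in STOP_CODONS:
            raise SequenceError(f"internal stop codon {c!r} at codon {i // 3}")
        out.append(c)
    return out


def _syn_site_fraction(codon: str) -> float:
    """Synonymous-site content of one codon: sum over the 3 positions of the
    fraction of the 3 possible single-nucleotide changes that preserve the
    amino acid (stop-creating changes count as nonsynonymous)."""
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut not in STOP_CODONS and CODON_TABLE[mut] == aa:
                syn += 1
        s += syn / 3.0
    return s


_SITE_CACHE: dict[str, float] = {}


def codon_sites(codon: str) -> float:
    codon = codon.upper()
    if codon not in _SITE_CACHE:
        if codon in STOP_CODONS or any(b not in BASES for b in codon):
            raise SequenceError(f"invalid codon {codon!r}")
        _SITE_CACHE[codon] = _syn_site_fraction(codon)
    return _SITE_CACHE[codon]


def count_sites(seq: str) -> tuple[float, float]:
    """Synonymous (S) and nonsynonymous (N) site counts of one sequence.

    S + N = 3L exactly, L the codon count.
    """
    codons = _codons(seq)
    S = sum(codon_sites(c) for c in codons)
    return S, 3.0 * len(codons) - S


def _step_class(c_from: str, c_to: str) -> str:
    """'syn' or 'nonsyn' for one single-nucleotide codon change; entering a
    stop codon is nonsynonymous."""
    if c_to in STOP_CODONS or c_from in STOP_CODONS:
        return "nonsyn"
    return "syn" if CODON_TABLE[c_from] == CODON_TABLE[c_to] else "nonsyn"


@lru_cache(maxsize=None)
def count_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts.

    Enumerates every ordering of the single-nucleotide steps turning
    ``codon_a`` into ``codon_b``; pathways whose intermediate codons are stops
    are excluded (all pathways are used if every one hits a stop); each step is
    scored by the genetic code; the unweighted mean over admissible pathways is
    returned.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    admissible: list[tuple[int, int]] = []
    all_paths: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        cur = codon_a
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != codon_b:
                through_stop = True
            if _step_class(cur, nxt) == "syn":
                sd += 1
            else:
                nd += 1
            cur = nxt
        all_paths.append((sd, nd))
        if not through_stop:
            admissible.append((sd, nd))
    paths = admissible or all_paths
    n = len(paths)
    return sum(p[0] for p in paths) / n, sum(p[1] for p in paths) / n


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor correction d = -(3/4) ln(1 - 4p/3); domain 0 <= p < 3/4."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        raise SaturationError(f"p = {p:.4f} is saturated (>= 3/4)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def compute_kaks(seq_a: str, seq_b: str) -> KaKsResult:
    """NG86 Ka/Ks for one gapless codon-aligned pair.

    S and N are averaged over the two sequences; Sd/Nd are pathway-averaged
    sums over codon pairs; omega is None when dS is 0 or either proportion is
    saturated (``saturated`` flags the latter).
    """
    ca, cb = _codons(seq_a), _codons(seq_b)
    if len(ca) != len(cb):
        raise SequenceError("sequences differ in codon length")
    if not ca:
        raise SequenceError("zero-length alignment")
    Sa, _ = count_sites(seq_a)
    Sb, _ = count_sites(seq_b)
    L = len(ca)
    S = (Sa + Sb) / 2.0
    N = 3.0 * L - S
    Sd = Nd = 0.0
    for x, y in zip(ca, cb):
        sd, nd = count_differences(x, y)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = dN = None
    saturated = False
    try:
        dS = jukes_cantor(pS)
        dN = jukes_cantor(pN)
    except SaturationError:
        saturated = True
    omega = None
    if dS is not None and dN is not None and dS > 0:
        omega = dN / dS
    return KaKsResult(S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, dS=dS, dN=dN,
                      omega=omega, saturated=saturated)


def kaks_table(pairs: dict[str, tuple[str, str]]) -> pd.DataFrame:
    """Tabulate NG86 results for named codon-aligned pairs."""
    rows = []
    for pair_id, (a, b) in sorted(pairs.items()):
        r = compute_kaks(a, b)
        rows.append(
            {
                "pair_id": pair_id,
                "S": r.S,
                "N": r.N,
                "Sd": r.Sd,
                "Nd": r.Nd,
                "pS": r.pS,
                "pN": r.pN,
                "dS": r.dS,
                "dN": r.dN,
                "omega": r.omega,
                "saturated": r.saturated,
                "below_4": r.below_reporting_cutoff,
            }
        )
    return pd.DataFrame(rows)
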