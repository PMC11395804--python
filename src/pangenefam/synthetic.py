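"""Synthetic multi-genome pangenomes with full ground truth.

Emulates the study design the downstream stages need: ranked gene orders with
planted syntelog structure and occupancy classes, codon sequences diverged at
chosen Ka/Ks targets, domain architectures with planted truncations (typical
vs atypical family members), variants with known consequence labels, and
expression matrices with planted coexpression modules and fold-changes.

Every genome is a single chromosome of ranked genes; members of one syntelog
group occupy matching ranks apart from configurable local-shuffle noise, and
tandem copies sit adjacent to their template.  All randomness flows from one
master seed through named substreams, so identical configs give byte-identical
outputs and any single artifact can be regenerated in isolation.
"""
from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import io as pio
from .kaks import BASES, CODON_TABLE, STOP_CODONS, SequenceError
from .models import DomainHit, GeneModel, Variant
from .pangenome import classify_occupancy, dispensable_occupancies, softcore_occupancies

SUBFAMILIES = ("a", "b", "c", "e", "f", "g")
NONSTOP_CODONS = tuple(sorted(CODON_TABLE))
# codons per planted ancestral CDS, by occupancy class: core genes are built
# longest and private genes shortest, mirroring the pangenome-wide trend
CLASS_CODONS = {"core": 450, "softcore": 400, "dispensable": 350, "private": 250}
FAMILY_CODONS = 320
VARIANT_CLASSES = (
    "splice_acceptor",
    "splice_donor",
    "splice_region",
    "intron",
    "upstream",
    "downstream",
    "coding_sequence",
    "utr5",
    "utr3",
)


class ConfigurationError(ValueError):
    """Raised when a SimConfig requests an unrealizable design."""


@dataclass
class SimConfig:
    """Study-design parameters of one synthetic pangenome.

    ``class_mix`` gives the fraction of syntelog groups per occupancy class
    and must sum to 1; ``genes_per_genome`` is a per-genome target from which
    the SG count is derived.  ``n_samples`` is per condition.
    """

    n_genomes: int = 12
    genes_per_genome: int = 200
    class_mix: dict[str, float] = field(
        default_factory=lambda: {
            "core": 0.25, "softcore": 0.25, "dispensable": 0.25, "private": 0.25
        }
    )
    tandem_rate: float = 0.05
    rearrangement_rate: float = 0.0
    family_fraction: float = 0.15
    truncation_rate: float = 0.2
    omega_grid: tuple[float, ...] = (0.1, 0.3, 0.5, 1.0)
    branch_length: float = 0.3
    n_samples: int = 12
    n_modules: int = 1
    module_size: int = 8
    module_correlation: float = 0.8
    n_deg: int = 20
    deg_fold_change: float = 4.0
    variant_rates: dict[str, float] = field(
        default_factory=lambda: {c: 1.0 for c in VARIANT_CLASSES}
    )
    n_variants: int = 1000
    n_accessions: int = 8
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("class_mix must sum to 1")
        for name in ("tandem_rate", "rearrangement_rate", "family_fraction",
                     "truncation_rate", "module_correlation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.n_genomes < 1:
            raise ConfigurationError("n_genomes must be >= 1")
        for cls, frac in self.class_mix.items():
            if frac > 0 and not _occupancy_choices(cls, self.n_genomes):
                raise ConfigurationError(
                    f"class {cls!r} requested but no occupancy in [1, "
                    f"{self.n_genomes}] realizes it"
                )
        bad = set(self.variant_rates) - set(VARIANT_CLASSES)
        if bad:
            raise ConfigurationError(f"unknown variant classes {sorted(bad)}")


def _occupancy_choices(cls: str, n_genomes: int) -> list[int]:
    if cls == "core":
        return [n_genomes]
    if cls == "private":
        return [1] if classify_occupancy(1, n_genomes).value == "private" else []
    if cls == "softcore":
        return softcore_occupancies(n_genomes)
    if cls == "dispensable":
        return dispensable_occupancies(n_genomes)
    raise ConfigurationError(f"unknown class {cls!r}")


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named substream off the master seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


@dataclass
class GroundTruth:
    """Planted truth for every emitted artifact."""

    sg_membership: dict[str, str] = field(default_factory=dict)  # gene -> sg
    sg_class: dict[str, str] = field(default_factory=dict)
    typicality: dict[str, str] = field(default_factory=dict)  # family genes
    domains_present: dict[str, list[str]] = field(default_factory=dict)
    family_members: list[str] = field(default_factory=list)
    subfamily: dict[str, str] = field(default_factory=dict)  # gene -> label
    true_omega: dict[str, float] = field(default_factory=dict)  # sg -> omega
    planted_modules: list[list[str]] = field(default_factory=list)
    true_consequences: dict[str, list[str]] = field(default_factory=dict)
    true_deg: dict[str, str] = field(default_factory=dict)  # gene -> up/down

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SyntheticPangenome:
    """All artifacts of one simulated study, plus the ground truth."""

    config: SimConfig
    genomes: dict[str, list[GeneModel]]
    cds: dict[str, str]
    similarity: pd.DataFrame
    reference_proteins: dict[str, str]
    reference_labels: dict[str, str]
    truth: GroundTruth
    domain_hits: list[DomainHit] = field(default_factory=list)
    variants: list[Variant] = field(default_factory=list)
    genotypes: dict[str, list[int]] = field(default_factory=dict)
    accessions: list[str] = field(default_factory=list)
    counts: pd.DataFrame | None = None
    gene_lengths: pd.Series | None = None
    condition_labels: pd.Series | None = None

    @property
    def all_genes(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for genes in self.genomes.values() for g in genes}

    def proteins(self) -> dict[str, str]:
        return {gid: str(Seq(s).translate()) for gid, s in self.cds.items()}

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for genome_id, genes in sorted(self.genomes.items()):
            pio.write_gff3(genes, out / f"{genome_id}.gff3")
        pio.write_fasta(self.cds, out / "cds.fasta")
        pio.write_fasta(
            {f"{rid} subfamily={self.reference_labels[rid]}": s
             for rid, s in self.reference_proteins.items()},
            out / "reference_proteins.fasta",
        )
        pio.write_tsv(self.similarity, out / "similarity.tsv")
        pio.write_tsv(domain_hits_table(self.domain_hits), out / "domain_hits.tsv")
        if self.variants:
            pio.write_vcf(self.variants, self.genotypes, self.accessions,
                          out / "variants.vcf")
        if self.counts is not None:
            pio.write_tsv(self.counts, out / "counts.tsv", index=True)
            self.gene_lengths.rename("length").to_csv(out / "gene_lengths.tsv", sep="\t")
            self.condition_labels.rename("condition").to_csv(out / "conditions.tsv", sep="\t")
        self.truth.to_json(out / "ground_truth.json")


def domain_hits_table(hits: list[DomainHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene_id": h.gene_id, "domain_id": h.domain_id, "evalue": h.evalue,
             "start": h.start, "end": h.end}
            for h in hits
        ],
        columns=["gene_id", "domain_id", "evalue", "start", "end"],
    )


# ---------------------------------------------------------------------------
# Sequence evolution


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Uniformly random stop-free CDS of ``n_codons`` codons."""
    idx = rng.integers(0, len(NONSTOP_CODONS), size=n_codons)
    return "".join(NONSTOP_CODONS[i] for i in idx)


def simulate_codon_divergence(
    ancestral_cds: str,
    omega: float,
    branch_length: float,
    seed: int | np.random.Generator,
) -> str:
    """Derive a sequence by proposal-acceptance codon evolution.

    Substitutions are proposed uniformly over one-step nucleotide changes at a
    Poisson(branch_length * L) rate (L codons, so ``branch_length`` is the
    expected number of proposed substitutions per codon).  Synonymous
    proposals are always accepted, nonsynonymous ones with probability
    min(omega, 1); proposals creating a stop codon are rejected.  The realized
    dN/dS therefore matches ``omega`` in expectation for omega <= 1.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len(ancestral_cds) % 3:
        raise SequenceError("ancestral CDS length not divisible by 3")
    codons = [ancestral_cds[i : i + 3].upper() for i in range(0, len(ancestral_cds), 3)]
    for c in codons:
        if c in STOP_CODONS:
            raise SequenceError(f"internal stop codon {c!r} in ancestor")
        if any(b not in BASES for b in c):
            raise SequenceError(f"invalid codon {c!r} in ancestor")
    L = len(codons)
    n_prop = int(rng.poisson(branch_length * L)) if branch_length > 0 else 0
    accept_nonsyn = min(float(omega), 1.0)
    for _ in range(n_prop):
        ci = int(rng.integers(L))
        pos = int(rng.integers(3))
        cur = codons[ci]
        alt = BASES[int(rng.integers(4))]
        # draw until the proposal actually changes the base (uniform over 3)
        while alt == cur[pos]:
            alt = BASES[int(rng.integers(4))]
        mut = cur[:pos] + alt + cur[pos + 1 :]
        if mut in STOP_CODONS:
            continue
        if CODON_TABLE[mut] == CODON_TABLE[cur]:
            codons[ci] = mut
        elif rng.random() < accept_nonsyn:
            codons[ci] = mut
    return "".join(codons)


# ---------------------------------------------------------------------------
# Pangenome generation


def _largest_remainder_counts(fracs: dict[str, float], total: int) -> dict[str, int]:
    raw = {c: fracs[c] * total for c in sorted(fracs)}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    # each positive-fraction class is realized at least once
    for c in counts:
        if fracs[c] > 0 and counts[c] == 0:
            counts[c] = 1
    remainder = total - sum(counts.values())
    order = sorted(raw, key=lambda c: (-(raw[c] - np.floor(raw[c])), c))
    i = 0
    while remainder != 0 and order:
        c = order[i % len(order)]
        if remainder > 0:
            counts[c] += 1
            remainder -= 1
        elif counts[c] > (1 if fracs[c] > 0 else 0):
            counts[c] -= 1
            remainder += 1
        i += 1
    return counts


def _gene_structure(
    rng: np.random.Generator, cds_len: int, strand: str, start: int
) -> tuple[GeneModel, int]:
    """Lay out one gene from ``start``; returns the model (rank unset) and the
    first base after the gene."""
    n_exons = 1 + min(int(rng.poisson(2.0)), 6)
    n_exons = min(n_exons, max(1, cds_len // 60))
    bounds = np.linspace(0, cds_len, n_exons + 1).round().astype(int)
    for i in range(1, n_exons):
        jitter = int(rng.integers(-10, 11))
        bounds[i] = int(np.clip(bounds[i] + jitter, bounds[i - 1] + 20, cds_len - 20 * (n_exons - i)))
    pieces = [int(bounds[i + 1] - bounds[i]) for i in range(n_exons)]
    utr5_len = int(rng.integers(100, 301))
    utr3_len = int(rng.integers(100, 301))
    introns = [int(rng.integers(100, 501)) for _ in range(n_exons - 1)]
    # transcript-order exon composition: (utr5 part, cds part, utr3 part)
    tx_exons = []
    for i, p in enumerate(pieces):
        u5 = utr5_len if i == 0 else 0
        u3 = utr3_len if i == n_exons - 1 else 0
        tx_exons.append((u5, p, u3))
    if strand == "-":
        tx_exons = tx_exons[::-1]
        tx_exons = [(u3, p, u5) for (u5, p, u3) in tx_exons]
        # after reversal the genomic-left part of exon 0 is the 3' UTR
        left_is_utr3 = True
    else:
        left_is_utr3 = False
    exons, cds, utr5, utr3 = [], [], [], []
    cursor = start
    for i, (left, p, right) in enumerate(tx_exons):
        ex_start = cursor
        if left:
            iv = (cursor, cursor + left)
            (utr3 if left_is_utr3 else utr5).append(iv)
            cursor += left
        cds.append((cursor, cursor + p))
        cursor += p
        if right:
            iv = (cursor, cursor + right)
            (utr5 if left_is_utr3 else utr3).append(iv)
            cursor += right
        exons.append((ex_start, cursor))
        if i < len(tx_exons) - 1:
            cursor += introns[i]
    gene = GeneModel(
        gene_id="", genome_id="", chrom="chr1", start=start, end=cursor,
        strand=strand, rank=-1, exons=exons, cds=cds, utr5=utr5, utr3=utr3,
    )
    return gene, cursor


def generate_pangenome(config: SimConfig) -> SyntheticPangenome:
    """Plant syntelog groups, derive member sequences, lay out gene models,
    and emit the cross-genome similarity table."""
    config.validate()
    seed = config.seed
    n = config.n_genomes
    genome_ids = [f"g{i:02d}" for i in range(n)]

    # how many SGs realize the per-genome gene target under the mix
    mean_occ = {
        cls: float(np.mean(_occupancy_choices(cls, n)))
        for cls, frac in config.class_mix.items()
        if frac > 0
    }
    e_occ = sum(config.class_mix[c] * mean_occ[c] for c in mean_occ)
    n_sg = max(len(mean_occ), round(config.genes_per_genome * n / e_occ))
    counts = _largest_remainder_counts(
        {c: f for c, f in config.class_mix.items() if f > 0}, n_sg
    )

    rng_plan = _rng(seed, "plan")
    sg_classes: list[str] = []
    for cls in sorted(counts):
        sg_classes.extend([cls] * counts[cls])
    rng_plan.shuffle(sg_classes)

    truth = GroundTruth()
    sg_occupancy: list[list[str]] = []
    for i, cls in enumerate(sg_classes):
        occ = int(rng_plan.choice(_occupancy_choices(cls, n)))
        members = sorted(rng_plan.choice(n, size=occ, replace=False).tolist())
        sg_occupancy.append([genome_ids[m] for m in members])
        truth.sg_class[f"SG{i:05d}"] = cls

    # family SGs and per-SG omega
    n_family = max(1, round(config.family_fraction * n_sg)) if config.family_fraction > 0 else 0
    family_idx = sorted(
        rng_plan.choice(n_sg, size=n_family, replace=False).tolist()
    ) if n_family else []
    family_set = set(family_idx)
    for i in range(n_sg):
        truth.true_omega[f"SG{i:05d}"] = float(
            config.omega_grid[i % len(config.omega_grid)]
        )

    # ancestors
    rng_seq = _rng(seed, "ancestors")
    subfam_refs = {
        f"ref_{sf}": random_cds(rng_seq, FAMILY_CODONS) for sf in SUBFAMILIES
    }
    reference_proteins = {
        rid: str(Seq(s).translate()) for rid, s in subfam_refs.items()
    }
    reference_labels = {f"ref_{sf}": sf for sf in SUBFAMILIES}
    ancestors: list[str] = []
    sg_subfam: dict[int, str] = {}
    for i, cls in enumerate(sg_classes):
        if i in family_set:
            sf = SUBFAMILIES[family_idx.index(i) % len(SUBFAMILIES)]
            sg_subfam[i] = sf
            anc = simulate_codon_divergence(
                subfam_refs[f"ref_{sf}"], omega=0.5, branch_length=0.1,
                seed=_rng(seed, f"fam-anc-{i}"),
            )
        else:
            n_codons = CLASS_CODONS[cls] + int(rng_seq.integers(-30, 31))
            anc = random_cds(rng_seq, n_codons)
        ancestors.append(anc)

    # member genes
    cds: dict[str, str] = {}
    genome_orders: dict[str, list[str]] = {g: [] for g in genome_ids}
    rng_tandem = _rng(seed, "tandem")
    rng_trunc = _rng(seed, "truncation")
    for i in range(n_sg):
        sg_id = f"SG{i:05d}"
        omega = truth.true_omega[sg_id]
        sg_members: list[tuple[str, str]] = []
        for genome in sg_occupancy[i]:
            gid = f"{genome}.{i:05d}"
            seq = simulate_codon_divergence(
                ancestors[i], omega=omega, branch_length=config.branch_length,
                seed=_rng(seed, f"seq-{gid}"),
            )
            sg_members.append((gid, seq))
            if rng_tandem.random() < config.tandem_rate:
                tid = f"{gid}.t1"
                tseq = simulate_codon_divergence(
                    seq, omega=omega, branch_length=0.05,
                    seed=_rng(seed, f"seq-{tid}"),
                )
                sg_members.append((tid, tseq))
        truncations: dict[str, str | None] = {}
        if i in family_set:
            for mid, _ in sg_members:
                if rng_trunc.random() < config.truncation_rate:
                    truncations[mid] = ["5prime", "3prime", "both"][
                        int(rng_trunc.integers(3))
                    ]
                else:
                    truncations[mid] = None
            # a family SG is always anchored by >= 1 domain-complete member,
            # otherwise no seed could exist and propagation could never find it
            if all(v is not None for v in truncations.values()):
                truncations[sg_members[0][0]] = None
        for mid, mseq in sg_members:
            domains = ["NTD", "CTD"]
            if i in family_set:
                mode = truncations[mid]
                if mode is not None:
                    ncod = len(mseq) // 3
                    cut = max(1, ncod // 3)
                    if mode in ("5prime", "both"):
                        mseq = mseq[3 * cut :]
                        domains.remove("NTD")
                    if mode in ("3prime", "both"):
                        mseq = mseq[: len(mseq) - 3 * cut]
                        domains.remove("CTD")
                    truth.typicality[mid] = "atypical"
                else:
                    truth.typicality[mid] = "typical"
                truth.domains_present[mid] = domains
                truth.family_members.append(mid)
                truth.subfamily[mid] = sg_subfam[i]
            cds[mid] = mseq
            truth.sg_membership[mid] = sg_id
            genome_orders[mid.split(".")[0]].append(mid)

    # rank shuffle noise: local swaps of adjacent entries
    rng_shuffle = _rng(seed, "shuffle")
    for genome in genome_ids:
        order = genome_orders[genome]
        n_swaps = round(config.rearrangement_rate * len(order))
        for _ in range(n_swaps):
            if len(order) < 2:
                break
            j = int(rng_shuffle.integers(len(order) - 1))
            order[j], order[j + 1] = order[j + 1], order[j]

    # genomic layout
    genomes: dict[str, list[GeneModel]] = {}
    for genome in genome_ids:
        rng_layout = _rng(seed, f"layout-{genome}")
        cursor = 1000
        models = []
        for rank, gid in enumerate(genome_orders[genome]):
            strand = "+" if rng_layout.random() < 0.5 else "-"
            gene, end = _gene_structure(rng_layout, len(cds[gid]), strand, cursor)
            gene.gene_id = gid
            gene.genome_id = genome
            gene.rank = rank
            models.append(gene)
            cursor = end + int(rng_layout.integers(1500, 3001))
        genomes[genome] = models

    # similarity table: true same-SG cross-genome pairs + background noise
    rng_sim = _rng(seed, "similarity")
    sim_rows = []
    by_sg: dict[str, list[str]] = {}
    for gid, sg in truth.sg_membership.items():
        by_sg.setdefault(sg, []).append(gid)
    all_gene_ids = sorted(cds)
    genome_of = {gid: gid.split(".")[0] for gid in all_gene_ids}
    for sg in sorted(by_sg):
        members = sorted(by_sg[sg])
        primary = [m for m in members if not m.endswith(".t1")]
        # within-genome tandem pairs (an aligner would report these too)
        for m in primary:
            t = f"{m}.t1"
            if t in cds:
                sim_rows.append((m, t, float(rng_sim.uniform(95, 100))))
        for a_i in range(len(primary)):
            for b_i in range(a_i + 1, len(primary)):
                ga, gb = primary[a_i], primary[b_i]
                if genome_of[ga] == genome_of[gb]:
                    continue
                base = float(rng_sim.uniform(90, 100))
                sim_rows.append((ga, gb, base))
                # tandem copies score slightly below their template
                for t in (f"{ga}.t1", f"{gb}.t1"):
                    if t in cds:
                        other = gb if t.startswith(ga) else ga
                        sim_rows.append(
                            (t, other, base * float(rng_sim.uniform(0.92, 0.99)))
                        )
    n_noise = len(all_gene_ids) // 10
    for _ in range(n_noise):
        ga, gb = rng_sim.choice(all_gene_ids, size=2, replace=False)
        if genome_of[ga] == genome_of[gb] or truth.sg_membership[ga] == truth.sg_membership[gb]:
            continue
        sim_rows.append((ga, gb, float(rng_sim.uniform(30, 60))))
    similarity = pd.DataFrame(sim_rows, columns=["gene_a", "gene_b", "score"])

    return SyntheticPangenome(
        config=config,
        genomes=genomes,
        cds=cds,
        similarity=similarity,
        reference_proteins=reference_proteins,
        reference_labels=reference_labels,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Domain hits


def generate_domain_hits(sim: SyntheticPangenome) -> list[DomainHit]:
    """Emit NTD/CTD hits for family members per their (possibly truncated)
    domain complement; non-members get no hits.  E-values are <= 1e-6."""
    rng = _rng(sim.config.seed, "domains")
    hits: list[DomainHit] = []
    for gid in sim.truth.family_members:
        plen = len(sim.cds[gid]) // 3
        for dom in sim.truth.domains_present.get(gid, []):
            ev = float(10.0 ** rng.uniform(-12, -6))
            if dom == "NTD":
                start, end = 5, min(plen, 105)
            else:
                start, end = max(1, plen - 105), max(2, plen - 5)
            hits.append(DomainHit(gene_id=gid, domain_id=dom, evalue=ev,
                                  start=start, end=end))
    sim.domain_hits = hits
    return hits


# ---------------------------------------------------------------------------
# Variants


def _variant_regions(gene: GeneModel, window: int = 5000) -> dict[str, list[int]]:
    """Genomic positions per consequence class for one gene, with the fixed
    precedence already applied (each position appears under one class)."""
    fwd = gene.strand == "+"
    donor, acceptor, sr, intron_rest = set(), set(), set(), set()
    for istart, iend in gene.introns:
        positions = list(range(istart, iend))
        five = positions if fwd else positions[::-1]
        donor.update(five[:2])
        acceptor.update(five[-2:])
        sr.update(five[2:8])  # intronic offsets 3..8 from the 5' end
        sr.update(five[-8:-2])  # and from the 3' end
        intron_rest.update(positions)
    sr -= donor | acceptor
    intron_rest -= donor | acceptor | sr
    sr_exonic = set()
    for istart, iend in gene.introns:
        sr_exonic.update(range(istart - 3, istart))
        sr_exonic.update(range(iend, iend + 3))
    exonic = set()
    for s, e in gene.exons:
        exonic.update(range(s, e))
    sr_exonic &= exonic
    cds_set = set()
    for s, e in gene.cds:
        cds_set.update(range(s, e))
    u5, u3 = set(), set()
    for s, e in gene.utr5:
        u5.update(range(s, e))
    for s, e in gene.utr3:
        u3.update(range(s, e))
    left = set(range(max(0, gene.start - window), gene.start))
    right = set(range(gene.end, gene.end + window))
    up, down = (left, right) if fwd else (right, left)
    regions = {
        "splice_acceptor": acceptor,
        "splice_donor": donor,
        "splice_region": sr | sr_exonic,
        "intron": intron_rest,
        "coding_sequence": cds_set - sr_exonic,
        "utr5": u5 - sr_exonic,
        "utr3": u3 - sr_exonic,
        "upstream": up,
        "downstream": down,
    }
    return {c: sorted(p) for c, p in regions.items()}


def generate_variants(
    sim: SyntheticPangenome,
    genome_id: str | None = None,
    window: int = 5000,
) -> tuple[list[Variant], dict[str, list[int]], list[str]]:
    """Sample SNVs over one genome's gene regions with known class labels.

    Classes are drawn in proportion to ``config.variant_rates``; positions are
    uniform within the sampled gene's positions of that class.  Truth records
    the focal gene and class per variant.
    """
    config = sim.config
    genome_id = genome_id or sorted(sim.genomes)[0]
    genes = sim.genomes[genome_id]
    rng = _rng(config.seed, "variants")
    rates = np.array([config.variant_rates.get(c, 0.0) for c in VARIANT_CLASSES])
    variants: list[Variant] = []
    genotypes: dict[str, list[int]] = {}
    accessions = [f"acc{i:03d}" for i in range(config.n_accessions)]
    if rates.sum() <= 0 or config.n_variants == 0:
        sim.variants, sim.genotypes, sim.accessions = [], {}, accessions
        return [], {}, accessions
    probs = rates / rates.sum()
    regions = {g.gene_id: _variant_regions(g, window) for g in genes}
    gene_ids = [g.gene_id for g in genes]
    for i in range(config.n_variants):
        cls = VARIANT_CLASSES[int(rng.choice(len(VARIANT_CLASSES), p=probs))]
        # uniform gene among those having positions of this class
        candidates = [g for g in gene_ids if regions[g][cls]]
        if not candidates:
            continue
        gid = candidates[int(rng.integers(len(candidates)))]
        pos0 = regions[gid][cls][int(rng.integers(len(regions[gid][cls])))]
        ref = BASES[int(rng.integers(4))]
        alt = BASES[int(rng.integers(4))]
        while alt == ref:
            alt = BASES[int(rng.integers(4))]
        vid = f"v{i:05d}"
        variants.append(Variant(chrom="chr1", pos=pos0 + 1, ref=ref, alt=alt,
                                variant_id=vid))
        carriers = (rng.random(config.n_accessions) < 0.3).astype(int).tolist()
        if not any(carriers):
            carriers[int(rng.integers(config.n_accessions))] = 1
        genotypes[vid] = carriers
        sim.truth.true_consequences[vid] = [gid, cls]
    sim.variants, sim.genotypes, sim.accessions = variants, genotypes, accessions
    return variants, genotypes, accessions


# ---------------------------------------------------------------------------
# Expression


def generate_expression(
    sim: SyntheticPangenome,
    genome_id: str | None = None,
    dispersion: float = 0.05,
    biological_cv: float = 1.0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Negative-binomial counts with planted modules and fold-changes.

    Within-module genes share a latent log-normal factor giving pairwise
    log-scale correlation ``module_correlation``; DEG genes get the
    multiplicative ``deg_fold_change`` between conditions (half up, half
    down); counts are NB around the expected means.
    """
    config = sim.config
    genome_id = genome_id or sorted(sim.genomes)[0]
    gene_ids = [g.gene_id for g in sim.genomes[genome_id]]
    rng = _rng(config.seed, "expression")
    n_genes = len(gene_ids)
    n_total = 2 * config.n_samples
    samples = [f"s{i:02d}" for i in range(n_total)]
    conditions = ["cond_a"] * config.n_samples + ["cond_b"] * config.n_samples

    needed = config.n_modules * config.module_size
    if needed > n_genes:
        raise ConfigurationError("module sizes exceed gene count")
    picked = rng.choice(n_genes, size=needed, replace=False)
    modules = [
        sorted(gene_ids[j] for j in picked[k * config.module_size : (k + 1) * config.module_size])
        for k in range(config.n_modules)
    ]
    sim.truth.planted_modules = modules
    module_of = {g: k for k, mod in enumerate(modules) for g in mod}

    in_module = set(module_of)
    free = [g for g in gene_ids if g not in in_module]
    n_deg = min(config.n_deg, len(free))
    deg_pick = sorted(rng.choice(len(free), size=n_deg, replace=False).tolist())
    deg_genes = [free[j] for j in deg_pick]
    for j, g in enumerate(deg_genes):
        sim.truth.true_deg[g] = "up" if j % 2 == 0 else "down"
    for g in gene_ids:
        sim.truth.true_deg.setdefault(g, "none")

    rho = config.module_correlation
    base = rng.normal(np.log(300.0), 0.7, size=n_genes)
    factors = rng.normal(0.0, 1.0, size=(config.n_modules, n_total))
    noise = rng.normal(0.0, 1.0, size=(n_genes, n_total))
    log_fc = np.log(config.deg_fold_change)
    mu = np.empty((n_genes, n_total))
    for gi, g in enumerate(gene_ids):
        z = noise[gi]
        if g in module_of:
            z = np.sqrt(rho) * factors[module_of[g]] + np.sqrt(1 - rho) * z
        lm = base[gi] + biological_cv * z
        shift = {"up": log_fc, "down": -log_fc, "none": 0.0}[sim.truth.true_deg[g]]
        lm = lm + shift * (np.array(conditions) == "cond_b")
        mu[gi] = np.exp(lm)
    if dispersion > 0:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples)
    counts_df.index.name = "gene_id"
    genes = {g.gene_id: g for g in sim.genomes[genome_id]}
    lengths = pd.Series({g: max(genes[g].cds_length, 1) for g in gene_ids}, name="length")
    labels = pd.Series(conditions, index=samples, name="condition")
    sim.counts, sim.gene_lengths, sim.condition_labels = counts_df, lengths, labels
    return counts_df, lengths, labels


def generate_all(config: SimConfig) -> SyntheticPangenome:
    """Full study: pangenome + domain hits + variants + expression."""
    sim = generate_pangenome(config)
    generate_domain_hits(sim)
    generate_variants(sim)
    generate_expression(sim)
    return sim
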