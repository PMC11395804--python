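"""End-to-end orchestration: simulate -> pangenome -> family -> kaks /
consequence / coexpression, with a provenance manifest.

Each stage reads the files the previous one wrote (the formats are the
package's external interface), so any stage can be replaced by externally
produced inputs.  The manifest records parameters, per-stage wall-clock and
sha256 checksums of every output; deterministic stages reproduce identical
checksums under the same config.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import consequence as vc
from . import coexpression as cx
from . import family as fam
from . import io as pio
from . import kaks as kk
from . import pangenome as pg
from .synthetic import SimConfig, generate_all

ALL_STAGES = ("simulate", "pangenome", "family", "kaks", "consequence", "coexpression")


@dataclass
class RunConfig:
    """One configuration for the whole pipeline."""

    out_dir: str = "pangenefam_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    sim: dict = field(default_factory=dict)
    # stage parameters (defaults mirror the analysis thresholds)
    e_threshold: float = 1e-5
    near_best: float = 0.9
    max_gap: int = 10
    min_block: int = 5
    max_intervening: int = 1
    window: int = 5000
    decay: float = 5.0
    penalty: float = 2.0
    min_module_size: int = 3
    overlap_threshold: float = 0.8
    module_p: float = 0.1
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    curve_orderings: int = 50
    max_kaks_pairs: int = 500

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if self.e_threshold <= 0:
            raise ValueError("e_threshold must be > 0")
        if self.min_block < 1 or self.max_gap < 1:
            raise ValueError("chaining parameters out of domain")


@dataclass
class RunManifest:
    config: dict
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: list[Path], elapsed: float) -> None:
        self.stages[stage] = {
            "status": "completed",
            "wall_clock_s": round(elapsed, 3),
            "outputs": {
                p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in outputs
            },
        }

    def skip(self, stage: str) -> None:
        self.stages[stage] = {"status": "skipped"}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "stages": self.stages}, indent=1, sort_keys=True
        ))


class DependencyError(RuntimeError):
    """An enabled stage is missing an upstream output."""


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DependencyError(f"stage {stage!r}: missing upstream input {path}")
    return path


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in dependency order."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_dir = out / "sim"
    manifest = RunManifest(config=dataclasses.asdict(config))

    sim_cfg = SimConfig(**{"seed": config.seed, **config.sim})

    if "simulate" in config.stages:
        t0 = time.perf_counter()
        sim = generate_all(sim_cfg)
        sim.write(sim_dir)
        manifest.record("simulate", sorted(sim_dir.iterdir()), time.perf_counter() - t0)
    else:
        manifest.skip("simulate")

    genes = {}
    sgs = None
    if "pangenome" in config.stages:
        t0 = time.perf_counter()
        gff_files = sorted(_require(sim_dir, "pangenome").glob("*.gff3"))
        if not gff_files:
            raise DependencyError("pangenome: no GFF3 inputs found")
        for f in gff_files:
            for g in pio.read_gff3(f, genome_id=f.stem):
                genes[g.gene_id] = g
        similarity = pio.read_tsv(_require(sim_dir / "similarity.tsv", "pangenome"))
        sgs = pg.build_pangenome(
            similarity, genes, near_best=config.near_best, max_gap=config.max_gap,
            min_block=config.min_block, max_intervening=config.max_intervening,
        )
        genomes = sorted({g.genome_id for g in genes.values()})
        pio.write_tsv(pg.sg_table(sgs), out / "sg_table.tsv")
        matrix = pg.pangenome_matrix(sgs, genomes)
        pio.write_tsv(matrix, out / "pav_matrix.tsv", index=True)
        curves = pg.accumulation_curves(matrix, config.curve_orderings, config.seed)
        pio.write_tsv(curves, out / "accumulation_curves.tsv")
        pio.write_tsv(pg.summarize_gene_features(sgs, genes), out / "gene_features.tsv")
        manifest.record(
            "pangenome",
            [out / n for n in ("sg_table.tsv", "pav_matrix.tsv",
                               "accumulation_curves.tsv", "gene_features.tsv")],
            time.perf_counter() - t0,
        )
    else:
        manifest.skip("pangenome")

    calls = None
    if "family" in config.stages:
        if sgs is None:
            raise DependencyError("family: pangenome stage outputs required")
        t0 = time.perf_counter()
        hits_df = pio.read_tsv(_require(sim_dir / "domain_hits.tsv", "family"))
        hits = [
            fam.DomainHit(r.gene_id, r.domain_id, r.evalue, r.start, r.end)
            for r in hits_df.itertuples(index=False)
        ]
        seeds = fam.call_family_by_domain(hits, config.e_threshold)
        calls = fam.propagate_membership(seeds, sgs)
        fam.classify_typicality(calls, hits, config.e_threshold)
        genomes = sorted({g.genome_id for g in genes.values()})
        pav, private = fam.build_pav(calls, sgs, genomes)
        pio.write_tsv(fam.calls_table(calls), out / "family_calls.tsv")
        pio.write_tsv(pav, out / "family_pav.tsv", index=True)
        private.rename("private_count").to_csv(out / "family_private_counts.tsv", sep="\t")
        lengths = fam.compare_lengths(calls, genes)
        (out / "family_length_comparison.json").write_text(json.dumps(lengths, indent=1))
        manifest.record(
            "family",
            [out / n for n in ("family_calls.tsv", "family_pav.tsv",
                               "family_private_counts.tsv",
                               "family_length_comparison.json")],
            time.perf_counter() - t0,
        )
    else:
        manifest.skip("family")

    if "kaks" in config.stages:
        if sgs is None:
            raise DependencyError("kaks: pangenome stage outputs required")
        t0 = time.perf_counter()
        cds = pio.read_fasta(_require(sim_dir / "cds.fasta", "kaks"))
        pairs: dict[str, tuple[str, str]] = {}
        for sg in sgs:
            ids = [g for g in sorted(sg.gene_ids) if g in cds]
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    a, b = ids[i], ids[j]
                    if len(cds[a]) == len(cds[b]) and len(cds[a]) > 0:
                        pairs[f"{sg.sg_id}:{a}|{b}"] = (cds[a], cds[b])
                        break
                else:
                    continue
                break
        if len(pairs) > config.max_kaks_pairs:
            keep = sorted(pairs)[: config.max_kaks_pairs]
            pairs = {k: pairs[k] for k in keep}
        table = kk.kaks_table(pairs)
        pio.write_tsv(table, out / "kaks.tsv")
        manifest.record("kaks", [out / "kaks.tsv"], time.perf_counter() - t0)
    else:
        manifest.skip("kaks")

    if "consequence" in config.stages:
        t0 = time.perf_counter()
        vcf = _require(sim_dir / "variants.vcf", "consequence")
        variants, genotypes, accessions = pio.read_vcf(vcf)
        genome0 = sorted(f.stem for f in sim_dir.glob("*.gff3"))[0]
        gmodels = pio.read_gff3(sim_dir / f"{genome0}.gff3", genome_id=genome0)
        calls_df = vc.annotate_all(variants, gmodels, window=config.window)
        load, profile = vc.summarize_load(calls_df, genotypes, accessions)
        pio.write_tsv(calls_df, out / "consequence_calls.tsv")
        pio.write_tsv(load, out / "variant_load.tsv")
        pio.write_tsv(profile.reset_index(), out / "variant_profile.tsv")
        manifest.record(
            "consequence",
            [out / n for n in ("consequence_calls.tsv", "variant_load.tsv",
                               "variant_profile.tsv")],
            time.perf_counter() - t0,
        )
    else:
        manifest.skip("consequence")

    if "coexpression" in config.stages:
        t0 = time.perf_counter()
        counts = pio.read_tsv(_require(sim_dir / "counts.tsv", "coexpression"),
                              index_col=0)
        lengths = pio.read_tsv(sim_dir / "gene_lengths.tsv", index_col=0)["length"]
        labels = pio.read_tsv(sim_dir / "conditions.tsv", index_col=0)["condition"]
        fpkm = cx.compute_fpkm(counts, lengths)
        pio.write_tsv(fpkm, out / "fpkm.tsv", index=True)
        de = cx.differential_expression(counts, labels, config.lfc_threshold,
                                        config.fdr_threshold)
        pio.write_tsv(de.reset_index(), out / "de_table.tsv")
        pcc, mr = cx.mutual_rank(fpkm)
        pio.write_tsv(cx.edge_table(pcc, mr), out / "edges.tsv")
        graph = cx.build_network(pcc, mr, x=config.decay)
        import networkx as nx

        nx.write_graphml(graph, out / "network.graphml")
        modules = cx.find_modules(
            graph, penalty=config.penalty, min_size=config.min_module_size,
            overlap_threshold=config.overlap_threshold, p_cutoff=config.module_p,
            seed=config.seed,
        )
        pio.write_tsv(cx.modules_table(modules), out / "modules.tsv")
        manifest.record(
            "coexpression",
            [out / n for n in ("fpkm.tsv", "de_table.tsv", "edges.tsv", "modules.tsv")],
            time.perf_counter() - t0,
        )
    else:
        manifest.skip("coexpression")

    manifest.to_json(out / "manifest.json")
    return manifest
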