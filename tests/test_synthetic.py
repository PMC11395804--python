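"""Generator contracts: determinism, ground-truth completeness, planted
structure, codon evolution, variant and expression sampling."""
from __future__ import annotations

import collections
import filecmp

import numpy as np
import pytest
from Bio.Seq import Seq
from scipy import stats

from pangenefam.synthetic import (
    VARIANT_CLASSES,
    ConfigurationError,
    SimConfig,
    generate_all,
    generate_expression,
    generate_pangenome,
    random_cds,
    simulate_codon_divergence,
)


# --- configuration validation ----------------------------------------------


def test_class_mix_must_sum_to_one():
    cfg = SimConfig(class_mix={"core": 0.5, "softcore": 0.0,
                               "dispensable": 0.0, "private": 0.4})
    with pytest.raises(ConfigurationError):
        cfg.validate()


def test_infeasible_softcore_is_a_configuration_error():
    # strict 'over 90% but not all' admits no occupancy for 10 genomes
    cfg = SimConfig(n_genomes=10)
    with pytest.raises(ConfigurationError):
        cfg.validate()
    SimConfig(n_genomes=12).validate()  # 11/12 > 0.9: feasible


def test_rates_must_be_probabilities():
    with pytest.raises(ConfigurationError):
        SimConfig(n_genomes=12, tandem_rate=1.5).validate()


# --- determinism and conservation ------------------------------------------


def test_identical_seed_gives_byte_identical_outputs(tmp_path):
    cfg = SimConfig(n_genomes=4, genes_per_genome=40,
                    class_mix={"core": 0.6, "softcore": 0.0,
                               "dispensable": 0.2, "private": 0.2},
                    n_variants=50, seed=9)
    for d in ("run1", "run2"):
        generate_all(SimConfig(**{**cfg.__dict__})).write(tmp_path / d)
    files = sorted(p.name for p in (tmp_path / "run1").iterdir())
    match, mismatch, errors = filecmp.cmpfiles(
        tmp_path / "run1", tmp_path / "run2", files, shallow=False
    )
    assert mismatch == [] and errors == []
    assert set(match) == set(files)


def test_all_core_pangenome_has_full_occupancy():
    cfg = SimConfig(n_genomes=4, genes_per_genome=30,
                    class_mix={"core": 1.0, "softcore": 0.0,
                               "dispensable": 0.0, "private": 0.0},
                    tandem_rate=0.0, seed=1)
    sim = generate_pangenome(cfg)
    occ = collections.Counter(sim.truth.sg_membership.values())
    assert all(v == 4 for v in occ.values())


def test_realized_class_fractions_match_request(softcore_sim):
    classes = collections.Counter(softcore_sim.truth.sg_class.values())
    total = sum(classes.values())
    for cls, frac in softcore_sim.config.class_mix.items():
        assert abs(classes[cls] / total - frac) <= 0.05, cls


def test_gene_conservation_and_truth_completeness(small_sim):
    emitted = set(small_sim.cds)
    assert emitted == set(small_sim.truth.sg_membership)
    per_genome = sum(len(g) for g in small_sim.genomes.values())
    assert per_genome == len(emitted)
    # every planted class realized
    realized = set(small_sim.truth.sg_class.values())
    assert realized == {c for c, f in small_sim.config.class_mix.items() if f > 0}
    # ranks unique within each genome
    for genes in small_sim.genomes.values():
        ranks = [g.rank for g in genes]
        assert len(ranks) == len(set(ranks))


def test_tandem_copies_share_group_and_sit_adjacent(small_sim):
    genes = small_sim.all_genes
    tandems = [g for g in genes if g.endswith(".t1")]
    assert tandems, "fixture should contain tandem copies"
    for t in tandems:
        template = t[:-3]
        assert small_sim.truth.sg_membership[t] == small_sim.truth.sg_membership[template]
        assert abs(genes[t].rank - genes[template].rank) == 1


# --- codon divergence -------------------------------------------------------


def test_zero_branch_length_is_identity():
    anc = random_cds(np.random.default_rng(0), 100)
    assert simulate_codon_divergence(anc, 0.5, 0.0, seed=1) == anc


def test_omega_zero_changes_only_synonymous_sites():
    anc = random_cds(np.random.default_rng(1), 300)
    der = simulate_codon_divergence(anc, 0.0, 1.0, seed=2)
    assert der != anc
    assert str(Seq(anc).translate()) == str(Seq(der).translate())


def test_internal_stop_in_ancestor_rejected():
    with pytest.raises(Exception):
        simulate_codon_divergence("ATGTAA", 0.5, 0.1, seed=0)


def test_no_stops_ever_introduced():
    rng = np.random.default_rng(3)
    anc = random_cds(rng, 200)
    der = simulate_codon_divergence(anc, 1.0, 2.0, seed=4)
    aas = str(Seq(der).translate())
    assert "*" not in aas


# --- domain hits ------------------------------------------------------------


def test_truncation_rate_zero_gives_no_atypical_members():
    cfg = SimConfig(n_genomes=4, genes_per_genome=40,
                    class_mix={"core": 0.7, "softcore": 0.0,
                               "dispensable": 0.0, "private": 0.3},
                    truncation_rate=0.0, seed=3)
    sim = generate_all(cfg)
    assert set(sim.truth.typicality.values()) == {"typical"}


def test_atypical_members_carry_at_most_one_domain(small_sim):
    by_gene = collections.defaultdict(set)
    for h in small_sim.domain_hits:
        assert h.evalue <= 1e-6
        by_gene[h.gene_id].add(h.domain_id)
    for gid, typ in small_sim.truth.typicality.items():
        if typ == "atypical":
            assert len(by_gene.get(gid, set())) <= 1
        else:
            assert by_gene[gid] == {"NTD", "CTD"}
    # non-members carry no hits
    assert set(by_gene) <= set(small_sim.truth.family_members)


def test_five_prime_truncation_removes_n_terminal_domain(small_sim):
    truth = small_sim.truth
    atypical = [g for g, t in truth.typicality.items() if t == "atypical"]
    one_domain = [g for g in atypical if len(truth.domains_present[g]) == 1]
    assert one_domain
    for g in one_domain:
        (kept,) = truth.domains_present[g]
        assert kept in {"NTD", "CTD"}


# --- variants ---------------------------------------------------------------


def test_zero_variant_rates_give_empty_vcf_body():
    cfg = SimConfig(n_genomes=4, genes_per_genome=30,
                    class_mix={"core": 1.0, "softcore": 0.0,
                               "dispensable": 0.0, "private": 0.0},
                    variant_rates={c: 0.0 for c in VARIANT_CLASSES}, seed=5)
    sim = generate_all(cfg)
    assert sim.variants == []


def test_variant_class_histogram_matches_rates(small_sim):
    counts = collections.Counter(
        cls for _, cls in small_sim.truth.true_consequences.values()
    )
    n = sum(counts.values())
    expected = np.full(len(VARIANT_CLASSES), n / len(VARIANT_CLASSES))
    observed = np.array([counts.get(c, 0) for c in VARIANT_CLASSES])
    chi2, p = stats.chisquare(observed, expected)
    assert p > 0.001  # multinomial sampling error only


def test_every_variant_has_a_truth_label(small_sim):
    assert {v.variant_id for v in small_sim.variants} == set(
        small_sim.truth.true_consequences
    )


# --- expression -------------------------------------------------------------


def test_planted_module_correlation_reaches_target(small_sim):
    import itertools

    from pangenefam.coexpression import compute_fpkm

    fpkm = np.log2(compute_fpkm(small_sim.counts, small_sim.gene_lengths) + 1)
    module = small_sim.truth.planted_modules[0]
    pccs = [
        np.corrcoef(fpkm.loc[a], fpkm.loc[b])[0, 1]
        for a, b in itertools.combinations(module, 2)
    ]
    assert float(np.median(pccs)) >= 0.6


def test_planted_fold_change_has_expected_log2fc():
    cfg = SimConfig(n_genomes=4, genes_per_genome=100,
                    class_mix={"core": 1.0, "softcore": 0.0,
                               "dispensable": 0.0, "private": 0.0},
                    tandem_rate=0.0, n_deg=20, deg_fold_change=4.0, seed=6)
    sim = generate_pangenome(cfg)
    counts, _, labels = generate_expression(sim, biological_cv=0.2)
    a = counts.loc[:, labels == "cond_a"].mean(axis=1)
    b = counts.loc[:, labels == "cond_b"].mean(axis=1)
    lfc = np.log2((b + 1) / (a + 1))
    up = [g for g, v in sim.truth.true_deg.items() if v == "up"]
    none = [g for g, v in sim.truth.true_deg.items() if v == "none"]
    assert float(np.median(lfc[up])) == pytest.approx(2.0, abs=0.5)
    assert abs(float(np.median(lfc[none]))) < 0.3


def test_module_sizes_larger_than_gene_count_rejected():
    cfg = SimConfig(n_genomes=4, genes_per_genome=5,
                    class_mix={"core": 1.0, "softcore": 0.0,
                               "dispensable": 0.0, "private": 0.0},
                    n_modules=3, module_size=30, seed=7)
    sim = generate_pangenome(cfg)
    with pytest.raises(ConfigurationError):
        generate_expression(sim)
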