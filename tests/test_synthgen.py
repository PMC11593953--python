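"""Generator determinism, planted-structure bookkeeping, simulator law."""

import json

import numpy as np
import pytest
from scipy.linalg import expm

from lepusmito.codonbias import GeneticCode
from lepusmito.compstats import base_counts
from lepusmito.mitio import L_STRAND_GENES
from lepusmito.selscan import MG94Machinery
from lepusmito.synthgen import (AlnSimConfig, GenomeSimConfig, SiteClass,
                                gen_codon_alignment, gen_genome_family,
                                gen_mitogenome, random_tree, rotate_genome,
                                write_genbank)


def test_same_seed_reproduces_genome_byte_identical(tmp_path):
    g1, t1 = gen_mitogenome(GenomeSimConfig(seed=7))
    g2, t2 = gen_mitogenome(GenomeSimConfig(seed=7))
    assert g1.sequence == g2.sequence
    p1, p2 = tmp_path / "a.gb", tmp_path / "b.gb"
    write_genbank(g1, p1)
    write_genbank(g2, p2)
    assert p1.read_bytes() == p2.read_bytes()
    t1.to_json(tmp_path / "a.json")
    t2.to_json(tmp_path / "b.json")
    assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()


def test_different_seeds_differ():
    g1, _ = gen_mitogenome(GenomeSimConfig(seed=7))
    g2, _ = gen_mitogenome(GenomeSimConfig(seed=8))
    assert g1.sequence != g2.sequence


def test_truth_matches_annotation(genome, truth):
    assert truth.genome_length == len(genome)
    assert len(truth.features) == 38
    by_name = {f["name"]: f for f in truth.features}
    for f in genome.features:
        t = by_name[f.canonical_name]
        assert (t["start"], t["end"], t["strand"]) == (f.start, f.end, f.strand)
        assert (f.strand == "L") == (f.canonical_name in L_STRAND_GENES)
    assert truth.l_strand_count == 9


def test_pcgs_are_orfs(genome):
    code = GeneticCode.vertebrate_mito()
    for f in genome.features_of_type("PCG"):
        seq = genome.coding_seq(f)
        assert seq[:3] in code.start_codons or seq[:3] == "ATG"
        n = len(seq) - len(seq) % 3
        internal = [seq[i:i + 3] for i in range(3, n - 3, 3)]
        assert not any(c in code.stop_codons for c in internal), f.canonical_name


def test_truth_base_counts_exact(genome, truth):
    for f in genome.features:
        c = base_counts(genome.coding_seq(f))
        t = truth.base_counts[f.canonical_name]
        assert (c.nA, c.nC, c.nG, c.nT) == (t["A"], t["C"], t["G"], t["T"])


def test_genome_length_target_respected():
    g, _ = gen_mitogenome(GenomeSimConfig(seed=1, genome_length_target=17200))
    assert len(g) == 17200


def test_rotate_genome_preserves_lengths_and_wraps():
    g, _ = gen_mitogenome(GenomeSimConfig(seed=2))
    L = len(g)
    r = rotate_genome(g, L - 300)
    assert len(r) == L
    for f in g.features:
        f2 = r.get(f.canonical_name)
        assert f2.length(L) == f.length(L)
    assert any(f.wraps_origin for f in r.features)


def test_family_members_share_annotation_and_diverge():
    genomes, _ = gen_genome_family(3, seed=5, divergence=0.01)
    a, b = genomes[0], genomes[1]
    assert [f.canonical_name for f in a.features] == \
        [f.canonical_name for f in b.features]
    diffs = sum(x != y for x, y in zip(a.sequence, b.sequence))
    assert 0 < diffs < 0.03 * len(a)


# ---------------------------------------------------------------------------
# codon alignment simulator
# ---------------------------------------------------------------------------


def test_alignment_sim_deterministic():
    nwk = random_tree(5, seed=1).as_string(schema="newick")
    cfg = AlnSimConfig(seed=4, tree=nwk, n_sites=40)
    a1, _, t1 = gen_codon_alignment(cfg)
    a2, _, t2 = gen_codon_alignment(cfg)
    assert a1.rows == a2.rows
    assert t1.site_class == t2.site_class


def test_zero_branch_lengths_give_identical_rows():
    nwk = "(A:0.0,B:0.0,C:0.0);"
    cfg = AlnSimConfig(seed=4, tree=nwk, n_sites=30)
    with pytest.warns(UserWarning, match="zero"):
        aln, _, _ = gen_codon_alignment(cfg)
    rows = [tuple(aln.rows[t]) for t in aln.taxa]
    assert rows[0] == rows[1] == rows[2]


def test_site_class_proportions_must_sum_to_one():
    nwk = "(A:0.1,B:0.1,C:0.1);"
    with pytest.raises(ValueError, match="sum to 1"):
        gen_codon_alignment(AlnSimConfig(
            seed=0, tree=nwk,
            site_classes=(SiteClass(0.5, 1, 1, 1, 0),)))


def test_empirical_transitions_match_analytic_matrix():
    """Parent->child codon transitions on a single branch follow the
    analytic transition matrix (Monte-Carlo agreement on marginals)."""
    code = GeneticCode.vertebrate_mito()
    m = MG94Machinery(code)
    nwk = "(A:0.5,B:0.0);"
    cfg = AlnSimConfig(seed=11, tree=nwk, kappa=2.0, n_sites=6000,
                       site_classes=(SiteClass(1.0, 1.0, 0.5, 0.5, 0.0),))
    aln, _, _ = gen_codon_alignment(cfg)
    # B sits at distance 0 from the root: rows[B] is the root state, and
    # rows[A] is one draw from P(0.5) per site
    pi = None
    from lepusmito.synthgen import _codon_profile_from_weights, DEFAULT_WEIGHTS

    prof = _codon_profile_from_weights(DEFAULT_WEIGHTS, code)
    pi = np.array([prof[c] for c in m.codons])
    pi /= pi.sum()
    Qs, Qn = m.components(2.0, pi)
    c = m.normalizer(Qs, Qn, pi, 1.0)
    P = expm((Qs + 0.5 * Qn) / c * 0.5)
    # empirical conditional distribution of "changed vs unchanged"
    same_pred = float(np.sum([pi[i] * P[i, i] for i in range(m.n)]))
    same_obs = np.mean([aln.rows["A"][k] == aln.rows["B"][k]
                        for k in range(cfg.n_sites)])
    assert same_obs == pytest.approx(same_pred, abs=0.02)
    # marginal distribution of the child matches pi P (stationarity)
    counts = np.zeros(m.n)
    for k in range(cfg.n_sites):
        counts[m.index[aln.rows["A"][k]]] += 1
    freq = counts / counts.sum()
    assert np.max(np.abs(freq - pi @ P)) < 0.015


def test_truth_json_roundtrip(tmp_path, truth):
    path = tmp_path / "truth.json"
    truth.to_json(path)
    data = json.loads(path.read_text())
    assert data["genome_length"] == truth.genome_length
    assert data["repeat"]["period"] == truth.repeat["period"]
    assert data["l_strand_count"] == 9
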