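"""MG94xHKY machinery, pruning correctness, and the per-site MEME test."""

import itertools

import dendropy
import numpy as np
import pytest
from scipy.linalg import expm

from lepusmito.codonbias import GeneticCode
from lepusmito.selscan import (EpisodicSelectionScan, MG94Machinery,
                               _SiteObjective, _TreeIndex, _encode_alignment,
                               _mixture_pvalue, _prune_loglik,
                               f3x4_frequencies, fit_global_model,
                               meme_site_test, scan_sites, selection_report)
from lepusmito.synthgen import (AlnSimConfig, SiteClass, gen_codon_alignment,
                                random_tree)


@pytest.fixture(scope="module")
def machinery():
    return MG94Machinery(GeneticCode.vertebrate_mito())


@pytest.fixture(scope="module")
def pi(machinery):
    rng = np.random.default_rng(0)
    p = rng.dirichlet(np.ones(machinery.n) * 5)
    return p


def test_sense_codon_state_space(machinery):
    # vertebrate mito code: 60 sense codons (TAA/TAG/AGA/AGG are stops)
    assert machinery.n == 60
    assert "AGA" not in machinery.index and "ATG" in machinery.index


def test_generator_components_are_proper(machinery, pi):
    Qs, Qn = machinery.components(2.0, pi)
    for Q in (Qs, Qn, Qs + 0.5 * Qn):
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        off = Q - np.diag(np.diag(Q))
        assert np.all(off >= 0)
    # detailed balance for both components
    for Q in (Qs, Qn):
        F = pi[:, None] * Q
        assert np.allclose(F, F.T, atol=1e-14)


def test_transition_matrices_stochastic_and_match_expm(machinery, pi):
    Qs, Qn = machinery.components(2.0, pi)
    Q = (Qs + 0.3 * Qn) / machinery.normalizer(Qs, Qn, pi, 0.3)
    ts = np.array([0.01, 0.4, 2.5])
    P = machinery.transition_matrices(Q, pi, ts)
    assert np.max(np.abs(P.sum(axis=2) - 1.0)) < 1e-10
    for k, t in enumerate(ts):
        assert np.max(np.abs(P[k] - expm(Q * t))) < 1e-10


def _brute_force_loglik(tindex, P, states, pi):
    """Enumerate all internal-node states (independent oracle)."""
    kids = tindex.children
    internals = [i for i in range(tindex.n_nodes) if kids[i]]
    parent = {}
    for i in range(tindex.n_nodes):
        for c in kids[i]:
            parent[c] = i
    n = pi.size
    total = 0.0
    for assign in itertools.product(range(n), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        prob = pi[amap[tindex.root]]
        for i in range(tindex.n_nodes):
            if i == tindex.root:
                continue
            si = amap.get(i)
            if si is None:
                ti = tindex.leaf_taxon[i]
                si = states[ti, 0]
                if si < 0:
                    prob *= P[i][amap[parent[i]]].sum()
                    continue
            prob *= P[i][amap[parent[i]], si]
        total += prob
    return np.log(total)


@pytest.mark.parametrize("newick, taxa, leaf_codons", [
    ("(A:0.2,B:0.4,C:0.1);", ("A", "B", "C"), ("ATA", "ATG", "CTA")),
    ("((A:0.2,B:0.3):0.15,(C:0.25,D:0.1):0.05);", ("A", "B", "C", "D"),
     ("ATA", "ATG", "CTA", "ATA")),
    ("((A:0.2,B:0.3):0.15,(C:0.25,D:0.1):0.05);", ("A", "B", "C", "D"),
     ("ATA", "---", "CTA", "ATA")),      # missing data marginalized
])
def test_pruning_equals_brute_force(machinery, pi, newick, taxa, leaf_codons):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tindex = _TreeIndex(tree, taxa)
    Qs, Qn = machinery.components(1.8, pi)
    Q = (Qs + 0.7 * Qn) / machinery.normalizer(Qs, Qn, pi, 0.7)
    P = np.zeros((tindex.n_nodes, machinery.n, machinery.n))
    P[tindex.edges] = machinery.transition_matrices(
        Q, pi, tindex.lengths[tindex.edges])
    states = np.array([[machinery.index.get(c, -1)] for c in leaf_codons])
    lnl = _prune_loglik(tindex, P, states, pi)
    assert abs(lnl - _brute_force_loglik(tindex, P, states, pi)) < 1e-8


def test_likelihood_invariant_to_rerooting(machinery, pi):
    """Reversibility: the same unrooted tree rooted two ways gives the same
    likelihood (zero-length complement on the root edge)."""
    reps = ["((A:0.1,B:0.2):0.05,(C:0.3,D:0.4):0.0);",
            "(((A:0.1,B:0.2):0.05,C:0.3):0.4,D:0.0);"]
    taxa = ("A", "B", "C", "D")
    Qs, Qn = machinery.components(2.0, pi)
    Q = (Qs + 0.4 * Qn) / machinery.normalizer(Qs, Qn, pi, 0.4)
    states = np.array([[machinery.index[c]]
                       for c in ("ATA", "ATG", "CTA", "GTA")])
    vals = []
    for nwk in reps:
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        ti = _TreeIndex(tree, taxa)
        P = np.zeros((ti.n_nodes, machinery.n, machinery.n))
        P[ti.edges] = machinery.transition_matrices(Q, pi,
                                                    ti.lengths[ti.edges])
        vals.append(_prune_loglik(ti, P, states, pi))
    assert vals[0] == pytest.approx(vals[1], abs=1e-9)


def test_f3x4_frequencies_sum_to_one(machinery):
    states = np.array([[machinery.index["ATA"], machinery.index["CCT"]],
                       [machinery.index["ATG"], -1]])
    pi = f3x4_frequencies(states, machinery)
    assert pi.shape == (machinery.n,)
    assert pi.sum() == pytest.approx(1.0)
    assert np.all(pi > 0)


def test_mixture_pvalue_reference():
    assert _mixture_pvalue(0.0) == 1.0
    assert _mixture_pvalue(-1.0) == 1.0
    from scipy.stats import chi2

    lrt = 3.2
    assert _mixture_pvalue(lrt) == pytest.approx(
        (chi2.sf(lrt, 1) + chi2.sf(lrt, 2)) / 3)
    assert _mixture_pvalue(10.0) < _mixture_pvalue(3.0)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def small_sim():
    tree = random_tree(6, seed=2, mean_branch=0.3)
    cfg = AlnSimConfig(seed=8, tree=tree.as_string(schema="newick"),
                       kappa=2.0, n_sites=300,
                       site_classes=(SiteClass(1.0, 1.0, 0.3, 0.3, 0.0),))
    aln, t, truth = gen_codon_alignment(cfg)
    return aln, t, truth


@pytest.fixture(scope="module")
def small_fit(small_sim):
    aln, tree, _ = small_sim
    return fit_global_model(aln, tree)


def test_global_fit_recovers_kappa_and_omega(small_fit):
    # simulated under kappa=2, omega=0.3
    assert 1.5 <= small_fit.kappa <= 2.7
    assert 0.2 <= small_fit.omega <= 0.45


def test_global_fit_zero_divergence_branch_lengths_collapse():
    nwk = "(A:0.2,B:0.3);"
    cfg = AlnSimConfig(seed=3, tree=nwk, n_sites=80,
                       site_classes=(SiteClass(1.0, 1.0, 0.5, 0.5, 0.0),))
    aln, tree, _ = gen_codon_alignment(cfg)
    # make the two rows identical: no substitutions at all
    aln.rows[aln.taxa[1]] = list(aln.rows[aln.taxa[0]])
    with pytest.warns(UserWarning, match="zero-variation"):
        params = fit_global_model(aln, tree)
    assert np.all(params.branch_lengths() < 1e-4)


def test_invariant_site_not_flagged(small_sim, small_fit):
    aln, tree, _ = small_sim
    col = None
    for k in range(aln.n_sites):
        if len({aln.rows[t][k] for t in aln.taxa}) == 1:
            col = k
            break
    assert col is not None
    r = meme_site_test(aln, tree, small_fit, col)
    assert r.lrt == pytest.approx(0.0, abs=1e-6)
    assert r.p_value == 1.0
    assert not r.flagged


def test_site_results_nested_and_lrt_nonnegative(small_sim, small_fit):
    aln, tree, _ = small_sim
    params, results = scan_sites(aln, tree, params=small_fit,
                                 sites=range(12), seed=3)
    for r in results:
        assert r.lnl_null <= r.lnl_alt + 1e-6
        assert r.lrt >= -1e-6
        assert 0.0 <= r.p_value <= 1.0
        assert r.flagged == ((r.beta_plus > r.alpha) and (r.p_value < 0.1))


def test_selection_report_contents(small_sim, small_fit):
    aln, tree, _ = small_sim
    params, results = scan_sites(aln, tree, params=small_fit,
                                 sites=range(6), seed=3)
    rep = selection_report(results, aln, only_flagged=False)
    assert len(rep) == 6
    assert {"gene", "codon", "alpha", "beta_plus", "p_value"} <= set(rep.columns)
    aa_cols = [c for c in rep.columns if c.startswith("aa:")]
    assert len(aa_cols) == len(aln.taxa)
    # property classes attached to amino-acid states
    val = rep[aa_cols[0]].iloc[0]
    assert val == "-" or "(" in val
    empty = selection_report([], aln)
    assert empty.empty and "gene" in empty.columns


def test_scan_surface_summary(small_sim, small_fit):
    aln, tree, _ = small_sim
    scan = EpisodicSelectionScan(aln, tree)
    res = scan.fit(seed=1, sites=range(4))
    df = res.to_frame()
    assert len(df) == 4
    text = res.summary()
    assert "kappa" in text and "flagged" in text


def test_omega_zero_simulation_has_constant_proteins():
    tree = random_tree(5, seed=4, mean_branch=0.4)
    cfg = AlnSimConfig(seed=9, tree=tree.as_string(schema="newick"),
                       n_sites=50,
                       site_classes=(SiteClass(1.0, 1.0, 0.0, 0.0, 0.0),))
    aln, t, _ = gen_codon_alignment(cfg)
    code = GeneticCode.vertebrate_mito()
    for k in range(aln.n_sites):
        aas = {code.amino_acid(aln.rows[tx][k]) for tx in aln.taxa}
        assert len(aas) == 1
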