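"""K2P distances, neighbor joining, protein-guided codon alignment."""

import math

import dendropy
import numpy as np
import pytest

from lepusmito.phylo import (DistanceMatrix, align_proteins,
                             concat_pcg_alignment, distance_matrix,
                             k2p_distance, nj_tree, path_length_matrix,
                             read_newick, robinson_foulds, write_newick)
from lepusmito.synthgen import gen_genome_family


def test_k2p_identical_sequences_zero():
    assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0


def test_k2p_direct_formula():
    # 100 sites: 10 transitions (A->G), 5 transversions (A->C)
    a = "A" * 100
    b = "G" * 10 + "C" * 5 + "A" * 85
    expected = -0.5 * math.log((1 - 2 * 0.1 - 0.05) * math.sqrt(1 - 2 * 0.05))
    assert k2p_distance(a, b) == pytest.approx(expected)


def test_k2p_symmetric_and_skips_gap_columns():
    a = "ACGT-NACGT"
    b = "ACGAACACGT"
    assert k2p_distance(a, b) == k2p_distance(b, a)
    # gap and N columns dropped pairwise: 8 comparable sites, 1 transversion
    assert k2p_distance(a, b) == pytest.approx(
        -0.5 * math.log((1 - 1 / 8) * math.sqrt(1 - 2 / 8)))


def test_k2p_saturated_flagged_nan():
    assert math.isnan(k2p_distance("AAAA", "CCCC"))


def test_k2p_length_mismatch_raises():
    with pytest.raises(ValueError):
        k2p_distance("ACG", "ACGT")


def test_k2p_reduces_to_jukes_cantor_with_balanced_changes():
    """When transitions are half the differences (P = Q/2 appropriately),
    K2P equals the JC69 transform of the p-distance (checked numerically)."""
    n = 300
    diff = 30
    # 10 transitions, 20 transversions: P=1/30? -> use P = d/3, Q = 2d/3
    a = "A" * n
    b = "G" * 10 + "C" * 10 + "T" * 10 + "A" * (n - diff)
    p = diff / n
    jc = -0.75 * math.log(1 - 4 * p / 3)
    assert k2p_distance(a, b) == pytest.approx(jc, rel=1e-9)


def _dm(taxa, dist):
    n = len(taxa)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = dist[(taxa[i], taxa[j])]
    return DistanceMatrix(tuple(taxa), M)


def test_nj_three_taxa_closed_form():
    D = _dm(["A", "B", "C"], {("A", "B"): 5, ("A", "C"): 9, ("B", "C"): 10})
    tree = nj_tree(D)
    # three-point formulas: a = (dAB + dAC - dBC)/2, etc.
    lengths = {leaf.taxon.label: leaf.edge.length
               for leaf in tree.leaf_node_iter()}
    assert lengths["A"] == pytest.approx(2.0)
    assert lengths["B"] == pytest.approx(3.0)
    assert lengths["C"] == pytest.approx(7.0)


def test_nj_recovers_additive_four_taxon_tree():
    # generating tree: ((A:1,B:2):3,(C:4,D:5))
    D = _dm(["A", "B", "C", "D"],
            {("A", "B"): 3, ("A", "C"): 8, ("A", "D"): 9,
             ("B", "C"): 9, ("B", "D"): 10, ("C", "D"): 9})
    tree = nj_tree(D)
    plm = path_length_matrix(tree)
    order = [plm.taxa.index(t) for t in ("A", "B", "C", "D")]
    got = plm.values[np.ix_(order, order)]
    assert np.max(np.abs(got - D.values)) < 1e-9
    # quartet topology AB|CD: the generating split is in the tree
    ref = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
    assert robinson_foulds(tree, ref) == 0


def test_nj_requires_three_taxa():
    with pytest.raises(ValueError):
        nj_tree(_dm(["A", "B"], {("A", "B"): 1}))


def test_nj_clamps_negative_branches():
    # near-degenerate matrix that induces a negative branch estimate
    D = _dm(["A", "B", "C", "D"],
            {("A", "B"): 0.1, ("A", "C"): 0.1, ("A", "D"): 0.4,
             ("B", "C"): 0.0001, ("B", "D"): 0.3, ("C", "D"): 0.3})
    tree = nj_tree(D)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            assert edge.length >= 0.0


def test_newick_roundtrip(tmp_path):
    t = read_newick("((A:1,B:2):0.5,C:3);")
    p = tmp_path / "t.nwk"
    write_newick(t, p)
    t2 = read_newick(p)
    assert robinson_foulds(t, t2) == 0
    d1 = path_length_matrix(t)
    d2 = path_length_matrix(t2)
    assert np.allclose(d1.values, d2.values)


# ---------------------------------------------------------------------------
# protein alignment / concatenated codon alignment
# ---------------------------------------------------------------------------


def _simple_dp_score(a, b, match=2, mismatch=-1, gap=-2):
    """Independent quadratic DP with linear gaps (oracle)."""
    n, m = len(a), len(b)
    S = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        S[i][0] = i * gap
    for j in range(1, m + 1):
        S[0][j] = j * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            S[i][j] = max(S[i - 1][j - 1] + sub,
                          S[i - 1][j] + gap, S[i][j - 1] + gap)
    return S[n][m]


@pytest.mark.parametrize("a, b", [
    ("MKV", "MKV"),
    ("MKVLW", "MKW"),
    ("HEAGAWGHEE", "PAWHEAE"),
])
def test_protein_alignment_score_matches_hand_dp(a, b):
    _, _, score = align_proteins(a, b, matrix=None, match=2, mismatch=-1,
                                 gap=-2)
    assert score == _simple_dp_score(a, b)


def test_self_alignment_gap_free_and_symmetric_score():
    a = "MKVLWAALLV"
    ga, gb, score = align_proteins(a, a)
    assert ga == gb == a
    _, _, s_ab = align_proteins("MKVLW", "MKWA")
    _, _, s_ba = align_proteins("MKWA", "MKVLW")
    assert s_ab == s_ba


@pytest.fixture(scope="module")
def family():
    return gen_genome_family(4, seed=17)[0]


def test_identical_genomes_align_gap_free(family):
    g = family[0]
    clone = type(g)(id="copy", sequence=g.sequence, topology=g.topology,
                    features=list(g.features))
    aln = concat_pcg_alignment([g, clone])
    nt = aln.to_nucleotide_dict()
    assert nt[g.id] == nt["copy"]
    assert "-" not in nt[g.id]
    total_pcg = sum(f.length(len(g)) for f in g.features_of_type("PCG"))
    # stop codons (complete or completed) are stripped per gene: 13 genes
    assert len(nt[g.id]) >= total_pcg - 13 * 3


def test_family_alignment_has_consistent_geometry(family):
    aln = concat_pcg_alignment(family)
    lens = {len("".join(aln.rows[t])) for t in aln.taxa}
    assert len(lens) == 1
    assert aln.n_sites == len(aln.genes) == len(aln.codon_index)
    assert set(aln.genes) == {f for f in aln.genes}  # per-column provenance


def test_planted_inframe_insertion_creates_one_gap_column(family):
    import copy

    from lepusmito.mitio import GeneFeature, MitoGenome

    base = family[0]
    # insert one codon into Nad3 of a copied genome, shifting downstream
    nad3 = base.get("Nad3")
    ins_at = nad3.start + 90   # in-frame position inside the gene
    seq = base.sequence[:ins_at - 1] + "GCA" + base.sequence[ins_at - 1:]
    feats = []
    for f in base.features:
        if f.start >= ins_at:
            feats.append(GeneFeature(f.canonical_name, f.ftype, f.strand,
                                     f.start + 3, f.end + 3))
        elif f.end >= ins_at:
            feats.append(GeneFeature(f.canonical_name, f.ftype, f.strand,
                                     f.start, f.end + 3))
        else:
            feats.append(f)
    mutant = MitoGenome(id="ins", sequence=seq, topology="circular",
                        features=feats)
    aln = concat_pcg_alignment([base, mutant])
    gap_cols = [k for k in range(aln.n_sites)
                if aln.rows[base.id][k] == "---"]
    assert len(gap_cols) == 1
    assert aln.genes[gap_cols[0]] == "Nad3"
    assert aln.rows["ins"][gap_cols[0]] == "GCA"


def test_nj_from_family_distances_is_fully_resolved(family):
    aln = concat_pcg_alignment(family)
    D = distance_matrix(aln.to_nucleotide_dict())
    tree = nj_tree(D)
    assert len(tree.leaf_nodes()) == len(family)
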