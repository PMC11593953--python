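"""Distance phylogeny: K2P distances, neighbor-joining, codon alignments.

This is the desk-scale stand-in for a full partitioned ML analysis: pairwise
Kimura two-parameter distances on the concatenated protein-coding alignment,
neighbor-joining with deterministic tie-breaking, optional outgroup rooting.
Externally built trees (newick) are accepted anywhere a tree is needed.

Trees are dendropy objects throughout; newick round-trips preserve branch
lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .codonbias import GeneticCode, complete_stop
from .mitio import MitoGenome, PCG_NAMES

__all__ = [
    "DistanceMatrix",
    "k2p_distance",
    "distance_matrix",
    "nj_tree",
    "concat_pcg_alignment",
    "align_proteins",
    "read_newick",
    "write_newick",
    "robinson_foulds",
]

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
_VALID = {"A", "C", "G", "T"}


@dataclass
class DistanceMatrix:
    taxa: tuple
    values: np.ndarray      # symmetric, zero diagonal

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")

    def get(self, a: str, b: str) -> float:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return float(self.values[i, j])


def k2p_distance(a: str, b: str) -> float:
    """Kimura two-parameter distance between two aligned sequences.

    Columns containing gaps or ambiguity in either sequence are skipped
    pairwise.  With transition proportion P and transversion proportion Q,
    ``d = -1/2 ln((1-2P-Q) sqrt(1-2Q))``.  Saturated pairs (non-positive
    logarithm argument) return NaN as the flagged-undefined value.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    a, b = a.upper(), b.upper()
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x not in _VALID or y not in _VALID:
            continue
        n += 1
        if x == y:
            continue
        if (x in PURINES) == (y in PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        return math.nan
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1 * math.sqrt(w2))


def distance_matrix(alignment: dict[str, str]) -> DistanceMatrix:
    """Pairwise K2P matrix over an aligned taxon -> sequence mapping."""
    taxa = tuple(alignment)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = k2p_distance(alignment[taxa[i]],
                                             alignment[taxa[j]])
    return DistanceMatrix(taxa, d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(D: DistanceMatrix, outgroup: Optional[str] = None) -> dendropy.Tree:
    """Neighbor-joining tree (Saitou-Nei with the standard Q criterion).

    Deterministic: ties in the Q criterion are broken by the lexicographic
    order of the (sorted) label pair being joined.  Negative branch lengths
    are clamped to 0 with the deficit transferred to the sibling branch.
    With an ``outgroup`` label the tree is rooted on that leaf's edge;
    otherwise it is returned unrooted (trifurcating root).
    """
    n = len(D.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    taxon_ns = dendropy.TaxonNamespace()
    nodes = []
    labels = []
    for t in D.taxa:
        taxon = taxon_ns.new_taxon(t)
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)
        labels.append(t)
    d = D.values.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i][j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i][j] - r[i] - r[j]
                key = (q, tuple(sorted((labels[i], labels[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = d[i][j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sibling branch
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        ni, nj_ = nodes[i], nodes[j]
        parent.add_child(ni)
        parent.add_child(nj_)
        ni.edge.length = li
        nj_.edge.length = lj
        # distances from the new node to the remaining taxa
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i][k] + d[j][k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        labels.append(min(labels[i], labels[j]))
        active = [k for k in active if k not in (i, j)] + [d.shape[0] - 1]

    # terminate on three nodes with the three-point formulas (trifurcation)
    i, j, k = active
    root = dendropy.Node()
    li = 0.5 * (d[i][j] + d[i][k] - d[j][k])
    lj = 0.5 * (d[i][j] + d[j][k] - d[i][k])
    lk = 0.5 * (d[i][k] + d[j][k] - d[i][j])
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = root
    tree.is_rooted = False
    if outgroup is not None:
        og = None
        for leaf in tree.leaf_node_iter():
            if leaf.taxon and leaf.taxon.label == outgroup:
                og = leaf
                break
        if og is None:
            raise ValueError(f"outgroup {outgroup!r} not among taxa")
        tree.to_outgroup_position(og, update_bipartitions=False)
        tree.is_rooted = True
    return tree


def path_length_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path lengths of a tree (for additivity checks)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = tuple(sorted(t.label for t in tree.taxon_namespace))
    lookup = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(lookup[taxa[i]],
                                                       lookup[taxa[j]])
    return DistanceMatrix(taxa, d)


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted RF (symmetric difference) distance; taxa must match."""
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=t1.as_string(schema="newick"),
                          schema="newick", taxon_namespace=tns)
    b = dendropy.Tree.get(data=t2.as_string(schema="newick"),
                          schema="newick", taxon_namespace=tns)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(a, b))


def read_newick(path_or_string) -> dendropy.Tree:
    s = str(path_or_string)
    if "(" in s and ";" in s:
        return dendropy.Tree.get(data=s, schema="newick")
    return dendropy.Tree.get(path=s, schema="newick")


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick",
               suppress_rooting=True, real_value_format_specifier=".10g")


# ---------------------------------------------------------------------------
# protein-guided codon alignment
# ---------------------------------------------------------------------------


def _make_aligner(matrix: Optional[str], match: float, mismatch: float,
                  gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if matrix:
        aligner.substitution_matrix = substitution_matrices.load(matrix)
    else:
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    # linear gap penalty
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def align_proteins(a: str, b: str, matrix: Optional[str] = "BLOSUM62",
                   match: float = 1.0, mismatch: float = -1.0,
                   gap: float = -8.0) -> tuple[str, str, float]:
    """Global pairwise protein alignment with a linear gap penalty.

    Returns the two gapped strings and the alignment score.  Deterministic:
    the first optimal alignment under Biopython's canonical traceback order
    is used.
    """
    aligner = _make_aligner(matrix, match, mismatch, gap)
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    return sa, sb, float(aln.score)


def _gene_codons(genome: MitoGenome, gene: str,
                 code: GeneticCode) -> Optional[list[str]]:
    feat = genome.get(gene)
    if feat is None:
        return None
    seq, _ = complete_stop(genome.coding_seq(feat))
    seq = seq[: len(seq) - len(seq) % 3]
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    # drop the terminal stop so proteins align cleanly
    if codons and set(codons[-1]) <= _VALID and code.amino_acid(codons[-1]) == "*":
        codons = codons[:-1]
    return codons


@dataclass
class CodonAlignment:
    """In-frame codon alignment with per-column provenance.

    ``columns[k]`` maps taxon -> codon string ('---' for a gap).  ``genes``
    and ``codon_index`` give, per column, the source gene and the 1-based
    codon number in the reference taxon's copy of that gene (0 for columns
    where the reference is gapped).
    """

    taxa: tuple
    rows: dict                   # taxon -> list of codon strings
    genes: list                  # per-column gene name
    codon_index: list            # per-column reference codon number
    reference: str

    @property
    def n_sites(self) -> int:
        return len(self.genes)

    def site(self, k: int) -> dict[str, str]:
        return {t: self.rows[t][k] for t in self.taxa}

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.taxa:
                fh.write(f">{t}\n")
                s = "".join(self.rows[t])
                for i in range(0, len(s), 60):
                    fh.write(s[i:i + 60] + "\n")

    def to_phylip(self, path) -> None:
        """Relaxed sequential PHYLIP."""
        n = len(self.taxa)
        L = 3 * self.n_sites
        with open(path, "w") as fh:
            fh.write(f" {n} {L}\n")
            for t in self.taxa:
                fh.write(f"{t}  {''.join(self.rows[t])}\n")

    def to_nucleotide_dict(self) -> dict[str, str]:
        return {t: "".join(self.rows[t]) for t in self.taxa}


def concat_pcg_alignment(genomes: Sequence[MitoGenome],
                         reference: Optional[str] = None,
                         code: Optional[GeneticCode] = None,
                         genes: Optional[Sequence[str]] = None,
                         matrix: Optional[str] = "BLOSUM62",
                         gap: float = -8.0) -> CodonAlignment:
    """Reference-anchored concatenated codon alignment of the shared PCGs.

    Per gene: translate with the vertebrate mitochondrial code, globally
    align each taxon's protein to the reference taxon's protein, then thread
    the pairwise alignments back to codons on a shared column layout.
    Insertions relative to the reference get their own columns (one block
    per inserting taxon; insertions of different taxa at the same reference
    slot are not homologized).  Genes missing in any genome are dropped with
    a warning.
    """
    import warnings

    code = code or GeneticCode.vertebrate_mito()
    if not genomes:
        raise ValueError("no genomes")
    reference = reference or genomes[0].id
    by_id = {g.id: g for g in genomes}
    if reference not in by_id:
        raise ValueError(f"reference taxon {reference!r} not among genomes")
    gene_list = list(genes) if genes else list(PCG_NAMES)

    taxa = tuple(g.id for g in genomes)
    rows: dict[str, list[str]] = {t: [] for t in taxa}
    out_genes: list[str] = []
    out_index: list[int] = []

    for gene in gene_list:
        per_taxon = {}
        missing = False
        for g in genomes:
            codons = _gene_codons(g, gene, code)
            if codons is None:
                warnings.warn(f"gene {gene} missing in {g.id}; dropped")
                missing = True
                break
            per_taxon[g.id] = codons
        if missing:
            continue
        ref_codons = per_taxon[reference]
        ref_prot = "".join(code.amino_acid(c) if set(c) <= _VALID else "X"
                           for c in ref_codons)
        nref = len(ref_codons)
        # per-taxon mapping: for each reference codon -> taxon codon or gap,
        # plus per-slot insertions (slot s = before reference codon s)
        matched = {reference: list(range(nref))}
        insertions: dict[int, dict[str, list[str]]] = {}
        for t in taxa:
            if t == reference:
                continue
            codons = per_taxon[t]
            prot = "".join(code.amino_acid(c) if set(c) <= _VALID else "X"
                           for c in codons)
            ga, gb = align_proteins(ref_prot, prot, matrix=matrix, gap=gap)[:2]
            mapping = [-1] * nref
            ri = ti = 0
            for ca, cb in zip(ga, gb):
                if ca != "-" and cb != "-":
                    mapping[ri] = ti
                    ri += 1
                    ti += 1
                elif ca != "-":
                    ri += 1
                else:
                    insertions.setdefault(ri, {}).setdefault(t, []).append(
                        codons[ti])
                    ti += 1
            matched[t] = mapping

        for s in range(nref + 1):
            if s in insertions:
                for t_ins in taxa:
                    for codon in insertions[s].get(t_ins, []):
                        for t in taxa:
                            rows[t].append(codon if t == t_ins else "---")
                        out_genes.append(gene)
                        out_index.append(0)
            if s < nref:
                for t in taxa:
                    if t == reference:
                        rows[t].append(ref_codons[s])
                    else:
                        ti = matched[t][s]
                        rows[t].append(per_taxon[t][ti] if ti >= 0 else "---")
                out_genes.append(gene)
                out_index.append(s + 1)

    return CodonAlignment(taxa=taxa, rows=rows, genes=out_genes,
                          codon_index=out_index, reference=reference)
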