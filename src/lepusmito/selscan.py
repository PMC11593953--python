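"""Per-site episodic positive-selection scan (MEME-style) on codon alignments.

The model is MG94xHKY: codon substitution rates are single-nucleotide moves
with transition/transversion ratio kappa, target-codon F3x4 frequencies, and
a synonymous rate alpha versus non-synonymous rate beta.  Fitting is
two-phase:

1. :func:`fit_global_model` maximizes the alignment-wide likelihood under a
   single global omega, estimating kappa and branch lengths (in expected
   substitutions per codon site at the fitted omega);
2. :func:`meme_site_test` holds kappa and branch lengths fixed and fits each
   site with a two-category mixed-effects model: a synonymous rate alpha, a
   conserved non-synonymous rate beta- <= alpha, and a second category
   beta+ applying independently on each branch with probability p+.  The
   null model additionally constrains beta+ <= alpha; the alternative
   leaves beta+ free.  Because branch categories are independent, the
   mixture likelihood is computed by Felsenstein pruning with per-branch
   mixed transition matrices.

The LRT ``2(lnL_alt - lnL_null)`` is referred to the mixture
``1/3 chi2_0 + 1/3 chi2_1 + 1/3 chi2_2``; a site is flagged as under
episodic positive selection when ``beta+ > alpha`` and ``p < 0.1``.

Missing data (gaps, ambiguous codons, stops in-frame) are marginalized as
fully unknown states.  Translation uses the vertebrate mitochondrial code
by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .codonbias import GeneticCode
from .phylo import CodonAlignment

__all__ = [
    "CodonModelParams",
    "SiteResult",
    "MG94Machinery",
    "f3x4_frequencies",
    "fit_global_model",
    "meme_site_test",
    "scan_sites",
    "selection_report",
    "EpisodicSelectionScan",
    "EpisodicSelectionResults",
    "AA_PROPERTY",
]

_NTS = "ACGT"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

AA_PROPERTY = {}
for _aa in "GAVLIPFMW":
    AA_PROPERTY[_aa] = "hydrophobic"
for _aa in "STCYNQ":
    AA_PROPERTY[_aa] = "polar"
for _aa in "DEKRH":
    AA_PROPERTY[_aa] = "charged"


# ---------------------------------------------------------------------------
# tree indexing
# ---------------------------------------------------------------------------


class _TreeIndex:
    """Postorder array view of a dendropy tree for pruning."""

    def __init__(self, tree: dendropy.Tree, taxa: Sequence[str]):
        nodes = list(tree.postorder_node_iter())
        self.n_nodes = len(nodes)
        self.node_of = {id(nd): i for i, nd in enumerate(nodes)}
        self.children: list[list[int]] = [[] for _ in nodes]
        self.lengths = np.zeros(self.n_nodes)
        self.leaf_taxon: list[Optional[int]] = [None] * self.n_nodes
        taxon_idx = {t: i for i, t in enumerate(taxa)}
        for i, nd in enumerate(nodes):
            for ch in nd.child_nodes():
                self.children[i].append(self.node_of[id(ch)])
            if nd.edge.length is not None:
                self.lengths[i] = max(float(nd.edge.length), 0.0)
            if nd.is_leaf():
                label = nd.taxon.label if nd.taxon else nd.label
                if label not in taxon_idx:
                    raise ValueError(f"tree leaf {label!r} not in alignment")
                self.leaf_taxon[i] = taxon_idx[label]
        self.root = self.n_nodes - 1
        self.postorder = list(range(self.n_nodes))
        # edges = every non-root node's subtending branch
        self.edges = [i for i in range(self.n_nodes) if i != self.root]

    def set_lengths(self, x: np.ndarray) -> None:
        self.lengths[self.edges] = x

    def get_lengths(self) -> np.ndarray:
        return self.lengths[self.edges].copy()


# ---------------------------------------------------------------------------
# MG94xHKY machinery
# ---------------------------------------------------------------------------


class MG94Machinery:
    """Sparse structure of the MG94 generator for a given genetic code.

    ``Q(alpha, beta) = alpha * Qs + beta * Qn`` over the sense-codon state
    space, where Qs (Qn) carries the synonymous (non-synonymous)
    single-nucleotide moves with HKY weights kappa^[transition] * pi_target.
    Both components are reversible with respect to the same codon
    distribution, so any positive combination is as well.
    """

    def __init__(self, code: GeneticCode):
        self.code = code
        self.codons = list(code.sense_codons)
        self.index = {c: i for i, c in enumerate(self.codons)}
        self.n = len(self.codons)
        syn_pairs, nsyn_pairs = [], []
        ts_flag = []
        for i, ci in enumerate(self.codons):
            for pos in range(3):
                for nt in _NTS:
                    if nt == ci[pos]:
                        continue
                    cj = ci[:pos] + nt + ci[pos + 1:]
                    j = self.index.get(cj)
                    if j is None:      # change to a stop codon: forbidden
                        continue
                    pair = (i, j)
                    is_ts = (ci[pos], nt) in _TRANSITIONS
                    if code.amino_acid(ci) == code.amino_acid(cj):
                        syn_pairs.append(pair + (is_ts,))
                    else:
                        nsyn_pairs.append(pair + (is_ts,))
        self._syn = np.array(syn_pairs, dtype=int)
        self._nsyn = np.array(nsyn_pairs, dtype=int)

    def components(self, kappa: float, pi: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
        """(Qs, Qn) generator components, unnormalized."""
        n = self.n
        Qs = np.zeros((n, n))
        Qn = np.zeros((n, n))
        for mat, pairs in ((Qs, self._syn), (Qn, self._nsyn)):
            i, j, ts = pairs[:, 0], pairs[:, 1], pairs[:, 2]
            mat[i, j] = np.where(ts == 1, kappa, 1.0) * pi[j]
            np.fill_diagonal(mat, 0.0)
            np.fill_diagonal(mat, -mat.sum(axis=1))
        return Qs, Qn

    @staticmethod
    def normalizer(Qs, Qn, pi, omega: float) -> float:
        """Expected substitutions per codon per unit time at rate (1, omega)."""
        return float(-pi @ np.diag(Qs + omega * Qn))

    def eig(self, Q: np.ndarray, pi: np.ndarray):
        """Symmetrized eigendecomposition; returns (U, w, W) with
        P(t) = U @ diag(exp(w t)) @ W."""
        sq = np.sqrt(pi)
        B = (sq[:, None] * Q) / sq[None, :]
        w, V = np.linalg.eigh((B + B.T) / 2.0)
        U = V / sq[:, None]
        W = V.T * sq[None, :]
        return U, w, W

    def transition_matrices(self, Q: np.ndarray, pi: np.ndarray,
                            t: np.ndarray) -> np.ndarray:
        """P(t_k) for a vector of branch lengths, shape (k, n, n)."""
        U, w, W = self.eig(Q, pi)
        E = np.exp(np.multiply.outer(t, w))            # (k, n)
        P = np.einsum("ij,kj->kij", U, E) @ W
        return np.clip(P, 0.0, None)


def f3x4_frequencies(codon_matrix: np.ndarray, machinery: MG94Machinery,
                     pseudocount: float = 0.5) -> np.ndarray:
    """F3x4 equilibrium frequencies over sense codons.

    Position-specific nucleotide frequencies are tallied from all observed
    (non-missing) codons; the codon frequency is their product restricted to
    sense codons and renormalized.
    """
    counts = np.full((3, 4), pseudocount)
    nt_idx = {b: k for k, b in enumerate(_NTS)}
    for s in codon_matrix.ravel():
        if s < 0:
            continue
        codon = machinery.codons[s]
        for pos in range(3):
            counts[pos, nt_idx[codon[pos]]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array([
        freqs[0, nt_idx[c[0]]] * freqs[1, nt_idx[c[1]]] * freqs[2, nt_idx[c[2]]]
        for c in machinery.codons
    ])
    return pi / pi.sum()


def _encode_alignment(aln: CodonAlignment, machinery: MG94Machinery
                      ) -> np.ndarray:
    """Taxa x sites integer state matrix; -1 = missing/gap/ambiguous/stop."""
    mat = np.full((len(aln.taxa), aln.n_sites), -1, dtype=int)
    for ti, taxon in enumerate(aln.taxa):
        row = aln.rows[taxon]
        for k, codon in enumerate(row):
            mat[ti, k] = machinery.index.get(codon, -1)
    return mat


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------


def _prune_loglik(tindex: _TreeIndex, P: np.ndarray, states: np.ndarray,
                  pi: np.ndarray) -> float:
    """Felsenstein pruning over all sites with one P per branch.

    ``P[i]`` is the transition matrix on node i's subtending branch;
    ``states`` is (taxa, sites).  Partial likelihoods are rescaled per node
    to avoid underflow.  Returns the total log-likelihood.
    """
    n = pi.size
    S = states.shape[1]
    partial = {}
    logscale = np.zeros(S)
    for node in tindex.postorder:
        kids = tindex.children[node]
        if not kids:
            ti = tindex.leaf_taxon[node]
            L = np.zeros((n, S))
            st = states[ti]
            miss = st < 0
            L[:, miss] = 1.0
            obs = ~miss
            L[st[obs], np.nonzero(obs)[0]] = 1.0
            partial[node] = L
        else:
            L = np.ones((n, S))
            for ch in kids:
                L = L * (P[ch] @ partial[ch])
                del partial[ch]
            mx = L.max(axis=0)
            mx[mx == 0.0] = 1.0
            L = L / mx
            logscale += np.log(mx)
            partial[node] = L
    site_lik = pi @ partial[tindex.root]
    return float(np.sum(np.log(np.clip(site_lik, 1e-300, None)) + logscale))


def _prune_site_loglik(tindex: _TreeIndex, P: np.ndarray,
                       states: np.ndarray, pi: np.ndarray) -> float:
    """Single-site pruning (states shape (taxa,))."""
    return _prune_loglik(tindex, P, states[:, None], pi)


# ---------------------------------------------------------------------------
# global fit
# ---------------------------------------------------------------------------


@dataclass
class CodonModelParams:
    """Fitted alignment-wide MG94xHKY parameters."""

    kappa: float
    omega: float
    pi: np.ndarray                     # sense-codon frequencies (F3x4)
    tree: dendropy.Tree                # branch lengths in subs/codon site
    lnl: float
    code_name: str
    converged: bool = True
    warnings: tuple = ()
    # cached machinery (not part of the public contract)
    _machinery: Optional[MG94Machinery] = dc_field(default=None, repr=False)
    _tindex: Optional[_TreeIndex] = dc_field(default=None, repr=False)
    _Qs: Optional[np.ndarray] = dc_field(default=None, repr=False)
    _Qn: Optional[np.ndarray] = dc_field(default=None, repr=False)

    def branch_lengths(self) -> np.ndarray:
        return self._tindex.get_lengths()


def fit_global_model(aln: CodonAlignment, tree: dendropy.Tree,
                     code: Optional[GeneticCode] = None,
                     init_kappa: float = 2.0, init_omega: float = 0.3,
                     maxiter: int = 200) -> CodonModelParams:
    """Fit kappa, a single global omega, and branch lengths by ML.

    Branch lengths are measured in expected substitutions per codon site at
    the fitted omega; the input tree's lengths (or 0.1 where absent) are the
    starting values.  F3x4 frequencies are fixed from observed counts.
    Zero-variation alignments yield a warning and lengths at the lower
    bound rather than an error.
    """
    code = code or GeneticCode.vertebrate_mito()
    machinery = MG94Machinery(code)
    states = _encode_alignment(aln, machinery)
    work = tree.clone(depth=1)
    tindex = _TreeIndex(work, aln.taxa)
    pi = f3x4_frequencies(states, machinery)

    t0 = tindex.get_lengths()
    t0[t0 <= 0.0] = 0.1
    nb = t0.size
    lo_t, hi_t = 1e-8, 20.0
    x0 = np.concatenate([np.log(t0), [np.log(init_kappa), np.log(init_omega)]])
    bounds = [(np.log(lo_t), np.log(hi_t))] * nb + \
             [(np.log(0.05), np.log(50.0)), (np.log(1e-4), np.log(50.0))]

    P_buf = np.zeros((tindex.n_nodes, machinery.n, machinery.n))

    def negloglik(x: np.ndarray) -> float:
        t = np.exp(x[:nb])
        kappa = float(np.exp(x[nb]))
        omega = float(np.exp(x[nb + 1]))
        Qs, Qn = machinery.components(kappa, pi)
        c = machinery.normalizer(Qs, Qn, pi, omega)
        Q = (Qs + omega * Qn) / c
        P = machinery.transition_matrices(Q, pi, t)
        P_buf[tindex.edges] = P
        return -_prune_loglik(tindex, P_buf, states, pi)

    res = minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": maxiter, "ftol": 1e-9})
    warns = ()
    if not res.success:
        warns = (f"global fit: {res.message}",)
    t_hat = np.exp(res.x[:nb])
    kappa_hat = float(np.exp(res.x[nb]))
    omega_hat = float(np.exp(res.x[nb + 1]))
    if np.all(t_hat <= 1e-5):
        warns = warns + ("zero-variation alignment: branch lengths at lower "
                         "bound; parameters not identifiable",)
        warnings.warn(warns[-1])
    tindex.set_lengths(t_hat)
    # write fitted lengths back onto the tree clone
    nodes = list(work.postorder_node_iter())
    for i, nd in enumerate(nodes):
        if i != tindex.root:
            nd.edge.length = float(tindex.lengths[i])
    Qs, Qn = machinery.components(kappa_hat, pi)
    c = machinery.normalizer(Qs, Qn, pi, omega_hat)
    return CodonModelParams(
        kappa=kappa_hat, omega=omega_hat, pi=pi, tree=work, lnl=-res.fun,
        code_name=code.name, converged=bool(res.success), warnings=warns,
        _machinery=machinery, _tindex=tindex, _Qs=Qs / c, _Qn=Qn / c)


# ---------------------------------------------------------------------------
# per-site MEME test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteResult:
    site: int                    # 0-based column index in the alignment
    gene: str
    codon_index: int             # reference-taxon codon number (0 if gapped)
    alpha: float
    beta_minus: float
    beta_plus: float
    p_plus: float
    lnl_null: float
    lnl_alt: float
    lrt: float
    p_value: float
    flagged: bool
    converged: bool
    amino_acids: dict            # taxon -> 1-letter aa ('-' for missing)


def _mixture_pvalue(lrt: float) -> float:
    """Reference distribution 1/3 chi2_0 + 1/3 chi2_1 + 1/3 chi2_2."""
    if lrt <= 0.0:
        return 1.0
    return float((chi2.sf(lrt, 1) + chi2.sf(lrt, 2)) / 3.0)


class _SiteObjective:
    """Negative per-site branch-mixture log-likelihood.

    Parameter vector (alternative): (log alpha, delta, log beta+, p+) with
    beta- = delta * alpha, delta in [0,1].  Null: (log alpha, delta-,
    delta+, p+) with beta+ = delta+ * alpha.
    """

    def __init__(self, params: CodonModelParams, states: np.ndarray):
        self.m = params._machinery
        self.ti = params._tindex
        self.pi = params.pi
        self.Qs = params._Qs
        self.Qn = params._Qn
        self.states = states
        self.t = self.ti.lengths[self.ti.edges]
        self.P_buf = np.zeros((self.ti.n_nodes, self.m.n, self.m.n))
        self.nevals = 0

    def loglik(self, alpha: float, beta_minus: float, beta_plus: float,
               p_plus: float) -> float:
        self.nevals += 1
        Qm = alpha * self.Qs + beta_minus * self.Qn
        Pm = self.m.transition_matrices(Qm, self.pi, self.t)
        if beta_plus != beta_minus and p_plus > 0.0:
            Qp = alpha * self.Qs + beta_plus * self.Qn
            Pp = self.m.transition_matrices(Qp, self.pi, self.t)
            P = (1.0 - p_plus) * Pm + p_plus * Pp
        else:
            P = Pm
        self.P_buf[self.ti.edges] = P
        ll = _prune_site_loglik(self.ti, self.P_buf, self.states, self.pi)
        return ll if np.isfinite(ll) else -1e10

    def neg_alt(self, x: np.ndarray) -> float:
        alpha = np.exp(x[0])
        return -self.loglik(alpha, x[1] * alpha, np.exp(x[2]), x[3])

    def neg_null(self, x: np.ndarray) -> float:
        alpha = np.exp(x[0])
        return -self.loglik(alpha, x[1] * alpha, x[2] * alpha, x[3])


_LOG_A_BOUNDS = (np.log(1e-5), np.log(100.0))
_LOG_B_BOUNDS = (np.log(1e-5), np.log(200.0))


def _multistart(fun, x0_list, bounds, maxfun: int):
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    best = None
    ok = False
    funs = []
    for x0 in x0_list:
        x0 = np.asarray(x0, dtype=float)
        x0 = np.where(np.isfinite(x0), x0, (lo + hi) / 2.0)
        x0 = np.clip(x0, lo, hi)
        try:
            r = minimize(fun, x0, method="L-BFGS-B", bounds=bounds,
                         options={"maxfun": maxfun, "ftol": 1e-10,
                                  "gtol": 1e-7})
        except ValueError:
            # L-BFGS-B occasionally drifts an iterate epsilon outside its
            # box and scipy's finite differencing then refuses; treat the
            # start as failed rather than aborting the scan
            continue
        if not np.all(np.isfinite(r.x)):
            continue
        funs.append(float(r.fun))
        ok = ok or bool(r.success)
        if best is None or r.fun < best.fun:
            best = r
    if len(funs) >= 2:
        # reproducible optimum across independent starts counts as converged
        fs = sorted(funs)
        ok = ok or (fs[1] - fs[0] < 1e-4)
    if best is None:            # every start diverged; report the first x0
        from scipy.optimize import OptimizeResult

        x0 = np.clip(np.where(np.isfinite(x0_list[0]), x0_list[0],
                              (lo + hi) / 2.0), lo, hi)
        best = OptimizeResult(x=x0, fun=float(fun(x0)), success=False,
                              message="all optimizer starts failed")
        ok = False
    return best, ok


def meme_site_test(aln: CodonAlignment, tree: dendropy.Tree,
                   params: CodonModelParams, site: int,
                   rng: Optional[np.random.Generator] = None,
                   n_starts: int = 3, maxfun: int = 120,
                   p_threshold: float = 0.1) -> SiteResult:
    """MEME likelihood-ratio test for episodic positive selection at a site.

    Branch lengths and kappa come fixed from ``params``.  The alternative
    model fits (alpha, beta- <= alpha, beta+ free, p+); the null constrains
    beta+ <= alpha.  Fitting uses ``n_starts`` bounded quasi-Newton starts
    (one informed by the global omega, the rest perturbed); the alternative
    additionally restarts from the null optimum, which guarantees
    LRT >= 0 up to optimizer tolerance.
    """
    rng = rng or np.random.default_rng(0)
    states_all = _encode_alignment(aln, params._machinery)
    return _site_test_encoded(states_all[:, site], aln, params, site, rng,
                              n_starts, maxfun, p_threshold)


def _site_test_encoded(col: np.ndarray, aln: CodonAlignment,
                       params: CodonModelParams, site: int,
                       rng: np.random.Generator, n_starts: int,
                       maxfun: int, p_threshold: float) -> SiteResult:
    machinery = params._machinery
    code_aa = {c: params._machinery.code.amino_acid(c)
               for c in machinery.codons}
    amino_acids = {}
    for t in aln.taxa:
        codon = aln.rows[t][site]
        amino_acids[t] = code_aa.get(codon, "-") if codon in machinery.index \
            else "-"

    gene = aln.genes[site] if site < len(aln.genes) else ""
    cidx = aln.codon_index[site] if site < len(aln.codon_index) else 0

    observed = col[col >= 0]
    obj = _SiteObjective(params, col)
    if observed.size == 0 or np.unique(observed).size <= 1:
        # invariant column: every rate optimum is 0; no signal by definition
        lnl = obj.loglik(1e-8, 1e-8, 1e-8, 0.0)
        return SiteResult(site, gene, cidx, 0.0, 0.0, 0.0, 0.0,
                          lnl, lnl, 0.0, 1.0, False, True, amino_acids)

    w = params.omega
    alt_bounds = [_LOG_A_BOUNDS, (0.0, 1.0), _LOG_B_BOUNDS, (0.0, 1.0)]
    null_bounds = [_LOG_A_BOUNDS, (0.0, 1.0), (0.0, 1.0), (0.0, 1.0)]

    starts_alt = [np.array([0.0, min(w, 1.0), np.log(max(2.0, 3 * w)), 0.5])]
    for _ in range(n_starts - 1):
        starts_alt.append(np.array([
            rng.normal(0.0, 0.7), rng.uniform(0.1, 0.9),
            rng.normal(np.log(3.0), 0.7), rng.uniform(0.1, 0.9)]))
    alt, alt_ok = _multistart(obj.neg_alt, starts_alt, alt_bounds, maxfun)

    a_hat = float(np.exp(alt.x[0]))
    bp_hat = float(np.exp(alt.x[2]))
    if bp_hat <= a_hat * (1.0 + 1e-8):
        # constraint not binding: null optimum equals the alternative
        lnl = -float(alt.fun)
        return SiteResult(site, gene, cidx, a_hat,
                          float(alt.x[1]) * a_hat, bp_hat, float(alt.x[3]),
                          lnl, lnl, 0.0, 1.0, False, alt_ok, amino_acids)

    starts_null = [np.array([alt.x[0], alt.x[1],
                             min(bp_hat / a_hat, 1.0), alt.x[3]])]
    starts_null.append(np.array([0.0, min(w, 1.0), min(w, 1.0), 0.5]))
    for _ in range(max(0, n_starts - 2)):
        starts_null.append(np.array([
            rng.normal(0.0, 0.7), rng.uniform(0.1, 0.9),
            rng.uniform(0.1, 1.0), rng.uniform(0.1, 0.9)]))
    null, null_ok = _multistart(obj.neg_null, starts_null, null_bounds, maxfun)

    if -null.fun > -alt.fun + 1e-9:
        # null beat the alternative: re-polish the alternative from there
        x_re = np.array([null.x[0], null.x[1],
                         null.x[0] + np.log(max(null.x[2], 1e-6)), null.x[3]])
        alt2, ok2 = _multistart(obj.neg_alt, [x_re], alt_bounds, maxfun)
        if alt2.fun < alt.fun:
            alt, alt_ok = alt2, alt_ok or ok2
            a_hat = float(np.exp(alt.x[0]))
            bp_hat = float(np.exp(alt.x[2]))

    lnl_alt = -float(alt.fun)
    lnl_null = -float(null.fun)
    lrt = max(2.0 * (lnl_alt - lnl_null), 0.0)
    pval = _mixture_pvalue(lrt)
    flagged = (bp_hat > a_hat) and (pval < p_threshold)
    converged = bool(alt_ok and null_ok)
    return SiteResult(site, gene, cidx, a_hat, float(alt.x[1]) * a_hat,
                      bp_hat, float(alt.x[3]), lnl_null, lnl_alt, lrt, pval,
                      flagged, converged, amino_acids)


def scan_sites(aln: CodonAlignment, tree: dendropy.Tree,
               params: Optional[CodonModelParams] = None,
               code: Optional[GeneticCode] = None,
               sites: Optional[Sequence[int]] = None,
               seed: int = 0, n_starts: int = 3, maxfun: int = 120,
               p_threshold: float = 0.1) -> tuple[CodonModelParams, list]:
    """Global fit (if not supplied) followed by per-site MEME tests."""
    if params is None:
        params = fit_global_model(aln, tree, code=code)
    machinery = params._machinery
    states = _encode_alignment(aln, machinery)
    rng = np.random.default_rng(seed)
    results = []
    for site in (sites if sites is not None else range(aln.n_sites)):
        results.append(_site_test_encoded(
            states[:, site], aln, params, site, rng, n_starts, maxfun,
            p_threshold))
    n_unconverged = sum(1 for r in results if not r.converged)
    if n_unconverged:
        warnings.warn(
            f"{n_unconverged}/{len(results)} site fits did not certify "
            "convergence; see the 'converged' column")
    return params, results


def common_flagged_sites(results_a: Sequence[SiteResult],
                         results_b: Sequence[SiteResult]) -> list[tuple]:
    """Sites flagged in two scans (e.g. a global-background run and a
    restricted-background run), keyed by reference coordinate."""
    keys_a = {(r.gene, r.codon_index) for r in results_a if r.flagged}
    keys_b = {(r.gene, r.codon_index) for r in results_b if r.flagged}
    return sorted(keys_a & keys_b)


def selection_report(results: Sequence[SiteResult], aln: CodonAlignment,
                     only_flagged: bool = True):
    """Tabulate (flagged) sites with reference coordinates and amino acids.

    Per-taxon amino acids carry the property class used in selection-site
    figures (hydrophobic / polar / charged).
    """
    import pandas as pd

    rows = []
    for r in results:
        if only_flagged and not r.flagged:
            continue
        aa_states = {}
        for taxon, aa in r.amino_acids.items():
            prop = AA_PROPERTY.get(aa, "other" if aa not in "-X" else "missing")
            aa_states[taxon] = f"{aa}({prop})" if aa not in "-X" else aa
        rows.append({
            "gene": r.gene, "codon": r.codon_index, "site": r.site,
            "alpha": r.alpha, "beta_minus": r.beta_minus,
            "beta_plus": r.beta_plus, "p_plus": r.p_plus,
            "LRT": r.lrt, "p_value": r.p_value, "flagged": r.flagged,
            **{f"aa:{t}": aa_states[t] for t in aln.taxa},
        })
    cols = (["gene", "codon", "site", "alpha", "beta_minus", "beta_plus",
             "p_plus", "LRT", "p_value", "flagged"]
            + [f"aa:{t}" for t in aln.taxa])
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# statsmodels-style surface
# ---------------------------------------------------------------------------


class EpisodicSelectionScan:
    """Model object: a codon alignment on a fixed tree, scanned per site.

    >>> scan = EpisodicSelectionScan(aln, tree)
    >>> res = scan.fit(seed=1)
    >>> res.summary()
    """

    def __init__(self, alignment: CodonAlignment, tree: dendropy.Tree,
                 code: Optional[GeneticCode] = None,
                 p_threshold: float = 0.1):
        self.alignment = alignment
        self.tree = tree
        self.code = code or GeneticCode.vertebrate_mito()
        self.p_threshold = p_threshold

    def fit(self, seed: int = 0, sites: Optional[Sequence[int]] = None,
            n_starts: int = 3, maxfun: int = 120) -> "EpisodicSelectionResults":
        params, results = scan_sites(
            self.alignment, self.tree, code=self.code, sites=sites,
            seed=seed, n_starts=n_starts, maxfun=maxfun,
            p_threshold=self.p_threshold)
        return EpisodicSelectionResults(self, params, results)


class EpisodicSelectionResults:
    def __init__(self, model: EpisodicSelectionScan,
                 params: CodonModelParams, sites: list):
        self.model = model
        self.params = params
        self.sites = sites

    @property
    def flagged(self) -> list:
        return [r for r in self.sites if r.flagged]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([{
            "site": r.site, "gene": r.gene, "codon": r.codon_index,
            "alpha": r.alpha, "beta_minus": r.beta_minus,
            "beta_plus": r.beta_plus, "p_plus": r.p_plus,
            "lnL_null": r.lnl_null, "lnL_alt": r.lnl_alt, "LRT": r.lrt,
            "p_value": r.p_value, "flagged": r.flagged,
            "converged": r.converged,
        } for r in self.sites])

    def report(self, only_flagged: bool = True):
        return selection_report(self.sites, self.model.alignment,
                                only_flagged=only_flagged)

    def summary(self) -> str:
        lines = [
            "Episodic positive-selection scan (MG94xHKY branch-mixture)",
            f"  taxa: {len(self.model.alignment.taxa)}   "
            f"sites: {len(self.sites)}",
            f"  kappa = {self.params.kappa:.3f}   "
            f"global omega = {self.params.omega:.3f}   "
            f"lnL = {self.params.lnl:.2f}",
            f"  flagged sites (beta+ > alpha, p < "
            f"{self.model.p_threshold}): {len(self.flagged)}",
        ]
        for r in self.flagged:
            lines.append(
                f"    {r.gene} codon {r.codon_index}: alpha={r.alpha:.3g} "
                f"beta+={r.beta_plus:.3g} p+={r.p_plus:.2f} "
                f"LRT={r.lrt:.2f} p={r.p_value:.4f}")
        return "\n".join(lines)
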