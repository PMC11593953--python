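"""Self-validation experiments: every pipeline stage scored against the
synthetic generator's ground truth.

These are the package's calibration studies — fixed study designs whose
inputs are generated in-process, run end to end through the public API, and
scored exactly.  The test suite and the acceptance script both call them.

Study designs (fixed; see docs/methods.md for rationale):

* genome structure / composition: default hare-like genomes;
* CR dissection: planted ETAS|CD|CSB boundaries and 200 planted repeat
  arrays with period 10-30, 3-15 copies, <= 2 mutations per copy;
* distance phylogeny: additive matrices and K2P/NJ on simulated codon
  alignments over an 8-taxon tree;
* selection scan: a 12-taxon balanced tree (branch length 0.45
  substitutions/codon), 500-site alignments with 60% purifying background
  (omega 0.2), 20% neutral sites (omega 1, the type-I condition) and 20%
  episodic sites (alpha 1, beta- 0, beta+ 5 alpha, branch weight p+ 0.5).
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .compstats import base_counts, genome_skew, length_budget, skew_report
from .crdissect import find_tandem_repeats, partition_cr
from .mitio import MitoGenome
from .phylo import distance_matrix, nj_tree, robinson_foulds
from .selscan import fit_global_model, scan_sites
from .synthgen import (AlnSimConfig, GenomeSimConfig, SiteClass,
                       gen_codon_alignment, gen_mitogenome, gen_repeat_case)

__all__ = [
    "balanced_tree_newick",
    "genome_structure_study",
    "skew_and_budget_study",
    "cr_recovery_study",
    "repeat_recovery_study",
    "nj_recovery_study",
    "selection_scan_study",
]


def balanced_tree_newick(n_taxa: int = 12, branch_length: float = 0.45) -> str:
    """Balanced binary tree with uniform branch lengths (newick)."""
    def clade(labels):
        if len(labels) == 1:
            return f"{labels[0]}:{branch_length}"
        mid = len(labels) // 2
        return (f"({clade(labels[:mid])},{clade(labels[mid:])})"
                f":{branch_length}")

    labels = [f"T{i:02d}" for i in range(1, n_taxa + 1)]
    mid = n_taxa // 2
    return f"({clade(labels[:mid])},{clade(labels[mid:])});"


def genome_structure_study(seed: int = 0) -> dict:
    """Generate a default genome and recount its annotation via mitio."""
    genome, truth = gen_mitogenome(GenomeSimConfig(seed=seed))
    return {
        "n_pcg": len(genome.features_of_type("PCG")),
        "n_trna": len(genome.features_of_type("tRNA")),
        "n_rrna": len(genome.features_of_type("rRNA")),
        "n_cr": len(genome.features_of_type("CR")),
        "n_l_strand": sum(1 for f in genome.features if f.strand == "L"),
        "genome_length": len(genome),
        "truth_l_strand": truth.l_strand_count,
    }


def skew_and_budget_study(seed: int = 0, n_genomes: int = 100) -> dict:
    """Skew antisymmetry and the length-conservation identity over many
    random genomes."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n_genomes)
    max_antisym = 0.0
    budget_violations = 0
    at_skews, gc_skews = [], []
    comp = str.maketrans("ACGT", "TGCA")
    for s in seeds:
        g, _ = gen_mitogenome(GenomeSimConfig(seed=int(s)))
        r = genome_skew(g)
        at_skews.append(r.at_skew)
        gc_skews.append(r.gc_skew)
        rc = g.sequence.translate(comp)[::-1]
        r2 = skew_report(base_counts(rc))
        max_antisym = max(max_antisym, abs(r.at_skew + r2.at_skew),
                          abs(r.gc_skew + r2.gc_skew))
        if length_budget(g).identity_residual != 0:
            budget_violations += 1
    return {
        "n_genomes": n_genomes,
        "max_antisymmetry_error": max_antisym,
        "budget_violations": budget_violations,
        "mean_at_skew": float(np.mean(at_skews)),
        "mean_gc_skew": float(np.mean(gc_skews)),
    }


def cr_recovery_study(seed: int = 0, n_genomes: int = 20) -> dict:
    """Exact recovery of planted ETAS/CD/CSB boundaries."""
    rng = np.random.default_rng(seed)
    exact = 0
    for s in rng.integers(0, 2 ** 31 - 1, size=n_genomes):
        g, truth = gen_mitogenome(GenomeSimConfig(seed=int(s)))
        part = partition_cr(g)
        segs = {x.name: x.length for x in part.segments}
        ok = (segs == truth.segment_lengths and
              part.segment("CD").start == truth.anchor_positions["CSB-F"] and
              part.segment("CSB").start == truth.anchor_positions["CSB1"] and
              part.etas1_variant == truth.etas1_variant and
              sum(segs.values()) == part.cr_length)
        exact += bool(ok)
    return {"n_genomes": n_genomes, "boundary_exact": exact,
            "boundary_exact_fraction": exact / n_genomes}


def repeat_recovery_study(seed: int = 0, n_arrays: int = 200) -> dict:
    """Planted tandem arrays: exact period, copy number within +/-1."""
    rng = np.random.default_rng(seed)
    period_ok = copies_ok = 0
    for s in rng.integers(0, 2 ** 31 - 1, size=n_arrays):
        case = gen_repeat_case(int(s))
        found = find_tandem_repeats(case["sequence"], 10, 30, 2)
        hit = None
        for r in found:
            lo = max(r.array_start, case["array_start"])
            hi = min(r.array_end, case["array_end"])
            if hi - lo > case["period"]:
                hit = r
                break
        if hit is not None and hit.period == case["period"]:
            period_ok += 1
            if abs(hit.full_copies - case["copies"]) <= 1:
                copies_ok += 1
    return {"n_arrays": n_arrays, "period_exact": period_ok,
            "copies_within_one": copies_ok,
            "period_exact_fraction": period_ok / n_arrays,
            "copies_within_one_fraction": copies_ok / n_arrays}


def nj_recovery_study(seed: int = 0, n_taxa: int = 8,
                      n_sites: int = 600) -> dict:
    """NJ topology recovery from K2P distances on a simulated alignment,
    plus exactness on an additive matrix."""
    from .phylo import DistanceMatrix, path_length_matrix
    from .synthgen import random_tree

    # additive part: random tree -> path-length matrix -> NJ -> RF
    tree = random_tree(n_taxa, seed=seed, mean_branch=0.3, min_internal=0.05)
    D_add = path_length_matrix(tree)
    rf_additive = robinson_foulds(nj_tree(D_add), tree)
    add_dev = float(np.max(np.abs(
        path_length_matrix(nj_tree(D_add)).values - D_add.values)))

    # sequence part: simulate codons on the same tree, K2P + NJ
    cfg = AlnSimConfig(seed=seed + 1, tree=tree.as_string(schema="newick"),
                       kappa=2.0, n_sites=n_sites,
                       site_classes=(SiteClass(1.0, 1.0, 0.3, 0.3, 0.0),))
    aln, sim_tree, _ = gen_codon_alignment(cfg)
    D = distance_matrix(aln.to_nucleotide_dict())
    rf_seq = robinson_foulds(nj_tree(D), sim_tree)
    return {"rf_additive": rf_additive, "rf_simulated": rf_seq,
            "additive_max_deviation": add_dev, "n_taxa": n_taxa,
            "n_sites": n_sites}


def selection_scan_study(seed: int = 0, n_sites: int = 500,
                         n_test_sites: int = 100,
                         branch_length: float = 0.45,
                         scan_seed: int = 7,
                         progress: bool = False) -> dict:
    """Type-I error and power of the episodic-selection scan.

    Two 12-taxon alignments share the study tree.  The *null* alignment is
    selection-free (80% purifying background at omega 0.2, 20% neutral
    omega=1 sites); the fraction of neutral sites flagged at p < 0.1 is the
    empirical type-I rate.  The *power* alignment replaces the neutral
    class by episodic sites (alpha 1, beta- 0, beta+ = 5 alpha applied per
    branch with probability 0.5); their flag fraction is the empirical
    power.  Each alignment gets its own global fit, mirroring how the scan
    is used on real data.
    """
    nwk = balanced_tree_newick(12, branch_length)
    bg = SiteClass(0.8, 1.0, 0.2, 0.2, 0.0)
    out = {}
    min_lrt = np.inf
    for label, test_class, sim_seed in (
            ("null", SiteClass(0.2, 1.0, 1.0, 1.0, 0.0), seed),
            ("power", SiteClass(0.2, 1.0, 0.0, 5.0, 0.5), seed + 1)):
        cfg = AlnSimConfig(seed=sim_seed, tree=nwk, kappa=2.0,
                           n_sites=n_sites, site_classes=(bg, test_class))
        aln, tree, truth = gen_codon_alignment(cfg)
        sites = [i for i, c in enumerate(truth.site_class)
                 if c == 1][:n_test_sites]
        params = fit_global_model(aln, tree)
        _, res = scan_sites(aln, tree, params=params, sites=sites,
                            seed=scan_seed)
        out[f"n_{label}_sites"] = len(res)
        out[f"{label}_flag_rate"] = sum(r.flagged for r in res) / len(res)
        out[f"{label}_omega_hat"] = params.omega
        min_lrt = min(min_lrt, min(r.lrt for r in res))
        if label == "power":
            out["kappa_hat"] = params.kappa
    out["min_lrt"] = float(min_lrt)
    return out
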