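"""Base composition, strand skews, and length accounting.

AT skew = (A - T) / (A + T) and GC skew = (G - C) / (G + C), computed on the
H strand for the whole genome and on the coding strand for individual genes.
Hare (and generally mammal) mitogenomes show positive AT skew and strongly
negative GC skew on the H strand — cytosine outnumbers guanine.

Percentages are reported to 1 decimal and skews to 3 decimals in the TSV
outputs; raw values are retained on the Python objects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .mitio import GeneFeature, MitoGenome

__all__ = [
    "BaseCounts",
    "SkewReport",
    "LengthBudget",
    "OverlapRecord",
    "base_counts",
    "skew_report",
    "genome_skew",
    "per_gene_skews",
    "overlaps_and_spacers",
    "length_budget",
    "genome_summary_table",
]


@dataclass(frozen=True)
class BaseCounts:
    nA: int
    nC: int
    nG: int
    nT: int
    n_ambiguous: int = 0

    @property
    def total(self) -> int:
        return self.nA + self.nC + self.nG + self.nT + self.n_ambiguous

    @property
    def unambiguous(self) -> int:
        return self.nA + self.nC + self.nG + self.nT

    def __add__(self, other: "BaseCounts") -> "BaseCounts":
        return BaseCounts(self.nA + other.nA, self.nC + other.nC,
                          self.nG + other.nG, self.nT + other.nT,
                          self.n_ambiguous + other.n_ambiguous)

    def reverse_complement(self) -> "BaseCounts":
        return BaseCounts(self.nT, self.nG, self.nC, self.nA, self.n_ambiguous)


@dataclass(frozen=True)
class SkewReport:
    at_content: float        # percent of unambiguous bases
    gc_content: float        # percent of unambiguous bases
    at_skew: Optional[float]  # None when A+T == 0
    gc_skew: Optional[float]  # None when G+C == 0


def base_counts(seq: str) -> BaseCounts:
    """Exact per-letter tally; IUPAC ambiguity codes land in n_ambiguous."""
    seq = seq.upper()
    nA = seq.count("A")
    nC = seq.count("C")
    nG = seq.count("G")
    nT = seq.count("T")
    return BaseCounts(nA, nC, nG, nT, len(seq) - nA - nC - nG - nT)


def skew_report(counts: BaseCounts) -> SkewReport:
    """Contents and skews from base counts.

    Ambiguous bases are excluded from both numerators and denominators.  A
    zero denominator yields a flagged-undefined (None) skew rather than NaN.
    """
    un = counts.unambiguous
    at = counts.nA + counts.nT
    gc = counts.nG + counts.nC
    at_content = 100.0 * at / un if un else 0.0
    gc_content = 100.0 * gc / un if un else 0.0
    at_skew = (counts.nA - counts.nT) / at if at else None
    gc_skew = (counts.nG - counts.nC) / gc if gc else None
    return SkewReport(at_content, gc_content, at_skew, gc_skew)


def genome_skew(genome: MitoGenome) -> SkewReport:
    return skew_report(base_counts(genome.sequence))


def per_gene_skews(genome: MitoGenome) -> pd.DataFrame:
    """Skew report per feature, on each gene's coding strand.

    For L-strand genes the counts are taken from the reverse complement, so
    the reported skew describes the strand the gene is read from.  Row order
    follows genome position.
    """
    L = len(genome)
    rows = []
    for f in sorted(genome.features, key=lambda f: (f.start, f.end)):
        if f.end > L or f.start > L:
            raise ValueError(f"feature {f.canonical_name} outside sequence")
        c = base_counts(genome.coding_seq(f))
        r = skew_report(c)
        rows.append({
            "genome_id": genome.id, "canonical_name": f.canonical_name,
            "ftype": f.ftype, "strand": f.strand, "start": f.start,
            "end": f.end, "length_bp": f.length(L),
            "at_content": r.at_content, "gc_content": r.gc_content,
            "at_skew": r.at_skew, "gc_skew": r.gc_skew,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# overlap / intergenic accounting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OverlapRecord:
    gene_a: str
    gene_b: str
    kind: str        # {overlap, spacer}
    length: int      # bp, >= 1
    contained: bool = False   # gene_b fully inside gene_a


def _unwrapped(f: GeneFeature, L: int) -> tuple[int, int]:
    """(start, end) with end possibly > L for origin-wrapping features."""
    if f.wraps_origin:
        return f.start, f.end + L
    return f.start, f.end


def overlaps_and_spacers(genome: MitoGenome) -> list[OverlapRecord]:
    """Classify every adjacent feature pair as an overlap or a spacer.

    Features are walked in start order; on circular genomes the pair
    (last feature, first feature) is classified across the origin.  Abutting
    genes (zero gap, zero overlap) produce no record.  A feature fully
    contained in its predecessor is reported as an overlap of the inner
    length with a containment flag.
    """
    L = len(genome)
    feats = sorted(genome.features, key=lambda f: (_unwrapped(f, L)[0],
                                                   _unwrapped(f, L)[1]))
    if len(feats) < 2:
        return []
    records: list[OverlapRecord] = []
    pairs = list(zip(feats[:-1], feats[1:]))
    if genome.topology == "circular":
        pairs.append((feats[-1], feats[0]))
    for a, b in pairs:
        sa, ea = _unwrapped(a, L)
        sb, eb = _unwrapped(b, L)
        if b is feats[0] and a is not feats[0]:
            # wrap-around pair: shift b one turn forward
            sb, eb = sb + L, eb + L
        gap = sb - ea - 1
        if gap > 0:
            records.append(OverlapRecord(a.canonical_name, b.canonical_name,
                                         "spacer", gap))
        elif gap < 0:
            shared = -gap
            contained = eb <= ea
            length = (eb - sb + 1) if contained else shared
            records.append(OverlapRecord(a.canonical_name, b.canonical_name,
                                         "overlap", length, contained=contained))
    return records


@dataclass(frozen=True)
class LengthBudget:
    whole: int
    pcg_total: int
    trna_total: int
    rrna_total: int
    cr: int
    overlap_total: int
    intergenic_total: int

    @property
    def identity_residual(self) -> int:
        """whole - (pcg + trna + rrna + cr + intergenic - overlap); 0 for a
        fully tiled annotation."""
        return self.whole - (self.pcg_total + self.trna_total +
                             self.rrna_total + self.cr +
                             self.intergenic_total - self.overlap_total)


def length_budget(genome: MitoGenome) -> LengthBudget:
    L = len(genome)
    totals = {"PCG": 0, "tRNA": 0, "rRNA": 0, "CR": 0}
    for f in genome.features:
        if f.ftype in totals:
            totals[f.ftype] += f.length(L)
    recs = overlaps_and_spacers(genome)
    overlap_total = sum(r.length for r in recs if r.kind == "overlap")
    intergenic_total = sum(r.length for r in recs if r.kind == "spacer")
    return LengthBudget(whole=L, pcg_total=totals["PCG"],
                        trna_total=totals["tRNA"], rrna_total=totals["rRNA"],
                        cr=totals["CR"], overlap_total=overlap_total,
                        intergenic_total=intergenic_total)


# ---------------------------------------------------------------------------
# per-genome summary table
# ---------------------------------------------------------------------------


def genome_summary_table(genomes: Iterable[MitoGenome],
                         rounded: bool = True) -> pd.DataFrame:
    """One row per genome: length, base percentages, A+T%, AT and GC skew."""
    rows = []
    for g in genomes:
        c = base_counts(g.sequence)
        r = skew_report(c)
        un = c.unambiguous or 1
        row = {
            "genome_id": g.id, "length_bp": len(g),
            "A_pct": 100.0 * c.nA / un, "C_pct": 100.0 * c.nC / un,
            "G_pct": 100.0 * c.nG / un, "T_pct": 100.0 * c.nT / un,
            "AT_pct": r.at_content,
            "at_skew": r.at_skew, "gc_skew": r.gc_skew,
        }
        rows.append(row)
    df = pd.DataFrame(rows)
    if rounded and not df.empty:
        for col in ("A_pct", "C_pct", "G_pct", "T_pct", "AT_pct"):
            df[col] = df[col].round(1)
        for col in ("at_skew", "gc_skew"):
            df[col] = df[col].astype(float).round(3)
    return df


def mean_spacer_length(genomes: Iterable[MitoGenome],
                       gene_a: str, gene_b: str) -> float:
    """Unweighted mean (over genomes) of the spacer between two named genes."""
    lengths = []
    for g in genomes:
        for r in overlaps_and_spacers(g):
            if r.kind == "spacer" and r.gene_a == gene_a and r.gene_b == gene_b:
                lengths.append(r.length)
    if not lengths:
        return math.nan
    return sum(lengths) / len(lengths)
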