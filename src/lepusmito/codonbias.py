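"""Codon extraction and relative synonymous codon usage (RSCU).

RSCU for codon *i* in a synonymous family of size *k* with family total *N*
is ``count_i * k / N``: 1 means no preference, >1 over-use, <1 under-use.
A codon with zero count is classed ``missing`` (the pattern behind, e.g., a
genome lacking CGG entirely while the other Arg codons are used).

Amino-acid families default to the *standard* genetic code, because published
mitogenome RSCU tables routinely label AGA as Arg and ATA as Ile — standard
assignments, not vertebrate-mitochondrial ones.  The vertebrate mitochondrial
code is available via ``GeneticCode.vertebrate_mito()`` and is the default
for translation elsewhere in the package.  Stop codons form a ``Ter`` family
and are included in the tally by default (``include_stops=False`` excludes
them).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable

from .mitio import MitoGenome

__all__ = [
    "GeneticCode",
    "CODONS",
    "extract_codons",
    "complete_stop",
    "rscu",
    "rscu_matrix",
    "preference_matrix",
]

CODONS = tuple("".join(c) for c in itertools.product("TCAG", repeat=3))


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map with start/stop sets (64 codons)."""

    name: str
    table: dict = field(repr=False)   # codon -> 1-letter aa, '*' for stop
    start_codons: frozenset = frozenset()

    def __post_init__(self):
        if len(self.table) != 64:
            raise ValueError("genetic code must map all 64 codons")

    @classmethod
    def from_ncbi(cls, table_id: int) -> "GeneticCode":
        t = CodonTable.unambiguous_dna_by_id[table_id]
        table = {c: t.forward_table.get(c, "*") for c in CODONS}
        return cls(name=t.names[0], table=table,
                   start_codons=frozenset(t.start_codons))

    @classmethod
    def standard(cls) -> "GeneticCode":
        return cls.from_ncbi(1)

    @classmethod
    def vertebrate_mito(cls) -> "GeneticCode":
        return cls.from_ncbi(2)

    @property
    def stop_codons(self) -> frozenset:
        return frozenset(c for c, aa in self.table.items() if aa == "*")

    @property
    def sense_codons(self) -> tuple:
        return tuple(c for c in CODONS if self.table[c] != "*")

    def amino_acid(self, codon: str) -> str:
        """1-letter amino acid, '*' for stop, 'X' for ambiguous codons."""
        return self.table.get(codon, "X")

    def family(self, codon: str) -> tuple:
        """All codons sharing this codon's amino acid (Ter = all stops)."""
        aa = self.table[codon]
        return tuple(c for c in CODONS if self.table[c] == aa)

    def translate(self, seq: str) -> str:
        seq = seq.upper()
        out = []
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i:i + 3]
            out.append(self.table.get(codon, "X"))
        return "".join(out)


def complete_stop(seq: str) -> tuple[str, bool]:
    """Complete a truncated terminal stop codon by polyadenylation convention.

    Mitochondrial PCGs frequently end in a bare ``T`` or ``TA`` that becomes
    a TAA stop only after polyadenylation of the mRNA.  Returns the
    (possibly extended) sequence and whether a completion was applied.
    """
    r = len(seq) % 3
    if r == 1 and seq.endswith("T"):
        return seq + "AA", True
    if r == 2 and seq.endswith("TA"):
        return seq + "A", True
    return seq, False


def extract_codons(genome: MitoGenome, code: GeneticCode | None = None,
                   complete_stops: bool = True) -> pd.Series:
    """Codon counts over the concatenated in-frame codons of all 13 PCGs.

    Each PCG is read on its coding strand.  Truncated terminal stops are
    completed to TAA (logged via ``warnings``) when ``complete_stops``;
    any remaining out-of-frame tail is dropped with a warning.  Codons
    containing ambiguity codes are skipped, not fractionally allocated.

    Returns a length-64 integer Series indexed by codon.
    """
    counts = dict.fromkeys(CODONS, 0)
    for f in genome.features_of_type("PCG"):
        seq = genome.coding_seq(f)
        if complete_stops:
            seq, done = complete_stop(seq)
            if done:
                warnings.warn(
                    f"{genome.id}:{f.canonical_name}: incomplete terminal stop "
                    "completed to TAA", stacklevel=2)
        if len(seq) % 3:
            warnings.warn(
                f"{genome.id}:{f.canonical_name}: length not a multiple of 3; "
                "trailing partial codon dropped", stacklevel=2)
            seq = seq[: len(seq) - len(seq) % 3]
        for i in range(0, len(seq), 3):
            codon = seq[i:i + 3]
            if codon in counts:
                counts[codon] += 1
    return pd.Series(counts, name=genome.id)


def rscu(counts: pd.Series, code: GeneticCode | None = None,
         include_stops: bool = True) -> pd.DataFrame:
    """RSCU table from a 64-codon count vector.

    Within each synonymous family of size k the RSCU of codon i is
    ``count_i * k / N`` where N is the family total.  A family with N = 0
    has all members flagged ``missing``; an individual zero-count codon in
    an observed family is likewise ``missing``.  Rows are ordered by amino
    acid then codon, matching :func:`rscu_matrix`.
    """
    code = code or GeneticCode.standard()
    rows = []
    for codon in _ordered_codons(code):
        aa = code.amino_acid(codon)
        if aa == "*" and not include_stops:
            continue
        fam = code.family(codon)
        k = len(fam)
        N = int(sum(counts.get(c, 0) for c in fam))
        n = int(counts.get(codon, 0))
        value = (n * k / N) if N > 0 else float("nan")
        if n == 0:
            pref = "missing"
        elif abs(value - 1.0) < 1e-9:
            pref = "none"
        elif value > 1.0:
            pref = "positive"
        else:
            pref = "negative"
        rows.append({"codon": codon, "amino_acid": "Ter" if aa == "*" else aa,
                     "count": n, "rscu": value, "preference": pref})
    return pd.DataFrame(rows).set_index("codon")


def _ordered_codons(code: GeneticCode) -> list[str]:
    """Deterministic codon order: by amino acid (Ter last), then codon."""

    def key(c):
        aa = code.amino_acid(c)
        return ("~" if aa == "*" else aa, c)

    return sorted(CODONS, key=key)


def rscu_matrix(genomes: list[MitoGenome], code: GeneticCode | None = None,
                include_stops: bool = True,
                complete_stops: bool = True) -> pd.DataFrame:
    """Species x codon RSCU matrix (rows = genome ids)."""
    code = code or GeneticCode.standard()
    cols = [c for c in _ordered_codons(code)
            if include_stops or code.amino_acid(c) != "*"]
    rows = {}
    for g in genomes:
        counts = extract_codons(g, code, complete_stops=complete_stops)
        tab = rscu(counts, code, include_stops=include_stops)
        rows[g.id] = tab["rscu"].reindex(cols)
    return pd.DataFrame(rows).T[cols]


def preference_matrix(genomes: list[MitoGenome],
                      code: GeneticCode | None = None,
                      include_stops: bool = True) -> pd.DataFrame:
    """Species x codon preference classes (positive/none/negative/missing)."""
    code = code or GeneticCode.standard()
    cols = [c for c in _ordered_codons(code)
            if include_stops or code.amino_acid(c) != "*"]
    rows = {}
    for g in genomes:
        counts = extract_codons(g, code)
        tab = rscu(counts, code, include_stops=include_stops)
        rows[g.id] = tab["preference"].reindex(cols)
    return pd.DataFrame(rows).T[cols]


def rscu_long_table(genomes: list[MitoGenome],
                    code: GeneticCode | None = None,
                    include_stops: bool = True) -> pd.DataFrame:
    """Long format: (species, codon, amino acid, count, RSCU, preference)."""
    code = code or GeneticCode.standard()
    frames = []
    for g in genomes:
        counts = extract_codons(g, code)
        tab = rscu(counts, code, include_stops=include_stops).reset_index()
        tab.insert(0, "genome_id", g.id)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)
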