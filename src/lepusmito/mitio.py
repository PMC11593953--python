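"""Mitogenome I/O and canonical feature tables.

Reads annotated mitochondrial genomes (GenBank flat files or FASTA plus a
feature table), normalizes the zoo of gene spellings found in public records
(``ND4`` / ``Nad4`` / ``nad4``, ``COI`` / ``COX1``, ``trnF`` / ``tRNA-Phe``)
onto a fixed 37-gene vocabulary, and writes deterministic tab-separated
feature tables.

Coordinates are 1-based inclusive on the H-strand reference, matching
GenBank.  Circular genomes may carry features that span the origin; these are
stored with ``wraps_origin=True`` and ``end < start``, and their unwrapped
length is ``(L - start + 1) + end``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GeneFeature",
    "MitoGenome",
    "UNMAPPED",
    "CANONICAL_NAMES",
    "PCG_NAMES",
    "TRNA_NAMES",
    "RRNA_NAMES",
    "L_STRAND_GENES",
    "canonicalize_gene_name",
    "read_genbank",
    "read_fasta",
    "write_fasta",
    "feature_table",
    "write_feature_table",
    "read_feature_table",
]

UNMAPPED = "unmapped"

PCG_NAMES = (
    "Nad1", "Nad2", "Nad3", "Nad4", "Nad4L", "Nad5", "Nad6",
    "Cox1", "Cox2", "Cox3", "Atp6", "Atp8", "Cytb",
)
RRNA_NAMES = ("rrnS", "rrnL")
_TRNA_AA = (
    "Phe", "Val", "Leu1", "Leu2", "Ile", "Gln", "Met", "Trp", "Ala", "Asn",
    "Cys", "Tyr", "Ser1", "Ser2", "Asp", "Lys", "Gly", "Arg", "His", "Thr",
    "Glu", "Pro",
)
TRNA_NAMES = tuple(f"tRNA-{aa}" for aa in _TRNA_AA)
CANONICAL_NAMES = PCG_NAMES + RRNA_NAMES + TRNA_NAMES + ("CR",)

#: genes encoded on the light strand in the standard vertebrate order:
#: Nad6 plus eight tRNAs.  (Ser1 = the UCN-codon serine tRNA downstream of
#: Cox1; Ser2 = the AGY-codon serine tRNA downstream of His, H strand.)
L_STRAND_GENES = frozenset({
    "Nad6", "tRNA-Gln", "tRNA-Ala", "tRNA-Asn", "tRNA-Cys", "tRNA-Tyr",
    "tRNA-Ser1", "tRNA-Glu", "tRNA-Pro",
})

_FTYPE_OF = {}
for _n in PCG_NAMES:
    _FTYPE_OF[_n] = "PCG"
for _n in RRNA_NAMES:
    _FTYPE_OF[_n] = "rRNA"
for _n in TRNA_NAMES:
    _FTYPE_OF[_n] = "tRNA"
_FTYPE_OF["CR"] = "CR"


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature on the H-strand coordinate system."""

    canonical_name: str          # one of CANONICAL_NAMES, or UNMAPPED
    ftype: str                   # {PCG, tRNA, rRNA, CR}
    strand: str                  # {H, L}
    start: int                   # 1-based inclusive
    end: int                     # 1-based inclusive; < start iff wraps_origin
    wraps_origin: bool = False
    raw_name: Optional[str] = None   # annotation spelling as found in the record

    def __post_init__(self):
        if self.start < 1:
            raise ValueError(f"feature start must be >= 1, got {self.start}")
        if not self.wraps_origin and self.end < self.start:
            raise ValueError(
                f"non-wrapping feature has end {self.end} < start {self.start}"
            )
        if self.strand not in ("H", "L"):
            raise ValueError(f"strand must be 'H' or 'L', got {self.strand!r}")

    @property
    def mapped(self) -> bool:
        return self.canonical_name != UNMAPPED

    def length(self, genome_length: int) -> int:
        if self.wraps_origin:
            return (genome_length - self.start + 1) + self.end
        return self.end - self.start + 1


@dataclass
class MitoGenome:
    """A (usually circular) mitochondrial genome with its feature annotation."""

    id: str
    sequence: str
    topology: str = "circular"   # {circular, linear}
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if len(self.sequence) == 0:
            raise ValueError("empty genome sequence")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"bad topology {self.topology!r}")
        L = len(self.sequence)
        for f in self.features:
            if f.start > L or f.end > L:
                raise ValueError(
                    f"feature {f.canonical_name} [{f.start},{f.end}] outside "
                    f"sequence of length {L}"
                )
            if f.wraps_origin and self.topology != "circular":
                raise ValueError("origin-wrapping feature on a linear genome")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_seq(self, feat: GeneFeature) -> str:
        """H-strand slice of a feature, unwrapped across the origin if needed.

        For L-strand features the *coding-strand* sequence is the reverse
        complement of this; see :meth:`coding_seq`.
        """
        if feat.wraps_origin:
            return self.sequence[feat.start - 1:] + self.sequence[:feat.end]
        return self.sequence[feat.start - 1:feat.end]

    def coding_seq(self, feat: GeneFeature) -> str:
        s = self.feature_seq(feat)
        if feat.strand == "L":
            return str(Seq(s).reverse_complement())
        return s

    def get(self, canonical_name: str) -> Optional[GeneFeature]:
        for f in self.features:
            if f.canonical_name == canonical_name:
                return f
        return None

    def features_of_type(self, ftype: str) -> list[GeneFeature]:
        return [f for f in self.features if f.ftype == ftype]


# ---------------------------------------------------------------------------
# gene-name canonicalization
# ---------------------------------------------------------------------------

_AA3 = {
    "F": "Phe", "V": "Val", "L": "Leu", "I": "Ile", "Q": "Gln", "M": "Met",
    "W": "Trp", "A": "Ala", "N": "Asn", "C": "Cys", "Y": "Tyr", "S": "Ser",
    "D": "Asp", "K": "Lys", "G": "Gly", "R": "Arg", "H": "His", "T": "Thr",
    "E": "Glu", "P": "Pro",
}
_AA_NAME_TO3 = {
    "phenylalanine": "Phe", "valine": "Val", "leucine": "Leu",
    "isoleucine": "Ile", "glutamine": "Gln", "methionine": "Met",
    "tryptophan": "Trp", "alanine": "Ala", "asparagine": "Asn",
    "cysteine": "Cys", "tyrosine": "Tyr", "serine": "Ser",
    "aspartate": "Asp", "aspartic acid": "Asp", "lysine": "Lys",
    "glycine": "Gly", "arginine": "Arg", "histidine": "His",
    "threonine": "Thr", "glutamate": "Glu", "glutamic acid": "Glu",
    "proline": "Pro",
}

_PCG_SYNONYMS = {
    "nd1": "Nad1", "nd2": "Nad2", "nd3": "Nad3", "nd4": "Nad4",
    "nd4l": "Nad4L", "nd5": "Nad5", "nd6": "Nad6",
    "nad1": "Nad1", "nad2": "Nad2", "nad3": "Nad3", "nad4": "Nad4",
    "nad4l": "Nad4L", "nad5": "Nad5", "nad6": "Nad6",
    "ndh1": "Nad1", "mt-nd1": "Nad1", "mt-nd2": "Nad2", "mt-nd3": "Nad3",
    "mt-nd4": "Nad4", "mt-nd4l": "Nad4L", "mt-nd5": "Nad5", "mt-nd6": "Nad6",
    "cox1": "Cox1", "cox2": "Cox2", "cox3": "Cox3",
    "coxi": "Cox1", "coxii": "Cox2", "coxiii": "Cox3",
    "co1": "Cox1", "co2": "Cox2", "co3": "Cox3",
    "coi": "Cox1", "coii": "Cox2", "coiii": "Cox3",
    "mt-co1": "Cox1", "mt-co2": "Cox2", "mt-co3": "Cox3",
    "atp6": "Atp6", "atp8": "Atp8", "atpase6": "Atp6", "atpase8": "Atp8",
    "atpase 6": "Atp6", "atpase 8": "Atp8", "mt-atp6": "Atp6", "mt-atp8": "Atp8",
    "cytb": "Cytb", "cob": "Cytb", "cyt b": "Cytb", "mt-cyb": "Cytb",
    "cyb": "Cytb",
}
_PCG_PRODUCTS = {
    "nadh dehydrogenase subunit 1": "Nad1",
    "nadh dehydrogenase subunit 2": "Nad2",
    "nadh dehydrogenase subunit 3": "Nad3",
    "nadh dehydrogenase subunit 4": "Nad4",
    "nadh dehydrogenase subunit 4l": "Nad4L",
    "nadh dehydrogenase subunit 5": "Nad5",
    "nadh dehydrogenase subunit 6": "Nad6",
    "cytochrome c oxidase subunit 1": "Cox1",
    "cytochrome c oxidase subunit 2": "Cox2",
    "cytochrome c oxidase subunit 3": "Cox3",
    "cytochrome c oxidase subunit i": "Cox1",
    "cytochrome c oxidase subunit ii": "Cox2",
    "cytochrome c oxidase subunit iii": "Cox3",
    "atp synthase f0 subunit 6": "Atp6",
    "atp synthase f0 subunit 8": "Atp8",
    "cytochrome b": "Cytb",
}
_RRNA_SYNONYMS = {
    "rrns": "rrnS", "rrnl": "rrnL", "12s": "rrnS", "16s": "rrnL",
    "12s rrna": "rrnS", "16s rrna": "rrnL", "12s ribosomal rna": "rrnS",
    "16s ribosomal rna": "rrnL", "s-rrna": "rrnS", "l-rrna": "rrnL",
    "small subunit ribosomal rna": "rrnS", "large subunit ribosomal rna": "rrnL",
    "rrn12": "rrnS", "rrn16": "rrnL", "mt-rnr1": "rrnS", "mt-rnr2": "rrnL",
    "srrna": "rrnS", "lrrna": "rrnL",
}
_CR_SYNONYMS = {
    "cr", "d-loop", "dloop", "d loop", "control region", "control-region",
    "mitochondrial control region", "putative control region",
}

# anticodon-class suffixes disambiguating the two Leu / Ser tRNAs.
_SER_CLASS = {"ucn": "tRNA-Ser1", "agy": "tRNA-Ser2", "agn": "tRNA-Ser2",
              "uca": "tRNA-Ser1", "gcu": "tRNA-Ser2", "tga": "tRNA-Ser1",
              "s1": "tRNA-Ser1", "s2": "tRNA-Ser2"}
_LEU_CLASS = {"uur": "tRNA-Leu1", "cun": "tRNA-Leu2", "uua": "tRNA-Leu1",
              "taa": "tRNA-Leu1", "uag": "tRNA-Leu2", "tag": "tRNA-Leu2",
              "l1": "tRNA-Leu1", "l2": "tRNA-Leu2"}

_TRNA_RE = re.compile(
    r"^(?:trn|mt-t|trna[-_ ]?|transfer rna[-_ ]?)\s*(.+)$", re.IGNORECASE
)


def _canonical_trna(body: str) -> str:
    """Resolve the amino-acid (and Leu/Ser class) part of a tRNA name."""
    body = body.strip().lower()
    # split off a parenthesized or dash-appended anticodon/class tag
    m = re.match(r"^([a-z]{1,13})\s*[-_(]?\s*([a-z0-9]{1,3})?\)?$", body)
    if not m:
        return UNMAPPED
    aa_part, tag = m.group(1), m.group(2)
    if len(aa_part) == 1:
        aa3 = _AA3.get(aa_part.upper())
    elif len(aa_part) == 3:
        aa3 = aa_part.capitalize() if aa_part.capitalize() in _AA3.values() else None
    else:
        aa3 = _AA_NAME_TO3.get(aa_part)
    if aa3 is None:
        return UNMAPPED
    if aa3 == "Ser":
        if tag and tag in _SER_CLASS:
            return _SER_CLASS[tag]
        n = re.search(r"([12])", body)
        if n:
            return f"tRNA-Ser{n.group(1)}"
        return UNMAPPED if tag else "tRNA-Ser2"   # bare trnS: AGY by convention
    if aa3 == "Leu":
        if tag and tag in _LEU_CLASS:
            return _LEU_CLASS[tag]
        n = re.search(r"([12])", body)
        if n:
            return f"tRNA-Leu{n.group(1)}"
        return UNMAPPED if tag else "tRNA-Leu1"   # bare trnL: UUR by convention
    return f"tRNA-{aa3}"


def canonicalize_gene_name(raw: str) -> str:
    """Map a raw annotation label onto the 37-gene vocabulary (or ``CR``).

    Case-insensitive and synonym-aware; a total function — out-of-vocabulary
    input returns the sentinel :data:`UNMAPPED`.  Idempotent on its own
    output.
    """
    if raw is None:
        return UNMAPPED
    s = str(raw).strip()
    if s in CANONICAL_NAMES:            # already canonical (idempotence)
        return s
    low = s.lower().strip(" .;")
    if low in _CR_SYNONYMS:
        return "CR"
    if low in _PCG_SYNONYMS:
        return _PCG_SYNONYMS[low]
    if low in _PCG_PRODUCTS:
        return _PCG_PRODUCTS[low]
    if low in _RRNA_SYNONYMS:
        return _RRNA_SYNONYMS[low]
    m = _TRNA_RE.match(s)
    if m:
        return _canonical_trna(m.group(1))
    return UNMAPPED


# ---------------------------------------------------------------------------
# GenBank / FASTA I/O
# ---------------------------------------------------------------------------

_GB_FTYPES = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA", "D-loop": "CR"}


def _feature_label(feat) -> Optional[str]:
    for key in ("gene", "product", "note", "standard_name"):
        if key in feat.qualifiers:
            return feat.qualifiers[key][0]
    if feat.type == "D-loop":
        return "D-loop"
    return None


def read_genbank(path) -> MitoGenome:
    """Read one annotated mitogenome from a GenBank flat file.

    Every CDS / tRNA / rRNA / D-loop feature is mapped to a canonical name;
    features whose label cannot be mapped are retained with
    ``canonical_name=UNMAPPED`` and the raw label preserved.  ``gene`` and
    ``source`` features are skipped (they duplicate the typed features).
    """
    record = SeqIO.read(str(path), "genbank")
    seq = str(record.seq).upper()
    if not seq or set(seq) == {"N"} and len(seq) == 0:
        raise ValueError(f"{path}: GenBank record has no sequence")
    topology = record.annotations.get("topology", "circular")
    if topology not in ("circular", "linear"):
        topology = "circular"
    L = len(seq)

    feats: list[GeneFeature] = []
    for gbf in record.features:
        if gbf.type not in _GB_FTYPES:
            continue
        label = _feature_label(gbf)
        canon = canonicalize_gene_name(label) if label else UNMAPPED
        if gbf.type == "D-loop":
            canon = "CR"
        ftype = _FTYPE_OF.get(canon, _GB_FTYPES[gbf.type])
        strand = "L" if gbf.location.strand == -1 else "H"
        parts = gbf.location.parts
        if len(parts) == 2 and int(parts[0].end) == L and int(parts[1].start) == 0:
            # join(x..L,1..y): wraps the origin
            start = int(parts[0].start) + 1
            end = int(parts[1].end)
            wraps = True
        else:
            start = int(gbf.location.start) + 1
            end = int(gbf.location.end)
            wraps = False
        feats.append(GeneFeature(canon, ftype, strand, start, end,
                                 wraps_origin=wraps, raw_name=label))
    if not feats:
        warnings.warn(f"{path}: no recognizable features; empty feature list")
    feats.sort(key=lambda f: (f.start, f.end))
    return MitoGenome(id=record.id or record.name, sequence=seq,
                      topology=topology, features=feats)


def read_fasta(path) -> list[MitoGenome]:
    """Read bare sequences (no annotation) from FASTA."""
    return [
        MitoGenome(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(genomes: Iterable[MitoGenome], path) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.sequence), 70):
                fh.write(g.sequence[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ("genome_id", "canonical_name", "ftype", "strand",
                  "start", "end", "length_bp")


def feature_table(genomes: Iterable[MitoGenome]):
    """Long-format feature table (one row per feature) as a DataFrame."""
    import pandas as pd

    rows = []
    for g in genomes:
        for f in sorted(g.features, key=lambda f: (f.start, f.end)):
            rows.append((g.id, f.canonical_name, f.ftype, f.strand,
                         f.start, f.end, f.length(len(g))))
    return pd.DataFrame(rows, columns=list(_TABLE_COLUMNS))


def write_feature_table(genomes: list[MitoGenome], path) -> None:
    """Write the canonical feature table as TSV, rows ordered by
    (genome id, start)."""
    df = feature_table(genomes)
    df.to_csv(path, sep="\t", index=False)


def read_feature_table(path):
    import pandas as pd

    return pd.read_csv(path, sep="\t", dtype={"genome_id": str})


def attach_features(genome: MitoGenome, table) -> MitoGenome:
    """Attach rows of a feature table (for this genome's id) to a bare genome."""
    feats = []
    L = len(genome)
    for row in table.itertuples(index=False):
        if str(row.genome_id) != genome.id:
            continue
        start, end = int(row.start), int(row.end)
        wraps = end < start
        feats.append(GeneFeature(str(row.canonical_name), str(row.ftype),
                                 str(row.strand), start, end, wraps_origin=wraps))
    feats.sort(key=lambda f: (f.start, f.end))
    return replace_features(genome, feats)


def replace_features(genome: MitoGenome, feats: list[GeneFeature]) -> MitoGenome:
    return MitoGenome(id=genome.id, sequence=genome.sequence,
                      topology=genome.topology, features=list(feats))
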