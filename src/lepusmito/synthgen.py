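"""Synthetic mitogenomes and codon alignments with machine-readable truth.

The genome generator emits a circular genome in the standard vertebrate
mitochondrial gene order — 13 protein-coding genes, 22 tRNAs, 2 rRNAs and a
control region, with Nad6 and eight tRNAs on the light strand — under a
configurable base-composition bias, with a control region assembled as
ETAS | CD | CSB around planted anchor motifs and a tandem-repeat array.
Protein-coding genes are genuine in-frame ORFs (valid start, no internal
stops, complete or truncated terminal stop), including the Atp8/Atp6
dual-frame overlap.  Every planted structure is recorded in a
:class:`GenomeTruth` so each downstream module can be scored exactly.

The alignment generator simulates codon columns down a tree under the same
MG94xHKY process the selection scan fits, with per-site rate classes
(alpha, beta- , beta+, p+) and independent per-branch category draws — the
episodic-selection regime the scan is built to detect.

All randomness flows from one master seed through named spawned streams, so
reruns are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import dendropy
import numpy as np

from .codonbias import GeneticCode
from .crdissect import CSB_MOTIFS, DEFAULT_ANCHORS, MotifSpec, scan_motif
from .mitio import GeneFeature, MitoGenome, L_STRAND_GENES
from .phylo import CodonAlignment

__all__ = [
    "GenomeSimConfig",
    "GenomeTruth",
    "AlnSimConfig",
    "SiteClass",
    "AlignmentTruth",
    "gen_mitogenome",
    "gen_codon_alignment",
    "write_genbank",
    "rotate_genome",
    "random_tree",
    "DEFAULT_GENE_PLAN",
]

_NTS = "ACGT"

#: hare-like H-strand base weights: A > T > C > G overall with A+T ~ 61%
#: and C well above G (positive AT skew, strongly negative GC skew).
DEFAULT_WEIGHTS = {"A": 0.315, "C": 0.254, "G": 0.136, "T": 0.295}

#: standard vertebrate mitochondrial gene order with plausible hare-scale
#: lengths (bp).  Strand is implied by L_STRAND_GENES.
DEFAULT_GENE_PLAN: tuple = (
    ("tRNA-Phe", "tRNA", 69), ("rrnS", "rRNA", 956), ("tRNA-Val", "tRNA", 69),
    ("rrnL", "rRNA", 1571), ("tRNA-Leu1", "tRNA", 75), ("Nad1", "PCG", 957),
    ("tRNA-Ile", "tRNA", 69), ("tRNA-Gln", "tRNA", 72), ("tRNA-Met", "tRNA", 69),
    ("Nad2", "PCG", 1044), ("tRNA-Trp", "tRNA", 69), ("tRNA-Ala", "tRNA", 69),
    ("tRNA-Asn", "tRNA", 72), ("tRNA-Cys", "tRNA", 66), ("tRNA-Tyr", "tRNA", 69),
    ("Cox1", "PCG", 1545), ("tRNA-Ser1", "tRNA", 72), ("tRNA-Asp", "tRNA", 69),
    ("Cox2", "PCG", 684), ("tRNA-Lys", "tRNA", 69), ("Atp8", "PCG", 204),
    ("Atp6", "PCG", 681), ("Cox3", "PCG", 785), ("tRNA-Gly", "tRNA", 69),
    ("Nad3", "PCG", 348), ("tRNA-Arg", "tRNA", 69), ("Nad4L", "PCG", 297),
    ("Nad4", "PCG", 1378), ("tRNA-His", "tRNA", 69), ("tRNA-Ser2", "tRNA", 60),
    ("tRNA-Leu2", "tRNA", 72), ("Nad5", "PCG", 1821), ("Nad6", "PCG", 528),
    ("tRNA-Glu", "tRNA", 69), ("Cytb", "PCG", 1140), ("tRNA-Thr", "tRNA", 69),
    ("tRNA-Pro", "tRNA", 69), ("CR", "CR", None),
)

#: GenBank-style spellings used when emitting records, so that reading them
#: back exercises real name canonicalization.
_RECORD_SPELLING = {
    "Nad1": "ND1", "Nad2": "ND2", "Nad3": "ND3", "Nad4": "ND4",
    "Nad4L": "ND4L", "Nad5": "ND5", "Nad6": "ND6", "Cox1": "COX1",
    "Cox2": "COX2", "Cox3": "COX3", "Atp6": "ATP6", "Atp8": "ATP8",
    "Cytb": "CYTB", "rrnS": "12S ribosomal RNA", "rrnL": "16S ribosomal RNA",
    "tRNA-Ser1": "trnS-UCN", "tRNA-Ser2": "trnS-AGY",
    "tRNA-Leu1": "trnL-UUR", "tRNA-Leu2": "trnL-CUN",
}


@dataclass
class GenomeSimConfig:
    """Knobs of the synthetic-genome generator (defaults = hare-like)."""

    seed: int = 0
    label: str = "synthetic"
    class_weights: dict = field(default_factory=lambda: {
        "PCG": dict(DEFAULT_WEIGHTS), "tRNA": dict(DEFAULT_WEIGHTS),
        "rRNA": dict(DEFAULT_WEIGHTS), "CR": dict(DEFAULT_WEIGHTS),
        "intergenic": dict(DEFAULT_WEIGHTS)})
    per_gene_weights: dict = field(default_factory=dict)
    codon_profile: Optional[dict] = None   # codon -> weight; None: from weights
    # CR layout
    etas_len: int = 368
    cd_len: int = 318
    csb_len: int = 914
    etas1_variant: str = "TCCCC"
    etas1_offset: int = 60                 # 1-based within ETAS
    anchors: dict = field(default_factory=lambda: dict(DEFAULT_ANCHORS))
    csb2_offset: int = 80                  # within CSB segment
    csb3_offset: int = 140
    repeat_motif: str = "CGTCTACGCGCACGTACACCCA"
    repeat_copies: int = 4
    repeat_offset: int = 200               # within CSB segment
    repeat_mut_rate: float = 0.02          # per-base, capped per copy
    repeat_max_mut_per_copy: int = 2
    # structure
    spacers: dict = field(default_factory=lambda: {("tRNA-Asn", "tRNA-Cys"): 32})
    overlaps: dict = field(default_factory=lambda: {("Atp8", "Atp6"): 43})
    incomplete_stops: dict = field(default_factory=lambda: {
        "Nad4": "T", "Cox3": "TA"})
    genome_length_target: Optional[int] = None   # adjusts csb_len if set
    rotate: int = 0                        # rotate origin (bp); CR wraps if >0


@dataclass
class GenomeTruth:
    """Everything the generator planted, for exact downstream scoring."""

    seed: int
    label: str
    genome_length: int
    features: list               # dicts: name, ftype, strand, start, end, wraps
    l_strand_count: int
    cr_start: int
    cr_end: int
    segment_lengths: dict        # ETAS/CD/CSB
    anchor_positions: dict       # motif name -> 1-based position within CR
    etas1_variant: str
    etas1_position: int
    repeat: dict                 # period, copies, consensus, phase, start (CR)
    codon_counts: dict           # realized codon counts over all PCGs
    base_counts: dict            # per-feature coding-strand ACGT counts
    spacers: dict
    overlaps: dict

    def to_json(self, path) -> None:
        d = asdict(self)
        d["spacers"] = {f"{a}|{b}": v for (a, b), v in self.spacers.items()}
        d["overlaps"] = {f"{a}|{b}": v for (a, b), v in self.overlaps.items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# low-level sequence sampling
# ---------------------------------------------------------------------------


def _sample_seq(rng: np.random.Generator, length: int, weights: dict) -> str:
    p = np.array([weights[b] for b in _NTS], dtype=float)
    p = p / p.sum()
    return "".join(rng.choice(list(_NTS), size=length, p=p))


def _codon_profile_from_weights(weights: dict, code: GeneticCode) -> dict:
    """Sense-codon profile whose realized base composition matches ``weights``.

    A plain product-of-weights profile is biased once stop codons are
    excluded (stops are A/T-rich), so the per-base weights are calibrated by
    fixed-point iteration until the expected marginal over sense codons
    equals the target composition.
    """
    target = np.array([weights[b] for b in _NTS], dtype=float)
    target = target / target.sum()
    w = target.copy()
    sense = code.sense_codons
    counts = np.array([[c.count(b) for b in _NTS] for c in sense], dtype=float)
    for _ in range(200):
        p = np.prod(np.power(w, counts), axis=1)
        p = p / p.sum()
        marg = (p @ counts) / 3.0
        if np.max(np.abs(marg - target)) < 1e-12:
            break
        w = np.clip(w * target / marg, 1e-9, None)
        w = w / w.sum()
    p = np.prod(np.power(w, counts), axis=1)
    p = p / p.sum()
    return dict(zip(sense, p))


def _sample_codons(rng: np.random.Generator, k: int, profile: dict,
                   code: GeneticCode) -> list[str]:
    codons = [c for c in profile if code.amino_acid(c) != "*"]
    p = np.array([profile[c] for c in codons], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(codons), size=k, p=p)
    return [codons[i] for i in idx]


def _gen_orf(rng: np.random.Generator, length: int, profile: dict,
             code: GeneticCode, stop_suffix: Optional[str] = None) -> str:
    """In-frame ORF: ATG + sense codons + TAA (or a truncated stop suffix)."""
    if stop_suffix:
        body_len = length - 3 - len(stop_suffix)
        if body_len % 3:
            raise ValueError(
                f"ORF length {length} incompatible with stop suffix "
                f"{stop_suffix!r}")
        body = "".join(_sample_codons(rng, body_len // 3, profile, code))
        return "ATG" + body + stop_suffix
    if length % 3:
        raise ValueError(f"complete ORF length {length} not a multiple of 3")
    body = "".join(_sample_codons(rng, length // 3 - 2, profile, code))
    return "ATG" + body + "TAA"


def _frame_codons(seq: str, offset: int = 0):
    end = offset + (len(seq) - offset) // 3 * 3
    return [seq[i:i + 3] for i in range(offset, end, 3)]


def _gen_overlapping_orfs(rng: np.random.Generator, len_a: int, len_b: int,
                          overlap: int, profile: dict, code: GeneticCode,
                          max_tries: int = 2000) -> tuple[str, str]:
    """Two overlapping ORFs (gene A then gene B) sharing ``overlap`` bp.

    Gene B's start codon sits inside gene A's tail; both reading frames must
    be stop-free through the shared stretch, with gene A ending in a genuine
    stop.  Built by rejection sampling of gene A's constrained tail.
    """
    stops = code.stop_codons
    tail_cod_start = (len_a - overlap - 1) // 3      # first codon touching B
    tail_nt0 = tail_cod_start * 3
    n_tail = len_a // 3 - tail_cod_start
    b_start_in_a = len_a - overlap                    # 0-based
    for _ in range(max_tries):
        tail = list("".join(_sample_codons(rng, n_tail, profile, code)))
        # final codon of A = stop
        tail[-3:] = "TAA"
        # plant B's ATG
        off = b_start_in_a - tail_nt0
        tail[off:off + 3] = "ATG"
        t = "".join(tail)
        a_codons = _frame_codons(t)[:-1]
        if any(c in stops for c in a_codons):
            continue
        b_codons = _frame_codons(t, off)[1:]          # B's codons after ATG
        if any(c in stops for c in b_codons):
            continue
        head = "".join(_sample_codons(rng, tail_cod_start - 1, profile, code))
        seq_a = "ATG" + head + t
        assert len(seq_a) == len_a
        # gene B: overlap prefix + fresh body + stop
        prefix = seq_a[b_start_in_a:]
        rem = len(prefix) % 3
        partial = prefix[len(prefix) - rem:] if rem else ""
        filled = partial
        if rem:
            # complete the straddling codon avoiding stops
            for _ in range(50):
                ext = "".join(rng.choice(list(_NTS), size=3 - rem))
                if partial + ext not in stops:
                    filled = partial + ext
                    break
            prefix_full = prefix[:len(prefix) - rem] + filled
        else:
            prefix_full = prefix
        n_body = (len_b - len(prefix_full)) // 3 - 1
        if n_body < 0 or (len_b - len(prefix_full)) % 3:
            raise ValueError("incompatible overlap geometry")
        body = "".join(_sample_codons(rng, n_body, profile, code))
        seq_b = prefix_full + body + "TAA"
        assert len(seq_b) == len_b
        return seq_a, seq_b
    raise RuntimeError("overlap ORF sampling did not converge")


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# control region assembly
# ---------------------------------------------------------------------------


def _mutate_copy(rng: np.random.Generator, motif: str, rate: float,
                 cap: int) -> tuple[str, int]:
    n_mut = min(int(rng.binomial(len(motif), rate)), cap)
    if n_mut == 0:
        return motif, 0
    pos = rng.choice(len(motif), size=n_mut, replace=False)
    s = list(motif)
    for p in pos:
        s[p] = rng.choice([b for b in _NTS if b != s[p]])
    return "".join(s), n_mut


def _assemble_cr(rng: np.random.Generator, cfg: GenomeSimConfig,
                 weights: dict) -> tuple[str, dict]:
    """Build ETAS|CD|CSB with planted anchors; returns (seq, truth dict)."""
    anchors = cfg.anchors
    csb1 = anchors.get("CSB1", CSB_MOTIFS["CSB1"])
    csb_f = anchors["CSB-F"]
    guard_specs = [MotifSpec("CSB-F", csb_f),
                   MotifSpec("CSB1", csb1)] + \
                  [MotifSpec(v, v, 0) for v in ("TCCCC", "ACCCC", "GCCCC")]

    array = []
    per_copy = []
    for _ in range(cfg.repeat_copies):
        c, m = _mutate_copy(rng, cfg.repeat_motif, cfg.repeat_mut_rate,
                            cfg.repeat_max_mut_per_copy)
        array.append(c)
        per_copy.append(m)
    array_seq = "".join(array)

    period = len(cfg.repeat_motif)
    need = cfg.repeat_offset - 1 + len(array_seq)
    if cfg.csb_len < need + 10:
        raise ValueError("csb_len too small for the configured repeat array")

    plant_csb = {
        1: csb1,
        cfg.csb2_offset: CSB_MOTIFS["CSB2"],
        cfg.csb3_offset: CSB_MOTIFS["CSB3"],
        cfg.repeat_offset: array_seq,
    }

    etas = list(_sample_seq(rng, cfg.etas_len, weights))
    etas[cfg.etas1_offset - 1:cfg.etas1_offset - 1 + 5] = cfg.etas1_variant
    cd = list(_sample_seq(rng, cfg.cd_len, weights))
    cd[:len(csb_f)] = csb_f
    csb = list(_sample_seq(rng, cfg.csb_len, weights))
    for off, motif in sorted(plant_csb.items()):
        if off + len(motif) - 1 > cfg.csb_len:
            raise ValueError("CSB motif layout exceeds csb_len")
        csb[off - 1:off - 1 + len(motif)] = motif
    seq = list("".join(etas) + "".join(cd) + "".join(csb))

    # positions belonging to planted structure must never be resampled
    protected = set(range(cfg.etas1_offset - 1, cfg.etas1_offset + 4))
    protected |= set(range(cfg.etas_len, cfg.etas_len + len(csb_f)))
    csb0 = cfg.etas_len + cfg.cd_len
    for off, motif in plant_csb.items():
        protected |= set(range(csb0 + off - 1, csb0 + off - 1 + len(motif)))

    p = np.array([weights[b] for b in _NTS], dtype=float)
    p = p / p.sum()
    for _ in range(500):
        bad = _first_violation(
            "".join(seq), cfg, guard_specs)
        if bad is None:
            break
        lo, hi = bad            # 0-based half-open window of the bad hit
        free = [k for k in range(lo, hi) if k not in protected]
        if not free:
            raise RuntimeError(
                "planted CR motifs conflict with the anchor configuration")
        for k in free:
            seq[k] = str(rng.choice(list(_NTS), p=p))
    else:
        raise RuntimeError("CR assembly failed to avoid spurious anchor hits")
    seq = "".join(seq)

    cd_start = cfg.etas_len + 1
    csb_start = cfg.etas_len + cfg.cd_len + 1
    truth = {
        "segment_lengths": {"ETAS": cfg.etas_len, "CD": cfg.cd_len,
                            "CSB": cfg.csb_len},
        "anchor_positions": {"CSB-F": cd_start, "CSB1": csb_start,
                             "CSB2": csb_start + cfg.csb2_offset - 1,
                             "CSB3": csb_start + cfg.csb3_offset - 1},
        "etas1_variant": cfg.etas1_variant,
        "etas1_position": cfg.etas1_offset,
        "repeat": {
            "period": period,
            "copies": cfg.repeat_copies,
            "consensus": cfg.repeat_motif,
            "start": csb_start + cfg.repeat_offset - 1,
            "per_copy_mutations": per_copy,
        },
    }
    return seq, truth


def _first_violation(seq: str, cfg: GenomeSimConfig,
                     guards: list) -> Optional[tuple[int, int]]:
    """First anchor-like hit outside its planted position, as a 0-based
    half-open window, or None if the CR is clean.

    Spurious CSB-F hits anywhere, CSB1 hits upstream of the planted CSB
    start, and ETAS1-variant pentamers inside the ETAS other than the
    planted one would derail partitioning, so they count as violations;
    motif look-alikes downstream of their anchors are harmless.
    """
    cd_start = cfg.etas_len + 1
    csb_start = cfg.etas_len + cfg.cd_len + 1
    allowed = {"CSB-F": {cd_start}, "CSB1": {csb_start}}
    for spec in guards:
        for h in scan_motif(seq, spec):
            if spec.name in ("TCCCC", "ACCCC", "GCCCC"):
                if h.position >= cd_start:
                    continue
                if spec.pattern == cfg.etas1_variant and \
                        h.position == cfg.etas1_offset:
                    continue
                return h.position - 1, h.position - 1 + len(spec.pattern)
            if h.position in allowed[spec.name]:
                continue
            if spec.name == "CSB1" and h.position > csb_start:
                continue
            return h.position - 1, h.position - 1 + len(spec.pattern)
    return None


# ---------------------------------------------------------------------------
# whole-genome assembly
# ---------------------------------------------------------------------------


def gen_mitogenome(cfg: Optional[GenomeSimConfig] = None
                   ) -> tuple[MitoGenome, GenomeTruth]:
    """Generate one annotated circular mitogenome plus its ground truth."""
    cfg = cfg or GenomeSimConfig()
    code = GeneticCode.vertebrate_mito()
    master = np.random.SeedSequence(cfg.seed)
    s_genes, s_cr, s_spacer = master.spawn(3)
    rng_g = np.random.default_rng(s_genes)
    rng_cr = np.random.default_rng(s_cr)
    rng_sp = np.random.default_rng(s_spacer)

    plan = [list(item) for item in DEFAULT_GENE_PLAN]
    csb_len = cfg.csb_len
    if cfg.genome_length_target is not None:
        base = _planned_length(cfg, csb_len=0)
        csb_len = cfg.genome_length_target - base
        if csb_len < cfg.repeat_offset + len(cfg.repeat_motif) * \
                cfg.repeat_copies + 20:
            raise ValueError("genome_length_target too small for CR layout")
    cfg_cr = cfg if csb_len == cfg.csb_len else _with_csb_len(cfg, csb_len)

    # generate per-gene coding sequences
    gene_seqs: dict[str, str] = {}
    cr_truth: dict = {}
    profile = cfg.codon_profile or _codon_profile_from_weights(
        cfg.class_weights["PCG"], code)
    pending_overlap = dict(cfg.overlaps)
    i = 0
    names = [p[0] for p in plan]
    while i < len(plan):
        name, ftype, length = plan[i]
        weights = cfg.per_gene_weights.get(
            name, cfg.class_weights.get(ftype, DEFAULT_WEIGHTS))
        if ftype == "CR":
            seq, cr_truth = _assemble_cr(rng_cr, cfg_cr, weights)
            gene_seqs[name] = seq
            plan[i][2] = len(seq)
        elif ftype == "PCG":
            nxt = names[i + 1] if i + 1 < len(plan) else None
            if nxt and (name, nxt) in pending_overlap:
                ov = pending_overlap[(name, nxt)]
                sa, sb = _gen_overlapping_orfs(
                    rng_g, length, plan[i + 1][2], ov, profile, code)
                gene_seqs[name] = sa
                gene_seqs[nxt] = sb
                i += 1            # the pair is done; skip the partner
            elif name not in gene_seqs:
                suffix = cfg.incomplete_stops.get(name)
                gene_seqs[name] = _gen_orf(rng_g, length, profile, code,
                                           stop_suffix=suffix)
        else:
            gene_seqs[name] = _sample_seq(rng_g, length, weights)
        i += 1

    # lay features on the circle
    seq_parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 1                        # next free 1-based position
    spacers_truth: dict = {}
    overlaps_truth: dict = {}
    prev_name = None
    for name, ftype, length in [(p[0], p[1], len(gene_seqs[p[0]]))
                                for p in plan]:
        if prev_name is not None:
            sp = cfg.spacers.get((prev_name, name), 0)
            if sp:
                seq_parts.append(_sample_seq(rng_sp, sp, cfg.class_weights.get(
                    "intergenic", DEFAULT_WEIGHTS)))
                spacers_truth[(prev_name, name)] = sp
                pos += sp
            ov = cfg.overlaps.get((prev_name, name), 0)
        else:
            ov = 0
        strand = "L" if name in L_STRAND_GENES else "H"
        coding = gene_seqs[name]
        placed = coding if strand == "H" else _revcomp(coding)
        if ov:
            # the first ov bases of this gene are already on the genome
            seq_parts.append(placed[ov:])
            start = pos - ov
            overlaps_truth[(prev_name, name)] = ov
            pos = start + length
        else:
            seq_parts.append(placed)
            start = pos
            pos = start + length
        features.append(GeneFeature(name, ftype, strand, start, pos - 1))
        prev_name = name

    sequence = "".join(seq_parts)
    L = len(sequence)
    genome = MitoGenome(id=cfg.label, sequence=sequence, topology="circular",
                        features=features)
    if cfg.rotate:
        genome = rotate_genome(genome, cfg.rotate)

    cr_feat = genome.get("CR")
    codon_counts = _realized_codon_counts(genome)
    bc = {}
    for f in genome.features:
        s = genome.coding_seq(f)
        bc[f.canonical_name] = {b: s.count(b) for b in _NTS}
    truth = GenomeTruth(
        seed=cfg.seed, label=cfg.label, genome_length=L,
        features=[{
            "name": f.canonical_name, "ftype": f.ftype, "strand": f.strand,
            "start": f.start, "end": f.end, "wraps": f.wraps_origin,
        } for f in genome.features],
        l_strand_count=sum(1 for f in genome.features if f.strand == "L"),
        cr_start=cr_feat.start, cr_end=cr_feat.end,
        segment_lengths=cr_truth["segment_lengths"],
        anchor_positions=cr_truth["anchor_positions"],
        etas1_variant=cr_truth["etas1_variant"],
        etas1_position=cr_truth["etas1_position"],
        repeat=cr_truth["repeat"],
        codon_counts=codon_counts, base_counts=bc,
        spacers=spacers_truth, overlaps=overlaps_truth)
    return genome, truth


def _with_csb_len(cfg: GenomeSimConfig, csb_len: int) -> GenomeSimConfig:
    import copy

    c = copy.deepcopy(cfg)
    c.csb_len = csb_len
    return c


def _planned_length(cfg: GenomeSimConfig, csb_len: Optional[int] = None) -> int:
    total = 0
    for name, ftype, length in DEFAULT_GENE_PLAN:
        if ftype == "CR":
            total += cfg.etas_len + cfg.cd_len + \
                (cfg.csb_len if csb_len is None else csb_len)
        else:
            total += length
    total += sum(cfg.spacers.values())
    total -= sum(cfg.overlaps.values())
    return total


def _realized_codon_counts(genome: MitoGenome) -> dict:
    """Codon tally over PCG coding strands with truncated stops completed,
    mirroring what an exact codon extractor should recover."""
    counts: dict[str, int] = {}
    for f in genome.features_of_type("PCG"):
        seq = genome.coding_seq(f)
        r = len(seq) % 3
        if r == 1 and seq.endswith("T"):
            seq += "AA"
        elif r == 2 and seq.endswith("TA"):
            seq += "A"
        for i in range(0, len(seq) - len(seq) % 3, 3):
            c = seq[i:i + 3]
            counts[c] = counts.get(c, 0) + 1
    return counts


def gen_genome_family(n: int, seed: int = 0, divergence: float = 0.02,
                      cfg: Optional[GenomeSimConfig] = None
                      ) -> tuple[list[MitoGenome], GenomeTruth]:
    """A set of related genomes: one ancestor plus point-mutated derivatives.

    Every derived genome keeps the ancestor's coordinates and annotation.
    Mutations are rejected where they would break biology the downstream
    stages rely on: PCG start/stop codons, internal stop creation, and the
    planted CR anchor motifs are protected.  Indels are not simulated, so
    the family is trivially alignable — by design, since the family exists
    to exercise multi-genome stages, not the aligner.
    """
    cfg = cfg or GenomeSimConfig(seed=seed, label="SYN01")
    base, truth = gen_mitogenome(cfg)
    code = GeneticCode.vertebrate_mito()
    stops = code.stop_codons
    L = len(base)

    protected = set()
    cr0 = base.get("CR").start - 1          # CR never wraps pre-rotation
    for name, pos in truth.anchor_positions.items():
        pat = cfg.anchors.get(name, CSB_MOTIFS.get(name, ""))
        width = len(pat) if pat else 17
        protected |= set(range(cr0 + pos - 1, cr0 + pos - 1 + width))
    protected |= set(range(cr0 + truth.etas1_position - 1,
                           cr0 + truth.etas1_position + 4))
    for f in base.features_of_type("PCG"):
        protected |= {f.start - 1, f.start, f.start + 1,
                      f.end - 3, f.end - 2, f.end - 1}

    genomes = [base]
    streams = np.random.SeedSequence(seed).spawn(n)
    for k in range(1, n):
        rng = np.random.default_rng(streams[k])
        seq = list(base.sequence)
        n_mut = rng.binomial(L, divergence)
        sites = rng.choice(L, size=n_mut, replace=False)
        for s in sites:
            if s in protected:
                continue
            seq[s] = rng.choice([b for b in _NTS if b != seq[s]])
        # repair any internal stop created in a PCG reading frame
        g = MitoGenome(id=f"SYN{k + 1:02d}", sequence="".join(seq),
                       topology="circular", features=list(base.features))
        for f in g.features_of_type("PCG"):
            coding = g.coding_seq(f)
            nn = len(coding) - len(coding) % 3
            for i in range(3, nn - 3, 3):
                if coding[i:i + 3] in stops:
                    orig = base.coding_seq(f)[i:i + 3]
                    if f.strand == "H":
                        lo = f.start - 1 + i
                        seq[lo:lo + 3] = orig
                    else:
                        hi = f.end - i          # 1-based end of codon on H
                        seq[hi - 3:hi] = _revcomp(orig)
        genomes.append(MitoGenome(id=f"SYN{k + 1:02d}", sequence="".join(seq),
                                  topology="circular",
                                  features=list(base.features)))
    return genomes, truth


def gen_repeat_case(seed: int, period: Optional[int] = None,
                    copies: Optional[int] = None,
                    max_mut_per_copy: int = 2,
                    flank: tuple[int, int] = (50, 300)) -> dict:
    """One planted tandem-repeat instance for scoring the repeat finder.

    The motif is drawn i.i.d. but rejected if it is itself nearly periodic
    (some shorter shift matches within twice the per-copy budget), so the
    planted period is the motif's minimal period and 'recovering the period'
    is well-posed.  Returns the sequence plus the planted truth.
    """
    rng = np.random.default_rng(seed)
    period = period or int(rng.integers(10, 31))
    copies = copies or int(rng.integers(3, 16))
    for _ in range(200):
        motif = "".join(rng.choice(list(_NTS), size=period))
        nearly_periodic = False
        for p2 in range(1, period):
            d = sum(motif[i] != motif[(i + p2) % period] for i in range(period))
            if d <= 4:
                nearly_periodic = True
                break
        if not nearly_periodic:
            break
    arr = []
    for _ in range(copies):
        c = list(motif)
        nm = int(rng.integers(0, max_mut_per_copy + 1))
        for pos in rng.choice(period, size=nm, replace=False):
            c[pos] = rng.choice([b for b in _NTS if b != c[pos]])
        arr.append("".join(c))
    left = "".join(rng.choice(list(_NTS), size=int(rng.integers(*flank))))
    right = "".join(rng.choice(list(_NTS), size=int(rng.integers(*flank))))
    return {
        "sequence": left + "".join(arr) + right,
        "period": period, "copies": copies, "motif": motif,
        "array_start": len(left) + 1,
        "array_end": len(left) + copies * period,
    }


def rotate_genome(genome: MitoGenome, offset: int) -> MitoGenome:
    """Rotate a circular genome's origin forward by ``offset`` bp.

    Features crossing the new origin become origin-wrapping.
    """
    L = len(genome)
    offset %= L
    if offset == 0:
        return genome
    seq = genome.sequence[offset:] + genome.sequence[:offset]
    feats = []
    for f in genome.features:
        ln = f.length(L)
        start = (f.start - offset - 1) % L + 1
        end = (start + ln - 2) % L + 1
        feats.append(GeneFeature(f.canonical_name, f.ftype, f.strand,
                                 start, end, wraps_origin=end < start,
                                 raw_name=f.raw_name))
    feats.sort(key=lambda f: (f.start, f.end))
    return MitoGenome(id=genome.id, sequence=seq, topology="circular",
                      features=feats)


# ---------------------------------------------------------------------------
# GenBank emission
# ---------------------------------------------------------------------------


def write_genbank(genome: MitoGenome, path) -> None:
    """Emit a minimal but valid GenBank record (LOCUS/FEATURES/ORIGIN)."""
    from Bio.SeqFeature import (CompoundLocation, FeatureLocation, SeqFeature)
    from Bio.SeqRecord import SeqRecord
    from Bio.Seq import Seq
    from Bio import SeqIO

    L = len(genome)
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                    description="synthetic mitochondrial genome")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = genome.topology
    for f in sorted(genome.features, key=lambda f: (f.start, f.end)):
        strand = -1 if f.strand == "L" else 1
        if f.wraps_origin:
            loc = CompoundLocation([
                FeatureLocation(f.start - 1, L, strand=strand),
                FeatureLocation(0, f.end, strand=strand)])
        else:
            loc = FeatureLocation(f.start - 1, f.end, strand=strand)
        if f.ftype == "CR":
            rec.features.append(SeqFeature(loc, type="D-loop"))
            continue
        gbtype = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}[f.ftype]
        label = _RECORD_SPELLING.get(f.canonical_name, f.canonical_name)
        qual = {"gene": [label]} if gbtype == "CDS" else {"product": [label]}
        rec.features.append(SeqFeature(loc, type=gbtype, qualifiers=qual))
    SeqIO.write([rec], str(path), "genbank")


# ---------------------------------------------------------------------------
# codon alignment simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteClass:
    """One rate class: (proportion, alpha, beta-, beta+, p+)."""

    proportion: float
    alpha: float
    beta_minus: float
    beta_plus: float
    p_plus: float

    def __post_init__(self):
        if min(self.alpha, self.beta_minus, self.beta_plus) < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.p_plus <= 1.0:
            raise ValueError("p_plus must lie in [0,1]")


@dataclass
class AlnSimConfig:
    seed: int = 0
    tree: str = ""                       # newick; required
    kappa: float = 2.0
    n_sites: int = 300
    site_classes: tuple = (SiteClass(1.0, 1.0, 1.0, 1.0, 0.0),)
    nt_weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    pi: Optional[np.ndarray] = None      # sense-codon freqs; None: from weights
    #: if True, each class's beta+ branches are one fixed subset of round
    #: (p_plus * n_branches) branches shared by all its sites (episodic
    #: selection on named lineages); if False, branches are drawn
    #: independently per site and branch with probability p_plus
    fixed_branch_selection: bool = False


@dataclass
class AlignmentTruth:
    seed: int
    n_sites: int
    site_class: list                 # per-site class index
    classes: list                    # SiteClass dicts
    kappa: float
    tree: str

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def gen_codon_alignment(cfg: AlnSimConfig
                        ) -> tuple[CodonAlignment, dendropy.Tree,
                                   AlignmentTruth]:
    """Simulate a codon alignment down a tree under MG94xHKY site classes.

    Each site draws a rate class; on every branch the non-synonymous rate is
    beta+ with probability p+ (independently per site and branch), beta-
    otherwise.  Branch lengths are expected substitutions per codon site at
    rates (alpha, beta) = (1, 1).  Deterministic under the seed.
    """
    from .selscan import MG94Machinery, _TreeIndex

    if not cfg.tree:
        raise ValueError("AlnSimConfig.tree (newick) is required")
    code = GeneticCode.vertebrate_mito()
    machinery = MG94Machinery(code)
    tree = dendropy.Tree.get(data=cfg.tree, schema="newick")
    taxa = tuple(sorted(leaf.taxon.label for leaf in tree.leaf_node_iter()))
    if len(taxa) < 2:
        raise ValueError("tree must have at least 2 leaves")
    tindex = _TreeIndex(tree, taxa)
    if np.all(tindex.get_lengths() == 0.0):
        import warnings as _w

        _w.warn("all branch lengths are zero: degenerate alignment")

    props = np.array([c.proportion for c in cfg.site_classes], dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("site-class proportions must sum to 1")

    if cfg.pi is not None:
        pi = np.asarray(cfg.pi, dtype=float)
        pi = pi / pi.sum()
    else:
        prof = _codon_profile_from_weights(cfg.nt_weights, code)
        pi = np.array([prof[c] for c in machinery.codons])
        pi = pi / pi.sum()

    Qs, Qn = machinery.components(cfg.kappa, pi)
    c_norm = machinery.normalizer(Qs, Qn, pi, 1.0)
    Qs, Qn = Qs / c_norm, Qn / c_norm

    t = tindex.lengths                      # per-node subtending branch
    # per class and category, transition matrices for every branch
    P_cat = {}
    for ci, sc in enumerate(cfg.site_classes):
        for cat, beta in ((0, sc.beta_minus), (1, sc.beta_plus)):
            Q = sc.alpha * Qs + beta * Qn
            P = machinery.transition_matrices(Q, pi, t)
            P_cat[(ci, cat)] = np.cumsum(P, axis=2)   # row CDFs

    master = np.random.SeedSequence(cfg.seed)
    s_class, s_evo = master.spawn(2)
    rng_c = np.random.default_rng(s_class)
    rng_e = np.random.default_rng(s_evo)

    n = machinery.n
    site_class = rng_c.choice(len(cfg.site_classes), size=cfg.n_sites, p=props)
    root_states = rng_c.choice(n, size=cfg.n_sites, p=pi)

    selected_edges: dict[int, set] = {}
    if cfg.fixed_branch_selection:
        edges = [e for e in tindex.edges]
        for ci, sc in enumerate(cfg.site_classes):
            k = int(round(sc.p_plus * len(edges)))
            chosen = rng_c.choice(len(edges), size=k, replace=False) \
                if k else np.array([], dtype=int)
            selected_edges[ci] = {edges[int(x)] for x in chosen}

    preorder = list(reversed(tindex.postorder))
    states = np.zeros((tindex.n_nodes, cfg.n_sites), dtype=int)
    states[tindex.root] = root_states
    parent_of = np.full(tindex.n_nodes, -1)
    for i in tindex.postorder:
        for ch in tindex.children[i]:
            parent_of[ch] = i
    for node in preorder:
        if node == tindex.root:
            continue
        par = states[parent_of[node]]
        u_cat = rng_e.random(cfg.n_sites)
        u_state = rng_e.random(cfg.n_sites)
        out = np.zeros(cfg.n_sites, dtype=int)
        for k in range(cfg.n_sites):
            sc = cfg.site_classes[site_class[k]]
            if cfg.fixed_branch_selection:
                cat = 1 if node in selected_edges[site_class[k]] else 0
            else:
                cat = 1 if u_cat[k] < sc.p_plus else 0
            cdf = P_cat[(site_class[k], cat)][node, par[k]]
            out[k] = int(np.searchsorted(cdf, u_state[k] * cdf[-1],
                                         side="right"))
        states[node] = np.minimum(out, n - 1)

    rows = {}
    for i in range(tindex.n_nodes):
        ti = tindex.leaf_taxon[i]
        if ti is not None:
            rows[taxa[ti]] = [machinery.codons[s] for s in states[i]]
    aln = CodonAlignment(taxa=taxa, rows=rows,
                         genes=["sim"] * cfg.n_sites,
                         codon_index=list(range(1, cfg.n_sites + 1)),
                         reference=taxa[0])
    truth = AlignmentTruth(seed=cfg.seed, n_sites=cfg.n_sites,
                           site_class=[int(x) for x in site_class],
                           classes=[asdict(c) for c in cfg.site_classes],
                           kappa=cfg.kappa, tree=cfg.tree)
    return aln, tree, truth


def random_tree(n_taxa: int, seed: int = 0, mean_branch: float = 0.25,
                min_internal: float = 0.05) -> dendropy.Tree:
    """Random binary tree by successive joins, exponential branch lengths."""
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    nodes = []
    for i in range(n_taxa):
        taxon = tns.new_taxon(f"T{i + 1:02d}")
        nd = dendropy.Node(taxon=taxon)
        nd.edge.length = max(float(rng.exponential(mean_branch)), min_internal)
        nodes.append(nd)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = max(float(rng.exponential(mean_branch)),
                                 min_internal)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = dendropy.Node()
    for nd in nodes:
        root.add_child(nd)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree
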