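"""Quadripartite plastome structure detection.

Land-plant and fern plastomes are circular molecules of roughly 120-170 kb
organised as a large single-copy region (LSC), a small single-copy region
(SSC), and two identical inverted repeats (IRa/IRb) separating them.  This
module locates the maximal inverted repeat on a circular sequence, derives
the LSC/IRa/SSC/IRb partition on a canonical rotation, and produces the
one-IR-removed linear sequence conventionally used for whole-plastome
alignment.

Coordinates are 0-based half-open internally; rendered reports use 1-based
inclusive spans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CircularGenome",
    "Span",
    "QuadripartitePartition",
    "find_maximal_inverted_repeat",
    "partition_quadripartite",
    "gc_content",
    "remove_one_ir",
    "summarize_genbank_record",
    "read_genomes",
]

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-"
)

IUPAC_CODES = set("ACGTRYSWKMBDHVN")
UNAMBIGUOUS = set("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement over the IUPAC alphabet (gaps preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Span:
    """0-based half-open interval on a (possibly circular) sequence.

    ``start`` lies in [0, genome length); ``length`` may wrap past the
    origin on circular molecules.
    """

    start: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length

    def to_1based(self) -> tuple[int, int]:
        return (self.start + 1, self.start + self.length)


@dataclass
class CircularGenome:
    """A circular nucleotide sequence with optional feature annotations."""

    id: str
    residues: str
    is_circular: bool = True
    features: list[tuple[str, Span, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.residues:
            raise ValueError(f"genome {self.id!r} is empty")
        bad = set(self.residues) - IUPAC_CODES
        if bad:
            raise ValueError(
                f"genome {self.id!r} contains non-IUPAC residues: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def slice(self, span: Span) -> str:
        """Extract a span, wrapping past the origin when circular."""
        L = len(self.residues)
        if span.end <= L:
            return self.residues[span.start : span.end]
        if not self.is_circular:
            raise ValueError("span wraps origin on a linear sequence")
        return self.residues[span.start :] + self.residues[: span.end - L]


@dataclass
class QuadripartitePartition:
    """LSC/IRa/SSC/IRb intervals on the canonical rotation.

    The canonical rotation places the LSC at position 0 with block order
    LSC-IRa-SSC-IRb; ``rotation_offset`` is the original coordinate of
    canonical position 0.  The identity
    ``lsc.length + ssc.length + 2 * ira.length == genome length`` holds for
    every successful partition.
    """

    lsc: Span
    ira: Span
    ssc: Span
    irb: Span
    rotation_offset: int
    mismatches: int = 0

    @property
    def total(self) -> int:
        return self.lsc.length + self.ssc.length + self.ira.length + self.irb.length

    def sizes(self) -> dict[str, int]:
        return {
            "lsc": self.lsc.length,
            "ssc": self.ssc.length,
            "ir": self.ira.length,
            "total": self.total,
        }


class StructureError(ValueError):
    """Raised when structure detection preconditions fail."""


def _match(a: str, b: str) -> bool:
    # Ambiguity codes never match in IR extension: only unambiguous
    # complementary pairs count.
    pair = a + b
    return pair in ("AT", "TA", "GC", "CG")


def find_maximal_inverted_repeat(
    genome: CircularGenome,
    min_len: int = 1000,
    max_mismatch: int = 0,
    seed_k: int = 21,
) -> Optional[tuple[Span, Span]]:
    """Locate the longest inverted-repeat pair on a circular genome.

    Seed-and-extend on the doubled sequence: exact ``seed_k``-mer matches
    against the reverse complement seed candidate anti-diagonals, each of
    which is then extended outward from its palindromic centre under the
    mismatch budget.  Returns the two spans (IRa first by start coordinate,
    both as spans on the original coordinates) or ``None`` when no pair of
    length >= ``min_len`` exists.

    The two copies must be disjoint on the circle; a best pair that
    self-overlaps (a purely palindromic sequence) yields ``None``.
    """
    if min_len < 100:
        raise StructureError("min_len must be >= 100")
    L = len(genome)
    if L <= 2 * min_len:
        raise StructureError(
            f"genome length {L} too short for min_len {min_len}"
        )
    seq = genome.residues
    D = seq + seq if genome.is_circular else seq
    nD = len(D)
    rc = revcomp(D)

    # index k-mers of the reverse complement
    index: dict[str, list[int]] = {}
    for m in range(nD - seed_k + 1):
        kmer = rc[m : m + seed_k]
        index.setdefault(kmer, []).append(m)

    # anti-diagonal c -> intervals of p already covered by an extension
    seen: dict[int, list[tuple[int, int]]] = {}
    best: Optional[tuple[int, int, int]] = None  # (length, a_start, b_start)

    for i in range(nD - seed_k + 1):
        hits = index.get(D[i : i + seed_k])
        if not hits:
            continue
        for m in hits:
            j = nD - m - seed_k  # partner start in D coordinates
            # Position p on anti-diagonal c pairs with position c-1-p.
            c = i + j + seed_k
            covered = seen.setdefault(c, [])
            if any(lo <= i <= hi for lo, hi in covered):
                continue
            lo, hi = _extend_from_seed(D, c, i, i + seed_k - 1, max_mismatch)
            covered.append((lo, hi))
            length = hi - lo + 1
            if length < min_len:
                continue
            a0, b0 = lo, c - 1 - hi
            # both copies must fit within one genome circumference
            if a0 >= L or (b0 + length) - a0 > L:
                continue
            if best is None or length > best[0]:
                best = (length, a0, b0)

    if best is None:
        return None
    length, a0, b0 = best
    gap_inner = (b0 - (a0 + length)) % L
    gap_outer = (a0 - (b0 + length)) % L
    if gap_inner == 0 and gap_outer == 0:
        import warnings

        warnings.warn(
            f"genome {genome.id!r}: best inverted-repeat pair is a full "
            "palindrome with no single-copy arcs; reporting none"
        )
        return None
    span_a = Span(a0 % L, length)
    span_b = Span(b0 % L, length)
    return (span_a, span_b)


def _extend_from_seed(
    D: str, c: int, seed_lo: int, seed_hi: int, max_mismatch: int
) -> tuple[int, int]:
    """Maximal run containing the seed on anti-diagonal ``c``.

    Position p of the first copy pairs with c-1-p of the second; the seed
    occupies [seed_lo, seed_hi] and matches exactly.  Extension grows
    toward the centre (p increasing, capped so the copies stay disjoint)
    and away from it (p decreasing), spending the shared mismatch budget
    greedily inward first; with the default budget 0 the run is the exact
    maximal repeat.  Both ends are trimmed to matching positions.
    """
    p_cap = (c - 2) // 2  # highest p with p < c-1-p (disjoint copies)
    budget = max_mismatch
    hi = seed_hi
    p = seed_hi + 1
    while p <= p_cap:
        if _match(D[p], D[c - 1 - p]):
            hi = p
        else:
            if budget == 0:
                break
            budget -= 1
        p += 1
    lo = seed_lo
    p = seed_lo - 1
    while p >= 0 and c - 1 - p < len(D):
        if _match(D[p], D[c - 1 - p]):
            lo = p
        else:
            if budget == 0:
                break
            budget -= 1
        p -= 1
    return lo, hi


def partition_quadripartite(
    genome: CircularGenome, ir: tuple[Span, Span]
) -> QuadripartitePartition:
    """Label the two inter-IR arcs LSC (longer) and SSC (shorter).

    The partition is reported on the canonical rotation (LSC start = 0,
    order LSC-IRa-SSC-IRb); sizes always sum to the genome length.
    """
    L = len(genome)
    a, b = ir
    ir_len = a.length
    if a.length != b.length:
        raise StructureError("IR copies differ in length")

    def arc(from_end: int, to_start: int) -> Span:
        gap = (to_start - from_end) % L
        return Span(from_end % L, gap)

    arc1 = arc(a.end, b.start)  # between IRa end and IRb start
    arc2 = arc(b.end, a.start)
    if arc1.length == arc2.length:
        # deterministic label by lexicographic arc sequence
        s1 = genome.slice(arc1)
        s2 = genome.slice(arc2)
        if s1 <= s2:
            lsc_arc, ssc_arc, ir_first, ir_second = arc2, arc1, b, a
        else:
            lsc_arc, ssc_arc, ir_first, ir_second = arc1, arc2, a, b
    elif arc1.length > arc2.length:
        # arc1 is LSC: order around circle is IRa, LSC ... so canonical IRa
        # is the copy following the LSC: b
        lsc_arc, ssc_arc, ir_first, ir_second = arc1, arc2, b, a
    else:
        lsc_arc, ssc_arc, ir_first, ir_second = arc2, arc1, a, b

    rotation_offset = lsc_arc.start
    lsc = Span(0, lsc_arc.length)
    ira = Span(lsc.length, ir_len)
    ssc = Span(ira.end, ssc_arc.length)
    irb = Span(ssc.end, ir_len)
    mismatches = sum(
        x != y
        for x, y in zip(genome.slice(ir_first), revcomp(genome.slice(ir_second)))
    )
    part = QuadripartitePartition(
        lsc=lsc,
        ira=ira,
        ssc=ssc,
        irb=irb,
        rotation_offset=rotation_offset,
        mismatches=mismatches,
    )
    if part.total != L:
        raise StructureError(
            f"partition sizes {part.sizes()} do not sum to genome length {L}"
        )
    return part


def gc_content(sequence: str | CircularGenome) -> float:
    """(G+C)/(A+C+G+T); ambiguity codes excluded from both terms."""
    seq = sequence.residues if isinstance(sequence, CircularGenome) else sequence
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return gc / (gc + at)


def canonical_rotation(genome: CircularGenome, partition: QuadripartitePartition) -> str:
    """Genome residues rotated so the LSC starts at position 0."""
    off = partition.rotation_offset
    return genome.residues[off:] + genome.residues[:off]


def remove_one_ir(genome: CircularGenome, partition: QuadripartitePartition) -> str:
    """LSC + IRa + SSC on the canonical rotation (one IR copy dropped)."""
    if not genome.is_circular:
        raise StructureError("remove_one_ir requires a circular genome")
    rotated = canonical_rotation(genome, partition)
    keep = partition.lsc.length + partition.ira.length + partition.ssc.length
    return rotated[:keep]


def summarize_genbank_record(record: SeqRecord) -> dict:
    """Length, GC% and unique gene counts by kind for an annotated record.

    Genes duplicated by the inverted repeat collapse to one count per
    distinct name.  Records with no features report sequence metrics only,
    with gene counts flagged unavailable.
    """
    seq = str(record.seq).upper()
    out: dict = {
        "id": record.id,
        "length": len(seq),
        "gc_percent": round(100 * gc_content(seq), 1),
    }
    gene_feats = [
        f for f in record.features if f.type in ("gene", "CDS", "tRNA", "rRNA")
    ]
    if not gene_feats:
        out["gene_counts"] = None
        return out
    kinds: dict[str, set[str]] = {"gene": set(), "tRNA": set(), "rRNA": set()}
    for f in record.features:
        name = f.qualifiers.get("gene", f.qualifiers.get("locus_tag", ["?"]))[0]
        if f.type == "tRNA" or (f.type == "gene" and name.startswith("trn")):
            kinds["tRNA"].add(name)
        elif f.type == "rRNA" or (f.type == "gene" and name.startswith("rrn")):
            kinds["rRNA"].add(name)
        elif f.type in ("gene", "CDS"):
            kinds["gene"].add(name)
    unique_total = len(kinds["gene"] | kinds["tRNA"] | kinds["rRNA"])
    out["gene_counts"] = {
        "protein_coding": len(kinds["gene"]),
        "tRNA": len(kinds["tRNA"]),
        "rRNA": len(kinds["rRNA"]),
        "unique_total": unique_total,
    }
    return out


def read_genomes(path: str, fmt: Optional[str] = None) -> list[CircularGenome]:
    """Read circular genomes from FASTA or GenBank flat files."""
    if fmt is None:
        with open(path) as fh:
            first = fh.read(1)
        fmt = "fasta" if first == ">" else "genbank"
    genomes = []
    for rec in SeqIO.parse(path, fmt):
        genomes.append(CircularGenome(id=rec.id, residues=str(rec.seq)))
    if not genomes:
        raise ValueError(f"no sequences found in {path}")
    return genomes


def structure_table(
    genomes: Iterable[CircularGenome],
    min_len: int = 1000,
    max_mismatch: int = 0,
) -> list[dict]:
    """Per-genome structure metrics (length, GC%, LSC/SSC/IR sizes)."""
    rows = []
    for g in genomes:
        row: dict = {
            "id": g.id,
            "length": len(g),
            "gc_percent": round(100 * gc_content(g), 1),
        }
        ir = find_maximal_inverted_repeat(g, min_len=min_len, max_mismatch=max_mismatch)
        if ir is None:
            row.update({"lsc": None, "ssc": None, "ir": None, "rotation_offset": None})
        else:
            part = partition_quadripartite(g, ir)
            row.update(
                {
                    "lsc": part.lsc.length,
                    "ssc": part.ssc.length,
                    "ir": part.ira.length,
                    "rotation_offset": part.rotation_offset,
                }
            )
        rows.append(row)
    return rows
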