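"""Barcode-candidate mining and in-silico PCR.

A usable barcode for species/lineage assignment must be short enough for a
single PCR amplicon (< 800 bp here), variable enough to separate the
groups (at least a handful of variable sites, with at least one strictly
group-diagnostic site per group), and embedded in invariant, gap-free
flanks where universal primers can sit.  ``scan_candidates`` slides cores
across the alignment and keeps windows satisfying all four constraints;
``in_silico_pcr`` re-measures the realised product on each (circular)
genome with a concrete primer pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .structure import CircularGenome, Span, revcomp
from .variation import (
    AlignedMatrix,
    GroupAssignment,
    SiteClassSummary,
    _column_classes,
    count_site_classes,
    find_diagnostic_sites,
    nucleotide_diversity,
)

__all__ = [
    "PrimerPair",
    "AmpliconHit",
    "BarcodeCandidate",
    "BarcodeScanParams",
    "in_silico_pcr",
    "check_flank_conservation",
    "scan_candidates",
    "extract_region",
    "concatenate_regions",
    "read_primers_tsv",
]


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair, both written 5'->3'."""

    name: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for label, p in (("forward", self.forward), ("reverse", self.reverse)):
            if not (15 <= len(p) <= 35):
                raise ValueError(
                    f"{self.name}: {label} primer length {len(p)} outside 15-35"
                )
            if set(p.upper()) - set("ACGT"):
                raise ValueError(f"{self.name}: {label} primer has ambiguous bases")
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())


@dataclass
class AmpliconHit:
    template_id: str
    span: Span  # template coordinates; may wrap the origin on circles
    product_length: int
    fwd_mismatches: int
    rev_mismatches: int


def read_primers_tsv(path: str) -> list[PrimerPair]:
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            name, fwd, rev = line.split("\t")[:3]
            pairs.append(PrimerPair(name, fwd, rev))
    return pairs


def _primer_sites(template: str, primer: str, max_mismatch: int) -> list[tuple[int, int]]:
    """(start, mismatches) for every placement with <= max_mismatch."""
    t = np.frombuffer(template.encode(), dtype=np.uint8)
    p = np.frombuffer(primer.encode(), dtype=np.uint8)
    n, k = len(t), len(p)
    if n < k:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(t, k)
    mm = (windows != p).sum(axis=1)
    return [(int(i), int(mm[i])) for i in np.nonzero(mm <= max_mismatch)[0]]


def in_silico_pcr(
    template: Union[CircularGenome, str],
    primers: PrimerPair,
    max_mismatch: int = 0,
    max_product: int = 2000,
    template_id: Optional[str] = None,
) -> list[AmpliconHit]:
    """Predict PCR products of a primer pair on a (circular) template.

    The forward primer is matched on the sense strand; the reverse
    primer's reverse complement is matched downstream within
    ``max_product``.  Circular templates may yield origin-spanning
    products.  All hits are returned sorted by product length.
    """
    if isinstance(template, CircularGenome):
        seq = template.residues
        circular = template.is_circular
        tid = template.id
    else:
        seq = template.upper()
        circular = False
        tid = template_id or "template"
    L = len(seq)
    if max_product <= len(primers.forward) + len(primers.reverse):
        raise ValueError("max_product must exceed the combined primer lengths")
    search = seq + seq[: min(max_product, L)] if circular else seq
    fwd_sites = [(s, m) for s, m in _primer_sites(search, primers.forward, max_mismatch) if s < L]
    rev_rc = revcomp(primers.reverse)
    rev_sites = _primer_sites(search, rev_rc, max_mismatch)

    hits: list[AmpliconHit] = []
    for fs, fm in fwd_sites:
        for rs, rm in rev_sites:
            end = rs + len(rev_rc)
            if rs < fs + len(primers.forward):
                continue
            length = end - fs
            if length > max_product:
                continue
            if circular and length >= L:
                continue  # a physical product cannot exceed the circumference
            hits.append(
                AmpliconHit(
                    template_id=tid,
                    span=Span(fs % L, length),
                    product_length=length,
                    fwd_mismatches=fm,
                    rev_mismatches=rm,
                )
            )
    # one product per (start mod L, length) on circles
    uniq = {}
    for h in hits:
        uniq.setdefault((h.span.start, h.product_length), h)
    out = sorted(uniq.values(), key=lambda h: (h.product_length, h.span.start))
    if len(out) > 10:
        import warnings

        warnings.warn(
            f"{primers.name} on {tid}: {len(out)} products; primers look non-specific"
        )
    return out


def check_flank_conservation(
    aln: AlignedMatrix,
    interval: tuple[int, int],
    flank_len: int = 25,
    groups: Optional[GroupAssignment] = None,
) -> tuple[bool, bool, dict]:
    """Test whether both flanks of an interval are invariant and gap-free.

    A flank passes iff all ``flank_len`` columns adjacent to the interval
    contain one identical unambiguous base in every (ingroup) sample.  A
    flank that runs past the alignment edge fails with reason ``edge``.
    """
    start, end = interval
    if not (0 <= start < end <= aln.n_cols):
        raise ValueError(f"bad interval {interval}")
    sub = aln
    if groups is not None:
        keep = [s for s in aln.sample_ids if s not in groups.outgroups]
        sub = aln.subset_samples(keep)
    ok_col = _conserved_columns(sub)

    detail: dict = {
        "left": (start - flank_len, start),
        "right": (end, end + flank_len),
    }
    if start - flank_len < 0:
        left_ok = False
        detail["left_reason"] = "edge"
    else:
        left_ok = bool(ok_col[start - flank_len : start].all())
        if not left_ok:
            detail["left_reason"] = "variation_or_gap"
    if end + flank_len > aln.n_cols:
        right_ok = False
        detail["right_reason"] = "edge"
    else:
        right_ok = bool(ok_col[end : end + flank_len].all())
        if not right_ok:
            detail["right_reason"] = "variation_or_gap"
    return left_ok, right_ok, detail


def _conserved_columns(aln: AlignedMatrix) -> np.ndarray:
    """True where a column is one identical unambiguous base in all rows."""
    m = aln.matrix
    valid = aln.valid_mask()
    return valid.all(axis=0) & (m == m[0]).all(axis=0)


@dataclass
class BarcodeScanParams:
    max_len: int = 800
    flank_len: int = 25
    min_diag_per_group: int = 1
    min_variable: int = 3
    max_gap_frac: float = 0.05
    max_pi: float = 0.05
    step: int = 50
    top_k: int = 5
    include_half_length: bool = True


@dataclass
class BarcodeCandidate:
    core: tuple[int, int]
    left_flank: tuple[int, int]
    right_flank: tuple[int, int]
    summary: SiteClassSummary
    diagnostic_coverage: dict[str, int]
    pi: Optional[float]
    gap_fraction: float
    rank_score: float

    @property
    def length(self) -> int:
        return self.core[1] - self.core[0]


def scan_candidates(
    aln: AlignedMatrix,
    groups: GroupAssignment,
    params: Optional[BarcodeScanParams] = None,
    required_groups: Optional[Sequence[str]] = None,
) -> tuple[list[BarcodeCandidate], dict[str, int]]:
    """Slide candidate cores and keep those meeting all barcode constraints.

    Cores of length ``max_len`` (and ``max_len // 2`` for a short option)
    slide at ``step``; a core is kept when every required group has >=
    ``min_diag_per_group`` strict diagnostic sites inside it, it contains
    >= ``min_variable`` variable sites, its gap fraction and window pi stay
    under their caps, and both flanks are conserved.  ``required_groups``
    defaults to the ingroup labels with at least two samples (a singleton
    group cannot meaningfully anchor fixed-site coverage).  Candidates are
    ranked by (parsimony-informative sites desc, gap fraction asc,
    leftmost) and the top ``top_k`` mutually non-overlapping cores are
    returned along with a per-constraint rejection tally.
    """
    params = params or BarcodeScanParams()
    groups.validate_against(aln)
    labels = groups.ingroup_labels()
    if len(labels) < 2:
        raise ValueError("need >= 2 non-outgroup groups")
    if required_groups is None:
        required_groups = [
            g
            for g in labels
            if len([s for s in groups.members(g) if s not in groups.outgroups]) >= 2
        ]
    else:
        unknown = set(required_groups) - set(labels)
        if unknown:
            raise ValueError(f"unknown required groups: {sorted(unknown)}")

    ingroup_ids = [s for s in aln.sample_ids if s not in groups.outgroups]
    sub = aln.subset_samples(ingroup_ids)
    codes = _column_classes(sub)  # per-column class on ingroup rows
    gap_col = (sub.matrix == ord("-")).any(axis=0)
    conserved = _conserved_columns(sub)

    diag = find_diagnostic_sites(aln, groups)
    diag_cols: dict[str, np.ndarray] = {
        g: np.zeros(aln.n_cols, dtype=np.int32) for g in labels
    }
    for d in diag:
        diag_cols[d.group][d.column] += 1

    # prefix sums for O(1) window aggregates
    cs_pi = np.concatenate([[0], np.cumsum(codes == 3)])
    cs_var = np.concatenate([[0], np.cumsum((codes == 2) | (codes == 3))])
    cs_gap = np.concatenate([[0], np.cumsum(gap_col)])
    cs_cons = np.concatenate([[0], np.cumsum(conserved)])
    cs_diag = {g: np.concatenate([[0], np.cumsum(v)]) for g, v in diag_cols.items()}

    lengths = [params.max_len]
    if params.include_half_length and params.max_len // 2 >= params.step:
        lengths.append(params.max_len // 2)

    tally = {
        "examined": 0,
        "diagnostic_coverage": 0,
        "min_variable": 0,
        "gap_fraction": 0,
        "pi_cap": 0,
        "flanks": 0,
    }
    kept: list[BarcodeCandidate] = []
    fl = params.flank_len
    for core_len in lengths:
        for start in range(0, aln.n_cols - core_len + 1, params.step):
            end = start + core_len
            tally["examined"] += 1
            cov = {g: int(cs_diag[g][end] - cs_diag[g][start]) for g in labels}
            if any(cov[g] < params.min_diag_per_group for g in required_groups):
                tally["diagnostic_coverage"] += 1
                continue
            n_var = int(cs_var[end] - cs_var[start])
            if n_var < params.min_variable:
                tally["min_variable"] += 1
                continue
            gap_frac = float(cs_gap[end] - cs_gap[start]) / core_len
            if gap_frac > params.max_gap_frac:
                tally["gap_fraction"] += 1
                continue
            left_ok = start - fl >= 0 and cs_cons[start] - cs_cons[start - fl] == fl
            right_ok = (
                end + fl <= aln.n_cols and cs_cons[end + fl] - cs_cons[end] == fl
            )
            if not (left_ok and right_ok):
                tally["flanks"] += 1
                continue
            pi, _ = nucleotide_diversity(sub, (start, end))
            if pi is not None and pi > params.max_pi:
                tally["pi_cap"] += 1
                continue
            summary = count_site_classes(sub, (start, end))
            kept.append(
                BarcodeCandidate(
                    core=(start, end),
                    left_flank=(start - fl, start),
                    right_flank=(end, end + fl),
                    summary=summary,
                    diagnostic_coverage=cov,
                    pi=pi,
                    gap_fraction=gap_frac,
                    rank_score=float(summary.n_parsimony_informative),
                )
            )

    kept.sort(key=lambda c: (-c.rank_score, c.gap_fraction, c.core[0], -c.length))
    selected: list[BarcodeCandidate] = []
    for cand in kept:
        if len(selected) >= params.top_k:
            break
        if any(
            cand.core[0] < s.core[1] and s.core[0] < cand.core[1] for s in selected
        ):
            continue
        selected.append(cand)
    return selected, tally


def extract_region(
    source: Union[AlignedMatrix, Sequence[CircularGenome]],
    locator: Union[tuple[int, int], PrimerPair],
    max_mismatch: int = 0,
    max_product: int = 2000,
) -> Union[AlignedMatrix, dict[str, str]]:
    """Extract one region from an alignment (span) or genomes (primers).

    Span mode returns a column-consistent sub-alignment.  Primer mode runs
    in-silico PCR per genome and requires exactly one hit each, returning
    unaligned amplicons keyed by genome id.
    """
    if isinstance(locator, tuple):
        if not isinstance(source, AlignedMatrix):
            raise TypeError("span extraction requires an alignment")
        return source.slice_columns(*locator)
    if isinstance(source, AlignedMatrix):
        raise TypeError("primer extraction requires genome sequences")
    amplicons: dict[str, str] = {}
    problems: list[str] = []
    for g in source:
        hits = in_silico_pcr(g, locator, max_mismatch=max_mismatch, max_product=max_product)
        if len(hits) != 1:
            problems.append(f"{g.id} ({len(hits)} hits)")
            continue
        amplicons[g.id] = g.slice(hits[0].span)
    if problems:
        raise ValueError(
            f"primer pair {locator.name} did not resolve uniquely in: "
            + ", ".join(problems)
        )
    return amplicons


def concatenate_regions(
    parts: Sequence[AlignedMatrix],
) -> tuple[AlignedMatrix, list[tuple[str, int, int]]]:
    """Concatenate sub-alignments column-wise with a partition map.

    All parts must carry the same sample set; rows follow the first part's
    sample order.  The partition map lists (part index label, start, end)
    in concatenated coordinates; the total length is the sum of parts.
    """
    if not parts:
        raise ValueError("no parts to concatenate")
    ref_ids = parts[0].sample_ids
    ref_set = set(ref_ids)
    for k, p in enumerate(parts[1:], start=2):
        if set(p.sample_ids) != ref_set:
            raise ValueError(f"part {k} sample set differs from part 1")
    rows = {s: [] for s in ref_ids}
    partition_map: list[tuple[str, int, int]] = []
    offset = 0
    for k, p in enumerate(parts, start=1):
        aligned = p.subset_samples(ref_ids)
        for s, row in zip(aligned.sample_ids, aligned.rows):
            rows[s].append(row)
        partition_map.append((f"part{k}", offset, offset + p.n_cols))
        offset += p.n_cols
    cat = AlignedMatrix(list(ref_ids), ["".join(rows[s]) for s in ref_ids])
    return cat, partition_map
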