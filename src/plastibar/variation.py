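"""Alignment column classification, nucleotide diversity, diagnostic sites.

All scans run on an :class:`AlignedMatrix` (equal-length rows over
``{A,C,G,T,-}`` plus IUPAC ambiguity codes).  Gaps and ambiguity codes are
treated as missing data throughout: they never match anything and never
count as a character state.  Nucleotide diversity follows the classic
definition pi = average per-site proportion of differences over all sample
pairs; the default complete-deletion policy (a column is usable only when
every sample carries an unambiguous base there) mirrors the behaviour of
the standard population-genetics desktop tools.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "AlignedMatrix",
    "GroupAssignment",
    "SiteClassSummary",
    "WindowDiversity",
    "DiagnosticSite",
    "classify_site",
    "count_site_classes",
    "nucleotide_diversity",
    "sliding_window_diversity",
    "find_diagnostic_sites",
]

_BASES = b"ACGT"
_BASE_CODES = frozenset(_BASES)


def _encode(rows: Sequence[str]) -> np.ndarray:
    arr = np.frombuffer("".join(rows).upper().encode(), dtype=np.uint8)
    return arr.reshape(len(rows), -1).copy()


@dataclass
class AlignedMatrix:
    """Multiple sequence alignment held as a byte matrix."""

    sample_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.rows):
            raise ValueError("sample_ids and rows differ in length")
        if len(self.sample_ids) < 2:
            raise ValueError("alignment needs >= 2 samples")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        self._matrix = _encode(self.rows)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_cols(self) -> int:
        return self._matrix.shape[1]

    @property
    def matrix(self) -> np.ndarray:
        """(n_samples, n_cols) uint8 view of the residues."""
        return self._matrix

    def valid_mask(self) -> np.ndarray:
        """Boolean matrix: True where the residue is an unambiguous base."""
        m = self._matrix
        return (m == ord("A")) | (m == ord("C")) | (m == ord("G")) | (m == ord("T"))

    def subset_samples(self, ids: Sequence[str]) -> "AlignedMatrix":
        order = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in order]
        if missing:
            raise KeyError(f"samples not in alignment: {missing}")
        return AlignedMatrix(list(ids), [self.rows[order[s]] for s in ids])

    def slice_columns(self, start: int, end: int) -> "AlignedMatrix":
        if not (0 <= start < end <= self.n_cols):
            raise ValueError(f"bad column interval [{start}, {end})")
        return AlignedMatrix(
            list(self.sample_ids), [r[start:end] for r in self.rows]
        )

    @classmethod
    def from_fasta(cls, path: str) -> "AlignedMatrix":
        from Bio import SeqIO

        ids, rows = [], []
        for rec in SeqIO.parse(path, "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(ids, rows)

    def to_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.sample_ids, self.rows):
                fh.write(f">{sid}\n{row}\n")

    def to_phylip(self, path: str) -> None:
        """Relaxed PHYLIP (name, two spaces, sequence)."""
        with open(path, "w") as fh:
            fh.write(f" {self.n_samples} {self.n_cols}\n")
            for sid, row in zip(self.sample_ids, self.rows):
                fh.write(f"{sid}  {row}\n")


@dataclass
class GroupAssignment:
    """sample id -> group label, with optional outgroup flags."""

    groups: dict[str, str]
    outgroups: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        unknown = self.outgroups - set(self.groups)
        if unknown:
            raise ValueError(f"outgroup flags for unlabeled samples: {unknown}")

    def ingroup_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for s, g in self.groups.items():
            if s not in self.outgroups:
                seen.setdefault(g, None)
        return list(seen)

    def members(self, label: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == label]

    def validate_against(self, aln: AlignedMatrix) -> None:
        unlabeled = [s for s in aln.sample_ids if s not in self.groups]
        if unlabeled:
            raise ValueError(f"unlabeled samples in alignment: {unlabeled}")

    @classmethod
    def from_tsv(cls, path: str) -> "GroupAssignment":
        groups: dict[str, str] = {}
        outgroups: set[str] = set()
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"bad groups line: {line!r}")
                sid, grp = parts[0], parts[1]
                groups[sid] = grp
                if len(parts) > 2 and parts[2].strip().lower() in (
                    "1",
                    "true",
                    "outgroup",
                    "yes",
                ):
                    outgroups.add(sid)
        return cls(groups, outgroups)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            for sid, grp in self.groups.items():
                flag = "\toutgroup" if sid in self.outgroups else ""
                fh.write(f"{sid}\t{grp}{flag}\n")


@dataclass
class SiteClassSummary:
    interval: tuple[int, int]
    n_variable: int
    n_parsimony_informative: int
    n_singleton: int
    n_excluded: int

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]

    def percent_variable(self) -> float:
        return round(100 * self.n_variable / self.length, 2)

    def percent_pi(self) -> float:
        return round(100 * self.n_parsimony_informative / self.length, 2)


@dataclass
class WindowDiversity:
    start: int  # 0-based half-open
    end: int
    pi: Optional[float]
    usable_sites: int
    truncated: bool = False


def classify_site(states: Iterable[str]) -> str:
    """Classify one alignment column.

    Returns one of ``invariant``, ``singleton``, ``parsimony_informative``
    or ``excluded``.  Gaps and ambiguity codes are missing data; a column
    with fewer than two non-missing states is excluded.  A column is
    variable when >= 2 distinct bases occur, and parsimony-informative
    when >= 2 of those bases each occur in >= 2 samples.
    """
    counts: dict[str, int] = {}
    for s in states:
        s = s.upper()
        if s in "ACGT":
            counts[s] = counts.get(s, 0) + 1
    n_obs = sum(counts.values())
    if n_obs < 2:
        return "excluded"
    if len(counts) < 2:
        return "invariant"
    if sum(1 for c in counts.values() if c >= 2) >= 2:
        return "parsimony_informative"
    return "singleton"


def _column_classes(aln: AlignedMatrix) -> np.ndarray:
    """Vectorised per-column classification code.

    0 = excluded, 1 = invariant, 2 = singleton, 3 = parsimony informative.
    """
    m = aln.matrix
    counts = np.stack([(m == b).sum(axis=0) for b in _BASES])  # (4, ncols)
    n_obs = counts.sum(axis=0)
    n_states = (counts > 0).sum(axis=0)
    n_ge2 = (counts >= 2).sum(axis=0)
    out = np.ones(aln.n_cols, dtype=np.int8)
    out[n_obs < 2] = 0
    variable = (n_obs >= 2) & (n_states >= 2)
    out[variable] = 2
    out[variable & (n_ge2 >= 2)] = 3
    return out


CLASS_NAMES = {0: "excluded", 1: "invariant", 2: "singleton", 3: "parsimony_informative"}


def count_site_classes(
    aln: AlignedMatrix, interval: Optional[tuple[int, int]] = None
) -> SiteClassSummary:
    """Column-wise site-class tally over an interval (default: full length)."""
    if interval is None:
        interval = (0, aln.n_cols)
    start, end = interval
    if not (0 <= start < end <= aln.n_cols):
        raise ValueError(f"bad interval {interval} for {aln.n_cols} columns")
    codes = _column_classes(aln)[start:end]
    n_pi = int((codes == 3).sum())
    n_single = int((codes == 2).sum())
    return SiteClassSummary(
        interval=interval,
        n_variable=n_pi + n_single,
        n_parsimony_informative=n_pi,
        n_singleton=n_single,
        n_excluded=int((codes == 0).sum()),
    )


def nucleotide_diversity(
    aln: AlignedMatrix,
    interval: Optional[tuple[int, int]] = None,
    deletion: str = "complete",
) -> tuple[Optional[float], int]:
    """Average pairwise per-site difference (pi) over an interval.

    pi = sum over sample pairs of (differing sites / comparable sites),
    divided by the number of pairs.  Under ``complete`` deletion (default)
    only columns where every sample has an unambiguous base are comparable;
    under ``pairwise`` deletion comparability is decided per pair.

    Returns ``(pi, usable_sites)``; pi is ``None`` (flagged undefined) when
    no comparable sites exist.  ``usable_sites`` is the complete-deletion
    column count under ``complete``, and the minimum per-pair comparable
    count under ``pairwise``.
    """
    if deletion not in ("complete", "pairwise"):
        raise ValueError(f"unknown deletion policy {deletion!r}")
    if interval is None:
        interval = (0, aln.n_cols)
    start, end = interval
    if not (0 <= start < end <= aln.n_cols):
        raise ValueError(f"bad interval {interval}")
    m = aln.matrix[:, start:end]
    valid = aln.valid_mask()[:, start:end]
    n = aln.n_samples
    pairs = list(itertools.combinations(range(n), 2))

    if deletion == "complete":
        usable = valid.all(axis=0)
        n_usable = int(usable.sum())
        if n_usable == 0:
            return None, 0
        sub = m[:, usable]
        total = 0.0
        for i, j in pairs:
            total += (sub[i] != sub[j]).sum() / n_usable
        return total / len(pairs), n_usable

    total = 0.0
    min_comparable = None
    for i, j in pairs:
        both = valid[i] & valid[j]
        comp = int(both.sum())
        min_comparable = comp if min_comparable is None else min(min_comparable, comp)
        if comp == 0:
            return None, 0
        total += int((m[i] != m[j])[both].sum()) / comp
    return total / len(pairs), int(min_comparable or 0)


def sliding_window_diversity(
    aln: AlignedMatrix,
    window_len: int = 800,
    step: int = 200,
    deletion: str = "complete",
) -> list[WindowDiversity]:
    """pi in sliding windows starting at 0, step, 2*step, ...

    The last window is truncated at the alignment end and flagged.  A
    window longer than the alignment yields a single truncated window.
    """
    if not (window_len >= step >= 1):
        raise ValueError("require window_len >= step >= 1")
    n = aln.n_cols
    out: list[WindowDiversity] = []
    start = 0
    while start < n:
        end = min(start + window_len, n)
        pi, usable = nucleotide_diversity(aln, (start, end), deletion)
        out.append(
            WindowDiversity(
                start=start,
                end=end,
                pi=pi,
                usable_sites=usable,
                truncated=(end - start) < window_len,
            )
        )
        if end == n:
            break
        start += step
    return out


@dataclass
class DiagnosticSite:
    """A column whose state is fixed in one group and absent elsewhere."""

    column: int  # 0-based
    group: str
    state: str
    complete: bool  # no missing data within the group
    strict: bool  # state absent from every other ingroup sample


def find_diagnostic_sites(
    aln: AlignedMatrix, groups: GroupAssignment
) -> list[DiagnosticSite]:
    """Group-diagnostic fixed sites across all ingroup comparisons.

    For every ingroup label and column: the group's non-missing samples all
    share one base, and that base does not occur in any other ingroup
    sample's non-missing state.  Outgroup rows are ignored entirely.
    Columns where the group has no data are skipped for that group;
    ``complete`` records whether the group had any missing data there.
    """
    groups.validate_against(aln)
    labels = groups.ingroup_labels()
    if len(labels) < 2:
        raise ValueError("need >= 2 non-outgroup groups")
    m = aln.matrix
    valid = aln.valid_mask()
    idx = {s: i for i, s in enumerate(aln.sample_ids)}
    rows_by_label = {
        g: np.array([idx[s] for s in groups.members(g) if s not in groups.outgroups])
        for g in labels
    }
    out: list[DiagnosticSite] = []
    for g in labels:
        rows_g = rows_by_label[g]
        other_rows = np.concatenate(
            [rows_by_label[h] for h in labels if h != g]
        )
        vg = valid[rows_g]  # (k, ncols)
        mg = m[rows_g]
        n_obs = vg.sum(axis=0)
        # fixed state within the group: all observed bases identical
        first = np.where(vg.any(axis=0), mg[vg.argmax(axis=0), np.arange(m.shape[1])], 0)
        fixed = np.ones(m.shape[1], dtype=bool)
        for r in range(len(rows_g)):
            fixed &= ~vg[r] | (mg[r] == first)
        candidate = fixed & (n_obs >= 1)
        vo = valid[other_rows]
        mo = m[other_rows]
        present_outside = ((mo == first[None, :]) & vo).any(axis=0)
        strict_cols = np.nonzero(candidate & ~present_outside)[0]
        for col in strict_cols:
            out.append(
                DiagnosticSite(
                    column=int(col),
                    group=g,
                    state=chr(first[col]),
                    complete=bool(n_obs[col] == len(rows_g)),
                    strict=True,
                )
            )
    out.sort(key=lambda d: (d.column, d.group))
    return out
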