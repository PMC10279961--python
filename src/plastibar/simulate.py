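"""Synthetic plastome datasets with recorded ground truth.

The generator emulates the sample structure of a small fern genus studied
by plastome skimming: three species-level clades (one of them split into
an eastern and a western lineage plus one phylogenetically unstable
island sample), an outgroup, quadripartite genomes whose IR length varies
between groups through a single IR-internal hypervariable hotspot, low
background diversity (pi well under 0.002), fixed group-diagnostic
substitutions, and one plantable barcode window with fully conserved
flanks.  Every planted feature is recorded in a :class:`SyntheticTruth`
so downstream recovery tests never re-derive truth from the generator's
internals.

Genomes default to ~20 kb (a scale-down of the 160-166 kb molecules the
architecture mimics); all pipeline algorithms are length-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np

from .structure import CircularGenome, QuadripartitePartition, Span, revcomp
from .variation import AlignedMatrix, GroupAssignment

__all__ = [
    "SimulationParams",
    "SyntheticTruth",
    "evolve_alignment",
    "plant_features",
    "assemble_circular_genomes",
    "generate_study_like_dataset",
    "DEFAULT_GUIDE_TREE",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _default_tree() -> str:
    """Guide topology: outgroup; species A; species B; species C split into
    eastern (E) and western (W) lineages plus one unstable singleton."""
    a = ",".join(f"A{i}:0.02" for i in range(1, 3))
    b = ",".join(f"B{i}:0.02" for i in range(1, 6))
    e = ",".join(f"E{i}:0.01" for i in range(1, 10))
    w = ",".join(f"W{i}:0.01" for i in range(1, 10))
    return (
        f"(OG1:1.2,({a}):0.35,(({b}):0.18,((({e}):0.05,({w}):0.05):0.02,"
        f"H1:0.06):0.10):0.05);"
    )


DEFAULT_GUIDE_TREE = _default_tree()

DEFAULT_GROUPS: dict[str, str] = {}
for _i in range(1, 3):
    DEFAULT_GROUPS[f"A{_i}"] = "speciesA"
for _i in range(1, 6):
    DEFAULT_GROUPS[f"B{_i}"] = "speciesB"
for _i in range(1, 10):
    DEFAULT_GROUPS[f"E{_i}"] = "lineageE"
for _i in range(1, 10):
    DEFAULT_GROUPS[f"W{_i}"] = "lineageW"
DEFAULT_GROUPS["H1"] = "unplaced"
DEFAULT_GROUPS["OG1"] = "outgroup"


@dataclass
class SimulationParams:
    """Study-condition defaults for the synthetic generator.

    Architecture: LSC 12 kb, SSC 3 kb, IR up to 2.5 kb -> circular genomes
    of ~20 kb.  The IR hotspot is both hypervariable (substitution rate
    multiplied by ``hotspot_multiplier``) and the locus of group-specific
    deletions that realise between-group IR length differences, mirroring
    plastomes whose IR length variation concentrates in one intergenic
    tract.  Background branch lengths keep within-lineage pi well below
    0.002.
    """

    guide_tree: str = DEFAULT_GUIDE_TREE
    groups: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    outgroup_ids: tuple[str, ...] = ("OG1",)
    unstable_ids: tuple[str, ...] = ("H1",)
    lsc_len: int = 12_000
    ssc_len: int = 3_000
    ir_len: int = 2_500
    hotspot_span: tuple[int, int] = (13_000, 13_600)  # alignment coords, inside IR
    ir_deletion_by_group: dict[str, int] = field(
        default_factory=lambda: {
            "speciesA": 0,
            "speciesB": 400,
            "lineageE": 150,
            "lineageW": 150,
            "unplaced": 150,
            "outgroup": 250,
        }
    )
    rate: float = 0.002  # substitutions per site per unit branch length
    # hotspot rate multiplier: high enough that the tract is effectively
    # alignment-unreliable (window pi far above the miner's 0.05 cap),
    # emulating the hypervariable IR-internal region the study rejected
    hotspot_multiplier: float = 200.0
    n_diagnostic_per_group: int = 12
    n_diag_in_barcode: int = 3
    barcode_core: tuple[int, int] = (4_000, 4_800)  # within LSC, step-aligned
    flank_len: int = 30
    seed: int = 0

    @property
    def row_length(self) -> int:
        return self.lsc_len + self.ir_len + self.ssc_len

    @property
    def diagnostic_labels(self) -> list[str]:
        """Groups that receive planted diagnostics (outgroup/unstable excluded)."""
        skip = set(self.outgroup_ids) | set(self.unstable_ids)
        seen: dict[str, None] = {}
        for s, g in self.groups.items():
            if s not in skip:
                seen.setdefault(g, None)
        return list(seen)


@dataclass
class SyntheticTruth:
    """Everything needed to score recovery without re-simulation."""

    tree_newick: str
    group_assignment: GroupAssignment
    diagnostic_columns: dict[str, list[int]]  # group -> planted columns
    barcode_core: tuple[int, int]
    barcode_flanks: tuple[tuple[int, int], tuple[int, int]]
    hotspot_span: tuple[int, int]
    partitions: dict[str, dict[str, int]]  # genome id -> lsc/ssc/ir sizes
    rotations: dict[str, int]

    def to_json_dict(self) -> dict:
        return {
            "tree_newick": self.tree_newick,
            "groups": self.group_assignment.groups,
            "outgroups": sorted(self.group_assignment.outgroups),
            "diagnostic_columns": self.diagnostic_columns,
            "barcode_core": list(self.barcode_core),
            "barcode_flanks": [list(f) for f in self.barcode_flanks],
            "hotspot_span": list(self.hotspot_span),
            "partitions": self.partitions,
            "rotations": self.rotations,
        }


def evolve_alignment(
    guide_tree: str, length: int, rate: float, seed: int
) -> tuple[AlignedMatrix, str]:
    """Simulate a gapless alignment by JC substitution along a tree.

    The root sequence is uniform over A/C/G/T; along each branch every
    site mutates independently with the Jukes-Cantor change probability
    p = (3/4)(1 - exp(-4 d / 3)) where d = branch length x rate, landing
    uniformly on one of the three other bases.  Deterministic given seed.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    tree = dendropy.Tree.get(data=guide_tree, schema="newick")
    rng = np.random.default_rng(seed)
    root_seq = rng.choice(_BASES, size=length)
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    leaves: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            parent_seq = seqs[id(node)]
        else:
            parent_seq = seqs[id(node.parent_node)]
            bl = node.edge.length or 0.0
            d = bl * rate
            p_change = 0.75 * (1 - np.exp(-4.0 * d / 3.0))
            seq = parent_seq.copy()
            hit = rng.random(length) < p_change
            n_hit = int(hit.sum())
            if n_hit:
                # uniform choice among the three other bases
                shift = rng.integers(1, 4, size=n_hit)
                cur = np.searchsorted(_BASES, seq[hit])
                seq[hit] = _BASES[(cur + shift) % 4]
            seqs[id(node)] = seq
        if node.is_leaf():
            leaves[node.taxon.label.replace(" ", "_")] = seqs[id(node)]
    ids = sorted(leaves)
    rows = [leaves[i].tobytes().decode() for i in ids]
    return AlignedMatrix(ids, rows), tree.as_string(schema="newick").strip()


def _resimulate_columns(
    aln: AlignedMatrix,
    cols: np.ndarray,
    guide_tree: str,
    rate: float,
    seed: int,
) -> AlignedMatrix:
    """Replace the given columns with a fresh simulation at ``rate``."""
    hot, _ = evolve_alignment(guide_tree, len(cols), rate, seed)
    order = {s: i for i, s in enumerate(hot.sample_ids)}
    rows = []
    for sid, row in zip(aln.sample_ids, aln.rows):
        chars = list(row)
        hot_row = hot.rows[order[sid]]
        for k, c in enumerate(cols):
            chars[c] = hot_row[k]
        rows.append("".join(chars))
    return AlignedMatrix(list(aln.sample_ids), rows)


def plant_features(
    aln: AlignedMatrix, params: SimulationParams
) -> tuple[AlignedMatrix, SyntheticTruth]:
    """Plant diagnostics, conserved flanks, and the IR hotspot into a core
    alignment; returns the edited alignment and the truth record.

    Per diagnostic group, ``n_diagnostic_per_group`` columns receive a
    private fixed state (``n_diag_in_barcode`` of them inside the barcode
    core, the rest in a group-specific zone of the LSC so that no other
    window accumulates full cross-group coverage).  Flank blocks around
    the barcode core are overwritten with the first row (zero variation).
    Hotspot columns are re-simulated at ``rate x hotspot_multiplier``.
    """
    rng = np.random.default_rng(params.seed + 1)
    labels = params.diagnostic_labels
    groups = GroupAssignment(
        dict(params.groups), set(params.outgroup_ids)
    )
    core_lo, core_hi = params.barcode_core
    fl = params.flank_len
    flanks = ((core_lo - fl, core_lo), (core_hi, core_hi + fl))
    if flanks[0][0] < 0 or flanks[1][1] > params.lsc_len:
        raise ValueError("barcode core plus flanks must sit inside the LSC")

    mat = aln.matrix.copy()
    idx = {s: i for i, s in enumerate(aln.sample_ids)}
    claimed: set[int] = set()
    claimed.update(range(flanks[0][0], flanks[0][1]))
    claimed.update(range(flanks[1][0], flanks[1][1]))
    hs_lo, hs_hi = params.hotspot_span
    claimed.update(range(hs_lo, hs_hi))

    # group-specific zones for the out-of-barcode diagnostics: disjoint
    # stretches of the LSC away from the barcode neighbourhood
    # keep zones a full window length clear of the core, so no single
    # window can bridge a zone and the core and outrank the planted signal
    zone_len = 1_000
    zone_guard = 1_000
    zones: dict[str, tuple[int, int]] = {}
    cursor = 200
    for g in labels:
        if not (
            cursor + zone_len <= flanks[0][0] - zone_guard
            or cursor >= flanks[1][1] + zone_guard
        ):
            cursor = flanks[1][1] + zone_guard
        if cursor + zone_len > params.lsc_len:
            raise ValueError("LSC too short for the diagnostic zones")
        zones[g] = (cursor, cursor + zone_len)
        cursor += zone_len + 100

    diagnostic_columns: dict[str, list[int]] = {g: [] for g in labels}

    def plant_column(col: int, g: str) -> None:
        rows_g = [idx[s] for s, lab in params.groups.items() if lab == g]
        others = [
            idx[s]
            for s, lab in params.groups.items()
            if lab != g and s not in params.outgroup_ids
        ]
        present = set(int(b) for b in mat[others, col])
        choices = [b for b in _BASES if int(b) not in present]
        if not choices:
            # force the others onto one base to free a private state
            mat[others, col] = _BASES[0]
            choices = [b for b in _BASES[1:]]
        state = choices[int(rng.integers(0, len(choices)))]
        mat[rows_g, col] = state
        diagnostic_columns[g].append(col)
        claimed.add(col)

    # inside-barcode diagnostics: one per group anchored in each 50-column
    # edge zone of the core (so every window shifted off the core loses
    # planted signal and the core is the unique ranking optimum), the rest
    # spread over the middle
    edge = 50
    for zone_lo, zone_hi in ((core_lo, core_lo + edge), (core_hi - edge, core_hi)):
        for g in labels:
            free = [c for c in range(zone_lo, zone_hi) if c not in claimed]
            plant_column(free[int(rng.integers(0, len(free)))], g)
    mid_free = [
        c for c in range(core_lo + edge, core_hi - edge) if c not in claimed
    ]
    n_mid = max(params.n_diag_in_barcode - 2, 0)
    for g in labels:
        picks = rng.choice(len(mid_free), size=n_mid, replace=False)
        for p in sorted(picks):
            plant_column(mid_free[p], g)
        mid_free = [c for c in mid_free if c not in claimed]

    # zone diagnostics
    n_rest = params.n_diagnostic_per_group - params.n_diag_in_barcode
    for g in labels:
        z_lo, z_hi = zones[g]
        free = [c for c in range(z_lo, z_hi) if c not in claimed]
        picks = rng.choice(len(free), size=n_rest, replace=False)
        for p in sorted(picks):
            plant_column(free[p], g)

    # conserved flanks: zero out variation
    for lo, hi in flanks:
        mat[:, lo:hi] = mat[0, lo:hi]

    # break complementarity at the block junctions, otherwise chance
    # matches would extend the assembled genomes' true maximal inverted
    # repeat past the planted boundaries: after assembly the IR copies
    # could grow outward iff LSC[-1] == comp(LSC[0]) and inward iff
    # SSC[0] == comp(SSC[-1]); fixing all four edge columns to 'A'
    # (complement 'T') blocks both directions in every sample
    ir_hi_col = params.lsc_len + params.ir_len
    for col in (0, params.lsc_len - 1, ir_hi_col, params.row_length - 1):
        mat[:, col] = ord("A")

    edited = AlignedMatrix(
        list(aln.sample_ids),
        [mat[i].tobytes().decode() for i in range(mat.shape[0])],
    )

    # hotspot: re-simulate at the elevated rate
    hot_cols = np.arange(hs_lo, hs_hi)
    edited = _resimulate_columns(
        edited,
        hot_cols,
        params.guide_tree,
        params.rate * params.hotspot_multiplier,
        params.seed + 2,
    )

    truth = SyntheticTruth(
        tree_newick=params.guide_tree,
        group_assignment=groups,
        diagnostic_columns={g: sorted(v) for g, v in diagnostic_columns.items()},
        barcode_core=params.barcode_core,
        barcode_flanks=flanks,
        hotspot_span=params.hotspot_span,
        partitions={},
        rotations={},
    )
    return edited, truth


def assemble_circular_genomes(
    aln: AlignedMatrix, params: SimulationParams, truth: SyntheticTruth
) -> list[CircularGenome]:
    """Fold alignment rows into rotated circular quadripartite genomes.

    Row layout is LSC | IR | SSC; each genome becomes
    LSC + IRa + SSC + revcomp(IRa), where the group's IR deletion removes
    bases from the hotspot tract, and a seeded random rotation is applied.
    True partitions and rotations are recorded on the truth object.
    """
    if aln.n_cols != params.row_length:
        raise ValueError(
            f"row length {aln.n_cols} != architecture total {params.row_length}"
        )
    rng = np.random.default_rng(params.seed + 3)
    hs_lo, hs_hi = params.hotspot_span
    ir_lo = params.lsc_len
    ir_hi = params.lsc_len + params.ir_len
    if not (ir_lo <= hs_lo < hs_hi <= ir_hi):
        raise ValueError("hotspot span must lie inside the IR block")
    genomes = []
    for sid, row in zip(aln.sample_ids, aln.rows):
        grp = params.groups[sid]
        delta = params.ir_deletion_by_group.get(grp, 0)
        if delta > hs_hi - hs_lo:
            raise ValueError(f"IR deletion {delta} exceeds hotspot length")
        lsc = row[:ir_lo]
        ir = row[ir_lo:hs_lo] + row[hs_lo + delta : ir_hi]
        ssc = row[ir_hi:]
        circ = lsc + ir + ssc + revcomp(ir)
        rot = int(rng.integers(0, len(circ)))
        rotated = circ[rot:] + circ[:rot]
        genomes.append(CircularGenome(id=sid, residues=rotated))
        truth.partitions[sid] = {
            "lsc": len(lsc),
            "ssc": len(ssc),
            "ir": len(ir),
            "total": len(circ),
        }
        truth.rotations[sid] = rot
    return genomes


def generate_study_like_dataset(
    params: Optional[SimulationParams] = None, seed: Optional[int] = None
) -> tuple[list[CircularGenome], AlignedMatrix, GroupAssignment, SyntheticTruth]:
    """One call producing all pipeline inputs plus the truth record.

    Returns (circular genomes, true alignment in LSC|IR|SSC layout, group
    assignment, truth).  Defaults give 25 ingroup samples in 4 groups,
    one outgroup and one unstable singleton, ~20 kb genomes.
    """
    params = params or SimulationParams()
    if seed is not None:
        params = SimulationParams(**{**params.__dict__, "seed": seed})
    aln, tree_str = evolve_alignment(
        params.guide_tree, params.row_length, params.rate, params.seed
    )
    missing = [s for s in params.groups if s not in aln.sample_ids]
    if missing:
        raise ValueError(f"guide tree lacks samples: {missing}")
    aln, truth = plant_features(aln, params)
    genomes = assemble_circular_genomes(aln, params, truth)
    return genomes, aln, truth.group_assignment, truth


def write_dataset(
    out_dir: str,
    genomes: list[CircularGenome],
    aln: AlignedMatrix,
    groups: GroupAssignment,
    truth: SyntheticTruth,
) -> None:
    import json
    import os

    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "genomes.fasta"), "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n{g.residues}\n")
    aln.to_fasta(os.path.join(out_dir, "truth_alignment.fasta"))
    groups.to_tsv(os.path.join(out_dir, "groups.tsv"))
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=2)
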