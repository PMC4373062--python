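"""Lineage delimitation and the curation steps that precede it.

ERV lineages are delimited the distance-based way: a pairwise distance
matrix feeds neighbor-joining for topology and single-linkage threshold
clustering for the partition itself (two sequences share a lineage iff they
are connected by a chain of pairwise distances at or below the divergence
threshold, 15% by default — single linkage is the unique linkage for which
"no inter-lineage pair below threshold" is guaranteed).  Upstream of the
matrix sit two curation utilities: conserved-block trimming of a multiple
alignment (Gblocks-style column classification) and threshold filtering of
homology-hit tables.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .distances import DistanceMatrix
from .types import HitRecord

__all__ = [
    "Tree",
    "LineagePartition",
    "TrimmedAlignment",
    "TrimParams",
    "HitFilterConfig",
    "neighbor_joining",
    "cut_lineages",
    "trim_blocks",
    "hit_filter",
]


@dataclass
class Tree:
    """An unrooted NJ tree: newick string plus clamping metadata."""

    newick: str
    n_leaves: int
    clamped_edges: list[str] = field(default_factory=list)

    def as_dendropy(self, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.newick,
            schema="newick",
            taxon_namespace=taxon_namespace,
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.newick + "\n")


def neighbor_joining(m: DistanceMatrix) -> Tree:
    """Neighbor joining (Saitou-Nei Q-criterion) with standard branch-length
    formulas.

    Q ties are broken by the lexicographically smallest pair of cluster
    labels (a cluster is labelled by its smallest leaf).  Negative branch
    length estimates are clamped to zero and flagged.
    """
    n = len(m.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = np.array(m.values, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite entry in distance matrix")
    # active clusters: (sort key = smallest leaf label, newick fragment)
    keys = list(m.labels)
    frags = [lab for lab in m.labels]
    clamped: list[str] = []

    def fmt(x: float) -> str:
        return f"{x:.10g}"

    def clamp(x: float, a: str, b: str) -> float:
        if x < 0:
            clamped.append(f"{a}|{b}")
            return 0.0
        return x

    active = list(range(n))
    while len(active) > 3:
        r = len(active)
        idx = np.array(active)
        sub = d[np.ix_(idx, idx)]
        R = sub.sum(axis=1)
        q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = [
            (ii, jj)
            for ii in range(r)
            for jj in range(ii + 1, r)
            if q[ii, jj] <= qmin + 1e-12
        ]
        ii, jj = min(ties, key=lambda p: tuple(sorted((keys[idx[p[0]]], keys[idx[p[1]]]))))
        gi, gj = int(idx[ii]), int(idx[jj])
        dij = d[gi, gj]
        bi = 0.5 * dij + (R[ii] - R[jj]) / (2.0 * (r - 2))
        bj = dij - bi
        bi = clamp(bi, keys[gi], keys[gj])
        bj = clamp(bj, keys[gj], keys[gi])
        new_frag = f"({frags[gi]}:{fmt(bi)},{frags[gj]}:{fmt(bj)})"
        new_key = min(keys[gi], keys[gj])
        # distances from the new node
        newrow = np.zeros(d.shape[0] + 1)
        for gk in active:
            if gk in (gi, gj):
                continue
            newrow[gk] = 0.5 * (d[gi, gk] + d[gj, gk] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = newrow[:-1]
        d[:-1, -1] = newrow[:-1]
        keys.append(new_key)
        frags.append(new_frag)
        active = [g for g in active if g not in (gi, gj)] + [len(keys) - 1]

    ga, gb, gc = active
    dab, dac, dbc = d[ga, gb], d[ga, gc], d[gb, gc]
    ba = clamp(0.5 * (dab + dac - dbc), keys[ga], "center")
    bb = clamp(0.5 * (dab + dbc - dac), keys[gb], "center")
    bc = clamp(0.5 * (dac + dbc - dab), keys[gc], "center")
    newick = (
        f"({frags[ga]}:{fmt(ba)},{frags[gb]}:{fmt(bb)},{frags[gc]}:{fmt(bc)});"
    )
    return Tree(newick=newick, n_leaves=n, clamped_edges=clamped)


@dataclass(frozen=True)
class LineagePartition:
    """Mapping of sequence ids to lineage labels under a divergence threshold."""

    assignment: dict[str, str]
    threshold: float
    min_inter_lineage: float
    max_intra_lineage: float

    def lineages(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, lab in self.assignment.items():
            out.setdefault(lab, []).append(sid)
        return out

    @property
    def n_lineages(self) -> int:
        return len(set(self.assignment.values()))

    def to_tsv(self, path: str | Path) -> None:
        lines = ["id\tlineage"]
        lines += [f"{sid}\t{lab}" for sid, lab in self.assignment.items()]
        Path(path).write_text("\n".join(lines) + "\n")


def cut_lineages(m: DistanceMatrix, threshold: float = 0.15) -> LineagePartition:
    """Single-linkage lineage delimitation at a divergence threshold.

    Two ids share a lineage iff connected by a chain of pairwise distances
    <= threshold; labels (L1, L2, ...) are assigned by order of each
    lineage's first member in the input.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    n = len(m.labels)
    if n == 1:
        return LineagePartition({m.labels[0]: "L1"}, threshold, np.inf, 0.0)
    z = linkage(squareform(m.values, checks=False), method="single")
    flat = fcluster(z, t=threshold, criterion="distance")
    label_map: dict[int, str] = {}
    assignment: dict[str, str] = {}
    for sid, c in zip(m.labels, flat):
        if c not in label_map:
            label_map[c] = f"L{len(label_map) + 1}"
        assignment[sid] = label_map[c]
    groups = np.asarray(flat)
    inter = np.inf
    intra = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            v = m.values[i, j]
            if groups[i] == groups[j]:
                intra = max(intra, v)
            else:
                inter = min(inter, v)
    return LineagePartition(assignment, threshold, float(inter), float(intra))


@dataclass(frozen=True)
class TrimParams:
    """Gblocks-style trimming options.

    ``min_flank`` is the conserved-column majority threshold; give either an
    absolute sequence count (int) or a fraction of the alignment depth
    (float in (0, 1]).
    """

    min_block: int = 5
    max_contig_nonconserved: int = 8
    min_flank: float | int = 0.55
    gap_mode: str = "half"  # columns with >= 50% gaps are excluded


@dataclass(frozen=True)
class TrimmedAlignment:
    rows: tuple[str, ...]          # source alignment
    kept_intervals: tuple[tuple[int, int], ...]  # 0-based half-open column spans
    params: TrimParams

    def __post_init__(self) -> None:
        prev = -1
        width = len(self.rows[0]) if self.rows else 0
        for a, b in self.kept_intervals:
            if not (prev < a < b <= width):
                raise ValueError("kept intervals must be sorted, disjoint, in bounds")
            prev = b
            if b - a < self.params.min_block:
                raise ValueError("kept block shorter than min_block")

    @property
    def kept_columns(self) -> list[int]:
        return [c for a, b in self.kept_intervals for c in range(a, b)]

    def trimmed_rows(self) -> list[str]:
        cols = self.kept_columns
        return ["".join(row[c] for c in cols) for row in self.rows]


def _classify_columns(rows: Sequence[str], params: TrimParams) -> str:
    """Per-column class string: c (conserved), n (nonconserved), g (gap-excluded)."""
    nseq = len(rows)
    if isinstance(params.min_flank, float):
        if not 0 < params.min_flank <= 1:
            raise ValueError("fractional min_flank must be in (0, 1]")
        need = params.min_flank * nseq
    else:
        need = float(params.min_flank)
    out = []
    for col in zip(*rows):
        gaps = sum(c == "-" for c in col)
        if params.gap_mode == "half" and gaps * 2 >= nseq:
            out.append("g")
            continue
        counts = Counter(c for c in col if c != "-")
        top = counts.most_common(1)[0][1] if counts else 0
        out.append("c" if top >= need else "n")
    return "".join(out)


def trim_blocks(
    rows: Sequence[str], params: TrimParams = TrimParams()
) -> TrimmedAlignment:
    """Remove unreliably aligned columns, Gblocks-style.

    Columns are classified conserved / nonconserved / gap-excluded (gaps in
    at least half the sequences).  Runs of non-conserved columns longer than
    ``max_contig_nonconserved`` — and any run containing a gap-excluded
    column — are removed; surviving stretches are trimmed back to conserved
    flanks, and blocks shorter than ``min_block`` are dropped.  Re-trimming
    a trimmed alignment is a no-op.
    """
    if len(rows) < 2:
        raise ValueError("need at least 2 aligned sequences")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError("ragged alignment: rows differ in length")
    classes = _classify_columns(rows, params)
    width = len(classes)
    keep = [cls == "c" for cls in classes]
    # decide the fate of each maximal non-conserved run
    i = 0
    while i < width:
        if classes[i] == "c":
            i += 1
            continue
        j = i
        while j < width and classes[j] != "c":
            j += 1
        run = classes[i:j]
        interior = i > 0 and j < width
        if interior and "g" not in run and len(run) <= params.max_contig_nonconserved:
            for c in range(i, j):
                keep[c] = True
        i = j
    # collect blocks and enforce min_block
    intervals: list[tuple[int, int]] = []
    i = 0
    while i < width:
        if not keep[i]:
            i += 1
            continue
        j = i
        while j < width and keep[j]:
            j += 1
        if j - i >= params.min_block:
            intervals.append((i, j))
        i = j
    return TrimmedAlignment(rows=tuple(rows), kept_intervals=tuple(intervals), params=params)


@dataclass(frozen=True)
class HitFilterConfig:
    min_identity: float = 30.0   # percent
    min_coverage: float = 70.0   # percent
    max_evalue: float = 0.001
    dedup_identity: float = 95.0  # percent


def hit_filter(
    records: Sequence[HitRecord], cfg: HitFilterConfig = HitFilterConfig()
) -> list[HitRecord]:
    """Curate a homology-hit table.

    Rows below the identity/coverage floors or above the e-value ceiling are
    removed; then, within each species, hits at or above the deduplication
    identity are treated as redundant and only the lowest-e-value
    representative is kept.  The filter is idempotent.
    """
    passing = [
        h
        for h in records
        if h.identity >= cfg.min_identity
        and h.coverage >= cfg.min_coverage
        and h.e_value <= cfg.max_evalue
    ]
    best_per_species: dict[str, HitRecord] = {}
    out: list[HitRecord] = []
    for h in passing:
        if h.identity >= cfg.dedup_identity:
            cur = best_per_species.get(h.species)
            if cur is None or (h.e_value, h.subject_id) < (cur.e_value, cur.subject_id):
                best_per_species[h.species] = h
        else:
            out.append(h)
    out.extend(best_per_species.values())
    # restore input order
    order = {id(h): i for i, h in enumerate(records)}
    out.sort(key=lambda h: order[id(h)])
    return out
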