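"""Detection of LTR-flanked proviruses in genomic contigs.

An intact provirus is two long terminal repeats — identical at integration —
around an internal gag-pol-env cassette.  Detection therefore looks for long
direct repeats at a proviral spacing: seeded k-mer self-matching finds
repeat anchors, anchors sharing an offset are chained and extended by
X-drop, and the extended pair is accepted when repeat length, inter-repeat
span and alignment identity all fall in the configured windows.  Direct
repeats are strand-symmetric, so one forward scan covers both orientations;
provirus orientation is inferred later from ORF strand.

Each accepted pair is then validated for LTR hallmarks (terminal TG...CA
inverted repeat motifs, the AATAAA polyadenylation signal, a TATA-like
AT-rich stretch), assembled into a provirus call with ORF structure and
intactness, and dated from the K2P divergence of its two LTRs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .dating import DEFAULT_RATE_PANEL, AgeEstimate, RatePanel, date_with_rate_panel
from .distances import (
    DistanceEstimate,
    ScoringScheme,
    count_site_patterns,
    global_align,
    k2p_distance,
)
from .intactness import ORFIntactnessReport, count_defects
from .types import GenomicInterval, NucSequence

__all__ = [
    "LTRScanConfig",
    "MotifFlags",
    "LTRCandidate",
    "ProvirusCall",
    "find_ltr_pairs",
    "annotate_ltr_motifs",
    "call_provirus",
]


@dataclass(frozen=True)
class LTRScanConfig:
    """Tunables of the repeat-pair scan and LTR validation.

    The identity floor of 0.65 (~K2P 0.45) leaves margin over the oldest
    datable elements (D up to ~0.3) even with sampling noise on short LTRs;
    the 3-12 kb internal window generalizes the canonical ~7-11 kb provirus
    so degraded elements are not silently missed.
    """

    seed_pattern: str = "1110101101011"  # spaced seed, weight 9
    min_ltr: int = 100
    max_ltr: int = 1500
    min_internal: int = 3000
    max_internal: int = 12000
    min_identity: float = 0.65
    min_anchors: int = 2   # spaced-seed hits required per repeat candidate
    band: int = 8          # offset tolerance when merging anchor clusters
    xdrop: int = 15        # ungapped extension drop-off
    boundary_slack: int = 12  # window for snapping to terminal TG/CA
    end_slack: int = 2     # motif check slack at LTR termini
    at_window: int = 20
    at_min: float = 0.7
    min_orf_aa: int = 80
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    rate_panel: RatePanel = field(default=DEFAULT_RATE_PANEL)

    @property
    def min_span(self) -> int:
        return 2 * self.min_ltr + self.min_internal


@dataclass(frozen=True)
class MotifFlags:
    """LTR hallmark flags for one repeat copy."""

    starts_TG: bool
    ends_CA: bool
    polyA_pos: int | None   # AATAAA position in the 3' half, or None
    at_rich_pos: int | None  # AT-rich window start in the 5' half, or None


@dataclass(frozen=True)
class LTRCandidate:
    """A detected direct-repeat pair, putative 5'/3' LTRs."""

    left: GenomicInterval
    right: GenomicInterval
    identity: float
    motifs: tuple[MotifFlags, MotifFlags]
    boundary_disagreement: bool = False

    def __post_init__(self) -> None:
        if self.left.contig_id != self.right.contig_id:
            raise ValueError("LTR pair must be on one contig")
        if self.left.end >= self.right.start:
            raise ValueError("left LTR must end before right LTR starts")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")


@dataclass(frozen=True)
class ProvirusCall:
    """A full provirus call: LTR pair, structure, decay and age estimates."""

    ltr_pair: LTRCandidate
    internal: GenomicInterval
    orf_order_ok: bool
    divergence: DistanceEstimate
    ages: list[AgeEstimate]
    strand: str = "+"
    orfs: list[GenomicInterval] = field(default_factory=list)
    intactness: ORFIntactnessReport | None = None
    tsd_length: int = 0

    def __post_init__(self) -> None:
        if not (
            self.ltr_pair.left.end <= self.internal.start
            and self.internal.end <= self.ltr_pair.right.start
        ):
            raise ValueError("internal region must lie between the LTRs")


def annotate_ltr_motifs(ltr: NucSequence | str, cfg: LTRScanConfig = LTRScanConfig()) -> MotifFlags:
    """Check one LTR copy for the canonical hallmarks.

    Terminal TG/CA are accepted within ``end_slack`` bp of the ends; AATAAA
    is searched exactly in the 3' half; the AT-rich (TATA-like) criterion is
    any ``at_window`` window with AT fraction >= ``at_min`` in the 5' half.
    """
    s = ltr.residues if isinstance(ltr, NucSequence) else ltr
    n = len(s)
    starts = any(s[i : i + 2] == "TG" for i in range(0, min(cfg.end_slack, n - 1) + 1))
    ends = any(
        s[n - 2 - i : n - i] == "CA" for i in range(0, min(cfg.end_slack, n - 1) + 1)
    )
    idx = s.find("AATAAA", n // 2)
    poly = idx if idx != -1 else None
    at_pos = None
    half = n // 2
    w = cfg.at_window
    if half >= w:
        at = sum(c in "AT" for c in s[:w])
        if at / w >= cfg.at_min:
            at_pos = 0
        else:
            for i in range(1, half - w + 1):
                at += (s[i + w - 1] in "AT") - (s[i - 1] in "AT")
                if at / w >= cfg.at_min:
                    at_pos = i
                    break
    return MotifFlags(starts_TG=starts, ends_CA=ends, polyA_pos=poly, at_rich_pos=at_pos)


def _xdrop_extend(seq: str, start: int, d: int, step: int, xdrop: int, lo: int, hi: int) -> int:
    """Ungapped X-drop extension comparing seq[x] to seq[x+d].

    Walks from ``start`` in direction ``step`` while x stays in [lo, hi);
    returns the position achieving the best running score.
    """
    best = score = 0
    best_x = start - step  # nothing taken yet
    x = start
    while lo <= x < hi and x + d < len(seq):
        score += 1 if seq[x] == seq[x + d] else -1
        if score > best:
            best, best_x = score, x
        elif best - score > xdrop:
            break
        x += step
    return best_x


def _refine_boundaries(seq: str, ls: int, le: int, d: int) -> tuple[int, int]:
    """Changepoint refinement of the raw extension boundaries.

    X-drop occasionally overruns into unrelated flank on a lucky run of
    matches.  Columns match at ~25% in flank and at the repeat's core
    identity inside, so each boundary is re-placed where the cumulative sum
    of (match - theta) turns, with theta halfway between the two rates.
    """
    L = le - ls
    if L < 20:
        return ls, le
    core = range(ls + L // 4, ls + 3 * L // 4)
    core_id = sum(seq[x] == seq[x + d] for x in core) / len(core)
    theta = 0.5 * (0.25 + core_id)
    w_in = min(40, L // 3)

    # start boundary: minimize C[s] over [ls - w_out, ls + w_in]
    w_out = min(40, ls)
    lo = ls - w_out
    vals = [(1.0 if seq[x] == seq[x + d] else 0.0) - theta for x in range(lo, ls + w_in)]
    c = [0.0]
    for v in vals:
        c.append(c[-1] + v)
    best = min(range(len(c)), key=lambda i: (c[i], abs(lo + i - ls)))
    new_ls = lo + best

    # end boundary: maximize C[e] over [le - w_in, le + w_out]
    w_out_r = min(40, len(seq) - d - le)
    lo_e = le - w_in
    vals = [(1.0 if seq[x] == seq[x + d] else 0.0) - theta for x in range(lo_e, le + w_out_r)]
    c = [0.0]
    for v in vals:
        c.append(c[-1] + v)
    best = max(range(len(c)), key=lambda i: (c[i], -abs(lo_e + i - le)))
    new_le = lo_e + best
    if new_le - new_ls >= 20:
        ls, le = new_ls, new_le
    return ls, le


def _snap_boundaries(
    seq: str, ls: int, le: int, d: int, cfg: LTRScanConfig
) -> tuple[int, int, bool]:
    """Trim the alignment extent to terminal TG...CA when both copies agree."""
    disagreement = False

    def nearest(target: int, pred) -> int | None:
        cands = [
            s
            for s in range(max(0, target - cfg.boundary_slack), target + cfg.boundary_slack + 1)
            if pred(s)
        ]
        return min(cands, key=lambda s: abs(s - target)) if cands else None

    s_new = nearest(
        ls,
        lambda s: 0 <= s and s + d + 2 <= len(seq)
        and seq[s : s + 2] == "TG" and seq[s + d : s + d + 2] == "TG",
    )
    e_new = nearest(
        le,
        lambda e: e >= 2 and e + d <= len(seq)
        and seq[e - 2 : e] == "CA" and seq[e + d - 2 : e + d] == "CA",
    )
    if s_new is not None:
        disagreement |= abs(s_new - ls) > 10
        ls = s_new
    if e_new is not None:
        disagreement |= abs(e_new - le) > 10
        le = e_new
    return ls, le, disagreement


def find_ltr_pairs(contig: NucSequence, cfg: LTRScanConfig = LTRScanConfig()) -> list[LTRCandidate]:
    """Find direct-repeat pairs compatible with an LTR-flanked provirus.

    Seeded k-mer self-matching yields repeat anchors; anchors sharing an
    offset are chained and extended by ungapped X-drop; a pair is reported
    iff repeat length, inter-repeat span and global-alignment identity pass
    the configured thresholds.  Overlapping candidates are resolved by
    keeping the highest identity, then the longest.  An empty list is a
    valid result.
    """
    seq = contig.residues
    n = len(seq)
    if n < cfg.min_span:
        return []
    pattern = [i for i, c in enumerate(cfg.seed_pattern) if c == "1"]
    k = len(cfg.seed_pattern)
    d_lo = cfg.min_internal + cfg.min_ltr
    d_hi = cfg.max_internal + cfg.max_ltr

    index: dict[str, list[int]] = defaultdict(list)
    for i in range(n - k + 1):
        key = "".join(seq[i + off] for off in pattern)
        if "N" not in key:
            index[key].append(i)

    by_offset: dict[int, list[int]] = defaultdict(list)
    for positions in index.values():
        t = len(positions)
        if t < 2 or t > 100:  # skip unique and low-complexity seeds
            continue
        for a_i in range(t):
            for b_i in range(a_i + 1, t):
                d = positions[b_i] - positions[a_i]
                if d_lo <= d <= d_hi:
                    by_offset[d].append(positions[a_i])
    if not by_offset:
        return []

    # anchors sharing an offset are clustered by left position; each cluster
    # with enough seed hits becomes one extension candidate
    raw: list[tuple[int, int, int, int]] = []  # (d, median anchor, extent, n_anchors)
    for d, positions in by_offset.items():
        positions.sort()
        start = 0
        for i in range(1, len(positions) + 1):
            if i == len(positions) or positions[i] - positions[i - 1] > cfg.max_ltr:
                cluster = positions[start:i]
                if len(cluster) >= cfg.min_anchors:
                    raw.append(
                        (d, cluster[len(cluster) // 2], cluster[-1] - cluster[0], len(cluster))
                    )
                start = i
    # merge clusters at nearly identical offsets covering the same region
    raw.sort(key=lambda r: (-r[3], r[0], r[1]))
    merged: list[tuple[int, int]] = []  # (offset, seed anchor)
    for d, mid, _extent, _cnt in raw:
        if any(
            abs(d - md) <= cfg.band and abs(mid - mmid) <= cfg.max_ltr
            for md, mmid in merged
        ):
            continue
        merged.append((d, mid))

    candidates: list[LTRCandidate] = []
    for d0, mid in merged:
        # extend outwards from the densest part of the anchor cluster
        ls = max(_xdrop_extend(seq, mid - 1, d0, -1, cfg.xdrop, 0, n), 0)
        le = min(_xdrop_extend(seq, mid + k, d0, +1, cfg.xdrop, 0, n) + 1, ls + d0, n - d0)
        ls, le = _refine_boundaries(seq, ls, le, d0)
        le = min(le, ls + d0, n - d0)
        ls, le, disagreement = _snap_boundaries(seq, ls, le, d0, cfg)
        rep_len = le - ls
        span = d0 - rep_len
        if not (cfg.min_ltr <= rep_len <= cfg.max_ltr):
            continue
        if not (cfg.min_internal <= span <= cfg.max_internal):
            continue
        left_s, right_s = seq[ls:le], seq[ls + d0 : le + d0]
        aln = global_align(left_s, right_s, cfg.scheme)
        if aln.identity < cfg.min_identity:
            continue
        candidates.append(
            LTRCandidate(
                left=GenomicInterval(contig.id, ls, le),
                right=GenomicInterval(contig.id, ls + d0, le + d0),
                identity=aln.identity,
                motifs=(annotate_ltr_motifs(left_s, cfg), annotate_ltr_motifs(right_s, cfg)),
                boundary_disagreement=disagreement,
            )
        )

    # resolve overlaps: highest identity, then longest, then leftmost
    candidates.sort(key=lambda c: (-c.identity, -len(c.left), c.left.start))
    kept: list[LTRCandidate] = []
    for c in candidates:
        clash = any(
            c.left.overlaps(o.left) or c.right.overlaps(o.right)
            or c.left.overlaps(o.right) or c.right.overlaps(o.left)
            for o in kept
        )
        if not clash:
            kept.append(c)
    kept.sort(key=lambda c: c.left.start)
    return kept


def _find_orfs(
    internal_seq: str, offset: int, contig_id: str, min_aa: int
) -> list[GenomicInterval]:
    """Six-frame ATG..stop ORFs of >= min_aa codons, in contig coordinates."""
    orfs: list[GenomicInterval] = []
    n = len(internal_seq)

    def scan(s: str, strand: str) -> None:
        for frame in range(3):
            start: int | None = None
            for i in range(frame, len(s) - 2, 3):
                codon = s[i : i + 3]
                if codon == "ATG" and start is None:
                    start = i
                elif codon in ("TAA", "TAG", "TGA") and start is not None:
                    if (i + 3 - start) // 3 - 1 >= min_aa:
                        if strand == "+":
                            orfs.append(
                                GenomicInterval(contig_id, offset + start, offset + i + 3, "+")
                            )
                        else:
                            orfs.append(
                                GenomicInterval(
                                    contig_id, offset + n - (i + 3), offset + n - start, "-"
                                )
                            )
                    start = None

    scan(internal_seq, "+")
    scan(str(Seq(internal_seq).reverse_complement()), "-")
    orfs.sort(key=lambda o: (o.start, o.end))
    return orfs


def call_provirus(
    contig: NucSequence,
    pair: LTRCandidate,
    pol_reference: str | None = None,
    cfg: LTRScanConfig = LTRScanConfig(),
) -> ProvirusCall:
    """Assemble a provirus call from a validated LTR pair.

    ORFs of at least ``min_orf_aa`` codons are extracted from the internal
    region in six frames; the call is structurally plausible
    (``orf_order_ok``) when at least three ORFs lie on one strand, their
    order standing in for the gag-pol-env cassette (positional assignment:
    first/middle/last).  LTR divergence is the K2P distance between the two
    repeat copies re-extracted from the contig; ages come from the rate
    panel; coding decay is scored against ``pol_reference`` when given,
    using the span between the first and last ORF as the pol query.
    """
    if pair.left.end >= pair.right.start:
        raise ValueError("empty internal region between LTRs")
    internal = GenomicInterval(contig.id, pair.left.end, pair.right.start)
    internal_seq = internal.slice(contig)
    if len(internal_seq) < 3 * cfg.min_orf_aa:
        raise ValueError(
            f"internal region ({len(internal_seq)} bp) shorter than one "
            f"minimum ORF ({3 * cfg.min_orf_aa} bp)"
        )
    orfs = _find_orfs(internal_seq, internal.start, contig.id, cfg.min_orf_aa)
    fwd = [o for o in orfs if o.strand == "+"]
    rev = [o for o in orfs if o.strand == "-"]
    strand = "+" if len(fwd) >= len(rev) else "-"
    stranded = fwd if strand == "+" else rev
    orf_order_ok = len(stranded) >= 3

    aln = global_align(pair.left.slice(contig), pair.right.slice(contig), cfg.scheme)
    divergence = k2p_distance(count_site_patterns(aln))
    ages = date_with_rate_panel(divergence, cfg.rate_panel)

    intact: ORFIntactnessReport | None = None
    if pol_reference is not None:
        if orf_order_ok:
            pol_lo = stranded[0].end - internal.start
            pol_hi = stranded[-1].start - internal.start
            query = internal_seq[pol_lo:pol_hi] if pol_hi - pol_lo >= 3 else internal_seq
        else:
            query = internal_seq
        if strand == "-":
            query = str(Seq(query).reverse_complement())
        intact = count_defects(query, pol_reference)

    # target-site duplication evidence (4-6 bp identical flanks); never
    # required for a call.  Small boundary shifts are tolerated because a
    # TSD overlapping the terminal motif can pull the called boundary a few
    # bases off the integration site.
    tsd_len = 0
    seq = contig.residues
    for t in (6, 5, 4):
        for shift_l, shift_r in sorted(
            ((a, b) for a in range(-3, 4) for b in range(-3, 4)),
            key=lambda ab: (abs(ab[0]) + abs(ab[1]), ab),
        ):
            a0 = pair.left.start + shift_l
            b0 = pair.right.end + shift_r
            if a0 - t >= 0 and b0 + t <= len(seq) and seq[a0 - t : a0] == seq[b0 : b0 + t]:
                tsd_len = t
                break
        if tsd_len:
            break

    return ProvirusCall(
        ltr_pair=pair,
        internal=internal,
        orf_order_ok=orf_order_ok,
        divergence=divergence,
        ages=ages,
        strand=strand,
        orfs=stranded,
        intactness=intact,
        tsd_length=tsd_len,
    )
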