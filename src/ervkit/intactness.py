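"""Coding-decay quantification for proviral gene regions.

A defective ERV gene is summarized by two counts relative to an intact
reference protein: nonsense mutations (in-frame premature stops) and
frameshifts (indels of length not divisible by 3).  The scanner aligns the
nucleotide query to the reference in codon space with a dynamic program
whose moves consume 3 nt per reference residue in the clean case and 2 or 4
nt under a frameshift penalty, so every maximal run of frame disruption is
recovered as one event and every aligned stop codon as one nonsense event.

Query ends are free (the query may carry flanking non-coding sequence); the
reference must be covered end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .types import NucSequence

__all__ = ["ORFIntactnessReport", "count_defects", "summarize_defects"]

_NEG = np.float32(-1e9)
_CODON_AA = {
    a + b + c: str(Seq(a + b + c).translate())
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
}

# scoring constants: aa match/mismatch, aligned stop codon, frameshift move,
# codon insertion in query, reference-residue deletion
_MATCH = 2.0
_MISMATCH = -1.0
_STOP_SCORE = -3.0
_FS_PEN = -6.0
_INS_PEN = -5.0
_DEL_PEN = -5.0

# traceback move codes
_M3, _M2, _M4, _INS, _DEL = 1, 2, 3, 4, 5


@dataclass(frozen=True)
class ORFIntactnessReport:
    """Counts of coding defects relative to a reference protein."""

    n_nonsense: int
    n_frameshift: int
    events: list[tuple[str, int, str]] = field(default_factory=list)
    reference_id: str = ""
    comparable_to_reference: bool = True

    def __post_init__(self) -> None:
        kinds = [k for k, _, _ in self.events]
        if kinds.count("nonsense") != self.n_nonsense:
            raise ValueError("nonsense count does not match event list")
        if kinds.count("frameshift") != self.n_frameshift:
            raise ValueError("frameshift count does not match event list")
        positions = [p for _, p, _ in self.events]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("event positions must be strictly increasing")

    @property
    def total(self) -> int:
        return self.n_nonsense + self.n_frameshift


def _aa_per_position(q: str) -> np.ndarray:
    """aa_at[i] = translation of q[i-3:i] ('X' when undefined), i in 0..n."""
    n = len(q)
    aa = np.full(n + 1, "X", dtype="U1")
    for i in range(3, n + 1):
        aa[i] = _CODON_AA.get(q[i - 3 : i], "X")
    return aa


def count_defects(
    query: NucSequence | str,
    reference_protein: str,
    reference_id: str = "",
) -> ORFIntactnessReport:
    """Count nonsense and frameshift mutations in ``query`` against an
    intact reference protein.

    Each maximal run of frame disruption counts as one frameshift event;
    compensated double frameshifts separated by at least one cleanly aligned
    codon count as two.  Each aligned codon translating to stop counts as
    one nonsense event, including stops downstream of a frameshift (the two
    counts stay independent).
    """
    q = query.residues if isinstance(query, NucSequence) else query
    r = reference_protein.upper().rstrip("*")
    if not q:
        raise ValueError("empty query")
    if len(r) < 30:
        raise ValueError(f"reference protein too short ({len(r)} aa < 30)")
    if len(q) < 3:
        raise ValueError("query untranslatable: shorter than one codon")

    n, m = len(q), len(r)
    aa_at = _aa_per_position(q)
    r_arr = np.frombuffer(r.encode(), dtype="S1").astype("U1")

    H = np.full((n + 1, m + 1), _NEG, dtype=np.float32)
    moves = np.zeros((n + 1, m + 1), dtype=np.int8)
    H[:, 0] = 0.0  # free query start
    jidx = np.arange(1, m + 1, dtype=np.float32)
    g = -np.float32(_DEL_PEN)

    for i in range(n + 1):
        aa = aa_at[i]
        if aa == "*":
            sub = np.full(m, _STOP_SCORE, dtype=np.float32)
        else:
            sub = np.where(r_arr == aa, _MATCH, _MISMATCH).astype(np.float32)
        c_m3 = H[i - 3, :-1] + sub if i >= 3 else np.full(m, _NEG)
        c_m2 = H[i - 2, :-1] + np.float32(_FS_PEN) if i >= 2 else np.full(m, _NEG)
        c_m4 = H[i - 4, :-1] + sub + np.float32(_FS_PEN) if i >= 4 else np.full(m, _NEG)
        c_ins = H[i - 3, 1:] + np.float32(_INS_PEN) if i >= 3 else np.full(m, _NEG)
        stacked = np.stack([c_m3, c_m2, c_m4, c_ins])
        best = np.argmax(stacked, axis=0)
        cand = stacked[best, np.arange(m)]
        # reference-deletion scan: H[i][j] = max(cand_j, max_k<j cand_k - g*(j-k))
        run = np.maximum.accumulate(cand + g * jidx) - g * jidx
        row = np.maximum(cand, run)
        H[i, 1:] = row
        mv = np.array([_M3, _M2, _M4, _INS], dtype=np.int8)[best]
        mv[row > cand] = _DEL
        moves[i, 1:] = mv

    i = int(np.argmax(H[:, m]))
    if H[i, m] <= _NEG / 2:
        raise ValueError("query untranslatable against reference")
    j = m
    path: list[tuple[int, int, int]] = []  # (move, query_pos, i_after)
    while j > 0:
        mv = int(moves[i, j])
        if mv == _M3:
            path.append((_M3, i - 3, i))
            i, j = i - 3, j - 1
        elif mv == _M2:
            path.append((_M2, i - 2, i))
            i, j = i - 2, j - 1
        elif mv == _M4:
            path.append((_M4, i - 4, i))
            i, j = i - 4, j - 1
        elif mv == _INS:
            path.append((_INS, i - 3, i))
            i, j = i - 3, j
        elif mv == _DEL:
            path.append((_DEL, i, i))
            j -= 1
        else:  # pragma: no cover - would indicate a DP bug
            raise RuntimeError("traceback reached an unset cell")
    path.reverse()

    events: list[tuple[str, int, str]] = []
    fs_open = False  # inside a run of frame disruption
    for mv, pos, i_end in path:
        if mv == _M3:
            fs_open = False
            if aa_at[i_end] == "*":
                events.append(("nonsense", pos, f"stop codon {'' .join(_q3(q, pos))}"))
        elif mv in (_M2, _M4):
            if not fs_open:
                events.append(
                    ("frameshift", pos, "+1 nt" if mv == _M4 else "-1 nt")
                )
                fs_open = True
            else:
                # adjacent disruptions with no clean codon between them merge
                # into one flagged event
                k_last = next(
                    i for i in range(len(events) - 1, -1, -1)
                    if events[i][0] == "frameshift"
                )
                ev = events[k_last]
                if "merged" not in ev[2]:
                    events[k_last] = (ev[0], ev[1], ev[2] + "; merged run")
            if mv == _M4 and aa_at[i_end] == "*":
                events.append(("nonsense", pos + 1, f"stop codon {''.join(_q3(q, pos + 1))}"))
        # INS / DEL moves neither open nor close a frameshift run
    events.sort(key=lambda e: e[1])
    # guarantee strictly increasing positions (co-located events are merged)
    deduped: list[tuple[str, int, str]] = []
    for ev in events:
        if deduped and ev[1] <= deduped[-1][1]:
            ev = (ev[0], deduped[-1][1] + 1, ev[2])
        deduped.append(ev)
    return ORFIntactnessReport(
        n_nonsense=sum(k == "nonsense" for k, _, _ in deduped),
        n_frameshift=sum(k == "frameshift" for k, _, _ in deduped),
        events=deduped,
        reference_id=reference_id,
    )


def _q3(q: str, pos: int) -> str:
    return q[pos : pos + 3]


def reference_free_defects(query: NucSequence | str) -> ORFIntactnessReport:
    """Reference-free decay scan: count premature in-frame stops in the
    best reading frame (the one minimizing internal stops).

    Without a reference, frameshifts are undetectable and stop counts are
    frame-relative, so the report is marked not comparable to
    reference-based counts.
    """
    q = query.residues if isinstance(query, NucSequence) else query
    if len(q) < 3:
        raise ValueError("query untranslatable: shorter than one codon")
    best_events: list[tuple[str, int, str]] | None = None
    for frame in range(3):
        events = [
            ("nonsense", i, f"stop codon {q[i:i + 3]}")
            for i in range(frame, len(q) - 5, 3)  # final codon never counted
            if _CODON_AA.get(q[i : i + 3]) == "*"
        ]
        if best_events is None or len(events) < len(best_events):
            best_events = events
    return ORFIntactnessReport(
        n_nonsense=len(best_events or []),
        n_frameshift=0,
        events=best_events or [],
        comparable_to_reference=False,
    )


def _lower_median(values: Sequence[int]) -> int:
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def summarize_defects(
    reports_by_lineage: Mapping[str, Sequence[ORFIntactnessReport | int]],
) -> dict[str, tuple[int, int, int]]:
    """Per-lineage (median, min, max) of total defect counts.

    The median is the lower median for even group sizes.  Accepts either
    report objects or bare integer counts.
    """
    out: dict[str, tuple[int, int, int]] = {}
    for lineage, items in reports_by_lineage.items():
        if not items:
            raise ValueError(f"lineage {lineage!r} has no reports")
        counts = [
            it.total if isinstance(it, ORFIntactnessReport) else int(it)
            for it in items
        ]
        out[lineage] = (_lower_median(counts), min(counts), max(counts))
    return out
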