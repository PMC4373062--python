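"""Pairwise global alignment and sequence-divergence estimators.

Two estimators matter downstream: the uncorrected p-distance (reported per
lineage) and Kimura's two-parameter distance, which corrects the observed
transition (P) and transversion (Q) proportions for multiple hits:

    D = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

D feeds the insertion-dating relation T = (D / R) / 2 in
:mod:`ervkit.dating`.  Columns containing a gap or an ambiguous residue are
excluded pairwise from the compared-site count, so distances are computed on
unambiguous sites only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from Bio import Align

from .types import NucSequence

__all__ = [
    "ScoringScheme",
    "PairwiseAlignment",
    "SiteCounts",
    "DistanceEstimate",
    "DistanceMatrix",
    "SaturationError",
    "global_align",
    "count_site_patterns",
    "p_distance",
    "k2p_distance",
    "distance_matrix",
]

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
_EXCLUDED = frozenset("-NX")  # skipped columns: gaps, ambiguous nt, ambiguous aa


class SaturationError(ValueError):
    """K2P distance undefined: substitution saturation (log argument <= 0)."""


@dataclass(frozen=True)
class ScoringScheme:
    """Affine alignment scoring.  A gap of length L scores
    ``gap_open + L * gap_extend`` (both negative)."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class PairwiseAlignment:
    gapped_a: str
    gapped_b: str
    score: float
    scoring_scheme: ScoringScheme

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b):
            raise ValueError("gapped rows differ in length")
        for a, b in zip(self.gapped_a, self.gapped_b):
            if a == "-" and b == "-":
                raise ValueError("gap/gap column in alignment")

    @property
    def identity(self) -> float:
        """Matching columns over all alignment columns."""
        m = sum(a == b for a, b in zip(self.gapped_a, self.gapped_b))
        return m / len(self.gapped_a)


@dataclass(frozen=True)
class SiteCounts:
    """Compared-site tallies from a pairwise alignment.

    ``n`` counts gap- and N-free columns; ``ts`` transitions (A<->G, C<->T);
    ``tv`` transversions.
    """

    n: int
    ts: int
    tv: int

    def __post_init__(self) -> None:
        if min(self.n, self.ts, self.tv) < 0 or self.ts + self.tv > self.n:
            raise ValueError(f"inconsistent site counts: {self}")

    @property
    def P(self) -> float:
        return self.ts / self.n

    @property
    def Q(self) -> float:
        return self.tv / self.n


@dataclass(frozen=True)
class DistanceEstimate:
    model: Literal["p", "K2P", "amino_p"]
    value: float
    se: float
    n_sites: int
    n_diff: int

    def __post_init__(self) -> None:
        if self.value < 0 or self.se < 0:
            raise ValueError("distance and SE must be non-negative")


def _make_aligner(scheme: ScoringScheme, protein: bool = False) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scheme.match
    aligner.mismatch_score = scheme.mismatch
    # Biopython charges open_gap_score for the first gapped position, so a
    # length-L gap scores open+ext + (L-1)*ext = gap_open + L*gap_extend.
    aligner.open_gap_score = scheme.gap_open + scheme.gap_extend
    aligner.extend_gap_score = scheme.gap_extend
    return aligner


def global_align(
    a: NucSequence | str,
    b: NucSequence | str,
    scheme: ScoringScheme = ScoringScheme(),
) -> PairwiseAlignment:
    """Optimal global (Needleman-Wunsch) alignment under affine gap scoring.

    Accepts nucleotide or plain strings (the latter so that amino-acid
    sequences can go through the same machinery).  Ties between co-optimal
    alignments are broken deterministically (the aligner's canonical first
    path).
    """
    sa = a.residues if isinstance(a, NucSequence) else a
    sb = b.residues if isinstance(b, NucSequence) else b
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(scheme)
    aln = aligner.align(sa, sb)[0]
    return PairwiseAlignment(
        gapped_a=str(aln[0]), gapped_b=str(aln[1]),
        score=float(aln.score), scoring_scheme=scheme,
    )


def count_site_patterns(aln: PairwiseAlignment) -> SiteCounts:
    """Tally compared sites, transitions and transversions.

    Columns containing '-' or an ambiguous residue (N/X) are excluded from
    ``n`` (pairwise deletion).
    """
    n = ts = tv = 0
    for x, y in zip(aln.gapped_a, aln.gapped_b):
        if x in _EXCLUDED or y in _EXCLUDED:
            continue
        n += 1
        if x == y:
            continue
        if {x, y} <= PURINES or {x, y} <= PYRIMIDINES:
            ts += 1
        else:
            tv += 1
    return SiteCounts(n=n, ts=ts, tv=tv)


def p_distance(
    counts: SiteCounts,
    se_method: Literal["analytic", "bootstrap"] = "analytic",
    n_bootstrap: int = 1000,
    seed: int = 0,
    model: Literal["p", "amino_p"] = "p",
) -> DistanceEstimate:
    """Uncorrected proportion of differing sites, with its standard error.

    The analytic SE is the binomial sqrt(p(1-p)/n); the bootstrap resamples
    sites with replacement (seeded).
    """
    if counts.n == 0:
        raise ValueError("no comparable sites (n = 0)")
    d = counts.ts + counts.tv
    p = d / counts.n
    if se_method == "analytic":
        se = math.sqrt(p * (1.0 - p) / counts.n)
    elif se_method == "bootstrap":
        rng = np.random.default_rng(seed)
        draws = rng.binomial(counts.n, p, size=n_bootstrap) / counts.n
        se = float(np.std(draws, ddof=1))
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    return DistanceEstimate(model=model, value=p, se=se, n_sites=counts.n, n_diff=d)


def k2p_distance(counts: SiteCounts) -> DistanceEstimate:
    """Kimura two-parameter distance with delta-method standard error.

    Raises
    ------
    SaturationError
        When 1-2P-Q <= 0 or 1-2Q <= 0 and the distance is undefined.
    """
    if counts.n == 0:
        raise ValueError("no comparable sites (n = 0)")
    P, Q = counts.P, counts.Q
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P distance undefined at P={P:.4f}, Q={Q:.4f} (saturation)"
        )
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    # delta-method variance (Kimura 1980): c1 = 1/w1, c2 = 1/w2, c3 = (c1+c2)/2
    c1 = 1.0 / w1
    c2 = 1.0 / w2
    c3 = 0.5 * (c1 + c2)
    var = (c1 * c1 * P + c3 * c3 * Q - (c1 * P + c3 * Q) ** 2) / counts.n
    se = math.sqrt(max(var, 0.0))
    return DistanceEstimate(
        model="K2P", value=d, se=se, n_sites=counts.n, n_diff=counts.ts + counts.tv
    )


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise distances with ordered labels."""

    labels: list[str]
    values: np.ndarray
    estimates: dict[tuple[str, str], DistanceEstimate] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distance matrix has negative entries")
        self.values = v

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t"
        )

    def to_phylip(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")


def distance_matrix(
    seqs: Sequence[NucSequence] | Sequence[tuple[str, str]],
    model: Literal["p", "K2P", "amino_p"] = "K2P",
    scheme: ScoringScheme = ScoringScheme(),
) -> DistanceMatrix:
    """All-pairs distances: global alignment -> site counts -> estimator.

    ``amino_p`` computes a p-distance on amino-acid strings passed as
    ``(id, residues)`` tuples; X and gap columns are excluded like N columns.
    Undefined pairs (K2P saturation) are reported with the offending ids.
    """
    items: list[tuple[str, str]] = []
    for s in seqs:
        if isinstance(s, NucSequence):
            items.append((s.id, s.residues))
        else:
            items.append((s[0], s[1]))
    if len(items) < 2:
        raise ValueError("need at least 2 sequences")
    labels = [i for i, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence ids")
    n = len(items)
    vals = np.zeros((n, n))
    estimates: dict[tuple[str, str], DistanceEstimate] = {}
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(items[i][1], items[j][1], scheme)
            counts = count_site_patterns(aln)
            try:
                if model == "K2P":
                    est = k2p_distance(counts)
                else:
                    est = p_distance(counts, model="amino_p" if model == "amino_p" else "p")
            except (SaturationError, ValueError) as exc:
                raise type(exc)(
                    f"pair ({labels[i]!r}, {labels[j]!r}): {exc}"
                ) from exc
            vals[i, j] = vals[j, i] = est.value
            estimates[(labels[i], labels[j])] = est
    return DistanceMatrix(labels=labels, values=vals, estimates=estimates)
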