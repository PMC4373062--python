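"""Synthetic provirus generator.

Builds host contigs containing a single LTR-flanked provirus with known
ground truth, so that detection, dating, intactness scoring and clustering
can all be benchmarked without genome downloads.  The generative model
mirrors the biology the dating relation assumes: one ancestral LTR is
duplicated at integration and each copy then evolves independently under a
Kimura two-parameter process at branch length R*T, so the expected pairwise
LTR divergence is 2*R*T.  The internal gag-pol-env cassette is built from
sense codons and decays only through explicitly injected nonsense and
frameshift mutations, which keeps the injected defect counts an exact truth
table for the intactness scanner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import write_fasta
from .types import GenomicInterval, NucSequence

__all__ = [
    "SimulationParams",
    "SimulatedProvirus",
    "make_ancestral_ltr",
    "mutate_k2p",
    "simulate_provirus",
    "generate_dataset",
]

_BASES = np.array(["A", "C", "G", "T"])
_CODE = {b: i for i, b in enumerate("ACGT")}
_TS_PARTNER = np.array([2, 3, 0, 1])  # A<->G, C<->T
_TV_PARTNERS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of one simulated provirus.

    Defaults emulate a typical gammaretrovirus-like felid ERV: ~400 bp LTRs
    around a ~7 kb internal cassette (provirus ~7.8 kb), a 10 MY-old
    insertion at the intermediate literature rate, a conventional mammalian
    transition bias (kappa = 2), a handful of coding defects, a 4-6 bp
    target-site duplication and a host backbone at felid-like GC.
    """

    ltr_length: int = 400
    internal_length: int = 7000
    true_age: float = 10e6  # years
    rate: float = 5e-9  # substitutions/site/year
    kappa: float = 2.0
    n_nonsense: int = 2
    n_frameshift: int = 2
    tsd_length: int = 5
    backbone_length: int = 20000
    gc_content: float = 0.42
    seed: int = 0

    def __post_init__(self) -> None:
        errs = []
        if self.ltr_length < 50:
            errs.append("ltr_length must be >= 50")
        if self.internal_length < 300:
            errs.append("internal_length must be >= 300")
        if self.true_age < 0:
            errs.append("true_age must be >= 0")
        if self.rate <= 0:
            errs.append("rate must be > 0")
        if self.kappa <= 0:
            errs.append("kappa must be > 0")
        if min(self.n_nonsense, self.n_frameshift, self.tsd_length) < 0:
            errs.append("counts and tsd_length must be >= 0")
        if not 0 < self.gc_content < 1:
            errs.append("gc_content must be in (0, 1)")
        if self.backbone_length <= 2 * self.ltr_length + self.internal_length:
            errs.append("backbone_length must exceed 2*ltr_length + internal_length")
        if errs:
            raise ValueError("; ".join(errs))


@dataclass(frozen=True)
class SimulatedProvirus:
    """A simulated contig plus its ground truth."""

    contig: NucSequence
    ltr5: GenomicInterval
    ltr3: GenomicInterval
    internal: GenomicInterval
    tsd: tuple[GenomicInterval, GenomicInterval]
    true_age: float
    rate: float
    expected_divergence: float
    injected_defects: list[tuple[str, int]]  # (kind, nt offset within pol ORF)
    # convenience truth beyond the minimal record
    pol_region: GenomicInterval = field(default=None)  # type: ignore[assignment]
    pol_protein: str = ""
    params: SimulationParams = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (
            self.ltr5.end <= self.internal.start
            and self.internal.end <= self.ltr3.start
        ):
            raise ValueError("intervals must be ordered ltr5 < internal < ltr3")
        expected = 2.0 * self.rate * self.true_age
        if abs(self.expected_divergence - expected) > 1e-12:
            raise ValueError("expected_divergence must equal 2*rate*true_age")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def make_ancestral_ltr(
    ltr_length: int, gc_content: float = 0.42, seed: int = 0
) -> NucSequence:
    """Construct an ancestral (age-0) LTR carrying the canonical hallmarks.

    The sequence begins TG and ends CA (the short inverted repeat motifs),
    carries a TATA-like 20 bp window with >= 70% AT in its 5' half and the
    polyadenylation signal AATAAA in its 3' half; all remaining positions
    are drawn i.i.d. at the requested GC content.
    """
    if ltr_length < 50:
        raise ValueError(f"ltr_length {ltr_length} too short to host all motifs")
    rng = np.random.default_rng(seed)
    codes = _random_bases(rng, ltr_length, gc_content)
    seq = list(_BASES[codes])
    seq[0], seq[1] = "T", "G"
    seq[-2], seq[-1] = "C", "A"
    # TATA-like AT-rich window in the 5' half
    w_start = max(2, ltr_length // 4 - 10)
    w_start = min(w_start, ltr_length // 2 - 20)
    window = list(_BASES[_random_bases(rng, 20, gc=0.2)])
    at = sum(b in "AT" for b in window)
    i = 0
    while at < 14 and i < 20:  # guarantee >= 70% AT
        if window[i] in "GC":
            window[i] = "A" if rng.random() < 0.5 else "T"
            at += 1
        i += 1
    seq[w_start : w_start + 20] = window
    # polyadenylation signal in the 3' half
    p_start = max(ltr_length // 2, ltr_length - 8 - max(2, ltr_length // 10))
    seq[p_start : p_start + 6] = list("AATAAA")
    return NucSequence(id=f"ltr_anc_{seed}", residues="".join(seq))


def mutate_k2p(
    seq: NucSequence, branch_length: float, kappa: float = 2.0, seed: int = 0
) -> NucSequence:
    """Evolve a sequence along one branch under the K2P substitution process.

    ``branch_length`` is the expected number of substitutions per site; the
    per-site replacement probabilities are the closed-form K80 transition
    probabilities with transition/transversion rate ratio ``kappa``.  The
    process is indel-free, so length is preserved; N sites are left
    untouched.
    """
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if branch_length == 0:
        return NucSequence(id=seq.id, residues=seq.residues, description=seq.description)
    d = branch_length
    beta_t = d / (kappa + 2.0)
    # P(transition) and P(each transversion) after time t with alpha/beta = kappa
    e1 = np.exp(-4.0 * beta_t)
    e2 = np.exp(-2.0 * d * (kappa + 1.0) / (kappa + 2.0))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # each of the two transversion targets
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(seq.residues.encode(), dtype="S1").astype("U1")
    valid = arr != "N"
    codes = np.zeros(arr.shape, dtype=np.int64)
    for b, c in _CODE.items():
        codes[arr == b] = c
    u = rng.random(arr.size)
    choice2 = rng.integers(0, 2, size=arr.size)
    out = codes.copy()
    ts_mask = valid & (u < p_ts)
    tv_mask = valid & (u >= p_ts) & (u < p_ts + 2 * p_tv)
    out[ts_mask] = _TS_PARTNER[codes[ts_mask]]
    out[tv_mask] = _TV_PARTNERS[codes[tv_mask], choice2[tv_mask]]
    res = _BASES[out]
    res[~valid] = "N"
    return NucSequence(id=seq.id, residues="".join(res), description=seq.description)


def _make_orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons-2) sense codons + TAA."""
    body = rng.choice(len(_SENSE_CODONS), size=max(0, n_codons - 2))
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + "TAA"


def _spaced_positions(
    rng: np.random.Generator, n: int, lo: int, hi: int, min_gap: int
) -> list[int]:
    """n distinct positions in [lo, hi) pairwise separated by >= min_gap."""
    if n == 0:
        return []
    span = hi - lo - (n - 1) * min_gap
    if span < n:
        raise ValueError("pol ORF too short for the requested defect count")
    picks = np.sort(rng.choice(span, size=n, replace=False))
    return [int(lo + p + i * min_gap) for i, p in enumerate(picks)]


def simulate_provirus(params: SimulationParams) -> SimulatedProvirus:
    """Generate one contig containing an LTR-flanked provirus.

    The ancestral LTR is duplicated and each copy evolves independently at
    branch length rate*true_age.  The internal region carries gag, pol and
    env ORFs in order (roughly 23/49/28% of the coding budget, matching
    gammaretroviral gene proportions) separated by short spacers; nonsense
    stops and single-base frameshifts are injected into pol at recorded
    positions.  The cassette is flanked by identical target-site
    duplications and embedded at a seeded position in a random backbone.
    """
    ss = np.random.SeedSequence(params.seed)
    seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(8)]
    (s_ltr, s_mut5, s_mut3, s_int, s_def, s_back, s_place, _spare) = seeds

    ltr_anc = make_ancestral_ltr(params.ltr_length, params.gc_content, s_ltr)
    branch = params.rate * params.true_age
    ltr5_seq = mutate_k2p(ltr_anc, branch, params.kappa, s_mut5).residues
    ltr3_seq = mutate_k2p(ltr_anc, branch, params.kappa, s_mut3).residues

    # --- internal cassette -------------------------------------------------
    rng_int = np.random.default_rng(s_int)
    spacer = min(30, params.internal_length // 20)
    budget = params.internal_length - 4 * spacer
    gag_n = max(4, int(budget * 0.23) // 3)
    pol_n = max(6, int(budget * 0.49) // 3)
    env_n = max(4, int(budget * 0.28) // 3)
    gag = _make_orf(rng_int, gag_n)
    pol = _make_orf(rng_int, pol_n)
    env = _make_orf(rng_int, env_n)
    pol_protein = str(Seq(pol[:-3]).translate())

    def mkspacer(n: int) -> str:
        return "".join(_BASES[_random_bases(rng_int, n, params.gc_content)])

    sp = [mkspacer(spacer) for _ in range(3)]
    tail = params.internal_length - (
        3 * spacer + len(gag) + len(pol) + len(env)
    )
    sp.append(mkspacer(max(0, tail)))

    # --- inject defects into pol ------------------------------------------
    rng_def = np.random.default_rng(s_def)
    defects: list[tuple[str, int]] = []
    codon_pool = _spaced_positions(
        rng_def, params.n_nonsense + params.n_frameshift, 2, pol_n - 2, 3
    )
    rng_def.shuffle(codon_pool)
    nonsense_at = sorted(codon_pool[: params.n_nonsense])
    frameshift_at = sorted(codon_pool[params.n_nonsense :])
    pol_codons = [pol[i : i + 3] for i in range(0, len(pol), 3)]
    for ci in nonsense_at:
        pol_codons[ci] = _STOPS[rng_def.integers(0, 3)]
        defects.append(("nonsense", 3 * ci))
    # apply frameshifts right-to-left so earlier offsets stay valid
    pol_mut = "".join(pol_codons)
    for ci in sorted(frameshift_at, reverse=True):
        pos = 3 * ci
        if rng_def.random() < 0.5:
            pol_mut = pol_mut[:pos] + _BASES[rng_def.integers(0, 4)] + pol_mut[pos:]
        else:
            pol_mut = pol_mut[:pos] + pol_mut[pos + 1 :]
        defects.append(("frameshift", pos))
    defects.sort(key=lambda e: e[1])

    internal_seq = sp[0] + gag + sp[1] + pol_mut + sp[2] + env + sp[3]
    pol_off = len(sp[0]) + len(gag) + len(sp[1])

    # --- backbone and placement --------------------------------------------
    rng_back = np.random.default_rng(s_back)
    backbone = "".join(
        _BASES[_random_bases(rng_back, params.backbone_length, params.gc_content)]
    )
    rng_place = np.random.default_rng(s_place)
    margin = params.tsd_length + 500
    p = int(rng_place.integers(margin, params.backbone_length - margin))
    tsd = backbone[p : p + params.tsd_length]
    provirus = ltr5_seq + internal_seq + ltr3_seq
    contig_seq = backbone[: p + params.tsd_length] + provirus + backbone[p:]

    cid = f"sim_seed{params.seed}"
    ltr5_start = p + params.tsd_length
    internal_start = ltr5_start + len(ltr5_seq)
    ltr3_start = internal_start + len(internal_seq)
    ltr3_end = ltr3_start + len(ltr3_seq)
    contig = NucSequence(id=cid, residues=contig_seq)
    tsd_pair = (
        GenomicInterval(cid, p, p + params.tsd_length),
        GenomicInterval(cid, ltr3_end, ltr3_end + params.tsd_length),
    ) if params.tsd_length > 0 else (
        GenomicInterval(cid, p, p + 1),
        GenomicInterval(cid, ltr3_end, ltr3_end + 1),
    )
    return SimulatedProvirus(
        contig=contig,
        ltr5=GenomicInterval(cid, ltr5_start, internal_start),
        ltr3=GenomicInterval(cid, ltr3_start, ltr3_end),
        internal=GenomicInterval(cid, internal_start, ltr3_start),
        tsd=tsd_pair,
        true_age=params.true_age,
        rate=params.rate,
        expected_divergence=2.0 * params.rate * params.true_age,
        injected_defects=defects,
        pol_region=GenomicInterval(
            cid, internal_start + pol_off, internal_start + pol_off + len(pol_mut)
        ),
        pol_protein=pol_protein,
        params=params,
    )


_TRUTH_COLUMNS = [
    "contig_id", "ltr5_start", "ltr5_end", "internal_start", "internal_end",
    "ltr3_start", "ltr3_end", "tsd5_start", "tsd5_end", "tsd3_start", "tsd3_end",
    "true_age", "rate", "expected_divergence", "n_nonsense", "n_frameshift",
    "injected_defects",
]


def generate_dataset(
    grid: Sequence[SimulationParams],
    seed: int = 0,
    fasta_path: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> tuple[list[SimulatedProvirus], pd.DataFrame]:
    """Simulate one contig per parameter point; optionally write FASTA + truth TSV.

    Each point's seed is derived from the master ``seed`` and its grid index,
    so the whole dataset is reproducible from one integer.
    """
    if not grid:
        raise ValueError("empty parameter grid")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(len(grid))]
    sims: list[SimulatedProvirus] = []
    rows = []
    seen_ids: set[str] = set()
    for i, (point, child) in enumerate(zip(grid, child_seeds)):
        from dataclasses import replace

        sim = simulate_provirus(replace(point, seed=child))
        cid = f"sim{i:03d}"
        if cid in seen_ids:
            raise ValueError(f"duplicate contig id {cid}")
        seen_ids.add(cid)
        sim = _relabel(sim, cid)
        sims.append(sim)
        rows.append(
            {
                "contig_id": cid,
                "ltr5_start": sim.ltr5.start, "ltr5_end": sim.ltr5.end,
                "internal_start": sim.internal.start, "internal_end": sim.internal.end,
                "ltr3_start": sim.ltr3.start, "ltr3_end": sim.ltr3.end,
                "tsd5_start": sim.tsd[0].start, "tsd5_end": sim.tsd[0].end,
                "tsd3_start": sim.tsd[1].start, "tsd3_end": sim.tsd[1].end,
                "true_age": sim.true_age, "rate": sim.rate,
                "expected_divergence": sim.expected_divergence,
                "n_nonsense": sum(k == "nonsense" for k, _ in sim.injected_defects),
                "n_frameshift": sum(k == "frameshift" for k, _ in sim.injected_defects),
                "injected_defects": json.dumps(sim.injected_defects),
            }
        )
    truth = pd.DataFrame(rows, columns=_TRUTH_COLUMNS)
    if fasta_path is not None:
        write_fasta([s.contig for s in sims], fasta_path)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return sims, truth


def _relabel(sim: SimulatedProvirus, cid: str) -> SimulatedProvirus:
    def mv(iv: GenomicInterval) -> GenomicInterval:
        return GenomicInterval(cid, iv.start, iv.end, iv.strand)

    return SimulatedProvirus(
        contig=NucSequence(id=cid, residues=sim.contig.residues),
        ltr5=mv(sim.ltr5), ltr3=mv(sim.ltr3), internal=mv(sim.internal),
        tsd=(mv(sim.tsd[0]), mv(sim.tsd[1])),
        true_age=sim.true_age, rate=sim.rate,
        expected_divergence=sim.expected_divergence,
        injected_defects=sim.injected_defects,
        pol_region=mv(sim.pol_region), pol_protein=sim.pol_protein,
        params=sim.params,
    )
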