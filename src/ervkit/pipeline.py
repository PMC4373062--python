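"""End-to-end orchestration: simulate -> scan -> date -> score -> cluster.

A run is driven by one JSON-serializable config (schema-validated, defaults
filled, resolved copy echoed to disk) and a single seed; outputs are written
under a run directory as plain-text TSV/GFF3/newick/JSON.  Reports carry no
timestamps, so identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .dating import RatePanel, date_with_rate_panel
from .detect import LTRScanConfig, ProvirusCall, call_provirus, find_ltr_pairs
from .distances import distance_matrix
from .io import read_fasta, write_gff3
from .lineage import cut_lineages, neighbor_joining
from .simulate import SimulationParams, generate_dataset
from .types import NucSequence

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_pipeline", "date_table", "round_sig"]

_DEFAULT_RATES = [
    ["human_erv_2.3e-9", 2.3e-9],
    ["human_erv_5e-9", 5e-9],
    ["felid_nuclear_1.2e-8", 1.2e-8],
]

_SCAN_FIELDS = {
    "k", "min_ltr", "max_ltr", "min_internal", "max_internal", "min_identity",
    "band", "xdrop", "boundary_slack", "end_slack", "at_window", "at_min",
    "min_orf_aa",
}
_SIM_FIELDS = {f.name for f in dataclasses.fields(SimulationParams)} - {"seed"}


@dataclass
class RunConfig:
    """Resolved pipeline configuration."""

    seed: int = 0
    output_dir: str = "ervkit_run"
    input_fasta: str | None = None
    pol_reference: str | None = None  # protein string; simulated runs use truth
    n_simulated: int = 3
    simulate: dict[str, Any] = field(default_factory=dict)
    scan: dict[str, Any] = field(default_factory=dict)
    rates: list[list[Any]] = field(default_factory=lambda: [list(r) for r in _DEFAULT_RATES])
    lineage_threshold: float = 0.15
    age_sigfigs: int = 3
    dist_decimals: int = 3

    def rate_panel(self) -> RatePanel:
        return RatePanel(rates=tuple((str(l), float(r)) for l, r in self.rates))

    def scan_config(self) -> LTRScanConfig:
        return LTRScanConfig(**self.scan, rate_panel=self.rate_panel())

    def sim_params(self, seed: int) -> SimulationParams:
        return SimulationParams(**self.simulate, seed=seed)

    def as_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def validate_config(config: dict[str, Any] | None) -> tuple[RunConfig | None, list[str]]:
    """Fill defaults and validate; all errors are collected and returned,
    never raised.  Unknown keys produce a logged warning, not an error."""
    config = dict(config or {})
    errors: list[str] = []
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in sorted(set(config) - known):
        logger.warning("unknown config key %r ignored", key)
        config.pop(key)

    resolved = RunConfig(**{k: v for k, v in config.items()})
    if not isinstance(resolved.seed, int):
        errors.append("seed must be an integer")
    if resolved.n_simulated < 1 and resolved.input_fasta is None:
        errors.append("n_simulated must be >= 1 when no input_fasta is given")
    try:
        resolved.rate_panel()
    except (ValueError, TypeError) as exc:
        errors.append(f"rates: {exc}")
    bad_scan = set(resolved.scan) - _SCAN_FIELDS
    if bad_scan:
        errors.append(f"scan: unknown fields {sorted(bad_scan)}")
    else:
        try:
            resolved.scan_config()
        except (TypeError, ValueError) as exc:
            errors.append(f"scan: {exc}")
    bad_sim = set(resolved.simulate) - _SIM_FIELDS
    if bad_sim:
        errors.append(f"simulate: unknown fields {sorted(bad_sim)}")
    else:
        try:
            resolved.sim_params(seed=0)
        except (TypeError, ValueError) as exc:
            errors.append(f"simulate: {exc}")
    if not 0 < resolved.lineage_threshold < 1:
        errors.append("lineage_threshold must be in (0, 1)")
    if errors:
        return None, errors
    return resolved, []


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def date_table(df: pd.DataFrame, panel: RatePanel, sigfigs: int = 3) -> pd.DataFrame:
    """Re-date a table of divergences: needs a ``D`` column; appends one
    age column (in MY) per panel rate."""
    if "D" not in df.columns:
        raise ValueError("input table must have a 'D' column")
    out = df.copy()
    for label, _rate in panel:
        out[f"T_MY_{label}"] = [
            round_sig(est.T_MY, sigfigs)
            for est in (
                next(a for a in date_with_rate_panel(d, panel) if a.rate_label == label)
                for d in df["D"].astype(float)
            )
        ]
    return out


@dataclass
class PipelineResult:
    config: RunConfig
    contigs: list[NucSequence]
    calls: list[tuple[str, ProvirusCall]]  # (contig_id, call)
    report: pd.DataFrame
    output_dir: Path


def _call_row(cid: str, call: ProvirusCall, cfg: RunConfig) -> dict[str, Any]:
    pair = call.ltr_pair
    d_printed = round(call.divergence.value, cfg.dist_decimals)
    row: dict[str, Any] = {
        "contig": cid,
        "ltr5_start": pair.left.start, "ltr5_end": pair.left.end,
        "ltr3_start": pair.right.start, "ltr3_end": pair.right.end,
        "avg_ltr_length": (len(pair.left) + len(pair.right)) / 2,
        "strand": call.strand,
        "identity": round(pair.identity, 4),
        "D": d_printed,
        "D_se": round(call.divergence.se, cfg.dist_decimals + 1),
        "n_sites": call.divergence.n_sites,
        "n_diff": call.divergence.n_diff,
    }
    # printed ages derive from the printed D so that re-dating the report's
    # own D column reproduces them exactly
    for age in date_with_rate_panel(d_printed, cfg.rate_panel()):
        row[f"T_MY_{age.rate_label}"] = round_sig(age.T_MY, cfg.age_sigfigs)
    m5, m3 = pair.motifs
    row.update(
        {
            "orf_order_ok": call.orf_order_ok,
            "n_orfs": len(call.orfs),
            "tsd_length": call.tsd_length,
            "ltr5_TG_CA": m5.starts_TG and m5.ends_CA,
            "ltr3_TG_CA": m3.starts_TG and m3.ends_CA,
            "polyA_present": m5.polyA_pos is not None or m3.polyA_pos is not None,
            "n_nonsense": call.intactness.n_nonsense if call.intactness else None,
            "n_frameshift": call.intactness.n_frameshift if call.intactness else None,
        }
    )
    return row


def run_pipeline(config: RunConfig | dict[str, Any]) -> PipelineResult:
    """Execute the full pipeline and write the report bundle.

    Stage order: simulate (or load) -> scan -> date -> score -> cluster.
    Any stage failure halts with a stage-attributed error.
    """
    if not isinstance(config, RunConfig):
        resolved, errors = validate_config(config)
        if resolved is None:
            raise ValueError("invalid config: " + "; ".join(errors))
        config = resolved
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setLevel(logging.INFO)
    root = logging.getLogger("ervkit")
    root.addHandler(fh)
    try:
        return _run_stages(config, outdir)
    finally:
        root.removeHandler(fh)
        fh.close()


def _run_stages(config: RunConfig, outdir: Path) -> PipelineResult:
    (outdir / "resolved_config.json").write_text(
        json.dumps({"ervkit_version": __version__, **config.as_dict()}, indent=2, sort_keys=True)
        + "\n"
    )
    pol_refs: dict[str, str] = {}

    # --- stage: simulate / load -------------------------------------------
    try:
        if config.input_fasta:
            contigs = read_fasta(config.input_fasta)
            logger.info("loaded %d contigs from %s", len(contigs), config.input_fasta)
            if config.pol_reference:
                pol_refs = {c.id: config.pol_reference for c in contigs}
        else:
            grid = [config.sim_params(seed=0)] * config.n_simulated
            sims, _truth = generate_dataset(
                grid,
                seed=config.seed,
                fasta_path=outdir / "simulated.fasta",
                truth_path=outdir / "truth.tsv",
            )
            contigs = [s.contig for s in sims]
            pol_refs = {s.contig.id: s.pol_protein for s in sims}
            logger.info("simulated %d contigs", len(contigs))
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate/load' failed: {exc}") from exc

    # --- stage: scan + date + score ---------------------------------------
    scan_cfg = config.scan_config()
    calls: list[tuple[str, ProvirusCall]] = []
    try:
        for contig in contigs:
            for pair in find_ltr_pairs(contig, scan_cfg):
                call = call_provirus(contig, pair, pol_refs.get(contig.id), scan_cfg)
                calls.append((contig.id, call))
        logger.info("called %d proviruses in %d contigs", len(calls), len(contigs))
    except Exception as exc:
        raise RuntimeError(f"stage 'scan' failed: {exc}") from exc

    report = pd.DataFrame([_call_row(cid, c, config) for cid, c in calls])
    report.to_csv(outdir / "report.tsv", sep="\t", index=False)
    write_gff3(
        [c for _, c in calls],
        outdir / "calls.gff3",
        contig_lengths={c.id: len(c) for c in contigs},
    )

    # --- stage: cluster ----------------------------------------------------
    summary: dict[str, Any] = {
        "n_contigs": len(contigs),
        "n_calls": len(calls),
        "calls": [
            {
                "contig": cid,
                "D": round(c.divergence.value, 6),
                "ages_MY": {a.rate_label: round_sig(a.T_MY, config.age_sigfigs) for a in c.ages},
            }
            for cid, c in calls
        ],
    }
    try:
        if len(calls) >= 3:
            ltr_seqs = [
                (f"{cid}_{i}", c.ltr_pair.left.slice(contig))
                for i, ((cid, c), contig) in enumerate(
                    zip(calls, [next(x for x in contigs if x.id == cid) for cid, _ in calls])
                )
            ]
            dm = distance_matrix(ltr_seqs, model="p")
            part = cut_lineages(dm, config.lineage_threshold)
            part.to_tsv(outdir / "lineages.tsv")
            neighbor_joining(dm).write(outdir / "tree.nwk")
            summary["n_lineages"] = part.n_lineages
    except Exception as exc:
        raise RuntimeError(f"stage 'cluster' failed: {exc}") from exc

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return PipelineResult(
        config=config, contigs=contigs, calls=calls, report=report, output_dir=outdir
    )
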