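"""End-to-end orchestration: database -> filter -> quantify -> classify.

A single config (YAML or dict) drives either a fully simulated experiment,
a run over user-supplied FASTA + PSM tables, or classification-only mode
over a pre-computed count matrix.  Every intermediate table is written to
the output directory together with a manifest recording the config hash,
seed, and per-stage row counts, so re-runs with the same config are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .coenrichment import ExperimentDesign, make_report, read_count_matrix, write_report
from .psm_filter import (
    FilterThresholds,
    assign_decoy_status,
    estimate_fdr,
    filter_psms,
    accept_proteins,
    read_psm_table,
    write_filter_report,
)
from .sequence_db import build_search_db, map_peptides, mapping_index, read_fasta, write_fasta
from .spectral_quant import build_count_matrix, quantify_run, write_count_matrix, write_quant_report
from .synthetic import ScoreModel, SimulationConfig, simulate_experiment, write_experiment

logger = logging.getLogger("coenrich")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _thresholds_from(cfg: Mapping[str, Any] | None) -> FilterThresholds:
    cfg = dict(cfg or {})
    if "min_xcorr_by_charge" in cfg:
        cfg["min_xcorr_by_charge"] = {
            int(k): float(v) for k, v in cfg["min_xcorr_by_charge"].items()
        }
    return FilterThresholds(**cfg)


def _design_from(cfg: Mapping[str, Any] | None) -> ExperimentDesign:
    cfg = dict(cfg or {})
    for key in ("bait_runs", "control_runs"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    return ExperimentDesign(**cfg)


def _simconfig_from(cfg: Mapping[str, Any] | None, seed: int) -> SimulationConfig:
    cfg = dict(cfg or {})
    for key in ("correct_score", "incorrect_score"):
        if key in cfg:
            cfg[key] = ScoreModel(**cfg[key])
    if "charge_probabilities" in cfg:
        cfg["charge_probabilities"] = {
            int(k): float(v) for k, v in cfg["charge_probabilities"].items()
        }
    for key in ("protein_length_range", "fold_gap_range", "background_abundance", "member_abundance"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    cfg.setdefault("seed", seed)
    return SimulationConfig(**cfg)


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "coenrich_out"
    log_level: str = "INFO"
    simulate: Mapping[str, Any] | None = None
    inputs: Mapping[str, Any] | None = None  # fasta / psm_tables / counts_matrix
    thresholds: FilterThresholds = dataclasses.field(default_factory=FilterThresholds)
    design: ExperimentDesign = dataclasses.field(default_factory=ExperimentDesign)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        return cls(
            seed=int(raw.get("seed", 0)),
            outdir=str(raw.get("outdir", "coenrich_out")),
            log_level=str(raw.get("log_level", "INFO")),
            simulate=raw.get("simulate"),
            inputs=raw.get("inputs"),
            thresholds=_thresholds_from(raw.get("thresholds")),
            design=_design_from(raw.get("design")),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def validate(self) -> None:
        if self.simulate is None and self.inputs is None:
            raise ValueError("config needs either a 'simulate' or an 'inputs' block")

    def canonical(self) -> str:
        """Canonical JSON of the analysis parameters (where outputs go and
        how verbosely we log are not part of the analysis identity)."""

        def enc(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Mapping):
                return {str(k): enc(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj

        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)
        payload.pop("log_level", None)
        return json.dumps(enc(payload), sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    outdir: Path
    report: pd.DataFrame
    manifest: dict[str, Any]

    @property
    def combined_positives(self) -> list[str]:
        mask = self.report["combined_positive"]
        return list(self.report.loc[mask, "accession"])


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages, writing intermediates and a manifest.

    Classification-only mode (``inputs.counts_matrix``) skips straight to
    the co-enrichment stage.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash,
        "stages": {},
    }
    design = config.design

    counts_path = (config.inputs or {}).get("counts_matrix")
    if counts_path:
        # classification-only mode
        try:
            matrix = read_count_matrix(counts_path, design.all_runs)
        except Exception as exc:
            raise StageError("load_counts", exc)
        report = _classify_stage(matrix, design, outdir, manifest)
        _write_manifest(manifest, outdir)
        return PipelineResult(outdir=outdir, report=report, manifest=manifest)

    # --- sequence_db stage ---------------------------------------------
    try:
        if config.simulate is not None:
            sim = simulate_experiment(_simconfig_from(config.simulate, config.seed))
            write_experiment(sim, outdir / "simulated")
            database = sim.database
            psms = sim.psms()
        else:
            targets = read_fasta(config.inputs["fasta"])
            has_decoys = any(r.accession.startswith("DECOY_") for r in targets)
            if has_decoys:
                database = [
                    dataclasses.replace(r, category="decoy")
                    if r.accession.startswith("DECOY_")
                    else r
                    for r in targets
                ]
            else:
                database = build_search_db(targets, seed=config.seed)
                write_fasta(database, outdir / "search_db.fasta")
            psms = []
            for path in config.inputs.get("psm_tables", []):
                psms.extend(read_psm_table(path))
        mapping = map_peptides({p.peptide for p in psms}, database)
        index = mapping_index(mapping)
        manifest["stages"]["sequence_db"] = {
            "database_entries": len(database),
            "distinct_peptides": len(mapping),
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError("sequence_db", exc)

    # --- psm_filter stage ----------------------------------------------
    try:
        assign_decoy_status(psms, index)
        result = filter_psms(psms, index, config.thresholds)
        fdr = estimate_fdr(result.accepted)
        accepted_proteins = accept_proteins(result.accepted, index)
        write_filter_report(result, outdir / "psms_filtered.tsv")
        manifest["stages"]["psm_filter"] = {
            "input_psms": len(psms),
            "accepted_psms": len(result.accepted),
            "fdr": fdr.fdr,
            "fdr_symmetric": fdr.fdr_symmetric,
            "accepted_proteins": len(accepted_proteins),
            "rejection_reasons": result.reasons,
        }
    except Exception as exc:
        raise StageError("psm_filter", exc)

    # --- spectral_quant stage ------------------------------------------
    try:
        lengths = {r.accession: r.length for r in database}
        run_ids = design.all_runs
        # decoys are FDR bookkeeping only: they never enter quantification
        # or the candidate report
        decoy_accs = {r.accession for r in database if r.category == "decoy"}
        quant_proteins = accepted_proteins - decoy_accs
        quants = []
        for run_id in run_ids:
            quants.extend(
                quantify_run(result.accepted, index, quant_proteins, lengths, run_id)
            )
        write_quant_report(quants, outdir / "quant.tsv")
        matrix = build_count_matrix(quants, run_ids)
        write_count_matrix(matrix, outdir / "count_matrix.tsv")
        manifest["stages"]["spectral_quant"] = {
            "quantified_proteins": int(matrix.dspc.shape[0]),
            "runs": list(run_ids),
        }
    except Exception as exc:
        raise StageError("spectral_quant", exc)

    report = _classify_stage(matrix, design, outdir, manifest)
    _write_manifest(manifest, outdir)
    return PipelineResult(outdir=outdir, report=report, manifest=manifest)


def _classify_stage(matrix, design, outdir: Path, manifest: dict) -> pd.DataFrame:
    try:
        report = make_report(matrix, design)
        write_report(report, outdir / "candidates.tsv")
        manifest["stages"]["coenrichment"] = {
            "candidates": int(len(report)),
            "combined_positive": int(report["combined_positive"].sum())
            if not report.empty
            else 0,
        }
        return report
    except Exception as exc:
        raise StageError("coenrichment", exc)


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
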