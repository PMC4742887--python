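"""End-to-end orchestration: simulate/load -> QC -> call -> compare ->
network -> enrich, with a reproducible run manifest.

Every run writes its artifacts plus a ``manifest.json`` mapping each file
to its SHA-256 hash and a snapshot of the effective configuration, so two
runs with the same config and seed produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import enrichment as enr
from . import hit_calling as hc
from . import network_analysis as net
from . import normalize_qc as qc
from . import synthetic_screen as synth
from .screen_data import (
    ARM_SENSITIZER,
    ARM_VEHICLE,
    ScreenDataset,
    read_library_csv,
    read_screen_csv,
    write_screen_csv,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("screen", "qc", "call", "compare", "network", "enrich")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and its context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


@dataclass
class PipelineConfig:
    """Serializable configuration of a full pipeline run."""

    out_dir: str = "myoscreen-run"
    seed: int = 0
    # inputs: either a measured screen CSV (+ library) or a simulation
    screen_csv: str | None = None
    library_csv: str | None = None
    library_size: int = 571
    simulation: dict[str, Any] = field(default_factory=dict)
    planted_hits: dict[str, dict[str, float]] = field(default_factory=dict)
    # downstream inputs
    edge_lists: list[str] = field(default_factory=list)
    symbol_map: dict[str, str] = field(default_factory=dict)
    gmt: str | None = None
    mrfs: list[str] = field(default_factory=lambda: list(net.DEFAULT_MRFS))
    hit_call: dict[str, Any] = field(default_factory=dict)
    enrichment_alpha: float = 0.05
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    log_level: str = "INFO"

    def hit_call_config(self) -> hc.HitCallConfig:
        return hc.HitCallConfig(**self.hit_call)

    def simulation_config(self) -> synth.SimulationConfig:
        planted = {
            gene: synth.PlantedEffect(**params)
            for gene, params in self.planted_hits.items()
        }
        params = dict(self.simulation)
        params.setdefault("seed", self.seed)
        return synth.SimulationConfig(planted_hits=planted, **params)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML or JSON pipeline config file."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_text(path: Path, text: str) -> None:
    path.write_text(text, encoding="utf-8")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the run manifest.

    Artifacts land in ``config.out_dir``; a stage failure aborts the run
    with a :class:`PipelineError` naming the stage. Disabling a downstream
    stage never alters upstream outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    artifacts: list[Path] = []
    manifest: dict[str, Any] = {"stages_run": [], "partial": False}

    def _record(path: Path) -> None:
        artifacts.append(path)

    config_path = out / "config.json"
    _write_text(config_path, json.dumps(config.to_dict(), indent=2, sort_keys=True))
    _record(config_path)

    dataset: ScreenDataset | None = None
    truth: synth.GroundTruth | None = None
    calls: list[hc.KinaseCall] = []

    try:
        stage = "screen"
        if config.screen_csv:
            if not config.library_csv:
                raise PipelineError(stage, "a measured screen needs library_csv")
            library = read_library_csv(config.library_csv)
            dataset = read_screen_csv(config.screen_csv, library)
        else:
            library = (
                read_library_csv(config.library_csv)
                if config.library_csv
                else synth.default_library(config.library_size)
            )
            dataset, truth = synth.simulate_screen(config.simulation_config(), library)
            screen_path = out / "screen.csv"
            write_screen_csv(dataset, screen_path)
            _record(screen_path)
            truth_path = out / "ground_truth.csv"
            truth.write_csv(truth_path)
            _record(truth_path)
        problems = dataset.validate()
        if problems:
            raise PipelineError(stage, f"dataset invalid: {problems[:5]}")
        manifest["stages_run"].append(stage)

        if "qc" in config.stages:
            stage = "qc"
            hcc = config.hit_call_config()
            report = qc.qc_report(dataset, hcc)
            qc_path = out / "qc_report.csv"
            report.to_csv(qc_path, index=False)
            _record(qc_path)
            controls = qc.score_controls(dataset, hcc)
            ctrl_path = out / "control_scores.csv"
            controls.to_csv(ctrl_path, index=False)
            _record(ctrl_path)
            lines = ["Assay-window QC", "================"]
            for _, row in report.iterrows():
                lines.append(
                    f"plate {row.plate_id} arm {row.arm}: "
                    f"Z'-factor {row.z_factor_percent_myogenin:.3f}, "
                    f"GM median {row.gm_median_percent_myogenin:.2f}% / "
                    f"DM+I median {row.dmi_median_percent_myogenin:.2f}% Myogenin"
                )
            _write_text(out / "qc_summary.txt", "\n".join(lines) + "\n")
            _record(out / "qc_summary.txt")
            manifest["stages_run"].append(stage)

        if "call" in config.stages:
            stage = "call"
            hcc = config.hit_call_config()
            calls = hc.call_screen(dataset, hcc)
            calls_path = out / "kinase_calls.csv"
            hc.calls_to_frame(calls).to_csv(calls_path, index=False)
            _record(calls_path)
            cell_only = hc.cell_number_only_report(dataset, hcc)
            cell_only_path = out / "cell_number_only.csv"
            cell_only.assign(genes=cell_only.genes.map(lambda g: ";".join(g))).to_csv(
                cell_only_path, index=False
            )
            _record(cell_only_path)
            if truth is not None:
                recovery = synth.truth_recovery_report(calls, truth)
                rec_path = out / "truth_recovery.csv"
                recovery.to_csv(rec_path, index=False)
                _record(rec_path)
            manifest["stages_run"].append(stage)

        if "compare" in config.stages and calls:
            stage = "compare"
            veh = [c for c in calls if c.arm == ARM_VEHICLE]
            sen = [c for c in calls if c.arm == ARM_SENSITIZER]
            if veh and sen:
                comparison = hc.compare_arms(veh, sen, dataset.library.size)
                cmp_path = out / "arm_comparison.json"
                _write_text(cmp_path, json.dumps(comparison.to_dict(), indent=2))
                _record(cmp_path)
                manifest["stages_run"].append(stage)

        hit_set = sorted(hc.hit_genes(calls))
        if "network" in config.stages and config.edge_lists:
            stage = "network"
            graphs = [
                net.read_edge_list(p, symbol_map=config.symbol_map)
                for p in config.edge_lists
            ]
            graph = net.merge_graphs(*graphs)
            classification = net.classify_regulators(graph, hit_set, config.mrfs)
            rows = [
                {
                    "kinase": pc.kinase,
                    "mrf": pc.mrf,
                    "connection": pc.connection,
                    "intermediaries": ";".join(sorted(pc.intermediaries)),
                }
                for pc in sorted(
                    classification.pairs.values(), key=lambda pc: (pc.kinase, pc.mrf)
                )
            ]
            import pandas as pd

            cls_path = out / "regulator_classification.csv"
            pd.DataFrame(rows).to_csv(cls_path, index=False)
            _record(cls_path)
            for name, table in net.summarize_network(classification).items():
                p = out / f"network_ranking_{name}.csv"
                table.to_csv(p, index=False)
                _record(p)
            sif_path = out / "subnetwork.sif"
            attrs_path = out / "subnetwork_nodes.tsv"
            net.export_subnetwork(classification, graph, sif_path, attrs_path)
            _record(sif_path)
            _record(attrs_path)
            manifest["stages_run"].append(stage)

        if "enrich" in config.stages and config.gmt:
            stage = "enrich"
            gmt_path = Path(config.gmt)
            if not gmt_path.exists():
                raise PipelineError(stage, f"GMT file not found: {gmt_path}")
            sets = enr.read_gmt(gmt_path)
            results = enr.binomial_enrichment(
                hit_set, dataset.library, sets, alpha=config.enrichment_alpha
            )
            enr_path = out / "enrichment.csv"
            enr.enrichment_to_frame(results).to_csv(enr_path, index=False)
            _record(enr_path)
            manifest["stages_run"].append(stage)

    except PipelineError:
        manifest["partial"] = True
        _finalize(out, manifest, artifacts)
        raise
    except Exception as exc:
        manifest["partial"] = True
        _finalize(out, manifest, artifacts)
        raise PipelineError(stage, str(exc)) from exc

    _finalize(out, manifest, artifacts)
    return manifest


def _finalize(out: Path, manifest: dict, artifacts: list[Path]) -> None:
    manifest["files"] = {
        p.name: _sha256(p) for p in sorted(set(artifacts)) if p.exists()
    }
    _write_text(out / "manifest.json", json.dumps(manifest, indent=2, sort_keys=True))
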