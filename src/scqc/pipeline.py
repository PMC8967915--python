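"""End-to-end QC pipeline: import -> droplet QC -> cell QC -> reports -> export.

The pipeline is configured by a :class:`PipelineConfig`, built from a YAML
file, command-line flags or both (flags win). A single global seed fans out
to per-operation seeds through a stable hash, so two runs with the same
configuration and seed produce byte-identical summary tables.

Stages are isolated: a failure in one QC algorithm is logged and the
pipeline continues, so completed results are still reported and exported;
the run then finishes with a nonzero status.
"""

from __future__ import annotations

import dataclasses
import sys
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .cellqc import per_cell_qc
from .container import MatrixLevel, QCExperiment
from .decontam import run_decontx
from .doublets import DEFAULT_DOUBLET_ALGORITHMS, run_doublet_qc
from .droplet import run_droplet_qc
from .errors import ConfigError, ScqcError
from .exporters import export_anndata, export_flatfiles
from .genesets import resolve_mito_token
from .importers import ImportSpec, import_samples
from .reporting import report_cell_qc, report_droplet_qc, summarize_qc, write_summary_tsv

VALID_FORMATS = {"FlatFile", "AnnData"}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    ``params`` holds per-operation overrides keyed by stage name
    (``droplet``, ``cellqc``, ``doublet``, ``decontx``), each a mapping of
    keyword arguments passed through to the stage function.
    """

    preproc: str = "cellranger_v3"
    sample_paths: list[str] = field(default_factory=list)
    sample_names: list[str] = field(default_factory=list)
    data_type: str = "Both"
    mito_geneset: str | None = None
    output_formats: list[str] = field(default_factory=lambda: ["FlatFile", "AnnData"])
    out_dir: str = "./scqc_out"
    seed: int = 12345
    gzip: bool = True
    params: dict[str, dict[str, Any]] = field(default_factory=dict)

    def validate(self) -> "PipelineConfig":
        if not self.sample_paths:
            raise ConfigError("no input sample paths given")
        if len(self.sample_paths) != len(self.sample_names):
            raise ConfigError("sample_paths and sample_names differ in length")
        if self.data_type not in {"Droplet", "Cell", "Both"}:
            raise ConfigError("data_type must be Droplet, Cell or Both")
        unknown = set(self.output_formats) - VALID_FORMATS
        if unknown:
            raise ConfigError(f"unknown output formats: {sorted(unknown)}")
        try:
            ImportSpec(
                tool=self.preproc,
                sample_dirs_or_files=list(self.sample_paths),
                sample_names=list(self.sample_names),
                data_type=self.data_type,
            )
        except ScqcError as exc:
            raise ConfigError(str(exc))
        return self

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: YAML root must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def merge_config(
    base: PipelineConfig, overrides: dict[str, Any]
) -> PipelineConfig:
    """Apply non-None overrides (CLI flags) on top of a base config."""
    data = base.to_dict()
    for key, value in overrides.items():
        if value is None:
            continue
        if isinstance(value, (list, tuple)) and not value:
            continue
        data[key] = list(value) if isinstance(value, tuple) else value
    return PipelineConfig.from_dict(data)


class _RunLog:
    def __init__(self, path: Path) -> None:
        self.path = path
        self.lines: list[str] = []

    def log(self, stage: str, message: str, t0: float | None = None) -> None:
        elapsed = f" [{time.time() - t0:.1f}s]" if t0 is not None else ""
        line = f"[{stage}]{elapsed} {message}"
        self.lines.append(line)
        print(line, file=sys.stderr)
        self.path.write_text("\n".join(self.lines) + "\n")


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the configured pipeline; returns an artifact manifest.

    The manifest maps artifact names to paths and includes ``status``
    (0 = success, 1 = at least one stage failed) and per-stage errors.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    runlog = _RunLog(out_dir / "run.log")
    manifest: dict[str, Any] = {"artifacts": {}, "errors": {}, "status": 0}

    def fail(stage: str, exc: Exception) -> None:
        manifest["errors"][stage] = f"{type(exc).__name__}: {exc}"
        manifest["status"] = 1
        runlog.log(stage, f"FAILED: {exc}")
        runlog.log(stage, traceback.format_exc().strip().splitlines()[-1])

    # ---- stage 1: import -------------------------------------------------
    t0 = time.time()
    spec = ImportSpec(
        tool=config.preproc,
        sample_dirs_or_files=list(config.sample_paths),
        sample_names=list(config.sample_names),
        data_type=config.data_type,
    )
    droplet, cell = import_samples(spec)
    runlog.log(
        "import",
        f"tool={config.preproc} droplet="
        f"{droplet.n_barcodes if droplet else 0} barcodes, cell="
        f"{cell.n_barcodes if cell else 0} cells",
        t0,
    )

    # ---- stage 2: droplet QC --------------------------------------------
    if droplet is not None:
        t0 = time.time()
        try:
            droplet = run_droplet_qc(
                droplet, seed=config.seed, **config.params.get("droplet", {})
            )
            runlog.log("droplet_qc", "empty-droplet detection complete", t0)
        except Exception as exc:
            fail("droplet_qc", exc)

    # ---- stage 3: cell QC -----------------------------------------------
    if cell is not None:
        gene_sets = []
        if config.mito_geneset:
            gene_sets.append(resolve_mito_token(config.mito_geneset))
        t0 = time.time()
        try:
            cell = per_cell_qc(cell, gene_sets=gene_sets,
                               **config.params.get("cellqc", {}))
            runlog.log("per_cell_qc", "general metrics computed", t0)
        except Exception as exc:
            fail("per_cell_qc", exc)
        t0 = time.time()
        try:
            doublet_params = {"algorithms": DEFAULT_DOUBLET_ALGORITHMS}
            doublet_params.update(config.params.get("doublet", {}))
            cell = run_doublet_qc(cell, seed=config.seed, **doublet_params)
            runlog.log("doublet_qc", "doublet scoring complete", t0)
        except Exception as exc:
            fail("doublet_qc", exc)
        t0 = time.time()
        try:
            cell = run_decontx(cell, seed=config.seed,
                               **config.params.get("decontx", {}))
            runlog.log("decontx", "ambient contamination estimated", t0)
        except Exception as exc:
            fail("decontx", exc)

    # ---- stage 4: reports and summary -----------------------------------
    if droplet is not None and "droplet_qc" not in manifest["errors"]:
        t0 = time.time()
        try:
            path = report_droplet_qc(droplet, out_dir / "dropletQC.html")
            manifest["artifacts"]["droplet_report"] = str(path)
            runlog.log("report", "droplet report written", t0)
        except Exception as exc:
            fail("droplet_report", exc)
    if cell is not None:
        t0 = time.time()
        try:
            path = report_cell_qc(cell, out_dir / "cellQC.html", droplet=droplet)
            manifest["artifacts"]["cell_report"] = str(path)
            summary = summarize_qc(cell, droplet)
            tsv = write_summary_tsv(summary, out_dir / "qc_summary.tsv")
            manifest["artifacts"]["summary_tsv"] = str(tsv)
            runlog.log("report", "cell report + summary written", t0)
        except Exception as exc:
            fail("cell_report", exc)

    # ---- stage 5: export -------------------------------------------------
    exports: list[tuple[str, QCExperiment]] = []
    if droplet is not None:
        exports.append(("droplet", droplet))
    if cell is not None:
        exports.append(("cell", cell))
    for label, exp in exports:
        for fmt in config.output_formats:
            t0 = time.time()
            try:
                if fmt == "FlatFile":
                    export_flatfiles(
                        exp, out_dir / f"flatfiles_{label}", use_gzip=config.gzip
                    )
                    manifest["artifacts"][f"flatfiles_{label}"] = str(
                        out_dir / f"flatfiles_{label}"
                    )
                elif fmt == "AnnData":
                    path = export_anndata(exp, out_dir / f"{label}.h5ad")
                    manifest["artifacts"][f"anndata_{label}"] = str(path)
                runlog.log("export", f"{fmt} ({label}) written", t0)
            except Exception as exc:
                fail(f"export_{fmt}_{label}", exc)

    config.to_yaml(out_dir / "resolved_config.yaml")
    manifest["artifacts"]["config"] = str(out_dir / "resolved_config.yaml")
    manifest["artifacts"]["run_log"] = str(runlog.path)
    runlog.log("done", f"status={manifest['status']}")
    return manifest
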