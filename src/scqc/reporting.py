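"""Per-sample QC summary tables and self-contained HTML reports.

Reports embed all figures as base64 PNG data URIs so a single file is the
whole artifact. Every number shown is recomputed from the experiment's
annotation columns through :func:`summarize_qc`; the reports perform no
derivations of their own. Report generation never mutates the experiment.
"""

from __future__ import annotations

import base64
import datetime
import io
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from jinja2 import Template

from .container import QCExperiment
from .droplet import EMPTYDROPS_COLUMNS, RANK_COLUMNS
from .errors import MissingResultError

# ----------------------------------------------------------------------
# Summary table


def _fmt_int(x) -> str:
    return "NA" if pd.isna(x) else f"{int(round(x))}"


def _fmt_pct(x) -> str:
    return "NA" if pd.isna(x) else f"{x:.2f}"


def summarize_qc(
    cell: QCExperiment,
    droplet: QCExperiment | None = None,
) -> pd.DataFrame:
    """Per-sample summary of all computed QC metrics.

    One row per metric, one column per sample. Metrics whose annotation
    columns are absent are reported as NA. Doublet percentages are
    100 x calls / cells; contamination is reported as a percentage.
    """
    annot = cell.cell_annotations
    samples = cell.samples
    rows: dict[str, dict[str, object]] = {}

    sample_col = annot["sample"].astype(str)
    for s in samples:
        mask = (sample_col == s).to_numpy()
        sub_matrix = cell.matrix[:, np.flatnonzero(mask)]
        n_cells = int(mask.sum())
        vals: dict[str, object] = {}
        genes_detected = int((np.asarray(sub_matrix.sum(axis=1)).ravel() > 0).sum())
        vals["Total number of genes detected"] = genes_detected
        if droplet is not None:
            d_mask = droplet.cell_annotations["sample"].astype(str) == s
            vals["Number of droplets, Droplet matrix"] = int(d_mask.sum())
        else:
            vals["Number of droplets, Droplet matrix"] = np.nan
        vals["Number of cells, Cell matrix"] = n_cells

        for label, col, fn in (
            ("Mean counts", "total", np.mean),
            ("Median counts", "total", np.median),
            ("Mean features detected", "detected", np.mean),
            ("Median features detected", "detected", np.median),
        ):
            vals[label] = (
                float(fn(annot.loc[mask, col])) if col in annot else np.nan
            )

        for col in annot.columns:
            if col.endswith("_doublet_call"):
                algo = col[: -len("_doublet_call")]
                calls = annot.loc[mask, col].astype(bool)
                vals[f"{algo}, Number of doublets"] = int(calls.sum())
                vals[f"{algo}, Percentage of doublets"] = (
                    100.0 * calls.sum() / n_cells if n_cells else np.nan
                )
        if "doublet_consensus_call" in annot:
            calls = annot.loc[mask, "doublet_consensus_call"].astype(bool)
            vals["Consensus, Number of doublets"] = int(calls.sum())
            vals["Consensus, Percentage of doublets"] = (
                100.0 * calls.sum() / n_cells if n_cells else np.nan
            )
        if "decontX_contamination" in annot:
            contam = annot.loc[mask, "decontX_contamination"].astype(float)
            vals["DecontX, Mean contamination percentage"] = 100.0 * contam.mean()
            vals["DecontX, Median contamination percentage"] = (
                100.0 * contam.median()
            )
        for metric, value in vals.items():
            rows.setdefault(metric, {})[s] = value

    return pd.DataFrame(rows).T[samples]


def format_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Render the summary with counts as integers and percentages to 2 dp."""
    out = table.copy().astype(object)
    for metric in out.index:
        is_pct = "ercentage" in metric or "Mean contamination" in metric
        fmt = _fmt_pct if is_pct else _fmt_int
        out.loc[metric] = [fmt(v) for v in table.loc[metric]]
    return out


def write_summary_tsv(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    format_summary(table).to_csv(path, sep="\t", index_label="Metric")
    return path


# ----------------------------------------------------------------------
# Figures


def _fig_to_datauri(fig) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=110, bbox_inches="tight",
                metadata={"Software": None})
    plt.close(fig)
    return "data:image/png;base64," + base64.b64encode(buf.getvalue()).decode()


def _rank_curve_figure(totals, knee, inflection) -> str:
    from scipy.stats import rankdata

    fig, ax = plt.subplots(figsize=(5, 4))
    rank = rankdata(-totals, method="average")
    ax.loglog(rank, np.maximum(totals, 1), ".", ms=2, color="steelblue")
    if np.isfinite(knee):
        ax.axhline(knee, color="firebrick", ls="--", label=f"knee = {knee:.0f}")
    if np.isfinite(inflection):
        ax.axhline(
            inflection, color="darkorange", ls=":",
            label=f"inflection = {inflection:.0f}",
        )
    ax.set_xlabel("barcode rank")
    ax.set_ylabel("total UMI counts")
    ax.legend(fontsize=8)
    return _fig_to_datauri(fig)


def _emptydrops_scatter(totals, logprob, is_cell) -> str:
    fig, ax = plt.subplots(figsize=(5, 4))
    ok = np.isfinite(logprob)
    colors = np.where(is_cell[ok], "firebrick", "grey")
    ax.scatter(totals[ok], -logprob[ok], s=4, c=colors, alpha=0.5)
    ax.set_xscale("log")
    ax.set_xlabel("total UMI counts")
    ax.set_ylabel("-log probability (ambient model)")
    return _fig_to_datauri(fig)


def _violin(values_by_sample: dict[str, np.ndarray], ylabel: str) -> str:
    fig, ax = plt.subplots(figsize=(4.2, 3.4))
    names = list(values_by_sample)
    data = [np.asarray(values_by_sample[s], dtype=float) for s in names]
    data = [d[np.isfinite(d)] for d in data]
    if any(len(d) for d in data):
        ax.violinplot([d if len(d) else [0] for d in data], showmedians=True)
    ax.set_xticks(range(1, len(names) + 1), names, rotation=30, fontsize=7)
    ax.set_ylabel(ylabel)
    return _fig_to_datauri(fig)


def _embedding_scatter(emb, color, title, categorical=False) -> str:
    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    if categorical:
        color = np.asarray(color)
        for val in np.unique(color):
            m = color == val
            ax.scatter(emb[m, 0], emb[m, 1], s=5, label=str(val), alpha=0.7)
        ax.legend(fontsize=7, markerscale=1.5)
    else:
        sc = ax.scatter(emb[:, 0], emb[:, 1], s=5, c=color, cmap="viridis")
        fig.colorbar(sc, ax=ax, shrink=0.8)
    ax.set_title(title, fontsize=9)
    ax.set_xticks([])
    ax.set_yticks([])
    return _fig_to_datauri(fig)


# ----------------------------------------------------------------------
# HTML assembly

_PAGE = Template(
    """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{{ title }}</title>
<style>
body { font-family: sans-serif; margin: 2em; color: #222; }
h1 { border-bottom: 2px solid #555; }
h2 { color: #356; margin-top: 1.5em; }
table { border-collapse: collapse; margin: 1em 0; }
td, th { border: 1px solid #bbb; padding: 4px 10px; font-size: 13px; }
img { margin: 6px; vertical-align: top; }
.ts { color: #999; font-size: 11px; }
</style></head><body>
<h1>{{ title }}</h1>
<p class="ts">generated: {{ timestamp }}</p>
{% for section in sections %}
<h2>{{ section.title }}</h2>
{% if section.text %}<p>{{ section.text }}</p>{% endif %}
{% for img in section.images %}<img src="{{ img }}" />{% endfor %}
{% if section.table %}{{ section.table }}{% endif %}
{% endfor %}
</body></html>
"""
)


def _provenance_table(exp: QCExperiment) -> str:
    rows = [
        {
            "operation": e.operation,
            "seed": e.seed,
            "parameters": "; ".join(f"{k}={v}" for k, v in e.parameters.items()),
        }
        for e in exp.provenance.entries
    ]
    if not rows:
        return ""
    return pd.DataFrame(rows).to_html(index=False, border=0)


def report_droplet_qc(
    droplet: QCExperiment,
    out_path: str | Path,
    timestamp: str | None = None,
) -> Path:
    """Write the droplet-level QC report (one section per sample)."""
    annot = droplet.cell_annotations
    missing = [
        c
        for c in (RANK_COLUMNS[1], EMPTYDROPS_COLUMNS[1], EMPTYDROPS_COLUMNS[5])
        if c not in annot.columns
    ]
    if missing:
        raise MissingResultError(
            f"droplet QC columns missing: {missing}; run run_droplet_qc first"
        )
    sections = []
    sample_col = annot["sample"].astype(str)
    for s in droplet.samples:
        mask = (sample_col == s).to_numpy()
        sub = annot.loc[mask]
        knee = float(sub[RANK_COLUMNS[2]].iloc[0])
        inflection = float(sub[RANK_COLUMNS[3]].iloc[0])
        totals = sub[RANK_COLUMNS[1]].to_numpy(dtype=float)
        images = [
            _rank_curve_figure(totals, knee, inflection),
            _emptydrops_scatter(
                sub[EMPTYDROPS_COLUMNS[0]].to_numpy(dtype=float),
                sub[EMPTYDROPS_COLUMNS[1]].to_numpy(dtype=float),
                sub[EMPTYDROPS_COLUMNS[5]].to_numpy(dtype=bool),
            ),
        ]
        n_cells = int(sub[EMPTYDROPS_COLUMNS[5]].astype(bool).sum())
        sections.append(
            {
                "title": f"Sample {s}",
                "text": (
                    f"{mask.sum()} droplets; {n_cells} called cells; "
                    f"knee = {knee:.1f}, inflection = {inflection:.1f}."
                ),
                "images": images,
                "table": None,
            }
        )
    sections.append(
        {
            "title": "Run parameters",
            "text": None,
            "images": [],
            "table": _provenance_table(droplet),
        }
    )
    html = _PAGE.render(
        title="Droplet QC report",
        timestamp=timestamp
        or datetime.datetime.now(datetime.timezone.utc).isoformat(),
        sections=sections,
    )
    out_path = Path(out_path)
    out_path.write_text(html)
    return out_path


def report_cell_qc(
    cell: QCExperiment,
    out_path: str | Path,
    droplet: QCExperiment | None = None,
    timestamp: str | None = None,
) -> Path:
    """Write the cell-level QC report.

    Includes violin plots of the general metrics per sample, one section
    per doublet algorithm (score violin + embedding colored by call),
    a decontamination section when present, and the per-sample summary
    table identical to :func:`summarize_qc`'s output.
    """
    annot = cell.cell_annotations
    sample_col = annot["sample"].astype(str)
    samples = cell.samples
    sections = []

    def by_sample(col: str) -> dict[str, np.ndarray]:
        return {
            s: annot.loc[(sample_col == s).to_numpy(), col].to_numpy(dtype=float)
            for s in samples
        }

    general_imgs = []
    for col, label in (
        ("total", "total counts"),
        ("detected", "genes detected"),
    ):
        if col in annot:
            general_imgs.append(_violin(by_sample(col), label))
    for col in annot.columns:
        if col.endswith("_percent"):
            general_imgs.append(_violin(by_sample(col), col))
    if general_imgs:
        sections.append(
            {"title": "General QC metrics", "text": None,
             "images": general_imgs, "table": None}
        )

    embedding = None
    if "decontX_UMAP" in cell.reduced_dims:
        embedding = cell.reduced_dims["decontX_UMAP"]

    algos = sorted(
        c[: -len("_doublet_score")]
        for c in annot.columns
        if c.endswith("_doublet_score")
    )
    for algo in algos:
        imgs = [_violin(by_sample(f"{algo}_doublet_score"), f"{algo} score")]
        if embedding is not None:
            imgs.append(
                _embedding_scatter(
                    embedding,
                    annot[f"{algo}_doublet_call"].astype(bool).to_numpy(),
                    f"{algo} doublet call",
                    categorical=True,
                )
            )
        calls = annot[f"{algo}_doublet_call"].astype(bool)
        sections.append(
            {
                "title": f"Doublet detection: {algo}",
                "text": f"{int(calls.sum())} of {len(calls)} cells called doublets.",
                "images": imgs,
                "table": None,
            }
        )

    if "decontX_contamination" in annot:
        imgs = [_violin(by_sample("decontX_contamination"), "contamination fraction")]
        if embedding is not None:
            imgs.append(
                _embedding_scatter(
                    embedding,
                    annot["decontX_contamination"].to_numpy(dtype=float),
                    "ambient contamination",
                )
            )
            if "decontX_clusters" in annot:
                imgs.append(
                    _embedding_scatter(
                        embedding,
                        annot["decontX_clusters"].to_numpy(),
                        "decontamination clusters",
                        categorical=True,
                    )
                )
        sections.append(
            {"title": "Ambient RNA contamination", "text": None,
             "images": imgs, "table": None}
        )

    summary = format_summary(summarize_qc(cell, droplet))
    sections.append(
        {
            "title": "Summary table",
            "text": None,
            "images": [],
            "table": summary.to_html(border=0),
        }
    )
    sections.append(
        {"title": "Run parameters", "text": None, "images": [],
         "table": _provenance_table(cell)}
    )
    html = _PAGE.render(
        title="Cell QC report",
        timestamp=timestamp
        or datetime.datetime.now(datetime.timezone.utc).isoformat(),
        sections=sections,
    )
    out_path = Path(out_path)
    out_path.write_text(html)
    return out_path
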