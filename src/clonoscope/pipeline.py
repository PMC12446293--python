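"""End-to-end run: import → merge → normalize → gate → clonotypes → CDR3 →
features/embed → export, with per-stage JSON reports and a run manifest.

Outputs are deterministic: the same config and seed produce byte-identical
TSVs (no timestamps are written).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cdr3 import cdr3_summary_plot, count_cdr3
from .clonotype import (ConstantRegionTable, clean_airr, count_clonotypes,
                        pair_chains)
from .export import export_assay
from .features import (EmbedParams, FeatureSpec, build_feature_matrix, embed,
                       plot_feature)
from .io_matrix import SampleInput, load_samples, read_airr
from .preprocess import (GateConfig, NormalizationParams, gate_cells,
                         log_normalize, manual_gate, subset_matrix)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    samples: list[SampleInput] = field(default_factory=list)
    airr_path: Path | None = None
    out_dir: Path = Path("clonoscope_out")
    normalization: NormalizationParams = field(default_factory=NormalizationParams)
    gate_mode: str | None = None  # None disables the gate stage
    gate: GateConfig = field(default_factory=GateConfig)
    manual_cells: list[str] | None = None
    min_umi: int = 1
    constant_table: ConstantRegionTable = field(default_factory=ConstantRegionTable)
    feature_spec: FeatureSpec = field(default_factory=FeatureSpec)
    embed_params: EmbedParams = field(default_factory=EmbedParams)
    cdr3_plot_top_n: int = 10
    make_plots: bool = False
    column_map: dict[str, str] | None = None


class StageError(RuntimeError):
    def __init__(self, stage: str, reports: dict, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.reports = reports


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, Path):
            return str(o)
        return str(o)

    blob = json.dumps(dataclasses.asdict(config), default=default,
                      sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _counts_tsv(counts: pd.DataFrame, path: Path) -> None:
    out = counts.copy()
    out["member_cells"] = out["member_cell_ids"].map(";".join)
    out.drop(columns="member_cell_ids").to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; returns the stage reports.

    Any stage failure raises StageError carrying the stage name and the
    reports accumulated so far.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reports: dict[str, dict] = {}

    def stage(name):
        def deco(fn):
            try:
                result = fn()
            except Exception as exc:  # abort with context
                _write_reports(out, reports)
                raise StageError(name, reports, exc) from exc
            return result
        return deco

    @stage("import")
    def _import():
        matrix = load_samples(config.samples)
        airr = read_airr(config.airr_path, column_map=config.column_map)
        reports["import"] = {
            "n_cells": matrix.n_cells,
            "n_features": matrix.n_features,
            "n_samples": len(config.samples),
            "airr_rows": len(airr),
            "airr_dropped_no_cell_id": airr.n_dropped_no_cell_id,
            "airr_dropped_unknown_locus": airr.n_dropped_unknown_locus,
        }
        return matrix, airr

    matrix, airr = _import

    @stage("normalize")
    def _normalize():
        norm = log_normalize(matrix, config.normalization)
        reports["normalize"] = {
            "cells_in": matrix.n_cells,
            "cells_out": norm.n_cells,
            "scale_factor": config.normalization.scale_factor,
        }
        return norm

    norm = _normalize

    @stage("gate")
    def _gate():
        current = norm
        if config.gate_mode:
            selected, gr = gate_cells(current, airr, config.gate,
                                      config.gate_mode)
            current = subset_matrix(current, selected)
            reports["gate"] = dataclasses.asdict(gr)
        if config.manual_cells is not None:
            kept = manual_gate(current, config.manual_cells)
            current = subset_matrix(current, kept)
            reports.setdefault("gate", {})["manual_selected"] = len(kept)
        if "gate" in reports:
            reports["gate"]["cells_in"] = norm.n_cells
            reports["gate"]["cells_out"] = current.n_cells
        return current

    gated = _gate

    @stage("clonotypes")
    def _clonotypes():
        cleaned = clean_airr(airr, min_umi=config.min_umi,
                             constant_table=config.constant_table)
        paired, pr = pair_chains(cleaned)
        counts = count_clonotypes(paired)
        _counts_tsv(counts, out / "clonotypes.tsv")
        reports["clonotypes"] = {
            **dataclasses.asdict(pr),
            "n_clonotypes": len(counts),
        }
        return paired, counts

    paired, clono_counts = _clonotypes

    @stage("cdr3")
    def _cdr3():
        counts = count_cdr3(paired)
        _counts_tsv(counts, out / "cdr3.tsv")
        if config.make_plots and not counts.empty:
            cdr3_summary_plot(counts, out / "cdr3_pie.png",
                              top_n=config.cdr3_plot_top_n)
        reports["cdr3"] = {"n_cdr3_types": len(counts)}
        return counts

    cdr3_counts = _cdr3

    @stage("features")
    def _features():
        fm = build_feature_matrix(gated, paired, clono_counts,
                                  config.feature_spec)
        emb = embed(fm, config.embed_params)
        fm.to_frame().to_csv(out / "features.tsv", sep="\t",
                             index_label="cell_id")
        pd.DataFrame(emb.coords, index=emb.cell_ids,
                     columns=["umap_1", "umap_2"]).to_csv(
            out / "coords.tsv", sep="\t", index_label="cell_id")
        pd.DataFrame({"cluster": emb.cluster_labels},
                     index=emb.cell_ids).to_csv(
            out / "clusters.tsv", sep="\t", index_label="cell_id")
        if config.make_plots:
            for name in ("tcr-type", "clonotype-count"):
                if name in fm.feature_names:
                    plot_feature(emb, fm.column(name),
                                 out / f"umap_{name}.png", title=name)
        n_clusters = len(set(emb.cluster_labels) - {-1})
        reports["features"] = {
            "cells_in": gated.n_cells,
            "cells_embedded": len(emb.cell_ids),
            "n_features": len(fm.feature_names),
            "n_clusters": n_clusters,
            "n_noise": int((emb.cluster_labels == -1).sum()),
        }
        return fm, emb

    fm, emb = _features

    @stage("export")
    def _export():
        tcr_table = fm.to_frame()
        tcr_table["cluster"] = pd.Series(
            emb.cluster_labels.astype(float), index=emb.cell_ids)
        export_assay(tcr_table, matrix, out / "tcr_assay.csv")
        reports["export"] = {
            "n_features": tcr_table.shape[1],
            "n_cells": matrix.n_cells,
        }

    _export

    manifest = {
        "version": __version__,
        "seed": config.embed_params.random_seed,
        "config_hash": _config_hash(config),
        "stages": list(reports),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    _write_reports(out, reports)
    return reports


def _write_reports(out: Path, reports: dict) -> None:
    with open(out / "stage_reports.json", "w") as fh:
        json.dump(reports, fh, indent=2, sort_keys=True, default=str)
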