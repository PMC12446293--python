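"""Zero-filled per-cell matrix export for downstream single-cell frameworks.

TCR-derived per-cell tables cover only cells with a paired receptor; the
export left-joins them to the full cell index of the expression matrix and
fills missing cells with zeros, producing a features x cells CSV that
Seurat's CreateAssayObject() (or an AnnData layer) accepts directly.
Underscores in feature names are rewritten to dashes eagerly, because
downstream frameworks do the same silently.
"""

from __future__ import annotations

import logging
import subprocess
from pathlib import Path

import pandas as pd

from .io_matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

_R_LOADER = Path(__file__).resolve().parents[2] / "r" / "load_assay.R"


def sanitize_feature_name(name: str) -> str:
    return name.replace("_", "-")


def export_assay(
    table: pd.DataFrame, matrix: ExpressionMatrix, out: str | Path
) -> Path:
    """Write a features x cells CSV aligned to ``matrix.barcodes``.

    ``table`` is cells x features (index = cell ids, a subset of the
    matrix barcodes; extras are an error since they indicate an upstream
    mismatch). Cells without TCR data become all-zero columns.
    """
    out = Path(out)
    extras = set(table.index) - set(matrix.barcodes)
    if extras:
        raise ValueError(
            f"{len(extras)} table cell ids not in the expression matrix, "
            f"e.g. {sorted(extras)[:3]}"
        )

    sanitized = [sanitize_feature_name(c) for c in table.columns]
    dupes = pd.Series(sanitized)
    collisions = sorted(set(dupes[dupes.duplicated(keep=False)]))
    if collisions:
        raise ValueError(f"feature name collisions after sanitization: {collisions}")

    aligned = table.reindex(matrix.barcodes).fillna(0.0)
    aligned.columns = sanitized
    wide = aligned.T  # features x cells
    wide.index.name = "feature"
    wide.to_csv(out, float_format=None)  # full precision
    logger.info("exported %d features x %d cells to %s",
                wide.shape[0], wide.shape[1], out)
    return out


def validate_seurat_load(csv: str | Path, rscript: str = "Rscript") -> dict:
    """Run the companion R loader, which builds a Seurat assay object from
    the CSV, and report whether its dimensions match the file."""
    csv = Path(csv)
    report = {"ok": False, "csv": str(csv), "stdout": "", "stderr": ""}
    if not csv.exists() or csv.stat().st_size == 0:
        report["stderr"] = "CSV missing or empty"
        return report
    try:
        proc = subprocess.run(
            [rscript, str(_R_LOADER), str(csv)],
            capture_output=True, text=True, timeout=300,
        )
    except (OSError, subprocess.TimeoutExpired) as exc:
        report["stderr"] = str(exc)
        return report
    report["stdout"] = proc.stdout
    report["stderr"] = proc.stderr
    if proc.returncode != 0:
        return report

    dims = None
    for line in proc.stdout.splitlines():
        if line.startswith("ASSAY_DIMS"):
            _, nf, nc = line.split()
            dims = (int(nf), int(nc))
    header = pd.read_csv(csv, nrows=0)
    expected = (sum(1 for _ in open(csv)) - 1, len(header.columns) - 1)
    report["assay_dims"] = dims
    report["csv_dims"] = expected
    report["ok"] = dims == expected
    return report
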