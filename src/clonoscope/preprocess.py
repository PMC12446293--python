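"""Expression normalization and marker-based T-cell gating.

Normalization is the counts-per-ten-thousand convention: each cell's counts
are scaled to a fixed library size (default 10,000), a pseudocount is added
and the result is log2-transformed. With pseudocount 1 zeros map to zero, so
sparsity is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io_matrix import AirrTable, ExpressionMatrix, TR_LOCI

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormalizationParams:
    scale_factor: float = 10_000.0
    pseudocount: float = 1.0
    log_base: float = 2.0

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


@dataclass
class NormalizedMatrix:
    """log2 counts-per-scale_factor values, features x cells (sparse)."""

    values: sp.csr_matrix
    feature_ids: list[str]
    feature_names: list[str]
    barcodes: list[str]
    sample_tags: list[str]
    params: NormalizationParams = field(default_factory=NormalizationParams)

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def marker_values(self, marker: str) -> np.ndarray:
        """Dense per-cell values for one feature, resolved by name then id."""
        idx = self.resolve_feature(marker)
        return np.asarray(self.values[idx, :].todense()).ravel()

    def resolve_feature(self, marker: str) -> int:
        if marker in self.feature_names:
            return self.feature_names.index(marker)
        if marker in self.feature_ids:
            return self.feature_ids.index(marker)
        raise KeyError(f"marker {marker!r} not found among features")


def log_normalize(
    matrix: ExpressionMatrix, params: NormalizationParams | None = None
) -> NormalizedMatrix:
    """value(f, c) = log2(count(f, c) / total(c) * scale_factor + pseudocount).

    Cells with zero total UMIs are dropped (with a warning) before
    normalization. When pseudocount == 1 the computation touches only the
    stored nonzeros, keeping the matrix sparse.
    """
    params = params or NormalizationParams()
    counts = matrix.counts.tocsc()
    totals = np.asarray(counts.sum(axis=0)).ravel()

    keep = totals > 0
    if not keep.all():
        logger.warning("dropping %d cells with zero total UMIs", int((~keep).sum()))
    counts = counts[:, keep]
    totals = totals[keep]

    scaled = counts.astype(np.float64).multiply(params.scale_factor / totals)
    log_scale = np.log2(params.log_base)  # log_b(x) = log2(x) / log2(b)
    if params.pseudocount == 1.0:
        out = scaled.tocsr()
        out.data = np.log2(out.data + 1.0) / log_scale
    else:
        dense = np.asarray(scaled.todense()) + params.pseudocount
        out = sp.csr_matrix(np.log2(dense) / log_scale)

    keep_idx = np.flatnonzero(keep)
    return NormalizedMatrix(
        values=out.tocsr(),
        feature_ids=list(matrix.feature_ids),
        feature_names=list(matrix.feature_names),
        barcodes=[matrix.barcodes[i] for i in keep_idx],
        sample_tags=[matrix.sample_tags[i] for i in keep_idx],
        params=params,
    )


@dataclass
class GateConfig:
    """Marker panel and threshold for automatic T / CD4 / CD8 gating.

    The default threshold keeps any cell with normalized expression strictly
    above zero for the positive markers; CD4/CD8 gates additionally require
    the opposing marker(s) at or below the threshold, so double positives
    fall in neither subset.
    """

    tcell_markers: tuple[str, ...] = ("CD3D", "CD3E", "CD3G")
    cd4_marker: str = "CD4"
    cd8_markers: tuple[str, ...] = ("CD8A", "CD8B")
    threshold: float = 0.0
    require_tcr_chain: bool = False


@dataclass
class GatingReport:
    mode: str
    n_cells_in: int
    n_pass_markers: int
    n_pass_tcr_chain: int
    n_selected: int


def gate_cells(
    matrix: NormalizedMatrix,
    airr: AirrTable | None,
    config: GateConfig,
    mode: str,
) -> tuple[list[str], GatingReport]:
    """Select T cells (or CD4/CD8 subsets) by marker expression.

    mode "T": any T-cell marker above threshold; when
    ``require_tcr_chain`` is set, the union with cells carrying at least one
    TR-locus chain. mode "CD4": T gate AND CD4 positive AND every CD8 marker
    at/below threshold; mode "CD8" symmetric.
    """
    if mode not in ("T", "CD4", "CD8"):
        raise ValueError(f"unknown gating mode: {mode!r}")

    thr = config.threshold
    n = matrix.n_cells

    def above(markers) -> np.ndarray:
        mask = np.zeros(n, dtype=bool)
        for m in markers:
            mask |= matrix.marker_values(m) > thr
        return mask

    t_mask = above(config.tcell_markers)
    tcr_mask = np.zeros(n, dtype=bool)
    if config.require_tcr_chain:
        if airr is None:
            raise ValueError("require_tcr_chain set but no AIRR table given")
        tr_cells = set(
            airr.df.loc[airr.df["locus"].isin(TR_LOCI), "cell_id"]
        )
        tcr_mask = np.array([bc in tr_cells for bc in matrix.barcodes])
        t_mask = t_mask | tcr_mask

    if mode == "T":
        sel = t_mask
    elif mode == "CD4":
        cd8_any = above(config.cd8_markers)
        sel = t_mask & above([config.cd4_marker]) & ~cd8_any
    else:  # CD8
        cd4_pos = above([config.cd4_marker])
        sel = t_mask & above(config.cd8_markers) & ~cd4_pos

    report = GatingReport(
        mode=mode,
        n_cells_in=n,
        n_pass_markers=int(t_mask.sum()),
        n_pass_tcr_chain=int(tcr_mask.sum()),
        n_selected=int(sel.sum()),
    )
    selected = [bc for bc, s in zip(matrix.barcodes, sel) if s]
    return selected, report


def manual_gate(matrix: NormalizedMatrix, cell_ids: list[str]) -> list[str]:
    """Intersect an explicit cell-id list with the matrix; missing ids logged."""
    present = set(matrix.barcodes)
    missing = [c for c in cell_ids if c not in present]
    if missing:
        logger.info("manual gate: %d of %d ids not in matrix",
                    len(missing), len(cell_ids))
    wanted = set(cell_ids)
    return [bc for bc in matrix.barcodes if bc in wanted]


def subset_matrix(matrix: NormalizedMatrix, cell_ids: list[str]) -> NormalizedMatrix:
    """Restrict a normalized matrix to the given cells (matrix order kept)."""
    wanted = set(cell_ids)
    idx = [i for i, bc in enumerate(matrix.barcodes) if bc in wanted]
    return NormalizedMatrix(
        values=matrix.values[:, idx].tocsr(),
        feature_ids=list(matrix.feature_ids),
        feature_names=list(matrix.feature_names),
        barcodes=[matrix.barcodes[i] for i in idx],
        sample_tags=[matrix.sample_tags[i] for i in idx],
        params=matrix.params,
    )
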