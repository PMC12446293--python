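"""Multimodal per-cell features and the standardize → PCA → UMAP → HDBSCAN
embedding.

The feature matrix concatenates, per paired T cell:

* normalized expression of a user-chosen marker panel (e.g. CD4, CD8A,
  NKG7, FOXP3);
* the size of the cell's clonotype (cells per contig);
* a one-hot Sample Tag block;
* a one-hot clonotype-identity block (clones below ``clonotype_min_cells``
  share a single "singleton" column to bound dimensionality);
* a TCR-type indicator (αβ = 1, γδ = 0);
* a one-hot V(D)J gene-segment block, allele-stripped so convergent clones
  sharing a gene but not an allele co-locate; a cell is 0 in every column
  of loci outside its own receptor type.

Clustering runs on the 2-D UMAP coordinates by default (``cluster_on`` can
switch it to the PCA space).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN
from sklearn.decomposition import PCA

from .clonotype import PairedCell
from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass
class FeatureSpec:
    markers: tuple[str, ...] = ()
    include_sample_tag: bool = True
    include_clonotype_id: bool = True
    include_tcr_type: bool = True
    include_vdj: bool = True
    include_clonotype_count: bool = True
    clonotype_min_cells: int = 2

    def __post_init__(self) -> None:
        if self.clonotype_min_cells < 1:
            raise ValueError("clonotype_min_cells must be >= 1")


@dataclass
class FeatureMatrix:
    cell_ids: list[str]
    feature_names: list[str]
    values: np.ndarray  # cells x features, dense
    provenance: list[str]  # per feature: marker|sample_tag|clonotype|tcr_type|vdj|count

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids,
                            columns=self.feature_names)

    def column(self, name: str) -> np.ndarray:
        try:
            return self.values[:, self.feature_names.index(name)]
        except ValueError:
            raise KeyError(f"feature {name!r} not in matrix") from None


@dataclass
class EmbedParams:
    standardize: bool = True
    n_pcs: int = 30
    umap_neighbors: int = 15
    umap_min_dist: float = 0.1
    hdbscan_min_cluster_size: int = 10
    random_seed: int = 42
    cluster_on: str = "umap"  # or "pca"


@dataclass
class EmbeddingResult:
    cell_ids: list[str]
    coords: np.ndarray  # cells x 2
    cluster_labels: np.ndarray  # int per cell, -1 = noise
    params: EmbedParams = field(default_factory=EmbedParams)


def _strip_allele(call: str) -> str:
    """'TRBV19*01' -> 'TRBV19'; multi-call strings keep the first call."""
    return call.split(",")[0].split("*")[0].strip()


def _segment_class(locus: str, slot: str) -> str:
    return f"{locus}{slot}"  # e.g. TRB + V -> TRBV


def one_hot_vdj(paired: list[PairedCell]) -> tuple[np.ndarray, list[str]]:
    """One binary column per observed (locus, segment class, gene) triple,
    named like ``TRBV:TRBV19``. Columns exist only for observed segments, so
    cells of one receptor type are 0 in every column of the other."""
    col_of_cell: list[set[str]] = []
    columns: set[str] = set()
    for pc in paired:
        cols = set()
        for chain in (pc.chain_1, pc.chain_2):
            for slot, call in (("V", chain.v_call), ("D", chain.d_call),
                               ("J", chain.j_call)):
                gene = _strip_allele(call)
                if gene:
                    cols.add(f"{_segment_class(chain.locus, slot)}:{gene}")
        columns |= cols
        col_of_cell.append(cols)

    names = sorted(columns)
    index = {c: j for j, c in enumerate(names)}
    block = np.zeros((len(paired), len(names)))
    for i, cols in enumerate(col_of_cell):
        for c in cols:
            block[i, index[c]] = 1.0
    return block, names


def build_feature_matrix(
    normalized: NormalizedMatrix,
    paired: list[PairedCell],
    counts: pd.DataFrame,
    spec: FeatureSpec,
) -> FeatureMatrix:
    """Assemble the multimodal feature matrix over paired cells present in
    the normalized expression matrix (absent cells are logged and skipped)."""
    present = set(normalized.barcodes)
    missing = [pc.cell_id for pc in paired if pc.cell_id not in present]
    if missing:
        logger.info("%d paired cells absent from expression matrix; skipped",
                    len(missing))
    paired = [pc for pc in paired if pc.cell_id in present]
    if not paired:
        raise ValueError("no paired cells overlap the expression matrix")

    cell_ids = [pc.cell_id for pc in paired]
    pos = {bc: i for i, bc in enumerate(normalized.barcodes)}
    cell_idx = [pos[c] for c in cell_ids]

    blocks: list[np.ndarray] = []
    names: list[str] = []
    prov: list[str] = []

    for marker in spec.markers:
        vals = normalized.marker_values(marker)  # KeyError if unresolvable
        blocks.append(vals[cell_idx][:, None])
        names.append(marker)
        prov.append("marker")

    size_of = dict(zip(counts["contig"], counts["n_cells"]))
    if spec.include_clonotype_count:
        col = np.array([float(size_of.get(pc.clonotype_contig, 1))
                        for pc in paired])
        blocks.append(col[:, None])
        names.append("clonotype-count")
        prov.append("count")

    if spec.include_sample_tag:
        tag_of = {bc: t for bc, t in zip(normalized.barcodes,
                                         normalized.sample_tags)}
        tags = sorted({tag_of[c] for c in cell_ids})
        block = np.zeros((len(paired), len(tags)))
        for i, c in enumerate(cell_ids):
            block[i, tags.index(tag_of[c])] = 1.0
        blocks.append(block)
        names.extend(f"tag:{t}" for t in tags)
        prov.extend("sample_tag" for _ in tags)

    if spec.include_clonotype_id:
        big = sorted({pc.clonotype_hash for pc in paired
                      if size_of.get(pc.clonotype_contig, 1)
                      >= spec.clonotype_min_cells})
        cols = [f"clonotype:{h}" for h in big] + ["clonotype:singleton"]
        index = {h: j for j, h in enumerate(big)}
        block = np.zeros((len(paired), len(cols)))
        for i, pc in enumerate(paired):
            j = index.get(pc.clonotype_hash, len(cols) - 1)
            block[i, j] = 1.0
        blocks.append(block)
        names.extend(cols)
        prov.extend("clonotype" for _ in cols)

    if spec.include_tcr_type:
        col = np.array([1.0 if pc.tcr_type == "AB" else 0.0 for pc in paired])
        blocks.append(col[:, None])
        names.append("tcr-type")
        prov.append("tcr_type")

    if spec.include_vdj:
        block, vdj_names = one_hot_vdj(paired)
        blocks.append(block)
        names.extend(vdj_names)
        prov.extend("vdj" for _ in vdj_names)

    values = np.hstack(blocks) if blocks else np.zeros((len(paired), 0))
    return FeatureMatrix(cell_ids=cell_ids, feature_names=names,
                         values=values, provenance=prov)


def standardize(values: np.ndarray) -> np.ndarray:
    """Per-feature z-score; zero-variance features are set to 0."""
    mean = values.mean(axis=0)
    std = values.std(axis=0)
    out = np.zeros_like(values, dtype=np.float64)
    nz = std > 0
    out[:, nz] = (values[:, nz] - mean[nz]) / std[nz]
    return out


def embed(features: FeatureMatrix, params: EmbedParams | None = None) -> EmbeddingResult:
    """Standardize → PCA → UMAP(2-D) → HDBSCAN with a fixed seed.

    Identical input and seed give identical coordinates and labels.
    """
    import umap  # deferred: numba compilation is slow at import time

    params = params or EmbedParams()
    n_cells, n_feat = features.values.shape
    minimum = max(params.umap_neighbors + 1, params.hdbscan_min_cluster_size)
    if n_cells < minimum:
        raise ValueError(
            f"embedding needs at least {minimum} cells, got {n_cells}")

    x = features.values.astype(np.float64)
    if params.standardize:
        x = standardize(x)

    n_pcs = min(params.n_pcs, n_feat - 1, n_cells - 1)
    if n_pcs < 2:
        raise ValueError("need at least 2 principal components")
    pcs = PCA(n_components=n_pcs,
              random_state=params.random_seed).fit_transform(x)

    # init="random" (seeded), not the spectral default: cells of one clone
    # carry identical one-hot rows, which makes the graph Laplacian's
    # eigengap degenerate; ARPACK then gives results that depend on its
    # process-level internal state, breaking run-to-run reproducibility.
    coords = umap.UMAP(
        n_components=2,
        n_neighbors=params.umap_neighbors,
        min_dist=params.umap_min_dist,
        random_state=params.random_seed,
        init="random",
    ).fit_transform(pcs)
    coords = np.asarray(coords, dtype=np.float64)

    space = coords if params.cluster_on == "umap" else pcs
    labels = HDBSCAN(
        min_cluster_size=params.hdbscan_min_cluster_size, copy=True
    ).fit_predict(space)

    return EmbeddingResult(cell_ids=list(features.cell_ids), coords=coords,
                           cluster_labels=np.asarray(labels), params=params)


def plot_feature(
    embedding: EmbeddingResult,
    feature_values: np.ndarray,
    out: str | Path,
    title: str = "",
) -> Path:
    """Scatter the 2-D embedding colored by one feature: two colors for a
    binary feature, a continuous colormap otherwise."""
    out = Path(out)
    vals = np.asarray(feature_values, dtype=np.float64)
    if vals.shape[0] != len(embedding.cell_ids):
        raise ValueError("feature length does not match embedded cells")

    fig, ax = plt.subplots(figsize=(6, 5))
    binary = set(np.unique(vals)) <= {0.0, 1.0}
    if binary:
        for val, color, label in ((0.0, "tab:blue", "0"), (1.0, "tab:red", "1")):
            m = vals == val
            ax.scatter(embedding.coords[m, 0], embedding.coords[m, 1],
                       s=8, c=color, label=label, linewidths=0)
        ax.legend(fontsize=8)
    else:
        sc = ax.scatter(embedding.coords[:, 0], embedding.coords[:, 1],
                        s=8, c=vals, cmap="viridis", linewidths=0)
        fig.colorbar(sc, ax=ax)
    ax.set_xlabel("UMAP1")
    ax.set_ylabel("UMAP2")
    if title:
        ax.set_title(title)
    fig.savefig(out, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return out
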