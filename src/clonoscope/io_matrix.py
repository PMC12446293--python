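"""Readers for expression triplets and AIRR rearrangement tables.

Expression data arrive as one directory per sample in the 10X-Genomics-like
triplet layout (Matrix Market sparse counts + features TSV + barcodes TSV),
the format BD Rhapsody exports. Chain-level V(D)J data arrive as a single
AIRR Rearrangement TSV with one row per assembled dominant contig.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

TR_LOCI = ("TRA", "TRB", "TRG", "TRD")
IG_LOCI = ("IGH", "IGK", "IGL")
KNOWN_LOCI = TR_LOCI + IG_LOCI

#: amino-acid alphabet: the 20 standard residues plus stop (*) and ambiguous (X)
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY*X")

#: logical AIRR field -> default column header (AIRR Rearrangement standard)
DEFAULT_COLUMN_MAP = {
    "cell_id": "cell_id",
    "locus": "locus",
    "v_call": "v_call",
    "d_call": "d_call",
    "j_call": "j_call",
    "c_call": "c_call",
    "productive": "productive",
    "sequence_aa": "sequence_aa",
    "cdr3_aa": "cdr3_aa",
    "umi_count": "duplicate_count",
}

REQUIRED_FIELDS = ("cell_id", "locus", "v_call", "j_call", "productive",
                   "sequence_aa", "cdr3_aa")
OPTIONAL_FIELDS = ("d_call", "c_call", "umi_count")

_TRUTHY = {"T", "TRUE", "true", "1", "True"}


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


@dataclass
class ExpressionMatrix:
    """Sparse UMI counts, features x cells, with one sample tag per cell."""

    counts: sp.csr_matrix
    feature_ids: list[str]
    feature_names: list[str]
    barcodes: list[str]
    sample_tags: list[str]

    def __post_init__(self) -> None:
        n_feat, n_cells = self.counts.shape
        if n_feat != len(self.feature_ids) or n_cells != len(self.barcodes):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.barcodes)} barcodes"
            )
        if len(self.sample_tags) != n_cells:
            raise FormatError("one sample tag required per cell")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative counts")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find_triplet_file(directory: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            cand = directory / (stem + suffix)
            if cand.exists():
                return cand
    raise FileNotFoundError(
        f"none of {', '.join(stems)} (optionally .gz) found in {directory}"
    )


def read_feature_matrix(directory: str | Path, sample_tag: str) -> ExpressionMatrix:
    """Read one sample's Matrix Market triplet and tag every cell.

    Matrix orientation is auto-detected: if the on-disk matrix is
    cells x features it is transposed so the result is always
    features x cells.
    """
    directory = Path(directory)
    mtx_path = _find_triplet_file(directory, ("matrix.mtx",))
    feat_path = _find_triplet_file(directory, ("features.tsv", "genes.tsv"))
    bc_path = _find_triplet_file(directory, ("barcodes.tsv",))

    feat_df = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    if feat_df.empty:
        raise FormatError(f"empty features file: {feat_path}")
    feature_ids = feat_df.iloc[:, 0].tolist()
    feature_names = (feat_df.iloc[:, 1] if feat_df.shape[1] > 1
                     else feat_df.iloc[:, 0]).tolist()

    with _open_maybe_gz(bc_path) as fh:
        barcodes = [line.strip().split("\t")[0] for line in fh if line.strip()]
    if not barcodes:
        raise FormatError(f"empty barcodes file: {bc_path}")

    counts = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    nf, nb = len(feature_ids), len(barcodes)
    if counts.shape == (nf, nb):
        pass
    elif counts.shape == (nb, nf):
        counts = counts.T.tocsr()
    else:
        raise FormatError(
            f"matrix shape {counts.shape} matches neither {nf} features x "
            f"{nb} barcodes nor its transpose"
        )
    if counts.nnz and not np.allclose(counts.data, np.round(counts.data)):
        raise FormatError("non-integral UMI counts")
    counts.data = np.asarray(np.round(counts.data), dtype=np.int64)

    return ExpressionMatrix(
        counts=counts,
        feature_ids=feature_ids,
        feature_names=feature_names,
        barcodes=barcodes,
        sample_tags=[sample_tag] * nb,
    )


def merge_samples(matrices: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Concatenate samples cell-wise over a shared feature list.

    Barcodes colliding between samples are disambiguated by suffixing
    ``-<sample_tag>``.
    """
    if not matrices:
        raise ValueError("no matrices to merge")
    ref = matrices[0]
    for m in matrices[1:]:
        if m.feature_ids != ref.feature_ids:
            mismatch = next(
                (a for a, b in zip(ref.feature_ids, m.feature_ids) if a != b),
                "<length mismatch>",
            )
            raise FormatError(f"feature lists differ; first mismatch: {mismatch}")

    all_barcodes = [bc for m in matrices for bc in m.barcodes]
    seen = pd.Series(all_barcodes)
    dup = set(seen[seen.duplicated(keep=False)])

    barcodes: list[str] = []
    tags: list[str] = []
    for m in matrices:
        for bc, tag in zip(m.barcodes, m.sample_tags):
            barcodes.append(f"{bc}-{tag}" if bc in dup else bc)
            tags.append(tag)
    if len(set(barcodes)) != len(barcodes):
        raise FormatError("barcode collision not resolved by sample-tag suffixing")

    counts = sp.hstack([m.counts for m in matrices], format="csr")
    return ExpressionMatrix(
        counts=counts,
        feature_ids=list(ref.feature_ids),
        feature_names=list(ref.feature_names),
        barcodes=barcodes,
        sample_tags=tags,
    )


@dataclass
class AirrTable:
    """Parsed AIRR rearrangement rows with normalized logical column names."""

    df: pd.DataFrame
    n_dropped_no_cell_id: int = 0
    n_dropped_unknown_locus: int = 0

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class ChainRecord:
    """One rearrangement row (one chain of one cell)."""

    cell_id: str
    locus: str
    v_call: str = ""
    d_call: str = ""
    j_call: str = ""
    c_call: str = ""
    productive: bool = False
    sequence_aa: str = ""
    cdr3_aa: str = ""
    umi_count: int = 0


def _parse_productive(values: pd.Series) -> pd.Series:
    return values.astype(str).str.strip().isin(_TRUTHY)


def read_airr(path: str | Path, column_map: dict[str, str] | None = None) -> AirrTable:
    """Read an AIRR Rearrangement TSV into a normalized table.

    ``column_map`` maps logical field names to source headers and defaults
    to the AIRR standard (with ``duplicate_count`` as the UMI count); pass
    overrides for dialects that drift from it. Rows with an empty cell id
    or an unrecognized locus are dropped and counted.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [f for f in REQUIRED_FIELDS if cmap[f] not in raw.columns]
    if missing:
        raise FormatError(
            "required AIRR fields missing (source columns): "
            + ", ".join(f"{f}={cmap[f]}" for f in missing)
        )

    df = pd.DataFrame(index=raw.index)
    for logical in REQUIRED_FIELDS + OPTIONAL_FIELDS:
        src = cmap[logical]
        if src in raw.columns:
            df[logical] = raw[src].astype(str).str.strip()
        else:
            df[logical] = ""

    df["productive"] = _parse_productive(df["productive"])

    umi = pd.to_numeric(df["umi_count"], errors="coerce")
    n_missing_umi = int(umi.isna().sum())
    if n_missing_umi:
        logger.warning("%d rows without a UMI count; set to 0", n_missing_umi)
    df["umi_count"] = umi.fillna(0).astype(np.int64).clip(lower=0)

    no_cell = df["cell_id"] == ""
    if no_cell.any():
        logger.info("dropped %d rows with empty cell_id", int(no_cell.sum()))
    df = df[~no_cell]

    bad_locus = ~df["locus"].isin(KNOWN_LOCI)
    if bad_locus.any():
        logger.warning(
            "dropped %d rows with unknown locus: %s",
            int(bad_locus.sum()),
            sorted(df.loc[bad_locus, "locus"].unique()),
        )
    df = df[~bad_locus].reset_index(drop=True)

    for col in ("sequence_aa", "cdr3_aa"):
        bad = df[col].map(lambda s: bool(set(s) - AA_ALPHABET))
        if bad.any():
            raise FormatError(
                f"{col} contains characters outside the amino-acid alphabet "
                f"in {int(bad.sum())} rows"
            )

    not_sub = (df["cdr3_aa"] != "") & ~pd.Series(
        [c in s for c, s in zip(df["cdr3_aa"], df["sequence_aa"])],
        index=df.index, dtype=bool,
    )
    if not_sub.any():
        logger.warning(
            "%d rows where cdr3_aa is not a substring of sequence_aa",
            int(not_sub.sum()),
        )

    return AirrTable(
        df=df,
        n_dropped_no_cell_id=int(no_cell.sum()),
        n_dropped_unknown_locus=int(bad_locus.sum()),
    )


@dataclass
class SampleInput:
    """One sample directory with its manually assigned Sample Tag."""

    directory: Path
    sample_tag: str


def load_samples(samples: list[SampleInput]) -> ExpressionMatrix:
    """Read and merge several sample triplets in one call."""
    return merge_samples(
        [read_feature_matrix(s.directory, s.sample_tag) for s in samples]
    )


def write_feature_matrix(matrix: ExpressionMatrix, directory: str | Path) -> None:
    """Write a features x cells triplet (uncompressed, Matrix Market)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), matrix.counts.tocoo())
    pd.DataFrame(
        {"id": matrix.feature_ids, "name": matrix.feature_names,
         "type": ["Gene Expression"] * matrix.n_features}
    ).to_csv(directory / "features.tsv", sep="\t", header=False, index=False)
    with open(directory / "barcodes.tsv", "w") as fh:
        fh.writelines(bc + "\n" for bc in matrix.barcodes)
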