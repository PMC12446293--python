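"""Ground-truth synthetic data: paired expression triplets + AIRR tables.

The generator emulates the input contract of a multiplexed BD-Rhapsody-style
run: a handful of samples distinguished by Sample Tags, αβ T cells drawn
from a clonotype pool with one planted dominant clone confined to the
"Post" sample (the shape of an antigen-stimulation experiment), a minority
γδ population, B-cell immunoglobulin contamination, and the artifact types
the cleaning stages must handle — pseudo-translated 5'-UTR prefixes,
missing constant-region calls, unpaired chains and duplicate-locus
multiplets. Expression counts are negative-binomial per population with a
small hallmark-marker panel; no attempt is made at realistic transcriptome
breadth.

Every random draw flows from the config seed, so identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .clonotype import CONTIG_SEP, DEFAULT_C_CALLS, assign_hash
from .io_matrix import AirrTable, ExpressionMatrix, write_feature_matrix

_AA_NO_M = "ACDEFGHIKLNPQRSTVWY"  # residues for random scaffolds, M excluded

GENE_VOCAB = {
    "TRA": {"V": [f"TRAV{i}" for i in range(1, 9)], "D": [],
            "J": [f"TRAJ{i}" for i in range(1, 7)]},
    "TRB": {"V": [f"TRBV{i}" for i in range(1, 9)],
            "D": ["TRBD1", "TRBD2"],
            "J": [f"TRBJ{i}" for i in range(1, 7)]},
    "TRG": {"V": [f"TRGV{i}" for i in range(1, 5)], "D": [],
            "J": [f"TRGJ{i}" for i in range(1, 4)]},
    "TRD": {"V": [f"TRDV{i}" for i in range(1, 4)], "D": ["TRDD2", "TRDD3"],
            "J": [f"TRDJ{i}" for i in range(1, 4)]},
    "IGH": {"V": [f"IGHV{i}" for i in range(1, 5)], "D": ["IGHD1"],
            "J": [f"IGHJ{i}" for i in range(1, 4)]},
    "IGK": {"V": [f"IGKV{i}" for i in range(1, 4)], "D": [],
            "J": ["IGKJ1", "IGKJ2"]},
}

#: hallmark panel: per-population negative-binomial mean expression.
#: Populations: ab_cd8 (bulk αβ CD8), ab_cd4 (bulk αβ CD4), ab_dominant
#: (the planted clone: activated CD8, IL2RA+ IFNG+), gd, b.
DEFAULT_MARKER_PANEL: dict[str, dict[str, float]] = {
    "CD3D":  {"ab_cd8": 3, "ab_cd4": 3, "ab_dominant": 3, "gd": 3, "b": 0.02},
    "CD3E":  {"ab_cd8": 3, "ab_cd4": 3, "ab_dominant": 3, "gd": 3, "b": 0.02},
    "CD3G":  {"ab_cd8": 2, "ab_cd4": 2, "ab_dominant": 2, "gd": 2, "b": 0.02},
    "CD4":   {"ab_cd8": 0.02, "ab_cd4": 3, "ab_dominant": 0.02, "gd": 0.02, "b": 0.02},
    "CD8A":  {"ab_cd8": 3, "ab_cd4": 0.02, "ab_dominant": 6, "gd": 0.05, "b": 0.02},
    "CD8B":  {"ab_cd8": 2, "ab_cd4": 0.02, "ab_dominant": 4, "gd": 0.05, "b": 0.02},
    "NKG7":  {"ab_cd8": 1, "ab_cd4": 0.1, "ab_dominant": 3, "gd": 4, "b": 0.02},
    "FOXP3": {"ab_cd8": 0.02, "ab_cd4": 0.5, "ab_dominant": 0.02, "gd": 0.02, "b": 0.02},
    "IL2RA": {"ab_cd8": 0.1, "ab_cd4": 0.3, "ab_dominant": 4, "gd": 0.1, "b": 0.05},
    "IFNG":  {"ab_cd8": 0.2, "ab_cd4": 0.2, "ab_dominant": 4, "gd": 1, "b": 0.02},
    "MS4A1": {"ab_cd8": 0.02, "ab_cd4": 0.02, "ab_dominant": 0.02, "gd": 0.02, "b": 4},
    "PTPRC": {"ab_cd8": 5, "ab_cd4": 5, "ab_dominant": 5, "gd": 5, "b": 5},
}


@dataclass(frozen=True)
class ArtifactRates:
    """Per-record injection probabilities / per-dataset fractions."""

    utr: float = 0.0           # chains prefixed with a pseudo-translated 5'-UTR
    missing_c_call: float = 0.0
    unpaired: float = 0.0      # paired cells that lose one chain
    multiplet: float = 0.0     # cells gaining a second, lower-UMI chain per locus

    def __post_init__(self) -> None:
        for name in ("utr", "missing_c_call", "unpaired", "multiplet"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"artifact rate {name} outside [0, 1]: {v}")


@dataclass(frozen=True)
class SimConfig:
    n_ab_cells: int = 500
    n_gd_cells: int = 50
    n_b_cells: int = 20
    n_clonotypes: int = 20          # αβ clonotype pool (incl. the dominant)
    n_gd_clonotypes: int = 5
    dominant_fraction: float = 0.3  # of αβ cells, all in the "Post" sample
    clonal_distribution: str = "zipf"  # or "uniform"
    zipf_shape: float = 1.5
    sample_tags: tuple[str, ...] = ("Pre", "Post")
    cd4_fraction: float = 0.3       # of non-dominant αβ cells
    nb_dispersion: float = 2.0
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.dominant_fraction < 1.0:
            raise ValueError("dominant_fraction must lie in (0, 1)")
        if self.dominant_fraction * self.n_ab_cells < 1:
            raise ValueError("dominant clone would be empty")
        if self.clonal_distribution not in ("zipf", "uniform"):
            raise ValueError(f"unknown clonal_distribution: "
                             f"{self.clonal_distribution!r}")
        if "Post" not in self.sample_tags:
            raise ValueError("sample_tags must include 'Post' (dominant-clone "
                             "sample)")
        if self.n_clonotypes < 2 or self.n_gd_clonotypes < 1:
            raise ValueError("need >= 2 αβ and >= 1 γδ clonotypes")
        n_dom = int(round(self.dominant_fraction * self.n_ab_cells))
        n_rest = self.n_ab_cells - n_dom
        if n_rest > (self.n_clonotypes - 1) * max(n_dom - 1, 1):
            raise ValueError(
                f"{n_rest} non-dominant αβ cells cannot be spread over "
                f"{self.n_clonotypes - 1} clones while keeping each smaller "
                f"than the dominant clone ({n_dom} cells); raise "
                "n_clonotypes or dominant_fraction")


@dataclass(frozen=True)
class Clonotype:
    """Ground-truth receptor: two chains with scaffold, CDR3 and gene calls."""

    tcr_type: str
    loci: tuple[str, str]
    sequences: tuple[str, str]
    cdr3s: tuple[str, str]
    v_calls: tuple[str, str]
    d_calls: tuple[str, str]
    j_calls: tuple[str, str]

    @property
    def contig(self) -> str:
        return (f"{self.loci[0]}:{self.sequences[0]}{CONTIG_SEP}"
                f"{self.loci[1]}:{self.sequences[1]}")

    @property
    def cdr3_contig(self) -> str:
        return (f"{self.loci[0]}:{self.cdr3s[0]}{CONTIG_SEP}"
                f"{self.loci[1]}:{self.cdr3s[1]}")


@dataclass
class GroundTruth:
    cells: pd.DataFrame  # cell_id, sample_tag, population, tcr_type, contigs...
    expected_clonotypes: pd.DataFrame
    expected_cdr3: pd.DataFrame
    dominant_contig: str
    dominant_n_cells: int
    n_unpaired_injected: int


@dataclass
class SimResult:
    airr: AirrTable
    expression: list[ExpressionMatrix]  # one per sample tag, in tag order
    truth: GroundTruth
    config: SimConfig


def _random_chain(rng: np.random.Generator, locus: str) -> tuple[str, str]:
    """One chain: (full sequence starting at M with an embedded canonical
    C...F CDR3, the CDR3 itself)."""
    def draw(n: int) -> str:
        return "".join(rng.choice(list(_AA_NO_M), size=n))

    cdr3 = "C" + draw(int(rng.integers(6, 11))) + "F"
    seq = "M" + draw(int(rng.integers(8, 15))) + cdr3 + draw(int(rng.integers(4, 9)))
    return seq, cdr3


def _random_clonotype(rng: np.random.Generator, tcr_type: str,
                      existing: set[str]) -> Clonotype:
    loci = ("TRA", "TRB") if tcr_type == "AB" else ("TRG", "TRD")
    while True:
        chains = [_random_chain(rng, loc) for loc in loci]
        calls = []
        for loc in loci:
            vocab = GENE_VOCAB[loc]
            v = str(rng.choice(vocab["V"])) + "*01"
            d = (str(rng.choice(vocab["D"])) + "*01") if vocab["D"] else ""
            j = str(rng.choice(vocab["J"])) + "*01"
            calls.append((v, d, j))
        ct = Clonotype(
            tcr_type=tcr_type, loci=loci,
            sequences=(chains[0][0], chains[1][0]),
            cdr3s=(chains[0][1], chains[1][1]),
            v_calls=(calls[0][0], calls[1][0]),
            d_calls=(calls[0][1], calls[1][1]),
            j_calls=(calls[0][2], calls[1][2]),
        )
        if ct.contig not in existing:
            existing.add(ct.contig)
            return ct


def _utr_prefix(rng: np.random.Generator) -> str:
    """A pseudo-translated 5'-UTR: random residues around 1-2 stop codons,
    with no methionine after the final stop, so trimming recovers the
    original chain exactly."""
    def draw(n: int) -> str:
        return "".join(rng.choice(list(_AA_NO_M), size=n))

    n_stops = int(rng.integers(1, 3))
    parts = []
    for _ in range(n_stops):
        parts.append(draw(int(rng.integers(2, 6))) + "*")
    return "".join(parts)


def _clone_sizes(rng: np.random.Generator, n_cells: int, n_clones: int,
                 distribution: str, shape: float,
                 max_size: int | None = None) -> np.ndarray:
    if n_clones == 0 or n_cells == 0:
        return np.zeros(max(n_clones, 0), dtype=int)
    if distribution == "uniform":
        weights = np.ones(n_clones)
    else:
        weights = 1.0 / np.arange(1, n_clones + 1) ** shape
    assignment = rng.choice(n_clones, size=n_cells, p=weights / weights.sum())
    sizes = np.bincount(assignment, minlength=n_clones)
    if max_size is not None:
        # keep the planted dominant clone the unique largest: spill any
        # excess over the cap into the currently smallest clones
        if n_cells > n_clones * max_size:
            raise ValueError(
                f"{n_cells} cells cannot fit {n_clones} clones of <= "
                f"{max_size} cells; the dominant clone would be overtaken")
        while sizes.max() > max_size:
            big = int(sizes.argmax())
            excess = int(sizes[big] - max_size)
            sizes[big] = max_size
            for _ in range(excess):
                sizes[int(sizes.argmin())] += 1
    return sizes


def simulate(config: SimConfig | None = None) -> SimResult:
    """Generate the full in-memory dataset: AIRR table, per-sample
    expression matrices and ground truth."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    rates = config.artifact_rates

    existing: set[str] = set()
    ab_pool = [_random_clonotype(rng, "AB", existing)
               for _ in range(config.n_clonotypes)]
    gd_pool = [_random_clonotype(rng, "GD", existing)
               for _ in range(config.n_gd_clonotypes)]

    n_dom = int(round(config.dominant_fraction * config.n_ab_cells))
    dominant = ab_pool[0]
    n_rest = config.n_ab_cells - n_dom
    rest_sizes = _clone_sizes(rng, n_rest, config.n_clonotypes - 1,
                              config.clonal_distribution, config.zipf_shape,
                              max_size=max(n_dom - 1, 1))
    gd_sizes = _clone_sizes(rng, config.n_gd_cells, config.n_gd_clonotypes,
                            "uniform", 1.0)

    # ---- per-cell assignments -------------------------------------------
    cells: list[dict] = []

    def add_cell(clone: Clonotype | None, population: str, tag: str) -> None:
        cells.append({
            "cell_id": f"CELL{len(cells):05d}",
            "sample_tag": tag,
            "population": population,
            "clone": clone,
        })

    tags = list(config.sample_tags)
    for _ in range(n_dom):
        add_cell(dominant, "ab_dominant", "Post")
    for k, size in enumerate(rest_sizes):
        clone = ab_pool[k + 1]
        for _ in range(size):
            pop = "ab_cd4" if rng.random() < config.cd4_fraction else "ab_cd8"
            add_cell(clone, pop, tags[int(rng.integers(len(tags)))])
    for k, size in enumerate(gd_sizes):
        for _ in range(size):
            add_cell(gd_pool[k], "gd", tags[int(rng.integers(len(tags)))])
    for _ in range(config.n_b_cells):
        add_cell(None, "b", tags[int(rng.integers(len(tags)))])

    # ---- artifact selection ---------------------------------------------
    t_cell_idx = [i for i, c in enumerate(cells) if c["clone"] is not None]
    n_unpaired = int(round(rates.unpaired * len(t_cell_idx)))
    unpaired_idx = set(
        rng.choice(t_cell_idx, size=n_unpaired, replace=False).tolist()
    ) if n_unpaired else set()

    # ---- AIRR rows -------------------------------------------------------
    airr_rows: list[dict] = []

    def chain_row(cell: dict, locus: str, seq: str, cdr3: str, v: str,
                  d: str, j: str, umi: int, c_call: str) -> dict:
        if rng.random() < rates.missing_c_call:
            c_call = ""
        if rng.random() < rates.utr:
            seq = _utr_prefix(rng) + seq
        return {
            "cell_id": cell["cell_id"], "locus": locus, "v_call": v,
            "d_call": d, "j_call": j, "c_call": c_call,
            "productive": "T", "sequence_aa": seq, "cdr3_aa": cdr3,
            "duplicate_count": umi,
        }

    for i, cell in enumerate(cells):
        clone = cell["clone"]
        if clone is None:  # B cell: an IGH and an IGK contaminant row
            for locus in ("IGH", "IGK"):
                vocab = GENE_VOCAB[locus]
                seq, cdr3 = _random_chain(rng, locus)
                airr_rows.append(chain_row(
                    cell, locus, seq, cdr3,
                    str(rng.choice(vocab["V"])) + "*01",
                    (str(rng.choice(vocab["D"])) + "*01") if vocab["D"] else "",
                    str(rng.choice(vocab["J"])) + "*01",
                    int(rng.integers(1, 5)), locus + "C",
                ))
            continue

        drop_locus = clone.loci[int(rng.integers(2))] if i in unpaired_idx else None
        for k, locus in enumerate(clone.loci):
            if locus == drop_locus:
                continue
            umi = int(rng.poisson(8)) + 2
            airr_rows.append(chain_row(
                cell, locus, clone.sequences[k], clone.cdr3s[k],
                clone.v_calls[k], clone.d_calls[k], clone.j_calls[k],
                umi, DEFAULT_C_CALLS[locus],
            ))
            if rng.random() < rates.multiplet:
                alt_seq, alt_cdr3 = _random_chain(rng, locus)
                airr_rows.append(chain_row(
                    cell, locus, alt_seq, alt_cdr3,
                    clone.v_calls[k], clone.d_calls[k], clone.j_calls[k],
                    1, DEFAULT_C_CALLS[locus],  # UMI 1 < true chain's >= 2
                ))

    airr_df = pd.DataFrame(airr_rows)

    # ---- expression ------------------------------------------------------
    genes = list(DEFAULT_MARKER_PANEL)
    theta = config.nb_dispersion
    matrices: list[ExpressionMatrix] = []
    for tag in tags:
        idx = [i for i, c in enumerate(cells) if c["sample_tag"] == tag]
        counts = np.zeros((len(genes), len(idx)), dtype=np.int64)
        for gi, gene in enumerate(genes):
            mu = np.array([DEFAULT_MARKER_PANEL[gene][cells[i]["population"]]
                           for i in idx])
            lam = rng.gamma(shape=theta, scale=mu / theta)
            counts[gi] = rng.poisson(lam)
        zero_total = counts.sum(axis=0) == 0
        counts[genes.index("PTPRC"), zero_total] = 1  # QC floor: no empty cells
        matrices.append(ExpressionMatrix(
            counts=sp.csr_matrix(counts),
            feature_ids=[f"ENSG-{g}" for g in genes],
            feature_names=genes,
            barcodes=[cells[i]["cell_id"] for i in idx],
            sample_tags=[tag] * len(idx),
        ))

    # ---- ground truth ----------------------------------------------------
    truth_rows = []
    for i, cell in enumerate(cells):
        clone = cell["clone"]
        truth_rows.append({
            "cell_id": cell["cell_id"],
            "sample_tag": cell["sample_tag"],
            "population": cell["population"],
            "tcr_type": clone.tcr_type if clone else "",
            "clonotype_contig": clone.contig if clone else "",
            "cdr3_contig": clone.cdr3_contig if clone else "",
            "is_unpaired": i in unpaired_idx,
        })
    truth_cells = pd.DataFrame(truth_rows)

    paired_mask = (truth_cells["clonotype_contig"] != "") & ~truth_cells["is_unpaired"]
    expected_clono = _expected_table(truth_cells[paired_mask], "clonotype_contig")
    expected_cdr3 = _expected_table(truth_cells[paired_mask], "cdr3_contig")

    truth = GroundTruth(
        cells=truth_cells,
        expected_clonotypes=expected_clono,
        expected_cdr3=expected_cdr3,
        dominant_contig=dominant.contig,
        dominant_n_cells=int(
            ((truth_cells["clonotype_contig"] == dominant.contig)
             & ~truth_cells["is_unpaired"]).sum()),
        n_unpaired_injected=n_unpaired,
    )
    return SimResult(airr=AirrTable(df=airr_df.rename(
        columns={"duplicate_count": "umi_count"}).assign(
            productive=lambda d: d["productive"] == "T")),
        expression=matrices, truth=truth, config=config)


def _expected_table(cells: pd.DataFrame, key: str) -> pd.DataFrame:
    counter: Counter[tuple[str, str]] = Counter(
        zip(cells[key], cells["tcr_type"]))
    rows = [{"contig": contig, "hash": assign_hash(contig),
             "tcr_type": tcr_type, "n_cells": n}
            for (contig, tcr_type), n in counter.items()]
    rows.sort(key=lambda r: (-r["n_cells"], r["contig"]))
    return pd.DataFrame(rows, columns=["contig", "hash", "tcr_type", "n_cells"])


def simulate_dataset(config: SimConfig, out: str | Path) -> SimResult:
    """Generate and write the dataset to disk: one expression triplet
    directory per sample, the AIRR TSV and the ground truth (TSV + JSON)."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    result = simulate(config)

    for tag, matrix in zip(config.sample_tags, result.expression):
        write_feature_matrix(matrix, out / f"sample_{tag}")

    airr_out = result.airr.df.copy()
    airr_out["productive"] = np.where(airr_out["productive"], "T", "F")
    airr_out = airr_out.rename(columns={"umi_count": "duplicate_count"})
    airr_out.to_csv(out / "Dominant_Contigs_AIRR.tsv", sep="\t", index=False)

    result.truth.cells.to_csv(out / "truth_cells.tsv", sep="\t", index=False)
    result.truth.expected_clonotypes.to_csv(
        out / "truth_clonotypes.tsv", sep="\t", index=False)
    result.truth.expected_cdr3.to_csv(
        out / "truth_cdr3.tsv", sep="\t", index=False)
    with open(out / "truth_summary.json", "w") as fh:
        json.dump({
            "dominant_contig": result.truth.dominant_contig,
            "dominant_n_cells": result.truth.dominant_n_cells,
            "n_unpaired_injected": result.truth.n_unpaired_injected,
            "seed": config.seed,
        }, fh, indent=2, sort_keys=True)
    return result
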