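"""Chain cleaning, pairing and clonotype quantification.

A clonotype here is the full-length paired amino-acid contig of both
receptor chains of one cell, written ``TRA:<aa>___TRB:<aa>`` for αβ cells
and ``TRG:<aa>___TRD:<aa>`` for γδ cells. Cells sharing an identical contig
belong to one clonotype; counting cells per unique contig quantifies clonal
expansion.

Cleaning steps before pairing:

* immunoglobulin rows (B-cell contamination) are removed;
* unproductive rearrangements and low-UMI chains are filtered;
* pseudo-translated 5'-UTR prefixes are trimmed to the first methionine
  after the last upstream stop codon;
* missing constant-region calls are restored from per-locus defaults
  (e.g. TRBC1 for β chains), optionally extending truncated sequences from
  a canonical constant-region table.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .io_matrix import AA_ALPHABET, IG_LOCI, AirrTable, ChainRecord

logger = logging.getLogger(__name__)

CONTIG_SEP = "___"

#: fixed chain order within a contig, per receptor type
CHAIN_ORDER = {"AB": ("TRA", "TRB"), "GD": ("TRG", "TRD")}

#: default constant-region label per TR locus
DEFAULT_C_CALLS = {"TRA": "TRAC", "TRB": "TRBC1", "TRG": "TRGC1", "TRD": "TRDC"}


@dataclass(frozen=True)
class ConstantRegionTable:
    """Per-locus default c_call labels plus optional canonical constant
    amino-acid sequences keyed by c_call, used for suffix extension of
    truncated chains."""

    defaults: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_C_CALLS))
    canonical_suffixes: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class PairedCell:
    """One cell's retained chain pair with derived contigs and hash ids."""

    cell_id: str
    tcr_type: str  # "AB" or "GD"
    chain_1: ChainRecord
    chain_2: ChainRecord
    clonotype_contig: str
    clonotype_hash: str
    cdr3_contig: str  # empty when either chain lacks a CDR3 annotation
    cdr3_hash: str


def filter_ig(airr: AirrTable) -> AirrTable:
    """Remove immunoglobulin (IGH/IGK/IGL) rows."""
    mask = airr.df["locus"].isin(IG_LOCI)
    if mask.any():
        logger.info("removed %d immunoglobulin rows", int(mask.sum()))
    return AirrTable(df=airr.df[~mask].reset_index(drop=True))


def filter_productive(airr: AirrTable, min_umi: int = 1) -> AirrTable:
    """Keep productive rearrangements with umi_count >= min_umi."""
    keep = airr.df["productive"] & (airr.df["umi_count"] >= min_umi)
    return AirrTable(df=airr.df[keep].reset_index(drop=True))


def trim_pseudo_utr(seq: str) -> str | None:
    """Trim a pseudo-translated 5'-UTR prefix from a chain sequence.

    The mature chain starts at the first methionine after the last stop
    codon; a 5'-UTR may pseudo-translate through several stops, so the last
    one anchors the trim. Without any stop, the sequence is trimmed to its
    first methionine. Returns None (drop) when no qualifying methionine
    exists.
    """
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise ValueError(f"invalid amino-acid characters: {sorted(bad)}")
    start = seq.rfind("*") + 1  # 0 when no stop present
    m = seq.find("M", start)
    if m == -1:
        return None
    return seq[m:]


def restore_constant_region(
    record: ChainRecord, table: ConstantRegionTable | None = None
) -> ChainRecord:
    """Restore a missing/ambiguous c_call from the locus default and, when a
    canonical constant sequence is configured, extend a truncated chain by
    the missing constant-region tail."""
    table = table or ConstantRegionTable()
    c_call = record.c_call
    if not c_call or "," in c_call:
        default = table.defaults.get(record.locus)
        if default:
            logger.debug("restored c_call %s for cell %s (%s)",
                         default, record.cell_id, record.locus)
            c_call = default

    seq = record.sequence_aa
    canonical = table.canonical_suffixes.get(c_call, "")
    if canonical and seq and not seq.endswith(canonical):
        # longest suffix of the chain matching a prefix of the canonical constant
        max_k = min(len(seq), len(canonical) - 1)
        for k in range(max_k, 0, -1):
            if seq.endswith(canonical[:k]):
                seq = seq + canonical[k:]
                logger.debug("extended %s chain of cell %s by %d canonical "
                             "constant residues", record.locus,
                             record.cell_id, len(canonical) - k)
                break

    if c_call == record.c_call and seq == record.sequence_aa:
        return record
    return replace(record, c_call=c_call, sequence_aa=seq)


def select_dominant_chain(records: list[ChainRecord]) -> ChainRecord:
    """Resolve a duplicate-locus multiplet to one chain: highest UMI count,
    ties broken by lexicographically smallest amino-acid sequence."""
    if not records:
        raise ValueError("no chain records")
    return min(records, key=lambda r: (-r.umi_count, r.sequence_aa))


def assign_hash(contig: str) -> str:
    """Stable numeric identifier for a contig: the first 8 bytes of its
    SHA-256 digest as an unsigned big-endian decimal. Equal contigs hash
    equal across runs and platforms."""
    if not contig:
        raise ValueError("empty contig")
    digest = hashlib.sha256(contig.encode("utf-8")).digest()
    return str(int.from_bytes(digest[:8], "big"))


def _make_contig(locus_1: str, seq_1: str, locus_2: str, seq_2: str) -> str:
    return f"{locus_1}:{seq_1}{CONTIG_SEP}{locus_2}:{seq_2}"


@dataclass
class PairingReport:
    n_cells_in: int = 0
    n_paired_ab: int = 0
    n_paired_gd: int = 0
    n_unpaired_dropped: int = 0
    n_dual_type: int = 0  # cells qualifying for both AB and GD
    n_multiplet_resolved: int = 0


def clean_airr(
    airr: AirrTable,
    min_umi: int = 1,
    constant_table: ConstantRegionTable | None = None,
) -> AirrTable:
    """Full chain-cleaning pass: IG removal, productive/UMI filter, 5'-UTR
    trimming (rows with no recoverable start are dropped) and constant-region
    restoration."""
    airr = filter_productive(filter_ig(airr), min_umi=min_umi)
    df = airr.df.copy()

    trimmed = df["sequence_aa"].map(trim_pseudo_utr)
    dropped = trimmed.isna()
    if dropped.any():
        logger.info("dropped %d chains with no methionine after the last stop",
                    int(dropped.sum()))
    df = df[~dropped].copy()
    df["sequence_aa"] = trimmed[~dropped]

    table = constant_table or ConstantRegionTable()
    restored_c, restored_seq = [], []
    for row in df.itertuples(index=False):
        rec = restore_constant_region(
            ChainRecord(
                cell_id=row.cell_id, locus=row.locus, v_call=row.v_call,
                d_call=row.d_call, j_call=row.j_call, c_call=row.c_call,
                productive=row.productive, sequence_aa=row.sequence_aa,
                cdr3_aa=row.cdr3_aa, umi_count=row.umi_count,
            ),
            table,
        )
        restored_c.append(rec.c_call)
        restored_seq.append(rec.sequence_aa)
    df["c_call"] = restored_c
    df["sequence_aa"] = restored_seq
    return AirrTable(df=df.reset_index(drop=True))


def pair_chains(airr: AirrTable) -> tuple[list[PairedCell], PairingReport]:
    """Pair one dominant chain per locus per cell into αβ or γδ receptors.

    Cells with both a complete αβ and a complete γδ pair get the type with
    the larger summed UMI count (tie: αβ) and are flagged. Cells without a
    complete pair are dropped. Output order is deterministic (sorted by
    cell id) and independent of input row order.
    """
    report = PairingReport()
    paired: list[PairedCell] = []

    df = airr.df
    by_cell: dict[str, dict[str, list[ChainRecord]]] = {}
    for row in df.itertuples(index=False):
        rec = ChainRecord(
            cell_id=row.cell_id, locus=row.locus, v_call=row.v_call,
            d_call=row.d_call, j_call=row.j_call, c_call=row.c_call,
            productive=row.productive, sequence_aa=row.sequence_aa,
            cdr3_aa=row.cdr3_aa, umi_count=row.umi_count,
        )
        by_cell.setdefault(rec.cell_id, {}).setdefault(rec.locus, []).append(rec)

    report.n_cells_in = len(by_cell)
    for cell_id in sorted(by_cell):
        loci = by_cell[cell_id]
        dominant: dict[str, ChainRecord] = {}
        for locus, recs in loci.items():
            if len(recs) > 1:
                report.n_multiplet_resolved += 1
            dominant[locus] = select_dominant_chain(recs)

        has_ab = "TRA" in dominant and "TRB" in dominant
        has_gd = "TRG" in dominant and "TRD" in dominant
        if not has_ab and not has_gd:
            report.n_unpaired_dropped += 1
            continue
        if has_ab and has_gd:
            report.n_dual_type += 1
            ab_umi = dominant["TRA"].umi_count + dominant["TRB"].umi_count
            gd_umi = dominant["TRG"].umi_count + dominant["TRD"].umi_count
            tcr_type = "GD" if gd_umi > ab_umi else "AB"
            logger.info("cell %s has both αβ and γδ pairs; assigned %s "
                        "(Σumi αβ=%d, γδ=%d)", cell_id, tcr_type, ab_umi, gd_umi)
        else:
            tcr_type = "AB" if has_ab else "GD"

        l1, l2 = CHAIN_ORDER[tcr_type]
        c1, c2 = dominant[l1], dominant[l2]
        contig = _make_contig(l1, c1.sequence_aa, l2, c2.sequence_aa)
        if c1.cdr3_aa and c2.cdr3_aa:
            cdr3_contig = _make_contig(l1, c1.cdr3_aa, l2, c2.cdr3_aa)
            cdr3_hash = assign_hash(cdr3_contig)
        else:
            cdr3_contig, cdr3_hash = "", ""
        paired.append(PairedCell(
            cell_id=cell_id, tcr_type=tcr_type, chain_1=c1, chain_2=c2,
            clonotype_contig=contig, clonotype_hash=assign_hash(contig),
            cdr3_contig=cdr3_contig, cdr3_hash=cdr3_hash,
        ))
        if tcr_type == "AB":
            report.n_paired_ab += 1
        else:
            report.n_paired_gd += 1
    return paired, report


def count_clonotypes(paired: list[PairedCell]) -> pd.DataFrame:
    """Cells per unique clonotype contig.

    Returns a DataFrame with columns contig, hash, tcr_type, n_cells,
    member_cell_ids, sorted by n_cells descending then contig ascending.
    """
    return _count_by(paired, key="clonotype_contig", hash_key="clonotype_hash")


def _count_by(paired: list[PairedCell], key: str, hash_key: str) -> pd.DataFrame:
    groups: dict[str, dict] = {}
    for pc in paired:
        contig = getattr(pc, key)
        if not contig:
            continue
        g = groups.setdefault(contig, {
            "contig": contig,
            "hash": getattr(pc, hash_key),
            "tcr_type": pc.tcr_type,
            "n_cells": 0,
            "member_cell_ids": [],
        })
        g["n_cells"] += 1
        g["member_cell_ids"].append(pc.cell_id)
    rows = sorted(groups.values(), key=lambda g: (-g["n_cells"], g["contig"]))
    for g in rows:
        g["member_cell_ids"] = sorted(g["member_cell_ids"])
    return pd.DataFrame(
        rows, columns=["contig", "hash", "tcr_type", "n_cells", "member_cell_ids"]
    )
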