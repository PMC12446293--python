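"""CDR3-type quantification and summary plots.

A CDR3-type is the coarser grouping of paired cells by the CDR3 amino-acid
sequences of both chains only (``TRA:<cdr3>___TRB:<cdr3>``), ignoring the
rest of the contig. Every clonotype maps to exactly one CDR3-type, so the
CDR3-type partition is a coarsening of the clonotype partition.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .clonotype import PairedCell, _count_by

logger = logging.getLogger(__name__)


def count_cdr3(paired: list[PairedCell]) -> pd.DataFrame:
    """Cells per unique paired-CDR3 contig.

    Cells whose pair lacks a CDR3 annotation on either chain carry an empty
    cdr3_contig and are excluded (logged); they still count toward
    full-length clonotypes.
    """
    n_excluded = sum(1 for pc in paired if not pc.cdr3_contig)
    if n_excluded:
        logger.info("excluded %d paired cells without a CDR3 on both chains",
                    n_excluded)
    return _count_by(paired, key="cdr3_contig", hash_key="cdr3_hash")


def cdr3_summary_plot(
    counts: pd.DataFrame, out: str | Path, top_n: int = 10
) -> Path | None:
    """Bar chart of cells per CDR3-type (labelled by hash) with an inset pie
    of the ``top_n`` dominant types; everything beyond top_n is pooled into
    an "other" wedge."""
    out = Path(out)
    if counts.empty:
        logger.warning("no CDR3-types to plot; skipping %s", out)
        return None

    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(counts)), 5))
    ax.bar(range(len(counts)), counts["n_cells"], color="#4472c4")
    ax.set_xticks(range(len(counts)))
    ax.set_xticklabels(counts["hash"], rotation=90, fontsize=6)
    ax.set_xlabel("CDR3-type (hash id)")
    ax.set_ylabel("cells")
    ax.set_title("CDR3-type distribution")

    head = counts.head(top_n)
    sizes = head["n_cells"].tolist()
    labels = head["hash"].tolist()
    rest = int(counts["n_cells"].iloc[top_n:].sum())
    if rest > 0:
        sizes.append(rest)
        labels.append("other")
    inset = fig.add_axes((0.55, 0.45, 0.4, 0.45))
    inset.pie(sizes, labels=labels, textprops={"fontsize": 6},
              counterclock=False, startangle=90)

    fig.savefig(out, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return out
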