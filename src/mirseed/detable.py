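"""Differential-expression tables and threshold partitioning.

Microarray DE results arrive as per-gene signed fold-change ratios (the
convention where -2.04 means "half as much in mutant, expressed as a ratio
with magnitude >= 1") or as log2 fold changes, plus raw and optionally
FDR-adjusted p-values.  Gene lists for enrichment are formed by thresholds
of the form "uncorrected P < 0.05, fold change <= -1.05": strict on p,
inclusive on the fold-change magnitude.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DeRecord",
    "Thresholds",
    "Partition",
    "ratio_to_log2fc",
    "log2fc_to_ratio",
    "load_de_table",
    "partition",
    "records_to_frame",
]


def ratio_to_log2fc(signed_ratio: float) -> float:
    """Signed fold-change ratio -> log2 fold change.

    Ratios encode direction in the sign and magnitude as |r| >= 1, so
    r >= 1 maps to log2(r) and r <= -1 to -log2(-r).  Values with |r| < 1
    (including 0) are ambiguous in this encoding and rejected.
    """
    if abs(signed_ratio) < 1:
        raise ValueError(
            f"signed ratio {signed_ratio!r} has magnitude < 1; "
            "the signed-ratio encoding requires |r| >= 1"
        )
    if signed_ratio >= 1:
        return math.log2(signed_ratio)
    return -math.log2(-signed_ratio)


def log2fc_to_ratio(log2fc: float) -> float:
    """Inverse of :func:`ratio_to_log2fc` (exact to machine precision)."""
    if log2fc >= 0:
        return 2.0**log2fc
    return -(2.0**-log2fc)


@dataclass(frozen=True)
class DeRecord:
    """One gene's differential-expression summary."""

    gene_id: str
    signed_ratio: float
    log2fc: float
    p_raw: float
    p_adj: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("DE record must have a gene_id")
        if not 0 <= self.p_raw <= 1:
            raise ValueError(f"{self.gene_id}: p_raw {self.p_raw} outside [0, 1]")
        if self.p_adj is not None and not 0 <= self.p_adj <= 1:
            raise ValueError(f"{self.gene_id}: p_adj {self.p_adj} outside [0, 1]")

    @classmethod
    def from_ratio(
        cls,
        gene_id: str,
        signed_ratio: float,
        p_raw: float,
        p_adj: Optional[float] = None,
    ) -> "DeRecord":
        return cls(gene_id, signed_ratio, ratio_to_log2fc(signed_ratio), p_raw, p_adj)

    @classmethod
    def from_log2fc(
        cls,
        gene_id: str,
        log2fc: float,
        p_raw: float,
        p_adj: Optional[float] = None,
    ) -> "DeRecord":
        return cls(gene_id, log2fc_to_ratio(log2fc), log2fc, p_raw, p_adj)


@dataclass(frozen=True)
class Thresholds:
    """Cutoffs defining the up/down gene sets.

    ``p_raw_max`` is compared strictly (P < cutoff); ``fc_min_abs_ratio`` is
    the minimum |signed ratio| and is compared inclusively.  With
    ``use_adjusted`` the FDR-adjusted p is thresholded instead of the raw p.
    """

    p_raw_max: float = 0.05
    fc_min_abs_ratio: float = 1.05
    use_adjusted: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.p_raw_max <= 1:
            raise ValueError("p_raw_max must be in (0, 1]")
        if self.fc_min_abs_ratio < 1:
            raise ValueError("fc_min_abs_ratio must be >= 1")


@dataclass(frozen=True)
class Partition:
    """Up/down/background gene sets induced by thresholds."""

    up: FrozenSet[str]
    down: FrozenSet[str]
    background: FrozenSet[str]

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down gene sets overlap")
        if not (self.up | self.down) <= self.background:
            raise ValueError("up/down genes must be contained in the background")


def partition(records: Sequence[DeRecord], thresholds: Thresholds) -> Partition:
    """Split genes into up/down/background sets by the thresholds."""
    if not records:
        raise ValueError("cannot partition an empty record list")
    up, down = set(), set()
    for rec in records:
        p = rec.p_adj if thresholds.use_adjusted else rec.p_raw
        if p is None:
            raise ValueError(
                f"{rec.gene_id}: use_adjusted requested but p_adj is missing"
            )
        if p < thresholds.p_raw_max:
            if rec.signed_ratio <= -thresholds.fc_min_abs_ratio:
                down.add(rec.gene_id)
            elif rec.signed_ratio >= thresholds.fc_min_abs_ratio:
                up.add(rec.gene_id)
    return Partition(
        up=frozenset(up),
        down=frozenset(down),
        background=frozenset(r.gene_id for r in records),
    )


def load_de_table(
    path,
    column_map: Dict[str, str],
    fc_kind: str = "ratio",
) -> List[DeRecord]:
    """Read a tab-separated DE table into records.

    ``column_map`` must name the ``gene``, ``fc`` and ``p`` columns and may
    name ``padj``.  ``fc_kind`` says whether the fold-change column holds
    signed ratios or log2 fold changes.  Rows without a gene id are dropped
    (count logged); duplicate gene ids keep the row with the smallest raw p,
    which collapses probesets onto genes.
    """
    if fc_kind not in ("ratio", "log2"):
        raise ValueError("fc_kind must be 'ratio' or 'log2'")
    for key in ("gene", "fc", "p"):
        if key not in column_map:
            raise ValueError(f"column_map must name the {key!r} column")
    table = pd.read_csv(path, sep="\t", dtype=str)
    for key in ("gene", "fc", "p") + (("padj",) if "padj" in column_map else ()):
        if column_map[key] not in table.columns:
            raise ValueError(
                f"column {column_map[key]!r} (mapped as {key!r}) not found in {path}"
            )

    gene_col = table[column_map["gene"]]
    missing = gene_col.isna() | (gene_col.astype(str).str.strip() == "")
    if missing.any():
        logger.info("dropped %d rows with missing gene id", int(missing.sum()))
        table = table[~missing]

    def numeric(key: str) -> pd.Series:
        raw = table[column_map[key]]
        values = pd.to_numeric(raw, errors="coerce")
        bad = values.isna() & raw.notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(
                f"unparseable numeric value {raw[bad.idxmax()]!r} in column "
                f"{column_map[key]!r} at file row {row}"
            )
        return values

    fc = numeric("fc")
    p = numeric("p")
    padj = numeric("padj") if "padj" in column_map else None

    records: Dict[str, DeRecord] = {}
    n_dup = 0
    for i in table.index:
        gene = str(table.at[i, column_map["gene"]]).strip()
        p_adj = None if padj is None or pd.isna(padj[i]) else float(padj[i])
        if fc_kind == "ratio":
            rec = DeRecord.from_ratio(gene, float(fc[i]), float(p[i]), p_adj)
        else:
            rec = DeRecord.from_log2fc(gene, float(fc[i]), float(p[i]), p_adj)
        if gene in records:
            n_dup += 1
            if rec.p_raw < records[gene].p_raw:
                records[gene] = rec
        else:
            records[gene] = rec
    if n_dup:
        logger.info("collapsed %d duplicate gene rows by min raw p", n_dup)
    return list(records.values())


def records_to_frame(records: Sequence[DeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "signed_ratio": [r.signed_ratio for r in records],
            "log2fc": [r.log2fc for r in records],
            "p_raw": [r.p_raw for r in records],
            "p_adj": [r.p_adj for r in records],
        }
    )
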