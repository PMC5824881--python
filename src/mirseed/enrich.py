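"""Per-family enrichment/depletion tests and cross-study overlap testing.

Each miRNA family is tested with a 2x2 table over the gene background:

====================  ==============  ==================
                      in gene set     not in gene set
====================  ==============  ==================
>= 1 seed site        a               b
no seed site          c               d
====================  ==============  ==================

The reported statistics are the odds ratio (a*d)/(b*c) -- with the
Haldane-Anscombe +0.5 correction when any cell is zero -- and the two-sided
Fisher exact p-value (point-probability method: the sum of hypergeometric
probabilities of all tables with the observed margins that are no more
probable than the observed one).  Benjamini-Hochberg FDR is applied across
families separately within each direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, NamedTuple, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .detable import Partition
from .universe import SeedUniverse

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "EnrichmentRow",
    "OddsRatioResult",
    "OverlapResult",
    "make_contingency",
    "odds_ratio",
    "fisher_exact_two_sided",
    "bh_fdr",
    "enrich_all",
    "overlap_test",
    "rows_to_frame",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table of gene-set membership against seed-site presence."""

    a: int  # in set, >= 1 site
    b: int  # not in set, >= 1 site
    c: int  # in set, no site
    d: int  # not in set, no site

    def __post_init__(self) -> None:
        for name in "abcd":
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 0:
                raise ValueError(f"cell {name}={value!r} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


class OddsRatioResult(NamedTuple):
    """Odds ratio, flagged when the zero-cell +0.5 correction was applied."""

    value: float
    corrected: bool

    def __float__(self) -> float:  # lets callers round()/compare directly
        return self.value


def odds_ratio(table: ContingencyTable) -> OddsRatioResult:
    """(a*d)/(b*c), Haldane-Anscombe corrected (+0.5 per cell) on zero cells."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return OddsRatioResult((a * d) / (b * c), True)
    return OddsRatioResult((a * d) / (b * c), False)


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p by the point-probability method."""
    return float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])


def bh_fdr(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def make_contingency(
    gene_set: Iterable[str], universe: SeedUniverse, family_key: str
) -> ContingencyTable:
    """Count the 2x2 table for one family's gene-level site presence."""
    gene_set = set(gene_set)
    known = set(universe.genes)
    offenders = sorted(gene_set - known)
    if offenders:
        raise ValueError(
            f"genes absent from the universe: {offenders[:10]}"
            + ("..." if len(offenders) > 10 else "")
        )
    with_sites = universe.genes_with_sites(family_key)
    a = len(gene_set & with_sites)
    b = len(with_sites - gene_set)
    c = len(gene_set) - a
    d = len(known) - len(gene_set) - b
    return ContingencyTable(a=a, b=b, c=c, d=d)


@dataclass(frozen=True)
class EnrichmentRow:
    """One family x direction test result."""

    family_key: str
    direction: str  # "down" (mutant < WT) or "up" (mutant > WT)
    table: ContingencyTable
    odds_ratio: float
    or_corrected: bool
    p_two_sided: float
    fdr: float


def enrich_all(part: Partition, universe: SeedUniverse) -> List[EnrichmentRow]:
    """Test every family against the down and up gene sets.

    BH-FDR is applied across families within each direction; rows come back
    sorted by (direction, fdr ascending).  An empty gene set is legal and
    produces p = 1 rows (warned, not an error).
    """
    if not part.background <= set(universe.genes):
        missing = sorted(part.background - set(universe.genes))
        raise ValueError(f"background genes absent from universe: {missing[:10]}")
    rows: List[EnrichmentRow] = []
    for direction, gene_set in (("down", part.down), ("up", part.up)):
        if not gene_set:
            logger.warning("empty gene set for direction %r", direction)
        tables = [
            make_contingency(gene_set, universe, family)
            for family in universe.families
        ]
        p_values = [fisher_exact_two_sided(t) for t in tables]
        fdrs = bh_fdr(p_values)
        block = [
            EnrichmentRow(
                family_key=family,
                direction=direction,
                table=t,
                odds_ratio=odds_ratio(t).value,
                or_corrected=odds_ratio(t).corrected,
                p_two_sided=p,
                fdr=f,
            )
            for family, t, p, f in zip(universe.families, tables, p_values, fdrs)
        ]
        block.sort(key=lambda r: (r.fdr, r.p_two_sided, r.family_key))
        rows.extend(block)
    return rows


def permutation_null_pvalues(
    universe: SeedUniverse,
    set_size: int,
    n_replicates: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-family Fisher p-values for random gene sets of a fixed size.

    Each replicate draws ``set_size`` genes uniformly without replacement
    from the universe and tests every family against that set, exactly the
    null that shuffling gene labels with the observed set size induces.
    Returns an array of shape (n_replicates, n_families).  Family tests
    within one replicate share a draw and are therefore correlated; treat
    the replicate, not the single test, as the independent unit.
    """
    genes = np.asarray(universe.genes, dtype=object)
    out = np.empty((n_replicates, len(universe.families)))
    for r in range(n_replicates):
        chosen = rng.choice(len(genes), size=set_size, replace=False)
        gene_set = set(genes[chosen])
        for j, family in enumerate(universe.families):
            out[r, j] = fisher_exact_two_sided(
                make_contingency(gene_set, universe, family)
            )
    return out


class OverlapResult(NamedTuple):
    table: ContingencyTable
    odds_ratio: OddsRatioResult
    p_two_sided: float


def overlap_test(
    n_a: int, n_b: int, n_both: int, n_universe: int
) -> OverlapResult:
    """Fisher test for the overlap of two gene lists drawn from one universe.

    ``n_a`` and ``n_b`` are the two list sizes, ``n_both`` their overlap and
    ``n_universe`` the number of genes interrogated by both studies.
    """
    if n_both > min(n_a, n_b):
        raise ValueError(
            f"overlap {n_both} exceeds a list size (n_a={n_a}, n_b={n_b})"
        )
    if n_a + n_b - n_both > n_universe:
        raise ValueError(
            f"lists cover {n_a + n_b - n_both} genes but the universe has "
            f"only {n_universe}"
        )
    table = ContingencyTable(
        a=n_both,
        b=n_a - n_both,
        c=n_b - n_both,
        d=n_universe - n_a - n_b + n_both,
    )
    return OverlapResult(table, odds_ratio(table), fisher_exact_two_sided(table))


def rows_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    """Long-format report with one row per family x direction."""
    return pd.DataFrame(
        {
            "family_key": [r.family_key for r in rows],
            "direction": [r.direction for r in rows],
            "a": [r.table.a for r in rows],
            "b": [r.table.b for r in rows],
            "c": [r.table.c for r in rows],
            "d": [r.table.d for r in rows],
            "odds_ratio": [r.odds_ratio for r in rows],
            "or_corrected": [r.or_corrected for r in rows],
            "p": [r.p_two_sided for r in rows],
            "fdr": [r.fdr for r in rows],
        }
    )
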