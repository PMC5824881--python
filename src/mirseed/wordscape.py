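"""Ranked-list sliding hypergeometric landscape over k-mer words in 3'UTRs.

Genes are ordered from most upregulated to most downregulated; at each
cutpoint the leading genes form a sample of k-mer positions drawn from the
whole transcriptome, and each word's count in that sample is scored against
Hypergeometric(N, K, n):

* N -- total k-mer positions over all genes,
* K -- global occurrences of the word,
* n -- k-mer positions in the leading set,
* k_obs -- occurrences of the word in the leading set.

The signed score is -log10 of the smaller tail: positive for enrichment
(P[X >= k_obs] smaller) and negative for depletion (P[X <= k_obs] smaller).
Overlapping occurrences all count; windows containing a non-ACGT letter
contribute neither occurrences nor positions.  This is an occurrence-level
statistic with no sequence-composition correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seeds import MatureMirna, collapse_families, seed_words
from .sites import UtrRecord

__all__ = [
    "WordCountIndex",
    "RankedGenes",
    "Landscape",
    "count_words",
    "mirna_word_panel",
    "landscape",
    "bonferroni_line",
]

_ACGT = frozenset("ACGT")


@dataclass
class WordCountIndex:
    """Per-gene word occurrence counts and valid k-mer position totals."""

    k: int
    per_gene_counts: Dict[str, Dict[str, int]] = field(repr=False)
    per_gene_positions: Dict[str, int] = field(repr=False)

    @property
    def genes(self) -> List[str]:
        return list(self.per_gene_positions)

    @property
    def total_positions(self) -> int:
        return sum(self.per_gene_positions.values())

    def total_count(self, word: str) -> int:
        return sum(counts.get(word, 0) for counts in self.per_gene_counts.values())

    @property
    def words(self) -> List[str]:
        seen: Dict[str, None] = {}
        for counts in self.per_gene_counts.values():
            for word in counts:
                seen.setdefault(word)
        return sorted(seen)


def count_words(
    utrs: Sequence[UtrRecord],
    k: int = 7,
    word_panel: Optional[Sequence[str]] = None,
) -> WordCountIndex:
    """Count overlapping k-mer occurrences per gene.

    With a ``word_panel`` only panel words are tallied (position totals still
    count every valid window); otherwise every observed word is tallied.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    panel = None if word_panel is None else frozenset(word_panel)
    per_gene_counts: Dict[str, Dict[str, int]] = {}
    per_gene_positions: Dict[str, int] = {}
    for utr in utrs:
        seq = utr.sequence
        counts: Dict[str, int] = {}
        positions = 0
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if set(window) - _ACGT:
                continue
            positions += 1
            if panel is None or window in panel:
                counts[window] = counts.get(window, 0) + 1
        per_gene_counts[utr.gene_id] = counts
        per_gene_positions[utr.gene_id] = positions
    return WordCountIndex(k=k, per_gene_counts=per_gene_counts,
                          per_gene_positions=per_gene_positions)


def mirna_word_panel(mirnas: Sequence[MatureMirna]) -> List[str]:
    """The deduplicated, sorted union of 7mer-m8 and 7mer-1A words.

    The heptamer prefix of each 8mer equals the family's 7mer-m8 word, so
    8mer sites add no new heptamers to the panel.
    """
    words = set()
    for members in collapse_families(mirnas).values():
        ws = seed_words(members[0])
        words.update(ws.heptamers)
    return sorted(words)


@dataclass(frozen=True)
class RankedGenes:
    """Gene ids ordered most-upregulated first.

    Build with :meth:`from_records` to rank by log2 fold change (descending,
    ties broken by stable input order).
    """

    gene_ids: tuple

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("ranked gene list contains duplicates")

    def __len__(self) -> int:
        return len(self.gene_ids)

    @classmethod
    def from_records(cls, records) -> "RankedGenes":
        order = sorted(
            range(len(records)), key=lambda i: -records[i].log2fc
        )  # sorted() is stable: ties keep input order
        return cls(tuple(records[i].gene_id for i in order))


@dataclass
class Landscape:
    """Signed -log10 hypergeometric p per (word, cutpoint)."""

    words: List[str]
    cutpoints: List[int]
    signed: np.ndarray = field(repr=False)  # shape (n_words, n_cutpoints)
    bonferroni: float = 0.0
    word_totals: Dict[str, int] = field(default_factory=dict)
    total_positions: int = 0

    def value(self, word: str, cutpoint: int) -> float:
        return float(
            self.signed[self.words.index(word), self.cutpoints.index(cutpoint)]
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (word, cutpoint, signed_log10_p)."""
        rows = []
        for i, word in enumerate(self.words):
            for j, cut in enumerate(self.cutpoints):
                rows.append((word, cut, self.signed[i, j]))
        return pd.DataFrame(rows, columns=["word", "cutpoint", "signed_log10_p"])


def default_cutpoints(n_genes: int) -> List[int]:
    """Every ceil(n_genes / 50) genes, up to and including n_genes."""
    step = math.ceil(n_genes / 50)
    cuts = list(range(step, n_genes + 1, step))
    if cuts[-1] != n_genes:
        cuts.append(n_genes)
    return cuts


def landscape(
    ranked: RankedGenes,
    index: WordCountIndex,
    cutpoints: Optional[Sequence[int]] = None,
    words: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> Landscape:
    """Compute the signed hypergeometric landscape along the ranking."""
    n_genes = len(ranked)
    if cutpoints is None:
        cutpoints = default_cutpoints(n_genes)
    cutpoints = list(cutpoints)
    for cut in cutpoints:
        if not 1 <= cut <= n_genes:
            raise ValueError(f"cutpoint {cut} outside 1..{n_genes}")
    for gene in ranked.gene_ids:
        if gene not in index.per_gene_positions:
            raise ValueError(f"ranked gene {gene!r} missing from the word index")
    word_list = sorted(words) if words is not None else index.words
    n_words = len(word_list)

    # per-gene counts in rank order -> cumulative counts at each cutpoint
    counts = np.zeros((n_words, n_genes), dtype=np.int64)
    positions = np.zeros(n_genes, dtype=np.int64)
    word_pos = {w: i for i, w in enumerate(word_list)}
    for j, gene in enumerate(ranked.gene_ids):
        positions[j] = index.per_gene_positions[gene]
        for word, count in index.per_gene_counts[gene].items():
            i = word_pos.get(word)
            if i is not None:
                counts[i, j] = count
    cum_counts = np.cumsum(counts, axis=1)
    cum_positions = np.cumsum(positions)

    N = int(cum_positions[-1])
    K = cum_counts[:, -1]
    cut_idx = np.array(cutpoints, dtype=np.int64) - 1
    n = cum_positions[cut_idx]  # leading-set positions per cutpoint
    k_obs = cum_counts[:, cut_idx]  # (n_words, n_cutpoints)

    signed = np.zeros((n_words, len(cutpoints)))
    for i in range(n_words):
        if K[i] == 0:
            continue  # absent word: flat zero by convention
        p_enrich = stats.hypergeom.sf(k_obs[i] - 1, N, int(K[i]), n)
        p_deplete = stats.hypergeom.cdf(k_obs[i], N, int(K[i]), n)
        enrich_side = p_enrich < p_deplete
        with np.errstate(divide="ignore"):
            signed[i] = np.where(
                enrich_side, -np.log10(p_enrich), np.log10(p_deplete)
            )
    return Landscape(
        words=word_list,
        cutpoints=cutpoints,
        signed=signed,
        bonferroni=bonferroni_line(max(n_words, 1), alpha),
        word_totals={w: int(K[i]) for i, w in enumerate(word_list)},
        total_positions=N,
    )


def bonferroni_line(n_words: int, alpha: float = 0.05) -> float:
    """-log10 of the Bonferroni-corrected significance threshold."""
    if n_words < 1:
        raise ValueError("n_words must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return -math.log10(alpha / n_words)
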