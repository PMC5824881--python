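"""The non-redundant seed-site universe: gene x miRNA-family site counts.

miRNAs sharing an identical nt 2-8 seed collapse into one family, so the
universe is *non-redundant* on the miRNA side; longest-site precedence in the
scanner makes it non-redundant on the site side.  Genes with zero sites stay
in the universe -- they populate the background of every contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .seeds import MatureMirna, collapse_families, seed_words
from .sites import SiteHit, UtrRecord, find_3comp_sites, find_seed_sites

__all__ = ["SeedUniverse", "build_universe"]


@dataclass
class SeedUniverse:
    """Gene x family incidence of seed sites over a 3'UTR set.

    ``incidence`` maps family_key -> {gene_id -> site count > 0}; genes with
    zero sites for a family are simply absent from that inner mapping but
    present in ``genes``.
    """

    genes: List[str]
    families: List[str]
    incidence: Dict[str, Dict[str, int]] = field(repr=False)
    n_sites_total: int = 0

    def __post_init__(self) -> None:
        gene_set = set(self.genes)
        if len(gene_set) != len(self.genes):
            raise ValueError("universe gene list contains duplicates")
        family_set = set(self.families)
        total = 0
        for family, per_gene in self.incidence.items():
            if family not in family_set:
                raise ValueError(f"incidence family {family!r} not in families")
            for gene, count in per_gene.items():
                if gene not in gene_set:
                    raise ValueError(f"incidence gene {gene!r} not in genes")
                if count <= 0:
                    raise ValueError("incidence counts must be positive")
                total += count
        if self.n_sites_total != total:
            raise ValueError(
                f"n_sites_total={self.n_sites_total} but counts sum to {total}"
            )

    def site_count(self, gene_id: str, family_key: str) -> int:
        return self.incidence.get(family_key, {}).get(gene_id, 0)

    def genes_with_sites(self, family_key: str) -> FrozenSet[str]:
        """Genes carrying at least one site of the family (gene-level presence)."""
        return frozenset(self.incidence.get(family_key, {}))

    def restrict(self, genes: Iterable[str]) -> "SeedUniverse":
        """Universe over exactly ``genes``: site counts are kept for genes we
        know about; genes new to the universe enter with zero sites."""
        genes = list(dict.fromkeys(genes))
        gene_set = set(genes)
        incidence = {
            family: {g: c for g, c in per_gene.items() if g in gene_set}
            for family, per_gene in self.incidence.items()
        }
        incidence = {f: pg for f, pg in incidence.items()}
        total = sum(c for pg in incidence.values() for c in pg.values())
        return SeedUniverse(
            genes=genes,
            families=list(self.families),
            incidence=incidence,
            n_sites_total=total,
        )

    def to_frame(self) -> pd.DataFrame:
        """Dense gene x family count matrix (genes as rows)."""
        frame = pd.DataFrame(0, index=self.genes, columns=self.families, dtype=int)
        for family, per_gene in self.incidence.items():
            for gene, count in per_gene.items():
                frame.at[gene, family] = count
        return frame

    def summary(self) -> pd.DataFrame:
        """Per-family totals: genes with >= 1 site and total site count."""
        rows = [
            {
                "family_key": family,
                "n_genes_with_sites": len(self.incidence.get(family, {})),
                "n_sites": sum(self.incidence.get(family, {}).values()),
            }
            for family in self.families
        ]
        return pd.DataFrame(rows)


def build_universe(
    utrs: Sequence[UtrRecord],
    mirnas: Sequence[MatureMirna],
    include_3comp: bool = False,
) -> SeedUniverse:
    """Scan every UTR for every seed family and assemble the universe.

    miRNAs are collapsed into families by identical nt 2-8 seed before
    scanning, so duplicated-seed miRNA lists yield identical universes.  When
    ``include_3comp`` is set, 3'-compensatory sites found with the family's
    first member as the pairing representative are added to the counts.
    """
    if not mirnas:
        raise ValueError("at least one miRNA is required")
    gene_ids = [u.gene_id for u in utrs]
    seen: Dict[str, str] = {}
    for u in utrs:
        if u.gene_id in seen:
            raise ValueError(f"duplicate gene_id {u.gene_id!r} in UTR set")
        seen[u.gene_id] = u.sequence

    families = collapse_families(mirnas)
    family_keys = list(families)
    incidence: Dict[str, Dict[str, int]] = {key: {} for key in family_keys}
    total = 0
    for utr in utrs:
        for key, members in families.items():
            hits: List[SiteHit] = find_seed_sites(utr, seed_words(members[0]))
            if include_3comp:
                hits = hits + find_3comp_sites(utr, members[0])
            if hits:
                incidence[key][utr.gene_id] = len(hits)
                total += len(hits)
    incidence = {k: v for k, v in incidence.items()}
    return SeedUniverse(
        genes=gene_ids,
        families=family_keys,
        incidence=incidence,
        n_sites_total=total,
    )
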