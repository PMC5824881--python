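"""End-to-end orchestration: universe -> partition -> enrichment -> landscape.

The enrichment gene universe is the intersection of the DE table and the UTR
set (or the TargetScan universe): the background must be the genes the
experiment actually interrogated.  Genes dropped by the intersection are
logged.  Every run writes a manifest carrying the package version, a hash of
the resolved configuration and the seed, so identical configs reproduce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from . import __version__
from .detable import DeRecord, Thresholds, load_de_table, partition, records_to_frame
from .enrich import enrich_all, rows_to_frame
from .io import read_mirna_table, read_targetscan, read_utr_fasta, write_tsv
from .universe import SeedUniverse, build_universe
from .wordscape import (
    RankedGenes,
    count_words,
    default_cutpoints,
    landscape,
    mirna_word_panel,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_enrichment_pipeline", "run_landscape_pipeline"]


@dataclass
class RunConfig:
    """Paths and settings for one pipeline run.

    Exactly one universe source must be given: UTR FASTA plus a miRNA table,
    or a TargetScan-style predicted-targets file.
    """

    de_table: str
    out_dir: str
    utrs: Optional[str] = None
    mirnas: Optional[str] = None
    targetscan: Optional[str] = None
    targetscan_species: str = "10090"
    gene_col: str = "gene_id"
    fc_col: str = "signed_ratio"
    p_col: str = "p_raw"
    padj_col: Optional[str] = None
    fc_kind: str = "ratio"
    thresholds: Thresholds = field(default_factory=Thresholds)
    include_3comp: bool = False
    k: int = 7
    cut_step: Optional[int] = None
    bonferroni_mode: str = "words"  # or "words_x_cuts"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        fasta_source = self.utrs is not None and self.mirnas is not None
        ts_source = self.targetscan is not None
        if fasta_source == ts_source:
            raise ValueError(
                "exactly one universe source required: "
                "(--utrs and --mirnas) or --targetscan"
            )
        if self.bonferroni_mode not in ("words", "words_x_cuts"):
            raise ValueError("bonferroni_mode must be 'words' or 'words_x_cuts'")

    def column_map(self) -> Dict[str, str]:
        cmap = {"gene": self.gene_col, "fc": self.fc_col, "p": self.p_col}
        if self.padj_col:
            cmap["padj"] = self.padj_col
        return cmap

    def resolved(self) -> Dict:
        d = asdict(self)
        d["thresholds"] = asdict(self.thresholds)
        return d


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.resolved(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_manifest(config: RunConfig, out: Path, extra: Dict) -> None:
    manifest = {
        "mirseed_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "config": config.resolved(),
        **extra,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _load_inputs(config: RunConfig):
    records = load_de_table(config.de_table, config.column_map(), config.fc_kind)
    de_genes = [r.gene_id for r in records]
    if config.targetscan is not None:
        universe = read_targetscan(
            config.targetscan,
            species_id=config.targetscan_species,
            background_genes=de_genes,
        )
        utrs = None
    else:
        utrs = read_utr_fasta(config.utrs)
        mirnas = read_mirna_table(config.mirnas)
        universe = build_universe(utrs, mirnas, include_3comp=config.include_3comp)
    common = [g for g in de_genes if g in set(universe.genes)]
    dropped = len(de_genes) - len(common)
    if dropped:
        logger.info(
            "dropped %d DE genes absent from the universe (%d remain)",
            dropped, len(common),
        )
    if not common:
        raise ValueError("no genes shared between the DE table and the universe")
    records = [r for r in records if r.gene_id in set(common)]
    universe = universe.restrict(common)
    return records, universe, utrs, dropped


def run_enrichment_pipeline(config: RunConfig) -> Path:
    """Universe summary, partition summary and per-direction enrichment reports."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, universe, _utrs, dropped = _load_inputs(config)
    part = partition(records, config.thresholds)
    rows = enrich_all(part, universe)

    write_tsv(universe.summary(), out / "universe_summary.tsv")
    part_frame = pd.DataFrame(
        {
            "set": ["up", "down", "background"],
            "n_genes": [len(part.up), len(part.down), len(part.background)],
            "p_cutoff": [config.thresholds.p_raw_max] * 3,
            "fc_cutoff_abs_ratio": [config.thresholds.fc_min_abs_ratio] * 3,
            "use_adjusted": [config.thresholds.use_adjusted] * 3,
        }
    )
    write_tsv(part_frame, out / "partition_summary.tsv")
    report = rows_to_frame(rows)
    for direction in ("down", "up"):
        write_tsv(
            report[report.direction == direction].drop(columns="direction"),
            out / f"enrichment_{direction}.tsv",
        )
    _write_manifest(
        config,
        out,
        {
            "n_background": len(part.background),
            "n_up": len(part.up),
            "n_down": len(part.down),
            "n_dropped_de_genes": dropped,
            "n_families": len(universe.families),
            "n_sites_total": universe.n_sites_total,
        },
    )
    return out


def run_landscape_pipeline(config: RunConfig) -> Path:
    """Ranked-list word landscape over the miRNA heptamer panel."""
    if config.targetscan is not None:
        raise ValueError("the landscape pipeline needs UTR sequences (--utrs/--mirnas)")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, _universe, utrs, dropped = _load_inputs(config)
    mirnas = read_mirna_table(config.mirnas)
    if config.k == 7:
        panel = mirna_word_panel(mirnas)
        if not panel:
            raise ValueError("empty word panel: no miRNA heptamers to score")
    else:
        panel = None  # non-heptamer runs score every observed word
    kept = {r.gene_id for r in records}
    utrs = [u for u in utrs if u.gene_id in kept]
    index = count_words(utrs, k=config.k, word_panel=panel)
    ranked = RankedGenes.from_records(records)
    cuts = (
        list(range(config.cut_step, len(ranked) + 1, config.cut_step))
        if config.cut_step
        else default_cutpoints(len(ranked))
    )
    scape = landscape(ranked, index, cutpoints=cuts, words=panel)
    n_words = len(scape.words)
    n_tests = (
        n_words * len(cuts) if config.bonferroni_mode == "words_x_cuts" else n_words
    )
    from .wordscape import bonferroni_line

    threshold = bonferroni_line(n_tests)
    frame = scape.to_frame()
    with open(out / "landscape.tsv", "w") as fh:
        fh.write(f"# total_positions\t{scape.total_positions}\n")
        fh.write(f"# bonferroni_minus_log10_p\t{threshold:.6g}\n")
        for word in scape.words:
            fh.write(f"# word_total\t{word}\t{scape.word_totals[word]}\n")
        frame.to_csv(fh, sep="\t", index=False, na_rep=".", float_format="%.6g")
    _write_manifest(
        config,
        out,
        {
            "n_words": n_words,
            "n_cutpoints": len(cuts),
            "bonferroni_minus_log10_p": threshold,
            "n_dropped_de_genes": dropped,
        },
    )
    return out
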