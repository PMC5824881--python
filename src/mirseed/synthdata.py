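"""Synthetic 3'UTRs with planted seed sites and a two-group expression study.

The generator emulates the data flow of a miRNA-misexpression microarray
experiment: random 3'UTRs in which a chosen fraction of genes carries planted
seed-match sites for one miRNA family, and a case/control expression
experiment in which site-bearing genes receive a directional log2 shift plus
Gaussian noise.  Per-gene summaries (log2 fold change and Welch t-test
p-value) feed the same partition -> enrichment -> landscape pipeline as a
real differential-expression table would.

Defaults model a single-cluster repression experiment at microarray-like
scale: 2,000 genes, UTRs 200-1500 nt, 30% of genes targeted, a -1 log2
shift, noise SD 0.5, and 5 replicates per group.

All randomness flows through one ``numpy.random.Generator`` stream; the
``simulate_scenario`` orchestrator threads a single stream (seeded from the
config) through decoy-family generation, UTR synthesis, and expression so a
given seed reproduces the run byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .detable import DeRecord, log2fc_to_ratio
from .seeds import MatureMirna, seed_words
from .sites import UtrRecord

__all__ = [
    "MIR96",
    "MIR182",
    "MIR183",
    "MIR96_DDL",
    "SynthConfig",
    "TruthTable",
    "Scenario",
    "gen_decoy_mirnas",
    "gen_utrs",
    "gen_expression",
    "gen_two_study",
    "simulate_scenario",
]

# The miR-183 cluster (mouse mature sequences) and the diminuendo seed mutant
# of miR-96, used as default planted families and in the word-panel checks.
MIR96 = MatureMirna("miR-96", "UUUGGCACUAGCACAUUUUUGCU")
MIR182 = MatureMirna("miR-182", "UUUGGCAAUGGUAGAACUCACACU")
MIR183 = MatureMirna("miR-183", "UAUGGCACUGGUAGAAUUCACU")
MIR96_DDL = MatureMirna("miR-96-ddl", "UUUGGCUCUAGCACAUUUUUGCU")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic experiment."""

    seed: int
    n_genes: int = 2000
    utr_len_range: Tuple[int, int] = (200, 1500)
    base_composition: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    planted_family: MatureMirna = MIR96
    target_fraction: float = 0.3
    copies_per_target: int = 1
    effect_log2: float = -1.0
    noise_sd: float = 0.5
    n_replicates: int = 5
    n_decoy_families: int = 20

    def __post_init__(self) -> None:
        if not 0 <= self.target_fraction <= 1:
            raise ValueError("target_fraction must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.copies_per_target < 1:
            raise ValueError("copies_per_target must be >= 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not (1 <= self.utr_len_range[0] <= self.utr_len_range[1]):
            raise ValueError("utr_len_range must be an increasing pair >= 1")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthTable:
    """Which genes carry planted sites, and where."""

    is_target: Dict[str, bool]
    offsets: Dict[str, List[int]] = field(default_factory=dict)

    @property
    def target_genes(self) -> List[str]:
        return [g for g, t in self.is_target.items() if t]


def _gene_ids(n_genes: int) -> List[str]:
    width = len(str(n_genes))
    return [f"gene{str(i + 1).zfill(width)}" for i in range(n_genes)]


def gen_decoy_mirnas(
    config: SynthConfig, rng: Optional[np.random.Generator] = None
) -> List[MatureMirna]:
    """Random 22 nt miRNAs whose seeds play no role in the expression model.

    Re-draws any decoy whose seed coincides with the planted family or an
    earlier decoy, so the universe has exactly ``n_decoy_families + 1``
    distinct families.
    """
    rng = rng if rng is not None else config.rng()
    planted_key = seed_words(config.planted_family).family_key
    taken = {planted_key}
    decoys: List[MatureMirna] = []
    bases = np.array(list("ACGU"))
    while len(decoys) < config.n_decoy_families:
        seq = "".join(rng.choice(bases, size=22))
        m = MatureMirna(f"decoy-{len(decoys) + 1:02d}", seq)
        key = seed_words(m).family_key
        if key in taken:
            continue
        taken.add(key)
        decoys.append(m)
    return decoys


def gen_utrs(
    config: SynthConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[List[UtrRecord], TruthTable]:
    """Random UTRs with planted seed words in a chosen subset of genes.

    Exactly ``round(target_fraction * n_genes)`` genes receive
    ``copies_per_target`` planted words, each either the family's 7mer-m8 or
    8mer word (random choice), written over the background sequence at
    non-overlapping random offsets so UTR lengths stay fixed.
    """
    rng = rng if rng is not None else config.rng()
    words = seed_words(config.planted_family)
    lo, hi = config.utr_len_range
    n_targets = round(config.target_fraction * config.n_genes)
    gene_ids = _gene_ids(config.n_genes)
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    bases = np.array(list("ACGT"))
    probs = np.asarray(config.base_composition, dtype=float)
    target_idx = set(
        rng.choice(config.n_genes, size=n_targets, replace=False).tolist()
    )

    utrs: List[UtrRecord] = []
    truth = TruthTable(is_target={}, offsets={})
    for i, gene in enumerate(gene_ids):
        length = int(lengths[i])
        seq = rng.choice(bases, size=length, p=probs)
        is_target = i in target_idx
        offsets: List[int] = []
        if is_target:
            taken: List[Tuple[int, int]] = []
            for _ in range(config.copies_per_target):
                word = words.word_8mer if rng.random() < 0.5 else words.word_7m8
                placed = False
                for _attempt in range(200):
                    start = int(rng.integers(0, length - len(word) + 1))
                    span = (start, start + len(word))
                    if all(span[1] <= s or span[0] >= e for s, e in taken):
                        seq[span[0] : span[1]] = list(word)
                        taken.append(span)
                        offsets.append(start)
                        placed = True
                        break
                if not placed:
                    raise ValueError(
                        f"UTR of length {length} too short to host "
                        f"{config.copies_per_target} non-overlapping planted sites"
                    )
        utrs.append(UtrRecord(gene, "".join(seq)))
        truth.is_target[gene] = is_target
        if offsets:
            truth.offsets[gene] = sorted(offsets)
    return utrs, truth


def gen_expression(
    truth: TruthTable,
    config: SynthConfig,
    rng: Optional[np.random.Generator] = None,
) -> List[DeRecord]:
    """Two-group expression with a mean log2 shift on site-bearing genes.

    Control samples are Normal(0, sd^2) and case samples
    Normal(effect_log2 * is_target, sd^2), ``n_replicates`` each; the per-gene
    summary is log2fc = mean(case) - mean(control) with a two-sided Welch
    t-test p-value, matching what a linear-model microarray fit would emit.
    """
    rng = rng if rng is not None else config.rng()
    genes = list(truth.is_target)
    n = len(genes)
    r = config.n_replicates
    shift = np.array(
        [config.effect_log2 if truth.is_target[g] else 0.0 for g in genes]
    )
    ctrl = rng.normal(0.0, config.noise_sd, size=(n, r))
    case = rng.normal(0.0, config.noise_sd, size=(n, r)) + shift[:, None]
    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    p_raw = stats.ttest_ind(case, ctrl, axis=1, equal_var=False).pvalue
    return [
        DeRecord(
            gene_id=g,
            signed_ratio=log2fc_to_ratio(float(fc)),
            log2fc=float(fc),
            p_raw=float(p),
        )
        for g, fc, p in zip(genes, log2fc, p_raw)
    ]


def gen_two_study(
    config_a: SynthConfig,
    config_b: SynthConfig,
    shared_fraction: float,
) -> Tuple[List[DeRecord], List[DeRecord], List[str]]:
    """Two expression studies whose true-effect genes partially coincide.

    A common subset (``shared_fraction`` of each study's target count) drives
    both studies; the remaining targets are drawn independently.  Returns the
    two DE tables and the shared target gene ids, for overlap-test recovery
    experiments.  Randomness comes from config_a's stream.
    """
    if not 0 <= shared_fraction <= 1:
        raise ValueError("shared_fraction must lie in [0, 1]")
    if config_a.n_genes != config_b.n_genes:
        raise ValueError(
            f"studies must share n_genes (got {config_a.n_genes} and "
            f"{config_b.n_genes})"
        )
    rng = config_a.rng()
    genes = _gene_ids(config_a.n_genes)
    n_a = round(config_a.target_fraction * config_a.n_genes)
    n_b = round(config_b.target_fraction * config_b.n_genes)
    n_shared = round(shared_fraction * min(n_a, n_b))
    shared = rng.choice(config_a.n_genes, size=n_shared, replace=False)
    rest = np.setdiff1d(np.arange(config_a.n_genes), shared)
    extra_a = rng.choice(rest, size=n_a - n_shared, replace=False)
    extra_b = rng.choice(rest, size=n_b - n_shared, replace=False)

    def truth_for(extra: np.ndarray) -> TruthTable:
        chosen = set(shared.tolist()) | set(extra.tolist())
        return TruthTable(is_target={g: (i in chosen) for i, g in enumerate(genes)})

    de_a = gen_expression(truth_for(extra_a), config_a, rng)
    de_b = gen_expression(truth_for(extra_b), config_b, rng)
    return de_a, de_b, [genes[i] for i in sorted(shared.tolist())]


@dataclass
class Scenario:
    """Everything one synthetic run produces."""

    config: SynthConfig
    mirnas: List[MatureMirna]  # planted family first, then decoys
    utrs: List[UtrRecord]
    truth: TruthTable
    de_records: List[DeRecord]

    @property
    def planted_key(self) -> str:
        return seed_words(self.config.planted_family).family_key


def simulate_scenario(config: SynthConfig) -> Scenario:
    """Run decoys -> UTRs -> expression on a single seeded RNG stream."""
    rng = config.rng()
    decoys = gen_decoy_mirnas(config, rng)
    utrs, truth = gen_utrs(config, rng)
    de_records = gen_expression(truth, config, rng)
    return Scenario(
        config=config,
        mirnas=[config.planted_family] + decoys,
        utrs=utrs,
        truth=truth,
        de_records=de_records,
    )
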