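"""Small self-contained statistics: Mendelian ratio goodness-of-fit and
delta-delta-Ct fold change.

These support transgenic-line bookkeeping: testing whether intercross
genotype counts fit the expected 1:2:1 segregation, and converting qPCR
cycle thresholds into relative expression fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

from scipy import stats

__all__ = ["GenotypeCounts", "GofResult", "DdctInput", "mendelian_gof", "ddct_fold"]


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotypes scored in an intercross: wild-type, heterozygous, homozygous."""

    wt: int
    het: int
    hom: int

    def __post_init__(self) -> None:
        for name in ("wt", "het", "hom"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count must be non-negative")
        if self.total == 0:
            raise ValueError("at least one genotype must be observed")

    @property
    def total(self) -> int:
        return self.wt + self.het + self.hom


@dataclass(frozen=True)
class GofResult:
    chi2: float
    df: int
    p: float


def mendelian_gof(
    counts: GenotypeCounts, ratio: Tuple[int, int, int] = (1, 2, 1)
) -> GofResult:
    """Pearson chi-square goodness of fit of genotype counts to a ratio.

    The default 1:2:1 ratio is the single-locus intercross expectation; the
    test has df = 2 (three categories) and no continuity correction.
    """
    total = counts.total
    weights = sum(ratio)
    expected = [total * r / weights for r in ratio]
    if min(expected) < 1:
        raise ValueError("expected counts must all be >= 1 for the chi-square test")
    chi2, p = stats.chisquare([counts.wt, counts.het, counts.hom], expected)
    return GofResult(chi2=float(chi2), df=len(ratio) - 1, p=float(p))


@dataclass(frozen=True)
class DdctInput:
    """Cycle thresholds for target and reference genes in case and control."""

    ct_target_case: float
    ct_ref_case: float
    ct_target_ctrl: float
    ct_ref_ctrl: float

    def __post_init__(self) -> None:
        for name in (
            "ct_target_case",
            "ct_ref_case",
            "ct_target_ctrl",
            "ct_ref_ctrl",
        ):
            value = getattr(self, name)
            if not (value > 0 and value == value and value != float("inf")):
                raise ValueError(f"{name}={value!r} must be finite and positive")


def ddct_fold(x: DdctInput) -> float:
    """Relative fold change 2^(-ddCt).

    ddCt = (Ct_target,case - Ct_ref,case) - (Ct_target,ctrl - Ct_ref,ctrl);
    a fold change > 1 means the target is more abundant in the case group.
    """
    ddct = (x.ct_target_case - x.ct_ref_case) - (x.ct_target_ctrl - x.ct_ref_ctrl)
    return 2.0**-ddct
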