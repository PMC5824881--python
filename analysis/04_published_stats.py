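#!/usr/bin/env python
"""Desk statistics computed from the published study's printed inputs.

Four small computations that need no sequence data: the cross-study
overlap Fisher test, Mendelian segregation chi-square tests for the three
transgenic lines, the seed-word panels of the miR-183 cluster and of the
diminuendo miR-96 seed mutant, and the Bonferroni threshold for a
912-heptamer landscape panel.  Writes results/published_stats.tsv.
"""

from pathlib import Path

import pandas as pd

import mirseed as ms
from mirseed.studystats import GenotypeCounts, mendelian_gof

OUT = Path(__file__).resolve().parent.parent / "results" / "published_stats.tsv"


def main() -> None:
    rows = []

    overlap = ms.overlap_test(97, 179, 6, 19358)
    rows.append(("cross_study_overlap_odds_ratio", round(overlap.odds_ratio.value, 2)))
    rows.append(("cross_study_overlap_p", float(f"{overlap.p_two_sided:.2g}")))
    print(
        f"overlap of 97- and 179-gene lists sharing 6 genes in 19,358: "
        f"OR {overlap.odds_ratio.value:.2f}, p {overlap.p_two_sided:.2g}"
    )

    for label, counts in (
        ("line1", GenotypeCounts(154, 240, 113)),
        ("line2", GenotypeCounts(23, 36, 25)),
        ("line3", GenotypeCounts(25, 49, 22)),
    ):
        result = mendelian_gof(counts)
        rows.append((f"mendelian_{label}_p", round(result.p, 3)))
        print(
            f"{label} ({counts.wt}:{counts.het}:{counts.hom}) vs 1:2:1 -> "
            f"chi2 {result.chi2:.2f}, p {result.p:.3f}"
        )

    cluster_panel = ms.mirna_word_panel([ms.MIR96, ms.MIR182, ms.MIR183])
    ddl_panel = ms.mirna_word_panel([ms.MIR96_DDL])
    print(f"miR-183 cluster heptamer panel: {', '.join(cluster_panel)}")
    print(f"miR-96 seed-mutant heptamer panel: {', '.join(ddl_panel)}")
    rows.append(("cluster_panel_n_words", len(cluster_panel)))
    rows.append(("ddl_panel_n_words", len(ddl_panel)))

    rows.append(("bonferroni_912_words", round(ms.bonferroni_line(912), 3)))
    print(f"Bonferroni line for 912 heptamers at alpha 0.05: "
          f"{ms.bonferroni_line(912):.3f}")

    OUT.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["statistic", "value"]).to_csv(
        OUT, sep="\t", index=False
    )
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
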