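#!/usr/bin/env python
"""Ranked-list heptamer landscape of the simulated study.

Genes are ranked from most upregulated to most downregulated; every miRNA
heptamer in the panel (7mer-m8 and 7mer-1A words of the planted family and
all decoys) is scored by the sliding hypergeometric statistic.  Under
planted repression, the planted heptamers should dip far below the
Bonferroni line on the downregulated (right) side of the ranking.
Outputs go to results/landscape/.
"""

from pathlib import Path

import pandas as pd

from mirseed.pipeline import RunConfig, run_landscape_pipeline

ROOT = Path(__file__).resolve().parent.parent
STUDY = ROOT / "results" / "synthetic_study"
OUT = ROOT / "results" / "landscape"
PLANTED = ("GTGCCAA", "TGCCAAA")


def main() -> None:
    config = RunConfig(
        de_table=str(STUDY / "de_table.tsv"),
        out_dir=str(OUT),
        utrs=str(STUDY / "utrs.fasta"),
        mirnas=str(STUDY / "mirnas.tsv"),
    )
    run_landscape_pipeline(config)
    table = pd.read_csv(OUT / "landscape.tsv", sep="\t", comment="#")
    threshold = next(
        float(line.split("\t")[1])
        for line in (OUT / "landscape.tsv").read_text().splitlines()
        if line.startswith("# bonferroni")
    )
    print(f"landscape table in {OUT} (Bonferroni line at {threshold:.2f})")
    for word in PLANTED:
        rows = table[table.word == word]
        deepest = rows.loc[rows.signed_log10_p.idxmin()]
        print(
            f"{word}: deepest depletion {deepest.signed_log10_p:.1f} "
            f"at leading-set size {int(deepest.cutpoint)} of 2000"
        )


if __name__ == "__main__":
    main()
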