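#!/usr/bin/env python
"""Fragment-level profiles of the panel: lengths, end bases, 4-mer motifs.

Runs the paired-end pipeline per library (merged reads plus the 90-nt
long-fragment pair rule), then writes per-sample length-class fractions,
3'-pyrimidine/purine ratios, 5'-adenine rates and the 256-entry end-motif
matrix that the cohort statistics consume.
"""

from pathlib import Path

import pandas as pd

from cfrna.fragmentomics import MOTIFS
from cfrna.pipeline import process_sample
from cfrna.preprocess import read_fastq
from cfrna.references import load_references

SIM = Path("results/sim")
OUT = Path("results/fragmentomics")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    refset = load_references(
        SIM / "references.fa", SIM / "references.tsv", SIM / "matures.tsv"
    )
    panel = pd.read_csv(SIM / "panel.tsv", sep="\t")

    rows, motif_cols = [], {}
    for sample in panel["sample"]:
        r1 = read_fastq(SIM / f"{sample}_R1.fastq", "R1")
        r2 = read_fastq(SIM / f"{sample}_R2.fastq", "R2")
        res = process_sample(refset, r1, r2)
        p = res.profile_long
        rows.append(
            {"sample": sample, **{f"frac_{k}": v
                                  for k, v in res.class_fractions.items()},
             "py_pu_ratio_3p": p.py_pu_ratio_3p if p else float("nan"),
             "adenine_rate_5p": p.adenine_rate_5p if p else float("nan")}
        )
        if p is not None:
            motif_cols[sample] = p.motif3
        hist = pd.Series(res.length_hist).sort_index()
        hist.rename("count").to_csv(
            OUT / f"{sample}_length_hist.tsv", sep="\t", index_label="length"
        )

    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "fragment_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))

    motifs = pd.DataFrame(motif_cols, index=list(MOTIFS))
    motifs.to_csv(OUT / "end_motifs_3p.tsv", sep="\t", index_label="motif")
    print(f"\nmotif matrix ({motifs.shape[0]} motifs x "
          f"{motifs.shape[1]} samples) -> {OUT / 'end_motifs_3p.tsv'}")


if __name__ == "__main__":
    main()
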