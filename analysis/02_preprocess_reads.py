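#!/usr/bin/env python
"""Clean every simulated library: adapter/poly(A)/quality trimming, the
17-nt and 10%-N filters, and paired-read merging.

Reads the panel from results/sim/ and writes per-sample cleanup reports
plus merged/unmerged FASTQ under results/clean/.  The report columns
partition the input: n_pass = n_input - removed_short - removed_N.
"""

from pathlib import Path

import pandas as pd

from cfrna.preprocess import (
    filter_reads, merge_pairs, read_fastq, trim_read_ex, write_fastq,
    CleanupReport,
)
from cfrna.simulate import DEFAULT_ADAPTER_3P

SIM = Path("results/sim")
OUT = Path("results/clean")


def clean_pair(sample: str) -> dict:
    r1 = read_fastq(SIM / f"{sample}_R1.fastq", "R1")
    r2 = read_fastq(SIM / f"{sample}_R2.fastq", "R2")
    report = CleanupReport()
    merged, unmerged_r1 = [], []
    for a, b in zip(r1, r2):
        t1, ad, pa = trim_read_ex(a, DEFAULT_ADAPTER_3P)
        report.n_adapter_trimmed += ad
        report.n_polyA_trimmed += pa
        t2, _, _ = trim_read_ex(b, "X" * 40, min_polyA_run=10**9)
        m = merge_pairs(t1, t2)
        (merged.append(m) if m is not None else unmerged_r1.append(t1))
    passing, report = filter_reads(merged + unmerged_r1, report=report)
    write_fastq(OUT / f"{sample}_clean.fastq", passing)
    return {"sample": sample, "n_merged": len(merged),
            "n_unmerged": len(unmerged_r1), **report.to_dict()}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    panel = pd.read_csv(SIM / "panel.tsv", sep="\t")
    rows = [clean_pair(s) for s in panel["sample"]]
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "cleanup_reports.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    assert (df["n_pass"] == df["n_input"] - df["n_removed_short"]
            - df["n_removed_N"]).all()
    print(f"\nreports -> {OUT / 'cleanup_reports.tsv'}")


if __name__ == "__main__":
    main()
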