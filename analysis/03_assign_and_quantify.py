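#!/usr/bin/env python
"""Tiered assignment and quantification of the cleaned panel.

For every library: depletion-first tier assignment with the <=1-mismatch
best-stratum aligner, weighted small-RNA counts normalized to RPM, and
EM-based gene TPM for the mRNA/lncRNA tier.  Writes the cross-sample
RPM and TPM matrices, per-sample assignment statistics, and the
detected-gene summary (a gene counts as present in the panel when seen
in at least two libraries).
"""

from pathlib import Path

import pandas as pd

from cfrna.pipeline import PipelineParams, process_sample
from cfrna.preprocess import read_fastq
from cfrna.quantify import detected_gene_counts_by_biotype
from cfrna.references import load_references

SIM = Path("results/sim")
CLEAN = Path("results/clean")
OUT = Path("results/quant")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    refset = load_references(
        SIM / "references.fa", SIM / "references.tsv", SIM / "matures.tsv"
    )
    panel = pd.read_csv(SIM / "panel.tsv", sep="\t")
    fluids = [s for s in panel["sample"] if not s.startswith("uhrr")]

    rpm, tpm, stats_rows = {}, {}, []
    for sample in fluids:
        reads = read_fastq(CLEAN / f"{sample}_clean.fastq")
        res = process_sample(refset, reads, params=PipelineParams())
        rpm[sample] = res.small_rpm
        tpm[sample] = res.gene_tpm
        s = res.align_stats
        stats_rows.append(
            {"sample": sample, "n_input": s["n_input"],
             "n_depleted": s["n_depleted"], **s["per_tier"],
             "n_unmapped": s["n_unmapped"]}
        )
    stats = pd.DataFrame(stats_rows)
    stats.to_csv(OUT / "assignment_stats.tsv", sep="\t", index=False)
    print(stats.to_string(index=False))

    rpm_mat = pd.DataFrame(rpm).fillna(0.0)
    tpm_mat = pd.DataFrame(tpm).fillna(0.0)
    rpm_mat.to_csv(OUT / "small_rna_rpm.tsv", sep="\t", index_label="target")
    tpm_mat.to_csv(OUT / "gene_tpm.tsv", sep="\t", index_label="gene_id")

    biotype_of = {
        t.gene_id: t.biotype for t in refset.transcripts.values()
    }
    detected = detected_gene_counts_by_biotype(
        tpm_mat, biotype_of, min_count=1.0, min_samples=2
    )
    detected.rename("n_detected").to_csv(
        OUT / "detected_genes.tsv", sep="\t", index_label="biotype"
    )
    print("\ngenes detected in >=2 libraries (TPM >= 1):")
    print(detected.to_string())
    print(f"\nmatrices -> {OUT}")


if __name__ == "__main__":
    main()
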