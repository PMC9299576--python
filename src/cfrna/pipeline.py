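"""End-to-end orchestration of one sample: cleanup → tiers → tables.

``process_sample`` drives the whole per-sample analysis in memory and is
what the command-line ``run`` subcommand, the analysis scripts and the
tests all call: read cleanup (with pair merging for paired libraries),
tiered alignment and assignment, small-RNA counting with RPM, EM-based
TPM for the long tier, and fragment-level profiling (length histogram
combining the merged-read and long-fragment pair strategies, end bases
and 4-mer motifs for the mRNA/lncRNA fraction).

Read-count conservation is tracked across stages and recorded in the run
manifest: every input read is depleted, assigned to exactly one tier, or
unmapped.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .align import AlignmentRecord, TieredAligner, TierAligner, assign_tiers
from .fragmentomics import (
    FragmentProfile,
    fragment_lengths,
    length_class_fractions,
    profile_fragments,
)
from .preprocess import (
    CleanupReport,
    ReadRecord,
    clean_reads,
    filter_reads,
    merge_pairs,
    read_fastq,
    trim_read_ex,
)
from .quantify import (
    count_small_rna,
    long_tier_tpm,
    rpm_normalize,
    total_mapped_reads,
)
from .references import ReferenceSet
from .simulate import DEFAULT_ADAPTER_3P, revcomp


@dataclass
class PipelineParams:
    """Stage parameters; defaults are the pipeline's documented contract."""

    adapter_3p: str = DEFAULT_ADAPTER_3P
    qual_threshold: int = 15
    min_polyA_run: int = 5
    min_len: int = 17
    max_n_frac: float = 0.10
    k: int = 8
    min_overlap: int = 10
    max_mismatch_rate: float = 0.1
    full_length_threshold: int = 90
    include_depleted_in_rpm: bool = False
    mirna_fallthrough: bool = True


@dataclass
class SampleResult:
    cleanup: CleanupReport
    n_pairs_merged: int
    n_pairs_unmerged: int
    assigned: list
    align_stats: dict
    small_counts: pd.Series
    small_rpm: pd.Series
    gene_tpm: pd.Series
    length_hist: Counter
    length_diag: dict
    class_fractions: dict
    profile_long: FragmentProfile | None


def process_sample(
    refset: ReferenceSet,
    r1_reads: list[ReadRecord],
    r2_reads: list[ReadRecord] | None = None,
    params: PipelineParams | None = None,
    tiered: TieredAligner | None = None,
) -> SampleResult:
    """Run cleanup, assignment, quantification and fragmentomics."""
    params = params or PipelineParams()
    if tiered is None:
        tiered = TieredAligner(refset, params.k)

    if r2_reads is None:
        cleaned, report = clean_reads(
            r1_reads, params.adapter_3p, params.qual_threshold,
            params.min_polyA_run, params.min_len, params.max_n_frac,
        )
        merged_for_assignment = cleaned
        unmerged_pairs: list[tuple[ReadRecord, ReadRecord]] = []
        n_merged = n_unmerged = 0
    else:
        if len(r1_reads) != len(r2_reads):
            raise ValueError("mate files differ in read count")
        report = CleanupReport()
        merged: list[ReadRecord] = []
        unmerged_pairs = []
        for r1, r2 in zip(r1_reads, r2_reads):
            # mate 1 carries poly(A) tail + 3' adapter; mate 2 is trimmed
            # for quality only (its adapter-side bases precede the read)
            t1, ad, pa = trim_read_ex(
                r1, params.adapter_3p, params.qual_threshold,
                params.min_polyA_run,
            )
            report.n_adapter_trimmed += ad
            report.n_polyA_trimmed += pa
            t2, _, _ = trim_read_ex(
                r2, "X" * 40, params.qual_threshold, min_polyA_run=10**9
            )
            m = merge_pairs(t1, t2, params.min_overlap, params.max_mismatch_rate)
            if m is not None:
                merged.append(m)
            else:
                unmerged_pairs.append((t1, t2))
        n_merged, n_unmerged = len(merged), len(unmerged_pairs)
        merged_ids = {m.read_id for m in merged}
        merged_for_assignment, report = filter_reads(
            merged + [p[0] for p in unmerged_pairs],
            params.min_len, params.max_n_frac, report,
        )

    assigned, align_stats = assign_tiers(
        merged_for_assignment, refset, params.k,
        params.mirna_fallthrough, tiered,
    )

    small_counts = count_small_rna(assigned)
    denom = total_mapped_reads(align_stats, params.include_depleted_in_rpm)
    small_rpm = (
        rpm_normalize(small_counts, denom)
        if denom > 0
        else small_counts * 0.0
    )
    gene_tpm = long_tier_tpm(assigned, refset)

    # fragmentomics: merged/single reads contribute aligned lengths;
    # unmerged pairs feed the long-fragment (>= 90 nt mate 1) rule only
    if r2_reads is None:
        frag_reads = [a for a in assigned if a.transcript_hits]
    else:
        frag_reads = [
            a for a in assigned
            if a.transcript_hits and a.read_id in merged_ids
        ]
    merged_alns = [
        AlignmentRecord(a.read_id, a.transcript_hits[0][0],
                        a.transcript_hits[0][1], _read_len(a), 0)
        for a in frag_reads
    ]
    pair_alns = _align_unmerged_pairs(unmerged_pairs, refset, params, tiered)
    length_hist, length_diag = fragment_lengths(
        merged_alns, pair_alns, params.full_length_threshold
    )
    class_fractions = (
        length_class_fractions(length_hist) if length_hist else {}
    )

    # end features only from reads spanning a whole fragment (merged or
    # single-end): an unmerged mate's 3' terminus is a sequencer artifact
    long_frags = [
        (a.transcript_hits[0][0], a.transcript_hits[0][1],
         a.transcript_hits[0][1] + _read_len(a))
        for a in frag_reads
        if a.tier == "long"
    ]
    profile_long = (
        profile_fragments(long_frags, refset) if long_frags else None
    )

    return SampleResult(
        cleanup=report,
        n_pairs_merged=n_merged,
        n_pairs_unmerged=n_unmerged,
        assigned=assigned,
        align_stats=align_stats,
        small_counts=small_counts,
        small_rpm=small_rpm,
        gene_tpm=gene_tpm,
        length_hist=length_hist,
        length_diag=length_diag,
        class_fractions=class_fractions,
        profile_long=profile_long,
    )


def _read_len(assigned_read) -> int:
    # tier alignment is end-to-end, so aligned length == cleaned read length
    return assigned_read.read_length


def _align_unmerged_pairs(unmerged_pairs, refset, params, tiered):
    """Best forward placements of mate 1 and reverse-complemented mate 2."""
    if not unmerged_pairs:
        return []
    aligner = TierAligner(list(refset.transcripts.values()), params.k)
    depletion = tiered.aligners.get("depletion")
    out = []
    for t1, t2 in unmerged_pairs:
        if len(t1) < 2 * params.k or len(t2) < 2 * params.k:
            continue
        if depletion is not None and depletion.align(t1.read_id, t1.bases):
            continue  # abundant-RNA fragments are removed before profiling
        alns1 = aligner.align(t1.read_id, t1.bases)
        alns2 = aligner.align(t2.read_id, revcomp(t2.bases))
        if not alns1 or not alns2:
            continue
        by_tid = {a.transcript_id: a for a in alns2}
        for a1 in alns1:  # deterministic: first shared transcript wins
            a2 = by_tid.get(a1.transcript_id)
            if a2 is not None:
                out.append((a1, a2))
                break
    return out


# ---------------------------------------------------------------------------
# file-level driver with manifest
# ---------------------------------------------------------------------------

def run_pipeline(
    refset: ReferenceSet,
    fastq1: str | Path,
    outdir: str | Path,
    fastq2: str | Path | None = None,
    params: PipelineParams | None = None,
    seed: int | None = None,
) -> SampleResult:
    """Process FASTQ file(s) and write all per-sample tables + manifest."""
    params = params or PipelineParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    r1 = read_fastq(fastq1, "R1" if fastq2 else "single")
    r2 = read_fastq(fastq2, "R2") if fastq2 else None
    result = process_sample(refset, r1, r2, params)
    write_sample_tables(result, outdir)

    cfg = {k: v for k, v in asdict(params).items()}
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()
    stats = result.align_stats
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "config_sha256": cfg_hash,
        "cleanup": result.cleanup.to_dict(),
        "n_pairs_merged": result.n_pairs_merged,
        "n_pairs_unmerged": result.n_pairs_unmerged,
        "alignment": {
            "n_input": stats["n_input"],
            "n_depleted": stats["n_depleted"],
            "n_unmapped": stats["n_unmapped"],
            "per_tier": stats["per_tier"],
        },
        "conservation_ok": stats["n_input"]
        == stats["n_depleted"]
        + sum(stats["per_tier"].values())
        + stats["n_unmapped"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return result


def write_sample_tables(result: SampleResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"count": result.small_counts, "rpm": result.small_rpm}
    ).to_csv(outdir / "small_rna.tsv", sep="\t", index_label="target")
    result.gene_tpm.rename("tpm").to_csv(
        outdir / "gene_tpm.tsv", sep="\t", index_label="gene_id"
    )
    with open(outdir / "length_hist.tsv", "w") as fh:
        fh.write("length\tcount\n")
        for length in sorted(result.length_hist):
            fh.write(f"{length}\t{result.length_hist[length]}\n")
    with open(outdir / "cleanup_report.tsv", "w") as fh:
        d = result.cleanup.to_dict()
        fh.write("\t".join(d) + "\n")
        fh.write("\t".join(str(v) for v in d.values()) + "\n")
    if result.class_fractions:
        pd.Series(result.class_fractions).rename("fraction").to_csv(
            outdir / "length_classes.tsv", sep="\t", index_label="class"
        )
    if result.profile_long is not None:
        from .fragmentomics import motif_series

        p = result.profile_long
        motif_df = pd.DataFrame(
            {
                "motif5_percent": motif_series(p.motif5),
                "motif3_percent": motif_series(p.motif3),
            }
        )
        motif_df.to_csv(outdir / "end_motifs.tsv", sep="\t", index_label="motif")
        summary = {
            "py_pu_ratio_3p": p.py_pu_ratio_3p,
            "adenine_rate_5p": p.adenine_rate_5p,
            **{f"end5_{b}": f for b, f in p.end5_base_freq.items()},
            **{f"end3_{b}": f for b, f in p.end3_base_freq.items()},
        }
        pd.Series(summary).rename("value").to_csv(
            outdir / "end_summary.tsv", sep="\t", index_label="stat"
        )
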