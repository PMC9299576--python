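"""Abundance estimation: weighted counts, RPM, and an EM-based TPM.

Small RNAs (mature miRNA, tRNA, piRNA, other ncRNA) are quantified as
weighted read counts — a read whose best stratum spans several genes
contributes ``1/n`` to each — normalized to reads per million mapped
reads (RPM).  mRNA and lncRNA are quantified as transcripts per million
(TPM) by an expectation-maximization over each read's best-stratum hit
set: the E-step splits a multi-mapping read across transcripts in
proportion to their current abundance, the M-step re-estimates abundance
as length-normalized assigned reads, and gene TPM sums the gene's
transcripts.  With uniquely mapping reads only, the EM reduces exactly to
count/length normalization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .align import AssignedRead

SMALL_TIERS = ("miRNA", "small", "other")
LONG_TIER = "long"


def count_small_rna(
    assigned: list[AssignedRead], tiers: tuple[str, ...] = SMALL_TIERS
) -> pd.Series:
    """Weighted read counts per target (mature miRNA / gene)."""
    counts: dict[str, float] = {}
    for a in assigned:
        if a.tier not in tiers:
            continue
        for t in a.target_ids:
            counts[t] = counts.get(t, 0.0) + a.weight_per_target
    return pd.Series(counts, dtype=float).sort_index()


def rpm_normalize(counts: pd.Series, total_mapped: int) -> pd.Series:
    """Reads of a target per million mapped reads."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return counts * 1e6 / total_mapped


def total_mapped_reads(stats: dict, include_depleted: bool = False) -> int:
    """RPM denominator: all tier-assigned reads, optionally + depleted."""
    total = sum(stats["per_tier"].values())
    if include_depleted:
        total += stats["n_depleted"]
    return total


# ---------------------------------------------------------------------------
# TPM via EM over best-stratum hit sets
# ---------------------------------------------------------------------------

def tpm_em(
    hit_sets: list[tuple[str, ...]],
    lengths: dict[str, int],
    max_iter: int = 200,
    tol: float = 1e-3,
) -> tuple[pd.Series, list[float]]:
    """Transcript TPM from (possibly multi-mapping) read hit sets.

    ``hit_sets`` holds, per read, the transcripts of its best stratum;
    ``lengths`` must cover every transcript to report (zero-read
    transcripts get TPM 0).  Returns the TPM series over all transcripts
    in ``lengths`` (summing to 1e6 when any read exists) and the
    per-iteration observed-data log-likelihood trace, which is
    non-decreasing.
    """
    tids = sorted(lengths)
    if not hit_sets:
        return pd.Series(0.0, index=tids), []
    idx = {t: i for i, t in enumerate(tids)}
    n = len(tids)
    lens = np.array([lengths[t] for t in tids], dtype=float)

    # compress identical hit sets
    grouped: dict[tuple[int, ...], int] = {}
    for hs in hit_sets:
        key = tuple(sorted(idx[t] for t in set(hs)))
        if not key:
            continue
        grouped[key] = grouped.get(key, 0) + 1
    sets = list(grouped)
    cnts = np.array([grouped[s] for s in sets], dtype=float)

    gamma = np.full(n, 1.0 / n)  # TPM-scale fractions
    n_reads = cnts.sum()
    trace: list[float] = []
    for _ in range(max_iter):
        weights = np.zeros(n)
        ll = 0.0
        for s, c in zip(sets, cnts):
            g = gamma[list(s)]
            denom = g.sum()
            ll += c * np.log(denom) if denom > 0 else -np.inf
            if denom > 0:
                for t, gt in zip(s, g):
                    weights[t] += c * gt / denom
        # observed-data log-likelihood on the molar (alpha) scale:
        # P(read | hit set h) prop. to sum_{t in h} alpha_t / len_t
        ll -= n_reads * np.log(float(gamma @ lens))
        trace.append(float(ll))
        new_gamma = weights / lens
        new_gamma /= new_gamma.sum()
        if np.max(np.abs(new_gamma - gamma)) * 1e6 < tol:
            gamma = new_gamma
            break
        gamma = new_gamma
    return pd.Series(gamma * 1e6, index=tids), trace


def gene_tpm(transcript_tpm: pd.Series, gene_of: dict[str, str]) -> pd.Series:
    """Aggregate transcript TPM to gene TPM."""
    genes = pd.Series({t: gene_of[t] for t in transcript_tpm.index})
    return transcript_tpm.groupby(genes).sum().sort_index()


def long_tier_tpm(
    assigned: list[AssignedRead], refset, max_iter: int = 200, tol: float = 1e-3
) -> pd.Series:
    """Gene TPM for the mRNA/lncRNA tier of a tier-assigned read set."""
    lengths = {
        t.transcript_id: t.length
        for t in refset.tier_transcripts(LONG_TIER)
    }
    hit_sets = [
        tuple(tid for tid, _ in a.transcript_hits)
        for a in assigned
        if a.tier == LONG_TIER
    ]
    t_tpm, _ = tpm_em(hit_sets, lengths, max_iter, tol)
    gene_of = {tid: refset.gene(tid) for tid in lengths}
    return gene_tpm(t_tpm, gene_of)


# ---------------------------------------------------------------------------
# detection summaries
# ---------------------------------------------------------------------------

def detected_genes(
    table: pd.DataFrame, min_count: float = 1.0, min_samples: int = 2
) -> set[str]:
    """Genes detected (count >= min_count) in at least min_samples samples."""
    hits = (table >= min_count).sum(axis=1)
    return set(table.index[hits >= min_samples])


def detected_gene_counts_by_biotype(
    table: pd.DataFrame,
    biotype_of: dict[str, str],
    min_count: float = 1.0,
    min_samples: int = 2,
) -> pd.Series:
    detected = detected_genes(table, min_count, min_samples)
    out: dict[str, int] = {}
    for g in detected:
        b = biotype_of.get(g, "unknown")
        out[b] = out.get(b, 0) + 1
    return pd.Series(out, dtype=int).sort_index()
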