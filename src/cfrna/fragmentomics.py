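"""Fragment-level features of cell-free RNA: lengths, end bases, motifs.

Fragment lengths come from two complementary strategies that are summed:
merged read pairs (or single-end reads) contribute their aligned length
directly, and unmerged pairs whose first read aligns over at least 90 nt
— i.e. fragments longer than a single read — contribute the distance
between the two mates' mapping loci plus the second mate's aligned
length.  Lengths are summarized into the degradation classes <50 nt,
50-200 nt and >200 nt.

Fragment ends are read off the reference: the 5' end base is the first
aligned base, the 3' end base the last aligned base (the residue RNase A
leaves its phosphate on).  The 4-mer end motif spans two bases inside and
two bases outside each fragment boundary; all 256 motifs are counted and
normalized to percentages.  The 3' pyrimidine/purine ratio and the 5'
adenine rate summarize the cleavage signature.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import product
from math import inf

import numpy as np
import pandas as pd

from .align import AlignmentRecord
from .references import ReferenceSet

FULL_LENGTH_THRESHOLD = 90

#: lexicographic 4-mers AAAA..TTTT
MOTIFS: tuple[str, ...] = tuple(
    "".join(p) for p in product("ACGT", repeat=4)
)
_MOTIF_INDEX = {m: i for i, m in enumerate(MOTIFS)}
BASES = "ACGT"


@dataclass(frozen=True)
class FragmentEndContext:
    """Reference context of one fragment's two ends (0-based half-open)."""

    transcript_id: str
    frag_start: int
    frag_end: int
    end5_base: str
    end3_base: str
    end5_motif: str | None  # None when the +/-2 window leaves the transcript
    end3_motif: str | None


# ---------------------------------------------------------------------------
# fragment lengths
# ---------------------------------------------------------------------------

def fragment_lengths(
    merged_alignments: list[AlignmentRecord],
    unmerged_pairs: list[tuple[AlignmentRecord, AlignmentRecord]] = (),
    full_length_threshold: int = FULL_LENGTH_THRESHOLD,
) -> tuple[Counter, dict]:
    """Length histogram from merged reads plus the long-fragment pair rule.

    Strategy 1: each merged (or single-end) alignment contributes its
    aligned length.  Strategy 2: an unmerged pair whose first mate aligns
    over >= ``full_length_threshold`` nt to the same transcript as its
    second mate contributes ``(R2_start - R1_start) + R2_aligned_length``.
    Discordant pairs (negative length) are discarded and tallied.
    """
    hist: Counter = Counter()
    diag = {"n_merged": 0, "n_paired": 0, "n_discordant": 0, "n_pair_skipped": 0}
    for a in merged_alignments:
        hist[a.aligned_length] += 1
        diag["n_merged"] += 1
    for r1, r2 in unmerged_pairs:
        if (
            r1.aligned_length < full_length_threshold
            or r1.transcript_id != r2.transcript_id
        ):
            diag["n_pair_skipped"] += 1
            continue
        length = (r2.start - r1.start) + r2.aligned_length
        if length <= 0:
            diag["n_discordant"] += 1
            continue
        hist[length] += 1
        diag["n_paired"] += 1
    return hist, diag


def length_class_fractions(length_hist: Counter | dict) -> dict[str, float]:
    """Fractions of fragments <50 nt, 50-200 nt, >200 nt."""
    total = sum(length_hist.values())
    if total == 0:
        raise ValueError("empty length histogram")
    lt50 = sum(c for l, c in length_hist.items() if l < 50)
    gt200 = sum(c for l, c in length_hist.items() if l > 200)
    return {
        "lt50": lt50 / total,
        "mid50_200": (total - lt50 - gt200) / total,
        "gt200": gt200 / total,
    }


# ---------------------------------------------------------------------------
# end contexts and statistics
# ---------------------------------------------------------------------------

def end_contexts(
    fragments, refset: ReferenceSet
) -> list[FragmentEndContext]:
    """Reference end contexts for (transcript_id, start, end) fragments.

    ``fragments`` may also yield :class:`AlignmentRecord`s.  Motif windows
    span [start-2, start+2) and [end-2, end+2); a window that overruns the
    transcript edge yields no motif but still defines the end base.
    """
    out = []
    for frag in fragments:
        if isinstance(frag, AlignmentRecord):
            tid, start, end = frag.transcript_id, frag.start, frag.end
        else:
            tid, start, end = frag
        seq = refset.sequence(tid)
        L = len(seq)
        if not (0 <= start < end <= L):
            raise ValueError(f"fragment [{start},{end}) outside {tid!r} (len {L})")
        m5 = seq[start - 2 : start + 2] if start >= 2 and start + 2 <= L else None
        m3 = seq[end - 2 : end + 2] if end - 2 >= 0 and end + 2 <= L else None
        out.append(
            FragmentEndContext(tid, start, end, seq[start], seq[end - 1], m5, m3)
        )
    return out


def end_statistics(contexts: list[FragmentEndContext]) -> dict:
    """End-base frequencies plus the cleavage-signature summaries.

    Returns 5'/3' base frequency dicts over A/C/G/T (N-ended fragments
    excluded), the 3' pyrimidine/purine ratio (C+T)/(A+G) — +inf with all
    pyrimidine 3' ends — and the 5' adenine rate.
    """
    if not contexts:
        raise ValueError("no fragment end contexts")
    c5 = Counter(c.end5_base for c in contexts if c.end5_base in BASES)
    c3 = Counter(c.end3_base for c in contexts if c.end3_base in BASES)
    n5, n3 = sum(c5.values()), sum(c3.values())
    freq5 = {b: c5.get(b, 0) / n5 for b in BASES}
    freq3 = {b: c3.get(b, 0) / n3 for b in BASES}
    purines = freq3["A"] + freq3["G"]
    ratio = (freq3["C"] + freq3["T"]) / purines if purines > 0 else inf
    return {
        "end5_base_freq": freq5,
        "end3_base_freq": freq3,
        "py_pu_ratio_3p": ratio,
        "adenine_rate_5p": freq5["A"],
    }


def motif_profile(
    contexts: list[FragmentEndContext], end: str = "three_prime"
) -> np.ndarray:
    """256-entry percentage vector of 4-mer end motifs at one end.

    Motifs containing N are excluded from numerator and denominator; the
    vector always has exactly 256 entries and sums to 100.
    """
    if end not in ("five_prime", "three_prime"):
        raise ValueError("end must be 'five_prime' or 'three_prime'")
    counts = np.zeros(256)
    for c in contexts:
        motif = c.end5_motif if end == "five_prime" else c.end3_motif
        if motif is None:
            continue
        idx = _MOTIF_INDEX.get(motif)
        if idx is not None:  # motifs containing N have no index
            counts[idx] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError(f"no defined {end} motif in any context")
    return counts / total * 100.0


def motif_series(profile: np.ndarray) -> pd.Series:
    return pd.Series(profile, index=list(MOTIFS))


# ---------------------------------------------------------------------------
# per-sample profile
# ---------------------------------------------------------------------------

@dataclass
class FragmentProfile:
    """All fragment-level summaries of one sample (or one biotype slice)."""

    length_hist: Counter
    class_fractions: dict[str, float]
    end5_base_freq: dict[str, float]
    end3_base_freq: dict[str, float]
    py_pu_ratio_3p: float
    adenine_rate_5p: float
    motif5: np.ndarray
    motif3: np.ndarray


def profile_fragments(
    fragments, refset: ReferenceSet, length_hist: Counter | None = None
) -> FragmentProfile:
    """Compute the full :class:`FragmentProfile` of one fragment set."""
    contexts = end_contexts(fragments, refset)
    if length_hist is None:
        length_hist = Counter(c.frag_end - c.frag_start for c in contexts)
    stats = end_statistics(contexts)
    return FragmentProfile(
        length_hist=length_hist,
        class_fractions=length_class_fractions(length_hist),
        motif5=motif_profile(contexts, "five_prime"),
        motif3=motif_profile(contexts, "three_prime"),
        **stats,
    )
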