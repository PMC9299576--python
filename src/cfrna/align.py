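"""Forward-strand, <=1-mismatch, best-stratum alignment and tier assignment.

The aligner reproduces v1-mode short-read semantics: reads align end to
end (no clipping, no gaps) with at most one substitution; all placements
in the best mismatch stratum are reported (any 0-mismatch hit suppresses
all 1-mismatch hits) and, by default, only the forward strand is
searched, matching a stranded cfRNA library.

Reads are assigned tier by tier — depletion (rRNA/Y RNA/vault RNA) first,
then miRNA hairpins, then tRNA/piRNA, then mRNA/lncRNA, then other
non-coding RNA — with the first tier producing an alignment claiming the
read.  Within the miRNA tier a positional filter keeps only reads whose
termini sit within 3 nt (5' end) and 5 nt (3' end) of an annotated mature
miRNA.  Within the small tier, best-stratum hits to both tRNA and piRNA
resolve to tRNA, piRNA annotations being the less confident.

Candidate placements come from a pigeonhole seed search on a k-mer index:
with at most one mismatch in a read, at least one of the read's two
halves matches the reference exactly, so the k-mers at offsets 0 and
len//2 enumerate every placement.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .references import KmerIndex, ReferenceSet, TranscriptRecord
from .simulate import revcomp

MIRNA_MAX_START_OFFSET = 3
MIRNA_MAX_END_OFFSET = 5

#: Within-tier biotype priority on best-stratum ties: tRNA annotations
#: outrank piRNA; protein-coding outranks lncRNA when one read hits both.
TIER_BIOTYPE_PRIORITY = {
    "small": ("tRNA", "piRNA"),
    "long": ("mRNA", "lncRNA"),
}


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    transcript_id: str
    start: int  # 0-based on the transcript
    aligned_length: int
    mismatches: int
    orientation: str = "forward"  # forward | reverse_complement

    @property
    def end(self) -> int:
        return self.start + self.aligned_length


@dataclass(frozen=True)
class AssignedRead:
    read_id: str
    tier: str
    biotype: str
    target_ids: tuple[str, ...]  # gene ids, or mature names in the miRNA tier
    weight_per_target: float
    transcript_hits: tuple[tuple[str, int], ...] = ()  # (transcript_id, start)
    read_length: int = 0  # cleaned read length == aligned length (end-to-end)


class TierAligner:
    """<=1-mismatch end-to-end aligner over one set of transcripts."""

    def __init__(self, transcripts: list[TranscriptRecord], k: int = 8) -> None:
        self.k = k
        self.index = KmerIndex(transcripts, k)
        self.seqs = {
            t.transcript_id: np.frombuffer(t.sequence.encode(), dtype=np.uint8)
            for t in transcripts
        }

    def align(
        self, read_id: str, bases: str, orientation: str = "forward"
    ) -> list[AlignmentRecord]:
        """All best-stratum placements of ``bases``, deterministically ordered."""
        L = len(bases)
        k = self.k
        if L < 2 * k:
            # pigeonhole needs both halves >= k; such reads are below the
            # pipeline's 17-nt floor for the default k=8
            raise ValueError(f"read shorter than 2k={2 * k} nt")
        half = L // 2
        candidates: set[tuple[str, int]] = set()
        for tid, o in self.index.lookup(bases[:k]):
            candidates.add((tid, o))
        for tid, o in self.index.lookup(bases[half : half + k]):
            candidates.add((tid, o - half))

        read_arr = np.frombuffer(bases.encode(), dtype=np.uint8)
        hits: list[tuple[int, str, int]] = []
        for tid, s in candidates:
            if s < 0:
                continue
            ref = self.seqs[tid]
            if s + L > len(ref):
                continue
            mm = int(np.count_nonzero(ref[s : s + L] != read_arr))
            if mm <= 1:
                hits.append((mm, tid, s))
        if not hits:
            return []
        best = min(h[0] for h in hits)
        return [
            AlignmentRecord(read_id, tid, s, L, mm, orientation)
            for mm, tid, s in sorted(hits)
            if mm == best
        ]


def align_v1(
    read_id: str,
    bases: str,
    transcripts: list[TranscriptRecord],
    aligner: TierAligner | None = None,
) -> list[AlignmentRecord]:
    """Convenience wrapper: best-stratum forward alignments of one read."""
    if aligner is None:
        aligner = TierAligner(transcripts)
    return aligner.align(read_id, bases)


# ---------------------------------------------------------------------------
# miRNA positional filter
# ---------------------------------------------------------------------------

def mirna_positional_filter(
    alignment: AlignmentRecord, matures
) -> tuple[str, str | None, tuple[int, int] | None]:
    """Check a hairpin alignment against the mature coordinates.

    Returns ``(status, mature_name, (start_offset, end_offset))`` with
    status ``kept`` when some mature's termini are within 3 nt at the
    start and 5 nt at the end of the read placement, ``rejected`` when no
    mature qualifies, and ``no_mature`` when the hairpin carries no
    annotation.  Among qualifying matures the smallest start offset wins,
    ties broken by the smaller end offset.
    """
    if not matures:
        return ("no_mature", None, None)
    read_start, read_end = alignment.start, alignment.end
    best = None
    for m in matures:
        d_start = abs(read_start - m.start)
        d_end = abs(read_end - m.end)
        if d_start <= MIRNA_MAX_START_OFFSET and d_end <= MIRNA_MAX_END_OFFSET:
            key = (d_start, d_end, m.mature_name)
            if best is None or key < best:
                best = key
    if best is None:
        return ("rejected", None, None)
    return ("kept", best[2], (best[0], best[1]))


# ---------------------------------------------------------------------------
# tiered assignment
# ---------------------------------------------------------------------------

class TieredAligner:
    """Per-tier aligners built once over a ReferenceSet."""

    def __init__(self, refset: ReferenceSet, k: int = 8) -> None:
        self.refset = refset
        self.k = k
        self.tier_names = [name for name, _ in refset.tiers]
        self.aligners: dict[str, TierAligner] = {}
        for name in self.tier_names:
            transcripts = refset.tier_transcripts(name)
            if transcripts:
                self.aligners[name] = TierAligner(transcripts, k)


def assign_tiers(
    reads,
    refset: ReferenceSet,
    k: int = 8,
    mirna_fallthrough: bool = True,
    tiered: TieredAligner | None = None,
) -> tuple[list[AssignedRead], dict]:
    """Assign each cleaned read to the first tier it aligns in.

    ``reads`` yields objects with ``read_id`` and ``bases``.  Returns the
    assignments of non-depleted, mapped reads plus a conservation-checked
    stats dict (``n_input = n_depleted + sum(assigned) + n_unmapped``).
    """
    if tiered is None:
        tiered = TieredAligner(refset, k)
    stats = {
        "n_input": 0,
        "n_depleted": 0,
        "n_unmapped": 0,
        "per_tier": {name: 0 for name in tiered.tier_names if name != "depletion"},
    }
    assigned: list[AssignedRead] = []
    for read in reads:
        stats["n_input"] += 1
        result = _assign_one(read.read_id, read.bases, tiered, mirna_fallthrough)
        if result == "depleted":
            stats["n_depleted"] += 1
        elif result is None:
            stats["n_unmapped"] += 1
        else:
            stats["per_tier"][result.tier] += 1
            assigned.append(result)
    return assigned, stats


def _assign_one(
    read_id: str, bases: str, tiered: TieredAligner, mirna_fallthrough: bool
) -> AssignedRead | str | None:
    refset = tiered.refset
    for tier_name in tiered.tier_names:
        aligner = tiered.aligners.get(tier_name)
        if aligner is None:
            continue
        alns = aligner.align(read_id, bases)
        if not alns:
            continue
        if tier_name == "depletion":
            return "depleted"
        if tier_name == "miRNA":
            picked = _pick_mature(alns, refset)
            if picked is None:
                if mirna_fallthrough:
                    continue
                return None
            return AssignedRead(
                read_id, "miRNA", "miRNA_hairpin", (picked,), 1.0,
                tuple((a.transcript_id, a.start) for a in alns),
                len(bases),
            )
        # biotype tie-breaking inside mixed tiers
        biotypes = {refset.biotype(a.transcript_id) for a in alns}
        for preferred in TIER_BIOTYPE_PRIORITY.get(tier_name, ()):
            if preferred in biotypes:
                alns = [
                    a for a in alns
                    if refset.biotype(a.transcript_id) == preferred
                ]
                biotypes = {preferred}
                break
        genes = tuple(sorted({refset.gene(a.transcript_id) for a in alns}))
        return AssignedRead(
            read_id,
            tier_name,
            sorted(biotypes)[0],
            genes,
            1.0 / len(genes),
            tuple((a.transcript_id, a.start) for a in alns),
            len(bases),
        )
    return None


def _pick_mature(alns, refset) -> str | None:
    best = None
    for a in alns:
        status, name, offsets = mirna_positional_filter(
            a, refset.matures_on(a.transcript_id)
        )
        if status == "kept":
            key = (*offsets, name)
            if best is None or key < best:
                best = key
    return None if best is None else best[2]


# ---------------------------------------------------------------------------
# sense/antisense diagnostic (relaxes the forward-only rule)
# ---------------------------------------------------------------------------

def sense_antisense_ratio(
    reads, refset: ReferenceSet, k: int = 8
) -> dict[str, dict[str, float]]:
    """Per-biotype sense/antisense read fractions.

    Each read is aligned both as-is and reverse-complemented against all
    transcripts; forward-only best hits count sense, reverse-only count
    antisense, and equal-stratum ties count sense.  Fractions sum to 1
    within each biotype that received reads.
    """
    aligner = TierAligner(list(refset.transcripts.values()), k)
    counts: dict[str, dict[str, int]] = {}
    for read in reads:
        fw = aligner.align(read.read_id, read.bases)
        rc = aligner.align(read.read_id, revcomp(read.bases), "reverse_complement")
        fw_mm = fw[0].mismatches if fw else 2
        rc_mm = rc[0].mismatches if rc else 2
        if fw_mm > 1 and rc_mm > 1:
            continue
        if fw_mm <= rc_mm:
            strand, alns = "sense", fw
        else:
            strand, alns = "antisense", rc
        biotype = refset.biotype(alns[0].transcript_id)
        counts.setdefault(biotype, {"sense": 0, "antisense": 0})[strand] += 1
    out: dict[str, dict[str, float]] = {}
    for biotype, c in counts.items():
        total = c["sense"] + c["antisense"]
        out[biotype] = {
            "sense": c["sense"] / total,
            "antisense": c["antisense"] / total,
        }
    return out


# ---------------------------------------------------------------------------
# SAM export
# ---------------------------------------------------------------------------

def write_sam(
    alignments: list[AlignmentRecord], refset: ReferenceSet, path: str | Path
) -> None:
    """Write alignments as text SAM (1-based POS, NM tag = mismatches)."""
    import pysam

    tids = sorted(refset.transcripts)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": tid, "LN": refset.transcripts[tid].length} for tid in tids
        ],
    }
    tid_idx = {tid: i for i, tid in enumerate(tids)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for a in alignments:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = a.read_id
            seg.reference_id = tid_idx[a.transcript_id]
            seg.reference_start = a.start
            seg.cigarstring = f"{a.aligned_length}M"
            seg.flag = 16 if a.orientation == "reverse_complement" else 0
            seg.mapping_quality = 255
            seg.set_tag("NM", a.mismatches)
            out.write(seg)
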