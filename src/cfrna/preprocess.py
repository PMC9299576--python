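"""Read cleanup: 3' adapter and poly(A) removal, quality trimming, filters.

The cleanup contract mirrors a standard small-RNA trimming stack:

1. locate the 3' adapter (full or end-anchored prefix match, minimum 5 nt,
   up to 10% mismatches) and cut it and everything after;
2. trim low-quality ends (Phred < 15) from both read ends;
3. strip a trailing poly(A) run of at least ``min_polyA_run`` bases
   (the library's template-independent tail);
4. drop reads shorter than 17 nt or with more than 10% unknown bases.

Paired reads are merged by maximal suffix/prefix overlap of read 1 with
the reverse complement of read 2, so downstream fragment analyses can
treat merged pairs as single-end reads.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .simulate import revcomp

DEFAULT_QUAL_THRESHOLD = 15
DEFAULT_MIN_LEN = 17
DEFAULT_MAX_N_FRAC = 0.10
DEFAULT_MIN_POLYA_RUN = 5
DEFAULT_MIN_OVERLAP = 10
DEFAULT_MAX_MISMATCH_RATE = 0.1
ADAPTER_MIN_MATCH = 5
ADAPTER_MISMATCH_RATE = 0.10


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read; ``quals`` is a Phred+33 string of equal length."""

    read_id: str
    bases: str
    quals: str
    mate: str = "single"  # single | R1 | R2

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"{self.read_id!r}: {len(self.bases)} bases vs "
                f"{len(self.quals)} qualities"
            )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def phred(self) -> list[int]:
        return [ord(c) - 33 for c in self.quals]


@dataclass
class CleanupReport:
    n_input: int = 0
    n_adapter_trimmed: int = 0
    n_polyA_trimmed: int = 0
    n_removed_short: int = 0
    n_removed_N: int = 0

    @property
    def n_pass(self) -> int:
        return self.n_input - self.n_removed_short - self.n_removed_N

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_adapter_trimmed": self.n_adapter_trimmed,
            "n_polyA_trimmed": self.n_polyA_trimmed,
            "n_removed_short": self.n_removed_short,
            "n_removed_N": self.n_removed_N,
            "n_pass": self.n_pass,
        }


# ---------------------------------------------------------------------------
# adapter location
# ---------------------------------------------------------------------------

def _find_adapter(bases: str, adapter: str) -> int:
    """Return the cut position of the 3' adapter, or -1 if absent.

    A match is the adapter (or an adapter prefix reaching the read end) of
    length >= 5 with at most 10% mismatches.  The longest match wins; ties
    go to the leftmost occurrence.  Exact matches are tried first via fast
    substring search before falling back to the tolerant scan.
    """
    L, A = len(bases), len(adapter)
    if L < ADAPTER_MIN_MATCH:
        return -1
    # fast path 1: exact full-adapter occurrence (leftmost)
    pos = bases.find(adapter)
    if pos != -1:
        return pos
    # fast path 2: exact adapter-prefix match flush with the read end
    max_ov = min(A, L)
    for ov in range(max_ov, ADAPTER_MIN_MATCH - 1, -1):
        if bases.endswith(adapter[:ov]):
            return L - ov
    # tolerant scan: longest match, leftmost on ties
    best_pos, best_ov = -1, 0
    for i in range(0, L - ADAPTER_MIN_MATCH + 1):
        ov = min(A, L - i)
        if ov <= best_ov:
            break  # positions further right can only match shorter
        allowed = int(ADAPTER_MISMATCH_RATE * ov)
        mism = 0
        for a, b in zip(bases[i : i + ov], adapter[:ov]):
            if a != b:
                mism += 1
                if mism > allowed:
                    break
        else:
            best_pos, best_ov = i, ov
    return best_pos


def trim_read(
    read: ReadRecord,
    adapter_3p: str,
    qual_threshold: int = DEFAULT_QUAL_THRESHOLD,
    min_polyA_run: int = DEFAULT_MIN_POLYA_RUN,
) -> ReadRecord:
    """Adapter cut, then two-sided quality trim, then poly(A) strip."""
    trimmed, _, _ = trim_read_ex(read, adapter_3p, qual_threshold, min_polyA_run)
    return trimmed


def trim_read_ex(
    read: ReadRecord,
    adapter_3p: str,
    qual_threshold: int = DEFAULT_QUAL_THRESHOLD,
    min_polyA_run: int = DEFAULT_MIN_POLYA_RUN,
) -> tuple[ReadRecord, bool, bool]:
    """As :func:`trim_read`, also reporting (adapter_found, polyA_found)."""
    if not adapter_3p:
        raise ValueError("adapter_3p must be non-empty")
    bases, quals = read.bases, read.quals

    pos = _find_adapter(bases, adapter_3p)
    adapter_found = pos != -1
    if adapter_found:
        bases, quals = bases[:pos], quals[:pos]

    qcut = chr(qual_threshold + 33)
    end = len(quals)
    while end > 0 and quals[end - 1] < qcut:
        end -= 1
    start = 0
    while start < end and quals[start] < qcut:
        start += 1
    bases, quals = bases[start:end], quals[start:end]

    n_a = len(bases) - len(bases.rstrip("A"))
    polyA_found = n_a >= min_polyA_run
    if polyA_found:
        bases, quals = bases[: len(bases) - n_a], quals[: len(quals) - n_a]

    return replace(read, bases=bases, quals=quals), adapter_found, polyA_found


def filter_reads(
    reads: list[ReadRecord],
    min_len: int = DEFAULT_MIN_LEN,
    max_n_frac: float = DEFAULT_MAX_N_FRAC,
    report: CleanupReport | None = None,
) -> tuple[list[ReadRecord], CleanupReport]:
    """Keep reads with length >= 17 nt and N fraction <= 10% (strict >)."""
    if report is None:
        report = CleanupReport()
    report.n_input += len(reads)
    kept = []
    for r in reads:
        if len(r) < min_len:
            report.n_removed_short += 1
        elif len(r) > 0 and r.bases.count("N") / len(r) > max_n_frac:
            report.n_removed_N += 1
        else:
            kept.append(r)
    return kept, report


def clean_reads(
    reads: list[ReadRecord],
    adapter_3p: str,
    qual_threshold: int = DEFAULT_QUAL_THRESHOLD,
    min_polyA_run: int = DEFAULT_MIN_POLYA_RUN,
    min_len: int = DEFAULT_MIN_LEN,
    max_n_frac: float = DEFAULT_MAX_N_FRAC,
) -> tuple[list[ReadRecord], CleanupReport]:
    """Full cleanup: trim every read, then apply the length/N filters."""
    report = CleanupReport()
    trimmed = []
    for r in reads:
        t, ad, pa = trim_read_ex(r, adapter_3p, qual_threshold, min_polyA_run)
        report.n_adapter_trimmed += ad
        report.n_polyA_trimmed += pa
        trimmed.append(t)
    return filter_reads(trimmed, min_len, max_n_frac, report)


# ---------------------------------------------------------------------------
# paired-read merging
# ---------------------------------------------------------------------------

def merge_pairs(
    r1: ReadRecord,
    r2: ReadRecord,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
) -> ReadRecord | None:
    """Assemble a pair into one insert, or None without a valid overlap.

    Read 2 is reverse-complemented; the longest suffix(r1)/prefix(rc-r2)
    overlap of length >= ``min_overlap`` whose mismatch rate is at most
    ``max_mismatch_rate`` wins.  Read 1 bases take precedence inside the
    overlap.  Adapter read-through is handled: when rc-r2 matches exactly
    inside read 1 with read-1 bases extending past its end (an undetected
    tail/adapter residue shorter than the trimmer's minimum match), the
    insert ends with rc-r2 and the residue is discarded.
    """
    rc2 = revcomp(r2.bases)
    rq2 = r2.quals[::-1]
    l1, l2 = len(r1), len(rc2)
    if min(l1, l2) < min_overlap:
        return None

    best_ov = 0
    # exact overlaps first: every occurrence of the rc2 seed in r1
    seed = rc2[:min_overlap]
    p = r1.bases.find(seed)
    while p != -1:
        ov = min(l1 - p, l2)
        if ov >= min_overlap and r1.bases[p : p + ov] == rc2[:ov]:
            if l1 - p <= l2:
                best_ov = max(best_ov, ov)
            else:
                # rc2 fully contained: read-through, cut read-1 residue
                stem = r1.read_id.rsplit("/", 1)[0]
                return ReadRecord(
                    stem, r1.bases[: p + l2], r1.quals[: p + l2], mate="single"
                )
        p = r1.bases.find(seed, p + 1)
    if best_ov == 0:
        # tolerant scan from longest overlap down
        for ov in range(min(l1, l2), min_overlap - 1, -1):
            allowed = int(max_mismatch_rate * ov)
            mism = 0
            a, b = r1.bases[l1 - ov :], rc2[:ov]
            ok = True
            for x, y in zip(a, b):
                if x != y:
                    mism += 1
                    if mism > allowed:
                        ok = False
                        break
            if ok:
                best_ov = ov
                break
    if best_ov == 0:
        return None
    stem = r1.read_id.rsplit("/", 1)[0]
    return ReadRecord(
        stem,
        r1.bases + rc2[best_ov:],
        r1.quals + rq2[best_ov:],
        mate="single",
    )


# ---------------------------------------------------------------------------
# FASTQ IO
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path, mate: str = "single") -> list[ReadRecord]:
    out = []
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            out.append(ReadRecord(title.split()[0], seq.upper(), qual, mate))
    return out


def write_fastq(path: str | Path, reads: list[ReadRecord]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{r.quals}\n")
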