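"""Multi-biotype transcript references and the alignment tiers built on them.

A :class:`ReferenceSet` holds biotype-annotated transcript sequences
(rRNA/Y RNA/vault RNA, miRNA hairpins, tRNA, piRNA, mRNA, lncRNA, other
non-coding RNA) together with mature-miRNA coordinates on their hairpins,
organized into the ordered alignment tiers the pipeline maps against:
abundant-RNA depletion first, then miRNA, then other small RNAs, then
mRNA/lncRNA, then everything else.

All coordinates are 0-based half-open. Sequences are stored uppercase in
DNA space (U converted to T) so that reads and references share one
alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BIOTYPES = (
    "rRNA",
    "Y_RNA",
    "vtRNA",
    "miRNA_hairpin",
    "tRNA",
    "piRNA",
    "mRNA",
    "lncRNA",
    "other_ncRNA",
)

#: Ordered tier definitions: a read is tested tier by tier and the first
#: tier producing an alignment claims it.  The depletion tier models the
#: in-silico removal of abundant structural RNAs.
DEFAULT_TIERS: tuple[tuple[str, frozenset[str]], ...] = (
    ("depletion", frozenset({"rRNA", "Y_RNA", "vtRNA"})),
    ("miRNA", frozenset({"miRNA_hairpin"})),
    ("small", frozenset({"tRNA", "piRNA"})),
    ("long", frozenset({"mRNA", "lncRNA"})),
    ("other", frozenset({"other_ncRNA"})),
)

DEPLETION_TIER = "depletion"


@dataclass(frozen=True)
class TranscriptRecord:
    """One reference transcript with its gene and biotype annotation."""

    transcript_id: str
    gene_id: str
    biotype: str
    sequence: str

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValueError(
                f"unknown biotype {self.biotype!r} for {self.transcript_id!r}; "
                f"expected one of {', '.join(BIOTYPES)}"
            )
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"empty sequence for {self.transcript_id!r}")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(
                f"invalid characters {sorted(bad)} in {self.transcript_id!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA located on its hairpin precursor (0-based half-open)."""

    mature_name: str
    hairpin_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"bad mature coordinates [{self.start}, {self.end}) "
                f"for {self.mature_name!r}"
            )


class ReferenceSet:
    """Transcripts + mature-miRNA coordinates + ordered alignment tiers."""

    def __init__(
        self,
        transcripts: Iterable[TranscriptRecord],
        matures: Iterable[MatureMiRNA] = (),
        tiers: tuple[tuple[str, frozenset[str]], ...] = DEFAULT_TIERS,
    ) -> None:
        self.transcripts: dict[str, TranscriptRecord] = {}
        for t in transcripts:
            if t.transcript_id in self.transcripts:
                raise ValueError(f"duplicate transcript_id {t.transcript_id!r}")
            self.transcripts[t.transcript_id] = t
        self.tiers = tiers
        tiered = {b for _, bts in tiers for b in bts}
        for t in self.transcripts.values():
            if t.biotype not in tiered:
                raise ValueError(
                    f"transcript {t.transcript_id!r} biotype {t.biotype!r} "
                    "belongs to no tier"
                )
        self.matures: list[MatureMiRNA] = []
        self._matures_by_hairpin: dict[str, list[MatureMiRNA]] = {}
        for m in matures:
            hp = self.transcripts.get(m.hairpin_id)
            if hp is None:
                raise ValueError(f"mature {m.mature_name!r} references unknown "
                                 f"hairpin {m.hairpin_id!r}")
            if hp.biotype != "miRNA_hairpin":
                raise ValueError(f"hairpin {m.hairpin_id!r} has biotype "
                                 f"{hp.biotype!r}, not miRNA_hairpin")
            if m.end > hp.length:
                raise ValueError(f"mature {m.mature_name!r} end {m.end} exceeds "
                                 f"hairpin length {hp.length}")
            self.matures.append(m)
            self._matures_by_hairpin.setdefault(m.hairpin_id, []).append(m)

    def __len__(self) -> int:
        return len(self.transcripts)

    def sequence(self, transcript_id: str) -> str:
        return self.transcripts[transcript_id].sequence

    def biotype(self, transcript_id: str) -> str:
        return self.transcripts[transcript_id].biotype

    def gene(self, transcript_id: str) -> str:
        return self.transcripts[transcript_id].gene_id

    def matures_on(self, hairpin_id: str) -> list[MatureMiRNA]:
        return self._matures_by_hairpin.get(hairpin_id, [])

    def tier_transcripts(self, tier_name: str) -> list[TranscriptRecord]:
        biotypes = dict(self.tiers)[tier_name]
        return [t for t in self.transcripts.values() if t.biotype in biotypes]

    def by_biotype(self, biotype: str) -> list[TranscriptRecord]:
        return [t for t in self.transcripts.values() if t.biotype == biotype]


# ---------------------------------------------------------------------------
# serialization: FASTA + 3-column annotation TSV + mature-coordinate TSV
# ---------------------------------------------------------------------------

def load_references(
    fasta_path: str | Path,
    annotation_path: str | Path,
    mature_path: str | Path | None = None,
) -> ReferenceSet:
    """Load a :class:`ReferenceSet` from FASTA + annotation TSV (+ mature TSV).

    The annotation TSV has columns ``transcript_id``, ``gene_id``,
    ``biotype``; the mature TSV has ``mature_name``, ``hairpin_id``,
    ``start``, ``end`` (0-based half-open).  Every FASTA record must have
    an annotation row; a missing row or an unknown biotype is a hard error.
    """
    annotation: dict[str, tuple[str, str]] = {}
    with open(annotation_path) as fh:
        header = _read_tsv_header(fh, ("transcript_id", "gene_id", "biotype"))
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            annotation[row["transcript_id"]] = (row["gene_id"], row["biotype"])

    transcripts = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in annotation:
            raise ValueError(f"FASTA record {rec.id!r} has no annotation row")
        gene_id, biotype = annotation[rec.id]
        transcripts.append(
            TranscriptRecord(rec.id, gene_id, biotype, str(rec.seq))
        )

    matures: list[MatureMiRNA] = []
    if mature_path is not None:
        with open(mature_path) as fh:
            header = _read_tsv_header(
                fh, ("mature_name", "hairpin_id", "start", "end")
            )
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                matures.append(
                    MatureMiRNA(
                        row["mature_name"],
                        row["hairpin_id"],
                        int(row["start"]),
                        int(row["end"]),
                    )
                )
    return ReferenceSet(transcripts, matures)


def save_references(
    refset: ReferenceSet,
    fasta_path: str | Path,
    annotation_path: str | Path,
    mature_path: str | Path | None = None,
) -> None:
    """Write FASTA + annotation TSV (+ mature TSV); inverse of load."""
    records = [
        SeqRecord(Seq(t.sequence), id=t.transcript_id, description="")
        for t in refset.transcripts.values()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(annotation_path, "w") as fh:
        fh.write("transcript_id\tgene_id\tbiotype\n")
        for t in refset.transcripts.values():
            fh.write(f"{t.transcript_id}\t{t.gene_id}\t{t.biotype}\n")
    if mature_path is not None:
        with open(mature_path, "w") as fh:
            fh.write("# coordinates are 0-based half-open on the hairpin\n")
            fh.write("mature_name\thairpin_id\tstart\tend\n")
            for m in refset.matures:
                fh.write(f"{m.mature_name}\t{m.hairpin_id}\t{m.start}\t{m.end}\n")


def _read_tsv_header(fh, required: tuple[str, ...]) -> list[str]:
    line = fh.readline()
    while line.startswith("#"):
        line = fh.readline()
    header = line.rstrip("\n").split("\t")
    missing = set(required) - set(header)
    if missing:
        raise ValueError(f"annotation file missing columns {sorted(missing)}")
    return header


# ---------------------------------------------------------------------------
# k-mer index used by the v1-mode aligner
# ---------------------------------------------------------------------------

class KmerIndex:
    """Exact k-mer → (transcript_id, offset) occurrence index.

    Every k-mer of every indexed transcript is stored, so any exact match
    of length >= k is discoverable from its first k bases.  Used for seed
    lookup by the pigeonhole strategy of the <=1-mismatch aligner.
    """

    def __init__(self, transcripts: Iterable[TranscriptRecord], k: int) -> None:
        if k < 8:
            raise ValueError("k must be >= 8")
        self.k = k
        self.occurrences: dict[str, list[tuple[str, int]]] = {}
        self.lengths: dict[str, int] = {}
        for t in transcripts:
            self.lengths[t.transcript_id] = t.length
            seq = t.sequence
            for o in range(t.length - k + 1):
                self.occurrences.setdefault(seq[o : o + k], []).append(
                    (t.transcript_id, o)
                )

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.occurrences.get(kmer, [])


def build_kmer_index(refset_or_transcripts, k: int = 12) -> KmerIndex:
    """Build a :class:`KmerIndex` over a ReferenceSet or transcript list."""
    if isinstance(refset_or_transcripts, ReferenceSet):
        transcripts: Iterable[TranscriptRecord] = (
            refset_or_transcripts.transcripts.values()
        )
    else:
        transcripts = refset_or_transcripts
    return KmerIndex(transcripts, k)
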