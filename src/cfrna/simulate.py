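"""Synthetic cell-free RNA library generator with per-fragment ground truth.

The generator emulates the statistical structure a cfRNA pipeline has to
recover, without any real sequencing data:

* per-gene molar abundances drawn log-normally within each biotype, and a
  biotype mixture giving the expected fragment share of each RNA class;
* RNase-A-like degradation: a fragment's 3' end is a cut site drawn with
  relative weight ``w_py`` when the cut base is a pyrimidine (C/T), weight
  1 otherwise.  Cleavage by RNase A leaves 5'-hydroxyl / 3'-phosphate
  ends, so the bias is applied only to fragments of that end-chemistry
  channel; a second channel of pre-phosphorylated (5'P/3'OH) fragments is
  cut uniformly;
* capture gating by end chemistry: without polynucleotide-kinase (PNK)
  treatment only 5'P/3'OH fragments can be adapter-ligated and tailed;
  PNK treatment repairs RNase-cleaved ends and makes every fragment
  eligible.  This is what couples library chemistry to 3'-end base
  composition;
* in-silico depletion of abundant structural RNAs (rRNA / Y RNA / vault
  RNA) at a configurable efficiency;
* a fragment-length mixture dominated by short (<50 nt) pieces, plus a
  minor long component, matching the degraded state of circulating RNA;
* library chemistry on the read level: each insert is emitted as fragment
  sequence + poly(A) tail + 3' adapter, truncated to the read length;
  paired mode adds a mate read taken reverse-complemented from the
  fragment 3' terminus.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .references import MatureMiRNA, ReferenceSet, TranscriptRecord

#: End chemistry of a fragment: RNase-A cleavage products carry
#: 5'-hydroxyl/3'-phosphate (OH5_P3); intact or kinase-repaired ends are
#: 5'-phosphate/3'-hydroxyl (P5_OH3), the ligatable/tailable chemistry.
OH5_P3 = "OH5_P3"
P5_OH3 = "P5_OH3"

DEPLETION_BIOTYPES = frozenset({"rRNA", "Y_RNA", "vtRNA"})

#: Bundled 60-nt 3' sequencing adapter (arbitrary fixed sequence, chosen
#: once; long enough that short inserts read through poly(A) into adapter).
DEFAULT_ADAPTER_3P = (
    "AGATCGGAAGAGCACACGTCTGAACTCCAGTCACGGATCCTTATCTCGTATGCCGTCTTC"
)

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class LengthMixture:
    """Fragment-length model: short (negative-binomial) + long (uniform).

    The short component is ``offset + NB(r, p)`` with mode in the 20-40 nt
    range at the defaults; the long component is uniform on
    ``[long_min, long_max]``.  ``short_fraction`` is the mixing weight of
    the short component.
    """

    short_fraction: float = 0.85
    nb_r: int = 4
    nb_p: float = 0.15
    offset: int = 10
    long_min: int = 50
    long_max: int = 500

    def __post_init__(self) -> None:
        if not 0.0 <= self.short_fraction <= 1.0:
            raise ValueError("short_fraction must be in [0, 1]")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        short = self.offset + rng.negative_binomial(self.nb_r, self.nb_p, n)
        long = rng.integers(self.long_min, self.long_max + 1, n)
        lengths = np.where(rng.random(n) < self.short_fraction, short, long)
        return np.maximum(lengths, 1)

    def mass_below(self, x: int) -> float:
        """P(length < x) under the mixture (no transcript-edge clipping)."""
        p_short = stats.nbinom.cdf(x - 1 - self.offset, self.nb_r, self.nb_p)
        if x <= self.long_min:
            p_long = 0.0
        elif x > self.long_max:
            p_long = 1.0
        else:
            p_long = (x - self.long_min) / (self.long_max - self.long_min + 1)
        s = self.short_fraction
        return s * p_short + (1 - s) * p_long


DEFAULT_BIOTYPE_MIX = {
    "rRNA": 0.05,
    "Y_RNA": 0.03,
    "vtRNA": 0.02,
    "miRNA_hairpin": 0.25,
    "tRNA": 0.15,
    "piRNA": 0.05,
    "mRNA": 0.30,
    "lncRNA": 0.10,
    "other_ncRNA": 0.05,
}


@dataclass
class SimulationConfig:
    """All knobs of one simulated library; seed is mandatory."""

    seed: int
    n_fragments: int = 50_000
    biotype_mix: dict = field(default_factory=lambda: dict(DEFAULT_BIOTYPE_MIX))
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.0
    w_py: float = 4.0
    rnaseA_channel_prob: float = 0.8
    pnk_treated: bool = True
    depletion_enabled: bool = True
    depletion_rate: float = 0.9
    length_mixture: LengthMixture = field(default_factory=LengthMixture)
    read_length: int = 100
    paired: bool = False
    adapter_3p: str = DEFAULT_ADAPTER_3P
    polyA_len: int = 20
    error_rate: float = 0.0
    lowqual_tail: int = 0

    def __post_init__(self) -> None:
        if self.n_fragments <= 0:
            raise ValueError("n_fragments must be positive")
        total = sum(self.biotype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"biotype_mix sums to {total}, expected 1")
        for name in ("rnaseA_channel_prob", "depletion_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.w_py < 1.0:
            raise ValueError("w_py must be >= 1")


# ---------------------------------------------------------------------------
# reference simulation
# ---------------------------------------------------------------------------

DEFAULT_N_GENES = {
    "rRNA": 3,
    "Y_RNA": 2,
    "vtRNA": 2,
    "miRNA_hairpin": 20,
    "tRNA": 20,
    "piRNA": 20,
    "mRNA": 50,
    "lncRNA": 30,
    "other_ncRNA": 10,
}

DEFAULT_LENGTH_RANGES = {
    "rRNA": (1000, 2000),
    "Y_RNA": (80, 120),
    "vtRNA": (90, 110),
    "miRNA_hairpin": (60, 90),
    "tRNA": (70, 90),
    "piRNA": (26, 32),
    "mRNA": (500, 2000),
    "lncRNA": (300, 1500),
    "other_ncRNA": (100, 300),
}


def simulate_transcriptome(
    seed: int,
    n_genes_per_biotype: dict | None = None,
    length_ranges: dict | None = None,
    gc: float = 0.5,
) -> ReferenceSet:
    """Random reference transcripts with expected GC fraction ``gc``.

    One transcript per gene; every miRNA hairpin gets a single embedded
    mature miRNA of 20-23 nt placed with >=2 nt margins so that end-motif
    windows around mature termini stay inside the hairpin.
    """
    if not 0.0 < gc <= 1.0:
        raise ValueError("gc must be in (0, 1]")
    n_genes = dict(DEFAULT_N_GENES, **(n_genes_per_biotype or {}))
    ranges = dict(DEFAULT_LENGTH_RANGES, **(length_ranges or {}))
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.array(list("ACGT"))

    transcripts: list[TranscriptRecord] = []
    matures: list[MatureMiRNA] = []
    for biotype in sorted(n_genes):
        lo, hi = ranges[biotype]
        for i in range(n_genes[biotype]):
            gene_id = f"{biotype}_{i:04d}"
            tid = f"{gene_id}.t1"
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(alphabet[rng.choice(4, size=length, p=probs)])
            transcripts.append(TranscriptRecord(tid, gene_id, biotype, seq))
            if biotype == "miRNA_hairpin":
                mlen = int(rng.integers(20, 24))
                start = int(rng.integers(2, length - mlen - 1))
                matures.append(
                    MatureMiRNA(f"miR_{i:04d}", tid, start, start + mlen)
                )
    return ReferenceSet(transcripts, matures)


# ---------------------------------------------------------------------------
# fragmentation
# ---------------------------------------------------------------------------

def fragment_transcript(
    sequence: str,
    w_py: float,
    length_mixture: LengthMixture,
    rng: np.random.Generator,
    n_fragments: int = 1,
    rnaseA_channel_prob: float = 1.0,
) -> list[tuple[int, int, str]]:
    """Draw fragments from one transcript under the two-channel cut model.

    Each fragment's 3' end is a cut position ``e`` in ``[1, L]``; for
    RNase-A-channel fragments (end chemistry 5'OH/3'P) position weights
    are ``w_py`` when the base at ``e-1`` is C/T and 1 otherwise, so the
    probability that an end base is a pyrimidine is
    ``w_py*f_py / (w_py*f_py + f_pu)`` for local base fractions ``f``.
    Channel-two fragments (5'P/3'OH, already ligatable without kinase
    treatment) are cut uniformly.  The fragment extends upstream of the
    cut by a draw from ``length_mixture``, clipped at the transcript
    start.
    """
    L = len(sequence)
    if L < 20:
        raise ValueError("transcript too short to fragment (<20 nt)")
    if w_py < 1.0:
        raise ValueError("w_py must be >= 1")

    base = np.frombuffer(sequence.encode(), dtype=np.uint8)
    is_py = (base == ord("C")) | (base == ord("T"))
    weights = np.where(is_py, w_py, 1.0)
    cdf = np.cumsum(weights)
    cdf /= cdf[-1]

    chem_rnase = rng.random(n_fragments) < rnaseA_channel_prob
    ends = np.empty(n_fragments, dtype=np.int64)
    n_rnase = int(chem_rnase.sum())
    # biased draw: end position e has weight of base e-1
    ends[chem_rnase] = np.searchsorted(cdf, rng.random(n_rnase)) + 1
    ends[~chem_rnase] = rng.integers(1, L + 1, n_fragments - n_rnase)
    lengths = length_mixture.draw(rng, n_fragments)
    starts = np.maximum(ends - lengths, 0)
    return [
        (int(s), int(e), OH5_P3 if c else P5_OH3)
        for s, e, c in zip(starts, ends, chem_rnase)
    ]


# ---------------------------------------------------------------------------
# library generation
# ---------------------------------------------------------------------------

@dataclass
class LibraryTruth:
    """Ground truth of one simulated library."""

    fragments: pd.DataFrame  # fragment_id, transcript_id, biotype, start, end,
    #                          length, end_chemistry, captured
    gene_abundance: pd.DataFrame  # gene_id, biotype, theta, true_tpm
    config: SimulationConfig


def _gene_abundances(
    refset: ReferenceSet, rng: np.random.Generator, mu: float, sigma: float
) -> pd.DataFrame:
    rows = []
    for tid in sorted(refset.transcripts):
        t = refset.transcripts[tid]
        rows.append((t.gene_id, tid, t.biotype, t.length,
                     float(rng.lognormal(mu, sigma))))
    df = pd.DataFrame(
        rows, columns=["gene_id", "transcript_id", "biotype", "length", "theta"]
    )
    # true TPM over the long tier: molar fraction scaled to 1e6
    long_mask = df["biotype"].isin(["mRNA", "lncRNA"])
    tpm = np.zeros(len(df))
    tpm[long_mask.to_numpy()] = (
        df.loc[long_mask, "theta"] / df.loc[long_mask, "theta"].sum() * 1e6
    )
    df["true_tpm"] = tpm
    return df


def simulate_fragments(
    config: SimulationConfig, refset: ReferenceSet
) -> LibraryTruth:
    """Draw fragments with end chemistry, capture and depletion flags.

    Fragment counts per biotype follow ``biotype_mix``; within a biotype,
    a transcript is chosen proportionally to (molar abundance x length),
    i.e. to the amount of degradable sequence it contributes.  miRNA
    fragments are the annotated mature species with at most 1 nt of
    terminal jitter, reflecting processed rather than degraded molecules.
    """
    rng = np.random.default_rng(config.seed)
    abund = _gene_abundances(
        refset, rng, config.abundance_mu, config.abundance_sigma
    )

    mix_biotypes = [b for b in sorted(config.biotype_mix) if
                    config.biotype_mix[b] > 0]
    present = {b for b in abund["biotype"]}
    mix_biotypes = [b for b in mix_biotypes if b in present]
    p = np.array([config.biotype_mix[b] for b in mix_biotypes])
    p = p / p.sum()
    counts = rng.multinomial(config.n_fragments, p)

    frag_rows = []
    frag_id = 0
    for biotype, n_b in zip(mix_biotypes, counts):
        if n_b == 0:
            continue
        sub = abund[abund["biotype"] == biotype]
        w = (sub["theta"] * sub["length"]).to_numpy()
        picks = rng.choice(len(sub), size=n_b, p=w / w.sum())
        per_t = np.bincount(picks, minlength=len(sub))
        for (row, n_t) in zip(sub.itertuples(), per_t):
            if n_t == 0:
                continue
            seq = refset.sequence(row.transcript_id)
            if biotype == "miRNA_hairpin":
                frags = _mature_fragments(
                    refset, row.transcript_id, int(n_t), rng,
                    config.rnaseA_channel_prob,
                )
            else:
                frags = fragment_transcript(
                    seq, config.w_py, config.length_mixture, rng,
                    n_fragments=int(n_t),
                    rnaseA_channel_prob=config.rnaseA_channel_prob,
                )
            for (s, e, chem) in frags:
                frag_rows.append(
                    (f"frag{frag_id:07d}", row.transcript_id, biotype,
                     s, e, e - s, chem)
                )
                frag_id += 1

    frags = pd.DataFrame(
        frag_rows,
        columns=["fragment_id", "transcript_id", "biotype", "start", "end",
                 "length", "end_chemistry"],
    )
    captured = (
        np.full(len(frags), True)
        if config.pnk_treated
        else (frags["end_chemistry"] == P5_OH3).to_numpy()
    )
    if config.depletion_enabled:
        depl = frags["biotype"].isin(DEPLETION_BIOTYPES).to_numpy()
        removed = depl & (rng.random(len(frags)) < config.depletion_rate)
        captured = captured & ~removed
    frags["captured"] = captured
    gene_ab = (
        abund.groupby(["gene_id", "biotype"], as_index=False)
        .agg(theta=("theta", "sum"), true_tpm=("true_tpm", "sum"))
    )
    return LibraryTruth(frags, gene_ab, config)


def _mature_fragments(refset, transcript_id, n, rng, rnase_prob):
    mats = refset.matures_on(transcript_id)
    L = len(refset.sequence(transcript_id))
    out = []
    for _ in range(n):
        m = mats[int(rng.integers(len(mats)))]
        s = max(0, m.start + int(rng.integers(-1, 2)))
        e = min(L, m.end + int(rng.integers(-1, 2)))
        chem = OH5_P3 if rng.random() < rnase_prob else P5_OH3
        out.append((s, e, chem))
    return out


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hit:
        choices = bases[bases != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode()


def generate_library(
    config: SimulationConfig,
    refset: ReferenceSet,
    out_dir: str | Path | None = None,
    prefix: str = "sim",
) -> tuple[list[Path], LibraryTruth]:
    """Emit FASTQ read(s) for every captured fragment, plus full truth.

    Single-end mode writes ``<prefix>.fastq``; paired mode writes
    ``<prefix>_R1.fastq`` / ``<prefix>_R2.fastq``.  Read 1 is the insert
    (fragment + poly(A) + 3' adapter) truncated to ``read_length``; read 2
    is the reverse complement of the fragment's 3'-terminal
    ``read_length`` bases (tail-strand trimming modeled as already done).
    If ``out_dir`` is None, no files are written and only truth plus
    in-memory reads are produced via :func:`simulated_reads`.
    """
    truth = simulate_fragments(config, refset)
    reads = simulated_reads(config, refset, truth)
    n_captured = int(truth.fragments["captured"].sum())
    if n_captured == 0:
        warnings.warn(
            "no fragment was captured under this configuration "
            "(pnk_treated=False with an all-RNase-A library?); "
            "enable PNK treatment or lower rnaseA_channel_prob",
            stacklevel=2,
        )
    paths: list[Path] = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if config.paired:
            p1 = out_dir / f"{prefix}_R1.fastq"
            p2 = out_dir / f"{prefix}_R2.fastq"
            with open(p1, "w") as f1, open(p2, "w") as f2:
                for rid, r1, q1, r2, q2 in reads:
                    f1.write(f"@{rid}/1\n{r1}\n+\n{q1}\n")
                    f2.write(f"@{rid}/2\n{r2}\n+\n{q2}\n")
            paths = [p1, p2]
        else:
            p = out_dir / f"{prefix}.fastq"
            with open(p, "w") as fh:
                for rid, r1, q1 in reads:
                    fh.write(f"@{rid}\n{r1}\n+\n{q1}\n")
            paths = [p]
        truth.fragments.to_csv(
            out_dir / f"{prefix}_truth.tsv", sep="\t", index=False
        )
        truth.gene_abundance.to_csv(
            out_dir / f"{prefix}_gene_abundance.tsv", sep="\t", index=False
        )
    return paths, truth


def simulated_reads(
    config: SimulationConfig, refset: ReferenceSet, truth: LibraryTruth
) -> list[tuple]:
    """Build the read tuples for every captured fragment of ``truth``.

    Returns ``(read_id, seq1, qual1)`` tuples, or 5-tuples with mate-2
    sequence/quality in paired mode.  Deterministic: the error/quality
    stream is seeded from ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    out = []
    cap = truth.fragments[truth.fragments["captured"]]
    for row in cap.itertuples():
        frag = refset.sequence(row.transcript_id)[row.start : row.end]
        construct = frag + "A" * config.polyA_len + config.adapter_3p
        r1 = _apply_errors(
            construct[: config.read_length], config.error_rate, rng
        )
        q1 = _quality(len(r1), config.lowqual_tail)
        if config.paired:
            r2 = _apply_errors(
                revcomp(frag)[: config.read_length], config.error_rate, rng
            )
            q2 = _quality(len(r2), config.lowqual_tail)
            out.append((row.fragment_id, r1, q1, r2, q2))
        else:
            out.append((row.fragment_id, r1, q1))
    return out


def _quality(n: int, lowqual_tail: int) -> str:
    if lowqual_tail <= 0 or lowqual_tail >= n:
        return "I" * n
    return "I" * (n - lowqual_tail) + "#" * lowqual_tail
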