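import numpy as np
import pytest

from cfrna.references import MatureMiRNA, ReferenceSet, TranscriptRecord
from cfrna.simulate import simulate_transcriptome


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def brute_force_align(bases: str, transcripts) -> list[tuple[str, int, int]]:
    """All-offset <=1-mismatch scan, best stratum only; the aligner oracle."""
    hits = []
    L = len(bases)
    for t in transcripts:
        seq = t.sequence
        for s in range(t.length - L + 1):
            mm = sum(a != b for a, b in zip(bases, seq[s : s + L]))
            if mm <= 1:
                hits.append((mm, t.transcript_id, s))
    if not hits:
        return []
    best = min(h[0] for h in hits)
    return sorted((tid, s, mm) for mm, tid, s in hits if mm == best)


@pytest.fixture(scope="session")
def sim_refset():
    """A full multi-biotype simulated reference shared across tests."""
    return simulate_transcriptome(7)


@pytest.fixture()
def toy_refset():
    """Small handcrafted reference with one transcript per tier role."""
    rng = np.random.default_rng(42)
    hairpin = random_seq(rng, 70)
    trna = random_seq(rng, 75)
    shared = random_seq(rng, 28)  # identical piRNA & tRNA-embedded segment
    transcripts = [
        TranscriptRecord("rRNA1", "rRNA1", "rRNA", random_seq(rng, 300)),
        TranscriptRecord("hp1", "hp1", "miRNA_hairpin", hairpin),
        TranscriptRecord("tRNA1", "tRNA1", "tRNA", shared + random_seq(rng, 45)),
        TranscriptRecord("piRNA1", "piRNA1", "piRNA", shared),
        TranscriptRecord("piRNA2", "piRNA2", "piRNA", random_seq(rng, 30)),
        TranscriptRecord("mRNA1", "mRNA1", "mRNA", random_seq(rng, 400)),
        TranscriptRecord("mRNA2", "mRNA2", "mRNA", random_seq(rng, 500)),
        TranscriptRecord("lnc1", "lnc1", "lncRNA", random_seq(rng, 350)),
        TranscriptRecord("oth1", "oth1", "other_ncRNA", random_seq(rng, 120)),
    ]
    matures = [MatureMiRNA("miR-1", "hp1", 10, 32)]
    return ReferenceSet(transcripts, matures)
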