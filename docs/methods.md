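# Methods

## Scope and data model

The package analyzes cfRNA sequencing reads against a *transcriptome*
reference (never a genome): a set of biotype-annotated transcript
sequences plus mature-miRNA coordinates on their hairpins. All
coordinates are 0-based half-open internally; 1-based coordinates appear
only in SAM export. Sequences are uppercased and U→T-converted at load
so reads and references share the DNA alphabet. The annotation is a
minimal three-column TSV (`transcript_id`, `gene_id`, `biotype`) because
real references of the relevant biotypes come from heterogeneous sources
and only this common schema is needed.

## Read cleanup

Order of operations per read: (1) 3' adapter removal — a valid match is
the full adapter anywhere or an adapter prefix flush with the read end,
minimum 5 nt, up to 10% mismatches; the longest match wins, ties go
leftmost; everything from the match onward is cut; (2) quality trimming
of both ends at Phred < 15; (3) removal of a trailing poly(A) run of
≥ 5 nt (the template-independent tail); (4) filters: length ≥ 17 nt and
N fraction ≤ 10% (strictly more than 10% removes). Cleanup counts
partition the input (`n_pass = n_input − short − N`), which the pipeline
asserts stage to stage.

Two consequences are inherent to this chemistry and worth knowing:

- a genuine 3'-terminal A run on a fragment is indistinguishable from
  the tail and is stripped with it (single-end length and 3'-end
  statistics are slightly depleted for A-ending fragments);
- an adapter or tail residue shorter than the 5-nt minimum match cannot
  be detected on a single read. In paired mode the merger compensates:
  when reverse-complemented mate 2 matches exactly *inside* mate 1 with
  mate-1 bases extending past its end, that is adapter read-through and
  the residue is cut at mate 2's terminus.

Pair merging reverse-complements mate 2 and takes the longest
suffix(R1)/prefix(rc-R2) overlap ≥ 10 nt with mismatch rate ≤ 0.1
(exact overlaps are searched first; read-1 bases win inside the
overlap). Merged pairs are analyzed as single-end reads downstream.

## Alignment and tier assignment

The aligner reproduces v1-mode semantics: end-to-end, ≤ 1 substitution,
no gaps or clipping, forward strand only (the library is stranded), all
hits in the best mismatch stratum reported. Candidates come from a
pigeonhole search on a k-mer index (k = 8): with at most one mismatch,
one of the read's two halves is exact, so the k-mers at offsets 0 and
len//2 enumerate every placement; each candidate is verified by direct
mismatch counting. Output ordering is deterministic
(`transcript_id, start`), making runs byte-reproducible. Equivalence
with an exhaustive all-offset scanner is property-tested.

Tier order: depletion {rRNA, Y RNA, vtRNA} → miRNA hairpins →
small {tRNA, piRNA} → long {mRNA, lncRNA} → other ncRNA. The first tier
with an alignment claims the read; depletion-tier reads are removed and
counted. Within the miRNA tier, a read is kept only if some annotated
mature's termini lie within 3 nt (start) and 5 nt (end) of the read
placement — interpreted as positional offsets of the termini, the
standard hairpin-quantification reading; among qualifying matures the
smallest start offset wins (tie: smaller end offset). A read failing
the filter falls through to later tiers (keeping read-count
conservation); this is switchable. Within mixed tiers, best-stratum
hits spanning two biotypes resolve by annotation confidence: tRNA over
piRNA, and analogously mRNA over lncRNA. Multi-gene hits inside one
biotype split weight equally (1/n per gene).

The sense/antisense diagnostic relaxes the forward-only rule: each read
is aligned both ways, forward-only best hits count sense, reverse-only
antisense, equal strata count sense.

## Quantification

Small RNAs (mature miRNA, tRNA, piRNA, other ncRNA): weighted counts,
normalized to reads per million mapped reads. The RPM denominator is
all tier-assigned reads after depletion; whether depleted reads should
count is genuinely ambiguous, so a flag (`include_depleted_in_rpm`)
exposes the alternative.

mRNA/lncRNA: transcript-level EM over best-stratum hit sets. Model:
a read from transcript t is uniform over its positions, so
P(read) ∝ Σ_{t∈hits} α_t/ℓ_t with molar fractions α and lengths ℓ.
E-step responsibilities are proportional to current TPM fractions
γ ∝ α/ℓ; the M-step sets γ ∝ (assigned read mass)/ℓ, renormalized.
Iteration stops when max |ΔTPM| < 10⁻³ (default) or after 200
iterations; the observed-data log-likelihood is non-decreasing (tested)
and with uniquely mapping reads the fixed point is exactly
count/length normalization. Gene TPM sums the gene's transcripts;
Σ TPM = 10⁶. Effective length equals transcript length — cfRNA
fragments are much shorter than transcripts and no fragment-length
correction is attempted; this is a deliberate, documented divergence
from full-length RNA-seq estimators. Differential abundance is out of
scope; the TPM/RPM matrices are written in a form directly consumable
by external DE tools.

Detection: a gene is detected in a sample at count ≥ 1 (default) and
present in a group when detected in ≥ 2 samples.

## Fragmentomics

Lengths merge two strategies: (1) merged pairs / single-end reads
contribute their aligned length; (2) unmerged pairs whose mate 1 aligns
over ≥ 90 nt to the same transcript as mate 2 contribute
`(R2_start − R1_start) + R2_aligned_length`; discordant (negative)
lengths are discarded and tallied. The 90-nt default reflects the
upper limit of what a single 100-nt read can span. Length classes are
< 50 nt, 50–200 nt, > 200 nt. Strategy-2 pairs are depletion-filtered
like everything else.

Ends: the 3' end is defined as the **last aligned base** (the residue
RNase A leaves its 3'-phosphate on), the 5' end as the first aligned
base. The alternative 3' reading ("first unaligned base") would shift
every index by one and is intentionally not the default. The 4-mer
motif spans positions [end−2, end+2) around each boundary; fragments
whose window leaves the transcript contribute to base frequencies but
not motif counts, and motifs containing N are excluded from both
numerator and denominator. Motif vectors always have exactly 256
entries and sum to 100 (percent). Motifs are reported separately for
the 5' and 3' ends. Summary statistics: 3' pyrimidine/purine ratio
(C+T)/(A+G) (reported as +inf when no purine 3' ends exist) and the 5'
adenine rate. End features are computed only from reads spanning a
whole fragment (merged or single-end); an unmerged mate's inner
terminus is a sequencer artifact, not a biological end.

## Cohort statistics

PCA follows prcomp semantics: columns centered, unscaled by default
(scaling exposed as a flag), SVD-based, with each component's sign fixed
so its largest-magnitude loading is positive (for reproducibility).
Pearson correlation reports the product-moment r with the two-sided
p-value from the t transform. The Wilcoxon rank-sum test uses the exact
null distribution when both groups have ≤ 20 observations and no ties,
the normal approximation otherwise; the matched t test is the standard
two-tailed paired test. P-values are reported raw with the conventional
tiers (*p < .05, **p < .01, ***p < .001); no multiple-testing
correction is applied in this module.

## The simulator

What it emulates, and why those pieces matter downstream:

- **Abundance**: per-gene molar abundances are log-normal(μ = 0,
  σ = 1) within each biotype; a biotype mixture fixes each class's
  expected fragment share (defaults: 25% miRNA, 30% mRNA, 15% tRNA,
  10% lncRNA, 5% each rRNA/piRNA/other, 3% Y RNA, 2% vtRNA — a
  plasma-like composition). Within a biotype, a transcript's fragment
  propensity is abundance × length, so TPM (a molar measure) is the
  recoverable target.
- **Fragmentation**: a fragment's 3' end is a cut drawn with weight
  `w_py` on pyrimidines for RNase-A-channel fragments and uniformly for
  the pre-phosphorylated channel; the fragment extends upstream by a
  draw from a length mixture (negative-binomial short component, mode
  ≈ 27 nt; uniform 50–500 nt long component; short fraction 0.85 by
  default), clipped at the transcript start. The closed-form check:
  the 3'-end pyrimidine probability is w_py·f_py/(w_py·f_py + f_pu)
  for local base fractions f. The cut bias is applied **only** to the
  RNase-A channel because the capture contrast (below) exists only if
  end chemistry and end-base composition are coupled. No explicit
  5'-adenine preference is imposed: on a random-composition reference
  none would emerge from pyrimidine cutting anyway, and adding an
  unjustified parameter would fake a signal the model cannot explain.
- **Capture**: without PNK treatment only 5'P/3'OH fragments are
  ligatable; with PNK all fragments are. Depletion removes
  rRNA/Y RNA/vtRNA fragments with probability 0.9 (configurable).
- **Reads**: mate 1 is `fragment + poly(A)·20 + adapter` truncated to
  100 nt (constant high quality, optional low-quality tail, optional
  uniform substitution errors). Mate 2 is the reverse complement of the
  fragment's 3'-terminal 100 nt with tail/adapter bases excluded —
  i.e. tail-strand trimming is modeled as already done, which keeps the
  merge and 90-nt analyses fully exercised without dragging a poly(T)
  head trimmer into scope. miRNA fragments are the annotated mature
  with ≤ 1 nt terminal jitter (processed, not degraded, species).
- Everything is deterministic under the config seed (FASTQ bytes and
  truth tables identical across runs).

What it does **not** emulate: secondary structure (real RNase A prefers
*unpaired* pyrimidines), position-dependent coverage, sequencing error
profiles beyond uniform substitutions, UMIs, spike-ins, GC bias, and
biofluid-specific RNase concentrations (the biofluid presets in
`analysis/01` are free parameters, not calibrated constants). Passing
recovery tests on this generator therefore demonstrates that the
pipeline's *logic* is correct — filters, tie-breaks, EM, length rules,
motif arithmetic — not that real biofluid data will look like the
simulation.

## Problem sizes and numerical choices

Simulation-recovery analyses use 20k–200k fragments (200k reads / 50
genes for TPM recovery, 100k fragments per cut-bias setting, 20k paired
fragments for length-truth checks) — large enough that binomial
standard errors are small against the tested effects, small enough to
run on a laptop in seconds. Statistical checks compare against
closed-form expectations within 3–4 standard errors at fixed seeds.
EM tolerance is 10⁻³ TPM; TPM conservation is asserted to 10⁻³ of 10⁶;
motif sums to 10⁻⁶ of 100. Degenerate inputs fail loudly: empty
histograms, constant vectors in correlation, zero mapped reads for RPM,
all-zero paired differences in the t test; an all-purine transcript
still fragments (the bias has nothing to act on), and a configuration
that captures zero fragments warns and advises enabling PNK.

## Known limitations

- The 17-nt floor and k = 8 pigeonhole mean reads of 16 nt are never
  aligned (they are filtered first anyway).
- piRNA-identical-to-tRNA sequences are resolved by priority at
  assignment time, not deduplicated at load time, so piRNA counts are
  conservative.
- Single-end libraries censor fragment lengths at the read length and
  bias 3'-end statistics toward fragment prefixes; paired mode avoids
  both.
- The EM reports gene-level TPM only; no isoform posteriors or
  uncertainty intervals.
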