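# cfrna

Analysis pipeline for cell-free RNA (cfRNA) sequencing libraries built
with poly(A)-tailing / 5'-adapter-ligation chemistry, together with a
chemistry-aware read simulator that makes every stage verifiable without
any external data.

## The problem

cfRNA circulating in biofluids (plasma, saliva, urine, seminal fluid,
amniotic fluid) is heavily degraded: most fragments are shorter than
50 nt, their ends carry the chemistry of the nucleases that produced
them, and mRNA/lncRNA fragments coexist with abundant structural RNAs
and small RNAs. Quantifying all biotypes at once and reading the
"fragmentomic" signal — fragment lengths, terminal bases, 4-mer end
motifs — requires a pipeline that is careful about library chemistry:

- RNase A-family enzymes cleave 3' of unpaired pyrimidines (C/U),
  leaving 5'-hydroxyl/3'-phosphate ends that cannot be ligated or tailed
  until T4 polynucleotide kinase (PNK) repairs them. PNK treatment
  therefore *gates which fragments enter the library*, coupling capture
  to end-base composition.
- A 3' poly(A) tail and sequencing adapter must be trimmed; reads
  shorter than 17 nt or with >10% N are discarded; quality <15 ends are
  clipped.
- Reads are assigned hierarchically: abundant rRNA/Y RNA/vault RNA
  first (in-silico depletion), then miRNA hairpins (with a positional
  filter against annotated mature coordinates: start offset ≤ 3 nt, end
  offset ≤ 5 nt), then tRNA/piRNA (tRNA outranks piRNA on equal
  evidence), then mRNA/lncRNA, then other ncRNA.
- Alignment is forward-strand, end-to-end, at most one substitution,
  reporting **all** placements in the best mismatch stratum (v1-mode
  semantics: 0-mismatch hits suppress 1-mismatch hits).
- Small RNAs are quantified as weighted counts → RPM (reads per million
  mapped); mRNA/lncRNA as TPM via an expectation–maximization over each
  read's best-stratum hit set (E-step splits multi-mappers by current
  abundance; M-step re-estimates abundance as length-normalized read
  mass; Σ TPM = 10⁶).
- Fragment lengths combine two strategies: merged read pairs contribute
  their aligned length; unmerged pairs whose first mate aligns ≥ 90 nt
  contribute `(R2_start − R1_start) + R2_aligned_length`.
- End features are read off the reference: 5' base at the first aligned
  position, 3' base at the last; 4-mer motifs span two bases inside and
  two outside each boundary, counted over all 256 motifs and normalized
  to percentages.

The simulator generates libraries with known per-fragment truth:
log-normal gene abundances, a biotype mixture, the two-channel end
chemistry (RNase-A cleaved 5'OH/3'P with pyrimidine cut bias `w_py`
vs. pre-phosphorylated 5'P/3'OH cut uniformly), PNK-dependent capture,
in-silico depletion, a short-dominated fragment-length mixture, and the
read layout `fragment + poly(A) + adapter` truncated to the read length.

## Worked example

```bash
python analysis/01_simulate_libraries.py
python analysis/02_preprocess_reads.py
python analysis/03_assign_and_quantify.py
python analysis/04_fragmentomics.py
python analysis/05_cohort_statistics.py
```

The panel simulates five biofluid-like libraries that differ only in
RNase activity (cut bias and degradation level) plus a PNK-on/off pair.
Script 04 prints, per sample, the length-class fractions and end
statistics, e.g.:

```
  sample  frac_lt50  frac_mid50_200  frac_gt200  py_pu_ratio_3p  adenine_rate_5p
  plasma   0.919935        0.067987    0.012078        3.383777         0.248550
 seminal   0.730901        0.158653    0.110447        1.292284         0.246855
```

i.e. the plasma-like library is dominated by sub-50-nt fragments and
shows a strong 3'-pyrimidine excess, while the seminal-fluid-like
library retains long fragments and a near-neutral end ratio. Script 05
then reports:

```
short-fragment rate vs 3' py/pu ratio: r = 0.977, p = 0.0042 **
PNK contrast (3' py/pu ratio): on = 2.771, off = 1.100, enrichment = 2.52x
```

— the two fragmentomic readouts of the same cleavage activity are
strongly correlated across samples, PCA of the 256-motif profiles
orders samples by that activity along PC1, and PNK treatment recruits
the RNase-cleaved (3'-pyrimidine-ended) fragments that an untreated
library cannot ligate.

A single sample can also be run end to end from a YAML config:

```bash
cfrna run --config demo.yaml     # see cfrna/cli.py docstring for the schema
```

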