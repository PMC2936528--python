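# cpgflank

Analysis of *de novo* DNA methylation pattern formation from bisulfite clone
sequencing, for epigenomics researchers studying the sequence preferences of
the DNMT3A/DNMT3B *de novo* methyltransferases and their DNMT3L cofactor.

When an unmethylated, CpG-rich region is methylated *in vivo* and read out by
clonal bisulfite sequencing, the resulting pattern is not uniform: individual
CpG sites are reproducibly hot or cold, with tens-of-fold differences in
per-site efficiency driven by the bases flanking the target CpG (offsets
−2/+2 for DNMT3A-like preference, −1/+1 for DNMT3B-like). `cpgflank`
implements the full analysis chain for such experiments, plus a simulator
that generates clone reads with planted, known preferences so that every
statistic can be validated by parameter recovery:

- **simulate** — episome-like reference regions; per-strand de novo
  methylation with probability `logistic(β₀ + Σ β(offset, base))`;
  maintenance symmetrization of hemimethylated CpGs; DNMT3L saturation
  stimulation `p′ = 1 − (1−p)^k`; dcm (CCWGG) marks tagging "old" bacterial
  strands; incomplete bisulfite conversion.
- **call** — strand assignment and per-CpG methylation calls from gapless
  reads; per-molecule conversion efficiency over eligible (non-CpG, non-Dcm)
  cytosines with an inclusive ≥95% filter; dcm+/dcm− classification.
- **patterns** — per-site efficiencies `e = m/n`, descending ranks with
  average ties, rank correlations (r, r²), fold ranges with Haldane
  pseudocounts, hot/cold decile selection, flank extraction and
  direct/reverse-complement orientation alignment, per-(offset, base) 1-df
  chi-square enrichment `X² = (O−E)²/E + (O−E)²/(N−E)` against the pooled
  CpG-context background, sequence-logo information content
  `IC = 2 − H(bits)`, DNMT3L fold-stimulation trends, and the one-tailed
  molecule-level Student t-test with ns/*/**/*** categories.
- **words** — first-order Markov (M1) word-count exceptionality: expected
  count `Ê(w) = Π N₂(wᵢwᵢ₊₁) / Π N₁(wᵢ)`, an asymptotic delta-method
  standard deviation validated against Monte-Carlo simulation, scores
  `z = (N − Ê)/σ̂` with two-sided normal p-values (z = 5 ↔ p ≈ 10⁻⁶), pattern
  scans such as `NTCGGN`/`NGCGCN`, and operational CpG-island metrics
  (GC > 0.55 and observed/expected CpG `N(CG)·L/(N(C)·N(G))` > 0.8).

## Worked example

`examples/02_flank_preference_recovery.py` plants a DNMT3A-like preference
(strength 1 logit at −2, half that at +2, baseline −1.7) in a 500 bp region,
simulates 200 molecules per strand at 99.1% conversion, and runs the full
flank analysis. It prints:

```
10 hot and 10 cold flanks (both strands pooled)
hot flanks:  most significant cell = (-2, T), O=9 vs E=1.8, p = 4.82e-09
cold flanks: most significant cell = (-2, A), p = 2.55e-11

hot-flank logo letter heights (bits; 2 = perfect conservation):
base       A     C     G     T
offset
-2      0.00  0.15  0.00  1.38
-1      0.02  0.03  0.05  0.06
 1      0.00  0.32  0.26  0.06
 2      0.08  0.59  0.00  0.17
```

The planted preference is recovered: among the 10% most methylated sites, T
at offset −2 is the single most significant enrichment (9 of 10 flanks
against 1.8 expected from the background composition), the coldest sites are
enriched for A at −2, and the logo matrix shows the corresponding ~1.4-bit
letter at −2. The other examples cover simulation + calling
(`01`), DNMT3L uniformization and dcm-stratified stimulation (`03`), and
word-exceptionality scans (`04`).

A thin CLI mirrors the library
(`cpgflank simulate|call|stats|enrich|stimulate|words|island|run`); `run`
executes the whole pipeline from a YAML config and writes every table plus a
JSON run log, byte-identically under a fixed seed.

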