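"""Markov-M1 word exceptionality: hotspot and coldspot motif scans.

Scores the predicted DNMT3B methylation hotspot (NTCGGN) and coldspot
(NGCGCN) word families against a first-order Markov background fitted to the
scanned sequence itself.  The score is (observed - expected) / sd; |score| 5
corresponds to p ~ 1e-6.  Also reports the operational CpG-island metrics.
"""

import warnings

import cpgflank as cf

warnings.filterwarnings("ignore", category=UserWarning)

# a CpG-island-like sequence large enough for 6-mer statistics
region = cf.generate_reference(20000, 0.6, 500, seed=3)
seq = region.sequence

m = cf.island_metrics(seq)
print(f"scanned sequence: {len(seq)} bp, GC = {m.gc_fraction:.2f}, "
      f"obs/exp CpG = {m.obs_exp_cpg:.2f} -> "
      f"{'meets' if m.is_island else 'fails'} the CpG-island definition")

for pattern, label in (("NTCGGN", "hotspot"), ("NGCGCN", "coldspot")):
    results, agg = cf.scan_words(seq, pattern)
    print(f"\n{pattern} ({label} family): aggregate observed {agg.observed} "
          f"vs expected {agg.expected:.0f}, score {agg.score:+.2f} "
          f"(p = {agg.pvalue:.2g})")
    extreme = max(results, key=lambda r: abs(r.score) if r.score == r.score else 0)
    print(f"  most exceptional word: {extreme.word}, observed {extreme.observed} "
          f"vs expected {extreme.expected:.1f}, score {extreme.score:+.2f}")
    # in an i.i.d.-style random region no family should be exceptional;
    # a real promoter CpG island would show depletion of hotspot words
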