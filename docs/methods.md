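# Methods

## The measurement being modelled

Clonal bisulfite sequencing of an initially unmethylated, CpG-rich region
reads out, molecule by molecule and strand by strand, which CpG cytosines
were methylated. Unmethylated cytosines deaminate to uracil and are read as
T after PCR; methylated cytosines resist and stay C. Three features of the
biology shape the analysis:

- **Flanking-sequence preference.** The per-site de novo methylation
  probability depends on the bases at small offsets around the target CpG.
  We model it with a logistic link: `p = logistic(β₀ + Σ β(offset, base))`,
  offsets −k…−1, +1…+k (the CpG itself excluded, k = 2 by default). The link
  itself is a modelling convenience; the scientific content is in the sign
  pattern and position of the effects.
- **Maintenance methylation.** Hemimethylated CpGs are restored to fully
  methylated between de novo events and readout, symmetrizing per-site
  efficiencies across strands.
- **dcm tagging.** Plasmids grown in *E. coli* carry 5-methylcytosine at the
  internal C of CCWGG. This mark is not maintained in human cells, so its
  retention distinguishes "old" transfected strands (dcm+) from newly
  replicated ones (dcm−).

## Simulator

Per duplex molecule: dcm status is Bernoulli(`dcm_plus_fraction`); de novo
methylation is drawn independently per strand per CpG from the flank model
(each strand's probability computed from its own 5′→3′ context, the bottom
window being the reverse complement of the top window); hemimethylated sites
are upgraded to fully methylated with probability μ
(`maintenance_efficiency`) in a single round — the simplest mechanism that
produces strand-symmetric patterns; each strand is then converted:
unmethylated C → T with probability c (`conversion_rate`), methylated C → T
with probability `inappropriate_conversion`, dcm+ molecules keeping their
Dcm cytosines methylated on both strands. Bottom-strand reads are emitted in
bottom-strand coordinates; the caller re-orients them.

DNMT3L stimulation is the saturation transform `p′ = 1 − (1−p)^k`, k ≥ 1
interpretable as effective catalysis rounds. It has the two properties the
stimulation analysis measures: the fold boost `p′/p` is strictly decreasing
in `p` (weak sites gain most) and the max/min spread across sites shrinks.
An optional separate exponent for dcm+ molecules phenomenologically encodes
the cofactor's preference for well-chromatinized (newly replicated)
templates; no chromatin mechanism is modelled.

Defaults and their rationale: `β₀ = −1.7` puts the mean neutral-context
probability near 0.15, the scale of observed strand-level efficiencies;
`c = 0.991` is the study-wide conversion efficiency; `μ = 0.95` reflects
efficient maintenance; `inappropriate_conversion = 0`;
`dcm_plus_fraction = 0.5` (an even mix of old and replicated strands);
36–120 molecules per strand is the realistic clone-sampling range, and
simulations here use 100–300. Planted profiles: DNMT3A-like puts ±s at
(−2, T)/(−2, A) and ±s/2 at (+2, C)/(+2, G); DNMT3B-like puts ±s at
(+1, G)/(+1, C) and +s/2 at (−1, T). The primary/secondary weighting
reflects the strongly unequal significances observed between the two
positions of each enzyme's signature; an exactly symmetric model would make
"which position dominates" a coin flip.

Edge CpGs with fewer than k flank bases cannot be scored by the model; they
are simulated at the baseline probability, flagged `edge` in truth tables,
and excluded from flank analyses.

All stochastic operations draw from one `numpy` generator seeded through
`SimulationParams.seed`; identical parameters give byte-identical FASTA.

## Calling

Reads must be gapless (reference-length); there is no internal aligner —
real alignments must be trimmed first. Orientation is chosen by
bisulfite-aware compatibility scoring, then the strand is assigned by
counting reference-C-read-T positions (top evidence) against
reference-G-read-A (bottom evidence); ties are dropped with a warning. Calls
at each CpG: retained C (top) / G (bottom) = methylated, converted base =
unmethylated, anything else missing.

Conversion efficiency is converted/eligible cytosines, where eligible
excludes CpG-context and Dcm-context cytosines of that strand. Excluding
Dcm contexts matters: a dcm+ strand legitimately retains C at CCWGG, and
counting those as unconverted would systematically fail dcm+ molecules at
the ≥95% filter (the filter is inclusive: 0.95 passes). Where a constructed
sequence makes a cytosine both CpG- and Dcm-context, CpG context takes
precedence. dcm classification thresholds the retained fraction of Dcm
cytosines at 0.5; a strand without Dcm sites is NA.

## Pattern statistics

Per-site efficiency is `m/n` over informative calls in the selected stratum
(strand, dcm class, filter status); sites with fewer than `n_min = 10`
informative calls are flagged and excluded from ranking extremes — low-n
sites make ratio statistics unstable. Ranks are descending with average
ties; rank correlations report signed Pearson-on-ranks r and r² (equal to
squared Spearman). Ratio computations (fold range, per-site fold
stimulation) replace zero-count efficiencies with the Haldane-adjusted
`(m+0.5)/(n+1)`; reported efficiencies are never pseudocounted.

Hot/cold selection takes the top and bottom `⌈fraction·N⌉` sites (default
10%), breaking ties by efficiency then ascending position; when a region is
too small for two disjoint deciles the cold set shrinks. Flanks (2k+2-base
windows centred on CG) are extracted per strand in that strand's 5′→3′
orientation and pooled across strands, so a site selected on both strands
contributes a reverse-complement pair. Orientation alignment then iterates
to a fixed point: build a +0.5-pseudocount position frequency matrix, flip
any flank whose reverse complement scores higher log-likelihood, rebuild
(ties keep direct, bounded at 20 iterations with a warning on
non-convergence).

Enrichment is tested per (offset, base) with a 1-df base-versus-rest
chi-square against `E = N·q_base`, no Yates correction, direction from the
sign of O−E; raw p-values are primary and a Bonferroni column across all
4·2k cells is secondary. The background composition `q` is pooled over the
±k flank windows of *all* CpG sites of the region(s), both strands —
conditioning on CpG context rather than whole-region composition — and is
therefore reverse-complement symmetric. Logo output is per-offset
information content `IC = 2 − H` bits with letter heights `f·IC`.

The molecule-level stimulation test is a classic two-sample Student t-test
(pooled variance) on per-molecule overall efficiencies, one-tailed for
stimulation, with categories ns / * (0.01–0.05) / ** (0.001–0.01) /
*** (<0.001).

**Identifiability of the preference orientation.** Under perfect maintenance
(μ = 1) the duplex data are exactly strand-symmetric: every pooled hot flank
arrives with its reverse complement, and "T at −2" cannot be distinguished
from the mirrored labelling "A at +2" by any statistic of the data. The
experiment that resolves the orientation is the maintenance-free one, where
each strand's efficiencies reflect only that strand's own flanks — this is
the role the in vitro reaction plays for the real enzyme. Parameter-recovery
validations therefore simulate with μ = 0; runs with maintenance enabled
recover the motif pair up to this two-fold labelling degeneracy.

## Word exceptionality (M1)

Counts are overlapping, pooled across sequences, never spanning sequence
boundaries; non-ACGT characters break word windows. The M1 expected count is
the plug-in estimator `Ê(w) = Π N₂(wᵢwᵢ₊₁) / Π N₁(interior wᵢ)`, which
reproduces every dinucleotide count exactly (all 2-letter words score 0,
identically). Words are counted single-strand as written, matching how
signature motifs are read 5′→3′; a both-strands scan is available by adding
reverse-complemented sequences.

The score is `z = (N(w) − Ê(w))/σ̂`. σ̂ is the asymptotic standard deviation
of `N(w) − Ê(w)` computed by the delta method: the estimator is linearized
in the word, dinucleotide and letter counts, and the covariance rate of any
two word counts in the fitted stationary chain is evaluated exactly — a sum
of overlapping-lag joint probabilities minus `μ(u)μ(v)` per lag, plus
long-range terms `μ(u)μ(v)(Z−I)(u_last, v_first)/π(v_first)` through the
fundamental matrix `Z = (I − P + 𝟙πᵀ)⁻¹`. The formula is validated against a
Monte-Carlo oracle: on a 5 kb sequence, the analytic z of a 4-mer agrees
with the z implied by the empirical standard deviation of `N − Ê` over 10⁴
simulated chains to within |Δz| ≈ 0.01 (tolerance 0.3). p-values are
two-sided normal, `p = 2Φ(−|z|)` — the only mapping consistent with both
printed score anchors (5 ↔ ~10⁻⁶, 10 ↔ ~10⁻²³). Pattern scans expand N
positions over ACGT and report per-word results plus an aggregate
(ΣO vs ΣÊ with variance approximated by the sum of per-word variances —
between-word covariances are ignored, adequate for calibration-level use).
No exact compound-Poisson p-values are attempted for rare words.

CpG-island metrics follow the strict operational definition: GC fraction
> 0.55 and observed/expected CpG ratio `N(CG)·L/(N(C)·N(G))` > 0.8.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; a CpG site is named by its
  top-strand C position (CG is its own reverse complement, so one index
  serves both strands). Site tables export as BED-like (start, start+2).
- Chi-square vs exact binomial: the 1-df chi-square p-value tracks the
  exact two-sided binomial only in the moderate range (within a factor ~3
  for p ≳ 10⁻²); in the far tail the normal approximation underestimates
  the exact tail by orders of magnitude. Printed p-values far below 10⁻⁴
  should be read as "very significant" rather than as precise tail masses.
- The enrichment null calibration uses 60 flanks per replicate, where the
  binomial is well within its asymptotic regime (exact rejection rate at
  nominal 5% is 5.1%); far smaller flank sets make the discrete chi-square
  conservative.
- Degenerate inputs return NA with a warning rather than raising wherever a
  stratum can legitimately be empty of signal (zero rank variance, constant
  folds, no Dcm sites, no eligible cytosines); structurally invalid inputs
  (length mismatches, unknown strands, empty strata) raise.

## What the simulator does and does not establish

Passing parameter recovery shows the statistics identify planted logistic
flank preferences at realistic sample sizes, conversion failure rates and
decile sizes. The generator does not model PCR or cloning bias, indels or
sequencing error beyond conversion failure, chromatin state (beyond the dcm
exponent split), processivity or iterative de novo/maintenance rounds, or
dinucleotide-coupled preferences (positions are independent in the model
and in the enrichment test). Conclusions about real data therefore rest on
the statistics' calibration, not on the generator capturing every bias of
the assay. CpG-spacing periodicity analysis is out of scope.
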