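# Methods

## The QC problem

Whole-genome amplification from very few cells starts from, at most,
`cell_count` template molecules per haplotype. Whether each template
seeds amplification, and how much product it yields, are random events
that dominate the downstream allele balance: a heterozygous site may be
observed as perfectly balanced, wildly skewed, homozygous (one
haplotype lost), or not at all. `sparsecellqc` quantifies this noise
from replicate assays at matched cell input and propagates it into
three complementary views: replicate mismatch, heterozygous
allele-frequency SNR, and copy-number inference from allelic imbalance.

## Generative model of the simulator

No public raw data exists for the replicate-dilution design this
package targets, so the synthetic-data module is a first-class
component, not a test convenience. Per truth site with `a` alternate
and `t − a` reference chromosome copies locally:

1. template counts: `cell_count · a` alt and `cell_count · (t − a)`
   ref molecules;
2. each template survives (seeds amplification) independently with
   probability `s` (`template_survival`, default **0.85**);
3. each surviving template contributes an independent Gamma(`k`, 1)
   yield (`gain_shape`, default **0.35**, see calibration); the
   pooled alternate fraction is `f = Σ alt yields / Σ all yields`
   (a sum of `m` Gamma(`k`) draws is Gamma(`m·k`), so this is sampled
   in closed form);
4. total depth is negative-binomial with mean `mean_depth` (default
   **90×**, the design target of the emulated assay) and size
   `depth_dispersion` (default **3**, giving the broad per-site
   coverage spread seen in MDA exomes);
5. alternate reads are Binomial(depth, `f` perturbed by a symmetric
   per-read miscall rate `e`, default **2·10⁻³**);
6. genotypes and PLs come from the binomial likelihoods of the three
   diploid genotypes (alt-read probability `e`, ½, `1 − e`),
   `PL = −10·log₁₀(L/L_max)` rounded, min-normalised to 0, capped at
   9999.

Sites whose templates all fail, draw zero depth, or genotype as hom-ref
are omitted from the VCF — single-sample variant files carry only
non-reference calls, and set intersection/union semantics downstream
rely on that.

The default ground-truth genome emulates a hyperdiploid leukemic cell
line: 3 450 SNV sites on eight chromosomes; whole-chromosome gains
(chr5, chr8 — trisomy at 2:1 allele ratio, so het VAF modes at 1/3 and
2/3), a large p-arm loss plus q-arm gain on chr1, a **< 100-variant**
interstitial loss on chr13, copy-neutral LoH of 19q, two fully neutral
chromosomes (chr2, chr3), three always-heterozygous driver mutations,
and a 21-locus STR panel with 18 heterozygous loci whose peak heights
are generated by the same survival/yield mechanism. Segments live in
variant-index space because the downstream median filter is defined
over variant neighborhoods, not genomic distance. Zygosity, gain
phases and retained haplotypes are drawn once at genome construction,
so a (spec, seed) pair pins the genome byte-for-byte.

What the simulator does **not** model: read-level artifacts (chimeras,
FASTQ, alignment), polymerase error accumulation along branching
amplification, GC-dependent coverage waves, and real linkage structure.
Passing tests therefore demonstrate that the analysis stack behaves
correctly on data with the *statistical* signatures of sparse-cell MDA
(cell-count-dependent dropout, heavy-tailed imbalance, CNA-shaped VAF
shifts), not that any particular laboratory protocol meets a spec.
Spurious variant calls can be injected via `false_positive_rate`
(expected spurious calls per assay as a fraction of true sites, placed
off-target); the default is 0 because no defensible rate is available,
and the coding-region filter tests enable it explicitly.

### Calibration

`template_survival` and `gain_shape` are the two knobs with no
measurable counterpart; they were set once so that the simulated
series reproduces the qualitative findings the framework is meant to
detect: single-cell duplicate mismatch ≈ 0.49 (in the 0.3–0.5 band
reported for MDA single cells), SNR(50 cells)/SNR(1 cell) ≈ 2.2 (the
"more than doubled" regime), STR dropout vanishing by 10-cell input,
and gain detectability emerging at 5 cells. The defaults are plain
dataclass fields; every analysis threshold is likewise config-exposed.

## Analysis definitions and numerical choices

* **Mismatch universe** — the union of the two replicates' non-reference
  SNV calls, keyed by (chromosome, position). One-sided sites are
  `total_dropout`; both-sided sites with different ALT alleles are
  `allele_change`; same ALT with het-vs-hom genotypes is `loh`.
  Indels pass through I/O but are excluded from the SNV statistic by
  default (`snv_only=False` to include them). Directional dropout
  counts (`dropout_only_a/b`) are reported alongside the symmetric
  union-based headline fraction.
* **Exponential fit** — `a·e^(−b·x) + c` with all three parameters
  constrained ≥ 0 (trust-region least squares), guaranteeing a
  non-increasing fitted curve with a non-negative plateau. Initial
  values: `c₀ = min y`, `a₀ = range(y)`, `b₀ = 1/mean(x)`.
  Non-convergence raises with solver diagnostics, never silently.
* **SNR** — sample (n−1) standard deviation; per-replicate SNRs are the
  default unit of analysis (pooling replicates before computing σ would
  mix inter-replicate shifts into the dispersion). The chromosome set
  is user-designated rather than auto-selected to avoid circularity
  with the CNA caller. σ = 0 or n < 2 raise `UndefinedStatisticError`
  rather than returning 0/NaN.
* **Normality** — Anderson–Darling with estimated mean and variance
  (`scipy.stats.anderson`), pass iff the statistic is below the
  critical value at α (default 0.05); n < 8 or constant input is
  signalled as insufficient.
* **Median filter** — the neighborhood parameter is a *radius*: range
  100 means the 201-variant window `values[i−100 : i+100]`, truncated
  (shrinking) at chromosome ends and never crossing a chromosome. The
  deliberate consequence: an event spanning fewer than ~100 variants
  cannot form a window majority and is smoothed away — the documented
  false-negative mode of the noise-reduction step, reproduced by the
  chr13 fixture segment.
* **Mirroring** — `v < 0.5 → 1 − v`. Idempotent; rejects out-of-range
  input.
* **KDE** — explicit Gaussian kernel sum, bandwidth
  `h = (4σ⁵/(3n))^(1/5)` (the standard Silverman rule; the formula's
  printed form is grouped as 3n in the denominator), evaluated on 512
  grid points over [−0.1, 1.1] so the hom-alt mode near 1 is interior.
  Raw density integrates to 1; a peak-scaled variant (max = 1) is kept
  for relative display. Modes are `scipy.signal.find_peaks` maxima
  with prominence ≥ 10 % of the global maximum. Modality is computed
  on all calls (het + hom-alt) to expose the bimodal-vs-trimodal
  contrast; het-only densities are available by building the series
  with `het_only=True`.
* **Gain calling** — on the mirrored, median-filtered het-only track,
  sliding windows of 100 variants (stride 50) are flagged where the
  mean filtered level exceeds
  `median(neutral mirrored het VAFs) + m · √(π/2) · σ_neutral / √201`,
  i.e. the sample's own folded noise level plus `m` (default 2.5)
  sampling standard deviations of a window median. Centring on the
  *observed* neutral folded median matters: folding pushes the neutral
  level to ≈ 0.5 + 0.67 σ, an O(σ) offset that a fixed 0.5 reference
  would misread as gain at low cell input. The neutral noise estimate
  always uses the same replicate-averaging as the tested track.
  KDE mode structure is attached as corroborating evidence.
* **Loss / CN-LoH calling** — a window is called when *both* the
  filtered all-call mirrored level is ≥ 0.9 (het sites have vanished,
  leaving hom-alt calls near 1) *and* the raw mid-band VAF fraction
  ([0.2, 0.8]) is ≤ 0.1. The conjunction keeps single-cell neutral
  chromosomes — where random dropout also produces many VAF ≈ 1
  calls, but plenty of mid-band survivors remain — from being called.
  Copy loss and copy-neutral LoH are reported as one class: allele
  frequencies alone cannot separate them (karyotyping can).
* **Replicate-mean series** — when two replicates are supplied, shared
  sites contribute the mean of their VAFs (unshared sites their single
  value), halving track noise before filtering.
* **Coordinates** — VCF positions 1-based, BED intervals 0-based
  half-open; conversion happens in exactly one place
  (`RegionSet.contains`). Depth filtering uses DP, inclusive at the
  threshold (default ≥ 30). Multi-allelic records are skipped with a
  warning by default.

## Problem sizes

The test suite and the acceptance script run the full default design:
3 450 truth sites × 6 cell counts × 2 replicates × 10 independent
series (≈ 120 simulated exomes), chosen so that every Monte Carlo
property (mismatch monotonicity, dispersion shrinkage, detection-rate
curves) is measured on the same footing as a single-laboratory
dilution experiment; the whole suite completes in well under a minute.

## Known limitations

* Sub-chromosomal calls inherit the median filter's resolution floor
  (~the filter window); breakpoints are window-aligned, not exact.
* The STR partial-dropout threshold (peak ratio > 3) is a convention;
  with heavy-tailed per-allele yields the simulated single-cell panels
  score more partial-dropout loci (median ≈ 15/21) than the 3–11 range
  typical of real capillary data, where peak heights saturate.
* Gain detection at 1–2 cells is unreliable by construction — the
  folded het level of a trisomy is barely distinguishable from the
  single-cell noise floor; this mirrors the biology of the assay, and
  the caller is calibrated to stay silent rather than guess.
* `loss_or_cnloh` never resolves copy number; integrating read-depth
  ratios would require a paired control, which the unpaired design
  excludes.
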