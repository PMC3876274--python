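# Methods

This note documents the models, parameter choices and numerical decisions
behind `scellcn`, and what its synthetic-data experiments do and do not
demonstrate about real single-cell data.

## Pipeline model and assumptions

The package analyzes one whole-genome-amplified (WGA) single tumor cell by
focal read depth. The core assumptions are:

* read depth in a bin is proportional to the local total DNA copy number,
  after correcting a smooth multiplicative GC effect;
* bins containing a fixed number of uniquely mappable positions (rather
  than fixed physical width) equalize the expected count per bin, so one
  genome-wide mean is a valid normalizer;
* a large reference region of known copy number exists, anchoring the
  ploidy factor Ψ in `CN = 2^logR × Ψ`;
* B-allele fractions at known germline-heterozygous SNPs are binomial in
  the allele-specific copy numbers (with optional WGA overdispersion).

Stage order follows the read-depth recipe exactly: pseudocount → GC < 28%
filter → logR against the mean of the *retained* bins → loess GC
correction → genome-wide median subtraction → per-chromosome PCF →
ploidy scaling → half-up integer rounding floored at 0.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| read length after trim | 69 bp | 101 bp raw reads minus the 32-base WGA adapter prefix |
| bin size B | config (`bin_unique`) | unique positions per bin; 50 kb on a human-scale genome, 2000–5000 on toy genomes so that a few thousand bins exist |
| pseudocount | 1 | keeps empty bins finite on the log scale |
| GC filter | < 0.28 | extreme-GC bins are unreliable after WGA |
| loess span / degree | 0.3 / 2 | local weighted polynomial of logR on GC, tricube weights; degree 2 follows common GC-correction practice |
| γ (sequencing bins) | 25 | PCF breakpoint penalty on corrected logR |
| γ, k_min (aCGH mode) | 60, 25 | noisier probe-level data need a stiffer fit |
| aCGH floor | −2 | clamps outlier probe log-ratios |
| BAF minimum depth | 8 reads | below this, allele dropout makes single-site BAF meaningless |
| allelic-state thresholds | 0.15 / 0.85 / 0.9 / 10 sites | a segment is LOH when ≥ 90% of ≥ 10 informative sites are extreme; cnLOH additionally requires integer CN 2; imbalance when mean mirrored BAF > 0.65 |
| duplicate key | (chrom, 5′ start, strand) | Picard-style single-end convention |

γ values are tied to the scale and noise of the data they were tuned on;
they are defaults, not constants, and are exposed in `RunConfig`.

## PCF: objective, exactness, tie-breaking

The segmentation objective is penalty-per-breakpoint:
`Σ_seg SSE(seg) + γ·K` for K breakpoints, with every segment at least
k_min points. This is equivalent up to an additive constant to
penalty-per-segment formulations. The optimum is found by an O(n²)
dynamic program over prefix sums — exact, unlike the fast heuristics used
at genome scale — which is affordable for the ≤ ~10⁴ bins this package
targets and directly verifiable: `segment_oracle` enumerates every
admissible breakpoint subset for n ≤ 15 and the test suite checks
objective *and* breakpoint agreement on random series. Ties are broken
deterministically: fewer breakpoints first, then the lexicographically
smallest (leftmost) breakpoint sequence; float ties use a 1e-9 relative
tolerance.

Localization accuracy depends on the jump-to-noise ratio: for a CN 2→3
step (logR jump 0.585) at per-bin noise SD 0.3, the exact optimum lands
within ±2 bins of the true boundary in ~94% of replicates and within ±3
bins in ~97% — a property of the estimator, not of the implementation.

## The synthetic-data generator

The generator is first-class, tested code; its defaults define the
conditions under which the pipeline is validated.

* **Genome**: i.i.d. bases with a position-dependent G+C probability
  interpolated from control points. The default landscape oscillates on a
  ~10%-of-chromosome scale, mimicking isochores. This scale matters: GC
  must vary faster than the planted copy-number events, otherwise the
  loess GC fit and real dosage signal are confounded (an early monotone
  default absorbed a whole-arm gain into the GC curve — the same failure
  mode a real pipeline would show on a pathological genome). Planted
  duplications are exact block copies and create unmappable regions.
* **Tumor truth**: clones with fractions summing to 1 (plus optional
  normal fraction), each a list of allele-specific events — whole-arm and
  focal gains/losses, cnLOH (copies of the lost allele transferred to the
  retained one, total unchanged), and chromothripsis-like shatter events
  expanded into oscillating focal segments. A sequenced cell is a pure
  clone.
* **WGA reads**: every chromosomal copy is partitioned into amplicons
  (normal lengths, mean 2 kb, SD 0.5 kb); each amplicon's sampling weight
  is its eligible length × a Gamma(1/d, d) multiplier (d = 0.15 variance;
  lognormal alternative behind `noise_model`) × a log-linear GC factor
  `exp(β·(gc − mean gc))` with β = 0.4. Reads start uniformly within an
  amplicon on a random strand; a fraction 0.05 of emitted alignments are
  exact PCR copies of earlier ones; every raw read carries the fixed
  32-base adapter prefix. Sequencing errors are off by default (a uniform
  substitution rate is available for BAF robustness experiments).
* **SNP counts**: site depth ~ Poisson(mean × totalCN/2), alt reads
  binomial in the alt-carrying copy fraction, beta-binomial when WGA
  overdispersion is requested; deleted alleles contribute nothing, CN-0
  sites record depth 0.
* **Bulk primary track**: probe logR = log2(fraction-weighted total CN/2)
  and BAF = weighted allele-B fraction (het probes) with Gaussian noise —
  a stand-in for SNP-CGH of the primary tumor; allele-specific bulk
  segmentation of real arrays is out of scope.

What the generator does **not** emulate: mismatch/gapped alignment and
mapping-quality artifacts, base-quality structure, chimeric WGA reads,
replication-timing or mappability-correlated coverage waves, and real
human genome scale. Passing tests therefore demonstrate correctness of
the algorithms under the stated noise model, not performance on real
DTC libraries.

## Allelic-state calling

WGA allele dropout makes single-site BAF unreliable, so states are called
per segment from the *fraction* of informative sites at extreme BAF.
Classification is intended for panels of germline-heterozygous SNPs (the
generator's `het_fraction=1`); with homozygous sites included the extreme
fraction baseline becomes genotype- rather than copy-number-driven. The
alt-allele convention defines B; calls are invariant to swapping ref and
alt at every site (mirror symmetry, tested).

## Concordance and event sharing

Concordance is defined on gain/neutral/loss status (baseline 2;
`round(Ψ)` available behind a flag), bp-weighted over the jointly covered
genome. This is a package definition — published concordance percentages
for real tumor/cell pairs do not state a denominator, so they are not
comparable figures. Event matching uses interval Jaccard ≥ 0.5 between
same-direction events; a matched event is clonal-shared when the pooled
clone fraction carrying it (relative to tumor content) is ≥ 0.8.

## aCGH mode

Probe-level tracks are processed floor → optional GC loess → zero-line
recentring → PCF(γ = 60, k_min = 25). Recentring is applied last so the
processed track has genome-wide mean exactly 0 (the documented contract);
flooring first keeps the outlier clamp at −2 on the input scale.

## Numerical and degenerate-input choices

* Mappability counting uses two independent 64-bit polynomial rolling
  hashes over both strands (pair-collision probability ~2⁻¹²⁸); the test
  suite verifies exact equality with a brute-force substring dictionary
  on small genomes. k-mers containing non-ACGT bases are non-unique by
  policy; uniqueness counting both strands is the default and matches how
  aligners place reads.
* Trailing partial bins are dropped, so all bins are exchangeable; bin
  width summaries trim the widest `floor(n·f)` bins and report the
  population SD (the convention the worked example `[1,3] → (2, 1)`
  implies).
* Degenerate GC range skips the loess fit (median-centring only, with a
  warning); chromosomes with fewer than k_min bins are emitted as one
  unsegmented segment with a warning; zero alignments yield zero coverage
  stats with a warning rather than division errors.
* Integer CN rounds half-up and floors at 0.
* The pipeline driver derives per-stage seeds by hashing the stage name
  into the global seed, so stages rerun independently yet
  deterministically; rerunning a config reproduces byte-identical
  artifacts (checksummed in the manifest).

## Validation study sizes

The end-to-end recovery study uses a 2 × 5 Mb genome, bins of 4950 unique
positions (~2020 bins of ~5 kb), 60 000 reads (~28 deduplicated reads per
bin), a planted arm gain (CN 3), a 500 kb focal deletion (CN 1) and a
1 Mb cnLOH region, with ploidy anchored on a CN-2 reference region. At
5 kb bins, a focal CN-1 event needs roughly 350 kb before the SSE gain of
an extra segment exceeds γ = 25 — event sizes below that are invisible at
this penalty, which is a property of PCF, not a bug. Real bins are ~50 kb
with thousands of reads each; the toy setting trades depth per bin for
runtime while keeping every algorithmic path identical.

## Known limitations

Exact-match toy mapping (no mismatches or gaps); no allele-specific
integer CN from single-cell BAF (major/minor decomposition); no joint
multi-sample segmentation; concordance numbers depend on the package's
own status-based definition; γ defaults inherited from probe/bin scales
other than the toy genomes and deliberately left untuned.
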