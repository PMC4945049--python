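# Methods

## The screening problem

A pregnant woman's plasma cell-free DNA is a maternal/placental mixture.
Writing *f* for the fetal (placental) fraction and c_mat,i, c_fet,i for the
maternal and fetal copy numbers in genomic bin *i*, the expected relative
read depth of the bin is the mixture copy ratio

    r_i = (1 − f) · c_mat,i / 2  +  f · c_fet,i / 2 .

A fetal heterozygous CNV moves r by ±f/2 (±0.05 at f = 0.10); a maternal
CNV moves it by ±(1−f)/2 ≈ ±0.5 — which is why maternal copy-number
background is the dominant false-positive mechanism in this kind of
screening. On chrX a male fetus contributes one copy (r = 1 − f/2); on
chrY female-fetus pregnancies retain a small mis-mapping background β and
male-fetus pregnancies add f/2 on top of it.

At screening depth (~7×10⁶ uniquely aligned reads, 100 kb bins, hence
~226 reads and σ ≈ 1/√226 ≈ 6.7% per bin) the fetal signal is ~0.75 σ per
bin and must be integrated over tens of bins; everything below is designed
around that regime.

## Synthetic data generator

The generator is the package's definition of the study conditions, not a
test fixture. Per sample it computes per-bin weights

    w_i ∝ m_i · g(GC_i) · r_i · (len_i / bin_size)

(m_i a mappability weight, default 1; the length factor covers short
terminal bins) and draws counts as a **single multinomial** of the total
read count — totals are exact by construction, matching how unique-read
counts are reported. Optional extra-Poisson noise multiplies the weights
by unit-mean gamma variates (variance = `dispersion`, default 0).

Defaults and the reasoning behind them:

| parameter | default | rationale |
|---|---|---|
| total_reads | 7,000,000 | the study's per-sample unique-read yield |
| bin_size | 100 kb | not stated by the source method; balances the 1 Mb smallest clinical event (10 bins) against per-bin noise (~226 reads) |
| fetal fraction | mean 0.10, SD 0.035, truncated to [0.03, 0.25] | male-pregnancy cohort average ≈ 9.7%, observed range ~4.7–17.6% |
| g(GC) | 1.2 − 1.5·(GC − 0.42)² | smooth unimodal Illumina-era bias peaking near GC 0.42, range ≈ 0.7–1.2 on [0,1]; configurable |
| GC field | smoothed random field, 0.25–0.65, ~Mb-scale autocorrelation | enough GC structure to make correction non-trivial without modelling isochores |
| chrY female background β | 0.002 | makes fetal-sex calling non-trivial but solvable at this depth |
| CNV sizes | uniform 1–129 Mb | the clinical cohort's event range |

What the generator does **not** emulate: alignment artifacts and blacklist
regions, mappability variation (m_i defaults to 1), GC dependence that
varies between samples, batch effects, fragment-length information, and
mosaicism beyond a reduced-dose `copy_delta`. Passing tests therefore
demonstrate correctness of the inference given the mixture-multinomial
model, not robustness to every real-world artifact; the GC-correction and
threshold machinery is exercised, but real data would add systematic noise
sources the simulation leaves out.

## GC correction

Counts are regressed on GC with LOWESS (tricube weights, span 0.3 of the
fitted points, 2 robustifying iterations, evaluation clamped to the fitted
GC range) over autosomal, full-length, mappable bins with GC in
[0.25, 0.75]; extreme-GC bins are corrected but never fitted. Copy ratio
is count over expected count, rescaled so the **autosomal median is
exactly 1** (median, not mean, so CNVs and sex chromosomes do not bias the
scale). Sex chromosomes are excluded from fitting and scaling — their
dosage depends on fetal sex — but are corrected with the autosomal curve.
Per-bin standard errors use the Poisson approximation
σ_i = √max(count_i, 1)/expected_i (zero-count bins get ratio 0 with a
finite σ). Correction is per-sample; no pooled reference panel is used.
Degenerate GC (no variation) falls back to a global-median curve with a
warning.

Because the curve and the median are fitted per sample, a CNV spanning a
non-negligible fraction of the autosomes contaminates both slightly; at
real genome scale a 15 Mb event is ~0.5% of the autosomes and the effect
is below Poisson noise (the test suite checks the 0.95 expectation at
hg19 scale for exactly this reason).

## Fetal fraction from chrY

cr_Y is chrY read density relative to **autosomal** read density (reads
per binned bp over reads per binned bp). Relative to the autosomes the
expectation is linear in f — background + f/2 for a male fetus — whereas
normalizing against the whole genome would make the denominator depend on
the sample's own sex-chromosome dosage. GC_Y is the coverage-weighted mean
GC of chrY bins.

Two reference regressions of cr_Y on GC_Y are fitted by OLS (degree 1 by
default): an adult-male panel (the f = 1 limit of the mixture) and a
female-fetus-pregnancy panel (background only). The estimate is

    ε = (cr_Y − f_female(GC_Y)) / (f_male(GC_Y) − f_female(GC_Y)),

clamped to [0, 1]; by construction ε = 0 exactly on the female curve and
ε = 1 exactly on the male curve. The male curve must lie strictly above
the female curve over the observed GC range or fitting fails. A panel
whose GC values span less than `min_gc_span` (default 0.02) carries no
usable GC information — the spread is counting noise — so its fit
collapses to the panel mean rather than extrapolating a spurious slope.
Sex is called male only when cr_Y exceeds the female curve by
k = 3 female-panel residual SDs; female samples get no ε (chrY carries no
fetal-fraction information for a female fetus — SNP-, size- or X-based
estimators are out of scope). ε is clamped rather than rejected when
sampling noise pushes it slightly outside [0, 1].

## CNV calling

**Segmentation.** Each chromosome's copy-ratio profile is segmented in two
deterministic phases:

1. *Breakpoint localization* — recursive binary splitting at the (leftmost)
   breakpoint maximizing the Welch-type statistic
   t(b) = (mean_L − mean_R) / √(SE_L² + SE_R²) (variances propagated from
   the per-bin Poisson σ), down to segments of `min_seg_bins` (default 10
   = 1 Mb).
2. *Significance filtering* — bottom-up agglomeration: repeatedly merge the
   adjacent pair with the smallest |t| until every remaining boundary
   separates its neighbors by |t| ≥ `z_split` (default 5, genome-wide
   control over ~3×10⁴ bins).

A single top-down split cannot be tested directly against `z_split`: for a
short CNV interior to a long chromosome, every single cut mixes the event
into a long flank and the maximal single-split |t| is a fraction of the
local contrast (e.g. ~1.5 for a 15 Mb event in the middle of a 190 Mb
chromosome at f = 0.10, versus ~7–9 between the event and its immediate
neighbors). Splitting to the floor and testing each boundary against its
neighbors restores the local contrast; under the null all boundaries fall
back below threshold and the chromosome returns as one segment. The
original caller's exact split statistic and threshold schedule are
unpublished; this construction is our reconstruction, constrained by the
published operating points (≥90% detection of >10 Mb events at f = 0.10,
~1.6% euploid false-positive rate).

Boundary localization at f = 0.10 is a few bins (a few hundred kb): the
per-bin shift is 0.75 σ, so single-bin precision is information-
theoretically out of reach at this depth.

**Dynamic threshold.** A segment becomes a call iff

    |mean − baseline| ≥ θ = max( z_c · SE_segment ,  κ · f_eff / 2 )

and its span is at least `min_report_mb` (default 1 Mb). The first term
(z_c = 3.5) shrinks with depth and segment length; the second (κ = 0.5)
is half the expected single-copy fetal shift and stops deep data from
reporting sub-biological wiggles. When f is unavailable (female fetus,
failed estimate), f_eff falls back to 0.07, near the low end of clinically
observed fractions. Adjacent same-direction calls separated by fewer than
`min_seg_bins` bins are merged, and the merged span is re-measured from
the data.

**Baselines.** Autosomes are tested against 1; chrX against the dosage
expected for the called sex (1 − f/2 for a male fetus); chrY is skipped by
default (background-dominated at screening depth, and whole-chromosome Y
dosage is the sex call itself). Whole-chromosome events emerge as ordinary
chromosome-spanning calls; there is no dedicated aneuploidy statistic.

## Concordance evaluation

Truth strings are parsed from two dialects: karyotype forms
(`46,XX,del(5)(p15.33p15.2)`, one or more del/dup segments, optional `?`)
resolved against a cytoband table — a band prefix like `p14` is the union
of p14.1–p14.3, a band pair spans the outer boundaries of both — and array
forms (`arr 13q21.2(60,399–61,730)×3`) whose kb coordinates are taken
verbatim (×1 → loss, ×3 → gain). Derivative/mosaic/isochromosome forms
raise and are supplied through the manifest's explicit-coordinate
override. The shipped cytoband file is a reconstructed hg19-like subset
(labelled synthetic); users can substitute a genuine UCSC file.

Each truth event is classified against same-sample calls: candidates are
same-chromosome, same-direction calls, each call matched to at most one
event (greedy by overlap, ties to the larger truth). **Consistent** means
the call is contained in the truth interval or the overlap reaches 50% of
*either* interval's length — the either-interval rule is the only simple
reading consistent with every published label, some of which are >50% only
truth-relative and some only call-relative. **Partly consistent** means a
candidate exists but overlaps less than 50% of both (possibly zero);
**inconsistent** means no candidate (a false negative). Overlap arithmetic
is closed-interval kb.

Sensitivity is per truth event with consistent + partly consistent as true
positives; specificity is per euploid sample (a sample with any
false-positive call counts once); both are stratified around 10 Mb (events
by truth size, false-positive calls by call size) and carry exact
Clopper–Pearson 95% CIs — which reproduce the published intervals to their
printed precision, confirming the CI-method choice. PPV is confirmed
events over confirmed events plus false-positive calls. Empty strata
report NA, never 0.

## Pipeline and determinism

`run_pipeline` wires simulate → normalize → fetal fraction → call →
evaluate. Calling stages never read the truth manifest (a static check in
the test suite enforces that the calling modules contain no truth-handling
code). Every stochastic stage derives its generator from the run seed via
`SeedSequence.spawn`, so reruns are byte-identical and the artifact
manifest records a SHA-256 per file.

## Problem sizes used in the test suite

Unit and property tests run on a 5-chromosome, 430 Mb toy genome at
depth-matched reads (10⁶ reads ≈ 226/bin) so the per-bin statistics equal
the study regime; end-to-end power, calibration and fetal-fraction
recovery checks run on the full hg19-scale genome at 7×10⁶ reads with
50–100 replicates — enough to measure a ≥90% detection rate and ≤5%
false-positive rate with useful precision.

## Known limitations

* The dynamic-threshold form and the split-then-merge stopping rule are
  reconstructions; the original caller's internals are unpublished.
* Per-sample GC correction cannot remove sample-specific bias that
  correlates with copy number, and no pooled-reference (PCA/batch)
  normalization is implemented.
* Sub-megabase events are out of scope by design (`min_report_mb` = 1).
* Fetal-fraction estimation requires a male fetus; female-fetus samples
  use the fallback fraction in the caller's threshold.
* Translocations and derivative chromosomes are represented only by their
  dosage consequence; breakpoint reconstruction is out of scope.
* The synthetic cytoband table is hg19-like, not the genuine UCSC release;
  band-resolved coordinates are faithful only to the boundaries it ships.
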