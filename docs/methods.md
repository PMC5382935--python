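# Methods

## The counting model

cfDNA from a pregnancy is a two-compartment mixture: maternal fragments at
proportion (1 − f) and feto-placental fragments at fetal fraction f. For a
genomic bin b the expected read count is proportional to

    copy_mix(b) = [(1 − f) · maternal_copies(b) + f · fetal_copies(b)] / 2

times a sample-specific GC bias factor and the sequencing depth. A fetal
trisomy (3 fetal copies) therefore inflates the affected chromosome's
share of autosomal reads by ≈ f/2; a mosaic trisomy with trisomic-cell
fraction m by ≈ f·m/2; a twin pregnancy contributes each fetus at its own
fraction. All calling logic in this package is derived from this mixture
algebra.

Everything is scored on *chromosome representation* — a chromosome's share
of the autosomal usable-bin total — so absolute depth cancels exactly and
samples at 9M and 16M reads are directly comparable.

## Normalization

Stage order: SCALED → GC_CORRECTED → DENOISED → SMOOTHED. Stage tags only
advance; values are clipped at zero; the map from raw counts to normalized
values is deterministic.

**Scaling.** Each bin count is divided by the sample's chromosome 1–22
total. Autosomal values then sum to 1 per sample.

**GC correction.** One loess curve per sample (statsmodels `lowess`,
local-linear, span 0.3, one robustness iteration) of scaled bin value
against bin GC. The curve is fitted on usable autosomal bins *excluding*
chromosomes 13/18/21 and applied to every bin: the scored chromosomes are
GC-shifted, and letting their bins into the fit would regress a genuine
trisomy partially away. Correction multiplies each bin by
(fit-mean / curve(gc)), clamps curve evaluation to the fitted GC range at
the endpoints, and renormalizes each row to its pre-correction autosomal
total so representations remain proportions. The curves are per-sample
because the clinically damaging component of GC bias varies from library
to library; a shared training curve can only remove the average trend and
leaves the sample-to-sample variance that drowns trisomy 13 (see the
rescue analysis below). Degenerate GC input (all bins equal) makes the
correction an identity, with a warning.

**PCA denoising.** A k = 5 principal-component model is fitted on
presumed-euploid training samples over usable autosomal bins excluding
13/18/21. Denoising returns the training mean plus the residual of the
mean-centred sample after projection onto the component subspace; k = 0 is
the identity. Excluding the scored chromosomes from the loadings makes it
structurally impossible for the model to absorb whole-chromosome trisomy
signal, which is confirmed by test (chr21 excess preserved ≥ 0.8×).

**Smoothing.** Bin values are expressed as ratios to *training* per-bin
medians (fixed constants — ratios to the sample's own chromosome median
would inject that median's sampling noise into every bin of the
chromosome, a coupling we measured as a 20–30% heavy-tailed inflation of
the chromosome-representation spread). Ratios are winsorized at training
1st/99th percentiles widened ten-fold (limits ≈ [0.65, 1.35]); a gross
single-bin artifact (10× spike) is clipped while genuine copy-number
excursions (maternal duplication ≈ 1.5, heterozygous fetal deletion
≈ 0.93, trisomy ≈ 1 + f/2) pass untouched. A 5-bin centred rolling median
follows. Chromosomes with fewer usable bins than the window pass through.
Uniform chromosome-wide shifts are preserved (ratio space is
location-equivariant here), chromosome totals move < 2%, and sporadic bin
artifacts are strongly suppressed (across-sample MAD of an
artifact-bearing chromosome drops ~3× in test).

## Z-scores and the reference

    Z = (x − μ) / σ

* μ is the sample's plate median (plates with fewer than 8 samples fall
  back to the training median). A second pass excludes from the plate
  median any sample whose first-pass |Z| exceeds 8 on any autosome:
  aneuploid or grossly aberrant samples shift every other chromosome's
  representation through the shared autosomal denominator, and in cohorts
  enriched for positives a single-pass median inherits that bias.
* σ is 1.4826 × MAD of plate-median-centred training representations
  (normal-consistency scaling, so Z is in SD-like units and the 4/8
  thresholds keep their usual meaning). Centring the training
  representations by their own plate medians before taking the MAD makes
  the euploid Z spread ≈ 1 under the same μ policy used at call time.

Calls: Z ≤ 4 NEGATIVE, Z > 8 POSITIVE, otherwise REVIEW (boundaries: 4 is
negative, 8 is review). Named regions — shipped defaults are synthetic
22q11 (DiGeorge-like, 20% of toy chromosome 22) and 1p36 stand-ins, with
coordinates generated to match the toy genome; supply a BED for real
coordinates — are scored identically with the region's usable bins as the
unit and carry their own training σ; deletions score negative.

Fetal fraction is *not* used to modify Z.

## Why GC correction rescues trisomy 13

With per-sample GC tilt b ~ N(0, 0.4) and chromosome 13 GC-shifted +0.12,
the uncorrected chr13 representation acquires a ≈ 0.4 × 0.115 ≈ 4.6%
sample-to-sample spread — an order of magnitude above counting noise — so
the training σ balloons and a trisomy-13 excess of f/2 = 5% scores Z ≈ 1.
After per-sample loess correction the spread returns to ≈ 0.3% and the
same samples score Z ≈ 28. The test suite asserts both sides (all T13
Z < 4 raw, > 8 corrected).

## Fetal fraction

Male fetuses (four methods, median consensus; all depth-invariant):

* **a** `2(1 − meanXbin/meanAutoBin)` — X bin average against the autosomal
  bin average, no external reference;
* **b** `2(1 − X_i/X_f)` — X_i the sample's median X-bin representation,
  X_f the median over called-female samples on the run (training fallback
  below 3 run females);
* **c** linear interpolation of X_i between non-pregnant female (FF ≡ 0)
  and non-pregnant male (FF ≡ 1) anchors;
* **d** `(normY − background)/slope` with the Y model fitted as background
  (female median, with MAD) and the least-squares slope of normalized Y
  count against X-based FF over male-fetus training.

Consensus = median (mean of middle two for four values); at least three
methods are required. Negative X-based FF is propagated: X
over-representation is evidence of maternal X gains, not an error.

Female fetuses: lasso regression (scikit-learn `LassoCV`, pure L1, 10-fold
CV over a 40-point penalty path selecting minimum CV error) of consensus
FF on bin counts scaled by total reads, uncorrected for GC, with bins on
chromosomes 13/18/21/X/Y excluded from the features. A null-model guard
collapses the fit to the intercept unless the selected model beats the
intercept-only CV error by at least 10% of the response variance: with
p ≫ n, the L1 path can otherwise express a small chance correlation
between the response and a high-variance count direction, and because
Pearson correlation is scale-free such a model produces confident-looking
held-out correlations from negligible predicted variance. The guard is
what makes a permuted-response fit predict a constant.

Reporting gate: final FF < 0.05 → no report (exactly 5% passes).

## Genetic sex and sex-chromosome aneuploidy

Genetic sex: MALE iff the normalized Y count over selected Y bins exceeds
background + 10 × background MAD. Y bins are selected from non-pregnant
adult training by the conjunctive rule male mean > 5 × female mean AND
male mean > 150 reads. The 10-MAD dead band (rather than a tighter 3)
costs nothing — a male fetus at even 2% FF sits ≈ 40 MADs above female
background — while a tight band lets a few percent of true females drift
over the line into the male FF path and spurious low-FF no-reports.

Classification in the (FFx, FFy) plane with band half-width τ = 0.02,
derived from mixture expectations (male fetus: FFx ≈ FFy ≈ f; 45,X:
FFx ≈ f, FFy ≈ 0; 47,XXX: FFx ≈ −f; 47,XXY: FFx ≈ 0, FFy ≈ f; 47,XYY:
FFy ≈ 2 FFx). Anything off these loci routes to REVIEW, never to a wrong
definite karyotype. Guards applied before any fetal call: FFx > 0.5 is
biologically impossible for a fetal event and flags suspected maternal
45,X mosaicism; FFx < −0.5 flags suspected non-mosaic maternal 47,XXX. A
fetal-range negative FFx (−0.5 < FFx < −τ with no Y) is called 47,XXX but
carries the maternal-XXX flag, since low-grade maternal X gains mimic it.

## Reporting rules

Precedence: read-depth QC failure > low fetal fraction > maternal-event
screens > calls. The two screens:

* **Partial duplication** — for any scored chromosome not called negative,
  the ideogram (bin value / euploid training median, DENOISED stage, so
  segment amplitudes are not winsorized) is segmented by binary
  change-point splitting (split accepted when it cuts the within-segment
  SSE by more than 10 σ̂² log n, σ̂ from successive differences; minimum
  segment 2 bins; ties break toward fewer segments). If elevated segments
  (mean ratio > 1.1) cover < 70% of usable bins while the rest sit in
  [0.97, 1.03], the chromosome is flagged as a suspected maternal
  duplication and the sample reports SUSPECTED_MATERNAL instead of
  positive. Whole-chromosome elevation (a real trisomy) does not flag.
* **Global screen** — ≥ 3 chromosomes outside {13, 18, 21} with |Z| > 8
  flag a global copy-number aberration (fibroid-like cfDNA); positive and
  review calls on such a background are suppressed to SUSPECTED_MATERNAL.

The 1.1 ratio, 70% span, [0.97, 1.03] flat band and ≥ 3-chromosome rule
are this package's operationalization of qualitative clinical review
practice; all are config-exposed. Mosaicism is not called separately — it
surfaces as an attenuated Z (expected f·m/2), which is why borderline
mosaics land in the review zone.

## The simulator

`cfnips.simulate` draws negative-binomial counts (size 5e4, i.e. variance
μ(1 + μ/5e4) — near-Poisson with mild overdispersion) around the mixture
expectation over a toy genome of 22 autosomes + X + Y with bin counts
proportional to human chromosome lengths (~2360 bins of 50 kb at scale 1).
Defaults are the study conditions: depth 1.2e7 reads, FF ~
Uniform(0.08, 0.15), 12-sample plates (round-robin assignment so plates
are scenario mixtures, as clinical plates are), per-bin GC ~ Beta(14, 21)
with chromosomes 13 and 18 shifted GC-rich (+0.12 / +0.06) so
GC-correction scenarios stress the scored chromosomes. At these settings
the euploid chromosome-representation robust CV is ≤ 0.3% (measured
≈ 0.16–0.18% on chr13/18/21), which is what puts a trisomy at FF 0.08 near
Z ≈ 17 and euploids' maximum near 3. GC bias defaults to off; bias
scenarios pass explicit per-sample tilt coefficients.

Y bins carry a small constant background weight (0.02 per bin) in every
sample — the misalignment floor that makes the female Y level non-zero —
plus a few deliberately defective bins (pseudoautosomal-like shared bins,
and weak bins with sub-threshold male signal) so the Y-selection rules
have something to reject.

**Planted female-FF signal.** Real cfDNA carries FF-correlated autosomal
coverage structure (fragment-length and accessibility effects) that the
female-FF regression exploits; read counts alone contain no such signal,
so the simulator plants an explicit stand-in: a fixed random direction v
over autosomal bins off 13/18/21, modulated per sample by a latent score
equal to `strength` × standardized FF plus complementary noise (amplitude
1%). The direction derives from a configuration-held seed — not the
cohort seed — so the same structure is present in training and test
cohorts, which is precisely what lets a trained model generalize. This is
a simulator construct: recovery tests (held-out r ≈ 0.84 at strength
0.85) validate the regression machinery, not any claim about real-world
female-FF accuracy. Strength 0 disables planting bit-identically.

What the simulator does not emulate: read-level artifacts (alignment,
duplicates, error profiles), fragment-length biology, mappability
structure beyond the planted defective bins, population variation in
maternal CNV burden, and laboratory batch effects beyond the GC tilt and
the rank-one structures above. Passing tests therefore demonstrate the
calling logic under the stated counting model, not clinical performance.

## Problem sizes and determinism

Reference fits use 200 euploid pregnancies + 30 non-pregnant adults;
validation cohorts are 40–140 samples. These sizes keep every reference
estimate comfortably stable (σ from 200 samples has ≈ 5% relative error)
while the whole suite runs in well under a minute of simulation time. All
randomness flows through explicit integer seeds; the same seed reproduces
cohorts byte-identically.

## Known limitations

* The toy genome has ~40× fewer bins than a real 50 kb binning of hg19;
  per-chromosome counting noise is matched by construction (robust CV
  calibration), but bin-level statistics are coarser.
* Region coordinates for 22q11/1p36 are synthetic toy-genome stand-ins.
* The smoothing stage slightly inflates clean-data spread on GC-shifted
  chromosomes (absorbed into σ, so Z remains calibrated); its benefit
  appears only under bin-level artifacts.
* Monosomy of autosomes, translocation detection and tumor signals are
  out of scope; a Robertsonian trisomy 21 is simply a high-Z trisomy 21.
* The redraw workflow for borderline results (Z slightly below 4) is a
  clinical-process decision and is not modeled.
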