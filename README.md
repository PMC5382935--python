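# cfnips

Aneuploidy screening from binned low-pass cfDNA read counts.

Non-invasive prenatal screening (NIPS) sequences cell-free DNA from
maternal plasma — a mixture of maternal and placental fragments at fetal
fraction *f* — at shallow depth (~0.2–0.6×) and asks whether a chromosome
contributes more reads than it should. A fetal trisomy adds one chromosome
copy to the fetal compartment only, so the affected chromosome's share of
reads rises by roughly *f*/2: a 1–10% excess that has to be separated from
GC bias, batch artifacts and maternal copy-number variation. `cfnips`
implements the full calling pipeline for this problem, plus the screens
that keep maternal events from becoming false-positive fetal calls, and a
simulator that generates every scenario with known truth.

## What the caller does

Given per-bin read counts (50 kb bins) for a plate of samples and a
trained reference:

1. **Normalization** — scale each sample by its autosomal total; fit and
   divide out a per-sample loess curve of count vs bin GC; remove
   high-order artifacts with a PCA model trained on euploid samples
   (components exclude chromosomes 13/18/21 so trisomy signal cannot be
   absorbed); winsorize and rolling-median-smooth bin-level outliers.
2. **Scoring** — chromosome representation
   `chrRep_i = chrTotalRC_i / Σ_{j=1..22} chrTotalRC_j`, scored as
   `Z = (x − μ) / σ` with μ the plate median and σ a normal-consistent MAD
   (1.4826 × MAD) from a training cohort. Calls: Z ≤ 4 negative, Z > 8
   positive, in between review. Named regions (22q11/DiGeorge, 1p36) are
   scored the same way; deletions give negative Z.
3. **Fetal fraction** — four X/Y-based estimators with a median consensus
   for male fetuses (`2(1 − X_i/X_f)` variants, anchored interpolation,
   and `(normY − background)/slope` from a fitted Y model); an
   L1-regularized regression over autosomal bins for female fetuses.
   Final FF below 5% blocks reporting.
4. **Sex-chromosome aneuploidy** — classification in the (FFx, FFy) plane:
   45,X / 47,XXX / 47,XXY / 47,XYY bands derived from mixture algebra,
   with guards for maternal 45,X mosaicism (FFx > 0.5) and maternal
   47,XXX (negative FFx).
5. **False-positive screens** — per-bin ideogram tracks (euploid
   expectation 1.0) with change-point segmentation detect maternal
   segmental duplications (elevated sub-chromosomal segment → suspected
   maternal, not positive); a whole-genome screen flags multi-chromosome
   aberrations (e.g. fibroid-shed DNA) and suppresses positives on such
   backgrounds.

Sample QC requires 9M reads for any report and 4.5M for sex-chromosome
analyses.

## Worked example

```python
from cfnips import (SimConfig, make_bins, simulate_cohort, train_models,
                    call_cohort, reports_to_frame)
from cfnips.simulate import training_scenarios

config = SimConfig()                      # 1.2e7 reads, ~2360 50kb bins
bins = make_bins(config, seed=1)
train_counts, _ = simulate_cohort(
    bins, training_scenarios(n_euploid=200, n_adult=15), config, seed=2,
    prefix="T")
models = train_models(train_counts, bins, seed=0)

cohort, truth = simulate_cohort(
    bins, [("euploid_female", 10), ("t21", 2), ("maternal_dup_chr21", 1)],
    config, seed=11, prefix="C")
reports = reports_to_frame(call_cohort(cohort, models))
print(reports[["z_chr21", "call_chr21", "ff_final", "final_status"]].round(2))
```

prints

```
           z_chr21 call_chr21  ff_final        final_status
sample_id
C0000         1.79   NEGATIVE      0.11            NEGATIVE
...
C0009        -0.96   NEGATIVE      0.11            NEGATIVE
C0010        29.04   POSITIVE      0.14            POSITIVE
C0011        23.24   POSITIVE      0.11            POSITIVE
C0012        13.55   POSITIVE      0.11  SUSPECTED_MATERNAL
```

The ten euploid pregnancies score |Z| < 3 on chromosome 21 and report
negative. The two trisomy-21 samples (fetal fractions 0.14 and 0.11) score
Z = 29.0 and 23.2 — far above the positive threshold of 8 — and report
positive. The last sample carries a *maternal* duplication of 10% of
chromosome 21: its chromosome-level Z (13.6) looks like a trisomy, but the
ideogram shows the elevation confined to a short segment at ratio ≈ 1.5,
so the report is downgraded to `SUSPECTED_MATERNAL` instead of a
false-positive fetal call.

The same pipeline is available from the shell:

```bash
cfnips simulate --seed 5 --out-dir sim/ \
    --scenarios euploid_female=60,euploid_male=60,adult_male=15,adult_female=15
cfnips train --bins sim/bins.bed --counts sim/counts.tsv \
    --truth sim/truth.tsv --out models.npz
cfnips call --counts sim/counts.tsv --models models.npz --out reports.tsv
cfnips stats --counts sim/counts.tsv --models models.npz \
    --truth sim/truth.tsv --out stats.tsv
```

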