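"""Y-bin selection, genetic sex calling and sex-chromosome aneuploidy
classification in the (FFx, FFy) plane.

All quantities here are computed from raw counts normalized by the sample's
autosomal total (sex-chromosome analyses deliberately bypass the GC/PCA/
smoothing pipeline, whose reference statistics are autosome-centric).

Decision geometry, from mixture expectations with fetal fraction f:
a male fetus under-represents X by f/2 (so FFx = 2*(1 - X_i/X_f) ~ f) and
contributes Y in proportion to f (FFy ~ f); a 45,X fetus gives (FFx ~ f,
FFy ~ 0); 47,XXX gives (FFx ~ -f, FFy ~ 0); 47,XXY (FFx ~ 0, FFy ~ f);
47,XYY (FFx ~ f, FFy ~ 2f). Classification bands of half-width tau around
those loci; anything else routes to REVIEW, never to a wrong definite
karyotype. FFx > 0.5 is biologically impossible for a fetal event and flags
suspected maternal 45,X mosaicism (fetal call suppressed); a strongly
negative FFx flags suspected non-mosaic maternal 47,XXX.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from .binmodel import BinSet, CountMatrix
from .errors import FitError, ValidationError

SEX_MALE = "MALE"
SEX_FEMALE = "FEMALE"
SEX_SUPPRESSED = "SUPPRESSED"

ANEU_NONE = "NONE"
ANEU_REVIEW = "REVIEW"

FLAG_MATERNAL_45X = "MATERNAL_45X_MOSAIC_SUSPECTED"
FLAG_MATERNAL_XXX = "MATERNAL_XXX_SUSPECTED"

_FEMALE_KARYOTYPES = {"45X", "47XXX"}
_MALE_KARYOTYPES = {"47XXY", "47XYY"}


@dataclass
class YBinReference:
    """Informative Y bins plus the background/slope model.

    Selection (conjunctive, from adult male vs adult female training):
    male mean > fold x female mean AND male mean > min_reads.
    ``background`` is the female level of the normalized Y count;
    ``slope`` converts normalized Y excess into a male fetal fraction.
    """

    bin_ids: pd.Index
    male_means: pd.Series
    female_means: pd.Series
    background: float = np.nan
    background_mad: float = np.nan
    slope: float = np.nan
    residual_sd: float = np.nan

    def __post_init__(self):
        if len(self.bin_ids) == 0:
            raise ValidationError("no Y bins selected")


def select_y_bins(
    male_training: CountMatrix,
    female_training: CountMatrix,
    bins: BinSet,
    fold: float = 5.0,
    min_reads: float = 150.0,
    min_samples: int = 10,
) -> YBinReference:
    """Mark well-performing Y bins from adult male/female training counts."""
    for name, cm in (("male", male_training), ("female", female_training)):
        if len(cm) < min_samples:
            raise FitError(f"need >= {min_samples} adult {name} samples, got {len(cm)}")
    y_ids = bins.ids[bins.chrom_mask("Y")]
    m = male_training.counts.loc[:, y_ids].mean(axis=0)
    f = female_training.counts.loc[:, y_ids].mean(axis=0)
    pass_fold = m > fold * f
    pass_reads = m > min_reads
    selected = pass_fold & pass_reads
    if not selected.any():
        if not pass_reads.any():
            raise FitError(
                f"no Y bin has male mean > {min_reads} reads at training depth"
            )
        raise FitError(f"no Y bin has male mean > {fold}-fold the female mean")
    ids = y_ids[selected.to_numpy()]
    return YBinReference(ids, m[selected], f[selected])


def normalized_y(counts: CountMatrix, bins: BinSet, y_ref: YBinReference) -> pd.Series:
    """Selected-Y-bin total / autosomal total, per sample."""
    auto = counts.autosomal_total(bins)
    return counts.counts.loc[:, y_ref.bin_ids].sum(axis=1) / auto


def fit_y_model(
    y_ref: YBinReference,
    norm_y: pd.Series,
    ffx: pd.Series,
    is_female: pd.Series,
    min_ff_span: float = 0.05,
) -> YBinReference:
    """Fit background (female level) and slope (normalized Y per unit FF).

    Slope from the least-squares line of normalized Y count against the
    X-based fetal fraction over male-fetus training samples; background and
    its MAD from the female samples.
    """
    females = is_female.astype(bool)
    males = ~females
    if not females.any():
        raise FitError("Y model needs female samples for the background level")
    if not males.any():
        raise FitError("Y model needs male-fetus samples; all-female training")
    ff_m = ffx[males].to_numpy(dtype=float)
    if ff_m.max() - ff_m.min() < min_ff_span:
        raise FitError(
            f"male FF span {ff_m.max() - ff_m.min():.3f} < {min_ff_span}; "
            "ill-conditioned slope fit"
        )
    y_m = norm_y[males].to_numpy(dtype=float)
    slope, intercept = np.polyfit(ff_m, y_m, 1)
    if slope <= 0:
        raise FitError("non-positive Y slope")
    resid = y_m - (intercept + slope * ff_m)
    bg = float(norm_y[females].median())
    bg_mad = float(median_abs_deviation(norm_y[females].to_numpy()))
    y_ref.background = bg
    y_ref.background_mad = max(bg_mad, 1e-12)
    y_ref.slope = float(slope)
    y_ref.residual_sd = float(resid.std(ddof=1)) if males.sum() > 2 else 0.0
    return y_ref


def call_genetic_sex(norm_y: float, y_ref: YBinReference, k_mads: float = 3.0) -> str:
    """MALE iff the normalized Y count exceeds background + k * MAD.

    Depth-invariant because the input is an autosomal-normalized proportion.
    """
    if not np.isfinite(y_ref.background):
        raise FitError("Y model not fitted")
    thresh = y_ref.background + k_mads * y_ref.background_mad
    return SEX_MALE if norm_y > thresh else SEX_FEMALE


@dataclass
class SexCall:
    genetic_sex: str
    aneuploidy: str
    ffx: float
    ffy: float
    flags: set = field(default_factory=set)

    def __post_init__(self):
        if self.aneuploidy in _MALE_KARYOTYPES and self.genetic_sex != SEX_MALE:
            raise ValidationError(f"{self.aneuploidy} requires MALE genetic sex")
        if self.aneuploidy in _FEMALE_KARYOTYPES and self.genetic_sex != SEX_FEMALE:
            raise ValidationError(f"{self.aneuploidy} requires FEMALE genetic sex")


def classify_sex_aneuploidy(
    ffx: float,
    ffy: float,
    tau: float = 0.02,
    maternal_45x_ffx: float = 0.5,
    maternal_xxx_ffx: float = -0.5,
) -> SexCall:
    """Classify in the (FFx, FFy) plane; see module docstring for geometry."""
    # maternal guards first: no fetal call on either
    if ffx > maternal_45x_ffx:
        return SexCall(SEX_SUPPRESSED, ANEU_REVIEW, ffx, ffy, {FLAG_MATERNAL_45X})
    if ffx < maternal_xxx_ffx:
        return SexCall(SEX_SUPPRESSED, ANEU_REVIEW, ffx, ffy, {FLAG_MATERNAL_XXX})

    if ffy <= tau:  # no meaningful Y contribution -> female fetus
        if abs(ffx) <= tau:
            return SexCall(SEX_FEMALE, ANEU_NONE, ffx, ffy)
        if ffx > tau:
            return SexCall(SEX_FEMALE, "45X", ffx, ffy)
        # X over-representation: fetal 47,XXX, but low-grade maternal X gains
        # produce the same signature — flag for review of maternal origin.
        return SexCall(SEX_FEMALE, "47XXX", ffx, ffy, {FLAG_MATERNAL_XXX})

    # Y present -> male fetus
    if abs(ffx - ffy) <= tau:
        return SexCall(SEX_MALE, ANEU_NONE, ffx, ffy)
    if abs(ffx) <= tau < ffy:
        return SexCall(SEX_MALE, "47XXY", ffx, ffy)
    if ffy > ffx + tau and ffx > tau:
        return SexCall(SEX_MALE, "47XYY", ffx, ffy)
    return SexCall(SEX_MALE, ANEU_REVIEW, ffx, ffy)
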