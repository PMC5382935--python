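"""Fetal fraction estimation.

Male fetuses: four depth-invariant estimators with a median consensus —

  a) ``2 * (1 - meanXbin / meanAutosomeBin)`` (X bin average against the
     autosomal bin average, no external reference);
  b) ``2 * (1 - X_i / X_f)`` where ``X_i`` is the sample's median X-bin
     representation and ``X_f`` the median over female samples on the run;
  c) linear interpolation of ``X_i`` between a non-pregnant-female (two X
     copies, FF-equivalent 0) and a non-pregnant-male (one X copy,
     FF-equivalent 1) anchor;
  d) ``(normalized Y count - background) / slope`` from the fitted Y model.

Female fetuses: an L1-regularized linear model (lasso, 10-fold CV over the
penalty path) trained on male-fetus samples with consensus FF as response,
using bin counts scaled by total reads and *uncorrected* for GC; bins on
chromosomes 13/18/21/X/Y are excluded from the features by construction.

Negative X-based FF is propagated, not clipped: X over-representation is
evidence of maternal X gains (e.g. 47,XXX), handled by the sex-aneuploidy
classifier. The reporting gate fails any final FF below 5%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV

from .binmodel import BinSet, CountMatrix
from .errors import FitError, ValidationError
from .sexaneu import YBinReference

GATE_PASS = "PASS"
GATE_LOW_FF = "LOW_FF"

FF_MODEL_EXCLUDE = ("13", "18", "21", "X", "Y")


# ---------------------------------------------------------------------------
# X / Y based estimators
# ---------------------------------------------------------------------------

def x_representation(counts: CountMatrix, bins: BinSet) -> pd.Series:
    """Median usable-X-bin count normalized by the autosomal total."""
    auto = counts.autosomal_total(bins)
    ids = bins.ids[bins.usable & bins.chrom_mask("X")]
    return counts.counts.loc[:, ids].median(axis=1) / auto


def ff_x(x_i: float, x_f: float) -> float:
    """FF = 2 * (1 - X_i / X_f); negative when X is over-represented."""
    if x_f <= 0:
        raise ValidationError("female X reference must be positive")
    return 2.0 * (1.0 - x_i / x_f)


def run_female_median_x(
    x_i: pd.Series,
    is_female: pd.Series,
    min_females: int = 3,
    training_x_f: float | None = None,
) -> float:
    """X_f = median of female samples' X representations on the run.

    Falls back to the training value (with a warning) when the run carries
    too few females.
    """
    females = x_i[is_female.astype(bool)]
    if len(females) < min_females:
        if training_x_f is None:
            raise FitError(
                f"only {len(females)} female samples on run and no training X_f"
            )
        warnings.warn(
            f"only {len(females)} female samples on run; using training X_f"
        )
        return float(training_x_f)
    return float(females.median())


def ff_a(counts: CountMatrix, bins: BinSet) -> pd.Series:
    """Method (a): X bin average over autosomal bin average, per sample."""
    x_ids = bins.ids[bins.usable & bins.chrom_mask("X")]
    a_ids = bins.ids[bins.usable & bins.autosomal]
    mean_x = counts.counts.loc[:, x_ids].mean(axis=1)
    mean_a = counts.counts.loc[:, a_ids].mean(axis=1)
    return 2.0 * (1.0 - mean_x / mean_a)


def ff_c(x_i: float, x_f_anchor: float, x_m_anchor: float) -> float:
    """Method (c): interpolate X_i between the 2-copy and 1-copy anchors."""
    if x_f_anchor <= x_m_anchor:
        raise ValidationError("female anchor must exceed male anchor")
    return (x_f_anchor - x_i) / (x_f_anchor - x_m_anchor)


def ff_y(norm_y: float, y_ref: YBinReference) -> float:
    """Method (d): (normalized Y count - background) / slope."""
    if not np.isfinite(y_ref.slope):
        raise FitError("Y model not fitted")
    if y_ref.slope <= 0:
        raise FitError("non-positive Y slope")
    return (norm_y - y_ref.background) / y_ref.slope


def consensus_male_ff(values: list[float]) -> float:
    """Median of the available method values (mean of middle two for four);
    requires at least three."""
    vals = [v for v in values if v is not None and np.isfinite(v)]
    if len(vals) < 3:
        raise FitError(f"consensus needs >= 3 method values, got {len(vals)}")
    return float(np.median(vals))


def ff_gate(final_ff: float, threshold: float = 0.05) -> str:
    """LOW_FF iff final FF < threshold (exactly 5% passes)."""
    return GATE_LOW_FF if final_ff < threshold else GATE_PASS


@dataclass
class FFEstimate:
    """Per-method fetal fraction values and the reported consensus."""

    ff_a: float | None = None
    ff_b: float | None = None
    ff_c: float | None = None
    ff_d: float | None = None
    consensus_male: float | None = None
    ff_female_model: float | None = None
    final: float | None = None
    gate: str = GATE_PASS

    def as_dict(self) -> dict:
        return {
            "ff_a": self.ff_a, "ff_b": self.ff_b, "ff_c": self.ff_c,
            "ff_d": self.ff_d, "consensus_male": self.consensus_male,
            "ff_female_model": self.ff_female_model, "final": self.final,
            "gate": self.gate,
        }


# ---------------------------------------------------------------------------
# female-fetus regression model
# ---------------------------------------------------------------------------

def scale_by_total(counts: CountMatrix) -> pd.DataFrame:
    """Bin counts divided by the sample's total read count (all bins)."""
    total = counts.total_reads
    return counts.counts.astype(float).div(total, axis=0)


@dataclass
class FemaleFFModel:
    """Lasso over autosomal bins excluding 13/18/21 (and X/Y).

    ``alpha`` is the CV-selected penalty; coefficients on excluded
    chromosomes are absent by construction of the feature set.
    """

    bin_ids: pd.Index
    coef: np.ndarray
    intercept: float
    alpha: float
    cv_folds: int
    schema: str = "cfnips-female-ff-1"

    def predict(self, features: pd.DataFrame) -> pd.Series:
        x = features.loc[:, self.bin_ids].to_numpy()
        return pd.Series(x @ self.coef + self.intercept, index=features.index)


def fit_female_ff_model(
    counts: CountMatrix,
    bins: BinSet,
    response_ff: pd.Series,
    cv: int = 10,
    min_samples: int = 50,
    min_cv_r2: float = 0.1,
    seed: int = 0,
) -> FemaleFFModel:
    """Fit the regularized female-FF regression on male-fetus training.

    10-fold cross-validation over the lasso path (pure L1) picks the penalty
    with minimum CV error. A null-model guard then compares that CV error
    with the intercept-only model: unless the selected model explains at
    least ``min_cv_r2`` of the response variance out of fold, the fit
    collapses to the intercept (a response-free model has nothing worth
    keeping — small chance correlations with high-variance count directions
    would otherwise be amplified into confident-looking predictions).
    """
    if len(counts) < min_samples:
        raise FitError(f"female-FF model needs >= {min_samples} samples")
    y = response_ff.loc[counts.samples].to_numpy(dtype=float)
    if np.std(y) < 1e-9:
        raise FitError("constant response; female-FF CV is degenerate")
    mask = bins.usable & ~np.isin(bins.chrom, FF_MODEL_EXCLUDE)
    ids = bins.ids[mask]
    X = scale_by_total(counts).loc[:, ids].to_numpy()
    model = LassoCV(cv=cv, alphas=40, max_iter=5000, tol=1e-4,
                    random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    best_cv_mse = model.mse_path_.mean(axis=1).min()
    coef, intercept, alpha = model.coef_.copy(), float(model.intercept_), float(model.alpha_)
    if best_cv_mse > (1.0 - min_cv_r2) * y.var():
        coef = np.zeros_like(coef)
        intercept = float(y.mean())
        alpha = float(np.max(model.alphas_))
    return FemaleFFModel(ids, coef, intercept, alpha, cv)


def ff_female(counts: CountMatrix, model: FemaleFFModel) -> pd.Series:
    """Predicted fetal fraction for (presumed female-fetus) samples."""
    return model.predict(scale_by_total(counts))
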