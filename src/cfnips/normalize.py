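"""Count normalization: autosomal scaling, GC correction, PCA denoising,
bin-level smoothing.

Stage order is SCALED -> GC_CORRECTED -> DENOISED -> SMOOTHED and tags only
advance in that order. All stages preserve the sample axis and commute with
sample reordering; values are clipped at zero from the SCALED stage on.

GC correction fits one loess curve per sample (scaled bin value vs bin GC)
because the bias that matters clinically varies from library to library; a
shared training curve can only remove the average bias. The curve is fitted
on usable autosomal bins *excluding* chromosomes 13/18/21 — the scored,
GC-shifted chromosomes — so that a genuine trisomy on a GC-rich chromosome
is not regressed away, and is then applied to every bin. After correction
each row is renormalized to its pre-correction autosomal total, so
chromosome representation remains a proportion.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from statsmodels.nonparametric.smoothers_lowess import lowess

from .binmodel import AUTOSOMES, BinSet, CountMatrix
from .errors import FitError, QCFailure, ValidationError


class Stage(enum.IntEnum):
    SCALED = 1
    GC_CORRECTED = 2
    DENOISED = 3
    SMOOTHED = 4


@dataclass
class NormalizedMatrix:
    """Sample x bin matrix of unitless scaled/corrected quantities."""

    values: pd.DataFrame
    stage: Stage

    def __post_init__(self):
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("negative values in normalized matrix")

    def advanced(self, values: pd.DataFrame, stage: Stage) -> "NormalizedMatrix":
        if stage <= self.stage:
            raise ValidationError(
                f"stage must advance: {self.stage.name} -> {stage.name}"
            )
        return NormalizedMatrix(values, stage)


def scale_by_autosomal_total(counts: CountMatrix, bins: BinSet) -> NormalizedMatrix:
    """Divide every bin count by the sample's chr1-22 total.

    Post: each sample's autosomal values sum to 1; depth cancels exactly.
    """
    auto = counts.autosomal_total(bins)
    if (auto <= 0).any():
        bad = auto.index[auto <= 0].tolist()
        raise QCFailure(f"zero autosomal total for samples: {bad}")
    values = counts.counts.astype(float).div(auto, axis=0)
    return NormalizedMatrix(values, Stage.SCALED)


# ---------------------------------------------------------------------------
# GC correction
# ---------------------------------------------------------------------------

@dataclass
class GCModel:
    """Per-sample loess curves: expected scaled count as a function of GC.

    Evaluation outside the fitted GC range clamps to the nearest endpoint.
    ``degenerate`` marks an all-equal GC input, for which correction is the
    identity.
    """

    span: float
    gc_grid: np.ndarray                      # sorted fit-bin GC values
    curves: pd.DataFrame                     # samples x grid, fitted values
    fit_means: pd.Series                     # per-sample mean over fit bins
    degenerate: bool = False

    def expected(self, sample_id: str, gc: np.ndarray) -> np.ndarray:
        c = self.curves.loc[sample_id].to_numpy()
        return np.interp(gc, self.gc_grid, c)   # np.interp clamps at endpoints


def fit_gc_model(
    scaled: NormalizedMatrix,
    bins: BinSet,
    span: float = 0.3,
    exclude_chroms: tuple[str, ...] = ("13", "18", "21"),
    min_bins: int = 100,
) -> GCModel:
    """Fit one loess curve per sample on usable autosomal bins.

    Local-linear loess (R ``loess`` family) via statsmodels ``lowess``.
    """
    fit_mask = bins.usable & bins.autosomal & ~np.isin(bins.chrom, exclude_chroms)
    if fit_mask.sum() < min_bins:
        raise FitError(f"GC fit needs >= {min_bins} usable bins, got {fit_mask.sum()}")
    gc = bins.gc[fit_mask]
    order = np.argsort(gc, kind="stable")
    gc_sorted = gc[order]
    if gc_sorted[-1] - gc_sorted[0] < 1e-6:
        warnings.warn("degenerate GC range; GC correction is the identity")
        grid = np.array([gc_sorted[0], gc_sorted[0] + 1e-6])
        X = scaled.values.loc[:, bins.ids[fit_mask]]
        means = X.mean(axis=1)
        curves = pd.DataFrame(
            np.tile(means.to_numpy()[:, None], 2), index=X.index, columns=[0, 1]
        )
        return GCModel(span, grid, curves, means, degenerate=True)

    X = scaled.values.loc[:, bins.ids[fit_mask]].to_numpy()[:, order]
    delta = 0.005 * (gc_sorted[-1] - gc_sorted[0])
    fitted = np.empty_like(X)
    for i in range(X.shape[0]):
        fitted[i] = lowess(
            X[i], gc_sorted, frac=span, it=1, delta=delta, return_sorted=False
        )
    curves = pd.DataFrame(fitted, index=scaled.values.index)
    fit_means = pd.Series(X.mean(axis=1), index=scaled.values.index)
    return GCModel(span, gc_sorted, curves, fit_means)


def gc_correct(scaled: NormalizedMatrix, model: GCModel, bins: BinSet) -> NormalizedMatrix:
    """Flatten the per-sample GC trend; renormalize to pre-correction totals."""
    if scaled.stage != Stage.SCALED:
        raise ValidationError("gc_correct expects a SCALED matrix")
    if model.degenerate:
        return scaled.advanced(scaled.values.copy(), Stage.GC_CORRECTED)
    auto_ids = bins.ids[bins.autosomal]
    out = np.empty_like(scaled.values.to_numpy())
    gc_all = bins.gc
    vals = scaled.values.to_numpy()
    pre_auto = scaled.values.loc[:, auto_ids].sum(axis=1).to_numpy()
    auto_mask = bins.autosomal
    for i, sid in enumerate(scaled.values.index):
        expected = model.expected(sid, gc_all)
        floor = 1e-3 * max(model.fit_means.loc[sid], 1e-300)
        expected = np.maximum(expected, floor)
        out[i] = vals[i] * (model.fit_means.loc[sid] / expected)
        post = out[i][auto_mask].sum()
        if post > 0:
            out[i] *= pre_auto[i] / post
    corrected = pd.DataFrame(
        np.clip(out, 0, None), index=scaled.values.index, columns=scaled.values.columns
    )
    return scaled.advanced(corrected, Stage.GC_CORRECTED)


# ---------------------------------------------------------------------------
# PCA artifact removal
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Top-k principal subspace of presumed-euploid training samples.

    Loadings live on usable autosomal bins excluding the scored trisomy
    chromosomes, so whole-chromosome signal on 13/18/21 cannot be absorbed.
    k = 0 is the identity.
    """

    k: int
    bin_ids: pd.Index
    mean: np.ndarray = field(default_factory=lambda: np.empty(0))
    components: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))


def fit_pca(
    training: NormalizedMatrix,
    bins: BinSet,
    k: int = 5,
    exclude_chroms: tuple[str, ...] = ("13", "18", "21"),
) -> PCAModel:
    mask = bins.usable & bins.autosomal & ~np.isin(bins.chrom, exclude_chroms)
    ids = bins.ids[mask]
    n = len(training.values)
    if k >= n:
        raise FitError(f"PCA k={k} must be < training size {n}")
    if k == 0:
        return PCAModel(0, ids)
    X = training.values.loc[:, ids].to_numpy()
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(X)
    return PCAModel(k, ids, pca.mean_, pca.components_)


def pca_denoise(matrix: NormalizedMatrix, model: PCAModel) -> NormalizedMatrix:
    """Remove the projection onto the training subspace.

    Output on modeled bins = training_mean + residual of the mean-centred
    sample after projection onto the top-k components; all other bins pass
    through unchanged.
    """
    out = matrix.values.copy()
    if model.k > 0:
        X = out.loc[:, model.bin_ids].to_numpy()
        Xc = X - model.mean
        Xc -= (Xc @ model.components.T) @ model.components
        out.loc[:, model.bin_ids] = np.clip(model.mean + Xc, 0, None)
    return matrix.advanced(out, Stage.DENOISED)


# ---------------------------------------------------------------------------
# bin-level smoothing
# ---------------------------------------------------------------------------

@dataclass
class SmoothModel:
    """Winsor limits and reference bin medians for the smoothing stage.

    Bin values are expressed as ratios to the *training* per-bin medians
    (fixed constants — using the sample's own chromosome median instead
    would leak its noise into every bin of the chromosome), winsorized at
    training percentiles widened by ``winsor_scale`` so that gross
    single-bin artifacts are clipped while genuine copy-number excursions
    (segment ratios ~0.5-1.5) survive, then passed through a centred
    rolling median.
    """

    ratio_limits: dict        # chrom -> (lo, hi)
    bin_medians: pd.Series    # training median per usable bin
    window: int = 5


def fit_smoother(
    training: NormalizedMatrix,
    bins: BinSet,
    lower_pct: float = 1.0,
    upper_pct: float = 99.0,
    scale: float = 10.0,
    window: int = 5,
) -> SmoothModel:
    limits = {}
    meds = {}
    for chrom in AUTOSOMES + ("X",):
        mask = bins.usable & bins.chrom_mask(chrom)
        if mask.sum() < window:
            continue
        ids = bins.ids[mask]
        block = training.values.loc[:, ids].to_numpy()
        med = np.median(block, axis=0)
        med = np.where(med > 0, med, np.nan)
        ratios = block / med
        q_lo, q_hi = np.nanpercentile(ratios, [lower_pct, upper_pct])
        limits[chrom] = (max(0.05, 1.0 + scale * (q_lo - 1.0)),
                         1.0 + scale * (q_hi - 1.0))
        meds[chrom] = pd.Series(med, index=ids)
    bin_medians = (pd.concat(meds.values()) if meds
                   else pd.Series(dtype=float))
    return SmoothModel(limits, bin_medians, window)


def smooth(matrix: NormalizedMatrix, model: SmoothModel, bins: BinSet) -> NormalizedMatrix:
    """Winsorize bin/training-median ratios, then 5-bin rolling median.

    Chromosomes with fewer usable bins than the window pass through, as do
    bins without a positive training median. Order-preserving at chromosome
    scale: a uniform (trisomy-like) shift passes through the ratio space
    untouched and the rolling median is location-equivariant.
    """
    out = matrix.values.copy()
    w = model.window
    for chrom, (lo, hi) in model.ratio_limits.items():
        mask = bins.usable & bins.chrom_mask(chrom)
        if mask.sum() < w:
            continue
        cols = bins.ids[mask].intersection(model.bin_medians.index)
        med = model.bin_medians.loc[cols].to_numpy()
        ok = np.isfinite(med) & (med > 0)
        if ok.sum() < w:
            continue
        cols = cols[ok]
        med = med[ok]
        block = out.loc[:, cols].to_numpy()
        ratios = np.clip(block / med, lo, hi)
        sm = (
            pd.DataFrame(ratios)
            .T.rolling(window=w, center=True, min_periods=1)
            .median()
            .T.to_numpy()
        )
        out.loc[:, cols] = sm * med
    return matrix.advanced(out, Stage.SMOOTHED)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

class Normalizer:
    """Fitted normalization pipeline: scale -> GC -> PCA -> smooth.

    GC curves are per-sample and therefore refit for every cohort passed to
    :meth:`transform`; the PCA subspace and winsor limits are trained once on
    a presumed-euploid reference cohort by :meth:`fit`. The raw-counts ->
    normalized map is deterministic.
    """

    def __init__(self, bins: BinSet, config=None):
        from .config import PipelineConfig

        self.bins = bins
        self.config = config or PipelineConfig()
        self.pca: PCAModel | None = None
        self.smoother: SmoothModel | None = None

    def fit(self, training: CountMatrix) -> "Normalizer":
        cfg = self.config
        scaled = scale_by_autosomal_total(training, self.bins)
        gc = fit_gc_model(scaled, self.bins, cfg.gc_span, cfg.pca_exclude)
        corrected = gc_correct(scaled, gc, self.bins)
        self.pca = fit_pca(corrected, self.bins, cfg.pca_components, cfg.pca_exclude)
        denoised = pca_denoise(corrected, self.pca)
        self.smoother = fit_smoother(
            denoised, self.bins, cfg.winsor_lower_pct, cfg.winsor_upper_pct,
            cfg.winsor_scale, cfg.smooth_window,
        )
        return self

    def transform(
        self, counts: CountMatrix, stop_stage: Stage = Stage.SMOOTHED
    ) -> dict[Stage, NormalizedMatrix]:
        """Run the pipeline, returning every computed stage keyed by tag."""
        if self.pca is None or self.smoother is None:
            raise FitError("Normalizer.fit must run before transform")
        cfg = self.config
        stages: dict[Stage, NormalizedMatrix] = {}
        m = scale_by_autosomal_total(counts, self.bins)
        stages[Stage.SCALED] = m
        if stop_stage >= Stage.GC_CORRECTED:
            gc = fit_gc_model(m, self.bins, cfg.gc_span, cfg.pca_exclude)
            m = gc_correct(m, gc, self.bins)
            stages[Stage.GC_CORRECTED] = m
        if stop_stage >= Stage.DENOISED:
            m = pca_denoise(m, self.pca)
            stages[Stage.DENOISED] = m
        if stop_stage >= Stage.SMOOTHED:
            m = smooth(m, self.smoother, self.bins)
            stages[Stage.SMOOTHED] = m
        return stages
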