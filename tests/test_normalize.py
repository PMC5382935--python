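"""Normalization stages: scaling, GC correction, PCA denoising, smoothing."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import median_abs_deviation, spearmanr

from cfnips import aneucall
from cfnips.binmodel import BinSet, CountMatrix
from cfnips.errors import FitError, QCFailure, ValidationError
from cfnips.normalize import (
    Stage,
    fit_gc_model,
    fit_pca,
    fit_smoother,
    gc_correct,
    pca_denoise,
    scale_by_autosomal_total,
    smooth,
)
from cfnips.simulate import SimConfig, simulate_cohort


def _flat_binset(n_per_chrom, gc=None, chroms=("1", "2", "3")):
    rows = []
    rng = np.random.default_rng(0)
    for c in chroms:
        for i in range(n_per_chrom):
            g = gc if gc is not None else float(rng.beta(14, 21))
            rows.append((c, i * 50_000, (i + 1) * 50_000, g, True))
    return BinSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "gc",
                                              "usable"]))


class TestScaling:
    def test_bin_share_arithmetic(self):
        bs = _flat_binset(1, gc=0.4)
        counts = pd.DataFrame([[500, 4_999_500, 5_000_000]], index=["s"],
                              columns=bs.ids)
        cm = CountMatrix(counts, pd.DataFrame({"plate": ["p"]}, index=["s"]))
        scaled = scale_by_autosomal_total(cm, bs)
        assert scaled.values.iloc[0, 0] == pytest.approx(5e-5)
        assert scaled.values.iloc[0].sum() == pytest.approx(1.0)
        assert scaled.stage is Stage.SCALED

    def test_depth_cancels_exactly(self):
        bs = _flat_binset(4, gc=0.4)
        row = np.arange(1, 13) * 100
        counts = pd.DataFrame([row, row * 2], index=["lo", "hi"], columns=bs.ids)
        cm = CountMatrix(counts, pd.DataFrame({"plate": ["p", "p"]},
                                              index=["lo", "hi"]))
        scaled = scale_by_autosomal_total(cm, bs)
        assert np.allclose(scaled.values.loc["lo"], scaled.values.loc["hi"])

    def test_zero_autosomal_total_is_qc_failure(self):
        bs = _flat_binset(2, gc=0.4)
        counts = pd.DataFrame([np.zeros(6, dtype=int)], index=["s"],
                              columns=bs.ids)
        cm = CountMatrix(counts, pd.DataFrame({"plate": ["p"]}, index=["s"]))
        with pytest.raises(QCFailure):
            scale_by_autosomal_total(cm, bs)

    def test_stage_tags_only_advance(self):
        bs = _flat_binset(2, gc=0.4)
        counts = pd.DataFrame([np.full(6, 10)], index=["s"], columns=bs.ids)
        cm = CountMatrix(counts, pd.DataFrame({"plate": ["p"]}, index=["s"]))
        scaled = scale_by_autosomal_total(cm, bs)
        with pytest.raises(ValidationError, match="advance"):
            scaled.advanced(scaled.values, Stage.SCALED)


class TestGCCorrection:
    @staticmethod
    def _biased_cohort(slope, n=30, bins_per_chrom=80, seed=0, depth=2000.0):
        rng = np.random.default_rng(seed)
        bs = _flat_binset(bins_per_chrom, chroms=("1", "2", "3", "4"))
        mean = depth * (1.0 + slope * (bs.gc - 0.4))
        counts = rng.poisson(np.tile(mean, (n, 1)))
        cm = CountMatrix(
            pd.DataFrame(counts, index=[f"s{i}" for i in range(n)],
                         columns=bs.ids),
            pd.DataFrame({"plate": ["p"] * n}, index=[f"s{i}" for i in range(n)]))
        return bs, cm

    def test_planted_bias_flattened(self):
        """mean x (1 + 2*(gc - 0.4)) bias: corrected bin medians are flat in
        GC (|Spearman| < 0.05)."""
        bs, cm = self._biased_cohort(slope=2.0)
        scaled = scale_by_autosomal_total(cm, bs)
        model = fit_gc_model(scaled, bs, exclude_chroms=())
        corrected = gc_correct(scaled, model, bs)
        rho_before = spearmanr(scaled.values.median(axis=0), bs.gc).statistic
        rho_after = spearmanr(corrected.values.median(axis=0), bs.gc).statistic
        assert abs(rho_before) > 0.5
        assert abs(rho_after) < 0.05

    def test_bias_free_input_nearly_identity(self):
        # deep counts: the identity property at negligible counting noise
        bs, cm = self._biased_cohort(slope=0.0, depth=50_000.0)
        scaled = scale_by_autosomal_total(cm, bs)
        model = fit_gc_model(scaled, bs, exclude_chroms=())
        corrected = gc_correct(scaled, model, bs)
        rel = np.abs(corrected.values.to_numpy() / scaled.values.to_numpy() - 1)
        assert rel.max() < 0.01

    def test_autosomal_total_preserved(self):
        bs, cm = self._biased_cohort(slope=1.0)
        scaled = scale_by_autosomal_total(cm, bs)
        corrected = gc_correct(scaled, fit_gc_model(scaled, bs, exclude_chroms=()),
                               bs)
        assert np.allclose(corrected.values.sum(axis=1),
                           scaled.values.sum(axis=1), rtol=1e-9)

    def test_degenerate_gc_warns_and_is_identity(self):
        bs = _flat_binset(40, gc=0.4)
        rng = np.random.default_rng(1)
        counts = rng.poisson(1000, size=(25, len(bs)))
        cm = CountMatrix(
            pd.DataFrame(counts, index=[f"s{i}" for i in range(25)],
                         columns=bs.ids),
            pd.DataFrame({"plate": ["p"] * 25}, index=[f"s{i}" for i in range(25)]))
        scaled = scale_by_autosomal_total(cm, bs)
        with pytest.warns(UserWarning, match="degenerate"):
            model = fit_gc_model(scaled, bs, exclude_chroms=())
        corrected = gc_correct(scaled, model, bs)
        assert np.allclose(corrected.values, scaled.values)

    def test_too_few_bins_rejected(self):
        bs, cm = self._biased_cohort(slope=0.0, bins_per_chrom=10)
        scaled = scale_by_autosomal_total(cm, bs)
        with pytest.raises(FitError, match="bins"):
            fit_gc_model(scaled, bs, exclude_chroms=())


class TestPCA:
    @staticmethod
    def _cohort(n=40, seed=0):
        rng = np.random.default_rng(seed)
        bs = _flat_binset(60, chroms=("1", "2", "13", "21"))
        counts = rng.poisson(2000, size=(n, len(bs)))
        cm = CountMatrix(
            pd.DataFrame(counts, index=[f"s{i}" for i in range(n)],
                         columns=bs.ids),
            pd.DataFrame({"plate": ["p"] * n}, index=[f"s{i}" for i in range(n)]))
        return bs, scale_by_autosomal_total(cm, bs)

    def test_k0_is_identity(self):
        bs, scaled = self._cohort()
        model = fit_pca(scaled, bs, k=0)
        out = pca_denoise(scaled, model)
        assert np.allclose(out.values, scaled.values)
        assert out.stage is Stage.DENOISED

    def test_k_at_least_training_size_rejected(self):
        bs, scaled = self._cohort(n=10)
        with pytest.raises(FitError, match="training size"):
            fit_pca(scaled, bs, k=10)

    def test_planted_rank_one_artifact_removed(self):
        bs, scaled = self._cohort(n=60, seed=1)
        rng = np.random.default_rng(2)
        ids = bs.ids[bs.autosomal & ~np.isin(bs.chrom, ("13", "21"))]
        v = rng.normal(size=len(ids))
        v /= np.linalg.norm(v)
        load = rng.normal(scale=5.0, size=len(scaled.values))
        vals = scaled.values.copy()
        amp = vals[ids].to_numpy().mean() * 0.05
        vals[ids] += amp * np.outer(load, v)
        vals = vals.clip(lower=0)
        perturbed = type(scaled)(vals, Stage.SCALED)
        model = fit_pca(perturbed, bs, k=3, exclude_chroms=("13", "21"))
        out = pca_denoise(perturbed, model)
        proj = (out.values[ids].to_numpy()
                - out.values[ids].to_numpy().mean(axis=0)) @ v
        assert proj.var() < 0.05 * (amp * load).var()

    def test_trisomy_signal_survives_euploid_trained_denoising(self):
        """A chr21-confined excess passes through components fitted on
        euploid training with 13/18/21 excluded."""
        bs, scaled = self._cohort(n=50, seed=3)
        model = fit_pca(scaled, bs, k=5, exclude_chroms=("13", "21"))
        sample = scaled.values.iloc[[0]].copy()
        ids21 = bs.ids[bs.chrom_mask("21")]
        sample[ids21] *= 1.05
        before = sample[ids21].sum(axis=1).iloc[0]
        base = scaled.values.iloc[[0]][ids21].sum(axis=1).iloc[0]
        out = pca_denoise(type(scaled)(sample, Stage.SCALED), model)
        after = out.values[ids21].sum(axis=1).iloc[0]
        assert (after - base) >= 0.8 * (before - base)


class TestSmoothing:
    def test_single_outlier_pulled_within_limits(self, bins, models, sim_config):
        cohort, _ = simulate_cohort(bins, [("euploid_female", 3)], sim_config,
                                    seed=11)
        stages = models.normalizer.transform(cohort, stop_stage=Stage.DENOISED)
        den = stages[Stage.DENOISED]
        sm_model = models.normalizer.smoother
        ids = bins.ids[bins.usable & bins.chrom_mask("2")]
        vals = den.values.copy()
        target = ids[10]
        vals.loc[vals.index[0], target] *= 10.0
        out = smooth(type(den)(vals, Stage.DENOISED), sm_model, models.bins)
        lo, hi = sm_model.ratio_limits["2"]
        ratio = (out.values.loc[out.values.index[0], target]
                 / sm_model.bin_medians.loc[target])
        assert ratio <= hi * 1.05   # rolling median can only pull it further in

    def test_constant_input_unchanged(self):
        bs = _flat_binset(30, gc=0.4, chroms=("1",))
        vals = pd.DataFrame(np.full((25, len(bs)), 1.0 / len(bs)),
                            index=[f"s{i}" for i in range(25)], columns=bs.ids)
        from cfnips.normalize import NormalizedMatrix

        train = NormalizedMatrix(vals, Stage.DENOISED)
        model = fit_smoother(train, bs)
        out = smooth(NormalizedMatrix(vals.copy(), Stage.DENOISED), model, bs)
        assert np.allclose(out.values, vals, rtol=1e-12)

    def test_short_chromosome_passes_through(self):
        bs = _flat_binset(3, gc=0.4, chroms=("1",))
        from cfnips.normalize import NormalizedMatrix, SmoothModel

        vals = pd.DataFrame(np.random.default_rng(0).random((5, 3)),
                            index=[f"s{i}" for i in range(5)], columns=bs.ids)
        model = SmoothModel({}, pd.Series(dtype=float), window=5)
        out = smooth(NormalizedMatrix(vals.copy(), Stage.DENOISED), model, bs)
        assert out.values.equals(vals)

    def test_smoothing_reduces_spread_under_bin_artifacts(self, bins, models,
                                                          sim_config):
        """Sporadic 10x bin spikes: across-sample MAD of the chr21
        representation shrinks after smoothing."""
        cohort, _ = simulate_cohort(bins, [("euploid_female", 40)], sim_config,
                                    seed=12)
        counts = cohort.counts.copy()
        rng = np.random.default_rng(9)
        spike = rng.choice(np.flatnonzero(models.bins.chrom_mask("21")
                                          & models.bins.usable), 3,
                           replace=False)
        for col in models.bins.ids[spike]:
            hit = rng.random(len(counts)) < 0.15
            counts.loc[hit, col] *= 10
        noisy = CountMatrix(counts, cohort.meta)
        stages = models.normalizer.transform(noisy)
        mads = {}
        for name, stage in [("raw", Stage.DENOISED), ("smoothed", Stage.SMOOTHED)]:
            reps = aneucall.chromosome_representations(stages[stage].values,
                                                       models.bins)
            mads[name] = median_abs_deviation(reps["21"])
        assert mads["smoothed"] <= mads["raw"]

    def test_chromosome_totals_stable(self, bins, models, sim_config):
        cohort, _ = simulate_cohort(bins, [("euploid_female", 5)], sim_config,
                                    seed=13)
        stages = models.normalizer.transform(cohort)
        for stage_pair in [(Stage.DENOISED, Stage.SMOOTHED)]:
            a = aneucall.chromosome_representations(stages[stage_pair[0]].values,
                                                    models.bins)
            b = aneucall.chromosome_representations(stages[stage_pair[1]].values,
                                                    models.bins)
            assert (np.abs(b / a - 1) < 0.02).all().all()


class TestPipelineProperties:
    def test_transform_is_deterministic(self, bins, models, sim_config):
        cohort, _ = simulate_cohort(bins, [("euploid_female", 4)], sim_config,
                                    seed=17)
        a = models.normalizer.transform(cohort)[Stage.SMOOTHED]
        b = models.normalizer.transform(cohort)[Stage.SMOOTHED]
        assert a.values.equals(b.values)

    def test_transform_commutes_with_sample_reordering(self, bins, models,
                                                       sim_config):
        cohort, _ = simulate_cohort(bins, [("euploid_female", 6)], sim_config,
                                    seed=18)
        fwd = models.normalizer.transform(cohort)[Stage.SMOOTHED]
        rev_cohort = cohort.subset(cohort.samples[::-1])
        rev = models.normalizer.transform(rev_cohort)[Stage.SMOOTHED]
        assert np.allclose(rev.values.loc[fwd.values.index], fwd.values)
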