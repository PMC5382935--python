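"""End-to-end training and calling.

``train_models`` fits every reference from a training cohort (euploid
pregnancies of known fetal sex plus non-pregnant adult controls):
usable bins, the normalization pipeline, chromosome/region sigma, euploid
per-bin medians for ideograms, the Y-bin reference with its background/slope
model, X anchors, and the female-FF regression. ``call_cohort`` then runs
the full caller over a cohort and assembles one report per sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import aneucall, fetalfrac, sexaneu
from .aneucall import TRISOMY_CHROMS, ChromosomeReference
from .binmodel import AUTOSOMES, BinSet, CountMatrix, QCStatus, fit_usable_bins, qc_sample
from .config import PipelineConfig
from .errors import FitError, ValidationError
from .fetalfrac import FemaleFFModel, FFEstimate
from .normalize import Normalizer, Stage
from .report import SampleReport, render_report
from .sexaneu import SEX_FEMALE, SEX_MALE, YBinReference


@dataclass
class TrainedModels:
    """Everything the caller needs, fitted once on a training cohort."""

    bins: BinSet                       # with usability fitted
    config: PipelineConfig
    normalizer: Normalizer
    reference: ChromosomeReference     # chromosomes + regions
    regions: pd.DataFrame
    euploid_bin_medians: pd.Series     # DENOISED-stage medians, ideogram baseline
    y_ref: YBinReference
    x_f_training: float                # training female-run X reference
    x_f_anchor: float                  # non-pregnant female anchor (2 X copies)
    x_m_anchor: float                  # non-pregnant male anchor (1 X copy)
    female_ff: FemaleFFModel | None


def _meta_masks(meta: pd.DataFrame):
    st = meta["sample_type"].astype(str)
    sex = meta.get("fetal_sex", pd.Series("", index=meta.index)).astype(str)
    pregnant = st == "pregnancy"
    return {
        "pregnant": pregnant,
        "adult_male": st == "adult_male",
        "adult_female": st == "adult_female",
        "male_fetus": pregnant & sex.isin(["XY", "XXY", "XYY"]),
        "female_fetus": pregnant & sex.isin(["XX", "45X", "XXX"]),
    }


def train_models(
    training: CountMatrix,
    bins: BinSet,
    config: PipelineConfig | None = None,
    regions: pd.DataFrame | None = None,
    fit_female_ff: bool = True,
    seed: int = 0,
) -> TrainedModels:
    """Fit all references from a training cohort.

    ``training.meta`` must carry ``plate``, ``sample_type``
    (pregnancy | adult_male | adult_female) and ``fetal_sex`` (known
    karyotype for pregnancies; used only in training).
    """
    config = config or PipelineConfig()
    masks = _meta_masks(training.meta)
    if not masks["pregnant"].any():
        raise FitError("training cohort has no pregnancy samples")

    # 1. usable bins (autosomes from everyone; X left as shipped; Y via its own rule)
    bins = fit_usable_bins(training, bins, config.cv_threshold,
                           min_samples=config.min_training_samples)

    # 2. Y-bin selection from non-pregnant adults
    y_ref = sexaneu.select_y_bins(
        training.subset(masks["adult_male"]),
        training.subset(masks["adult_female"]),
        bins, config.y_fold, config.y_min_reads,
    )
    usable = bins.usable.copy()
    y_mask = bins.chrom_mask("Y")
    usable[y_mask] = np.isin(bins.ids[y_mask], y_ref.bin_ids)
    bins = bins.with_usable(usable)

    # 3. normalization pipeline on euploid pregnancies
    euploid = training.subset(masks["pregnant"])
    normalizer = Normalizer(bins, config).fit(euploid)
    stages = normalizer.transform(euploid)
    denoised, smoothed = stages[Stage.DENOISED], stages[Stage.SMOOTHED]

    # 4. chromosome + region reference
    if regions is None:
        regions = aneucall.default_regions(bins)
    reps = aneucall.chromosome_representations(smoothed.values, bins)
    reps = pd.concat(
        [reps, aneucall.region_representations(smoothed.values, bins, regions)],
        axis=1,
    )
    reference = aneucall.fit_reference(reps, euploid.plates, config.mad_scale)
    euploid_bin_medians = denoised.values.median(axis=0)

    # 5. X references and the Y background/slope model (raw-count domain)
    x_i = fetalfrac.x_representation(training, bins)
    female_side = masks["female_fetus"] | masks["adult_female"]
    x_f_training = float(x_i[female_side].median())
    x_f_anchor = float(x_i[masks["adult_female"]].median())
    x_m_anchor = float(x_i[masks["adult_male"]].median())
    norm_y = sexaneu.normalized_y(training, bins, y_ref)
    ffx_all = 2.0 * (1.0 - x_i / x_f_training)
    y_ref = sexaneu.fit_y_model(
        y_ref, norm_y[masks["pregnant"]], ffx_all[masks["pregnant"]],
        is_female=masks["female_fetus"][masks["pregnant"]],
    )

    # 6. female-FF regression on male-fetus pregnancies with consensus FF
    female_ff = None
    if fit_female_ff:
        males = training.subset(masks["male_fetus"])
        consensus = _consensus_ff_for(males, bins, y_ref, x_f_training,
                                      x_f_anchor, x_m_anchor)
        female_ff = fetalfrac.fit_female_ff_model(
            males, bins, consensus, seed=seed)

    return TrainedModels(bins, config, normalizer, reference, regions,
                         euploid_bin_medians, y_ref, x_f_training,
                         x_f_anchor, x_m_anchor, female_ff)


def _consensus_ff_for(counts, bins, y_ref, x_f, x_f_anchor, x_m_anchor):
    """Median-of-four male FF for every sample in ``counts``."""
    x_i = fetalfrac.x_representation(counts, bins)
    a = fetalfrac.ff_a(counts, bins)
    norm_y = sexaneu.normalized_y(counts, bins, y_ref)
    out = {}
    for sid in counts.samples:
        vals = [a.loc[sid],
                fetalfrac.ff_x(x_i.loc[sid], x_f),
                fetalfrac.ff_c(x_i.loc[sid], x_f_anchor, x_m_anchor),
                fetalfrac.ff_y(norm_y.loc[sid], y_ref)]
        out[sid] = fetalfrac.consensus_male_ff(vals)
    return pd.Series(out)


def call_cohort(
    cohort: CountMatrix,
    models: TrainedModels,
) -> list[SampleReport]:
    """Run the full caller over a cohort and build one report per sample."""
    cfg, bins = models.config, models.bins
    total = cohort.total_reads
    qc = {sid: qc_sample(sid, float(total.loc[sid]), cfg.min_total_reads,
                         cfg.min_sex_reads)
          for sid in cohort.samples}

    analyzable = pd.Series(
        [total.loc[sid] > 0 for sid in cohort.samples], index=cohort.samples
    )
    stages = models.normalizer.transform(cohort.subset(analyzable))
    denoised, smoothed = stages[Stage.DENOISED], stages[Stage.SMOOTHED]

    reps = aneucall.chromosome_representations(smoothed.values, bins)
    region_reps = aneucall.region_representations(smoothed.values, bins,
                                                  models.regions)
    all_reps = pd.concat([reps[list(AUTOSOMES)], region_reps], axis=1)
    plates = cohort.plates[analyzable]
    z = aneucall.cohort_zscores(all_reps, plates, models.reference,
                                cfg.min_plate_samples)

    # sex-chromosome domain (raw counts)
    x_i = fetalfrac.x_representation(cohort, bins)
    norm_y = sexaneu.normalized_y(cohort, bins, models.y_ref)
    sex_called = pd.Series(
        {sid: sexaneu.call_genetic_sex(norm_y.loc[sid], models.y_ref,
                                       cfg.y_sex_mads)
         for sid in cohort.samples})
    x_f = fetalfrac.run_female_median_x(
        x_i, sex_called == SEX_FEMALE, cfg.min_run_females, models.x_f_training)
    ff_a_all = fetalfrac.ff_a(cohort, bins)
    ff_female_all = (fetalfrac.ff_female(cohort, models.female_ff)
                     if models.female_ff is not None else None)

    reports = []
    for sid in cohort.samples:
        s_qc = qc[sid]
        if not analyzable.loc[sid]:
            reports.append(render_report(sid, s_qc, None, {}, {}, None,
                                         False, set()))
            continue

        chrom_calls = {
            c: (float(z.loc[sid, c]),
                aneucall.classify_trisomy(float(z.loc[sid, c]),
                                          cfg.z_negative_max, cfg.z_positive_min))
            for c in TRISOMY_CHROMS
        }
        region_z = {n: float(z.loc[sid, n]) for n in models.regions["name"]}
        global_flag = aneucall.global_screen(
            z.loc[sid, list(AUTOSOMES)], cfg.global_z, cfg.global_min_chroms)

        # ideogram review of elevated scored chromosomes
        dup_flagged = set()
        for c in TRISOMY_CHROMS:
            if chrom_calls[c][1] != "NEGATIVE":
                track = aneucall.ideogram(
                    denoised.values.loc[sid], bins, c,
                    models.euploid_bin_medians, cfg.segment_penalty,
                    cfg.min_segment_bins)
                if aneucall.detect_partial_duplication(
                        track, cfg.dup_ratio_min, cfg.dup_span_max,
                        cfg.flat_ratio_low, cfg.flat_ratio_high):
                    dup_flagged.add(c)

        # fetal fraction + sex aneuploidy
        ff_est, sex_call = None, None
        if s_qc.sex_analysis_allowed:
            ffx = fetalfrac.ff_x(float(x_i.loc[sid]), x_f)
            ffy = fetalfrac.ff_y(float(norm_y.loc[sid]), models.y_ref)
            ff_est = FFEstimate(
                ff_a=float(ff_a_all.loc[sid]), ff_b=ffx,
                ff_c=fetalfrac.ff_c(float(x_i.loc[sid]), models.x_f_anchor,
                                    models.x_m_anchor),
                ff_d=ffy)
            if sex_called.loc[sid] == SEX_MALE:
                ff_est.consensus_male = fetalfrac.consensus_male_ff(
                    [ff_est.ff_a, ff_est.ff_b, ff_est.ff_c, ff_est.ff_d])
                ff_est.final = ff_est.consensus_male
            else:
                if ff_female_all is not None:
                    ff_est.ff_female_model = float(ff_female_all.loc[sid])
                    ff_est.final = ff_est.ff_female_model
                else:
                    ff_est.final = max(ffx, 0.0)
            ff_est.gate = fetalfrac.ff_gate(ff_est.final, cfg.ff_report_min)
            sex_call = sexaneu.classify_sex_aneuploidy(
                ffx, ffy, cfg.sex_tau, cfg.maternal_45x_ffx, cfg.maternal_xxx_ffx)

        reports.append(render_report(sid, s_qc, ff_est, chrom_calls, region_z,
                                     sex_call, global_flag, dup_flagged))
    return reports


# ---------------------------------------------------------------------------
# model persistence (npz container: arrays + JSON header)
# ---------------------------------------------------------------------------

_SCHEMA = "cfnips-models-1"


def save_models(models: TrainedModels, path) -> None:
    header = {
        "schema": _SCHEMA,
        "config": models.config.as_dict(),
        "x_f_training": models.x_f_training,
        "x_f_anchor": models.x_f_anchor,
        "x_m_anchor": models.x_m_anchor,
        "y": {"background": models.y_ref.background,
              "background_mad": models.y_ref.background_mad,
              "slope": models.y_ref.slope,
              "residual_sd": models.y_ref.residual_sd},
        "reference": {"n_training": models.reference.n_training},
        "has_female_ff": models.female_ff is not None,
    }
    arrays = {
        "bins_chrom": models.bins.chrom.astype("U8"),
        "bins_start": models.bins.df["start"].to_numpy(),
        "bins_end": models.bins.df["end"].to_numpy(),
        "bins_gc": models.bins.gc,
        "bins_usable": models.bins.usable,
        "sigma_index": models.reference.sigma.index.to_numpy().astype("U32"),
        "sigma": models.reference.sigma.to_numpy(),
        "training_median": models.reference.training_median.to_numpy(),
        "regions_name": models.regions["name"].to_numpy().astype("U32"),
        "regions_chrom": models.regions["chrom"].to_numpy().astype("U8"),
        "regions_start": models.regions["start"].to_numpy(),
        "regions_end": models.regions["end"].to_numpy(),
        "euploid_bin_median_ids": models.euploid_bin_medians.index.to_numpy().astype("U40"),
        "euploid_bin_medians": models.euploid_bin_medians.to_numpy(),
        "y_bin_ids": models.y_ref.bin_ids.to_numpy().astype("U40"),
        "y_male_means": models.y_ref.male_means.to_numpy(),
        "y_female_means": models.y_ref.female_means.to_numpy(),
        "pca_mean": models.normalizer.pca.mean,
        "pca_components": models.normalizer.pca.components,
        "pca_bin_ids": models.normalizer.pca.bin_ids.to_numpy().astype("U40"),
        "winsor_chroms": np.array(list(models.normalizer.smoother.ratio_limits),
                                  dtype="U8"),
        "winsor_limits": np.array(list(models.normalizer.smoother.ratio_limits.values())),
        "winsor_med_ids": models.normalizer.smoother.bin_medians.index.to_numpy().astype("U40"),
        "winsor_med": models.normalizer.smoother.bin_medians.to_numpy(),
    }
    if models.female_ff is not None:
        arrays["ff_bin_ids"] = models.female_ff.bin_ids.to_numpy().astype("U40")
        arrays["ff_coef"] = models.female_ff.coef
        header["female_ff"] = {"intercept": models.female_ff.intercept,
                               "alpha": models.female_ff.alpha,
                               "cv_folds": models.female_ff.cv_folds}
    np.savez(path, header=np.array(json.dumps(header)), **arrays)


def load_models(path) -> TrainedModels:
    from .normalize import PCAModel, SmoothModel

    data = np.load(path, allow_pickle=False)
    header = json.loads(str(data["header"]))
    if header.get("schema") != _SCHEMA:
        raise ValidationError(f"unexpected model schema {header.get('schema')!r}")
    cfg_dict = header["config"]
    cfg_dict["pca_exclude"] = tuple(cfg_dict["pca_exclude"])
    config = PipelineConfig(**cfg_dict)
    bins = BinSet(pd.DataFrame({
        "chrom": data["bins_chrom"], "start": data["bins_start"],
        "end": data["bins_end"], "gc": data["bins_gc"],
        "usable": data["bins_usable"]}))
    reference = ChromosomeReference(
        pd.Series(data["sigma"], index=data["sigma_index"]),
        pd.Series(data["training_median"], index=data["sigma_index"]),
        header["reference"]["n_training"])
    regions = pd.DataFrame({
        "name": data["regions_name"], "chrom": data["regions_chrom"],
        "start": data["regions_start"], "end": data["regions_end"]})
    y_ref = YBinReference(
        pd.Index(data["y_bin_ids"]),
        pd.Series(data["y_male_means"], index=data["y_bin_ids"]),
        pd.Series(data["y_female_means"], index=data["y_bin_ids"]),
        background=header["y"]["background"],
        background_mad=header["y"]["background_mad"],
        slope=header["y"]["slope"], residual_sd=header["y"]["residual_sd"])
    normalizer = Normalizer(bins, config)
    normalizer.pca = PCAModel(
        int(data["pca_components"].shape[0]), pd.Index(data["pca_bin_ids"]),
        data["pca_mean"], data["pca_components"])
    normalizer.smoother = SmoothModel(
        {c: tuple(l) for c, l in zip(data["winsor_chroms"],
                                     data["winsor_limits"])},
        pd.Series(data["winsor_med"], index=data["winsor_med_ids"]),
        config.smooth_window)
    female_ff = None
    if header.get("has_female_ff"):
        female_ff = FemaleFFModel(
            pd.Index(data["ff_bin_ids"]), data["ff_coef"],
            header["female_ff"]["intercept"], header["female_ff"]["alpha"],
            header["female_ff"]["cv_folds"])
    return TrainedModels(
        bins, config, normalizer, reference, regions,
        pd.Series(data["euploid_bin_medians"],
                  index=data["euploid_bin_median_ids"]),
        y_ref, header["x_f_training"], header["x_f_anchor"],
        header["x_m_anchor"], female_ff)
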