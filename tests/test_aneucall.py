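"""Chromosome representation, Z scoring, region scoring, ideograms, screens."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from cfnips import aneucall
from cfnips.aneucall import (
    CALL_NEGATIVE,
    CALL_POSITIVE,
    CALL_REVIEW,
    classify_trisomy,
    cohort_zscores,
    default_regions,
    detect_partial_duplication,
    fit_reference,
    global_screen,
    ideogram,
    region_representations,
    segment_track,
    zscore,
)
from cfnips.binmodel import BinSet
from cfnips.errors import ValidationError
from cfnips.normalize import Stage, scale_by_autosomal_total
from cfnips.pipeline import call_cohort
from cfnips.report import reports_to_frame
from cfnips.simulate import SimConfig, simulate_cohort


def _toy_values(chrom_totals: dict, bins_per_chrom=10):
    rows = []
    vals = []
    for c, total in chrom_totals.items():
        for i in range(bins_per_chrom):
            rows.append((c, i * 50_000, (i + 1) * 50_000, 0.4, True))
            vals.append(total / bins_per_chrom)
    bs = BinSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "gc",
                                            "usable"]))
    return bs, pd.DataFrame([vals], index=["s"], columns=bs.ids)


class TestRepresentation:
    def test_share_arithmetic(self):
        bs, vals = _toy_values({"1": 500, "2": 300, "3": 200})
        reps = aneucall.chromosome_representations(vals, bs, ("1", "2", "3"))
        assert reps.loc["s"].tolist() == pytest.approx([0.5, 0.3, 0.2])

    def test_single_chromosome_hoards_everything(self):
        bs, vals = _toy_values({"1": 100, "2": 0, "3": 0})
        reps = aneucall.chromosome_representations(vals, bs, ("1",))
        assert reps.loc["s", "1"] == pytest.approx(1.0)

    def test_zero_denominator_rejected(self):
        bs, vals = _toy_values({"1": 0, "2": 0})
        with pytest.raises(ValidationError, match="denominator"):
            aneucall.chromosome_representations(vals, bs)

    def test_autosomal_representations_sum_to_one(self, separation_reports,
                                                  separation_cohort, models):
        cohort, _ = separation_cohort
        stages = models.normalizer.transform(cohort.subset(cohort.samples[:10]))
        reps = aneucall.chromosome_representations(
            stages[Stage.SMOOTHED].values, models.bins)
        sums = reps[[str(i) for i in range(1, 23)]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_depth_invariance(self, bins, sim_config):
        cohort, _ = simulate_cohort(bins, [("euploid_female", 2)], sim_config,
                                    seed=30)
        from cfnips.binmodel import CountMatrix

        doubled = CountMatrix(cohort.counts * 2, cohort.meta)
        a = aneucall.chromosome_representations(
            scale_by_autosomal_total(cohort, bins).values, bins)
        b = aneucall.chromosome_representations(
            scale_by_autosomal_total(doubled, bins).values, bins)
        assert np.allclose(a, b)


class TestZScore:
    def test_zero_at_the_reference(self):
        assert zscore(0.014, 0.014, 1e-4) == 0.0

    def test_arithmetic(self):
        assert zscore(0.0142, 0.0140, 0.0001) == pytest.approx(2.0)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValidationError, match="sigma"):
            zscore(0.014, 0.014, 0.0)

    def test_euploid_cohort_centred_near_zero(self, separation_reports,
                                              separation_cohort):
        _, df, truth = separation_reports
        eup = truth["scenario"].isin(["euploid_female", "euploid_male"]).values
        for col in ("z_chr13", "z_chr18", "z_chr21"):
            assert abs(df.loc[eup, col].median()) < 0.2


class TestTrisomyCalls:
    @pytest.mark.parametrize(
        "z,call",
        [
            (36.96, CALL_POSITIVE),   # whole-chromosome trisomy archetype
            (5.11, CALL_REVIEW),      # intermediate score prompting ideogram review
            (2.0, CALL_NEGATIVE),
            (4.0, CALL_NEGATIVE),     # boundary: 4 is still negative
            (8.0, CALL_REVIEW),       # boundary: positive needs Z > 8
            (-12.0, CALL_NEGATIVE),
        ],
    )
    def test_thresholds(self, z, call):
        assert classify_trisomy(z) == call

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            classify_trisomy(float("nan"))

    def test_trisomy_z_monotone_in_fetal_fraction(self, bins, models, sim_config):
        from cfnips.binmodel import CountMatrix

        grid = [0.02, 0.04, 0.06, 0.08, 0.12, 0.16, 0.20]
        counts, truths = [], []
        for i, f in enumerate(grid):
            c, t = simulate_cohort(bins, [("t21", 2)], sim_config, seed=40 + i,
                                   prefix=f"G{i}_", ff=f)
            counts.append(c)
            truths.append(t)
        eup, teup = simulate_cohort(bins, [("euploid_female", 12)], sim_config,
                                    seed=39, prefix="GE_")
        all_counts = CountMatrix(
            pd.concat([c.counts for c in counts] + [eup.counts]),
            pd.concat([c.meta for c in counts] + [eup.meta]))
        all_counts.meta["plate"] = "single"
        truth = pd.concat(truths + [teup])
        df = reports_to_frame(call_cohort(all_counts, models))
        t21 = truth["scenario"] == "t21"
        rho = spearmanr(truth.loc[t21, "ff"], df.loc[t21.values, "z_chr21"]).statistic
        assert rho > 0.95


class TestRegions:
    def test_region_equal_to_whole_chromosome(self, bins, models, sim_config):
        cohort, _ = simulate_cohort(bins, [("euploid_female", 5)], sim_config,
                                    seed=44)
        vals = models.normalizer.transform(cohort)[Stage.SMOOTHED].values
        chr21_span = bins.df[bins.df["chrom"] == "21"]["end"].max()
        regions = pd.DataFrame([("whole21", "21", 0, chr21_span)],
                               columns=["name", "chrom", "start", "end"])
        rr = region_representations(vals, models.bins, regions)
        cr = aneucall.chromosome_representations(vals, models.bins, ("21",))
        assert np.allclose(rr["whole21"], cr["21"], rtol=0, atol=1e-9)

    def test_region_without_usable_bins_rejected(self, models):
        regions = pd.DataFrame([("nowhere", "21", 10 ** 9, 10 ** 9 + 1000)],
                               columns=["name", "chrom", "start", "end"])
        vals = pd.DataFrame(
            [np.ones(len(models.bins))], index=["s"], columns=models.bins.ids)
        with pytest.raises(ValidationError, match="usable bins"):
            region_representations(vals, models.bins, regions)

    def test_fetal_microdeletion_scores_negative(self, bins, models, sim_config):
        """Heterozygous fetal deletion of the DiGeorge-like region at FF 15%
        drives the region Z below -4; euploids stay within +/-4."""
        cohort, truth = simulate_cohort(
            bins, [("euploid_female", 20), ("digeorge_del", 6)], sim_config,
            seed=45, ff=0.15)
        df = reports_to_frame(call_cohort(cohort, models))
        dele = (truth["scenario"] == "digeorge_del").values
        assert (df.loc[dele, "z_22q11"] < -4).all()
        assert (df.loc[~dele, "z_22q11"].abs() < 4).all()

    def test_default_regions_cover_enough_bins(self, bins):
        regions = default_regions(bins)
        assert set(regions["name"]) == {"22q11", "1p36"}


@pytest.fixture(scope="module")
def tracks(bins, models, sim_config):
    cohort, truth = simulate_cohort(
        bins, [("euploid_female", 2), ("t21", 2), ("maternal_dup_chr21", 2)],
        sim_config, seed=31, ff=0.10)
    den = models.normalizer.transform(cohort)[Stage.DENOISED]
    out = {}
    for sid, scen in truth["scenario"].items():
        out.setdefault(scen, []).append(
            ideogram(den.values.loc[sid], models.bins, "21",
                     models.euploid_bin_medians))
    return out


class TestIdeogram:
    def test_euploid_track_flat_at_unity(self, tracks):
        for tr in tracks["euploid_female"]:
            assert len(tr.segments) == 1
            assert 0.99 <= tr.ratio.mean() <= 1.01

    def test_trisomy_track_single_elevated_segment(self, tracks):
        for tr in tracks["t21"]:
            assert len(tr.segments) == 1
            assert tr.segments["mean"].iloc[0] == pytest.approx(1.05, abs=0.01)

    def test_maternal_duplication_segment_at_half_copy_gain(self, tracks):
        for tr in tracks["maternal_dup_chr21"]:
            means = tr.segments["mean"]
            assert means.max() == pytest.approx(1.45, abs=0.05)
            assert (means < 1.1).sum() >= 1

    def test_flagging_rules(self, tracks):
        assert all(detect_partial_duplication(t)
                   for t in tracks["maternal_dup_chr21"])
        assert not any(detect_partial_duplication(t) for t in tracks["t21"])
        assert not any(detect_partial_duplication(t)
                       for t in tracks["euploid_female"])

    def test_missing_training_medians_rejected(self, models):
        vals = pd.Series(1.0, index=models.bins.ids)
        with pytest.raises(ValidationError, match="medians"):
            ideogram(vals, models.bins, "21", pd.Series(dtype=float))


class TestSegmentation:
    def test_flat_noise_yields_single_segment(self):
        rng = np.random.default_rng(5)
        seg = segment_track(1.0 + 0.015 * rng.standard_normal(40))
        assert len(seg) == 1

    def test_step_is_found(self):
        rng = np.random.default_rng(6)
        x = 1.0 + 0.015 * rng.standard_normal(40)
        x[20:26] += 0.45
        seg = segment_track(x)
        assert len(seg) == 3
        assert seg["mean"].max() > 1.3


class TestGlobalScreen:
    def test_fibroid_like_pattern_flags(self):
        z = pd.Series(0.0, index=[str(i) for i in range(1, 23)])
        z[["3", "9"]] = [9.0, 10.0]
        z["21"] = 21.0
        z[["4", "11"]] = -9.0
        z["6"] = -8.5
        assert global_screen(z)

    def test_single_elevated_chromosome_does_not_flag(self):
        z = pd.Series(0.0, index=[str(i) for i in range(1, 23)])
        z["21"] = 25.0
        assert not global_screen(z)

    def test_two_off_target_chromosomes_below_threshold(self):
        z = pd.Series(0.0, index=[str(i) for i in range(1, 23)])
        z[["5", "7"]] = 12.0
        assert not global_screen(z)
        z["16"] = -8.5
        assert global_screen(z)


class TestReferenceAndPlates:
    def test_two_pass_mu_resists_aneuploid_contamination(self, models):
        rng = np.random.default_rng(8)
        n = 24
        cols = ["13", "18", "21"]
        base = models.reference.training_median[cols]
        reps = pd.DataFrame(
            base.to_numpy() * (1 + 0.002 * rng.standard_normal((n, 3))),
            columns=cols, index=[f"s{i}" for i in range(n)])
        # half of plate A is strongly trisomic for 21
        reps.iloc[:6, 2] *= 1.05
        plates = pd.Series(["A"] * 12 + ["B"] * 12, index=reps.index)
        z = cohort_zscores(reps, plates, models.reference, min_plate=8)
        eup_a = z.iloc[6:12]["21"]
        eup_b = z.iloc[12:]["21"]
        # contaminated plate A euploids stay comparable to plate B euploids
        assert abs(eup_a.mean() - eup_b.mean()) < 2.0

    def test_small_plates_fall_back_to_training_median(self, models):
        cols = ["13", "18", "21"]
        reps = pd.DataFrame(
            [models.reference.training_median[cols].to_numpy()] * 3,
            columns=cols, index=["a", "b", "c"])
        plates = pd.Series(["tiny"] * 3, index=reps.index)
        z = cohort_zscores(reps, plates, models.reference, min_plate=8)
        assert np.allclose(z, 0.0)
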