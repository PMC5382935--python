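"""Synthetic cfDNA bin-count cohorts with known truth.

The generator emulates the data-generating process the caller assumes:
shallow (~9-16M read) single-end shotgun counts over 50 kb bins, cfDNA as a
maternal/fetal mixture at fetal fraction ``f``, with per-bin negative-binomial
sampling. Expected bin count is proportional to

    copy_mix(bin) * gc_bias(gc)      with
    copy_mix = [(1 - f) * maternal_copy + f * fetal_copy] / 2

(for twins, ``(1 - f1 - f2)*maternal + f1*fetal1 + f2*fetal2`` over 2; a
mosaic trisomy contributes fetal copy ``2 + mosaic_fraction``). Supported
scenarios cover euploid pregnancies of both fetal sexes, whole-chromosome
trisomies, mosaics, twins, sex-chromosome aneuploidies, maternal segmental
duplications, maternal 45,X mosaicism and 47,XXX, multi-chromosome "global"
aberrations (fibroid-like), fetal region microdeletions, non-pregnant adult
references, and low fetal fraction.

GC content per bin is drawn from Beta(14, 21) (mean ~0.40); chromosomes 13
and 18 are shifted GC-rich by construction so that GC-bias scenarios stress
exactly the chromosomes the caller scores. GC bias, when enabled, is a
per-sample linear tilt ``1 + b_i * (gc - 0.40)`` with ``b_i ~ N(mean, sd)``
— the sample-to-sample variation is what inflates chromosome spread and
degrades uncorrected Z scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .binmodel import AUTOSOMES, BinSet, CountMatrix
from .errors import ValidationError

# Toy genome: autosome/X/Y bin counts proportional to human chromosome
# lengths (Mb), scaled so the autosomes total ~2200 50-kb bins.
_CHROM_MB = {
    "1": 249, "2": 243, "3": 198, "4": 191, "5": 181, "6": 171, "7": 159,
    "8": 146, "9": 141, "10": 136, "11": 135, "12": 134, "13": 115,
    "14": 107, "15": 103, "16": 90, "17": 81, "18": 78, "19": 59,
    "20": 63, "21": 48, "22": 51, "X": 155, "Y": 59,
}
_BINS_PER_MB = 0.7636

# Sex-karyotype -> (fetal X copies, fetal Y copies)
SEX_COPIES = {
    "XX": (2, 0), "XY": (1, 1), "45X": (1, 0),
    "XXX": (3, 0), "XXY": (2, 1), "XYY": (1, 2),
}

FF_SIGNAL_CENTER = 0.115  # fixed affine map ff -> latent score, shared by
FF_SIGNAL_SCALE = 0.02    # cohorts; standardizes ff under the default
                          # Uniform(0.08, 0.15) fetal-fraction distribution
FF_SIGNAL_EXCLUDE = ("13", "18", "21", "X", "Y")


def toy_chrom_bins(scale: float = 1.0) -> dict[str, int]:
    """Bin counts per chromosome for the toy genome (scale 1.0 ~ 2360 bins)."""
    return {c: max(8, round(mb * _BINS_PER_MB * scale)) for c, mb in _CHROM_MB.items()}


@dataclass
class SimConfig:
    """Study conditions for a simulated cohort.

    ``depth`` and ``nb_size`` are calibrated together so that the euploid
    chromosome-representation robust CV stays <= 0.3% at the default depth
    (1.2e7 reads, negative-binomial size 5e4 — near-Poisson with a mild
    overdispersion allowance).
    """

    chrom_bins: dict[str, int] = field(default_factory=toy_chrom_bins)
    bin_size: int = 50_000
    depth: float = 1.2e7
    nb_size: float = 5e4           # NB inverse-dispersion (variance = mu(1 + mu/size))
    gc_beta: tuple[float, float] = (14.0, 21.0)
    gc_shift: dict = field(default_factory=lambda: {"13": 0.12, "18": 0.06})
    gc_bias_mean: float = 0.0
    gc_bias_sd: float = 0.0
    ff_range: tuple[float, float] = (0.08, 0.15)
    plate_size: int = 12
    y_background: float = 0.02     # female-level Y weight per bin (misalignment floor)
    y_shared_bins: int = 6         # pseudoautosomal-like Y bins (high female background)
    y_weak_bins: int = 2           # Y bins with too few male reads to be informative
    ff_signal_strength: float = 0.85
    ff_signal_amp: float = 0.01
    ff_signal_seed: int = 202409   # fixed across cohorts so the planted
                                   # structure transfers train -> test

    def __post_init__(self):
        if self.depth <= 0:
            raise ValidationError("depth must be positive")


@dataclass
class SampleTruth:
    """Ground truth for one simulated sample."""

    sample_id: str
    scenario: str = "euploid_female"
    plate: str = "P0"
    sample_type: str = "pregnancy"      # pregnancy | adult_male | adult_female
    ff: float = 0.10
    fetal_sex: str = "XX"               # key of SEX_COPIES
    fetal_autosomal: dict = field(default_factory=dict)   # chrom -> copies (default 2)
    mosaic_fraction: float = 1.0        # fraction of trisomic fetal cells
    fetal_region_del: tuple | None = None   # (chrom, lo_frac, hi_frac) heterozygous
    maternal_autosomal: dict = field(default_factory=dict)  # chrom -> copies
    maternal_dup: tuple | None = None   # (chrom, lo_frac, hi_frac, copies)
    maternal_x_copies: float = 2.0
    maternal_y_copies: float = 0.0
    twin: tuple | None = None           # (ff2, fetal_sex2, fetal_autosomal2)
    depth: float | None = None          # per-sample override

    def __post_init__(self):
        if not 0.0 <= self.ff <= 0.4:
            raise ValidationError(f"{self.sample_id}: ff {self.ff} outside [0, 0.4]")
        if not 0.0 <= self.mosaic_fraction <= 1.0:
            raise ValidationError(f"{self.sample_id}: mosaic fraction outside [0, 1]")
        if self.twin is not None and self.ff + self.twin[0] > 0.5:
            raise ValidationError(
                f"{self.sample_id}: combined twin fetal fractions exceed 0.5"
            )


def make_bins(config: SimConfig, seed: int = 0) -> BinSet:
    """Build the toy-genome bin map with GC drawn per bin."""
    rng = np.random.default_rng(seed)
    rows = []
    a, b = config.gc_beta
    for chrom, n in config.chrom_bins.items():
        gc = rng.beta(a, b, size=n) + config.gc_shift.get(chrom, 0.0)
        gc = np.clip(gc, 0.2, 0.8)
        for i in range(n):
            rows.append(
                (chrom, i * config.bin_size, (i + 1) * config.bin_size, gc[i], True)
            )
    return BinSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "gc", "usable"]))


def _fetal_copies(bins: BinSet, sex: str, autosomal: dict, mosaic: float,
                  region_del: tuple | None) -> np.ndarray:
    xc, yc = SEX_COPIES[sex]
    copies = np.full(len(bins), 2.0)
    for chrom, c in autosomal.items():
        copies[bins.chrom_mask(chrom)] = 2.0 + mosaic * (float(c) - 2.0)
    if region_del is not None:
        chrom, lo, hi = region_del
        m = bins.chrom_mask(chrom)
        idx = np.flatnonzero(m)
        n = len(idx)
        copies[idx[int(np.floor(lo * n)):int(np.ceil(hi * n))]] = 1.0
    copies[bins.chrom_mask("X")] = xc
    copies[bins.chrom_mask("Y")] = yc
    return copies


def _maternal_copies(bins: BinSet, truth: SampleTruth) -> np.ndarray:
    copies = np.full(len(bins), 2.0)
    for chrom, c in truth.maternal_autosomal.items():
        copies[bins.chrom_mask(chrom)] = float(c)
    if truth.maternal_dup is not None:
        chrom, lo, hi, c = truth.maternal_dup
        m = bins.chrom_mask(chrom)
        idx = np.flatnonzero(m)
        n = len(idx)
        copies[idx[int(np.floor(lo * n)):int(np.ceil(hi * n))]] = float(c)
    copies[bins.chrom_mask("X")] = truth.maternal_x_copies
    copies[bins.chrom_mask("Y")] = truth.maternal_y_copies
    return copies


def _y_bin_profile(bins: BinSet, config: SimConfig):
    """Per-Y-bin (specific weight, background weight).

    Most Y bins are male-specific (weight 1 per haploid copy, tiny female
    background). A few are "shared" (pseudoautosomal-like: large background
    in everyone) and a few "weak" (too little male signal) so the Y-bin
    selection rules have something to reject.
    """
    y_idx = np.flatnonzero(bins.chrom_mask("Y"))
    weight = np.ones(len(y_idx))
    background = np.full(len(y_idx), config.y_background)
    ns, nw = config.y_shared_bins, config.y_weak_bins
    background[:ns] = 0.3
    weight[ns:ns + nw] = 0.025
    background[ns:ns + nw] = 0.002
    return y_idx, weight, background


def expected_bin_weights(truth: SampleTruth, bins: BinSet, config: SimConfig,
                         gc_bias: float = 0.0) -> np.ndarray:
    """Un-normalized expected weight per bin for one sample."""
    if truth.sample_type == "adult_male":
        mix = _fetal_copies(bins, "XY", {}, 1.0, None) / 2.0
    elif truth.sample_type == "adult_female":
        mix = _fetal_copies(bins, "XX", {}, 1.0, None) / 2.0
    else:
        maternal = _maternal_copies(bins, truth)
        fetal = _fetal_copies(bins, truth.fetal_sex, truth.fetal_autosomal,
                              truth.mosaic_fraction, truth.fetal_region_del)
        f1 = truth.ff
        if truth.twin is not None:
            ff2, sex2, auto2 = truth.twin
            fetal2 = _fetal_copies(bins, sex2, auto2, 1.0, None)
            mix = ((1 - f1 - ff2) * maternal + f1 * fetal + ff2 * fetal2) / 2.0
        else:
            mix = ((1 - f1) * maternal + f1 * fetal) / 2.0
    # Y-bin structure: copy-proportional specific part + constant background.
    y_idx, y_weight, y_bg = _y_bin_profile(bins, config)
    w = mix.copy()
    w[y_idx] = mix[y_idx] * y_weight + y_bg
    w *= 1.0 + gc_bias * (bins.gc - 0.40)
    return np.maximum(w, 1e-9)


def simulate_sample(truth: SampleTruth, bins: BinSet, config: SimConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Draw one sample's bin counts (negative binomial around the mixture mean)."""
    gc_bias = config.gc_bias_mean
    if config.gc_bias_sd > 0:
        gc_bias = rng.normal(config.gc_bias_mean, config.gc_bias_sd)
    w = expected_bin_weights(truth, bins, config, gc_bias)
    depth = truth.depth if truth.depth is not None else config.depth
    mu = depth * w / w.sum()
    size = config.nb_size
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


# --------------------------------------------------------------------------
# scenarios
# --------------------------------------------------------------------------

def _draw_ff(rng, config) -> float:
    lo, hi = config.ff_range
    return float(rng.uniform(lo, hi))


def _scenario(name, rng, config, **kw) -> dict:
    """Truth keyword arguments for one named scenario."""
    ff = kw.pop("ff", None)
    base: dict = {"scenario": name, "ff": ff if ff is not None else _draw_ff(rng, config)}
    sex = "XX" if rng.random() < 0.5 else "XY"
    if name == "euploid_female":
        base["fetal_sex"] = "XX"
    elif name == "euploid_male":
        base["fetal_sex"] = "XY"
    elif name in ("t21", "t18", "t13"):
        base["fetal_sex"] = sex
        base["fetal_autosomal"] = {name[1:]: 3}
        base["mosaic_fraction"] = kw.pop("mosaic_fraction", 1.0)
    elif name == "mosaic_t21_25":
        base.update(fetal_sex=sex, fetal_autosomal={"21": 3}, mosaic_fraction=0.25)
    elif name == "t21_twin":
        # dizygotic twins discordant for trisomy 21
        f1 = base["ff"] / 2
        base.update(ff=f1, fetal_sex=sex, fetal_autosomal={"21": 3},
                    twin=(f1, "XX", {}))
    elif name == "maternal_dup_chr21":
        base.update(fetal_sex=sex, maternal_dup=("21", 0.60, 0.70, 3))
    elif name == "global_aberration":
        base.update(fetal_sex=sex, maternal_autosomal={
            "3": 2.15, "9": 2.15, "21": 2.15, "4": 1.85, "6": 1.85, "11": 1.85})
    elif name == "digeorge_del":
        base.update(fetal_sex=sex, fetal_region_del=("22", 0.15, 0.35))
    elif name in SEX_COPIES:            # XX / XY / 45X / XXX / XXY / XYY fetus
        base["fetal_sex"] = name
    elif name == "maternal_45x_mosaic":
        base.update(fetal_sex="XX", maternal_x_copies=2.0 - kw.pop("mosaic", 0.6))
    elif name == "maternal_xxx":
        base.update(fetal_sex="XX", maternal_x_copies=3.0)
    elif name == "low_ff_male":
        base.update(ff=kw.pop("ff_low", 0.0275), fetal_sex="XY")
    elif name == "adult_male":
        base.update(sample_type="adult_male", ff=0.0)
    elif name == "adult_female":
        base.update(sample_type="adult_female", ff=0.0)
    else:
        raise ValidationError(f"unknown scenario {name!r}")
    base.update(kw)
    return base


def simulate_cohort(
    bins: BinSet,
    scenarios: list[tuple[str, int]],
    config: SimConfig,
    seed: int,
    prefix: str = "S",
    **scenario_kw,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate a cohort; fully determined by (bins, scenarios, config, seed).

    Samples are laid out scenario-by-scenario and assigned to plates
    round-robin, so every plate is a mixture of scenarios (as clinical
    plates are) and the plate median stays euploid-dominated.
    """
    if not scenarios:
        raise ValidationError("scenario list is empty")
    rng = np.random.default_rng(seed)
    truths: list[SampleTruth] = []
    k = 0
    for name, n in scenarios:
        for _ in range(n):
            kw = _scenario(name, rng, config, **dict(scenario_kw))
            truths.append(SampleTruth(sample_id=f"{prefix}{k:04d}", **kw))
            k += 1
    n_plates = max(1, int(np.ceil(len(truths) / config.plate_size)))
    for i, t in enumerate(truths):
        t.plate = f"{prefix}_plate{i % n_plates:02d}"

    counts = np.stack([simulate_sample(t, bins, config, rng) for t in truths])
    truth_df = pd.DataFrame(
        {
            "sample_id": [t.sample_id for t in truths],
            "plate": [t.plate for t in truths],
            "scenario": [t.scenario for t in truths],
            "sample_type": [t.sample_type for t in truths],
            "ff": [t.ff for t in truths],
            "fetal_sex": [t.fetal_sex for t in truths],
            "trisomy": [";".join(t.fetal_autosomal) or "" for t in truths],
            "mosaic_fraction": [t.mosaic_fraction for t in truths],
        }
    ).set_index("sample_id")
    cm = CountMatrix(
        pd.DataFrame(counts, index=truth_df.index, columns=bins.ids),
        pd.DataFrame({"plate": truth_df["plate"],
                      "sample_type": truth_df["sample_type"],
                      "fetal_sex": truth_df["fetal_sex"]}),
    )
    if config.ff_signal_strength > 0:
        cm = plant_female_ff_signal(
            cm, truth_df["ff"], bins, config.ff_signal_strength, config, rng
        )
    return cm, truth_df


def plant_female_ff_signal(
    cohort: CountMatrix,
    ff: pd.Series,
    bins: BinSet,
    strength: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> CountMatrix:
    """Add a low-rank, fetal-fraction-proportional count perturbation.

    Real cfDNA carries FF-correlated autosomal coverage structure (fragment
    length and accessibility effects); this plants an explicit stand-in so
    the regularized female-FF regression has learnable signal. The direction
    ``v`` over allowed bins is derived from ``config.ff_signal_seed`` (not the
    cohort seed) so the same structure is present in every cohort generated
    under one configuration. Bins on chromosomes 13/18/21/X/Y are untouched.
    ``strength`` in [0, 1] is the correlation between the per-sample latent
    score and fetal fraction; 0 leaves the counts bit-identical.
    """
    if not 0.0 <= strength <= 1.0:
        raise ValidationError("strength outside [0, 1]")
    if strength == 0.0:
        return cohort
    allowed = bins.autosomal & ~np.isin(bins.chrom, FF_SIGNAL_EXCLUDE[:3])
    v_rng = np.random.default_rng(config.ff_signal_seed)
    v = v_rng.normal(size=int(allowed.sum()))
    z = (ff.to_numpy(dtype=float) - FF_SIGNAL_CENTER) / FF_SIGNAL_SCALE
    s = strength * z + np.sqrt(1.0 - strength**2) * rng.normal(size=len(z))
    factor = 1.0 + config.ff_signal_amp * np.outer(s, v)
    counts = cohort.counts.copy()
    block = counts.loc[:, bins.ids[allowed]].to_numpy(dtype=float)
    counts.loc[:, bins.ids[allowed]] = np.rint(np.clip(block * factor, 0, None)).astype(
        np.int64
    )
    return CountMatrix(counts, cohort.meta)


def training_scenarios(n_euploid: int = 150, n_adult: int = 15) -> list[tuple[str, int]]:
    """Reference-cohort layout: euploid pregnancies of both fetal sexes plus
    non-pregnant adult controls for the Y-bin and X-anchor references."""
    half = n_euploid // 2
    return [
        ("euploid_female", half),
        ("euploid_male", n_euploid - half),
        ("adult_male", n_adult),
        ("adult_female", n_adult),
    ]


def write_cohort(out_dir, bins: BinSet, cohort: CountMatrix, truth: pd.DataFrame,
                 config: SimConfig) -> None:
    """Emit bins.bed, counts.tsv, truth.tsv and config.yaml to a directory."""
    import os
    import yaml

    os.makedirs(out_dir, exist_ok=True)
    bins.write_bed(os.path.join(out_dir, "bins.bed"))
    cohort.write_tsv(os.path.join(out_dir, "counts.tsv"))
    truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t")
    cfg = {k: v for k, v in vars(config).items()}
    cfg["chrom_bins"] = dict(config.chrom_bins)
    cfg["gc_beta"] = list(config.gc_beta)
    cfg["ff_range"] = list(config.ff_range)
    cfg["gc_shift"] = dict(config.gc_shift)
    with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
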