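"""Chromosome representation, robust Z-scores and trisomy/region calling.

The calling statistic is

    Z = (x - mu) / sigma

where ``x`` is the sample's chromosome representation (its share of the
autosomal usable-bin total), ``mu`` is the plate median of that
representation, and ``sigma`` is a normal-consistent MAD (1.4826 * MAD)
estimated from a training cohort. Clinical thresholds: Z <= 4 NEGATIVE,
Z > 8 POSITIVE, in between REVIEW. Named regions (microdeletion/duplication
loci such as the DiGeorge 22q11 region or 1p36) are scored identically with
the region's usable bins as the unit; deletions give negative Z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from .binmodel import AUTOSOMES, BinSet
from .errors import FitError, ValidationError

CALL_NEGATIVE = "NEGATIVE"
CALL_REVIEW = "REVIEW"
CALL_POSITIVE = "POSITIVE"

FLAG_MATERNAL_DUP = "MATERNAL_DUP_SUSPECTED"
FLAG_GLOBAL = "GLOBAL_ABNORMALITY"

TRISOMY_CHROMS = ("13", "18", "21")


def chromosome_representations(
    values: pd.DataFrame, bins: BinSet, chroms: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Per-sample representation of each chromosome.

    Denominator is always the autosomal usable-bin total, also for X and Y,
    so autosomal representations sum to 1 for every sample.
    """
    if chroms is None:
        chroms = AUTOSOMES + ("X", "Y")
    usable = bins.usable
    denom = values.loc[:, bins.ids[usable & bins.autosomal]].sum(axis=1)
    if (denom <= 0).any():
        raise ValidationError("zero autosomal denominator")
    reps = {}
    for chrom in chroms:
        ids = bins.ids[usable & bins.chrom_mask(chrom)]
        reps[chrom] = values.loc[:, ids].sum(axis=1) / denom
    return pd.DataFrame(reps)


def region_representations(
    values: pd.DataFrame, bins: BinSet, regions: pd.DataFrame, min_bins: int = 5
) -> pd.DataFrame:
    """Representation of each named region (summed usable bins / autosomal total).

    ``regions``: DataFrame with columns name, chrom, start, end.
    """
    usable = bins.usable
    denom = values.loc[:, bins.ids[usable & bins.autosomal]].sum(axis=1)
    out = {}
    for _, r in regions.iterrows():
        mask = (
            usable
            & bins.chrom_mask(r["chrom"])
            & (bins.df["start"].to_numpy() < r["end"])
            & (bins.df["end"].to_numpy() > r["start"])
        )
        if mask.sum() < min_bins:
            raise ValidationError(
                f"region {r['name']}: only {int(mask.sum())} usable bins (< {min_bins})"
            )
        out[r["name"]] = values.loc[:, bins.ids[mask]].sum(axis=1) / denom
    return pd.DataFrame(out)


def default_regions(bins: BinSet) -> pd.DataFrame:
    """Synthetic stand-ins for the 22q11 (DiGeorge) and 1p36 regions.

    The toy genome is not hg19, so the shipped coordinates are fractional
    spans of the toy chromosomes chosen to match the simulator's deletion
    scenarios; load a real BED for genome-matched coordinates.
    """
    rows = []
    for name, chrom, lo, hi in [("22q11", "22", 0.15, 0.35), ("1p36", "1", 0.0, 0.07)]:
        sub = bins.df[bins.df["chrom"] == chrom].reset_index(drop=True)
        n = len(sub)
        i0 = int(np.floor(lo * n))
        i1 = max(int(np.ceil(hi * n)), i0 + 5)   # at least 5 bins
        i1 = min(i1, n)
        rows.append((name, chrom, int(sub.loc[i0, "start"]),
                     int(sub.loc[i1 - 1, "end"])))
    return pd.DataFrame(rows, columns=["name", "chrom", "start", "end"])


# ---------------------------------------------------------------------------
# reference + Z
# ---------------------------------------------------------------------------

@dataclass
class ChromosomeReference:
    """Training spread (sigma) and median per scored unit (chromosome/region).

    sigma = mad_scale * MAD of plate-median-centred training representations,
    so euploid Z has spread ~1 under the plate-median mu policy.
    """

    sigma: pd.Series
    training_median: pd.Series
    n_training: int

    def __post_init__(self):
        if (self.sigma <= 0).any():
            bad = self.sigma.index[self.sigma <= 0].tolist()
            raise FitError(f"non-positive sigma for: {bad}")


def fit_reference(
    reps: pd.DataFrame,
    plates: pd.Series,
    mad_scale: float = 1.4826,
) -> ChromosomeReference:
    """Fit sigma/median from training representations (chromosomes + regions)."""
    mu = reps.groupby(plates).transform("median")
    centred = reps - mu
    sigma = pd.Series(
        mad_scale * median_abs_deviation(centred.to_numpy(), axis=0),
        index=reps.columns,
    )
    return ChromosomeReference(sigma, reps.median(), len(reps))


def plate_mu(
    reps: pd.DataFrame,
    plates: pd.Series,
    reference: ChromosomeReference,
    min_plate: int = 8,
) -> pd.DataFrame:
    """Per-sample mu: the sample's plate median, or the training median for
    plates smaller than ``min_plate``."""
    mu = reps.groupby(plates).transform("median")
    sizes = plates.map(plates.value_counts())
    small = (sizes < min_plate).to_numpy()
    if small.any():
        fallback = reference.training_median[reps.columns]
        mu.loc[small, :] = fallback.to_numpy()
    return mu


def zscore(x, mu, sigma):
    """Robust Z; sigma must be positive."""
    sigma = np.asarray(sigma, dtype=float)
    if (sigma <= 0).any():
        raise ValidationError("sigma must be > 0")
    z = (np.asarray(x, dtype=float) - np.asarray(mu, dtype=float)) / sigma
    if not np.all(np.isfinite(z)):
        raise ValidationError("non-finite Z")
    return z


def cohort_zscores(
    reps: pd.DataFrame,
    plates: pd.Series,
    reference: ChromosomeReference,
    min_plate: int = 8,
    outlier_z: float = 8.0,
) -> pd.DataFrame:
    """Z for every sample and scored unit, with a two-pass plate median.

    Pass 1 scores against the raw plate medians; samples with any autosomal
    |Z| above ``outlier_z`` (aneuploid or grossly aberrant cfDNA — their
    representation shifts leak into every other chromosome through the
    shared autosomal denominator) are then excluded from the plate medians
    of pass 2. Plates left with fewer than ``min_plate`` clean samples fall
    back to the training median.
    """
    sigma = reference.sigma[reps.columns]
    mu = plate_mu(reps, plates, reference, min_plate)
    z1 = (reps - mu) / sigma
    auto_cols = [c for c in reps.columns if c in AUTOSOMES]
    clean = (z1[auto_cols].abs() <= outlier_z).all(axis=1)
    if clean.all():
        return z1
    mu2 = pd.DataFrame(index=reps.index, columns=reps.columns, dtype=float)
    fallback = reference.training_median[reps.columns]
    for plate, idx in reps.groupby(plates).groups.items():
        keep = clean.loc[idx]
        if int(keep.sum()) >= min_plate:
            mu2.loc[idx, :] = reps.loc[idx[keep], :].median().to_numpy()
        else:
            mu2.loc[idx, :] = fallback.to_numpy()
    return (reps - mu2) / sigma


def classify_trisomy(z: float, neg_max: float = 4.0, pos_min: float = 8.0) -> str:
    """Z <= 4 NEGATIVE; Z > 8 POSITIVE; otherwise REVIEW (boundaries: 4 is
    NEGATIVE, 8 is REVIEW)."""
    if not np.isfinite(z):
        raise ValidationError("non-finite Z")
    if z <= neg_max:
        return CALL_NEGATIVE
    if z > pos_min:
        return CALL_POSITIVE
    return CALL_REVIEW


# ---------------------------------------------------------------------------
# ideogram tracks + review screens
# ---------------------------------------------------------------------------

@dataclass
class IdeogramTrack:
    """Per-bin normalized ratio along one chromosome (euploid expectation 1.0)
    with a change-point segmentation."""

    chrom: str
    bin_ids: pd.Index
    ratio: np.ndarray
    segments: pd.DataFrame    # columns: start, end (bin offsets, half-open), mean

    def to_frame(self) -> pd.DataFrame:
        seg_id = np.empty(len(self.ratio), dtype=int)
        for i, (_, s) in enumerate(self.segments.iterrows()):
            seg_id[int(s["start"]):int(s["end"])] = i
        return pd.DataFrame(
            {"bin": self.bin_ids, "ratio": self.ratio, "segment_id": seg_id}
        )


def _sse(x: np.ndarray) -> float:
    return float(((x - x.mean()) ** 2).sum())


def segment_track(
    ratio: np.ndarray, penalty: float = 10.0, min_seg: int = 2
) -> pd.DataFrame:
    """Binary change-point splitting minimizing within-segment SSE.

    A split is accepted when it reduces the SSE by more than
    ``penalty * sigma^2 * log(n)`` where sigma is a robust noise estimate
    from successive differences; ties break toward fewer segments.
    """
    n = len(ratio)
    diffs = np.diff(ratio)
    sigma = 1.4826 * np.median(np.abs(diffs)) / np.sqrt(2) if len(diffs) else 0.0
    sigma = max(sigma, 1e-12)
    threshold = penalty * sigma**2 * np.log(max(n, 2))

    segments: list[tuple[int, int]] = []

    def split(lo: int, hi: int) -> None:
        x = ratio[lo:hi]
        if len(x) < 2 * min_seg:
            segments.append((lo, hi))
            return
        base = _sse(x)
        best_gain, best_k = 0.0, None
        for k in range(min_seg, len(x) - min_seg + 1):
            gain = base - _sse(x[:k]) - _sse(x[k:])
            if gain > best_gain:
                best_gain, best_k = gain, k
        if best_k is not None and best_gain > threshold:
            split(lo, lo + best_k)
            split(lo + best_k, hi)
        else:
            segments.append((lo, hi))

    split(0, n)
    segments.sort()
    return pd.DataFrame(
        [(lo, hi, float(ratio[lo:hi].mean())) for lo, hi in segments],
        columns=["start", "end", "mean"],
    )


def ideogram(
    sample_values: pd.Series,
    bins: BinSet,
    chrom: str,
    euploid_bin_medians: pd.Series,
    penalty: float = 10.0,
    min_seg: int = 2,
) -> IdeogramTrack:
    """Normalized per-bin track: sample value / euploid training median."""
    ids = bins.ids[bins.usable & bins.chrom_mask(chrom)]
    missing = ids.difference(euploid_bin_medians.index)
    if len(missing):
        raise ValidationError(f"missing training medians for {len(missing)} bins")
    med = euploid_bin_medians.loc[ids].to_numpy()
    if (med <= 0).any():
        raise ValidationError("non-positive training bin medians")
    ratio = sample_values.loc[ids].to_numpy() / med
    return IdeogramTrack(chrom, ids, ratio, segment_track(ratio, penalty, min_seg))


def detect_partial_duplication(
    track: IdeogramTrack,
    dup_ratio_min: float = 1.1,
    dup_span_max: float = 0.7,
    flat_low: float = 0.97,
    flat_high: float = 1.03,
) -> bool:
    """Flag a chromosome whose elevation is confined to a sub-segment.

    True when the elevated segments (mean ratio > ``dup_ratio_min``) cover
    less than ``dup_span_max`` of the usable bins while every remaining
    segment mean lies in [flat_low, flat_high] — the signature of a maternal
    segmental duplication rather than a fetal whole-chromosome trisomy.
    Whole-chromosome elevation does not flag.
    """
    seg = track.segments
    lengths = (seg["end"] - seg["start"]).to_numpy(dtype=float)
    elevated = (seg["mean"] > dup_ratio_min).to_numpy()
    if not elevated.any():
        return False
    span = lengths[elevated].sum() / lengths.sum()
    if span >= dup_span_max:
        return False
    rest = seg["mean"].to_numpy()[~elevated]
    return bool(np.all((rest >= flat_low) & (rest <= flat_high)))


def global_screen(
    z: pd.Series,
    z_thresh: float = 8.0,
    min_chroms: int = 3,
    exclude: tuple[str, ...] = TRISOMY_CHROMS,
) -> bool:
    """Whole-genome screen: >= ``min_chroms`` chromosomes outside the scored
    trisomy set with |Z| > ``z_thresh`` indicates a global (likely maternal)
    copy-number aberration; positive calls are then suppressed to
    suspected-maternal status."""
    off = [c for c in z.index if c in AUTOSOMES and c not in exclude]
    return int((z[off].abs() > z_thresh).sum()) >= min_chroms
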