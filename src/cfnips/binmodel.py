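"""Genome bins, count matrices and sample-level QC.

Coordinates are 0-based half-open (BED convention). Chromosome labels are
plain ``1``..``22``, ``X``, ``Y``. Counts arrive pre-binned: one integer per
(sample, bin); alignment is upstream of this package.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from .errors import ParseError, ValidationError, FitError

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
CHROM_ORDER: tuple[str, ...] = AUTOSOMES + ("X", "Y")
_CHROM_RANK = {c: i for i, c in enumerate(CHROM_ORDER)}

BIN_COLUMNS = ("chrom", "start", "end", "gc", "usable")


def bin_ids(df: pd.DataFrame) -> pd.Index:
    """Canonical ``chrom:start-end`` identifier per bin."""
    return pd.Index(
        df["chrom"].astype(str)
        + ":"
        + df["start"].astype(str)
        + "-"
        + df["end"].astype(str)
    )


class BinSet:
    """An ordered, validated set of genome bins.

    Wraps a DataFrame with columns chrom/start/end/gc/usable, sorted by
    chromosome then start, with non-overlapping intervals and gc in [0, 1].
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = set(BIN_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"bin table missing columns: {sorted(missing)}")
        df["chrom"] = df["chrom"].astype(str)
        bad = ~df["chrom"].isin(CHROM_ORDER)
        if bad.any():
            raise ValidationError(
                f"unknown chromosome labels: {sorted(df.loc[bad, 'chrom'].unique())}"
            )
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["gc"] = df["gc"].astype(float)
        df["usable"] = df["usable"].astype(bool)
        if (df["end"] <= df["start"]).any():
            i = int(np.argmax((df["end"] <= df["start"]).to_numpy()))
            raise ValidationError(f"bin {i}: end <= start")
        if ((df["gc"] < 0) | (df["gc"] > 1)).any():
            raise ValidationError("gc fraction outside [0, 1]")
        df["_rank"] = df["chrom"].map(_CHROM_RANK)
        df = df.sort_values(["_rank", "start"], kind="stable").drop(columns="_rank")
        df = df.reset_index(drop=True)
        for _, sub in df.groupby("chrom", sort=False):
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            if len(s) > 1 and (s[1:] < e[:-1]).any():
                raise ValidationError(
                    f"overlapping bins on chromosome {sub['chrom'].iloc[0]}"
                )
        self.df = df
        self.ids = bin_ids(df)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, BinSet) and self.df.equals(other.df)

    # -- masks, all as numpy bool arrays aligned to self.ids -------------------
    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def gc(self) -> np.ndarray:
        return self.df["gc"].to_numpy()

    @property
    def usable(self) -> np.ndarray:
        return self.df["usable"].to_numpy()

    @property
    def autosomal(self) -> np.ndarray:
        return np.isin(self.chrom, AUTOSOMES)

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return self.chrom == str(chrom)

    def with_usable(self, usable: np.ndarray) -> "BinSet":
        df = self.df.copy()
        df["usable"] = np.asarray(usable, dtype=bool)
        return BinSet(df)

    # -- I/O --------------------------------------------------------------------
    def write_bed(self, path) -> None:
        out = self.df.copy()
        out["usable"] = out["usable"].astype(int)
        out.to_csv(path, sep="\t", header=False, index=False)


def load_bins(path) -> BinSet:
    """Read a 5-column BED (chrom, start, end, gc, usable)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ParseError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            chrom, start, end, gc, usable = parts[:5]
            try:
                rows.append(
                    (chrom.removeprefix("chr"), int(start), int(end), float(gc),
                     bool(int(usable)))
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    if not rows:
        raise ParseError(f"{path}: no bins")
    return BinSet(pd.DataFrame(rows, columns=list(BIN_COLUMNS)))


class CountMatrix:
    """Per-sample per-bin raw read counts with plate labels.

    ``counts``: integer DataFrame, index = sample IDs, columns = bin IDs.
    ``meta``: DataFrame indexed like counts with at least a ``plate`` column;
    extra columns (sample_type, fetal_sex, ...) ride along untouched.
    """

    def __init__(self, counts: pd.DataFrame, meta: pd.DataFrame):
        if (counts.to_numpy() < 0).any():
            raise ValidationError("negative read counts")
        if "plate" not in meta.columns:
            raise ValidationError("every sample needs a plate label")
        if not counts.index.equals(meta.index):
            meta = meta.loc[counts.index]
        self.counts = counts.astype(np.int64)
        self.meta = meta.copy()

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def samples(self) -> pd.Index:
        return self.counts.index

    @property
    def plates(self) -> pd.Series:
        return self.meta["plate"]

    @property
    def total_reads(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def autosomal_total(self, bins: BinSet) -> pd.Series:
        return self.counts.loc[:, bins.ids[bins.autosomal]].sum(axis=1)

    def subset(self, sample_mask) -> "CountMatrix":
        return CountMatrix(self.counts.loc[sample_mask], self.meta.loc[sample_mask])

    # -- I/O --------------------------------------------------------------------
    def write_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "plate_id", self.plates)
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


def load_counts(path, bins: BinSet | None = None) -> CountMatrix:
    """Read a counts TSV (sample_id, plate_id, one column per bin)."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    if "plate_id" not in df.columns:
        raise ParseError(f"{path}: missing plate_id column")
    meta = pd.DataFrame({"plate": df.pop("plate_id")})
    if bins is not None:
        missing = bins.ids.difference(df.columns)
        if len(missing):
            raise ValidationError(f"{path}: counts missing {len(missing)} bins")
        df = df.loc[:, bins.ids]
    return CountMatrix(df, meta)


class QCStatus(str, enum.Enum):
    PASS = "PASS"
    NO_REPORT_LOW_READS = "NO_REPORT_LOW_READS"
    NO_REPORT_SEX_CHR_LOW_READS = "NO_REPORT_SEX_CHR_LOW_READS"
    NO_REPORT_OTHER = "NO_REPORT_OTHER"


@dataclass(frozen=True)
class SampleQC:
    sample_id: str
    status: QCStatus
    sex_analysis_allowed: bool
    reason: str = ""


def qc_sample(
    sample_id: str,
    total_reads: float,
    min_total: float = 9e6,
    min_sex: float = 4.5e6,
) -> SampleQC:
    """Apply the read-depth gates.

    The overall report requires ``total_reads >= min_total`` (inclusive);
    sex-chromosome analyses are additionally suppressed below ``min_sex``.
    A pure function of the total read count.
    """
    sex_ok = total_reads >= min_sex
    if total_reads >= min_total:
        return SampleQC(sample_id, QCStatus.PASS, sex_analysis_allowed=True)
    reason = f"total reads {total_reads:.3g} < minimum {min_total:.3g}"
    if not sex_ok:
        reason += f"; sex-chromosome analysis suppressed (< {min_sex:.3g})"
    return SampleQC(sample_id, QCStatus.NO_REPORT_LOW_READS, sex_ok, reason)


def fit_usable_bins(
    training: CountMatrix,
    bins: BinSet,
    cv_threshold: float = 0.3,
    chroms: tuple[str, ...] | None = None,
    min_samples: int = 20,
) -> BinSet:
    """Mask bins that behave inconsistently across a training cohort.

    A bin is unusable when its across-sample robust coefficient of variation
    (1.4826 * MAD / median) exceeds ``cv_threshold`` or its median count is 0.
    Applied to ``chroms`` (default: autosomes — X/Y counts legitimately vary
    with fetal sex and fetal fraction, so they get their own selection rules).
    Permutation-invariant over samples.
    """
    if len(training) < min_samples:
        raise FitError(
            f"usable-bin fitting needs >= {min_samples} samples, got {len(training)}"
        )
    if chroms is None:
        chroms = AUTOSOMES
    scope = np.isin(bins.chrom, list(chroms))
    x = training.counts.to_numpy(dtype=float)
    med = np.median(x, axis=0)
    mad = median_abs_deviation(x, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(med > 0, 1.4826 * mad / med, np.inf)
    usable = bins.usable.copy()
    usable[scope] &= (cv[scope] <= cv_threshold) & (med[scope] > 0)
    return bins.with_usable(usable)
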