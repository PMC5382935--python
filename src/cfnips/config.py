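"""Pipeline configuration.

Every decision threshold of the caller lives here so that the clinical
rules (read-depth gates, Z cutoffs, fetal-fraction gate, review heuristics)
can be audited and overridden from a single YAML file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class PipelineConfig:
    """Thresholds and tuning parameters for the whole caller.

    Units: read counts are absolute reads; fractions are proportions in
    [0, 1]; Z values are in robust-SD units (MAD scaled by 1.4826).
    """

    # --- binning / sample QC -------------------------------------------------
    bin_size: int = 50_000          # genome-wide bin width, bp
    min_total_reads: float = 9e6    # below this: no report at all
    min_sex_reads: float = 4.5e6    # below this: sex-chromosome analysis suppressed
    cv_threshold: float = 0.3       # robust CV above which a bin is masked
    min_training_samples: int = 20  # for usable-bin fitting

    # --- normalization -------------------------------------------------------
    gc_span: float = 0.3            # loess span for per-sample GC curves
    pca_components: int = 5
    pca_exclude: tuple = ("13", "18", "21")
    winsor_lower_pct: float = 1.0   # training percentile of bin/chrom-median ratios
    winsor_upper_pct: float = 99.0
    winsor_scale: float = 10.0      # widen percentile half-widths; keeps CNV signal
    smooth_window: int = 5          # rolling-median window (bins)

    # --- Z-scoring / trisomy calls ------------------------------------------
    mad_scale: float = 1.4826       # normal-consistency factor for the MAD
    z_negative_max: float = 4.0     # Z <= 4 -> NEGATIVE
    z_positive_min: float = 8.0     # Z > 8  -> POSITIVE
    min_plate_samples: int = 8      # smaller plates fall back to the training median

    # --- review heuristics ---------------------------------------------------
    dup_ratio_min: float = 1.1      # ideogram segment mean flagging a duplication
    dup_span_max: float = 0.7       # elevated span below this fraction -> maternal dup
    flat_ratio_low: float = 0.97    # remaining segments must sit in this band
    flat_ratio_high: float = 1.03
    global_z: float = 8.0           # |Z| threshold for the whole-genome screen
    global_min_chroms: int = 3      # off-target chromosomes needed to flag
    segment_penalty: float = 10.0   # change-point split penalty (x sigma^2 log n)
    min_segment_bins: int = 2

    # --- fetal fraction / sex aneuploidy -------------------------------------
    ff_report_min: float = 0.05     # final FF below 5% -> no report
    sex_tau: float = 0.02           # half-width of the (FFx, FFy) decision bands
    maternal_45x_ffx: float = 0.5   # FFx above this: suspected maternal 45,X mosaic
    maternal_xxx_ffx: float = -0.5  # FFx below this: suspected maternal 47,XXX
    y_fold: float = 5.0             # male mean > fold x female mean for Y bins
    y_min_reads: float = 150.0      # male mean reads required for a Y bin
    y_sex_mads: float = 10.0        # male iff normY > background + k * MAD; a
                                    # male fetus at the 5% FF gate sits ~40+
                                    # MADs up, so 10 keeps a wide dead band
    min_run_females: int = 3        # females on run needed for X_f, else training

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=False)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["pca_exclude"] = list(d["pca_exclude"])
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "pca_exclude" in raw:
            raw["pca_exclude"] = tuple(str(c) for c in raw["pca_exclude"])
        return cls(**raw)
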