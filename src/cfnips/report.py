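"""Final per-sample reports and cohort-level statistics.

Reporting precedence (highest first): read-depth QC failure > low fetal
fraction > maternal-event flags (global copy-number aberration, maternal
segmental duplication on the called chromosome) > aneuploidy calls. A
POSITIVE final status therefore requires QC PASS, FF gate PASS and no
maternal flag on the called chromosome; flagged positives are downgraded to
SUSPECTED_MATERNAL, and review-zone Z scores surface as REVIEW with the
ideogram attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aneucall import (
    CALL_NEGATIVE,
    CALL_POSITIVE,
    CALL_REVIEW,
    FLAG_GLOBAL,
    FLAG_MATERNAL_DUP,
    TRISOMY_CHROMS,
)
from .binmodel import QCStatus, SampleQC
from .errors import ValidationError
from .fetalfrac import GATE_LOW_FF, FFEstimate
from .sexaneu import FLAG_MATERNAL_45X, FLAG_MATERNAL_XXX, SexCall

FINAL_NEGATIVE = "NEGATIVE"
FINAL_POSITIVE = "POSITIVE"
FINAL_REVIEW = "REVIEW"
FINAL_SUSPECTED_MATERNAL = "SUSPECTED_MATERNAL"
FINAL_NO_REPORT = "NO_REPORT"


@dataclass
class SampleReport:
    """Assembled result for one sample."""

    sample_id: str
    qc: SampleQC
    ff: FFEstimate | None = None
    chrom_calls: dict = field(default_factory=dict)   # chrom -> (z, call)
    region_z: dict = field(default_factory=dict)      # region name -> z
    sex: SexCall | None = None
    flags: set = field(default_factory=set)
    flagged_chroms: set = field(default_factory=set)  # chroms with maternal-dup flag
    final_status: str = FINAL_NEGATIVE
    reasons: list = field(default_factory=list)

    def to_row(self) -> dict:
        row: dict = {"sample_id": self.sample_id, "qc_status": self.qc.status.value,
                     "final_status": self.final_status,
                     "flags": ";".join(sorted(self.flags)),
                     "reasons": "; ".join(self.reasons)}
        if self.ff is not None:
            d = self.ff.as_dict()
            d["ff_final"] = d.pop("final")
            d["ff_gate"] = d.pop("gate")
            row.update(d)
        for chrom in TRISOMY_CHROMS:
            z, call = self.chrom_calls.get(chrom, (np.nan, ""))
            row[f"z_chr{chrom}"] = z
            row[f"call_chr{chrom}"] = call
        for name, z in self.region_z.items():
            row[f"z_{name}"] = z
        if self.sex is not None:
            row.update({"genetic_sex": self.sex.genetic_sex,
                        "sex_aneuploidy": self.sex.aneuploidy,
                        "ffx": self.sex.ffx, "ffy": self.sex.ffy})
        return row


def render_report(
    sample_id: str,
    qc: SampleQC,
    ff: FFEstimate | None,
    chrom_calls: dict,
    region_z: dict,
    sex: SexCall | None,
    global_flag: bool,
    dup_flagged_chroms: set,
) -> SampleReport:
    """Apply the reporting precedence and assemble the final status."""
    flags: set = set()
    reasons: list[str] = []
    if global_flag:
        flags.add(FLAG_GLOBAL)
    if dup_flagged_chroms:
        flags.add(FLAG_MATERNAL_DUP)
    if sex is not None:
        flags |= sex.flags

    report = SampleReport(sample_id, qc, ff, dict(chrom_calls), dict(region_z),
                          sex, flags, set(dup_flagged_chroms), reasons=reasons)

    if qc.status is not QCStatus.PASS:
        report.final_status = FINAL_NO_REPORT
        reasons.append(qc.reason or qc.status.value)
        return report
    if ff is not None and ff.gate == GATE_LOW_FF:
        report.final_status = FINAL_NO_REPORT
        reasons.append(f"fetal fraction {ff.final:.4f} below reporting threshold")
        return report

    calls = {c: call for c, (z, call) in chrom_calls.items()}
    positives = {c for c, call in calls.items() if call == CALL_POSITIVE}
    reviews = {c for c, call in calls.items() if call == CALL_REVIEW}

    if global_flag and (positives or reviews):
        report.final_status = FINAL_SUSPECTED_MATERNAL
        reasons.append("multi-chromosome copy-number aberration; "
                       "suspected maternal origin")
        return report

    # maternal duplication downgrades the affected chromosome only
    clean_positives = positives - dup_flagged_chroms
    clean_reviews = reviews - dup_flagged_chroms
    if positives & dup_flagged_chroms or reviews & dup_flagged_chroms:
        reasons.append(
            "partial-chromosome duplication on "
            + ",".join(sorted((positives | reviews) & dup_flagged_chroms))
            + "; suspected maternal duplication"
        )

    region_positive = {n: z for n, z in region_z.items() if abs(z) > 8}
    region_review = {n: z for n, z in region_z.items() if 4 < abs(z) <= 8}

    if clean_positives or region_positive:
        report.final_status = FINAL_POSITIVE
        for c in sorted(clean_positives):
            reasons.append(f"chromosome {c} Z {chrom_calls[c][0]:.2f} > 8")
        for n, z in sorted(region_positive.items()):
            kind = "deletion" if z < 0 else "duplication"
            reasons.append(f"region {n} {kind} Z {z:.2f}")
        return report
    if clean_reviews or region_review:
        report.final_status = FINAL_REVIEW
        for c in sorted(clean_reviews):
            reasons.append(f"chromosome {c} Z {chrom_calls[c][0]:.2f} in (4, 8]; "
                           "ideogram review")
        for n, z in sorted(region_review.items()):
            reasons.append(f"region {n} |Z| {abs(z):.2f} in (4, 8]")
        return report
    if (positives | reviews) & dup_flagged_chroms:
        report.final_status = FINAL_SUSPECTED_MATERNAL
        return report
    if sex is not None and (sex.flags & {FLAG_MATERNAL_45X, FLAG_MATERNAL_XXX}):
        if sex.genetic_sex == "SUPPRESSED":
            report.final_status = FINAL_SUSPECTED_MATERNAL
            reasons.append("sex-chromosome signature of maternal origin")
            return report
    if sex is not None and sex.aneuploidy not in ("NONE",):
        report.final_status = (
            FINAL_REVIEW if sex.aneuploidy == "REVIEW" else FINAL_POSITIVE
        )
        if sex.aneuploidy != "REVIEW":
            reasons.append(f"sex-chromosome aneuploidy {sex.aneuploidy}")
        return report
    report.final_status = FINAL_NEGATIVE
    return report


def reports_to_frame(reports: list[SampleReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in reports]).set_index("sample_id")


# ---------------------------------------------------------------------------
# PPV arithmetic
# ---------------------------------------------------------------------------

def ppv(tp: int, fp: int) -> int:
    """Positive predictive value 100 * TP / (TP + FP), rounded to the
    nearest integer percent (presentation used in clinical follow-up
    tables)."""
    if tp + fp <= 0:
        raise ValidationError("PPV undefined for tp + fp == 0")
    return round(100.0 * tp / (tp + fp))


def adjusted_ppv(tp: int, fp: int, reclassified: int) -> int:
    """PPV after excluding false positives reclassified as true negatives
    under revised reporting rules (maternal events)."""
    if reclassified > fp:
        raise ValidationError("cannot reclassify more than the false positives")
    return ppv(tp, fp - reclassified)


def ppv_analytic(sensitivity: float, specificity: float, prevalence: float) -> float:
    """Bayes PPV, in percent (unrounded):
    100 * sens*prev / (sens*prev + (1-spec)*(1-prev))."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity),
                    ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name} outside [0, 1]")
    if prevalence <= 0:
        raise ValidationError("prevalence must be > 0")
    num = sensitivity * prevalence
    denom = num + (1.0 - specificity) * (1.0 - prevalence)
    if denom == 0:
        raise ValidationError("zero denominator")
    return 100.0 * num / denom


def positive_rate(n_positive: int, n_total: int) -> float:
    """Positive rate in percent: 1 decimal place at >= 1%, 2 below."""
    if n_total <= 0:
        raise ValidationError("empty cohort")
    rate = 100.0 * n_positive / n_total
    return round(rate, 1) if rate >= 1.0 else round(rate, 2)


# ---------------------------------------------------------------------------
# cohort statistics
# ---------------------------------------------------------------------------

@dataclass
class FollowUpTable:
    """Per-condition follow-up bookkeeping: PPV = TP/(TP+FP); the adjusted
    PPV excludes false positives reclassified by revised reporting rules."""

    table: pd.DataFrame    # index condition; columns n_positive, tp, fp,
                           # reclassified, ppv, adjusted_ppv, rate

    @classmethod
    def from_counts(cls, counts: dict, n_total: int) -> "FollowUpTable":
        """``counts``: condition -> dict(n_positive, tp, fp[, reclassified])."""
        rows = {}
        for cond, c in counts.items():
            tp, fp = c.get("tp", 0), c.get("fp", 0)
            reclass = c.get("reclassified", 0)
            row = {
                "n_positive": c["n_positive"],
                "tp": tp, "fp": fp, "reclassified": reclass,
                "rate": positive_rate(c["n_positive"], n_total),
                "ppv": ppv(tp, fp) if tp + fp > 0 else np.nan,
                "adjusted_ppv": (adjusted_ppv(tp, fp, reclass)
                                 if tp + fp > 0 and reclass else np.nan),
            }
            rows[cond] = row
        return cls(pd.DataFrame(rows).T)


_CONDITIONS = ("T21", "T18", "T13", "45X", "47XXX", "47XXY", "47XYY")


def _true_condition(truth_row: pd.Series) -> str | None:
    tri = str(truth_row.get("trisomy", "") or "")
    for chrom in ("21", "18", "13"):
        if chrom in tri.split(";"):
            return f"T{chrom}"
    sex = str(truth_row.get("fetal_sex", ""))
    if sex in ("45X", "XXX", "XXY", "XYY"):
        return {"45X": "45X", "XXX": "47XXX", "XXY": "47XXY",
                "XYY": "47XYY"}[sex]
    return None


def _called_conditions(report: SampleReport) -> set:
    called = set()
    if report.final_status == FINAL_POSITIVE:
        for chrom, (z, call) in report.chrom_calls.items():
            if call == CALL_POSITIVE and chrom not in report.flagged_chroms:
                called.add(f"T{chrom}")
        if report.sex is not None and report.sex.aneuploidy not in ("NONE", "REVIEW"):
            called.add({"45X": "45X", "47XXX": "47XXX", "47XXY": "47XXY",
                        "47XYY": "47XYY"}[report.sex.aneuploidy])
    return called


def cohort_stats(
    reports: list[SampleReport],
    truth: pd.DataFrame | None = None,
) -> FollowUpTable:
    """Positive rates per condition, and PPVs when simulation truth is given.

    With truth, TP/FP bookkeeping is exact: a positive call is a true
    positive iff the sample's true condition matches the called condition.
    """
    if not reports:
        raise ValidationError("no reports")
    n_total = len(reports)
    counts: dict = {c: {"n_positive": 0, "tp": 0, "fp": 0} for c in _CONDITIONS}
    for r in reports:
        called = _called_conditions(r)
        for cond in called:
            if cond not in counts:
                counts[cond] = {"n_positive": 0, "tp": 0, "fp": 0}
            counts[cond]["n_positive"] += 1
            if truth is not None:
                true_cond = (_true_condition(truth.loc[r.sample_id])
                             if r.sample_id in truth.index else None)
                counts[cond]["tp" if true_cond == cond else "fp"] += 1
    return FollowUpTable.from_counts(counts, n_total)
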