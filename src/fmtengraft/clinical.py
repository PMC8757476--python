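"""Clinical outcome scoring and responder classification for an IBS trial.

Instruments handled:

* IBS-SSS — symptom severity, 0-500, lower is better; responder = a
  decrease of at least 50 points from baseline to week 10.
* IBS-QoL — 34 Likert items (1-5) linearly transformed to 0-100, higher is
  better; responder = an improvement of at least 12 points.
* GIS — global improvement scale 1-7; responder = moderately (6) or
  substantially (7) improved.
* Adequate relief — dichotomous; a yes at follow-up is a responder.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats as fstats
from .metadata import FMT_ARMS

__all__ = [
    "ClinicalRecord",
    "qol_score",
    "classify_responders",
    "outcomes_table",
    "read_clinical",
    "write_clinical",
]

QOL_N_ITEMS = 34
#: Affine constants of the published 34-item transform: with items summed
#: raw in [34, 170], score = 100 * (170 - raw) / 136 maps worst->0, best->100.
QOL_RAW_MAX = 5 * QOL_N_ITEMS
QOL_RAW_RANGE = 4 * QOL_N_ITEMS


@dataclass
class ClinicalRecord:
    """Per-subject questionnaire scores; None marks a missing measurement."""

    subject: str
    arm: str
    ibs_sss_baseline: float | None = None
    ibs_sss_week10: float | None = None
    ibs_qol_baseline: float | None = None
    ibs_qol_week10: float | None = None
    gis_week10: int | None = None
    adequate_relief_week10: bool | None = None

    def __post_init__(self) -> None:
        for name in ("ibs_sss_baseline", "ibs_sss_week10"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 500:
                raise ValueError(f"{name} must be in [0, 500], got {v}")
        for name in ("ibs_qol_baseline", "ibs_qol_week10"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 100:
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if self.gis_week10 is not None and self.gis_week10 not in range(1, 8):
            raise ValueError(f"gis_week10 must be in 1..7, got {self.gis_week10}")

    @property
    def sss_change(self) -> float | None:
        if self.ibs_sss_baseline is None or self.ibs_sss_week10 is None:
            return None
        return self.ibs_sss_week10 - self.ibs_sss_baseline

    @property
    def qol_change(self) -> float | None:
        if self.ibs_qol_baseline is None or self.ibs_qol_week10 is None:
            return None
        return self.ibs_qol_week10 - self.ibs_qol_baseline


def qol_score(items: Sequence[int], higher_is_worse: bool = True) -> float:
    """Transform 34 Likert responses (1-5) to the 0-100 quality-of-life scale.

    With the default orientation a higher item value means more
    interference with daily life, so all-1 responses score 100 (best) and
    all-5 responses score 0 (worst). Missing items are an error: the
    instrument defines no imputation here.
    """
    if len(items) != QOL_N_ITEMS:
        raise ValueError(f"expected {QOL_N_ITEMS} items, got {len(items)}")
    vals = []
    for i, v in enumerate(items):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError(f"item {i + 1} is missing; no imputation is applied")
        if v not in (1, 2, 3, 4, 5):
            raise ValueError(f"item {i + 1} must be an integer in 1..5, got {v!r}")
        vals.append(int(v))
    raw = sum(vals)
    score = 100.0 * (QOL_RAW_MAX - raw) / QOL_RAW_RANGE
    return score if higher_is_worse else 100.0 - score


def classify_responders(record: ClinicalRecord) -> dict[str, bool | None]:
    """Responder flags per instrument; None where the inputs are missing.

    Boundaries are inclusive: a 50-point SSS decrease or a 12-point QoL
    gain is a response.
    """
    flags: dict[str, bool | None] = {}
    flags["sss"] = None if record.sss_change is None else record.sss_change <= -50
    flags["qol"] = None if record.qol_change is None else record.qol_change >= 12
    flags["gis"] = None if record.gis_week10 is None else record.gis_week10 >= 6
    flags["adequate_relief"] = record.adequate_relief_week10
    return flags


def _group_summaries(records: list[ClinicalRecord], attr: str,
                     arms: Sequence[str]) -> list[fstats.GroupSummary]:
    out = []
    for arm in arms:
        vals = [getattr(r, attr) for r in records
                if r.arm == arm and getattr(r, attr) is not None]
        if len(vals) >= 2:
            out.append(fstats.GroupSummary.from_values(arm, vals))
    return out


def _responder_counts(records: list[ClinicalRecord], flag: str,
                      arms: Sequence[str]) -> dict[str, tuple[int, int]]:
    counts = {}
    for arm in arms:
        flags = [classify_responders(r)[flag] for r in records if r.arm == arm]
        flags = [f for f in flags if f is not None]
        if flags:
            counts[arm] = (sum(flags), len(flags))
    return counts


def outcomes_table(records: list[ClinicalRecord],
                   arms: Sequence[str] = ("FMT", "R-FMT", "CM-FMT", "placebo"),
                   placebo_arm: str = "placebo") -> dict:
    """Per-arm outcome summaries with omnibus and combined-arm tests.

    Continuous changes (IBS-SSS, IBS-QoL) get per-arm mean (sd) and a
    one-way ANOVA across arms; dichotomous responder outcomes get per-arm
    counts and a Freeman–Halton exact test. A combined view pools the
    active FMT arms against placebo with a pooled-variance t-test
    (continuous) or a 2x2 Fisher exact test (dichotomous).
    """
    present_arms = [a for a in arms
                    if any(r.arm == a for r in records)]
    dropped = [a for a in arms if a not in present_arms]
    if dropped:
        warnings.warn(f"empty arm(s) excluded: {dropped}")
    if len(present_arms) < 2:
        raise ValueError("need at least two non-empty arms")
    report: dict = {"arms": present_arms, "continuous": {}, "dichotomous": {},
                    "combined_fmt_vs_placebo": {}}

    for label, attr in (("change_ibs_sss", "sss_change"),
                        ("change_ibs_qol", "qol_change")):
        summaries = _group_summaries(records, attr, present_arms)
        entry = {
            "per_arm": {s.label: {"n": s.n, "mean": s.mean, "sd": s.sd}
                        for s in summaries}
        }
        if len(summaries) >= 2:
            f, p = fstats.anova_oneway_summary(summaries)
            entry["anova_F"], entry["anova_p"] = f, p
        report["continuous"][label] = entry

    for flag in ("adequate_relief", "gis", "sss", "qol"):
        counts = _responder_counts(records, flag, present_arms)
        entry = {"per_arm": {a: {"responders": k, "n": n}
                             for a, (k, n) in counts.items()}}
        if len(counts) >= 2:
            tbl = [[k for k, _ in counts.values()],
                   [n - k for k, n in counts.values()]]
            entry["fisher_p"] = fstats.fisher_exact(tbl)
        report["dichotomous"][f"{flag}_responders"] = entry

    fmt_arms = [a for a in present_arms if a in FMT_ARMS]
    if fmt_arms and placebo_arm in present_arms:
        combined: dict = {}
        for label, attr in (("change_ibs_sss", "sss_change"),
                            ("change_ibs_qol", "qol_change")):
            fmt_vals = [getattr(r, attr) for r in records
                        if r.arm in fmt_arms and getattr(r, attr) is not None]
            plc_vals = [getattr(r, attr) for r in records
                        if r.arm == placebo_arm and getattr(r, attr) is not None]
            if len(fmt_vals) >= 2 and len(plc_vals) >= 2:
                a = fstats.GroupSummary.from_values("FMT combined", fmt_vals)
                b = fstats.GroupSummary.from_values(placebo_arm, plc_vals)
                t, p = fstats.t_test_summary(a, b, variant="pooled")
                combined[label] = {
                    "fmt": {"n": a.n, "mean": a.mean, "sd": a.sd},
                    "placebo": {"n": b.n, "mean": b.mean, "sd": b.sd},
                    "t": t, "p": p,
                }
        for flag in ("adequate_relief", "gis", "sss", "qol"):
            fmt_flags = [classify_responders(r)[flag] for r in records
                         if r.arm in fmt_arms]
            plc_flags = [classify_responders(r)[flag] for r in records
                         if r.arm == placebo_arm]
            fmt_flags = [f for f in fmt_flags if f is not None]
            plc_flags = [f for f in plc_flags if f is not None]
            if fmt_flags and plc_flags:
                tbl = [[sum(fmt_flags), sum(plc_flags)],
                       [len(fmt_flags) - sum(fmt_flags),
                        len(plc_flags) - sum(plc_flags)]]
                combined[f"{flag}_responders"] = {
                    "fmt": (sum(fmt_flags), len(fmt_flags)),
                    "placebo": (sum(plc_flags), len(plc_flags)),
                    "fisher_p": fstats.fisher_exact(tbl),
                }
        report["combined_fmt_vs_placebo"] = combined
    return report


_CLINICAL_COLUMNS = ["subject", "arm", "ibs_sss_baseline", "ibs_sss_week10",
                     "ibs_qol_baseline", "ibs_qol_week10", "gis_week10",
                     "adequate_relief_week10"]


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read per-subject clinical records from a TSV (one row per subject)."""
    df = pd.read_csv(path, sep="\t", dtype={"subject": str, "arm": str})
    records = []
    for _, row in df.iterrows():
        def get(col, cast=float):
            v = row.get(col)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            return cast(v)
        relief = row.get("adequate_relief_week10")
        if isinstance(relief, str):
            relief = relief.strip().lower() in ("yes", "true", "1")
        elif relief is not None and not (isinstance(relief, float) and math.isnan(relief)):
            relief = bool(relief)
        else:
            relief = None
        records.append(ClinicalRecord(
            subject=str(row["subject"]), arm=str(row["arm"]),
            ibs_sss_baseline=get("ibs_sss_baseline"),
            ibs_sss_week10=get("ibs_sss_week10"),
            ibs_qol_baseline=get("ibs_qol_baseline"),
            ibs_qol_week10=get("ibs_qol_week10"),
            gis_week10=get("gis_week10", int),
            adequate_relief_week10=relief,
        ))
    return records


def write_clinical(records: list[ClinicalRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        relief = r.adequate_relief_week10
        rows.append({
            "subject": r.subject, "arm": r.arm,
            "ibs_sss_baseline": r.ibs_sss_baseline,
            "ibs_sss_week10": r.ibs_sss_week10,
            "ibs_qol_baseline": r.ibs_qol_baseline,
            "ibs_qol_week10": r.ibs_qol_week10,
            "gis_week10": r.gis_week10,
            "adequate_relief_week10": ("" if relief is None
                                       else ("yes" if relief else "no")),
        })
    pd.DataFrame(rows, columns=_CLINICAL_COLUMNS).to_csv(path, sep="\t", index=False)
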