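"""Alpha diversity (Shannon index, natural log) and timepoint contrasts."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .otu_table import OtuTable

__all__ = ["DiversitySeries", "shannon", "diversity_table", "compare_diversity"]


@dataclass
class DiversitySeries:
    """Shannon index per timepoint for one subject."""

    subject: str
    arm: str
    shannon_by_timepoint: dict[str, float]


def shannon(counts) -> float:
    """Shannon diversity H = -sum p_i ln(p_i), in nats.

    Zero-count taxa contribute nothing. Raises on an all-zero vector.
    The value is bounded by ln(observed richness).
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    total = arr.sum()
    if total == 0:
        raise ValueError("cannot compute Shannon diversity of an all-zero sample")
    p = arr[arr > 0] / total
    return float(-(p * np.log(p)).sum())


def diversity_table(table: OtuTable, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Shannon diversity joined with the trial metadata."""
    h = {sid: shannon(table.counts.loc[sid].to_numpy()) for sid in table.sample_ids}
    out = meta[meta["sample_id"].isin(h)].copy()
    out["shannon"] = out["sample_id"].map(h)
    return out[["sample_id", "subject_id", "arm", "timepoint", "shannon"]]


def series_from_table(div: pd.DataFrame) -> list[DiversitySeries]:
    series = []
    for subject, sub in div[div["timepoint"] != "donor"].groupby("subject_id", sort=True):
        series.append(DiversitySeries(
            subject=subject,
            arm=sub["arm"].iloc[0],
            shannon_by_timepoint=dict(zip(sub["timepoint"], sub["shannon"])),
        ))
    return series


def compare_diversity(series: list[DiversitySeries], timepoint_a: str,
                      timepoint_b: str) -> dict:
    """Paired t-test on within-subject Shannon differences (b minus a).

    Subjects missing either timepoint are excluded and counted in the
    report. A zero-variance difference vector (every subject unchanged)
    has no defined t statistic and is reported as non-significant with a
    ``zero_variance`` flag.
    """
    diffs = []
    excluded = 0
    for s in series:
        a = s.shannon_by_timepoint.get(timepoint_a)
        b = s.shannon_by_timepoint.get(timepoint_b)
        if a is None or b is None:
            excluded += 1
            continue
        diffs.append(b - a)
    report = {
        "timepoints": (timepoint_a, timepoint_b),
        "n_pairs": len(diffs),
        "n_excluded": excluded,
        "mean_difference": float(np.mean(diffs)) if diffs else None,
        "zero_variance": False,
    }
    if len(diffs) < 2:
        warnings.warn("fewer than two complete pairs; comparison undefined")
        report.update(t=None, p=None)
        return report
    arr = np.asarray(diffs)
    if np.allclose(arr.std(ddof=1), 0):
        report.update(t=None, p=None, zero_variance=True, significant=False)
        return report
    t, p = sps.ttest_1samp(arr, 0.0)
    report.update(t=float(t), p=float(p))
    return report
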