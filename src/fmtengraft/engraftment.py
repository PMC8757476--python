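"""Donor-OTU engraftment after fecal microbiota transplant.

An OTU counts as engrafted in a recipient at a post-FMT timepoint when it
is present in the donor material AND present in that post-FMT stool sample
AND absent from the recipient's pre-FMT baseline sample (collected before
any antibiotics). Per-subject engraftment is summarized as a percentage at
week 1 and week 10 and as the average of the two.

The percentage's denominator is configurable, because presence/absence set
logic alone does not fix one:

``abundance``
    share of post-FMT reads carried by the engrafted OTUs (default —
    scale-free and robust to sequencing depth),
``donor_richness``
    engrafted OTUs as a fraction of the donor OTU set,
``post_richness``
    engrafted OTUs as a fraction of OTUs present post-FMT.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as fstats
from .metadata import FMT_ARMS
from .otu_table import OtuTable

__all__ = [
    "MODES",
    "EngraftmentResult",
    "engrafted_otus",
    "engraftment_percent",
    "average_engraftment",
    "compute_engraftment",
    "compare_engraftment_by_arm",
    "compare_engraftment_by_response",
    "results_to_frame",
]

MODES = ("abundance", "donor_richness", "post_richness")


@dataclass
class EngraftmentResult:
    """Per-subject engraftment outcome.

    ``percent_w1`` / ``percent_w10`` are None when the corresponding
    post-FMT sample is missing; ``percent_avg`` averages the available
    timepoints and ``single_timepoint`` flags that only one contributed.
    """

    subject: str
    arm: str
    engrafted_otus_w1: frozenset[str] = frozenset()
    engrafted_otus_w10: frozenset[str] = frozenset()
    percent_w1: float | None = None
    percent_w10: float | None = None
    percent_avg: float | None = None
    single_timepoint: bool = False
    mode: str = "abundance"
    exclusions: list[str] = field(default_factory=list)


def engrafted_otus(donor_present: frozenset[str] | set[str],
                   pre_present: frozenset[str] | set[str],
                   post_present: frozenset[str] | set[str]) -> frozenset[str]:
    """OTUs present in donor and post-FMT sample but absent at baseline."""
    return frozenset((set(donor_present) & set(post_present)) - set(pre_present))


def engraftment_percent(engrafted: frozenset[str] | set[str],
                        donor_present: frozenset[str] | set[str],
                        post_sample: pd.Series,
                        mode: str = "abundance") -> float | None:
    """Engraftment as a percentage under the chosen denominator.

    ``post_sample`` is the post-FMT count vector indexed by OTU id.
    Returns None (with a warning) for donor_richness with an empty donor
    set, where the ratio is undefined.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    engrafted = set(engrafted)
    if not engrafted <= set(donor_present):
        raise ValueError("engrafted set must be a subset of the donor set")
    total = int(post_sample.sum())
    if total <= 0:
        raise ValueError("post-FMT sample has zero total reads")
    if mode == "abundance":
        reads = int(post_sample.loc[list(engrafted)].sum()) if engrafted else 0
        return 100.0 * reads / total
    if mode == "donor_richness":
        if len(donor_present) == 0:
            warnings.warn("empty donor OTU set: donor_richness undefined")
            return None
        return 100.0 * len(engrafted) / len(donor_present)
    post_present = set(post_sample.index[post_sample > 0])
    if len(post_present) == 0:
        raise ValueError("post-FMT sample has no present OTUs")
    return 100.0 * len(engrafted) / len(post_present)


def average_engraftment(percent_w1: float | None,
                        percent_w10: float | None) -> tuple[float | None, bool]:
    """Mean of the available timepoint percentages.

    Returns (average, single_timepoint_flag); (None, False) when both
    timepoints are missing.
    """
    vals = [v for v in (percent_w1, percent_w10) if v is not None]
    if not vals:
        return None, False
    return float(np.mean(vals)), len(vals) == 1


def compute_engraftment(table: OtuTable, meta: pd.DataFrame,
                        mode: str = "abundance",
                        donor_policy: str = "union",
                        presence_floor: float = 0.0) -> list[EngraftmentResult]:
    """Per-subject engraftment for every FMT-arm recipient in the metadata.

    Presence means count >= 1 in the (already filtered) table; a nonzero
    ``presence_floor`` additionally requires the OTU's within-sample
    relative abundance to reach that floor. ``donor_policy`` is ``union``
    (pool every donor sample listed for the subject — the default, matching
    a capsule product manufactured from a fixed donor panel) or ``listed``
    (identical mechanics, but requires an explicit non-empty donor list per
    subject).

    Subjects with no baseline sample are excluded (engraftment is undefined
    without the pre-FMT reference); missing post-FMT timepoints yield
    single-timepoint averages. Placebo subjects are processed too when donor
    samples exist — their engraftment is a specificity control.
    """
    if donor_policy not in ("union", "listed"):
        raise ValueError(f"unknown donor_policy {donor_policy!r}")

    def present(sample_id: str) -> frozenset[str]:
        row = table.counts.loc[sample_id]
        if presence_floor > 0:
            total = row.sum()
            return frozenset(row.index[(row >= 1) & (row / total >= presence_floor)])
        return frozenset(row.index[row >= 1])

    donor_samples = meta[meta["timepoint"] == "donor"]
    donor_by_subject = dict(zip(donor_samples["subject_id"], donor_samples["sample_id"]))

    results: list[EngraftmentResult] = []
    recipients = meta[meta["timepoint"] != "donor"]
    for subject, sub in recipients.groupby("subject_id", sort=True):
        arm = sub["arm"].iloc[0]
        by_tp = dict(zip(sub["timepoint"], sub["sample_id"]))
        res = EngraftmentResult(subject=subject, arm=arm, mode=mode)
        if "baseline" not in by_tp:
            res.exclusions.append("no_baseline_sample")
            results.append(res)
            continue
        donor_ids = [d for d in sub["donor_ids"].iloc[0].split(",") if d]
        if donor_policy == "listed" and not donor_ids:
            res.exclusions.append("no_donor_listed")
            results.append(res)
            continue
        if not donor_ids:  # union policy falls back to the full donor panel
            donor_ids = sorted(donor_by_subject)
        donor_set: frozenset[str] = frozenset()
        for did in donor_ids:
            if did not in donor_by_subject:
                raise ValueError(f"subject {subject!r}: unknown donor {did!r}")
            donor_set |= present(donor_by_subject[did])
        pre = present(by_tp["baseline"])
        percents: dict[str, float | None] = {}
        sets: dict[str, frozenset[str]] = {}
        for tp in ("week1", "week10"):
            if tp not in by_tp:
                res.exclusions.append(f"no_{tp}_sample")
                percents[tp] = None
                sets[tp] = frozenset()
                continue
            post_counts = table.counts.loc[by_tp[tp]]
            post = present(by_tp[tp])
            eng = engrafted_otus(donor_set, pre, post)
            assert not (eng & pre), "engrafted set overlaps baseline-present set"
            sets[tp] = eng
            percents[tp] = engraftment_percent(eng, donor_set, post_counts, mode)
        res.engrafted_otus_w1 = sets["week1"]
        res.engrafted_otus_w10 = sets["week10"]
        res.percent_w1 = percents["week1"]
        res.percent_w10 = percents["week10"]
        res.percent_avg, res.single_timepoint = average_engraftment(
            percents["week1"], percents["week10"])
        results.append(res)
    return results


def compare_engraftment_by_arm(results: list[EngraftmentResult],
                               arms: tuple[str, ...] = FMT_ARMS) -> dict:
    """Kruskal–Wallis across arms with Dunn pairwise posttests.

    Compares the averaged engraftment percentage over the requested arms
    (the three FMT arms by default — the placebo arm received no donor
    material, so its engraftment is a negative control, not a group in the
    omnibus test). Arms with fewer than two evaluable subjects are dropped
    with a warning.
    """
    values, labels = [], []
    for arm in arms:
        vals = [r.percent_avg for r in results
                if r.arm == arm and r.percent_avg is not None]
        if len(vals) < 2:
            warnings.warn(f"arm {arm!r} has <2 evaluable subjects; excluded")
            continue
        values.append(vals)
        labels.append(arm)
    if len(values) < 2:
        raise ValueError("need at least two arms with >=2 subjects each")
    h, p = fstats.kruskal_wallis(values)
    report = {
        "arms": labels,
        "n": {a: len(v) for a, v in zip(labels, values)},
        "median": {a: float(np.median(v)) for a, v in zip(labels, values)},
        "kruskal_H": h,
        "kruskal_p": p,
    }
    if len(values) >= 3:
        dunn = fstats.dunn_posttest(values, labels)
        report["dunn"] = {f"{a} vs {b}": {"z": z, "p": pv}
                          for (a, b), (z, pv) in dunn.items()}
    return report


def compare_engraftment_by_response(results: list[EngraftmentResult],
                                    responder_flags: dict[str, bool]
                                    ) -> dict | None:
    """Mann–Whitney U on averaged engraftment: responders vs non-responders.

    ``responder_flags`` maps subject id to a clinical responder flag;
    subjects absent from the map or without an engraftment value are
    dropped. Returns None (with a warning) if either class is empty.
    """
    resp, nonresp = [], []
    for r in results:
        if r.percent_avg is None or r.subject not in responder_flags:
            continue
        (resp if responder_flags[r.subject] else nonresp).append(r.percent_avg)
    if len(resp) < 2 or len(nonresp) < 2:
        warnings.warn("fewer than two subjects in a response class")
        return None
    u, p = fstats.mann_whitney_u(resp, nonresp)
    return {
        "n_responders": len(resp),
        "n_nonresponders": len(nonresp),
        "median_responders": float(np.median(resp)),
        "median_nonresponders": float(np.median(nonresp)),
        "mannwhitney_U": u,
        "mannwhitney_p": p,
    }


def results_to_frame(results: list[EngraftmentResult]) -> pd.DataFrame:
    """Flatten results to the per-subject output table."""
    rows = []
    for r in results:
        rows.append({
            "subject": r.subject,
            "arm": r.arm,
            "percent_w1": r.percent_w1 if r.percent_w1 is not None else math.nan,
            "percent_w10": r.percent_w10 if r.percent_w10 is not None else math.nan,
            "percent_avg": r.percent_avg if r.percent_avg is not None else math.nan,
            "n_engrafted_w1": len(r.engrafted_otus_w1),
            "n_engrafted_w10": len(r.engrafted_otus_w10),
            "single_timepoint": r.single_timepoint,
            "mode": r.mode,
            "exclusions": ";".join(r.exclusions),
        })
    return pd.DataFrame(rows)
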