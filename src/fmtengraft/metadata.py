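"""Per-sample trial metadata: subject, arm, timepoint, donor assignment."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["ARMS", "FMT_ARMS", "TIMEPOINTS", "read_metadata", "write_metadata"]

ARMS = ("FMT", "R-FMT", "CM-FMT", "placebo")
#: Arms that actually received donor material.
FMT_ARMS = ("FMT", "R-FMT", "CM-FMT")
TIMEPOINTS = ("baseline", "during_abx", "week1", "week10", "donor")

REQUIRED_COLUMNS = ("sample_id", "subject_id", "arm", "timepoint", "donor_ids")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV and validate its vocabulary.

    Columns: sample_id, subject_id, arm, timepoint, donor_ids (comma-joined
    donor subject ids, empty for donor samples). Donor samples carry
    arm='donor' and timepoint='donor'.
    """
    meta = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in REQUIRED_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    bad_tp = set(meta["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise ValueError(f"{path}: unknown timepoint(s) {sorted(bad_tp)}")
    bad_arm = set(meta["arm"]) - set(ARMS) - {"donor"}
    if bad_arm:
        raise ValueError(f"{path}: unknown arm(s) {sorted(bad_arm)}")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)
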