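"""OTU count tables: reading, writing, filtering, normalization, aggregation.

The on-disk dialect is the classic QIIME tab-separated table: OTUs as rows,
samples as columns, with a leading ``#OTU ID`` header cell. The in-memory
orientation is samples x OTUs (a :class:`pandas.DataFrame` of non-negative
integers), which matches how every downstream computation consumes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "OtuTableError",
    "read_otu_table",
    "write_otu_table",
    "read_taxonomy",
    "filter_otus",
    "relative_abundance",
    "aggregate_by_rank",
    "rarefy",
    "RANKS",
]

#: Canonical lineage ranks, outermost first.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

HEADER_TOKEN = "#OTU ID"


class OtuTableError(ValueError):
    """Malformed OTU table input (parse or validation failure)."""


@dataclass
class OtuTable:
    """An integer count matrix (samples x OTUs) with optional taxonomy.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id with one column per OTU id; values
        are non-negative integers.
    taxonomy
        Optional map from OTU id to an ordered lineage tuple
        (domain, ..., genus). Lineages may be shorter than six ranks.
    """

    counts: pd.DataFrame
    taxonomy: dict[str, tuple[str, ...]] | None = field(default=None)

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise OtuTableError(f"duplicate sample id {dup!r}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise OtuTableError(f"duplicate OTU id {dup!r}")
        vals = self.counts.to_numpy()
        if vals.size:
            if not np.issubdtype(vals.dtype, np.integer):
                if not np.all(np.equal(np.mod(vals, 1), 0)):
                    bad = np.argwhere(np.mod(vals, 1) != 0)[0]
                    raise OtuTableError(
                        f"non-integer count {vals[tuple(bad)]!r} at sample "
                        f"{self.counts.index[bad[0]]!r}, OTU {self.counts.columns[bad[1]]!r}"
                    )
                self.counts = self.counts.astype(np.int64)
                vals = self.counts.to_numpy()
            if (vals < 0).any():
                bad = np.argwhere(vals < 0)[0]
                raise OtuTableError(
                    f"negative count at sample {self.counts.index[bad[0]]!r}, "
                    f"OTU {self.counts.columns[bad[1]]!r}"
                )
        else:
            self.counts = self.counts.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def presence(self, sample_id: str, min_count: int = 1) -> frozenset[str]:
        """OTUs observed in ``sample_id`` with at least ``min_count`` reads."""
        row = self.counts.loc[sample_id]
        return frozenset(row.index[row >= min_count])

    def sample_counts(self, sample_id: str) -> pd.Series:
        return self.counts.loc[sample_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.taxonomy == other.taxonomy


def _parse_cells(df: pd.DataFrame, path: str) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        series = pd.to_numeric(df[col], errors="coerce")
        if series.isna().any():
            row = df.index[series.isna()][0]
            raise OtuTableError(
                f"{path}: non-numeric count {df.loc[row, col]!r} "
                f"(row {row!r}, column {col!r})"
            )
        frac = np.mod(series.to_numpy(dtype=float), 1)
        if (frac != 0).any():
            row = df.index[np.argmax(frac != 0)]
            raise OtuTableError(
                f"{path}: non-integer count {df.loc[row, col]!r} "
                f"(row {row!r}, column {col!r})"
            )
        out[col] = series.astype(np.int64)
    return pd.DataFrame(out, index=df.index)


def read_otu_table(path: str | Path, format: str = "tsv",
                   taxonomy_path: str | Path | None = None) -> OtuTable:
    """Read a tab-separated OTU table.

    Orientation is auto-detected: a ``#OTU ID`` first header cell marks the
    QIIME-classic layout (OTUs as rows); a ``#SampleID`` cell marks the
    transposed layout. ``format`` accepts ``tsv`` or ``biom-tsv`` (a BIOM
    TSV export, which carries an extra comment line before the header).
    """
    if format not in ("tsv", "biom-tsv"):
        raise OtuTableError(f"unknown format {format!r}; expected 'tsv' or 'biom-tsv'")
    path = Path(path)
    skip = 1 if format == "biom-tsv" else 0
    with open(path) as fh:
        for _ in range(skip):
            fh.readline()
        header = fh.readline().rstrip("\n")
        if not header:
            raise OtuTableError(f"{path}: empty file")
        df = pd.read_csv(fh, sep="\t", header=None, index_col=0, dtype=str,
                         names=header.split("\t"))
    first = header.split("\t")[0]
    df.index = df.index.astype(str)
    df = _parse_cells(df, str(path))
    if first == HEADER_TOKEN:
        counts = df.T  # rows were OTUs
    elif first.lstrip("#").lower() in ("sampleid", "sample id", "sample_id"):
        counts = df
    else:
        raise OtuTableError(
            f"{path}: unrecognized header token {first!r}; expected "
            f"'{HEADER_TOKEN}' (OTUs as rows) or '#SampleID' (samples as rows)"
        )
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    counts.index.name = None
    counts.columns.name = None
    taxonomy = read_taxonomy(taxonomy_path) if taxonomy_path else None
    return OtuTable(counts, taxonomy)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    """Write in the QIIME-classic dialect (OTUs as rows, ``#OTU ID`` header)."""
    out = table.counts.T.copy()
    out.index.name = HEADER_TOKEN
    out.to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a two-column TSV of OTU id and semicolon-delimited lineage."""
    taxonomy: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise OtuTableError(f"{path}:{lineno}: expected two tab-separated fields")
            otu, lineage = parts
            taxonomy[otu] = tuple(t.strip() for t in lineage.split(";") if t.strip())
    return taxonomy


def write_taxonomy(taxonomy: dict[str, tuple[str, ...]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#OTU ID\tlineage\n")
        for otu, lineage in taxonomy.items():
            fh.write(f"{otu}\t{';'.join(lineage)}\n")


def filter_otus(table: OtuTable, min_samples: int = 2,
                min_total_reads: int = 10) -> OtuTable:
    """Drop low-evidence OTUs.

    An OTU is retained iff it has a nonzero count in at least ``min_samples``
    distinct samples AND its total read count across all samples is at least
    ``min_total_reads``. Defaults implement the study-standard rule of
    discarding OTUs seen in fewer than two unique samples or with fewer than
    ten reads in total. Boundary values (exactly 2 samples, exactly 10 reads)
    are retained. Idempotent; the sample set is never changed.
    """
    if min_samples < 1:
        raise ValueError(f"min_samples must be >= 1, got {min_samples}")
    if min_total_reads < 0:
        raise ValueError(f"min_total_reads must be >= 0, got {min_total_reads}")
    counts = table.counts
    n_present = (counts > 0).sum(axis=0)
    totals = counts.sum(axis=0)
    keep = (n_present >= min_samples) & (totals >= min_total_reads)
    kept = counts.loc[:, keep[keep].index]
    taxonomy = None
    if table.taxonomy is not None:
        taxonomy = {o: l for o, l in table.taxonomy.items() if o in kept.columns}
    return OtuTable(kept, taxonomy)


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Per-sample relative abundances; each row sums to one.

    Raises on any sample with zero total reads, naming the sample.
    """
    totals = table.counts.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total reads")
    return table.counts.div(totals, axis=0)


def aggregate_by_rank(table: OtuTable, rank: str) -> OtuTable:
    """Collapse OTU counts to taxa at ``rank`` (e.g. ``order``).

    OTUs whose lineage does not reach the requested rank are pooled under
    ``unclassified``. Per-sample totals are conserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if table.taxonomy is None:
        raise ValueError("table has no taxonomy; cannot aggregate by rank")
    depth = RANKS.index(rank)
    labels = {}
    for otu in table.otu_ids:
        lineage = table.taxonomy.get(otu, ())
        labels[otu] = lineage[depth] if len(lineage) > depth else "unclassified"
    grouped = table.counts.T.groupby(pd.Series(labels)).sum().T
    return OtuTable(grouped)


def rarefy(table: OtuTable, depth: int, seed: int, drop_short: bool = True) -> OtuTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Off by default everywhere in the pipeline; provided for sensitivity
    analysis. Samples with fewer than ``depth`` reads are dropped when
    ``drop_short`` (otherwise kept as-is).
    """
    rng = np.random.default_rng(seed)
    rows = {}
    for sid in table.sample_ids:
        vec = table.counts.loc[sid].to_numpy()
        total = vec.sum()
        if total < depth:
            if drop_short:
                continue
            rows[sid] = vec
            continue
        # multivariate hypergeometric draw = subsampling without replacement
        rows[sid] = rng.multivariate_hypergeometric(vec, depth)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=table.otu_ids)
    return OtuTable(out.astype(np.int64), table.taxonomy)
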