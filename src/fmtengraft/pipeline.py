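"""End-to-end trial analysis: filter -> engraftment -> diversity ->
composition -> clinical outcomes, with TSV/JSON artifacts and a log.

Analysis semantics are per-protocol: a subject without a post-FMT stool
sample drops out of the engraftment analysis (logged with a reason code)
but keeps contributing clinical outcomes if questionnaires exist.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import clinical as fclinical
from . import diversity as fdiversity
from . import engraftment as fengraft
from .metadata import read_metadata
from .otu_table import (OtuTable, aggregate_by_rank, filter_otus,
                        read_otu_table, relative_abundance)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("fmtengraft")


@dataclass
class RunConfig:
    """Paths and options for one pipeline run."""

    otu_table: Path
    metadata: Path
    out_dir: Path
    taxonomy: Path | None = None
    clinical: Path | None = None
    mode: str = "abundance"
    donor_policy: str = "union"
    presence_floor: float = 0.0
    min_samples: int = 2
    min_total_reads: int = 10
    composition_rank: str = "order"
    diversity_pairs: tuple[tuple[str, str], ...] = (
        ("baseline", "during_abx"),
        ("baseline", "week1"),
        ("baseline", "week10"),
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        def p(key, required=False):
            v = raw.get(key)
            if v is None:
                if required:
                    raise ValueError(f"{path}: missing required key {key!r}")
                return None
            q = Path(v)
            return q if q.is_absolute() else base / q
        kwargs = dict(
            otu_table=p("otu_table", required=True),
            metadata=p("metadata", required=True),
            out_dir=p("out_dir", required=True),
            taxonomy=p("taxonomy"),
            clinical=p("clinical"),
        )
        for key in ("mode", "donor_policy", "presence_floor", "min_samples",
                    "min_total_reads", "composition_rank"):
            if key in raw:
                kwargs[key] = raw[key]
        if "diversity_pairs" in raw:
            kwargs["diversity_pairs"] = tuple(tuple(x) for x in raw["diversity_pairs"])
        return cls(**kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the report dict and writes artifacts.

    Artifacts in ``config.out_dir``: filtered_table.tsv, engraftment.tsv,
    diversity.tsv, composition_<rank>.tsv, report.json, summary.txt and
    run.log. Deterministic given fixed inputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> dict:
    report: dict = {"config": {
        "mode": config.mode, "donor_policy": config.donor_policy,
        "presence_floor": config.presence_floor,
        "min_samples": config.min_samples,
        "min_total_reads": config.min_total_reads,
    }}

    table = read_otu_table(config.otu_table,
                           taxonomy_path=config.taxonomy)
    meta = read_metadata(config.metadata)
    log.info("loaded %d samples x %d OTUs", table.n_samples, table.n_otus)

    missing = set(meta["sample_id"]) - set(table.sample_ids)
    for sid in sorted(missing):
        log.warning("excluded sample %s: reason=not_in_otu_table", sid)
    meta = meta[meta["sample_id"].isin(table.sample_ids)]

    # stage: filter
    filtered = filter_otus(table, config.min_samples, config.min_total_reads)
    log.info("filter retained %d/%d OTUs (min_samples=%d, min_total_reads=%d)",
             filtered.n_otus, table.n_otus, config.min_samples,
             config.min_total_reads)
    report["filter"] = {"otus_before": table.n_otus,
                        "otus_after": filtered.n_otus}
    from .otu_table import write_otu_table
    write_otu_table(filtered, out / "filtered_table.tsv")

    # stage: engraftment
    results = fengraft.compute_engraftment(
        filtered, meta, mode=config.mode, donor_policy=config.donor_policy,
        presence_floor=config.presence_floor)
    for r in results:
        for reason in r.exclusions:
            log.warning("subject %s: reason=%s", r.subject, reason)
    frame = fengraft.results_to_frame(results)
    frame.to_csv(out / "engraftment.tsv", sep="\t", index=False)
    evaluable = [r for r in results if r.percent_avg is not None]
    if sum(1 for r in evaluable if r.arm != "placebo") >= 4:
        report["engraftment"] = fengraft.compare_engraftment_by_arm(results)
    else:
        log.warning("too few evaluable FMT-arm subjects; omnibus test skipped")
        report["engraftment"] = {
            "note": "omnibus test skipped: too few evaluable FMT-arm subjects"}
    placebo = [r.percent_avg for r in evaluable if r.arm == "placebo"]
    if placebo:
        report["engraftment"]["placebo_median"] = float(
            pd.Series(placebo).median())

    # stage: diversity
    div = fdiversity.diversity_table(filtered, meta)
    div.to_csv(out / "diversity.tsv", sep="\t", index=False)
    series = fdiversity.series_from_table(div)
    report["diversity"] = {}
    for a, b in config.diversity_pairs:
        for arm in sorted({s.arm for s in series}):
            arm_series = [s for s in series if s.arm == arm]
            comp = fdiversity.compare_diversity(arm_series, a, b)
            report["diversity"][f"{arm}:{a}->{b}"] = comp

    # stage: composition
    if filtered.taxonomy:
        comp_table = aggregate_by_rank(filtered, config.composition_rank)
        rel = relative_abundance(comp_table)
        rel.to_csv(out / f"composition_{config.composition_rank}.tsv", sep="\t")
        report["composition"] = {"rank": config.composition_rank,
                                 "taxa": list(rel.columns)}

    # stage: clinical outcomes
    if config.clinical:
        records = fclinical.read_clinical(config.clinical)
        report["clinical"] = fclinical.outcomes_table(records)
        flags = {r.subject: fclinical.classify_responders(r)["sss"]
                 for r in records}
        flags = {s: f for s, f in flags.items() if f is not None}
        by_resp = fengraft.compare_engraftment_by_response(
            [r for r in results if r.arm != "placebo"], flags)
        if by_resp:
            report["engraftment_by_response"] = by_resp

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    (out / "summary.txt").write_text(_summary_text(report))
    log.info("pipeline complete")
    return report


def _summary_text(report: dict) -> str:
    lines = ["FMT engraftment analysis summary", "=" * 34, ""]
    eng = report.get("engraftment", {})
    if "median" in eng:
        lines.append("Median engraftment (averaged week 1 / week 10):")
        for arm, med in eng["median"].items():
            lines.append(f"  {arm:10s} {med:6.1f}%  (n={eng['n'][arm]})")
        lines.append(f"  Kruskal-Wallis H={eng['kruskal_H']:.3f}, "
                     f"p={eng['kruskal_p']:.4f}")
        for pair, d in eng.get("dunn", {}).items():
            lines.append(f"  Dunn {pair}: z={d['z']:.3f}, p={d['p']:.4f}")
    if "placebo_median" in eng:
        lines.append(f"  placebo control median: {eng['placebo_median']:.2f}%")
    lines.append("")
    if report.get("diversity"):
        lines.append("Paired diversity contrasts (Shannon, nats):")
        for key, comp in report["diversity"].items():
            if comp.get("p") is not None:
                lines.append(f"  {key}: mean diff={comp['mean_difference']:+.3f}, "
                             f"p={comp['p']:.4f} (n={comp['n_pairs']})")
    if "clinical" in report:
        lines.append("")
        lines.append("Clinical outcomes:")
        for label, entry in report["clinical"]["continuous"].items():
            if "anova_p" in entry:
                lines.append(f"  {label}: ANOVA p={entry['anova_p']:.3f}")
        for label, entry in report["clinical"]["dichotomous"].items():
            if "fisher_p" in entry:
                lines.append(f"  {label}: Fisher exact p={entry['fisher_p']:.3f}")
    if "engraftment_by_response" in report:
        r = report["engraftment_by_response"]
        lines.append(f"  engraftment responders vs non-responders: "
                     f"Mann-Whitney p={r['mannwhitney_p']:.3f}")
    return "\n".join(lines) + "\n"
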