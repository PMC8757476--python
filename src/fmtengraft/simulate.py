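"""Synthetic FMT trial with known ground truth.

Generates a four-arm capsule-FMT trial (FMT alone, rifaximin-pretreated
R-FMT, ciprofloxacin/metronidazole-pretreated CM-FMT, placebo) with four
stool timepoints per subject (baseline, during antibiotics, week 1,
week 10) and a panel of donors, so every stage of the engraftment pipeline
can be validated against a generative truth.

Generative model
----------------
Relative-abundance profiles are log-normal: taxon weights are drawn
``exp(sigma * Z)`` and normalized, a standard heavy-tailed null for
microbiome communities. Recipients draw over a shared taxon pool; each
donor draws over the shared pool plus its own donor-unique taxa, which are
absent from every recipient baseline by construction — this is what makes
engraftment identifiable. Antibiotic arms have a configurable fraction of
baseline taxa multiplied by a depletion factor at the during-antibiotics
timepoint (then renormalized), which strictly lowers expected Shannon
diversity. Post-FMT samples mix the recovered recipient profile with the
administered donor's unique-taxon profile at the arm's transfer fraction
``f``; the expected share of post-FMT reads on transferred taxa is exactly
``f``. Every sample is a multinomial draw at the configured depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .clinical import ClinicalRecord, write_clinical
from .metadata import ARMS, write_metadata
from .otu_table import OtuTable, write_otu_table, write_taxonomy

__all__ = ["SimConfig", "GroundTruth", "simulate_trial", "write_fixture"]

_DEFAULT_TRANSFER = {"FMT": 0.15, "R-FMT": 0.05, "CM-FMT": 0.02, "placebo": 0.0}

# synthetic lineage templates; orders chosen to exercise order-level
# composition summaries typical of gut 16S data
_ORDERS = (
    ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales"),
    ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales"),
    ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales"),
    ("Bacteria", "Actinobacteria", "Actinomycetia", "Bifidobacteriales"),
)


@dataclass
class SimConfig:
    """All generative parameters of the synthetic trial.

    Defaults mirror a small pilot trial: 10 subjects per arm, six donors,
    sequencing depth 10,000 reads, and per-arm transfer fractions of 0.15
    (FMT alone), 0.05 (R-FMT), 0.02 (CM-FMT) and 0 (placebo). The
    antibiotic arms have half their baseline taxa depleted tenfold during
    treatment.
    """

    seed: int
    n_per_arm: int = 10
    n_donors: int = 6
    n_otus_recipient: int = 150
    n_otus_donor_unique: int = 60
    transfer_fraction: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TRANSFER))
    abx_depletion: float = 0.1
    abx_affected_fraction: float = 0.5
    abx_arms: tuple[str, ...] = ("R-FMT", "CM-FMT")
    permanently_lost_fraction: float = 0.0
    depth: int = 10_000
    lognormal_sigma: float = 1.5
    # clinical generator: arm-independent (null) improvement by default
    sss_change_mean: float = -80.0
    sss_change_sd: float = 110.0
    qol_change_mean: float = 12.0
    qol_change_sd: float = 20.0
    relief_prob: float = 0.4
    arm_sss_effect: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for arm, f in self.transfer_fraction.items():
            if not 0 <= f <= 1:
                raise ValueError(f"transfer_fraction[{arm!r}] must be in [0,1]")
        if any(f > 0 for f in self.transfer_fraction.values()) \
                and self.n_otus_donor_unique < self.n_donors:
            raise ValueError(
                "donor-unique pool too small: need at least one unique OTU "
                "per donor when any transfer fraction is positive")
        if not 0 < self.abx_depletion <= 1:
            raise ValueError("abx_depletion must be in (0, 1]")
        if not 0 <= self.abx_affected_fraction <= 1:
            raise ValueError("abx_affected_fraction must be in [0, 1]")
        if not 0 <= self.permanently_lost_fraction <= 1:
            raise ValueError("permanently_lost_fraction must be in [0, 1]")
        if self.depth < 1:
            raise ValueError("depth must be positive")
        if self.lognormal_sigma <= 0:
            raise ValueError("lognormal_sigma must be positive")


@dataclass
class GroundTruth:
    """Per-subject generative truth for validating the pipeline."""

    transfer_fraction: dict[str, float]
    administered_donor: dict[str, str]
    transferred_otus: dict[str, list[str]]
    expected_engrafted_share: dict[str, dict[str, float]]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _lognormal_profile(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    w = np.exp(sigma * rng.standard_normal(n))
    return w / w.sum()


def simulate_trial(config: SimConfig
                   ) -> tuple[OtuTable, pd.DataFrame, GroundTruth,
                              list[ClinicalRecord]]:
    """Generate (OtuTable, sample metadata, ground truth, clinical records).

    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_shared = config.n_otus_recipient
    n_unique = config.n_otus_donor_unique
    otu_ids = [f"OTU_{i + 1:04d}" for i in range(n_shared + n_unique)]
    shared_idx = np.arange(n_shared)
    unique_idx = np.arange(n_shared, n_shared + n_unique)

    # partition the donor-unique pool across donors
    donor_ids = [f"D{d + 1}" for d in range(config.n_donors)]
    unique_split = np.array_split(unique_idx, config.n_donors)

    taxonomy = {}
    for i, otu in enumerate(otu_ids):
        if i % 11 == 10:  # sprinkle OTUs with no order-level call
            taxonomy[otu] = ("Bacteria",)
        else:
            base = _ORDERS[i % len(_ORDERS)]
            taxonomy[otu] = base + (f"Family_{i % 7}", f"Genus_{i % 13}")

    n_total = n_shared + n_unique
    counts: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []

    donor_profiles = {}
    donor_unique_profiles = {}
    for d, did in enumerate(donor_ids):
        p = np.zeros(n_total)
        w_shared = _lognormal_profile(rng, n_shared, config.lognormal_sigma)
        w_unique = _lognormal_profile(rng, len(unique_split[d]),
                                      config.lognormal_sigma)
        # donors carry ~20% of their mass on their unique taxa
        p[shared_idx] = 0.8 * w_shared
        p[unique_split[d]] = 0.2 * w_unique
        sid = f"{did}_donor"
        counts[sid] = rng.multinomial(config.depth, p)
        meta_rows.append({"sample_id": sid, "subject_id": did, "arm": "donor",
                          "timepoint": "donor", "donor_ids": ""})
        donor_profiles[did] = p
        up = np.zeros(n_total)
        up[unique_split[d]] = w_unique
        donor_unique_profiles[did] = up

    truth = GroundTruth({}, {}, {}, {})
    records: list[ClinicalRecord] = []
    all_donors = ",".join(donor_ids)

    subject_no = 0
    for arm in ARMS:
        f = config.transfer_fraction.get(arm, 0.0)
        for _ in range(config.n_per_arm):
            subject_no += 1
            subj = f"S{subject_no:03d}"
            base_p = np.zeros(n_total)
            base_p[shared_idx] = _lognormal_profile(rng, n_shared,
                                                    config.lognormal_sigma)
            counts[f"{subj}_baseline"] = rng.multinomial(config.depth, base_p)

            # during-antibiotics: depletion in the antibiotic arms only
            abx_p = base_p.copy()
            affected = np.zeros(n_total, dtype=bool)
            if arm in config.abx_arms and config.abx_affected_fraction > 0:
                n_aff = int(round(config.abx_affected_fraction * n_shared))
                aff = rng.choice(shared_idx, size=n_aff, replace=False)
                affected[aff] = True
                abx_p[aff] *= config.abx_depletion
                abx_p /= abx_p.sum()
            counts[f"{subj}_during_abx"] = rng.multinomial(config.depth, abx_p)

            # recovery toward baseline, minus any permanently lost taxa
            recovered = base_p.copy()
            if config.permanently_lost_fraction > 0 and affected.any():
                aff_ids = np.flatnonzero(affected)
                n_lost = int(round(config.permanently_lost_fraction * len(aff_ids)))
                if n_lost:
                    lost = rng.choice(aff_ids, size=n_lost, replace=False)
                    recovered[lost] = 0
                    recovered /= recovered.sum()

            donor = donor_ids[int(rng.integers(config.n_donors))]
            post_p = (1 - f) * recovered + f * donor_unique_profiles[donor]
            for tp in ("week1", "week10"):
                counts[f"{subj}_{tp}"] = rng.multinomial(config.depth, post_p)

            for tp in ("baseline", "during_abx", "week1", "week10"):
                meta_rows.append({"sample_id": f"{subj}_{tp}", "subject_id": subj,
                                  "arm": arm, "timepoint": tp,
                                  "donor_ids": all_donors})

            transferred = [otu_ids[i] for i in
                           np.flatnonzero(donor_unique_profiles[donor] > 0)] if f > 0 else []
            truth.transfer_fraction[subj] = f
            truth.administered_donor[subj] = donor if f > 0 else ""
            truth.transferred_otus[subj] = transferred
            truth.expected_engrafted_share[subj] = {"week1": f, "week10": f}

            records.append(_simulate_clinical(rng, subj, arm, config))

    table = OtuTable(
        pd.DataFrame.from_dict(counts, orient="index", columns=otu_ids),
        taxonomy)
    meta = pd.DataFrame(meta_rows)
    return table, meta, truth, records


def _simulate_clinical(rng: np.random.Generator, subj: str, arm: str,
                       config: SimConfig) -> ClinicalRecord:
    sss0 = float(np.clip(rng.normal(310, 70), 176, 500))
    shift = config.arm_sss_effect.get(arm, 0.0)
    sss10 = float(np.clip(sss0 + rng.normal(config.sss_change_mean + shift,
                                            config.sss_change_sd), 0, 500))
    qol0 = float(np.clip(rng.normal(48, 18), 0, 100))
    qol10 = float(np.clip(qol0 + rng.normal(config.qol_change_mean,
                                            config.qol_change_sd), 0, 100))
    gis = int(rng.integers(1, 8))
    relief = bool(rng.random() < config.relief_prob)
    return ClinicalRecord(
        subject=subj, arm=arm,
        ibs_sss_baseline=round(sss0, 1), ibs_sss_week10=round(sss10, 1),
        ibs_qol_baseline=round(qol0, 1), ibs_qol_week10=round(qol10, 1),
        gis_week10=gis, adequate_relief_week10=relief)


def write_fixture(dataset: tuple[OtuTable, pd.DataFrame, GroundTruth,
                                 list[ClinicalRecord]],
                  out_dir: str | Path) -> dict[str, Path]:
    """Write the simulated trial as a directory of plain-text files.

    Produces otu_table.tsv (QIIME-classic orientation), metadata.tsv,
    taxonomy.tsv, clinical.tsv and ground_truth.json; byte-identical for
    identical configs.
    """
    table, meta, truth, records = dataset
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "otu_table": out / "otu_table.tsv",
        "metadata": out / "metadata.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "clinical": out / "clinical.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    write_otu_table(table, paths["otu_table"])
    write_metadata(meta, paths["metadata"])
    if table.taxonomy:
        write_taxonomy(table.taxonomy, paths["taxonomy"])
    write_clinical(records, paths["clinical"])
    paths["ground_truth"].write_text(truth.to_json() + "\n")
    return paths
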