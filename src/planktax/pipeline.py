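"""End-to-end reproducible pipeline and its configuration.

``run_pipeline`` ties the stages together for one marker:

    simulate -> build databases -> in-silico PCR validation -> read QC ->
    OTU clustering -> chimera flagging -> OTU table -> classification against
    the old and the new database -> old-vs-new comparison

Everything is driven by one global seed; each stage derives its own stream
from it by a fixed offset, so stages are individually reproducible.  A stage
ledger records input/output record counts.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import classify, cluster, compare, qc, refdb, simulate
from .pcr import builtin_pair
from .refdb import KeywordFilter, ReferenceDatabase


@dataclass
class PipelineConfig:
    """All numeric thresholds of the analysis, at their stated defaults."""

    seed: int = 0
    marker: str = "18S"
    n_species: int = 24
    n_genera: int = 8
    frac_warm: float = 0.25
    years: int = 4
    decoy_count: int = 5
    registration_counts: dict | None = None
    sim: simulate.SimParams = field(default_factory=simulate.SimParams)
    keyword_filter: KeywordFilter = field(default_factory=KeywordFilter)
    qc: qc.QCParams = field(default_factory=qc.QCParams)
    cluster_identity: float = 0.990
    min_frequency: int = 2
    scoring: classify.ScoringScheme = field(
        default_factory=classify.ScoringScheme)
    species_threshold: float = 0.98
    merge_artificial: bool = True
    flag_chimeras: bool = True

    def __post_init__(self) -> None:
        self.sim = dataclasses.replace(self.sim, seed=self.seed)

    def to_dict(self) -> dict:
        def enc(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {k: enc(x) for k, x in dataclasses.asdict(v).items()}
            if isinstance(v, tuple):
                return list(v)
            return v
        return {f.name: enc(getattr(self, f.name))
                for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "sim" in data and isinstance(data["sim"], dict):
            sim = {k: tuple(v) if isinstance(v, list) else v
                   for k, v in data["sim"].items()}
            data["sim"] = simulate.SimParams(**sim)
        if "keyword_filter" in data and isinstance(data["keyword_filter"], dict):
            kf = {k: tuple(v) if isinstance(v, list) else v
                  for k, v in data["keyword_filter"].items()}
            data["keyword_filter"] = KeywordFilter(**kf)
        if "qc" in data and isinstance(data["qc"], dict):
            data["qc"] = qc.QCParams(**data["qc"])
        if "scoring" in data and isinstance(data["scoring"], dict):
            data["scoring"] = classify.ScoringScheme(**data["scoring"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    taxa: list
    scenario: simulate.CommunityScenario
    truth: pd.DataFrame
    old_db: ReferenceDatabase
    new_db: ReferenceDatabase
    otus: list
    chimeric_otus: list
    table: pd.DataFrame
    assignments_old: list
    assignments_new: list
    table_old: pd.DataFrame
    table_new: pd.DataFrame
    detection_old: compare.DetectionTable
    detection_new: compare.DetectionTable
    report: compare.ComparisonReport
    stage_counts: dict
    manifest: dict


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"pipeline stage {stage!r} failed: {detail}")
        self.stage = stage


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full synthetic study for one marker; deterministic per seed."""
    config = config or PipelineConfig()
    ledger: dict[str, dict] = {}
    marker = config.marker

    # --- simulate -----------------------------------------------------------
    try:
        taxa = simulate.generate_taxon_pool(
            config.n_species, config.n_genera, config.frac_warm, config.sim,
            registration_counts=config.registration_counts,
            markers=(marker,))
        scenario = simulate.generate_scenario(taxa, years=config.years,
                                              params=config.sim)
        reads_by_sample, truth = simulate.simulate_reads(
            scenario, marker, config.sim)
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", str(e)) from e
    n_pairs = sum(len(r1) for r1, _ in reads_by_sample.values())
    ledger["simulate"] = {"taxa": len(taxa),
                          "samples": len(scenario.samples),
                          "read_pairs": n_pairs}

    # --- reference databases ------------------------------------------------
    try:
        old_raw, verified = simulate.generate_reference_databases(
            taxa, decoy_count=config.decoy_count, params=config.sim,
            markers=(marker,))
        old_records = refdb.dedup_records(
            refdb.filter_records(old_raw, config.keyword_filter))
        old_db = ReferenceDatabase(records=old_records, label="old")
        new_db = refdb.augment(old_db, verified)
    except Exception as e:  # noqa: BLE001
        raise StageError("build-db", str(e)) from e
    ledger["build_db"] = {"old_raw": len(old_raw),
                          "old_filtered": len(old_db),
                          "verified": len(verified), "new": len(new_db)}

    # --- in-silico PCR validation ------------------------------------------
    pair = builtin_pair(marker)
    amplicons = simulate.taxon_amplicons(taxa, marker, pair)
    ledger["pcr"] = {"templates": len(amplicons),
                     "amplicons": len(amplicons)}

    # --- read QC -------------------------------------------------------------
    merged_with_samples: list[tuple[str, str, str]] = []
    counts = qc.StageCounts()
    for sample_id, (r1s, r2s) in reads_by_sample.items():
        for r1, r2 in zip(r1s, r2s):
            counts.input_pairs += 1
            m = qc.process_pair((r1, r2), config.qc, counts)
            if m is not None:
                merged_with_samples.append((m.bases, sample_id, m.read_id))
    if counts.merged > counts.input_pairs:
        raise StageError("qc", "merged more reads than were input")
    ledger["qc"] = counts.as_dict()

    # --- clustering -----------------------------------------------------------
    try:
        otus = cluster.cluster_greedy(merged_with_samples,
                                      config.cluster_identity)
        if config.flag_chimeras:
            otus, chimeric = cluster.flag_chimeras(otus)
        else:
            chimeric = []
        sample_ids = [s.sample_id for s in scenario.samples]
        table = cluster.build_otu_table(otus, sample_ids,
                                        min_total=config.min_frequency)
        otus = [o for o in otus if o.otu_id in table.index]
    except Exception as e:  # noqa: BLE001
        raise StageError("cluster", str(e)) from e
    ledger["cluster"] = {"merged_reads": len(merged_with_samples),
                         "otus": len(otus),
                         "chimeric": len(chimeric),
                         "table_total": int(table.values.sum())}

    # --- classification against both databases ------------------------------
    try:
        assignments_old = classify.classify_otus(
            otus, old_db.for_marker(marker), config.species_threshold,
            config.scoring)
        assignments_new = classify.classify_otus(
            otus, new_db.for_marker(marker), config.species_threshold,
            config.scoring)
        if config.merge_artificial:
            assignments_old, table_old, _ = classify.merge_artificial_otus(
                assignments_old, table)
            assignments_new, table_new, _ = classify.merge_artificial_otus(
                assignments_new, table)
        else:
            table_old = table_new = table
    except Exception as e:  # noqa: BLE001
        raise StageError("classify", str(e)) from e
    ledger["classify"] = {
        "otus": len(otus),
        "species_old": sum(a.resolution == "species" for a in assignments_old),
        "species_new": sum(a.resolution == "species" for a in assignments_new),
    }

    # --- comparison -----------------------------------------------------------
    try:
        detection_old = compare.detection_table(assignments_old, table_old,
                                                "old")
        detection_new = compare.detection_table(assignments_new, table_new,
                                                "new")
        report = compare.summarize(detection_old, detection_new,
                                   dates=scenario.dates())
    except Exception as e:  # noqa: BLE001
        raise StageError("compare", str(e)) from e
    ledger["compare"] = {"difference": report.difference,
                         "mean_delta": report.mean_delta}

    manifest = {
        "seed": config.seed,
        "marker": marker,
        "config_hash": config.config_hash(),
        "stages": list(ledger),
    }
    return PipelineResult(
        config=config, taxa=taxa, scenario=scenario, truth=truth,
        old_db=old_db, new_db=new_db, otus=otus, chimeric_otus=chimeric,
        table=table, assignments_old=assignments_old,
        assignments_new=assignments_new, table_old=table_old,
        table_new=table_new, detection_old=detection_old,
        detection_new=detection_new, report=report,
        stage_counts=ledger, manifest=manifest)
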