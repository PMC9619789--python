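"""End-to-end orchestration: vocabulary → baseline → EHR → derived →
coverage → data quality → phenotyping, with a machine-checkable run
manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from .baseline import VISIT_DATE_FIELD, run_baseline_etl
from .cdm import CdmStore
from .config import PipelineConfig
from .ehr import run_ehr_etl
from .phenotyping import (apply_codelist_phenotype, ascertain_covid_status,
                          compare_cohorts, format_concordance_report,
                          load_phenotype_definition)
from .quality import (coverage_report, coverage_to_csv,
                      format_coverage_markdown, run_dq)
from .runlog import EtlLog
from .synthetic import CONCEPTS
from .vocabulary import load_vocabulary

__all__ = ["RunManifest", "run_pipeline"]

#: concepts whose clinical plausibility depends on recorded gender
GENDER_SPECIFIC_CONCEPTS = {CONCEPTS["male_infertility"]: CONCEPTS["male"]}


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    streams: dict = field(default_factory=dict)
    conservation_ok: bool = True
    row_counts: dict = field(default_factory=dict)
    output_checksums: dict = field(default_factory=dict)
    dq_pass: int = 0
    dq_fail: int = 0
    dq_error_failure: bool = False
    started_at: str = ""
    finished_at: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    blob = yaml.safe_dump(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(bundle_dir: str | Path, out_dir: str | Path,
                 config: PipelineConfig | None = None) -> RunManifest:
    """Run every stage over a source bundle and write all artifacts.

    Outputs under ``out_dir``: ``cdm/`` (one CSV per CDM table),
    ``coverage.csv``/``coverage.md``, ``dq.json``/``dq.md``,
    ``run_log.json``, ``manifest.json`` and, when phenotype definitions
    ship with the bundle, ``phenotypes/<name>.json``.
    """
    config = config or PipelineConfig()
    bundle = Path(bundle_dir)
    out = Path(out_dir)
    required = [bundle / "vocabulary" / "concepts.csv",
                bundle / "baseline.csv", bundle / "field_dictionary.csv"]
    missing = [str(p) for p in required if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {missing}")
    out.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()

    vocab_dir = bundle / "vocabulary"
    store = load_vocabulary(
        vocab_dir / "concepts.csv",
        [p for p in (vocab_dir / "crossmaps.csv",) if p.exists()],
        [p for p in (vocab_dir / "custom_maps.csv",) if p.exists()])

    cdm = CdmStore()
    etl_log = EtlLog()
    withdrawals = []
    wpath = bundle / "withdrawals.csv"
    if wpath.exists():
        wdf = pd.read_csv(wpath, dtype=str)
        withdrawals = list(wdf["eid"]) if "eid" in wdf else []

    person_ids, rejections = run_baseline_etl(
        bundle / "baseline.csv", bundle / "field_dictionary.csv",
        store, cdm, config, etl_log, withdrawals)

    wide = pd.read_csv(bundle / "baseline.csv", dtype=str)
    date_col = f"{VISIT_DATE_FIELD}-0.0"
    visit_dates = {}
    if date_col in wide.columns:
        for _, r in wide.iterrows():
            pid = person_ids.get(str(r["eid"]))
            if pid is not None and isinstance(r[date_col], str):
                visit_dates[pid] = r[date_col]

    run_ehr_etl(bundle, store, cdm, person_ids, config, etl_log,
                baseline_visit_dates=visit_dates)

    # -- exports -----------------------------------------------------------
    cdm_paths = cdm.to_csv(out / "cdm")
    stats = coverage_report(etl_log)
    coverage_to_csv(stats, out / "coverage.csv")
    (out / "coverage.md").write_text(format_coverage_markdown(stats) + "\n",
                                     encoding="utf-8")
    dq = run_dq(cdm, store, config.completeness_threshold,
                GENDER_SPECIFIC_CONCEPTS)
    (out / "dq.json").write_text(dq.to_json() + "\n", encoding="utf-8")
    (out / "dq.md").write_text(dq.to_markdown() + "\n", encoding="utf-8")
    run_log = {"streams": etl_log.summary(),
               "coverage": {v: {"used_terms": len(c.used_terms),
                                "mapped_terms": len(c.mapped_terms),
                                "events": c.events,
                                "mapped_events": c.mapped_events}
                            for v, c in sorted(etl_log.coverage.items())},
               "rejections": rejections}
    (out / "run_log.json").write_text(json.dumps(run_log, indent=1,
                                                 sort_keys=True),
                                      encoding="utf-8")

    # -- phenotyping over the freshly built CDM ---------------------------
    pheno_dir = bundle / "phenotypes"
    if pheno_dir.is_dir():
        pout = out / "phenotypes"
        pout.mkdir(exist_ok=True)
        gt_path = bundle / "ground_truth.json"
        gt = (json.loads(gt_path.read_text(encoding="utf-8"))
              if gt_path.exists() else None)
        for ypath in sorted(pheno_dir.glob("*.yaml")):
            definition = load_phenotype_definition(ypath)
            if definition.name == "covid19":
                members = ascertain_covid_status(
                    cdm, definition, [CONCEPTS["positive"]])
            else:
                members = apply_codelist_phenotype(cdm, definition)
            payload = {"phenotype": definition.name,
                       "n_members": len(members),
                       "members": sorted(members)}
            if gt is not None:
                key = ("covid_cases" if definition.name == "covid19"
                       else definition.name)
                source_eids = gt.get(key, [])
                src_pids = [person_ids[e] for e in source_eids
                            if e in person_ids]
                payload["concordance"] = compare_cohorts(
                    src_pids, members, universe_size=len(person_ids))
            (pout / f"{definition.name}.json").write_text(
                json.dumps(payload, indent=1, sort_keys=True),
                encoding="utf-8")

    checksums = {p.name: _sha256(p) for p in sorted(cdm_paths)}
    for name in ("coverage.csv", "dq.json"):
        checksums[name] = _sha256(out / name)
    manifest = RunManifest(
        config_hash=_config_hash(config), seed=config.seed,
        streams=etl_log.summary(),
        conservation_ok=all(etl_log.conservation_ok().values()),
        row_counts=cdm.row_counts(),
        output_checksums=checksums,
        dq_pass=dq.n_pass, dq_fail=dq.n_fail,
        dq_error_failure=dq.has_error_failure(),
        started_at=started,
        finished_at=datetime.now(timezone.utc).isoformat())
    (out / "manifest.json").write_text(manifest.to_json() + "\n",
                                       encoding="utf-8")
    return manifest
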