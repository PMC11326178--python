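"""End-to-end orchestration: config, staged execution, run manifest.

Stages run in dependency order (io → burden → sets → cluster → annotate →
score → survive), each writing TSV outputs into the run directory; a JSON
manifest records parameters, seeds, per-stage row counts and the sha256
of every output file, so identical config + seed reproduces identical
manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .burden import call_differential, event_zscores, \
    splicing_burden_index
from .cluster_enrich import cluster_enrichment, hierarchical_cluster, \
    select_variable_events
from .cohort_sets import group_set_decomposition, per_patient_normalized_counts, \
    recurrent_events
from .rmats_io import apply_junction_filter, build_psi_matrix, read_clinical, \
    read_rmats_table
from .survival_assoc import km_logrank

logger = logging.getLogger(__name__)

CONFIG_VERSION = 1


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class RunConfig:
    rmats_dir: str
    clinical: str
    out_dir: str
    splice_type: str = "SE"
    min_reads: int = 10
    min_sample_fraction: float = 0.8
    z_threshold: float = 2.0
    sd_floor: float = 0.01
    top_events: int = 5000
    k_clusters: int | None = None
    min_n: int = 2
    endpoint: str = "EFS"
    seed: int = 0
    config_version: int = CONFIG_VERSION

    def validate(self) -> None:
        for name in ("min_reads", "z_threshold", "top_events", "min_n"):
            if getattr(self, name) <= 0 and name != "min_reads":
                raise PipelineError("config", "bad_threshold",
                                    f"{name} must be positive")
        if not Path(self.rmats_dir).is_dir():
            raise PipelineError("config", "missing_input",
                                f"rmats_dir not found: {self.rmats_dir}")
        if not Path(self.clinical).is_file():
            raise PipelineError("config", "missing_input",
                                f"clinical table not found: {self.clinical}")
        if self.endpoint not in ("OS", "EFS"):
            raise PipelineError("config", "bad_endpoint",
                                f"endpoint must be OS or EFS, got {self.endpoint}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(cfg),
        "stages": {},
        "outputs": {},
    }

    def _write(name: str, df: pd.DataFrame, index=False) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=index)
        manifest["outputs"][name] = {"sha256": _sha256(path), "rows": len(df)}

    # --- io ----------------------------------------------------------------
    stage = "io"
    try:
        pattern = f"*.{cfg.splice_type}.MATS.JC.txt"
        files = sorted(Path(cfg.rmats_dir).glob(pattern))
        if not files:
            raise PipelineError(stage, "no_inputs",
                                f"no files matching {pattern} in {cfg.rmats_dir}")
        tables = [
            apply_junction_filter(read_rmats_table(p, cfg.splice_type),
                                  min_reads=cfg.min_reads)
            for p in files
        ]
        matrix = build_psi_matrix(tables, min_sample_fraction=cfg.min_sample_fraction)
        clinical = read_clinical(cfg.clinical)
        matrix.write(out / "psi_matrix.tsv", out / "events.tsv")
        for name in ("psi_matrix.tsv", "events.tsv"):
            manifest["outputs"][name] = {"sha256": _sha256(out / name),
                                         "rows": matrix.n_events}
        manifest["stages"][stage] = {
            "n_samples": matrix.n_samples, "n_events": matrix.n_events,
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, "stage_failed", str(exc)) from exc

    # --- burden ------------------------------------------------------------
    stage = "burden"
    try:
        z = event_zscores(matrix, sd_floor=cfg.sd_floor)
        calls = call_differential(z, threshold=cfg.z_threshold)
        sbi = splicing_burden_index(calls, splice_type=cfg.splice_type)
        _write("sbi.tsv", sbi)
        manifest["stages"][stage] = {
            "n_calls": int((calls.abs() > 0).sum().sum()),
        }
    except Exception as exc:
        raise PipelineError(stage, "stage_failed", str(exc)) from exc

    # --- sets --------------------------------------------------------------
    stage = "sets"
    try:
        groups = clinical.set_index("sample_id")["histology"]
        groups = groups.loc[groups.index.intersection(calls.columns)]
        sets = recurrent_events(calls[groups.index], groups, min_n=cfg.min_n,
                                splice_type=cfg.splice_type)
        if len(sets) >= 2:
            membership, patterns, unique = group_set_decomposition(sets)
            _write("set_membership.tsv", membership.astype(int), index=True)
            _write("set_patterns.tsv", patterns)
            n_pat = groups.value_counts().to_dict()
            norm = per_patient_normalized_counts(sets, n_pat)
            _write("unique_events_per_patient.tsv", norm)
        manifest["stages"][stage] = {
            "n_groups": len(sets),
            "n_recurrent": int(sum(len(s.events) for s in sets)),
        }
    except Exception as exc:
        raise PipelineError(stage, "stage_failed", str(exc)) from exc

    # --- cluster -----------------------------------------------------------
    stage = "cluster"
    try:
        top = select_variable_events(matrix, k_events=cfg.top_events)
        assign = hierarchical_cluster(top, k=cfg.k_clusters)
        _write("clusters.tsv",
               assign.labels.rename("cluster").rename_axis("sample_id").reset_index())
        enrich = cluster_enrichment(assign, groups.reindex(assign.labels.index)
                                    .fillna("unknown"))
        _write("cluster_enrichment.tsv", enrich)
        manifest["stages"][stage] = {"k": assign.k, "n_top_events": top.n_events}
    except Exception as exc:
        raise PipelineError(stage, "stage_failed", str(exc)) from exc

    # --- survive -----------------------------------------------------------
    stage = "survive"
    try:
        surv = clinical.set_index("sample_id").loc[assign.labels.index]
        time_col = "efs_days" if cfg.endpoint == "EFS" else "os_days"
        event_col = "efs_status" if cfg.endpoint == "EFS" else "os_status"
        surv = surv.assign(cluster=assign.labels.astype(str))
        km = km_logrank(surv.reset_index(), time_col, event_col, "cluster")
        km_table = pd.DataFrame({
            "endpoint": [cfg.endpoint], "logrank_p": [km.logrank_p],
            "n_events": [km.n_events],
        })
        _write("km_logrank.tsv", km_table)
        manifest["stages"][stage] = {"logrank_p": km.logrank_p}
    except Exception as exc:
        raise PipelineError(stage, "stage_failed", str(exc)) from exc

    cfg.to_yaml(out / "config.yaml")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
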