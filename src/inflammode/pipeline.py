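"""End-to-end pipeline: synthesize -> fit -> report -> group statistics.

``run_pipeline`` wires the stages together exactly as the library exposes
them, emits every intermediate artifact as CSV/JSON, and writes a
``RunManifest`` recording seeds, config hashes and artifact digests so a
rerun with the same inputs is byte-identical (manifest timestamps aside).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .exceptions import InflammodeError, InvalidInputError
from .model import DoseProtocol
from .params import ModelParameters, read_params, write_params, young_default
from .recalibration import (
    Ensemble,
    FitConfig,
    FitResult,
    fold_change_report,
    sparse_search,
    truth_referenced_threshold,
)
from .stats import holm_sidak, t_from_summary
from .synthetic import (
    MIDDLE_AGED_BEST_OVERLAY,
    default_two_arm_design,
    generate_timecourse,
    make_middle_aged_params,
    summarize,
)

log = logging.getLogger("inflammode.pipeline")


@dataclass
class RunManifest:
    """Traceability record for one pipeline run."""

    seeds: dict
    config_hash: str
    package_version: str = __version__
    digests: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _hash_config(*objs) -> str:
    h = hashlib.sha256()
    for obj in objs:
        h.update(json.dumps(obj, sort_keys=True, default=str).encode())
    return h.hexdigest()


def ensemble_to_dict(ensemble: Ensemble) -> dict:
    return {
        "error_threshold": ensemble.error_threshold,
        "dedup_radius": ensemble.dedup_radius,
        "provenance": ensemble.provenance,
        "report": ensemble.report,
        "members": [
            {
                "changed": m.changed,
                "error": m.error,
                "n_changed": m.n_changed,
                "seed_used": m.seed_used,
                "subset": list(m.subset),
            }
            for m in ensemble.members
        ],
    }


def ensemble_from_dict(doc: dict) -> Ensemble:
    members = [
        FitResult(
            changed=dict(m["changed"]),
            error=float(m["error"]),
            n_changed=int(m["n_changed"]),
            seed_used=int(m.get("seed_used", 0)),
            subset=tuple(m.get("subset", sorted(m["changed"]))),
        )
        for m in doc["members"]
    ]
    return Ensemble(
        members=members,
        error_threshold=float(doc["error_threshold"]),
        dedup_radius=float(doc["dedup_radius"]),
        provenance=doc.get("provenance", {}),
        report=doc.get("report", {}),
    )


def load_design_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise InvalidInputError(f"{path}: design config must be a mapping")
    return doc


def load_fit_config(path, **overrides) -> FitConfig:
    """Read a fit.yaml (mirrors FitConfig field-for-field)."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise InvalidInputError(f"{path}: fit config must be a mapping")
    known = set(FitConfig.__dataclass_fields__)
    unknown = sorted(set(doc) - known)
    if unknown:
        raise InvalidInputError(f"{path}: unknown fit config key(s): {unknown}")
    doc.update(overrides)
    for tup_key in ("fold_bounds", "step_schedule"):
        if tup_key in doc and doc[tup_key] is not None:
            doc[tup_key] = tuple(doc[tup_key])
    if "candidate_params" in doc and doc["candidate_params"] is not None:
        doc["candidate_params"] = tuple(doc["candidate_params"])
    return FitConfig(**doc)


def run_pipeline(design_cfg: dict | None, fit_cfg: FitConfig | None,
                 outdir, seed: int | None = None) -> RunManifest:
    """Execute the full workflow and write artifacts under ``outdir``.

    Stages: load the young parameters; build the synthetic two-age study
    (the middle-aged arm carries the reference overlay); sparse-search the
    middle-aged LPS data; write the fold-change report; summarize groups
    and run the between-age comparisons with multiplicity adjustment.
    Stage failures raise with the stage name attached.
    """
    design_cfg = dict(design_cfg or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    stage = "init"
    try:
        stage = "read_params"
        params_path = design_cfg.get("young_params")
        young = read_params(params_path) if params_path else young_default()

        stage = "design"
        if seed is None:
            seed = int(design_cfg.get("seed", 0))
        overlay = dict(design_cfg.get("overlay", MIDDLE_AGED_BEST_OVERLAY))
        design = default_two_arm_design(
            young,
            overlay=overlay,
            seed=seed,
            noise_cv=float(design_cfg.get("noise_cv", 0.3)),
            n_per_timepoint=int(design_cfg.get("n_per_timepoint", 4)),
        )

        stage = "synth"
        log.info("generating synthetic time courses (seed %d)", seed)
        dataset = generate_timecourse(design)
        dataset_csv = outdir / "timecourse.csv"
        dataset.to_csv(dataset_csv)

        stage = "fit"
        mid_lps = dataset.subset(age="middle-aged", treatment="LPS")
        truth = make_middle_aged_params(young, overlay)
        if fit_cfg is None:
            fit_cfg = FitConfig(seed=seed + 1)
        if fit_cfg.error_threshold is None:
            thr = truth_referenced_threshold(truth, mid_lps)
            fit_cfg = FitConfig(**{**fit_cfg.__dict__, "error_threshold": thr})
        log.info("sparse search (threshold %.3g)", fit_cfg.error_threshold)
        ensemble = sparse_search(young, mid_lps, fit_cfg)
        ensemble_json = outdir / "ensemble.json"
        with open(ensemble_json, "w", encoding="utf-8") as fh:
            json.dump(ensemble_to_dict(ensemble), fh, indent=2, sort_keys=True)
            fh.write("\n")

        stage = "report"
        report_csv = outdir / "fold_changes.csv"
        if ensemble.members:
            fold_change_report(ensemble, young).to_csv(report_csv, index=False)
        else:
            log.warning("empty ensemble: %s", ensemble.report)
            report_csv.write_text(
                "member,parameter,definition,fold,change,error\n")

        stage = "stats"
        at_time = float(design_cfg.get("summary_time_min", 90.0))
        summary = summarize(dataset, at_time=at_time)
        summary_csv = outdir / "group_summary.csv"
        summary.to_csv(summary_csv)
        stats_rows = []
        recs = summary.records
        for (trt, analyte), grp in recs.groupby(["treatment", "analyte"]):
            g = {row["age"]: row for _, row in grp.iterrows()}
            if len(g) != 2:
                continue
            a, b = g["young"], g["middle-aged"]
            res = t_from_summary(a["mean"], a["sem"], a["n"],
                                 b["mean"], b["sem"], b["n"])
            stats_rows.append({
                "treatment": trt, "analyte": analyte,
                "young_mean": a["mean"], "young_sem": a["sem"],
                "middle_aged_mean": b["mean"], "middle_aged_sem": b["sem"],
                "t": res.t, "df": res.df, "p": res.p, "method": res.method,
            })
        import pandas as pd

        stats_df = pd.DataFrame(stats_rows)
        if not stats_df.empty:
            stats_df["p_holm_sidak"] = holm_sidak(stats_df["p"].to_numpy())
        stats_csv = outdir / "group_stats.csv"
        stats_df.to_csv(stats_csv, index=False)

        stage = "params_out"
        params_json = outdir / "young_params.json"
        write_params(young, params_json)

        stage = "manifest"
        artifacts = [dataset_csv, ensemble_json, report_csv, summary_csv,
                     stats_csv, params_json]
        manifest = RunManifest(
            seeds={"design": seed, "fit": fit_cfg.seed},
            config_hash=_hash_config(design_cfg, fit_cfg.__dict__),
            digests={p.name: _sha256(p) for p in artifacts},
            timestamps={"started": t_start, "finished": time.time()},
        )
        manifest.to_json(outdir / "manifest.json")
        return manifest
    except InflammodeError as exc:
        log.error("pipeline failed at stage %r: %s", stage, exc)
        raise InflammodeError(f"stage {stage!r}: {exc}") from exc
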