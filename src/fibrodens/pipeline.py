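"""End-to-end run orchestration: simulate -> densitometry -> score -> efficacy.

A run is described by a :class:`RunConfig` (JSON-serializable).  Each stage
writes one CSV; a :class:`RunManifest` recording the config hash, input
checksums and per-stage outputs is written at the end, so re-running the
same config over the same inputs reproduces identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import glob
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .densitometry import summarize
from .efficacy import (GroupMeasurements, PfCallCriteria, classify_pf,
                       compare_to_vehicle, mortality, pf_incidence,
                       surviving_animals)
from .histology import score_animal
from .image import RIGHT_LUNG, read_mask, read_volume
from .phantom import CohortConfig, generate_cohort

logger = logging.getLogger("fibrodens")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    out_dir: str
    cohort_dir: str = ""            # existing cohort; empty => simulate
    simulate: bool = True
    cohort: CohortConfig = field(default_factory=CohortConfig)
    lung_label: int = RIGHT_LUNG    # irradiated lung analysed by densitometry
    thresholds: tuple[float, ...] = ()
    quantiles: tuple[float, ...] = ()
    pf_criteria: PfCallCriteria = field(default_factory=PfCallCriteria)
    endpoint_week: int = 20
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "cohort" in raw:
            c = dict(raw["cohort"])
            from .phantom import GroupSpec, MixtureParams, StageParams
            if "groups" in c:
                c["groups"] = [GroupSpec(**g) for g in c["groups"]]
            if "mixture" in c:
                c["mixture"] = MixtureParams(**c["mixture"])
            if "grid_shape" in c:
                c["grid_shape"] = tuple(c["grid_shape"])
            if "spacing_mm" in c:
                c["spacing_mm"] = tuple(c["spacing_mm"])
            if "stage_by_group_week" in c:
                c["stage_by_group_week"] = {
                    (k.split("|")[0], int(k.split("|")[1])): StageParams(**v)
                    for k, v in c["stage_by_group_week"].items()}
            raw["cohort"] = CohortConfig(**c)
        if "pf_criteria" in raw:
            raw["pf_criteria"] = PfCallCriteria(**raw["pf_criteria"])
        for key in ("thresholds", "quantiles"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RunManifest:
    """Record of one pipeline run: config hash, inputs, outputs, timing."""

    tool_version: str
    config_hash: str
    seed: int
    input_checksums: dict[str, str]
    outputs: dict[str, str]
    started: str
    finished: str


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, dict):
            return {str(k): v for k, v in o.items()}
        return str(o)
    blob = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def densitometry_table(cohort_dir: str, lung_label: int,
                       thresholds=(), quantiles=()) -> pd.DataFrame:
    """Summarize every ``*_ct.nii.gz`` / ``*_mask.nii.gz`` pair in a cohort
    directory into one row per scan."""
    rows = []
    for vpath in sorted(glob.glob(os.path.join(cohort_dir, "*_ct.nii.gz"))):
        mpath = vpath.replace("_ct.nii.gz", "_mask.nii.gz")
        if not os.path.exists(mpath):
            raise FileNotFoundError(f"mask missing for {vpath}")
        stem = os.path.basename(vpath)[: -len("_ct.nii.gz")]
        animal_id, week = stem.rsplit("_w", 1)
        vol, msk = read_volume(vpath), read_mask(mpath)
        s = summarize(vol, msk, lung_label, thresholds, quantiles)
        row = {"animal_id": animal_id, "week": int(week), "label": lung_label,
               "n_voxels": s.n_voxels, "lung_volume_mm3": s.lung_volume_mm3}
        for t, v in s.v_map.items():
            row[f"V_{t:g}"] = v
        for q, h in s.percentiles.items():
            row[f"HU_{q:g}"] = h
        rows.append(row)
    if not rows:
        raise FileNotFoundError(f"no *_ct.nii.gz volumes found in {cohort_dir!r}")
    return pd.DataFrame(rows)


def score_table(histology: pd.DataFrame) -> pd.DataFrame:
    """Per-animal PF scores from the slide-grade table."""
    rows = []
    for _, r in histology.iterrows():
        s = score_animal((int(r["slide1"]), int(r["slide2"]), int(r["slide3"])))
        rows.append({"animal_id": r["animal_id"], "group": r["group"],
                     "week": int(r["week"]), "total": s.total,
                     "percent_of_max": s.percent_of_max})
    return pd.DataFrame(rows)


def efficacy_table(scores: pd.DataFrame, densito: pd.DataFrame,
                   survival: pd.DataFrame, pairing: dict[str, str],
                   criteria: PfCallCriteria, endpoint_week: int,
                   welch: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drug-vs-matched-vehicle comparisons plus per-group summaries.

    Animals dead before the endpoint are excluded from fibrosis means and
    reported only through the mortality column.
    """
    alive = surviving_animals(survival, endpoint_week)
    end_scores = scores[(scores["week"] == endpoint_week)
                        & scores["animal_id"].isin(alive)]
    end_dens = densito[(densito["week"] == endpoint_week)
                       & densito["animal_id"].isin(alive)]
    merged = end_scores.merge(end_dens[["animal_id", "V_-200"]], on="animal_id",
                              how="left")

    def group_values(group: str, column: str, frame: pd.DataFrame) -> GroupMeasurements:
        sub = frame[frame["group"] == group]
        if sub.empty:
            raise ValueError(f"no endpoint animals in group {group!r}")
        return GroupMeasurements(group=group, values=sub[column].to_numpy(),
                                 animal_ids=tuple(sub["animal_id"]))

    comparisons = []
    for drug, vehicle in pairing.items():
        for readout, column, frame in (("histology_total", "total", end_scores),
                                       ("ct_v200", "V_-200", merged)):
            res = compare_to_vehicle(group_values(drug, column, frame),
                                     group_values(vehicle, column, frame),
                                     welch=welch)
            comparisons.append({
                "drug_group": res.drug_group, "vehicle_group": res.vehicle_group,
                "readout": readout,
                "normalized_mean_percent": res.normalized_mean_percent,
                "attenuation_percent": res.attenuation_percent,
                "t_statistic": res.t_statistic,
                "degrees_of_freedom": res.degrees_of_freedom,
                "p_two_sided": res.p_two_sided,
                "n_drug": res.n_drug, "n_vehicle": res.n_vehicle})

    group_rows = []
    for group in scores["group"].unique():
        sub = merged[merged["group"] == group]
        calls = [classify_pf(r["total"], r["V_-200"], criteria)
                 for _, r in sub.iterrows()] if not sub.empty else []
        group_rows.append({
            "group": group,
            "n_endpoint": len(sub),
            "mean_histology_total": sub["total"].mean() if len(sub) else np.nan,
            "mean_v200": sub["V_-200"].mean() if len(sub) else np.nan,
            "pf_incidence_percent": pf_incidence(calls) if calls else np.nan,
            "mortality_percent": mortality(survival, group, endpoint_week)})
    return pd.DataFrame(comparisons), pd.DataFrame(group_rows)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full pipeline and write all stage CSVs plus the manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s %(message)s")
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    os.makedirs(config.out_dir, exist_ok=True)
    outputs: dict[str, str] = {}

    cohort_dir = config.cohort_dir
    if config.simulate and not cohort_dir:
        stage = "simulate"
        try:
            cohort_dir = os.path.join(config.out_dir, "cohort")
            cohort_cfg = dataclasses.replace(config.cohort, rng_seed=config.seed)
            manifest = generate_cohort(cohort_cfg, cohort_dir)
            logger.info("stage=simulate n_volumes=%d seed=%d",
                        manifest["n_volumes"], config.seed)
            outputs["cohort_manifest"] = os.path.join(cohort_dir, "manifest.json")
        except Exception as exc:
            logger.error("stage=%s error=%s", stage, exc)
            raise StageError(stage, str(exc)) from exc
    elif not cohort_dir:
        raise StageError("simulate", "no cohort_dir given and simulate disabled")

    stage = "densitometry"
    try:
        dens = densitometry_table(cohort_dir, config.lung_label,
                                  config.thresholds, config.quantiles)
        dens_path = os.path.join(config.out_dir, "summary.csv")
        dens.to_csv(dens_path, index=False, float_format="%.6g")
        outputs["summary"] = dens_path
        logger.info("stage=densitometry n_scans=%d", len(dens))
    except Exception as exc:
        logger.error("stage=%s error=%s", stage, exc)
        raise StageError(stage, str(exc)) from exc

    stage = "score"
    try:
        histology = pd.read_csv(os.path.join(cohort_dir, "histology.csv"))
        scores = score_table(histology)
        scores_path = os.path.join(config.out_dir, "scores.csv")
        scores.to_csv(scores_path, index=False, float_format="%.6g")
        outputs["scores"] = scores_path
        logger.info("stage=score n_animals=%d", len(scores))
    except Exception as exc:
        logger.error("stage=%s error=%s", stage, exc)
        raise StageError(stage, str(exc)) from exc

    stage = "efficacy"
    try:
        survival = pd.read_csv(os.path.join(cohort_dir, "survival.csv"))
        with open(os.path.join(cohort_dir, "pairing.json")) as fh:
            pairing = json.load(fh)
        comp, groups = efficacy_table(scores, dens, survival, pairing,
                                      config.pf_criteria, config.endpoint_week)
        eff_path = os.path.join(config.out_dir, "efficacy.csv")
        grp_path = os.path.join(config.out_dir, "groups.csv")
        comp.to_csv(eff_path, index=False, float_format="%.6g")
        groups.to_csv(grp_path, index=False, float_format="%.6g")
        outputs["efficacy"] = eff_path
        outputs["groups"] = grp_path
        logger.info("stage=efficacy n_comparisons=%d", len(comp))
    except Exception as exc:
        logger.error("stage=%s error=%s", stage, exc)
        raise StageError(stage, str(exc)) from exc

    checksums = {}
    for name in ("histology.csv", "survival.csv", "timecourse.csv", "pairing.json"):
        p = os.path.join(cohort_dir, name)
        if os.path.exists(p):
            checksums[name] = _sha256(p)

    manifest = RunManifest(
        tool_version=__version__, config_hash=_config_hash(config),
        seed=config.seed, input_checksums=checksums, outputs=outputs,
        started=started, finished=time.strftime("%Y-%m-%dT%H:%M:%S"))
    man_path = os.path.join(config.out_dir, "manifest.json")
    tmp = man_path + ".tmp"
    with open(tmp, "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2)
    os.replace(tmp, man_path)  # atomic finalize
    return manifest
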