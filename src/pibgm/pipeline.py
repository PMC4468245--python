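"""End-to-end orchestration: phantom or files -> preprocess -> threshold ->
segment -> quantify -> diagnose, with JSON/CSV/NIfTI artifacts.

The per-patient pipeline follows the acquisition-analysis order: PET
upsampling onto the CT grid, PET-driven bed removal, two-Gaussian histogram
auto-thresholding, threshold-augmented Chan-Vese bone segmentation,
cortex/marrow labeling, SUV computation under the three normalizations, and
the PIBGM profile over the SUV-cutoff grid.  The cohort driver repeats this
per patient, assembles the tidy biomarker table, and applies the DANP sweep
and ROC analysis.

Everything is deterministic under a fixed config + seed; each report embeds
a config hash and the package version for provenance.  Volumes are exchanged
as NIfTI with JSON sidecars (units, patient metadata); DICOM ingestion is
out of scope.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .autothreshold import (ThresholdParams, build_histogram, compute_threshold,
                            fit_two_gaussians)
from .cvseg import (CVParams, segment_bone_volume, split_cortex_marrow,
                    transfer_mask_to_pet)
from .diagnostics import (CohortTable, DiagnosticReport, ROCCurve, danp_sweep,
                          roc_auc, sweep_frame)
from .errors import ConfigError, PibgmError, StageError
from .phantom import PhantomCase, PhantomSpec, BedSpec, make_cohort, make_phantom, write_case
from .preprocess import (BedRemovalParams, body_mask_from_pet, remove_bed,
                         upsample_pet_replicate, upsample_pet_trilinear)
from .quantify import (SUV_MODES, PatientMeta, pibgm_profile, region_suv_stats,
                       suv_map)
from .volume import (RegionMask, Volume3D, read_mask, read_volume, write_volume)

log = logging.getLogger("pibgm")


@dataclass
class PipelineConfig:
    """Complete, serializable parameterization of a run.

    Input is either a phantom spec (synthetic patient) or CT/PET NIfTI paths
    with a patient-metadata JSON.  Every stage parameter has a default; the
    config round-trips losslessly through JSON.
    """

    phantom: PhantomSpec | None = field(default_factory=PhantomSpec)
    ct_path: str | None = None
    pet_path: str | None = None
    meta_path: str | None = None
    upsample: str = "replicate"          # replicate | trilinear
    bed: BedRemovalParams = field(default_factory=BedRemovalParams)
    threshold: ThresholdParams = field(default_factory=ThresholdParams)
    cv: CVParams = field(default_factory=CVParams)
    split_mode: str = "otsu"
    t_grid: tuple[float, float, float] = (0.4, 0.2, 2.2)  # start, step, stop
    danp: float = 0.95
    region: str = "cortex"
    mode: str = "bw"
    decision_t: float = 1.2              # SUV cutoff of the decision biomarker
    seed: int = 0
    out_dir: str | None = None
    log_level: str = "INFO"

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("phantom") is not None:
            ph = dict(d["phantom"])
            ph["grid_shape"] = tuple(ph["grid_shape"])
            ph["voxel_spacing"] = tuple(ph["voxel_spacing"])
            ph["bed"] = BedSpec(**ph["bed"])
            ph["meta"] = PatientMeta(**ph["meta"])
            ph["lesion_spec"] = [tuple(l) for l in ph.get("lesion_spec", [])]
            d["phantom"] = PhantomSpec(**ph)
        if isinstance(d.get("bed"), dict):
            d["bed"] = BedRemovalParams(**d["bed"])
        if isinstance(d.get("threshold"), dict):
            th = dict(d["threshold"])
            th["hu_range"] = tuple(th["hu_range"])
            d["threshold"] = ThresholdParams(**th)
        if isinstance(d.get("cv"), dict):
            d["cv"] = CVParams(**d["cv"])
        d["t_grid"] = tuple(d["t_grid"])
        return cls(**d)

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def t_values(self) -> np.ndarray:
        start, step, stop = self.t_grid
        if step <= 0 or stop < start:
            raise ConfigError(f"bad t_grid {self.t_grid}: need start<=stop, step>0")
        return np.round(np.arange(start, stop + step / 2, step), 10)


@dataclass
class PatientReport:
    """Numerical per-patient result plus provenance."""

    patient_id: str
    group: str
    counts: dict
    histogram_fit: dict
    bone_threshold_hu: float
    suv_stats: dict          # mode -> list of {region, mean, sd, n}
    pibgm: dict              # region -> list of {t, value, n_t, n_b}
    provenance: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def numeric_content(self) -> dict:
        """Report content excluding volatile provenance (timestamps)."""
        d = self.to_dict()
        d["provenance"] = {k: v for k, v in d["provenance"].items()
                           if k != "timestamp"}
        return d


def _stage(name):
    """Decorator-ish helper: run fn, wrap domain errors with the stage name."""
    class _Ctx:
        def __init__(self):
            self.t0 = time.perf_counter()

        def __enter__(self):
            log.debug("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage %s: done in %.3fs", name, dt)
                return False
            if isinstance(exc, PibgmError) and not isinstance(exc, StageError):
                raise StageError(name, str(exc), cause=exc) from exc
            return False
    return _Ctx()


def check_coregistration(ct: Volume3D, pet: Volume3D, atol: float = 1e-3) -> None:
    """Refuse volumes whose affines disagree beyond tolerance."""
    if ct.shape != pet.shape:
        raise ConfigError(
            f"CT and PET grids differ after upsampling: {ct.shape} vs {pet.shape}")
    if not np.allclose(ct.affine, pet.affine, atol=atol):
        raise ConfigError(
            "CT and PET affines disagree beyond tolerance:\n"
            f"CT affine:\n{ct.affine}\nPET affine:\n{pet.affine}")


def load_inputs(config: PipelineConfig):
    """Resolve the configured input into (ct, pet, meta, group, truth|None)."""
    if config.ct_path or config.pet_path:
        if not (config.ct_path and config.pet_path and config.meta_path):
            raise ConfigError("file input needs ct_path, pet_path and meta_path")
        ct = read_volume(config.ct_path)
        pet = read_volume(config.pet_path)
        meta = PatientMeta.from_dict(json.loads(Path(config.meta_path).read_text()))
        return ct, pet, meta, "normal", None
    if config.phantom is None:
        raise ConfigError("config has neither file paths nor a phantom spec")
    case = make_phantom(config.phantom)
    pet = case.pet_lowres if case.pet_lowres is not None else case.pet
    return case.ct, pet, case.meta, case.group_label, case


def analyze_case(ct: Volume3D, pet: Volume3D, meta: PatientMeta,
                 config: PipelineConfig, patient_id: str | None = None,
                 group: str = "normal") -> tuple[PatientReport, dict]:
    """Run the full per-patient analysis; returns (report, artifacts).

    ``artifacts`` maps names to in-memory objects (masks, SUV maps) so
    callers and the CLI can write whichever they need.
    """
    with _stage("upsample"):
        if pet.shape != ct.shape:
            if config.upsample == "replicate":
                pet = upsample_pet_replicate(pet, ct.shape[1])
            elif config.upsample == "trilinear":
                pet = upsample_pet_trilinear(pet, ct.shape)
            else:
                raise ConfigError(f"unknown upsample mode {config.upsample!r}")
        check_coregistration(ct, pet)

    with _stage("bed_removal"):
        body = body_mask_from_pet(pet, config.bed)
        ct_clean = remove_bed(ct, body, config.bed.background_fill)

    with _stage("auto_threshold"):
        edges, counts = build_histogram(ct_clean, body, config.threshold.n_bins,
                                        config.threshold.hu_range)
        fit = fit_two_gaussians(edges, counts, config.threshold)
        thr = compute_threshold(fit, config.threshold.omega)

    with _stage("bone_segmentation"):
        bone = segment_bone_volume(ct_clean, body, thr, config.cv)
        labels = split_cortex_marrow(ct_clean, bone, config.split_mode)

    with _stage("quantify"):
        suv_stats: dict = {}
        suv_maps: dict = {}
        for mode in SUV_MODES:
            suv = suv_map(pet, meta, mode)
            suv_maps[mode] = suv
            suv_stats[mode] = region_suv_stats(suv, labels).to_dict("records")
        t_grid = config.t_values()
        profiles = {
            region: [{"t": r.t, "value": r.value, "n_t": r.n_t, "n_b": r.n_b}
                     for r in pibgm_profile(suv_maps[config.mode], labels,
                                            region, t_grid)]
            for region in ("whole_bone", "marrow", "cortex")
        }

    report = PatientReport(
        patient_id=meta.id if patient_id is None else patient_id,
        group=group,
        counts={"body": int(body.as_bool().sum()),
                "bone": labels.count("whole_bone"),
                "marrow": labels.count("marrow"),
                "cortex": labels.count("cortex")},
        histogram_fit={"A_m": fit.A_m, "B_m": fit.B_m, "c_m": fit.c_m,
                       "A_f": fit.A_f, "B_f": fit.B_f, "c_f": fit.c_f,
                       "residual_norm": fit.residual_norm},
        bone_threshold_hu=float(thr),
        suv_stats=suv_stats,
        pibgm=profiles,
        provenance={"config_hash": config.config_hash(),
                    "version": __version__,
                    "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")},
    )
    artifacts = {"body": body, "ct_clean": ct_clean, "bone": bone,
                 "labels": labels, "suv": suv_maps,
                 "pet_values": transfer_mask_to_pet(labels, pet)}
    return report, artifacts


def run_patient(config: PipelineConfig) -> PatientReport:
    """Execute all stages for one configured patient; write artifacts."""
    ct, pet, meta, group, _case = load_inputs(config)
    report, artifacts = analyze_case(ct, pet, meta, config, group=group)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_volume(artifacts["labels"], out / "bone_labels.nii.gz")
        write_volume(artifacts["suv"][config.mode].volume,
                     out / f"suv_{config.mode}.nii.gz")
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=1))
        config.to_json(out / "config.json")
    return report


@dataclass
class CohortResult:
    """Everything a cohort run produces."""

    table: CohortTable
    patient_reports: list[PatientReport]
    sweep: list[DiagnosticReport]
    roc: ROCCurve
    decision: DiagnosticReport


def run_cohort(config: PipelineConfig, n_per_group: dict,
               effect: dict | None = None, between_sd: float = 0.12) -> CohortResult:
    """Generate a phantom cohort, analyze every patient, and diagnose.

    The decision biomarker is (config.region, config.mode, config.decision_t);
    the sweep covers the whole t grid at the configured DANP.
    """
    if config.phantom is None:
        raise ConfigError("run_cohort needs a phantom spec as cohort template")
    groups_present = {g for g, n in n_per_group.items() if n > 0}
    if len(groups_present) < 2:
        raise ConfigError("run_cohort needs at least two groups with patients")
    cases = make_cohort(n_per_group, effect=effect, seed=config.seed,
                        base_spec=config.phantom, between_sd=between_sd)
    reports, records = [], []
    for case in cases:
        pet = case.pet_lowres if case.pet_lowres is not None else case.pet
        try:
            rep, _ = analyze_case(case.ct, pet, case.meta, config,
                                  group=case.group_label)
        except PibgmError as exc:
            raise StageError("cohort", f"patient {case.meta.id}: {exc}",
                             cause=exc) from exc
        reports.append(rep)
        for region, profile in rep.pibgm.items():
            records.append((rep.patient_id, rep.group, region, config.mode,
                            {p["t"]: p["value"] for p in profile}))
    table = CohortTable.from_profiles(records)
    sweep = danp_sweep(table, danp_grid=(config.danp,),
                       t_grid=config.t_values(), region=config.region,
                       mode=config.mode)
    decision = next(r for r in sweep if np.isclose(r.t, config.decision_t))
    bio = table.biomarker(config.region, config.mode, config.decision_t)
    roc = roc_auc(bio["value"].to_numpy(), bio["group"].to_numpy() != "normal")

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.frame.to_csv(out / "cohort_biomarkers.csv", index=False)
        sweep_frame(sweep).to_csv(out / "danp_sweep.csv", index=False)
        pd.DataFrame(roc.points, columns=["fpr", "tpr"]).to_csv(
            out / "roc_points.csv", index=False)
        summary = {
            "auc": roc.auc, "grade": roc.grade,
            "decision": dataclasses.asdict(decision),
            "n_per_group": {g: int(n) for g, n in n_per_group.items()},
            "config_hash": config.config_hash(),
        }
        (out / "cohort_report.json").write_text(json.dumps(summary, indent=1))
    return CohortResult(table=table, patient_reports=reports, sweep=sweep,
                        roc=roc, decision=decision)
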