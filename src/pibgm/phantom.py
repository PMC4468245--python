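"""Synthetic co-registered CT/PET phantoms with ground truth.

The phantom is a stylized torso: stacked identical ellipses forming an
elliptical cylinder of fat enclosing muscle enclosing a bone ring (cortex)
with a marrow core, surrounded by air, with an optional scanner-bed arc below
the body.  Geometry is deliberately non-anatomical: the downstream algorithms
are intensity-driven (histogram thresholding, region-competition contours,
SUV statistics), so what matters is that the tissue intensity populations,
their spatial nesting, and the bed artifact are realistic, not the shapes.

CT values are Hounsfield units drawn per tissue as mean + Gaussian noise
(air -1000, fat -100, muscle 40, marrow 150, cortex 700, bed 300 by default).
PET activity is set so that each tissue's voxel SUV_bw equals a prescribed
baseline uptake given the patient metadata (activity = uptake * dose/weight,
unit-consistent), plus optional in-body Gaussian noise and focal lesions.

All randomness flows from a single seeded generator: identical spec + seed
gives byte-identical volumes.  Cohorts add group-level cortex-uptake uplifts
(FUO etiologies run hotter than normals) and per-patient variability.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .quantify import G_PER_KG, PatientMeta
from .volume import CORTEX, MARROW, RegionMask, Volume3D, write_volume

GROUPS = ("normal", "inflammatory", "infection", "neoplasm")

#: Internal tissue codes in the generated label volume.
_AIR, _FAT, _MUSCLE, _MARROW, _CORTEX, _BED = 0, 1, 2, 3, 4, 5

DEFAULT_TISSUE_MEANS = {"fat": -100.0, "muscle": 40.0, "marrow": 150.0, "cortex": 700.0}
DEFAULT_TISSUE_SDS = {"fat": 15.0, "muscle": 15.0, "marrow": 20.0, "cortex": 30.0}
#: Baseline per-tissue SUV_bw for a normal subject.  Marrow runs hotter than
#: cortex (hematopoietic glycolysis); soft tissues sit well below bone.
DEFAULT_PET_UPTAKE = {"fat": 0.3, "muscle": 0.5, "marrow": 0.93, "cortex": 0.86}
#: Group-level cortex uplifts for cohorts: FUO etiologies above normal.
DEFAULT_CORTEX_EFFECT = {"normal": 0.0, "inflammatory": 0.20,
                         "infection": 0.17, "neoplasm": 0.23}

AIR_HU = -1000.0


@dataclass
class BedSpec:
    """Scanner-bed arc: an elliptical annulus segment below the body."""

    enabled: bool = True
    hu: float = 300.0
    inner_scale: float = 1.45   # of body semi-axes
    outer_scale: float = 1.58
    half_angle_deg: float = 55.0  # around straight-down


@dataclass
class PhantomSpec:
    """Full description of one synthetic patient."""

    grid_shape: tuple[int, int, int] = (16, 64, 64)
    voxel_spacing: tuple[float, float, float] = (5.0, 4.0, 4.0)
    body_radius_frac: float = 0.42
    tissue_means: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_MEANS))
    tissue_sds: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_SDS))
    bed: BedSpec = field(default_factory=BedSpec)
    pet_uptake: dict = field(default_factory=lambda: dict(DEFAULT_PET_UPTAKE))
    pet_noise_sd: float = 0.05          # SUV units, inside the body only
    cortex_frac: float = 0.5            # fraction of bone volume that is cortex
    muscle_scale: float = 0.82          # of body semi-axes
    bone_scale: float = 0.50            # of body semi-axes (cortex outer wall)
    lesion_spec: list = field(default_factory=list)  # (region, multiplier, frac)
    meta: PatientMeta = field(default_factory=lambda: PatientMeta(370.0, 70.0, 170.0))
    pet_lowres: bool = False            # also emit a block-averaged coarse PET
    seed: int = 0

    def validate(self) -> None:
        if any(int(n) < 16 for n in self.grid_shape):
            raise ConfigError(f"grid_shape axes must all be >= 16, got {self.grid_shape}")
        m = self.tissue_means
        if not (m["fat"] < m["muscle"] < m["marrow"] < m["cortex"]):
            raise ConfigError(
                "tissue_means must be ordered fat < muscle < marrow < cortex, "
                f"got {m}"
            )
        if not 0.0 < self.body_radius_frac < 1.0:
            raise ConfigError("body_radius_frac must be in (0,1)")
        if not 0.0 <= self.cortex_frac <= 1.0:
            raise ConfigError("cortex_frac must be in [0,1]")
        for region, mult, frac in self.lesion_spec:
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"lesion volume fraction must be in [0,1], got {frac}")
            if region not in ("marrow", "cortex"):
                raise ConfigError(f"lesion region must be marrow or cortex, got {region!r}")
        if self.pet_noise_sd < 0 or any(s < 0 for s in self.tissue_sds.values()):
            raise ConfigError("noise standard deviations must be non-negative")
        # PatientMeta validates dose/weight/height on construction.


@dataclass
class PhantomCase:
    """One generated patient: volumes, ground truth, and metadata."""

    ct: Volume3D
    pet: Volume3D
    truth_body: RegionMask
    truth_bone: RegionMask
    meta: PatientMeta
    group_label: str = "normal"
    pet_lowres: Volume3D | None = None
    spec: PhantomSpec | None = None


def _tissue_labels(spec: PhantomSpec) -> np.ndarray:
    """2D tissue label map replicated over slices -> 3D int array."""
    _, n_row, n_col = (int(n) for n in spec.grid_shape)
    rr, cc = np.meshgrid(np.arange(n_row), np.arange(n_col), indexing="ij")
    cr, ccen = (n_row - 1) / 2.0, (n_col - 1) / 2.0
    a = spec.body_radius_frac * n_row / 2.0
    b = min(1.25 * spec.body_radius_frac, 0.95) * n_col / 2.0

    def inside(scale_a, scale_b):
        return ((rr - cr) / (a * scale_a)) ** 2 + ((cc - ccen) / (b * scale_b)) ** 2 <= 1.0

    body = inside(1.0, 1.0)
    muscle = inside(spec.muscle_scale, spec.muscle_scale)
    bone = inside(spec.bone_scale, spec.bone_scale)
    marrow_scale = spec.bone_scale * np.sqrt(max(0.0, 1.0 - spec.cortex_frac))
    marrow = inside(marrow_scale, marrow_scale) if marrow_scale > 0 else np.zeros_like(body)

    lab = np.zeros((n_row, n_col), dtype=np.int16)
    lab[body] = _FAT
    lab[muscle] = _MUSCLE
    lab[bone] = _CORTEX
    lab[marrow] = _MARROW

    if spec.bed.enabled:
        u, v = (rr - cr) / a, (cc - ccen) / b
        rho = np.hypot(u, v)
        theta = np.degrees(np.arctan2(np.abs(v), u))  # 0 deg = straight down
        arc = ((rho >= spec.bed.inner_scale) & (rho <= spec.bed.outer_scale)
               & (theta <= spec.bed.half_angle_deg) & ~body)
        lab[arc] = _BED

    n_slice = int(spec.grid_shape[0])
    return np.repeat(lab[None, :, :], n_slice, axis=0)


def _apply_lesions(spec: PhantomSpec, labels3d: np.ndarray,
                   uptake: np.ndarray, rng: np.random.Generator) -> None:
    """Multiply uptake inside compact blobs occupying a fraction of a region."""
    code = {"marrow": _MARROW, "cortex": _CORTEX}
    for region, mult, frac in spec.lesion_spec:
        sel = np.argwhere(labels3d == code[region])
        if len(sel) == 0 or frac == 0.0:
            continue
        n_target = max(1, int(round(frac * len(sel))))
        centre = sel[rng.integers(len(sel))]
        d2 = np.sum((sel - centre) ** 2, axis=1)
        chosen = sel[np.argsort(d2, kind="stable")[:n_target]]
        uptake[tuple(chosen.T)] *= mult


def make_phantom(spec: PhantomSpec) -> PhantomCase:
    """Generate one co-registered CT/PET phantom with exact truth masks."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    labels = _tissue_labels(spec)

    # --- CT (HU) --------------------------------------------------------
    ct = np.full(labels.shape, AIR_HU, dtype=float)
    for name, code in (("fat", _FAT), ("muscle", _MUSCLE),
                       ("marrow", _MARROW), ("cortex", _CORTEX)):
        sel = labels == code
        mean, sd = spec.tissue_means[name], spec.tissue_sds.get(name, 0.0)
        vals = np.full(int(sel.sum()), mean)
        if sd > 0:
            vals = vals + rng.normal(0.0, sd, size=vals.shape)
        ct[sel] = vals
    ct[labels == _BED] = spec.bed.hu

    # --- PET (Bq/mL); voxel SUV_bw == prescribed uptake -----------------
    suv_to_bq = (spec.meta.injected_dose_mbq
                 / (spec.meta.body_weight_kg * G_PER_KG)) * 1e6
    uptake = np.zeros(labels.shape, dtype=float)
    for name, code in (("fat", _FAT), ("muscle", _MUSCLE),
                       ("marrow", _MARROW), ("cortex", _CORTEX)):
        uptake[labels == code] = spec.pet_uptake[name]
    _apply_lesions(spec, labels, uptake, rng)
    if spec.pet_noise_sd > 0:
        body_sel = (labels >= _FAT) & (labels <= _CORTEX)
        noise = rng.normal(0.0, spec.pet_noise_sd, size=int(body_sel.sum()))
        uptake[body_sel] = np.maximum(uptake[body_sel] + noise, 0.0)
    pet = uptake * suv_to_bq

    spacing = tuple(float(s) for s in spec.voxel_spacing)
    ct_vol = Volume3D(ct, spacing, "HU")
    pet_vol = Volume3D(pet, spacing, "Bq/mL")

    body_mask = ((labels >= _FAT) & (labels <= _CORTEX)).astype(np.int16)
    bone = np.zeros(labels.shape, dtype=np.int16)
    bone[labels == _MARROW] = MARROW
    bone[labels == _CORTEX] = CORTEX

    lowres = _block_average_pet(pet_vol) if spec.pet_lowres else None
    return PhantomCase(
        ct=ct_vol, pet=pet_vol,
        truth_body=RegionMask.like(ct_vol, body_mask),
        truth_bone=RegionMask.like(ct_vol, bone),
        meta=spec.meta, pet_lowres=lowres, spec=spec,
    )


def _block_average_pet(pet: Volume3D) -> Volume3D:
    """Coarse PET on a grid/3 in-plane lattice by 3x3 block averaging.

    The low-res size s is the largest with 3s <= n and n - 3s even, so the
    replicate-upsampling contract (3x blocks + equal zero border) holds
    exactly on the way back up.
    """
    ns, nr, nc = pet.shape
    if nr != nc:
        raise ConfigError("low-res PET generation expects square in-plane grids")
    s = nr // 3
    if (nr - 3 * s) % 2 != 0:
        s -= 1
    if s < 1:
        raise ConfigError("grid too small for low-res PET")
    pad = (nr - 3 * s) // 2
    core = pet.data[:, pad:pad + 3 * s, pad:pad + 3 * s]
    coarse = core.reshape(ns, s, 3, s, 3).mean(axis=(2, 4))
    spacing = (pet.spacing[0], pet.spacing[1] * 3, pet.spacing[2] * 3)
    # coarse voxel j covers fine voxels pad+3j .. pad+3j+2; its centre sits at
    # fine index pad+3j+1, so the coarse origin is offset accordingly and the
    # replicate-upsampled volume lands back on the CT grid exactly.
    affine = np.asarray(pet.affine, dtype=float).copy()
    affine[1, 1], affine[2, 2] = spacing[1], spacing[2]
    affine[1, 3] = pet.affine[1, 3] + pet.spacing[1] * (pad + 1)
    affine[2, 3] = pet.affine[2, 3] + pet.spacing[2] * (pad + 1)
    return Volume3D(coarse, spacing, "Bq/mL", affine)


def make_cohort(n_per_group: dict, effect: dict | None = None, seed: int = 0,
                base_spec: PhantomSpec | None = None,
                between_sd: float = 0.12) -> list[PhantomCase]:
    """Generate a cohort with group-level cortex-uptake structure.

    Parameters
    ----------
    n_per_group : mapping group -> count (groups from :data:`GROUPS`).
    effect : mapping group -> cortex SUV uplift added to the baseline uptake
        (default patterned on normal-vs-FUO cortex differences).
    between_sd : SD of the per-patient random cortex-uptake deviation (SUV).
    """
    effect = dict(DEFAULT_CORTEX_EFFECT) if effect is None else dict(effect)
    base = base_spec if base_spec is not None else PhantomSpec()
    for g, n in n_per_group.items():
        if g not in GROUPS:
            raise ConfigError(f"unknown group {g!r}; expected one of {GROUPS}")
        if n < 0:
            raise ConfigError("group counts must be >= 0")
    if any(v < 0 for v in effect.values()):
        raise ConfigError("cortex uplifts must be >= 0")
    if between_sd < 0:
        raise ConfigError("between_sd must be >= 0")

    rng = np.random.default_rng(seed)
    cases: list[PhantomCase] = []
    idx = 0
    for group in GROUPS:  # fixed order for determinism
        for _ in range(int(n_per_group.get(group, 0))):
            spec = copy.deepcopy(base)
            spec.seed = int(rng.integers(0, 2**31 - 1))
            jitter = rng.normal(0.0, between_sd) if between_sd > 0 else 0.0
            spec.pet_uptake = dict(spec.pet_uptake)
            spec.pet_uptake["cortex"] = max(
                0.01, spec.pet_uptake["cortex"] + effect.get(group, 0.0) + jitter)
            spec.meta = PatientMeta(
                injected_dose_mbq=base.meta.injected_dose_mbq,
                body_weight_kg=base.meta.body_weight_kg,
                body_height_cm=base.meta.body_height_cm,
                sex=base.meta.sex, id=f"{group}-{idx:03d}",
            )
            case = make_phantom(spec)
            case.group_label = group
            cases.append(case)
            idx += 1
    return cases


#: Group-level locations of the per-patient SUV distribution used by the
#: profile cohort: FUO etiologies sit above normals.
DEFAULT_PROFILE_LOC = {"normal": 0.90, "inflammatory": 1.25,
                       "infection": 1.15, "neoplasm": 1.30}


def make_profile_cohort(n_per_group: dict, t_grid=None, seed: int = 0,
                        region: str = "cortex", mode: str = "bw",
                        group_loc: dict | None = None,
                        between_spread: float = 0.15,
                        within_spread: float = 0.30):
    """Per-patient PIBGM profiles drawn from continuous distributions.

    A cheap stand-in for running the imaging chain on a whole cohort: each
    patient's bone-SUV population is modelled as lognormal with a
    patient-level median (group location x a lognormal patient effect), and
    the PIBGM profile is its survival function evaluated on the SUV-cutoff
    grid -- monotone non-increasing in t and continuous, so all patients'
    values at any t are distinct almost surely.

    Returns records ``(patient_id, group, region, mode, {t: value})`` ready
    for ``CohortTable.from_profiles``.
    """
    from scipy.stats import norm  # local: keep module import light

    t_grid = (np.round(np.arange(0.4, 2.2 + 1e-9, 0.2), 10)
              if t_grid is None else np.asarray(t_grid, dtype=float))
    loc = dict(DEFAULT_PROFILE_LOC) if group_loc is None else dict(group_loc)
    rng = np.random.default_rng(seed)
    records = []
    idx = 0
    for group in GROUPS:
        for _ in range(int(n_per_group.get(group, 0))):
            mu = np.log(loc[group]) + rng.normal(0.0, between_spread)
            sigma = abs(rng.normal(within_spread, 0.05)) + 1e-3
            profile = {float(t): float(norm.sf((np.log(t) - mu) / sigma))
                       for t in t_grid}
            records.append((f"{group}-{idx:03d}", group, region, mode, profile))
            idx += 1
    return records


def write_case(case: PhantomCase, out_dir) -> dict:
    """Write a phantom case as NIfTI volumes + a JSON metadata sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ct": write_volume(case.ct, out / "ct.nii.gz"),
        "pet": write_volume(case.pet, out / "pet.nii.gz",
                            extra_meta={"patient": case.meta.to_dict(),
                                        "group": case.group_label}),
        "truth_body": write_volume(case.truth_body, out / "truth_body.nii.gz"),
        "truth_bone": write_volume(case.truth_bone, out / "truth_bone.nii.gz"),
    }
    if case.pet_lowres is not None:
        paths["pet_lowres"] = write_volume(case.pet_lowres, out / "pet_lowres.nii.gz")
    return {k: str(v) for k, v in paths.items()}
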