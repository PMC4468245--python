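"""SUV normalization and the PIBGM biomarker.

The standardized uptake value (SUV) divides the decay-corrected tissue
activity concentration by the injected dose per unit of a body-size
normalizer:

* ``bw``  -- body weight in grams (the classic SUV),
* ``bsa`` -- body surface area (DuBois: 0.007184 * w^0.425 * h^0.725),
* ``lbm`` -- lean body mass (James: 1.07w - 148(w/h)^2 female,
  1.1w - 120(w/h)^2 male).

:func:`bsa` and :func:`lbm` return m^2 and kg.  Inside :func:`suv_map` the
mass normalizers are expressed in grams and BSA in cm^2 so that the three SUV
flavours live on the magnitudes clinical cohorts report (SUV_lbm a bit below
SUV_bw, SUV_bsa roughly a quarter of it); the tissue concentration is taken in
MBq/mL.  PET voxel values are assumed to be decay-corrected activity
concentration as exported by the scanner; no further decay correction is
applied.

PIBGM (PET Index of Bone Glucose Metabolism) is the fraction of bone voxels
whose SUV strictly exceeds a cutoff ``t``:

    PIBGM(t) = N_t / N_b,   N_t = #{i in bone : P_i > t},  N_b = #bone voxels.

It generalizes the bone scan index from planar scintigraphy to volumetric
PET.  ``t`` is swept over a grid (default 0.4 to 2.2 in steps of 0.2) and the
profile is non-increasing in ``t`` by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyRegionError
from .volume import RegionMask, Volume3D, check_same_grid

MBQ_PER_BQ = 1e-6
G_PER_KG = 1000.0
CM2_PER_M2 = 1e4

SUV_MODES = ("bw", "bsa", "lbm")


@dataclass(frozen=True)
class PatientMeta:
    """Acquisition metadata needed for SUV computation."""

    injected_dose_mbq: float
    body_weight_kg: float
    body_height_cm: float
    sex: str = "female"
    id: str = "anonymous"

    def __post_init__(self):
        if self.injected_dose_mbq <= 0:
            raise ConfigError("injected dose must be positive")
        if self.body_weight_kg <= 0 or self.body_height_cm <= 0:
            raise ConfigError("body weight and height must be positive")
        if self.sex not in ("female", "male"):
            raise ConfigError(f"sex must be 'female' or 'male', got {self.sex!r}")

    def to_dict(self) -> dict:
        return {
            "injected_dose_mbq": self.injected_dose_mbq,
            "body_weight_kg": self.body_weight_kg,
            "body_height_cm": self.body_height_cm,
            "sex": self.sex,
            "id": self.id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PatientMeta":
        return cls(**d)


def bsa(weight_kg: float, height_cm: float) -> float:
    """Body surface area in m^2 (DuBois & DuBois power law)."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ConfigError("bsa: weight and height must be positive")
    return 0.007184 * weight_kg**0.425 * height_cm**0.725


def lbm(weight_kg: float, height_cm: float, sex: str) -> float:
    """Lean body mass in kg (James formulas, sex-specific).

    The quadratic term makes the formula invalid for extreme weight/height
    ratios; a non-positive result is rejected rather than propagated.
    """
    if weight_kg <= 0 or height_cm <= 0:
        raise ConfigError("lbm: weight and height must be positive")
    r = weight_kg / height_cm
    if sex == "female":
        value = 1.07 * weight_kg - 148.0 * r * r
    elif sex == "male":
        value = 1.1 * weight_kg - 120.0 * r * r
    else:
        raise ConfigError(f"sex must be 'female' or 'male', got {sex!r}")
    if value <= 0:
        raise ConfigError(
            f"lbm formula out of validity range: got {value:.3f} kg for "
            f"weight={weight_kg} kg, height={height_cm} cm"
        )
    return value


@dataclass
class SUVMap:
    """A PET volume converted to SUV under one normalization mode."""

    volume: Volume3D
    mode: str
    meta: PatientMeta


def suv_map(pet: Volume3D, meta: PatientMeta, mode: str = "bw") -> SUVMap:
    """Convert an activity-concentration PET volume (Bq/mL) to SUV.

    SUV = concentration(MBq/mL) / (dose(MBq) / normalizer), with the
    normalizer in grams (bw, lbm) or cm^2 (bsa).  Linear in the PET values
    and inversely linear in the injected dose.
    """
    if pet.unit != "Bq/mL":
        raise ConfigError(f"suv_map expects PET in Bq/mL, got unit {pet.unit!r}")
    if mode not in SUV_MODES:
        raise ConfigError(f"unknown SUV mode {mode!r}; expected one of {SUV_MODES}")
    conc = pet.data * MBQ_PER_BQ  # MBq/mL
    if mode == "bw":
        normalizer = meta.body_weight_kg * G_PER_KG
    elif mode == "bsa":
        normalizer = bsa(meta.body_weight_kg, meta.body_height_cm) * CM2_PER_M2
    else:
        normalizer = lbm(meta.body_weight_kg, meta.body_height_cm, meta.sex) * G_PER_KG
    values = conc / (meta.injected_dose_mbq / normalizer)
    return SUVMap(pet.with_data(values, unit="SUV"), mode, meta)


def region_suv_stats(suv: SUVMap, mask: RegionMask,
                     regions=("whole_bone", "marrow", "cortex")) -> pd.DataFrame:
    """Per-region mean, sample SD (n-1 denominator) and voxel count.

    Raises :class:`EmptyRegionError` if any requested region is empty.
    """
    check_same_grid(suv.volume, mask, "SUV map and mask")
    rows = []
    for region in regions:
        sel = mask.select(region)
        n = int(np.count_nonzero(sel))
        if n == 0:
            raise EmptyRegionError(region)
        vals = suv.volume.data[sel]
        sd = float(np.std(vals, ddof=1)) if n > 1 else float("nan")
        rows.append({"region": region, "mode": suv.mode,
                     "mean": float(np.mean(vals)), "sd": sd, "n": n})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PIBGMResult:
    """PIBGM at one SUV cutoff: value = N_t / N_b over one bone region."""

    t: float
    n_t: int
    n_b: int
    value: float
    region: str

    def __post_init__(self):
        if self.n_b <= 0:
            raise ConfigError("PIBGM requires a non-empty bone region (N_b > 0)")
        if not (0 <= self.n_t <= self.n_b):
            raise ConfigError("PIBGM counts inconsistent: need 0 <= N_t <= N_b")


def pibgm(suv: SUVMap, mask: RegionMask, region: str = "whole_bone",
          t: float = 1.2) -> PIBGMResult:
    """Fraction of region voxels with SUV strictly greater than ``t``.

    Ties at exactly ``t`` count as not exceeding (strict inequality).
    """
    if not np.isfinite(t):
        raise ConfigError("PIBGM cutoff t must be finite")
    check_same_grid(suv.volume, mask, "SUV map and mask")
    sel = mask.select(region)
    n_b = int(np.count_nonzero(sel))
    if n_b == 0:
        raise EmptyRegionError(region)
    n_t = int(np.count_nonzero(suv.volume.data[sel] > t))
    return PIBGMResult(t=float(t), n_t=n_t, n_b=n_b, value=n_t / n_b, region=region)


def default_t_grid() -> np.ndarray:
    """The standard SUV-cutoff grid: 0.4 to 2.2 in steps of 0.2 (10 values)."""
    return np.round(np.arange(0.4, 2.2 + 1e-9, 0.2), 10)


def pibgm_profile(suv: SUVMap, mask: RegionMask, region: str = "whole_bone",
                  t_grid=None) -> list[PIBGMResult]:
    """PIBGM at every cutoff of a strictly increasing grid (non-increasing)."""
    t_grid = default_t_grid() if t_grid is None else np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) == 0 or np.any(np.diff(t_grid) <= 0):
        raise ConfigError("t_grid must be 1D and strictly increasing")
    return [pibgm(suv, mask, region, t) for t in t_grid]
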