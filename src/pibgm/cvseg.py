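"""Threshold-augmented Chan-Vese refinement of the bone pre-segmentation.

Model
-----
The classic two-phase Chan-Vese energy drives a closed contour C so that the
image is well approximated by its mean c1 inside and c2 outside:

    F(C) = sum_inside (I - c1)^2 + sum_outside (I - c2)^2 .

The augmented energy adds, with weight epsilon, a penalty tying intensities
to a predefined local threshold Th (the bone pre-segmentation threshold):

    F(C) = sum_inside  [(I - c1)^2 + eps (I - Th)^2]
         + sum_outside [(I - c2)^2 + eps (I - Th)^2] .

As written the epsilon term covers the whole domain, so it offsets the energy
by a constant and cancels from the first variation; :func:`cv_energy`
evaluates the literal sum, and the evolution force is formed from the two
integrands (the epsilon parts subtract out numerically).  Smoothness, which
region competition alone does not provide, enters through an optional
contour-length term with weight ``mu``; ``mu = 0`` reproduces the bare
energy above.

Numerics
--------
Two regimes:

* ``mu = 0`` -- the energy depends only on which intensity goes to which
  region, so it is minimized by alternating mean/assignment sweeps (each
  monotonically decreases the energy) followed by an exact scan over
  value-threshold partitions.  The global optimum of a two-mean
  sum-of-squares split of scalars is always a threshold partition, so the
  scan lands on it.
* ``mu > 0`` -- a 2D level-set descent: signed-distance initialization from
  the pre-segmentation, a compact-support smoothed delta of width ~1 voxel
  (only voxels near the contour move -- this is what lets a marrow core with
  soft-tissue-like HU survive inside its cortical shell), curvature term
  weighted by mu, re-initialization every few iterations, and a stopping
  rule on the fraction of voxels changing sign.

Evolution is slice-wise 2D; :func:`segment_bone_volume` stacks the slices
and restricts the region competition to the body mask so that the air
background does not dominate the outside mean.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import (ConfigError, ContourVanishedError, EmptyMaskError,
                     EmptyRegionError)
from .volume import CORTEX, MARROW, RegionMask, Volume3D, check_same_grid


@dataclass
class CVParams:
    """Active-contour parameters.

    ``thresh`` is the local threshold Th (HU); inside the pipeline it
    defaults to the histogram-derived bone threshold.  ``mu`` weights the
    contour-length term; ``None`` resolves to 0.1 x (intensity dynamic
    range)^2 of the evolved image so the smoothing force is commensurate
    with the squared-intensity data forces.
    """

    epsilon: float = 1.0
    thresh: float | None = None
    mu: float | None = None
    max_iters: int = 200
    tol: float = 1e-4              # fraction of voxels allowed to change label
    heaviside_width: float = 1.0   # voxels
    reinit_every: int = 10
    #: voxels at or below this HU are left out of the competition domain in
    #: segment_bone_volume: the PET-derived body mask is deliberately
    #: generous, and residual air would drag the outside mean far below any
    #: soft tissue, turning bone-vs-soft-tissue into body-vs-air
    domain_hu_min: float = -500.0

    def validate(self) -> None:
        if self.epsilon < 0:
            raise ConfigError("epsilon must be >= 0")
        if self.max_iters < 1:
            raise ConfigError("max_iters must be >= 1")
        if not 0.0 < self.tol < 0.1:
            raise ConfigError("tol must be in (0, 0.1)")
        if self.mu is not None and self.mu < 0:
            raise ConfigError("mu must be >= 0")
        if self.heaviside_width <= 0:
            raise ConfigError("heaviside_width must be > 0")


@dataclass(frozen=True)
class RegionMeans:
    """Mean intensity inside (c1) and outside (c2) the contour."""

    c1: float
    c2: float


def _as_domain(image: np.ndarray, domain) -> np.ndarray:
    if domain is None:
        return np.ones(image.shape, dtype=bool)
    domain = np.asarray(domain, dtype=bool)
    if domain.shape != image.shape:
        raise ConfigError("domain shape does not match image")
    return domain


def region_means(image: np.ndarray, mask, domain=None) -> RegionMeans:
    """Exact arithmetic means inside/outside the mask (within the domain)."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    dom = _as_domain(image, domain)
    inside, outside = mask & dom, dom & ~mask
    if not inside.any():
        raise EmptyRegionError("inside")
    if not outside.any():
        raise EmptyRegionError("outside")
    return RegionMeans(float(image[inside].mean()), float(image[outside].mean()))


def _epsilon_term(image, dom, params: CVParams) -> float:
    if params.epsilon == 0:
        return 0.0
    if params.thresh is None:
        raise ConfigError("CVParams.thresh (Th) must be set when epsilon > 0")
    return float(params.epsilon * np.sum((image[dom] - params.thresh) ** 2))


def cv_energy(image: np.ndarray, mask, params: CVParams | None = None,
              domain=None) -> float:
    """Literal augmented Chan-Vese energy of a labeling.

    sum_inside (I-c1)^2 + sum_outside (I-c2)^2 + eps * sum_domain (I-Th)^2;
    with eps = 0 this is the classic Chan-Vese fidelity.
    """
    params = params or CVParams(epsilon=0.0)
    params.validate()
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    dom = _as_domain(image, domain)
    means = region_means(image, mask, dom)
    inside, outside = mask & dom, dom & ~mask
    fidelity = (float(np.sum((image[inside] - means.c1) ** 2))
                + float(np.sum((image[outside] - means.c2) ** 2)))
    return fidelity + _epsilon_term(image, dom, params)


# ---------------------------------------------------------------------------
# mu = 0: exact partition descent
# ---------------------------------------------------------------------------

def _threshold_partition_scan(vals_sorted: np.ndarray):
    """Best upper-tail split of sorted scalars by two-mean SSE.

    Returns (split_index k, SSE) minimizing SSE(low = vals[:k]) +
    SSE(high = vals[k:]) over 1 <= k <= n-1, using prefix sums.
    """
    n = len(vals_sorted)
    cs = np.cumsum(vals_sorted)
    cs2 = np.cumsum(vals_sorted**2)
    k = np.arange(1, n)
    sse_low = cs2[k - 1] - cs[k - 1] ** 2 / k
    s_hi = cs[-1] - cs[k - 1]
    s2_hi = cs2[-1] - cs2[k - 1]
    sse_high = s2_hi - s_hi**2 / (n - k)
    total = sse_low + sse_high
    best = int(np.argmin(total))
    return k[best], float(total[best])


def _evolve_exact(image, init, dom, params: CVParams):
    """Alternating mean/assignment descent plus exact threshold-split polish."""
    inside = init & dom
    n_dom = int(dom.sum())
    for it in range(params.max_iters):
        outside = dom & ~inside
        if not inside.any():
            raise ContourVanishedError(it, "inside")
        if not outside.any():
            raise ContourVanishedError(it, "outside")
        c1, c2 = float(image[inside].mean()), float(image[outside].mean())
        d_in, d_out = (image - c1) ** 2, (image - c2) ** 2
        new = ((d_in < d_out) | ((d_in == d_out) & inside)) & dom
        changed = int(np.count_nonzero(new ^ inside))
        inside = new
        if changed / n_dom < params.tol:
            break
    if not inside.any():
        raise ContourVanishedError(params.max_iters, "inside")
    if not (dom & ~inside).any():
        raise ContourVanishedError(params.max_iters, "outside")

    # Exact polish: the mu=0 optimum is a value-threshold partition.
    vals = np.sort(image[dom], kind="stable")
    if vals[0] != vals[-1]:
        k, sse = _threshold_partition_scan(vals)
        cut = vals[k]  # upper side (>= cut) plays "inside"
        cand = dom & (image >= cut)
        if cand.any() and (dom & ~cand).any():
            cur = cv_energy(image, inside, replace(params, epsilon=0.0), dom)
            if sse < cur - 1e-9 * max(1.0, abs(cur)):
                inside = cand
    return inside


# ---------------------------------------------------------------------------
# mu > 0: level-set descent
# ---------------------------------------------------------------------------

def _signed_distance(inside: np.ndarray) -> np.ndarray:
    pos = ndimage.distance_transform_edt(inside)
    neg = ndimage.distance_transform_edt(~inside)
    return np.where(inside, pos - 0.5, -(neg - 0.5))


def _curvature(phi: np.ndarray) -> np.ndarray:
    gr, gc = np.gradient(phi)
    norm = np.sqrt(gr**2 + gc**2) + 1e-8
    nr, nc = gr / norm, gc / norm
    return np.gradient(nr, axis=0) + np.gradient(nc, axis=1)


def _smoothed_delta(phi: np.ndarray, width: float) -> np.ndarray:
    w = 1.5 * width
    out = np.zeros_like(phi)
    band = np.abs(phi) < w
    out[band] = (1.0 + np.cos(np.pi * phi[band] / w)) / (2.0 * w)
    return out


def _evolve_levelset(image, init, dom, params: CVParams, mu: float):
    phi = _signed_distance(init & dom)
    phi[~dom] = -max(phi.shape)  # frozen background, always outside
    n_dom = int(dom.sum())
    prev_sign = (phi > 0) & dom
    # a voxel needs ~|phi|/0.45 steps to flip, so "converged" means several
    # consecutive iterations without label changes, not just one
    quiet = 0
    for it in range(1, params.max_iters + 1):
        inside = (phi > 0) & dom
        outside = dom & ~inside
        if not inside.any():
            raise ContourVanishedError(it, "inside")
        if not outside.any():
            raise ContourVanishedError(it, "outside")
        c1, c2 = float(image[inside].mean()), float(image[outside].mean())
        in_term = (image - c1) ** 2
        out_term = (image - c2) ** 2
        if params.epsilon > 0:
            if params.thresh is None:
                raise ConfigError("CVParams.thresh (Th) must be set when epsilon > 0")
            aug = params.epsilon * (image - params.thresh) ** 2
            in_term = in_term + aug
            out_term = out_term + aug
        force = out_term - in_term
        dphi = _smoothed_delta(phi, params.heaviside_width) * (mu * _curvature(phi) + force)
        dphi[~dom] = 0.0
        step = float(np.max(np.abs(dphi)))
        if step == 0.0:
            break
        phi = phi + (0.45 / step) * dphi
        if it % params.reinit_every == 0:
            phi = _signed_distance((phi > 0) & dom)
            phi[~dom] = -max(phi.shape)
        sign = (phi > 0) & dom
        changed = int(np.count_nonzero(sign ^ prev_sign))
        prev_sign = sign
        quiet = quiet + 1 if changed / n_dom < params.tol else 0
        if quiet >= 3:
            break
    inside = (phi > 0) & dom
    if not inside.any():
        raise ContourVanishedError(params.max_iters, "inside")
    if not (dom & ~inside).any():
        raise ContourVanishedError(params.max_iters, "outside")
    return inside


def evolve_contour(image: np.ndarray, init_mask, params: CVParams | None = None,
                   domain=None) -> np.ndarray:
    """Evolve a 2D contour to a lower-energy labeling.

    Starts from ``init_mask`` (both regions must be non-empty), descends the
    augmented Chan-Vese energy (exact partition descent when the smoothness
    weight resolves to zero, level-set descent otherwise) and returns the
    final boolean inside mask.  Raises :class:`ContourVanishedError`, tagged
    with the iteration index, if either region empties.
    """
    params = params or CVParams()
    params.validate()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ConfigError("evolve_contour operates on 2D slices")
    init = np.asarray(init_mask, dtype=bool)
    dom = _as_domain(image, domain)
    if not (init & dom).any() or not (dom & ~init).any():
        raise ConfigError("init_mask is degenerate: both regions must be non-empty")
    if params.mu is None:
        rng_vals = image[dom]
        mu = 0.1 * float(rng_vals.max() - rng_vals.min()) ** 2
    else:
        mu = float(params.mu)
    if mu == 0.0:
        return _evolve_exact(image, init, dom, params)
    return _evolve_levelset(image, init, dom, params, mu)


# ---------------------------------------------------------------------------
# Volume-level operations
# ---------------------------------------------------------------------------

def segment_bone_volume(ct: Volume3D, body: RegionMask, fit_threshold: float,
                        params: CVParams | None = None) -> RegionMask:
    """Slice-wise bone segmentation of a bed-removed CT volume.

    Each slice is pre-segmented by thresholding body voxels at
    ``fit_threshold``, then refined by :func:`evolve_contour` with the
    competition restricted to the body mask (outside(C) is the non-bone
    tissue, not the air background).  Th defaults to ``fit_threshold``.
    Slices with an empty pre-segmentation stay empty; evolution failures
    propagate with the slice index attached.
    """
    params = params or CVParams()
    params.validate()
    check_same_grid(ct, body, "CT and body mask")
    if not body.as_bool().any():
        return RegionMask.like(ct, np.zeros(ct.shape, dtype=np.int16))
    p = params if params.thresh is not None else replace(params, thresh=float(fit_threshold))
    out = np.zeros(ct.shape, dtype=np.int16)
    for z in range(ct.shape[0]):
        dom = body.as_bool()[z] & (ct.data[z] > p.domain_hu_min)
        if not dom.any():
            continue
        pre = dom & (ct.data[z] >= fit_threshold)
        if not pre.any():
            continue
        if not (dom & ~pre).any():
            out[z][pre] = 1  # whole domain pre-segmented: nothing to compete
            continue
        try:
            mask = evolve_contour(ct.data[z], pre, p, domain=dom)
        except ContourVanishedError as exc:
            raise ContourVanishedError(exc.iteration,
                                       f"{exc.which} (slice {z})") from exc
        out[z][mask] = 1
    return RegionMask.like(ct, out)


def split_cortex_marrow(ct: Volume3D, bone_mask: RegionMask,
                        split_mode: str = "otsu") -> RegionMask:
    """Label bone voxels as marrow (1) or cortex (2) by HU.

    ``split_mode`` is ``"otsu"`` (threshold from the within-bone intensity
    distribution; needs at least two distinct values) or ``"fixed:<HU>"``.
    Voxels strictly above the cutoff become cortex.
    """
    check_same_grid(ct, bone_mask, "CT and bone mask")
    sel = bone_mask.as_bool()
    if not sel.any():
        raise EmptyMaskError("split_cortex_marrow: bone mask is empty")
    vals = ct.data[sel]
    if split_mode == "otsu":
        if len(np.unique(vals)) < 2:
            raise ConfigError(
                "cannot Otsu-split bone with fewer than 2 distinct HU values")
        cutoff = float(threshold_otsu(vals))
    elif split_mode.startswith("fixed:"):
        cutoff = float(split_mode.split(":", 1)[1])
    else:
        raise ConfigError(f"split_mode must be 'otsu' or 'fixed:<HU>', got {split_mode!r}")
    labels = np.zeros(ct.shape, dtype=np.int16)
    labels[sel] = MARROW
    labels[sel & (ct.data > cutoff)] = CORTEX
    return RegionMask.like(ct, labels)


def transfer_mask_to_pet(mask: RegionMask, pet: Volume3D) -> dict[str, np.ndarray]:
    """Extract per-region PET voxel values through a co-registered mask.

    Returns arrays keyed ``whole_bone`` / ``marrow`` / ``cortex``; an empty
    label yields an empty array, not an error.
    """
    check_same_grid(mask, pet, "mask and PET")
    return {region: pet.data[mask.select(region)]
            for region in ("whole_bone", "marrow", "cortex")}


def seg_metrics(pred: RegionMask, truth: RegionMask) -> tuple[float, float, float]:
    """(TPR, FPR, Dice) of a predicted binary mask against ground truth.

    TPR = TP/(TP+FN), FPR = FP/(FP+TN), Dice = 2|A n B| / (|A| + |B|).
    An empty truth mask makes TPR undefined and raises; a full-grid truth
    makes FPR undefined (returned as NaN).
    """
    check_same_grid(pred, truth, "prediction and truth")
    p, t = pred.as_bool(), truth.as_bool()
    if not t.any():
        raise EmptyRegionError("truth", "truth mask empty: TPR undefined")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    tpr = tp / (tp + fn)
    fpr = fp / (fp + tn) if (fp + tn) > 0 else float("nan")
    denom = int(p.sum()) + int(t.sum())
    dice = 2.0 * tp / denom if denom > 0 else float("nan")
    return tpr, fpr, dice
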