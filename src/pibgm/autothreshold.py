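"""Two-Gaussian histogram model of the body CT and the bone pre-threshold.

The HU histogram of a (bed-removed, body-masked) whole-body CT is dominated
by two soft-tissue populations, fat and muscle; the bone peak is submerged
beneath them because bone occupies a small volume fraction.  The model is

    y(x) = A_m * exp(-((x - B_m)/c_m)^2) + A_f * exp(-((x - B_f)/c_f)^2)

with centres B (HU), widths c (HU; c = sqrt(2)*sigma for a normal density)
and amplitudes A fitted to the histogram curve by nonlinear least squares.
The bone pre-segmentation threshold is then placed above the muscle centre
by a fraction of the fat-muscle separation:

    threshold = B_m + (omega/2) * (B_m - B_f)

with weighting coefficient omega (default 0.5).  The fit window (default
-200..300 HU) excludes air and dense cortical bone, which the two-component
model does not describe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .errors import (ConfigError, DegenerateHistogramError, EmptyMaskError,
                     HistogramFitError)
from .volume import RegionMask, Volume3D, check_same_grid


@dataclass
class ThresholdParams:
    """Histogram / threshold configuration."""

    omega: float = 0.5
    n_bins: int = 128
    hu_range: tuple[float, float] = (-200.0, 300.0)
    #: minimum HU separation of the two initializing histogram peaks
    min_peak_separation: float = 50.0

    def validate(self) -> None:
        if self.omega <= 0:
            raise ConfigError("omega must be > 0")
        if self.n_bins < 32:
            raise ConfigError("n_bins must be >= 32")
        lo, hi = self.hu_range
        if not lo < hi:
            raise ConfigError("hu_range must be (low, high) with low < high")


@dataclass
class HistogramFit:
    """Fitted two-Gaussian model; components sorted so B_f < B_m."""

    A_m: float
    B_m: float
    c_m: float
    A_f: float
    B_f: float
    c_f: float
    residual_norm: float
    bin_edges: np.ndarray
    bin_counts: np.ndarray

    def __post_init__(self):
        if not (self.c_m > 0 and self.c_f > 0):
            raise ConfigError("Gaussian widths must be positive")
        if not (self.A_m > 0 and self.A_f > 0):
            raise ConfigError("Gaussian amplitudes must be positive")
        if not self.B_f < self.B_m:
            raise ConfigError("components must satisfy B_f < B_m (fat darker)")

    def predict(self, x: np.ndarray) -> np.ndarray:
        return two_gaussian(np.asarray(x, dtype=float),
                            self.A_m, self.B_m, self.c_m,
                            self.A_f, self.B_f, self.c_f)


def two_gaussian(x, A1, B1, c1, A2, B2, c2):
    """Sum of two Gaussians in the amplitude/centre/width parameterization."""
    return (A1 * np.exp(-(((x - B1) / c1) ** 2))
            + A2 * np.exp(-(((x - B2) / c2) ** 2)))


def build_histogram(ct: Volume3D, body: RegionMask, n_bins: int = 128,
                    hu_range: tuple[float, float] = (-200.0, 300.0)):
    """Histogram of body-masked CT intensities inside the HU window.

    Returns ``(bin_edges, bin_counts)``; counts sum to the number of body
    voxels whose HU falls inside ``hu_range``.
    """
    check_same_grid(ct, body, "CT and body mask")
    sel = body.as_bool()
    if not sel.any():
        raise EmptyMaskError("build_histogram: body mask is empty")
    counts, edges = np.histogram(ct.data[sel], bins=n_bins, range=hu_range)
    return edges, counts


def _initial_guess(centers, counts, min_separation):
    """Two largest separated histogram peaks -> starting parameters."""
    order = max(1, len(counts) // 32)
    peaks, props = find_peaks(counts, height=0.05 * counts.max(), distance=order)
    if len(peaks) < 2:
        raise DegenerateHistogramError(
            f"need two histogram modes, found {len(peaks)} peak(s)")
    by_height = peaks[np.argsort(props["peak_heights"], kind="stable")[::-1]]
    first = by_height[0]
    second = None
    for p in by_height[1:]:
        if abs(centers[p] - centers[first]) >= min_separation:
            second = p
            break
    if second is None:
        raise DegenerateHistogramError(
            f"no two peaks separated by >= {min_separation} HU")
    sep = abs(centers[second] - centers[first])
    return [(counts[p], centers[p], sep / 2.0) for p in (first, second)]


def fit_two_gaussians(bin_edges, bin_counts,
                      params: ThresholdParams | None = None) -> HistogramFit:
    """Nonlinear least-squares fit of the two-Gaussian histogram model.

    Initialization: the two largest peaks separated by at least
    ``min_peak_separation`` HU; widths start at half the peak separation.
    Centres are kept inside the histogram support by bounds.  Failure to
    converge raises :class:`HistogramFitError` carrying the last iterate.
    """
    params = params or ThresholdParams()
    params.validate()
    edges = np.asarray(bin_edges, dtype=float)
    counts = np.asarray(bin_counts, dtype=float)
    if np.any(counts < 0):
        raise ConfigError("bin_counts must be non-negative")
    centers = 0.5 * (edges[:-1] + edges[1:])
    (A1, B1, c1), (A2, B2, c2) = _initial_guess(centers, counts,
                                                params.min_peak_separation)
    p0 = [A1, B1, c1, A2, B2, c2]
    lo, hi = edges[0], edges[-1]
    span = hi - lo
    # widths below half a bin are unresolvable; a floor there also keeps the
    # optimizer from grinding towards zero on spiky (noise-free) histograms
    w_min = 0.5 * (edges[1] - edges[0])
    p0[2] = max(p0[2], w_min)
    p0[5] = max(p0[5], w_min)
    bounds = ([1e-9, lo, w_min, 1e-9, lo, w_min],
              [10.0 * counts.max() + 1.0, hi, span, 10.0 * counts.max() + 1.0, hi, span])
    try:
        popt, _ = curve_fit(two_gaussian, centers, counts, p0=p0, bounds=bounds,
                            maxfev=20000)
    except RuntimeError as exc:
        raise HistogramFitError(f"two-Gaussian fit did not converge: {exc}",
                                last_params=p0) from exc
    resid = counts - two_gaussian(centers, *popt)
    residual_norm = float(np.linalg.norm(resid))
    comps = sorted([popt[:3], popt[3:]], key=lambda c: c[1])  # by centre
    (A_f, B_f, c_f), (A_m, B_m, c_m) = comps
    if np.isclose(B_f, B_m, atol=1e-6):
        raise HistogramFitError("fit collapsed to a single centre",
                                last_params=list(popt), residual=residual_norm)
    return HistogramFit(A_m=float(A_m), B_m=float(B_m), c_m=abs(float(c_m)),
                        A_f=float(A_f), B_f=float(B_f), c_f=abs(float(c_f)),
                        residual_norm=residual_norm,
                        bin_edges=edges, bin_counts=counts)


def compute_threshold(fit: HistogramFit, omega: float = 0.5) -> float:
    """Bone pre-segmentation threshold: B_m + (omega/2) * (B_m - B_f)."""
    if omega < 0:
        raise ConfigError("omega must be >= 0")
    if fit.B_m <= fit.B_f:
        raise ConfigError("invalid fit: muscle centre must exceed fat centre")
    return float(fit.B_m + 0.5 * omega * (fit.B_m - fit.B_f))


def presegment_bone(ct: Volume3D, body: RegionMask, threshold: float) -> RegionMask:
    """Binary mask of body voxels with HU >= threshold."""
    if not np.isfinite(threshold):
        raise ConfigError("threshold must be finite")
    check_same_grid(ct, body, "CT and body mask")
    mask = body.as_bool() & (ct.data >= threshold)
    return RegionMask.like(ct, mask.astype(np.int16))
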