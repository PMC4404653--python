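"""Per-bundle size measurement.

Each detected bundle is measured on a 40x40 px patch around its center:
homomorphic filtering (log-domain Fourier high-emphasis) removes the
smooth illumination component and boosts the bundle's own contrast, a
full-covariance 2D Gaussian is fit to the enhanced patch, and the area
of the 2-sigma level ellipse of the fit is reported as the bundle size.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import fft as spfft
from scipy import optimize

from .io import Calibration

logger = logging.getLogger(__name__)

DEFAULT_PATCH_SIZE = 40
#: Level-contour multiplier defining the reported ellipse: area =
#: pi * (k sigma_major) * (k sigma_minor) with k = 2 by default (the
#: outermost clearly visible contour of the fitted surface).
DEFAULT_CONTOUR_SIGMA = 2.0


@dataclass
class BundleFit:
    """Result of fitting one bundle patch."""

    center_offset: tuple[float, float]  # (d_row, d_col) from patch center
    amplitude: float
    sigma_major: float
    sigma_minor: float
    theta: float  # radians in [-pi/2, pi/2)
    baseline: float
    area_px2: float
    area_cm2: float
    converged: bool
    edge_clipped: bool = False


def extract_patch(
    gray: np.ndarray, center: tuple[int, int], size: int = DEFAULT_PATCH_SIZE
) -> tuple[np.ndarray, bool]:
    """Copy a size x size region around a bundle center.

    The patch spans ``size//2`` pixels before the center and
    ``size - size//2`` after, matching array-slice conventions.  Patches
    that would run off the image are padded by reflection and flagged.
    """
    if size < 8 or size % 2:
        raise ValueError("patch size must be even and >= 8")
    gray = np.asarray(gray)
    r, c = int(center[0]), int(center[1])
    if not (0 <= r < gray.shape[0] and 0 <= c < gray.shape[1]):
        raise ValueError(f"center {center} outside image {gray.shape}")
    half = size // 2
    top, left = r - half, c - half
    bottom, right = top + size, left + size
    clipped = top < 0 or left < 0 or bottom > gray.shape[0] or right > gray.shape[1]
    if clipped:
        pr0, pc0 = max(0, -top), max(0, -left)
        pr1 = max(0, bottom - gray.shape[0])
        pc1 = max(0, right - gray.shape[1])
        gray = np.pad(gray, ((pr0, pr1), (pc0, pc1)), mode="reflect")
        top, left = top + pr0, left + pc0
        bottom, right = top + size, left + size
    return gray[top:bottom, left:right].copy(), bool(clipped)


def homomorphic_filter(
    patch: np.ndarray,
    cutoff_frac: float = 0.08,
    gain_low: float = 0.5,
    gain_high: float = 1.5,
) -> np.ndarray:
    """Suppress low-frequency illumination in the log domain.

    Computes exp(IDFT(H . DFT(log(1 + patch)))) - 1 with a Gaussian
    high-emphasis transfer function H(f) = gain_low + (gain_high -
    gain_low) * (1 - exp(-|f|^2 / (2 (cutoff_frac N)^2))): low spatial
    frequencies (illumination) are attenuated toward gain_low while high
    frequencies (reflectance structure) are amplified toward gain_high.
    Output is rescaled to [0, 255].
    """
    patch = np.asarray(patch, dtype=np.float64)
    if np.any(patch < 0):
        raise ValueError("patch values must be >= 0")
    n0, n1 = patch.shape
    logp = np.log1p(patch)
    spectrum = spfft.fft2(logp)
    u = spfft.fftfreq(n0) * n0
    v = spfft.fftfreq(n1) * n1
    d2 = u[:, None] ** 2 + v[None, :] ** 2
    n = 0.5 * (n0 + n1)
    h = gain_low + (gain_high - gain_low) * (1.0 - np.exp(-d2 / (2.0 * (cutoff_frac * n) ** 2)))
    out = np.expm1(np.real(spfft.ifft2(h * spectrum)))
    lo, hi = out.min(), out.max()
    if hi - lo < 1e-12:
        return np.clip(out, 0.0, 255.0)
    return (out - lo) * (255.0 / (hi - lo))


def _moment_init(patch: np.ndarray) -> np.ndarray:
    """Initial parameters [baseline, amp, r0, c0, sa, sb, theta] from moments.

    Moments are taken over the central half of the patch only: the patch
    is centered on the bundle being measured, and neighboring bundles in
    the periphery must not drag the initialization away from it.
    """
    n0, n1 = patch.shape
    baseline = float(np.percentile(patch, 25))
    yy, xx = np.mgrid[0:n0, 0:n1]
    central = (np.abs(yy - n0 / 2) <= n0 / 4) & (np.abs(xx - n1 / 2) <= n1 / 4)
    w = np.where(central, np.clip(patch - baseline, 0, None), 0.0)
    total = w.sum()
    if total <= 0:
        return np.array([baseline, (np.ptp(patch) or 1.0), n0 / 2, n1 / 2, 3.0, 3.0, 0.0])
    r0 = float((w * yy).sum() / total)
    c0 = float((w * xx).sum() / total)
    mrr = float((w * (yy - r0) ** 2).sum() / total)
    mcc = float((w * (xx - c0) ** 2).sum() / total)
    mrc = float((w * (yy - r0) * (xx - c0)).sum() / total)
    cov = np.array([[mrr, mrc], [mrc, mcc]])
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.25, None)
    sb, sa = np.sqrt(evals)  # eigh ascending
    vmaj = evecs[:, 1]
    theta = float(np.arctan2(vmaj[1], vmaj[0]))  # angle vs row axis
    amp = float(patch.max() - baseline)
    return np.array([baseline, amp, r0, c0, min(sa, n0 / 6), min(sb, n1 / 6), theta])


def _gauss2d(params: np.ndarray, yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
    baseline, amp, r0, c0, sa, sb, theta = params
    ct, st = np.cos(theta), np.sin(theta)
    dr, dc = yy - r0, xx - c0
    qa = (dr * ct + dc * st) / sa
    qb = (-dr * st + dc * ct) / sb
    return baseline + amp * np.exp(-0.5 * (qa**2 + qb**2))


def fit_gaussian2d(
    patch: np.ndarray,
    contour_sigma: float = DEFAULT_CONTOUR_SIGMA,
    cal: Calibration | None = None,
) -> BundleFit:
    """Least-squares fit of a rotated 2D Gaussian plus constant baseline.

    The size reported is the area of the ``contour_sigma`` level ellipse,
    pi * (k sigma_major) * (k sigma_minor).  A fit is flagged not
    converged (and its area withheld) when the optimizer fails, the
    amplitude is non-positive, the fitted center leaves the patch, or
    the Gaussian explains too little of the patch variance to be a
    credible bundle (degenerate or pure-noise patches).
    """
    patch = np.asarray(patch, dtype=np.float64)
    n0, n1 = patch.shape
    if np.ptp(patch) == 0:
        raise ValueError("constant patch cannot be fit")
    yy, xx = np.mgrid[0:n0, 0:n1]
    p0 = _moment_init(patch)
    scale = max(np.ptp(patch), 1.0)
    # the fitted center may wander at most a quarter patch from the
    # detected bundle center, and the footprint must fit the patch:
    # beyond that the fit is measuring a neighbor or the background
    lower = [-np.inf, 0.0, n0 / 4, n1 / 4, 0.3, 0.3, -np.pi]
    upper = [np.inf, np.inf, 3 * n0 / 4, 3 * n1 / 4, n0 / 3, n1 / 3, np.pi]
    p0 = np.clip(p0, lower, upper)

    def residuals(p: np.ndarray) -> np.ndarray:
        return (_gauss2d(p, yy, xx) - patch).ravel() / scale

    try:
        res = optimize.least_squares(residuals, p0, bounds=(lower, upper), method="trf")
        success = bool(res.success)
        p = res.x
    except Exception:
        success, p = False, p0
    baseline, amp, r0, c0, sa, sb, theta = p
    if sb > sa:
        sa, sb = sb, sa
        theta += np.pi / 2
    theta = (theta + np.pi / 2) % np.pi - np.pi / 2
    ss_res = float(np.sum((_gauss2d(p, yy, xx) - patch) ** 2))
    ss_tot = float(np.sum((patch - patch.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    half = n0 // 2
    inside = (0 <= r0 < n0) and (0 <= c0 < n1)
    converged = success and amp > 0 and inside and sb >= 0.5 and r2 >= 0.2
    area_px2 = np.pi * (contour_sigma * sa) * (contour_sigma * sb) if converged else np.nan
    area_cm2 = cal.px2_to_cm2(area_px2) if (cal is not None and converged) else np.nan
    return BundleFit(
        center_offset=(float(r0 - half), float(c0 - half)),
        amplitude=float(amp),
        sigma_major=float(sa),
        sigma_minor=float(sb),
        theta=float(theta),
        baseline=float(baseline),
        area_px2=float(area_px2),
        area_cm2=float(area_cm2),
        converged=bool(converged),
    )


def bundle_sizes(
    gray: np.ndarray,
    centers: list[tuple[int, int]],
    cal: Calibration,
    patch_size: int = DEFAULT_PATCH_SIZE,
    contour_sigma: float = DEFAULT_CONTOUR_SIGMA,
    enhance: bool = True,
    homomorphic_kwargs: dict | None = None,
) -> tuple[list[BundleFit], float]:
    """Fit every detected bundle and summarize the mean area in cm^2.

    Fits are performed on the homomorphically enhanced patch; bundles
    whose fit does not converge are excluded from the summary.  Returns
    (fits, mean_bundle_area_cm2); the mean is NaN when no fit converged.
    """
    fits: list[BundleFit] = []
    for center in centers:
        try:
            patch, clipped = extract_patch(gray, center, size=patch_size)
            if enhance:
                patch = homomorphic_filter(patch, **(homomorphic_kwargs or {}))
            fit = fit_gaussian2d(patch, contour_sigma=contour_sigma, cal=cal)
        except ValueError:
            fit = BundleFit(
                center_offset=(np.nan, np.nan),
                amplitude=np.nan,
                sigma_major=np.nan,
                sigma_minor=np.nan,
                theta=np.nan,
                baseline=np.nan,
                area_px2=np.nan,
                area_cm2=np.nan,
                converged=False,
            )
            clipped = False
        fit.edge_clipped = clipped
        fits.append(fit)
    areas = [f.area_cm2 for f in fits if f.converged and np.isfinite(f.area_cm2)]
    if not areas:
        if centers:
            logger.warning("no bundle fit converged; mean bundle area missing")
        return fits, float("nan")
    return fits, float(np.mean(areas))
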