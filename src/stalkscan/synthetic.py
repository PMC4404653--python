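"""Synthetic flatbed-scan generator with exact ground truth.

Renders scanner-like images of stalk transections: a bright pith disc
inside a darker rind annulus on a near-black background, small bright
elliptical-Gaussian vascular bundles scattered through the pith with a
minimum-spacing constraint, low-amplitude correlated parenchyma texture,
a planar illumination gradient, i.i.d. pixel noise, and occasional
debris (thin bright strokes and small blobs sized to exercise both
clauses of the debris filter).  Every random draw comes from one seeded
generator, so identical specs give bit-identical images, and the true
masks, bundle centers, and bundle shapes are returned alongside.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .io import ScanImage

#: RGB tint applied to the rendered intensity map (dried stalk tissue is
#: slightly yellowish; the green channel carries the full signal).
RGB_TINT = (0.98, 1.0, 0.85)

SUPERSAMPLE = 4


class SyntheticSpecError(ValueError):
    """Unsatisfiable synthetic-scene specification."""


@dataclass(frozen=True)
class TransectionSpec:
    """Geometry and intensities of one rendered stalk section.

    Defaults portray a maize-like section at 800 dpi (~315 px/cm): a
    1.8 cm diameter stalk with a 1.6 mm rind and 140 pith bundles.
    """

    center: tuple[float, float] = (380.0, 380.0)
    outer_radius_px: float = 280.0
    rind_thickness_px: float = 50.0
    pith_intensity: float = 185.0
    rind_intensity: float = 140.0
    n_bundles: int = 140
    sigma_major_range: tuple[float, float] = (2.2, 4.0)
    sigma_minor_frac_range: tuple[float, float] = (0.7, 1.0)
    bundle_boost_range: tuple[float, float] = (45.0, 75.0)
    min_spacing_px: float = 16.0

    def __post_init__(self) -> None:
        if not 0 < self.rind_thickness_px < self.outer_radius_px:
            raise SyntheticSpecError("rind thickness must be in (0, outer_radius)")
        if self.min_spacing_px < 2 * self.sigma_major_range[1]:
            raise SyntheticSpecError(
                "bundle spacing must be >= 2 x max bundle radius"
            )
        for v in (self.pith_intensity, self.rind_intensity):
            if not 0 <= v <= 255:
                raise SyntheticSpecError("intensities must be in [0, 255]")


@dataclass(frozen=True)
class SyntheticSpec:
    """A full synthetic scan: transections plus global nuisance factors."""

    image_shape: tuple[int, int] = (760, 760)
    transections: tuple[TransectionSpec, ...] = (TransectionSpec(),)
    background_intensity: float = 15.0
    illumination_gradient: float = 0.15  # plane amplitude, fraction of intensity
    noise_sigma: float = 5.0  # additive Gaussian, 8-bit units
    texture_amplitude: float = 4.0  # parenchyma texture std, 8-bit units
    texture_scale_px: float = 3.0
    n_debris: int = 4
    debris_intensity: float = 150.0
    seed: int = 0
    dpi: float = 800.0


@dataclass
class BundleTruth:
    center: tuple[float, float]  # (row, col), full-image frame
    sigma_major: float
    sigma_minor: float
    theta: float
    boost: float

    @property
    def area_px2(self) -> float:
        """2-sigma level-ellipse area of the rendered Gaussian."""
        return float(np.pi * 2 * self.sigma_major * 2 * self.sigma_minor)


@dataclass
class TransectionTruth:
    center: tuple[float, float]
    outer_radius_px: float
    rind_thickness_px: float
    object_mask: np.ndarray  # full-image frame
    pith_mask: np.ndarray
    bundles: list[BundleTruth] = field(default_factory=list)

    @property
    def object_area_px(self) -> int:
        return int(self.object_mask.sum())

    @property
    def pith_area_px(self) -> int:
        return int(self.pith_mask.sum())

    @property
    def bundle_centers(self) -> np.ndarray:
        return np.array([b.center for b in self.bundles]).reshape(-1, 2)


@dataclass
class GroundTruth:
    transections: list[TransectionTruth]

    def to_json(self, path: str | Path) -> None:
        """Serialize the geometric truth (masks are reconstructible)."""
        data = [
            {
                "center": list(t.center),
                "outer_radius_px": t.outer_radius_px,
                "rind_thickness_px": t.rind_thickness_px,
                "bundles": [
                    {
                        "center": list(b.center),
                        "sigma_major": b.sigma_major,
                        "sigma_minor": b.sigma_minor,
                        "theta": b.theta,
                        "boost": b.boost,
                    }
                    for b in t.bundles
                ],
            }
            for t in self.transections
        ]
        Path(path).write_text(json.dumps(data, indent=2) + "\n")


def _render_annulus(
    img: np.ndarray, tspec: TransectionSpec, background: float
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one antialiased disc+rind; return (object_mask, pith_mask)."""
    rows, cols = img.shape
    cr, cc = tspec.center
    R = tspec.outer_radius_px
    pith_r = R - tspec.rind_thickness_px
    pad = 3
    top = max(0, int(np.floor(cr - R - pad)))
    bottom = min(rows, int(np.ceil(cr + R + pad)))
    left = max(0, int(np.floor(cc - R - pad)))
    right = min(cols, int(np.ceil(cc + R + pad)))
    h, w = bottom - top, right - left
    s = SUPERSAMPLE
    # supersampled pixel-center coordinates of the local patch
    ys = top + (np.arange(h * s) + 0.5) / s - 0.5
    xs = left + (np.arange(w * s) + 0.5) / s - 0.5
    d = np.hypot(ys[:, None] - cr, xs[None, :] - cc)
    vals = np.where(
        d <= pith_r,
        tspec.pith_intensity,
        np.where(d <= R, tspec.rind_intensity, background),
    )
    patch = vals.reshape(h, s, w, s).mean(axis=(1, 3))
    img[top:bottom, left:right] = patch

    yy, xx = np.mgrid[0:rows, 0:cols]
    dd = np.hypot(yy - cr, xx - cc)
    return dd <= R, dd <= pith_r


def _place_bundles(
    rng: np.random.Generator, tspec: TransectionSpec
) -> list[BundleTruth]:
    """Rejection-sample bundle centers in the pith with minimum spacing."""
    cr, cc = tspec.center
    pith_r = tspec.outer_radius_px - tspec.rind_thickness_px
    margin = 3.0 * tspec.sigma_major_range[1]
    place_r = pith_r - margin
    if place_r <= 0 and tspec.n_bundles > 0:
        raise SyntheticSpecError("pith too small to hold bundles")
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < tspec.n_bundles:
        attempts += 1
        if attempts > 10_000:
            raise SyntheticSpecError(
                f"could not place {tspec.n_bundles} bundles with spacing "
                f"{tspec.min_spacing_px} after 10000 rejections"
            )
        rad = place_r * np.sqrt(rng.uniform())
        ang = rng.uniform(0, 2 * np.pi)
        p = (cr + rad * np.sin(ang), cc + rad * np.cos(ang))
        if centers and np.min(cdist([p], centers)) < tspec.min_spacing_px:
            continue
        centers.append(p)
    bundles = []
    for p in centers:
        sa = rng.uniform(*tspec.sigma_major_range)
        sb = sa * rng.uniform(*tspec.sigma_minor_frac_range)
        theta = rng.uniform(-np.pi / 2, np.pi / 2)
        boost = rng.uniform(*tspec.bundle_boost_range)
        bundles.append(
            BundleTruth(center=p, sigma_major=sa, sigma_minor=sb, theta=theta, boost=boost)
        )
    return bundles


def _render_bundle(img: np.ndarray, b: BundleTruth) -> None:
    cr, cc = b.center
    ext = int(np.ceil(4 * b.sigma_major))
    top = max(0, int(np.floor(cr)) - ext)
    bottom = min(img.shape[0], int(np.ceil(cr)) + ext + 1)
    left = max(0, int(np.floor(cc)) - ext)
    right = min(img.shape[1], int(np.ceil(cc)) + ext + 1)
    yy, xx = np.mgrid[top:bottom, left:right]
    dr, dc = yy - cr, xx - cc
    ct, st = np.cos(b.theta), np.sin(b.theta)
    qa = (dr * ct + dc * st) / b.sigma_major
    qb = (-dr * st + dc * ct) / b.sigma_minor
    img[top:bottom, left:right] += b.boost * np.exp(-0.5 * (qa**2 + qb**2))


def _render_debris(
    img: np.ndarray,
    rng: np.random.Generator,
    spec: SyntheticSpec,
    keepout: list[tuple[tuple[float, float], float]],
) -> None:
    """Thin bright strokes and small blobs away from the transections."""
    rows, cols = img.shape
    placed = 0
    attempts = 0
    while placed < spec.n_debris and attempts < 2000:
        attempts += 1
        r0 = rng.uniform(10, rows - 10)
        c0 = rng.uniform(10, cols - 10)
        if any(
            np.hypot(r0 - kc[0], c0 - kc[1]) < kr + 60 for kc, kr in keepout
        ):
            continue
        if placed % 2 == 0:  # thin stroke: high eccentricity
            length = rng.uniform(80, 200)
            ang = rng.uniform(0, np.pi)
            n = int(length * 2)
            ts = np.linspace(-length / 2, length / 2, n)
            rr = np.clip(np.round(r0 + ts * np.sin(ang)).astype(int), 0, rows - 1)
            cc = np.clip(np.round(c0 + ts * np.cos(ang)).astype(int), 0, cols - 1)
            stroke = np.zeros_like(img, dtype=bool)
            stroke[rr, cc] = True
            img[stroke] = spec.debris_intensity
        else:  # small blob: area well under the size filter
            rad = rng.uniform(8, 30)
            yy, xx = np.mgrid[0:rows, 0:cols]
            blob = np.hypot(yy - r0, xx - c0) <= rad
            img[blob] = spec.debris_intensity
        placed += 1


def generate(spec: SyntheticSpec) -> tuple[ScanImage, GroundTruth]:
    """Render a synthetic scan and its exact ground truth.

    Deterministic in ``spec.seed``: identical specs give byte-identical
    images.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.image_shape
    img = np.full((rows, cols), float(spec.background_intensity))

    truths: list[TransectionTruth] = []
    object_union = np.zeros((rows, cols), bool)
    for tspec in spec.transections:
        obj_mask, pith_mask = _render_annulus(img, tspec, spec.background_intensity)
        bundles = _place_bundles(rng, tspec)
        for b in bundles:
            _render_bundle(img, b)
        object_union |= obj_mask
        truths.append(
            TransectionTruth(
                center=tspec.center,
                outer_radius_px=tspec.outer_radius_px,
                rind_thickness_px=tspec.rind_thickness_px,
                object_mask=obj_mask,
                pith_mask=pith_mask,
                bundles=bundles,
            )
        )

    if spec.texture_amplitude > 0:
        tex = ndimage.gaussian_filter(
            rng.standard_normal((rows, cols)), spec.texture_scale_px
        )
        tex *= spec.texture_amplitude / max(tex.std(), 1e-12)
        img[object_union] += tex[object_union]

    keepout = [
        (t.center, t.outer_radius_px) for t in spec.transections
    ]
    if spec.n_debris > 0:
        _render_debris(img, rng, spec, keepout)

    if spec.illumination_gradient > 0:
        ang = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:rows, 0:cols]
        proj = (yy - rows / 2) * np.sin(ang) + (xx - cols / 2) * np.cos(ang)
        half_span = 0.5 * abs(rows * np.sin(ang)) + 0.5 * abs(cols * np.cos(ang))
        plane = 1.0 + spec.illumination_gradient * proj / max(half_span, 1.0)
        img *= plane

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=(rows, cols))

    img = np.clip(img, 0, 255)
    rgb = np.stack([np.clip(img * t, 0, 255) for t in RGB_TINT], axis=2)
    pixels = np.round(rgb).astype(np.uint8)
    scan = ScanImage(pixels=pixels, dpi=spec.dpi, source_id=f"synthetic-{spec.seed}")
    return scan, GroundTruth(transections=truths)


def grid_layout(
    n_rows: int,
    n_cols: int,
    tspec: TransectionSpec,
    margin_px: float = 60.0,
) -> SyntheticSpec:
    """Spec for an n_rows x n_cols grid of identical sections on one scan.

    Mirrors the acquisition convention of laying 12 sections (4 rows of
    3, or any grid) on the scanner bed at once.
    """
    pitch = 2 * tspec.outer_radius_px + 2 * margin_px
    shape = (int(n_rows * pitch), int(n_cols * pitch))
    specs = []
    for i in range(n_rows):
        for j in range(n_cols):
            center = ((i + 0.5) * pitch, (j + 0.5) * pitch)
            specs.append(replace(tspec, center=center))
    return SyntheticSpec(image_shape=shape, transections=tuple(specs))


def composite_scene(spec: SyntheticSpec) -> tuple[ScanImage, GroundTruth]:
    """Render a multi-transection scene, checking for overlap first."""
    rows, cols = spec.image_shape
    for i, a in enumerate(spec.transections):
        if not (
            0 <= a.center[0] - a.outer_radius_px
            and a.center[0] + a.outer_radius_px <= rows
            and 0 <= a.center[1] - a.outer_radius_px
            and a.center[1] + a.outer_radius_px <= cols
        ):
            raise SyntheticSpecError(f"transection {i} does not fit the image")
        for j, b in enumerate(spec.transections[:i]):
            dist = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
            if dist < a.outer_radius_px + b.outer_radius_px:
                raise SyntheticSpecError(f"transections {j} and {i} overlap")
    return generate(spec)


def match_centers(
    detected: np.ndarray | list,
    truth: np.ndarray | list,
    max_dist_px: float = 8.0,
) -> dict:
    """One-to-one matching of detected vs true centers.

    Hungarian assignment on Euclidean distance; pairs farther apart than
    ``max_dist_px`` never match.  Returns counts plus recall (matched /
    true) and precision (matched / detected).
    """
    det = np.asarray(detected, dtype=float).reshape(-1, 2)
    tru = np.asarray(truth, dtype=float).reshape(-1, 2)
    if det.size == 0 or tru.size == 0:
        n_matched = 0
    else:
        dist = cdist(det, tru)
        cost = np.where(dist <= max_dist_px, dist, 1e6)
        ri, ci = linear_sum_assignment(cost)
        n_matched = int(np.sum(dist[ri, ci] <= max_dist_px))
    n_det, n_true = len(det), len(tru)
    return {
        "n_detected": n_det,
        "n_true": n_true,
        "n_matched": n_matched,
        "recall": n_matched / n_true if n_true else float("nan"),
        "precision": n_matched / n_det if n_det else float("nan"),
    }
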