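"""Image quantification: fibril area fraction, cell/nucleus morphometry and
cell–cell junction thickness.

Fibril pipeline: multi-orientation linear top-hat enhancement ("openlines"
style) → threshold → foreground area fraction.

Monolayer pipeline: nuclei as primary objects (threshold, hole filling,
distance-transform watershed declumping), cells as secondary objects (seeded
watershed on the junction/actin intensity landscape), per-object shape
metrics (area, perimeter, eccentricity, form factor), and junction thickness
from the skeleton of the cleaned junction mask via the Euclidean distance
transform (vessel-diameter convention: thickness = 2 x distance at skeleton
pixels, averaged over random regions of interest).

Conventions: 8-connected foreground, 0-based (row, column) pixel coordinates.
Areas use hole-filled regions; perimeters use the raw boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure, morphology, segmentation
from skimage.draw import line as draw_line
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu

__all__ = [
    "LabeledObjects",
    "JunctionThicknessResult",
    "enhance_lines",
    "threshold_image",
    "fibril_area_fraction",
    "identify_nuclei",
    "identify_cells",
    "shape_metrics",
    "clean_junction_image",
    "junction_thickness",
]


@dataclass
class LabeledObjects:
    """Integer label map (0 = background, ids contiguous from 1) with
    per-object shape metrics."""

    labels: np.ndarray
    pixel_size: float
    metrics: pd.DataFrame  # object_id, area_um2, perimeter_um, eccentricity, form_factor

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())


@dataclass
class JunctionThicknessResult:
    cleaned_mask: np.ndarray
    skeleton: np.ndarray
    roi_thicknesses: list[float]  # um, one per ROI
    mean_thickness: float         # um
    n_rois: int


# ---------------------------------------------------------------------------
# fibrils
# ---------------------------------------------------------------------------

def _line_footprint(length: int, angle: float) -> np.ndarray:
    """Binary line structuring element of given length through the center."""
    half = (length - 1) / 2
    r0 = int(round(half - half * np.sin(angle)))
    c0 = int(round(half - half * np.cos(angle)))
    r1 = int(round(half + half * np.sin(angle)))
    c1 = int(round(half + half * np.cos(angle)))
    fp = np.zeros((length, length), dtype=bool)
    rr, cc = draw_line(r0, c0, r1, c1)
    fp[rr, cc] = True
    return fp


def enhance_lines(image: np.ndarray, line_length: int = 9, n_orientations: int = 8) -> np.ndarray:
    """Curvilinear-feature enhancement: maximum over orientations of the
    morphological white top-hat with linear structuring elements.

    Retains thin bright lines at near-input intensity while suppressing
    blob-like and flat background; output is non-negative.
    """
    image = np.asarray(image, dtype=float)
    if line_length < 3 or line_length % 2 == 0:
        raise ValueError("line_length must be odd and >= 3")
    if line_length > min(image.shape):
        raise ValueError("line_length larger than the image")
    if n_orientations < 1:
        raise ValueError("n_orientations must be >= 1")
    out = np.zeros_like(image)
    for k in range(n_orientations):
        fp = _line_footprint(line_length, np.pi * k / n_orientations)
        np.maximum(out, morphology.white_tophat(image, footprint=fp), out=out)
    return np.clip(out, 0.0, None)


def threshold_image(image: np.ndarray, method: str = "otsu",
                    threshold: float | None = None) -> tuple[np.ndarray, dict]:
    """Binary mask with provenance.  ``method`` is "otsu" or "fixed"."""
    image = np.asarray(image, dtype=float)
    if method == "otsu":
        if np.ptp(image) == 0:
            raise ValueError("constant image: Otsu undefined, use method='fixed'")
        thr = float(threshold_otsu(image))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold value")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown method {method!r}")
    return image >= thr, {"method": method, "threshold": thr}


def fibril_area_fraction(mask: np.ndarray) -> float:
    """Foreground pixels / total pixels, in [0, 1]."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("empty mask")
    return float(mask.sum() / mask.size)


# ---------------------------------------------------------------------------
# nuclei and cells
# ---------------------------------------------------------------------------

def _boundary_perimeter(mask: np.ndarray, window: int = 5) -> float:
    """Boundary-polygon length with light contour smoothing.

    The marching-squares contour of a binary region overestimates smooth
    boundaries by ~5% (staircase bias) while being near-exact on straight
    axis-aligned edges; a short circular moving average over the contour
    vertices removes the staircase so discs and rectangles both measure close
    to their analytic perimeters.  Open (clipped) contours are left
    unsmoothed.
    """
    total = 0.0
    padded = np.pad(mask.astype(float), 1)
    for contour in measure.find_contours(padded, 0.5):
        closed = np.allclose(contour[0], contour[-1])
        pts = contour[:-1] if closed else contour
        if not closed or len(pts) < window:
            diffs = np.diff(contour, axis=0)
            total += np.sqrt((diffs**2).sum(axis=1)).sum()
            continue
        half = window // 2
        kernel = np.ones(window) / window
        wrapped = np.vstack([pts[-half:], pts, pts[:half]])
        smooth = np.column_stack([
            np.convolve(wrapped[:, 0], kernel, "valid"),
            np.convolve(wrapped[:, 1], kernel, "valid"),
        ])
        diffs = np.diff(np.vstack([smooth, smooth[:1]]), axis=0)
        total += np.sqrt((diffs**2).sum(axis=1)).sum()
    return total


def shape_metrics(labels: np.ndarray, pixel_size: float) -> pd.DataFrame:
    """Per-object area (um^2, holes filled), perimeter (um, smoothed boundary
    polygon), eccentricity of the moment-matched ellipse, and form factor
    4*pi*A/P^2 (1 for a circle, lower for irregular shapes)."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    rows = []
    for rp in measure.regionprops(labels):
        area = rp.area_filled * pixel_size**2
        perim = _boundary_perimeter(rp.image) * pixel_size
        rows.append({
            "object_id": rp.label,
            "area_um2": float(area),
            "perimeter_um": float(perim),
            "eccentricity": float(rp.eccentricity),
            "form_factor": float(4 * np.pi * area / perim**2) if perim > 0 else np.nan,
        })
    return pd.DataFrame(rows, columns=["object_id", "area_um2", "perimeter_um",
                                       "eccentricity", "form_factor"])


def identify_nuclei(
    dapi: np.ndarray,
    pixel_size: float,
    min_area: float = 50.0,
    max_area: float = 1500.0,
) -> LabeledObjects:
    """Primary objects: threshold → fill holes → distance-transform watershed
    declumping → size filter (areas in um^2).  Zero objects is a valid result."""
    dapi = np.asarray(dapi, dtype=float)
    if np.ptp(dapi) == 0:
        labels = np.zeros(dapi.shape, dtype=np.int32)
        return LabeledObjects(labels, pixel_size, shape_metrics(labels, pixel_size))
    mask, _ = threshold_image(dapi, "otsu")
    mask = ndi.binary_fill_holes(mask)
    distance = ndi.distance_transform_edt(mask)
    min_radius_px = max(3, int(round(np.sqrt(min_area / np.pi) / pixel_size)))
    coords = peak_local_max(distance, min_distance=min_radius_px, labels=mask)
    markers = np.zeros(dapi.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, coords.shape[0] + 1)
    labels = segmentation.watershed(-distance, markers, mask=mask)
    # size filter and contiguous relabel
    out = np.zeros_like(labels)
    next_id = 1
    for rp in measure.regionprops(labels):
        area = rp.area * pixel_size**2
        if min_area <= area <= max_area:
            out[labels == rp.label] = next_id
            next_id += 1
    return LabeledObjects(out, pixel_size, shape_metrics(out, pixel_size))


def identify_cells(
    intensity: np.ndarray,
    nuclei: LabeledObjects,
    foreground: np.ndarray | None = None,
    smoothing_sigma: float = 2.0,
) -> LabeledObjects:
    """Secondary objects: seeded watershed from the nuclei on an elevation
    map given by the (smoothed) junction/actin intensity, restricted to the
    foreground (whole frame for a confluent monolayer).  Every cell contains
    exactly one nucleus and the cells partition the foreground."""
    if nuclei.n_objects < 1:
        raise ValueError("need at least one nucleus seed")
    intensity = np.asarray(intensity, dtype=float)
    if foreground is None:
        foreground = np.ones(intensity.shape, dtype=bool)
    elevation = ndi.gaussian_filter(intensity, smoothing_sigma)
    labels = segmentation.watershed(elevation, nuclei.labels.astype(np.int32),
                                    mask=foreground)
    return LabeledObjects(labels, nuclei.pixel_size,
                          shape_metrics(labels, nuclei.pixel_size))


# ---------------------------------------------------------------------------
# junctions
# ---------------------------------------------------------------------------

def clean_junction_image(
    vecad: np.ndarray,
    nuclei: LabeledObjects | None = None,
    artifact_form_factor: float = 0.8,
    artifact_max_area: float = 400.0,
    nuclei_dilation_px: int = 2,
    pixel_size: float = 1.0,
) -> np.ndarray:
    """Isolate the junction network from a junction-stain image.

    Thresholds the image, zeroes pixels inside (dilated) nuclei, and removes
    connected components that are both compact (form factor above the
    threshold) and small (area below ``artifact_max_area`` um^2) — the
    rounded, brightly stained dead-cell artifacts."""
    mask, _ = threshold_image(np.asarray(vecad, dtype=float), "otsu")
    if nuclei is not None:
        pixel_size = nuclei.pixel_size
        nuc = nuclei.labels > 0
        if nuclei_dilation_px > 0:
            nuc = ndi.binary_dilation(nuc, morphology.disk(nuclei_dilation_px))
        mask &= ~nuc
    labels = measure.label(mask, connectivity=2)
    remove = np.zeros(labels.max() + 1, dtype=bool)
    for rp in measure.regionprops(labels):
        area = rp.area_filled * pixel_size**2
        perim = _boundary_perimeter(rp.image) * pixel_size
        ff = 4 * np.pi * area / perim**2 if perim > 0 else 1.0
        if ff > artifact_form_factor and area < artifact_max_area:
            remove[rp.label] = True
    mask[remove[labels]] = False
    return mask


def junction_thickness(
    mask: np.ndarray,
    pixel_size: float,
    n_rois: int = 4,
    roi_size: int = 256,
    seed: int = 0,
    max_attempts: int = 1000,
) -> JunctionThicknessResult:
    """Skeleton + distance-transform thickness averaged over random ROIs.

    Thickness at a skeleton pixel is twice its Euclidean distance to the
    background.  ROIs are square windows with uniform-random top-left corners
    (redrawn if they contain no skeleton pixel; they may overlap); the result
    is the unweighted mean of the per-ROI mean thicknesses, in um.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    skeleton = morphology.skeletonize(mask)
    if not skeleton.any():
        raise ValueError("mask has no skeleton pixels")
    distance = ndi.distance_transform_edt(mask)
    thickness = 2.0 * distance * pixel_size
    h, w = mask.shape
    rh, rw = min(roi_size, h), min(roi_size, w)
    rng = np.random.default_rng(seed)
    roi_means: list[float] = []
    for _ in range(n_rois):
        for _attempt in range(max_attempts):
            r0 = rng.integers(0, h - rh + 1)
            c0 = rng.integers(0, w - rw + 1)
            sk = skeleton[r0:r0 + rh, c0:c0 + rw]
            if sk.any():
                roi_means.append(float(thickness[r0:r0 + rh, c0:c0 + rw][sk].mean()))
                break
        else:
            raise RuntimeError("could not place an ROI containing skeleton pixels")
    return JunctionThicknessResult(
        cleaned_mask=mask, skeleton=skeleton,
        roi_thicknesses=roi_means,
        mean_thickness=float(np.mean(roi_means)),
        n_rois=n_rois,
    )
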