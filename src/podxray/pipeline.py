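"""Image treatment: from holder projections to per-pod virtual-biomass images.

The chain is: crop the holder projection into four single-pod images; average the
blank (empty-holder) projections and subtract them pixelwise, taking the absolute
value; threshold the difference image to label residual eps-grid pixels; estimate
the flat-field level i0 from a pod-free region; in-paint labeled grid pixels with
i0; and finally apply the Beer-Lambert linearization v = ln(i0 / I), clipped at 0,
yielding an image whose pixel values are proportional to the absorbing biomass
along each ray ("virtual biomass").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .phantom import HolderLayout, RawProjection

__all__ = [
    "PodImage",
    "GridLabel",
    "VirtualBiomassImage",
    "PipelineParams",
    "ProcessedPod",
    "average_blanks",
    "crop_into_pods",
    "subtract_blank_abs",
    "label_grid",
    "estimate_i0",
    "fill_grid_with_i0",
    "virtual_biomass_transform",
    "preprocess",
]

LABEL_EXPORT_WHITE = 65535


@dataclass
class PodImage:
    """One cropped single-pod image in raw detector counts."""

    pixels: np.ndarray
    pod_id: str
    projection_id: str
    slot: int


@dataclass
class GridLabel:
    """Binary mask of residual eps-grid pixels ({0,1} internally, 0/65535 on export)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def export(self) -> np.ndarray:
        return np.where(self.mask, LABEL_EXPORT_WHITE, 0).astype(np.uint16)


@dataclass
class VirtualBiomassImage:
    """Nonnegative linearized image; pixel values are optical depths ln(i0/I)."""

    pixels: np.ndarray
    i0_used: float

    def __post_init__(self) -> None:
        if np.any(self.pixels < 0):
            raise ValueError("virtual biomass values must be >= 0")

    @property
    def integral(self) -> float:
        return float(self.pixels.sum())


@dataclass(frozen=True)
class PipelineParams:
    """Tunables of the treatment chain.

    ``label_threshold`` is the absolute counts threshold on the |pod - blank|
    image (>= is labeled).  When ``label_threshold_relative`` is set, the
    threshold is instead that fraction of the mean of the cropped blank, which
    makes labeling robust to per-scan flat-field drift; the absolute value is
    retained as the real-scanner convention.  Pixels <= 0 after grid filling are
    clamped to ``count_floor`` before the log to avoid infinities.
    """

    label_threshold: float = 5250.0
    label_threshold_relative: float | None = None
    i0_region_shape: tuple[int, int] = (40, 30)
    i0_region_anchor: tuple[int, int] = (3, 3)
    count_floor: float = 1.0


def average_blanks(blanks: list[RawProjection | np.ndarray]) -> np.ndarray:
    """Pixelwise arithmetic mean of two or more blank projections (float image)."""
    imgs = [b.pixels if isinstance(b, RawProjection) else np.asarray(b) for b in blanks]
    if len(imgs) < 2:
        raise ValueError("need at least 2 blank projections")
    shapes = {im.shape for im in imgs}
    if len(shapes) != 1:
        raise ValueError(f"blank shapes differ: {shapes}")
    return np.mean(np.stack([im.astype(float) for im in imgs]), axis=0)


def crop_into_pods(proj: RawProjection, layout: HolderLayout) -> list[PodImage]:
    """Crop one holder projection into four single-pod images (one per slot)."""
    rows, cols = proj.pixels.shape
    pods = []
    for slot, (r0, r1, c0, c1) in enumerate(layout.slots):
        if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
            raise ValueError(f"slot {slot} {(r0, r1, c0, c1)} outside projection bounds")
        pods.append(
            PodImage(
                pixels=proj.pixels[r0:r1, c0:c1].copy(),
                pod_id=f"{proj.projection_id}_s{slot}",
                projection_id=proj.projection_id,
                slot=slot,
            )
        )
    return pods


def crop_like(image: np.ndarray, layout: HolderLayout, slot: int) -> np.ndarray:
    """Crop an arbitrary full-detector image with a slot's crop window."""
    r0, r1, c0, c1 = layout.slots[slot]
    return image[r0:r1, c0:c1]


def subtract_blank_abs(pod: PodImage | np.ndarray, blank_crop: np.ndarray) -> np.ndarray:
    """|pod - mean blank| pixelwise (square-then-square-root is exactly |x|)."""
    px = pod.pixels if isinstance(pod, PodImage) else np.asarray(pod)
    if px.shape != blank_crop.shape:
        raise ValueError(f"shape mismatch: {px.shape} vs {blank_crop.shape}")
    return np.abs(px.astype(float) - blank_crop.astype(float))


def label_grid(abs_image: np.ndarray, threshold: float = 5250.0) -> GridLabel:
    """Label residual eps-grid pixels: abs difference >= threshold is grid."""
    if not 0 <= threshold <= 65535:
        raise ValueError("threshold must be within the 16-bit range")
    return GridLabel(mask=np.asarray(abs_image) >= threshold)


def _region_slices(anchor: tuple[int, int], shape: tuple[int, int]) -> tuple[slice, slice]:
    return slice(anchor[0], anchor[0] + shape[0]), slice(anchor[1], anchor[1] + shape[1])


def estimate_i0(
    pod: PodImage | np.ndarray,
    label: GridLabel | None = None,
    region_shape: tuple[int, int] = (40, 30),
    anchor: tuple[int, int] = (3, 3),
) -> float:
    """Mean gray value of a small pod-free region: the per-image flat-field i0.

    The default region sits at a fixed offset in the crop corner.  If it touches
    a grid label or a low-count area (the pod silhouette, detected as mean below
    80% of the image median, the median being background-dominated), the region
    is slid along the image border until a clear position is found; a warning is
    emitted when relocation happens.
    """
    px = (pod.pixels if isinstance(pod, PodImage) else np.asarray(pod)).astype(float)
    rows, cols = px.shape
    h, w = region_shape
    if h > rows or w > cols:
        raise ValueError(f"i0 region {region_shape} larger than image {px.shape}")
    background = float(np.median(px))

    def ok(a: tuple[int, int]) -> bool:
        sl = _region_slices(a, region_shape)
        if label is not None and label.mask[sl].any():
            return False
        return float(px[sl].mean()) >= 0.8 * background

    if ok(anchor):
        return float(px[_region_slices(anchor, region_shape)].mean())

    candidates: list[tuple[int, int]] = []
    step = max(2, min(h, w) // 2)
    for c in range(0, cols - w + 1, step):  # top and bottom borders
        candidates += [(anchor[0], c), (rows - h - anchor[0], c)]
    for r in range(0, rows - h + 1, step):  # left and right borders
        candidates += [(r, anchor[1]), (r, cols - w - anchor[1])]
    for a in candidates:
        if a[0] >= 0 and a[1] >= 0 and ok(a):
            warnings.warn(
                f"i0 region relocated from {anchor} to {a} (grid label or pod overlap)",
                stacklevel=2,
            )
            return float(px[_region_slices(a, region_shape)].mean())
    raise ValueError("no pod-free, label-free i0 region found along the image border")


def fill_grid_with_i0(
    pod: PodImage | np.ndarray, label: GridLabel, i0: float
) -> np.ndarray:
    """Replace labeled grid pixels with i0, leaving everything else untouched."""
    px = (pod.pixels if isinstance(pod, PodImage) else np.asarray(pod)).astype(float)
    if px.shape != label.mask.shape:
        raise ValueError("pod image and grid label shapes differ")
    out = px.copy()
    out[label.mask] = i0
    return out


def virtual_biomass_transform(
    filled: np.ndarray, i0: float, count_floor: float = 1.0
) -> VirtualBiomassImage:
    """Beer-Lambert linearization v = max(0, ln(i0 / I)).

    Inverts the exponential absorption law so pixel values become attenuation
    line integrals, linearly related to the biomass along each ray; negative
    values (pixels brighter than i0, i.e. pure noise) are clipped to 0.  Pixels
    at or below zero counts are clamped to ``count_floor`` before the log.
    """
    if i0 <= 0:
        raise ValueError(f"i0 must be positive, got {i0}")
    counts = np.maximum(np.asarray(filled, dtype=float), count_floor)
    v = np.log(i0 / counts)
    return VirtualBiomassImage(pixels=np.clip(v, 0.0, None), i0_used=float(i0))


@dataclass
class ProcessedPod:
    """Everything the predictors need for one pod.

    ``filled`` is the grid-in-painted intensity image (the Otsu segmentation
    domain); ``vb`` the virtual-biomass image (CNN input and XRT integrand).
    """

    pod_id: str
    projection_id: str
    slot: int
    raw: np.ndarray
    label: GridLabel
    i0: float
    filled: np.ndarray
    vb: VirtualBiomassImage


def preprocess(
    projections: list[RawProjection],
    blanks: list[RawProjection],
    layout: HolderLayout,
    params: PipelineParams | None = None,
) -> tuple[list[ProcessedPod], pd.DataFrame]:
    """Run the full treatment chain on a batch of holder projections.

    Returns the processed pods (in projection-then-slot order) and a provenance
    log with the i0, grid-label pixel count and virtual-biomass integral of
    every pod.  The function is a pure function of its inputs and parameters.
    """
    params = params or PipelineParams()
    mean_blank = average_blanks(blanks)
    processed: list[ProcessedPod] = []
    rows: list[dict] = []
    for proj in projections:
        for pod in crop_into_pods(proj, layout):
            blank_crop = crop_like(mean_blank, layout, pod.slot)
            diff = subtract_blank_abs(pod, blank_crop)
            if params.label_threshold_relative is not None:
                thr = params.label_threshold_relative * float(blank_crop.mean())
            else:
                thr = params.label_threshold
            label = label_grid(diff, threshold=thr)
            i0 = estimate_i0(
                pod,
                label,
                region_shape=params.i0_region_shape,
                anchor=params.i0_region_anchor,
            )
            filled = fill_grid_with_i0(pod, label, i0)
            vb = virtual_biomass_transform(filled, i0, count_floor=params.count_floor)
            processed.append(
                ProcessedPod(
                    pod_id=pod.pod_id,
                    projection_id=pod.projection_id,
                    slot=pod.slot,
                    raw=pod.pixels,
                    label=label,
                    i0=i0,
                    filled=filled,
                    vb=vb,
                )
            )
            rows.append(
                {
                    "pod_id": pod.pod_id,
                    "i0": i0,
                    "n_label_px": label.n_pixels,
                    "vb_sum": vb.integral,
                }
            )
    return processed, pd.DataFrame(rows)


def export_vb(vb: VirtualBiomassImage, path) -> None:
    """Write a virtual-biomass image as 32-bit float TIFF."""
    tifffile.imwrite(path, vb.pixels.astype(np.float32))
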