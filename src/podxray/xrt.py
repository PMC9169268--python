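"""XRT prediction pathway: segment kernels, integrate virtual biomass, calibrate.

The kernel mask is found on the grid-filled intensity image by Otsu's method
(exhaustive minimization of the within-class variance) with a fixed offset
subtracted from the threshold so the faint shell falls into the background;
the mask is refined by a morphological erosion (5x5 ellipse) followed by a
dilation (9x9 ellipse).  Kernel and shell integrals of the virtual-biomass
image are then mapped to grams by per-trait ordinary least squares against
gravimetric ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from skimage.morphology import dilation as _sk_dilation
from skimage.morphology import erosion as _sk_erosion

from .pipeline import VirtualBiomassImage

__all__ = [
    "KernelMask",
    "CalibrationModel",
    "otsu_threshold",
    "ellipse_se",
    "segment_kernel",
    "integrate_masked",
    "fit_calibration",
    "predict_weights_xrt",
]


def otsu_threshold(image: np.ndarray, n_levels: int | None = None) -> float:
    """Otsu's threshold by exhaustive search over candidate gray levels.

    Minimizes the within-class variance
    ``sigma_w^2(t) = w0(t) sigma0^2(t) + w1(t) sigma1^2(t)`` with class 0 the
    pixels < t and class 1 the pixels >= t (equivalently, maximizes the
    between-class variance).  Candidates are every distinct pixel value, or the
    edges of an ``n_levels`` equal-width binning when given; ties are broken by
    the smallest minimizing threshold.
    """
    x = np.asarray(image, dtype=float).ravel()
    values, counts = np.unique(x, return_counts=True)
    if values.size < 2:
        raise ValueError("Otsu threshold undefined for a constant image")
    if n_levels is not None and values.size > n_levels:
        hist, edges = np.histogram(x, bins=n_levels)
        values = edges[:-1]
        counts = hist
        keep = counts > 0
        values, counts = values[keep], counts[keep]

    # cumulative class statistics; candidate t = values[k] puts values[:k] in
    # class 0 (pixels < t) and values[k:] in class 1 (pixels >= t)
    w = counts.astype(float)
    total = w.sum()
    csum = np.cumsum(w)
    cmean = np.cumsum(w * values)
    ctot = cmean[-1]
    csq = np.cumsum(w * values**2)
    sqtot = csq[-1]

    n0 = np.concatenate([[0.0], csum[:-1]])
    s0 = np.concatenate([[0.0], cmean[:-1]])
    q0 = np.concatenate([[0.0], csq[:-1]])
    n1 = total - n0
    s1 = ctot - s0
    q1 = sqtot - q0

    with np.errstate(invalid="ignore", divide="ignore"):
        var0 = np.where(n0 > 0, q0 / np.maximum(n0, 1) - (s0 / np.maximum(n0, 1)) ** 2, 0.0)
        var1 = np.where(n1 > 0, q1 / np.maximum(n1, 1) - (s1 / np.maximum(n1, 1)) ** 2, 0.0)
    sigma_w = (n0 / total) * var0 + (n1 / total) * var1
    # skip k=0 (empty class 0): that split is degenerate (everything class 1)
    k = 1 + int(np.argmin(sigma_w[1:]))
    return float(values[k])


def ellipse_se(size: int) -> np.ndarray:
    """Rasterized ellipse structuring element of odd ``size``.

    Pixels whose centers satisfy (dr/a)^2 + (dc/a)^2 <= 1 with a = (size-1)/2;
    at 5x5 and 9x9 this is the discrete disc used for the mask refinement.
    """
    if size < 1 or size % 2 == 0:
        raise ValueError("structuring element size must be odd and positive")
    a = (size - 1) / 2
    r = np.arange(size) - a
    if a == 0:
        return np.ones((1, 1), dtype=bool)
    return (r[:, None] / a) ** 2 + (r[None, :] / a) ** 2 <= 1.0


def binary_erode(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Binary erosion with outside-the-image treated as background.

    A pixel survives only if the whole SE fits inside the in-image foreground.
    """
    r = se.shape[0] // 2
    padded = np.pad(np.asarray(mask, dtype=bool), r, constant_values=False)
    return _sk_erosion(padded, se)[r:-r, r:-r] if r else padded


def binary_dilate(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Binary dilation: a pixel turns on if the reflected SE hits the foreground."""
    return _sk_dilation(np.asarray(mask, dtype=bool), se)


@dataclass
class KernelMask:
    """Binary kernel mask with the parameters that produced it."""

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    def export(self) -> np.ndarray:
        return np.where(self.mask, 255, 0).astype(np.uint8)


def segment_kernel(
    image: np.ndarray,
    offset: float = 50.0,
    erosion_size: int = 5,
    dilation_size: int = 9,
    vb_domain: bool = False,
) -> KernelMask:
    """Kernel segmentation: threshold at (Otsu - offset), then refine morphology.

    On the intensity image kernels are the darkest structures, so the foreground
    is every pixel strictly below the shifted threshold; erosion with the small
    ellipse removes speckle, dilation with the larger ellipse restores (and
    slightly grows) the kernel footprint, recovering the soft projected rim.

    With ``vb_domain=True`` the same procedure runs on the virtual-biomass image
    rescaled to the 16-bit range with inverted polarity (so kernels are again
    the low tail), for pipelines that segment the transformed image instead.
    """
    img = np.asarray(image, dtype=float)
    if vb_domain:
        rng = img.max() - img.min()
        if rng == 0:
            raise ValueError("Otsu threshold undefined for a constant image")
        img = (1.0 - (img - img.min()) / rng) * 65535.0
    t = otsu_threshold(img)
    thr = t - offset
    raw = img < thr
    if not raw.any():
        import warnings

        warnings.warn(
            f"offset {offset} pushed threshold ({thr}) below the minimum pixel; empty mask",
            stacklevel=2,
        )
    mask = binary_dilate(binary_erode(raw, ellipse_se(erosion_size)), ellipse_se(dilation_size))
    return KernelMask(
        mask=mask,
        provenance={
            "otsu_t": t,
            "offset": offset,
            "erosion_size": erosion_size,
            "dilation_size": dilation_size,
            "vb_domain": vb_domain,
        },
    )


def integrate_masked(
    vb: VirtualBiomassImage | np.ndarray,
    mask: KernelMask | np.ndarray,
    invert: bool = False,
) -> float:
    """Sum of virtual biomass under the mask (or its complement with invert)."""
    v = vb.pixels if isinstance(vb, VirtualBiomassImage) else np.asarray(vb, dtype=float)
    m = mask.mask if isinstance(mask, KernelMask) else np.asarray(mask, dtype=bool)
    if v.shape != m.shape:
        raise ValueError(f"shape mismatch: {v.shape} vs {m.shape}")
    sel = ~m if invert else m
    return float(v[sel].sum())


@dataclass
class CalibrationModel:
    """Per-trait linear map grams = slope * integrated_vb + intercept."""

    trait: str
    slope: float
    intercept: float
    n: int
    diagnostics: dict = field(default_factory=dict)

    def predict(self, integral: float | np.ndarray) -> np.ndarray:
        """Apply the calibration; negative masses are floored at 0."""
        return np.clip(self.slope * np.asarray(integral, dtype=float) + self.intercept, 0.0, None)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "trait": self.trait,
                    "slope": self.slope,
                    "intercept": self.intercept,
                    "n": self.n,
                    "diagnostics": self.diagnostics,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def fit_calibration(
    integrals: np.ndarray, grams: np.ndarray, trait: str
) -> CalibrationModel:
    """Ordinary least squares of gravimetric weight on integrated virtual biomass."""
    x = np.asarray(integrals, dtype=float)
    y = np.asarray(grams, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("calibration needs at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("integrated values have zero variance; cannot calibrate")
    res = stats.linregress(x, y)
    pred = res.slope * x + res.intercept
    diag = {
        "r": float(res.rvalue),
        "r2": float(res.rvalue**2),
        "mse": float(np.mean((pred - y) ** 2)),
        "mae": float(np.mean(np.abs(pred - y))),
    }
    return CalibrationModel(
        trait=trait,
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=int(x.size),
        diagnostics=diag,
    )


def predict_weights_xrt(
    vb: VirtualBiomassImage | np.ndarray,
    mask: KernelMask | np.ndarray,
    models: dict[str, CalibrationModel],
) -> tuple[float, float]:
    """Predict (kernel_g, shell_g) for one pod from its VB image and kernel mask."""
    for trait in ("kernel", "shell"):
        if trait not in models:
            raise KeyError(f"missing calibration model for trait {trait!r}")
    k_int = integrate_masked(vb, mask, invert=False)
    s_int = integrate_masked(vb, mask, invert=True)
    return (
        float(models["kernel"].predict(k_int)),
        float(models["shell"].predict(s_int)),
    )
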