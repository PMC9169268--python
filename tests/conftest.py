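"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the implementation's code paths: chord
lengths come from quadratic root-finding, Otsu from a double loop over
candidate thresholds, morphology from explicit structuring-element sweeps,
and regression metrics from textbook sum formulas.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from podxray import phantom as ph
from podxray import pipeline as pl


@pytest.fixture(scope="session")
def desk_cfg() -> ph.ScanConfig:
    return ph.desk_config(seed=11)


@pytest.fixture(scope="session")
def layout(desk_cfg) -> ph.HolderLayout:
    return ph.HolderLayout.from_detector(desk_cfg.detector_shape)


@pytest.fixture(scope="session")
def desk_params() -> pl.PipelineParams:
    return pl.PipelineParams(label_threshold_relative=0.75, i0_region_shape=(8, 8))


@pytest.fixture(scope="session")
def small_batch(desk_cfg, layout):
    """Ten noisy holder projections (40 pods) with blanks and ground truth."""
    return ph.simulate_batch(10, desk_cfg, layout)


@pytest.fixture(scope="session")
def processed_batch(small_batch, layout, desk_params):
    projections, blanks, records = small_batch
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        processed, provenance = pl.preprocess(projections, blanks, layout, desk_params)
    return processed, provenance, records


# ------------------------------------------------------------------ oracles


def chord_by_roots(ellipsoid, u: float, v: float) -> float:
    """z-chord through an ellipsoid via the roots of the ray-surface quadratic."""
    cu, cv, cz = ellipsoid.center
    au, av, az = ellipsoid.semi
    # ((u-cu)/au)^2 + ((v-cv)/av)^2 + ((z-cz)/az)^2 = 1, solve for z
    c0 = ((u - cu) / au) ** 2 + ((v - cv) / av) ** 2 - 1.0
    # (dz/az)^2 = -c0  ->  quadratic z^2/az^2 - ... ; use np.roots on [1/az^2, -2cz/az^2, cz^2/az^2 + c0]
    roots = np.roots([1.0 / az**2, -2.0 * cz / az**2, cz**2 / az**2 + c0])
    if np.iscomplexobj(roots) and np.any(np.abs(roots.imag) > 1e-12):
        return 0.0
    roots = np.real(roots)
    return float(abs(roots[0] - roots[1]))


def brute_otsu(image: np.ndarray) -> float:
    """Exhaustive within-class-variance minimization, smallest-t tie-break."""
    x = np.asarray(image, dtype=float).ravel()
    values = np.unique(x)
    best_t, best = None, np.inf
    n = x.size
    for t in values[1:]:  # t = values[0] leaves class 0 empty
        lo, hi = x[x < t], x[x >= t]
        s = 0.0
        if lo.size:
            s += lo.size / n * lo.var()
        if hi.size:
            s += hi.size / n * hi.var()
        if s < best - 1e-12:
            best, best_t = s, t
    return float(best_t)


def brute_erosion(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Erosion by definition: the SE, centered at p, fits entirely in the mask."""
    r = se.shape[0] // 2
    padded = np.pad(mask, r, constant_values=False)
    out = np.zeros_like(mask)
    offs = [(i - r, j - r) for i in range(se.shape[0]) for j in range(se.shape[1]) if se[i, j]]
    for p in range(mask.shape[0]):
        for q in range(mask.shape[1]):
            out[p, q] = all(padded[p + r + di, q + r + dj] for di, dj in offs)
    return out


def brute_dilation(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Dilation by definition: the reflected SE, centered at p, hits the mask."""
    r = se.shape[0] // 2
    padded = np.pad(mask, r, constant_values=False)
    out = np.zeros_like(mask)
    offs = [(i - r, j - r) for i in range(se.shape[0]) for j in range(se.shape[1]) if se[i, j]]
    for p in range(mask.shape[0]):
        for q in range(mask.shape[1]):
            out[p, q] = any(padded[p + r - di, q + r - dj] for di, dj in offs)
    return out


def metric_formulas(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Textbook sum formulas for r, R^2, MSE, MAE, OLS slope/intercept."""
    x, y = np.asarray(truth, float), np.asarray(pred, float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    cov = sxy / n - sx / n * sy / n
    vx = sxx / n - (sx / n) ** 2
    vy = syy / n - (sy / n) ** 2
    r = cov / np.sqrt(vx * vy)
    slope = cov / vx
    intercept = sy / n - slope * sx / n
    err = y - x
    return {
        "r": r,
        "r2": r * r,
        "mse": float(np.mean(err**2)),
        "mae": float(np.mean(np.abs(err))),
        "slope": slope,
        "intercept": intercept,
    }
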