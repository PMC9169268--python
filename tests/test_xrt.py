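"""XRT tests: Otsu against brute force, morphology by definition, calibration."""

import warnings

import numpy as np
import pytest

from podxray import phantom as ph
from podxray import pipeline as pl
from podxray import xrt

from conftest import brute_dilation, brute_erosion, brute_otsu


# ------------------------------------------------------------------ Otsu


def test_otsu_equals_brute_force_on_random_images():
    rng = np.random.default_rng(0)
    for _ in range(40):
        img = rng.integers(0, 30, size=(8, 8)).astype(float)
        if np.unique(img).size < 2:
            continue
        assert xrt.otsu_threshold(img) == brute_otsu(img)


def test_otsu_separates_bimodal_point_masses():
    img = np.concatenate([np.full(1000, 1500.0), np.full(1000, 4800.0)])
    t = xrt.otsu_threshold(img)
    assert 1500.0 < t <= 4800.0


def test_otsu_shift_equivariance():
    rng = np.random.default_rng(1)
    img = rng.integers(0, 50, size=(10, 10)).astype(float)
    t = xrt.otsu_threshold(img)
    for c in (10.0, 123.0, -7.0):
        assert xrt.otsu_threshold(img + c) == pytest.approx(t + c, abs=1e-9)


def test_otsu_constant_image_errors():
    with pytest.raises(ValueError, match="constant"):
        xrt.otsu_threshold(np.full((5, 5), 3.0))


def test_otsu_tie_break_smallest():
    # symmetric histogram: both central splits minimize; smallest must win
    img = np.array([0.0, 0.0, 1.0, 2.0, 3.0, 3.0])
    assert xrt.otsu_threshold(img) == brute_otsu(img)


# ------------------------------------------------------------------ morphology


def test_ellipse_se_rasterization():
    se5 = xrt.ellipse_se(5)
    r = np.arange(5) - 2.0
    pred = (r[:, None] / 2) ** 2 + (r[None, :] / 2) ** 2 <= 1
    assert np.array_equal(se5, pred)
    assert xrt.ellipse_se(1).tolist() == [[True]]
    with pytest.raises(ValueError):
        xrt.ellipse_se(4)


@pytest.mark.parametrize("size", [5, 9])
def test_morphology_equals_brute_force(size):
    se = xrt.ellipse_se(size)
    rng = np.random.default_rng(size)
    for _ in range(10):
        mask = rng.random((32, 32)) < 0.45
        assert np.array_equal(xrt.binary_erode(mask, se), brute_erosion(mask, se))
        assert np.array_equal(xrt.binary_dilate(mask, se), brute_dilation(mask, se))


def test_single_pixel_removed_by_erosion():
    img = np.full((40, 40), 5000.0)
    img[20, 20] = 100.0  # one isolated dark pixel below any threshold
    mask = xrt.segment_kernel(img, offset=50)
    assert mask.mask.sum() == 0


# ------------------------------------------------------------------ segmentation


def _single_pod_processed(mu_kernel=0.12, seed=31):
    """One noiseless pod plus its true kernel silhouette on the crop grid.

    Uses the full-scale 49.5 um detector so the fixed +-2 px morphology margin
    is negligible against kernels that span hundreds of pixels.
    """
    cfg = ph.ScanConfig(rng_seed=seed, noise=False)
    layout = ph.HolderLayout.from_detector(cfg.detector_shape)
    rng = np.random.default_rng(seed)
    dist = ph.TraitDistribution(
        kernel_range=(0.4, 1.2), shell_range=(0.1, 0.6), mu_kernel=mu_kernel
    )
    pod = ph.make_pod_phantom(rng, dist, pod_id="pod")
    proj, _ = ph.project_holder([pod, None, None, None], layout, cfg, rng)
    blanks = [ph.project_blank(layout, cfg, i0=proj.truth["i0"]) for _ in range(2)]
    params = pl.PipelineParams(label_threshold_relative=0.75)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        processed, _ = pl.preprocess([proj], blanks, layout, params)
    p = cfg.pixel_size_mm
    r0, r1, c0, c1 = layout.slots[0]
    cu = 0.5 * (r0 + r1 - 1) * p
    cv = 0.5 * (c0 + c1 - 1) * p
    u = (np.arange(r0, r1) * p - cu)[:, None]
    v = (np.arange(c0, c1) * p - cv)[None, :]
    return processed[0], pod.kernel_silhouette(u, v)


def test_segment_kernel_matches_silhouette():
    """On a noiseless pod the mask overlaps the true kernel silhouette (Jaccard >= 0.95)."""
    pod, silhouette = _single_pod_processed()
    mask = xrt.segment_kernel(pod.filled).mask
    jac = (mask & silhouette).sum() / (mask | silhouette).sum()
    assert jac >= 0.95


def test_segment_kernel_excludes_shell():
    pod, silhouette = _single_pod_processed()
    mask = xrt.segment_kernel(pod.filled).mask
    outside = mask & ~silhouette
    # mask spill beyond the kernel silhouette stays a thin rim
    assert outside.sum() <= 0.3 * silhouette.sum()


def test_segment_offset_zero_is_plain_otsu():
    rng = np.random.default_rng(3)
    img = np.where(rng.random((40, 40)) < 0.3, 1500.0, 4800.0)
    img += rng.integers(0, 10, size=img.shape)  # break ties, keep two clusters
    t = xrt.otsu_threshold(img)
    expected = xrt.binary_dilate(xrt.binary_erode(img < t, xrt.ellipse_se(5)), xrt.ellipse_se(9))
    got = xrt.segment_kernel(img, offset=0)
    assert np.array_equal(got.mask, expected)
    assert got.provenance["otsu_t"] == t


def test_segment_empty_mask_warns():
    img = np.where(np.arange(100).reshape(10, 10) < 50, 4000.0, 4020.0)
    with pytest.warns(UserWarning, match="empty mask"):
        mask = xrt.segment_kernel(img, offset=5000.0)
    assert mask.mask.sum() == 0


def test_segment_vb_domain_variant():
    pod, silhouette = _single_pod_processed()
    mask = xrt.segment_kernel(pod.vb.pixels, offset=50, vb_domain=True).mask
    jac = (mask & silhouette).sum() / (mask | silhouette).sum()
    assert jac >= 0.9  # the rescaled-VB path finds the same kernels


# ------------------------------------------------------------------ integration


def test_integrate_full_mask_and_partition():
    rng = np.random.default_rng(4)
    vb = rng.random((20, 30))
    mask = rng.random((20, 30)) < 0.4
    full = xrt.integrate_masked(vb, np.ones((20, 30), dtype=bool))
    assert full == pytest.approx(vb.sum(), rel=1e-12)
    k = xrt.integrate_masked(vb, mask)
    s = xrt.integrate_masked(vb, mask, invert=True)
    assert k + s == pytest.approx(vb.sum(), rel=1e-9)  # float associativity only
    # brute-force loop oracle
    acc = 0.0
    for i in range(20):
        for j in range(30):
            if mask[i, j]:
                acc += vb[i, j]
    assert k == pytest.approx(acc, rel=1e-12)
    with pytest.raises(ValueError):
        xrt.integrate_masked(vb, np.ones((3, 3), dtype=bool))


def test_kernel_integral_monotone_in_kernel_size():
    """Enlarging the kernel (fixed shell) strictly increases the kernel integral."""
    integrals = []
    for wk in (0.3, 0.6, 0.9):
        cfg = ph.desk_config(seed=7, noise=False)
        layout = ph.HolderLayout.from_detector(cfg.detector_shape)
        dist = ph.TraitDistribution(
            kernel_range=(wk, wk), shell_range=(0.3, 0.3), n_kernel_probs=(1.0, 0, 0)
        )
        pod = ph.make_pod_phantom(np.random.default_rng(7), dist)
        proj, _ = ph.project_holder([pod, None, None, None], layout, cfg, i0=5100.0, shift=(0, 0))
        blanks = [ph.project_blank(layout, cfg, i0=5100.0) for _ in range(2)]
        params = pl.PipelineParams(label_threshold_relative=0.75, i0_region_shape=(8, 8))
        processed, _ = pl.preprocess([proj], blanks, layout, params)
        mask = xrt.segment_kernel(processed[0].filled)
        integrals.append(xrt.integrate_masked(processed[0].vb, mask))
    assert integrals[0] < integrals[1] < integrals[2]


# ------------------------------------------------------------------ calibration


def test_fit_calibration_exact_line():
    x = np.linspace(0, 10, 20)
    m = xrt.fit_calibration(x, 2 * x + 0.1, "kernel")
    assert m.slope == pytest.approx(2.0, abs=1e-12)
    assert m.intercept == pytest.approx(0.1, abs=1e-12)
    assert m.diagnostics["r2"] == pytest.approx(1.0, abs=1e-12)
    assert m.n == 20


def test_fit_calibration_noisy_recovery():
    rng = np.random.default_rng(5)
    x = rng.uniform(0, 10, 500)
    y = 2 * x + 0.1 + rng.normal(0, 0.05, 500)
    m = xrt.fit_calibration(x, y, "kernel")
    # closed-form OLS standard errors on the generated sample
    xc = x - x.mean()
    resid = y - (m.slope * x + m.intercept)
    s2 = resid @ resid / (500 - 2)
    se_slope = np.sqrt(s2 / (xc @ xc))
    se_int = np.sqrt(s2 * (1 / 500 + x.mean() ** 2 / (xc @ xc)))
    assert abs(m.slope - 2.0) < 3 * se_slope
    assert abs(m.intercept - 0.1) < 3 * se_int


def test_fit_calibration_degenerate():
    with pytest.raises(ValueError):
        xrt.fit_calibration(np.ones(10), np.arange(10.0), "kernel")
    with pytest.raises(ValueError):
        xrt.fit_calibration(np.arange(2.0), np.arange(2.0), "kernel")


def test_calibration_json_roundtrip(tmp_path):
    m = xrt.fit_calibration(np.arange(10.0), 2 * np.arange(10.0) + 1, "shell")
    m.to_json(tmp_path / "m.json")
    m2 = xrt.CalibrationModel.from_json(tmp_path / "m.json")
    assert m2.slope == m.slope and m2.trait == "shell" and m2.n == 10


def test_predict_weights_xrt_floor_and_errors():
    vb = np.zeros((4, 4))
    mask = np.zeros((4, 4), dtype=bool)
    models = {
        "kernel": xrt.CalibrationModel("kernel", slope=1.0, intercept=0.2, n=5),
        "shell": xrt.CalibrationModel("shell", slope=1.0, intercept=-0.05, n=5),
    }
    k, s = xrt.predict_weights_xrt(vb, mask, models)
    assert k == 0.2  # zero integral -> the intercept
    assert s == 0.0  # negative prediction floored at zero
    with pytest.raises(KeyError):
        xrt.predict_weights_xrt(vb, mask, {"kernel": models["kernel"]})
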