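"""Synthetic holder-projection simulator.

Generates 2-D parallel-beam X-ray projections of a four-slot extruded-polystyrene
(eps) pod holder carrying ellipsoidal peanut-pod phantoms, together with per-pod
ground-truth kernel and shell weights.  The real scan archive behind the study
design (438 holder projections, 1752 pods, 14-bit detector, raw counts roughly
707..5597, flat-field level i0 drifting within 4864.444..5382.635) is emulated
statistically; pod geometry itself is a stand-in chosen so that every ray's
attenuation line integral has a closed form (ellipsoid chord lengths), which makes
the Beer-Lambert forward model exactly testable.

Units: millimetres for geometry, grams for mass, detector counts are unitless.
Coordinates: image row = u axis, image column = v axis, beam along z;
0-based, row-major, origin top-left, rectangles half-open.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Ellipsoid",
    "ShellLobe",
    "PodPhantom",
    "TraitDistribution",
    "ScanConfig",
    "HolderLayout",
    "RawProjection",
    "PodRecord",
    "PhantomGeometryError",
    "make_pod_phantom",
    "project_holder",
    "project_blank",
    "make_dataset",
]

DETECTOR_MAX = 2 ** 14 - 1  # 14-bit CMOS sensor stored in 16-bit TIFFs


class PhantomGeometryError(RuntimeError):
    """Raised when no geometrically feasible phantom can be drawn."""


# --------------------------------------------------------------------------- geometry


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: center (u, v, z) and semi-axes (au, av, az) in mm."""

    center: tuple[float, float, float]
    semi: tuple[float, float, float]

    def __post_init__(self) -> None:
        if min(self.semi) <= 0:
            raise ValueError(f"semi-axes must be positive, got {self.semi}")

    @property
    def volume(self) -> float:
        au, av, az = self.semi
        return 4.0 / 3.0 * np.pi * au * av * az

    def chord_length(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Length of the z-directed chord through the ellipsoid at points (u, v).

        For a ray parallel to z the intersection is governed by
        ((u-cu)/au)^2 + ((v-cv)/av)^2 + ((z-cz)/az)^2 = 1, whose two roots in z
        are symmetric about cz; the chord is 2*az*sqrt(1 - ru^2 - rv^2) where
        ru, rv are the normalized in-plane offsets (0 outside the silhouette).
        """
        cu, cv, _ = self.center
        au, av, az = self.semi
        s = 1.0 - ((u - cu) / au) ** 2 - ((v - cv) / av) ** 2
        return 2.0 * az * np.sqrt(np.clip(s, 0.0, None))

    def contains(self, pts: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """True for points (n, 3) strictly inside the ellipsoid shrunk by margin."""
        c = np.asarray(self.center)
        a = np.asarray(self.semi)
        q = np.sum(((pts - c) / a) ** 2, axis=1)
        return q < (1.0 - margin) ** 2

    def surface_points(self, n: int = 96) -> np.ndarray:
        """Deterministic quasi-uniform sample of the surface (Fibonacci sphere)."""
        i = np.arange(n, dtype=float)
        phi = np.arccos(1 - 2 * (i + 0.5) / n)
        theta = np.pi * (1 + 5 ** 0.5) * i
        sphere = np.stack(
            [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
            axis=1,
        )
        return np.asarray(self.center) + sphere * np.asarray(self.semi)


@dataclass(frozen=True)
class ShellLobe:
    """One pod lobe: outer shell ellipsoid minus its concentric-axis cavity."""

    outer: Ellipsoid
    cavity: Ellipsoid

    @property
    def shell_volume(self) -> float:
        return self.outer.volume - self.cavity.volume

    def shell_chord(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        return self.outer.chord_length(u, v) - self.cavity.chord_length(u, v)


@dataclass(frozen=True)
class PodPhantom:
    """A whole-pod phantom: 1-2 shell lobes enclosing 1-3 solid kernels.

    Weights are derived quantities (density times analytic volume); lobes are
    mutually disjoint so that volumes, and hence masses, add exactly.
    """

    pod_id: str
    lobes: tuple[ShellLobe, ...]
    kernels: tuple[Ellipsoid, ...]
    density_shell: float  # g/mm^3
    density_kernel: float  # g/mm^3
    mu_shell: float  # attenuation per mm
    mu_kernel: float  # attenuation per mm

    @property
    def kernel_weight_g(self) -> float:
        return self.density_kernel * sum(k.volume for k in self.kernels)

    @property
    def shell_weight_g(self) -> float:
        return self.density_shell * sum(l.shell_volume for l in self.lobes)

    @property
    def extent_mm(self) -> tuple[float, float]:
        """Tight (u, v) bounding-box extents of the outer shell surfaces."""
        us = [abs(l.outer.center[0]) + l.outer.semi[0] for l in self.lobes]
        vs_lo = [l.outer.center[1] - l.outer.semi[1] for l in self.lobes]
        vs_hi = [l.outer.center[1] + l.outer.semi[1] for l in self.lobes]
        return 2 * max(us), max(vs_hi) - min(vs_lo)

    def attenuation(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Line integral of mu along the z ray at each (u, v), in optical depths."""
        a = np.zeros(np.broadcast(u, v).shape, dtype=float)
        for lobe in self.lobes:
            a += self.mu_shell * lobe.shell_chord(u, v)
        for k in self.kernels:
            a += self.mu_kernel * k.chord_length(u, v)
        return a

    def kernel_silhouette(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Boolean union of the kernels' projected silhouettes."""
        m = np.zeros(np.broadcast(u, v).shape, dtype=bool)
        for k in self.kernels:
            m |= k.chord_length(u, v) > 0
        return m

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        if not 1 <= len(self.lobes) <= 2:
            raise ValueError("pod must have 1-2 shell lobes")
        if not 1 <= len(self.kernels) <= 3:
            raise ValueError("pod must have 1-3 kernels")
        if self.kernel_weight_g <= 0 or self.shell_weight_g <= 0:
            raise ValueError("weights must be positive")
        for k in self.kernels:
            inside = any(
                bool(np.all(lobe.cavity.contains(k.surface_points())))
                for lobe in self.lobes
            )
            if not inside:
                raise ValueError(f"kernel at {k.center} not inside any shell cavity")


# --------------------------------------------------------------------------- sampling


@dataclass(frozen=True)
class TraitDistribution:
    """Sampling law for per-pod traits, mirroring the gravimetric dataset.

    Weights are drawn from Beta distributions rescaled to the observed trait
    ranges; the default Beta shapes put most mass at low weights (right skew),
    reproducing the reported over-representation of light pods.  Setting
    ``skewed=False`` switches to uniform draws; a zero-width range is a point
    mass (useful for deterministic tests).
    """

    kernel_range: tuple[float, float] = (0.003, 2.47)
    shell_range: tuple[float, float] = (0.05, 1.40)
    kernel_beta: tuple[float, float] = (1.7, 3.4)
    shell_beta: tuple[float, float] = (1.5, 4.5)
    n_kernel_probs: tuple[float, float, float] = (0.25, 0.5, 0.25)
    density_kernel: float = 1.0e-3  # g/mm^3
    density_shell: float = 4.0e-4  # g/mm^3
    mu_kernel: float = 0.07  # per mm
    mu_shell: float = 0.004  # per mm
    aspect_range: tuple[float, float] = (1.25, 1.6)
    cavity_margin: float = 1.18
    lobe_gap_mm: float = 0.4
    max_extent_mm: tuple[float, float] = (21.0, 42.0)
    skewed: bool = True
    max_tries: int = 200

    def sample_weight(self, rng: np.random.Generator, trait: str) -> float:
        lo, hi = self.kernel_range if trait == "kernel" else self.shell_range
        if hi <= lo:
            return lo
        if not self.skewed:
            return float(rng.uniform(lo, hi))
        a, b = self.kernel_beta if trait == "kernel" else self.shell_beta
        return lo + (hi - lo) * float(rng.beta(a, b))


def _build_lobe(
    kernels: list[tuple[float, Ellipsoid]],
    shell_volume: float,
    margin: float,
) -> ShellLobe:
    """Assemble one lobe around its kernels (given as (v-offset, ellipsoid at origin))."""
    lo = min(off - k.semi[1] for off, k in kernels)
    hi = max(off + k.semi[1] for off, k in kernels)
    mid = 0.5 * (lo + hi)
    semi_v = margin * 0.5 * (hi - lo) if len(kernels) > 1 else margin * kernels[0][1].semi[1]
    semi_v = max(semi_v, margin * 0.5 * (hi - lo))
    semi_u = margin * max(k.semi[0] for _, k in kernels)
    semi_z = margin * max(k.semi[2] for _, k in kernels)
    cavity = Ellipsoid((0.0, mid, 0.0), (semi_u, semi_v, semi_z))
    scale = (1.0 + shell_volume / cavity.volume) ** (1.0 / 3.0)
    outer = Ellipsoid(cavity.center, tuple(s * scale for s in cavity.semi))
    return ShellLobe(outer=outer, cavity=cavity)


def make_pod_phantom(
    rng: np.random.Generator,
    dist: TraitDistribution | None = None,
    pod_id: str = "pod",
) -> PodPhantom:
    """Draw one pod phantom whose analytic weights hit the sampled targets exactly.

    Kernel volumes are scaled to match the drawn kernel weight; the shell wall is
    scaled around the cavity so the shell volume matches the drawn shell weight.
    Geometrically infeasible draws (pod exceeding ``max_extent_mm``, which is tied
    to the holder slot size) are rejected and resampled up to ``max_tries``.
    """
    dist = dist or TraitDistribution()
    for _ in range(dist.max_tries):
        wk = dist.sample_weight(rng, "kernel")
        ws = dist.sample_weight(rng, "shell")
        n_k = int(rng.choice([1, 2, 3], p=dist.n_kernel_probs))
        v_kernel = wk / dist.density_kernel
        v_shell = ws / dist.density_shell

        shares = rng.uniform(0.7, 1.3, size=n_k)
        shares /= shares.sum()
        kernels_local: list[Ellipsoid] = []
        for s in shares:
            vol = v_kernel * s
            asp = float(rng.uniform(*dist.aspect_range))
            b = (3.0 * vol / (4.0 * np.pi * asp)) ** (1.0 / 3.0)
            kernels_local.append(Ellipsoid((0.0, 0.0, 0.0), (b, asp * b, b)))

        # lobe membership: single kernel -> one lobe, else two lobes (2+1 or 1+1)
        if n_k == 1:
            groups = [[0]]
        elif n_k == 2:
            groups = [[0], [1]]
        else:
            groups = [[0, 1], [2]]

        lobes: list[ShellLobe] = []
        placed: list[list[tuple[float, Ellipsoid]]] = []
        cav_vols = []
        for g in groups:
            offs: list[tuple[float, Ellipsoid]] = []
            if len(g) == 1:
                offs = [(0.0, kernels_local[g[0]])]
            else:
                k0, k1 = kernels_local[g[0]], kernels_local[g[1]]
                d = 0.5 * 1.05 * (k0.semi[1] + k1.semi[1])
                offs = [(-d, k0), (d, k1)]
            placed.append(offs)
            # provisional cavity volume for shell split
            tmp = _build_lobe(offs, 1e-9, dist.cavity_margin)
            cav_vols.append(tmp.cavity.volume)

        cav_total = sum(cav_vols)
        for offs, cv in zip(placed, cav_vols):
            lobes.append(_build_lobe(offs, v_shell * cv / cav_total, dist.cavity_margin))

        # place lobes along v, disjoint with a small waist gap
        if len(lobes) == 1:
            centers = [0.0]
        else:
            a1 = lobes[0].outer.semi[1]
            a2 = lobes[1].outer.semi[1]
            ext = 2 * a1 + 2 * a2 + dist.lobe_gap_mm
            centers = [-(ext / 2 - a1), ext / 2 - a2]

        final_lobes = []
        final_kernels = []
        for lobe, offs, cv in zip(lobes, placed, centers):
            shift = cv - lobe.outer.center[1]
            final_lobes.append(
                ShellLobe(
                    outer=replace(lobe.outer, center=(0.0, lobe.outer.center[1] + shift, 0.0)),
                    cavity=replace(lobe.cavity, center=(0.0, lobe.cavity.center[1] + shift, 0.0)),
                )
            )
            for off, k in offs:
                final_kernels.append(
                    replace(k, center=(0.0, lobe.cavity.center[1] + shift + off, 0.0))
                )

        pod = PodPhantom(
            pod_id=pod_id,
            lobes=tuple(final_lobes),
            kernels=tuple(final_kernels),
            density_shell=dist.density_shell,
            density_kernel=dist.density_kernel,
            mu_shell=dist.mu_shell,
            mu_kernel=dist.mu_kernel,
        )
        eu, ev = pod.extent_mm
        if eu <= dist.max_extent_mm[0] and ev <= dist.max_extent_mm[1]:
            pod.validate()
            return pod
    raise PhantomGeometryError(
        f"no feasible phantom in {dist.max_tries} tries "
        f"(last draw: kernel={wk:.3f} g, shell={ws:.3f} g, n_kernels={n_k}, "
        f"max_extent_mm={dist.max_extent_mm})"
    )


# --------------------------------------------------------------------------- scan model


@dataclass(frozen=True)
class ScanConfig:
    """Acquisition model: detector geometry, flat-field level, eps grid, noise.

    ``i0_range`` bounds the per-scan flat-field draw; the default interval equals
    the reported source-stability extremes.  Counts are generated as
    Poisson(photon_scale * expected) / photon_scale plus Gaussian read noise, so
    ``photon_scale`` acts as a detector gain controlling relative shot noise
    (default tuned for a blank-image SD of roughly 0.5% of i0); everything is
    clipped to the 14-bit range.  ``rng_seed`` fully determines simulator output.
    """

    detector_shape: tuple[int, int] = (1300, 2304)
    pixel_size_um: float = 49.5
    i0_range: tuple[float, float] = (4864.444, 5382.635)
    grid_attenuation: float = 0.095  # per mm of eps
    bar_thickness_mm: float = 20.0
    photon_scale: float = 8.0
    read_sigma: float = 5.0
    jitter_px: int = 2
    noise: bool = True
    rng_seed: int = 0
    kv: float = 60.0
    ua: float = 103.0
    exposure_ms: float = 300.0

    @property
    def pixel_size_mm(self) -> float:
        return self.pixel_size_um / 1000.0

    @property
    def bar_tau(self) -> float:
        """Optical depth of one eps bar."""
        return self.grid_attenuation * self.bar_thickness_mm


def desk_config(seed: int = 0, **overrides) -> ScanConfig:
    """A reduced-scale acquisition preset for CPU-friendly experiments.

    Coarser pixels (0.4 mm) on a 160x256 detector keep whole-holder scans cheap
    while preserving the radiometric structure (i0 interval, grid, noise model).
    """
    kw = dict(detector_shape=(160, 256), pixel_size_um=400.0, rng_seed=seed)
    kw.update(overrides)
    return ScanConfig(**kw)


@dataclass(frozen=True)
class HolderLayout:
    """2x2 slot layout framed by straight eps bars.

    ``slots`` are the half-open interior rectangles (r0, r1, c0, c1) used for
    cropping; ``bars`` are the half-open bar rectangles.
    """

    shape: tuple[int, int]
    slots: tuple[tuple[int, int, int, int], ...]
    bars: tuple[tuple[int, int, int, int], ...]
    bar_width_px: int

    @classmethod
    def from_detector(
        cls,
        shape: tuple[int, int],
        bar_width_px: int | None = None,
        margin_px: int | None = None,
    ) -> "HolderLayout":
        rows, cols = shape
        w = bar_width_px if bar_width_px is not None else max(2, min(rows, cols) // 60)
        m = margin_px if margin_px is not None else w

        def lines(n: int) -> list[tuple[int, int]]:
            return [(m, m + w), ((n - w) // 2, (n - w) // 2 + w), (n - m - w, n - m)]

        hbars = lines(rows)
        vbars = lines(cols)
        row_spans = [(hbars[0][1], hbars[1][0]), (hbars[1][1], hbars[2][0])]
        col_spans = [(vbars[0][1], vbars[1][0]), (vbars[1][1], vbars[2][0])]
        slots = tuple(
            (r0, r1, c0, c1) for (r0, r1) in row_spans for (c0, c1) in col_spans
        )
        bars = tuple((r0, r1, 0, cols) for (r0, r1) in hbars) + tuple(
            (0, rows, c0, c1) for (c0, c1) in vbars
        )
        for i, a in enumerate(slots):
            for b in slots[i + 1 :]:
                if not (a[1] <= b[0] or b[1] <= a[0] or a[3] <= b[2] or b[3] <= a[2]):
                    raise ValueError("slots overlap")
        return cls(shape=shape, slots=slots, bars=bars, bar_width_px=w)

    def bar_mask(self, shift: tuple[int, int] = (0, 0)) -> np.ndarray:
        """Boolean mask of bar pixels, optionally shifted by (drow, dcol)."""
        m = np.zeros(self.shape, dtype=bool)
        dr, dc = shift
        rows, cols = self.shape
        for r0, r1, c0, c1 in self.bars:
            rr0, rr1 = np.clip([r0 + dr, r1 + dr], 0, rows)
            cc0, cc1 = np.clip([c0 + dc, c1 + dc], 0, cols)
            m[rr0:rr1, cc0:cc1] = True
        return m


@dataclass
class RawProjection:
    """One holder (or blank) projection: 14-bit counts plus acquisition metadata.

    ``truth`` carries simulator-side ground facts (i0 of the scan, grid shift,
    noiseless counts) for oracle tests; it is not serialized into the TIFF.
    """

    pixels: np.ndarray
    projection_id: str
    metadata: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixels.dtype != np.uint16:
            raise ValueError("projection pixels must be uint16")


@dataclass(frozen=True)
class PodRecord:
    """Ground truth for one pod: identity, slot, and gravimetric weights."""

    pod_id: str
    projection_id: str
    slot: int
    kernel_weight_g: float
    shell_weight_g: float


def _expected_counts(
    phantoms: list[PodPhantom] | None,
    layout: HolderLayout,
    config: ScanConfig,
    i0: float,
    shift: tuple[int, int],
) -> np.ndarray:
    """Noiseless expected counts i0 * exp(-sum mu*L) over the whole detector."""
    rows, cols = layout.shape
    tau = np.where(layout.bar_mask(shift), config.bar_tau, 0.0)
    if phantoms is not None:
        p = config.pixel_size_mm
        for slot_idx, pod in enumerate(phantoms):
            if pod is None:
                continue
            r0, r1, c0, c1 = layout.slots[slot_idx]
            cu = 0.5 * (r0 + r1 - 1) * p
            cv = 0.5 * (c0 + c1 - 1) * p
            eu, ev = pod.extent_mm
            if eu > (r1 - r0) * p or ev > (c1 - c0) * p:
                raise ValueError(
                    f"phantom {pod.pod_id} (extent {eu:.1f}x{ev:.1f} mm) does not fit "
                    f"slot {slot_idx} ({(r1 - r0) * p:.1f}x{(c1 - c0) * p:.1f} mm)"
                )
            u = (np.arange(r0, r1) * p - cu)[:, None]
            v = (np.arange(c0, c1) * p - cv)[None, :]
            tau[r0:r1, c0:c1] += pod.attenuation(u, v)
    return i0 * np.exp(-tau)


def _digitize(expected: np.ndarray, config: ScanConfig, rng: np.random.Generator | None) -> np.ndarray:
    if config.noise and rng is not None:
        k = config.photon_scale
        counts = rng.poisson(expected * k) / k
        counts = counts + rng.normal(0.0, config.read_sigma, size=counts.shape)
    else:
        counts = expected
    return np.clip(np.rint(counts), 0, DETECTOR_MAX).astype(np.uint16)


def project_holder(
    phantoms: list[PodPhantom],
    layout: HolderLayout,
    config: ScanConfig,
    rng: np.random.Generator | None = None,
    projection_id: str = "proj",
    i0: float | None = None,
    shift: tuple[int, int] | None = None,
) -> tuple[RawProjection, list[PodRecord]]:
    """Project four pod phantoms (entries may be None for empty slots).

    The holder is re-placed for every scan, so the grid is shifted by a small
    random jitter relative to its nominal (blank-scan) position; the flat-field
    level i0 is drawn per scan from ``config.i0_range``.
    """
    if len(phantoms) != len(layout.slots):
        raise ValueError(f"expected {len(layout.slots)} phantoms (None allowed)")
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    if i0 is None:
        i0 = float(rng.uniform(*config.i0_range))
    if shift is None:
        j = config.jitter_px
        shift = (int(rng.integers(-j, j + 1)), int(rng.integers(-j, j + 1))) if j else (0, 0)
    expected = _expected_counts(phantoms, layout, config, i0, shift)
    pixels = _digitize(expected, config, rng if config.noise else None)
    records = [
        PodRecord(
            pod_id=f"{projection_id}_s{slot}",
            projection_id=projection_id,
            slot=slot,
            kernel_weight_g=pod.kernel_weight_g,
            shell_weight_g=pod.shell_weight_g,
        )
        for slot, pod in enumerate(phantoms)
        if pod is not None
    ]
    meta = {"kv": config.kv, "ua": config.ua, "exposure_ms": config.exposure_ms}
    truth = {"i0": i0, "shift": shift, "expected": expected, "phantoms": phantoms}
    return RawProjection(pixels, projection_id, meta, truth), records


def project_blank(
    layout: HolderLayout,
    config: ScanConfig,
    rng: np.random.Generator | None = None,
    projection_id: str = "blank",
    i0: float | None = None,
) -> RawProjection:
    """Project the empty eps grid at its nominal position (no pods, no jitter)."""
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    if i0 is None:
        i0 = float(rng.uniform(*config.i0_range))
    expected = _expected_counts(None, layout, config, i0, (0, 0))
    pixels = _digitize(expected, config, rng if config.noise else None)
    meta = {"kv": config.kv, "ua": config.ua, "exposure_ms": config.exposure_ms}
    return RawProjection(pixels, projection_id, meta, {"i0": i0, "shift": (0, 0), "expected": expected})


# --------------------------------------------------------------------------- dataset


def simulate_batch(
    n_projections: int,
    config: ScanConfig,
    layout: HolderLayout | None = None,
    dist: TraitDistribution | None = None,
) -> tuple[list[RawProjection], list[RawProjection], list[PodRecord]]:
    """In-memory dataset: n holder projections, 2 blanks, 4n pod records."""
    if n_projections < 1:
        raise ValueError("n_projections must be >= 1")
    layout = layout or HolderLayout.from_detector(config.detector_shape)
    if dist is None:
        p = config.pixel_size_mm
        slot = layout.slots[0]
        dist = TraitDistribution(
            max_extent_mm=(
                min(21.0, (slot[1] - slot[0] - 8) * p),
                min(42.0, (slot[3] - slot[2] - 8) * p),
            )
        )
    rng = np.random.default_rng(config.rng_seed)
    blanks = [
        project_blank(layout, config, rng, projection_id=f"blank{i:02d}") for i in range(2)
    ]
    projections: list[RawProjection] = []
    records: list[PodRecord] = []
    for i in range(n_projections):
        pid = f"proj{i:04d}"
        pods = [
            make_pod_phantom(rng, dist, pod_id=f"{pid}_s{s}") for s in range(len(layout.slots))
        ]
        proj, recs = project_holder(pods, layout, config, rng, projection_id=pid)
        projections.append(proj)
        records.extend(recs)
    return projections, blanks, records


def records_to_frame(records: list[PodRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pod_id": r.pod_id,
                "projection_id": r.projection_id,
                "slot": r.slot,
                "kernel_weight_g": r.kernel_weight_g,
                "shell_weight_g": r.shell_weight_g,
            }
            for r in records
        ]
    )


def write_config(config: ScanConfig, path: Path) -> None:
    cp = configparser.ConfigParser()
    cp["scan"] = {k: repr(v) for k, v in vars(config).items()}
    with open(path, "w") as fh:
        cp.write(fh)


def make_dataset(
    n_projections: int,
    config: ScanConfig,
    out_dir: str | Path,
    layout: HolderLayout | None = None,
    dist: TraitDistribution | None = None,
) -> pd.DataFrame:
    """Write a seed-reproducible scan set: holder TIFFs, 2 blank TIFFs, manifest CSV.

    Returns the ground-truth manifest (4 * n_projections rows).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    projections, blanks, records = simulate_batch(n_projections, config, layout, dist)
    for proj in projections + blanks:
        tifffile.imwrite(out / f"{proj.projection_id}.tiff", proj.pixels)
    manifest = records_to_frame(records)
    manifest.to_csv(out / "manifest.csv", index=False)
    write_config(config, out / "scan_config.txt")
    return manifest
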