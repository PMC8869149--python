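"""Synthetic STORM data with known ground truth.

Two generation paths share the same fluorophore and blink draws for a
given seed:

* the fast path (:func:`simulate_localizations`) adds isotropic Gaussian
  localization error directly to true blink positions;
* the frame path (:func:`simulate_frames` + :func:`localize_spots`) renders
  each blink as photons on a pixel grid and re-localizes the spots with an
  integrated-2D-Gaussian fit, emulating the full acquisition chain.

Blink schedules are independent per fluorophore (Poisson blink counts,
frames uniform) — no photokinetic dark-state model, which is sufficient
for size estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy.ndimage import gaussian_filter, maximum_filter
from scipy.optimize import least_squares
from scipy.special import erf

from .errors import InvalidParameterError, UndersamplingError
from .fitting import fit_sba, measure_fwhm
from .io import LocalizationTable
from .models import Shape
from .profiles import extract_profile, find_clusters

__all__ = [
    "Geometry",
    "EmitterSpec",
    "SimConfig",
    "FrameStack",
    "BenchmarkReport",
    "sample_fluorophores",
    "simulate_localizations",
    "simulate_frames",
    "localize_spots",
    "run_benchmark",
]


class Geometry(str, Enum):
    """Emitter geometries.

    ``cylinder_surface`` follows the same surface-labeling convention as
    ``sphere_surface``: its cross-sectional (transverse) projection is
    uniform on ``[-R, R]``, matching the uniform-projection structural
    function used to fit it.  ``cylinder_tube`` is the exact 3D tube:
    fluorophores uniform on the cylindrical shell, whose transverse
    projection is the edge-peaked arcsine density (fitting it with the
    uniform-projection model overestimates the diameter by ~19%).
    """

    CYLINDER_SURFACE = "cylinder_surface"
    CYLINDER_TUBE = "cylinder_tube"
    SPHERE_SURFACE = "sphere_surface"
    SPHERE_VOLUME = "sphere_volume"
    DISC_SOLID = "disc_solid"


@dataclass(frozen=True)
class EmitterSpec:
    """Ground-truth emitter geometry: shape, size, pose, labeling."""

    geometry: Geometry
    diameter: float
    length: float | None = None  # cylinders only
    center: tuple[float, float] = (0.0, 0.0)
    angle: float = 0.0  # in-plane orientation, rad
    n_fluorophores: int | None = None
    label_density: float | None = None  # per nm^2 (surface) or nm^3 (volume)

    def __post_init__(self) -> None:
        try:
            object.__setattr__(self, "geometry", Geometry(self.geometry))
        except ValueError:
            raise InvalidParameterError(
                f"unknown geometry {self.geometry!r}"
            ) from None
        if self.diameter <= 0:
            raise InvalidParameterError("diameter must be > 0")
        if self.geometry in (Geometry.CYLINDER_SURFACE, Geometry.CYLINDER_TUBE):
            if self.length is None or self.length <= 0:
                raise InvalidParameterError("cylinders need length > 0")
        if (self.n_fluorophores is None) == (self.label_density is None):
            raise InvalidParameterError(
                "specify exactly one of n_fluorophores or label_density"
            )

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    def fluorophore_count(self) -> int:
        if self.n_fluorophores is not None:
            return int(self.n_fluorophores)
        R, rho = self.radius, self.label_density
        if self.geometry in (Geometry.CYLINDER_SURFACE, Geometry.CYLINDER_TUBE):
            measure = np.pi * self.diameter * self.length
        elif self.geometry is Geometry.SPHERE_SURFACE:
            measure = 4.0 * np.pi * R**2
        elif self.geometry is Geometry.SPHERE_VOLUME:
            measure = 4.0 / 3.0 * np.pi * R**3
        else:  # DISC_SOLID
            measure = np.pi * R**2
        return max(1, int(round(rho * measure)))


@dataclass(frozen=True)
class SimConfig:
    """Noise and acquisition settings for both generation paths."""

    sigma_loc: float = 20.0  # nm
    blinks_per_fluorophore: float = 3.0
    n_frames: int = 10_000
    seed: int = 0
    pixel_size: float = 100.0  # nm, frame path
    psf_sigma: float = 130.0  # nm, frame path
    photons_per_blink: float = 2000.0
    background: float = 2.0  # photons / pixel / frame

    def __post_init__(self) -> None:
        if self.sigma_loc <= 0:
            raise InvalidParameterError("sigma_loc must be > 0")
        if self.blinks_per_fluorophore < 0:
            raise InvalidParameterError("blinks_per_fluorophore must be >= 0")
        if self.n_frames < 1:
            raise InvalidParameterError("n_frames must be >= 1")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_fluorophores(spec: EmitterSpec, seed) -> np.ndarray:
    """Uniformly sample fluorophore positions on the spec's manifold.

    Returns an (n, 2) array of image-plane positions in nm after applying
    the pose (rotation + translation).  ``seed`` may be an int or a
    ``numpy.random.Generator``.
    """
    rng = _as_rng(seed)
    n = spec.fluorophore_count()
    R = spec.radius
    geom = spec.geometry
    if geom is Geometry.CYLINDER_SURFACE:
        # surface-labeling convention: transverse projection uniform on [-R, R]
        u = rng.uniform(-spec.length / 2.0, spec.length / 2.0, n)
        local = np.column_stack([u, rng.uniform(-R, R, n)])
    elif geom is Geometry.CYLINDER_TUBE:
        # exact 3D shell: transverse projection is the arcsine density
        u = rng.uniform(-spec.length / 2.0, spec.length / 2.0, n)
        phi = rng.uniform(0.0, 2.0 * np.pi, n)
        local = np.column_stack([u, R * np.sin(phi)])
    elif geom is Geometry.SPHERE_SURFACE:
        v = rng.standard_normal((n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        local = R * v[:, :2]
    elif geom is Geometry.SPHERE_VOLUME:
        v = rng.standard_normal((n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = R * rng.uniform(0.0, 1.0, n) ** (1.0 / 3.0)
        local = (r[:, None] * v)[:, :2]
    else:  # DISC_SOLID
        r = R * np.sqrt(rng.uniform(0.0, 1.0, n))
        phi = rng.uniform(0.0, 2.0 * np.pi, n)
        local = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    c, s = np.cos(spec.angle), np.sin(spec.angle)
    rot = np.array([[c, -s], [s, c]])
    return local @ rot.T + np.asarray(spec.center)


def _draw_blinks(spec: EmitterSpec, cfg: SimConfig, rng: np.random.Generator):
    """Common blink schedule for both paths: positions, frames, photons."""
    fluors = sample_fluorophores(spec, rng)
    k = rng.poisson(cfg.blinks_per_fluorophore, fluors.shape[0])
    positions = np.repeat(fluors, k, axis=0)
    n_blinks = positions.shape[0]
    frames = rng.integers(1, cfg.n_frames + 1, n_blinks)
    photons = rng.poisson(cfg.photons_per_blink, n_blinks).astype(float)
    return positions, frames, photons


def simulate_localizations(
    spec: EmitterSpec, cfg: SimConfig, return_truth: bool = False
):
    """Fast-path synthetic localization table.

    Each fluorophore blinks ``k ~ Poisson(blinks_per_fluorophore)`` times;
    each blink yields one localization at the true position plus isotropic
    Gaussian error of SD ``sigma_loc``.  ``return_truth=True`` additionally
    returns the (n, 2) true blink positions.
    """
    rng = np.random.default_rng(cfg.seed)
    positions, frames, photons = _draw_blinks(spec, cfg, rng)
    n = positions.shape[0]
    if n == 0:
        warnings.warn("zero expected localizations; returning empty table", stacklevel=2)
        empty = LocalizationTable(
            frame=np.empty(0, int),
            x=np.empty(0),
            y=np.empty(0),
            photons=np.empty(0),
            precision=np.empty(0),
            metadata={"units": "nm"},
        )
        return (empty, np.empty((0, 2))) if return_truth else empty
    noisy = positions + rng.normal(0.0, cfg.sigma_loc, (n, 2))
    table = LocalizationTable(
        frame=frames,
        x=noisy[:, 0],
        y=noisy[:, 1],
        photons=photons,
        precision=np.full(n, cfg.sigma_loc),
        metadata={"units": "nm", "seed": cfg.seed},
    )
    return (table, positions) if return_truth else table


@dataclass
class FrameStack:
    """A stack of rendered camera frames (photon counts)."""

    frames: np.ndarray  # (n_frames, ny, nx), uint16
    pixel_size: float  # nm
    origin: tuple[float, float]  # nm position of the (0, 0) pixel corner
    psf_sigma: float  # nm, for downstream defaults

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def simulate_frames(
    spec: EmitterSpec, cfg: SimConfig, return_truth: bool = False
):
    """Frame-path rendering: photons of each blink land on the pixel grid.

    Photon positions are drawn from the PSF Gaussian around each blink's
    true position and histogrammed into pixels, so pixel statistics are the
    physical multinomial/Poisson ones; Poisson background is added per
    pixel.  The blink schedule is identical to the fast path at the same
    seed.
    """
    if cfg.pixel_size >= 4.0 * cfg.psf_sigma:
        raise UndersamplingError(
            f"pixel_size {cfg.pixel_size} >= 4 * psf_sigma {cfg.psf_sigma}"
        )
    rng = np.random.default_rng(cfg.seed)
    positions, frames, photons = _draw_blinks(spec, cfg, rng)

    margin = 6.0 * cfg.psf_sigma + 2.0 * cfg.pixel_size
    if positions.shape[0]:
        xmin, ymin = positions.min(axis=0) - margin
        xmax, ymax = positions.max(axis=0) + margin
    else:
        xmin = ymin = -margin
        xmax = ymax = margin
    x0 = np.floor(xmin / cfg.pixel_size) * cfg.pixel_size
    y0 = np.floor(ymin / cfg.pixel_size) * cfg.pixel_size
    nx = int(np.ceil((xmax - x0) / cfg.pixel_size))
    ny = int(np.ceil((ymax - y0) / cfg.pixel_size))

    stack = np.zeros((cfg.n_frames, ny, nx), dtype=np.uint16)
    order = np.argsort(frames, kind="stable")
    for f in np.unique(frames[order]):
        sel = np.flatnonzero(frames == f)
        img = np.zeros((ny, nx), dtype=np.int64)
        for b in sel:
            n_ph = int(photons[b])
            if n_ph == 0:
                continue
            pts = positions[b] + rng.normal(0.0, cfg.psf_sigma, (n_ph, 2))
            jj = np.floor((pts[:, 0] - x0) / cfg.pixel_size).astype(int)
            ii = np.floor((pts[:, 1] - y0) / cfg.pixel_size).astype(int)
            ok = (ii >= 0) & (ii < ny) & (jj >= 0) & (jj < nx)
            np.add.at(img, (ii[ok], jj[ok]), 1)
        stack[f - 1] = np.clip(img, 0, np.iinfo(np.uint16).max)
    if cfg.background > 0:
        stack = (
            stack.astype(np.int64)
            + rng.poisson(cfg.background, stack.shape)
        ).clip(0, np.iinfo(np.uint16).max).astype(np.uint16)

    result = FrameStack(
        frames=stack,
        pixel_size=cfg.pixel_size,
        origin=(float(x0), float(y0)),
        psf_sigma=cfg.psf_sigma,
    )
    if return_truth:
        truth = LocalizationTable(
            frame=frames if len(frames) else np.empty(0, int),
            x=positions[:, 0],
            y=positions[:, 1],
            photons=photons,
            metadata={"units": "nm", "ground_truth": True},
        )
        return result, truth
    return result


def _integrated_gaussian(window_shape, x0, y0, sigma, amp, bg):
    """Expected photons per pixel for a pixel-integrated 2D Gaussian (px units)."""
    ny, nx = window_shape
    jx = np.arange(nx)
    iy = np.arange(ny)
    s = sigma * np.sqrt(2.0)
    fx = 0.5 * (erf((jx + 1 - x0) / s) - erf((jx - x0) / s))
    fy = 0.5 * (erf((iy + 1 - y0) / s) - erf((iy - y0) / s))
    return amp * np.outer(fy, fx) + bg


def localize_spots(
    stack: FrameStack,
    det_threshold: float = 15.0,
    fit_window: int = 7,
    smooth_sigma_px: float = 1.0,
) -> tuple[LocalizationTable, dict]:
    """Detect and fit single-molecule spots in a frame stack.

    Candidates are local maxima of a Gaussian-smoothed frame above
    ``det_threshold`` (photons, background-subtracted).  Each candidate is
    fit with a pixel-integrated 2D Gaussian (center, sigma, amplitude,
    constant background) over a ``fit_window`` x ``fit_window`` patch;
    fits that diverge or whose center leaves the window are discarded.
    Returns the localization table (nm) and a per-spot failure report.
    """
    if stack.frames.size == 0:
        raise InvalidParameterError("empty frame stack")
    half = fit_window // 2
    px = stack.pixel_size
    x0_nm, y0_nm = stack.origin
    out_frame, out_x, out_y, out_ph, out_prec = [], [], [], [], []
    n_candidates = n_failed = n_discarded = 0

    for fi in range(stack.n_frames):
        frame = stack.frames[fi].astype(float)
        med = float(np.median(frame))
        sm = gaussian_filter(frame - med, smooth_sigma_px)
        is_max = (sm == maximum_filter(sm, size=3)) & (sm > det_threshold)
        ii, jj = np.nonzero(is_max)
        for i, j in zip(ii, jj):
            if i < half or j < half or i >= frame.shape[0] - half or j >= frame.shape[1] - half:
                continue
            n_candidates += 1
            patch = frame[i - half : i + half + 1, j - half : j + half + 1]
            bg0 = float(patch.min())
            amp0 = max(float(patch.sum() - bg0 * patch.size), 1.0)
            p0 = [half + 0.5, half + 0.5, max(stack.psf_sigma / px, 0.5), amp0, bg0]
            lo = [0.0, 0.0, 0.25, 1e-3, 0.0]
            hi = [fit_window, fit_window, float(fit_window), np.inf, np.inf]

            def resid(theta, patch=patch):
                return (
                    _integrated_gaussian(patch.shape, *theta) - patch
                ).ravel()

            try:
                sol = least_squares(
                    resid, p0, bounds=(lo, hi), method="trf", xtol=1e-8, ftol=1e-8
                )
            except Exception:  # noqa: BLE001 - per-spot failure, not fatal
                n_failed += 1
                continue
            if not sol.success or not np.all(np.isfinite(sol.x)):
                n_failed += 1
                continue
            cx, cy, sig, amp, _bg = sol.x
            # center must stay strictly inside the window
            if not (0.5 < cx < fit_window - 0.5 and 0.5 < cy < fit_window - 0.5):
                n_discarded += 1
                continue
            x_nm = x0_nm + (j - half + cx) * px
            y_nm = y0_nm + (i - half + cy) * px
            out_frame.append(fi + 1)
            out_x.append(x_nm)
            out_y.append(y_nm)
            out_ph.append(amp)
            out_prec.append(sig * px / np.sqrt(max(amp, 1.0)))

    table = LocalizationTable(
        frame=np.asarray(out_frame, int) if out_frame else np.empty(0, int),
        x=np.asarray(out_x),
        y=np.asarray(out_y),
        photons=np.asarray(out_ph),
        precision=np.asarray(out_prec),
        metadata={"units": "nm", "source": "localize_spots"},
    )
    report = {
        "n_candidates": n_candidates,
        "n_failed": n_failed,
        "n_discarded": n_discarded,
        "n_localized": len(table),
    }
    return table, report


@dataclass
class BenchmarkReport:
    """Per-replicate estimates and per-spec summaries for a benchmark run."""

    entries: list[dict]
    summaries: list[dict]
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "summaries": self.summaries,
            "entries": self.entries,
        }

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.entries)


def _perpendicular(direction) -> np.ndarray:
    d = np.asarray(direction, float)
    p = np.array([-d[1], d[0]])
    if p[0] < 0 or (p[0] == 0 and p[1] < 0):
        p = -p
    return p


def run_benchmark(
    specs: list[EmitterSpec],
    cfg: SimConfig,
    n_replicates: int,
    shape: Shape | str = Shape.SPHERE_SURFACE,
    bin_width: float = 10.0,
    profile_axis: str = "auto",
    fix_sigma: float | None = None,
    cluster_eps: float = 100.0,
    cluster_min_pts: int = 10,
) -> BenchmarkReport:
    """Full-pipeline benchmark: simulate, cluster, profile, fit, and summarize.

    Replicate ``r`` of every spec uses seed ``cfg.seed + r``, so the run is
    deterministic.  ``profile_axis``: ``major`` profiles along the principal
    axis (spheres), ``minor`` along the perpendicular (cylinder
    cross-sections), ``auto`` picks minor for cylinders and major otherwise.
    Replicate-level failures are logged and excluded from summaries.
    """
    if n_replicates < 2:
        raise InvalidParameterError("n_replicates must be >= 2")
    shape = Shape(shape)
    entries: list[dict] = []
    summaries: list[dict] = []
    for si, spec in enumerate(specs):
        sba_vals, fwhm_vals = [], []
        n_excluded = 0
        for r in range(n_replicates):
            seed = cfg.seed + r
            entry = {
                "spec": si,
                "geometry": spec.geometry.value,
                "true_diameter": spec.diameter,
                "replicate": r,
                "seed": seed,
                "sba_diameter": np.nan,
                "fwhm": np.nan,
                "converged": False,
                "error": "",
            }
            try:
                table = simulate_localizations(spec, replace(cfg, seed=seed))
                clusters = find_clusters(table, eps=cluster_eps, min_pts=cluster_min_pts)
                if not clusters:
                    raise RuntimeError("no clusters found")
                cluster = max(clusters, key=lambda c: c.n_localizations)
                use_minor = profile_axis == "minor" or (
                    profile_axis == "auto"
                    and spec.geometry
                    in (Geometry.CYLINDER_SURFACE, Geometry.CYLINDER_TUBE)
                )
                axis = _perpendicular(cluster.principal_axis) if use_minor else None
                prof = extract_profile(cluster, table, bin_width=bin_width, axis=axis)
                fit = fit_sba(prof, shape, fix_sigma=fix_sigma)
                entry["sba_diameter"] = fit.diameter_hat
                entry["converged"] = fit.converged
                sba_vals.append(fit.diameter_hat)
                try:
                    w = measure_fwhm(prof, baseline_mode="edge_mean")
                    entry["fwhm"] = w.fwhm
                    fwhm_vals.append(w.fwhm)
                except Exception as exc:  # noqa: BLE001
                    entry["error"] = f"fwhm: {exc}"
            except Exception as exc:  # noqa: BLE001
                entry["error"] = str(exc)
                n_excluded += 1
            entries.append(entry)
        sba = np.asarray(sba_vals)
        fw = np.asarray(fwhm_vals)
        summaries.append(
            {
                "spec": si,
                "geometry": spec.geometry.value,
                "true_diameter": spec.diameter,
                "n_replicates": n_replicates,
                "n_excluded": n_excluded,
                "sba_mean": float(sba.mean()) if sba.size else np.nan,
                "sba_sd": float(sba.std(ddof=1)) if sba.size > 1 else np.nan,
                "sba_bias": float(sba.mean() - spec.diameter) if sba.size else np.nan,
                "sba_rmse": float(np.sqrt(np.mean((sba - spec.diameter) ** 2)))
                if sba.size
                else np.nan,
                "fwhm_mean": float(fw.mean()) if fw.size else np.nan,
                "fwhm_sd": float(fw.std(ddof=1)) if fw.size > 1 else np.nan,
            }
        )
    config = {
        "sigma_loc": cfg.sigma_loc,
        "blinks_per_fluorophore": cfg.blinks_per_fluorophore,
        "n_frames": cfg.n_frames,
        "seed": cfg.seed,
        "bin_width": bin_width,
        "shape": shape.value,
        "profile_axis": profile_axis,
        "fix_sigma": fix_sigma,
    }
    return BenchmarkReport(entries=entries, summaries=summaries, config=config)
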