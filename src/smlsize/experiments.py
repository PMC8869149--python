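"""Canned validation experiments: simulate ground truth, recover size.

These functions wire the full pipeline (simulate -> cluster -> principal
axis -> profile -> fit) into the three standard recovery experiments used
for validation: cross-sections of long surface-labeled cylinders (d = 200
and 400 nm), replicate 100 nm spheres profiled along their principal axes,
and the frame-level consistency check between the rendering+relocalization
path and the direct localization-noise path.

The kernel sigma is fixed to the (exactly known) simulated localization
precision in all experiments here; `fit_sba`'s default remains a jointly
fitted sigma.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .fitting import fit_sba, measure_fwhm
from .profiles import extract_profile, find_clusters
from .simulate import (
    EmitterSpec,
    SimConfig,
    _perpendicular,
    localize_spots,
    run_benchmark,
    simulate_frames,
    simulate_localizations,
)

__all__ = [
    "cylinder_recovery",
    "bead_recovery",
    "frame_vs_fast_consistency",
]

CYLINDER_LENGTH = 2000.0  # nm
CYLINDER_FLUOROPHORES = 1667  # x blinks mean 3 ~ 5000 localizations
BEAD_FLUOROPHORES = 334  # x blinks mean 3 ~ 1000 localizations
SIGMA_LOC = 20.0
BIN_WIDTH = 10.0


def cylinder_recovery(
    diameter: float, seed: int, n_replicates: int = 10
) -> dict:
    """Fit the cross-sectional profile of simulated surface-labeled cylinders.

    Each replicate (seeds ``seed .. seed + n_replicates - 1``) simulates one
    ~5000-localization cylinder, profiles it perpendicular to its principal
    axis at 10 nm bins, and fits the uniform-projection model with sigma
    fixed at the known 20 nm precision.  Returns per-replicate and mean
    diameters plus FWHMs.
    """
    spec = EmitterSpec(
        geometry="cylinder_surface",
        diameter=diameter,
        length=CYLINDER_LENGTH,
        n_fluorophores=CYLINDER_FLUOROPHORES,
    )
    diams, fwhms = [], []
    for r in range(n_replicates):
        cfg = SimConfig(
            sigma_loc=SIGMA_LOC, blinks_per_fluorophore=3.0, seed=seed + r
        )
        table = simulate_localizations(spec, cfg)
        clusters = find_clusters(table, eps=150.0, min_pts=10)
        cluster = max(clusters, key=lambda c: c.n_localizations)
        axis = _perpendicular(cluster.principal_axis)
        prof = extract_profile(cluster, table, bin_width=BIN_WIDTH, axis=axis)
        diams.append(
            fit_sba(prof, "sphere_surface", fix_sigma=SIGMA_LOC).diameter_hat
        )
        fwhms.append(measure_fwhm(prof).fwhm)
    return {
        "true_diameter": diameter,
        "diameters": diams,
        "diameter_mean": float(np.mean(diams)),
        "fwhm_mean": float(np.mean(fwhms)),
        "n_replicates": n_replicates,
    }


def bead_recovery(seed: int, n_beads: int = 123) -> dict:
    """Replicate-sphere recovery: mean/SD of fitted diameter vs FWHM.

    ``n_beads`` independent 100 nm surface-labeled spheres (~1000
    localizations each, seeds ``seed .. seed + n_beads - 1``) are profiled
    along their principal axes and fit with sigma fixed at 20 nm.
    """
    spec = EmitterSpec(
        geometry="sphere_surface", diameter=100.0, n_fluorophores=BEAD_FLUOROPHORES
    )
    cfg = SimConfig(sigma_loc=SIGMA_LOC, blinks_per_fluorophore=3.0, seed=seed)
    report = run_benchmark(
        [spec],
        cfg,
        n_replicates=n_beads,
        shape="sphere_surface",
        bin_width=BIN_WIDTH,
        profile_axis="major",
        fix_sigma=SIGMA_LOC,
    )
    s = report.summaries[0]
    return {
        "true_diameter": 100.0,
        "n_beads": n_beads,
        "sba_mean": s["sba_mean"],
        "sba_sd": s["sba_sd"],
        "fwhm_mean": s["fwhm_mean"],
        "fwhm_sd": s["fwhm_sd"],
        "n_excluded": s["n_excluded"],
    }


def _frame_path_replicate(spec: EmitterSpec, cfg: SimConfig) -> tuple[float, float]:
    """One frame-path replicate: (fitted diameter, empirical precision)."""
    stack, truth = simulate_frames(spec, cfg, return_truth=True)
    table, _ = localize_spots(stack, det_threshold=30.0, fit_window=7)
    errs = []
    for i in range(len(table)):
        sel = np.flatnonzero(truth.frame == table.frame[i])
        if sel.size == 0:
            continue
        d2 = (truth.x[sel] - table.x[i]) ** 2 + (truth.y[sel] - table.y[i]) ** 2
        j = sel[np.argmin(d2)]
        errs.append([table.x[i] - truth.x[j], table.y[i] - truth.y[j]])
    emp_sigma = float(np.asarray(errs).std(ddof=1)) if len(errs) > 2 else np.nan
    cluster = max(
        find_clusters(table, eps=100.0, min_pts=10), key=lambda c: c.n_localizations
    )
    prof = extract_profile(cluster, table, bin_width=BIN_WIDTH)
    fit = fit_sba(prof, "sphere_surface", fix_sigma=max(emp_sigma, 1.0))
    return fit.diameter_hat, emp_sigma


def frame_vs_fast_consistency(
    seed: int, n_replicates: int = 20, n_frames: int = 500
) -> dict:
    """Frame-level vs fast-path mean diameter on the 100 nm sphere preset.

    Reduced scale: 150 fluorophores, one mean blink each, over ``n_frames``
    frames per replicate.  The empirical localization precision of the
    frame path (frame-matched nearest ground-truth blink) is fed to the
    fast path as its sigma_loc / fixed kernel sigma.
    """
    spec = EmitterSpec(geometry="sphere_surface", diameter=100.0, n_fluorophores=150)
    base = SimConfig(
        sigma_loc=SIGMA_LOC,
        blinks_per_fluorophore=1.0,
        n_frames=n_frames,
        seed=seed,
        pixel_size=100.0,
        psf_sigma=130.0,
        photons_per_blink=2000.0,
        background=2.0,
    )
    frame_diams, sigmas = [], []
    for r in range(n_replicates):
        d, s = _frame_path_replicate(spec, replace(base, seed=seed + r))
        frame_diams.append(d)
        if np.isfinite(s):
            sigmas.append(s)
    emp_sigma = float(np.mean(sigmas))

    fast_diams = []
    for r in range(n_replicates):
        cfg = replace(base, sigma_loc=emp_sigma, seed=seed + r)
        table = simulate_localizations(spec, cfg)
        cluster = max(
            find_clusters(table, eps=100.0, min_pts=10),
            key=lambda c: c.n_localizations,
        )
        prof = extract_profile(cluster, table, bin_width=BIN_WIDTH)
        fast_diams.append(
            fit_sba(prof, "sphere_surface", fix_sigma=emp_sigma).diameter_hat
        )
    frame_mean = float(np.mean(frame_diams))
    fast_mean = float(np.mean(fast_diams))
    return {
        "frame_mean": frame_mean,
        "fast_mean": fast_mean,
        "relative_difference": abs(frame_mean - fast_mean) / fast_mean,
        "empirical_sigma": emp_sigma,
        "n_replicates": n_replicates,
        "n_frames": n_frames,
    }
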