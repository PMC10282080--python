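"""End-to-end session orchestration: simulate -> track -> reconstruct ->
estimate -> report.

Each ``run_*_session`` function takes a config dict (see the ``DEFAULT_*``
templates), simulates a synthetic session from a single seed (split
hierarchically per component), runs the full analysis chain, and returns a
JSON-serializable report carrying the config hash for provenance.  Pass
``outdir`` to persist reports (JSON) and intermediate arrays (npz).
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import calibnet, eyetrack, foveal, gazestim, mtvel, rfmap, tuning
from .datatypes import TrackerNoiseSpec
from .simulate import (
    NeuronModel,
    apply_tracker_noise,
    gen_dot_stimulus,
    gen_eye_trace,
    gen_grating_stimulus,
    gen_motion_dot_stimulus,
    simulate_neuron,
    simulate_pixel_neuron,
)

__all__ = [
    "DEFAULT_V1_CONFIG",
    "DEFAULT_MT_CONFIG",
    "DEFAULT_FOVEAL_CONFIG",
    "config_hash",
    "child_seeds",
    "run_v1_session",
    "run_mt_session",
    "run_foveal_session",
    "simulate_foveal_session",
]

DEFAULT_V1_CONFIG = {
    "n_frames": 20000,
    "frame_rate": 60.0,
    "dots_per_frame": 10,
    "dot_size": 0.5,
    "screen": [28.0, 16.0],
    "n_units": 10,
    "rf_sigma_range": [0.25, 1.0],  # RF sizes 0.5-2 d.v.a (2 sigma)
    "eccentricity_max": 6.0,
    "precision_sd": 0.0,
    "calibration_gain": 1.0,
    "coarse_extent": [20.0, 14.0],
    "coarse_spacing": 1.0,
    "n_lags": 6,
}

DEFAULT_MT_CONFIG = {
    "n_frames": 60000,  # 10 min at 100 Hz
    "frame_rate": 100.0,
    "max_dots": 32,
    "speed": 15.0,
    "n_dirs": 16,
    "lifetime": 5,
    "screen": [28.0, 16.0],
    "n_units": 8,
    "grid_spacing": 2.0,
    "grid_extent": [20.0, 12.0],
    "n_lags": 5,
    "precision_sd": 0.0,
    "calibration_gain": 1.0,
}

DEFAULT_FOVEAL_CONFIG = {
    "n_frames": 50000,
    "frame_rate": 120.0,
    "roi_px": 20,
    "pitch_arcmin": 3.0,
    "n_units": 20,
    "dot_size": 0.15,
    "dots_per_frame": 150,
    "screen": [12.0, 12.0],
    "offset_arcmin": [0.0, 0.0],  # constant calibration offset (distortion)
    "calibration_gain": 1.0,
    "precision_sd": 0.0,
    "train_steps": 600,
    "n_sta_lags": 8,
}


def config_hash(config: dict) -> str:
    return hashlib.sha1(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def child_seeds(seed: int, n: int) -> list[int]:
    """Split a session seed into independent component seeds (< 2^31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _write(outdir, name: str, report: dict) -> None:
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        with open(Path(outdir) / name, "w") as fh:
            json.dump(report, fh, indent=1, default=float)


# ---------------------------------------------------------------------------
# V1 retinotopy + selection
# ---------------------------------------------------------------------------

def run_v1_session(config: dict | None = None, seed: int = 0,
                   outdir=None) -> dict:
    """Retinotopic-mapping session: sparse dots, coarse + fine regression,
    Gaussian fits, selection criteria; per-unit ground-truth comparison."""
    cfg = {**DEFAULT_V1_CONFIG, **(config or {})}
    s_eye, s_noise, s_dots, s_units = child_seeds(seed, 4)
    duration = cfg["n_frames"] / cfg["frame_rate"]
    trace, _ = gen_eye_trace(duration + 1.0, rate=1000.0, seed=s_eye,
                             screen=tuple(cfg["screen"]), bounds_frac=0.35)
    noisy = apply_tracker_noise(
        trace,
        TrackerNoiseSpec(precision_sd=cfg["precision_sd"],
                         gain=cfg["calibration_gain"]),
        seed=s_noise,
    )
    dots = gen_dot_stimulus(
        cfg["n_frames"], cfg["dots_per_frame"], cfg["dot_size"],
        cfg["frame_rate"], seed=s_dots, screen=tuple(cfg["screen"]),
    )
    rng = np.random.default_rng(s_units)
    units = []
    counts = np.zeros((cfg["n_frames"], cfg["n_units"]))
    truth = []
    for u in range(cfg["n_units"]):
        ecc = rng.uniform(0.0, cfg["eccentricity_max"])
        ang = rng.uniform(0, 2 * np.pi)
        center = (ecc * np.cos(ang), ecc * np.sin(ang))
        sigma = rng.uniform(*cfg["rf_sigma_range"])
        m = NeuronModel(kind="simple", center=center, sigma=sigma, sf=0.0,
                        rectify_polarity=True, baseline=2.0,
                        gain=30.0 / max(sigma, 0.1))
        _, c, _ = simulate_neuron(m, dots, trace, seed=int(rng.integers(2**31)),
                                  unit=u)
        units.append(m)
        counts[:, u] = c
        # half-squaring makes the regression's target profile the squared
        # Gaussian envelope: effective SD is sigma / sqrt(2)
        truth.append({"center": list(center), "sigma": sigma,
                      "area": float(np.pi * sigma**2 / 2.0)})

    grid = gazestim.Grid.centered(tuple(cfg["coarse_extent"]),
                                  cfg["coarse_spacing"])
    binned = gazestim.bin_dots_gaze_contingent(dots, noisy, grid,
                                               ignore_sign=True)
    coarse = rfmap.ReceptiveFieldModel(binned, counts,
                                       n_lags=cfg["n_lags"]).fit()
    report = {"config_hash": config_hash(cfg), "seed": seed, "units": []}
    for u in range(cfg["n_units"]):
        entry = {"unit": u, "truth": truth[u]}
        try:
            fine, fgrid, _ = rfmap.coarse_to_fine(coarse, dots, noisy,
                                                  unit=u)
            fmap = fine.spatial_map(0)
            gfit = rfmap.fit_gaussian_rf(fmap, fgrid)
            cx, cy, _ = rfmap._threshold_blob(fmap, fgrid)
            selected, rep = rfmap.select_unit(fine, gfit, (cx, cy))
            err = float(np.hypot(gfit.mean[0] - truth[u]["center"][0],
                                 gfit.mean[1] - truth[u]["center"][1]))
            entry.update(rep)
            entry.update({"selected": bool(selected), "center_error": err,
                          "area_ratio": float(gfit.area / truth[u]["area"])})
        except Exception as exc:  # stage failure -> partial bundle
            entry.update({"selected": False, "error": f"{type(exc).__name__}: {exc}"})
        report["units"].append(entry)
    report["n_selected"] = sum(u.get("selected", False) for u in report["units"])
    _write(outdir, "v1_report.json", report)
    return report


# ---------------------------------------------------------------------------
# MT velocity session
# ---------------------------------------------------------------------------

def run_mt_session(config: dict | None = None, seed: int = 0,
                   outdir=None) -> dict:
    """Motion-noise session: velocity decomposition, Poisson GLM fits,
    preferred directions and von Mises tuning, vs ground truth."""
    cfg = {**DEFAULT_MT_CONFIG, **(config or {})}
    s_eye, s_noise, s_stim, s_units = child_seeds(seed, 4)
    duration = cfg["n_frames"] / cfg["frame_rate"]
    trace, _ = gen_eye_trace(duration + 1.0, rate=1000.0, seed=s_eye,
                             screen=tuple(cfg["screen"]), bounds_frac=0.3)
    noisy = apply_tracker_noise(
        trace,
        TrackerNoiseSpec(precision_sd=cfg["precision_sd"],
                         gain=cfg["calibration_gain"]),
        seed=s_noise,
    )
    motion = gen_motion_dot_stimulus(
        cfg["n_frames"], cfg["frame_rate"], cfg["max_dots"], cfg["speed"],
        cfg["n_dirs"], cfg["lifetime"], seed=s_stim,
        screen=tuple(cfg["screen"]),
    )
    grid = gazestim.Grid.centered(tuple(cfg["grid_extent"]),
                                  cfg["grid_spacing"])
    vstim = gazestim.decompose_velocity(motion, noisy, grid)

    rng = np.random.default_rng(s_units)
    prefs = np.arange(cfg["n_units"]) * 2 * np.pi / cfg["n_units"]
    report = {"config_hash": config_hash(cfg), "seed": seed, "units": []}
    for u, pref in enumerate(prefs):
        center = (rng.uniform(-4, 4), rng.uniform(-2, 2))
        m = NeuronModel(kind="mt", center=center, pref_dir=float(pref),
                        dir_kappa=3.0, envelope_sigma=2.0, baseline=4.0,
                        gain=10.0)
        _, c, _ = simulate_neuron(m, motion, trace,
                                  seed=int(rng.integers(2**31)), unit=u)
        glm = mtvel.VelocityGLM(vstim, c, n_lags=cfg["n_lags"])
        res = glm.fit()
        tun = mtvel.direction_tuning_forward(
            motion, c, noisy, res.rf_mask(), grid,
            peak_lag=res.peak_lag, seed=int(rng.integers(2**31)),
        )
        vm = mtvel.fit_von_mises(tun)
        err = np.degrees(np.angle(np.exp(1j * (np.radians(
            res.preferred_direction_deg()) - pref))))
        report["units"].append({
            "unit": u,
            "true_pref_deg": float(np.degrees(pref)),
            "glm_pref_deg": res.preferred_direction_deg(),
            "glm_pref_error_deg": float(abs(err)),
            "vm_pref_deg": vm.theta_hat_deg,
            "vm_r2": vm.r2,
            "converged": bool(res.converged),
            "tuning_peak_dir_deg": float(np.degrees(
                tun.directions[tun.preferred_index])),
        })
    _write(outdir, "mt_report.json", report)
    return report


# ---------------------------------------------------------------------------
# foveal high-resolution session with neural calibration
# ---------------------------------------------------------------------------

def simulate_foveal_session(cfg: dict, seed: int = 0) -> dict:
    """Miscalibrated high-resolution session.

    Generates a true eye trace, corrupts it with the configured calibration
    distortion (constant offset in arcmin, and/or gain about screen center),
    renders the dot stimulus into ROI movies under BOTH traces (true movie
    drives the neurons; measured movie is all any analysis sees), and
    simulates a population of simple/complex pixel units anchored near the
    ROI center.
    """
    s_eye, s_noise, s_dots, s_units = child_seeds(seed, 4)
    duration = cfg["n_frames"] / cfg["frame_rate"]
    trace, saccades = gen_eye_trace(
        duration + 1.0, rate=1000.0, seed=s_eye,
        screen=tuple(cfg["screen"]), bounds_frac=0.84,
        amplitude_range=(1.0, 6.0),
    )
    off = np.asarray(cfg["offset_arcmin"], dtype=float) / 60.0
    warp = None
    if np.any(off != 0):
        warp = lambda x, y: (np.full_like(x, off[0]), np.full_like(y, off[1]))
    measured = apply_tracker_noise(
        trace,
        TrackerNoiseSpec(precision_sd=cfg["precision_sd"],
                         gain=cfg["calibration_gain"], warp=warp),
        seed=s_noise,
    )
    dots = gen_dot_stimulus(
        cfg["n_frames"], cfg["dots_per_frame"], cfg["dot_size"],
        cfg["frame_rate"], seed=s_dots, screen=tuple(cfg["screen"]),
    )
    roi = gazestim.ROISpec(shape=(cfg["roi_px"], cfg["roi_px"]),
                           pitch_arcmin=cfg["pitch_arcmin"])
    movie_true = gazestim.reconstruct_roi_movie(dots, trace, roi)
    movie_meas = gazestim.reconstruct_roi_movie(dots, measured, roi)

    rng = np.random.default_rng(s_units)
    pitch = roi.pitch
    n = cfg["n_units"]
    counts = np.zeros((cfg["n_frames"], n))
    anchors = np.zeros((n, 2))
    filters = []
    kinds = []
    for u in range(n):
        kind = "simple" if u % 2 == 0 else "complex"
        center = (rng.uniform(-0.25, 0.25), rng.uniform(-0.25, 0.25))
        m = NeuronModel(
            kind=kind, center=center, sigma=rng.uniform(0.08, 0.14),
            sf=rng.uniform(2.0, 5.0), ori=rng.uniform(0, np.pi),
            phase=rng.uniform(0, 2 * np.pi), baseline=1.0,
            gain=10.0 if kind == "simple" else 6.0,
        )
        _, c, _, f = simulate_pixel_neuron(
            m, movie_true.movie, cfg["frame_rate"], pitch,
            seed=int(rng.integers(2**31)), unit=u,
        )
        counts[:, u] = c
        anchors[u] = center
        filters.append(f)
        kinds.append(kind)
    gx, gy = measured.position_at(dots.frame_times)
    return {
        "trace_true": trace,
        "trace_measured": measured,
        "saccades": saccades,
        "dots": dots,
        "roi": roi,
        "movie_true": movie_true,
        "movie_measured": movie_meas,
        "counts": counts,
        "anchors": anchors,
        "filters": np.array(filters),
        "kinds": kinds,
        "gaze_measured": np.column_stack([gx, gy]),
    }


def refine_gauge_with_sta(
    grid,
    sess: dict,
    counts: np.ndarray,
    mask: np.ndarray | None = None,
    n_lags: int = 8,
    min_peak_z: float = 4.0,
):
    """Resolve the residual constant of a calibration grid with STA anchors.

    A gaze-independent component of the calibration error is degenerate with
    the learned readout positions, so the shifter cannot see it.  With known
    ground-truth filters (synthetic sessions), the residual appears as a
    common displacement between each unit's STA on the corrected movie and
    its true filter; the SNR-weighted mean displacement (sub-pixel, by
    quadratic interpolation of the cross-correlation peak) is added to every
    grid node.  Returns (refined grid, corrected ROI movie).
    """
    from scipy.signal import fftconvolve

    from . import foveal
    from .calibnet import CalibrationGrid

    movie = gazestim.reconstruct_roi_movie(
        sess["dots"], sess["trace_measured"], sess["roi"],
        calibration_grid=grid,
    )
    pitch = sess["roi"].pitch
    disps = []
    weights = []
    for u in range(counts.shape[1]):
        res = foveal.compute_sta(movie.movie, counts[:, u], n_lags=n_lags,
                                 mask=mask)
        z = np.abs(res.z).max()
        if z < min_peak_z:
            continue
        frame = res.sta[res.peak_lag]
        filt = sess["filters"][u]
        cc = fftconvolve(frame, filt[::-1, ::-1], mode="full")
        pr, pc = np.unravel_index(np.argmax(cc), cc.shape)

        def _parab(cm, c0, cp):
            d = cm - 2 * c0 + cp
            return 0.0 if d >= 0 else 0.5 * (cm - cp) / d

        sub_r = _parab(*cc[pr - 1 : pr + 2, pc]) if 0 < pr < cc.shape[0] - 1 else 0.0
        sub_c = _parab(*cc[pr, pc - 1 : pc + 2]) if 0 < pc < cc.shape[1] - 1 else 0.0
        s_row = pr + sub_r - (filt.shape[0] - 1)
        s_col = pc + sub_c - (filt.shape[1] - 1)
        disps.append((s_col * pitch, -s_row * pitch))  # screen coords, y up
        weights.append(z)
    if not disps:
        return grid, movie
    disps = np.asarray(disps)
    w = np.asarray(weights)
    dx, dy = (disps * w[:, None]).sum(axis=0) / w.sum()
    refined = CalibrationGrid(
        nodes=grid.nodes.copy(),
        dx_arcmin=grid.dx_arcmin + dx * 60.0,
        dy_arcmin=grid.dy_arcmin + dy * 60.0,
    )
    return refined, movie


def _true_correction_field(cfg: dict):
    """Analytic correction measured gaze -> true gaze for the configured
    distortion: true = (measured - offset) / gain."""
    off = np.asarray(cfg["offset_arcmin"], dtype=float) / 60.0
    g = cfg["calibration_gain"]

    def corr(x, y):
        return ((x - off[0]) / g - x, (y - off[1]) / g - y)

    return corr


def run_foveal_session(config: dict | None = None, seed: int = 0,
                       outdir=None) -> dict:
    """Foveal session: simulate miscalibration, train the calibration model,
    export the correction grid, re-extract the movie, and compare pre/post
    STAs (significance + simple/complex labels)."""
    cfg = {**DEFAULT_FOVEAL_CONFIG, **(config or {})}
    sess = simulate_foveal_session(cfg, seed)
    s_train = child_seeds(seed, 6)[4]

    saccades = eyetrack.detect_saccades(sess["trace_measured"])
    mask = eyetrack.analysis_mask(sess["dots"].frame_times, saccades)

    model = calibnet.GazeCalibrationModel(
        sess["roi"].shape, cfg["n_units"], sess["roi"].pitch, seed=s_train
    )
    results = model.fit(
        sess["movie_measured"].movie, sess["gaze_measured"], sess["counts"],
        frame_mask=mask, n_steps=cfg["train_steps"], seed=s_train,
    )
    grid = calibnet.absolute_correction_grid(results, sess["anchors"])
    grid, movie_corr = refine_gauge_with_sta(grid, sess, sess["counts"],
                                             mask=mask)
    # true-correction residual on the grid
    corr = _true_correction_field(cfg)
    gx, gy = np.meshgrid(grid.nodes, grid.nodes)
    tx, ty = corr(gx, gy)
    resid = np.hypot(grid.dx_arcmin - tx * 60.0, grid.dy_arcmin - ty * 60.0)

    report = {
        "config_hash": config_hash(cfg),
        "seed": seed,
        "calibration_failed": results.failed,
        "grid_median_residual_arcmin": float(np.median(resid)),
        "units": [],
    }
    n_lags = cfg["n_sta_lags"]
    for u in range(cfg["n_units"]):
        # energy STA for phase-invariant units (their linear STA is noise)
        sta_fn = (foveal.compute_sta if sess["kinds"][u] == "simple"
                  else foveal.squared_sta)
        pre = sta_fn(sess["movie_measured"].movie, sess["counts"][:, u],
                     n_lags=n_lags, mask=mask)
        post = sta_fn(movie_corr.movie, sess["counts"][:, u], n_lags=n_lags,
                      mask=mask, norm_constants=pre.norm_constants)
        label, dll = foveal.classify_simple_complex(
            movie_corr.movie, sess["counts"][:, u], mask=mask
        )
        report["units"].append({
            "unit": u,
            "kind_true": sess["kinds"][u],
            "label": label,
            "delta_cvll": dll,
            "pre_peak_z": float(np.abs(pre.z).max()),
            "post_peak_z": float(np.abs(post.z).max()),
        })
    report["frac_z_improved"] = float(np.mean(
        [u["post_peak_z"] >= u["pre_peak_z"] for u in report["units"]]
    ))
    _write(outdir, "foveal_report.json", report)
    return report
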