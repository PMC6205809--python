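"""Seeded generators for every input the analysis pipeline consumes.

Five generators emulate the recordings of a single-synapse optogenetic
plasticity experiment: line-scan trial sets (stochastic paired-pulse
transmission with GCaMP6s-like transients), frame-scan movies (responder
detection), structural two-photon stacks (spheres on a cylindrical
dendrite, blurred by a Gaussian PSF with exponential depth attenuation),
sub-resolution bead stacks (PSF calibration), and longitudinal cohorts
(induction outcomes, transient volume changes and day-1→day-7 spine
elimination). Every stochastic draw is recorded in a :class:`GroundTruth`
object kept separate from the generated data, so parameter-recovery tests
can compare pipeline output against the generating truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .config import (ROLES, SESSIONS, PlasticityCondition, RunConfig,
                     StimulusProtocol, SynapseModel)
from .epscat import Trace
from .shapes import double_exp

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: When a condition's induction fails, survival statistics follow the
#: matching failed-protocol condition instead.
FAILURE_FALLBACK = {
    "LTP_with_CSB": "oTFS_no_CSB",
    "LTD_then_LTP": "LTD_then_oTFS_fail",
    "LTP_then_LTD": "LTP_then_oLFS_fail",
    "LTD": "control",  # no-LTD experiments are excluded downstream
}

#: Protocol sequence implied by each condition label (day0, day1).
CONDITION_PROTOCOLS = {
    "control": (None, None),
    "responsive_only": (None, None),
    "LTP_with_CSB": ("oTFS", None),
    "oTFS_no_CSB": ("oTFS", None),
    "LTD": ("oLFS", None),
    "LTD_then_LTP": ("oLFS", "oTFS"),
    "LTD_then_oTFS_fail": ("oLFS", "oTFS"),
    "LTP_then_LTD": ("oTFS", "oLFS"),
    "LTP_then_oLFS_fail": ("oTFS", "oLFS"),
}


@dataclass
class GroundTruth:
    """Record of every stochastic draw behind a generated dataset.

    Emitted alongside the data but never consumed by analysis stages.
    """

    kind: str
    data: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"kind": self.kind, "data": _jsonable(self.data)}, fh,
                      indent=1)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    return obj


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and CV."""
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _draw_amplitudes(rng, mean: float, cv: float, n: int) -> np.ndarray:
    if mean == 0:
        return np.zeros(n)
    if cv == 0:
        return np.full(n, mean)
    mu, sigma = _lognormal_params(mean, cv)
    return rng.lognormal(mu, sigma, size=n)


# ---------------------------------------------------------------------------
# Line-scan trial sets
# ---------------------------------------------------------------------------

def generate_trial_set(model: SynapseModel, protocol: StimulusProtocol,
                       n_trials: int = 20, fs: float = 500.0,
                       duration_s: float = 3.0, first_pulse_s: float = 0.2,
                       seed: int = 0) -> tuple[list[Trace], GroundTruth]:
    """Simulate repeated line-scan trials of one stimulated spine.

    Each trace is zero-mean Gaussian baseline noise plus, for each light
    pulse independently with probability ``p_release``, a unit-peak double
    exponential scaled by a log-normal amplitude (the second pulse of a pair
    additionally by ``paired_pulse_ratio``).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if fs < 2.0 / model.tau_rise_s:
        raise ValueError("fs too low to resolve the transient rise")
    pulse_times = protocol.pulse_times(first_pulse_s)
    if duration_s < pulse_times[-1] + 5.0 * model.tau_decay_s:
        raise ValueError("duration must cover all pulses plus 5 tau_decay")

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    n_pulses = len(pulse_times)

    # per-pulse unit-peak shapes, normalised on the sampled grid so a
    # noiseless deterministic trial peaks exactly at amplitude_mean
    pulse_shapes = []
    for t0 in pulse_times:
        s = double_exp(t, model.tau_rise_s, model.tau_decay_s, t0)
        pulse_shapes.append(s / s.max())

    released = rng.random((n_trials, n_pulses)) < model.p_release
    amps = _draw_amplitudes(rng, model.amplitude_mean, model.amplitude_cv,
                            n_trials * n_pulses).reshape(n_trials, n_pulses)
    if protocol.paired_pulse_interval_ms is not None and n_pulses == 2:
        amps[:, 1] *= model.paired_pulse_ratio
    amps = np.where(released, amps, 0.0)

    traces = []
    for i in range(n_trials):
        y = rng.normal(0.0, model.noise_sd, size=n) if model.noise_sd > 0 \
            else np.zeros(n)
        for j in range(n_pulses):
            if released[i, j]:
                y = y + amps[i, j] * pulse_shapes[j]
        traces.append(Trace(y, fs, pulse_times, roi_id="spine0",
                            roi_kind="spine"))

    truth = GroundTruth("trial_set", {
        "released": released, "amplitudes": amps,
        "pulse_times_s": list(pulse_times),
        "model": {"p_release": model.p_release,
                  "amplitude_mean": model.amplitude_mean,
                  "amplitude_cv": model.amplitude_cv,
                  "tau_rise_s": model.tau_rise_s,
                  "tau_decay_s": model.tau_decay_s,
                  "noise_sd": model.noise_sd,
                  "paired_pulse_ratio": model.paired_pulse_ratio},
    })
    return traces, truth


# ---------------------------------------------------------------------------
# Frame-scan movies
# ---------------------------------------------------------------------------

def generate_frame_scan(model: SynapseModel, n_trials: int = 5,
                        n_frames: int = 14, frame_rate_hz: float = 7.8,
                        field_um: float = 10.0, px: int = 64,
                        rest_frames: int = 5, n_spines: int = 3,
                        responding_index: int = 0, baseline: float = 100.0,
                        shot_scale: float = 1.0, seed: int = 0
                        ) -> tuple[np.ndarray, dict, GroundTruth]:
    """Simulate repeated frame-scan trials over a dendritic field.

    Returns ``(movie, roi_masks, truth)`` where ``movie`` has shape
    (n_trials, n_frames, px, px). Spines are 2-D Gaussian blobs on a static
    dendrite band; only the responding spine follows the stimulated
    transient time course, resampled at the frame rate. Noise is Gaussian
    with variance proportional to intensity (shot-like).
    """
    if px < 1 or n_frames < 1:
        raise ValueError("px and n_frames must be >= 1")
    if rest_frames >= n_frames:
        raise ValueError("need post-stimulus frames")
    rng = np.random.default_rng(seed)
    um_per_px = field_um / px
    yy, xx = np.mgrid[0:px, 0:px] * um_per_px

    dendrite_y = field_um / 2.0
    background = baseline * 0.5 * np.exp(-((yy - dendrite_y) / 0.5) ** 2)

    # spines spaced along the dendrite, offset laterally
    spine_sigma_um = 0.35
    positions = []
    for k in range(n_spines):
        x_um = field_um * (k + 1) / (n_spines + 1)
        y_um = dendrite_y + 1.2 * (1 if k % 2 == 0 else -1)
        positions.append((x_um, y_um))

    blobs, roi_masks = [], {}
    for k, (x_um, y_um) in enumerate(positions):
        blob = np.exp(-(((xx - x_um) ** 2 + (yy - y_um) ** 2)
                        / (2 * spine_sigma_um**2)))
        blobs.append(blob)
        roi_masks[f"spine{k}"] = blob > 0.3

    # transient time course at frame resolution; stimulus at the first
    # post-rest frame
    t_frames = np.arange(n_frames) / frame_rate_hz
    t_stim = rest_frames / frame_rate_hz
    shape = double_exp(t_frames, model.tau_rise_s, model.tau_decay_s, t_stim)
    shape = shape / shape.max() if shape.max() > 0 else shape

    released = rng.random(n_trials) < model.p_release
    amps = _draw_amplitudes(rng, model.amplitude_mean, model.amplitude_cv,
                            n_trials)
    amps = np.where(released, amps, 0.0)

    movie = np.empty((n_trials, n_frames, px, px))
    for i in range(n_trials):
        for f in range(n_frames):
            frame = background.copy()
            for k, blob in enumerate(blobs):
                dff = amps[i] * shape[f] if k == responding_index else 0.0
                frame = frame + baseline * blob * (1.0 + dff)
            noisy = frame + rng.normal(0.0, 1.0, frame.shape) * \
                shot_scale * np.sqrt(np.maximum(frame, 0.0))
            movie[i, f] = noisy

    truth = GroundTruth("frame_scan", {
        "responding_roi": f"spine{responding_index}",
        "released": released, "amplitudes": amps,
        "rest_frames": rest_frames, "positions_um": positions,
    })
    return movie, roi_masks, truth


# ---------------------------------------------------------------------------
# Structural stacks and bead stacks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StackGeometry:
    """Voxel grid for synthetic structural / bead stacks (z, y, x order)."""

    shape_vox: tuple = (60, 100, 100)
    voxel_um: tuple = (0.25, 0.1, 0.1)

    @property
    def extent_um(self) -> tuple:
        return tuple(s * v for s, v in zip(self.shape_vox, self.voxel_um))


def _rasterize_ball(grid: StackGeometry, center_um, radius_um) -> np.ndarray:
    """Volume-fraction rasterisation of a solid sphere (3× supersampled)."""
    shape = grid.shape_vox
    vz, vy, vx = grid.voxel_um
    cz, cy, cx = center_um
    out = np.zeros(shape)
    # bounding box in voxels
    zr = int(np.ceil(radius_um / vz)) + 2
    yr = int(np.ceil(radius_um / vy)) + 2
    xr = int(np.ceil(radius_um / vx)) + 2
    iz, iy, ix = int(cz / vz), int(cy / vy), int(cx / vx)
    sub = 3
    offs = (np.arange(sub) + 0.5) / sub
    for z in range(max(0, iz - zr), min(shape[0], iz + zr + 1)):
        for y in range(max(0, iy - yr), min(shape[1], iy + yr + 1)):
            for x in range(max(0, ix - xr), min(shape[2], ix + xr + 1)):
                zc = (z + offs) * vz - cz
                yc = (y + offs) * vy - cy
                xc = (x + offs) * vx - cx
                d2 = (zc[:, None, None]**2 + yc[None, :, None]**2
                      + xc[None, None, :]**2)
                out[z, y, x] = np.mean(d2 <= radius_um**2)
    return out


def _psf_sigma_vox(fwhm_um: Sequence[float], voxel_um: Sequence[float]):
    # fwhm given laterally-first (x, y, z); grid is (z, y, x)
    fx, fy, fz = fwhm_um
    vz, vy, vx = voxel_um
    return (fz * FWHM_TO_SIGMA / vz, fy * FWHM_TO_SIGMA / vy,
            fx * FWHM_TO_SIGMA / vx)


def generate_structural_stack(spines: Sequence[tuple], psf_fwhm_um,
                              brightness: float = 1000.0,
                              depth_um: float = 0.0,
                              attenuation_length_um: float = 50.0,
                              dendrite_radius_um: float = 0.4,
                              neck_length_um: float = 1.0,
                              noise_sd: float = 0.0,
                              grid: Optional[StackGeometry] = None,
                              seed: int = 0
                              ) -> tuple[np.ndarray, dict, GroundTruth]:
    """Render a dendritic segment with spherical spine heads through the PSF.

    ``spines`` is a list of ``(position_um_along_dendrite, volume_um3)``.
    The dendrite is a cylinder along x at mid-field; spine heads sit above
    it, separated by a thin neck (not rendered — necks are below
    resolution). Output intensity is ``brightness × exp(−depth/λ)`` inside
    cytosol, convolved with the Gaussian PSF, plus optional Gaussian noise.
    """
    grid = grid or StackGeometry()
    rng = np.random.default_rng(seed)
    ez, ey, ex = grid.extent_um
    for fw, v in zip(psf_fwhm_um, (grid.voxel_um[2], grid.voxel_um[1],
                                   grid.voxel_um[0])):
        if fw * FWHM_TO_SIGMA < 1.0 * v:
            raise ValueError("PSF must span >= ~3 voxels per axis")

    cyto = np.zeros(grid.shape_vox)
    vz, vy, vx = grid.voxel_um
    z_um = (np.arange(grid.shape_vox[0]) + 0.5) * vz
    y_um = (np.arange(grid.shape_vox[1]) + 0.5) * vy
    cz, cy = ez / 2.0, ey / 2.0
    r2 = ((z_um[:, None] - cz) ** 2 + (y_um[None, :] - cy) ** 2)
    cyl = (r2 <= dendrite_radius_um**2).astype(float)
    cyto += cyl[:, :, None]

    centers = []
    for pos_um, vol_um3 in spines:
        if vol_um3 <= 0:
            raise ValueError("spine volumes must be positive")
        r_head = (3.0 * vol_um3 / (4.0 * np.pi)) ** (1.0 / 3.0)
        head_y = cy + dendrite_radius_um + neck_length_um + r_head
        center = (cz, head_y, pos_um)
        if head_y - r_head < cy + dendrite_radius_um:
            raise ValueError(
                f"spine at {pos_um} um overlaps the dendrite shaft")
        cyto = np.maximum(cyto, _rasterize_ball(grid, center, r_head))
        centers.append(center)

    atten = np.exp(-depth_um / attenuation_length_um)
    stack = gaussian_filter(brightness * atten * cyto,
                            _psf_sigma_vox(psf_fwhm_um, grid.voxel_um),
                            mode="constant")
    if noise_sd > 0:
        stack = stack + rng.normal(0.0, noise_sd * brightness, stack.shape)

    meta = {
        "voxel_um": list(grid.voxel_um), "depth_um": depth_um,
        "attenuation_length_um": attenuation_length_um,
        "brightness": brightness, "psf_fwhm_um": list(psf_fwhm_um),
        "dendrite_center_um": [cz, cy], "dendrite_radius_um": dendrite_radius_um,
    }
    truth = GroundTruth("structural_stack", {
        "volumes_um3": [v for _, v in spines],
        "positions_um": [p for p, _ in spines],
        "head_centers_um": centers,
    })
    return stack, meta, truth


def generate_bead_stack(psf_fwhm_um=(0.4, 0.4, 1.6),
                        bead_diameter_um: float = 0.17,
                        n_beads: int = 4, brightness: float = 1000.0,
                        noise_sd: float = 0.0,
                        grid: Optional[StackGeometry] = None,
                        seed: int = 0) -> tuple[np.ndarray, dict, GroundTruth]:
    """Image isolated sub-resolution beads through the stated Gaussian PSF."""
    fx, fy, fz = psf_fwhm_um
    if bead_diameter_um >= min(fx, fy):
        raise ValueError("bead must be smaller than the lateral PSF FWHM")
    grid = grid or StackGeometry()
    rng = np.random.default_rng(seed)
    ez, ey, ex = grid.extent_um

    # beads on a jittered grid, kept well apart and away from borders
    margin = 1.5
    centers = []
    slots = np.linspace(margin, ex - margin, n_beads)
    for k in range(n_beads):
        centers.append((
            ez / 2.0 + rng.uniform(-0.5, 0.5),
            margin + rng.uniform(0, ey - 2 * margin),
            slots[k] + rng.uniform(-0.3, 0.3),
        ))

    field = np.zeros(grid.shape_vox)
    r_bead = bead_diameter_um / 2.0
    for c in centers:
        field += _rasterize_ball(grid, c, r_bead)
    stack = gaussian_filter(brightness * field,
                            _psf_sigma_vox(psf_fwhm_um, grid.voxel_um),
                            mode="constant")
    if noise_sd > 0:
        stack = stack + rng.normal(0.0, noise_sd * stack.max(), stack.shape)

    meta = {"voxel_um": list(grid.voxel_um), "psf_fwhm_um": list(psf_fwhm_um),
            "bead_diameter_um": bead_diameter_um}
    truth = GroundTruth("bead_stack", {"centers_um": centers,
                                       "psf_fwhm_um": list(psf_fwhm_um)})
    return stack, meta, truth


# ---------------------------------------------------------------------------
# Longitudinal cohorts
# ---------------------------------------------------------------------------

def generate_cohort(condition: PlasticityCondition, n_experiments: int,
                    spines_per_dendrite: int = 6, seed: int = 0,
                    config: Optional[RunConfig] = None,
                    displacement_frac: float = 0.02,
                    ratio_noise_cv: float = 0.03,
                    volume_noise_cv: float = 0.05
                    ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a longitudinal imaging cohort for one plasticity condition.

    Returns ``(spines, experiments, truth)``. ``spines`` has one row per
    spine × session (d0_pre, d0_post30, d1, d7) with volume, presence and
    displacement; ``experiments`` has one row per experiment with the
    measured post/pre calcium-response ratios and the protocol sequence.
    The induction outcome is drawn per experiment; when induction fails,
    elimination probabilities fall back to the matching failed-protocol
    condition.
    """
    if n_experiments < 1:
        raise ValueError("n_experiments must be >= 1")
    config = config or RunConfig()
    rng = np.random.default_rng(seed)
    cal = config.calibration
    dend_len = cal["cohort"]["dendrite_length_um"]
    vol_mean = cal["cohort"]["baseline_volume_um3"]["mean"]
    vol_cv = cal["cohort"]["baseline_volume_um3"]["cv"]
    cutoff = cal["thresholds"]["distant_cutoff_um"]
    horizon = cal["thresholds"]["neighbor_horizon_um"]
    proto_d0, proto_d1 = CONDITION_PROTOCOLS[condition.label]

    fallback = FAILURE_FALLBACK.get(condition.label)
    fallback_cond = config.condition(fallback) if fallback else None

    spine_rows, exp_rows = [], []
    truth_rows, exp_success = [], []
    for e in range(n_experiments):
        exp_id = f"exp{e:05d}"
        success = bool(rng.random() < condition.induction_success_prob)
        elim_table = (condition.elimination_prob_d1_d7 if success
                      else (fallback_cond.elimination_prob_d1_d7
                            if fallback_cond
                            else condition.elimination_prob_d1_d7))

        # measured post/pre response ratios for day-0 and day-1 stages
        def ratio_for(protocol, stage_success):
            if protocol is None:
                return None
            scale = (condition.potency_scale_post * condition.pca_scale_post
                     if stage_success else 1.0)
            mu, sg = _lognormal_params(max(scale, 1e-6), ratio_noise_cv)
            return float(rng.lognormal(mu, sg))

        if proto_d1 is None:
            ratio_d0 = ratio_for(proto_d0, success)
            ratio_d1 = None
            csb_d0 = success if proto_d0 == "oTFS" else None
            csb_d1 = None
        else:
            # two-stage conditions presume a successful day-0 stage; the
            # condition's success probability governs the day-1 stage
            day0_success = True
            day0_scale = {"oLFS": 0.4, "oTFS": 1.5}[proto_d0]
            mu, sg = _lognormal_params(day0_scale, ratio_noise_cv)
            ratio_d0 = float(rng.lognormal(mu, sg))
            ratio_d1 = ratio_for(proto_d1, success)
            csb_d0 = day0_success if proto_d0 == "oTFS" else None
            csb_d1 = success if proto_d1 == "oTFS" else None

        # spine layout: stimulated spine mid-dendrite, neighbors around it
        stim_pos = dend_len / 2.0
        positions = [stim_pos]
        for _ in range(spines_per_dendrite - 1):
            positions.append(float(rng.uniform(max(0.0, stim_pos - horizon),
                                               min(dend_len, stim_pos + horizon))))
        for s_idx, pos in enumerate(positions):
            stimulated = s_idx == 0
            dist = abs(pos - stim_pos)
            if stimulated:
                role = "stimulated"
            elif dist <= cutoff:
                role = "nearest_neighbor"
            elif dist <= horizon:
                role = "distant"
            else:
                role = "ignored"
            vmu, vsg = _lognormal_params(vol_mean, vol_cv)
            v_base = float(rng.lognormal(vmu, vsg))
            vol_scale = {"stimulated": condition.volume_scale_stim,
                         "nearest_neighbor": condition.volume_scale_nearest,
                         "distant": condition.volume_scale_distant,
                         "ignored": 1.0}[role]
            if not success:
                vol_scale = 1.0

            elim_p = elim_table.get(role, 0.0) if role != "ignored" else 0.0
            eliminated = bool(rng.random() < elim_p)
            displaced = bool(rng.random() < displacement_frac)

            session_vols = {"d0_pre": v_base,
                            "d0_post30": v_base * vol_scale,
                            "d1": v_base, "d7": v_base}
            for sess in SESSIONS:
                present = not (eliminated and sess == "d7")
                vmeas = None
                if present:
                    mu2, sg2 = _lognormal_params(session_vols[sess],
                                                 volume_noise_cv)
                    vmeas = float(rng.lognormal(mu2, sg2))
                disp = 0.0
                if sess != "d0_pre":
                    disp = float(abs(rng.normal(0.0, 0.15)))
                    if displaced and sess == "d1":
                        disp = float(rng.uniform(1.2, 2.0))
                spine_rows.append({
                    "experiment_id": exp_id, "condition": condition.label,
                    "spine_id": f"{exp_id}_s{s_idx}", "role": role,
                    "position_um": pos, "session": sess,
                    "volume_um3": vmeas, "present": present,
                    "displacement_um": disp,
                })
            truth_rows.append({
                "experiment_id": exp_id, "spine_id": f"{exp_id}_s{s_idx}",
                "role": role, "true_volume_um3": v_base,
                "eliminated": eliminated, "displaced": displaced,
            })

        exp_rows.append({
            "experiment_id": exp_id, "condition": condition.label,
            "protocol_d0": proto_d0, "protocol_d1": proto_d1,
            "ratio_d0": ratio_d0, "ratio_d1": ratio_d1,
            "csb_d0": csb_d0, "csb_d1": csb_d1,
        })
        exp_success.append(success)

    spines = pd.DataFrame(spine_rows)
    experiments = pd.DataFrame(exp_rows)
    truth = GroundTruth("cohort", {
        "condition": condition.label,
        "spines": truth_rows,
        "induction_success_by_experiment": exp_success,
    })
    return spines, experiments, truth
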