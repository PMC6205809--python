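"""PSF calibration, fluorescence-to-volume conversion and spine tracking.

Spine head volumes are estimated from a single optical section through the
head center: the background-subtracted fluorescence integral over the head
ROI, divided by the brightness of a PSF fully immersed in cytoplasm
(``f_max``), gives the head's effective area; multiplying by the PSF's
effective axial extent ``z_eff = V_PSF / A_xy`` converts it to an absolute
volume. ``V_PSF = (2π)^{3/2}·σx·σy·σz`` and ``A_xy = 2π·σx·σy`` follow from
the Gaussian PSF calibrated on sub-resolution fluorescent beads. A defining
property of the formula: an ROI placed in a uniform cytoplasm slab returns
ROI area × z_eff.

The longitudinal side tracks spines across registered sessions by nearest
dendritic position, excludes spines displaced by more than 1 µm between
consecutive sessions (ambiguous identity), classifies neighbors of the
stimulated spine by distance, and reports per-condition, per-role survival
fractions with bootstrap intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import center_of_mass, label as nd_label
from scipy.optimize import least_squares

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PsfCalibration:
    """Gaussian PSF summary used by the volume conversion.

    ``fwhm_um`` is (x, y, z). ``f_max`` — the voxel value with the PSF fully
    immersed in cytoplasm — is attached by :func:`measure_f_max`.
    """

    fwhm_um: tuple
    f_max: Optional[float] = None

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fwhm_um):
            raise ValueError("FWHMs must be positive")

    @property
    def sigma_um(self) -> tuple:
        return tuple(f * FWHM_TO_SIGMA for f in self.fwhm_um)

    @property
    def v_psf_um3(self) -> float:
        sx, sy, sz = self.sigma_um
        return float((2.0 * np.pi) ** 1.5 * sx * sy * sz)

    @property
    def a_xy_um2(self) -> float:
        sx, sy, _ = self.sigma_um
        return float(2.0 * np.pi * sx * sy)

    @property
    def z_eff_um(self) -> float:
        return self.v_psf_um3 / self.a_xy_um2  # = sqrt(2 pi) * sigma_z


# ---------------------------------------------------------------------------
# PSF calibration from bead stacks
# ---------------------------------------------------------------------------

def _fit_gaussian_3d(crop: np.ndarray, voxel_um) -> tuple:
    """Least-squares 3-D Gaussian fit; returns (center_um, sigma_um (z,y,x))."""
    coords = [np.arange(n) * v for n, v in zip(crop.shape, voxel_um)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    amp0 = float(crop.max())
    c0 = [float(c[i]) for c, i in
          zip(coords, np.unravel_index(np.argmax(crop), crop.shape))]
    s0 = [max(0.3 * (c[-1] - c[0]), 0.05) for c in coords]

    def resid(p):
        a, cz, cy, cx, sz, sy, sx, off = p
        g = a * np.exp(-(((zz - cz) / sz) ** 2 / 2
                         + ((yy - cy) / sy) ** 2 / 2
                         + ((xx - cx) / sx) ** 2 / 2)) + off
        return (g - crop).ravel()

    p0 = [amp0, *c0, *s0, 0.0]
    lb = [0.0, coords[0][0], coords[1][0], coords[2][0], 1e-3, 1e-3, 1e-3,
          -np.inf]
    ub = [np.inf, coords[0][-1], coords[1][-1], coords[2][-1],
          coords[0][-1] + 1, coords[1][-1] + 1, coords[2][-1] + 1, np.inf]
    sol = least_squares(resid, np.clip(p0, lb, ub), bounds=(lb, ub),
                        xtol=1e-10, ftol=1e-10)
    _, cz, cy, cx, sz, sy, sx, _ = sol.x
    return (cz, cy, cx), (sz, sy, sx)


def find_beads(stack: np.ndarray, voxel_um, min_separation_um: float = 1.0,
               threshold_frac: float = 0.3) -> list[tuple]:
    """Centroids (µm, z/y/x) of isolated bright blobs; overlapping pairs dropped."""
    stack = np.asarray(stack, dtype=float)
    if stack.max() <= 0:
        raise ValueError("no bead found above noise")
    mask = stack > threshold_frac * stack.max()
    labels, n = nd_label(mask)
    if n == 0:
        raise ValueError("no bead found above noise")
    centroids = [tuple(c * v for c, v in zip(com, voxel_um))
                 for com in center_of_mass(stack, labels, range(1, n + 1))]
    keep = []
    for i, ci in enumerate(centroids):
        ok = all(np.linalg.norm(np.subtract(ci, cj)) >= min_separation_um
                 for j, cj in enumerate(centroids) if j != i)
        if ok:
            keep.append(ci)
    if not keep:
        raise ValueError("all detected beads overlap; calibration invalid")
    return keep


def calibrate_psf(bead_stack: np.ndarray, voxel_um,
                  crop_um: float = 2.5) -> PsfCalibration:
    """Average per-bead 3-D Gaussian fits into a PSF calibration.

    ``voxel_um`` is (z, y, x). Each isolated bead is cropped and fitted;
    the per-axis FWHMs are averaged across beads.
    """
    stack = np.asarray(bead_stack, dtype=float)
    centers = find_beads(stack, voxel_um)
    half = [max(int(round(crop_um / v)), 3) for v in voxel_um]
    sigmas = []
    for c in centers:
        idx = [int(round(ci / v)) for ci, v in zip(c, voxel_um)]
        sl = tuple(slice(max(0, i - h), min(n, i + h + 1))
                   for i, h, n in zip(idx, half, stack.shape))
        crop = stack[sl]
        _, s = _fit_gaussian_3d(crop, voxel_um)
        sigmas.append(s)
    sz, sy, sx = np.mean(sigmas, axis=0)
    fwhm = tuple(float(s / FWHM_TO_SIGMA) for s in (sx, sy, sz))
    return PsfCalibration(fwhm_um=fwhm)


def measure_f_max(stack: np.ndarray, trunk_mask: np.ndarray,
                  cal: PsfCalibration,
                  trunk_width_um: Optional[float] = None,
                  percentile: float = 99.0,
                  smooth_vox: int = 5) -> tuple[float, bool]:
    """Cytoplasmic brightness with the PSF fully immersed in the trunk.

    Uses a robust maximum: the 99th-percentile value of the locally
    averaged stack inside the trunk ROI. Local averaging (a ``smooth_vox``
    box filter) suppresses the upward bias a raw-voxel percentile would
    take from shot noise, while the high percentile still selects voxels
    with the PSF fully immersed. Returns ``(f_max, flagged)``; ``flagged``
    is True when the trunk is thinner than twice the lateral FWHM, in which
    case ``f_max`` underestimates the true cytoplasmic brightness.
    """
    from scipy.ndimage import uniform_filter
    arr = np.asarray(stack, dtype=float)
    if smooth_vox > 1:
        arr = uniform_filter(arr, size=smooth_vox, mode="nearest")
    vals = arr[np.asarray(trunk_mask, dtype=bool)]
    if vals.size == 0:
        raise ValueError("empty trunk ROI")
    flagged = False
    if trunk_width_um is not None and trunk_width_um < 2.0 * max(cal.fwhm_um[:2]):
        flagged = True
    return float(np.percentile(vals, percentile)), flagged


# ---------------------------------------------------------------------------
# Volume estimation
# ---------------------------------------------------------------------------

def estimate_spine_volume(section: np.ndarray, roi_mask: np.ndarray,
                          cal: PsfCalibration, pixel_um: Sequence[float],
                          f_max: Optional[float] = None,
                          depth_offset_um: float = 0.0,
                          attenuation_length_um: float = np.inf,
                          background: Optional[float] = None,
                          annulus_width_px: int = 3) -> tuple[float, dict]:
    """Absolute spine-head volume from one optical section.

    ``V = Σ_ROI (F − background) · a_pixel / f_max_corrected · z_eff`` with
    ``f_max_corrected = f_max · exp(−Δdepth / attenuation_length)``
    accounting for laser attenuation when spine and calibration were imaged
    at different depths. ``background`` defaults to the median of an annulus
    around the ROI. Returns ``(volume_um3, flags)``.
    """
    section = np.asarray(section, dtype=float)
    roi = np.asarray(roi_mask, dtype=bool)
    if section.shape != roi.shape:
        raise ValueError("section and ROI shapes differ")
    f_max = f_max if f_max is not None else cal.f_max
    if f_max is None:
        raise ValueError("f_max required (measure_f_max or cal.f_max)")

    flags = {"border": False, "thin_trunk": False}
    edge = np.zeros_like(roi)
    edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
    if np.any(roi & edge):
        flags["border"] = True

    if background is None:
        from scipy.ndimage import binary_dilation
        outer = binary_dilation(roi, iterations=annulus_width_px * 2)
        annulus = outer & ~binary_dilation(roi, iterations=annulus_width_px)
        background = float(np.median(section[annulus])) if annulus.any() else 0.0

    f_max_corr = f_max * np.exp(-depth_offset_um / attenuation_length_um)
    if f_max_corr <= background:
        raise ValueError("f_max does not exceed background; ROI not measurable")

    a_pixel = float(pixel_um[0]) * float(pixel_um[1])
    integral = float((section[roi] - background).sum()) * a_pixel
    volume = integral / (f_max_corr - 0.0) * cal.z_eff_um
    return float(volume), flags


def measure_spine_from_stack(stack: np.ndarray, meta: dict,
                             head_center_um: Sequence[float],
                             cal: PsfCalibration, f_max: float,
                             roi_radius_um: float = 0.8,
                             depth_offset_um: float = 0.0,
                             attenuation_length_um: float = np.inf
                             ) -> tuple[float, dict]:
    """Convenience wrapper: central section + circular ROI from a 3-D stack.

    ``head_center_um`` is (z, y, x) in the stack's coordinate frame;
    ``meta['voxel_um']`` supplies the voxel size (z, y, x).
    """
    vz, vy, vx = meta["voxel_um"]
    cz, cy, cx = head_center_um
    iz = int(round(cz / vz))
    section = stack[iz]
    h, w = section.shape
    yy, xx = np.mgrid[0:h, 0:w]
    roi = ((yy * vy - cy) ** 2 + (xx * vx - cx) ** 2) <= roi_radius_um**2
    return estimate_spine_volume(section, roi, cal, (vy, vx), f_max=f_max,
                                 depth_offset_um=depth_offset_um,
                                 attenuation_length_um=attenuation_length_um)


def relative_volume_change(v_a: float, v_b: float) -> float:
    """Percent volume change from session a to session b: 100·(V_b−V_a)/V_a."""
    if v_a <= 0:
        raise ValueError("reference volume must be positive")
    return 100.0 * (v_b - v_a) / v_a


# ---------------------------------------------------------------------------
# Session registration and spine tracking
# ---------------------------------------------------------------------------

def register_sessions(stack_t0: np.ndarray, stack_t1: np.ndarray,
                      quality_floor: float = 0.2
                      ) -> tuple[tuple[int, ...], float, bool]:
    """Integer-voxel shift aligning ``stack_t1`` onto ``stack_t0``.

    Maximises the circular cross-correlation computed by FFT; the quality
    score is the normalised correlation at the optimum (1.0 for identical
    stacks). Returns ``(shift, quality, ok)``; ``ok`` is False below the
    quality floor (sessions unalignable).
    """
    a = np.asarray(stack_t0, dtype=float)
    b = np.asarray(stack_t1, dtype=float)
    if a.shape != b.shape:
        raise ValueError("stacks must share a shape for registration")
    a0 = a - a.mean()
    b0 = b - b.mean()
    corr = np.fft.ifftn(np.fft.fftn(a0) * np.conj(np.fft.fftn(b0))).real
    idx = np.unravel_index(np.argmax(corr), corr.shape)
    shift = tuple(int(i if i <= n // 2 else i - n)
                  for i, n in zip(idx, corr.shape))
    denom = np.sqrt((a0**2).sum() * (b0**2).sum())
    quality = float(corr[idx] / denom) if denom > 0 else 1.0
    return shift, quality, quality >= quality_floor


def track_spines(detections: dict, session_order: Sequence[str],
                 max_shift_um: float = 1.0,
                 ambiguity_um: float = 0.2) -> tuple[pd.DataFrame, list]:
    """Match spines across sessions by dendritic arclength position.

    ``detections`` maps session label → sequence of positions (µm) of the
    spines detected in that session. Greedy nearest matching links
    consecutive sessions; an unmatched prior spine is recorded absent from
    then on (eliminated); a match displaced by more than ``max_shift_um``
    excludes the spine from analysis (identity ambiguous); detections with
    no prior partner are returned as gained (reported, not used in
    survival). Returns ``(table, gained)``.
    """
    first = session_order[0]
    positions = {f"s{i}": float(p)
                 for i, p in enumerate(detections[first])}
    pos_vals = sorted(positions.values())
    for p, q in zip(pos_vals, pos_vals[1:]):
        if q - p < ambiguity_um:
            raise ValueError(
                f"ambiguous detections {p:.3f} and {q:.3f} um apart")

    state = {sid: {"position": p, "present": True, "excluded": False,
                   "reason": ""} for sid, p in positions.items()}
    rows = [{"spine_id": sid, "session": first, "position_um": p,
             "present": True, "displacement_um": 0.0, "excluded": False,
             "reason": ""} for sid, p in positions.items()]
    gained: list = []

    for prev, curr in zip(session_order, session_order[1:]):
        avail = sorted(float(p) for p in detections[curr])
        for p, q in zip(avail, avail[1:]):
            if q - p < ambiguity_um:
                raise ValueError(
                    f"ambiguous detections {p:.3f} and {q:.3f} um apart")
        unclaimed = list(avail)
        # greedy: closest (spine, detection) pairs first
        candidates = []
        for sid, st in state.items():
            if not st["present"] or st["excluded"]:
                continue
            for d in unclaimed:
                candidates.append((abs(d - st["position"]), sid, d))
        candidates.sort()
        matched_sids, claimed = set(), set()
        for dist, sid, d in candidates:
            if sid in matched_sids or d in claimed:
                continue
            matched_sids.add(sid)
            claimed.add(d)
            st = state[sid]
            if dist > max_shift_um:
                st["excluded"] = True
                st["reason"] = f"displaced {dist:.2f} um > {max_shift_um} um"
            st["position"] = d
            rows.append({"spine_id": sid, "session": curr, "position_um": d,
                         "present": True, "displacement_um": dist,
                         "excluded": st["excluded"], "reason": st["reason"]})
        for sid, st in state.items():
            if st["excluded"]:
                if sid not in matched_sids:
                    rows.append({"spine_id": sid, "session": curr,
                                 "position_um": st["position"],
                                 "present": False, "displacement_um": np.nan,
                                 "excluded": True, "reason": st["reason"]})
                continue
            if st["present"] and sid not in matched_sids:
                st["present"] = False  # eliminated; terminal
            if not st["present"]:
                rows.append({"spine_id": sid, "session": curr,
                             "position_um": st["position"], "present": False,
                             "displacement_um": np.nan,
                             "excluded": False, "reason": ""})
        gained.extend((curr, d) for d in unclaimed if d not in claimed)

    return pd.DataFrame(rows), gained


def classify_roles(positions: dict, stimulated_id: str,
                   distant_cutoff_um: float = 5.0,
                   neighbor_horizon_um: float = 10.0,
                   mode: str = "all_within_cutoff") -> dict:
    """Assign stimulated / nearest_neighbor / distant / ignored roles.

    Distances are measured along the dendrite from the stimulated spine:
    ≤ cutoff → nearest neighbor, (cutoff, horizon] → distant, beyond →
    ignored. ``mode='single_closest'`` restricts the nearest-neighbor label
    to the one closest spine.
    """
    if stimulated_id not in positions:
        raise ValueError(f"stimulated spine {stimulated_id!r} not in positions")
    vals = list(positions.values())
    if len(set(np.round(vals, 6))) != len(vals):
        raise ValueError("positions must be unique")
    p0 = positions[stimulated_id]
    roles = {}
    others = {sid: abs(p - p0) for sid, p in positions.items()
              if sid != stimulated_id}
    closest = min(others, key=others.get) if others else None
    for sid, dist in others.items():
        if dist <= distant_cutoff_um:
            if mode == "single_closest" and sid != closest:
                roles[sid] = "distant" if dist <= neighbor_horizon_um else "ignored"
            else:
                roles[sid] = "nearest_neighbor"
        elif dist <= neighbor_horizon_um:
            roles[sid] = "distant"
        else:
            roles[sid] = "ignored"
    roles[stimulated_id] = "stimulated"
    return roles


# ---------------------------------------------------------------------------
# Survival analysis
# ---------------------------------------------------------------------------

def survival_fractions(cohort: pd.DataFrame, from_session: str,
                       to_session: str, n_bootstrap: int = 2000,
                       seed: int = 0, ci: float = 0.95) -> pd.DataFrame:
    """Surviving fraction per (condition, role) with percentile bootstrap CI.

    A spine contributes when it is not excluded and present at
    ``from_session``; it survives when also present at ``to_session``.
    Bootstrap resamples experiments (cluster bootstrap). Zero denominators
    yield NaN fractions (undefined), never 0.
    """
    df = cohort.copy()
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    wide = df.pivot_table(index=["condition", "role", "experiment_id",
                                 "spine_id"],
                          columns="session", values="present",
                          aggfunc="first").reset_index()
    for s in (from_session, to_session):
        if s not in wide.columns:
            raise ValueError(f"session {s!r} missing from cohort")
    wide = wide[wide[from_session].fillna(False).astype(bool)]
    wide["survived"] = wide[to_session].fillna(False).astype(bool)

    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci) / 2.0
    out = []
    for (cond, role), grp in wide.groupby(["condition", "role"], sort=True):
        if role == "ignored":
            continue
        n_from = len(grp)
        n_to = int(grp["survived"].sum())
        frac = n_to / n_from if n_from else np.nan
        lo = hi = np.nan
        exps = grp["experiment_id"].unique()
        if n_from and n_bootstrap and len(exps):
            by_exp = {e: g["survived"].to_numpy()
                      for e, g in grp.groupby("experiment_id")}
            stats = np.empty(n_bootstrap)
            keys = list(by_exp)
            for b in range(n_bootstrap):
                pick = rng.integers(0, len(keys), size=len(keys))
                vals = np.concatenate([by_exp[keys[i]] for i in pick])
                stats[b] = vals.mean() if vals.size else np.nan
            lo, hi = np.nanquantile(stats, [alpha, 1.0 - alpha])
        out.append({"condition": cond, "role": role, "n_from": n_from,
                    "n_to": n_to, "fraction": frac,
                    "ci_low": float(lo) if np.isfinite(lo) else np.nan,
                    "ci_high": float(hi) if np.isfinite(hi) else np.nan})
    return pd.DataFrame(out)
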