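"""Run configuration and the declarative calibration table.

Every literature-derived default — stimulation protocols, induction success
rates, volume effect sizes, day-1 to day-7 elimination probabilities, and
analysis thresholds — lives in :data:`DEFAULT_CALIBRATION`. Generator and
analysis code read these numbers from the config object; none are hard-coded
in logic, so a single edited YAML file redefines the simulated experiment.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

#: Condition labels recognised throughout the pipeline.
CONDITION_LABELS = (
    "control",
    "responsive_only",
    "LTP_with_CSB",
    "oTFS_no_CSB",
    "LTD",
    "LTD_then_LTP",
    "LTD_then_oTFS_fail",
    "LTP_then_LTD",
    "LTP_then_oLFS_fail",
)

SESSIONS = ("d0_pre", "d0_post30", "d1", "d7")

ROLES = ("stimulated", "nearest_neighbor", "distant")


@dataclass(frozen=True)
class StimulusProtocol:
    """A train of optogenetic light pulses.

    ``paired_pulse_interval_ms`` is set only for the two-pulse test stimulus
    used to probe transmission; induction trains (theta-frequency, 5 Hz, and
    low-frequency, 1 Hz) are single-pulse trains.
    """

    name: str
    n_pulses: int
    pulse_rate_hz: float
    pulse_width_ms: float = 2.0
    paired_pulse_interval_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if self.pulse_rate_hz <= 0:
            raise ValueError("pulse_rate_hz must be > 0")
        if self.pulse_width_ms <= 0:
            raise ValueError("pulse_width_ms must be > 0")

    @property
    def duration_s(self) -> float:
        return self.n_pulses / self.pulse_rate_hz

    def pulse_times(self, first_pulse_s: float = 0.0) -> list[float]:
        """Stimulus onset times in seconds.

        For the paired test stimulus the second pulse follows the first by
        the paired-pulse interval; induction trains tick at 1/rate.
        """
        if self.paired_pulse_interval_ms is not None:
            if self.n_pulses != 2:
                raise ValueError("paired-pulse protocol requires n_pulses == 2")
            return [first_pulse_s, first_pulse_s + self.paired_pulse_interval_ms / 1000.0]
        return [first_pulse_s + i / self.pulse_rate_hz for i in range(self.n_pulses)]


@dataclass(frozen=True)
class SynapseModel:
    """Generative model of one stimulated spine synapse.

    Parameters mirror the quantities the analysis estimates: per-pulse
    release probability (the P_Ca counterpart), mean success amplitude
    (potency counterpart, ΔF/F_0 units), log-normal amplitude CV, GCaMP6s-like
    rise/decay time constants, baseline noise SD, and a paired-pulse scale
    applied to the second response of a pulse pair.
    """

    p_release: float = 0.5
    amplitude_mean: float = 1.0
    amplitude_cv: float = 0.3
    tau_rise_s: float = 0.05
    tau_decay_s: float = 0.5
    noise_sd: float = 0.1
    paired_pulse_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_release <= 1.0:
            raise ValueError("p_release must lie in [0, 1]")
        if self.tau_rise_s >= self.tau_decay_s:
            raise ValueError("tau_rise must be < tau_decay")
        if self.tau_rise_s <= 0:
            raise ValueError("tau_rise must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.amplitude_mean < 0:
            raise ValueError("amplitude_mean must be non-negative")
        if self.amplitude_cv < 0:
            raise ValueError("amplitude_cv must be non-negative")
        if self.paired_pulse_ratio <= 0:
            raise ValueError("paired_pulse_ratio must be positive")


@dataclass(frozen=True)
class PlasticityCondition:
    """Calibrated effect sizes for one experimental condition.

    ``elimination_prob_d1_d7`` maps spine role to the probability that a
    spine present on day 1 is gone by day 7. ``volume_scale_*`` apply
    transiently at the 30-min post-induction session and relax to baseline
    by day 1.
    """

    label: str
    induction_success_prob: float = 1.0
    potency_scale_post: float = 1.0
    pca_scale_post: float = 1.0
    volume_scale_stim: float = 1.0
    volume_scale_nearest: float = 1.0
    volume_scale_distant: float = 1.0
    elimination_prob_d1_d7: dict = field(
        default_factory=lambda: {r: 0.27 for r in ROLES}
    )

    def __post_init__(self) -> None:
        if self.label not in CONDITION_LABELS:
            raise ValueError(f"unknown condition label {self.label!r}")
        for p in (self.induction_success_prob, *self.elimination_prob_d1_d7.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for m in (
            self.potency_scale_post,
            self.pca_scale_post,
            self.volume_scale_stim,
            self.volume_scale_nearest,
            self.volume_scale_distant,
        ):
            if m <= 0:
                raise ValueError("multipliers must be > 0")


# ---------------------------------------------------------------------------
# Default calibration.  All printed effect sizes used by the generator live
# here and only here.  Entries marked `placeholder: true` are quantities the
# source experiments did not report numerically; they are editable defaults,
# not measurements.
# ---------------------------------------------------------------------------

DEFAULT_CALIBRATION: dict = {
    "protocols": {
        # paired 2-ms test pulses, 40 ms apart, used to probe transmission
        "test": {"n_pulses": 2, "pulse_rate_hz": 25.0, "pulse_width_ms": 2.0,
                 "paired_pulse_interval_ms": 40.0},
        # theta-frequency LTP induction: 150 pulses at 5 Hz (30 s)
        "oTFS": {"n_pulses": 150, "pulse_rate_hz": 5.0, "pulse_width_ms": 2.0},
        # low-frequency LTD induction: 900 pulses at 1 Hz (900 s)
        "oLFS": {"n_pulses": 900, "pulse_rate_hz": 1.0, "pulse_width_ms": 2.0},
    },
    "synapse_model": {
        "p_release": 0.5,        # placeholder: per-pulse release probability
        "amplitude_mean": 1.0,   # placeholder: mean success ΔF/F_0
        "amplitude_cv": 0.3,     # placeholder: trial-to-trial amplitude CV
        "tau_rise_s": 0.05,      # GCaMP6s-like rise
        "tau_decay_s": 0.5,      # GCaMP6s-like decay
        "noise_sd": 0.1,
        "paired_pulse_ratio": 1.0,  # placeholder: short-term dynamics unreported
    },
    "acquisition": {
        "linescan_fs_hz": 500.0,
        "linescan_trials": 20,
        "linescan_duration_s": 3.0,
        "frame_scan": {"n_frames": 14, "frame_rate_hz": 7.8, "px": 64,
                       "field_um": 10.0},
        "min_frame_trials": 5,
    },
    "thresholds": {
        "responder_sd": 2.0,      # frame-scan responder criterion (×SD rest)
        "success_sigma": 2.0,     # per-trial success criterion (×σ baseline)
        "ltd_ratio": 0.90,        # post/pre < 0.90 after oLFS -> LTD success
        "ltp_ratio": 1.10,        # post/pre > 1.10 after oTFS -> LTP success
        "csb_sd": 5.0,            # dendritic-calcium CSB proxy (×SD baseline)
        "max_shift_um": 1.0,      # cross-session displacement exclusion
        "distant_cutoff_um": 5.0,  # nearest vs distant neighbor boundary
        "neighbor_horizon_um": 10.0,  # beyond this, spines are ignored
    },
    "optics": {
        "psf_fwhm_um": [0.4, 0.4, 1.6],
        "bead_diameter_um": 0.17,
        "attenuation_length_um": 50.0,  # placeholder: exponential depth model
        "voxel_um": [0.1, 0.1, 0.25],
    },
    # Condition table: induction success rates and day1->day7 elimination
    # probabilities per spine role; volume multipliers apply 30 min
    # post-induction and relax by day 1.
    "conditions": {
        "control": {
            "induction_success_prob": 1.0,
            "elimination_prob_d1_d7": {"stimulated": 0.27,
                                       "nearest_neighbor": 0.27,
                                       "distant": 0.27},
        },
        "responsive_only": {
            # test-pulse-only spines; elimination not reported numerically
            "induction_success_prob": 1.0,
            "elimination_prob_d1_d7": {"stimulated": 0.27,   # placeholder
                                       "nearest_neighbor": 0.27,
                                       "distant": 0.27},
        },
        "LTP_with_CSB": {
            "induction_success_prob": 0.72,   # 18/25 day-0 LTP
            "potency_scale_post": 1.5,
            "pca_scale_post": 1.0,
            "volume_scale_stim": 1.21,        # +21 % 30 min post
            "volume_scale_nearest": 1.15,     # +15 %
            "volume_scale_distant": 1.02,     # +2 %
            "elimination_prob_d1_d7": {"stimulated": 0.09,   # 1/11 spines
                                       "nearest_neighbor": 0.12,
                                       "distant": 0.35},
        },
        "oTFS_no_CSB": {
            "induction_success_prob": 0.0,
            "pca_scale_post": 0.7,            # presynaptic depression
            "elimination_prob_d1_d7": {"stimulated": 0.45,   # placeholder
                                       "nearest_neighbor": 0.45,
                                       "distant": 0.45},
        },
        "LTD": {
            "induction_success_prob": 0.70,   # 28/40 day-0 LTD
            "potency_scale_post": 0.8,
            "pca_scale_post": 0.5,
            "elimination_prob_d1_d7": {"stimulated": 0.45,
                                       "nearest_neighbor": 0.45,
                                       "distant": 0.45},
        },
        "LTD_then_LTP": {
            "induction_success_prob": 0.64,   # 18/28 day-1 LTP after LTD
            "potency_scale_post": 1.5,
            "volume_scale_stim": 1.21,
            "volume_scale_nearest": 1.15,
            "volume_scale_distant": 1.02,
            "elimination_prob_d1_d7": {"stimulated": 0.12,
                                       "nearest_neighbor": 0.12,
                                       "distant": 0.12},
        },
        "LTD_then_oTFS_fail": {
            "induction_success_prob": 0.0,
            "elimination_prob_d1_d7": {"stimulated": 0.43,
                                       "nearest_neighbor": 0.43,
                                       "distant": 0.43},
        },
        "LTP_then_LTD": {
            "induction_success_prob": 0.33,   # 6/18 day-1 LTD after LTP
            "potency_scale_post": 0.8,
            "pca_scale_post": 0.5,
            "elimination_prob_d1_d7": {"stimulated": 0.50,
                                       "nearest_neighbor": 0.50,
                                       "distant": 0.50},
        },
        "LTP_then_oLFS_fail": {
            "induction_success_prob": 0.0,
            "elimination_prob_d1_d7": {"stimulated": 0.08,
                                       "nearest_neighbor": 0.08,
                                       "distant": 0.08},
        },
    },
    "cohort": {
        "spines_per_dendrite": 6,
        "dendrite_length_um": 20.0,
        "baseline_volume_um3": {"mean": 0.15, "cv": 0.5},
    },
    "analysis": {
        "sigma_mode": "projection",       # or "raw"
        "amplitude_mode": "fitted",       # or "zeroed_failures"
        "neighbor_mode": "all_within_cutoff",  # or "single_closest"
    },
}


@dataclass
class RunConfig:
    """Complete, serialisable description of one pipeline run."""

    seed: int = 0
    calibration: dict = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_CALIBRATION)
    )

    # -- typed accessors -----------------------------------------------------

    def protocol(self, name: str) -> StimulusProtocol:
        try:
            spec = self.calibration["protocols"][name]
        except KeyError as exc:
            raise KeyError(f"unknown protocol {name!r}") from exc
        return StimulusProtocol(name=name, **{
            "n_pulses": spec["n_pulses"],
            "pulse_rate_hz": spec["pulse_rate_hz"],
            "pulse_width_ms": spec.get("pulse_width_ms", 2.0),
            "paired_pulse_interval_ms": spec.get("paired_pulse_interval_ms"),
        })

    def synapse_model(self, **overrides) -> SynapseModel:
        params = dict(self.calibration["synapse_model"])
        params.update(overrides)
        return SynapseModel(**params)

    def condition(self, label: str) -> PlasticityCondition:
        try:
            spec = self.calibration["conditions"][label]
        except KeyError as exc:
            raise ValueError(f"unknown condition label {label!r}") from exc
        return PlasticityCondition(label=label, **spec)

    @property
    def thresholds(self) -> dict:
        return self.calibration["thresholds"]

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        return {"seed": self.seed, "calibration": copy.deepcopy(self.calibration)}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls(seed=int(d.get("seed", 0)))
        overrides = d.get("calibration", {})
        _deep_update(cfg.calibration, overrides)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _deep_update(base: dict, overrides: dict) -> None:
    for key, val in overrides.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], val)
        else:
            base[key] = val


@dataclass(frozen=True)
class Finding:
    """A single config-validation finding."""

    level: str  # "error" or "warning"
    message: str


def validate_config(config: RunConfig) -> list[Finding]:
    """Check threshold ranges, probability bounds and protocol consistency.

    Returns findings rather than raising, so callers can distinguish hard
    errors from deviations-from-default worth a warning.
    """
    findings: list[Finding] = []
    thr = config.thresholds

    if not 0 < thr["ltd_ratio"] < 1:
        findings.append(Finding("error", "ltd_ratio must lie in (0, 1)"))
    if thr["ltp_ratio"] <= 1:
        findings.append(Finding("error", "ltp_ratio must be > 1"))
    for key in ("responder_sd", "success_sigma", "csb_sd", "max_shift_um",
                "distant_cutoff_um", "neighbor_horizon_um"):
        if thr[key] <= 0:
            findings.append(Finding("error", f"{key} must be positive"))
    if thr["distant_cutoff_um"] >= thr["neighbor_horizon_um"]:
        findings.append(Finding(
            "error", "distant_cutoff_um must be below neighbor_horizon_um"))

    for name, expected in (("oTFS", (150, 5.0)), ("oLFS", (900, 1.0))):
        try:
            proto = config.protocol(name)
        except (KeyError, ValueError) as exc:
            findings.append(Finding("error", f"protocol {name}: {exc}"))
            continue
        if (proto.n_pulses, proto.pulse_rate_hz) != expected:
            findings.append(Finding(
                "warning",
                f"protocol {name} redefined to {proto.n_pulses} pulses at "
                f"{proto.pulse_rate_hz} Hz (default {expected[0]} at "
                f"{expected[1]} Hz)"))
    try:
        test = config.protocol("test")
        if test.paired_pulse_interval_ms is None:
            findings.append(Finding(
                "warning", "test protocol has no paired-pulse interval"))
    except (KeyError, ValueError) as exc:
        findings.append(Finding("error", f"protocol test: {exc}"))

    for label in config.calibration["conditions"]:
        try:
            config.condition(label)
        except ValueError as exc:
            findings.append(Finding("error", f"condition {label}: {exc}"))
    try:
        config.synapse_model()
    except ValueError as exc:
        findings.append(Finding("error", f"synapse_model: {exc}"))

    if not isinstance(config.seed, int):
        findings.append(Finding("error", "seed must be an integer"))
    return findings
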