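"""End-to-end orchestration: simulate → analyze → classify → survive.

A run expands one global seed into independent per-stage substreams, executes
every stage on generated (or user-supplied) data, and emits a report whose
central piece is the condition × role survival matrix together with a
recovered-vs-configured comparison table.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import epscat, morphometry, plasticity, synthetic
from .config import RunConfig, validate_config


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the global seed."""
    ss = np.random.SeedSequence([seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunReport:
    """Outputs of one end-to-end run."""

    config: dict
    stages: dict = field(default_factory=dict)
    survival_matrix: Optional[pd.DataFrame] = None
    recovery: Optional[pd.DataFrame] = None
    log: list = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "config": self.config,
            "stages": self.stages,
            "survival_matrix": (self.survival_matrix.to_dict(orient="records")
                                if self.survival_matrix is not None else None),
            "recovery": (self.recovery.to_dict(orient="records")
                         if self.recovery is not None else None),
            "log": self.log,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)


def _log(report: RunReport, stage: str, t0: float, outcome: str) -> None:
    report.log.append({"stage": stage, "elapsed_s": round(time.time() - t0, 3),
                       "outcome": outcome})


def analyze_generated_trial_set(config: RunConfig, seed: int) -> dict:
    """Simulate one spine's line-scan session and analyze it end to end."""
    model = config.synapse_model()
    protocol = config.protocol("test")
    acq = config.calibration["acquisition"]
    traces, truth = synthetic.generate_trial_set(
        model, protocol, n_trials=acq["linescan_trials"],
        fs=acq["linescan_fs_hz"], duration_s=acq["linescan_duration_s"],
        seed=seed)
    template, fits, stats = epscat.analyze_trial_set(
        traces, sigma_mode=config.calibration["analysis"]["sigma_mode"],
        amplitude_mode=config.calibration["analysis"]["amplitude_mode"])
    released = np.asarray(truth.data["released"])
    out = {
        "true_p_release": model.p_release,
        "true_trial_release_fraction": float(released.any(axis=1).mean()),
    }
    if stats is not None:
        out.update({
            "p_ca": stats.p_ca, "potency": stats.potency,
            "mean_amplitude": stats.mean_amplitude,
            "sigma_baseline": stats.sigma_baseline,
            "tau_rise_s": template.tau_rise_s,
            "tau_decay_s": template.tau_decay_s,
        })
    return out


def classify_cohort(experiments: pd.DataFrame, config: RunConfig
                    ) -> pd.DataFrame:
    """Attach measured condition labels to a cohort's experiments table."""
    thr = config.thresholds
    labels = []
    for _, row in experiments.iterrows():
        day0 = day1 = None
        if row["protocol_d0"] is not None and pd.notna(row["ratio_d0"]):
            day0 = plasticity.classify_induction_ratio(
                row["ratio_d0"], row["protocol_d0"],
                ltd_ratio=thr["ltd_ratio"], ltp_ratio=thr["ltp_ratio"],
                csb_observed=(None if pd.isna(row["csb_d0"])
                              else bool(row["csb_d0"])))
        if row["protocol_d1"] is not None and pd.notna(row["ratio_d1"]):
            day1 = plasticity.classify_induction_ratio(
                row["ratio_d1"], row["protocol_d1"],
                ltd_ratio=thr["ltd_ratio"], ltp_ratio=thr["ltp_ratio"],
                csb_observed=(None if pd.isna(row["csb_d1"])
                              else bool(row["csb_d1"])))
        if day0 is None:
            # unstimulated conditions keep their generating label
            labels.append(row["condition"])
        else:
            labels.append(plasticity.label_experiment(day0, day1))
    out = experiments.copy()
    out["measured_condition"] = labels
    return out


def run_end_to_end(config: RunConfig,
                   conditions: Optional[Sequence[str]] = None,
                   n_experiments: int = 20,
                   exclude_max_shift: bool = True) -> RunReport:
    """Execute the full pipeline on generated data for each condition.

    Per condition: generate a longitudinal cohort, classify each
    experiment's induction outcome from its measured post/pre ratios, drop
    displacement-excluded spines and excluded experiments, and compute the
    d1→d7 survival matrix per measured condition × role.
    """
    findings = validate_config(config)
    errors = [f for f in findings if f.level == "error"]
    if errors:
        raise ValueError("invalid config: "
                         + "; ".join(f.message for f in errors))
    report = RunReport(config=config.to_dict())
    conditions = list(conditions
                      or config.calibration["conditions"].keys())

    t0 = time.time()
    trial_stats = analyze_generated_trial_set(
        config, stage_seed(config.seed, "traces"))
    report.stages["trace_analysis"] = trial_stats
    _log(report, "trace_analysis", t0, "ok")

    all_spines, recovery_rows = [], []
    t0 = time.time()
    max_shift = config.thresholds["max_shift_um"]
    for cond_label in conditions:
        cond = config.condition(cond_label)
        spines, experiments, truth = synthetic.generate_cohort(
            cond, n_experiments=n_experiments,
            spines_per_dendrite=config.calibration["cohort"]
            ["spines_per_dendrite"],
            seed=stage_seed(config.seed, f"cohort/{cond_label}"),
            config=config)
        experiments = classify_cohort(experiments, config)
        merged = spines.merge(
            experiments[["experiment_id", "measured_condition"]],
            on="experiment_id")
        merged = merged[merged["measured_condition"] != "excluded"]
        if exclude_max_shift:
            excl = (merged.groupby("spine_id")["displacement_um"]
                    .transform("max") > max_shift)
            merged = merged.assign(excluded=excl)
        else:
            merged = merged.assign(excluded=False)
        merged = merged.drop(columns=["condition"]).rename(
            columns={"measured_condition": "condition"})
        all_spines.append(merged)

        success = np.asarray(truth.data["induction_success_by_experiment"])
        # recovery is evaluated within this cohort only, on the experiments
        # whose measured label equals the generating condition
        own = merged[merged["condition"] == cond_label]
        surv_c = morphometry.survival_fractions(
            own, "d1", "d7", n_bootstrap=0,
            seed=stage_seed(config.seed, f"boot/{cond_label}"))
        for role in ("stimulated", "nearest_neighbor", "distant"):
            cfg_p = cond.elimination_prob_d1_d7.get(role)
            row = surv_c[(surv_c["condition"] == cond_label)
                         & (surv_c["role"] == role)]
            if cfg_p is None or row.empty:
                continue
            recovery_rows.append({
                "condition": cond_label, "role": role,
                "configured_success_prob": cond.induction_success_prob,
                "true_success_fraction": float(success.mean()),
                "classified_success_fraction": float(
                    (experiments["measured_condition"] == cond_label).mean()),
                "configured_elimination": cfg_p,
                "recovered_elimination": 1.0 - float(row["fraction"].iloc[0]),
                "n": int(row["n_from"].iloc[0]),
            })
    cohort = pd.concat(all_spines, ignore_index=True)
    _log(report, "cohort_generation", t0, "ok")

    t0 = time.time()
    report.survival_matrix = morphometry.survival_fractions(
        cohort, "d1", "d7", n_bootstrap=500,
        seed=stage_seed(config.seed, "bootstrap"))
    report.recovery = pd.DataFrame(recovery_rows)
    _log(report, "survival", t0, "ok")
    return report
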