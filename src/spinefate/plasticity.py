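"""Classification of plasticity-induction outcomes.

An induction experiment is judged by the ratio of the average spine Ca²⁺
response after the protocol to the (same-day) baseline before it: LTD after
low-frequency stimulation is successful when the ratio drops below 0.90,
LTP after theta-frequency stimulation when it rises above 1.10. Because LTP
induction in this preparation requires dendritic calcium spikes during
complex spike bursts (CSBs), a thresholded dendritic-calcium proxy flags
whether CSBs occurred. Outcome pairs across days map onto the condition
taxonomy used by the survival analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .epscat import TrialSetStats

PROTOCOL_OF_LABEL = {"oTFS": "LTP", "oLFS": "LTD"}


@dataclass(frozen=True)
class InductionOutcome:
    """Result of one induction attempt on one spine."""

    protocol: str  # "oTFS" or "oLFS"
    ratio_post_pre: float
    csb_observed: Optional[bool]  # None = not applicable / not recorded
    label: str  # "LTP_success" | "LTD_success" | "no_change"


@dataclass
class InductionRecording:
    """Frame-scan ΔF/F recorded during the induction protocol.

    ``dendrite_trace`` covers the induction period; ``baseline_sd`` is
    estimated from pre-induction frames. ``ap_counts`` are per-experiment
    postsynaptic action-potential totals when an electrophysiological
    reporter is available.
    """

    dendrite_trace: Optional[np.ndarray]
    baseline_sd: float
    spine_trace: Optional[np.ndarray] = None
    ap_counts: Optional[Sequence[float]] = None


def classify_induction(pre: TrialSetStats, post: TrialSetStats,
                       protocol: str, ltd_ratio: float = 0.90,
                       ltp_ratio: float = 1.10,
                       csb_observed: Optional[bool] = None,
                       use_potency: bool = False) -> InductionOutcome:
    """Label an induction attempt from pre/post trial-set statistics.

    The default response measure is ``mean_amplitude`` over all trials
    (failures included); ``use_potency`` switches to success-only potency
    for sensitivity analyses. Thresholds are strict: LTD requires
    ratio < ``ltd_ratio`` after oLFS, LTP requires ratio > ``ltp_ratio``
    after oTFS.
    """
    if protocol not in PROTOCOL_OF_LABEL:
        raise ValueError(f"unknown protocol {protocol!r}")
    if use_potency:
        if pre.potency is None or post.potency is None:
            raise ValueError("potency undefined for pre or post trial set")
        pre_val, post_val = pre.potency, post.potency
    else:
        pre_val, post_val = pre.mean_amplitude, post.mean_amplitude
    if pre_val <= 0:
        raise ValueError("pre response must be positive to form a ratio")
    ratio = post_val / pre_val
    return classify_induction_ratio(ratio, protocol, ltd_ratio, ltp_ratio,
                                    csb_observed)


def classify_induction_ratio(ratio: float, protocol: str,
                             ltd_ratio: float = 0.90,
                             ltp_ratio: float = 1.10,
                             csb_observed: Optional[bool] = None
                             ) -> InductionOutcome:
    """Ratio-level variant of :func:`classify_induction`."""
    if ratio <= 0:
        raise ValueError("ratio_post_pre must be positive")
    if protocol == "oLFS":
        label = "LTD_success" if ratio < ltd_ratio else "no_change"
    elif protocol == "oTFS":
        label = "LTP_success" if ratio > ltp_ratio else "no_change"
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    return InductionOutcome(protocol=protocol, ratio_post_pre=float(ratio),
                            csb_observed=csb_observed, label=label)


def detect_csb_proxy(rec: InductionRecording, threshold_sd: float = 5.0
                     ) -> tuple[Optional[bool], np.ndarray]:
    """Thresholded dendritic-calcium proxy for complex spike bursts.

    Returns ``(observed, event_indices)``. Large dendritic transients —
    samples exceeding ``threshold_sd`` × the pre-induction baseline SD —
    mark CSB-like events; contiguous supra-threshold runs count once.
    A missing dendrite trace yields ``(None, [])`` (not-applicable), never a
    silent ``False``.
    """
    if rec.dendrite_trace is None:
        return None, np.array([], dtype=int)
    if rec.baseline_sd <= 0:
        raise ValueError("baseline_sd must be positive")
    x = np.asarray(rec.dendrite_trace, dtype=float)
    above = x > threshold_sd * rec.baseline_sd
    # rising edges of supra-threshold runs = event onsets
    onsets = np.nonzero(above & ~np.r_[False, above[:-1]])[0]
    return bool(onsets.size > 0), onsets


def spike_probability(ap_counts: Sequence[float], n_pulses: int
                      ) -> tuple[float, np.ndarray]:
    """Postsynaptic spike probability during an induction train.

    Returns ``(median_total_ap_count / n_pulses, per-experiment
    probabilities)``; e.g. a median of 1.5 APs over the 900 pulses of the
    low-frequency protocol gives 0.00167.
    """
    counts = np.asarray(ap_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty ap_counts")
    if n_pulses <= 0:
        raise ValueError("n_pulses must be positive")
    if np.any(counts < 0):
        raise ValueError("ap counts must be nonnegative")
    return float(np.median(counts) / n_pulses), counts / n_pulses


def label_experiment(day0: InductionOutcome,
                     day1: Optional[InductionOutcome] = None) -> str:
    """Map a day-0 (and optional day-1) outcome pair to a condition label.

    Experiments failing the day-0 criterion are labelled ``excluded`` —
    they are not considered further in the survival analysis. Single-day
    experiments map to the one-protocol conditions; the oTFS conditions
    additionally split on whether CSBs were observed.
    """
    if day0 is None:
        raise ValueError("day0 outcome required")

    if day0.protocol == "oLFS":
        if day0.label != "LTD_success":
            return "excluded"
        if day1 is None:
            return "LTD"
        if day1.protocol != "oTFS":
            raise ValueError("day-1 protocol after LTD must be oTFS")
        return ("LTD_then_LTP" if day1.label == "LTP_success"
                else "LTD_then_oTFS_fail")

    if day0.protocol == "oTFS":
        if day0.label != "LTP_success":
            if day0.csb_observed is False:
                return "oTFS_no_CSB"
            return "excluded"
        if day1 is None:
            return "LTP_with_CSB"
        if day1.protocol != "oLFS":
            raise ValueError("day-1 protocol after LTP must be oLFS")
        return ("LTP_then_LTD" if day1.label == "LTD_success"
                else "LTP_then_oLFS_fail")

    raise ValueError(f"unknown day-0 protocol {day0.protocol!r}")
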