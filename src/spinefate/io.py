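"""Plain-text and TIFF I/O for traces, stacks and cohort tables.

Traces travel as long-format CSV (time_s, roi_id, dFF) with a JSON sidecar
for protocol metadata; movies and stacks as multi-page TIFF with a JSON
sidecar carrying voxel size and depth; cohorts as one-row-per-spine×session
CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .epscat import Trace


def save_traces(path, traces: Sequence[Trace]) -> None:
    """Write a trial set to CSV plus a JSON metadata sidecar."""
    path = Path(path)
    rows = []
    for i, tr in enumerate(traces):
        t = tr.time
        rows.append(pd.DataFrame({
            "trial": i, "time_s": t, "roi_id": tr.roi_id, "dFF": tr.samples}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    meta = {
        "fs_hz": traces[0].fs,
        "stimulus_times_s": list(traces[0].stimulus_times),
        "roi_kind": traces[0].roi_kind,
        "n_trials": len(traces),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_traces(path) -> list[Trace]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path)
    traces = []
    for (_, roi), grp in df.groupby(["trial", "roi_id"], sort=True):
        grp = grp.sort_values("time_s")
        traces.append(Trace(grp["dFF"].to_numpy(), meta["fs_hz"],
                            meta["stimulus_times_s"], roi_id=str(roi),
                            roi_kind=meta.get("roi_kind", "spine")))
    return traces


def save_stack(path, stack: np.ndarray, meta: dict) -> None:
    """Multi-page TIFF + JSON sidecar (voxel size, depth, optics)."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_stack(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    stack = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return np.asarray(stack, dtype=float), meta


def save_cohort(path, spines: pd.DataFrame) -> None:
    spines.to_csv(path, index=False)


def load_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("present", "excluded"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df
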