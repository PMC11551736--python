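"""Plain-text I/O for traces, manifests, and result tables.

Trace tables are tab-separated, one file per condition, with columns
``trace_id, time_s, intensity`` (NISP) or ``trace_id, time_s, donor,
acceptor`` (FRET); the sidecar manifest records per-condition metadata.
Image stacks are multi-frame 16-bit grayscale TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import tifffile

from .models import FretTrace, Trace

PathLike = Union[str, Path]


def write_trace_table(path: PathLike, traces: Sequence[Union[Trace, FretTrace]]) -> None:
    """Write one condition's traces as a tidy TSV."""
    frames = []
    for i, tr in enumerate(traces):
        tid = tr.meta.get("trace_id", i)
        if isinstance(tr, FretTrace):
            frames.append(
                pd.DataFrame(
                    {"trace_id": tid, "time_s": tr.times, "donor": tr.donor, "acceptor": tr.acceptor}
                )
            )
        else:
            frames.append(
                pd.DataFrame({"trace_id": tid, "time_s": tr.times, "intensity": tr.intensities})
            )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["trace_id", "time_s", "intensity"])
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_trace_table(path: PathLike) -> list[Union[Trace, FretTrace]]:
    """Read a trace table written by :func:`write_trace_table`."""
    df = pd.read_csv(path, sep="\t")
    is_fret = "donor" in df.columns
    out: list[Union[Trace, FretTrace]] = []
    for tid, grp in df.groupby("trace_id", sort=True):
        times = grp["time_s"].to_numpy()
        if is_fret:
            out.append(
                FretTrace(
                    times=times,
                    donor=grp["donor"].to_numpy(),
                    acceptor=grp["acceptor"].to_numpy(),
                    meta={"trace_id": int(tid)},
                )
            )
        else:
            out.append(
                Trace(times=times, intensities=grp["intensity"].to_numpy(), meta={"trace_id": int(tid)})
            )
    return out


def write_manifest(path: PathLike, manifest: pd.DataFrame) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_manifest(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_movie(path: PathLike, stack: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint16))


def read_movie(path: PathLike) -> np.ndarray:
    return tifffile.imread(path)


def format_occurrence_table(table: pd.DataFrame) -> pd.DataFrame:
    """Human-readable occurrence table with "p% (count/total)" cells."""
    rows = []
    for _, r in table.iterrows():
        row = {"condition": r["condition"]}
        for sc, label in (
            ("no_drop", "no_photodropping"),
            ("one_step", "one_step"),
            ("two_step", "two_step"),
        ):
            row[label] = f"{r[f'p_{sc}']:.1f} ({int(r[f'n_{sc}'])}/{int(r['n_total'])})"
        for sc in ("no_drop", "one_step", "two_step"):
            row[f"delta_{sc}"] = f"{r[f'delta_{sc}']:+.1f}"
        rows.append(row)
    return pd.DataFrame(rows)


def write_json(path: PathLike, payload: dict) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=default) + "\n")
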