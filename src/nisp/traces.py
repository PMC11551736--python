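"""Trace processing: spot extraction, trace selection, and step detection.

Turns raw image stacks or intensity traces into classified photodropping
events.  The step finder fits a piecewise-constant signal by binary
segmentation with a BIC-style penalty per change point; accepted steps are
downward with magnitude near one fluorophore unit, and each trace is
classified into the no-drop / one-step / two-step scenarios whose dwell
times (T1, T2) feed the kinetic analysis.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage.feature import peak_local_max

from .models import Scenario, SnrStats, StepCall, Trace


# ---------------------------------------------------------------------------
# SNR and selection
# ---------------------------------------------------------------------------

def compute_snr(
    signal_mean: float, background_mean: float, background_sd: float
) -> SnrStats:
    """Signal-to-noise ratio (signal - background) / background sd."""
    if background_sd <= 0:
        raise ValueError("background_sd must be > 0 for a defined SNR")
    snr = (signal_mean - background_mean) / background_sd
    return SnrStats(
        signal_mean=float(signal_mean),
        background_mean=float(background_mean),
        background_sd=float(background_sd),
        snr=float(snr),
    )


def initial_intensity(trace: Trace, n_frames: int = 5) -> float:
    """Mean of the first frames, used as the molecule's starting intensity."""
    return float(np.mean(trace.intensities[:n_frames]))


def select_traces(
    traces: Sequence[Trace], unit: float, rel_tol: float = 0.25
) -> list[Trace]:
    """Keep molecules whose initial intensity matches two fluorophore units.

    The two-unit criterion rejects molecules with a single active
    fluorophore (mislabeled or pre-bleached), which would otherwise produce
    spurious one-step events.
    """
    if unit <= 0:
        raise ValueError("unit must be > 0")
    lo, hi = 2.0 * (1.0 - rel_tol) * unit, 2.0 * (1.0 + rel_tol) * unit
    return [t for t in traces if lo <= initial_intensity(t) <= hi]


# ---------------------------------------------------------------------------
# Binary-segmentation step finder
# ---------------------------------------------------------------------------

def _noise_sigma(y: np.ndarray) -> float:
    """Robust per-frame noise sd from the MAD of first differences."""
    d = np.diff(y)
    mad = np.median(np.abs(d - np.median(d)))
    return float(mad / 0.6744897501960817 / np.sqrt(2.0))


def _binary_segmentation(y: np.ndarray, penalty: float, min_size: int) -> list[int]:
    """Change points of a piecewise-constant least-squares fit.

    Recursively splits segments at the point of maximal residual-sum-of-
    squares reduction; a split is kept only when the reduction exceeds
    ``penalty``.  Segments shorter than ``min_size`` are never created, so
    consecutive change points are at least ``min_size`` frames apart.
    """
    n = len(y)
    cs = np.concatenate(([0.0], np.cumsum(y)))
    cs2 = np.concatenate(([0.0], np.cumsum(y * y)))

    def seg_cost(a: int, b: int) -> float:
        s = cs[b] - cs[a]
        return float(cs2[b] - cs2[a] - s * s / (b - a))

    changepoints: list[int] = []
    stack = [(0, n)]
    while stack:
        a, b = stack.pop()
        if b - a < 2 * min_size:
            continue
        t = np.arange(a + min_size, b - min_size + 1)
        nl = t - a
        nr = b - t
        sl = cs[t] - cs[a]
        sr = cs[b] - cs[t]
        cost_split = (cs2[t] - cs2[a] - sl * sl / nl) + (cs2[b] - cs2[t] - sr * sr / nr)
        i = int(np.argmin(cost_split))
        gain = seg_cost(a, b) - cost_split[i]
        if gain > penalty:
            cp = int(t[i])
            changepoints.append(cp)
            stack.append((a, cp))
            stack.append((cp, b))
    changepoints.sort()
    return changepoints


def _merge_close(
    cps: list[int], mags: np.ndarray, min_dwell: int
) -> tuple[list[int], list[float]]:
    """When two change points fall within min_dwell, keep the larger-magnitude one."""
    keep_cps: list[int] = []
    keep_mags: list[float] = []
    for cp, m in zip(cps, mags):
        if keep_cps and cp - keep_cps[-1] < min_dwell:
            if abs(m) > abs(keep_mags[-1]):
                keep_cps[-1], keep_mags[-1] = cp, m
        else:
            keep_cps.append(cp)
            keep_mags.append(m)
    return keep_cps, keep_mags


def detect_steps(
    trace: Trace,
    unit: float,
    penalty: Optional[float] = None,
    min_dwell: int = 3,
    mag_window: tuple[float, float] = (0.5, 1.5),
) -> StepCall:
    """Detect photodropping steps in one trace and classify its scenario.

    Accepted steps are downward with magnitude in ``mag_window * unit``;
    a downward step larger than the window (e.g. both fluorophores lost in
    one frame) or more than two accepted steps mark the trace rejected.
    Times are reported as ``frame_index * frame_interval`` where the index
    is the first frame at the new level.
    """
    y = np.asarray(trace.intensities, dtype=float)
    n = len(y)
    if n < 2 * min_dwell:
        raise ValueError(f"trace too short ({n} frames) for min_dwell={min_dwell}")
    dt = trace.frame_interval or 1.0
    if penalty is None:
        sigma = _noise_sigma(y)
        scale = max(np.ptp(y), abs(np.max(y)), 1.0)
        sigma = max(sigma, 1e-6 * scale)  # floor for noiseless input
        penalty = 10.0 * np.log(n) * sigma**2
    cps = _binary_segmentation(y, penalty, min_dwell)
    edges = [0] + cps + [n]
    means = [float(np.mean(y[a:b])) for a, b in zip(edges[:-1], edges[1:])]
    mags = np.diff(means)
    cps, mag_list = _merge_close(cps, mags, min_dwell)

    lo, hi = mag_window[0] * unit, mag_window[1] * unit
    accepted_t: list[float] = []
    accepted_m: list[float] = []
    oversized = False
    for cp, m in zip(cps, mag_list):
        if m < 0 and lo <= -m <= hi:
            accepted_t.append(cp * dt)
            accepted_m.append(m)
        elif m < 0 and -m > hi:
            oversized = True

    k = len(accepted_t)
    if oversized or k > 2:
        scenario, T1, T2 = Scenario.REJECTED, None, None
    elif k == 0:
        scenario, T1, T2 = Scenario.NO_DROP, None, None
    elif k == 1:
        scenario, T1, T2 = Scenario.ONE_STEP, accepted_t[0], None
    else:
        scenario = Scenario.TWO_STEP
        T1 = None
        T2 = accepted_t[1] - accepted_t[0]
    return StepCall(
        step_times=np.asarray(accepted_t),
        step_magnitudes=np.asarray(accepted_m),
        scenario=scenario,
        T1=T1,
        T2=T2,
        meta=dict(trace.meta),
    )


def estimate_unit_intensity(
    traces: Sequence[Trace],
    config_unit: Optional[float] = None,
    min_traces: int = 20,
    min_dwell: int = 3,
) -> float:
    """Robust single-fluorophore intensity from candidate downward steps.

    Median of all downward step magnitudes found by unconstrained
    segmentation; falls back to ``config_unit`` when fewer than
    ``min_traces`` traces contain a candidate.
    """
    mags: list[float] = []
    n_with = 0
    for trace in traces:
        y = np.asarray(trace.intensities, dtype=float)
        if len(y) < 2 * min_dwell:
            continue
        sigma = max(_noise_sigma(y), 1e-6 * max(np.ptp(y), abs(np.max(y)), 1.0))
        cps = _binary_segmentation(y, 10.0 * np.log(len(y)) * sigma**2, min_dwell)
        edges = [0] + cps + [len(y)]
        means = [float(np.mean(y[a:b])) for a, b in zip(edges[:-1], edges[1:])]
        down = [-d for d in np.diff(means) if d < 0]
        if down:
            n_with += 1
            mags.extend(down)
    if n_with >= min_traces:
        return float(np.median(mags))
    if config_unit is not None:
        return float(config_unit)
    raise ValueError(
        f"only {n_with} traces with step candidates (< {min_traces}) and no config unit"
    )


# ---------------------------------------------------------------------------
# Movie extraction
# ---------------------------------------------------------------------------

def extract_traces_from_movie(
    stack: np.ndarray,
    detect_threshold: float = 5.0,
    window_radius: int = 3,
    frame_interval: float = 0.1,
) -> list[Trace]:
    """Extract per-spot intensity traces from a grayscale image stack.

    Spots are local maxima of the mean of the first 10 (non-saturated)
    frames above ``background + detect_threshold * background_sd``, with
    non-maximum suppression within ``2 * window_radius``.  The per-frame
    trace value is the sum over the ``(2r+1)^2`` window minus the local
    median background times the window area.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 10:
        raise ValueError("stack must be 3-D with >= 10 frames")
    sat = (
        np.max(stack.reshape(stack.shape[0], -1), axis=1) >= np.iinfo(stack.dtype).max
        if np.issubdtype(stack.dtype, np.integer)
        else np.zeros(stack.shape[0], dtype=bool)
    )
    good = np.nonzero(~sat)[0]
    if len(good) < 10:
        raise ValueError("fewer than 10 unsaturated frames for the detection average")
    mean_img = stack[good[:10]].astype(float).mean(axis=0)
    bg_mean = float(np.median(mean_img))
    bg_sd = float(np.median(np.abs(mean_img - bg_mean)) * 1.4826)
    if bg_sd == 0:
        # MAD degenerate (e.g. noiseless synthetic background): use the sd of
        # the non-spot pixels, with a tiny floor so the threshold stays finite
        below = mean_img[mean_img <= np.percentile(mean_img, 90)]
        bg_sd = max(float(below.std()), 1e-6)
    peaks = peak_local_max(
        mean_img,
        min_distance=2 * window_radius,
        threshold_abs=bg_mean + detect_threshold * bg_sd,
        exclude_border=window_radius,
    )
    n_frames = stack.shape[0]
    times = (np.arange(n_frames) + 0.5) * frame_interval
    area = (2 * window_radius + 1) ** 2
    traces: list[Trace] = []
    fstack = stack.astype(float)
    for r, c in peaks:
        win = fstack[:, r - window_radius : r + window_radius + 1,
                     c - window_radius : c + window_radius + 1]
        # local background: median of a surrounding box with the window cut out
        rad = 3 * window_radius + 2
        r0, r1 = max(0, r - rad), min(stack.shape[1], r + rad + 1)
        c0, c1 = max(0, c - rad), min(stack.shape[2], c + rad + 1)
        box = fstack[:, r0:r1, c0:c1].copy()
        box[:, (r - window_radius) - r0 : (r + window_radius + 1) - r0,
            (c - window_radius) - c0 : (c + window_radius + 1) - c0] = np.nan
        local_bg = np.nanmedian(box.reshape(n_frames, -1), axis=1)
        values = win.reshape(n_frames, -1).sum(axis=1) - local_bg * area
        traces.append(
            Trace(
                times=times,
                intensities=values,
                meta={
                    "position": (int(r), int(c)),
                    "saturated_frames": np.nonzero(sat)[0].tolist(),
                },
            )
        )
    return traces


# ---------------------------------------------------------------------------
# Scenario tabulation
# ---------------------------------------------------------------------------

def classify_and_extract(
    calls: Sequence[StepCall], window: float = 100.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate scenario counts per condition and pool the dwell samples.

    Returns ``(counts, dwells)``: counts has one row per condition
    (n_total excludes rejected traces); dwells has one row per extracted
    T1 or T2 value.
    """
    rows = []
    dwell_rows = []
    for i, call in enumerate(calls):
        cond = call.meta.get("condition", "all")
        rows.append({"condition": cond, "scenario": call.scenario.value})
        tid = call.meta.get("trace_id", i)
        if call.scenario is Scenario.ONE_STEP and call.T1 is not None:
            dwell_rows.append(
                {"condition": cond, "trace_id": tid, "dwell_type": "T1", "dwell_s": call.T1}
            )
        elif call.scenario is Scenario.TWO_STEP and call.T2 is not None:
            if not 0.0 < call.T2 <= window:
                raise ValueError(f"T2={call.T2} outside (0, window={window}]")
            dwell_rows.append(
                {"condition": cond, "trace_id": tid, "dwell_type": "T2", "dwell_s": call.T2}
            )
    df = pd.DataFrame(rows)
    counts = []
    for cond, grp in df.groupby("condition", sort=False):
        c = grp["scenario"].value_counts()
        n_rej = int(c.get(Scenario.REJECTED.value, 0))
        counts.append(
            {
                "condition": cond,
                "n_total": int(len(grp) - n_rej),
                "n_no_drop": int(c.get(Scenario.NO_DROP.value, 0)),
                "n_one_step": int(c.get(Scenario.ONE_STEP.value, 0)),
                "n_two_step": int(c.get(Scenario.TWO_STEP.value, 0)),
                "n_rejected": n_rej,
            }
        )
    dwells = pd.DataFrame(dwell_rows, columns=["condition", "trace_id", "dwell_type", "dwell_s"])
    return pd.DataFrame(counts), dwells
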