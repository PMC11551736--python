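"""End-to-end pipelines: simulate -> detect -> fit -> decompose.

These functions chain the generator, the step finder, the background-
subtracted dwell fits, and the kinetic decomposition under the study
conditions (100 ms frames, 100 s window, unit intensity 1000 a.u., noise
sd 50 a.u., control photobleaching scenario mix 78.4/15.8/5.8%).  They are
the library surface behind both the command-line interface and the
reproduction scripts.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .benchmark import BenchmarkConfig, Condition, generate_benchmark_set
from .fret import compute_efficiency, detect_unwinding, fit_efficiency_histogram, unwinding_rate
from .kinetics import (
    BackgroundFit,
    GaussPolyFit,
    KineticDecomposition,
    decompose_linear,
    fit_background,
    fit_gaussian_plus_background,
    make_histogram,
    select_bin_width,
)
from .models import (
    EnzymeKineticsModel,
    EnzymeMode,
    LabelType,
    OverhangEnd,
    PhotophysicsModel,
    SubstrateSpec,
    Trace,
)
from .traces import classify_and_extract, detect_steps, estimate_unit_intensity, select_traces

#: Non-enzymatic scenario probabilities of the enzyme-free control
#: (no-drop, one-drop, two-drop), used as the photobleaching contamination
#: model in every realistic simulation.
CONTROL_MIX = (0.784, 0.158, 0.058)

#: Default camera/photophysics for realistic runs: SNR ~ 20, control-level
#: spontaneous bleaching drawn from the scenario mixture above.
DEFAULT_PHOTO = PhotophysicsModel(bleach_mixture=CONTROL_MIX)


def run_step_detection(
    traces: Sequence[Trace],
    config_unit: Optional[float] = 1000.0,
    rel_tol: float = 0.25,
    min_dwell: int = 3,
) -> list:
    """Unit estimation, two-unit selection, and step detection for a batch."""
    unit = estimate_unit_intensity(traces, config_unit=config_unit)
    selected = select_traces(traces, unit, rel_tol=rel_tol)
    return [detect_steps(t, unit, min_dwell=min_dwell) for t in selected]


def analyze_conditions(
    traces_by_condition: dict[str, Sequence[Trace]],
    window: float = 100.0,
    config_unit: Optional[float] = 1000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detect and classify steps for every condition; returns (counts, dwells)."""
    calls = []
    for cond, traces in traces_by_condition.items():
        for i, call_trace in enumerate(traces):
            call_trace.meta.setdefault("condition", cond)
            call_trace.meta.setdefault("trace_id", i)
        calls.extend(run_step_detection(traces, config_unit=config_unit))
    return classify_and_extract(calls, window=window)


def fit_condition_t2(
    t2_samples: Sequence[float],
    control_t2_samples: Sequence[float],
    stability_tol: float = 0.3,
    mode: str = "joint",
) -> GaussPolyFit:
    """Bin-width selection, control quartic fit, and Gaussian+background fit.

    The control (enzyme-free) T2 samples are histogrammed at the same bin
    width as the enzyme condition and fitted with a quartic polynomial that
    initializes the spontaneous-photobleaching background of the
    Gaussian-plus-quartic fit.
    """
    bw = select_bin_width(t2_samples, stability_tol=stability_tol)
    hist = make_histogram(t2_samples, bw)
    background: Optional[BackgroundFit] = None
    ctrl = np.asarray(control_t2_samples, dtype=float)
    if len(ctrl) > 0:
        ctrl_hist = make_histogram(ctrl, bw)
        if np.count_nonzero(ctrl_hist.counts) >= 6:
            background = fit_background(ctrl_hist)
    return fit_gaussian_plus_background(hist, background, mode=mode)


def _nisp_grid(
    spacings: Sequence[int],
    tau_bond: float,
    tau_label: float,
    label_type: LabelType,
    overhang_end: OverhangEnd,
    concentration: float,
    n_traces: int,
    n_control: int,
    photo: PhotophysicsModel,
) -> BenchmarkConfig:
    conditions = [
        Condition(
            name=f"S{S}",
            kind="processive",
            n_traces=n_traces,
            substrate=SubstrateSpec(
                spacing=S,
                label_type=label_type,
                overhang_end=overhang_end,
                overhang_length=max(40, S + 10),
            ),
            enzyme=EnzymeKineticsModel(
                mode=EnzymeMode.PROCESSIVE,
                tau_bond=tau_bond,
                tau_label=tau_label,
                concentration=concentration,
            ),
            photo=photo,
        )
        for S in spacings
    ]
    conditions.append(
        Condition(name="control", kind="bleach_only", n_traces=n_control, photo=photo)
    )
    return BenchmarkConfig(conditions=tuple(conditions))


def recover_degradation_rate(
    spacings: Sequence[int],
    tau_bond: float,
    tau_label: float,
    seed: int,
    label_type: LabelType = LabelType.ICY3,
    overhang_end: OverhangEnd = OverhangEnd.FIVE_PRIME,
    concentration: float = 10.0,
    n_traces: int = 260,
    n_control: int = 1200,
    photo: PhotophysicsModel = DEFAULT_PHOTO,
) -> tuple[KineticDecomposition, dict[str, GaussPolyFit]]:
    """Full pipeline: simulate a spacing grid, recover 1/slope (nt/s).

    Simulates processive-exonuclease traces for each inter-fluorophore
    spacing plus an enzyme-free control, detects steps, fits each T2
    histogram with the Gaussian-plus-quartic model, and regresses the
    fitted means on spacing.
    """
    config = _nisp_grid(
        spacings, tau_bond, tau_label, label_type, overhang_end,
        concentration, n_traces, n_control, photo,
    )
    traces, _ = generate_benchmark_set(config, seed)
    counts, dwells = analyze_conditions(traces)
    ctrl_t2 = dwells.query("condition == 'control' and dwell_type == 'T2'")["dwell_s"].to_numpy()
    fits: dict[str, GaussPolyFit] = {}
    points = []
    for S in spacings:
        t2 = dwells.query(f"condition == 'S{S}' and dwell_type == 'T2'")["dwell_s"].to_numpy()
        fit = fit_condition_t2(t2, ctrl_t2)
        fits[f"S{S}"] = fit
        points.append((S, fit.mu, fit.sigma / max(np.sqrt(len(t2)), 1.0)))
    return decompose_linear(points), fits


def recover_t2_at_spacing(
    spacing: int,
    tau_bond: float,
    tau_label: float,
    concentrations: Sequence[float],
    seed: int,
    n_traces: int = 260,
    n_control: int = 1200,
    photo: PhotophysicsModel = DEFAULT_PHOTO,
) -> dict[float, GaussPolyFit]:
    """Background-subtracted T2_av at one spacing across enzyme concentrations.

    For a processive enzyme the fitted means must not trend with
    concentration (single-turnover traversal).
    """
    conditions = [
        Condition(
            name=f"c{c}",
            kind="processive",
            n_traces=n_traces,
            substrate=SubstrateSpec(spacing=spacing),
            enzyme=EnzymeKineticsModel(
                mode=EnzymeMode.PROCESSIVE,
                tau_bond=tau_bond,
                tau_label=tau_label,
                concentration=c,
            ),
            photo=photo,
        )
        for c in concentrations
    ]
    conditions.append(
        Condition(name="control", kind="bleach_only", n_traces=n_control, photo=photo)
    )
    traces, _ = generate_benchmark_set(BenchmarkConfig(tuple(conditions)), seed)
    counts, dwells = analyze_conditions(traces)
    ctrl_t2 = dwells.query("condition == 'control' and dwell_type == 'T2'")["dwell_s"].to_numpy()
    out: dict[float, GaussPolyFit] = {}
    for c in concentrations:
        t2 = dwells.query(f"condition == 'c{c}' and dwell_type == 'T2'")["dwell_s"].to_numpy()
        out[c] = fit_condition_t2(t2, ctrl_t2)
    return out


def recover_unwinding_rate(
    seed: int,
    n_traces: int = 500,
    t_unwind_mean: float = 1.4,
    low: float = 0.15,
    high: float = 0.77,
    bp_unwound: float = 19.0,
    photo: Optional[PhotophysicsModel] = None,
) -> dict:
    """Simulate FRET unwinding traces and recover bp / Gaussian-mean dwell."""
    photo = photo or PhotophysicsModel()
    cond = Condition(
        name="unwinding",
        kind="fret_unwinding",
        n_traces=n_traces,
        photo=photo,
        fret={"low": low, "high": high, "t_unwind_mean": t_unwind_mean},
    )
    traces, _ = generate_benchmark_set(BenchmarkConfig((cond,)), seed)
    calls = []
    for tr in traces["unwinding"]:
        series = compute_efficiency(tr, floor=0.2 * photo.unit_intensity)
        call = detect_unwinding(series, low, high, bp_unwound=bp_unwound)
        if call is not None:
            calls.append(call)
    return unwinding_rate(calls, bp_unwound)


def recover_fret_efficiency(
    seed: int,
    n_traces: int = 200,
    level: float = 0.85,
    photo: Optional[PhotophysicsModel] = None,
    bin_width: float = 0.01,
) -> dict:
    """Simulate static FRET traces, pool frames, fit one Gaussian to the
    proximity-ratio histogram, and report its mean."""
    photo = photo or PhotophysicsModel()
    cond = Condition(
        name="static",
        kind="fret_static",
        n_traces=n_traces,
        photo=photo,
        fret={"level": level},
    )
    traces, _ = generate_benchmark_set(BenchmarkConfig((cond,)), seed)
    pool = [compute_efficiency(tr, floor=0.2 * photo.unit_intensity) for tr in traces["static"]]
    comps = fit_efficiency_histogram(pool, bin_width=bin_width)
    main = max(comps, key=lambda g: g.weight)
    return {"mean": main.mean, "sd": main.sd, "n_components": len(comps), "n_frames": sum(len(p.efficiency) for p in pool)}
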