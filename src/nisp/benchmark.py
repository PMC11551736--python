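"""Batch simulation over a grid of experimental conditions.

``generate_benchmark_set`` reproduces a whole assay's condition grid
(enzyme, concentrations, substrates with different inter-fluorophore
spacings, matched enzyme-free controls) in one deterministic call, and
returns the traces together with a ground-truth manifest.  Per-trace
random streams are derived from the master seed by a counter-based scheme
``default_rng([master_seed, condition_index, trace_index])`` recorded in
each trace's metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import pandas as pd

from .models import (
    EnzymeKineticsModel,
    EnzymeMode,
    PhotophysicsModel,
    SubstrateSpec,
)
from .simulate import (
    simulate_bleach_only_trace,
    simulate_distributive_trace,
    simulate_fret_trace,
    simulate_processive_trace,
)

_KINDS = {"processive", "distributive", "inactive", "bleach_only", "fret_static", "fret_unwinding"}


@dataclass(frozen=True)
class Condition:
    """One cell of the benchmark grid."""

    name: str
    kind: str
    n_traces: int
    substrate: Optional[SubstrateSpec] = None
    enzyme: Optional[EnzymeKineticsModel] = None
    photo: PhotophysicsModel = field(default_factory=PhotophysicsModel)
    fret: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown condition kind {self.kind!r}; known: {sorted(_KINDS)}")
        if self.n_traces < 0:
            raise ValueError("n_traces must be >= 0")
        if self.kind in ("processive", "distributive") and (
            self.substrate is None or self.enzyme is None
        ):
            raise ValueError(f"kind {self.kind!r} requires substrate and enzyme")


@dataclass(frozen=True)
class BenchmarkConfig:
    conditions: tuple[Condition, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            raise ValueError("condition names must be unique")


def _simulate_one(cond: Condition, rng_seed: list[int], render: bool):
    if cond.kind == "processive":
        return simulate_processive_trace(cond.substrate, cond.enzyme, cond.photo, rng_seed, render)
    if cond.kind == "distributive":
        return simulate_distributive_trace(cond.substrate, cond.enzyme, cond.photo, rng_seed, render)
    if cond.kind == "inactive":
        enzyme = cond.enzyme or EnzymeKineticsModel(mode=EnzymeMode.INACTIVE)
        substrate = cond.substrate or SubstrateSpec(spacing=18)
        return simulate_processive_trace(substrate, enzyme, cond.photo, rng_seed, render)
    if cond.kind == "bleach_only":
        return simulate_bleach_only_trace(cond.photo, rng_seed, render)
    if cond.kind == "fret_static":
        return simulate_fret_trace("static", cond.photo, rng_seed, **cond.fret)
    if cond.kind == "fret_unwinding":
        return simulate_fret_trace("unwinding", cond.photo, rng_seed, **cond.fret)
    raise AssertionError(cond.kind)


def generate_benchmark_set(
    config: BenchmarkConfig,
    seed: int,
    render: bool = True,
) -> tuple[dict[str, list], pd.DataFrame]:
    """Simulate every condition in the grid; deterministic given ``seed``.

    Returns ``(traces_by_condition, manifest)`` where the manifest is one
    row per condition carrying its ground-truth parameters.
    """
    traces: dict[str, list] = {}
    rows = []
    for ci, cond in enumerate(config.conditions):
        cond_traces = []
        for ti in range(cond.n_traces):
            tr = _simulate_one(cond, [int(seed), ci, ti], render)
            tr.meta.update(condition=cond.name, seed=(int(seed), ci, ti), trace_id=ti)
            cond_traces.append(tr)
        traces[cond.name] = cond_traces
        enz = cond.enzyme
        sub = cond.substrate
        rows.append(
            {
                "condition": cond.name,
                "kind": cond.kind,
                "n_traces": cond.n_traces,
                "spacing_nt": sub.spacing if sub else None,
                "label_type": sub.label_type.value if sub else None,
                "overhang_end": sub.overhang_end.value if sub else None,
                "enzyme_mode": enz.mode.value if enz else None,
                "concentration_nM": enz.concentration if enz else None,
                "tau_bond_s": enz.tau_bond if enz else None,
                "tau_label_s": enz.tau_label if enz else None,
                "k_site_per_s": enz.site_rate() if enz and enz.mode is EnzymeMode.DISTRIBUTIVE else None,
                "k_bleach_per_s": cond.photo.k_bleach,
                "frame_interval_s": cond.photo.frame_interval,
                "window_s": cond.photo.window,
                "master_seed": int(seed),
                "condition_index": ci,
                **{f"fret_{k}": v for k, v in cond.fret.items()},
            }
        )
    columns = [
        "condition", "kind", "n_traces", "spacing_nt", "label_type", "overhang_end",
        "enzyme_mode", "concentration_nM", "tau_bond_s", "tau_label_s", "k_site_per_s",
        "k_bleach_per_s", "frame_interval_s", "window_s", "master_seed", "condition_index",
    ]
    manifest = pd.DataFrame(rows) if rows else pd.DataFrame(columns=columns)
    return traces, manifest
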