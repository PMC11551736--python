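"""Monte-Carlo generator of NISP intensity traces and FRET trace pairs.

The generator emulates the experimental conditions of a two-fluorophore
photodropping assay: a surface-immobilized DNA overhang carries two Cy3
labels, a nuclease removes them (processively or distributively), every
fluorophore may instead photobleach spontaneously, and the camera records
the summed intensity at a fixed frame interval over a fixed acquisition
window.  All events after the window are censored: they appear in the
ground-truth log flagged ``censored`` but are not rendered.

Per-bond cleavage times are independent exponentials, so traversal of the
``spacing`` native bonds between the fluorophores is Gamma-distributed and
the expected inter-drop dwell is ``spacing * tau_bond + tau_label`` -- the
linear model the downstream kinetic decomposition inverts.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence, Union

import numpy as np

from .models import (
    EnzymeKineticsModel,
    EnzymeMode,
    FretTrace,
    OverhangEnd,
    PhotophysicsModel,
    SubstrateSpec,
    Trace,
    TruthEvent,
)

SeedLike = Union[int, Sequence[int], np.random.Generator]


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _exp(rng: np.random.Generator, mean: float) -> float:
    """Exponential draw with the given mean; mean 0 -> 0, mean inf -> inf."""
    if mean == 0.0:
        return 0.0
    if not math.isfinite(mean):
        return math.inf
    return float(rng.exponential(mean))


def _truncated_exp(rng: np.random.Generator, rate: float, upper: float) -> float:
    """Exponential(rate) conditioned on being < upper (inverse-CDF)."""
    if rate <= 0:
        # degenerate conditional: fall back to uniform inside the window
        return float(rng.uniform(0.0, upper))
    u = rng.uniform()
    return float(-math.log1p(-u * (1.0 - math.exp(-rate * upper))) / rate)


def _sample_bleach_times(
    photo: PhotophysicsModel, rng: np.random.Generator
) -> tuple[float, float]:
    """Spontaneous bleach times for the two fluorophores (may be inf).

    Independent exponentials at ``k_bleach`` by default; with
    ``photo.bleach_mixture`` set, the non-enzymatic scenario is drawn
    directly from the supplied 3-vector and times are sampled conditionally
    inside the acquisition window.
    """
    if photo.bleach_mixture is not None:
        k = int(rng.choice(3, p=np.asarray(photo.bleach_mixture, dtype=float)))
        times = [math.inf, math.inf]
        which = rng.permutation(2)
        for i in range(k):
            times[which[i]] = _truncated_exp(rng, photo.k_bleach, photo.window)
        return times[0], times[1]
    if photo.k_bleach <= 0:
        return math.inf, math.inf
    mean = 1.0 / photo.k_bleach
    return _exp(rng, mean), _exp(rng, mean)


def _render(
    removals: list[TruthEvent],
    photo: PhotophysicsModel,
    rng: np.random.Generator,
    render: bool,
    meta: dict,
) -> Trace:
    """Render removal events into a noisy stepwise intensity trace."""
    n = photo.n_frames
    times = (np.arange(n) + 0.5) * photo.frame_interval
    if render:
        alive = np.full(n, 2.0)
        for ev in removals:
            if not ev.censored:
                alive -= times >= ev.time
        np.clip(alive, 0.0, None, out=alive)
        intensities = alive * photo.unit_intensity
        if photo.noise_sd > 0:
            intensities = intensities + rng.normal(0.0, photo.noise_sd, size=n)
    else:
        intensities = np.zeros(n)
        meta = {**meta, "rendered": False}
    return Trace(times=times, intensities=intensities, truth=removals, meta=meta)


def _removals_from_times(
    cleave: tuple[float, float],
    bleach: tuple[float, float],
    window: float,
) -> list[TruthEvent]:
    """Per fluorophore, whichever of cleavage and bleach comes first removes it."""
    out: list[TruthEvent] = []
    for i in range(2):
        if cleave[i] <= bleach[i]:
            t, cause = cleave[i], "cleave"
        else:
            t, cause = bleach[i], "bleach"
        if math.isfinite(t):
            out.append(TruthEvent(time=t, cause=cause, fluor=i, censored=t > window))
    out.sort(key=lambda ev: ev.time)
    return out


def simulate_processive_trace(
    substrate: SubstrateSpec,
    enzyme: EnzymeKineticsModel,
    photo: PhotophysicsModel,
    seed: SeedLike,
    render: bool = True,
) -> Trace:
    """Simulate one trace for a processive exonuclease.

    The enzyme binds after an exponential waiting time (rate
    ``k_bind_per_nM * concentration``; zero if ``prebound``), traverses the
    ``lead_nt`` native bonds before the first fluorophore, cleaves the first
    label bond, traverses the ``spacing`` native bonds, and cleaves the
    second label bond.  Each bond time is an independent exponential with
    mean ``tau_bond`` (native) or ``tau_label`` (fluorophore-conjugated).
    Bleaching competes independently for each fluorophore.
    """
    if enzyme.mode is not EnzymeMode.PROCESSIVE and enzyme.mode is not EnzymeMode.INACTIVE:
        raise ValueError("simulate_processive_trace requires processive (or inactive) mode")
    if (
        enzyme.mode is EnzymeMode.PROCESSIVE
        and substrate.overhang_end is OverhangEnd.BLUNT_DUPLEX
    ):
        raise ValueError("a processive single-strand exonuclease needs an overhang end")
    rng = _rng(seed)

    def label_time() -> float:
        if enzyme.tau_label == 0.0:
            return 0.0
        return float(rng.gamma(enzyme.label_shape, enzyme.tau_label / enzyme.label_shape))

    if enzyme.mode is EnzymeMode.INACTIVE:
        c1 = c2 = math.inf
    else:
        rate = enzyme.binding_rate()
        t_bind = 0.0 if enzyme.prebound else _exp(rng, math.inf if rate <= 0 else 1.0 / rate)
        lead = rng.exponential(enzyme.tau_bond, substrate.lead_nt).sum() if substrate.lead_nt else 0.0
        c1 = t_bind + lead + label_time()
        span = rng.exponential(enzyme.tau_bond, substrate.spacing).sum() if substrate.spacing else 0.0
        c2 = c1 + span + label_time()
    removals = _removals_from_times((c1, c2), _sample_bleach_times(photo, rng), photo.window)
    meta = {"substrate": substrate, "enzyme": enzyme, "photo": photo}
    return _render(removals, photo, rng, render, meta)


def simulate_distributive_trace(
    substrate: SubstrateSpec,
    enzyme: EnzymeKineticsModel,
    photo: PhotophysicsModel,
    seed: SeedLike,
    render: bool = True,
) -> Trace:
    """Simulate one trace for a distributive endonuclease.

    Each labeled site is excised at an independent exponential time with the
    concentration-dependent per-site rate ``k_site(c)``; by memorylessness
    the inter-drop interval is itself Exponential(k_site), so its mean
    shrinks with concentration -- the signature that separates distributive
    from processive action downstream.
    """
    if enzyme.mode is not EnzymeMode.DISTRIBUTIVE:
        raise ValueError("simulate_distributive_trace requires distributive mode")
    rng = _rng(seed)
    k = enzyme.site_rate()
    if not math.isfinite(k) or k < 0:
        raise ValueError(f"k_site must be finite and >= 0, got {k}")
    mean = math.inf if k == 0 else 1.0 / k
    cleave = (_exp(rng, mean), _exp(rng, mean))
    removals = _removals_from_times(cleave, _sample_bleach_times(photo, rng), photo.window)
    meta = {"substrate": substrate, "enzyme": enzyme, "photo": photo}
    return _render(removals, photo, rng, render, meta)


def simulate_bleach_only_trace(
    photo: PhotophysicsModel,
    seed: SeedLike,
    render: bool = True,
) -> Trace:
    """Enzyme-free control: both fluorophores only photobleach spontaneously."""
    rng = _rng(seed)
    removals = _removals_from_times(
        (math.inf, math.inf), _sample_bleach_times(photo, rng), photo.window
    )
    for ev in removals:
        assert ev.cause == "bleach"
    meta = {"substrate": None, "enzyme": None, "photo": photo}
    return _render(removals, photo, rng, render, meta)


def simulate_fret_trace(
    kind: str,
    photo: PhotophysicsModel,
    seed: SeedLike,
    level: Optional[float] = None,
    low: float = 0.15,
    high: float = 0.77,
    t_unwind_mean: float = 1.4,
    k_ramp: float = 19.0,
    total_intensity: Optional[float] = None,
    start_frac: tuple[float, float] = (0.05, 0.5),
) -> FretTrace:
    """Simulate a donor/acceptor FRET trace pair.

    ``kind="static"`` holds the true efficiency at ``level``.
    ``kind="unwinding"`` holds ``low`` until a random start time, ramps
    linearly to ``high`` over a Gamma(``k_ramp``, mean ``t_unwind_mean``)
    duration, then holds ``high`` -- the signature of duplex unwinding
    converting a low-FRET geometry into a high-FRET one.  Channels are
    rendered as ``total*(1-E)`` (donor) and ``total*E`` (acceptor) plus
    independent Gaussian noise.
    """
    rng = _rng(seed)
    n = photo.n_frames
    times = (np.arange(n) + 0.5) * photo.frame_interval
    total = 2.0 * photo.unit_intensity if total_intensity is None else float(total_intensity)
    if kind == "static":
        if level is None or not 0.0 <= level <= 1.0:
            raise ValueError("static kind requires level in [0, 1]")
        eff = np.full(n, float(level))
        truth = {"kind": "static", "level": float(level)}
    elif kind == "unwinding":
        if not 0.0 <= low < high <= 1.0:
            raise ValueError("unwinding requires 0 <= low < high <= 1")
        t_start = float(rng.uniform(*start_frac)) * photo.window
        dur = float(rng.gamma(k_ramp, t_unwind_mean / k_ramp))
        eff = np.where(
            times < t_start,
            low,
            np.where(
                times < t_start + dur,
                low + (high - low) * (times - t_start) / max(dur, 1e-12),
                high,
            ),
        )
        truth = {
            "kind": "unwinding",
            "low": low,
            "high": high,
            "t_start": t_start,
            "t_unwind": dur,
        }
    else:
        raise ValueError(f"unknown FRET kind {kind!r}")
    donor = total * (1.0 - eff)
    acceptor = total * eff
    if photo.noise_sd > 0:
        donor = donor + rng.normal(0.0, photo.noise_sd, size=n)
        acceptor = acceptor + rng.normal(0.0, photo.noise_sd, size=n)
    return FretTrace(
        times=times, donor=donor, acceptor=acceptor, truth=truth,
        meta={"photo": photo},
    )


def simulate_movie(
    traces: Sequence[Trace],
    field_size: int = 64,
    psf_sd: float = 1.2,
    spot_positions: Optional[np.ndarray] = None,
    seed: SeedLike = 0,
    background: float = 100.0,
    shot_noise: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Render traces as diffraction-limited spots in a TIRF-like image stack.

    Each trace becomes a 2-D Gaussian spot whose integrated intensity per
    frame equals the trace intensity, on a constant background with
    Poisson (shot-like) noise.  Returns ``(stack, positions)`` where the
    16-bit stack has one frame per trace frame and ``positions`` holds the
    ground-truth (row, col) spot centers.
    """
    rng = _rng(seed)
    margin = 4.0 * psf_sd
    min_sep = 6.0 * psf_sd
    n_spots = len(traces)
    if spot_positions is None:
        # deterministic centered grid layout honoring margin and separation
        if n_spots > 0:
            per_row = max(1, int((field_size - 2 * margin) // min_sep) + 1)
            n_rows = int(np.ceil(n_spots / per_row))
            n_cols = min(n_spots, per_row)
            extent = (n_rows - 1) * min_sep, (n_cols - 1) * min_sep
            r0 = (field_size - extent[0]) / 2.0
            c0 = (field_size - extent[1]) / 2.0
            coords = []
            for i in range(n_spots):
                r, c = divmod(i, per_row)
                coords.append((r0 + r * min_sep, c0 + c * min_sep))
            positions = np.asarray(coords, dtype=float)
            if (
                positions.min() < margin - 1e-9
                or positions.max() > field_size - margin + 1e-9
            ):
                raise ValueError("overcrowded layout: spots do not fit in the field")
        else:
            positions = np.zeros((0, 2))
    else:
        positions = np.asarray(spot_positions, dtype=float).reshape(-1, 2)
        if len(positions) != n_spots:
            raise ValueError("spot_positions length must match number of traces")
        if len(positions) and (
            positions.min() < margin or positions.max() > field_size - margin
        ):
            raise ValueError(f"overcrowded layout: spots need a {margin:.1f}-px margin")
        for i in range(len(positions)):
            d = np.hypot(*(positions[i] - positions[i + 1 :]).T)
            if len(d) and d.min() < min_sep:
                raise ValueError(f"overcrowded layout: spots closer than {min_sep:.1f} px")
    n_frames = len(traces[0].times) if n_spots else 100
    clean = np.full((n_frames, field_size, field_size), float(background))
    half = int(np.ceil(5 * psf_sd))
    for trace, (r0, c0) in zip(traces, positions):
        ri, ci = int(round(r0)), int(round(c0))
        rs = np.arange(max(0, ri - half), min(field_size, ri + half + 1))
        cs = np.arange(max(0, ci - half), min(field_size, ci + half + 1))
        kr = np.exp(-0.5 * ((rs - r0) / psf_sd) ** 2)
        kc = np.exp(-0.5 * ((cs - c0) / psf_sd) ** 2)
        kernel = np.outer(kr, kc)
        kernel /= 2.0 * np.pi * psf_sd**2  # unit integral over the plane
        clean[:, rs[0] : rs[-1] + 1, cs[0] : cs[-1] + 1] += (
            trace.intensities[:, None, None] * kernel[None, :, :]
        )
    np.clip(clean, 0.0, None, out=clean)
    if shot_noise:
        stack = rng.poisson(clean).astype(np.uint16)
    else:
        stack = np.clip(np.round(clean), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return stack, positions
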