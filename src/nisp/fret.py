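"""FRET-branch analysis: efficiency series, histograms, unwinding dwells.

Used for the duplex-DNA negative control (a static high-FRET population
that an ssDNA-specific nuclease leaves untouched) and for duplex-unwinding
kinetics, where an enzyme converts a low-FRET geometry into a high-FRET
one; the low-to-high transition dwell divided into the number of base
pairs unwound gives the unwinding rate.

Efficiency is the uncorrected proximity ratio acceptor/(acceptor+donor):
no gamma, leakage, or direct-excitation correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .kinetics import _fit_plain_gaussian, make_histogram
from .models import FretTrace


@dataclass(frozen=True)
class EfficiencySeries:
    """Per-frame FRET efficiency, defined only above the intensity floor."""

    times: np.ndarray
    efficiency: np.ndarray  # clipped to [0, 1]


@dataclass(frozen=True)
class UnwindingCall:
    """A detected low-to-high FRET transition."""

    t_start: float
    t_end: float
    T_unwinding: float       # s, = t_end - t_start
    paused: bool
    v_unwinding: Optional[float] = None  # bp/s, set when bp_unwound is known


@dataclass(frozen=True)
class GaussianComponent:
    mean: float
    sd: float
    weight: float


def compute_efficiency(trace: FretTrace, floor: float = 400.0) -> EfficiencySeries:
    """Proximity-ratio efficiency E = acceptor / (acceptor + donor).

    Frames whose total emission falls below ``floor`` (bleached or unbound
    molecules) are dropped; values are clipped to [0, 1].
    """
    if floor <= 0:
        raise ValueError("floor must be > 0")
    total = trace.donor + trace.acceptor
    mask = total >= floor
    if not np.any(mask):
        raise ValueError("all frames below the intensity floor; no efficiency defined")
    eff = np.clip(trace.acceptor[mask] / total[mask], 0.0, 1.0)
    return EfficiencySeries(times=trace.times[mask], efficiency=eff)


def fit_efficiency_histogram(
    series_pool: Sequence[EfficiencySeries],
    bin_width: float = 0.02,
    bimodality_threshold: float = 0.5,
) -> list[GaussianComponent]:
    """Gaussian summary of a pooled efficiency histogram (one or two modes).

    Pools all frames, builds a uniform histogram on [0, 1], and fits one
    Gaussian -- or two when the dip-style contrast between the two largest
    modes exceeds ``bimodality_threshold``.
    """
    pooled = np.concatenate([s.efficiency for s in series_pool])
    if len(pooled) < 100:
        raise ValueError(f"need >= 100 pooled frames, got {len(pooled)}")
    n_bins = max(4, int(round(1.0 / bin_width)))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(pooled, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    peaks, props = find_peaks(smooth, prominence=0.05 * smooth.max())
    bimodal = False
    if len(peaks) >= 2:
        order = np.argsort(smooth[peaks])[::-1][:2]
        p_lo, p_hi = sorted(peaks[order])
        minor = min(smooth[p_lo], smooth[p_hi])
        valley = smooth[p_lo : p_hi + 1].min()
        contrast = (minor - valley) / minor if minor > 0 else 0.0
        bimodal = contrast > bimodality_threshold
    c = counts.astype(float)
    if not bimodal:
        mu, sigma, A, _ = _fit_plain_gaussian(centers, c, bin_width)
        return [GaussianComponent(mean=float(mu), sd=float(sigma), weight=1.0)]
    # two-component fit, initialized at the detected modes
    import lmfit

    span = centers[-1] - centers[0]
    p = lmfit.Parameters()
    for i, pk in enumerate((p_lo, p_hi)):
        p.add(f"A{i}", value=float(max(smooth[pk], 1.0)), min=0.0)
        p.add(f"mu{i}", value=float(centers[pk]), min=0.0, max=1.0)
        p.add(f"sd{i}", value=0.05, min=bin_width / 2, max=span / 2)

    def resid(pars):
        v = pars.valuesdict()
        model = sum(
            v[f"A{i}"] * np.exp(-0.5 * ((centers - v[f"mu{i}"]) / v[f"sd{i}"]) ** 2)
            for i in range(2)
        )
        return model - c

    out = lmfit.minimize(resid, p, method="leastsq")
    v = out.params.valuesdict()
    masses = [v[f"A{i}"] * v[f"sd{i}"] for i in range(2)]
    total_mass = sum(masses) or 1.0
    comps = [
        GaussianComponent(mean=float(v[f"mu{i}"]), sd=float(v[f"sd{i}"]),
                          weight=float(masses[i] / total_mass))
        for i in range(2)
    ]
    return sorted(comps, key=lambda g: g.mean)


def detect_unwinding(
    series: EfficiencySeries,
    low_level: float,
    high_level: float,
    enter_frac: float = 0.1,
    pause_max: float = 0.5,
    bp_unwound: Optional[float] = None,
) -> Optional[UnwindingCall]:
    """Detect one complete low-to-high FRET transition, or return None.

    Threshold crossings at ``low + enter_frac*(high-low)`` and
    ``high - enter_frac*(high-low)`` are located, then linearly
    extrapolated to the full low/high levels so the reported dwell spans
    the entire transition rather than the inter-threshold fraction.
    A contiguous intermediate-level plateau of at least ``pause_max``
    seconds marks the call as paused (excluded from rate aggregation).
    """
    if not low_level < high_level:
        raise ValueError("low_level must be < high_level")
    t = series.times
    e = series.efficiency
    if len(t) < 3:
        return None
    span = high_level - low_level
    thr_lo = low_level + enter_frac * span
    thr_hi = high_level - enter_frac * span
    above = np.nonzero(e >= thr_hi)[0]
    if len(above) == 0:
        return None
    i_hi = int(above[0])
    below = np.nonzero(e[:i_hi] <= thr_lo)[0]
    if len(below) == 0:
        return None
    i_lo = int(below[-1])
    if i_hi <= i_lo:
        return None

    # slope of the transition from a least-squares line over the
    # inter-threshold segment (unbiased under frame noise, unlike the raw
    # first/last crossing frames); the line's crossings of the full low and
    # high levels delimit the dwell
    seg_t = t[i_lo : i_hi + 1]
    seg_e = e[i_lo : i_hi + 1]
    if len(seg_t) >= 3:
        A = np.vstack([seg_t, np.ones_like(seg_t)]).T
        m, b = np.linalg.lstsq(A, seg_e, rcond=None)[0]
    else:
        m, b = 0.0, 0.0
    if m <= 0:
        # degenerate (e.g. single-frame jump): fall back to frame crossings
        dt_frame = float(t[1] - t[0])
        m = (thr_hi - thr_lo) / max(float(t[i_hi] - t[i_lo]), dt_frame)
        b = thr_lo - m * float(t[i_lo])
    t_start = (low_level - b) / m
    t_end = (high_level - b) / m

    paused = False
    if i_hi - i_lo > 2:
        dt = float(np.median(np.diff(t)))
        k = max(1, int(round(0.3 / dt)))  # ~0.3 s smoothing for the rate estimate
        seg = e[i_lo : i_hi + 1]
        sm = np.convolve(seg, np.ones(k) / k, mode="same")
        rate = np.abs(np.gradient(sm, t[i_lo : i_hi + 1]))
        mid = (sm > low_level + 0.2 * span) & (sm < high_level - 0.2 * span)
        flat = mid & (rate < 0.25 * m)
        run = 0
        for f in flat:
            run = run + 1 if f else 0
            if run * dt >= pause_max:
                paused = True
                break
    T = t_end - t_start
    v = bp_unwound / T if bp_unwound is not None else None
    return UnwindingCall(t_start=t_start, t_end=t_end, T_unwinding=T, paused=paused, v_unwinding=v)


def unwinding_rate(
    calls: Sequence[UnwindingCall],
    bp_unwound: float,
    bin_width: Optional[float] = None,
) -> dict:
    """Aggregate unwinding rate: bp divided by the Gaussian-mean dwell.

    Pauses are excluded.  The reported rate uses the Gaussian-fitted mean
    of the dwell histogram (robust to the heavy right tail of per-call
    1/T); its sd is propagated from the dwell sd by the delta method.
    Per-call rates are returned alongside.
    """
    dwells = np.array([c.T_unwinding for c in calls if not c.paused], dtype=float)
    if len(dwells) < 20:
        raise ValueError(f"need >= 20 unpaused calls, got {len(dwells)}")
    if bin_width is None:
        fd = np.histogram_bin_edges(dwells, bins="fd")
        bin_width = float(fd[1] - fd[0])
    hist = make_histogram(dwells, bin_width)
    mu, sigma, _, _ = _fit_plain_gaussian(hist.centers, hist.counts.astype(float), bin_width)
    rate = bp_unwound / mu
    sd_rate = bp_unwound * sigma / mu**2
    return {
        "n_calls": int(len(dwells)),
        "mean_dwell_s": float(mu),
        "sd_dwell_s": float(sigma),
        "rate_bp_per_s": float(rate),
        "sd_rate_bp_per_s": float(sd_rate),
        "per_call_rates": bp_unwound / dwells,
    }
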