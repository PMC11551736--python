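"""Kinetic analysis of photodropping dwell times.

This is the statistical core of the assay: scenario-occurrence tables with
control subtraction, dwell-time (T2) histogramming with bin-width stability
selection, a quartic-polynomial photobleaching background, a Gaussian-plus-
background fit whose mean is the degradation time T2_av, the linear
decomposition T2_av = tau_bond * spacing + tau_label whose inverted slope is
the per-nucleotide degradation rate, and a processive-vs-distributive
classifier based on the concentration dependence of T2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# Histograms and fits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DwellHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    n_events: int
    bin_width: float

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def make_histogram(samples: Sequence[float], bin_width: float, t_min: float = 0.0) -> DwellHistogram:
    """Uniform-width histogram of dwell samples starting at ``t_min``."""
    x = np.asarray(samples, dtype=float)
    if len(x) == 0:
        raise ValueError("no samples to histogram")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    n_bins = max(1, int(np.ceil((x.max() - t_min) / bin_width + 1e-9)))
    edges = t_min + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(x, bins=edges)
    return DwellHistogram(bin_edges=edges, counts=counts, n_events=len(x), bin_width=bin_width)


@dataclass(frozen=True)
class BackgroundFit:
    """Quartic polynomial in t fitted to control (enzyme-free) dwell counts."""

    coeffs: np.ndarray  # a0..a4, ascending powers
    rss: float

    def predict(self, t: np.ndarray) -> np.ndarray:
        # predicted counts are clipped at zero over the fitted range
        return np.clip(np.polynomial.polynomial.polyval(t, self.coeffs), 0.0, None)


@dataclass(frozen=True)
class GaussPolyFit:
    """Gaussian degradation peak over a quartic photobleaching background."""

    mu: float        # T2_av, s
    sigma: float     # s
    amplitude: float # peak counts
    background: BackgroundFit
    rss: float
    mode: str = "joint"
    n_events: int = 0


@dataclass(frozen=True)
class KineticDecomposition:
    """T2_av-vs-spacing regression: slope = per-bond time, 1/slope = rate."""

    slope: float         # s nt^-1
    intercept: float     # s (label-bond time)
    rate: float          # nt s^-1 = 1/slope
    se_slope: float
    se_intercept: float
    se_rate: float       # delta method: se_slope / slope^2
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class ProcessivityCall:
    classification: str  # "processive" or "distributive"
    slope: float         # d T2_av / d ln(concentration)
    se_slope: float
    one_step_trend: Optional[float] = None


def _fit_plain_gaussian(
    centers: np.ndarray, counts: np.ndarray, bin_width: float
) -> tuple[float, float, float, float]:
    """Least-squares Gaussian on binned counts; returns (mu, sigma, A, rss)."""
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    mu0 = float(centers[np.argmax(counts)])
    mean = float(np.average(centers, weights=counts))
    sd = float(np.sqrt(np.average((centers - mean) ** 2, weights=counts)))
    span = max(centers[-1] - centers[0], bin_width)
    p = lmfit.Parameters()
    p.add("A", value=float(counts.max()), min=0.0)
    p.add("mu", value=mu0, min=float(centers[0] - bin_width), max=float(centers[-1] + bin_width))
    p.add("sigma", value=max(sd, bin_width / 2 + 1e-9), min=bin_width / 2, max=max(span / 2, bin_width))

    def resid(pars):
        v = pars.valuesdict()
        return v["A"] * np.exp(-0.5 * ((centers - v["mu"]) / v["sigma"]) ** 2) - counts

    best = None
    for mu_init in (mu0, mean):
        p["mu"].value = mu_init
        out = lmfit.minimize(resid, p, method="leastsq")
        if best is None or out.chisqr < best.chisqr:
            best = out
    v = best.params.valuesdict()
    return v["mu"], v["sigma"], v["A"], float(best.chisqr)


def select_bin_width(
    t2_samples: Sequence[float],
    candidate_widths: Sequence[float] = (0.25, 0.5, 0.75, 1.0, 1.5, 2.0),
    stability_tol: float = 0.2,
) -> float:
    """Smallest bin width at which the fitted Gaussian mean has stabilized.

    Fits a plain Gaussian at each candidate width in ascending order and
    returns the smallest width whose fitted mean differs from the next
    wider one by less than ``stability_tol``; falls back to the
    Freedman-Diaconis width if no pair stabilizes.
    """
    x = np.asarray(t2_samples, dtype=float)
    if len(x) < 30:
        raise ValueError(f"need >= 30 samples to select a bin width, got {len(x)}")
    widths = sorted(candidate_widths)
    if len(widths) < 3:
        raise ValueError("need >= 3 candidate widths")
    if np.ptp(x) == 0:
        return float(widths[0])
    mus: list[Optional[float]] = []
    for w in widths:
        try:
            hist = make_histogram(x, w)
            mu, *_ = _fit_plain_gaussian(hist.centers, hist.counts.astype(float), w)
            mus.append(mu)
        except Exception:
            mus.append(None)
    for i in range(len(widths) - 1):
        if mus[i] is not None and mus[i + 1] is not None:
            if abs(mus[i] - mus[i + 1]) < stability_tol:
                return float(widths[i])
    fd_edges = np.histogram_bin_edges(x, bins="fd")
    return float(fd_edges[1] - fd_edges[0])


def fit_background(histogram: DwellHistogram) -> BackgroundFit:
    """Quartic least-squares fit to an enzyme-free dwell histogram."""
    nonempty = int(np.count_nonzero(histogram.counts))
    if nonempty < 6:
        raise ValueError(f"need >= 6 nonempty bins for a quartic fit, got {nonempty}")
    t = histogram.centers
    c = histogram.counts.astype(float)
    coeffs = np.polynomial.polynomial.polyfit(t, c, 4)
    rss = float(np.sum((np.polynomial.polynomial.polyval(t, coeffs) - c) ** 2))
    return BackgroundFit(coeffs=coeffs, rss=rss)


def fit_gaussian_plus_background(
    histogram: DwellHistogram,
    control_background: Optional[BackgroundFit] = None,
    mode: str = "joint",
) -> GaussPolyFit:
    """Fit A*exp(-(t-mu)^2/2 sigma^2) + quartic(t) to a dwell histogram.

    ``joint`` refits the quartic initialized at the control fit: the
    background keeps the control's shape but its overall scale is free and
    each coefficient may be refined within +/-50%, which prevents the
    (clipped) polynomial from collapsing onto the degradation peak.
    ``fixed_shape`` only scales the control quartic by one factor.  The
    fitted ``mu`` is the background-subtracted mean degradation time T2_av.
    """
    if mode not in ("joint", "fixed_shape"):
        raise ValueError(f"unknown mode {mode!r}")
    t = histogram.centers
    c = histogram.counts.astype(float)
    if int(np.count_nonzero(c)) < 8:
        raise ValueError("need >= 8 nonempty bins")
    bw = histogram.bin_width
    span = max(t[-1] - t[0], bw)

    if control_background is None:
        ctrl_coeffs = np.zeros(5)
        ctrl_pred = np.zeros_like(t)
        mode = "joint"
    else:
        ctrl_coeffs = np.asarray(control_background.coeffs, dtype=float)
        ctrl_pred = control_background.predict(t)

    ctrl_mass = float(ctrl_pred.sum())
    scale0 = 0.25 * c.sum() / ctrl_mass if ctrl_mass > 0 else 0.0
    resid0 = np.clip(c - scale0 * ctrl_pred, 0.0, None)
    mu0 = float(t[np.argmax(resid0)])
    mean0 = float(np.average(t, weights=np.maximum(resid0, 1e-12)))
    sd0 = float(
        np.sqrt(np.average((t - mean0) ** 2, weights=np.maximum(resid0, 1e-12)))
    )

    def build_params(mu_init: float) -> lmfit.Parameters:
        p = lmfit.Parameters()
        p.add("A", value=max(float(resid0.max()), 1.0), min=0.0)
        p.add("mu", value=mu_init, min=float(t[0]), max=float(t[-1]))
        p.add("sigma", value=min(max(sd0, bw / 2 + 1e-9), span / 2), min=bw / 2, max=span / 2)
        has_bg = np.any(ctrl_coeffs != 0.0)
        p.add("bg_scale", value=max(scale0, 1e-6) if has_bg else 0.0,
              min=0.0, vary=has_bg)
        if mode == "joint":
            for i in range(5):
                p.add(f"d{i}", value=0.0, min=-0.5, max=0.5, vary=has_bg)
        return p

    def bg_coeffs(v: dict) -> np.ndarray:
        if mode == "fixed_shape":
            return ctrl_coeffs * v["bg_scale"]
        refine = np.array([1.0 + v[f"d{i}"] for i in range(5)])
        return ctrl_coeffs * v["bg_scale"] * refine

    def model(pars) -> np.ndarray:
        v = pars.valuesdict()
        g = v["A"] * np.exp(-0.5 * ((t - v["mu"]) / v["sigma"]) ** 2)
        bg = np.clip(np.polynomial.polynomial.polyval(t, bg_coeffs(v)), 0.0, None)
        return g + bg

    best = None
    for mu_init in dict.fromkeys((mu0, mean0, float(np.median(t)))):
        try:
            out = lmfit.minimize(lambda p: model(p) - c, build_params(mu_init), method="leastsq")
        except Exception:
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None:
        raise RuntimeError("Gaussian-plus-background fit did not converge from any start")
    v = best.params.valuesdict()
    bg = BackgroundFit(coeffs=bg_coeffs(v), rss=math.nan)
    return GaussPolyFit(
        mu=float(v["mu"]),
        sigma=float(v["sigma"]),
        amplitude=float(v["A"]),
        background=bg,
        rss=float(best.chisqr),
        mode=mode,
        n_events=histogram.n_events,
    )


# ---------------------------------------------------------------------------
# Occurrence tables
# ---------------------------------------------------------------------------

def occurrence_delta(prob: float, prob_control: float) -> float:
    """Population change in percentage points, on one-decimal-rounded inputs."""
    return round(round(prob, 1) - round(prob_control, 1), 1)


def build_occurrence_table(
    counts: pd.DataFrame, control_condition: str
) -> pd.DataFrame:
    """Scenario probabilities (one decimal, %) and deltas vs the control.

    ``counts`` is the per-condition table from
    :func:`nisp.traces.classify_and_extract` (rejected traces are already
    excluded from ``n_total``).
    """
    if control_condition not in set(counts["condition"]):
        raise ValueError(f"control condition {control_condition!r} not present")
    out = counts.copy()
    for sc in ("no_drop", "one_step", "two_step"):
        out[f"p_{sc}"] = (100.0 * out[f"n_{sc}"] / out["n_total"]).round(1)
    ctrl = out.loc[out["condition"] == control_condition].iloc[0]
    for sc in ("no_drop", "one_step", "two_step"):
        out[f"delta_{sc}"] = out[f"p_{sc}"].map(
            lambda p, p0=float(ctrl[f"p_{sc}"]): occurrence_delta(p, p0)
        )
    return out


def efficiency_ratio(delta_a: float, delta_b: float) -> float:
    """Fold difference between two population deltas, to one decimal."""
    if delta_b <= 0:
        raise ValueError("denominator delta must be > 0")
    return round(delta_a / delta_b, 1)


# ---------------------------------------------------------------------------
# Linear decomposition and processivity
# ---------------------------------------------------------------------------

def decompose_linear(
    points: Sequence[tuple], weighted: bool = False
) -> KineticDecomposition:
    """Regress T2_av on fluorophore spacing; 1/slope is the degradation rate.

    ``points`` are ``(spacing_nt, t2_av_s)`` or ``(spacing_nt, t2_av_s, se_s)``
    tuples.  Ordinary least squares by default; ``weighted=True`` applies
    1/se^2 weights when the per-point standard errors are given.
    """
    pts = [tuple(p) for p in points]
    S = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if len(set(S)) < 3:
        raise ValueError("need >= 3 distinct spacing values")
    if np.ptp(S) == 0:
        raise ValueError("zero variance in spacing")
    if weighted:
        se = np.array([p[2] for p in pts], dtype=float)
        w = 1.0 / se**2
        W = np.sum(w)
        xbar = np.sum(w * S) / W
        ybar = np.sum(w * y) / W
        sxx = np.sum(w * (S - xbar) ** 2)
        slope = np.sum(w * (S - xbar) * (y - ybar)) / sxx
        intercept = ybar - slope * xbar
        resid = y - (slope * S + intercept)
        dof = len(S) - 2
        s2 = np.sum(w * resid**2) / dof
        se_slope = float(np.sqrt(s2 / sxx))
        se_intercept = float(np.sqrt(s2 * (1.0 / W + xbar**2 / sxx)))
        ss_tot = np.sum(w * (y - ybar) ** 2)
        r2 = float(1.0 - np.sum(w * resid**2) / ss_tot) if ss_tot > 0 else 1.0
    else:
        res = stats.linregress(S, y)
        slope, intercept = float(res.slope), float(res.intercept)
        se_slope, se_intercept = float(res.stderr), float(res.intercept_stderr)
        r2 = float(res.rvalue**2)
    if slope <= 0:
        raise ValueError(f"nonpositive slope {slope}: dwell must grow with spacing")
    rate = 1.0 / slope
    return KineticDecomposition(
        slope=slope,
        intercept=float(intercept),
        rate=rate,
        se_slope=se_slope,
        se_intercept=se_intercept,
        se_rate=se_slope / slope**2,
        r_squared=r2,
        n_points=len(S),
    )


def classify_processivity(
    t2_by_concentration: Sequence[tuple],
    occurrence_deltas: Optional[Sequence[tuple]] = None,
) -> ProcessivityCall:
    """Processive vs distributive from the concentration dependence of T2.

    A processive enzyme completes the whole traversal in one binding event,
    so T2_av does not depend on enzyme concentration; a distributive one
    rebinds between cuts and T2_av shrinks as concentration rises.  The
    call regresses T2_av on log-concentration: distributive when the slope
    is negative and exceeds twice its standard error in magnitude.
    """
    pts = [tuple(p) for p in t2_by_concentration]
    if len(pts) < 3:
        raise ValueError("need >= 3 concentrations to classify processivity")
    c = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0")
    res = stats.linregress(np.log(c), y)
    slope, se = float(res.slope), float(res.stderr)
    distributive = slope < 0 and abs(slope) > 2.0 * se
    trend = None
    if occurrence_deltas is not None and len(occurrence_deltas) >= 2:
        oc = np.array([p[0] for p in occurrence_deltas], dtype=float)
        od = np.array([p[1] for p in occurrence_deltas], dtype=float)
        trend = float(stats.linregress(np.log(oc), od).slope)
    return ProcessivityCall(
        classification="distributive" if distributive else "processive",
        slope=slope,
        se_slope=se,
        one_step_trend=trend,
    )
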