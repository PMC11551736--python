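"""Domain types for the NISP (nuclease-induced stepwise photodropping) pipeline.

A NISP substrate is a surface-immobilized DNA duplex carrying a single-stranded
overhang labeled with two Cy3 fluorophores.  A nuclease removes the fluorophores
one by one, producing a stepwise decrease of the molecule's fluorescence
intensity; spontaneous photobleaching produces the same signature and must be
subtracted downstream.  These dataclasses carry the substrate geometry, the
enzyme kinetic model, the camera/photophysics parameters, and the simulated or
measured traces themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Optional

import numpy as np


class LabelType(str, Enum):
    """Fluorophore attachment chemistry.

    iCy3 is conjugated internally into the phosphate backbone, eCy3 externally
    onto a thymine base; the two retard cleavage of the labeled bond
    differently and therefore carry different label-bond dwell intercepts.
    """

    ICY3 = "iCy3"
    ECY3 = "eCy3"


class OverhangEnd(str, Enum):
    FIVE_PRIME = "5'"
    THREE_PRIME = "3'"
    BLUNT_DUPLEX = "blunt"


class EnzymeMode(str, Enum):
    PROCESSIVE = "processive"
    DISTRIBUTIVE = "distributive"
    INACTIVE = "inactive"


class Scenario(str, Enum):
    """Trace classes: zero, one, or two photodrops in the acquisition window."""

    NO_DROP = "no_drop"
    ONE_STEP = "one_step"
    TWO_STEP = "two_step"
    REJECTED = "rejected"


@dataclass(frozen=True)
class SubstrateSpec:
    """Geometry of a di-labeled overhang substrate.

    Parameters
    ----------
    spacing
        Number of nucleotides with native scissile phosphodiester bonds
        between the two fluorophores (the substrate's ``S``), in nt.
    lead_nt
        Nucleotides between the free overhang end and the first fluorophore.
    label_type
        iCy3 (backbone) or eCy3 (base) conjugation.
    overhang_end
        Which end of the duplex carries the labeled overhang; ``BLUNT_DUPLEX``
        denotes a fully double-stranded (negative-control) substrate.
    overhang_length
        Total overhang length in nt; must accommodate both labels.
    """

    spacing: int
    lead_nt: int = 5
    label_type: LabelType = LabelType.ICY3
    overhang_end: OverhangEnd = OverhangEnd.FIVE_PRIME
    overhang_length: int = 40

    def __post_init__(self) -> None:
        if self.spacing < 0:
            raise ValueError(f"spacing must be >= 0, got {self.spacing}")
        if self.lead_nt < 0:
            raise ValueError(f"lead_nt must be >= 0, got {self.lead_nt}")
        if (
            self.overhang_end is not OverhangEnd.BLUNT_DUPLEX
            and self.lead_nt + self.spacing + 2 > self.overhang_length
        ):
            raise ValueError(
                "labels do not fit on the overhang: "
                f"lead_nt + spacing + 2 = {self.lead_nt + self.spacing + 2} "
                f"> overhang_length = {self.overhang_length}"
            )


@dataclass(frozen=True)
class EnzymeKineticsModel:
    """Kinetic model of a nuclease acting on a NISP substrate.

    A processive enzyme binds once and traverses the overhang, spending an
    exponential time with mean ``tau_bond`` (s) on each native scissile bond
    and ``tau_label`` (s) on each fluorophore-conjugated bond, so the expected
    inter-drop dwell is ``spacing * tau_bond + tau_label``.  A distributive
    enzyme cleaves each labeled site independently at rate ``k_site(c)``
    (s^-1), so the inter-drop interval is memoryless and concentration
    dependent.  ``INACTIVE`` produces no enzymatic events (inhibitory-ion or
    dead-mutant controls).

    Native-bond times are exponential (memoryless single-enzyme catalysis),
    so traversal of ``spacing`` bonds is Gamma(spacing, tau_bond).  The
    label-bond time is Gamma(``label_shape``, mean ``tau_label``): cleaving
    the fluorophore-conjugated bond is a multi-substep stall, giving the
    peaked, unimodal dwell histograms seen in this assay rather than an
    exponential tail; ``label_shape = 1`` recovers the exponential case.
    """

    mode: EnzymeMode
    tau_bond: float = 0.16          # s per native bond (processive)
    tau_label: float = 0.40         # s per fluorophore-conjugated bond
    label_shape: float = 4.0        # Gamma shape of the label-bond time
    k_bind_per_nM: float = 0.01     # first-binding rate per nM, s^-1 nM^-1
    concentration: float = 1.0      # nM
    prebound: bool = False          # Mg2+-triggered wash condition: t_bind = 0
    k_site: Optional[float] = None  # distributive per-site rate, s^-1 (direct)
    k_max: Optional[float] = None   # saturating form k_max*c/(c + c_half)
    c_half: Optional[float] = None  # nM

    def __post_init__(self) -> None:
        if not math.isfinite(self.label_shape) or self.label_shape <= 0:
            raise ValueError(f"label_shape must be finite and > 0, got {self.label_shape}")
        for name in ("tau_bond", "tau_label", "k_bind_per_nM", "concentration"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.mode is EnzymeMode.PROCESSIVE and self.tau_bond <= 0:
            raise ValueError("processive mode requires tau_bond > 0")
        if self.mode is EnzymeMode.DISTRIBUTIVE:
            if self.k_site is None and (self.k_max is None or self.c_half is None):
                raise ValueError(
                    "distributive mode requires k_site, or k_max and c_half"
                )

    def site_rate(self, concentration: Optional[float] = None) -> float:
        """Distributive per-site cleavage rate at the given concentration (s^-1)."""
        c = self.concentration if concentration is None else concentration
        if self.k_site is not None:
            return float(self.k_site)
        assert self.k_max is not None and self.c_half is not None
        return float(self.k_max) * c / (c + float(self.c_half))

    def binding_rate(self) -> float:
        return self.k_bind_per_nM * self.concentration


@dataclass(frozen=True)
class PhotophysicsModel:
    """Camera and dye photophysics shared by every simulated condition.

    ``bleach_mixture``, when set, replaces independent per-fluorophore
    exponential bleaching by a direct draw of the non-enzymatic scenario
    (no-drop / one-drop / two-drop) from the given 3-vector of probabilities,
    with bleach times then sampled conditionally inside the window.  This
    reproduces empirical control scenario splits that two independent
    exponentials cannot.
    """

    unit_intensity: float = 1000.0  # single-fluorophore mean intensity, a.u.
    noise_sd: float = 50.0          # additive Gaussian noise per frame, a.u.
    k_bleach: float = 0.0012        # per-fluorophore bleach rate, s^-1
    frame_interval: float = 0.1     # s
    window: float = 100.0           # acquisition length, s
    bleach_mixture: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if self.unit_intensity <= 0:
            raise ValueError("unit_intensity must be > 0")
        if self.noise_sd < 0 or self.k_bleach < 0:
            raise ValueError("noise_sd and k_bleach must be >= 0")
        n = self.window / self.frame_interval
        if abs(n - round(n)) > 1e-9:
            raise ValueError("window must be a whole number of frames")
        if self.bleach_mixture is not None:
            p = np.asarray(self.bleach_mixture, dtype=float)
            if p.shape != (3,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-6):
                raise ValueError("bleach_mixture must be 3 probabilities summing to 1")

    @property
    def n_frames(self) -> int:
        return int(round(self.window / self.frame_interval))


@dataclass(frozen=True)
class TruthEvent:
    """Ground-truth fluorophore-removal event recorded by the simulator."""

    time: float          # s, uncensored
    cause: str           # "cleave" or "bleach"
    fluor: int           # 0 = proximal (first reached), 1 = distal
    censored: bool       # True if time > acquisition window (not rendered)


@dataclass
class Trace:
    """One molecule's intensity time trace with optional ground truth."""

    times: np.ndarray
    intensities: np.ndarray
    truth: Optional[list[TruthEvent]] = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("times must be strictly increasing with constant spacing")

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0


@dataclass
class FretTrace:
    """Donor/acceptor intensity pair for a single molecule."""

    times: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    truth: Optional[dict[str, Any]] = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if not (self.times.shape == self.donor.shape == self.acceptor.shape):
            raise ValueError("times, donor, acceptor must have equal length")


@dataclass
class StepCall:
    """Output of the step finder for one trace."""

    step_times: np.ndarray        # ordered change-point times, s
    step_magnitudes: np.ndarray   # signed intensity changes, a.u.
    scenario: Scenario
    T1: Optional[float] = None    # s, one-step dwell (start -> sole drop)
    T2: Optional[float] = None    # s, two-step dwell (between the two drops)
    meta: dict[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class SnrStats:
    """Signal-to-noise statistics, snr = (signal - background) / background sd."""

    signal_mean: float
    background_mean: float
    background_sd: float
    snr: float
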