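"""Fluorescence-titration readouts of membrane electrostatics.

Three probe classes are handled, each reporting a distinct potential:

* 1,8-ANS emission time courses (surface potential ψ_s): membranes are
  added to the cuvette, a baseline window is read, and peptide is added in
  steps; each step settles to a plateau whose height grows saturably with
  cumulative dose.
* di-8-ANEPPS excitation scans (dipole potential ψ_d): the readout is the
  ratio R = I(ex 420 nm)/I(ex 520 nm) at fixed emission.
* TMRM quench-mode time courses (transmembrane potential ΔΨ_m): energised
  mitochondria quench the probe; the readout is the fractional change of
  emission after the addition.

The module reports probe responses only; no conversion of responses to
millivolt potentials is attempted. Saturation behaviour is summarised by a
one-site hyperbolic fit (response = R_max·d/(K + d)) exposed through the
:class:`SaturationModel`/:class:`SaturationResults` pair.

Also included is the PFG-NMR hydration-radius conversion against an
internal reference standard (DSS, R_h = 3.34 Å), for which solvent
viscosity cancels in the diffusion-coefficient ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ConfigError, DataError, NumericalError

__all__ = [
    "TitrationTrace",
    "SaturationCurve",
    "SaturationModel",
    "SaturationResults",
    "normalize_trace",
    "saturation_from_trace",
    "anepps_ratio",
    "tmrm_fractional_change",
    "hydration_radius",
    "DSS_HYDRATION_RADIUS",
]

DSS_HYDRATION_RADIUS = 3.34   # Å, internal reference standard


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TitrationTrace:
    """A time-stamped fluorescence intensity trace with addition events.

    ``events`` is a list of ``(time_s, label, dose)`` tuples; dose units are
    whatever the titration uses (nmol here). ``baseline_window`` is the
    (start, stop) time interval used for normalisation.
    """

    time: np.ndarray
    intensity: np.ndarray
    events: list = field(default_factory=list)
    baseline_window: tuple = (0.0, 0.0)
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape or self.time.ndim != 1:
            raise DataError("time and intensity must be matching 1-D arrays")
        if np.any(np.diff(self.time) <= 0):
            raise DataError("time must be strictly increasing")
        t0, t1 = self.baseline_window
        if not (self.time[0] <= t0 < t1 <= self.time[-1]):
            raise DataError("baseline window must lie inside the trace")

    def window_mean(self, t0: float, t1: float) -> float:
        mask = (self.time >= t0) & (self.time <= t1)
        if not mask.any():
            raise DataError(f"window ({t0}, {t1}) contains no samples")
        return float(self.intensity[mask].mean())


@dataclass
class SaturationCurve:
    """Dose-response summary of a stepwise titration."""

    dose: np.ndarray              # cumulative dose after each addition
    response: np.ndarray          # plateau minus baseline (normalised units)
    fractional: np.ndarray        # response / fitted maximum
    half_saturation: float
    max_response: float
    identifiable: bool


# ---------------------------------------------------------------------------
# trace operations
# ---------------------------------------------------------------------------

def normalize_trace(trace: TitrationTrace) -> TitrationTrace:
    """Divide the trace by its baseline-window mean (idempotent)."""
    t0, t1 = trace.baseline_window
    mask = (trace.time >= t0) & (trace.time <= t1)
    if mask.sum() < 2:
        raise DataError("baseline window must contain at least 2 samples")
    base = float(trace.intensity[mask].mean())
    if base <= 0:
        raise DataError(f"baseline mean {base:g} is not positive")
    return replace(trace, intensity=trace.intensity / base, normalized=True)


def saturation_from_trace(
    trace: TitrationTrace,
    settle_fraction: float = 0.5,
) -> SaturationCurve:
    """Per-addition plateaus versus cumulative dose, with a hyperbolic fit.

    The plateau for each addition is the mean intensity over the final
    ``settle_fraction`` of the interval between that addition and the next
    (or the end of the trace). Responses are measured relative to the
    baseline level (1.0 on a normalised trace).
    """
    if not 0 < settle_fraction <= 1:
        raise ConfigError("settle fraction must lie in (0, 1]")
    additions = [(t, d) for (t, _label, d) in trace.events if d and d > 0]
    if len(additions) < 2:
        raise DataError("need at least 2 addition events with doses")
    additions.sort()
    base = trace.window_mean(*trace.baseline_window)
    times = [t for t, _ in additions] + [float(trace.time[-1])]
    doses = np.cumsum([d for _, d in additions])
    plateaus = []
    for k in range(len(additions)):
        start, stop = times[k], times[k + 1]
        span = stop - start
        if span <= 0:
            raise DataError(
                f"settle windows overlap: additions at t={start:g} and t={stop:g}"
            )
        # right edge exclusive: the sample at the next addition time already
        # carries the next dose
        mask = (trace.time >= stop - settle_fraction * span) & (trace.time < stop)
        if k == len(additions) - 1:
            mask |= trace.time == stop           # trace end, no later addition
        if not mask.any():
            raise DataError(f"settle window before t={stop:g} contains no samples")
        plateaus.append(float(trace.intensity[mask].mean()))
    response = np.asarray(plateaus) - base
    fit = SaturationModel(doses, response).fit()
    return SaturationCurve(
        dose=doses,
        response=response,
        fractional=fit.fractional(response),
        half_saturation=fit.half_saturation,
        max_response=fit.max_response,
        identifiable=fit.identifiable,
    )


def anepps_ratio(
    wavelengths: np.ndarray,
    intensities: np.ndarray,
    ex_numerator: float = 420.0,
    ex_denominator: float = 520.0,
    window_nm: float = 2.0,
) -> float:
    """Dual-excitation ratio R = I(420 nm)/I(520 nm) from an excitation scan.

    Each intensity is read as the mean over ±``window_nm`` around the
    nominal excitation wavelength.
    """
    wl = np.asarray(wavelengths, dtype=float)
    inten = np.asarray(intensities, dtype=float)
    if wl.shape != inten.shape:
        raise DataError("wavelengths and intensities must align")

    def _read(centre: float) -> float:
        mask = np.abs(wl - centre) <= window_nm
        if not mask.any():
            raise DataError(f"scan does not cover {centre:g} nm")
        return float(inten[mask].mean())

    num = _read(ex_numerator)
    den = _read(ex_denominator)
    if den <= 0:
        raise DataError(f"denominator intensity at {ex_denominator:g} nm is not positive")
    return num / den


def tmrm_fractional_change(
    trace: TitrationTrace,
    post_event_window: tuple,
) -> float:
    """Fractional emission change after an addition: (post − base)/base.

    A quench (probe accumulation in energised mitochondria) gives a
    negative value; no response gives 0.
    """
    t0, t1 = post_event_window
    if not (trace.time[0] <= t0 < t1 <= trace.time[-1]):
        raise DataError("post-event window must lie inside the trace")
    base = trace.window_mean(*trace.baseline_window)
    if base <= 0:
        raise DataError("baseline mean is not positive")
    post = trace.window_mean(t0, t1)
    return (post - base) / base


def hydration_radius(
    d_ref: float,
    d_analyte: float,
    r_h_ref: float = DSS_HYDRATION_RADIUS,
) -> float:
    """Hydration radius from PFG-NMR diffusion against an internal reference.

    By the Stokes-Einstein relation R_h ∝ 1/D at fixed temperature and
    viscosity; referencing to an internal standard cancels viscosity, so
    R_h = R_h_ref × D_ref / D_analyte.
    """
    if d_ref <= 0 or d_analyte <= 0 or r_h_ref <= 0:
        raise ConfigError("diffusion coefficients and reference radius must be positive")
    return r_h_ref * d_ref / d_analyte


# ---------------------------------------------------------------------------
# hyperbolic saturation fit
# ---------------------------------------------------------------------------

class SaturationModel:
    """One-site hyperbolic dose-response model: R(d) = R_max·d/(K + d)."""

    def __init__(self, dose: np.ndarray, response: np.ndarray):
        self.dose = np.asarray(dose, dtype=float)
        self.response = np.asarray(response, dtype=float)
        if self.dose.shape != self.response.shape or self.dose.ndim != 1:
            raise DataError("dose and response must be matching 1-D arrays")
        if self.dose.size < 2:
            raise DataError("need at least 2 dose points")
        if np.any(np.diff(self.dose) < 0):
            raise DataError("doses must be non-decreasing")

    @staticmethod
    def _hyperbola(d: np.ndarray, rmax: float, k: float) -> np.ndarray:
        return rmax * d / (k + d)

    def fit(self) -> "SaturationResults":
        d, r = self.dose, self.response
        scale = float(np.max(np.abs(r)))
        if scale == 0 or not np.isfinite(scale):
            # flat curve: no dose dependence to fit
            return SaturationResults(
                model=self, max_response=0.0, half_saturation=float("nan"),
                max_response_se=float("nan"), half_saturation_se=float("nan"),
                identifiable=False,
            )
        sign = np.sign(r[np.argmax(np.abs(r))])
        p0 = (sign * scale, float(np.median(d)))
        try:
            popt, pcov = curve_fit(
                self._hyperbola, d, r, p0=p0, maxfev=10000,
                bounds=([-np.inf, 1e-12], [np.inf, np.inf]),
            )
        except RuntimeError as err:
            raise NumericalError(f"saturation fit failed: {err}") from err
        se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
        return SaturationResults(
            model=self,
            max_response=float(popt[0]),
            half_saturation=float(popt[1]),
            max_response_se=float(se[0]),
            half_saturation_se=float(se[1]),
            identifiable=True,
        )


@dataclass
class SaturationResults:
    """Fitted hyperbola parameters with standard errors."""

    model: SaturationModel
    max_response: float
    half_saturation: float
    max_response_se: float
    half_saturation_se: float
    identifiable: bool

    def fractional(self, response: np.ndarray) -> np.ndarray:
        if not self.identifiable or self.max_response == 0:
            return np.zeros_like(np.asarray(response, dtype=float))
        return np.asarray(response, dtype=float) / self.max_response

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": ["max_response", "half_saturation"],
                "value": [self.max_response, self.half_saturation],
                "se": [self.max_response_se, self.half_saturation_se],
            }
        )

    def summary(self) -> str:
        status = "ok" if self.identifiable else "UNIDENTIFIABLE (flat response)"
        return (
            f"Hyperbolic saturation fit [{status}]\n"
            f"  R_max           {self.max_response: .4g} ± {self.max_response_se:.3g}\n"
            f"  half-saturation {self.half_saturation: .4g} ± {self.half_saturation_se:.3g}"
        )
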