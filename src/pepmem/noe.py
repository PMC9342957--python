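"""Ensemble- and time-averaged NOE distance calculus and violation statistics.

NOE cross-peak intensities scale as r⁻⁶, so when a distance restraint is
applied collectively to an ensemble of N identical chains the physically
meaningful instantaneous distance is the r⁻⁶-weighted ensemble average

    r*(t) = [ (1/N) Σ_i r_i(t)⁻⁶ ]^(−1/6),

which is dominated by the shortest members of the ensemble. To avoid
over-weighting transient excursions the ensemble average is then smoothed
with an r⁻³-weighted forward time window

    r̄*(t) = [ (1/m) Σ_{j=t}^{t+τ/Δt} r*(j)⁻³ ]^(−1/3),

with window parameter τ (default 10 ps) and frame spacing Δt (default 1 ps);
m is the number of samples actually in the window (τ/Δt + 1 in the interior,
fewer in the truncated terminal windows). A restraint is counted as violated
at time t when r̄*(t) exceeds its experimental upper bound plus a buffer
tolerance (default 0.3 Å).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = [
    "NOERestraint",
    "DistanceSeries",
    "ViolationReport",
    "ensemble_avg_distance",
    "time_avg_distance",
    "violation_fraction",
    "filter_long_range",
    "compliance_report",
    "DEFAULT_TAU_PS",
    "DEFAULT_DT_PS",
    "DEFAULT_TOLERANCE",
]

DEFAULT_TAU_PS = 10.0
DEFAULT_DT_PS = 1.0
DEFAULT_TOLERANCE = 0.3

_CLASS_BY_SEP = {1: "sequential", 2: "i+2", 3: "i+3"}


@dataclass(frozen=True)
class NOERestraint:
    """An upper-bound distance restraint between two atoms.

    ``residue_i < residue_j`` is enforced; the restraint class (sequential,
    i+2, i+3) is derived from the residue separation.
    """

    residue_i: int
    atom_i: str
    residue_j: int
    atom_j: str
    upper_bound: float

    def __post_init__(self) -> None:
        if self.residue_i >= self.residue_j:
            raise DataError(
                f"restraint residues must satisfy i < j, got "
                f"{self.residue_i} >= {self.residue_j}"
            )
        if self.upper_bound <= 0:
            raise DataError("restraint upper bound must be positive")

    @property
    def separation(self) -> int:
        return self.residue_j - self.residue_i

    @property
    def restraint_class(self) -> str:
        return _CLASS_BY_SEP.get(self.separation, f"i+{self.separation}")

    @property
    def label(self) -> str:
        return (
            f"{self.residue_i}{self.atom_i}-{self.residue_j}{self.atom_j}"
        )


@dataclass
class DistanceSeries:
    """Per-chain, per-frame measured distances for one restraint."""

    restraint: NOERestraint
    distances: np.ndarray          # (n_chains, n_frames), Å
    dt: float = DEFAULT_DT_PS      # frame spacing, ps
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.distances = np.atleast_2d(np.asarray(self.distances, dtype=float))
        if self.dt <= 0:
            raise DataError("frame spacing dt must be positive")
        if self.distances.size == 0:
            raise DataError("distance series is empty")
        if np.any(self.distances <= 0):
            raise DataError("all distances must be positive")

    @property
    def n_chains(self) -> int:
        return self.distances.shape[0]

    @property
    def n_frames(self) -> int:
        return self.distances.shape[1]


@dataclass
class ViolationReport:
    """Per-restraint violation fractions and the compliance summary."""

    table: pd.DataFrame            # restraint label, class, upper bound, fraction
    tolerance: float
    tau: float
    dt: float
    compliance_threshold: float = 0.20

    @property
    def share_compliant(self) -> float:
        """Share of restraints violated less than the threshold fraction of time."""
        return float((self.table["violation_fraction"] < self.compliance_threshold).mean())


# ---------------------------------------------------------------------------
# averaging operators
# ---------------------------------------------------------------------------

def ensemble_avg_distance(series: DistanceSeries | np.ndarray) -> np.ndarray:
    """r⁻⁶-weighted ensemble average across chains, per frame (r*(t))."""
    d = series.distances if isinstance(series, DistanceSeries) else np.atleast_2d(
        np.asarray(series, dtype=float)
    )
    if d.size == 0 or d.shape[0] < 1:
        raise DataError("need at least one chain")
    if np.any(d <= 0):
        raise DataError("all distances must be positive")
    return np.power(np.mean(np.power(d, -6.0), axis=0), -1.0 / 6.0)


def time_avg_distance(
    rstar: np.ndarray,
    tau: float = DEFAULT_TAU_PS,
    dt: float = DEFAULT_DT_PS,
) -> np.ndarray:
    """r⁻³-weighted forward time window of the ensemble average (r̄*(t)).

    The window starting at frame t spans frames t .. t+τ/Δt inclusive
    (τ/Δt + 1 samples); windows that run past the end of the series are
    truncated and renormalised by the number of samples present. τ must be
    an integer multiple of Δt and at least Δt.
    """
    x = np.asarray(rstar, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise DataError("rstar must be a non-empty 1-D series")
    if np.any(x <= 0):
        raise DataError("all distances must be positive")
    if tau < dt:
        raise ConfigError(f"tau ({tau}) must be at least dt ({dt})")
    ratio = tau / dt
    w = int(round(ratio))
    if abs(ratio - w) > 1e-9:
        raise ConfigError(f"tau ({tau}) must be an integer multiple of dt ({dt})")
    n = x.size
    inv3 = np.power(x, -3.0)
    csum = np.concatenate([[0.0], np.cumsum(inv3)])
    start = np.arange(n)
    stop = np.minimum(start + w + 1, n)          # exclusive
    sums = csum[stop] - csum[start]
    m = (stop - start).astype(float)
    return np.power(sums / m, -1.0 / 3.0)


def violation_fraction(
    avg: np.ndarray,
    restraint: NOERestraint,
    tolerance: float = DEFAULT_TOLERANCE,
) -> float:
    """Fraction of windows in which r̄* exceeds the bound plus tolerance."""
    x = np.asarray(avg, dtype=float)
    if x.size == 0:
        raise DataError("averaged-distance series is empty")
    if tolerance < 0:
        raise ConfigError("tolerance must be non-negative")
    return float(np.mean(x > restraint.upper_bound + tolerance))


def filter_long_range(restraints: list[NOERestraint]) -> list[NOERestraint]:
    """Retain only i→i+2 and i→i+3 restraints, preserving order.

    Sequential restraints are dropped: imposing them would over-restrain
    local dynamics without adding long-range structural information.
    """
    return [r for r in restraints if r.separation in (2, 3)]


def compliance_report(
    series: list[DistanceSeries],
    tau: float = DEFAULT_TAU_PS,
    dt: float | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
    compliance_threshold: float = 0.20,
) -> ViolationReport:
    """Violation fractions for every restraint plus the compliance summary.

    The summary statistic is the share of restraints whose time- and
    ensemble-averaged distance exceeds its bound (plus tolerance) in fewer
    than ``compliance_threshold`` (default 20%) of windows.
    """
    if not series:
        raise DataError("no distance series supplied")
    dts = {s.dt for s in series}
    if len(dts) > 1:
        raise DataError(f"mixed frame spacings in input: {sorted(dts)}")
    if dt is None:
        dt = dts.pop()
    elif abs(dt - dts.pop()) > 1e-12:
        raise DataError("explicit dt disagrees with the series frame spacing")
    rows = []
    for s in series:
        rstar = ensemble_avg_distance(s)
        rbar = time_avg_distance(rstar, tau=tau, dt=dt)
        frac = violation_fraction(rbar, s.restraint, tolerance)
        rows.append(
            {
                "restraint": s.restraint.label,
                "class": s.restraint.restraint_class,
                "upper_bound": s.restraint.upper_bound,
                "violation_fraction": frac,
            }
        )
    table = pd.DataFrame(rows)
    return ViolationReport(
        table=table,
        tolerance=tolerance,
        tau=tau,
        dt=dt,
        compliance_threshold=compliance_threshold,
    )
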