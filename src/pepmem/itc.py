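"""Single-site ITC analysis for lipid-into-peptide titrations.

Peptide sits in the calorimeter cell and lipid vesicles are titrated in.
Because externally added peptide only reaches the outer leaflet of a
liposome, binding is expressed against the *effective* lipid concentration
[lipid]eff = outer_fraction × [lipid]total (outer_fraction defaults to 0.5,
the symmetric-leaflet assumption for ~100 nm LUVs).

The binding model is n independent, identical lipid sites per peptide
(Wiseman one-site). With S = n·[peptide] the total site concentration and
X the effective lipid concentration in the cell, the bound site fraction
follows the closed-form quadratic root

    θ = ½ [ 1 + X/S + K_D/S − sqrt( (1 + X/S + K_D/S)² − 4 X/S ) ],

the cumulative heat content is Q = θ·S·V0·ΔH, and per-injection heats are
successive differences with the standard perfusion-cell displacement
correction. :class:`WisemanModel`.fit() performs the nonlinear least-squares
regression and returns a :class:`WisemanResults` carrying {n, K_D, ΔH} with
standard errors, the derived ΔG/TΔS decomposition, and a summary table.

Thermodynamics: ΔG = RT·ln K_D (K_D in molar, so K_D = 1 M gives ΔG = 0),
TΔS = ΔH − ΔG, and the entropy/enthalpy balance is quantified by the
dimensionless ratio TΔS/|ΔH|. The per-peptide membrane footprint is the
stoichiometry times the composition-weighted lipid cross-sectional area.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import ConfigError, DataError, NumericalError

__all__ = [
    "ITCExperiment",
    "BindingParameters",
    "LipidComposition",
    "WisemanModel",
    "WisemanResults",
    "effective_lipid",
    "thermo_derive",
    "footprint",
    "one_site_heats",
    "R_KJ",
    "DEFAULT_TEMPERATURE_K",
    "ITC_COMPOSITION",
]

R_KJ = 8.31446261815324e-3        # gas constant, kJ/(mol K)
DEFAULT_TEMPERATURE_K = 298.15    # titrations performed at 25 °C


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ITCExperiment:
    """An injection-level calorimetry record for a lipid-into-peptide run.

    Heats are integrated, blank-corrected per-injection values in the unit
    named by ``heat_unit`` (µJ by default; µcal accepted and converted by
    the reader).
    """

    cell_conc_uM: float                 # peptide in the cell, µM
    syringe_conc_mM: float              # total lipid in the syringe, mM
    injection_volumes_ul: np.ndarray    # per-injection volume, µl
    heats: np.ndarray                   # per-injection integrated heat
    cell_volume_ul: float = 170.0
    temperature_K: float = DEFAULT_TEMPERATURE_K
    outer_fraction: float = 0.5
    heat_unit: str = "uJ"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.injection_volumes_ul = np.asarray(self.injection_volumes_ul, dtype=float)
        self.heats = np.asarray(self.heats, dtype=float)
        if self.cell_conc_uM <= 0 or self.syringe_conc_mM <= 0:
            raise DataError("concentrations must be positive")
        if self.cell_volume_ul <= 0 or self.temperature_K <= 0:
            raise DataError("cell volume and temperature must be positive")
        if not 0 < self.outer_fraction <= 1:
            raise DataError("outer-leaflet fraction must lie in (0, 1]")
        if np.any(self.injection_volumes_ul <= 0):
            raise DataError("injection volumes must be positive")
        if self.heats.shape != self.injection_volumes_ul.shape:
            raise DataError("heats and injection volumes must align")
        if np.any(~np.isfinite(self.heats)):
            raise DataError("heats must be finite")

    @property
    def n_injections(self) -> int:
        return self.injection_volumes_ul.size

    def molar_ratio(self) -> np.ndarray:
        """Per-injection [lipid]eff : [peptide] molar ratio in the cell."""
        x, p = _cell_concentrations(self)
        return x / p


@dataclass
class BindingParameters:
    """Fitted one-site parameters with the derived thermodynamic split."""

    n: float                       # lipids per bound peptide (effective lipid)
    kd_uM: float                   # dissociation constant, µM
    dh_kJ_mol: float               # binding enthalpy, kJ/mol
    temperature_K: float = DEFAULT_TEMPERATURE_K
    n_se: float = float("nan")
    kd_se_uM: float = float("nan")
    dh_se_kJ_mol: float = float("nan")
    cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n <= 0 or self.kd_uM <= 0:
            raise DataError("n and K_D must be positive")

    @property
    def dg_kJ_mol(self) -> float:
        return R_KJ * self.temperature_K * math.log(self.kd_uM * 1e-6)

    @property
    def tds_kJ_mol(self) -> float:
        return self.dh_kJ_mol - self.dg_kJ_mol

    @property
    def tds_over_abs_dh(self) -> float:
        if self.dh_kJ_mol == 0:
            return float("nan")
        return self.tds_kJ_mol / abs(self.dh_kJ_mol)


@dataclass
class LipidComposition:
    """Mole fractions and cross-sectional areas of the bilayer species."""

    fractions: dict                 # species -> mole fraction
    areas: dict                     # species -> cross-sectional area, Å²

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise DataError(f"mole fractions must sum to 1, got {total}")
        if set(self.fractions) - set(self.areas):
            raise DataError("every species needs a cross-sectional area")
        if any(a <= 0 for a in self.areas.values()):
            raise DataError("cross-sectional areas must be positive")

    @property
    def mean_area(self) -> float:
        """Composition-weighted mean lipid cross-sectional area, Å²."""
        return sum(f * self.areas[s] for s, f in self.fractions.items())


#: The 80:20 POPC:TOCL composition used for the liposome titrations,
#: with literature cross-sectional areas (POPC 70 Å², TOCL 129 Å²).
ITC_COMPOSITION = LipidComposition(
    fractions={"POPC": 0.80, "TOCL": 0.20},
    areas={"POPC": 70.0, "TOCL": 129.0},
)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def effective_lipid(total: float, outer_fraction: float = 0.5) -> float:
    """Lipid concentration accessible to externally added peptide.

    Only the outer leaflet of a closed liposome is reachable, so the
    effective concentration is ``total × outer_fraction``.
    """
    if not 0 < outer_fraction <= 1:
        raise ConfigError("outer-leaflet fraction must lie in (0, 1]")
    if total < 0:
        raise ConfigError("total lipid concentration must be non-negative")
    return total * outer_fraction


def thermo_derive(
    n: float,
    kd_uM: float,
    dh_kJ_mol: float,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> BindingParameters:
    """Derive ΔG, TΔS and TΔS/|ΔH| from fitted {n, K_D, ΔH}."""
    if temperature_K <= 0:
        raise ConfigError("temperature must be positive")
    params = BindingParameters(
        n=n, kd_uM=kd_uM, dh_kJ_mol=dh_kJ_mol, temperature_K=temperature_K
    )
    if dh_kJ_mol == 0:
        warnings.warn("ΔH = 0: TΔS/|ΔH| is undefined (reported as NaN)", stacklevel=2)
    return params


def footprint(n: float, composition: LipidComposition = ITC_COMPOSITION) -> float:
    """Per-peptide membrane binding footprint, Å².

    The stoichiometry ``n`` (lipids per bound peptide on the effective-lipid
    axis) times the composition-weighted mean lipid cross-sectional area.
    Reports round the result to the nearest Å².
    """
    if n <= 0:
        raise ConfigError("stoichiometry n must be positive")
    return n * composition.mean_area


# ---------------------------------------------------------------------------
# the one-site forward model
# ---------------------------------------------------------------------------

def _cell_concentrations(
    exp: ITCExperiment, displacement: str = "perfusion"
) -> tuple[np.ndarray, np.ndarray]:
    """Effective lipid and peptide concentrations in the cell after each injection.

    ``perfusion`` uses the standard overfill-cell ladder: injected volume
    displaces an equal volume of cell contents, giving the usual
    (1 − v/2V0)/(1 + v/2V0) dilution of the cell species and
    (v/V0)(1 − v/2V0) accumulation of the titrant. ``simple`` treats the
    cell as a growing volume with no expulsion.
    """
    v0 = exp.cell_volume_ul
    v = np.cumsum(exp.injection_volumes_ul)
    p0 = exp.cell_conc_uM * 1e-6                       # M
    x0 = effective_lipid(exp.syringe_conc_mM, exp.outer_fraction) * 1e-3  # M
    if displacement == "perfusion":
        pep = p0 * (1 - v / (2 * v0)) / (1 + v / (2 * v0))
        lip = x0 * (v / v0) * (1 - v / (2 * v0))
    elif displacement == "simple":
        pep = p0 * v0 / (v0 + v)
        lip = x0 * v / (v0 + v)
    else:
        raise ConfigError(f"unknown displacement model {displacement!r}")
    return lip, pep


def _bound_site_fraction(x: np.ndarray, s: np.ndarray, kd: float) -> np.ndarray:
    """Closed-form bound fraction of sites for independent identical sites."""
    a = 1.0 + x / s + kd / s
    disc = a * a - 4.0 * x / s
    return 0.5 * (a - np.sqrt(np.maximum(disc, 0.0)))


def one_site_heats(
    exp: ITCExperiment,
    n: float,
    kd_uM: float,
    dh_kJ_mol: float,
    displacement: str = "perfusion",
) -> np.ndarray:
    """Per-injection integrated heats (µJ) predicted by the one-site model."""
    if n <= 0 or kd_uM <= 0:
        raise ConfigError("n and K_D must be positive")
    lip, pep = _cell_concentrations(exp, displacement)
    kd = kd_uM * 1e-6
    theta = _bound_site_fraction(lip, n * pep, kd)
    v0_l = exp.cell_volume_ul * 1e-6                   # litres
    q = theta * n * pep * v0_l * dh_kJ_mol * 1e3       # J (dh in kJ/mol)
    q_prev = np.concatenate([[0.0], q[:-1]])
    if displacement == "perfusion":
        dv = exp.injection_volumes_ul / exp.cell_volume_ul
        dq = q - q_prev + dv * (q + q_prev) / 2.0
    else:
        dq = q - q_prev
    return dq * 1e6                                    # µJ


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class WisemanModel:
    """One-site (independent identical sites) model for an ITC isotherm.

    Parameters
    ----------
    experiment : ITCExperiment
        The injection record; heats must be in µJ (use the readers in
        :mod:`pepmem.io` to convert µcal inputs).
    displacement : {"perfusion", "simple"}
        Per-injection dilution model for the overfill cell.

    Examples
    --------
    >>> result = WisemanModel(experiment).fit()
    >>> result.params.n, result.params.kd_uM, result.params.dh_kJ_mol
    """

    def __init__(self, experiment: ITCExperiment, displacement: str = "perfusion"):
        if experiment.n_injections < 6:
            raise DataError(
                f"need at least 6 injections to fit, got {experiment.n_injections}"
            )
        if displacement not in ("perfusion", "simple"):
            raise ConfigError(f"unknown displacement model {displacement!r}")
        self.experiment = experiment
        self.displacement = displacement

    # -- starting values ---------------------------------------------------
    def _initial_guess(self) -> tuple[float, float, float]:
        exp = self.experiment
        ratio = exp.molar_ratio()
        q = exp.heats
        total = q.sum()
        if total == 0:
            raise NumericalError("all heats are zero; nothing to fit")
        cum = np.cumsum(q)
        # stoichiometry ~ molar ratio at the half-saturation point
        half_idx = int(np.argmin(np.abs(cum - 0.5 * total)))
        n0 = max(ratio[half_idx], 1e-3)
        p0_m = exp.cell_conc_uM * 1e-6
        v0_l = exp.cell_volume_ul * 1e-6
        dh0 = total * 1e-6 / (n0 * p0_m * v0_l) * 1e-3   # kJ/mol
        kd0 = max(n0 * exp.cell_conc_uM / 10.0, 1e-3)     # c ≈ 10 guess, µM
        return n0, kd0, dh0

    def predict(self, n: float, kd_uM: float, dh_kJ_mol: float) -> np.ndarray:
        return one_site_heats(
            self.experiment, n, kd_uM, dh_kJ_mol, self.displacement
        )

    def fit(self, start: tuple[float, float, float] | None = None) -> "WisemanResults":
        """Nonlinear least-squares fit; returns a :class:`WisemanResults`.

        ``n`` and ``K_D`` are optimised in log space to enforce positivity.
        A c-value (n·[peptide]/K_D) outside the reliable 1–1000 window is
        reported as a warning, not a failure.
        """
        exp = self.experiment
        if start is None:
            start = self._initial_guess()
        n0, kd0, dh0 = start
        x0 = np.array([math.log(n0), math.log(kd0), dh0])

        def residuals(theta: np.ndarray) -> np.ndarray:
            n, kd = math.exp(theta[0]), math.exp(theta[1])
            return self.predict(n, kd, theta[2]) - exp.heats

        sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
        if not sol.success:
            raise NumericalError(
                f"isotherm fit did not converge: {sol.message}; "
                f"last residual norm {np.linalg.norm(sol.fun):.3g}"
            )
        n_hat = math.exp(sol.x[0])
        kd_hat = math.exp(sol.x[1])
        dh_hat = sol.x[2]

        dof = max(exp.n_injections - 3, 1)
        s2 = float(sol.fun @ sol.fun) / dof
        jtj = sol.jac.T @ sol.jac
        try:
            cov_log = np.linalg.inv(jtj) * s2
        except np.linalg.LinAlgError:
            cov_log = np.full((3, 3), np.nan)
        # delta method back to natural scale for the log-parameters
        grad = np.diag([n_hat, kd_hat, 1.0])
        cov = grad @ cov_log @ grad
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))

        c_value = n_hat * exp.cell_conc_uM / kd_hat
        if not 1.0 <= c_value <= 1000.0:
            warnings.warn(
                f"c-value {c_value:.3g} outside the reliable 1-1000 window; "
                "fitted parameters may be poorly determined",
                stacklevel=2,
            )
        params = BindingParameters(
            n=n_hat,
            kd_uM=kd_hat,
            dh_kJ_mol=dh_hat,
            temperature_K=exp.temperature_K,
            n_se=float(se[0]),
            kd_se_uM=float(se[1]),
            dh_se_kJ_mol=float(se[2]),
            cov=cov,
        )
        return WisemanResults(
            model=self,
            params=params,
            fitted=self.predict(n_hat, kd_hat, dh_hat),
            residuals=exp.heats - self.predict(n_hat, kd_hat, dh_hat),
            c_value=c_value,
        )


@dataclass
class WisemanResults:
    """Fit results: parameters, uncertainties, diagnostics, summary."""

    model: WisemanModel
    params: BindingParameters
    fitted: np.ndarray
    residuals: np.ndarray
    c_value: float

    @property
    def rss(self) -> float:
        return float(self.residuals @ self.residuals)

    def to_frame(self) -> pd.DataFrame:
        p = self.params
        rows = [
            ("n (lipids/peptide)", p.n, p.n_se, ""),
            ("K_D", p.kd_uM, p.kd_se_uM, "µM"),
            ("ΔH", p.dh_kJ_mol, p.dh_se_kJ_mol, "kJ/mol"),
            ("ΔG", p.dg_kJ_mol, float("nan"), "kJ/mol"),
            ("TΔS", p.tds_kJ_mol, float("nan"), "kJ/mol"),
            ("TΔS/|ΔH|", p.tds_over_abs_dh, float("nan"), ""),
        ]
        return pd.DataFrame(rows, columns=["parameter", "value", "se", "unit"])

    def summary(self) -> str:
        exp = self.model.experiment
        lines = [
            "One-site ITC fit (lipid-into-peptide, effective lipid axis)",
            f"  injections: {exp.n_injections}, cell {exp.cell_conc_uM:g} µM peptide, "
            f"syringe {exp.syringe_conc_mM:g} mM total lipid "
            f"(outer fraction {exp.outer_fraction:g})",
            f"  T = {exp.temperature_K:.2f} K, c-value = {self.c_value:.3g}, "
            f"RSS = {self.rss:.4g} µJ²",
        ]
        for _, row in self.to_frame().iterrows():
            se = f" ± {row.se:.3g}" if np.isfinite(row.se) else ""
            unit = f" {row.unit}" if row.unit else ""
            lines.append(f"  {row.parameter:<20s} {row.value: .4g}{se}{unit}")
        return "\n".join(lines)
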