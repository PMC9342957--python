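"""Seeded synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here at desk
scale: a two-leaflet lamellar bilayer carrying surface-bound tetrapeptides,
per-restraint NOE distance ensembles with designed violation behaviour,
one-site ITC isotherms with Gaussian noise, and saturable fluorescence
titration traces. The generators are pure functions of their parameters and
a single integer seed (sub-streams are derived deterministically per
artifact), and each emitted object records its generation parameters in
``meta`` so the file writers can embed provenance headers.

The defaults emulate the study conditions of the membrane systems these
tools target: 150 lipids (75 per leaflet) at a 20:80 TOCL:POPC molar ratio,
20 surface-bound tetrapeptides (10 per leaflet), phosphate planes near
±19 Å, a composition-weighted area per lipid of 81.8 Å², 20-chain NOE
ensembles sampled at 1 ps, and 20 × 2.5 µl lipid injections into a 170 µl
cell holding 150 µM peptide.

There is no force field here: lipids are minimal pseudo-atom templates
(choline/phosphate/ester/terminal-acyl beads) and peptide dynamics are
independent Gaussian jitter around target depths — sufficient for the
geometric metrics downstream, and nothing more.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError
from .itc import ITCExperiment, one_site_heats
from .noe import NOERestraint, DistanceSeries, DEFAULT_TOLERANCE
from .titration import TitrationTrace
from .traj_analysis import Trajectory

__all__ = [
    "BilayerSpec",
    "SyntheticTruth",
    "NOEDesign",
    "make_bilayer_trajectory",
    "make_noe_series",
    "make_itc_isotherm",
    "make_titration_trace",
    "make_excitation_scan",
    "system_composition",
    "ELEMENT_RADII",
]

# van der Waals radii (Å) for the pseudo-atom elements
ELEMENT_RADII = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "P": 1.8, "S": 1.8}

# minimal pseudo-atom templates: (name, element, role, depth offset from the
# phosphate plane toward the bilayer midplane, Å)
LIPID_TEMPLATES = {
    "POPC": [
        ("CHL", "N", "headgroup", -1.5),
        ("P", "P", "headgroup", 0.0),
        ("EST", "C", "headgroup", 4.0),
        ("ACY", "C", "acyl", 14.0),
    ],
    "TOCL": [
        ("P1", "P", "headgroup", 0.0),
        ("P2", "P", "headgroup", 0.0),
        ("EST1", "C", "headgroup", 4.0),
        ("EST2", "C", "headgroup", 4.0),
        ("ACY1", "C", "acyl", 14.0),
        ("ACY2", "C", "acyl", 14.0),
    ],
}

# deterministic sub-stream ids so each artifact draws from its own stream
_STREAM_TRAJ = 101
_STREAM_NOE = 301
_STREAM_ITC = 501
_STREAM_TRACE = 701
_STREAM_SCAN = 901


@dataclass
class BilayerSpec:
    """Geometry and composition of the synthetic lamellar bilayer."""

    n_lipids_per_leaflet: int = 75
    mole_fractions: dict = field(
        default_factory=lambda: {"TOCL": 0.20, "POPC": 0.80}
    )
    leaflet_z_offset: float = 19.0      # phosphate plane |z|, Å
    box_xy: float | None = None         # Å; derived from area per lipid if None

    def __post_init__(self) -> None:
        if self.n_lipids_per_leaflet <= 0:
            raise ConfigError("n_lipids_per_leaflet must be positive")
        total = sum(self.mole_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"mole fractions must sum to 1, got {total}")
        if self.leaflet_z_offset <= 0:
            raise ConfigError("leaflet_z_offset must be positive")
        unknown = set(self.mole_fractions) - set(LIPID_TEMPLATES)
        if unknown:
            raise ConfigError(f"no pseudo-atom template for: {sorted(unknown)}")

    def species_counts(self) -> dict:
        """Integer lipid counts per leaflet by largest-remainder rounding."""
        n = self.n_lipids_per_leaflet
        raw = {s: f * n for s, f in self.mole_fractions.items()}
        counts = {s: int(math.floor(v)) for s, v in raw.items()}
        short = n - sum(counts.values())
        for s in sorted(raw, key=lambda s: raw[s] - counts[s], reverse=True)[:short]:
            counts[s] += 1
        return counts


@dataclass
class NOEDesign:
    """Designed behaviour of one restraint's synthetic distance series."""

    mean_distance: float = 3.5          # Å, value of non-violating segments
    violation_fraction: float = 0.0     # designed fraction of violating segments
    excursion: float = 0.5              # Å above bound+tolerance when violating
    segment_frames: int = 100           # frames per constant segment
    chain_jitter: float = 0.0           # per-chain Gaussian spread, Å

    def __post_init__(self) -> None:
        if not 0.0 <= self.violation_fraction <= 1.0:
            raise ConfigError("violation fraction must lie in [0, 1]")
        if self.mean_distance <= 0 or self.excursion <= 0 or self.segment_frames < 1:
            raise ConfigError("invalid NOE design parameters")
        if self.chain_jitter < 0:
            raise ConfigError("chain jitter must be non-negative")


@dataclass
class SyntheticTruth:
    """Ground-truth parameters shared by all generators, plus the seed."""

    seed: int = 0
    # bilayer / peptide geometry
    residue_depths: tuple = (13.0, 11.0, 12.0, 10.0)   # target Z^pos per residue, Å
    depth_jitter: float = 1.0                          # Å
    thickness: float | None = None                     # overrides 2×leaflet offset
    lipid_z_jitter: float = 0.4                        # Å
    lipid_xy_jitter: float = 0.5                       # Å
    peptide_xy_jitter: float = 1.0                     # Å
    area_per_lipid: float = 81.8                       # Å² (composition-weighted)
    apl_jitter: float = 0.5                            # Å² frame-to-frame
    # NOE
    noe_designs: tuple = ()                            # per-restraint NOEDesign
    noe_tolerance: float = DEFAULT_TOLERANCE
    # ITC (one-site truth)
    itc_n: float = 5.0
    itc_kd_uM: float = 30.0
    itc_dh_kJ_mol: float = -5.0
    itc_noise_sd_uJ: float = 0.0
    # titration traces
    ans_fold_change: float = 1.8        # saturated normalised plateau
    half_saturation_nmol: float = 20.0
    dose_per_addition_nmol: float = 10.0
    n_additions: int = 8
    trace_noise_sd: float = 0.0         # fraction of baseline intensity
    tmrm_quench: float = -0.35          # fractional change after addition
    anepps_r0: float = 0.9
    anepps_amplitude: float = 0.3       # saturable fractional drop of R

    def __post_init__(self) -> None:
        for name in (
            "depth_jitter", "lipid_z_jitter", "lipid_xy_jitter",
            "peptide_xy_jitter", "apl_jitter", "itc_noise_sd_uJ",
            "trace_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if len(self.residue_depths) != 4:
            raise ConfigError("residue_depths must list 4 per-residue targets")

    def public_params(self) -> dict:
        d = asdict(self)
        d["noe_designs"] = [asdict(x) if isinstance(x, NOEDesign) else x
                            for x in self.noe_designs]
        return d


# ---------------------------------------------------------------------------
# bilayer + peptide trajectory
# ---------------------------------------------------------------------------

def system_composition(spec: BilayerSpec, n_peptides: int) -> dict:
    """Headline composition ratios of the built system.

    Reports total lipids, lipids per peptide, and cardiolipin (TOCL) per
    peptide — e.g. 150 lipids with 20 peptides at 20% TOCL gives 7.5
    lipids/peptide and 1.5 CL/peptide.
    """
    counts = spec.species_counts()
    total = 2 * sum(counts.values())
    cl = 2 * counts.get("TOCL", 0)
    if n_peptides <= 0:
        raise ConfigError("n_peptides must be positive")
    return {
        "n_lipids": total,
        "n_peptides": n_peptides,
        "lipids_per_peptide": total / n_peptides,
        "cl_per_peptide": cl / n_peptides,
    }


def make_bilayer_trajectory(
    spec: BilayerSpec,
    n_peptides: int,
    truth: SyntheticTruth,
    n_frames: int,
) -> Trajectory:
    """A lamellar bilayer with surface-bound tetrapeptides, jittered per frame.

    Lipids sit on a per-leaflet lattice with their pseudo-atoms at
    template depths relative to the phosphate plane; peptide chains (4
    residues, one backbone and one Cβ bead each) are split evenly across
    leaflets with Cβ |z| fluctuating about the per-residue target depths.
    The per-frame box fluctuates about the target area per lipid.
    """
    if n_frames < 1:
        raise ConfigError("n_frames must be at least 1")
    if n_peptides % 2 != 0:
        raise ConfigError(
            f"n_peptides must be even for an equal split across leaflets, "
            f"got {n_peptides}"
        )
    rng = np.random.default_rng([truth.seed, _STREAM_TRAJ])
    offset = (
        truth.thickness / 2.0 if truth.thickness is not None
        else spec.leaflet_z_offset
    )
    n_leaf = spec.n_lipids_per_leaflet
    box_xy0 = (
        spec.box_xy if spec.box_xy is not None
        else math.sqrt(truth.area_per_lipid * n_leaf)
    )

    names, elements, resids, chains, roles = [], [], [], [], []
    base = []        # (A, 3) base coordinates
    counts = spec.species_counts()
    nx = math.ceil(math.sqrt(n_leaf))
    spacing = box_xy0 / nx
    resid = 0
    for sign in (+1.0, -1.0):
        site = 0
        for species in sorted(counts):
            for _ in range(counts[species]):
                resid += 1
                gx = (site % nx + 0.5) * spacing
                gy = (site // nx + 0.5) * spacing
                site += 1
                for (aname, elem, role, dz) in LIPID_TEMPLATES[species]:
                    names.append(aname)
                    elements.append(elem)
                    resids.append(resid)
                    chains.append("L")
                    roles.append(role)
                    base.append([gx, gy, sign * (offset - dz)])

    n_per_leaf = n_peptides // 2
    chain_no = 0
    for sign in (+1.0, -1.0):
        for _ in range(n_per_leaf):
            chain_no += 1
            label = f"P{chain_no:02d}"
            ox, oy = rng.uniform(0.0, box_xy0, size=2)
            for r, depth in enumerate(truth.residue_depths, start=1):
                x = (ox + 3.5 * (r - 1)) % box_xy0
                for aname, dz in (("CA", 1.0), ("CB", 0.0)):
                    names.append(aname)
                    elements.append("C")
                    resids.append(r)
                    chains.append(label)
                    roles.append("peptide")
                    base.append([x, oy, sign * (depth + dz)])

    base = np.asarray(base)
    n_atoms = base.shape[0]
    atoms = pd.DataFrame(
        {
            "name": names,
            "element": elements,
            "resid": resids,
            "chain": chains,
            "role": roles,
        }
    )
    atoms["radius"] = atoms["element"].map(ELEMENT_RADII)

    is_lipid = atoms["role"].isin(["headgroup", "acyl"]).to_numpy()
    is_cb = (atoms["name"] == "CB").to_numpy()
    is_pep = (atoms["role"] == "peptide").to_numpy()

    coords = np.broadcast_to(base, (n_frames, n_atoms, 3)).copy()
    if truth.lipid_z_jitter > 0:
        coords[:, is_lipid, 2] += rng.normal(
            0.0, truth.lipid_z_jitter, size=(n_frames, int(is_lipid.sum()))
        )
    if truth.lipid_xy_jitter > 0:
        coords[:, is_lipid, :2] += rng.normal(
            0.0, truth.lipid_xy_jitter, size=(n_frames, int(is_lipid.sum()), 2)
        )
    if truth.peptide_xy_jitter > 0:
        coords[:, is_pep, :2] += rng.normal(
            0.0, truth.peptide_xy_jitter, size=(n_frames, int(is_pep.sum()), 2)
        )
    if truth.depth_jitter > 0:
        # jitter the whole residue bead pair coherently in z
        coords[:, is_pep, 2] += np.repeat(
            rng.normal(0.0, truth.depth_jitter, size=(n_frames, int(is_pep.sum()) // 2)),
            2, axis=1,
        )

    apl = truth.area_per_lipid + (
        rng.normal(0.0, truth.apl_jitter, size=n_frames)
        if truth.apl_jitter > 0 else np.zeros(n_frames)
    )
    box_xy = np.sqrt(np.maximum(apl, 1.0) * n_leaf)
    box = np.column_stack([box_xy, box_xy, np.full(n_frames, 2 * offset + 40.0)])

    meta = {
        "generator": "make_bilayer_trajectory",
        "seed": truth.seed,
        "n_peptides": n_peptides,
        "n_frames": n_frames,
        "spec": {
            "n_lipids_per_leaflet": spec.n_lipids_per_leaflet,
            "mole_fractions": dict(spec.mole_fractions),
            "leaflet_z_offset": offset,
            "box_xy": box_xy0,
        },
        "truth": truth.public_params(),
    }
    return Trajectory(coords=coords, box=box, atoms=atoms, meta=meta)


# ---------------------------------------------------------------------------
# NOE distance ensembles
# ---------------------------------------------------------------------------

def make_noe_series(
    n_chains: int,
    n_frames: int,
    restraints: list[NOERestraint],
    truth: SyntheticTruth,
    dt: float = 1.0,
) -> list[DistanceSeries]:
    """Per-restraint (chains × frames) distance matrices with designed violations.

    Each restraint's series is piecewise constant over segments; a designed
    fraction of segments sits ``excursion`` Å above the upper bound plus
    tolerance and the rest at the design mean, so the downstream time- and
    ensemble-averaging recovers the designed violation fraction (up to
    window-boundary mixing and binomial sampling error). An empty restraint
    list yields an empty result.
    """
    if n_chains < 1:
        raise ConfigError("need at least one chain")
    if n_frames < 1:
        raise ConfigError("need at least one frame")
    out: list[DistanceSeries] = []
    designs = truth.noe_designs or (NOEDesign(),)
    for k, restraint in enumerate(restraints):
        design = designs[k % len(designs)]
        if design.mean_distance >= restraint.upper_bound + truth.noe_tolerance:
            raise ConfigError(
                f"design mean {design.mean_distance} Å for {restraint.label} is "
                "not below the bound plus tolerance; it would always violate"
            )
        rng = np.random.default_rng([truth.seed, _STREAM_NOE, k])
        n_seg = math.ceil(n_frames / design.segment_frames)
        p = design.violation_fraction
        if p == 0.0:
            flags = np.zeros(n_seg, dtype=bool)
        elif p == 1.0:
            flags = np.ones(n_seg, dtype=bool)
        else:
            flags = rng.random(n_seg) < p
        hi = restraint.upper_bound + truth.noe_tolerance + design.excursion
        seg_vals = np.where(flags, hi, design.mean_distance)
        frame_vals = np.repeat(seg_vals, design.segment_frames)[:n_frames]
        realized = float(np.mean(frame_vals > restraint.upper_bound + truth.noe_tolerance))
        d = np.broadcast_to(frame_vals, (n_chains, n_frames)).copy()
        if design.chain_jitter > 0:
            d = d + rng.normal(0.0, design.chain_jitter, size=d.shape)
            d = np.maximum(d, 0.5)
        out.append(
            DistanceSeries(
                restraint=restraint,
                distances=d,
                dt=dt,
                meta={
                    "generator": "make_noe_series",
                    "seed": truth.seed,
                    "design": asdict(design),
                    "designed_violation_fraction": p,
                    "realized_violation_fraction": realized,
                },
            )
        )
    return out


# ---------------------------------------------------------------------------
# ITC isotherms
# ---------------------------------------------------------------------------

def make_itc_isotherm(
    truth: SyntheticTruth,
    injection_volumes_ul: np.ndarray | None = None,
    cell_conc_uM: float = 150.0,
    syringe_conc_mM: float = 8.0,
    cell_volume_ul: float = 170.0,
    outer_fraction: float = 0.5,
    noise_sd_uJ: float | None = None,
) -> ITCExperiment:
    """A one-site lipid-into-peptide isotherm with Gaussian heat noise.

    Defaults reproduce the standard protocol: 20 injections of 2.5 µl of
    8 mM total lipid into a 170 µl cell holding 150 µM peptide. The
    ground-truth {n, K_D, ΔH} is taken from ``truth`` and recorded in
    ``meta`` alongside the seed.
    """
    if injection_volumes_ul is None:
        injection_volumes_ul = np.full(20, 2.5)
    if noise_sd_uJ is None:
        noise_sd_uJ = truth.itc_noise_sd_uJ
    exp = ITCExperiment(
        cell_conc_uM=cell_conc_uM,
        syringe_conc_mM=syringe_conc_mM,
        injection_volumes_ul=injection_volumes_ul,
        heats=np.zeros(len(injection_volumes_ul)),
        cell_volume_ul=cell_volume_ul,
        outer_fraction=outer_fraction,
    )
    q = one_site_heats(exp, truth.itc_n, truth.itc_kd_uM, truth.itc_dh_kJ_mol)
    if noise_sd_uJ > 0:
        rng = np.random.default_rng([truth.seed, _STREAM_ITC])
        q = q + rng.normal(0.0, noise_sd_uJ, size=q.shape)
    exp.heats = q
    exp.meta = {
        "generator": "make_itc_isotherm",
        "seed": truth.seed,
        "truth": {
            "n": truth.itc_n,
            "kd_uM": truth.itc_kd_uM,
            "dh_kJ_mol": truth.itc_dh_kJ_mol,
        },
        "noise_sd_uJ": noise_sd_uJ,
    }
    return exp


# ---------------------------------------------------------------------------
# fluorescence traces and scans
# ---------------------------------------------------------------------------

TRACE_KINDS = ("surface-probe", "dipole-scan", "transmembrane")


def _saturable(dose: float, amplitude: float, k: float) -> float:
    return amplitude * dose / (k + dose)


def make_titration_trace(kind: str, truth: SyntheticTruth) -> TitrationTrace:
    """A synthetic fluorescence time course with stepwise additions.

    ``surface-probe``: an ANS-style time course — membranes added early, a
    60–120 s baseline window, then sequential peptide additions (default
    10 nmol each, 30 s apart) producing saturable plateaus with truth
    half-saturation dose.

    ``dipole-scan``: a time course of the ANEPPS excitation ratio R under
    the same addition schedule, decreasing saturably from its baseline.

    ``transmembrane``: a TMRM quench-mode course — baseline 40–55 s,
    mitochondria added at 60 s quenching the probe by the truth fractional
    change, valinomycin at 180 s restoring it.
    """
    if kind not in TRACE_KINDS:
        raise ConfigError(f"unknown trace kind {kind!r}; expected one of {TRACE_KINDS}")
    rng = np.random.default_rng([truth.seed, _STREAM_TRACE, TRACE_KINDS.index(kind)])

    if kind in ("surface-probe", "dipole-scan"):
        t = np.arange(0.0, 381.0, 1.0)
        events = [(10.0, "LUV", 0.0)]
        add_times = 140.0 + 30.0 * np.arange(truth.n_additions)
        if add_times[-1] >= t[-1]:
            raise ConfigError("too many additions for the trace duration")
        dose = np.zeros_like(t)
        for at in add_times:
            events.append((float(at), "peptide", truth.dose_per_addition_nmol))
            dose[t >= at] += truth.dose_per_addition_nmol
        if kind == "surface-probe":
            f0 = 200.0
            amp = truth.ans_fold_change - 1.0
            resp = np.array(
                [_saturable(d, amp, truth.half_saturation_nmol) for d in dose]
            )
            intensity = f0 * (1.0 + resp)
        else:
            f0 = truth.anepps_r0
            resp = np.array(
                [_saturable(d, truth.anepps_amplitude, truth.half_saturation_nmol)
                 for d in dose]
            )
            intensity = f0 * (1.0 - resp)
        baseline = (60.0, 120.0)
    else:
        t = np.arange(0.0, 241.0, 1.0)
        f0 = 500.0
        intensity = np.full_like(t, f0)
        intensity[t >= 60.0] = f0 * (1.0 + truth.tmrm_quench)
        intensity[t >= 180.0] = f0
        events = [(60.0, "Mito", 0.0), (180.0, "Val", 0.0)]
        baseline = (40.0, 55.0)

    if truth.trace_noise_sd > 0:
        intensity = intensity + rng.normal(
            0.0, truth.trace_noise_sd * f0, size=intensity.shape
        )

    return TitrationTrace(
        time=t,
        intensity=intensity,
        events=events,
        baseline_window=baseline,
        meta={
            "generator": "make_titration_trace",
            "kind": kind,
            "seed": truth.seed,
            "truth": {
                "half_saturation_nmol": truth.half_saturation_nmol,
                "ans_fold_change": truth.ans_fold_change,
                "tmrm_quench": truth.tmrm_quench,
                "anepps_r0": truth.anepps_r0,
                "anepps_amplitude": truth.anepps_amplitude,
            },
        },
    )


def make_excitation_scan(
    r_truth: float,
    truth: SyntheticTruth,
    index: int = 0,
    noise_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """A two-peak excitation scan whose 420/520 nm ratio equals ``r_truth``.

    Gaussian peaks at 420 and 520 nm (σ = 30 nm) with heights in the ratio
    ``r_truth``; returns (wavelengths, intensities) over 380–580 nm at 1 nm.
    """
    if r_truth <= 0:
        raise ConfigError("the excitation ratio must be positive")
    wl = np.arange(380.0, 581.0, 1.0)
    h520 = 400.0
    h420 = r_truth * h520
    inten = (
        h420 * np.exp(-0.5 * ((wl - 420.0) / 30.0) ** 2)
        + h520 * np.exp(-0.5 * ((wl - 520.0) / 30.0) ** 2)
    )
    if noise_sd > 0:
        rng = np.random.default_rng([truth.seed, _STREAM_SCAN, index])
        inten = inten + rng.normal(0.0, noise_sd * h520, size=inten.shape)
    return wl, inten
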