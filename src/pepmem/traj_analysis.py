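"""Membrane-trajectory metrics for surface-bound peptide simulations.

Operates on :class:`Trajectory` objects — labelled pseudo-atom or all-atom
coordinate stacks with per-frame orthorhombic boxes — and computes the
standard observables for a peptide/bilayer system:

* per-residue membrane insertion depth relative to the bilayer centre of
  mass (with the lower leaflet folded onto the upper so depths are positive),
* bilayer (phosphate-to-phosphate) thickness,
* cross-sectional area per lipid from the lateral box dimensions,
* ensemble RMSD/R_g statistics with optimal least-squares superposition,
* fraction of simulation time spent within an RMSD threshold of a reference
  conformer,
* Shrake-Rupley solvent-accessible surface area partitioned by role,
* lateral (x-y plane) radial distribution functions with minimum-image
  periodicity,
* block-averaged standard errors for correlated time series.

All lengths are in Å, areas in Å².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

ROLES = ("headgroup", "acyl", "peptide", "solvent")
LIPID_ROLES = ("headgroup", "acyl")

__all__ = [
    "Trajectory",
    "DepthProfile",
    "EnsembleStats",
    "SASAReport",
    "RDFProfile",
    "BlockAverageResult",
    "insertion_depth",
    "bilayer_thickness",
    "area_per_lipid",
    "ensemble_stats",
    "fraction_below_rmsd",
    "sasa",
    "shrake_rupley",
    "lateral_rdf",
    "block_average",
    "superpose_rmsd",
    "radius_of_gyration",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Frames of labelled 3-D coordinates with per-frame orthorhombic box.

    Parameters
    ----------
    coords : ndarray, shape (n_frames, n_atoms, 3)
        Cartesian coordinates in Å.
    box : ndarray, shape (n_frames, 3)
        Orthorhombic box edges (Lx, Ly, Lz) in Å for every frame.
    atoms : pandas.DataFrame
        One row per atom with columns ``name``, ``element``, ``resid``,
        ``chain``, ``role`` and ``radius`` (van der Waals radius, Å).
        ``role`` must be one of ``headgroup``, ``acyl``, ``peptide``,
        ``solvent``.
    meta : dict
        Free-form provenance (generator parameters, seed, source path).
    """

    coords: np.ndarray
    box: np.ndarray
    atoms: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise DataError("coords must have shape (n_frames, n_atoms, 3)")
        if self.box.shape != (self.coords.shape[0], 3):
            raise DataError(
                f"box shape {self.box.shape} does not match "
                f"({self.coords.shape[0]}, 3)"
            )
        if np.any(self.box <= 0):
            raise DataError("all box edges must be positive")
        if len(self.atoms) != self.coords.shape[1]:
            raise DataError("atom table length does not match coordinate array")
        bad = set(self.atoms["role"]) - set(ROLES)
        if bad:
            raise DataError(f"unknown atom roles: {sorted(bad)}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def role_indices(self, role: str) -> np.ndarray:
        return np.flatnonzero((self.atoms["role"] == role).to_numpy())

    def lipid_indices(self) -> np.ndarray:
        mask = self.atoms["role"].isin(LIPID_ROLES).to_numpy()
        return np.flatnonzero(mask)

    def select(self, pattern: str) -> np.ndarray:
        """Resolve a ``chain/resid/name`` selection pattern to atom indices.

        Each of the three fields may be ``*`` (wildcard), a literal value,
        or for ``name`` a prefix ending in ``*`` (e.g. ``P*``).
        """
        parts = pattern.split("/")
        if len(parts) != 3:
            raise ConfigError(
                f"selection {pattern!r} must be 'chain/resid/name'"
            )
        chain_s, resid_s, name_s = parts
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain_s != "*":
            mask &= (self.atoms["chain"].astype(str) == chain_s).to_numpy()
        if resid_s != "*":
            mask &= (self.atoms["resid"] == int(resid_s)).to_numpy()
        if name_s != "*":
            names = self.atoms["name"].astype(str)
            if name_s.endswith("*"):
                mask &= names.str.startswith(name_s[:-1]).to_numpy()
            else:
                mask &= (names == name_s).to_numpy()
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise DataError(f"selection {pattern!r} matched no atoms")
        return idx

    def bilayer_com_z(self) -> np.ndarray:
        """Per-frame z of the bilayer centre of mass (lipid atoms only)."""
        lip = self.lipid_indices()
        if lip.size == 0:
            raise DataError("trajectory contains no lipid atoms to define the bilayer COM")
        return self.coords[:, lip, 2].mean(axis=1)


@dataclass
class DepthProfile:
    """Per-residue insertion depths (Z^pos) and reference lipid planes."""

    residue_ids: np.ndarray          # residue position within the chain
    mean: np.ndarray                 # per-residue mean depth over chains, Å
    sd: np.ndarray                   # per-residue SD over chains, Å
    per_chain: pd.DataFrame          # rows: chain, columns: residue position
    phosphate_plane: float           # mean |z_P - z_COM|, Å
    ester_plane: float               # mean |z_ester - z_COM|, Å

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"residue": self.residue_ids, "mean_depth": self.mean, "sd": self.sd}
        )


@dataclass
class EnsembleStats:
    """RMSD-to-average and radius of gyration for a conformer ensemble."""

    rmsd: np.ndarray        # per-conformer RMSD to the ensemble average, Å
    rg: np.ndarray          # per-conformer radius of gyration, Å
    average: np.ndarray     # (n_atoms, 3) ensemble-average structure

    @property
    def rmsd_mean(self) -> float:
        return float(self.rmsd.mean())

    @property
    def rmsd_sd(self) -> float:
        return float(self.rmsd.std(ddof=1)) if len(self.rmsd) > 1 else 0.0

    @property
    def rg_mean(self) -> float:
        return float(self.rg.mean())

    @property
    def rg_sd(self) -> float:
        return float(self.rg.std(ddof=1)) if len(self.rg) > 1 else 0.0


@dataclass
class SASAReport:
    """Solvent-accessible surface area of the solute, partitioned by role."""

    per_frame: pd.DataFrame       # columns: one per group plus "total", Å²
    mean: dict                    # group -> block-averaged mean, Å²
    se: dict                      # group -> block-averaged SE, Å²
    probe_radius: float
    n_sphere_points: int


@dataclass
class RDFProfile:
    """Lateral (x-y) radial distribution function."""

    r: np.ndarray            # bin centres, Å
    g: np.ndarray            # g(r)
    counts: np.ndarray       # raw pair counts per bin (all frames)
    n_reference: int
    n_target: int


@dataclass
class BlockAverageResult:
    """Standard error of the mean versus block size, with plateau choice."""

    mean: float
    block_sizes: np.ndarray
    se_curve: np.ndarray
    chosen_block: int
    se: float
    converged: bool


# ---------------------------------------------------------------------------
# superposition and ensemble statistics
# ---------------------------------------------------------------------------

def _kabsch_rotations(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rotations aligning each centred ``mobile[i]`` onto ``target``.

    mobile: (n, A, 3) centred; target: (A, 3) centred. Returns (n, 3, 3).
    Degenerate (reflection) branches are resolved to det(+1).
    """
    h = np.einsum("nai,aj->nij", mobile, target)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(np.einsum("nij,njk->nik", u, vt)))
    u[:, :, -1] *= d[:, None]
    return np.einsum("nij,njk->nik", u, vt).transpose(0, 2, 1)


def superpose_rmsd(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Minimum RMSD of conformers onto a reference after optimal rigid fit.

    Parameters
    ----------
    mobile : ndarray (n, A, 3) or (A, 3)
    reference : ndarray (A, 3)

    Returns
    -------
    ndarray (n,) — least-squares RMSD after translation + rotation.
    """
    mob = np.asarray(mobile, dtype=float)
    single = mob.ndim == 2
    if single:
        mob = mob[None]
    ref = np.asarray(reference, dtype=float)
    if mob.shape[1:] != ref.shape:
        raise DataError(
            f"conformer shape {mob.shape[1:]} does not match reference {ref.shape}"
        )
    refc = ref - ref.mean(axis=0)
    mobc = mob - mob.mean(axis=1, keepdims=True)
    rot = _kabsch_rotations(mobc, refc)
    aligned = np.einsum("nij,naj->nai", rot, mobc)
    rmsd = np.sqrt(((aligned - refc) ** 2).sum(axis=2).mean(axis=1))
    return rmsd[0] if single else rmsd


def radius_of_gyration(coords: np.ndarray) -> np.ndarray:
    """Unit-weight radius of gyration about the centre of mass.

    Accepts (A, 3) or (n, A, 3); returns scalar or (n,).
    """
    c = np.asarray(coords, dtype=float)
    single = c.ndim == 2
    if single:
        c = c[None]
    if c.shape[1] < 2:
        raise DataError("radius of gyration requires at least 2 atoms")
    dev = c - c.mean(axis=1, keepdims=True)
    rg = np.sqrt((dev ** 2).sum(axis=2).mean(axis=1))
    return float(rg[0]) if single else rg


def ensemble_stats(conformers: np.ndarray, max_iter: int = 5) -> EnsembleStats:
    """RMSD to the ensemble-average structure and per-conformer R_g.

    The average structure is computed self-consistently: conformers are
    superposed onto the current average and the average recomputed until it
    stabilises (a few iterations suffice for compact ensembles).
    """
    conf = np.asarray(conformers, dtype=float)
    if conf.ndim != 3:
        raise DataError("conformers must be an (n, n_atoms, 3) array")
    if conf.shape[0] < 2:
        raise DataError("ensemble statistics need at least 2 conformers")
    centred = conf - conf.mean(axis=1, keepdims=True)
    avg = centred[0]
    for _ in range(max_iter):
        rot = _kabsch_rotations(centred, avg)
        aligned = np.einsum("nij,naj->nai", rot, centred)
        new_avg = aligned.mean(axis=0)
        if np.allclose(new_avg, avg, atol=1e-10):
            avg = new_avg
            break
        avg = new_avg
    rmsd = superpose_rmsd(centred, avg)
    rg = radius_of_gyration(conf)
    return EnsembleStats(rmsd=rmsd, rg=np.atleast_1d(rg), average=avg)


def _peptide_chain_atoms(traj: Trajectory) -> dict:
    """Map chain id -> atom indices (sorted by resid then name) for peptides."""
    pep = traj.atoms[traj.atoms["role"] == "peptide"]
    chains = {}
    for chain, grp in pep.groupby("chain", sort=True):
        chains[chain] = grp.sort_values(["resid", "name"]).index.to_numpy()
    if not chains:
        raise DataError("trajectory contains no peptide atoms")
    return chains


def fraction_below_rmsd(
    traj: Trajectory,
    reference: np.ndarray,
    threshold: float = 3.0,
) -> pd.Series:
    """Fraction of frames each peptide chain spends below an RMSD threshold.

    Each chain's coordinates are optimally superposed frame-by-frame onto
    ``reference`` (same atom count and order as one chain, typically the
    heavy atoms of the lead NMR structure). The default threshold of 3 Å
    follows the convention of counting "native-like" conformations.

    Returns a Series indexed by chain id, plus the ensemble mean under the
    index ``"ensemble"``.
    """
    ref = np.asarray(reference, dtype=float)
    chains = _peptide_chain_atoms(traj)
    fractions = {}
    for chain, idx in chains.items():
        if idx.size != ref.shape[0]:
            raise DataError(
                f"reference with {ref.shape[0]} atoms does not map onto chain "
                f"{chain!r} with {idx.size} atoms"
            )
        rmsd = superpose_rmsd(traj.coords[:, idx, :], ref)
        fractions[chain] = float(np.mean(rmsd < threshold))
    out = pd.Series(fractions, name="fraction_below_rmsd")
    out.loc["ensemble"] = out.mean()
    return out


# ---------------------------------------------------------------------------
# membrane geometry
# ---------------------------------------------------------------------------

def _phosphate_indices(traj: Trajectory) -> np.ndarray:
    names = traj.atoms["name"].astype(str)
    mask = (traj.atoms["role"] == "headgroup").to_numpy() & names.str.startswith("P").to_numpy()
    # exclude non-phosphorus headgroup atoms that merely start with P
    mask &= (traj.atoms["element"] == "P").to_numpy()
    return np.flatnonzero(mask)


def _ester_indices(traj: Trajectory) -> np.ndarray:
    names = traj.atoms["name"].astype(str)
    return np.flatnonzero(names.str.startswith("EST").to_numpy())


def insertion_depth(traj: Trajectory, atom_name: str = "CB") -> DepthProfile:
    """Per-residue membrane insertion depth of peptide side chains (Z^pos).

    For each peptide chain and residue, the depth is the average over frames
    of the unsigned z-distance between the named side-chain atom (Cβ by
    default) and the bilayer centre of mass. Chains bound to the lower
    leaflet are folded onto the upper by the absolute value, so all depths
    are positive. The phosphate and ester-carbon planes are reported with
    the same convention for reference.
    """
    names = traj.atoms["name"].astype(str)
    sel = (
        (traj.atoms["role"] == "peptide").to_numpy()
        & (names == atom_name).to_numpy()
    )
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        raise DataError(f"no peptide atoms named {atom_name!r} in trajectory")
    com_z = traj.bilayer_com_z()                      # (F,)
    depth = np.abs(traj.coords[:, idx, 2] - com_z[:, None]).mean(axis=0)

    table = traj.atoms.iloc[idx][["chain", "resid"]].copy()
    table["depth"] = depth
    per_chain = table.pivot_table(index="chain", columns="resid", values="depth")
    residue_ids = per_chain.columns.to_numpy()
    mean = per_chain.mean(axis=0).to_numpy()
    sd = per_chain.std(axis=0, ddof=1).fillna(0.0).to_numpy()

    p_idx = _phosphate_indices(traj)
    e_idx = _ester_indices(traj)
    p_plane = (
        float(np.abs(traj.coords[:, p_idx, 2] - com_z[:, None]).mean())
        if p_idx.size else float("nan")
    )
    e_plane = (
        float(np.abs(traj.coords[:, e_idx, 2] - com_z[:, None]).mean())
        if e_idx.size else float("nan")
    )
    return DepthProfile(
        residue_ids=residue_ids,
        mean=mean,
        sd=sd,
        per_chain=per_chain,
        phosphate_plane=p_plane,
        ester_plane=e_plane,
    )


def bilayer_thickness(traj: Trajectory) -> tuple[np.ndarray, BlockAverageResult]:
    """Phosphate-plane separation per frame, plus block-averaged mean ± SE.

    Leaflets are assigned once, at frame 0, by the sign of each phosphate's
    z relative to the bilayer COM (no flip-flop tracking). The thickness is
    the distance between the mean phosphate z of the two leaflets.
    """
    p_idx = _phosphate_indices(traj)
    if p_idx.size == 0:
        raise DataError("no phosphate atoms found; cannot measure thickness")
    com0 = traj.bilayer_com_z()[0]
    z0 = traj.coords[0, p_idx, 2]
    upper = p_idx[z0 >= com0]
    lower = p_idx[z0 < com0]
    if upper.size == 0 or lower.size == 0:
        raise DataError("one leaflet has no phosphate atoms")
    series = (
        traj.coords[:, upper, 2].mean(axis=1)
        - traj.coords[:, lower, 2].mean(axis=1)
    )
    stats = _series_stats(series)
    return series, stats


def area_per_lipid(
    traj: Trajectory, lipids_per_leaflet: int
) -> tuple[np.ndarray, BlockAverageResult]:
    """Lateral box area divided by the lipid count of one leaflet, per frame."""
    if lipids_per_leaflet <= 0:
        raise ConfigError("lipids_per_leaflet must be positive")
    series = traj.box[:, 0] * traj.box[:, 1] / lipids_per_leaflet
    return series, _series_stats(series)


def _series_stats(series: np.ndarray) -> BlockAverageResult:
    """Block-averaged mean ± SE; degrades gracefully for very short series."""
    series = np.asarray(series, dtype=float)
    if series.size >= 8:
        return block_average(series)
    mean = float(series.mean())
    se = float(series.std(ddof=1) / np.sqrt(series.size)) if series.size > 1 else 0.0
    return BlockAverageResult(
        mean=mean,
        block_sizes=np.array([1]),
        se_curve=np.array([se]),
        chosen_block=1,
        se=se,
        converged=False,
    )


# ---------------------------------------------------------------------------
# solvent-accessible surface area
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area by the Shrake-Rupley method.

    Each atom's accessible sphere (vdW radius + probe) is sampled with a
    fixed quasi-uniform point set; points falling inside any neighbour's
    accessible sphere are occluded. The per-atom area is the accessible
    fraction times the full sphere area. Accuracy is set by ``n_points``
    (the dot density).

    Parameters
    ----------
    coords : (A, 3) array, Å
    radii : (A,) array of van der Waals radii, Å
    probe_radius : probe sphere radius, Å (water ≈ 1.4)
    n_points : number of test points per atom

    Returns
    -------
    (A,) array of per-atom SASA in Å².
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if probe_radius < 0:
        raise ConfigError("probe radius must be non-negative")
    if coords.ndim != 2 or coords.shape[0] != radii.shape[0]:
        raise DataError("coords and radii must agree on the atom count")
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        bad = int(np.flatnonzero(~np.isfinite(radii) | (radii <= 0))[0])
        raise DataError(f"atom {bad} has no valid radius")
    n_atoms = coords.shape[0]
    big = radii + probe_radius
    unit = _sphere_points(n_points)
    areas = np.empty(n_atoms)
    # pairwise distances once, to prefilter neighbours
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    for i in range(n_atoms):
        neigh = np.flatnonzero((dist[i] < big[i] + big) & (np.arange(n_atoms) != i))
        full = 4.0 * np.pi * big[i] ** 2
        if neigh.size == 0:
            areas[i] = full
            continue
        pts = coords[i] + big[i] * unit                       # (P, 3)
        d2 = ((pts[:, None, :] - coords[neigh][None, :, :]) ** 2).sum(axis=2)
        buried = (d2 < (big[neigh] ** 2)[None, :]).any(axis=1)
        areas[i] = full * (1.0 - buried.mean())
    return areas


def sasa(
    traj: Trajectory,
    probe_radius: float = 1.4,
    n_points: int = 960,
    stride: int = 1,
    groups: tuple = ("headgroup", "acyl", "peptide"),
) -> SASAReport:
    """Component SASA of the solute (lipids + peptides) over a trajectory.

    Solvent atoms are excluded from the solute set entirely (they neither
    contribute area nor occlude it). Each solute atom's exposed area counts
    toward its own role group, so the group values sum to the total.
    """
    solute = np.flatnonzero((traj.atoms["role"] != "solvent").to_numpy())
    if solute.size == 0:
        raise DataError("no solute atoms for SASA")
    radii = traj.atoms["radius"].to_numpy()[solute]
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        bad = solute[int(np.flatnonzero(~np.isfinite(radii) | (radii <= 0))[0])]
        name = traj.atoms.iloc[bad]["name"]
        raise DataError(f"atom {bad} ({name}) is missing a van der Waals radius")
    roles = traj.atoms["role"].to_numpy()[solute]
    frames = range(0, traj.n_frames, stride)
    records = []
    for f in frames:
        per_atom = shrake_rupley(
            traj.coords[f, solute, :], radii, probe_radius, n_points
        )
        row = {g: float(per_atom[roles == g].sum()) for g in groups}
        row["total"] = float(per_atom.sum())
        records.append(row)
    per_frame = pd.DataFrame(records)
    mean, se = {}, {}
    for col in per_frame.columns:
        stats = _series_stats(per_frame[col].to_numpy())
        mean[col] = stats.mean
        se[col] = stats.se
    return SASAReport(
        per_frame=per_frame,
        mean=mean,
        se=se,
        probe_radius=probe_radius,
        n_sphere_points=n_points,
    )


# ---------------------------------------------------------------------------
# lateral radial distribution function
# ---------------------------------------------------------------------------

def lateral_rdf(
    traj: Trajectory,
    reference: np.ndarray | str,
    target: np.ndarray | str,
    bin_edges: np.ndarray,
) -> RDFProfile:
    """Radial distribution function in the membrane (x-y) plane.

    Pair distances are computed from x-y separations only, with the minimum
    image convention applied in x and y. Counts in each annulus are
    normalised by the ideal-gas expectation (annulus area × mean target
    surface density), so a structureless fluid gives g(r) = 1. When the
    reference and target selections share atoms, self-pairs are excluded
    and the target density is corrected accordingly.
    """
    ref_idx = traj.select(reference) if isinstance(reference, str) else np.asarray(reference)
    tgt_idx = traj.select(target) if isinstance(target, str) else np.asarray(target)
    if ref_idx.size == 0 or tgt_idx.size == 0:
        raise DataError("reference and target selections must be non-empty")
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ConfigError("bin edges must be strictly increasing")
    shared = np.isin(ref_idx, tgt_idx)
    counts = np.zeros(edges.size - 1)
    expected = np.zeros(edges.size - 1)
    annulus = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    for f in range(traj.n_frames):
        lx, ly = traj.box[f, 0], traj.box[f, 1]
        rxy = traj.coords[f, ref_idx, :2]
        txy = traj.coords[f, tgt_idx, :2]
        d = txy[None, :, :] - rxy[:, None, :]
        d[..., 0] -= lx * np.round(d[..., 0] / lx)
        d[..., 1] -= ly * np.round(d[..., 1] / ly)
        r = np.sqrt((d ** 2).sum(axis=2))
        # mask self-pairs
        self_mask = ref_idx[:, None] == tgt_idx[None, :]
        r = r[~self_mask]
        counts += np.histogram(r, bins=edges)[0]
        n_pairs_ideal = float(
            (tgt_idx.size - shared.astype(int)).sum()
        )  # sum over refs of available targets
        expected += annulus * n_pairs_ideal / (lx * ly)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(expected > 0, counts / expected, 0.0)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return RDFProfile(
        r=centres, g=g, counts=counts,
        n_reference=int(ref_idx.size), n_target=int(tgt_idx.size),
    )


# ---------------------------------------------------------------------------
# block averaging
# ---------------------------------------------------------------------------

def block_average(
    series: np.ndarray,
    block_sizes: np.ndarray | None = None,
    rel_tol: float = 0.05,
) -> BlockAverageResult:
    """Standard error of the mean of a correlated series by block averaging.

    The series is chopped into non-overlapping blocks; the SE of the mean is
    estimated from the scatter of block means. As the block size exceeds the
    correlation time the estimate plateaus. The chosen block size is the
    first at which the relative change of the SE between consecutive
    (doubling) block sizes drops below ``rel_tol``.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if block_sizes is None:
        sizes = []
        b = 1
        while n // b >= 8:
            sizes.append(b)
            b *= 2
        block_sizes = np.array(sizes, dtype=int)
    else:
        block_sizes = np.asarray(block_sizes, dtype=int)
    if block_sizes.size == 0 or n < 2 * block_sizes.max():
        raise DataError(
            f"series of length {n} is too short for the requested blocks"
        )
    se_curve = np.empty(block_sizes.size)
    for k, b in enumerate(block_sizes):
        nb = n // b
        means = x[: nb * b].reshape(nb, b).mean(axis=1)
        se_curve[k] = means.std(ddof=1) / np.sqrt(nb)
    chosen_i = block_sizes.size - 1
    converged = False
    for k in range(block_sizes.size - 1):
        prev, nxt = se_curve[k], se_curve[k + 1]
        if prev == 0.0 and nxt == 0.0:
            chosen_i, converged = k, True
            break
        if prev > 0 and abs(nxt - prev) / prev < rel_tol:
            chosen_i, converged = k + 1, True
            break
    if not converged:
        warnings.warn(
            "block-averaged SE did not plateau; reporting the largest block",
            stacklevel=2,
        )
    return BlockAverageResult(
        mean=float(x.mean()),
        block_sizes=block_sizes,
        se_curve=se_curve,
        chosen_block=int(block_sizes[chosen_i]),
        se=float(se_curve[chosen_i]),
        converged=converged,
    )
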