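"""File readers/writers, run configuration, and the pipeline driver.

Formats are all plain text:

* trajectories as multi-model PDB (frames as MODEL records, one CRYST1 per
  file) or as a self-describing frames format (JSON provenance header,
  atom table, per-frame box + ``x y z`` rows);
* NOE restraint tables, ITC isotherms, fluorescence traces and reports as
  comma-separated text with ``#`` provenance headers;
* GRO files (nm-based) are converted to Å on ingestion.

Atom roles are assigned from a residue/atom classification table: lipid
pseudo-atoms split into headgroup (choline, phosphate, ester carbon) and
acyl (beads below the ester carbon), peptide residues are ``peptide``, and
water is ``solvent``.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError
from .synthetic import ELEMENT_RADII, LIPID_TEMPLATES
from .noe import NOERestraint, DEFAULT_TAU_PS, DEFAULT_DT_PS, DEFAULT_TOLERANCE
from .itc import ITCExperiment, DEFAULT_TEMPERATURE_K
from .titration import TitrationTrace
from .traj_analysis import Trajectory

__all__ = [
    "read_trajectory",
    "write_frames",
    "read_frames",
    "write_pdb",
    "read_pdb",
    "read_gro",
    "write_restraints",
    "read_restraints",
    "write_isotherm",
    "read_isotherm",
    "write_trace",
    "read_trace",
    "RunConfig",
    "run_pipeline",
]

UCAL_TO_UJ = 4.184

# residue-level role classification; lipid species resolve per atom name
_SOLVENT_RESNAMES = {"HOH", "SOL", "TIP3", "WAT"}
_PEPTIDE_RESNAMES = {"PEP", "ARG", "LYS", "PHE", "TYR", "TRP", "DMT"}
_LIPID_RESNAME_ALIASES = {"POPC": "POPC", "LPC": "POPC", "POP": "POPC",
                          "TOCL": "TOCL", "LCL": "TOCL", "TOC": "TOCL"}

_LIPID_ATOM_ROLE = {
    species: {name: role for (name, _el, role, _dz) in template}
    for species, template in LIPID_TEMPLATES.items()
}


def classify_atom(resname: str, atom_name: str) -> str:
    """Role of an atom from its residue and atom names."""
    resname = resname.strip().upper()
    if resname in _SOLVENT_RESNAMES:
        return "solvent"
    if resname in _PEPTIDE_RESNAMES:
        return "peptide"
    species = _LIPID_RESNAME_ALIASES.get(resname)
    if species is not None:
        role = _LIPID_ATOM_ROLE[species].get(atom_name.strip())
        if role is None:
            # acyl-region convention: beads below the ester carbon
            return "acyl" if atom_name.strip().startswith("ACY") else "headgroup"
        return role
    raise DataError(f"unknown residue name {resname!r}; cannot assign a role")


def _resname_for(traj_row) -> str:
    if traj_row.role == "peptide":
        return "PEP"
    if traj_row.role == "solvent":
        return "HOH"
    # lipid: recover species from the atom-role tables
    for species, table in _LIPID_ATOM_ROLE.items():
        if traj_row.name in table:
            return species
    return "POPC"


# ---------------------------------------------------------------------------
# frames text format
# ---------------------------------------------------------------------------

def write_frames(traj: Trajectory, path: str | Path) -> None:
    """Write the self-describing plain-text frames format."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# pepmem-frames 1\n")
        fh.write("# meta " + json.dumps(traj.meta, default=str) + "\n")
        fh.write(f"# natoms {traj.n_atoms} nframes {traj.n_frames}\n")
        for _, row in traj.atoms.iterrows():
            fh.write(
                f"@atom {row['name']} {row['element']} {row['resid']} "
                f"{row['chain']} {row['role']} {row['radius']:.4f}\n"
            )
        for f in range(traj.n_frames):
            bx, by, bz = traj.box[f]
            fh.write(f"FRAME {f} box {bx:.8f} {by:.8f} {bz:.8f}\n")
            np.savetxt(fh, traj.coords[f], fmt="%.8f")


def read_frames(path: str | Path) -> Trajectory:
    """Read the plain-text frames format written by :func:`write_frames`."""
    path = Path(path)
    meta: dict = {}
    atoms_rows = []
    frames: list[np.ndarray] = []
    boxes: list[list[float]] = []
    current: list[list[float]] | None = None
    n_atoms = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("# meta "):
                meta = json.loads(line[len("# meta "):])
                continue
            if line.startswith("# natoms"):
                parts = line.split()
                n_atoms = int(parts[2])
                continue
            if line.startswith("#"):
                continue
            if line.startswith("@atom"):
                _, name, elem, resid, chain, role, radius = line.split()
                atoms_rows.append(
                    {
                        "name": name, "element": elem, "resid": int(resid),
                        "chain": chain, "role": role, "radius": float(radius),
                    }
                )
                continue
            if line.startswith("FRAME"):
                if current is not None:
                    if n_atoms is not None and len(current) != n_atoms:
                        raise DataError(
                            f"frame {len(frames)} is truncated: "
                            f"{len(current)} of {n_atoms} atoms"
                        )
                    frames.append(np.asarray(current))
                parts = line.split()
                boxes.append([float(parts[3]), float(parts[4]), float(parts[5])])
                current = []
                continue
            if current is None:
                raise DataError(f"line {lineno}: coordinates before any FRAME record")
            vals = line.split()
            if len(vals) != 3:
                raise DataError(f"line {lineno}: expected 3 coordinates, got {len(vals)}")
            current.append([float(v) for v in vals])
    if current is not None:
        if n_atoms is not None and len(current) != n_atoms:
            raise DataError(
                f"frame {len(frames)} is truncated: {len(current)} of {n_atoms} atoms"
            )
        frames.append(np.asarray(current))
    if not frames:
        raise DataError(f"{path} contains no frames")
    return Trajectory(
        coords=np.stack(frames),
        box=np.asarray(boxes),
        atoms=pd.DataFrame(atoms_rows),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# PDB and GRO
# ---------------------------------------------------------------------------

_CHAIN_CHARS = "ABCDEFGHIJKMNOPQRSTUVWXYZ0123456789abcdefghijkmnopqrstuvwxyz"


def write_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write frames as a multi-model PDB (one CRYST1 per file).

    Only the frame-0 box is representable in the single CRYST1 record;
    use the frames format to preserve per-frame box fluctuations. Peptide
    chains are mapped to single-character PDB chain ids; lipids and solvent
    share chain ``L``.
    """
    path = Path(path)
    pep_chains = sorted(
        set(traj.atoms.loc[traj.atoms["role"] == "peptide", "chain"])
    )
    if len(pep_chains) > len(_CHAIN_CHARS):
        raise DataError("too many peptide chains for PDB chain ids")
    chain_map = {c: _CHAIN_CHARS[i] for i, c in enumerate(pep_chains)}
    with path.open("w") as fh:
        fh.write(f"REMARK   1 pepmem meta {json.dumps(traj.meta, default=str)}\n")
        bx, by, bz = traj.box[0]
        fh.write(
            f"CRYST1{bx:9.3f}{by:9.3f}{bz:9.3f}  90.00  90.00  90.00 P 1           1\n"
        )
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            serial = 0
            for a, row in enumerate(traj.atoms.itertuples()):
                serial += 1
                chain = chain_map.get(row.chain, "L")
                resname = _resname_for(row)
                x, y, z = traj.coords[f, a]
                name = row.name[:4]
                fh.write(
                    f"ATOM  {serial % 100000:5d} {name:<4s} {resname[:3]:>3s} "
                    f"{chain}{int(row.resid) % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {row.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_pdb(path: str | Path) -> Trajectory:
    """Read a multi-model PDB into a role-tagged trajectory (Biopython)."""
    from Bio.PDB import PDBParser

    path = Path(path)
    box = None
    meta: dict = {}
    with path.open() as fh:
        for line in fh:
            if line.startswith("REMARK   1 pepmem meta "):
                meta = json.loads(line[len("REMARK   1 pepmem meta "):])
            if line.startswith("CRYST1"):
                box = [float(line[6:15]), float(line[15:24]), float(line[24:33])]
    if box is None:
        raise DataError(f"{path} has no CRYST1 record; box is required")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("traj", str(path))
    frames = []
    atoms_rows = None
    for model in structure:
        coords = []
        rows = []
        for chain in model:
            for residue in chain:
                resname = residue.get_resname()
                for atom in residue:
                    coords.append(atom.get_coord())
                    role = classify_atom(resname, atom.get_name())
                    elem = (atom.element or "C").strip() or "C"
                    rows.append(
                        {
                            "name": atom.get_name(),
                            "element": elem,
                            "resid": residue.get_id()[1],
                            "chain": chain.get_id(),
                            "role": role,
                            "radius": ELEMENT_RADII.get(elem, 1.7),
                        }
                    )
        if atoms_rows is None:
            atoms_rows = rows
        elif len(rows) != len(atoms_rows):
            raise DataError(
                f"model {model.get_id() + 1} has {len(rows)} atoms, "
                f"expected {len(atoms_rows)}"
            )
        frames.append(np.asarray(coords, dtype=float))
    if not frames:
        raise DataError(f"{path} contains no models")
    n_frames = len(frames)
    return Trajectory(
        coords=np.stack(frames),
        box=np.tile(np.asarray(box, dtype=float), (n_frames, 1)),
        atoms=pd.DataFrame(atoms_rows),
        meta=meta,
    )


def read_gro(path: str | Path) -> Trajectory:
    """Read a single-frame GRO file; coordinates convert from nm to Å."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise DataError(f"{path} is not a valid GRO file")
    try:
        n_atoms = int(lines[1].strip())
    except ValueError as err:
        raise DataError(f"{path}: malformed atom count on line 2") from err
    if len(lines) < n_atoms + 3:
        raise DataError(
            f"{path}: expected {n_atoms} atom lines, found {len(lines) - 3}"
        )
    rows = []
    coords = []
    for i in range(n_atoms):
        line = lines[2 + i]
        try:
            resid = int(line[0:5])
            resname = line[5:10].strip()
            name = line[10:15].strip()
            x = float(line[20:28]) * 10.0
            y = float(line[28:36]) * 10.0
            z = float(line[36:44]) * 10.0
        except (ValueError, IndexError) as err:
            raise DataError(f"{path}: malformed GRO record on line {3 + i}") from err
        role = classify_atom(resname, name)
        elem = "P" if name.startswith("P") and role == "headgroup" else (
            "N" if name.startswith("CHL") else "C"
        )
        rows.append(
            {
                "name": name, "element": elem, "resid": resid,
                "chain": "L" if role in ("headgroup", "acyl") else name[0],
                "role": role, "radius": ELEMENT_RADII.get(elem, 1.7),
            }
        )
        coords.append([x, y, z])
    box_fields = lines[2 + n_atoms].split()
    if len(box_fields) < 3:
        raise DataError(f"{path}: malformed box line")
    box = [float(v) * 10.0 for v in box_fields[:3]]
    return Trajectory(
        coords=np.asarray(coords)[None, :, :],
        box=np.asarray(box)[None, :],
        atoms=pd.DataFrame(rows),
        meta={"source": str(path), "format": "gro"},
    )


def read_trajectory(path: str | Path, fmt: str | None = None) -> Trajectory:
    """Read a trajectory, dispatching on extension (.pdb, .gro, frames text)."""
    path = Path(path)
    if fmt is None:
        fmt = {".pdb": "pdb", ".gro": "gro"}.get(path.suffix.lower(), "frames")
    if fmt == "pdb":
        return read_pdb(path)
    if fmt == "gro":
        return read_gro(path)
    if fmt == "frames":
        return read_frames(path)
    raise ConfigError(f"unknown trajectory format {fmt!r}")


# ---------------------------------------------------------------------------
# delimited tables
# ---------------------------------------------------------------------------

def _provenance_header(meta: dict | None) -> str:
    return "# pepmem " + json.dumps(meta or {}, default=str) + "\n"


def write_restraints(
    restraints: list[NOERestraint], path: str | Path, meta: dict | None = None
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_provenance_header(meta))
        fh.write("residue_i,atom_i,residue_j,atom_j,upper_bound\n")
        for r in restraints:
            fh.write(
                f"{r.residue_i},{r.atom_i},{r.residue_j},{r.atom_j},{r.upper_bound}\n"
            )


def read_restraints(path: str | Path) -> list[NOERestraint]:
    df = pd.read_csv(path, comment="#")
    required = {"residue_i", "atom_i", "residue_j", "atom_j", "upper_bound"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"restraint table missing columns: {sorted(missing)}")
    return [
        NOERestraint(
            residue_i=int(row.residue_i),
            atom_i=str(row.atom_i),
            residue_j=int(row.residue_j),
            atom_j=str(row.atom_j),
            upper_bound=float(row.upper_bound),
        )
        for row in df.itertuples()
    ]


def write_isotherm(exp: ITCExperiment, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_provenance_header(exp.meta))
        for key, val in (
            ("cell_conc_uM", exp.cell_conc_uM),
            ("syringe_conc_mM", exp.syringe_conc_mM),
            ("cell_volume_ul", exp.cell_volume_ul),
            ("temperature_K", exp.temperature_K),
            ("outer_fraction", exp.outer_fraction),
            ("heat_unit", exp.heat_unit),
        ):
            fh.write(f"# {key} = {val}\n")
        fh.write("injection_volume_ul,heat\n")
        for v, q in zip(exp.injection_volumes_ul, exp.heats):
            fh.write(f"{float(v)!r},{float(q)!r}\n")


def read_isotherm(path: str | Path) -> ITCExperiment:
    """Read an isotherm file; µcal heats are converted to µJ on ingestion."""
    path = Path(path)
    header: dict = {}
    meta: dict = {}
    with path.open() as fh:
        for line in fh:
            if line.startswith("# pepmem "):
                meta = json.loads(line[len("# pepmem "):])
            elif line.startswith("#") and "=" in line:
                key, val = line[1:].split("=", 1)
                header[key.strip()] = val.strip()
    df = pd.read_csv(path, comment="#")
    if not {"injection_volume_ul", "heat"} <= set(df.columns):
        raise DataError("isotherm file needs injection_volume_ul and heat columns")
    heats = df["heat"].to_numpy(dtype=float)
    unit = header.get("heat_unit", "uJ")
    if unit in ("ucal", "µcal"):
        heats = heats * UCAL_TO_UJ
        unit = "uJ"
    elif unit not in ("uJ", "µJ"):
        raise DataError(f"unknown heat unit {unit!r}")
    try:
        return ITCExperiment(
            cell_conc_uM=float(header["cell_conc_uM"]),
            syringe_conc_mM=float(header["syringe_conc_mM"]),
            injection_volumes_ul=df["injection_volume_ul"].to_numpy(dtype=float),
            heats=heats,
            cell_volume_ul=float(header.get("cell_volume_ul", 170.0)),
            temperature_K=float(header.get("temperature_K", DEFAULT_TEMPERATURE_K)),
            outer_fraction=float(header.get("outer_fraction", 0.5)),
            heat_unit="uJ",
            meta=meta,
        )
    except KeyError as err:
        raise DataError(f"isotherm file missing header key {err}") from err


def write_trace(trace: TitrationTrace, path: str | Path) -> None:
    """Write a trace plus its events sidecar (``<path>.events``)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_provenance_header(trace.meta))
        fh.write(f"# baseline_window = {trace.baseline_window[0]},{trace.baseline_window[1]}\n")
        fh.write("time,intensity\n")
        for t, i in zip(trace.time, trace.intensity):
            fh.write(f"{float(t)!r},{float(i)!r}\n")
    with Path(str(path) + ".events").open("w") as fh:
        fh.write("time,label,dose\n")
        for t, label, dose in trace.events:
            fh.write(f"{t},{label},{dose}\n")


def read_trace(path: str | Path) -> TitrationTrace:
    path = Path(path)
    meta: dict = {}
    baseline = (0.0, 0.0)
    with path.open() as fh:
        for line in fh:
            if line.startswith("# pepmem "):
                meta = json.loads(line[len("# pepmem "):])
            elif line.startswith("# baseline_window"):
                vals = line.split("=", 1)[1].split(",")
                baseline = (float(vals[0]), float(vals[1]))
    df = pd.read_csv(path, comment="#")
    events = []
    sidecar = Path(str(path) + ".events")
    if sidecar.exists():
        ev = pd.read_csv(sidecar)
        events = [(float(r.time), str(r.label), float(r.dose)) for r in ev.itertuples()]
    return TitrationTrace(
        time=df["time"].to_numpy(dtype=float),
        intensity=df["intensity"].to_numpy(dtype=float),
        events=events,
        baseline_window=baseline,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

STAGES = ("simulate", "traj", "noe", "itc", "titration", "seqspace")


@dataclass
class RunConfig:
    """Pipeline parameters; defaults follow the study conventions.

    τ = 10 ps and Δt = 1 ps for NOE time averaging, 0.3 Å violation
    tolerance, 3 Å RMSD similarity threshold, 1.4 Å SASA probe, 0.5
    outer-leaflet fraction, T = 298.15 K.
    """

    outdir: str = "pepmem_out"
    stages: tuple = ("traj", "noe", "itc", "titration", "seqspace")
    seed: int = 0
    # trajectory stage
    n_frames: int = 100
    n_peptides: int = 20
    rmsd_threshold: float = 3.0
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    sasa_stride: int = 10
    # NOE stage
    tau_ps: float = DEFAULT_TAU_PS
    dt_ps: float = DEFAULT_DT_PS
    tolerance: float = DEFAULT_TOLERANCE
    noe_chains: int = 20
    noe_frames: int = 2000
    # ITC stage
    outer_fraction: float = 0.5
    temperature_K: float = DEFAULT_TEMPERATURE_K
    itc_noise_sd_uJ: float = 1.0
    # titration stage
    settle_fraction: float = 0.5
    # optional external inputs (otherwise synthetic fixtures are generated)
    trajectory_path: str | None = None
    restraints_path: str | None = None
    isotherm_path: str | None = None
    trace_path: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path} must contain a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        payload = asdict(self)
        payload.pop("outdir")
        return hashlib.sha1(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages and write per-stage delimited reports.

    Returns a dict of stage name -> output paths. Any stage failure aborts
    with the stage name attached; outputs of completed stages are retained
    and listed in the run log.
    """
    from . import __version__
    from . import noe as noe_mod
    from . import seqspace as seq_mod
    from . import titration as tit_mod
    from .itc import WisemanModel, footprint, ITC_COMPOSITION
    from .synthetic import (
        BilayerSpec, SyntheticTruth, NOEDesign,
        make_bilayer_trajectory, make_noe_series, make_itc_isotherm,
        make_titration_trace, system_composition,
    )
    from .traj_analysis import (
        insertion_depth, bilayer_thickness, area_per_lipid, sasa,
    )

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"{config.config_hash()}-seed{config.seed}"
    log_path = outdir / "run.log"
    outputs: dict = {}

    def log(msg: str) -> None:
        stamp = time.strftime("%Y-%m-%d %H:%M:%S")
        with log_path.open("a") as fh:
            fh.write(f"{stamp} {msg}\n")
        print(f"pepmem: {msg}", file=sys.stderr)

    log(f"pepmem {__version__} run {tag} stages={','.join(config.stages)}")
    log(f"config {json.dumps(asdict(self_ := config), sort_keys=True, default=str)}")
    defaults = RunConfig()
    for fname in config.__dataclass_fields__:
        if fname in ("outdir", "stages", "seed"):
            continue
        if getattr(self_, fname) != getattr(defaults, fname):
            log(f"override {fname} = {getattr(self_, fname)!r}")

    truth = SyntheticTruth(seed=config.seed)

    stage = None
    try:
        for stage in config.stages:
            paths: list[str] = []
            if stage in ("simulate", "traj"):
                if config.trajectory_path:
                    traj = read_trajectory(config.trajectory_path)
                else:
                    traj = make_bilayer_trajectory(
                        BilayerSpec(), config.n_peptides, truth, config.n_frames
                    )
                if stage == "simulate":
                    p = outdir / f"trajectory-{tag}.frames.txt"
                    write_frames(traj, p)
                    paths.append(str(p))
                else:
                    comp = system_composition(BilayerSpec(), config.n_peptides)
                    depth = insertion_depth(traj)
                    thick_series, thick = bilayer_thickness(traj)
                    apl_series, apl = area_per_lipid(
                        traj, BilayerSpec().n_lipids_per_leaflet
                    )
                    rep = sasa(
                        traj, config.probe_radius, config.n_sphere_points,
                        stride=config.sasa_stride,
                    )
                    p = outdir / f"traj-report-{tag}.csv"
                    with p.open("w") as fh:
                        fh.write(_provenance_header(
                            {"config": tag, "seed": config.seed}
                        ))
                        fh.write("metric,value,se\n")
                        for key, val in comp.items():
                            fh.write(f"{key},{val},\n")
                        fh.write(f"thickness_A,{thick.mean},{thick.se}\n")
                        fh.write(f"area_per_lipid_A2,{apl.mean},{apl.se}\n")
                        for g, v in rep.mean.items():
                            fh.write(f"sasa_{g}_A2,{v},{rep.se[g]}\n")
                        for rid, m, s in zip(depth.residue_ids, depth.mean, depth.sd):
                            fh.write(f"depth_res{rid}_A,{m},{s}\n")
                        fh.write(f"phosphate_plane_A,{depth.phosphate_plane},\n")
                        fh.write(f"ester_plane_A,{depth.ester_plane},\n")
                    paths.append(str(p))
            elif stage == "noe":
                if config.restraints_path:
                    restraints = read_restraints(config.restraints_path)
                else:
                    restraints = [
                        NOERestraint(1, "HA", 3, "HN", 4.0),
                        NOERestraint(1, "HA", 4, "HN", 5.0),
                        NOERestraint(2, "HA", 4, "HN", 4.5),
                    ]
                designs = truth.noe_designs or (
                    NOEDesign(violation_fraction=0.0),
                    NOEDesign(violation_fraction=0.3),
                    NOEDesign(violation_fraction=0.1),
                )
                series = make_noe_series(
                    config.noe_chains, config.noe_frames,
                    noe_mod.filter_long_range(restraints),
                    SyntheticTruth(seed=config.seed, noe_designs=designs),
                    dt=config.dt_ps,
                )
                report = noe_mod.compliance_report(
                    series, tau=config.tau_ps, tolerance=config.tolerance
                )
                p = outdir / f"noe-report-{tag}.csv"
                with p.open("w") as fh:
                    fh.write(_provenance_header({
                        "config": tag, "seed": config.seed,
                        "tau_ps": report.tau, "dt_ps": report.dt,
                        "tolerance_A": report.tolerance,
                        "share_compliant": report.share_compliant,
                    }))
                    report.table.to_csv(fh, index=False)
                paths.append(str(p))
            elif stage == "itc":
                if config.isotherm_path:
                    exp = read_isotherm(config.isotherm_path)
                else:
                    exp = make_itc_isotherm(
                        SyntheticTruth(
                            seed=config.seed,
                            itc_noise_sd_uJ=config.itc_noise_sd_uJ,
                        ),
                        outer_fraction=config.outer_fraction,
                    )
                result = WisemanModel(exp).fit()
                p = outdir / f"itc-report-{tag}.csv"
                with p.open("w") as fh:
                    fh.write(_provenance_header({
                        "config": tag, "seed": config.seed,
                        "c_value": result.c_value,
                        "footprint_A2": round(
                            footprint(result.params.n, ITC_COMPOSITION)
                        ),
                    }))
                    result.to_frame().to_csv(fh, index=False)
                paths.append(str(p))
            elif stage == "titration":
                trace = (
                    read_trace(config.trace_path) if config.trace_path
                    else make_titration_trace("surface-probe", truth)
                )
                norm = tit_mod.normalize_trace(trace)
                curve = tit_mod.saturation_from_trace(
                    norm, settle_fraction=config.settle_fraction
                )
                p = outdir / f"titration-report-{tag}.csv"
                with p.open("w") as fh:
                    fh.write(_provenance_header({
                        "config": tag, "seed": config.seed,
                        "half_saturation": curve.half_saturation,
                        "max_response": curve.max_response,
                        "identifiable": curve.identifiable,
                    }))
                    fh.write("cumulative_dose,response,fractional\n")
                    for d, r, fr in zip(curve.dose, curve.response, curve.fractional):
                        fh.write(f"{d},{r},{fr}\n")
                paths.append(str(p))
            elif stage == "seqspace":
                specs = seq_mod.enumerate_space()
                table = seq_mod.to_table(specs)
                p = outdir / f"seqspace-{tag}.csv"
                with p.open("w") as fh:
                    fh.write(_provenance_header({
                        "config": tag, "seed": config.seed,
                        "n_sequences": len(specs),
                    }))
                    table.to_csv(fh, index=False)
                pf = outdir / f"seqspace-{tag}.fasta"
                pf.write_text(seq_mod.to_fasta(specs))
                paths.extend([str(p), str(pf)])
            outputs[stage] = paths
            log(f"stage {stage} ok: {', '.join(paths) if paths else 'no outputs'}")
    except Exception as err:
        log(f"stage {stage} FAILED: {err}; outputs so far retained: "
            f"{json.dumps(outputs)}")
        raise DataError(f"pipeline stage {stage!r} failed: {err}") from err
    return outputs
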