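"""Tabular and structural I/O: titration tables, trajectories, topologies, masses.

Conventions used throughout the package:

* lengths in nm (PDB Angstroms are converted on load),
* chemical shifts in ppm,
* association constants in M^-1,
* dihedral angles in degrees in (-180, 180],
* CSV dialect: comma separated, dot decimal, one header row whose column
  names carry unit suffixes (``Ltot_mM``, ``T1_s``, ...).  Key=value
  metadata lives on a single leading comment line starting with ``#``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqUtils import molecular_weight

from .errors import FormatError, ValidationError

_H_MASS = 1.008  # average H mass, Da
_WATER_MASS = 18.015

_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Topology:
    """Static atom/residue metadata for a structure or trajectory.

    Atom attributes are parallel numpy arrays; ``residue_numbers`` must be
    non-decreasing within a chain/segment and masses strictly positive.
    """

    atom_names: np.ndarray          # str
    residue_numbers: np.ndarray     # int
    residue_names: np.ndarray       # 3-letter str
    elements: np.ndarray            # str
    masses: np.ndarray              # Da
    segids: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.atom_names)
        if n == 0:
            raise ValidationError("topology must contain at least one atom")
        for arr in (self.residue_numbers, self.residue_names, self.elements, self.masses):
            if len(arr) != n:
                raise ValidationError("topology attribute arrays must have equal length")
        if np.any(np.asarray(self.masses) <= 0):
            raise ValidationError("atom masses must be positive")
        if self.segids is None:
            self.segids = np.array(["A"] * n)
        for seg in np.unique(self.segids):
            resnum = self.residue_numbers[self.segids == seg]
            if np.any(np.diff(resnum) < 0):
                raise ValidationError(
                    f"residue numbers decrease within segment {seg!r}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(set(zip(self.segids, self.residue_numbers)))

    def select(self, predicate) -> np.ndarray:
        """Indices of atoms for which predicate(resnum, resname, atomname) holds."""
        idx = [
            i
            for i in range(self.n_atoms)
            if predicate(
                int(self.residue_numbers[i]),
                str(self.residue_names[i]),
                str(self.atom_names[i]),
            )
        ]
        return np.asarray(idx, dtype=int)

    def heavy_atoms(self) -> np.ndarray:
        """Indices of non-hydrogen atoms (the default analysis selection)."""
        return np.flatnonzero(np.char.upper(self.elements.astype(str)) != "H")


@dataclass
class TrajectoryView:
    """Frames x atoms x 3 coordinates in nm, with optional box and times.

    ``box`` holds per-frame 3x3 lattice vectors (nm); ``times`` is in ps.
    """

    coordinates: np.ndarray
    box: np.ndarray | None = None
    times: np.ndarray | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValidationError("coordinates must have shape (frames, atoms, 3)")
        if self.coordinates.shape[0] < 1:
            raise ValidationError("trajectory must contain at least one frame")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValidationError("coordinates contain non-finite values")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (self.n_frames, 3, 3):
                raise ValidationError("box must have shape (frames, 3, 3)")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class ScheduleTable:
    """Titration schedule: cumulative volumes and total concentrations per step."""

    added_volumes: np.ndarray       # uL per step (0 for the initial point)
    cumulative_volumes: np.ndarray  # uL
    ligand_totals: np.ndarray       # mM
    protein_totals: np.ndarray      # mM

    def __post_init__(self):
        for name in ("added_volumes", "cumulative_volumes", "ligand_totals", "protein_totals"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.added_volumes)
        if not (len(self.cumulative_volumes) == len(self.ligand_totals) == len(self.protein_totals) == n):
            raise ValidationError("schedule columns must have equal length")
        if n == 0:
            raise ValidationError("schedule must contain at least one step")
        if np.any(np.diff(self.cumulative_volumes) <= 0):
            raise ValidationError("cumulative volumes must be strictly increasing")
        if np.any(np.diff(self.ligand_totals) < 0):
            raise ValidationError("ligand totals must be non-decreasing")
        if np.any(np.diff(self.protein_totals) > 0):
            raise ValidationError("protein totals must be non-increasing")

    @property
    def n_steps(self) -> int:
        return len(self.added_volumes)


@dataclass
class ShiftTable:
    """Per-residue chemical shifts (ppm) across titration steps.

    ``is_delta`` flags whether values are changes from the zero-ligand point
    (the usual CSP representation) or absolute shifts.
    """

    residue_numbers: np.ndarray
    residue_names: np.ndarray
    nucleus: str                    # "N15" or "H1"
    shifts: np.ndarray              # residues x steps, ppm
    is_delta: bool = True

    def __post_init__(self):
        if self.nucleus not in ("N15", "H1"):
            raise ValidationError(f"nucleus must be N15 or H1, got {self.nucleus!r}")
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.shifts.ndim != 2:
            raise ValidationError("shifts must be a residues x steps matrix")
        if self.shifts.shape[0] == 0:
            raise ValidationError("shift table contains no residue rows")
        if self.shifts.shape[0] != len(self.residue_numbers):
            raise ValidationError("one shift row per residue required")
        if not np.all(np.isfinite(self.shifts)):
            raise ValidationError("shift values must be finite")

    @property
    def n_steps(self) -> int:
        return self.shifts.shape[1]

    def residue_label(self, i: int) -> str:
        return f"{self.residue_names[i]}{int(self.residue_numbers[i])}"


# ---------------------------------------------------------------------------
# titration CSV dialect
# ---------------------------------------------------------------------------

def write_schedule(schedule: ScheduleTable, path) -> None:
    df = pd.DataFrame(
        {
            "added_volume_uL": schedule.added_volumes,
            "cumulative_volume_uL": schedule.cumulative_volumes,
            "Ltot_mM": schedule.ligand_totals,
            "Ptot_mM": schedule.protein_totals,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_schedule(path) -> ScheduleTable:
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse schedule CSV {path}: {exc}") from exc
    required = ["added_volume_uL", "cumulative_volume_uL", "Ltot_mM", "Ptot_mM"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"schedule CSV {path} lacks columns {missing}")
    return ScheduleTable(
        df["added_volume_uL"].to_numpy(),
        df["cumulative_volume_uL"].to_numpy(),
        df["Ltot_mM"].to_numpy(),
        df["Ptot_mM"].to_numpy(),
    )


def write_shifts(table: ShiftTable, path) -> None:
    cols = {"residue_number": table.residue_numbers, "residue_name": table.residue_names}
    for k in range(table.n_steps):
        cols[f"d{k}_ppm"] = table.shifts[:, k]
    header = f"# nucleus={table.nucleus},kind={'delta' if table.is_delta else 'absolute'}\n"
    with open(path, "w") as fh:
        fh.write(header)
        pd.DataFrame(cols).to_csv(fh, index=False, float_format="%.10g")


def read_shifts(path) -> ShiftTable:
    meta = {"nucleus": "N15", "kind": "delta"}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for item in first[1:].strip().split(","):
            if "=" in item:
                k, v = item.split("=", 1)
                meta[k.strip()] = v.strip()
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise FormatError(f"cannot parse shift CSV {path}: {exc}") from exc
    if "residue_number" not in df.columns:
        raise FormatError(f"shift CSV {path} lacks a residue_number column")
    step_cols = [c for c in df.columns if c.startswith("d") and c.endswith("_ppm")]
    if not step_cols:
        raise FormatError(f"shift CSV {path} has no d<k>_ppm step columns")
    step_cols.sort(key=lambda c: int(c[1:-4]))
    if df.shape[0] == 0:
        raise ValidationError(f"shift CSV {path} contains no residue rows")
    if df[step_cols].isna().any().any():
        raise ValidationError(f"shift CSV {path} contains empty shift cells")
    names = (
        df["residue_name"].to_numpy()
        if "residue_name" in df.columns
        else np.array(["UNK"] * len(df))
    )
    return ShiftTable(
        df["residue_number"].to_numpy(int),
        names,
        meta["nucleus"],
        df[step_cols].to_numpy(float),
        is_delta=(meta["kind"] == "delta"),
    )


def read_titration(schedule_path, shifts_path) -> tuple[ScheduleTable, ShiftTable]:
    """Read and cross-validate a titration schedule plus shift table pair."""
    schedule = read_schedule(schedule_path)
    shifts = read_shifts(shifts_path)
    if shifts.n_steps != schedule.n_steps:
        raise FormatError(
            f"step count mismatch: {schedule_path} has {schedule.n_steps} steps "
            f"but {shifts_path} has {shifts.n_steps} shift columns"
        )
    return schedule, shifts


def write_titration(schedule: ScheduleTable, shifts: ShiftTable, schedule_path, shifts_path) -> None:
    write_schedule(schedule, schedule_path)
    write_shifts(shifts, shifts_path)


# ---------------------------------------------------------------------------
# relaxation and ITC CSV dialects
# ---------------------------------------------------------------------------

def write_relaxation(df: pd.DataFrame, path) -> None:
    """Write a relaxation table (residue, T1_s, T2_s, NOE and *_err columns)."""
    df.to_csv(path, index=False, float_format="%.10g")


def read_relaxation(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise FormatError(f"cannot parse relaxation CSV {path}: {exc}") from exc
    required = ["residue", "T1_s", "T2_s", "NOE"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"relaxation CSV {path} lacks columns {missing}")
    if np.any(df["T1_s"] <= 0) or np.any(df["T2_s"] <= 0):
        raise ValidationError("T1 and T2 must be positive")
    if np.any(df["T2_s"] > df["T1_s"]):
        warnings.warn("some residues have T2 > T1; check the input", stacklevel=2)
    return df


def write_itc(exp, path) -> None:
    """Write an ITC experiment; geometry on the metadata comment line."""
    meta = (
        f"# cell_volume_uL={exp.cell_volume},cell_protein_uM={exp.cell_protein},"
        f"syringe_ligand_mM={exp.syringe_ligand}\n"
    )
    cols = {"injection_volume_uL": exp.injection_volumes}
    if exp.heats is not None:
        cols["heat_ucal"] = exp.heats
    with open(path, "w") as fh:
        fh.write(meta)
        pd.DataFrame(cols).to_csv(fh, index=False, float_format="%.10g")


def read_itc(path):
    from .binding import ITCExperiment

    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise FormatError(f"ITC CSV {path} lacks the geometry metadata line")
    meta = {}
    for item in first[1:].strip().split(","):
        if "=" in item:
            k, v = item.split("=", 1)
            meta[k.strip()] = float(v)
    df = pd.read_csv(path, comment="#")
    if "injection_volume_uL" not in df.columns:
        raise FormatError(f"ITC CSV {path} lacks an injection_volume_uL column")
    heats = df["heat_ucal"].to_numpy(float) if "heat_ucal" in df.columns else None
    return ITCExperiment(
        cell_volume=meta["cell_volume_uL"],
        cell_protein=meta["cell_protein_uM"],
        syringe_ligand=meta["syringe_ligand_mM"],
        injection_volumes=df["injection_volume_uL"].to_numpy(float),
        heats=heats,
    )


# ---------------------------------------------------------------------------
# structures and trajectories (MDAnalysis backend)
# ---------------------------------------------------------------------------

def _universe(*args, **kwargs):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(*args, **kwargs)


def _resolve_altlocs(u):
    """Keep one atom per (segid, resid, name): highest occupancy, then altloc."""
    atoms = u.atoms
    try:
        altlocs = atoms.altLocs
    except Exception:
        return atoms
    if all(a.strip() == "" for a in altlocs):
        return atoms
    try:
        occ = atoms.occupancies
    except Exception:
        occ = np.ones(len(atoms))
    best: dict[tuple, int] = {}
    for i, at in enumerate(atoms):
        key = (at.segid, at.resid, at.name)
        if key not in best:
            best[key] = i
            continue
        j = best[key]
        if (occ[i], -ord((altlocs[i] or " ")[0])) > (occ[j], -ord((altlocs[j] or " ")[0])):
            best[key] = i
    keep = sorted(best.values())
    return atoms[keep]


_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "CA": 40.078, "MG": 24.305, "NA": 22.990, "K": 39.098,
    "CL": 35.45, "FE": 55.845, "ZN": 65.38,
}


def _guess_element(name: str, resname: str) -> str:
    name = name.strip()
    if resname.strip().upper() in ("CA", "MG", "NA", "K", "CL", "ZN", "FE"):
        return resname.strip().upper()
    lead = name.lstrip("0123456789")
    if lead[:1].upper() == "H":
        return "H"
    return lead[:1].upper()


def topology_from_atomgroup(ag) -> Topology:
    names = np.array([a.name for a in ag])
    resnames = np.array([a.resname for a in ag])
    elements = np.array([_guess_element(n, r) for n, r in zip(names, resnames)])
    masses = np.array([_ELEMENT_MASSES.get(e, 12.011) for e in elements])
    return Topology(
        atom_names=names,
        residue_numbers=np.array([a.resid for a in ag], dtype=int),
        residue_names=resnames,
        elements=elements,
        masses=masses,
        segids=np.array([a.segid if a.segid.strip() else "A" for a in ag]),
    )


def load_topology(pdb_path) -> Topology:
    """Build a Topology from the ATOM/HETATM records of a PDB file.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken lexicographically by altloc id); masses come from the
    element inferred from the atom name.
    """
    path = Path(pdb_path)
    if not path.exists():
        raise FormatError(f"no such PDB file: {path}")
    text = path.read_text()
    if "ATOM" not in text and "HETATM" not in text:
        raise FormatError(f"{path} contains no ATOM records")
    u = _universe(str(path))
    ag = _resolve_altlocs(u)
    return topology_from_atomgroup(ag)


def _dcd_declared_frames(path) -> int | None:
    """Frame count promised by a DCD header (NSET field), or None."""
    import struct

    with open(path, "rb") as fh:
        head = fh.read(12)
    if len(head) < 12:
        return None
    for endian in ("<", ">"):
        (blocksize,) = struct.unpack(endian + "i", head[:4])
        if blocksize == 84 and head[4:8] == b"CORD":
            return struct.unpack(endian + "i", head[8:12])[0]
    return None


def _parse_cryst1(path) -> np.ndarray | None:
    """CRYST1 unit cell as MDAnalysis dimensions [a b c alpha beta gamma] (A)."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                vals = np.array(
                    [line[6:15], line[15:24], line[24:33], line[33:40], line[40:47], line[47:54]],
                    dtype=float,
                )
                # the 1 A placeholder cell written for boxless structures
                if np.allclose(vals[:3], 1.0):
                    return None
                return vals
    return None


def load_trajectory(path, topology: Topology, format: str | None = None) -> TrajectoryView:
    """Load a multi-model PDB / XTC / DCD trajectory as coordinates in nm.

    XTC and DCD carry no topology, so the caller's ``topology`` supplies
    atom metadata; its atom count must match the file.
    """
    import MDAnalysis as mda
    from MDAnalysis.lib import mdamath

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such trajectory file: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    pdb_box = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if fmt == "pdb":
                u = _universe(str(path))
                pdb_box = _parse_cryst1(path)
            else:
                u = mda.Universe.empty(topology.n_atoms, trajectory=True)
                u.load_new(str(path), format=fmt.upper())
    except (OSError, EOFError, ValueError, IndexError) as exc:
        msg = str(exc)
        if "number of atoms" in msg or "atoms" in msg.lower() and "match" in msg.lower():
            raise FormatError(
                f"atom count mismatch: topology has {topology.n_atoms} atoms "
                f"but trajectory {path} disagrees ({msg})"
            ) from exc
        raise FormatError(f"cannot parse trajectory {path}: {exc}") from exc

    if u.atoms.n_atoms != topology.n_atoms:
        raise FormatError(
            f"atom count mismatch: topology has {topology.n_atoms}, "
            f"trajectory {path} has {u.atoms.n_atoms}"
        )
    coords, boxes, times = [], [], []
    has_box = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for ts in u.trajectory:
                coords.append(ts.positions / 10.0)  # A -> nm
                dims = ts.dimensions if ts.dimensions is not None else pdb_box
                if dims is not None and dims[:3].all():
                    has_box = True
                    boxes.append(mdamath.triclinic_vectors(dims) / 10.0)
                else:
                    boxes.append(np.zeros((3, 3)))
                times.append(ts.time)
    except (OSError, EOFError, ValueError, IndexError) as exc:
        raise FormatError(f"truncated or corrupt trajectory {path}: {exc}") from exc
    if fmt == "dcd":
        declared = _dcd_declared_frames(path)
        if declared is not None and declared > 0 and len(coords) < declared:
            raise FormatError(
                f"truncated trajectory {path}: header declares {declared} frames, "
                f"only {len(coords)} readable"
            )
    return TrajectoryView(
        coordinates=np.array(coords),
        box=np.array(boxes) if has_box else None,
        times=np.array(times),
    )


def write_trajectory(path, topology: Topology, traj: TrajectoryView, format: str | None = None) -> None:
    """Write a TrajectoryView as multi-model PDB, XTC or DCD (nm -> A)."""
    import MDAnalysis as mda
    from MDAnalysis.lib import mdamath

    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    reskeys = list(dict.fromkeys(zip(topology.segids, topology.residue_numbers)))
    resindex = {key: i for i, key in enumerate(reskeys)}
    atom_resindex = [resindex[(s, r)] for s, r in zip(topology.segids, topology.residue_numbers)]
    u = mda.Universe.empty(
        topology.n_atoms,
        n_residues=len(reskeys),
        atom_resindex=atom_resindex,
        residue_segindex=[0] * len(reskeys),
        trajectory=True,
    )
    u.add_TopologyAttr("names", list(topology.atom_names))
    u.add_TopologyAttr("resids", [int(r) for _, r in reskeys])
    first_of_res = {}
    for i, key in enumerate(atom_resindex):
        first_of_res.setdefault(key, i)
    u.add_TopologyAttr(
        "resnames", [str(topology.residue_names[first_of_res[i]]) for i in range(len(reskeys))]
    )
    u.add_TopologyAttr("masses", list(topology.masses))
    u.add_TopologyAttr("elements", list(topology.elements))

    frames = traj.coordinates * 10.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=topology.n_atoms, format=fmt.upper(), multiframe=True) as w:
            for k in range(traj.n_frames):
                u.atoms.positions = frames[k]
                if traj.box is not None:
                    u.dimensions = mdamath.triclinic_box(*(traj.box[k] * 10.0))
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# sequences and masses
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an {id: sequence} dict."""
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def protein_average_mass(sequence: str, n_disulfides: int = 0) -> float:
    """Average molecular mass of a peptide in kDa, to 3 decimals.

    The reduced-chain mass is the sum of average residue masses plus one
    water; each disulfide bond removes two hydrogens.  Matches ExPASy
    ProtParam values for the canonical 20 amino acids.
    """
    if n_disulfides < 0:
        raise ValidationError("n_disulfides must be non-negative")
    for pos, letter in enumerate(sequence):
        if letter not in _AA_LETTERS:
            raise ValidationError(
                f"non-canonical residue {letter!r} at position {pos + 1}"
            )
    if 2 * n_disulfides > sequence.count("C"):
        raise ValidationError(
            f"{n_disulfides} disulfides require {2 * n_disulfides} cysteines, "
            f"sequence has {sequence.count('C')}"
        )
    if sequence:
        mass = molecular_weight(sequence, seq_type="protein", monoisotopic=False)
    else:
        mass = _WATER_MASS
    mass -= n_disulfides * 2 * _H_MASS
    return round(mass / 1000.0, 3)
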