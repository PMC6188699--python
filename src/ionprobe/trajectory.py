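"""MD-trajectory observables for ion-binding and dynamics studies.

Covers the descriptors used to characterise weak cation binding and its
dynamic consequences: minimum ion-site distances and binding-site
occupancy, Lys-carboxylate salt-bridge distances, disulfide dihedrals,
RMSD/RMSF/radius of gyration, GROMOS-style conformational clustering,
N-H bond-vector order parameters, and mutual-information generalized
correlation matrices.  All distances are in nm, angles in degrees.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .formats import Topology, TrajectoryView

logger = logging.getLogger(__name__)


@dataclass
class AtomSelection:
    """Materialized atom index list with a human-readable label."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValidationError(f"selection {self.label!r} has duplicate indices")

    def __len__(self):
        return len(self.indices)


@dataclass
class DistanceSeries:
    label: str
    values: np.ndarray  # nm per frame

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValidationError(f"distance series {self.label!r} has invalid values")


@dataclass
class CorrelationMatrix:
    labels: list
    values: np.ndarray  # symmetric, rMI in [0, 1], unit diagonal
    flagged: list = field(default_factory=list)  # static atoms with undefined MI


@dataclass
class ClusterResult:
    assignments: np.ndarray          # per-frame cluster id, 0 = most populated
    sizes: np.ndarray
    representative_frames: np.ndarray  # one per cluster

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


# ---------------------------------------------------------------------------
# distances and occupancy
# ---------------------------------------------------------------------------

def _mda_dimensions(box_frame):
    from MDAnalysis.lib import mdamath

    return mdamath.triclinic_box(*(box_frame * 10.0))


def min_distance_series(
    traj: TrajectoryView, selA: AtomSelection, selB: AtomSelection, label: str | None = None
) -> DistanceSeries:
    """Per-frame minimum distance over all A x B atom pairs (nm).

    Uses the minimum-image convention whenever the trajectory carries box
    vectors (orthorhombic or triclinic); raw distances otherwise.
    """
    from MDAnalysis.lib.distances import distance_array

    for sel in (selA, selB):
        if len(sel) == 0:
            raise ValidationError(f"empty atom selection: {sel.label!r}")
    out = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        a = traj.coordinates[k, selA.indices] * 10.0  # nm -> A for MDAnalysis
        b = traj.coordinates[k, selB.indices] * 10.0
        box = _mda_dimensions(traj.box[k]) if traj.box is not None else None
        out[k] = distance_array(a, b, box=box).min() / 10.0
    return DistanceSeries(label or f"{selA.label}--{selB.label}", out)


def occupancy_percent(series: DistanceSeries, cutoff: float = 0.4) -> float:
    """Percent of frames with distance strictly below ``cutoff`` (nm).

    The binding-site occupancy convention: frames where the ion sits
    closer to the site atom than the cutoff, divided by all frames, x100.
    """
    if len(series.values) == 0:
        raise ValidationError("empty distance series")
    return float(100.0 * np.count_nonzero(series.values < cutoff) / len(series.values))


_CARBOXYLATE_C = {"ASP": "CG", "GLU": "CD"}


def salt_bridge_series(traj: TrajectoryView, topology: Topology) -> list[DistanceSeries]:
    """Distance series for every Lys NZ vs carboxylate/hydroxyl partner pair.

    Partners: Asp CG and Glu CD (carboxylate carbons), Ser OG (the
    hydroxyl that replaces a carboxylate in Asp->Ser variants), and the
    C-terminal carboxylate carbon (backbone C of the last residue).
    """
    lys_nz = [
        i
        for i in range(topology.n_atoms)
        if topology.residue_names[i] == "LYS" and topology.atom_names[i] == "NZ"
    ]
    if not lys_nz:
        logger.warning("no Lys NZ atoms in topology; returning no salt-bridge series")
        return []

    partners = []
    for i in range(topology.n_atoms):
        resname = str(topology.residue_names[i])
        name = str(topology.atom_names[i])
        if _CARBOXYLATE_C.get(resname) == name or (resname == "SER" and name == "OG"):
            partners.append((i, f"{resname}{int(topology.residue_numbers[i])}-{name}"))
    # C-terminal carboxylate carbon: backbone C of the last protein residue
    last_res = int(np.max(topology.residue_numbers))
    cterm = [
        i
        for i in range(topology.n_atoms)
        if topology.residue_numbers[i] == last_res and topology.atom_names[i] == "C"
    ]
    for i in cterm:
        partners.append((i, f"{topology.residue_names[i]}{last_res}-Cterm"))

    series = []
    for nz in lys_nz:
        nz_label = f"LYS{int(topology.residue_numbers[nz])}-NZ"
        for j, plabel in partners:
            s = min_distance_series(
                traj,
                AtomSelection(np.array([nz]), nz_label),
                AtomSelection(np.array([j]), plabel),
                label=f"{nz_label}--{plabel}",
            )
            series.append(s)
    return series


def dihedral_series(traj: TrajectoryView, four_atoms: AtomSelection) -> np.ndarray:
    """Torsion angle (degrees, in (-180, 180]) of an ordered atom quadruple.

    IUPAC sign convention; frames with a collinear central triple yield NaN
    (flagged via a warning).
    """
    if len(four_atoms) != 4:
        raise ValidationError("dihedral requires exactly 4 atoms")
    p = traj.coordinates[:, four_atoms.indices, :]
    b1 = p[:, 1] - p[:, 0]
    b2 = p[:, 2] - p[:, 1]
    b3 = p[:, 3] - p[:, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm1 = np.linalg.norm(n1, axis=1)
    norm2 = np.linalg.norm(n2, axis=1)
    bad = (norm1 < 1e-12) | (norm2 < 1e-12)
    b2n = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2n)
    with np.errstate(invalid="ignore"):
        ang = np.degrees(np.arctan2(y, x))
    ang[bad] = np.nan
    if np.any(bad):
        warnings.warn(f"{bad.sum()} frame(s) with collinear atoms: torsion undefined")
    # fold -180 to +180 so the range is (-180, 180]
    ang[ang == -180.0] = 180.0
    return ang


# ---------------------------------------------------------------------------
# superposition, RMSD, RMSF, Rg
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, reference: np.ndarray, weights=None):
    """Optimal proper rotation R and translations aligning mobile onto reference.

    Returns (R, t_mobile, t_reference) such that
    (mobile - t_mobile) @ R.T + t_reference best fits reference in the
    least-squares sense; reflections are excluded via the determinant sign
    correction on the SVD.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    w = np.ones(len(mobile)) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    mu_m = w @ mobile
    mu_r = w @ reference
    H = (mobile - mu_m).T @ ((reference - mu_r) * w[:, None])
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, mu_m, mu_r


def superpose(
    traj: TrajectoryView, reference: np.ndarray, selection: AtomSelection
) -> TrajectoryView:
    """Least-squares superpose every frame onto ``reference`` (atoms x 3, nm).

    The rotation is fitted on ``selection`` and applied to all atoms.
    """
    if len(selection) < 3:
        raise ValidationError("superposition requires at least 3 atoms")
    ref_sel = reference[selection.indices]
    out = np.empty_like(traj.coordinates)
    for k in range(traj.n_frames):
        R, mu_m, mu_r = kabsch(traj.coordinates[k, selection.indices], ref_sel)
        out[k] = (traj.coordinates[k] - mu_m) @ R.T + mu_r
    return TrajectoryView(out, box=None, times=traj.times)


def rmsd_series(
    traj: TrajectoryView, reference: np.ndarray, selection: AtomSelection
) -> np.ndarray:
    """Per-frame RMSD (nm) to ``reference`` after optimal superposition on
    ``selection``; the RMSD is evaluated over the same selection."""
    aligned = superpose(traj, reference, selection)
    diff = aligned.coordinates[:, selection.indices] - reference[selection.indices]
    return np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))


def _mean_structure(traj: TrajectoryView, selection: AtomSelection, tol=1e-6, max_iter=50):
    """Iteratively superpose to the mean structure until it stops moving."""
    ref = traj.coordinates[0].copy()
    aligned = traj
    for _ in range(max_iter):
        aligned = superpose(aligned, ref, selection)
        new_ref = aligned.coordinates.mean(axis=0)
        if np.max(np.abs(new_ref - ref)) < tol:
            ref = new_ref
            break
        ref = new_ref
    return aligned, ref


def rmsf_per_residue(
    traj: TrajectoryView, topology: Topology, selection: AtomSelection | None = None
) -> dict[int, float]:
    """Per-residue RMSF (nm) over heavy atoms, after iterative alignment.

    Frames are superposed onto the converged mean structure; the per-atom
    fluctuation is the root time-mean squared deviation from the mean
    position, and residues aggregate their atoms by root mean square.
    """
    if selection is None:
        selection = AtomSelection(topology.heavy_atoms(), "heavy")
    if traj.n_frames == 1:
        warnings.warn("single-frame trajectory: RMSF is zero by construction")
        return {int(r): 0.0 for r in np.unique(topology.residue_numbers[selection.indices])}
    aligned, mean = _mean_structure(traj, selection)
    disp2 = np.sum((aligned.coordinates - mean) ** 2, axis=2)  # frames x atoms
    msf = disp2.mean(axis=0)
    out = {}
    for res in np.unique(topology.residue_numbers[selection.indices]):
        atoms = selection.indices[topology.residue_numbers[selection.indices] == res]
        out[int(res)] = float(np.sqrt(np.mean(msf[atoms])))
    return out


def radius_of_gyration_series(
    traj: TrajectoryView, masses=None, mass_weighted: bool = True
) -> np.ndarray:
    """Per-frame radius of gyration (nm); unit masses when not weighted."""
    if traj.n_atoms < 2:
        raise ValidationError("radius of gyration requires at least 2 atoms")
    if mass_weighted and masses is not None:
        m = np.asarray(masses, dtype=float)
    else:
        m = np.ones(traj.n_atoms)
    m = m / m.sum()
    com = np.einsum("a,fax->fx", m, traj.coordinates)
    d2 = np.sum((traj.coordinates - com[:, None, :]) ** 2, axis=2)
    return np.sqrt(np.einsum("a,fa->f", m, d2))


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def pairwise_rmsd_matrix(traj: TrajectoryView, selection: AtomSelection) -> np.ndarray:
    """Symmetric frames x frames matrix of pairwise superposed RMSD (nm)."""
    n = traj.n_frames
    X = traj.coordinates[:, selection.indices]
    X = X - X.mean(axis=1, keepdims=True)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            R, _, _ = kabsch(X[j], X[i])
            diff = X[j] @ R.T - X[i]
            mat[i, j] = mat[j, i] = np.sqrt(np.mean(np.sum(diff**2, axis=1)))
    return mat


def cluster_frames(
    traj: TrajectoryView, selection: AtomSelection, cutoff: float = 0.15
) -> ClusterResult:
    """Greedy neighbour-count (GROMOS-style) clustering of frames.

    The frame with most neighbours within ``cutoff`` RMSD seeds the first
    cluster (ties to the lowest frame index); the cluster is removed and
    the procedure repeats.  The representative of a cluster is the member
    with minimal mean RMSD to its co-members.
    """
    if traj.n_frames < 2:
        raise ValidationError("clustering needs at least 2 frames")
    dmat = pairwise_rmsd_matrix(traj, selection)
    n = traj.n_frames
    remaining = np.ones(n, dtype=bool)
    assignments = np.full(n, -1, dtype=int)
    sizes, reps = [], []
    cid = 0
    while remaining.any():
        neigh = (dmat < cutoff) & remaining[None, :] & remaining[:, None]
        counts = neigh.sum(axis=1)
        counts[~remaining] = -1
        seed = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neigh[seed])
        assignments[members] = cid
        remaining[members] = False
        sizes.append(len(members))
        if len(members) == 1:
            reps.append(int(members[0]))
        else:
            sub = dmat[np.ix_(members, members)]
            mean_to_others = sub.sum(axis=1) / (len(members) - 1)
            reps.append(int(members[np.argmin(mean_to_others)]))
        cid += 1
    order = np.argsort(sizes)[::-1]
    relabel = np.empty(len(sizes), dtype=int)
    relabel[order] = np.arange(len(sizes))
    return ClusterResult(
        assignments=relabel[assignments],
        sizes=np.asarray(sizes)[order],
        representative_frames=np.asarray(reps)[order],
    )


# ---------------------------------------------------------------------------
# N-H order parameters
# ---------------------------------------------------------------------------

def vector_order_parameter(vectors: np.ndarray) -> float:
    """S2 of a unit-vector time series via the second-rank tensor estimator.

    S2 = (3/2) sum_ab <mu_a mu_b>^2 - 1/2, clipped to [0, 1]; equals 1 for
    a static vector and tends to 0 for isotropic reorientation.
    """
    mu = vectors / np.linalg.norm(vectors, axis=1, keepdims=True)
    outer = np.einsum("fi,fj->ij", mu, mu) / len(mu)
    s2 = 1.5 * np.sum(outer**2) - 0.5
    return float(np.clip(s2, 0.0, 1.0))


def _reconstruct_amide_h(topology, coords, res):
    """Place H along the bisector-opposed direction from N, using CA and
    the preceding residue's C; returns None when geometry is unavailable."""
    def find(resnum, name):
        idx = np.flatnonzero(
            (topology.residue_numbers == resnum) & (topology.atom_names == name)
        )
        return int(idx[0]) if len(idx) else None

    iN, iCA, iC = find(res, "N"), find(res, "CA"), find(res - 1, "C")
    if iN is None or iCA is None or iC is None:
        return None
    n, ca, c = coords[:, iN], coords[:, iCA], coords[:, iC]
    u1 = (n - ca) / np.linalg.norm(n - ca, axis=1, keepdims=True)
    u2 = (n - c) / np.linalg.norm(n - c, axis=1, keepdims=True)
    h_dir = u1 + u2
    norms = np.linalg.norm(h_dir, axis=1, keepdims=True)
    if np.any(norms < 1e-6):  # degenerate (collinear) backbone geometry
        return None
    h_dir /= norms
    return n + 0.102 * h_dir  # standard N-H bond length, nm


def nh_order_parameters(traj: TrajectoryView, topology: Topology) -> dict[int, float]:
    """Per-residue S2 of backbone N-H bond vectors.

    The trajectory must already be superposed (global tumbling removed);
    amide protons are taken from the topology (H/HN/H01 names) or
    reconstructed from N, CA and the previous C when absent.  Residues
    lacking both are skipped and logged.
    """
    out, skipped = {}, []
    resnums = np.unique(topology.residue_numbers)
    for res in resnums:
        mask = topology.residue_numbers == res
        if "PRO" in topology.residue_names[mask]:
            continue
        iN = np.flatnonzero(mask & (topology.atom_names == "N"))
        if len(iN) == 0:
            continue
        iH = np.flatnonzero(mask & np.isin(topology.atom_names, ("H", "HN", "H01", "H1")))
        n = traj.coordinates[:, int(iN[0])]
        if len(iH):
            h = traj.coordinates[:, int(iH[0])]
        else:
            h = _reconstruct_amide_h(topology, traj.coordinates, int(res))
            if h is None:
                skipped.append(int(res))
                continue
        out[int(res)] = vector_order_parameter(h - n)
    if skipped:
        logger.info("skipped residues without resolvable N-H vectors: %s", skipped)
    return out


# ---------------------------------------------------------------------------
# generalized correlation (Gaussian mutual information)
# ---------------------------------------------------------------------------

def generalized_correlation(
    traj: TrajectoryView, atoms: AtomSelection, estimator: str = "gaussian"
) -> CorrelationMatrix:
    """Mutual-information generalized correlation matrix of atomic motions.

    For displacement vectors about the mean, the Gaussian mutual
    information of a pair is I = (1/2) ln[det(Cii) det(Cjj) / det(Cjoint)]
    from the 3x3 marginal and 6x6 joint covariances, normalized to
    rMI = sqrt(1 - exp(-2 I / 3)) in [0, 1].  Static atoms (singular
    covariance) get rMI 0 off-diagonal and are flagged.
    """
    if estimator != "gaussian":
        raise ValidationError(f"unknown estimator {estimator!r}")
    if traj.n_frames < 100:
        warnings.warn("fewer than 100 frames: correlation estimates will be noisy")
    X = traj.coordinates[:, atoms.indices, :]
    X = X - X.mean(axis=0, keepdims=True)
    n = len(atoms)
    F = traj.n_frames
    flat = X.reshape(F, n * 3)
    cov = flat.T @ flat / F  # (3n x 3n)
    rmi = np.eye(n)
    flagged = []
    dets = np.empty(n)
    for i in range(n):
        Cii = cov[3 * i : 3 * i + 3, 3 * i : 3 * i + 3]
        dets[i] = np.linalg.det(Cii)
        if dets[i] <= 1e-30:
            flagged.append(i)
    for i in range(n):
        for j in range(i + 1, n):
            if i in flagged or j in flagged:
                rmi[i, j] = rmi[j, i] = 0.0
                continue
            sl = np.r_[3 * i : 3 * i + 3, 3 * j : 3 * j + 3]
            Cjoint = cov[np.ix_(sl, sl)]
            detj = np.linalg.det(Cjoint)
            if detj <= 1e-60:
                val = 1.0  # perfectly dependent pair
            else:
                I = 0.5 * np.log(max(dets[i] * dets[j] / detj, 1.0))
                val = np.sqrt(1.0 - np.exp(-2.0 * I / 3.0))
            rmi[i, j] = rmi[j, i] = val
    labels = [f"atom{int(k)}" for k in atoms.indices]
    return CorrelationMatrix(labels=labels, values=rmi, flagged=flagged)


def matrix_abs_difference(A: CorrelationMatrix, B: CorrelationMatrix) -> np.ndarray:
    """Elementwise |A - B| of two same-shaped correlation matrices."""
    if A.values.shape != B.values.shape:
        raise ValidationError(
            f"shape mismatch: {A.values.shape} vs {B.values.shape}"
        )
    return np.abs(A.values - B.values)
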