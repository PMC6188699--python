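"""Synthetic-data generators with exact ground truth for every pipeline stage.

Each generator is a deterministic function of its spec and seed and
returns, beside the data, a machine-readable truth record that the test
suite consumes directly.  The generators encode statistical structure
only (no physics): titration tables follow the one-site fast-exchange
model, relaxation triples the model-free forward equations, and toy
trajectories are Gaussian jitter around fixed sites with optional shared
latent terms (pairwise correlation) and scripted ion-binding episodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import ITCExperiment, fraction_bound, itc_predict_heats
from .errors import ValidationError
from .formats import ScheduleTable, ShiftTable, Topology, TrajectoryView
from .modelfree import FieldSpec, relaxation_rates


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# titration
# ---------------------------------------------------------------------------

@dataclass
class TitrationSimSpec:
    true_Ka: float                      # M^-1
    n_residues: int = 12
    ddmax_range: tuple = (0.5, 4.5)     # ppm
    noise_sd: float = 0.05              # ppm
    schedule: ScheduleTable | None = None
    seed: int = 0
    nucleus: str = "N15"
    residues: tuple | None = None       # optional (resnum, resname, ddmax) rows

    def __post_init__(self):
        if self.true_Ka <= 0:
            raise ValidationError("true_Ka must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


def simulate_titration(spec: TitrationSimSpec):
    """Per-residue |shift change| trajectories under a shared one-site Ka.

    Returns (schedule, shift_table, truth) where truth carries the exact
    Ka and per-residue amplitudes used.
    """
    rng = _rng(spec.seed)
    schedule = spec.schedule
    if schedule is None:
        from .datasets import nmr_titration_schedule

        schedule = nmr_titration_schedule()
    if spec.residues is not None:
        resnums = np.array([r[0] for r in spec.residues], dtype=int)
        resnames = np.array([r[1] for r in spec.residues])
        ddmax = np.array([r[2] for r in spec.residues], dtype=float)
    else:
        resnums = np.arange(1, spec.n_residues + 1)
        resnames = np.array(["UNK"] * spec.n_residues)
        ddmax = rng.uniform(*spec.ddmax_range, size=spec.n_residues)
    fb = fraction_bound(schedule.protein_totals, schedule.ligand_totals, spec.true_Ka)
    clean = ddmax[:, None] * fb[None, :]
    noisy = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape)
    noisy[:, 0] = 0.0  # the zero-ligand reference point has no shift change
    noisy = np.abs(noisy)
    table = ShiftTable(resnums, resnames, spec.nucleus, noisy, is_delta=True)
    truth = {
        "Ka": spec.true_Ka,
        "ddmax": dict(zip((int(r) for r in resnums), ddmax.tolist())),
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    return schedule, table, truth


def paf_like_titration(noise_sd: float = 0.05, seed: int = 0):
    """Synthetic stand-in for the PAF 15N CSP titration table.

    Twelve Ca2+-sensitive residues around the C-terminal binding site with
    a shared true Ka of 463 M^-1 and the largest amplitude (> 4 ppm) at
    Cys54, on the packaged 1 mM protein NMR schedule.  Synthetic: the
    amplitudes are invented, only their ordering and scale follow the
    published characterisation.
    """
    from .datasets import PAF_CA_KA_N15, PAF_SENSITIVE_RESIDUES

    spec = TitrationSimSpec(
        true_Ka=PAF_CA_KA_N15,
        residues=PAF_SENSITIVE_RESIDUES,
        noise_sd=noise_sd,
        seed=seed,
    )
    return simulate_titration(spec)


# ---------------------------------------------------------------------------
# relaxation
# ---------------------------------------------------------------------------

def simulate_relaxation(
    tau_c: float,
    S2,
    tau_e,
    field: FieldSpec,
    noise_fraction: float = 0.0,
    seed: int = 0,
):
    """Per-residue (T1, T2, NOE) triples from known model-free parameters.

    ``tau_c`` in ns, ``S2`` and ``tau_e`` (ps) per residue.  Multiplicative
    Gaussian noise of relative size ``noise_fraction`` is applied to each
    observable; quoted errors equal the noise level.  Returns
    (DataFrame, truth).
    """
    rng = _rng(seed)
    S2 = np.asarray(S2, dtype=float)
    tau_e = np.broadcast_to(np.asarray(tau_e, dtype=float), S2.shape)
    rows = []
    for i, (s2, te) in enumerate(zip(S2, tau_e), start=1):
        R1, R2, noe = relaxation_rates(s2, tau_c * 1e-9, te * 1e-12, field)
        T1, T2 = 1.0 / R1, 1.0 / R2
        f = noise_fraction
        T1n = T1 * (1.0 + f * rng.standard_normal())
        T2n = T2 * (1.0 + f * rng.standard_normal())
        noen = noe * (1.0 + f * rng.standard_normal())
        rows.append(
            dict(
                residue=i,
                T1_s=T1n,
                T2_s=T2n,
                NOE=noen,
                T1_err_s=f * T1 if f > 0 else np.nan,
                T2_err_s=f * T2 if f > 0 else np.nan,
                NOE_err=f * abs(noe) if f > 0 else np.nan,
            )
        )
    df = pd.DataFrame(rows)
    truth = {
        "tau_c": tau_c,
        "S2": S2.tolist(),
        "tau_e": np.asarray(tau_e).tolist(),
        "noise_fraction": noise_fraction,
        "seed": seed,
    }
    return df, truth


# ---------------------------------------------------------------------------
# toy trajectories
# ---------------------------------------------------------------------------

@dataclass
class IonEpisode:
    start_frame: int
    end_frame: int            # exclusive
    bound_distance: float     # nm
    unbound_distance: float   # nm


@dataclass
class ToyTrajectorySpec:
    n_atoms: int = 10
    n_frames: int = 1000
    fluctuation_sd: float | np.ndarray = 0.02      # nm, per atom
    correlated_pairs: list = field(default_factory=list)   # (i, j, rho)
    ion_episodes: list = field(default_factory=list)       # IonEpisode
    site_atom: int = 0
    box: float | None = None                        # cubic box edge, nm
    seed: int = 0
    site_spacing: float = 1.0                       # nm between rest positions

    def __post_init__(self):
        for (i, j, rho) in self.correlated_pairs:
            if not (0.0 <= rho < 1.0):
                raise ValidationError("pair correlation must satisfy 0 <= rho < 1")
            if i == j or not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms):
                raise ValidationError("correlated pair indices out of range")
        eps = sorted(self.ion_episodes, key=lambda e: e.start_frame)
        for e in eps:
            if not (0 <= e.start_frame < e.end_frame <= self.n_frames):
                raise ValidationError("ion episode outside the frame range")
        for a, b in zip(eps, eps[1:]):
            if b.start_frame < a.end_frame:
                raise ValidationError("ion episodes overlap")


def simulate_toy_trajectory(spec: ToyTrajectorySpec):
    """(Topology, TrajectoryView, truth) with prescribed statistics.

    Atoms jitter independently and isotropically about fixed rest sites
    with the given per-coordinate sd; listed pairs share a latent Gaussian
    term giving per-axis displacement correlation rho.  When ion episodes
    are given, an extra "ion" atom (resname CA) is appended and placed at
    the exact bound/unbound distance from the instantaneous position of
    the designated site atom, so the ground-truth occupancy is a frame
    count by construction.
    """
    rng = _rng(spec.seed)
    n, F = spec.n_atoms, spec.n_frames
    sd = np.broadcast_to(np.asarray(spec.fluctuation_sd, dtype=float), (n,)).copy()

    # rest sites on a line, spaced widely relative to the jitter
    sites = np.zeros((n, 3))
    sites[:, 0] = np.arange(n) * spec.site_spacing

    noise = rng.standard_normal((F, n, 3))
    for (i, j, rho) in spec.correlated_pairs:
        z = rng.standard_normal((F, 3))
        noise[:, i] = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * rng.standard_normal((F, 3))
        noise[:, j] = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * rng.standard_normal((F, 3))
    coords = sites[None, :, :] + noise * sd[None, :, None]

    names = np.array(["CA"] * n)
    resnames = np.array(["GLY"] * n)
    resnums = np.arange(1, n + 1)
    elements = np.array(["C"] * n)

    bound_frames = 0
    if spec.ion_episodes:
        ion = np.empty((F, 1, 3))
        site = coords[:, spec.site_atom, :]
        dist = np.full(F, np.nan)
        default_unbound = max(e.unbound_distance for e in spec.ion_episodes)
        dist[:] = default_unbound
        for e in spec.ion_episodes:
            dist[e.start_frame : e.end_frame] = e.bound_distance
            bound_frames += e.end_frame - e.start_frame
        direction = np.array([0.0, 0.0, 1.0])
        ion[:, 0, :] = site + dist[:, None] * direction[None, :]
        coords = np.concatenate([coords, ion], axis=1)
        names = np.append(names, "CA")
        resnames = np.append(resnames, "CA")
        resnums = np.append(resnums, n + 1)
        elements = np.append(elements, "CA")

    top = Topology(
        atom_names=names,
        residue_numbers=resnums,
        residue_names=resnames,
        elements=elements,
        masses=np.where(elements == "CA", 40.078, 12.011),
    )
    box = None
    if spec.box is not None:
        box = np.tile(np.eye(3) * spec.box, (F, 1, 1))
    traj = TrajectoryView(coords, box=box, times=np.arange(F, dtype=float))
    truth = {
        "occupancy_percent": 100.0 * bound_frames / F if spec.ion_episodes else None,
        "rho": {f"{i}-{j}": rho for (i, j, rho) in spec.correlated_pairs},
        "fluctuation_sd": sd.tolist(),
        "site_atom": spec.site_atom,
        "ion_atom": n if spec.ion_episodes else None,
        "seed": spec.seed,
    }
    return top, traj, truth


# ---------------------------------------------------------------------------
# ITC
# ---------------------------------------------------------------------------

def simulate_itc(
    exp: ITCExperiment,
    Ka: float,
    dH: float,
    n: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """ITC injection heats from the one-site forward model plus noise.

    ``noise_sd`` is the absolute Gaussian sd in ucal added per injection.
    Returns (ITCExperiment with heats, truth).
    """
    rng = _rng(seed)
    heats = itc_predict_heats(exp, Ka, dH, n)
    noisy = heats + rng.normal(0.0, noise_sd, size=heats.shape)
    out = ITCExperiment(
        cell_volume=exp.cell_volume,
        cell_protein=exp.cell_protein,
        syringe_ligand=exp.syringe_ligand,
        injection_volumes=exp.injection_volumes.copy(),
        heats=noisy,
    )
    truth = {"Ka": Ka, "dH": dH, "n": n, "noise_sd": noise_sd, "seed": seed}
    return out, truth
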