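"""Reference constants and packaged synthetic stand-in datasets for PAF.

PAF, the 55-residue antifungal protein of *Penicillium chrysogenum*
(solution structure PDB 2MHV, Ca2+-bound form PDB 2NBF), binds Ca2+
weakly at a C-terminal site formed by Asp53, Asp55 and the C-terminal
carboxylate; Cys54 sits between the two aspartates and shows the largest
15N chemical shift perturbation on titration (> 4 ppm).  The functions
here bundle those facts into small, clearly synthetic datasets used by
tests and examples in place of the original measured tables.
"""

from __future__ import annotations

import numpy as np

from .binding import ligand_schedule
from .formats import ScheduleTable

# Mature PAF sequence (PDB 2MHV numbering, residues 1-55).
PAF_SEQUENCE = "AKYTGKCTKSKNECKYKNDAGKDTFIKCPKFDNKKCTKDNNKCTVDTYNNAVDCD"

# Disulfide pattern of the folded protein: Cys7-Cys36, Cys14-Cys43, Cys28-Cys54.
PAF_DISULFIDES = ((7, 36), (14, 43), (28, 54))

# Average Ca2+ association constant from 15N CSP titration, M^-1.
PAF_CA_KA_N15 = 463.0

# The 12 Ca2+-sensitive residues used for the synthetic stand-in titration:
# clustered around the C-terminal binding site (beta-strands 4/5 and loop 3),
# with maximal-amplitude perturbation at Cys54.  (residue number, name,
# ddmax ppm) -- amplitudes are synthetic but respect the published ordering:
# Cys54 largest at > 4 ppm, everything else well below.
PAF_SENSITIVE_RESIDUES = (
    (32, "ASP", 0.9),
    (34, "LYS", 0.8),
    (36, "CYS", 1.1),
    (37, "THR", 0.7),
    (42, "LYS", 1.3),
    (43, "CYS", 1.6),
    (44, "THR", 1.2),
    (51, "ALA", 1.8),
    (52, "VAL", 2.4),
    (53, "ASP", 3.2),
    (54, "CYS", 4.5),
    (55, "ASP", 3.0),
)


def apply_mutations(sequence: str, *mutations: str) -> str:
    """Apply point mutations written as e.g. "D53S" to a one-letter sequence."""
    seq = list(sequence)
    for mut in mutations:
        wt, pos, new = mut[0], int(mut[1:-1]), mut[-1]
        if seq[pos - 1] != wt:
            raise ValueError(
                f"mutation {mut}: sequence has {seq[pos - 1]} at position {pos}"
            )
        seq[pos - 1] = new
    return "".join(seq)


def nmr_titration_schedule() -> ScheduleTable:
    """A CaCl2-into-protein NMR titration schedule at 1 mM protein.

    500 uL of 1 mM protein titrated with small volumes of a concentrated
    (200 mM) CaCl2 stock so the sample is only mildly diluted, reaching
    ~36 mM total Ca2+ (~20-40 protein equivalents, well past the
    millimolar Kd of the site).  14 points including the zero-ligand one.
    """
    additions = [1, 1, 2, 3, 4, 6, 8, 11, 15, 20, 26, 34, 45]
    return ligand_schedule(P0=1.0, V0=500.0, stock=200.0, additions=additions)


def itc_geometry():
    """Injection geometry of the calorimetric Ca2+ titration.

    200 uL cell with 100 uM protein; 38 uL of 10 mM CaCl2 delivered as
    19 x 2 uL injections.  With Ka ~ 400 M^-1 this sits deep in the
    low-c regime (c = n Ka [P] ~ 0.04).
    """
    from .binding import ITCExperiment

    return ITCExperiment(
        cell_volume=200.0,
        cell_protein=100.0,
        syringe_ligand=10.0,
        injection_volumes=np.full(19, 2.0),
    )
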