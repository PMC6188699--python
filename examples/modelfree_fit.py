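"""Lipari-Szabo model-free fit of backbone 15N relaxation.

Simulates (T1, T2, NOE) triples for 40 residues of a small protein
tumbling with tau_c = 4.5 ns (order parameters drawn from [0.6, 0.95],
2% noise) at a 70.966 MHz 15N field, then inverts them into one global
correlation time plus per-residue S2.
"""

import numpy as np

from ionprobe import FieldSpec, fit_modelfree
from ionprobe.synthetic import simulate_relaxation

field = FieldSpec(70.966)  # 15N frequency of a 700 MHz spectrometer
rng = np.random.default_rng(0)
s2_true = rng.uniform(0.6, 0.95, 40)

df, truth = simulate_relaxation(4.5, s2_true, 0.0, field, noise_fraction=0.02, seed=1)
records = [
    dict(residue=r.residue, T1=r.T1_s, T2=r.T2_s, NOE=r.NOE,
         T1_err=r.T1_err_s, T2_err=r.T2_err_s, NOE_err=r.NOE_err)
    for r in df.itertuples()
]
result = fit_modelfree(records, field, model="S2_only")

fitted = np.array([p.S2 for p in result.per_residue])
print(f"true tau_c      : 4.500 ns")
print(f"fitted tau_c    : {result.tau_c:.3f} ns")
print(f"mean S2         : {result.mean_S2:.2f} +/- {result.sd_S2:.2f}")
print(f"median |S2 err| : {np.median(np.abs(fitted - s2_true)):.4f}")
print()
print("S2 near 1 means a rigid N-H bond vector; the global tau_c is shared")
print("by all residues, as appropriate for an isotropically tumbling protein.")
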