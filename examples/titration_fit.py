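"""Fast-exchange CSP titration: recover a weak association constant.

Simulates a 15N chemical-shift-perturbation titration of a 1 mM protein
sample with a Ca2+ stock (12 sensitive residues sharing one true
Ka = 463 M^-1, 0.05 ppm noise), then fits every residue with the
depletion-aware one-site model and averages the per-residue constants.
"""

from ionprobe import fit_average_ka
from ionprobe.synthetic import paf_like_titration

schedule, shifts, truth = paf_like_titration(noise_sd=0.05, seed=1)
fit = fit_average_ka(schedule, shifts, sensitivity_threshold=0.3)

print(f"true Ka            : {truth['Ka']:.0f} M^-1")
print(f"mean per-residue Ka: {fit.Ka:.0f} +/- {fit.Ka_stderr:.0f} M^-1  ({fit.n_sites_used} sites)")
print(f"shared-Ka joint fit: {fit.shared_Ka:.0f} +/- {fit.shared_Ka_stderr:.0f} M^-1")
print()
print("per residue:")
for r in fit.per_residue:
    print(f"  {r.residue:>6}  Ka = {r.Ka:6.0f} M^-1   ddmax = {r.ddmax:4.2f} ppm   rmse = {r.rmse:.3f} ppm")
print()
print("The mean and the joint fit agree within error: the shifts are all")
print("reporting on the same one-site binding event (Kd ~ 2 mM).")
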