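# Methods

This note records the models implemented in `ionprobe`, the conventions
and defaults they use, what the synthetic generators do and do not
emulate, and the design choices made where several defensible options
existed.

## Units and conventions

Internal length unit is nm (PDB Ångströms are divided by 10 on load);
chemical shifts are ppm; association constants M⁻¹ (concentrations in
tables are mM, converted at the model boundary); dihedral angles are
degrees in (−180°, 180°] with the IUPAC sign convention.  CSV files are
comma-separated with dot decimals, one header row with unit-suffixed
column names, and a single optional `#`-prefixed metadata line.
Carboxylate carbons are addressed by their PDB names: CG for Asp, CD for
Glu, and the backbone C of the last residue for the C-terminal
carboxylate.  Published figure labels sometimes call the Asp carboxylate
carbon "Cδ" although the PDB name is CG; both labels are mapped to atom
name CG here.  The default "heavy atom" selection excludes hydrogens.

## One-site binding with depletion

`fraction_bound` solves the 1:1 mass-action quadratic using the
numerically stable smaller-root form 2PL/(b + √(b² − 4PL)), avoiding
catastrophic cancellation at high affinity.  The no-depletion hyperbola
is available behind an explicit flag; at the study conditions (protein
~1 mM, K_d ~2 mM) it overestimates binding and is never the default.
The two agree within 1% whenever P ≤ K_d/100, which the tests verify.

**CSP fitting.** Each residue's absolute shift-change series is fitted
to Δδ_max·f_b by bounded nonlinear least squares (K_a > 0, Δδ_max ≥ 0).
K_a is initialised from the half-saturation point of the series and the
fit is restarted from 3 log-spaced K_a values to avoid local minima;
signed input series are folded to |Δδ| so the fit is sign-invariant.
Residues qualify as ligand-sensitive when max|Δδ| ≥ 0.3 ppm by default
(¹⁵N scale; configurable).  The reported constant is the mean of the
per-residue K_a values and its uncertainty the standard error of that
mean across residues — the between-site spread, not the propagated fit
error.  A shared-K_a joint fit (one K_a, per-residue amplitudes) is
always computed alongside as a consistency check; on clean data the two
agree within their joint errors.

**ITC.** The one-site isotherm uses the same dilution rule as the NMR
schedule (cell concentrations scaled by V₀/V_i, ligand by the injected
fraction) and the trapezoidal displaced-volume correction
ΔQ_i = Q_i − Q_{i−1} + (dV_i/V₀)(Q_i + Q_{i−1})/2.  The correction is
accurate for small relative injection volumes; at ~30% cumulative
dilution the summed heats drift a few percent from strict conservation,
which is a property of this standard correction, not a bug.  The fit
parameters are (K_a, ΔH, n, baseline); the per-injection baseline models
the heat of dilution and can be pinned to zero when a blank titration
has already been subtracted (`fit_baseline=False`).  Uncertainties come
from the Jacobian at the optimum using a true matrix inverse — in the
low-c regime the (n, ΔH, K_a) directions are nearly degenerate, and a
pseudo-inverse would silently truncate exactly the sloppy direction
whose size is the scientifically relevant answer.  Fits with
c = n·K_a·[P] < 1 carry a low-confidence flag on K_a.

## Model-free relaxation analysis

The spectral density is J(ω) = (2/5)[S²τc/(1+(ωτc)²) + (1−S²)τ/(1+(ωτ)²)]
with 1/τ = 1/τc + 1/τe; the default model has τe = 0 (global τc plus
per-residue S² only), the τe variant is available.  Rates use the
standard ¹⁵N amide constants r_NH = 1.02 Å, Δσ = −160 ppm,
γH/γN = −9.8656; different software defaults for these constants shift
S² by a few percent, so absolute comparisons with other packages carry a
possible small systematic offset.  The inversion is a two-stage fit: an
outer 1-D search of τc (60 log-spaced points in 1–20 ns, then
golden-section refinement to 0.01 ns — appropriate for a small protein
tumbling at a few ns) around an inner per-residue weighted least squares.
With τe = 0 both rates are linear in S² and the NOE is S²-independent,
so the inner problem has a closed form; the NOE residual still
contributes to the τc objective.  Weights are inverse-variance from the
supplied errors (σ_R = σ_T/T²), unit weights when absent.  S² is clipped
to [0, 1].

## Trajectory observables

* **Distances/occupancy**: per-frame minimum over all selected pairs,
  with the minimum-image convention (orthorhombic and triclinic boxes)
  whenever box vectors are present; PBC arithmetic is delegated to
  MDAnalysis.  Occupancy counts frames strictly below the cutoff
  (default 0.4 nm), so a frame exactly at the cutoff does not count.
* **Salt bridges**: every Lys NZ against every Asp CG, Glu CD, Ser OG
  and the C-terminal backbone C.  Ser OG is included because Asp→Ser
  binding-site variants replace a carboxylate with a hydroxyl.
* **Superposition**: own Kabsch implementation (SVD with determinant
  sign correction, so reflections are never returned); tests verify it
  beats a 10°-step SO(3) grid on random instances.
* **RMSF**: frames are superposed iteratively onto the converged mean
  structure (tolerance 1e-6 nm) rather than frame 0 — the standard
  fluctuation reference.  Note the alignment absorbs 6 rigid-body DOF,
  so for N atoms the measured isotropic-jitter RMSF is √(1 − 6/3N)
  of σ√3; the effect is negligible for protein-sized selections.
* **Clustering**: greedy neighbour-count (GROMOS-style) on the pairwise
  superposed-RMSD matrix, default cutoff 0.15 nm; ties seed at the
  lowest frame index; the representative minimises mean RMSD to
  co-members.  The O(F²) matrix is intended for desk-scale frame counts.
* **N–H order parameters**: the second-rank tensor estimator
  S² = (3/2)Σ⟨μ_αμ_β⟩² − ½ on unit bond vectors after superposition.  It
  is deterministic and needs no correlation-function plateau fitting; a
  time-correlation estimator could differ systematically on
  non-converged trajectories.  Missing amide protons are reconstructed
  along the in-plane bisector-opposed direction from N, CA and the
  preceding C (bond length 0.102 nm); residues with degenerate geometry
  are skipped and listed.
* **Generalized correlation**: Gaussian mutual-information estimator
  only, from 3×3 marginal and 6×6 joint displacement covariances, with
  rMI = √(1 − e^(−2I/3)) (dimensionality 3 in the normalisation).  For
  per-axis Gaussian correlation ρ this equals |ρ| exactly, which is the
  closed form the tests pin.  A k-nearest-neighbour MI estimator is out
  of scope.  Static atoms (singular covariance) get rMI 0 off-diagonal
  and are flagged rather than producing NaNs.

## Synthetic data

The generators emulate the *statistical* structure of each input class
— shift trajectories that follow the one-site model, relaxation triples
that follow the forward rate equations, toy trajectories made of
Gaussian jitter around fixed sites with optional shared latent terms
(exact per-axis correlation ρ) and scripted ion-binding episodes (the
ion is placed at the exact bound/unbound distance from the site atom, so
ground-truth occupancy is a frame count).  They do **not** emulate
force-field physics, solvent, correlated backbone motion beyond the
planted pairs, chemical-shift referencing artefacts, or baseline drifts;
passing the recovery tests therefore demonstrates the correctness of the
estimators under their own model assumptions, not robustness to every
pathology of real data.  Every generator is a deterministic function of
(spec, seed) and returns a truth record the tests consume directly.

Default study conditions follow the experimental design they mirror:
NMR titration at 1 mM protein in 500 μL with a concentrated stock
(~14 points to ~36 mM ligand, noise 0.05 ppm); relaxation at the
70.966 MHz ¹⁵N field of a 700 MHz spectrometer, τc = 4.5 ns,
S² ∈ [0.6, 0.95], 2% noise; ITC at 200 μL / 100 μM / 19 × 2 μL of
10 mM ligand with K_a = 400 M⁻¹ (c ≈ 0.04).  The packaged PAF-like
titration table is **synthetic**: the twelve Ca²⁺-sensitive residues
cluster around the C-terminal binding site and the amplitude ordering
peaks at Cys54 above 4 ppm, but the individual Δδ_max values are
invented stand-ins, not the measured ones.

## Problem sizes and limitations

Tests and the acceptance script run at desk scale by design: toy
trajectories of 10²–10⁴ frames and ≤ tens of atoms, 20-seed recovery
experiments, 40-residue relaxation sets.  Microsecond-trajectory
quantities (sub-Å ensemble RMSDs between variants, ~0.01 nm radius-of-
gyration shifts, per-site occupancy tables from multi-copy ion
simulations, experimental/MD S² averages) require the original
trajectories and raw relaxation tables and are not recomputable here;
the estimators that would produce them are instead validated against
closed forms, independent oracles and exact construction truths at
small scale.  Other known limitations: no multi-site/cooperative
binding, no slow-exchange lineshape analysis, no anisotropic diffusion
or Rex terms, no mmCIF/NMR-STAR input, Gaussian-only MI, and clustering
that materialises the full pairwise RMSD matrix.
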