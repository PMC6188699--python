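"""Lipari-Szabo model-free analysis of backbone 15N relaxation.

Forward prediction of (R1, R2, NOE) from (S2, tau_c, tau_e) with the
standard 15N dipolar + CSA rate expressions, and the inverse problem:
a two-stage fit of one global rotational correlation time tau_c for the
whole protein plus residue-specific order parameters S2 (optionally with
an internal correlation time tau_e).

Fixed physical constants (the conventional backbone-amide values):
r_NH = 1.02 A, Delta-sigma(15N CSA) = -160 ppm, gammaH/gammaN = -9.8656.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, ValidationError

# physical constants (SI)
MU0 = 4e-7 * np.pi          # T m / A
HBAR = 1.054571817e-34      # J s
GAMMA_H = 2.6752218744e8    # rad / s / T
GAMMA_N = -2.7126189e7      # rad / s / T  (15N, negative)
R_NH = 1.02e-10             # m
CSA_N = -160e-6             # unitless (ppm)


@dataclass
class FieldSpec:
    """Spectrometer field stated as the 15N Larmor frequency in MHz."""

    nitrogen_frequency: float  # MHz

    def __post_init__(self):
        if self.nitrogen_frequency <= 0:
            raise ValidationError("nitrogen frequency must be positive")

    @property
    def omega_N(self) -> float:
        """15N angular frequency, rad/s (sign dropped; J is even in omega)."""
        return 2 * np.pi * self.nitrogen_frequency * 1e6

    @property
    def omega_H(self) -> float:
        return self.omega_N * abs(GAMMA_H / GAMMA_N)

    @property
    def proton_frequency(self) -> float:
        """MHz, derived via the gyromagnetic ratio."""
        return self.nitrogen_frequency * abs(GAMMA_H / GAMMA_N)


@dataclass
class ResidueModelFree:
    residue: int
    S2: float
    tau_e: float | None   # ps, None in the S2-only model
    chi2: float


@dataclass
class ModelFreeResult:
    tau_c: float                      # ns
    per_residue: list[ResidueModelFree]
    mean_S2: float
    sd_S2: float
    chi2: float
    model: str
    excluded: list[int]


def spectral_density(omega, S2, tau_c, tau_e=0.0):
    """Model-free spectral density J(omega) in s/rad.

    J = (2/5) [S2*tau_c/(1+(w*tau_c)^2) + (1-S2)*tau/(1+(w*tau)^2)] with
    1/tau = 1/tau_c + 1/tau_e; the internal term vanishes for tau_e = 0.
    Times in seconds, omega in rad/s.
    """
    omega = np.asarray(omega, dtype=float)
    S2 = np.asarray(S2, dtype=float)
    j = S2 * tau_c / (1.0 + (omega * tau_c) ** 2)
    if np.any(np.asarray(tau_e) > 0):
        tau = 1.0 / (1.0 / tau_c + 1.0 / np.asarray(tau_e))
        j = j + (1.0 - S2) * tau / (1.0 + (omega * tau) ** 2)
    return 0.4 * j


def _dipolar_csa(field: FieldSpec):
    d = MU0 / (4 * np.pi) * HBAR * GAMMA_H * abs(GAMMA_N) / R_NH**3  # rad/s
    c = field.omega_N * abs(CSA_N) / np.sqrt(3.0)
    return d * d, c * c


def relaxation_rates(S2, tau_c, tau_e, field: FieldSpec):
    """(R1, R2, NOE) for given model-free parameters at the stated field.

    R1 = (d2/4)[J(wH-wN) + 3 J(wN) + 6 J(wH+wN)] + c2 J(wN)
    R2 = (d2/8)[4 J(0) + J(wH-wN) + 3 J(wN) + 6 J(wH) + 6 J(wH+wN)]
         + (c2/6)[4 J(0) + 3 J(wN)]
    NOE = 1 + (d2 / 4 R1) (gammaH/gammaN) [6 J(wH+wN) - J(wH-wN)]
    """
    d2, c2 = _dipolar_csa(field)
    wN, wH = field.omega_N, field.omega_H
    J = lambda w: spectral_density(w, S2, tau_c, tau_e)
    R1 = d2 / 4.0 * (J(wH - wN) + 3 * J(wN) + 6 * J(wH + wN)) + c2 * J(wN)
    R2 = (
        d2 / 8.0 * (4 * J(0.0) + J(wH - wN) + 3 * J(wN) + 6 * J(wH) + 6 * J(wH + wN))
        + c2 / 6.0 * (4 * J(0.0) + 3 * J(wN))
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        noe = 1.0 + d2 / (4.0 * R1) * (GAMMA_H / GAMMA_N) * (6 * J(wH + wN) - J(wH - wN))
    return R1, R2, noe


# ---------------------------------------------------------------------------
# inversion
# ---------------------------------------------------------------------------

def _rate_coefficients(tau_c, field):
    """R1 and R2 are linear in S2 when tau_e = 0: R = a * S2."""
    a1, a2, _ = relaxation_rates(1.0, tau_c, 0.0, field)
    return a1, a2


def _residue_fit_s2(R1, R2, noe, w, tau_c, field):
    """Closed-form weighted LSQ of S2 (tau_e = 0) against (R1, R2, NOE).

    With tau_e = 0 both rates scale linearly with S2 and the NOE is
    independent of S2, so the optimum is a weighted linear regression; the
    NOE residual still contributes to chi2 and hence to the tau_c search.
    """
    a1, a2 = _rate_coefficients(tau_c, field)
    w1, w2, w3 = w
    s2 = (w1 * a1 * R1 + w2 * a2 * R2) / (w1 * a1**2 + w2 * a2**2)
    s2 = np.clip(s2, 0.0, 1.0)
    _, _, noe_pred = relaxation_rates(1.0, tau_c, 0.0, field)
    chi2 = (
        w1 * (a1 * s2 - R1) ** 2
        + w2 * (a2 * s2 - R2) ** 2
        + w3 * (noe_pred - noe) ** 2
    )
    return s2, chi2


def _residue_fit_s2_taue(R1, R2, noe, w, tau_c, field):
    sw = np.sqrt(np.asarray(w, dtype=float))

    def resid(p):
        s2, te = p
        r1, r2, nn = relaxation_rates(s2, tau_c, te * 1e-12, field)
        return sw * np.array([r1 - R1, r2 - R2, nn - noe])

    best = None
    for te0 in (5.0, 50.0, 500.0):
        try:
            res = least_squares(resid, [0.8, te0], bounds=([0.0, 0.0], [1.0, 5000.0]))
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return None
    s2, te = best.x
    return s2, te, float(2.0 * best.cost)


def _global_chi2(tau_c, data, weights, field, model):
    total = 0.0
    for (R1, R2, noe), w in zip(data, weights):
        if model == "S2_only":
            _, chi2 = _residue_fit_s2(R1, R2, noe, w, tau_c, field)
        else:
            out = _residue_fit_s2_taue(R1, R2, noe, w, tau_c, field)
            chi2 = out[2] if out is not None else 0.0
        total += chi2
    return total


def _golden_min(f, a, b, tol):
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while abs(b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def fit_modelfree(records, field: FieldSpec, model: str = "S2_only") -> ModelFreeResult:
    """Invert per-residue (T1, T2, NOE) into a global tau_c and S2 values.

    ``records`` is an iterable of dicts or objects with fields residue,
    T1, T2, NOE and optional T1_err/T2_err/NOE_err (inverse-variance
    weights on the corresponding rates; unit weights when absent).

    Two-stage fit: an outer 1-D search of tau_c (60 log-spaced points in
    1-20 ns, then golden-section refinement to 0.01 ns) around an inner
    per-residue weighted least-squares of S2 (and tau_e for the
    S2_and_tau_e model).
    """
    if model not in ("S2_only", "S2_and_tau_e"):
        raise ValidationError(f"unknown model {model!r}")
    recs = list(records)
    if len(recs) < 5:
        raise ValidationError("need at least 5 residues for a model-free fit")

    def get(r, k, default=None):
        if isinstance(r, dict):
            return r.get(k, default)
        return getattr(r, k, default)

    residues, data, weights = [], [], []
    for r in recs:
        T1, T2, noe = float(get(r, "T1")), float(get(r, "T2")), float(get(r, "NOE"))
        if T1 <= 0 or T2 <= 0:
            raise ValidationError(f"residue {get(r, 'residue')}: T1 and T2 must be positive")
        R1, R2 = 1.0 / T1, 1.0 / T2
        w = []
        for key, rate, T in (("T1_err", R1, T1), ("T2_err", R2, T2), ("NOE_err", None, None)):
            err = get(r, key)
            if err is None or not np.isfinite(err) or err <= 0:
                w.append(1.0)
            elif key == "NOE_err":
                w.append(1.0 / err**2)
            else:
                # sigma(R) = sigma(T) / T^2
                w.append(1.0 / (err / T**2) ** 2)
        residues.append(int(get(r, "residue")))
        data.append((R1, R2, noe))
        weights.append(tuple(w))

    grid = np.geomspace(1e-9, 20e-9, 60)
    chi = [_global_chi2(t, data, weights, field, model) for t in grid]
    k = int(np.argmin(chi))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    tau_c = _golden_min(
        lambda t: _global_chi2(t, data, weights, field, model), lo, hi, 0.01e-9
    )

    per_res, excluded, total_chi2 = [], [], 0.0
    for resnum, (R1, R2, noe), w in zip(residues, data, weights):
        if model == "S2_only":
            s2, chi2 = _residue_fit_s2(R1, R2, noe, w, tau_c, field)
            per_res.append(ResidueModelFree(resnum, float(s2), None, float(chi2)))
            total_chi2 += chi2
        else:
            out = _residue_fit_s2_taue(R1, R2, noe, w, tau_c, field)
            if out is None:
                excluded.append(resnum)
                continue
            s2, te, chi2 = out
            per_res.append(ResidueModelFree(resnum, float(s2), float(te), chi2))
            total_chi2 += chi2
    if not per_res:
        raise FitError("no residue converged in the model-free fit")
    s2s = np.array([p.S2 for p in per_res])
    return ModelFreeResult(
        tau_c=float(tau_c * 1e9),
        per_residue=per_res,
        mean_S2=float(np.mean(s2s)),
        sd_S2=float(np.std(s2s, ddof=1)) if len(s2s) > 1 else 0.0,
        chi2=float(total_chi2),
        model=model,
        excluded=excluded,
    )
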