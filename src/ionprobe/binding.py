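"""One-site binding models: fast-exchange CSP titrations and ITC isotherms.

The protein studied here binds its ligand weakly (Ka of a few hundred M^-1,
i.e. millimolar Kd) while NMR titrations run at ~1 mM protein, so ligand
depletion is substantial and the full 1:1 mass-action quadratic is the
default model.  The no-depletion hyperbola is available as an explicit
option for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, ValidationError
from .formats import ScheduleTable, ShiftTable


# ---------------------------------------------------------------------------
# schedules and fraction bound
# ---------------------------------------------------------------------------

def ligand_schedule(P0: float, V0: float, stock: float, additions) -> ScheduleTable:
    """Dilution-corrected titration schedule.

    Parameters are the initial protein concentration ``P0`` (mM), initial
    volume ``V0`` (uL), ligand stock concentration (mM) and the list of
    added stock volumes (uL).  Step 0 is the zero-ligand point.
    """
    additions = np.asarray(list(additions), dtype=float)
    if np.any(additions <= 0):
        raise ValidationError("all additions must be positive volumes")
    cum_added = np.concatenate([[0.0], np.cumsum(additions)])
    volumes = V0 + cum_added
    return ScheduleTable(
        added_volumes=np.concatenate([[0.0], additions]),
        cumulative_volumes=volumes,
        ligand_totals=stock * cum_added / volumes,
        protein_totals=P0 * V0 / volumes,
    )


def fraction_bound(Ptot, Ltot, Ka, depletion: bool = True):
    """Fraction of protein bound, f_b = [PL]/Ptot, for 1:1 binding.

    Concentrations in mM, Ka in M^-1.  With ``depletion`` (default) [PL] is
    the smaller root of [PL]^2 - (Ptot+Ltot+Kd)[PL] + Ptot*Ltot = 0;
    otherwise the no-depletion hyperbola Ka*L/(1+Ka*L) is used.
    """
    Ptot = np.asarray(Ptot, dtype=float)
    Ltot = np.asarray(Ltot, dtype=float)
    if np.any(Ptot <= 0) or np.any(Ltot < 0):
        raise ValidationError("need Ptot > 0 and Ltot >= 0")
    if Ka <= 0:
        raise ValidationError("Ka must be positive")
    Kd = 1000.0 / Ka  # mM
    if not depletion:
        return (Ltot / Kd) / (1.0 + Ltot / Kd)
    b = Ptot + Ltot + Kd
    disc = b * b - 4.0 * Ptot * Ltot
    # stable smaller quadratic root: 2ac / (b + sqrt(b^2-4ac))
    pl = 2.0 * Ptot * Ltot / (b + np.sqrt(np.maximum(disc, 0.0)))
    return pl / Ptot


# ---------------------------------------------------------------------------
# CSP titration fitting
# ---------------------------------------------------------------------------

@dataclass
class ResidueFit:
    residue: str
    Ka: float           # M^-1
    ddmax: float        # ppm
    rmse: float         # ppm


@dataclass
class BindingFit:
    """Averaged and joint one-site fit over the ligand-sensitive residues."""

    Ka: float                   # M^-1, mean of per-residue fits
    Ka_stderr: float            # standard error of that mean (NaN for n=1)
    per_residue: list[ResidueFit]
    n_sites_used: int
    model: str = "per_residue_average"
    shared_Ka: float | None = None          # joint fit: one Ka, per-residue ddmax
    shared_Ka_stderr: float | None = None


def _csp_model(params, Ptot, Ltot):
    ka, ddmax = params
    return ddmax * fraction_bound(Ptot, Ltot, ka)


def fit_residue_csp(schedule: ScheduleTable, shifts) -> ResidueFit:
    """Fit one residue's |shift change| series to ddmax * f_b(Ka).

    ``shifts`` is the per-step series in ppm (signed values are accepted
    and folded to absolute changes).  Requires >= 4 titration points.
    """
    dd = np.abs(np.asarray(shifts, dtype=float))
    if len(dd) != schedule.n_steps:
        raise ValidationError("shift series length must equal schedule step count")
    if len(dd) < 4:
        raise ValidationError("need at least 4 titration points")
    if np.all(dd == 0):
        raise FitError("residue not ligand-sensitive: all shift changes are zero")
    Ptot, Ltot = schedule.protein_totals, schedule.ligand_totals

    # Ka start from the half-saturation ligand concentration
    half = dd[-1] / 2.0
    above = np.flatnonzero(dd >= half)
    L_half = Ltot[above[0]] if len(above) and Ltot[above[0]] > 0 else max(Ltot[-1] / 2, 1e-3)
    ka0 = 1000.0 / L_half  # M^-1

    best = None
    for ka_start in (ka0 / 10.0, ka0, ka0 * 10.0):
        try:
            res = least_squares(
                lambda p: _csp_model(p, Ptot, Ltot) - dd,
                x0=[ka_start, max(dd[-1], 1e-3)],
                bounds=([1e-6, 0.0], [1e9, np.inf]),
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        raise FitError(
            "CSP fit did not converge",
            last_iterate=None if best is None else best.x,
        )
    ka, ddmax = best.x
    rmse = float(np.sqrt(np.mean((_csp_model(best.x, Ptot, Ltot) - dd) ** 2)))
    return ResidueFit(residue="", Ka=float(ka), ddmax=float(ddmax), rmse=rmse)


def _fit_shared_ka(schedule, dd_matrix):
    """Joint fit: one global Ka, one ddmax per residue. Returns (Ka, stderr)."""
    Ptot, Ltot = schedule.protein_totals, schedule.ligand_totals
    n_res = dd_matrix.shape[0]

    def resid(p):
        ka = p[0]
        ddmax = p[1:]
        fb = fraction_bound(Ptot, Ltot, ka)
        return (ddmax[:, None] * fb[None, :] - dd_matrix).ravel()

    x0 = np.concatenate([[500.0], dd_matrix[:, -1].clip(min=1e-3)])
    res = least_squares(resid, x0, bounds=([1e-6] + [0.0] * n_res, np.inf))
    if not res.success:
        raise FitError("shared-Ka joint fit did not converge", last_iterate=res.x)
    # stderr from the Jacobian at the optimum
    dof = max(res.fun.size - res.x.size, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        ka_err = float(np.sqrt(cov[0, 0]))
    except np.linalg.LinAlgError:
        ka_err = float("nan")
    return float(res.x[0]), ka_err


def fit_average_ka(
    schedule: ScheduleTable,
    shift_table: ShiftTable,
    sensitivity_threshold: float = 0.3,
) -> BindingFit:
    """Per-residue one-site fits averaged over the ligand-sensitive residues.

    Residues whose maximum |shift change| reaches ``sensitivity_threshold``
    (ppm) are fitted individually; the reported Ka is the mean of the
    per-residue constants with its standard error across residues.  A
    shared-Ka joint fit (one Ka, per-residue amplitudes) is reported
    alongside as a consistency check.
    """
    if sensitivity_threshold < 0:
        raise ValidationError("sensitivity threshold must be non-negative")
    dd = np.abs(shift_table.shifts)
    if shift_table.is_delta is False:
        dd = np.abs(shift_table.shifts - shift_table.shifts[:, :1])
    maxima = dd.max(axis=1)
    keep = np.flatnonzero(maxima >= sensitivity_threshold)
    if len(keep) == 0:
        raise ValidationError(
            f"no residue reaches the {sensitivity_threshold} ppm sensitivity "
            f"threshold (largest observed maximum: {maxima.max():.3f} ppm)"
        )
    fits = []
    for i in keep:
        f = fit_residue_csp(schedule, dd[i])
        f.residue = shift_table.residue_label(i)
        fits.append(f)
    kas = np.array([f.Ka for f in fits])
    mean_ka = float(np.mean(kas))
    stderr = float(np.std(kas, ddof=1) / np.sqrt(len(kas))) if len(kas) > 1 else float("nan")
    shared_ka, shared_err = _fit_shared_ka(schedule, dd[keep])
    return BindingFit(
        Ka=mean_ka,
        Ka_stderr=stderr,
        per_residue=fits,
        n_sites_used=len(fits),
        model="per_residue_average",
        shared_Ka=shared_ka,
        shared_Ka_stderr=shared_err,
    )


# ---------------------------------------------------------------------------
# ITC
# ---------------------------------------------------------------------------

@dataclass
class ITCExperiment:
    """Cell geometry and injection series of a titration calorimetry run.

    Volumes in uL, cell protein in uM, syringe ligand in mM, heats in ucal
    (absent when predicting).
    """

    cell_volume: float
    cell_protein: float
    syringe_ligand: float
    injection_volumes: np.ndarray
    heats: np.ndarray | None = None

    def __post_init__(self):
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if self.cell_volume <= 0 or self.cell_protein <= 0 or self.syringe_ligand <= 0:
            raise ValidationError("cell volume and concentrations must be positive")
        if np.any(self.injection_volumes <= 0):
            raise ValidationError("injection volumes must be positive")
        if self.heats is not None:
            self.heats = np.asarray(self.heats, dtype=float)
            if len(self.heats) != len(self.injection_volumes):
                raise ValidationError("one heat per injection required")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)


@dataclass
class ITCFit:
    Ka: float               # M^-1
    Ka_stderr: float
    dH: float               # cal per mole of complex
    dH_stderr: float
    n: float                # stoichiometry
    n_stderr: float
    baseline: float         # ucal per injection (heat of dilution)
    c_value: float          # n * Ka * [cell protein]
    low_c_flag: bool        # Ka poorly identifiable when c < 1
    rmse: float             # ucal


def itc_predict_heats(exp: ITCExperiment, Ka: float, dH: float, n: float = 1.0) -> np.ndarray:
    """Per-injection heats (ucal) of the one-site isotherm.

    Cumulative heat Q_i = n * Ptot_i * dH * V0 * f_b with the binding-site
    concentration n*Ptot_i in the mass-action quadratic; the per-injection
    signal is differenced with the standard displaced-volume correction
    dQ_i = Q_i - Q_{i-1} + (dV_i/V0) * (Q_i + Q_{i-1}) / 2.
    """
    V0_L = exp.cell_volume * 1e-6
    cum = np.cumsum(exp.injection_volumes)
    volumes = exp.cell_volume + cum
    Ptot = exp.cell_protein * 1e-3 * exp.cell_volume / volumes     # mM
    Ltot = exp.syringe_ligand * cum / volumes                      # mM
    fb = fraction_bound(np.maximum(n * Ptot, 1e-30), Ltot, Ka)
    Q = n * (Ptot * 1e-3) * dH * V0_L * fb * 1e6                   # ucal
    Qprev = np.concatenate([[0.0], Q[:-1]])
    dV = exp.injection_volumes / exp.cell_volume
    return Q - Qprev + dV * (Q + Qprev) / 2.0


def fit_itc(exp: ITCExperiment, fix_n: float | None = None, fit_baseline: bool = True) -> ITCFit:
    """Least-squares one-site fit of an injection-heat series.

    Fits (Ka, dH, n, baseline); ``fix_n`` pins the stoichiometry, which is
    essential in the low-c regime where n and Ka are nearly degenerate.
    ``fit_baseline=False`` pins the per-injection heat-of-dilution offset
    at zero — appropriate when a blank titration has already been
    subtracted.  A ``low_c_flag`` marks fits with c = n*Ka*[P] < 1, where
    Ka is poorly determined by construction of the experiment.
    """
    if exp.heats is None:
        raise ValidationError("fit_itc requires measured heats")
    if exp.n_injections < 5:
        raise ValidationError("need at least 5 injections")
    heats = exp.heats
    scale = np.max(np.abs(heats))
    if scale == 0:
        # nothing to fit: a flat, zero isotherm
        return ITCFit(
            Ka=float("nan"), Ka_stderr=float("nan"), dH=0.0, dH_stderr=0.0,
            n=fix_n if fix_n is not None else float("nan"), n_stderr=float("nan"),
            baseline=0.0, c_value=0.0, low_c_flag=True, rmse=0.0,
        )

    free_n = fix_n is None

    def unpack(p):
        ka, dh = p[0], p[1]
        base = p[2] if fit_baseline else 0.0
        nn = p[-1] if free_n else fix_n
        return ka, dh, nn, base

    def resid(p):
        ka, dh, nn, base = unpack(p)
        return itc_predict_heats(exp, ka, dh, nn) + base - heats

    dh0 = np.sum(heats) / (exp.cell_protein * 1e-6 * exp.cell_volume * 1e-6) / 1e6
    dh0 = dh0 if abs(dh0) > 1e-6 else np.sign(np.sum(heats) or 1.0)
    best = None
    for ka0 in (50.0, 500.0, 5000.0):
        x0 = [ka0, dh0] + ([0.0] if fit_baseline else []) + ([1.0] if free_n else [])
        lo = [1e-3, -1e12] + ([-np.inf] if fit_baseline else []) + ([0.05] if free_n else [])
        hi = [1e9, 1e12] + ([np.inf] if fit_baseline else []) + ([10.0] if free_n else [])
        try:
            res = least_squares(resid, x0, bounds=(lo, hi), x_scale="jac", max_nfev=5000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    # in the low-c regime the (n, dH) valley is nearly flat, so the solver
    # may stop on its evaluation budget with the cost long since stationary;
    # only a genuinely non-stationary stop is treated as failure
    if best is None or (not best.success and best.optimality > 1e-3 * max(1.0, best.cost)):
        raise FitError("ITC fit did not converge", last_iterate=None if best is None else best.x)

    ka, dh, nn, base = unpack(best.x)
    dof = max(best.fun.size - best.x.size, 1)
    s2 = 2.0 * best.cost / dof
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            # a true inverse, so a sloppy (e.g. n*dH degenerate) direction
            # shows up as the large uncertainty it is
            cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
            errs = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            errs = np.full(best.x.size, np.inf)
    c_value = nn * ka * exp.cell_protein * 1e-6
    return ITCFit(
        Ka=float(ka),
        Ka_stderr=float(errs[0]),
        dH=float(dh),
        dH_stderr=float(errs[1]),
        n=float(nn),
        n_stderr=float(errs[-1]) if free_n else 0.0,
        baseline=float(base),
        c_value=float(c_value),
        low_c_flag=bool(c_value < 1.0),
        rmse=float(np.sqrt(np.mean(best.fun**2))),
    )
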