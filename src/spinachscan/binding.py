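"""Two-state ligand-binding thermodynamics from fluorescence titrations.

The aptamer S and fluorogen D form a fluorescent complex SD governed by a
single dissociation constant K_d = [S][D]/[SD].  With ligand in excess the
fraction of aptamer in complex — and hence the normalized fluorescence —
follows the rectangular hyperbola

    f(D) = (D/K_d) / (1 + D/K_d),

so a titration series (12 DFHBI concentrations spanning 0.435-43.5 uM by
default) is fit by nonlinear least squares to  signal = A * f(D)  with the
plateau amplitude A free.  Mutant effects are expressed relative to wild
type as dissociation-constant ratios:

    ddG(T) = -R T ln(K_d^m / K_d^wt)        (as printed)

with the ``favorable_negative`` convention negating this so that tighter
binders carry negative ddG.  The binding enthalpy comes from the linear
Van't Hoff regression of ln K_d on 1/T across titrations repeated at
three temperatures (19, 23 and 28 C by default):

    ln K_d = -dH/(R T) + dS/R.

Applied literally to a *dissociation* constant, the slope-derived dH is
the enthalpy of complex dissociation; the binding enthalpy is its
negative (``dh_binding``), negative for exothermic binding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import lmfit
import numpy as np
from scipy import stats

from .constants import R_KCAL

#: default 12-point DFHBI concentration series (uM), two decades
DEFAULT_CONC_UM = tuple(np.geomspace(0.435, 43.5, 12))
#: default binding-assay temperatures (Celsius)
DEFAULT_BINDING_TEMPS_C = (19.0, 23.0, 28.0)


class InsufficientDataError(ValueError):
    """Too few points (or too few distinct temperatures) to fit."""


def fraction_bound(conc, kd):
    """Fraction of aptamer in complex at free-ligand concentration ``conc``.

    Strictly increasing in ``conc``, approaching 1 as conc -> inf; equals
    1/2 at conc = kd.  Units of conc and kd must match.
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("ligand concentration must be non-negative")
    if np.any(np.asarray(kd) <= 0):
        raise ValueError("Kd must be positive")
    x = conc / kd
    return x / (1.0 + x)


@dataclass
class BindingFit:
    kd: float | None            # uM
    kd_stderr: float | None
    amplitude: float | None     # plateau signal, S_m units
    amplitude_stderr: float | None
    converged: bool
    fluorogenic: bool
    residual_norm: float | None
    n_points: int

    @property
    def flags(self) -> list[str]:
        out = []
        if not self.fluorogenic:
            out.append("non_fluorogenic")
        if self.fluorogenic and not self.converged:
            out.append("fit_failed")
        return out


def _binding_residual(params, conc, signal):
    return params["amplitude"] * fraction_bound(conc, params["kd"]) - signal


def fit_binding(
    conc,
    signal,
    fluorogenic_threshold: float = 0.0,
    normalize_at_max: bool = False,
) -> BindingFit:
    """Fit  signal = amplitude * fraction_bound(conc, kd)  by bounded
    trust-region least squares, multi-started from three log-spaced Kd
    initials.

    ``fluorogenic_threshold``: a curve whose maximum signal does not
    exceed this value is flagged non-fluorogenic and not fit (default 0:
    only identically non-positive curves are excluded; pipelines supply a
    threshold calibrated on negative controls).

    ``normalize_at_max`` reproduces the normalize-to-highest-concentration
    procedure: the signal is divided by its value at the top concentration
    and the amplitude is fixed at 1, leaving Kd the only free parameter.
    The default free-amplitude fit avoids the plateau bias this incurs
    when the top concentration is only a few tens of Kd.
    """
    conc = np.asarray(conc, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if conc.shape != signal.shape:
        raise ValueError("conc and signal must have the same length")
    if conc.size < 4:
        raise InsufficientDataError("need at least 4 concentration points")
    if np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be strictly ascending")

    if np.max(signal) <= fluorogenic_threshold:
        return BindingFit(None, None, None, None, False, False, None, conc.size)

    if normalize_at_max:
        top = signal[-1]
        if top <= 0:
            return BindingFit(None, None, None, None, False, False, None, conc.size)
        signal = signal / top

    kd_lo, kd_hi = 0.01 * conc.min(), 100.0 * conc.max()
    amp_guess = max(float(np.max(signal)), 1e-12)
    best = None
    for kd0 in np.geomspace(max(conc.min(), kd_lo * 10), min(conc.max(), kd_hi / 10), 3):
        params = lmfit.Parameters()
        params.add("kd", value=float(kd0), min=kd_lo, max=kd_hi)
        if normalize_at_max:
            params.add("amplitude", value=1.0, vary=False)
        else:
            params.add("amplitude", value=amp_guess, min=1e-12, max=1e6)
        try:
            with warnings.catch_warnings():
                # zero-residual (noiseless) fits make lmfit's correlation
                # matrix divide by zero; the parameters are still exact
                warnings.simplefilter("ignore", RuntimeWarning)
                res = lmfit.minimize(
                    _binding_residual,
                    params,
                    args=(conc, signal),
                    method="least_squares",
                    ftol=1e-14, xtol=1e-14, gtol=1e-14,
                )
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        return BindingFit(None, None, None, None, False, True, None, conc.size)
    p = best.params
    return BindingFit(
        kd=float(p["kd"].value),
        kd_stderr=(float(p["kd"].stderr) if p["kd"].stderr is not None else None),
        amplitude=float(p["amplitude"].value),
        amplitude_stderr=(
            float(p["amplitude"].stderr) if p["amplitude"].stderr is not None else None
        ),
        converged=bool(best.success),
        fluorogenic=True,
        residual_norm=float(np.sqrt(best.chisqr)),
        n_points=conc.size,
    )


def delta_delta_g(
    kd_mutant: float,
    kd_wildtype: float,
    temperature_K: float,
    sign_convention: str = "favorable_negative",
) -> float:
    """Mutational change in binding free energy, kcal/mol.

    ``as_printed``:  -R T ln(kd_mutant / kd_wildtype)  — positive for a
    tighter binder.  ``favorable_negative`` (default) negates this so a
    tighter binder carries negative ddG, matching the usual stability
    convention.  Antisymmetric under swapping the two Kd.
    """
    if kd_mutant <= 0 or kd_wildtype <= 0 or temperature_K <= 0:
        raise ValueError("Kd values and temperature must be positive")
    value = -R_KCAL * temperature_K * np.log(kd_mutant / kd_wildtype)
    if sign_convention == "as_printed":
        return float(value)
    if sign_convention == "favorable_negative":
        return float(-value)
    raise ValueError(f"unknown sign convention {sign_convention!r}")


@dataclass
class VantHoffFit:
    """Literal inversion of the linear Van't Hoff form on ln K_d vs 1/T.

    ``dh``/``ds`` follow the printed form (slope = -dH/R, intercept =
    dS/R) and therefore describe complex *dissociation* when the fitted
    constant is K_d; ``dh_binding``/``ds_binding`` negate them into the
    binding convention (exothermic binding => dh_binding < 0).  dS depends
    on the concentration standard state (molar here); dH does not.
    """

    dh: float                   # kcal/mol
    ds: float                   # kcal/(mol K)
    dh_stderr: float | None
    ds_stderr: float | None
    r_squared: float
    n_points: int

    @property
    def dh_binding(self) -> float:
        return -self.dh

    @property
    def ds_binding(self) -> float:
        return -self.ds


def vant_hoff(points) -> VantHoffFit:
    """Ordinary least squares of ln K_d (molar) on 1/T.

    ``points``: iterable of (temperature_K, kd_uM) with at least two
    distinct temperatures.  Recovers the generating (dH, dS) exactly on
    noiseless input.
    """
    pts = [(float(t), float(kd)) for t, kd in points]
    if any(t <= 0 or kd <= 0 for t, kd in pts):
        raise ValueError("temperatures and Kd must be positive")
    temps = np.array([t for t, _ in pts])
    kds_molar = np.array([kd * 1e-6 for _, kd in pts])
    if np.unique(temps).size < 2:
        raise InsufficientDataError("need Kd at >= 2 distinct temperatures")
    x = 1.0 / temps
    y = np.log(kds_molar)
    fit = stats.linregress(x, y)
    dh = -fit.slope * R_KCAL
    ds = fit.intercept * R_KCAL
    dh_se = fit.stderr * R_KCAL if np.isfinite(fit.stderr) else None
    ds_se = fit.intercept_stderr * R_KCAL if np.isfinite(fit.intercept_stderr) else None
    r2 = float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 1.0
    return VantHoffFit(
        dh=float(dh), ds=float(ds),
        dh_stderr=dh_se, ds_stderr=ds_se,
        r_squared=r2, n_points=len(pts),
    )


def kd_at_temperature(
    kd_ref_uM: float, dh_binding: float, t_ref_K: float, t_K
):
    """Extrapolate K_d along its Van't Hoff line.

    ``dh_binding`` is the binding-convention enthalpy (kcal/mol, negative
    = exothermic), so K_d shrinks as temperature drops for an exothermic
    binder:  ln Kd(T) = ln Kd(T_ref) + (dh_binding/R) (1/T - 1/T_ref).
    """
    if kd_ref_uM <= 0 or t_ref_K <= 0:
        raise ValueError("reference Kd and temperature must be positive")
    t_K = np.asarray(t_K, dtype=float)
    return kd_ref_uM * np.exp((dh_binding / R_KCAL) * (1.0 / t_K - 1.0 / t_ref_K))
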