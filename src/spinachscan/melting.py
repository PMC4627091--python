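"""Two-state thermal stability of the aptamer-fluorogen complex.

A melt series holds the ligand saturating (43.5 uM) and ramps temperature
(23 to 49 C in 2 C steps by default) while the fluorescence tracks the
folded fraction of the complex.  For a two-state folded/unfolded
equilibrium with unfolding enthalpy dH_T and apparent midpoint
T_m^ap = dH_T/dS_T, the folded fraction is the logistic-in-1/T curve

    f(T) = 1 / (1 + exp[(dH_T/R) (1/T_m^ap - 1/T)]),

which equals 1/2 at T = T_m^ap and decreases with temperature for
dH_T > 0.  Note the model's hot asymptote is 1/(1 + exp[dH_T/(R T_m)]),
not exactly zero.  Curves are fit by bounded nonlinear least squares to
signal = amplitude * f(T); misfolding variants that are dark at both
temperature extremes but fluoresce in between (a rise-then-fall melt) are
flagged by a robust interior-peak detector rather than forced through the
two-state model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import lmfit
import numpy as np
from scipy import signal as sps

from .constants import R_KCAL, celsius_to_kelvin

#: default melt grid: 23..49 C in 2 C steps (14 points)
DEFAULT_MELT_TEMPS_C = tuple(float(t) for t in range(23, 51, 2))
#: DFHBI concentration held during melts (uM)
DEFAULT_MELT_CONC_UM = 43.5


class InsufficientDataError(ValueError):
    pass


def fraction_folded(temperature_K, tm_K, dh_t):
    """Folded fraction of the complex at ``temperature_K``.

    ``dh_t`` is the unfolding enthalpy in kcal/mol (positive for a
    cooperative transition); equals 0.5 exactly at T = tm_K.
    """
    temperature_K = np.asarray(temperature_K, dtype=float)
    if np.any(temperature_K <= 0) or np.any(np.asarray(tm_K) <= 0):
        raise ValueError("temperatures must be positive kelvin")
    exponent = (dh_t / R_KCAL) * (1.0 / tm_K - 1.0 / temperature_K)
    # clip to keep exp finite; 700 is past double overflow anyway
    return 1.0 / (1.0 + np.exp(np.clip(exponent, -700, 700)))


@dataclass
class MeltFit:
    tm: float | None            # kelvin
    tm_stderr: float | None
    dh_t: float | None          # kcal/mol, unfolding
    dh_t_stderr: float | None
    amplitude: float | None
    converged: bool
    no_transition: bool
    bimodal: bool
    residual_norm: float | None
    n_points: int

    @property
    def tm_celsius(self) -> float | None:
        return None if self.tm is None else self.tm - 273.15

    @property
    def flags(self) -> list[str]:
        out = []
        if self.no_transition:
            out.append("no_transition")
        if self.bimodal:
            out.append("bimodal")
        if not self.no_transition and not self.converged:
            out.append("fit_failed")
        return out


def _melt_residual(params, temps_K, signal):
    return params["amplitude"] * fraction_folded(
        temps_K, params["tm"], params["dh_t"]
    ) - signal


def fit_melting(
    temps_K,
    signal,
    amplitude_mode: str = "free",
    check_bimodal: bool = True,
) -> MeltFit:
    """Fit  signal = amplitude * fraction_folded(T, Tm, dH_T).

    ``amplitude_mode``: 'free' fits the cold-plateau amplitude (robust to
    a noisy first point); 'anchor_low' fixes it to the lowest-temperature
    signal, the normalize-to-S_low convention (the two coincide for clean
    monotone melts).

    A curve with no signal anywhere, or monotonically increasing signal,
    carries the ``no_transition`` flag and is not fit.  Rise-then-fall
    curves are additionally flagged ``bimodal``.
    """
    temps_K = np.asarray(temps_K, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if temps_K.shape != signal.shape:
        raise ValueError("temperature and signal must have the same length")
    if temps_K.size < 5:
        raise InsufficientDataError("need at least 5 temperature points")
    if np.any(np.diff(temps_K) <= 0):
        raise ValueError("temperatures must be strictly ascending")

    bimodal = detect_bimodal(temps_K, signal)[0] if (check_bimodal and temps_K.size >= 7) else False

    span = float(np.max(signal) - np.min(signal))
    if np.max(signal) <= 0 or span <= 0 or np.all(np.diff(signal) >= 0):
        return MeltFit(None, None, None, None, None, False, True, bimodal, None, temps_K.size)

    amp0 = max(float(signal[0]), float(np.max(signal)), 1e-12)
    tm0 = float(temps_K[np.argmin(np.abs(signal - 0.5 * np.max(signal)))])
    params = lmfit.Parameters()
    params.add("tm", value=tm0, min=temps_K.min() - 15.0, max=temps_K.max() + 15.0)
    params.add("dh_t", value=40.0, min=0.5, max=400.0)
    if amplitude_mode == "anchor_low":
        params.add("amplitude", value=float(signal[0]), vary=False)
    elif amplitude_mode == "free":
        params.add("amplitude", value=amp0, min=1e-12, max=1e6)
    else:
        raise ValueError(f"unknown amplitude_mode {amplitude_mode!r}")
    with warnings.catch_warnings():
        # zero-residual fits trip lmfit's correlation-matrix division
        warnings.simplefilter("ignore", RuntimeWarning)
        res = lmfit.minimize(
            _melt_residual,
            params,
            args=(temps_K, signal),
            method="least_squares",
            ftol=1e-14, xtol=1e-14, gtol=1e-14,
        )
    p = res.params
    return MeltFit(
        tm=float(p["tm"].value),
        tm_stderr=(float(p["tm"].stderr) if p["tm"].stderr is not None else None),
        dh_t=float(p["dh_t"].value),
        dh_t_stderr=(float(p["dh_t"].stderr) if p["dh_t"].stderr is not None else None),
        amplitude=float(p["amplitude"].value),
        converged=bool(res.success),
        no_transition=False,
        bimodal=bimodal,
        residual_norm=float(np.sqrt(res.chisqr)),
        n_points=temps_K.size,
    )


def detect_bimodal(temps, signal):
    """Flag rise-then-fall melting profiles (interior fluorescence maximum
    with low signal at both temperature extremes) — the signature of a
    variant that only folds transiently at intermediate temperature.

    The curve is smoothed with a 3-point moving average; an interior peak
    qualifies when it stands above *both* endpoints by more than 3x the
    robust point-to-point noise scale (1.4826 * MAD of first differences /
    sqrt(2)).  Returns ``(flag, diagnostics)``; ambiguous input yields
    ``(False, ...)``.
    """
    signal = np.asarray(signal, dtype=float)
    temps = np.asarray(temps, dtype=float)
    if signal.size < 7:
        return False, {"reason": "too_few_points"}
    kernel = np.ones(3) / 3.0
    smooth = np.convolve(signal, kernel, mode="valid")  # length n-2
    diffs = np.diff(signal)
    mad = np.median(np.abs(diffs - np.median(diffs)))
    noise = 1.4826 * mad / np.sqrt(2.0)
    threshold = max(3.0 * noise, 1e-12)
    peaks, props = sps.find_peaks(smooth, prominence=threshold)
    interior = [
        p for p in peaks
        if smooth[p] - smooth[0] > threshold and smooth[p] - smooth[-1] > threshold
    ]
    if not interior:
        return False, {"noise": noise, "n_peaks": len(peaks)}
    best = max(interior, key=lambda p: smooth[p])
    peak_temp = float(temps[best + 1])  # +1: 'valid' convolution trim
    return True, {
        "noise": noise,
        "peak_temperature": peak_temp,
        "peak_height": float(smooth[best]),
        "edge_excess": float(min(smooth[best] - smooth[0], smooth[best] - smooth[-1])),
    }


def melt_grid_celsius(start: float = 23.0, stop: float = 49.0, step: float = 2.0):
    """Kelvin temperature grid for a melt ramp given in Celsius."""
    n = int(round((stop - start) / step)) + 1
    return celsius_to_kelvin(start + step * np.arange(n))
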