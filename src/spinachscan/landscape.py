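"""Landscape assembly, per-position scoring, candidate selection and
compensatory-rescue analysis.

Four per-mutant parameters make up the landscapes: the saturating
fluorescence S_m, the binding free-energy change ddG, the binding
enthalpy change ddH and the melting-temperature change dTm (all relative
to wild type).  For scoring, each parameter is min-max normalized over
the fluorogenic SPMs to X_i in [0, 1] after orienting it so larger means
more beneficial (higher S_m, more favorable ddG/ddH under the
favorable-negative convention, higher dTm); non-fluorogenic SPMs carry
X_i = -1.  The four X_i sum to a per-SPM score S_j in [-4, 4]; the three
SPMs at a position are averaged and a 3-position moving window (truncated
at the termini) smooths the track into Score(n).  Paired stem positions
produce mirror-symmetric score tracks — the structural readout.

Parameter uncertainties combine the replicate scatter with the per-fit
standard errors:

    sigma = sqrt( (sum_j (X_j - Xbar)^2 / ((N-1) N))^2
                  + ((1/N) sum_j sigma_j^2)^2 )          ('as_printed')

as well as the conventional quadrature alternative
sqrt(SEM^2 + mean(sigma_j^2)).  The printed form squares quantities that
are already variances, so its two addends carry fourth-power units; it is
retained verbatim as one of the two modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: landscape parameters and the sign that makes "larger = more beneficial"
PARAMETER_ORIENTATION = {
    "s_m": +1.0,
    "ddg": -1.0,   # favorable_negative: more negative = tighter binding
    "ddh": -1.0,   # more negative = more exothermic binding
    "dtm": +1.0,
}
PARAMETERS = tuple(PARAMETER_ORIENTATION)

NONFLUOROGENIC_SCORE = -1.0


class DegenerateRangeError(ValueError):
    """All parameter values identical: min-max normalization undefined."""


class InsufficientDataError(ValueError):
    pass


@dataclass
class ThermoRecord:
    """One mutant's landscape entry (values relative to wild type)."""

    mutant_id: str
    positions: tuple[int, ...]
    s_m: float | None
    ddg: float | None
    ddh: float | None
    dtm: float | None
    sigma: dict = field(default_factory=dict)
    fluorogenic: bool = True
    flags: tuple[str, ...] = ()

    def parameter(self, name: str):
        return getattr(self, name)


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "mutant_id": r.mutant_id,
                "positions": ";".join(str(p) for p in r.positions),
                "s_m": r.s_m,
                "ddg": r.ddg,
                "ddh": r.ddh,
                "dtm": r.dtm,
                "sigma_s_m": r.sigma.get("s_m", np.nan),
                "sigma_ddg": r.sigma.get("ddg", np.nan),
                "sigma_ddh": r.sigma.get("ddh", np.nan),
                "sigma_dtm": r.sigma.get("dtm", np.nan),
                "fluorogenic": r.fluorogenic,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows)


def normalize_parameter(values, fluorogenic, orientation: float = 1.0):
    """Min-max normalize one parameter over fluorogenic SPMs to [0, 1].

    ``orientation`` (+1/-1) is applied before normalization so that
    X = 1 is always the most beneficial SPM.  Non-fluorogenic entries map
    to -1.  The result is invariant under any positive-affine transform
    of the input.  Raises :class:`DegenerateRangeError` when fewer than
    two distinct finite values exist among fluorogenic SPMs.
    """
    values = np.asarray(values, dtype=float) * orientation
    fluorogenic = np.asarray(fluorogenic, dtype=bool)
    live = fluorogenic & np.isfinite(values)
    if np.unique(values[live]).size < 2:
        raise DegenerateRangeError("need >= 2 distinct finite fluorogenic values")
    lo, hi = values[live].min(), values[live].max()
    x = np.full(values.shape, NONFLUOROGENIC_SCORE)
    x[live] = (values[live] - lo) / (hi - lo)
    return x


def score_spms(frame: pd.DataFrame, parameters=PARAMETERS) -> pd.DataFrame:
    """Per-SPM combined score S_j: sum of the four oriented X_i.

    ``frame`` is a landscape table (one row per SPM) with the parameter
    columns and a ``fluorogenic`` column.  A fluorogenic SPM missing any
    parameter is an incomplete record and raises.  Returns a copy with
    X_<param> columns and ``score``; S_j is bounded by [-4, 4].
    """
    out = frame.copy()
    fl = out["fluorogenic"].to_numpy(dtype=bool)
    for p in parameters:
        vals = out[p].to_numpy(dtype=float)
        if np.any(fl & ~np.isfinite(vals)):
            bad = out.loc[fl & ~np.isfinite(vals), "mutant_id"].tolist()
            raise ValueError(f"fluorogenic SPMs missing {p!r}: {bad[:5]}")
        out[f"X_{p}"] = normalize_parameter(vals, fl, PARAMETER_ORIENTATION[p])
    out["score"] = sum(out[f"X_{p}"] for p in parameters)
    return out


def position_score(
    scored: pd.DataFrame,
    n_positions: int,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Per-position smoothed score track Score(n).

    The (up to three) SPM scores at each position are aggregated (mean by
    default, 'max' optional), then a moving average over the window
    {n-1, n, n+1} is applied, truncated at the two termini.  The track
    never leaves the range of the aggregated per-position scores.
    """
    if aggregate not in ("mean", "max"):
        raise ValueError("aggregate must be 'mean' or 'max'")
    pos = scored["positions"].astype(str).str.split(";").str[0].astype(int) \
        if scored["positions"].dtype == object else scored["positions"].astype(int)
    per_pos = scored.assign(_pos=pos).groupby("_pos")["score"].agg(aggregate)
    s = np.full(n_positions, np.nan)
    for p, v in per_pos.items():
        if 1 <= p <= n_positions:
            s[p - 1] = v
    track = np.empty(n_positions)
    for i in range(n_positions):
        window = s[max(0, i - 1): min(n_positions, i + 2)]
        track[i] = np.nanmean(window)
    return pd.DataFrame(
        {"position": np.arange(1, n_positions + 1), "s_position": s, "score": track}
    )


def propagate_error(replicate_values, fit_errors, mode: str = "as_printed") -> float:
    """Combine replicate scatter with per-replicate fit errors.

    'as_printed' squares the squared-error terms before summing (see
    module docstring); 'quadrature' is the conventional
    sqrt(SEM^2 + mean fit variance).  Needs N >= 2 replicates.
    """
    x = np.asarray(replicate_values, dtype=float)
    s = np.asarray(fit_errors, dtype=float)
    if x.size != s.size:
        raise ValueError("replicate values and fit errors must pair up")
    n = x.size
    if n < 2:
        raise InsufficientDataError("error propagation needs >= 2 replicates")
    sem_sq = np.sum((x - x.mean()) ** 2) / ((n - 1) * n)
    fit_sq = np.sum(s**2) / n
    if mode == "as_printed":
        return float(np.sqrt(sem_sq**2 + fit_sq**2))
    if mode == "quadrature":
        return float(np.sqrt(sem_sq + fit_sq))
    raise ValueError(f"unknown mode {mode!r}")


def select_quantiles(
    frame: pd.DataFrame,
    parameter: str,
    q: float = 0.10,
    direction: str | None = None,
    fluorogenic_only: bool = True,
) -> pd.DataFrame:
    """Mutants beyond the empirical q-quantile in the beneficial direction.

    ``direction`` 'high'/'low' overrides the default orientation of the
    parameter (e.g. 'low' for ddG under favorable_negative).  Quantiles
    are the type-7 (linear-interpolation) empirical quantiles; ties at
    the cut are broken by mutant id so the selection is deterministic.
    q = 0 selects nothing.
    """
    if not 0 <= q <= 1:
        raise ValueError("q must lie in [0, 1]")
    sub = frame[frame["fluorogenic"]] if fluorogenic_only else frame
    sub = sub[np.isfinite(sub[parameter].astype(float))]
    if len(sub) < 10:
        raise InsufficientDataError("quantile selection needs >= 10 records")
    if q == 0:
        return sub.iloc[0:0]
    if direction is None:
        direction = "high" if PARAMETER_ORIENTATION.get(parameter, 1.0) > 0 else "low"
    values = sub[parameter].astype(float)
    k = int(np.ceil(q * len(sub)))  # number selected: top/bottom q fraction
    ascending = direction == "low"
    ranked = sub.assign(_v=values).sort_values(
        ["_v", "mutant_id"], ascending=[ascending, True]
    )
    return ranked.head(k).drop(columns="_v")


def intersect_candidates(frame: pd.DataFrame, parameters, q: float = 0.10) -> pd.DataFrame:
    """Mutants present in the beneficial q-quantile of *all* given
    parameters — the engineering shortlist."""
    ids = None
    for p in parameters:
        sel = set(select_quantiles(frame, p, q=q)["mutant_id"])
        ids = sel if ids is None else ids & sel
    ids = ids or set()
    return frame[frame["mutant_id"].isin(ids)].sort_values("mutant_id")


@dataclass
class CompensationRecord:
    pair: tuple[int, int]
    spm_signal: float
    dpm_signal: float
    wt_signal: float
    rescue: float          # clipped to [-1, 2] for reporting; NaN if undefined
    undefined: bool
    element: str = ""      # structural element label (S1/S2/S3/K/Q/L/control)


def rescue_index(spm_signal: float, dpm_signal: float, wt_signal: float) -> float:
    """Fractional recovery of the wild-type signal by the double mutant:
    (S_dpm - S_spm)/(S_wt - S_spm); 1 = full rescue, 0 = none.  Undefined
    (NaN) when the single mutant already matches wild type."""
    denom = wt_signal - spm_signal
    if np.isclose(denom, 0.0):
        return float("nan")
    return (dpm_signal - spm_signal) / denom


def rescue_analysis(
    spm_signals: dict[str, float],
    dpm_table: pd.DataFrame,
    wt_signal: float,
    clip: tuple[float, float] = (-1.0, 2.0),
) -> pd.DataFrame:
    """Score compensatory rescue for a set of double mutants.

    ``dpm_table`` needs columns mutant_id, spm_a, spm_b (constituent SPM
    ids), s_m and optionally element.  For each DPM the *more deleterious*
    constituent (lower signal) anchors the rescue index.  Reported rescue
    is clipped to ``clip``; the unclipped value is kept alongside.
    """
    required = {"mutant_id", "spm_a", "spm_b", "s_m"}
    if not required <= set(dpm_table.columns):
        raise ValueError(f"dpm table needs columns {sorted(required)}")
    rows = []
    for rec in dpm_table.itertuples(index=False):
        missing = [s for s in (rec.spm_a, rec.spm_b) if s not in spm_signals]
        if missing:
            raise KeyError(f"{rec.mutant_id}: no SPM signal for {missing}")
        s_a, s_b = spm_signals[rec.spm_a], spm_signals[rec.spm_b]
        anchor_id, s_spm = (rec.spm_a, s_a) if s_a <= s_b else (rec.spm_b, s_b)
        raw = rescue_index(s_spm, rec.s_m, wt_signal)
        rows.append(
            {
                "mutant_id": rec.mutant_id,
                "anchor_spm": anchor_id,
                "spm_signal": s_spm,
                "dpm_signal": rec.s_m,
                "wt_signal": wt_signal,
                "rescue_raw": raw,
                "rescue": float(np.clip(raw, *clip)) if np.isfinite(raw) else np.nan,
                "undefined": not np.isfinite(raw),
                "element": getattr(rec, "element", ""),
            }
        )
    return pd.DataFrame(rows)


def correlate_landscapes(frame: pd.DataFrame, x_param: str, y_param: str):
    """OLS line and Pearson r between two landscape parameters over
    fluorogenic mutants; returns (slope, intercept, r)."""
    sub = frame[frame["fluorogenic"]] if "fluorogenic" in frame else frame
    x = sub[x_param].astype(float)
    y = sub[y_param].astype(float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise InsufficientDataError("correlation needs >= 3 paired values")
    if np.isclose(np.var(x), 0.0):
        raise ValueError(f"degenerate variance in {x_param!r}: slope undefined")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)


def partner_score_correlation(track: pd.DataFrame, pairs) -> float:
    """Pearson correlation between the smoothed scores of paired stem
    positions — near 1 when base-paired partners share thermodynamic
    profiles (the score-plot symmetry diagnostic)."""
    score = track.set_index("position")["score"]
    a = [score[i] for i, _ in pairs]
    b = [score[j] for _, j in pairs]
    if len(a) < 3:
        raise InsufficientDataError("need >= 3 pairs")
    return float(stats.pearsonr(a, b)[0])
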