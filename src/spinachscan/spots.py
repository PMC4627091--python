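"""Pull-down spot segmentation and background-corrected signal extraction.

Each chip unit cell is imaged in three channels: the aptamer-fluorogen
complex (ex. 470 nm), the surface pull-down anchor (ex. 555 nm) and the
RNA-quantifying probe (ex. 625 nm).  The anchor channel defines the spot:
a generalized (elliptical, rotated, offset) 2D Gaussian is fit and its
iso-contour circle delimits the circular foreground; a surrounding
annulus of outer radius 1.5x the spot radius provides the local
background.  Per channel the *median* over these pixel sets gives the
complex signal S_i, background S_b and probe signal S_p, combined into
the RNA-normalized fluorescence

    S_m = (S_i - S_b) / S_p,

which may legitimately be negative for spots dimmer than their local
background.  Medians make the extraction robust to salt-and-pepper
outliers; the probe foreground median is used uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize


class SegmentationError(RuntimeError):
    """No credible spot could be segmented in the anchor image."""


@dataclass
class SpotGeometry:
    center: tuple[float, float]   # (row, col), sub-pixel
    radius: float                 # foreground radius, px
    sigma: tuple[float, float]    # fitted Gaussian widths (row, col axes)
    theta: float                  # rotation, radians
    amplitude: float
    offset: float

    @property
    def annulus_outer(self) -> float:
        return 1.5 * self.radius


def _gaussian2d(coords, amplitude, r0, c0, sigma_r, sigma_c, theta, offset):
    rr, cc = coords
    ct, st = np.cos(theta), np.sin(theta)
    dr, dc = rr - r0, cc - c0
    u = ct * dc + st * dr
    v = -st * dc + ct * dr
    return offset + amplitude * np.exp(-0.5 * ((u / sigma_c) ** 2 + (v / sigma_r) ** 2))


def fit_spot(anchor: np.ndarray, radius_scale: float = 2.0) -> SpotGeometry:
    """Fit a generalized 2D Gaussian to the anchor image and derive the
    foreground disk.

    The 7-parameter model (amplitude, center, two widths, rotation,
    constant offset) is initialized from intensity moments and fit by
    bounded trust-region least squares.  The foreground radius is
    ``radius_scale * max(sigma)`` (default 2 sigma: >=95% of the spot
    energy), clipped inside the image.  Raises
    :class:`SegmentationError` when the fit fails or the fitted amplitude
    does not clear 3x the residual noise scale — a flat or empty image.
    """
    img = np.asarray(anchor, dtype=float)
    if img.ndim != 2:
        raise ValueError("anchor image must be 2D")
    if not np.all(np.isfinite(img)):
        raise ValueError("anchor image contains non-finite values")
    nr, nc = img.shape
    rr, cc = np.mgrid[0:nr, 0:nc]

    offset0 = float(np.median(img))
    peak = float(img.max())
    if peak - offset0 <= 0:
        raise SegmentationError("no intensity contrast in anchor image")
    weights = np.clip(img - offset0, 0, None)
    wsum = weights.sum()
    if wsum <= 0:
        raise SegmentationError("no positive signal above background")
    r0 = float((rr * weights).sum() / wsum)
    c0 = float((cc * weights).sum() / wsum)
    sigma0 = max(float(np.sqrt(((rr - r0) ** 2 * weights).sum() / wsum)), 1.0)

    p0 = [peak - offset0, r0, c0, sigma0, sigma0, 0.0, offset0]
    lower = [0.0, -1.0, -1.0, 0.3, 0.3, -np.pi / 2, -np.inf]
    upper = [np.inf, nr + 1.0, nc + 1.0, nr, nc, np.pi / 2, np.inf]

    def residual(p):
        return (_gaussian2d((rr, cc), *p) - img).ravel()

    try:
        sol = optimize.least_squares(residual, p0, bounds=(lower, upper), xtol=1e-10)
    except Exception as exc:  # pragma: no cover - scipy internal failures
        raise SegmentationError(f"Gaussian fit failed: {exc}") from exc
    amplitude, r0, c0, sr, sc, theta, offset = sol.x
    resid = sol.fun.reshape(img.shape)
    noise = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    if amplitude <= 3.0 * max(noise, 1e-12):
        raise SegmentationError("fitted amplitude below the noise floor")

    radius = radius_scale * max(sr, sc)
    radius = float(np.clip(radius, 1.0, min(nr, nc) / 3.0))
    return SpotGeometry(
        center=(float(r0), float(c0)),
        radius=radius,
        sigma=(float(sr), float(sc)),
        theta=float(theta),
        amplitude=float(amplitude),
        offset=float(offset),
    )


@dataclass
class SpotSignals:
    s_i: float       # complex-channel foreground median
    s_b: float       # complex-channel annulus median
    s_p: float       # probe-channel foreground median
    s_m: float       # (s_i - s_b)/s_p; NaN when undefined
    undefined_normalization: bool = False


def _masks(shape, geom: SpotGeometry):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    d = np.hypot(rr - geom.center[0], cc - geom.center[1])
    fg = d <= geom.radius
    annulus = (d > geom.radius) & (d <= geom.annulus_outer)
    return fg, annulus


def extract_signals(
    complex_img: np.ndarray,
    probe_img: np.ndarray,
    geom: SpotGeometry,
    probe_floor: float = 0.0,
) -> SpotSignals:
    """Median foreground/annulus signals and the normalized S_m.

    A probe median at or below ``probe_floor`` leaves S_m undefined (NaN,
    flagged) rather than dividing by a vanishing RNA amount.
    """
    complex_img = np.asarray(complex_img, dtype=float)
    probe_img = np.asarray(probe_img, dtype=float)
    if complex_img.shape != probe_img.shape:
        raise ValueError("channel images must share dimensions")
    fg, annulus = _masks(complex_img.shape, geom)
    if not fg.any() or not annulus.any():
        raise ValueError("spot geometry leaves foreground or annulus empty")
    s_i = float(np.median(complex_img[fg]))
    s_b = float(np.median(complex_img[annulus]))
    s_p = float(np.median(probe_img[fg]))
    if s_p <= probe_floor:
        return SpotSignals(s_i, s_b, s_p, float("nan"), True)
    return SpotSignals(s_i, s_b, s_p, (s_i - s_b) / s_p, False)


def quantify_cell(
    images: dict[str, np.ndarray],
    radius_scale: float = 2.0,
    probe_floor: float = 0.0,
) -> tuple[SpotGeometry, SpotSignals]:
    """Segment on the anchor channel, then extract signals.

    ``images`` maps channel names ('complex', 'anchor', 'probe') to 2D
    arrays of identical shape.
    """
    for name in ("complex", "anchor", "probe"):
        if name not in images:
            raise KeyError(f"missing channel {name!r}")
    geom = fit_spot(images["anchor"], radius_scale=radius_scale)
    sig = extract_signals(images["complex"], images["probe"], geom, probe_floor=probe_floor)
    return geom, sig


def replicate_qc(
    signals: pd.DataFrame,
    cv_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate consistency of S_m per mutant.

    ``signals`` needs columns mutant_id, replicate, s_m.  Returns
    ``(per_mutant, correlations)``: per-mutant mean, sample (n-1) sd,
    CV = sd/mean (NaN when the mean is ~0) and a high-CV flag; plus the
    pairwise Pearson correlation across mutants for every replicate pair.
    Requires >= 2 replicates.
    """
    required = {"mutant_id", "replicate", "s_m"}
    if not required <= set(signals.columns):
        raise ValueError(f"signals table needs columns {sorted(required)}")
    if signals["replicate"].nunique() < 2:
        raise ValueError("replicate QC needs at least 2 replicates")

    def _stats(g):
        mean = g["s_m"].mean()
        sd = g["s_m"].std(ddof=1)
        cv = np.nan if np.isclose(mean, 0.0) else sd / abs(mean)
        return pd.Series({"mean": mean, "sd": sd, "cv": cv, "n": len(g)})

    per_mutant = signals.groupby("mutant_id", sort=True).apply(_stats, include_groups=False)
    per_mutant["high_cv"] = per_mutant["cv"] > cv_threshold

    wide = signals.pivot_table(index="mutant_id", columns="replicate", values="s_m")
    reps = list(wide.columns)
    rows = []
    for i, a in enumerate(reps):
        for b in reps[i + 1:]:
            pair = wide[[a, b]].dropna()
            r = pair[a].corr(pair[b]) if len(pair) >= 2 else np.nan
            rows.append({"replicate_a": a, "replicate_b": b, "pearson_r": r, "n": len(pair)})
    return per_mutant.reset_index(), pd.DataFrame(rows)
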