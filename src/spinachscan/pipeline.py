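"""End-to-end orchestration: curves -> fits -> landscape -> scores.

The pipeline consumes long-format titration and melt tables (simulated
or measured), fits every (mutant, replicate) binding curve at each
temperature and every melt curve, runs the per-replicate Van't Hoff
regression, combines replicates with the documented error propagation,
assembles the relative landscape (ddG, ddH, dTm, S_m vs wild type),
scores positions and selects engineering candidates.  Partial failures
(non-convergence, no transition, bimodal melts, undefined
normalization) travel as machine-readable flag strings on the records,
never as silent drops.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import binding, landscape, melting
from .constants import celsius_to_kelvin
from .io import write_table


@dataclass
class RunConfig:
    """Serializable run configuration, archived beside the outputs."""

    wt_id: str = "WT"
    neg_id: str = "NEG"
    t_ref_C: float = 23.0
    sign_convention: str = "favorable_negative"
    error_mode: str = "as_printed"
    quantile: float = 0.10
    select_parameters: tuple[str, ...] = ("s_m", "ddg", "dtm")
    # non-fluorogenic cutoff: max signal below (this factor x negative-control
    # spread); absolute floor used when no negative control is present
    nonfluorogenic_factor: float = 3.0
    nonfluorogenic_floor: float = 0.02
    amplitude_mode: str = "free"
    seed: int = 0


def fit_binding_table(
    titrations: pd.DataFrame,
    fluorogenic_threshold: float = 0.0,
    normalize_at_max: bool = False,
) -> pd.DataFrame:
    """Fit every (mutant, replicate, temperature) titration series.

    Returns one row per fit: kd_uM, kd_se, amplitude, amplitude_se,
    converged, fluorogenic, flags.
    """
    rows = []
    grouped = titrations.sort_values("conc_uM").groupby(
        ["mutant_id", "replicate", "temperature_C"], sort=True
    )
    for (mutant, rep, temp), g in grouped:
        fit = binding.fit_binding(
            g["conc_uM"].to_numpy(),
            g["signal"].to_numpy(),
            fluorogenic_threshold=fluorogenic_threshold,
            normalize_at_max=normalize_at_max,
        )
        rows.append(
            {
                "mutant_id": mutant, "replicate": rep, "temperature_C": temp,
                "kd_uM": fit.kd, "kd_se": fit.kd_stderr,
                "amplitude": fit.amplitude, "amplitude_se": fit.amplitude_stderr,
                "converged": fit.converged, "fluorogenic": fit.fluorogenic,
                "flags": ";".join(fit.flags),
            }
        )
    return pd.DataFrame(rows)


def fit_melting_table(
    melts: pd.DataFrame,
    fluorogenic_ids=None,
    amplitude_mode: str = "free",
) -> pd.DataFrame:
    """Fit every (mutant, replicate) melt; mutants outside
    ``fluorogenic_ids`` (when given) are carried with the
    non_fluorogenic flag and no fit."""
    rows = []
    for (mutant, rep), g in melts.sort_values("temperature_C").groupby(
        ["mutant_id", "replicate"], sort=True
    ):
        if fluorogenic_ids is not None and mutant not in fluorogenic_ids:
            rows.append(
                {
                    "mutant_id": mutant, "replicate": rep, "tm_C": np.nan,
                    "tm_se": np.nan, "dh_t": np.nan, "dh_t_se": np.nan,
                    "amplitude": np.nan, "converged": False,
                    "flags": "non_fluorogenic",
                }
            )
            continue
        fit = melting.fit_melting(
            celsius_to_kelvin(g["temperature_C"].to_numpy()),
            g["signal"].to_numpy(),
            amplitude_mode=amplitude_mode,
        )
        rows.append(
            {
                "mutant_id": mutant, "replicate": rep,
                "tm_C": fit.tm_celsius, "tm_se": fit.tm_stderr,
                "dh_t": fit.dh_t, "dh_t_se": fit.dh_t_stderr,
                "amplitude": fit.amplitude, "converged": fit.converged,
                "flags": ";".join(fit.flags),
            }
        )
    return pd.DataFrame(rows)


def vant_hoff_table(binding_fits: pd.DataFrame) -> pd.DataFrame:
    """Per-(mutant, replicate) Van't Hoff regression across temperatures.

    ``dh`` is reported in the binding convention (negative = exothermic).
    """
    rows = []
    ok = binding_fits[binding_fits["fluorogenic"] & binding_fits["kd_uM"].notna()]
    for (mutant, rep), g in ok.groupby(["mutant_id", "replicate"], sort=True):
        if g["temperature_C"].nunique() < 2:
            continue
        points = [
            (celsius_to_kelvin(t), kd)
            for t, kd in zip(g["temperature_C"], g["kd_uM"])
        ]
        fit = binding.vant_hoff(points)
        rows.append(
            {
                "mutant_id": mutant, "replicate": rep,
                "dh": fit.dh_binding,
                "dh_se": fit.dh_stderr if fit.dh_stderr is not None else np.nan,
                "ds": fit.ds_binding, "r_squared": fit.r_squared,
            }
        )
    return pd.DataFrame(rows)


def _combine(values, errors, mode):
    values = np.asarray(values, dtype=float)
    errors = np.asarray(errors, dtype=float)
    keep = np.isfinite(values)
    values, errors = values[keep], np.nan_to_num(errors[keep])
    if values.size == 0:
        return np.nan, np.nan
    if values.size == 1:
        return float(values[0]), float(errors[0])
    return float(values.mean()), landscape.propagate_error(values, errors, mode=mode)


def nonfluorogenic_threshold(
    titrations: pd.DataFrame, config: RunConfig
) -> float:
    """Signal cutoff below which a mutant counts as non-fluorogenic:
    ``nonfluorogenic_factor`` times the negative-control signal spread at
    the top ligand concentration (falling back to the absolute floor)."""
    neg = titrations[titrations["mutant_id"] == config.neg_id]
    if len(neg) == 0:
        return config.nonfluorogenic_floor
    top = neg[neg["conc_uM"] == neg["conc_uM"].max()]["signal"]
    spread = float(top.std(ddof=1)) if len(top) > 1 else float(abs(top.iloc[0]))
    return max(config.nonfluorogenic_factor * spread, config.nonfluorogenic_floor)


def assemble_landscape(
    binding_fits: pd.DataFrame,
    vanthoff: pd.DataFrame,
    melt_fits: pd.DataFrame,
    positions: dict[str, tuple[int, ...]],
    config: RunConfig,
) -> pd.DataFrame:
    """Combine per-replicate fits into one landscape row per mutant,
    relative to the wild type (which lands at exactly 0 in ddG/ddH/dTm)."""
    t_ref_K = celsius_to_kelvin(config.t_ref_C)
    rt = binding.R_KCAL * t_ref_K
    ref = binding_fits[np.isclose(binding_fits["temperature_C"], config.t_ref_C)]

    wt = ref[ref["mutant_id"] == config.wt_id]
    if len(wt) == 0 or wt["kd_uM"].isna().all():
        raise ValueError(f"no usable wild-type ({config.wt_id!r}) binding fits")
    kd_wt = float(wt["kd_uM"].mean())
    wt_vh = vanthoff[vanthoff["mutant_id"] == config.wt_id]
    dh_wt = float(wt_vh["dh"].mean()) if len(wt_vh) else np.nan
    wt_melt = melt_fits[melt_fits["mutant_id"] == config.wt_id]
    tm_wt = float(wt_melt["tm_C"].mean()) if len(wt_melt) else np.nan

    rows = []
    for mutant in sorted(set(binding_fits["mutant_id"])):
        m_ref = ref[ref["mutant_id"] == mutant]
        fluorogenic = bool(m_ref["fluorogenic"].any())
        flags = sorted(
            set(
                f
                for fs in binding_fits.loc[
                    binding_fits["mutant_id"] == mutant, "flags"
                ].fillna("")
                for f in str(fs).split(";")
                if f
            )
        )
        if not fluorogenic:
            rows.append(
                {
                    "mutant_id": mutant,
                    "positions": ";".join(map(str, positions.get(mutant, ()))),
                    "s_m": 0.0, "ddg": np.nan, "ddh": np.nan, "dtm": np.nan,
                    "sigma_s_m": np.nan, "sigma_ddg": np.nan,
                    "sigma_ddh": np.nan, "sigma_dtm": np.nan,
                    "fluorogenic": False, "flags": ";".join(flags),
                }
            )
            continue

        amp, amp_sigma = _combine(
            m_ref["amplitude"], m_ref["amplitude_se"], config.error_mode
        )
        # ddG per replicate against the WT mean Kd; fit error via d(ddG)/dKd
        kd_vals = m_ref["kd_uM"].to_numpy(dtype=float)
        kd_ses = np.nan_to_num(m_ref["kd_se"].to_numpy(dtype=float))
        sign = -1.0 if config.sign_convention == "as_printed" else 1.0
        ddg_vals = sign * rt * np.log(kd_vals / kd_wt)
        ddg_ses = rt * kd_ses / kd_vals
        ddg, ddg_sigma = _combine(ddg_vals, ddg_ses, config.error_mode)

        m_vh = vanthoff[vanthoff["mutant_id"] == mutant]
        ddh_vals = m_vh["dh"].to_numpy(dtype=float) - dh_wt
        ddh, ddh_sigma = _combine(ddh_vals, m_vh["dh_se"], config.error_mode)

        m_melt = melt_fits[melt_fits["mutant_id"] == mutant]
        melt_flags = set(
            f
            for fs in m_melt["flags"].fillna("")
            for f in str(fs).split(";")
            if f
        )
        flags = sorted(set(flags) | melt_flags)
        dtm_vals = m_melt["tm_C"].to_numpy(dtype=float) - tm_wt
        dtm, dtm_sigma = _combine(dtm_vals, m_melt["tm_se"], config.error_mode)

        rows.append(
            {
                "mutant_id": mutant,
                "positions": ";".join(map(str, positions.get(mutant, ()))),
                "s_m": amp, "ddg": ddg, "ddh": ddh, "dtm": dtm,
                "sigma_s_m": amp_sigma, "sigma_ddg": ddg_sigma,
                "sigma_ddh": ddh_sigma, "sigma_dtm": dtm_sigma,
                "fluorogenic": True, "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    binding_fits: pd.DataFrame
    vanthoff: pd.DataFrame
    melt_fits: pd.DataFrame
    landscape: pd.DataFrame
    scored: pd.DataFrame
    score_track: pd.DataFrame
    candidates: pd.DataFrame
    warnings: list = field(default_factory=list)


def run_pipeline(
    titrations: pd.DataFrame,
    melts: pd.DataFrame,
    positions: dict[str, tuple[int, ...]],
    n_positions: int,
    config: RunConfig = RunConfig(),
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Fit, assemble, score and (optionally) persist one full run.

    ``positions`` maps mutant id to its mutated 1-based positions
    (empty for controls); ``n_positions`` is the reference length for
    the score track.  With ``outdir`` all tables and a JSON run log
    (config, seed, library versions, warnings) are written; identical
    inputs and config reproduce the files byte for byte.
    """
    if len(titrations) == 0 or len(melts) == 0:
        raise ValueError("empty input tables")
    warnings: list[str] = []

    threshold = nonfluorogenic_threshold(titrations, config)
    binding_fits = fit_binding_table(titrations, fluorogenic_threshold=threshold)
    fluorogenic_ids = set(
        binding_fits.loc[binding_fits["fluorogenic"], "mutant_id"]
    )
    vanthoff = vant_hoff_table(binding_fits)
    melt_fits = fit_melting_table(
        melts, fluorogenic_ids=fluorogenic_ids, amplitude_mode=config.amplitude_mode
    )
    for col, table, msg in (
        ("converged", binding_fits, "binding fits did not converge"),
        ("converged", melt_fits, "melt fits did not converge"),
    ):
        n_bad = int((~table[col] & table["flags"].str.contains("fit_failed")).sum())
        if n_bad:
            warnings.append(f"{n_bad} {msg}")

    land = assemble_landscape(binding_fits, vanthoff, melt_fits, positions, config)

    spm_mask = land["mutant_id"].map(
        lambda m: len(positions.get(m, ())) == 1
    )
    spms = land[spm_mask].copy()
    scored = landscape.score_spms(spms)
    track = landscape.position_score(scored, n_positions)
    candidates = landscape.intersect_candidates(
        land[spm_mask], config.select_parameters, q=config.quantile
    )

    result = PipelineResult(
        binding_fits=binding_fits,
        vanthoff=vanthoff,
        melt_fits=melt_fits,
        landscape=land,
        scored=scored,
        score_track=track,
        candidates=candidates,
        warnings=warnings,
    )
    if outdir is not None:
        _persist(result, config, Path(outdir))
    return result


def _persist(result: PipelineResult, config: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(outdir / "binding_fits.tsv", result.binding_fits)
    write_table(outdir / "vant_hoff.tsv", result.vanthoff)
    write_table(outdir / "melt_fits.tsv", result.melt_fits)
    write_table(outdir / "landscape.tsv", result.landscape)
    write_table(outdir / "score_track.tsv", result.score_track)
    write_table(outdir / "candidates.tsv", result.candidates)
    import lmfit
    import scipy

    log = {
        "config": asdict(config),
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "lmfit": lmfit.__version__,
        },
        "warnings": result.warnings,
        "n_mutants": int(result.landscape.shape[0]),
        "n_fluorogenic": int(result.landscape["fluorogenic"].sum()),
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
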