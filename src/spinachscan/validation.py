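"""Seeded end-to-end validation studies on synthetic chip data.

Three studies exercise the whole chain under the measurement design the
pipeline targets and quantify how well it recovers known truth:

* :func:`recovery_study` — simulate titrations (12 concentrations,
  0.435-43.5 uM, at 19/23/28 C) and melts (23-49 C in 2 C steps) for a
  panel of fluorogenic mutants at 4 replicates with 2% multiplicative
  noise, re-fit everything, and report median K_d and T_m recovery
  errors plus the sign accuracy of the Van't Hoff binding enthalpy.
* :func:`qc_study` — build a full 160-mutant, 4-replicate chip of
  simulated three-channel spot images, quantify every unit cell through
  the segmentation pipeline, and report the replicate coefficient of
  variation and inter-replicate correlations of the recovered S_m.
* :func:`symmetry_study` — generate a landscape with planted stems and
  compensatory double-mutant rescue, score it, and report the
  partner-position score correlation and the rescue-index contrast
  between true stem pairs and mismatched controls.

All randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import binding, landscape, library, melting, simulate, spots
from .constants import celsius_to_kelvin


def recovery_study(seed: int = 0, n_mutants: int = 100) -> dict:
    """Parameter recovery under the standard measurement design.

    Uses fluorogenic mutants only (a dark mutant has no K_d or T_m to
    recover).  Returns medians over ``n_mutants`` mutants of the
    per-mutant replicate-averaged estimates.
    """
    seq, _ = simulate.synthetic_reference()
    cfg = simulate.TruthConfig(nonfluorogenic_fraction=0.0)
    truth = simulate.make_truth(seq, config=cfg, seed=seed)
    spm_ids = [m for m in truth["mutant_id"] if m not in ("WT", "NEG")][:n_mutants]
    panel = truth[truth["mutant_id"].isin(spm_ids)].reset_index(drop=True)

    noise = simulate.NoiseModel(mult_sd=0.02, add_sd=0.0, replicates=4, seed=seed + 1)
    titr = simulate.simulate_titration(panel, noise=noise)
    melts = simulate.simulate_melting(panel, noise=noise)

    t_ref = 23.0
    tr = panel.set_index("mutant_id")
    kd_errors, tm_errors, dh_signs = [], [], []
    for mutant in spm_ids:
        m_titr = titr[titr["mutant_id"] == mutant]
        kd_reps, dh_reps = [], []
        for rep, g_rep in m_titr.groupby("replicate"):
            points = []
            for temp, g in g_rep.groupby("temperature_C"):
                g = g.sort_values("conc_uM")
                fit = binding.fit_binding(g["conc_uM"].to_numpy(), g["signal"].to_numpy())
                if fit.kd is not None:
                    points.append((celsius_to_kelvin(temp), fit.kd))
                    if np.isclose(temp, t_ref):
                        kd_reps.append(fit.kd)
            if len(points) >= 2:
                dh_reps.append(binding.vant_hoff(points).dh_binding)
        kd_hat = float(np.mean(kd_reps))
        dh_hat = float(np.mean(dh_reps))
        kd_errors.append(abs(kd_hat - tr.loc[mutant, "kd_uM"]) / tr.loc[mutant, "kd_uM"])
        dh_signs.append(np.sign(dh_hat) == np.sign(tr.loc[mutant, "dh"]))

        m_melt = melts[melts["mutant_id"] == mutant]
        tm_reps = []
        for rep, g in m_melt.groupby("replicate"):
            g = g.sort_values("temperature_C")
            fit = melting.fit_melting(
                celsius_to_kelvin(g["temperature_C"].to_numpy()),
                g["signal"].to_numpy(),
            )
            if fit.tm is not None:
                tm_reps.append(fit.tm_celsius)
        tm_errors.append(abs(float(np.mean(tm_reps)) - tr.loc[mutant, "tm_C"]))

    return {
        "n_mutants": len(spm_ids),
        "median_kd_rel_error": float(np.median(kd_errors)),
        "median_tm_abs_error_C": float(np.median(tm_errors)),
        "dh_sign_accuracy": float(np.mean(dh_signs)),
    }


def wt_reference_study(seed: int = 0) -> dict:
    """Recover the wild-type binding constants from a standard noisy run:
    K_d at 23 C and the Van't Hoff binding enthalpy over 19/23/28 C."""
    seq, _ = simulate.synthetic_reference()
    truth = simulate.make_truth(seq, seed=seed)
    wt = truth[truth["mutant_id"] == "WT"]
    noise = simulate.NoiseModel(mult_sd=0.02, add_sd=0.005, replicates=4, seed=seed + 2)
    titr = simulate.simulate_titration(wt, noise=noise)
    kd_reps, dh_reps = [], []
    for rep, g_rep in titr.groupby("replicate"):
        points = []
        for temp, g in g_rep.groupby("temperature_C"):
            g = g.sort_values("conc_uM")
            fit = binding.fit_binding(g["conc_uM"].to_numpy(), g["signal"].to_numpy())
            points.append((celsius_to_kelvin(temp), fit.kd))
            if np.isclose(temp, 23.0):
                kd_reps.append(fit.kd)
        dh_reps.append(binding.vant_hoff(points).dh_binding)
    return {
        "wt_kd_uM": float(np.mean(kd_reps)),
        "wt_dh_binding_kcal_mol": float(np.mean(dh_reps)),
        "n_replicates": len(kd_reps),
    }


def qc_study(seed: int = 0, n_mutants: int = 160) -> dict:
    """Replicate QC of S_m recovered from a full simulated image chip.

    A 640-cell chip hosts ``n_mutants`` mutants (wild type, negative
    control and SPMs) at 4 replicates; per-replicate signals carry the
    default noise (emulating transcription-yield variation), images are
    generated and quantified cell by cell, and the recovered S_m feeds
    the replicate QC.
    """
    seq, pairs = simulate.synthetic_reference()
    truth = simulate.make_truth(seq, seed=seed, stem_pairs=pairs)
    specs = [library.wildtype_spec(), library.negative_control_spec()]
    spm_specs = library.enumerate_spms(seq)
    specs += spm_specs[: n_mutants - 2]
    layout = library.plan_chip_layout(specs, n_cells=4 * n_mutants, replicates=4)

    amp = truth.set_index("mutant_id")["amplitude"]
    noise = simulate.NoiseModel(seed=seed + 3)
    rng = np.random.default_rng(seed + 4)
    signals = {
        (a.mutant_id, a.replicate): float(noise.apply(rng, amp[a.mutant_id]))
        for a in layout.assignments
    }
    images, _ = simulate.simulate_chip_images(layout, signals, seed=seed + 5)

    rows = []
    for a in layout.assignments:
        _, sig = spots.quantify_cell(images[a.cell])
        rows.append({"mutant_id": a.mutant_id, "replicate": a.replicate, "s_m": sig.s_m})
    recovered = pd.DataFrame(rows)
    per_mutant, corr = spots.replicate_qc(recovered)
    cvs = per_mutant["cv"].dropna()
    return {
        "n_mutants": n_mutants,
        "n_cells": 4 * n_mutants,
        "median_cv": float(cvs.median()),
        "max_cv": float(cvs.max()),
        "min_inter_replicate_r": float(corr["pearson_r"].min()),
    }


def symmetry_study(seed: int = 0) -> dict:
    """Stem symmetry and compensatory rescue on a planted landscape.

    Scores the ground-truth landscape (with stem partners sharing their
    thermodynamic effects), correlates the smoothed score track between
    partner positions, and contrasts rescue indices of Watson-Crick
    restoring double mutants with mismatched control pairs.

    The planted landscape is fully fluorogenic: the symmetry diagnostic
    measures shared *thermodynamic* profiles between partners, whereas a
    dark mutant contributes only the -1 sentinel.  Sentinel spikes at
    stem-flanking positions bleed into the 3-position smoothing windows
    and would dilute the track correlation without bearing on pairing;
    the pre-smoothing per-position scores are exactly symmetric either
    way (``partner_raw_correlation``).
    """
    seq, pairs = simulate.synthetic_reference()
    cfg = simulate.TruthConfig(nonfluorogenic_fraction=0.0)
    truth = simulate.make_truth(seq, config=cfg, seed=seed, stem_pairs=pairs)
    spms = truth[~truth["mutant_id"].isin(["WT", "NEG"])]
    frame = pd.DataFrame(
        {
            "mutant_id": spms["mutant_id"],
            "positions": spms["position"].astype(str),
            "s_m": spms["amplitude"],
            "ddg": spms["ddg"],
            "ddh": spms["ddh"],
            "dtm": spms["dtm_C"],
            "fluorogenic": spms["fluorogenic"],
        }
    )
    scored = landscape.score_spms(frame)
    track = landscape.position_score(scored, len(seq))
    partner_r = landscape.partner_score_correlation(track, pairs)
    raw = track.rename(columns={"score": "smoothed", "s_position": "score"})
    partner_raw_r = landscape.partner_score_correlation(raw, pairs)

    rescue_truth = simulate.make_rescue_truth(seq, pairs, truth, seed=seed + 6)
    signals = dict(zip(truth["mutant_id"], truth["amplitude"].astype(float)))
    table = landscape.rescue_analysis(signals, rescue_truth, signals["WT"])
    table = table.merge(rescue_truth[["mutant_id", "element"]], on="mutant_id",
                        suffixes=("", "_truth"))
    by_element = table.groupby("element_truth")["rescue"].mean()
    return {
        "n_stem_pairs": len(pairs),
        "partner_score_correlation": float(partner_r),
        "partner_raw_correlation": float(partner_raw_r),
        "rescue_true_pairs_mean": float(by_element.get("stem", np.nan)),
        "rescue_control_pairs_mean": float(by_element.get("control", np.nan)),
    }
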