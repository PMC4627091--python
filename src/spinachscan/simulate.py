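"""Synthetic chip-data generator with per-mutant ground truth.

The generator emulates the statistical structure of a scanning-
mutagenesis fluorogenic-aptamer chip experiment so every downstream
stage (spot quantification, binding and melting fits, landscape scoring,
rescue analysis) can be exercised against known truth:

* an 87-nt reference with designed stems (a synthetic stand-in sequence;
  all combinatorics depend only on length);
* wild-type anchors: K_d = 1.18 uM at 23 C, binding enthalpy -9 kcal/mol
  (exothermic), T_m^ap mid-way through the 23-49 C melt window,
  unfolding enthalpy 60 kcal/mol, unit amplitude;
* per-SPM perturbations: ddG ~ N(0, 0.3 kcal/mol), dTm ~ N(0, 2 C),
  ddH ~ N(0, 2 kcal/mol), log-normal amplitude spread, and a ~29%
  non-fluorogenic fraction (76 of 261 in the measured landscape);
* stem positions take deleterious draws shared between base-pairing
  partners, so partner positions carry matching thermodynamic profiles
  and compensatory double mutants can rescue them;
* measurements: 12-point titrations over 0.435-43.5 uM at 19/23/28 C,
  melts over 23-49 C in 2 C steps at 43.5 uM, four replicates, 2%
  multiplicative plus small additive Gaussian noise (replicate CV well
  under the 5% QC bound);
* optional three-channel unit-cell images with a Gaussian spot whose
  channel amplitudes encode the anchor, RNA amount and complex signal.

K_d(T) follows the same linear-in-1/T Van't Hoff family the fitter
assumes, with the binding convention: exothermic binders bind tighter
cold, so K_d(19 C) < K_d(28 C) for the wild type.

All randomness flows through explicit integer seeds; a given (config,
seed) reproduces the dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .constants import celsius_to_kelvin
from . import binding, melting
from .library import (
    WC_PAIR,
    enumerate_spms,
    negative_control_spec,
    wildtype_spec,
    ChipLayout,
)


def synthetic_reference(length: int = 87):
    """A deterministic synthetic RNA reference with designed stems.

    This is a programmatically constructed stand-in sequence (the
    measured aptamer's own sequence is not redistributed here),
    built with three Watson-Crick stems, a
    tetraloop and a G-rich core so that stem-symmetry and rescue logic
    have real structure to find.  Returns ``(sequence, stem_pairs)``
    where stem_pairs is a list of 1-based paired position tuples.
    """
    if length < 40:
        raise ValueError("reference construction needs length >= 40")
    rng = np.random.default_rng(87429)  # fixed: the reference is a constant
    bases = rng.choice(list("ACGU"), size=length, p=[0.3, 0.2, 0.3, 0.2]).tolist()

    # three stems: (5' start, 3' end, length), 1-based, end pairs with start
    stem_defs = [(1, length, 8), (12, length - 11, 7), (24, length - 23, 5)]
    pairs = []
    for start, end, k in stem_defs:
        for off in range(k):
            i, j = start + off, end - off
            pairs.append((i, j))
            bases[j - 1] = WC_PAIR[bases[i - 1]]
    # G-rich quadruplex-like core and a UUCG tetraloop in the middle
    mid = length // 2
    for p in range(mid - 2, mid + 2):
        bases[p] = "G"
    loop_anchor = 24 + 5  # just inside stem 3
    for p, b in zip(range(loop_anchor, loop_anchor + 4), "UUCG"):
        bases[p] = b
    return "".join(bases), pairs


@dataclass
class NoiseModel:
    """Measurement noise: signal*(1+N(0, mult_sd)) + N(0, add_sd)."""

    mult_sd: float = 0.02
    add_sd: float = 0.005
    replicates: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.mult_sd < 0 or self.add_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")

    def apply(self, rng: np.random.Generator, clean):
        clean = np.asarray(clean, dtype=float)
        return clean * (1.0 + rng.normal(0.0, self.mult_sd, clean.shape)) + rng.normal(
            0.0, self.add_sd, clean.shape
        )


NOISELESS = NoiseModel(mult_sd=0.0, add_sd=0.0, replicates=1)


@dataclass
class TruthConfig:
    """Ground-truth anchors and perturbation scales.

    Wild-type anchors follow the measured system (K_d 1.18 uM at 23 C,
    exothermic binding enthalpy -9 kcal/mol, T_m mid-window);
    perturbation scales are bracketed by the measured landscape extremes
    (maximum fluorescence gain 1.3-fold, maximum T_m gain 8.4 C, K_d
    span of two decades, 76/261 non-fluorogenic).
    """

    kd_wt_uM: float = 1.18
    dh_wt: float = -9.0          # binding enthalpy, kcal/mol (exothermic < 0)
    tm_wt_C: float = 36.0        # mid 23-49 C window
    dh_t_wt: float = 60.0        # unfolding enthalpy, kcal/mol
    amplitude_wt: float = 1.0
    t_ref_C: float = 23.0
    ddg_sd: float = 0.3          # kcal/mol, favorable_negative convention
    ddh_sd: float = 2.0          # kcal/mol
    dtm_sd: float = 2.0          # C
    dh_t_sd: float = 5.0         # kcal/mol
    amplitude_log_sd: float = 0.08
    nonfluorogenic_fraction: float = 76.0 / 261.0
    # deleterious shift applied to stem-position SPMs (shared by partners)
    stem_ddg_shift: float = 0.6
    stem_dtm_shift: float = -3.0
    stem_amplitude_factor: float = 0.45


def make_truth(
    seq: str,
    config: TruthConfig = TruthConfig(),
    seed: int = 0,
    stem_pairs=None,
) -> pd.DataFrame:
    """Ground-truth table: WT + negative control + all 3n SPMs.

    Columns: mutant_id, position, kd_uM, ddg, dh, ddh, tm_C, dtm_C,
    dh_t, amplitude, fluorogenic, stem, bimodal.  Stem-position SPMs
    (when ``stem_pairs`` is given) take additional deleterious shifts
    drawn once per (pair, substitution slot) and shared by both
    partners, producing the mirror-symmetric landscape a real stem
    yields.  ddg is in the favorable_negative convention at the
    reference temperature.
    """
    if not 0 <= config.nonfluorogenic_fraction <= 1:
        raise ValueError("nonfluorogenic_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    t_ref_K = celsius_to_kelvin(config.t_ref_C)
    rt = binding.R_KCAL * t_ref_K
    spms = enumerate_spms(seq)

    partner = {}
    if stem_pairs:
        for i, j in stem_pairs:
            partner[i], partner[j] = j, i

    # pair-level draws, keyed by (min(pair), slot)
    pair_draws = {}

    def draw_effects(position, slot):
        if position in partner:
            key = (min(position, partner[position]), slot)
            if key not in pair_draws:
                pair_draws[key] = {
                    "ddg": rng.normal(config.stem_ddg_shift, config.ddg_sd),
                    "ddh": rng.normal(0.0, config.ddh_sd),
                    "dtm": rng.normal(config.stem_dtm_shift, config.dtm_sd),
                    "dh_t": rng.normal(0.0, config.dh_t_sd),
                    "amp_factor": config.stem_amplitude_factor
                    * np.exp(rng.normal(0.0, config.amplitude_log_sd)),
                    "nonfluor": rng.random() < config.nonfluorogenic_fraction,
                }
            return pair_draws[key]
        return {
            "ddg": rng.normal(0.0, config.ddg_sd),
            "ddh": rng.normal(0.0, config.ddh_sd),
            "dtm": rng.normal(0.0, config.dtm_sd),
            "dh_t": rng.normal(0.0, config.dh_t_sd),
            "amp_factor": np.exp(rng.normal(0.0, config.amplitude_log_sd)),
            "nonfluor": rng.random() < config.nonfluorogenic_fraction,
        }

    rows = [
        {
            "mutant_id": "WT", "position": 0, "kd_uM": config.kd_wt_uM,
            "ddg": 0.0, "dh": config.dh_wt, "ddh": 0.0,
            "tm_C": config.tm_wt_C, "dtm_C": 0.0, "dh_t": config.dh_t_wt,
            "amplitude": config.amplitude_wt, "fluorogenic": True,
            "stem": False, "bimodal": False,
        },
        {
            "mutant_id": "NEG", "position": 0, "kd_uM": np.nan,
            "ddg": np.nan, "dh": np.nan, "ddh": np.nan,
            "tm_C": np.nan, "dtm_C": np.nan, "dh_t": np.nan,
            "amplitude": 0.0, "fluorogenic": False,
            "stem": False, "bimodal": False,
        },
    ]
    slot_counter = {}
    for spec in spms:
        pos = spec.substitutions[0].position
        slot = slot_counter.get(pos, 0)
        slot_counter[pos] = slot + 1
        eff = draw_effects(pos, slot)
        fluorogenic = not eff["nonfluor"]
        kd = config.kd_wt_uM * np.exp(eff["ddg"] / rt)
        rows.append(
            {
                "mutant_id": spec.id,
                "position": pos,
                "kd_uM": kd if fluorogenic else np.nan,
                "ddg": eff["ddg"] if fluorogenic else np.nan,
                "dh": config.dh_wt + eff["ddh"] if fluorogenic else np.nan,
                "ddh": eff["ddh"] if fluorogenic else np.nan,
                "tm_C": config.tm_wt_C + eff["dtm"] if fluorogenic else np.nan,
                "dtm_C": eff["dtm"] if fluorogenic else np.nan,
                "dh_t": max(config.dh_t_wt + eff["dh_t"], 10.0) if fluorogenic else np.nan,
                "amplitude": config.amplitude_wt * eff["amp_factor"] if fluorogenic else 0.0,
                "fluorogenic": fluorogenic,
                "stem": pos in partner,
                "bimodal": False,
            }
        )
    return pd.DataFrame(rows)


def make_rescue_truth(
    seq: str,
    stem_pairs,
    truth: pd.DataFrame,
    seed: int = 0,
    n_controls: int = 10,
    rescue_level: float = 0.92,
    control_level: float = 0.08,
    jitter_sd: float = 0.03,
) -> pd.DataFrame:
    """Planted compensatory-DPM signals for the rescue screen.

    For every stem pair, the Watson-Crick-restoring double mutant
    recovers ~``rescue_level`` of the wild-type signal drop caused by
    its more deleterious constituent SPM; ``n_controls`` mismatched
    (non-paired) position pairs recover only ~``control_level``.
    Returns a table ready for :func:`landscape.rescue_analysis` with
    columns mutant_id, spm_a, spm_b, s_m, element, pair_i, pair_j.
    """
    rng = np.random.default_rng(seed)
    amp = truth.set_index("mutant_id")["amplitude"]
    wt_signal = float(amp["WT"])

    def spm_ids_at(position):
        return [
            m for m in truth["mutant_id"]
            if m not in ("WT", "NEG")
            and int(truth.set_index("mutant_id").loc[m, "position"]) == position
        ]

    by_pos = truth[~truth["mutant_id"].isin(["WT", "NEG"])].groupby("position")["mutant_id"]
    ids_at = {pos: list(g) for pos, g in by_pos}

    rows = []
    paired = set()
    for i, j in stem_pairs:
        paired.update((i, j))
        spm_a, spm_b = ids_at[i][0], ids_at[j][0]
        s_a, s_b = float(amp[spm_a]), float(amp[spm_b])
        s_spm = min(s_a, s_b)
        level = np.clip(rescue_level + rng.normal(0.0, jitter_sd), 0, 1.5)
        s_dpm = s_spm + level * (wt_signal - s_spm)
        rows.append(
            {
                "mutant_id": f"{spm_a}+{spm_b}", "spm_a": spm_a, "spm_b": spm_b,
                "s_m": float(s_dpm), "element": "stem",
                "pair_i": i, "pair_j": j,
            }
        )
    n = len(seq)
    unpaired = [p for p in range(1, n + 1) if p not in paired]
    for _ in range(n_controls):
        i, j = sorted(rng.choice(unpaired, size=2, replace=False))
        spm_a, spm_b = ids_at[int(i)][0], ids_at[int(j)][0]
        s_spm = min(float(amp[spm_a]), float(amp[spm_b]))
        level = np.clip(control_level + rng.normal(0.0, jitter_sd), 0, 1.5)
        s_dpm = s_spm + level * (wt_signal - s_spm)
        rows.append(
            {
                "mutant_id": f"{spm_a}+{spm_b}", "spm_a": spm_a, "spm_b": spm_b,
                "s_m": float(s_dpm), "element": "control",
                "pair_i": int(i), "pair_j": int(j),
            }
        )
    return pd.DataFrame(rows)


def simulate_titration(
    truth: pd.DataFrame,
    temps_C=binding.DEFAULT_BINDING_TEMPS_C,
    conc_uM=binding.DEFAULT_CONC_UM,
    noise: NoiseModel = NoiseModel(),
    t_ref_C: float = 23.0,
) -> pd.DataFrame:
    """Simulated titration curves for every truth row.

    signal = amplitude * fraction_bound(D, K_d(T)), with K_d(T) on each
    mutant's Van't Hoff line through (K_d at t_ref, dh); noise and
    replication per the noise model.  Non-fluorogenic mutants emit
    additive noise only.
    """
    rng = np.random.default_rng(noise.seed)
    conc = np.asarray(conc_uM, dtype=float)
    t_ref_K = celsius_to_kelvin(t_ref_C)
    records = []
    for row in truth.itertuples(index=False):
        for temp_C in temps_C:
            t_K = celsius_to_kelvin(float(temp_C))
            if row.fluorogenic:
                kd_t = binding.kd_at_temperature(row.kd_uM, row.dh, t_ref_K, t_K)
                clean = row.amplitude * binding.fraction_bound(conc, kd_t)
            else:
                clean = np.zeros_like(conc)
            for rep in range(1, noise.replicates + 1):
                sig = noise.apply(rng, clean)
                records.append(
                    pd.DataFrame(
                        {
                            "mutant_id": row.mutant_id,
                            "replicate": rep,
                            "temperature_C": float(temp_C),
                            "conc_uM": conc,
                            "signal": sig,
                        }
                    )
                )
    return pd.concat(records, ignore_index=True)


def _bimodal_profile(temps_K, amplitude, peak_C=35.0, width_C=4.0, dh_t=60.0):
    """Low-high-low misfolding melt: transient folding between two
    transitions flanking the peak temperature."""
    t_lo = celsius_to_kelvin(peak_C - width_C)
    t_hi = celsius_to_kelvin(peak_C + width_C)
    rise = 1.0 - melting.fraction_folded(temps_K, t_lo, dh_t)
    fall = melting.fraction_folded(temps_K, t_hi, dh_t)
    prof = rise * fall
    return amplitude * prof / prof.max()


def simulate_melting(
    truth: pd.DataFrame,
    temps_C=melting.DEFAULT_MELT_TEMPS_C,
    noise: NoiseModel = NoiseModel(),
) -> pd.DataFrame:
    """Simulated melt curves (14 temperatures 23-49 C by default) at
    saturating ligand: signal = amplitude * fraction_folded(T, Tm, dH_T)
    plus noise; rows flagged ``bimodal`` in the truth emit the
    low-high-low misfolding profile instead."""
    rng = np.random.default_rng(noise.seed + 1)
    temps_K = celsius_to_kelvin(np.asarray(temps_C, dtype=float))
    records = []
    for row in truth.itertuples(index=False):
        if not row.fluorogenic:
            clean = np.zeros_like(temps_K)
        elif getattr(row, "bimodal", False):
            clean = _bimodal_profile(temps_K, row.amplitude)
        else:
            clean = row.amplitude * melting.fraction_folded(
                temps_K, celsius_to_kelvin(row.tm_C), row.dh_t
            )
        for rep in range(1, noise.replicates + 1):
            sig = noise.apply(rng, clean)
            records.append(
                pd.DataFrame(
                    {
                        "mutant_id": row.mutant_id,
                        "replicate": rep,
                        "temperature_C": np.asarray(temps_C, dtype=float),
                        "signal": sig,
                    }
                )
            )
    return pd.concat(records, ignore_index=True)


@dataclass
class ImageConfig:
    """Geometry and intensity scales for simulated unit-cell images."""

    shape: tuple[int, int] = (64, 64)
    sigma: float = 6.0
    center_jitter: float = 2.0
    anchor_amplitude: float = 500.0
    probe_amplitude: float = 400.0
    background: float = 50.0
    noise_sd: float = 10.0


def simulate_chip_images(
    layout: ChipLayout,
    signals: dict,
    config: ImageConfig = ImageConfig(),
    seed: int = 0,
):
    """Three-channel Gaussian-spot images for every layout cell.

    ``signals`` maps (mutant_id, replicate) -> target normalized signal
    S_m; the complex-channel spot amplitude is S_m times the probe
    amplitude so that quantification recovers S_m as the amplitude
    ratio.  Returns ``(images, params)``: a dict cell -> {channel:
    2D array} and a DataFrame of the generation parameters per cell.
    """
    rng = np.random.default_rng(seed)
    nr, nc = config.shape
    rr, cc = np.mgrid[0:nr, 0:nc]
    images, rows = {}, []
    for a in layout.assignments:
        key = (a.mutant_id, a.replicate)
        if key not in signals:
            raise KeyError(f"no signal for layout cell {a.cell} ({key})")
        s_m = float(signals[key])
        r0 = nr / 2 + rng.uniform(-config.center_jitter, config.center_jitter)
        c0 = nc / 2 + rng.uniform(-config.center_jitter, config.center_jitter)
        spot = np.exp(-(((rr - r0) ** 2) + ((cc - c0) ** 2)) / (2 * config.sigma**2))
        chans = {}
        for channel, amp in (
            ("anchor", config.anchor_amplitude),
            ("probe", config.probe_amplitude),
            ("complex", s_m * config.probe_amplitude),
        ):
            img = config.background + amp * spot
            img = img + rng.normal(0.0, config.noise_sd, img.shape)
            chans[channel] = img
        images[a.cell] = chans
        rows.append(
            {
                "cell": a.cell, "mutant_id": a.mutant_id, "replicate": a.replicate,
                "s_m": s_m, "center_row": r0, "center_col": c0,
                "sigma": config.sigma,
                "complex_amplitude": s_m * config.probe_amplitude,
            }
        )
    return images, pd.DataFrame(rows)


def truth_provenance(config: TruthConfig, seed: int) -> dict:
    """Serializable provenance block stored beside generated datasets."""
    return {"generator": "spinachscan.simulate", "seed": int(seed), "config": asdict(config)}
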