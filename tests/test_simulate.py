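"""Synthetic-data generator: truth tables, curves, images, determinism."""

import numpy as np
import pandas as pd
import pytest

from spinachscan import binding, library, melting, simulate
from spinachscan.constants import celsius_to_kelvin
from spinachscan.melting import detect_bimodal
from spinachscan.simulate import (
    ImageConfig,
    NOISELESS,
    NoiseModel,
    TruthConfig,
    make_rescue_truth,
    make_truth,
    simulate_chip_images,
    simulate_melting,
    simulate_titration,
    synthetic_reference,
)


class TestReference:
    def test_default_is_87nt_with_watson_crick_stems(self):
        seq, pairs = synthetic_reference()
        assert len(seq) == 87
        for i, j in pairs:
            assert library.WC_PAIR[seq[i - 1]] == seq[j - 1]

    def test_construction_is_deterministic(self):
        assert synthetic_reference() == synthetic_reference()


class TestMakeTruth:
    def test_default_87nt_truth_has_261_spms_plus_controls(self, reference):
        seq, _ = reference
        truth = make_truth(seq, seed=0)
        assert truth.shape[0] == 261 + 2
        assert {"WT", "NEG"} <= set(truth["mutant_id"])
        wt = truth.set_index("mutant_id").loc["WT"]
        assert wt["kd_uM"] == pytest.approx(1.18)
        assert wt["dh"] == pytest.approx(-9.0)

    def test_zero_nonfluorogenic_fraction_keeps_all_spms_fluorogenic(self):
        seq, _ = synthetic_reference()
        cfg = TruthConfig(nonfluorogenic_fraction=0.0)
        truth = make_truth(seq[:15], config=cfg, seed=1)
        spms = truth[~truth["mutant_id"].isin(["WT", "NEG"])]
        assert spms["fluorogenic"].all()

    def test_same_seed_reproduces_table(self, reference):
        seq, _ = reference
        pd.testing.assert_frame_equal(
            make_truth(seq, seed=9), make_truth(seq, seed=9)
        )

    def test_nonfluorogenic_fraction_near_default(self, reference):
        seq, _ = reference
        truth = make_truth(seq, seed=0)
        spms = truth[~truth["mutant_id"].isin(["WT", "NEG"])]
        frac = 1.0 - spms["fluorogenic"].mean()
        assert frac == pytest.approx(76.0 / 261.0, abs=0.08)

    def test_stem_partners_share_effects(self, reference):
        seq, pairs = reference
        truth = make_truth(seq, seed=2, stem_pairs=pairs)
        by_pos = truth[truth["stem"]].groupby("position")["ddg"].mean()
        for i, j in pairs:
            a, b = by_pos.get(i), by_pos.get(j)
            if np.isfinite(a) and np.isfinite(b):
                # partner positions draw from the same pair-level effects
                assert a == pytest.approx(b, abs=1e-12)


class TestSimulateTitration:
    def test_wildtype_half_saturation_noiseless(self, small_truth):
        _, truth = small_truth
        curves = simulate_titration(
            truth, temps_C=(23.0,), conc_uM=(0.435, 0.9, 1.18, 43.5), noise=NOISELESS
        )
        wt = curves[(curves["mutant_id"] == "WT") & (curves["conc_uM"] == 1.18)]
        assert wt["signal"].iloc[0] == pytest.approx(0.5 * 1.0)

    def test_non_fluorogenic_rows_carry_only_additive_noise(self, small_truth):
        _, truth = small_truth
        noise = NoiseModel(mult_sd=0.5, add_sd=0.01, replicates=2, seed=3)
        curves = simulate_titration(truth, noise=noise)
        neg = curves[curves["mutant_id"] == "NEG"]["signal"]
        assert neg.abs().max() < 0.1  # multiplicative part never enters

    def test_exothermic_wildtype_binds_tighter_cold(self, small_truth):
        _, truth = small_truth
        curves = simulate_titration(truth, noise=NOISELESS)
        wt = curves[curves["mutant_id"] == "WT"]
        # at fixed sub-saturating concentration, higher signal = lower Kd
        sub = wt[np.isclose(wt["conc_uM"], wt["conc_uM"].min())]
        by_temp = sub.set_index("temperature_C")["signal"]
        assert by_temp[19.0] > by_temp[28.0]

    def test_default_design_is_12_concentrations_3_temperatures(self, small_truth):
        _, truth = small_truth
        curves = simulate_titration(truth, noise=NOISELESS)
        wt = curves[curves["mutant_id"] == "WT"]
        assert wt["conc_uM"].nunique() == 12
        assert wt["conc_uM"].min() == pytest.approx(0.435)
        assert wt["conc_uM"].max() == pytest.approx(43.5)
        assert sorted(wt["temperature_C"].unique()) == [19.0, 23.0, 28.0]


class TestSimulateMelting:
    def test_fourteen_temperature_points_per_curve(self, small_truth):
        _, truth = small_truth
        melts = simulate_melting(truth, noise=NOISELESS)
        wt = melts[melts["mutant_id"] == "WT"]
        temps = sorted(wt["temperature_C"].unique())
        assert len(temps) == 14
        assert temps[0] == 23.0 and temps[-1] == 49.0
        assert np.allclose(np.diff(temps), 2.0)

    def test_noiseless_signal_at_tm_is_half_amplitude(self, small_truth):
        _, truth = small_truth
        wt_tm = float(truth.set_index("mutant_id").loc["WT", "tm_C"])
        melts = simulate_melting(
            truth, temps_C=(23.0, wt_tm, 49.0, 51.0, 53.0), noise=NOISELESS
        )
        wt = melts[(melts["mutant_id"] == "WT") & (melts["temperature_C"] == wt_tm)]
        assert wt["signal"].iloc[0] == pytest.approx(0.5)

    def test_bimodal_mutant_detected_end_to_end(self, small_truth):
        _, truth = small_truth
        truth = truth.copy()
        idx = truth.index[truth["mutant_id"] == "WT"][0]
        truth.loc[idx, "bimodal"] = True
        melts = simulate_melting(truth, noise=NOISELESS)
        wt = melts[melts["mutant_id"] == "WT"].sort_values("temperature_C")
        flag, diag = detect_bimodal(
            celsius_to_kelvin(wt["temperature_C"].to_numpy()),
            wt["signal"].to_numpy(),
        )
        assert flag
        assert diag["peak_temperature"] == pytest.approx(
            celsius_to_kelvin(35.0), abs=3.0
        )


class TestSimulateChipImages:
    def _layout_and_signals(self):
        mutants = [library.wildtype_spec(), library.negative_control_spec()]
        layout = library.plan_chip_layout(mutants, n_cells=8, replicates=2)
        signals = {(a.mutant_id, a.replicate): (0.0 if a.mutant_id == "NEG" else 0.7)
                   for a in layout.assignments}
        return layout, signals

    def test_zero_signal_cell_keeps_anchor_loses_complex(self):
        layout, signals = self._layout_and_signals()
        images, params = simulate_chip_images(layout, signals, seed=1)
        neg_cell = params[params["mutant_id"] == "NEG"]["cell"].iloc[0]
        chans = images[neg_cell]
        cfg = ImageConfig()
        assert chans["anchor"].max() > cfg.background + 0.5 * cfg.anchor_amplitude
        assert chans["complex"].max() < cfg.background + 6 * cfg.noise_sd

    def test_same_seed_bit_identical_images(self):
        layout, signals = self._layout_and_signals()
        a, _ = simulate_chip_images(layout, signals, seed=4)
        b, _ = simulate_chip_images(layout, signals, seed=4)
        for cell in a:
            for ch in a[cell]:
                assert np.array_equal(a[cell][ch], b[cell][ch])

    def test_quantified_s_m_rank_matches_generated_at_snr_10(self):
        from scipy import stats
        from spinachscan import spots

        rng = np.random.default_rng(12)
        mutants = [library.MutantSpec(id=f"m{i}") for i in range(24)]
        layout = library.plan_chip_layout(mutants, n_cells=24, replicates=1)
        truth_sm = {(m.id, 1): float(rng.uniform(0.1, 1.0)) for m in mutants}
        cfg = ImageConfig(noise_sd=ImageConfig().probe_amplitude / 10 / 4)
        images, params = simulate_chip_images(layout, truth_sm, config=cfg, seed=13)
        recovered, generated = [], []
        for rec in params.itertuples(index=False):
            _, sig = spots.quantify_cell(images[rec.cell])
            recovered.append(sig.s_m)
            generated.append(rec.s_m)
        rho = stats.spearmanr(recovered, generated).statistic
        assert rho > 0.95


def test_rescue_truth_contrasts_true_pairs_with_controls(reference):
    seq, pairs = reference
    truth = make_truth(seq, seed=5, stem_pairs=pairs)
    table = make_rescue_truth(seq, pairs, truth, seed=5)
    stem = table[table["element"] == "stem"]["s_m"]
    wt_amp = float(truth.set_index("mutant_id").loc["WT", "amplitude"])
    assert (stem > 0.5 * wt_amp).mean() > 0.9
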