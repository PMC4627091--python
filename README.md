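# spinachscan

Reconstruction of the thermodynamic **binding** and **stability landscapes** of a
fluorogenic RNA aptamer (Spinach, in complex with its fluorogen DFHBI) from
chip-based saturation scanning mutagenesis — from mutant-library design and
pull-down spot quantification through curve fitting, landscape scoring and
engineering-candidate selection, validated by parameter recovery on a synthetic
chip-data generator.

## Who this is for

RNA engineers and biophysicists who measure fluorogenic-aptamer mutant panels
(microfluidic pull-down chips, plate titrations) and want a reproducible chain
from raw per-mutant fluorescence series to per-position thermodynamic scores and
a shortlist of beneficial mutations.

## The models

For an aptamer *S* binding its fluorogen *D* with dissociation constant
*K*<sub>d</sub> = [S][D]/[SD], the normalized fluorescence of a titration follows
the two-state isotherm

```
S(D) = A · (D/Kd) / (1 + D/Kd)
```

fit by bounded nonlinear least squares (free plateau amplitude *A*). Mutant
effects are expressed relative to wild type,

```
ΔΔG(T) = −R·T·ln(Kd_m / Kd_wt)        (R = 1.987×10⁻³ kcal/(mol·K))
```

(reported by default in the *favorable-negative* convention: tighter binders get
ΔΔG < 0), and the binding enthalpy ΔH comes from the linear Van't Hoff
regression of ln K<sub>d</sub> on 1/T over titrations repeated at 19, 23 and
28 °C. Melts (23→49 °C in 2 °C steps at saturating DFHBI) are fit to the
two-state unfolding model

```
S(T) = A / (1 + exp[(ΔH_T/R)·(1/Tm − 1/T)])
```

giving the apparent melting temperature T<sub>m</sub><sup>ap</sup> and unfolding
enthalpy ΔH<sub>T</sub>. The four per-mutant parameters (S_m, ΔΔG, ΔΔH, ΔT_m)
are min–max normalized over the single-point mutants (non-fluorogenic mutants
pinned to −1), summed to a per-mutant score, averaged per sequence position and
smoothed with a 3-position window — base-pairing partners in stems show
mirror-symmetric score tracks, and compensatory double mutants quantifiably
rescue the fluorescence lost to their constituent single mutants.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic chip
data with known ground truth:

```
$ python analysis/01_design_library.py --seed 1
reference: 87 nt, 20 designed stem pairs
SPM library: 261 mutants (3 per position)
complete compensatory DPM scan: 11223 mutants (3 per pair)
chip: 640 cells, 4 replicates, capacity 160 mutants

$ python analysis/02_simulate_chip.py --seed 1
truth: 263 rows (261 SPMs; 63 non-fluorogenic SPMs, 24.1% of the library)

$ python analysis/04_fit_landscape.py --seed 1
landscape: 263 mutants, 199 fluorogenic
  median |recovered - truth| s_m : 0.0017
  median |recovered - truth| ddg : 0.0067 kcal/mol
  median |recovered - truth| ddh : 0.3769 kcal/mol
  median |recovered - truth| dtm : 0.1232 C
  wild-type Kd at 23 C: 1.188 uM (truth 1.180)

$ python analysis/06_dpm_rescue.py --seed 1
  partner score correlation (smoothed track): +0.993
  mean rescue index, true pairs   : 0.911
  mean rescue index, control pairs: 0.072
```

Reading: the 87-nt reference yields exactly 3 substitutions per position (261
single mutants; 3·C(87,2) = 11223 for the complete pairwise scan); under 2%
multiplicative measurement noise with 4 replicates, the pipeline recovers the
generating K_d to well within 10% and T_m to ~0.1 °C; planted stem partners are
detectable from score symmetry; Watson–Crick-restoring double mutants recover
~91% of the wild-type signal while mismatched control pairs recover ~7%.

A `spinachscan` CLI mirrors the stages (`design`, `simulate`, `quantify`,
`fit binding`, `fit melting`, `score`, `select`, `rescue`, `run`) over
tab-separated tables; run `spinachscan --help`.

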