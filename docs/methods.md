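# Methods

## Overview

The package reconstructs four per-mutant landscapes from scanning-mutagenesis
fluorescence data of a fluorogenic RNA aptamer: saturating fluorescence S_m,
binding free-energy change ΔΔG, binding enthalpy change ΔΔH, and apparent
melting-temperature change ΔT_m, all relative to wild type. The chain is:
mutant-library enumeration → (optional) spot quantification from three-channel
unit-cell images → two-state binding and melting fits per replicate →
Van't Hoff regression → replicate combination with error propagation →
min–max scoring per position → quantile-based candidate selection and
compensatory-rescue analysis. A synthetic generator produces chip datasets
with known truth so that every stage can be validated by parameter recovery.

## Binding model

Binding is a single-site equilibrium; with ligand in large excess over surface-
bound aptamer, the free-ligand concentration equals the nominal one and the
bound fraction is (D/K_d)/(1+D/K_d). Titrations use 12 concentrations
geometrically spanning 0.435–43.5 μM (two decades; top ≈ 37 × the wild-type
K_d of 1.18 μM). Fits are trust-region least squares (lmfit), multi-started
from three log-spaced K_d initials, K_d bounded to [0.01·min(D), 100·max(D)].

The plateau amplitude is a free parameter by default. Normalizing the curve by
its top-concentration signal instead (the `normalize_at_max` compatibility
mode) biases the apparent plateau low whenever the top concentration is only a
few tens of K_d; the free-amplitude fit removes that bias and its amplitude
doubles as the S_m landscape parameter.

### Van't Hoff sign convention

The linear form ln K = −ΔH/(RT) + ΔS/R applies to an association constant.
Applied literally to a *dissociation* constant, the slope-derived ΔH is the
enthalpy of complex dissociation. `vant_hoff` inverts the literal form
(slope = −ΔH/R, intercept = ΔS/R on ln K_d vs 1/T, K_d in molar), and exposes
`dh_binding = −dh` as the binding-convention enthalpy: negative = exothermic.
The pipeline reports ΔH and ΔΔH in the binding convention, so an exothermic
binder has ΔH < 0 and binds tighter cold (K_d(19 °C) < K_d(28 °C)). The
entropy depends on the standard-state unit chosen for K_d (molar, fixed);
the enthalpy does not.

ΔΔG is reported in the favorable-negative convention by default (tighter
binder ⇒ ΔΔG < 0); the as-printed convention (−RT ln(K_d^m/K_d^wt), positive
for tighter binders) is available via `sign_convention`.

## Folding model

Melts hold the ligand saturating (43.5 μM) and ramp 23→49 °C in 2 °C steps
(14 points). The folded fraction is logistic in 1/T with midpoint
T_m^ap = ΔH_T/ΔS_T; note the hot asymptote is 1/(1+exp[ΔH_T/(R·T_m)]), not
exactly zero. The amplitude is free by default; `anchor_low` pins it to the
lowest-temperature signal (the normalize-to-S_low convention — identical for
clean monotone melts, fragile when the first point is noisy). Temperatures are
converted to kelvin once at the I/O boundary; all model math is in kelvin,
energies in kcal/mol, R = 1.987×10⁻³ kcal/(mol·K).

Rise-then-fall melts (dark at both temperature extremes, fluorescent in
between — a misfolding signature) are flagged, not forced through the
two-state model: the curve is smoothed with a 3-point window and an interior
peak qualifies when it exceeds both endpoints by 3 × the robust point-to-point
noise scale (1.4826·MAD of first differences/√2) — robust and scale-free.

## Spot quantification

The anchor channel defines the pull-down spot: a 7-parameter generalized 2D
Gaussian (elliptical, rotated, constant offset), moment-initialized, fit by
bounded least squares. The foreground disk radius is 2·max(σ) (≥95% energy,
deterministic), the background annulus extends to 1.5 × that radius, and all
signals are channel medians: S_m = (S_i − S_b)/S_p. The probe median is used
uncorrected; with a nonzero probe background this attenuates S_m by a common
factor, which cancels in the min–max-normalized landscape. A fitted amplitude
below 3 × the residual noise scale is a segmentation failure (flagged, never
silently dropped); a probe median at or below the floor leaves S_m undefined.

## Replicates and errors

Each quantity is fit per replicate (four by default) and combined as the mean.
The combined uncertainty follows the as-printed convention of the platform,
σ = sqrt[(Σ(X_j−X̄)²/((N−1)N))² + ((1/N)Σσ_j²)²], which squares terms that are
already variances (its two addends carry fourth-power units); the conventional
quadrature alternative sqrt(SEM² + mean σ_j²) is provided as `quadrature` and
the choice is a config field. ΔΔG per replicate is taken against the
wild-type replicate-mean K_d; its fit error transforms as RT·σ_Kd/K_d.

Non-fluorogenic calls use a threshold of 3 × the negative-control signal
spread at the top ligand concentration (absolute floor 0.02 without a
negative control). Dark mutants carry no thermodynamic parameters and are
pinned to −1 in every normalized score.

## Scoring and selection

Each parameter is oriented so larger = more beneficial (higher S_m, more
negative ΔΔG and ΔΔH, higher ΔT_m — configurable), min–max normalized over
fluorogenic single mutants (affine-invariant), summed to the per-mutant score
in [−4, 4]. The three substitutions at a position are averaged (mean; max
optional) and a 3-position moving window, truncated at the termini, yields the
positional track. Quantile selection uses type-7 empirical quantiles over
fluorogenic mutants, ties broken by mutant id; the engineering shortlist is
the intersection of the beneficial 10% quantiles of fluorescence, binding and
melting temperature.

The rescue index for a double mutant, (S_dpm − S_spm)/(S_wt − S_spm) anchored
on the more deleterious constituent, is a statistic of this package's design
(1 = full rescue, 0 = none; clipped to [−1, 2] for reporting, undefined when
the single mutant already matches wild type).

## Synthetic data generator

The generator emulates the measured system's statistical structure: wild-type
anchors K_d = 1.18 μM at 23 °C, binding ΔH = −9 kcal/mol, T_m = 36 °C
(mid-window), unfolding ΔH_T = 60 kcal/mol, unit amplitude; per-mutant
perturbations ΔΔG ~ N(0, 0.3 kcal/mol), ΔΔH ~ N(0, 2), ΔT_m ~ N(0, 2 °C),
log-normal amplitude spread (σ = 0.08), and a 76/261 ≈ 29% non-fluorogenic
fraction. These scales are bracketed by the measured landscape extremes
(maximum fluorescence gain 1.3-fold, maximum T_m gain 8.4 °C, K_d span of two
decades). Measurement noise is 2% multiplicative plus 0.005 additive, chosen
so the replicate CV sits well under the 5% platform QC bound. K_d(T) follows
the same linear-in-1/T family the fitter assumes — generator and fitter share
a model family, so recovery tests probe estimation error, not model
misspecification.

The 87-nt reference sequence is a deterministic synthetic stand-in with three
designed Watson–Crick stems (8, 7 and 5 bp), a UUCG tetraloop and a G-rich
core; all combinatorial results depend only on length. Stem-position mutant
effects are drawn once per (pair, substitution slot) and shared by both
partners, so partner positions carry identical per-position scores — the
planted analogue of a real stem, where disrupting either strand of a pair
damages the same structure. Compensatory double mutants for stem pairs
recover ~92% of the wild-type signal drop; mismatched control pairs ~8%.

What the generator does *not* emulate: ligand depletion, cooperative or
multi-site binding, sloped melt baselines, heat-capacity (ΔC_p) terms,
photobleaching, spatial chip gradients and cross-talk between unit cells.
Passing recovery tests therefore show the estimation chain is unbiased and
precise under the assumed models and noise — not that real chip data obey
those models.

## Validation studies and problem sizes

`spinachscan.validation` holds the three seeded studies the acceptance script
and tests run: (1) recovery over 100 fluorogenic mutants under the standard
design (a dark mutant has no K_d or T_m to recover); (2) QC of a fully
quantified 640-cell image chip (160 mutants × 4 replicates), summarized by the
median replicate CV — the CV of a near-zero-signal dark mutant is unstable by
construction — and the minimum pairwise inter-replicate correlation; (3) the
stem-symmetry and rescue study on a fully fluorogenic planted landscape. The
symmetry diagnostic targets shared *thermodynamic* profiles between partners;
dark-mutant sentinel spikes (−1 in every score) adjacent to a stem bleed into
the truncated 3-position smoothing windows and dilute the track correlation
without bearing on pairing, so the study isolates the signal it is designed to
detect; the pre-smoothing per-position correlation is reported alongside and
equals 1 by construction whenever partners share effects.

Grid-search oracles (binding: 400-point log K_d grid with the amplitude
profiled out in closed form; melting: 200×200 T_m × ΔH_T grid with ±3-step
local refinement) provide brute-force cross-checks of the nonlinear fits. T_m
is sharply identified; ΔH_T lies along a flat likelihood valley, where a few
refined-grid steps of slack remain.

## Known limitations

* The two-state models carry no baselines; strongly sloped pre/post-transition
  baselines in real melts bias T_m estimates.
* The as-printed error formula is dimensionally inconsistent (documented
  above); comparisons across packages should use the quadrature mode.
* Fragment design treats promoter/anchor/probe tags as opaque strings and the
  19-nt overlap window placement (centred by default) is a design choice —
  no primer-melting optimization is attempted.
* The rescue index is undefined when a single mutant is wild-type-like; such
  pairs are flagged rather than scored.
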