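# Methods

## The thermodynamic cycle

All partition coefficients are dimensionless concentration ratios at
25 °C, carried as log10 values. Because the hexadecane/water and
hexadecane/air coefficients share the hexadecane phase, at equilibrium

    log K_aw = log K_Hxd/w − log K_Hxd/air

holds exactly; no approximation is involved beyond the accuracy of the
two inputs. The package measures (or ingests) K_Hxd/w, takes K_Hxd/air
as an external input table, and derives K_aw. No temperature
dependence, activity-coefficient, or salting-out modelling is included;
everything refers to 25 °C and dilute solutions.

## Mass-balance estimators

**Batch (two-phase).** A hexadecane solution equilibrated against water
in a closed vial; only the water phase concentration c_w is measured.
Under mass conservation,

    K_Hxd/w = (m − c_w·V_w) / (c_w·V_Hxd).

Headspace mass in the 10 mL batch vial is neglected — the procedure
analyzes the water phase only, and for the compounds measured this way
(K_Hxd/air ≥ ~10³) the air inventory is negligible. The shared-headspace
estimator exposes the air term explicitly precisely because there
V_air ≈ 8.65 mL dominates the vial.

**Shared-headspace (three-phase).** Hexadecane and water never touch;
they exchange analyte only through the common headspace. With the air
mass written through K_Hxd/air,

    K_Hxd/w = (m − c_w·V_w) / (c_w·(V_Hxd + V_air / K_Hxd/air)).

When no K_Hxd/air is supplied the air term is dropped and the estimator
reduces to the batch formula; the induced bias is exactly
log10(1 + V_air/(K_Hxd/air·V_Hxd)) (the estimate is biased *high*,
because neglected headspace mass is attributed to hexadecane), which
the simulator tests verify numerically.

**Replicate statistics.** Replicate log10 values are summarized as
mean ± t(0.975, n−1)·SD/√n; at the standard n = 5 design the multiplier
is 2.776. The quantile is computed, not hard-coded, so other n and
confidence levels work unchanged.

**Final-value selection.** When several methods measured one compound,
the default policy prefers the shared-headspace value whenever it is
present and above the batch applicability limit (3.6, see below) or no
batch value exists; otherwise the batch value; the modified VPR-HS
value only when nothing else is available (its CIs are wide under
sorption artifacts). For compounds where batch and shared-headspace
values nearly coincide the choice is immaterial at the reported
precision; the policy threshold and preference order are configurable.

## VPR-HS models and fitting

Both designs vary phase volumes across vials receiving the same spike m
and read a headspace GC/MS peak area PA, assuming response linearity
and no third-phase sorption:

- modified (water + hexadecane, total liquid V_tot fixed):
  PA = α·m / (V_tot + (K_Hxd/w − 1)·V_Hxd)
- standard (water only, vial volume fixed):
  PA = α·m / (V_gas + V_w / K_aw)

α (instrument response) and m are not separately identifiable and are
lumped into one scale parameter. Fits are unweighted least squares on
raw peak areas (a weighted option is a natural extension; the default
mirrors how such series are usually fitted), parameterized in
(log10 scale, log10 K) so the search is unconstrained and stable over
the ~8 decades K can span. Convergence: trust-region least squares,
xtol 1e−10 on relative parameter change, 500 evaluation cap;
non-convergence raises an error carrying the best iterate.

**Initialization** uses the exact two-point solution through the
extreme-volume vials — for the modified design this is the identity
PA(0)/PA(V_tot) = K when the endpoints were run — so noise-free series
converge to machine precision in a few steps, and a 1-D grid-search
oracle (scale is closed-form for fixed K) cross-checks the iterative
fit in the tests.

**Confidence intervals** are a seeded residual bootstrap (default 999
resamples). Measurement noise on areas is multiplicative, so relative
residuals (residual/prediction) are the exchangeable quantity: they are
centered, inflated by √(n/(n−2)) to undo the shrinkage a two-parameter
fit imposes on n points, resampled onto the fitted curve, and refitted.
The interval is the symmetric bootstrap interval log K ± q with q the
95% quantile of |log K* − log K̂|, which calibrates markedly better
than the percentile interval at the 4–8 design points a VPR-HS series
offers (simulated coverage ≈ 93–95% at nominal 95%; the plain
percentile interval undercovers at ~87%).

**Residual diagnostic.** Sorptive losses (glass wall, septum, air/water
interface) violate the mass-balance assumption vial-dependently and
bend the PA-vs-volume curve outside the model family. The fit flags
`systematic_residuals` when the relative residuals both exceed 1% in
magnitude and correlate significantly with the varied volume
(two-sided Pearson p < 0.05, n ≥ 4). The significance requirement keeps
the false-positive rate on plain noisy series near the nominal 5%.

## Artifact models

**Microdroplets.** Entrained hexadecane at volume fraction f in the
sampled water inflates the measured concentration to c_w + f·c_hxd, so

    K_app = K / (1 + f·K),   bias = log10(1 + f·K),
    max measurable log K at bias b = log10((10^b − 1)/f).

This depletion-free closed form is the primary model; an exact variant
that pushes the contaminated concentration through the finite-volume
batch mass balance is provided and used as an oracle in the tests (for
the affected compounds, log K > 4, the two agree to < 0.01 log units).
Per-pair fractions from (accurate, apparent) value pairs are
f = (K/K_app − 1)/K; the summary is their unweighted mean (a one-
parameter least-squares alternative is exposed). On the five bundled
pairs the mean is ~6×10⁻⁵ (0.006 vol %), capping the batch method at
log K_Hxd/w ≈ 3.6 for a 0.1 log-unit bias tolerance.

**Ionization.** Sulfonamides are monoprotic weak acids; only the
neutral species is assumed to partition into hexadecane (anion
partitioning is taken as zero). The neutral fraction is
1/(1 + 10^(pH − pKa)) and the apparent coefficient shifts by its log10.
The 1 mM HCl medium is assigned pH 3.0 and unbuffered water pH 7.0
(both configurable); pKa values are inputs, never predicted. At pH 7 a
pKa 6.3–6.4 acid shifts by 0.70–0.78 log units.

## Homologue trends

Within a homologue group, log K is regressed on the chain-unit count by
OLS; the per-unit increment pools the group slopes as their unweighted
mean, with the SE of that mean as uncertainty (a common-slope,
per-group-intercept regression is available as an alternative and
agrees to ~0.01). The CF₂ count convention is the number of
perfluorinated chain carbons — carbons bearing ≥ 2 fluorines, so the
terminal CF₃ and an ω-CF₂H both count — matching the X of the X:Y
nomenclature; only count differences enter slopes, so any consistent
convention gives identical increments. SMILES-based counting (rdkit)
cross-validates the registry counts. CH₂-increment analysis uses the
same machinery over methylene counts but mixes compound classes whose
membership is less clear-cut, so it is exercised in tests only via
synthetic panels.

## Model evaluation

Errors are predicted − experimental log K_aw. RMSE divides by n (population
mean, no dof correction — these are fixed compound sets, not samples
from a population of compounds); ME is the mean error;
the bias-corrected RMSE is the RMSE of mean-centered errors,
√(RMSE² − ME²). Compounds missing on either side are excluded pairwise
and counted, never imputed. Applicability-domain annotations pass
through as opaque labels.

## Synthetic experiments

The simulator computes exact equilibrium concentrations from the mass
balance at a known true K and layers on disturbances:

- multiplicative lognormal noise with mean-1 factors
  (σ² = ln(1 + CV²)), since analytical variability is relative; CV
  defaults used in tests are 2–5%, typical of chromatographic replicates;
- droplet contamination f·c_hxd added to the sampled water
  concentration (batch only — shared-headspace phases never touch);
- sorptive loss removed from the spike before equilibrium. For VPR-HS
  series the loss is proportional to each vial's water volume fraction
  (a wall/air-water-interface sink); a vial-independent loss would be
  absorbed into the scale parameter and could not distort the curve.

Default geometries mirror the real designs: batch 5 + 5 mL in a 10 mL
vial, shared-headspace 0.35 mL hexadecane / 1 mL water / 8.65 mL air,
VPR-HS 20 mL total liquid with at least four volume levels. All
randomness flows through a mandatory integer seed; identical seeds
reproduce tables bit-for-bit.

What the simulator does *not* emulate: chromatographic peak shapes and
integration, calibration-curve nonlinearity, equilibration kinetics,
temperature drift, or concentration-dependent (isotherm) sorption.
Passing round-trip and coverage tests therefore demonstrates estimator
correctness and calibration under the stated noise model, not immunity
to every artifact of real instruments.

## Problem sizes in the test and acceptance runs

The statistical checks use sizes chosen to make sampling error small
relative to the asserted tolerances while keeping the suite quick:
200 repetitions for the bootstrap-coverage study (binomial SE ≈ 2% at
coverage 0.95) with 300 bootstrap resamples per fit, 200 seeded panels
for the OLS-unbiasedness check, and 0.002-log-unit grid resolution for
the grid-search oracle. The dataset-derived quantities (increments,
droplet fraction, applicability limit, K_aw range) involve no
randomness at all.

## Known limitations

- The droplet model treats f as compound-independent; the five bundled
  pairs scatter between 0.004 and 0.007 vol %, so per-compound droplet
  physics (interfacial activity, sampling depth) is averaged over.
- CI propagation from K_Hxd/w and K_Hxd/air into K_aw is provided
  (quadrature on log-scale half-widths) but the bundled K_aw values
  carry no CI, so it is an extension, not a reproduced result.
- The ionization correction assumes zero anion partitioning into
  hexadecane and a single pKa.
- Bootstrap CIs on ≤ 4-point series degenerate (too few residuals to
  resample meaningfully); the fit then reports the point estimate with
  a CI from the resamples it can form, and replicate-based designs are
  preferable at such sizes.
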