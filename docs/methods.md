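# Methods

This note documents the models implemented in `neqsel`, their
assumptions, the defaults and why they were chosen, what the synthetic
data generator does and does not emulate, and the numerical choices that
matter for reproducing results.

## Work distributions and free energy estimators

A `WorkSet` holds the work values of repeated fast alchemical switches
between two ligands, in both directions, at one temperature. Reverse
works are stored in the reverse direction's own sign convention — the
work done *during* the 1→0 switch — because that is how switching engines
emit them; every estimator negates them internally where the theory
requires. All energies are kJ/mol; β = 1/(RT) with
R = 8.314462618×10⁻³ kJ/(mol·K).

**Jarzynski (JAR).** ΔG = −(1/β) ln⟨exp(−βW_F)⟩ for the forward
direction and the negated analogue for reverse. Exponential averages are
always evaluated via log-sum-exp, so large βW products cannot overflow.
The one-sided estimator is biased (upward for forward, downward for
reverse, shrinking with n); the headline "JAR" value is the arithmetic
mean of the two one-sided estimates when both directions exist, else the
available side, with the method tag recording which. The test suite
verifies the bias signs and their decay on wide work distributions.

**Crooks Gaussian Intersection (CGI).** Normal densities are fitted by
sample mean and unbiased (n−1) variance — deliberately plain moments, not
a likelihood fit, for closed-form testability — to the forward and the
negated-reverse works. With variances equal within relative tolerance
10⁻⁹ the estimate is the midpoint of the means; otherwise the quadratic
from equating the two Gaussian log-densities is solved and the root lying
between the two means is returned. If neither root lies in that interval
(possible when the densities barely overlap), the root closer to the
midpoint is returned and the estimate is flagged.

*Known limitation.* When the mean gap between the two fitted densities
(βσ² for Gaussian work of width σ) falls below the sampling noise of the
fitted variances, the intersection point is ill-conditioned and wanders
by O(σ) rather than O(σ/√n). This shows up in near-noiseless synthetic
studies (σ = 0.05 kJ/mol, n = 400 gives CGI errors up to ~0.1 kJ/mol
while JAR/BAR sit at ~0.002); recovery tests therefore use method-aware
tolerances (0.02 kJ/mol for JAR/BAR, 0.2 for CGI). This is a property of
the estimator, not of the implementation.

**Bennett Acceptance Ratio (BAR).** ΔG is the unique root of the
self-consistent Bennett equation written in Fermi-function form. The
residual is strictly increasing in ΔG (asserted on random instances in
the tests), so the root is found by Brent's method on a bracket spanning
the pooled work range padded by 50 kJ/mol, doubling the padding up to
three times before reporting a convergence error with diagnostics.
Default root tolerance: 10⁻⁸ kJ/mol. The tests cross-check BAR against
two independent routes: a dense zoom-grid minimizer of the squared
residual and a damped fixed-point iteration of the Bennett ratio, both
written separately from the production solver.

**Bootstrap errors.** Standard errors come from resampling with
replacement independently within each direction, preserving per-direction
sample sizes; default 1000 replicates, seed required. If the estimator
fails in more than 20% of replicates the bootstrap aborts loudly.

## Thermodynamic cycle and conformers

ΔΔG = ΔG_complex − ΔG_solvent per (compound pair, kinase), with SEs added
in quadrature. Transformations are all run from one reference compound;
pairs between two non-reference compounds are re-referenced as
ΔΔG(a→b) = ΔΔG(ref→b) − ΔΔG(ref→a), again with quadrature SEs, which
makes chained derivations exactly cycle-consistent.

When a ligand was started from alternative conformers (e.g. the two
orientations of an intramolecular hydrogen bond), the conformer with the
lowest ΔΔG is selected per (pair, target, method) — per method
independently, since results are reported method-wise — with ties broken
by lexicographic conformer label. The selected conformer's own SE is
carried unchanged: no selection-uncertainty inflation is applied, which
mirrors the lowest-ΔΔG rule literally; inflation schemes are out of
scope. Cells missing a leg are reported as diagnostics, never imputed.

## Experimental conversion

IC50 values with 95% CIs are converted through the Cheng–Prusoff
equation, Ki = IC50/(1 + [ATP]/Km), and pairs on the same kinase through
ΔΔG_exp = RT ln(K_i/K_j). Within one target at fixed [ATP] the
Cheng–Prusoff factor cancels in the ratio, so the implementation computes
ratio-based ΔΔG whenever no Km is supplied and requires an explicit Km
only to report absolute Ki (never a silent default). The CI is treated as
symmetric in log-IC50 — potency assay errors are multiplicative — giving
the log-scale SE s = ln(CI_high/CI_low)/(2z) with z = 1.959964, and
SE(ΔΔG) = RT·√(s_i² + s_j²).

Default conversion temperature is 303.15 K (the 30 °C of the kinase
assay), configurable. Default simulated-work temperature is 298.15 K.

## Selectivity

ΔS_ij = ΔΔG_ij^k − ΔΔG_ij^ref across kinases, with quadrature SEs — the
selectivity shift therefore carries the combined error of two ΔΔG values
and is intrinsically noisier. Pairs are re-referenced to a configurable
selectivity compound (default compound "2") before taking the
cross-kinase difference; the reference kinase (default CDK2) is excluded
by construction since its ΔS is identically zero. On a 4-compound ×
4-kinase panel this yields 3 pairs × 3 kinases = 9 values per method.

## Errors-in-variables validation

Calculated (y) and experimental (x) tables are joined per (pair, target)
and fitted per estimator method with generalized Deming regression:
x_i = ξ_i + δ_i, y_i = a + bξ_i + ε_i with per-point variances x_se_i²
and y_se_i². Profiling out the latent ξ_i and the intercept reduces the
problem to minimizing S(b) = Σ (y_i − a(b) − b·x_i)²/(y_se_i² + b²·x_se_i²)
in the slope alone, which is solved by 1-D Brent to xtol 10⁻¹³ from
OLS/orthogonal-regression starting points with bracket expansion. This
direct profile minimization reaches the same stationary point that
iterative-reweighting schemes target, but cannot stall or oscillate; with
equal constant SEs it reproduces the closed-form orthogonal (λ = 1)
Deming slope to 10⁻⁸ and tends to weighted OLS as x_se → 0 (both
asserted in tests). Zero SEs are replaced by the smallest positive SE on
the same axis (or 1 if that axis has none), so exactly-known points keep
the largest finite weight.

The slope's 95% CI comes from a leave-one-out jackknife with the normal
quantile z = 1.959964; a statistically significant linear relationship is
declared when the CI excludes zero. With n = 12 points the z-based
jackknife CI is slightly anticonservative (a t-quantile would widen it
~12%); measured coverage of the true slope over 50 seeded synthetic
studies is 90–92%.

R², RMSE and MAE are computed against the identity line y = x (squared
Pearson correlation for R²), not against the fitted line: they measure
how well calculation reproduces experiment. With zero variance on either
axis R² is reported as undefined (NaN) while RMSE/MAE are still returned.

kcal presentations divide by 4.184 (thermochemical) by default; the IT
convention (4.1868) is also exposed because published two-decimal
equivalents of kJ/mol quantities are reproducible under either truncation
of the thermochemical quotient or the calorie-convention choice, and the
raw quotient is what the function returns.

## Synthetic data generator

The generator emulates the two inputs of a real campaign from a known
ground truth so every stage is testable without MD:

* **Work samples** are Gaussian with dissipation βσ²/2: forward
  ~N(ΔG + βσ²/2, σ²), reverse ~N(−ΔG + βσ²/2, σ²), which satisfies the
  Crooks theorem exactly at the distribution level (the tests fit
  ln(P_F(W)/P_R(−W)) against W and recover slope β and crossing ΔG).
  Complex-leg truth is solvent_dG + (ΔG_bind[alt] − ΔG_bind[ref]);
  solvent-leg truth is per compound pair (target-independent, as the
  solvent leg of the cycle is), though samples are drawn per (pair,
  target) so each cell closes its own cycle.
* **IC50 records** follow Ki = exp(ΔG/RT) (molar standard state,
  reported in µM) times the Cheng–Prusoff factor, multiplied by
  log-normal noise exp(N(0, sd²)), with a log-symmetric 95% CI consistent
  with that sd.

Defaults describe a small kinase-inhibitor panel: 4 compounds (reference
"1") × 4 CDKs (reference "CDK2"), 100 switches per direction, work spread
σ = 2 kJ/mol, binding free energies near −35 kJ/mol with a few kJ/mol of
compound/target structure (sub-µM potencies at 303 K), [ATP] = 1 µM,
Km = 10 µM, log-IC50 noise sd = 0.1 (~±20% potency scatter). Randomness
uses one root seed with per-record substreams derived from CRC32 tags, so
regenerating any record is order-independent and bit-reproducible.

What the generator does *not* emulate: non-Gaussian work tails from rare
switching events, correlations between legs or between conformers,
systematic force-field error (calculated and experimental truths coincide
by construction), Km uncertainty, and asymmetric dose–response CIs.
Passing recovery tests therefore demonstrate the correctness of the
estimators and plumbing under the stated noise model, not the accuracy of
any force field or sampling protocol on real systems.

## Problem sizes in the tests

The shipped suites use study sizes chosen to make the statistical checks
sharp while keeping the whole suite fast: estimator-consistency sweeps at
n = 200/direction over 50 seeds, coverage over 50 synthetic studies at
n = 60/direction with a 30-replicate bootstrap, and end-to-end recovery
at σ = 0.05 kJ/mol, n = 400/direction. The acceptance script
(`scripts/acceptance.py`) recomputes its numbers at these same sizes from
a single `--seed`.

## Known limitations

* Only two-state non-equilibrium work inputs: no multi-λ equilibrium
  FEP/MBAR estimation.
* CGI's near-degenerate ill-conditioning (above).
* The jackknife-with-z slope CI is mildly anticonservative at small n.
* Conformer selection carries no selection-induced uncertainty.
* Absolute Ki (and hence absolute ΔG) requires user-supplied Km values;
  the packaged kinase panel ships without them, which is sufficient for
  all ΔΔG/ΔS work.
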