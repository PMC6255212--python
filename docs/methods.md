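# Methods

This note documents the models, numerical choices, and limitations of the
package, stage by stage.

## Units and conventions

Residual activity is stored in **percent** of the untreated control
(A0 ≈ 100). This is load-bearing: the second-order rate constant kd then
has units %⁻¹·min⁻¹, intercepts of 1/A-vs-t regressions are ~0.01, and the
half-life formula t½ = 1/(100·kd) is exact (time for A to fall from 100 to
50 is (1/50 − 1/100)/kd). Temperatures cross API boundaries in °C and are
converted to Kelvin inside all thermodynamic expressions. Residue numbering
is 1-based sequence numbering, so mutation names like H192P address residue
192 directly.

## Inactivation kinetics

The second-order model 1/A(t) = 1/A0 + kd·t is fitted by **ordinary least
squares in the transformed space** (t, 1/A), with R² reported in that same
space. A weighted fit (weights ∝ A⁴, the delta-method variance of 1/A under
homoscedastic noise on A) would be statistically tighter, but the plain OLS
matches how such regressions are conventionally reported alongside
1/RA-vs-time plots and is kept as the default; the transformed-space
estimator is unbiased under Gaussian noise on 1/A (verified by Monte Carlo
in the tests). Activities ≤ 0 are rejected rather than dropped: the
transform is undefined and silently discarding points would bias the slope.

T50 (the temperature halving activity within a fixed incubation) is the
inflection of a four-parameter Boltzmann sigmoid
RA(T) = A2 + (A1−A2)/(1+exp((T−T50)/w)). Initialization: plateaus from the
data extremes, T50 at the steepest observed descent, width 2 °C; T50 is
bounded to the measured range so the optimizer cannot wander outside the
data.

Deactivation free-energy changes use
ΔΔG‡ = RT·ln[(1−RA_wt)·RA_var/((1−RA_var)·RA_wt)] with R = 8.314
J·mol⁻¹·K⁻¹ and T defaulting to 333.15 K (the 60 °C incubation). Retained
activities enter as fractions in (0, 1); the function is exactly
antisymmetric under swapping variant and WT. Published values computed from
rounded retained activities can differ from ours below the 1% level (e.g.
9.25 vs a printed 9.30 kJ·mol⁻¹); we make no attempt to reverse-engineer
unrounded inputs.

## Two-state unfolding

The melt signal is fitted to
I(T) = [I_N + aT + (I_D + bT)·K]/(1+K), K = exp[(ΔHvh/R)(1/Tm − 1/T)], with
R = 1.987 cal·mol⁻¹·K⁻¹, all temperatures in Kelvin, and ΔHvh (not ΔSvh) as
the free parameter; ΔSvh = ΔHvh/Tm is always derived, so the two can never
be inconsistent. Baselines are linear in Kelvin (slopes are identical per
°C; only intercept bookkeeping differs). Initialization: baselines by OLS
over the first/last 15% of points, Tm at the extremum of the smoothed
derivative, ΔHvh start 100 kcal·mol⁻¹. The optimizer runs at tight
tolerances (1e-14), giving parameter recovery at the 1e-8 level on
noiseless model-generated curves; Tm is bounded to the scanned range and
the result flagged when the midpoint lands on the boundary. A flat
(zero-amplitude) melt raises a fit error instead of returning arbitrary
parameters.

The model is deliberately two-state. For a homodimer whose unfolding,
cofactor release, and dimer dissociation happen together, the fitted ΔHvh
is an *apparent* van't Hoff enthalpy; low ΔSvh values then read as reduced
apparent cooperativity, not a calorimetric quantity.

Note on round trips: published (Tm, ΔSvh, f60) triples are rounded, and not
every row of a printed table is self-consistent under Eq. 3–4 round-tripping;
consistency checks in the tests are restricted to rows that are (WT and the
H192P/A282P double).

## Aggregation onset

The instrument software that produced the published Tagg values is closed,
so the package defines its own detector, chosen for robustness and affine
invariance (SLS counts are arbitrary units): estimate the baseline mean and
SD from the initial flat region (first 5 points, extended to the trigger),
declare a rise at the first run of ≥3 consecutive points above
mean + 5·SD, fit an OLS line through that run, and report the intersection
of that line with the baseline level. The SD is floored at 1e-9 of the
signal range so exactly flat noiseless baselines still trigger;
back-extrapolated onsets are clamped to the scanned range. A trace whose
"baseline" slope is more than half the rise slope has no flat
pre-aggregation region and is rejected. Trigger multiplier and run length
are configurable. A completely flat trace returns the no-aggregation
sentinel (None) rather than an arbitrary temperature.

## Epistasis

Coupling is ΔXY − (ΔX + ΔY) with root-sum-of-squares SE propagation. The
taxonomy is evaluated with precedence reciprocal-sign → sign → 
additive/positive/negative because the categories overlap at their
boundaries; "additive" is an interval of half-width equal to the tolerance
(default: the propagated SE — published panels call combinations additive
"within error", never at exact equality). The sign-epistasis condition "the
double is below (one of) the singles" is implemented in its weaker reading,
ΔXY < max(ΔX, ΔY); results that satisfy only the weaker condition carry a
`weak_sign` flag so the stricter reading can be recovered.

The unit partition is explicit configuration: phase-1 analyses use
({A}, {B}), phase-2 analyses treat the double AB as a single inherited unit
alongside C and D, and both run through identical machinery. Expected
values for multi-mutant combinations are **sums of partner deltas** (as an
observed-vs-expected scatter's x-axis would be), not recombinations of raw
retained activities. Pathway enumeration materializes all n! orderings and
verifies telescoping (step deltas sum exactly to the target's delta);
"no local minima" means every step of every pathway is favorable within
tolerance.

## Trajectory dynamics

Superposition is a per-frame Kabsch fit onto a reference frame (default:
first analysis frame; an iterative mean-structure reference is available
via `iterative_mean=True`). RMSF is computed about the
time-mean position per replicate and replicate profiles are averaged
arithmetically — matrices and profiles are averaged, never concatenated
trajectories, so replicates with different equilibration states do not
cross-contaminate covariances.

One statistical subtlety: rigid-body fitting absorbs 6 of the 3N
fluctuation degrees of freedom, biasing RMSF low by a factor ≈ √(1−2/N)
for N fitted atoms of comparable mobility. For N ≥ 100 this is under 1% and
irrelevant in practice; synthetic closed-form checks in the tests use
ensembles large enough that the bias is inside their tolerance.

The DCCM uses the standard isotropic (scalar dot-product) normalization —
one coefficient per residue pair in [−1, 1] — computed per replicate and
then averaged. Zero-variance atoms get off-diagonal 0 / diagonal 1 and are
recorded in the provenance. Homodimer chain averaging pairs residue i of
chain B with residue i of chain A (or an explicit bijection) and averages
the two intra-chain blocks; inter-chain entries, which are weak for this
system, are discarded. Correlated-region extraction thresholds |C_ij| (default
0.2, the conventional cutoff for "strong" dynamic coupling), requires
sequence separation > 20 residues so the trivially correlated diagonal band
is excluded, groups surviving entries into connected components, and
reports each component's bounding box, mean C, and sign.

ΔRMSF normalization is not standardized in the literature; the package
divides each profile by its own all-residue mean before differencing.
Rationale: it removes overall scale differences between simulations
(temperature, sampling, replicate count) while preserving the spatial
pattern and sign structure; z-scoring would additionally equalize the
spread, which conflates a genuine global rigidification with a scale
change. Mutation-site summaries average the profile over 11 sequential
residues centered on the site (window clipped at termini).

## Synthetic data

Generators mirror the fitted models exactly, so at σ = 0 every fit is an
exact inverse (property-tested). Noise is Gaussian on the measured channel;
defaults are sized to the reference panel's reported triplicate SEMs
(decay: 1% activity; melt ratio: 0.002; SLS: 50 counts; T50 curves: 1%
activity). The trajectory generator samples i.i.d. frames from a
multivariate Gaussian with per-axis covariance D·R·D (D = per-residue σ, R
= planted correlation), so the ground-truth isotropic DCCM is R and the
ground-truth RMSF is √3·σ. Planted cross-block correlations are applied as
compound symmetry over the union of the two blocks — a bare cross-block
correlation without matching within-block correlation is not a valid
(positive semi-definite) structure. An AR(1) frame-memory option exists for
effective-sample-size experiments; it preserves the stationary covariance.

What the generators do *not* emulate: real MD autocorrelation by default,
anisotropic per-residue fluctuations, aggregation kinetics beyond the
flat-then-linear onset phenomenology, and any coupling between the
stability metrics of one variant. Passing tests therefore demonstrate
correctness of the estimators under the stated models, not the physics of
any particular protein.

## Problem sizes

Test and demonstration runs use 61-point melts (30–90 °C at 1 °C), 44-point
Boltzmann curves, 7–13-point decay series, trajectory ensembles of
100–200 residues with 5,000–10,000 frames for closed-form checks, and
100–500 Monte-Carlo replicates for bias checks — sizes chosen so the whole
suite runs in well under a minute per module while keeping Monte-Carlo
error small against the tested tolerances.

## Known limitations

- The two-state fit reports apparent van't Hoff parameters; no three-state
  or dissociation-coupled model is provided.
- The Tagg detector assumes a monotone rise after onset; saturating or
  non-monotone SLS traces are fitted only through the first above-threshold
  run.
- Binary trajectory formats (dcd/xtc) are not read; multi-model PDB and
  plain XYZ are the interchange formats, with the same contract available
  for binary readers if ever added.
- Higher-order (three-way) epistasis decompositions are out of scope; only
  pairwise bipartition couplings are computed.
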