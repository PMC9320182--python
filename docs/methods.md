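# Methods

This note records the scientific assumptions, defaults and numerical choices
behind `aquarisk`, in the spirit of a model-description appendix.

## Reference constants and classification

Permissible limits (mg/L), oral reference doses (mg/kg-day), cancer slope
factors ((mg/kg-day)⁻¹) and cohort exposure parameters are compiled into
`reference.py` and exportable to YAML for other jurisdictions. The slope
factors cover As (1.5), Pb (8.5×10⁻³) and Ni (0.84); lead's carcinogenic
treatment follows the source risk framework even though agencies differ on
it. The default authority is PNSDW; WHO is selectable. Mixing authorities
inside a single MPI computation is rejected, since the weights W = 1/S are
authority-specific.

Classification scales are ordered thresholds with explicit boundary
closures. Where the printed inequality conventions overlap or leave a gap
(CV at 35%, TCR at each decade boundary), the more-polluted/riskier label
wins — the conservative call for a screening tool. The CV variability
classes are ≤15% low, (15,35)% intermediate, ≥35% high.

All concentrations are mg/L throughout. The intake equation is sometimes
stated with µg/L inputs in the literature this framework follows, but the
reported intake values are only consistent with mg/L; the package fixes
mg/L and does no unit conversion.

## The intake algebra

With the default cohort parameters EF×ED = AT exactly (365×70 = 25550;
365×10 = 3650), so CDI collapses to C×IR/BW. The implementation evaluates
the full five-parameter expression; the collapse is verified to 15 digits in
the tests as an algebraic identity, not assumed. Risk from grouped samples
follows the mean-concentration convention: average concentrations within the
group first, then apply the chain. A per-sample mode exists because ranges
and percentiles across sites require it.

## Synthetic campaigns

The generator emulates a three-source-type campaign (defaults 25 water
refilling station / 26 groundwater / 21 tap-water samples — the explicit
per-source counts of the emulated design; the total is configurable because
published counts for such campaigns are often internally inconsistent).
Concentrations are lognormal, moment-matched to target (mean, SD) via
σ² = ln(1+s²/m²), µ = ln m − σ²/2. Lognormality is an assumption, chosen
because environmental concentrations are non-negative and right-skewed and
the emulated campaign's CVs (up to ~366%) are impossible under normality.
Below-detection results are stored as 0; the default censoring probability
is 0 (no censoring rate is published for the emulated campaign) and is
configurable per metal, with an optional LOD/2-style substitution value.
Physicochemical fields are independent truncated normals (pH clipped to
0–14, others to ≥0); they exist to exercise the correlation machinery, not
to model aquifer chemistry.

Spatial mode adds a smooth latent field — low-order polynomial trend plus
six random cosine modes at the configured correlation length, normalised to
zero mean and SD `trend_amplitude` — to the log-concentration of one chosen
metal. The generator exposes the true field, giving the mapping module a
ground truth. What the synthetic campaign does **not** reproduce: between-
metal correlation beyond the shared field, instrument error structure,
preferential sampling near pollution sources. Tests passing on synthetic
campaigns therefore validate the *computations*, not any claim about real
aquifers.

## Pollution indices

Metals reported as 0 are kept in the MPI/NPI summations with Q = 0; dropping
them would silently change ΣW. Group indices are reported two ways — index
of mean concentrations and mean of per-sample indices — because the two
differ for the nonlinear NPI and "average index" phrasing is ambiguous in
routine reports.

## Monte Carlo and sensitivity

Inputs are drawn independently (no correlation structure is assumed),
alphabetically by variable name from a single seeded `numpy` generator, so
results are reproducible across platforms and the seed fully determines the
run. Percentiles are the linear-interpolation empirical quantiles.
Concentration distributions are lognormal moment fits to the sample moments;
exposure variables default to point masses, with an optional
uncertain-exposure profile (normal BW with 10% CV, uniform IR ±25%) for
sensitivity studies. Truncation, when requested, clips draws to the bounds
(cheap, slightly inflates boundary mass; acceptable for the wide bounds used
here).

Sensitivity is the contribution-to-variance convention of spreadsheet risk
add-ins: signed squared Spearman rank correlations normalised to 100% in
absolute value. Numerator variables of the CR equation can only contribute
non-negatively, denominator variables non-positively. Published MC means and
percentiles for this kind of study depend on undisclosed distributional
assumptions, so the package ships an illustrative "paper-style" profile
(lognormal concentrations fit to summary moments, point exposures) and
validates the machinery by properties instead: degenerate runs equal the
closed-form CR to 1e-12, and the RMSE of the MC mean decays as n^(−1/2).

## Statistics

SD uses the n−1 denominator; a single observation reports SD 0 with a
warning. "Pearson rank-order correlation" conflates two methods, so both
Pearson (default; matrix plots of raw parameters) and Spearman are
implemented. p-values come from the t transform of r on pairwise-complete
observations; no multiplicity correction is applied (none is conventional in
these campaign reports). Significance stars are two-sided at 0.05/0.01.
Metal clustering z-scores each variable and applies Ward linkage on
Euclidean distances between variable profiles — the common default for
water-chemistry dendrograms; average linkage is available. Zero-variance
variables are excluded with a warning; ties break deterministically by
lowest index.

## MLGI mapping

The trend is a 2→H→1 tanh network (k = 4H+1 weights) trained by global-best
PSO with constriction constants (inertia 0.729, cognitive = social = 1.494),
velocity clamp ±1 in standardised weight space, positions initialised in
[−1,1]. Inputs and target are standardised internally and the scalings are
stored on the model, so predictions are in original units (round-trip checked
to 1e-10). The data split is a seeded 70/15/15 train/validation/test;
training minimises train MSE, and the report carries validation MSE and
Pearson R on both held-out sets because either may be quoted as "R".
Architecture selection minimises AIC = n·ln(MSE_train) + 2k over H ∈ 1..30,
ties to the smaller network.

The residual stage is ordinary kriging with an exponential variogram
γ(h) = nugget + psill·(1 − e^(−h/range)) fitted by Cressie-weighted least
squares (weights N(h)/γ²) to a 12-bin empirical semivariogram capped at half
the maximum lag; fewer than four usable lags fall back to a
method-of-moments guess (nugget 0, psill = variance, range = h_max/3).
True empirical Bayesian kriging is proprietary and unspecified; the
"EBK-flavoured" option approximates its treatment of variogram uncertainty
by refitting the variogram on B = 20 seeded 80% bootstrap subsamples and
averaging the B prediction surfaces. Singular kriging systems get diagonal
jitter with a warning. Grid cells outside the Delaunay hull of the sites are
flagged extrapolated. Lon/lat coordinates are projected by a local
equirectangular transform about the centroid — adequate at island scale,
wrong for continental domains.

Published MSE/R tables for this kind of two-stage mapping depend on
unreleased per-site data and are not reproduction targets; parity is
structural (same report columns) and property-based: exact interpolation at
zero nugget, monotone best-so-far PSO traces, surface recovery R ≥ 0.9 on a
150-site synthetic smooth field, and cross-validated kriging beating an
independent inverse-distance baseline on a field with known covariance.

## Problem sizes and defaults

Tests and examples use campaign sizes of 24–10,000 samples, MC runs of
10²–4×10⁴ iterations, mapping fits of 25–30 particles × 250–400 iterations
on 60–150 sites, and 10⁴-draw moment-recovery checks — sizes at which every
stochastic assertion has comfortable statistical margin while the whole
suite stays interactive. The pipeline defaults (10,000 MC iterations, 40×40
grid) match routine analysis practice.

## Known limitations

- Ingestion pathway only; no dermal/inhalation routes, no age-interpolated
  exposure factors.
- Independence of MC inputs; no 2-D variability/uncertainty separation.
- Isotropic exponential variograms only; no co-kriging across metals.
- The equirectangular projection ignores datum and convergence; use planar
  coordinates where precision matters.
- The CV of extremely skewed concentration distributions is itself a noisy
  statistic; class labels near the 35% boundary should not be
  over-interpreted.
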