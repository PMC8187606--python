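# Methods

This note documents the models, conventions, numerical choices and known
limitations of `lemfold`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Thermodynamic models

**Linear extrapolation (LEM).** Every chemical transition is summarized
by a zero-denaturant free energy ΔG°(H₂O) (kcal/mol) and a slope *m*
(kcal mol⁻¹ M⁻¹): ΔG(c) = ΔG° − m·c. The midpoint Dm = ΔG°/m is the
concentration with the two flanking states equally populated. *m* tracks
the surface area newly exposed on unfolding; small *m* (≲1 for a ~340
residue chain) means a broad, weakly cooperative transition.

**Two-state** (N ⇌ U): K = exp(−ΔG(c)/RT), f_U = K/(1+K).

**Three-state** (N ⇌ I ⇌ U): both equilibrium constants are referenced
to the native state, K_NI and K_NU, each with its own LEM line; the
fractions are the 3-way Boltzmann weights. The I ⇌ U leg follows by
additivity (ΔG_IU° = ΔG_NU° − ΔG_NI°, m_IU = m_NU − m_NI) and is exposed
as derived accessors, never fitted independently. Construction enforces
ΔG_NU° ≥ ΔG_NI° (the N → I → U scheme presumes ordered stability); the
fitter honours it through the reparameterization ΔG_NU° = ΔG_NI° + δ,
δ ≥ 0.

**Observed signal.** Probe signals (MRE at 222 nm, relative fluorescence
at 340 nm) are population-weighted averages of per-state baselines that
are linear in the perturbant: S_N = a₁ + b₁c, S_I = c₁ + p₁c,
S_U = e₁ + g₁c (two-state uses a₁,b₁/c₁,p₁).

**Thermal melts.** Van't Hoff two-state: ΔG(T) = ΔH_vH·(1 − T/Tm), with
ΔCp = 0 — the heat-capacity change is not identifiable from a single
melt — and baselines linear in T. Tm is stored in kelvin and reported in
°C at interfaces.

**Conditions.** R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹; chemical analyses default
to T = 298.15 K, the temperature at which denaturation samples are
equilibrated. Celsius is accepted at interfaces and converted.

**Numerical safety.** Boltzmann exponents are clipped at ±700 before
exponentiation; three-state weights are computed shift-stably (softmax),
so fractions sum to one to 1×10⁻¹² at any denaturant concentration and
saturate rather than overflow in extreme limits.

## Fitting

All fits minimize unweighted SSR with lmfit's trust-region least squares
(ftol = xtol = gtol = 10⁻¹⁵), multi-started over candidate midpoints at
the 20/35/50/65/80% quantiles of the x-range (pairs of quantiles, both
orderings and several cooperativity levels for the double sigmoid).
Baselines are pre-estimated from straight lines through the first and
last three points of the sorted curve; the intermediate baseline starts
flat at the mid-curve median. SSR ties within 10⁻¹⁰ go to the smaller
total stability.

**Three-state candidate structure.** The fully free 10-parameter double
sigmoid has a degenerate ridge: solutions with a transition driven to a
step function (cooperativity slammed against its physical cap of
10 kcal mol⁻¹ M⁻¹) or with a free baseline tilted through the real
transition can undercut the true basin's SSR at realistic noise. The fit
therefore assembles three candidates and compares them by AICc with each
one's true parameter count:

1. *fixed-baseline* — baselines held at their drawn estimates (the
   classical protocol of drawing baselines first), only the four
   thermodynamic parameters optimized; still charged ten parameters,
   since the baselines came from the data;
2. *free* — all ten parameters, multistart plus polishes of the leading
   fixed-baseline basins, discarding any solution pinned against an
   upper parameter cap (lower bounds — zero stability, δ = 0, a flat
   transition — are legitimate degenerate limits and are reported, not
   rejected);
3. *collapsed* — the intermediate switched off (δ = 0, m_NI ≈ 0, S_I
   tied to S_U): an effective two-state fit in three-state form with six
   free parameters.

Within 2 AICc units of the best candidate the one with fewer parameters
wins: the least-intermediate reading consistent with the evidence is the
reported default, and a collapsed winner carries an explicit warning.
This matters because on a single probe the state labels of an
unsupported intermediate are pure convention — equally good fits exist
in which "I" is the unfolded state.

**Uncertainties.** Per-fit standard errors come from the covariance at
the optimum (linear approximation), with derived quantities (Dm, ΔG_IU°,
m_IU, Tm in °C) propagated through their gradients.
`aggregate_replicates` separately reports the across-replicate mean and
SEM (sample SD/√n), the statistic triplicate experiments quote; the two
kinds of uncertainty are never conflated.

**Ill-conditioning.** A curve with all points effectively on one
baseline (monotone drift, constant signal, an irreversible refolding
branch) supports no transition. The criterion is effect size: the fitted
model must reduce a straight line's SSR by at least 20%, else the fit
raises `IllConditionedError`. Model-comparison (AICc vs line) and
polynomial-curvature variants were considered and perform worse: a
well-separated double sigmoid is globally almost line-like, so
curvature tests misfire, while information criteria flip by seed on
borderline misspecified fits.

**Model selection.** `select_model` fits both chemical models and
recommends the lower AICc (k + 1 parameters including the noise
variance); ΔAICc < 2 is flagged ambiguous. A three-state fit that
collapsed is itself the verdict that no intermediate is supportable, and
converts directly into a two-state recommendation.

## Synthetic experiments

`SyntheticConfig`/`simulate_curves` emulate the real experimental
designs: urea 0–8 M and GdnHCl 0–6 M in 0.25 M steps, melts 20–90 °C in
1 °C steps, three replicates, Gaussian noise with σ equal to 2% of the
transition amplitude |S_N(x_min) − S_U(x_max)| by default. Amplitude
scaling makes one noise level mean the same thing for an MRE curve, a
fluorescence curve, or a melt. Generation is deterministic per seed
(numpy `default_rng`).

A coverage check requires at least three grid points on each baseline
plateau, judged relative to the plateau level (within 10% of the
fraction's own maximum, maximum above 0.8): a marginally stable protein
with ΔG_NI° ≈ 1.4 kcal/mol never reaches 95% native even in water, yet
its pre-transition baseline is still resolved.

`simulate_emission_scans` produces tryptophan emission bands (Gaussian,
25 nm FWHM) whose center mixes the native (340 nm), intermediate
(345 nm) and unfolded (360 nm GdnHCl / 357 nm urea) maxima by the
species fractions, and whose height is normalized so the 340-nm reading
equals the closed-form probe signal — the titration extracted from the
scans is byte-for-byte the curve the curve-generator produces at zero
noise (pipeline closure). An irreversible refolding branch is emulated
as the unfolded baseline plus noise, for failure-mode tests only.

What the generator does **not** emulate: instrument drift,
photobleaching, aggregation artifacts, heteroscedastic noise,
wavelength-dependent band shapes. Passing recovery tests therefore show
estimator correctness under the stated statistical model, not robustness
to every artifact of real instruments.

## Spectra handling

Scan tables are read from delimited text in wide (wavelength + one
column per condition) or long (tidy) layout; malformed rows are reported
with their line numbers. Mean residue ellipticity uses the molar
convention MRE = θ/(10·l·C·N_res) (θ in mdeg, l in cm, C in mol/L),
which reproduces standard deg·cm²·dmol⁻¹ values; whether a published
MRE used the molar or mass convention is often unstated, so the
conversion inputs are explicit arguments. Probe extraction interpolates
linearly between grid neighbours with no smoothing; relative
fluorescence subtracts the reading at the highest perturbant
concentration. The emission maximum refines the grid argmax with a
3-point parabola (falling back, flagged, to the raw argmax at grid
edges), avoiding 1-nm quantization artifacts.

A280 extinction coefficients use the Pace chromophore increments
(5500 Trp + 1490 Tyr + 125 cystine, M⁻¹cm⁻¹); a reduced protein
contributes no cystine term. For AAR (6 Trp + 6 Tyr) this gives exactly
41,940 M⁻¹cm⁻¹.

## Known limitations

* **Three-state parameter identifiability.** With free linear baselines
  and 2% noise on ~25 points, the individual ΔG° and *m* of two
  overlapping transitions are weakly identified: SSR-equivalent fits
  with very different parameter vectors exist, and the data often cannot
  statistically justify the intermediate at all (the collapsed candidate
  wins AICc). What is robustly recovered is the curve itself — fits
  track the generating signal to a few noise SD everywhere — and, when
  the transitions are well separated, the model choice. Classical
  analyses escape this by drawing and fixing baselines by hand and by
  asserting the intermediate from orthogonal evidence (probe
  non-coincidence, size exclusion); the fixed-baseline candidate
  reproduces that protocol, and its warning tells you when it was used.
* Thermal fits neglect ΔCp; Tm is reliable, ΔH_vH is an effective
  (van't Hoff) value.
* No global multi-probe fitting: each probe's curve is fitted
  independently, as in the source experiments.
* Report precision follows the conventional tables: two decimals for
  ΔG/m/Dm, one for Tm.

## Problem sizes

Defaults used throughout tests and examples: chemical curves of 25–33
points, melts of 71 points, 3 replicates; recovery studies use 50 seeds;
selection studies 10 seeds per truth. These match the experimental
designs being emulated and keep any single study in the seconds-to-
minutes range.
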