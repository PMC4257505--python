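# Methods

`borealacid` assesses anthropogenic acidification of boreal lakes two ways —
through water chemistry (deviation of contemporary pH from a pre-industrial
reference) and through biology (loss of roach, *Rutilus rutilus*, from the
historical survey record) — and quantifies how consistently the two agree.
This note documents the models, their assumptions, the defaults, and what
the synthetic data do and do not establish.

## Charge-balance speciation

The chemical core solves a steady-state proton balance for one lake-water
sample. Let BC = 2[Ca²⁺]+2[Mg²⁺]+[Na⁺]+[K⁺]+[NH₄⁺] and
SAA = 2[SO₄²⁻]+[Cl⁻]+[NO₃⁻]+[F⁻], both supplied directly as charge
equivalents (μeq/L). The solver finds the pH at which

```
H⁺ + BC + 3[Al³⁺] + 2[AlOH²⁺] + [Al(OH)₂⁺]
  = SAA + HCO₃⁻ + OH⁻ + [Al(OH)₄⁻] + ΣOA
```

with three pH-coupled subsystems:

* **Aluminum.** A gibbsite-like Al(OH)₃ solid phase controls the free ion,
  `pAl = S_Al·pH − log K_Al`, with defaults S_Al = 3 and log K_Al = 8.1
  (median of the regional calibration; total spread 2.4, hence the curve
  family {6.9, 8.1, 9.3}). Hydrolysis products follow cumulative constants
  log*β = −5.0 / −10.1 / −22.7 for AlOH²⁺, Al(OH)₂⁺, Al(OH)₄⁻. Fluoride and
  organic Al complexes are not speciated — fluoride counts only as a strong
  acid anion — and total (organic + inorganic) aluminum is out of scope.
  The cationic pool is also reported as mass (×26.98 g/mol, μg/L) because
  50 μg/L is the conventional roach-toxicity limit. Al(OH)₃⁰ carries no
  charge and is omitted; CO₃²⁻ is negligible over the solved range.
* **Carbonate.** Open-system bicarbonate at a fixed CO₂ pressure of 0.156%
  by volume (four times atmospheric — boreal lakes are CO₂-supersaturated),
  with log kH = −1.5 mol/L/atm and pK₁ = 6.3:
  [HCO₃⁻] = K₁·kH·pCO₂/[H⁺].
* **Organic acids.** An Oliver-style triprotic analogue. The total charge
  site pool is `site_density · TOC` with a default of 10 μeq per mg C —
  this product is the full-dissociation charge bound, so the molar triprotic
  acid concentration is one third of it. Default pKs 3.04 / 4.51 / 6.46.
  The organic constants and the hydrolysis/carbonate constants are
  conventional values for this model family, not regionally fitted ones;
  all are overridable through `EquilibriumConstants` or a YAML file.

Activity is equated with concentration: these are dilute waters (ionic
strength well below 1 mmol/L) and no activity model is part of the design.
pKw = 14.0; constants carry no temperature dependence (temperature is
retained as metadata only).

**Numerics.** Every term of the residual is strictly decreasing in pH, so
the root on the bracket [3, 10] is unique and bisection cannot miss it.
The solver iterates until the absolute charge imbalance is ≤ 1e-4 μeq/L
(1e-10 eq/L, roughly 1e-4 pH in poorly buffered water). A composition
whose residual does not change sign on the bracket (e.g. mineral-acid
content beyond pH 3) raises an error naming the lake. Tests verify
agreement within 0.01 pH against an exhaustive 0.001-step grid scan on
hundreds of random compositions, and the strong-acid closed form
pH = −log₁₀(|SAA−BC|·10⁻⁶) when all subsystems are disabled.

**K_Al calibration.** The single free parameter is log K_Al, adjusted
within [6.9, 9.3] so the solved pH matches an observed value (Brent root
find on a monotone response). At circumneutral pH the aluminum terms are
negligible and the solved pH barely responds to K_Al; when the response
across the full bounds is under 0.01 pH the default 8.1 is retained with
an `insensitive` flag rather than pretending to fit. An observed pH outside
the attainable range yields a non-converged report, not an exception —
most lakes keep the default, mirroring regional practice.

## Biological classification

Survey records (interview / questionnaire / gillnet, 1890–2012) are grouped
into three periods: P1 before 1960, P2 1960–1990 (both boundary years
inclusive in P2), P3 after 1990. A lake is

* **acidified** when the fraction of surveys reporting roach is ≥ 0.75 in
  P1 and ≤ 0.25 in P2 (inclusive thresholds, exactly as printed);
* **nonacidified** when that fraction is strictly above 0.90 in both P1
  and P2;
* **excluded** when either P1 or P2 has fewer than two surveys (both
  periods are needed for the before/after contrast; a config switch
  restricts exclusion to lakes sparse in both);
* **indeterminate** otherwise.

The thresholds are probabilistic by design: single gillnet surveys miss
low-density populations, so unanimity is not required. An acidified lake
with any P3 presence record is flagged `recolonized` (low-confidence when
P3 holds a single record). Expert-knowledge reversals of false absences
enter only as an explicit per-lake override field in the input — they are
never inferred.

## Consistency assessment

For each lake the ΔpH criterion is evaluated at the 1980 (peak) and 2010
(recovery) assessments against the 1860 reference: `acidified` means
ΔpH strictly greater than 0.4, and `below_threshold` means pH strictly
under the roach threshold 5.5. Threshold comparisons carry a 1e-9 guard so
that inputs with a few decimals behave exactly at the boundary
(6.0 − 5.6 is not 0.4 in binary floats).

The lake-level chemical verdict used for the contingency is:

> chemically acidified ⇔ ΔpH(1980) > 0.4 AND
> (pH(1980) < 5.5 OR ΔpH(2010) > 0.4)

i.e. a significant peak-era deviation that either crossed the biological
threshold or persisted to the recovery assessment. A transient exceedance
that never approached the species threshold and was gone by 2010 counts as
recovered. This single deterministic rule is the package's own resolution
of a genuine ambiguity: per-year ΔpH counts and the four-category
contingency cannot be derived from one another with any single-year flag,
and this rule reproduces both sets of marginals simultaneously on the
packaged fixture.

Crossing the chemical verdict with the biological status gives the four
categories — i nonacidified by both, ii acidified by both, iii chemically
acidified with roach present, iv chemically nonacidified with roach absent.
Excluded/indeterminate lakes are omitted from the contingency with a
logged reason. The conceptual quadrant locates (pH_ref, pH_assess) against
both thresholds: D within the accepted deviation (taking precedence even
when the reference is below the species threshold), otherwise C when the
reference was already below 5.5, B when the change crossed 5.5, A when it
did not. The headline quadrant of a lake is evaluated at the peak (1980)
assessment — that is where a biological effect would have been exerted —
with per-year quadrants also reported. Percentages (reduction in acidified
lakes, recolonization) are reported rounded to integers; counts retain
full precision.

## The 85-lake fixture

`build_results_fixture()` constructs, deterministically and without
randomness, 85 lakes whose trajectories and survey histories jointly
satisfy every published ensemble marginal (28/14 acidified per year,
14 below 5.5 in 1980 with 11 roach-absent, 7 below in 2010 with 5 absent,
categories 64/14/3/4, 5 of 14 recolonized, 14 of the 28 peak-acidified
with heavy-period presence records). Eight named lakes carry their
published pH values; unpublished values (the 1980 pH of the nonacidified
named lakes, all filler-lake values) are synthetic, evenly spaced within
each category's constraint bounds, and flagged `synthetic=True`. Three
category-ii lakes are significantly acidified without ever crossing
pH 5.5 — this is forced by the published below-threshold counts, and they
are the category-ii lakes that land in quadrant A rather than B. The
builder re-runs the real classifier and assessment on itself and raises an
error naming the first violated marginal, so it cannot drift silently.

## Synthetic ensemble generator

The generator emulates the study conditions rather than any particular
lake set. Per lake: a reference pH drawn uniformly on 4.5–8.2 and TOC on
3–32 mg C/L (the monitoring ranges); anions drawn within dilute boreal
ranges and the base-cation total then solved so the reference-year charge
balance hits the drawn pH — every pH in the package is produced by the
solver, never asserted. Acidification enters as a sulfate pulse (default
80 μeq/L, per-lake exposure scale 0.5–1.5) with a piecewise-linear time
profile: slow growth to 1945, the steep post-war rise to near-peak by
1965, peak plateau through 1970–1980, then linear decline to half the
pulse by 2010 (recovery fraction 0.5). The charge balance is solved at the
profile's anchor years and annual pH is linearly interpolated between them
— a deliberate cost/accuracy trade: the profile is itself piecewise linear
and pH varies smoothly over each segment.

Roach occupancy is threshold-with-lag: extirpation after five consecutive
years below pH 5.5 (recruitment failure kills a population only after the
adults die out). An extirpated lake is restocked with probability 0.36 at
a uniform year after 1990. Surveys (default four per period) fall within
each period's survey-effort era — heavy-period records are drawn from
1972–1990, the gillnet test-fishing era that dominates the historical
databases' heavy-period holdings. An occupied lake is detected with
probability 0.9 per survey; false presences do not occur.

**Classifier evaluation.** `evaluate_classifier_recovery` scores the
classifier against the generator's extinction assignments over the
population the study design can address: lakes truly occupied at the start
of the heavy period. Populations lost before 1960 are counted separately
and not scored — the real analysis required documented presence in P1 and
could never have included them. Sensitivity is the fraction of truly
extirpated lakes called acidified (indeterminate outcomes count as
misses); specificity is the fraction of persistent populations *not*
called acidified. Both exceed 0.9 at the default conditions (seeds and
sizes in the test suite; ~0.93–0.97 sensitivity, ≥0.99 specificity at
n = 1000).

What passing synthetic tests does **not** show: real survey records are
not temporally uniform within eras, detection varies by method and lake,
restocking is not random, deposition had spatial structure, and real
reference chemistry is not uniform in pH. The generator establishes that
the pipeline's logic is correct under known ground truth, not that its
error rates transfer to any real data set.

## Problem sizes and runtime choices

The default test suite solves a few thousand charge balances (200-composition
oracle comparison, 1,000-lake classifier experiment) and runs in well under
a minute for the chemistry and a few tens of seconds for the ensemble work.
The acceptance script runs only the deterministic fixture pipeline.

## Known limitations

* No ionic-strength or temperature correction of equilibrium constants
  (a Davies-correction hook is a natural extension).
* The organic-acid model is a fixed-pK triprotic analogue; site density
  does not vary with DOC quality.
* The generator's pulse affects sulfate only; nitrogen dynamics and
  episodic (snowmelt) acidification are absent, so lags driven by episodes
  are outside the model.
* Total aluminum cannot be estimated from the gibbsite equilibrium; only
  the cationic inorganic pool is modeled.
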