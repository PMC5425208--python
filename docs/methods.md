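# Methods

## Scope and model

`erascreen` implements a screening-level ecological risk assessment in which
risk is the product of *effect* (consequence), elicited from experts, and
*exposure*, derived from spatial data. The risk units are habitats; the risk
sources are human-mediated threats. The design goals are transparency (every
output number is reproducible from the module operations), explicit
uncertainty, and applicability where empirical data are sparse.

### Effect elicitation

Each expert scores every applicable threat–habitat combination on two
indicators — change in physical habitat structure, and change in species
composition and trophic structure — under three scenarios: best case,
most-likely, worst case. Scores are ordinal integers on a configurable scale
(default 0–5, 0 = no effect). The per-response ordering
best ≤ most-likely ≤ worst is a hard invariant enforced at read time;
violating rows are rejected with row numbers rather than repaired, because a
silent swap would flip the sign of the uncertainty statistic.

Per combination, indicator and scenario the package reports the arithmetic
mean, the standard error (sample SD/√n, undefined at n = 1) and n. A missing
score is an abstention (n is reduced), never a zero: zero would assert "no
effect", a substantive claim the respondent did not make.

### Knowledge uncertainty

Uncertainty is the difference between the worst-case and best-case scenario
means of the combined effect. It is a knowledge-based *risk range* — wide
when experts cannot pin the outcome down, zero when all scenarios agree —
and it is carried through the assessment alongside risk, never multiplied
into it. Because the mean is linear, computing the difference on scenario
means equals the mean of per-response differences; the per-response route is
available for diagnostics.

### Spatial exposure

Where presence/absence rasters exist for both layers, percent overlap is
100 × (overlapping cell count × cell area) / (habitat cell count × cell
area); for uniform grids the area term cancels, and the value is invariant
under grid refinement. Grids must share registration (shape, cell size,
origin); no-data cells are treated as absent and logged, keeping the binary
contract. Readers accept ESRI ASCII and single-band GeoTIFF.

Percentages bin to an ordinal 0–5 score: 0 only for exactly zero overlap
(distinct from "< 10%"), then half-open bins [0,10), [10,25), [25,50),
[50,75), [75,100]. The half-open choice resolves boundary ambiguity
deterministically and keeps the map monotone and surjective onto 0–5.
Records for threats assessed from literature or expert opinion (quality 2–3)
carry a hand-assigned score and no percentage; if both are present and
disagree, a warning is emitted rather than trusting either silently.

Each record carries a data-quality category: 1 adequate spatial data,
2 limited data / well-documented whole-of-habitat threat, 3 expert opinion,
4 limited knowledge / no data. Before risk scoring, records are filtered:
quality 4, near-future threats (scored for effect but with no present
footprint to weight by) and zero-overlap records are excluded, each with a
logged reason; the filter partitions its input exactly.

### Risk, rescaling, ranking

Risk per scenario is the combined effect multiplied by spatial_score/5
(default) or overlap%/100 (config). The multiplicative form is the simplest
that is zero at zero coverage, the identity at full coverage, and monotone
in both arguments; the functional form of the exposure weighting was a
genuinely open design point and is therefore a config switch. The indicator
combination (mean by default, max as a precautionary option) is likewise
config.

Effect, uncertainty and risk are each min–max rescaled to [0,1] over one
joint pool per assessment (all combinations and, for scenario-indexed
scores, all three scenarios), because the purpose of rescaling is
comparability across habitats, threats and scenarios. Per-habitat pooling is
available by config. A degenerate pool (all values equal) maps to 0 with a
warning. Since every transform is monotone and the pool is shared, the
scenario ordering propagates to rescaled risk.

Rankings use competition ranking ("1224") on descending most-likely risk;
all entries tied at the k-th value are included, so a top-five table can
hold more than five threats. Ties are ordered for display by threat id only.
Total risk per threat is the sum of rescaled most-likely risks over the
habitats where it was assessed; these totals are exported as word-cloud
weights (weight plus a min–max display size), with rendering left to
external tools.

### Perceived risk

Respondents' unstructured ordered top-five lists are aggregated per habitat
by positional points 5, 4, 3, 2, 1 — a truncated Borda count. Shorter lists
award points from the top (position 1 is always worth 5), anchoring the
maximum to "highest-ranked threat". Threat names outside the structured
registry are retained with a warning: dropping them would hide exactly the
perception signal this channel exists to capture. The aggregate is
permutation-invariant in respondents and conserves total points.

## Synthetic data

The generator stands in for the unobservable expert consensus. Most-likely
scores are Gaussian draws around a true effect with standard deviation
`spread`, rounded half-up to the scale and clamped to its bounds; best and
worst are the most-likely score minus/plus rounded half-normal draws with
scale `range_width`, clamped, so the scenario invariant holds by
construction. Perceived lists rank a noisy perturbation of the per-threat
truth. Grid pairs are built with exact cell counts, so the requested overlap
fraction is recovered up to one-cell rounding.

Defaults emulate the study conditions the package is shaped around: eight
habitats with expert panels of 15/13/12/11/8/8/8/6 (81 surveys in all), 38
threats across nine source categories (304 threat–habitat combinations),
three near-future threats, six threats with quality-4 spatial knowledge and
four with quality 3; climate-change threats get full spatial coverage
(score 5), other exposures are drawn uniformly over scores 1–5 and
qualities 1–2. Where no value was stated by the emulated design, defaults
(`spread` = 0.8, `range_width` = 0.8 scale units) were chosen once as
plausible between-expert dispersion for ordinal elicitation — roughly one
scale step of disagreement — and are not tuned thereafter.

What the model omits, deliberately: expert correlation (shared training or
literature), linguistic uncertainty, survey fatigue and order effects,
habitat-structured effect covariance. Passing recovery tests therefore show
that the arithmetic chain is unbiased and consistent under independent
dispersed experts; they do not show robustness to correlated or
systematically biased panels.

## Numerical choices and degenerate inputs

- Rounding in the generator is half-up (`floor(x + 0.5)`); clamping happens
  after rounding.
- SE at n = 1 is NaN, not 0; recovery statistics skip unanimous panels
  (SE = 0) because a ±3 SE window is undefined there.
- Negative uncertainty is a hard error (it can only arise from an upstream
  invariant breach), as is a zero spatial score reaching the risk weighting.
- An empty habitat raster is an error (undefined denominator), not 0%.
- Exact zero overlap is required for exposure score 0; any positive overlap
  bins to at least 1.
- CSV outputs are written at 3 decimals for reading; `results.json` keeps
  full precision for regression comparison.

## Problem sizes used in tests and the acceptance script

Property suites run on 20×20 grids and panels of ≤ 8 experts. Recovery
statistics use 4–6 threats × 2 indicators per assessment, panels of 6 and 15
(the smallest and largest of the emulated design), spread 1.0, with 500
assessments per condition in the test suite and 200 in the acceptance
script; both complete in seconds and the coverage estimate is stable to
well under a percentage point at these counts.

## Known limitations

- The exposure weighting and indicator combination rules are defensible
  defaults, not identified from data; conclusions sensitive to them should
  be checked under the alternative config switches.
- Min–max rescaling is pool-relative: adding or removing a single extreme
  combination rescales every score in the assessment.
- No modelling of interactions among co-occurring threats, and no
  social-economic risk layer; both are downstream extensions.
- Raster handling assumes co-registered uniform grids; reprojection and
  vector ingestion must happen upstream.
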