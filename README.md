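# erascreen

Screening-level ecological risk assessment for multi-habitat marine regions,
built around expert elicitation. Given (a) score-based expert surveys of the
effect each human-mediated threat would have on each habitat, (b) spatial
exposure derived from presence/absence rasters or assigned from literature,
and (c) respondents' unstructured top-five perceived threats, the package
produces per-habitat risk rankings with an explicit knowledge-uncertainty
bound on every score.

It is aimed at researchers and natural-resource managers who need to
prioritise threats across many threat–habitat combinations when empirical
data are too sparse for a quantitative assessment.

## The model

For each applicable threat *t* and habitat *h*, every expert *e* scores the
effect on two indicators *i* (change in physical habitat structure; change in
species composition and trophic structure) under three scenarios
*s* ∈ {best, most-likely, worst}, on an ordinal scale (default 0–5), with
best ≤ most-likely ≤ worst enforced per response. The pipeline computes

- mean effect per indicator and scenario: E(t,h,i,s) = mean over experts,
  with SE = SD/√n;
- combined effect: E(t,h,s) = ½ [E(t,h,struct,s) + E(t,h,comp,s)]
  (or max, by config);
- knowledge uncertainty (risk range):
  U(t,h) = E(t,h,worst) − E(t,h,best), retained independently — it is never
  folded into the risk score;
- spatial exposure: percent overlap of co-registered binary rasters,
  overlap% = 100 · |cells(t) ∩ cells(h)| / |cells(h)|, binned to an ordinal
  score S ∈ 0–5 (0 only for exactly zero overlap; 1: <10%, 2: 10–25%,
  3: 25–50%, 4: 50–75%, 5: 75–100%);
- risk: R(t,h,s) = E(t,h,s) · S(t,h)/5, computed only for combinations that
  survive the exposure filter (data-quality 4 = no spatial data, near-future
  threats, and zero overlap are excluded, with a logged reason);
- min–max rescaling of effect, uncertainty and risk to [0,1], each pooled
  over the whole assessment so habitats, threats and scenarios compare;
- rankings: top-k threats per habitat by most-likely-scenario risk
  (competition ranking, ties at the cutoff included), and a total risk per
  threat (sum of rescaled scores over habitats) exported as word-cloud
  weights.

Independently, each respondent's ordered top-five perceived threats are
aggregated by positional points 5, 4, 3, 2, 1 (a truncated Borda count),
summed and ranked per habitat, and compared side-by-side with the
score-based ranking to surface perception gaps.

A synthetic-data module generates survey panels and paired rasters from a
known ground truth, so the whole pipeline is testable and its statistical
behaviour at realistic panel sizes is measurable.

## Worked example

Generate a miniature assessment (3 habitats × 6 threats × 8 experts, grids
included) and run it:

```sh
erascreen simulate --out-dir demo --seed 7
erascreen assess --config demo/config.yaml --out-dir demo_out
```

which prints the run log

```
13 files written to demo_out
  responses_read: 24
  respondents: 8
  applicable_combinations: 18
  combinations_with_effect_data: 18
  combinations_in_risk: 18
  exclusions: {}
```

(24 responses = 8 experts × 3 habitat surveys; all 18 threat–habitat pairs
had exposure records with temporal category > 0 and none were excluded).
`demo_out/top_risk.csv` then starts

```
rank,threat_id,habitat_id,scenario,effect_combined,uncertainty,spatial_score,quality,n,risk_raw,risk_rescaled
1,thr5,hab1,most_likely,3.125,1.312,4,2,8,2.500,0.515
2,thr3,hab1,most_likely,2.688,1.125,4,3,8,2.150,0.430
```

read: in habitat `hab1` the top-ranked threat is `thr5` with a combined
most-likely effect of 3.125 (on 0–5, averaged over 8 experts and both
indicators), an uncertainty of 1.31 scale points between the worst- and
best-case means, spatial-exposure score 4 (50–75% coverage), giving a raw
risk of 3.125 × 4/5 = 2.5, which rescales to 0.515 within this assessment.
`total_risk.csv` sums the rescaled most-likely risks over habitats
(`thr2,1.615,3` = threat 2's total over its 3 habitats) and
`wordcloud_weights.csv` carries the same totals with a min–max display size.

The same tables are available programmatically:

```python
from erascreen import AssessmentConfig, run_assessment
config = AssessmentConfig.from_yaml("demo/config.yaml")
res = run_assessment(config, "demo/survey.csv", "demo/exposure.csv",
                     "demo/perceived.csv")
res.risk.total_risk.head()
```

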