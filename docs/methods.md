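# Methods

## The scalogram procedure

`scalorank` ranks administrative regions by a composite of per-capita
health-resource indicators. The procedure assumes that (a) each indicator is
a nonnegative rate per common population denominator, (b) a higher rate
reflects a better-resourced region unless the schema says otherwise, and
(c) the ordinal 1–4 score of a region on an indicator depends only on that
indicator's observed distribution across regions. Composite totals are plain
integer sums — no weighting — so the method is transparent but treats every
indicator as equally important, a deliberate simplification of the classic
technique.

### Input normalization

Tables are UTF-8 comma- or tab-delimited with a leading `region` column; the
schema (YAML) declares each indicator's cluster (institutional,
human_resource, rural_institutional), denominator and orientation. Rates
published against denominators other than 1,000 persons (e.g. specialist
densities per 10,000) are rescaled on read so all arithmetic happens on a
common per-1,000 scale. `normalize_counts` converts raw facility/staff
counts to per-1,000 rates when populations are supplied.

Missing cells are an error by default. The permissive mode imputes the
indicator's observed minimum — reading absence of data as the worst observed
condition — and warns; imputation never invents a value outside the observed
range.

### Scoring

Equal-width binning (default): the observed [min, max] of each indicator is
split into four equal sub-intervals, half-open `[low, high)` with the top
bin closed, scores 1–4 from the low end (reflected to 5 − s for
higher-is-worse indicators). This is deterministic and tie-free except
exactly at bin edges. Empirical-quartile binning (values ≤ Q1 → 1, ≤ median
→ 2, ≤ Q3 → 3, else 4) is offered because "ranking" language in field usage
is ambiguous between the two; reports record which was used.

A constant indicator column cannot discriminate, so every region scores 4
and a warning is raised — a non-informative indicator should not penalize
anyone. Degenerate single-region input is valid (score 4 by the same rule).

### Class intervals (Sturges rule)

The five development tiers (under_development → development) have width

    i = R / (1 + 3.3·log10 N)

with R the score-range amplitude and N the number of items classified.
Two conventions matter and are the package's own choices:

- **Width is rounded to the reporting precision (default 1 decimal) before
  bounds are accumulated.** Published five-tier tables print bounds that are
  exact multiples of the printed width; accumulating the unrounded width and
  rounding each bound afterwards drifts the upper bounds (e.g. a fourth
  bound of 75.06 → 75.1 instead of the printed 75). With rounding first, the
  reference scheme (endpoints 33/89.4, N = 21, width 10.5) yields bounds
  [33, 43.5, 54, 64.5, 75] exactly.
- **The top tier is closed at the range maximum** and therefore absorbs any
  remainder when five widths undershoot R (the reference top tier is ~14.4
  wide versus 10.5 for the rest). Stored bounds are exactly half-open —
  `[low, next_low)`, top closed — so the tiers partition the range with no
  gap or overlap; the paper-style display "(upper−lower)" with upper one
  reporting unit below the next lower bound is rendering only.

Defaults: N = number of regions and R = observed total range, both
overridable to pin a published scheme. Five Sturges widths only fit inside R
when 1 + 3.3·log₁₀ N > 4 (N ≥ 9); for smaller studies `build_class_scheme`
raises and the caller must supply an explicit N. Ties in ranking use
competition ranking (1, 2, 2, 4). Tier percentages are arithmetic
(100·count/n, 2 decimals) and always sum to 100 within rounding.

## Synthetic data generator

The generator emulates a provincial statistical-yearbook matrix whose
per-city cells are not published: ~22 regions × 31 indicators (8
institutional, 20 human-resource, 3 rural-institutional). A single latent
development level drives all indicators multiplicatively:

    rate(r, j) = base_j · exp(d_r + ε_rj),  d_r ~ N(0, σ_d),  ε_rj ~ N(0, σ_ε)

Defaults (chosen once as study-shaped, not tuned): n_regions = 22; the
packaged 31-indicator schema; σ_d = 0.5 (latent spread, log scale);
σ_ε = 0.3 (per-cell noise); base rates are the packaged province-wide
indicator totals (31–64) scaled by 1/100 to plausible densities of 0.31–0.64
per 1,000 residents. Under these defaults composite totals typically span
roughly the mid-30s to high-90s within the theoretical [31, 124] band. The
same seed gives bit-identical output.

What the generator does **not** emulate: cluster-specific development axes
(real provinces can be rural-strong but hospital-poor), spatial
autocorrelation between neighboring regions, population-size-dependent
sampling noise in small-denominator rates, and reporting artifacts. Passing
recovery tests therefore shows the pipeline faithfully recovers a *single
common gradient* under multiplicative noise — not that five tiers are the
right description of any real province.

### Rank recovery and its quirks

`recovery_correlation` is the Monte-Carlo oracle: it reruns
generate → score → aggregate over replicate seeds and returns the Spearman
correlation between planted d_r and composite total per replicate. Under the
default conditions (200 replicates) the mean correlation is ≈ 0.977
(sd ≈ 0.015) and stable across seed sets; the acceptance floor is frozen at
0.90.

Two quantization effects are worth knowing. With σ_ε = 0 every column yields
the *same* four-level score vector, so totals are tied within score bins and
Spearman is well below 1 even though the ordering has no inversions (the
noiseless test asserts inversion-freeness, not perfect correlation). And
mean recovery is not monotone in σ_ε near zero — a little noise breaks those
ties across 31 columns and *raises* Spearman — so monotone degradation is
asserted across well-separated noise levels (0.3 > 0.8 > 1.5 in mean
recovery).

## Outputs

`write_report` emits `ranked.csv` (region, cluster sums, total, tier, rank),
`tier_summary.csv` (members, count, percent, interval in both conventions)
and `run.json` (binning mode, Sturges parameters, class bounds, input
digest, seed) — all deterministic, no timestamps. `write_choropleth` tags a
GeoJSON FeatureCollection with `total_score`, `tier`, `rank` and per-cluster
scores, joining features to regions by name (exact after trim + casefold; no
fuzzy matching, for determinism). Features without a matching region are
kept and tiered `not_assessed`; regions without geometry are dropped from
the file but listed in the collection's properties so nothing disappears
silently. No projection handling: coordinates pass through unchanged.

## Problem sizes

The test suite and acceptance script run the full pipeline on 22 × 31
matrices; recovery checks use 200 replicates per seed set (a few seconds).
These sizes match the study design the generator emulates.

## Known limitations

- Equal scoring weight per indicator; no reliability analysis of the
  composite (e.g. no Guttman reproducibility coefficient).
- Scores depend on the observed min/max, so adding or removing one region
  can shift every region's score on an indicator.
- Only five tiers with Sturges widths; no optimal-breaks alternatives.
- The class-interval width rule uses log₁₀ N of the *item count*, not the
  sample-size-based histogram variant; the two coincide only in form.
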