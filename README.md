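# scalorank

Scalogram-based regional development ranking of per-capita health-resource
indicators.

Health planners often need to know which districts of a province are
under-served before reallocating facilities and staff. A simple, transparent
way to do this is the **scalogram technique**: score every region ordinally
on each of a battery of structural indicators (facilities, beds, specialist
physicians, rural health houses — all as rates per 1,000 residents), sum the
scores into a composite, and cut the composite range into development tiers.
`scalorank` implements that pipeline end to end, from delimited-table input
to a choropleth-ready GeoJSON, for analysts ranking administrative regions
by health-system inputs.

## Method

Given a region × indicator matrix *X* of nonnegative rates per 1,000
population (indicators grouped into institutional, human-resource and
rural-institutional clusters):

1. **Ordinal scoring.** Each indicator column is cut into four classes and
   each region receives a score *s* ∈ {1, …, 4} (4 = best observed
   condition). The default cut is equal-width quarters of the observed
   [min, max] range, half-open with the top bin closed; empirical-quartile
   binning is available as an alternative.
2. **Aggregation.** Scores are summed per cluster and overall:
   *T(r) = Σ_j s(r, j)*, so *n* indicators bound the composite at
   [*n*, 4*n*] (30 indicators give the familiar 30–120 band).
3. **Sturges class intervals.** The composite range *R* is split into five
   development tiers of width *i = R / (1 + 3.3·log₁₀ N)*, where *N* is the
   number of items classified. The width is rounded to the reporting
   precision, tiers rise from the range minimum in steps of *i*, and the top
   tier is closed at the range maximum (absorbing any remainder).
4. **Classification and ranking.** Each region's total selects the unique
   half-open tier interval containing it; regions are ranked by total
   (competition ranking for ties) and tier occupancy is summarized with
   percentages.

A seeded synthetic generator produces study-shaped matrices (22 regions, 31
indicators in three clusters) from a single latent development level per
region, `rate(r, j) = base_j · exp(d_r + ε)`, so ranking recovery of the
planted gradient can be measured directly.

## Worked example

```python
import scalorank as sr

matrix, truth = sr.generate(sr.SyntheticConfig(seed=1))
bundle = sr.run_pipeline(matrix)
print(bundle.ranked.head(5).to_string(index=False))
print(bundle.tiers[["tier", "count", "percent", "interval"]].to_string(index=False))
```

```
region  institutional  human_resource  rural_institutional  total_score             tier  rank
   R05             23              68                    8           99      development     1
   R02             21              64                    7           92      development     2
   R12             23              58                    9           90      development     3
   R16             22              53                   10           85      development     4
   R06             21              52                    8           81 semi_development     5

                tier  count  percent    interval
         development      4    18.18   (99-81.8)
    semi_development      5    22.73 (81.7-69.6)
moderate_development      3    13.64 (69.5-57.4)
    less_development      6    27.27 (57.3-45.2)
   under_development      4    18.18   (45.1-33)
```

Region R05 scores highest: its cluster sums (23 institutional + 68
human-resource + 8 rural) give a composite of 99 out of a theoretical
[31, 124] for 31 indicators. Observed totals span 33–99, the Sturges width
for N = 22 items is 12.2, and the five tiers partition that range; 4 of 22
regions (18.18%) land in the top tier. Intervals are rendered in the
conventional "(upper−lower)" table style, with printed uppers one reporting
unit below the next tier's lower bound.

The same pipeline runs from the shell:

```
scalorank simulate --seed 1 --out-dir sim/
scalorank score --table sim/indicator_table.csv --schema sim/schema.yaml \
    --out-dir out/ --geojson regions.geojson
scalorank reproduce-table2
```

`reproduce-table2` rebuilds the published Fars-province scheme (endpoints 33
and 89.4, N = 21): lower bounds [33, 43.5, 54, 64.5, 75], composite 85 in
the top tier and 36 in the bottom.

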