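# Methods

`roaddust` implements a complete contamination-assessment workflow for
site × metal concentration matrices (mg/kg dry weight) from road dust or
surface soil, of the kind produced by ICP-OES surveys of urban zones. This
note records the models, conventions and numerical choices, and what the
synthetic validation does and does not demonstrate.

## Pollution indices

For a site concentration `C_i`, geochemical background `CB_i` and
pre-industrial reference `C_pj` (all 1e-6 mass fractions; µg/g ≡ mg/kg):

| index | formula | level |
|---|---|---|
| geo-accumulation | `Igeo_i = log2(C_i / (1.5 CB_i))` | site × metal |
| pollution index | `PI_i = C_i / CB_i` | site × metal |
| enrichment factor | `EF_i = (C_i/C_ref) / (CB_i/CB_ref)` | site × metal |
| contamination factor | `CF_j = mean_zone(C_j) / C_pj` | zone × metal |
| pollution load index | `PLI = (∏ PI_j)^(1/n)` | site |
| Nemerow index | `PI_Nem = sqrt((mean(PI)² + max(PI)²)/2)` | site |
| combined index | `CPI = mean(PI)` | site |
| degree of contamination | `CD = Σ CF_j`, `mCD = CD / n` | zone |

The 1.5 in `Igeo` buffers natural lithological variation of the
background. `EF` is the standard double ratio against a crustal normalizer
element — `Mn` and `Fe` are the packaged candidates; the normalizer is an
explicit argument and reports are produced for each requested normalizer.
A naive reading of `EF` as "PI of the sample over PI of the background"
is degenerate (the background's own PI is identically 1), which is why the
double-ratio form is implemented.

Class schemes are the published interval sets; all intervals are
left-closed/right-open with the top class closed below only, so every
finite value receives exactly one label. `CD` uses the CF boundaries
multiplied by the number of assessed metals; `mCD` keeps the raw CF
boundaries — the only convention consistent with zone verdicts such as
mCD 8.70 → "very high" and 4.80 → "high". PLI's "baseline" class is an
exact-equality class and is tested at 1e-9.

Choices where the design was genuinely open:

* **No packaged backgrounds.** Geochemical backgrounds are survey-specific
  (soil-science compilations differ); `Igeo`/`PI`/`EF` therefore require
  them in configuration and fail loudly otherwise. Pre-industrial
  references for Cd, Cr, Cu, Ni, Pb, Zn, Mn (1, 90, 50, 68, 70, 175,
  850 µg/g) are packaged because the Håkanson scheme fixes them.
* **CF needs ≥ 5 sites per zone** (the definition averages at least five
  samples). Already-averaged zone summaries — e.g. published survey
  tables — enter through `cf_from_zone_means`, which skips that check
  since the averaging already happened upstream.
* Metals without a pre-industrial reference (Co, Ba, Fe here) are excluded
  from CF/CD/mCD with a logged warning, never given invented references.
* The without-one-metal sensitivity variant (`sensitivity_without`)
  recomputes any per-site composite on the reduced subset, because a single
  dominant pollutant (typically Cd) can saturate Nemerow-type composites.

## Representative local level (EF_local)

A zone's per-metal index series is condensed to one representative level:
split `[min, max]` into `m` equal-width sub-intervals (left-closed, last
closed so the maximum is binned), count values per sub-interval, and keep
the most populated one; frequency ties go to the sub-interval whose
internal mean is nearest the series mean (gaps within 1e-9 count as equal
and resolve to the leftmost bin, which keeps the choice deterministic
under floating-point jitter). `m` defaults to 3; if a sub-interval is
empty, `m` is decremented until none is (`m = 2` cannot fail when the
series has two distinct values) and the value used is reported as
`m_used`. The reported representative value is the mean of the values in
the chosen sub-interval, with the interval bounds and frequency always
carried alongside; a constant series is an error (no interval structure).
The EF normalizer metal is omitted from EF_local (its EF is identically
1). The same condensation applies unchanged to PI or Igeo matrices.

## Clustering

Site profiles are grouped by k-medoids (PAM): random initialisation
followed by a full swap phase to a local optimum of the summed
point-to-medoid distance, best of `n_restarts = 10` restarts, all driven
by one seeded generator (default seed 20250829) so results are
bit-reproducible. Distances are Euclidean on per-metal z-scores;
standardization prevents Fe/Ni magnitudes from dominating the metric.
Swaps must improve the objective by more than 1e-12, which guarantees
termination. On small instances the restarted heuristic is verified
against exhaustive search over all medoid subsets.

The number of clusters is a majority vote over five internal indices —
silhouette, Dunn, Calinski–Harabasz (maximised), Davies–Bouldin
(minimised) and the gap statistic with the one-standard-error rule
(B = 10 uniform reference draws over the bounding box) — with vote ties
resolved toward the smaller k. This is a deliberately reduced panel that
reproduces the majority-vote mechanism of the ~30-index panels popular in
R without carrying thirty indices.

Cluster quality is reported as connectivity (neighbour-count form, L = 10
nearest neighbours; lower is better), the Dunn index (minimum
between-cluster distance over maximum cluster diameter) and mean
silhouette. Reproducibility is the bootstrap Jaccard: for each of B = 100
nonparametric resamples the resampled sites are re-clustered and each
original cluster is matched to the resample cluster of maximal Jaccard
overlap (computed on the distinct sites present in the resample); the
per-cluster mean is labelled "highly stable" above 0.85 and "stable" from
0.6, matching the verbal scale commonly attached to values like 0.92 and
0.80. Fewer than 20 resamples triggers a warning.

## PCA and zone comparison

PCA is correlation-based (metals are z-scored; mixed scales make
covariance PCA meaningless here): eigendecomposition of the correlation
matrix, components signed so the largest-magnitude loading is positive,
loadings = eigenvector × sqrt(eigenvalue), per-component contributions
`100 · loading²/eigenvalue`, cos2 = squared loading (sums to 1 per metal),
and site scores from the projected z-scores. Component counts are
reported under the Kaiser rule (eigenvalue > 1) and the cumulative
explained-variance rule (default threshold 0.8); the operative choice is
the Kaiser count extended until the threshold is met, falling back to the
variance rule when no eigenvalue exceeds 1. Multi-component contributions
are eigenvalue-weighted averages, with 100/n_metals as the expected-average
reference line.

Zones are compared per indicator (Igeo, PI, EF per normalizer) with the
Kruskal–Wallis rank test — the standard nonparametric one-way ANOVA —
applied to the pooled index values of each zone rather than to raw
concentrations, so values of different metals are rank-comparable. Fully
tied data return H = 0, p = 1 by convention.

## Synthetic surveys

The generator plants a known truth:

    C[s,i] = CB_i · (1 + Σ_k e[s,k] · (m[k,i] − 1)) · ε,
    ε ~ LogNormal(−σ²/2, σ),  σ² = ln(1 + noise_cv²)

with geogenic baseline `CB`, source profiles `m` (multipliers ≥ 1),
gamma-distributed per-site exposures `e` around each zone's mean
(coefficient of variation `exposure_cv`), optional hot-spot sites whose
exposure is multiplied, and mean-one multiplicative lognormal noise, so
expected concentrations equal the deterministic mixture. Multiplicative
lognormal noise keeps concentrations positive and right-skewed, matching
the positive skew and kurtosis such surveys report.

The default `uae_like` scenario emulates a two-city arid-region survey:
a mountainous-coastal zone (15 sites) with an ultramafic/geogenic source
(Ni 30×, Cr 1.8×, Co 2.5×, Fe 1.3×), a port/industrial source (Cd 60×,
Zn 9×, Pb 5×) and one Ni hot-spot site, and an urban-coastal zone
(14 sites) with a traffic/urban source (Cd 50×, Zn 4.5×, plus the milder
Cu/Ba/Co/Pb/Ni/Cr signature of brake and tyre wear). Defaults
`exposure_cv = 0.35` and `noise_cv = 0.3` give total concentration
coefficients of variation near 0.45, inside the 0.3–0.75 the emulated
survey's summary tables print. Backgrounds are a synthetic plausible
geogenic set, clearly labelled as such — they are not published background
values.

`recovery_check` diagnoses (never asserts) whether the pipeline sees the
planted structure: EF ranking of strongly enriched (mixture multiplier
≥ 2) versus untouched metals per zone (metals in between are inconclusive
by construction and skipped, as is the normalizer); adjusted Rand index of
majority-vote-k k-medoids against the planted partition; and the cosine
between the leading eigenvector and the nearest planted contrast (each
source's standardized concentration gradient plus the between-zone mean
contrast).

**What passing synthetic tests do not show.** The generator draws
independent lognormal noise per cell; real surveys have spatially
correlated residuals, censoring at detection limits and analytical drift,
none of which are modelled. The planted two-zone partition is recovered
reliably only where zones are well separated relative to the pooled
spread: under the default calibration (matching realistic per-zone
dispersions, whose concentration ranges overlap between zones) one to
three low-exposure mountain-zone sites are genuinely ambiguous in roughly
half of the random seeds, so perfect partition recovery is not a guarantee
of the method — a limitation the test suite documents rather than hides.
EF ranking and PCA-contrast alignment, by contrast, are stable across
seeds at the default noise level.

## Problem sizes and determinism

Everything random (generator, k-medoids restarts, bootstrap, gap
references) flows from explicit integer seeds; identical seeds give
bit-identical outputs, and the pipeline's `report.json` is byte-stable
across reruns. The validation suite uses survey-scale problems (29 × 10
matrices, ≤ 100 generator seeds, 200 exhaustive k-medoids instances,
500 oracle rows, bootstrap B ≤ 100) — sizes chosen to exercise every code
path at the scale the method targets.
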