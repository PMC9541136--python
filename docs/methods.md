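# Methods

## What the package computes

`robitt` screens species occurrence records for sampling biases relative to
a declared statistical target population, and records the screening in a
structured 17-question risk-of-bias document. The screening statistics are
*heuristics*: without a probability sample for comparison the magnitude of a
bias cannot be measured, only its potential indicated. The tool therefore
computes evidence and enforces document structure (every flagged bias needs
a mitigation answer or a not-relevant justification) but never converts
evidence into a verdict or a score — the bias flag is an explicit boolean
set by the assessor.

## Target population, gridding and binning

A `TargetPopulation` declares a geographic extent (bounding box, WKT/GeoJSON
polygon, treated as planar WGS84 degrees), an inclusive year range, a target
taxon list, and the inference grain: grid-cell edge in degrees and period
width in years.

* **Grid.** Cells are half-open squares `[edge, edge+res)` anchored at a
  configurable origin (default −180, −90), so cell ids depend only on the
  grid, never on the data. A point exactly on a lower edge belongs to the
  cell whose lower edge it equals.
* **Periods.** Bins of `width` years labelled p1, p2, … from `start_year`;
  the final bin is truncated by `end_year` where necessary, so the bins
  always partition the extent (1950–2019 at width 10 gives seven full
  decades; 1950–2020 gives an eighth one-year bin).
* **Population filtering.** A record outside the population is excluded for
  the *first* failing reason in the fixed order geo → time → taxon, making
  the exclusion tally deterministic; `input = retained + Σ excluded` always.

## Cleaning and provenance

Cleaning is an ordered pipeline of named rules (missing coordinates, missing
year, out-of-range coordinates, exact duplicates on taxon+lon+lat+year,
coordinate uncertainty above a threshold in metres). Duplicates are exact by
design — fuzzy matching would be impossible to justify line-by-line in an
assessment answer. The `ProvenanceLog` records the count removed by each
rule in order and satisfies `input = output + Σ removed` by construction.
Malformed input rows are tallied in the parse report, never silently
imputed or dropped: the package's purpose is exposing data decisions.

## Nearest-neighbour index

For `n ≥ 2` records, the observed statistic is the mean distance from each
record to its nearest other record (`d̄`). Duplicate coordinates are allowed
and contribute a distance of 0, since aggregated occurrence data genuinely
contain exact duplicates after rounding. The reference is the mean of the
same statistic over `n_ref_sims = 99` datasets of `n` points drawn uniformly
over the declared extent (rejection sampling inside polygons), and the index
is observed/reference. Simulating the reference instead of using the closed
form handles edge effects and irregular domains implicitly; the closed-form
Clark–Evans ratio `R = 2 d̄ √(n/A)` (no edge correction) is retained as an
independent test oracle on rectangular domains, where the two agree to
within a few percent at n = 1000.

Distances are Euclidean in decimal degrees by default — adequate for
regional-extent screening but increasingly distorted with latitude span;
`metric="haversine"` computes great-circle distances in km (nearest
neighbours found via the unit-sphere chord embedding, which preserves the
nearest-neighbour relation exactly). The reference is still sampled
uniformly in lon/lat under either metric.

**Bootstrap.** The per-period uncertainty band is a percentile interval
(default 199 resamples, level 0.95) over with-replacement resamples of the
records, where each resampled record contributes its nearest-neighbour
distance *measured in the original pattern*, and the reference is held
fixed. Recomputing nearest neighbours inside each resample was rejected: a
with-replacement resample duplicates ~37% of points, each duplicated point
then has distance 0, and every bootstrap replicate is biased low by ~20%,
so the interval would systematically exclude the CSR value even for
perfectly random data. Bootstrapping the distances is a classical bootstrap
of a sample mean and covers the CSR expectation at close to nominal rate
(checked by simulation in the test suite). The interval reflects sampling
noise in the observed pattern, not Monte-Carlo noise in the reference.

Periods with fewer than two records yield an explicit undefined result with
a reason — thin periods must be reported, not skipped. All periods share the
same base seed, so identical point sets in different periods give identical
results (bit-for-bit); the resulting mild correlation between periods'
reference draws is harmless for a screening statistic.

## Coverage heuristics

* **Periods-sampled map**: per cell, the number of distinct periods with at
  least one record; a direct picture of how the spatial footprint of
  recording moved over time.
* **Density surface**: per-cell per-period counts with a log10 display
  column; zero cells are absent rather than −∞; counts sum to the number of
  in-extent records.
* **Coverage overlap / taxon turnover**: Jaccard similarity of sampled cell
  sets (or recorded taxon sets) between two periods, sharing a single
  Jaccard implementation; undefined (None) when both sets are empty.
* **Taxon coverage**: per period, the fraction of the declared target list
  recorded, per-taxon record shares, and Pielou-type evenness H′/ln S
  (undefined below two recorded taxa). Records of off-target taxa are
  tallied, never silently dropped.
* **Environmental coverage**: covariates are summarized per grid cell (one
  vector per cell), matching the grain declaration and avoiding per-record
  climate lookups. Each axis is cut into equal-width bins over the domain's
  range (default 5; quantile edges optional) and a cell's joint bin is the
  tuple of per-axis bins. The reference set is the bins *realized* by the
  domain's cells — unrealizable covariate combinations never count as
  uncovered — and a period's coverage is occupied/realized. Note that
  refining the binning does not mathematically guarantee a lower coverage
  fraction for arbitrary covariate tables (both numerator and denominator
  grow); the tests exercise the property on a structured table where it
  holds, alongside the true monotonicity of coverage under adding records.

## The assessment document

17 questions: 4 research-statement (target population and inferential goal,
provenance, cleaning justification), 1 resolution statement, then
representativeness / temporal-consistency / mitigation triples for the
geographic, environmental and taxonomic domains and an other-biases triple.
Prompts are paraphrases stored as an editable YAML resource with stable ids;
the schema counts are asserted on every construction and parse. Validation
is pure and idempotent: it lists unanswered questions, flags subsections
where a bias is flagged without a mitigation answer or not-relevant
justification, and warns (never errors) when the assessment grain differs
from the declared inference grain — a screen at decadal/100 km grain says
little about yearly/1 km inference.

Iteration produces a deep copy with version+1, a parent link, a recorded
reason and an explicit diff of any redefined target population; prior
versions are untouched. Serialization is deterministic YAML (fixed key
order), so serialize → parse → serialize is byte-identical and the document
diffs cleanly under version control. Rendering (Markdown or minimal HTML)
uses a fixed section order with the version history newest first.

## Bias simulator

The simulator is the validation harness: it generates data whose bias
signature is known by construction.

* **csr** — uniform points; the unbiased baseline (index ≈ 1).
* **clustered** — Thomas-style: parent locations Poisson(`parent_rate` ×
  area, minimum 1) over the domain; the period's records are allocated to
  parents multinomially with equal weights and scattered
  Gaussian(`offspring_sd`) around them, redrawn (not clipped) when they fall
  outside the domain. Realized counts per period are exact
  (`n_per_period` × effort multiplier), which keeps calibration and
  detection-power tests free of count noise; `mean_offspring` sets the
  parent count (`n/mean_offspring`) when `parent_rate` is unset.
* **drifting_window** — records uniform inside a window spanning the full
  latitude range and `window_fraction` of the longitude range, translated
  eastward by `drift` (fraction of the longitude range) per period and
  clamped with a warning at the domain edge. With `window_fraction = drift`
  the windows tile the domain: first and last periods are spatially
  disjoint and no cell is sampled in more than two periods — the canonical
  space–time confounding scenario.

Taxa are assigned independently of location from normalized preference
weights; years are uniform within each record's period. The same scenario
and seed reproduce identical records.

Default study conditions used throughout the tests mirror a decadal
screening problem: 1950–2019 in 10-year bins over regional extents of
~10–70 degrees at 1° grain, a few hundred records per period, 99 CSR
reference simulations and 199 bootstrap resamples. Calibration checks use
50 replicate CSR datasets of n = 500 on the unit square (mean index within
±0.05 of 1) and 20 replicate clustered datasets (median index < 1); these
sizes give Monte-Carlo noise comfortably inside the stated tolerances while
keeping the whole suite under a minute. What the simulator does *not*
emulate: real observer behaviour (road bias, list-length effects),
detectability, abundance processes, or location-linked taxon preferences —
so passing tests demonstrate that the heuristics detect the injected
mechanisms, not that they capture every bias in real GBIF-style data.

## Numerical and design choices

* Seeds: every stochastic routine takes an explicit seed
  (`numpy.random.default_rng`); fixed seed ⇒ bit-identical results,
  including CSV artifacts.
* The index of two coincident points is exactly 0 (zero numerator), and a
  degenerate (zero-area) domain is an error.
* Undefined heuristic values are first-class (None + reason in results,
  empty fields in CSV), never silent omissions.
* CSV artifacts carry a single `#` metadata line (tool version, config
  hash, seed); `read_table` skips it.
* Exit codes: 0 success, 1 configuration error, 2 runtime error (argument
  parsing errors surface through the CLI library's own exit code).

## Known limitations

Planar-degree distances distort with latitude; no CRS transformations, no
marine/terrestrial masking, no taxonomic backbone matching, no ordination of
environmental space, and no bias *mitigation* (thinning, bias covariates) —
mitigation is recorded as free text in the assessment, by design. The
question prompts are paraphrases maintained as package data and may be
revised without code changes.
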