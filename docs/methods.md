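# Methods

This note documents the models, numeric conventions and design choices
behind `soilecotox`, and what the packaged data do and do not allow one to
reproduce.

## Experimental frame

A single fungicide is applied once to sieved sandy loam and incubated at
constant conditions. The design has five dose levels — an untreated control
plus 0.075 (the manufacturer's field rate), 2.25, 11.25 and 22.50 mg active
ingredient per kg soil dry matter — and three sampling days (30, 60, 90).
Responses are culturable microbial counts (organotrophic bacteria,
actinomycetes, fungi; log₁₀ CFU kg⁻¹ DM), five soil enzyme activities
(dehydrogenases, catalase, urease, acid and alkaline phosphatase, each in
its own unit per kg DM h⁻¹), and 10-day colony-emergence profiles.

## Indices

**Colony development (CD).** `CD = 100 · Σ_{d=1..10} p_d / d` with
`p_d = N_d / Σ N`. The index is computed on emergence *proportions*, not raw
counts: with raw counts the weighted sum is unbounded, whereas the
proportion form is bounded in `[100/w, 100]` for a `w`-day window and all
reported values fall in [10, 100]. The window length is a parameter
defaulting to 10 days. An all-zero profile has no defined index and raises
an error rather than returning a number.

**Ecophysiological diversity (EP).** `EP = −Σ p_i log₁₀ p_i`, zero-count
days contributing nothing. The logarithm base is exposed as a parameter and
defaults to 10, the only base for which a 10-day window yields EP ≤ 1 as
reported; EP = 1 then corresponds to perfectly even emergence.

**Resistance (RS) and resilience (RL)** follow Orwin & Wardle:
`RS = 1 − 2|D₀|/(C₀ + |D₀|)` and `RL = 2|D₀|/(|D₀| + |Dₓ|) − 1`, with
`D₀ = C₀ − P₀` the control-minus-treated difference at the sampling day and
`Dₓ` the same at follow-up (here day 90, with day 30 as baseline). Each
sampling day serves as its own RS baseline. Degenerate RL inputs are
handled explicitly: with `D₀ = Dₓ = 0` (no disturbance at either time) the
formula's value −1 would be absurd, so a flagged-missing result (NaN with a
note) is returned and summaries exclude it; with `D₀ = 0, Dₓ ≠ 0` a
disturbance emerged only at follow-up and the limit −1 is returned with a
warning.

## PEC dissipation model

The published concentration grid is consistent with dose-proportional,
shared first-order decay, `PEC(d, t) = f · d · e^(−kt)`: within each time
column the value/dose ratio is constant, and every row decays by the same
~0.782 factor per 30 days. The fit is ordinary least squares of
`ln(PEC/d) = ln f − k·t` pooled over all positive doses, so `f` and `k` are
shared; `DT50 = ln 2 / k`. On the packaged grid this gives
`k = 0.00834 day⁻¹` and `DT50 = 83.2 days`. The fit is unweighted; note
that the lowest-dose row is printed to only 4 decimals (cells of order
0.003 carry up to ~2–3 % quantization), which pulls the pooled estimate
slightly away from the value implied by the well-resolved rows
(`k ≈ 0.0082`, `DT50 ≈ 84.5`). Consistency checks against the printed grid
therefore use a 0.5 % relative tolerance plus one unit in the last printed
place of each cell involved; without that allowance the printed grid itself
would fail its own dose-linearity (the 0.0029 cell deviates 2.9 % from the
column ratio purely through rounding).

## Statistics

**Dose correlations** are Pearson coefficients on the raw dose scale (no
log transform), with a two-sided t test at α = 0.01 supplying the
significance flag; exact p-values are always carried alongside. For
measurement tables the control dose participates (n = 5); for RS/RL tables
the indices are undefined at dose 0, so correlations span the four treated
doses (n = 4). Both published anchor values reproduce exactly at three
decimals under these conventions (−0.993 urease day 90; −0.996
dehydrogenase RL).

**η² partitions.** For a means grid (one value per dose × time cell) the
classical two-way decomposition without replication is used: SS_dose (rows),
SS_time (columns), SS_interaction (residual of the additive fit); each η²
is the share of SS_total. For replicated input a two-way ANOVA with
interaction (statsmodels OLS) adds an error stratum. A partition from a
published means grid approximates the replicate-level one — it has no error
term — which is documented rather than hidden; the alkaline phosphatase
dose share (0.6 %) is insensitive to the distinction, the time share is not
(99.1 % from the grid vs 99.0 % published).

**Tukey letters.** Pairwise p-values come from `scipy.stats.tukey_hsd`;
homogeneous groups are rendered with the insert-and-absorb compact
letter display (start from one column holding all groups; for each
significant pair split every column containing both and absorb subset
columns), assigned in group order. The construction is verified against
the defining property — two groups share a letter iff their comparison is
non-significant — on exhaustive pairwise oracles.

**Ward clustering** standardizes each feature (z-score, sample s.d.),
then applies the classic minimum-variance linkage on Euclidean distances
(scipy); other linkage dialects are selectable. Constant features are
dropped with a warning before standardization. Merge heights are
non-decreasing and the tree is invariant to input order.

**PCA.** Explained variance is computed on standardized variables
(correlation-matrix PCA, the convention for mixed- or bounded-scale
variables), with a covariance option. Percentages are non-increasing and
sum to 100.

## Numeric conventions

Printed-table summaries are recomputed with *decimal* arithmetic on the
stored cell strings: binary floats misround exact halves (1.182/4 = 0.2955
would round to 0.295 in floating point while the exact decimal mean rounds
to 0.296). The package's rounding convention is round-half-even, with the
truncated rendering reported whenever the two differ at the printed
precision; the published tables themselves round exact halves
inconsistently (0.9105 → 0.911 but 0.8475 → 0.847), so a printed summary
cell is accepted as a valid rendering when it lies within half a unit of
the last printed place of the exact mean.

## Synthetic data generator

The generator emulates the study's design and effect structure, not its
exact numbers:

- **Enzyme activities**: `A = A₀(t) · (1 − Imax·d/(d + K50)) · exp(ε)`,
  `ε ~ N(0, σ²)`. The saturating (Michaelis–Menten-type) inhibition form
  mirrors the sub-proportional decline of activities at high doses seen in
  the real means; noise is multiplicative because activities are positive
  and replicate dispersions are unpublished. Defaults: baselines equal to
  the real control activities per day, `Imax = 0.3`, `K50 = 5 mg kg⁻¹`,
  `σ = 0.05` (log scale) — chosen to give a means-table spread comparable
  to the real inter-dose spread; replicate-level σ is a convention, not an
  estimate. Nine replicates per cell.
- **Counts**: `y = μ(t) + β·log₁₀(1 + d/d_ref) + N(0, σ_c²)` with
  `β = −0.3`, matching the ~0.4-log suppression scale at the top dose;
  three replicates per cell.
- **Emergence**: multinomial draws over a 10-day window from
  `w(d)·fast + (1 − w(d))·slow`, with the fast-grower weight declining in
  dose as `w(d) = w₀·K_w/(K_w + d)` (`w₀ = 0.7`, `K_w = 5`), the fast
  distribution concentrated on days 1–3 and the slow one uniform. Expected
  CD strictly decreases as weight shifts to slow growers.

All generators are pure functions of (config, seed). What passing synthetic
tests show: the estimators recover known ground truth (noiseless recovery
is exact to ≤ 1e-6; `|Îmax − Imax| ≤ 0.05` at σ = 0.05 with 9 replicates)
and the pipeline detects strong inhibition as significant negative dose
correlations. What they do not show: robustness to real-data features the
generator omits — heteroscedastic or correlated replicate errors,
non-monotone dose responses (hormesis), temporal autocorrelation, plate
count saturation.

## Problem sizes

Every packaged computation is desk-scale: the largest inputs are the 75-cell
activity table and 675-row synthetic experiments; the property suites use
10⁴ random emergence profiles and bootstrap sizes of a few dozen. The full
test suite runs in well under a minute on one core.

## Known limitations

- The published RS cells cannot be derived from the published activity
  means (the authors evidently applied RS per replicate and averaged:
  day-30 dehydrogenases gives 0.919 from the means vs 0.878 printed), so
  the RS table is treated as primary input for downstream summaries, never
  recomputed from activities.
- The published correlation rows carry third-decimal wobble (≤ 0.005)
  relative to recomputation from the printed means — consistent with the
  source having used the mislabelled dose value 11.50 and/or replicate
  data; one cell (urease day 30 RS, printed −0.933 vs −0.892 recomputed)
  is irreproducible under any dose vector and is flagged as-printed.
- The published PCA cumulative variance for the first two components of
  the 12 × 5 RS matrix (93.78 %) is not reproducible from the printed
  matrix under either correlation (80.42 %) or covariance (90.54 %) PCA,
  nor under transposed, subset or rank-based dialects; it presumably
  derives from the same unpublished replicate-level RS values. The
  correlation dialect remains the default and the discrepancy is reported,
  not patched.
- Tukey letters and the CD/EP bar values shown only graphically in the
  source are out of scope: they require unpublished replicate-level data.
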