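# soilecotox

Soil-ecotoxicological assessment of fungicide contamination as a tested,
reusable Python pipeline. The package targets soil microbiologists and
ecotoxicologists who evaluate how a pesticide dose series affects culturable
microbial communities and soil enzyme activities in laboratory incubation
experiments — specifically the azoxystrobin (strobilurin fungicide) design:
sandy loam treated at 0.075 (field rate), 2.25, 11.25 and 22.50 mg a.i. kg⁻¹
soil DM plus an untreated control, sampled after 30, 60 and 90 days.

## What it computes

**Biodiversity indices** from 10-day colony-emergence profiles
(N₁…N₁₀ new colonies per observation day, pᵢ = Nᵢ/ΣNⱼ):

- colony development `CD = 100 · Σ pᵢ / i` ∈ [10, 100] — high values mean
  fast-appearing r-strategists dominate;
- ecophysiological diversity `EP = −Σ pᵢ · log₁₀ pᵢ` ∈ [0, 1] — evenness of
  emergence, low values signal loss of functional diversity.

**Orwin–Wardle stability indices** from paired control/treated series
(D₀ = C₀ − P₀ at the sampling day, Dₓ at follow-up):

- resistance `RS = 1 − 2|D₀| / (C₀ + |D₀|)` ∈ (−1, 1];
- resilience `RL = 2|D₀| / (|D₀| + |Dₓ|) − 1` ∈ [−1, 1].

**PEC dissipation model** — predicted environmental concentration with
shared first-order decay, proportional to dose:
`PEC(d, t) = f · d · e^(−kt)`, half-life `DT50 = ln 2 / k`.

**Dose–response statistics** — Pearson dose correlations (raw dose scale,
two-sided t test at p = 0.01), two-way η² variance partitioning
(dose × incubation time), Tukey-range homogeneous groups rendered as a
compact letter display, Ward minimum-variance clustering of standardized
response profiles, and correlation-matrix PCA explained variance.

Transcriptions of the published summary tables (PEC grid, microbial counts,
enzyme activities, RS, RL, soil characterisation) ship as checksum-locked
CSV fixtures, and a seeded synthetic-experiment generator provides
replicate-level data with known ground truth (saturating dose inhibition
with log-normal noise, log-linear count suppression, fast/slow-grower
emergence mixtures) for end-to-end validation.

## Worked example

```python
import soilecotox as st

# fungicide dissipation: fit the shared first-order decay to the PEC grid
fit = st.fit_pec(st.load_fixture("pec").table)
print(f"k = {fit.k:.5f} 1/day, DT50 = {fit.dt50:.1f} days")

# enzyme resistance ranking over the published RS table
rs = st.load_fixture("resistance").table
summary = st.summarize_index(rs, by="variable")
for rank, enzyme in enumerate(summary.ranking, start=1):
    print(f"{rank}. {enzyme:22s} mean RS = {summary.group_means[enzyme]:.3f}")

# variance partition and dose correlation for single enzymes
sub = st.load_fixture("enzyme_activity").table.query("variable == 'alkaline_phosphatase'")
print({k: round(v, 1) for k, v in st.eta_squared(sub).eta_squared_percent.items()})
col = st.load_fixture("enzyme_activity").table.query("variable == 'urease' and time == 90")
r = st.dose_correlation(col["dose"], col["value"])
print(f"urease day 90: r = {r.r:.3f} (n = {r.n}, p = {r.p_value:.1e})")
```

prints

```
k = 0.00834 1/day, DT50 = 83.2 days
1. dehydrogenases         mean RS = 0.874
2. alkaline_phosphatase   mean RS = 0.810
3. acid_phosphatase       mean RS = 0.746
4. catalase               mean RS = 0.718
5. urease                 mean RS = 0.646
{'dose': 0.6, 'time': 99.1, 'interaction': 0.3}
urease day 90: r = -0.993 (n = 5, p = 7.0e-04)
```

The fungicide half-life of ~83 days marks it as moderately persistent;
dehydrogenases resist the disturbance best and urease worst; the alkaline
phosphatase partition shows incubation time (99.1 %) dwarfing dose (0.6 %);
and urease activity on day 90 declines almost perfectly linearly with dose.

## Command line

```sh
soilecotox indices --fixture resistance --out out/          # RS summaries
soilecotox reproduce 6 --out out/                           # computed vs printed
soilecotox simulate --seed 7 --out sim/                     # synthetic experiment
soilecotox stats enzyme_activity --out stats/               # correlations, η², Ward, PCA
```

`reproduce` recomputes every derivable summary cell (mean rows, correlation
rows, grand-mean rankings, PEC dose-proportionality and shared-decay
checks) from the table bodies and reports computed vs printed at the
printed precision; exit code 2 flags deviations beyond the declared
tolerances, and known replicate-derived cells are listed "as_printed".

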