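# Methods

## The measurement being modelled

A droplet-microfluidic secretion assay encapsulates immune cells at limiting
dilution (0.2–0.4 cells/droplet, Poisson) in 65-pL water-in-oil droplets
together with antibody-functionalized magnetic nanoparticles and fluorescent
detection antibodies. Secreted cytokine is captured on the magnetically
aligned nanoparticle aggregate, relocating detection-antibody fluorescence
onto it. Each droplet is imaged every 30 min over 4 hr (9 frames including
the encapsulation frame t₀) on three fluorescence channels, one per panel
cytokine, plus a cell-stain channel. The data unit is therefore a per-droplet,
per-channel relocation time series R(t) in arbitrary units, with a boolean
cell-stain flag.

dropcyte implements the downstream analysis of those time series. Image
segmentation and beadline extraction are upstream of this package and out of
scope; the input contract is the long-format trace CSV defined in
`dropcyte.io`.

## Secreting-cell calling

A droplet is called a secreting cell for cytokine *c* when all four hold:

1. positive cell stain (`c_cell`);
2. some frame after t₀ exceeds R(t₀) + m·σ_BLK (`c_exceed`);
3. max R − min R > m·σ_BLK (`c_range`);
4. the OLS slope of R against time is strictly > 0 (`c_slope`);

with m = 1.645 · 2 = 3.29 by default (a one-sided 95% normal bound on a
difference of two frames, doubled). All comparisons are strict. Design
choices where the procedure is underdetermined:

* **Baseline.** R(t₀) is the droplet's *own* first-frame relocation, not a
  population mean: droplet-to-droplet baselines vary (nanoparticle content,
  focus), and the exceed criterion references the change from encapsulation.
* **σ_BLK estimator.** Sample sd of the t₀-referenced deltas R(t) − R(t₀),
  t > 0, pooled over all cell-free droplets of the same measurement and
  channel. This matches the functional form of the criterion it feeds: both
  are differences of two frames, so i.i.d. frame noise of sd σ gives
  σ_BLK ≈ σ√2 and the threshold is calibrated on that scale. The estimator
  requires at least one blank droplet and warns below a configurable floor
  (30 by default).
* **Slope.** Plain OLS over all frames; only the sign matters, so the
  implementation uses the covariance Σ(t − t̄)·R, which is exactly zero for
  exactly symmetric series.
* **Multi-cell droplets** are called as single cells: the assay cannot
  distinguish occupancy. The simulator records true occupancy so tests can
  quantify the consequence.

QC: a cytokine with fewer than 50 positives per measurement is flagged for
manual inspection; fewer than 10 flags exclusion. The flags never mutate the
calls — inspection is a human step — and the reporting layer independently
suppresses any population with fewer than 10 secreting cells.

## Quantification

Calibration curves map baseline-subtracted relocation to concentration (nM).
Two forms are supported: linear (gain in nM per a.u.) and a baseline-
subtracted four-parameter-logistic/Hill response, inverted analytically.
Curves must be strictly increasing and carry a finite maximum detectable
concentration C_max. Concentrations are clamped to [0, C_max]: relocation
noise must not create negative concentrations, and the first frame reaching
C_max marks the censoring point, after which the trace is held at C_max.

Frame-to-frame increments convert to molecules/second:

    rate_i = ΔC_i [nM] · 10⁻⁹ · V [pL] · 10⁻¹² · N_A / Δt [s]

(1 nM over 30 min in 65 pL ≈ 21.75 molecules/s). The per-cell average rate
is the mean of interval rates up to the censoring frame (all intervals when
uncensored, so it telescopes to the endpoint-based rate). Negative interval
rates from noise are retained in the per-interval record — unbiased
averaging — but the final average is floored at 0, the physical constraint.
A trace saturating before frame 2 has no usable interval and its rate is
marked unavailable.

The bundled default calibration used by the simulator and the tests is a toy
linear curve (0.05 nM/a.u., C_max 500 nM) per cytokine; real-data analyses
must supply their own per-cytokine curves in the run config.

## Polyfunctionality binning

Each secreting cell contributes to exactly one combination bin — the full set
of cytokines it is positive for — so bins are mutually exclusive, their
counts sum to the CSC total, and CSC-normalized percentages sum to 100%.
%Bin divides by all assayed *cell-containing* droplets of the measurement
(the natural reading of "all measured cells"; configurable via the
`n_total_cells` argument). Multiplicity rollups (mono/bi/tri and "two or
more" = bi + tri) derive from bin-set size. Aggregation across measurements
reports mean ± SEM (sd with n−1 over √n) and enforces identical measurement
keys across conditions so paired tests stay paired. Condition comparisons
report deltas in percentage points and fold changes guarded against zero
denominators.

## Co-secretion dynamics

The assay samples every 30 min, so onset/offset times snap to frame
boundaries; sub-frame timing is unknowable. An interval is *active* when its
concentration increment exceeds k·σ_C, where σ_C is σ_BLK propagated through
the local slope of the calibration curve and k = 1.645·√2 by default. Since
σ_BLK is itself delta-based (≈ σ√2 for frame noise σ), the default threshold
sits at ≈ 2.33 sd of a frame-to-frame difference — about a 1% false
activation rate per interval, a deliberate compromise between window
inflation and missed low-rate intervals. The active window spans the first
to the last active interval.

A cytokine pair in one cell is classified from its two windows:

* **sequential** — zero intersection (touching windows count: the shared
  boundary has zero measure at this sampling rate);
* **simultaneous** — intersection ≥ ρ · (shorter window), ρ = 0.75 default;
* **semi_sequential** — anything between;
* **indeterminate** — either window undetectable.

The original classification of these patterns was by manual inspection;
no quantitative boundary between "simultaneous" and "overlapping" exists to
inherit, so k and ρ are explicit, configurable parameters with the defaults
above. Classification is symmetric in the pair, and triple-positive cells
are classified pair-wise (three pairs) — no three-way label is defined.
Population summaries report the per-frame mean concentration trajectory,
fractions of cells above 100 and 1000 molecules/s, and suppress populations
with fewer than 10 cells.

## Statistics

Paired two-sided t-tests (measurement-paired condition comparisons) and
two-sample two-sided Kolmogorov–Smirnov tests (secretion-rate distributions;
exact p when both n ≤ 100, asymptotic otherwise) via scipy, behind a thin
result type carrying n, stars, and a correction flag. No multiple-testing
correction is applied anywhere, matching the analysis this package
reimplements; the flag makes that explicit in every output. Star mapping:
p < 0.0001 → \*\*\*\*, < 0.001 → \*\*\*, < 0.01 → \*\*, < 0.05 → \*, else ns
(boundaries resolve downward: p = 0.05 is ns, p = 0.01 is \*). Zero-variance
paired differences raise a degenerate-test error rather than returning a
meaningless p.

## The simulator

`simulate_measurement` draws, per droplet: cell count ~ Poisson(loading,
default 0.3); per cell and cytokine, secretion with probability
`secretor_fraction` and a lognormal rate (default median 30 molecules/s,
log-sd 1.5, so the support spans ~1–1000 molecules/s); an activity window.
Mono-secretors draw a uniform frame-aligned onset over the first half of the
measurement (configurable; `window_mode="full"` gives constant full-run
secretion). Co-secreting cells draw a pattern from
(simultaneous, sequential, semi-sequential) fractions, default (0.4, 0.4,
0.2): identical windows, disjoint windows separated by one frame, or windows
overlapping by one frame (well under 75% of the shorter window). For cells
secreting all three cytokines the pattern applies to one random pair; the
third cytokine gets an independent window.

Accumulated concentration is C(t) = Σ_cells rate · active-seconds(0,t) /
(V·N_A), capped at C_max; emitted relocation is the droplet baseline
(default 100 ± 10 a.u.) plus the inverse calibration of C(t) plus Gaussian
frame noise (sd `sigma_blk`, default 5 a.u.). Cell-free droplets emit
baseline plus noise. Each droplet consumes an independent RNG substream
spawned from the root seed, so identical configs are bit-identical and
droplet order never changes results.

**What the simulator does not model** — and hence what passing tests do not
establish about real data: immunoassay binding kinetics and detection lag,
cytokine degradation or uptake, droplet-size variation, focus drift and
fluorescent aggregates, correlated (non-Gaussian) imaging noise, and any
biological correlation between cytokines' rates beyond the co-secretion
windows. Tests demonstrate that the analysis recovers what the generative
model puts in, at the stated noise levels — not that the generative model is
the truth of any particular experiment.

## Numerical choices and problem sizes

* Strict inequalities at every calling boundary; exact-zero covariance for
  symmetric slope cases.
* Censoring index is the first frame whose *pre-clamp* concentration reaches
  C_max; rates use intervals strictly before it.
* The 4PL inverse guards the asymptote (C_max must stay invertible) and
  clamps negative relocation excess to zero before inversion.
* Test and acceptance runs use 400–12,000 droplets per scenario — enough for
  the binomial/multinomial intervals they assert while keeping the whole
  suite around ten seconds — with fixed seeds throughout.
* JSON/CSV writers sort keys and rows so identical inputs are byte-identical.

## Known limitations

* The manual-inspection step of the original protocol is flagged, not
  emulated; calls are never mutated by QC.
* Calibration parameters for real cytokine panels are not bundled; the
  defaults are toy curves for simulation and testing.
* Occupancy is unidentifiable from a trace: multi-cell droplets inflate
  apparent single-cell rates (sum over cells). The ground-truth output makes
  this measurable on simulated data.
* Pattern classification at 30-min sampling cannot resolve sub-frame timing;
  one-frame window inflation from noise occasionally reclassifies sequential
  pairs as semi-sequential (the dominant error mode at the default k).
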