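# dropcyte

Analysis pipeline for **dynamic single-cell cytokine-secretion assays** in
droplet microfluidics, plus a forward simulator that generates such assays
with known ground truth.

In these assays, single immune cells (e.g. PBMCs) are encapsulated together
with antibody-functionalized magnetic nanoparticles in ~65-pL water-in-oil
droplets. Under a magnetic field the nanoparticles form an elongated
aggregate ("beadline"); secreted cytokine is captured on the beadline and
detected by fluorescent antibodies, so fluorescence *relocation* onto the
beadline grows as the cell secretes. Imaging every 30 min over 4 hr on three
multiplexed channels per panel (IL-6/TNF-α/IFN-γ, IL-2/IL-8/MIP-1α, or
IL-6/TNF-α/IL-1β) yields a relocation time series per droplet and channel.
dropcyte turns those time series into:

* **secreting-cell calls** — a droplet is a cytokine-secreting cell (CSC) for
  cytokine *c* when all four criteria hold: (1) positive cell stain;
  (2) ∃ t > t₀ with R(t) > R(t₀) + 1.645·2·σ_BLK; (3) max R − min R >
  1.645·2·σ_BLK; (4) OLS slope of R against t strictly > 0 — with σ_BLK
  estimated from cell-free droplets of the same measurement;
* **concentrations and secretion rates** — relocation is mapped to in-droplet
  concentration (nM) through a monotone calibration curve with a maximum
  detectable concentration C_max; frame-to-frame increments ΔC convert to
  molecules/second as ΔC·V·N_A/Δt (V = 65 pL) and are averaged, censoring at
  the first frame that reaches C_max;
* **polyfunctionality bins** — each CSC falls into exactly one
  cytokine-combination bin; %Bin = Σ n_cells-in-bin / Σ n_cells-per-measurement,
  reported both of all assayed cells and normalized to all CSCs, with
  mono/bi/tri multiplicity rollups and condition comparisons;
* **co-secretion dynamics** — per-cytokine active windows (intervals whose
  concentration increment clears a noise threshold) classified pair-wise as
  simultaneous, sequential, or semi-sequential;
* **statistics** — paired two-sided t-tests, two-sample Kolmogorov–Smirnov
  tests on secretion-rate distributions, mean ± SEM, and the star convention
  (\* 0.05–0.01, \*\* 0.01–0.001, \*\*\* 0.001–0.0001, \*\*\*\* < 0.0001).

The simulator (`dropcyte.simulate`) emulates Poisson cell loading
(0.2–0.4 cells/droplet), lognormal secretion rates, blank-droplet noise, and
configurable simultaneous/sequential/semi-sequential co-secretion programs,
so every stage is testable against ground truth without raw microscopy data.

## Worked example

```python
import numpy as np
import dropcyte as dc

config = dc.SimConfig(n_droplets=5000, seed=7)
meta = dc.MeasurementMeta(stimulant="LPS", stim_duration_hr=1, panel_id="panel1")
traces, truth = dc.simulate_measurement(config, meta)

panel = dc.BUILTIN_PANELS["panel1"]
constants = dc.AssayConstants()
grid = dc.make_time_grid(30, 240)

blanks = dc.estimate_blanks(traces, panel)
calls = dc.call_secretors(traces, blanks, panel, constants, grid)
n_cells = sum(t.has_cell for t in traces)
summary = dc.bin_cells(calls, panel, n_cells)

print(f"cell-containing droplets: {n_cells} of {len(traces)}")
print(f"cytokine-secreting cells (CSCs): {summary.n_csc}")
print(f"mono-secretors: {summary.multiplicity_pct(1):.2f}% of cells, "
      f"{summary.multiplicity_pct(1, normalized=True):.2f}% of CSCs")
print(f"polyfunctional (2+ cytokines): {summary.two_or_more_pct():.2f}% of cells")

_, rates = dc.quantify_secretors(traces, calls, panel,
                                 dc.default_calibration(panel), constants, grid)
avg = np.array([r.avg_rate for r in rates if r.available])
print(f"median secretion rate: {np.median(avg):.1f} molecules/s "
      f"({(avg > 100).mean() * 100:.1f}% above 100 molecules/s)")
```

prints

```
cell-containing droplets: 1261 of 5000
cytokine-secreting cells (CSCs): 290
mono-secretors: 20.70% of cells, 90.00% of CSCs
polyfunctional (2+ cytokines): 2.30% of cells
median secretion rate: 19.6 molecules/s (9.1% above 100 molecules/s)
```

About a quarter of droplets contain a cell (Poisson at 0.3 cells/droplet);
of those, 290 pass the four calling criteria for at least one cytokine.
Most CSCs secrete a single cytokine; 2.3% of all cells are polyfunctional.
The median per-cell rate reflects the simulator's lognormal rate
distribution after the calling threshold removes the weakest secretors.

A command-line interface covers the same stages
(`dropcyte simulate | call | quantify | bin | dynamics | stats | run-all`);
`examples/demo.yaml` is a complete run configuration:

```bash
dropcyte run-all --config examples/demo.yaml --seed 7 --out out/
```

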