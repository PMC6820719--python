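# porelab

Analysis toolkit for engineered biological nanopores — pore geometry from
simulation trajectories, per-species ionic currents under applied bias, and
single-channel blockade-event kinetics, with a synthetic-data module that
provides ground truth for every stage.

## Who it is for

Groups that engineer protein nanopores (e.g. aerolysin-family β-barrel
sensors) combine two data streams: biased molecular-dynamics trajectories of
the pore in electrolyte, and single-channel current recordings of analyte
translocation. `porelab` implements the downstream analysis chain shared by
both streams as a tested, reusable Python library:

* **Pore geometry** — pore axis from the protein centre of mass; local radius
  per 1 Å slice by iterative 0.5 Å ring growth on the water/non-water
  occupancy ratio (threshold 25%); diameters at named sensing regions
  (R282/R220 in the cap, K238/K242 in the stem) over a 3 Å window;
  per-residue RMSF after Kabsch superposition.
* **Ion transport** — charge-displacement current
  `I = (e/Δt·L_z)·Σᵢ qᵢ·Δzᵢ` per species (I_K, I_Cl) with block-averaged
  uncertainty; z-resolved ion densities inside the pore cavity at 1 Å
  resolution; Gaussian fits of open-current histograms; anion selectivity
  |I_Cl|/(|I_Cl|+|I_K|).
* **Event analysis** — threshold-crossing blockade detection against a
  histogram-fitted baseline (I₀ − k·σ); exponential dwell-time constants τ
  (censoring-corrected MLE and falling-exponential histogram fits with
  bootstrap CIs); capture frequency f = 1/τ_on from inter-event intervals;
  blockade ratios I_res/I₀; and a translocation-vs-bumping classifier based
  on the exponential voltage dependence of τ.
* **Comparative reporting** — percent/fold changes between pores, per-base
  translocation times, diameter–dwell correlations (Pearson/Spearman), all
  emitted as provenance-carrying CSV tables.
* **Synthetic data** — channel phantoms with prescribed radius profiles,
  drift–diffusion ion trajectories with closed-form currents, and two-state
  current traces with Poisson arrivals and exponential dwells, each returning
  its ground truth.

## Worked example

```python
import porelab as pl

spec = pl.TraceSpec(open_current_pa=61.5, noise_sd_pa=1.2,
                    event_rate_hz=20.0, dwell_mean_s=2e-3,
                    blockade_depth=0.5, duration_s=20.0,
                    sampling_rate_hz=100000.0, seed=5)
trace, truth = pl.gen_current_trace(spec)
events = pl.detect_events(trace, k_sigma=5.0)
fit = pl.fit_dwell_exponential(events, seed=1)
cap = pl.capture_rate(events)
print(events.n_events, round(1e3 * fit.tau_s, 2), round(cap.f_hz, 1))
```

prints `406 2.06 21.3`: 406 blockades detected against the 61.5 pA baseline,
a dwell constant of 2.06 ms (the generator used 2.00 ms), and a capture
frequency of 21.3 s⁻¹ (arrivals were Poisson at 20 s⁻¹). The `examples/`
directory has one short narrative script per capability (radius profiles,
per-species currents, event kinetics, the translocation classifier, and the
comparison tables), each printing the numbers it computes and what they mean.

A thin CLI wraps the same functions for shell pipelines:

```bash
porelab simulate-trace --spec spec.toml --seed 5 -o trace.tsv
porelab events trace.tsv --k-sigma 5 -o events.csv
porelab pore-profile traj.tsv -o profile.csv
porelab report -o out/
```

All file formats are plain text: PDB or a pseudo-atom CSV for structures, a
`#`-headed TSV dialect for trajectories, two-column TSV for current traces,
CSV with provenance headers for results.

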