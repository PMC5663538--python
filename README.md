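# adchrom — cell adhesion chromatography

`adchrom` quantifies how persistently circulating cells engage a
selectin-coated surface under flow. It is written for groups using
parallel-plate or microfluidic flow chambers to compare rolling adhesion
between cell subtypes (e.g. metastatic carcinoma vs. leukocytic lines),
selectin types and concentrations, wall shear stresses, and adhesion
antagonists such as heparin.

The experimental idea is chromatographic: a pulse of cells is injected
upstream of a selectin-functionalized channel, and each cell's arrival time
at a microscope field of view (FOV) at the channel end encodes how much of
its transit it spent adhesively bound. The package provides all four stages
needed to run and validate that analysis without experimental data:

1. **Simulation** (`adchrom.synthetic`) — each cell is a continuous-time
   two-state Markov chain alternating between a *bound* (rolling) state at a
   per-cell rolling speed and a *free-flow* state at the shear-dependent
   velocity, advanced until it reaches the FOV. Transits are rendered as
   noisy 8-bit TIFF stacks with ground-truth track tables.
2. **Tracking** (`adchrom.tracker`) — running-average background
   subtraction (weight 0.0005 ≈ 80 s moving average at 25 fps), 13 px blur,
   absolute threshold of 15 counts, contour filter at 5 μm, and greedy
   flow-biased frame-to-frame linking.
3. **Chromatography metrics** (`adchrom.chromatography`) — for each cell
   with elution time *t*<sub>e</sub>, median FOV instantaneous velocity
   *V*<sub>inst</sub>, channel length *L* and mean settling-feature offset
   *t*<sub>o</sub>:

   - average velocity: *V*<sub>avg</sub> = *L* / (*t*<sub>e</sub> − *t*<sub>o</sub>)
   - percent binding time (mass balance over a two-speed transit):

     %BT = [*v*<sub>ff</sub>(*t*<sub>e</sub> − *t*<sub>o</sub>) − *L*] /
     [(*v*<sub>ff</sub> − *V*<sub>inst</sub>)(*t*<sub>e</sub> − *t*<sub>o</sub>)]

   plus rolling/free-flow/arrested classification against the
   shear-dependent thresholds (125/250/375 μm/s at 0.5/1.0/1.5 dyn/cm²,
   with free-flow velocities 529/1059/1588 μm/s), residence-time
   distributions and population summaries.
4. **Comparisons** (`adchrom.comparisons`) — OLS regressions (slope t-test,
   Pearson's r) of metrics such as median rolling *V*<sub>inst</sub> versus
   % rolling, and tidy mean ± SEM dose-response tables across runs.

## Worked example

The bundled demo simulates a 200-cell pulse through the 1.3 cm channel at
1.0 dyn/cm², renders a 60 s video at 25 fps, tracks it, and analyzes the
tracks:

```bash
adchrom demo --outdir demo_run --seed 1
```

prints

```json
{
  "n_total": 210,
  "pct_rolling": 16.19047619047619,
  "median_v_inst_rolling_um_s": 66.09115245545485,
  "mean_pct_binding_time": 0.930410259713961
}
```

Reading the numbers: 210 tracks were recovered from the video (a handful
more than the 200 simulated cells, since a track interrupted mid-crossing
re-opens under a new id). About 16% of tracked cells moved at a nonzero
median speed below the 250 μm/s rolling threshold — an underestimate of the
simulated rolling fraction, because a 60 s acquisition misses slow rollers
that have not yet eluted (a real 2 h acquisition, `acquisition_duration_s`,
catches them). The rolling cells' median instantaneous velocity was
66 μm/s, close to the simulated 60 μm/s mean rolling speed. The mean
percent binding time is high both because rolling cells genuinely spent
most of their transit bound and because near-free-flow cells contribute
noisy clamped values (see `docs/methods.md`). Full per-cell results are in
`demo_run/cell_records.csv` and the aggregate in
`demo_run/population_summary.json`.

Library use mirrors the CLI:

```python
import adchrom as ac

geom = ac.ChannelGeometry()                      # 1.3 cm channel presets
cond = ac.FlowCondition(tau_wall_dyn_cm2=1.0)    # fills 1059 / 250 μm/s
params = ac.SimulationParams(n_cells=1000, seed=0)
transits = ac.simulate_transits(params, cond, geom)
records = ac.records_from_transits(transits, cond, geom, ac.AnalysisConfig())
print(ac.summarize_population(records).pct_rolling)
```

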