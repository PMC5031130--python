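# platedrc

Dose-response analysis of kinetic live-cell imaging data.

Live-cell imaging platforms monitor cell proliferation in real time,
typically as percent confluence per microplate well every couple of hours
over several days. In oncology drug discovery this is used to measure how
small-molecule inhibitors slow the proliferation of cancer cell lines:
each compound is dosed in a dilution series across replicate wells, and the
growth metric read off at a single *cut time* becomes a conventional
dose-response table from which an EC50 is fitted.

`platedrc` implements that workflow end to end for scientists running
plate-based proliferation screens:

1. **Import** a plate map (XML or tab-delimited dialect documented in
   `platedrc.plate_io`) and a kinetic growth export.
2. **Split** the plate into `DRCSet` objects, one per (growth condition,
   cell type) pair, so every set shares a single vehicle-control background.
3. **Fit growth curves** by tricube local regression (LOESS, degree 2,
   span 0.5 by default) — pooled over replicates per (compound,
   concentration) and individually per well.
4. **Compute the cut time** from the pooled vehicle-control curve: the time
   at which the untreated cells achieve a requested number of doublings
   from a baseline, restricted to the exponential growth phase and a
   maximum growth value. Normalising to doublings makes EC50s comparable
   between fast- and slow-growing lines.
5. **Fit dose-response curves**: each well's smoothed value at the cut time
   enters a four-parameter log-logistic (LL.4) fit per compound,

   f(x) = c + (d − c) / (1 + exp(b (ln x − ln e)))

   with hill slope *b*, lower asymptote *c*, upper asymptote *d* and
   inflection dose *e*; the relative EC50 equals *e*. Tables export in
   tidy, PRISM-style and stacked-block layouts.

The cut-time algorithm truncates the control curve at the minimum of an
n-point moving average of its second differences — the time at which growth
is decelerating most rapidly, i.e. the end of the exponential phase — and at
the crossing of a maximum allowable value (80 by convention for percent
confluence). If the doubling target is not reached on the truncated curve,
the truncation time is returned instead ("capped") with the number of
doublings actually achieved.

A seeded plate simulator (`platedrc.synthetic`) generates complete screens
with known growth rates and compound potencies, so the entire pipeline is
testable against closed-form ground truth.

## Worked example

```python
import platedrc as pdrc

spec = pdrc.SimulationSpec(seed=1)            # 6 compounds, 8 doses x 3 reps
platemap, platedata, truth = pdrc.simulate_plate(spec)
(s,) = pdrc.split_drc_sets(platemap, platedata)

pdrc.fit_growth_curves_grouped(s)
pdrc.fit_growth_curves_individual(s)
res = pdrc.calculate_cut_time(
    s, pdrc.CutTimeParams(baseline_time_h=0, no_doublings=2, max_val=80))
print(res)
```

```
CutTimeResult(cut_time_h=58.1015625, baseline_value=4.9651054274681865,
              target_value=19.860421709872746, achieved_doublings=2,
              truncation_time_h=96.0, capped=False)
```

The control wells (doubling time 24 h, 4 h lag) took 58.1 h to double twice
from their baseline value of 4.97 confluence units; the target of 19.9 was
reached inside the exponential phase, so the result is not capped.

```python
pdrc.calculate_drc_data(s)
pdrc.fit_dose_response(s)
print(s.dose_response_results["CMP002"].summary())
```

```
Four-parameter log-logistic dose-response fit
====================================================
compound:      CMP002
observations:  24
converged:     True
rss:           4.95331
----------------------------------------------------
param         estimate       std err
b              1.14642     0.0944139
c              5.03198      0.200131
d              20.1352      0.398939
e            0.0539305    0.00430721
----------------------------------------------------
EC50 (relative): 0.0539305
```

The fitted apparent EC50 for CMP002 is 0.054 µM: untreated wells reach
~20 confluence units at the cut time (upper asymptote *d*), fully inhibited
wells stay near the seeding confluence of ~5 (*c*), and half-maximal effect
occurs at 0.054 µM. `pdrc.export_ec50_table(s)` collects one such row per
compound.

The same workflow runs from the shell:

```sh
platedrc simulate --outdir sim --seed 1
platedrc run --config run.cfg          # or: platedrc drc --platemap ... --platedata ...
```

where `run.cfg` is a flat key = value file (`platemap`, `platedata`,
`outdir`, optionally `span`, `no_doublings`, `max_val`, `window_n`,
`cut_time_h`, `layouts`, `plots`).

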