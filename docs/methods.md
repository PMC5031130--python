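# Methods

## Scope and data model

`platedrc` analyses kinetic proliferation data from plate-based live-cell
imaging: a growth metric (typically percent confluence, 0–100) per well per
elapsed hour. Two inputs define an experiment: a *plate map* (what is in
each well: compound, concentration, growth condition, cell type) and a
*kinetic export* (the rectangular time × well matrix). Both are plain text;
the XML and tab-delimited dialects are documented in `platedrc.plate_io`.
Elapsed hours are the single time authority — any wall-clock column in an
export is ignored. Missing numeric cells are an error rather than imputed,
because silent imputation would bias the smoothing that everything
downstream reads.

The unit of analysis is the `DRCSet`: a plate-map/plate-data pairing in
which every well shares one (growth condition, cell type) pair and hence
one vehicle-control growth background. Plates mixing conditions are
partitioned by `split_drc_sets`; the grouping key includes the growth
condition as well as the cell type because lines grown under different
conditions proliferate differently and must not share a control curve.
Setting or changing a set's cut time clears any attached dose-response
results, so stale EC50s cannot survive a cut-time change.

## Growth-curve smoothing

Growth curves are fitted by tricube-weighted local polynomial regression
(LOESS), degree 2, default span 0.5. The smoother is implemented in
`platedrc.smoothing` with prediction at arbitrary times and a strict
no-extrapolation contract: the cut-time logic must never read a value the
data cannot support, so predictions outside the observed time range raise.
Degree ≥ 1 local regression reproduces affine data to machine precision;
that identity is the primary regression test of the backend. Replicate
wells are pooled point-by-point (no pre-averaging), so each replicate
carries its own weight in the local fits. A tiny tricube weight floor
(1e-9) keeps edge points from dropping out of boundary windows; it does not
affect the exactness properties.

Span is user-visible everywhere. Smaller spans track curvature better
(the dense-grid logistic test uses 0.25) at the cost of noise; 0.5 is a
reasonable default for 2-hourly sampling over 4 days.

## Cut-time algorithm

Parameters (with defaults): `baseline_time_h` (0), `no_doublings` (2),
`max_val` (80, in metric units), `window_n` (30 grid points),
`grid_step_h` (median sampling interval of the control data).

1. Predict the pooled vehicle-control curve on a uniform grid.
2. Form second differences d2[i] = y[i+1] − 2 y[i] + y[i−1] and smooth
   them with a centered moving average of half-width `window_n // 2`
   (windows truncated at the ends; `window_n = 1` degenerates to the raw
   second differences). The grid time of the earliest minimum is the end
   of the exponential phase — the moment growth decelerates most rapidly.
   A minimum falling in the left-truncated half-window, or a flat profile,
   means no deceleration was detected (initial lag/settling, or purely
   accelerating growth); the end of the data is then used, with a warning.
3. Truncate the curve at the earliest of: the exponential-phase end, the
   (bisection-refined) crossing of `max_val`, and the end of the data.
   Refining the `max_val` crossing, rather than stopping at the first grid
   point above it, keeps the capped prediction at `max_val` rather than one
   grid step beyond it.
4. The target value is `y(baseline) · 2^no_doublings`. The cut time is the
   earliest time at or after the baseline where the truncated curve reaches
   the target, refined by bisection to 0.01 h. If the target is never
   reached, the truncation time is returned (`capped=True`) together with
   the doublings actually achieved, log2(y(truncation)/y(baseline)).

Window semantics are a genuine design choice: the moving-average window is
counted in *grid* points, with the grid step defaulting to the median raw
sampling interval, so on near-uniformly sampled data the two readings
coincide. Both `window_n` and `grid_step_h` are exposed. Non-unique minima
take the earliest time, a convention rather than a derived fact.

Diagnostics (`cut_time_diagnostics` and the two-panel plot) expose the
control curve, the smoothed second-difference profile and both the
user-set (baseline, max_val) and computed (truncation, cut time, target)
markers.

## Dose-response model

The four-parameter log-logistic,
f(x) = c + (d − c)/(1 + exp(b (ln x − ln e))), is fitted per compound to
replicate-level (concentration, value-at-cut-time) points by multi-start
Levenberg–Marquardt least squares over (b, c, d, ln e). Starts: c and d
from the response range, e at the dose nearest the half-range crossing, and
slopes b ∈ {0.5, 1, 2, −1}; best residual sum wins, ties broken by the
shallowest slope. The parameterisation has the exact symmetry
(b, c, d, e) ↔ (−b, d, c, e); fits are canonicalised to d ≥ c so decreasing
responses carry the conventional b > 0. The relative EC50 is e itself and
f(e) = (c + d)/2 identically. Zero-dose (control) records are exported but
excluded from the fit, since log 0 is undefined. Standard errors come from
the Gauss–Newton approximation at the optimum (delta method back to the e
scale); they are NaN for noiseless or unconverged fits. Flat responses
(d ≈ c) are reported unconverged rather than raising, because e and b are
unidentifiable there. EC50s with e outside [min dose / 10, max dose × 10]
are flagged `extrapolated_ec50`.

Confidence intervals by profile likelihood or bootstrap, and model
families beyond the 4PL, are out of scope.

## Synthetic screens and what they do (not) show

The simulator emulates a cytostatic screen: delayed logistic growth
y(t) = K y0 / (y0 + (K − y0) e^{−r(t−lag)}) with r = ln2/doubling time,
and compounds scaling r by 1 − Imax·C^h/(C^h + EC50^h). Defaults — the
standard study condition used throughout the tests — are a 384-well layout
with 6 compounds × 8 half-log doses from 10 µM × 3 replicates plus 6
vehicle controls, y0 = 5, K = 100, 4 h lag, 24 h doubling time, imaging
every 2 h for 96 h, additive Gaussian noise sd 1.5 clipped at zero.
Compound potencies span pEC50 6.0–7.5 so every EC50 lies inside the dose
range. (Six compounds at 8 × 3 wells plus controls need 150 wells, hence
the 384-well format.)

Because compounds act on the growth *rate*, the apparent (value-scale)
EC50 at a finite cut time is not the rate-scale EC50; the reference for
pipeline accuracy is therefore a brute-force oracle that evaluates the
noiseless model on a 200-point log-dose grid at the same cut time and fits
the 4PL to that clean curve. End-to-end recovery within 0.2 log10 units of
this oracle for ≥ 90% of compound × seed pairs is the headline check.

What the simulator does not emulate: cytotoxic (confluence-decreasing)
kinetics, heteroscedastic or spatially structured noise, edge effects, or
segmentation artefacts of real imaging. Passing tests demonstrate the
correctness of the algorithmic chain under the stated growth model, not
robustness to those real-data pathologies.

Numerical conventions throughout: bisection crossings resolved to 0.01 h;
exports formatted at 6 significant digits (reproducibility over precision
theatre); pipelines are deterministic given config + inputs, and the
simulator is deterministic given its seed.

## Known limitations

- The exponential-phase detector assumes a single deceleration; biphasic
  growth (e.g. medium change mid-run) can mislead the minimum.
- Boundary bias of local regression slightly inflates values at the very
  start of a curve; with the default span this moves an exponential-growth
  cut time by a few tenths of an hour.
- Real instrument plate-map files are proprietary; the XML dialect here
  carries the same fields but is not a reader for those binaries.
- One growth metric per kinetic file; the metric name is a parameter.
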