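# lungcn

Complex-network quantification of diffuse interstitial lung disease (DILD)
on high-resolution CT.

Diffuse interstitial lung diseases — idiopathic pulmonary fibrosis and its
relatives — are hard to diagnose early and hard to monitor objectively:
radiological reading is pattern-based and interobserver variability is
substantial, while functional tests (FVC, DLco) change late. `lungcn`
implements a quantitative pipeline for pulmonologists, radiologists and
imaging researchers that turns an HRCT slice into a handful of graph-theoretic
numbers and a longitudinal progression rate:

1. **Calibration** — DICOM stored values are converted to Hounsfield units
   (HU = raw × slope + intercept, clamped to [−1024, 3071]); plain-text HU
   grids are accepted directly, and an optional region-of-interest mask
   restricts the analysis window.
2. **Band layering** — pixels are kept only if their attenuation falls in one
   of three pathologically meaningful HU bands:
   E = [−1024, −977) (emphysema, cyst lumina), GGO = [−977, −703)
   (ground-glass opacity), C = [−100, 5) (consolidation, reticulation).
   Everything else is discarded.
3. **Pixel networks** — within each band layer, two pixels are linked iff
   |ΔHU| ≤ 50 and their Euclidean distance is < 4 px; unlinked pixels are
   detached. Three degree metrics summarize each network: the maximum degree
   k_max, the total link count E, and the mean degree 2E/N.
4. **Progression speed** — for a metric s at follow-up and s₀ at the oldest
   scan of the same anatomical site, separated by t years (day count / 365),

       v = (s − s₀) / (s₀ · t)   if s₀ ≠ 0,   else   v = s / t     [1/year]

5. **Statistics** — Welch two-sample t-tests (unequal variances,
   Welch–Satterthwaite df, one-tail p, two-tail critical value) compare metric
   speeds against DLco variation, or borderline cases (DLco 70–85 %
   predicted, GAP-ILD 0–3) against normal lungs.

A synthetic phantom generator produces 2-D lung slices at the study geometry
(0.4557 mm/px) with parameterized lesions in each band — emphysema blobs,
cysts, ground-glass patches, reticulation lines, consolidation disks, nodule
strings, honeycomb clusters — plus controlled longitudinal growth, providing
ground truth for every pipeline stage.

## Worked example

A noise-free phantom with a 5 mm consolidation at the slice centre grows 40 %
per year in linear size; DLco stays constant at 78 %:

```python
from lungcn import (LesionSpec, generate_slice, grow_lesions, split_bands,
                    build_network, compute_metrics, speed_table, TimepointRecord)

t0 = generate_slice(shape=(96, 96), background_hu=(-880, 0),
                    lesions=[LesionSpec("consolidation_disk", (48, 48), 5.0)],
                    seed=11)
t1 = grow_lesions(t0, annual_growth=0.4, t_years=1.0, seed=12)

records = []
for truth, dlco in ((t0, 78.0), (t1, 78.0)):
    metrics = {layer.band.name: compute_metrics(build_network(layer))
               for layer in split_bands(truth.slice)}
    records.append(TimepointRecord("phantom", "center",
                                   truth.slice.acquisition_date,
                                   metrics, {"dlco_pct": dlco}))

for s in speed_table(records):
    if s.band in ("C", "functional"):
        print(f"{s.band:10s} {s.metric_name:14s} "
              f"s0={s.s0:g} s={s.s:g} v={s.v:+.3f} / year")
```

prints

```
C          max_degree     s0=44 s=44 v=+0.000 / year
C          total_count    s0=1516 s=3208 v=+1.116 / year
C          average_count  s0=31.2577 s=34.6811 v=+0.110 / year
functional dlco_pct       s0=78 s=78 v=+0.000 / year
```

The consolidation-band (C) link count more than doubles over one simulated
year (v = +1.116/year — the network "grew" 112 % relative to baseline), the
mean degree rises modestly, while the maximum degree is already saturated at
its lattice bound of 44 and the constant functional covariate correctly
reports zero speed. This is the intended reading: total count tracks overall
damage extent, average count its compactness, maximum degree its peak
intensity — and the speed highlights rapidly deteriorating sites even when
function is stationary.

The same pipeline is available from the shell:

```sh
lungcn simulate -o sim --seed 3 --shape 96,96 --background -880,0 \
       --lesion consolidation_disk:48,48:5 --growth 0.4 --years 1 --timepoints 2
lungcn analyze sim/t0.txt sim/t1.txt -o metrics.csv --meta meta.csv
lungcn progress metrics.csv -o speeds.csv
lungcn compare speeds.csv -o ttests.csv            # speeds vs DLco variation
lungcn export-graph sim/t0.txt -o net --band C --graphml
```

All defaults (band bounds, 50 HU tolerance, 4 px distance, 365-day year,
α = 0.05) reproduce the reference method; a YAML config or flags override
them.

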