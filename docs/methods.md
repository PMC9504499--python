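# Methods

## Model

`lungcn` treats an HRCT slice as a source of three sparse pixel populations,
one per pathological attenuation band, and each population as an undirected
simple graph. The premise is physical: two visual points in the lung that are
very close together and have similar density are very probably part of the
same tissue, healthy or lesional. Lesion extent and compactness then become
graph properties instead of reader impressions.

**Bands.** Pixels are retained iff their HU value falls in one of three
half-open intervals: E = [−1024, −977) for emphysema and cyst lumina,
GGO = [−977, −703) for ground-glass opacity, C = [−100, 5) for consolidation
and reticulation. Boundary values belong to the band whose lower bound they
equal (so −977 HU is GGO, not E). The gap [−703, −100) — normal to
indeterminate parenchymal attenuation — and everything ≥ 5 HU are deliberately
unassigned: those pixels are eliminated before graph construction. The band
set is scanner-calibrated and therefore configurable; the defaults correspond
to the GE Optima 520 geometry the pipeline was designed around. No automatic
band discovery is attempted.

**Attachment rule.** Within one band layer, pixels i and j are linked iff
|HU_i − HU_j| ≤ τ (τ = 50 HU, inclusive) **and** the Euclidean distance
between their centres is strictly less than δ (δ = 4 px). Pixels with no link
are *detached* and removed from the node set, so metrics describe connected
tissue, not isolated noise pixels. Two consequences worth noting:

* the only displacements that can ever link two pixels are the 44 integer
  offsets with 0 < dr² + dc² < 16, which bounds every node degree at 44 and
  lets construction scan a fixed neighbourhood per pixel (vectorized over
  shifted array overlaps) instead of all O(n²) pairs — the naive all-pairs
  construction is retained as `build_network_bruteforce` and used as the
  test oracle;
* band E is only 47 HU wide, narrower than τ, so inside band E the HU
  condition never binds and edge structure is purely geometric.

Chebyshev distance and a region-valued node variant were considered and
rejected: the strict Euclidean reading is the literal one, and the
aggregation rule for region nodes is underdetermined. Links are only formed
within a band layer; other bands' pixels were already eliminated by the time
a layer is built.

**Metrics.** For each layer graph: maximum degree (peak local intensity of
the alteration), total link count E (overall damage load), and average degree
2E/N (how compact/localized the damage is). An empty graph reports zeros.

**Progression speed.** For metric value s at a follow-up scan and s₀ at the
*oldest* scan (t₀) of the same subject and anatomical site,

    v = (s − s₀) / (s₀ · t)  for s₀ ≠ 0,    v = s / t  otherwise,

with t = (days between acquisitions) / 365. Units are 1/year; halving the
interval doubles the speed. Branch selection uses exact equality s₀ == 0 —
the second branch is a discontinuous convention of the definition, not a
numerical guard, and must not be triggered by small s₀. The alternative
typographic parse ((s − s₀)/s₀) · t was considered and rejected: it has units
of years, not 1/year, and is inconsistent with reading the statistic as a
speed. The reference is always t₀ (never chained pairwise), and a 360-day
year is available behind `year_basis: 360` for consistency with
financial-style conventions; 365 is the default and was used everywhere.
Functional covariates measured at the same visits (DLco % predicted) pass
through the identical formula, so CN speeds and functional speeds are
directly comparable.

**Statistics.** Group comparisons use the unequal-variance (Welch) two-sample
t-test: t = (x̄_a − x̄_b)/√(s²_a/n_a + s²_b/n_b) with Welch–Satterthwaite
degrees of freedom. The reported triple mirrors the spreadsheet layout many
clinical teams use: t statistic, one-tail p (upper-tail probability of |t|),
and the two-tail critical value at α = 0.05. The Welch form is the right one
here because per-comparison critical values differ when group variances do —
a pooled-variance test with fixed group sizes could not produce row-specific
fractional df. Used as a one-sided test, the one-tail p must be combined with
the sign of t (reject "a > b" only when t > 0 and p < α); the Monte-Carlo
calibration test does exactly this and recovers a 5 % type-I error. No
multiple-testing correction is applied, matching the intended workflow of
reading each band × metric comparison on its own. The borderline/normal
selector takes diagnosed cases with DLco between 70 and 85 % predicted
(inclusive; an interval centred on the 80 % lower normal limit) and GAP-ILD
0–3 points; "normal" rows are taken by label. Speed values are pooled across
sites when compared; per-patient pairing is not attempted because site
correspondence across subjects is not defined.

## Synthetic phantom

The generator emulates what the pipeline needs from a real axial HRCT window,
not the anatomy: an elliptical lung field (semi-axes 0.45 × grid size) of
parenchyma at −880 ± 20 HU (rounded Gaussian, i.i.d. per pixel) over a
soft-tissue border at +40 HU, with lesions rasterized on top in list order
(later lesions overwrite earlier ones; lesions protruding outside the lung
field are clipped with a warning). A pixel belongs to a shape iff its centre
is inside; geometric assertions allow 1 px of rasterization error. Defaults:

| parameter | default | rationale |
|---|---|---|
| pixel spacing | 0.4557 mm | 35 cm field of view / 768 matrix |
| background | −880 ± 20 HU | healthy parenchyma attenuation; sits *inside* the GGO band, so detection tests are non-trivial |
| emphysema blob / cyst lumen | −1000 HU | band E |
| ggo patch | −800 HU | band GGO |
| reticulation / consolidation / nodules / cyst walls | −50 HU | band C |
| cyst wall thickness | 1.5 px | thin but unbroken ring at this spacing |

Lesion shapes: circular disks (ggo patch, consolidation), harmonic-perturbed
blobs (emphysema), 1-px-wide segments (reticulation), strings of 1-px-radius
nodules every 3 px (perilymphatic micronodularity, giving the characteristic
sparse "string" network), and honeycomb clusters — hexagonally packed
thick-walled cysts whose lumina are band-E content and walls band-C content
in the same neighbourhood, spaced so lumina stay disconnected components.
A "clean" mode (background −1000 HU or any out-of-band value) isolates a
single band for detectability and monotonicity experiments.

Longitudinal growth rescales each lesion's linear size by
(1 + annual_growth)^t, regenerates background noise from the new seed, and
advances the acquisition date by round(365·t) days — so mask area scales
quadratically with linear growth and the recovered total-count speed is
positive by construction when lesions grow.

What the phantom does **not** model: airway/vessel trees, reconstruction
kernels and beam hardening, partial-volume gradients at lesion rims, spatial
noise correlation, 3-D continuity between slices, and anatomically plausible
lesion co-occurrence. Tests passing on phantoms therefore establish that the
algorithmic chain is correct and sensitive at the stated scales (lesions down
to 3 mm produce non-empty networks at 0.4557 mm/px), not that clinical
discrimination thresholds transfer to patient data.

## Numerical and design choices

* HU values are integers; stored DICOM values pass through
  round(raw·slope + intercept) and are clamped to [−1024, 3071]. Missing
  rescale tags default to slope 1 / intercept 0, missing pixel spacing to
  0.4557 mm — both with a logged warning.
* ROI exclusion writes the sentinel −32768 (outside every representable band)
  instead of cropping, so pixel coordinates remain comparable across
  timepoints of the same site.
* Edges are stored once as index pairs (i < j), sorted lexicographically;
  node order follows row-major pixel order, making exports byte-stable.
* Degenerate inputs: an empty band layer yields an empty graph (all-zero
  metrics, not an error); identical acquisition dates are rejected for speed
  computation; single-timepoint subjects are skipped with a warning;
  two samples that are both constant and equal return t = 0, p = 0.5 rather
  than failing.
* Test problem sizes — 40×40 oracle layers, 64–128 px phantoms, 2000
  Monte-Carlo replicates — were chosen as the smallest scales at which each
  property is meaningfully exercised (a 40×40 layer can hold several hundred
  nodes, an order of magnitude above the 44-offset neighbourhood).

## Known limitations

* Single-slice, axial-plane analysis only; no 3-D volume assembly or
  sagittal/coronal equivalence.
* No lung segmentation: inputs are assumed to be lung windows already, with
  an optional rectangular/free-form ROI mask as the only spatial selection.
* The node-per-pixel variant is the only one implemented; region-valued nodes
  are out of scope.
* Clusterization, path-length and centrality metrics beyond the three degree
  statistics are intentionally not computed.
* Cohort-level clinical conclusions require patient data the package does not
  ship; the statistical machinery is validated by oracle agreement and
  Monte-Carlo calibration instead.
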