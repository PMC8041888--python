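# Methods

This note documents the models and procedures implemented in `tofscape`,
the parameters that matter, what the synthetic scenes do and do not
emulate, and the numerical choices made where the design was open.

## Extent classification

**Compositing.** Optical collections are reduced per pixel to the date
maximizing NDVI (`(NIR − red)/(NIR + red)`, nodata where both bands are
zero), copying *all* bands from that date; ties break toward the earliest
date so the operation is deterministic, and compositing a composite is the
identity. Radar backscatter is averaged over time in the **linear power
domain** — `10·log10(mean(10^(dB/10)))` — never by averaging dB values,
which would underestimate the mean by Jensen's inequality. Scan-line gaps
between swaths in the descending average (pixels below a configurable
−25 dB floor, or nodata) are filled from the ascending average; the
ascending image is the only donor, so a low donor value is kept but
flagged.

**Thresholds.** The fusion rule is the intersection of a photosynthetic
mask and a structural mask. NDVI bounds (0.3, 0.9) are *exclusive*, as the
decision rule is a strict double inequality; the VH window [−14, −9] dB
(volumetric canopy scattering) and the VV veto window [−8, −2] dB are
*inclusive* ranges. All six bounds and the sieve size are configurable
(`ThresholdConfig`, YAML-loadable), with these values as shipped defaults.

**Order of operations.** fuse → polygon exclusion (pixel-center rule) →
sieve. Running the sieve last guarantees that mask edits can never
resurrect clumps below the 25-pixel minimum. The sieve clumps with
edge-or-corner (8-neighbour) adjacency; patch *reporting* uses edge-only
(4-neighbour) adjacency. The two stages intentionally differ: the sieve is
a noise filter, while stand statistics follow the stricter
shared-edge definition of connectedness.

## Patch structure

Stands are 4-connected components; areas are `pixel_count × pixel_area`
with pixel area taken from the geotransform (0.01 ha at 10 m). Size-class
bins are lower-exclusive/upper-inclusive with edges at 1, 5, 10, 100,
1000, 10⁴ and 10⁵ ha. No reprojection-based area correction is applied —
synthetic grids are planar; real-data users must supply an equal-area
grid.

## Terrain and canopy height

The DTM is inverse-distance-weighted: `ẑ(x) = Σ w_i z_i / Σ w_i`,
`w_i = d_i^(−p)`. Defaults follow the common terrain-gridding tool
convention: power `p = 2` and all points contributing (no search radius).
A cell within `ε = 10⁻⁶ × pixel` of a GCP takes that GCP's elevation
exactly, which avoids the `d → 0` singularity deterministically and makes
the surface interpolating. The surface is a convex combination of GCP
elevations, hence bounded by their range. Holdout GCPs report an RMSE;
points on nodata cells are excluded and counted.

The **pipeline** default is a 300 m search radius rather than all-points.
At the package's working GCP density (≈1 point per 80 pixels), global IDW
oversmooths an undulating terrain field (plot-level error ≈ 1.7 m sd here),
and that error propagates into both sides of the height calibration where
it attenuates the fitted slope (classical errors-in-variables). A local
neighbourhood cuts the error to ≈0.6 m sd and removes the attenuation.
Users reproducing the all-points convention can set `idw_radius: null`.

Raw canopy height is `DSM − DTM` restricted to the tree mask; negative
values are retained at this stage and handled by calibration.

## Height calibration

Both the raw CHM and a reference canopy-height surface (the reference
surface model differenced against the *same* DTM, so both regression
variables are heights above the same datum) are averaged over
non-overlapping 1 ha plots anchored at the raster origin; only tree-mask
pixels contribute and empty tiles are dropped. Plots with
`|Δ| > 2 × P99(|Δ|)` are screened out, then an ordinary least-squares line
`h_ref = a·h_raw + b` is fitted; MAE is reported before (identity line)
and after the correction, and least-squares optimality keeps
`mae_after ≤ mae_before` on the fitting set. OLS was chosen as the
simplest estimator consistent with a linear correction; the plot
averaging, not the estimator, is the defence against geolocation and
classification error.

Applying the model: raw values at or below 0 m are removed *before* the
transform (they are misclassified ground, not short trees); calibrated
heights must exceed the 2.19 m minimum credible tree height (a constant of
the calibration, config-exposed, not re-derived); surviving heights are
capped at the 99th percentile computed per administrative division, on the
surviving pixels (i.e. after the minimum-height filter — the cap is meant
to trim implausible maxima among accepted heights). Pixels outside every
division polygon fall back to a global percentile with a warning. The
transform is affine with positive slope, so calibration is monotone within
a division up to the cap.

A known temporal mismatch between an extent map and an older surface model
is not modeled; at observed national tree-gain rates it is a minor error
source relative to the penetration bias the calibration removes.

## Area accounting and accuracy

Per-division areas are integer pixel counts × pixel area, so the national
total equals the sum over divisions exactly. Canopy-cover products are
converted to extent masks by `cover > threshold` (default 0%), and map
comparisons report `a − b` with the second map as the percentage
denominator.

The accuracy assessment uses the standard stratified "good practice"
estimator suite. Strata are division × mapped class; weights are
mapped-area proportions. With `p̂_hj = n_hj / n_h`:

- overall accuracy `= Σ_h W_h p̂_h,m(h)` (m(h) = the stratum's mapped class),
- class-area estimate `Â_j = A_tot Σ_h W_h p̂_hj` (unbiased),
- `SE(p̂_·j)² = Σ_h W_h² p̂_hj (1 − p̂_hj) / (n_h − 1)`, CI `= 1.96·SE·A_tot`,
- user's accuracy per mapped class and producer's accuracy per reference
  class as the correspondingly conditioned weighted proportions.

With one stratum these collapse to the binomial proportion and its
normal-approximation interval (asserted in tests); against a 10,000-rep
stratified bootstrap the CI agrees to within the `n/(n−1)` variance
convention. Validation points carry a 10 m geolocation buffer: a point
whose mask value disagrees with its reference label counts as agreement if
any pixel center within the buffer carries the reference label. The
agreement is recorded on the diagonal cell of the point's own stratum so
strata keep a single mapped class.

## Synthetic scenes

The generator emulates a flat deltaic agricultural landscape: smooth
terrain (Gaussian-filtered noise, default 5 m sd around a 12 m base,
24-pixel correlation length), and tree patches placed until the requested
tree fraction (default 0.15) is met, drawn from three archetypes —
homestead blobs (3–10 px), field-boundary lines (1–3 px wide, 10–40 px
long), and sinuous riparian corridors (2–4 px wide, 60–200 steps) — mixed
0.35/0.45/0.20. Heights are per-stand bases from U(4, 16) m plus smooth
within-stand texture, clipped to [2.5, 30] m.

Optical scenes are abstract red/NIR reflectances in [0, 1] carrying only
the NDVI statistics the classifier uses: tree pixels peak in U(0.45, 0.62)
on a per-pixel greenest date; water/settlement/fallow classes stay below
0.3 at every date. Vegetation brightness is drawn from U(0.6, 0.9) —
band-level Gaussian noise (default sd 0.05) maps onto NDVI roughly as
σ/brightness, so dim vegetation would be disproportionately noisy.
SAR speckle is additive Gaussian in the dB domain (default 1.5 dB), a
deliberate simplification of multiplicative gamma speckle that suffices to
exercise linear-domain averaging. Class backscatter means sit strictly
inside (trees: VH U(−12.7, −10.3), VV U(−6.7, −3.3)) or outside (water,
fields, settlement) the decision windows with ≳1 dB margin, reflecting
thresholds chosen conservatively around separable cover types. Scan-line
stripes are vertical, full-height, 1–3 px wide at −30 dB, with the column
budget matched exactly to the configured gap fraction, descending pass
only.

The surface-model pair applies an affine canopy bias per surface (working
DSM default slope 0.8, emulating radar penetration; reference default
identity) plus Gaussian elevation noise (0.5 m / 0.3 m). Ground control
points sample non-tree pixels without replacement and read the noiseless
terrain.

**What passing tests do not show:** no orbital geometry, incidence-angle
or terrain-flattening effects; no real cloud masks (occlusion is an
optional NDVI knock-down); no multiplicative speckle or spatial
correlation of noise; no mixed pixels at stand edges; archetype geometry
is qualitative, not fitted to any real patch census. Synthetic results
demonstrate the correctness of the algorithms under the stated noise
model, not the accuracy of any particular national map.

## Problem sizes and determinism

Tests and the acceptance script run on 192²–256² scenes with 820 fitting /
40 holdout GCPs and 60 validation points per class per division — a
~1/10-scale version of a national campaign (8 200/400 GCPs, 500 points per
class per division), chosen so the statistical properties of interest are
measurable while the suite stays fast. Every stochastic component draws
from `numpy.random.default_rng` seeded from explicit integers; the same
seed yields bit-identical scenes, masks and reports.
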