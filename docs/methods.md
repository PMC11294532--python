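# Methods

## Model overview and assumptions

`ftcmap` treats a coarse-resolution pixel as a two-component mixture of
tree canopy and herbaceous/background cover. The estimation chain assumes:

* annual vegetation dynamics are well represented by 46 eight-day
  composites (composite *c* covers DOY 8*c*+1 … 8*c*+8; composite 45
  absorbs the 2-day remainder; leap days are ignored);
* the two cover types differ most in the *shape* of their seasonal
  curves — a plateau for trees against a single rounded peak for
  herbaceous vegetation — so that, once growing seasons are aligned to a
  common calendar position, a handful of phase-anchored readings
  discriminate them;
* residual cloud and shadow bias NDVI downward, never upward, so the clean
  seasonal curve is the *upper envelope* of the clear-sky observations.

## Preprocessing and the envelope smoother

Non-clear composites (cloud, snow, water, fill) are set to NaN. The NDVI
series is then reconstructed by a periodic truncated-harmonic fit with
iterative rejection:

1. fill gaps by linear interpolation with periodic wrap;
2. fit by keeping the first 16 Fourier harmonics of the 46-point series;
3. mark observations more than 0.05 NDVI *below* the fit as contaminated,
   remove them, and repeat (at most 10 passes or until the rejected set
   stabilises).

Parameter choices: 16 harmonics reproduce a steep double-logistic
(logistic rate 2/composite) to better than 0.01 NDVI while still averaging
out single-composite artefacts; the 0.05 rejection margin sits well above
the reflectance-noise level (~0.01–0.02 NDVI) and well below typical
cloud-induced NDVI drops (≥ 0.1). An early design used raise-to-fit
capping instead of rejection, but capping feeds spurious bumps at the
fit's ringing lobes back into the data and locks a sharp-cutoff fit into a
sustained mid-frequency oscillation; rejection with gap interpolation has
the same upper-envelope intent and converges cleanly.

Two exact properties follow from this construction and are load-bearing
downstream. The operator is a projection: its output is band-limited, so
applying it twice changes nothing. And it is bitwise rotation-equivariant:
the series is anchored at its (earliest) maximum before fitting, so
smoothing a circularly shifted pixel yields exactly the shifted result —
which is what makes realignment invariance testable bit-for-bit rather
than to a tolerance.

Red and SWIR2.1 (and LST) gaps are filled by periodic linear interpolation
only; the envelope argument does not apply to reflectance, and the
features read these bands at isolated composites where interpolation
suffices. Pixels with fewer than 8 clear composites are unusable. The
SWIR2.1 band, provided at twice the grid spacing of the red/NIR bands, is
matched by nearest-neighbour duplication of each coarse cell into its 2×2
fine cells.

## Growing-season detection and realignment

The reference curve is the per-composite mean of the smoothed NDVI over
all available years (composites with no finite year propagate NaN; more
than 10 such composites invalidate the pixel). Its amplitude is max − min;
the run threshold is min + amplitude/2.

* amplitude < 0.2 → evergreen branch: the midpoint is the circular mean of
  the 18 greenest composites (value ties break to the earlier composite;
  the rounded mean breaks half-way ties toward the smaller index). Below
  amplitude 0.02 the curve is treated as flat and no shift is applied.
* amplitude ≥ 0.2 → seasonal branch: maximal circular runs above the
  threshold are enumerated (wrapping the year boundary, so southern-
  hemisphere seasons are handled); with several runs the one with the
  highest mean daytime LST wins, falling back to the longest run (ties to
  the earliest start) when LST is unavailable. The midpoint of a run of
  length L starting at s is s + ⌊(L−1)/2⌋ on the circle — a deterministic
  tie rule for even lengths.

Realignment rotates every band by whole composites so the midpoint lands
on composite 23 (DOY 185–192). Whole-composite granularity matches the
data's native resolution, keeps rotation a pure permutation (value
multisets preserved exactly) and avoids interpolation artefacts. Season
detection runs once per pixel on the multi-year reference and the
resulting shift is applied to every year of that pixel.

## Features

Four phases × three bands: annual NDVI maximum, annual NDVI minimum
(argmax/argmin of the smoothed realigned NDVI, ties to the earliest
composite), and the fixed shoulders at composites 17 (DOY 137–144) and 29
(DOY 233–240), roughly one and a half months either side of the centred
midpoint. The minimum phase is a pluggable locator with argmin as the
default. Features are read from the smoothed NDVI and interpolated
red/SWIR arrays, in the documented order `ndvi_max.* , ndvi_min.* ,
grow_left.* , grow_right.*` with bands NDVI, red, SWIR2.1 within each
phase.

## Training references

Categorical tree/non-tree maps at subcell resolution are aggregated to
percent cover (cells with under half their subcells valid become nodata),
and at least two products are combined into a per-pixel mean (TC_RefMean)
and mean absolute deviation (MAE_Ref). Exclusion rules, with deliberate
boundary semantics: MAE_Ref strictly greater than 10% excluded (10.0
retained); fewer than 25 clear composites excluded (25 retained); seasonal
pixels with runs shorter than 12 composites (~3 months; 96 days) excluded,
evergreen pixels exempt; water, permanent snow/ice and barren land
excluded. MAE_Ref is applied per pixel — a regional statistic could not
drive a per-pixel exclusion. Balancing down-samples the integer 0% and
100% bins (round-half-up binning) to their caps uniformly at random under
a recorded seed; no row is ever altered, only membership.

## Network and training recipe

12 → 400 → 200 → 100 → 50 → 25 → 1, ReLU between hidden layers, linear
output clipped post-hoc to [0, 100] (simpler gradients than a bounded
activation). Training: MSE loss, Adam at learning rate 1e-3, batches of
1024, at most 100 epochs, early stopping with patience 5 on a 10%
validation split, per-feature z-scoring. The target is also z-scored
internally (predictions are back-transformed): with a linear output head
and Adam steps of ~1e-3, an unscaled target in 0–100 would need tens of
thousands of updates just to move the output bias into range. Optimisation
is delegated to scikit-learn's MLPRegressor; prediction uses this
package's own forward pass on the extracted weights, so a saved model
(plain npz) reproduces predictions bit-exactly. Post-processing zeroes
pixels whose annual maximum NDVI is strictly below 0.35 and writes water
and permanent snow/ice as nodata; maps are stored as unsigned 8-bit
percent with nodata 255.

## Validation

MAE, RMSE and ME are weighted by the inverse inclusion probability
ω_i = K_h/k_h of each sample's stratum; R² (squared Pearson correlation)
and the OLS regression of reference on prediction are unweighted — the
error metrics and the regression diagnostics answer different questions
and the weighting convention is kept separate deliberately. Range subsets
(e.g. 15–95%) select on the reference value, bounds inclusive. Mean
difference between two cover stacks divides by the number of *shared
valid* years per pixel, not the nominal period length.

## Synthetic scenes: what they emulate and what they do not

The generator mixes tree and herbaceous endmember reflectance linearly by
area fraction — reflectance mixes linearly, NDVI is computed from the
mixed red/NIR, never mixed itself, which is the physically defensible
convention. Endmember NDVI follows a double logistic; red and SWIR2.1
decrease affinely with greenness; NIR is derived consistently from NDVI
and red. Default endmembers: tree vmin 0.25 / vmax 0.85, green-up
composite 12, senescence 34, logistic rate 2.0 (a sharp-edged plateau);
herbaceous vmin 0.15 / vmax 0.75, rates 0.3 (a rounded single peak). These
are typical of temperate deciduous forest against grassland/cropland
seasonal trajectories.

Per-pixel phenology is a circular shift by whole composites — matching the
realignment granularity so shift-invariance is exact. Noise is i.i.d.
Gaussian on reflectance (default sd 0.01); cloud masking is i.i.d. per
composite (default probability 0.1); a synthetic LST curve (270–300 K)
tracks the seasonal cycle. The four pseudo categorical products label
exactly `round(fraction × subcells/100)` subcells as tree at seeded-random
positions (so zero-error aggregation is exact), then flip labels at
per-product omission/commission rates (defaults 0.05/0.05, 0.08/0.04,
0.10/0.05, 0.02/0.01, spanning the accuracy range reported for public
forest maps); the last product additionally drops tree labels below 30%
true cover, emulating products that map only significant clusters of tall
dense vegetation — below roughly that density trees rarely form such
clusters.

Not emulated: radiative-transfer or BRDF effects, snow phenology, spatially
correlated cloud, sensor-specific noise, geolocation error, multi-year
land-cover change. Passing tests therefore show the chain is correct and
self-consistent under the stated mixture model, not that it reaches any
particular accuracy on real satellite archives.

## Problem sizes

The end-to-end checks use 48×48 to 64×64 scenes (a few thousand pixels)
with an 80/20 train/test split and the full network; parameter-recovery
unit tests use up to 50,000 analytic mixture rows. These sizes give stable
error estimates (binomial/CLT fluctuations well under the asserted
margins) while keeping the whole suite fast.

## Known limitations

* The envelope smoother's sharp harmonic cutoff can ring by a few 0.001
  NDVI near very steep transitions; the rejection margin absorbs this.
* With heavy gaps in a steep transition the reconstruction error can reach
  ~0.1 NDVI locally.
* The season-midpoint rule identifies one primary season; genuinely
  bimodal vegetation (double cropping) is realigned to its warmer season
  only.
* The categorical-product emulation draws subcell arrangements
  independently per product; real products share landscape structure and
  their errors are spatially correlated.
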