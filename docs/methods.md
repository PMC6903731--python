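# Methods

This note documents the models, numerical choices, and synthetic study
conditions behind `pengwinter`, in the spirit of the methods sections of
the mature simulation/inference packages the library imitates. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Working geometry

All inference, binning, and area computation happen in a spherical
Lambert azimuthal equal-area projection, south-polar aspect with the +y
axis along 60°W, Earth radius R = 6371.0 km (`pengwinter.projection`).
The projection is exactly area-preserving, so hexagon cells and habitat
polygons have exact planar areas, and a polar aspect has no dateline
seam for tracks spanning 170°W–25°W. Longitude/latitude appear only at
I/O; great-circle distances use the haversine formula on the same
sphere. Longitudes are normalized to (−180, 180].

## Track state-space model

Per axis (x east, y north in the projected plane, km and days), the
CTCRW has state (p, v) with OU velocity: dv = −β v dt + σ dW. The
exact one-step transition and its covariance are given in the README;
the implementation computes them with `expm1` and a series expansion of
the position-variance term below βΔ < 10⁻³, where the direct expression
cancels catastrophically. The two axes are independent given (β, σ)
and share parameters (isotropic movement).

* **Measurement model.** Argos class → isotropic position sd, default
  {3: 0.25, 2: 0.5, 1: 1.5, 0: 5, A: 5, B: 10} km (literature-typical
  magnitudes; the class Z code carries no usable position and is
  removed in QC). An optional global `error_scale` multiplier exists
  but is fixed at 1 by default rather than estimated.
* **Initial state.** The prior sits at the first processed node:
  position = first fix with its class variance, velocity = 0 with
  diffuse variance 10⁶ km²/day². The first fix is then assimilated
  like any other observation; the brute-force joint-Gaussian oracle in
  the tests encodes the same generative convention, which is what makes
  the likelihood-equivalence check exact rather than approximate.
* **Estimation.** (log β, log σ) are maximized with L-BFGS-B (bounds
  ±8 on log β, −8..12 on log σ) from a fixed default start (β = 1/day,
  σ = 20 km/day^1.5) plus one deterministically jittered restart; the
  better optimum wins. Non-convergence flags the deployment and
  excludes it downstream with a recorded reason.
* **Smoothing/imputation.** Kalman filter with Joseph-form updates and
  an RTS backward pass (covariances symmetrized by construction; a
  pseudo-inverse fallback guards singular predicted covariances at
  σ → 0). Imputation uses Durbin–Koopman mean-corrected simulation
  smoothing: simulate an unconditional state path plus synthetic
  observations, smooth them with the same prior, and add the residual
  to the real smoothed mean. Draws are therefore joint over time, not
  per-node noise. The output clock runs from tag release in exact
  2-hour steps; the last fix instant is appended as a final node when
  it falls off-grid.
* **Seeding.** A single run seed fans out per deployment as
  `(seed * 1000003) XOR crc32(deployment_id)` masked to 31 bits, so
  per-deployment results are independent of processing order.

## Quality control

Filters run per deployment, in order: (1) remove class-Z fixes and
fixes whose error ellipse is unspecified (missing or non-positive
semi-major axis); (2) a recursive forward speed filter — walking
forward from the release site, which is always trusted, drop any fix
whose great-circle speed from the last retained fix exceeds 2.5 m/s,
inclusive (9 km in exactly one hour survives); duplicate timestamps
keep the first fix; (3) retain deployments whose filtered fixes span at
least 7 days, measured first fix to last fix. The speed filter is
deterministic and idempotent, and per-deployment application equals
global application. On the default synthetic data the speed filter
removes a large share of low-quality fixes because the duty cycle packs
fixes about an hour apart while class A/B/0 errors are 5–10 km; this is
a property of the error magnitudes, not a tuning target.

## HUDs and overlap

Flat-top hexagonal tessellation anchored at the projection origin,
centroid spacing d = 25 km, circumradius d/√3, cell area (√3/2)d² =
541.266 km². Point-to-cell assignment is nearest-centroid via axial
cube rounding, which is deterministic on boundaries and provably
equivalent to polygon containment (the tests verify agreement on 10⁵
random points). Months are UTC calendar months; a track contributes to
every month it spans. A bird is present in a (month, cell) if any of
its imputed positions lands there — draws deduplicate for presence but
accumulate as a visit weight, which the overlap index does not use
(occupancy is binary). Inter-colony overlap needs ≥ 2 distinct
colonies in a cell; intra-colony overlap ≥ 2 distinct birds of the
colony; a bird co-occurring with itself across draws is never overlap.
Ratios are computed on cell counts (exact integers) and reported as
percentages of occupied area.

## Migration classification and speeds

Classification runs on the smoothed mean path (the deterministic
per-deployment summary; per-draw variants are available but
non-normative). Local ⇔ maximum haversine distance from the tagging
site ≤ 500 km over the whole track. Otherwise the net longitudinal
displacement — accumulated with `unwrap`, so a westbound dateline
crossing stays negative — at the time of maximum distance sets the bin;
if exactly zero, the displacement at the last position decides, and a
still-zero displacement is flagged instead of guessed. Monthly net
speed is the great-circle distance between a month's first and last
position over the elapsed seconds between them; the mean daily speed
weights months by the number of calendar days with at least one
position; the max daily speed divides each day's net displacement by a
full 86 400 s (so a day sampled 00:00–22:00 at constant speed v reports
(22/24)·v). Single-position months and days are excluded and logged.

## Habitat metrics

Per-hexagon covariate means average the grid values whose cell centers
fall in the hexagon (the same nearest-centroid rule as the HUD); a
hexagon smaller than the grid spacing falls back to the nearest grid
center and is flagged. Along-track matching picks the nearest grid
cell on the fix's UTC day and never interpolates across missing days.
Ice residence assigns each fix the interval to the next fix and reports
the fraction of that time with matched SIC ≥ 5% (the MIZ outer limit;
configurable) plus the mean SIC of in-ice fixes.

Isocline regions come from marching squares (`skimage.find_contours`)
on the field padded just past the contour level so that regions
touching the domain boundary close on the outer edge. Each closed
loop is classified by sampling the field at an interior point; the
region is the union of interior-positive loops minus the union of
negative loops, which resolves two levels of nesting — enough for the
monotone analytic fields used here, and a stated limitation for wilder
fields. The open-water bound is inclusive in SST (≤ 2 °C) and
exclusive in SIC (< 5%) so that open water and the MIZ partition
cleanly at the 5% isocline. Areas densify polygon edges to ≤ 0.25°
segments before projecting, and a raster cell-count of the same
inequalities over exact spherical cell areas serves as an independent
cross-check (agreement tightens with grid resolution; ≤ 2% at the
default 0.5°).

## Synthetic study conditions

The generator (`pengwinter.synthetic`) encodes the study conditions and
is deterministic in its seed.

* **Deployments.** Three colonies — Admiralty Bay (58.469°W,
  62.236°S), Cape Shirreff (60.789°W, 62.46°S), Cierva Cove (60.984°W,
  64.143°S) — with releases between 18 Feb and 9 Mar 2017 at 12:00 UTC.
  The table-shaped fixture deploys 10/20/20 tags (40 adults, 10
  juveniles) and assigns each colony/stage group its behavior mix
  (no eastbound Cierva Cove birds, no westbound juveniles) and duration
  ranges patterned on the study's tracking summary; the non-viable
  remainder transmit 2–6 days so the 7-day filter removes exactly 6
  adults and 3 juveniles.
* **Movement.** β = 1/day, σ = 30 km/day^1.5 for all behaviors
  (stationary velocity sd ≈ 21 km/day). Local birds add a restoring
  drift −γ(p − colony) with γ = 0.05/day, giving a stationary position
  sd of σ/√(2βγ(β+γ)) ≈ 93 km — comfortably inside the 500-km local
  radius, and simulated exactly in the azimuthal-equidistant tangent
  plane at the colony via a Van Loan matrix-exponential discretization.
  Migrants integrate CTCRW velocities in local east/north steps with a
  ±40 km/day zonal drift along a synthetic front at 62°S (the
  stand-in for the southern ACC front; the Polar Front stand-in sits at
  58°S) plus a weak 0.02/day meridional pull toward the front.
* **Argos process.** Daily duty window 12:00–18:00 UTC; Poisson fix
  counts per window with mean 6.0 (adults) / 3.4 (juveniles); class
  frequencies {3: .08, 2: .12, 1: .18, 0: .17, A: .15, B: .25, Z: .05};
  isotropic class errors as above; class-Z positions corrupted
  uniformly up to 1000 km; 2% of non-Z fixes lack ellipse fields.
* **Environment.** 0.5° grids over 180°W–0°W, 75°S–50°S, months
  Feb–Oct 2017. SST is linear in latitude (−1.8 °C at 75°S, slope
  0.21 °C/°) with a seasonal cosine (amplitude 0.8 °C, warmest in
  February) and a small longitudinal meander (0.3 °C, wavenumber 2).
  SIC is a logistic front in latitude (width 1.5°) whose 50% isocline
  advances from 70°S (March) to 60°S (September) with a 1°, wavenumber-3
  longitudinal ripple; every isocline has a closed-form inverse used as
  a test oracle. Daily SIC adds a field-wide AR(1) offset (sd 3%,
  lag-1 correlation 0.8), clipped to [0, 100]. Bathymetry is a
  Gaussian shelf band (−500 m) over a −4000 m basin; the zonal current
  is a small eastward jet near the Polar Front stand-in. The land mask
  is a synthetic peninsula-plus-island polygon pair. The meandering
  fronts are part of the analytic form: a grid-aligned straight front
  would give any center-counting raster comparison a systematic
  half-cell bias, and real fronts are not latitude-constant.

**What the generator does not emulate.** Satellite-pass geometry and
real Argos error anisotropy; coastline-constrained movement; and —
most consequentially — ice avoidance: synthetic local birds mean-revert
to their colony even as the ice edge advances over it, so the
ice-residence fraction on synthetic data (~0.26 on the default fixture)
is far larger than for real ice-avoiding penguins, and the in-ice mean
SIC differs accordingly. Passing tests therefore demonstrate that the
metrics are computed correctly, not that the synthetic birds behave
like real ones in ice. Likewise the migrants drift for their whole
deployment, so synthetic maximum distances for long west-bound tracks
exceed the real study's ranges while preserving the local ≪ migrant
ordering.

## Problem sizes and determinism

Default analyses use 100 imputed tracks per deployment on the 2-h
clock, 0.5° environmental grids, and the 50-deployment fixture; the
test suite runs reduced-size variants (e.g. 10–20 draws, 12–50 fit
replicates) chosen so each check's Monte-Carlo error is well inside its
assertion tolerance. Identical seeds reproduce every product
byte-for-byte; the run manifest records the config snapshot, software
version, per-deployment status, and SHA-256 hashes of all outputs.
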