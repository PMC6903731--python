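# pengwinter

Winter-migration analysis for satellite-tracked penguins: Argos track
quality control, continuous-time correlated random walk (CTCRW)
state-space smoothing with multiple track imputation, hexagonal
habitat-utilization distributions (HUDs) and overlap indices,
migration-strategy classification, and an isocline-based index of
open-water and marginal-ice-zone habitat availability.

The package targets movement ecologists working with duty-cycled Argos
telemetry of central-place seabirds — the motivating system is chinstrap
penguins (*Pygoscelis antarctica*) dispersing from Antarctic Peninsula
colonies across the Southern Ocean in winter — but every stage runs end
to end on a built-in synthetic dataset (three colonies, 40 adult + 10
juvenile deployments, analytic SST/sea-ice/bathymetry/current grids), so
nothing external is required to exercise or validate the pipeline.

## The models and statistics at the core

**Track model.** Each bird's velocity follows an Ornstein–Uhlenbeck
process per axis of an equal-area polar plane, dv = −β v dt + σ dW, and
position integrates velocity (the CTCRW). Over a step Δ the exact
discretization is

    v' = e^{−βΔ} v + N(0, σ²(1−e^{−2βΔ})/(2β))
    p' = p + v (1−e^{−βΔ})/β + noise,

with Var(p) = (σ²/β²)(Δ − 2(1−e^{−βΔ})/β + (1−e^{−2βΔ})/(2β)) and
Cov(p,v) = (σ²/(2β²))(1−e^{−βΔ})². Argos fixes observe position with a
known class-dependent Gaussian sd. (β, σ) are fit by maximum likelihood
through the Kalman filter; the RTS smoother plus mean-corrected
simulation smoothing yields 100 jointly consistent imputed tracks on a
2-hour clock from tag release to tag failure.

**Quality control.** Class-Z and unspecified-ellipse fixes are dropped;
a recursive forward speed filter anchored at the release site removes
fixes implying sustained swim speeds above 2.5 m/s; deployments with
under 7 days of filtered data are excluded.

**Occupancy and overlap.** Imputed positions pool onto flat-top
hexagons with 25-km centroid spacing (cell area (√3/2)·25² ≈ 541 km²)
per calendar month. Overlap is the area of cells where ≥ 2 individuals
(inter-colony: ≥ 2 colonies) co-occur relative to the total occupied
area.

**Migration bins.** A deployment is *local* if it stays within 500 km
(great-circle, R = 6371 km) of its tagging site, else *east*/*west* by
the sign of the dateline-unwrapped net longitude displacement at the
time of maximum distance. Sustained swim speed is the monthly net
displacement rate weighted by days tracked per month.

**Habitat availability.** Per month, 180°W–0°W: open water is the area
between the 5% sea-ice-concentration (SIC) isocline and the 2 °C
isotherm (SST ≤ 2 °C and SIC < 5%); the marginal ice zone (MIZ) is the
5–50% SIC band. Isoclines are traced with marching squares, converted
to polygons, differenced against a land mask, and measured in the
equal-area plane; a rasterized cell-count computation cross-checks the
polygon areas.

## Worked example

```bash
python examples/01_simulate_and_qc.py
```

prints, for the default deployment-table-shaped dataset at seed 1:

```
simulated 19751 raw fixes from 50 deployments
removed by quality screen: 1359 fixes (class Z or unspecified ellipse)
removed by speed filter:   7401 fixes (> 2.5 m/s sustained)
adult    : 34/40 deployments kept >= 7 d of data (15% removed)
juvenile : 7/10 deployments kept >= 7 d of data (30% removed)
total retained deployments: 41
```

i.e. the three-stage QC retains 41 of 50 deployments — 34 adults (15%
of adult tracks removed) and 7 juveniles (30% removed). Running the
full pipeline (`python examples/06_full_pipeline.py`, ~20 s) then fits
all 41 retained birds, imputes 100 tracks each, and reports inter-colony
overlap peaking at ~12–13% of the occupied area in March–April before
decaying as migrants disperse, alongside the monthly open-water/MIZ
habitat series (open water shrinking from ~6.4 to ~0.9 million km² as
the synthetic ice edge advances north, the MIZ staying a narrow band
near 4–5 million km²).

Other examples cover single-deployment smoothing and imputation
(`02`), HUD construction and overlap (`03`), migration classification
against the simulator's ground-truth behaviors (`04`), and the habitat
index with its raster cross-check (`05`). The same stages are exposed
as a thin CLI: `pengwinter simulate|qc|ssm|hud|classify|habitat|run-all`.

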