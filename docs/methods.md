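# Methods

This note documents the models, numerical choices and synthetic-data design
behind `batrack`, and what the test suite does and does not demonstrate
about field data.

## Acoustic forward model and multilateration

A call emitted at position **x** (array frame, metres) reaches microphone
*i* after `‖x − m_i‖ / c` seconds, assuming isotropic spherical spreading
in still, homogeneous air. The observable is the time-of-arrival-difference
against the designated reference microphone (the top of the frame):

    toad_i(x) = (‖x − m_i‖ − ‖x − m_ref‖) / c ,   i over the 7 other mics.

The sign convention `t_mic − t_reference` is used throughout the package
and its file formats. The speed of sound defaults to `c = 343.0` m/s
(≈ 20 °C); `speed_of_sound(T)` provides the temperature model
`c = 331.3·√(1 + T/273.15)` for users who log air temperature.

**Solver.** The position minimises the sum of squared TOAD residuals over
the valid channels. The cost is non-convex (hyperboloid intersections), so
the residual norm is first evaluated on a deterministic coarse grid — 26
golden-angle hemisphere directions × radii {2, 5, 10, 20, 40} m around the
array centre — and the best four starts are polished with
Levenberg–Marquardt least squares using the analytic Jacobian

    ∂toad_i/∂x = (û_i − û_ref) / c ,   û_k = (x − m_k)/‖x − m_k‖ .

The lowest-residual polish wins; the whole procedure is deterministic given
its inputs. A solution whose residual RMS exceeds a configurable cap
(default 10⁻⁴ s) is flagged invalid — this also catches non-physical TOAD
sets such as all-zeros, for which no point reproduces the observations with
the default non-coplanar geometry. At least 4 valid microphones including
the reference are required; fewer is a hard rejection.

**Default array geometry.** Mics at (±1,0,0), (0,±1,0), (0,0,1)
[reference], (0,0,0.5), (0.5,0,0.5), (0,0.5,0.5) m: 2.0 m aperture, 8
channels, non-coplanar (a unique 3D solution requires rank-3 geometry).
Field arrays are configured with a geometry CSV; nothing downstream assumes
the default. The five frame reference points used for co-registration are
the four frame ends (±1,0,0), (0,1,0), (0,0,1) and the centre (0,0,0) —
deliberately non-coplanar so the rigid fit is fully constrained.

## Error assessment (overdetermined array)

With 8 microphones the 7-dimensional TOAD vector over-determines the
3-dimensional position, and the misfit at the solution estimates the
localisation uncertainty. We linearise at the solution: with Jacobian `J`
(rows = valid channels) and residual variance `s² = SSR/(n − 3)` for `n`
valid TOADs, the position covariance is `C = s²(JᵀJ)⁻¹`. Writing `r̂` for
the unit vector from the array centre to the position:

- **radial error** = `√(r̂ᵀ C r̂)` — 1-σ uncertainty along the line of
  sight, the poorly constrained "range" direction;
- **tangential error** = `√(tr(P C P))`, `P = I − r̂r̂ᵀ` — combined 1-σ
  uncertainty in the perpendicular plane;
- **max TOAD distance error** = `c · max_i |toad_i^obs − toad_i(x̂)|`, a
  worst-channel consistency check in metres.

With exactly 4 microphones the residuals vanish identically (zero degrees
of freedom), so the errors are undefined and the position is flagged
unassessable rather than given a spuriously perfect score.

These estimates are *calibrated*, not exact: across random sources in the
2–20 m working range with 2 µs TOAD noise the estimated total error
correlates with the realised error at r ≈ 0.6 and its mean sits within a
factor 2 of the empirical RMS. At one fixed range the correlation is much
weaker (≈ 0.2) — there the geometry factor is constant and both quantities
are dominated by independent noise draws, which is a property of any
residual-based estimator, not a defect of this one. Estimated errors grow
monotonically with range, roughly as range²/(aperture·c) per unit of TOAD
noise, which is why the 2–20 m band (1–10 array apertures) is the working
range and why the filters below exist.

## Position filtering, tracks, passes

- Positions closer than 2 m to the array centre are excluded (near-field
  reflections and frame shading make them unreliable); there is **no upper
  range cut** — loud calls localise far beyond 20 m and are kept.
- A position is excluded when **either** the radial or the tangential error
  exceeds 0.5 m; both thresholds are inclusive (≤ 0.5 m passes).
- Tracks are built greedily: each position joins the open track with the
  nearest last point, subject to a time gap ≤ 1 s and an implied speed
  ≤ 20 m/s (generous for *Pipistrellus*); tracks shorter than 3 positions
  are dropped. Track identity makes no claim of individual identity across
  gaps — a bat leaving and re-entering the covered hemisphere gets a new
  track.
- Activity is summarised as *bat passes*: 10 s windows aligned to the
  recording start that contain at least one localised position.

## Call detection and TOAD estimation

Detection is short-time band energy (1 ms frames, 15–120 kHz band-pass)
against a 100 ms rolling-median noise floor, trigger at 8× the floor, 20 ms
hold-off; windows are 25 ms so every channel's copy of a call (delay spread
≤ aperture/c ≈ 6 ms plus a 5 ms call) lies inside. TOADs come from the FFT
cross-correlation of the band-passed window against the reference channel,
with the lag search clamped to the physical bound `±(baseline/c + 1
sample)` and a 3-point parabolic interpolation for sub-sample precision
(≤ 0.04 samples error on clean constructed shifts; ≤ 0.2 samples at 20 dB
SNR). Channels that are silent, or whose normalised correlation peak falls
below 0.35 (e.g. occluded channels containing only noise), are excluded
from the solve.

## LiDAR handling

Point clouds are ingested from XYZ[,deviation] CSV text with coordinates in
metres. Returns with pulse deviation **strictly greater than 15** are
removed (high deviation marks semi-returns and soft targets). Voxelisation
uses half-open cubic cells `[lo, lo+edge)` with `index =
floor((p−origin)/edge)`; the default origin snaps the cloud minimum down to
edge multiples so binning is reproducible, and the default edge is 0.20 m —
small enough to preserve canopy gaps that matter to bats, large enough to
suppress point-density artefacts. Voxels with **at least 10** returns are
vegetation voxels; isolated returns are treated as background. Distances
are measured to vegetation-voxel *centres* by default (KD-tree, exact
nearest neighbour); measuring to the raw filtered cloud instead is a
one-line change (`distance_to_vegetation(positions, cloud.points)`) and
gives systematically smaller distances by up to half a voxel diagonal.

## Rigid co-registration

The array's five reference points, surveyed in the LiDAR cloud, give ≥ 3
correspondences for the orthogonal-Procrustes (Kabsch) fit: SVD of the
cross-covariance with the smallest singular direction sign-corrected so
det(R) = +1 — a reflection would mirror the scene and is never a physical
mounting of the array. The fit is least squares over all five points; the
post-fit RMSD is reported and a warning is raised above 5 cm, the level at
which alignment error becomes comparable to the voxel size. Rigid motion
preserves distances, so per-position error estimates transfer unchanged
into the LiDAR frame.

## Statistics

Welch's *t* (unequal variances, Welch–Satterthwaite df) and the two-sample
Kolmogorov–Smirnov *D* (sup of ECDF differences at pooled points) are
implemented from their formulas; the test suite cross-checks both against
scipy to 10⁻⁹ on random inputs. p-values are two-sided with no
multiple-testing correction; the corridor comparison reports per-group
summaries, within-group vegetation-vs-lamppost contrasts, and all pairwise
between-group tests for both metrics. Lamppost distance defaults to the
horizontal distance to the post's vertical axis (positions at lamp height
fly past the post, not its head); a 3D distance-to-lamp-head mode is
provided.

## Synthetic scenes: what they emulate and what they do not

The generator covers every input the pipeline consumes: trunk cylinders and
Gaussian foliage blobs sampled into deviation-tagged point clouds (a
configurable fraction of returns exceeds deviation 15 to exercise the
filter; reference-point markers are stamped in as 1 cm point clusters so
registration runs on measured, not oracle, correspondences), parameterised
flight paths (circling a trunk at a standoff, corridor commuting, smooth
random walk) sampled at the call rate, and 8-channel renderings in which
each call — a 5 ms linear-period FM downsweep, 100→45 kHz, Hann envelope,
pipistrelle-like — is evaluated in continuous time at each channel's sample
instants with the exact `‖x−m‖/c` delay and 1/r amplitude decay. Occlusion
is **hard and binary**: a channel receives nothing when a trunk intersects
the source→microphone segment; foliage does not occlude. Noise is white
Gaussian, set by an SNR referenced to a 10 m-range call.

Deliberately not modelled: echoes/reverberation, atmospheric absorption
(negligible ≤ 40 m at these frequencies), Doppler, microphone and call
directionality, feeding-buzz call-rate dynamics, and any soft attenuation
by foliage. Passing tests therefore demonstrate the *geometry and
statistics* of the method — exact forward models inverted correctly, error
estimates calibrated, shadows where line of sight is lost — not robustness
to reverberant, directional field recordings, where cross-correlation
mismatch between overlapping calls remains the dominant failure mode.

### Scenario problem sizes

The packaged demo scenarios are desk-scale by design: the corridor scenario
runs 16 s at 8 calls/s (128 calls, ~5 M samples per channel at 300 kHz)
with a ~10⁵-point cloud; the circling scenario 12 s at 10 calls/s. These
sizes give dense coverage of every geometric regime the scenarios exist to
probe while keeping a full pipeline run in tens of seconds. Monte-Carlo
ensembles use 100 sources (noiseless round trip), 500 trials (calibration)
and 200 trials per range bin (monotonicity), with seeds fixed in the tests.

## Degenerate inputs and tie-breaks

- Boundary voxel points go to the higher-index cell (half-open convention).
- A point cloud without a deviation attribute raises on `filter_deviation`
  rather than silently passing everything.
- Collinear or < 3 registration correspondences raise; a singular or
  ill-conditioned `JᵀJ` (cond > 10¹⁴) marks a position degenerate.
- `localise` called with all-zero TOADs converges to the least-bad point
  but is flagged invalid by the residual cap.
- Track chaining breaks ties by spatial proximity; equal-distance ties go
  to the earlier-opened track (stable iteration order).

## Known limitations

- The TOAD channel-quality gate (normalised correlation ≥ 0.35) is tuned
  for the synthetic SNR regime; field recordings with overlapping calls may
  need a per-deployment value.
- The error model is first-order; at ranges ≫ 10 apertures the linearised
  covariance understates the true (banana-shaped) uncertainty, which is
  one reason such positions are filtered out of fine-scale analyses.
- Corridor polygons are user-supplied XY vertex lists; no attempt is made
  to derive corridors from the vegetation automatically.
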