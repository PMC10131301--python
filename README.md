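# batrack

**3D acoustic tracking of echolocating bats, fused with terrestrial-LiDAR
vegetation structure.**

`batrack` is for bioacousticians and movement ecologists who want to know
*where* bats fly relative to fine-scale habitat structure — how close to the
vegetation edge, how far from a lamppost — rather than merely whether they
are present. It implements the full workflow:

1. **Acoustic localisation.** An overdetermined 8-microphone array (2 m
   aperture T-frame, top microphone as reference) records ultrasound at
   300 kHz / 16 bit. Echolocation calls are detected by band-limited energy,
   and the time-of-arrival-difference (TOAD) of each call between every
   microphone and the reference is estimated by cross-correlation with
   sub-sample (parabolic) refinement, using the convention
   `toad_i = t_i − t_ref`.
2. **Multilateration.** A source at **x** predicts
   `toad_i(x) = (‖x − m_i‖ − ‖x − m_ref‖)/c` under isotropic spherical
   spreading at the speed of sound `c` (default 343 m/s). The position
   estimate minimises `Σ_i (toad_i^obs − toad_i(x))²` by damped least
   squares from a deterministic multi-start grid. Four microphones suffice
   for a solution; the four extra channels make the array overdetermined so
   the residuals carry uncertainty information.
3. **Error assessment.** Linearised propagation at the solution: with
   Jacobian `J = ∂toad/∂x` and residual variance `s²`, the covariance is
   `C = s²(JᵀJ)⁻¹`, decomposed into a **radial** error (along the line from
   the array centre to the position) and a **tangential** error (in the
   perpendicular plane), plus the max-TOAD distance error
   `c·max_i|residual_i|`. Positions closer than 2 m to the array or with
   either error above 0.5 m are excluded; distant positions are kept.
4. **LiDAR fusion.** Terrestrial laser-scan point clouds are filtered by
   pulse deviation (> 15 removed), voxelised into 20 cm cubes, and voxels
   with ≥ 10 returns become *vegetation voxels*. The five array frame
   reference points (four ends + centre) surveyed in the cloud give a rigid
   rotation + translation (Kabsch fit, reflections excluded) that maps
   acoustic positions into the LiDAR frame.
5. **Analysis.** Per-position nearest-vegetation-voxel distance and
   lamppost distance, corridor assignment by polygon, and group comparisons
   with Welch's unequal-variance *t*-test and the two-sample
   Kolmogorov–Smirnov *D*.

A fully synthetic scene generator (trunk cylinders, foliage blobs,
lamppost, parameterised flight paths, exact propagation delays with hard
trunk occlusion) exercises every stage end to end with known ground truth —
including the acoustic shadows that trunks cast on the array.

## Worked example

```python
import numpy as np
from batrack import (build_default_array, theoretical_toads, localise,
                     assess_errors, ToadSet)

array = build_default_array()          # 8 mics, 2.0 m aperture
source = np.array([5.0, 3.0, 2.0])     # metres, array frame

toads = ToadSet(toads=theoretical_toads(source, array) + np.random.default_rng(0).normal(0, 2e-6, 7),
                peak_correlations=np.ones(7), detection_time=0.0)
pos = localise(toads, array)
assess_errors(pos, toads, array)
print(np.round(pos.xyz, 3), round(pos.radial_error, 3), round(pos.tangential_error, 3))
```

prints

```
[4.997 2.996 2.   ] 0.036 0.002
```

— the source at 6.2 m range is recovered within half a centimetre, and the
radial/tangential error estimates (3.6 cm / 0.2 cm) report the uncertainty
implied by the 2 µs TOAD noise, with the radial component dominating as
expected for a range-like observable.

The full pipeline on a synthetic forest-edge corridor:

```bash
batrack pipeline --out demo_run --seed 1
```

writes `positions.csv` (localised, filtered, LiDAR-frame positions with
per-position errors and track ids), `voxels.csv`, `distances.csv`,
`comparisons.json` (corridor Welch-t / KS statistics) and
`ground_truth.csv` for scoring.

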