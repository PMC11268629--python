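# tomogeom

Geometry-based annotation tools for cryo-electron tomography, as a headless
library and CLI. tomogeom turns sparse manual annotations — clicked points,
per-slice point strips, a few labelled slices — into the dense, ordered data
downstream processing needs:

* **Filament picking**: points along a filament → an arc-length
  parametrised spline → a helical lattice of particle poses (rise ρ, twist
  τ, radius r, Cn symmetry), each oriented with its local Z along the
  filament axis.
* **Surface picking**: point strips on a few z-slices → a rectangular
  spline-grid of equidistant surface points with full orientation frames
  (local Z = surface normal), particle poses, and a display mesh.
* **Volume straightening**: resample a tomogram along the annotated surface
  normals into a regular box where the curved membrane is flat and central.
* **Label interpolation**: densify a segmentation annotated on a few slices
  by per-label signed-distance-field averaging.
* **I/O**: Relion STAR (≥ 3.0), Dynamo TBL, EMAN BOX / CrYOLO CBOX,
  MRC2014, TIFF and EM, with format guessing and experiment-id grouping, all
  converting through one validated pose container.
* **Image ops**: arbitrary-kernel convolution with texture-style clamped
  borders, separable Gaussian and radial bandpass filters, power spectra.

The core geometric primitives are a B-spline with a dense arc-length map —
so samples are equidistant in Euclidean space, not in parameter — and a
rotation-minimising (parallel-transport) moving frame, which gives
twist-free orientations along arbitrary smooth curves. Helical poses compose
the transported frame with `Rz(j·τ)` and shift by r along the resulting
local X; surface orientations come from the cross product of two
spline-family tangents at every grid node. See `docs/methods.md` for the
full account.

## Worked example

Pick a helical filament from five clicked points and write Relion particles:

```sh
python - <<'EOF'
import numpy as np
np.savetxt("picks.csv", [[32,32,10],[32,32,20],[32,32,30],[32,32,40],[32,32,50]],
           delimiter=",")
EOF
tomogeom filament-pick --points picks.csv --rise 5 --twist 30 --radius 8 \
    --sym 2 --out particles.star
python - <<'EOF'
from tomogeom.io_formats import read_star
(ps,) = read_star("particles.star")
print(len(ps), "poses")
print(ps.positions[:3].round(3))
EOF
```

prints

```
18 poses
[[40.    32.    10.   ]
 [24.    32.    10.   ]
 [38.928 36.    15.   ]]
```

— 9 axial subunits (40 voxels of filament at rise 5) × 2 symmetry copies;
the first two poses are the C2 pair of subunit 0 at radius 8 from the axis
(x = 32 ± 8), and the third is subunit 1, advanced 5 voxels in z and rotated
30° in azimuth. Each STAR row carries the pose's ZYZ Euler angles so the
lattice can seed subtomogram averaging directly.

Surface picking and straightening work the same way from a CSV of strip
picks (`x,y,z[,strip]`):

```sh
tomogeom surface-pick --points strips.csv --spacing 4 --out surf.star --mesh surf.obj
tomogeom resample --volume tomo.mrc --points strips.csv --spacing 4 \
    --thickness 10 --step 1 --out straightened.mrc --project projected.tif
```

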