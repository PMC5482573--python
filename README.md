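# tomocoat

Subtomogram averaging, multireference classification and difference-density
analysis for coated-vesicle cryo-electron tomography — with a synthetic
scene generator so the whole chain is testable end to end against known
ground truth.

## Who this is for

Structural biologists and methods developers who want a compact, fully
inspectable implementation of the classical vesicle-coat processing
pipeline: missing-wedge-aware constrained-correlation alignment,
wedge-compensated averaging with Cn symmetry, gold-standard FSC validation,
B-factor sharpening, and the classification/difference-mapping procedure
used to localize a substoichiometric binder (an ArfGAP on a COPI-type coat
being the motivating case). Everything runs on a laptop because the data are
simulated: Gaussian-blob "leaf" phantoms arranged as C3 triads on spherical
vesicles, projected into dose-symmetric ±60° tilt series with CTF and
exposure filtering, and reconstructed by weighted back-projection.

## The core quantities

* **Constrained cross-correlation** between volumes `a`, `b` with missing
  wedges `W_a`, `W_b`:
  `CC = Re Σ_k A(k) B*(k) / (‖A‖‖B‖)` over `k ∈ W_a ∩ W_b ∩ band`,
  so a particle is never scored on frequencies it does not contain.
* **Wedge-compensated average**: `Σ_i F(R_i^{-1} x_i) / max(Σ_i R_i^{-1} w_i, floor)`.
* **Gold-standard FSC** between half maps refined from disjoint
  odd/even-vesicle half-sets; resolution read at FSC = 0.143 (and 0.5) with
  linear interpolation between one-voxel shells.
* **B-factor sharpening**: amplitudes × `exp(−B k²/4)`, `B < 0` restores
  high-resolution contrast.
* **Difference density**: `EM − s·model` with `s` the least-squares
  amplitude scale; suprathreshold connected components ranked by voxel
  volume.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
import numpy as np
from tomocoat.core import WedgeSpec
from tomocoat.synthetic_scene import default_leaf_spec, build_leaf_phantom, simulate_leaf_stack
from tomocoat.alignment import average_particles
from tomocoat.particles import pose_from_row
from tomocoat.refine import fsc, resolution_at

spec = default_leaf_spec()                      # 32^3 voxels at 4 A/voxel
leaf = build_leaf_phantom(spec)
wedge = WedgeSpec(-60, 60)

def half_map(n, seed):
    subs, wedges, truth = simulate_leaf_stack(leaf, n, wedge, snr=0.5, seed=seed)
    poses = [pose_from_row(r) for _, r in truth.iterrows()]
    return average_particles(subs, poses, wedges)

curve = fsc(half_map(100, 1), half_map(100, 2))
res, crossed = resolution_at(curve, 0.143)
print(f"FSC 0.143 resolution: {res:.2f} A (crossed={crossed})")
```

Output:

```
FSC 0.143 resolution: 14.41 A (crossed=True)
```

Two independent 100-particle half-averages of the noisy (SNR 0.5),
wedge-filtered leaf stack agree to ~14 Å on the 4 Å grid; with only 10
particles per half the same readout degrades to ~16 Å — the
particle-number scaling that the gold-standard FSC is supposed to show.

The full pipeline (simulate → reconstruct → pick → align two independent
half-sets → clean/dedup → FSC → sharpen) runs from a TOML config or the
CLI:

```
tomocoat run-all --seed 1 --output runs/demo
tomocoat simulate --seed 2 --output runs/sim
tomocoat validate runs/demo/half1_reference.mrc runs/demo/half2_reference.mrc --output fsc.tsv
```

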