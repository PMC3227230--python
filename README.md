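# cardioshape

Statistical 3D shape modeling and exact B-spline volumetry of ventricle-like
surfaces.

Quantitative assessment of cardiac function hinges on ventricular volumes:
end-diastolic and end-systolic volume, stroke volume, and the ejection
fraction EF = (EDV − ESV)/EDV that cardiologists read as an index of pump
function. `cardioshape` implements the full model-based pipeline that turns a
population of corresponded 3D landmark sets into those numbers:

1. **Point-distribution model.** Training shapes, each a vector
   `x = (x₁, y₁, z₁, …, xₙ, yₙ, zₙ)ᵀ` of corresponded landmarks, are brought
   into a common frame by generalized Procrustes analysis — similarity
   transforms `Tᵢ` minimizing `G = Σᵢ |m − Tᵢ(xᵢ)|²` against the evolving
   unit-norm mean `m`. PCA of the aligned cloud yields the linear generative
   model `x = x̄ + Φb`, where the columns of `Φ` are the principal modes and
   the variance of `bⱼ` is the eigenvalue `λⱼ`.
2. **GA meanshape (optional).** Instead of seeding the model with the first
   training shape, a real-coded genetic algorithm can construct the initial
   meanshape three ways: searching the shape parameters `b`, searching the
   full coordinate vector, or optimizing each landmark separately with
   per-shape weights. Each objective has a closed-form optimum that the GA
   population is seeded with, so the GA never does worse than the trivial
   estimator.
3. **B-spline surfaces.** Landmark grids become tensor-product B-spline
   surfaces: each knot span evaluates in matrix form `S(t,w) = T M V Mᵀ Wᵀ`,
   i.e. as an explicit polynomial patch `Σ B(r,l) tʳ wˡ`.
4. **Exact volumetry.** Because every patch is a polynomial, the enclosed
   volume is a closed-form surface integral: the flux of `F = (0, y, 0)`
   through the surface, integrated per patch by the
   `Σ C(l₁,l₂) / ((l₁+1)(l₂+1))` rule — no quadrature error on polynomial
   geometry. Simpson slice integration and Monte-Carlo rejection sampling are
   provided as independent cross-checks.
5. **Model-to-image fitting.** An active-shape-model loop matches the model
   to a 3D image volume by minimizing `f = |X − T(x̄ + Φb)|²`: search along
   each landmark's normal for the best Mahalanobis match to trained gradient
   profiles, then update pose `T` and shape `b` in closed form; repeat to
   convergence.
6. **Cycle analysis.** Per-phase endocardial/epicardial volumes over a
   cardiac cycle give EF, stroke volume, and myocardial volume.

No clinical data are required anywhere: the `synthetic` module generates
corresponded truncated-ellipsoid ventricle phantoms with planted deformation
modes, rendered three-class image volumes, and cardiac cycles with a
prescribed ejection fraction — all with closed-form ground truth.

## Worked example

```python
import numpy as np
from cardioshape import (PhantomSpec, make_training_set, align_shapes, build_model,
                         make_cardiac_cycle, fit_surface_to_landmark_grid,
                         cycle_volumes, exact_volume, unit_cube_surface)

# sanity anchor: polynomial integration is exact on polynomial geometry
exact_volume(unit_cube_surface()).volume     # -> 1.0

# train a point-distribution model on 100 synthetic ventricle grids
spec = PhantomSpec(seed=1)
ts = make_training_set(spec, n_shapes=100, seed=1)
alignment = align_shapes(ts.shapes)
model = build_model(alignment, 10)
model.eigenvalues[:4] * ts.template_scale**2
# -> [3.694 0.763 0.196 0.   ]   (planted variances: 4, 1, 0.25 mm^2)

# synthetic cardiac cycle with prescribed EF = 0.5, measured end to end
seq = make_cardiac_cycle(spec, n_phases=4, ef_target=0.5)
surfaces = [(fit_surface_to_landmark_grid(e), fit_surface_to_landmark_grid(p))
            for _, e, p in seq]
res = cycle_volumes(surfaces, [t for t, _, _ in seq])
print(res.table.round(1))
#    time_ms  endo_volume  epi_volume  myocardial_volume
# 0      0.0     103741.9    260190.5           156448.6
# 1    250.0      75581.5    208603.3           133021.7
# 2    500.0      51871.0    162710.1           110839.1
# 3    750.0      75581.5    208603.3           133021.7
res.ejection_fraction, res.stroke_volume / 1000.0
# -> (0.5, 51.87)               # EF recovered exactly; stroke volume in mL
```

The eigenvalues recover the three planted mode variances (the fourth is
numerically zero); the cycle table shows volumes in mm³ at end-diastole
(t = 0), mid-contraction, and end-systole (t = 500 ms), and the derived EF
matches the prescribed 0.5.

The same pipeline is scriptable from the shell:

```sh
cardioshape --seed 4 simulate --out sim --n-shapes 12 --n-images 4
cardioshape train --manifest sim/manifest.txt --out model.npz \
    --images-manifest sim/images_manifest.txt --profiles-out profiles.npz
cardioshape fit --model model.npz --profiles profiles.npz \
    --image sim/image_003.nii --out-prefix fit/case
cardioshape volume --surface fit/case.surface.npz --method exact
cardioshape cycle --phases 4 --ef 0.5 --out cycle.csv
```

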