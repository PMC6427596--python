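# phenocloud

Point-cloud phenotyping of single maize plants. Given an unstructured 3D
scan of a juvenile plant (trefoil to jointing stage, coordinates in mm),
`phenocloud` simplifies the cloud with a curvature-adaptive grid, denoises
the feature-rich regions with a point-cloud bilateral filter, and extracts
three agronomic traits — **plant height**, **stem diameter** and **canopy
breadth** — by fitting geometric primitives. A seedable synthetic plant
generator with analytically known traits makes every stage verifiable
without scanner data.

Intended users: plant-phenotyping and agricultural-robotics researchers who
work with hand-held laser scans of individual plants and want a
reproducible, scriptable alternative to manual ruler measurements.

## Method

For every point *p*ᵢ the local covariance (scatter) matrix of its
neighborhood (the point plus its *k* nearest neighbors) is
eigendecomposed, C = Σ (p − p̄)(p − p̄)ᵀ, with eigenvalues
λ₀ ≤ λ₁ ≤ λ₂. The eigenvector of λ₀ is the surface normal and

σ = λ₀ / (λ₀ + λ₁ + λ₂) ∈ [0, ⅓]

is the *surface variation*, a curvature surrogate (0 on planes, ⅓ for an
isotropic blob).

**Simplification.** The cloud is binned into a grid of base cell size
D = γ·(X·Y·Z/N)^⅓ from the bounding-box volume per point. A cell whose
mean σ exceeds the cloud-wide mean is a *detail* cell; detail and
non-detail cells are re-binned at β_d·D and β_nd·D (β_d < β_nd) and one
original point — the member nearest its sub-cell's member centroid —
survives per sub-cell. The simplification rate is
(P − P_kept)/P × 100%.

**Denoising.** Points with σ below the cloud mean form the *single*
(flat) region and are left untouched; the rest form the *rich* region and
move along their own normals by the bilateral displacement

α = Σᵢ w₁(xᵢ) w₂(yᵢ) yᵢ / Σᵢ w₁(xᵢ) w₂(yᵢ),  p′ = p + α·n,

with xᵢ = ‖p − pᵢ‖, yᵢ = ⟨pᵢ − p, n⟩ and Gaussian kernels w₁, w₂ whose
scales are the maximum neighbor distance (σ₁) and the standard deviation
of the projections (σ₂), recomputed per point. A classical Laplacian
umbrella-operator smoother is included as the comparison baseline, along
with max/mean displacement metrics.

**Traits.** Plant height is the radius of a sphere centred on the canopy
apex and passing through the base point beneath it; canopy breadth is the
radius of a sphere centred on the leftmost canopy point reaching the
farthest point at that height; stem diameter is twice the radius of a
least-squares cylinder (algebraic initialization, trust-region geometric
refinement of Σ(dᵢ − r)²) fitted to the third-internode slab of the stem.

## Worked example

```python
from phenocloud import (PlantSpec, generate_plant, PipelineConfig,
                        run_pipeline)

cloud, truth = generate_plant(PlantSpec(seed=7, outlier_fraction=0.0))
cfg = PipelineConfig(stem_window=tuple(truth.third_internode_window))
report = run_pipeline(cloud, cfg)
print(report["stages"]["simplify"])
print({k: round(v, 1) for k, v in report["traits"].items()
       if isinstance(v, float)})
```

prints

```
{'n_raw': 12640, 'n_kept': 9955, 'rate_percent': 21.2,
 'n_detail_cells': 4321, 'n_nondetail_cells': 8145}
{'plant_height_mm': 400.8, 'stem_diameter_mm': 13.9,
 'canopy_breadth_mm': 539.3}
```

The synthetic 3-leaf plant has a true height of 400 mm, stem diameter of
14 mm and canopy breadth of 540.1 mm: after removing 21.2% of the points
and denoising, the pipeline recovers all three traits within a fraction of
a percent. The same chain is available from the shell:

```sh
phenocloud simulate --seed 7 -o plant.ply --truth truth.json
phenocloud pipeline plant.ply --report report.json
```

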