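# Methods

This note documents the models and numerical choices behind `phenocloud`,
the defaults that matter, what the synthetic generator does and does not
emulate, and the package's known limitations.

## Local surface model

All stages share one local model: for each point, the unnormalized scatter
matrix of its neighborhood (the point itself plus its k nearest Euclidean
neighbors) is eigendecomposed. The smallest-eigenvalue eigenvector is the
surface normal; the surface variation σ = λ₀/(λ₀+λ₁+λ₂) is the curvature
surrogate. σ is scale-free, so the missing normalization of the scatter
matrix is immaterial, and it is invariant under rigid motion. When the
eigenvalue sum vanishes (all neighborhood points coincident) the point is
flagged degenerate, gets σ = 0 and a +z normal.

Normal signs from an eigensolver are arbitrary; for determinism they are
oriented away from the cloud centroid, with +z breaking exact ties. This
outward heuristic is adequate for a single plant scanned from outside; it
is not a globally consistent orientation (no minimum-spanning-tree
propagation), which the displacement formulas tolerate because both the
projection y and the step α·n flip sign together under n → −n.

**k (neighbor count), default 15.** Small enough to stay local on the
sparsest 3-leaf clouds (~1.8 mm spacing), large enough for a stable 3×3
covariance. Exact k-NN is used throughout (brute force below 4096 points,
k-d tree above); ties are broken toward the lower point id so runs are
reproducible point-for-point.

## Simplification

Base cell size D = γ·(Xbox·Ybox·Zbox/N)^⅓, the cube root of bounding-box
volume per point. Cells are half-open, indexed from the cloud minimum, and
points on the global maximum face are clamped into the last cell; a
zero-thickness extent (perfectly flat cloud) is inflated to the 0.178 mm
scanner resolution floor before the volume is formed, with a warning.

A cell is *detail* iff its members' mean σ strictly exceeds the cloud-wide
mean σ (with a 1e-9 relative tolerance so a uniform-curvature cloud — all
cells tied at the threshold — classifies as all non-detail rather than
splitting on float summation order). Each label class is then re-binned on
a global grid of size β·D (β_detail = 1.0, β_nondetail = 2.0 by default)
and exactly one member survives per occupied sub-cell: the member nearest
the sub-cell's member centroid, ties to the lower id. Survivors are
original scan points — coordinates are never averaged — so ids, normals
and downstream traits remain meaningful.

**γ, default 0.1.** The volumetric formula measures volume per point, but
a plant cloud samples a 2-D surface inside a mostly empty box, so D at
γ = 1 is roughly an order of magnitude larger than the inter-point spacing
and nearly every point would be removed (~98%). γ = 0.1 brings D to
~1–2× the surface spacing, yielding 14–33% removal (mean ≈ 23%) across
the benchmark sizes — the regime the method is meant to operate in, where
simplification trims redundancy without erasing shape. The reported rate
is (P − P_kept)/P·100, the removal percentage relative to the raw count.

## Denoising

Region division marks a point *single* when σ < mean σ (strict) and *rich*
otherwise; only rich points move. Each rich point moves along its own
normal by the bilateral displacement α (see README for the formula), with
per-point kernel scales σ₁ = max neighbor distance and σ₂ = sample
standard deviation (ddof = 1) of the neighbor projections, floored at
1e-6 mm so an exactly planar neighborhood (zero projection spread) keeps a
defined range kernel and the plane remains a fixed point.

Numerics: the two Gaussian kernels are evaluated in the log domain and
normalized per point so the largest weight is exactly 1 — the ratio
defining α is unchanged, but a far-outlying point whose raw weights would
underflow to 0/0 still gets the correct limit (a single-neighbor point
moves exactly onto its neighbor's tangent projection). Within one pass all
displacements use the pass's input positions (Jacobi update) for
determinism; between passes (iterations, default 1) the neighbor graph,
normals and region labels are refreshed.

The Laplacian baseline is the umbrella operator with the self-inclusive
neighborhood average, p′ = p + λ·(mean({p} ∪ neighbors) − p), λ = 0.5 by
default, applied to every point. Self-inclusion keeps the full step λ = 1
contractive (two mutual neighbors meet at their midpoint rather than
swapping). The baseline runs on all points, matching its classical form;
displacement metrics (max and mean per-point movement, shared ids
required) quantify both filters. On a noisy crease the bilateral filter
retains a markedly higher maximum σ than the Laplacian at its smaller
smoothing step — the edge-preservation property the range kernel buys.

Note the bilateral filter is an exact no-op only on planes: on a curved
noise-free surface the neighbors sit systematically below the tangent
plane, so points drift slightly (≈0.04 mm mean on a clean synthetic
plant). This is inherent to normal-projection bilateral filtering, not a
defect of the implementation.

## Traits

The vertical axis defaults to y and the breadth axis to x (the scanner
convention); both are configurable.

**Plant height** is the Euclidean distance from the apex (the point at the
`apex_quantile` of the vertical coordinate, default 1.0 = the literal
maximum) to the base point: the lowest point within `search_radius`
(default 30 mm) of the apex's vertical line, falling back to the global
minimum when that cylinder is empty. The literal vertical line under the
apex almost never contains a sample, hence the cylinder search. Quantiles
slightly below 1 reject spike outliers at the cost of a small negative
bias.

**Stem diameter** is twice the radius of a least-squares cylinder fitted
to the points inside a vertical window. The window for the third internode
is an explicit input — a point cloud alone does not identify internodes —
with a [0.2 H, 0.35 H] heuristic default that is only a stand-in. Leaves
can cross the window heights, and on leaf-heavy plants they can dominate
the slab, so the stem's center line is anchored on the base band (the
lowest 8% of the height range, which is leaf-free on a rooted plant): slab
points farther than `r_gate_factor` (default 3) × the base band's median
radial distance from that line are discarded before the fit. Gating on
the slab's own centroid — the more obvious choice — fails outright when a
leaf crosses the window (the fitted radius ran to meters in testing).

**Canopy breadth** is the distance from the leftmost point (minimal
breadth-axis coordinate) to the farthest point whose height is within
`height_tolerance` (default 10 mm) of the leftmost point's, falling back
to the plain breadth-axis extent (with a warning) when no second point
shares that height band. Because the trait anchors on a fixed scanner
axis, it is translation-invariant but *not* rotation-invariant: rotating
the plant changes which point is leftmost. Height and stem diameter are
invariant under rotation about the vertical axis.

**Primitive fits.** The sphere fit seeds a trust-region refinement of the
geometric residual ‖c − Pᵢ‖ − r with the linear algebraic solve of
‖P‖² = 2c·P + (r² − c·c); rank deficiency of that system (coplanar input)
raises a degeneracy error. The cylinder minimizes Σ(dᵢ − r)² over axis
point, axis direction (normalized inside the residual) and radius, seeded
by the centroid, principal scatter axis and mean radial distance;
`scipy.optimize.least_squares(method="trf")` with 1e-15 tolerances is used
because the Levenberg–Marquardt backend stalls on the gauge-degenerate
parametrization (the axis point is free to slide along the axis; it is
reported projected onto the centroid-normal plane). Exact data are
recovered to ~1e-8 mm; the iterative radius is reproducible across rigid
motions to ~1e-5 mm, i.e. optimizer precision rather than bit-exactness.

## Synthetic plants

The generator emulates a hand-held-scanner cloud of a juvenile maize
plant: a vertical stem cylinder (half-azimuth sampling by default, as a
one-sided scan sees it), 3–8 ruled leaf blades on constant-curvature
midribs that rise then arch outward with elliptic width taper, isotropic
Gaussian surface noise (default 0.3 mm, matching the sub-millimetre
scanner regime) and a sparse fraction of bounding-box outliers (default
0.5%). Point counts scale with surface area / spacing²; the default
1.8 mm spacing gives ~12,600 points for the default 3-leaf plant and
40–60 k for large 8-leaf plants, matching the scanner's reported range.
Blades diverge from the stem one internode above their node (the sheath
wraps the stem below the ligule), and any blade that could not clear the
radial gate by the bottom of the third internode is pushed above the
window top, so the measured internode contains only stem points — as it
does on a real plant, where the sheath hugging the stem *is* part of the
measured cylinder.

Ground truth: plant height = stem height and stem diameter = 2 × stem
radius are analytic; canopy breadth has no closed form under the
extreme-point definition and is computed from the noise-free, outlier-free
sampled surface with the same rule the trait uses. The benchmark suite
draws heights 250–900 mm, stem radii 4–12 mm and leaf sizes proportional
to height, cycling 3→8 leaves across seeds. Generation is a pure function
of the spec (including its seed).

What the generator does **not** emulate: self-occlusion and scan shadows,
registration artefacts from multiple sweeps, leaf twist and rippled
margins, the collar/ligule geometry, soil or pot returns, and
non-Gaussian (streaky) scanner noise. Passing the recovery tests therefore
demonstrates correctness of the geometry pipeline under the stated noise
model, not field-readiness on arbitrary real scans.

Problem sizes in the test suite and acceptance script (6–20 plants of
10–60 k points, 4 k-point denoising fixtures) were chosen to exercise the
full pipeline at realistic scan sizes while keeping a complete run in the
minutes range on one core.

## Known limitations

- No automatic internode detection: the stem window is the user's
  responsibility; the default heuristic band is not the third internode.
- The outward normal-orientation heuristic can flip on deeply concave
  geometry (not present in juvenile maize at this scale).
- Canopy breadth depends on the scanner's axis convention (by
  definition); report it together with the breadth axis used.
- Simplification rates depend on γ through the volumetric cell-size
  formula; clouds with very different bounding-box occupancy may need γ
  adjusted to stay in the ~25% regime.
- The literal apex (quantile 1.0) is outlier-sensitive; with outliers
  present use a quantile slightly below 1 or denoise first.
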