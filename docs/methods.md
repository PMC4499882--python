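# Methods

`geltrax` quantifies how collectively migrating epithelial cohorts deform
and remodel the collagen gel around them. It implements four analysis
stages — matrix kinematics from bead tracking, traction reconstruction by
a direct elastic boundary-value solve, collagen fibril orientation
statistics, and cohort-dynamics/directionality statistics — together with
a synthetic-data module that generates every input with known ground
truth. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic validations do and do not show.

## Matrix kinematics

Fiducial beads (1-um polystyrene spheres seeded at ~4x10^8 beads/ml, i.e.
4e-4 beads/um^3) are tracked in 3D; tracking itself is out of scope and
trajectories enter as a CSV table. Subtracting each bead's position in a
force-free reference state — experimentally obtained by lysing the tissue,
synthetically by a zero-amplitude frame — gives a scattered displacement
field u at the reference bead positions.

The field is interpolated mesh-free with radial basis functions
(thin-plate spline by default, per displacement component, `neighbors=128`
for scalability; a Gaussian kernel with a length scale is available). The
default length scale is the mean nearest-neighbour bead spacing (~14 um at
the study density), which also sets the radius beyond which queries are
flagged as extrapolation. The displacement gradient is obtained by central
differences of the interpolant with step h = 1 um; this is exact for
affine fields and robust to irregular bead placement, unlike per-bead
tetrahedral triads.

Both strain measures are reported: the finite Green-Lagrange strain
E = 1/2(grad u + grad u^T + grad u^T grad u), which vanishes identically
for rigid motions, and the infinitesimal strain eps = sym(grad u) that
Hooke's law uses. The workflow being reproduced mixes a finite-strain
kinematic measure with linear elasticity; we expose both and use the small
strain consistently inside the solver. At the deformation magnitudes of
interest (|grad u| of a few percent) the two differ at second order.

## Traction reconstruction

The gel is modelled as an isotropic Hookean solid, T = 2 mu eps +
lam tr(eps) I, with nu = 0.2 and a configurable Young's modulus
(default E = 500 Pa — a placeholder typical of a few-mg/ml collagen gel;
the source workflow never reports its measured modulus, so absolute
traction magnitudes scale with E and only spatial patterns are meaningful).
Static equilibrium div T = 0 is solved with displacement boundary
conditions: the interpolated bead field on the tissue-matrix interface and
zero displacement on the outer gel boundary (a cylinder 2 mm in height and
diameter by default; spherical and box-shaped gels are available and used
in tests to keep solves small).

Meshing is by radial extrusion: each vertex of the triangulated tissue
surface defines a ray from the centroid; nodes are laid out along the ray
with geometric grading (refinement concentrated at the interface) and each
surface triangle sweeps out a stack of prisms split into tetrahedra with a
globally consistent smallest-index diagonal rule. This requires the
surface to be star-shaped about its centroid, which holds for the
idealised geometries used here (spheres; watertight STL/PLY surfaces are
accepted under the same restriction). Elements are quadratic (10-node)
tetrahedra by default; for spherical tissues the interface edge midpoints
are projected onto the exact sphere, giving curved isoparametric elements.

Assembly uses a 4-point degree-2 Gauss rule and the solve is a sparse
direct factorisation. On the strongly graded, anisotropic meshes produced
by radial extrusion, ILU-preconditioned conjugate gradients stagnates, so
no iterative option is exposed. Cauchy stress is evaluated per element;
nodal stress is recovered by evaluating each adjacent element's stress at
the node itself and volume-averaging. (Averaging element-centroid values
instead biases the interface stress low by ~25% on coarse meshes, because
the cavity stress decays as r^-3 across the first element layer.)
Tractions follow as t_i = T_ij n_j with n the outward unit interface
normal, pointing from tissue into gel.

Sign convention, fixed once and used everywhere: a tensile load (p > 0)
pulls the matrix toward the tissue; beads move inward, the gel is
stretched radially, and the normal traction t.n at the interface is
positive. "Tensile fraction" in the localisation summary counts nodes
with t.n > 0.

Verification rests on two closed forms: the Lame pressurised-cavity
solution u_r = p a^3/(4 mu r^2) (for which the finite outer boundary at
radius R perturbs the field only at order (a/R)^3) and the Kelvin
point-force solution u_i = F_j/(16 pi mu (1-nu) r)[(3-4nu) delta_ij +
r_i r_j / r^2]. The solver reproduces the cavity displacement field to
~1-3% in relative L2 over r <= 4a at the mesh sizes used in the tests
(icosphere subdivision 2, 8 radial layers, ~33k dofs), with monotone
convergence under simultaneous angular/radial refinement, and satisfies
the classical patch test exactly on straight-edged elements (on curved
isoparametric elements quadrature leaves a ~1e-5 relative residual, which
is expected and immaterial).

## Collagen fibril orientation

Fibril alignment is measured from reflection-style images via the
structure tensor: Gaussian-derivative gradients (scale 2 px, which
suppresses the pixel-grid orientation bias of small difference stencils),
outer products accumulated per subregion, dominant eigenvector taken, and
the fibre axis defined as the gradient orientation rotated by 90 deg. A
30x30 subregion grid gives 900 measurement locations per analysed crop.
Subregions with structure-tensor coherence below 0.2 (featureless or
isotropic-mixture regions) are dropped.

Within each subregion the tensor is accumulated over a centred window of
half the grid stride (default: 12 px window in a 24 px cell). The guard
margin keeps any single fibril — and the derivative kernel's support —
from contributing to two neighbouring subregions, so the per-subregion
angles behave as independent samples. This matters because uniformity is
assessed with the Rayleigh test, whose calibration assumes independence:
without the margin the type-I error at nominal alpha = 0.05 was measured
at 8-24% on isotropic synthetic images, with it 5.2% over 400 nulls (and
the mean null resultant length matches the sqrt(pi/4n) prediction for
independent samples).

Fibres are orientations, not directions, so all statistics use doubled
angles: the alignment index R is the resultant length of 2*theta, the
circular mean is halved back into [0, 180), and the deviation from a
reference direction (e.g. the migration direction) is folded into
[0, 90] deg. Region contrasts (matrix at the invasive front vs far from
the tissue) use a label-shuffling permutation test on the difference in R
(10,000 permutations by default, seeded), since no parametric test for a
difference in axial concentration is standard.

## Cohort dynamics and correlation

Cohort length is measured from the edge of the original tissue to the
cohort tip (straight-line by default; a geodesic option measures along
the mask for bent cohorts), and projected area is the pixel count scaled
by the pixel size. Beads are classed "near" (< 50 um) or "far" (> 50 um)
by minimum distance to the cohort; exact ties go to "far" because the
classes are strict inequalities.

The lagged sample cross-covariance uses the biased estimator
c_xy(k) = (1/n) sum_t (x_t - xbar)(y_{t+k} - ybar), with full-series
means, and r_xy(k) = c_xy(k)/(s_x s_y) with ddof-1 standard deviations
(so r_xx(0) = (n-1)/n; an unbiased 1/(n-|k|) variant and ddof-0
normalisation are config options). A positive peak lag means the bead
series trails the cohort. The peak is the signed maximum of r: coupling
between cohort extension and nearby matrix displacement is physically
positive, and taking max |r| would let half-period anticorrelations of a
periodic fluctuation masquerade as the peak.

The near/far report first-differences both series by default before
correlating — the quantity of interest is the temporal change in cohort
length. With raw series, a shared monotone growth trend dominates the
biased estimator: dropping the k largest end-products penalises every
nonzero lag and pins the peak at zero regardless of the true coupling
lag. Differencing removes the trend and leaves the lag-carrying
fluctuation. Class comparison uses Welch's t-test on per-bead peak r.

Directionality across replicate tissues uses binarised masks registered
to a common initial geometry: the frequency map is the exact per-pixel
fraction of masks occupied, and invasion angles are one angle per
connected component outside the base geometry (direction from the tissue
centroid to the component's farthest pixel; 0 deg = east, CCW, y up).
Invasion angles are directions, not axes, so plain circular statistics
and the standard Rayleigh test apply.

## Synthetic-data generator

The generator reproduces the statistical structure of each input at the
study's stated conditions:

- **Bead clouds**: homogeneous Poisson process at 4e-4 beads/um^3;
  positions displaced by the closed-form cavity or Kelvin field with a
  per-frame amplitude schedule whose first entry must be 0 (the force-free
  reference); isotropic Gaussian tracking noise, default sigma = 0.1 um
  (sub-pixel accuracy for 1-um beads), applied to every frame including
  the reference — so a measured displacement carries noise variance
  2 sigma^2 per coordinate.
- **Fibril images**: anti-aliased line segments with axial angles from a
  doubled-angle von Mises law (kappa = 0 isotropic), Gaussian blur and
  additive noise. Defaults (720 px image, 10 px fibres, 6000 fibres)
  pair with the 24 px analysis grid so one fibre occupies about one
  subregion; see the calibration rationale above.
- **Coupled series**: length(t) = baseline + growth*t + A sin(2 pi t/P)
  sampled every 2 h for 40 h; near-bead series are gain-scaled copies
  shifted by an integer lag plus noise; far beads are independent noise
  of the same marginal variance. P defaults to 16 h because a periodic
  fluctuation aliases lags separated by a full period: recoverable lags
  must stay well inside half a period (8 samples), which a 12-h period
  would not allow for the lags of interest. The default noise sets an
  SNR of 5 against the RMS of the fluctuation component — the trend
  carries no lag information, so scaling noise to total signal variance
  would conflate trend magnitude with coupling detectability.
- **Mask stacks**: a shared base disk plus finger-like protrusions at
  angles drawn uniformly or from a von Mises law, stamped with a round
  brush from the base boundary outward.

What the synthetic data does **not** emulate: nonlinear, viscoelastic or
fibrous matrix mechanics (displacements follow linear closed forms);
bead-tracking failures (identities are perfect, noise is isotropic
Gaussian); photorealistic speckle or depth-dependent attenuation in
fibril images; cell biology (protrusions appear instantaneously with
fixed shape). Passing tests therefore demonstrate that the estimators
recover known ground truth under the stated noise models — not that the
pipeline is robust to tracking artefacts or to constitutive
model mismatch in real gels.

## Problem sizes and numerical defaults

Test and acceptance runs use scaled-down domains chosen so each stage
still operates at the study's stated sampling conditions: bead scenes are
300-um boxes (~10,700 beads at the study density) around a 50-um
spherical tissue in a 400-um spherical gel, meshed at icosphere
subdivision 2 with 8 geometrically graded layers (~33k dofs); statistical
criteria use 100-400 Monte-Carlo replicates. Key tolerances: interpolant
exactness at samples 1e-8; rigid-motion strain 1e-12; ccf vs brute force
1e-12; FEM patch test 1e-8; determinism is byte-exact (JSON with sorted
keys, no timestamps in manifests or image metadata).

## Known limitations

- The mesh generator requires star-shaped surfaces; real branched tissue
  reconstructions generally are not, and would need an external mesher.
- Traction magnitudes are meaningful only relative to the assumed E.
- The direct Dirichlet solve transmits interpolation error in the bead
  field straight into the tractions (no regularisation); at the study
  bead density this contributes most of the ~8% end-to-end error in the
  cavity benchmark.
- The geodesic cohort-length option measures along pixel connectivity
  and differs from the Euclidean measure by up to ~1 px even for
  straight cohorts.
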