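# Methods

This note documents the models, conventions, numerical choices, and
limitations behind `cortiq`. It is the companion to the API
documentation: everything here is implemented and exercised by the test
suite, and nothing here states a result that the tests or
`scripts/acceptance.py` do not themselves compute.

## 1. Signal model and b-tensor algebra

### Forward model

A voxel is modelled as a discrete **diffusion tensor distribution**
(DTD): microscopic Gaussian environments with diffusion tensors
`D_i` (µm²/ms) and fractions `f_i`. Under tensor-valued encoding with
b-tensor `B` (ms/µm²) the noise-free magnitude signal is

    S(B) = S0 · Σ_i f_i · exp(−⟨B, D_i⟩),

with `⟨A, B⟩` the Frobenius inner product. This is the ground-truth
generator; it is exact for Gaussian compartments without exchange or
time dependence.

### Cumulant (QTI) model

The second-order cumulant expansion of `ln S` in `B` is

    ln S(B) = ln S0 − ⟨B, ⟨D⟩⟩ + ½ ⟨B⊗B, C⟩,

where `⟨D⟩ = Σ f_i D_i` (6 unique elements) and
`C = Σ f_i D_i⊗D_i − ⟨D⟩⊗⟨D⟩` (21 unique elements) is the fourth-order
covariance of the DTD. Per voxel the model therefore has 28 parameters.

### Voigt convention

Symmetric 3×3 tensors are stored as 6-vectors
`(xx, yy, zz, √2·xy, √2·xz, √2·yz)`; symmetric 6×6 (Voigt-basis)
fourth-order tensors as 21-vectors (6 diagonal entries, then the 15
upper off-diagonals scaled by √2). Both scalings preserve inner
products, so every contraction in the code is a dot product. The
convention is defined once (`cortiq.btensor.mat_to_voigt`,
`cortiq.qti.c66_to_c21`) and verified by round-trip and
inner-product-preservation tests.

### Scalar metrics

With the isotropic fourth-order bases `E_bulk = (1/9) δ⊗δ`,
`E_iso` (the symmetric identity, `I₆/3` in Voigt form) and
`E_shear = E_iso − E_bulk`:

| metric | definition | range |
|---|---|---|
| MD | tr⟨D⟩/3 | ≥ 0 |
| AD, RD | λ₁, (λ₂+λ₃)/2 of ⟨D⟩ | ≥ 0 |
| FA² | (3/2)·(⟨D⟩⊗⟨D⟩ : E_shear)/(⟨D⟩⊗⟨D⟩ : E_iso) | [0, 1] |
| µFA² | (3/2)·(⟨D⊗D⟩ : E_shear)/(⟨D⊗D⟩ : E_iso), ⟨D⊗D⟩ = C + ⟨D⟩⊗⟨D⟩ | [0, 1] |
| CC | FA²/µFA² (undefined when µFA = 0) | [0, 1] |
| V_MD | C : E_bulk (= variance of compartment MDs) | ≥ 0 |
| V_shear | C : E_shear | ≥ 0 |
| K_bulk | 3·V_MD/MD² | ≥ 0 |
| K_shear | (6/5)·V_shear/MD² | ≥ 0 |

Several inequivalent normalisation conventions for the kurtosis
prefactors circulate in the literature. The tests therefore pin the
prefactor-independent properties (zeros, ordering FA ≤ µFA, rotation
invariance, sign guarantees) separately from the convention-dependent
constants, so a deliberate convention change cannot silently corrupt
the correctness suite. `dtd_moments` computes `⟨D⟩`, `C` and all
metrics exactly from a DTD and serves as the independent oracle for
every fit test.

### Waveforms and schemes

`waveform_to_btensor` integrates `B = ∫ q qᵀ dt` with trapezoidal
quadrature from an *effective* gradient waveform (post-refocusing lobes
already sign-flipped) and refuses waveforms whose residual `|q|` at the
end exceeds 0.1% of its peak. The bundled spherical-encoding generator
(`ste_waveform`) sweeps q on a magic-angle cone with raised-cosine
ramps, then applies an exact isotropising linear map
`q ← √(b/3)·B^{−1/2} q`. That map makes `B = (b/3)·I` to integration
precision and nulls the xz/yz cross-moments, so splitting the waveform
by gradient axis (z → linear encoding; x, y → planar encoding) yields
`B_lte + B_pte = B_ste` exactly and rank-1/rank-2 b-tensors by
construction. User-supplied waveforms enjoy the identity only on the
xx/yy/zz/xy components, since axis-splitting discards xz/yz energy.

The default acquisition has shells at b = 200/700/1400/2000 s/mm² with
10 spherical encodings per shell plus one b = 0 measurement. Per-shell
linear and planar direction counts are configuration (default 10 each,
from deterministic seeded electrostatic-repulsion point sets); the
published acquisition table is ambiguous about these counts, and 10
per shell keeps the 28-column design matrix at full rank (asserted at
build time). Scheme files are plain text, one row per volume
(`b  shape  6 Voigt components`, s/mm²), with a 3×3-per-row dialect
accepted on read.

## 2. QTI+ fitting

Fitting is weighted least squares on the log-signal with
predicted-signal-squared weights (the standard first-order variance
correction for log-linearised models), two reweighting iterations from
an OLS start. `S0` is always a fitted parameter — low-b shells are
never treated as a measured `S0`, and b = 200 s/mm² is not treated as
b = 0.

**Positivity constraints ("+")**: when the WLS solution violates
`⟨D⟩ ⪰ 0` or `C ⪰ 0` (checked against a relative tolerance of 1e−8),
the affected voxels are refit by accelerated projected gradient (FISTA)
on the same weighted quadratic objective over the convex product cone
{⟨D⟩ PSD} × {C PSD}, projecting each block via eigenvalue clipping.
Because every iterate is projected, the returned solution is feasible
regardless of early stopping (iteration cap 500, relative objective
tolerance 1e−10), and the constrained residual can only exceed the
unconstrained one. This constraint pair guarantees all metric sign
invariants (K_bulk, K_shear ≥ 0, µFA real); the stronger joint
conditions of a full semidefinite relaxation are intentionally not
implemented — the pair already provides every guarantee the downstream
statistics rely on.

**Validity filter**: voxels with FA, µFA or CC outside [0, 1] are
excluded from the analysis mask (never clamped) and reported; a
warning is raised when the excluded fraction exceeds 0.5%, the level
regarded as normal operation for a well-conditioned acquisition.

**Known bias — cumulant truncation.** The cumulant model is an
expansion around b = 0. At this protocol's maximum `b·D ≈ 6` the
quadratic model cannot follow the multi-Gaussian signal decay, and the
fitted `C` (hence K_bulk, K_shear, µFA) is systematically biased — for
a `{1, 3}` µm²/ms isotropic mixture the fitted K_bulk is roughly 35–40%
below the exact 0.75 regardless of weighting, recovering to within 15%
only when the fit is restricted to the two lowest shells. This bias is
intrinsic to the model class, affects both groups of a comparison
equally, and is characterised (not hidden) by the test suite.

## 3. Synthetic cortex phantom and cohorts

The phantom is a single 2D coronal slice: an annulus sector with pial
radius 3.6 mm, gray/white radius 2.0 mm (cortical thickness 1.6 mm,
typical of rat neocortex), 70° span, 0.2 mm isotropic voxels (the
in-plane acquisition resolution). Normalised depth `d ∈ [0, 1]` runs
pial → white matter; the tangential coordinate `s ∈ [0, 1]` spans the
sector.

Per depth, the tissue is a three-compartment DTD:

* **radial anisotropic** (axons/dendrites): prolate tensors
  (AD 2.0, RD 0.25 µm²/ms) Watson-dispersed (κ = 12) about the local
  radial axis; volume fraction `0.2 + 0.4·sin(πd)` (peaks mid-depth);
* **cellular isotropic**: 0.6 µm²/ms, the remainder;
* **free water**: 3.0 µm²/ms, `0.03 + 0.15·exp(−(d/0.2)²)`
  (superficial CSF contamination).

These numbers are a cartoon of cortical lamination chosen to give
realistic metric ranges, not a quantitative atlas. Depth is quantised
into 48 bins; each bin's canonical DTD (30 Watson samples, oriented
along +x) is generated from a *fixed* internal seed, so every subject
shares the same tissue template, and is rotated per voxel to the local
radial direction. All metrics are rotation invariant, so ground-truth
maps are exact per bin; signals use the rotated tensors.

**Cohorts.** Each subject receives independently jittered boundaries
(smooth low-order sinusoidal perturbations of both radii, SD 0.05 mm)
and independent Rician noise `√((S+ε₁)² + ε₂²)` with
`σ = S0/SNR`, SNR(b=0) = 30 by default (the acquisition's noise level
is not published; 30 is typical for preclinical 7 T). Group "treated"
carries a lesion: inside a configured `(s, d)` block the anisotropic
fraction is multiplied by a factor — given directly, or solved by
bisection on the exact DTD moments so that ground-truth µFA drops by a
requested absolute amount (used to plant effects in units of the
measured vertex-wise pooled SD). The per-voxel ground-truth effect map
travels with each subject for validation.

What the generator does **not** emulate: EPI distortion and eddy
currents, partial volume across the slice, diffusion-time dependence
and exchange, T2/T1 contrast, coil profiles. Passing tests therefore
demonstrate correctness of the estimation and inference machinery
under the stated model, not robustness to those acquisition artifacts.

## 4. Laplacian cortical coordinates

The potential `φ` solves Laplace's equation on the ribbon between the
delineated boundaries with Dirichlet conditions `φ = 0` (pial) and
`φ = 1` (white matter) and no-flux conditions on the lateral caps.

Numerics: red-black successive over-relaxation (ω = 1.9) on a regular
grid (default spacing: half the metric-map voxel), Shortley–Weller
shortened-arm stencils at Dirichlet boundaries — the axis-aligned
crossing of each boundary-adjacent stencil arm is intersected exactly
with the boundary polyline — giving sub-pixel boundary accuracy
(verified against the analytic log-radial annulus solution and the
linear slab solution). Convergence: maximum stencil residual < 1e−6,
iteration cap 1e5. The streamline direction field is built from
trusted cells only (interior + Dirichlet ghost ring) with masked
one-sided differences and nearest-extension outside, which keeps
directions clean near the cap corners.

Grid-lines seed at equal arc-length midpoints along the pial polyline
(avoiding the caps) and integrate the normalised gradient with
fixed-step RK4 (step = ¼ grid cell) until the interpolated potential
reaches 0.97; the final fraction of a voxel — where the discrete field
is least accurate — is covered by a straight continuation truncated at
the exact polyline crossing. Lines that exit laterally or stall are
excluded with a warning; more than 10% excluded is an error. Metric
values are sampled at arc-length fractions `(k+0.5)/10` (bin midpoints
rather than the endpoints 0 and 1, avoiding pial/WM partial-volume) by
mask-aware bilinear interpolation: invalid neighbours are dropped from
the weighted mean, and all-invalid samples are missing (NaN), never
zero-filled.

Coordinates are world mm with voxel-center origin, stated in every
file header. Hemispheres (or any disjoint delineations) are processed
independently.

## 5. Group statistics

Vertex-wise two-sample pooled-variance Student's t with
`df = n_A + n_B − 2`, two-sided p, and Cohen's
`d = (mean_A − mean_B)/SD_pooled`. Zero-pooled-variance vertices are
flagged (t = 0, p = 1, d = 0); vertices missing for any subject are
excluded from testing entirely, which guarantees ≥ 2 subjects per
group under every relabeling.

Family-wise error control is by cluster-extent permutation: vertices
with `p_uncorr < 0.01` are clustered by 4-connectivity on the
(line, depth) lattice, **separately per effect sign** (merging signs
would conflate opposite abnormalities; connectivity and sign handling
are configuration). For each of 5000 label permutations (group sizes
preserved) the maximum cluster extent across both signs is recorded;

    p_clus = (1 + #{null max extent ≥ observed extent}) / (1 + n_perm),

the +1 making the p-value valid (never zero). When the requested
permutation count reaches the number of distinct relabelings, all are
enumerated exhaustively (identity included, plain count ratio) after a
warning. Each metric is tested independently; no cross-metric
multiplicity correction is applied, matching the per-metric reporting
convention. Significance: `p_clus < 0.05`.

## 6. Histology texture analysis

The structure tensor is the Gaussian-windowed (default 15 µm, converted
through the pixel size) outer product of Gaussian-derivative image
gradients (inner scale: 1 pixel, configurable — the reference tools do
not publish their pre-smoothing). Per pixel: energy `λ₁+λ₂`, coherency
`(λ₁−λ₂)/(λ₁+λ₂) ∈ [0, 1]` (defined as 0 where energy vanishes), and
orientation `½·atan2(2J_xy, J_yy−J_xx)`, reported in degrees in
(−90, 90] with 0° along the image x-axis (Cartesian sense). Radiality
is `|cos(orientation − pial-normal angle)|`: 1 for radial, 0 for
tangential texture. Coherency and orientation are invariant to linear
intensity rescaling by construction.

Area fractions ("automatically adjusted threshold") use Otsu's
between-class-variance criterion with the brighter class as
foreground; a constant image is an error. Depth profiles bin a measure
map by normalised depth (Laplacian depth when boundaries are supplied,
straight-line depth within a rectangular column ROI otherwise); empty
bins are missing, not zero. Group comparisons of per-subject region
summaries reuse the pooled t-test. Vortex patterns are generated for
qualitative inspection but not algorithmically scored.

## 7. Problem sizes and seeds

All randomness flows through explicit `numpy.random.Generator` objects;
cohort generation, permutation inference, and direction sets are
bit-reproducible given a seed. The shipped experiments use: annulus
verification at 50 µm spacing; fit verification on 20–200 voxel
batches; permutation validity on 200 null cohorts × 500 permutations
(the statistical null is planted at the grid-sample level — simulating
hundreds of full DWI cohorts adds cost but no information about the
permutation engine); and effect recovery as full-pipeline replicates
(cohort → QTI+ → grid → cluster permutation) of 10 + 10 subjects with
a planted one-pooled-SD µFA reduction, the pooled SD being calibrated
on a null pilot cohort. `scripts/acceptance.py` reports the same
quantities at 10 replicates.

## 8. Known limitations

* The cumulant truncation bias above; comparisons remain valid because
  both groups share it, but absolute metric values are biased at this
  b-range.
* A one-pooled-SD vertex-wise effect (Cohen's d = 1) with n = 10 + 10
  has only ~25% per-vertex power at the 0.01 cluster-forming threshold,
  so focal clusters of this strength are usually *not* significant
  after family-wise correction — the detection-rate experiments report
  exactly this. Cluster inference at these sample sizes needs d ≈ 2 or
  spatially extensive effects.
* The grid oversamples 0.2 mm voxels (50 lines across a few mm of
  cortex), so neighbouring vertices are strongly correlated; the
  permutation null accounts for this automatically, but effective
  spatial resolution is set by the voxels, not the lattice.
* 2D single-slice geometry throughout; no 3D surface machinery.
* Rician bias is simulated but not corrected in fitting; at SNR 30 the
  residual floor mainly affects the highest shell.
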