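# Methods

This note records the models, conventions and numerical choices behind
`oriscat`, and what the test suite's synthetic systems do and do not probe.

## Structural models

A model is a **docking list**: an ordered set of subunit positions (nm) with
optional per-subunit Tait–Bryan orientations (degrees) and an optional
periodic box. `build_crystal` places points at integer combinations of the
lattice vectors and recenters the set on its geometric mean; lattice constants
(a, b, c, α, β, γ) are converted to vectors with the standard crystallographic
frame (a along x, b in the xy-plane at angle γ from a, c fixed by α, β and the
cell volume). For mutually orthogonal lattice vectors the periodic box
(n_a|a|, n_b|b|, n_c|c|) is attached; oblique cells carry no box, since the
rectangular minimum-image convention would be wrong for them.

**Thermal fluctuation.** `thermalize` adds per-coordinate displacements:
uniform Δr = 2uv − u with v ~ U[0, 1) (so Δr ∈ [−u, u)), or zero-mean Gaussian
with standard deviation σ_u. One seeded generator per call; fixed seeds are
bit-reproducible.

**Metropolis Monte Carlo.** `mc_simulate` works against a harmonic
V(r) = ½k(r − r₀)² or Lennard-Jones V(r) = 4ε[(σ/r)¹² − (σ/r)⁶] potential
between **static nearest neighbors** selected once, by distance cutoff, from
the initial configuration — the natural topology for a lattice, and
deterministic. Each iteration displaces one random point (components uniform
in [−max_step, max_step)) and accepts with min(1, exp(−ΔE/k_BT)); the pairwise
cost carries a factor ½ because each bond is shared between its pair. The
summed shared costs are not additionally normalized by the neighbor count.
Periodic boxes use minimum-image distances and coordinate wrapping. No
re-neighboring or cell lists: dense liquids at large N are out of scope.

## Amplitudes and structure factors

Subunit amplitudes are closed forms in electron units: sphere
4πΔρ[sin(qR) − qR·cos(qR)]/q³, cylinder (axis along local z)
Δρ·V·[2J₁(q⊥R)/(q⊥R)]·sinc(q_zH/2), point scatterers a constant scattering
length. Removable singularities use series limits; the sphere switches to its
series below qR = 10⁻³ (branch mismatch < 10⁻⁷ relative). The cylinder's
orientation-averaged |f|² uses a 256-point Gauss–Legendre rule over cos θ
(relative accuracy well below 10⁻⁴ on the tested q range, cross-checked
against a 10⁶-sample Monte Carlo average).

The structure factor is normalized as S(q) = (1/N)ΣᵢΣⱼ, so S(0) = N,
S(∞) → 1, and I = N|f|²S holds for identical spherically symmetric subunits.
The self terms (i = j) are included — they are what makes S(0) = N. The
isotropic curve is the Debye sum over free-cluster pair distances (no
periodic wrapping: the model is a finite cluster). Above 2000 points the
double sum is replaced by a pair-distance histogram with 10⁻³ nm bins whose
**per-bin centroids** serve as the representative distances; centroids, not
bin centers, because lattice distances are often exact multiples of the
spacing and otherwise sit on bin edges, producing a coherent half-bin error
(observed to reach 10% relative where S is small).

`s_q_from_intensity` inverts S = I/(N|f|²). This is exact only for
spherically symmetric subunits; for anisotropic subunits the form factor and
the lattice sum do not decouple under the orientation average and the
deviation grows with q (material by q ≈ 3 nm⁻¹ for a 3.2 × 0.17 nm cylinder).

## g(r), transforms, and coordination numbers

`g_r_from_model` bins minimum-image pair distances into half-open shells
[r, r + Δr) with edges at multiples of Δr, reporting bin centers;
ρ_b = N/V comes from the periodic box, which is therefore required. Default
references are **all** subunits (deterministic); a random seeded subset is
available. With a positive subunit radius each neighbor deposits into every
shell the exact fraction of its spherical volume inside that shell
(sphere–sphere intersection volumes), which removes the delta-function peaks
of ideal lattices. No tail or finite-size correction is applied.

The transforms

    S(q) = 1 + (4πρ_b/q) ∫₀^{r_max} r [g − 1] sin(qr) dr
    g(r) = 1 + 1/(2π²ρ_b r) ∫₀^{q_max} q [S − 1] sin(qr) dq

are evaluated by composite Simpson on the stored grid, or by a type-I
discrete sine transform after resampling the integrand onto the uniform grid
n·h. The DST input is zero-padded 8× — beyond the truncation radius the
integrand is zero by construction, and padding refines the transform's native
output grid enough to resolve the requested one (bringing the two methods
within 1% on smooth inputs). Truncation at r_max or q_max causes ringing;
transform-derived g(r) may dip below zero near sharp features, and the q = 0
value of S uses the analytic limit.

**Forward-scattering exclusion.** The Debye S(q) of a finite cluster carries
a forward peak at q ≲ 2π/L (L the model's linear size) that encodes the
cluster's overall shape, not its internal order, while the transform pair
above assumes the thermodynamic limit. Round-trip conversions therefore set
S = 1 below 2π/L before inverting. Without this, the inverse transform
re-adds the uniform background on top of the +1 baseline and the first-shell
coordination integral overshoots by exactly the uniform-density window term
(≈ 0.72 neighbors for the reference crystal's [3.4, 3.6] nm window). With the
cut, the result is stable to within ±0.03 for any cutoff between 0.2 and
1.0 nm⁻¹.

`coordination_number` evaluates 4πρ_b ∫ r²g dr by Simpson over the stored bin
centers inside the window, augmented with linearly interpolated endpoint
values at r₁ and r₂ (dropping the partial edge bins loses up to Δr of window
otherwise). A `shell_sum` method performs the exact inverse of the binning
normalization — Σ 4πρ_b r_c² g Δr over bins in the window — and returns the
exact neighbor count for an ideal shell (6.0 for the simple cubic first
shell). On the reference crystal (a = 3.5 nm, 10×10×10, Δr = 0.05 nm,
subunit radius 0.1 nm) the Simpson window [3.4, 3.6] nm gives 5.93: the shell
is spread over four bins and the quadrature loses a few percent at the window
edges. A point-delta shell concentrated in a single bin makes Simpson
quadrature registration-dependent (6–8 depending on where the shell falls);
the finite subunit radius is what makes the integral well posed.

The DST-based inverse centers the first g(r) peak at the lattice distance to
within one native bin (π/q_max ≈ 0.03 nm at q_max = 100 nm⁻¹); integrating
the off-center window [3.5, 3.7] nm therefore captures only about half the
shell (≈ 2.9 neighbors). This window is only meaningful for DST variants
whose peaks are shifted to the right of the lattice distance, which a
correctly registered transform does not produce.

## Reciprocal grids and 2D patterns

Grids sample F(q, θ_q, φ_q) on uniform radial shells up to q_max; shell i
carries 2i + 1 polar samples (poles included) and 2(2i + 1) azimuthal
samples, keeping the angular density roughly uniform per shell; the origin is
a single value. Interpolation is separable and local: Catmull–Rom bicubic on
each angular shell (periodic in φ, bilinear fallback where the θ stencil
would cross a pole) followed by a Catmull–Rom cubic across the four
surrounding shells (linear near q = 0 and q_max). The scheme is exact at grid
nodes, and its error on band-limited amplitudes falls at least fourfold per
shell-count doubling (the linear-fallback regions dominate the bound).

Assemblies are trees of (source, placements): F(**q**) = Σ F_child(A⁻¹**q**)·
exp(i**q**·**R**) with A the intrinsic x→y→z Tait–Bryan rotation (α about x,
then β about y, then γ about z). Child grids are evaluated by interpolation;
closed-form leaves exactly. Direct summation is available for any source; the
grid-free hybrid pathway for very large trees is not implemented.

Orientation averages and fiber patterns are Monte Carlo: uniform solid-angle
sampling via φ = 2πu, cos θ = 2v − 1, with the sample budget doubling until
the relative L² change between consecutive cumulative estimates falls below
rel_tol (default 10⁻³) or the budget cap is reached — the result is then
flagged unconverged in metadata rather than raising.

Detector images identify the detector plane with (q⊥, q_z) — the flat-detector
small-angle convention, no Ewald-sphere curvature. Pixel centers avoid q = 0
(even pixel counts only), out-of-range pixels beyond a grid's q_max are
zero-filled and masked, and negative-q⊥ pixels sample φ′ + π. Fiber images
average |F|² over a uniform azimuth domain (default [0°, 360°), restrictable)
with the same doubling scheme; display rescaling is cosmetic and outside the
numeric contracts.

## Smearing

Resolution smearing convolves I(q) with a Gaussian kernel of width σ_r,
truncated at ±4σ and renormalized per output point, so constants are
preserved exactly and interior-supported integrals to ≈1%. Polydispersity
evaluates the model at 15 parameter values equally spaced over ±3σ_p around
the center (99.7% of the Gaussian weight), clipped below at 10⁻⁶ of the
center to avoid invalid geometry, with normalized Gaussian weights; σ = 0 is
a single central evaluation. Equally spaced abscissae were chosen over
Gauss–Hermite for transparency; the 15-point rule matches a 61-point
refinement to better than 1% for σ_p/center ≤ 0.2. Other weighting
distributions can be supplied by calling `polydisperse_intensity`'s evaluator
hook with custom weights upstream; only the Gaussian is shipped.

## What the synthetic systems do and do not show

The test fixtures — cubic and triclinic crystals, an ideal gas, a graphene
sheet, point-scatterer helices — exercise exact geometric predictions
(neighbor counts, hexagonal reciprocal rings at 4π/(a√3), helical layer-line
symmetry) and statistical limits (g → 1, S → 1). They are noiseless point
models: they do not probe atomic form factors, solvent contrast layers,
detector noise, or fitting against measured data, all of which are outside
this package's scope. Passing tests demonstrate the correctness of the
computational machinery on models, not agreement with any particular
experiment.

## Problem sizes

The reference computations use the 10×10×10 crystal (10³ points,
≈ 5×10⁵ pair distances), structure factors to q_max = 100 nm⁻¹ at
Δq = 0.02 nm⁻¹, transforms on 0.01 nm r-grids, a 40-shell grid to
36 nm⁻¹ for the graphene pattern, and Monte Carlo budgets of 2¹⁴–2¹⁶
orientations — sizes chosen so every check runs in seconds on one CPU while
keeping quadrature and sampling errors well below the asserted tolerances.
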