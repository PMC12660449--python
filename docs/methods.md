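# Methods

This note records the modelling choices behind `osteoadapt`: what is
simulated, which parameters matter, what the synthetic anatomy does and
does not emulate, and where the numerically delicate decisions lie.

## Remodelling model

The remodelling state variable is the per-element apparent density
ρ (g/cm³). The mechanical stimulus is the strain energy density per unit
apparent density, S = U/ρ (J/g). In the mm–N–MPa unit system the element
SED U = ½σ:ε is numerically a J/cm³ quantity, so S is per-mass; we treat
U itself as energy per unit volume throughout (the standard form for
SED-driven adaptation; descriptions that call U itself "per unit density"
conflate the two, and only the per-mass S enters the rate law).

The rate law has a lazy zone of half-width x·S_ref around the reference
stimulus and a quadratic saturation term on the formation side:

    dρ/dt = C₁[S − (1+x)S_ref] − C₂[S − (1+x)S_ref]²   S ≥ (1+x)S_ref
    dρ/dt = C₁[S − (1−x)S_ref]                          S ≤ (1−x)S_ref
    dρ/dt = 0                                           otherwise

Defaults: C₁ = 60, C₂ = 120, x = 0.10, S_ref = 3.6·10⁻⁵ J/g, Δt = 1 month.
The printed units of C₁/C₂ in the source literature ("month × g/cm³") are
dimensionally ambiguous; we adopt rate-consistent units — C₁ in
(g/cm³)·month⁻¹ per (J/g) and C₂ in (g/cm³)·month⁻¹ per (J/g)² — so that
every branch returns g/cm³ per month. Whether S_ref folds in a monthly
gait-cycle count is not stated by its sources; the constant is adopted
verbatim. Densities are clamped to [0.05, 2.0] g/cm³; the law itself has
no bounds and would otherwise run away under sustained over- or
under-loading.

Time stepping is explicit Euler with Δt = 1 month. Each month the seven
gait load steps are solved at month-frozen moduli; the default
`monthly-average` update applies Δρ = Δt · mean over steps of the rate
(order-independent); the `per-step` mode instead applies seven sequential
Δt/7 sub-updates, which makes the result depend on step order. Both are
exposed because the source description of "updates for each of the
successive seven load steps" is ambiguous between them. The element
moduli are refreshed from density once per month, not per load step, so a
single sparse factorisation serves all seven solves.

Convergence (relative change of total strain energy and of mean density
both ≤ 0.05 % between successive months) is logged and surfaced in the
results but does not stop the run: the clinically interesting output is
the full 36-month trajectory, converged or not.

Scalar dynamics under constant U relax towards the lazy-zone boundary
with rate constant λ ≈ C₁·S_ref²/U per month, which is of order 10⁻³ for
physiological stimuli — hence trajectories approach equilibrium over
hundreds to thousands of months, and 36-month runs generically end
unconverged. This matches the test suite: the explicit Δt = 1 update
stays within 1 % of a Δt = 10⁻³ integration because λ·Δt ≪ 1.

## Finite-element core

Four-node constant-strain tetrahedra for bone *and* implant, assembled
with per-element isotropic (E, ν) into a sparse symmetric stiffness.
Interfaces are all bonded: the conforming lattice meshing (below) makes
plate–bone, screw–bone and callus interfaces share nodes, the linear
analogue of tie constraints. Frictional contact is outside the scope of a
linear solver; pre-union osteotomy compliance is represented instead by a
soft callus layer (default 50 MPa) bridging the gap until the union
event.

Boundary conditions reproduce the isolated-femur set: the knee centre
fixed in all translations, the most lateral greater-trochanter nodes
fixed in the anterior–posterior and medial–lateral directions, and the
femoral head centre free to translate only along the head–knee axis. The
axial connector is realised exactly as a rotated single-DOF constraint:
the head node's three DOFs are condensed to one generalised coordinate
along the axis through the transformation u = Tq, and the solver works
with TᵀKT, which is symmetric positive definite whenever the constraint
set removes all six rigid-body modes. Node-level rotational restraints
(the trochanter's superior–inferior spin) have no counterpart in a
translational-DOF element and are omitted; the transverse translational
locks remove the same rigid mode.

Loads: the hip contact force acts on the head-centre node (only its
component along the connector axis does work); muscle bundle forces are
divided equally over their attachment node set. Stresses, strains and SED
are evaluated at the element's single integration point, so "neighbouring
integration points" in the stress filter means neighbouring elements'
constant stresses. A direct SuperLU factorisation is computed once per
month and reused across the seven load steps.

Verification oracles in the test suite: an affine-displacement patch test
(exact to 1e-8), an axial bar against FL/EA, σ = F/A and U = σ²/2E (1e-8),
energy consistency between the element SED sum and ½uᵀKu, exact load
linearity, and a slender cantilever converging monotonically from below
to the Euler–Bernoulli deflection — within 10 % at the reference
refinement of 8 element divisions through the thickness. Constant-strain
tets are intentionally stiff in bending; this is acceptable here because
every comparison is made between scenarios discretised identically.

## Synthetic anatomy

No imaging data is used. The femur is an idealised parametric solid —
cylindrical shaft (length 160 mm, outer radius 12 mm, cortical shell
3 mm), neck cylinder at 130° and spherical head (radius 14 mm) — voxelised
on a regular lattice (default cell 4 mm, ≈10 000 tetrahedra) with each
cell split into six positively oriented tetrahedra. Setting the neck
length to zero yields a plain cylinder whose meshed volume is checked
against πr²L. The comparative retain/remove logic is geometry-agnostic;
the idealisation preserves the load-path topology (lateral plate bridging
an osteotomy, screws crossing into the medial cortex, blade into the
neck) without claiming anatomical fidelity.

The initial density field assigns the cortical density (1.8 g/cm³) to
elements within the cortical thickness of the surface and a spatially
smoothed Gaussian random field (mean 0.30, sd 0.08 g/cm³, clipped to
[0.05, 2.0]) to the trabecular interior — emulating the heterogeneity of a
CT-mapped field, not its anatomical structure (no trabecular
architecture, no density gradients along the neck). The field is then
discretised into ten equal-width density–modulus layers before the run,
mirroring common CT-based FE practice; remodelling updates moduli
continuously thereafter (per-month re-binning exists behind a flag; the
source practice is not specified).

The density–modulus law E = 6850·ρ^1.49 MPa is a published femoral power
law from the citation lineage commonly used with CT-mapped models; the
exact relation used by any particular study is often unstated, and the
comparative results depend on relative, not absolute, stiffness. The law
is configurable.

The implant is carved from the same lattice: plate cells fill the space
between the lateral cortical staircase and the plate's outer face
(80 × 12 × 4 mm default), screws are cylinders of bone cells reassigned to
screw sets (4 screws, radius 2.5 mm, snapped to lattice planes so coarse
meshes still capture a full column), and the blade is an angled prong
(blade angle 130° by default, 90° available). Tie pairs between sets are
exactly their shared faces. The osteotomy is a transverse plane at
120 mm; the one-cell-thick bone layer containing it forms the callus set.

Load program: seven stance-phase steps. The hip contact force follows an
M-shaped magnitude profile peaking mid-stance at 3× body weight, directed
13° medially from the shaft axis; a single abductor bundle (peak 1.5× body
weight, 20° to the shaft axis) acts on the greater trochanter. Default
body weight 450 N — a paediatric patient of ≈46 kg, matching the lighter
of the two clinical anthropometries that motivated the scenario design.
All magnitudes scale linearly with body weight and are configurable. This
replaces EMG-informed musculoskeletal load estimation entirely: step
count, the stance-like shape and trochanteric abductor loading are the
structural features retained; per-muscle decomposition (14 monitored
muscles in gait-lab practice) is deliberately not reconstructed.

What passing tests therefore show: the remodelling law, solver and
metrics behave correctly and reproduce the *directional* clinical
findings — shielding-suppressed proximal gain, post-removal rebound,
declining RoY — on a femur-like geometry. They do not validate absolute
density magnitudes or implant stresses for any real patient; with
idealised geometry and synthetic loads the RoY sits far below yield,
whereas patient-specific geometry and full gait loads can approach it.

## Scenario events

Hardware exists from month 1 in both implanted scenarios; the soft callus
makes the plate carry most of the inter-fragment load until union. After
the event month (default 12): `retained` upgrades the callus to the bone
law; `removed` additionally deactivates plate and screw elements — their
stiffness and stress contributions vanish and DOFs no longer attached to
active elements leave the system. Removed hardware leaves voids (the
default; a backfill option was considered and rejected as harder to
defend than an explicit void). The callus layer does not remodel while
soft — it is provisional tissue, not bone — and joins the remodelling set
at union. Applying an event twice is a state error. RoY is reported while
hardware is active: months 1–36 for `retained`, 1–12 for `removed`.

## Output measures

Regional density change: Δρ_i = (1/N)Σ_k[ρ_end_i(k) − ρ_start(k)] over
the proximal or distal fragment's elements, reported monthly.

Risk of yield: RoY = PVMS / 792 MPa × 100 %. The PVMS filter visits
component elements in descending von Mises order and accepts the first
whose value is within 10 % of the maximum among its face-adjacent
neighbours *within the same component* — face adjacency is the strictest
standard notion of neighbourhood, and the neighbour *maximum* is the most
permissive reading of "within 10 % of neighbouring values" (both
configurable). An element with no in-component neighbours is compared
against the component's next-highest value; if every candidate fails, the
raw maximum is returned with a warning. Screws are pooled into one
component. RoY uses the per-month envelope (max) of the seven load steps'
stress fields rather than a designated step, so it is robust to the
ordering of the stance profile; a last-step mode is available. Reports
flag RoY ≥ 100 % (local yield) and RoY ≤ 50 % (a conservative
rehabilitation-loading threshold).

## Numerical choices and degenerate inputs

- Determinism: a single integer seed drives the density field (geometry
  is deterministic given parameters); identical inputs give byte-identical
  meshes, fields and result series. Seeds are stored in run manifests.
- Voxel meshes bound the tetrahedron aspect ratio by construction
  (longest edge / inradius ≤ ≈8 for cube cells; the generator asserts
  ≤ 20 across randomised geometries).
- Rate-law boundaries: the formation branch is exactly zero at
  S = (1+x)S_ref, so trajectories may sit on the zone boundary to
  rounding precision at equilibrium.
- Binning with ≤ n_bins distinct densities keeps each value as its own
  material, making the operation exactly idempotent and covering constant
  fields with a single layer.
- Degenerate geometry (non-positive dimensions, cortical thickness
  exceeding the radius, osteotomy outside the shaft, plate clear of the
  cortex, meshes with no trabecular interior) raises typed errors naming
  the offending quantity.
- Problem sizes: default assembly ≈ 10 000 elements (~7 500 DOFs), chosen
  so a 36-month three-scenario comparison completes in about a minute on
  one CPU while keeping several elements across the cortical thickness;
  verification problems use meshes from 1 to ~30 000 elements.

## Known limitations

Linear elasticity with bonded interfaces (no frictional contact, no
post-union micromotion); tet4 bending stiffness; idealised geometry and
loads (no growth, no gait adaptation over time, no muscle-by-muscle
forces); remodelling constants taken from adult literature and not
validated for paediatric bone; no fatigue-damage accumulation — the RoY
plateau flags latent fatigue risk but the simulator does not quantify it.
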