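# Methods

This note records the models implemented in `pqinr`, the assumptions
behind them, the numerical choices, and what the synthetic-data tests do
and do not demonstrate.

## Scattering-length densities

All contrast arithmetic reduces to the scattering length density (SLD)
of a component, `SLD = Σb / V`, with Σb the sum of bound coherent
neutron scattering lengths over the component's atoms and `V` its
molecular volume. Scattering lengths come from the standard
bound-coherent table (H −3.739 fm, D 6.671 fm, C 6.646 fm, N 9.36 fm,
O 5.803 fm, P 5.13 fm, S 2.847 fm, Si 4.149 fm). The water molecular
volume is fixed at 30.0 Å³ for both isotopes, giving endpoint SLDs of
−0.558×10⁻⁶ Å⁻² (H₂O) and 6.382×10⁻⁶ Å⁻² (D₂O); solvent mixtures
interpolate linearly in the D₂O volume fraction. Using the measured
D₂O molar volume (≈30.1 Å³) instead would give the often-quoted
6.36×10⁻⁶ Å⁻²; the difference (0.3%) is far below every tolerance used
here, and a single shared volume keeps the H₂O/D₂O interpolation exactly
linear in composition.

DMPC is split into a headgroup component (phosphocholine + glycerol
backbone + carbonyls, C₁₀H₁₈NO₈P, 319 Å³) and the pair of myristoyl
tails (C₂₆H₅₄, 782 Å³), literature values for fluid-phase DMPC. The
chain-deuterated variant (d54) substitutes all 54 tail hydrogens. These
sit in an editable registry and can be overridden through the run
configuration.

Protein SLDs are computed from amino-acid composition using per-residue
formulas, consensus folded-protein residue volumes, and labile-hydrogen
counts (backbone amide plus side-chain OH/NH/SH; proline contributes no
amide H). Labile hydrogens are assumed to exchange completely and in
proportion to the solvent D₂O fraction — no kinetic retardation — which
is the convention underlying protein-matched water. The match point is
the intersection of the (affine) protein and solvent SLD lines; for the
built-in average globular-protein composition it evaluates to ≈43% D₂O,
consistent with the ~42% protein-matched-water convention. Because the
specific protein's sequence shifts this by at most a few percent, both
the generic composition and user-supplied sequences (plain text or
FASTA) are accepted everywhere a composition is needed.

## Reflectivity kernel

Specular reflectivity of a slab stack is computed with the exact
optical-matrix (Abelès) method: per-medium normal wavevectors
`k_n = sqrt((Q/2)² − 4π(ρ_n − ρ_fronting))`, interface Fresnel
coefficients damped by Névot–Croce factors `exp(−2 k_n k_{n+1} σ²)` for
Gaussian roughness of width σ, and reflectivity `|M₁₀/M₀₀|²` of the
characteristic-matrix product. An imaginary SLD term is carried through
the arithmetic but defaults to zero (no absorber in these systems).
The kernel is validated in the test suite against the closed-form
Fresnel solution and against an independently written scalar-loop
transfer matrix to a relative 10⁻¹⁰ on random 1–10-layer stacks.

Instrument resolution is a Gaussian in Q of constant fractional width;
`dq_over_q` is interpreted as **FWHM/Q** (σ = dQ/Q · Q / 2.355), the
convention of time-of-flight reflectometers reporting "dQ/Q = 3.5%".
Smearing of a model curve is computed by 17-point quadrature of the
Gaussian kernel truncated at ±3.5σ, re-evaluating the exact model at
the shifted Q points of every datum. This evaluates the model far more
densely than the data spacing (≥17 points per datum), so thickness
fringes are not aliased, and it handles the grid endpoints by genuine
evaluation beyond the data range rather than extrapolation.  When a
data file carries a per-point dQ column (absolute FWHM), it takes
precedence over the constant fraction in the likelihood.

## Interfacial models

Two bespoke parametric structures are provided, both bounded by
semi-infinite silicon (SLD 2.07×10⁻⁶ Å⁻²) and bulk solvent.

**Five-layer model** (substrate → solution): native oxide SiO₂
(3.47×10⁻⁶ Å⁻², free thickness and hydration), inner headgroups, two
tail leaflets, outer headgroups, and a uniform protein slab (the
membrane-surface lipoprotein, PqiC). Head and tail thicknesses are not
free: they derive from one shared area per lipid molecule (APM) as
`thickness = V_component / APM`, one leaflet per tail layer, which
pins the head:tail molar ratio. Water enters through two hydration
fractions (heads, tails) plus an overall bilayer coverage — the minimal
parameterisation of the water-associated membrane defect. Each layer
SLD is the convex mixture of its component SLD and the solvent SLD with
the component's volume fraction; the protein slab mixes the protein SLD
(at the solvent's D₂O fraction, so it changes with contrast through
labile exchange) with solvent. The protein slab is deliberately a
single uniform layer: the ~50 Å slab interpretation needs no shape
function.

**Seven-layer model**: the five-layer structure plus a thick, dilute
periplasmic-spanning protein layer (PqiB) and a distal mixed
protein/lipid layer (PqiA + hydrogenous DMPC), completing a double-
membrane trans-envelope assembly. The spanning-layer SLD is tied to the
same protein composition as the lipoprotein slab, free only through its
volume fraction (an untied mode can be configured). A mixing fraction
dilutes the proximal deuterated tails with hydrogenous lipid; it acts
on the tail layers only, since head groups are isotope-identical apart
from labile hydrogens.

**Contrast sharing.** For fixed parameters, all geometry (thicknesses,
roughnesses, fractions) is identical across solvent contrasts; only
SLDs change. This is enforced structurally — the stack builder takes
(params, solvent) and geometry never reads the solvent.

**Volume-fraction profiles.** Each slab's component occupancy is
rendered as an error-function-smeared boxcar using its interfacial
roughnesses; the substrate fills z < 0 and solvent takes the residual
volume, so fractions sum to 1 identically. Because the same boxcars
underlie the slab SLD profile, the component-weighted SLD profile
reproduces the smeared slab profile exactly (tested to 10⁻⁶ relative).

**Intermembrane distance.** Defined as lipoprotein slab + spanning
slab: the span from the solution-side boundary of the proximal outer
headgroups to the substrate-side boundary of the distal lipid layer.
Headgroup thicknesses are excluded; the convention is recorded in every
report that prints the distance, since a measured value of this kind is
meaningless without its endpoint definition.

## Fitting and posterior sampling

All contrasts are fitted simultaneously with shared geometry. The data
term is `½ Σ ((R_model − R)/dR)²` with the model smeared at each
dataset's resolution and modified by per-dataset multiplicative scale
and additive background nuisance parameters (free by default, standard
reflectometry practice). Priors are uniform within bounds unless a
normal prior is configured, in which case it contributes
`½((θ−μ)/σ)²`. Out-of-bounds parameters return +∞ rather than raising,
so samplers can propose freely.

Optimisation is Powell's bounded derivative-free method, run in
bounds-normalised coordinates (parameters span ten orders of magnitude
— ångström thicknesses vs ~10⁻⁶ backgrounds — and direction-set methods
fail badly on such anisotropic scaling). Powell is restarted from its
own optimum until the objective stops improving (at most 4 rounds):
a fresh direction set reliably escapes the correlated valley between
the two protein-layer thicknesses, whose sum is much better determined
than their difference. The optimiser is deterministic given its start
point.

Posteriors are sampled with the affine-invariant ensemble sampler
(emcee), walkers initialised in a small ball around the best fit,
burn-in discarded, and the run seeded for exact reproducibility.
Defaults are 64 walkers / 5,000 steps / 1,000 burn-in; the validation
harness uses deliberately short chains (16 walkers / 200 steps / 70
burn-in) — checked against 2.5×-longer chains to give
indistinguishable intervals on these unimodal, nearly Gaussian
posteriors. A mean acceptance fraction outside [0.1, 0.9] is flagged in
the sampler metadata. Credible bands are central pointwise quantile
intervals of any functional of the parameters (a parameter itself, a
reflectivity curve, a volume-fraction profile); the 65% level used
throughout corresponds to ±0.935σ for a normal marginal.

## Synthetic experiments

The generator emulates time-of-flight measurements of the four assembly
stages — bare substrate, protein-free bilayer, bilayer + lipoprotein
(50 Å slab), and the full trans-envelope structure (230 Å spanning
layer, hence a 280 Å membrane separation) — each at the four solvent
contrasts (100%, 80%, 42%, 0% D₂O), on a logarithmic Q grid of 90
points over 0.01–0.3 Å⁻¹ at dQ/Q = 3.5%. Ground-truth bilayer values
(APM 60 Å², head hydration 0.35, tail hydration 0.05, coverage 0.95,
12 Å oxide, 3–5 Å roughnesses) are typical of high-coverage DMPC on
piranha-cleaned silicon.

Noise is Gaussian with relative width
`σ/R = floor · sqrt(1 + b/R)`, floor 1% and instrument background
b = 10⁻⁷: a flat fractional error where the signal is strong, inflating
as the reflectivity approaches background, qualitatively matching
time-of-flight error bars without modelling the instrument. The `dR`
column stores the true σ, so `(data − model)/dR` is standard normal by
construction (verified distributionally at n = 800).

What the round trip demonstrates: that the forward model, resolution
treatment, likelihood and samplers are mutually consistent, and that
four-contrast data of this quality determine the layer geometry to
fractions of an ångström. What it does not demonstrate: robustness to
model misspecification (real interfaces have correlated residuals,
imperfect backgrounds, alignment errors and inter-measurement drift
that the generator deliberately omits), so recovery precision on
synthetic data is an upper bound on what measured data can give.

## Geometry metrics

Superposition uses the Kabsch SVD algorithm (proper rotation enforced);
optional pruning iteratively drops the worst pair above a cutoff
(default 2.0 Å) and re-superposes until stable — an approximation to
the unstated pruning schemes of interactive tools, so only all-pair
values should be compared across programs. Cα atoms are the assumed
alignment targets. Salt bridges are counted between side-chain
carboxylate oxygens (Asp/Glu) and basic side-chain nitrogens (Lys/Arg;
His only via an explicit flag) within 4.0 Å, once per residue pair,
symmetric in chain order; residues with missing charged atoms are
skipped with a logged note. Ring assemblies are built from explicit
affine operators or crystallographic space-group operators (via gemmi),
deduplicated by centroid; copies are accepted as a closed ring when the
centroid contact graph (edges below 1.3× the median nearest-neighbour
separation) is a single cycle, and the ring axis is the normal of the
best plane through the centroids. The axial pore profile reports, at
each station along the axis, the largest probe sphere clearing all
atoms' van der Waals spheres (Bondi-type radii), plus the minimum pore
diameter and maximum outer diameter. This is a probe-on-axis
definition, not a solvent-rolled surface.

## QCM-D

The Sauerbrey relation `Δm = −C·Δf/n`, `C = sqrt(ρ_q μ_q)/(2 f₀²)`,
converts overtone-normalised frequency shifts to areal mass with the
sign convention "frequency decrease → positive adsorbed mass". For the
standard 5 MHz AT-cut crystal (ρ_q 2648 kg m⁻³, μ_q 2.947×10¹⁰
kg m⁻¹ s⁻²) the sensitivity is 17.7 ng cm⁻² Hz⁻¹. Step changes are
differences of windowed medians per harmonic — robust to transient
spikes. The rigid-film assumption fails for high-dissipation
depositions (vesicle layers); those steps should be read qualitatively,
and no viscoelastic model is provided.

## Problem sizes and known limitations

The validation harness uses 90 points × 4 contrasts for the recovery
fits and 60 points × 4 contrasts × 20 replicates for the coverage
study; these sizes give sub-ångström recovery and stable coverage
estimates while keeping a full validation run to a few minutes on one
CPU. Known limitations: no off-specular or polarised scattering, no
lateral inhomogeneity beyond area-fraction mixing, no absorption by
default, no model-selection machinery (fit quality is judged by χ² per
point and posterior width), and the crystallographic ring detection
assumes an approximately planar ring of centroids.
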