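# Methods

This note records the models, numerical choices and known limitations of
`helixfit`, in the order the pipeline uses them.

## Peptide specifications and sequence-derived quantities

A peptide is written as an optional `Ac-` cap, dash-separated literal runs
and `(XYZ)n` repeats of one-letter codes (standard twenty plus `O` for
4-hydroxyproline), and an optional `-NH2` cap. Masses are average residue
masses; the trimer mass is three chains, each residue sum + one water +
cap increments (acetyl +42.037 Da, amide −0.985 Da). Hydroxyproline always
carries its true mass (113.116 Da) in mass bookkeeping.

The partial specific volume v̄ is the classical composition estimate
v̄ = ΣVᵢ·0.6022/Σmᵢ with consensus residue volumes taken as the mean of
the three classical determinations (Cohn–Edsall 1943 densitometry,
Zamyatnin 1972 solution volumes, Chothia 1975 crystal interiors). The
tables cover only the standard residues, so hydroxyproline is evaluated
with proline's parameters — by default for both the volume and the mass in
the ratio, which makes (POG)ₙ and (PPG)ₙ indistinguishable, the behaviour
of composition-only calculators; `hyp_mass="hyp"` switches the denominator
to the true mass. One terminal water per chain is included in both sums
(`include_chain_ends=False` disables it; the effect is ~0.3 % for a
30-residue chain). Blocking groups are not part of the v̄ composition.

Extinction coefficients: 1280 M⁻¹cm⁻¹ per tyrosine at 280 nm; 2200 per
peptide bond at 214 nm with residues−1 bonds per chain plus one per
blocked terminus (each cap is an amide linkage), times three chains.

The s₂₀,w standardisation uses
s₂₀,w = s_T,B·(η_T,B/η₂₀,w)·(1 − v̄ρ)₂₀,w/(1 − v̄ρ)_T,B with the canonical
water constants η₂₀,w = 0.010020 P and ρ₂₀,w = 0.99823 g/ml. A vanishing
or sign-flipping buoyancy term raises an explicit error.

## Linear triple-helix builder

The builder is parametric, not crystallographic: backbone atoms sit on
concentric helices with the ideal 7/2 screw (−2·360/21° and 0.286 nm per
residue), Cα at radius 0.385 nm (consecutive Cα–Cα ≈ 0.365 nm), N and C at
0.33/0.28 nm with ±0.33-residue phase offsets, and carbonyl O radially
outward. Chains A→B→C are staggered by one residue and rotated by 120°.
Side chains are placed in a single fixed conformation that points the
first bond outward and wraps deeper atoms tangentially around the helix
surface (clamped at 0.585 nm radius, with an axial zigzag), keeping the
helix at its physical ~1.1 nm diameter. Acetyl (CH₃-C=O) and amide (N)
caps are placed on the same parametric curve just beyond the termini.

The geometry is deliberately idealised: bond lengths are approximate and
rotamers are not real. The constructions it feeds — sphere-model
scattering at Q ≤ 4 nm⁻¹ and shell hydrodynamics — are sensitive to
overall length, cross-section and total volume, all of which are enforced
by tests (axial rise 0.286 ± 0.01 nm; dry sphere-model volume within 5 %
of M·v̄/N_A for all nine study sequences; no non-bonded contact below
0.15 nm). Atomic-resolution properties (dihedrals, hydrogen bonds) are out
of scope, and G→A substitutions or interruptions are built on the ideal
backbone without local unwinding — non-ideal geometry is the ensemble
stage's job.

Models are written/read as PDB (Å, exact factor 10; Hyp as residue HYP;
caps as ACE/NH2 hetero records) via biotite.

## Bend-conformer ensembles

The sampler replaces force-field dynamics with geometry: conformational
selection only needs a pool of clash-free conformers spanning the bend
range. Each conformer applies a rigid rotation of the C-terminal arm about
a random axis perpendicular to the helix axis, with the bend angle drawn
from U[0, max_bend] (default max_bend 90°, covering the largest bends the
analysis must reach) and a linear ramp across the hinge triplet so the
backbone stays connected; optional worm-like noise adds independent
N(0, sd) per-triplet rotations (default 0). The hinge defaults to the
GQG-interruption triplet when a Gln is present, else the centre triplet.
A bent hinge triplet is a genuine local kink: the ideal Cα–Cα window does
not apply there (validation uses a relaxed connectivity window of
0.27–0.62 nm for conformers). Conformers with non-bonded contacts below
0.15 nm are redrawn (bounded retries, counted). One seeded generator
drives everything; ensembles are bit-reproducible.

Bend angles are measured as the angle between the principal axes of the
two arms flanking the hinge, each axis fitted to stagger-aligned triplet
centroids (chain k looks one residue earlier than chain k−1), for which
the nine azimuths cancel exactly on an ideal helix — the measurement
returns 0.0° for the builder output and reproduces pure hinge rotations to
better than 0.1°.

## Sphere-model scattering

Coarse-graining follows the grid method: the model is centred, its
dominant principal axis is aligned with z (minimal rotation, skipped below
2° so built models keep their frame), for clearly bent shapes (lateral
anisotropy > 1.10) the bend plane is additionally rotated onto x, and a
cubic grid of side 0.53 nm is laid from the bounding-box corner. Cells
with ≥ 4 atoms become spheres at the cell centres with radius
0.53·(3/4π)^⅓ nm (cube-volume equivalence, conserving total volume). The
frame canonicalisation makes the sphere model independent of the
conformer's orientation, which removes most of the grid jitter between
rigid-motion-related conformers; the residual translation jitter is below
0.5 % in Rg.

Hydration (X-ray contrast) appends spheres of the same size on empty grid
cells adjacent to the dry model until they account for 0.3 g water per g
peptide (volume = 0.3·M·v_water, met to within one sphere). Cells touching
≥ 5 spheres form the wrapping lateral surface — cells beyond the helix
tips touch at most ~3 — and the shell is spread uniformly along the long
axis by deterministic systematic sampling, so hydration thickens the rod
without artificially lengthening it (the hydrated-minus-dry length
difference stays a few tenths of a nm, as observed). Neutron (heavy-water)
curves use the dry model unchanged.

Intensities follow the Debye equation adapted to spheres with the squared
single-sphere form factor, normalised to I(0)=1, equal weight per sphere
(single contrast per measurement; no per-element form factors or
solvent-exclusion terms). The default evaluation bins pairwise distances
at 0.002 nm (O(n_Q·n_bins)); it agrees with the exact double sum to better
than 0.1 % and both are available. The default Q grid is 400 linear points
on 0.04–4 nm⁻¹, an instrument-like density: a sparser grid measurably
degrades the stability of ensemble ranking under noise.

The R factor interpolates the model curve onto the experimental grid over
the overlapping window (full range by default, configurable and recorded);
the scale factor η minimises Σ| |I_e| − η|I_t| | by golden-section search
to 10⁻⁶ relative, which bounds the R factor of two identical curves at
~10⁻⁵ %.

## Curve analysis

Guinier fits are (weighted, when σ is present) least squares of ln I vs
Q². With an explicit window the fit uses exactly that window — theoretical
windowed Rg values are computed this way, over the same windows used for
the corresponding experimental fits, because the windowed apparent Rg of a
rod is substantially below its true Rg and depends on the window. The
automatic window grows from the lowest Q by fixed-point iteration to
max(Q)·Rg ≤ 1.3 (≤ 20 rounds, 0.01 tolerance), widening first if a noisy
start hides the decay. Note the Guinier approximation itself biases
sphere-like shapes by ~2 % at Q·Rg = 1.3 and <1 % at Q·Rg ≤ 0.8.

P(r) from a curve is a regularised indirect transform: P ≥ 0 on an r-grid
over [0, Dmax] with fixed zero endpoints, fitted through the Debye kernel
by non-negative least squares with a second-difference penalty; the
regularisation weight is chosen on a fixed logarithmic grid by an L-curve
corner search (maximum distance from the chord), and a residual blow-up
triggers a "Dmax too small" error. P(r) from a sphere model is the
centre-distance histogram convolved with the finite-sphere kernel (the
self-convolution of a sphere's axial profile) plus the intra-sphere term;
the reported maximum length L is the 1 %-of-peak support end — "reaches
zero" is ill-posed both for noisy data and for discrete models — while the
geometric maximum (max pairwise distance + 2R) is kept as `span`. The mode
M is taken from the inter-sphere part, since the sub-resolution
intra-sphere spread is not a structural distance.

Melting curves are analysed as two-state transitions: the full sigmoid ×
linear-baselines model is fitted only to estimate the folded/unfolded
baselines, then the fraction folded F(T) = (signal − unfolded)/(folded −
unfolded) is formed pointwise and T_m is interpolated at F = 0.5. Zero- and
2 %-noise synthetic melts are recovered to 0.05 °C and ~0.3 °C respectively.

## Hydrodynamics

Bead models use one bead of hydrodynamic radius 0.29 nm per heavy atom
(the radius already accounts for bound water, so no explicit hydration
beads are added); hydroxyproline's ring hydroxyl oxygen is deleted so Hyp
is treated with proline's bead content. The friction calculation is a
shell strategy: the fused-sphere surface is tiled with mini-beads of
radius σ (Fibonacci lattices per atom, buried points pruned, σ-pitch
dedupe), the rigid-body translational friction is computed for
σ ∈ {0.24, 0.20, 0.16, 0.13} nm, and f is extrapolated linearly to σ → 0.
The default per-shell solver is the full Rotne–Prager–Yamakawa mobility
supermatrix (solve, then contract); the Kirkwood double-sum approximation
is available (`method="kirkwood"`) and is the cross-check in tests, but it
underestimates the friction of elongated shells by ~5 % (enough to push
s ~9 % high), so the supermatrix is the default. The sphere limit is
recovered to ~1.5 % and a single-atom model falls back to the exact Stokes
expression. Shells are built in a canonical frame, so s is invariant under
rigid motion of the model up to shell discretisation (~0.2 %; the lateral
axes of a near-cylindrical helix are close to degenerate).

## Ensemble filtering

Every conformer is coarse-grained, hydrated (X-ray) or not (neutron), its
Debye curve scored against the target per contrast. Ranking is by
ascending X-ray R factor (denser sampling); ties break by neutron R
factor, then index. Neutron data act as cross-validation: on consistent
synthetic data the two contrasts select strongly overlapping top sets.
The pipeline emits the R-factor-vs-Rg scatter, the top-k conformers (PDB),
per-model Guinier/P(r)/s summaries for the linear and best-fit models, and
a machine-readable report; identical configuration and seeds give
byte-identical outputs. Selection picks single best-fit conformers — no
ensemble reweighting.

## Synthetic data

Synthetic experiments generate the noise-free sphere-model curve of a
known (usually hinge-bent) conformer per contrast on the instrument-like
window and add multiplicative Gaussian noise σ(Q) = σ_rel·I(Q)·(1 + c·Q)
(defaults σ_rel = 0.02, c = 0.5 nm), emulating counting statistics that
worsen toward wide angle; an optional Gaussian Q-resolution kernel
provides neutron-like smearing. This emulates noise magnitude and trend
but not instrument backgrounds, buffer subtraction or radiation damage, so
recovery results bound what the method can do on well-reduced data, not on
raw data. Melting curves are two-state sigmoids between linear baselines
with additive Gaussian noise. Everything is seeded.

At these conditions (2 % noise, 400-point curves) the bend of the
generating conformer is identifiable from the top-10 mean of a filtered
ensemble to within ~5–10° for bends of 20–85°; small bends (≲ 20°) are the
hardest because curves of nearly straight conformers differ by less than
the noise floor — the same reason the original analyses report their
smallest bends with the least contrast. Recovery statements in the tests
therefore average the top-10 mean over three noise realisations.

## Problem sizes and determinism

Default runs use ensembles of 2,000 conformers (a 2,000-conformer filter
of a 10-triplet helix takes ~15 s on one CPU; 12,000 scales linearly),
shells of ~1,000–1,500 mini-beads per σ for hydrodynamics, and 400-point
curves. All stochastic stages take explicit integer seeds and are
bit-reproducible; all deterministic stages (gridding, hydration placement,
shell construction) are tie-broken lexicographically.

## Known limitations

- The builder's idealised geometry reproduces length/volume/cross-section,
  not stereochemistry; PDB output is not suitable for force-field work.
- The hinge sampler explores a single localized bend (plus optional gentle
  worm-like noise); multi-hinge or globally curved shapes are outside the
  search space.
- v̄ for sequences containing residues outside the classical volume tables
  raises rather than guessing.
- The windowed theoretical Rg of a straight model is fully determined by
  its geometry: for the 12-triplet MBL peptide the value implied by the
  model's own length (≈ 3.0 nm over the 0.14–0.44 nm⁻¹ window, confirmed
  against the closed-form rod intensity) sits a few per cent above the
  historically reported value, which corresponds to a slightly shorter
  effective rod.
- SANS-specific hydration-contrast effects on P(r) mode values are not
  modelled (the dry model is used unchanged for neutrons).
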