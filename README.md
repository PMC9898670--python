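# helixfit

Solution-structure analysis of collagen triple-helix peptides.

Collagen model peptides such as (Pro-Hyp-Gly)₁₀ form rod-like triple
helices, but small-angle X-ray/neutron scattering (SAXS/SANS) and
analytical ultracentrifugation routinely report them as *more compact* than
an ideal straight helix — especially when the (Xaa-Yaa-Gly)ₙ repeat is
interrupted, as by the GQG break in the collagen stalk of mannan-binding
lectin (MBL). `helixfit` implements the full modelling side of that
analysis:

1. **Build** an atomistic linear triple helix from a one-line peptide
   specification (ideal 7/2 symmetry: −2·360/21° twist and 0.286 nm rise per
   residue, chains staggered by one residue).
2. **Sample** an ensemble of bent conformers with a localized hinge at a
   chosen triplet (the GQG interruption by default), bend ~ U[0, θmax].
3. **Predict** SAXS/SANS curves per conformer: coarse-grain onto a cubic
   grid (box side 0.53 nm, ≥ 4 atoms per occupied cell), add a hydration
   shell of 0.3 g water / g peptide for the X-ray contrast, and evaluate
   the Debye equation adapted to spheres,
   `I(Q)/I(0) = g(Q)·[n + 2Σ_{i<j} sin(Qr_ij)/(Qr_ij)]/n²`.
4. **Filter** the ensemble against experimental (or synthetic) curves with
   the crystallographic-style R factor,
   `R = Σ| |I_e| − η|I_t| | / Σ|I_e| × 100`, η fitted.
5. **Cross-check** with bead-shell hydrodynamics: per-atom beads of
   hydrodynamic radius 0.29 nm, surface shells of mini-beads extrapolated
   to zero bead size, giving the theoretical sedimentation coefficient
   s₂₀,w = M(1 − v̄ρ)/(N_A f).

Sequence-level physics (triple-helix mass, consensus-volume partial
specific volume v̄, extinction coefficients, s₂₀,w buffer correction),
Guinier fits (ln I = ln I₀ − Rg²Q²/3, valid to Q·Rg ≈ 1.3), pair-distance
distributions P(r) (regularized indirect transform from curves; distance
histograms from models, giving the maximum length L and mode M), two-state
melting analysis (T_m at fraction-folded = 0.5 between linear baselines),
and a synthetic-data generator for all of the above are included, so every
stage is testable without instrument data.

## Worked example

Sequence-level properties of the (POG)₁₀ helix:

```text
$ helixfit props "Ac-(POG)10-NH2"
sequence        Ac-(POG)10-NH2
residues/chain  30
full triplets   10
trimer mass (Da)        8195.7
vbar (ml/g)     0.7339
eps280 (/M/cm)  0
eps214 (/M/cm)  204600
```

The trimer mass is the three-chain helix with acetyl/amide caps; v̄ comes
from consensus crystallographic residue volumes with proline substituted
for hydroxyproline (the volume tables only cover the standard residues).

A demonstration fit against synthetic data generated from a 40°-bent
conformer of the MBL-center peptide (GQG interruption at triplet 5):

```toml
# demo.toml
sequence = "Ac-(POG)4-QG-(POG)5-NH2"
name = "mbl-center-demo"
n_conformers = 400
seed = 11
synthetic_truth_bend = 40.0
```

```text
$ helixfit fit --config demo.toml --out demo_out
{
 "conformer_index": 86,
 "r_factor_xray": 2.3,
 "r_factor_neutron": 2.293,
 "bend_deg": 33.41,
 "s20w_sved": 0.9078,
 "pr_length_nm": 8.45,
 "pr_mode_nm": 1.35
}
```

Reading `demo_out/report.json`: the straight model fits the bent target
with R = 2.6 % (X-ray) / 3.8 % (neutron) while the best-fit conformer
reaches 2.3 % in both contrasts with a 33° bend; the ten best conformers
average 37° (truth: 40°), and the best-fit model sediments slightly faster
(0.908 S) than the straight one (0.905 S), the expected signature of a more
compact shape. `rfactor_scatter.csv` holds the R-factor-vs-Rg cloud for
every conformer, and the top-10 models are written as a multi-model PDB.

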