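# Methods

This note records the models, conventions and design choices behind
`cannmotif`, in the spirit of a methods section: what is computed, under
which assumptions, and what the synthetic generators do and do not emulate.

## Backbone construction

Peptide models are grown by sequential internal-coordinate extension
(NeRF-style placement): each atom is positioned from a bond length, a bond
angle and a torsion relative to three previously placed atoms.  Because the
construction is exact, re-measuring (φ, ψ) from the coordinates reproduces
the requested torsions to floating-point precision; the package-wide
contract is agreement within 0.5°.

Fixed ideal geometry (Engh–Huber-style values, Å and degrees):
N–Cα 1.458, Cα–C 1.525, C–N 1.329, C=O 1.231, N–H 1.01, Cα–Hα 1.09,
Cα–Cβ 1.53; N–Cα–C 111.2, Cα–C–N 116.2, C–N–Cα 121.7, Cα–C–O 120.8,
C–N–H 119.5.  All peptide bonds are trans (ω = 180°), including the caps.
The N-acetyl cap (CH₃–CO–, residue index 0) defines φ of residue 1 and the
C-amide cap (–CO–NH₂, index n+1) defines ψ of residue n, matching how
torsions are tabulated for residue 1 of each design.

Carbonyl oxygens, amide hydrogens and the cap NH₂ are placed planar
(improper torsion 180° across the relevant sp² centre).  Cβ and Hα sit at
the tetrahedral improper torsions −120° / +120° from C(i)–N(i)–Cα(i),
which gives L-configuration at Cα (the values match CCD ideal residue
templates).  Glycine receives two alpha hydrogens (HA2/HA3), Aib two
methyl carbons (CB1/CB2) and no Hα; side chains beyond Cβ are not built,
because every interaction analysed here involves main-chain atoms of the
motif only.  Models are validated by round-tripping torsions, by bond-length
checks (±0.02 Å), and by the right-handedness of the built helices
(positive consecutive Cα-triad torsions).

Truncated 5-residue designs are produced by cutting a built 18-residue
model after residue 5 and converting the backbone N of residue 6 into the
amide-cap nitrogen, so all kept coordinates — and ψ of residue 5 — are
preserved exactly.

Anions are ideal tetrahedra centred on S/P: S–O 1.49 Å, P–O 1.54 Å, one
O–H of 0.96 Å on hydrogen phosphate.

## Hydrogen-bond detection and scoring

A donor–acceptor pair is a geometric contact when H⋯O ≤ 3.0 Å (Cα donors)
or ≤ 2.7 Å (amide donors) and ∠X–H⋯O ≥ 90°, all thresholds inclusive
(a 10⁻⁹ epsilon keeps exact-boundary geometries from flipping on float
noise).  The amide cutoff is configurable because published conventions
vary between 2.7 Å and the 3 Å used in crystal-structure surveys; 2.7 Å is
the default.  For glycine the alpha hydrogen nearer the candidate acceptor
is evaluated (the pro-R/pro-S assignment is not distinguished).

Accepted contacts are scored with the four-term Coulomb sum

    E = 332 (q_S q_H / r_SH + q_S q_X / r_SX + q_O q_H / r_OH + q_O q_X / r_OX)

in kcal/mol, with q_S = 1.6, q_O = −0.9 and donor-specific charges
(amide: q_H = 0.3, q_N = −0.5; alpha: q_H = 0.06, q_Cα = −0.1).
E ≤ −1.0 kcal/mol is a strong H-bond, −1.0 < E ≤ −0.5 weak, otherwise
unclassified; the boundaries go to the stronger class because the defining
inequalities are non-strict.  Energy labels are reported per contact but do
not gate the canonical-pattern predicate, which is purely geometric.

The canonical recognition pattern requires exactly two engaged oxygens:
one bridging Cα₋₁–H and N₀–H simultaneously, the other contacting N₊₁–H
alone.  The predicate is verified in the tests by exhaustive enumeration of
all 4 096 oxygen→donor contact assignments against a direct restatement of
the definition.

## Conformational state and helicity

Per-residue states use inclusive (φ, ψ) windows: right-handed helical
φ ∈ [−85°, −55°], ψ ∈ [−69°, −45°]; polyproline II φ ∈ [−85°, −55°],
ψ ∈ [130°, 170°].  "Non-canonical helical" — used for the delayed
relaxation of the N₊₁ residue next to a helix-promoting Aib — is defined
here as the broad right-handed basin [−110°, −40°] × [−80°, −5°] minus the
strict helical window; ties at borders resolve to the more specific state
(helical > PPII > non-canonical > other).  The broad-basin bounds are a
package choice (the notion is qualitative in the source literature) and are
exposed in the configuration.

Helicity is additionally tracked by the NH–NH(i,i+1) amide-proton
distance, helical when < 4 Å.  Pairs missing an amide hydrogen (proline)
are skipped.

Trajectory analysis reports, per frame, contacts, states and NH–NH pairs.
The anion residence is the initial maximal run of frames with at least one
motif contact, tolerating contact-flicker gaps shorter than k frames
(default k = 10, configurable) so that a single residence episode is not
split by transient detachment.  The transition report compares the
helical-state fraction of each motif residue before and after residence
end.

## Ensemble statistics

For each donor, distances and angles are collected over the models in
which that donor is engaged (models where it is not are excluded per donor,
matching how ranges are tabulated for interacting conformers only), and
summarised as min–max (mean).  A Gaussian A·exp(−(x−μ)²/2σ²) is fitted by
least squares to the density histogram (Sturges binning — 9 bins at
n = 250; binning is configurable since the choice is not canonical), and
the fit quality is reported as R² and adjusted
R²  = 1 − (1 − R²)(n_bins − 1)/(n_bins − 3).  The coefficient of variation
σ/μ ≈ 10⁻² on tight ensembles indicates a single well-defined binding
geometry; the fit is diagnostic — bimodal pose sets drive adjusted R²
below ~0.7.  Cells with fewer than three observations, or with degenerate
(zero-spread) data, are reported as insufficient rather than raising.

## Restraints and masses

NOE classes map to upper limits weak 4.25 Å / medium 3.5 Å / strong 3.0 Å.
The Karplus relation ³J = 6.4 cos²θ − 1.4 cosθ + 1.9 Hz uses
θ = |φ − 60°| taken as the wrapped absolute difference on [0°, 180°], so
torsions near ±180° behave correctly.  Inversion scans a 0.1° grid for
sign changes, refines each root by bisection, widens to ±10° (the
conventional restraint window) and merges overlaps; an unattainable J
returns an empty list with a warning.

Peptide masses are elemental-composition sums (residues + water + cap
deltas: acetyl +C₂H₂O, amide −OH +NH₂) using standard residue compositions,
with Aib registered as C₄H₇NO.  Adduct m/z = (M_pep + M_anion + |z|·mₑ)/|z|
with monoisotopic SO₄ 95.9517 Da / HPO₄ 95.9612 Da; the electron mass is
included for correctness though invisible at one decimal.  The computed
doubly charged sulfate adduct of CPS224Ac is 926.49 → 926.5 at one
decimal.  The phosphate adduct computes to 926.50 while the observed value
is quoted as 926.4; the package reports the computed value and notes the
0.1 discrepancy as an observed-value offset rather than forcing it.

## Synthetic generators

The generators are statistical stand-ins for docking and MD output, not
simulations: there is no force field, no water, and the anion is rigid.

**Canonical pose.**  The anion is placed by rigid-body least squares
(seeded multi-start) against target H-bond geometry: distance targets are
two-sided (defaults d_Cα 2.6 Å, d_N 1.9 Å), while angle targets (120° Cα,
160° N) are lower bounds — an H-bond more linear than requested is better,
not a miss.  This hinge treatment is deliberate: a minimax feasibility
analysis shows the full two-sided target set is not rigid-body realizable
on the built conformations (consistent with docked native-model angles
falling to ~100–105° in the reference data), whereas with angle
lower bounds the defaults are exactly realizable on the native model.
Both glycine alpha hydrogens are tried as the Cα donor.  Additional hinge
penalties keep the two non-designated oxygens outside the detection
cutoffs, so the generated pose is canonical by construction.  The achieved
geometry must land within 0.15 Å of each distance target and no more than
10° below each angle target, else the call fails with the achieved
residuals.

**Pose ensembles** apply n (default 250, the docking iteration count)
seeded rigid-body perturbations to the anion: Gaussian translation
(default σ 0.03 Å) and rotation about the anion centre (default σ 2°).
Defaults are chosen as realistic docking scatter; at the documented
small-noise recovery condition (0.02 Å translation only) the ensemble
statistics recover the generator geometry with σ/μ ≈ 1.1 × 10⁻² and
adjusted R² ≥ 0.9 across seeds.

**Switch trajectories** emulate a bound→unbound event with ground truth
(default 1 000 frames, unbinding at frame 400, mirroring the ~400 ps
residence at 1 ps/frame).  While bound, the N₀ and N₊₁ residues jitter
(Gaussian σ 3°, clipped 0.5° inside the window so float noise cannot
straddle a boundary) about their native torsions, which already lie in the
strict helical window; the Cα₋₁ residue keeps its native β-region torsions
throughout, because the motif's recognition conformation is β–αR–αR and
the conformational switch concerns the two amide donors.  The anion is
carried along by rigid superposition of the donor frame plus small jitter;
every bound frame passes the canonical-pattern check at default noise.
From the unbinding frame on, N₀ is resampled in the PPII window (N₊₁
optionally lagging in the broad helical basin for `relax_frames` frames,
mimicking the restraint imposed by the neighbouring Aib) and the anion
retreats radially from the donor centroid at 0.5 Å/frame.  Analysis
recovers the residence within ±10 frames, the N₀ helical fraction ≥ 0.9
before vs ≤ 0.1 after, and the N₀–N₊₁ NH–NH distance crossing 4 Å at the
transition.

What passing these closed-loop tests shows is that the analysis stages
correctly measure what the generators encode.  It does not show that real
docked or simulated ensembles behave this way: real pose scatter is not
isotropic Gaussian, real unbinding is not a clean switch, and solvent and
side-chain effects are absent by construction.

## Numerical conventions and edge cases

Torsions live on (−180°, 180°] with 180 ≡ −180 in comparisons; collinear
point triples raise a geometry error rather than returning an arbitrary
value.  PDB output is fixed-column v3.3 (via Biopython) with anions as
HETATM residues SO4/PO4; coordinates survive write→read at the format's
3-decimal precision.  Alternate locations are not modelled (first altLoc
kept with a warning); mmCIF, symmetry and B-factor semantics are out of
scope.  All stochastic routines take an explicit seed and share no global
state.

## Known limitations

- Docking scoring/search and MD force-field behaviour are explicitly not
  reproduced; binding free energies are therefore absent from reports.
- The experimental NMR-derived conformation is supported only through
  user-supplied motif torsions (`experimental_like`), since its full
  coordinates are not tabulated in the source material.
- Chain construction uses fixed ideal internal coordinates; strained
  conformations that would relax bond angles in a force field are
  represented ideally instead.
- The Gaussian ensemble fit assumes unimodal scatter; its adjusted R² is a
  diagnostic, not a hypothesis test.
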