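# Methods

This note documents the models and procedures the package implements,
the defaults and why, what the synthetic generators do and do not
emulate, and the numerical choices a maintainer would want spelled
out.

## Trajectory statistics

**Superposition and fluctuations.** Rigid-body fits use the Kabsch
algorithm (SVD of the cross-covariance, with the determinant
correction so the rotation is proper). RMSF and PCA superpose frames
onto an iteratively refined mean structure (two passes: first onto
frame 0, then onto the mean of the superposed set). With a
mean-structure reference the PCA eigenvalue sum equals the total
positional variance, which is asserted as an invariant.

**PCA.** Covariance of the superposed selected coordinates with
population normalisation (divide by n_frames, not n−1 — the same
convention as the hydrophobicity statistic below, stated once here to
avoid ambiguity), diagonalised through the SVD of the centered data
matrix for numerical stability. The default selection is Cα atoms,
unweighted; hydrogens and mass weighting are a caller's choice via
the selection. Free N-/C-terminal tails are included unless masked —
tail-dominated low modes are expected behaviour of kinase-domain
trajectories, not an artifact the package suppresses.

## Interaction networks

Detection is residue-level: any qualifying atom pair makes the
residue pair present in a frame, once. Defaults (exposed on
`ContactCriteria`): salt bridge = basic nitrogen (Lys NZ; Arg
NE/NH1/NH2; His ND1/NE2) within 4.0 Å of an acidic oxygen (Asp
OD1/OD2; Glu OE1/OE2); hydrogen bond = donor–acceptor heavy atoms
within 3.5 Å with a 120° donor–hydrogen–acceptor angle, or, when
hydrogens are absent, an acceptor–donor–antecedent proxy angle ≥ 90°
(antecedent = nearest heavy atom in the donor's residue).
Sequence-adjacent backbone N(i+1)···O(i) pairs are excluded — they
are one covalent bond apart. Residues missing their charged/polar
side-chain atoms are skipped with a logged warning, never an error
(truncated side chains are common in real structures).

A pair is *persistent* when its survival fraction (fraction of frames
present) reaches the threshold, default 0.6 — a value chosen so that
interactions weakened to ~70% survival still count as present, which
matches how "persistent" is used when comparing monomer and dimer
networks. The salt-bridge/H-bond label is a per-frame vote: salt
bridge if the charged-pair geometry fires in at least half of the
frames where the pair is present. This vote is the package's rule for
pairs that satisfy both geometries in different frames (e.g. an
Asp–Arg contact that is a salt bridge in one kinase and an H-bond in
a homolog); whether the original analyses used the same rule or
manual inspection is not documented anywhere, so the rule is stated
here and exposed.

**Conserved interactions.** The packaged interaction table aligns
homologous residue pairs across kinases on shared rows.
`conserved_interactions` intersects rows per state; with
`characteristic=True` it further drops rows that also occur in the
opposite conformational state of any queried kinase, leaving the
state-characteristic network — for the active conformation of
EGFR/ErbB2/ErbB4 that is exactly six interactions (two salt bridges
and four H-bond-class contacts coupling N-lobe, αC-helix, A-loop and
C-loop), while the characteristic inactive intersection is a single
row: the inactive state is sequestering, not network-building.

## Hydrophobicity from water density fluctuations

The raw statistic is χ = Vol_N · (⟨N²⟩ − ⟨N⟩²)/⟨N⟩² with N the
per-frame water-oxygen count in the observation volume and population
moments. χ is normalized by its value for bulk water far from the
protein, so χ* = 1 is neutral, χ* > 1 signals enhanced fluctuations
(a drier, more hydrophobic surface) and χ* < 1 suppressed
fluctuations (hydrophilic).

**Observation volume.** The union of spheres of radius 5.5 Å centered
on the region's heavy atoms, minus any point inside a protein heavy
atom's van der Waals sphere; volume estimated on a regular grid
(0.25 Å spacing; one KD-tree per distinct vdW radius keeps the
per-atom radii exact). No published definition of the observation
volume exists for this analysis; a first-shell-scale union is the
closest reading of a "volume of interest", and radius, spacing and
exclusion are all exposed parameters. Water is counted by oxygen
position only, making counts integers and unambiguous.

**Bulk reference.** The mean raw χ over n random congruent probes
(random rotation about the centroid plus random translation), each
fully inside the box and with every center at least a minimum
distance from any protein heavy atom. Seeded; placements and
therefore results are bit-reproducible. Since congruent probes share
Vol_N, the normalized ratio is independent of the grid-estimation
error in the volume.

**Standard errors.** `chi_standard_error` is the delta-method SE of
V·s²/m̄² from sample central moments, exact to O(1/n) for independent
frames — which the synthetic water generator guarantees by
construction. Acceptance-style checks use 3 propagated SEs.

**SASA and quadrants.** Shrake–Rupley SASA (via biotite) with a 1.4 Å
probe, 960 sphere points, element vdW radii (C 1.70, N 1.55, O 1.52,
S 1.80, H 1.20 Å), computed for the region's atoms in the context of
the whole protein and averaged over frames. The χ*–SASA plane is
split at χ* = 1 (the physically meaningful neutral point) and a SASA
split that defaults to the median of the point set under comparison —
no universal SASA split exists, and a data-driven default is
reproducible. Quadrants: I low χ*/high SASA (hydrophilically
favorable), II high/high (fragile, perturbation sensitive), III
low/low (buried hydrophilic), IV high χ*/low SASA (hydrophobically
favorable). Boundary ties go to the lower quadrant index.

Whether the observation volume should be held fixed across systems
for the same region or recomputed per system is genuinely open; both
are possible (pass a prebuilt `ProbeVolume` to hold it fixed), and
neither is asserted as canonical.

## The signaling model

Mass-action only; concentrations in nM, time in minutes (declared in
the model metadata). The network: ligand binding (EGF→EGFR,
NRG-1β→ErbB3; ErbB2 is ligand-less), homo-/heterodimerization
including lapatinib-bound receptors (the inhibitor blocks catalysis,
never binding or dimerization), one-step internalization+degradation
of ligand-induced dimers into explicit sink species (so every
receptor, ligand, adaptor and enzyme obeys an exact conservation law
— the moiety vectors are verified against the stoichiometric matrix
at build time), catalytic production of phosphosites (pY1068, pY1173
on the EGFR tail; pErbB3), a generic ErbB phosphatase, adaptor
docking (Grb2+GAB-1 on pY1068, Shc on pY1173, PI3K on pErbB3 and on
the GAB-1 complex), the Ras→Raf→MEK→ERK chain, and PI3K→PIP3→AKT
with PTEN as an explicit enzyme–substrate cycle. ErbB4 is omitted
(weak or absent signaling in the relevant cell lines); trafficking
beyond one-step internalization is not modeled.

Phosphorylation is *trans*: each dimer species carries a multiplier
equal to the number of catalytically competent kinases facing a
substrate tail, so a half-inhibited homodimer still phosphorylates
its blocked partner's tail at half rate, and fully inhibited dimers
carry zero flux. ErbB3's catalytic rate is 1/1000 of the canonical
rate (`erbb3_cat_scale`), the single structural constant of the
weak-pseudokinase hypothesis; NRG-elicited EGFR/ErbB3 heterodimers
are included but weak.

**Saturable PTEN.** PTEN is modeled as binding + catalysis rather
than a single catalytic step. This is both more realistic (enzymes
saturate) and load-bearing: when PI3K flux exceeds PTEN's maximal
turnover, PIP3 switches on sharply, which is what lets a weak
ErbB3-homodimer drive restore most of the AKT signal once ErbB3 is
over-expressed, while leaving near-basal signal below threshold.

**Parameters and calibration.** No authoritative rate-constant set
exists for this exact network; the packaged set
(`data/signaling_params.yaml`) is the package's own, produced by
`scripts/calibrate_signaling.py`. Structural constants (the 1/1000
ErbB3 scale, lapatinib's catalysis-blocking mechanism) are fixed;
three quantities are solved by root-finding: the L834R Y1173 and
Y1068 phosphorylation scales (so the mutant shows a 5-fold lower peak
pERK and a 15% lower peak pAKT than wildtype under 8 nM EGF at normal
expression), and the ErbB3 homodimerization rate (so 2× surface
ErbB3 under saturating lapatinib restores peak pAKT to 60% of the
no-inhibitor control at 25 nM NRG-1β). Everything else is a
plausible-scale choice held fixed. The calibrated set then also
reproduces, without being fit to them: ~97% restoration at 100 nM
NRG-1β; a small (~28%) but strictly positive residual at 1× ErbB3;
sustained deletion-mutant signaling at late times with
ligand-independent basal activity for both mutants; and the
sensitivity sign structure below. The L834R/T766M profile sets the
Y1068/Y1173 rates to exactly 100× wildtype.

**Readouts.** "Activation" defaults to the peak of pERK or pAKT over
0–60 min (configurable: integral and value-at-t are provided; the
readout is stated in every scenario). "Over-expressed EGFR" means 10×
surface receptors — a declared assumption, exposed in the scenario
config, since no factor is documented.

**Simulation.** LSODA with an analytic Jacobian, rtol 1e-8, atol
1e-10 by default; conservation drift across all moieties is recorded
in the diagnostics and stays below 1e-6 relative; solver negatives
stay above −1e-9 and are clipped only for reporting.

**Sensitivity analysis.** Local: normalized logarithmic coefficients
S = d ln y/d ln p by central differences (default step 5%), over rate
constants and species totals alike — cellular perturbations are
mostly expression-level. Global: Latin-hypercube sampling in
log-space with partial rank correlation coefficients, seeded.
Under 25 nM NRG-1β the model's pAKT sensitivities rank ErbB3 and
NRG-1β first, ErbB2 next, EGFR near zero; PTEN and the ErbB
phosphatase are negative; adding saturating lapatinib roughly doubles
the ErbB3/NRG-1β coefficients and collapses the EGFR/ErbB2 ones. The
package computes these at run time (nothing here is asserted that
`tests/` and `scripts/acceptance.py` do not recompute).

**Fitting.** `fit_rate_constants` is a bounded log-space
least-squares with seeded Latin-hypercube multi-start (≤5 free
parameters); parameters whose Jacobian column is numerically flat at
the optimum are flagged non-identifiable.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical* structure the analyses
consume, with exact ground truth, not the physics of real systems:

- **Toy kinases** are hairpin poly-alanine chains (10 Å strand gap)
  with labeled helix/loop segments and Lys/Glu pairs whose NZ/OE
  atoms bridge the gap at salt-bridge distance. Geometry is designed
  so the planted contacts are the only inter-residue polar contacts —
  that is what makes exact precision/recall statements possible, and
  it is also why passing them says nothing about crowded real
  interfaces.
- **Planted-mode trajectories** superpose orthonormal sinusoidal
  displacement patterns (projected out of the rigid-body subspace, so
  superposition cannot mix them) on isotropic Gaussian noise. A
  sampled sinusoid of amplitude A has variance A²/2, giving exact
  expected eigenvalues. Real anharmonic, correlated protein motion is
  not emulated.
- **Water boxes** resample positions independently every frame
  (ideal-gas dynamics): the χ statistic depends only on count
  marginals, and independence makes the SE formulas exact. The
  Poisson model fills the box at 0.0334 Å⁻³ (liquid water number
  density); the suppressed (binomial from a fixed pool) and enhanced
  (two-state Poisson mixture, ±50% density) models apply their
  statistics inside a central target sphere with Poisson bulk
  outside, emulating a hydrophilic or hydrophobic surface patch
  without any surface physics. Waters not realised in a frame are
  parked far outside the box so no probe can count them.
- **Planted interaction traces** switch each pair's NZ between an
  in-contact and a >8 Å position by independent Bernoulli draws;
  targets 0 and 1 are honoured deterministically.
- **Signaling datasets** multiply simulated trajectories by lognormal
  noise with mean 1 and the stated CV.

Every generator is a pure function of (recipe, seed).

## Numerical choices and degenerate inputs

- Coordinates are Å internally everywhere; XTC's native nm is
  converted at the I/O boundary, and XTC writing uses 5 stored
  decimal places so round trips hold to <1e-3 Å.
- PDB parsing keeps altloc 'A' or blank and drops others
  (deterministic single conformer); author residue numbering is never
  changed; parse errors name the offending line.
- Collinear superposition selections, empty regions/selections,
  zero-mean water counts, non-positive bulk χ, out-of-span residue
  positions, unknown mutant/inhibitor ids and frame/topology shape
  mismatches all raise typed errors (`erbbscale.errors`); persistence
  thresholds above 1 warn and return an empty network.
- Quadrant boundary ties go to the lower quadrant index (documented
  tie-break, tested by ±ε perturbation).

## Known limitations

- The analysis sizes here are desk-scale. MD-derived magnitudes
  (absolute SASA means of real spine regions, top-10 eigenmode
  variance fractions of real kinase trajectories, per-pair survival
  values of real monomer/dimer systems) require the original
  trajectories; the test suite substitutes property-based checks with
  planted ground truth at sizes that run in seconds to minutes
  (water boxes ≤2000 frames, trajectories ≤2000 frames, LHS ≤500
  samples).
- The signaling rate constants are calibrated, not measured; they
  make the model's behaviour reproducible, not predictive for any
  particular cell line. Receptor trafficking, stochastic kinetics and
  spatial effects are out of scope.
- The ErbB2/3/4 numbering offsets are not packaged (only EGFR's +24
  is documented); they raise lookup errors unless user-configured.
- Several packaged residue lists (EGFR/ErbB4 hydrophobic core, the
  EGFR αC-β4 span, non-EGFR spines) are provisional homology-based
  reconstructions and are flagged as such in `regions.csv`.
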