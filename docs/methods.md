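# Methods

This note documents the models, numerical choices and known limitations
of the `emip` package, in the order the pipeline runs them.

## Interaction model and unit system

Molecules are **rigid bodies**: a topology fixes the body-frame site
geometry, and a pose is a position plus a unit quaternion. Torsional
flexibility is deliberately not modelled — the statistics this package
computes (shell populations, funnel head-counts, relative cavity
energies) are all exercisable with rigid o-PD-like and water-like
molecules, and rigidity keeps every energy a pure pairwise sum.

The pair potential is OPLS-style nonbonded only:

    U_ij = Σ_ab 4 ε_ab [ (σ_ab/r_ab)¹² − (σ_ab/r_ab)⁶ ] + C q_a q_b / r_ab

with geometric-mean combining rules for both σ and ε,
C = 332.06371 kcal mol⁻¹ Å e⁻², k_B = 0.0019872041 kcal mol⁻¹ K⁻¹, and
one fixed unit system (Å, kcal mol⁻¹, K, atm, elementary charges).
Pressure–volume work converts through
1 atm = 1.458 40 × 10⁻⁵ kcal mol⁻¹ Å⁻³.

**Cutoff handling.** A pair of molecules interacts if and only if the
minimum-image distance between their site centroids is at most the
cutoff; inside the cutoff every site pair contributes, with the LJ term
shifted to vanish at the cutoff distance and Coulomb plainly truncated.
The molecule-based criterion keeps whole molecules switching together,
which matters downstream when cavity energies are compared. Straight
truncation of the electrostatics (no Ewald sum) is a documented
approximation: at desk-scale box sizes and for the population/funnel
statistics being tested, lattice-sum corrections change no conclusions,
and the error is absorbed into the toy parameterization.

Cavity (cluster) energies use the same functional form but isolated:
no periodic images, no cutoff, no shift.

## NPT Monte Carlo

Displacement moves pick a molecule uniformly and either translate it
(uniform in a cube of half-width `max_translation`) or rotate it about
a uniform random axis by an angle uniform in ±`max_rotation`;
single-site molecules only translate. Acceptance is the standard
Metropolis min{1, exp(−βΔU)}.

Volume moves (probability `volume_move_frequency`) are uniform in ln V
with acceptance

    min{1, exp(−β[ΔU + PΔV] + (N+1)·ln(V′/V))},

scaling molecule centers, not sites. A proposed volume that would drop
any box edge below twice the cutoff is auto-rejected. Default move
amplitudes (1.0 Å, 0.8 rad, ln V step 0.1) are tuned to the dilute toy
boxes this package ships, giving roughly 40–70 % acceptance there;
every study sets its own amplitudes explicitly in config.

The total energy is tracked incrementally (ΔU of the moved molecule)
and a full O(N²) recomputation is available; the test suite holds the
drift below 10⁻⁸ kcal mol⁻¹ over 10⁵ moves. Parallel runs are
logically independent chains seeded from (seed, run index); the
determinism contract is bitwise reproducibility of frames given the
spec, not any execution-order guarantee.

**Validation oracles.** Two closed-form checks pin the sampler: the
ideal-gas NPT mean volume ⟨V⟩ = (N+1) k_B T / P at N = 50 (the +1 is
the Jacobian of ln-V sampling), and the two-particle LJ separation law
p(r) ∝ r² exp(−βU(r)) for r ≤ L/2, compared by Kolmogorov–Smirnov
distance against numerical quadrature. Sizes (2×10⁵ steps, 10⁵
samples) were chosen so both tests resolve a 2 %/0.02 tolerance with
comfortable statistical margin.

## Layered starting box

The starting configuration mirrors the imprinting recipe: a monomer
slab in the lower half, an aqueous slab in the upper half, and the one
template centered on the dividing plane. The cubic box edge comes from
the total molar mass and a target density; molecules sit on jittered
lattices with random orientations, placed sequentially with
per-molecule retries until no two inter-molecular sites are closer than
0.85 σ_ij. Anchors inside the template's contact radius are skipped.
The jitter amplitude shrinks with the slack between the lattice spacing
and the same-species contact distance, so near-liquid-density aqueous
slabs still place cleanly; the practical ceiling for the toy force
field is about 0.75–0.9 g cm⁻³ depending on composition. The full-size
composition (1 template, 601 monomers, 5 000 waters) builds in a few
seconds; routine desk runs use 30–60 monomers and 60–500 waters.

## First solvation shell and cavity funnel

A monomer belongs to the template's first shell when its minimum-image
minimum site–site distance to any template site is at most the shell
cutoff. The default cutoff is 4.0 Å; alternatively
`shell_cutoff_from_rdf` histograms template–monomer minimum distances
over a trajectory and returns the first local minimum after the first
peak (moving-average smoothing, parabolic refinement over three bins),
the standard "first RDF minimum" reading of a solvation shell. Solvent
is never a shell member. Extraction is verified against an O(N²)
brute-force double loop on every tested frame.

Relaxation is greedy rigid-body coordinate descent on the isolated
cluster: cycles over molecules trying axis-aligned translations and
rotations, keeping only energy-lowering moves, halving step sizes when
a cycle improves less than the stage tolerance, terminating when the
translation step falls below 10⁻⁴ Å. The two stages differ **only** in
their per-cycle tolerance (10⁻² vs 10⁻⁴ kcal mol⁻¹), mirroring a
coarse→fine optimization hierarchy without any quantum chemistry; the
descent is monotone by construction and recovers the LJ-dimer minimum
r = 2^(1/6) σ to 10⁻³ σ.

The funnel applies, in order: group by monomer count; restrict to the
configured group range; stage-1 relax and keep members within the
stage-1 window (default 10 kcal mol⁻¹, **inclusive** ≤) of their *group*
minimum; stage-2 relax survivors and keep those within the stage-2
window (default 5 kcal mol⁻¹) of the *overall* minimum; final
single-point rescoring. Per-group at stage 1 and global at stage 2 is
a deliberate reading of the two cuts' different reference points; the
thresholds' inclusive semantics and the tie-break for "most stable"
(lower energy, then fewer monomers, then earlier provenance step) are
fixed so reports are deterministic. Survivor counts are monotone
non-increasing across stages and each group's minimum always survives
its own stage-1 cut.

Binding energies are stored signed (negative = stabilizing); reports
that discuss magnitudes print |BE|.

## QTAIM tables and the Espinosa relation

The package consumes bond-critical-point property tables (CSV, atomic
units) rather than wavefunctions. Classification is a pure function of
(∇²ρ, H): non-covalent iff ∇²ρ > 0 and |H| ≤ h_tol, covalent iff
∇²ρ < 0, otherwise ambiguous. The "close to zero" window defaults to
h_tol = 0.005 a.u. — a typical closed-shell threshold — and is
configurable because the qualitative label can be sensitive to it.
H is reconstructed as V + G when absent and validated against V + G to
10⁻⁶ a.u. when present. The Espinosa estimate BE = V/2 is converted at
627.5095 kcal mol⁻¹ per hartree with the sign preserved.

## Electroanalysis

**SWV peaks.** A linear baseline through the current minima flanking
the in-window maximum, then ip = max of the corrected current and Ep
from a three-point parabolic refinement. Flat traces and monotone ramps
raise a "peak not detected" error, matching how non-responding
interferents are reported. The flanking-minima baseline is the simplest
defensible rule; it recovers a 10 μA Gaussian peak on a sloped
background to 0.1 μA and 2 mV.

**Calibration.** Ordinary least squares; LOD = 3.3 s/|slope| and
LOQ = 10 s/|slope|, so LOQ/LOD is fixed at 10/3.3. The noise estimate s
is the intercept standard error by default, or a supplied blank
standard deviation — the former is what a calibration line alone can
provide, the latter is what replicate blanks provide; published limits
rarely state which rule produced them, so both are explicit options.

**EIS.** The fitted circuit is R_s + (R_ct ∥ CPE) with CPE impedance
1/(Q(jω)ⁿ) — a single depressed semicircle, which is the feature the
charge-transfer-resistance readout relies on; a Warburg branch is out
of scope. Fitting is complex nonlinear least squares on residuals
weighted by 1/|Z| (modulus weighting, standard for spectra spanning
decades), with bound constraints, asymptotic standard errors from the
Jacobian, and explicit flagging of parameters pinned at bounds (a pure
resistor pins R_ct low, for example). Initial guesses come from the
high-frequency real limit (R_s), the real-axis span (R_ct) and the
−Im(Z) apex (Q).

**Film thickness.** h = q·M/(ρ·A·n·F) with q in C, M in g mol⁻¹, ρ in
g cm⁻³, A in cm², yielding cm and reported in nm. The polymer density
defaults to 1.2 g cm⁻³ (the customary assumed value for poly(o-PD));
the electron count n is never defaulted silently in the CLI because it
is mechanism-dependent. The polymerization charge comes from the
baseline-corrected trapezoidal integral of the anodic peak divided by
the scan rate, summed over cycles.

## Synthetic data and what it does (not) show

The toy force field is a deliberately small stand-in: a +1 cationic
template with three acceptor oxygens and an amine nitrogen buried
behind a bulky shield site (so the charged group is sterically
hindered, as in the protonated analyte), a neutral monomer with an
aromatic-core site and two amine donors, and one-bead water. The site
masses use grouped-fragment pseudo-elements so the monomer weighs
exactly 108.14 g mol⁻¹. Charges and LJ parameters were chosen once so
that the canonical donor–acceptor approach has its energy minimum at
2.9 Å (within the 2.8–3.2 Å hydrogen-bond range) at about
−1 kcal mol⁻¹; the carbonyl-side acceptor adjacent to the cation is
blocked, which is chemically sensible but means not every acceptor is
productive.

The cavity-count fixture places the requested number of monomers on a
near-uniform (Fibonacci) sphere with the min site–site distance bisected
to 3.3 Å (inside the 4.0 Å cutoff) plus decoys at 8 Å (outside it), so
extraction reproduces the requested counts exactly; the generator
re-extracts every frame as a self-check. The preset 616-count
distribution (80/126/140/114/88/68 for sizes 18–23) is **authored to
match printed population percentages, not re-simulated**: passing the
population tests shows the counting and reporting machinery is exact,
not that the toy force field reproduces full-scale shell statistics.
Desk-scale MC runs of the toy system give shells of roughly 4–8
monomers; the tens-of-monomers range requires the full-size box and a
full force field, both out of scope.

Calibration and EIS generators add, respectively, additive Gaussian
noise of the blank standard deviation and proportional complex Gaussian
noise (std `noise_fraction`·|Z|/√2 per quadrature); BCP generators draw
non-covalent rows from documented ranges (∇²ρ ∈ (0.02, 0.15), V ∈
(−0.03, −0.002), |H| ≤ 0.004 a.u.) with labels kept as ground truth.
All generators are deterministic per seed and emit their truth as
sidecar files. None of them model drift, electrode fouling, correlated
instrument noise, or multi-peak voltammograms beyond what the tests
construct explicitly.

## Known limitations

- Rigid molecules; no torsional reparameterization, no intramolecular
  terms.
- Truncated Coulomb (no Ewald/PME); acceptable at desk scale, wrong
  for large charged systems.
- Whether a step count means single-move attempts or per-molecule
  cycles is left abstract; all frame arithmetic is expressed in strides
  of recorded steps, so the 616-frame bookkeeping holds either way.
- The classical relax-and-rescore funnel preserves the topology of a
  coarse→fine quantum-chemical protocol but none of its energetics;
  absolute cavity energies here are toy numbers.
- Enantiomer-specific modelling is not attempted; the toy template is
  achiral by construction, consistent with treating the analyte as a
  racemate.
- Temperature and pressure default to 298 K and 1 atm as assumptions;
  thermalization lengths are configuration choices, not derived values.
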