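# Methods

## The problem this package models

Inward-rectifier potassium (Kir) channels are gated by the signalling lipid
PI(4,5)P₂, which binds at the interface between the transmembrane and
cytoplasmic domains of each of the four subunits. Closely related
phosphoinositides — PI(3,4,5)P₃ and PI(3,4)P₂, differing only in the number
and ring position of the inositol phosphates — activate Kir2.2 weakly or not
at all. The computational anatomy of that selectivity consists of (a)
relative binding free energies from alchemical free-energy perturbation
(FEP) over a thermodynamic cycle, and (b) trajectory statistics — residue
contact ratios, hydration-shell counts, salt-bridge distances and
pore-radius profiles — that explain *why* the free energies come out as they
do.

This package implements that full analysis stack and exercises it on toy
systems whose answers are known exactly (closed forms or low-dimensional
quadrature). The published cluster-scale simulations themselves are not
reproducible on a desk; their printed leg values are treated as *inputs* to
the cycle arithmetic, and every sampling-dependent claim is validated
against synthetic ground truth instead.

## Alchemical model

Two end states V₁ (reference ligand, λ = 0) and V₂ (mutant, λ = 1) are
coupled linearly, V(λ) = (1−λ)V₁ + λV₂, with two standard refinements:

* **Soft-core van der Waals.** Perturbed pairs replace the 12-6 form with
  the separation-shifted soft-core

  V_sc(r) = 4 ε λₑ [ (σ⁶/(α(1−λₑ)σ⁶ + r⁶))² − σ⁶/(α(1−λₑ)σ⁶ + r⁶) ],

  where λₑ is λ for appearing pairs and 1−λ for disappearing ones, and
  α = 0.5 (configurable). The form is finite at r = 0 for λₑ < 1 and equals
  the plain 12-6 potential exactly at λₑ = 1, which removes the end-point
  catastrophe. The soft-core family and α are a package choice among the
  standard variants; both endpoint identities are property-tested.
* **Staged electrostatics.** Appearing atoms' charges switch on linearly
  only after λ > 0.1 (ramp (λ−0.1)/0.9), disappearing atoms' switch off by
  λ = 0.9 (ramp 1 − λ/0.9), so soft-core repulsion resolves overlaps before
  Coulomb forces act. Appearing–disappearing pairs never interact.

Per-atom external wells carry their own end-state stiffnesses and
interpolate linearly in λ; a receptor-site well that exists in only one end
state uses zero stiffness for the other. Lorentz–Berthelot combining rules;
units kcal/mol, Å, elementary charges; k_B = 0.0019872041 kcal/(mol·K),
Coulomb constant 332.0636 kcal·Å/(mol·e²); default temperature 303.15 K.
No periodic electrostatics — toy systems use direct sums; an optional plain
12 Å truncation exists for the vdW term but is off by default.

## Sampling

Each λ window is sampled with seeded Metropolis Monte Carlo at V(λ): the
study's molecular-dynamics windows only need a Boltzmann ensemble, and MC
provides that without integrator or thermostat machinery. Defaults keep the
study's protocol counts: 4000 equilibration sweeps, 200 000 production
samples per window (scaled down in tests and drivers, see below), 5
replicates. The maximum displacement is auto-tuned toward 40% acceptance
during equilibration and frozen before production so the production chain
is a fixed-kernel Markov chain. Replicates differ by a derived seed
(seed + run index) and a 0.1 Å Gaussian jitter of the initial mobile
coordinates; each window chain starts from the previous window's final
configuration. Samples are recorded every sweep. A window records the
forward difference V(λ_next) − V(λ) split exactly into electrostatic, vdW
and external components.

## Estimation

Per window, the free-energy increment is the Zwanzig exponential average
ΔG_λ = −kT ln ⟨exp(−β ΔV)⟩_λ, computed with log-sum-exp; a leg is the sum
of its window increments over the 21-point ladder
λ = 0, 10⁻⁵, 10⁻⁴, 10⁻³, 0.01, 0.05, 0.1, 0.2, …, 0.9, 0.95, 0.99, 0.999,
0.9999, 0.99999, 0.999999 (dense at both ends where the soft-core
transformation is steep). The final λ is treated as the end state; the
residual coupling of 10⁻⁶ is far below replicate error on every system
tested. Component free energies apply the same exponential average to the
stored per-sample components, and the coupling term is *defined* by
ΔG_couple = ΔG − ΔG_elec − ΔG_vdW, so the decomposition identity is exact
by construction and all non-additivity lands in the coupling term. Reported
values are plain means over replicates with se = sd/√n; a single run
reports se as NaN. Backward legs re-run the mutation in the opposite
direction; samples are never reused.

Cycle arithmetic: ΔΔG = ΔG_bound − ΔG_free, applied component-wise, with
leg errors combined in quadrature under an independence assumption (the
published table reports per-leg errors only). Display rounds half-even to
one decimal, mirroring the published table; JSON reports keep full
precision.

## Trajectory statistics

* **Contacts.** An atom is in contact when it lies within 5 Å (inclusive)
  of *any* ligand heavy atom; heavy means element ≠ H. The residue contact
  ratio q_r sums the per-atom contact probabilities of the residue's heavy
  atoms, with equivalent copies across the subunit chains averaged per
  (frame, chain) before summation, so 0 ≤ q_r ≤ heavy-atom count. The
  per-atom contact test is applied against the full ligand selection (all
  chains); in the fixtures chains are 140 Å apart, so cross-chain contacts
  cannot occur, and the order of averaging (over subunits after the per-atom
  any-ligand-atom test) is thereby fixed and documented here.
* **Contact differences.** Δq = q_MUT − q_WT per residue (missing residues
  count as 0), aggregated into Δq₍₊₎, Δq₍₋₎ and Δq_all = Δq₍₊₎ + Δq₍₋₎;
  residues with |Δq| > 0.5 are highlighted.
* **Hydration.** A water is in the first shell when its oxygen lies within
  the shell radius (inclusive) of any solute heavy atom. The shell radius
  defaults to 3.5 Å — a conventional first-shell distance for phosphate
  oxygens; the source study never states the radius behind its water
  counts, so it is configurable. Desolvation = mean free count − mean
  bound count.
* **Salt bridges.** Minimum pairwise distance between the heavy atoms of
  two selections; hydrogens are excluded even if selected.
* **Pore profile.** At each z slice, the radius of the largest probe sphere
  whose center is optimized on a bounded (x, y) grid around the pore axis
  (default: x/y center of geometry; half-width 5 Å, step 0.2 Å), where a
  center's clearance is min over atoms of (3-D distance − vdW radius);
  radii clip to [0, 15 Å] and empty neighbourhoods report the cap. This is
  a per-slice inscribed-sphere search in the spirit of HOLE-style profilers,
  without sphere propagation; vdW radii come from a bundled Bondi table
  (override per atom or per element).
* **RMSD/RMSF.** Optimal rigid (Kabsch) superposition onto a reference
  frame; RMSF is the per-atom fluctuation about the mean superposed
  structure, averaged per residue.

Selections are exact matches on chain / residue id / residue name / atom
name / element, with an optional heavy-atom filter.

## Synthetic ground truth

* **Harmonic alchemy** — one particle whose per-axis well stiffness morphs
  k₁ → k₂ on 1–3 axes; ΔG = (dims·kT/2) ln(k₂/k₁) exactly. Non-morphing
  axes keep a fixed stiffness so the chain stays bounded while contributing
  nothing.
* **Gaussian work** — i.i.d. N(μ, σ²) forward differences;
  ΔG = μ − σ²/(2kT) exactly. Defaults μ = 1, σ = 2 kcal/mol make the
  exponential average genuinely heavy-tailed (σ/kT ≈ 3.3) without being
  unestimable at n = 10⁵.
* **Toy binding cycle** — a two-well "phosphate shift": a disappearing atom
  near a strong frozen cationic site and an appearing atom near a weak one,
  plus a frozen anchor atom present in both legs; the free system drops the
  site atoms. Stiff flat-bottom wells (k = 300 kcal/mol/Å², radius 0.75 Å)
  stand in for the bonded terms that keep a real phosphate on its ring
  carbon — and, critically, keep oppositely charged atoms out of the
  Coulomb singularity at intermediate λ, where soft-core repulsion alone is
  too weak. With the default charges the mutation weakens binding
  (ΔΔG ≈ +4.7 kcal/mol), mirroring the sign of the real phosphate-shift
  mutations. Ground truth comes from per-atom 3-D Gauss–Legendre quadrature
  of both partition-function ratios (the mobile atoms do not interact with
  each other, so the integral factorizes; the oracle refuses systems where
  they do, or with more than 6 dimensions). Every oracle value is
  cross-checked against a doubled-resolution grid to 10⁻⁶ relative.
* **Trajectories** — 4 chains of a 4-atom ligand plus residues whose tagged
  heavy atoms sit inside the 5 Å shell with prescribed Bernoulli
  probabilities, independently per frame and chain; 3-site waters placed so
  that exactly n oxygens occupy the hydration shell every frame (so the
  hydration truth is exact, not statistical). A permanently in-shell
  hydrogen per residue exercises heavy-atom filtering.
* **Ring channels** — stacked atom rings on the z axis. The exact inscribed
  radius at a ring is min over rings of √(R_k² + Δz²) − r_vdW; the default
  spacing is chosen so no ring shadows another and the truth reduces to
  R − r_vdW.

All generator randomness flows from one integer seed; a fixed seed gives
byte-identical files (PDB fixtures, CSV samples, JSON sidecars carrying the
truth values).

What the fixtures deliberately do not emulate: membrane and solvent
degrees of freedom, bonded force-field terms, correlated protein motions,
and long-range electrostatics. Passing tests therefore certify the
*machinery* — estimators, bookkeeping, geometry — not the force-field
accuracy of any real-system prediction.

## Problem sizes in tests and drivers

The acceptance checks run the harmonic legs at 5 runs × 20 000 production
samples per window (the package's standard validation size; the study-scale
200 000 default remains for real use) and the toy binding legs at 5 × 10 000
with 2000 equilibration sweeps, sizes at which the replicate standard error
is a reliable yardstick and the whole suite runs in about a minute.
Statistical assertions use 3-standard-error bands: replicate SE for legs,
bootstrap SE (200 resamples) for single-window estimates, binomial SE for
contact ratios.

## Numerical choices and edge cases

* Exponential averages in log space; a window containing non-finite samples
  is an error, never a warning.
* Null perturbations produce dV ≡ 0 exactly (identical coefficient tables
  at both λ), so ΔG = 0 with zero error, independent of seed.
* Contact and hydration boundaries are inclusive (distance = cutoff
  counts); documented because the source protocol states only the cutoffs.
* The published free-leg coupling value 17.0 for the PI(3,4)P₂ mutation is
  inconsistent at one-decimal rounding with its own identity
  (24.6 − 20.3 − (−12.6) = 16.9); the package derives coupling terms from
  the identity, so that cell reads 16.9.
* The published per-residue contact-change table is only partially printed;
  the bundled reconstruction keeps the highlighted residues and folds the
  sub-threshold remainder into explicit "other(±)" entries so the published
  aggregates are exact sums (labelled synthetic in the code).
* Quadrature boxes extend to where the well energy exceeds 40 kT;
  Gauss–Legendre node counts double until two successive levels agree to
  10⁻⁶ relative, else the oracle raises.
* Pore slices far from all atoms report the configured cap (15 Å) rather
  than infinity.

## Known limitations

* The Zwanzig estimator is forward-only by design (matching the modelled
  protocol); BAR/MBAR would use the same samples better but is out of
  scope.
* Replicate SE understates error when a window is systematically
  under-sampled; the forward/backward closure check in the validation
  driver is the intended guard.
* The quadrature oracle requires non-interacting mobile atoms (≤ 6
  dimensions); richer toy systems would need a different oracle.
* The Metropolis chain is pure Python and deliberately simple; it is sized
  for few-particle toys, not condensed-phase systems.
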