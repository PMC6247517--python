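# pipfep

Alchemical free-energy perturbation and trajectory statistics for
phosphoinositide selectivity on inward-rectifier potassium channels —
implemented as a tested pipeline and exercised on toy systems with exact
ground truth.

## The problem

Kir2.2 is activated by PI(4,5)P₂ but barely by its isomers PI(3,4,5)P₃ and
PI(3,4)P₂. The standard computational dissection of that selectivity has
two halves:

1. **Relative binding free energies.** Alchemically mutate the bound and the
   free ligand (PI(4,5)P₂ → mutant) over a λ ladder, estimate each leg with
   the Zwanzig exponential average
   ΔG_λ = −kT ln ⟨exp(−β[V(λ+Δλ) − V(λ)])⟩_λ, and close the thermodynamic
   cycle: ΔΔG = ΔG_bound − ΔG_free, with electrostatic / van der Waals /
   coupling components (ΔG_couple = ΔG − ΔG_elec − ΔG_vdW).
2. **Mechanistic statistics.** Residue contact ratios q_r (per-heavy-atom
   contact probabilities within 5 Å of the ligand, summed per residue),
   their mutation differences Δq, first-hydration-shell water counts and
   desolvation, salt-bridge heavy-atom distances, and pore-radius profiles
   along the channel axis.

This package provides both halves as a library (`src/pipfep/`), a CLI
(`pipfep`), narrative drivers (`analysis/`), and a synthetic-data module
whose generators embed their own analytic or quadrature ground truth — soft-
core λ-coupling, a seeded Metropolis sampler, the 21-window schedule,
cycle bookkeeping, and multi-model-PDB trajectory statistics are all
first-class, tested code. See `docs/methods.md` for the model details.

## Worked example: the Kir2.2 cycle arithmetic

The published leg free energies for the two ligand mutations are bundled as
example data; the cycle module turns them into the headline numbers:

```python
from pipfep.cycle import component_ddg
from pipfep.data import PIP2_TO_PIP3

res = component_ddg(PIP2_TO_PIP3)
print(f"ddG = {res.ddG:.1f} kcal/mol (elec {res.ddG_elec:.1f}, "
      f"vdw {res.ddG_vdw:.1f}, couple {res.ddG_couple:.1f})")
```

```
ddG = 13.9 kcal/mol (elec 13.7, vdw 2.0, couple -1.8)
```

i.e. mutating bound-and-free PI(4,5)P₂ to PI(3,4,5)P₃ costs 13.9 kcal/mol of
binding free energy, almost entirely electrostatic — the native ligand's
phosphates sit on their salt-bridge partners, the mutant's do not.
`analysis/01_cycle_arithmetic.py` prints the full two-mutation table
(ΔΔG = 39.7 kcal/mol for PI(3,4)P₂) plus the contact aggregates
(Δq_all = −1.06 and −6.05) and desolvation counts (17 vs 15 waters).

## Worked example: an alchemical leg with a known answer

```bash
pipfep gen harmonic --k1 1 --k2 4 --dims 1 --out ha
pipfep simulate --system ha.yaml --n-prod 4000 --n-equil 1000 --n-runs 3 \
    --seed 5 --out ha_windows.csv
pipfep fep-estimate --windows ha_windows.csv --out ha_leg
```

```
analytic dG = 0.417566 kcal/mol -> ha
3 runs x 20 windows -> ha_windows.csv
dG = 0.4157 +- 0.0076 kcal/mol (elec 0.0000, vdw 0.0000, couple 0.4157)
```

The sampled estimate agrees with the analytic partition-function ratio
(kT/2)·ln 4 within one replicate standard error. The same pattern runs the
toy binding cycle (`analysis/03_toy_binding_cycle.py`), where the sampled
ΔΔG is checked against a numerical-quadrature oracle, and the trajectory
statistics (`analysis/04_trajectory_statistics.py`,
`analysis/05_pore_profiles.py`), where contact probabilities and pore radii
are prescribed by construction.

## Layout

```
src/pipfep/        potentials, sampler, fep, cycle, traj_stats, synthetic,
                   pdbio, cli, data (bundled published example values)
analysis/          numbered narrative drivers writing to results/
tests/             pytest suite incl. acceptance checks
scripts/           acceptance.py
docs/methods.md    model, assumptions, numerical choices, limitations
```
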