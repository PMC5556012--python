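# rigidpmf

Rigidity-theoretic stability maps, umbrella-sampling free-energy profiles,
and Cα-trajectory PCA for studying how dimerization changes the mechanics
of multidomain enzymes — built around the analysis of the pyruvate
phosphate dikinase (PPDK) dimer, whose nucleotide-binding domains (NBDs)
open and close along a Cα–Cα reaction coordinate while the dimer interface
couples the two chains mechanically.

It is aimed at structural bioinformaticians who want the analysis layer of
such a study — the estimators, the rigidity machinery, and the diagnostics
— as tested, reusable components, with synthetic generators that make every
stage verifiable against known ground truth without any external data.

## What it computes

**Rigidity / stability maps.** A structure becomes a body-bar constraint
network (atoms = bodies with 6 degrees of freedom; covalent bonds 5–6 bars,
hydrogen bonds and salt bridges 5, hydrophobic tethers 2). The (6,6)
pebble game decomposes it into rigid clusters. Diluting hydrogen bonds
stepwise (E_cut from −0.1 to −6 kcal/mol in 0.1 steps) yields, per residue
pair (i, j), the energy rc_ij at which their rigid contact vanishes — the
stability map. The difference map

    Δrc_ij = rc_ij(dimer) − rc_ij(monomer A) − rc_ij(monomer B)

on conformations taken from the same frames isolates the effect of
dimerization, including long-range rigidity percolation: a single interface
interaction can stabilize residue pairs far from the interface.

**Free-energy profiles.** Umbrella windows with harmonic biases
½k(r − r0)² along the reaction coordinate are combined by WHAM into a
potential of mean force G(r), with Monte-Carlo block-bootstrap errors,
adjacent-window overlap coefficients, and a half-versus-all-data
convergence check.

**Trajectory analysis.** Two-pass RMS fitting on the least-fluctuating
residues, PCA of the 3N×3N Cα covariance with variance fractions, the
collectivity index κ = (1/N)·exp(−Σ Δr_i² ln Δr_i²) (κ = 1 for a uniform
mode, 1/N for a single active atom), and dynamic cross-correlation maps
with domain-block means.

**Synthetic data.** Toy monomer/dimer structures with planted, energy-
labelled constraints (the complete non-covalent ground truth is returned
alongside the PDB text), exact or Langevin samplers for biased Boltzmann
distributions of known 1D potentials, and Gaussian planted-mode Cα
trajectories with symmetric/antisymmetric two-block structure.

## Worked example

Plant one interface hydrogen bond (E = −2.0 kcal/mol, plus one hydrophobic
tether) between two rigidified 6-residue chains and measure what
dimerization does to the stability map:

```python
from rigidpmf import dilution_stability as ds, synthetic_data as sd
from rigidpmf.synthetic_data import PlantedBond, split_dimer_truth, stiffen_backbone

sched = ds.DilutionSchedule()                      # -0.1 -> -6.0, 60 states
planted = (stiffen_backbone("A", 1, 6) + stiffen_backbone("B", 1, 6)
           + [PlantedBond("hbond", "A", 6, "B", 1, -2.0),
              PlantedBond("hydrophobic", "A", 5, "B", 2, anchor="CA")])
_, truth = sd.toy_structure(n_res=6, kind="dimer", planted=planted)

dimer = ds.stability_map(truth["model"], sched,
                         hbonds=truth["hbonds"], tethers=truth["tethers"])
monos = []
for cid in ("A", "B"):
    sub, hb, te = split_dimer_truth(truth, cid)
    monos.append(ds.stability_map(sub, sched, hbonds=hb, tethers=te))
diff = ds.difference_stability_map(dimer, monos[0], monos[1])

res = diff.residues
print(diff.values[res.index(("A", 1)), res.index(("B", 6))])   # -2.1
```

The remote pair (A1, B6) — five residues away from the interface bond on
either side — prints `Δrc = -2.1`: the two chains stay in one rigid
cluster until the interface hydrogen bond drops out of the network at the
−2.1 kcal/mol dilution state, and every one of the 36 inter-chain backbone
pairs is stabilized by the same single bond, while all intra-chain entries
stay exactly 0. That is rigidity percolation: the stabilization is
long-range even though the added interaction is local.

On the free-energy side, 17 windows × 10⁴ biased samples of the planted
potential U(r) = 2(r − 34)² recover the profile with an RMS error of
0.019 kcal/mol over the well-sampled bins; at r = 36 Å the estimate reads
G = 7.594 ± 0.022 kcal/mol against the analytic 7.6 (the ± is the
200-trial bootstrap SD).

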