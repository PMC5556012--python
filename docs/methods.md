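# Methods

`rigidpmf` bundles three families of analyses used to ask how dimerization
changes the mechanics of a two-domain enzyme such as pyruvate phosphate
dikinase (PPDK): rigidity-theoretic stability maps with a
dimer-minus-monomers difference map, umbrella-sampling free-energy profiles
along the NBD opening-closing reaction coordinate, and Cα-trajectory PCA
with collectivity and cross-correlation summaries.  This note records the
models, the parameters that matter, and the design choices made where the
methodology was genuinely open.

## Structure bookkeeping

Structures are read from PDB text with Biopython.  HETATM records and
waters are dropped; alternate locations are resolved to the
highest-occupancy conformer, ties broken alphabetically by altloc id.
Residue numbering is 1-based author numbering.  Unresolved-residue
accounting compares the SEQRES-declared sequence length against the
resolved residue list per chain and refuses to guess when sequence records
are absent — a silent zero would hide exactly the situation the count is
meant to expose (e.g. 86 of 1748 residues missing from a dimer model).

The opening-closing reaction coordinate is the Cα–Cα distance between two
marker residues, defaulting to 215 and 272 (*F. trinervia* numbering) but
configurable because homologous structures use different numbering.  Open
and closed NBD states are classified against explicit cutoffs (defaults
36 Å / 33 Å, bracketing the crystallographic open ≈ 38.5 Å and closed
≈ 31 Å values); the thresholds exist so that event counting is reproducible
rather than anecdotal.

## Constraint networks and rigidity

Each atom is a rigid body with 6 degrees of freedom; interactions are bar
sets: covalent single bonds 5 bars (the dihedral stays free), peptide and
carbonyl double bonds 6 bars, hydrogen bonds and salt bridges 5 bars,
hydrophobic tethers 2 bars.  These counts follow the established body-bar
coarse-graining of protein rigidity analysis and are configurable in
`NetworkParams`.  One body per atom (rather than pre-grouped peptide
units) is a modelling choice: it keeps the network construction local and
lets the pebble game discover locked units itself.

Hydrogen-bond energies use a Mayo-style function,
`E = V0 (5 (R0/R)^12 − 6 (R0/R)^10) cos²θ cos²φ` with `V0 = 8 kcal/mol`,
`R0 = 2.8 Å`, `R` the donor–acceptor distance, `θ` the D–H···A angle and
`φ` the H···A–base angle; angles under 90° give no bond, and pairs beyond
3.6 Å are not considered.  When the structure carries no polar hydrogens,
backbone amide H positions are inferred from heavy-atom geometry; a
structure where nothing is inferable raises an error pointing at
protonation preprocessing.  The geometric pre-filters are deliberately
simple and are *not* claimed to reproduce any particular legacy
implementation's bond list; planted-constraint fixtures (below) keep the
downstream science testable independent of these details.  Salt bridges are
hydrogen bonds pinned at a floor energy (default −10 kcal/mol) so they
survive deep dilution.  Hydrophobic tethers join carbon/sulfur atoms with
no N/O neighbour when the gap over the van-der-Waals contact distance
(Bondi radii: C 1.70 Å, S 1.80 Å) is at most 0.35 Å, boundary inclusive.

Rigidity is decided by the (6,6) body-bar pebble game: each body holds six
pebbles, a bar is independent iff seven pebbles can be gathered on its two
endpoints, and two bodies share a rigid cluster iff no seventh pebble can be
brought onto the pair — an equivalence, since relative rigid transforms
compose.  Pebble searches are depth-first by ascending body id, so the
output is reproducible bit-for-bit.  Internal floppy modes are the free
pebbles beyond the six global motions.  An independent linear-algebra
oracle — the rank of the bar incidence matrix at random generic placements
— verifies both the mode counts (exhaustively for all networks with ≤ 4
bodies and ≤ 8 bars) and the cluster partition (200 random networks);
the oracle is used only in tests, never by the production path.

## Dilution stability maps and the difference map

A dilution trajectory lowers the hydrogen-bond inclusion cutoff `E_cut`
from −0.1 to −6.0 kcal/mol in 0.1 steps (60 network states); only hydrogen
bonds and salt bridges are removed, covalent bars and hydrophobic tethers
persist.  Grid states are rounded so that a bond of energy −2.3 is included
at the −2.3 state exactly.  For each residue pair the stability value
`rc_ij` is the *first* (least negative) state at which the Cα bodies of the
two residues no longer share a cluster — the energy at which the rigid
contact vanishes, not the last energy at which it is present.  Contacts
still rigid at −6.0 are PERSISTENT; pairs rigid at no state are NEVER.

Ensemble averaging resolves sentinels to numbers first (defaults:
PERSISTENT → E_end, NEVER → E_start) and records the policy.  The
difference map `Δrc = rc(dimer) − rc(monomer A) − rc(monomer B)` is taken
on conformations extracted from the same frames, so only interactions
across the interface — never conformational differences — can move it.  In
the difference map, NEVER resolves to 0: a pair that is rigid at no state
carries no dimerization signal, and this convention makes the
zero-interface control identically zero over the whole map, inter-chain
entries included.  Intra-chain entries subtract the matching monomer value;
inter-chain entries keep the dimer value.  Desk-scale ensembles default to
tens of frames (the jittered toy generator) rather than the thousands of
MD snapshots a production study would use; the maps average exactly the
same way in either regime.

## Umbrella sampling and WHAM

The bias is harmonic with the ½-convention, `U_bias = ½ k (r − r0)²`,
`k` in kcal/mol/Å².  Since a bare "force constant of 1 kcal/mol/Å²" is
ambiguous between the `k` and `½k` conventions, the convention here is
fixed by construction: the synthetic sampler generates data under the same
formula the estimator assumes, and a parameter-recovery test pins the pair.
Windows are planned inclusively from `rmin` to `rmax` (26–42 Å at 1 Å
spacing gives 17 windows).  `kB = 0.0019872041 kcal/mol/K`, default
temperature 300 K, default equilibration cut the first 5% of each window.

WHAM iterates the self-consistent equations on per-window histograms
(default 0.2 Å bins over the sampled support, tolerance 1e-6 on the window
constants, at most 1e5 iterations with explicit failure) in log space.
Support handling: occupied bins must form one connected run; disconnected
regions holding non-negligible mass raise an error naming the gap, while
isolated slivers under 0.5% of the mass (stray excursions) are trimmed with
a warning.  Errors come from Monte-Carlo bootstrap (default 200 trials)
over contiguous blocks whose length is the integrated autocorrelation time
estimate of each window, so time-correlated data are not treated as
independent.  Diagnostics: adjacent-window histogram overlap
`Σ_b min(p_i, p_j)`, and a half-versus-all-data convergence check that
ignores bins with fewer than 10 samples in the half data (their difference
measures shot noise, not drift).

For the synthetic recovery study — 17 windows × 10⁴ exact
inverse-CDF draws from the biased Boltzmann densities of
`U(r) = 2 (r − 34)²` — the analysis uses 0.1 Å bins: the rule of thumb is
that the potential drop across a bin should stay below ~2 kT at the
steepest well-sampled point (|U′| ≈ 12 kcal/mol/Å there), and the package
default of 0.2 Å violates it for this deliberately steep test potential.
Error statistics are quoted on bins holding at least 50 samples, and
bootstrap SDs at the umbrella reference points, the positions where such
errors are conventionally reported.  Two desk-scale caveats follow from
the fixture itself: the biased densities concentrate near the potential
minimum, so the identifiable support is roughly 31–37 Å even though
windows are planned out to 26 and 42 Å; and at the outermost in-support
reference points the local sample count bounds the achievable bootstrap SD
near 0.023–0.027 kcal/mol — interior references reach ≤ 0.015.  These are
properties of sampling a steep potential with weak biases, not of the
estimator.

## Trajectory PCA, collectivity, cross-correlation

Global motion is removed by a two-pass RMS fit: superpose all frames,
rank residues by RMSF, re-superpose on the least-fluctuating fraction
(default 15%).  The selection is refined once, not iterated, for
determinism, and the reference is the ensemble mean rather than frame 0.
PCA diagonalizes the full 3N×3N Cα covariance; eigenvalues are
mean-square mode fluctuations and variance fractions are eigenvalue
shares.  The collectivity index
`κ = (1/N) exp(−Σ Δr_i² ln Δr_i²)` with `Σ Δr_i² = 1` uses the natural
logarithm — the only base for which a uniform mode gives exactly κ = 1 —
and is bounded by 1/N (one active atom) and 1.  Cross-correlation maps use
the vector-dot-product convention
`C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨Δr_i²⟩⟨Δr_j²⟩)`; zero-variance residues are
zeroed off-diagonal with a warning rather than propagating NaNs.

## Synthetic data: what it emulates, what it does not

The toy structures are idealized poly-alanine-like backbones (N, CA, C, O,
CB; 3.9 Å residue spacing, dimer chains offset by 9 Å) whose geometry
plants *no* incidental hydrogen bonds or tethers, so the returned
constraint list is the complete non-covalent ground truth.  Planted
hydrogen bonds attach at Cα atoms and hydrophobic tethers at Cβ by
default; fixtures may anchor a tether at Cα to stand for a side-chain
contact whose side chain is internally rigid (a pendant Cβ body wastes a
constraint on its free spin and cannot transmit rigidity).  A run of
consecutive Cα–Cα bonds below the dilution end point (`stiffen_backbone`)
makes a backbone segment persistently rigid, giving fixtures with known
rigid halves.  Window seeding between end states is linear interpolation —
the package deliberately contains no normal-mode path generator.

The umbrella sampler draws either exact inverse-CDF samples from the
biased Boltzmann density (the estimator oracle) or overdamped
Euler–Maruyama Langevin steps (diffusion 1 Å²/time, dt 0.02, thinned), with
divergence reported rather than silently clipped.  Planted-mode
trajectories add Gaussian-amplitude orthonormal modes plus isotropic noise
to a base geometry, with symmetric/antisymmetric two-block constructors
mimicking coupled domain motions.

None of the generators model force fields, solvent, side-chain rotamers or
realistic protein topology.  Passing tests therefore demonstrate that the
estimators and the rigidity machinery are correct on data whose ground
truth is known — not that any particular biological system behaves a given
way, and not that the microsecond-MD-scale numbers of a production study
are reproduced.  Quantities that require long MD sampling (absolute
ΔG values of an opening-closing transition, experimental PCA variance
fractions, domain-correlation magnitudes, crystal-structure stability
maps) are out of desk-scale reach by construction.

## Known limitations

* The hydrogen-bond detector covers backbone amides and common polar side
  chains only; no π-stacking, metal coordination, or protonation-state
  prediction.
* The pebble-game implementation is tuned for clarity and determinism, not
  asymptotic speed; it is comfortable at thousands of bodies, not millions.
* The rank oracle is restricted to small networks (dense SVD).
* WHAM is 1D; multi-dimensional profiles and MBAR-style estimators are out
  of scope.
* Trajectory readers handle multi-model PDB and the plain-text table
  format only — no MD-engine binary formats.
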