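"""Synthetic inputs with known ground truth for every analysis stage.

Three generators:

* :func:`toy_structure` — idealized monomer/dimer backbones (N, CA, C, O, CB
  per residue) whose geometry produces no incidental hydrogen bonds or
  hydrophobic tethers, so the planted constraint list returned alongside the
  PDB text *is* the complete non-covalent ground truth.
* :func:`umbrella_sampler` — samples of a 1D reaction coordinate under a
  known potential plus harmonic umbrella biases (½ k (r−r0)²), either exact
  draws from the biased Boltzmann density (inverse-CDF) or an overdamped
  Langevin (Euler–Maruyama) walker.
* :func:`mode_trajectory` — Gaussian-amplitude planted normal modes on a Cα
  geometry, with optional symmetric/antisymmetric two-block structure
  mimicking coupled domain motions.

Every generator is deterministic under a fixed seed and returns the ground
truth needed by downstream assertions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constraint_network import (
    KIND_HBOND,
    KIND_HYDROPHOBIC,
    Constraint,
    NetworkParams,
)
from .pmf_wham import KB, UmbrellaWindow
from .structure_io import Atom, StructureModel, TrajectoryEnsemble, write_structure

__all__ = [
    "PotentialSpec",
    "PlantedModeSpec",
    "PlantedBond",
    "toy_structure",
    "umbrella_sampler",
    "analytic_pmf",
    "mode_trajectory",
    "two_block_mode_spec",
]


# ---------------------------------------------------------------------------
# 1D potentials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PotentialSpec:
    """1D reaction-coordinate potential with a known analytic form.

    forms: ``harmonic`` U = a (r − r_min)²; ``double_well``
    U = h ((r−c)² − w²)² / w⁴ (barrier height h between minima at c ± w);
    ``flat`` U = 0; ``piecewise`` linear interpolation of (r, U) knots.
    Parameters in kcal/mol and Å.
    """

    form: str
    params: dict = field(default_factory=dict)
    domain: tuple[float, float] = (0.0, 100.0)

    def u(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        p = self.params
        if self.form == "harmonic":
            return p["a"] * (r - p["r_min"]) ** 2
        if self.form == "flat":
            return np.zeros_like(r)
        if self.form == "double_well":
            c, w, h = p["center"], p["half_separation"], p["barrier"]
            return h * ((r - c) ** 2 - w**2) ** 2 / w**4
        if self.form == "piecewise":
            knots_r = np.asarray(p["r"])
            knots_u = np.asarray(p["u"])
            return np.interp(r, knots_r, knots_u)
        raise ValueError(f"unknown potential form {self.form!r}")

    def grad(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        h = 1e-5
        return (self.u(r + h) - self.u(r - h)) / (2 * h)

    @property
    def analytic_minimum(self) -> float:
        grid = np.linspace(*self.domain, 20001)
        return float(grid[np.argmin(self.u(grid))])


def analytic_pmf(
    potential: PotentialSpec,
    bin_centers: np.ndarray,
    bin_width: float | None = None,
    temperature: float = 300.0,
) -> np.ndarray:
    """Reference profile at the bin centers, min-shifted to zero.

    With ``bin_width`` set, returns the bin-discretized curve
    ``-kT ln( <exp(-U/kT)>_bin )`` — the exact expectation of a histogram
    estimator, which differs from the pointwise U where the potential is
    steep on the scale of a bin.  Without it, returns pointwise U.
    """
    centers = np.asarray(bin_centers, dtype=float)
    if bin_width is None:
        u = potential.u(centers)
        return u - u.min()
    beta = 1.0 / (KB * temperature)
    quad = np.linspace(-0.5, 0.5, 33) * bin_width
    w = np.exp(-beta * potential.u(centers[:, None] + quad[None, :]))
    u = -np.log(np.trapezoid(w, dx=quad[1] - quad[0], axis=1) / bin_width) / beta
    return u - u.min()


# ---------------------------------------------------------------------------
# umbrella sampling
# ---------------------------------------------------------------------------

def umbrella_sampler(
    potential: PotentialSpec,
    windows: list[dict],
    n_per_window: int,
    seed: int = 0,
    method: str = "exact",
    temperature: float = 300.0,
    dt: float = 0.02,
    diffusion: float = 1.0,
    stride: int = 25,
    burn_in: int = 2000,
) -> list[UmbrellaWindow]:
    """Draw reaction-coordinate samples for each umbrella window.

    ``windows`` are dicts with ``r0`` and ``k`` (from
    :func:`rigidpmf.pmf_wham.plan_umbrella_windows`).  ``method='exact'``
    samples the biased Boltzmann density by inverse-CDF on a dense grid;
    ``method='langevin'`` runs an overdamped Euler–Maruyama walker (time step
    ``dt``, diffusion constant ``diffusion`` Å²/time) thinned by ``stride``
    with ``burn_in`` discarded steps.  Reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    beta = 1.0 / (KB * temperature)
    out: list[UmbrellaWindow] = []
    for w in windows:
        r0, k = float(w["r0"]), float(w["k"])

        def u_tot(r):
            return potential.u(r) + 0.5 * k * (r - r0) ** 2

        if method == "exact":
            samples = _exact_biased_samples(u_tot, r0, beta, n_per_window, rng)
        elif method == "langevin":
            samples = _langevin_samples(
                potential, r0, k, beta, n_per_window, rng, dt, diffusion, stride, burn_in
            )
        else:
            raise ValueError(f"unknown sampling method {method!r}")
        times = np.arange(n_per_window, dtype=float)
        out.append(UmbrellaWindow(r0, k, times, samples, equilibration_cut=0.0))
    return out


def _exact_biased_samples(u_tot, r0, beta, n, rng):
    # locate the biased minimum, then grid out to +40 kT on both sides
    probe = np.linspace(r0 - 50, r0 + 50, 20001)
    u = u_tot(probe)
    center = probe[np.argmin(u)]
    u_min = u.min()
    span = 1.0
    while span < 200:
        lo, hi = center - span, center + span
        if u_tot(np.array([lo]))[0] > u_min + 40 / beta and u_tot(np.array([hi]))[0] > u_min + 40 / beta:
            break
        span *= 1.5
    grid = np.linspace(center - span, center + span, 4001)
    w = np.exp(-beta * (u_tot(grid) - u_min))
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(grid))])
    cdf /= cdf[-1]
    # strictly increasing cdf for interpolation
    keep = np.concatenate([[True], np.diff(cdf) > 0])
    return np.interp(rng.uniform(size=n), cdf[keep], grid[keep])


def _langevin_samples(potential, r0, k, beta, n, rng, dt, diffusion, stride, burn_in):
    r = r0
    samples = np.empty(n)
    noise_scale = math.sqrt(2.0 * diffusion * dt)
    n_steps = burn_in + n * stride
    collected = 0
    for step in range(n_steps):
        force = -(potential.grad(np.array([r]))[0] + k * (r - r0))
        r = r + diffusion * beta * force * dt + noise_scale * rng.standard_normal()
        if not math.isfinite(r) or abs(r) > 1e6:
            raise RuntimeError(
                f"Langevin trajectory diverged (r={r!r}); reduce dt={dt} for this potential stiffness"
            )
        if step >= burn_in and (step - burn_in) % stride == 0:
            samples[collected] = r
            collected += 1
            if collected == n:
                break
    return samples


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedBond:
    """A planted non-covalent constraint at residue resolution.

    Hydrogen bonds attach at the Cα atoms, hydrophobic tethers at the Cβ
    atoms (a documented toy convention — the constraint list, not geometric
    redetection, is the ground truth consumed downstream).
    """

    kind: str  # hbond | saltbridge | hydrophobic
    chain_i: str
    res_i: int
    chain_j: str
    res_j: int
    energy: float | None = None
    anchor: str | None = None  # override the default attachment atom


# per-residue template (name, element, offset from residue origin), Å
_RESIDUE_TEMPLATE = [
    ("N", "N", np.array([0.00, 0.35, 0.00])),
    ("CA", "C", np.array([1.22, -0.45, 0.00])),
    ("C", "C", np.array([2.57, 0.25, 0.00])),
    ("O", "O", np.array([1.992, 1.332, 0.00])),
    ("CB", "C", np.array([1.22, -1.45, 1.15])),
]
_RESIDUE_SPACING = 3.90  # places C(i)–N(i+1) at 1.33 Å
_CHAIN_OFFSET = np.array([0.0, 0.0, 9.0])


def toy_structure(
    n_res: int = 10,
    kind: str = "monomer",
    planted: list[PlantedBond] | None = None,
    seed: int = 0,
    jitter: float = 0.0,
    params: NetworkParams = NetworkParams(),
) -> tuple[str, dict]:
    """Idealized alanine-like backbone, monomer (chain A) or dimer (A + B).

    Returns ``(pdb_text, ground_truth)`` where the ground truth carries the
    model, the planted constraints resolved to atom indices (``hbonds``,
    ``tethers``), and the declared sequences.  ``jitter`` adds seeded
    Gaussian coordinate noise (Å) to emulate an ensemble of conformations
    without altering the covalent topology.
    """
    if n_res < 2:
        raise ValueError("need at least two residues per chain")
    chains = ["A"] if kind == "monomer" else ["A", "B"]
    if kind not in ("monomer", "dimer"):
        raise ValueError("kind must be 'monomer' or 'dimer'")
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    chain_res: dict[str, list[int]] = {}
    serial = 1
    for c_idx, cid in enumerate(chains):
        chain_res[cid] = list(range(1, n_res + 1))
        for res in range(1, n_res + 1):
            origin = np.array([(res - 1) * _RESIDUE_SPACING, 0.0, 0.0]) + c_idx * _CHAIN_OFFSET
            for name, elem, offset in _RESIDUE_TEMPLATE:
                coord = origin + offset
                if jitter > 0:
                    coord = coord + rng.normal(0.0, jitter, 3)
                atoms.append(Atom(serial, name, elem, res, "ALA", cid, coord))
                serial += 1
    declared = {cid: "A" * n_res for cid in chains}
    model = StructureModel(atoms, chain_res, declared)

    index = {(a.chain_id, a.res_seq, a.name): i for i, a in enumerate(atoms)}
    hbonds: list[Constraint] = []
    tethers: list[Constraint] = []
    for pb in planted or []:
        anchor = pb.anchor or ("CA" if pb.kind in (KIND_HBOND, "saltbridge") else "CB")
        key_i = (pb.chain_i, pb.res_i, anchor)
        key_j = (pb.chain_j, pb.res_j, anchor)
        if key_i not in index or key_j not in index:
            raise ValueError(f"planted constraint references absent residue: {pb}")
        i, j = index[key_i], index[key_j]
        if pb.kind == KIND_HYDROPHOBIC:
            tethers.append(Constraint(KIND_HYDROPHOBIC, i, j, params.bars_hydrophobic))
        else:
            if pb.energy is None:
                raise ValueError(f"planted {pb.kind} needs an energy: {pb}")
            hbonds.append(Constraint(pb.kind, i, j, params.bars_hbond, pb.energy))

    ground_truth = {
        "model": model,
        "hbonds": hbonds,
        "tethers": tethers,
        "declared_sequence": declared,
        "chains": chains,
    }
    return write_structure(model), ground_truth


def split_dimer_truth(truth: dict, chain: str) -> tuple[StructureModel, list[Constraint], list[Constraint]]:
    """Restrict a dimer ground truth to one chain's model and constraints.

    Returns (monomer model, hbonds, tethers) with atom indices remapped to
    the monomer's atom ordering; interface constraints are dropped.  Used to
    build the monomer stability maps entering the difference map from the
    same conformation as the dimer.
    """
    model: StructureModel = truth["model"]
    sub = model.subset_chain(chain)
    sub_index = {(a.chain_id, a.res_seq, a.name): k for k, a in enumerate(sub.atoms)}

    def remap(cons: list[Constraint]) -> list[Constraint]:
        out = []
        for c in cons:
            ai, aj = model.atoms[c.i], model.atoms[c.j]
            if ai.chain_id != chain or aj.chain_id != chain:
                continue
            out.append(Constraint(
                c.kind,
                sub_index[(ai.chain_id, ai.res_seq, ai.name)],
                sub_index[(aj.chain_id, aj.res_seq, aj.name)],
                c.bars, c.energy,
            ))
        return out

    return sub, remap(truth["hbonds"]), remap(truth["tethers"])


def stiffen_backbone(chain: str, first_res: int, last_res: int, energy: float = -8.0) -> list[PlantedBond]:
    """Planted Cα(i)–Cα(i+1) hydrogen bonds making a backbone run rigid.

    Each bond closes a 5-bar triangle through the peptide unit, fusing the
    consecutive Cα bodies into one rigid cluster; at ``energy`` below the
    dilution end point the run stays rigid through the whole trajectory.
    """
    return [
        PlantedBond(KIND_HBOND, chain, r, chain, r + 1, energy)
        for r in range(first_res, last_res)
    ]


# ---------------------------------------------------------------------------
# planted-mode trajectories
# ---------------------------------------------------------------------------

@dataclass
class PlantedModeSpec:
    """Gaussian-mode trajectory specification.

    ``modes`` is a list of (orthonormal 3N-vector, variance Å²); ``blocks``
    optionally names two residue index sets (the toy "NBDs") used by the
    symmetric/antisymmetric constructors.
    """

    base: np.ndarray  # (N, 3)
    modes: list[tuple[np.ndarray, float]]
    noise_sd: float = 0.0
    symmetry: str = "none"
    blocks: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self):
        vecs = np.stack([m[0].ravel() for m in self.modes]) if self.modes else np.empty((0, 0))
        if self.modes:
            gram = vecs @ vecs.T
            if not np.allclose(gram, np.eye(len(self.modes)), atol=1e-8):
                raise ValueError("planted modes must be orthonormal")
        if any(v < 0 for _, v in self.modes):
            raise ValueError("mode variances must be non-negative")


def two_block_mode_spec(
    n_per_block: int = 20,
    variance: float = 4.0,
    noise_sd: float = 0.05,
    symmetry: str = "antisymmetric",
) -> PlantedModeSpec:
    """Two rigid residue blocks sharing one planted x-displacement mode.

    ``antisymmetric``: the blocks move in opposite x directions (one domain
    opens while the other closes); ``symmetric``: same direction.
    """
    n = 2 * n_per_block
    base = np.zeros((n, 3))
    base[:, 0] = np.arange(n) * 3.8
    base[n_per_block:, 1] = 25.0  # separate the blocks
    mode = np.zeros((n, 3))
    mode[:n_per_block, 0] = 1.0
    sign = -1.0 if symmetry == "antisymmetric" else 1.0
    mode[n_per_block:, 0] = sign
    mode /= np.linalg.norm(mode)
    blocks = (np.arange(n_per_block), np.arange(n_per_block, n))
    return PlantedModeSpec(base, [(mode, variance)], noise_sd, symmetry, blocks)


def mode_trajectory(spec: PlantedModeSpec, n_frames: int, seed: int = 0) -> TrajectoryEnsemble:
    """frames = base + Σ_m a_m(t)·mode_m + noise, a_m ~ N(0, variance_m)."""
    if n_frames < 2:
        raise ValueError("need at least two frames")
    rng = np.random.default_rng(seed)
    n = spec.base.shape[0]
    flat_base = spec.base.ravel()
    frames = np.tile(flat_base, (n_frames, 1))
    for vec, var in spec.modes:
        amp = rng.normal(0.0, math.sqrt(var), n_frames)
        frames += amp[:, None] * vec.ravel()[None, :]
    if spec.noise_sd > 0:
        frames += rng.normal(0.0, spec.noise_sd, frames.shape)
    coords = frames.reshape(n_frames, n, 3)
    ids = [("A", i + 1) for i in range(n)]
    return TrajectoryEnsemble(coords, np.arange(n_frames, dtype=float), ids)
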