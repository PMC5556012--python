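"""Body-bar constraint networks from protein structures.

Each atom is one rigid body with 6 degrees of freedom; interactions become
sets of bars between bodies:

* covalent single bond — 5 bars (the bond dihedral stays free),
* peptide and carbonyl double bonds — 6 bars (locked),
* hydrogen bond / salt bridge — 5 bars, carrying an energy label,
* hydrophobic tether — 2 bars.

Hydrogen-bond energies come from a Mayo-style distance–angle function
(12-10 radial core with cosine-squared angular damping).  Salt bridges are
treated as hydrogen bonds pinned at a strong floor energy so that they
survive deep constraint dilution.  Only hydrogen bonds and salt bridges with
E ≤ E_cut enter the network at a given cutoff; hydrophobic tethers and
covalent bars are always present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structure_io import Atom, StructureModel, StructureError

__all__ = [
    "Constraint",
    "ConstraintNetwork",
    "NetworkParams",
    "assign_hbond_energies",
    "detect_hydrophobic_tethers",
    "detect_covalent_bonds",
    "build_constraint_network",
    "mayo_hbond_energy",
    "network_to_table",
    "network_from_table",
]

KIND_COVALENT = "covalent"
KIND_HBOND = "hbond"
KIND_SALTBRIDGE = "saltbridge"
KIND_HYDROPHOBIC = "hydrophobic"

# Bondi van der Waals radii (Å) for tether-forming elements.
VDW_RADII = {"C": 1.70, "S": 1.80}

# Covalent radii (Å), Cordero et al. consensus values; used for bond detection.
COVALENT_RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07}


@dataclass(frozen=True)
class Constraint:
    kind: str
    i: int  # body (atom) index
    j: int
    bars: int
    energy: float | None = None  # kcal/mol, hbond/saltbridge only

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("self-constraints are not allowed")
        if not 1 <= self.bars <= 6:
            raise ValueError("bar count must be in 1..6")
        if self.kind in (KIND_HBOND, KIND_SALTBRIDGE):
            if self.energy is None or not math.isfinite(self.energy):
                raise ValueError(f"{self.kind} constraint requires a finite energy")
        elif self.energy is not None:
            raise ValueError(f"{self.kind} constraint must not carry an energy")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.i, self.j) if self.i < self.j else (self.j, self.i)


@dataclass
class ConstraintNetwork:
    """Bodies plus typed bar sets; input to the pebble game.

    ``body_meta`` maps each body index to (chain_id, res_seq, atom_name);
    duplicate endpoint pairs are merged keeping the strongest (most negative
    energy, then most bars) constraint.
    """

    n_bodies: int
    constraints: list[Constraint]
    body_meta: list[tuple[str, int, str]] = field(default_factory=list)

    def __post_init__(self):
        merged: dict[tuple[int, int, str], Constraint] = {}
        for c in self.constraints:
            if not (0 <= c.i < self.n_bodies and 0 <= c.j < self.n_bodies):
                raise ValueError("constraint references a missing body")
            key = (*c.pair, c.kind)
            old = merged.get(key)
            if old is None or _strength(c) > _strength(old):
                merged[key] = c
        self.constraints = sorted(merged.values(), key=lambda c: (c.pair, c.kind))

    def ca_body(self, chain_id: str, res_seq: int) -> int:
        for idx, (cid, rs, name) in enumerate(self.body_meta):
            if cid == chain_id and rs == res_seq and name == "CA":
                return idx
        raise ValueError(f"no Cα body for residue {chain_id}:{res_seq}")


def _strength(c: Constraint) -> tuple[float, int]:
    return (-(c.energy if c.energy is not None else 0.0), c.bars)


@dataclass(frozen=True)
class NetworkParams:
    """Tunable conventions of the network construction."""

    bars_covalent_single: int = 5
    bars_covalent_double: int = 6
    bars_hbond: int = 5
    bars_hydrophobic: int = 2
    hydrophobic_delta: float = 0.35  # Å beyond vdW contact, inclusive
    hbond_max_da: float = 3.6  # donor–acceptor heavy-atom cutoff, Å
    salt_bridge_energy: float = -10.0  # energy floor for salt bridges
    covalent_tolerance: float = 0.45  # Å slack over covalent radii sum


def mayo_hbond_energy(r_da: float, theta_dha: float, phi_acc: float,
                      v0: float = 8.0, r0: float = 2.8) -> float:
    """Mayo-style hydrogen-bond energy (kcal/mol).

    ``E = v0 * (5 (r0/R)^12 - 6 (r0/R)^10) * cos^2(theta) * cos^2(phi)``
    with R the donor–acceptor distance, theta the D–H···A angle and phi the
    H···A–base angle (radians).  Angles below 90° give zero (no bond).
    """
    if r_da <= 0:
        raise ValueError("distance must be positive")
    if math.cos(theta_dha) > 0 or math.cos(phi_acc) > 0:
        return 0.0
    ratio = r0 / r_da
    radial = v0 * (5.0 * ratio**12 - 6.0 * ratio**10)
    return radial * math.cos(theta_dha) ** 2 * math.cos(phi_acc) ** 2


_SIDECHAIN_DONORS = {
    ("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
    ("HIS", "ND1"), ("HIS", "NE2"), ("TRP", "NE1"), ("ASN", "ND2"),
    ("GLN", "NE2"), ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
}
_SALT_DONORS = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
                ("HIS", "ND1"), ("HIS", "NE2")}
_SALT_ACCEPTORS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}


def _index_atoms(model: StructureModel) -> dict[tuple[str, int, str], int]:
    return {(a.chain_id, a.res_seq, a.name): i for i, a in enumerate(model.atoms)}


def _infer_backbone_h(model: StructureModel, idx: dict, atom: Atom) -> np.ndarray | None:
    """Amide H position from heavy-atom geometry (anti to the C(prev)/CA bisector)."""
    ca = idx.get((atom.chain_id, atom.res_seq, "CA"))
    cprev = idx.get((atom.chain_id, atom.res_seq - 1, "C"))
    if ca is None or cprev is None:
        return None
    n = atom.coord
    u1 = model.atoms[ca].coord - n
    u2 = model.atoms[cprev].coord - n
    u1 /= np.linalg.norm(u1)
    u2 /= np.linalg.norm(u2)
    bisector = u1 + u2
    norm = np.linalg.norm(bisector)
    if norm < 1e-8:
        return None
    return n - 1.01 * bisector / norm


def assign_hbond_energies(model: StructureModel, params: NetworkParams = NetworkParams()) -> list[Constraint]:
    """Score donor–acceptor pairs, returning hbond/salt-bridge constraints.

    Donors are backbone amide N (hydrogen taken from the structure when
    present, otherwise inferred from heavy-atom geometry) and common polar
    side-chain N/O; acceptors are carbonyl and carboxylate oxygens.  Pairs
    outside the geometric limits get no constraint.  Salt bridges (charged
    donor + carboxylate acceptor) are pinned at ``params.salt_bridge_energy``.
    """
    idx = _index_atoms(model)
    has_h = any(a.element == "H" for a in model.atoms)

    donors: list[tuple[int, np.ndarray]] = []  # (donor heavy index, H position)
    for i, a in enumerate(model.atoms):
        is_backbone_n = a.name == "N" and a.res_name != "PRO"
        is_side = (a.res_name, a.name) in _SIDECHAIN_DONORS
        if not (is_backbone_n or is_side):
            continue
        h_pos = None
        for b in model.residue_atoms(a.chain_id, a.res_seq):
            if b.element == "H" and np.linalg.norm(b.coord - a.coord) < 1.25:
                h_pos = b.coord
                break
        if h_pos is None and is_backbone_n:
            h_pos = _infer_backbone_h(model, idx, a)
        if h_pos is not None:
            donors.append((i, h_pos))
    if not donors:
        if not has_h:
            raise StructureError(
                "no hydrogens and no inferable donors: add polar hydrogens "
                "(protonation preprocessing) before hydrogen-bond assignment"
            )
        return []

    acceptors: list[tuple[int, int | None]] = []  # (acceptor index, base atom index)
    for i, a in enumerate(model.atoms):
        if a.element != "O":
            continue
        base = None
        for key in (("C",), ("CG",), ("CD",)):
            j = idx.get((a.chain_id, a.res_seq, key[0]))
            if j is not None and np.linalg.norm(model.atoms[j].coord - a.coord) < 1.8:
                base = j
                break
        acceptors.append((i, base))

    out: list[Constraint] = []
    for di, h_pos in donors:
        d_atom = model.atoms[di]
        for ai, base in acceptors:
            a_atom = model.atoms[ai]
            if d_atom.chain_id == a_atom.chain_id and abs(d_atom.res_seq - a_atom.res_seq) <= 1:
                continue  # local backbone geometry, not a network constraint
            r_da = float(np.linalg.norm(d_atom.coord - a_atom.coord))
            if r_da > params.hbond_max_da:
                continue
            is_salt = ((d_atom.res_name, d_atom.name) in _SALT_DONORS
                       and (a_atom.res_name, a_atom.name) in _SALT_ACCEPTORS)
            if is_salt:
                out.append(Constraint(KIND_SALTBRIDGE, di, ai, params.bars_hbond,
                                      params.salt_bridge_energy))
                continue
            theta = _angle(d_atom.coord, h_pos, a_atom.coord)
            if base is not None:
                phi = _angle(h_pos, a_atom.coord, model.atoms[base].coord)
            else:
                phi = math.pi
            energy = mayo_hbond_energy(r_da, theta, phi)
            if energy < 0.0:
                out.append(Constraint(KIND_HBOND, di, ai, params.bars_hbond, energy))
    return out


def _angle(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    v1 = p1 - p2
    v2 = p3 - p2
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(math.acos(np.clip(c, -1.0, 1.0)))


def detect_covalent_bonds(model: StructureModel, params: NetworkParams = NetworkParams()) -> list[Constraint]:
    """Distance-based covalent bond detection with name-based double-bond rules.

    Backbone carbonyl C–O and peptide C–N(next) get 6 bars (locked); every
    other bond gets 5 (free dihedral).
    """
    coords = np.array([a.coord for a in model.atoms])
    out: list[Constraint] = []
    n = len(model.atoms)
    # neighbor search via cell-free O(n^2) is fine at toy scale; use KDTree above it
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=2.2)
    for i, j in sorted(pairs):
        ai, aj = model.atoms[i], model.atoms[j]
        ri = COVALENT_RADII.get(ai.element)
        rj = COVALENT_RADII.get(aj.element)
        if ri is None or rj is None:
            continue
        d = float(np.linalg.norm(ai.coord - aj.coord))
        if d > ri + rj + params.covalent_tolerance:
            continue
        same_res = ai.chain_id == aj.chain_id and ai.res_seq == aj.res_seq
        names = {ai.name, aj.name}
        double = (same_res and names == {"C", "O"}) or (
            not same_res
            and names == {"C", "N"}
            and ai.chain_id == aj.chain_id
            and abs(ai.res_seq - aj.res_seq) == 1
        )
        bars = params.bars_covalent_double if double else params.bars_covalent_single
        out.append(Constraint(KIND_COVALENT, i, j, bars))
    return out


def _is_nonpolar(model: StructureModel, covalent: list[Constraint], i: int) -> bool:
    a = model.atoms[i]
    if a.element not in VDW_RADII:
        return False
    for c in covalent:
        if i in (c.i, c.j):
            other = model.atoms[c.j if c.i == i else c.i]
            if other.element in ("N", "O"):
                return False
    return True


def detect_hydrophobic_tethers(
    model: StructureModel,
    delta: float | None = None,
    params: NetworkParams = NetworkParams(),
    covalent: list[Constraint] | None = None,
) -> list[Constraint]:
    """Hydrophobic tethers between nonpolar C/S atoms.

    A tether joins atoms i, j iff ``d(i,j) <= r_vdw(i) + r_vdw(j) + delta``
    (inclusive), both atoms are carbon or sulfur with no N/O covalent
    neighbor, and the pair is not itself covalently linked.
    """
    if delta is None:
        delta = params.hydrophobic_delta
    if delta < 0:
        raise ValueError("hydrophobic delta must be non-negative")
    if covalent is None:
        covalent = detect_covalent_bonds(model, params)
    bonded = {c.pair for c in covalent}
    candidates = [i for i in range(len(model.atoms)) if _is_nonpolar(model, covalent, i)]
    out: list[Constraint] = []
    for a_pos, i in enumerate(candidates):
        ai = model.atoms[i]
        for j in candidates[a_pos + 1 :]:
            aj = model.atoms[j]
            if ai.chain_id == aj.chain_id and abs(ai.res_seq - aj.res_seq) <= 1:
                continue
            if (min(i, j), max(i, j)) in bonded:
                continue
            cutoff = VDW_RADII[ai.element] + VDW_RADII[aj.element] + delta
            d = float(np.linalg.norm(ai.coord - aj.coord))
            if d <= cutoff + 1e-12:
                out.append(Constraint(KIND_HYDROPHOBIC, i, j, params.bars_hydrophobic))
    return out


def build_constraint_network(
    model: StructureModel,
    e_cut: float,
    params: NetworkParams = NetworkParams(),
    hbonds: list[Constraint] | None = None,
    tethers: list[Constraint] | None = None,
    covalent: list[Constraint] | None = None,
) -> ConstraintNetwork:
    """Assemble the body-bar network at hydrogen-bond cutoff ``e_cut``.

    Keeps all covalent bars and hydrophobic tethers, plus exactly those
    hydrogen bonds / salt bridges with ``E <= e_cut``.  ``hbonds`` /
    ``tethers`` / ``covalent`` may be supplied explicitly (e.g. planted
    ground-truth constraints from the synthetic generators); otherwise they
    are detected from the model geometry.
    """
    if e_cut > 0:
        raise ValueError("E_cut must be <= 0 kcal/mol")
    if not model.atoms:
        raise StructureError("empty model")
    if covalent is None:
        covalent = detect_covalent_bonds(model, params)
    if tethers is None:
        tethers = detect_hydrophobic_tethers(model, params=params, covalent=covalent)
    if hbonds is None:
        hbonds = assign_hbond_energies(model, params)
    kept = [c for c in hbonds if c.energy is not None and c.energy <= e_cut]
    meta = [(a.chain_id, a.res_seq, a.name) for a in model.atoms]
    return ConstraintNetwork(len(model.atoms), covalent + tethers + kept, meta)


def network_to_table(network: ConstraintNetwork) -> str:
    """Dump as a tab-separated edge list (body_i, body_j, kind, energy, bars)."""
    lines = ["body_i\tbody_j\tkind\tenergy\tbars"]
    for c in network.constraints:
        e = "" if c.energy is None else f"{c.energy:.6f}"
        lines.append(f"{c.i}\t{c.j}\t{c.kind}\t{e}\t{c.bars}")
    return "\n".join(lines) + "\n"


def network_from_table(text: str, n_bodies: int | None = None) -> ConstraintNetwork:
    constraints = []
    max_body = -1
    for line in text.strip().splitlines()[1:]:
        i, j, kind, energy, bars = line.split("\t")
        c = Constraint(kind, int(i), int(j), int(bars), float(energy) if energy else None)
        constraints.append(c)
        max_body = max(max_body, c.i, c.j)
    if n_bodies is None:
        n_bodies = max_body + 1
    return ConstraintNetwork(n_bodies, constraints)
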