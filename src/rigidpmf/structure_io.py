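"""Structure and trajectory bookkeeping.

Reads PDB-format structures into a light :class:`StructureModel`, accounts for
residues declared in SEQRES but absent from the coordinates, computes the
nucleotide-binding-domain (NBD) opening-closing reaction coordinate (the
Cα–Cα distance between two marker residues, by default S215 and E272 in
*Flaveria trinervia* numbering), and classifies open/closed/intermediate NBD
states against explicit distance cutoffs.

Parsing is delegated to Biopython (`Bio.PDB` for coordinates, `Bio.SeqIO`'s
``pdb-seqres`` reader for declared sequences).  HETATM records and waters are
dropped on read; alternate locations are resolved to the highest-occupancy
conformer (ties broken alphabetically by altloc id).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

__all__ = [
    "Atom",
    "StructureModel",
    "TrajectoryEnsemble",
    "StructureError",
    "read_structure",
    "write_structure",
    "read_trajectory_pdb",
    "read_trajectory_table",
    "write_trajectory_table",
    "count_unresolved_residues",
    "nbd_distance",
    "reaction_coordinate_series",
    "classify_nbd_state",
]

# Reaction-coordinate defaults (F. trinervia numbering); configurable in every op.
DEFAULT_RC_RESIDUES = (215, 272)
DEFAULT_OPEN_MIN = 36.0
DEFAULT_CLOSED_MAX = 33.0


class StructureError(ValueError):
    """Raised for malformed structures or unsatisfiable structure queries."""


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    res_seq: int
    res_name: str
    chain_id: str
    coord: np.ndarray  # (3,) Å
    altloc: str = ""
    occupancy: float = 1.0


@dataclass
class StructureModel:
    """Parsed protein structure: atoms, per-chain residue lists, declared sequences.

    ``declared_sequence`` maps chain id to the SEQRES sequence (one-letter),
    which may be longer than the resolved residue list.
    """

    atoms: list[Atom]
    chains: dict[str, list[int]]  # chain id -> ordered resolved residue numbers
    declared_sequence: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a in self.atoms:
            if not np.all(np.isfinite(a.coord)):
                raise StructureError(f"non-finite coordinates for atom {a.serial}")
        for cid, residues in self.chains.items():
            if any(b <= a for a, b in zip(residues, residues[1:])):
                raise StructureError(f"residue numbers not strictly increasing in chain {cid}")

    @property
    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    def residue_atoms(self, chain_id: str, res_seq: int) -> list[Atom]:
        return [a for a in self.atoms if a.chain_id == chain_id and a.res_seq == res_seq]

    def atom(self, chain_id: str, res_seq: int, name: str) -> Atom:
        for a in self.atoms:
            if a.chain_id == chain_id and a.res_seq == res_seq and a.name == name:
                return a
        raise StructureError(f"atom {name} of residue {chain_id}:{res_seq} not found")

    def subset_chain(self, chain_id: str) -> "StructureModel":
        """Model restricted to one chain (same coordinates, same numbering)."""
        if chain_id not in self.chains:
            raise StructureError(f"chain {chain_id} not in model")
        atoms = [a for a in self.atoms if a.chain_id == chain_id]
        decl = {chain_id: self.declared_sequence[chain_id]} if chain_id in self.declared_sequence else {}
        return StructureModel(atoms, {chain_id: list(self.chains[chain_id])}, decl)


@dataclass
class TrajectoryEnsemble:
    """Ordered Cα frames sharing one residue mapping.

    coords: (n_frames, n_residues, 3) in Å; times in ns;
    residue_ids: list of (chain_id, res_seq) defining the column order.
    """

    coords: np.ndarray
    times: np.ndarray
    residue_ids: list[tuple[str, int]]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructureError("trajectory coords must be (n_frames, n_residues, 3)")
        if self.coords.shape[0] < 1:
            raise StructureError("trajectory needs at least one frame")
        if self.coords.shape[0] != self.times.shape[0]:
            raise StructureError("frame/time count mismatch")
        if self.coords.shape[1] != len(self.residue_ids):
            raise StructureError("residue mapping does not match coordinate columns")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def concat(self, other: "TrajectoryEnsemble") -> "TrajectoryEnsemble":
        if self.residue_ids != other.residue_ids:
            raise StructureError("cannot concatenate trajectories with different residue mappings")
        return TrajectoryEnsemble(
            np.concatenate([self.coords, other.coords]),
            np.concatenate([self.times, other.times]),
            list(self.residue_ids),
        )


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def _pick_altloc(bio_atom):
    """Highest-occupancy conformer; ties broken alphabetically by altloc id."""
    if not bio_atom.is_disordered():
        return bio_atom
    children = sorted(
        bio_atom.disordered_get_list(),
        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
    )
    return children[0]


def read_structure(pdb_text: str, model_index: int = 0) -> StructureModel:
    """Parse PDB text into a :class:`StructureModel`.

    HETATM records and waters are dropped; altlocs resolved to highest
    occupancy.  Raises :class:`StructureError` if no ATOM records are present
    or a coordinate field is malformed.
    """
    if "ATOM" not in pdb_text:
        raise StructureError("no ATOM records in input")
    parser = PDBParser(QUIET=True, PERMISSIVE=0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure("model", io.StringIO(pdb_text))
    except (PDBConstructionException, ValueError) as exc:
        raise StructureError(f"PDB parse error: {exc}") from exc
    models = list(structure)
    if not models:
        raise StructureError("no ATOM records parsed")
    bio_model = models[model_index]

    atoms: list[Atom] = []
    chains: dict[str, list[int]] = {}
    for chain in bio_model:
        residues = []
        for res in chain:
            hetflag, resseq, _icode = res.id
            if hetflag != " ":  # HETATM / water
                continue
            residues.append(resseq)
            for bio_atom in res:
                at = _pick_altloc(bio_atom)
                elem = (at.element or "").strip() or at.get_name()[0]
                atoms.append(
                    Atom(
                        serial=at.get_serial_number() or len(atoms) + 1,
                        name=at.get_name(),
                        element=elem.upper(),
                        res_seq=resseq,
                        res_name=res.get_resname(),
                        chain_id=chain.id,
                        coord=np.array(at.get_coord(), dtype=float),
                        altloc=at.get_altloc().strip(),
                        occupancy=float(at.get_occupancy() or 1.0),
                    )
                )
        if residues:
            chains[chain.id] = residues
    if not atoms:
        raise StructureError("no ATOM records parsed")

    declared: dict[str, str] = {}
    for record in SeqIO.parse(io.StringIO(pdb_text), "pdb-seqres"):
        chain_id = record.annotations.get("chain", record.id.split(":")[-1])
        declared[chain_id] = str(record.seq)
    return StructureModel(atoms, chains, declared)


def write_structure(model: StructureModel) -> str:
    """Serialize a model to PDB text (ATOM + SEQRES records)."""
    lines: list[str] = []
    for cid, seq in model.declared_sequence.items():
        one_to_three = {v: k for k, v in _THREE_TO_ONE.items()}
        names = [one_to_three.get(c, "UNK") for c in seq]
        for i in range(0, len(names), 13):
            row = names[i : i + 13]
            lines.append(
                f"SEQRES {i // 13 + 1:3d} {cid} {len(seq):4d}  " + " ".join(row)
            )
    serial = 1
    for a in model.atoms:
        x, y, z = a.coord
        lines.append(
            f"ATOM  {serial:5d} {a.name:^4s}{a.res_name:>4s} {a.chain_id}{a.res_seq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}  0.00          {a.element:>2s}"
        )
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_trajectory_pdb(pdb_text: str) -> TrajectoryEnsemble:
    """Read a multi-model PDB as a Cα trajectory (frame index used as time, ns)."""
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure("traj", io.StringIO(pdb_text))
    frames = []
    residue_ids: list[tuple[str, int]] | None = None
    for bio_model in structure:
        ids, coords = [], []
        for chain in bio_model:
            for res in chain:
                if res.id[0] != " " or "CA" not in res:
                    continue
                ids.append((chain.id, res.id[1]))
                coords.append(_pick_altloc(res["CA"]).get_coord())
        if residue_ids is None:
            residue_ids = ids
        elif ids != residue_ids:
            raise StructureError("frames do not share a residue mapping")
        frames.append(np.array(coords, dtype=float))
    if not frames:
        raise StructureError("no frames found")
    return TrajectoryEnsemble(np.stack(frames), np.arange(len(frames), dtype=float), residue_ids)


def read_trajectory_table(text: str, residue_ids: list[tuple[str, int]] | None = None) -> TrajectoryEnsemble:
    """Read the plain-text Cα table: one row per frame, ``time_ns x1 y1 z1 x2 ...``."""
    data = np.atleast_2d(np.loadtxt(io.StringIO(text)))
    if data.shape[1] < 4 or (data.shape[1] - 1) % 3:
        raise StructureError("trajectory table must have time plus x,y,z triplets")
    n_res = (data.shape[1] - 1) // 3
    if residue_ids is None:
        residue_ids = [("A", i + 1) for i in range(n_res)]
    coords = data[:, 1:].reshape(len(data), n_res, 3)
    return TrajectoryEnsemble(coords, data[:, 0], residue_ids)


def write_trajectory_table(traj: TrajectoryEnsemble) -> str:
    flat = traj.coords.reshape(traj.n_frames, -1)
    rows = np.column_stack([traj.times, flat])
    out = io.StringIO()
    np.savetxt(out, rows, fmt="%.6f")
    return out.getvalue()


def count_unresolved_residues(model: StructureModel) -> dict[str, int]:
    """Per-chain ``|declared| - |resolved|`` counts plus ``total``.

    Requires SEQRES-style declared sequences; errors rather than silently
    reporting zero when they are absent.
    """
    counts: dict[str, int] = {}
    total = 0
    for cid, residues in model.chains.items():
        if cid not in model.declared_sequence:
            raise StructureError(
                f"sequence unavailable for chain {cid}: SEQRES records required to count unresolved residues"
            )
        n = len(model.declared_sequence[cid]) - len(residues)
        if n < 0:
            raise StructureError(f"chain {cid} resolves more residues than declared")
        counts[cid] = n
        total += n
    counts["total"] = total
    return counts


def nbd_distance(
    model: StructureModel,
    chain: str,
    res_a: int = DEFAULT_RC_RESIDUES[0],
    res_b: int = DEFAULT_RC_RESIDUES[1],
) -> float:
    """Cα–Cα distance (Å) between two residues of one chain.

    Default residue pair (215, 272) is the NBD1–NBD3 opening-closing reaction
    coordinate.  Symmetric in its residue arguments.
    """
    try:
        ca_a = model.atom(chain, res_a, "CA")
    except StructureError:
        raise StructureError(f"residue {chain}:{res_a} has no Cα atom") from None
    try:
        ca_b = model.atom(chain, res_b, "CA")
    except StructureError:
        raise StructureError(f"residue {chain}:{res_b} has no Cα atom") from None
    return float(np.linalg.norm(ca_a.coord - ca_b.coord))


def reaction_coordinate_series(
    traj: TrajectoryEnsemble,
    chain: str,
    res_a: int = DEFAULT_RC_RESIDUES[0],
    res_b: int = DEFAULT_RC_RESIDUES[1],
) -> np.ndarray:
    """Per-frame NBD distance (Å) for one chain of a Cα trajectory."""
    try:
        ia = traj.residue_ids.index((chain, res_a))
        ib = traj.residue_ids.index((chain, res_b))
    except ValueError as exc:
        raise StructureError(f"reaction-coordinate residue missing from trajectory: {exc}") from None
    return np.linalg.norm(traj.coords[:, ia, :] - traj.coords[:, ib, :], axis=1)


def classify_nbd_state(
    d: float, open_min: float = DEFAULT_OPEN_MIN, closed_max: float = DEFAULT_CLOSED_MAX
) -> str:
    """Classify an NBD distance as ``open``/``closed``/``intermediate``.

    Defaults 36/33 Å bracket the crystallographic open (~38.5 Å) and closed
    (~31 Å) values.
    """
    if open_min <= closed_max:
        raise ValueError("open_min must exceed closed_max")
    if d >= open_min:
        return "open"
    if d <= closed_max:
        return "closed"
    return "intermediate"
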