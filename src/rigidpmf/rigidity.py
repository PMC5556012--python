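"""Generic rigidity of body-bar networks via the (6,6) pebble game.

Bodies carry 6 degrees of freedom (pebbles); each bar, when independent,
consumes one.  A bar between bodies u, v is independent iff 7 pebbles can be
gathered on {u, v}.  After all bars are played, the number of free pebbles
minus the 6 global rigid-body motions gives the internal floppy-mode count,
and two bodies belong to the same rigid cluster iff a 7th pebble cannot be
brought onto the pair (no relative motion remains — an equivalence relation,
since relative rigid transforms compose).

An independent linear-algebra oracle (:func:`dof_count_oracle`) computes
``6 n - rank`` of the bar incidence matrix at random generic placements; it
is used in tests to verify the combinatorial game and never by the game
itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constraint_network import ConstraintNetwork

__all__ = [
    "PebbleGame",
    "RigidClusterDecomposition",
    "rigid_cluster_decomposition",
    "rigid_contact_map",
    "dof_count_oracle",
    "oracle_cluster_partition",
]

K_PEBBLES = 6


class PebbleGame:
    """(6,6) body-bar pebble game on a directed multigraph.

    Deterministic: bars are inserted in the caller's order and pebble searches
    are depth-first by ascending body id.
    """

    def __init__(self, n_bodies: int):
        self.n = n_bodies
        self.pebbles = [K_PEBBLES] * n_bodies
        # out[u][v] = number of bars currently oriented u -> v
        self.out: list[dict[int, int]] = [dict() for _ in range(n_bodies)]
        self.rejected = 0

    # -- pebble motion ----------------------------------------------------
    def _find_pebble_path(self, roots: tuple[int, ...]) -> list[int] | None:
        """DFS from the roots to a body holding a free pebble, roots excluded."""
        seen = set(roots)
        stack = [(r, [r]) for r in reversed(roots)]
        while stack:
            u, path = stack.pop()
            for v in sorted(self.out[u]):
                if v in seen:
                    continue
                seen.add(v)
                if self.pebbles[v] > 0:
                    return path + [v]
                stack.append((v, path + [v]))
        return None

    def _move_pebble(self, path: list[int]) -> None:
        """Reverse the edges along ``path``; the pebble appears at path[0]."""
        for a, b in zip(path, path[1:]):
            self.out[a][b] -= 1
            if not self.out[a][b]:
                del self.out[a][b]
            self.out[b][a] = self.out[b].get(a, 0) + 1
        self.pebbles[path[-1]] -= 1
        self.pebbles[path[0]] += 1

    def _collect(self, u: int, v: int, target: int) -> bool:
        """Try to gather ``target`` pebbles onto {u, v}."""
        while self.pebbles[u] + self.pebbles[v] < target:
            path = self._find_pebble_path((u, v))
            if path is None:
                return False
            self._move_pebble(path)
        return True

    # -- public api --------------------------------------------------------
    def add_bar(self, u: int, v: int) -> bool:
        """Insert one bar; returns False (and counts it) if redundant."""
        if u == v:
            raise ValueError("self-bar")
        if not self._collect(u, v, K_PEBBLES + 1):
            self.rejected += 1
            return False
        # consume a pebble from whichever endpoint still has one
        donor = u if self.pebbles[u] > 0 else v
        other = v if donor == u else u
        self.pebbles[donor] -= 1
        self.out[donor][other] = self.out[donor].get(other, 0) + 1
        return True

    def free_pebbles(self) -> int:
        return sum(self.pebbles)

    def pair_rigid(self, u: int, v: int) -> bool:
        """True iff only 6 pebbles are gatherable on {u, v} (no relative DOF)."""
        if u == v:
            return True
        return not self._collect(u, v, K_PEBBLES + 1)


@dataclass
class RigidClusterDecomposition:
    """Partition of bodies into rigid clusters.

    ``labels[b]`` is the smallest body id in b's cluster; ``floppy_modes`` is
    the internal degree-of-freedom count beyond the 6 global motions.
    """

    labels: np.ndarray
    floppy_modes: int

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def cluster_sizes(self) -> dict[int, int]:
        uniq, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(uniq.tolist(), counts.tolist()))

    def same_cluster(self, u: int, v: int) -> bool:
        return bool(self.labels[u] == self.labels[v])


def _expand_bars(network: ConstraintNetwork):
    for c in network.constraints:
        for _ in range(c.bars):
            yield c.pair


def rigid_cluster_decomposition(network: ConstraintNetwork) -> RigidClusterDecomposition:
    """Play the (6,6) pebble game and extract the rigid-cluster partition.

    Deterministic for a fixed constraint ordering; cluster labels are the
    smallest member body id.
    """
    n = network.n_bodies
    if n == 0:
        raise ValueError("empty network")
    game = PebbleGame(n)
    for u, v in _expand_bars(network):
        game.add_bar(u, v)
    floppy = game.free_pebbles() - K_PEBBLES

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    # Rigid components are connected, so testing constrained pairs suffices.
    for c in network.constraints:
        u, v = c.pair
        if find(u) != find(v) and game.pair_rigid(u, v):
            union(u, v)
    labels = np.array([find(b) for b in range(n)], dtype=int)
    return RigidClusterDecomposition(labels, max(floppy, 0))


def rigid_contact_map(
    decomp: RigidClusterDecomposition,
    network: ConstraintNetwork,
    residues: list[tuple[str, int]],
) -> np.ndarray:
    """Boolean residue-pair matrix: True iff the Cα bodies share a cluster."""
    ca = [network.ca_body(cid, rs) for cid, rs in residues]
    lab = decomp.labels[ca]
    return lab[:, None] == lab[None, :]


# ----------------------------------------------------------------------------
# Linear-algebra oracle
# ----------------------------------------------------------------------------

def _bar_rows(network: ConstraintNetwork, rng: np.random.Generator,
              extra_pair: tuple[int, int] | None = None) -> np.ndarray:
    """Generic bar incidence matrix: one row per bar, 6 columns per body."""
    n = network.n_bodies
    centers = rng.uniform(-10, 10, size=(n, 3))
    pairs = list(_expand_bars(network))
    if extra_pair is not None:
        pairs.append(extra_pair)
    rows = np.zeros((len(pairs), 6 * n))
    for r, (u, v) in enumerate(pairs):
        pu = centers[u] + rng.uniform(-1, 1, 3)
        pv = centers[v] + rng.uniform(-1, 1, 3)
        d = pu - pv
        d /= np.linalg.norm(d)
        rows[r, 6 * u : 6 * u + 3] = d
        rows[r, 6 * u + 3 : 6 * u + 6] = np.cross(pu - centers[u], d)
        rows[r, 6 * v : 6 * v + 3] = -d
        rows[r, 6 * v + 3 : 6 * v + 6] = -np.cross(pv - centers[v], d)
    return rows


def dof_count_oracle(network: ConstraintNetwork, n_trials: int = 3, seed: int = 0) -> int:
    """Total floppy modes ``6 n - rank`` at generic placements (max over trials).

    Includes the 6 global rigid-body motions; intended for small networks
    (rank of a dense matrix) as an independent check on the pebble game.
    """
    rng = np.random.default_rng(seed)
    best_rank = 0
    for _ in range(n_trials):
        rows = _bar_rows(network, rng)
        if rows.size:
            best_rank = max(best_rank, int(np.linalg.matrix_rank(rows, tol=1e-8)))
    return 6 * network.n_bodies - best_rank


def oracle_cluster_partition(network: ConstraintNetwork, n_trials: int = 3, seed: int = 0) -> np.ndarray:
    """Rigid-cluster labels from the rank oracle (pair rigid iff a trial bar is dependent)."""
    n = network.n_bodies
    rng = np.random.default_rng(seed)
    base_rank = 0
    for _ in range(n_trials):
        rows = _bar_rows(network, rng)
        base_rank = max(base_rank, int(np.linalg.matrix_rank(rows, tol=1e-8)) if rows.size else 0)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for c in network.constraints:
        u, v = c.pair
        if find(u) == find(v):
            continue
        rank_with = 0
        for t in range(n_trials):
            rows = _bar_rows(network, np.random.default_rng(seed + 1000 + t), extra_pair=(u, v))
            rank_with = max(rank_with, int(np.linalg.matrix_rank(rows, tol=1e-8)))
        if rank_with == base_rank:  # trial bar dependent => pair already rigid
            ra, rb = find(u), find(v)
            parent[max(ra, rb)] = min(ra, rb)
    return np.array([find(b) for b in range(n)], dtype=int)
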