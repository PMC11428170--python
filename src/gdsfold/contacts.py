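"""Binary inter-residue contact maps and the shortest-contact-hop metric.

A contact map G marks bead pairs closer than a cutoff r_c (strict <, 8 A
by default).  Folding states are compared either by the Hamming distance
(number of differing unordered pairs) or by the SCH metric

    f_SCH(A, B) = 2 / (N(N-1)) * sum_{i<j} |S^A_ij - S^B_ij| / max(S^A, S^B)

where S is the all-pairs shortest-hop matrix of the contact graph.  The
relative-difference summand makes f_SCH a true metric and down-weights
differences between topologically distant pairs, so SCH tracks real-space
structural similarity far better than raw Hamming counts.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import _kernels
from .bln import Conformation

DEFAULT_CUTOFF = 8.0  # Angstrom
MIN_MUTABLE_SEPARATION = 3  # |i-j| < 3 pairs are backbone-fixed

__all__ = [
    "ContactMap",
    "map_from_conformation",
    "hamming_distance",
    "shortest_hop_matrix",
    "sch_distance",
    "apply_bit_flips",
    "mutable_pairs",
    "write_dense",
    "read_dense",
    "write_edge_list",
    "read_edge_list",
]


class ContactMap:
    """Symmetric binary N x N matrix with a zero diagonal.

    The all-pairs hop matrix is computed lazily and cached, since the
    annealing loops evaluate SCH distances against unchanged maps many
    times.
    """

    __slots__ = ("matrix", "_hops")

    def __init__(self, matrix: np.ndarray):
        m = np.asarray(matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact map must be square")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("contact map entries must be 0 or 1")
        m = m.astype(np.int8)
        if not np.array_equal(m, m.T):
            raise ValueError("contact map must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("contact map diagonal must be zero")
        self.matrix = m
        self._hops: np.ndarray | None = None

    @property
    def n_beads(self) -> int:
        return self.matrix.shape[0]

    def hops(self) -> np.ndarray:
        if self._hops is None:
            self._hops = _kernels.all_pairs_hops(self.matrix, self.n_beads)
        return self._hops

    def copy(self) -> "ContactMap":
        return ContactMap(self.matrix.copy())

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, ContactMap)
                and np.array_equal(self.matrix, other.matrix))

    def __hash__(self) -> int:
        return hash(self.matrix.tobytes())

    def __repr__(self) -> str:
        return (f"ContactMap(N={self.n_beads}, "
                f"contacts={int(self.matrix.sum()) // 2})")


def map_from_conformation(conf: Conformation,
                          r_c: float = DEFAULT_CUTOFF) -> ContactMap:
    """Contact map of a conformation: G_ij = 1 iff r_ij < r_c (strict)."""
    coords = conf.coords if isinstance(conf, Conformation) else np.asarray(conf)
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff ** 2).sum(-1))
    g = (d < r_c).astype(np.int8)
    np.fill_diagonal(g, 0)
    return ContactMap(g)


def _check_same_size(a: ContactMap, b: ContactMap) -> None:
    if a.n_beads != b.n_beads:
        raise ValueError(
            f"contact maps differ in size: {a.n_beads} vs {b.n_beads}")


def hamming_distance(a: ContactMap, b: ContactMap) -> int:
    """Number of unordered pairs i < j on which the two maps differ."""
    _check_same_size(a, b)
    return int(np.sum(a.matrix != b.matrix)) // 2


def shortest_hop_matrix(g: ContactMap) -> np.ndarray:
    """All-pairs shortest hop counts; disconnected pairs capped at N."""
    return g.hops().copy()


def sch_distance(a: ContactMap, b: ContactMap) -> float:
    """Shortest-contact-hop distance in [0, 1)."""
    _check_same_size(a, b)
    if a.n_beads < 2:
        raise ValueError("SCH needs at least two beads")
    return float(_kernels.sch_from_hops(a.hops(), b.hops()))


def mutable_pairs(n: int,
                  min_sep: int = MIN_MUTABLE_SEPARATION) -> np.ndarray:
    """All (i, j) with j - i >= min_sep, as an (n_pairs, 2) int array."""
    iu = np.triu_indices(n, k=min_sep)
    return np.stack(iu, axis=1)


def apply_bit_flips(g: ContactMap, flips,
                    min_sep: int = MIN_MUTABLE_SEPARATION) -> ContactMap:
    """Toggle the listed (k, m) entries symmetrically; returns a new map.

    Pairs closer than min_sep along the chain are backbone-fixed and
    rejected.  Applying the same flip list twice is the identity.
    """
    m = g.matrix.copy()
    for k, mm in flips:
        if k == mm or abs(k - mm) < min_sep:
            raise ValueError(
                f"pair ({k}, {mm}) is not mutable (|i-j| < {min_sep})")
        if not (0 <= k < g.n_beads and 0 <= mm < g.n_beads):
            raise ValueError(f"pair ({k}, {mm}) out of range")
        m[k, mm] ^= 1
        m[mm, k] = m[k, mm]
    return ContactMap(m)


# ---------------------------------------------------------------------------
# serialization: dense 0/1 matrices and sparse edge-list TSV

def write_dense(g: ContactMap, path) -> None:
    np.savetxt(path, g.matrix, fmt="%d")


def read_dense(path) -> ContactMap:
    return ContactMap(np.loadtxt(path, dtype=int, ndmin=2))


def write_edge_list(g: ContactMap, path) -> None:
    """Sparse TSV: header '# n_beads <N>' then one 'i<TAB>j' line per
    contact with i < j (0-based)."""
    ii, jj = np.nonzero(np.triu(g.matrix, k=1))
    with open(path, "w") as fh:
        fh.write(f"# n_beads {g.n_beads}\n")
        for i, j in zip(ii, jj):
            fh.write(f"{i}\t{j}\n")


def read_edge_list(path) -> ContactMap:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("# n_beads"):
        raise ValueError(f"{path}: missing '# n_beads' header")
    n = int(lines[0].split()[-1])
    m = np.zeros((n, n), dtype=np.int8)
    for line in lines[1:]:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        i, j = (int(tok) for tok in line.split())
        m[i, j] = m[j, i] = 1
    return ContactMap(m)
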