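"""Synthetic bead-protein fixtures.

Everything the pipeline consumes can be generated here from a seed: toy
bead sequences with declared hairpin ranges, extended starting chains,
annealed local-minima databases, and perturbed reconstruction targets
(random bit-flip maps, which mix physical and non-physical targets, and
high-temperature-MD maps, which are physical by construction).

The canonical test protein is a 56-bead two-hairpin + helix architecture:
two hydrophobic beta-hairpins flanking a central amphipathic helix,
joined by neutral turns, with a native-biased backbone parametrization
(toy_protein_parameters).  It plays the role of a real multipathway
folder without requiring any external parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bln import BeadSequence, BLNParameters, Conformation, MDConfig, \
    anneal_to_minimum, make_bln_callables, minimize_geometry, run_md_nvt
from .contacts import ContactMap, apply_bit_flips, map_from_conformation, \
    mutable_pairs
from .geometry import rmsd

__all__ = [
    "ToyProteinSpec",
    "toy_protein_parameters",
    "extended_chain",
    "make_toy_protein",
    "build_minima_database",
    "perturb_targets_bitflip",
    "perturb_targets_md",
]


@dataclass(frozen=True)
class ToyProteinSpec:
    """Declarative segment list for a synthetic bead protein.

    Each motif entry is (name, length, label_pattern, dihedral_class):
    the label pattern is tiled over the segment, the dihedral class is one
    of H/E/T.  Segments named 'strand*' belonging to the same hairpin are
    grouped by the 'hairpin' names list.
    """

    length: int = 56
    motif: tuple = (
        ("strand1a", 9, "B", "E"),
        ("turn1", 4, "N", "T"),
        ("strand1b", 9, "B", "E"),
        ("loop1", 2, "N", "T"),
        ("helix", 12, "BBLN", "H"),
        ("loop2", 2, "N", "T"),
        ("strand2a", 8, "B", "E"),
        ("turn2", 4, "N", "T"),
        ("strand2b", 6, "B", "E"),
    )
    hairpins: tuple = (("strand1a", "strand1b"), ("strand2a", "strand2b"))
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(seg[1] for seg in self.motif)
        if total != self.length:
            raise ValueError(
                f"motif lengths sum to {total}, expected {self.length}")


def toy_protein_parameters() -> BLNParameters:
    """Force-field instance for the canonical two-hairpin test protein.

    The BLN parametrization is per-protein: dihedral coefficients encode
    the protein's native secondary structure.  The canonical fixture uses
    a strongly native-biased backbone (doubled strand/helix dihedral
    stiffness relative to the soft library defaults) so the designed
    two-hairpin + helix fold is a stable two-state folder with a funneled
    landscape rather than a glassy collapse.
    """
    return BLNParameters(dihedral_table={
        "H": (0.0, 0.4, 0.4),
        "E": (1.8, 2.4, 0.0),
        "T": (0.2, 0.2, 0.2),
    })


def extended_chain(n: int, bond_length: float = 3.8) -> Conformation:
    """Nearly collinear zigzag chain with exact bond lengths.

    A small fixed transverse dither (planar zigzag of half-angle 0.02 rad)
    keeps every bond exactly `bond_length` while avoiding the collinear
    geometry where angle and dihedral gradients are singular.  Contacts of
    the output are exactly the |i-j| <= 2 pairs at the 8 A cutoff.
    """
    if n < 2:
        raise ValueError("need at least two beads")
    delta = 0.02
    x = np.arange(n) * bond_length * np.cos(delta)
    y = (np.arange(n) % 2) * bond_length * np.sin(delta)
    coords = np.column_stack([x, y, np.zeros(n)])
    return Conformation(coords)


def make_toy_protein(
        spec: ToyProteinSpec = ToyProteinSpec()
) -> tuple[BeadSequence, dict[str, tuple[int, int]]]:
    """Build the bead sequence and declared hairpin residue ranges.

    Returns (sequence, {"beta1": (start, stop), "beta2": ...}) with
    half-open 0-based ranges spanning strand-turn-strand of each hairpin.
    """
    labels = []
    bead_cls = []
    seg_bounds: dict[str, tuple[int, int]] = {}
    pos = 0
    for name, length, pattern, dclass in spec.motif:
        seg = (pattern * (length // len(pattern) + 1))[:length]
        labels.append(seg)
        bead_cls.extend(dclass * length)
        seg_bounds[name] = (pos, pos + length)
        pos += length
    label_str = "".join(labels)
    # dihedral d spans beads d..d+3; classify by the second bead
    dihedral_classes = "".join(bead_cls[d + 1]
                               for d in range(max(0, spec.length - 3)))
    seq = BeadSequence(label_str, dihedral_classes)
    ranges = {}
    for hp_idx, (first, last) in enumerate(spec.hairpins, start=1):
        start = seg_bounds[first][0]
        stop = seg_bounds[last][1]
        ranges[f"beta{hp_idx}"] = (start, stop)
    return seq, ranges


def build_minima_database(seq: BeadSequence,
                          params: BLNParameters | None = None,
                          n_restarts: int = 200,
                          stop_after: int = 20,
                          seed: int = 0,
                          start: Conformation | None = None,
                          start_T: float = 10.0,
                          stage_duration: float = 10.0,
                          dedup_energy: float = 1e-6,
                          dedup_rmsd: float = 0.1,
                          ) -> list[tuple[Conformation, float]]:
    """Annealing-with-restarts database of unique local minima.

    Each restart anneals from the current best-guess global minimum; the
    search stops once the best energy has not improved for `stop_after`
    consecutive restarts (or after n_restarts total).  Minima matching an
    existing entry in both energy (dedup_energy) and superposed RMSD
    (dedup_rmsd) are merged.  Sorted by energy, best first.
    """
    params = params or BLNParameters()
    rng = np.random.default_rng(seed)
    current = (start or extended_chain(seq.n_beads)).copy()
    db: list[tuple[Conformation, float]] = []
    best_e = np.inf
    unimproved = 0
    for _ in range(n_restarts):
        run_seed = int(rng.integers(0, 2 ** 31 - 1))
        try:
            minimum, energy = anneal_to_minimum(
                current, seq, params, start_T=start_T,
                stage_duration=stage_duration, seed=run_seed)
        except RuntimeError:  # MD divergence: log-and-skip per restart
            unimproved += 1
            if unimproved >= stop_after:
                break
            continue
        duplicate = any(
            abs(energy - e) < dedup_energy
            and rmsd(minimum.coords, c.coords) < dedup_rmsd
            for c, e in db)
        if not duplicate:
            db.append((minimum, energy))
        if energy < best_e - dedup_energy:
            best_e = energy
            current = minimum.copy()
            unimproved = 0
        else:
            unimproved += 1
        if unimproved >= stop_after:
            break
    db.sort(key=lambda item: item[1])
    return db


def perturb_targets_bitflip(db: list[tuple[Conformation, float]],
                            n_flips: int = 5, n_targets: int = 100,
                            seed: int = 0, r_c: float = 8.0,
                            ) -> list[tuple[Conformation, ContactMap]]:
    """Bit-flip reconstruction targets: (start structure, flipped map)."""
    if not db:
        raise ValueError("minima database is empty")
    rng = np.random.default_rng(seed)
    n = db[0][0].n_beads
    pairs = mutable_pairs(n)
    out = []
    for _ in range(n_targets):
        conf = db[int(rng.integers(len(db)))][0]
        g = map_from_conformation(conf, r_c)
        if n_flips > 0:
            chosen = rng.choice(len(pairs), size=n_flips, replace=False)
            g = apply_bit_flips(g, pairs[chosen])
        out.append((conf.copy(), g))
    return out


def perturb_targets_md(db: list[tuple[Conformation, float]],
                       seq: BeadSequence,
                       params: BLNParameters | None = None,
                       temperature: float = 1.0, duration: float = 10.0,
                       n_targets: int = 100, seed: int = 0,
                       r_c: float = 8.0,
                       ) -> list[tuple[Conformation, ContactMap]]:
    """Physical reconstruction targets from high-T MD + minimization.

    Each target map is the contact map of a local minimum reached by
    running thermostatted MD at `temperature` from a database entry and
    minimizing; such maps are realizable by construction.
    """
    if not db:
        raise ValueError("minima database is empty")
    params = params or BLNParameters()
    rng = np.random.default_rng(seed)
    energy_fn, force_fn = make_bln_callables(seq, params)
    out = []
    while len(out) < n_targets:
        conf = db[int(rng.integers(len(db)))][0]
        md = MDConfig(temperature=temperature, duration=duration,
                      seed=int(rng.integers(0, 2 ** 31 - 1)),
                      sample_every=10 ** 9)
        try:
            hot = run_md_nvt(conf, seq, params, md)[-1]
        except RuntimeError:
            continue
        minimum, _, _ = minimize_geometry(hot, energy_fn, force_fn,
                                          tol=1e-5)
        out.append((conf.copy(), map_from_conformation(minimum, r_c)))
    return out
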