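"""Plain-text I/O for bead sequences, conformations and run configs.

Formats:
  * sequence file: line 1 = B/L/N bead labels, line 2 = H/E/T dihedral
    classes (length N-3; omitted for chains shorter than 4 beads);
  * XYZ (multi-frame): element column = bead class letter;
  * CA-only bead PDB via biotite with the reversible residue-name map
    B -> ALA, L -> SER, N -> GLY;
  * key-value config files: 'key = value' lines, '#' comments.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .bln import BeadSequence, Conformation

__all__ = [
    "write_sequence",
    "read_sequence",
    "write_xyz",
    "read_xyz",
    "write_bead_pdb",
    "read_bead_pdb",
    "write_config",
    "read_config",
]

BEAD_TO_RESIDUE = {"B": "ALA", "L": "SER", "N": "GLY"}
RESIDUE_TO_BEAD = {v: k for k, v in BEAD_TO_RESIDUE.items()}


def write_sequence(seq: BeadSequence, path) -> None:
    text = seq.labels + "\n"
    if seq.dihedral_classes:
        text += seq.dihedral_classes + "\n"
    Path(path).write_text(text)


def read_sequence(path) -> BeadSequence:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty sequence file")
    labels = lines[0]
    dihedrals = lines[1] if len(lines) > 1 else ""
    return BeadSequence(labels, dihedrals)


def write_xyz(confs, path, labels: str | None = None,
              comments=None) -> None:
    """Write one or more conformations as (multi-frame) XYZ."""
    if isinstance(confs, Conformation):
        confs = [confs]
    with open(path, "w") as fh:
        for k, conf in enumerate(confs):
            n = conf.n_beads
            elems = labels if labels is not None else "C" * n
            comment = "" if comments is None else str(comments[k])
            fh.write(f"{n}\n{comment}\n")
            for i in range(n):
                x, y, z = conf.coords[i]
                fh.write(f"{elems[i]} {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz(path) -> list[tuple[str, Conformation]]:
    """Read multi-frame XYZ; returns [(labels, Conformation), ...]."""
    lines = Path(path).read_text().splitlines()
    frames = []
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        n = int(lines[k].strip())
        body = lines[k + 2:k + 2 + n]
        labels = []
        coords = np.empty((n, 3))
        for i, ln in enumerate(body):
            parts = ln.split()
            labels.append(parts[0])
            coords[i] = [float(v) for v in parts[1:4]]
        frames.append(("".join(labels), Conformation(coords)))
        k += 2 + n
    return frames


def write_bead_pdb(conf: Conformation, seq: BeadSequence, path) -> None:
    n = conf.n_beads
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(conf.coords, dtype=np.float32)
    atoms.chain_id = np.full(n, "A")
    atoms.res_id = np.arange(1, n + 1)
    atoms.res_name = np.array([BEAD_TO_RESIDUE[c] for c in seq.labels])
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.hetero = np.full(n, False)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(path)


def read_bead_pdb(path) -> tuple[str, Conformation]:
    """Returns (bead labels, conformation); dihedral classes are not
    stored in PDB and must come from a sequence file."""
    atoms = PDBFile.read(path).get_structure(model=1)
    ca = atoms[atoms.atom_name == "CA"]
    labels = "".join(RESIDUE_TO_BEAD[r] for r in ca.res_name)
    return labels, Conformation(np.asarray(ca.coord, dtype=float))


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        for key, value in cfg.items():
            fh.write(f"{key} = {value}\n")


def read_config(path) -> dict:
    """Parse 'key = value' lines; values are int/float/bool where they
    parse as such, else strings."""
    out: dict = {}
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        key, _, value = ln.partition("=")
        key = key.strip()
        value = value.strip()
        if value.lower() in ("true", "false"):
            out[key] = value.lower() == "true"
            continue
        for cast in (int, float):
            try:
                out[key] = cast(value)
                break
            except ValueError:
                continue
        else:
            out[key] = value
    return out
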