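"""BLN coarse-grained protein model.

Each residue is a single bead classed Hydrophobic (B), Hydrophilic (L) or
Neutral (N); every backbone dihedral additionally carries a secondary
structure class Helix (H), Extended strand (E) or Turn/coil (T).  The
potential is

    V(r) = sum_bonds  k_b (r - sigma)^2
         + sum_angles (k_theta / 2) (theta - theta0)^2
         + sum_dihedrals  A(1 + cos phi) + B(1 + cos 3 phi) + C(1 + sin phi)
         + sum_{|i-j|>=3}  4 eps S1 [ (sigma/r)^12 - S2 (sigma/r)^6 ]

in reduced units (energy eps, distance Angstrom, mass mu, time tu,
k_B = 1).  The bond term carries the full printed prefactor
k_b = 115.6 eps/A^2 (no 1/2); the angle term uses k_theta/2.
(A, B, C) depend on the dihedral's secondary-structure class and
(S1, S2) on the bead-class pair; both tables are user-editable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from . import _kernels

BEAD_CLASSES = "BLN"
DIHEDRAL_CLASSES = "HET"

__all__ = [
    "BeadSequence",
    "BLNParameters",
    "Conformation",
    "MDConfig",
    "EnergyDivergenceError",
    "bln_energy",
    "bln_gradient",
    "minimize_geometry",
    "run_md_nvt",
    "anneal_to_minimum",
]


class EnergyDivergenceError(RuntimeError):
    """MD energy exceeded the configured bound (or became non-finite)."""


@dataclass(frozen=True)
class BeadSequence:
    """Bead classes plus per-dihedral secondary-structure classes.

    labels : string over {B, L, N}, one char per bead.
    dihedral_classes : string over {H, E, T}, length N - 3 (one per
        dihedral); empty for chains shorter than 4 beads.
    """

    labels: str
    dihedral_classes: str

    def __post_init__(self) -> None:
        if any(c not in BEAD_CLASSES for c in self.labels):
            raise ValueError(f"bead labels must be drawn from {BEAD_CLASSES!r}")
        if any(c not in DIHEDRAL_CLASSES for c in self.dihedral_classes):
            raise ValueError(
                f"dihedral classes must be drawn from {DIHEDRAL_CLASSES!r}")
        expected = max(0, len(self.labels) - 3)
        if len(self.dihedral_classes) != expected:
            raise ValueError(
                f"need {expected} dihedral classes for {len(self.labels)} "
                f"beads, got {len(self.dihedral_classes)}")

    @property
    def n_beads(self) -> int:
        return len(self.labels)


# Literature-style class tables.  The bead-pair (S1, S2) scalings follow the
# standard convention: B-B fully attractive, L-L and L-B weakly repulsive
# (negative S2 flips the r^-6 term), N pairs purely repulsive (S2 = 0).
DEFAULT_PAIR_TABLE: dict[frozenset, tuple[float, float]] = {
    frozenset("B"): (1.0, 1.0),
    frozenset("LL"): (2.0 / 3.0, -1.0),
    frozenset("LB"): (2.0 / 3.0, -1.0),
    frozenset("NN"): (1.0, 0.0),
    frozenset("NB"): (1.0, 0.0),
    frozenset("NL"): (1.0, 0.0),
}

# (A, B, C) per dihedral class.  H favours the gauche well through the
# sin term, E favours trans through the cos terms, T is soft/flexible.
DEFAULT_DIHEDRAL_TABLE: dict[str, tuple[float, float, float]] = {
    "H": (0.0, 0.2, 0.2),
    "E": (0.9, 1.2, 0.0),
    "T": (0.2, 0.2, 0.2),
}


@dataclass(frozen=True)
class BLNParameters:
    """Force-field constants; defaults are the printed reduced-unit values."""

    k_b: float = 115.6
    sigma: float = 3.8
    k_theta: float = 10.0
    theta0: float = 1.8326
    epsilon: float = 1.0
    dihedral_table: dict = field(
        default_factory=lambda: dict(DEFAULT_DIHEDRAL_TABLE))
    pair_table: dict = field(default_factory=lambda: dict(DEFAULT_PAIR_TABLE))

    def compile_tables(
            self, seq: BeadSequence
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Expand class tables into per-pair / per-dihedral arrays."""
        n = seq.n_beads
        s1 = np.zeros((n, n))
        s2 = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                key = frozenset(seq.labels[i] + seq.labels[j])
                s1[i, j], s2[i, j] = self.pair_table[key]
        dih = np.zeros((max(0, n - 3), 3))
        for d, cls in enumerate(seq.dihedral_classes):
            dih[d] = self.dihedral_table[cls]
        return s1, s2, dih


@dataclass
class Conformation:
    """Cartesian bead coordinates (N, 3) in Angstrom, optional velocities."""

    coords: np.ndarray
    velocities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.coords.shape:
                raise ValueError("velocities must match coords shape")

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "Conformation":
        vel = None if self.velocities is None else self.velocities.copy()
        return Conformation(self.coords.copy(), vel)


@dataclass(frozen=True)
class MDConfig:
    """NVT molecular-dynamics settings (reduced units)."""

    dt: float = 1e-3
    temperature: float = 1.0
    collision_rate: float = 1e-3  # per-bead per-step Andersen probability
    duration: float = 10.0  # tu
    seed: int = 0
    sample_every: int = 100  # steps between stored frames
    energy_bound: float = 1e8

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        if not 0.0 <= self.collision_rate <= 1.0:
            raise ValueError("collision_rate must lie in [0, 1]")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


def _check(conf: Conformation, seq: BeadSequence) -> None:
    if conf.n_beads != seq.n_beads:
        raise ValueError(
            f"conformation has {conf.n_beads} beads, sequence {seq.n_beads}")


def bln_energy(conf: Conformation, seq: BeadSequence,
               params: BLNParameters | None = None) -> float:
    """Total BLN potential energy in eps; +inf for singular geometry."""
    params = params or BLNParameters()
    _check(conf, seq)
    s1, s2, dih = params.compile_tables(seq)
    energy, _ = _kernels.bln_energy_forces(
        conf.coords, s1, s2, dih, params.k_b, params.sigma,
        params.k_theta, params.theta0, params.epsilon)
    return float(energy)


def bln_gradient(conf: Conformation, seq: BeadSequence,
                 params: BLNParameters | None = None) -> np.ndarray:
    """Forces -grad V, shape (N, 3), in eps/Angstrom."""
    params = params or BLNParameters()
    _check(conf, seq)
    s1, s2, dih = params.compile_tables(seq)
    _, forces = _kernels.bln_energy_forces(
        conf.coords, s1, s2, dih, params.k_b, params.sigma,
        params.k_theta, params.theta0, params.epsilon)
    return forces


def make_bln_callables(
        seq: BeadSequence, params: BLNParameters | None = None
) -> tuple[Callable[[np.ndarray], float],
           Callable[[np.ndarray], np.ndarray]]:
    """(energy_fn, force_fn) closures over precompiled tables.

    Both accept an (N, 3) coordinate array; force_fn returns -grad V.
    """
    params = params or BLNParameters()
    s1 = s2 = dih = None

    def _tables(n):
        nonlocal s1, s2, dih
        if s1 is None:
            if n != seq.n_beads:
                raise ValueError("coordinate size does not match sequence")
            t = params.compile_tables(seq)
            s1, s2, dih = t
        return s1, s2, dih

    def energy_fn(coords: np.ndarray) -> float:
        a, b, d = _tables(coords.shape[0])
        e, _ = _kernels.bln_energy_forces(
            coords, a, b, d, params.k_b, params.sigma,
            params.k_theta, params.theta0, params.epsilon)
        return float(e)

    def force_fn(coords: np.ndarray) -> np.ndarray:
        a, b, d = _tables(coords.shape[0])
        _, f = _kernels.bln_energy_forces(
            coords, a, b, d, params.k_b, params.sigma,
            params.k_theta, params.theta0, params.epsilon)
        return f

    return energy_fn, force_fn


def minimize_geometry(conf: Conformation,
                      energy_fn: Callable[[np.ndarray], float],
                      gradient_fn: Callable[[np.ndarray], np.ndarray],
                      tol: float = 1e-6,
                      max_iter: int = 50_000
                      ) -> tuple[Conformation, float, bool]:
    """Quasi-Newton (L-BFGS) minimization to RMS force <= tol.

    gradient_fn returns forces (-grad).  Returns (conformation, energy,
    converged).  converged is False on non-finite evaluations, optimizer
    abort, or an unmet force tolerance; the returned energy is never above
    the starting energy.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    n = conf.n_beads
    start_e = energy_fn(conf.coords)
    saw_bad = [not np.isfinite(start_e)]

    def fun(x: np.ndarray) -> tuple[float, np.ndarray]:
        coords = x.reshape(n, 3)
        e = energy_fn(coords)
        g = -gradient_fn(coords)
        if not np.isfinite(e) or not np.all(np.isfinite(g)):
            saw_bad[0] = True
            return 1e100, np.zeros(3 * n)
        return e, g.ravel()

    try:
        res = _scipy_minimize(
            fun, conf.coords.ravel(), jac=True, method="L-BFGS-B",
            options={"maxiter": max_iter, "gtol": tol * 0.1,
                     "ftol": 1e-14, "maxls": 60})
        x = res.x
    except (ValueError, FloatingPointError):
        return conf.copy(), float(start_e), False
    out = Conformation(x.reshape(n, 3))
    e_out = energy_fn(out.coords)
    if not np.isfinite(e_out) or e_out > start_e:
        return conf.copy(), float(start_e), False
    forces = gradient_fn(out.coords)
    rms = float(np.sqrt(np.mean(forces ** 2)))
    converged = bool(np.isfinite(rms) and rms <= tol and not saw_bad[0])
    return out, float(e_out), converged


def run_md_nvt(conf: Conformation, seq: BeadSequence,
               params: BLNParameters | None = None,
               md: MDConfig = MDConfig()) -> list[Conformation]:
    """Velocity-Verlet NVT trajectory with an Andersen thermostat.

    Missing initial velocities are drawn from Maxwell-Boltzmann at the run
    temperature.  Deterministic for a fixed MDConfig.seed.  Raises
    EnergyDivergenceError when |V| exceeds md.energy_bound.
    """
    params = params or BLNParameters()
    _check(conf, seq)
    s1, s2, dih = params.compile_tables(seq)
    rng = np.random.default_rng(md.seed)
    if conf.velocities is None:
        vels = rng.normal(scale=np.sqrt(md.temperature),
                          size=conf.coords.shape)
    else:
        vels = conf.velocities
    kseed = int(rng.integers(0, 2 ** 31 - 1))
    traj, vtraj, n_saved, ok = _kernels.md_nvt_run(
        conf.coords, vels, s1, s2, dih, params.k_b, params.sigma,
        params.k_theta, params.theta0, params.epsilon,
        md.n_steps, md.dt, md.temperature, md.collision_rate, kseed,
        md.sample_every, md.energy_bound)
    if not ok:
        raise EnergyDivergenceError(
            f"energy exceeded bound {md.energy_bound:g} eps during MD "
            f"(T={md.temperature:g}, dt={md.dt:g})")
    return [Conformation(traj[i].copy(), vtraj[i].copy())
            for i in range(n_saved)]


def anneal_to_minimum(conf: Conformation, seq: BeadSequence,
                      params: BLNParameters | None = None,
                      start_T: float = 10.0, n_halvings: int = 10,
                      stage_duration: float = 10.0, dt: float = 1e-3,
                      collision_rate: float = 1e-3, seed: int = 0,
                      min_tol: float = 1e-6
                      ) -> tuple[Conformation, float]:
    """Simulated-annealing MD quench followed by L-BFGS minimization.

    Runs `stage_duration` tu of thermostatted MD at each temperature of the
    ladder start_T, start_T/2, ..., start_T/2^n_halvings, then minimizes.
    """
    params = params or BLNParameters()
    _check(conf, seq)
    current = conf.copy()
    rng = np.random.default_rng(seed)
    for stage in range(n_halvings + 1):
        temp = start_T / 2.0 ** stage
        md = MDConfig(dt=dt, temperature=temp, collision_rate=collision_rate,
                      duration=stage_duration,
                      seed=int(rng.integers(0, 2 ** 31 - 1)),
                      sample_every=10 ** 9)
        current = run_md_nvt(current, seq, params, md)[-1]
        current.velocities = None  # re-thermalize at the next rung
    energy_fn, force_fn = make_bln_callables(seq, params)
    final, energy, _ = minimize_geometry(current, energy_fn, force_fn,
                                         tol=min_tol)
    return final, energy
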