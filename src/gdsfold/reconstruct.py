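"""Back-mapping contact maps to Cartesian bead structures.

A target contact map G is enforced through a graph restraining potential
(GRP) W(r, G) added to the physical BLN energy V(r); minimizing
V_total = V + W and then relaxing under V alone yields a physical
conformation consistent with G wherever G is geometrically realizable.

Two GRPs are provided.  The production form is a set of one-sided
harmonics (shared force constant k = 100 eps/A^2) that act only when a
restraint is violated: contacts pulled inside r_con = 8 A, non-contacts
pushed outside r_con, and every nonbonded pair pushed outside
r_steric = 2 A.  The legacy form (harmonic contact term plus a bounded
logistic repulsion) is retained as a baseline; its soft repulsion is
prone to numerical blow-ups on conflicting restraints.

An alternative to gradient back-mapping is Metropolis crankshaft Monte
Carlo on W: single-bead rotations about the neighbour axis with outright
rejection of steric clashes, followed by minimization under V.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial.distance import pdist

from . import _kernels
from .bln import BeadSequence, BLNParameters, Conformation
from .contacts import ContactMap, map_from_conformation, mutable_pairs, \
    sch_distance, apply_bit_flips

__all__ = [
    "GRPNewConfig",
    "DEFAULT_RECONSTRUCTION_GRP",
    "GRPOldConfig",
    "ReconstructionResult",
    "grp_new_energy",
    "grp_new_gradient",
    "grp_old_energy",
    "reconstruct_minimize",
    "reconstruct_crankshaft",
    "benchmark_reconstruction",
    "BenchmarkReport",
]

MIN_PAIR_DISTANCE = 0.5  # A; closer output pairs count as numerical failure


@dataclass(frozen=True)
class GRPNewConfig:
    """One-sided harmonic GRP constants."""

    k: float = 100.0  # eps / A^2
    r_con: float = 8.0  # A, contact-formation threshold
    r_steric: float = 2.0  # A, steric floor
    # Restraint margin (A): contacts are pulled inside r_con - margin and
    # non-contacts pushed outside r_con + margin, so pairs end up strictly
    # clear of the classification threshold.  Zero reproduces the bare
    # one-sided form; back-mapping uses DEFAULT_RECONSTRUCTION_GRP.
    margin: float = 0.0
    # Separate steric floor (A) for second neighbours (|i-j| = 2);
    # 0 disables.  The harmonic angle term is finite at theta = 0, so an
    # angle can collapse its i/i+2 pair through the minimizer unless the
    # restraining potential keeps such pairs near the bond-length scale.
    r_steric13: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.r_steric < self.r_con):
            raise ValueError("need 0 < r_steric < r_con")
        if self.k <= 0:
            raise ValueError("k must be positive")


# Back-mapping default: a 0.8 A margin keeps reconstructed pairs strictly
# inside/outside the 8 A contact threshold so the final physical relaxation
# does not flip borderline pairs.
DEFAULT_RECONSTRUCTION_GRP = GRPNewConfig(margin=0.8, r_steric13=3.8)


@dataclass(frozen=True)
class GRPOldConfig:
    """Legacy GRP: harmonic contacts + bounded logistic repulsion."""

    kappa1: float = 1.0  # eps / A^2
    kappa2: float = 6.0  # eps
    gamma: float = 6.0  # A^2
    r_min: float = 2.0  # A
    r_max: float = 8.0  # A

    def __post_init__(self) -> None:
        if self.r_min >= self.r_max:
            raise ValueError("need r_min < r_max")

    @property
    def r_con(self) -> float:
        return 0.5 * (self.r_min + self.r_max)


@dataclass
class ReconstructionResult:
    conformation: Conformation
    achieved_map: ContactMap
    sch_to_target: float
    failed: bool
    diagnostics: str = ""


def grp_new_energy(conf: Conformation, g: ContactMap,
                   cfg: GRPNewConfig = GRPNewConfig()) -> float:
    """W(r, G) of the one-sided harmonic GRP; zero iff all restraints hold."""
    e, _ = _kernels.grp_new_energy_forces(
        conf.coords, g.matrix, cfg.k, cfg.r_con, cfg.r_steric, cfg.margin,
        cfg.r_steric13)
    return float(e)


def grp_new_gradient(conf: Conformation, g: ContactMap,
                     cfg: GRPNewConfig = GRPNewConfig()) -> np.ndarray:
    """Forces -grad W, shape (N, 3)."""
    _, f = _kernels.grp_new_energy_forces(
        conf.coords, g.matrix, cfg.k, cfg.r_con, cfg.r_steric, cfg.margin,
        cfg.r_steric13)
    return f


def _nonbonded_mask(n: int) -> np.ndarray:
    idx = np.arange(n)
    return (idx[None, :] - idx[:, None]) >= 3  # upper triangle, |i-j| >= 3


def grp_old_energy(conf: Conformation, g: ContactMap,
                   cfg: GRPOldConfig = GRPOldConfig()) -> float:
    """Legacy GRP energy (smooth everywhere, bounded repulsion)."""
    coords = conf.coords
    n = coords.shape[0]
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt((diff ** 2).sum(-1))
    mask = _nonbonded_mask(n)
    contact = (g.matrix != 0) & mask
    noncontact = (g.matrix == 0) & mask
    e = cfg.kappa1 * ((r[contact] - cfg.r_con) ** 2).sum()
    x = np.clip((cfg.r_max ** 2 - r[noncontact] ** 2) / cfg.gamma, -500, 500)
    e += cfg.kappa2 * (1.0 / (1.0 + np.exp(-x))).sum()
    return float(e)


def _grp_old_gradient(coords: np.ndarray, gmat: np.ndarray,
                      cfg: GRPOldConfig) -> np.ndarray:
    n = coords.shape[0]
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt((diff ** 2).sum(-1))
    np.fill_diagonal(r, 1.0)
    mask = _nonbonded_mask(n)
    mask = mask | mask.T
    dedr = np.zeros((n, n))
    contact = (gmat != 0) & mask
    noncontact = (gmat == 0) & mask
    dedr[contact] = 2.0 * cfg.kappa1 * (r[contact] - cfg.r_con)
    x = (cfg.r_max ** 2 - r ** 2) / cfg.gamma
    sig = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
    dedr[noncontact] = (cfg.kappa2 * sig[noncontact]
                        * (1.0 - sig[noncontact])
                        * (-2.0 * r[noncontact] / cfg.gamma))
    coef = dedr / r
    grad = (coef[:, :, None] * diff).sum(axis=1)
    return -grad  # forces


def _lbfgs(x0: np.ndarray, fun, max_iter: int, gtol: float):
    """L-BFGS with non-finite trapping; returns (x, ok, saw_nonfinite)."""
    saw_bad = [False]

    def wrapped(x):
        e, g = fun(x)
        if not np.isfinite(e) or not np.all(np.isfinite(g)):
            saw_bad[0] = True
            return 1e100, np.zeros_like(x)
        return e, g

    try:
        res = _scipy_minimize(wrapped, x0, jac=True, method="L-BFGS-B",
                              options={"maxiter": max_iter, "gtol": gtol,
                                       "ftol": 1e-12, "maxls": 60})
        return res.x, True, saw_bad[0]
    except (ValueError, FloatingPointError, np.linalg.LinAlgError):
        return x0, False, True


COLLAPSED_ANGLE_DISTANCE = 2.0  # A; i/i+2 pairs below this are repaired


def _steric_repair_fun(n: int, v_fun, k: float = 100.0,
                       r13: float = 3.8, r_far: float = 2.0):
    """V plus steric-only hinges: second neighbours pushed outside r13,
    |i-j| >= 3 pairs outside r_far.  Used to lift a physical relaxation
    out of collapsed-angle artifact basins (the harmonic angle term is
    finite at theta = 0, so such basins are genuine V minima)."""
    idx = np.arange(n)
    sep = np.abs(idx[None, :] - idx[:, None])
    iu = np.triu_indices(n, k=2)
    floors = np.where(sep[iu] == 2, r13, r_far)

    def fun(x):
        e, grad = v_fun(x)
        coords = x.reshape(n, 3)
        diff = coords[iu[0]] - coords[iu[1]]
        r = np.sqrt((diff ** 2).sum(-1))
        viol = np.clip(floors - r, 0.0, None)
        e += 0.5 * k * float((viol ** 2).sum())
        dedr = -k * viol / np.maximum(r, 1e-12)
        gmat = np.zeros((n, 3))
        np.add.at(gmat, iu[0], dedr[:, None] * diff)
        np.add.at(gmat, iu[1], -dedr[:, None] * diff)
        return e, grad + gmat.ravel()

    return fun


def _min_distances(coords: np.ndarray) -> tuple[float, float]:
    """(min |i-j|>=3 distance, min |i-j|=2 distance)."""
    n = coords.shape[0]
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    idx = np.arange(n)
    sep = np.abs(idx[None, :] - idx[:, None])
    far = d[sep >= 3].min() if n > 3 else np.inf
    second = d[sep == 2].min() if n > 2 else np.inf
    return float(far), float(second)


def _finalize(coords: np.ndarray, g: ContactMap, ok: bool,
              note: str) -> ReconstructionResult:
    finite = bool(np.all(np.isfinite(coords)))
    if finite:
        min_d = float(pdist(coords).min()) if coords.shape[0] > 1 else np.inf
    else:
        coords = np.zeros_like(coords)
        min_d = 0.0
    failed = (not ok) or (not finite) or (min_d < MIN_PAIR_DISTANCE)
    conf = Conformation(coords)
    amap = map_from_conformation(conf)
    sch = sch_distance(amap, g)
    diag = note
    if failed:
        diag = (note + "; " if note else "") + (
            "non-finite geometry" if not finite else
            f"min pair distance {min_d:.3f} A" if min_d < MIN_PAIR_DISTANCE
            else "optimizer abort")
    return ReconstructionResult(conf, amap, sch, failed, diag)


def _physical_relax(x: np.ndarray, v_fun, n: int, max_iter: int,
                    tol: float, max_repairs: int = 3):
    """Minimize V, repairing collapsed-angle artifacts.

    If the V minimum has a second-neighbour pair below
    COLLAPSED_ANGLE_DISTANCE (or any far pair below MIN_PAIR_DISTANCE),
    re-minimize under V plus steric-only hinges and descend again; the
    returned configuration always comes from a plain V minimization.
    """
    x2, ok, bad = _lbfgs(x, v_fun, max_iter, tol)
    repair_fun = None
    for _ in range(max_repairs):
        if not np.all(np.isfinite(x2)):
            break
        far, second = _min_distances(x2.reshape(n, 3))
        if far >= MIN_PAIR_DISTANCE and second >= COLLAPSED_ANGLE_DISTANCE:
            break
        if repair_fun is None:
            repair_fun = _steric_repair_fun(n, v_fun)
        x_r, ok_r, bad_r = _lbfgs(x2, repair_fun, max_iter, tol)
        x2, ok2, bad2 = _lbfgs(x_r, v_fun, max_iter, tol)
        ok = ok and ok_r and ok2
        bad = bad or bad_r or bad2
    return x2, ok, bad


def reconstruct_minimize(conf0: Conformation, g: ContactMap,
                         seq: BeadSequence,
                         params: BLNParameters | None = None,
                         grp: GRPNewConfig | GRPOldConfig | None = None,
                         tol: float = 1e-5,
                         max_iter: int = 20_000,
                         n_anneal_retries: int = 0,
                         anneal_t_high: float = 1.0,
                         anneal_steps: int = 2500,
                         seed: int = 0) -> ReconstructionResult:
    """Minimize V + W from conf0, then V alone; report map fidelity.

    With n_anneal_retries > 0, a run whose achieved map misses the target
    is retried from configurations produced by short thermostatted MD on
    the restrained surface V + W (cooling ladder from anneal_t_high); the
    best result by SCH distance is kept.  Thermal retries let the
    back-mapping escape local minima of the mixed surface that trap plain
    quasi-Newton descent.

    Numerical failure (captured in the result, never raised): non-finite
    output, optimizer abort, or any output pair closer than 0.5 A.
    """
    params = params or BLNParameters()
    grp = grp if grp is not None else DEFAULT_RECONSTRUCTION_GRP
    n = conf0.n_beads
    s1, s2, dih = params.compile_tables(seq)
    gmat = g.matrix
    use_old = isinstance(grp, GRPOldConfig)

    def v_fun(x):
        coords = x.reshape(n, 3)
        e, f = _kernels.bln_energy_forces(
            coords, s1, s2, dih, params.k_b, params.sigma,
            params.k_theta, params.theta0, params.epsilon)
        return e, -f.ravel()

    def vw_fun(x):
        coords = x.reshape(n, 3)
        e, f = _kernels.bln_energy_forces(
            coords, s1, s2, dih, params.k_b, params.sigma,
            params.k_theta, params.theta0, params.epsilon)
        if use_old:
            we = grp_old_energy(Conformation(coords), g, grp)
            wf = _grp_old_gradient(coords, gmat, grp)
        else:
            we, wf = _kernels.grp_new_energy_forces(
                coords, gmat, grp.k, grp.r_con, grp.r_steric, grp.margin,
                grp.r_steric13)
        return e + we, -(f + wf).ravel()

    def _descend(x0):
        x1, ok1, bad1 = _lbfgs(x0, vw_fun, max_iter, tol)
        x2, ok2, bad2 = _physical_relax(x1, v_fun, n, max_iter, tol)
        note = "restrained+physical minimization"
        if bad1 or bad2:
            note += " (transient non-finite evaluations recovered)"
        return _finalize(x2.reshape(n, 3), g, ok1 and ok2, note)

    best = _descend(conf0.coords.ravel())
    if use_old or n_anneal_retries <= 0:
        return best
    rng = np.random.default_rng(seed)
    ladder_base = np.array([1.0, 1.0 / 3.0, 1.0 / 9.0, 1.0 / 30.0])
    attempt = 0
    while best.sch_to_target > 0.0 and attempt < n_anneal_retries:
        base = (best.conformation.coords if attempt % 2
                else conf0.coords)
        warm, ok = _kernels.md_vw_run(
            base, s1, s2, dih, params.k_b, params.sigma, params.k_theta,
            params.theta0, params.epsilon, gmat, grp.k, grp.r_con,
            grp.r_steric, grp.margin, grp.r_steric13, int(anneal_steps),
            anneal_t_high * ladder_base, 1e-3, 5e-3,
            int(rng.integers(0, 2 ** 31 - 1)))
        attempt += 1
        if not ok:
            continue
        res = _descend(warm.ravel())
        if not res.failed and res.sch_to_target < best.sch_to_target:
            best = res
    return best


def reconstruct_crankshaft(conf0: Conformation, g: ContactMap,
                           seq: BeadSequence,
                           params: BLNParameters | None = None,
                           grp: GRPNewConfig | None = None,
                           n_steps: int = 100_000,
                           t_start: float = 1.0, t_end: float = 0.01,
                           seed: int = 0,
                           tol: float = 1e-5,
                           max_iter: int = 20_000) -> ReconstructionResult:
    """Crankshaft Metropolis MC on W(r, G), then minimize under V.

    Interior beads rotate about the axis through their chain neighbours
    (angle uniform on [-pi, pi]); terminal beads pivot about a random axis
    through their neighbour.  Proposals creating a nonbonded pair closer
    than r_steric are rejected outright.
    """
    params = params or BLNParameters()
    grp = grp if grp is not None else DEFAULT_RECONSTRUCTION_GRP
    n = conf0.n_beads
    coords, w_final, n_acc = _kernels.crankshaft_run(
        conf0.coords, g.matrix, grp.k, grp.r_con, grp.r_steric, grp.margin,
        grp.r_steric13, int(n_steps), t_start, t_end,
        int(seed) % (2 ** 31 - 1))
    s1, s2, dih = params.compile_tables(seq)

    def v_fun(x):
        c = x.reshape(n, 3)
        e, f = _kernels.bln_energy_forces(
            c, s1, s2, dih, params.k_b, params.sigma,
            params.k_theta, params.theta0, params.epsilon)
        return e, -f.ravel()

    x2, ok, _ = _physical_relax(coords.ravel(), v_fun, n, max_iter, tol)
    note = f"crankshaft MC ({n_acc}/{n_steps} accepted, final W={w_final:.3g})"
    return _finalize(x2.reshape(n, 3), g, ok, note)


@dataclass
class BenchmarkReport:
    method: str
    n_trials: int
    failure_pct: float
    mean_sch_to_target: float
    table: pd.DataFrame = field(repr=False)

    def to_text(self) -> str:
        lines = [self.table.to_string(index=False), "",
                 f"method: {self.method}",
                 f"trials: {self.n_trials}",
                 f"% numerical failures: {self.failure_pct:.1f}",
                 f"mean SCH distance to target: "
                 f"{self.mean_sch_to_target:.4f}"]
        return "\n".join(lines)


def benchmark_reconstruction(minima_db: Sequence[tuple[Conformation, float]],
                             seq: BeadSequence,
                             params: BLNParameters | None = None,
                             n_trials: int = 500, n_flips: int = 5,
                             method: str = "new-grp", seed: int = 0,
                             grp_new: GRPNewConfig | None = None,
                             grp_old: GRPOldConfig = GRPOldConfig(),
                             crankshaft_steps: int = 100_000,
                             ) -> BenchmarkReport:
    """Bit-flip reconstruction benchmark over a local-minima database.

    Per trial: draw a random minimum, toggle n_flips random mutable
    contact-map entries, reconstruct with the chosen method, record the
    failure flag and the SCH distance to the target.  Failures are the
    measurement, never exceptions.
    """
    if method not in ("new-grp", "old-grp", "crankshaft"):
        raise ValueError(f"unknown reconstruction method {method!r}")
    params = params or BLNParameters()
    grp_new = grp_new if grp_new is not None else DEFAULT_RECONSTRUCTION_GRP
    rng = np.random.default_rng(seed)
    rows = []
    pairs = mutable_pairs(seq.n_beads)
    for trial in range(n_trials):
        if not minima_db:
            break
        idx = int(rng.integers(len(minima_db)))
        start = minima_db[idx][0]
        gmap = map_from_conformation(start)
        chosen = rng.choice(len(pairs), size=n_flips, replace=False)
        target = apply_bit_flips(gmap, pairs[chosen])
        trial_seed = int(rng.integers(0, 2 ** 31 - 1))
        if method == "crankshaft":
            res = reconstruct_crankshaft(start, target, seq, params,
                                         grp=grp_new, seed=trial_seed,
                                         n_steps=crankshaft_steps)
        else:
            grp = grp_new if method == "new-grp" else grp_old
            res = reconstruct_minimize(start, target, seq, params, grp=grp)
        rows.append({"method": method, "trial": trial, "seed": trial_seed,
                     "failed": res.failed,
                     "sch_to_target": res.sch_to_target})
    table = pd.DataFrame(rows, columns=["method", "trial", "seed", "failed",
                                        "sch_to_target"])
    n_done = len(table)
    failure_pct = 100.0 * table["failed"].mean() if n_done else 0.0
    mean_sch = float(table["sch_to_target"].mean()) if n_done else 0.0
    return BenchmarkReport(method, n_done, float(failure_pct), mean_sch,
                           table)
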