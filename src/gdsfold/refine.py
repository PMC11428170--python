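"""Minimum-energy-path tooling: LST interpolation, freezing-string growth,
NEB refinement with QuickMin, and the floored-energy path score.

All operations are generic over an (energy_fn, gradient_fn) contract on
flat configuration vectors, where gradient_fn returns *forces* (-grad V),
matching the convention used by the minimizer.  Production code binds the
BLN potential; analytic 1D surfaces exercise the same code paths in tests.

The floored energy of an energy profile (E_1, ..., E_n) is the sum of all
uphill increments  dE+ = sum_k max(0, E_{k+1} - E_k):  a kinetic
plausibility score that is zero for monotone downhill paths and invariant
to shifting the profile by a constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

__all__ = [
    "ImagePath",
    "FSMConfig",
    "NEBConfig",
    "lst_interpolate",
    "fsm_grow",
    "neb_optimize",
    "floored_energy",
]


@dataclass
class ImagePath:
    """Ordered configurations with parallel energies; endpoints immutable."""

    images: list[np.ndarray]
    energies: np.ndarray
    converged: bool = False

    def __post_init__(self) -> None:
        if len(self.images) < 2:
            raise ValueError("a path needs at least two images")
        self.energies = np.asarray(self.energies, dtype=float)
        if len(self.energies) != len(self.images):
            raise ValueError("energies must parallel images")


@dataclass(frozen=True)
class FSMConfig:
    max_images_per_side: int = 10
    advance_rmsd_cap: float = 2.0  # A
    freeze_force_threshold: float = 100.0  # eps / A, RMS
    n_resampled: int = 10
    perp_relax_steps: int = 20


@dataclass(frozen=True)
class NEBConfig:
    max_iter: int = 10_000
    rms_force_tol: float = 1e-4  # eps / A
    max_force_tol: float = 1e-2  # eps / A
    spring_constant: float = 1.0  # eps / A^2
    dt: float = 0.05  # QuickMin time step


def _n_particles(x: np.ndarray) -> int:
    return x.size // 3 if x.size % 3 == 0 and x.size >= 3 else x.size


def _cfg_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.sum((a - b) ** 2) / _n_particles(a)))


def _is_3d(x: np.ndarray) -> bool:
    return x.size % 3 == 0 and x.size >= 9


def lst_interpolate(a: np.ndarray, b: np.ndarray, f: float,
                    regularization: float = 1e-6) -> np.ndarray:
    """Linear-synchronous-transit interpolant at fraction f in [0, 1].

    For 3D configurations, minimizes the LST deviation functional: squared
    error to linearly interpolated internal pairwise distances weighted by
    d^-4, plus a small Cartesian regularization toward the linear
    interpolant.  Seeded from Cartesian interpolation; falls back to it
    (with a warning) if the inner minimization fails.  Non-3D vectors are
    interpolated linearly.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("endpoint dimensionality mismatch")
    if f <= 0.0:
        return a.copy()
    if f >= 1.0:
        return b.copy()
    lin = (1.0 - f) * a + f * b
    if not _is_3d(a):
        return lin
    n = a.size // 3
    ra = a.reshape(n, 3)
    rb = b.reshape(n, 3)
    iu = np.triu_indices(n, k=1)

    def _dists(r):
        d = r[:, None, :] - r[None, :, :]
        return np.sqrt((d ** 2).sum(-1))[iu]

    d_target = (1.0 - f) * _dists(ra) + f * _dists(rb)
    w = 1.0 / np.maximum(d_target, 1e-6) ** 4

    def fun(x):
        r = x.reshape(n, 3)
        diff = r[:, None, :] - r[None, :, :]
        dmat = np.sqrt((diff ** 2).sum(-1))
        np.fill_diagonal(dmat, 1.0)
        dv = dmat[iu]
        err = dv - d_target
        val = float((w * err ** 2).sum()) \
            + regularization * float(((x - lin) ** 2).sum())
        coef = np.zeros((n, n))
        coef[iu] = 2.0 * w * err / dv
        coef = coef + coef.T
        grad = (coef[:, :, None] * diff).sum(axis=1).ravel()
        grad += 2.0 * regularization * (x - lin)
        return val, grad

    try:
        res = _scipy_minimize(fun, lin, jac=True, method="L-BFGS-B",
                              options={"maxiter": 500, "gtol": 1e-10})
        if not np.all(np.isfinite(res.x)):
            raise ValueError("non-finite LST solution")
        return res.x
    except (ValueError, FloatingPointError):
        warnings.warn("LST minimization failed; using Cartesian "
                      "interpolation", RuntimeWarning)
        return lin


def _perp_relax(x: np.ndarray, tau: np.ndarray,
                energy_fn, gradient_fn, n_steps: int,
                max_move: float) -> np.ndarray:
    """Minimize the advancing image perpendicular to tau (projected
    steepest descent with backtracking), keeping within max_move RMSD."""
    x = x.copy()
    start = x.copy()
    e = energy_fn(x)
    step = 0.05
    for _ in range(n_steps):
        force = np.asarray(gradient_fn(x), dtype=float).ravel()
        f_perp = force - np.dot(force, tau) * tau
        norm = np.linalg.norm(f_perp)
        if norm < 1e-10:
            break
        trial = x + step * f_perp
        if _cfg_rmsd(trial, start) > max_move:
            break
        e_trial = energy_fn(trial)
        if np.isfinite(e_trial) and e_trial < e:
            x, e = trial, e_trial
            step = min(step * 1.5, 0.5)
        else:
            step *= 0.4
            if step < 1e-6:
                break
    return x


def fsm_grow(a: np.ndarray, b: np.ndarray,
             energy_fn: Callable[[np.ndarray], float],
             gradient_fn: Callable[[np.ndarray], np.ndarray],
             cfg: FSMConfig = FSMConfig()) -> ImagePath:
    """Freezing-string growth of an initial path between two endpoints.

    Frontier images advance alternately toward the opposite frontier by
    LST steps capped at cfg.advance_rmsd_cap RMSD, each new image relaxed
    only perpendicular to the local tangent.  A frontier freezes when its
    RMS force exceeds cfg.freeze_force_threshold.  The final node string is
    resampled to cfg.n_resampled equidistant images by LST.
    """
    a = np.asarray(a, dtype=float).ravel().copy()
    b = np.asarray(b, dtype=float).ravel().copy()
    if a.shape != b.shape:
        raise ValueError("endpoint dimensionality mismatch")
    if np.allclose(a, b):
        ee = np.array([energy_fn(a), energy_fn(b)])
        return ImagePath([a, b], ee, converged=True)
    left = [a]
    right = [b]
    frozen_left = frozen_right = False
    nparts = _n_particles(a)

    def _advance(frontier: np.ndarray, target: np.ndarray):
        gap = _cfg_rmsd(frontier, target)
        frac = min(1.0, cfg.advance_rmsd_cap / max(gap, 1e-12))
        new = lst_interpolate(frontier, target, frac)
        tau = target - frontier
        tn = np.linalg.norm(tau)
        if tn > 1e-12:
            tau = tau / tn
            new = _perp_relax(new, tau, energy_fn, gradient_fn,
                              cfg.perp_relax_steps,
                              max_move=0.5 * cfg.advance_rmsd_cap)
        force = np.asarray(gradient_fn(new), dtype=float).ravel()
        rms_force = float(np.sqrt(np.sum(force ** 2) / nparts))
        e = energy_fn(new)
        ok = np.isfinite(e) and np.all(np.isfinite(new))
        return new, rms_force, ok

    while (len(left) < cfg.max_images_per_side + 1
           or len(right) < cfg.max_images_per_side + 1):
        gap = _cfg_rmsd(left[-1], right[-1])
        if gap <= cfg.advance_rmsd_cap:
            break
        advanced = False
        if not frozen_left and len(left) < cfg.max_images_per_side + 1:
            new, rms_f, ok = _advance(left[-1], right[-1])
            if not ok:
                warnings.warn("FSM: energy failure at advancing image; "
                              "returning partial path", RuntimeWarning)
                break
            left.append(new)
            advanced = True
            if rms_f > cfg.freeze_force_threshold:
                frozen_left = True
        gap = _cfg_rmsd(left[-1], right[-1])
        if gap <= cfg.advance_rmsd_cap:
            break
        if not frozen_right and len(right) < cfg.max_images_per_side + 1:
            new, rms_f, ok = _advance(right[-1], left[-1])
            if not ok:
                warnings.warn("FSM: energy failure at advancing image; "
                              "returning partial path", RuntimeWarning)
                break
            right.append(new)
            advanced = True
            if rms_f > cfg.freeze_force_threshold:
                frozen_right = True
        if not advanced:
            break
    nodes = left + right[::-1]
    if _cfg_rmsd(left[-1], right[-1]) > cfg.advance_rmsd_cap:
        warnings.warn("FSM frontiers did not meet within the image budget; "
                      "bridging by resampling", RuntimeWarning)
    images = resample_path(nodes, cfg.n_resampled)
    energies = np.array([energy_fn(x) for x in images])
    return ImagePath(images, energies)


def resample_path(nodes: Sequence[np.ndarray], n_out: int
                  ) -> list[np.ndarray]:
    """Resample a node string to n_out equidistant (RMSD arc length)
    images using LST interpolation between bracketing nodes."""
    if n_out < 2:
        raise ValueError("need at least two output images")
    nodes = [np.asarray(x, dtype=float).ravel() for x in nodes]
    seg = np.array([_cfg_rmsd(nodes[i], nodes[i + 1])
                    for i in range(len(nodes) - 1)])
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total <= 0:
        return [nodes[0].copy() for _ in range(n_out)]
    targets = np.linspace(0.0, total, n_out)
    out = [nodes[0].copy()]
    for s in targets[1:-1]:
        k = int(np.searchsorted(arc, s, side="right") - 1)
        k = min(k, len(seg) - 1)
        frac = (s - arc[k]) / max(seg[k], 1e-12)
        out.append(lst_interpolate(nodes[k], nodes[k + 1], frac))
    out.append(nodes[-1].copy())
    return out


def neb_optimize(path: ImagePath,
                 energy_fn: Callable[[np.ndarray], float],
                 gradient_fn: Callable[[np.ndarray], np.ndarray],
                 cfg: NEBConfig = NEBConfig()) -> ImagePath:
    """Nudged-elastic-band refinement with QuickMin updates.

    Uses the energy-weighted upwind tangent; the NEB force on each interior
    image is the perpendicular true force plus the parallel spring force.
    Convergence requires per-image RMS force <= rms_force_tol and max
    component <= max_force_tol.  Endpoints are never moved.
    """
    if len(path.images) < 3:
        raise ValueError("NEB needs at least three images")
    images = [np.asarray(x, dtype=float).ravel().copy()
              for x in path.images]
    n_img = len(images)
    nparts = _n_particles(images[0])
    vel = [np.zeros_like(images[0]) for _ in range(n_img)]
    energies = np.array([energy_fn(x) for x in images])
    converged = False
    for _ in range(cfg.max_iter):
        neb_forces = [np.zeros_like(images[0]) for _ in range(n_img)]
        worst_rms = 0.0
        worst_max = 0.0
        for i in range(1, n_img - 1):
            d_prev = images[i] - images[i - 1]
            d_next = images[i + 1] - images[i]
            e_prev, e_i, e_next = energies[i - 1], energies[i], energies[i + 1]
            # improved (energy-weighted upwind) tangent
            if e_next > e_i > e_prev:
                tau = d_next.copy()
            elif e_next < e_i < e_prev:
                tau = d_prev.copy()
            else:
                dmax = max(abs(e_next - e_i), abs(e_prev - e_i))
                dmin = min(abs(e_next - e_i), abs(e_prev - e_i))
                if e_next > e_prev:
                    tau = d_next * dmax + d_prev * dmin
                else:
                    tau = d_next * dmin + d_prev * dmax
            tn = np.linalg.norm(tau)
            if tn < 1e-12:
                tau = d_next + d_prev
                tn = np.linalg.norm(tau) or 1.0
            tau /= tn
            force = np.asarray(gradient_fn(images[i]), dtype=float).ravel()
            f_perp = force - np.dot(force, tau) * tau
            f_spring = cfg.spring_constant * (
                np.linalg.norm(d_next) - np.linalg.norm(d_prev))
            f_neb = f_perp + f_spring * tau
            neb_forces[i] = f_neb
            worst_rms = max(worst_rms,
                            float(np.sqrt(np.sum(f_neb ** 2) / nparts)))
            worst_max = max(worst_max, float(np.abs(f_neb).max()))
        if worst_rms <= cfg.rms_force_tol and worst_max <= cfg.max_force_tol:
            converged = True
            break
        for i in range(1, n_img - 1):
            f = neb_forces[i]
            fn = np.linalg.norm(f)
            if fn > 1e-14:
                fhat = f / fn
                proj = np.dot(vel[i], fhat)
                vel[i] = proj * fhat if proj > 0.0 else np.zeros_like(f)
            else:
                vel[i] = np.zeros_like(f)
            vel[i] = vel[i] + cfg.dt * f
            images[i] = images[i] + cfg.dt * vel[i]
            energies[i] = energy_fn(images[i])
    return ImagePath(images, energies, converged=converged)


def floored_energy(path_energies: Sequence[float]) -> float:
    """Sum of uphill energy increments dE+ along a profile (>= 0)."""
    e = np.asarray(path_energies, dtype=float)
    if e.size < 2:
        raise ValueError("need at least two energies")
    if not np.all(np.isfinite(e)):
        raise ValueError("energies must be finite")
    return float(np.clip(np.diff(e), 0.0, None).sum())
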