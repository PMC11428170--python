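"""Rigid-body superposition helpers (Kabsch algorithm)."""

from __future__ import annotations

import numpy as np

__all__ = ["kabsch_superpose", "rmsd"]


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray,
                     subset: np.ndarray | None = None) -> np.ndarray:
    """Least-squares superpose `mobile` onto `target`.

    The optimal rotation/translation is fitted on `subset` (an index array;
    default all points) and applied to the whole mobile set.  Returns the
    transformed copy of `mobile`.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    idx = np.arange(len(mobile)) if subset is None else np.asarray(subset)
    mc = mobile[idx].mean(axis=0)
    tc = target[idx].mean(axis=0)
    h = (mobile[idx] - mc).T @ (target[idx] - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return (mobile - mc) @ rot.T + tc


def rmsd(a: np.ndarray, b: np.ndarray, superpose: bool = True) -> float:
    """Root-mean-square deviation, optionally after optimal superposition."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shapes must match")
    if superpose and a.ndim == 2 and a.shape[1] == 3:
        a = kabsch_superpose(a, b)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))
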