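"""Folding-path analysis: hairpin order parameters, Fréchet distances,
density-based path clustering, transition pruning, and a TM-score utility.

The chi order parameter of a structure against a reference pair set is the
fraction of native pair distances reproduced within a tolerance:

    chi = (1/|pairs|) sum_{(i,j)} H( tol_ij - |r_ij - r_ij^folded| )

with H the (strict) Heaviside step.  Tracking (chi_beta1, chi_beta2) along
a folding path distinguishes which hairpin forms first; paths are compared
as tracks in chi-space with the discrete Fréchet distance and clustered
with HDBSCAN on the precomputed distance matrix.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.cluster import HDBSCAN

from .bln import BeadSequence, BLNParameters, Conformation, MDConfig, \
    make_bln_callables, minimize_geometry, run_md_nvt
from .contacts import hamming_distance, map_from_conformation, \
    sch_distance
from .geometry import kabsch_superpose

__all__ = [
    "chi_order_parameter",
    "native_pair_set",
    "chi_track",
    "discrete_frechet",
    "select_low_energy_paths",
    "cluster_paths",
    "prune_transition_segment",
    "tm_score",
    "metric_validation",
]

DEFAULT_CHI_TOLERANCE = 0.76  # A = 0.2 * sigma(3.8 A)


def _pair_distances(coords: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    d = coords[pairs[:, 0]] - coords[pairs[:, 1]]
    return np.sqrt((d ** 2).sum(-1))


def native_pair_set(folded: Conformation, residue_range: tuple[int, int],
                    r_c: float = 8.0, min_sep: int = 3) -> np.ndarray:
    """Native contact pairs (|i-j| >= min_sep, in contact in the folded
    structure) restricted to a half-open residue range."""
    start, stop = residue_range
    g = map_from_conformation(folded, r_c).matrix
    ii, jj = np.nonzero(np.triu(g, k=min_sep))
    keep = (ii >= start) & (jj < stop)
    pairs = np.stack([ii[keep], jj[keep]], axis=1)
    if len(pairs) == 0:
        raise ValueError(f"no native pairs in range {residue_range}")
    return pairs


def chi_order_parameter(conf: Conformation, folded: Conformation,
                        pair_set: np.ndarray,
                        tolerance: float = DEFAULT_CHI_TOLERANCE,
                        mode: str = "absolute") -> float:
    """Fraction of pair distances within tolerance of their folded values.

    mode "absolute": tol_ij = tolerance (Angstrom);
    mode "relative_native": tol_ij = tolerance * r_ij^folded.
    """
    pairs = np.asarray(pair_set)
    if pairs.size == 0:
        raise ValueError("pair set is empty")
    r = _pair_distances(conf.coords, pairs)
    r0 = _pair_distances(folded.coords, pairs)
    tol = tolerance * r0 if mode == "relative_native" else tolerance
    return float(np.mean(np.abs(r - r0) < tol))


def chi_track(confs: Sequence[Conformation], folded: Conformation,
              pairs_beta1: np.ndarray, pairs_beta2: np.ndarray,
              tolerance: float = DEFAULT_CHI_TOLERANCE,
              mode: str = "absolute") -> np.ndarray:
    """(n_frames, 2) array of (chi_beta1, chi_beta2) along a path."""
    return np.array([
        [chi_order_parameter(c, folded, pairs_beta1, tolerance, mode),
         chi_order_parameter(c, folded, pairs_beta2, tolerance, mode)]
        for c in confs])


def discrete_frechet(track_a: np.ndarray, track_b: np.ndarray) -> float:
    """Discrete Fréchet distance between two ordered point tracks.

    Dynamic program over monotone couplings with the Euclidean point
    metric; respects time order but not step size.
    """
    a = np.atleast_2d(np.asarray(track_a, dtype=float))
    b = np.atleast_2d(np.asarray(track_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("tracks must be nonempty")
    na, nb = len(a), len(b)
    d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))
    ca = np.empty((na, nb))
    ca[0, 0] = d[0, 0]
    for i in range(1, na):
        ca[i, 0] = max(ca[i - 1, 0], d[i, 0])
    for j in range(1, nb):
        ca[0, j] = max(ca[0, j - 1], d[0, j])
    for i in range(1, na):
        for j in range(1, nb):
            ca[i, j] = max(min(ca[i - 1, j], ca[i - 1, j - 1],
                               ca[i, j - 1]), d[i, j])
    return float(ca[-1, -1])


def select_low_energy_paths(paths: Sequence, n: int = 100) -> list:
    """The n paths with smallest floored energy; ties broken by path_id."""
    scored = [p for p in paths if p.floored_energy is not None]
    if n > len(scored):
        warnings.warn(f"requested {n} paths but only {len(scored)} have "
                      "floored energies; returning all", RuntimeWarning)
        n = len(scored)
    order = sorted(scored, key=lambda p: (p.floored_energy, p.path_id))
    return order[:n]


def cluster_paths(distance_matrix: np.ndarray,
                  min_cluster_size: int = 5) -> np.ndarray:
    """HDBSCAN labels from a precomputed symmetric distance matrix.

    Label -1 marks noise.  Fewer paths than min_cluster_size -> all noise.
    """
    m = np.asarray(distance_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("distance matrix must be square")
    n = m.shape[0]
    if n < min_cluster_size:
        return np.full(n, -1, dtype=int)
    model = HDBSCAN(min_cluster_size=min_cluster_size, metric="precomputed",
                    copy=True)
    labels = model.fit_predict(m)
    if (labels == -1).all():
        # the whole set forms one density blob (stock HDBSCAN excludes the
        # hierarchy root); report it as a single cluster instead of noise
        model = HDBSCAN(min_cluster_size=min_cluster_size,
                        metric="precomputed", allow_single_cluster=True,
                        copy=True)
        labels = model.fit_predict(m)
    return labels


def prune_transition_segment(track: np.ndarray, unfolded_below: float = 0.4,
                             folded_above: float = 0.8) -> np.ndarray:
    """Contiguous segment from the last fully unfolded frame (both chi <
    unfolded_below) to the first subsequent fully folded frame (both chi >
    folded_above).  Empty (with a warning) if either regime is missing."""
    t = np.atleast_2d(np.asarray(track, dtype=float))
    unfolded = np.nonzero((t < unfolded_below).all(axis=1))[0]
    if len(unfolded) == 0:
        warnings.warn("track never visits the unfolded regime",
                      RuntimeWarning)
        return t[:0]
    start = unfolded[-1]
    folded = np.nonzero((t[start:] > folded_above).all(axis=1))[0]
    if len(folded) == 0:
        warnings.warn("track never reaches the folded regime after its "
                      "last unfolded frame", RuntimeWarning)
        return t[:0]
    stop = start + folded[0]
    return t[start:stop + 1]


def tm_score(conf_a: Conformation, conf_b: Conformation,
             max_cycles: int = 20) -> float:
    """Template-modeling score for equal-length bead chains (no alignment
    search):  max over superpositions of (1/L) sum 1/(1 + (d_i/d0)^2),
    d0(L) = 1.24 (L-15)^{1/3} - 1.8, via iterative least-squares
    superposition on the d0-selected residue subset."""
    a = conf_a.coords
    b = conf_b.coords
    if a.shape != b.shape:
        raise ValueError("TM-score requires equal-length chains")
    length = a.shape[0]
    d0 = 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8 if length > 15 else 0.0
    if d0 < 0.5:
        warnings.warn("chain too short for the TM-score d0 formula; "
                      "clamping d0 to 0.5 A", RuntimeWarning)
        d0 = 0.5
    subset = np.arange(length)
    best = 0.0
    for _ in range(max_cycles):
        aligned = kabsch_superpose(a, b, subset)
        d = np.sqrt(((aligned - b) ** 2).sum(-1))
        score = float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))
        best = max(best, score)
        new_subset = np.nonzero(d < d0)[0]
        if len(new_subset) < 3:
            new_subset = np.argsort(d)[:3]
        if len(new_subset) == len(subset) and \
                np.array_equal(new_subset, subset):
            break
        subset = new_subset
    return best


def metric_validation(db, seq: BeadSequence,
                      params: BLNParameters | None = None,
                      n_pairs: int = 200, pool_size: int = 50,
                      seed: int = 0,
                      temperature_range: tuple[float, float] = (0.3, 3.0),
                      duration_range: tuple[float, float] = (2.0, 8.0),
                      ) -> tuple[pd.DataFrame, dict]:
    """Rank-correlation comparison of SCH and Hamming against TM-score.

    Builds a structurally diverse pool -- the supplied local minima plus
    MD-perturbed-and-minimized variants of random pool seeds at
    temperatures spanning temperature_range -- then scores random
    structure pairs from the pool with TM-score, SCH and Hamming.
    Comparing pairs *across* basins (not only against one reference) is
    essential: on a single melt continuum both contact-map metrics track
    the TM-score, whereas between genuinely different folds the Hamming
    count saturates and only the hop-based SCH metric remains informative.

    Returns (per-pair table, {"spearman_sch_vs_tm", "spearman_hamming_vs_tm"}).
    """
    params = params or BLNParameters()
    if isinstance(db, Conformation):
        db = [(db, 0.0)]
    rng = np.random.default_rng(seed)
    energy_fn, force_fn = make_bln_callables(seq, params)
    pool = [conf for conf, _ in db[:max(1, pool_size // 4)]]
    attempts = 0
    while len(pool) < pool_size and attempts < 4 * pool_size:
        attempts += 1
        base = db[int(rng.integers(len(db)))][0]
        md = MDConfig(temperature=float(rng.uniform(*temperature_range)),
                      duration=float(rng.uniform(*duration_range)),
                      seed=int(rng.integers(0, 2 ** 31 - 1)),
                      sample_every=10 ** 9)
        try:
            hot = run_md_nvt(base, seq, params, md)[-1]
        except RuntimeError:
            continue
        pert, _, _ = minimize_geometry(hot, energy_fn, force_fn, tol=1e-4)
        pool.append(pert)
    maps = [map_from_conformation(c) for c in pool]
    rows = []
    seen: set = set()
    attempts = 0
    while len(rows) < n_pairs and attempts < 20 * n_pairs:
        attempts += 1
        i, j = (int(v) for v in rng.integers(len(pool), size=2))
        key = (min(i, j), max(i, j))
        if i == j or key in seen:
            continue
        seen.add(key)
        rows.append({
            "tm_score": tm_score(pool[i], pool[j]),
            "sch": sch_distance(maps[i], maps[j]),
            "hamming": hamming_distance(maps[i], maps[j]),
        })
    table = pd.DataFrame(rows)
    rho_sch = spearmanr(table["sch"], table["tm_score"]).statistic
    rho_ham = spearmanr(table["hamming"], table["tm_score"]).statistic
    return table, {"spearman_sch_vs_tm": float(rho_sch),
                   "spearman_hamming_vs_tm": float(rho_ham)}
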