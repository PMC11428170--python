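"""Graph-driven sampling: folding paths as optimized contact-map sequences.

A candidate folding path is a graph sequence [G^0, ..., G^{M+1}] whose
endpoints are pinned to the unfolded and folded contact maps.  Simulated
annealing perturbs one intermediate at a time with 1-5 random bit flips
and scores the sequence with

    F = sum_{i=1..M} | d(G^{i-1}, G^i) - d(G^i, G^{i+1}) |
      + lambda * sum_{j=1..M+1} H( d(G^{j-1}, G^j) - k_cont )

where d is the SCH metric, H the Heaviside step (H(0) = 0) and
k_cont = 0.15, the SCH scale of a single topology-preserving
conformational step.  The first term drives intermediates toward
equidistance; the second penalizes any transition larger than k_cont.

Bit-flipped maps need not be geometrically realizable, so each proposal
may be "corrected": the flipped map is back-mapped to a conformation
under the graph restraining potential and replaced by the contact map
that the reconstructed structure actually achieves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .bln import BeadSequence, BLNParameters, Conformation
from .contacts import (ContactMap, apply_bit_flips, map_from_conformation,
                       mutable_pairs, sch_distance)
from .reconstruct import (DEFAULT_RECONSTRUCTION_GRP, GRPNewConfig,
                          ReconstructionResult, reconstruct_minimize)

__all__ = [
    "GraphSequence",
    "AnnealSchedule",
    "MoveProposal",
    "ObjectiveConfig",
    "FoldingPath",
    "sequence_objective",
    "propose_move",
    "correct_and_score",
    "sa_optimize_sequence",
    "initialize_sequence",
    "reconstruct_sequence",
    "generate_ensemble",
    "default_n_intermediates",
]


@dataclass
class GraphSequence:
    """Ordered contact maps [G^0 ... G^{M+1}] with pinned endpoints."""

    maps: list[ContactMap]
    conformations: list[Conformation] | None = None
    endpoints_fixed: bool = True

    def __post_init__(self) -> None:
        if len(self.maps) < 2:
            raise ValueError("a graph sequence needs at least two maps")
        n = self.maps[0].n_beads
        if any(g.n_beads != n for g in self.maps):
            raise ValueError("all maps must share the same bead count")
        if self.conformations is not None and \
                len(self.conformations) != len(self.maps):
            raise ValueError("conformations must parallel maps")

    @property
    def n_intermediates(self) -> int:
        return len(self.maps) - 2

    @property
    def n_beads(self) -> int:
        return self.maps[0].n_beads

    def copy(self) -> "GraphSequence":
        confs = None if self.conformations is None else \
            [c.copy() for c in self.conformations]
        return GraphSequence([g.copy() for g in self.maps], confs,
                             self.endpoints_fixed)


@dataclass(frozen=True)
class AnnealSchedule:
    """Linearly decreasing SA temperature protocol."""

    n_updates: int = 10_000
    t_start: float = 1e-3  # objective units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_updates < 1 or self.t_start <= 0:
            raise ValueError("need n_updates >= 1 and t_start > 0")

    def temperature(self, step: int) -> float:
        return self.t_start * (1.0 - step / self.n_updates)


@dataclass(frozen=True)
class MoveProposal:
    t: int  # intermediate index, 1..M
    flips: tuple  # ((k, m), ...) with 1 <= len <= 5


@dataclass(frozen=True)
class ObjectiveConfig:
    k_cont: float = 0.15
    lambda_penalty: float = 1.0
    penalty_form: str = "step"  # "step" or "hinge"


@dataclass
class FoldingPath:
    """One reconstructed, refinable folding path and its bookkeeping."""

    sequence: GraphSequence
    seed: int
    objective: float
    trace: np.ndarray = field(repr=False)
    conformations: list[Conformation] | None = None
    energy_profile: np.ndarray | None = None
    floored_energy: float | None = None
    path_id: int = 0


def _consecutive_distances(maps: Sequence[ContactMap]) -> np.ndarray:
    return np.array([sch_distance(maps[i], maps[i + 1])
                     for i in range(len(maps) - 1)])


def sequence_objective(seq: GraphSequence,
                       cfg: ObjectiveConfig = ObjectiveConfig()) -> float:
    """SA objective F >= 0: equidistance residual + threshold penalty."""
    if seq.n_intermediates < 1:
        raise ValueError("sequence needs at least one intermediate")
    d = _consecutive_distances(seq.maps)
    f = float(np.abs(np.diff(d)).sum())
    excess = d - cfg.k_cont
    if cfg.penalty_form == "step":
        f += cfg.lambda_penalty * float((excess > 0).sum())
    elif cfg.penalty_form == "hinge":
        f += cfg.lambda_penalty * float(np.clip(excess, 0.0, None).sum())
    else:
        raise ValueError(f"unknown penalty form {cfg.penalty_form!r}")
    return f


def propose_move(seq: GraphSequence, rng: np.random.Generator,
                 max_flips: int = 5, min_sep: int = 3) -> MoveProposal:
    """Uniform intermediate, 1..max_flips bit flips without replacement."""
    m = seq.n_intermediates
    if m < 1:
        raise ValueError("no intermediates to perturb")
    t = int(rng.integers(1, m + 1))
    n_b = int(rng.integers(1, max_flips + 1))
    pairs = mutable_pairs(seq.n_beads, min_sep)
    chosen = rng.choice(len(pairs), size=min(n_b, len(pairs)), replace=False)
    flips = tuple(tuple(int(v) for v in pairs[c]) for c in chosen)
    return MoveProposal(t=t, flips=flips)


def correct_and_score(
        seq: GraphSequence, move: MoveProposal,
        reconstructor: Callable[[Conformation, ContactMap],
                                ReconstructionResult],
        cfg: ObjectiveConfig = ObjectiveConfig(),
) -> tuple[ContactMap, Conformation | None, float]:
    """Apply a move, snap the flipped map to a physical one, score it.

    The flipped map is back-mapped starting from the stored conformation of
    the perturbed intermediate; the contact map of the reconstructed
    structure -- not the raw flipped map -- is what the sequence is scored
    with (and what enters it on acceptance).  A failed reconstruction
    scores +inf.
    """
    if seq.conformations is None:
        raise ValueError("correction requires stored conformations")
    flipped = apply_bit_flips(seq.maps[move.t], move.flips)
    res = reconstructor(seq.conformations[move.t], flipped)
    if res.failed:
        return flipped, None, math.inf
    corrected = res.achieved_map
    trial_maps = list(seq.maps)
    trial_maps[move.t] = corrected
    trial = GraphSequence(trial_maps, endpoints_fixed=seq.endpoints_fixed)
    return corrected, res.conformation, sequence_objective(trial, cfg)


def sa_optimize_sequence(
        seq0: GraphSequence,
        schedule: AnnealSchedule = AnnealSchedule(),
        cfg: ObjectiveConfig = ObjectiveConfig(),
        reconstructor: Callable[[Conformation, ContactMap],
                                ReconstructionResult] | None = None,
        correction: str = "per-update",
) -> tuple[GraphSequence, np.ndarray]:
    """Metropolis simulated annealing over graph sequences.

    correction:
      "per-update" -- every proposal is reconstructed and its corrected map
                      scored (the literal protocol; needs a reconstructor),
      "on-accept"  -- raw flipped maps are scored; corrections are applied
                      only to accepted moves,
      "none"       -- pure graph-space annealing.
    Returns the best-seen sequence and the objective trace (current F per
    update).  Deterministic given schedule.seed.
    """
    if correction not in ("per-update", "on-accept", "none"):
        raise ValueError(f"unknown correction mode {correction!r}")
    if correction != "none" and reconstructor is None:
        raise ValueError(f"correction={correction!r} needs a reconstructor")
    rng = np.random.default_rng(schedule.seed)
    current = seq0.copy()
    f_cur = sequence_objective(current, cfg)
    best = current.copy()
    f_best = f_cur
    trace = np.empty(schedule.n_updates)
    for step in range(schedule.n_updates):
        move = propose_move(current, rng)
        new_conf: Conformation | None = None
        if correction == "per-update":
            new_map, new_conf, f_try = correct_and_score(
                current, move, reconstructor, cfg)
            if new_conf is None:
                trace[step] = f_cur
                continue
        else:
            new_map = apply_bit_flips(current.maps[move.t], move.flips)
            trial_maps = list(current.maps)
            trial_maps[move.t] = new_map
            f_try = sequence_objective(
                GraphSequence(trial_maps,
                              endpoints_fixed=current.endpoints_fixed), cfg)
        temp = schedule.temperature(step)
        df = f_try - f_cur
        accept = df <= 0.0 or (
            temp > 0.0 and rng.random() < math.exp(-df / temp))
        if accept and correction == "on-accept":
            corrected, conf, f_corr = correct_and_score(
                current, move, reconstructor, cfg)
            if conf is None:
                accept = False
            else:
                new_map, new_conf, f_try = corrected, conf, f_corr
        if accept:
            current.maps[move.t] = new_map
            if new_conf is not None and current.conformations is not None:
                current.conformations[move.t] = new_conf
            f_cur = f_try
            if f_cur < f_best:
                best = current.copy()
                f_best = f_cur
        trace[step] = f_cur
    return best, trace


def default_n_intermediates(unfolded: ContactMap, folded: ContactMap,
                            k_cont: float = 0.15) -> int:
    """M = ceil(d(G^I, G^F) / k_cont) - 1: enough transitions that each
    consecutive SCH step can stay below k_cont."""
    d = sch_distance(unfolded, folded)
    return max(1, math.ceil(d / k_cont) - 1)


def initialize_sequence(unfolded: ContactMap, folded: ContactMap, m: int,
                        rng: np.random.Generator,
                        min_sep: int = 3) -> GraphSequence:
    """Random linear label interpolation between the endpoint maps.

    Intermediate i starts as the unfolded map with a random subset of the
    mutable symmetric-difference pairs toggled, of size
    ceil(i * K / (M + 1)).
    """
    diff = np.triu(unfolded.matrix != folded.matrix, k=min_sep)
    pairs = np.argwhere(diff)
    order = rng.permutation(len(pairs))
    maps = [unfolded.copy()]
    for i in range(1, m + 1):
        k = math.ceil(i * len(pairs) / (m + 1))
        g = unfolded.matrix.copy()
        for idx in order[:k]:
            a, b = pairs[idx]
            g[a, b] ^= 1
            g[b, a] = g[a, b]
        maps.append(ContactMap(g))
    maps.append(folded.copy())
    return GraphSequence(maps)


def reconstruct_sequence(gseq: GraphSequence, start: Conformation,
                         reconstructor: Callable[[Conformation, ContactMap],
                                                 ReconstructionResult],
                         ) -> list[ReconstructionResult]:
    """Back-map every map in order, chaining each result as the next start.

    The first and last entries are reconstructed too (from `start` and the
    last intermediate respectively) so the output list parallels the maps.
    """
    results = []
    current = start
    for g in gseq.maps:
        res = reconstructor(current, g)
        results.append(res)
        if not res.failed:
            current = res.conformation
    return results


def make_reconstructor(seq: BeadSequence,
                       params: BLNParameters | None = None,
                       grp: GRPNewConfig | None = None,
                       tol: float = 1e-4,
                       max_iter: int = 5000):
    """GRP-minimization reconstructor closure for use inside SA loops."""
    params = params or BLNParameters()
    grp = grp if grp is not None else DEFAULT_RECONSTRUCTION_GRP

    def _rec(conf0: Conformation, g: ContactMap) -> ReconstructionResult:
        return reconstruct_minimize(conf0, g, seq, params, grp=grp,
                                    tol=tol, max_iter=max_iter)

    return _rec


def generate_ensemble(unfolded: Conformation, folded: Conformation,
                      seq: BeadSequence,
                      params: BLNParameters | None = None,
                      n_paths: int = 100, m: int | None = None,
                      schedule: AnnealSchedule = AnnealSchedule(),
                      cfg: ObjectiveConfig = ObjectiveConfig(),
                      correction: str = "none",
                      reconstruct_final: bool = True,
                      r_c: float = 8.0,
                      grp: GRPNewConfig | None = None,
                      ) -> list[FoldingPath]:
    """Independent seeded SA runs between the two endpoint structures.

    Each path gets its own seed derived from schedule.seed; failures of
    individual runs are recorded and skipped, never aborting the ensemble.
    With reconstruct_final=True (or correction != "none") every returned
    path carries reconstructed intermediate conformations.
    """
    params = params or BLNParameters()
    g_unfolded = map_from_conformation(unfolded, r_c)
    g_folded = map_from_conformation(folded, r_c)
    if m is None:
        m = default_n_intermediates(g_unfolded, g_folded, cfg.k_cont)
    master = np.random.default_rng(schedule.seed)
    reconstructor = make_reconstructor(seq, params, grp)
    paths: list[FoldingPath] = []
    for pid in range(n_paths):
        run_seed = int(master.integers(0, 2 ** 31 - 1))
        rng = np.random.default_rng(run_seed)
        try:
            seq0 = initialize_sequence(g_unfolded, g_folded, m, rng)
            if correction != "none":
                recs = reconstruct_sequence(seq0, unfolded, reconstructor)
                seq0.conformations = [r.conformation for r in recs]
                seq0.maps = ([seq0.maps[0]]
                             + [r.achieved_map for r in recs[1:-1]]
                             + [seq0.maps[-1]])
                seq0.conformations[0] = unfolded.copy()
                seq0.conformations[-1] = folded.copy()
            sched = replace(schedule, seed=run_seed)
            best, trace = sa_optimize_sequence(
                seq0, sched, cfg, reconstructor, correction)
            path = FoldingPath(sequence=best, seed=run_seed,
                               objective=sequence_objective(best, cfg),
                               trace=trace, path_id=pid)
            if correction != "none" and best.conformations is not None:
                path.conformations = best.conformations
            elif reconstruct_final:
                # endpoints keep their given structures; only the
                # intermediates need back-mapping, chained from unfolded
                confs = [unfolded.copy()]
                current = unfolded
                for gmap in best.maps[1:-1]:
                    res = reconstructor(current, gmap)
                    confs.append(res.conformation)
                    if not res.failed:
                        current = res.conformation
                confs.append(folded.copy())
                path.conformations = confs
            paths.append(path)
        except (ValueError, RuntimeError):  # pragma: no cover - per-run guard
            continue
    return paths
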