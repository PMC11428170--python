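"""End-to-end orchestration: native search -> GDS ensemble ->
reconstruction -> FSM/NEB refinement -> floored-energy ranking ->
Fréchet clustering -> chi-space summaries.

Every stage writes plain-text artifacts into a run directory together
with a config snapshot and the seeds actually used, so a finished run can
be reproduced bitwise from its own metadata.  Stages are resumable: a
stage whose marker file exists is skipped.  Per-path failures are data
(recorded in the failure ledger), never aborts.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .analysis import chi_track, cluster_paths, discrete_frechet, \
    native_pair_set, select_low_energy_paths
from .bln import BeadSequence, BLNParameters, Conformation, \
    make_bln_callables
from .contacts import write_edge_list
from .fixtures import ToyProteinSpec, build_minima_database, \
    extended_chain, make_toy_protein
from .gds import AnnealSchedule, ObjectiveConfig, FoldingPath, \
    generate_ensemble
from .refine import FSMConfig, NEBConfig, floored_energy, fsm_grow, \
    neb_optimize

__all__ = ["RunConfig", "run_full_pipeline"]


@dataclass
class RunConfig:
    """Master configuration; every stochastic stage derives its seed
    deterministically from `seed`."""

    out_dir: str = "gds_run"
    seed: int = 0
    sequence_file: str | None = None  # external bead protein, else the toy
    protein_length: int = 56
    # native search
    db_restarts: int = 60
    db_stop_after: int = 20
    # GDS ensemble
    n_paths: int = 50
    n_intermediates: int = 3
    n_updates: int = 2000
    t_start: float = 1e-3
    k_cont: float = 0.15
    correction: str = "none"  # "per-update" | "on-accept" | "none"
    # refinement
    refine: bool = True
    fsm_images: int = 6
    neb_max_iter: int = 300
    # analysis
    n_select: int = 25
    min_cluster_size: int = 5
    chi_tolerance: float = 0.76

    def stage_seed(self, stage: str) -> int:
        tag = zlib.crc32(stage.encode())  # stable across processes
        return int(np.random.default_rng(
            [self.seed, tag]).integers(0, 2 ** 31 - 1))


def _marker(run_dir: Path, stage: str) -> Path:
    return run_dir / f".{stage}.done"


def _load_protein(cfg: RunConfig):
    if cfg.sequence_file:
        seq = gio.read_sequence(cfg.sequence_file)
        n = seq.n_beads
        # without declared hairpins, track native-contact formation in the
        # two chain halves
        ranges = {"beta1": (0, n // 2), "beta2": (n // 2, n)}
    else:
        seq, ranges = make_toy_protein(ToyProteinSpec())
    return seq, ranges


def _stage_native(cfg: RunConfig, run_dir: Path, seq: BeadSequence,
                  params: BLNParameters):
    db = build_minima_database(seq, params, n_restarts=cfg.db_restarts,
                               stop_after=cfg.db_stop_after,
                               seed=cfg.stage_seed("native"))
    native, e_native = db[0]
    gio.write_xyz(native, run_dir / "native.xyz", labels=seq.labels,
                  comments=[f"E = {e_native:.6f} eps"])
    pd.DataFrame({"energy": [e for _, e in db]}).to_csv(
        run_dir / "minima_energies.csv", index=False)
    _marker(run_dir, "native").write_text(f"{e_native:.12f}\n")
    return native


def _stage_ensemble(cfg: RunConfig, run_dir: Path, seq: BeadSequence,
                    params: BLNParameters, native: Conformation):
    unfolded = extended_chain(seq.n_beads)
    schedule = AnnealSchedule(n_updates=cfg.n_updates, t_start=cfg.t_start,
                              seed=cfg.stage_seed("ensemble"))
    obj = ObjectiveConfig(k_cont=cfg.k_cont)
    paths = generate_ensemble(
        unfolded, native, seq, params, n_paths=cfg.n_paths,
        m=cfg.n_intermediates or None, schedule=schedule, cfg=obj,
        correction=cfg.correction)
    for path in paths:
        pdir = run_dir / "paths" / f"path_{path.path_id:04d}"
        pdir.mkdir(parents=True, exist_ok=True)
        for k, g in enumerate(path.sequence.maps):
            write_edge_list(g, pdir / f"map_{k}.tsv")
        if path.conformations:
            gio.write_xyz(path.conformations, pdir / "intermediates.xyz",
                          labels=seq.labels)
        meta = {"seed": path.seed, "objective": path.objective,
                "trace_final": float(path.trace[-1]) if len(path.trace)
                else None}
        (pdir / "metadata.json").write_text(json.dumps(meta, indent=1))
    _marker(run_dir, "ensemble").write_text(f"{len(paths)}\n")
    return paths


def _stage_refine(cfg: RunConfig, run_dir: Path, seq: BeadSequence,
                  params: BLNParameters, paths: list[FoldingPath]):
    energy_fn, force_fn = make_bln_callables(seq, params)

    def e_flat(x):
        return energy_fn(x.reshape(-1, 3))

    def f_flat(x):
        return force_fn(x.reshape(-1, 3)).ravel()

    fsm_cfg = FSMConfig(n_resampled=cfg.fsm_images)
    neb_cfg = NEBConfig(max_iter=cfg.neb_max_iter)
    failures = []
    for path in paths:
        if not path.conformations:
            failures.append((path.path_id, "no conformations"))
            continue
        profile: list[float] = []
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for a, b in zip(path.conformations[:-1],
                                path.conformations[1:]):
                    seg = fsm_grow(a.coords.ravel(), b.coords.ravel(),
                                   e_flat, f_flat, fsm_cfg)
                    seg = neb_optimize(seg, e_flat, f_flat, neb_cfg)
                    profile.extend(seg.energies[:-1])
                profile.append(
                    e_flat(path.conformations[-1].coords.ravel()))
        except (ValueError, RuntimeError) as exc:
            failures.append((path.path_id, str(exc)))
            continue
        path.energy_profile = np.asarray(profile)
        path.floored_energy = floored_energy(path.energy_profile)
        pdir = run_dir / "paths" / f"path_{path.path_id:04d}"
        if pdir.is_dir():
            np.savetxt(pdir / "energy_profile.txt", path.energy_profile,
                       header="NEB image energies (eps)")
    if failures:
        (run_dir / "failure_ledger.txt").write_text(
            "\n".join(f"path {pid}: {msg}" for pid, msg in failures) + "\n")
    _marker(run_dir, "refine").write_text(f"{len(failures)} failures\n")


def _stage_analyze(cfg: RunConfig, run_dir: Path, seq: BeadSequence,
                   native: Conformation, ranges: dict,
                   paths: list[FoldingPath]):
    pairs1 = native_pair_set(native, ranges["beta1"])
    pairs2 = native_pair_set(native, ranges["beta2"])
    if any(p.floored_energy is not None for p in paths):
        selected = select_low_energy_paths(paths, n=cfg.n_select)
    else:
        selected = [p for p in paths if p.conformations][:cfg.n_select]
    tracks = [chi_track(p.conformations, native, pairs1, pairs2,
                        tolerance=cfg.chi_tolerance)
              for p in selected]
    n = len(tracks)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = discrete_frechet(tracks[i], tracks[j])
    labels = cluster_paths(dmat, min_cluster_size=cfg.min_cluster_size)
    np.savetxt(run_dir / "frechet_matrix.txt", dmat)
    pd.DataFrame({
        "path_id": [p.path_id for p in selected],
        "floored_energy": [p.floored_energy for p in selected],
        "cluster": labels,
    }).to_csv(run_dir / "clusters.csv", index=False)
    # chi-space occupancy per cluster (gridded tabular output for plotting)
    edges = np.linspace(0.0, 1.0, 21)
    for lab in sorted(set(labels)):
        pts = np.vstack([t for t, l in zip(tracks, labels) if l == lab])
        hist, _, _ = np.histogram2d(pts[:, 0], pts[:, 1],
                                    bins=[edges, edges])
        np.savetxt(run_dir / f"chi_occupancy_cluster{lab}.txt", hist,
                   header="20x20 occupancy over (chi_beta1, chi_beta2) "
                          "in [0,1]^2")
    _marker(run_dir, "analyze").write_text(
        f"{len(set(labels) - {-1})} clusters\n")
    return labels


def run_full_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages; returns the run directory."""
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.json").write_text(json.dumps(asdict(cfg), indent=1))
    seq, ranges = _load_protein(cfg)
    params = BLNParameters()
    gio.write_sequence(seq, run_dir / "sequence.txt")
    native = _stage_native(cfg, run_dir, seq, params)
    if cfg.n_paths > 0:
        paths = _stage_ensemble(cfg, run_dir, seq, params, native)
        if cfg.refine:
            _stage_refine(cfg, run_dir, seq, params, paths)
        usable = [p for p in paths if p.conformations]
        if usable:
            _stage_analyze(cfg, run_dir, seq, native, ranges, usable)
    return run_dir
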