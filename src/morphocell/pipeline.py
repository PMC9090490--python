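"""End-to-end orchestration: ingest/synthesize → descriptors → uncertainty →
kinematics → time-series stats → behavioral map, with a reproducibility
manifest.

Same config and seed reproduce the descriptor tables bit-identically and the
embeddings identically; any stage failure halts with a stage-attributed
error while earlier outputs are preserved on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import behavior, kinematics, shape_space, spharm, tsstats, uropod
from .config import RunConfig
from .mesh_io import CellSequence

log = logging.getLogger(__name__)

STAGES = ("ingest", "descriptors", "uncertainty", "kinematics", "stats", "behavior")


class StageError(RuntimeError):
    def __init__(self, stage: str, dataset: str, detail: Exception):
        super().__init__(f"stage '{stage}' failed on dataset '{dataset}': {detail}")
        self.stage = stage
        self.dataset = dataset


def run_pipeline(
    sequences: list[CellSequence],
    config: Optional[RunConfig] = None,
    out_dir=None,
) -> dict:
    """Run the full analysis over a list of cell sequences.

    Returns a results dict with the descriptor table, the fitted shape
    space, per-dataset uropod tracks and kinematics, the channel statistics
    table, the pooled behavioral map and the manifest.  When ``out_dir`` is
    given, tables are written as CSV/JSON as each stage completes.
    """
    cfg = config or RunConfig()
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "stages": {},
        "datasets": [s.dataset_id for s in sequences],
    }
    results: dict = {"manifest": manifest, "config": cfg}

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                fn()
            except Exception as e:
                manifest["stages"][name] = {"status": "failed", "error": str(e)}
                _dump_manifest(out, manifest)
                if isinstance(e, StageError):
                    raise
                raise StageError(name, "pooled", e) from e
            manifest["stages"][name] = {"status": "complete", "seconds": round(time.time() - t0, 2)}
            log.info("stage %s complete (%.1fs)", name, time.time() - t0)
            _dump_manifest(out, manifest)
        return deco

    @stage("ingest")
    def _ingest():
        for s in sequences:
            bad = [i for i, f in enumerate(s.frames) if not f.valid]
            if bad:
                raise StageError("ingest", s.dataset_id, ValueError(f"invalid mesh at frame(s) {bad}"))

    @stage("descriptors")
    def _desc():
        tables = []
        for s in sequences:
            try:
                tables.append(spharm.descriptor_series(s, cfg))
            except Exception as e:
                raise StageError("descriptors", s.dataset_id, e) from e
        table = pd.concat(tables, ignore_index=True)
        results["descriptors"] = table
        results["shape_space"] = shape_space.fit_pca(table)
        if out:
            table.to_csv(out / "descriptors.csv", index=False)

    @stage("uncertainty")
    def _unc():
        tracks = {}
        rows = []
        for s in sequences:
            try:
                tr = uropod.track_sequence(s, results["shape_space"], cfg)
            except Exception as e:
                raise StageError("uncertainty", s.dataset_id, e) from e
            tracks[s.dataset_id] = tr
            rows.append(
                {
                    "dataset_id": s.dataset_id,
                    "chord_um": tr.chord,
                    "tau_sig_s": tr.tau_sig,
                    "sigma_d0": tr.sigma_d0,
                    **{f"sigma_pc{k+1}": tr.sigma_pc[k] for k in range(len(tr.sigma_pc))},
                    "flags": "; ".join(tr.flags),
                }
            )
        results["uropod_tracks"] = tracks
        results["uncertainty_table"] = pd.DataFrame(rows)
        if out:
            results["uncertainty_table"].to_csv(out / "uncertainty.csv", index=False)

    @stage("kinematics")
    def _kin():
        kin = {}
        frames = []
        for s in sequences:
            tr = results["uropod_tracks"][s.dataset_id]
            try:
                k = kinematics.track_kinematics(s, tr.tau_sig, uropod=tr.positions, config=cfg)
            except Exception as e:
                raise StageError("kinematics", s.dataset_id, e) from e
            kin[s.dataset_id] = k
            frames.append(k.to_frame(s.dataset_id))
        results["kinematics"] = kin
        results["kinematics_table"] = pd.concat(frames, ignore_index=True)
        if out:
            results["kinematics_table"].to_csv(out / "kinematics.csv", index=False)

    @stage("stats")
    def _stats():
        table = results["descriptors"]
        space = results["shape_space"]
        rows = []
        for s in sequences:
            tr = results["uropod_tracks"][s.dataset_id]
            sub = table[table.dataset_id == s.dataset_id]
            scores = space.project(sub[spharm.descriptor_columns(cfg.l_max)].to_numpy())
            chans = {f"PC{k+1}": scores[:, k] for k in range(space.n_components)}
            low = shape_space.snr_flags(space, tr.sigma_pc, cfg.snr_min) if np.all(np.isfinite(tr.sigma_pc)) else np.zeros(space.n_components, bool)
            chans = {k: v for j, (k, v) in enumerate(chans.items()) if not low[j]}
            if not tr.near_stationary:
                chans["speed"] = np.nan_to_num(results["kinematics"][s.dataset_id].speed_uc)
            try:
                for r in tsstats.channel_report(chans, s.dt, cfg):
                    rows.append({"dataset_id": s.dataset_id, **r})
            except Exception as e:
                raise StageError("stats", s.dataset_id, e) from e
        results["stats_table"] = pd.DataFrame(rows)
        if out:
            results["stats_table"].to_csv(out / "stats.csv", index=False)

    @stage("behavior")
    def _behave():
        table = results["descriptors"]
        space = results["shape_space"]
        bank = None
        specs = []
        lengths = []
        for s in sequences:
            sub = table[table.dataset_id == s.dataset_id]
            scores = space.project(sub[spharm.descriptor_columns(cfg.l_max)].to_numpy())
            chans = {f"PC{k+1}": tsstats.detrend(scores[:, k], s.dt, cfg) for k in range(space.n_components)}
            if bank is None:
                bank = behavior.make_bank(s.dt, config=cfg)
            spec, meta = behavior.build_spectrogram(chans, bank)
            specs.append(spec)
            lengths.append(spec.shape[1])
        pooled = np.hstack(specs)
        pts = behavior.embed(pooled, seed=cfg.seed, config=cfg)
        bias = cfg.binarize_bias
        while True:
            try:
                mm = behavior.density_and_motifs(
                    pts,
                    square_dim=cfg.binarize_square,
                    bias=bias,
                    grid_size=cfg.kde_grid,
                    bandwidth=cfg.kde_bandwidth,
                )
                break
            except ValueError:
                bias /= 2.0
                if bias < 0.5:
                    raise
                log.warning("no motif regions at bias %.1f; retrying with %.1f", bias * 2, bias)
        bounds = np.cumsum([0] + lengths)
        label_seqs = [mm.assignments[bounds[i] : bounds[i + 1]] for i in range(len(lengths))]
        P, counts, zero_rows = behavior.transition_matrix(label_seqs)
        mm.transition, mm.transition_counts = P, counts
        point_seqs = [pts[bounds[i] : bounds[i + 1]] for i in range(len(lengths))]
        mm.entropy = behavior.grid_entropy(point_seqs, grid=cfg.entropy_grid)
        results["map"] = mm
        results["bank"] = bank
        if out:
            np.savez(
                out / "map.npz",
                points=pts,
                pdf=mm.pdf,
                region_labels=mm.region_labels,
                assignments=mm.assignments,
                transition=P,
                entropy=mm.entropy,
            )
            pd.DataFrame(mm.regions).to_csv(out / "motifs.csv", index=False)

    return results


def _dump_manifest(out, manifest) -> None:
    if out:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def table_checksum(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:16]
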