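"""End-to-end pipeline driver: (synth|read) → preprocess → segment → track →
morphometry, writing labels, a TrackMate XML forest, CSV tables and a JSON
log into an output directory.

Each stage writes a ``<stage>.done`` marker containing the config hash;
rerunning with an unchanged config resumes after completed stages.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as btio
from . import morphometry as morph
from . import preprocess as pre
from . import segment as seg
from . import synth
from . import track as trk
from .config import PipelineConfig
from .core import DataFormatError
from .trackmate import export_trackmate, read_trackmate

_FLOAT_FMT = "%.6f"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _marker(out: Path, stage: str) -> Path:
    return out / f"{stage}.done"


def _fresh(out: Path, stage: str, cfg_hash: str) -> bool:
    m = _marker(out, stage)
    return m.exists() and m.read_text().strip() == cfg_hash


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run the full chain; deterministic given config + seed.

    Returns the output directory.  On stage failure raises
    :class:`StageError` with the stage name; outputs of the failed stage are
    removed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    seeds = config.module_seeds()
    log: dict = {"config_hash": cfg_hash, "seed": config.seed, "stages": {}}

    def stage(name):
        def deco(fn):
            def run():
                t0 = time.perf_counter()
                if _fresh(out, name, cfg_hash):
                    log["stages"][name] = {"skipped": True}
                    return
                try:
                    info = fn() or {}
                except Exception as exc:
                    log["stages"][name] = {"error": str(exc)}
                    (out / "log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
                    raise StageError(name, exc) from exc
                info["seconds"] = round(time.perf_counter() - t0, 3)
                log["stages"][name] = info
                _marker(out, name).write_text(cfg_hash)
            return run
        return deco

    movie_h5 = out / "movie.h5"
    labels_h5 = out / "labels.h5"
    forest_xml = out / "forest.xml"

    @stage("acquire")
    def acquire():
        if config.input_path is None:
            sc = config.synth
            truth = synth.make_preset(
                sc.preset, seed=seeds["synth"], n_outer=sc.n_outer,
                n_inner=sc.n_inner, n_frames=sc.n_frames,
                division_schedule=list(sc.division_schedule), kappa=sc.kappa,
                oscillation=tuple(sc.oscillation), radius=sc.radius,
                drift=sc.drift, n_micronuclei=sc.n_micronuclei)
            frames, truth_labels = synth.render(
                truth, spacing=sc.spacing, blur_sigma=sc.blur_sigma,
                noise=tuple(sc.noise), seed=seeds["synth"])
            btio.write_movie_hdf5(movie_h5, frames=frames)
            synth.write_truth_csv(truth, out / "truth.csv")
            btio.write_movie_hdf5(out / "truth_labels.h5", labels=truth_labels)
            return {"frames": len(frames), "nuclei": len(truth.nuclei)}
        frames = btio.read_movie(config.input_path, config.input_layout,
                                 spacing=config.input_spacing)
        btio.write_movie_hdf5(movie_h5, frames=frames)
        return {"frames": len(frames)}

    @stage("segment")
    def segment():
        frames, _ = btio.read_movie_hdf5(movie_h5)
        pc, sc = config.preprocess, config.segment
        labels = []
        for f in frames:
            # segmentation runs on the *linear* normalized frame: the
            # classical detector places boundaries at the half-max level,
            # which is exact for blur-limited bodies before gamma stretching
            g = pre.preprocess_frame(f, target_spacing=pc.target_spacing,
                                     p_low=pc.p_low, p_high=pc.p_high,
                                     gamma=1.0, axial_factor=pc.axial_factor)
            lv = seg.detect_nuclei_classical(
                g, smooth_sigma=sc.smooth_sigma, threshold=sc.threshold,
                min_seed_distance=sc.min_seed_distance)
            lv = seg.filter_small(lv, sc.min_volume)
            lv.frame_index = f.time_index
            labels.append(lv)
        btio.write_movie_hdf5(labels_h5, labels=labels)
        return {"instances": int(sum(len(lv.ids()) for lv in labels))}

    @stage("track")
    def track():
        _, labels = btio.read_movie_hdf5(labels_h5)
        tc = config.track
        forest = trk.track_movie(labels, epsilon=tc.epsilon,
                                 lambda_disp=tc.lambda_disp,
                                 min_daughter_fraction=tc.min_daughter_fraction)
        records = {}
        for lv in labels:
            for r in morph.frame_records(lv):
                records[(r.frame, r.label)] = dict(centroid=tuple(r.centroid),
                                                   volume=r.volume)
        export_trackmate(forest, records, spacing=labels[0].spacing,
                         path=forest_xml)
        edges = pd.DataFrame(
            [dict(frame_src=u[0], label_src=u[1], frame_dst=v[0], label_dst=v[1],
                  kind=k) for u, v, k in forest.edges()])
        edges.to_csv(out / "edges.csv", index=False)
        forest.counts().to_csv(out / "counts.csv", float_format=_FLOAT_FMT)
        return {"edges": len(edges), "divisions": len(forest.division_nodes())}

    @stage("morphometry")
    def morphometry():
        _, labels = btio.read_movie_hdf5(labels_h5)
        forest, _ = read_trackmate(forest_xml)
        mc = config.morphometry
        recs_by_frame = {}
        embryos = {}
        all_recs = []
        shapes = []
        for lv in labels:
            recs = morph.frame_records(lv)
            recs_by_frame[lv.frame_index] = recs
            all_recs.extend(recs)
            if (lv.labels > 0).sum() >= 4:
                try:
                    es = morph.embryo_shape_from_labels(lv, recs,
                                                        seed=seeds["morphometry"])
                    embryos[lv.frame_index] = es
                    shapes.append(es)
                except DataFormatError:
                    pass
        morph.nuclei_table(all_recs).to_csv(out / "nuclei.csv", index=False,
                                            float_format=_FLOAT_FMT)
        morph.embryo_table(shapes).to_csv(out / "embryo.csv", index=False,
                                          float_format=_FLOAT_FMT)
        angles = morph.angle_table(recs_by_frame, embryos, forest)
        angles.to_csv(out / "angles.csv", index=False, float_format=_FLOAT_FMT)
        stats = {}
        for kind in ("beta", "theta"):
            sub = angles.loc[angles["kind"] == kind, "degrees"].to_numpy()
            if len(sub) >= 5:
                d, p = morph.ks_isotropy_test(sub, null=mc.ks_null)
                stats[kind] = {"n": int(len(sub)), "ks_D": d, "ks_p": p}
        (out / "angle_stats.json").write_text(json.dumps(stats, indent=2,
                                                         sort_keys=True))
        return {"nuclei_rows": len(all_recs), "angles": len(angles)}

    for fn in (acquire, segment, track, morphometry):
        fn()
    (out / "log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return out
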