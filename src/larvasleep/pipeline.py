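"""End-to-end pipeline stages: simulate fixtures, score larval videos,
score adult DAM files, and compare groups.

These functions are the library surface behind the CLI subcommands; each
writes CSV outputs plus a JSON sidecar with the resolved configuration so
that every run is reproducible from its output directory alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activity import (calibrate_activity_threshold, classify_activity,
                       pixel_change_scores, track_centroids)
from .config import RunConfig
from .dam import adult_sleep_record, score_adult_sleep
from .errors import InvalidParameterError
from .io import (parse_clock, read_dam2, read_frame_stack, states_from_table,
                 write_dam2, write_frame_stack, write_trace_csv)
from .sleep import call_sleep_bouts, locomotion_speed, metrics_record, sleep_metrics
from .stats import bonferroni, mann_whitney_u
from .synthetic import (BodyGeometry, CellGeometry, MotionParams,
                        render_dyed_larva, render_larva_video,
                        render_translocation_image, simulate_behavior_trace,
                        simulate_dam_series, write_truth_sidecar)

log = logging.getLogger("larvasleep")


def _write_provenance(out_dir: Path, config: RunConfig, extra: dict | None = None) -> None:
    payload = {"tool": "larvasleep", "version": __version__, **asdict(config)}
    if extra:
        payload.update(extra)
    (out_dir / "config.json").write_text(json.dumps(payload, indent=2, default=str) + "\n")


def run_simulate(config: RunConfig, out_dir: str | Path, n_animals: int = 24,
                 duration_s: float = 1200.0, mean_wake_s: float = 60.0,
                 mean_sleep_s: float = 60.0, well_size_px: int = 80,
                 with_dam: bool = True, with_cells: bool = True,
                 with_dye: bool = True) -> Path:
    """Generate a full synthetic fixture bundle: per-well larva videos with
    truth sidecars, a DAM text file, translocation cell images and dyed
    larva images."""
    config.validate()
    out = Path(out_dir)
    (out / "videos").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    motion = MotionParams(fps=config.fps, pixel_size_mm=config.pixel_size_mm)
    for i in range(n_animals):
        seed = config.seed * 10_000 + i
        trace, truth = simulate_behavior_trace(
            config.fps, duration_s, mean_wake_s, mean_sleep_s, seed=seed)
        stack = render_larva_video(truth, motion, well_size_px=well_size_px,
                                   seed=seed + 1)
        write_frame_stack(stack, out / "videos" / f"well_{i:02d}.tif")
        write_truth_sidecar(
            truth,
            {"fps": config.fps, "duration_s": duration_s,
             "mean_wake_s": mean_wake_s, "mean_sleep_s": mean_sleep_s},
            out / "truth" / f"well_{i:02d}.csv",
            out / "truth" / f"well_{i:02d}.json")
    if with_dam:
        (out / "dam").mkdir(exist_ok=True)
        schedule = [(120, 480), (700, 760)]
        series = simulate_dam_series(schedule, mean_counts_awake=4.0,
                                     n_minutes=2880, seed=config.seed)
        write_dam2(series, out / "dam" / "monitor01.txt")
    if with_cells:
        (out / "cells").mkdir(exist_ok=True)
        import tifffile
        for j, f in enumerate((0.3, 0.5, 0.7)):
            img, _ = render_translocation_image(f, CellGeometry(),
                                                seed=config.seed * 100 + j)
            tifffile.imwrite(out / "cells" / f"cell_f{int(f * 100):02d}.tif", img)
    if with_dye:
        (out / "dye").mkdir(exist_ok=True)
        import tifffile
        for j, s in enumerate((0.1, 0.3, 0.5)):
            img, _ = render_dyed_larva(s, BodyGeometry(), seed=config.seed * 100 + j)
            tifffile.imwrite(out / "dye" / f"larva_s{int(s * 100):02d}.tif", img)
    _write_provenance(out, config, {"n_animals": n_animals,
                                    "duration_s": duration_s,
                                    "mean_wake_s": mean_wake_s,
                                    "mean_sleep_s": mean_sleep_s})
    return out


def run_score_larva(config: RunConfig, input_dir: str | Path,
                    out_csv: str | Path | None = None,
                    with_tracking: bool = True) -> pd.DataFrame:
    """Score every per-well video in ``input_dir/videos`` (or ``input_dir``).

    The activity threshold is calibrated once on the pooled score histogram
    of the whole cohort (all wells were recorded on the same rig), then
    each well is classified, bouts are called at the 12-frame criterion and
    the per-animal metrics table is returned (and written when ``out_csv``
    is given).
    """
    config.validate()
    root = Path(input_dir)
    video_dir = root / "videos" if (root / "videos").is_dir() else root
    videos = sorted(video_dir.glob("*.tif")) + sorted(video_dir.glob("*.tiff"))
    if not videos:
        raise FileNotFoundError(f"no videos found under {video_dir}")
    stacks, score_list = [], []
    for v in videos:
        stack = read_frame_stack(v, fps=config.fps,
                                 pixel_size_mm=config.pixel_size_mm)
        scores = pixel_change_scores(stack, noise_floor=config.noise_floor,
                                     well_id=v.stem)
        stacks.append(stack)
        score_list.append(scores)
    pooled = np.concatenate([s.scores for s in score_list])
    threshold = calibrate_activity_threshold(pooled)
    log.info("calibrated pooled activity threshold: %.1f changed pixels", threshold)
    records = []
    for stack, scores in zip(stacks, score_list):
        trace = classify_activity(scores, threshold)
        bouts = call_sleep_bouts(trace, min_frames=config.min_sleep_frames)
        metrics = sleep_metrics(bouts, trace)
        speed = None
        if with_tracking:
            track = track_centroids(stack, noise_floor=config.noise_floor)
            speed = locomotion_speed(track, bouts, config.fps)
        records.append(metrics_record(scores.well_id, metrics, wake_speed=speed))
    df = pd.DataFrame(records)
    if out_csv is not None:
        write_trace_csv(df, out_csv)
        _write_provenance(Path(out_csv).parent, config,
                          {"threshold": threshold, "n_wells": len(videos)})
    return df


def score_against_truth(config: RunConfig, input_dir: str | Path) -> float:
    """Pooled frame-level classification accuracy against truth sidecars."""
    config.validate()
    root = Path(input_dir)
    correct = total = 0
    videos = sorted((root / "videos").glob("*.tif"))
    stacks = [read_frame_stack(v, fps=config.fps, pixel_size_mm=config.pixel_size_mm)
              for v in videos]
    score_list = [pixel_change_scores(s, noise_floor=config.noise_floor)
                  for s in stacks]
    threshold = calibrate_activity_threshold(
        np.concatenate([s.scores for s in score_list]))
    for v, scores in zip(videos, score_list):
        truth = states_from_table(pd.read_csv(root / "truth" / f"{v.stem}.csv"))
        pred = classify_activity(scores, threshold).states
        correct += int((pred == truth).sum())
        total += len(truth)
    return correct / total


def run_score_adult(config: RunConfig, dam_path: str | Path,
                    out_csv: str | Path | None = None) -> pd.DataFrame:
    """Score adult sleep for every channel of a DAM2 monitor file."""
    config.validate()
    series = read_dam2(dam_path)
    series.lights_on_min = parse_clock(config.lights_on)
    series.lights_off_min = parse_clock(config.lights_off)
    records = []
    for ch in series.channel_ids:
        result = score_adult_sleep(series, min_gap_min=config.adult_min_gap_min,
                                   channel=ch)
        records.append(adult_sleep_record(ch, result))
    df = pd.DataFrame(records)
    if out_csv is not None:
        write_trace_csv(df, out_csv)
        _write_provenance(Path(out_csv).parent, config, {"dam_file": str(dam_path)})
    return df


def run_compare(config: RunConfig, metrics_by_group: dict[str, pd.DataFrame],
                column: str = "total_sleep_s",
                family_size: int | None = None,
                out_csv: str | Path | None = None) -> pd.DataFrame:
    """Pairwise Mann-Whitney comparisons of one metric across groups.

    The Bonferroni family defaults to the number of pairwise comparisons
    performed; a larger planned family can be declared explicitly.
    """
    names = list(metrics_by_group)
    if len(names) < 2:
        raise InvalidParameterError("need at least two groups to compare")
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    m = family_size if family_size is not None else len(pairs)
    rows = []
    for a, b in pairs:
        xa = metrics_by_group[a][column].dropna().to_numpy()
        xb = metrics_by_group[b][column].dropna().to_numpy()
        if xa.size == 0 or xb.size == 0:
            raise InvalidParameterError(f"group {a if xa.size == 0 else b} is empty")
        cmp = mann_whitney_u(xa, xb, family_size=m)
        (med_a, q1_a, q3_a), (med_b, q1_b, q3_b) = cmp.summary
        rows.append({
            "group_a": a, "group_b": b, "n_a": xa.size, "n_b": xb.size,
            "U": cmp.statistic, "p": cmp.p_value, "p_adj": cmp.p_adjusted,
            "median_a": med_a, "q1_a": q1_a, "q3_a": q3_a,
            "median_b": med_b, "q1_b": q1_b, "q3_b": q3_b,
        })
    df = pd.DataFrame(rows)
    df["p_adj"] = bonferroni(df["p"].to_numpy(), family_size=m)
    if out_csv is not None:
        write_trace_csv(df, out_csv)
        _write_provenance(Path(out_csv).parent, config,
                          {"column": column, "family_size": m})
    return df
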