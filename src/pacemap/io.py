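"""File I/O: multi-page TIFF movies, masks (PNG or polygon CSV), YAML
simulation configs, and the CSV/JSON outputs of the pipeline."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .simulate import (FretParams, GroundTruth, NoiseModel, PacemakerSpec,
                       SimConfig, TwoChannelMovie)


def write_movie_tiff(movie: TwoChannelMovie, path) -> None:
    tifffile.imwrite(path, movie.frames, metadata={
        "frame_rate": movie.frame_rate, "layout": movie.layout,
        "bit_depth": movie.bit_depth})


def read_movie_tiff(path, frame_rate: float, layout: str,
                    bit_depth: int = 16) -> TwoChannelMovie:
    return TwoChannelMovie(frames=tifffile.imread(path), frame_rate=frame_rate,
                           layout=layout, bit_depth=bit_depth)


def write_stack_tiff(stack: np.ndarray, path) -> None:
    tifffile.imwrite(path, stack.astype(np.float32))


def load_mask_png(path) -> np.ndarray:
    """Nonzero pixels are in-mask."""
    import imageio.v3 as iio
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return img > 0


def load_mask_polygon_csv(path, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon given as (row, col) vertices, one per line."""
    from skimage.draw import polygon
    verts = pd.read_csv(path, header=None).to_numpy(float)
    rr, cc = polygon(verts[:, 0], verts[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def config_to_yaml(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def config_from_yaml(path) -> SimConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["pacemakers"] = [PacemakerSpec(**{**pm, "site": tuple(pm["site"])})
                         for pm in raw.get("pacemakers", [])]
    raw["fret_params"] = FretParams(**raw.get("fret_params", {}))
    raw["noise_model"] = NoiseModel(**raw.get("noise_model", {}))
    raw["grid_shape"] = tuple(raw["grid_shape"])
    return SimConfig(**raw)


def write_ground_truth(gt: GroundTruth, out_dir) -> None:
    """Events as JSON; per-beat activation maps flattened to one CSV with
    columns (beat, row, col, time_ms)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    events = [{"time_ms": t, "pacemaker": pm, "origin": list(site)}
              for t, pm, site in gt.firing_events]
    (out / "events.json").write_text(json.dumps(
        {"firing_events": events,
         "realized_beat_times_ms": gt.realized_beat_times.tolist()}, indent=1))
    rows = []
    for b, amap in enumerate(gt.activation_times):
        rr, cc = np.nonzero(np.isfinite(amap))
        for r, c in zip(rr, cc):
            rows.append((b, int(r), int(c), float(amap[r, c])))
    pd.DataFrame(rows, columns=["beat", "row", "col", "time_ms"]).to_csv(
        out / "activation_times.csv", index=False)


def write_activation_maps_csv(maps, path) -> None:
    rows = []
    for amap in maps:
        rr, cc = np.nonzero(np.isfinite(amap.times))
        for r, c in zip(rr, cc):
            rows.append((amap.beat_index, int(r), int(c),
                         float(amap.times[r, c])))
    pd.DataFrame(rows, columns=["beat", "row", "col", "time_ms"]).to_csv(
        path, index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonify))


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
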