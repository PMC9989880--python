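"""Reading and writing movies and analysis products.

A movie on disk is a multi-page TIFF stack plus a JSON sidecar with
timestamps and optics metadata; ground truth, when attached, is written as a
CSV of (theta_deg, tau_s) next to the stack.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from shgflux.errors import InvalidParameterError
from shgflux.geometry import GUVGeometry
from shgflux.synthetic import (
    CompositionPreset,
    OpticsConfig,
    SHMovie,
    TauField,
    TruthBundle,
)


def _jsonable(value):
    if isinstance(value, float) and math.isinf(value):
        return "inf"
    return value


def sidecar_path(tiff_path: Path) -> Path:
    return Path(tiff_path).with_suffix(".json")


def truth_tau_path(tiff_path: Path) -> Path:
    p = Path(tiff_path)
    return p.with_name(p.stem + "_truth_tau.csv")


def write_movie(movie: SHMovie, tiff_path) -> Path:
    """Write TIFF stack + JSON sidecar (+ truth tau CSV when present)."""
    tiff_path = Path(tiff_path)
    tiff_path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(tiff_path, movie.frames.astype(np.float32))
    meta = {
        "timestamps_s": [float(t) for t in movie.timestamps],
        "optics": {k: _jsonable(v) for k, v in
                   dataclasses.asdict(movie.optics).items()},
    }
    if movie.truth is not None:
        geo = movie.truth.geometry
        meta["truth"] = {
            "geometry": {
                "center_px": [float(geo.center[0]), float(geo.center[1])],
                "radius_um": geo.radius_um,
                "band_halfwidth_um": geo.band_halfwidth_um,
                "pixel_size_um": geo.pixel_size_um,
            },
            "preset": {k: _jsonable(v) for k, v in
                       dataclasses.asdict(movie.truth.preset).items()},
            "tau_csv": truth_tau_path(tiff_path).name,
            "tau_seed": movie.truth.tau_field.seed,
        }
        pd.DataFrame(
            {
                "theta_deg": movie.truth.tau_field.theta_grid,
                "tau_s": movie.truth.tau_field.tau,
            }
        ).to_csv(truth_tau_path(tiff_path), index=False)
    sidecar_path(tiff_path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return tiff_path


def read_movie(tiff_path) -> SHMovie:
    """Load a movie written by :func:`write_movie`."""
    tiff_path = Path(tiff_path)
    frames = tifffile.imread(tiff_path).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    side = sidecar_path(tiff_path)
    if not side.exists():
        raise InvalidParameterError(f"sidecar {side} not found")
    meta = json.loads(side.read_text())
    optics_dict = dict(meta["optics"])
    optics = OpticsConfig(**{k: (math.inf if v == "inf" else v)
                             for k, v in optics_dict.items()})
    truth = None
    if "truth" in meta:
        tm = meta["truth"]
        geo = GUVGeometry(
            center=tuple(tm["geometry"]["center_px"]),
            radius_um=tm["geometry"]["radius_um"],
            band_halfwidth_um=tm["geometry"]["band_halfwidth_um"],
            pixel_size_um=tm["geometry"]["pixel_size_um"],
        )
        preset = CompositionPreset(**{k: (math.inf if v == "inf" else v)
                                      for k, v in tm["preset"].items()})
        df = pd.read_csv(tiff_path.parent / tm["tau_csv"])
        field = TauField(
            theta_grid=df["theta_deg"].to_numpy(float),
            tau=df["tau_s"].to_numpy(float),
            seed=int(tm["tau_seed"]),
        )
        truth = TruthBundle(geometry=geo, tau_field=field, preset=preset)
    return SHMovie(
        frames=frames,
        timestamps=np.asarray(meta["timestamps_s"], dtype=float),
        optics=optics,
        truth=truth,
    )


def decay_map_frame(decay_map) -> pd.DataFrame:
    """Tabulate a decay map: one row per ROI."""
    rows = []
    for i, (rng, fit) in enumerate(zip(decay_map.roi_boundaries, decay_map.fits)):
        rows.append(
            {
                "roi_index": i,
                "theta_start_deg": rng[0],
                "theta_end_deg": rng[1],
                "tau_s": fit.tau,
                "tau_se_s": fit.tau_se,
                "amplitude": fit.amplitude,
                "baseline": fit.baseline,
                "converged": fit.converged,
                "no_decay": fit.no_decay,
            }
        )
    return pd.DataFrame(rows)


def trace_frame(trace, normalized: bool = True) -> pd.DataFrame:
    """Tabulate an integrated trace, raw and t=0-normalized."""
    df = pd.DataFrame({"t_s": trace.times, "intensity": trace.intensity})
    if normalized:
        first = trace.intensity[0] if trace.intensity[0] != 0 else 1.0
        df["intensity_norm"] = trace.intensity / first
    return df
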