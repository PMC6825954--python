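"""Readers and writers for the open interchange formats.

Frames are plain PNG/TIFF rasters (8-bit per channel); the paw-detection
log and the gait table are CSV; run results are JSON; species profiles can
be loaded from YAML.  Frame indexing is 1-based throughout: the first
raster in lexical order is frame 1.

Gait-table schema (one row per run)::

    animal_id, genotype, age, run_id,
    stride_{front,hind}_{left,right}          # cm
    stand_time_{front,hind}_{left,right}      # s
    swing_time_{front,hind}_{left,right}      # s
    step_cycle_{front,hind}_{left,right}      # s
    swing_speed_{front,hind}_{left,right}     # cm/s
    body_speed_{rf,lf,rh,lh}                  # cm/s
    weight                                    # g, optional

Left/right columns are kept raw here; averaging is done in the scaling
module.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .errors import InputError, ParseError, SchemaError, ShapeError, ValidationError
from .silhouette import (
    FrameSilhouette,
    FrameWindow,
    PAW_LABELS,
    PawTrackSet,
    ResolutionSpec,
    RunInput,
    RunSilhouette,
    SPECIES_PROFILES,
    SpeciesProfile,
)

FRAME_SUFFIXES = (".png", ".tif", ".tiff")

#: Paired gait parameters with left/right columns in the raw table.
PAIRED_COLUMNS = [
    f"{p}_{fh}_{side}"
    for p in ("stride", "stand_time", "swing_time", "step_cycle", "swing_speed")
    for fh in ("front", "hind")
    for side in ("left", "right")
]
BODY_SPEED_COLUMNS = ["body_speed_rf", "body_speed_lf", "body_speed_rh", "body_speed_lh"]
ID_COLUMNS = ["animal_id", "genotype", "age", "run_id"]
REQUIRED_GAIT_COLUMNS = ID_COLUMNS + PAIRED_COLUMNS + BODY_SPEED_COLUMNS


def read_frame_sequence(
    directory: str | Path,
    resolution: ResolutionSpec,
    background: str | Path | None = None,
    species_profile: SpeciesProfile | None = None,
) -> RunInput:
    """Load a lexically ordered PNG/TIFF frame sequence plus background.

    ``background`` defaults to a file whose stem is ``background`` inside
    ``directory``; it is excluded from the frame list.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise InputError(f"not a directory: {directory}")
    rasters = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in FRAME_SUFFIXES
    )
    if background is None:
        candidates = [p for p in rasters if p.stem.lower() == "background"]
        if not candidates:
            raise InputError(f"no background image found in {directory}")
        background = candidates[0]
    background = Path(background)
    if not background.is_file():
        raise InputError(f"background image not found: {background}")
    frame_paths = [p for p in rasters if p.resolve() != background.resolve()]
    if not frame_paths:
        raise InputError(f"no frame images found in {directory}")
    frames = [np.asarray(iio.imread(p)) for p in frame_paths]
    bg = np.asarray(iio.imread(background))
    shape = frames[0].shape
    for p, f in zip(frame_paths, frames):
        if f.shape != shape:
            raise ShapeError(f"{p.name} has shape {f.shape}, expected {shape}")
    if bg.shape != shape:
        raise ShapeError(f"background shape {bg.shape} != frame shape {shape}")
    return RunInput(
        frames=frames,
        background=bg,
        resolution=resolution,
        species_profile=species_profile or SPECIES_PROFILES["rat"],
    )


def read_paw_tracks(csv: str | Path) -> PawTrackSet:
    """Parse a ``frame,paw`` CSV into four ascending, de-duplicated
    frame-index lists."""
    df = pd.read_csv(csv)
    for col in ("frame", "paw"):
        if col not in df.columns:
            raise SchemaError(f"paw log is missing column {col!r}")
    frames = pd.to_numeric(df["frame"], errors="coerce")
    if frames.isna().any() or (frames != frames.astype(int)).any():
        raise ParseError("paw log column 'frame' must contain integers")
    if (frames < 1).any():
        raise ParseError("paw log frame indices must be positive (1-based)")
    paws = df["paw"].astype(str).str.strip().str.upper()
    unknown = sorted(set(paws) - set(PAW_LABELS))
    if unknown:
        raise ParseError(f"unknown paw label(s): {unknown}")
    idx = {
        paw: tuple(sorted(set(frames[paws == paw].astype(int))))
        for paw in PAW_LABELS
    }
    return PawTrackSet(
        f_RF=idx["RF"], f_LF=idx["LF"], f_RH=idx["RH"], f_LH=idx["LH"]
    )


def read_gait_table(csv: str | Path) -> pd.DataFrame:
    """Read and validate the raw run-level gait table (left/right columns
    retained; averaging happens in the scaling module)."""
    df = pd.read_csv(csv)
    missing = [c for c in REQUIRED_GAIT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"gait table is missing column(s): {missing}")
    numeric = PAIRED_COLUMNS + BODY_SPEED_COLUMNS
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise ValidationError(f"column {col!r} contains non-numeric values")
        if (vals < 0).any():
            raise ValidationError(f"column {col!r} contains negative values")
        df[col] = vals.astype(float)
    if "weight" in df.columns:
        df["weight"] = pd.to_numeric(df["weight"], errors="coerce")
    return df


# --------------------------------------------------------------------------
# run results
# --------------------------------------------------------------------------

def run_result_to_dict(run: RunSilhouette) -> dict:
    return {
        "silhouette_length_cm": run.silhouette_length_cm,
        "area_with_tail_mm2": run.area_with_tail_mm2,
        "area_without_tail_mm2": run.area_without_tail_mm2,
        "f_start": run.window.f_start,
        "f_stop": run.window.f_stop,
        "n_frames_used": run.n_frames_used,
        "per_frame": [
            {
                "frame": fs.frame,
                "length_cm": fs.length_cm,
                "area_with_tail_mm2": fs.area_with_tail_mm2,
                "area_without_tail_mm2": fs.area_without_tail_mm2,
                "endpoints": [list(fs.endpoints[0]), list(fs.endpoints[1])],
            }
            for fs in run.per_frame
        ],
    }


def write_run_result(run: RunSilhouette, path: str | Path) -> None:
    """Write a run result as JSON (round-trips with :func:`read_run_result`)."""
    Path(path).write_text(json.dumps(run_result_to_dict(run), indent=2))


def read_run_result(path: str | Path) -> RunSilhouette:
    d = json.loads(Path(path).read_text())
    per_frame = tuple(
        FrameSilhouette(
            frame=int(f["frame"]),
            length_cm=float(f["length_cm"]),
            area_with_tail_mm2=float(f["area_with_tail_mm2"]),
            area_without_tail_mm2=float(f["area_without_tail_mm2"]),
            endpoints=(tuple(f["endpoints"][0]), tuple(f["endpoints"][1])),
        )
        for f in d.get("per_frame", [])
    )
    return RunSilhouette(
        silhouette_length_cm=float(d["silhouette_length_cm"]),
        area_with_tail_mm2=float(d["area_with_tail_mm2"]),
        area_without_tail_mm2=float(d["area_without_tail_mm2"]),
        window=FrameWindow(int(d["f_start"]), int(d["f_stop"])),
        n_frames_used=int(d["n_frames_used"]),
        per_frame=per_frame,
    )


def load_species_profiles(path: str | Path) -> dict[str, SpeciesProfile]:
    """Load species profiles from YAML::

        species:
          rat: {r_d_mm: 9, threshold: 10}
    """
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "species" not in data:
        raise SchemaError("species config must have a top-level 'species' map")
    profiles = {}
    for name, params in data["species"].items():
        if "r_d_mm" not in params:
            raise SchemaError(f"species {name!r} is missing r_d_mm")
        profiles[name] = SpeciesProfile(
            name=name,
            r_d_mm=float(params["r_d_mm"]),
            threshold=int(params.get("threshold", 10)),
        )
    return profiles
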