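"""Silhouette extraction and measurement from walkway video frames.

The pipeline turns one run of a rodent crossing an illuminated walkway into a
single body-length and body-area estimate:

1. an analysis window is chosen from the paw-detection log — the run starts
   at the first frame where both hind paws have appeared and ends at the last
   frame where both front paws are still visible;
2. each frame in the window is compared against the background image; a pixel
   is foreground when it differs by more than a threshold in at least one
   RGB channel;
3. the tail is removed by morphological opening with a diamond structuring
   element whose radius matches the tail thickness of the species;
4. holes are filled and the largest connected component is kept as the body
   silhouette;
5. the silhouette length is the Euclidean distance between the extreme
   pixels along the walkway axis, corrected by the structuring-element
   radius (roughly half the element sits in the tail-root area), and the
   silhouette area is the foreground pixel count times the pixel area;
6. run-level values are the maxima over all frames in the window.

The walkway axis is assumed to run along image columns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import diamond as _diamond_footprint

from .errors import (
    EmptyWindowError,
    MissingPawError,
    NoSilhouetteError,
    ParameterError,
    ShapeError,
)

logger = logging.getLogger("silgait")

#: Default foreground threshold on the per-channel absolute intensity
#: difference (8-bit counts); strict inequality is applied.
DEFAULT_THRESHOLD = 10

PAW_LABELS = ("RF", "LF", "RH", "LH")


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ResolutionSpec:
    """Physical pixel size: ``x_mm`` along the walkway, ``y_mm`` across it."""

    x_mm: float
    y_mm: float

    def __post_init__(self) -> None:
        for name in ("x_mm", "y_mm"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ParameterError(f"{name} must be finite and > 0, got {v!r}")

    @property
    def pixel_area_mm2(self) -> float:
        return self.x_mm * self.y_mm


@dataclass(frozen=True)
class SpeciesProfile:
    """Named parameter set: structuring-element radius and threshold."""

    name: str
    r_d_mm: float
    threshold: int = DEFAULT_THRESHOLD


#: Presets: rats use a 9 mm diamond radius, mice 5 mm; both use threshold 10.
SPECIES_PROFILES = {
    "rat": SpeciesProfile("rat", r_d_mm=9.0),
    "mouse": SpeciesProfile("mouse", r_d_mm=5.0),
}


@dataclass
class RunInput:
    """One run: ordered RGB frames, a background frame, and metadata.

    Frame indices are 1-based: ``frames[0]`` is frame 1.
    """

    frames: list[np.ndarray]
    background: np.ndarray
    resolution: ResolutionSpec
    species_profile: SpeciesProfile = field(
        default_factory=lambda: SPECIES_PROFILES["rat"]
    )

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ShapeError("a run needs at least one frame")
        shape = self.background.shape
        for i, f in enumerate(self.frames, start=1):
            if f.shape != shape:
                raise ShapeError(
                    f"frame {i} has shape {f.shape}, background has {shape}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class PawTrackSet:
    """Strictly ascending frame-index lists of detected paws (1-based)."""

    f_RF: tuple[int, ...]
    f_LF: tuple[int, ...]
    f_RH: tuple[int, ...]
    f_LH: tuple[int, ...]

    def __post_init__(self) -> None:
        for paw in PAW_LABELS:
            idx = getattr(self, f"f_{paw}")
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ParameterError(f"f_{paw} must be strictly ascending")
            if any(i < 1 for i in idx):
                raise ParameterError(f"f_{paw} contains a non-positive index")


@dataclass(frozen=True)
class FrameWindow:
    """Inclusive 1-based frame range [f_start, f_stop]."""

    f_start: int
    f_stop: int

    def __post_init__(self) -> None:
        if self.f_start > self.f_stop:
            raise EmptyWindowError(
                f"empty window: f_start={self.f_start} > f_stop={self.f_stop}"
            )


@dataclass(frozen=True)
class DiamondSE:
    """Diamond structuring element with a physical and a pixel radius."""

    r_d_mm: float
    r_d_px: int
    footprint: np.ndarray

    @property
    def n_pixels(self) -> int:
        return int(self.footprint.sum())


@dataclass(frozen=True)
class FrameSilhouette:
    """Per-frame measurement result."""

    frame: int
    length_cm: float
    area_with_tail_mm2: float
    area_without_tail_mm2: float
    endpoints: tuple[tuple[int, int], tuple[int, int]]  # ((x1,y1),(x2,y2))


@dataclass(frozen=True)
class RunSilhouette:
    """Run-level silhouette values: maxima over the per-frame values."""

    silhouette_length_cm: float
    area_with_tail_mm2: float
    area_without_tail_mm2: float
    window: FrameWindow
    n_frames_used: int
    per_frame: tuple[FrameSilhouette, ...] = ()


# --------------------------------------------------------------------------
# pipeline stages
# --------------------------------------------------------------------------

def compute_frame_window(tracks: PawTrackSet) -> FrameWindow:
    """Analysis window: from first appearance of both hind paws to last
    appearance of both front paws.

    f_start = max{f_RH(1), f_LH(1)};  f_stop = min{f_RF(last), f_LF(last)}.
    """
    for paw in PAW_LABELS:
        if not getattr(tracks, f"f_{paw}"):
            raise MissingPawError(f"paw {paw} was never detected")
    f_start = max(tracks.f_RH[0], tracks.f_LH[0])
    f_stop = min(tracks.f_RF[-1], tracks.f_LF[-1])
    return FrameWindow(f_start, f_stop)  # raises EmptyWindowError if inverted


def _as_rgb(frame: np.ndarray) -> np.ndarray:
    """Promote grayscale to 3 identical channels; drop alpha if present."""
    if frame.ndim == 2:
        return np.stack([frame] * 3, axis=-1)
    if frame.ndim == 3 and frame.shape[2] == 4:
        return frame[:, :, :3]
    if frame.ndim == 3 and frame.shape[2] == 3:
        return frame
    raise ShapeError(f"expected HxW or HxWx3 image, got shape {frame.shape}")


def subtract_background(
    frame: np.ndarray, background: np.ndarray, threshold: int = DEFAULT_THRESHOLD
) -> np.ndarray:
    """Foreground mask: |frame − background| strictly greater than the
    threshold in at least one of the R, G, B channels (logical OR)."""
    if threshold < 0:
        raise ParameterError(f"threshold must be >= 0, got {threshold}")
    frame = _as_rgb(np.asarray(frame))
    background = _as_rgb(np.asarray(background))
    if frame.shape != background.shape:
        raise ShapeError(
            f"frame shape {frame.shape} != background shape {background.shape}"
        )
    diff = np.abs(frame.astype(np.int32) - background.astype(np.int32))
    return (diff > threshold).any(axis=2)


def make_diamond_se(r_d_mm: float, resolution: ResolutionSpec) -> DiamondSE:
    """Diamond structuring element: all pixels with Manhattan distance
    ≤ r_d_px from the origin, where r_d_px = round(r_d_mm / x_mm)
    (half-up, minimum 1).

    5 mm at 0.7 mm/px gives a 7-pixel radius; 9 mm at 1 mm/px gives 9.
    """
    if not (math.isfinite(r_d_mm) and r_d_mm > 0):
        raise ParameterError(f"r_d_mm must be > 0, got {r_d_mm!r}")
    r_d_px = max(1, int(math.floor(r_d_mm / resolution.x_mm + 0.5)))
    return DiamondSE(r_d_mm, r_d_px, _diamond_footprint(r_d_px).astype(bool))


def open_remove_tail(mask: np.ndarray, se: DiamondSE) -> np.ndarray:
    """Morphological opening (erosion then dilation) with the diamond
    element; removes any structure narrower than the element — the tail."""
    return ndimage.binary_opening(np.asarray(mask, bool), structure=se.footprint)


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background regions not 4-connected to the image border."""
    return ndimage.binary_fill_holes(np.asarray(mask, bool))


_EIGHT = np.ones((3, 3), bool)


def retain_largest_object(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected component (the body silhouette).

    Equal-size maxima are broken by row-major scan order of each
    component's first pixel.
    """
    mask = np.asarray(mask, bool)
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        raise NoSilhouetteError("mask contains no foreground pixels")
    counts = np.bincount(labels.ravel())[1:]
    # scipy assigns labels in row-major scan order, so argmax's first-max
    # rule implements the earliest-first-pixel tie-break
    keep = int(np.argmax(counts)) + 1
    return labels == keep


def _endpoint_row(mask: np.ndarray, col: int, centroid_row: float) -> int:
    """Row of the endpoint in an extreme column: nearest the silhouette
    centroid row, lower row on ties."""
    rows = np.flatnonzero(mask[:, col])
    return int(rows[np.argmin(np.abs(rows - centroid_row))])


def measure_silhouette(
    mask_r: np.ndarray,
    mask_with_tail: np.ndarray,
    se: DiamondSE,
    resolution: ResolutionSpec,
    frame_index: int = 0,
) -> FrameSilhouette:
    """Length and areas of one frame's silhouette.

    The length is the Euclidean distance between the rightmost and leftmost
    silhouette pixels along the walkway axis, with the structuring-element
    radius subtracted from the x-span (about half the element lies in the
    tail-root area).  A negative x-span after subtraction clamps the length
    to zero.  Areas are pixel counts times the pixel area, for the
    tail-free mask and the with-tail mask.
    """
    mask_r = np.asarray(mask_r, bool)
    cols = np.flatnonzero(mask_r.any(axis=0))
    if cols.size == 0:
        raise NoSilhouetteError("empty silhouette mask")
    x2, x1 = int(cols[0]), int(cols[-1])  # leftmost, rightmost columns
    centroid_row = float(np.mean(np.nonzero(mask_r)[0]))
    y1 = _endpoint_row(mask_r, x1, centroid_row)
    y2 = _endpoint_row(mask_r, x2, centroid_row)

    dx_mm = (x1 - x2 - se.r_d_px) * resolution.x_mm
    dy_mm = (y1 - y2) * resolution.y_mm
    length_mm = 0.0 if dx_mm < 0 else math.hypot(dx_mm, dy_mm)

    px_area = resolution.pixel_area_mm2
    area_without = float(mask_r.sum()) * px_area
    area_with = float(np.asarray(mask_with_tail, bool).sum()) * px_area
    return FrameSilhouette(
        frame=frame_index,
        length_cm=length_mm / 10.0,
        area_with_tail_mm2=area_with,
        area_without_tail_mm2=area_without,
        endpoints=((x1, y1), (x2, y2)),
    )


def extract_frame_silhouette(
    frame: np.ndarray,
    background: np.ndarray,
    se: DiamondSE,
    resolution: ResolutionSpec,
    threshold: int = DEFAULT_THRESHOLD,
    frame_index: int = 0,
) -> FrameSilhouette:
    """Full per-frame chain: background subtraction, tail removal via
    opening, hole filling, largest-object retention, measurement.

    The with-tail area uses the hole-filled largest component of the raw
    foreground (tail kept, noise blobs suppressed).
    """
    fg = subtract_background(frame, background, threshold)
    if not fg.any():
        raise NoSilhouetteError("background subtraction produced an empty mask")
    with_tail = retain_largest_object(fill_holes(fg))
    opened = open_remove_tail(fg, se)
    if not opened.any():
        raise NoSilhouetteError("opening removed the entire foreground")
    mask_r = retain_largest_object(fill_holes(opened))
    return measure_silhouette(mask_r, with_tail, se, resolution, frame_index)


def process_run(run: RunInput, tracks: PawTrackSet) -> RunSilhouette:
    """Apply the per-frame chain to every frame in the paw-defined window
    and aggregate by taking the maximum length and areas over frames.

    Frames yielding no silhouette are skipped with a warning; the run fails
    only if every frame in the window is empty.
    """
    for paw in PAW_LABELS:
        idx = getattr(tracks, f"f_{paw}")
        if idx and idx[-1] > run.n_frames:
            raise ParameterError(
                f"paw log references frame {idx[-1]} but run has {run.n_frames}"
            )
    window = compute_frame_window(tracks)
    se = make_diamond_se(run.species_profile.r_d_mm, run.resolution)
    threshold = run.species_profile.threshold

    results: list[FrameSilhouette] = []
    for f in range(window.f_start, window.f_stop + 1):
        try:
            results.append(
                extract_frame_silhouette(
                    run.frames[f - 1], run.background, se, run.resolution,
                    threshold=threshold, frame_index=f,
                )
            )
        except NoSilhouetteError as exc:
            logger.warning("frame %d skipped: %s", f, exc)
    if not results:
        raise NoSilhouetteError(
            f"no frame in window [{window.f_start}, {window.f_stop}] "
            "yielded a silhouette"
        )
    return RunSilhouette(
        silhouette_length_cm=max(r.length_cm for r in results),
        area_with_tail_mm2=max(r.area_with_tail_mm2 for r in results),
        area_without_tail_mm2=max(r.area_without_tail_mm2 for r in results),
        window=window,
        n_frames_used=len(results),
        per_frame=tuple(results),
    )
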