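"""Acquisition schedules and image/line-scan assembly.

Two protocols are modeled after the in-vivo acquisition geometry:

* **line scan** — hold 5 min at A, traverse 5 min to B, hold at B, traverse
  to C, hold at C.  Holds are averaged whole (15,000 frames at 50 Hz);
  traverses are divided into 150-frame (3 s) points.  25 min total.
* **2-D raster** — 64 pixels (8×8 by default, 0.25 mm pitch), 1800 frames
  (36 s) per pixel, each grid cell visited exactly once per image so that
  repeated images leave the cumulative laser fluence uniform across pixels
  and photobleaching cannot imprint the visit order on the image.

Coordinates: x runs along the cord (rostral→caudal positive), y across it,
origin at the impact site B; pixel indices are 0-based row-major and
positions are pixel centers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import pvoh, spectra
from .errors import InvalidInputError, InvalidProtocolError, StreamAlignmentError

DEFAULT_POSITIONS = {"A": (-1.0, 1.0), "B": (0.0, 0.0), "C": (1.0, 1.0)}


@dataclass(frozen=True)
class ScanProtocol:
    """Declarative acquisition plan (defaults match the reference protocol)."""

    frame_rate: float = 50.0        # Hz
    exposure: float = 0.020         # s
    hold_duration: float = 300.0    # s per hold
    traverse_duration: float = 300.0  # s per traverse leg
    traverse_block: int = 150       # frames per averaged traverse point
    positions: dict = field(default_factory=lambda: dict(DEFAULT_POSITIONS))
    grid_shape: tuple[int, int] = (8, 8)   # rows (y) × cols (x)
    pixel_pitch: float = 0.25       # mm
    pixel_dwell: float = 36.0       # s per raster pixel
    grid_center: tuple[float, float] = (0.0, 0.0)  # mm, at the impact site

    def __post_init__(self):
        if self.frame_rate * self.exposure > 1.0 + 1e-9:
            raise InvalidProtocolError("frame_rate * exposure must be <= 1")
        if min(self.hold_duration, self.traverse_duration, self.pixel_dwell) <= 0:
            raise InvalidProtocolError("durations must be positive")
        if self.traverse_block < 1:
            raise InvalidProtocolError("traverse_block must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "ScanProtocol":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "positions" in payload:
            payload["positions"] = {k: tuple(v) for k, v in payload["positions"].items()}
        if "grid_shape" in payload:
            payload["grid_shape"] = tuple(payload["grid_shape"])
        if "grid_center" in payload:
            payload["grid_center"] = tuple(payload["grid_center"])
        return cls(**payload)


@dataclass(frozen=True)
class Segment:
    """One timed, positioned block of frames in a schedule."""

    kind: str                      # "hold" | "traverse" | "pixel"
    start_xy: tuple[float, float]  # mm
    end_xy: tuple[float, float]    # mm (== start for stationary kinds)
    t0: float                      # s from schedule start
    n_frames: int
    block_size: int
    label: str = ""
    grid_index: tuple[int, int] | None = None  # (row, col) for pixels

    @property
    def duration(self) -> float:
        return self.n_frames  # frames; seconds via schedule frame_rate

    def frame_positions(self, frame_rate: float):
        """Per-frame (t, x, y); traverse positions interpolate linearly."""
        tt = self.t0 + (np.arange(self.n_frames) + 0.5) / frame_rate
        frac = ((np.arange(self.n_frames) + 0.5) / self.n_frames
                if self.kind == "traverse" else np.zeros(self.n_frames))
        x = self.start_xy[0] + frac * (self.end_xy[0] - self.start_xy[0])
        y = self.start_xy[1] + frac * (self.end_xy[1] - self.start_xy[1])
        return tt, x, y


@dataclass(frozen=True)
class Schedule:
    """A protocol expanded into contiguous, timed, positioned segments."""

    segments: tuple[Segment, ...]
    frame_rate: float
    kind: str = "line"             # "line" | "raster"
    grid_shape: tuple[int, int] | None = None
    pixel_pitch: float | None = None

    @property
    def n_frames(self) -> int:
        return sum(s.n_frames for s in self.segments)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def n_blocks(self) -> int:
        return sum(s.n_frames // s.block_size for s in self.segments)


def build_line_schedule(protocol: ScanProtocol) -> Schedule:
    """hold(A) → traverse(A→B) → hold(B) → ... for the protocol's positions.

    With defaults: 15,000 frames per hold, 100 traverse points of 150 frames
    (3 s) each, 1500 s (25 min) overall.
    """
    names = list(protocol.positions)
    if len(names) < 2:
        raise InvalidProtocolError("line scan needs >= 2 positions")
    hold_frames = int(round(protocol.hold_duration * protocol.frame_rate))
    trav_frames = int(round(protocol.traverse_duration * protocol.frame_rate))
    if trav_frames % protocol.traverse_block:
        import warnings
        warnings.warn(
            f"traverse of {trav_frames} frames is not a whole number of "
            f"{protocol.traverse_block}-frame points; the trailing partial "
            "point is handled by average_blocks", stacklevel=2)
    segs: list[Segment] = []
    t = 0.0
    for i, name in enumerate(names):
        xy = tuple(protocol.positions[name])
        segs.append(Segment("hold", xy, xy, t, hold_frames, hold_frames, label=name))
        t += hold_frames / protocol.frame_rate
        if i + 1 < len(names):
            nxt = names[i + 1]
            segs.append(Segment("traverse", xy, tuple(protocol.positions[nxt]), t,
                                trav_frames, protocol.traverse_block,
                                label=f"{name}{nxt}"))
            t += trav_frames / protocol.frame_rate
    return Schedule(tuple(segs), protocol.frame_rate, kind="line")


def serpentine_order(rows: int, cols: int) -> list[tuple[int, int]]:
    """Boustrophedon row-major visit order."""
    order = []
    for r in range(rows):
        cc = range(cols) if r % 2 == 0 else range(cols - 1, -1, -1)
        order.extend((r, c) for c in cc)
    return order


def pixel_centers(protocol: ScanProtocol) -> tuple[np.ndarray, np.ndarray]:
    """(x_cols, y_rows) pixel-center coordinates in mm."""
    rows, cols = protocol.grid_shape
    cx, cy = protocol.grid_center
    x = cx + (np.arange(cols) - (cols - 1) / 2) * protocol.pixel_pitch
    y = cy + (np.arange(rows) - (rows - 1) / 2) * protocol.pixel_pitch
    return x, y


def build_raster_schedule(protocol: ScanProtocol,
                          visit_order: list[tuple[int, int]] | None = None) -> Schedule:
    """One timed visit to every grid cell, default boustrophedon order.

    The same visit order is reused for successive images so that after k
    images every pixel has endured identical cumulative fluence.  Each
    pixel's frames are attributed to its center.
    """
    rows, cols = protocol.grid_shape
    if rows * cols == 0:
        raise InvalidProtocolError("raster grid must have positive area")
    order = visit_order if visit_order is not None else serpentine_order(rows, cols)
    if sorted(order) != sorted((r, c) for r in range(rows) for c in range(cols)):
        raise InvalidProtocolError(
            "visit order must cover every grid cell exactly once")
    px, py = pixel_centers(protocol)
    n_frames = int(round(protocol.pixel_dwell * protocol.frame_rate))
    segs = []
    t = 0.0
    for (r, c) in order:
        xy = (float(px[c]), float(py[r]))
        segs.append(Segment("pixel", xy, xy, t, n_frames, n_frames,
                            label=f"r{r}c{c}", grid_index=(r, c)))
        t += n_frames / protocol.frame_rate
    return Schedule(tuple(segs), protocol.frame_rate, kind="raster",
                    grid_shape=protocol.grid_shape, pixel_pitch=protocol.pixel_pitch)


# ---------------------------------------------------------------------------
# assembly

def _check_alignment(stream: pd.DataFrame, schedule: Schedule) -> str:
    """Return 'frames' or 'blocks' depending on which count the stream matches."""
    n = len(stream)
    if n == schedule.n_frames:
        return "frames"
    if n == schedule.n_blocks:
        return "blocks"
    raise StreamAlignmentError(schedule.n_frames, n)


def _segment_slices(schedule: Schedule, unit: str):
    """Yield (segment, slice) pairs over the stream rows."""
    i = 0
    for seg in schedule.segments:
        n = seg.n_frames if unit == "frames" else seg.n_frames // seg.block_size
        yield seg, slice(i, i + n)
        i += n


def assemble_line_scan(samples, schedule: Schedule,
                       calib: pvoh.CalibrationParams) -> pd.DataFrame:
    """Reduce an emission stream to a PV[O]H line-scan profile.

    Per schedule point: block-averaged ee/ie, inverted volume fractions and
    apparent Hct; positions interpolated linearly along traverse segments at
    block-midpoint times.  Returns a DataFrame with columns
    ``t, x, y, path_mm, ee, ie, phi_r, phi_p, phi_s, hct, n_frames, label,
    in_range``.
    """
    stream = spectra._as_stream(samples).reset_index(drop=True)
    unit = _check_alignment(stream, schedule)
    rows = []
    path_offset = 0.0
    for seg, sl in _segment_slices(schedule, unit):
        part = stream.iloc[sl]
        pts = (spectra.average_blocks(part, seg.block_size) if unit == "frames"
               else part.reset_index(drop=True))
        n_pts = len(pts)
        frac = ((np.arange(n_pts) + 0.5) / n_pts if seg.kind == "traverse"
                else np.zeros(n_pts))
        dx = seg.end_xy[0] - seg.start_xy[0]
        dy = seg.end_xy[1] - seg.start_xy[1]
        seg_len = float(np.hypot(dx, dy))
        out = pts.copy()
        out["x"] = seg.start_xy[0] + frac * dx
        out["y"] = seg.start_xy[1] + frac * dy
        out["path_mm"] = path_offset + frac * seg_len
        out["label"] = seg.label
        rows.append(out)
        path_offset += seg_len
    prof = pd.concat(rows, ignore_index=True)
    phi_r, phi_p, phi_s, ok = pvoh.invert_stream(prof["ee"], prof["ie"], calib)
    prof["phi_r"], prof["phi_p"], prof["phi_s"] = phi_r, phi_p, phi_s
    prof["hct"] = pvoh.hematocrit_arrays(phi_r, phi_p)
    prof["in_range"] = ok
    return prof


@dataclass(frozen=True)
class ImageGrid:
    """A PV[O]H raster image: per-pixel Hct with its provenance matrices."""

    hct: np.ndarray
    ee: np.ndarray
    ie: np.ndarray
    in_range: np.ndarray            # quality flags (False = extrapolated)
    x_mm: np.ndarray                # column centers
    y_mm: np.ndarray                # row centers
    t_mid: np.ndarray               # per-pixel acquisition mid-times, s
    calib_hash: str = ""

    def __post_init__(self):
        shape = self.hct.shape
        for name in ("ee", "ie", "in_range", "t_mid"):
            if getattr(self, name).shape != shape:
                raise InvalidInputError(f"{name} matrix shape mismatch")
        if (len(self.y_mm), len(self.x_mm)) != shape:
            raise InvalidInputError("coordinate vectors inconsistent with grid shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.hct.shape

    @property
    def center_index(self) -> tuple[int, int]:
        return (self.shape[0] // 2, self.shape[1] // 2)

    def save(self, path: str | Path) -> None:
        """TSV matrix of Hct plus a JSON sidecar with coordinates/times."""
        path = Path(path)
        np.savetxt(path, self.hct, delimiter="\t", fmt="%.10g")
        sidecar = {
            "x_mm": self.x_mm.tolist(), "y_mm": self.y_mm.tolist(),
            "t_mid": self.t_mid.tolist(),
            "ee": self.ee.tolist(), "ie": self.ie.tolist(),
            "in_range": self.in_range.astype(int).tolist(),
            "calib_hash": self.calib_hash,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "ImageGrid":
        path = Path(path)
        hct = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            hct=hct,
            ee=np.array(meta["ee"]), ie=np.array(meta["ie"]),
            in_range=np.array(meta["in_range"], dtype=bool),
            x_mm=np.array(meta["x_mm"]), y_mm=np.array(meta["y_mm"]),
            t_mid=np.array(meta["t_mid"]), calib_hash=meta.get("calib_hash", ""),
        )


def _calib_hash(calib: pvoh.CalibrationParams) -> str:
    return hashlib.sha256(calib.to_json().encode()).hexdigest()[:12]


def assemble_image(samples, schedule: Schedule,
                   calib: pvoh.CalibrationParams) -> ImageGrid:
    """Reduce an emission stream from a raster schedule to an image grid."""
    if schedule.kind != "raster" or schedule.grid_shape is None:
        raise InvalidProtocolError("assemble_image requires a raster schedule")
    stream = spectra._as_stream(samples).reset_index(drop=True)
    unit = _check_alignment(stream, schedule)
    rows, cols = schedule.grid_shape
    ee = np.full((rows, cols), np.nan)
    ie = np.full((rows, cols), np.nan)
    t_mid = np.full((rows, cols), np.nan)
    for seg, sl in _segment_slices(schedule, unit):
        part = stream.iloc[sl]
        r, c = seg.grid_index
        ee[r, c] = float(part["ee"].mean())
        ie[r, c] = float(part["ie"].mean())
        t_mid[r, c] = float(part["t"].mean())
    phi_r, phi_p, _, ok = pvoh.invert_stream(ee, ie, calib)
    hct = pvoh.hematocrit_arrays(phi_r, phi_p)
    x0 = np.array(sorted({s.start_xy[0] for s in schedule.segments}))
    y0 = np.array(sorted({s.start_xy[1] for s in schedule.segments}))
    return ImageGrid(hct=hct, ee=ee, ie=ie, in_range=ok, x_mm=x0, y_mm=y0,
                     t_mid=t_mid, calib_hash=_calib_hash(calib))


def image_stats(images) -> tuple[np.ndarray, np.ndarray]:
    """Element-wise mean and sample std (ddof=1) over an image sequence."""
    imgs = [im.hct if isinstance(im, ImageGrid) else np.asarray(im, float)
            for im in images]
    if len(imgs) < 2:
        raise InvalidInputError("need >= 2 images")
    shape = imgs[0].shape
    if any(im.shape != shape for im in imgs):
        raise InvalidInputError("image shapes differ")
    stack = np.stack(imgs)
    return stack.mean(axis=0), stack.std(axis=0, ddof=1)
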