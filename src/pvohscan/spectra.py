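"""Spectral-frame handling: Raman-shift axis, band integration, averaging.

A CCD exposure is a :class:`SpectralFrame` (counts on a monotone wavenumber
axis).  Each frame is reduced to one :class:`EmissionSample` by integrating
two bands: the elastic emission (EE, −30..+10 cm⁻¹ around the laser line) and
the inelastic emission (IE, ≈500..1750 cm⁻¹, fluorescence plus Raman).
Sequences of emission samples are represented as pandas DataFrames with
columns ``t, ee, ie, n_frames`` ("streams") throughout the package.

Band endpoints are closed intervals: a channel belongs to a band iff its
center shift lies in [lo, hi].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyBandError, InvalidInputError

logger = logging.getLogger(__name__)

#: default CCD exposure, s (20 ms frames sampled at 50 Hz)
DEFAULT_EXPOSURE_S = 0.020
DEFAULT_FRAME_RATE_HZ = 50.0

STREAM_COLUMNS = ("t", "ee", "ie", "n_frames")


def raman_shift(lambda_nm, laser_nm: float = 830.0):
    """Raman shift Δν = 10⁷/λ₀ − 10⁷/λ in cm⁻¹ for wavelengths in nm.

    Emission blue of the laser line (λ < λ₀, anti-Stokes) comes out
    negative.  Accepts scalars or arrays.
    """
    lam = np.asarray(lambda_nm, dtype=float)
    if np.any(lam <= 0) or laser_nm <= 0:
        raise InvalidInputError("wavelengths must be positive")
    out = 1e7 / laser_nm - 1e7 / lam
    return float(out) if np.isscalar(lambda_nm) else out


@dataclass(frozen=True)
class SpectralFrame:
    """One CCD exposure: counts vs. Raman shift at time ``t``."""

    shift_axis: np.ndarray  # cm⁻¹, strictly increasing
    counts: np.ndarray      # nonnegative, same length
    t: float = 0.0          # s from stream start
    exposure: float = DEFAULT_EXPOSURE_S

    def __post_init__(self):
        axis = np.asarray(self.shift_axis, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "shift_axis", axis)
        object.__setattr__(self, "counts", counts)
        if axis.ndim != 1 or axis.size < 2 or counts.shape != axis.shape:
            raise InvalidInputError(
                "shift_axis and counts must be 1-D, equal length >= 2"
            )
        if not np.all(np.diff(axis) > 0):
            raise InvalidInputError("shift_axis must be strictly increasing")
        if np.any(counts < 0):
            raise InvalidInputError("counts must be nonnegative")
        if self.exposure <= 0:
            raise InvalidInputError("exposure must be positive")


@dataclass(frozen=True)
class BandWindows:
    """Closed EE/IE integration windows on the Raman-shift axis (cm⁻¹)."""

    ee_lo: float = -30.0
    ee_hi: float = 10.0
    ie_lo: float = 500.0
    ie_hi: float = 1750.0

    def __post_init__(self):
        if not (self.ee_lo < self.ee_hi and self.ie_lo < self.ie_hi):
            raise InvalidInputError("band windows must have lo < hi")
        # overlap check on closed intervals
        if self.ee_hi >= self.ie_lo and self.ie_hi >= self.ee_lo:
            if max(self.ee_lo, self.ie_lo) <= min(self.ee_hi, self.ie_hi):
                raise InvalidInputError("EE and IE windows must not overlap")


@dataclass(frozen=True)
class EmissionSample:
    """Band-integrated emissions from one (or several averaged) frames."""

    ee: float
    ie: float
    t: float = 0.0
    n_frames: int = 1

    def __post_init__(self):
        if self.ee < 0 or self.ie < 0:
            raise InvalidInputError("emissions must be nonnegative")
        if self.n_frames < 1:
            raise InvalidInputError("n_frames must be >= 1")


def integrate_bands(frame: SpectralFrame, windows: BandWindows | None = None) -> EmissionSample:
    """Sum counts over the EE and IE windows of one frame.

    Raises :class:`EmptyBandError` if either window lies entirely outside the
    axis range (no channel could ever fall in it).
    """
    windows = windows or BandWindows()
    axis = frame.shift_axis
    lo, hi = axis[0], axis[-1]
    for name, (wlo, whi) in (("EE", (windows.ee_lo, windows.ee_hi)),
                             ("IE", (windows.ie_lo, windows.ie_hi))):
        if whi < lo or wlo > hi:
            raise EmptyBandError(f"{name} window [{wlo}, {whi}] outside axis [{lo}, {hi}]")
    ee_mask = (axis >= windows.ee_lo) & (axis <= windows.ee_hi)
    ie_mask = (axis >= windows.ie_lo) & (axis <= windows.ie_hi)
    return EmissionSample(
        ee=float(frame.counts[ee_mask].sum()),
        ie=float(frame.counts[ie_mask].sum()),
        t=frame.t,
        n_frames=1,
    )


def samples_to_stream(samples: Sequence[EmissionSample]) -> pd.DataFrame:
    """Pack EmissionSamples into the canonical stream DataFrame."""
    if len(samples) == 0:
        raise InvalidInputError("empty sample sequence")
    return pd.DataFrame(
        {
            "t": [s.t for s in samples],
            "ee": [s.ee for s in samples],
            "ie": [s.ie for s in samples],
            "n_frames": [s.n_frames for s in samples],
        }
    )


def _as_stream(samples) -> pd.DataFrame:
    if isinstance(samples, pd.DataFrame):
        missing = set(STREAM_COLUMNS) - set(samples.columns)
        if missing:
            raise InvalidInputError(f"stream missing columns {sorted(missing)}")
        return samples
    return samples_to_stream(list(samples))


def average_blocks(samples, block_size: int) -> pd.DataFrame:
    """Average consecutive non-overlapping blocks of emission samples.

    Within a block ``ee`` and ``ie`` are arithmetic means, ``t`` is the block
    midpoint (mean of the member times) and ``n_frames`` is summed.  A
    trailing partial block is dropped when shorter than ``block_size / 2``
    and averaged otherwise (logged either way).
    """
    if block_size < 1:
        raise InvalidInputError("block_size must be >= 1")
    stream = _as_stream(samples)
    n = len(stream)
    if n == 0:
        raise InvalidInputError("empty sample sequence")
    if block_size == 1:
        return stream.reset_index(drop=True).copy()

    n_full = n // block_size
    rem = n - n_full * block_size
    keep_partial = rem >= block_size / 2
    if rem:
        logger.info(
            "average_blocks: trailing partial block of %d/%d frames %s",
            rem, block_size, "averaged" if keep_partial else "dropped",
        )
    groups = np.arange(n) // block_size
    if not keep_partial and rem:
        stream = stream.iloc[: n_full * block_size]
        groups = groups[: n_full * block_size]
    if len(stream) == 0:
        raise InvalidInputError("no complete block in input")
    agg = stream.groupby(groups).agg(
        t=("t", "mean"), ee=("ee", "mean"), ie=("ie", "mean"), n_frames=("n_frames", "sum")
    )
    return agg.reset_index(drop=True)


def smooth_adjacent(series, width: int = 25) -> np.ndarray:
    """Centered adjacent-average smoothing of odd ``width``.

    Output length equals input length; near the edges the window shrinks
    symmetrically to the available points, so a constant series is returned
    unchanged and no padding values are invented.
    """
    if width < 1 or width % 2 == 0:
        raise InvalidInputError("width must be odd and >= 1")
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise InvalidInputError("series must be 1-D and nonempty")
    if width == 1:
        return x.copy()
    half = width // 2
    n = x.size
    out = np.empty(n)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return out


# ---------------------------------------------------------------------------
# file I/O

def read_frames(path: str | Path, frame_rate: float = DEFAULT_FRAME_RATE_HZ,
                exposure: float = DEFAULT_EXPOSURE_S) -> list[SpectralFrame]:
    """Read a delimited frame-stream file (auto-detected dialect).

    Two dialects are accepted:

    * long — columns ``frame_index, shift, counts`` (any delimiter pandas
      sniffs from ``.csv``/``.tsv`` suffix);
    * wide — a header row of numeric shift values, one row per frame, with an
      optional leading ``t`` column of timestamps.

    Timestamps absent from the file are synthesized as
    ``frame_index / frame_rate``.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    cols = [str(c).strip().lower() for c in df.columns]
    if {"frame_index", "shift", "counts"} <= set(cols):
        df.columns = cols
        frames = []
        for idx, grp in df.groupby("frame_index", sort=True):
            grp = grp.sort_values("shift")
            frames.append(SpectralFrame(
                shift_axis=grp["shift"].to_numpy(),
                counts=grp["counts"].to_numpy(),
                t=float(idx) / frame_rate,
                exposure=exposure,
            ))
        return frames
    # wide dialect: numeric headers are the shift axis
    t_col = None
    if cols and cols[0] in {"t", "time", "time_s"}:
        t_col = df.columns[0]
    shift_cols = [c for c in df.columns if c != t_col]
    try:
        axis = np.array([float(c) for c in shift_cols])
    except ValueError as exc:
        raise InvalidInputError(
            f"{path}: unrecognized frame-stream dialect (headers {list(df.columns)[:5]}...)"
        ) from exc
    order = np.argsort(axis)
    axis = axis[order]
    mat = df[shift_cols].to_numpy(dtype=float)[:, order]
    times = (df[t_col].to_numpy(dtype=float) if t_col is not None
             else np.arange(len(df)) / frame_rate)
    return [SpectralFrame(axis, row, t=float(tt), exposure=exposure)
            for row, tt in zip(mat, times)]


def integrate_stream(frames: Sequence[SpectralFrame],
                     windows: BandWindows | None = None) -> pd.DataFrame:
    """Integrate a sequence of frames into an emission stream DataFrame."""
    return samples_to_stream([integrate_bands(f, windows) for f in frames])


def write_stream(stream: pd.DataFrame, path: str | Path) -> None:
    _as_stream(stream).to_csv(path, index=False, columns=list(STREAM_COLUMNS))


def read_stream(path: str | Path) -> pd.DataFrame:
    return _as_stream(pd.read_csv(path))
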