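"""Reading and writing the package's on-disk formats.

Waveforms travel as two-column CSV (``time_s,speed_um_per_s``); videos as
multi-page TIFF stacks or globs of numbered single-frame PNG/TIFF files
(lexicographic order = time order). RGB frames are converted to grayscale
by channel averaging.
"""

from __future__ import annotations

import glob
import os

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .motiontrack import FrameSequence, MotionWaveform

__all__ = [
    "read_waveform_csv",
    "write_waveform_csv",
    "load_frame_sequence",
]

WAVEFORM_COLUMNS = ("time_s", "speed_um_per_s")


def write_waveform_csv(w: MotionWaveform, path: str | os.PathLike) -> None:
    pd.DataFrame({WAVEFORM_COLUMNS[0]: w.t, WAVEFORM_COLUMNS[1]: w.S}).to_csv(
        path, index=False
    )


def read_waveform_csv(path: str | os.PathLike, meta: dict | None = None) -> MotionWaveform:
    df = pd.read_csv(path)
    for col in WAVEFORM_COLUMNS:
        if col not in df.columns:
            raise InvalidInputError(f"waveform CSV {path} lacks required column {col!r}")
    t = df[WAVEFORM_COLUMNS[0]].to_numpy(dtype=float)
    S = df[WAVEFORM_COLUMNS[1]].to_numpy(dtype=float)
    if t.size < 2:
        raise InvalidInputError("waveform CSV needs at least 2 rows")
    dt = np.diff(t)
    if dt.min() <= 0 or (dt.max() - dt.min()) > 1e-6 * dt.mean() + 1e-12:
        raise InvalidInputError("waveform CSV time grid is not uniform")
    fps = 1.0 / float(np.mean(dt))
    info = {"source": str(path)}
    if meta:
        info.update(meta)
    return MotionWaveform(t=t, S=S, fps=fps, meta=info)


def _to_gray(a: np.ndarray) -> np.ndarray:
    if a.ndim == 3 and a.shape[-1] in (3, 4):
        return a[..., :3].mean(axis=-1)
    if a.ndim == 2:
        return a
    raise InvalidInputError(f"cannot interpret frame of shape {a.shape} as grayscale")


def load_frame_sequence(
    path_or_glob: str, fps: float, um_per_px: float
) -> FrameSequence:
    """Load a multi-page TIFF stack or a glob of numbered frame files."""
    if any(ch in path_or_glob for ch in "*?["):
        paths = sorted(glob.glob(path_or_glob))
        if len(paths) < 2:
            raise InvalidInputError(f"glob {path_or_glob!r} matched {len(paths)} files")
        import imageio.v3 as iio

        frames = np.stack([_to_gray(np.asarray(iio.imread(p))) for p in paths])
    else:
        if not os.path.exists(path_or_glob):
            raise InvalidInputError(f"no such file: {path_or_glob}")
        import tifffile

        stack = np.asarray(tifffile.imread(path_or_glob))
        if stack.ndim == 2:
            raise InvalidInputError("TIFF contains a single frame; need a stack")
        if stack.ndim == 4:  # (n, H, W, C)
            stack = stack[..., :3].mean(axis=-1)
        frames = stack
    return FrameSequence(frames=frames, fps=fps, um_per_px=um_per_px)
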