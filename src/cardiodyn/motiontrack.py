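"""Block-matching motion tracking.

Converts an image sequence into per-frame-pair displacement-vector fields by
exhaustive block matching (sum of absolute differences), and collapses the
fields into a scalar contraction-motion waveform (mean block speed, µm/s).

Conventions
-----------
* Coordinates are (row, col) = (y, x), origin top-left, 0-based.
* A displacement (dy, dx) means the block content of frame k is found at
  position + (dy, dx) in frame k+1.
* The macroblock grid covers ``floor(H / block_size) x floor(W / block_size)``
  blocks; trailing pixels that do not fill a block are ignored.
* Candidate displacements whose target window exits the frame are skipped
  (search clipped to the valid region), so border blocks choose among the
  remaining candidates.
* Ties in SAD are broken by smallest displacement magnitude, then by
  row-major scan order of the search window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "FrameSequence",
    "MotionField",
    "MotionWaveform",
    "compute_motion_fields",
    "fields_to_waveform",
    "track",
]


@dataclass
class FrameSequence:
    """An ordered stack of equally shaped grayscale frames.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, H, W)
        Grayscale intensities. Any numeric dtype.
    fps : float
        Acquisition frame rate (frames / second), finite and > 0.
    um_per_px : float
        Physical pixel size (µm / pixel), finite and > 0.
    """

    frames: np.ndarray
    fps: float
    um_per_px: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise InvalidInputError(
                f"frames must be a (n, H, W) stack, got ndim={self.frames.ndim}"
            )
        if self.frames.shape[0] < 2:
            raise InvalidInputError("need at least 2 frames")
        for name, v in (("fps", self.fps), ("um_per_px", self.um_per_px)):
            if not (np.isfinite(v) and v > 0):
                raise InvalidInputError(f"{name} must be finite and > 0, got {v}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class MotionField:
    """Displacement vectors for one consecutive frame pair.

    ``vectors`` has shape (n_blocks_y, n_blocks_x, 2) holding (dy, dx) in
    pixels; magnitudes never exceed ``search_radius``.
    """

    vectors: np.ndarray
    block_size: int
    search_radius: int

    def speeds(self) -> np.ndarray:
        """Per-block displacement magnitude in pixels/frame."""
        return np.hypot(self.vectors[..., 0], self.vectors[..., 1])


@dataclass
class MotionWaveform:
    """Uniformly sampled motion-speed time series.

    ``t`` is in seconds (step 1/fps), ``S`` in µm/s; both length N >= 2.
    ``meta`` records provenance (source video or simulator parameters).
    """

    t: np.ndarray
    S: np.ndarray
    fps: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if self.t.ndim != 1 or self.S.ndim != 1 or self.t.size != self.S.size:
            raise InvalidInputError("t and S must be 1-D arrays of equal length")
        if self.t.size < 2:
            raise InvalidInputError("waveform needs at least 2 samples")
        if not (np.isfinite(self.fps) and self.fps > 0):
            raise InvalidInputError(f"fps must be finite and > 0, got {self.fps}")
        if not np.all(np.isfinite(self.S)):
            raise InvalidInputError("S contains non-finite values")

    @property
    def n(self) -> int:
        return self.S.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fps


def _candidate_displacements(search_radius: int) -> list[tuple[int, int]]:
    # Row-major enumeration, stably sorted by squared magnitude: iterating in
    # this order with a strict "<" update implements the documented
    # tie-breaking (smallest magnitude, then row-major scan order).
    cands = [
        (dy, dx)
        for dy in range(-search_radius, search_radius + 1)
        for dx in range(-search_radius, search_radius + 1)
    ]
    cands.sort(key=lambda c: c[0] * c[0] + c[1] * c[1])
    return cands


def _sad_grid(
    f1: np.ndarray,
    f2: np.ndarray,
    dy: int,
    dx: int,
    block_size: int,
    n_by: int,
    n_bx: int,
) -> np.ndarray:
    """SAD of every macroblock of f1 against f2 shifted by (dy, dx).

    Blocks whose shifted window exits the frame get +inf.
    """
    H, W = f1.shape
    bs = block_size
    r0, r1 = max(0, -dy), min(H, H - dy)
    c0, c1 = max(0, -dx), min(W, W - dx)
    Hc, Wc = n_by * bs, n_bx * bs
    # NaN marks pixels without a valid shifted counterpart; any NaN inside a
    # block poisons its sum, which then becomes +inf.
    D = np.full((Hc, Wc), np.nan)
    rr0, rr1 = max(r0, 0), min(r1, Hc)
    cc0, cc1 = max(c0, 0), min(c1, Wc)
    if rr1 > rr0 and cc1 > cc0:
        D[rr0:rr1, cc0:cc1] = np.abs(
            f1[rr0:rr1, cc0:cc1] - f2[rr0 + dy : rr1 + dy, cc0 + dx : cc1 + dx]
        )
    sad = D.reshape(n_by, bs, n_bx, bs).sum(axis=(1, 3))
    return np.where(np.isnan(sad), np.inf, sad)


def _block_sad(
    f1: np.ndarray, f2: np.ndarray, by: int, bx: int, dy: int, dx: int, bs: int
) -> float:
    """SAD for a single block; inf if the shifted window exits the frame."""
    H, W = f1.shape
    y0, x0 = by * bs, bx * bs
    ty0, tx0 = y0 + dy, x0 + dx
    if ty0 < 0 or tx0 < 0 or ty0 + bs > H or tx0 + bs > W:
        return np.inf
    return float(
        np.abs(f1[y0 : y0 + bs, x0 : x0 + bs] - f2[ty0 : ty0 + bs, tx0 : tx0 + bs]).sum()
    )


def _parabolic_offset(s_minus: float, s0: float, s_plus: float) -> float:
    denom = s_minus - 2.0 * s0 + s_plus
    if not np.isfinite(denom) or denom <= 0:
        return 0.0
    off = 0.5 * (s_minus - s_plus) / denom
    return float(np.clip(off, -0.5, 0.5))


def compute_motion_fields(
    seq: FrameSequence,
    block_size: int = 16,
    search_radius: int = 7,
    subpixel: bool = False,
) -> list[MotionField]:
    """Exhaustive block matching between every consecutive frame pair.

    Each macroblock of frame k is matched to the position in frame k+1
    (within ±``search_radius``) minimizing the sum of absolute intensity
    differences. Optional parabolic subpixel refinement interpolates the SAD
    surface around the integer minimum, one axis at a time.

    Returns one :class:`MotionField` per frame pair (n_frames - 1 fields).
    """
    if block_size < 4:
        raise InvalidInputError(f"block_size must be >= 4, got {block_size}")
    if search_radius < 1:
        raise InvalidInputError(f"search_radius must be >= 1, got {search_radius}")
    H, W = seq.frame_shape
    n_by, n_bx = H // block_size, W // block_size
    if n_by < 1 or n_bx < 1:
        raise InvalidInputError(
            f"frames of shape {(H, W)} are smaller than one {block_size}-px block"
        )
    cands = _candidate_displacements(search_radius)
    frames = seq.frames.astype(np.float64, copy=False)
    fields: list[MotionField] = []
    for k in range(seq.n_frames - 1):
        f1, f2 = frames[k], frames[k + 1]
        best = np.full((n_by, n_bx), np.inf)
        vec = np.zeros((n_by, n_bx, 2))
        for dy, dx in cands:
            sad = _sad_grid(f1, f2, dy, dx, block_size, n_by, n_bx)
            upd = sad < best
            if np.any(upd):
                best[upd] = sad[upd]
                vec[upd] = (dy, dx)
        if subpixel:
            for by in range(n_by):
                for bx in range(n_bx):
                    dy, dx = int(vec[by, bx, 0]), int(vec[by, bx, 1])
                    s0 = best[by, bx]
                    if not np.isfinite(s0):
                        continue
                    sy = [_block_sad(f1, f2, by, bx, dy + d, dx, block_size) for d in (-1, 1)]
                    sx = [_block_sad(f1, f2, by, bx, dy, dx + d, block_size) for d in (-1, 1)]
                    if np.isfinite(sy).all():
                        vec[by, bx, 0] += _parabolic_offset(sy[0], s0, sy[1])
                    if np.isfinite(sx).all():
                        vec[by, bx, 1] += _parabolic_offset(sx[0], s0, sx[1])
        fields.append(MotionField(vec, block_size, search_radius))
    return fields


def fields_to_waveform(
    fields: list[MotionField], fps: float, um_per_px: float, meta: Optional[dict] = None
) -> MotionWaveform:
    """Collapse vector fields into a motion-speed waveform.

    ``S[k]`` is the mean over blocks of the displacement magnitude between
    frames k-1 and k, converted to µm/s. The first inter-frame speed is
    duplicated so the waveform has the same length as the video.
    """
    if not fields:
        raise InvalidInputError("empty field list")
    speeds = np.array([f.speeds().mean() for f in fields]) * um_per_px * fps
    S = np.concatenate([[speeds[0]], speeds])
    t = np.arange(S.size) / fps
    info = {
        "source": "motiontrack",
        "block_size": fields[0].block_size,
        "search_radius": fields[0].search_radius,
    }
    if meta:
        info.update(meta)
    return MotionWaveform(t=t, S=S, fps=fps, meta=info)


def track(
    seq: FrameSequence,
    block_size: int = 16,
    search_radius: int = 7,
    subpixel: bool = False,
) -> MotionWaveform:
    """Convenience wrapper: image sequence -> contraction-motion waveform."""
    fields = compute_motion_fields(seq, block_size, search_radius, subpixel)
    return fields_to_waveform(fields, seq.fps, seq.um_per_px)
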