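"""Sparse pixel frames and their plain-text on-disk format.

One file per detector layer.  Layout::

    # layer 3 mode energy
    # frame 0 t0 0.0
    12 200 4593
    13 200 812
    # frame 1 t0 1000.0
    ...

Data lines are ``col row value`` with 0-based indices and integer values:
arrival-time ticks in time mode, energy counts in energy mode.  A frame
header with no data lines is an empty frame.  The format is lossless with
respect to the simulator output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Frame", "FrameParseError", "write_frames", "read_frames"]

COUNTER_MAX_DEFAULT = 11810


class FrameParseError(ValueError):
    """Malformed frame file; carries the offending 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass
class Frame:
    """Hits of one layer during one acquisition frame.

    ``pixels`` maps (col, row) -> integer value; at most one entry per
    pixel.  ``t0_us`` is the frame start time on the run clock.
    """

    layer: int
    index: int
    mode: str
    t0_us: float = 0.0
    pixels: dict = field(default_factory=dict)

    @property
    def n_hits(self) -> int:
        return len(self.pixels)

    def to_arrays(self):
        """(cols, rows, values) as int arrays, insertion-ordered."""
        if not self.pixels:
            z = np.zeros(0, dtype=np.int64)
            return z, z.copy(), z.copy()
        arr = np.array([(c, r, v) for (c, r), v in self.pixels.items()],
                       dtype=np.int64)
        return arr[:, 0], arr[:, 1], arr[:, 2]

    def dense(self, n: int = 256) -> np.ndarray:
        img = np.zeros((n, n), dtype=np.int64)
        for (c, r), v in self.pixels.items():
            img[r, c] = v
        return img


def write_frames(path, frames: list[Frame]) -> None:
    """Write the frames of one layer; all frames must share layer and mode."""
    if not frames:
        raise ValueError("nothing to write")
    layer, mode = frames[0].layer, frames[0].mode
    with open(path, "w") as fh:
        fh.write(f"# layer {layer} mode {mode}\n")
        for fr in frames:
            if (fr.layer, fr.mode) != (layer, mode):
                raise ValueError("mixed layers/modes in one file")
            fh.write(f"# frame {fr.index} t0 {fr.t0_us:.3f}\n")
            for (c, r), v in fr.pixels.items():
                fh.write(f"{c} {r} {int(v)}\n")


def read_frames(path, counter_max: int = COUNTER_MAX_DEFAULT,
                n_pixels: int = 256) -> list[Frame]:
    """Decode a frame file; inverse of :func:`write_frames`.

    Raises :class:`FrameParseError` (with line number) on malformed lines,
    out-of-range pixel indices, or values exceeding the counter range.
    """
    frames: list[Frame] = []
    layer = mode = None
    current: Frame | None = None
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts[:1] == ["layer"]:
                    try:
                        layer, mode = int(parts[1]), parts[3]
                    except (IndexError, ValueError) as exc:
                        raise FrameParseError(f"bad layer header: {line}", ln) from exc
                    if mode not in ("time", "energy"):
                        raise FrameParseError(f"unknown mode {mode!r}", ln)
                elif parts[:1] == ["frame"]:
                    if layer is None:
                        raise FrameParseError("frame header before layer header", ln)
                    try:
                        idx, t0 = int(parts[1]), float(parts[3])
                    except (IndexError, ValueError) as exc:
                        raise FrameParseError(f"bad frame header: {line}", ln) from exc
                    current = Frame(layer=layer, index=idx, mode=mode, t0_us=t0)
                    frames.append(current)
                else:
                    raise FrameParseError(f"unknown header: {line}", ln)
                continue
            if current is None:
                raise FrameParseError("data line outside any frame", ln)
            parts = line.split()
            if len(parts) != 3:
                raise FrameParseError(f"expected 'col row value': {line}", ln)
            try:
                c, r, v = int(parts[0]), int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FrameParseError(f"non-integer field: {line}", ln) from exc
            if not (0 <= c < n_pixels and 0 <= r < n_pixels):
                raise FrameParseError(f"pixel ({c}, {r}) out of range", ln)
            if v < 1:
                raise FrameParseError(f"value {v} below 1", ln)
            if v > counter_max:
                raise FrameParseError(
                    f"value {v} exceeds counter range {counter_max}", ln)
            current.pixels[(c, r)] = v
    return frames
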