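"""File I/O: TPS landmark files, long-form landmark CSV, TIFF stacks.

The TPS dialect used here writes one record per frame::

    LM=63
    x y          (63 lines, space-separated, decimal point)
    IMAGE=<subject>_cycle<cycle>_frame<frame>
    ID=<int>
    SCALE=<float>     (optional)

The long-form CSV has columns subject, cycle, frame, line (culmen /
tomium / ventrum), landmark_index (1-21), x, y.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile

from .morphometry import (
    FrameConfiguration,
    LINE_NAMES,
    LINE_SLICES,
    N_LANDMARKS,
    N_PER_LINE,
)


class TPSFormatError(ValueError):
    """Malformed TPS record; the message carries the offending line number."""


_IMAGE_RE = re.compile(r"^(?P<subject>.+)_cycle(?P<cycle>\d+)_frame(?P<frame>\d+)$")


def write_tps(path, frames: Iterable[FrameConfiguration],
              scale: float | None = None) -> None:
    lines = []
    for i, fr in enumerate(frames):
        lines.append(f"LM={fr.landmarks.shape[0]}")
        for x, y in fr.landmarks:
            lines.append(f"{x:.8f} {y:.8f}")
        lines.append(f"IMAGE={fr.subject_id}_cycle{int(fr.cycle_id):02d}"
                     f"_frame{int(fr.frame_index):02d}")
        lines.append(f"ID={i}")
        if scale is not None:
            lines.append(f"SCALE={scale}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_tps(path) -> list[FrameConfiguration]:
    text = Path(path).read_text().splitlines()
    frames: list[FrameConfiguration] = []
    i = 0
    n_lines = len(text)
    while i < n_lines:
        line = text[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise TPSFormatError(f"line {i + 1}: expected LM=, got {line!r}")
        try:
            lm_count = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TPSFormatError(f"line {i + 1}: bad LM count") from exc
        i += 1
        coords = []
        for _ in range(lm_count):
            if i >= n_lines:
                raise TPSFormatError(f"line {i + 1}: truncated record")
            parts = text[i].split()
            if len(parts) != 2:
                raise TPSFormatError(
                    f"line {i + 1}: expected 'x y', got {text[i]!r}"
                )
            try:
                coords.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise TPSFormatError(
                    f"line {i + 1}: non-numeric coordinate"
                ) from exc
            i += 1
        subject, cycle, frame = "subject", 0, 0
        scale = None
        while i < n_lines and "=" in text[i] and not text[i].upper().startswith("LM="):
            key, val = text[i].split("=", 1)
            key = key.strip().upper()
            if key == "IMAGE":
                m = _IMAGE_RE.match(val.strip())
                if m:
                    subject = m.group("subject")
                    cycle = int(m.group("cycle"))
                    frame = int(m.group("frame"))
                else:
                    subject = val.strip()
            elif key == "SCALE":
                try:
                    scale = float(val)
                except ValueError as exc:
                    raise TPSFormatError(f"line {i + 1}: bad SCALE") from exc
            i += 1
        arr = np.asarray(coords, dtype=float)
        if scale is not None:
            arr = arr * scale
        frames.append(FrameConfiguration(arr, frame, cycle, subject))
    return frames


def frames_to_dataframe(frames: Iterable[FrameConfiguration]) -> pd.DataFrame:
    rows = []
    for fr in frames:
        for name in LINE_NAMES:
            pts = fr.line(name)
            for j, (x, y) in enumerate(pts, start=1):
                rows.append(
                    {
                        "subject": fr.subject_id,
                        "cycle": fr.cycle_id,
                        "frame": fr.frame_index,
                        "line": name,
                        "landmark_index": j,
                        "x": x,
                        "y": y,
                    }
                )
    return pd.DataFrame(rows)


def dataframe_to_frames(df: pd.DataFrame) -> list[FrameConfiguration]:
    frames = []
    for (subject, cycle, frame), grp in df.groupby(
        ["subject", "cycle", "frame"], sort=True
    ):
        lm = np.full((N_LANDMARKS, 2), np.nan)
        for name in LINE_NAMES:
            sub = grp[grp["line"] == name].sort_values("landmark_index")
            if len(sub) != N_PER_LINE:
                raise ValueError(
                    f"{subject}/cycle{cycle}/frame{frame}: line {name} has "
                    f"{len(sub)} landmarks, expected {N_PER_LINE}"
                )
            lm[LINE_SLICES[name]] = sub[["x", "y"]].to_numpy()
        frames.append(FrameConfiguration(lm, int(frame), cycle, str(subject)))
    return frames


def write_landmarks_csv(path, frames: Iterable[FrameConfiguration]) -> None:
    frames_to_dataframe(frames).to_csv(path, index=False)


def read_landmarks_csv(path) -> list[FrameConfiguration]:
    return dataframe_to_frames(pd.read_csv(path, comment="#"))


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

def write_stack_tiff(path, stack: np.ndarray) -> None:
    """Grayscale multi-page TIFF, 16-bit."""
    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint16),
                     photometric="minisblack")


def write_mask_tiff(path, mask: np.ndarray) -> None:
    """ROI mask multi-page TIFF, 8-bit."""
    tifffile.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8),
                     photometric="minisblack")


def read_stack_tiff(path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return arr
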