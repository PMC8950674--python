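"""Video and frame I/O plus colour-space helpers.

A well-scan recording is held in memory as a :class:`VideoClip` — an ordered
stack of frames with a known frame rate.  Downstream analysis works on the
HSL *lightness* channel, the achromatic intensity used to segment the cell
layer, so this module also owns the RGB/GRAY -> lightness conversion.

Multi-page TIFF is the lossless container used for fixtures and round-trip
tests (the frame rate travels in the ImageDescription tag as JSON).  Other
containers (AVI/MP4) are delegated to whatever imageio backend is present.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "VideoClip",
    "Frame",
    "DegenerateInputError",
    "read_video",
    "write_video",
    "to_lightness",
    "export_frame_png",
]


class DegenerateInputError(ValueError):
    """Input violates a structural precondition (e.g. a 1-frame video)."""


@dataclass
class VideoClip:
    """An ordered stack of frames with a frame rate.

    ``frames`` has shape (T, H, W) for grayscale or (T, H, W, 3) for colour,
    dtype uint8.  At least two frames are required: a single frame carries no
    motion information.
    """

    frames: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise DegenerateInputError(
                f"frames must be (T,H,W) or (T,H,W,3), got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise DegenerateInputError(
                f"a video needs at least 2 frames, got {self.frames.shape[0]}"
            )
        if self.frame_rate <= 0:
            raise ValueError(f"frame_rate must be positive, got {self.frame_rate}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def duration(self) -> float:
        """Recording length in seconds (span from first to last frame time)."""
        return (self.n_frames - 1) / self.frame_rate

    @property
    def is_color(self) -> bool:
        return self.frames.ndim == 4

    def gray_frames(self) -> np.ndarray:
        """Float32 grayscale stack in [0, 255], averaging channels if colour."""
        if self.is_color:
            return self.frames.astype(np.float32).mean(axis=-1)
        return self.frames.astype(np.float32)


@dataclass
class Frame:
    """A single raster with an explicit colour space.

    ``color_space`` is one of ``RGB`` (H,W,3 uint8), ``GRAY`` (H,W uint8) or
    ``HSL`` (here: the lightness channel alone, H,W float in [0,1]).
    """

    pixels: np.ndarray
    color_space: str = "GRAY"

    VALID: tuple = field(default=("RGB", "GRAY", "HSL"), init=False, repr=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.color_space not in ("RGB", "GRAY", "HSL"):
            raise ValueError(f"unknown color_space {self.color_space!r}")
        if self.color_space == "RGB" and (self.pixels.ndim != 3 or self.pixels.shape[-1] != 3):
            raise ValueError("RGB frame must have shape (H, W, 3)")
        if self.color_space in ("GRAY", "HSL") and self.pixels.ndim != 2:
            raise ValueError("GRAY/HSL frame must have shape (H, W)")


def to_lightness(frame: Frame | np.ndarray) -> Frame:
    """Convert a frame to the HSL lightness channel, scaled to [0, 1].

    For RGB input, lightness is the mean of the per-pixel channel extremes,
    L = (max(R,G,B) + min(R,G,B)) / 2, normalised by 255.  Grayscale input
    maps to intensity/255.  HSL input is returned unchanged (idempotent).
    """
    if isinstance(frame, np.ndarray):
        frame = Frame(frame, "RGB" if frame.ndim == 3 else "GRAY")
    if frame.color_space == "HSL":
        logger.debug("to_lightness called on HSL input; identity")
        return frame
    px = frame.pixels.astype(np.float64)
    if frame.color_space == "RGB":
        light = (px.max(axis=-1) + px.min(axis=-1)) / 2.0 / 255.0
    else:
        light = px / 255.0
    return Frame(light, "HSL")


_TIFF_EXT = {".tif", ".tiff"}


def read_video(path: str | Path, frame_rate: float | None = None) -> VideoClip:
    """Read a video file into a :class:`VideoClip`.

    Multi-page TIFF is read natively (frame rate recovered from the
    ImageDescription metadata written by :func:`write_video`, or taken from
    the ``frame_rate`` argument).  Other containers go through imageio and
    require an ffmpeg-capable backend.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"video file not found: {path}")
    if path.suffix.lower() in _TIFF_EXT:
        frames, fps = _read_tiff(path)
    else:
        frames, fps = _read_imageio(path)
    if frame_rate is not None:
        fps = frame_rate
    if fps is None:
        raise IOError(
            f"no frame rate in container metadata for {path}; pass frame_rate="
        )
    if frames.shape[0] < 2:
        raise DegenerateInputError(f"{path} holds {frames.shape[0]} frame(s); need >= 2")
    return VideoClip(frames=frames, frame_rate=float(fps))


def _read_tiff(path: Path) -> tuple[np.ndarray, float | None]:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        frames = tf.asarray()
        fps = None
        desc = tf.pages[0].tags.get("ImageDescription")
        if desc is not None:
            try:
                meta = json.loads(desc.value)
                fps = float(meta["frame_rate"])
            except (json.JSONDecodeError, KeyError, TypeError):
                fps = None
    if frames.ndim == 2:
        frames = frames[None]
    return frames, fps


def _read_imageio(path: Path) -> tuple[np.ndarray, float | None]:
    import imageio.v3 as iio

    try:
        frames = iio.imread(path, index=None)
        meta = iio.immeta(path)
    except Exception as exc:  # no ffmpeg plugin, corrupt file, ...
        raise IOError(f"could not decode {path}: {exc}") from exc
    fps = meta.get("fps")
    return np.asarray(frames), fps


def write_video(clip: VideoClip, path: str | Path) -> Path:
    """Write a clip losslessly.  TIFF targets are written natively."""
    path = Path(path)
    if path.suffix.lower() in _TIFF_EXT:
        import tifffile

        desc = json.dumps({"frame_rate": clip.frame_rate})
        photometric = "rgb" if clip.is_color else "minisblack"
        tifffile.imwrite(path, clip.frames, description=desc, photometric=photometric)
        return path
    import imageio.v3 as iio

    try:
        iio.imwrite(path, clip.frames, fps=clip.frame_rate)
    except Exception as exc:
        raise IOError(
            f"could not encode {path} (is an ffmpeg backend installed?): {exc}"
        ) from exc
    return path


def export_frame_png(frame: Frame | np.ndarray, path: str | Path) -> Path:
    """Export a single frame as PNG (lightness frames are scaled to 0-255)."""
    import imageio.v3 as iio

    if isinstance(frame, Frame):
        px = frame.pixels
        if frame.color_space == "HSL":
            px = np.clip(px * 255.0, 0, 255).astype(np.uint8)
    else:
        px = frame
    iio.imwrite(Path(path), np.asarray(px).astype(np.uint8))
    return Path(path)
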