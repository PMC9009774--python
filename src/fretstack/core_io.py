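"""Reading, writing and configuration for FRET stack processing.

Image data move through the pipeline as :class:`ImageStack` objects: an
ordered set of 2-D grayscale frames from one fluorescence channel, together
with the acquisition bit depth and the original frame indices.  Frame
selection may be discontinuous — a stack read with ``frame_ranges`` keeps
the source indices in ``frame_ids`` so that per-range parameters and the
photobleaching time axis stay anchored to the original acquisition.

Frame indices are 1-based in configuration files (microscopy convention)
and 0-based everywhere in code; :func:`parse_config` is the boundary.
"""

from __future__ import annotations

import configparser
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile

VALID_BIT_DEPTHS = (8, 12, 16)


class StackError(ValueError):
    """Raised for malformed stacks or invalid frame selections."""


class ConfigError(ValueError):
    """Raised for unparseable or inconsistent run configurations."""


def _container_dtype(bit_depth: int) -> np.dtype:
    # 12-bit data has no native TIFF container; it travels in uint16.
    return np.dtype(np.uint8 if bit_depth == 8 else np.uint16)


@dataclass
class ImageStack:
    """Frames of one fluorescence channel plus indexing metadata.

    Parameters
    ----------
    frames : numpy.ndarray
        Array of shape ``(n_frames, height, width)`` with unsigned integer
        pixel counts.
    bit_depth : int
        Acquisition bit depth, one of 8, 12, 16.  Pixel values must lie in
        ``[0, 2**bit_depth - 1]`` even when the container dtype is wider.
    frame_ids : numpy.ndarray
        Strictly increasing original frame indices (0-based), one per frame.
    channel_label : str
        Free text, conventionally ``"donor"`` or ``"acceptor"``.
    """

    frames: np.ndarray
    bit_depth: int
    frame_ids: np.ndarray
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.frame_ids = np.asarray(self.frame_ids, dtype=np.int64)
        if self.frames.ndim != 3:
            raise StackError(f"frames must be 3-D (n, h, w), got shape {self.frames.shape}")
        if self.frames.shape[0] == 0:
            raise StackError("empty stack: at least one frame required")
        if self.bit_depth not in VALID_BIT_DEPTHS:
            raise StackError(f"bit_depth must be one of {VALID_BIT_DEPTHS}, got {self.bit_depth}")
        if len(self.frame_ids) != self.frames.shape[0]:
            raise StackError("frame_ids length must equal number of frames")
        if len(self.frame_ids) > 1 and not np.all(np.diff(self.frame_ids) > 0):
            raise StackError("frame_ids must be strictly increasing")
        if self.frames.max() > self.max_value:
            raise StackError(
                f"pixel value {self.frames.max()} exceeds {self.max_value} "
                f"for bit depth {self.bit_depth}"
            )

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def with_frames(self, frames: np.ndarray) -> "ImageStack":
        """Copy of this stack with the pixel data replaced."""
        return ImageStack(frames, self.bit_depth, self.frame_ids.copy(), self.channel_label)


@dataclass
class FrameRange:
    """Inclusive 0-based frame interval with its clustering radius."""

    start: int
    stop: int
    eps: float

    def __post_init__(self) -> None:
        if self.start > self.stop:
            raise ConfigError(f"frame range start {self.start} > stop {self.stop}")
        if self.eps <= 0:
            raise ConfigError(f"eps must be positive, got {self.eps}")

    def __contains__(self, frame_id: int) -> bool:
        return self.start <= frame_id <= self.stop


@dataclass
class RunConfig:
    """Parsed run configuration (all frame indices 0-based)."""

    donor_path: str | None = None
    acceptor_path: str | None = None
    output_dir: str = "."
    bit_depth_override: int | None = None
    modules_enabled: tuple[str, ...] = ("background",)
    # background
    window: int = 40
    eps: float = 1.5
    frame_ranges: list[FrameRange] = field(default_factory=list)
    min_samples: int = 5
    # ratio
    registration_enabled: bool = True
    register_per_frame: bool = False
    bilateral_sigma_space: float = 2.0
    bilateral_sigma_range_frac: float = 0.05
    boundary_area_frac: float = 0.01
    rescale_percentiles: tuple[float, float] = (10.0, 90.0)
    # bleach
    bleach_model: str = "exponential"
    bleach_fit_range: tuple[int, int] | None = None
    bleach_channels: tuple[str, ...] = ("donor", "acceptor")
    ridge_lambda: float = 0.0
    n_jobs: int = 1

    def __post_init__(self) -> None:
        for m in self.modules_enabled:
            if m not in ("background", "ratio", "bleach"):
                raise ConfigError(f"unknown module {m!r}")
        if self.bleach_model not in ("linear", "exponential"):
            raise ConfigError(f"bleach_model must be linear|exponential, got {self.bleach_model!r}")
        for ch in self.bleach_channels:
            if ch not in ("donor", "acceptor"):
                raise ConfigError(f"bleach channel must be donor|acceptor, got {ch!r}")
        self._check_ranges()
        if "bleach" in self.modules_enabled and self.bleach_fit_range is not None and self.frame_ranges:
            lo, hi = self.bleach_fit_range
            covered = set()
            for fr in self.frame_ranges:
                covered.update(range(fr.start, fr.stop + 1))
            if not set(range(lo, hi + 1)) <= covered:
                raise ConfigError("bleach_fit_range must lie within the processed frame ranges")

    def _check_ranges(self) -> None:
        spans = sorted((fr.start, fr.stop) for fr in self.frame_ranges)
        for (s0, e0), (s1, _) in zip(spans, spans[1:]):
            if s1 <= e0:
                raise ConfigError(f"overlapping frame ranges: {s0}-{e0} and {s1}-...")

    def eps_for_frame(self, frame_id: int) -> float:
        """Clustering radius applied to ``frame_id`` (per-range override or global)."""
        for fr in self.frame_ranges:
            if frame_id in fr:
                return fr.eps
        return self.eps

    def selected_intervals(self) -> list[tuple[int, int]] | None:
        """0-based inclusive intervals to read, or None for the whole stack."""
        if not self.frame_ranges:
            return None
        return [(fr.start, fr.stop) for fr in sorted(self.frame_ranges, key=lambda f: f.start)]

    def snapshot(self) -> str:
        """JSON snapshot of the configuration, for HDF5 attributes and manifests."""
        d = dataclasses.asdict(self)
        return json.dumps(d, sort_keys=True, default=str)


def _parse_ranges(text: str) -> list[FrameRange]:
    """Parse ``"1-50:0.6, 51-100:0.9"`` (1-based, inclusive) into FrameRanges."""
    out = []
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        try:
            span, eps_s = part.split(":")
            lo_s, hi_s = span.split("-")
            lo, hi, eps = int(lo_s), int(hi_s), float(eps_s)
        except ValueError as exc:
            raise ConfigError(f"cannot parse range entry {part!r} (expected LO-HI:EPS)") from exc
        if lo < 1:
            raise ConfigError(f"config frame indices are 1-based; got {lo}")
        out.append(FrameRange(lo - 1, hi - 1, eps))
    return out


def parse_config(path: str | Path) -> RunConfig:
    """Read an INI run configuration.

    Sections ``[input]``, ``[run]``, ``[background]``, ``[ratio]``, ``[bleach]``
    are all optional; missing keys take the defaults of :class:`RunConfig`.
    Frame indices in the file are 1-based and converted here.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    cp = configparser.ConfigParser()
    try:
        cp.read(path)
    except configparser.Error as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc

    kw: dict = {}
    if cp.has_section("input"):
        s = cp["input"]
        kw["donor_path"] = s.get("donor", None)
        kw["acceptor_path"] = s.get("acceptor", None)
        if "bit_depth" in s:
            kw["bit_depth_override"] = s.getint("bit_depth")
        if "output_dir" in s:
            kw["output_dir"] = s.get("output_dir")
    if cp.has_section("run"):
        s = cp["run"]
        if "modules" in s:
            kw["modules_enabled"] = tuple(m.strip() for m in s.get("modules").split(",") if m.strip())
        if "jobs" in s:
            kw["n_jobs"] = s.getint("jobs")
    if cp.has_section("background"):
        s = cp["background"]
        if "window" in s:
            kw["window"] = s.getint("window")
        if "eps" in s:
            kw["eps"] = s.getfloat("eps")
        if "ranges" in s:
            kw["frame_ranges"] = _parse_ranges(s.get("ranges"))
        if "min_samples" in s:
            kw["min_samples"] = s.getint("min_samples")
    if cp.has_section("ratio"):
        s = cp["ratio"]
        if "register" in s:
            kw["registration_enabled"] = s.getboolean("register")
        if "register_per_frame" in s:
            kw["register_per_frame"] = s.getboolean("register_per_frame")
        if "bilateral_sigma_space" in s:
            kw["bilateral_sigma_space"] = s.getfloat("bilateral_sigma_space")
        if "bilateral_sigma_range" in s:
            kw["bilateral_sigma_range_frac"] = s.getfloat("bilateral_sigma_range")
        if "boundary_area_frac" in s:
            kw["boundary_area_frac"] = s.getfloat("boundary_area_frac")
        if "rescale_percentiles" in s:
            lo, hi = (float(v) for v in s.get("rescale_percentiles").split(","))
            kw["rescale_percentiles"] = (lo, hi)
    if cp.has_section("bleach"):
        s = cp["bleach"]
        if "bleach_model" in s:
            kw["bleach_model"] = s.get("bleach_model").strip()
        if "bleach_range" in s:
            span = s.get("bleach_range").strip()
            try:
                lo, hi = (int(v) for v in span.split("-"))
            except ValueError as exc:
                raise ConfigError(f"cannot parse bleach_range {span!r}") from exc
            if lo < 1:
                raise ConfigError("config frame indices are 1-based")
            kw["bleach_fit_range"] = (lo - 1, hi - 1)
        if "bleach_channels" in s:
            kw["bleach_channels"] = tuple(
                c.strip() for c in s.get("bleach_channels").split(",") if c.strip()
            )
        if "ridge_lambda" in s:
            kw["ridge_lambda"] = s.getfloat("ridge_lambda")
    return RunConfig(**kw)


def _normalize_intervals(frame_ranges) -> list[tuple[int, int]]:
    out = []
    for fr in frame_ranges:
        if isinstance(fr, FrameRange):
            out.append((fr.start, fr.stop))
        else:
            lo, hi = fr
            out.append((int(lo), int(hi)))
    return sorted(out)


def read_stack(
    path: str | Path,
    frame_ranges=None,
    bit_depth: int | None = None,
    channel_label: str = "",
) -> ImageStack:
    """Read a multi-page grayscale TIFF, optionally selecting frame intervals.

    Parameters
    ----------
    path : path
        Multi-page grayscale TIFF file.
    frame_ranges : sequence of (start, stop) or FrameRange, optional
        Inclusive 0-based intervals; only those pages are loaded and their
        original indices are kept in ``frame_ids``.  ``None`` loads everything.
    bit_depth : int, optional
        Override for the inferred bit depth.  Needed for 12-bit data, which
        TIFF stores in a 16-bit container; the default inference is the
        container depth.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack not found: {path}")
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise StackError(f"{path}: expected single-sample grayscale pages, got shape {data.shape}")
    n_avail = data.shape[0]

    if frame_ranges is None:
        ids = np.arange(n_avail)
    else:
        intervals = _normalize_intervals(frame_ranges)
        ids = []
        for lo, hi in intervals:
            if lo < 0 or hi >= n_avail:
                raise StackError(
                    f"frame interval {lo}-{hi} out of range for {n_avail}-frame stack"
                )
            ids.extend(range(lo, hi + 1))
        ids = np.asarray(sorted(set(ids)))
        data = data[ids]

    if bit_depth is None:
        if data.dtype == np.uint8:
            bit_depth = 8
        elif data.dtype == np.uint16:
            bit_depth = 16
        else:
            raise StackError(f"{path}: unsupported pixel dtype {data.dtype}")
    return ImageStack(data, bit_depth, ids, channel_label)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as a multi-page TIFF (8-bit container for 8-bit data,
    16-bit container otherwise)."""
    path = Path(path)
    dtype = _container_dtype(stack.bit_depth)
    tifffile.imwrite(str(path), stack.frames.astype(dtype), photometric="minisblack")


def write_h5(
    artifacts: dict[str, np.ndarray],
    path: str | Path,
    frame_ids: np.ndarray | None = None,
    config: RunConfig | None = None,
) -> None:
    """Store run artifacts (corrected stacks, metrics, bleach factors) in one
    HDF5 file, with frame ids and the config snapshot as root attributes."""
    names = list(artifacts)
    if len(set(names)) != len(names):
        raise ValueError("artifact names must be unique")
    path = Path(path)
    with h5py.File(path, "w") as f:
        for name, arr in artifacts.items():
            f.create_dataset(name, data=np.asarray(arr))
        if frame_ids is not None:
            f.attrs["frame_ids"] = np.asarray(frame_ids, dtype=np.int64)
        f.attrs["config"] = config.snapshot() if config is not None else "{}"


def read_h5(path: str | Path) -> dict[str, np.ndarray]:
    """Load every dataset of an artifact file into a dict of arrays."""
    out: dict[str, np.ndarray] = {}
    with h5py.File(path, "r") as f:
        def visit(name, obj):
            if isinstance(obj, h5py.Dataset):
                out[name] = obj[()]
        f.visititems(visit)
    return out


def setup_run_logger(output_dir: str | Path, verbose: bool = False) -> logging.Logger:
    """Per-run plain-text logger writing ``run.log`` under ``output_dir``."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    logger = logging.getLogger(f"fretstack.{output_dir}")
    logger.handlers.clear()
    logger.setLevel(logging.DEBUG)
    fh = logging.FileHandler(output_dir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    if verbose:
        sh = logging.StreamHandler()
        sh.setLevel(logging.INFO)
        logger.addHandler(sh)
    logger.propagate = False
    return logger
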