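"""File I/O: gray-scale image readers (PNG / DICOM / NIfTI slice), mask
round-tripping, YAML pipeline configuration, and run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from . import pipeline, preprocess, pso

__all__ = [
    "UnreadableImageError",
    "SliceSelectionError",
    "UnsupportedImageError",
    "ConfigError",
    "RunManifest",
    "read_gray_image",
    "read_mask",
    "write_gray_image",
    "write_mask",
    "load_config",
    "dump_config",
]


class UnreadableImageError(OSError):
    """The file could not be read or parsed as the named format."""


class SliceSelectionError(ValueError):
    """A multi-slice volume needs a valid ``slice_index``."""


class UnsupportedImageError(ValueError):
    """The image's sample layout is not supported (e.g. color DICOM)."""


class ConfigError(ValueError):
    """The YAML configuration violates the schema."""


def _rescale_to_uint8(data: np.ndarray) -> np.ndarray:
    """Min-max rescale arbitrary-depth data to [0, 255] (half-away rounding)."""
    data = np.asarray(data, dtype=float)
    lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        return np.zeros(data.shape, dtype=np.uint8)
    scaled = 255.0 * (data - lo) / (hi - lo)
    return np.clip(preprocess.round_half_away(scaled), 0, 255).astype(np.uint8)


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".dcm", ".dicom")):
        return "dicom"
    if name.endswith(".png"):
        return "png"
    raise UnreadableImageError(f"cannot infer image format from file name {path.name!r}")


def _select_slice(volume: np.ndarray, slice_index: int | None, path: Path) -> np.ndarray:
    if volume.ndim == 2:
        return volume
    if volume.ndim != 3:
        raise UnsupportedImageError(f"{path}: expected 2-D or 3-D data, got {volume.ndim}-D")
    n = volume.shape[-1]
    if slice_index is None:
        raise SliceSelectionError(f"{path}: volume has {n} slices; a slice_index is required")
    if not (0 <= slice_index < n):
        raise SliceSelectionError(f"{path}: slice_index {slice_index} outside [0, {n - 1}]")
    return volume[..., slice_index]


def read_gray_image(
    path: str | Path,
    fmt: str | None = None,
    slice_index: int | None = None,
) -> np.ndarray:
    """Read one 2-D 8-bit gray-scale slice from a PNG, DICOM or NIfTI file.

    Sources deeper than 8 bits (or floating point) are min-max rescaled to
    [0, 255].  Multi-slice DICOM/NIfTI volumes require ``slice_index``
    (last axis).
    """
    path = Path(path)
    if not path.exists():
        raise UnreadableImageError(f"no such file: {path}")
    fmt = fmt or _infer_format(path)

    if fmt == "png":
        try:
            with Image.open(path) as img:
                if img.mode in ("L", "1"):
                    data = np.asarray(img.convert("L"))
                elif img.mode.startswith("I") or img.mode == "F":
                    data = np.asarray(img)
                elif img.mode in ("RGB", "RGBA", "P", "LA"):
                    raise UnsupportedImageError(
                        f"{path}: color/palette PNG not supported; provide gray-scale"
                    )
                else:
                    raise UnsupportedImageError(f"{path}: unsupported PNG mode {img.mode!r}")
        except (OSError, SyntaxError) as exc:
            raise UnreadableImageError(f"{path}: not a readable PNG ({exc})") from exc
        if data.dtype == np.uint8:
            return data
        return _rescale_to_uint8(data)

    if fmt == "dicom":
        import pydicom

        try:
            ds = pydicom.dcmread(str(path))
            photometric = getattr(ds, "PhotometricInterpretation", "MONOCHROME2")
            if photometric not in ("MONOCHROME1", "MONOCHROME2"):
                raise UnsupportedImageError(
                    f"{path}: photometric interpretation {photometric!r} not supported"
                )
            data = ds.pixel_array
        except UnsupportedImageError:
            raise
        except Exception as exc:
            raise UnreadableImageError(f"{path}: not a readable DICOM ({exc})") from exc
        data = _select_slice(np.asarray(data), slice_index, path)
        if photometric == "MONOCHROME1":  # inverted gray scale
            data = data.max() - data
        if data.dtype == np.uint8:
            return data
        return _rescale_to_uint8(data)

    if fmt == "nifti":
        import nibabel as nib

        try:
            volume = np.asarray(nib.load(str(path)).get_fdata())
        except Exception as exc:
            raise UnreadableImageError(f"{path}: not a readable NIfTI ({exc})") from exc
        data = _select_slice(volume, slice_index, path)
        if np.array_equal(data, data.astype(np.uint8)):
            return data.astype(np.uint8)
        return _rescale_to_uint8(data)

    raise UnreadableImageError(f"unknown image format {fmt!r}")


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask PNG (any value > 127 counts as foreground)."""
    data = read_gray_image(path, fmt="png")
    return (data > 127).astype(np.uint8)


def write_gray_image(image: np.ndarray, path: str | Path) -> None:
    image = np.asarray(image, dtype=np.uint8)
    Image.fromarray(image, mode="L").save(str(path))


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a {0,1} mask as an 8-bit PNG with foreground 255."""
    mask = np.asarray(mask)
    write_gray_image((mask > 0).astype(np.uint8) * 255, path)


# --- configuration -----------------------------------------------------------

_PSO_KEYS = {f.name for f in dataclasses.fields(pso.PSOConfig)}
_PIPELINE_KEYS = {f.name for f in dataclasses.fields(pipeline.PipelineConfig)}


def load_config(path: str | Path | None) -> pipeline.PipelineConfig:
    """Load and validate a YAML pipeline configuration.

    An empty (or absent) file yields the all-defaults configuration.
    Unknown keys are rejected by name; nested ``pso:`` holds the optimizer
    block.
    """
    raw: dict = {}
    if path is not None:
        try:
            text = Path(path).read_text()
        except OSError as exc:
            raise ConfigError(f"cannot read config file {path}: {exc}") from exc
        try:
            loaded = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config root must be a mapping, got {type(loaded).__name__}")
        raw = loaded

    unknown = set(raw) - _PIPELINE_KEYS
    if unknown:
        raise ConfigError(
            f"unknown config key(s) {sorted(unknown)}; known keys: {sorted(_PIPELINE_KEYS)}"
        )
    pso_raw = raw.pop("pso", {}) or {}
    if not isinstance(pso_raw, dict):
        raise ConfigError("'pso' must be a mapping of optimizer parameters")
    unknown_pso = set(pso_raw) - _PSO_KEYS
    if unknown_pso:
        raise ConfigError(
            f"unknown pso key(s) {sorted(unknown_pso)}; known keys: {sorted(_PSO_KEYS)}"
        )
    try:
        pso_config = pso.PSOConfig(**pso_raw)
        return pipeline.PipelineConfig(pso=pso_config, **raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc


def dump_config(config: pipeline.PipelineConfig) -> dict:
    """Configuration as a plain dict (the inverse of :func:`load_config`)."""
    return config.to_dict()


# --- run manifests -----------------------------------------------------------


def sha256_of(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


@dataclass
class RunManifest:
    """Provenance record emitted once per CLI run."""

    tool_version: str
    command: str
    config: dict
    seed: int | None
    inputs: dict[str, str] = field(default_factory=dict)
    started: str = ""
    finished: str = ""
    stages: list[dict] = field(default_factory=list)

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = sha256_of(path)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str) + "\n")
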