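"""Shared image data model and format I/O.

The pipeline works on named 2-D channels (``FN`` = total-fibronectin
antibody, ``FNBPA5`` = Cy5-FnBPA5 tension probe, ``CD31`` = platelet /
endothelial marker, ``DAPI`` = nuclear stain) sharing one pixel geometry.
Channel identity is by *name*, never by display colour.

Coordinate convention, used package-wide: 0-based ``(row, col)``, pixel
centers at integer coordinates; physical distance in µm = Euclidean pixel
distance × ``pixel_size_um``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from ._errors import ChannelMissingError, ConfigError

CHANNEL_NAMES = ("FN", "FNBPA5", "CD31", "DAPI")

RATIOMETRIC_CHANNELS = ("FN", "FNBPA5")


@dataclass
class MultiChannelImage:
    """Named 2-D intensity grids sharing one pixel geometry.

    Parameters
    ----------
    channels
        Mapping from channel name to a 2-D float array. ``FN`` and
        ``FNBPA5`` are required for ratiometrics, ``CD31`` for platelet
        detection; ``DAPI`` is optional (gating degrades gracefully).
    pixel_size_um
        Physical size of one pixel side, µm.
    source_id
        Free-text provenance (file path, simulation seed, ...).
    """

    channels: dict
    pixel_size_um: float
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ConfigError("image has no channels")
        if self.pixel_size_um is None or not self.pixel_size_um > 0:
            raise ConfigError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        shapes = {name: np.asarray(a).shape for name, a in self.channels.items()}
        first = next(iter(shapes.values()))
        for name, shp in shapes.items():
            if len(shp) != 2:
                raise ConfigError(f"channel {name!r} is not 2-D: shape {shp}")
            if shp != first:
                raise ConfigError(f"channel shapes differ: {shapes}")
        clean = {}
        for name, arr in self.channels.items():
            a = np.asarray(arr, dtype=np.float64)
            if not np.all(np.isfinite(a)):
                raise ConfigError(f"channel {name!r} has non-finite intensities")
            if a.min() < 0:
                raise ConfigError(f"channel {name!r} has negative intensities")
            clean[name] = a
        self.channels = clean

    @property
    def shape(self) -> tuple:
        return next(iter(self.channels.values())).shape

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def __getitem__(self, name: str) -> np.ndarray:
        self.require(name)
        return self.channels[name]

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise ChannelMissingError(
                f"image {self.source_id!r} lacks required channel(s) {missing}; "
                f"present: {sorted(self.channels)}"
            )


@dataclass
class PixelMask:
    """A named boolean pixel mask tied to the parent image geometry."""

    grid: np.ndarray
    name: str
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ConfigError(f"mask {self.name!r} is not 2-D")
        if not self.pixel_size_um > 0:
            raise ConfigError("pixel_size_um must be > 0")

    @property
    def count(self) -> int:
        return int(self.grid.sum())


# ---------------------------------------------------------------------------
# reading


def _read_ome(path: Path) -> tuple:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        names, px = None, None
        if tf.is_ome and tf.ome_metadata:
            meta = tifffile.xml2dict(tf.ome_metadata)
            try:
                pixels = meta["OME"]["Image"]
                if isinstance(pixels, list):
                    pixels = pixels[0]
                pixels = pixels["Pixels"]
                px = pixels.get("PhysicalSizeX")
                ch = pixels.get("Channel")
                if isinstance(ch, dict):
                    ch = [ch]
                if ch is not None:
                    names = [c.get("Name") for c in ch]
            except (KeyError, TypeError):
                pass
    if data.ndim == 2:
        data = data[None]
    return data, names, px


def read_image(
    path,
    channel_map: Mapping | None = None,
    pixel_size_um: float | None = None,
    require: Sequence[str] = (),
) -> MultiChannelImage:
    """Read a multichannel image from OME-TIFF or per-channel TIFFs.

    ``channel_map`` maps channel names either to integer plane indices
    (single multi-plane file) or to file paths (one grayscale TIFF per
    channel). Without a map, OME channel names are used. A pixel size in
    the OME metadata wins; otherwise ``pixel_size_um`` must be given.

    ``require`` lists channel names validated at read time, so a file
    unsuited for a downstream stage fails here with a clear message.
    """
    channels: dict = {}
    px_meta = None
    if channel_map and all(
        isinstance(v, (str, Path)) for v in channel_map.values()
    ):
        for name, p in channel_map.items():
            arr = tifffile.imread(p)
            if arr.ndim != 2:
                raise ConfigError(f"per-channel file {p} is not a 2-D grayscale image")
            channels[name] = arr
    else:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        data, ome_names, px_meta = _read_ome(path)
        if channel_map:
            for name, idx in channel_map.items():
                if not 0 <= int(idx) < data.shape[0]:
                    raise ChannelMissingError(
                        f"channel {name!r}: plane index {idx} out of range "
                        f"for {data.shape[0]} planes"
                    )
                channels[name] = data[int(idx)]
        elif ome_names:
            for i, name in enumerate(ome_names):
                if name:
                    channels[name] = data[i]
        else:
            raise ChannelMissingError(
                f"{path}: no OME channel names and no channel_map given"
            )
    px = px_meta if px_meta is not None else pixel_size_um
    img = MultiChannelImage(channels, pixel_size_um=px, source_id=str(path) if not channel_map else str(sorted(channel_map.items())))
    if require:
        img.require(*require)
    return img


# ---------------------------------------------------------------------------
# writing


def write_ome_tiff(
    path,
    image: MultiChannelImage,
    order: Sequence[str] | None = None,
    dtype=np.uint16,
) -> None:
    """Write channels as one OME-TIFF with channel names and pixel size."""
    names = list(order) if order else list(image.channels)
    stack = np.stack(
        [np.clip(np.round(image.channels[n]), 0, np.iinfo(dtype).max).astype(dtype) for n in names]
    )
    tifffile.imwrite(
        path,
        stack,
        photometric="minisblack",
        metadata={
            "axes": "CYX",
            "Channel": {"Name": names},
            "PhysicalSizeX": image.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": image.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
        },
    )


def write_mask_png(path, mask: PixelMask) -> None:
    iio.imwrite(Path(path), (mask.grid.astype(np.uint8) * 255))


def read_mask_png(path, name: str, pixel_size_um: float) -> PixelMask:
    arr = iio.imread(Path(path))
    return PixelMask(arr > 0, name=name, pixel_size_um=pixel_size_um)


def content_hash(path) -> str:
    """Canonical sha256 of an artifact.

    TIFFs are hashed over pixel bytes + shape + dtype + channel names +
    pixel size (the OME writer embeds a fresh UUID per write, so raw bytes
    are never reproducible); all other formats hash raw bytes.
    """
    path = Path(path)
    h = hashlib.sha256()
    if path.suffix.lower() in {".tif", ".tiff"}:
        data, names, px = _read_ome(path)
        h.update(np.ascontiguousarray(data).tobytes())
        h.update(str(data.shape).encode())
        h.update(str(data.dtype).encode())
        h.update(repr(names).encode())
        h.update(repr(px).encode())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(
    out_dir,
    masks: Sequence[PixelMask] = (),
    tables: Mapping[str, pd.DataFrame] | None = None,
    maps: Mapping[str, np.ndarray] | None = None,
    manifest_name: str = "manifest.json",
) -> dict:
    """Write masks (PNG 0/255), tables (CSV), ratio maps (float32 TIFF).

    Returns a manifest mapping each artifact filename to its content hash,
    and writes it as JSON alongside the artifacts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for mask in masks:
        p = out_dir / f"{mask.name}.png"
        write_mask_png(p, mask)
        written.append(p)
    for name, df in (tables or {}).items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    for name, grid in (maps or {}).items():
        p = out_dir / f"{name}.tif"
        tifffile.imwrite(p, np.asarray(grid, dtype=np.float32))
        written.append(p)
    manifest = {p.name: content_hash(p) for p in written}
    (out_dir / manifest_name).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
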