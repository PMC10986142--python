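"""Shared containers and image I/O.

A :class:`FibreFieldImage` is one imaged field holding the three
co-registered channels used throughout the pipeline: dystrophin (plasma
membrane), GLUT4, and MHC1 (slow myosin, the type-I fibre marker).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

#: Layer names in membrane-to-centre order; "interior" is deeper than L5.
LAYER_NAMES: tuple[str, ...] = ("PM", "L1", "L2", "L3", "L4", "L5")
ALL_REGIONS: tuple[str, ...] = LAYER_NAMES + ("interior",)

DEFAULT_CHANNELS: tuple[str, str, str] = ("dystrophin", "glut4", "mhc1")


@dataclass
class FibreFieldImage:
    """One field with a single muscle fibre and three stain channels."""

    channels: np.ndarray  # (3, H, W)
    pixel_size_um: float
    image_id: str = ""
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 3 or self.channels.shape[0] != len(self.channel_names):
            raise ValueError(
                f"expected ({len(self.channel_names)}, H, W) channel stack, "
                f"got {self.channels.shape}"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channel_names}") from None
        return self.channels[idx]

    def write_tiff(self, path: str | Path) -> None:
        """Write as a multi-page TIFF with pixel size and channel names embedded."""
        meta = {
            "pixel_size_um": self.pixel_size_um,
            "channel_names": list(self.channel_names),
            "image_id": self.image_id,
            **self.metadata,
        }
        tifffile.imwrite(str(path), self.channels, metadata={"glut4quant": json.dumps(meta)})


def read_fibre_tiff(
    path: str | Path,
    *,
    pixel_size_um: float | None = None,
    channel_names: tuple[str, ...] | None = None,
    image_id: str | None = None,
) -> FibreFieldImage:
    """Read a multi-page/OME TIFF as a :class:`FibreFieldImage`.

    Metadata written by :meth:`FibreFieldImage.write_tiff` is honoured;
    explicit arguments override it (required for third-party files that
    carry no pixel size).
    """
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        stored: dict = {}
        if tif.shaped_metadata:
            raw = tif.shaped_metadata[0].get("glut4quant")
            if raw:
                stored = json.loads(raw)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a (C, H, W) stack, got shape {arr.shape}")
    ps = pixel_size_um if pixel_size_um is not None else stored.get("pixel_size_um")
    if ps is None:
        raise ValueError(f"{path}: pixel size not in metadata; pass pixel_size_um")
    names = channel_names or tuple(stored.get("channel_names", DEFAULT_CHANNELS[: arr.shape[0]]))
    return FibreFieldImage(
        channels=arr,
        pixel_size_um=float(ps),
        image_id=image_id if image_id is not None else stored.get("image_id", path.stem),
        channel_names=tuple(names),
    )
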