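"""Multi-channel stack I/O, maximum-intensity projection and Gaussian denoising.

Raw inputs are confocal z-stacks of retinal cryosections with (at least) a
photoreceptor-opsin channel and an RPE channel.  Stacks are flattened to
maximum-intensity projections and lightly smoothed (Gaussian, sigma = 1 px by
default) before segmentation and spot detection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

REQUIRED_ROLES = ("photoreceptor", "rpe")
OPTIONAL_ROLES = ("nuclei", "actin")


@dataclass
class ImageStack:
    """Multi-channel 3-D intensity data.

    Parameters
    ----------
    data : ndarray, shape (channels, z, rows, cols)
        Per-channel z-stacks.
    channel_roles : dict
        Maps a role name (``photoreceptor``, ``rpe``, optionally ``nuclei``,
        ``actin``) to a channel index.
    pixel_size_um : float
        Lateral pixel size in micrometres.
    bit_depth : int
        Nominal bit depth of the acquisition.
    """

    data: np.ndarray
    channel_roles: dict[str, int]
    pixel_size_um: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"expected (channels, z, rows, cols) data, got shape {self.data.shape}"
            )
        for role in REQUIRED_ROLES:
            if role not in self.channel_roles:
                raise ValueError(f"required channel role {role!r} missing")
        n_channels = self.data.shape[0]
        for role, idx in self.channel_roles.items():
            if not 0 <= idx < n_channels:
                raise ValueError(
                    f"channel role {role!r} maps to index {idx}, "
                    f"but the stack has {n_channels} channel(s)"
                )
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    def channel(self, role: str) -> np.ndarray:
        """Return the (z, rows, cols) stack for a channel role."""
        if role not in self.channel_roles:
            raise KeyError(f"channel role {role!r} not present")
        return self.data[self.channel_roles[role]]


@dataclass
class Image2D:
    """A single-channel 2-D image with physical pixel size."""

    pixels: np.ndarray
    pixel_size_um: float = field(default=1.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {self.pixels.shape}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write an :class:`ImageStack` as OME-TIFF.

    Pixel size goes into the OME PhysicalSize attributes and channel roles
    into the OME channel names, so the file round-trips through
    :func:`read_stack` without sidecar information.
    """
    path = Path(path)
    by_index = {idx: role for role, idx in stack.channel_roles.items()}
    names = [by_index.get(i, f"channel{i}") for i in range(stack.data.shape[0])]
    meta = {
        "axes": "CZYX",
        "PhysicalSizeX": stack.pixel_size_um,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": stack.pixel_size_um,
        "PhysicalSizeYUnit": "µm",
        "Channel": {"Name": names},
        "Description": json.dumps({"bit_depth": stack.bit_depth}),
    }
    tifffile.imwrite(path, stack.data, photometric="minisblack", metadata=meta)


def _ome_text(tif: tifffile.TiffFile) -> str:
    try:
        return tif.ome_metadata or ""
    except Exception:  # pragma: no cover - backend quirk
        return ""


def _pixel_size_from_ome(ome: str) -> float | None:
    # cheap scan; a full OME-XML parse is overkill for one attribute
    import re

    m = re.search(r'PhysicalSizeX="([0-9.eE+-]+)"', ome)
    return float(m.group(1)) if m else None


def _roles_from_ome(ome: str) -> tuple[dict[str, int], int]:
    """Channel roles from OME channel names, plus the stored bit depth."""
    import html
    import re

    roles: dict[str, int] = {}
    names = re.findall(r'<Channel[^>]*?Name="([^"]*)"', ome)
    for i, name in enumerate(names):
        if name in REQUIRED_ROLES + OPTIONAL_ROLES:
            roles[name] = i
    bit_depth = 16
    m = re.search(r"<Description>(.*?)</Description>", ome, re.DOTALL)
    if m:
        try:
            bit_depth = int(json.loads(html.unescape(m.group(1))).get("bit_depth", 16))
        except (ValueError, json.JSONDecodeError):
            pass
    return roles, bit_depth


def read_stack(
    path: str | Path,
    channel_map: dict[str, int] | None = None,
    pixel_size_um: float | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF z-stack and bind channel roles.

    ``channel_map`` maps roles to channel indices; if omitted, a role map
    stored in the image description (as written by :func:`write_stack`) is
    used.  The pixel size is taken from OME metadata unless overridden.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        series_axes = tif.series[0].axes if tif.series else ""
        ome = _ome_text(tif)
    ome_px = _pixel_size_from_ome(ome)
    stored_roles, bit_depth = _roles_from_ome(ome)

    if data.ndim == 3:
        # Either (C, Y, X) single-slice multi-channel or (Z, Y, X) single channel;
        # trust the stored axes when available.
        if "C" in series_axes and "Z" not in series_axes:
            data = data[:, None, :, :]
        else:
            data = data[None, :, :, :]
    elif data.ndim == 2:
        data = data[None, None, :, :]
    elif data.ndim != 4:
        raise ValueError(f"cannot interpret TIFF with shape {data.shape} as a stack")
    if series_axes[:2] == "ZC":
        data = np.swapaxes(data, 0, 1)

    roles = dict(channel_map) if channel_map else stored_roles
    if not roles:
        raise ValueError(f"{path}: no channel map supplied and none stored in the file")
    n_channels = data.shape[0]
    for role, idx in roles.items():
        if idx >= n_channels:
            raise ValueError(
                f"{path}: channel map requires index {idx} for role {role!r}, "
                f"but the file has {n_channels} channel(s)"
            )

    px = pixel_size_um if pixel_size_um is not None else ome_px
    if px is None:
        raise ValueError(f"{path}: no pixel-size metadata; supply pixel_size_um")
    return ImageStack(data=data, channel_roles=roles, pixel_size_um=px, bit_depth=bit_depth)


def max_project(stack: ImageStack, role: str) -> Image2D:
    """Maximum-intensity projection of one channel along z."""
    channel = stack.channel(role)
    if channel.shape[0] == 0:
        raise ValueError("empty z dimension")
    return Image2D(channel.max(axis=0).astype(float), stack.pixel_size_um)


def gaussian_denoise(img: Image2D, sigma: float = 1.0) -> Image2D:
    """Gaussian smoothing with reflective boundary handling.

    Reflective padding keeps the mean intensity of flat regions unchanged at
    the image border, so a constant image is a fixed point.
    """
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    smoothed = ndimage.gaussian_filter(img.pixels, sigma=sigma, mode="reflect")
    return Image2D(smoothed, img.pixel_size_um)
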