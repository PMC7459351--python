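"""Core image containers for en-face OCTA angiograms.

An en-face OCTA angiogram is an 8-bit grayscale image of decorrelation
(flow) signal in one retinal capillary plexus, fovea-centered, with a known
physical scale.  The default acquisition geometry is a 304 x 304 pixel grid
covering 3 x 3 mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
from PIL import Image as PILImage

DEFAULT_SIZE_PX = 304
DEFAULT_SCALE_MM_PER_PX = 3.0 / 304.0


class Plexus(str, Enum):
    """Retinal capillary layer an angiogram was segmented from."""

    SVP = "SVP"  # superficial vascular plexus: arterioles/venules + cross-links
    DVP = "DVP"  # deep vascular plexus: converging capillary vortices


@dataclass(frozen=True)
class AngiogramImage:
    """8-bit en-face angiogram with physical scale and plexus tag.

    Parameters
    ----------
    pixels
        H x W array of intensities in [0, 255] (stored as ``uint8``).
    scale_mm_per_px
        Millimetres per pixel side; must be positive.  Default 3/304.
    plexus
        Which capillary layer the image shows (SVP or DVP).
    center
        Fovea position as (row, col) pixel coordinates.  Defaults to the
        geometric image center.
    """

    pixels: np.ndarray
    scale_mm_per_px: float = DEFAULT_SCALE_MM_PER_PX
    plexus: Plexus = Plexus.SVP
    center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 3 or px.shape[1] < 3:
            raise ValueError("angiogram must be a 2-D grid of at least 3 x 3 pixels")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        if not self.scale_mm_per_px > 0:
            raise ValueError("scale_mm_per_px must be positive")
        object.__setattr__(self, "pixels", px)
        if self.center is None:
            object.__setattr__(
                self, "center", ((px.shape[0] - 1) / 2.0, (px.shape[1] - 1) / 2.0)
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def n_pixels(self) -> int:
        return self.pixels.size

    def with_pixels(self, pixels: np.ndarray) -> "AngiogramImage":
        return AngiogramImage(
            pixels=pixels,
            scale_mm_per_px=self.scale_mm_per_px,
            plexus=self.plexus,
            center=self.center,
        )


@dataclass(frozen=True)
class RegionSpec:
    """Fovea-centered circular analysis regions.

    The foveal region is a circle of 1 mm diameter; the parafoveal region is
    the 1-mm-wide annulus around it, so the annulus spans radii 0.5–1.5 mm
    and has geometric area ``pi * (1.5**2 - 0.5**2) = 2*pi`` mm².
    """

    center: tuple[float, float]
    fovea_radius_mm: float = 0.5
    parafovea_outer_radius_mm: float = 1.5

    def __post_init__(self) -> None:
        if not 0 < self.fovea_radius_mm < self.parafovea_outer_radius_mm:
            raise ValueError("require 0 < fovea radius < parafoveal outer radius")

    def radius_map_mm(self, shape: tuple[int, int], scale_mm_per_px: float) -> np.ndarray:
        """Distance of every pixel center from the region center, in mm."""
        rows = np.arange(shape[0])[:, None] - self.center[0]
        cols = np.arange(shape[1])[None, :] - self.center[1]
        return np.hypot(rows, cols) * scale_mm_per_px

    def fovea_mask(self, shape: tuple[int, int], scale_mm_per_px: float) -> np.ndarray:
        """Boolean mask of the central 1-mm-diameter foveal circle."""
        return self.radius_map_mm(shape, scale_mm_per_px) <= self.fovea_radius_mm

    def annulus_mask(self, shape: tuple[int, int], scale_mm_per_px: float) -> np.ndarray:
        """Boolean mask of the 1-mm-wide parafoveal annulus."""
        r = self.radius_map_mm(shape, scale_mm_per_px)
        return (r > self.fovea_radius_mm) & (r <= self.parafovea_outer_radius_mm)

    def contains(self, shape: tuple[int, int], scale_mm_per_px: float) -> bool:
        """Whether the outer analysis circle fits inside the image.

        Only requires the circle inscribed in the image: the default
        3 x 3 mm scan has its 1.5-mm outer radius exactly inscribed.
        """
        r_px = self.parafovea_outer_radius_mm / scale_mm_per_px
        cy, cx = self.center
        h, w = shape
        return (
            cy - r_px >= -0.5
            and cx - r_px >= -0.5
            and cy + r_px <= h - 0.5
            and cx + r_px <= w - 0.5
        )


def default_region(img: AngiogramImage) -> RegionSpec:
    return RegionSpec(center=img.center)


def load_angiogram(path: str | Path) -> AngiogramImage:
    """Load an 8-bit grayscale PNG/TIFF angiogram plus optional JSON sidecar.

    A sidecar ``<image>.json`` next to the file may carry
    ``scale_mm_per_px``, ``plexus`` and ``center``; defaults are applied for
    any missing field.
    """
    path = Path(path)
    arr = np.asarray(PILImage.open(path).convert("L"))
    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    center = meta.get("center")
    return AngiogramImage(
        pixels=arr,
        scale_mm_per_px=float(meta.get("scale_mm_per_px", DEFAULT_SCALE_MM_PER_PX)),
        plexus=Plexus(meta.get("plexus", "SVP")),
        center=tuple(center) if center is not None else None,
    )


def save_angiogram(img: AngiogramImage, path: str | Path) -> None:
    """Write the image as PNG/TIFF with a JSON metadata sidecar."""
    path = Path(path)
    PILImage.fromarray(img.pixels, mode="L").save(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "scale_mm_per_px": img.scale_mm_per_px,
                "plexus": img.plexus.value,
                "center": list(img.center),
            }
        )
    )
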