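"""Image I/O and morphological preprocessing for fluorescence micrographs.

Confocal GFP imagery of cultured neurons arrives as 8/16-bit grayscale
rasters (optionally z-stacks). Photomultiplier acquisition introduces
salt-and-pepper noise, so the standard cleanup chain before backbone
extraction is: median filter, optional anisotropic-diffusion enhancement,
grayscale opening (or top-hat) to suppress small bright jiggers, intensity
thresholding, and a 3x3 majority vote on the binary mask.

Conventions: images are (row, col) 0-based arrays with intensities in
[0, 1]; x = column, y = row; edges are handled by reflect padding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .errors import ValidationError

#: Physical pixel pitch of the reference acquisition (µm/pixel).
DEFAULT_PIXEL_SIZE_UM = 0.24


@dataclass
class GrayImage:
    """2-D grayscale image with intensities normalized to [0, 1].

    Parameters
    ----------
    pixels : ndarray
        2-D float array, values in [0, 1].
    pixel_size_um : float
        Physical size of one pixel in micrometres (default 0.24).
    """

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("GrayImage requires a non-empty 2-D array")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValidationError(
                f"intensities must lie in [0,1], got [{lo}, {hi}]"
            )
        np.clip(self.pixels, 0.0, 1.0, out=self.pixels)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def with_pixels(self, pixels: np.ndarray) -> "GrayImage":
        return GrayImage(pixels, pixel_size_um=self.pixel_size_um)


@dataclass
class BinaryMask:
    """2-D boolean foreground raster."""

    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("BinaryMask requires a non-empty 2-D array")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class StructuringElement:
    """Flat structuring element: a disk of given radius or a square of given side."""

    shape: str = "disk"
    size: int = 2
    footprint: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.shape not in ("disk", "square"):
            raise ValidationError("SE shape must be 'disk' or 'square'")
        if self.size < 1:
            raise ValidationError("SE size must be >= 1")
        if self.shape == "disk":
            self.footprint = disk(self.size).astype(bool)
        else:
            self.footprint = np.ones((self.size, self.size), dtype=bool)


def _to_unit_range(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / float(np.iinfo(arr.dtype).max)
    out = arr.astype(float)
    if out.size and out.max() > 1.0:  # float image stored on a 0..255 scale
        out = out / out.max()
    return out


def load_image(path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> GrayImage:
    """Read a TIFF or PNG image as a normalized grayscale :class:`GrayImage`.

    Multi-page TIFFs are collapsed by maximum-intensity projection; RGB(A)
    images are converted by the ITU-R 601 luminance weights. Intensities are
    rescaled to [0, 1] by the dtype maximum.
    """
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # RGB(A)
        arr = (
            0.299 * arr[..., 0].astype(float)
            + 0.587 * arr[..., 1].astype(float)
            + 0.114 * arr[..., 2].astype(float)
        ).astype(arr.dtype)
    if arr.ndim == 3:  # z-stack
        slices = [GrayImage(_to_unit_range(a), pixel_size_um) for a in arr]
        return project_stack(slices)
    if arr.ndim != 2 or arr.size == 0:
        raise ValidationError(f"cannot interpret {path!r} as a 2-D grayscale image")
    return GrayImage(_to_unit_range(arr), pixel_size_um)


def project_stack(slices) -> GrayImage:
    """Maximum-intensity projection of a z-stack onto the XY plane."""
    if len(slices) == 0:
        raise ValidationError("project_stack requires at least one slice")
    shape = slices[0].pixels.shape
    for s in slices:
        if s.pixels.shape != shape:
            raise ValidationError("all slices must share the same dimensions")
    stacked = np.stack([s.pixels for s in slices], axis=0)
    return GrayImage(stacked.max(axis=0), pixel_size_um=slices[0].pixel_size_um)


def median_filter(img: GrayImage, window: int = 3) -> GrayImage:
    """2-D median filter (reflect padding); removes salt-and-pepper impulses."""
    if window < 3 or window % 2 == 0:
        raise ValidationError("median window must be odd and >= 3")
    out = ndimage.median_filter(img.pixels, size=window, mode="reflect")
    return img.with_pixels(out)


def enhance_pde(
    img: GrayImage,
    iterations: int = 10,
    conductance: float = 0.1,
    dt: float = 0.2,
) -> GrayImage:
    """Edge-preserving enhancement by Perona-Malik anisotropic diffusion.

    Explicit 4-neighbour scheme with exponential conductance
    g(s) = exp(-(s/K)^2); stable for dt <= 0.25.
    """
    if iterations < 0:
        raise ValidationError("iterations must be >= 0")
    if not (0 < dt <= 0.25):
        raise ValidationError("dt must lie in (0, 0.25] for stability")
    if conductance <= 0:
        raise ValidationError("conductance must be positive")
    u = img.pixels.copy()
    k2 = conductance * conductance
    for _ in range(iterations):
        p = np.pad(u, 1, mode="reflect")
        dn = p[:-2, 1:-1] - u
        ds = p[2:, 1:-1] - u
        de = p[1:-1, 2:] - u
        dw = p[1:-1, :-2] - u
        u = u + dt * (
            np.exp(-(dn * dn) / k2) * dn
            + np.exp(-(ds * ds) / k2) * ds
            + np.exp(-(de * de) / k2) * de
            + np.exp(-(dw * dw) / k2) * dw
        )
        np.clip(u, 0.0, 1.0, out=u)
    return img.with_pixels(u)


def _check_se(img: GrayImage, se: StructuringElement):
    if (
        se.footprint.shape[0] > img.height
        or se.footprint.shape[1] > img.width
    ):
        raise ValidationError("structuring element larger than image")


def opening(img: GrayImage, se: StructuringElement) -> GrayImage:
    """Grayscale opening: erosion followed by dilation with the same SE.

    Removes bright structures smaller than the SE ("small jiggers") while
    preserving larger tubes. Idempotent.
    """
    _check_se(img, se)
    out = ndimage.grey_opening(
        img.pixels, footprint=se.footprint, mode="reflect"
    )
    return img.with_pixels(out)


def top_hat(img: GrayImage, se: StructuringElement) -> GrayImage:
    """White top-hat: image minus its opening (small bright-structure extractor)."""
    _check_se(img, se)
    out = img.pixels - opening(img, se).pixels
    return img.with_pixels(np.clip(out, 0.0, None))


def majority(mask: BinaryMask, n: int = 4) -> BinaryMask:
    """Keep a pixel only if its 3x3 window (centre included) has more than
    ``n`` positive pixels; isolated noise pixels are relegated to 0."""
    if not (1 <= n <= 9):
        raise ValidationError("majority n must lie in [1, 9]")
    counts = ndimage.correlate(
        mask.pixels.astype(np.int16), np.ones((3, 3), dtype=np.int16), mode="reflect"
    )
    return BinaryMask(counts > n)


def otsu_threshold(img: GrayImage) -> float:
    """Otsu threshold of the intensity histogram (0.5 for constant images)."""
    px = img.pixels
    if float(px.max()) - float(px.min()) < 1e-12:
        return 0.5
    return float(threshold_otsu(px, nbins=256))


def binarize(
    img: GrayImage, method: str = "otsu", threshold: float | None = None
) -> BinaryMask:
    """Threshold to a foreground mask. ``otsu`` picks the threshold from the
    intensity histogram; ``fixed`` uses the supplied value in (0, 1).
    Foreground is ``pixels >= threshold``."""
    if method == "fixed":
        if threshold is None or not (0 < threshold < 1):
            raise ValidationError("fixed binarize needs threshold in (0,1)")
        t = threshold
    elif method == "otsu":
        px = img.pixels
        if float(px.max()) - float(px.min()) < 1e-12:
            warnings.warn(
                "constant image: Otsu undefined, falling back to fixed 0.5",
                stacklevel=2,
            )
            t = 0.5
        else:
            t = float(threshold_otsu(px, nbins=256))
    else:
        raise ValidationError(f"unknown binarize method {method!r}")
    return BinaryMask(img.pixels >= t)
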