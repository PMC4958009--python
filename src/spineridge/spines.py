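"""Spine candidate detection, measurement, normalization and pseudo-filtering.

Candidate spines are 8-connected foreground components outside the dendrite
mask that come within ``max_gap`` pixels of the dendrite boundary. Each is
measured by geodesic length (attachment to farthest pixel through the pixel
graph, diagonal steps sqrt(2)) and pixel area, converted to micrometres via
the pixel pitch. A trained binary twin-SVM on Hu features separates true
spines from pseudo-spines; a report aggregates dendrite length, spine count
and total spine length/area per image.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .boundary import DendriteBoundary
from .density_ridge import BackboneGraph
from .errors import ValidationError
from .hu_features import feature_vector
from .io_preprocess import DEFAULT_PIXEL_SIZE_UM, BinaryMask
from .tsvm import TSVMModel, predict_batch

_EIGHT = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class SpineRegion:
    """A connected candidate spine with its boundary attachment point."""

    pixels: np.ndarray              # (K, 2) int (row, col)
    attachment: np.ndarray          # (2,) float, on the dendrite boundary
    label: str = "unlabeled"
    length_um: float = 0.0
    area_um2: float = 0.0
    intensities: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.pixels = np.atleast_2d(np.asarray(self.pixels, dtype=int))
        if self.pixels.size == 0:
            raise ValidationError("SpineRegion needs at least one pixel")
        self.attachment = np.asarray(self.attachment, dtype=float)

    @property
    def area_px(self) -> int:
        return self.pixels.shape[0]

    def to_image(self, weighted: bool = False, pad: int = 1) -> np.ndarray:
        """Cropped binary (or intensity) raster of the region."""
        r0, c0 = self.pixels.min(axis=0)
        r1, c1 = self.pixels.max(axis=0)
        img = np.zeros((r1 - r0 + 1 + 2 * pad, c1 - c0 + 1 + 2 * pad))
        rr = self.pixels[:, 0] - r0 + pad
        cc = self.pixels[:, 1] - c0 + pad
        if weighted and self.intensities is not None:
            img[rr, cc] = self.intensities
        else:
            img[rr, cc] = 1.0
        return img

    def to_record(self) -> dict:
        return {
            "label": self.label,
            "area_px": int(self.area_px),
            "area_um2": float(self.area_um2),
            "length_um": float(self.length_um),
            "attachment": [float(v) for v in self.attachment],
        }


def detect_spines(
    mask: BinaryMask,
    dendrite: BinaryMask,
    bnd: DendriteBoundary,
    min_area: int = 4,
    max_gap: float = 2.0,
    dilate_px: int = 0,
    close_px: int = 1,
    min_protrusion: float = 1.0,
):
    """Connected components of (mask AND NOT dendrite) near the boundary.

    Components with >= ``min_area`` pixels whose nearest boundary sample is
    within ``max_gap`` px become candidates with that sample as attachment;
    everything else is background clutter and discarded. A small closing
    (``close_px``) reconnects protrusions fragmented by noise; components
    that never reach deeper than ``min_protrusion`` px beyond the boundary
    are discretization slivers of the boundary polygon itself and are
    dropped. ``dilate_px`` optionally dilates the dendrite mask first.
    """
    if mask.shape != dendrite.shape:
        raise ValidationError("mask and dendrite mask must share dims")
    dpx = dendrite.pixels
    if dilate_px > 0:
        dpx = ndimage.binary_dilation(dpx, iterations=dilate_px)
    outside = mask.pixels & ~dpx
    if close_px > 0:
        # reconnect fragments of one protrusion split by noise, without
        # growing into the dendrite
        closed = ndimage.binary_closing(
            outside, iterations=close_px, structure=np.ones((3, 3))
        )
        outside = closed & ~dpx
    labels, n = ndimage.label(outside, structure=np.ones((3, 3)))
    if n == 0:
        return []
    bpts = np.vstack([bnd.left[bnd.valid], bnd.right[bnd.valid]])
    if bpts.shape[0] == 0:
        return []
    tree = cKDTree(bpts)
    regions = []
    for lab in range(1, n + 1):
        pix = np.argwhere(labels == lab)
        if pix.shape[0] < min_area:
            continue
        d, idx = tree.query(pix.astype(float))
        k = int(np.argmin(d))
        if d[k] > max_gap:
            continue
        if d.max() <= min_protrusion:
            continue
        regions.append(
            SpineRegion(pixels=pix, attachment=bpts[idx[k]])
        )
    return regions


def _geodesic_px(region: SpineRegion, max_attach_dist: float = 4.0) -> float:
    """Inclusive geodesic pixel length from the attachment-adjacent pixel
    to the farthest region pixel (Dijkstra, diagonal = sqrt(2)).

    ``max_attach_dist`` accommodates the sub-pixel margin between the
    marched boundary rails and the subtracted dendrite region."""
    pix = region.pixels
    index = {tuple(p): i for i, p in enumerate(map(tuple, pix))}
    d_att = np.linalg.norm(pix - region.attachment, axis=1)
    if d_att.min() > max_attach_dist:
        raise ValidationError("attachment is not adjacent to the region")
    src = int(np.argmin(d_att))
    dist = np.full(pix.shape[0], np.inf)
    dist[src] = 0.0
    heap = [(0.0, src)]
    while heap:
        d, i = heapq.heappop(heap)
        if d > dist[i]:
            continue
        r, c = pix[i]
        for dr, dc in _EIGHT:
            j = index.get((r + dr, c + dc))
            if j is None:
                continue
            nd = d + (1.4142135623730951 if dr and dc else 1.0)
            if nd < dist[j]:
                dist[j] = nd
                heapq.heappush(heap, (nd, j))
    finite = dist[np.isfinite(dist)]
    return float(finite.max()) + 1.0   # count the source pixel itself


def measure_spine(region: SpineRegion, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM):
    """(length_um, area_um2) of a candidate; also stored on the region."""
    length_um = _geodesic_px(region) * pixel_size_um
    area_um2 = region.area_px * pixel_size_um**2
    region.length_um = length_um
    region.area_um2 = area_um2
    return length_um, area_um2


def measure_dendrite(backbone: BackboneGraph, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> float:
    """Total dendrite length: polyline arc length of all curves, in µm."""
    if not backbone.curves:
        raise ValidationError("backbone is empty")
    return backbone.total_length_px() * pixel_size_um


def normalize_measurements(values) -> list:
    """Min-max style normalization N = R / (L - S) with L = max, S = min."""
    vals = [float(v) for v in values]
    if not vals:
        raise ValidationError("values must be non-empty")
    L, S = max(vals), min(vals)
    if L == S:
        raise ValidationError("normalization undefined for constant values")
    return [v / (L - S) for v in vals]


def filter_pseudo(candidates, model: TSVMModel, features=None):
    """Partition candidates into (true_spines, pseudo_spines) by the binary
    TSVM (+1 = true spine); labels are set on the regions."""
    if model is None or model.z1 is None:
        raise ValidationError("binary model is not trained")
    if not candidates:
        return [], []
    if features is None:
        features = np.array([feature_vector(r) for r in candidates])
    else:
        features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = predict_batch(model, features)
    true_spines, pseudo = [], []
    for region, lab in zip(candidates, labels):
        if lab == 1:
            true_spines.append(region)
        else:
            region.label = "pseudo"
            pseudo.append(region)
    return true_spines, pseudo


@dataclass
class SpineReport:
    """Per-image morphometry summary (plus per-spine records)."""

    dendrite_length_um: float
    spine_count: int
    total_spine_length_um: float
    total_spine_area_um2: float
    spines: list = field(default_factory=list)

    @classmethod
    def from_spines(cls, backbone_length_um: float, spines) -> "SpineReport":
        return cls(
            dendrite_length_um=backbone_length_um,
            spine_count=len(spines),
            total_spine_length_um=float(sum(s.length_um for s in spines)),
            total_spine_area_um2=float(sum(s.area_um2 for s in spines)),
            spines=list(spines),
        )

    def summary_row(self) -> dict:
        return {
            "dendrite_length_um": round(self.dendrite_length_um, 6),
            "spine_count": self.spine_count,
            "total_spine_length_um": round(self.total_spine_length_um, 6),
            "total_spine_area_um2": round(self.total_spine_area_um2, 6),
        }

    def to_csv(self, path):
        import pandas as pd

        pd.DataFrame([self.summary_row()]).to_csv(
            path, index=False, float_format="%.6f"
        )

    def to_json(self, path):
        payload = {
            "summary": self.summary_row(),
            "spines": [s.to_record() for s in self.spines],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=1)
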