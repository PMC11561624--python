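"""Microsphere packing analysis from grayscale micrographs.

Pipeline: grayscale → global threshold → Euclidean distance transform →
watershed on the negated distance map, which yields a Voronoi-like
tessellation around the sphere centers → per-cell area and perimeter →
packing summary (means ± SE, deviation from the ideal hexagonal cell,
kinetic-theory mean free path).

Conventions: images are (row, col) with 0-based indices; regions use
8-connectivity; watershed lines carry label 0 and are excluded from
cell areas; cells touching the image border are flagged non-interior
(their Voronoi cells are unbounded) and excluded from summary
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

__all__ = [
    "SegmentationResult",
    "CellMetrics",
    "PackingSummary",
    "preprocess",
    "distance_map",
    "tessellate",
    "segment_spheres",
    "cell_metrics",
    "packing_summary",
    "mean_free_path",
    "edge_overlay",
]

AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class SegmentationResult:
    """Labeled Voronoi tessellation of a micrograph.

    label_image has one connected positive-integer region per seed and
    0 on watershed boundary lines; px_size_nm converts pixel metrics to
    nanometers.
    """

    label_image: np.ndarray
    n_cells: int
    px_size_nm: float
    seeds: np.ndarray            # (n, 2) array of (row, col)

    def __post_init__(self) -> None:
        lab = np.asarray(self.label_image)
        labels = np.unique(lab)
        labels = labels[labels > 0]
        if labels.size != self.n_cells:
            raise ValueError("n_cells does not match label image")
        if labels.size and not np.array_equal(
                labels, np.arange(1, labels.size + 1)):
            raise ValueError("labels must be contiguous positive integers")
        object.__setattr__(self, "label_image", lab)
        object.__setattr__(self, "seeds",
                           np.asarray(self.seeds, dtype=float).reshape(-1, 2))


@dataclass(frozen=True)
class CellMetrics:
    label: int
    area_nm2: float
    perimeter_nm: float
    interior: bool

    def __post_init__(self) -> None:
        if not (self.area_nm2 > 0 and self.perimeter_nm > 0):
            raise ValueError("area and perimeter must be positive")


@dataclass(frozen=True)
class PackingSummary:
    mean_area_nm2: float
    se_area_nm2: float
    mean_perimeter_nm: float
    se_perimeter_nm: float
    hex_area_ideal_nm2: float
    hex_perimeter_ideal_nm: float
    hex_area_deviation_nm2: float
    hex_perimeter_deviation_nm: float
    mean_free_path_nm: float
    n_interior_cells: int

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)


def preprocess(
    image: np.ndarray,
    threshold: float | None = None,
    invert: bool = False,
) -> np.ndarray:
    """Binarize a grayscale image; foreground = pixels above threshold.

    Defaults to Otsu's global threshold.  ``invert=True`` selects the
    dark phase instead (for dark objects on a bright background).
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a 2-D single-channel image")
    if np.ptp(img) == 0:
        raise ValueError("constant image cannot be thresholded")
    theta = threshold_otsu(img) if threshold is None else threshold
    mask = img > theta
    return ~mask if invert else mask


def distance_map(mask: np.ndarray) -> np.ndarray:
    """Euclidean distance of each foreground pixel to nearest background."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask has no foreground pixels")
    return ndi.distance_transform_edt(mask)


def _markers_from_seeds(seeds: np.ndarray, shape) -> np.ndarray:
    markers = np.zeros(shape, dtype=np.int32)
    for k, (r, c) in enumerate(np.asarray(seeds).reshape(-1, 2), start=1):
        markers[int(round(r)), int(round(c))] = k
    return markers


def find_seeds(distance: np.ndarray, min_distance: int = 5) -> np.ndarray:
    """Sphere centers as local maxima of the distance transform."""
    coords = peak_local_max(distance, min_distance=min_distance,
                            exclude_border=False)
    if coords.shape[0] == 0:
        raise ValueError("no seeds found in distance map")
    return coords


def tessellate(
    distance: np.ndarray,
    seeds: np.ndarray | None = None,
    px_size_nm: float = 1.0,
    min_distance: int = 5,
) -> SegmentationResult:
    """Watershed the negated distance map into one region per seed.

    Seeds default to local maxima of the distance transform.  The
    watershed floods the whole frame (no mask), so regions tile the
    image like Voronoi cells; boundary lines get label 0.
    """
    distance = np.asarray(distance, dtype=float)
    if seeds is None:
        seeds = find_seeds(distance, min_distance=min_distance)
    seeds = np.asarray(seeds).reshape(-1, 2)
    if seeds.shape[0] == 0:
        raise ValueError("need at least one seed")
    markers = _markers_from_seeds(seeds, distance.shape)
    labels = watershed(-distance, markers, watershed_line=True)
    labels = _relabel_contiguous(labels)
    n = int(labels.max())
    return SegmentationResult(labels, n, float(px_size_nm), seeds)


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    present = np.unique(labels)
    present = present[present > 0]
    out = np.zeros_like(labels)
    for new, old in enumerate(present, start=1):
        out[labels == old] = new
    return out


def segment_spheres(
    image: np.ndarray,
    px_size_nm: float = 1.0,
    threshold: float | None = None,
    min_distance: int = 5,
    seeds: np.ndarray | None = None,
) -> SegmentationResult:
    """Full pipeline: threshold → distance transform → watershed."""
    mask = preprocess(image, threshold=threshold)
    dist = distance_map(mask)
    return tessellate(dist, seeds=seeds, px_size_nm=px_size_nm,
                      min_distance=min_distance)


def cell_metrics(seg: SegmentationResult) -> list[CellMetrics]:
    """Per-cell area (nm²) and perimeter (nm).

    Area is the pixel count scaled by px_size²; perimeter is the
    weighted boundary length (straight steps 1, diagonal √2) scaled by
    px_size.  Cells touching the image border are flagged non-interior.
    """
    if seg.n_cells < 1:
        raise ValueError("empty segmentation")
    px = seg.px_size_nm
    lab = seg.label_image
    border_labels = set(np.unique(np.concatenate([
        lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])))
    out = []
    for rp in regionprops(lab):
        out.append(CellMetrics(
            label=int(rp.label),
            area_nm2=float(rp.area) * px * px,
            perimeter_nm=float(rp.perimeter) * px,
            interior=rp.label not in border_labels,
        ))
    return out


def hexagonal_ideal(sphere_diameter_nm: float) -> tuple[float, float]:
    """Area and perimeter of the densest-packing Voronoi cell.

    The regular hexagon whose inscribed circle diameter equals the
    sphere diameter d: side s = d/√3, area (√3/2)·d², perimeter 2√3·d.
    """
    if not sphere_diameter_nm > 0:
        raise ValueError("diameter must be positive")
    d = sphere_diameter_nm
    return (np.sqrt(3.0) / 2.0) * d * d, 2.0 * np.sqrt(3.0) * d


def mean_free_path(
    concentration_m: float,
    diameter_nm: float,
    kinetic_factor: float = np.sqrt(2.0),
) -> float:
    """Kinetic-theory mean free path λ = 1/(factor·π·d²·ρ_n), in nm.

    ρ_n is the number density in particles/nm³ obtained from the molar
    concentration via Avogadro's number (1 L = 10²⁴ nm³).  The √2
    factor assumes a Maxwellian relative-speed distribution and is
    configurable (set 1.0 for the fixed-target form).
    """
    if not (concentration_m > 0 and diameter_nm > 0):
        raise ValueError("concentration and diameter must be positive")
    rho_n = concentration_m * AVOGADRO * 1e-24      # nm^-3
    return float(1.0 / (kinetic_factor * np.pi * diameter_nm ** 2 * rho_n))


def packing_summary(
    cells: list[CellMetrics],
    sphere_diameter_nm: float,
    concentration_m: float,
) -> PackingSummary:
    """Summarize interior-cell geometry against the hexagonal ideal."""
    interior = [c for c in cells if c.interior]
    if len(interior) < 2:
        raise ValueError("need at least 2 interior cells")
    areas = np.array([c.area_nm2 for c in interior])
    perims = np.array([c.perimeter_nm for c in interior])
    n = len(interior)
    hex_area, hex_perim = hexagonal_ideal(sphere_diameter_nm)
    mean_area = float(areas.mean())
    mean_perim = float(perims.mean())
    return PackingSummary(
        mean_area_nm2=mean_area,
        se_area_nm2=float(areas.std(ddof=1) / np.sqrt(n)),
        mean_perimeter_nm=mean_perim,
        se_perimeter_nm=float(perims.std(ddof=1) / np.sqrt(n)),
        hex_area_ideal_nm2=hex_area,
        hex_perimeter_ideal_nm=hex_perim,
        hex_area_deviation_nm2=abs(mean_area - hex_area),
        hex_perimeter_deviation_nm=abs(mean_perim - hex_perim),
        mean_free_path_nm=mean_free_path(concentration_m, sphere_diameter_nm),
        n_interior_cells=n,
    )


def edge_overlay(image: np.ndarray, seg: SegmentationResult) -> np.ndarray:
    """Watershed boundaries in red over the grayscale original (RGB)."""
    img = np.asarray(image)
    if img.shape != seg.label_image.shape:
        raise ValueError("image and segmentation shapes differ")
    if img.dtype != np.uint8:
        lo, hi = float(img.min()), float(img.max())
        scale = 255.0 / (hi - lo) if hi > lo else 1.0
        img = ((img - lo) * scale).astype(np.uint8)
    rgb = np.stack([img, img, img], axis=-1)
    edges = seg.label_image == 0
    rgb[edges] = (255, 0, 0)
    return rgb
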