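"""Point-count stereology on histology class maps, plus necropsy ratios.

A regular √n × √n lattice is overlaid on a labelled image and the class
under each intersection is tallied ("touch count"); class percentages
estimate area fractions.  Classes follow the lung-injury convention:
airspace, acinar tissue (gas-exchange parenchyma incl. septal vessels),
non-acinar tissue (airways/large vessels/pleura), and hemorrhage.
Alveolar-tissue percentage subtracts non-acinar points from the overall
tissue count.

Also provides the wet-to-dry mass ratio (edema index) and the
lung/body-weight ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CLASS_NAMES",
    "DEFAULT_LEGEND",
    "HistologyLabelImage",
    "PointCountResult",
    "alveolar_tissue_percent",
    "lung_body_ratio",
    "overlay_grid",
    "point_count",
    "sample_fields",
    "wet_to_dry",
]

CLASS_NAMES = ("airspace", "acinar_tissue", "nonacinar_tissue", "hemorrhage")
DEFAULT_LEGEND = {i: name for i, name in enumerate(CLASS_NAMES)}

TISSUE_CLASSES = ("acinar_tissue", "nonacinar_tissue")


@dataclass(frozen=True)
class HistologyLabelImage:
    """2-D integer class map with a legend and optional pixel size."""

    data: np.ndarray
    legend: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LEGEND))
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        object.__setattr__(self, "data", data)
        if data.ndim != 2:
            raise ValueError("label image must be 2-D")
        present = set(np.unique(data).tolist())
        unknown = present - set(self.legend)
        if unknown:
            raise ValueError(f"pixel classes {sorted(unknown)} missing from legend")

    @property
    def pixel_fractions(self) -> dict[str, float]:
        """Exact area fraction of each legend class."""
        total = self.data.size
        out = {}
        for code, name in self.legend.items():
            out[name] = float(np.count_nonzero(self.data == code)) / total
        return out


@dataclass(frozen=True)
class PointCountResult:
    """Touch counts at grid intersections and derived percentages."""

    grid: np.ndarray  # (n, 2) array of (row, col)
    counts: dict[str, int]
    total_points: int
    percentages: dict[str, float]


def overlay_grid(
    width: int,
    height: int,
    n_points: int = 100,
    random_offset: np.random.Generator | None = None,
) -> np.ndarray:
    """Regular centered √n × √n point lattice over a width × height image.

    Returns an (n, 2) integer array of (row, col) pixel coordinates with
    pitch ``dim/√n`` and a half-pitch margin.  ``random_offset`` switches
    to an unbiased uniformly translated lattice (offset drawn in
    [0, pitch) per axis).
    """
    k = math.isqrt(n_points)
    if k * k != n_points:
        raise ValueError(f"n_points must be a perfect square, got {n_points}")
    if width < k or height < k:
        raise ValueError("image smaller than the grid pitch")
    pitch_x = width / k
    pitch_y = height / k
    if random_offset is not None:
        off_x = float(random_offset.uniform(0, pitch_x))
        off_y = float(random_offset.uniform(0, pitch_y))
    else:
        off_x, off_y = pitch_x / 2.0, pitch_y / 2.0
    cols = ((np.arange(k) * pitch_x + off_x) % width).astype(int)
    rows = ((np.arange(k) * pitch_y + off_y) % height).astype(int)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return np.stack([rr.ravel(), cc.ravel()], axis=1)


def point_count(image: HistologyLabelImage, grid: np.ndarray) -> PointCountResult:
    """Tally the class under each grid intersection."""
    grid = np.asarray(grid, dtype=int)
    h, w = image.data.shape
    if grid.size == 0:
        raise ValueError("empty grid")
    if grid[:, 0].min() < 0 or grid[:, 0].max() >= h or grid[:, 1].min() < 0 or grid[:, 1].max() >= w:
        raise ValueError("grid points fall outside the image")
    touched = image.data[grid[:, 0], grid[:, 1]]
    for code in np.unique(touched):
        if int(code) not in image.legend:
            raise ValueError(f"class code {int(code)} at a grid point is not in the legend")
    total = grid.shape[0]
    counts = {name: int(np.count_nonzero(touched == code)) for code, name in image.legend.items()}
    percentages = {name: 100.0 * c / total for name, c in counts.items()}
    return PointCountResult(grid=grid, counts=counts, total_points=total, percentages=percentages)


def alveolar_tissue_percent(
    result: PointCountResult, hemorrhage_as_tissue: bool = False
) -> float:
    """Alveolar (acinar) tissue percentage.

    Non-acinar points are subtracted from the overall tissue count; by
    default hemorrhage is its own class and not part of "overall tissue"
    (``hemorrhage_as_tissue=True`` includes it).
    """
    tissue = sum(result.counts.get(c, 0) for c in TISSUE_CLASSES)
    if hemorrhage_as_tissue:
        tissue += result.counts.get("hemorrhage", 0)
    alveolar = tissue - result.counts.get("nonacinar_tissue", 0)
    return 100.0 * alveolar / result.total_points


def wet_to_dry(wet_g: float, dry_g: float) -> float:
    """Wet-to-dry lung mass ratio (edema index)."""
    if dry_g <= 0:
        raise ValueError("dry mass must be positive")
    if wet_g < dry_g:
        raise ValueError("wet mass cannot be below dry mass")
    return wet_g / dry_g


def lung_body_ratio(lung_g: float, body_kg: float) -> float:
    """Lung weight over body weight, g/kg."""
    if lung_g <= 0 or body_kg <= 0:
        raise ValueError("weights must be positive")
    return lung_g / body_kg


def sample_fields(
    image: HistologyLabelImage,
    field_shape: tuple[int, int],
    n_fields: int = 2,
    rng: np.random.Generator | None = None,
) -> list[HistologyLabelImage]:
    """Choose ``n_fields`` non-overlapping fields of view at random.

    Mirrors the practice of selecting random fields per slide before
    point counting; windows are drawn by seeded rejection sampling.
    """
    rng = rng or np.random.default_rng(0)
    fh, fw = field_shape
    h, w = image.data.shape
    if fh > h or fw > w:
        raise ValueError("field larger than image")
    placed: list[tuple[int, int]] = []
    fields = []
    attempts = 0
    while len(fields) < n_fields:
        attempts += 1
        if attempts > 10_000:
            raise ValueError("could not place non-overlapping fields")
        r = int(rng.integers(0, h - fh + 1))
        c = int(rng.integers(0, w - fw + 1))
        if any(abs(r - r0) < fh and abs(c - c0) < fw for r0, c0 in placed):
            continue
        placed.append((r, c))
        fields.append(
            HistologyLabelImage(
                data=image.data[r : r + fh, c : c + fw].copy(),
                legend=dict(image.legend),
                pixel_size_um=image.pixel_size_um,
            )
        )
    return fields
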