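"""Quantitative lung-CT densitometry.

Voxel attenuation in Hounsfield units (HU) maps linearly onto gas and
tissue content: −1000 HU is pure gas, 0 HU is water-density tissue.  A
masked lung volume therefore yields gas volume, tissue weight, mean
density, and the four canonical aeration compartments:

===============  ======================
hyper-aerated    −1000 to −901 HU
normally aerated  −900 to −501 HU
poorly aerated    −500 to −101 HU
non-aerated       −100 to +100 HU
===============  ======================

The module also provides the gravitational (sterno-vertebral) band
analysis, the ventro-dorsal density gradient, ten-slice sampling with
whole-lung extrapolation, and the CRALE criterion (mean lung density
≥ −500 HU).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AXIS_ROLES",
    "COMPARTMENTS",
    "CRALE_THRESHOLD_HU",
    "AerationReport",
    "BandStats",
    "CTVolume",
    "GravitationalProfile",
    "LungMask",
    "classify_hu",
    "classify_hu_array",
    "detect_crale",
    "extrapolate_whole_lung",
    "gravitational_profile",
    "mean_lung_density",
    "quantify",
    "select_slices",
    "slice_report",
    "ten_slice_report",
    "ventrodorsal_gradient",
    "voxel_gas_tissue",
]

AXIS_ROLES = ("craniocaudal", "ventrodorsal", "leftright")
COMPARTMENTS = ("hyper", "normal", "poor", "non")

#: CRALE criterion: mean lung density at or above this value flags edema.
CRALE_THRESHOLD_HU = -500.0

# Internal half-open compartment edges.  The printed integer ranges leave
# sub-integer values undefined; bins split at the midpoints so that every
# printed integer keeps its printed class (−901 → hyper, −900 → normal, …).
_EDGES = (-900.5, -500.5, -100.5)
_HU_MIN, _HU_MAX = -1000.0, 100.0


@dataclass(frozen=True)
class CTVolume:
    """A 3-D attenuation field with voxel spacing and axis-role labels.

    Parameters
    ----------
    data
        3-D array of attenuation values (HU).
    spacing_mm
        Voxel edge length per array axis, millimetres.
    axis_roles
        Anatomical role of each array axis; a permutation of
        ``("craniocaudal", "ventrodorsal", "leftright")``.  Along the
        ventro-dorsal axis the index increases toward dorsal (the
        dependent region in a supine subject).
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    axis_roles: tuple[str, str, str] = AXIS_ROLES

    def __post_init__(self) -> None:
        if np.ndim(self.data) != 3:
            raise ValueError("CT data must be 3-D")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be three positive lengths (mm)")
        if sorted(self.axis_roles) != sorted(AXIS_ROLES):
            raise ValueError(f"axis_roles must be a permutation of {AXIS_ROLES}")

    def axis(self, role: str) -> int:
        """Array axis index carrying the given anatomical role."""
        return self.axis_roles.index(role)

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0


@dataclass(frozen=True)
class LungMask:
    """Binary lung segmentation congruent with a :class:`CTVolume`.

    Masks are inputs (manual or synthetic); the exclusion flags record
    whether large vessels/bronchi and pleural effusion were removed at
    segmentation time, as the quantitative method assumes.
    """

    data: np.ndarray
    provenance: str = "synthetic"
    vessels_excluded: bool = True
    effusion_excluded: bool = True

    def __post_init__(self) -> None:
        if np.ndim(self.data) != 3:
            raise ValueError("mask must be 3-D")
        if self.data.dtype != bool:
            object.__setattr__(self, "data", self.data.astype(bool))
        if not self.data.any():
            raise ValueError("lung mask is empty")


@dataclass(frozen=True)
class AerationReport:
    """Per-lung quantitative CT summary."""

    lung_volume_ml: float
    gas_volume_ml: float
    weight_g: float
    mean_density_hu: float
    f_hyper: float
    f_normal: float
    f_poor: float
    f_non: float
    crale: bool
    n_voxels: int
    n_out_of_range: int = 0

    @property
    def fractions(self) -> dict[str, float]:
        return {
            "hyper": self.f_hyper,
            "normal": self.f_normal,
            "poor": self.f_poor,
            "non": self.f_non,
        }

    def as_dict(self) -> dict:
        d = {
            "lung_volume_ml": self.lung_volume_ml,
            "gas_volume_ml": self.gas_volume_ml,
            "weight_g": self.weight_g,
            "mean_density_hu": self.mean_density_hu,
            "f_hyper": self.f_hyper,
            "f_normal": self.f_normal,
            "f_poor": self.f_poor,
            "f_non": self.f_non,
            "crale": bool(self.crale),
            "n_voxels": int(self.n_voxels),
            "n_out_of_range": int(self.n_out_of_range),
        }
        return d


@dataclass(frozen=True)
class BandStats:
    """Summary of one gravitational band."""

    name: str
    mean_hu: float
    n_voxels: int
    fractions: dict[str, float]


@dataclass(frozen=True)
class GravitationalProfile:
    """Ventral → dorsal band statistics pooled over all slices."""

    bands: tuple[BandStats, ...]
    boundary_definition: str
    n_thin_slices: int = 0

    @property
    def band_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bands)

    def as_dict(self) -> dict:
        return {
            "boundary_definition": self.boundary_definition,
            "n_thin_slices": self.n_thin_slices,
            "bands": [
                {
                    "name": b.name,
                    "mean_hu": b.mean_hu,
                    "n_voxels": b.n_voxels,
                    "fractions": dict(b.fractions),
                }
                for b in self.bands
            ],
        }


def classify_hu(hu: float) -> str:
    """Classify one attenuation value into an aeration compartment.

    Returns one of ``"hyper"``, ``"normal"``, ``"poor"``, ``"non"`` or
    ``"out_of_range"`` (outside [−1000, +100] HU).  Boundaries between
    compartments sit at integer midpoints so every integer HU value falls
    in its printed range.
    """
    hu = float(hu)
    if not math.isfinite(hu):
        raise ValueError("HU value must be finite")
    if hu < _HU_MIN or hu > _HU_MAX:
        return "out_of_range"
    for edge, label in zip(_EDGES, COMPARTMENTS):
        if hu < edge:
            return label
    return COMPARTMENTS[-1]


def classify_hu_array(hu: np.ndarray) -> np.ndarray:
    """Vectorised :func:`classify_hu`: codes 0..3 (compartment order), −1 out of range."""
    hu = np.asarray(hu, dtype=float)
    if not np.all(np.isfinite(hu)):
        raise ValueError("HU values must be finite")
    codes = np.digitize(hu, _EDGES).astype(np.int8)
    codes[(hu < _HU_MIN) | (hu > _HU_MAX)] = -1
    return codes


def voxel_gas_tissue(hu):
    """Per-voxel gas and tissue fractions from attenuation.

    Gas fraction is ``−HU/1000`` with HU clipped to [−1000, 0]; tissue
    fraction is ``1 + HU/1000`` with HU clipped to [−1000, +100] and the
    result capped at 1.0, i.e. voxels denser than water count as pure
    tissue of density 1 g/mL.  Works element-wise on arrays.
    """
    hu = np.asarray(hu, dtype=float)
    gas = -np.clip(hu, -1000.0, 0.0) / 1000.0
    tissue = np.minimum(1.0 + np.clip(hu, -1000.0, 100.0) / 1000.0, 1.0)
    if gas.ndim == 0:
        return float(gas), float(tissue)
    return gas, tissue


def _check_pair(ct: CTVolume, mask: LungMask) -> None:
    if ct.data.shape != mask.data.shape:
        raise ValueError(
            f"CT shape {ct.data.shape} and mask shape {mask.data.shape} differ"
        )


def mean_lung_density(ct: CTVolume, mask: LungMask) -> float:
    """Mean lung density: per-slice means averaged with slice-area weights.

    Computed as the average of per-(cranio-caudal)-slice mean HU weighted
    by in-mask slice area.  With uniform voxel dimensions this equals the
    plain in-mask voxel mean; the equivalence is asserted.
    """
    _check_pair(ct, mask)
    cc = ct.axis("craniocaudal")
    m = np.moveaxis(mask.data, cc, 0)
    v = np.moveaxis(np.asarray(ct.data, dtype=float), cc, 0)
    counts = m.reshape(m.shape[0], -1).sum(axis=1)
    if counts.sum() == 0:
        raise ValueError("lung mask is empty")
    sums = np.where(m, v, 0.0).reshape(m.shape[0], -1).sum(axis=1)
    nz = counts > 0
    slice_means = sums[nz] / counts[nz]
    area_weighted = float(np.sum(slice_means * counts[nz]) / counts[nz].sum())
    plain = float(sums.sum() / counts.sum())
    assert math.isclose(area_weighted, plain, rel_tol=1e-9, abs_tol=1e-6)
    return area_weighted


def detect_crale(report: AerationReport | float) -> bool:
    """CRALE criterion: mean lung density ≥ −500 HU (inclusive)."""
    mean = report.mean_density_hu if isinstance(report, AerationReport) else float(report)
    return bool(mean >= CRALE_THRESHOLD_HU)


def _summarise(hu: np.ndarray, voxel_volume_ml: float, mean_hu: float) -> AerationReport:
    n = hu.size
    gas, tissue = voxel_gas_tissue(hu)
    gas_ml = float(np.sum(gas)) * voxel_volume_ml
    weight_g = float(np.sum(tissue)) * voxel_volume_ml * 1.0  # tissue density 1 g/mL
    codes = classify_hu_array(hu)
    in_range = codes >= 0
    n_out = int(n - in_range.sum())
    denom = max(int(in_range.sum()), 1)
    counts = np.bincount(codes[in_range], minlength=4)
    f = counts / denom
    return AerationReport(
        lung_volume_ml=n * voxel_volume_ml,
        gas_volume_ml=gas_ml,
        weight_g=weight_g,
        mean_density_hu=mean_hu,
        f_hyper=float(f[0]),
        f_normal=float(f[1]),
        f_poor=float(f[2]),
        f_non=float(f[3]),
        crale=detect_crale(mean_hu),
        n_voxels=int(n),
        n_out_of_range=n_out,
    )


def quantify(ct: CTVolume, mask: LungMask) -> AerationReport:
    """Whole-lung quantitative CT analysis over all masked voxels.

    Volume is voxel count × voxel volume; gas volume and weight come from
    the linear gas/tissue decomposition of each voxel's HU; compartment
    fractions are taken over in-range voxels (out-of-range voxels are
    clipped into gas/weight and reported via ``n_out_of_range``).
    """
    _check_pair(ct, mask)
    hu = np.asarray(ct.data, dtype=float)[mask.data]
    if hu.size == 0:
        raise ValueError("lung mask is empty")
    return _summarise(hu, ct.voxel_volume_ml, mean_lung_density(ct, mask))


def slice_report(ct: CTVolume, mask: LungMask, index: int) -> AerationReport:
    """Quantitative analysis of one cranio-caudal slice."""
    _check_pair(ct, mask)
    cc = ct.axis("craniocaudal")
    m = np.take(mask.data, index, axis=cc)
    v = np.take(np.asarray(ct.data, dtype=float), index, axis=cc)
    hu = v[m]
    if hu.size == 0:
        raise ValueError(f"slice {index} contains no masked voxels")
    return _summarise(hu, ct.voxel_volume_ml, float(hu.mean()))


def gravitational_profile(
    ct: CTVolume,
    mask: LungMask,
    n_bands: int = 3,
    band_names: Sequence[str] = ("ventral", "ventrodorsal", "dorsal"),
) -> GravitationalProfile:
    """Split the lung into sterno-vertebral bands of equal height.

    Within every cranio-caudal slice the in-mask ventro-dorsal extent is
    divided into ``n_bands`` equal-height bands (fractional boundaries, so
    no remainder rows exist); voxels are pooled across slices per band.
    Slices thinner than ``n_bands`` rows contribute only to the bands they
    span and are counted in ``n_thin_slices``.
    """
    _check_pair(ct, mask)
    if n_bands < 2:
        raise ValueError("need at least 2 bands")
    if len(band_names) != n_bands:
        band_names = tuple(f"band{i}" for i in range(n_bands))
    cc = ct.axis("craniocaudal")
    vd = ct.axis("ventrodorsal")
    # canonical order (cc, vd, lr)
    order = [cc, vd, ({0, 1, 2} - {cc, vd}).pop()]
    m = np.transpose(mask.data, order)
    v = np.transpose(np.asarray(ct.data, dtype=float), order)

    hu_sum = np.zeros(n_bands)
    n_vox = np.zeros(n_bands, dtype=np.int64)
    comp = np.zeros((n_bands, 4), dtype=np.int64)
    n_thin = 0
    for k in range(m.shape[0]):
        ms = m[k]
        if not ms.any():
            continue
        rows = np.where(ms.any(axis=1))[0]
        lo, hi = rows[0], rows[-1]
        extent = hi - lo + 1
        if extent < n_bands:
            n_thin += 1
        row_idx, col_idx = np.nonzero(ms)
        band = np.minimum(
            (n_bands * (row_idx - lo)) // extent, n_bands - 1
        ).astype(np.int64)
        hu = v[k][row_idx, col_idx]
        np.add.at(hu_sum, band, hu)
        np.add.at(n_vox, band, 1)
        codes = classify_hu_array(hu)
        ok = codes >= 0
        np.add.at(comp, (band[ok], codes[ok].astype(np.int64)), 1)

    bands = []
    for b in range(n_bands):
        n = int(n_vox[b])
        fr = comp[b] / max(comp[b].sum(), 1)
        bands.append(
            BandStats(
                name=band_names[b],
                mean_hu=float(hu_sum[b] / n) if n else float("nan"),
                n_voxels=n,
                fractions={c: float(fr[i]) for i, c in enumerate(COMPARTMENTS)},
            )
        )
    return GravitationalProfile(
        bands=tuple(bands),
        boundary_definition=(
            f"per-slice in-mask ventro-dorsal extent split into {n_bands} "
            "equal-height bands (fractional boundaries)"
        ),
        n_thin_slices=n_thin,
    )


def ventrodorsal_gradient(profile: GravitationalProfile) -> float:
    """Ventro-dorsal density gradient: (ventral − dorsal)/ventral × 100.

    Applied to signed HU band means; a denser (less negative) dorsal band
    with a negative ventral mean yields a positive percentage.
    """
    ventral = profile.bands[0].mean_hu
    dorsal = profile.bands[-1].mean_hu
    if ventral == 0:
        raise ValueError("ventral band mean is 0 HU; gradient undefined")
    return (ventral - dorsal) / ventral * 100.0


def select_slices(mask: LungMask, cc_axis: int, n: int = 10) -> list[int]:
    """Select the most cranial and caudal masked slices plus ``n−2`` evenly
    spaced slices between them.

    Ideal (real-valued) positions are mapped to the nearest unused integer
    index, ties resolved toward the cranial end, which both implements
    round-half-cranial and re-spreads collisions deterministically.
    """
    m = np.moveaxis(mask.data, cc_axis, 0)
    present = np.where(m.reshape(m.shape[0], -1).any(axis=1))[0]
    first, last = int(present[0]), int(present[-1])
    span = last - first + 1
    if span < n:
        raise ValueError(
            f"mask spans only {span} slices; choose n ≤ {span}"
        )
    targets = [first + (last - first) * k / (n - 1) for k in range(n)]
    chosen: set[int] = set()
    for r in targets:
        best = None
        for i in range(first, last + 1):
            if i in chosen:
                continue
            d = abs(i - r)
            if best is None or d < best[0] - 1e-12:
                best = (d, i)
        chosen.add(best[1])
    return sorted(chosen)


def extrapolate_whole_lung(
    slice_reports: Sequence[AerationReport],
    positions_mm: Sequence[float],
    thickness_mm: float,
    span_mm: tuple[float, float],
) -> AerationReport:
    """Extrapolate sampled-slice quantities to the whole lung.

    Each sampled slice is converted to linear densities (mL gas per mm,
    g per mm, mm² area, HU·mm² and per-compartment area), linearly
    interpolated along the cranio-caudal axis (constant extension beyond
    the outermost samples) and integrated by the trapezoid rule over the
    full mask span — exact whenever per-slice quantities vary linearly
    between samples.
    """
    if len(slice_reports) < 2:
        raise ValueError("need at least 2 sampled slices")
    z = np.asarray(positions_mm, dtype=float)
    if np.any(np.diff(z) <= 0):
        raise ValueError("slice positions must be strictly increasing")
    lo, hi = span_mm
    if z[0] < lo - 1e-9 or z[-1] > hi + 1e-9:
        raise ValueError("slice positions fall outside the stated span")
    th = float(thickness_mm)

    def lin(values: np.ndarray) -> float:
        knots = np.concatenate(([lo], z, [hi]))
        vals = np.interp(knots, z, values)  # constant beyond end samples
        return float(np.trapezoid(vals, knots))

    gas = lin(np.array([r.gas_volume_ml / th for r in slice_reports]))
    weight = lin(np.array([r.weight_g / th for r in slice_reports]))
    vol = lin(np.array([r.lung_volume_ml / th for r in slice_reports]))
    count = lin(np.array([r.n_voxels / th for r in slice_reports]))
    area_int = vol  # mL·(mm/mm) — used only as density weight
    hu_int = lin(
        np.array([r.mean_density_hu * r.lung_volume_ml / th for r in slice_reports])
    )
    mean_hu = hu_int / area_int
    f = {}
    for name in COMPARTMENTS:
        f[name] = lin(
            np.array(
                [r.fractions[name] * r.lung_volume_ml / th for r in slice_reports]
            )
        ) / area_int
    return AerationReport(
        lung_volume_ml=vol,
        gas_volume_ml=gas,
        weight_g=weight,
        mean_density_hu=mean_hu,
        f_hyper=f["hyper"],
        f_normal=f["normal"],
        f_poor=f["poor"],
        f_non=f["non"],
        crale=detect_crale(mean_hu),
        n_voxels=int(round(count)),
        n_out_of_range=int(sum(r.n_out_of_range for r in slice_reports)),
    )


def ten_slice_report(ct: CTVolume, mask: LungMask, n: int = 10) -> AerationReport:
    """Sampled-slice whole-lung estimate reproducing the ten-slice protocol.

    Selects ``n`` slices with :func:`select_slices`, analyses each with the
    standard per-slice densitometry, and extrapolates to the whole lung
    with :func:`extrapolate_whole_lung`.
    """
    cc = ct.axis("craniocaudal")
    th = ct.spacing_mm[cc]
    idx = select_slices(mask, cc, n=n)
    reports = [slice_report(ct, mask, i) for i in idx]
    positions = [(i + 0.5) * th for i in idx]
    span = (idx[0] * th, (idx[-1] + 1) * th)
    return extrapolate_whole_lung(reports, positions, th, span)
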