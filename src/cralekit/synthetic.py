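"""Synthetic study-shaped inputs with exact ground truth.

Every analysis stage of the package can be exercised without any acquired
data: this module generates

- **CT phantoms** — two ellipsoidal lungs in an air background with a
  soft-tissue rim, a ventro-dorsal density gradient (dorsal = dependent,
  index increasing toward dorsal), an edema shift of the whole HU
  distribution, and additive HU noise.  The accompanying
  :class:`PhantomTruth` is computed analytically from the noiseless field.
- **CPR pressure waveforms** — unsynchronized volume-controlled
  ventilation (500 mL at 10/min, I:E 1:1, ZEEP by default) superimposed
  with a raised-cosine compression pulse train (102/min, duty cycle 0.5,
  the rate/duty of a piston compression device), ≥ 5 s occlusion
  maneuvers, and a two-compartment (lung + chest wall) pressure model:
  ``Pes = V/Ccw + compressions`` and ``Paw = R·V̇ + V/CL + Pes + PEEP``.
- **blood-gas panels** — a forward model of the Berggren venous-admixture
  equation, exactly invertible at zero noise.
- **histology label images** — blob-textured class maps whose realized
  pixel fractions are recorded as ground truth.
- **cohorts** — per-animal baseline/post phantoms, compression epochs
  alternating mechanical/manual, blood-gas panels and histology, with
  edema severity coupled to compression amplitude by construction.

All randomness flows from one seeded generator per call; identical
parameters and seed give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from cralekit import ct as ctmod
from cralekit import oxygen as oxmod
from cralekit.mechanics import Epoch, PressureTrace
from cralekit.stereology import CLASS_NAMES, DEFAULT_LEGEND, HistologyLabelImage

__all__ = [
    "CohortAnimal",
    "CohortBundle",
    "CohortConfig",
    "EpochSpec",
    "GasExchangeParams",
    "GasTruth",
    "HistologyTruth",
    "OcclusionSpec",
    "PhantomCTParams",
    "PhantomTruth",
    "WaveformParams",
    "WaveformTruth",
    "gen_bloodgas_panel",
    "gen_cohort",
    "gen_ct_phantom",
    "gen_histology_image",
    "gen_pressure_traces",
]


# --------------------------------------------------------------------------
# CT phantoms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomCTParams:
    """Parameters of the two-ellipsoid lung phantom.

    ``base_mean_hu`` is the target in-mask mean of the noiseless field at
    zero edema shift (the gradient is centred so the mean is preserved);
    ``vd_slope_hu`` is the HU change across the normalized ventro-dorsal
    depth 0 → 1 of the lung mask; ``edema_shift_hu`` shifts the whole
    distribution toward water density.  Coordinates are millimetres from
    the grid centre; axis order is (cranio-caudal, ventro-dorsal,
    left-right) with the ventro-dorsal index increasing toward dorsal.
    """

    shape: tuple[int, int, int] = (96, 64, 80)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    lung_centers_mm: tuple[tuple[float, float, float], ...] = (
        (0.0, 0.0, -35.0),
        (0.0, 0.0, 35.0),
    )
    semi_axes_mm: tuple[tuple[float, float, float], ...] = (
        (80.0, 45.0, 25.0),
        (80.0, 45.0, 25.0),
    )
    base_mean_hu: float = -549.0
    vd_slope_hu: float = 150.0
    edema_shift_hu: float = 0.0
    noise_sd_hu: float = 5.0
    rim_hu: float = 40.0
    background_hu: float = -1000.0
    rim_thickness_mm: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape):
            raise ValueError("grid shape must be positive")
        if self.edema_shift_hu < 0:
            raise ValueError("edema shift must be ≥ 0 HU")
        if len(self.lung_centers_mm) != len(self.semi_axes_mm):
            raise ValueError("one semi-axis triple per lung centre is required")
        half = [n * s / 2.0 for n, s in zip(self.shape, self.spacing_mm)]
        for li, (c, a) in enumerate(zip(self.lung_centers_mm, self.semi_axes_mm)):
            for ax in range(3):
                if abs(c[ax]) + a[ax] > half[ax]:
                    raise ValueError(
                        f"lung {li} ellipsoid exceeds the grid along the "
                        f"{ctmod.AXIS_ROLES[ax]} axis"
                    )


@dataclass(frozen=True)
class PhantomTruth:
    """Analytic ground truth of a phantom, from the noiseless field."""

    lung_volume_ml: float
    gas_volume_ml: float
    weight_g: float
    mean_density_hu: float
    band_mean_hu: tuple[float, float, float]
    compartment_fractions: dict[str, float]
    n_voxels: int
    seed: int

    def as_dict(self) -> dict:
        return {
            "lung_volume_ml": self.lung_volume_ml,
            "gas_volume_ml": self.gas_volume_ml,
            "weight_g": self.weight_g,
            "mean_density_hu": self.mean_density_hu,
            "band_mean_hu": list(self.band_mean_hu),
            "compartment_fractions": dict(self.compartment_fractions),
            "n_voxels": self.n_voxels,
            "seed": self.seed,
        }


def gen_ct_phantom(
    params: PhantomCTParams,
) -> tuple[ctmod.CTVolume, ctmod.LungMask, PhantomTruth]:
    """Generate a lung CT phantom, its mask, and analytic ground truth.

    Outside the lungs the volume is air (−1000 HU) with a +40 HU
    soft-tissue rim around the lungs, so mask-based analysis is honest
    about what it excludes.  Truth is computed from the noiseless in-mask
    field before noise is added; noise is then applied in-mask only and
    the result clipped to [−1000, +100] HU.
    """
    rng = np.random.default_rng(params.seed)
    shape = params.shape
    spacing = params.spacing_mm
    coords = [
        (np.arange(n) + 0.5) * s - n * s / 2.0 for n, s in zip(shape, spacing)
    ]
    cc, vd, lr = np.meshgrid(*coords, indexing="ij", sparse=True)

    mask = np.zeros(shape, dtype=bool)
    for c, a in zip(params.lung_centers_mm, params.semi_axes_mm):
        mask |= (
            ((cc - c[0]) / a[0]) ** 2
            + ((vd - c[1]) / a[1]) ** 2
            + ((lr - c[2]) / a[2]) ** 2
        ) <= 1.0
    if not mask.any():
        raise ValueError("phantom mask is empty; enlarge the ellipsoids")

    # normalized ventro-dorsal depth over the mask's bounding extent
    rows = np.where(mask.any(axis=(0, 2)))[0]
    lo, hi = rows[0], rows[-1]
    extent = max(hi - lo, 1)
    depth_row = np.clip((np.arange(shape[1]) - lo) / extent, 0.0, 1.0)
    depth = np.broadcast_to(depth_row[None, :, None], shape)
    depth_mean = float(depth[mask].mean())

    clean = np.full(shape, params.background_hu, dtype=float)
    # soft-tissue rim via an anisotropy-aware distance to the lungs
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    clean[(dist <= params.rim_thickness_mm) & ~mask] = params.rim_hu
    field_in = (
        params.base_mean_hu
        + params.edema_shift_hu
        + params.vd_slope_hu * (depth[mask] - depth_mean)
    )
    field_in = np.clip(field_in, -1000.0, 100.0)
    clean[mask] = field_in

    truth = _phantom_truth(clean, mask, spacing, params.seed)

    data = clean.copy()
    if params.noise_sd_hu > 0:
        data[mask] = np.clip(
            field_in + rng.normal(0.0, params.noise_sd_hu, size=field_in.shape),
            -1000.0,
            100.0,
        )
    vol = ctmod.CTVolume(data=data, spacing_mm=spacing)
    return vol, ctmod.LungMask(data=mask, provenance="synthetic"), truth


def _phantom_truth(
    clean: np.ndarray,
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    seed: int,
) -> PhantomTruth:
    vv = float(np.prod(spacing)) / 1000.0
    hu = clean[mask]
    gas, tissue = ctmod.voxel_gas_tissue(hu)
    vol = ctmod.CTVolume(data=clean, spacing_mm=spacing)
    msk = ctmod.LungMask(data=mask, provenance="synthetic")
    profile = ctmod.gravitational_profile(vol, msk)
    codes = ctmod.classify_hu_array(hu)
    counts = np.bincount(codes[codes >= 0], minlength=4)
    frac = counts / max(counts.sum(), 1)
    return PhantomTruth(
        lung_volume_ml=hu.size * vv,
        gas_volume_ml=float(gas.sum()) * vv,
        weight_g=float(tissue.sum()) * vv,
        mean_density_hu=float(hu.mean()),
        band_mean_hu=tuple(b.mean_hu for b in profile.bands),
        compartment_fractions={
            c: float(f) for c, f in zip(ctmod.COMPARTMENTS, frac)
        },
        n_voxels=int(hu.size),
        seed=seed,
    )


# --------------------------------------------------------------------------
# CPR pressure waveforms
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OcclusionSpec:
    """An airway occlusion maneuver of at least 5 s."""

    start_s: float
    duration_s: float = 5.5
    kind: str = "insp"  # insp | exp | test

    def __post_init__(self) -> None:
        if self.duration_s < 5.0:
            raise ValueError("occlusion maneuvers must last at least 5 s")
        if self.kind not in ("insp", "exp", "test"):
            raise ValueError(f"unknown occlusion kind {self.kind!r}")


@dataclass(frozen=True)
class EpochSpec:
    """A labelled epoch of the simulated protocol.

    ``comp_amplitude_cmh2o`` overrides the default compression amplitude
    for chest-compression epochs (mechanical vs manual strategies differ
    only in this amplitude here).
    """

    label: str
    start_s: float
    end_s: float
    kind: str
    comp_amplitude_cmh2o: float | None = None


@dataclass(frozen=True)
class WaveformParams:
    """CPR waveform generator parameters.

    Compression defaults follow a piston compression device (102/min, duty
    cycle 0.50); ventilation defaults follow the intra-CPR ventilator
    settings (VT 500 mL, 10/min, I:E 1:1, ZEEP).  The compression pulse
    is a raised cosine whose amplitude is expressed directly in cmH2O of
    esophageal pressure.  Ventilation and compressions run on independent
    phases (unsynchronized).
    """

    fs_hz: float = 250.0
    duration_s: float = 60.0
    comp_rate_per_min: float = 102.0
    comp_amplitude_cmh2o: float = 15.0
    comp_duty: float = 0.5
    comp_phase_s: float = 0.0
    vent_rate_per_min: float = 10.0
    vt_ml: float = 500.0
    ie_ratio: float = 1.0
    peep_cmh2o: float = 0.0
    vent_phase_s: float = 0.0
    resistance_cmh2o_s_l: float = 10.0
    cl_ml_cmh2o: float = 50.0
    ccw_ml_cmh2o: float = 100.0
    occlusions: tuple[OcclusionSpec, ...] = ()
    epochs: tuple[EpochSpec, ...] = ()
    include_vascular: bool = False
    ao_dia_mmhg: float = 20.0
    ao_pulse_mmhg: float = 60.0
    ra_mean_mmhg: float = 8.0
    ra_pulse_mmhg: float = 55.0
    noise_sd_cmh2o: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.comp_rate_per_min <= 0 or self.vent_rate_per_min <= 0:
            raise ValueError("rates must be positive")
        if self.cl_ml_cmh2o <= 0 or self.ccw_ml_cmh2o <= 0:
            raise ValueError("compliances must be positive")
        if self.fs_hz < 20.0 * self.comp_rate_per_min / 60.0:
            raise ValueError(
                "sampling rate below 20× the compression frequency would alias "
                "the compression waveform"
            )


@dataclass(frozen=True)
class WaveformTruth:
    """Generator ground truth for a waveform trace."""

    cl_ml_cmh2o: float
    ccw_ml_cmh2o: float
    crs_ml_cmh2o: float
    vt_ml: float
    peep_cmh2o: float
    comp_rate_per_min: float
    epoch_amplitude: dict[str, float]
    cycle_swings: dict[str, np.ndarray]
    epoch_mean_swing: dict[str, float]
    seed: int


def _vent_volume(params: WaveformParams, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Triangular volume-controlled volume signal and its flow (mL, mL/s)."""
    period = 60.0 / params.vent_rate_per_min
    ti = period * params.ie_ratio / (1.0 + params.ie_ratio)
    te = period - ti
    tau = np.mod(t - params.vent_phase_s, period)
    insp = tau < ti
    v = np.where(insp, params.vt_ml * tau / ti, params.vt_ml * (1.0 - (tau - ti) / te))
    flow = np.where(insp, params.vt_ml / ti, -params.vt_ml / te)
    return v, flow


def _pulse_shape(params: WaveformParams, t: np.ndarray) -> np.ndarray:
    """Unit raised-cosine compression pulse train (0..1)."""
    tc = 60.0 / params.comp_rate_per_min
    phase = np.mod(t - params.comp_phase_s, tc)
    width = params.comp_duty * tc
    return np.where(
        phase < width, 0.5 * (1.0 - np.cos(2.0 * np.pi * phase / width)), 0.0
    )


def _amplitude_profile(
    params: WaveformParams, t: np.ndarray, epochs: Sequence[Epoch],
    amp_by_label: dict[str, float],
) -> np.ndarray:
    amp = np.zeros_like(t)
    for e in epochs:
        if e.kind in ("cc_mechanical", "cc_manual", "occlusion_test"):
            a = amp_by_label.get(e.label, params.comp_amplitude_cmh2o)
            amp[(t >= e.start_s) & (t < e.end_s)] = a
    return amp


def gen_pressure_traces(params: WaveformParams) -> tuple[PressureTrace, WaveformTruth]:
    """Generate Paw/Pes (and optional vascular) traces with ground truth.

    The truth records the compliances, the series respiratory-system
    compliance Crs = CL·Ccw/(CL+Ccw), and the exact per-cycle Pes swing
    measured on the noiseless signal within each chest-compression epoch.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.fs_hz))
    t = np.arange(n) / params.fs_hz

    epochs = [Epoch(e.label, e.start_s, e.end_s, e.kind) for e in params.epochs]
    amp_by_label = {
        e.label: e.comp_amplitude_cmh2o
        for e in params.epochs
        if e.comp_amplitude_cmh2o is not None
    }
    for i, occ in enumerate(params.occlusions):
        kind = {"insp": "occlusion_insp", "exp": "occlusion_exp", "test": "occlusion_test"}[
            occ.kind
        ]
        epochs.append(
            Epoch(f"occl_{occ.kind}_{i}", occ.start_s, occ.start_s + occ.duration_s, kind)
        )
    if not any(e.kind in ("cc_mechanical", "cc_manual") for e in epochs):
        has_occl = [e for e in epochs if e.kind.startswith("occlusion")]
        if not has_occl and params.comp_amplitude_cmh2o >= 0:
            epochs.append(Epoch("cc", 0.0, params.duration_s, "cc_mechanical"))

    v, flow = _vent_volume(params, t)
    # occlusions override the ventilator pattern: no flow, volume held
    for e in epochs:
        w = (t >= e.start_s) & (t < e.end_s)
        if e.kind == "occlusion_insp":
            v[w], flow[w] = params.vt_ml, 0.0
        elif e.kind == "occlusion_exp":
            v[w], flow[w] = 0.0, 0.0
        elif e.kind == "occlusion_test":
            idx = np.nonzero(w)[0]
            if idx.size:
                v[w], flow[w] = v[idx[0]], 0.0

    pulse = _pulse_shape(params, t)
    amp = _amplitude_profile(params, t, epochs, amp_by_label)
    pes_clean = v / params.ccw_ml_cmh2o + amp * pulse
    paw_clean = (
        params.resistance_cmh2o_s_l * flow / 1000.0
        + v / params.cl_ml_cmh2o
        + pes_clean
        + params.peep_cmh2o
    )

    pes = pes_clean + rng.normal(0.0, params.noise_sd_cmh2o, n) if params.noise_sd_cmh2o else pes_clean.copy()
    paw = paw_clean + rng.normal(0.0, params.noise_sd_cmh2o, n) if params.noise_sd_cmh2o else paw_clean.copy()

    pao = pra = None
    if params.include_vascular:
        active = amp > 0
        pao = params.ao_dia_mmhg + params.ao_pulse_mmhg * pulse * active
        pra = params.ra_mean_mmhg + params.ra_pulse_mmhg * pulse * active

    trace = PressureTrace(
        fs_hz=params.fs_hz, paw=paw, pes=pes, pao=pao, pra=pra, epochs=tuple(epochs)
    )

    # exact per-cycle swings on the noiseless Pes
    tc = 60.0 / params.comp_rate_per_min
    cycle_swings: dict[str, np.ndarray] = {}
    epoch_mean: dict[str, float] = {}
    for e in epochs:
        if e.kind not in ("cc_mechanical", "cc_manual"):
            continue
        first = math.ceil((e.start_s - params.comp_phase_s) / tc - 0.5 + 1e-9)
        swings = []
        m = first
        while True:
            peak = params.comp_phase_s + (m + params.comp_duty / 2.0) * tc
            if peak >= e.end_s:
                break
            w0 = max(peak - tc / 2.0, e.start_s)
            w1 = min(peak + tc / 2.0, e.end_s)
            sl = slice(int(np.ceil(w0 * params.fs_hz)), int(w1 * params.fs_hz))
            seg = pes_clean[sl]
            if seg.size:
                swings.append(float(seg.max() - seg.min()))
            m += 1
        if swings:
            cycle_swings[e.label] = np.asarray(swings)
            epoch_mean[e.label] = float(np.mean(swings))

    cl, ccw = params.cl_ml_cmh2o, params.ccw_ml_cmh2o
    truth = WaveformTruth(
        cl_ml_cmh2o=cl,
        ccw_ml_cmh2o=ccw,
        crs_ml_cmh2o=cl * ccw / (cl + ccw),
        vt_ml=params.vt_ml,
        peep_cmh2o=params.peep_cmh2o,
        comp_rate_per_min=params.comp_rate_per_min,
        epoch_amplitude={
            e.label: amp_by_label.get(e.label, params.comp_amplitude_cmh2o)
            for e in epochs
            if e.kind in ("cc_mechanical", "cc_manual")
        },
        cycle_swings=cycle_swings,
        epoch_mean_swing=epoch_mean,
        seed=params.seed,
    )
    return trace, truth


# --------------------------------------------------------------------------
# Blood-gas panels (Berggren forward model)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GasExchangeParams:
    """Forward-model parameters for one blood-gas panel."""

    qs_qt: float = 0.3
    co_l_min: float = 3.0
    hb_g_dl: float = 9.0
    fio2: float = 1.0
    vo2_ml_min: float = 120.0
    paco2_mmhg: float = 40.0
    pvco2_mmhg: float = 60.0
    capillary_saturation: float = 1.0
    lactate_mmol_l: float | None = None
    noise_sd_so2: float = 0.0
    noise_sd_po2_mmhg: float = 0.0
    timepoint: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.qs_qt <= 1.0:
            raise ValueError("shunt fraction must lie in [0, 1]")
        if self.co_l_min <= 0:
            raise ValueError("cardiac output must be positive")
        if self.hb_g_dl <= 0:
            raise ValueError("hemoglobin must be positive")
        if self.vo2_ml_min < 0:
            raise ValueError("VO2 must be non-negative")


@dataclass(frozen=True)
class GasTruth:
    """Generator ground truth for a blood-gas panel."""

    qs_qt: float
    co_l_min: float
    vo2_ml_min: float
    do2_ml_min: float
    cao2_ml_dl: float
    cvo2_ml_dl: float
    cco2_ml_dl: float
    seed: int


def gen_bloodgas_panel(
    params: GasExchangeParams,
    constants: oxmod.O2Constants | None = None,
) -> tuple[oxmod.BloodGasPanel, oxmod.O2Transport, GasTruth]:
    """Generate a blood-gas panel by inverting the Berggren system.

    The admixture equation CaO2 = Qs/Qt·CvO2 + (1 − Qs/Qt)·CcO2 and the
    Fick relation CvO2 = CaO2 − VO2/(10·CO) are two linear equations
    solved in closed form; the emitted saturations/tensions reproduce the
    exact contents, so zero-noise panels invert exactly to the true shunt.
    Returns the panel, the transport values recomputed from the noiseless
    panel, and the truth record.
    """
    consts = constants or oxmod.O2Constants(
        capillary_saturation=params.capillary_saturation
    )
    rng = np.random.default_rng(params.seed)
    s = params.qs_qt
    v = params.vo2_ml_min / (10.0 * params.co_l_min)
    pao2_alv = oxmod.alveolar_po2(params.fio2, params.paco2_mmhg, consts)
    cco2 = oxmod.capillary_content(params.fio2, params.paco2_mmhg, params.hb_g_dl, consts)
    if s >= 1.0:
        if params.vo2_ml_min > 0:
            raise ValueError(
                "a total shunt (Qs/Qt = 1) forces CaO2 = CvO2 and cannot "
                "sustain a positive VO2"
            )
        cao2 = cco2
    else:
        cao2 = cco2 - s * v / (1.0 - s)
    cvo2 = cao2 - v
    if cvo2 <= 0:
        raise ValueError("infeasible VO2: mixed-venous O2 content would be ≤ 0")

    k1 = consts.hb_binding_ml_g * params.hb_g_dl
    k2 = consts.solubility_ml_dl_mmhg

    def emit(content: float, po2_guess: float) -> tuple[float, float]:
        """Saturation + PO2 pair reproducing the content exactly."""
        so2 = (content - k2 * po2_guess) / k1
        po2 = po2_guess
        if so2 > 1.0:
            so2 = 1.0
            po2 = (content - k1) / k2
        elif so2 < 0.0:
            so2 = 0.0
            po2 = content / k2
        return so2, max(po2, 1e-6)

    sao2, pao2 = emit(cao2, pao2_alv * (1.0 - s) + 40.0 * s)
    svo2, pvo2 = emit(cvo2, 40.0)

    noiseless = oxmod.BloodGasPanel(
        pao2_mmhg=pao2,
        paco2_mmhg=params.paco2_mmhg,
        pvo2_mmhg=pvo2,
        pvco2_mmhg=params.pvco2_mmhg,
        sao2=sao2,
        svo2=svo2,
        hb_g_dl=params.hb_g_dl,
        fio2=params.fio2,
        lactate_mmol_l=params.lactate_mmol_l,
        timepoint=params.timepoint,
    )
    try:
        reference = oxmod.transport_panel(noiseless, params.co_l_min, consts)
    except ValueError:
        # degenerate total shunt: CcO2 = CvO2 makes the Berggren ratio 0/0,
        # so report the constructed shunt directly
        reference = oxmod.O2Transport(
            cao2_ml_dl=cao2,
            cvo2_ml_dl=cvo2,
            cco2_ml_dl=cco2,
            do2_ml_min=oxmod.oxygen_delivery(params.co_l_min, cao2),
            vo2_ml_min=params.vo2_ml_min,
            qs_qt=s,
            shunt_clipped=False,
            vo2_implausible=False,
            constants=consts.as_dict(),
        )

    panel = noiseless
    if params.noise_sd_so2 or params.noise_sd_po2_mmhg:
        panel = replace(
            noiseless,
            sao2=float(np.clip(sao2 + rng.normal(0, params.noise_sd_so2), 0.0, 1.0)),
            svo2=float(np.clip(svo2 + rng.normal(0, params.noise_sd_so2), 0.0, 1.0)),
            pao2_mmhg=float(max(pao2 + rng.normal(0, params.noise_sd_po2_mmhg), 1.0)),
            pvo2_mmhg=float(max(pvo2 + rng.normal(0, params.noise_sd_po2_mmhg), 1.0)),
        )
    truth = GasTruth(
        qs_qt=s,
        co_l_min=params.co_l_min,
        vo2_ml_min=params.vo2_ml_min,
        do2_ml_min=oxmod.oxygen_delivery(params.co_l_min, cao2),
        cao2_ml_dl=cao2,
        cvo2_ml_dl=cvo2,
        cco2_ml_dl=cco2,
        seed=params.seed,
    )
    return panel, reference, truth


# --------------------------------------------------------------------------
# Histology label images
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HistologyTruth:
    """Per-class area fractions (airspace, acinar, non-acinar, hemorrhage)."""

    airspace: float
    acinar_tissue: float
    nonacinar_tissue: float = 0.0
    hemorrhage: float = 0.0

    def __post_init__(self) -> None:
        fr = self.as_tuple()
        if any(f < 0 or f > 1 for f in fr):
            raise ValueError("class fractions must lie in [0, 1]")
        if abs(sum(fr) - 1.0) > 1e-6:
            raise ValueError("class fractions must sum to 1")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.airspace, self.acinar_tissue, self.nonacinar_tissue, self.hemorrhage)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(CLASS_NAMES, self.as_tuple()))


def gen_histology_image(
    width: int,
    height: int,
    truth: HistologyTruth,
    texture_scale: float = 16.0,
    seed: int = 0,
) -> tuple[HistologyLabelImage, HistologyTruth]:
    """Generate a blob-textured class map hitting the requested fractions.

    A Gaussian-smoothed noise field is quantile-thresholded at the
    requested cumulative fractions; its level sets give contiguous blobs
    per class.  The *realized* pixel fractions (after rounding to whole
    pixels) are recorded back into the returned truth.
    """
    rng = np.random.default_rng(seed)
    u = ndimage.gaussian_filter(rng.standard_normal((height, width)), texture_scale)
    order = np.argsort(u, axis=None, kind="stable")
    total = width * height
    requested = truth.as_tuple()
    counts = [int(round(f * total)) for f in requested]
    counts[-1] = total - sum(counts[:-1])
    if counts[-1] < 0:
        # rounding overshoot; shave the largest class
        counts[int(np.argmax(counts[:-1]))] += counts[-1]
        counts[-1] = 0
    labels = np.empty(total, dtype=np.uint8)
    start = 0
    for code, c in enumerate(counts):
        labels[order[start : start + c]] = code
        start += c
    img = HistologyLabelImage(
        data=labels.reshape(height, width), legend=dict(DEFAULT_LEGEND)
    )
    realized = np.bincount(img.data.ravel(), minlength=4) / total
    realized_truth = HistologyTruth(*[float(f) for f in realized])
    return img, realized_truth


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Study-timeline configuration for synthetic cohorts.

    The protocol shape mirrors the experiment — baseline CT, chest
    compressions alternating mechanical/manual strategies, blood gases
    during CC and after ROSC, post CT, necropsy — with epoch durations
    scaled down for desk-scale analysis.  Edema severity is coupled to
    the per-animal compression amplitude by construction
    (``edema = edema_intercept + edema_per_amp × amplitude``), which is
    the dependency the downstream association analysis should recover.
    """

    phantom_shape: tuple[int, int, int] = (64, 48, 48)
    phantom_spacing_mm: tuple[float, float, float] = (3.0, 2.5, 2.5)
    base_mean_hu: float = -549.0
    vd_slope_hu: float = 150.0
    noise_sd_hu: float = 5.0
    n_cc_epochs: int = 5
    epoch_duration_s: float = 30.0
    fs_hz: float = 100.0
    amplitude_range_cmh2o: tuple[float, float] = (14.0, 30.0)
    manual_amplitude_factor: float = 0.55
    edema_intercept_hu: float = 36.0
    edema_per_amp_hu: float = 8.0
    edema_jitter_sd_hu: float = 10.0
    edema_scale: float = 1.0
    cl_baseline_ml_cmh2o: float = 50.0
    ccw_ml_cmh2o: float = 100.0
    vt_ml: float = 500.0
    histology_size: int = 256


@dataclass(frozen=True)
class CohortAnimal:
    """All generated inputs and truths for one animal."""

    subject_id: str
    baseline_ct: ctmod.CTVolume
    baseline_mask: ctmod.LungMask
    baseline_truth: PhantomTruth
    post_ct: ctmod.CTVolume
    post_mask: ctmod.LungMask
    post_truth: PhantomTruth
    cc_trace: PressureTrace
    cc_truth: WaveformTruth
    baseline_occl_trace: PressureTrace
    baseline_occl_truth: WaveformTruth
    post_occl_trace: PressureTrace
    post_occl_truth: WaveformTruth
    vt_ml: float
    gas_panels: tuple[tuple[str, oxmod.BloodGasPanel, float, GasTruth], ...]
    histology: HistologyLabelImage
    histology_truth: HistologyTruth
    ex_vivo_weight_g: float
    body_weight_kg: float
    wet_mass_g: float
    dry_mass_g: float
    mech_amplitude_cmh2o: float
    edema_shift_hu: float


@dataclass(frozen=True)
class CohortBundle:
    animals: tuple[CohortAnimal, ...]
    config: CohortConfig
    seed: int


def _occlusion_trace_params(
    config: CohortConfig, cl: float, seed: int
) -> WaveformParams:
    return WaveformParams(
        fs_hz=config.fs_hz,
        duration_s=18.0,
        comp_amplitude_cmh2o=0.0,
        vt_ml=config.vt_ml,
        cl_ml_cmh2o=cl,
        ccw_ml_cmh2o=config.ccw_ml_cmh2o,
        occlusions=(
            OcclusionSpec(start_s=3.0, duration_s=5.5, kind="insp"),
            OcclusionSpec(start_s=11.0, duration_s=5.5, kind="exp"),
        ),
        noise_sd_cmh2o=0.05,
        seed=seed,
    )


def gen_cohort(
    n_animals: int = 5,
    config: CohortConfig = CohortConfig(),
    seed: int = 0,
) -> CohortBundle:
    """Generate a deterministic multi-animal cohort bundle."""
    if n_animals < 1:
        raise ValueError("need at least one animal")
    rng = np.random.default_rng(seed)

    animals = []
    for i in range(n_animals):
        sub = rng.integers(0, 2**31, size=16)
        amp_lo, amp_hi = config.amplitude_range_cmh2o
        # spread amplitudes over the range deterministically, with jitter
        frac = i / max(n_animals - 1, 1)
        amp = amp_lo + (amp_hi - amp_lo) * frac + float(rng.normal(0, 0.5))
        edema = config.edema_scale * max(
            config.edema_intercept_hu
            + config.edema_per_amp_hu * amp
            + float(rng.normal(0, config.edema_jitter_sd_hu)),
            0.0,
        )
        ext = [n * s for n, s in zip(config.phantom_shape, config.phantom_spacing_mm)]
        semi = (0.42 * ext[0], 0.37 * ext[1], 0.21 * ext[2])
        lr_off = 0.27 * ext[2]
        phantom_base = PhantomCTParams(
            shape=config.phantom_shape,
            spacing_mm=config.phantom_spacing_mm,
            lung_centers_mm=((0.0, 0.0, -lr_off), (0.0, 0.0, lr_off)),
            semi_axes_mm=(semi, semi),
            base_mean_hu=config.base_mean_hu,
            vd_slope_hu=config.vd_slope_hu,
            noise_sd_hu=config.noise_sd_hu,
            edema_shift_hu=0.0,
            seed=int(sub[0]),
        )
        b_ct, b_mask, b_truth = gen_ct_phantom(phantom_base)
        p_ct, p_mask, p_truth = gen_ct_phantom(
            replace(phantom_base, edema_shift_hu=edema, seed=int(sub[1]))
        )

        # alternating mechanical/manual CC epochs
        ep = []
        for k in range(config.n_cc_epochs):
            mech = k % 2 == 0
            ep.append(
                EpochSpec(
                    label=f"cc_{k}",
                    start_s=k * config.epoch_duration_s,
                    end_s=(k + 1) * config.epoch_duration_s,
                    kind="cc_mechanical" if mech else "cc_manual",
                    comp_amplitude_cmh2o=amp if mech else amp * config.manual_amplitude_factor,
                )
            )
        cc_params = WaveformParams(
            fs_hz=config.fs_hz,
            duration_s=config.n_cc_epochs * config.epoch_duration_s,
            comp_amplitude_cmh2o=amp,
            comp_phase_s=float(rng.uniform(0, 0.5)),
            vent_phase_s=float(rng.uniform(0, 6.0)),
            vt_ml=config.vt_ml,
            cl_ml_cmh2o=config.cl_baseline_ml_cmh2o,
            ccw_ml_cmh2o=config.ccw_ml_cmh2o,
            epochs=tuple(ep),
            include_vascular=True,
            noise_sd_cmh2o=0.2,
            seed=int(sub[2]),
        )
        cc_trace, cc_truth = gen_pressure_traces(cc_params)

        cl_post = max(config.cl_baseline_ml_cmh2o - 0.1 * edema, 15.0)
        b_occl_trace, b_occl_truth = gen_pressure_traces(
            _occlusion_trace_params(config, config.cl_baseline_ml_cmh2o, int(sub[3]))
        )
        p_occl_trace, p_occl_truth = gen_pressure_traces(
            _occlusion_trace_params(config, cl_post, int(sub[4]))
        )

        sev = min(edema / 280.0, 1.0)
        panels = []
        for j, (label, qs, co, vo2) in enumerate(
            (
                ("cpr_min15_mechanical", 0.20 + 0.35 * sev, 3.0, 40.0),
                ("cpr_min20_manual", 0.12 + 0.30 * sev, 2.0, 30.0),
                ("post_rosc", 0.10 + 0.15 * sev, 2.4, 120.0),
            )
        ):
            gp = GasExchangeParams(
                qs_qt=min(qs, 0.95),
                co_l_min=co,
                hb_g_dl=9.0,
                fio2=1.0 if label != "post_rosc" else 0.3,
                vo2_ml_min=vo2,
                timepoint=label,
                seed=int(sub[5 + j]),
            )
            panel, _, gtruth = gen_bloodgas_panel(gp)
            panels.append((label, panel, co, gtruth))

        hemo = 0.03 + 0.12 * sev
        nonac = 0.08
        airspace = max(0.65 - 0.30 * sev, 0.05)
        acinar = 1.0 - airspace - nonac - hemo
        hist_truth_req = HistologyTruth(airspace, acinar, nonac, hemo)
        hist_img, hist_truth = gen_histology_image(
            config.histology_size, config.histology_size, hist_truth_req,
            texture_scale=12.0, seed=int(sub[8]),
        )

        ex_vivo = p_truth.weight_g * float(1.0 + rng.normal(0, 0.03))
        body_kg = float(max(rng.normal(33.0, 4.0), 20.0))
        w2d = 4.0 + 4.0 * sev + float(rng.normal(0, 0.15))
        wet = 10.0
        animals.append(
            CohortAnimal(
                subject_id=f"pig{i + 1:02d}",
                baseline_ct=b_ct,
                baseline_mask=b_mask,
                baseline_truth=b_truth,
                post_ct=p_ct,
                post_mask=p_mask,
                post_truth=p_truth,
                cc_trace=cc_trace,
                cc_truth=cc_truth,
                baseline_occl_trace=b_occl_trace,
                baseline_occl_truth=b_occl_truth,
                post_occl_trace=p_occl_trace,
                post_occl_truth=p_occl_truth,
                vt_ml=config.vt_ml,
                gas_panels=tuple(panels),
                histology=hist_img,
                histology_truth=hist_truth,
                ex_vivo_weight_g=ex_vivo,
                body_weight_kg=body_kg,
                wet_mass_g=wet,
                dry_mass_g=wet / w2d,
                mech_amplitude_cmh2o=amp,
                edema_shift_hu=edema,
            )
        )
    return CohortBundle(animals=tuple(animals), config=config, seed=seed)
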