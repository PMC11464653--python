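"""Airway and esophageal pressure processing during CPR.

Esophageal pressure (Pes) is the clinical surrogate for pleural pressure;
recorded together with airway pressure (Paw) it partitions respiratory
system mechanics into lung and chest-wall components.  This module covers:

- the occlusion test validating catheter placement (ΔPes/ΔPaw within
  [0.8, 1.2] during chest compressions against a closed airway),
- detection of individual chest-compression cycles and per-cycle Pes
  minimum / maximum / swing (ΔPes) statistics,
- plateau extraction from ≥ 5 s inspiratory/expiratory occlusions and the
  partitioned compliances (Crs, CL, Ccw) and driving pressures
  (ΔPrs = ΔPL + ΔPcw), related by 1/Crs = 1/CL + 1/Ccw,
- per-cycle coronary perfusion pressure from time-coincident diastolic
  aortic and right-atrial pressure.

Airway/esophageal pressures are in cmH2O, vascular pressures in mmHg;
:func:`cmh2o_to_mmhg` / :func:`mmhg_to_cmh2o` convert between them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "CC_EPOCH_KINDS",
    "EPOCH_KINDS",
    "CCCycles",
    "CCCycleStats",
    "CPPResult",
    "Epoch",
    "MechanicsPanel",
    "PressureTrace",
    "cmh2o_to_mmhg",
    "coronary_perfusion_pressure",
    "detect_cc_cycles",
    "mechanics_from_plateaus",
    "mmhg_to_cmh2o",
    "occlusion_test",
    "partitioned_mechanics",
    "pes_swing_stats",
    "plateau_values",
]

_CMH2O_PER_MMHG = 1.35951

EPOCH_KINDS = (
    "baseline",
    "cc_mechanical",
    "cc_manual",
    "occlusion_insp",
    "occlusion_exp",
    "occlusion_test",
    "post_rosc",
)
CC_EPOCH_KINDS = ("cc_mechanical", "cc_manual")

#: sanity band for detected compression rates (per minute)
CC_RATE_BAND = (50.0, 150.0)


def cmh2o_to_mmhg(p: float) -> float:
    return p / _CMH2O_PER_MMHG


def mmhg_to_cmh2o(p: float) -> float:
    return p * _CMH2O_PER_MMHG


@dataclass(frozen=True)
class Epoch:
    """A labelled time window on a trace."""

    label: str
    start_s: float
    end_s: float
    kind: str

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError(f"epoch {self.label!r}: end must exceed start")
        if self.kind not in EPOCH_KINDS:
            raise ValueError(f"unknown epoch kind {self.kind!r}")


@dataclass(frozen=True)
class PressureTrace:
    """Uniformly sampled Paw/Pes (cmH2O) with optional vascular channels (mmHg)."""

    fs_hz: float
    paw: np.ndarray
    pes: np.ndarray
    pao: np.ndarray | None = None
    pra: np.ndarray | None = None
    epochs: tuple[Epoch, ...] = ()

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        paw = np.asarray(self.paw, dtype=float)
        pes = np.asarray(self.pes, dtype=float)
        object.__setattr__(self, "paw", paw)
        object.__setattr__(self, "pes", pes)
        if paw.shape != pes.shape or paw.ndim != 1:
            raise ValueError("paw and pes must be 1-D arrays of equal length")
        for name in ("pao", "pra"):
            ch = getattr(self, name)
            if ch is not None:
                ch = np.asarray(ch, dtype=float)
                object.__setattr__(self, name, ch)
                if ch.shape != paw.shape:
                    raise ValueError(f"{name} length differs from paw")
        if not (np.all(np.isfinite(paw)) and np.all(np.isfinite(pes))):
            raise ValueError("pressures must be finite")
        dur = self.duration_s
        for e in self.epochs:
            if e.start_s < -1e-9 or e.end_s > dur + 1e-9:
                raise ValueError(f"epoch {e.label!r} lies outside the trace span")

    @property
    def n(self) -> int:
        return self.paw.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fs_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n) / self.fs_hz

    def sl(self, start_s: float, end_s: float) -> slice:
        """Sample slice covering [start_s, end_s)."""
        i0 = max(int(np.ceil(start_s * self.fs_hz - 1e-9)), 0)
        i1 = min(int(np.floor(end_s * self.fs_hz + 1e-9)), self.n)
        return slice(i0, i1)

    def epoch(self, label: str) -> Epoch:
        for e in self.epochs:
            if e.label == label:
                return e
        raise KeyError(f"no epoch labelled {label!r}")


@dataclass(frozen=True)
class CCCycles:
    """Detected chest-compression cycles within one epoch."""

    peak_indices: np.ndarray
    boundaries: np.ndarray  # (n_cycles, 2) sample index windows
    rate_per_min: float
    rate_warning: bool

    @property
    def n_cycles(self) -> int:
        return len(self.peak_indices)


@dataclass(frozen=True)
class CCCycleStats:
    """Per-compression Pes statistics and per-epoch ΔPes aggregates."""

    cycle_times_s: np.ndarray
    pes_min: np.ndarray
    pes_max: np.ndarray
    swing: np.ndarray
    epoch_mean_swing: dict[str, float] = field(default_factory=dict)
    epoch_cycle_count: dict[str, int] = field(default_factory=dict)
    epoch_rate_warning: dict[str, bool] = field(default_factory=dict)


@dataclass(frozen=True)
class MechanicsPanel:
    """Partitioned compliance / driving-pressure panel from an occlusion pair."""

    vt_ml: float
    pplat_cmh2o: float
    peep_total_cmh2o: float
    pes_insp_cmh2o: float
    pes_exp_cmh2o: float
    dp_rs_cmh2o: float
    dp_l_cmh2o: float
    dp_cw_cmh2o: float
    crs_ml_cmh2o: float
    cl_ml_cmh2o: float
    ccw_ml_cmh2o: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class CPPResult:
    """Per-cycle coronary perfusion pressure (mmHg)."""

    times_s: np.ndarray
    cpp_mmhg: np.ndarray
    mean_mmhg: float


def occlusion_test(trace: PressureTrace, epoch: Epoch) -> tuple[float, bool]:
    """Catheter-placement check: ΔPes/ΔPaw during an occluded compression.

    The ratio of peak-to-trough Pes to peak-to-trough Paw over the window;
    acceptable placement is 0.8 ≤ ratio ≤ 1.2.
    """
    s = trace.sl(epoch.start_s, epoch.end_s)
    dpaw = float(np.ptp(trace.paw[s]))
    dpes = float(np.ptp(trace.pes[s]))
    if dpaw < 1.0:
        raise ValueError(
            "no compression detected during occlusion test (ΔPaw < 1 cmH2O)"
        )
    ratio = dpes / dpaw
    return ratio, 0.8 <= ratio <= 1.2


def detect_cc_cycles(
    trace: PressureTrace,
    epoch: Epoch,
    band_hz: tuple[float, float] = (0.5, 5.0),
    min_prominence_cmh2o: float = 1.0,
) -> CCCycles:
    """Locate individual chest compressions within a CC epoch.

    Pes is band-passed around the compression frequency (zero-phase
    Butterworth, 0.5–5 Hz by default, separating ~1.7 Hz compressions from
    ~0.17 Hz ventilation) and peaks are found with a prominence threshold
    of 25% of the filtered signal's IQR-based swing, floored at
    ``min_prominence_cmh2o``.  Cycle windows are midpoints between
    successive peaks (epoch edges for the outermost cycles).
    """
    if epoch.kind not in CC_EPOCH_KINDS and epoch.kind != "occlusion_test":
        raise ValueError(f"epoch kind {epoch.kind!r} is not a compression epoch")
    s = trace.sl(epoch.start_s, epoch.end_s)
    x = trace.pes[s]
    if x.size < 10:
        raise ValueError("epoch too short for cycle detection")
    sos = signal.butter(2, band_hz, btype="bandpass", fs=trace.fs_hz, output="sos")
    xf = signal.sosfiltfilt(sos, x)
    q75, q25 = np.percentile(xf, [75, 25])
    prominence = max(0.25 * (q75 - q25), min_prominence_cmh2o)
    min_dist = max(int(trace.fs_hz * 60.0 / CC_RATE_BAND[1] * 0.8), 1)
    peaks, _ = signal.find_peaks(xf, prominence=prominence, distance=min_dist)
    if peaks.size == 0:
        raise ValueError("no compression cycles detected in epoch")
    # cycle windows: midpoints between neighbouring peaks
    mids = ((peaks[:-1] + peaks[1:]) // 2) if peaks.size > 1 else np.array([], int)
    starts = np.concatenate(([0], mids))
    ends = np.concatenate((mids, [x.size]))
    bounds = np.stack([starts, ends], axis=1) + s.start
    if peaks.size > 1:
        rate = 60.0 * trace.fs_hz / float(np.mean(np.diff(peaks)))
    else:
        rate = 60.0 / (x.size / trace.fs_hz)
    warning = not (CC_RATE_BAND[0] <= rate <= CC_RATE_BAND[1])
    return CCCycles(
        peak_indices=peaks + s.start,
        boundaries=bounds,
        rate_per_min=float(rate),
        rate_warning=warning,
    )


def pes_swing_stats(
    trace: PressureTrace,
    cycles_by_epoch: dict[str, CCCycles] | None = None,
    epochs: Sequence[Epoch] | None = None,
    smooth_s: float = 0.13,
) -> CCCycleStats:
    """Per-cycle Pes min/max/swing and per-epoch mean ΔPes.

    ``epochs`` defaults to every CC epoch on the trace; cycles are
    detected with :func:`detect_cc_cycles` unless supplied.  The reported
    per-epoch ΔPes is the mean of per-cycle swings within the epoch.
    Extremes are taken on Pes after local-quadratic (Savitzky–Golay)
    smoothing over ``smooth_s``: a second-order fit preserves the curved
    compression peak while suppressing the upward bias that raw min/max
    acquire under measurement noise.  Pass ``smooth_s=0`` for raw
    extremes (exact on noiseless signals).
    """
    if epochs is None:
        epochs = [e for e in trace.epochs if e.kind in CC_EPOCH_KINDS]
    if not epochs:
        raise ValueError("no chest-compression epochs to analyse")
    pes = trace.pes
    wlen = int(round(smooth_s * trace.fs_hz)) | 1
    if wlen >= 5:
        pes = signal.savgol_filter(pes, wlen, polyorder=2)
    times, mins, maxs = [], [], []
    epoch_mean: dict[str, float] = {}
    epoch_n: dict[str, int] = {}
    epoch_warn: dict[str, bool] = {}
    for e in epochs:
        cyc = (cycles_by_epoch or {}).get(e.label) or detect_cc_cycles(trace, e)
        if cyc.n_cycles == 0:
            raise ValueError(f"empty cycle list for epoch {e.label!r}")
        sw = []
        for (i0, i1), pk in zip(cyc.boundaries, cyc.peak_indices):
            seg = pes[i0:i1]
            times.append(pk / trace.fs_hz)
            mins.append(float(seg.min()))
            maxs.append(float(seg.max()))
            sw.append(maxs[-1] - mins[-1])
        epoch_mean[e.label] = float(np.mean(sw))
        epoch_n[e.label] = len(sw)
        epoch_warn[e.label] = cyc.rate_warning
    times = np.asarray(times)
    mins = np.asarray(mins)
    maxs = np.asarray(maxs)
    return CCCycleStats(
        cycle_times_s=times,
        pes_min=mins,
        pes_max=maxs,
        swing=maxs - mins,
        epoch_mean_swing=epoch_mean,
        epoch_cycle_count=epoch_n,
        epoch_rate_warning=epoch_warn,
    )


def plateau_values(
    trace: PressureTrace,
    epoch: Epoch,
    settle_cmh2o_per_s: float = 0.5,
    tail_s: float = 0.5,
    smooth_s: float = 0.25,
) -> tuple[float, float]:
    """Occlusion plateau pressures (Paw, Pes) from a ≥ 5 s hold.

    The pressure is smoothed over ``smooth_s``, its slope estimated over
    the same span, and the last contiguous segment with
    |dP/dt| < ``settle_cmh2o_per_s`` is taken as stable; the plateau is
    the mean over the final ``tail_s`` of that segment.
    """
    if epoch.end_s - epoch.start_s < 5.0 - 1e-9:
        raise ValueError("occlusion window must last at least 5 s")
    s = trace.sl(epoch.start_s, epoch.end_s)
    fs = trace.fs_hz
    w = max(int(round(smooth_s * fs)), 1)
    ntail = max(int(round(tail_s * fs)), 1)

    def plateau(x: np.ndarray) -> float:
        from scipy.ndimage import uniform_filter1d

        xs = uniform_filter1d(x, size=w, mode="nearest")
        # slope over ±smooth_s of the smoothed signal, robust to sample noise
        k = w
        pad = np.pad(xs, k, mode="edge")
        slope = (pad[2 * k :] - pad[: -2 * k]) * fs / (2 * k)
        stable = np.abs(slope) < settle_cmh2o_per_s
        # slope estimates within two smoothing widths of the end are
        # edge-dominated; the tail mean covers that region anyway
        idx = np.where(~stable[: -(2 * w)])[0]
        start = (idx[-1] + 1) if idx.size else 0
        if (x.size - 2 * w) - start < ntail:
            raise ValueError("no stable plateau segment found in occlusion window")
        return float(np.mean(x[-ntail:]))

    return plateau(trace.paw[s]), plateau(trace.pes[s])


def mechanics_from_plateaus(
    vt_ml: float,
    pplat_cmh2o: float,
    peep_total_cmh2o: float,
    pes_insp_cmh2o: float,
    pes_exp_cmh2o: float,
) -> MechanicsPanel:
    """Partitioned mechanics from occlusion plateau pressures.

    ΔPrs = Pplat − PEEPtot, ΔPcw = Pes(insp plateau) − Pes(exp plateau),
    ΔPL = ΔPrs − ΔPcw (the transpulmonary difference Paw − Pes at each
    occlusion); compliances are VT over the corresponding driving
    pressure, so 1/Crs = 1/CL + 1/Ccw holds identically.
    """
    if vt_ml <= 0:
        raise ValueError("tidal volume must be positive")
    dp_rs = pplat_cmh2o - peep_total_cmh2o
    dp_cw = pes_insp_cmh2o - pes_exp_cmh2o
    dp_l = dp_rs - dp_cw
    for name, dp in (("respiratory system", dp_rs), ("chest wall", dp_cw), ("lung", dp_l)):
        if dp <= 0:
            raise ValueError(f"non-positive driving pressure for the {name} ({dp:.3g} cmH2O)")
    return MechanicsPanel(
        vt_ml=float(vt_ml),
        pplat_cmh2o=float(pplat_cmh2o),
        peep_total_cmh2o=float(peep_total_cmh2o),
        pes_insp_cmh2o=float(pes_insp_cmh2o),
        pes_exp_cmh2o=float(pes_exp_cmh2o),
        dp_rs_cmh2o=float(dp_rs),
        dp_l_cmh2o=float(dp_l),
        dp_cw_cmh2o=float(dp_cw),
        crs_ml_cmh2o=float(vt_ml / dp_rs),
        cl_ml_cmh2o=float(vt_ml / dp_l),
        ccw_ml_cmh2o=float(vt_ml / dp_cw),
    )


def partitioned_mechanics(
    trace: PressureTrace,
    insp_epoch: Epoch,
    exp_epoch: Epoch,
    vt_ml: float,
) -> MechanicsPanel:
    """Partitioned mechanics from inspiratory and expiratory occlusions on a trace."""
    if insp_epoch.kind != "occlusion_insp" or exp_epoch.kind != "occlusion_exp":
        raise ValueError("epochs must be an inspiratory and an expiratory occlusion")
    pplat, pes_insp = plateau_values(trace, insp_epoch)
    peep, pes_exp = plateau_values(trace, exp_epoch)
    return mechanics_from_plateaus(vt_ml, pplat, peep, pes_insp, pes_exp)


def coronary_perfusion_pressure(
    trace: PressureTrace,
    epoch: Epoch,
    cycles: CCCycles | None = None,
) -> CPPResult:
    """Per-cycle CPP: diastolic aortic minus time-coincident right-atrial pressure.

    The diastolic instant of each compression cycle is the aortic-pressure
    minimum in the decompression phase; CPP subtracts the right-atrial
    pressure at the same sample.
    """
    if trace.pao is None or trace.pra is None:
        raise ValueError("trace lacks aortic and/or right-atrial channels")
    if cycles is None:
        cycles = detect_cc_cycles(trace, epoch)
    times, cpp = [], []
    for i0, i1 in cycles.boundaries:
        seg = trace.pao[i0:i1]
        j = i0 + int(np.argmin(seg))
        times.append(j / trace.fs_hz)
        cpp.append(float(trace.pao[j] - trace.pra[j]))
    cpp = np.asarray(cpp)
    return CPPResult(times_s=np.asarray(times), cpp_mmhg=cpp, mean_mmhg=float(cpp.mean()))
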