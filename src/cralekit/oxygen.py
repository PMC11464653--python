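"""Oxygen contents, delivery, uptake, and the Berggren shunt fraction.

Blood oxygen content combines hemoglobin-bound and dissolved oxygen,

    C = k1 · Hb · SO2 + k2 · PO2          (mL O2 / dL)

with k1 = 1.34 mL/g and k2 = 0.003 mL/dL/mmHg by default.  End-capillary
content uses the alveolar gas equation
``PAO2 = FiO2·(Pb − PH2O) − PaCO2/RQ`` with capillary saturation 1.0.
The venous-admixture (Berggren) shunt fraction is

    Qs/Qt = (CcO2 − CaO2) / (CcO2 − CvO2),

oxygen delivery DO2 = CO × CaO2 × 10 and uptake
VO2 = CO × (CaO2 − CvO2) × 10 (CO in L/min, contents in mL/dL).

All physical constants are configurable through :class:`O2Constants` and
are embedded in every :class:`O2Transport` result.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import NamedTuple

__all__ = [
    "BloodGasPanel",
    "O2Constants",
    "O2Transport",
    "ShuntResult",
    "alveolar_po2",
    "capillary_content",
    "o2_content",
    "oxygen_delivery",
    "oxygen_uptake",
    "shunt_fraction",
    "transport_panel",
]


@dataclass(frozen=True)
class O2Constants:
    """Physical constants of the oxygen-transport calculations.

    hb_binding_ml_g : O2 bound per gram of saturated hemoglobin (1.34)
    solubility_ml_dl_mmhg : dissolved O2 per mmHg (0.003)
    pb_mmhg / ph2o_mmhg : barometric and water-vapor pressure (760 / 47)
    rq : respiratory quotient in the alveolar gas equation (0.8)
    capillary_saturation : assumed end-capillary SO2 (1.0)
    """

    hb_binding_ml_g: float = 1.34
    solubility_ml_dl_mmhg: float = 0.003
    pb_mmhg: float = 760.0
    ph2o_mmhg: float = 47.0
    rq: float = 0.8
    capillary_saturation: float = 1.0

    def as_dict(self) -> dict:
        return asdict(self)


DEFAULT_CONSTANTS = O2Constants()


@dataclass(frozen=True)
class BloodGasPanel:
    """Arterial and mixed-venous blood-gas values at one timepoint."""

    pao2_mmhg: float
    paco2_mmhg: float
    pvo2_mmhg: float
    pvco2_mmhg: float
    sao2: float
    svo2: float
    hb_g_dl: float
    fio2: float
    lactate_mmol_l: float | None = None
    timepoint: str = ""

    def __post_init__(self) -> None:
        for name in ("pao2_mmhg", "paco2_mmhg", "pvo2_mmhg", "pvco2_mmhg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("sao2", "svo2"):
            s = getattr(self, name)
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.hb_g_dl <= 0:
            raise ValueError("hemoglobin must be positive (g/dL)")
        if not 0.0 < self.fio2 <= 1.0:
            raise ValueError("FiO2 must lie in (0, 1]")


class ShuntResult(NamedTuple):
    value: float
    clipped: bool


@dataclass(frozen=True)
class O2Transport:
    """Derived oxygen-transport panel."""

    cao2_ml_dl: float
    cvo2_ml_dl: float
    cco2_ml_dl: float
    do2_ml_min: float
    vo2_ml_min: float
    qs_qt: float
    shunt_clipped: bool
    vo2_implausible: bool
    constants: dict

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def o2_content(
    hb_g_dl: float, so2: float, po2_mmhg: float, constants: O2Constants = DEFAULT_CONSTANTS
) -> float:
    """Oxygen content (mL/dL) of blood with the given Hb, saturation and PO2."""
    if hb_g_dl <= 0:
        raise ValueError("hemoglobin must be positive")
    if not 0.0 <= so2 <= 1.0:
        raise ValueError("saturation must lie in [0, 1]")
    if po2_mmhg < 0:
        raise ValueError("PO2 must be non-negative")
    return constants.hb_binding_ml_g * hb_g_dl * so2 + constants.solubility_ml_dl_mmhg * po2_mmhg


def alveolar_po2(
    fio2: float, paco2_mmhg: float, constants: O2Constants = DEFAULT_CONSTANTS
) -> float:
    """Alveolar oxygen tension PAO2 = FiO2·(Pb − PH2O) − PaCO2/RQ."""
    if not 0.0 < fio2 <= 1.0:
        raise ValueError("FiO2 must lie in (0, 1]")
    if paco2_mmhg <= 0:
        raise ValueError("PaCO2 must be positive")
    pao2 = fio2 * (constants.pb_mmhg - constants.ph2o_mmhg) - paco2_mmhg / constants.rq
    if pao2 <= 0:
        raise ValueError("alveolar PO2 is non-positive for these inputs")
    return pao2


def capillary_content(
    fio2: float,
    paco2_mmhg: float,
    hb_g_dl: float,
    constants: O2Constants = DEFAULT_CONSTANTS,
) -> float:
    """End-capillary O2 content assuming equilibration with alveolar gas."""
    pao2 = alveolar_po2(fio2, paco2_mmhg, constants)
    return o2_content(hb_g_dl, constants.capillary_saturation, pao2, constants)


def shunt_fraction(cco2: float, cao2: float, cvo2: float) -> ShuntResult:
    """Berggren venous-admixture shunt Qs/Qt = (CcO2 − CaO2)/(CcO2 − CvO2).

    Noise in measured panels can push the raw ratio outside [0, 1]; the
    value is clipped and flagged rather than rejected.
    """
    denom = cco2 - cvo2
    if denom <= 0:
        raise ValueError("CcO2 must exceed CvO2 (non-positive shunt denominator)")
    raw = (cco2 - cao2) / denom
    clipped = raw < 0.0 or raw > 1.0
    return ShuntResult(min(max(raw, 0.0), 1.0), clipped)


def oxygen_delivery(co_l_min: float, cao2_ml_dl: float) -> float:
    """DO2 (mL/min) = cardiac output × arterial O2 content (×10 for dL→L)."""
    if co_l_min <= 0:
        raise ValueError("cardiac output must be positive")
    if cao2_ml_dl < 0:
        raise ValueError("arterial content must be non-negative")
    return co_l_min * cao2_ml_dl * 10.0


def oxygen_uptake(co_l_min: float, cao2_ml_dl: float, cvo2_ml_dl: float) -> float:
    """VO2 (mL/min) = cardiac output × (CaO2 − CvO2) × 10.

    A negative arterio-venous difference is returned as-is; callers
    (e.g. :func:`transport_panel`) flag it as physiologically implausible.
    """
    if co_l_min <= 0:
        raise ValueError("cardiac output must be positive")
    return co_l_min * (cao2_ml_dl - cvo2_ml_dl) * 10.0


def transport_panel(
    panel: BloodGasPanel,
    co_l_min: float,
    constants: O2Constants = DEFAULT_CONSTANTS,
) -> O2Transport:
    """Full oxygen-transport computation for one blood-gas panel."""
    cao2 = o2_content(panel.hb_g_dl, panel.sao2, panel.pao2_mmhg, constants)
    cvo2 = o2_content(panel.hb_g_dl, panel.svo2, panel.pvo2_mmhg, constants)
    cco2 = capillary_content(panel.fio2, panel.paco2_mmhg, panel.hb_g_dl, constants)
    qs = shunt_fraction(cco2, cao2, cvo2)
    vo2 = oxygen_uptake(co_l_min, cao2, cvo2)
    return O2Transport(
        cao2_ml_dl=cao2,
        cvo2_ml_dl=cvo2,
        cco2_ml_dl=cco2,
        do2_ml_min=oxygen_delivery(co_l_min, cao2),
        vo2_ml_min=vo2,
        qs_qt=qs.value,
        shunt_clipped=qs.clipped,
        vo2_implausible=vo2 < 0,
        constants=constants.as_dict(),
    )
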