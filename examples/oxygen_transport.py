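"""Oxygen transport and the Berggren shunt on a synthetic blood-gas panel.

The generator solves the venous-admixture system forward (true shunt
0.30, cardiac output 2 L/min, Hb 9 g/dL, VO2 60 mL/min); the analysis
inverts it from the emitted panel.  At zero measurement noise the
recovery is exact.
"""

from cralekit import oxygen as ox
from cralekit.synthetic import GasExchangeParams, gen_bloodgas_panel

params = GasExchangeParams(qs_qt=0.30, co_l_min=2.0, hb_g_dl=9.0,
                           fio2=1.0, vo2_ml_min=60.0, seed=0)
panel, _, truth = gen_bloodgas_panel(params)
t = ox.transport_panel(panel, co_l_min=params.co_l_min)

print(f"panel: PaO2 {panel.pao2_mmhg:.0f} mmHg  SaO2 {panel.sao2:.3f}  "
      f"PvO2 {panel.pvo2_mmhg:.0f} mmHg  SvO2 {panel.svo2:.3f}  Hb {panel.hb_g_dl} g/dL")
print(f"contents (mL O2/dL): capillary {t.cco2_ml_dl:.2f}  "
      f"arterial {t.cao2_ml_dl:.2f}  mixed venous {t.cvo2_ml_dl:.2f}")
print(f"DO2 {t.do2_ml_min:.0f} mL/min   VO2 {t.vo2_ml_min:.0f} mL/min")
print(f"Berggren shunt Qs/Qt = (CcO2-CaO2)/(CcO2-CvO2) = {t.qs_qt:.3f} "
      f"(truth {truth.qs_qt:.3f})")
print("about a third of pulmonary blood flow bypasses ventilated alveoli")
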