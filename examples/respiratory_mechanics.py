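"""Partitioned respiratory mechanics and ΔPes from simulated traces.

Builds two traces: an occlusion pair (inspiratory + expiratory hold,
each > 5 s) from which compliance and driving pressure are partitioned
into lung and chest-wall components, and a chest-compression trace from
which per-compression esophageal-pressure swings (ΔPes) are measured.
"""

from cralekit import mechanics as mech
from cralekit.synthetic import EpochSpec, OcclusionSpec, WaveformParams, gen_pressure_traces

# occlusion maneuvers, no compressions: CL=50, Ccw=100 mL/cmH2O
occl = WaveformParams(
    duration_s=18.0,
    comp_amplitude_cmh2o=0.0,
    cl_ml_cmh2o=50.0,
    ccw_ml_cmh2o=100.0,
    occlusions=(OcclusionSpec(3.0, 5.5, "insp"), OcclusionSpec(11.0, 5.5, "exp")),
    noise_sd_cmh2o=0.05,
    seed=2,
)
trace, truth = gen_pressure_traces(occl)
panel = mech.partitioned_mechanics(
    trace, trace.epoch("occl_insp_0"), trace.epoch("occl_exp_1"), vt_ml=500.0
)
print("--- partitioned mechanics (truth CL=50, Ccw=100, Crs=33.3) ---")
print(f"Crs {panel.crs_ml_cmh2o:5.1f}  CL {panel.cl_ml_cmh2o:5.1f}  "
      f"Ccw {panel.ccw_ml_cmh2o:5.1f} mL/cmH2O")
print(f"driving pressures  rs {panel.dp_rs_cmh2o:.1f}  lung {panel.dp_l_cmh2o:.1f}  "
      f"chest wall {panel.dp_cw_cmh2o:.1f} cmH2O")
print(f"series identity 1/Crs = 1/CL + 1/Ccw holds to "
      f"{abs(1/panel.crs_ml_cmh2o - 1/panel.cl_ml_cmh2o - 1/panel.ccw_ml_cmh2o):.1e}\n")

# compressions at 102/min: mechanical (strong) then manual (weaker) epoch
cc = WaveformParams(
    duration_s=60.0,
    epochs=(
        EpochSpec("mechanical", 0.0, 30.0, "cc_mechanical", 24.0),
        EpochSpec("manual", 30.0, 60.0, "cc_manual", 14.0),
    ),
    noise_sd_cmh2o=0.2,
    seed=3,
)
trace2, truth2 = gen_pressure_traces(cc)
stats = mech.pes_swing_stats(trace2)
print("--- ΔPes per 30-s compression epoch (mean of per-cycle swings) ---")
for label, swing in stats.epoch_mean_swing.items():
    print(f"{label:10s} ΔPes {swing:5.1f} cmH2O "
          f"(truth {truth2.epoch_mean_swing[label]:.1f}, "
          f"{stats.epoch_cycle_count[label]} compressions)")
print("larger compression amplitude -> larger intrathoracic pressure swing")
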