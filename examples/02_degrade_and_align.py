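"""Degrade a reference recording into a sensor recording and recover the
misalignment.

A sit-to-stand recording is degraded with a rigid misalignment (6 deg yaw,
~300 mm translation), a 0.35 s clock offset, resampling to 30 Hz and
per-body-region noise.  The alignment stage then estimates the
sensor-to-reference transform by pooled Kabsch registration on the trunk
landmarks, and the printout compares it against the known truth.
"""

import numpy as np

from mocapval import SensorModel, degrade, register_recordings, simulate_sas

reference = simulate_sas()
sensor, truth = degrade(reference, SensorModel.default(), seed=42)

declared_offset = float(
    sensor.recording.timestamps[0] - reference.recording.timestamps[0]
)
estimate = register_recordings(
    reference.recording, sensor.recording, time_offset_s=declared_offset
)

rot_err = estimate.compose(truth.inverse()).rotation_angle_deg()
trans_err = np.linalg.norm(estimate.translation - truth.translation)
print(f"declared clock offset : {declared_offset:8.3f} s (true 0.350)")
print(f"rotation error        : {rot_err:8.4f} deg")
print(f"translation error     : {trans_err:8.2f} mm")
print(f"registration residual : {estimate.residual_rms_mm:8.2f} mm RMS")
print()
print(
    "The residual reflects the injected landmark noise; the transform"
    " itself is recovered to a fraction of a degree because registration"
    " pools thousands of frames of the low-noise trunk landmarks."
)
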