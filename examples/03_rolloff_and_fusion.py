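"""Sensitivity roll-off of one reference arm and the dual-arm compensation.

Steps a simulated mirror through depth to trace the sinc-shaped sensitivity
decay caused by the finite per-pixel spectral width, then shows how two
reference arms with an ~11 mm zero-delay offset fold that decay into a
V-shaped combined profile whose drop-off is the value at mid-depth.
"""

import numpy as np

from asoct import (
    SourceSpectrum,
    max_scan_depth,
    rolloff_experiment,
    system_preset,
)
from asoct.fusion import BScanFrame, RigidTransform, overlap_frames

config = system_preset("system3")
source = SourceSpectrum()
zmax = max_scan_depth(source.center_wavelength, config.delta_lambda)

depths = np.linspace(0.5, 0.9 * zmax, 8)
curve = rolloff_experiment(config, source, depths, seed=0)
print("single-arm roll-off (mirror stepping, OD 2.0 compensated):")
for z, s in zip(curve.depths, curve.sensitivities):
    print(f"  depth {z:5.2f} mm  sensitivity {s:6.2f} dB")
print(f"  drop over the range: {curve.dropoff_db:.2f} dB")
print()

# hand-computable fusion case: linear 60 dB/11 mm roll-off, arms offset 11 mm
dpp = 11.0 / 1000
f1 = BScanFrame(np.full((1000, 32), -20.0), 1, "top", dpp, 0.01)
f2 = BScanFrame(np.full((1000, 32), -20.0), 2, "top", dpp, 0.01)
model = lambda d: 10.0 ** (-(60.0 / 11.0) * np.abs(np.asarray(d, float)) / 10.0)
fused = overlap_frames(f1, f2, RigidTransform(0.0, (0.0, 0.0)),
                       nominal_offset_px=1, sensitivity_model=model)
print("dual-arm fusion of a linear 60 dB / 11 mm roll-off, offset 11 mm:")
print(f"  combined drop-off {fused.combined_dropoff_db:.1f} dB "
      f"(single arm would lose 60 dB); the profile minimum sits at "
      f"{fused.depth_axis[np.argmin(fused.sensitivity_profile)]:.2f} mm, "
      f"i.e. mid-depth.")
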