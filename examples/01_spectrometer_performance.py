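"""Analytic performance figures of the three spectrometer designs.

Builds each preset (CCD 2048 px, CCD 4096 px, CMOS 4096 px sharing one
optical train: 1800 lines/mm grating, 240 mm lens, 10 um pixels) and prints
its per-pixel spectral resolution, the scan depth that resolution supports,
the source-limited axial resolution, and how much of the 50 nm-FWHM
Gaussian spectrum the camera window captures.
"""

import pandas as pd

from asoct import performance_figures, system_preset

rows = [performance_figures(system_preset(n)).as_dict()
        for n in ("system1", "system2", "system3")]
df = pd.DataFrame(rows).round(
    {"delta_lambda_nm": 4, "max_depth_air_mm": 2,
     "theoretical_axial_resolution_um": 2, "depth_per_pixel_mm": 5,
     "captured_energy_fraction": 3}
)
print(df.to_string(index=False))
print()
print("All three share delta_lambda ~0.0152 nm -> ~11.6 mm scan depth in air.")
print("The 2048-px camera captures only ~54% of the source spectrum (worse")
print("axial resolution); the 4096-px cameras capture ~86%.")
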