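"""Point-spread-function metrology: axial resolution vs camera window.

Synthesizes a single-mirror interferogram at 0.5 mm path difference,
reconstructs it, and measures the amplitude FWHM for (a) a hypothetical
detector wide enough to pass the whole Gaussian spectrum, (b) the 4096-px
window, (c) the 2048-px window.  Spectral truncation broadens the PSF.
"""

from asoct import (
    SourceSpectrum,
    SpectrometerConfig,
    measure_psf,
    reconstruct_ascan,
    synthesize_interferogram,
    system_preset,
    theoretical_axial_resolution,
)

source = SourceSpectrum()
wide = SpectrometerConfig(name="wide", camera="CCD", n_pixels=10240, max_line_rate=1.0)

print(f"closed form (840 nm, 50 nm FWHM): "
      f"{theoretical_axial_resolution(840.0, 50.0):.2f} um")
for cfg in (wide, system_preset("system2"), system_preset("system1")):
    ig = synthesize_interferogram([(0.5, 0.05)], cfg, source, n_sub=1)
    ascan = reconstruct_ascan(ig, cfg, source, window=None, pad_factor=16)
    m = measure_psf(ascan)
    print(f"{cfg.name:8s} ({cfg.n_pixels:5d} px window): FWHM {m.fwhm:5.2f} um "
          f"at depth {m.peak_depth:.3f} mm")
print()
print("The full spectrum reproduces the coherence-length formula; the 4096-px")
print("window (~62 nm) truncates the Gaussian and costs ~30% of resolution,")
print("the 2048-px window roughly doubles the FWHM.")
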