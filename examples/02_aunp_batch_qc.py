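"""UV-Vis quality control of a gold-nanoparticle batch.

Builds a synthetic citrate-sphere extinction band whose peak-to-450 nm
ratio corresponds to a ~14 nm batch, then estimates diameter and molar
concentration from the spectrum alone and the dilution needed to reach
the 6 nM working concentration.
"""

import numpy as np

from conan_assay import Spectrum, dilution_to_working, qc_aunp_batch

wavelengths = np.arange(400.0, 901.0, 1.0)
absorbance = np.exp(-((wavelengths - 519.0) ** 2) / (2 * 70.6**2))
spectrum = Spectrum(wavelengths, absorbance, well_id="batch")

# effective optical path of ~100 ul in a flat-bottom 96-well plate
batch = qc_aunp_batch(spectrum, path_length_cm=0.30, batch_id="demo-batch")
print(f"LSPR peak:      {batch.lspr_wavelength_nm:.0f} nm "
      "(sharp single band -> monodispersed spheres)")
print(f"diameter:       {batch.diameter_nm:.1f} nm  (UV-Vis sizing)")
print(f"concentration:  {batch.concentration_nM:.1f} nM")
print(f"dilute 1:{dilution_to_working(batch):.2f} to reach the 6 nM working level")
print(f"QC flags:       {batch.flags or 'none'}")
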