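"""Calibrate a raw millidegree CD scan into molar units.

Builds a small synthetic far-UV scan the way a spectropolarimeter would
export it (observed ellipticity in millidegrees), then converts it to mean
residue ellipticity and molar circular dichroism.
"""

import numpy as np

from chirospec import SampleInfo, Spectrum, calibration

grid = np.arange(185.0, 251.0)
theta_mdeg = 20.0 * np.exp(-0.5 * ((grid - 192) / 4) ** 2) \
    - 25.0 * np.exp(-0.5 * ((grid - 204) / 5) ** 2)
scan = Spectrum(grid, theta_mdeg)                      # unit: millidegrees

# 20 µM protein, 0.1 cm cuvette, 70 peptide bonds
info = SampleInfo(protein_conc=20e-6, pathlength=0.1, n_bonds=70)

mre = calibration.to_mean_residue_ellipticity(scan, info)
deps = calibration.to_delta_epsilon(calibration.to_molar_ellipticity(scan, info))

print(f"observed ellipticity at 192 nm : {scan.value_at(192):8.2f} mdeg")
print(f"mean residue ellipticity       : {mre.value_at(192):8.1f} deg cm^2 dmol^-1")
print(f"molar CD (delta-epsilon)       : {deps.value_at(192):8.3f} M^-1 cm^-1")
print()
print("The mean residue ellipticity removes the linear dependence on "
      "concentration, pathlength and chain length, so spectra of different "
      "proteins become directly comparable; delta-epsilon is the same signal "
      "expressed as a differential molar absorptivity.")
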