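"""Recover a known enantiomer composition from noisy synthetic spectra.

Generates a conjugate/parent spectrum pair with a known signed optical
purity, partial labeling and additive noise, then runs the analysis chain
(normalized difference → couplet-amplitude estimate → calculus) and compares
against the generating truth.
"""

import numpy as np

from chirospec import enantiomer_calculus, estimate_op, normalized_difference
from chirospec.synthetic import CoupletModel, MixtureSpec, generate_conjugate_spectrum

grid = np.arange(240.0, 331.0)
model = CoupletModel()                       # Λ couplet: +295 nm / −270 nm lobes
mix = MixtureSpec(frac_lambda=0.17, frac_delta=0.83,   # strongly Δ-enriched
                  label_ratio=0.93, noise_sd=2.0, seed=42)

conjugate, parent, truth = generate_conjugate_spectrum(model, mix, grid)
diff = normalized_difference(conjugate, parent, mix.label_ratio)
op_hat = estimate_op(diff, model.spectrum(grid))
result = enantiomer_calculus(op_hat * 114.0, 114.0)

print(f"true signed op      : {truth['op_true']:+.3f}")
print(f"recovered signed op : {op_hat:+.3f}")
print(f"ee                  : {result.ee_percent:.1f}%  (major: {result.major})")
print(f"mole fractions      : Λ {result.frac_lambda:.3f} / Δ {result.frac_delta:.3f}")
print()
print("The least-squares projection onto the known couplet shape averages "
      "the per-point noise over the whole near-UV band, so the recovered op "
      "lands within a few thousandths of the generating value even at 2 "
      "M^-1 cm^-1 noise and partial labeling.")
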