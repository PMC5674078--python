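"""Extract absorbance from time-domain pulses and preprocess it.

Builds a toy sample/reference pulse pair, Fourier-transforms them into a
decadic absorbance spectrum, crops the 20-80 cm^-1 analysis band and applies
standard normal variate (SNV) normalization — the exact chain that feeds the
multivariate models.
"""

import numpy as np

from thzchem import TimeDomainTrace, compute_absorbance, crop_band, snv

t = np.arange(640) * 0.1  # ps
pulse = np.exp(-(((t - 12.0) / 0.35) ** 2)) * np.cos(2 * np.pi * (t - 12.0) / 1.2)
reference = TimeDomainTrace(t, pulse, "reference")
sample = TimeDomainTrace(t, 0.1 * pulse, "sample")  # 10x amplitude attenuation

spec = compute_absorbance(sample, reference)
print(f"absorbance is flat at A = {spec.absorbance[5]:.3f} "
      "(-2*log10(0.1): a pure 10x amplitude attenuation under the power convention)")

band = crop_band(spec, 20.0, 80.0)
print(f"cropped band: {band.wavenumber.size} points, "
      f"{band.wavenumber[0]:.2f}-{band.wavenumber[-1]:.2f} cm^-1")

rng = np.random.default_rng(0)
noisy = band.absorbance + 0.05 * rng.standard_normal(band.absorbance.size)
z = snv(noisy)
print(f"after SNV: mean = {z.mean():.2e}, sample sd = {z.std(ddof=1):.6f}")
print("SNV removes per-pellet offset and scale so every spectrum contributes "
      "equally to PCA and PLS.")
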