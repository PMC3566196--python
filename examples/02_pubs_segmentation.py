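"""Segment a lumen with pulsatility-based segmentation (PUBS).

A seed pixel supplies the reference cardiac waveform; every pixel is
scored by the correlation of its velocity-time series with that
reference, and the seed's 4-connected supra-threshold region is the
lumen. The example runs noiseless (exact recovery) and at lumen-centre
SNR 10, reporting the Dice overlap with the true disc.
"""

import numpy as np

import cranioflow as cf

t = np.arange(32) / 32
wave = 4.0 * (0.8 * np.sin(2 * np.pi * t) + 0.2 * np.sin(4 * np.pi * t + 1))
spec = cf.PlugSpec("CSF", (24.0, 24.0), 0.36, tuple(wave),
                   radial_profile=lambda r: 1.0 - 0.5 * r ** 4)

for noise_sd, label in ((0.0, "noiseless"), (0.4 * np.pi / 8.0, "SNR ~ 10")):
    p = cf.AcquisitionParams(venc=8.0, pixel_area=9e-4, noise_sd=noise_sd)
    scan = cf.generate_cine([spec], p, p, shape=(48, 48), seed=2)
    mask = cf.segment_from_seed(scan.high, (24, 24), label="CSF")
    dice = cf.dice_overlap(mask, scan.masks["CSF"])
    print(f"{label:10s}: {mask.n_pixels:3d} px segmented / "
          f"{scan.masks['CSF'].n_pixels} true, Dice = {dice:.3f}")

print("\nDice 1.0 means the recovered pixel set equals the true lumen;")
print("with phase noise the rim may gain or lose single pixels.")
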