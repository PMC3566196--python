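"""Shared fixtures: small synthetic scans with known ground truth."""

import numpy as np
import pytest

import cranioflow as cf


def blunt_profile(s):
    """Separable blunt amplitude profile: 1 at the centre, 0.5 at the wall."""
    return 1.0 - 0.5 * np.asarray(s) ** 4


def pulse_waveform(n_phases=32, amplitude=4.0):
    """A two-harmonic pulsatile velocity waveform (cm/s), zero mean."""
    t = np.arange(n_phases) / n_phases
    return amplitude * (0.8 * np.sin(2 * np.pi * t)
                        + 0.2 * np.sin(4 * np.pi * t + 1.0))


def separable_disc_scan(noise_sd=0.0, seed=0, radius_px=12, shape=(48, 48),
                        amplitude=4.0, venc=8.0):
    """One separable (single-waveform) disc on a static background.

    Lumen-centre velocity SNR is amplitude / (venc * noise_sd / pi).
    """
    spacing = 0.03
    spec = cf.PlugSpec("CSF", (shape[0] / 2, shape[1] / 2),
                       radius_px * spacing,
                       tuple(pulse_waveform(amplitude=amplitude)),
                       radial_profile=blunt_profile)
    params = cf.AcquisitionParams(venc=venc, pixel_area=spacing ** 2,
                                  noise_sd=noise_sd)
    params_low = cf.AcquisitionParams(venc=venc, pixel_area=spacing ** 2,
                                      noise_sd=noise_sd)
    return cf.generate_cine([spec], params, params_low, shape=shape, seed=seed)


@pytest.fixture
def noiseless_disc():
    return separable_disc_scan()


@pytest.fixture
def default_scan():
    """The ten-lumen default exam, noiseless."""
    return cf.default_exam(seed=0)
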